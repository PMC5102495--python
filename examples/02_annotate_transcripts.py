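"""Annotate simulated IgG heavy-chain transcripts and check the calls.

Simulates a small mutation-free repertoire (so every call is exactly
recoverable), runs the per-transcript pipeline — variable-region
extraction at the CH1 motif GCCTCCACC, QC, FR-only IGHV assignment,
FR4H/IGHJ assignment, CDR3H delimitation, IGHD search in both
orientations — and compares calls against the generator's ground truth.
"""

from bovig import SimConfig, make_toy_germline_db, simulate_repertoire, annotate_all

cfg = SimConfig(seed=2, groups=("A",), n_records_per_group=40,
                mutation_rate=0.0, junction_trim_range=(0, 0),
                antisense_d_prob=0.25,
                conversion={"prob": 0.0},
                qc_defect_probs={"premature_stop": 0.0, "truncation": 0.0})
db = make_toy_germline_db(cfg)
records, truths = simulate_repertoire(db, cfg)
recs, annotations = annotate_all(records, db)

print(f"{len(records)} transcripts, {len(annotations)} pass QC\n")
print("first five annotations (call <- truth):")
by_id = {a.sample_id: a for a in annotations}
for t in truths[:5]:
    a = by_id[t.sample_id]
    want_d = t.true_d + ("_as" if t.d_orientation == "antisense" else "")
    print(f"  {t.sample_id}: V {a.v_call.candidates[0]:14s} <- {t.true_v:14s} "
          f"D {a.d_call.candidates[0]:10s} <- {want_d:10s} "
          f"J {a.j_call.candidates[0]}  CDR3H {a.cdr3_length} aa "
          f"(group {a.cdr3_group})")

hits = sum(
    by_id[t.sample_id].v_call.candidates == [t.true_v]
    and by_id[t.sample_id].j_call.candidates == [t.true_j]
    for t in truths
)
print(f"\nexact V and J recovery: {hits}/{len(truths)}")
# With zero somatic mutation and verbatim junction segments, recovery is
# exact: minimal divergence against the true germline is 0 and unique.
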