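import numpy as np
import pytest

from bovig import SimConfig, make_toy_germline_db, simulate_repertoire
from bovig.annotate import (
    CH1_MOTIF,
    SampleRecord,
    annotate_all,
    annotate_record,
    assign_d,
    assign_j_fr4,
    assign_v,
    delimit_cdr3,
    extract_variable_region,
    qc_filter,
)
from bovig.germline import (
    GermlineDatabase,
    GermlineSegment,
    number_functional_v,
    prepare_database,
)
from bovig.numbering import cattle_scheme
from bovig.simdata import CH1_STUB, _random_functional_v
from conftest import CLEAN

SCHEME = cattle_scheme()


def _recovered(truths, annotations):
    """Fraction of records whose unique calls equal the planted truth."""
    by_id = {a.sample_id: a for a in annotations}
    hits = 0
    for t in truths:
        a = by_id.get(t.sample_id)
        if a is None:
            continue
        want_d = t.true_d + ("_as" if t.d_orientation == "antisense" else "")
        if (
            a.v_call.candidates == [t.true_v]
            and a.d_call.candidates == [want_d]
            and a.j_call.candidates == [t.true_j]
            and a.d_call.orientation == t.d_orientation
        ):
            hits += 1
    return hits / len(truths)


class TestExtraction:
    def test_prefix_before_first_motif(self):
        rec = SampleRecord(id="s", raw_sequence="ACGTTT" + CH1_MOTIF + "AAAA")
        extract_variable_region(rec)
        assert rec.variable_region == "ACGTTT"
        assert rec.qc_status == "pass"

    def test_motif_absent_fails(self):
        rec = extract_variable_region(SampleRecord(id="s", raw_sequence="ACGT" * 30))
        assert (rec.qc_status, rec.qc_reason) == ("fail", "no_motif")

    def test_motif_at_start_is_incomplete(self):
        rec = extract_variable_region(SampleRecord(id="s", raw_sequence=CH1_MOTIF + "AAA"))
        assert (rec.qc_status, rec.qc_reason) == ("fail", "incomplete")

    def test_frame_anchored_at_motif(self):
        # 7-nt variable region: 1-nt 5' overhang is trimmed, 2 codons remain
        rec = SampleRecord(id="s", raw_sequence="TATGCCC" + CH1_MOTIF)
        extract_variable_region(rec)
        assert rec.translation == "MP"


class TestQC:
    def test_planted_stop_fails(self, toy_db, clean_repertoire):
        records, truths = clean_repertoire
        sid, group, seq = records[0]
        # overwrite one in-frame FR3H codon with TAA
        broken = seq[:240] + "TAA" + seq[243:]
        rec = extract_variable_region(SampleRecord(id=sid, raw_sequence=broken))
        rec = qc_filter(rec, toy_db)
        assert (rec.qc_status, rec.qc_reason) == ("fail", "premature_stop")

    def test_truncated_record_fails_incomplete(self, toy_db, clean_repertoire):
        records, _ = clean_repertoire
        sid, group, seq = records[0]
        rec = extract_variable_region(SampleRecord(id=sid, raw_sequence=seq[80:]))
        rec = qc_filter(rec, toy_db)
        assert (rec.qc_status, rec.qc_reason) == ("fail", "incomplete")

    def test_clean_record_passes(self, toy_db, clean_repertoire):
        records, _ = clean_repertoire
        sid, group, seq = records[0]
        rec = qc_filter(extract_variable_region(SampleRecord(id=sid, raw_sequence=seq)), toy_db)
        assert rec.qc_status == "pass"


class TestAssignV:
    def test_exact_copy_has_zero_divergence(self, toy_db):
        group = toy_db.v_references(functional_only=True)[0]
        nmap = toy_db.numbering[group.id]
        v_nt = nmap.mapped_sequence(group, SCHEME)
        j_id = sorted(toy_db.fr4_templates)[0]
        seq = v_nt + "GGGACGTTTGGGACGTTTGGG" + toy_db.fr4_templates[j_id] + CH1_STUB
        rec = extract_variable_region(SampleRecord(id="s", raw_sequence=seq))
        call = assign_v(rec, toy_db)
        assert call.candidates == [group.id]
        assert call.divergence == 0.0

    def test_equidistant_references_tie(self):
        # two references differing at exactly two FR positions; the sample
        # carries one base from each -> equal divergence, ambiguous call
        base = _random_functional_v(np.random.default_rng(123), SCHEME)
        positions = SCHEME.v_positions()
        i1 = 3 * positions.index(45)  # FR2H
        i2 = 3 * positions.index(80)  # FR3H
        def substitute(seq_list, i):
            codon_start = 3 * (i // 3)
            for b in "ACGT":
                if b == seq_list[i]:
                    continue
                trial = seq_list[codon_start : codon_start + 3]
                trial[i - codon_start] = b
                if "".join(trial) not in ("TAA", "TAG", "TGA"):
                    seq_list[i] = b
                    return

        other = list(base)
        substitute(other, i1)
        substitute(other, i2)
        db = GermlineDatabase(SCHEME)
        db.add(GermlineSegment(id="IGHV1", segment_class="V", sequence=base))
        db.add(GermlineSegment(id="IGHV2", segment_class="V", sequence="".join(other)))
        db.add(GermlineSegment(id="IGHD1", segment_class="D", sequence="ACGGATTACGGATC"))
        db.add(GermlineSegment(id="IGHJ1", segment_class="J",
                               sequence="ACGGTTACCGGTACTTGGATCCGGCAAGGGACCACGGTCACCGTCTCCTCA"[:51]))
        db = prepare_database(db)
        sample_v = list(base)
        sample_v[i1] = other[i1]  # matches IGHV2 here, IGHV1 at i2
        seq = "".join(sample_v) + "GGGACGTTTGGG" + db.fr4_templates["IGHJ1"] + CH1_STUB
        rec = extract_variable_region(SampleRecord(id="s", raw_sequence=seq))
        call = assign_v(rec, db)
        assert call.candidates == ["IGHV1", "IGHV2"]

    def test_zero_mutation_repertoire_fully_recovered(self, toy_db, clean_repertoire):
        records, truths = clean_repertoire
        _, annotations = annotate_all(records, toy_db)
        assert len(annotations) == len(records)
        assert _recovered(truths, annotations) == 1.0


class TestAssignJ:
    def test_verbatim_template(self, toy_db, clean_repertoire):
        records, truths = clean_repertoire
        rec = extract_variable_region(
            SampleRecord(id="s", raw_sequence=records[0][2])
        )
        call = assign_j_fr4(rec, toy_db)
        assert call.candidates == [truths[0].true_j]
        assert call.divergence == 0.0

    def test_two_substitutions_give_2_over_33(self, toy_db, clean_repertoire):
        records, truths = clean_repertoire
        seq = records[0][2]
        var_len = len(seq) - len(CH1_STUB)
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        s = list(seq)
        for off in (5, 20):
            i = var_len - 33 + off
            s[i] = swap[s[i]]
        rec = extract_variable_region(SampleRecord(id="s", raw_sequence="".join(s)))
        call = assign_j_fr4(rec, toy_db)
        assert call.candidates == [truths[0].true_j]
        assert call.divergence == pytest.approx(2 / 33)

    def test_too_short_variable_region_rejected(self, toy_db):
        rec = extract_variable_region(
            SampleRecord(id="s", raw_sequence="ACGTACGTAC" + CH1_MOTIF)
        )
        with pytest.raises(ValueError):
            assign_j_fr4(rec, toy_db)


class TestCdr3AndD:
    def test_planted_lengths_and_groups(self, toy_db, clean_repertoire):
        records, truths = clean_repertoire
        _, annotations = annotate_all(records, toy_db)
        by_id = {a.sample_id: a for a in annotations}
        for t in truths:
            a = by_id[t.sample_id]
            assert a.cdr3_length == t.cdr3_length
            assert a.cdr3_group == (1 if t.cdr3_length <= 10 else 2 if t.cdr3_length <= 47 else 3)
            assert len(a.cdr3_labels) == t.cdr3_length

    def test_ultralong_cdr3_extended_labels(self):
        cdr3, length, group, labels = delimit_cdr3("A" * (65 * 3 + 33), 0)
        assert (length, group) == (65, 3)
        assert sum(1 for p in labels if p.sub is not None) == 52

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            delimit_cdr3("ACGT" * 10, 20)

    def test_sense_and_antisense_d_recovered(self, toy_db, clean_repertoire):
        records, truths = clean_repertoire
        _, annotations = annotate_all(records, toy_db)
        by_id = {a.sample_id: a for a in annotations}
        orientations = set()
        for t in truths:
            a = by_id[t.sample_id]
            want = t.true_d + ("_as" if t.d_orientation == "antisense" else "")
            assert a.d_call.candidates == [want]
            orientations.add(t.d_orientation)
        assert orientations == {"sense", "antisense"}

    def test_empty_cdr3_is_undetermined(self, toy_db):
        call = assign_d("", toy_db)
        assert call.undetermined

    def test_short_cdr3_call_low_confidence(self, toy_db):
        d = sorted(toy_db.by_class("D"), key=lambda s: len(s.sequence))[0]
        call = assign_d(d.sequence[:5], toy_db)
        assert call.undetermined or call.low_confidence


class TestPipelineProperties:
    @pytest.mark.parametrize("procedure", [1, 2, 3])
    def test_procedures_all_run(self, toy_db, clean_repertoire, procedure):
        records, _ = clean_repertoire
        _, annotations = annotate_all(records[:5], toy_db, d_procedure=procedure)
        assert all(a.d_call.procedure == f"procedure{procedure}" for a in annotations)

    def test_recovery_degrades_monotonically_with_mutation(self, toy_db):
        rates = [0.0, 0.02, 0.05, 0.10]
        recovered = []
        for rate in rates:
            cfg = SimConfig(seed=42, n_v_functional=6, n_v_pseudo=3,
                            identical_v_pairs=1, n_d=5, n_j=2,
                            groups=("A",), n_records_per_group=40,
                            antisense_d_prob=0.25, **{**CLEAN, "mutation_rate": rate})
            records, truths = simulate_repertoire(toy_db, cfg)
            _, annotations = annotate_all(records, toy_db)
            recovered.append(_recovered(truths, annotations))
        assert recovered[0] == 1.0
        assert all(a >= b - 0.05 for a, b in zip(recovered, recovered[1:]))

    def test_annotation_is_deterministic(self, toy_db, clean_repertoire):
        records, _ = clean_repertoire
        _, first = annotate_all(records[:10], toy_db)
        _, second = annotate_all(records[:10], toy_db)
        for a, b in zip(first, second):
            assert a.v_call == b.v_call
            assert a.d_call == b.d_call
            assert a.j_call == b.j_call

    def test_every_pass_record_has_nonempty_calls(self, toy_db, clean_repertoire):
        records, _ = clean_repertoire
        recs, annotations = annotate_all(records, toy_db)
        assert len(annotations) == sum(r.qc_status == "pass" for r in recs)
        for a in annotations:
            assert a.v_call.candidates and a.j_call.candidates
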