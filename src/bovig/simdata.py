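"""Seeded generator of toy germline references and simulated transcripts.

The generator emulates the anatomy of the cloned IgG heavy-chain
transcripts the framework was designed for: a rearranged variable region
``V + N + D + N + J`` followed by the CH1-start motif ``GCCTCCACC`` and
a constant-region stub.  Diversification knobs cover somatic point
mutation, antisense D incorporation, planted pseudogene conversion
tracts, and the two QC defect classes (premature stop codons and 5'
truncation).  Every record carries a ground-truth label, and output is
byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import reverse_complement
from .germline import (
    GermlineDatabase,
    GermlineSegment,
    number_functional_v,
    prepare_database,
    translate_codon,
)
from .numbering import ANCHORS, RegionScheme, cattle_scheme

__all__ = ["SimConfig", "TruthRecord", "make_toy_germline_db", "simulate_repertoire"]

BASES = "ACGT"
CH1_STUB = "GCCTCCACCACAGCCCCGAAAGTCTCAGGG"  # 30 nt, begins with the CH1 motif

_ANCHOR_CODONS = {23: ("TGT", "TGC"), 41: ("TGG",), 89: ("CTG", "CTC", "TTG"), 104: ("TGT", "TGC")}
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ConversionConfig:
    prob: float = 0.02
    tract_length_range: tuple[int, int] = (9, 30)
    target_regions: tuple[str, ...] = ("CDR1H", "CDR2H")
    min_diagnostic_bases: int = 3


@dataclass
class QCDefectConfig:
    premature_stop: float = 0.05
    truncation: float = 0.05


@dataclass
class SimConfig:
    """Study conditions for one simulated repertoire.

    Defaults emulate the observed sample set: four breed groups of 160
    transcripts, somatic point mutation at 1% per base (uniform, no
    hotspots; together with the planted defects this reproduces the
    roughly one-fifth QC exclusion seen in cloned IgG sets), antisense D
    in about 7% of records, conversion as a rare event, and amplification
    defects (premature stops, 5' truncation) at 5% each.
    """

    seed: int = 0
    n_v_functional: int = 8
    n_v_pseudo: int = 4
    identical_v_pairs: int = 1
    n_d: int = 6
    n_j: int = 2
    d_length_range: tuple[int, int] = (15, 27)
    j_length: int = 51
    usage_weights: dict[str, float] | None = None
    junction_trim_range: tuple[int, int] = (0, 3)
    n_addition_range: tuple[int, int] = (0, 6)
    mutation_rate: float = 0.01
    antisense_d_prob: float = 0.075
    conversion: ConversionConfig = field(default_factory=ConversionConfig)
    qc_defect_probs: QCDefectConfig = field(default_factory=QCDefectConfig)
    pseudo_divergence: float = 0.10
    groups: tuple[str, ...] = ("A", "GBP", "GS", "HF")
    n_records_per_group: int = 160

    def __post_init__(self) -> None:
        if isinstance(self.conversion, dict):
            self.conversion = ConversionConfig(**self.conversion)
        if isinstance(self.qc_defect_probs, dict):
            self.qc_defect_probs = QCDefectConfig(**self.qc_defect_probs)
        for p in (
            self.mutation_rate,
            self.antisense_d_prob,
            self.conversion.prob,
            self.qc_defect_probs.premature_stop,
            self.qc_defect_probs.truncation,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.identical_v_pairs > self.n_v_functional:
            raise ValueError("identical_v_pairs exceeds n_v_functional")
        for n in (self.n_v_functional, self.n_d, self.n_j):
            if n < 1:
                raise ValueError("segment counts must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one simulated transcript."""

    sample_id: str
    group: str
    true_v: str
    true_d: str
    true_j: str
    d_orientation: str
    cdr3_length: int
    conversion_events: list[dict] = field(default_factory=list)
    qc_defect: str | None = None
    # components for exact reconstruction
    v_nt: str = ""
    n1: str = ""
    d_core: str = ""
    n2: str = ""
    j_part: str = ""
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    truncated_by: int = 0
    sequence: str = ""

    def reconstruct(self) -> str:
        var = list(self.v_nt + self.n1 + self.d_core + self.n2 + self.j_part)
        for pos, old, new in self.mutations:
            assert var[pos] == old
            var[pos] = new
        seq = "".join(var) + CH1_STUB
        return seq[self.truncated_by :]


# ---------------------------------------------------------------------------
# germline construction


def _random_codon(rng: np.random.Generator, position: int) -> str:
    if position in _ANCHOR_CODONS:
        options = _ANCHOR_CODONS[position]
        return options[rng.integers(len(options))]
    while True:
        codon = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if codon not in _STOPS:
            return codon


def _random_functional_v(rng: np.random.Generator, scheme: RegionScheme) -> str:
    return "".join(_random_codon(rng, p) for p in scheme.v_positions())


def _stop_free_all_frames(seq: str) -> bool:
    return not any(seq[i : i + 3] in _STOPS for i in range(len(seq) - 2))


def _derive_pseudogene(
    rng: np.random.Generator,
    parent: str,
    scheme: RegionScheme,
    rate: float,
    min_diag: int,
    target_regions: tuple[str, ...],
) -> str:
    """Substitute the parent at ``rate`` per base, force at least
    ``min_diag`` differences inside each conversion target region, and
    plant one internal stop codon in FR3H."""
    seq = list(parent)
    positions = scheme.v_positions()
    nt_region = []  # region of each nucleotide
    for p in positions:
        nt_region.extend([scheme.region_of(p)] * 3)
    protected: set[int] = set()
    for anchor in ANCHORS:
        idx = positions.index(anchor)
        protected.update(range(3 * idx, 3 * idx + 3))
    for i in range(len(seq)):
        if i in protected:
            continue
        if rng.random() < rate:
            seq[i] = rng.choice([b for b in BASES if b != seq[i]])
    for region in target_regions:
        idxs = [i for i in range(len(seq)) if nt_region[i] == region]
        diffs = [i for i in idxs if seq[i] != parent[i]]
        while len(diffs) < min_diag:
            i = int(rng.choice([k for k in idxs if seq[k] == parent[k]]))
            seq[i] = rng.choice([b for b in BASES if b != seq[i]])
            diffs.append(i)
        # keep donor regions stop-free so planted tracts stay productive
        for k in range(0, len(idxs) - 2, 3):
            codon_idx = idxs[k : k + 3]
            while "".join(seq[i] for i in codon_idx) in _STOPS:
                i = int(rng.choice(codon_idx))
                choices = [b for b in BASES if b != seq[i] and b != parent[i]]
                seq[i] = rng.choice(choices or [b for b in BASES if b != seq[i]])
    # internal stop inside FR3H, away from the anchors
    fr3_codons = [
        k
        for k, p in enumerate(positions)
        if scheme.region_of(p) == "FR3H" and p not in ANCHORS
    ]
    k = int(fr3_codons[len(fr3_codons) // 2])
    seq[3 * k : 3 * k + 3] = "TAA"
    return "".join(seq)


def make_toy_germline_db(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> GermlineDatabase:
    """Build (and optionally write) a prepared toy germline database.

    Functional V satisfy the four IMGT anchors; pseudogenes derive from a
    functional parent by seeded substitutions plus an internal stop;
    requested identical pairs are byte-identical through position 104.
    Genomic metadata places every segment on a toy chromosome with
    pseudogenes upstream of the functional block, so donor-upstream
    checks can fire.
    """
    rng = np.random.default_rng(cfg.seed)
    scheme = cattle_scheme()
    db = GermlineDatabase(scheme)

    v_seqs: list[str] = []
    while len(v_seqs) < cfg.n_v_functional:
        seq = _random_functional_v(rng, scheme)
        if seq not in v_seqs:
            v_seqs.append(seq)
    pos = 500_000
    for i, seq in enumerate(v_seqs, start=1):
        db.add(
            GermlineSegment(
                id=f"IGHV{i}",
                segment_class="V",
                functionality="functional",
                sequence=seq,
                chromosome="BTA21",
                genomic_start=pos,
            )
        )
        pos += 20_000
    for i in range(cfg.identical_v_pairs):
        twin_of = db.segments[f"IGHV{i + 1}"]
        db.add(
            GermlineSegment(
                id=f"IGHV{cfg.n_v_functional + i + 1}",
                segment_class="V",
                functionality="functional",
                sequence=twin_of.sequence,
                chromosome="BTA21",
                genomic_start=pos,
            )
        )
        pos += 20_000
    # pseudogenes sit upstream (5') of the functional block
    pseudo_pos = 100_000
    n_named = cfg.n_v_functional + cfg.identical_v_pairs
    for i in range(cfg.n_v_pseudo):
        parent = v_seqs[int(rng.integers(len(v_seqs)))]
        seq = _derive_pseudogene(
            rng,
            parent,
            scheme,
            cfg.pseudo_divergence,
            cfg.conversion.min_diagnostic_bases,
            cfg.conversion.target_regions,
        )
        db.add(
            GermlineSegment(
                id=f"IGHV{n_named + i + 1}P",
                segment_class="V",
                functionality="pseudogene",
                sequence=seq,
                chromosome="BTA21",
                genomic_start=pseudo_pos,
            )
        )
        pseudo_pos += 18_000

    lo, hi = cfg.d_length_range
    d_seqs: list[str] = []
    while len(d_seqs) < cfg.n_d:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        # transcribed D must stay productive in any frame and orientation
        if not (_stop_free_all_frames(seq) and _stop_free_all_frames(reverse_complement(seq))):
            continue
        pool = d_seqs + [reverse_complement(s) for s in d_seqs]
        if seq != reverse_complement(seq) and all(
            seq not in other and other not in seq for other in pool
        ):
            d_seqs.append(seq)
    for i, seq in enumerate(d_seqs, start=1):
        db.add(GermlineSegment(id=f"IGHD{i}", segment_class="D", sequence=seq, chromosome="BTA21"))

    fr4_seen: set[str] = set()
    j_count = 0
    while j_count < cfg.n_j:
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=cfg.j_length))
        if not _stop_free_all_frames(seq) or seq[-33:] in fr4_seen:
            continue
        fr4_seen.add(seq[-33:])
        j_count += 1
        db.add(GermlineSegment(id=f"IGHJ{j_count}", segment_class="J", sequence=seq, chromosome="BTA21"))

    db = prepare_database(db)
    if out_dir is not None:
        db.save(out_dir)
    return db


# ---------------------------------------------------------------------------
# repertoire simulation


def _sample_weighted(rng: np.random.Generator, ids: list[str], weights) -> str:
    if weights:
        w = np.array([weights.get(i, 1.0) for i in ids], dtype=float)
        w /= w.sum()
        return str(rng.choice(ids, p=w))
    return str(ids[int(rng.integers(len(ids)))])


def plant_gene_conversion(
    v_nt: str,
    v_map,
    donor: GermlineSegment,
    donor_map,
    region: str,
    scheme: RegionScheme,
    cfg: ConversionConfig,
) -> tuple[str, dict] | None:
    """Overwrite a tract of ``v_nt`` (acceptor coordinates) with the donor's
    aligned nucleotides inside ``region``; returns the modified V and the
    event record, or None when the donor carries too few diagnostic bases."""
    pairs = []  # (acceptor nt index, donor base)
    for p in scheme.occupied_positions(region):
        a = v_map.codon_positions.get(p)
        d = donor_map.codon_positions.get(p)
        if a is None or d is None:
            continue
        for ai, di in zip(a, d):
            pairs.append((ai, donor.sequence[di]))
    if not pairs:
        return None
    pairs.sort()
    idxs = [i for i, _ in pairs]
    span = idxs[-1] - idxs[0] + 1
    max_tract = cfg.tract_length_range[1]
    chosen = pairs if span <= max_tract else pairs[: max_tract]
    diag = [(i, b) for i, b in chosen if v_nt[i] != b]
    if len(diag) < cfg.min_diagnostic_bases:
        return None
    seq = list(v_nt)
    for i, b in chosen:
        seq[i] = b
    event = {
        "region": region,
        "donor": donor.id,
        "tract_start": chosen[0][0],
        "tract_end": chosen[-1][0] + 1,
        "diagnostic_bases": len(diag),
    }
    return "".join(seq), event


def simulate_repertoire(
    db: GermlineDatabase, cfg: SimConfig, out_dir: str | Path | None = None
) -> tuple[list[tuple[str, str, str]], list[TruthRecord]]:
    """Simulate rearranged transcripts with full ground truth.

    Returns ``(records, truths)`` where each record is
    ``(sample_id, group, sequence)``.  When ``out_dir`` is given, writes
    ``samples.fasta``, ``samples.tsv`` (id, group) and ``truth.tsv``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    scheme = db.scheme
    v_groups = [s.id for s in db.v_references(functional_only=True)]
    d_ids = sorted(s.id for s in db.by_class("D") if s.orientation == "sense")
    j_ids = sorted(db.fr4_templates)
    pseudos = [s for s in db.v_references() if s.functionality == "pseudogene"]

    records: list[tuple[str, str, str]] = []
    truths: list[TruthRecord] = []
    counter = 0
    for group in cfg.groups:
        for _ in range(cfg.n_records_per_group):
            counter += 1
            sid = f"SIM{counter:06d}"
            v_id = _sample_weighted(rng, v_groups, cfg.usage_weights)
            d_id = _sample_weighted(rng, d_ids, cfg.usage_weights)
            j_id = _sample_weighted(rng, j_ids, cfg.usage_weights)
            v_seg, v_map = db.segments[v_id], db.numbering[v_id]
            v_nt = v_map.mapped_sequence(v_seg, scheme)

            conversion_events: list[dict] = []
            if pseudos and rng.random() < cfg.conversion.prob:
                region = str(rng.choice(list(cfg.conversion.target_regions)))
                order = rng.permutation(len(pseudos))
                for k in order:
                    donor = pseudos[int(k)]
                    planted = plant_gene_conversion(
                        v_nt, v_map, donor, db.numbering[donor.id],
                        region, scheme, cfg.conversion,
                    )
                    if planted is not None:
                        v_nt, event = planted
                        conversion_events.append(event)
                        break

            d_seq = db.segments[d_id].sequence
            orientation = "sense"
            if rng.random() < cfg.antisense_d_prob:
                orientation = "antisense"
                d_seq = reverse_complement(d_seq)
            j_seq = db.segments[j_id].sequence
            t_lo, t_hi = cfg.junction_trim_range
            n_lo, n_hi = cfg.n_addition_range
            # redraw junctions until the rearrangement is productive
            # (no in-frame stop downstream of the V segment)
            for _attempt in range(200):
                d5 = int(rng.integers(t_lo, t_hi + 1))
                d3 = int(rng.integers(t_lo, t_hi + 1))
                d_core = d_seq[d5 : len(d_seq) - d3]
                j5 = int(rng.integers(t_lo, t_hi + 1))
                j_part = j_seq[j5:]
                n1 = "".join(BASES[i] for i in rng.integers(0, 4, size=int(rng.integers(n_lo, n_hi + 1))))
                n2 = "".join(BASES[i] for i in rng.integers(0, 4, size=int(rng.integers(n_lo, n_hi + 1))))
                cdr3_nt = len(n1) + len(d_core) + len(n2) + len(j_part) - 33
                pad = (3 - cdr3_nt % 3) % 3
                n2 += "".join(BASES[i] for i in rng.integers(0, 4, size=pad))
                tail = n1 + d_core + n2 + j_part
                codons = [tail[i : i + 3] for i in range(0, len(tail) - 2, 3)]
                if not any(c in _STOPS for c in codons):
                    break
            else:
                raise RuntimeError("could not draw a productive junction")
            cdr3_len = (cdr3_nt + pad) // 3

            truth = TruthRecord(
                sample_id=sid,
                group=group,
                true_v=v_id,
                true_d=d_id,
                true_j=j_id,
                d_orientation=orientation,
                cdr3_length=cdr3_len,
                conversion_events=conversion_events,
                v_nt=v_nt,
                n1=n1,
                d_core=d_core,
                n2=n2,
                j_part=j_part,
            )

            variable = list(v_nt + n1 + d_core + n2 + j_part)
            # somatic point mutations, uniform across substitution types
            if cfg.mutation_rate > 0:
                hits = np.nonzero(rng.random(len(variable)) < cfg.mutation_rate)[0]
                for i in hits:
                    old = variable[i]
                    new = str(rng.choice([b for b in BASES if b != old]))
                    variable[i] = new
                    truth.mutations.append((int(i), old, new))

            # QC defects
            roll = rng.random()
            if roll < cfg.qc_defect_probs.premature_stop:
                truth.qc_defect = "premature_stop"
                fr3 = [
                    k
                    for k, p in enumerate(scheme.v_positions())
                    if scheme.region_of(p) == "FR3H" and p not in ANCHORS
                    and p in v_map.codon_positions
                ]
                k = int(fr3[len(fr3) // 3])
                codon_start = 3 * k
                for off, b in enumerate("TAA"):
                    i = codon_start + off
                    variable[i] = b
                    # reconcile the mutation log so reconstruction stays exact
                    truth.mutations = [(p, o, n) for p, o, n in truth.mutations if p != i]
                    base = truth.v_nt[i]
                    if base != b:
                        truth.mutations.append((i, base, b))
            elif roll < cfg.qc_defect_probs.premature_stop + cfg.qc_defect_probs.truncation:
                truth.qc_defect = "truncation"
                truth.truncated_by = int(rng.integers(40, 121))

            truth.mutations.sort()
            seq = "".join(variable) + CH1_STUB
            seq = seq[truth.truncated_by :]
            truth.sequence = seq
            records.append((sid, group, seq))
            truths.append(truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "samples.fasta", "w") as fh:
            for sid, group, seq in records:
                fh.write(f">{sid} group={group}\n{seq}\n")
        pd.DataFrame(
            [(sid, group) for sid, group, _ in records], columns=["id", "group"]
        ).to_csv(out / "samples.tsv", sep="\t", index=False)
        truth_table(truths).to_csv(out / "truth.tsv", sep="\t", index=False)
    return records, truths


def truth_table(truths: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truths:
        rows.append(
            {
                "sample_id": t.sample_id,
                "group": t.group,
                "true_v": t.true_v,
                "true_d": t.true_d,
                "true_j": t.true_j,
                "d_orientation": t.d_orientation,
                "cdr3_length": t.cdr3_length,
                "qc_defect": t.qc_defect or ".",
                "n_mutations": len(t.mutations),
                "conversion_region": t.conversion_events[0]["region"] if t.conversion_events else ".",
                "conversion_donor": t.conversion_events[0]["donor"] if t.conversion_events else ".",
            }
        )
    return pd.DataFrame(rows)
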