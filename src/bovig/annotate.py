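"""Per-transcript annotation: variable-region extraction, QC, and
minimal-divergence V/D/J assignment.

The variable region is everything 5' of the first occurrence of the
CH1-start motif ``GCCTCCACC`` (AlaSerThr, the first codon triplet of the
IgG constant region).  Records with premature stop codons or without
full FR1H-FR4H coverage are excluded.  IGHV is assigned on the framework
regions only, to keep the hypervariable CDRs from dominating the
distance; IGHJ is assigned on the 3'-terminal 33 nt against each FR4H
template; IGHD is sought inside the CDR3H against both orientations of
every germline D under a selectable scoring procedure.  Assignment is by
minimal divergence; exact ties list every tied reference (an ambiguous
call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import (
    IUB_SETS,
    ScoringScheme,
    builtin_scheme,
    global_align,
)
from .germline import GermlineDatabase, translate_codon
from .numbering import PositionLabel, cdr3_group, extend_cdr3_labels

__all__ = [
    "CH1_MOTIF",
    "SampleRecord",
    "SegmentCall",
    "Annotation",
    "extract_variable_region",
    "qc_filter",
    "assign_v",
    "assign_j_fr4",
    "delimit_cdr3",
    "assign_d",
    "annotate_record",
    "annotate_all",
    "annotations_table",
]

CH1_MOTIF = "GCCTCCACC"

FR_REGIONS = ("FR1H", "FR2H", "FR3H")
V_REGIONS = ("FR1H", "CDR1H", "FR2H", "CDR2H", "FR3H")

#: a reference is usable for a call only if at least this fraction of its
#: nucleotides lands in gap-free columns
MIN_COVERAGE = 0.5

#: D calls supported by fewer informative columns are flagged low-confidence
MIN_D_COLUMNS = 6


@dataclass
class SampleRecord:
    id: str
    group: str = ""
    raw_sequence: str = ""
    variable_region: str | None = None
    translation: str | None = None
    qc_status: str = "pass"
    qc_reason: str | None = None

    def fail(self, reason: str) -> "SampleRecord":
        self.qc_status = "fail"
        self.qc_reason = reason
        return self


@dataclass
class SegmentCall:
    """Minimal-divergence call; exact ties are all listed."""

    candidates: list[str]
    divergence: float | None
    compared_columns: int = 0
    orientation: str | None = None  # D only
    procedure: str | None = None  # D only
    low_confidence: bool = False

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1

    @property
    def undetermined(self) -> bool:
        return not self.candidates


@dataclass
class Annotation:
    sample_id: str
    group: str
    v_call: SegmentCall
    d_call: SegmentCall
    j_call: SegmentCall
    region_slices: dict[str, tuple[int, int]]
    cdr3_length: int
    cdr3_group: int
    cdr3_labels: list[PositionLabel]
    position_residues: dict[str, str] = field(default_factory=dict)
    #: sample nucleotide codon per IMGT V position (from the V alignment)
    position_codons: dict[int, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# extraction and QC


def extract_variable_region(record: SampleRecord, motif: str = CH1_MOTIF) -> SampleRecord:
    """Cut the variable region 5' of the first CH1 motif and translate it.

    The reading frame is anchored so that the motif begins a codon; a 5'
    overhang shorter than one codon is trimmed before translation.
    """
    seq = record.raw_sequence.upper()
    if not seq:
        raise ValueError(f"{record.id}: empty sequence")
    idx = seq.find(motif)
    if idx < 0:
        return record.fail("no_motif")
    if idx == 0:
        record.variable_region = ""
        return record.fail("incomplete")
    record.variable_region = seq[:idx]
    offset = idx % 3
    codons = [
        record.variable_region[i : i + 3]
        for i in range(offset, idx - 2, 3)
    ]
    record.translation = "".join(translate_codon(c) for c in codons)
    return record


def qc_filter(
    record: SampleRecord, db: GermlineDatabase, scheme: ScoringScheme | None = None
) -> SampleRecord:
    """Flag premature stops and incomplete variable regions.

    A record passes only if its translation is stop-free through the
    FR4H end and the best V alignment covers IMGT position 1 with at
    least 33 nt left for FR4H.  Failures are statuses, never errors.
    """
    if record.qc_status == "fail":
        return record
    if record.translation is None:
        raise ValueError(f"{record.id}: extraction not attempted")
    if "*" in record.translation:
        return record.fail("premature_stop")
    info = _best_v(record, db, scheme or builtin_scheme(1))
    if info is None:
        return record.fail("incomplete")
    return record


# ---------------------------------------------------------------------------
# V assignment


@dataclass
class _VInfo:
    call: SegmentCall
    region_slices: dict[str, tuple[int, int]]
    v_end: int  # sample index just past the column aligned to position 104
    position_codons: dict[int, str]  # IMGT position -> sample codon


def _align_to_v(
    variable: str, db: GermlineDatabase, ref_id: str, scoring: ScoringScheme
):
    """Align the sample's variable region to one V reference and measure
    divergence over the framework columns; returns None when coverage of
    the reference's FR nucleotides falls below MIN_COVERAGE."""
    seg = db.segments[ref_id]
    nmap = db.numbering[ref_id]
    ref_nt = nmap.mapped_sequence(seg, db.scheme)
    if not ref_nt:
        return None
    aln = global_align(variable, ref_nt, scoring, free_a_overhangs=(True, True))
    positions = [p for p in db.scheme.v_positions() if p in nmap.codon_positions]
    nt_pos: list[int] = []
    for p in positions:
        nt_pos.extend([p, p, p])
    fr_total = sum(3 for p in positions if db.scheme.region_of(p) in FR_REGIONS)
    compared = mismatches = 0
    i = j = 0
    col_info = []  # (sample index or None, position) per reference nucleotide
    for x, y in aln.columns():
        if y != "-":
            pos = nt_pos[j]
            col_info.append((i if x != "-" else None, pos))
            if x != "-" and db.scheme.region_of(pos) in FR_REGIONS:
                compared += 1
                if not IUB_SETS[x] & IUB_SETS[y]:
                    mismatches += 1
        if x != "-":
            i += 1
        if y != "-":
            j += 1
    if fr_total == 0 or compared < MIN_COVERAGE * fr_total:
        return None
    return mismatches / compared, compared, col_info


def _v_projection(variable: str, db: GermlineDatabase, ref_id: str, col_info) -> _VInfo:
    scheme = db.scheme
    slices: dict[str, tuple[int, int]] = {}
    per_pos: dict[int, list[str]] = {}
    region_cols: dict[str, list[int]] = {}
    v_end = 0
    for sample_i, pos in col_info:
        region = scheme.region_of(pos)
        if sample_i is not None:
            region_cols.setdefault(region, []).append(sample_i)
            v_end = max(v_end, sample_i + 1)
        per_pos.setdefault(pos, []).append(
            variable[sample_i] if sample_i is not None else "-"
        )
    for region in V_REGIONS:
        cols = region_cols.get(region)
        slices[region] = (min(cols), max(cols) + 1) if cols else (v_end, v_end)
    codons = {
        pos: "".join(chars)
        for pos, chars in per_pos.items()
        if len(chars) == 3 and "-" not in chars
    }
    return _VInfo(call=SegmentCall([], None), region_slices=slices, v_end=v_end, position_codons=codons)


def _best_v(
    record: SampleRecord, db: GermlineDatabase, scoring: ScoringScheme
) -> _VInfo | None:
    variable = record.variable_region
    if not variable:
        return None
    results: dict[str, tuple[float, int, list]] = {}
    for seg in db.v_references():
        out = _align_to_v(variable, db, seg.id, scoring)
        if out is not None:
            results[seg.id] = out
    if not results:
        return None
    best_div = min(div for div, _, _ in results.values())
    tied = sorted(rid for rid, (div, _, _) in results.items() if div == best_div)
    lead = tied[0]
    info = _v_projection(variable, db, lead, results[lead][2])
    info.call = SegmentCall(tied, best_div, results[lead][1])
    # FR1H position 1 must be covered and 33 nt must remain for FR4H
    if 1 not in info.position_codons or len(variable) - info.v_end < 33:
        return None
    return info


def assign_v(
    record: SampleRecord, db: GermlineDatabase, scheme: ScoringScheme | None = None
) -> SegmentCall:
    """Assign IGHV on the framework regions only (minimal divergence)."""
    if record.qc_status != "pass":
        raise ValueError(f"{record.id}: record failed QC")
    info = _best_v(record, db, scheme or builtin_scheme(1))
    if info is None:
        raise ValueError(f"{record.id}: unassignable (no reference with sufficient coverage)")
    return info.call


# ---------------------------------------------------------------------------
# J / CDR3 / D


def assign_j_fr4(
    record: SampleRecord, db: GermlineDatabase, scheme: ScoringScheme | None = None
) -> SegmentCall:
    """Assign IGHJ by the 3'-terminal 33 nt against each FR4H template."""
    scoring = scheme or builtin_scheme(1)
    variable = record.variable_region or ""
    if len(variable) < 33:
        raise ValueError(f"{record.id}: variable region shorter than the FR4H template")
    tail = variable[-33:]
    results: dict[str, tuple[float, int]] = {}
    for j_id, template in db.fr4_templates.items():
        aln = global_align(tail, template, scoring)
        compared = mismatches = 0
        for x, y in aln.columns():
            if x == "-" or y == "-":
                continue
            compared += 1
            if not IUB_SETS[x] & IUB_SETS[y]:
                mismatches += 1
        if compared >= MIN_COVERAGE * 33:
            results[j_id] = (mismatches / compared, compared)
    if not results:
        raise ValueError(f"{record.id}: no FR4H template aligns")
    best = min(d for d, _ in results.values())
    tied = sorted(j for j, (d, _) in results.items() if d == best)
    return SegmentCall(tied, best, results[tied[0]][1])


def delimit_cdr3(
    variable: str, v_end: int
) -> tuple[str, int, int, list[PositionLabel]]:
    """CDR3H nucleotides between the FR3H end and the FR4H start."""
    fr4_start = len(variable) - 33
    if fr4_start < v_end:
        raise ValueError("overlapping V and J calls leave no CDR3H interval")
    cdr3 = variable[v_end:fr4_start]
    length = len(cdr3) // 3
    if length < 1:
        raise ValueError("empty CDR3H interval")
    return cdr3, length, cdr3_group(length), extend_cdr3_labels(length)


def assign_d(
    cdr3: str, db: GermlineDatabase, scheme: ScoringScheme | None = None
) -> SegmentCall:
    """Assign IGHD inside the CDR3H (global in the D, free CDR3H end gaps).

    Divergence is computed over D-covered columns only.  Both
    orientations of every germline D compete; the winning variant's
    orientation is reported.  Calls on fewer than six informative
    columns are flagged low-confidence; an empty result is
    'undetermined'.
    """
    scoring = scheme or builtin_scheme(3)
    if not cdr3:
        return SegmentCall([], None, procedure=scoring.name)
    results: dict[str, tuple[float, int]] = {}
    for seg in sorted(db.by_class("D"), key=lambda s: s.id):
        if len(seg.sequence) > len(cdr3) + 6:
            continue  # D cannot plausibly fit this CDR3H
        aln = global_align(cdr3, seg.sequence, scoring, free_a_overhangs=(True, True))
        compared = mismatches = 0
        for x, y in aln.columns():
            if x == "-" or y == "-":
                continue
            compared += 1
            if not IUB_SETS[x] & IUB_SETS[y]:
                mismatches += 1
        if compared == 0:
            continue
        results[seg.id] = (mismatches / compared, compared)
    if not results:
        return SegmentCall([], None, procedure=scoring.name)
    best = min(d for d, _ in results.values())
    tied = sorted(d_id for d_id, (d, _) in results.items() if d == best)
    compared = results[tied[0]][1]
    orientation = db.segments[tied[0]].orientation
    return SegmentCall(
        tied,
        best,
        compared,
        orientation=orientation,
        procedure=scoring.name,
        low_confidence=compared < MIN_D_COLUMNS,
    )


# ---------------------------------------------------------------------------
# full pipeline


def annotate_record(
    record: SampleRecord,
    db: GermlineDatabase,
    d_procedure: int | str = 3,
    motif: str = CH1_MOTIF,
) -> tuple[SampleRecord, Annotation | None]:
    """Run the full per-transcript pipeline; QC failures return no annotation."""
    extract_variable_region(record, motif)
    if record.qc_status == "fail":
        return record, None
    if "*" in (record.translation or ""):
        return record.fail("premature_stop"), None
    info = _best_v(record, db, builtin_scheme(1))
    if info is None:
        return record.fail("incomplete"), None
    variable = record.variable_region or ""
    j_call = assign_j_fr4(record, db)
    cdr3, length, group_id, labels = delimit_cdr3(variable, info.v_end)
    d_scheme = (
        builtin_scheme(d_procedure)
        if isinstance(d_procedure, int) or d_procedure in ("procedure1", "procedure2", "procedure3")
        else d_procedure
    )
    d_call = assign_d(cdr3, db, d_scheme)

    slices = dict(info.region_slices)
    slices["CDR3H"] = (info.v_end, len(variable) - 33)
    slices["FR4H"] = (len(variable) - 33, len(variable))

    residues: dict[str, str] = {
        str(pos): translate_codon(codon) for pos, codon in info.position_codons.items()
    }
    for k, label in enumerate(labels):
        codon = cdr3[3 * k : 3 * k + 3]
        if len(codon) == 3:
            residues[str(label)] = translate_codon(codon)
    fr4 = variable[-33:]
    for k, pos in enumerate(range(118, 129)):
        residues[str(pos)] = translate_codon(fr4[3 * k : 3 * k + 3])

    ann = Annotation(
        sample_id=record.id,
        group=record.group,
        v_call=info.call,
        d_call=d_call,
        j_call=j_call,
        region_slices=slices,
        cdr3_length=length,
        cdr3_group=group_id,
        cdr3_labels=labels,
        position_residues=residues,
        position_codons=dict(info.position_codons),
    )
    return record, ann


def annotate_all(
    records,
    db: GermlineDatabase,
    d_procedure: int | str = 3,
) -> tuple[list[SampleRecord], list[Annotation]]:
    """Annotate an iterable of (id, group, sequence) triples."""
    out_records: list[SampleRecord] = []
    annotations: list[Annotation] = []
    for sid, group, seq in records:
        rec = SampleRecord(id=sid, group=group, raw_sequence=seq)
        rec, ann = annotate_record(rec, db, d_procedure)
        out_records.append(rec)
        if ann is not None:
            annotations.append(ann)
    return out_records, annotations


def annotations_table(
    records: list[SampleRecord], annotations: list[Annotation]
) -> pd.DataFrame:
    """One row per input record: QC state plus calls for pass-QC records."""
    by_id = {a.sample_id: a for a in annotations}
    rows = []
    for rec in records:
        ann = by_id.get(rec.id)
        rows.append(
            {
                "sample_id": rec.id,
                "group": rec.group,
                "qc_status": rec.qc_status,
                "qc_reason": rec.qc_reason or ".",
                "v_call": ";".join(ann.v_call.candidates) if ann else ".",
                "v_divergence": ann.v_call.divergence if ann else None,
                "d_call": (";".join(ann.d_call.candidates) or "undetermined") if ann else ".",
                "d_divergence": ann.d_call.divergence if ann else None,
                "d_orientation": (ann.d_call.orientation or ".") if ann else ".",
                "d_procedure": (ann.d_call.procedure or ".") if ann else ".",
                "d_low_confidence": ann.d_call.low_confidence if ann else None,
                "j_call": ";".join(ann.j_call.candidates) if ann else ".",
                "j_divergence": ann.j_call.divergence if ann else None,
                "cdr3_length": ann.cdr3_length if ann else None,
                "cdr3_group": ann.cdr3_group if ann else None,
            }
        )
    return pd.DataFrame(rows)
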