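"""Region-separated re-alignment to flag putative gene-conversion events.

Gene conversion replaces a tract of the rearranged V with sequence from
a donor — typically an upstream pseudogene — and is recognised as a
cluster of nucleotide changes shared with the donor, with homologous
flanks.  To expose such tracts each of FR1H, CDR1H, FR2H, CDR2H and
FR3H is re-aligned on its own against the corresponding region of every
germline V (functional and pseudogene).  A region whose
minimal-divergence set excludes the full-framework acceptor call yields
an event; the event is *unique* (unambiguous) when that set contains no
functional or ORF segment at all, mirroring the ambiguous/unambiguous
distinction of the source counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import IUB_SETS, ScoringScheme, builtin_scheme, global_align
from .annotate import Annotation, SampleRecord, SegmentCall, V_REGIONS, _best_v
from .germline import GermlineDatabase

__all__ = [
    "RegionCall",
    "RegionCallSet",
    "GeneConversionEvent",
    "per_region_assign",
    "detect_conversion",
    "evaluate_evidence",
    "analyze_record",
    "events_table",
    "region_summary",
]

#: two donor-shared changes within this window count as clustered
CLUSTER_WINDOW_NT = 9

#: minimal exact flanking homology expected of a genuine conversion tract
MIN_FLANK_NT = 3


@dataclass
class RegionCall:
    region: str
    divergence: float
    candidates: list[str]
    functionalities: list[str]


@dataclass
class RegionCallSet:
    sample_id: str
    per_region: dict[str, RegionCall]


@dataclass
class GeneConversionEvent:
    sample_id: str
    region: str
    donor_candidates: list[str]
    acceptor: str
    region_divergence: float
    acceptor_region_divergence: float | None
    unique: bool
    evidence: dict = field(default_factory=dict)


def _region_divergence(sample_region: str, ref_region: str, scoring: ScoringScheme):
    aln = global_align(sample_region, ref_region, scoring)
    compared = mismatches = 0
    for x, y in aln.columns():
        if x == "-" or y == "-":
            continue
        compared += 1
        if not IUB_SETS[x] & IUB_SETS[y]:
            mismatches += 1
    if compared == 0:
        return None
    return mismatches / compared


def per_region_assign(
    annotation: Annotation,
    record: SampleRecord,
    db: GermlineDatabase,
    scheme: ScoringScheme | None = None,
) -> RegionCallSet:
    """Minimal-divergence germline set for each V region separately.

    The sample's region nucleotides are taken from the region slices of
    its full-framework V alignment; each germline contributes the
    corresponding region of its numbering map (germlines whose map does
    not cover the region are skipped for that region).
    """
    scoring = scheme or builtin_scheme(1)
    variable = record.variable_region or ""
    per_region: dict[str, RegionCall] = {}
    for region in V_REGIONS:
        lo, hi = annotation.region_slices[region]
        sample_region = variable[lo:hi]
        if not sample_region:
            continue
        divs: dict[str, float] = {}
        for seg in db.v_references():
            nmap = db.numbering.get(seg.id)
            if nmap is None:
                continue
            ref_region = nmap.region_sequence(seg, region, db.scheme)
            expected = 3 * len(db.scheme.occupied_positions(region))
            if not ref_region or len(ref_region) < 0.5 * expected:
                continue  # e.g. pseudogene deletion spanning the region
            div = _region_divergence(sample_region, ref_region, scoring)
            if div is not None:
                divs[seg.id] = div
        if not divs:
            continue
        best = min(divs.values())
        tied = sorted(sid for sid, d in divs.items() if d == best)
        per_region[region] = RegionCall(
            region=region,
            divergence=best,
            candidates=tied,
            functionalities=[db.segments[sid].functionality for sid in tied],
        )
    return RegionCallSet(annotation.sample_id, per_region)


def detect_conversion(
    calls: RegionCallSet,
    v_call: SegmentCall,
    db: GermlineDatabase,
    region_divergences: dict[str, dict[str, float]] | None = None,
) -> list[GeneConversionEvent]:
    """Emit one event per region whose minimal set excludes the acceptor.

    ``unique`` is True when the minimal set consists exclusively of
    non-functional segments (no functional/ORF candidate ties it) —
    the unambiguous case; pseudogenes tied with functional segments are
    reported with ``unique`` False.
    """
    acceptors = set(v_call.candidates)
    events: list[GeneConversionEvent] = []
    for region, call in calls.per_region.items():
        minimal = set(call.candidates)
        if minimal & acceptors:
            continue
        unique = all(f == "pseudogene" for f in call.functionalities)
        donors = sorted(
            sid
            for sid, f in zip(call.candidates, call.functionalities)
            if f != "functional"
        ) or sorted(call.candidates)
        acceptor = v_call.candidates[0]
        acc_div = None
        if region_divergences is not None:
            acc_div = region_divergences.get(region, {}).get(acceptor)
        events.append(
            GeneConversionEvent(
                sample_id=calls.sample_id,
                region=region,
                donor_candidates=donors,
                acceptor=acceptor,
                region_divergence=call.divergence,
                acceptor_region_divergence=acc_div,
                unique=unique,
            )
        )
    return events


def evaluate_evidence(
    event: GeneConversionEvent,
    annotation: Annotation,
    record: SampleRecord,
    db: GermlineDatabase,
) -> GeneConversionEvent:
    """Fill the evidence block of an event.

    Columns are the nucleotides of the IMGT positions mapped by both
    donor and acceptor in the event's region; the sample's region slice
    is aligned onto the donor (the putative template of the tract).
    ``changed_columns`` counts columns where the sample matches the
    donor but not the acceptor; ``clustered`` requires two such changes
    within a 9-nt window; flanking homology is the maximal exact
    sample=donor=acceptor run immediately outside the changed tract.
    ``donor_upstream`` is set only when genomic metadata places a donor
    5' of the acceptor on the same chromosome.
    """
    donor_id = event.donor_candidates[0]
    donor = db.segments[donor_id]
    acceptor = db.segments[event.acceptor]
    donor_map = db.numbering[donor_id]
    acc_map = db.numbering[event.acceptor]
    donor_nt: list[str] = []
    acc_nt: list[str] = []
    for pos in db.scheme.occupied_positions(event.region):
        d_codon = donor_map.codon_positions.get(pos)
        a_codon = acc_map.codon_positions.get(pos)
        if d_codon is None or a_codon is None:
            continue
        donor_nt.extend(donor.sequence[i] for i in d_codon)
        acc_nt.extend(acceptor.sequence[i] for i in a_codon)
    lo, hi = annotation.region_slices[event.region]
    sample_region = (record.variable_region or "")[lo:hi]
    columns: list[tuple[str, str, str]] = []  # (sample, donor, acceptor)
    if donor_nt and sample_region:
        aln = global_align(sample_region, "".join(donor_nt), builtin_scheme(1))
        j = 0
        for x, y in aln.columns():
            if y != "-":
                columns.append((x, donor_nt[j], acc_nt[j]))
                j += 1
    changed = [k for k, (s, d, a) in enumerate(columns) if s == d and s != a]
    clustered = any(
        b - a < CLUSTER_WINDOW_NT for a, b in zip(changed, changed[1:])
    )
    flank5 = flank3 = 0
    if changed:
        k = changed[0] - 1
        while k >= 0 and len({columns[k][0], columns[k][1], columns[k][2]}) == 1:
            flank5 += 1
            k -= 1
        k = changed[-1] + 1
        while k < len(columns) and len({columns[k][0], columns[k][1], columns[k][2]}) == 1:
            flank3 += 1
            k += 1
    evidence = {
        "changed_columns": len(changed),
        "clustered": clustered,
        "flank_homology_5": flank5,
        "flank_homology_3": flank3,
        "min_flank_required": MIN_FLANK_NT,
    }
    upstream = _donor_upstream(event, db)
    if upstream is not None:
        evidence["donor_upstream"] = upstream
    event.evidence = evidence
    return event


def _donor_upstream(event: GeneConversionEvent, db: GermlineDatabase) -> bool | None:
    def members(group_id: str) -> list[str]:
        return db.identity_groups.get(group_id, [group_id])

    acc = db.segments[event.acceptor]
    if acc.genomic_start is None or acc.chromosome is None:
        return None
    found = None
    for donor_group in event.donor_candidates:
        seg = db.segments.get(donor_group)
        if seg is None or seg.genomic_start is None or seg.chromosome is None:
            continue
        found = False if found is None else found
        if seg.chromosome == acc.chromosome and seg.genomic_start < acc.genomic_start:
            return True
    return found


def analyze_record(
    annotation: Annotation,
    record: SampleRecord,
    db: GermlineDatabase,
    scheme: ScoringScheme | None = None,
) -> list[GeneConversionEvent]:
    """per_region_assign -> detect_conversion -> evaluate_evidence."""
    scoring = scheme or builtin_scheme(1)
    calls = per_region_assign(annotation, record, db, scoring)
    # acceptor's own per-region divergence, for reporting
    variable = record.variable_region or ""
    acc = annotation.v_call.candidates[0]
    acc_divs: dict[str, dict[str, float]] = {}
    for region, call in calls.per_region.items():
        nmap = db.numbering.get(acc)
        seg = db.segments[acc]
        ref_region = nmap.region_sequence(seg, region, db.scheme) if nmap else ""
        lo, hi = annotation.region_slices[region]
        if ref_region and hi > lo:
            d = _region_divergence(variable[lo:hi], ref_region, scoring)
            if d is not None:
                acc_divs[region] = {acc: d}
    events = detect_conversion(calls, annotation.v_call, db, acc_divs)
    return [evaluate_evidence(e, annotation, record, db) for e in events]


def events_table(events: list[GeneConversionEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "sample_id": e.sample_id,
                "region": e.region,
                "donors": ";".join(e.donor_candidates),
                "acceptor": e.acceptor,
                "region_divergence": e.region_divergence,
                "acceptor_region_divergence": e.acceptor_region_divergence,
                "unique": e.unique,
                "changed_columns": e.evidence.get("changed_columns"),
                "clustered": e.evidence.get("clustered"),
                "flank_homology_5": e.evidence.get("flank_homology_5"),
                "flank_homology_3": e.evidence.get("flank_homology_3"),
                "donor_upstream": e.evidence.get("donor_upstream", "."),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "region", "donors", "acceptor", "region_divergence",
            "acceptor_region_divergence", "unique", "changed_columns",
            "clustered", "flank_homology_5", "flank_homology_3", "donor_upstream",
        ],
    )


def region_summary(
    events: list[GeneConversionEvent], groups: dict[str, str]
) -> pd.DataFrame:
    """Counts per donor x region x sample group, split by ambiguity.

    ``groups`` maps sample id -> group label.  The ambiguous column
    counts events where functional candidates tie with the donor; the
    unambiguous column counts unique (all-pseudogene) events.
    """
    rows: dict[tuple[str, str, str], dict[str, int]] = {}
    for e in events:
        group = groups.get(e.sample_id, "")
        for donor in e.donor_candidates:
            key = (donor, e.region, group)
            cell = rows.setdefault(key, {"ambiguous": 0, "unambiguous": 0})
            cell["unambiguous" if e.unique else "ambiguous"] += 1
    table = [
        {
            "donor": donor,
            "region": region,
            "group": group,
            "ambiguous": cell["ambiguous"],
            "unambiguous": cell["unambiguous"],
        }
        for (donor, region, group), cell in sorted(rows.items())
    ]
    return pd.DataFrame(
        table, columns=["donor", "region", "group", "ambiguous", "unambiguous"]
    )
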