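"""Germline V/D/J reference preparation.

The reference workflow: load segment FASTA files, assign IMGT codon
numbers to functional IGHV by locating the conserved anchors (Cys23,
Trp41, Leu89, Cys104), transfer that numbering onto pseudogenes by
nucleotide alignment against the closest functional segment (pseudogene
insertions are discarded, deletions leave positions unassigned), merge V
segments that are 100% identical through the end of FR3H into one
reference group, cut the 3'-terminal 33 nt of each IGHJ as the FR4H
template, and add a reverse-complement (antisense) variant of every
IGHD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import (
    IUB_SETS,
    ScoringScheme,
    builtin_scheme,
    divergence,
    global_align,
    reverse_complement,
)
from .numbering import ANCHORS, RegionScheme, cattle_scheme

__all__ = [
    "GermlineSegment",
    "NumberingMap",
    "GermlineDatabase",
    "load_germline_fasta",
    "number_functional_v",
    "transfer_numbering_to_pseudogene",
    "collapse_identical_v",
    "fr4_template",
    "expand_d_orientations",
    "build_database",
]

FUNCTIONALITIES = ("functional", "ORF", "pseudogene")

CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            CODON_TABLE[stop] = "*"
    return CODON_TABLE


def translate_codon(codon: str) -> str:
    """One codon to one amino acid; 'X' for ambiguity or partial codons."""
    return _codon_table().get(codon.upper(), "X")


@dataclass
class GermlineSegment:
    """One reference V, D or J gene."""

    id: str
    segment_class: str  # V | D | J
    functionality: str = "functional"
    sequence: str = ""
    orientation: str = "sense"  # antisense only for derived D variants
    chromosome: str | None = None
    genomic_start: int | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set(IUB_SETS)
        if bad:
            raise ValueError(f"{self.id}: non-IUB characters {sorted(bad)}")
        if self.segment_class not in "VDJ":
            raise ValueError(f"{self.id}: segment class must be V, D or J")
        if self.functionality not in FUNCTIONALITIES:
            raise ValueError(f"{self.id}: unknown functionality {self.functionality!r}")
        if self.orientation == "antisense" and self.segment_class != "D":
            raise ValueError(f"{self.id}: antisense orientation is D-only")


@dataclass
class NumberingMap:
    """IMGT codon assignment of one V segment.

    ``codon_positions`` maps each occupied IMGT base position to the
    three nucleotide indices of its codon within the segment sequence
    (not necessarily contiguous for pseudogenes whose insertions were
    discarded).
    """

    segment_id: str
    codon_positions: dict[int, tuple[int, int, int]]
    anchor_positions: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    def region_sequence(self, seg: GermlineSegment, region: str, scheme: RegionScheme) -> str:
        """Nucleotides of one region, concatenated over its mapped codons."""
        out = []
        for pos in scheme.occupied_positions(region):
            codon = self.codon_positions.get(pos)
            if codon is not None:
                out.append("".join(seg.sequence[i] for i in codon))
        return "".join(out)

    def mapped_sequence(self, seg: GermlineSegment, scheme: RegionScheme, through: int = 104) -> str:
        """Concatenated nucleotides of all mapped positions <= ``through``."""
        out = []
        for pos in scheme.v_positions():
            if pos > through:
                break
            codon = self.codon_positions.get(pos)
            if codon is not None:
                out.append("".join(seg.sequence[i] for i in codon))
        return "".join(out)

    def position_of_nt(self) -> dict[int, int]:
        """Inverse map: nucleotide index -> IMGT base position."""
        inv: dict[int, int] = {}
        for pos, codon in self.codon_positions.items():
            for i in codon:
                inv[i] = pos
        return inv


class GermlineDatabase:
    """Prepared germline reference: segments, numbering, groups, templates."""

    def __init__(self, scheme: RegionScheme | None = None) -> None:
        self.scheme = scheme or cattle_scheme()
        self.segments: dict[str, GermlineSegment] = {}
        self.numbering: dict[str, NumberingMap] = {}
        self.identity_groups: dict[str, list[str]] = {}
        self.fr4_templates: dict[str, str] = {}

    # -- access -----------------------------------------------------------
    def by_class(self, segment_class: str) -> list[GermlineSegment]:
        return [s for s in self.segments.values() if s.segment_class == segment_class]

    def v_references(self, functional_only: bool = False) -> list[GermlineSegment]:
        refs = self.by_class("V")
        if functional_only:
            refs = [s for s in refs if s.functionality in ("functional", "ORF")]
        return sorted(refs, key=lambda s: s.id)

    def add(self, seg: GermlineSegment) -> None:
        if seg.id in self.segments:
            raise ValueError(f"duplicate segment id {seg.id!r}")
        self.segments[seg.id] = seg

    # -- persistence ------------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cls in "VDJ":
            records = [
                SeqRecord(Seq(s.sequence), id=f"{s.id}|{cls}|{s.functionality}", description="")
                for s in sorted(self.by_class(cls), key=lambda s: s.id)
            ]
            if records:
                SeqIO.write(records, out / f"igh{cls.lower()}.fasta", "fasta")
        meta = {
            "scheme": json.loads(self.scheme.to_json()),
            "segments": {
                s.id: {
                    "segment_class": s.segment_class,
                    "functionality": s.functionality,
                    "orientation": s.orientation,
                    "chromosome": s.chromosome,
                    "genomic_start": s.genomic_start,
                }
                for s in self.segments.values()
            },
            "numbering": {
                sid: {str(pos): list(codon) for pos, codon in nmap.codon_positions.items()}
                for sid, nmap in self.numbering.items()
            },
            "identity_groups": self.identity_groups,
            "fr4_templates": self.fr4_templates,
        }
        (out / "db.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        return out

    @classmethod
    def load(cls, db_dir: str | Path) -> "GermlineDatabase":
        db_dir = Path(db_dir)
        meta = json.loads((db_dir / "db.json").read_text())
        db = cls(RegionScheme.from_json(json.dumps(meta["scheme"])))
        for seg_class in "VDJ":
            path = db_dir / f"igh{seg_class.lower()}.fasta"
            if not path.exists():
                continue
            for rec in SeqIO.parse(str(path), "fasta"):
                sid = rec.id.split("|")[0]
                info = meta["segments"][sid]
                db.add(
                    GermlineSegment(
                        id=sid,
                        segment_class=info["segment_class"],
                        functionality=info["functionality"],
                        sequence=str(rec.seq),
                        orientation=info["orientation"],
                        chromosome=info["chromosome"],
                        genomic_start=info["genomic_start"],
                    )
                )
        db.numbering = {
            sid: NumberingMap(
                sid, {int(pos): tuple(codon) for pos, codon in codons.items()}
            )
            for sid, codons in meta["numbering"].items()
        }
        db.identity_groups = meta["identity_groups"]
        db.fr4_templates = meta["fr4_templates"]
        return db


# ---------------------------------------------------------------------------
# loading


def _parse_header(header: str, segment_class: str) -> tuple[str, str]:
    """Parse 'id|class|functionality' headers, falling back to bare ids."""
    parts = header.split("|")
    seg_id = parts[0]
    functionality = "functional"
    if len(parts) >= 3 and parts[2]:
        functionality = parts[2]
    elif "P" in seg_id.upper().replace("IGH", "") and segment_class == "V":
        # bare-id fallback: a trailing P (or Greek psi in curated sets)
        # conventionally marks pseudogenes
        if seg_id.rstrip().upper().endswith("P") or "Ψ" in seg_id:
            functionality = "pseudogene"
    return seg_id, functionality


def load_germline_fasta(
    path: str | Path,
    segment_class: str,
    metadata: str | Path | None = None,
    db: GermlineDatabase | None = None,
) -> GermlineDatabase:
    """Load one class of germline segments from FASTA into a database.

    Headers follow ``id|class|functionality``; a sidecar TSV
    (id, functionality, chromosome, genomic_start) may override or
    supply metadata.  Records with non-IUB characters are rejected with
    a diagnostic naming the record.
    """
    db = db or GermlineDatabase()
    meta: dict[str, dict[str, str]] = {}
    if metadata is not None:
        import csv

        with open(metadata, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                meta[row["id"]] = row
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    for rec in records:
        seg_id, functionality = _parse_header(rec.id, segment_class)
        row = meta.get(seg_id, {})
        if row.get("functionality"):
            functionality = row["functionality"]
        genomic_start = row.get("genomic_start")
        seq = str(rec.seq).upper()
        bad = set(seq) - set(IUB_SETS)
        if bad:
            raise ValueError(
                f"record {seg_id!r}: non-IUB characters {sorted(bad)} rejected"
            )
        db.add(
            GermlineSegment(
                id=seg_id,
                segment_class=segment_class,
                functionality=functionality if segment_class == "V" else "functional",
                sequence=seq,
                chromosome=row.get("chromosome") or None,
                genomic_start=int(genomic_start) if genomic_start else None,
            )
        )
    return db


# ---------------------------------------------------------------------------
# numbering


def number_functional_v(
    seg: GermlineSegment, scheme: RegionScheme | None = None
) -> NumberingMap:
    """Assign IMGT codon numbers to a functional/ORF V segment.

    All three reading frames from the 5' end are tried; the frame kept is
    the first in which every anchor residue covered by the sequence
    decodes correctly (Cys23, Trp41, Leu89, Cys104) and no stop codon
    precedes the FR3H end.  Codons are assigned to the occupied positions
    1..104 in order; positions beyond a truncated 3' end stay unassigned.
    """
    scheme = scheme or cattle_scheme()
    if seg.segment_class != "V":
        raise ValueError(f"{seg.id}: not a V segment")
    if seg.functionality == "pseudogene":
        raise ValueError(f"{seg.id}: use transfer_numbering_to_pseudogene")
    positions = scheme.v_positions()
    pos_index = {p: i for i, p in enumerate(positions)}
    first_error: str | None = None
    for frame in range(3):
        codons = [
            seg.sequence[i : i + 3]
            for i in range(frame, len(seg.sequence) - 2, 3)
        ]
        n = min(len(codons), len(positions))
        failed = None
        for anchor_pos, residue in ANCHORS.items():
            idx = pos_index[anchor_pos]
            if idx >= n:
                continue  # truncated before this anchor
            if translate_codon(codons[idx]) != residue:
                failed = anchor_pos
                break
        if failed is None and pos_index[23] < n:
            # reject frames with stops before the FR3H end
            if any(translate_codon(c) == "*" for c in codons[:n]):
                failed = -1
        elif failed is None:
            failed = 23  # too short to even reach the first anchor
        if failed is None:
            codon_positions = {
                positions[i]: (frame + 3 * i, frame + 3 * i + 1, frame + 3 * i + 2)
                for i in range(n)
            }
            anchors = {
                p: codon_positions[p] for p in ANCHORS if p in codon_positions
            }
            return NumberingMap(seg.id, codon_positions, anchors)
        if first_error is None:
            first_error = (
                f"{seg.id}: stop codon before FR3H end (frame {frame})"
                if failed == -1
                else f"{seg.id}: anchor residue mismatch at position {failed} (frame {frame})"
            )
    raise ValueError(first_error or f"{seg.id}: no valid reading frame")


def transfer_numbering_to_pseudogene(
    pseudo: GermlineSegment,
    functional_profiles: dict[str, tuple[GermlineSegment, NumberingMap]],
    scheme: RegionScheme | None = None,
    scoring: ScoringScheme | None = None,
) -> NumberingMap:
    """Copy IMGT numbering onto a pseudogene from the closest functional V.

    The pseudogene is globally aligned (affine gaps, nucleotide level)
    against every numbered functional V; numbering transfers from the one
    with minimal divergence (ties broken by id).  Pseudogene nucleotides
    opposite a gap in the template (insertions) are discarded from the
    map; template positions opposite a gap in the pseudogene (deletions)
    are left unassigned.  Internal stop codons do not block numbering.
    """
    scheme = scheme or cattle_scheme()
    scoring = scoring or builtin_scheme(1)
    if not functional_profiles:
        raise ValueError("no numbered functional V available")
    best = None  # (divergence, template id, alignment)
    for tid in sorted(functional_profiles):
        tseg, tmap = functional_profiles[tid]
        template = tmap.mapped_sequence(tseg, scheme)
        aln = global_align(pseudo.sequence, template, scoring)
        div = divergence(aln).value
        if best is None or div < best[0]:
            best = (div, tid, aln, tseg, tmap)
    div, tid, aln, tseg, tmap = best
    # template nucleotide index -> IMGT position, in mapped order
    positions = [p for p in scheme.v_positions() if p in tmap.codon_positions]
    nt_to_pos: list[int] = []
    for p in positions:
        nt_to_pos.extend([p, p, p])
    per_position: dict[int, list[int]] = {}
    i = j = 0  # i: pseudo index, j: template index
    for x, y in aln.columns():
        if x != "-" and y != "-":
            per_position.setdefault(nt_to_pos[j], []).append(i)
        # x != '-' and y == '-': pseudogene insertion, discarded
        if x != "-":
            i += 1
        if y != "-":
            j += 1
    codon_positions = {
        pos: tuple(idx) for pos, idx in per_position.items() if len(idx) == 3
    }
    if len(codon_positions) < 0.5 * len(positions):
        raise ValueError(
            f"{pseudo.id}: unmappable pseudogene "
            f"({len(codon_positions)}/{len(positions)} positions transferred)"
        )
    anchors = {p: codon_positions[p] for p in ANCHORS if p in codon_positions}
    return NumberingMap(pseudo.id, codon_positions, anchors)


def collapse_identical_v(db: GermlineDatabase) -> GermlineDatabase:
    """Merge V segments identical through position 104 into one reference.

    Identity compares the concatenated nucleotides of mapped positions
    only ("up to the 3' end of FR3H"), so two segments differing solely
    beyond FR3H still collapse.  The merged id joins member names with
    '/' (sorted); the best functionality among members is retained.
    """
    rank = {f: i for i, f in enumerate(FUNCTIONALITIES)}
    groups: dict[str, list[GermlineSegment]] = {}
    for seg in db.v_references():
        if seg.id not in db.numbering:
            raise ValueError(f"{seg.id}: V segment not numbered")
        key = db.numbering[seg.id].mapped_sequence(seg, db.scheme)
        groups.setdefault(key, []).append(seg)
    new_db = GermlineDatabase(db.scheme)
    new_db.fr4_templates = dict(db.fr4_templates)
    for seg in db.segments.values():
        if seg.segment_class != "V":
            new_db.add(seg)
    for key, members in groups.items():
        members.sort(key=lambda s: s.id)
        group_id = "/".join(s.id for s in members)
        lead = min(members, key=lambda s: rank[s.functionality])
        merged = GermlineSegment(
            id=group_id,
            segment_class="V",
            functionality=lead.functionality,
            sequence=members[0].sequence,
            chromosome=members[0].chromosome,
            genomic_start=members[0].genomic_start,
        )
        new_db.add(merged)
        old_map = db.numbering[members[0].id]
        new_db.numbering[group_id] = NumberingMap(
            group_id, dict(old_map.codon_positions), dict(old_map.anchor_positions)
        )
        new_db.identity_groups[group_id] = [s.id for s in members]
    return new_db


def fr4_template(j: GermlineSegment) -> str:
    """The 3'-terminal 33 nucleotides of a germline J define FR4H."""
    if j.segment_class != "J":
        raise ValueError(f"{j.id}: not a J segment")
    if len(j.sequence) < 33:
        raise ValueError(f"{j.id}: J segment shorter than 33 nt")
    return j.sequence[-33:]


def expand_d_orientations(db: GermlineDatabase) -> GermlineDatabase:
    """Add an antisense (reverse-complement) variant of every sense D."""
    for seg in sorted(db.by_class("D"), key=lambda s: s.id):
        if seg.orientation != "sense":
            continue
        as_id = f"{seg.id}_as"
        if as_id in db.segments:
            continue
        db.add(
            GermlineSegment(
                id=as_id,
                segment_class="D",
                functionality=seg.functionality,
                sequence=reverse_complement(seg.sequence),
                orientation="antisense",
                chromosome=seg.chromosome,
                genomic_start=seg.genomic_start,
            )
        )
    return db


# ---------------------------------------------------------------------------
# full preparation


def build_database(
    v_fasta: str | Path,
    d_fasta: str | Path,
    j_fasta: str | Path,
    metadata: str | Path | None = None,
    scheme: RegionScheme | None = None,
) -> GermlineDatabase:
    """Load and fully prepare a germline database from FASTA inputs."""
    db = GermlineDatabase(scheme)
    load_germline_fasta(v_fasta, "V", metadata=metadata, db=db)
    load_germline_fasta(d_fasta, "D", metadata=metadata, db=db)
    load_germline_fasta(j_fasta, "J", metadata=metadata, db=db)
    return prepare_database(db)


def prepare_database(db: GermlineDatabase) -> GermlineDatabase:
    """Number V segments, collapse identical groups, build FR4H templates,
    and expand D orientations on an already-loaded database."""
    profiles: dict[str, tuple[GermlineSegment, NumberingMap]] = {}
    for seg in db.v_references(functional_only=True):
        nmap = number_functional_v(seg, db.scheme)
        db.numbering[seg.id] = nmap
        profiles[seg.id] = (seg, nmap)
    for seg in db.v_references():
        if seg.functionality == "pseudogene":
            db.numbering[seg.id] = transfer_numbering_to_pseudogene(
                seg, profiles, db.scheme
            )
    for j in sorted(db.by_class("J"), key=lambda s: s.id):
        db.fr4_templates[j.id] = fr4_template(j)
    db = collapse_identical_v(db)
    expand_d_orientations(db)
    return db
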