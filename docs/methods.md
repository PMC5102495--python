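# Methods

This note documents the models, conventions and numerical choices behind
`bovig`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the simulation-based validation does and
does not demonstrate.

## Divergence and assignment

All germline assignment is pairwise: one sample sequence against one
reference. The criterion is the **p-distance of an optimal alignment** —
mismatching gap-free columns divided by all gap-free columns — called
*divergence* throughout. Gap columns (including end gaps) are excluded,
so divergence is a fraction of shared sequence. Mismatch is decided by
IUB set intersection: `R` vs `A` is a match because {A,G} ∩ {A} ≠ ∅.
Divergences are ratios of small integers, so ties are tested by exact
equality — no epsilon. Every tied reference is reported; downstream
statistics expand such ambiguous calls to one count per candidate (a
`fractional` 1/ties weighting is available), which is why per-group
denominators can exceed the number of sequences.

## Alignment engine

Alignments are exact affine-gap global alignments (Gotoh three-state
dynamic programme) computed by Biopython's `PairwiseAligner` with
scheme-specific substitution matrices over the full 15-letter IUB
alphabet. A gap of length *k* costs `gap_open + (k−1)·gap_extend`.
Scores are real-valued (procedure 2/3 use a fractional −0.3 extension);
no integer rescaling is applied.

| scheme | match | transition | transversion | gap open | gap extend | used for |
|---|---|---|---|---|---|---|
| procedure1 | +2 | −1 | −1 | −4 | −1 | V, J, optionally D |
| procedure2 | +2 | −1 | −1 | −4 | −0.3 | D |
| procedure3 | +2 | +1 | −1 | −4 | −0.3 | D (recommended) |

Procedure schemes apply to the D search only; V and J assignments always
use the default (procedure 1) scheme. Correctness of the engine under
all three schemes is asserted against an independent brute-force
enumeration of every alignment path for sequences up to length 6 (no
dynamic programming in the oracle). Where several alignments are
co-optimal the engine's first traceback is used; this is deterministic
across runs, and only the divergence readout — never the optimal
score — could differ between co-optimal paths.

Semi-global behaviour (free end gaps on one sequence's overhangs) is
used in two places: the sample's variable region may extend beyond the V
reference (CDR3H+J tail, leader remnants), and the CDR3H extends beyond
the D segment. The shorter sequence is always aligned end-to-end at full
penalty.

## IMGT numbering

The V domain is numbered 1–128 with fixed region bounds (FR1H 1–26,
CDR1H 27–38, FR2H 39–55, CDR2H 56–65, FR3H 66–104, CDR3H 105–117, FR4H
118–128). The scheme is parameterised by the species' unoccupied
positions; the bundled cattle scheme omits 10, 31–34, 60–62 and 73
(119 occupied positions; CDR1H covers 8 of 12, CDR2H 7 of 10). Numbering
a functional V tries the three reading frames from the 5′ end and keeps
the first in which every covered anchor decodes correctly (Cys23, Trp41,
Leu89, Cys104) with no stop before the FR3H end; ties between frames
cannot occur for realistic sequences and resolve to the lowest frame.
Pseudogene numbering is transferred from the minimal-divergence
functional V (ties by id): pseudogene insertions are discarded from the
map, deletions leave positions unassigned, and internal stops are
irrelevant at the nucleotide level. A pseudogene that maps fewer than
50% of the template's positions is rejected as unmappable.

CDR3H loops longer than the 13 base positions gain extended labels
111.1…111.x and 112.y…112.1 at the loop apex; the odd extra position
goes to the 112 side (for length 15: 111.1 and 112.1). Loops shorter
than 13 keep a subset filled from both ends inward, dropping the 5′
apex position first. This fill convention follows general IMGT practice;
no authoritative per-length table exists for the ultralong bovine class,
so the convention is configurable in principle and documented here as a
package choice.

## Per-transcript pipeline

1. **Extraction.** The variable region is the prefix strictly before the
   first occurrence of `GCCTCCACC` (the AlaSerThr start of the IgG CH1
   domain); the reading frame is anchored so the motif begins a codon.
2. **QC.** Records fail with `no_motif`, `premature_stop` (stop anywhere
   in the variable-region translation) or `incomplete` (best V alignment
   does not cover IMGT position 1, or fewer than 33 nt remain for FR4H).
3. **V call.** Each reference's mapped sequence (positions 1–104) is
   aligned to the variable region; divergence is evaluated over the
   framework columns only, per-candidate, using that candidate's own
   numbering map projected through the alignment. References with < 50%
   framework coverage are skipped.
4. **J call.** The 3′-terminal 33 nt against every FR4H template.
5. **CDR3H.** Nucleotides between the sample column aligned to position
   104 and the FR4H start; length in codons, class 1/2/3, extended
   labels as needed.
6. **D call.** Every D variant (sense and antisense) aligned global-in-D
   with free CDR3H end gaps; divergence over D-covered columns only.
   Calls supported by fewer than 6 informative columns are flagged
   low-confidence rather than suppressed; an empty candidate set is
   `undetermined`.

## Gene-conversion detection

Each of FR1H, CDR1H, FR2H, CDR2H, FR3H is re-aligned separately against
the corresponding region of every germline V. An event is emitted for a
region whose minimal-divergence set excludes the full-framework
(acceptor) call; it is **unambiguous** (`unique`) when that set contains
no functional or ORF segment. Evidence is computed on columns anchored
by the sample→donor alignment with donor and acceptor paired by shared
IMGT position: `changed_columns` counts sample=donor≠acceptor columns,
`clustered` requires ≥ 2 such changes within a 9-nt window, flank
homology is the exact sample=donor=acceptor run just outside the changed
tract (3 nt is the documented minimum for plausible conversion), and
`donor_upstream` is set only when genomic metadata places a donor 5′ of
the acceptor on the same chromosome — missing metadata omits the flag,
it never blocks annotation. The window and flank constants are exposed
as module-level configuration. Events are descriptive; no hypothesis
test is attached to them.

## Statistics

Wu–Kabat variability at a position is `k / (c_max / n)` over the
samples that occupy the position (k distinct residues, c_max the count
of the most common, n residues observed); unoccupied positions are
flagged absent, and extended CDR3H labels enter once any sample reaches
them. Bounds: 1 ≤ V ≤ k·n/c_max, with V = k² when residues are equally
frequent. Ambiguous ('X') and stop translations are excluded from the
counts.

The chi-square test is a goodness-of-fit against a **uniform null over
the observed categories** (df = categories − 1). This null is a package
choice — the original statistical design behind such repertoire tables
is typically unstated — so raw counts are always emitted for downstream
re-analysis. Fisher's exact test on segment × group tables uses the
closed-form hypergeometric test for 2×2 (scipy), exact enumeration of
the margin-constrained table space while it is small (≤ 2·10⁵ tables by
a cheap bound), and otherwise a seeded Monte-Carlo permutation estimate
`p = (1 + #{P ≤ P_obs}) / (B + 1)` with the replicate count reported.

## Synthetic data

The generator emulates cloned IgG heavy-chain transcript sets:
`V + N + D + N + J + GCCTCCACC + constant-region stub`, with ground
truth recorded per record and byte-deterministic output under a fixed
seed (a reconstruction check re-derives every emitted sequence from its
truth components). Defaults model the study conditions this framework
targets: four sample groups of 160 records; uniform per-base somatic
mutation at 1%; antisense D usage at 7.5%; junction trimming of 0–3 nt
and N additions of 0–6 nt (junctions are redrawn until the rearrangement
is productive, since cloned IgG transcripts derive from selected B
cells); conversion as a rare event (2%); and 5% + 5% planted QC defects
(premature stop, 5′ truncation), which together with mutation-induced
stops reproduce the ~20% QC exclusion typical of such sets. Toy
germline references are random anchor-satisfying sequences: functional V
mutually distinct (with requested byte-identical pairs), pseudogenes
derived from a functional parent by ~10% substitution plus one internal
FR3H stop, D segments stop-free in all frames and orientations and free
of substring relations, J segments stop-free with distinct FR4H tails.

What the simulations do **not** model: SHM hotspot motifs (RGYW/WRCY),
selection, indels within the V, allelic variation, leader sequences,
CSNS insertions at the V–D junction, or the strongly skewed segment
usage of real repertoires (usage is uniform unless weights are given).
Passing the recovery benchmarks therefore demonstrates correctness of
the assignment machinery under the stated noise model, not performance
on real immunogenetic data, where reference incompleteness and hotspot
mutation are the dominant error sources.

## Validation problem sizes

The test suite and the acceptance script size their simulations for a
single CPU: 500 records for the mutation-free recovery benchmark (100%
V/D/J and orientation recovery; junction trimming disabled there so
planted segments are verbatim — with trimming enabled a trimmed D
legitimately no longer matches its germline uniquely), 200 records for
conversion sensitivity (planted tracts with ≥ 3 diagnostic bases, zero
background mutation: sensitivity 100%, zero false positives), 500
records at 2% background mutation for the false-positive regression
bound (≤ 0.05 unique events per record), 1000 replicates at n = 500 for
chi-square type-I calibration, and 20 000 resamples for the Fisher
Monte-Carlo check. Recovery is scored as the candidate set equalling
exactly the planted truth.
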