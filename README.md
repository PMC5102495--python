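# bovig

Annotation of rearranged bovine immunoglobulin heavy-chain (IgG)
transcripts against a germline IGHV/IGHD/IGHJ reference, with detection
of putative gene-conversion events and repertoire-level statistics.

## The problem

Cattle diversify their antibody repertoire from a small set of germline
genes, relying on somatic hypermutation, junctional diversity, an
exceptionally long CDR3H class (≥ 48 amino acids) found in no other
species, and — more controversially — gene conversion, the templated
replacement of a tract of the rearranged V segment by sequence from a
(typically upstream) pseudogene. General-purpose V(D)J annotation tools
cannot number ultralong bovine CDR3Hs in the IMGT system and do not
compare the functional regions of the V domain separately, which is what
exposes conversion tracts. `bovig` is a framework for exactly this
analysis, aimed at immunogenetics researchers working with livestock
repertoires.

## Method

Sequences are compared by **minimal divergence**: the fraction of
mismatching gap-free columns of an optimal affine-gap global alignment
(p-distance); exact ties produce ambiguous multi-candidate calls.

* **Reference preparation** — functional germline IGHV are IMGT-numbered
  by locating the conserved anchors Cys23, Trp41, Leu89, Cys104;
  numbering is transferred to pseudogenes by alignment against the
  closest functional V (insertions discarded, deletions unassigned).
  V segments 100% identical through the FR3H end are collapsed into one
  reference group (`IGHVx/y`). The 3′-terminal 33 nt of each IGHJ define
  the FR4H template; every IGHD also gets a reverse-complement
  (antisense) variant.
* **Per-transcript annotation** — the variable region is cut at the
  first CH1-start motif `GCCTCCACC` (AlaSerThr); records with premature
  stops or incomplete FR1H–FR4H coverage fail QC. IGHV is assigned on
  the concatenated framework regions only (FR1H+FR2H+FR3H), so the
  hypervariable CDRs cannot dominate the distance; IGHJ on the
  3′-terminal 33 nt; IGHD inside the delimited CDR3H (global in the D,
  free CDR3H end gaps) under one of three scoring procedures —
  `procedure3` adds transition/transversion weighting (match +2,
  transition +1, transversion −1) with IUB ambiguity codes matched by
  set intersection.
* **Gene-conversion scan** — FR1H, CDR1H, FR2H, CDR2H and FR3H are
  re-aligned *separately* against the corresponding region of every
  germline V (functional and pseudogene). A region whose
  minimal-divergence set excludes the full-framework call is an event;
  it is *unambiguous* when no functional segment ties the pseudogene
  donor. Evidence: donor-shared changes, clustering within 9 nt,
  flanking homology, and donor-upstream position when genomic metadata
  is available.
* **Statistics** — usage and V×D×J recombination tables (ambiguous
  calls expand to one count per tied candidate), CDR3H length classes
  (group 1 ≤ 10 aa, group 2 11–47 aa, group 3 ≥ 48 aa with extended
  IMGT labels 111.1…111.x / 112.y…112.1), Wu–Kabat variability
  `k / (c_max / n)` per occupied IMGT position, a chi-square
  goodness-of-fit test of usage skew, and Fisher's exact test for
  segment × group tables (exact enumeration for small tables, seeded
  Monte-Carlo otherwise).

The bundled cattle position scheme occupies 119 of the 128 IMGT
positions (10, 31–34, 60–62 and 73 are unassigned in cattle); other
schemes can be supplied as JSON.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/03_detect_gene_conversion.py` simulates 60 transcripts,
plants pseudogene conversion tracts in half of them, and prints:

```
example event in SIM000004:
  region CDR2H: donor ['IGHV12P'] at divergence 0.000, acceptor IGHV6 at 0.619
  evidence: {'changed_columns': 13, 'clustered': True, 'flank_homology_5': 0,
             'flank_homology_3': 1, 'min_flank_required': 3, 'donor_upstream': True}

planted tracts: 29
detected:       29  (sensitivity 100.0%)
false positives on unconverted records: 0
```

Read: in CDR2H the sample is identical to pseudogene IGHV12P
(divergence 0.000) while its own full-framework germline IGHV6 is 62%
divergent there; the 13 donor-shared changes are clustered and the donor
lies upstream of the acceptor — the classic conversion signature. All 29
planted tracts are recovered with no false calls.

The same workflow is available from the shell:

```bash
bovig simulate --out sim            # toy germline db + simulated samples
bovig run --db sim/db --in sim/samples.fasta --sheet sim/samples.tsv --out results
```

which writes the annotation/event/usage/variability TSV tables, a
self-contained `report.html` and a run manifest.

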