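# Methods

## Coordinate model

All internal genomic coordinates are 0-based half-open; HGVS cDNA anchors
are 1-based per the HGVS standard. The reported "distance from start
codon" is a signed offset with the A of ATG at 0 and negative values
upstream. This origin was chosen so the conversion is exactly invertible:
`c.1` maps to distance 0, and `genomic_to_cdna` recovers the positional
fields of any legal descriptor bit-for-bit (property-tested over ≥1,000
random descriptors across ≥50 random models, plus an exhaustive
base-labelling oracle over every base of 50 models).

Conversion semantics, by region class:

- **coding `c.K`** — the K-th coding base counted along the spliced exons
  from the start codon. The model carries no stop codon, so the coding
  region is taken to run to the end of the last exon; `K` beyond that
  total is an out-of-range error.
- **intronic `c.K±N`** — N bases into the intron from anchor base K. At
  mapping time the anchor must sit at the matching exon boundary (`+` on
  an exon-last base, `−` on an exon-first base) and the landing position
  must lie strictly inside the intron; violations are reported as a
  gene-model/variant inconsistency rather than silently mapped. Anchors in
  a transcribed 5'UTR intron (`c.-M+N`) are accepted, so every genomic
  offset of a gene whose ATG sits beyond exon 1 remains classifiable.
- **5'UTR `c.−M`** — M bases upstream of ATG along the transcript; once
  upstream exonic bases are exhausted, counting continues contiguously
  into the genomic flank upstream of exon 1. HGVS has no notation for
  beyond-transcript positions, and this contiguous extension is what makes
  promoter/upstream variants addressable at all; it is symmetric with the
  `c.*M` rule below.
- **3'UTR `c.*M`** — M bases downstream of the last coding base,
  continuing contiguously into the downstream flank.

The inverse mapping assigns intron bases to the nearer exon boundary, ties
to the upstream boundary (the HGVS convention); `genomic_to_cdna` is total
on `[0, len(sequence))`.

**Strand.** The FASTA is assumed to be the coding strand read 5'→3'.
Minus-strand genes must be supplied reverse-complemented; the strict-mode
reference-base error message points at this when checks fail
systematically. `N` bases are permitted in sequence, never match a
reference base (they report `indeterminate`), and score 0 in the scanner.

**Reference-base checking** is lenient by default — a mismatch produces a
warning, not a failure — because variant nomenclature and the downloaded
sequence frequently disagree in the wild; `--strict-ref` upgrades it to a
fatal error.

## G4 scoring

Per-base scores: +min(n, 4) for each base of a G-run of length n, the
negative for C-runs, 0 for A/T/N. Window means use a sliding arithmetic
mean. Defaults window = 25 nt, threshold = 1.2 — the conventional
operating point of G4Hunter-style scanners, at which |mean| ≥ 1.2
discriminates experimentally supported quadruplex formation reasonably
well. Both are plain keyword arguments / CLI flags.

Region calling: qualifying windows (|mean| ≥ threshold) of the same sign
that overlap or abut are merged into one maximal region spanning the union
of their windows; opposite-sign windows never merge, so an adjacent G-rich
and C-rich tract yield two regions even if their spans touch. The region
score is the mean per-base score over the merged span, and
`max_window_score` the most extreme window mean within it. The merge rule
and region-score definition are this package's own fixed convention;
published scanners differ in their post-processing and none of it changes
which windows qualify.

Antisymmetry under reverse complement (scores negate and reverse) is
property-tested and is what justifies reporting C-rich regions as
G4-forming on the opposite strand.

## Variant–G4 joining

`start_only` (default) measures |SNP − region start| with both expressed
as signed distances from the ATG — equivalently |snp_offset − g4_start| —
and extracts the minimum over regions. It deliberately ignores region
extent; it exists because distance-to-start is the natural quantity when
the G4 table came from an external scanner whose end coordinates may be
absent or differently defined. `interval` mode adds containment: distance
0 iff the SNP lies inside the chosen region, else the gap to the nearer
edge. Distances are absolute, with a separate `relation` field
(`overlapping`/`upstream`/`downstream`, the G4 relative to the SNP), since
a signed minimum over mixed directions has no biological meaning. Ties are
broken toward the smaller genomic start, then smaller end, making output
order-independent and deterministic; both modes are verified against a
brute-force minimum on 1,000 random configurations. An empty region list
raises a dedicated error: "no regions predicted" must not be confusable
with "no overlap".

## Synthetic fixtures

The simulator emulates the structure of a single-gene validation study:
multi-exon genes (default 4 exons of 150–250 bp, introns 150–400 bp,
800 bp flanks, 60 bp transcribed 5'UTR, GC 0.40 — unremarkable values for
short human genes) with an ATG written literally at the start codon,
planted canonically G4-forming motifs (the human telomeric repeat
`GGGTTAGGGTTAGGGTTAGGG`), and planted variants whose truth offsets come
from an exhaustive base labeller that shares no code with the exon-walking
converter. The default validation cohort is 31 variants over 4 genes
spread evenly across coding, intronic, transcribed-5'UTR and upstream
positions, mirroring a realistic mix of regulatory and coding SNPs; all 31
must be recovered exactly, since with consistent inputs the conversion is
deterministic arithmetic.

Two deliberate departures from real genomic sequence: background G/C
homopolymer runs are capped at 2, and each planted motif is insulated by
30 bp of AT-pattern flank. This guarantees the planted motifs are the only
strong G4 signals, so scanner truth is unambiguous at any seed. Real
sequence is not this polite — genes contain many genuine G4 candidates,
and passing fixtures therefore demonstrates correctness of the
coordinate arithmetic, scoring, merging and minimum-extraction, not
biological completeness of G4 annotation on real genes. No population
genetics is modelled (no allele frequencies, no linkage).

## Numerical and degenerate-input choices

- Window means are computed from a cumulative sum; agreement with naive
  per-window summation is asserted to 1e−9.
- A sequence shorter than the window yields an empty result with a
  warning, not an error (a short promoter fragment is a legitimate input).
- File-dialect readers fail loudly with line numbers rather than skipping
  malformed rows; G4-table scores are written with full `repr` precision
  so write → read → write is byte-identical.
- G4-table starts are 1-based inclusive on disk (the GRanges convention of
  web-scanner output) and converted on read.
- The CLI maps missing files to exit code 2 and any library error to exit
  code 1, always as a one-line message.

## Known limitations

- Single transcript per gene; no GFF3/GenBank feature parsing (the
  structure sidecar is deliberately minimal), no fusion or complex
  alleles, no indels/duplications — substitutions only, rejected loudly
  otherwise.
- Minus-strand genes require a reverse-complemented FASTA.
- No structural G4 folding prediction, RNA-specific scoring, or
  enrichment statistics; the scanner scores sequence composition only.
- `start_only` distances can understate proximity to a long region whose
  start is far but whose body is near; use `interval` mode when
  containment matters.
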