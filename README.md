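# g4snp

Locate single-nucleotide variants given in HGVS cDNA notation within a
gene's genomic sequence, and map each variant to the overlapping or nearest
predicted G-quadruplex (G4) region.

G-quadruplexes are four-stranded secondary structures that form in
guanine-rich DNA and RNA and participate in gene regulation; SNPs falling
in or near G4-forming tracts can modulate expression of the harbouring
gene. Answering "how far is this variant from the nearest predicted G4?"
requires (1) converting the clinically reported cDNA coordinate
(`c.506-1G>A`) into a genomic offset on the gene's own sequence, and
(2) predicting G4-prone tracts on that same sequence. `g4snp` does both
locally, for geneticists and molecular biologists who have a single-gene
FASTA, the gene's exon layout, and a list of variants.

## What it computes

**Coordinate conversion.** A gene model is the genomic sequence (coding
strand, 5'→3'), its ordered exon intervals (0-based half-open) and the
offset of the A of the ATG start codon. A cDNA anchor is resolved by exon
walking: `c.K` is the K-th coding base along the spliced exons (`c.1` = A
of ATG); `c.K+N` / `c.K−N` step N bases into the intron beyond
exon-boundary base K; `c.−M` counts upstream of ATG along the transcript,
continuing contiguously into the upstream genomic flank once the
transcribed 5'UTR is exhausted (so promoter and upstream regulatory
variants can be located); `c.*M` counts downstream of the last coding
base. Every position is reported as a signed distance from the A of ATG
(negative = upstream), and the conversion is exactly invertible.

**G4 prediction.** A G4Hunter-style score: each base in a maximal run of
*n* G's scores +min(*n*, 4), each base in a run of *n* C's scores
−min(*n*, 4), A/T/N score 0; a sliding window (default 25 nt) takes the
arithmetic mean, and windows with |mean| ≥ threshold (default 1.2) of
consistent sign are merged into maximal regions. Positive score: the given
strand is G-rich; negative: the complementary strand is.

**Joining.** For each located variant the distance to every G4 region is
measured and the minimum extracted (ties to the smaller genomic start).
The default `start_only` mode measures to the region *start* expressed in
the same ATG-anchored frame; `interval` mode treats a variant inside a
region as distance 0 (`overlapping`).

## Worked example

Simulate a single synthetic gene with planted telomeric-repeat motifs and
ground-truth variants, then run the three stages:

```sh
g4snp simulate --out demo --seed 7 --n-genes 1 --n-variants 4
g4snp locate --folder demo --fasta GENE1.fasta --variant "c.135-4T>A" \
             --append-results demo/results.txt
```

```
GENE1	c.135-4T>A
GTTAACAGCCGGCGTGGCTG"T"GTGACTTCTGCTCCAGCTCA
distance from start codon: 504
```

The variant base is shown in quotation marks inside ±20 bp of context; it
sits 4 bases before coding base 135, i.e. 504 bp downstream of the A of
ATG on the genomic sequence (introns included).

```sh
g4snp scan demo/GENE1.fasta --out-table demo/g4.txt
cat demo/g4.txt
```

```
GENE1 >
GENE1	261	293	ATTAATGGGTTAGGGTTAGGGTTAGGGATTAAT	1.0909090909090908
GENE1	2732	2764	ATTAATCCCTAACCCTAACCCTAACCCATTAAT	-1.0909090909090908
```

Two G4 regions (table coordinates 1-based inclusive): the planted
telomeric repeat in the upstream flank (positive score, G-rich on the
given strand) and its reverse complement downstream (negative score).

```sh
g4snp annotate --results demo/results.txt --g4-table demo/g4.txt --genes-dir demo
```

```
gene	variant	snp_offset	snp_distance_from_ATG	g4_start	g4_end	g4_score	distance	relation	mode
GENE1	c.135-4T>A	1364	504	260	293	1.0909090909090908	1104	upstream	start_only
```

The nearest G4 starts at genomic offset 260 (0-based), 564 bp upstream of
ATG; the variant sits 504 bp downstream, so the start-to-SNP gap is
|504 − (−600)| = 1104 bp and the region lies `upstream` of the SNP.

The same operations are available as a library:

```python
from g4snp import GeneModel, parse_hgvs_cdna, cdna_to_genomic, find_g4_regions
```

## File formats

- **FASTA** — single-gene genomic sequence; the header becomes the gene name.
- **Structure sidecar** — TSV lines `exon <start> <end>` (0-based
  half-open) plus `start_codon <offset>`, or JSON with `exons` /
  `start_codon_offset`.
- **G4 table** — per-gene blocks introduced by a `NAME >` marker line;
  rows `seqnames start end sequence score` with 1-based inclusive starts.
  Tables copied by hand from a web scanner need that same marker edit.
- **SNP results** — per-gene blocks: a bare gene-name line, then
  `variant<TAB>distance` rows.
- **BED6** — scanner output; score = 1000-clamped 250×|score|, strand
  `+`/`-` for G-/C-rich.

See `docs/methods.md` for the model conventions, defaults, and what the
synthetic fixtures do and do not emulate.
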