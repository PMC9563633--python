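"""Synthetic gene models with planted G4 motifs and planted variants.

The simulator builds random multi-exon genes — upstream flank, alternating
exons and introns, downstream flank — over an i.i.d. background with a
chosen GC content, writes a literal ATG at the start-codon offset, splices
in canonically G4-forming motifs (the human telomeric repeat by default)
and samples variants whose true genomic offsets are known by construction,
so every pipeline stage can be checked against ground truth without any
download.

Truth positions come from :func:`label_bases`, a deliberately naive
labeller that enumerates every base of the sequence and classifies it by
linear scan.  It shares no code with the exon-walking arithmetic in
:mod:`~g4snp.gene_model`, so agreement between the two is a genuine
cross-check, not a tautology.

Background G/C homopolymer runs are capped (default 2) so that planted
motifs are the only strong G4 signals and scanner truth stays unambiguous;
real genomic sequence is not this polite, which is exactly why the planted
truth is recoverable at 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, PlantingError
from .g4scan import reverse_complement
from .gene_model import CdnaPosition, GeneModel
from .hgvs import HgvsVariant, format_hgvs

TELOMERIC_MOTIF = "GGGTTAGGGTTAGGGTTAGGG"

REGION_CLASSES = ("coding", "intronic", "utr5", "upstream")


@dataclass(frozen=True)
class PlantedVariant:
    """One planted variant with its ground truth."""

    hgvs: str
    offset: int                     # true genomic offset in the gene FASTA
    distance_from_start_codon: int  # signed, A of ATG = 0
    region_class: str               # one of REGION_CLASSES


@dataclass(frozen=True)
class PlantedG4:
    """Interval of a spliced-in motif, with its strand orientation."""

    start: int
    end: int
    orientation: str  # '+' motif on the given strand, '-' reverse complement


@dataclass(frozen=True)
class FixtureTruth:
    """A simulated gene plus everything planted in it."""

    model: GeneModel
    variants: list[PlantedVariant]
    planted_g4s: list[PlantedG4]
    seed: int


# ---------------------------------------------------------------------------
# exhaustive base labelling (the naive oracle)

def label_bases(model: GeneModel) -> list[CdnaPosition]:
    """Classify every genomic offset of the model by brute enumeration.

    Builds the explicit list of exonic offsets, indexes the ATG in it, and
    labels each base as coding / 5'UTR / 3'UTR / intronic (intron bases go
    to the nearer exon boundary, ties upstream).  Quadratic-ish and
    allocation-happy on purpose: this is the reference path.
    """
    n = len(model.sequence)
    labels: list[CdnaPosition | None] = [None] * n
    exonic = [off for s, e in model.exons for off in range(s, e)]
    t_atg = exonic.index(model.start_codon_offset)

    for t, off in enumerate(exonic):
        if t >= t_atg:
            labels[off] = CdnaPosition("coding", t - t_atg + 1)
        else:
            labels[off] = CdnaPosition("utr5", -(t_atg - t))

    first_start = model.exons[0][0]
    for off in range(first_start):
        labels[off] = CdnaPosition("utr5", -(t_atg + first_start - off))

    last_end = model.exons[-1][1]
    for off in range(last_end, n):
        labels[off] = CdnaPosition("utr3", off - last_end + 1)

    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        for off in range(e1, s2):
            d_prev = off - (e1 - 1)
            d_next = s2 - off
            if d_prev <= d_next:
                labels[off] = CdnaPosition("intronic", labels[e1 - 1].anchor,
                                           d_prev)
            else:
                labels[off] = CdnaPosition("intronic", labels[s2].anchor,
                                           -d_next)
    return labels  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# gene simulation

def _background(rng: np.random.Generator, length: int, gc_content: float,
                max_gc_run: int) -> list[str]:
    """i.i.d. background with capped G/C homopolymer runs."""
    p = [gc_content / 2, gc_content / 2,
         (1 - gc_content) / 2, (1 - gc_content) / 2]
    bases = rng.choice(np.array(list("GCAT")), size=length, p=p)
    out: list[str] = []
    for b in bases:
        b = str(b)
        if b in "GC" and len(out) >= max_gc_run \
                and all(x == b for x in out[-max_gc_run:]):
            b = str(rng.choice(np.array(["A", "T"])))
        out.append(b)
    return out


def simulate_gene(name: str = "GENE1", n_exons: int = 4,
                  exon_len_range: tuple[int, int] = (150, 250),
                  intron_len_range: tuple[int, int] = (150, 400),
                  flank_len: int = 800, gc_content: float = 0.4,
                  utr5_len: int = 60, seed: int = 0,
                  max_gc_run: int = 2) -> GeneModel:
    """Simulate one validated multi-exon gene model.

    The start codon sits ``utr5_len`` bases into exon 1 and an ATG is
    literally written there.  Reproducible given ``seed``.
    """
    if n_exons < 1:
        raise ConfigurationError("need at least one exon")
    if not (0 < gc_content < 1):
        raise ConfigurationError(f"gc_content must be in (0, 1), got {gc_content}")
    for lo, hi in (exon_len_range, intron_len_range):
        if lo < 1 or hi < lo:
            raise ConfigurationError("length ranges must be positive and ordered")
    if flank_len < 0:
        raise ConfigurationError("flank_len must be >= 0")

    rng = np.random.default_rng(seed)
    exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1,
                             size=n_exons)
    intron_lens = rng.integers(intron_len_range[0], intron_len_range[1] + 1,
                               size=max(n_exons - 1, 0))
    if utr5_len + 3 > exon_lens[0]:
        raise ConfigurationError(
            f"utr5_len {utr5_len} + ATG does not fit in exon 1 "
            f"({exon_lens[0]} bp)")

    total = flank_len * 2 + int(exon_lens.sum()) + int(intron_lens.sum())
    seq = _background(rng, total, gc_content, max_gc_run)

    exons: list[tuple[int, int]] = []
    pos = flank_len
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < len(intron_lens):
            pos += int(intron_lens[i])

    sco = flank_len + utr5_len
    seq[sco:sco + 3] = list("ATG")
    return GeneModel(name, "".join(seq), exons, sco)


# ---------------------------------------------------------------------------
# motif planting

def plant_g4(model: GeneModel, at_offset: int,
             motif: str = TELOMERIC_MOTIF, orientation: str = "+",
             existing: list[PlantedG4] | None = None,
             clear_flank: int = 0) -> tuple[GeneModel, PlantedG4]:
    """Splice a G4 motif (or its reverse complement) into the sequence.

    ``clear_flank`` bases on each side are rewritten to an AT pattern so
    the motif's window scores are not perturbed by chance background G/C.
    Overlap with a previously planted interval (pass them via ``existing``)
    or with the ATG start codon raises :class:`PlantingError`.
    """
    if orientation not in "+-":
        raise ConfigurationError(f"orientation must be '+' or '-', got {orientation!r}")
    start, end = at_offset, at_offset + len(motif)
    lo, hi = start - clear_flank, end + clear_flank
    if lo < 0 or hi > len(model.sequence):
        raise ConfigurationError(
            f"motif interval [{lo}, {hi}) (incl. clear_flank) outside "
            f"sequence of length {len(model.sequence)}")
    for p in existing or []:
        if start < p.end and p.start < end:
            raise PlantingError(
                f"motif at [{start}, {end}) overlaps planted [{p.start}, {p.end})")
    if lo < model.start_codon_offset + 3 and model.start_codon_offset < hi:
        raise PlantingError("motif (incl. clear_flank) would clobber the ATG")

    insert = motif.upper() if orientation == "+" else reverse_complement(motif).upper()
    seq = list(model.sequence)
    pad = "ATTA"
    for k, off in enumerate(range(lo, start)):
        seq[off] = pad[k % 4]
    seq[start:end] = list(insert)
    for k, off in enumerate(range(end, hi)):
        seq[off] = pad[k % 4]
    new_model = GeneModel(model.gene_name, "".join(seq), model.exons,
                          model.start_codon_offset)
    return new_model, PlantedG4(start, end, orientation)


# ---------------------------------------------------------------------------
# variant planting

def _class_of(label: CdnaPosition, offset: int, model: GeneModel) -> str:
    if label.region == "intronic":
        return "intronic"
    if label.region == "coding":
        return "coding"
    if label.region == "utr5":
        return "upstream" if offset < model.exons[0][0] else "utr5"
    return "utr3"


def _allocate(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n draws over the mix."""
    total = sum(mix.values())
    if total <= 0:
        raise ConfigurationError("region_mix proportions must sum to > 0")
    quotas = {k: n * v / total for k, v in mix.items() if v > 0}
    counts = {k: int(q) for k, q in quotas.items()}
    short = n - sum(counts.values())
    for k in sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True):
        if short == 0:
            break
        counts[k] += 1
        short -= 1
    return counts


def plant_variants(model: GeneModel, n: int,
                   region_mix: dict[str, float] | None = None,
                   seed: int = 0,
                   exclude: list[PlantedG4] | None = None
                   ) -> list[PlantedVariant]:
    """Sample ``n`` variants with known truth offsets from the model.

    ``region_mix`` gives the proportions per region class (coding /
    intronic / utr5 / upstream); positions are drawn without replacement,
    skipping N bases and any intervals in ``exclude`` (planted motifs).
    The HGVS reference base is read off the sequence, so every planted
    string is consistent with the model by construction.  The alternate
    base is drawn from A/T where possible so no G/C run is created or
    destroyed were the substitution applied.
    """
    if region_mix is None:
        region_mix = {k: 0.25 for k in REGION_CLASSES}
    unknown = set(region_mix) - set(REGION_CLASSES) - {"utr3"}
    if unknown:
        raise ConfigurationError(f"unknown region classes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    labels = label_bases(model)
    excluded = set()
    for p in exclude or []:
        excluded.update(range(p.start, p.end))

    candidates: dict[str, list[int]] = {k: [] for k in region_mix}
    for off, lab in enumerate(labels):
        if off in excluded or model.sequence[off] == "N":
            continue
        cls = _class_of(lab, off, model)
        if cls in candidates:
            candidates[cls].append(off)

    counts = _allocate(n, region_mix)
    out: list[PlantedVariant] = []
    for cls, k in counts.items():
        pool = candidates.get(cls, [])
        if k > len(pool):
            raise ConfigurationError(
                f"region class {cls!r} has only {len(pool)} usable positions "
                f"in gene {model.gene_name!r}, cannot plant {k}")
        for off in map(int, rng.choice(pool, size=k, replace=False)):
            lab = labels[off]
            ref = model.sequence[off]
            alts = [b for b in "AT" if b != ref] or ["C" if ref != "C" else "G"]
            alt = str(rng.choice(np.array(alts)))
            v = HgvsVariant(raw="", region=lab.region, anchor=lab.anchor,
                            intron_offset=lab.intron_offset,
                            ref_base=ref, alt_base=alt)
            out.append(PlantedVariant(
                hgvs=format_hgvs(v), offset=off,
                distance_from_start_codon=off - model.start_codon_offset,
                region_class=cls))
    out.sort(key=lambda p: p.offset)
    return out


# ---------------------------------------------------------------------------
# whole datasets

def simulate_dataset(n_genes: int = 4, n_variants: int = 31, seed: int = 0,
                     n_g4_per_gene: int = 2,
                     region_mix: dict[str, float] | None = None,
                     **gene_kwargs) -> list[FixtureTruth]:
    """Simulate a small validation-style cohort: several genes, planted G4s
    in the flanks, and a pool of variants spread over the region classes.

    Variants are apportioned across genes as evenly as possible (31 over 4
    genes gives 8+8+8+7).  One G4 motif goes into the upstream flank of
    each gene and, when ``n_g4_per_gene`` is 2, a second (reverse-
    complemented) one into the downstream flank.
    """
    if n_genes < 1:
        raise ConfigurationError("need at least one gene")
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=n_genes * 2)
    per_gene = _allocate(n_variants, {f"G{i}": 1.0 for i in range(n_genes)})

    flank = gene_kwargs.setdefault("flank_len", 800)
    truths: list[FixtureTruth] = []
    for i in range(n_genes):
        name = f"GENE{i + 1}"
        model = simulate_gene(name=name, seed=int(sub[2 * i]), **gene_kwargs)
        planted: list[PlantedG4] = []
        motif_len = len(TELOMERIC_MOTIF)
        spots = [(flank // 3, "+")]
        if n_g4_per_gene >= 2:
            spots.append((model.exons[-1][1] + flank // 3, "-"))
        for at, orient in spots[:n_g4_per_gene]:
            if at + motif_len + 30 > len(model.sequence):
                raise ConfigurationError("flank too short to plant a motif")
            model, g4 = plant_g4(model, at, orientation=orient,
                                 existing=planted, clear_flank=30)
            planted.append(g4)
        variants = plant_variants(model, per_gene[f"G{i}"],
                                  region_mix=region_mix,
                                  seed=int(sub[2 * i + 1]), exclude=planted)
        truths.append(FixtureTruth(model=model, variants=variants,
                                   planted_g4s=planted, seed=int(sub[2 * i])))
    return truths


def write_dataset(outdir: str | Path, truths: list[FixtureTruth]) -> dict[str, Path]:
    """Write FASTA + structure sidecar per gene, a batch variants file and
    the truth table.  Returns the paths written, keyed by role."""
    from . import io_formats  # local import: io_formats does not need fixtures

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    var_lines, truth_lines = [], ["gene\thgvs\toffset\tdistance_from_ATG\tregion_class"]
    for t in truths:
        name = t.model.gene_name
        fasta = outdir / f"{name}.fasta"
        sidecar = outdir / f"{name}.structure.tsv"
        io_formats.write_fasta(fasta, name, t.model.sequence)
        io_formats.write_structure(sidecar, t.model.exons,
                                   t.model.start_codon_offset)
        paths[f"{name}.fasta"] = fasta
        paths[f"{name}.structure"] = sidecar
        for v in t.variants:
            var_lines.append(f"{name}\t{v.hgvs}")
            truth_lines.append(f"{name}\t{v.hgvs}\t{v.offset}\t"
                               f"{v.distance_from_start_codon}\t{v.region_class}")
    (outdir / "variants.tsv").write_text("\n".join(var_lines) + "\n")
    (outdir / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    paths["variants"] = outdir / "variants.tsv"
    paths["truth"] = outdir / "truth.tsv"
    return paths
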