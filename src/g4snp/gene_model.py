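"""Gene models and cDNA <-> genomic coordinate conversion.

A :class:`GeneModel` is a single gene's genomic sequence (coding strand,
5'->3'), its ordered exon intervals (0-based, half-open) and the offset of
the A of the ATG start codon.  All reported distances are signed offsets
from that A, which sits at 0; negative means upstream.

The cDNA -> genomic conversion walks the exons, accumulating coding bases
until the requested anchor is reached — the classic exon-counting approach —
and handles four position classes:

* coding ``c.K``: the K-th coding base along the spliced exons, ``c.1`` being
  the A of ATG.  The coding region is taken to extend from the start codon to
  the end of the last exon (the model carries no stop codon).
* intronic ``c.K+N`` / ``c.K-N``: N bases into the intron beyond coding base
  K, which must sit at the corresponding exon boundary.
* 5'UTR ``c.-M``: M bases upstream of ATG along the spliced transcript; once
  the transcribed bases of upstream exons are exhausted, counting continues
  contiguously into the genomic flank upstream of exon 1, which is what lets
  promoter and upstream regulatory variants be located.
* 3'UTR ``c.*M``: M bases downstream of the last coding base, continuing
  contiguously into the downstream flank.

``genomic_to_cdna`` is the exact inverse on every classifiable offset, with
intron bases assigned to the nearer exon boundary (ties to the upstream
boundary, the HGVS convention).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .errors import (
    AlphabetError,
    CoordinateError,
    GeneStructureError,
    OutOfRangeError,
    ReferenceMismatchError,
)
from .hgvs import HgvsVariant

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomicLocation:
    """A 0-based offset in the gene sequence plus its signed distance from
    the A of the start codon (negative = upstream of ATG)."""

    offset: int
    distance_from_start_codon: int


@dataclass(frozen=True)
class CdnaPosition:
    """Positional part of a cDNA description: region kind, anchor, intronic
    offset.  Mirrors the positional fields of :class:`~g4snp.hgvs.HgvsVariant`."""

    region: str  # coding | intronic | utr5 | utr3
    anchor: int
    intron_offset: int = 0


class GeneModel:
    """Validated gene structure: sequence + exons + start-codon offset.

    Parameters
    ----------
    gene_name : str
    sequence : str
        Over {A, C, G, T, N}, any case; stored upper-cased.
    exons : iterable of (start, end)
        0-based half-open, sorted ascending, non-overlapping, non-empty,
        contained in the sequence.
    start_codon_offset : int
        0-based index of the A of ATG; must lie inside some exon.
    """

    def __init__(self, gene_name: str, sequence: str,
                 exons: list[tuple[int, int]], start_codon_offset: int):
        sequence = sequence.upper()
        bad = set(sequence) - _ALPHABET
        if bad:
            raise AlphabetError(
                f"illegal sequence characters {sorted(bad)!r} in gene "
                f"{gene_name!r} (allowed: A, C, G, T, N)"
            )
        exons = [(int(s), int(e)) for s, e in exons]
        if not exons:
            raise GeneStructureError("gene model needs at least one exon")
        prev_end = None
        for s, e in exons:
            if not (0 <= s < e <= len(sequence)):
                raise GeneStructureError(
                    f"exon ({s}, {e}) empty or outside sequence of length "
                    f"{len(sequence)}"
                )
            if prev_end is not None and s < prev_end:
                raise GeneStructureError(
                    f"exons unsorted or overlapping at ({s}, {e})"
                )
            prev_end = e
        if not any(s <= start_codon_offset < e for s, e in exons):
            raise GeneStructureError(
                f"start codon offset {start_codon_offset} does not lie "
                "inside any exon"
            )
        self.gene_name = gene_name
        self.sequence = sequence
        self.exons = exons
        self.start_codon_offset = int(start_codon_offset)
        self._exon_starts = [s for s, _ in exons]
        self._start_exon_index = next(
            i for i, (s, e) in enumerate(exons) if s <= start_codon_offset < e
        )

    # -- derived quantities -------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def coding_length(self) -> int:
        """Exonic bases from the start codon through the end of the last exon."""
        i = self._start_exon_index
        s, e = self.exons[i]
        n = e - self.start_codon_offset
        for s, e in self.exons[i + 1:]:
            n += e - s
        return n

    @property
    def utr5_transcribed_length(self) -> int:
        """Exonic bases upstream of the ATG (the transcribed 5'UTR)."""
        i = self._start_exon_index
        n = self.start_codon_offset - self.exons[i][0]
        for s, e in self.exons[:i]:
            n += e - s
        return n

    def exon_index_of(self, offset: int) -> int | None:
        """Index of the exon containing ``offset``, or None if intronic/flank."""
        i = bisect.bisect_right(self._exon_starts, offset) - 1
        if i >= 0 and self.exons[i][0] <= offset < self.exons[i][1]:
            return i
        return None

    def location(self, offset: int) -> GenomicLocation:
        if not (0 <= offset < len(self.sequence)):
            raise CoordinateError(
                f"offset {offset} outside sequence of length {len(self.sequence)}"
            )
        return GenomicLocation(offset, offset - self.start_codon_offset)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"GeneModel({self.gene_name!r}, {len(self.sequence)} bp, "
                f"{len(self.exons)} exon(s), ATG@{self.start_codon_offset})")


def build_gene_model(name: str, sequence: str, exons: list[tuple[int, int]],
                     start_codon_offset: int) -> GeneModel:
    """Construct and validate a :class:`GeneModel` (functional alias)."""
    return GeneModel(name, sequence, exons, start_codon_offset)


# ---------------------------------------------------------------------------
# cDNA -> genomic

def _coding_base_offset(model: GeneModel, k: int) -> int:
    """Genomic offset of coding base ``c.k`` (k >= 1) by exon walking."""
    if k < 1:
        raise OutOfRangeError(f"coding anchor must be >= 1, got {k}")
    remaining = k
    i = model._start_exon_index
    pos = model.start_codon_offset
    while True:
        s, e = model.exons[i]
        avail = e - pos  # coding bases available in this exon from `pos`
        if remaining <= avail:
            return pos + remaining - 1
        remaining -= avail
        i += 1
        if i >= len(model.exons):
            raise OutOfRangeError(
                f"coding anchor {k} exceeds coding length "
                f"{model.coding_length} of gene {model.gene_name!r}"
            )
        pos = model.exons[i][0]


def _utr5_base_offset(model: GeneModel, m: int) -> int:
    """Genomic offset of 5'UTR base ``c.-m`` (m >= 1), walking upstream exons
    then continuing contiguously into the upstream genomic flank."""
    if m < 1:
        raise OutOfRangeError(f"5'UTR anchor must be <= -1, got -{m}")
    remaining = m
    i = model._start_exon_index
    pos = model.start_codon_offset  # exclusive upper bound for upstream bases
    while True:
        s, _ = model.exons[i]
        avail = pos - s
        if remaining <= avail:
            return pos - remaining
        remaining -= avail
        i -= 1
        if i < 0:
            off = model.exons[0][0] - remaining
            if off < 0:
                raise CoordinateError(
                    f"5'UTR anchor -{m} reaches {-off} bp past the start of "
                    f"the supplied sequence for gene {model.gene_name!r}"
                )
            return off
        pos = model.exons[i][1]


def _utr3_base_offset(model: GeneModel, m: int) -> int:
    """Genomic offset of 3'UTR base ``c.*m`` (m >= 1): m bases downstream of
    the last coding base, i.e. into the downstream flank."""
    if m < 1:
        raise OutOfRangeError(f"3'UTR anchor must be >= 1, got {m}")
    off = model.exons[-1][1] - 1 + m
    if off >= len(model.sequence):
        raise CoordinateError(
            f"3'UTR anchor *{m} reaches past the end of the supplied "
            f"sequence for gene {model.gene_name!r}"
        )
    return off


def _anchor_base_offset(model: GeneModel, anchor: int) -> int:
    """Genomic offset of an intronic variant's anchor base (coding if anchor
    positive, transcribed 5'UTR if negative)."""
    return (_coding_base_offset(model, anchor) if anchor > 0
            else _utr5_base_offset(model, -anchor))


def resolve_cdna_position(model: GeneModel, region: str, anchor: int,
                          intron_offset: int = 0) -> GenomicLocation:
    """Map a cDNA position descriptor to a :class:`GenomicLocation`."""
    if region == "coding":
        return model.location(_coding_base_offset(model, anchor))
    if region == "utr5":
        return model.location(_utr5_base_offset(model, -anchor))
    if region == "utr3":
        return model.location(_utr3_base_offset(model, anchor))
    if region != "intronic":
        raise ValueError(f"unknown region kind {region!r}")
    if intron_offset == 0:
        raise GeneStructureError("intronic position requires a nonzero offset")

    g = _anchor_base_offset(model, anchor)
    i = model.exon_index_of(g)
    if i is None:
        raise GeneStructureError(
            f"anchor {anchor} lies outside the transcribed exons and cannot "
            "carry an intronic offset"
        )
    s, e = model.exons[i]
    if intron_offset > 0:
        if g != e - 1:
            raise GeneStructureError(
                f"anchor {anchor} (+{intron_offset}) is not the last base of "
                f"its exon in gene {model.gene_name!r}: gene model and "
                "variant are inconsistent"
            )
        if i + 1 >= len(model.exons):
            raise GeneStructureError(
                f"anchor {anchor} is in the last exon; no intron follows"
            )
        off = g + intron_offset
        if off >= model.exons[i + 1][0]:
            raise CoordinateError(
                f"intronic offset +{intron_offset} from anchor {anchor} "
                "lands inside the next exon"
            )
    else:
        if g != s:
            raise GeneStructureError(
                f"anchor {anchor} ({intron_offset}) is not the first base of "
                f"its exon in gene {model.gene_name!r}: gene model and "
                "variant are inconsistent"
            )
        if i == 0:
            raise GeneStructureError(
                f"anchor {anchor} is in the first exon; no intron precedes"
            )
        off = g + intron_offset
        if off < model.exons[i - 1][1]:
            raise CoordinateError(
                f"intronic offset {intron_offset} from anchor {anchor} "
                "lands inside the previous exon"
            )
    return model.location(off)


def cdna_to_genomic(model: GeneModel, variant: HgvsVariant) -> GenomicLocation:
    """Genomic location of a parsed HGVS cDNA substitution."""
    return resolve_cdna_position(model, variant.region, variant.anchor,
                                 variant.intron_offset)


# ---------------------------------------------------------------------------
# genomic -> cDNA (exact inverse on the reachable range)

def _classify_exonic(model: GeneModel, offset: int, exon_idx: int) -> CdnaPosition:
    """cDNA descriptor of an exonic base via spliced-transcript arithmetic."""
    t = sum(e - s for s, e in model.exons[:exon_idx])
    t += offset - model.exons[exon_idx][0]
    t_atg = model.utr5_transcribed_length
    if t >= t_atg:
        return CdnaPosition("coding", t - t_atg + 1)
    return CdnaPosition("utr5", -(t_atg - t))


def genomic_to_cdna(model: GeneModel, offset: int) -> CdnaPosition:
    """Classify any genomic offset of the model as a cDNA position.

    Every offset is classifiable: exonic bases become coding or 5'UTR
    anchors, intron bases attach to the nearer exon boundary (ties go
    upstream, per HGVS), the upstream flank continues the 5'UTR count and
    the downstream flank continues the 3'UTR (``*``) count.
    """
    if not (0 <= offset < len(model.sequence)):
        raise CoordinateError(
            f"offset {offset} outside sequence of length {len(model.sequence)}"
        )
    i = model.exon_index_of(offset)
    if i is not None:
        return _classify_exonic(model, offset, i)

    first_start = model.exons[0][0]
    last_end = model.exons[-1][1]
    if offset < first_start:
        return CdnaPosition(
            "utr5", -(model.utr5_transcribed_length + first_start - offset))
    if offset >= last_end:
        return CdnaPosition("utr3", offset - (last_end - 1))

    # intronic: find flanking exons
    j = bisect.bisect_right(model._exon_starts, offset) - 1
    prev_s, prev_e = model.exons[j]
    next_s, _ = model.exons[j + 1]
    d_prev = offset - (prev_e - 1)
    d_next = next_s - offset
    if d_prev <= d_next:
        anchor_pos = _classify_exonic(model, prev_e - 1, j)
        return CdnaPosition("intronic", anchor_pos.anchor, d_prev)
    anchor_pos = _classify_exonic(model, next_s, j + 1)
    return CdnaPosition("intronic", anchor_pos.anchor, -d_next)


# ---------------------------------------------------------------------------
# reference-base checking

@dataclass(frozen=True)
class RefBaseCheck:
    """Result of comparing the sequence base against the variant's stated
    reference base: ``match``, ``mismatch`` or ``indeterminate`` (N)."""

    status: str
    observed: str
    expected: str

    @property
    def ok(self) -> bool:
        return self.status == "match"


def verify_ref_base(model: GeneModel, loc: GenomicLocation,
                    variant: HgvsVariant, strict: bool = False) -> RefBaseCheck:
    """Check that the base at ``loc`` equals the variant's reference base.

    An ``N`` in the sequence is reported ``indeterminate``, never a silent
    match.  In lenient mode (default) a mismatch is only reported — the
    caller decides whether to warn; in strict mode it raises
    :class:`ReferenceMismatchError`.
    """
    observed = model.sequence[loc.offset]
    if observed == "N":
        status = "indeterminate"
    elif observed == variant.ref_base:
        status = "match"
    else:
        status = "mismatch"
    check = RefBaseCheck(status, observed, variant.ref_base)
    if strict and status != "match":
        raise ReferenceMismatchError(
            f"reference base check failed for {variant.raw!r} at offset "
            f"{loc.offset}: sequence has {observed!r}, variant states "
            f"{variant.ref_base!r}. If this happens systematically the FASTA "
            "may be the non-coding strand; supply it reverse-complemented."
        )
    return check
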