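"""Join located variants to predicted G4 regions.

Two distance conventions are provided:

* ``start_only`` (default): distance between the SNP and the *start* of
  each G4 region, both expressed as signed distances from the start codon —
  the G4 start distances are obtained by subtracting the start-codon
  position from each region start, the SNP-to-start gaps are collected and
  the minimum is extracted.
* ``interval``: the SNP is compared against the whole region interval, so
  a SNP inside a region gets distance 0 and relation ``overlapping``;
  otherwise the gap to the nearer region edge is used.

Ties on distance are broken toward the smaller genomic start (then smaller
end) so output is deterministic.  Distances are reported as absolute base
counts with a separate ``relation`` field saying whether the chosen G4 lies
upstream of, downstream of, or over the SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CoordinateError, NoRegionsError
from .g4scan import G4Region
from .gene_model import GeneModel, GenomicLocation, cdna_to_genomic
from .hgvs import HgvsVariant

MODES = ("start_only", "interval")


@dataclass(frozen=True)
class OverlapAnnotation:
    """One variant joined to its nearest / overlapping G4 region."""

    gene_name: str
    variant: HgvsVariant | None
    snp_location: GenomicLocation
    g4: G4Region
    distance: int
    relation: str  # overlapping | upstream | downstream (G4 relative to SNP)
    mode: str


def g4_distance_from_start_codon(model: GeneModel, g4: G4Region) -> int:
    """Signed distance of a G4 region's start from the A of the start codon
    (negative = the region starts upstream of ATG)."""
    if not (0 <= g4.start < g4.end <= len(model.sequence)):
        raise CoordinateError(
            f"G4 region [{g4.start}, {g4.end}) outside sequence of length "
            f"{len(model.sequence)} for gene {model.gene_name!r}"
        )
    return g4.start - model.start_codon_offset


def _distance_and_relation(snp: GenomicLocation, g4: G4Region,
                           mode: str) -> tuple[int, str]:
    if mode == "start_only":
        d = snp.offset - g4.start
        if d == 0:
            return 0, "overlapping"
        return abs(d), ("upstream" if d > 0 else "downstream")
    # interval mode
    if g4.start <= snp.offset < g4.end:
        return 0, "overlapping"
    if snp.offset >= g4.end:
        return snp.offset - (g4.end - 1), "upstream"
    return g4.start - snp.offset, "downstream"


def nearest_g4(snp: GenomicLocation, g4s: list[G4Region], model: GeneModel,
               mode: str = "start_only", gene_name: str | None = None,
               variant: HgvsVariant | None = None) -> OverlapAnnotation:
    """Pick the overlapping or closest G4 region for one located SNP.

    Distances to every region are measured (per ``mode``) and the minimum
    is extracted; ties go to the region with the smaller genomic start.
    An empty region list raises :class:`NoRegionsError` — 'no regions
    predicted' is a different statement from 'no overlap found'.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not g4s:
        raise NoRegionsError(
            f"no G4 regions supplied for gene {gene_name or model.gene_name!r}"
        )
    best = None
    for g4 in g4s:
        g4_distance_from_start_codon(model, g4)  # bounds check
        d, rel = _distance_and_relation(snp, g4, mode)
        key = (d, g4.start, g4.end)
        if best is None or key < best[0]:
            best = (key, g4, d, rel)
    _, g4, d, rel = best
    return OverlapAnnotation(
        gene_name=gene_name or model.gene_name, variant=variant,
        snp_location=snp, g4=g4, distance=d, relation=rel, mode=mode)


def annotate_variants(model: GeneModel, variants: list[HgvsVariant],
                      g4s: list[G4Region],
                      mode: str = "start_only") -> list[OverlapAnnotation]:
    """Locate each variant on the model and join it to its nearest G4."""
    out = []
    for v in variants:
        loc = cdna_to_genomic(model, v)
        out.append(nearest_g4(loc, g4s, model, mode=mode, variant=v))
    return out
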