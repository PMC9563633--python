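"""Parsing and formatting of HGVS cDNA substitution descriptions.

Only single-nucleotide substitutions are in scope: ``c.100A>T``,
``c.88+2T>C``, ``c.506-1G>A``, ``c.-45C>T``, ``c.*12G>A``.  Everything else
(deletions, insertions, duplications, delins, inversions, protein- or
genome-level descriptions) is rejected loudly with an error naming the
offending operator or level.

Anchor semantics follow the HGVS standard: ``c.1`` is the A of the ATG start
codon, ``c.-M`` counts upstream of it along the spliced transcript,
``c.*M`` counts downstream of the last coding base, and ``c.K+N`` / ``c.K-N``
are intronic offsets from exon-boundary base ``K``.  Intronic offsets on
5'UTR anchors (``c.-M+N``) are accepted as well, so that every position of a
gene whose start codon lies beyond exon 1 remains describable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .errors import HgvsParseError, UnsupportedVariantError, WrongLevelError

BASES = frozenset("ACGT")

_TRANSCRIPT_PREFIX = re.compile(r"^[A-Za-z][A-Za-z0-9_.]*:")
_SUBSTITUTION = re.compile(
    r"^c\.(?P<star>\*)?(?P<anchor>-?\d+)(?P<offset>[+-]\d+)?"
    r"(?P<ref>[ACGTacgt])>(?P<alt>[ACGTacgt])$"
)
_UNSUPPORTED_OPS = ("delins", "del", "dup", "ins", "inv", "con")
_WRONG_LEVELS = {"p.": "protein", "g.": "genomic", "n.": "non-coding RNA",
                 "m.": "mitochondrial", "r.": "RNA"}


@dataclass(frozen=True)
class HgvsVariant:
    """A parsed cDNA single-nucleotide substitution.

    ``region`` is one of ``coding``, ``intronic``, ``utr5``, ``utr3``.
    ``anchor`` is the cDNA base number the position is attached to (negative
    for 5'UTR anchors, the star-number for 3'UTR).  ``intron_offset`` is the
    signed ``+N`` / ``-N`` part and is nonzero iff the region is intronic.
    """

    raw: str
    region: str
    anchor: int
    intron_offset: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise HgvsParseError(
                f"reference and alternate base are identical: {self.ref_base!r}"
            )
        if (self.intron_offset != 0) != (self.region == "intronic"):
            raise HgvsParseError(
                "intron_offset must be nonzero exactly for intronic variants"
            )
        if self.region == "utr5" and self.anchor > -1:
            raise HgvsParseError("5'UTR anchors must be negative")
        if self.region in ("coding", "utr3") and self.anchor < 1:
            raise HgvsParseError(f"{self.region} anchor must be >= 1")

    def position_string(self) -> str:
        """Canonical position part, e.g. ``506-1`` or ``*12``."""
        if self.region == "utr3":
            pos = f"*{self.anchor}"
        else:
            pos = str(self.anchor)
        if self.intron_offset:
            pos += f"{self.intron_offset:+d}"
        return pos

    def __str__(self) -> str:
        return format_hgvs(self)


def format_hgvs(variant: HgvsVariant) -> str:
    """Canonical HGVS cDNA string, e.g. ``c.506-1G>A``."""
    return f"c.{variant.position_string()}{variant.ref_base}>{variant.alt_base}"


def parse_hgvs_cdna(text: str) -> HgvsVariant:
    """Parse an HGVS cDNA substitution string into an :class:`HgvsVariant`.

    A leading transcript identifier (``NM_000106.6:``) is stripped; embedded
    whitespace is tolerated; base case is normalised to upper.

    Raises
    ------
    WrongLevelError
        For ``p.`` / ``g.`` / other non-cDNA descriptions.
    UnsupportedVariantError
        For non-substitution operators, naming the operator.
    HgvsParseError
        For anything else malformed, naming the offending token.
    """
    raw = text
    s = "".join(text.split())  # whitespace-tolerant
    if not s:
        raise HgvsParseError("empty variant string")
    s = _TRANSCRIPT_PREFIX.sub("", s, count=1)
    for prefix, level in _WRONG_LEVELS.items():
        if s.startswith(prefix):
            raise WrongLevelError(
                f"{level}-level description {prefix!r} is not cDNA; "
                f"expected a 'c.' variant, got {raw!r}"
            )
    if not s.startswith("c."):
        raise HgvsParseError(f"expected 'c.' prefix, got {s[:2]!r} in {raw!r}")

    m = _SUBSTITUTION.match(s)
    if m is None:
        lowered = s.lower()
        for op in _UNSUPPORTED_OPS:
            if op in lowered:
                raise UnsupportedVariantError(
                    f"unsupported HGVS operator {op!r} in {raw!r}: only "
                    "single-nucleotide substitutions are handled"
                )
        raise HgvsParseError(f"malformed cDNA substitution: {s!r}")

    anchor = int(m.group("anchor"))
    offset = int(m.group("offset")) if m.group("offset") else 0
    if m.group("star"):
        if anchor < 1:
            raise HgvsParseError(f"3'UTR anchor must be positive in {s!r}")
        if offset:
            raise UnsupportedVariantError(
                f"intronic offsets on 3'UTR anchors are not supported: {s!r}"
            )
        region = "utr3"
    elif offset != 0:
        if anchor == 0:
            raise HgvsParseError(f"anchor 0 is not a valid cDNA position: {s!r}")
        region = "intronic"
    elif anchor < 0:
        region = "utr5"
    elif anchor >= 1:
        region = "coding"
    else:
        raise HgvsParseError(f"anchor 0 is not a valid cDNA position: {s!r}")

    return HgvsVariant(
        raw=raw,
        region=region,
        anchor=anchor,
        intron_offset=offset,
        ref_base=m.group("ref").upper(),
        alt_base=m.group("alt").upper(),
    )


def parse_variants_file(path: str | Path) -> list[tuple[str | None, HgvsVariant]]:
    """Read a batch file: one variant per line, optionally ``gene<TAB>variant``.

    Blank lines and ``#`` comment lines are skipped.  Returns a list of
    ``(gene_name or None, variant)`` pairs in file order.
    """
    out: list[tuple[str | None, HgvsVariant]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            gene, _, var = line.partition("\t")
            gene = gene.strip() or None
        else:
            gene, var = None, line
        try:
            out.append((gene, parse_hgvs_cdna(var)))
        except HgvsParseError as exc:
            raise HgvsParseError(f"line {lineno}: {exc}") from exc
    return out
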