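"""Exception hierarchy for the toolkit.

Every error raised by the library derives from :class:`G4SnpError`, so the CLI
can catch one type and print a clean message instead of a traceback.
"""


class G4SnpError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(G4SnpError):
    """Sequence contains a character outside {A, C, G, T, N}."""


class GeneStructureError(G4SnpError):
    """Exon list / start-codon layout violates the gene-model invariants,
    or a variant is inconsistent with the gene structure (e.g. an intronic
    offset anchored to a base that is not at an exon boundary)."""


class CoordinateError(G4SnpError):
    """A computed genomic coordinate falls outside the sequence, or an
    intronic offset lands inside an exon."""


class OutOfRangeError(CoordinateError):
    """A cDNA anchor exceeds the coding length of the model."""


class HgvsParseError(G4SnpError):
    """Malformed HGVS cDNA string; the message names the offending token."""


class UnsupportedVariantError(HgvsParseError):
    """Syntactically valid HGVS that is not a single-nucleotide substitution
    (del / ins / dup / delins / inv); the message names the operator."""


class WrongLevelError(HgvsParseError):
    """A non-cDNA HGVS description (p., g., n., m., r.)."""


class ReferenceMismatchError(G4SnpError):
    """Strict-mode failure: the base in the sequence does not match the
    variant's stated reference base."""


class FormatError(G4SnpError):
    """Malformed line in one of the text-file dialects."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class NoRegionsError(G4SnpError):
    """Nearest-G4 lookup over an empty region list (distinct from 'no
    overlapping region')."""


class ConfigurationError(G4SnpError):
    """Impossible simulation geometry or an unavailable region class."""


class PlantingError(ConfigurationError):
    """A motif would overlap a previously planted one."""
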