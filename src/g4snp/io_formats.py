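"""Readers and writers for the toolkit's text formats.

Besides standard FASTA / BED6 / TSV this module implements two small
single-purpose dialects used to pass results between the locator and the
overlap stage:

* **G4 table** — whitespace-separated per-gene blocks.  A gene's block is
  introduced by a marker line consisting of the gene name followed by a
  ``>`` symbol; data rows carry the columns ``seqnames start end sequence
  score`` with 1-based *inclusive* coordinates (the convention of
  GRanges-style G4Hunter output), converted to internal 0-based half-open
  on read.  Unknown trailing columns are ignored.  Tables hand-copied from
  a web scanner need the same edit: insert the ``NAME >`` marker before each
  gene's rows.
* **SNP results file** — per-gene blocks: a line with the bare gene name,
  then one line per located variant: ``<variant><TAB><signed distance from
  the start codon>``.

All readers reject malformed rows with a :class:`~g4snp.errors.FormatError`
carrying the line number rather than skipping them silently, and each
writer/reader pair round-trips byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO

from .errors import FormatError
from .g4scan import G4Region
from .overlap import OverlapAnnotation

ANNOTATION_COLUMNS = [
    "gene", "variant", "snp_offset", "snp_distance_from_ATG",
    "g4_start", "g4_end", "g4_score", "distance", "relation", "mode",
]


# ---------------------------------------------------------------------------
# FASTA + gene-structure sidecar

def read_fasta(path: str | Path, record_name: str | None = None) -> tuple[str, str]:
    """Return ``(gene_name, sequence)`` from a FASTA file.

    The first record is used unless ``record_name`` selects one; the header
    text after ``>`` becomes the default gene name.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if record_name is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_name]
        if not matches:
            raise FormatError(
                f"record {record_name!r} not found in {path} "
                f"(available: {[r.id for r in records]})"
            )
        rec = matches[0]
    return rec.description or rec.id, str(rec.seq).upper()


def write_fasta(path: str | Path, name: str, sequence: str,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def read_structure(path: str | Path) -> tuple[list[tuple[int, int]], int]:
    """Read a gene-structure sidecar; returns ``(exons, start_codon_offset)``.

    Two formats are accepted: JSON with keys ``exons`` and
    ``start_codon_offset``, or TSV with lines ``exon <start> <end>``
    (0-based half-open) plus one line ``start_codon <offset>``.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        data = json.loads(text)
        try:
            exons = [(int(s), int(e)) for s, e in data["exons"]]
            sco = int(data["start_codon_offset"])
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"bad structure JSON in {path}: {exc}") from exc
        return exons, sco

    exons: list[tuple[int, int]] = []
    sco: int | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        fields = line.split()
        if not fields or fields[0].startswith("#"):
            continue
        try:
            if fields[0] == "exon":
                exons.append((int(fields[1]), int(fields[2])))
            elif fields[0] == "start_codon":
                sco = int(fields[1])
            else:
                raise FormatError(
                    f"unknown directive {fields[0]!r}", lineno)
        except (IndexError, ValueError) as exc:
            raise FormatError(f"bad structure line {line!r}", lineno) from exc
    if sco is None:
        raise FormatError(f"no start_codon line in {path}")
    if not exons:
        raise FormatError(f"no exon lines in {path}")
    return exons, sco


def write_structure(path: str | Path, exons: Iterable[tuple[int, int]],
                    start_codon_offset: int) -> None:
    with open(path, "w") as fh:
        for s, e in exons:
            fh.write(f"exon\t{s}\t{e}\n")
        fh.write(f"start_codon\t{start_codon_offset}\n")


# ---------------------------------------------------------------------------
# G4 table dialect

def read_g4_table(path: str | Path) -> dict[str, list[G4Region]]:
    """Parse a per-gene G4 table into ``{gene_name: [G4Region, ...]}``.

    Starts are converted from the table's 1-based inclusive convention to
    internal 0-based half-open; sequences are upper-cased.  A data row
    appearing before any ``NAME >`` marker is a format error.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"empty G4 table: {path}")
    tables: dict[str, list[G4Region]] = {}
    gene: str | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) == 2 and fields[1] == ">":
            gene = fields[0]
            tables.setdefault(gene, [])
            continue
        if fields[0].lower() == "seqnames":  # tolerated header from web output
            continue
        if gene is None:
            raise FormatError(
                f"data row before any gene marker ('NAME >'): {line!r}", lineno)
        if len(fields) < 5:
            raise FormatError(
                f"expected >=5 columns (seqnames start end sequence score), "
                f"got {len(fields)}: {line!r}", lineno)
        seqname, start_s, end_s, seq, score_s = fields[:5]
        try:
            start1 = int(start_s)
            end1 = int(end_s)
        except ValueError as exc:
            raise FormatError(f"unparseable start/end in {line!r}", lineno) from exc
        if start1 < 1:
            raise FormatError(f"start must be a positive integer, got {start1}",
                              lineno)
        try:
            score = float(score_s)
        except ValueError as exc:
            raise FormatError(f"unparseable score in {line!r}", lineno) from exc
        tables[gene].append(G4Region(
            seqname=seqname, start=start1 - 1, end=end1,
            sequence=seq.upper(), score=score, max_window_score=score))
    return tables


def write_g4_table(path: str | Path, tables: dict[str, list[G4Region]]) -> None:
    """Write the per-gene G4 table dialect (inverse of :func:`read_g4_table`)."""
    with open(path, "w") as fh:
        for gene, regions in tables.items():
            fh.write(f"{gene} >\n")
            for r in regions:
                fh.write(f"{r.seqname}\t{r.start + 1}\t{r.end}\t"
                         f"{r.sequence}\t{r.score!r}\n")


# ---------------------------------------------------------------------------
# SNP results dialect

def read_snp_results(path: str | Path) -> dict[str, list[tuple[str, int]]]:
    """Parse a SNP results file into ``{gene: [(variant_text, distance), ...]}``.

    Gene lines carry a single token; variant lines carry the variant text
    and its signed distance from the start codon.  Blank lines are fine;
    a variant line before any gene line, or a non-integer distance, is a
    format error with the line number.
    """
    results: dict[str, list[tuple[str, int]]] = {}
    gene: str | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) == 1:
            gene = fields[0]
            results.setdefault(gene, [])
            continue
        if len(fields) != 2:
            raise FormatError(
                f"expected 'variant distance' (2 fields), got {line!r}", lineno)
        if gene is None:
            raise FormatError(
                f"variant line before any gene name: {line!r}", lineno)
        try:
            dist = int(fields[1])
        except ValueError as exc:
            raise FormatError(
                f"distance is not an integer in {line!r}", lineno) from exc
        results[gene].append((fields[0], dist))
    return results


def write_snp_results(path: str | Path,
                      results: dict[str, list[tuple[str, int]]]) -> None:
    with open(path, "w") as fh:
        for gene, rows in results.items():
            fh.write(f"{gene}\n")
            for variant_text, dist in rows:
                fh.write(f"{variant_text}\t{dist}\n")


def append_snp_result(path: str | Path, gene: str, variant_text: str,
                      distance: int) -> None:
    """Append one located variant, writing the gene header only when the
    file's last gene block is a different gene."""
    path = Path(path)
    existing = read_snp_results(path) if path.exists() else {}
    last_gene = next(reversed(existing), None) if existing else None
    with open(path, "a") as fh:
        if gene != last_gene:
            fh.write(f"{gene}\n")
        fh.write(f"{variant_text}\t{distance}\n")


# ---------------------------------------------------------------------------
# BED + annotation TSV

def write_bed(path_or_handle: str | Path | TextIO,
              regions: Iterable[G4Region]) -> None:
    """Write G4 regions as BED6: score column = 1000-clamped 250x|score|,
    strand '+' for G-rich, '-' for C-rich."""
    own = isinstance(path_or_handle, (str, Path))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        for i, r in enumerate(regions, start=1):
            bed_score = min(1000, int(round(abs(r.score) * 250)))
            fh.write(f"{r.seqname}\t{r.start}\t{r.end}\tG4_{i}\t"
                     f"{bed_score}\t{r.strand}\n")
    finally:
        if own:
            fh.close()


def annotations_to_frame(annotations: Iterable[OverlapAnnotation]) -> pd.DataFrame:
    """Tabulate overlap annotations (one row per variant-G4 join)."""
    rows = []
    for a in annotations:
        rows.append({
            "gene": a.gene_name,
            "variant": str(a.variant) if a.variant is not None else ".",
            "snp_offset": a.snp_location.offset,
            "snp_distance_from_ATG": a.snp_location.distance_from_start_codon,
            "g4_start": a.g4.start,
            "g4_end": a.g4.end,
            "g4_score": a.g4.score,
            "distance": a.distance,
            "relation": a.relation,
            "mode": a.mode,
        })
    frame = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return frame.sort_values(["gene", "variant"], kind="stable",
                             ignore_index=True)


def write_annotation_tsv(path_or_handle: str | Path | TextIO,
                         annotations: Iterable[OverlapAnnotation]) -> None:
    frame = annotations_to_frame(annotations)
    frame.to_csv(path_or_handle, sep="\t", index=False)


def write_snp_bed(path_or_handle: str | Path | TextIO,
                  annotations: Iterable[OverlapAnnotation]) -> None:
    """BED of SNP positions, nearest-G4 annotation packed into the name field."""
    own = isinstance(path_or_handle, (str, Path))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        for a in annotations:
            name = (f"{a.variant if a.variant is not None else 'SNP'}"
                    f"|G4@{a.g4.start}-{a.g4.end}|d={a.distance}|{a.relation}")
            fh.write(f"{a.gene_name}\t{a.snp_location.offset}\t"
                     f"{a.snp_location.offset + 1}\t{name}\t0\t+\n")
    finally:
        if own:
            fh.close()
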