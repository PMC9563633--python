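"""G4Hunter-style prediction of G-quadruplex-prone regions.

The score rewards G-richness and G-skewness: each base in a maximal run of
``n`` consecutive G's scores ``+min(n, 4)``, each base in a run of ``n``
C's scores ``-min(n, 4)``, and A/T/N score 0.  A sliding window (default
25 nt) averages the per-base scores; windows whose |mean| reaches the
threshold (default 1.2) on a consistent sign are merged, when they overlap
or abut, into maximal candidate regions.  Positive scores mean the given
strand is G-rich; negative scores mean the opposite strand is (the region
coordinates are identical either way).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import groupby

import numpy as np

from .errors import AlphabetError

DEFAULT_WINDOW = 25
DEFAULT_THRESHOLD = 1.2

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class G4Region:
    """A predicted quadruplex-prone interval (0-based half-open).

    ``score`` is the mean per-base score over the whole region;
    ``max_window_score`` is the most extreme window mean inside it.  Both
    carry the same sign: positive for G-rich, negative for C-rich.
    """

    seqname: str
    start: int
    end: int
    sequence: str
    score: float
    max_window_score: float

    @property
    def strand(self) -> str:
        return "+" if self.score >= 0 else "-"


def base_scores(sequence: str) -> np.ndarray:
    """Per-base G4Hunter scores (int array, same length as the sequence).

    Runs of G score +min(run length, 4) per base, runs of C the negative;
    A, T and N score 0 (N breaks a run).
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise AlphabetError(
            f"illegal sequence characters {sorted(bad)!r} (allowed: A, C, G, T, N)"
        )
    scores = np.zeros(len(seq), dtype=np.int64)
    pos = 0
    for base, run in groupby(seq):
        n = sum(1 for _ in run)
        if base == "G":
            scores[pos:pos + n] = min(n, 4)
        elif base == "C":
            scores[pos:pos + n] = -min(n, 4)
        pos += n
    return scores


def window_scores(scores: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Sliding-window arithmetic means of the per-base scores.

    Returns ``len(scores) - window + 1`` values (value i covers
    ``scores[i : i + window]``); an input shorter than the window yields an
    empty array with a warning rather than an error.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    scores = np.asarray(scores, dtype=float)
    if len(scores) < window:
        warnings.warn(
            f"sequence length {len(scores)} shorter than window {window}; "
            "no windows scored", stacklevel=2)
        return np.empty(0, dtype=float)
    c = np.concatenate(([0.0], np.cumsum(scores)))
    return (c[window:] - c[:-window]) / window


def find_g4_regions(seqname: str, sequence: str,
                    window: int = DEFAULT_WINDOW,
                    threshold: float = DEFAULT_THRESHOLD) -> list[G4Region]:
    """Scan a sequence and return merged G4 candidate regions sorted by start.

    Windows with ``|mean| >= threshold`` are kept; same-sign qualifying
    windows that overlap or abut are merged into one maximal region whose
    span is the union of its windows.  Opposite-sign windows never merge
    (a G-rich and an adjacent C-rich region stay separate even if their
    spans touch).  The region score is the mean per-base score over the
    merged span and ``max_window_score`` the most extreme window mean in it.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    scores = base_scores(sequence)
    wmeans = window_scores(scores, window)
    if len(wmeans) == 0:
        return []
    hits = np.flatnonzero(np.abs(wmeans) >= threshold)
    regions: list[G4Region] = []
    group: list[int] = []

    def flush(idxs: list[int]) -> None:
        start = idxs[0]
        end = idxs[-1] + window
        span_score = float(np.mean(scores[start:end]))
        vals = wmeans[idxs]
        mx = float(vals[np.argmax(np.abs(vals))])
        regions.append(G4Region(seqname=seqname, start=start, end=end,
                                sequence=sequence[start:end].upper(),
                                score=span_score, max_window_score=mx))

    for i in hits:
        i = int(i)
        if group and (i - group[-1] > window
                      or np.sign(wmeans[i]) != np.sign(wmeans[group[-1]])):
            flush(group)
            group = []
        group.append(i)
    if group:
        flush(group)
    regions.sort(key=lambda r: (r.start, r.end))
    return regions
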