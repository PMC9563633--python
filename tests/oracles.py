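"""Independent reference implementations used as oracles by the tests.

Everything here is deliberately naive — linear scans, per-window summation,
brute-force minima — and shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np

from g4snp.gene_model import CdnaPosition, GeneModel


def label_all_bases(model: GeneModel) -> list[CdnaPosition]:
    """Label every genomic offset by explicit enumeration.

    Walks the sequence base by base, tracking the transcript index of each
    exonic base; intron bases go to the nearer exon boundary (ties to the
    upstream boundary); flanks continue the 5'UTR / 3'UTR counts.
    """
    transcript: dict[int, int] = {}  # genomic offset -> transcript index
    t = 0
    for s, e in model.exons:
        for off in range(s, e):
            transcript[off] = t
            t += 1
    t_atg = transcript[model.start_codon_offset]

    def exonic_label(off: int) -> CdnaPosition:
        ti = transcript[off]
        if ti >= t_atg:
            return CdnaPosition("coding", ti - t_atg + 1)
        return CdnaPosition("utr5", ti - t_atg)

    labels = []
    for off in range(len(model.sequence)):
        if off in transcript:
            labels.append(exonic_label(off))
            continue
        if off < model.exons[0][0]:
            labels.append(CdnaPosition("utr5", -t_atg - (model.exons[0][0] - off)))
            continue
        if off >= model.exons[-1][1]:
            labels.append(CdnaPosition("utr3", off - model.exons[-1][1] + 1))
            continue
        prev_end = max(e for _, e in model.exons if e <= off)
        next_start = min(s for s, _ in model.exons if s > off)
        d_prev = off - (prev_end - 1)
        d_next = next_start - off
        if d_prev <= d_next:
            labels.append(CdnaPosition("intronic",
                                       exonic_label(prev_end - 1).anchor, d_prev))
        else:
            labels.append(CdnaPosition("intronic",
                                       exonic_label(next_start).anchor, -d_next))
    return labels


def brute_base_scores(sequence: str) -> list[int]:
    """Per-base G4Hunter scores by explicit run enumeration."""
    seq = sequence.upper()
    scores = [0] * len(seq)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if seq[i] == "G":
            scores[i:j] = [min(j - i, 4)] * (j - i)
        elif seq[i] == "C":
            scores[i:j] = [-min(j - i, 4)] * (j - i)
        i = j
    return scores


def brute_window_means(scores, window: int) -> list[float]:
    return [sum(scores[i:i + window]) / window
            for i in range(len(scores) - window + 1)]


def brute_nearest(snp_offset: int, g4s, mode: str):
    """Exhaustive-scan nearest region; returns (region, distance)."""
    def dist(g4) -> int:
        if mode == "start_only":
            return abs(snp_offset - g4.start)
        if g4.start <= snp_offset < g4.end:
            return 0
        if snp_offset >= g4.end:
            return snp_offset - (g4.end - 1)
        return g4.start - snp_offset

    best = min(g4s, key=lambda g: (dist(g), g.start, g.end))
    return best, dist(best)


def random_model(rng: np.random.Generator, max_exons: int = 5) -> GeneModel:
    """A small random-but-valid gene model for property tests."""
    n_exons = int(rng.integers(1, max_exons + 1))
    flank = int(rng.integers(5, 60))
    pieces, exons = [], []
    pos = flank
    pieces.append("".join(rng.choice(list("ACGT"), size=flank)))
    for i in range(n_exons):
        el = int(rng.integers(5, 40))
        exons.append((pos, pos + el))
        pieces.append("".join(rng.choice(list("ACGT"), size=el)))
        pos += el
        if i < n_exons - 1:
            il = int(rng.integers(2, 50))
            pieces.append("".join(rng.choice(list("ACGT"), size=il)))
            pos += il
    pieces.append("".join(rng.choice(list("ACGT"), size=flank)))
    seq = list("".join(pieces))
    # start codon anywhere inside a random exon (ATG written literally when room)
    ei = int(rng.integers(0, n_exons))
    s, e = exons[ei]
    sco = int(rng.integers(s, e))
    for k, b in enumerate("ATG"):
        if sco + k < len(seq):
            seq[sco + k] = b
    return GeneModel(f"RND{int(rng.integers(1e6))}", "".join(seq), exons, sco)
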