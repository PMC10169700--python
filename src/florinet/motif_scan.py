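"""Log-odds motif scanning of promoters with exact p-values.

Each motif is turned into a pseudocounted log2-odds matrix against a 0-order
background. Scores are discretized to a fixed granularity (default 1/1000
bit) and the exact null distribution of the total window score is obtained by
convolving the per-position score distributions under the background — the
same dynamic programme FIMO uses — so every emitted hit carries the exact
probability that a random background word scores at least as high.

Both strands of every promoter are scanned; windows overlapping an N are
skipped rather than scored. The occurrence threshold is a raw per-test
p-value (default 1e-5); no multiple-testing correction is applied across
positions or promoters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import MotifModel
from .promoters import PromoterSequence
from .seqcodes import encode

__all__ = [
    "ScoringModel",
    "build_scoring_model",
    "scan_promoters",
    "scan_sequences",
    "estimate_background",
]

UNIFORM_BG = np.full(4, 0.25)

HIT_COLUMNS = ["gene", "motif", "offset", "strand", "score_bits", "p_value"]


def estimate_background(sequences: Iterable[str]) -> np.ndarray:
    """0-order A/C/G/T composition of a sequence collection (N ignored)."""
    tot = np.zeros(4)
    for seq in sequences:
        codes = encode(seq)
        tot += np.bincount(codes[codes < 4], minlength=4)
    if tot.sum() == 0:
        raise ValueError("no unambiguous bases to estimate background from")
    return tot / tot.sum()


@dataclass
class ScoringModel:
    """Discretized log-odds matrix plus the exact null tail distribution.

    ``tail[i]`` is P(score >= (min_score + i) * granularity) under the
    background; ``tail[0]`` is 1 by construction.
    """

    motif_id: str
    log_odds: np.ndarray  # (width, 4), bits
    granularity: float
    int_scores: np.ndarray  # (width, 4), log_odds rounded to granularity units
    min_score: int  # sum over positions of per-column minima (granularity units)
    tail: np.ndarray  # exact upper-tail probability per achievable bin

    @property
    def width(self) -> int:
        return int(self.log_odds.shape[0])

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.tail) - 1

    def pvalue(self, score_units: int | np.ndarray) -> np.ndarray:
        """Exact P(null score >= score) for integer scores in granularity units."""
        idx = np.clip(np.asarray(score_units) - self.min_score, 0, len(self.tail) - 1)
        p = self.tail[idx]
        # scores above the achievable maximum are impossible under any word
        return np.where(np.asarray(score_units) > self.max_score, 0.0, p)


def build_scoring_model(
    motif: MotifModel,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.1,
    granularity: float = 1e-3,
) -> ScoringModel:
    """Pseudocounted log2-odds scores and their exact null distribution.

    The pseudocounted probability is (p + pseudocount*bg) / (1 + pseudocount),
    the FIMO convention, so a zero matrix entry stays finite whenever the
    pseudocount is positive.
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6 or (bg < 0).any():
        raise ValueError("background must be 4 probabilities summing to 1")
    if pseudocount == 0 and ((motif.matrix == 0).any() or (bg == 0).any()):
        raise ValueError(
            f"motif {motif.motif_id!r}: zero probability with zero pseudocount gives undefined log-odds"
        )
    if (bg == 0).any():
        raise ValueError("zero background frequency gives undefined log-odds")
    p = (motif.matrix + pseudocount * bg) / (1.0 + pseudocount)
    log_odds = np.log2(p / bg)
    int_scores = np.rint(log_odds / granularity).astype(np.int64)

    # exact null distribution by position-wise convolution under the background
    pmf = np.array([1.0])
    total_min = 0
    for i in range(int_scores.shape[0]):
        col = int_scores[i]
        cmin, cmax = int(col.min()), int(col.max())
        new = np.zeros(len(pmf) + (cmax - cmin))
        for b in range(4):
            off = int(col[b]) - cmin
            new[off : off + len(pmf)] += bg[b] * pmf
        pmf = new
        total_min += cmin
    tail = pmf[::-1].cumsum()[::-1]
    return ScoringModel(motif.motif_id, log_odds, granularity, int_scores, total_min, tail)


def _window_scores(codes: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total discretized score of every window, plus validity (no N) mask."""
    w = int_scores.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    total = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(w):
        c = codes[i : i + n]
        ok = c < 4
        valid &= ok
        total += int_scores[i][np.minimum(c, 3)]
    return total, valid


def scan_sequences(
    sequences: dict[str, str],
    models: Sequence[ScoringModel],
    p_threshold: float = 1e-5,
    both_strands: bool = True,
    rc_models: Sequence[ScoringModel] | None = None,
) -> pd.DataFrame:
    """Scan named sequences with prebuilt scoring models.

    Returns a hit table with one row per (sequence, motif, offset, strand)
    whose exact p-value is <= ``p_threshold``, sorted by
    (gene, motif, offset, strand). Offsets are 0-based starts in the given
    sequence orientation; strand "-" means the motif matches the reverse
    complement of the window.
    """
    if not (0 <= p_threshold <= 1):
        raise ValueError("p_threshold must lie in [0, 1]")
    names = list(sequences)
    # concatenate with a separator code (4) so no window spans two sequences
    pieces, starts, pos = [], [], 0
    for name in names:
        codes = encode(sequences[name])
        if (codes > 4).any():
            raise ValueError(f"sequence {name!r} contains non-ACGTN characters")
        pieces.append(codes)
        pieces.append(np.array([4], dtype=np.uint8))
        starts.append(pos)
        pos += len(codes) + 1
    cat = np.concatenate(pieces) if pieces else np.zeros(0, dtype=np.uint8)
    starts_arr = np.asarray(starts)
    lengths = np.asarray([len(sequences[n]) for n in names])

    if rc_models is None and both_strands:
        rc_models = [None] * len(models)  # built lazily below

    rows: list[pd.DataFrame] = []
    for mi, model in enumerate(models):
        strand_models = [("+", model)]
        if both_strands:
            rc = rc_models[mi] if rc_models is not None and rc_models[mi] is not None else None
            if rc is None:
                rc = ScoringModel(
                    model.motif_id,
                    model.log_odds[::-1, ::-1].copy(),
                    model.granularity,
                    model.int_scores[::-1, ::-1].copy(),
                    model.min_score,
                    model.tail,
                )
            strand_models.append(("-", rc))
        for strand, sm in strand_models:
            total, valid = _window_scores(cat, sm.int_scores)
            if len(total) == 0:
                continue
            pvals = sm.pvalue(total)
            hit_idx = np.nonzero(valid & (pvals <= p_threshold) & (p_threshold > 0))[0]
            if len(hit_idx) == 0:
                continue
            seq_i = np.searchsorted(starts_arr, hit_idx, side="right") - 1
            offsets = hit_idx - starts_arr[seq_i]
            inside = offsets + sm.width <= lengths[seq_i]
            hit_idx, seq_i, offsets = hit_idx[inside], seq_i[inside], offsets[inside]
            if len(hit_idx) == 0:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "gene": [names[j] for j in seq_i],
                        "motif": model.motif_id,
                        "offset": offsets.astype(int),
                        "strand": strand,
                        "score_bits": total[hit_idx] * sm.granularity,
                        "p_value": pvals[hit_idx],
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=HIT_COLUMNS)
    hits = pd.concat(rows, ignore_index=True)
    return hits.sort_values(["gene", "motif", "offset", "strand"], kind="mergesort").reset_index(
        drop=True
    )


def scan_promoters(
    promoters: Sequence[PromoterSequence],
    models: Sequence[ScoringModel],
    p_threshold: float = 1e-5,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan promoter windows (transcription orientation) with scoring models."""
    seqs = {p.gene_id: p.sequence for p in promoters}
    return scan_sequences(seqs, models, p_threshold=p_threshold, both_strands=both_strands)
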