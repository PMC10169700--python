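"""K-mer survey genome-size estimation.

Every k-length window of the input reads (default k=17) without an ambiguous
base contributes its canonical form — the lexicographic minimum of the k-mer
and its reverse complement, so both sequencing strands count together. The
multiplicity histogram of distinct canonical k-mers then yields

    genome size = total k-mer count / k-mer depth,

where depth is, by default, the histogram peak (the modal multiplicity above
the low-multiplicity error trough), which stands in for sequencing coverage;
a coverage-weighted mean depth matching the literal "average depth" reading
is available via ``depth_mode="mean"``. K-mers below an error cutoff
(default: the first local minimum of the histogram, i.e. the error trough)
are excluded before both the total and the depth are computed.

Counting is fully in-memory and vectorized, adequate for desk-scale surveys;
read pre-filtering (adapter/quality trimming, organelle and contaminant
removal) is an upstream concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .seqcodes import encode

__all__ = ["KmerHistogram", "SurveyEstimate", "build_kmer_histogram", "estimate_genome_size"]


@dataclass
class KmerHistogram:
    """Multiplicity -> number of distinct canonical k-mers."""

    k: int
    counts: dict[int, int]

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.counts.items())

    @property
    def distinct_kmers(self) -> int:
        return sum(self.counts.values())


@dataclass
class SurveyEstimate:
    depth: float
    genome_size_bp: float
    depth_mode_used: str
    error_cutoff: int
    total_kmers_after_cutoff: int


def _canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical integer codes of all valid k-windows of a code array.

    Windows containing any non-ACGT code are dropped. Packing is base-4 into
    int64, so k must be <= 31.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    c64 = codes.astype(np.int64)
    for i in range(k):
        c = c64[i : i + n]
        bad = c >= 4
        invalid |= bad
        cc = np.where(bad, 0, c)
        fwd += cc << (2 * (k - 1 - i))
        rev += (3 - cc) << (2 * i)
    canon = np.minimum(fwd, rev)
    return canon[~invalid]


def build_kmer_histogram(reads: Iterable[str] | str | Path, k: int = 17) -> KmerHistogram:
    """Count canonical k-mers in reads (strings, or a FASTA/FASTQ path)."""
    if not (1 <= k <= 31):
        raise ValueError("k must lie in [1, 31]")
    if isinstance(reads, (str, Path)):
        from .io_formats import read_reads

        reads = read_reads(reads)
    # concatenate with an N separator so windows never span two reads
    joined = "N".join(reads)
    if not joined:
        raise ValueError("no reads supplied")
    cat = encode(joined)
    canon = _canonical_codes(cat, k)
    if len(canon) == 0:
        raise ValueError(f"no valid {k}-mer window in any read (k too large?)")
    _, per_kmer = np.unique(canon, return_counts=True)
    mult, n_distinct = np.unique(per_kmer, return_counts=True)
    return KmerHistogram(k=k, counts={int(m): int(c) for m, c in zip(mult, n_distinct)})


def _error_trough(hist: KmerHistogram) -> int:
    """First local minimum of the histogram, scanning multiplicity upward.

    If the histogram rises immediately (no error shoulder, e.g. error-free
    reads), the cutoff is the smallest multiplicity and nothing is excluded.
    """
    mults = sorted(hist.counts)
    counts = [hist.counts[m] for m in mults]
    i = 0
    while i < len(mults) - 1 and counts[i] > counts[i + 1]:
        i += 1
    return mults[i]


def estimate_genome_size(
    hist: KmerHistogram,
    depth_mode: str = "histogram_peak",
    error_cutoff: int | None = None,
) -> SurveyEstimate:
    """Apply genome size = total k-mers / depth after removing error k-mers."""
    if depth_mode not in ("histogram_peak", "mean"):
        raise ValueError("depth_mode must be 'histogram_peak' or 'mean'")
    if not hist.counts:
        raise ValueError("empty k-mer histogram")
    cutoff = _error_trough(hist) if error_cutoff is None else int(error_cutoff)
    kept = {m: c for m, c in hist.counts.items() if m >= cutoff}
    if not kept:
        raise ValueError(f"error cutoff {cutoff} removed every k-mer")
    total = sum(m * c for m, c in kept.items())
    if depth_mode == "histogram_peak":
        # modal multiplicity; ties broken toward the smaller multiplicity
        depth = float(min(m for m, c in kept.items() if c == max(kept.values())))
    else:
        depth = total / sum(kept.values())
    if depth <= 0:
        raise ValueError("estimated depth is zero")
    return SurveyEstimate(
        depth=depth,
        genome_size_bp=total / depth,
        depth_mode_used=depth_mode,
        error_cutoff=cutoff,
        total_kmers_after_cutoff=total,
    )
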