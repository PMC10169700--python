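"""Count normalization and negative-binomial differential expression.

The DEG definition applied throughout is the one used for the floral
induction comparisons: fold change >= 2 with Benjamini-Hochberg FDR <= 0.05
(a ``raw_p`` criterion is available as the alternate reading).

The test itself is a deliberately minimal, self-contained NB Wald test:
median-of-ratios size factors, a per-gene method-of-moments dispersion pooled
across the two conditions, and a Wald statistic on the log2 ratio of
normalized group means referred to a t distribution with n_a + n_b - 2
degrees of freedom (the t reference tempers the anti-conservativeness of a
plug-in dispersion at small replicate numbers). A precomputed DE table from
any external caller can be substituted via :func:`de_table_from_frame`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix

__all__ = [
    "DEConfig",
    "normalize_counts",
    "test_differential_expression",
    "benjamini_hochberg",
    "deg_set",
    "de_table_from_frame",
]

DE_COLUMNS = ["log2_fold_change", "p_value", "fdr", "is_deg", "tested"]


@dataclass(frozen=True)
class DEConfig:
    fc_threshold: float = 2.0
    alpha: float = 0.05
    criterion: str = "fdr"  # or "raw_p"

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.criterion not in ("fdr", "raw_p"):
            raise ValueError("criterion must be 'fdr' or 'raw_p'")


def normalize_counts(cm: CountMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The reference is the per-gene geometric mean across samples; genes with a
    zero anywhere are excluded from the reference (their log geometric mean is
    -inf) but are still normalized. Each sample's size factor is the median,
    over reference genes, of count / reference.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("normalization needs at least 2 samples")
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    log_geo = logc.mean(axis=1)
    ref = np.isfinite(log_geo)
    if not ref.any():
        raise ValueError("no gene with all-positive counts; cannot normalize")
    log_ratios = logc[ref] - log_geo[ref, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    sf = pd.Series(factors, index=cm.counts.columns, name="size_factor")
    normalized = cm.counts / sf
    return sf, normalized


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (NaNs propagate, excluded from m)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def test_differential_expression(
    cm: CountMatrix,
    condition_a: str,
    condition_b: str,
    config: DEConfig = DEConfig(),
) -> pd.DataFrame:
    """Per-gene NB Wald test of condition_b over condition_a.

    Returns a DataFrame indexed by gene with columns log2_fold_change,
    p_value, fdr, is_deg, tested. Genes with zero counts in every sample of
    both conditions are reported untested (NaN statistics, is_deg False).
    """
    samples_a = cm.samples_of(condition_a)
    samples_b = cm.samples_of(condition_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"conditions {condition_a!r}/{condition_b!r} need >= 2 samples each "
            f"(got {len(samples_a)}, {len(samples_b)})"
        )
    sub = cm.subset_samples(samples_a + samples_b)
    _, norm = normalize_counts(sub)
    a = norm[samples_a].to_numpy(dtype=float)
    b = norm[samples_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]

    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    v_a, v_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    tested = (m_a + m_b) > 0

    # method-of-moments NB dispersion per condition, pooled by df; Poisson
    # fallback (alpha -> 0) when the moment estimate goes negative
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (v_a - m_a) / m_a**2
        alpha_b = (v_b - m_b) / m_b**2
    alpha_a = np.nan_to_num(alpha_a, nan=0.0)
    alpha_b = np.nan_to_num(alpha_b, nan=0.0)
    disp = ((n_a - 1) * alpha_a + (n_b - 1) * alpha_b) / (n_a + n_b - 2)
    disp = np.maximum(disp, 1e-8)

    # moderate means away from zero so the fold change and its variance are finite
    eps = 0.5
    ma, mb = m_a + eps, m_b + eps
    lfc = np.log2(mb / ma)
    ln2sq = np.log(2.0) ** 2
    var_log_a = (ma + disp * ma**2) / (n_a * ma**2 * ln2sq)
    var_log_b = (mb + disp * mb**2) / (n_b * mb**2 * ln2sq)
    se = np.sqrt(var_log_a + var_log_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
    df_t = n_a + n_b - 2
    pvals = 2.0 * stats.t.sf(np.abs(wald), df=df_t)
    pvals = np.where(tested, pvals, np.nan)
    lfc = np.where(tested, lfc, np.nan)

    fdr = benjamini_hochberg(pvals)
    crit = fdr if config.criterion == "fdr" else pvals
    with np.errstate(invalid="ignore"):
        is_deg = tested & (np.abs(lfc) >= np.log2(config.fc_threshold)) & (crit <= config.alpha)

    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": pvals,
            "fdr": fdr,
            "is_deg": is_deg,
            "tested": tested,
        },
        index=cm.counts.index,
    )


# the name starts with "test_" but it is an API function, not a pytest item
test_differential_expression.__test__ = False  # type: ignore[attr-defined]


def de_table_from_frame(df: pd.DataFrame, config: DEConfig = DEConfig()) -> pd.DataFrame:
    """Adapt an external DE table (gene-indexed log2FC/p/fdr) to this module's schema."""
    out = pd.DataFrame(index=df.index)
    out["log2_fold_change"] = df["log2_fold_change"].astype(float)
    out["p_value"] = df["p_value"].astype(float)
    out["fdr"] = df["fdr"] if "fdr" in df else benjamini_hochberg(out["p_value"].to_numpy())
    out["tested"] = ~out["p_value"].isna()
    crit = out["fdr"] if config.criterion == "fdr" else out["p_value"]
    out["is_deg"] = (
        out["tested"]
        & (out["log2_fold_change"].abs() >= np.log2(config.fc_threshold))
        & (crit <= config.alpha)
    )
    return out[DE_COLUMNS]


def deg_set(de_table: pd.DataFrame) -> set[str]:
    return set(de_table.index[de_table["is_deg"]])
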