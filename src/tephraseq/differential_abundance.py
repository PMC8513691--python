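"""Simplified two-group negative-binomial Wald differential-abundance test.

Counts are normalized by median-of-ratios size factors (computed over
positive counts so zero-inflated amplicon tables keep a usable reference),
per-feature dispersion comes from a method-of-moments estimate on the
normalized counts, and the log2 fold change between groups is tested with a
normal Wald statistic; p-values are Benjamini-Hochberg adjusted.

This is a deliberately simplified reimplementation of the shrinkage-based
negative-binomial GLM tools commonly used for this step: there is no
dispersion shrinkage, no iterative GLM fit and no fold-change shrinkage, so
feature lists will not match those tools exactly.  The statistical contract
(size-factor normalization, NB-variance Wald test, BH adjustment,
significance at adjusted p < 0.01) is what is tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import FeatureTable, SampleRecord

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class DifferentialAbundanceResult:
    feature_id: str
    base_mean: float
    lfc: float  # log2 fold change, group B over group A
    se: float
    wald: float
    p: float
    p_adj: float

    def __post_init__(self) -> None:
        if self.p_adj + 1e-12 < self.p:
            raise ValueError("adjusted p below raw p")


def size_factors(table: FeatureTable) -> pd.Series:
    """Median-of-ratios size factors with positive-count geometric means.

    Reference g_i = exp(mean of ln x_ij over samples with x_ij > 0);
    s_j = median over features with x_ij > 0 of x_ij / g_i; the factors are
    rescaled to geometric mean 1.
    """
    x = table.counts.astype(float)
    if (x.sum(axis=0) == 0).any():
        zero = table.sample_ids[int(np.argmax(x.sum(axis=0) == 0))]
        raise ValueError(f"sample {zero!r} has no positive count")
    logx = np.zeros_like(x)
    np.log(x, out=logx, where=x > 0)
    n_pos = (x > 0).sum(axis=1)
    usable = n_pos > 0  # all-zero features contribute no reference
    log_ref = np.divide(logx.sum(axis=1), n_pos,
                        out=np.zeros(x.shape[0]), where=usable)
    factors = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        mask = usable & (x[:, j] > 0)
        if not mask.any():
            raise ValueError(
                f"sample {table.sample_ids[j]!r} shares no positive feature "
                "with the reference"
            )
        factors[j] = np.exp(np.median(np.log(x[mask, j]) - log_ref[mask]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=table.sample_ids, name="size_factor")


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment; monotone in rank, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_two_group(
    table: FeatureTable,
    metadata: Mapping[str, SampleRecord] | Mapping[str, str],
    group_a: str,
    group_b: str,
    group_of=None,
    alpha_min: float = 1e-8,
    pseudo: float = 0.5,
) -> list[DifferentialAbundanceResult]:
    """Two-group negative-binomial Wald test per feature.

    ``group_of`` maps a sample's metadata record to its group label; by
    default the record's ``sample_type`` value is used (plain string maps are
    also accepted).  Features with zero counts across both groups are
    excluded from testing.
    """
    if group_of is None:
        def group_of(rec):
            if isinstance(rec, SampleRecord):
                return rec.sample_type.value
            return str(rec)

    samples_a = [s for s in table.sample_ids
                 if s in metadata and group_of(metadata[s]) == group_a]
    samples_b = [s for s in table.sample_ids
                 if s in metadata and group_of(metadata[s]) == group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need at least 2 samples")

    sub = table.select_samples(samples_a + samples_b)
    s = size_factors(sub)
    y = sub.counts.astype(float) / s.to_numpy()[None, :]
    idx_a = [sub.sample_ids.index(x) for x in samples_a]
    idx_b = [sub.sample_ids.index(x) for x in samples_b]
    ya, yb = y[:, idx_a], y[:, idx_b]
    n_a, n_b = len(idx_a), len(idx_b)

    mu_a = ya.mean(axis=1)
    mu_b = yb.mean(axis=1)
    mu_all = y.mean(axis=1)
    # pooled within-group variance with df N - 2
    ss = ((ya - mu_a[:, None]) ** 2).sum(axis=1) + ((yb - mu_b[:, None]) ** 2).sum(axis=1)
    v = ss / (n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu_all > 0, (v - mu_all) / np.maximum(mu_all, 1e-300) ** 2, 0.0)
    alpha = np.maximum(alpha_min, alpha)

    lfc = np.log2((mu_b + pseudo) / (mu_a + pseudo))
    var_a = (mu_a + alpha * mu_a**2) / (n_a * (mu_a + pseudo) ** 2)
    var_b = (mu_b + alpha * mu_b**2) / (n_b * (mu_b + pseudo) ** 2)
    se = np.sqrt((var_a + var_b)) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc / np.maximum(se, 1e-300), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, 0.0, 1.0)

    tested = (ya.sum(axis=1) + yb.sum(axis=1)) > 0
    p_adj_tested = benjamini_hochberg(p[tested])
    results: list[DifferentialAbundanceResult] = []
    it = iter(p_adj_tested)
    for i, fid in enumerate(sub.feature_ids):
        if not tested[i]:
            continue
        results.append(DifferentialAbundanceResult(
            feature_id=fid,
            base_mean=float(mu_all[i]),
            lfc=float(lfc[i]),
            se=float(se[i]),
            wald=float(wald[i]),
            p=float(p[i]),
            p_adj=float(next(it)),
        ))
    return results


def results_frame(
    results: Sequence[DifferentialAbundanceResult], alpha: float = 0.01
) -> pd.DataFrame:
    """Tabulate results with a significance flag at adjusted p < ``alpha``."""
    df = pd.DataFrame([r.__dict__ for r in results])
    if not df.empty:
        df["significant"] = df["p_adj"] < alpha
    return df
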