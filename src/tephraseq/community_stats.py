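"""Community ecology statistics: α-diversity with ANOVA/Tukey HSD,
rarefaction, Bray-Curtis dissimilarity, non-metric multidimensional scaling
(NMDS), PERMANOVA with pairwise comparisons, and envfit-style environmental
vector fitting.

Conventions: Shannon entropy uses the natural log; rarefaction subsamples
without replacement (multivariate hypergeometric); NMDS minimizes Kruskal
stress-1 with primary (averaging) tie handling in the isotonic regression;
PERMANOVA permutes sample labels freely; all randomized procedures take an
explicit seed and are deterministic under it.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .tables_io import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("matrix shape inconsistent with sample ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero diagonal")
        self.values = v

    def submatrix(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: np.ndarray  # n x k
    stress: float
    n_restarts: int
    converged: bool
    stress_trace: list[float] = field(default_factory=list)


@dataclass
class TestResult:
    name: str
    statistic: float
    df_between: int | None = None
    df_within: int | None = None
    n_permutations: int | None = None
    p: float | None = None
    p_adjusted: float | None = None
    effect_size: float | None = None
    payload: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rarefaction and α diversity
# ---------------------------------------------------------------------------

def rarefy_even_depth(
    table: FeatureTable, depth: int | None = None, seed: int = 0
) -> FeatureTable:
    """Subsample every sample without replacement to the same depth.

    ``depth`` defaults to the minimum column sum (the "even depth"
    convention).  Samples with fewer reads than ``depth`` are dropped with a
    logged warning.  Deterministic under ``seed``.
    """
    sums = table.column_sums()
    if depth is None:
        depth = int(sums.min())
    if depth < 1:
        raise ValueError("depth must be >= 1")
    keep = [s for s in table.sample_ids if sums[s] >= depth]
    dropped = [s for s in table.sample_ids if sums[s] < depth]
    if not keep:
        raise ValueError(f"all samples have fewer than {depth} reads")
    if dropped:
        logger.warning("rarefaction drops %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    df = table.to_dataframe()[keep]
    out = np.empty((df.shape[0], len(keep)), dtype=np.int64)
    for j, s in enumerate(keep):
        col = df[s].to_numpy()
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return FeatureTable(pd.DataFrame(out, index=df.index, columns=keep))


def observed_richness(counts: np.ndarray) -> int:
    """Number of features with a nonzero count."""
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise ValueError("all-zero sample")
    return int(np.count_nonzero(counts))


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy H = -sum p ln p over nonzero relative abundances."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity_frame(table: FeatureTable) -> pd.DataFrame:
    """Per-sample observed richness and Shannon diversity."""
    rows = []
    for s in table.sample_ids:
        col = table.sample(s)
        rows.append({"sample_id": s,
                     "observed_richness": observed_richness(col),
                     "shannon": shannon(col)})
    return pd.DataFrame(rows).set_index("sample_id")


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Closed-form expectation of richness after rarefying one sample:
    sum_i [1 - C(N - n_i, depth) / C(N, depth)] (hypergeometric)."""
    counts = np.asarray(counts, dtype=int)
    n_total = int(counts.sum())
    if depth > n_total:
        raise ValueError("depth exceeds sample total")
    # log-space binomial ratio for numerical safety
    def log_c(a, b):
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)
    total = 0.0
    denom = log_c(n_total, depth)
    for n_i in counts[counts > 0]:
        if n_total - n_i < depth:
            total += 1.0
        else:
            total += 1.0 - math.exp(log_c(n_total - n_i, depth) - denom)
    return total


# ---------------------------------------------------------------------------
# ANOVA and Tukey HSD
# ---------------------------------------------------------------------------

def anova_oneway(values: np.ndarray, groups: np.ndarray) -> TestResult:
    """One-way fixed-effects ANOVA, F = MS_between / MS_within."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("ANOVA requires at least two groups")
    n_total = len(values)
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    means = {}
    for g in labels:
        x = values[groups == g]
        means[g] = float(x.mean())
        ss_between += len(x) * (x.mean() - grand) ** 2
        ss_within += float(((x - x.mean()) ** 2).sum())
    df_b = len(labels) - 1
    df_w = n_total - len(labels)
    if df_w <= 0:
        raise ValueError("not enough observations for within-group df")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = 0.0 if ms_b == 0 else float("inf")
        p = 1.0 if ms_b == 0 else 0.0
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    return TestResult("anova", statistic=float(f), df_between=df_b, df_within=df_w,
                      p=p, payload={"group_means": means})


def tukey_hsd(values: np.ndarray, groups: np.ndarray) -> list[TestResult]:
    """All pairwise Tukey(-Kramer) HSD comparisons after a one-way ANOVA.

    q_ij = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)); p from the
    studentized-range distribution with k groups and N - k df.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("Tukey HSD requires at least two groups")
    data = {g: values[groups == g] for g in labels}
    for g, x in data.items():
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    k = len(labels)
    n_total = len(values)
    df_w = n_total - k
    mse = sum(float(((x - x.mean()) ** 2).sum()) for x in data.values()) / df_w
    results = []
    for g1, g2 in itertools.combinations(labels, 2):
        x1, x2 = data[g1], data[g2]
        diff = abs(float(x1.mean() - x2.mean()))
        se = math.sqrt(mse / 2.0 * (1.0 / len(x1) + 1.0 / len(x2)))
        if se == 0:
            q = 0.0 if diff == 0 else float("inf")
            p = 1.0 if diff == 0 else 0.0
        else:
            q = diff / se
            p = float(stats.studentized_range.sf(q, k, df_w))
        results.append(TestResult(
            f"tukey:{g1}|{g2}", statistic=q, df_between=k, df_within=df_w, p=p,
            payload={"group_means": {str(g1): float(x1.mean()),
                                     str(g2): float(x2.mean())}},
        ))
    return results


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table: FeatureTable) -> DistanceMatrix:
    sums = table.column_sums()
    zero = [s for s in table.sample_ids if sums[s] == 0]
    if zero:
        raise ValueError(f"all-zero sample {zero[0]!r}")
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = squareform(pdist(table.counts.T.astype(float), metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, mat)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _stress1(d_embed: np.ndarray, disparities: np.ndarray) -> float:
    denom = float((d_embed**2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((d_embed - disparities) ** 2).sum()) / denom)


def _classical_mds(dist: np.ndarray, k: int) -> np.ndarray:
    """Torgerson double-centering initialization."""
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> Ordination:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Guttman-transform (SMACOF) updates with disparities from an isotonic
    regression of the embedding distances on the rank order of the input
    dissimilarities.  Restart 1 starts from classical metric scaling; the
    remaining restarts from seeded Gaussian configurations.  The reported
    stress trace of the winning restart is non-increasing.
    """
    delta = np.asarray(dist.condensed(), dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("non-finite distances")
    n = len(dist.sample_ids)
    if n < k + 1:
        raise ValueError("need at least k + 1 samples")
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, list[float], bool] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            x = _classical_mds(dist.values, k)
            if not np.all(np.isfinite(x)):
                x = rng.normal(size=(n, k))
        else:
            x = rng.normal(size=(n, k))
        trace: list[float] = []
        converged = False
        x_final = x
        for _ in range(max_iter):
            d = pdist(x)
            if d.max() == 0:
                x = x + 1e-6 * rng.normal(size=x.shape)
                d = pdist(x)
            # primary (averaging) isotonic fit of d on the rank order of delta
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
            s = _stress1(d, dhat)
            if trace and s > trace[-1]:  # keep the trace monotone; stop on uptick
                break
            x_final = x
            trace.append(s)
            if len(trace) >= 2 and trace[-2] - trace[-1] < tol:
                converged = True
                break
            # Guttman transform toward the disparities
            ratio = np.divide(dhat, d, out=np.zeros_like(d), where=d > 0)
            b = -squareform(ratio)
            np.fill_diagonal(b, -b.sum(axis=1))
            x = (b @ x) / n
        final = trace[-1] if trace else _stress1(pdist(x_final), dhat)
        if best is None or final < best[0]:
            best = (final, x_final.copy(), trace, converged)

    stress, coords, trace, converged = best
    # center, and rescale to unit RMS distance (stress-1 is invariant to
    # translation and uniform scaling; this keeps coordinates readable)
    coords = coords - coords.mean(axis=0)
    rms = math.sqrt(float((pdist(coords) ** 2).mean())) if n > 1 else 0.0
    if rms > 0:
        coords = coords / rms
    return Ordination(list(dist.sample_ids), coords, float(stress),
                      n_restarts=max(1, n_restarts), converged=converged,
                      stress_trace=trace)


def ordination_stress(coordinates: np.ndarray, dist: DistanceMatrix) -> float:
    """Recompute Kruskal stress-1 of a configuration against a dissimilarity
    matrix (isotonic disparities refit)."""
    delta = dist.condensed()
    d = pdist(np.asarray(coordinates, dtype=float))
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
    return _stress1(d, dhat)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    g = len(uniq)
    ss_total, ss_within = _permanova_ss(d2, labels, uniq)
    ss_among = ss_total - ss_within
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    if ss_within <= 0:
        f = 0.0 if ss_among <= 0 else float("inf")
    else:
        f = (ss_among / (g - 1)) / (ss_within / (n - g))
    return f, r2


def permanova(
    dist: DistanceMatrix,
    groups: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> TestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_among/(g-1)) / (SS_within/(N-g)) with SS computed from
    squared dissimilarities; p = (1 + #{F_perm >= F_obs}) / (1 + m) over free
    label permutations.  ``exhaustive=True`` enumerates all distinct
    permutations instead of sampling (the +1 correction is then dropped, as
    the identity permutation is part of the enumeration).
    """
    labels = np.asarray(groups)
    n = len(labels)
    if n != len(dist.sample_ids):
        raise ValueError("group labels inconsistent with distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    d2 = dist.values**2
    f_obs, r2 = _pseudo_f(d2, labels, uniq)
    if not np.isfinite(f_obs) and f_obs > 0:
        # fully separated degenerate case: report as-is with the smallest p
        f_obs = float("inf")
    if np.allclose(dist.values, 0.0):
        return TestResult("permanova", statistic=0.0, df_between=len(uniq) - 1,
                          df_within=n - len(uniq), n_permutations=0, p=1.0,
                          effect_size=0.0)
    if exhaustive:
        seen = set()
        count_ge = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            key = tuple(labels[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            f_perm, _ = _pseudo_f(d2, np.array(key), uniq)
            total += 1
            if f_perm >= f_obs - 1e-12:
                count_ge += 1
        p = count_ge / total
        m = total
    else:
        if n_permutations < 1:
            raise ValueError("need at least one permutation")
        rng = np.random.default_rng(seed)
        count_ge = 0
        for _ in range(n_permutations):
            perm_labels = labels[rng.permutation(n)]
            f_perm, _ = _pseudo_f(d2, perm_labels, uniq)
            if f_perm >= f_obs - 1e-12:
                count_ge += 1
        p = (1 + count_ge) / (1 + n_permutations)
        m = n_permutations
    return TestResult(
        "permanova", statistic=float(f_obs), df_between=len(uniq) - 1,
        df_within=n - len(uniq), n_permutations=m, p=float(p),
        effect_size=float(r2),
    )


def pairwise_permanova(
    dist: DistanceMatrix,
    groups: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    adjust: str = "benjamini_hochberg",
) -> list[TestResult]:
    """PERMANOVA on every group pair with multiplicity adjustment across
    pairs (Benjamini-Hochberg by default)."""
    from .differential_abundance import benjamini_hochberg

    labels = np.asarray(groups)
    uniq = list(dict.fromkeys(labels))
    sample_ids = np.asarray(dist.sample_ids)
    results = []
    rng = np.random.default_rng(seed)
    for g1, g2 in itertools.combinations(uniq, 2):
        mask = np.isin(labels, [g1, g2])
        sub = dist.submatrix(list(sample_ids[mask]))
        res = permanova(sub, labels[mask], n_permutations=n_permutations,
                        seed=int(rng.integers(0, 2**31 - 1)))
        res.name = f"permanova:{g1}|{g2}"
        results.append(res)
    if adjust == "benjamini_hochberg":
        adjusted = benjamini_hochberg(np.array([r.p for r in results]))
        for r, padj in zip(results, adjusted):
            r.p_adjusted = float(padj)
    elif adjust is not None and adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------

def envfit(
    ordination: Ordination,
    variables: pd.DataFrame | dict,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict[str, TestResult]:
    """Fit environmental variables onto ordination axes.

    Per variable: least-squares regression of the centered variable on the
    axis coordinates; r² = 1 - SS_res/SS_tot; the direction is the unit
    coefficient vector; p by permuting the variable's values across samples.
    Samples with missing values are excluded per variable with a warning.
    """
    if not isinstance(variables, pd.DataFrame):
        variables = pd.DataFrame(variables)
    variables = variables.reindex(ordination.sample_ids)
    coords = np.asarray(ordination.coordinates, dtype=float)
    rng = np.random.default_rng(seed)
    out: dict[str, TestResult] = {}
    for name in variables.columns:
        v = variables[name].astype(float).to_numpy()
        keep = np.isfinite(v)
        if keep.sum() < 3:
            raise ValueError(f"variable {name!r}: fewer than 3 finite values")
        if (~keep).any():
            logger.warning("envfit drops %d sample(s) with missing %r",
                           int((~keep).sum()), name)
        y = v[keep] - v[keep].mean()
        if np.allclose(y, 0.0):
            raise ValueError(f"variable {name!r}: zero variance")
        x = coords[keep]
        x = x - x.mean(axis=0)

        def r_squared(yy: np.ndarray) -> tuple[float, np.ndarray]:
            beta, *_ = np.linalg.lstsq(x, yy, rcond=None)
            resid = yy - x @ beta
            ss_tot = float((yy**2).sum())
            return 1.0 - float((resid**2).sum()) / ss_tot, beta

        r2_obs, beta = r_squared(y)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        count_ge = 0
        for _ in range(n_permutations):
            r2_perm, _ = r_squared(rng.permutation(y))
            if r2_perm >= r2_obs - 1e-12:
                count_ge += 1
        p = (1 + count_ge) / (1 + n_permutations)
        out[name] = TestResult(
            f"envfit:{name}", statistic=float(r2_obs),
            n_permutations=n_permutations, p=float(p),
            payload={"direction": direction.tolist()},
        )
    return out
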