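"""Maturation statistics: lateralization, age trends, group contrasts,
effect sizes, and the multivariate Mahalanobis maturation distance.

The maturation index of a neonatal bundle is its Mahalanobis distance

    M^2(x) = (x - mu)^T Sigma^-1 (x - mu) = sum_i ((x - mu) . v_i)^2 / lambda_i

from the adult reference distribution of the same bundle, where x stacks
the six tract-mean metrics (NDI, ODI, FA, MD, AD, RD), mu and Sigma are
the adult mean vector and covariance, and (v_i, lambda_i) are Sigma's
eigenpairs.  Whitening by the eigenvalues makes M invariant to per-metric
rescaling (and to any invertible linear remap of the metric space), so
metrics of wildly different magnitudes — diffusivities in mm^2/s against
dimensionless fractions — can be combined.  Smaller M means the bundle is
closer to its mature adult state.

Multiple-comparison policy: trend and contrast significance flags divide
the alpha threshold by the number of tests (0.05/6 = 0.008 for the six
metrics); reported contrast p-values are additionally Bonferroni-
multiplied (min(1, p * n_tests)).  Branch-wise Wilcoxon comparisons of M
use alpha = 0.05/3 ~ 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

__all__ = [
    "METRICS",
    "BUNDLES",
    "AdultReference",
    "MahalanobisResult",
    "TrendResult",
    "ContrastResult",
    "MaturationReport",
    "lateralization_index",
    "one_sample_t",
    "t_from_r",
    "pearson_trend",
    "cohen_d",
    "group_contrast",
    "wilcoxon_signed_rank",
    "build_adult_reference",
    "mahalanobis_distance",
    "trend_report",
    "contrast_report",
    "lateralization_report",
    "maturation_analysis",
]

METRICS = ("NDI", "ODI", "FA", "MD", "AD", "RD")
BUNDLES = ("SLF_I", "SLF_II", "SLF_III")

MAX_CONDITION_NUMBER = 1e10


# ---------------------------------------------------------------------------
# Elementary statistics


def lateralization_index(left: float, right: float) -> float:
    """(Left - Right) / (Left + Right); positive = left-lateralized."""
    denom = left + right
    if denom == 0:
        raise StatsError("lateralization undefined: left + right = 0")
    return (left - right) / denom


def one_sample_t(values, null: float = 0.0) -> tuple[float, int, float]:
    """One-sample t test against ``null``; returns (t, df, two-sided p)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise StatsError("one-sample t needs n >= 2")
    sd = values.std(ddof=1)
    if sd == 0:
        raise StatsError("one-sample t undefined: zero standard deviation")
    t = (values.mean() - null) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def t_from_r(r: float, n: int) -> float:
    """The r -> t identity for a Pearson correlation on n pairs:
    t = r * sqrt(n - 2) / sqrt(1 - r^2)."""
    if not -1.0 < r < 1.0:
        raise StatsError("|r| must be < 1 for a finite t")
    return float(r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r))


@dataclass
class TrendResult:
    r: float
    t: float
    df: int
    p: float
    significant: bool
    alpha_corrected: float


def pearson_trend(values, ages, n_tests: int = 6) -> TrendResult:
    """Pearson correlation of a metric with age, with the Bonferroni-Dunn
    significance flag at alpha = 0.05 / n_tests."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = len(values)
    if n < 3:
        raise StatsError("Pearson trend needs n >= 3")
    if values.std() == 0 or ages.std() == 0:
        raise StatsError("Pearson correlation undefined for constant input")
    r, p = sps.pearsonr(values, ages)
    t = t_from_r(float(r), n) if abs(r) < 1.0 else np.inf * np.sign(r)
    alpha = 0.05 / n_tests
    return TrendResult(
        r=float(r), t=float(t), df=n - 2, p=float(p),
        significant=bool(p < alpha), alpha_corrected=alpha,
    )


def cohen_d(first, second) -> float:
    """Standardised mean difference (first - second) / pooled SD."""
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    n1, n2 = len(first), len(second)
    if n1 < 2 or n2 < 2:
        raise StatsError("Cohen's d needs n >= 2 per group")
    pooled_var = (
        (n1 - 1) * first.var(ddof=1) + (n2 - 1) * second.var(ddof=1)
    ) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise StatsError("Cohen's d undefined: zero pooled variance")
    return float((first.mean() - second.mean()) / np.sqrt(pooled_var))


@dataclass
class ContrastResult:
    t: float
    df: int
    p: float  # raw two-sided p
    p_adjusted: float  # Bonferroni: min(1, p * n_tests)
    d: float  # Cohen's d, (first - second) / pooled SD


def group_contrast(first, second, n_tests: int = 6) -> ContrastResult:
    """Pooled-variance two-sample Student t plus Cohen's d.

    The sign convention is (first - second); callers comparing adults with
    neonates pass the adult sample first.
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    d = cohen_d(first, second)  # validates sizes and pooled SD
    t, p = sps.ttest_ind(first, second, equal_var=True)
    df = len(first) + len(second) - 2
    return ContrastResult(
        t=float(t), df=df, p=float(p),
        p_adjusted=float(min(1.0, p * n_tests)), d=d,
    )


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Wilcoxon signed-rank test with Pratt zero handling.

    Exact null distribution for n <= 25 when the differences carry no zeros
    or ties; otherwise the normal approximation with tie and continuity
    corrections.  Returns (W, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if len(d) < 6:
        raise StatsError("Wilcoxon signed-rank needs n >= 6")
    if np.all(d == 0):
        raise StatsError("Wilcoxon undefined: all differences are zero")
    has_zeros = bool(np.any(d == 0))
    abs_d = np.abs(d[d != 0])
    has_ties = len(np.unique(abs_d)) < len(abs_d)
    if not has_zeros and not has_ties and len(d) <= 25:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(
        d, zero_method="pratt", correction=(method == "approx"), method=method
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Mahalanobis maturation distance


@dataclass
class AdultReference:
    """Per-bundle adult distribution: mean vector, covariance, eigenpairs."""

    bundle: str
    metrics: tuple
    mean: np.ndarray  # (k,)
    cov: np.ndarray  # (k, k)
    eigenvalues: np.ndarray  # (k,) ascending
    eigenvectors: np.ndarray  # rows are eigenvectors v_i
    n_adults: int
    condition_number: float


def build_adult_reference(
    adult_table: pd.DataFrame,
    bundle: str,
    metrics=METRICS,
    hemisphere: str = "LR",
) -> AdultReference:
    """Sample mean and covariance (n-1 denominator) of the adult metric
    vectors for one bundle, eigen-decomposed.

    Refuses references built from fewer than 8 adults or with a covariance
    condition number above 1e10 (naming the most collinear metric pair).
    """
    cols = [f"{bundle}_{m}_{hemisphere}" for m in metrics]
    missing = [c for c in cols if c not in adult_table.columns]
    if missing:
        raise StatsError(f"adult table lacks columns {missing}")
    X = adult_table[cols].to_numpy(dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n = X.shape[0]
    if n < 8:
        raise StatsError(f"adult reference needs >= 8 complete subjects, got {n}")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        raise StatsError(f"degenerate adult reference for {bundle}: zero covariance")
    # degeneracy is judged on the correlation matrix: the metrics live on
    # wildly different scales (diffusivities in mm^2/s against unit-free
    # fractions), which inflates the covariance condition number without
    # any true collinearity — and M itself is scale invariant
    sd_vec = np.sqrt(np.diag(cov))
    if np.any(sd_vec == 0):
        raise StatsError(
            f"degenerate adult reference for {bundle}: a metric has zero variance"
        )
    corr = cov / np.outer(sd_vec, sd_vec)
    corr_evals = np.linalg.eigvalsh(corr)
    cond = (
        float(corr_evals[-1] / corr_evals[0]) if corr_evals[0] > 0 else np.inf
    )
    if cond > MAX_CONDITION_NUMBER:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise StatsError(
            f"adult covariance for {bundle} is rank-deficient "
            f"(condition number {cond:.3g}); most collinear metrics: "
            f"{metrics[i]} and {metrics[j]} (|r| = {abs(corr[i, j]):.4f})"
        )
    return AdultReference(
        bundle=bundle,
        metrics=tuple(metrics),
        mean=mean,
        cov=cov,
        eigenvalues=evals,
        eigenvectors=evecs.T,
        n_adults=n,
        condition_number=cond,
    )


@dataclass
class MahalanobisResult:
    m: float  # eigen-decomposition form (primary)
    m_direct: float  # direct-inverse form (cross-check)
    x: np.ndarray
    bundle: str


def mahalanobis_distance(x, ref: AdultReference) -> MahalanobisResult:
    """Mahalanobis distance of one metric vector from the adult reference,
    computed in the eigenbasis (primary) and by direct inversion
    (cross-check); both are stored."""
    x = np.asarray(x, dtype=float)
    if x.shape != ref.mean.shape:
        raise StatsError("metric vector does not match the reference dimension")
    if np.any(ref.eigenvalues <= 0):
        raise StatsError("degenerate reference: non-positive eigenvalue")
    delta = x - ref.mean
    proj = ref.eigenvectors @ delta  # components (x - mu) . v_i
    m2_eigen = float(np.sum(proj**2 / ref.eigenvalues))
    m2_direct = float(delta @ np.linalg.solve(ref.cov, delta))
    return MahalanobisResult(
        m=float(np.sqrt(max(m2_eigen, 0.0))),
        m_direct=float(np.sqrt(max(m2_direct, 0.0))),
        x=x,
        bundle=ref.bundle,
    )


# ---------------------------------------------------------------------------
# Report builders


def lateralization_report(
    table: pd.DataFrame, bundles=BUNDLES, metrics=METRICS
) -> pd.DataFrame:
    """Per bundle x metric: mean LI over subjects and the one-sample t test
    of LI against zero."""
    rows = []
    for bundle in bundles:
        for metric in metrics:
            left = table[f"{bundle}_{metric}_L"].to_numpy(dtype=float)
            right = table[f"{bundle}_{metric}_R"].to_numpy(dtype=float)
            li = np.array(
                [lateralization_index(l, r) for l, r in zip(left, right)]
            )
            t, df, p = one_sample_t(li)
            rows.append(
                dict(bundle=bundle, metric=metric, mean_li=float(li.mean()),
                     t=t, df=df, p=p)
            )
    return pd.DataFrame(rows)


def trend_report(
    table: pd.DataFrame,
    bundles=BUNDLES,
    metrics=METRICS,
    hemisphere: str = "LR",
    n_tests: int = 6,
) -> pd.DataFrame:
    """Metric-vs-age Pearson correlations per bundle (Table-3-style layout)."""
    ages = table["age"].to_numpy(dtype=float)
    rows = []
    for metric in metrics:
        for bundle in bundles:
            res = pearson_trend(
                table[f"{bundle}_{metric}_{hemisphere}"].to_numpy(dtype=float),
                ages,
                n_tests=n_tests,
            )
            rows.append(
                dict(metric=metric, bundle=bundle, r=res.r, t=res.t, df=res.df,
                     p=res.p, significant=res.significant)
            )
    return pd.DataFrame(rows)


def contrast_report(
    neonate_table: pd.DataFrame,
    adult_table: pd.DataFrame,
    bundles=BUNDLES,
    metrics=METRICS,
    hemisphere: str = "LR",
    n_tests: int = 6,
) -> pd.DataFrame:
    """Adult-vs-neonate two-sample contrasts per bundle x metric
    (Table-4-style layout); d is (adult - neonate) / pooled SD and its
    absolute value is reported alongside."""
    rows = []
    for metric in metrics:
        for bundle in bundles:
            col = f"{bundle}_{metric}_{hemisphere}"
            res = group_contrast(
                adult_table[col].to_numpy(dtype=float),
                neonate_table[col].to_numpy(dtype=float),
                n_tests=n_tests,
            )
            rows.append(
                dict(metric=metric, bundle=bundle, t=res.t, df=res.df,
                     p_adjusted=res.p_adjusted, d=res.d, abs_d=abs(res.d))
            )
    return pd.DataFrame(rows)


@dataclass
class MaturationReport:
    distances: pd.DataFrame  # per neonate: subject_id, age, M per bundle
    wilcoxon: dict  # (bundle_a, bundle_b) -> {"w", "p", "significant"}
    spearman: dict  # bundle -> {"rho", "p"}
    ranking: list  # bundles by mean M descending (least mature first)
    alpha: float = 0.01
    references: dict = field(default_factory=dict)


def maturation_analysis(
    neonate_table: pd.DataFrame,
    adult_table: pd.DataFrame,
    bundles=BUNDLES,
    metrics=METRICS,
    hemisphere: str = "LR",
    alpha: float = 0.01,
) -> MaturationReport:
    """Full maturation comparison across branches.

    Computes each neonate's Mahalanobis distance to the adult reference of
    every bundle (left/right-averaged metric vectors), compares branches
    pairwise with Wilcoxon signed-rank tests at the Bonferroni-corrected
    alpha (0.05/3), correlates M with age by Spearman rank, and ranks the
    bundles by mean M (largest = least mature).
    """
    if len(neonate_table) < 6:
        raise StatsError("maturation analysis needs >= 6 neonates")
    references = {
        b: build_adult_reference(adult_table, b, metrics, hemisphere)
        for b in bundles
    }
    rows = []
    for _, subject in neonate_table.iterrows():
        row = {"subject_id": subject.get("subject_id"), "age": subject.get("age")}
        for bundle in bundles:
            x = np.array(
                [subject[f"{bundle}_{m}_{hemisphere}"] for m in metrics],
                dtype=float,
            )
            row[bundle] = mahalanobis_distance(x, references[bundle]).m
        rows.append(row)
    distances = pd.DataFrame(rows)

    wilcoxon = {}
    for a, b in combinations(bundles, 2):
        try:
            w, p = wilcoxon_signed_rank(
                distances[a].to_numpy(), distances[b].to_numpy()
            )
            wilcoxon[(a, b)] = {"w": w, "p": p, "significant": bool(p < alpha)}
        except StatsError:
            # identical distances (e.g. every M = 0): no detectable difference
            wilcoxon[(a, b)] = {"w": np.nan, "p": np.nan, "significant": False}

    spearman = {}
    ages = distances["age"].to_numpy(dtype=float)
    for bundle in bundles:
        m_values = distances[bundle].to_numpy()
        if np.ptp(m_values) == 0 or np.ptp(ages) == 0:
            spearman[bundle] = {"rho": np.nan, "p": np.nan}
            continue
        rho, p = sps.spearmanr(m_values, ages)
        spearman[bundle] = {"rho": float(rho), "p": float(p)}

    means = {b: float(distances[b].mean()) for b in bundles}
    ranking = sorted(bundles, key=lambda b: -means[b])
    return MaturationReport(
        distances=distances,
        wilcoxon=wilcoxon,
        spearman=spearman,
        ranking=ranking,
        alpha=alpha,
        references=references,
    )
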