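"""Expression-ratio estimation, two-way ANOVA selection and overlap statistics.

The ratio estimator follows a robust Bayesian contract: condition means are
modelled as Gaussian measurements of positive true intensities (flat prior
truncated at zero) and the reported ratio is the posterior median of B/A,
which shrinks toward 1 as the measurement error grows and recovers the
plain mean ratio in the noiseless limit.  P-values come from the
equal-variance two-sample t-test.  Response sets are selected by two-way
ANOVA (treatment x time, Type II sums of squares) on the treatment-effect
P-value, thresholded either by Benjamini-Hochberg FDR or by raw P, then
mapped to gene symbols.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp, ndtr
from statsmodels.stats.multitest import multipletests

from regks.containers import ExpressionMatrix, OverlapStats

__all__ = [
    "RatioEstimate",
    "AnovaResult",
    "estimate_ratio",
    "ratio_profile",
    "two_way_anova",
    "anova_matrix",
    "bh_fdr",
    "select_response_set",
    "overlap_statistics",
    "set_algebra",
]


@dataclass(frozen=True)
class RatioEstimate:
    """Point estimate of an expression ratio B/A with its test P-value."""

    ratio_estimate: float
    log2_ratio: float
    p_value: float
    gene: Optional[str] = None
    contrast: Optional[str] = None


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA summary for one response vector."""

    f_treatment: float
    p_treatment: float
    f_time: float
    p_time: float
    f_interaction: float
    p_interaction: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# ratio estimation


def _posterior_ratio_cdf(
    r: np.ndarray,
    mean_a: np.ndarray,
    se_a: np.ndarray,
    mean_b: np.ndarray,
    se_b: np.ndarray,
    n_grid: int = 200,
) -> np.ndarray:
    """P(B/A <= r) under independent truncated-Gaussian posteriors.

    A ~ N(mean_a, se_a^2) and B ~ N(mean_b, se_b^2), both truncated to
    (0, inf); the expectation over A is taken by trapezoidal quadrature.
    All arguments broadcast; returns an array shaped like ``r``.
    """
    r, mean_a, se_a, mean_b, se_b = np.broadcast_arrays(r, mean_a, se_a, mean_b, se_b)
    out = np.empty(r.shape)
    # quadrature grid over the truncated support of A (per element)
    lo = np.maximum(mean_a - 8.0 * se_a, 0.0)
    hi = mean_a + 8.0 * se_a
    t = np.linspace(0.0, 1.0, n_grid)
    a = lo[..., None] + (hi - lo)[..., None] * t  # (..., n_grid)
    pdf_a = np.exp(-0.5 * ((a - mean_a[..., None]) / se_a[..., None]) ** 2)
    norm_a = np.trapezoid(pdf_a, a, axis=-1)
    # P(B <= r*a | a) for truncated B
    z0 = ndtr(-mean_b / se_b)  # mass of untruncated B below 0
    cdf_b = (ndtr((r[..., None] * a - mean_b[..., None]) / se_b[..., None]) - z0[..., None])
    cdf_b = np.clip(cdf_b, 0.0, None) / (1.0 - z0[..., None])
    out = np.trapezoid(pdf_a * cdf_b, a, axis=-1) / norm_a
    return out


def _posterior_ratio_median_oneway(
    mean_a: np.ndarray, se_a: np.ndarray, mean_b: np.ndarray, se_b: np.ndarray
) -> np.ndarray:
    """Vectorized posterior median of B/A by bisection on log2 r."""
    naive = np.log2(mean_b / mean_a)
    lo = np.minimum(naive, 0.0) - 1.0
    hi = np.maximum(naive, 0.0) + 1.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        below = _posterior_ratio_cdf(np.exp2(mid), mean_a, se_a, mean_b, se_b) < 0.5
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def _posterior_ratio_median(
    mean_a: np.ndarray, se_a: np.ndarray, mean_b: np.ndarray, se_b: np.ndarray
) -> np.ndarray:
    """Antisymmetrized posterior median: log2 r(A,B) = -log2 r(B,A) exactly.

    Averaging the forward and reversed log-medians cancels the leading
    quadrature asymmetry, so equal conditions give a ratio of exactly 1.
    """
    mean_a, se_a, mean_b, se_b = np.broadcast_arrays(
        np.asarray(mean_a, float), se_a, mean_b, se_b
    )
    fwd = _posterior_ratio_median_oneway(mean_a, se_a, mean_b, se_b)
    rev = _posterior_ratio_median_oneway(mean_b, se_b, mean_a, se_a)
    return 0.5 * (fwd - rev)


def _t_test_p(
    mean_a: float,
    se_a: float,
    mean_b: float,
    se_b: float,
    n_a: Optional[int],
    n_b: Optional[int],
) -> float:
    denom = np.hypot(se_a, se_b)
    if denom == 0.0:
        return 1.0 if mean_a == mean_b else 0.0
    tstat = (mean_b - mean_a) / denom
    if n_a is None or n_b is None:
        return float(2.0 * stats.norm.sf(abs(tstat)))
    df = n_a + n_b - 2
    return float(2.0 * stats.t.sf(abs(tstat), df))


def estimate_ratio(
    mean_a: float,
    se_a: float,
    mean_b: float,
    se_b: float,
    n_a: Optional[int] = None,
    n_b: Optional[int] = None,
    gene: Optional[str] = None,
    contrast: Optional[str] = None,
) -> RatioEstimate:
    """Robust Bayesian estimate of the expression ratio B/A.

    The point estimate is the posterior median of B/A under Gaussian
    measurement of the two positive condition means (flat prior truncated
    at zero); it equals ``mean_b / mean_a`` when both standard errors
    vanish and shrinks monotonically toward 1 as they grow.  The P-value is
    the equal-variance t-test on the difference of means (degrees of
    freedom from ``n_a``/``n_b`` when given, normal approximation
    otherwise).
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("condition means must be positive")
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be nonnegative")
    p = _t_test_p(mean_a, se_a, mean_b, se_b, n_a, n_b)
    if se_a == 0.0 and se_b == 0.0:
        log2_ratio = float(np.log2(mean_b / mean_a))
    else:
        # degenerate one-sided se: treat as a tiny but positive error
        eps_a = se_a if se_a > 0 else 1e-9 * mean_a
        eps_b = se_b if se_b > 0 else 1e-9 * mean_b
        log2_ratio = float(_posterior_ratio_median(mean_a, eps_a, mean_b, eps_b))
    return RatioEstimate(
        ratio_estimate=float(np.exp2(log2_ratio)),
        log2_ratio=log2_ratio,
        p_value=p,
        gene=gene,
        contrast=contrast,
    )


def ratio_profile(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    treatment_a: str,
    treatment_b: str,
    tissue: str,
    probe_map: Optional[pd.DataFrame] = None,
    times: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per-gene, per-time ratio estimates of ``treatment_b`` over ``treatment_a``.

    ``matrix`` is a (probeset or gene) x sample intensity frame.  Replicate
    means and standard errors of the mean feed :func:`estimate_ratio`
    (vectorized); P-values come from the equal-variance t-test on log2
    intensities.  With a ``probe_map``, rows are collapsed to genes by the
    minimum-P rule: the probeset with the smallest P-value contributes that
    gene's reported (ratio, P).  Cells with fewer than two replicates are
    flagged missing (NaN).
    """
    sub = design[design["tissue"] == tissue]
    if times is None:
        times = sorted(sub["time_h"].unique())
    rows = []
    for time_h in times:
        cols_a = sub.loc[
            (sub["treatment"] == treatment_a) & (sub["time_h"] == time_h), "sample_id"
        ]
        cols_b = sub.loc[
            (sub["treatment"] == treatment_b) & (sub["time_h"] == time_h), "sample_id"
        ]
        va = matrix.loc[:, list(cols_a)].to_numpy()
        vb = matrix.loc[:, list(cols_b)].to_numpy()
        if va.shape[1] < 2 or vb.shape[1] < 2:
            rows.append(
                pd.DataFrame(
                    {
                        "id": matrix.index,
                        "time_h": time_h,
                        "log2_ratio": np.nan,
                        "ratio": np.nan,
                        "p_value": np.nan,
                    }
                )
            )
            continue
        mean_a, mean_b = va.mean(axis=1), vb.mean(axis=1)
        se_a = va.std(axis=1, ddof=1) / np.sqrt(va.shape[1])
        se_b = vb.std(axis=1, ddof=1) / np.sqrt(vb.shape[1])
        se_a = np.maximum(se_a, 1e-9 * mean_a)
        se_b = np.maximum(se_b, 1e-9 * mean_b)
        log2_ratio = _posterior_ratio_median(mean_a, se_a, mean_b, se_b)
        with np.errstate(invalid="ignore"):
            t_res = stats.ttest_ind(np.log2(vb), np.log2(va), axis=1, equal_var=True)
        p = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)
        rows.append(
            pd.DataFrame(
                {
                    "id": matrix.index,
                    "time_h": time_h,
                    "log2_ratio": log2_ratio,
                    "ratio": np.exp2(log2_ratio),
                    "p_value": p,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    if probe_map is not None:
        table = table.merge(
            probe_map.rename(columns={"probeset_id": "id"}), on="id", how="inner"
        )
        idx = table.groupby(["gene_symbol", "time_h"])["p_value"].idxmin()
        table = (
            table.loc[idx]
            .rename(columns={"id": "probeset_id", "gene_symbol": "gene"})
            .sort_values(["time_h", "gene"])
            .reset_index(drop=True)
        )
        table = table[["gene", "probeset_id", "time_h", "log2_ratio", "ratio", "p_value"]]
    else:
        table = table.rename(columns={"id": "gene"})
    return table


# ---------------------------------------------------------------------------
# two-way ANOVA (Type II sums of squares), vectorized across genes


def _dummy(levels: pd.Series) -> np.ndarray:
    cats = pd.Categorical(levels)
    return pd.get_dummies(cats, drop_first=True).to_numpy(float)


def _residual_projector(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    Q, _ = np.linalg.qr(X)
    return np.eye(n) - Q @ Q.T


def anova_matrix(
    values: np.ndarray,
    treatment: Sequence,
    time: Sequence,
) -> pd.DataFrame:
    """Two-way ANOVA over a genes x samples matrix with a shared design.

    Type II sums of squares: each main effect is tested against the
    additive model, the interaction against the full model, with the full
    cell-means model providing the error term.  Rows whose response is
    constant (or that leave no residual error) are flagged degenerate with
    all P-values set to 1.
    """
    values = np.atleast_2d(np.asarray(values, float))
    n = values.shape[1]
    treatment = pd.Series(list(treatment))
    time = pd.Series(list(time))
    if treatment.nunique() < 2 or time.nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    cell = treatment.astype(str) + "|" + time.astype(str)
    if not (cell.value_counts() >= 2).any():
        raise ValueError("at least one design cell needs >= 2 replicates")

    A = _dummy(treatment)
    B = _dummy(time)
    AB = np.einsum("ij,ik->ijk", A, B).reshape(n, -1)
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept, A, B, AB])
    X_add = np.hstack([intercept, A, B])
    X_a = np.hstack([intercept, A])
    X_b = np.hstack([intercept, B])

    def rss(X: np.ndarray) -> np.ndarray:
        R = _residual_projector(X)
        resid = values @ R
        return np.einsum("ij,ij->i", resid, resid)

    rss_full, rss_add, rss_a, rss_b = rss(X_full), rss(X_add), rss(X_a), rss(X_b)
    df_a = A.shape[1]
    df_b = B.shape[1]
    df_ab = df_a * df_b
    df_err = n - (1 + df_a + df_b + df_ab)
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom in the full model")

    ss_a = np.maximum(rss_b - rss_add, 0.0)
    ss_b = np.maximum(rss_a - rss_add, 0.0)
    ss_ab = np.maximum(rss_add - rss_full, 0.0)
    mse = rss_full / df_err

    degenerate = mse <= 1e-12 * np.maximum(values.var(axis=1), 1e-300)
    safe_mse = np.where(degenerate, 1.0, mse)
    f_a = (ss_a / df_a) / safe_mse
    f_b = (ss_b / df_b) / safe_mse
    f_ab = (ss_ab / df_ab) / safe_mse
    p_a = stats.f.sf(f_a, df_a, df_err)
    p_b = stats.f.sf(f_b, df_b, df_err)
    p_ab = stats.f.sf(f_ab, df_ab, df_err)
    for p in (p_a, p_b, p_ab):
        p[degenerate] = 1.0

    return pd.DataFrame(
        {
            "f_treatment": f_a,
            "p_treatment": p_a,
            "f_time": f_b,
            "p_time": p_b,
            "f_interaction": f_ab,
            "p_interaction": p_ab,
            "degenerate": degenerate,
        }
    )


def two_way_anova(
    values: Sequence[float], treatment: Sequence, time: Sequence
) -> AnovaResult:
    """Two-way ANOVA (treatment, time, interaction) for a single response."""
    values = np.asarray(values, float)
    if np.allclose(values, values[0]):
        return AnovaResult(0.0, 1.0, 0.0, 1.0, 0.0, 1.0, degenerate=True)
    row = anova_matrix(values[None, :], treatment, time).iloc[0]
    return AnovaResult(
        f_treatment=float(row["f_treatment"]),
        p_treatment=float(row["p_treatment"]),
        f_time=float(row["f_time"]),
        p_time=float(row["p_time"]),
        f_interaction=float(row["f_interaction"]),
        p_interaction=float(row["p_interaction"]),
        degenerate=bool(row["degenerate"]),
    )


# ---------------------------------------------------------------------------
# FDR and selection


def bh_fdr(p_values: Sequence[float], q: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted P-values and selected indices."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    selected = np.flatnonzero(adjusted <= q)
    return adjusted, selected


def _parse_threshold_spec(threshold_spec: dict) -> tuple[str, float]:
    spec = dict(threshold_spec)
    if "fdr" in spec and "raw_p" in spec:
        raise ValueError("threshold_spec must name either an FDR or a raw-P cutoff, not both")
    if "mode" in spec:
        mode, value = spec["mode"], float(spec["value"])
    elif "fdr" in spec:
        mode, value = "fdr", float(spec["fdr"])
    elif "raw_p" in spec:
        mode, value = "raw_p", float(spec["raw_p"])
    else:
        raise ValueError("threshold_spec needs a mode ('fdr' or 'raw_p') and value")
    if mode not in ("fdr", "raw_p"):
        raise ValueError(f"unknown threshold mode {mode!r}")
    return mode, value


def select_response_set(
    matrix: ExpressionMatrix | pd.DataFrame,
    design: pd.DataFrame,
    tissue: str,
    contrast: tuple[str, str],
    threshold_spec: dict,
    probe_map: Optional[pd.DataFrame] = None,
) -> tuple[list[str], pd.DataFrame]:
    """Select the treatment-response gene set in one tissue.

    Runs the two-way ANOVA (treatment restricted to the two ``contrast``
    levels, crossed with time) on log2 intensities at the probeset level,
    thresholds the treatment-effect P-values per ``threshold_spec``
    ({'mode': 'fdr'|'raw_p', 'value': q}), then maps selected rows to gene
    symbols and deduplicates.  Returns the sorted gene list and the full
    per-row ANOVA table.
    """
    mode, value = _parse_threshold_spec(threshold_spec)
    intensity = matrix.intensity if isinstance(matrix, ExpressionMatrix) else matrix
    sub = design[(design["tissue"] == tissue) & (design["treatment"].isin(contrast))]
    if sub.empty:
        raise ValueError(f"tissue {tissue!r} with treatments {contrast} not in design")
    cols = list(sub["sample_id"])
    values = np.log2(intensity.loc[:, cols].to_numpy())
    table = anova_matrix(values, sub["treatment"], sub["time_h"])
    table.insert(0, "id", intensity.index.to_numpy())

    if mode == "fdr":
        adjusted, sel_idx = bh_fdr(table["p_treatment"].to_numpy(), value)
        table["fdr_treatment"] = adjusted
        selected_ids = table["id"].iloc[sel_idx]
    else:
        table["fdr_treatment"] = bh_fdr(table["p_treatment"].to_numpy(), value)[0]
        selected_ids = table.loc[table["p_treatment"] < value, "id"]

    if probe_map is not None:
        genes = probe_map.loc[
            probe_map["probeset_id"].isin(selected_ids), "gene_symbol"
        ].unique()
    else:
        genes = selected_ids.unique()
    return sorted(genes), table


# ---------------------------------------------------------------------------
# overlap statistics and set algebra


def overlap_statistics(n1: int, n2: int, universe: int, observed: int) -> OverlapStats:
    """Hypergeometric null for the overlap of two gene lists.

    Expected overlap n1*n2/N with its standard error, and the upper-tail
    probability P(X >= observed) computed by summing hypergeometric log
    probabilities (stable far into the tail).
    """
    if universe <= 0:
        raise ValueError("universe size must be positive")
    if not (0 <= n1 <= universe and 0 <= n2 <= universe):
        raise ValueError("set sizes must lie within the universe")
    if not (0 <= observed <= min(n1, n2)):
        raise ValueError("observed overlap must lie in [0, min(n1, n2)]")
    N = universe
    mean = n1 * n2 / N
    var = n1 * n2 * (N - n1) * (N - n2) / (N**2 * (N - 1)) if N > 1 else 0.0
    se = float(np.sqrt(var))
    support = np.arange(observed, min(n1, n2) + 1)
    if len(support) == 0:
        log_p = 0.0
    else:
        log_p = float(logsumexp(stats.hypergeom.logpmf(support, N, n1, n2)))
        log_p = min(log_p, 0.0)
    return OverlapStats(
        n1=n1,
        n2=n2,
        universe=N,
        observed=observed,
        expected_mean=mean,
        expected_se=se,
        tail_p=float(np.exp(log_p)),
        log10_tail_p=log_p / np.log(10.0),
    )


def set_algebra(
    list_a: Sequence[str], list_b: Sequence[str]
) -> tuple[list[str], list[str], dict[str, int]]:
    """Exact-symbol intersection and union of two gene lists, with sizes."""
    a, b = set(list_a), set(list_b)
    inter = sorted(a & b)
    union = sorted(a | b)
    sizes = {"A": len(a), "B": len(b), "intersection": len(inter), "union": len(union)}
    return inter, union, sizes
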