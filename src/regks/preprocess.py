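"""QC, percentile normalization, gene collapse, standardization, filtering.

The normalization contract mirrors MAS5-era practice: each chip is linearly
rescaled so that the 75th percentile of its present-call intensities hits a
common target (here the median of the per-chip percentiles).  Percentiles
use linear interpolation between order statistics.  Probesets collapse to
genes by maximum intensity; standardization is a per-gene z-score of log2
intensities; the unsupervised filter ranks genes by the total sum of
squared deviations of their log2 profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

from regks.containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ChipQCSummary",
    "chip_qc_summary",
    "flag_outliers",
    "normalize_to_common_percentile",
    "collapse_to_genes",
    "standardize_genes",
    "variation_statistic",
    "top_k",
    "cluster_gene_profiles",
]


@dataclass(frozen=True)
class ChipQCSummary:
    """Per-chip QC statistics over present-call intensities."""

    sample_id: str
    n_present_calls: int
    p75_present: float  # NaN when no present calls
    flagged: bool = False


def _p75(values: np.ndarray) -> float:
    # linear interpolation between order statistics (numpy default)
    return float(np.percentile(values, 75.0, method="linear"))


def chip_qc_summary(matrix: ExpressionMatrix) -> list[ChipQCSummary]:
    """Number of present calls and 75th percentile of present intensities per chip.

    Chips with zero present calls get an undefined (NaN) percentile and are
    flagged.
    """
    present = matrix.present_mask().to_numpy()
    intensity = matrix.intensity.to_numpy()
    out = []
    for j, sample_id in enumerate(matrix.sample_ids):
        mask = present[:, j]
        n = int(mask.sum())
        if n == 0:
            out.append(ChipQCSummary(str(sample_id), 0, float("nan"), flagged=True))
        else:
            out.append(ChipQCSummary(str(sample_id), n, _p75(intensity[mask, j])))
    return out


def qc_summary_frame(summaries: Sequence[ChipQCSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "n_present_calls": [s.n_present_calls for s in summaries],
            "p75_present": [s.p75_present for s in summaries],
            "flagged": [s.flagged for s in summaries],
        }
    )


def flag_outliers(
    summaries: Sequence[ChipQCSummary],
    matrix: ExpressionMatrix,
    design: pd.DataFrame,
    z_threshold: float = 5.0,
) -> pd.DataFrame:
    """Flag summary-space outlier chips and potential tissue-assignment swaps.

    Outliers are chips whose (n_present_calls, log p75) depart from the
    cohort by more than ``z_threshold`` robust z-units (median/MAD).  The
    swap check correlates each chip's log2 profile against the mean profile
    (centroid) of each tissue computed with that chip held out; a chip more
    correlated with the other tissue than its own is flagged.
    """
    frame = qc_summary_frame(summaries).set_index("sample_id")
    stats = np.column_stack(
        [frame["n_present_calls"].to_numpy(float), np.log(frame["p75_present"].to_numpy())]
    )

    def robust_z(col: np.ndarray) -> np.ndarray:
        med = np.nanmedian(col)
        mad = np.nanmedian(np.abs(col - med))
        scale = 1.4826 * mad if mad > 0 else (np.nanstd(col) or 1.0)
        return (col - med) / scale

    z = np.column_stack([robust_z(stats[:, 0]), robust_z(stats[:, 1])])
    summary_outlier = (np.abs(z) > z_threshold).any(axis=1) | frame["flagged"].to_numpy()

    tissue_of = design.set_index("sample_id")["tissue"]
    log2x = np.log2(matrix.intensity.to_numpy())
    sample_ids = [str(s) for s in matrix.sample_ids]
    tissues_present = sorted(set(tissue_of.loc[sample_ids]))
    swap = np.zeros(len(sample_ids), dtype=bool)
    if len(tissues_present) < 2:
        warnings.warn("single tissue present: tissue-swap check skipped", stacklevel=2)
    else:
        cols_by_tissue = {
            t: [j for j, s in enumerate(sample_ids) if tissue_of.loc[s] == t]
            for t in tissues_present
        }
        if min(len(c) for c in cols_by_tissue.values()) < 4:
            warnings.warn(
                "fewer than 4 samples in a tissue: swap flags may be unstable",
                stacklevel=2,
            )
        sums = {t: log2x[:, cols].sum(axis=1) for t, cols in cols_by_tissue.items()}
        for j, s in enumerate(sample_ids):
            own = tissue_of.loc[s]
            own_cols = cols_by_tissue[own]
            if len(own_cols) < 2:
                continue
            own_centroid = (sums[own] - log2x[:, j]) / (len(own_cols) - 1)
            corrs = {}
            for t in tissues_present:
                if t == own:
                    centroid = own_centroid
                else:
                    centroid = sums[t] / len(cols_by_tissue[t])
                corrs[t] = np.corrcoef(log2x[:, j], centroid)[0, 1]
            if max(corrs, key=corrs.get) != own:
                swap[j] = True

    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "summary_outlier": summary_outlier,
            "tissue_swap": swap,
            "flagged": summary_outlier | swap,
        }
    )


def normalize_to_common_percentile(
    matrix: ExpressionMatrix, target: Optional[float] = None
) -> tuple[ExpressionMatrix, pd.Series]:
    """Linearly rescale each chip so its present-call p75 hits a common value.

    The default target is the median of the per-chip 75th percentiles (the
    contract only requires "a single common value"; the median is stable
    under rescaling of subsets of chips).  Returns the rescaled matrix and
    the per-chip scale factors.
    """
    summaries = chip_qc_summary(matrix)
    p75 = np.array([s.p75_present for s in summaries])
    if np.isnan(p75).any():
        bad = [s.sample_id for s in summaries if np.isnan(s.p75_present)]
        raise ValueError(f"samples with zero present calls cannot be normalized: {bad}")
    if target is None:
        target = float(np.median(p75))
    factors = target / p75
    scaled = matrix.intensity * factors[None, :]
    result = ExpressionMatrix(scaled, matrix.calls.copy())
    return result, pd.Series(factors, index=matrix.sample_ids, name="scale_factor")


def collapse_to_genes(matrix: ExpressionMatrix, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse probesets to genes by taking the maximum intensity per cell.

    When a gene maps to several probesets, the largest intensity observed
    among them is assigned as that gene's measured intensity in each sample.
    Probesets absent from the annotation are dropped (count logged).
    """
    if probe_map.empty:
        raise ValueError("empty probeset-to-gene annotation")
    mapped = probe_map[probe_map["probeset_id"].isin(matrix.probeset_ids)]
    if mapped.empty:
        raise ValueError("annotation and matrix share no probesets")
    n_dropped = matrix.n_probesets - mapped["probeset_id"].nunique()
    if n_dropped:
        logger.info("collapse: dropped %d unmapped probesets", n_dropped)
    values = matrix.intensity.loc[mapped["probeset_id"].to_numpy()]
    values.index = mapped["gene_symbol"].to_numpy()
    gene_matrix = values.groupby(level=0).max()
    gene_matrix.index.name = "gene"
    return gene_matrix


def standardize_genes(
    gene_matrix: pd.DataFrame, sample_subset: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-gene z-score of log2 intensities over the chosen samples.

    Uses the sample (n-1) standard deviation.  Genes with zero variance are
    set to all-zero z-scores with a warning rather than rejected.
    """
    sub = gene_matrix if sample_subset is None else gene_matrix.loc[:, list(sample_subset)]
    if sub.shape[1] < 2:
        raise ValueError("standardization needs at least 2 samples")
    log2x = np.log2(sub.to_numpy())
    mean = log2x.mean(axis=1, keepdims=True)
    sd = log2x.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s) standardized to 0", stacklevel=2
        )
    sd[sd == 0] = 1.0
    z = (log2x - mean) / sd
    return pd.DataFrame(z, index=sub.index, columns=sub.columns)


def variation_statistic(gene_matrix: pd.DataFrame) -> pd.Series:
    """Total sum of squared deviations of each gene's log2 profile.

    S^2 = sum_j (y_gj - mean_g)^2 with y = log2 intensity, taken over all
    samples; large for genes with many moderate or a few large deviations.
    """
    if gene_matrix.shape[1] < 2:
        raise ValueError("variation statistic needs at least 2 samples")
    log2x = np.log2(gene_matrix.to_numpy())
    s2 = ((log2x - log2x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return pd.Series(s2, index=gene_matrix.index, name="S2")


def top_k(s2: pd.Series, k: int = 1000) -> list[str]:
    """The k genes with largest variation statistic (ties broken by name)."""
    if k > len(s2):
        warnings.warn(f"k={k} exceeds {len(s2)} genes; clamping", stacklevel=2)
        k = len(s2)
    order = s2.sort_index().sort_values(ascending=False, kind="stable")
    return list(order.index[:k])


def cluster_gene_profiles(
    z_matrix: pd.DataFrame, n_clusters: int, seed: int = 0
) -> tuple[pd.Series, list[str]]:
    """Seeded partition of standardized gene profiles plus a display order.

    A deterministic KMeans partition stands in for the original
    self-organized map: only cluster memberships and a similarity-based
    display ordering (clusters ordered by centroid, genes within a cluster
    by correlation to their centroid) are part of the contract.
    """
    if n_clusters > len(z_matrix):
        raise ValueError("more clusters than genes")
    X = z_matrix.to_numpy()
    if n_clusters == 1:
        labels = np.zeros(len(z_matrix), dtype=int)
    else:
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
    # stable relabeling: clusters numbered by their first gene in input order
    first_seen: dict[int, int] = {}
    for lab in labels:
        first_seen.setdefault(int(lab), len(first_seen))
    labels = np.array([first_seen[int(lab)] for lab in labels])

    order: list[str] = []
    for c in range(labels.max() + 1):
        members = np.flatnonzero(labels == c)
        centroid = X[members].mean(axis=0)
        sim = _similarity_order(X[members], centroid)
        order.extend(z_matrix.index[members[sim]])
    return pd.Series(labels, index=z_matrix.index, name="cluster"), order


def _similarity_order(X: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    if len(X) <= 2:
        return np.arange(len(X))
    if len(X) > 3 and np.isfinite(X).all():
        try:
            link = linkage(X, method="average", metric="euclidean")
            return np.asarray(leaves_list(link))
        except ValueError:  # pragma: no cover - degenerate input
            pass
    dev = X - centroid
    return np.argsort((dev**2).sum(axis=1), kind="stable")
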