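"""Regulated (sign-aware) Kolmogorov-Smirnov gene-set enrichment.

A target profile of n expression values (typically log2 ratios) is turned
into ranks, rank 1 for the largest value.  For a signed gene set with k_u
positive and k_d negative regulatees, the empirical CDFs of the two
regulatee groups' ranks are compared with the uniform CDF and the maximum
signed deviations d_u and d_d extracted (signed versions of the classical
KS statistic, evaluated on the discrete rank grid at both sides of each
step).  The combined statistic

    d_UpDown = (k_u * d_u - k_d * d_d) / (k_u + k_d)

is bounded in [-1, 1], behaves continuously as either k goes to 0, weighs
each group by its membership, and is positive for coherent regulation
(up-regulatees ranked high, down-regulatees low).  Significance comes from
Monte-Carlo permutation of set membership; the left/right enrichment
scores C_L and C_R are chord slopes of the regulatee CDFs at the
maximum-deviation points (1 = neutral); leading-edge genes are the
regulatees ranked before (up) or after (down) those points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kstwo

from regks.containers import (
    EnrichmentResult,
    GeneSet,
    GeneSetCollection,
    KsDeviations,
)
from regks.diffexpr import bh_fdr

__all__ = [
    "RankedProfile",
    "rank_transform",
    "signed_deviations",
    "combined_statistic",
    "permutation_pvalue",
    "enrichment_scores",
    "leading_edge",
    "screen_collection",
    "ks_plot_data",
]


@dataclass(frozen=True)
class RankedProfile:
    """Descending ranks of a gene expression profile.

    ``ranks`` maps each gene of the universe to an integer rank in 1..n,
    rank 1 for the largest profile value.  Ties are resolved
    deterministically by (value descending, gene symbol ascending).
    """

    ranks: pd.Series

    def __post_init__(self) -> None:
        r = self.ranks.to_numpy()
        if sorted(r) != list(range(1, len(r) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")

    @property
    def n(self) -> int:
        return len(self.ranks)

    def rank_of(self, genes: Sequence[str]) -> np.ndarray:
        return self.ranks.loc[list(genes)].to_numpy()


def rank_transform(profile: pd.Series) -> RankedProfile:
    """Transform profile values into descending ranks (1 = largest).

    Raises if any value is missing; ties are broken by gene symbol so the
    rank vector is always a permutation of 1..n and reproducible.
    """
    if profile.isna().any():
        missing = list(profile.index[profile.isna()][:5])
        raise ValueError(f"profile has missing values, e.g. {missing}")
    if profile.index.has_duplicates:
        raise ValueError("profile index has duplicate genes")
    order = profile.sort_index().sort_values(ascending=False, kind="stable")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index, name="rank")
    return RankedProfile(ranks.loc[profile.index])


# ---------------------------------------------------------------------------
# signed deviations


def _group_deviation(
    member_ranks: np.ndarray, n: int, prefer_sign: int = 1
) -> tuple[float, Optional[int]]:
    """Maximum signed deviation of a group's rank CDF from uniform.

    Evaluates F_sample(r) - r/n over the discrete rank grid at both sides
    of every member step (r = r_i and r = r_i - 1); returns the signed
    value at the point of maximum absolute deviation and that grid point
    r*.  Exact |dev| ties are broken toward ``prefer_sign`` (the group's
    coherent direction: +1 for up-, -1 for down-regulatees, which keeps
    the statistic invariant under profile negation with group swap), then
    toward the smallest r.  An empty group has deviation 0 and no argmax.
    """
    k = len(member_ranks)
    if k == 0:
        return 0.0, None
    r = np.sort(np.asarray(member_ranks, dtype=np.int64))
    i = np.arange(1, k + 1, dtype=np.int64)
    # exact integer arithmetic: dev * (k*n) at each candidate grid point
    after = i * n - r * k  # F at r_i
    before = (i - 1) * n - (r - 1) * k  # F just below the step
    cand_dev = np.concatenate([after, before])
    cand_r = np.concatenate([r, r - 1])
    order = np.lexsort(
        (cand_r, -prefer_sign * np.sign(cand_dev), -np.abs(cand_dev))
    )
    best = order[0]
    return float(cand_dev[best]) / (k * n), int(cand_r[best])


def signed_deviations(
    ranked: RankedProfile, up_set: Sequence[str], down_set: Sequence[str]
) -> KsDeviations:
    """Signed KS deviations d_u and d_d of the two regulatee groups.

    Both groups must be subsets of the ranked universe and disjoint; at
    least one must be nonempty.  The fractional population ranks of the
    maximum-deviation points are reported alongside.
    """
    up, down = list(up_set), list(down_set)
    if not up and not down:
        raise ValueError("both regulatee groups are empty")
    if set(up) & set(down):
        raise ValueError("up and down regulatee groups must be disjoint")
    missing = (set(up) | set(down)) - set(ranked.ranks.index)
    if missing:
        raise ValueError(f"regulatees outside the ranked universe: {sorted(missing)[:5]}")
    n = ranked.n
    d_u, r_u = _group_deviation(ranked.rank_of(up), n, 1) if up else (0.0, None)
    d_d, r_d = _group_deviation(ranked.rank_of(down), n, -1) if down else (0.0, None)
    return KsDeviations(
        d_u=d_u,
        d_d=d_d,
        x_u=None if r_u is None else r_u / n,
        x_d=None if r_d is None else r_d / n,
    )


def combined_statistic(d_u: float, k_u: int, d_d: float, k_d: int) -> float:
    """Membership-weighted signed combination of the two KS deviations.

    d_UpDown = (k_u*d_u - k_d*d_d)/(k_u + k_d): positive for coherent
    regulation, reduces to d_u when k_d = 0 and to -d_d when k_u = 0,
    bounded in [-1, 1].
    """
    if k_u + k_d < 1:
        raise ValueError("gene set has no regulatees")
    return (k_u * d_u - k_d * d_d) / (k_u + k_d)


def _statistic_for_set(
    ranked: RankedProfile, up_set: Sequence[str], down_set: Sequence[str]
) -> float:
    dev = signed_deviations(ranked, up_set, down_set)
    return combined_statistic(dev.d_u, len(up_set), dev.d_d, len(down_set))


# ---------------------------------------------------------------------------
# permutation null


def _batch_group_deviation(R: np.ndarray, n: int, prefer_sign: int = 1) -> np.ndarray:
    """Signed max-abs deviation per row of a (m, k) rank matrix."""
    m, k = R.shape
    if k == 0:
        return np.zeros(m)
    R = np.sort(np.asarray(R, dtype=np.int64), axis=1)
    i = np.arange(1, k + 1, dtype=np.int64)[None, :]
    # integer-scaled deviations (dev * k * n): exact tie handling
    after = i * n - R * k
    before = (i - 1) * n - (R - 1) * k
    cand = np.concatenate([after, before], axis=1)
    cand_r = np.concatenate([R, R - 1], axis=1)
    # max |dev|; ties toward the preferred sign, then the smallest r
    key = (
        np.abs(cand) * np.int64(4 * n + 8)
        + prefer_sign * np.sign(cand) * np.int64(2 * n + 4)
        - cand_r
    )
    idx = np.argmax(key, axis=1)
    return cand[np.arange(m), idx] / (k * n)


def _sample_rank_rows(
    rng: np.random.Generator, m: int, k: int, n: int
) -> np.ndarray:
    """m rows of k distinct ranks drawn uniformly from 1..n."""
    if k > n:
        raise ValueError("cannot draw more distinct ranks than the universe size")
    if k * (k - 1) < n:  # sparse: rejection sampling of duplicate rows
        R = rng.integers(1, n + 1, size=(m, k))
        while True:
            S = np.sort(R, axis=1)
            bad = np.flatnonzero((np.diff(S, axis=1) == 0).any(axis=1))
            if len(bad) == 0:
                return R
            R[bad] = rng.integers(1, n + 1, size=(len(bad), k))
    # dense: per-row partial permutation via random keys, chunked
    out = np.empty((m, k), dtype=np.int64)
    chunk = max(1, int(2e7) // n)
    for start in range(0, m, chunk):
        stop = min(m, start + chunk)
        keys = rng.random((stop - start, n))
        out[start:stop] = np.argpartition(keys, k - 1, axis=1)[:, :k] + 1
    return out


def null_statistics(
    n: int, k_u: int, k_d: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo null distribution of d_UpDown for random memberships.

    Draws ``n_perm`` sign-preserving random memberships (k_u + k_d distinct
    ranks, the first k_u treated as up-regulatees) and returns the
    resulting statistics.
    """
    k = k_u + k_d
    if k > n:
        raise ValueError("k_u + k_d exceeds the universe size")
    R = _sample_rank_rows(rng, n_perm, k, n)
    d_u = _batch_group_deviation(R[:, :k_u], n, 1)
    d_d = _batch_group_deviation(R[:, k_u:], n, -1)
    return (k_u * d_u - k_d * d_d) / k


def permutation_pvalue(
    ranked: RankedProfile,
    gene_set: GeneSet,
    n_perm: int = 100_000,
    seed: int = 0,
    null: Optional[np.ndarray] = None,
) -> float:
    """One-sided Monte-Carlo P-value for a gene set's d_UpDown.

    The null holds membership sizes fixed and redraws the member ranks
    uniformly without replacement from the universe; P is the fraction of
    permuted statistics at least as large as the observed one.  The
    resolution floor is 1/n_perm, so a P of 0 means P < 1/n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = _statistic_for_set(ranked, gene_set.up_genes, gene_set.down_genes)
    if null is None:
        rng = np.random.default_rng(seed)
        null = null_statistics(ranked.n, gene_set.k_u, gene_set.k_d, n_perm, rng)
    return float(np.mean(null >= obs - 1e-12))


# ---------------------------------------------------------------------------
# enrichment scores and leading edges


def enrichment_scores(
    ranked: RankedProfile, up_set: Sequence[str], down_set: Sequence[str]
) -> tuple[float, float]:
    """Chord-slope enrichment scores (C_L, C_R) of the two regulatee CDFs.

    C_L is the slope of the chord from the origin of the KS plot to the
    up-regulatee CDF at its maximum-deviation point; C_R the mirrored
    chord slope from the down-regulatee CDF's maximum-deviation point to
    the plot's upper-right corner.  An empty group scores the neutral
    value 1; a degenerate argmax at a plot corner is moved to the adjacent
    step with a warning.
    """
    n = ranked.n
    c_left = 1.0
    c_right = 1.0
    if up_set:
        d, r = _group_deviation(ranked.rank_of(up_set), n, 1)
        if r == 0:
            warnings.warn("up argmax at plot origin; using first member step", stacklevel=2)
            ranks = np.sort(ranked.rank_of(up_set))
            r = int(ranks[0])
            d = 1 / len(up_set) - r / n
        x = r / n
        f_at = d + x
        c_left = f_at / x
    if down_set:
        d, r = _group_deviation(ranked.rank_of(down_set), n, -1)
        if r == n:
            warnings.warn("down argmax at plot corner; using previous step", stacklevel=2)
            r = n - 1
            ranks = np.asarray(ranked.rank_of(down_set))
            d = float(np.mean(ranks <= r) - r / n)
        x = r / n
        f_at = d + x
        c_right = (1.0 - f_at) / (1.0 - x)
    return float(c_left), float(c_right)


def leading_edge(
    ranked: RankedProfile, up_set: Sequence[str], down_set: Sequence[str]
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Regulatees driving the enrichment signal.

    Up-regulatees ranked at or above the up group's maximum-deviation
    point, and down-regulatees ranked below the down group's
    maximum-deviation point, each ordered by rank.
    """
    n = ranked.n

    def sorted_by_rank(members: Sequence[str]) -> tuple[list[str], np.ndarray]:
        ranks = ranked.rank_of(members)
        order = np.argsort(ranks)
        genes = [str(g) for g in np.asarray(list(members), dtype=object)[order]]
        return genes, ranks[order]

    edge_up: tuple[str, ...] = ()
    edge_down: tuple[str, ...] = ()
    if up_set:
        _, r_star = _group_deviation(ranked.rank_of(up_set), n, 1)
        genes, ranks = sorted_by_rank(up_set)
        edge_up = tuple(g for g, r in zip(genes, ranks) if r <= r_star)
    if down_set:
        _, r_star = _group_deviation(ranked.rank_of(down_set), n, -1)
        genes, ranks = sorted_by_rank(down_set)
        edge_down = tuple(g for g, r in zip(genes, ranks) if r > r_star)
    return edge_up, edge_down


# ---------------------------------------------------------------------------
# collection screening


def score_gene_set(
    ranked: RankedProfile,
    gene_set: GeneSet,
    n_perm: int = 10_000,
    seed: int = 0,
    null: Optional[np.ndarray] = None,
) -> EnrichmentResult:
    """Full regulated-KS scoring of one gene set against a ranked profile."""
    dev = signed_deviations(ranked, gene_set.up_genes, gene_set.down_genes)
    d = combined_statistic(dev.d_u, gene_set.k_u, dev.d_d, gene_set.k_d)
    p = permutation_pvalue(ranked, gene_set, n_perm=n_perm, seed=seed, null=null)
    c_left, c_right = enrichment_scores(ranked, gene_set.up_genes, gene_set.down_genes)
    edge_up, edge_down = leading_edge(ranked, gene_set.up_genes, gene_set.down_genes)
    return EnrichmentResult(
        name=gene_set.name,
        source=gene_set.source,
        k_u=gene_set.k_u,
        k_d=gene_set.k_d,
        d_updown=d,
        p_value=p,
        c_left=c_left,
        c_right=c_right,
        leading_edge_up=edge_up,
        leading_edge_down=edge_down,
    )


def screen_collection(
    profile: pd.Series | RankedProfile,
    collection: GeneSetCollection,
    fdr_max: float = 0.25,
    c_min: float = 2.0,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Score every gene set of a collection and flag the significant ones.

    Sets are restricted to the profile universe (skipped with a warning if
    nothing remains).  FDR is Benjamini-Hochberg computed within each
    source collection separately; a set is selected when fdr < fdr_max and
    max(C_L, C_R) >= c_min.  Null distributions are shared between sets of
    equal (k_u, k_d), which keeps the permutation cost modest.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    ranked = profile if isinstance(profile, RankedProfile) else rank_transform(profile)
    universe = frozenset(str(g) for g in ranked.ranks.index)
    rng = np.random.default_rng(seed)
    null_cache: dict[tuple[int, int], np.ndarray] = {}
    results: list[EnrichmentResult] = []
    for gs in collection:
        restricted = gs.restricted_to(universe)
        if restricted is None:
            warnings.warn(
                f"gene set {gs.name!r} has no members in the universe; skipped",
                stacklevel=2,
            )
            continue
        key = (restricted.k_u, restricted.k_d)
        if key not in null_cache:
            null_cache[key] = null_statistics(ranked.n, key[0], key[1], n_perm, rng)
        results.append(
            score_gene_set(ranked, restricted, n_perm=n_perm, null=null_cache[key])
        )

    by_source: dict[str, list[int]] = {}
    for i, r in enumerate(results):
        by_source.setdefault(r.source, []).append(i)
    for idxs in by_source.values():
        adjusted, _ = bh_fdr([results[i].p_value for i in idxs], fdr_max)
        for i, fdr in zip(idxs, adjusted):
            selected = fdr < fdr_max and max(results[i].c_left, results[i].c_right) >= c_min
            results[i] = replace(results[i], fdr=float(fdr), selected=bool(selected))
    return results


# ---------------------------------------------------------------------------
# KS plot data


def ks_plot_data(
    ranked: RankedProfile,
    up_set: Sequence[str],
    down_set: Sequence[str],
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Step coordinates of the regulatee CDFs plus a null confidence band.

    Returns a tidy frame with columns (curve, x, y): 'up' and 'down' step
    functions of sample fractional rank against population fractional
    rank, and 'band_lower'/'band_upper' at +-D where D is the two-sided KS
    critical value at the requested confidence for k = k_u + k_d members.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    n = ranked.n
    frames = []
    for curve, members in (("up", list(up_set)), ("down", list(down_set))):
        if not members:
            continue
        r = np.sort(ranked.rank_of(members))
        k = len(r)
        x = np.concatenate([[0.0], np.repeat(r / n, 2), [1.0]])
        y = np.concatenate([[0.0], np.repeat(np.arange(k + 1) / k, 2)[1:-1], [1.0]])
        frames.append(pd.DataFrame({"curve": curve, "x": x, "y": y}))
    k_total = len(list(up_set)) + len(list(down_set))
    d_crit = float(kstwo.ppf(confidence, k_total))
    grid = np.linspace(0.0, 1.0, 101)
    frames.append(pd.DataFrame({"curve": "band_lower", "x": grid, "y": grid - d_crit}))
    frames.append(pd.DataFrame({"curve": "band_upper", "x": grid, "y": grid + d_crit}))
    return pd.concat(frames, ignore_index=True)
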