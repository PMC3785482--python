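"""Membership matrices, nested set derivations and Fisher-exact enrichment.

Post-processing of the enrichment screen: build the {gene set x gene}
leading-edge membership matrix (keeping genes backed by at least two
selected sets), intersect pathway-relevant genes with ANOVA response sets,
derive the NBQX-responsive "epileptogenic" set as the union over tissues of
per-tissue (HS response AND NBQX response) intersections, and test discrete
set overlaps with the one-sided Fisher/hypergeometric exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from regks.containers import EnrichmentResult
from regks.preprocess import cluster_gene_profiles

__all__ = [
    "MembershipMatrix",
    "EpileptogenicSet",
    "build_membership_matrix",
    "pathway_relevant_intersection",
    "derive_epileptogenic_set",
    "fisher_enrichment",
]


@dataclass
class MembershipMatrix:
    """Boolean {selected gene set x gene} matrix with clustered display orders."""

    matrix: pd.DataFrame  # bool, rows = set names, columns = genes
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def set_names(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class EpileptogenicSet:
    """Genes passing both an HS and an NBQX selection in at least one tissue."""

    genes: list[str]
    provenance: pd.DataFrame  # columns: gene, tissue


def build_membership_matrix(
    enrichment_results: Sequence[EnrichmentResult],
    min_sets: int = 2,
    n_clusters: int = 4,
    seed: int = 0,
) -> MembershipMatrix:
    """Leading-edge membership matrix of the selected gene sets.

    Rows are the selected sets; columns the union of their leading-edge
    genes restricted to genes occurring in at least ``min_sets`` of them.
    Row and column display orders come from the seeded clustering used for
    expression heat maps.
    """
    selected = [r for r in enrichment_results if r.selected]
    counts: dict[str, int] = {}
    for r in selected:
        for g in set(r.leading_edge):
            counts[g] = counts.get(g, 0) + 1
    genes = sorted(g for g, c in counts.items() if c >= min_sets)
    if not genes:
        warnings.warn("no leading-edge gene occurs in enough selected sets", stacklevel=2)
        return MembershipMatrix(pd.DataFrame(index=[r.name for r in selected]))
    rows = {
        r.name: [g in set(r.leading_edge) for g in genes] for r in selected
    }
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=genes).astype(bool)

    def display_order(frame: pd.DataFrame) -> list[str]:
        if len(frame) < 2:
            return list(frame.index)
        k = min(n_clusters, len(frame))
        _, order = cluster_gene_profiles(frame.astype(float), n_clusters=k, seed=seed)
        return order

    return MembershipMatrix(
        matrix=matrix,
        row_order=display_order(matrix),
        col_order=display_order(matrix.T),
    )


def pathway_relevant_intersection(
    membership_genes: Sequence[str], anova_set: Sequence[str]
) -> list[str]:
    """Pathway-relevant genes that also pass the ANOVA response selection."""
    return sorted(set(membership_genes) & set(anova_set))


def derive_epileptogenic_set(
    hs_sets_by_tissue: Mapping[str, Sequence[str]],
    nbqx_sets_by_tissue: Mapping[str, Sequence[str]],
) -> EpileptogenicSet:
    """Union over tissues of per-tissue HS/NBQX response intersections.

    A gene enters the set when, in at least one tissue, it was selected
    both as hypoxic-seizure responsive and as NBQX responsive (both
    NBQX-induced and NBQX-repressed genes qualify; the selection itself is
    sign-blind).  Tissues present in only one input are skipped with a
    warning.
    """
    tissues = set(hs_sets_by_tissue) | set(nbqx_sets_by_tissue)
    rows = []
    for tissue in sorted(tissues):
        if tissue not in hs_sets_by_tissue or tissue not in nbqx_sets_by_tissue:
            warnings.warn(
                f"tissue {tissue!r} present in only one selection; skipped", stacklevel=2
            )
            continue
        both = set(hs_sets_by_tissue[tissue]) & set(nbqx_sets_by_tissue[tissue])
        rows.extend({"gene": g, "tissue": tissue} for g in sorted(both))
    provenance = pd.DataFrame(rows, columns=["gene", "tissue"])
    genes = sorted(provenance["gene"].unique()) if len(provenance) else []
    return EpileptogenicSet(genes=genes, provenance=provenance)


def fisher_enrichment(
    query_set: Sequence[str],
    target_set: Sequence[str],
    universe_n: int,
    p_max: float = 0.01,
) -> tuple[int, float, bool]:
    """One-sided over-representation test of a query against a target set.

    Returns the observed overlap, the hypergeometric upper-tail P
    (P(X >= overlap) with the stated background size) and whether it
    clears ``p_max``.
    """
    query, target = set(query_set), set(target_set)
    if universe_n < len(query) or universe_n < len(target):
        raise ValueError("universe smaller than one of the gene sets")
    overlap = len(query & target)
    p = float(stats.hypergeom.sf(overlap - 1, universe_n, len(target), len(query)))
    p = min(p, 1.0)
    return overlap, p, bool(p < p_max)
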