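"""Core in-memory containers shared across the pipeline.

Expression data and sample metadata are held in pandas objects; gene sets
and per-set enrichment results are lightweight frozen dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

#: Valid per-cell detection calls (MAS5 convention): present / absent / marginal.
CALL_SYMBOLS = frozenset({"P", "A", "M"})

#: Factor levels of the study design.
TISSUES = ("hippocampus", "cortex")
TREATMENTS = ("noHS", "HS", "HS_NBQX")
TIMES_H = (1, 6, 12, 48, 168)

#: Required columns of a sample design table.
DESIGN_COLUMNS = ("sample_id", "tissue", "treatment", "time_h", "replicate")


@dataclass
class ExpressionMatrix:
    """Probeset x sample intensity matrix with per-cell detection calls.

    Parameters
    ----------
    intensity
        Positive linear-scale intensities, index = probeset ids,
        columns = sample ids.
    calls
        Detection calls ('P', 'A' or 'M'), same index/columns as
        ``intensity``.
    """

    intensity: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensity.index.has_duplicates:
            dupes = self.intensity.index[self.intensity.index.duplicated()]
            raise ValueError(f"duplicate probeset ids: {list(dupes[:5])}")
        if self.intensity.columns.has_duplicates:
            dupes = self.intensity.columns[self.intensity.columns.duplicated()]
            raise ValueError(f"duplicate sample ids: {list(dupes[:5])}")
        if self.intensity.shape != self.calls.shape:
            raise ValueError(
                f"intensity {self.intensity.shape} and call {self.calls.shape} "
                "grids differ in shape"
            )
        if not self.intensity.index.equals(self.calls.index) or not (
            self.intensity.columns.equals(self.calls.columns)
        ):
            raise ValueError("intensity and call grids must share index/columns")
        vals = self.intensity.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            bad = np.argwhere(~(np.isfinite(vals) & (vals > 0)))[0]
            raise ValueError(
                "nonpositive or non-finite intensity at probeset "
                f"{self.intensity.index[bad[0]]!r}, sample "
                f"{self.intensity.columns[bad[1]]!r}"
            )
        call_vals = self.calls.to_numpy()
        bad_calls = ~np.isin(call_vals, list(CALL_SYMBOLS))
        if bad_calls.any():
            bad = np.argwhere(bad_calls)[0]
            raise ValueError(
                f"invalid call symbol {call_vals[bad[0], bad[1]]!r} at probeset "
                f"{self.calls.index[bad[0]]!r}, sample {self.calls.columns[bad[1]]!r}"
            )

    @property
    def probeset_ids(self) -> pd.Index:
        return self.intensity.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensity.columns

    @property
    def n_probesets(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[1]

    def present_mask(self) -> pd.DataFrame:
        """Boolean mask of present calls ('M' counts as absent)."""
        return self.calls == "P"

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.intensity.loc[:, list(sample_ids)], self.calls.loc[:, list(sample_ids)]
        )


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample design table against the factorial study layout.

    Checks required columns, factor levels, uniqueness of sample ids and of
    (tissue, treatment, time_h, replicate) combinations.  Returns the table
    unchanged on success.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing required columns: {missing}")
    if design["sample_id"].duplicated().any():
        dupes = design.loc[design["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample_id values: {list(dupes[:5])}")
    bad_tissue = set(design["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValueError(f"unknown tissue level(s): {sorted(bad_tissue)}")
    bad_treat = set(design["treatment"]) - set(TREATMENTS)
    if bad_treat:
        raise ValueError(f"unknown treatment level(s): {sorted(bad_treat)}")
    bad_time = set(design["time_h"]) - set(TIMES_H)
    if bad_time:
        raise ValueError(f"unknown time_h level(s): {sorted(bad_time)}")
    combo = design[["tissue", "treatment", "time_h", "replicate"]]
    if combo.duplicated().any():
        raise ValueError("duplicate (tissue, treatment, time_h, replicate) combinations")
    if (design["replicate"] < 1).any():
        raise ValueError("replicate numbers must be positive integers")
    return design


@dataclass(frozen=True)
class GeneSet:
    """Named signed gene set: positive (up) and negative (down) regulatees.

    ``up_genes`` are the k_u genes expected to rise when the pathway is
    active, ``down_genes`` the k_d genes expected to fall.
    """

    name: str
    source: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(
                f"gene set {self.name!r}: members with both signs: {sorted(overlap)[:5]}"
            )
        if len(self.up_genes) + len(self.down_genes) < 1:
            raise ValueError(f"gene set {self.name!r} is empty")

    @property
    def k_u(self) -> int:
        return len(self.up_genes)

    @property
    def k_d(self) -> int:
        return len(self.down_genes)

    @property
    def k(self) -> int:
        return self.k_u + self.k_d

    def restricted_to(self, universe: frozenset[str]) -> Optional["GeneSet"]:
        """Return the set restricted to ``universe``, or None if empty."""
        up = tuple(g for g in self.up_genes if g in universe)
        down = tuple(g for g in self.down_genes if g in universe)
        if not up and not down:
            return None
        return GeneSet(self.name, self.source, up, down)


@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets, each tagged with a source label."""

    sets: list[GeneSet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def sources(self) -> list[str]:
        seen: dict[str, None] = {}
        for gs in self.sets:
            seen.setdefault(gs.source, None)
        return list(seen)

    def by_source(self, source: str) -> list[GeneSet]:
        return [gs for gs in self.sets if gs.source == source]


@dataclass(frozen=True)
class KsDeviations:
    """Maximum signed CDF deviations of a regulatee group pair.

    ``d_u``/``d_d`` are the signed Kolmogorov-Smirnov deviations of the up-
    and down-regulatee rank CDFs from uniform; ``x_u``/``x_d`` the fractional
    population ranks at which each maximum is attained (None for an empty
    group, whose deviation is 0).
    """

    d_u: float
    d_d: float
    x_u: Optional[float]
    x_d: Optional[float]


@dataclass
class EnrichmentResult:
    """Per-gene-set output of the regulated KS analysis."""

    name: str
    source: str
    k_u: int
    k_d: int
    d_updown: float
    p_value: float
    fdr: float = float("nan")
    c_left: float = float("nan")
    c_right: float = float("nan")
    leading_edge_up: tuple[str, ...] = ()
    leading_edge_down: tuple[str, ...] = ()
    selected: bool = False

    @property
    def leading_edge(self) -> tuple[str, ...]:
        return self.leading_edge_up + self.leading_edge_down


@dataclass(frozen=True)
class OverlapStats:
    """Hypergeometric null statistics for the overlap of two gene lists."""

    n1: int
    n2: int
    universe: int
    observed: int
    expected_mean: float
    expected_se: float
    tail_p: float
    log10_tail_p: float


@dataclass
class SyntheticTruth:
    """Planted ground-truth labels of a simulated study.

    ``genes`` has one row per gene with columns ``gene``, ``developmental``
    (up/down/flat), ``hs`` (up/down/null), ``hs_peak_h``, ``nbqx``
    (responsive/null) and ``nbqx_direction``; ``gene_sets`` has one row per
    simulated set with columns ``name`` and ``enriched``.
    """

    genes: pd.DataFrame
    gene_sets: pd.DataFrame = field(default_factory=pd.DataFrame)

    def hs_genes(self, direction: Optional[str] = None) -> list[str]:
        mask = self.genes["hs"] != "null"
        if direction is not None:
            mask = self.genes["hs"] == direction
        return list(self.genes.loc[mask, "gene"])

    def nbqx_genes(self) -> list[str]:
        return list(self.genes.loc[self.genes["nbqx"] == "responsive", "gene"])

    def enriched_set_names(self) -> list[str]:
        if self.gene_sets.empty:
            return []
        return list(self.gene_sets.loc[self.gene_sets["enriched"], "name"])
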