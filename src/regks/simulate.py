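"""Synthetic factorial microarray studies with planted ground truth.

Emulates the structure of a neonatal hypoxic-seizure profiling experiment:
two tissues (hippocampus, cortex) x three treatments (noHS, HS, HS+NBQX) x
five sampling times (1, 6, 12, 48, 168 h) with 4-6 replicate animals per
cell.  Gene-level log2 signal is additive:

    log2 intensity = baseline + developmental trend(time)
                     + HS effect(treatment, time) + NBQX effect + noise

with the HS temporal profile maximal at 12 h.  Probesets replicate the gene
signal plus independent probe noise (many-to-many collapse is exercised
downstream), detection calls are thinned with an absent rate that decreases
with intensity, and signed gene sets are drawn with configurable enrichment
purity against the planted HS labels.  Everything is reproducible from a
single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from regks.containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SyntheticTruth,
    TIMES_H,
    TISSUES,
    TREATMENTS,
    validate_design,
)

__all__ = [
    "SimulationConfig",
    "null_config",
    "generate_study",
    "generate_phenotypes",
    "generate_signed_gene_sets",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated study.

    Defaults are the documented strong-signal study conditions: 2,000 genes,
    HS effects of 1.5 log2 units peaking at 12 h with a roughly 2:1 up:down
    direction mix, 100 gene sets of which 20% are truly enriched at purity
    0.9, and seizure phenotypes with exponential latency (mean 114 s) and
    near-normal seizure counts (mean 10.6, sd 2.9).
    """

    n_genes: int = 2000
    probesets_per_gene_max: int = 3
    replicates_min: int = 4
    replicates_max: int = 6
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    # developmental (maturation) trends in the noHS baseline
    dev_up_fraction: float = 0.15
    dev_down_fraction: float = 0.15
    dev_effect_log2: float = 2.0
    # tissue-specific expression (drives tissue centroids / swap detection)
    tissue_specific_fraction: float = 0.2
    tissue_effect_sd_log2: float = 1.0
    # hypoxic-seizure response
    hs_fraction: float = 0.10
    hs_up_share: float = 2.0 / 3.0  # ~2:1 up:down direction mix
    hs_effect_log2: float = 1.5
    hs_time_weights: tuple[float, ...] = (0.6, 0.8, 1.0, 0.5, 0.3)  # peak at 12 h
    # NBQX response (subset of HS genes, further shift under HS+NBQX)
    nbqx_fraction_of_hs: float = 0.5
    nbqx_effect_log2: float = 1.0
    nbqx_up_share: float = 0.7
    # noise model
    noise_sd_log2: float = 0.35
    probe_noise_sd_log2: float = 0.15
    chip_effect_sd_log2: float = 0.15
    # absent-call thinning: P(absent) decreasing in log2 intensity
    call_midpoint_log2: float = 5.5
    call_scale_log2: float = 1.0
    # signed gene sets
    n_gene_sets: int = 100
    set_size_min: int = 10
    set_size_max: int = 30
    fraction_enriched: float = 0.2
    set_down_share: float = 1.0 / 3.0
    purity: float = 0.9
    # seizure phenotypes
    latency_mean_s: float = 114.0
    seizure_count_mean: float = 10.6
    seizure_count_sd: float = 2.9
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "dev_up_fraction": self.dev_up_fraction,
            "dev_down_fraction": self.dev_down_fraction,
            "tissue_specific_fraction": self.tissue_specific_fraction,
            "hs_fraction": self.hs_fraction,
            "hs_up_share": self.hs_up_share,
            "nbqx_fraction_of_hs": self.nbqx_fraction_of_hs,
            "nbqx_up_share": self.nbqx_up_share,
            "fraction_enriched": self.fraction_enriched,
            "set_down_share": self.set_down_share,
            "purity": self.purity,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.dev_up_fraction + self.dev_down_fraction > 1.0:
            raise ValueError("developmental fractions sum above 1")
        for name in ("dev_effect_log2", "hs_effect_log2", "nbqx_effect_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates_min < 1:
            raise ValueError("at least one replicate per cell is required")
        if self.replicates_max < self.replicates_min:
            raise ValueError("replicates_max < replicates_min")
        if len(self.hs_time_weights) != len(TIMES_H):
            raise ValueError("hs_time_weights must give one weight per sampling time")
        if self.latency_mean_s <= 0 or self.seizure_count_mean <= 0:
            raise ValueError("phenotype means must be positive")


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study with no planted effects: pure baseline + noise (calibration runs)."""
    cfg = SimulationConfig(
        dev_up_fraction=0.0,
        dev_down_fraction=0.0,
        tissue_specific_fraction=0.0,
        hs_fraction=0.0,
        nbqx_fraction_of_hs=0.0,
        fraction_enriched=0.0,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------


def _gene_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    width = len(str(n))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, n + 1)])

    dev = np.full(n, "flat", dtype=object)
    n_up = int(round(config.dev_up_fraction * n))
    n_down = int(round(config.dev_down_fraction * n))
    dev_idx = rng.choice(n, size=n_up + n_down, replace=False)
    dev[dev_idx[:n_up]] = "up"
    dev[dev_idx[n_up:]] = "down"

    hs = np.full(n, "null", dtype=object)
    n_hs = int(round(config.hs_fraction * n))
    hs_idx = rng.choice(n, size=n_hs, replace=False)
    n_hs_up = int(round(config.hs_up_share * n_hs))
    hs[hs_idx[:n_hs_up]] = "up"
    hs[hs_idx[n_hs_up:]] = "down"

    nbqx = np.full(n, "null", dtype=object)
    nbqx_dir = np.full(n, "none", dtype=object)
    n_nbqx = int(round(config.nbqx_fraction_of_hs * n_hs))
    if n_nbqx:
        nbqx_idx = rng.choice(hs_idx, size=n_nbqx, replace=False)
        nbqx[nbqx_idx] = "responsive"
        up_mask = rng.random(n_nbqx) < config.nbqx_up_share
        nbqx_dir[nbqx_idx[up_mask]] = "up"
        nbqx_dir[nbqx_idx[~up_mask]] = "down"

    tissue_pref = np.full(n, "none", dtype=object)
    n_ts = int(round(config.tissue_specific_fraction * n))
    if n_ts:
        ts_idx = rng.choice(n, size=n_ts, replace=False)
        half = n_ts // 2
        tissue_pref[ts_idx[:half]] = "hippocampus"
        tissue_pref[ts_idx[half:]] = "cortex"

    peak_h = TIMES_H[int(np.argmax(config.hs_time_weights))]
    return pd.DataFrame(
        {
            "gene": genes,
            "developmental": dev,
            "hs": hs,
            "hs_peak_h": np.where(hs != "null", peak_h, 0),
            "nbqx": nbqx,
            "nbqx_direction": nbqx_dir,
            "tissue_preference": tissue_pref,
        }
    )


def _build_design(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Full factorial sample table with jittered replicate counts.

    Replicate counts are drawn per (treatment, time) cohort and shared by
    the two tissues: each simulated animal contributes one sample of each
    tissue, as in the profiling design being emulated.
    """
    rows = []
    for treatment in TREATMENTS:
        for time_h in TIMES_H:
            n_rep = int(rng.integers(config.replicates_min, config.replicates_max + 1))
            for rep in range(1, n_rep + 1):
                for tissue in TISSUES:
                    short = "hip" if tissue == "hippocampus" else "cx"
                    rows.append(
                        {
                            "sample_id": f"{short}_{treatment}_{time_h}h_r{rep}",
                            "tissue": tissue,
                            "treatment": treatment,
                            "time_h": time_h,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


def generate_phenotypes(
    config: SimulationConfig, n_animals: int, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Seizure phenotypes for hypoxia-treated animals.

    Latency to first seizure is exponential with the configured mean;
    seizure count over the hypoxic interval is normal (configured mean/sd),
    truncated at zero and rounded to an integer.
    """
    if n_animals < 1:
        raise ValueError("need at least one hypoxia-treated animal")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    latency = rng.exponential(config.latency_mean_s, size=n_animals)
    counts = rng.normal(config.seizure_count_mean, config.seizure_count_sd, size=n_animals)
    counts = np.round(np.clip(counts, 0.0, None)).astype(int)
    return pd.DataFrame({"latency_s": latency, "seizure_count": counts})


def generate_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate one full study.

    Returns the probeset-level expression matrix with calls, the sample
    design table (with seizure phenotypes on hypoxia-treated animals), the
    many-to-many probeset-to-gene annotation, and the planted truth labels.
    """
    rng = np.random.default_rng(config.seed)
    truth_genes = _gene_truth(config, rng)
    design = _build_design(config, rng)
    n_genes = config.n_genes
    n_samples = len(design)

    # --- gene-level log2 signal -------------------------------------------
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    dev_sign = np.where(
        truth_genes["developmental"] == "up",
        1.0,
        np.where(truth_genes["developmental"] == "down", -1.0, 0.0),
    )
    hs_sign = np.where(
        truth_genes["hs"] == "up", 1.0, np.where(truth_genes["hs"] == "down", -1.0, 0.0)
    )
    nbqx_sign = np.where(
        truth_genes["nbqx_direction"] == "up",
        1.0,
        np.where(truth_genes["nbqx_direction"] == "down", -1.0, 0.0),
    )
    tissue_shift = np.zeros(n_genes)
    ts_mask = truth_genes["tissue_preference"] != "none"
    tissue_shift[ts_mask.to_numpy()] = rng.normal(
        0.0, config.tissue_effect_sd_log2, int(ts_mask.sum())
    )

    time_index = {t: i for i, t in enumerate(TIMES_H)}
    dev_ramp = np.linspace(0.0, 1.0, len(TIMES_H))  # monotone maturation ramp
    hs_w = np.asarray(config.hs_time_weights, dtype=float)

    log2_gene = np.empty((n_genes, n_samples))
    for j, row in enumerate(design.itertuples(index=False)):
        ti = time_index[row.time_h]
        signal = baseline + dev_sign * config.dev_effect_log2 * dev_ramp[ti]
        if row.tissue == "cortex":
            # tissue-specific genes shift in cortex relative to hippocampus
            signal = signal + tissue_shift
        if row.treatment in ("HS", "HS_NBQX"):
            signal = signal + hs_sign * config.hs_effect_log2 * hs_w[ti]
        if row.treatment == "HS_NBQX":
            signal = signal + nbqx_sign * config.nbqx_effect_log2 * hs_w[ti]
        log2_gene[:, j] = signal

    chip_effect = rng.normal(0.0, config.chip_effect_sd_log2, n_samples)
    log2_gene = log2_gene + chip_effect[None, :]
    log2_gene = log2_gene + rng.normal(0.0, config.noise_sd_log2, (n_genes, n_samples))

    # --- probeset layer ----------------------------------------------------
    n_ps_per_gene = rng.integers(1, config.probesets_per_gene_max + 1, n_genes)
    gene_of_ps = np.repeat(np.arange(n_genes), n_ps_per_gene)
    ps_ids = [
        f"{truth_genes['gene'].iloc[g]}_ps{k + 1}_at"
        for g, reps in zip(range(n_genes), n_ps_per_gene)
        for k in range(reps)
    ]
    log2_ps = log2_gene[gene_of_ps, :] + rng.normal(
        0.0, config.probe_noise_sd_log2, (len(ps_ids), n_samples)
    )
    intensity = np.exp2(log2_ps)

    # --- detection calls: absent rate decreases with intensity -------------
    p_present = 1.0 / (
        1.0 + np.exp(-(log2_ps - config.call_midpoint_log2) / config.call_scale_log2)
    )
    calls = np.where(rng.random(log2_ps.shape) < p_present, "P", "A")

    matrix = ExpressionMatrix(
        pd.DataFrame(intensity, index=ps_ids, columns=design["sample_id"].to_numpy()),
        pd.DataFrame(calls, index=ps_ids, columns=design["sample_id"].to_numpy()),
    )
    probe_map = pd.DataFrame(
        {
            "probeset_id": ps_ids,
            "gene_symbol": truth_genes["gene"].to_numpy()[gene_of_ps],
        }
    )

    # --- seizure phenotypes for hypoxia-treated animals --------------------
    design["latency_s"] = np.nan
    design["seizure_count"] = pd.array([pd.NA] * len(design), dtype="Int64")
    hyp = design["treatment"].isin(["HS", "HS_NBQX"])
    animals = design.loc[hyp, ["treatment", "time_h", "replicate"]].drop_duplicates()
    pheno = generate_phenotypes(config, len(animals), rng)
    pheno = pd.concat([animals.reset_index(drop=True), pheno], axis=1)
    design = design.merge(
        pheno,
        on=["treatment", "time_h", "replicate"],
        how="left",
        suffixes=("_drop", ""),
    )
    design = design.drop(columns=["latency_s_drop", "seizure_count_drop"])
    validate_design(design)

    truth = SyntheticTruth(genes=truth_genes)
    return matrix, design, probe_map, truth


def generate_signed_gene_sets(
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    source: str = "simulated",
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Draw signed gene sets against the planted HS labels.

    Enriched sets sample their up-regulatees preferentially (probability =
    ``config.purity``) from planted HS-up genes and their down-regulatees
    from HS-down genes; null sets sample uniformly.  Returns the collection
    and the per-set truth table (also attached to ``truth.gene_sets``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    genes = truth.genes["gene"].to_numpy()
    n = len(genes)
    if config.set_size_max > n:
        raise ValueError("gene-set size range exceeds the gene universe")
    hs_up = truth.genes.loc[truth.genes["hs"] == "up", "gene"].to_numpy()
    hs_down = truth.genes.loc[truth.genes["hs"] == "down", "gene"].to_numpy()

    n_enriched = int(round(config.fraction_enriched * config.n_gene_sets))
    enriched_flags = np.zeros(config.n_gene_sets, dtype=bool)
    if n_enriched:
        enriched_flags[rng.choice(config.n_gene_sets, n_enriched, replace=False)] = True

    sets: list[GeneSet] = []
    rows = []
    width = len(str(config.n_gene_sets))
    for i in range(config.n_gene_sets):
        name = f"set{i + 1:0{width}d}"
        size = int(rng.integers(config.set_size_min, config.set_size_max + 1))
        k_d = int(round(config.set_down_share * size))
        k_u = size - k_d
        if enriched_flags[i] and len(hs_up) and len(hs_down):
            up = _draw_pure(rng, k_u, hs_up, genes, config.purity)
            down = _draw_pure(rng, k_d, hs_down, genes, config.purity, exclude=up)
        else:
            members = rng.choice(genes, size=size, replace=False)
            up, down = members[:k_u], members[k_u:]
        sets.append(GeneSet(name, source, tuple(up), tuple(down)))
        rows.append({"name": name, "enriched": bool(enriched_flags[i])})
    set_truth = pd.DataFrame(rows)
    truth.gene_sets = set_truth
    return GeneSetCollection(sets), set_truth


def _draw_pure(
    rng: np.random.Generator,
    k: int,
    pool: np.ndarray,
    universe: np.ndarray,
    purity: float,
    exclude: np.ndarray = np.array([], dtype=object),
) -> np.ndarray:
    """Sample k distinct genes, each from ``pool`` with probability ``purity``.

    Falls back to the whole universe if the pool is exhausted.
    """
    taken: list[str] = []
    seen = set(exclude.tolist())
    avail_pool = [g for g in pool if g not in seen]
    rng.shuffle(avail_pool)
    while len(taken) < k:
        if rng.random() < purity and avail_pool:
            g = avail_pool.pop()
        else:
            g = universe[rng.integers(len(universe))]
        if g not in seen:
            seen.add(g)
            taken.append(g)
            if g in pool and g in avail_pool:
                avail_pool.remove(g)
    return np.asarray(taken, dtype=object)
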