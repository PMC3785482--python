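"""Readers and writers for every external artifact the pipeline touches.

All tabular formats are plain TSV/CSV; gene sets use a GMT dialect in which
member tokens may carry a ``+``/``-`` suffix giving the regulatee sign
(unsuffixed tokens are positive regulatees).  Intensities are stored on the
linear scale; any log transform happens inside computations, never at I/O.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from regks.containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    EnrichmentResult,
    validate_design,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Fixed float format for all serialized tables (round-trip stable).
FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# intensity + call matrices


def read_intensity_matrix(path: PathLike, calls_path: PathLike) -> ExpressionMatrix:
    """Read a probeset x sample intensity TSV and its paired call TSV.

    Both files carry a header row of sample ids and a first column of
    probeset ids.  Validation (positivity, call alphabet, duplicate ids,
    matching grids) is delegated to :class:`ExpressionMatrix`.
    """
    intensity = pd.read_csv(path, sep="\t", index_col=0)
    calls = pd.read_csv(calls_path, sep="\t", index_col=0, dtype=str)
    matrix = ExpressionMatrix(intensity.astype(float), calls)
    logger.info(
        "read intensity matrix: %d probesets x %d samples",
        matrix.n_probesets,
        matrix.n_samples,
    )
    return matrix


def write_intensity_matrix(
    matrix: ExpressionMatrix, path: PathLike, calls_path: PathLike
) -> None:
    matrix.intensity.to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT, index_label="probeset_id"
    )
    matrix.calls.to_csv(calls_path, sep="\t", index_label="probeset_id")


# ---------------------------------------------------------------------------
# sample design


def read_design_table(path: PathLike) -> pd.DataFrame:
    """Read and validate a sample design CSV/TSV.

    Factor levels are checked against the allowed sets; duplicate sample ids
    or unknown treatment levels are rejected.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    design = pd.read_csv(path, sep=sep)
    return validate_design(design)


def write_design_table(design: pd.DataFrame, path: PathLike) -> None:
    validate_design(design)
    design.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# probeset -> gene annotation


def read_probe_gene_map(path: PathLike) -> pd.DataFrame:
    """Read a two-column (probeset_id, gene_symbol) TSV; many-to-many."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["probeset_id", "gene_symbol"]
    if list(table.columns[:2]) != expected:
        raise ValueError(
            f"annotation table must have columns {expected}, got {list(table.columns)}"
        )
    if table.duplicated().any():
        raise ValueError("duplicate (probeset_id, gene_symbol) pairs in annotation")
    return table[expected]


def write_probe_gene_map(mapping: pd.DataFrame, path: PathLike) -> None:
    mapping[["probeset_id", "gene_symbol"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signed gene sets (GMT dialect)


def _parse_member(token: str) -> tuple[str, str]:
    if token.endswith("+"):
        return token[:-1], "+"
    if token.endswith("-"):
        return token[:-1], "-"
    return token, "+"  # unsuffixed members default to positive regulatees


def read_signed_gene_sets(
    path: PathLike, source: str | None = None
) -> GeneSetCollection:
    """Read a signed-GMT file into a :class:`GeneSetCollection`.

    Each line is ``name<TAB>description<TAB>member...``; member tokens may
    end in ``+`` (positive regulatee) or ``-`` (negative regulatee), with
    unsuffixed tokens treated as positive.  Duplicate members within a set
    are deduplicated with a warning; a member listed with both signs causes
    that set to be rejected.
    """
    source = source if source is not None else Path(path).stem
    sets: list[GeneSet] = []
    n_dedup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name = fields[0]
            up: dict[str, None] = {}
            down: dict[str, None] = {}
            conflict = False
            for token in fields[2:]:
                if not token:
                    continue
                gene, sign = _parse_member(token)
                bucket = up if sign == "+" else down
                other = down if sign == "+" else up
                if gene in other:
                    raise ValueError(
                        f"{path}:{lineno}: set {name!r} lists {gene!r} with both signs"
                    )
                if gene in bucket:
                    n_dedup += 1
                else:
                    bucket[gene] = None
            if conflict:
                continue
            sets.append(GeneSet(name, source, tuple(up), tuple(down)))
    if n_dedup:
        warnings.warn(
            f"{path}: deduplicated {n_dedup} repeated member(s) within sets",
            stacklevel=2,
        )
    return GeneSetCollection(sets)


def write_signed_gene_sets(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            members = [f"{g}+" for g in gs.up_genes] + [f"{g}-" for g in gs.down_genes]
            fh.write("\t".join([gs.name, gs.source] + members) + "\n")


def read_gene_set_registry(paths: dict[str, PathLike]) -> GeneSetCollection:
    """Read several signed-GMT files into one collection.

    ``paths`` maps a source label to a file; the label overrides the
    filename-derived source so per-collection FDR grouping is explicit.
    """
    sets: list[GeneSet] = []
    for source, path in paths.items():
        sets.extend(read_signed_gene_sets(path, source=source).sets)
    logger.info(
        "gene-set registry: %d collections, %d sets total", len(paths), len(sets)
    )
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# result tables

ENRICHMENT_COLUMNS = ["name", "source", "ku", "kd", "dUpDown", "P", "FDR", "cLeft", "cRight"]


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "name": r.name,
            "source": r.source,
            "ku": r.k_u,
            "kd": r.k_d,
            "dUpDown": r.d_updown,
            "P": r.p_value,
            "FDR": r.fdr,
            "cLeft": r.c_left,
            "cRight": r.c_right,
            "selected": r.selected,
            "leading_edge_up": ",".join(r.leading_edge_up),
            "leading_edge_down": ",".join(r.leading_edge_down),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=ENRICHMENT_COLUMNS + ["selected", "leading_edge_up", "leading_edge_down"],
    )


def write_results_tables(
    results: Sequence[EnrichmentResult] | pd.DataFrame, out_dir: PathLike
) -> list[Path]:
    """Write enrichment results (or any stage table) as TSV under ``out_dir``.

    Column order is deterministic and floats use a fixed format so that
    re-serializing a read-back table is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(results, pd.DataFrame):
        frame = results
    else:
        frame = enrichment_to_frame(results)
    path = out_dir / "enrichment.tsv"
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return [path]


def read_truth_table(path: PathLike) -> pd.DataFrame:
    """Read a simulation truth table ('null' is a label, not missing data)."""
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def write_table(frame: pd.DataFrame, path: PathLike, index: bool = False) -> Path:
    """Write any intermediate table with the package-wide fixed precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    return path
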