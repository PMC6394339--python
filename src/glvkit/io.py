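"""Readers and writers for every file format the toolkit touches.

All tabular files are tab-separated UTF-8 text with a mandatory header
row and '.' as the decimal separator.  Floats are written with 17
significant digits so that every writer/reader pair round-trips
exactly.  Readers never silently drop rows or columns.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GLVModel, Trajectory
from .errors import FormatError, ValidationError
from .tables import AbundanceTable

__all__ = [
    "read_abundance_table",
    "read_metadata",
    "read_model_files",
    "write_model_files",
    "write_trajectory",
    "write_abundance_table",
    "write_distance_matrix",
    "write_dtw_table",
    "write_newick",
    "write_edge_list",
    "write_graphml",
]

FLOAT_FMT = "%.17g"
DEFAULT_TIME_COLUMN = "Time"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _check_header(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", header=0, comment="#", float_precision="round_trip"
        )
    except Exception as exc:  # noqa: BLE001 - rewrap parser errors
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
    if frame.shape[1] < 1 or frame.shape[0] < 1:
        raise FormatError(f"{path} has no data rows")
    return frame


def _check_header(path: Path) -> None:
    # pandas mangles duplicate header names ("A", "A.1"); catch them here
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            names = [c.strip() for c in line.rstrip("\n").split("\t")]
            if len(set(names)) != len(names):
                dupes = sorted({n for n in names if names.count(n) > 1})
                raise FormatError(f"duplicate column names in {path}: {dupes}")
            return


def read_abundance_table(
    path: str | Path, time_column: str | int = DEFAULT_TIME_COLUMN
) -> AbundanceTable:
    """Read a taxa abundance TSV with one numeric sampling-time column.

    Rows are sorted by time ascending; duplicate times, negative or
    non-finite abundances, and duplicate taxon names all raise.
    ``time_column`` may be a header name (default ``"Time"``) or a
    0-based column index.
    """
    frame = _read_tsv(path)
    if isinstance(time_column, int):
        if not (0 <= time_column < frame.shape[1]):
            raise FormatError(
                f"time column index {time_column} out of range "
                f"({frame.shape[1]} columns)"
            )
        time_name = frame.columns[time_column]
    else:
        if time_column not in frame.columns:
            raise FormatError(
                f"time column {time_column!r} not found in {path}; "
                f"columns are {list(frame.columns)}"
            )
        time_name = time_column
    taxa_cols = [c for c in frame.columns if c != time_name]
    if not taxa_cols:
        raise FormatError(f"{path} has no taxa columns")
    trimmed = [str(c).strip() for c in taxa_cols]
    if len(set(trimmed)) != len(trimmed):
        dupes = sorted({t for t in trimmed if trimmed.count(t) > 1})
        raise FormatError(f"duplicate taxon names in {path}: {dupes}")
    try:
        times = frame[time_name].astype(float).to_numpy()
        values = frame[taxa_cols].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    if np.any(pd.isna(times)) or np.any(pd.isna(values)):
        raise ValidationError(f"missing (empty) cells in {path} are not allowed")
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    if np.any(np.diff(times) == 0):
        k = int(np.nonzero(np.diff(times) == 0)[0][0])
        raise ValidationError(
            f"duplicate sampling time {times[k]:g} in {path} "
            f"(sorted rows {k} and {k + 1})"
        )
    return AbundanceTable(times=times, taxa=trimmed, values=values)


def read_metadata(
    path: str | Path, time_column: str | int = DEFAULT_TIME_COLUMN
) -> dict[int, str]:
    """Read a per-timepoint metadata TSV into index -> label.

    The file carries the time column plus one label column; rows are
    matched to time-point indices by ascending time order.
    """
    frame = _read_tsv(path)
    if isinstance(time_column, int):
        time_name = frame.columns[time_column]
    else:
        time_name = time_column
    if time_name not in frame.columns:
        raise FormatError(f"time column {time_name!r} not found in {path}")
    label_cols = [c for c in frame.columns if c != time_name]
    if len(label_cols) != 1:
        raise FormatError(
            f"metadata file {path} must have exactly one label column, "
            f"found {label_cols}"
        )
    order = np.argsort(frame[time_name].astype(float).to_numpy(), kind="stable")
    labels = frame[label_cols[0]].astype(str).to_numpy()[order]
    return {i: lab for i, lab in enumerate(labels)}


# ---- model parameter files -------------------------------------------


def read_model_files(
    growth_path: str | Path, interaction_path: str | Path
) -> GLVModel:
    """Read a growth-rate file and an interaction-matrix file.

    The growth file is a two-column TSV (taxon, rate); the interaction
    file is a labeled square matrix whose row and column taxa must both
    match the growth file's taxon set.  Taxa order follows the growth
    file; the matrix is reordered to match.
    """
    growth = _read_tsv(growth_path)
    if growth.shape[1] != 2:
        raise FormatError(
            f"growth file {growth_path} must have 2 columns, "
            f"found {growth.shape[1]}"
        )
    taxa = [str(t).strip() for t in growth.iloc[:, 0]]
    try:
        rates = growth.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric growth rate: {exc}") from exc

    _check_header(Path(interaction_path))
    inter = pd.read_csv(
        interaction_path,
        sep="\t",
        header=0,
        index_col=0,
        float_precision="round_trip",
    )
    inter.index = [str(t).strip() for t in inter.index]
    inter.columns = [str(t).strip() for t in inter.columns]
    if inter.shape[0] != inter.shape[1]:
        raise FormatError(
            f"interaction matrix {interaction_path} is not square: "
            f"{inter.shape}"
        )
    if sorted(inter.index) != sorted(inter.columns):
        raise FormatError(
            "interaction matrix row and column labels differ: "
            f"{sorted(set(inter.index) ^ set(inter.columns))}"
        )
    diff = set(taxa) ^ set(inter.index)
    if diff:
        raise ValidationError(
            "taxon sets of growth and interaction files differ; "
            f"symmetric difference: {sorted(diff)}"
        )
    matrix = inter.loc[taxa, taxa].astype(float).to_numpy()
    return GLVModel(
        taxa=taxa,
        growth_rates=rates,
        interactions=matrix,
        method_tag="user_supplied",
    )


def write_model_files(
    model: GLVModel,
    growth_path: str | Path,
    interaction_path: str | Path,
) -> None:
    """Write growth-rate and interaction TSVs that round-trip exactly."""
    growth = pd.DataFrame(
        {"Taxon": model.taxa, "GrowthRate": model.growth_rates}
    )
    growth.to_csv(growth_path, sep="\t", index=False, float_format=FLOAT_FMT)
    inter = pd.DataFrame(model.interactions, index=model.taxa, columns=model.taxa)
    inter.index.name = "Taxon"
    inter.to_csv(interaction_path, sep="\t", float_format=FLOAT_FMT)


# ---- trajectories and tables -----------------------------------------


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a TSV with a Time column, full precision."""
    if len(traj.taxa) == 0:
        raise ValidationError("cannot write a trajectory with no taxa")
    frame = pd.DataFrame(traj.values, columns=traj.taxa)
    frame.insert(0, DEFAULT_TIME_COLUMN, traj.times)
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_abundance_table(
    table: AbundanceTable, path: str | Path, comment: str | None = None
) -> None:
    """Write an abundance table as TSV; optional '#' comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


# ---- evaluation / exploration artifacts ------------------------------


def write_distance_matrix(labels, values, path: str | Path) -> None:
    frame = pd.DataFrame(np.asarray(values, dtype=float), index=labels, columns=labels)
    frame.index.name = "Taxon"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_dtw_table(
    per_taxon: dict[str, float], cumulative: float, path: str | Path
) -> None:
    """Per-taxon DTW distances plus the cumulative (sum-total) score."""
    rows = [(t, d) for t, d in per_taxon.items()]
    rows.append(("__cumulative__", cumulative))
    pd.DataFrame(rows, columns=["Taxon", "DTW"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(newick.rstrip("\n") + "\n")


def write_edge_list(edges, path: str | Path) -> None:
    """Correlation network as a (source, target, pearson_r) TSV."""
    pd.DataFrame(edges, columns=["Source", "Target", "PearsonR"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def write_graphml(nodes, edges, path: str | Path) -> None:
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for a, b, r in edges:
        graph.add_edge(a, b, pearson_r=float(r))
    nx.write_graphml(graph, path)


def format_float(x: float) -> str:
    """Render a float at round-trip precision (shared by ad-hoc writers)."""
    if math.isnan(x) or math.isinf(x):
        raise ValidationError("refusing to write non-finite value")
    return FLOAT_FMT % x
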