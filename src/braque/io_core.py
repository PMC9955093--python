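"""Cell-table I/O, run configuration and logging.

The pipeline's universal input is a *cell table*: one row per segmented
cell, with an identifier, optional x/y tissue coordinates, and a block of
non-negative continuous marker intensities (e.g. mean pixel value per cell
from multiplex immunofluorescence).  CSV is the only supported format —
upstream segmentation tools emit per-cell CSV tables.  Row order is the
canonical cell order: every per-cell artifact produced downstream aligns
to it.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("braque")

__all__ = [
    "CellTable",
    "RunConfig",
    "read_cell_table",
    "write_labels",
    "load_config",
]

#: column names recognised as the cell identifier when none is given
_ID_CANDIDATES = ("cell_id", "id")


@dataclass
class CellTable:
    """Cells × markers matrix plus per-cell coordinates and identifiers.

    Parameters
    ----------
    cell_id
        One identifier per row; duplicates are rejected.
    markers
        (N, M) float array of non-negative, finite marker intensities.
    marker_names
        M marker column names.
    x, y
        Spatial coordinates (same arbitrary length unit), or ``None`` when
        the table carries no spatial information — the pipeline still runs,
        spatial outputs are skipped.
    """

    cell_id: np.ndarray
    markers: np.ndarray
    marker_names: list[str]
    x: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id)
        self.markers = np.asarray(self.markers, dtype=float)
        self.marker_names = list(self.marker_names)
        if self.markers.ndim != 2:
            raise ValueError("markers must be a 2-D cells × markers matrix")
        n, m = self.markers.shape
        if m != len(self.marker_names):
            raise ValueError(
                f"{len(self.marker_names)} marker names for {m} marker columns"
            )
        if len(self.cell_id) != n:
            raise ValueError("cell_id length does not match marker matrix")
        if n >= 1 and len(np.unique(self.cell_id)) != n:
            raise ValueError("duplicate cell_id values")
        if not np.all(np.isfinite(self.markers)):
            raise ValueError("non-finite marker values")
        if np.any(self.markers < 0):
            bad = np.where((self.markers < 0).any(axis=0))[0][0]
            raise ValueError(
                f"negative marker value in column {self.marker_names[bad]!r}"
            )
        for coord, name in ((self.x, "x"), (self.y, "y")):
            if coord is not None and len(np.asarray(coord)) != n:
                raise ValueError(f"coordinate column {name!r} length mismatch")
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.markers.shape[0]

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    @property
    def has_coordinates(self) -> bool:
        return self.x is not None and self.y is not None

    def to_frame(self) -> pd.DataFrame:
        """Full table as a DataFrame (id, coordinates, markers)."""
        data: dict = {"cell_id": self.cell_id}
        if self.has_coordinates:
            data["x"] = self.x
            data["y"] = self.y
        for j, name in enumerate(self.marker_names):
            data[name] = self.markers[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_cell_table(
    path,
    marker_columns: Optional[Sequence[str]] = None,
    coord_columns: tuple[str, str] = ("x", "y"),
    id_column: Optional[str] = None,
) -> CellTable:
    """Read a cell table from CSV.

    Columns not named as coordinates or identifier are treated as markers
    unless ``marker_columns`` restricts them explicitly.  Marker values must
    parse as non-negative reals; a non-numeric or negative entry raises with
    the offending column (and row, where known).
    """
    df = pd.read_csv(path)
    if id_column is None:
        id_column = next((c for c in _ID_CANDIDATES if c in df.columns), None)
    cx, cy = coord_columns
    have_coords = cx in df.columns and cy in df.columns
    if marker_columns is None:
        skip = {id_column, cx, cy}
        marker_columns = [c for c in df.columns if c not in skip]
    else:
        missing = [c for c in marker_columns if c not in df.columns]
        if missing:
            raise ValueError(f"marker columns not in file: {missing}")

    markers = np.empty((len(df), len(marker_columns)), dtype=float)
    for j, col in enumerate(marker_columns):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.where(~np.isfinite(vals))[0]
        if bad.size:
            raise ValueError(
                f"non-numeric marker value in column {col!r}, row {bad[0]}"
            )
        if np.any(vals < 0):
            row = int(np.where(vals < 0)[0][0])
            raise ValueError(
                f"negative marker value in column {col!r}, row {row}"
            )
        markers[:, j] = vals

    cell_id = (
        df[id_column].to_numpy() if id_column is not None else np.arange(len(df))
    )
    x = df[cx].to_numpy(dtype=float) if have_coords else None
    y = df[cy].to_numpy(dtype=float) if have_coords else None
    return CellTable(
        cell_id=cell_id, markers=markers, marker_names=list(marker_columns), x=x, y=y
    )


def write_labels(table: CellTable, labels, path) -> None:
    """Write per-cell cluster labels as CSV (cell_id, x, y, cluster, phase).

    ``labels`` is a :class:`~braque.clustering.ClusterLabels` or anything
    with ``labels``/``phase`` arrays.  Noise rows (cluster −1) are included.
    """
    lab = np.asarray(labels.labels)
    phase = np.asarray(labels.phase)
    if len(lab) != table.n_cells:
        raise ValueError(
            f"labels length {len(lab)} does not match table with {table.n_cells} cells"
        )
    df = pd.DataFrame(
        {
            "cell_id": table.cell_id,
            "x": table.x if table.x is not None else np.full(table.n_cells, np.nan),
            "y": table.y if table.y is not None else np.full(table.n_cells, np.nan),
            "cluster": lab.astype(int),
            "phase": phase.astype(int),
        }
    )
    df.to_csv(path, index=False)


# Table of advisory parameter ranges.  Values outside a range are kept but
# trigger a warning: the ranges are tuning suggestions, not hard contracts.
_SUGGESTED_RANGES = {
    "contraction_factor": (2.0, 10.0),
    "bgm_max_components": (10, 30),
    "bgm_tol": (1e-5, 1e-1),
    "umap_nn": (30, 500),
    "umap_min_dist": (0.0, 0.1),
    "cluster_selection_eps": (0.0, 0.3),
}


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their suggested defaults.

    The defaults encode the recommended operating point: contraction factor
    γ=5 with base-2 logarithms, a 15-component Dirichlet-process mixture
    upper bound at tolerance 1e-2, UMAP with 50 neighbours / min_dist 0 /
    Euclidean metric / spectral initialisation, and HDBSCAN with
    min_samples = max(0.005% of cells, 10) and cluster_selection_eps 0.1.
    """

    contraction_factor: float = 5.0
    log_base: float = 2.0
    shift_epsilon: float = 1e-3
    bgm_max_components: int = 15
    bgm_tol: float = 1e-2
    bgm_max_iter: int = 1500
    umap_nn: int = 50
    umap_min_dist: float = 0.0
    umap_metric: str = "euclidean"
    umap_init: str = "spectral"
    hdbscan_min_samples_frac: float = 0.00005
    hdbscan_min_samples_floor: int = 10
    cluster_selection_eps: float = 0.1
    two_phase: bool = True
    phase2_min_samples_mult: int = 10
    rescale_after_lns: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        if self.bgm_max_components < 2:
            raise ValueError("bgm_max_components must be >= 2")
        if self.contraction_factor <= 0:
            raise ValueError("contraction_factor must be positive")
        self.warn_out_of_range()

    def warn_out_of_range(self) -> None:
        for key, (lo, hi) in _SUGGESTED_RANGES.items():
            val = getattr(self, key)
            if not (lo <= val <= hi):
                warnings.warn(
                    f"config {key}={val} outside suggested range [{lo}, {hi}]; "
                    "keeping it (ranges are advisory)",
                    stacklevel=2,
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_NUMERIC_FIELDS = {
    f.name: f.type
    for f in dataclasses.fields(RunConfig)
    if f.name not in ("umap_metric", "umap_init", "two_phase", "rescale_after_lns")
}


def load_config(path=None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from defaults, an optional YAML file and
    keyword overrides (overrides beat file, file beats defaults).

    Unknown keys in the file produce a warning and are ignored; a
    non-numeric value for a numeric key is an error; values outside the
    suggested ranges are kept with a warning.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(RunConfig)}
        for key, val in raw.items():
            if key not in known:
                warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
                continue
            if key in _NUMERIC_FIELDS and not isinstance(val, (int, float)):
                raise ValueError(f"config key {key!r} must be numeric, got {val!r}")
            values[key] = val
    values.update(overrides)
    return RunConfig(**values)


def setup_run_logging(out_dir: Optional[Path] = None) -> logging.Logger:
    """Attach a run-log file handler under ``out_dir`` (if given)."""
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return logger
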