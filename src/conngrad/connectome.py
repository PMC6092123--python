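"""Dense connectivity matrices from voxel time series.

The analysis starts from a "dense connectome": the Pearson correlation of every
seed voxel's time course with every target voxel's.  For multi-run data each
voxel's series is z-scored within run and the runs concatenated before
correlating, so between-run offsets never masquerade as connectivity.  Values
may be carried as raw correlations or variance-stabilized Fisher z; the
``value_kind`` flag records which.

All voxel indexing is 0-based; matrices are plain ``numpy`` arrays with id
vectors alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    DomainError,
    FlaggedVoxelError,
    InvalidParameterError,
    ParseError,
    ShapeMismatchError,
)

__all__ = [
    "TimeseriesMatrix",
    "ConnectivityMatrix",
    "normalize_concat",
    "correlation_connectome",
    "fisher_z",
    "inverse_fisher_z",
    "save_connectivity",
    "load_connectivity",
]


@dataclass
class TimeseriesMatrix:
    """Voxels x timepoints signal matrix.

    ``run_boundaries`` are the exclusive end columns of each run, strictly
    increasing and ending at the final column, e.g. ``[300, 600]`` for two
    300-timepoint runs.
    """

    values: np.ndarray
    voxel_ids: np.ndarray
    run_boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids)
        if self.values.ndim != 2:
            raise ShapeMismatchError("timeseries must be 2-D (voxels x timepoints)")
        if len(self.voxel_ids) != self.values.shape[0]:
            raise ShapeMismatchError(
                f"{len(self.voxel_ids)} voxel ids for {self.values.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.values)):
            raise DomainError("timeseries contains non-finite entries")
        if not self.run_boundaries:
            self.run_boundaries = [self.values.shape[1]]
        bounds = list(self.run_boundaries)
        if bounds != sorted(set(bounds)) or bounds[-1] != self.values.shape[1]:
            raise ShapeMismatchError(
                "run boundaries must be strictly increasing and end at the final column"
            )

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def run_slices(self) -> list[slice]:
        starts = [0] + list(self.run_boundaries[:-1])
        return [slice(a, b) for a, b in zip(starts, self.run_boundaries)]


@dataclass
class ConnectivityMatrix:
    """Seed-voxels x targets connectivity.

    ``value_kind`` is ``"pearson-r"`` or ``"fisher-z"``.  A square intra-set
    connectome sets ``symmetric=True`` with ``seed_ids == target_ids``.
    """

    values: np.ndarray
    seed_ids: np.ndarray
    target_ids: np.ndarray
    value_kind: str = "pearson-r"
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.seed_ids = np.asarray(self.seed_ids)
        self.target_ids = np.asarray(self.target_ids)
        if self.values.shape != (len(self.seed_ids), len(self.target_ids)):
            raise ShapeMismatchError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.seed_ids)} seeds x {len(self.target_ids)} targets"
            )
        if self.value_kind not in ("pearson-r", "fisher-z"):
            raise InvalidParameterError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "pearson-r" and self.values.size:
            # allow a hair of floating slop beyond [-1, 1]
            if np.nanmax(np.abs(self.values)) > 1 + 1e-12:
                raise DomainError("pearson-r values must lie in [-1, 1]")
        if self.symmetric:
            if self.values.shape[0] != self.values.shape[1] or not np.array_equal(
                self.seed_ids, self.target_ids
            ):
                raise ShapeMismatchError("symmetric matrix requires seed_ids == target_ids")
            if self.values.size and np.max(np.abs(self.values - self.values.T)) > 1e-10:
                raise ShapeMismatchError("symmetric flag set but matrix is not symmetric")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def normalize_concat(runs: list[TimeseriesMatrix]) -> TimeseriesMatrix:
    """Z-score each voxel within each run, then concatenate runs column-wise.

    All runs must share ``voxel_ids`` and have at least 3 timepoints.  A voxel
    with zero variance inside any run raises :class:`FlaggedVoxelError` naming
    the offenders (the caller decides whether to drop them and retry).
    """
    if not runs:
        raise InvalidParameterError("need at least one run")
    ids = runs[0].voxel_ids
    for r in runs[1:]:
        if not np.array_equal(r.voxel_ids, ids):
            raise ShapeMismatchError("all runs must share voxel_ids")
    flagged: set = set()
    pieces = []
    for run in runs:
        if run.n_timepoints < 3:
            raise InvalidParameterError("each run needs >= 3 timepoints")
        x = run.values
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        # relative cutoff: a constant series can carry sd ~ 1e-16 float noise
        zero = np.flatnonzero((sd <= 1e-12 * (np.abs(mu) + 1)).ravel())
        if zero.size:
            flagged.update(ids[zero].tolist())
            sd = np.where(sd == 0, 1.0, sd)  # placeholder; error raised below
        pieces.append((x - mu) / sd)
    if flagged:
        raise FlaggedVoxelError("zero variance within a run", sorted(flagged))
    out = np.concatenate(pieces, axis=1)
    boundaries = np.cumsum([r.n_timepoints for r in runs]).tolist()
    return TimeseriesMatrix(out, ids.copy(), boundaries)


def _zscore_rows(x: np.ndarray, ids: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=0)
    mu = x.mean(axis=1)
    zero = np.flatnonzero(sd <= 1e-12 * (np.abs(mu) + 1))
    if zero.size:
        raise FlaggedVoxelError("zero-variance series", np.asarray(ids)[zero].tolist())
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def correlation_connectome(
    seed_ts: TimeseriesMatrix, target_ts: TimeseriesMatrix | None = None
) -> ConnectivityMatrix:
    """Pearson correlation of each seed voxel with each target voxel.

    With ``target_ts=None`` the intra-set (square, symmetric) connectome is
    returned.  Correlations are computed over the full concatenated series.
    """
    symmetric = target_ts is None
    tgt = seed_ts if target_ts is None else target_ts
    if tgt.n_timepoints != seed_ts.n_timepoints:
        raise ShapeMismatchError(
            f"seed has {seed_ts.n_timepoints} timepoints, target {tgt.n_timepoints}"
        )
    if not symmetric and list(tgt.run_boundaries) != list(seed_ts.run_boundaries):
        raise ShapeMismatchError("seed and target must share run structure")
    t = seed_ts.n_timepoints
    zs = _zscore_rows(seed_ts.values, seed_ts.voxel_ids)
    zt = zs if symmetric else _zscore_rows(tgt.values, tgt.voxel_ids)
    r = zs @ zt.T / t
    np.clip(r, -1.0, 1.0, out=r)
    if symmetric:
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        r, seed_ts.voxel_ids.copy(), tgt.voxel_ids.copy(), "pearson-r", symmetric
    )


def fisher_z(values):
    """Fisher's variance-stabilizing transform z = atanh(r).

    Inputs must lie strictly inside (-1, 1); offenders raise
    :class:`DomainError` with their flat indices.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(np.abs(arr) < 1))
    if bad.size:
        raise DomainError(f"|r| >= 1 at flat indices {bad.tolist()[:10]}")
    return np.arctanh(arr)


def inverse_fisher_z(values):
    """Inverse Fisher transform r = tanh(z)."""
    return np.tanh(np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# I/O: delimited text with JSON sidecar, or raw float64 binary with JSON header

_META_SUFFIX = ".json"


def _meta(conn: ConnectivityMatrix) -> dict:
    return {
        "format": "conngrad-connectivity",
        "version": 1,
        "shape": list(conn.shape),
        "seed_ids": np.asarray(conn.seed_ids).tolist(),
        "target_ids": np.asarray(conn.target_ids).tolist(),
        "value_kind": conn.value_kind,
        "symmetric": bool(conn.symmetric),
    }


def save_connectivity(conn: ConnectivityMatrix, path, binary: bool = False) -> Path:
    """Write a connectivity matrix to ``path`` with a JSON metadata sidecar.

    ``binary=False`` writes a TSV of full-precision floats; ``binary=True``
    writes raw little-endian float64 (row-major).  Returns the data path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = _meta(conn)
    meta["encoding"] = "float64-le" if binary else "tsv"
    if binary:
        conn.values.astype("<f8").tofile(path)
    else:
        np.savetxt(path, conn.values, fmt="%.17g", delimiter="\t")
    Path(str(path) + _META_SUFFIX).write_text(json.dumps(meta, indent=1))
    return path


def load_connectivity(path) -> ConnectivityMatrix:
    """Read a matrix written by :func:`save_connectivity`."""
    path = Path(path)
    meta_path = Path(str(path) + _META_SUFFIX)
    if not meta_path.exists():
        raise ParseError(f"missing metadata sidecar {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as e:  # pragma: no cover - passthrough context
        raise ParseError(f"{meta_path}: {e}") from e
    if meta.get("format") != "conngrad-connectivity":
        raise ParseError(f"{meta_path}: not a conngrad connectivity sidecar")
    shape = tuple(meta["shape"])
    if meta.get("encoding") == "float64-le":
        values = np.fromfile(path, dtype="<f8")
        if values.size != shape[0] * shape[1]:
            raise ParseError(
                f"{path}: expected {shape[0] * shape[1]} float64 values, got {values.size}"
            )
        values = values.reshape(shape)
    else:
        try:
            values = np.loadtxt(path, delimiter="\t", ndmin=2)
        except ValueError as e:
            raise ParseError(f"{path}: {e}") from e
        if values.shape != shape:
            raise ParseError(f"{path}: shape {values.shape} != declared {shape}")
    return ConnectivityMatrix(
        values,
        np.asarray(meta["seed_ids"]),
        np.asarray(meta["target_ids"]),
        meta["value_kind"],
        meta["symmetric"],
    )
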