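"""Diffusion map embedding of connectivity matrices.

Each voxel's row of the (sparsified) connectome is its "connectivity pattern";
cosine similarity between patterns defines an affinity graph, and the spectrum
of the anisotropically normalized random walk on that graph yields continuous
per-voxel coordinates — the functional *gradients*.  Gradient 1 orders voxels
along the dominant axis of connectivity-pattern change; further gradients are
orthogonal refinements.

Pipeline: ``sparsify_rows`` (keep each row's top fraction) → ``cosine_affinity``
→ ``diffusion_map``.  Post-hoc helpers orient gradient signs against an anchor
and match/align gradients across datasets.

Notation for :func:`diffusion_map`: with affinity ``W`` and degree ``D``,
``W' = D^-a W D^-a`` (anisotropy ``a``), ``M = D'^-1 W'`` the Markov matrix;
gradients are the nontrivial right eigenvectors of ``M`` scaled by
``lambda^t`` (diffusion time ``t > 0``) or ``lambda / (1 - lambda)`` (``t = 0``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.optimize import linear_sum_assignment

from .connectome import ConnectivityMatrix
from .exceptions import (
    DegenerateRowError,
    GraphConnectivityError,
    InvalidParameterError,
    InvalidStateError,
    ShapeMismatchError,
)

__all__ = [
    "AffinityMatrix",
    "GradientSet",
    "sparsify_rows",
    "cosine_affinity",
    "diffusion_map",
    "variance_explained",
    "orient_gradients",
    "match_gradients",
    "save_gradients",
    "load_gradients",
]


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative voxel-by-voxel similarity with unit diagonal."""

    values: np.ndarray
    voxel_ids: np.ndarray
    kernel: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ShapeMismatchError("affinity must be square")
        if len(self.voxel_ids) != n:
            raise ShapeMismatchError("voxel_ids length mismatch")
        if n and np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ShapeMismatchError("affinity must be symmetric within 1e-10")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass
class GradientSet:
    """Voxels x components embedding with its spectrum and provenance.

    ``components[:, i]`` assigns every voxel a unitless position along
    gradient ``i+1``.  ``eigenvalues`` are the corresponding nontrivial Markov
    eigenvalues (non-increasing); ``params`` records the embedding settings;
    ``orientation`` the per-component sign decisions applied so far.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    voxel_ids: np.ndarray
    params: dict = field(default_factory=dict)
    orientation: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids)
        if self.components.ndim != 2:
            raise ShapeMismatchError("components must be voxels x n_components")
        if self.components.shape[0] != len(self.voxel_ids):
            raise ShapeMismatchError("voxel_ids length mismatch")
        if self.components.shape[1] != len(self.eigenvalues):
            raise ShapeMismatchError("one eigenvalue per component required")
        if not np.all(np.isfinite(self.components)):
            raise InvalidStateError("components contain non-finite values")
        if not self.orientation:
            self.orientation = ["unset"] * self.n_components

    @property
    def n_voxels(self) -> int:
        return self.components.shape[0]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def variance_explained(self) -> np.ndarray:
        return variance_explained(self)

    def gradient(self, k: int) -> np.ndarray:
        """1-based accessor: ``gradient(1)`` is the principal gradient."""
        if not 1 <= k <= self.n_components:
            raise InvalidParameterError(f"gradient index {k} outside 1..{self.n_components}")
        return self.components[:, k - 1]

    def copy(self) -> "GradientSet":
        return GradientSet(
            self.components.copy(),
            self.eigenvalues.copy(),
            self.voxel_ids.copy(),
            dict(self.params),
            list(self.orientation),
        )


def sparsify_rows(conn: ConnectivityMatrix, keep_pct: float) -> ConnectivityMatrix:
    """Keep each row's top ``keep_pct`` percent of entries; zero the rest.

    Per row the cut is that row's ``100 - keep_pct`` percentile; entries equal
    to the threshold are retained (closed threshold), so ties never drop below
    the nominal count.  Row order and retained values are untouched.
    """
    if not 0 < keep_pct <= 100:
        raise InvalidParameterError(f"keep_pct must be in (0, 100], got {keep_pct}")
    values = conn.values.copy()
    if keep_pct < 100:
        cuts = np.percentile(values, 100 - keep_pct, axis=1, keepdims=True)
        values[values < cuts] = 0.0
    return ConnectivityMatrix(
        values, conn.seed_ids.copy(), conn.target_ids.copy(), conn.value_kind, False
    )


def cosine_affinity(conn_sparse: ConnectivityMatrix) -> AffinityMatrix:
    """Cosine similarity between sparsified connectivity rows.

    Negative cosines are clamped to 0 so the downstream Markov construction
    has a valid nonnegative kernel; the diagonal is exactly 1.
    """
    x = conn_sparse.values
    norms = np.linalg.norm(x, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise DegenerateRowError("all-zero connectivity row", dead.tolist())
    unit = x / norms[:, None]
    aff = unit @ unit.T
    np.clip(aff, 0.0, 1.0, out=aff)
    aff = (aff + aff.T) / 2.0
    np.fill_diagonal(aff, 1.0)
    return AffinityMatrix(
        aff,
        conn_sparse.seed_ids.copy(),
        kernel={"metric": "cosine", "clamp_negative": True},
    )


def diffusion_map(
    aff: AffinityMatrix,
    n_components: int = 8,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> GradientSet:
    """Diffusion map embedding of an affinity matrix.

    Anisotropic normalization ``W' = D^-alpha W D^-alpha`` (``alpha = 0.5``
    discounts sampling-density effects), row-normalization to a Markov matrix,
    then eigendecomposition via the symmetric conjugate
    ``S = D'^-1/2 W' D'^-1/2`` (dense ``eigh``; deterministic).  The trivial
    constant eigenvector is dropped; remaining right eigenvectors are divided
    by the stationary one and scaled by ``lambda/(1-lambda)`` at diffusion
    time 0 or ``lambda**t`` at time ``t > 0``.  Eigenvalues are returned in
    non-increasing order.

    Raises :class:`GraphConnectivityError` when the affinity graph is
    disconnected (multiple unit eigenvalues) — typically a sign that row
    sparsification was too aggressive.
    """
    if not 0 <= alpha <= 1:
        raise InvalidParameterError(f"alpha must be in [0, 1], got {alpha}")
    if diffusion_time < 0:
        raise InvalidParameterError("diffusion_time must be >= 0")
    w = aff.values
    n = w.shape[0]
    if not 0 < n_components < n:
        raise InvalidParameterError(f"n_components must be in 1..{n - 1}")

    d = w.sum(axis=1)
    if np.any(d <= 0):
        raise DegenerateRowError("zero-degree node in affinity", np.flatnonzero(d <= 0).tolist())
    if alpha > 0:
        da = d**-alpha
        w = w * da[:, None] * da[None, :]
        d = w.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(d)
    s = w * d_isqrt[:, None] * d_isqrt[None, :]
    s = (s + s.T) / 2.0  # guard numerical asymmetry before eigh

    lo = n - (n_components + 1)
    evals, evecs = scipy.linalg.eigh(s, subset_by_index=[lo, n - 1])
    evals, evecs = evals[::-1], evecs[:, ::-1]  # descending

    if n_components >= 1 and evals[1] > 1 - 1e-10:
        raise GraphConnectivityError(
            "affinity graph is disconnected (repeated unit eigenvalue); "
            "inspect sparsification settings"
        )

    # right eigenvectors of M, normalized by the trivial (stationary-direction) one
    psi = evecs * d_isqrt[:, None]
    psi = psi / psi[:, [0]]
    lam = evals[1:]
    lam = np.clip(lam, -1 + 1e-15, 1 - 1e-15)
    scale = lam**diffusion_time if diffusion_time > 0 else lam / (1 - lam)
    components = psi[:, 1:] * scale[None, :]

    return GradientSet(
        components,
        evals[1:],
        aff.voxel_ids.copy(),
        params={
            "alpha": alpha,
            "diffusion_time": diffusion_time,
            "n_components": n_components,
            "kernel": dict(aff.kernel),
            "variance_convention": "lambda-squared over computed spectrum",
        },
    )


def variance_explained(g: GradientSet) -> np.ndarray:
    """Proportion of spectral energy per component: lambda_i^2 / sum lambda_j^2.

    Normalized over the computed components, so the proportions sum to 1 for
    the components present (a lower bound on nothing — the convention is
    recorded in ``params``).
    """
    lam = np.asarray(g.eigenvalues, dtype=float)
    if lam.size == 0:
        raise InvalidStateError("empty spectrum")
    sq = lam**2
    total = sq.sum()
    if total == 0:
        return np.zeros_like(sq)
    return sq / total


def orient_gradients(g: GradientSet, anchor_low, warn=None) -> GradientSet:
    """Fix each gradient's sign against an anchor.

    ``anchor_low`` is either a boolean voxel mask that should sit at the *low*
    end of every gradient (sign flipped iff the anchor mean is positive), or a
    per-voxel reference vector (sign flipped iff the correlation with it is
    negative).  Idempotent; decisions recorded in ``orientation``.
    """
    anchor = np.asarray(anchor_low)
    out = g.copy()
    if anchor.dtype == bool:
        if anchor.shape != (g.n_voxels,):
            raise ShapeMismatchError("anchor mask length must equal voxel count")
        if not anchor.any():
            raise InvalidParameterError("anchor mask is empty")
        stats = out.components[anchor].mean(axis=0)
        flip = stats > 0
        unresolved = stats == 0
    else:
        if anchor.shape != (g.n_voxels,):
            raise ShapeMismatchError("reference vector length must equal voxel count")
        ref = anchor.astype(float)
        ref = ref - ref.mean()
        stats = ref @ out.components
        flip = stats < 0
        unresolved = stats == 0
    for i in range(out.n_components):
        if unresolved[i]:
            out.orientation[i] = "unresolved"
            if warn is not None:
                warn(f"gradient {i + 1}: anchor statistic exactly 0; sign kept")
        elif flip[i]:
            out.components[:, i] = -out.components[:, i]
            out.orientation[i] = "flipped"
        else:
            out.orientation[i] = "kept"
    return out


def match_gradients(g_target: GradientSet, g_reference: GradientSet, k: int) -> GradientSet:
    """Reorder and sign-flip target gradients to best match a reference.

    Solves the optimal one-to-one assignment maximizing the summed |Pearson r|
    between the first ``k`` target and reference components, then flips signs
    so each matched correlation is positive.  The assignment and correlations
    are recorded in ``params['matching']``.
    """
    if k > g_target.n_components or k > g_reference.n_components:
        raise InvalidParameterError(
            f"k={k} exceeds available components "
            f"({g_target.n_components} target, {g_reference.n_components} reference)"
        )
    if g_target.n_voxels != g_reference.n_voxels:
        raise ShapeMismatchError("gradient sets must share the voxel set")
    tgt = g_target.components[:, :k]
    ref = g_reference.components[:, :k]
    tz = (tgt - tgt.mean(axis=0)) / tgt.std(axis=0, ddof=0)
    rz = (ref - ref.mean(axis=0)) / ref.std(axis=0, ddof=0)
    corr = tz.T @ rz / tgt.shape[0]  # corr[i, j] = r(target_i, ref_j)
    rows, cols = linear_sum_assignment(-np.abs(corr))
    order = np.empty(k, dtype=int)
    order[cols] = rows  # target component that lands in reference slot j
    signs = np.sign(corr[order, np.arange(k)])
    signs[signs == 0] = 1.0

    out = g_target.copy()
    out.components = out.components.copy()
    out.components[:, :k] = tgt[:, order] * signs[None, :]
    out.eigenvalues = out.eigenvalues.copy()
    out.eigenvalues[:k] = g_target.eigenvalues[order]
    out.orientation = list(g_target.orientation)
    for j in range(k):
        out.orientation[j] = "matched"
    out.params = dict(out.params)
    out.params["matching"] = {
        "assignment": order.tolist(),
        "signs": signs.tolist(),
        "abs_correlations": np.abs(corr[order, np.arange(k)]).tolist(),
    }
    return out


def save_gradients(g: GradientSet, prefix) -> Path:
    """Write a gradient table (``<prefix>.tsv``) plus JSON sidecar.

    The table has one row per voxel (voxel id, gradient 1..k); the sidecar
    carries eigenvalues, variance explained, parameters, and orientation.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    k = g.n_components
    with open(tsv, "w") as fh:
        fh.write("voxel_id\t" + "\t".join(f"gradient_{i + 1}" for i in range(k)) + "\n")
        for v in range(g.n_voxels):
            row = "\t".join(f"{g.components[v, i]:.17g}" for i in range(k))
            fh.write(f"{g.voxel_ids[v]}\t{row}\n")
    sidecar = {
        "format": "conngrad-gradients",
        "version": 1,
        "n_voxels": g.n_voxels,
        "n_components": k,
        "eigenvalues": g.eigenvalues.tolist(),
        "variance_explained": variance_explained(g).tolist(),
        "params": g.params,
        "orientation": g.orientation,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return tsv


def load_gradients(prefix) -> GradientSet:
    """Read a gradient set written by :func:`save_gradients`."""
    from .exceptions import ParseError

    prefix = Path(prefix)
    sidecar_path = prefix.with_suffix(".json")
    if not sidecar_path.exists():
        raise ParseError(f"missing gradient sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("format") != "conngrad-gradients":
        raise ParseError(f"{sidecar_path}: not a conngrad gradient sidecar")
    rows = prefix.with_suffix(".tsv").read_text().strip().split("\n")
    body = [r.split("\t") for r in rows[1:]]
    if len(body) != meta["n_voxels"]:
        raise ParseError(
            f"{prefix}.tsv: {len(body)} rows, sidecar declares {meta['n_voxels']}"
        )
    ids = np.array([int(r[0]) for r in body])
    comps = np.array([[float(x) for x in r[1:]] for r in body])
    return GradientSet(
        comps,
        np.asarray(meta["eigenvalues"], dtype=float),
        ids,
        params=meta.get("params", {}),
        orientation=meta.get("orientation", []),
    )
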