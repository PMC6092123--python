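"""Seed-based connectivity contrasts between representation areas.

Two seed voxels A and B each have a connectivity map over the same targets.
Because both maps are computed from the same sample, comparing r(A, target)
with r(B, target) must account for the correlation between the seeds
themselves: Meng, Rosenthal & Rubin's z-test for correlated correlation
coefficients does exactly that.  Per-target p-values are then corrected with
Benjamini–Hochberg voxelwise FDR.

Meng's statistic for comparing r_jk and r_jh sharing variable j, with
r_kh the correlation between the two predictors and n the sample size:

    rbar2 = (r_jk^2 + r_jh^2) / 2
    f     = min(1, (1 - r_kh) / (2 (1 - rbar2)))
    h     = (1 - f * rbar2) / (1 - rbar2)
    z     = (atanh(r_jk) - atanh(r_jh)) * sqrt((n - 3) / (2 (1 - r_kh) h))

with a two-sided p from the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import DomainError, InvalidParameterError, ShapeMismatchError

__all__ = [
    "meng_z",
    "bh_fdr",
    "seed_contrast",
    "gradient_peak",
    "ContrastResult",
]


def _check_r(name: str, r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    bad = np.flatnonzero(~(np.abs(r) < 1))
    if bad.size:
        raise DomainError(f"{name}: |r| >= 1 at flat indices {bad.tolist()[:10]}")
    return r


def meng_z(r_jk, r_jh, r_kh, n: int):
    """Meng's z for comparing two correlated correlations (vectorized).

    ``r_jk`` and ``r_jh`` are the two correlations sharing variable j;
    ``r_kh`` the correlation between the compared variables k and h; ``n`` the
    sample size (>= 4).  Returns ``(z, p)`` with two-sided normal p-values.
    The factor f is capped at 1, exactly as in the original method.
    """
    if n < 4:
        raise InvalidParameterError(f"n must be >= 4, got {n}")
    r_jk = _check_r("r_jk", r_jk)
    r_jh = _check_r("r_jh", r_jh)
    r_kh = _check_r("r_kh", r_kh)
    rbar2 = (r_jk**2 + r_jh**2) / 2.0
    if np.any(rbar2 >= 1):
        raise DomainError("mean squared correlation must be < 1")
    f = np.minimum(1.0, (1.0 - r_kh) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (np.arctanh(r_jk) - np.arctanh(r_jh)) * np.sqrt((n - 3) / (2.0 * (1.0 - r_kh) * h))
    p = 2.0 * norm.sf(np.abs(z))
    return z, p


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini–Hochberg step-up procedure.

    Rejects all p <= p_(k*) where k* = max{k : p_(k) <= q k / m}.  Returns
    ``(rejected mask, rejection_threshold)``; the threshold is the largest
    rejected p-value, 0.0 when nothing is rejected.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise InvalidParameterError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise InvalidParameterError(f"q must be in (0, 1), got {q}")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), 0.0
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(sorted_p <= crit)
    if passing.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    threshold = sorted_p[passing[-1]]
    return p <= threshold, float(threshold)


@dataclass
class ContrastResult:
    """Per-target Meng contrast of two seed connectivity maps."""

    table: pd.DataFrame  # target_id, r_a, r_b, z_a, z_b, z, p, rejected
    r_ab: float
    n: int
    q: float
    rejection_threshold: float
    params: dict = field(default_factory=dict)

    @property
    def rejected(self) -> np.ndarray:
        return self.table["rejected"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy()


def seed_contrast(
    conn_a, conn_b, r_ab: float, n: int, q: float = 0.05, target_ids=None
) -> ContrastResult:
    """Contrast two seeds' connectivity maps across shared targets.

    ``conn_a`` / ``conn_b``: correlation rows of seeds A and B over identical
    targets; ``r_ab`` the seed-seed correlation; ``n`` the sample size behind
    the correlations (the caller must state it — it is not inferred).  Per
    target, Meng's z with shared ``r_ab`` and ``n``; then BH-FDR at level
    ``q`` across targets.  Fisher z values of the inputs are carried in the
    output table for inspection.
    """
    a = np.asarray(conn_a, dtype=float)
    b = np.asarray(conn_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeMismatchError(f"seed rows misaligned: {a.shape} vs {b.shape}")
    if target_ids is None:
        target_ids = np.arange(a.size)
    target_ids = np.asarray(target_ids)
    if target_ids.shape != a.shape:
        raise ShapeMismatchError("target_ids must align with the seed rows")
    z, p = meng_z(a, b, float(r_ab), n)
    rejected, threshold = bh_fdr(p, q)
    table = pd.DataFrame(
        {
            "target_id": target_ids,
            "r_a": a,
            "r_b": b,
            "z_a": np.arctanh(a),
            "z_b": np.arctanh(b),
            "z": z,
            "p": p,
            "rejected": rejected,
        }
    )
    return ContrastResult(
        table=table,
        r_ab=float(r_ab),
        n=int(n),
        q=float(q),
        rejection_threshold=threshold,
        params={"test": "Meng correlated correlations", "sided": "two"},
    )


def gradient_peak(values, region_mask, direction: str = "high") -> int:
    """Index of the gradient-peak voxel inside a region.

    The voxel with the most extreme gradient value (largest for ``"high"``,
    smallest for ``"low"``); ties break toward the lower voxel index.  Used to
    pick contrast seeds inside representation areas.
    """
    values = np.asarray(values, dtype=float)
    region = np.flatnonzero(np.asarray(region_mask, dtype=bool))
    if region.size == 0:
        raise InvalidParameterError("region mask is empty")
    key = -values[region] if direction == "high" else values[region]
    if direction not in ("high", "low"):
        raise InvalidParameterError(f"direction must be 'high' or 'low', got {direction!r}")
    order = np.lexsort((region, key))
    return int(region[order[0]])
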