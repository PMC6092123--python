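"""Synthetic scenes with a known two-gradient latent structure.

Every downstream stage (connectome → embedding → parcellation → clustering →
contrasts) is exercised on data generated here, so recovery can be checked
against ground truth without any download.

Generative model
----------------
Each voxel ``v`` carries latent coordinates ``(g1, g2)`` in ``[-1, 1]^2``,
drawn uniformly inside its *zone*'s box (motor / task-focused nonmotor /
task-unfocused nonmotor by default, mirroring the motor, working-memory-like
and DMN/language-like poles of the empirical gradients).  ``K`` network
centers ``c_k`` live in the same space with bandwidth ``tau``; each drives a
unit-variance white-noise source ``s_k(t)``, and

    x_v(t) = sum_k w_k(v) s_k(t) + eps,   w_k(v) = exp(-||x_v - c_k||^2 / (2 tau^2))

with ``eps ~ N(0, noise_sd^2)``.  Inter-voxel correlation therefore decays
smoothly with latent distance, which is exactly the structure diffusion map
embedding is meant to recover.

Representation labels (M1/M2 motor, N1/N2/N3 nonmotor) are assigned within
each zone by radial rank from the latent center: second-motor and
third-nonmotor representations take the innermost voxels, placing them at less
extreme latent positions *by construction*.  Task maps threshold a noisy
linear read-out of the latent coordinates (default cut 0.5, mirroring a
medium effect size); the network map is winner-take-all on the loadings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InvalidParameterError, InvalidSpecError, ParseError
from .parcel import RepresentationMap

__all__ = [
    "LatentGroundTruth",
    "SyntheticScene",
    "RepresentationScheme",
    "TaskSpec",
    "DEFAULT_ZONES",
    "DEFAULT_CENTERS",
    "arch_zone_spec",
    "arch_network_centers",
    "DEFAULT_SCHEME",
    "DEFAULT_TASKS",
    "make_latent_map",
    "synth_timeseries",
    "synth_labels",
    "make_scene",
    "save_scene",
    "load_scene",
]

def arch_zone_spec(
    apex: float = 0.55,
    curvature: float = 1.35,
    half_thickness: float = 0.18,
    step: float = 0.1,
    g1_min: float = -0.95,
    g1_max: float = 0.95,
    boundary_density: float = 0.3,
) -> list[tuple]:
    """Zone boxes tiling an arch-shaped band in latent space.

    The band follows ``g2 = apex - curvature * g1^2`` with vertical half
    thickness ``half_thickness``, approximated by stair-step boxes of width
    ``step``; at the apex (|g1| <= 0.25) the band widens into a radially deep
    blob of stacked boxes.  This reproduces the canonical shape of the
    empirical gradient-1 x gradient-2 scatter: motor voxels at low G1/low G2
    on the left arm, task-unfocused (DMN/language-like) voxels at high G1/low
    G2 on the right arm, and task-focused (working-memory-like) voxels at the
    mid-G1/high-G2 apex — with no voxels at the joint G1+G2 maximum.  The
    deep apex blob gives the concentric representation bands enough radial
    width that adjacent bands stay separable after embedding.  Boxes in the
    rising bridge segments get ``boundary_density`` relative weight, giving
    three dense clumps joined by thinner bridges (cluster structure without
    disconnecting the band).
    """
    boxes = []
    for xl in np.arange(g1_min, g1_max - 1e-9, step):
        xr = xl + step
        xm = xl + step / 2.0
        if abs(xm) <= 0.25:
            continue  # the apex blob replaces the band here
        yc = apex - curvature * xm * xm
        # the rising bridge segments belong to the task-focused zone, so the
        # arm zones stay low on g2 and representation bands separate cleanly
        zone = "motor" if xm < -0.45 else (
            "task-unfocused-nonmotor" if xm > 0.45 else "task-focused-nonmotor"
        )
        weight = boundary_density if abs(xm) <= 0.45 else 1.0
        boxes.append(
            [
                zone,
                weight,
                (xl, xr),
                (max(-1.0, yc - half_thickness), min(1.0, yc + half_thickness)),
            ]
        )
    # apex blob: three stacked boxes, 0.5 wide x 0.65 tall in total; weight
    # proportional to area (relative to a 0.1 x 0.36 arm box) times a 0.75
    # density factor — the blob's horizontal coordinate is only weakly
    # encoded in connectivity, so over-weighting it degrades gradient-1
    # recovery
    blob_w = 0.75 * (0.5 * 0.65 / 3) / (step * 2 * half_thickness)
    for y_lo, y_hi in ((0.30, 0.5167), (0.5167, 0.7333), (0.7333, 0.95)):
        boxes.append(["task-focused-nonmotor", blob_w, (-0.25, 0.25), (y_lo, y_hi)])
    total = sum(b[1] for b in boxes)
    for b in boxes:
        b[1] /= total
    return [tuple(b) for b in boxes]


def arch_network_centers(
    arm_positions=(-0.8, -0.55, 0.55, 0.8),
    blob_positions=((-0.08, 0.45), (0.08, 0.8)),
    apex: float = 0.55,
    curvature: float = 1.35,
) -> list[tuple[float, float]]:
    """Network centers: two per arm along the ridge, two stacked in the apex.

    Two centers inside each zone clump and none inside the sparse boundary
    bridges keep the embedded scatter in exactly three dense clumps (one per
    zone), while the centers still triangulate latent position finely along
    the arms and vertically through the apex blob.
    """
    centers = [(float(x), float(apex - curvature * x * x)) for x in arm_positions]
    centers[2:2] = [(float(x), float(y)) for x, y in blob_positions]
    return centers


# Zone boxes: (zone, fraction, (g1_lo, g1_hi), (g2_lo, g2_hi)); see
# arch_zone_spec for the layout rationale.
DEFAULT_ZONES: list[tuple] = arch_zone_spec()

DEFAULT_CENTERS: list[tuple[float, float]] = arch_network_centers()

DEFAULT_TAU = 0.40
DEFAULT_NOISE_SD = 0.5
DEFAULT_N_VOXELS = 1500
DEFAULT_N_TIMEPOINTS = 1200

ALLOWED_REPRESENTATIONS = ("M1", "M2", "N1", "N2", "N3", "none")


@dataclass
class LatentGroundTruth:
    """Per-voxel latent coordinates, zone labels, and the network layout."""

    voxel_ids: np.ndarray
    latent_g1: np.ndarray
    latent_g2: np.ndarray
    zone_label: np.ndarray
    network_centers: np.ndarray
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids)
        self.latent_g1 = np.asarray(self.latent_g1, dtype=float)
        self.latent_g2 = np.asarray(self.latent_g2, dtype=float)
        self.zone_label = np.asarray(self.zone_label)
        self.network_centers = np.atleast_2d(np.asarray(self.network_centers, dtype=float))
        n = len(self.voxel_ids)
        if not (len(self.latent_g1) == len(self.latent_g2) == len(self.zone_label) == n):
            raise InvalidSpecError("latent fields must share one length")
        if not (np.all(np.isfinite(self.latent_g1)) and np.all(np.isfinite(self.latent_g2))):
            raise InvalidSpecError("latent coordinates must be finite")
        if self.network_centers.shape[0] < 2:
            raise InvalidSpecError("need at least 2 network centers")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.latent_g1, self.latent_g2])


@dataclass(frozen=True)
class RepresentationScheme:
    """How zones map onto representation labels.

    ``assignments[zone]`` is a list of ``(label, fraction, offset)``.  Within a
    zone, voxels are ranked by Euclidean distance from ``center``; labels are
    allocated contiguous rank blocks ordered by ``offset`` (ascending), so the
    label with the smallest offset receives the innermost (least extreme)
    voxels.  Fractions within a zone must sum to 1.
    """

    assignments: dict
    center: tuple[float, float] = (0.0, 0.0)

    def validate(self, zones: set) -> None:
        for zone, reps in self.assignments.items():
            if zone not in zones:
                raise InvalidSpecError(f"scheme references unknown zone {zone!r}")
            if abs(sum(fr for _, fr, _ in reps) - 1.0) > 1e-9:
                raise InvalidSpecError(f"fractions for zone {zone!r} must sum to 1")
            for label, _, _ in reps:
                if label not in ALLOWED_REPRESENTATIONS:
                    raise InvalidSpecError(f"unknown representation label {label!r}")


DEFAULT_SCHEME = RepresentationScheme(
    assignments={
        # double motor: M2 (second representation) innermost by construction
        "motor": [("M2", 0.35, 0.0), ("M1", 0.65, 1.0)],
        # triple nonmotor: N3 (third representation) innermost
        "task-unfocused-nonmotor": [("N3", 0.25, 0.0), ("N2", 0.35, 0.5), ("N1", 0.40, 1.0)],
        "task-focused-nonmotor": [("N3", 0.25, 0.0), ("N2", 0.35, 0.5), ("N1", 0.40, 1.0)],
    }
)


@dataclass(frozen=True)
class TaskSpec:
    """A thresholded noisy linear read-out of the latent coordinates."""

    name: str
    weights: tuple[float, float]
    noise_sd: float = 0.1
    threshold: float = 0.5


DEFAULT_TASKS: list[TaskSpec] = [
    TaskSpec("motor", (-1.0, 0.0)),
    TaskSpec("language", (1.0, 0.0)),
    TaskSpec("working_memory", (0.0, 1.0)),
    TaskSpec("emotion", (0.35, 0.30), noise_sd=0.15),
    TaskSpec("social", (0.25, 0.10), noise_sd=0.30),
]


@dataclass
class SyntheticScene:
    """A complete generated dataset plus its ground truth."""

    latent: LatentGroundTruth
    timeseries: np.ndarray
    representation_map: RepresentationMap
    task_maps: dict
    network_map: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)
    target_latent: LatentGroundTruth | None = None
    target_timeseries: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.latent.n_voxels
        if self.timeseries.shape[0] != n:
            raise InvalidSpecError("timeseries rows must match voxel count")
        if len(self.representation_map.labels) != n:
            raise InvalidSpecError("representation map must cover every voxel")
        bad = set(np.unique(self.representation_map.labels)) - set(ALLOWED_REPRESENTATIONS)
        if bad:
            raise InvalidSpecError(f"representation labels outside allowed set: {bad}")
        for name, mask in self.task_maps.items():
            if np.asarray(mask).shape != (n,):
                raise InvalidSpecError(f"task map {name!r} must be a voxel-length mask")


def make_latent_map(
    n_voxels: int,
    zone_spec: list[tuple] | None = None,
    seed: int = 0,
    network_centers=None,
    tau: float = DEFAULT_TAU,
) -> LatentGroundTruth:
    """Draw per-voxel latent coordinates uniformly within each zone's box.

    ``zone_spec`` entries are ``(zone, fraction, (g1_lo, g1_hi), (g2_lo, g2_hi))``;
    fractions must sum to 1 (±1e-9) and ranges lie within [-1, 1].  Zone sizes
    are fractions rounded to integers summing to ``n_voxels`` (largest-remainder
    apportionment; ties to earlier zones).  Deterministic given ``seed``.
    """
    if zone_spec is None:
        zone_spec = DEFAULT_ZONES
    if not zone_spec:
        raise InvalidSpecError("zone list is empty")
    if n_voxels < 10:
        raise InvalidSpecError(f"n_voxels must be >= 10, got {n_voxels}")
    fractions = np.array([z[1] for z in zone_spec], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise InvalidSpecError(f"zone fractions sum to {fractions.sum()}, expected 1")
    for zone, _, r1, r2 in zone_spec:
        for lo, hi in (r1, r2):
            if not (-1 <= lo <= hi <= 1):
                raise InvalidSpecError(f"zone {zone!r} range ({lo}, {hi}) invalid")

    # largest-remainder apportionment of n_voxels across zones
    raw = fractions * n_voxels
    sizes = np.floor(raw).astype(int)
    remainder = n_voxels - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    sizes[order[:remainder]] += 1

    rng = np.random.default_rng(seed)
    g1, g2, zones = [], [], []
    for (zone, _, (a1, b1), (a2, b2)), size in zip(zone_spec, sizes):
        g1.append(rng.uniform(a1, b1, size))
        g2.append(rng.uniform(a2, b2, size))
        zones.extend([zone] * size)
    centers = DEFAULT_CENTERS if network_centers is None else network_centers
    return LatentGroundTruth(
        voxel_ids=np.arange(n_voxels),
        latent_g1=np.concatenate(g1),
        latent_g2=np.concatenate(g2),
        zone_label=np.array(zones),
        network_centers=np.asarray(centers, dtype=float),
        tau=tau,
    )


def network_loadings(latent: LatentGroundTruth, tau: float | None = None) -> np.ndarray:
    """Gaussian loading of each voxel on each network center: voxels x K."""
    tau = latent.tau if tau is None else tau
    if tau <= 0:
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    d2 = ((latent.coords[:, None, :] - latent.network_centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * tau**2))


def synth_timeseries(
    latent: LatentGroundTruth,
    n_timepoints: int,
    noise_sd: float,
    tau: float | None = None,
    seed: int = 0,
    sources: np.ndarray | None = None,
) -> np.ndarray:
    """Mixture-of-network time series: ``x_v = sum_k w_k(v) s_k + noise``.

    ``s_k`` are independent unit-variance white-noise courses (drawn here, or
    passed via ``sources`` shaped K x T to share them across voxel sets).
    Requires ``n_timepoints >= 2 K``; reproducible given ``seed``.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    k = latent.network_centers.shape[0]
    if n_timepoints < 2 * k:
        raise InvalidParameterError(
            f"n_timepoints must be >= 2 x {k} network centers, got {n_timepoints}"
        )
    w = network_loadings(latent, tau)
    rng = np.random.default_rng(seed)
    s = rng.standard_normal((k, n_timepoints)) if sources is None else np.asarray(sources)
    if s.shape != (k, n_timepoints):
        raise InvalidParameterError(f"sources must be {k} x {n_timepoints}")
    x = w @ s
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.shape)
    return x


def synth_labels(
    latent: LatentGroundTruth,
    scheme: RepresentationScheme | None = None,
    tasks: list[TaskSpec] | None = None,
    seed: int = 0,
) -> tuple[RepresentationMap, dict, np.ndarray]:
    """Representation labels, task masks, and winner-take-all network map.

    Representations: within each zone, voxels are ranked by distance from the
    scheme's latent center and allocated to labels inner-first by the scheme's
    offsets (see :class:`RepresentationScheme`), so e.g. M2 sits nearer the
    center than M1 by construction.  Task masks threshold
    ``w . (g1, g2) + noise`` at each task's threshold.  The network map assigns
    each voxel its maximal-loading center.
    """
    scheme = DEFAULT_SCHEME if scheme is None else scheme
    tasks = DEFAULT_TASKS if tasks is None else tasks
    scheme.validate(set(np.unique(latent.zone_label)))

    labels = np.full(latent.n_voxels, "none", dtype=object)
    cx, cy = scheme.center
    radius = np.hypot(latent.latent_g1 - cx, latent.latent_g2 - cy)
    for zone, reps in scheme.assignments.items():
        idx = np.flatnonzero(latent.zone_label == zone)
        if idx.size == 0:
            continue
        idx = idx[np.argsort(radius[idx], kind="stable")]  # innermost first
        fracs = np.array([fr for _, fr, _ in reps], dtype=float)
        raw = fracs * idx.size
        sizes = np.floor(raw).astype(int)
        extra = np.argsort(-(raw - sizes), kind="stable")[: idx.size - sizes.sum()]
        sizes[extra] += 1
        inner_first = np.argsort([off for _, _, off in reps], kind="stable")
        start = 0
        for j in inner_first:
            label = reps[j][0]
            labels[idx[start : start + sizes[j]]] = label
            start += sizes[j]
    rep_map = RepresentationMap(
        labels=labels.astype(str),
        voxel_ids=latent.voxel_ids.copy(),
        provenance="synthetic radial-rank scheme",
    )

    rng = np.random.default_rng(seed)
    task_maps = {}
    for t in tasks:
        readout = t.weights[0] * latent.latent_g1 + t.weights[1] * latent.latent_g2
        if t.noise_sd > 0:
            readout = readout + rng.normal(0.0, t.noise_sd, latent.n_voxels)
        task_maps[t.name] = readout >= t.threshold

    w = network_loadings(latent)
    network_map = w.argmax(axis=1)
    return rep_map, task_maps, network_map


def make_scene(
    n_voxels: int = DEFAULT_N_VOXELS,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    noise_sd: float = DEFAULT_NOISE_SD,
    tau: float = DEFAULT_TAU,
    seed: int = 0,
    zone_spec: list[tuple] | None = None,
    network_centers=None,
    scheme: RepresentationScheme | None = None,
    tasks: list[TaskSpec] | None = None,
    n_targets: int = 0,
    target_noise_sd: float | None = None,
) -> SyntheticScene:
    """Generate a full scene; the one-stop entry point for tests and pipelines.

    With ``n_targets > 0`` a second ("cortical target") voxel set is generated
    sharing the same network source signals, enabling rectangular
    set-to-target connectomes.  Target latent coordinates are drawn from
    isotropic Gaussian blobs (sd ``tau``) around the network centers.
    """
    ss = np.random.SeedSequence(seed)
    s_latent, s_ts, s_labels, s_tgt = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))
    latent = make_latent_map(n_voxels, zone_spec, seed=s_latent, network_centers=network_centers, tau=tau)
    k = latent.network_centers.shape[0]
    rng_src = np.random.default_rng(s_ts)
    sources = rng_src.standard_normal((k, n_timepoints))
    ts = synth_timeseries(latent, n_timepoints, noise_sd, seed=s_ts + 1, sources=sources)
    rep_map, task_maps, network_map = synth_labels(latent, scheme, tasks, seed=s_labels)
    params = {
        "n_voxels": n_voxels,
        "n_timepoints": n_timepoints,
        "noise_sd": noise_sd,
        "tau": tau,
        "seed": seed,
        "n_targets": n_targets,
    }
    target_latent = target_ts = None
    if n_targets:
        rng_t = np.random.default_rng(s_tgt)
        centers = latent.network_centers
        which = rng_t.integers(0, k, n_targets)
        coords = centers[which] + rng_t.normal(0.0, tau, (n_targets, 2))
        target_latent = LatentGroundTruth(
            voxel_ids=np.arange(n_targets),
            latent_g1=coords[:, 0],
            latent_g2=coords[:, 1],
            zone_label=np.array([f"target-net{j}" for j in which]),
            network_centers=centers.copy(),
            tau=tau,
        )
        t_noise = noise_sd if target_noise_sd is None else target_noise_sd
        target_ts = synth_timeseries(
            target_latent, n_timepoints, t_noise, seed=s_tgt + 1, sources=sources
        )
    return SyntheticScene(
        latent=latent,
        timeseries=ts,
        representation_map=rep_map,
        task_maps=task_maps,
        network_map=network_map,
        seed=seed,
        params=params,
        target_latent=target_latent,
        target_timeseries=target_ts,
    )


# ---------------------------------------------------------------------------
# Scene I/O: delimited tables + binary time series + JSON sidecar


def save_scene(scene: SyntheticScene, outdir) -> Path:
    """Write a scene as text tables, a float64 time-series blob, and a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lat = scene.latent
    header = ["voxel_id", "latent_g1", "latent_g2", "zone", "representation", "network"]
    with open(outdir / "voxels.tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i in range(lat.n_voxels):
            fh.write(
                f"{lat.voxel_ids[i]}\t{lat.latent_g1[i]:.17g}\t{lat.latent_g2[i]:.17g}"
                f"\t{lat.zone_label[i]}\t{scene.representation_map.labels[i]}"
                f"\t{scene.network_map[i]}\n"
            )
    scene.timeseries.astype("<f8").tofile(outdir / "timeseries.bin")
    sidecar = {
        "format": "conngrad-scene",
        "version": 1,
        "params": scene.params,
        "seed": scene.seed,
        "tau": lat.tau,
        "network_centers": lat.network_centers.tolist(),
        "timeseries_shape": list(scene.timeseries.shape),
        "task_maps": {k: np.flatnonzero(v).tolist() for k, v in scene.task_maps.items()},
    }
    (outdir / "scene.json").write_text(json.dumps(sidecar, indent=1))
    return outdir


def load_scene(indir) -> SyntheticScene:
    """Read a scene written by :func:`save_scene` (targets are not persisted)."""
    indir = Path(indir)
    sidecar_path = indir / "scene.json"
    if not sidecar_path.exists():
        raise ParseError(f"missing {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("format") != "conngrad-scene":
        raise ParseError(f"{sidecar_path}: not a conngrad scene sidecar")
    rows = (indir / "voxels.tsv").read_text().strip().split("\n")
    body = [r.split("\t") for r in rows[1:]]
    n = len(body)
    latent = LatentGroundTruth(
        voxel_ids=np.array([int(r[0]) for r in body]),
        latent_g1=np.array([float(r[1]) for r in body]),
        latent_g2=np.array([float(r[2]) for r in body]),
        zone_label=np.array([r[3] for r in body]),
        network_centers=np.asarray(meta["network_centers"], dtype=float),
        tau=meta["tau"],
    )
    shape = tuple(meta["timeseries_shape"])
    ts = np.fromfile(indir / "timeseries.bin", dtype="<f8")
    if ts.size != shape[0] * shape[1]:
        raise ParseError(f"timeseries.bin holds {ts.size} values, expected {shape[0] * shape[1]}")
    task_maps = {}
    for name, idx in meta["task_maps"].items():
        m = np.zeros(n, dtype=bool)
        m[np.asarray(idx, dtype=int)] = True
        task_maps[name] = m
    return SyntheticScene(
        latent=latent,
        timeseries=ts.reshape(shape),
        representation_map=RepresentationMap(
            labels=np.array([r[4] for r in body]),
            voxel_ids=latent.voxel_ids.copy(),
            provenance="loaded scene",
        ),
        task_maps=task_maps,
        network_map=np.array([int(r[5]) for r in body]),
        seed=meta["seed"],
        params=meta["params"],
    )
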