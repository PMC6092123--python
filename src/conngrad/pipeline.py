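"""Configuration-driven orchestration of the full gradient analysis.

``run_pipeline`` executes the stages in method order — scene (synthetic or
loaded) → connectome → embedding (intra-set and, when targets exist,
set-to-target) → parcellation → clustering → seed contrast — writing every
intermediate artifact, a line-delimited structured log, and a manifest whose
parameter fingerprint changes iff a semantically meaningful parameter changes.
Reruns with the same config are bit-reproducible: every stochastic stage
derives its seed from the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cluster as _cluster
from . import connectome as _connectome
from . import contrast as _contrast
from . import embed as _embed
from . import parcel as _parcel
from . import synth as _synth
from .exceptions import ConngradError, InvalidSpecError

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("scene", "connectome", "embed", "parcel", "cluster", "contrast")


@dataclass
class RunConfig:
    """All knobs of the pipeline; every seed explicit, no hidden entropy.

    ``scene`` holds keyword arguments for :func:`conngrad.synth.make_scene`
    (ignored when ``scene_dir`` points at a saved scene).  Stage toggles allow
    a run to stop after any stage; later stages are skipped and marked so in
    the manifest.
    """

    outdir: str = "conngrad-run"
    seed: int = 0
    scene: dict = field(default_factory=dict)
    scene_dir: str | None = None
    # stage toggles
    do_embed: bool = True
    do_parcel: bool = True
    do_cluster: bool = True
    do_contrast: bool = True
    # embedding
    sparsify_pct: float = 10.0
    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 8
    match_to_latent: bool = True
    # parcellation
    extract_pct: float = 5.0
    sweep_pcts: tuple = _parcel.DEFAULT_SWEEP_PCTS
    n_boot: int = 1000
    # clustering
    k_min: int = 2
    k_max: int = 8
    cluster_method: str = "kmeans"
    cluster_components: tuple = (1, 2)
    n_init: int = 50
    # contrast
    q: float = 0.05

    def validate(self) -> None:
        if not 0 < self.sparsify_pct <= 100:
            raise InvalidSpecError("sparsify_pct outside (0, 100]")
        if not 0 <= self.alpha <= 1:
            raise InvalidSpecError("alpha outside [0, 1]")
        if self.n_components < 1:
            raise InvalidSpecError("n_components must be >= 1")
        if not 0 < self.extract_pct <= 100:
            raise InvalidSpecError("extract_pct outside (0, 100]")
        if any(not 0 < p <= 100 for p in self.sweep_pcts):
            raise InvalidSpecError("sweep_pcts outside (0, 100]")
        if not 2 <= self.k_min <= self.k_max:
            raise InvalidSpecError("need 2 <= k_min <= k_max")
        if self.cluster_method not in ("kmeans", "spectral"):
            raise InvalidSpecError(f"unknown cluster_method {self.cluster_method!r}")
        if not 0 < self.q < 1:
            raise InvalidSpecError("q outside (0, 1)")
        if self.n_boot < 100:
            raise InvalidSpecError("n_boot must be >= 100")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a config from JSON or YAML."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("sweep_pcts", "cluster_components"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def fingerprint(self) -> str:
        """sha256 over every semantically meaningful parameter (not outdir)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.records: list[dict] = []

    def emit(self, stage: str, event: str, **extra) -> None:
        rec = {"t": round(time.time(), 3), "stage": stage, "event": event, **extra}
        self.records.append(rec)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def _stage_scene(cfg: RunConfig, out: Path, log: _Log):
    if cfg.scene_dir:
        scene = _synth.load_scene(cfg.scene_dir)
        log.emit("scene", "loaded", source=str(cfg.scene_dir))
    else:
        kwargs = dict(cfg.scene)
        kwargs.setdefault("seed", cfg.seed)
        scene = _synth.make_scene(**kwargs)
        log.emit("scene", "generated", **{k: v for k, v in scene.params.items()})
    _synth.save_scene(scene, out / "scene")
    return scene


def _latent_reference(scene) -> _embed.GradientSet:
    return _embed.GradientSet(
        np.column_stack([scene.latent.latent_g1, scene.latent.latent_g2]),
        np.array([1.0, 1.0]),
        scene.latent.voxel_ids,
        params={"source": "latent ground truth"},
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute all enabled stages; returns the artifact directory.

    Any stage error is re-raised annotated with the stage name; artifacts of
    completed stages are retained.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "log.jsonl")
    manifest: dict = {
        "fingerprint": config.fingerprint(),
        "config": dataclasses.asdict(config),
        "stages": {},
        "artifacts": {},
    }
    stage = "scene"
    try:
        scene = _stage_scene(config, out, log)
        manifest["stages"]["scene"] = "completed"
        manifest["artifacts"]["scene"] = "scene/"

        stage = "connectome"
        ts = _connectome.TimeseriesMatrix(scene.timeseries, scene.latent.voxel_ids)
        conn = _connectome.correlation_connectome(ts)
        _connectome.save_connectivity(conn, out / "connectome.bin", binary=True)
        manifest["stages"]["connectome"] = "completed"
        manifest["artifacts"]["connectome"] = "connectome.bin"
        log.emit("connectome", "computed", shape=list(conn.shape))
        rect = None
        if scene.target_timeseries is not None:
            tts = _connectome.TimeseriesMatrix(
                scene.target_timeseries, scene.target_latent.voxel_ids
            )
            rect = _connectome.correlation_connectome(ts, tts)
            _connectome.save_connectivity(rect, out / "connectome_targets.bin", binary=True)
            manifest["artifacts"]["connectome_targets"] = "connectome_targets.bin"
            log.emit("connectome", "computed set-to-target", shape=list(rect.shape))

        gradients = None
        if config.do_embed:
            stage = "embed"
            aff = _embed.cosine_affinity(_embed.sparsify_rows(conn, config.sparsify_pct))
            gradients = _embed.diffusion_map(
                aff, config.n_components, config.alpha, config.diffusion_time
            )
            if config.match_to_latent:
                gradients = _embed.match_gradients(gradients, _latent_reference(scene), 2)
            else:
                motor = np.isin(scene.representation_map.labels, _parcel.MOTOR_LABELS)
                if motor.any():
                    gradients = _embed.orient_gradients(gradients, motor)
            _embed.save_gradients(gradients, out / "gradients")
            manifest["stages"]["embed"] = "completed"
            manifest["artifacts"]["gradients"] = "gradients.tsv"
            log.emit(
                "embed",
                "computed",
                eigenvalues=gradients.eigenvalues.tolist(),
                variance_explained=_embed.variance_explained(gradients).tolist(),
            )
            if rect is not None:
                aff_t = _embed.cosine_affinity(
                    _embed.sparsify_rows(rect, config.sparsify_pct)
                )
                g_t = _embed.diffusion_map(
                    aff_t, config.n_components, config.alpha, config.diffusion_time
                )
                g_t = _embed.match_gradients(g_t, gradients, 2)
                _embed.save_gradients(g_t, out / "gradients_settotarget")
                manifest["artifacts"]["gradients_settotarget"] = "gradients_settotarget.tsv"
        else:
            manifest["stages"]["embed"] = "skipped"

        if config.do_parcel and gradients is not None:
            stage = "parcel"
            rep = scene.representation_map
            parc = _parcel.gradient_parcellation(gradients, rep, config.extract_pct)
            sweep = {}
            for pct in config.sweep_pcts:
                p = _parcel.gradient_parcellation(gradients, rep, pct)
                sweep[pct] = {
                    name: int(getattr(p, name).sum())
                    for name in ("high_g1", "high_g2", "low_g1")
                }
            summary = _parcel.position_summary(
                gradients,
                {
                    "high_g1": parc.high_g1,
                    "high_g2": parc.high_g2,
                    "low_g1": parc.low_g1,
                    **{m: rep.mask(m) for m in np.unique(rep.labels) if m != "none"},
                },
                n_boot=config.n_boot,
                seed=config.seed,
            )
            summary.to_csv(out / "position_summary.tsv", sep="\t", index=False)
            verdicts = {}
            lg = parc.per_representation["low_g1"]
            hg1 = parc.per_representation["high_g1"]
            hg2 = parc.per_representation["high_g2"]
            g1v, g2v = gradients.gradient(1), gradients.gradient(2)
            if {"M1", "M2"} <= set(lg):
                verdicts["M2_vs_M1_lowG1_on_g2"] = _parcel.less_extreme_test(
                    g2v, lg["M2"], lg["M1"], n_boot=config.n_boot, seed=config.seed
                ).verdict
            if {"N1", "N2", "N3"} <= set(hg1):
                verdicts["N3_vs_N1N2_highG1_on_g1"] = _parcel.less_extreme_test(
                    g1v, hg1["N3"], hg1["N1"] | hg1["N2"],
                    n_boot=config.n_boot, seed=config.seed,
                ).verdict
            if {"N1", "N2", "N3"} <= set(hg2):
                verdicts["N3_vs_N1_highG2_on_g2"] = _parcel.less_extreme_test(
                    g2v, hg2["N3"], hg2["N1"], n_boot=config.n_boot, seed=config.seed
                ).verdict
                verdicts["N3_vs_N2_highG2_on_g2"] = _parcel.less_extreme_test(
                    g2v, hg2["N3"], hg2["N2"], n_boot=config.n_boot, seed=config.seed
                ).verdict
            (out / "parcellation.json").write_text(
                json.dumps(
                    {
                        "threshold_pct": config.extract_pct,
                        "mask_sizes": {
                            name: int(getattr(parc, name).sum())
                            for name in ("high_g1", "high_g2", "low_g1")
                        },
                        "sweep_sizes": sweep,
                        "less_extreme_verdicts": verdicts,
                        "extremeness": "median |v - structure median|, voxel bootstrap",
                    },
                    indent=1,
                )
            )
            manifest["stages"]["parcel"] = "completed"
            manifest["artifacts"]["parcellation"] = "parcellation.json"
            log.emit("parcel", "computed", verdicts=verdicts)
        else:
            manifest["stages"]["parcel"] = "skipped"

        if config.do_cluster and gradients is not None:
            stage = "cluster"
            feats = _cluster.normalize_gradients(gradients, config.cluster_components)
            kwargs = {"n_init": config.n_init} if config.cluster_method == "kmeans" else {}
            best = _cluster.silhouette_select(
                feats,
                range(config.k_min, config.k_max + 1),
                method=config.cluster_method,
                seed=config.seed,
                **kwargs,
            )
            with open(out / "cluster_labels.tsv", "w") as fh:
                fh.write("voxel_id\tcluster\n")
                for vid, lab in zip(scene.latent.voxel_ids, best.labels):
                    fh.write(f"{vid}\t{lab}\n")
            best.per_k_scores.to_csv(out / "silhouette_per_k.tsv", sep="\t", index=False)
            (out / "cluster.json").write_text(
                json.dumps(
                    {
                        "k": best.k,
                        "method": best.method,
                        "components": list(config.cluster_components),
                        "silhouette_mean": best.silhouette_mean,
                        "weak": best.weak,
                        "params": {k: v for k, v in best.params.items()},
                    },
                    indent=1,
                )
            )
            manifest["stages"]["cluster"] = "completed"
            manifest["artifacts"]["cluster"] = "cluster_labels.tsv"
            log.emit("cluster", "selected", k=best.k, silhouette=best.silhouette_mean)
        else:
            manifest["stages"]["cluster"] = "skipped"

        if config.do_contrast and gradients is not None:
            stage = "contrast"
            rep = scene.representation_map
            g1v = gradients.gradient(1)
            seed_a = _contrast.gradient_peak(g1v, rep.mask("M1"), "low")
            seed_b = _contrast.gradient_peak(g1v, rep.mask("N1"), "high")
            rows = rect.values if rect is not None else conn.values
            n_eff = scene.timeseries.shape[1]
            if rect is not None:
                row_a, row_b = rows[seed_a], rows[seed_b]
            else:
                keep = np.ones(rows.shape[1], dtype=bool)
                keep[[seed_a, seed_b]] = False
                row_a, row_b = rows[seed_a][keep], rows[seed_b][keep]
            r_ab = float(conn.values[seed_a, seed_b])
            tids = (
                scene.target_latent.voxel_ids
                if rect is not None
                else scene.latent.voxel_ids[keep]
            )
            result = _contrast.seed_contrast(
                np.clip(row_a, -0.999999, 0.999999),
                np.clip(row_b, -0.999999, 0.999999),
                r_ab,
                n_eff,
                config.q,
                target_ids=tids,
            )
            result.table.to_csv(out / "contrast.tsv", sep="\t", index=False)
            (out / "contrast.json").write_text(
                json.dumps(
                    {
                        "seed_a_voxel": int(seed_a),
                        "seed_b_voxel": int(seed_b),
                        "r_ab": result.r_ab,
                        "n": result.n,
                        "q": result.q,
                        "rejection_threshold": result.rejection_threshold,
                        "n_rejected": int(result.rejected.sum()),
                    },
                    indent=1,
                )
            )
            manifest["stages"]["contrast"] = "completed"
            manifest["artifacts"]["contrast"] = "contrast.tsv"
            log.emit("contrast", "computed", n_rejected=int(result.rejected.sum()))
        else:
            manifest["stages"]["contrast"] = "skipped"
    except ConngradError as err:
        log.emit(stage, "error", error=type(err).__name__, message=str(err))
        manifest["stages"][stage] = "failed"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise ConngradError(f"stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
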