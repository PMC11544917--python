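"""One-command orchestration: simulate -> preprocess -> cluster -> evaluate.

A single YAML config drives every stage; artifacts land in a directory with
a manifest recording the config hash, the seeds each stage consumed, and the
package version, so a rerun with an unchanged config can skip completed
stages and reproduce outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .evaluation import DEFAULT_ALGORITHMS, render_report, run_benchmark
from .exceptions import ConfigurationError
from .clustering import fit_cluster_model
from .preprocessing import (
    NH_MIN_RUN,
    NH_THRESHOLD,
    preprocess_records,
    read_long_csv,
    read_segments_csv,
    write_segments_csv,
)
from .synthetic import ArchetypeSpec, CohortConfig, generate_cohort, write_cohort_csv

log = logging.getLogger("glucluster")


@dataclass
class PipelineConfig:
    """Validated settings for a full pipeline run."""

    n_patients: int = 240
    archetypes: list | None = None  # list of ArchetypeSpec kwargs dicts, or None for defaults
    archetype_mix: list | None = None
    noise_phi: float = 0.8
    noise_sigma: float = 0.3
    offset_sigma: float = 0.5
    gap_rate_single: float = 0.01
    gap_rate_long: float = 0.05
    nh_threshold: float = NH_THRESHOLD
    nh_min_run: int = NH_MIN_RUN
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    k: int | None = None
    k_range: tuple[int, int] = (2, 10)
    stability_reps: int = 0
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    horizons_min: tuple[int, ...] = (15, 30)
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        bad = sorted(set(raw) - known)
        if bad:
            raise ConfigurationError(f"unknown config keys: {bad}")
        cfg = cls(**raw)
        errors = []
        if cfg.n_patients <= 0:
            errors.append("n_patients must be positive")
        if abs(sum(cfg.split) - 1.0) > 1e-9 or any(r < 0 for r in cfg.split):
            errors.append("split must be three nonnegative ratios summing to 1")
        if any(m <= 0 or m % 5 for m in cfg.horizons_min):
            errors.append("horizons_min must be positive multiples of 5")
        unknown_algos = set(cfg.algorithms) - {
            "mtsc", "wmtsc", "holt", "rf_global", "gbt_global", "rf_cluster", "gbt_cluster"
        }
        if unknown_algos:
            errors.append(f"unknown algorithms: {sorted(unknown_algos)}")
        if errors:
            raise ConfigurationError("; ".join(errors))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(
            n_patients=self.n_patients,
            archetype_mix=self.archetype_mix,
            noise_phi=self.noise_phi,
            noise_sigma=self.noise_sigma,
            offset_sigma=self.offset_sigma,
            gap_rate_single=self.gap_rate_single,
            gap_rate_long=self.gap_rate_long,
            seed=self.seed,
        )
        if self.archetypes is not None:
            kwargs["archetypes"] = [ArchetypeSpec(**a) for a in self.archetypes]
        return CohortConfig(**kwargs)

    def content_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def default_demo_config() -> PipelineConfig:
    """The shipped demo profile: a six-pattern cohort small enough to run in
    a couple of minutes on one CPU."""
    return PipelineConfig(
        n_patients=240,
        hyperparams={
            "random_forest": {"n_estimators": 150},
            "gradient_boosting": {"n_estimators": 150},
        },
        seed=1,
    )


def run_pipeline(config: PipelineConfig, outdir, force: bool = False) -> Path:
    """Execute all stages, skipping those whose artifacts are up to date.

    Stage outputs: cohort.csv + archetype_labels.csv (simulate), segments.csv
    (preprocess), cluster_<group>.json/.csv (cluster), benchmark.csv +
    per_step_mae.csv + report.txt (evaluate), and manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.content_hash()
    manifest_path = outdir / "manifest.json"
    manifest = {"config_hash": cfg_hash, "version": __version__, "stages": {}}
    previous = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == cfg_hash and not force:
            previous = old.get("stages", {})

    def fresh(name: str, outputs: list[Path]) -> bool:
        return name in previous and all(p.exists() for p in outputs)

    def done(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
        log.info("stage %s done (%.1fs) %s", name, time.time() - t0, info)

    cohort_csv = outdir / "cohort.csv"
    labels_csv = outdir / "archetype_labels.csv"
    t0 = time.time()
    if fresh("simulate", [cohort_csv, labels_csv]):
        manifest["stages"]["simulate"] = previous["simulate"]
    else:
        cohort = generate_cohort(config.cohort_config())
        write_cohort_csv(cohort, cohort_csv, labels_csv)
        done("simulate", t0, n_patients=config.n_patients, seed=config.seed)

    segments_csv = outdir / "segments.csv"
    t0 = time.time()
    if fresh("preprocess", [segments_csv]):
        manifest["stages"]["preprocess"] = previous["preprocess"]
    else:
        records = read_long_csv(cohort_csv)
        segset, summary = preprocess_records(
            records,
            nh_threshold=config.nh_threshold,
            nh_min_run=config.nh_min_run,
            ratios=config.split,
            seed=config.seed,
        )
        write_segments_csv(segset, segments_csv)
        done(
            "preprocess", t0,
            candidates=summary.n_candidates, kept=summary.n_kept,
            rejected=summary.rejected, seed=config.seed,
        )

    segset = read_segments_csv(segments_csv)
    groups = segset.by_nh_group()

    cluster_outputs = [
        p for g in groups for p in
        (outdir / f"cluster_{g}.json", outdir / f"cluster_{g}_medoids.csv")
    ]
    t0 = time.time()
    if fresh("cluster", cluster_outputs):
        manifest["stages"]["cluster"] = previous["cluster"]
    else:
        info = {}
        for group, gset in sorted(groups.items()):
            model = fit_cluster_model(
                gset.matrix("train"),
                k=config.k,
                k_range=config.k_range,
                stability_reps=config.stability_reps,
                seed=config.seed,
            )
            model.save(outdir / f"cluster_{group}.json",
                       outdir / f"cluster_{group}_medoids.csv")
            info[group] = {"k": model.k, "silhouette": model.silhouette}
        done("cluster", t0, seed=config.seed, **info)

    benchmark_csv = outdir / "benchmark.csv"
    per_step_csv = outdir / "per_step_mae.csv"
    report_txt = outdir / "report.txt"
    t0 = time.time()
    if fresh("evaluate", [benchmark_csv, per_step_csv, report_txt]):
        manifest["stages"]["evaluate"] = previous["evaluate"]
    else:
        result = run_benchmark(
            groups,
            algorithms=tuple(config.algorithms),
            horizons_min=tuple(config.horizons_min),
            seed=config.seed,
            k=config.k,
            k_range=config.k_range,
            hyperparams=config.hyperparams,
            stability_reps=config.stability_reps,
        )
        result.to_csv(benchmark_csv, per_step_csv)
        report_txt.write_text(render_report(result.table))
        done("evaluate", t0, seed=config.seed, rows=len(result.table))

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
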