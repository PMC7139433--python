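"""End-to-end orchestration: simulate -> extract -> select -> evaluate -> ratings.

A single :class:`RunConfig` (round-trippable through YAML) drives the run;
every stage derives its own seed deterministically from the global seed, so
a repeated run with the same configuration reproduces every output file
byte for byte.  The run ends with a manifest declaring each output file and
its SHA-256 digest (the manifest itself is timestamp-free; wall-clock times
go to the run log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .evaluation import CVConfig, repeated_cv
from .features import assemble_feature_sets
from .io import (
    feature_set_stem,
    iter_saved_epochs,
    load_feature_dir,
    load_feature_matrix,
    load_model,
    load_ratings,
    save_epochs,
    save_feature_matrix,
    save_model,
    save_ratings,
)
from .lasso import LassoLogisticRegression, loso_select_lambda
from .ratings import compare_groups
from .simulate import CohortSpec, EffectSpec, generate_ratings, iter_epochs

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "extract", "select", "evaluate", "ratings")


@dataclass(frozen=True)
class SelectConfig:
    n_lambdas: int = 100
    lam_min_ratio: float = 1e-4
    min_nonzero: int = 2
    rule: str = "min"


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    effect: EffectSpec = field(default_factory=EffectSpec)
    select: SelectConfig = field(default_factory=SelectConfig)
    k: int = 16
    reps: int = 1000
    m_hypotheses: int = 6
    simultaneous_level: float = 0.95
    nested: bool = False
    n_pictures_per_category: int = 60
    n_incomplete_patients: int = 2
    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        d["effect"] = dataclasses.asdict(self.effect)
        d["effect"]["affected_channels"] = list(self.effect.affected_channels)
        if self.effect.affected_categories is not None:
            d["effect"]["affected_categories"] = list(self.effect.affected_categories)
        d["select"] = dataclasses.asdict(self.select)
        d["stages"] = list(self.stages)
        d["cohort"]["epoch_window_ms"] = list(self.cohort.epoch_window_ms)
        d["cohort"]["trials_per_category"] = list(self.cohort.trials_per_category)
        d["cohort"]["categories"] = list(self.cohort.categories)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = dict(d.pop("cohort", {}))
        for key in ("epoch_window_ms", "trials_per_category", "categories"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        effect = dict(d.pop("effect", {}))
        if "affected_channels" in effect:
            effect["affected_channels"] = tuple(effect["affected_channels"])
        if effect.get("affected_categories") is not None:
            effect["affected_categories"] = tuple(effect["affected_categories"])
        if isinstance(effect.get("band_power_ratio"), dict):
            effect["band_power_ratio"] = dict(effect["band_power_ratio"])
        select = dict(d.pop("select", {}))
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(
            cohort=CohortSpec(**cohort),
            effect=EffectSpec(**effect),
            select=SelectConfig(**select),
            **d,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_simulate(config: RunConfig, out: Path) -> list[Path]:
    files = save_epochs(
        iter_epochs(config.cohort, config.effect, stage_seed(config.seed, "simulate")),
        out / "epochs",
    )
    table = generate_ratings(
        config.cohort,
        config.effect,
        n_pictures_per_category=config.n_pictures_per_category,
        seed=stage_seed(config.seed, "ratings_sim"),
        n_incomplete_patients=config.n_incomplete_patients,
    )
    files.append(save_ratings(table, out / "ratings.csv"))
    return files


def run_extract(config: RunConfig, out: Path) -> list[Path]:
    feature_sets = assemble_feature_sets(iter_saved_epochs(out / "epochs"))
    files = []
    for fm in feature_sets.values():
        files += save_feature_matrix(fm, out / "features")
    return files


def run_select(config: RunConfig, out: Path) -> list[Path]:
    files = []
    for (category, ftype), fm in sorted(load_feature_dir(out / "features").items()):
        selection = loso_select_lambda(
            fm.values,
            fm.y,
            n_lambdas=config.select.n_lambdas,
            lam_min_ratio=config.select.lam_min_ratio,
            min_nonzero=config.select.min_nonzero,
            rule=config.select.rule,
        )
        model = LassoLogisticRegression(lam=selection.chosen_lam).fit(fm.values, fm.y)
        stem = feature_set_stem(category, ftype)
        model_dir = out / "models"
        model_dir.mkdir(parents=True, exist_ok=True)
        files.append(
            save_model(
                model,
                model_dir / f"{stem}.model.json",
                extra={"category": category, "feature_type": ftype},
            )
        )
        sel_path = model_dir / f"{stem}.selection.json"
        sel_path.write_text(
            json.dumps(
                {
                    "chosen_lam": selection.chosen_lam,
                    "chosen_index": selection.chosen_index,
                    "constraint_active": selection.constraint_active,
                    "nonzero_count": int(selection.nonzero_counts[selection.chosen_index]),
                    "cv_deviance_min": float(selection.cv_deviance[selection.chosen_index]),
                    "rule": selection.rule,
                },
                sort_keys=True,
                indent=1,
            )
            + "\n"
        )
        files.append(sel_path)
    return files


def run_evaluate(config: RunConfig, out: Path) -> list[Path]:
    results_dir = out / "results"
    results_dir.mkdir(parents=True, exist_ok=True)
    summary = {}
    rep_rows = []
    seed = stage_seed(config.seed, "evaluate")
    for (category, ftype), fm in sorted(load_feature_dir(out / "features").items()):
        stem = feature_set_stem(category, ftype)
        model_payload = json.loads((out / "models" / f"{stem}.model.json").read_text())
        cv = CVConfig(
            k=config.k,
            reps=config.reps,
            lam=model_payload["lam"],
            seed=seed,
            m_hypotheses=config.m_hypotheses,
            simultaneous_level=config.simultaneous_level,
            nested=config.nested,
        )
        dist = repeated_cv(fm.values, fm.y, cv)
        summary[stem] = {
            "category": category,
            "feature_type": ftype,
            "lam": model_payload["lam"],
            "individual_level": dist.individual_level,
            "reps": config.reps,
            "k": config.k,
            "seed": seed,
            **dist.as_summary(),
        }
        for r in range(config.reps):
            rep_rows.append(
                {
                    "feature_set": stem,
                    "category": category,
                    "feature_type": ftype,
                    "rep": r,
                    "accuracy": dist.accuracy[r],
                    "sensitivity": dist.sensitivity[r],
                    "specificity": dist.specificity[r],
                }
            )
    summary_path = results_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, sort_keys=True, indent=1) + "\n")
    reps_path = results_dir / "metrics_reps.csv"
    pd.DataFrame(rep_rows).to_csv(reps_path, index=False, float_format="%.10g")
    return [summary_path, reps_path]


def run_ratings(config: RunConfig, out: Path) -> list[Path]:
    table = load_ratings(out / "ratings.csv")
    report = compare_groups(table)
    path = out / "ratings_tests.csv"
    with open(path, "w") as fh:
        fh.write("# two-sided Wilcoxon rank-sum on per-picture medians; "
                 "p-values are raw (no multiplicity correction)\n")
        report.to_csv(fh, index=False, float_format="%.10g")
    return [path]


_STAGE_FUNCS = {
    "simulate": run_simulate,
    "extract": run_extract,
    "select": run_select,
    "evaluate": run_evaluate,
    "ratings": run_ratings,
}


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the run manifest.

    Logs go to the console and to ``<out>/run.log``; the log (which carries
    wall-clock timestamps) is deliberately kept out of the manifest so the
    declared outputs stay byte-identical across reruns.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    files: list[Path] = []
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            logger.info("stage %s starting", stage)
            try:
                files += _STAGE_FUNCS[stage](config, out)
            except Exception as exc:
                logger.error("stage %s failed: %s", stage, exc)
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            logger.info("stage %s done", stage)
    finally:
        logger.removeHandler(handler)
        handler.close()
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(files))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest


def load_real_features(path) -> dict[tuple[str, str], "object"]:
    """Entry point for user-supplied data: feature CSVs or FIF epoch files.

    A directory of feature CSVs (with JSON sidecars) is loaded and
    validated; a directory containing ``*-epo.fif`` files is read through
    MNE and featurized with the standard pipeline.
    """
    path = Path(path)
    fifs = sorted(path.glob("*-epo.fif"))
    if fifs:
        from .io import epochs_from_fif

        return assemble_feature_sets(epochs_from_fif(f) for f in fifs)
    if path.is_file():
        fm = load_feature_matrix(path)
        return {(fm.category, fm.feature_type): fm}
    return load_feature_dir(path)
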