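"""End-to-end pipeline: config in, report bundle out.

A single YAML config drives either a fully synthetic run (the default) or a
run on existing TSV inputs.  Outputs are plain-text report tables mirroring
the screen's result structure (differential tables, tier table, correlation
tables, Newick tree, maturity trend, sulcal measurements) plus a JSON run
manifest recording the seed, thresholds, package versions and per-stage
record counts.  Identical config + seed reproduces byte-identical outputs;
a failing stage aborts with a stage-named error and removes partial
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as sio
from .groupstats import diff_results_frame
from .model import SerumBiomarkerModel
from .quantify import maturity_trend
from .simulate import (
    CohortConfig,
    generate_annotation,
    generate_brain_image,
    generate_cohort,
    generate_reads,
)
from .sulcal import compare_groups, sulcal_fraction

log = logging.getLogger("seromir")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_THRESHOLDS = {
    "min_subjects": 5,
    "seq_alpha": 0.05,
    "array_alpha": 0.10,
    "fdr_threshold": 0.05,
}

DEFAULT_READS = {"n_precursors": 50, "mature_fraction": 0.9, "n_reads": 20000}

DEFAULT_IMAGES = {
    "height": 64,
    "width": 64,
    "base_fraction": 0.15,
    "case_ratio": 1.16,
    "subject_sd": 0.015,
    "noise_sd": 6.0,
}


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 42
    thresholds: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    cohort: dict = dataclasses.field(default_factory=dict)
    reads: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_READS))
    images: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_IMAGES))
    inputs: dict = dataclasses.field(default_factory=dict)  # optional pre-existing files

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("seed",):
            if key in raw:
                setattr(cfg, key, raw[key])
        for key in ("thresholds", "reads", "images"):
            if key in raw:
                getattr(cfg, key).update(raw[key] or {})
        cfg.cohort = raw.get("cohort", {}) or {}
        cfg.inputs = raw.get("inputs", {}) or {}
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("seq_alpha", "array_alpha", "fdr_threshold"):
            v = self.thresholds.get(name, DEFAULT_THRESHOLDS[name])
            if not 0 < v < 1:
                raise ValueError(f"threshold {name}={v} must be in (0, 1)")
        for name, p in self.inputs.items():
            if not Path(p).exists():
                raise ValueError(f"input path for {name!r} does not exist: {p}")


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run every stage and write the report bundle into ``outdir``.

    Returns the manifest dictionary.  On stage failure, files written by
    this run are removed and a stage-named :class:`PipelineError` is raised.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict[str, Any] = {
        "seromir_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "thresholds": {**DEFAULT_THRESHOLDS, **config.thresholds},
        "stages": {},
    }
    seeds = _child_seeds(config.seed, 4)

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    stage = "setup"
    try:
        # ---- cohort -------------------------------------------------------
        stage = "simulate"
        if config.inputs:
            seq = sio.read_matrix(config.inputs["seq_counts"])
            arr = (
                sio.read_matrix(config.inputs["array_intensity"])
                if "array_intensity" in config.inputs else None
            )
            subjects = sio.read_table(config.inputs["subjects"]).set_index("subject")
            variable_classes = {}
            truth = None
        else:
            cohort_cfg = CohortConfig(**{**config.cohort, "seed": seeds[0]})
            cohort = generate_cohort(cohort_cfg)
            seq, arr = cohort.seq_counts, cohort.array_intensity
            subjects, variable_classes = cohort.subjects, cohort.variable_classes
            truth = cohort.truth
            emit("seq_counts.tsv", lambda p: sio.write_matrix(seq, p))
            emit("array_intensity.tsv", lambda p: sio.write_matrix(arr, p))
            emit("subjects.tsv", lambda p: sio.write_table(subjects.reset_index(), p))
            emit("truth.json", lambda p: sio.write_json(truth.to_dict(), p))
        manifest["stages"]["simulate"] = {
            "n_features": int(seq.shape[0]), "n_samples": int(seq.shape[1]),
        }
        log.info("simulate: %d features x %d samples", *seq.shape)

        # ---- screen (filter, normalize, test, tiers, correlations) -------
        stage = "screen"
        model = SerumBiomarkerModel(seq, arr, subjects, variable_classes)
        res = model.fit(**{**DEFAULT_THRESHOLDS, **config.thresholds})
        emit("seq_diff.tsv", lambda p: sio.write_table(res.seq_diff, p))
        emit("array_diff.tsv", lambda p: sio.write_table(res.array_diff, p))
        emit("variable_diff.tsv", lambda p: sio.write_table(res.variable_diff, p))
        emit("tiers.tsv", lambda p: sio.write_table(res.tiers, p))
        if res.targeted_correlations is not None:
            emit("correlations_targeted.tsv",
                 lambda p: sio.write_table(res.targeted_correlations, p))
        if res.exploratory_correlations is not None:
            emit("correlations_exploratory.tsv",
                 lambda p: sio.write_table(res.exploratory_correlations, p))
        manifest["stages"]["screen"] = {
            "features_in": int(seq.shape[0]),
            "features_after_detection_filter": int(len(res.seq_diff)),
            "tier_counts": res.tier_counts,
        }
        log.info("screen: tiers %s", res.tier_counts)

        # ---- clustering ---------------------------------------------------
        stage = "cluster"
        try:
            tree = res.cluster()
            emit("cluster.nwk", lambda p: Path(p).write_text(tree.to_newick() + "\n"))
            manifest["stages"]["cluster"] = {"n_leaves": len(tree.leaf_order)}
        except ValueError as exc:
            manifest["stages"]["cluster"] = {"skipped": str(exc)}
            log.info("cluster: skipped (%s)", exc)

        # ---- maturity trend ----------------------------------------------
        stage = "maturity"
        annotation = generate_annotation(
            n_precursors=int(config.reads["n_precursors"]), seed=seeds[1]
        )
        reads = generate_reads(
            annotation,
            mature_fraction=float(config.reads["mature_fraction"]),
            n_reads=int(config.reads["n_reads"]),
            seed=seeds[1],
        )
        profile = maturity_trend(reads, annotation)
        emit("maturity_trend.tsv", lambda p: sio.write_table(profile.to_frame(), p))
        emit("annotation.gff3", lambda p: sio.write_gff3(annotation, p))
        emit("reads.bed", lambda p: sio.write_bed6(reads, p))
        manifest["stages"]["maturity"] = {
            "n_reads": profile.n_reads,
            "mature_fraction": profile.mature_fraction,
        }

        # ---- sulcal morphometry ------------------------------------------
        stage = "sulcal"
        img_cfg = {**DEFAULT_IMAGES, **config.images}
        rng = np.random.default_rng(seeds[2])
        rows = []
        measurements, glabels = [], []
        for sid, grp in subjects[model.group_col].items():
            base = img_cfg["base_fraction"] * (
                img_cfg["case_ratio"] if grp == model.case_label else 1.0
            )
            frac = float(np.clip(rng.normal(base, img_cfg["subject_sd"]), 0.02, 0.6))
            img, img_truth = generate_brain_image(
                int(img_cfg["height"]), int(img_cfg["width"]), frac,
                noise_sd=float(img_cfg["noise_sd"]),
                seed=int(rng.integers(2**31 - 1)),
            )
            m = sulcal_fraction(img, subject=str(sid))
            measurements.append(m)
            glabels.append(grp)
            rows.append(
                {
                    "subject": sid, "group": grp,
                    "true_fraction_pct": 100 * img_truth.sulcal_fraction,
                    "percent_sulci": m.percent_sulci,
                    "area_triangle": m.area_triangle, "area_moments": m.area_moments,
                }
            )
        sulcal_table = pd.DataFrame(rows)
        emit("sulcal.tsv", lambda p: sio.write_table(sulcal_table, p))
        diff = compare_groups(measurements, glabels, case_label=model.case_label,
                              control_label=model.control_label)
        emit("sulcal_diff.tsv", lambda p: sio.write_table(diff_results_frame([diff]), p))
        manifest["stages"]["sulcal"] = {
            "percent_change": diff.percent_change, "test_p": diff.test_p,
            "chosen_test": diff.chosen_test,
        }

        stage = "manifest"
        emit("manifest.json", lambda p: sio.write_json(manifest, p))
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return manifest
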