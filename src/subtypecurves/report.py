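"""Config-driven experiment runner and report assembly.

A single YAML file describes the cohort (synthetic parameters or file
paths), the curve design, and which experiments to run (``supervised``,
``receptor``, ``depth``, ``unsupervised``).  ``run_from_config`` executes
the selected experiments, writes tidy per-round tables, per-condition
summaries (mean ± SEM), confusion matrices, and a JSON manifest echoing the
config and seed — reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
import warnings

import numpy as np
import pandas as pd
import yaml

from . import io, preprocessing
from .classifiers import ClassifierSpec
from .errors import ConfigurationError, StructuralError
from .receptor import run_receptor_curve, summarize_receptor_curve
from .simulate import MARKER_GENES, Cohort, CohortConfig, simulate_cohort
from .supervised import (CurveConfig, DatasetDef, LearningCurveResult,
                         run_learning_curve, summarize_records)
from .unsupervised import run_unsupervised_curve

logger = logging.getLogger(__name__)

EXPERIMENTS = ("supervised", "receptor", "depth", "unsupervised")
FLOAT_FORMAT = io.FLOAT_FORMAT


def load_config(path: str) -> dict:
    if not os.path.exists(path):
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    return config


def _build_cohort(config: dict, seed: int) -> Cohort:
    cohort_cfg = config.get("cohort")
    if not isinstance(cohort_cfg, dict) or \
            ("synthetic" in cohort_cfg) == ("files" in cohort_cfg):
        raise ConfigurationError(
            "cohort: exactly one of 'synthetic' or 'files' must be given")
    if "synthetic" in cohort_cfg:
        params = dict(cohort_cfg["synthetic"] or {})
        params.setdefault("seed", seed)
        return simulate_cohort(CohortConfig(**params))
    files = cohort_cfg["files"]
    for key in ("counts", "annotation"):
        if key not in files:
            raise ConfigurationError(f"cohort.files.{key}: missing path")
        if not os.path.exists(files[key]):
            raise ConfigurationError(f"cohort.files.{key}: no such file "
                                     f"{files[key]!r}")
    counts = io.read_counts(files["counts"])
    annotation = io.read_annotation(files["annotation"])
    if "centroids" in files:
        centroids = io.read_matrix(files["centroids"], dtype=float)
    else:
        centroids = pd.DataFrame(index=counts.index)
    cohort = Cohort(counts=counts, annotation=annotation,
                    true_centroids=centroids, informative_genes=[],
                    config=CohortConfig(seed=seed))
    if counts.shape[1] != len(annotation):
        raise StructuralError("counts/annotation sample dimensions differ")
    return cohort


def _build_datasets(entries: list | None) -> tuple:
    if not entries:
        return (("Top25", DatasetDef("top_variance", fraction=0.25)),)
    out = []
    for entry in entries:
        entry = dict(entry)
        name = entry.pop("name", entry.get("kind", "dataset"))
        if "genes_file" in entry:
            entry["genes"] = tuple(io.read_panel(entry.pop("genes_file")))
        if "genes" in entry and entry["genes"] is not None:
            entry["genes"] = tuple(entry["genes"])
        out.append((name, DatasetDef(**entry)))
    return tuple(out)


def _build_curve_config(config: dict, seed: int,
                        with_depths: bool = False) -> CurveConfig:
    curve = dict(config.get("curve") or {})
    specs = tuple(
        ClassifierSpec(entry["family"], entry.get("grid"), seed=seed)
        for entry in curve.get("classifiers", [{"family": "nsc"}]))
    kwargs = dict(
        classifier_specs=specs,
        datasets=_build_datasets(curve.get("datasets")),
        master_seed=seed,
    )
    for key in ("training_sizes", "test_fraction", "n_rounds", "inner_folds"):
        if key in curve:
            kwargs[key] = curve[key]
    if with_depths:
        depths = curve.get("read_depths")
        if not depths:
            raise ConfigurationError("curve.read_depths: required for the "
                                     "read-depth experiment")
        kwargs["read_depth_grid"] = tuple(depths)
    return CurveConfig(**kwargs)


def _write_curve_result(result: LearningCurveResult, outdir: str,
                        tag: str) -> list[str]:
    written = []
    for frame, stem in ((result.records, f"results_{tag}"),
                        (result.summary, f"summary_{tag}")):
        path = os.path.join(outdir, f"{stem}.tsv")
        frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written.append(path)
    for key, counts in result.confusions.items():
        stem = "confusion_" + tag + "_" + "_".join(str(k) for k in key)
        path = os.path.join(outdir, f"{stem}.tsv")
        counts.to_csv(path, sep="\t")
        written.append(path)
    return written


def summarize(records: pd.DataFrame, value_cols=("accuracy", "balanced_accuracy"),
              by=None) -> pd.DataFrame:
    """Per-condition mean, SD and SEM of round-level accuracies.

    SEM = SD / sqrt(n_rounds); a condition observed in a single round gets
    SEM 0 by convention (with a warning, since no spread is estimable).
    """
    value_cols = [c for c in value_cols if c in records.columns]
    summary = summarize_records(records, value_cols=value_cols, by=by)
    if (summary["n_rounds"] == 1).any():
        warnings.warn("single-round condition: SEM reported as 0")
    return summary


def plot_learning_curve(summary: pd.DataFrame, path: str,
                        value: str = "accuracy") -> None:
    """Accuracy-vs-size curves with SEM error bars (headless-safe)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    group_cols = [c for c in ("dataset", "depth", "classifier", "receptor")
                  if c in summary.columns]
    for key, grp in summary.groupby(group_cols) if group_cols else [("", summary)]:
        label = key if isinstance(key, str) else "/".join(str(k) for k in key)
        grp = grp.sort_values("size")
        ax.errorbar(grp["size"], grp[f"{value}_mean"], yerr=grp[f"{value}_sem"],
                    marker="o", capsize=3, label=label)
    ax.set_xlabel("training sample size")
    ax.set_ylabel(value.replace("_", " "))
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_from_config(path: str, output_dir: str | None = None) -> dict:
    """Execute the experiments a YAML config selects; return the manifest."""
    config = load_config(path)
    seed = int(config.get("seed", 0))
    outdir = output_dir or config.get("output_dir", "results")
    os.makedirs(outdir, exist_ok=True)
    experiments = config.get("experiments", ["supervised"])
    unknown = set(experiments) - set(EXPERIMENTS)
    if unknown:
        raise ConfigurationError(
            f"experiments: unknown entries {sorted(unknown)!r}; "
            f"choose from {EXPERIMENTS}")

    logging.basicConfig(level=getattr(logging, str(config.get("log_level",
                                                              "INFO")).upper()))
    cohort = _build_cohort(config, seed)
    written: list[str] = []

    if "supervised" in experiments:
        result = run_learning_curve(cohort, _build_curve_config(config, seed))
        written += _write_curve_result(result, outdir, "supervised")
    if "depth" in experiments:
        result = run_learning_curve(
            cohort, _build_curve_config(config, seed, with_depths=True))
        written += _write_curve_result(result, outdir, "depth")
    if "receptor" in experiments:
        receptor_cfg = dict(config.get("receptor") or {})
        receptors = receptor_cfg.get("receptors", list(MARKER_GENES))
        curve_config = _build_curve_config(config, seed)
        frames = [run_receptor_curve(cohort, r, curve_config) for r in receptors]
        records = pd.concat(frames, ignore_index=True)
        path_r = os.path.join(outdir, "results_receptor.tsv")
        records.to_csv(path_r, sep="\t", index=False, float_format=FLOAT_FORMAT)
        summary = summarize_receptor_curve(records)
        path_s = os.path.join(outdir, "summary_receptor.tsv")
        summary.to_csv(path_s, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written += [path_r, path_s]
    if "unsupervised" in experiments:
        unsup = dict(config.get("unsupervised") or {})
        result = run_unsupervised_curve(
            cohort, _build_curve_config(config, seed),
            alpha=float(unsup.get("alpha", 0.05)),
            n_sim=int(unsup.get("n_sim", 100)))
        written += _write_curve_result(result, outdir, "unsupervised")

    if config.get("plots"):
        for tag in ("supervised", "receptor", "unsupervised", "depth"):
            path_s = os.path.join(outdir, f"summary_{tag}.tsv")
            if os.path.exists(path_s):
                plot_learning_curve(pd.read_csv(path_s, sep="\t"),
                                    os.path.join(outdir, f"curve_{tag}.png"))

    manifest = {
        "config_path": os.path.abspath(path),
        "config": config,
        "seed": seed,
        "outputs": sorted(os.path.relpath(p, outdir) for p in written),
    }
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
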