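"""End-to-end orchestration: simulate -> preprocess -> train -> unmix -> report.

A run is driven by a nested configuration dictionary (validated against a
schema before any work starts) and a master seed that fans out to per-stage
seeds, so any stage can be re-run in isolation and reproduce its output.
Each completed stage leaves a ``<stage>.done`` marker in the run directory;
re-running a completed directory without ``force`` is a no-op.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import cnn as cnn_mod
from .core import FINGERPRINT_AXIS
from .io import read_dataset_h5, write_dataset_h5, write_map
from .mcr import hca_segment, smcr_decompose
from .peaks import default_peak_table
from .preprocess import (
    PreprocessConfig,
    extract_peak_table,
    group_mean_sd,
    peak_group_ttest,
    preprocess_dataset,
)
from .profiles import default_profiles
from .reporting import summary_report
from .synthetic import CohortConfig, generate_afp, generate_cohort, generate_map

__all__ = ["ConfigError", "validate_config", "run_all", "REDUCED_OVERRIDES", "STAGES"]

logger = logging.getLogger("ramanhisto")

STAGES = ("simulate", "preprocess", "train", "unmix", "report")

# schema: section -> key -> required type(s)
_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "cohort": {
        "n_patients": int,
        "n_hcc": int,
        "n_icc": int,
        "spectra_per_sample": int,
        "patient_effect_sd": (int, float),
        "noise_sd": (int, float),
    },
    "preprocess": {
        "baseline_method": str,
        "baseline_lam": (int, float),
        "baseline_p": (int, float),
        "sg_window": int,
        "sg_order": int,
        "cosmic_z": (int, float),
    },
    "model": {
        "n_epochs": int,
        "batch_size": int,
        "learning_rate": (int, float),
        "dropout_rate": (int, float),
        "channel_divisor": int,
        "optimizer": str,
    },
    "splits": {"binary_test_pairs": (int, float), "subgroup_test_fraction": (int, float)},
    "tasks": None,  # list of task names
    "imaging": {"shape": None, "k": int, "noise_sd": (int, float)},
    "report": {},
    "seed": None,
}

#: Desk-scale profile: a smaller cohort and a narrower network so a full run
#: finishes on one CPU in minutes. 40 patients (32 HCC / 8 ICC) x 2 samples
#: x 30 spectra = 2,400 spectra; all layer widths divided by 4; 10 epochs.
REDUCED_OVERRIDES: dict = {
    "cohort": {"n_patients": 40, "n_hcc": 32, "n_icc": 8, "spectra_per_sample": 30},
    "model": {"channel_divisor": 4, "n_epochs": 10},
}


class ConfigError(ValueError):
    """Configuration rejected before any stage ran."""


def default_config() -> dict:
    return {
        "seed": 0,
        "cohort": {},
        "preprocess": {},
        "model": {},
        "splits": {"binary_test_pairs": 20, "subgroup_test_fraction": 0.2},
        "tasks": ["binary", "subtype", "stage", "differentiation"],
        "imaging": {"shape": [25, 25], "k": 2, "noise_sd": 5.0},
        "report": {},
    }


def validate_config(config: dict) -> dict:
    """Merge a user configuration over the defaults, rejecting unknown keys.

    Raises :class:`ConfigError` naming the offending path.
    """
    merged = default_config()
    for section, value in config.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown configuration key: {section}")
        if section == "seed":
            if not isinstance(value, int):
                raise ConfigError("seed: must be an integer")
            merged["seed"] = value
        elif section == "tasks":
            if not isinstance(value, list) or not set(value) <= set(cnn_mod.splits.TASKS):
                raise ConfigError(f"tasks: must be a subset of {list(cnn_mod.splits.TASKS)}")
            merged["tasks"] = list(value)
        else:
            if not isinstance(value, dict):
                raise ConfigError(f"{section}: must be a mapping")
            allowed = _SCHEMA[section]
            for key, v in value.items():
                if allowed is not None and key not in allowed:
                    raise ConfigError(f"unknown configuration key: {section}.{key}")
                expected = None if allowed is None else allowed[key]
                if expected is not None and not isinstance(v, expected):
                    raise ConfigError(f"{section}.{key}: expected {expected}, got {type(v)}")
            merged[section].update(value)
    return merged


def apply_reduced(config: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in config.items()}
    for section, overrides in REDUCED_OVERRIDES.items():
        out[section].update(overrides)
    return out


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence([master, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _marker(outdir: Path, stage: str) -> Path:
    return outdir / f"{stage}.done"


def run_all(
    config: dict | None = None,
    outdir: str | Path = "run",
    seed: int | None = None,
    reduced: bool = False,
    force: bool = False,
) -> Path:
    """Execute the whole pipeline into a run directory.

    Stage order: simulate, preprocess, train (split + fit + evaluate per
    task), unmix (two-component margin phantom, MCR-ALS + HCA), report.
    Completed stages are skipped unless ``force`` is set.
    """
    config = validate_config(config or {})
    if seed is not None:
        config["seed"] = seed
    if reduced:
        config = apply_reduced(config)
    master = config["seed"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("run start: numpy %s, master seed %d", np.__version__, master)

    peaks = default_peak_table()
    pp_conf = PreprocessConfig(
        baseline_method=config["preprocess"].get("baseline_method", "als"),
        baseline_lam=config["preprocess"].get("baseline_lam", 1e5),
        baseline_p=config["preprocess"].get("baseline_p", 0.01),
        sg_window=config["preprocess"].get("sg_window", 11),
        sg_order=config["preprocess"].get("sg_order", 3),
        cosmic_z=config["preprocess"].get("cosmic_z", 8.0),
    )

    try:
        # -- simulate -------------------------------------------------------
        if force or not _marker(outdir, "simulate").exists():
            t0 = time.perf_counter()
            cc = CohortConfig(seed=stage_seed(master, "simulate"), **config["cohort"])
            cohort = generate_cohort(cc, peaks=peaks)
            write_dataset_h5(cohort, outdir / "cohort.h5")
            afp = generate_afp(cohort, rng=stage_seed(master, "simulate"))
            afp.to_csv(outdir / "afp.tsv", sep="\t", index=False)
            _marker(outdir, "simulate").touch()
            logger.info("simulate: %d spectra in %.1fs", len(cohort), time.perf_counter() - t0)

        # -- preprocess -----------------------------------------------------
        if force or not _marker(outdir, "preprocess").exists():
            t0 = time.perf_counter()
            cohort = read_dataset_h5(outdir / "cohort.h5")
            clean = preprocess_dataset(cohort, pp_conf)
            write_dataset_h5(clean, outdir / "preprocessed.h5")
            table = extract_peak_table(clean, peaks)
            tests = peak_group_ttest(table, "tissue")
            tests.to_csv(outdir / "peak_ttests.tsv", sep="\t")
            _marker(outdir, "preprocess").touch()
            logger.info("preprocess: done in %.1fs", time.perf_counter() - t0)

        # -- train ----------------------------------------------------------
        if force or not _marker(outdir, "train").exists():
            clean = read_dataset_h5(outdir / "preprocessed.h5")
            model_conf = cnn_mod.CNNConfig(
                seed=stage_seed(master, "train"), **config["model"]
            )
            results = {}
            for task in config["tasks"]:
                t0 = time.perf_counter()
                sub, y, classes = cnn_mod.task_labels(clean, task)
                labelled = sub.meta.copy()
                labelled["_y"] = y
                if task == "binary":
                    plan = cnn_mod.SplitPlan(
                        test_pairs=config["splits"]["binary_test_pairs"],
                        train_val_ratio=(0.8, 0.2),
                        seed=stage_seed(master, "train"),
                    )
                else:
                    strat = {"subtype": "subtype", "stage": "stage", "differentiation": "differentiation"}[task]
                    plan = cnn_mod.SplitPlan(
                        test_pairs=config["splits"]["subgroup_test_fraction"],
                        train_val_ratio=(0.9, 0.1),
                        stratify_by=strat,
                        seed=stage_seed(master, "train"),
                    )
                split = cnn_mod.split_by_patient(sub, plan)
                y_of = lambda ds: cnn_mod.task_labels(ds, task)[1]
                model = cnn_mod.build_model(model_conf, sub.axis.n_points, len(classes))
                cnn_mod.train(
                    model,
                    (split.train.X, y_of(split.train)),
                    (split.val.X, y_of(split.val)),
                )
                proba, _ = cnn_mod.predict(model, split.test.X)
                report = cnn_mod.evaluate(y_of(split.test), proba, classes)
                results[task] = report
                np.savetxt(
                    outdir / f"history_{task}.tsv",
                    np.column_stack([model.history[k] for k in sorted(model.history)]),
                    delimiter="\t",
                    header="\t".join(sorted(model.history)),
                )
                logger.info(
                    "train[%s]: accuracy %.3f in %.1fs",
                    task, report.accuracy, time.perf_counter() - t0,
                )
            with open(outdir / "eval.json", "w") as f:
                json.dump(
                    {
                        t: {
                            "classes": [str(c) for c in r.classes],
                            "confusion": r.confusion.tolist(),
                            "accuracy": r.accuracy,
                            "sensitivity": r.sensitivity,
                            "specificity": r.specificity,
                            "auc": r.auc,
                        }
                        for t, r in results.items()
                    },
                    f,
                    indent=1,
                )
            _marker(outdir, "train").touch()

        # -- unmix ----------------------------------------------------------
        if force or not _marker(outdir, "unmix").exists():
            t0 = time.perf_counter()
            profiles = default_profiles()
            rows, cols = config["imaging"]["shape"]
            yy, xx = np.mgrid[0:rows, 0:cols]
            layout = ((xx + yy) >= (rows + cols) // 2).astype(int)  # diagonal margin
            phantom = generate_map(
                [profiles["paracancer"], profiles["HCC"]],
                layout,
                FINGERPRINT_AXIS,
                noise_sd=config["imaging"]["noise_sd"],
                rng=stage_seed(master, "unmix"),
                peaks=peaks,
                surface_amplitude=30.0,
            )
            write_map(phantom, outdir / "phantom.h5")
            res = smcr_decompose(phantom, k=config["imaging"]["k"])
            seg = hca_segment(phantom, n_clusters=config["imaging"]["k"])
            np.savetxt(outdir / "concentrations.tsv", res.C, delimiter="\t")
            np.savetxt(outdir / "pure_spectra.tsv", res.S, delimiter="\t")
            np.savetxt(outdir / "hca_labels.tsv", seg.labels, fmt="%d", delimiter="\t")
            logger.info(
                "unmix: lack of fit %.3f%% after %d iterations in %.1fs",
                res.lack_of_fit[-1], res.n_iterations, time.perf_counter() - t0,
            )
            _marker(outdir, "unmix").touch()

        # -- report ---------------------------------------------------------
        if force or not _marker(outdir, "report").exists():
            clean = read_dataset_h5(outdir / "preprocessed.h5")
            with open(outdir / "eval.json") as f:
                raw = json.load(f)
            reports = {
                t: cnn_mod.EvalReport(
                    classes=d["classes"],
                    confusion=np.asarray(d["confusion"]),
                    confusion_percent=_row_percent(np.asarray(d["confusion"])),
                    accuracy=d["accuracy"],
                    sensitivity=d["sensitivity"],
                    specificity=d["specificity"],
                    auc=d["auc"],
                )
                for t, d in raw.items()
            }
            import pandas as pd

            serology = pd.read_csv(outdir / "afp.tsv", sep="\t")
            tests = pd.read_csv(outdir / "peak_ttests.tsv", sep="\t", index_col=0)
            summary_report(
                outdir / "report",
                eval_reports=reports,
                serology=serology,
                peak_tests=tests,
                group_bands=group_mean_sd(clean, "tissue"),
                axis=clean.axis,
                config=config,
                seed=master,
            )
            _marker(outdir, "report").touch()
            logger.info("report: written")
    except Exception:
        (outdir / "FAILED").touch()
        logger.exception("stage failed; partial run directory left in place")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    with open(outdir / "config.yaml", "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)
    return outdir


def _row_percent(confusion: np.ndarray) -> np.ndarray:
    row = confusion.sum(axis=1, keepdims=True)
    return np.where(row > 0, confusion / np.maximum(row, 1) * 100.0, 0.0)
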