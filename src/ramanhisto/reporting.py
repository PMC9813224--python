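"""Cohort-level reporting: AFP serology and the consolidated run report."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnn.metrics import EvalReport

__all__ = ["afp_sensitivity", "summary_report"]


def afp_sensitivity(
    table: pd.DataFrame, threshold: float = 200.0
) -> tuple[float, int, int]:
    """Sensitivity of AFP serology for HCC at a positivity threshold.

    ``table`` needs an ``afp_ng_ml`` column and an HCC indicator (boolean
    ``is_hcc`` or a ``subtype`` column). Returns (sensitivity %, rounded to
    one decimal; positive count; HCC total).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if "is_hcc" in table.columns:
        hcc = table[table["is_hcc"].astype(bool)]
    elif "subtype" in table.columns:
        hcc = table[table["subtype"] == "HCC"]
    else:
        raise ValueError("table needs an 'is_hcc' or 'subtype' column")
    total = len(hcc)
    if total == 0:
        raise ValueError("no HCC patients in the table")
    if (table["afp_ng_ml"] < 0).any():
        raise ValueError("AFP values must be non-negative")
    positives = int((hcc["afp_ng_ml"] > threshold).sum())
    return round(positives / total * 100.0, 1), positives, total


def _confusion_frame(report: EvalReport) -> pd.DataFrame:
    return pd.DataFrame(
        np.round(report.confusion_percent, 1),
        index=[f"true_{c}" for c in report.classes],
        columns=[f"pred_{c}" for c in report.classes],
    )


def summary_report(
    outdir,
    eval_reports: dict[str, EvalReport] | None = None,
    serology: pd.DataFrame | None = None,
    peak_tests: pd.DataFrame | None = None,
    group_bands: dict | None = None,
    axis=None,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write a consolidated run report.

    Layout: ``report/{tables/*.tsv, figures/*.png, config.yaml, log.txt}``.
    Tables are fully determined by their inputs, so regenerating a report
    from the same run reproduces them byte for byte. Figures: mean +/- SD
    spectral bands, confusion matrices in percent, ROC curves annotated with
    their AUC (to three decimals), and the peak t-test table.
    """
    if not any(v is not None for v in (eval_reports, serology, peak_tests, group_bands)):
        raise ValueError("report needs at least one input section")
    outdir = Path(outdir)
    tables = outdir / "tables"
    figures = outdir / "figures"
    tables.mkdir(parents=True, exist_ok=True)
    figures.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if eval_reports:
        metrics_rows = []
        for task, rep in sorted(eval_reports.items()):
            _confusion_frame(rep).to_csv(tables / f"confusion_{task}.tsv", sep="\t")
            metrics_rows.append(
                {
                    "task": task,
                    "accuracy_pct": round(rep.accuracy * 100, 1),
                    "sensitivity_pct": ""
                    if rep.sensitivity is None
                    else round(rep.sensitivity * 100, 1),
                    "specificity_pct": ""
                    if rep.specificity is None
                    else round(rep.specificity * 100, 1),
                    "auc": "" if rep.auc is None else round(rep.auc, 3),
                }
            )
            fig, ax = plt.subplots(figsize=(4, 3.5))
            im = ax.imshow(rep.confusion_percent, cmap="Blues", vmin=0, vmax=100)
            ax.set_xticks(range(len(rep.classes)), rep.classes, rotation=45, ha="right")
            ax.set_yticks(range(len(rep.classes)), rep.classes)
            for i in range(len(rep.classes)):
                for j in range(len(rep.classes)):
                    ax.text(j, i, f"{rep.confusion_percent[i, j]:.1f}", ha="center", va="center")
            ax.set_xlabel("predicted")
            ax.set_ylabel("true")
            fig.colorbar(im, ax=ax)
            fig.tight_layout()
            fig.savefig(figures / f"confusion_{task}.png", dpi=120)
            plt.close(fig)
        pd.DataFrame(metrics_rows).to_csv(tables / "metrics.tsv", sep="\t", index=False)
        log.append(f"evaluation tasks: {', '.join(sorted(eval_reports))}")

        roc_tasks = [(t, r) for t, r in sorted(eval_reports.items()) if r.roc is not None]
        if roc_tasks:
            fig, ax = plt.subplots(figsize=(4.5, 4))
            for task, rep in roc_tasks:
                fpr, tpr, _ = rep.roc
                ax.plot(fpr, tpr, label=f"{task} (AUC = {rep.auc:.3f})")
            ax.plot([0, 1], [0, 1], "k--", lw=0.8)
            ax.set_xlabel("1 - specificity")
            ax.set_ylabel("sensitivity")
            ax.legend(loc="lower right", fontsize=8)
            fig.tight_layout()
            fig.savefig(figures / "roc.png", dpi=120)
            plt.close(fig)

    if serology is not None:
        sens, pos, total = afp_sensitivity(
            serology, serology.attrs.get("threshold_ng_ml", 200.0)
        )
        pd.DataFrame(
            [{"afp_positive": pos, "hcc_total": total, "sensitivity_pct": sens}]
        ).to_csv(tables / "afp_serology.tsv", sep="\t", index=False)
        log.append(f"AFP serology: {pos}/{total} positive, sensitivity {sens}%")

    if peak_tests is not None:
        peak_tests.to_csv(tables / "peak_ttests.tsv", sep="\t")
        log.append(f"peak t-tests: {int(peak_tests['significant'].sum())} significant bands")

    if group_bands is not None and axis is not None:
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for label, (mean, sd) in sorted(group_bands.items()):
            ax.plot(axis.grid, mean, label=label, lw=1.0)
            ax.fill_between(axis.grid, mean - sd, mean + sd, alpha=0.25)
        ax.set_xlabel("Raman shift (cm$^{-1}$)")
        ax.set_ylabel("intensity (a.u.)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(figures / "mean_sd_spectra.png", dpi=120)
        plt.close(fig)

    with open(outdir / "config.yaml", "w") as f:
        yaml.safe_dump({"config": config or {}, "seed": seed}, f, sort_keys=True)
    with open(outdir / "log.txt", "w") as f:
        f.write("\n".join(log) + "\n")
    return outdir
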