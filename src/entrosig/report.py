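"""Study reports: machine-readable JSON and human-readable tables."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .classify import ClassificationResult
from .eeg import GroupTestResult

__all__ = ["study_report", "report_to_json", "report_to_text"]


def study_report(
    test_results: list[GroupTestResult] | None = None,
    classification_results: list[ClassificationResult] | None = None,
    feature_table: pd.DataFrame | None = None,
    labels=None,
    alpha: float = 0.01,
) -> dict:
    """Assemble a study report dictionary.

    Contains per-config group medians (when a feature table and labels
    are given), hypothesis-test outcomes with significance flags, and
    the best cross-validated accuracy per feature-vector size.
    """
    report: dict = {"alpha": alpha}

    if feature_table is not None and labels is not None:
        y = np.asarray(labels)
        medians: dict = {}
        for col in feature_table.columns:
            medians[col] = {
                str(g): float(np.nanmedian(feature_table[col].to_numpy()[y == g]))
                for g in np.unique(y)
            }
        report["group_medians"] = medians
        report["n_features"] = int(feature_table.shape[1])
        report["n_segments"] = int(feature_table.shape[0])

    if test_results:
        report["tests"] = [
            {
                "test": t.test,
                "groups": list(t.groups),
                "statistic": float(t.statistic),
                "p_value": float(t.p_value),
                "group_sizes": list(t.group_sizes),
                "significant": bool(t.significant),
                "degenerate": bool(t.degenerate),
            }
            for t in test_results
        ]

    if classification_results:
        best_by_size: dict[int, ClassificationResult] = {}
        for res in classification_results:
            size = len(res.features)
            cur = best_by_size.get(size)
            if cur is None or res.sort_key() < cur.sort_key():
                best_by_size[size] = res
        report["best_accuracy_by_size"] = {
            str(size): {
                "features": list(res.features),
                "mean_accuracy": round(res.mean_accuracy, 10),
                "pooled_accuracy": round(res.pooled_accuracy, 10),
                "fold_accuracies": [round(a, 10) for a in res.fold_accuracies],
                "k": res.k,
                "folds": res.folds,
                "seed": res.seed,
            }
            for size, res in sorted(best_by_size.items())
        }
    return report


def report_to_json(report: dict) -> str:
    """Deterministic JSON rendering (sorted keys, fixed separators)."""
    return json.dumps(report, indent=2, sort_keys=True)


def report_to_text(report: dict) -> str:
    """Plain-text tables for terminal reading."""
    lines: list[str] = []
    if "tests" in report:
        lines.append("Hypothesis tests (alpha = %g)" % report.get("alpha", 0.01))
        lines.append(f"{'test':<22}{'groups':<28}{'statistic':>12}{'p-value':>12}  sig")
        for t in report["tests"]:
            lines.append(
                f"{t['test']:<22}{' vs '.join(t['groups']):<28}"
                f"{t['statistic']:>12.4g}{t['p_value']:>12.3g}  "
                + ("*" if t["significant"] else "")
            )
        lines.append("")
    if "best_accuracy_by_size" in report:
        lines.append("Best cross-validated accuracy per feature-vector size")
        lines.append(f"{'size':<6}{'mean acc':>10}{'pooled':>10}  features")
        for size, entry in report["best_accuracy_by_size"].items():
            lines.append(
                f"{size:<6}{entry['mean_accuracy']:>10.3f}{entry['pooled_accuracy']:>10.3f}  "
                + ", ".join(entry["features"])
            )
        lines.append("")
    if "group_medians" in report:
        lines.append(
            "Feature table: %d segments x %d configurations"
            % (report["n_segments"], report["n_features"])
        )
    return "\n".join(lines)
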