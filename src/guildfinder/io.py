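"""Plain-text serialization of groupings and score reports.

Groupings travel as two-column TSV (``species_id``, ``group_label``,
1-based species ids) or as JSON mapping species id to group label; score
reports and model coefficients as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .partition import Grouping
from .regression import GroupRegressionModel
from .scoring import ScoreReport

__all__ = [
    "write_grouping_tsv",
    "read_grouping_tsv",
    "write_grouping_json",
    "read_grouping_json",
    "write_score_report",
    "model_to_dict",
]


def write_grouping_tsv(grouping: Grouping, path: str | Path) -> None:
    labels = grouping.to_labels()
    df = pd.DataFrame(
        {"species_id": np.arange(1, grouping.n_species + 1), "group_label": labels}
    )
    df.to_csv(path, sep="\t", index=False)


def read_grouping_tsv(path: str | Path) -> Grouping:
    df = pd.read_csv(path, sep="\t")
    if not {"species_id", "group_label"} <= set(df.columns):
        raise ValueError("grouping TSV needs species_id and group_label columns")
    order = np.argsort(df["species_id"].to_numpy())
    labels = df["group_label"].to_numpy()[order]
    return Grouping.from_labels(labels)


def write_grouping_json(grouping: Grouping, path: str | Path) -> None:
    labels = grouping.to_labels()
    data = {str(i + 1): int(lab) for i, lab in enumerate(labels)}
    Path(path).write_text(json.dumps(data, indent=1))


def read_grouping_json(path: str | Path) -> Grouping:
    data = json.loads(Path(path).read_text())
    labels = np.empty(len(data), dtype=int)
    for sp, lab in data.items():
        labels[int(sp) - 1] = int(lab)
    return Grouping.from_labels(labels)


def write_score_report(report: ScoreReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


def model_to_dict(model: GroupRegressionModel) -> dict:
    """JSON-serializable view of a fitted group regression model."""
    out = {
        "order": model.order,
        "intercept": model.intercept,
        "linear": model.linear.tolist(),
        "rss": model.rss,
        "rmse": model.rmse,
        "n_samples": model.n_samples,
        "flagged": model.flagged,
    }
    if model.quadratic is not None:
        k = model.k
        iu, ju = np.triu_indices(k)
        out["quadratic"] = {
            f"{i + 1},{j + 1}": float(model.quadratic[i, j]) for i, j in zip(iu, ju)
        }
    return out
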