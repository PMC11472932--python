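"""CSV and YAML dialects for trial series, summaries and parameter files."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .model_core import (
    MODEL_SPECS,
    PARAM_NAMES,
    ModelParams,
    ModelSpec,
    TrialRecord,
    TrialSeries,
)

__all__ = [
    "trial_series_to_frame",
    "write_trial_series_csv",
    "read_trial_series_csv",
    "write_summary_csv",
    "write_params_yaml",
    "read_params_yaml",
]

#: Column order of the trial-series CSV dialect.
TRIAL_COLUMNS = ["participant_id", "group", "condition", "trial", "x_cm", "y_cm", "reward"]


def trial_series_to_frame(series_set: Iterable[TrialSeries]) -> pd.DataFrame:
    rows = []
    for series in series_set:
        for rec in series.records:
            rows.append(
                {
                    "participant_id": series.participant_id,
                    "group": series.group,
                    "condition": series.condition,
                    "trial": rec.trial_index,
                    "x_cm": rec.x,
                    "y_cm": rec.y,
                    "reward": rec.reward,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trial_series_csv(series_set: Iterable[TrialSeries], path) -> None:
    # %.17g round-trips IEEE doubles exactly
    trial_series_to_frame(series_set).to_csv(path, index=False, float_format="%.17g")


def read_trial_series_csv(path, experiment: str = "") -> list[TrialSeries]:
    """Read the trial-series dialect back into TrialSeries objects.

    Endpoint aims are latent and not part of the on-disk dialect; they are
    read back as nan placeholders.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns {sorted(missing)}")
    out: list[TrialSeries] = []
    for (pid, group, condition), block in frame.groupby(
        ["participant_id", "group", "condition"], sort=True
    ):
        block = block.sort_values("trial")
        records = [
            TrialRecord(
                trial_index=int(row.trial),
                x=float(row.x_cm),
                y=float(row.y_cm),
                aim_x=float("nan"),
                aim_y=float("nan"),
                reward=int(row.reward),
            )
            for row in block.itertuples()
        ]
        out.append(
            TrialSeries(
                participant_id=str(pid),
                group=str(group),
                condition=str(condition),
                records=records,
                experiment=experiment,
            )
        )
    return out


def write_summary_csv(frame: pd.DataFrame, path) -> None:
    """Write a tidy metrics table (axis, condition, group, metric, value, n)."""
    frame.to_csv(path, index=False)


def write_params_yaml(
    params: ModelParams, path, model_id: Optional[int] = None
) -> None:
    doc = {name: float(getattr(params, name)) for name in PARAM_NAMES}
    if model_id is not None:
        doc["model_id"] = int(model_id)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_params_yaml(path) -> tuple[ModelParams, Optional[ModelSpec]]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("parameter file must be a flat key-value mapping")
    model_id = doc.pop("model_id", None)
    missing = set(PARAM_NAMES) - set(doc)
    if missing:
        raise ValueError(f"parameter file missing {sorted(missing)}")
    params = ModelParams(**{name: float(doc[name]) for name in PARAM_NAMES})
    spec = MODEL_SPECS[int(model_id)] if model_id is not None else None
    return params, spec
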