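"""Error metrics per SAPT component and correlation-table export."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import SaptRecord

__all__ = ["ErrorReport", "error_metrics", "correlation_export"]

ROWS = ("Elst", "Exch", "Indu", "Disp", "Total")
_ATTRS = ("elst", "exch", "indu", "disp", "total")


@dataclass
class ErrorReport:
    """MAE / RMSE / MAX per component and total, kcal/mol."""

    table: pd.DataFrame   # index Elst..Total, columns MAE RMSE MAX
    n_records: int

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["MAE"] <= t["RMSE"] + 1e-12).all()
                and (t["RMSE"] <= t["MAX"] + 1e-12).all()):
            raise ValueError("metric ordering MAE <= RMSE <= MAX violated")

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="Component")

    def __getitem__(self, key: str) -> pd.Series:
        return self.table.loc[key]


def _records_to_array(records: list[SaptRecord]) -> np.ndarray:
    return np.array([[getattr(r, a) for a in _ATTRS] for r in records])


def error_metrics(predicted: list[SaptRecord], reference: list[SaptRecord],
                  ids: list[str] | None = None,
                  reference_ids: list[str] | None = None) -> ErrorReport:
    """MAE = mean|d|, RMSE = sqrt(mean d^2), MAX = max|d| per component.

    Records must be aligned; optional id lists are checked for agreement.
    """
    if len(predicted) != len(reference):
        raise ValueError(
            f"length mismatch: {len(predicted)} predicted vs "
            f"{len(reference)} reference records"
        )
    if not predicted:
        raise ValueError("no records to evaluate")
    if ids is not None and reference_ids is not None and ids != reference_ids:
        raise ValueError("record id mismatch between predicted and reference")
    delta = _records_to_array(predicted) - _records_to_array(reference)
    table = pd.DataFrame(
        {
            "MAE": np.mean(np.abs(delta), axis=0),
            "RMSE": np.sqrt(np.mean(delta * delta, axis=0)),
            "MAX": np.max(np.abs(delta), axis=0),
        },
        index=list(ROWS),
    )
    return ErrorReport(table=table, n_records=len(predicted))


def correlation_export(predicted: list[SaptRecord], reference: list[SaptRecord],
                       path: str | Path,
                       ids: list[str] | None = None,
                       classes: list[str] | None = None) -> pd.DataFrame:
    """Write the long-format table behind reference-vs-predicted plots.

    Columns: dimer_id, class, component, reference_kcal, predicted_kcal.
    Returns the DataFrame that was written.
    """
    if len(predicted) != len(reference):
        raise ValueError("length mismatch between predicted and reference")
    ids = ids or [str(k) for k in range(len(predicted))]
    classes = classes or [""] * len(predicted)
    rows = []
    for did, cls, p, r in zip(ids, classes, predicted, reference):
        for comp, attr in zip(ROWS, _ATTRS):
            rows.append(
                {
                    "dimer_id": did,
                    "class": cls,
                    "component": comp,
                    "reference_kcal": getattr(r, attr),
                    "predicted_kcal": getattr(p, attr),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.10g")
    return df
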