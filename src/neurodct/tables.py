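"""Bundled per-method reference metric table and its derived report tables.

``reference_metrics.csv`` carries the published per-class metric values (RCI
plus per-class CEN/IBA/GM/MCC) for the 20 benchmark method configurations of
the original comparison study; only those printed values — not the underlying
restricted scans — are redistributable.  From them this module rebuilds the
two derived reports: the balanced (unweighted) per-method averages and the
five-way dense-rank aggregation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import class_average
from .ranking import aggregate_ranking

__all__ = ["load_reference_metrics", "compute_averages", "compute_ranking"]

_AVERAGED = ("cen", "iba", "gm", "mcc")


def load_reference_metrics() -> pd.DataFrame:
    """The bundled 20-method reference table (per-class metric values)."""
    with resources.files("neurodct.data").joinpath("reference_metrics.csv").open() as fh:
        return pd.read_csv(fh)


def compute_averages(metrics: pd.DataFrame, decimals: int | None = 4) -> pd.DataFrame:
    """Balanced per-class averages of CEN/IBA/GM/MCC for each method, rounded
    to the reporting precision (4 decimals, half away from zero)."""
    rows = []
    for rec in metrics.to_dict("records"):
        row = {"method_id": int(rec["method_id"])}
        for name in _AVERAGED:
            per_class = [rec[f"{name}_ad"], rec[f"{name}_nc"], rec[f"{name}_pd"]]
            row[f"avg_{name}"] = class_average(per_class, decimals=decimals)
        rows.append(row)
    return pd.DataFrame(rows)


def compute_ranking(metrics: pd.DataFrame, decimals: int | None = 4) -> pd.DataFrame:
    """Full rank aggregation from a per-class metric table: average, then
    dense-rank RCI and the four averaged metrics, sum, and rank the sums."""
    table = compute_averages(metrics, decimals=decimals)
    table.insert(1, "rci", metrics["rci"].values)
    return aggregate_ranking(table)
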