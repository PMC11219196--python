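"""Survey cost model and cheapest-feasible design selection.

Total cost of a design with S sites and K repeat surveys is

    C = UC + S * CS + S * K * CSS

where UC is a one-off startup cost (equipment, training, licencing), CS
the per-site cost (deployment, travel, maintenance) and CSS the per-site
per-survey cost (post-processing, or field time per repeat).  Cost
parameters are pure configuration — realistic values are program- and
method-specific, so there are deliberately no defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .power import DesignGrid


@dataclass(frozen=True)
class CostParams:
    """Eq.-style cost inputs; all in the same currency unit, all >= 0."""

    uc: float
    cs: float
    css: float

    def __post_init__(self) -> None:
        if self.uc < 0 or self.cs < 0 or self.css < 0:
            raise ValueError("cost parameters must be non-negative")


def total_cost(params: CostParams, S, K):
    """C = UC + S*CS + S*K*CSS (vectorised over S, K)."""
    S = np.asarray(S)
    K = np.asarray(K)
    if np.any(S < 1) or np.any(K < 1):
        raise ValueError("S and K must be >= 1")
    out = params.uc + S * params.cs + S * K * params.css
    return float(out) if out.ndim == 0 else out


@dataclass
class CostResult:
    """Costed grid plus the cheapest feasible design per decline R.

    ``best`` has one row per R with columns S, K, G, cost; an R with no
    feasible cell appears with NaN design columns and ``feasible=False``.
    Ties in cost are broken by smaller S, then smaller K.
    """

    frame: pd.DataFrame
    best: pd.DataFrame
    params: CostParams
    threshold: float
    tie_break: str = "cost, then smaller S, then smaller K"


def cheapest_feasible(
    grid: DesignGrid, params: CostParams, threshold: float = 0.8
) -> CostResult:
    """Exhaustively scan the design grid for the minimum-cost cell with
    G >= threshold, separately for each decline magnitude R."""
    frame = grid.frame.copy()
    frame["cost"] = total_cost(params, frame["S"].to_numpy(), frame["K"].to_numpy())

    rows = []
    for R, sub in frame.groupby("R"):
        feas = sub[sub["G"] >= threshold]
        if feas.empty:
            rows.append(
                {"R": R, "S": np.nan, "K": np.nan, "G": np.nan,
                 "cost": np.nan, "feasible": False}
            )
            continue
        best = feas.sort_values(["cost", "S", "K"], kind="stable").iloc[0]
        rows.append(
            {"R": R, "S": int(best["S"]), "K": int(best["K"]),
             "G": float(best["G"]), "cost": float(best["cost"]),
             "feasible": True}
        )
    return CostResult(
        frame=frame,
        best=pd.DataFrame(rows),
        params=params,
        threshold=threshold,
    )
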