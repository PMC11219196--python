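"""Cumulative detection curves and closed-form power over design grids.

For an occupied site the probability of at least one detection in K
occasions at single-visit detection probability p is

    P* = 1 - (1 - p)^K.

Power to detect a proportional occupancy decline R (psi2 = psi1 (1 - R))
from S sites surveyed K times before and after the change follows the
two-sample Wald construction for the occupancy MLE.  Imperfect detection
inflates the estimator variance through

    F = (1 - P*) / (P* - K p (1 - p)^(K - 1)),
    sigma_i^2 = psi_i (1 - psi_i + F) / S,

and the power of the two-sided level-alpha test is

    G = 1 - Phi((z_{a/2} sd - D) / sd) + Phi((-z_{a/2} sd - D) / sd)

with D = psi1 - psi2 and sd = sqrt(sigma_1^2 + sigma_2^2).  At R = 0 the
expression collapses to G = alpha exactly.  Alpha defaults to 0.2: for
declining species a Type II error (missing a real decline) is costlier
than a false alarm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

#: Scenario presets for the three koala survey methods: daily detection
#: probabilities as reported in the source study's abstract and results
#: sections (two slightly different rounding/model choices), shared
#: occupancy and the study's alpha.
PRESETS = {
    "abstract": {"acoustic": 0.32, "drone": 0.28, "camera": 0.019},
    "results": {"acoustic": 0.31, "drone": 0.28, "camera": 0.017},
    "psi1": 0.54,
    "alpha": 0.2,
}


def cumulative_detection(p, K):
    """P* = 1 - (1-p)^K, the chance of >= 1 detection in K occasions.

    Vectorised; K may be real-valued (fractional deployment days)."""
    p = np.asarray(p, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if np.any(K < 0):
        raise ValueError("K must be >= 0")
    out = 1.0 - (1.0 - p) ** K
    return float(out) if out.ndim == 0 else out


def occasions_for_confidence(p: float, target: float) -> float:
    """Continuous number of occasions K with P*(p, K) = target:
    K = ln(1-target) / ln(1-p)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie in (0, 1)")
    return math.log1p(-target) / math.log1p(-p)


def variance_inflation(p: float, K: int) -> float:
    """Detection-driven variance inflation F for the occupancy MLE.

    Requires K >= 2: with a single visit the denominator
    P* - K p (1-p)^(K-1) is identically zero and the design cannot
    separate occupancy from detection."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if K < 2:
        raise ValueError("K must be >= 2 (occupancy not identifiable at K=1)")
    pstar = 1.0 - (1.0 - p) ** K
    denom = pstar - K * p * (1.0 - p) ** (K - 1)
    if denom <= 0:
        raise ValueError(f"non-positive variance denominator at p={p}, K={K}")
    return (1.0 - pstar) / denom


@dataclass(frozen=True)
class PowerInputs:
    """Inputs to the closed-form power evaluation for one design."""

    psi1: float
    R: float
    p: float
    K: int
    S: int
    alpha: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.psi1 < 1.0:
            raise ValueError("psi1 must lie in (0, 1)")
        if not 0.0 <= self.R < 1.0:
            raise ValueError("R must lie in [0, 1)")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        if int(self.K) != self.K or self.K < 2:
            raise ValueError("K must be an integer >= 2")
        if int(self.S) != self.S or self.S < 1:
            raise ValueError("S must be an integer >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def psi2(self) -> float:
        return self.psi1 * (1.0 - self.R)


@dataclass
class DesignEvaluation:
    """Power G and all intermediates for one (p, S, K, R) design."""

    inputs: PowerInputs
    pstar: float
    F1: float
    F2: float
    sigma1_sq: float
    sigma2_sq: float
    z: float
    G: float
    threshold: float = 0.8

    @property
    def feasible(self) -> bool:
        return self.G >= self.threshold


def power(inputs: PowerInputs, threshold: float = 0.8) -> DesignEvaluation:
    """Closed-form power of the before/after occupancy comparison.

    Both groups share S, K and p; only occupancy differs
    (psi2 = psi1 (1 - R)).  Returns G with every intermediate stored."""
    F = variance_inflation(inputs.p, int(inputs.K))
    pstar = cumulative_detection(inputs.p, inputs.K)
    psi1, psi2 = inputs.psi1, inputs.psi2
    s1 = psi1 * (1.0 - psi1 + F) / inputs.S
    s2 = psi2 * (1.0 - psi2 + F) / inputs.S
    sd = math.sqrt(s1 + s2)
    z = norm.ppf(1.0 - inputs.alpha / 2.0)
    diff = psi1 - psi2
    G = float(
        1.0 - norm.cdf((z * sd - diff) / sd) + norm.cdf((-z * sd - diff) / sd)
    )
    return DesignEvaluation(
        inputs=inputs, pstar=float(pstar), F1=F, F2=F,
        sigma1_sq=s1, sigma2_sq=s2, z=float(z), G=G, threshold=threshold,
    )


@dataclass
class DesignGrid:
    """Power over the cross-product of site counts, occasion counts and
    decline magnitudes for one method/detection probability."""

    frame: pd.DataFrame
    p: float
    psi1: float
    alpha: float
    threshold: float
    method: str | None = None

    @property
    def n_cells(self) -> int:
        return len(self.frame)

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "DesignGrid":
        frame = pd.read_csv(path)
        method = frame["method"].iloc[0] if "method" in frame else None
        if isinstance(method, float) and np.isnan(method):
            method = None
        return cls(
            frame=frame,
            p=float(frame.attrs.get("p", np.nan)) if frame.attrs else np.nan,
            psi1=np.nan, alpha=np.nan,
            threshold=0.8, method=method,
        )


def evaluate_grid(
    p: float,
    psi1: float,
    S_range=range(1, 201),
    K_range=range(2, 21),
    R_set=(0.3, 0.5, 0.8),
    alpha: float = 0.2,
    threshold: float = 0.8,
    method: str | None = None,
) -> DesignGrid:
    """Evaluate power on every (S, K, R) cell.  The default ranges
    (S=1..200, K=2..20, R in {0.3, 0.5, 0.8}) give 11,400 cells."""
    S_vals = np.asarray(sorted(set(int(s) for s in S_range)))
    K_vals = np.asarray(sorted(set(int(k) for k in K_range)))
    R_vals = np.asarray(sorted(set(float(r) for r in R_set)))
    if len(S_vals) == 0 or len(K_vals) == 0 or len(R_vals) == 0:
        raise ValueError("S, K and R ranges must be non-empty")
    if K_vals.min() < 2:
        raise ValueError("K range must not include values < 2")

    F_by_K = np.array([variance_inflation(p, int(k)) for k in K_vals])
    pstar_by_K = cumulative_detection(p, K_vals.astype(float))
    z = norm.ppf(1.0 - alpha / 2.0)

    # broadcast: axis order (R, K, S)
    Rg, Kg, Sg = np.meshgrid(R_vals, K_vals, S_vals, indexing="ij")
    Fg = F_by_K[None, :, None]
    psi2 = psi1 * (1.0 - Rg)
    s1 = psi1 * (1.0 - psi1 + Fg) / Sg
    s2 = psi2 * (1.0 - psi2 + Fg) / Sg
    sd = np.sqrt(s1 + s2)
    diff = psi1 - psi2
    G = 1.0 - norm.cdf((z * sd - diff) / sd) + norm.cdf((-z * sd - diff) / sd)

    frame = pd.DataFrame(
        {
            "method": method,
            "S": Sg.ravel(),
            "K": Kg.ravel(),
            "R": Rg.ravel(),
            "pstar": np.broadcast_to(pstar_by_K[None, :, None], Rg.shape).ravel(),
            "F": np.broadcast_to(Fg, Rg.shape).ravel(),
            "sigma1_sq": s1.ravel(),
            "sigma2_sq": s2.ravel(),
            "G": G.ravel(),
        }
    )
    frame["feasible"] = frame["G"] >= threshold
    return DesignGrid(frame=frame, p=p, psi1=psi1, alpha=alpha,
                      threshold=threshold, method=method)


def min_design_for_power(grid: DesignGrid, threshold: float = 0.8) -> dict[str, pd.DataFrame]:
    """Per decline magnitude R: the smallest K reaching the power
    threshold at each S, and the smallest S at each K.  Absence (no cell
    meets the threshold) is encoded as NaN, never raised."""
    frame = grid.frame
    feasible = frame[frame["G"] >= threshold]

    def _minimise(by: str, minimised: str) -> pd.DataFrame:
        full_index = pd.MultiIndex.from_product(
            [sorted(frame["R"].unique()), sorted(frame[by].unique())],
            names=["R", by],
        )
        if feasible.empty:
            out = pd.Series(np.nan, index=full_index, name=f"min_{minimised}")
        else:
            out = (
                feasible.groupby(["R", by])[minimised].min()
                .reindex(full_index)
                .rename(f"min_{minimised}")
            )
        return out.reset_index()

    return {"min_K_by_S": _minimise("S", "K"), "min_S_by_K": _minimise("K", "S")}
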