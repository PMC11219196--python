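"""Parametric-bootstrap goodness-of-fit for occupancy-detection models.

Two discrepancy statistics are computed per surveyed occasion against the
unconditional expectation e_ij = psi_hat * p_hat_ij:

* sum of squared errors,  SSE = sum (y_ij - e_ij)^2
* Freeman-Tukey,          FT  = sum (sqrt(y_ij) - sqrt(e_ij))^2

The null distribution of each statistic is built by simulating replicate
histories from the fitted model on the same site/occasion/covariate
layout, refitting the same spec, and recomputing the statistic.  The
p-value uses the add-one estimator p = (1 + #{T_b >= T_obs}) / (B + 1),
which can never be exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .occupancy import FitError, FitResult, OccupancyModel, design_matrix
from .survey_data import DetectionHistory


def _occasion_expectations(fit: FitResult, history: DetectionHistory):
    X, _, mask = design_matrix(fit.spec, history)
    y = history.frame["y"].to_numpy(dtype=float)[mask]
    p = expit(X[mask] @ fit.coef[1:])
    return y, p, mask


def gof_statistics(fit: FitResult, history: DetectionHistory) -> tuple[float, float]:
    """Observed (SSE, Freeman-Tukey) statistics; occasions the spec cannot
    use (missing covariates) are skipped, mirroring the likelihood."""
    if not fit.converged:
        raise FitError("fit did not converge; refit before assessing adequacy")
    if fit.boundary:
        raise FitError("fit is on the parameter boundary; refit before GOF")
    y, p, _ = _occasion_expectations(fit, history)
    e = fit.psi * p
    sse = float(np.sum((y - e) ** 2))
    ft = float(np.sum((np.sqrt(y) - np.sqrt(e)) ** 2))
    return sse, ft


@dataclass
class GofResult:
    sse_obs: float
    ft_obs: float
    B: int
    n_kept: int
    n_dropped: int
    sse_boot: np.ndarray
    ft_boot: np.ndarray
    p_sse: float
    p_ft: float
    seed: int
    high_drop_warning: bool = False
    expectation: str = "unconditional (psi_hat * p_hat)"

    def __post_init__(self) -> None:
        for p in (self.p_sse, self.p_ft):
            if not (0.0 < p <= 1.0):
                raise ValueError("bootstrap p-values must lie in (0, 1]")


def parametric_bootstrap(
    fit: FitResult,
    history: DetectionHistory,
    B: int = 10_000,
    seed: int = 0,
    refit_options: dict | None = None,
) -> GofResult:
    """Bootstrap both GOF statistics under the fitted model.

    Each replicate draws latent occupancy z_i ~ Bernoulli(psi_hat) and
    detections y_ij ~ Bernoulli(z_i * p_hat_ij) on the observed layout,
    refits the same spec (warm-started at the fitted coefficients, single
    start), and recomputes the statistics from the replicate fit.
    Non-converged replicates are dropped and counted; more than 20% drops
    flags a warning in the result.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sse_obs, ft_obs = gof_statistics(fit, history)

    frame = history.frame
    _, p_hat, mask = _occasion_expectations(fit, history)
    psi_hat = fit.psi
    site_of_row = frame["site"].to_numpy()[mask]
    sites = np.unique(frame["site"].to_numpy())
    site_idx = {s: i for i, s in enumerate(sites)}
    row_site = np.array([site_idx[s] for s in site_of_row])

    options = {"n_restarts": 0, "start": fit.coef, "gtol": 1e-6}
    options.update(refit_options or {})

    rng = np.random.default_rng(seed)
    sse_boot, ft_boot = [], []
    dropped = 0
    masked_positions = np.flatnonzero(mask)
    for _ in range(B):
        z = rng.random(len(sites)) < psi_hat
        y_rep = (rng.random(len(p_hat)) < p_hat) & z[row_site]
        rep_frame = frame.copy()
        y_col = rep_frame["y"].to_numpy().copy()
        y_col[masked_positions] = y_rep.astype(int)
        rep_frame["y"] = y_col
        rep_history = DetectionHistory(frame=rep_frame, scaler=history.scaler)
        try:
            rep_fit = OccupancyModel(spec=fit.spec, **options).fit(rep_history).result_
            if not rep_fit.converged or rep_fit.boundary:
                dropped += 1
                continue
            sse_b, ft_b = gof_statistics(rep_fit, rep_history)
        except FitError:
            dropped += 1
            continue
        sse_boot.append(sse_b)
        ft_boot.append(ft_b)

    n_kept = len(sse_boot)
    if n_kept == 0:
        raise FitError("all bootstrap replicates failed to refit")
    high_drop = dropped > 0.2 * B
    if high_drop:
        warnings.warn(
            f"{dropped}/{B} bootstrap replicates dropped (non-convergence)",
            stacklevel=2,
        )
    sse_boot = np.asarray(sse_boot)
    ft_boot = np.asarray(ft_boot)
    return GofResult(
        sse_obs=sse_obs,
        ft_obs=ft_obs,
        B=B,
        n_kept=n_kept,
        n_dropped=dropped,
        sse_boot=sse_boot,
        ft_boot=ft_boot,
        p_sse=(1.0 + np.sum(sse_boot >= sse_obs)) / (n_kept + 1.0),
        p_ft=(1.0 + np.sum(ft_boot >= ft_obs)) / (n_kept + 1.0),
        seed=seed,
        high_drop_warning=high_drop,
    )
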