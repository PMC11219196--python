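"""Single-season site occupancy-detection models.

The observation model treats each site's detection history as the outcome
of two simultaneous binomial processes: the site is occupied with
probability psi (held constant across sites and methods), and, given
occupancy, each surveyed occasion yields a detection with probability
p_ij.  The site likelihood is

    L_i = psi * prod_j p_ij^y_ij (1 - p_ij)^(1 - y_ij)
          + (1 - psi) * I(site i has no detections)

with logit links on both psi and p.  Detection covariates enter as a
method main effect (acoustic / drone / camera) optionally crossed with
linear or linear+quadratic weather terms; occupancy is intercept-only.
Models are ranked by AICc with the number of sites as the effective
sample size.

The fitting engine is :class:`OccupancyModel`, a scikit-learn style
estimator; :func:`fit` is a thin functional wrapper over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .survey_data import METHODS, DetectionHistory

_EPS = 1e-12
_BOUNDARY_LOGIT = 12.0

#: covariate block name -> (column base, polynomial order)
BLOCKS: dict[str, tuple[str, int]] = {
    "rain": ("rain", 1),
    "rh": ("rel_humidity", 1),
    "rh2": ("rel_humidity", 2),
    "temp": ("temp_max", 1),
    "temp2": ("temp_max", 2),
}


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Detection-side formula: method effect plus covariate blocks.

    ``blocks`` are drawn from ``rain, rh, rh2, temp, temp2``; a quadratic
    block always carries its linear term (standard nesting).  Occupancy is
    always intercept-only.
    """

    name: str
    method_effect: bool = True
    blocks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for b in self.blocks:
            if b not in BLOCKS:
                raise ValueError(f"unknown covariate block {b!r}")
        bases = {BLOCKS[b][0] for b in self.blocks}
        if len(bases) != len(self.blocks):
            raise ValueError("covariate blocks must use distinct covariates")
        if len(bases) > 2:
            raise ValueError("at most two weather covariates per model")
        if self.blocks and not self.method_effect:
            raise ValueError("covariate blocks require the method effect")

    @property
    def formula(self) -> str:
        if not self.method_effect:
            det = "p(.)"
        elif not self.blocks:
            det = "p(method)"
        else:
            det = "p(" + " + ".join(f"method x {b}" for b in self.blocks) + ")"
        return f"{det} psi(.)"

    def required_covariates(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(BLOCKS[b][0] for b in self.blocks))


def candidate_set() -> list[ModelSpec]:
    """The 15-model candidate set: null, method-only, the five single
    covariate-block models, and the eight admissible two-block
    combinations (each pairing two distinct weather covariates)."""
    singles = ["rain", "rh", "rh2", "temp", "temp2"]
    pairs = [
        ("rain", "rh"),
        ("rain", "rh2"),
        ("rain", "temp"),
        ("rain", "temp2"),
        ("rh", "temp"),
        ("rh", "temp2"),
        ("rh2", "temp"),
        ("rh2", "temp2"),
    ]
    specs = [ModelSpec("M1", method_effect=False), ModelSpec("M2")]
    for i, b in enumerate(singles, start=3):
        specs.append(ModelSpec(f"M{i}", blocks=(b,)))
    for i, pair in enumerate(pairs, start=8):
        specs.append(ModelSpec(f"M{i}", blocks=pair))
    return specs


def get_spec(name: str) -> ModelSpec:
    for spec in candidate_set():
        if spec.name == name:
            return spec
    raise KeyError(f"no candidate model named {name!r}")


def _zcolumn(frame: pd.DataFrame, base: str) -> np.ndarray:
    zcol = f"{base}_z"
    col = zcol if zcol in frame.columns else base
    if col not in frame.columns:
        raise FitError(f"history lacks covariate column {base!r}")
    return frame[col].to_numpy(dtype=float)


def design_matrix(
    spec: ModelSpec, history: DetectionHistory
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Detection design matrix, column names, and the row mask of
    occasions usable by this spec (occasions missing a needed covariate
    are excluded from covariate models)."""
    frame = history.frame
    n = len(frame)
    method = frame["method"].to_numpy()
    present = tuple(m for m in METHODS if m in set(method))

    cov_values = {}
    mask = np.ones(n, dtype=bool)
    for base in spec.required_covariates():
        z = _zcolumn(frame, base)
        cov_values[base] = z
        mask &= np.isfinite(z)

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["p:(intercept)"]
    if spec.method_effect:
        # treatment coding; first method present is the reference level
        for m in present[1:]:
            cols.append((method == m).astype(float))
            names.append(f"p:method[{m}]")
    for block in spec.blocks:
        base, order = BLOCKS[block]
        z = cov_values[base]
        for power_ in range(1, order + 1):
            term = z**power_
            label = base if power_ == 1 else f"{base}^2"
            for m in present:
                cols.append(term * (method == m))
                names.append(f"p:{label}[{m}]")
    X = np.column_stack(cols)
    return X, names, mask


@dataclass
class _SiteData:
    """Pre-packed arrays for fast repeated likelihood evaluation."""

    X: np.ndarray          # masked design matrix (rows usable by the spec)
    y: np.ndarray
    site_codes: np.ndarray  # 0..n_sites-1 aligned with X rows
    n_sites: int           # all sites in the history (incl. zero-row ones)

    @classmethod
    def build(cls, spec: ModelSpec, history: DetectionHistory) -> "_SiteData":
        X, _, mask = design_matrix(spec, history)
        frame = history.frame
        codes, _ = pd.factorize(frame["site"], sort=True)
        return cls(
            X=X[mask],
            y=frame["y"].to_numpy(dtype=float)[mask],
            site_codes=codes[mask],
            n_sites=int(frame["site"].nunique()),
        )

    def nll(self, params: np.ndarray) -> float:
        psi = expit(params[0])
        eta = self.X @ params[1:]
        if not np.all(np.isfinite(eta)):
            raise FitError("non-finite linear predictor")
        p = np.clip(expit(eta), _EPS, 1.0 - _EPS)
        logterms = self.y * np.log(p) + (1.0 - self.y) * np.log1p(-p)
        site_ll = np.bincount(self.site_codes, weights=logterms,
                              minlength=self.n_sites)
        detected = np.bincount(self.site_codes, weights=self.y,
                               minlength=self.n_sites) > 0
        lik = psi * np.exp(site_ll) + (1.0 - psi) * (~detected)
        return float(-np.sum(np.log(np.maximum(lik, _EPS))))


def neg_log_likelihood(
    params, spec: ModelSpec, history: DetectionHistory
) -> float:
    """Negative log-likelihood of the occupancy-detection model.

    ``params[0]`` is logit(psi); the remainder are detection coefficients
    in design-matrix order.  Occasions excluded by the spec's covariate
    mask (missing weather) contribute a factor of 1.
    """
    if history.n_occasions == 0:
        raise FitError("empty detection history")
    data = _SiteData.build(spec, history)
    params = np.asarray(params, dtype=float)
    expected = 1 + data.X.shape[1]
    if params.shape != (expected,):
        raise FitError(
            f"expected {expected} parameters for {spec.name}, got {params.shape}"
        )
    return data.nll(params)


def _numeric_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    h = step * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


@dataclass
class FitResult:
    """A fitted occupancy-detection model.

    Coefficients are on the logit scale; ``cov`` is the inverse observed
    information (None when the information matrix is singular or the fit
    sits on a boundary).  AICc uses the number of sites as the effective
    sample size (recorded in ``n_eff_convention``).
    """

    spec: ModelSpec
    coef: np.ndarray
    coef_names: list[str]
    cov: np.ndarray | None
    loglik: float
    n_params: int
    n_sites: int
    n_occasions_used: int
    aicc: float
    converged: bool
    boundary: bool
    data_hash: int
    methods: tuple[str, ...] = METHODS
    covariate_range: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_eff_convention: str = "sites"

    @property
    def psi(self) -> float:
        return float(expit(self.coef[0]))

    def se(self) -> np.ndarray | None:
        if self.cov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))


@dataclass
class DetectionEstimate:
    method: str
    covariates: dict[str, float]
    estimate: float
    lower: float | None
    upper: float | None

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if not (0 <= self.lower <= self.estimate <= self.upper <= 1):
                raise ValueError("detection CI must nest the estimate in [0,1]")


def _aicc(loglik: float, n_params: int, n_eff: int) -> float:
    aic = -2.0 * loglik + 2.0 * n_params
    denom = n_eff - n_params - 1
    if denom <= 0:
        return np.inf
    return aic + 2.0 * n_params * (n_params + 1) / denom


class OccupancyModel(BaseEstimator):
    """Maximum-likelihood single-season occupancy-detection estimator.

    Parameters
    ----------
    spec : str or ModelSpec, default "M2"
        Detection formula; a name from :func:`candidate_set` or an
        explicit :class:`ModelSpec`.
    n_restarts : int
        Multi-start restarts with seeded Gaussian jitter (sd
        ``jitter_sd`` on the link scale) around the deterministic start.
    gtol : float
        Gradient-norm tolerance passed to the quasi-Newton optimizer.
    seed : int
        Seed for the restart jitter only; the fit is deterministic.
    start : array or None
        Optional explicit starting vector (used for warm-started refits,
        e.g. bootstrap replicates); skips the deterministic default.

    After ``fit(history)`` the estimator exposes ``result_`` (a
    :class:`FitResult`) plus the usual fitted attributes ``coef_``,
    ``cov_``, ``loglik_``, ``aicc_``, ``converged_``.
    """

    def __init__(self, spec="M2", n_restarts=5, jitter_sd=0.5, gtol=1e-8,
                 seed=0, start=None):
        self.spec = spec
        self.n_restarts = n_restarts
        self.jitter_sd = jitter_sd
        self.gtol = gtol
        self.seed = seed
        self.start = start

    def _resolved_spec(self) -> ModelSpec:
        return get_spec(self.spec) if isinstance(self.spec, str) else self.spec

    def fit(self, X: DetectionHistory, y=None) -> "OccupancyModel":
        if not isinstance(X, DetectionHistory):
            raise TypeError("X must be a DetectionHistory")
        if X.n_occasions == 0:
            raise FitError("empty detection history")
        occ_per_site = X.frame.groupby("site").size()
        if (occ_per_site < 2).all():
            raise FitError("need at least one site with >= 2 occasions")

        spec = self._resolved_spec()
        data = _SiteData.build(spec, X)
        if data.X.shape[0] == 0:
            raise FitError("no occasions usable by this spec (covariates missing)")
        n_par = 1 + data.X.shape[1]

        starts = []
        if self.start is not None:
            starts.append(np.asarray(self.start, dtype=float))
        else:
            starts.append(self._default_start(X, n_par))
        rng = np.random.default_rng(self.seed)
        for _ in range(self.n_restarts):
            starts.append(starts[0] + rng.normal(0.0, self.jitter_sd, n_par))

        best = None
        for x0 in starts:
            res = minimize(data.nll, x0, method="BFGS",
                           options={"gtol": self.gtol, "maxiter": 500})
            if best is None or res.fun < best.fun - 1e-10:
                best = res

        coef = best.x
        grad_norm = float(np.max(np.abs(best.jac)))
        converged = bool(best.success or grad_norm < 1e-3)
        boundary = bool(np.any(np.abs(coef) > _BOUNDARY_LOGIT))

        cov = None
        if converged and not boundary:
            H = _numeric_hessian(data.nll, coef)
            try:
                cov = np.linalg.inv(H)
                if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
                    cov = None
            except np.linalg.LinAlgError:
                cov = None

        _, names, mask = design_matrix(spec, X)
        cov_range = {}
        for base in spec.required_covariates():
            z = _zcolumn(X.frame, base)[mask]
            cov_range[base] = (float(np.nanmin(z)), float(np.nanmax(z)))

        loglik = -best.fun
        self.result_ = FitResult(
            spec=spec,
            coef=coef,
            coef_names=["psi:(intercept)"] + names,
            cov=cov,
            loglik=loglik,
            n_params=n_par,
            n_sites=data.n_sites,
            n_occasions_used=int(data.X.shape[0]),
            aicc=_aicc(loglik, n_par, data.n_sites),
            converged=converged,
            boundary=boundary,
            data_hash=X.data_hash(),
            methods=tuple(
                m for m in METHODS if m in set(X.frame["method"].to_numpy())
            ),
            covariate_range=cov_range,
        )
        self.coef_ = coef
        self.cov_ = cov
        self.loglik_ = loglik
        self.aicc_ = self.result_.aicc
        self.converged_ = converged
        return self

    @staticmethod
    def _default_start(history: DetectionHistory, n_par: int) -> np.ndarray:
        frame = history.frame
        naive_psi = frame.groupby("site")["y"].max().mean()
        naive_p = frame["y"].mean()
        x0 = np.zeros(n_par)
        x0[0] = logit(np.clip(naive_psi, 0.05, 0.95))
        x0[1] = logit(np.clip(naive_p, 0.01, 0.99))
        return x0

    def predict_detection(self, method: str,
                          covariates=None) -> DetectionEstimate:
        return predict_detection(self.result_, method, covariates)


def fit(spec, history: DetectionHistory, **options) -> FitResult:
    """Fit one model spec by maximum likelihood; wrapper over
    :class:`OccupancyModel`."""
    return OccupancyModel(spec=spec, **options).fit(history).result_


def fit_candidates(history: DetectionHistory, specs=None, **options) -> list[FitResult]:
    specs = candidate_set() if specs is None else specs
    return [fit(s, history, **options) for s in specs]


def rank_models(fits: list[FitResult]) -> pd.DataFrame:
    """AICc ranking table: n, AICc, dAICc, Akaike weight, cumulative weight."""
    if not fits:
        raise ValueError("no fits to rank")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were computed on different datasets")
    table = pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "formula": [f.spec.formula for f in fits],
            "n": [f.n_params for f in fits],
            "AICc": [f.aicc for f in fits],
        }
    ).sort_values("AICc", kind="stable").reset_index(drop=True)
    table["dAICc"] = table["AICc"] - table["AICc"].iloc[0]
    rel = np.exp(-0.5 * table["dAICc"].to_numpy())
    table["weight"] = rel / rel.sum()
    table["cum_weight"] = table["weight"].cumsum()
    return table


def predict_detection(fit_result: FitResult, method: str,
                      covariates=None) -> DetectionEstimate:
    """Daily detection probability for one method at given z-scored
    covariate values, with a 95% delta-method CI computed on the link
    scale and back-transformed (hence always inside [0, 1])."""
    if not fit_result.converged:
        raise FitError("cannot predict from a non-converged fit")
    if method not in fit_result.methods:
        raise ValueError(
            f"method {method!r} was not in the fitted data "
            f"(fitted methods: {fit_result.methods})"
        )
    covariates = dict(covariates or {})
    spec = fit_result.spec

    for base, (lo, hi) in fit_result.covariate_range.items():
        val = covariates.get(base, 0.0)
        if val < lo or val > hi:
            warnings.warn(
                f"{base}={val} outside fitted support [{lo:.2f}, {hi:.2f}]",
                stacklevel=2,
            )

    x = np.zeros(fit_result.n_params)  # index 0 is psi, never set
    idx = 1
    x[idx] = 1.0  # detection intercept
    idx += 1
    if spec.method_effect:
        for m in fit_result.methods[1:]:
            x[idx] = 1.0 if method == m else 0.0
            idx += 1
    for block in spec.blocks:
        base, order = BLOCKS[block]
        z = float(covariates.get(base, 0.0))
        for power_ in range(1, order + 1):
            for m in fit_result.methods:
                x[idx] = (z**power_) if m == method else 0.0
                idx += 1

    eta = float(x[1:] @ fit_result.coef[1:])
    est = float(expit(eta))
    lower = upper = None
    if fit_result.cov is not None:
        var = float(x @ fit_result.cov @ x)
        if var >= 0 and np.isfinite(var):
            half = norm.ppf(0.975) * np.sqrt(var)
            lower = float(expit(eta - half))
            upper = float(expit(eta + half))
    return DetectionEstimate(
        method=method, covariates=covariates, estimate=est,
        lower=lower, upper=upper,
    )


def psi_estimate(fit_result: FitResult) -> tuple[float, float | None, float | None]:
    """Occupancy estimate with a 95% Wald CI on the logit scale."""
    est = fit_result.psi
    if fit_result.cov is None:
        return est, None, None
    se = float(np.sqrt(max(fit_result.cov[0, 0], 0.0)))
    half = norm.ppf(0.975) * se
    return est, float(expit(fit_result.coef[0] - half)), float(
        expit(fit_result.coef[0] + half)
    )
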