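"""The standard dichotomous (quantal) model suite and binomial MLE fitting.

Eight response models map dose d >= 0 to a probability of effect, each
constrained so the curve is non-decreasing in dose:

    logistic        p(d) = 1 / (1 + exp(-(a + b d)))
    gamma           p(d) = g + (1-g) * G(b d; a)          (G: unit-scale gamma CDF)
    weibull         p(d) = g + (1-g) * (1 - exp(-b d^a))
    log_logistic    p(d) = g + (1-g) / (1 + exp(-(a + b ln d)))
    probit          p(d) = Phi(a + b d)
    log_probit      p(d) = g + (1-g) * Phi(a + b ln d)
    multistage2     p(d) = g + (1-g) * (1 - exp(-(b d + b2 d^2)))
    quantal_linear  p(d) = g + (1-g) * (1 - exp(-b d))

g in [0, 1) is the background response; slopes are constrained >= 0; the
gamma shape, weibull power and log-probit slope are box-bounded to
[0.2, 18] to exclude degenerate spike fits.  logistic and probit have no
explicit background term; their dose-0 value 1/(1+e^-a) resp. Phi(a)
plays that role.  Log-dose models take the value g at d = 0 by
continuity.

Fitting maximizes the binomial log-likelihood of the pooled
affected/total counts (binomial coefficients omitted — constant in the
parameters) with L-BFGS-B from several deterministic starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .core_data import DoseResponseGroup

P_CLIP = 1e-9  # probability clip for the likelihood
_SLOPE_MAX = 1e4  # generous cap keeping the optimizer on a finite box
_POWER_BOUNDS = (0.2, 18.0)
_G_BOUNDS = (0.0, 1.0 - 1e-6)


@dataclass(frozen=True)
class ModelSpec:
    name: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _phi(z):
    return stats.norm.cdf(z)


def _expit(z):
    return special.expit(z)


def _safe_log(d):
    d = np.asarray(d, float)
    with np.errstate(divide="ignore"):
        return np.where(d > 0, np.log(np.where(d > 0, d, 1.0)), -np.inf)


def _logistic(params, d):
    a, b = params
    return _expit(a + b * d)


def _gamma(params, d):
    g, a, b = params
    return g + (1 - g) * special.gammainc(a, b * np.asarray(d, float))


def _weibull(params, d):
    g, a, b = params
    d = np.asarray(d, float)
    return g + (1 - g) * -np.expm1(-b * d**a)


def _log_logistic(params, d):
    g, a, b = params
    ld = _safe_log(d)
    at_zero = ld == -np.inf
    inner = a + b * np.where(at_zero, 0.0, ld)  # avoid 0 * -inf
    return np.where(at_zero, g, g + (1 - g) * _expit(inner))


def _probit(params, d):
    a, b = params
    return _phi(a + b * np.asarray(d, float))


def _log_probit(params, d):
    g, a, b = params
    ld = _safe_log(d)
    at_zero = ld == -np.inf
    inner = a + b * np.where(at_zero, 0.0, ld)
    return np.where(at_zero, g, g + (1 - g) * _phi(inner))


def _multistage2(params, d):
    g, b, b2 = params
    d = np.asarray(d, float)
    return g + (1 - g) * -np.expm1(-(b * d + b2 * d**2))


def _quantal_linear(params, d):
    g, b = params
    return g + (1 - g) * -np.expm1(-b * np.asarray(d, float))


#: registry in the conventional EPA listing order (used for tie-breaks)
MODELS: dict[str, ModelSpec] = {
    "logistic": ModelSpec("logistic", ("a", "b"), ((-50.0, 50.0), (0.0, _SLOPE_MAX))),
    "gamma": ModelSpec("gamma", ("g", "a", "b"), (_G_BOUNDS, _POWER_BOUNDS, (0.0, _SLOPE_MAX))),
    "weibull": ModelSpec("weibull", ("g", "a", "b"), (_G_BOUNDS, _POWER_BOUNDS, (0.0, _SLOPE_MAX))),
    "log_logistic": ModelSpec(
        "log_logistic", ("g", "a", "b"), (_G_BOUNDS, (-50.0, 50.0), (0.0, 18.0))
    ),
    "probit": ModelSpec("probit", ("a", "b"), ((-20.0, 20.0), (0.0, _SLOPE_MAX))),
    "log_probit": ModelSpec(
        "log_probit", ("g", "a", "b"), (_G_BOUNDS, (-20.0, 20.0), _POWER_BOUNDS)
    ),
    "multistage2": ModelSpec(
        "multistage2", ("g", "b", "b2"), (_G_BOUNDS, (0.0, _SLOPE_MAX), (0.0, _SLOPE_MAX))
    ),
    "quantal_linear": ModelSpec("quantal_linear", ("g", "b"), (_G_BOUNDS, (0.0, _SLOPE_MAX))),
}

MODEL_ORDER = tuple(MODELS)

_CURVES = {
    "logistic": _logistic,
    "gamma": _gamma,
    "weibull": _weibull,
    "log_logistic": _log_logistic,
    "probit": _probit,
    "log_probit": _log_probit,
    "multistage2": _multistage2,
    "quantal_linear": _quantal_linear,
}


def _check_params(name: str, params) -> np.ndarray:
    spec = MODELS[name]
    params = np.asarray(params, float)
    if params.shape != (spec.n_params,):
        raise ValueError(f"{name} expects {spec.n_params} parameters {spec.param_names}")
    for value, (lo, hi), pname in zip(params, spec.bounds, spec.param_names):
        if not (lo <= value <= hi):
            raise ValueError(f"{name} parameter {pname}={value} outside [{lo}, {hi}]")
    return params


def response_probability(name: str, params, dose) -> np.ndarray | float:
    """Evaluate a model curve at the given dose(s); validates constraints."""
    params = _check_params(name, params)
    scalar = np.isscalar(dose)
    p = _CURVES[name](params, np.atleast_1d(np.asarray(dose, float)))
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if scalar else p


def background(name: str, params) -> float:
    """p(0): the explicit g, or the curve value at dose 0 for logistic/probit."""
    return float(response_probability(name, params, 0.0))


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------


def _nll_arrays(p: np.ndarray, x: np.ndarray, n: np.ndarray) -> float:
    p = np.clip(p, P_CLIP, 1 - P_CLIP)
    return float(-np.sum(x * np.log(p) + (n - x) * np.log1p(-p)))


def neg_log_likelihood(name: str, params, group: DoseResponseGroup) -> float:
    """Binomial negative log-likelihood (nats, binomial coefficients omitted).

    Probabilities are clipped to [1e-9, 1 - 1e-9] so impossible
    observations yield a large finite penalty rather than -inf.
    """
    params = _check_params(name, params)
    d = group.concentrations
    x = group.doses["affected"].to_numpy(float)
    n = group.doses["total"].to_numpy(float)
    return _nll_arrays(_CURVES[name](params, d), x, n)


def saturated_nll(group: DoseResponseGroup) -> float:
    """NLL of the saturated model (p_i = observed proportion); the attainable floor."""
    x = group.doses["affected"].to_numpy(float)
    n = group.doses["total"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(x / n), 0.0) + np.where(
            n - x > 0, (n - x) * np.log1p(-x / n), 0.0
        )
    return float(-terms.sum())


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass(eq=False)
class FittedModel:
    """One model's MLE fit to a group."""

    model: str
    params: np.ndarray
    log_likelihood: float
    aic: float
    converged: bool
    n_params: int
    clipped: bool = False
    flags: list[str] = field(default_factory=list)
    gof_statistic: float = float("nan")
    gof_pvalue: float = float("nan")

    def predict(self, dose):
        return response_probability(self.model, self.params, dose)

    @property
    def background(self) -> float:
        return background(self.model, self.params)


def _heuristic_start(name: str, group: DoseResponseGroup) -> np.ndarray:
    """Moment-style starting values from the observed response pattern."""
    d = group.concentrations
    r = group.response
    g0 = float(np.clip(group.control_response() if not np.isnan(group.control_response()) else r.min(), 1e-3, 0.8))
    pos = d > 0
    dmax = float(d[pos].max()) if pos.any() else 1.0
    rmax = float(np.clip(r.max(), g0 + 1e-3, 1 - 1e-3))
    # dose at which the response is halfway between background and maximum
    half = g0 + 0.5 * (rmax - g0)
    above = d[pos][r[pos] >= half] if pos.any() else np.array([])
    d50 = float(above.min()) if above.size else dmax / 2 or 1.0
    extra = np.clip((rmax - g0) / (1 - g0), 1e-3, 1 - 1e-3)
    lam = -np.log1p(-extra) / dmax  # quantal-linear scale for rmax at dmax
    logit = special.logit
    if name == "logistic":
        a0 = logit(np.clip(g0, 1e-3, 0.5))
        return np.array([a0, (logit(rmax) - a0) / dmax])
    if name == "probit":
        a0 = stats.norm.ppf(np.clip(g0, 1e-3, 0.5))
        return np.array([a0, (stats.norm.ppf(rmax) - a0) / dmax])
    if name == "log_logistic":
        return np.array([g0, -np.log(d50), 1.0])
    if name == "log_probit":
        return np.array([g0, -np.log(d50), 1.0])
    if name == "gamma":
        return np.array([g0, 1.0, lam])
    if name == "weibull":
        return np.array([g0, 1.0, lam])
    if name == "multistage2":
        return np.array([g0, lam, 1e-6])
    if name == "quantal_linear":
        return np.array([g0, lam])
    raise KeyError(name)


def _clip_to_bounds(x: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.minimum(np.maximum(x, lo + 1e-10), hi - 1e-10)


def fit_model(
    group: DoseResponseGroup, name: str, seed: int = 0, n_starts: int = 5
) -> FittedModel:
    """Constrained binomial MLE for one model on one group.

    L-BFGS-B from a moment-style heuristic start plus deterministic
    perturbations drawn from a seeded generator; the best-NLL converged
    run wins (ties: first).  AIC = 2k + 2*NLL with k = number of free
    parameters.
    """
    spec = MODELS[name]
    d = group.concentrations
    x = group.doses["affected"].to_numpy(float)
    n = group.doses["total"].to_numpy(float)
    curve = _CURVES[name]

    def objective(theta):
        return _nll_arrays(curve(theta, d), x, n)

    base = _clip_to_bounds(_heuristic_start(name, group), spec.bounds)
    rng = np.random.default_rng([seed % (2**31), MODEL_ORDER.index(name)])
    starts = [base]
    for _ in range(n_starts - 1):
        pert = base * rng.lognormal(0.0, 0.5, size=base.shape) + rng.normal(0, 0.1, base.shape)
        starts.append(_clip_to_bounds(pert, spec.bounds))

    best = None
    for s in starts:
        res = optimize.minimize(objective, s, method="L-BFGS-B", bounds=spec.bounds)
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        return FittedModel(name, base, float("nan"), float("nan"), False, spec.n_params,
                           flags=["no_start_converged"])

    params = _clip_to_bounds(np.asarray(best.x, float), spec.bounds)
    nll = objective(params)
    k = spec.n_params
    fitted = FittedModel(
        model=name,
        params=params,
        log_likelihood=-nll,
        aic=2 * k + 2 * nll,
        converged=True,
        n_params=k,
        clipped=bool(np.any((curve(params, d) < P_CLIP) | (curve(params, d) > 1 - P_CLIP))),
    )
    slopes = [p for pn, p in zip(spec.param_names, params) if pn in ("b", "b2")]
    if all(s <= 1e-8 for s in slopes):
        fitted.flags.append("no_concentration_effect")
    return fitted


def fit_all_models(
    group: DoseResponseGroup, names: tuple[str, ...] = MODEL_ORDER, seed: int = 0
) -> list[FittedModel]:
    return [fit_model(group, name, seed=seed) for name in names]
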