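"""Model selection and benchmark-dose computation.

Workflow per group, following the EPA dichotomous guidance: fit the
model suite, drop fits failing the Pearson chi-square goodness-of-fit
screen (p < 0.1), restrict to models within 2 AIC of the best, compute
each candidate's BMDL, and select the candidate with the smallest BMDL.

The benchmark dose at benchmark response ``bmr`` uses the extra-risk
convention by default:

    extra risk at dose d  =  (p(d) - p(0)) / (1 - p(0))

BMD10/BMD50 are the doses at bmr = 0.10/0.50.  The BMDL is the
profile-likelihood lower confidence bound at the 95% one-sided level:
the smallest BMD among parameter vectors whose deviance lies within
chi2(1, 0.90) = 2.706 of the MLE deviance, found by bisection on the
BMD axis with the slope-like parameter re-expressed in terms of the BMD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_data import DoseResponseGroup
from .models import (
    MODEL_ORDER,
    MODELS,
    FittedModel,
    P_CLIP,
    _CURVES,
    _nll_arrays,
    fit_all_models,
    response_probability,
)

logger = logging.getLogger("bmdkit")

GOF_ALPHA = 0.1
AIC_WINDOW = 2.0
DEFAULT_BMRS = (0.10, 0.50)
_FLAT_SLOPE = 1e-8


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------


def goodness_of_fit(fit: FittedModel, group: DoseResponseGroup) -> tuple[float, float]:
    """Pearson chi-square GOF against the pooled dose-group counts.

    statistic = sum_i (x_i - n_i p_i)^2 / (n_i p_i (1 - p_i)), df =
    (#doses - #free parameters).  Returns (statistic, p); p is NaN when
    df <= 0 (the fit is then kept but flagged rather than screened).
    """
    x = group.doses["affected"].to_numpy(float)
    n = group.doses["total"].to_numpy(float)
    p = np.clip(fit.predict(group.concentrations), P_CLIP, 1 - P_CLIP)
    statistic = float(np.sum((x - n * p) ** 2 / (n * p * (1 - p))))
    df = len(x) - fit.n_params
    if df <= 0:
        return statistic, float("nan")
    return statistic, float(stats.chi2.sf(statistic, df))


def screen_fits(
    fits: list[FittedModel], group: DoseResponseGroup, alpha: float = GOF_ALPHA
) -> list[FittedModel]:
    """Attach GOF results and drop converged fits with p < alpha.

    Fits with undefined p (no residual degrees of freedom) are retained
    with a flag; unconverged fits are dropped outright.
    """
    passing = []
    for fit in fits:
        if not fit.converged:
            continue
        fit.gof_statistic, fit.gof_pvalue = goodness_of_fit(fit, group)
        if np.isnan(fit.gof_pvalue):
            fit.flags.append("gof_undefined")
            passing.append(fit)
        elif fit.gof_pvalue >= alpha:
            passing.append(fit)
    return passing


def aic_window(fits: list[FittedModel], window: float = AIC_WINDOW) -> list[FittedModel]:
    """Fits with AIC within ``window`` of the minimum (inclusive)."""
    if not fits:
        return []
    best = min(f.aic for f in fits)
    return [f for f in fits if f.aic <= best + window]


# --------------------------------------------------------------------------
# benchmark dose
# --------------------------------------------------------------------------


def extra_risk(fit: FittedModel, dose) -> np.ndarray | float:
    p0 = fit.background
    return (fit.predict(dose) - p0) / (1.0 - p0)


def added_risk(fit: FittedModel, dose) -> np.ndarray | float:
    return fit.predict(dose) - fit.background


def _is_flat(fit: FittedModel) -> bool:
    spec = MODELS[fit.model]
    slopes = [p for pn, p in zip(spec.param_names, fit.params) if pn in ("b", "b2")]
    return all(s <= _FLAT_SLOPE for s in slopes)


def bmd_at_bmr(
    fit: FittedModel,
    bmr: float = 0.10,
    risk: str = "extra",
    method: str = "auto",
    max_dose: float | None = None,
) -> float:
    """Dose at which the fitted curve reaches the benchmark response.

    Closed forms are used for quantal_linear and weibull; the remaining
    models are solved by monotone root-finding (brentq, relative
    tolerance 1e-10), bracketing upward from zero.  Flat fits (slope ~ 0)
    return NaN: no dose produces the benchmark response.
    ``method='numeric'`` forces root-finding for every model (used to
    cross-check the closed forms).
    """
    if not 0 < bmr < 1:
        raise ValueError("bmr must be in (0, 1)")
    if _is_flat(fit):
        return float("nan")
    name, params = fit.model, fit.params

    if method != "numeric" and risk == "extra":
        if name == "quantal_linear":
            g, b = params
            return float(-np.log1p(-bmr) / b)
        if name == "weibull":
            g, a, b = params
            return float((-np.log1p(-bmr) / b) ** (1.0 / a))

    riskfun = extra_risk if risk == "extra" else added_risk
    if risk == "added" and bmr >= 1 - fit.background:
        return float("nan")  # added risk cannot exceed 1 - p(0)

    def f(d):
        return riskfun(fit, d) - bmr

    hi = max_dose or 1.0
    for _ in range(200):
        if f(hi) >= 0:
            break
        hi *= 2.0
    else:
        return float("nan")
    lo = hi * 1e-12
    while f(lo) > 0 and lo > 1e-300:
        lo *= 1e-3
    if f(lo) > 0:
        return float("nan")
    return float(optimize.brentq(f, lo, hi, rtol=1e-10, maxiter=200))


# --------------------------------------------------------------------------
# BMDL: profile likelihood
# --------------------------------------------------------------------------

# For the profile, one parameter is re-expressed in terms of the BMD so the
# constraint "BMD(theta) = d" is exact.  _PROFILE_SOLVED names that
# parameter per model; _params_from_bmd reconstructs the full vector from
# the free ones.  All solutions below are for EXTRA risk.


def _params_from_bmd(name: str, free: np.ndarray, d: float, bmr: float) -> np.ndarray | None:
    """Full parameter vector with the slope-like parameter solved from BMD = d.

    Returns None when no feasible (in-bounds) solution exists at this d.
    """
    A = -np.log1p(-bmr)  # common "hazard at BMD" term for exponential-family forms
    if name == "quantal_linear":
        (g,) = free
        return np.array([g, A / d])
    if name == "weibull":
        g, a = free
        return np.array([g, a, A / d**a])
    if name == "gamma":
        g, a = free
        return np.array([g, a, special.gammaincinv(a, bmr) / d])
    if name == "multistage2":
        g, b2 = free
        b = (A - b2 * d**2) / d
        if b < 0:
            return None
        return np.array([g, b, b2])
    if name == "log_logistic":
        g, b = free
        return np.array([g, special.logit(bmr) - b * np.log(d), b])
    if name == "log_probit":
        g, b = free
        return np.array([g, stats.norm.ppf(bmr) - b * np.log(d), b])
    if name == "logistic":
        (a,) = free
        p0 = special.expit(a)
        pt = p0 + bmr * (1 - p0)
        b = (special.logit(pt) - a) / d
        if b < 0:
            return None
        return np.array([a, b])
    if name == "probit":
        (a,) = free
        p0 = stats.norm.cdf(a)
        pt = p0 + bmr * (1 - p0)
        b = (stats.norm.ppf(pt) - a) / d
        if b < 0:
            return None
        return np.array([a, b])
    raise KeyError(name)


def _profile_free_indices(name: str) -> list[int]:
    """Indices (into the model's parameter vector) that stay free in the profile."""
    solved = {"quantal_linear": "b", "weibull": "b", "gamma": "b", "multistage2": "b",
              "log_logistic": "a", "log_probit": "a", "logistic": "b", "probit": "b"}[name]
    return [i for i, pn in enumerate(MODELS[name].param_names) if pn != solved]


def _profile_nll(
    name: str, group: DoseResponseGroup, d: float, bmr: float, start_free: np.ndarray
) -> tuple[float, np.ndarray]:
    """min over free params of NLL subject to BMD(params) = d."""
    spec = MODELS[name]
    free_idx = _profile_free_indices(name)
    free_bounds = [spec.bounds[i] for i in free_idx]
    x = group.doses["affected"].to_numpy(float)
    n = group.doses["total"].to_numpy(float)
    doses = group.concentrations
    curve = _CURVES[name]
    slope_bounds = dict(zip(spec.param_names, spec.bounds))

    def objective(free):
        params = _params_from_bmd(name, free, d, bmr)
        if params is None:
            return 1e10
        # keep the solved parameter inside its own box
        for pn, val, (lo, hi) in zip(spec.param_names, params, spec.bounds):
            if not (lo - 1e-12 <= val <= hi + 1e-12):
                return 1e10
        return _nll_arrays(curve(params, doses), x, n)

    if not free_idx:
        return objective(np.array([])), np.array([])
    res = optimize.minimize(
        objective, start_free, method="L-BFGS-B", bounds=free_bounds
    )
    fun = objective(res.x)
    return float(fun), np.asarray(res.x, float)


def bmdl(
    fit: FittedModel,
    group: DoseResponseGroup,
    bmr: float = 0.10,
    level: float = 0.95,
    rel_tol: float = 1e-3,
) -> float:
    """Profile-likelihood lower confidence bound on the BMD.

    The one-sided ``level`` bound accepts parameter vectors whose
    deviance exceeds the MLE deviance by at most chi2_1(2*level - 1)
    (2.706 at 95%); the BMDL is the smallest constrained BMD still
    accepted, located by bisection in log-dose.  Returns NaN when the
    profile cannot be bracketed.
    """
    bmd_mle = bmd_at_bmr(fit, bmr)
    if not np.isfinite(bmd_mle) or bmd_mle <= 0:
        return float("nan")
    name = fit.model
    target = -fit.log_likelihood + stats.chi2.ppf(2 * level - 1, 1) / 2.0

    free_idx = _profile_free_indices(name)
    start = fit.params[free_idx]

    def excess(d, start_free):
        nll, sol = _profile_nll(name, group, d, bmr, start_free)
        return nll - target, sol

    # walk down from the MLE until the profile crosses the cutoff
    hi = bmd_mle
    e_hi, sol = excess(hi * (1 - 1e-9), start)
    if e_hi > 0:  # numerical wobble at the MLE itself
        e_hi = -1e-12
    lo = None
    d = bmd_mle
    floor = bmd_mle * 1e-8
    while d > floor:
        d /= 4.0
        e, sol = excess(d, sol)
        if e > 0:
            lo = d
            break
        hi = d
        e_hi = e
    if lo is None:
        # likelihood stays flat all the way down; no finite lower bound found
        logger.warning("BMDL profile for %s did not bracket above %.3g", name, floor)
        return float("nan")

    # bisection in log d between lo (outside region) and hi (inside region)
    llo, lhi = np.log(lo), np.log(hi)
    for _ in range(60):
        if lhi - llo < rel_tol:
            break
        mid = 0.5 * (llo + lhi)
        e, sol = excess(np.exp(mid), sol)
        if e > 0:
            llo = mid
        else:
            lhi = mid
    return float(min(np.exp(lhi), bmd_mle))


# --------------------------------------------------------------------------
# winner selection
# --------------------------------------------------------------------------


@dataclass(eq=False)
class BMDResult:
    """Selected model and benchmark doses for one (chemical, endpoint) group."""

    chemical_id: object
    endpoint: str
    status: str  # fitted | no_candidate | not_fit
    selected_model: str | None = None
    bmd10: float = float("nan")
    bmdl: float = float("nan")
    bmd50: float = float("nan")
    aic: float = float("nan")
    gof_pvalue: float = float("nan")
    params: np.ndarray | None = None
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)
    flags: list[str] = field(default_factory=list)


def select_winner(
    candidates: list[FittedModel],
    bmdls: list[float],
    bmds: list[float],
) -> tuple[FittedModel | None, list[str]]:
    """Smallest-BMDL rule with deterministic tie-breaks.

    Ties on BMDL go to the lower AIC, then to the conventional model
    listing order.  When every BMDL is NA the lowest-AIC candidate wins,
    flagged ``bmdl_unavailable``.
    """
    flags: list[str] = []
    usable = [
        (b, f.aic, MODEL_ORDER.index(f.model), f)
        for f, b, d in zip(candidates, bmdls, bmds)
        if np.isfinite(b)
    ]
    if usable:
        usable.sort(key=lambda t: (t[0], t[1], t[2]))
        return usable[0][3], flags
    with_bmd = [
        (f.aic, MODEL_ORDER.index(f.model), f)
        for f, d in zip(candidates, bmds)
        if np.isfinite(d)
    ]
    if with_bmd:
        with_bmd.sort(key=lambda t: (t[0], t[1]))
        flags.append("bmdl_unavailable")
        return with_bmd[0][2], flags
    return None, flags


def analyze_group(
    group: DoseResponseGroup,
    models: tuple[str, ...] = MODEL_ORDER,
    bmrs: tuple[float, float] = DEFAULT_BMRS,
    gof_alpha: float = GOF_ALPHA,
    window: float = AIC_WINDOW,
    level: float = 0.95,
    risk: str = "extra",
    seed: int = 0,
) -> BMDResult:
    """Full fit/screen/select pass for one group.

    Status ``no_candidate``: nothing converged or everything failed the
    GOF screen.  Status ``not_fit``: candidates exist but none produces
    the benchmark response (flat response — the treatment shows no
    concentration effect, so no curve is reported).
    """
    bmr_low, bmr_high = bmrs
    fits = fit_all_models(group, models, seed=seed)
    passing = screen_fits(fits, group, alpha=gof_alpha)

    def cand_table(cands, bmds=None, bmdls=None):
        rows = []
        for i, f in enumerate(cands):
            rows.append(
                {
                    "model": f.model,
                    "aic": f.aic,
                    "gof_statistic": f.gof_statistic,
                    "gof_pvalue": f.gof_pvalue,
                    "bmd10": bmds[i] if bmds else float("nan"),
                    "bmdl": bmdls[i] if bmdls else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    if not passing:
        return BMDResult(
            group.chemical_id, group.endpoint, "no_candidate",
            candidates=cand_table([f for f in fits if f.converged]),
            flags=["all_failed_gof" if any(f.converged for f in fits) else "no_convergence"],
        )

    cands = aic_window(passing, window)
    bmds = [bmd_at_bmr(f, bmr_low, risk=risk) for f in cands]
    # a BMD far beyond the tested range means the benchmark response is not
    # attained where there is data: treat the curve as showing no effect
    max_dose = float(group.concentrations.max())
    bmds = [
        d if np.isfinite(d) and d <= 10.0 * max_dose else float("nan") for d in bmds
    ]
    bmdls = [
        bmdl(f, group, bmr_low, level=level) if np.isfinite(d) else float("nan")
        for f, d in zip(cands, bmds)
    ]
    winner, flags = select_winner(cands, bmdls, bmds)
    table = cand_table(cands, bmds, bmdls)
    if winner is None:
        return BMDResult(
            group.chemical_id, group.endpoint, "not_fit", candidates=table,
            flags=flags + ["no_concentration_effect"],
        )
    i = cands.index(winner)
    return BMDResult(
        chemical_id=group.chemical_id,
        endpoint=group.endpoint,
        status="fitted",
        selected_model=winner.model,
        bmd10=bmds[i],
        bmdl=bmdls[i],
        bmd50=bmd_at_bmr(winner, bmr_high, risk=risk),
        aic=winner.aic,
        gof_pvalue=winner.gof_pvalue,
        params=winner.params,
        candidates=table,
        flags=flags,
    )
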