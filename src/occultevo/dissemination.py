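"""Tumour thickness at dissemination / colonisation from current-status data.

Each patient is observed once, at surgery: the tumour thickness ``t`` is
measured and it is known only whether the event of interest (lymphatic
dissemination, or colonisation of the sentinel node) has already happened.
If it has, the thickness at the event lies in [0, t]; if not, in (t, inf).
This is current-status (extreme interval) censoring, with thickness playing
the role of time.

Provided here are

* the nonparametric maximum-likelihood estimator (Turnbull's
  self-consistency / EM iteration on the innermost censoring intervals),
* maximum-likelihood fits of five parametric families, optionally with a
  cure / asymptote parameter ``pi`` bounding the maximum proportion of
  patients that ever experience the event, P(t) = pi * F0(t),
* BIC model selection, a grouped chi-square goodness-of-fit test, hazard
  rates, quantiles of the susceptible fraction and parametric-bootstrap
  confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TurnbullEstimate",
    "turnbull_npmle",
    "pava_current_status",
    "ParametricCureModel",
    "fit_parametric",
    "model_select",
    "goodness_of_fit",
    "hazard",
    "model_quantile",
    "bootstrap_ci",
    "FAMILIES",
]


def _validate_data(t, event):
    t = np.asarray(t, dtype=float)
    event = np.asarray(event, dtype=bool)
    if t.shape != event.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("t and event must be equal-length 1-d arrays")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("observation thicknesses must be finite and > 0")
    return t, event


# ---------------------------------------------------------------------------
# Turnbull NPMLE


@dataclass
class TurnbullEstimate:
    """NPMLE of the event-thickness distribution from current-status data.

    Mass can only be located within the innermost censoring intervals;
    ``intervals`` are (lo, hi) pairs (hi may be inf) and ``masses`` the
    probabilities assigned to them.  The cumulative evaluator uses the
    right-endpoint convention, i.e. an interval's mass is counted once the
    argument reaches its upper end.
    """

    intervals: list[tuple[float, float]]
    masses: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def cdf(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        for (lo, hi), q in zip(self.intervals, self.masses):
            out = out + q * (t >= hi)
        return out


class ConvergenceError(RuntimeError):
    def __init__(self, msg, estimate=None):
        super().__init__(msg)
        self.estimate = estimate


def turnbull_npmle(t, event, tol: float = 1e-9,
                   max_iter: int = 200_000) -> TurnbullEstimate:
    """Turnbull self-consistency (EM) estimate for current-status data.

    Censoring sets are [0, t] for events and (t, inf) otherwise.  Iterates
    the self-consistency update on the innermost-interval masses until the
    maximum absolute mass change falls below ``tol``; the log-likelihood is
    non-decreasing along the iteration.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    t, event = _validate_data(t, event)

    # innermost (Turnbull) intervals: a left endpoint immediately followed
    # by a right endpoint in the sorted endpoint sequence.
    lefts = np.concatenate([[0.0], t[~event]])          # open at t (exclusive)
    rights = np.concatenate([t[event], [np.inf]])        # closed at t
    endpoints = [(x, 0) for x in np.unique(lefts)] + [(x, 1) for x in np.unique(rights)]
    # at equal value a left endpoint (t, open) sorts after a right endpoint
    # (t, closed), so sort by (value, kind reversed): right before left
    endpoints.sort(key=lambda e: (e[0], 1 - e[1]))
    intervals = []
    for (v1, k1), (v2, k2) in zip(endpoints[:-1], endpoints[1:]):
        if k1 == 0 and k2 == 1:
            intervals.append((v1, v2))
    if not intervals:  # e.g. all events: single interval [0, min t]
        intervals = [(0.0, float(np.min(t[event])) if event.any() else np.inf)]

    # membership: interval j=(lo, hi] (lo open unless 0) contained in
    # censoring set of observation i
    m = len(intervals)
    lo = np.array([iv[0] for iv in intervals])
    hi = np.array([iv[1] for iv in intervals])
    a = np.zeros((t.size, m), dtype=bool)
    for i in range(t.size):
        if event[i]:
            a[i] = hi <= t[i]
        else:
            a[i] = lo >= t[i]
    if not a.any(axis=1).all():
        raise RuntimeError("internal error: observation without interval")

    q = np.full(m, 1.0 / m)
    af = a.astype(float)
    last_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = af @ q
        ll = float(np.log(denom).sum())
        if ll + 1e-12 < last_ll:  # EM guarantee, numerical guard
            raise RuntimeError("log-likelihood decreased in Turnbull EM")
        last_ll = ll
        q_new = q * (af.T @ (1.0 / denom)) / t.size
        delta = float(np.max(np.abs(q_new - q)))
        q = q_new
        if delta < tol:
            converged = True
            break

    est = TurnbullEstimate(intervals=intervals, masses=q,
                           loglik=last_ll, n_iter=it, converged=converged)
    if not converged:
        raise ConvergenceError(
            f"Turnbull EM did not converge in {max_iter} iterations", est)
    # prune negligible masses
    keep = q >= 1e-12
    est.intervals = [iv for iv, k in zip(intervals, keep) if k]
    est.masses = q[keep]
    return est


def pava_current_status(t, event) -> tuple[np.ndarray, np.ndarray]:
    """Isotonic-regression (PAVA) solution for current-status data.

    Independent closed-form oracle for the Turnbull NPMLE: the NPMLE of
    F at the observation points equals the isotonic regression of the
    event indicators on thickness.  Returns (sorted unique thicknesses,
    fitted F values).
    """
    from sklearn.isotonic import IsotonicRegression

    t, event = _validate_data(t, event)
    order = np.argsort(t, kind="stable")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    fit = iso.fit_transform(t[order], event[order].astype(float))
    ts, idx = np.unique(t[order], return_index=True)
    return ts, fit[idx]


# ---------------------------------------------------------------------------
# parametric families

_SQRT2 = math.sqrt(2.0)


class _Family:
    name: str
    n_base: int
    param_names: tuple[str, ...]

    def cdf(self, t, p): ...
    def pdf(self, t, p): ...
    def quantile(self, q, p): ...

    # transforms between the unconstrained optimisation space and the
    # natural (positive) parameter space
    def to_natural(self, x):
        return np.exp(x)

    def to_free(self, p):
        return np.log(p)


class _StdLogLogistic(_Family):
    """F0(t) = t / (t + theta): log-logistic with shape fixed at 1."""
    name = "std_log_logistic"
    n_base = 1
    param_names = ("theta",)

    def cdf(self, t, p):
        return t / (t + p[0])

    def pdf(self, t, p):
        return p[0] / (t + p[0]) ** 2

    def quantile(self, q, p):
        return p[0] * q / (1.0 - q)


class _Exponential(_Family):
    name = "exponential"
    n_base = 1
    param_names = ("theta",)  # scale; median = theta * ln 2

    def cdf(self, t, p):
        return -np.expm1(-t / p[0])

    def pdf(self, t, p):
        return np.exp(-t / p[0]) / p[0]

    def quantile(self, q, p):
        return -p[0] * np.log1p(-q)


class _Weibull(_Family):
    name = "weibull"
    n_base = 2
    param_names = ("theta", "shape")

    def cdf(self, t, p):
        return -np.expm1(-((t / p[0]) ** p[1]))

    def pdf(self, t, p):
        z = (t / p[0]) ** p[1]
        return p[1] / t * z * np.exp(-z)

    def quantile(self, q, p):
        return p[0] * (-np.log1p(-q)) ** (1.0 / p[1])


class _LogNormal(_Family):
    name = "log_normal"
    n_base = 2
    param_names = ("mu", "sigma")  # mu in log-mm, sigma > 0

    def cdf(self, t, p):
        return stats.norm.cdf((np.log(t) - p[0]) / p[1])

    def pdf(self, t, p):
        return stats.norm.pdf((np.log(t) - p[0]) / p[1]) / (t * p[1])

    def quantile(self, q, p):
        return np.exp(p[0] + p[1] * stats.norm.ppf(q))

    def to_natural(self, x):
        return np.array([x[0], np.exp(x[1])])

    def to_free(self, p):
        return np.array([p[0], np.log(p[1])])


class _Frechet(_Family):
    name = "frechet"
    n_base = 2
    param_names = ("theta", "shape")

    def cdf(self, t, p):
        return np.exp(-((t / p[0]) ** (-p[1])))

    def pdf(self, t, p):
        z = (t / p[0]) ** (-p[1])
        return p[1] / t * z * np.exp(-z)

    def quantile(self, q, p):
        return p[0] * (-np.log(q)) ** (-1.0 / p[1])


FAMILIES: dict[str, _Family] = {
    f.name: f for f in (_StdLogLogistic(), _Exponential(), _Weibull(),
                        _LogNormal(), _Frechet())
}


@dataclass
class ParametricCureModel:
    """Fitted cure-fraction model P(t) = pi * F0(t; params).

    ``pi`` is the asymptote: the maximum proportion of patients that ever
    experience the event.  When the cure parameter is not estimated, pi is
    exactly 1 and is not counted in ``n_params``.
    """

    family: str
    params: dict
    pi: float
    cure: bool
    loglik: float
    n_obs: int
    boundary: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return FAMILIES[self.family].n_base + (1 if self.cure else 0)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * math.log(self.n_obs)

    def _p(self) -> np.ndarray:
        fam = FAMILIES[self.family]
        return np.array([self.params[k] for k in fam.param_names])

    def cdf(self, t) -> np.ndarray:
        return self.pi * FAMILIES[self.family].cdf(np.asarray(t, float), self._p())

    def base_cdf(self, t) -> np.ndarray:
        return FAMILIES[self.family].cdf(np.asarray(t, float), self._p())

    def pdf(self, t) -> np.ndarray:
        return self.pi * FAMILIES[self.family].pdf(np.asarray(t, float), self._p())

    def quantile(self, q) -> float:
        return model_quantile(self, q)

    def hazard(self, t) -> np.ndarray:
        return hazard(self, t)


def _negloglik(free: np.ndarray, fam: _Family, cure: bool,
               t: np.ndarray, event: np.ndarray) -> float:
    if cure:
        pi = 1.0 / (1.0 + np.exp(-free[0]))
        base = fam.to_natural(free[1:])
    else:
        pi = 1.0
        base = fam.to_natural(free)
    with np.errstate(over="ignore", invalid="ignore"):
        p = pi * fam.cdf(t, base)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = np.where(event, np.log(p), np.log1p(-p)).sum()
    return -float(ll) if np.isfinite(ll) else 1e30


def _default_starts(fam: _Family, cure: bool, t: np.ndarray,
                    event: np.ndarray) -> list[np.ndarray]:
    qs = np.quantile(t, [0.25, 0.5, 0.75])
    scales = [max(q, 1e-3) for q in qs] + [max(np.mean(t), 1e-3)]
    shapes = [0.7, 1.0, 2.0]
    rate = float(np.clip(event.mean(), 0.05, 0.95))
    pis = [rate, min(0.95, rate * 1.5)]
    starts = []
    for s in scales:
        base_list: list[list[float]]
        if fam.n_base == 1:
            base_list = [[s]]
        elif fam.name == "log_normal":
            base_list = [[math.log(s), sh] for sh in (0.5, 1.0)]
        else:
            base_list = [[s, sh] for sh in shapes[:2]]
        for base in base_list:
            if cure:
                for pi in pis:
                    starts.append(np.concatenate([
                        [math.log(pi / (1 - pi))], fam.to_free(np.array(base))]))
            else:
                starts.append(fam.to_free(np.array(base)))
    return starts[:8]


def fit_parametric(t, event, family: str, cure: bool = False,
                   starts=None) -> ParametricCureModel:
    """Interval-censored maximum-likelihood fit of a parametric family.

    Maximises sum of event*log(pi*F0(t)) + (1-event)*log(1 - pi*F0(t))
    by multi-start Nelder-Mead on transformed parameters (logit pi, log
    scales).  Optima pinned at a boundary (pi near 0/1 when free, or a
    scale far outside the data range) are flagged via ``boundary``.
    """
    t, event = _validate_data(t, event)
    fam = FAMILIES[family]
    if cure and (event.all() or not event.any()):
        raise ValueError("cure-parameter fit needs both event states")
    if t.size < 2:
        raise ValueError("need at least two observations")

    if starts is None:
        starts = _default_starts(fam, cure, t, event)

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _negloglik, x0, args=(fam, cure, t, event),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    if cure:
        pi = 1.0 / (1.0 + np.exp(-x[0]))
        base = fam.to_natural(x[1:])
    else:
        pi = 1.0
        base = fam.to_natural(x)

    boundary = False
    if cure and (pi < 1e-4 or pi > 1.0 - 1e-4):
        boundary = True
    scale = base[0] if fam.name != "log_normal" else math.exp(base[0])
    if scale > 1e4 * float(np.max(t)) or scale < 1e-6 * float(np.min(t)):
        boundary = True

    return ParametricCureModel(
        family=family,
        params=dict(zip(fam.param_names, np.atleast_1d(base).tolist())),
        pi=float(pi), cure=cure, loglik=-float(best.fun), n_obs=t.size,
        boundary=boundary)


def model_select(t, event, families=None, cure: bool = False) -> pd.DataFrame:
    """Fit several families and rank them by BIC (ties: fewer parameters).

    BIC = -2 loglik + n_params * ln(n_obs).  Families that fail to fit are
    reported with their error message rather than dropped.
    """
    if families is None:
        families = list(FAMILIES)
    families = list(families)
    rows = []
    for name in families:
        try:
            m = fit_parametric(t, event, name, cure=cure)
            rows.append({"family": name, "loglik": m.loglik,
                         "n_params": m.n_params, "bic": m.bic,
                         "pi": m.pi, "params": m.params,
                         "boundary": m.boundary, "error": None, "model": m})
        except Exception as exc:  # noqa: BLE001 - failure is data, not control flow
            rows.append({"family": name, "loglik": np.nan, "n_params": np.nan,
                         "bic": np.inf, "pi": np.nan, "params": None,
                         "boundary": False, "error": str(exc), "model": None})
    df = pd.DataFrame(rows).sort_values(
        ["bic", "n_params"], kind="stable").reset_index(drop=True)
    df.index = pd.RangeIndex(1, len(df) + 1, name="rank")
    return df


def goodness_of_fit(model: ParametricCureModel, t, event,
                    k_groups: int) -> tuple[float, int, float]:
    """Grouped chi-square goodness of fit on thickness quantile groups.

    Observations are grouped into ``k_groups`` thickness quantile classes;
    the observed event count per group is compared with the model-expected
    count sum(P(t_i)).  df = max(1, k_groups - 1 - n_params).
    """
    t, event = _validate_data(t, event)
    if k_groups < 2:
        raise ValueError("k_groups must be >= 2")
    if t.size < k_groups:
        raise ValueError("fewer observations than groups")
    edges = np.quantile(t, np.linspace(0, 1, k_groups + 1)[1:-1])
    grp = np.searchsorted(edges, t, side="right")
    p = model.cdf(t)
    chi2 = 0.0
    for g in range(k_groups):
        sel = grp == g
        if not sel.any():
            continue
        o = float(event[sel].sum())
        e = float(p[sel].sum())
        if e == 0.0:
            raise ValueError(f"degenerate group {g}: expected count 0")
        chi2 += (o - e) ** 2 / e
    df = max(1, k_groups - 1 - model.n_params)
    pval = float(stats.chi2.sf(chi2, df))
    return chi2, df, pval


def hazard(model: ParametricCureModel, t) -> np.ndarray:
    """Instantaneous event risk per mm: h(t) = pi f0(t) / (1 - pi F0(t))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    exceed = 1.0 - model.cdf(t)
    if np.any(exceed <= 0):
        raise ValueError("exceedance probability is 0: hazard undefined")
    return model.pdf(t) / exceed


def model_quantile(model: ParametricCureModel, q: float) -> float:
    """Smallest thickness with F0(t) >= q (quantile of the susceptible
    fraction for cure models)."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    fam = FAMILIES[model.family]
    p = model._p()
    return float(fam.quantile(q, p))


def bootstrap_ci(t, event, family: str, cure: bool = False,
                 level: float = 0.95, B: int = 500, seed: int = 0,
                 quantiles=(0.15, 0.5)) -> dict:
    """Parametric-bootstrap percentile confidence intervals.

    The model is fitted, B replicate cohorts are generated by redrawing
    each event indicator as Bernoulli(P(t_i)) at the observed thicknesses,
    each replicate is refitted, and percentile intervals are formed for
    every parameter, pi and the requested F0 quantiles.  More than 20%
    refit failures raise a reliability error.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    t, event = _validate_data(t, event)
    model = fit_parametric(t, event, family, cure=cure)
    rng = np.random.default_rng(seed)
    p = model.cdf(t)
    names = list(model.params) + (["pi"] if cure else []) \
        + [f"td{int(round(100 * q))}" for q in quantiles]
    draws: dict[str, list[float]] = {k: [] for k in names}
    failures = 0
    for _ in range(B):
        ev = rng.random(t.size) < p
        try:
            m = fit_parametric(t, ev, family, cure=cure)
        except Exception:  # noqa: BLE001
            failures += 1
            continue
        for k, v in m.params.items():
            draws[k].append(v)
        if cure:
            draws["pi"].append(m.pi)
        for q in quantiles:
            draws[f"td{int(round(100 * q))}"].append(model_quantile(m, q))
    if failures > 0.2 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed")
    alpha = 1.0 - level
    out = {"model": model, "B": B, "failures": failures}
    for k, v in draws.items():
        arr = np.asarray(v)
        out[k] = (float(np.quantile(arr, alpha / 2)),
                  float(np.quantile(arr, 1 - alpha / 2)))
    return out
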