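"""Maximum-likelihood fitting of the single-progenitor model to clone sizes.

The likelihood of an observed clone (m basal, n suprabasal cells at chase
time t) is read off the exact truncated master-equation distribution,
renormalized over the conditioning set that matches the inclusion rule used
to collect the data (by default clones with at least one basal cell).
Plausible parameter regions are profile-likelihood intervals at a 1.92
log-likelihood drop (the halved chi-squared 95% quantile with one degree of
freedom), and a fate-balance likelihood-ratio test compares the free model
against the homeostatic ``delta = 0`` restriction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .progenitor_model import (
    CloneRecord,
    CloneState,
    CONDITIONINGS,
    DAYS_PER_WEEK,
    ModelParams,
    OverflowMassError,
    _generator_matrix,
    _uniformization,
)

__all__ = ["FitResult", "loglikelihood", "fit", "fate_balance_test",
           "PLAUSIBLE_DROP"]

logger = logging.getLogger(__name__)

#: log-likelihood drop defining the plausible region (chi2_1 95% / 2)
PLAUSIBLE_DROP = 1.92

_PARAM_ORDER = ("lambda_div", "r", "delta", "gamma", "mu")


@dataclass
class FitResult:
    params_hat: ModelParams
    loglik: float
    plausible_region: dict[str, tuple[float, float]]
    profile: dict[str, list[tuple[float, float]]]
    conditioning: str
    converged: bool
    message: str = ""


def _conditioning_mask(shape: tuple[int, int], conditioning: str) -> np.ndarray:
    m = np.arange(shape[0])[:, None]
    n = np.arange(shape[1])[None, :]
    if conditioning == "all":
        return np.ones(shape, dtype=bool)
    if conditioning == "at_least_one_cell":
        return np.broadcast_to((m + n) >= 1, shape)
    if conditioning == "at_least_one_basal":
        return np.broadcast_to(m >= 1, shape)
    raise ValueError(f"conditioning must be one of {CONDITIONINGS}, got {conditioning!r}")


def _caps_for(data_mn: np.ndarray, margin: int = 6) -> tuple[int, int, int]:
    m_max = int(data_mn[:, 0].max())
    n_max = int(data_mn[:, 1].max())
    c = max(m_max, 4) + margin
    return (c, c + margin, max(n_max, 4) + margin)


class LikelihoodEngine:
    """Precomputed scaffolding for repeated likelihood evaluations.

    Groups the clone records by chase time, tabulates unique observed sizes
    with their multiplicities, and solves the master equation for all
    timepoints in a single uniformization sweep per parameter vector.
    """

    def __init__(self, data: list[CloneRecord], conditioning: str,
                 caps: tuple[int, int, int] | None = None,
                 state0: CloneState | None = None,
                 overflow_tol: float = 1e-6,
                 max_states: int = 300_000,
                 strict_overflow: bool = False):
        self.max_states = max_states
        self.strict_overflow = strict_overflow
        if not data:
            raise ValueError("data must be nonempty")
        if conditioning not in CONDITIONINGS:
            raise ValueError(f"conditioning must be one of {CONDITIONINGS}, "
                             f"got {conditioning!r}")
        self.conditioning = conditioning
        self.overflow_tol = overflow_tol
        self.state0 = state0 or CloneState()

        by_t: dict[float, dict[tuple[int, int], int]] = {}
        for rec in data:
            sizes = by_t.setdefault(float(rec.t_days), {})
            key = (rec.m, rec.n)
            sizes[key] = sizes.get(key, 0) + 1
        self.times = np.array(sorted(by_t))
        self.obs = [np.array([(m, n, c) for (m, n), c in sorted(by_t[t].items())],
                             dtype=int) for t in self.times]

        all_mn = np.asarray([(r.m, r.n) for r in data], dtype=int)
        self.caps = caps or _caps_for(all_mn)
        self._prepare_indexing()

    def _prepare_indexing(self) -> None:
        pmax, dmax, smax = self.caps
        self.n_states = (pmax + 1) * (dmax + 1) * (smax + 1)
        P, D, S = np.meshgrid(*(np.arange(c + 1) for c in self.caps), indexing="ij")
        self.m_of_state = (P + D).ravel()
        self.n_of_state = S.ravel()
        self.mask = _conditioning_mask((pmax + dmax + 1, smax + 1),
                                       self.conditioning)
        # flat (m, n) bin per state for fast marginalization
        self.mn_flat = self.m_of_state * (smax + 1) + self.n_of_state
        self.i0 = ((self.state0.n_p * (dmax + 1) + self.state0.n_d)
                   * (smax + 1) + self.state0.n_s)
        if (self.state0.n_p > pmax or self.state0.n_d > dmax
                or self.state0.n_s > smax):
            raise ValueError(f"caps {self.caps} below initial state")

    def grow_caps(self) -> bool:
        """Double the caps; returns False when the state budget is exhausted."""
        new_caps = tuple(2 * c for c in self.caps)
        if (new_caps[0] + 1) * (new_caps[1] + 1) * (new_caps[2] + 1) > self.max_states:
            return False
        self.caps = new_caps
        self._prepare_indexing()
        return True

    def loglik(self, params: ModelParams) -> float:
        while True:
            Q = _generator_matrix(params, self.caps)
            p0 = np.zeros(self.n_states + 1)
            p0[self.i0] = 1.0
            sols = _uniformization(Q, p0, self.times / DAYS_PER_WEEK)
            if sols[:, -1].max() <= self.overflow_tol:
                break
            if not self.grow_caps():
                if self.strict_overflow:
                    raise OverflowMassError(
                        f"overflow mass {float(sols[:, -1].max()):.2e} exceeds "
                        f"{self.overflow_tol:.1e} and the state budget "
                        f"({self.max_states}) is exhausted; increase caps")
                # state budget reached: fall back to the censored likelihood,
                # with escaped trajectories pooled in the overflow class
                logger.debug("state budget reached at caps %s (overflow %.2e); "
                             "using censored likelihood", self.caps,
                             float(sols[:, -1].max()))
                break
        pmax, dmax, smax = self.caps

        total = 0.0
        n_mn = (pmax + dmax + 1) * (smax + 1)
        for sol, obs in zip(sols, self.obs):
            overflow = float(sol[-1])
            mn = np.bincount(self.mn_flat, weights=np.clip(sol[:-1], 0, None),
                             minlength=n_mn).reshape(pmax + dmax + 1, smax + 1)
            # overflow trajectories escaped the caps, i.e. grew large; they
            # belong to every conditioning set
            z = float(mn[self.mask].sum()) + overflow
            if z <= 0:
                raise OverflowMassError("conditioning set has zero probability; "
                                        "enlarge caps")
            m_idx, n_idx, counts = obs[:, 0], obs[:, 1], obs[:, 2]
            inside = (m_idx <= pmax + dmax) & (n_idx <= smax)
            probs = np.where(inside,
                             mn[np.minimum(m_idx, pmax + dmax),
                                np.minimum(n_idx, smax)],
                             overflow) / z
            if (probs <= 0).any():
                bad = np.argmax(probs <= 0)
                raise OverflowMassError(
                    f"observed clone size ({m_idx[bad]},{n_idx[bad]}) has zero "
                    f"conditioned probability under caps {self.caps}; increase caps")
            total += float(counts @ np.log(probs))
        return total


def loglikelihood(params: ModelParams, data: list[CloneRecord],
                  conditioning: str = "at_least_one_basal",
                  caps: tuple[int, int, int] | None = None,
                  overflow_tol: float = 1e-6) -> float:
    """Sum of log P(m, n | params, t, conditioning) over the clone records.

    Truncation caps are chosen from the data (or given explicitly) and
    doubled automatically until the overflow mass is below ``overflow_tol``;
    an observed size with zero conditioned probability raises an error
    advising larger caps.
    """
    engine = LikelihoodEngine(data, conditioning, caps=caps,
                              overflow_tol=overflow_tol,
                              max_states=2_000_000, strict_overflow=True)
    return engine.loglik(params)


def _profile_interval(curve: list[tuple[float, float]], theta_hat: float,
                      ll_max: float) -> tuple[float, float]:
    """Plausible interval from a profile curve, with linear interpolation of
    the threshold crossings between grid points."""
    thresh = ll_max - PLAUSIBLE_DROP
    lo, hi = theta_hat, theta_hat
    for (g0, v0), (g1, v1) in zip(curve[:-1], curve[1:]):
        in0, in1 = v0 >= thresh, v1 >= thresh
        if in0:
            lo, hi = min(lo, g0), max(hi, g0)
        if in1:
            lo, hi = min(lo, g1), max(hi, g1)
        if in0 != in1 and v1 != v0:
            gx = g0 + (thresh - v0) * (g1 - g0) / (v1 - v0)
            lo, hi = min(lo, gx), max(hi, gx)
    return (lo, hi)


def _make_params(free_names, free_values, fixed: dict) -> ModelParams | None:
    d = dict(fixed)
    d.update(zip(free_names, free_values))
    try:
        return ModelParams(**{k: float(d[k]) for k in _PARAM_ORDER})
    except (ValueError, KeyError):
        return None


def fit(data: list[CloneRecord], search_space: dict[str, tuple[float, float]],
        fixed: dict[str, float] | None = None,
        conditioning: str = "at_least_one_basal",
        seed: int | None = None,
        grid_points: int = 5, profile_points: int = 13,
        profile_params: list[str] | None = None,
        caps: tuple[int, int, int] | None = None,
        overflow_tol: float = 5e-5, max_states: int = 50_000) -> FitResult:
    """Maximum-likelihood fit over the free parameters in ``search_space``.

    Coarse grid search followed by Nelder-Mead refinement from the best grid
    point; each free parameter then gets a profile-likelihood curve (the
    other free parameters re-maximized at every grid value) and a plausible
    interval {theta : max loglik - loglik <= 1.92}.

    ``fixed`` supplies values for parameters not in ``search_space``; the
    full parameter vector (lambda_div, r, delta, gamma, mu) must be covered.
    ``seed`` is accepted for provenance symmetry only — the objective is
    deterministic.
    """
    if not data:
        raise ValueError("data must be nonempty")
    fixed = dict(fixed or {})
    free_names = [p for p in _PARAM_ORDER if p in search_space]
    if not free_names:
        raise ValueError("search_space must name at least one free parameter")
    missing = [p for p in _PARAM_ORDER if p not in search_space and p not in fixed]
    if missing:
        raise ValueError(f"parameters neither free nor fixed: {missing}")
    bounds = [tuple(map(float, search_space[p])) for p in free_names]

    engine = LikelihoodEngine(data, conditioning, caps=caps,
                              overflow_tol=overflow_tol, max_states=max_states)

    def nll(theta):
        for v, (lo, hi) in zip(theta, bounds):
            if not (lo <= v <= hi):
                return 1e12
        params = _make_params(free_names, theta, fixed)
        if params is None:
            return 1e12
        try:
            return -engine.loglik(params)
        except OverflowMassError:
            return 1e12

    axes = [np.linspace(lo, hi, grid_points) for lo, hi in bounds]
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    grid_vals = np.array([nll(p) for p in pts])
    x0 = pts[int(np.argmin(grid_vals))]

    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 5e-4, "fatol": 1e-4, "maxiter": 250})
    theta_hat = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    ll_hat = -nll(theta_hat)

    on_boundary = any(
        abs(v - lo) < 1e-6 * max(1.0, abs(hi - lo)) or
        abs(v - hi) < 1e-6 * max(1.0, abs(hi - lo))
        for v, (lo, hi) in zip(theta_hat, bounds))
    converged = bool(res.success) and not on_boundary
    message = "" if converged else (
        "maximum on the search-space boundary" if on_boundary else res.message)

    profile: dict[str, list[tuple[float, float]]] = {}
    region: dict[str, tuple[float, float]] = {}
    to_profile = free_names if profile_params is None else [
        p for p in free_names if p in profile_params]
    for i, name in enumerate(free_names):
        if name not in to_profile:
            continue
        lo, hi = bounds[i]
        grid = np.linspace(lo, hi, profile_points)
        others = [j for j in range(len(free_names)) if j != i]
        curve = []
        for g in grid:
            if others:
                def nll_fixed(sub, g=g, i=i, others=others):
                    theta = np.empty(len(free_names))
                    theta[i] = g
                    for k, j in enumerate(others):
                        theta[j] = sub[k]
                    return nll(theta)
                sub0 = theta_hat[others]
                sub_res = minimize(nll_fixed, sub0, method="Nelder-Mead",
                                   options={"xatol": 2e-3, "fatol": 5e-4,
                                            "maxiter": 40})
                ll = -min(sub_res.fun, nll_fixed(sub0))
            else:
                theta = theta_hat.copy()
                theta[i] = g
                ll = -nll(theta)
            curve.append((float(g), float(ll)))
        profile[name] = curve
        ll_max = max(ll_hat, max(v for _, v in curve))
        region[name] = _profile_interval(curve, float(theta_hat[i]), ll_max)

    params_hat = _make_params(free_names, theta_hat, fixed)
    return FitResult(params_hat=params_hat, loglik=ll_hat,
                     plausible_region=region, profile=profile,
                     conditioning=conditioning, converged=converged,
                     message=message)


def fate_balance_test(data: list[CloneRecord],
                      search_space: dict[str, tuple[float, float]],
                      fixed: dict[str, float] | None = None,
                      conditioning: str = "at_least_one_basal",
                      grid_points: int = 5,
                      caps: tuple[int, int, int] | None = None,
                      overflow_tol: float = 5e-5,
                      max_states: int = 50_000) -> dict:
    """Likelihood-ratio test of homeostasis (delta = 0) against a free delta.

    Returns ``{lr_statistic, p_value, fit_free, fit_null}``; the statistic is
    ``2 (loglik_free - loglik_null)`` clipped at zero and p comes from a
    chi-squared with one degree of freedom.
    """
    if "delta" not in search_space:
        raise ValueError("search_space must include 'delta' for the fate-balance test")
    fixed = dict(fixed or {})
    fit_free = fit(data, search_space, fixed=fixed, conditioning=conditioning,
                   grid_points=grid_points, profile_points=3, caps=caps,
                   overflow_tol=overflow_tol, max_states=max_states)
    null_space = {k: v for k, v in search_space.items() if k != "delta"}
    null_fixed = dict(fixed)
    null_fixed["delta"] = 0.0
    if null_space:
        fit_null = fit(data, null_space, fixed=null_fixed, conditioning=conditioning,
                       grid_points=grid_points, profile_points=3, caps=caps,
                       overflow_tol=overflow_tol, max_states=max_states)
        ll_null = fit_null.loglik
    else:
        params_null = _make_params([], [], null_fixed)
        engine = LikelihoodEngine(data, conditioning, caps=caps,
                                  overflow_tol=overflow_tol, max_states=max_states)
        ll_null = engine.loglik(params_null)
        fit_null = None
    lr = max(0.0, 2.0 * (fit_free.loglik - ll_null))
    return {"lr_statistic": lr, "p_value": float(chi2.sf(lr, 1)),
            "fit_free": fit_free, "fit_null": fit_null}
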