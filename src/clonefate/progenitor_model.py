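"""Single-progenitor model of clonal growth in a stratified epithelium.

A clone is tracked as three cell compartments:

* progenitors ``n_p`` — divide at rate ``lambda_div``; each division yields
  two progenitors (probability ``r * (1 + delta)``), one progenitor and one
  post-mitotic basal cell (``1 - 2 r``), or two post-mitotic basal cells
  (``r * (1 - delta)``),
* post-mitotic basal cells ``n_d`` — stratify to the first suprabasal layer
  at rate ``gamma``,
* first-suprabasal cells ``n_s`` — shed at rate ``mu``.

All rates are per week; public APIs take time in days.  ``delta = 0`` is
homeostasis (the progenitor count is a martingale); ``delta > 0`` biases
fate toward proliferation and drives exponential clone growth.

Two routes to the clone-size distribution are provided: an exact
event-driven (Gillespie) stochastic simulation and the numerically exact
solution of the master equation on a truncated state space with an
absorbing overflow class.  The two are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "ModelParams",
    "CloneState",
    "CloneRecord",
    "ObservableSummary",
    "ExactDistribution",
    "ValidationError",
    "OverflowMassError",
    "DAYS_PER_WEEK",
    "DAYS_PER_MONTH",
    "division_outcome_probs",
    "simulate_clone",
    "simulate_clones_batch",
    "simulate_cohort",
    "exact_distribution",
    "adaptive_caps",
    "expected_progenitors",
    "predict_observables",
    "CONDITIONINGS",
]

DAYS_PER_WEEK = 7.0
#: convenience conversion used for chase times quoted in months
DAYS_PER_MONTH = 30.0

CONDITIONINGS = ("all", "at_least_one_cell", "at_least_one_basal")


class ValidationError(ValueError):
    """Raised when model parameters or states violate their bounds."""


class OverflowMassError(RuntimeError):
    """Raised when the truncated master equation leaks too much probability."""


@dataclass(frozen=True)
class ModelParams:
    """Rates (per week) and fate probabilities of the single-progenitor model.

    Parameters
    ----------
    lambda_div
        Progenitor division rate, events per week (>= 0; 0 freezes divisions).
    r
        Symmetric-division probability scale, 0 < r <= 0.5.
    delta
        Fate-imbalance parameter in [-1, 1]; 0 is homeostasis.
    gamma
        Stratification rate of post-mitotic basal cells, per week (>= 0).
    mu
        Shedding rate from the first suprabasal layer, per week (>= 0).
    """

    lambda_div: float
    r: float
    delta: float
    gamma: float
    mu: float

    def __post_init__(self) -> None:
        if not self.lambda_div >= 0:
            raise ValidationError(f"lambda_div must be >= 0, got {self.lambda_div}")
        if not 0 < self.r <= 0.5:
            raise ValidationError(f"r must be in (0, 0.5], got {self.r}")
        if not -1 <= self.delta <= 1:
            raise ValidationError(f"delta must be in [-1, 1], got {self.delta}")
        if not self.gamma >= 0:
            raise ValidationError(f"gamma must be >= 0, got {self.gamma}")
        if not self.mu >= 0:
            raise ValidationError(f"mu must be >= 0, got {self.mu}")

    def to_dict(self) -> dict:
        return {
            "lambda_div": self.lambda_div,
            "r": self.r,
            "delta": self.delta,
            "gamma": self.gamma,
            "mu": self.mu,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(d[k]) for k in ("lambda_div", "r", "delta", "gamma", "mu")})


@dataclass(frozen=True)
class CloneState:
    """Cell counts of one clone: progenitor / post-mitotic basal / first-suprabasal."""

    n_p: int = 1
    n_d: int = 0
    n_s: int = 0
    t: float = 0.0  # elapsed chase time, days

    def __post_init__(self) -> None:
        for name in ("n_p", "n_d", "n_s"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.t < 0:
            raise ValidationError(f"t must be >= 0, got {self.t}")

    @property
    def basal(self) -> int:
        return self.n_p + self.n_d

    @property
    def total(self) -> int:
        return self.basal + self.n_s

    @property
    def floating(self) -> bool:
        """A clone with no basal cells (all progeny stratified)."""
        return self.basal == 0


@dataclass(frozen=True)
class CloneRecord:
    """One observed clone: ``m`` basal and ``n`` suprabasal cells at a chase time."""

    animal_id: str
    condition: str
    t_days: float
    m: int
    n: int

    def __post_init__(self) -> None:
        if self.t_days < 0:
            raise ValidationError(f"t_days must be >= 0, got {self.t_days}")
        for name in ("m", "n"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class ObservableSummary:
    mean_basal: float
    mean_total: float
    suprabasal_fraction: float
    floating_fraction: float
    conditioning: str


def division_outcome_probs(params: ModelParams) -> tuple[float, float, float]:
    """Probabilities of the three division outcomes ``(PP, PD, DD)``.

    ``PP = r (1 + delta)``, ``PD = 1 - 2 r``, ``DD = r (1 - delta)``; they sum
    to one exactly.
    """
    pp = params.r * (1.0 + params.delta)
    dd = params.r * (1.0 - params.delta)
    pd_ = 1.0 - 2.0 * params.r
    return (pp, pd_, dd)


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------


def _gillespie(params: ModelParams, duration_weeks: float, p: int, d: int, s: int,
               rng: np.random.Generator) -> tuple[int, int, int]:
    lam, gamma, mu = params.lambda_div, params.gamma, params.mu
    pp, pd_, dd = division_outcome_probs(params)
    t = 0.0
    while True:
        rate_div = lam * p
        rate_strat = gamma * d
        rate_shed = mu * s
        total = rate_div + rate_strat + rate_shed
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > duration_weeks:
            break
        u = rng.random() * total
        if u < rate_div:
            v = rng.random()
            if v < pp:
                p += 1
            elif v < pp + pd_:
                d += 1
            else:
                p -= 1
                d += 2
        elif u < rate_div + rate_strat:
            d -= 1
            s += 1
        else:
            s -= 1
    return p, d, s


def simulate_clone(params: ModelParams, t_end: float, state0: CloneState | None = None,
                   seed: int | np.random.SeedSequence | None = None) -> CloneState:
    """Exact event-driven simulation of one clone up to chase time ``t_end`` (days).

    The clone starts from ``state0`` (default: a single founder progenitor at
    ``t = 0``) and is evolved for ``t_end - state0.t`` days.  Identical seed
    and inputs give identical output.
    """
    if state0 is None:
        state0 = CloneState()
    if t_end < state0.t:
        raise ValidationError(f"t_end ({t_end}) must be >= state0.t ({state0.t})")
    rng = np.random.default_rng(seed)
    duration = (t_end - state0.t) / DAYS_PER_WEEK
    p, d, s = _gillespie(params, duration, state0.n_p, state0.n_d, state0.n_s, rng)
    return CloneState(n_p=p, n_d=d, n_s=s, t=float(t_end))


def simulate_clones_batch(params: ModelParams, t_days: float, n_clones: int,
                          seed: int | np.random.SeedSequence | None = None,
                          state0: CloneState | None = None) -> np.ndarray:
    """Vectorized Gillespie for many independent clones (one shared stream).

    Returns an ``(n_clones, 3)`` integer array of ``(n_p, n_d, n_s)`` at
    ``t_days``.  Used for large Monte-Carlo checks; `simulate_cohort` is the
    per-clone-substream variant whose output is order-independent.
    """
    if state0 is None:
        state0 = CloneState()
    rng = np.random.default_rng(seed)
    lam, gamma, mu = params.lambda_div, params.gamma, params.mu
    pp, pd_, dd = division_outcome_probs(params)
    T = t_days / DAYS_PER_WEEK

    p = np.full(n_clones, state0.n_p, dtype=np.int64)
    d = np.full(n_clones, state0.n_d, dtype=np.int64)
    s = np.full(n_clones, state0.n_s, dtype=np.int64)
    t = np.zeros(n_clones)
    alive = np.ones(n_clones, dtype=bool)

    while True:
        rate_div = lam * p
        rate_strat = gamma * d
        total = rate_div + rate_strat + mu * s
        active = alive & (total > 0)
        if not active.any():
            break
        idx = np.flatnonzero(active)
        tot = total[idx]
        t[idx] += rng.exponential(1.0, idx.size) / tot
        done = t[idx] > T
        alive[idx[done]] = False
        idx = idx[~done]
        if idx.size == 0:
            continue
        u = rng.random(idx.size) * total[idx]
        v = rng.random(idx.size)  # division outcome draw (unused for non-divisions)
        is_div = u < rate_div[idx]
        is_strat = ~is_div & (u < rate_div[idx] + rate_strat[idx])
        is_shed = ~is_div & ~is_strat

        div_idx = idx[is_div]
        vv = v[is_div]
        p[div_idx[vv < pp]] += 1
        mid = (vv >= pp) & (vv < pp + pd_)
        d[div_idx[mid]] += 1
        sym_dd = vv >= pp + pd_
        p[div_idx[sym_dd]] -= 1
        d[div_idx[sym_dd]] += 2

        st_idx = idx[is_strat]
        d[st_idx] -= 1
        s[st_idx] += 1
        s[idx[is_shed]] -= 1
    return np.stack([p, d, s], axis=1)


def simulate_cohort(params: ModelParams, n_clones: int, timepoints: list[float],
                    seed: int | None = None, state0: CloneState | None = None,
                    animal_id: str = "sim", condition: str = "sim") -> list[CloneRecord]:
    """Simulate ``n_clones`` independent clones observed at each timepoint (days).

    Each (clone, timepoint) pair is an independent realization drawn from its
    own random substream spawned from the master seed, so the result does not
    depend on evaluation order.
    """
    if n_clones <= 0:
        raise ValidationError(f"n_clones must be > 0, got {n_clones}")
    if state0 is None:
        state0 = CloneState()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_clones * len(timepoints))
    records: list[CloneRecord] = []
    k = 0
    for t in timepoints:
        for _ in range(n_clones):
            st = simulate_clone(params, t, state0, seed=children[k])
            records.append(CloneRecord(animal_id=animal_id, condition=condition,
                                       t_days=float(t), m=st.basal, n=st.n_s))
            k += 1
    return records


# ---------------------------------------------------------------------------
# master-equation oracle
# ---------------------------------------------------------------------------


@dataclass
class ExactDistribution:
    """Joint distribution over truncated clone states at one chase time.

    ``p`` is a ``(p_max+1, d_max+1, s_max+1)`` array of state probabilities;
    ``overflow_mass`` is the probability absorbed by states beyond the caps.
    """

    p: np.ndarray
    overflow_mass: float
    caps: tuple[int, int, int]
    params: ModelParams
    t_days: float
    state0: CloneState = field(default_factory=CloneState)

    def marginal_mn(self) -> np.ndarray:
        """Marginal over (m = basal, n = suprabasal); shape (p_max+d_max+1, s_max+1)."""
        pmax, dmax, smax = self.caps
        out = np.zeros((pmax + dmax + 1, smax + 1))
        P, D = np.meshgrid(np.arange(pmax + 1), np.arange(dmax + 1), indexing="ij")
        for s in range(smax + 1):
            np.add.at(out[:, s], (P + D).ravel(), self.p[:, :, s].ravel())
        return out


def _generator_matrix(params: ModelParams, caps: tuple[int, int, int]) -> sparse.csr_matrix:
    """Sparse generator Q (column = source state) with absorbing overflow row."""
    pmax, dmax, smax = caps
    shape = (pmax + 1, dmax + 1, smax + 1)
    n_states = shape[0] * shape[1] * shape[2]
    over = n_states
    P, D, S = np.meshgrid(*(np.arange(c + 1) for c in caps), indexing="ij")
    P, D, S = P.ravel(), D.ravel(), S.ravel()
    src_idx = np.arange(n_states)

    lam, gamma, mu = params.lambda_div, params.gamma, params.mu
    pp, pd_, dd = division_outcome_probs(params)

    rows, cols, vals = [], [], []

    def add(rate, tgt_p, tgt_d, tgt_s):
        mask = rate > 0
        if not mask.any():
            return
        tp, td, ts = tgt_p[mask], tgt_d[mask], tgt_s[mask]
        within = (tp <= pmax) & (td <= dmax) & (ts <= smax)
        tgt = np.where(within, (tp * (dmax + 1) + td) * (smax + 1) + ts, over)
        rows.append(tgt)
        cols.append(src_idx[mask])
        vals.append(rate[mask])

    add(lam * pp * P, P + 1, D, S)
    add(lam * pd_ * P, P, D + 1, S)
    add(lam * dd * P, P - 1, D + 2, S)
    add(gamma * D, P, D - 1, S + 1)
    add(mu * S, P, D, S - 1)

    rows = np.concatenate(rows) if rows else np.array([], dtype=int)
    cols = np.concatenate(cols) if cols else np.array([], dtype=int)
    vals = np.concatenate(vals) if vals else np.array([])
    # diagonal: total outflow per source state
    outflow = np.bincount(cols, weights=vals, minlength=n_states + 1)
    rows = np.concatenate([rows, src_idx])
    cols = np.concatenate([cols, src_idx])
    vals = np.concatenate([vals, -outflow[:n_states]])
    Q = sparse.coo_matrix((vals, (rows, cols)), shape=(n_states + 1, n_states + 1))
    return Q.tocsr()


def _uniformization(Q: sparse.csr_matrix, p0: np.ndarray,
                    times_weeks: np.ndarray, tol: float = 1e-13) -> np.ndarray:
    """Action of expm(Q t) on p0 at several times via uniformization.

    ``W = I + Q / rate_max`` is substochastic, so the series
    ``exp(-rate t) sum_k (rate t)^k / k! W^k p0`` is evaluated with
    nonnegative terms only; one sweep of matvecs serves every requested
    time.  Returns an array of shape ``(len(times), len(p0))``.
    """
    times = np.asarray(times_weeks, dtype=float)
    rate = float(-Q.diagonal().min())
    if rate <= 0 or times.max() == 0:
        return np.tile(p0, (times.size, 1))
    from scipy.stats import poisson

    W = sparse.identity(Q.shape[0], format="csr") + Q * (1.0 / rate)
    lam = rate * times  # Poisson means, one per requested time
    lam_max = lam.max()
    k_max = int(lam_max + 8.0 * math.sqrt(lam_max + 1.0) + 20)
    ks = np.arange(k_max + 1)
    # pmf computed in log space by scipy: immune to exp(-lam) underflow
    pmf = poisson.pmf(ks[None, :], lam[:, None])
    out = np.zeros((times.size, p0.size))
    v = p0.copy()
    done_mass = pmf[:, 0].copy()
    out += pmf[:, 0][:, None] * v[None, :]
    for k in range(1, k_max + 1):
        v = W @ v
        w = pmf[:, k]
        if w.max() > 0:
            out += w[:, None] * v[None, :]
        done_mass += w
        if (1.0 - done_mass).max() < tol:
            break
    return out


def exact_distribution(params: ModelParams, t: float, caps: tuple[int, int, int],
                       state0: CloneState | None = None,
                       overflow_tol: float = 1e-6,
                       strict: bool = True) -> ExactDistribution:
    """Solve the truncated master equation from a point mass at ``state0``.

    Integrates ``dP/dt = Q P`` over ``t`` days on the state space
    ``{0..p_max} x {0..d_max} x {0..s_max}`` with an absorbing overflow class;
    the returned table sums to ``1 - overflow_mass``.

    Raises
    ------
    OverflowMassError
        If ``strict`` and the overflow mass exceeds ``overflow_tol``.
    """
    if state0 is None:
        state0 = CloneState()
    pmax, dmax, smax = caps
    if state0.n_p > pmax or state0.n_d > dmax or state0.n_s > smax:
        raise ValidationError(f"caps {caps} below initial state "
                              f"({state0.n_p},{state0.n_d},{state0.n_s})")
    if t < 0:
        raise ValidationError(f"t must be >= 0, got {t}")
    shape = (pmax + 1, dmax + 1, smax + 1)
    n_states = shape[0] * shape[1] * shape[2]
    p0 = np.zeros(n_states + 1)
    i0 = (state0.n_p * (dmax + 1) + state0.n_d) * (smax + 1) + state0.n_s
    p0[i0] = 1.0
    if t == 0:
        pt = p0
    else:
        Q = _generator_matrix(params, caps)
        pt = _uniformization(Q, p0, np.array([t / DAYS_PER_WEEK]))[0]
        pt = np.clip(pt, 0.0, None)
    overflow = float(pt[-1])
    if strict and overflow > overflow_tol:
        raise OverflowMassError(
            f"overflow mass {overflow:.3e} exceeds {overflow_tol:.1e} at t={t}; "
            f"increase caps (currently {caps})")
    return ExactDistribution(p=pt[:-1].reshape(shape), overflow_mass=overflow,
                             caps=caps, params=params, t_days=float(t), state0=state0)


def adaptive_caps(params: ModelParams, t: float, state0: CloneState | None = None,
                  start: tuple[int, int, int] = (8, 12, 16),
                  overflow_tol: float = 1e-6,
                  max_states: int = 2_000_000) -> ExactDistribution:
    """Double the truncation caps until the overflow mass is below tolerance."""
    if state0 is None:
        state0 = CloneState()
    caps = (max(start[0], state0.n_p), max(start[1], state0.n_d), max(start[2], state0.n_s))
    while True:
        dist = exact_distribution(params, t, caps, state0=state0,
                                  overflow_tol=overflow_tol, strict=False)
        if dist.overflow_mass <= overflow_tol:
            return dist
        caps = tuple(2 * c for c in caps)
        if (caps[0] + 1) * (caps[1] + 1) * (caps[2] + 1) > max_states:
            raise OverflowMassError(
                f"cannot reach overflow tolerance {overflow_tol} within "
                f"{max_states} states (last overflow {dist.overflow_mass:.3e})")


def expected_progenitors(params: ModelParams, t: float) -> float:
    """Mean progenitor count per founding progenitor at chase time ``t`` (days).

    The mean change per division is ``+2 r delta``, giving
    ``exp(2 r delta lambda t)``.
    """
    tw = t / DAYS_PER_WEEK
    return math.exp(2.0 * params.r * params.delta * params.lambda_div * tw)


def predict_observables(params: ModelParams, t: float, conditioning: str = "all",
                        state0: CloneState | None = None,
                        overflow_tol: float = 1e-6) -> ObservableSummary:
    """Exact clone observables at ``t`` days under the requested conditioning.

    ``suprabasal_fraction`` is the expected suprabasal cell share
    E[n] / E[m + n] over the conditioning set; ``floating_fraction`` is the
    probability of a clone having no basal cells among clones with at least
    one cell (independent of ``conditioning``).
    """
    if conditioning not in CONDITIONINGS:
        raise ValidationError(f"conditioning must be one of {CONDITIONINGS}, "
                              f"got {conditioning!r}")
    dist = adaptive_caps(params, t, state0=state0, overflow_tol=overflow_tol)
    mn = dist.marginal_mn()
    m = np.arange(mn.shape[0])[:, None]
    n = np.arange(mn.shape[1])[None, :]

    if conditioning == "all":
        mask = np.ones_like(mn, dtype=bool)
    elif conditioning == "at_least_one_cell":
        mask = (m + n) >= 1
    else:
        mask = m >= 1
    w = mn * mask
    z = w.sum()
    if z <= 0:
        raise OverflowMassError("conditioning set has zero probability")
    mean_basal = float((w * m).sum() / z)
    mean_total = float((w * (m + n)).sum() / z)
    mean_supra = float((w * n).sum() / z)
    supra_frac = mean_supra / mean_total if mean_total > 0 else 0.0

    alive = mn * ((m + n) >= 1)
    za = alive.sum()
    floating = float((alive * (m == 0)).sum() / za) if za > 0 else 0.0
    return ObservableSummary(mean_basal=mean_basal, mean_total=mean_total,
                             suprabasal_fraction=supra_frac,
                             floating_fraction=floating, conditioning=conditioning)


def with_delta(params: ModelParams, delta: float) -> ModelParams:
    """Convenience: a copy of ``params`` with a different fate imbalance."""
    return replace(params, delta=delta)
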