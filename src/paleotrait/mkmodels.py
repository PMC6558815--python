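"""Ordered discrete Markov models with single-step gains and losses.

States are consecutive integers 0..S-1 and the rate matrix is tridiagonal:
only +1 (gain, rate q_gain) and -1 (loss, rate q_loss) transitions are
allowed. The symmetric model ties the two rates. Likelihoods come from
Felsenstein pruning with matrix exponentials cached per branch length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .treekit import DatedTree
from .traitio import TraitVector

__all__ = [
    "MkError",
    "OrderedMkSpec",
    "MkFit",
    "LRTResult",
    "build_q",
    "mk_loglik",
    "fit_mk",
    "lrt",
]

ROOT_PRIORS = ("uniform", "equilibrium", "fitzjohn")


class MkError(ValueError):
    """Invalid Mk specification or data."""


@dataclass(frozen=True)
class OrderedMkSpec:
    n_states: int
    symmetric: bool
    q_gain: float
    q_loss: float

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise MkError("need at least 2 states")
        if self.q_gain < 0 or self.q_loss < 0:
            raise MkError("rates must be >= 0")
        if self.symmetric and self.q_gain != self.q_loss:
            raise MkError("symmetric model requires q_gain == q_loss")


@dataclass(frozen=True)
class MkFit:
    spec: OrderedMkSpec
    lnL: float
    k: int
    aic: float
    converged: bool
    n_states: int
    tree_id: str | int | None = None


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    significant: bool
    alpha: float


def build_q(spec: OrderedMkSpec) -> np.ndarray:
    """Tridiagonal rate matrix; rows sum to zero."""
    S = spec.n_states
    Q = np.zeros((S, S))
    idx = np.arange(S - 1)
    Q[idx, idx + 1] = spec.q_gain
    Q[idx + 1, idx] = spec.q_loss
    np.fill_diagonal(Q, -Q.sum(axis=1) + np.diag(Q))
    return Q


def _root_distribution(prior: str, Q: np.ndarray, partial: np.ndarray) -> np.ndarray:
    S = len(Q)
    if prior == "uniform":
        return np.full(S, 1.0 / S)
    if prior == "equilibrium":
        # stationary distribution: left null vector of Q
        w, v = np.linalg.eig(Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()
    if prior == "fitzjohn":
        s = partial.sum()
        if s <= 0:
            return np.full(S, 1.0 / S)
        return partial / s
    raise MkError(f"unknown root prior {prior!r}; options: {ROOT_PRIORS}")


def mk_loglik(
    tree: DatedTree,
    states: TraitVector,
    spec: OrderedMkSpec,
    root_prior: str = "uniform",
) -> float:
    """Felsenstein pruning log-likelihood of integer tip states."""
    S = spec.n_states
    x = np.asarray(states.values)
    xi = x.astype(int)
    if np.any(x != xi):
        raise MkError("states must be integers")
    bad = [states.labels[i] for i in range(len(xi)) if not (0 <= xi[i] < S)]
    if bad:
        raise MkError(f"states out of range 0..{S - 1} at tips: {bad[:5]}")
    if len(xi) != tree.n_tips:
        raise MkError("states not aligned to tips")

    Q = build_q(spec)
    pcache: dict[float, np.ndarray] = {}

    def P(t: float) -> np.ndarray:
        key = round(t, 12)
        if key not in pcache:
            pcache[key] = expm(Q * t)
        return pcache[key]

    tip_state = dict(zip((t.index for t in tree.tips), xi))
    partials: dict[int, np.ndarray] = {}
    logscale = 0.0
    for node in tree.nodes:  # postorder
        if node.is_tip:
            f = np.zeros(S)
            f[tip_state[node.index]] = 1.0
        else:
            f = np.ones(S)
            for c in node.children:
                f = f * (P(c.length) @ partials.pop(c.index))
            m = f.max()
            if m <= 0:
                return -math.inf
            f = f / m
            logscale += math.log(m)
        partials[node.index] = f
    root_partial = partials[tree.root.index]
    pi = _root_distribution(root_prior, Q, root_partial)
    like = float(pi @ root_partial)
    if like <= 0:
        return -math.inf
    return math.log(like) + logscale


def infer_n_states(states: TraitVector, n_states: int | None = None) -> int:
    observed_max = int(np.max(states.values))
    if n_states is None:
        return observed_max + 1
    if n_states < observed_max + 1:
        raise MkError(f"n_states={n_states} smaller than max observed state + 1")
    return n_states


def fit_mk(
    tree: DatedTree,
    states: TraitVector,
    symmetric: bool,
    n_states: int | None = None,
    root_prior: str = "uniform",
    restarts: int = 3,
    rate_bounds: tuple[float, float] = (1e-8, 1e4),
    tree_id: str | int | None = None,
    init_rates: tuple[float, ...] | None = None,
) -> MkFit:
    """ML rates by bounded optimization in log-rate space with restarts.

    ``init_rates`` adds an explicit warm-start point (e.g. the symmetric
    optimum when fitting the asymmetric model, which guarantees the nested
    likelihood ordering).
    """
    if tree.n_tips < 3:
        raise MkError("need at least 3 tips")
    S = infer_n_states(states, n_states)
    if len(np.unique(states.values)) < 2:
        warnings.warn("fewer than 2 observed states; rates are unidentifiable",
                      RuntimeWarning, stacklevel=2)
    total_len = sum(n.length for n in tree.nodes if n.parent is not None)
    # crude initial rate: parsimony-ish change count per unit tree length
    heuristic = max(len(np.unique(states.values)) - 1, 1) / max(total_len, 1e-9)
    nparam = 1 if symmetric else 2
    lo, hi = math.log(rate_bounds[0]), math.log(rate_bounds[1])

    def nll(logrates: np.ndarray) -> float:
        r = np.exp(logrates)
        g, l = (r[0], r[0]) if symmetric else (r[0], r[1])
        spec = OrderedMkSpec(S, symmetric, float(g), float(l))
        val = mk_loglik(tree, states, spec, root_prior)
        return -val if math.isfinite(val) else 1e12

    # coarse pre-scan keeps the optimizer off the high-rate likelihood plateau
    candidates = [np.full(nparam, min(max(math.log(heuristic * f), lo), hi))
                  for f in (0.1, 0.5, 2.0, 8.0, 32.0)]
    if init_rates is not None:
        r0 = np.asarray(init_rates, dtype=float)
        if len(r0) == 1:
            r0 = np.repeat(r0, nparam)
        candidates.insert(0, np.clip(np.log(r0[:nparam]), lo, hi))
    scored = sorted(candidates, key=lambda x0: nll(x0))
    best = None
    for x0 in scored[: max(restarts, 1)]:
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(lo, hi)] * nparam,
                       options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun):
        raise MkError("all Mk optimizer restarts failed")
    r = np.exp(best.x)
    g, l = (float(r[0]), float(r[0])) if symmetric else (float(r[0]), float(r[1]))
    if min(g, l) <= rate_bounds[0] * (1 + 1e-6):
        warnings.warn("fitted rate at lower bound (degenerate data?)",
                      RuntimeWarning, stacklevel=2)
    spec = OrderedMkSpec(S, symmetric, g, l)
    k = nparam
    lnL = -float(best.fun)
    return MkFit(spec, lnL, k, 2 * k - 2 * lnL, bool(best.success), S, tree_id)


def lrt(sym: MkFit, asym: MkFit, alpha: float = 0.05) -> LRTResult:
    """Likelihood-ratio test of the asymmetric vs the symmetric model (df=1)."""
    if sym.spec.symmetric is False or asym.spec.symmetric is True:
        raise MkError("arguments must be (symmetric fit, asymmetric fit)")
    if sym.n_states != asym.n_states or sym.tree_id != asym.tree_id:
        raise MkError("fits are not on identical tree/states")
    stat = 2.0 * (asym.lnL - sym.lnL)
    if stat < -1e-6:
        raise MkError(f"asymmetric lnL below symmetric by {-stat / 2:.3g}")
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df=1))
    return LRTResult(stat, 1, p, p < alpha, alpha)
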