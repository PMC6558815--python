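"""Gaussian trait models on trees: BM, OU, EB, trend and white noise.

All five models induce a multivariate normal distribution over tip values
whose mean is linear in the location parameters and whose covariance is
sigma2 times a shape matrix that depends only on the tree and, for EB/OU, on
one shape parameter (beta resp. alpha). Fitting therefore profiles the
location parameters by generalized least squares and sigma2 analytically, so
BM/TREND/WN are closed form and EB/OU reduce to bounded one-dimensional
searches with grid restarts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .treekit import DatedTree, phylo_covariance
from .traitio import TraitVector

__all__ = [
    "ModelError",
    "MODEL_NAMES",
    "MODEL_K",
    "ContModelSpec",
    "ContParams",
    "FitResult",
    "ModelComparison",
    "model_moments",
    "loglik",
    "fit_ml",
    "akaike_compare",
    "akaike_weights_from_aic",
    "simulate_traits",
    "ancestral_states",
]

MODEL_NAMES = ("BM", "OU", "EB", "TREND", "WN")
#: AIC parameter counts
MODEL_K = {"BM": 2, "OU": 4, "EB": 3, "TREND": 3, "WN": 2}

_JITTER = 1e-10


class ModelError(ValueError):
    """Invalid model specification, parameters or data."""


@dataclass(frozen=True)
class ContModelSpec:
    name: str
    beta_bounds: tuple[float, float] = (-10.0, 0.0)   # EB
    alpha_bounds: tuple[float, float] = (1e-8, 100.0)  # OU
    allow_positive_beta: bool = False

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ModelError(f"unknown model {self.name!r}")

    @property
    def k(self) -> int:
        return MODEL_K[self.name]


@dataclass(frozen=True)
class ContParams:
    theta0: float
    sigma2: float
    theta1: float | None = None  # OU optimum
    alpha: float | None = None   # OU attractor strength
    beta: float | None = None    # EB rate change
    trend: float | None = None   # TREND drift per unit time

    def __post_init__(self) -> None:
        if not (self.sigma2 > 0) or not math.isfinite(self.sigma2):
            raise ModelError(f"sigma2 must be positive and finite, got {self.sigma2}")
        if self.alpha is not None and self.alpha < 0:
            raise ModelError("alpha must be >= 0")


@dataclass(frozen=True)
class FitResult:
    model: ContModelSpec
    params: ContParams
    lnL: float
    aic: float
    converged: bool
    n_restarts_used: int
    tree_id: str | int | None = None

    def __post_init__(self) -> None:
        expected = 2 * self.model.k - 2 * self.lnL
        if abs(self.aic - expected) > 1e-9:
            raise ModelError("aic inconsistent with lnL and k")

    def params_dict(self) -> dict[str, float]:
        d = {"theta0": self.params.theta0, "sigma2": self.params.sigma2}
        for key in ("theta1", "alpha", "beta", "trend"):
            v = getattr(self.params, key)
            if v is not None:
                d[key] = v
        return d


@dataclass(frozen=True)
class ModelComparison:
    models: tuple[str, ...]
    aic: np.ndarray
    delta_aic: np.ndarray
    akaike_weight: np.ndarray


# ---------------------------------------------------------------------------
# Moments


def _shape_matrix(
    name: str, tree: DatedTree, alpha: float | None, beta: float | None,
    ST: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Covariance shape (covariance / sigma2) for each model."""
    S, T = ST if ST is not None else phylo_covariance(tree)
    if name in ("BM", "TREND"):
        return S
    if name == "WN":
        return np.eye(len(T))
    if name == "EB":
        b = beta or 0.0
        if b == 0.0:
            return S
        return np.expm1(b * S) / b
    if name == "OU":
        a = alpha if alpha is not None else 0.0
        if a == 0.0:
            return S
        D = T[:, None] + T[None, :] - 2.0 * S
        # (1 - e^{-2 a S}) / (2 a), via expm1 for small a
        return np.exp(-a * D) * (-np.expm1(-2.0 * a * S)) / (2.0 * a)
    raise ModelError(name)


def _mean_vector(name: str, params: ContParams, T: np.ndarray) -> np.ndarray:
    if name in ("BM", "EB", "WN"):
        return np.full_like(T, params.theta0)
    if name == "TREND":
        if params.trend is None:
            raise ModelError("TREND requires a trend parameter")
        return params.theta0 + params.trend * T
    if name == "OU":
        if params.theta1 is None or params.alpha is None:
            raise ModelError("OU requires theta1 and alpha")
        w = np.exp(-params.alpha * T)
        return params.theta1 + (params.theta0 - params.theta1) * w
    raise ModelError(name)


def model_moments(
    spec: ContModelSpec, params: ContParams, tree: DatedTree
) -> tuple[np.ndarray, np.ndarray]:
    """Tip-value mean vector and covariance matrix implied by the model."""
    for v in (params.theta0, params.sigma2, params.theta1, params.alpha,
              params.beta, params.trend):
        if v is not None and not math.isfinite(v):
            raise ModelError("non-finite parameter")
    S, T = phylo_covariance(tree)
    C = _shape_matrix(spec.name, tree, params.alpha, params.beta, ST=(S, T))
    return _mean_vector(spec.name, params, T), params.sigma2 * C


def _chol_logdet(C: np.ndarray) -> tuple[tuple, float]:
    """Cholesky factor and log-determinant, with a jitter retry.

    A numerically semi-definite matrix can pass ``cho_factor`` with a
    near-zero pivot, which poisons the solves; such factors are rejected and
    redone with a relative diagonal jitter.
    """
    scale = float(np.max(np.diag(C))) or 1.0

    def factor(M):
        cf = cho_factor(M, lower=True)
        d = np.diag(cf[0])
        if d.min() <= math.sqrt(scale) * 1e-9:
            raise np.linalg.LinAlgError("near-zero Cholesky pivot")
        return cf

    try:
        cf = factor(C)
    except (np.linalg.LinAlgError, ValueError):
        try:
            cf = factor(C + (_JITTER * scale) * np.eye(len(C)))
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise ModelError(
                f"covariance not positive definite after jitter "
                f"(cond~{np.linalg.cond(C):.3g})"
            ) from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return cf, logdet


def loglik(
    spec: ContModelSpec, params: ContParams, tree: DatedTree, traits: TraitVector
) -> float:
    """Exact multivariate-normal log density of the tip values."""
    y = np.asarray(traits.values, dtype=float)
    mu, V = model_moments(spec, params, tree)
    if len(y) != len(mu):
        raise ModelError("traits not aligned to tips")
    cf, logdet = _chol_logdet(V)
    r = y - mu
    q = float(r @ cho_solve(cf, r))
    n = len(y)
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + q)


# ---------------------------------------------------------------------------
# Fitting


def _gls_profile(C: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Profile (location params, sigma2, lnL) for covariance sigma2*C, mean X@b."""
    n = len(y)
    cf, logdet = _chol_logdet(C)
    Ci_X = cho_solve(cf, X)
    Ci_y = cho_solve(cf, y)
    XtCiX = X.T @ Ci_X
    try:
        b = np.linalg.solve(XtCiX, X.T @ Ci_y)
    except np.linalg.LinAlgError:
        # rank-deficient design (e.g. OU theta0/theta1 on an ultrametric
        # tree): minimum-norm solution, likelihood is unaffected
        b = np.linalg.lstsq(XtCiX, X.T @ Ci_y, rcond=None)[0]
    r = y - X @ b
    q = float(r @ cho_solve(cf, r))
    sigma2 = max(q / n, 1e-300)
    lnL = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return b, sigma2, lnL


def _design(name: str, T: np.ndarray, alpha: float | None) -> np.ndarray:
    ones = np.ones((len(T), 1))
    if name == "TREND":
        return np.hstack([ones, T[:, None]])
    if name == "OU":
        w = np.exp(-(alpha or 0.0) * T)
        return np.column_stack([w, 1.0 - w])  # coefficients (theta0, theta1)
    return ones


def fit_ml(
    spec: ContModelSpec,
    tree: DatedTree,
    traits: TraitVector,
    restarts: Sequence[float] | None = None,
    tol: float = 1e-10,
    tree_id: str | int | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one model.

    Location parameters and sigma2 are profiled exactly; for EB and OU the
    remaining shape parameter is found by bounded Brent searches started from
    a grid (``restarts`` overrides/extends the shape-parameter grid).
    """
    y = np.asarray(traits.values, dtype=float)
    n = tree.n_tips
    if len(y) != n:
        raise ModelError("traits not aligned to tips")
    if n < 3 and spec.name not in ("BM", "WN"):
        raise ModelError(f"{spec.name} requires at least 3 tips")
    if n < 2:
        raise ModelError("need at least 2 tips")
    constant = bool(np.ptp(y) == 0)
    S, T = phylo_covariance(tree)
    name = spec.name

    def pack(b, sigma2, lnL, shape: dict, nrs: int, conv=True) -> FitResult:
        if constant:
            warnings.warn(
                "constant trait values: sigma2 reported at the lower bound",
                RuntimeWarning,
                stacklevel=2,
            )
            sigma2 = max(sigma2, 1e-12)
            lnL = _lnl_at(name, shape, sigma2, b)
        theta0 = float(b[0])
        params = ContParams(
            theta0=theta0,
            sigma2=float(sigma2),
            theta1=float(b[1]) if name == "OU" else None,
            alpha=shape.get("alpha"),
            beta=shape.get("beta"),
            trend=float(b[1]) if name == "TREND" else None,
        )
        aic = 2 * spec.k - 2 * lnL
        return FitResult(spec, params, float(lnL), float(aic), conv, nrs, tree_id)

    def _lnl_at(name, shape, sigma2, b):
        C = _shape_matrix(name, tree, shape.get("alpha"), shape.get("beta"), ST=(S, T))
        X = _design(name, T, shape.get("alpha"))
        cf, logdet = _chol_logdet(C)
        r = y - X @ np.asarray(b, dtype=float)
        q = float(r @ cho_solve(cf, r))
        return -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + q / sigma2)

    if name == "WN":
        theta0 = float(np.mean(y))
        sigma2 = float(np.mean((y - theta0) ** 2))
        if sigma2 == 0:
            return pack([theta0], 0.0, 0.0, {}, 0)
        lnL = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
        return pack([theta0], sigma2, lnL, {}, 0)

    if name in ("BM", "TREND"):
        X = _design(name, T, None)
        b, sigma2, lnL = _gls_profile(S, X, y)
        return pack(b, sigma2, lnL, {}, 0)

    # EB / OU: 1-D profile search
    if name == "EB":
        lo, hi = spec.beta_bounds
        if spec.allow_positive_beta and hi <= 0:
            hi = -lo
        grid = list(restarts) if restarts else []
        grid += [lo * f for f in (0.8, 0.4, 0.2, 0.05, 0.01)] + [0.0]
        grid = sorted({min(max(g, lo), hi) for g in grid})

        def nll(beta: float) -> float:
            C = _shape_matrix("EB", tree, None, beta, ST=(S, T))
            _, _, l = _gls_profile(C, _design("EB", T, None), y)
            return -l

        best = _profile_search(nll, grid, lo, hi, tol)
        beta = best["x"]
        C = _shape_matrix("EB", tree, None, beta, ST=(S, T))
        b, sigma2, lnL = _gls_profile(C, _design("EB", T, None), y)
        return pack(b, sigma2, lnL, {"beta": float(beta)}, len(grid), best["converged"])

    if name == "OU":
        lo, hi = spec.alpha_bounds
        grid = list(restarts) if restarts else []
        grid += [0.01, 0.1, 0.5, 1.0, 3.0, 10.0, 30.0]
        grid = sorted({min(max(g, lo), hi) for g in grid})

        def nll_log(la: float) -> float:
            a = math.exp(la)
            C = _shape_matrix("OU", tree, a, None, ST=(S, T))
            _, _, l = _gls_profile(C, _design("OU", T, a), y)
            return -l

        log_grid = [math.log(g) for g in grid]
        best = _profile_search(nll_log, log_grid, math.log(lo), math.log(hi), tol)
        alpha = math.exp(best["x"])
        C = _shape_matrix("OU", tree, alpha, None, ST=(S, T))
        b, sigma2, lnL = _gls_profile(C, _design("OU", T, alpha), y)
        return pack(b, sigma2, lnL, {"alpha": float(alpha)}, len(grid), best["converged"])

    raise ModelError(name)


def _profile_search(nll, grid, lo, hi, tol) -> dict:
    """Grid evaluation followed by a bounded Brent polish around the best point."""
    evals = []
    for g in grid:
        try:
            evals.append((nll(g), g))
        except ModelError:
            continue
    if not evals:
        raise ModelError("all restarts failed")
    evals.sort(key=lambda t: t[0])
    f0, x0 = evals[0]
    # bracket around the best grid point
    xs = sorted(g for _, g in evals)
    i = xs.index(x0)
    a = xs[i - 1] if i > 0 else lo
    b = xs[i + 1] if i < len(xs) - 1 else hi
    a, b = max(a, lo), min(b, hi)
    converged = True
    if b - a > 1e-12:
        res = minimize_scalar(nll, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-10})
        converged = bool(res.success)
        if res.fun < f0:
            f0, x0 = float(res.fun), float(res.x)
    return {"x": x0, "fun": f0, "converged": converged}


# ---------------------------------------------------------------------------
# Model comparison


def akaike_compare(fits: Sequence[FitResult]) -> ModelComparison:
    """Delta-AIC and Akaike weights, computed in log space."""
    if len(fits) < 1:
        raise ModelError("no fits to compare")
    ids = {f.tree_id for f in fits}
    if len(ids) > 1:
        raise ModelError(f"fits come from different trees: {ids}")
    names = tuple(f.model.name for f in fits)
    aic = np.array([f.aic for f in fits], dtype=float)
    delta = aic - aic.min()
    logw = -delta / 2.0
    logw -= _logsumexp(logw)
    return ModelComparison(names, aic, delta, np.exp(logw))


def akaike_weights_from_aic(aic: Sequence[float]) -> np.ndarray:
    """Akaike weights directly from AIC values (log-space normalization)."""
    a = np.asarray(aic, dtype=float)
    logw = -(a - a.min()) / 2.0
    logw -= _logsumexp(logw)
    return np.exp(logw)


def _logsumexp(v: np.ndarray) -> float:
    m = float(v.max())
    return m + math.log(float(np.sum(np.exp(v - m))))


# ---------------------------------------------------------------------------
# Simulation


def simulate_traits(
    spec: ContModelSpec,
    params: ContParams,
    tree: DatedTree,
    n_reps: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """``n_reps`` independent draws of tip values; shape (n_reps, n_tips)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, V = model_moments(spec, params, tree)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(V + _JITTER * np.eye(len(V)))
    z = rng.standard_normal((n_reps, len(mu)))
    return mu[None, :] + z @ L.T


# ---------------------------------------------------------------------------
# Ancestral states


def _eb_rescaled_depths(tree: DatedTree, beta: float) -> np.ndarray:
    """Node depths after the EB clock transform t -> (e^{beta t} - 1)/beta."""
    d = tree.depths
    if beta == 0.0:
        return d.copy()
    return np.expm1(beta * d) / beta


def ancestral_states(
    fit: FitResult, tree: DatedTree, traits: TraitVector
) -> dict[int, float]:
    """GLS ancestral estimates for BM, EB or TREND fits, keyed by node index.

    The tree is first rescaled so the fitted model becomes Brownian (EB
    branches get length (e^{beta t2} - e^{beta t1})/beta); the root estimate
    equals the fitted theta0.
    """
    name = fit.model.name
    if name not in ("BM", "EB", "TREND"):
        raise ModelError(f"ancestral states unsupported for {name}")
    y = np.asarray(traits.values, dtype=float)
    S, T = phylo_covariance(tree)
    if name == "EB" and fit.params.beta:
        beta = fit.params.beta
        S = np.expm1(beta * S) / beta
        depth_fn = _eb_rescaled_depths(tree, beta)
    else:
        depth_fn = tree.depths.copy()

    # representative tip below each node, and tip membership per node
    rep_tip = np.empty(len(tree.nodes), dtype=int)
    below: dict[int, set[int]] = {}
    tip_pos = {t.index: k for k, t in enumerate(tree.tips)}
    for node in tree.nodes:
        if node.is_tip:
            below[node.index] = {tip_pos[node.index]}
            rep_tip[node.index] = tip_pos[node.index]
        else:
            s: set[int] = set()
            for c in node.children:
                s |= below[c.index]
            below[node.index] = s
            rep_tip[node.index] = rep_tip[node.children[0].index]

    mu_tips = _mean_vector(name, fit.params, T) if name == "TREND" else np.full(
        len(T), fit.params.theta0
    )
    cf, _ = _chol_logdet(S)
    w = cho_solve(cf, y - mu_tips)

    out: dict[int, float] = {}
    for node in tree.nodes:
        if node.is_tip:
            continue
        members = below[node.index]
        cross = np.empty(len(T))
        for j in range(len(T)):
            if j in members:
                cross[j] = depth_fn[node.index]
            else:
                cross[j] = S[rep_tip[node.index], j]
        if name == "TREND":
            mu_node = fit.params.theta0 + (fit.params.trend or 0.0) * tree.depths[node.index]
        else:
            mu_node = fit.params.theta0
        out[node.index] = float(mu_node + cross @ w)
    return out
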