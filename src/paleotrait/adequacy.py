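"""Independent contrasts and contrast-based model-adequacy tests.

Four statistics are computed from the standardized contrasts of a fitted
model's unit tree (the tree rescaled so that, if the model is adequate, the
contrasts are standard normal): the mean squared contrast, the coefficient of
variation of absolute contrasts (c_var), the slope of |contrast| on nodal
value (s_asr), and the Kolmogorov-Smirnov distance of the contrasts from
Normal(0, sqrt(mean squared contrast)) (d_cdf). Monte-Carlo p-values come
from re-simulating under the fitted model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .treekit import DatedTree
from .traitio import TraitVector
from .contmodels import FitResult, ModelError, simulate_traits

__all__ = [
    "ContrastSet",
    "AdequacyStats",
    "PPResult",
    "unit_tree",
    "pic",
    "adequacy_stats",
    "pp_test",
]

#: variance floor for zero-length cherries
VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class ContrastSet:
    contrasts: np.ndarray
    nodal_values: np.ndarray
    expected_variances: np.ndarray
    node_heights: np.ndarray


@dataclass(frozen=True)
class AdequacyStats:
    m_sig: float   # mean squared contrast
    c_var: float   # coefficient of variation of |contrasts|
    s_asr: float   # OLS slope of |contrast| on nodal value (nan if < 3 contrasts)
    d_cdf: float   # KS distance of contrasts from Normal(0, sqrt(m_sig))

    def as_dict(self) -> dict[str, float]:
        return {"m_sig": self.m_sig, "c_var": self.c_var,
                "s_asr": self.s_asr, "d_cdf": self.d_cdf}


@dataclass(frozen=True)
class PPResult:
    observed: AdequacyStats
    null_distribution: dict[str, np.ndarray]
    p_values: dict[str, float]
    extreme_tail: dict[str, str]
    n_sim: int


def unit_tree(fit: FitResult, tree: DatedTree) -> DatedTree:
    """Rescale branches so the fitted model becomes unit-rate Brownian motion.

    BM/TREND branches become sigma2*t; an EB branch spanning root-depths
    [t1, t2] becomes sigma2*(e^{beta t2} - e^{beta t1})/beta.
    """
    name = fit.model.name
    if name not in ("BM", "EB", "TREND"):
        raise ModelError(f"unit tree unsupported for {name}")
    s2 = fit.params.sigma2
    beta = fit.params.beta if name == "EB" else None
    new = tree.copy()
    depths = tree.depths
    for node in new.nodes:
        if node.parent is None:
            continue
        t2 = depths[node.index]
        t1 = depths[node.parent.index]
        if beta:
            node.length = s2 * (math.exp(beta * t2) - math.exp(beta * t1)) / beta
        else:
            node.length = s2 * (t2 - t1)
    return DatedTree(new.root, resolve_polytomies=False)


def pic(tree: DatedTree, traits: TraitVector) -> ContrastSet:
    """Standardized independent contrasts via the Felsenstein recursion.

    At each internal node joining values (x_i, x_j) on (variance-adjusted)
    branches (v_i, v_j): contrast = (x_i - x_j)/sqrt(v_i + v_j), nodal value
    is the inverse-variance weighted average, and the node's parent branch is
    extended by v_i*v_j/(v_i + v_j).
    """
    if len(traits.values) != tree.n_tips:
        raise ValueError("traits not aligned to tips")
    x: dict[int, float] = {}
    v: dict[int, float] = {}
    for tip, val in zip(tree.tips, traits.values):
        x[tip.index] = float(val)
        v[tip.index] = tip.length
    contrasts, nodal, evars, heights = [], [], [], []
    floored = 0
    for node in tree.nodes:  # postorder
        if node.is_tip:
            continue
        if len(node.children) != 2:
            raise ValueError("non-binary node; resolve polytomies first")
        ci, cj = node.children
        xi, xj = x.pop(ci.index), x.pop(cj.index)
        vi, vj = v.pop(ci.index), v.pop(cj.index)
        ev = vi + vj
        if ev < VAR_FLOOR:
            ev = VAR_FLOOR
            floored += 1
        contrasts.append((xi - xj) / math.sqrt(ev))
        if vi + vj > 0:
            xk = (xi / vi + xj / vj) / (1 / vi + 1 / vj) if vi > 0 and vj > 0 else (
                xi if vj > 0 else xj if vi > 0 else 0.5 * (xi + xj)
            )
            extra = vi * vj / (vi + vj)
        else:
            xk = 0.5 * (xi + xj)
            extra = 0.0
        nodal.append(xk)
        evars.append(ev)
        heights.append(tree.node_ages[node.index])
        x[node.index] = xk
        v[node.index] = node.length + extra
    if floored:
        warnings.warn(f"{floored} zero-length cherry variances floored at {VAR_FLOOR}",
                      RuntimeWarning, stacklevel=2)
    return ContrastSet(
        contrasts=np.array(contrasts),
        nodal_values=np.array(nodal),
        expected_variances=np.array(evars),
        node_heights=np.array(heights),
    )


def adequacy_stats(cs: ContrastSet, sqrt_transform: bool = False) -> AdequacyStats:
    """The four adequacy statistics of a contrast set.

    ``sqrt_transform`` switches the s_asr regression to square-root
    transformed absolute contrasts.
    """
    c = cs.contrasts
    a = np.abs(c)
    m_sig = float(np.mean(c ** 2))
    mean_a = float(np.mean(a))
    c_var = float(np.std(a, ddof=1) / mean_a) if mean_a > 0 and len(a) > 1 else 0.0
    if len(c) >= 3:
        yv = np.sqrt(a) if sqrt_transform else a
        xv = cs.nodal_values
        denom = float(np.sum((xv - xv.mean()) ** 2))
        s_asr = float(np.sum((xv - xv.mean()) * (yv - yv.mean())) / denom) if denom > 0 else 0.0
    else:
        s_asr = float("nan")
    d_cdf = _ks_distance(c, math.sqrt(m_sig)) if m_sig > 0 else 0.0
    return AdequacyStats(m_sig=m_sig, c_var=c_var, s_asr=s_asr, d_cdf=d_cdf)


def _ks_distance(sample: np.ndarray, sd: float) -> float:
    """Sup distance between the sample ECDF and Normal(0, sd), at step points."""
    xs = np.sort(sample)
    n = len(xs)
    cdf = norm.cdf(xs, loc=0.0, scale=sd)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def pp_test(
    fit: FitResult,
    tree: DatedTree,
    traits: TraitVector,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    sqrt_transform: bool = False,
) -> PPResult:
    """Posterior-predictive adequacy test of a fitted BM/EB/TREND model.

    Simulates ``n_sim`` datasets under the fitted model on the original tree,
    recomputes the statistics on the same unit tree, and reports two-tailed
    Monte-Carlo p-values with the +1 correction:
    p = min(1, 2*min((1+#{sim<=obs})/(n+1), (1+#{sim>=obs})/(n+1))).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    ut = unit_tree(fit, tree)
    observed = adequacy_stats(pic(ut, traits), sqrt_transform=sqrt_transform)
    sims = simulate_traits(fit.model, fit.params, tree, n_sim, seed)
    names = ("m_sig", "c_var", "s_asr", "d_cdf")
    null = {k: np.empty(n_sim) for k in names}
    for i in range(n_sim):
        tv = TraitVector(values=sims[i], variant=traits.variant, labels=traits.labels)
        st = adequacy_stats(pic(ut, tv), sqrt_transform=sqrt_transform)
        for k in names:
            null[k][i] = getattr(st, k)
    p_values, tails = {}, {}
    for k in names:
        obs = getattr(observed, k)
        sim = null[k]
        if not math.isfinite(obs):
            p_values[k] = float("nan")
            tails[k] = "undefined"
            continue
        p_lo = (1 + int(np.sum(sim <= obs))) / (n_sim + 1)
        p_hi = (1 + int(np.sum(sim >= obs))) / (n_sim + 1)
        p_values[k] = min(1.0, 2.0 * min(p_lo, p_hi))
        tails[k] = "lower" if p_lo < p_hi else "upper"
    return PPResult(observed, null, p_values, tails, n_sim)
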