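"""Multi-tree ensemble fitting and fossil/extant jackknife experiments."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .treekit import DatedTree, prune_to_taxa
from .traitio import TraitRecord, map_to_tips
from .contmodels import (
    ContModelSpec,
    FitResult,
    akaike_weights_from_aic,
    fit_ml,
)

__all__ = [
    "JackknifePlan",
    "EnsembleResult",
    "run_ensemble",
    "make_jackknife_plan",
    "run_jackknife",
    "jackknife_summary",
    "run_mk_ensemble",
]

log = logging.getLogger(__name__)

PARAM_COLS = ("theta0", "theta1", "sigma2", "alpha", "beta", "trend")


@dataclass(frozen=True)
class JackknifePlan:
    group: str                   # "fossil" or "extant"
    pool: tuple[str, ...]        # removable tip labels
    step_sizes: tuple[int, ...]  # removal counts, strictly increasing
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        if self.group not in ("fossil", "extant"):
            raise ValueError("group must be 'fossil' or 'extant'")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        sizes = self.step_sizes
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("step_sizes must be strictly increasing")
        if sizes and sizes[-1] > len(self.pool):
            raise ValueError("largest step exceeds pool size")


@dataclass
class EnsembleResult:
    """Long-format table of fits keyed by (tree_id, rep, n_removed, model)."""

    table: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Per-model mean +/- SD across trees, mean AIC and Akaike weights.

        Weights are computed from the mean AICs (which reproduces weights
        computed from printed mean AICs); per-tree weights are in the table.
        """
        g = self.table.groupby("model", sort=False)
        rows = []
        for model, df in g:
            row: dict[str, object] = {"model": model, "n_fits": len(df)}
            for p in PARAM_COLS + ("lnL",):
                if p in df and df[p].notna().any():
                    row[f"{p}_mean"] = float(df[p].mean())
                    row[f"{p}_sd"] = float(df[p].std(ddof=1)) if len(df) > 1 else 0.0
            row["aic_mean"] = float(df["aic"].mean())
            rows.append(row)
        out = pd.DataFrame(rows)
        out["akaike_weight"] = akaike_weights_from_aic(out["aic_mean"].to_numpy())
        return out


def _fit_row(fit: FitResult, tree_id, rep: int, n_removed: int) -> dict:
    row = {
        "tree_id": tree_id,
        "rep": rep,
        "n_removed": n_removed,
        "model": fit.model.name,
        "lnL": fit.lnL,
        "aic": fit.aic,
        "converged": fit.converged,
    }
    for p in PARAM_COLS:
        row[p] = fit.params_dict().get(p, np.nan)
    return row


def _fit_all_models(
    tree: DatedTree,
    traits,
    models: Sequence[ContModelSpec],
    tree_id,
    rep: int = 0,
    n_removed: int = 0,
    warm_starts: dict[str, float] | None = None,
) -> list[dict]:
    rows = []
    for spec in models:
        restarts = None
        if warm_starts and spec.name in warm_starts:
            restarts = [warm_starts[spec.name]]
        try:
            fit = fit_ml(spec, tree, traits, restarts=restarts, tree_id=tree_id)
        except Exception as exc:  # record and continue, per contract
            warnings.warn(f"fit failure ({spec.name}, tree {tree_id}): {exc}",
                          RuntimeWarning, stacklevel=2)
            continue
        rows.append(_fit_row(fit, tree_id, rep, n_removed))
    if rows:
        aics = np.array([r["aic"] for r in rows])
        for r, w in zip(rows, akaike_weights_from_aic(aics)):
            r["akaike_weight"] = float(w)
    return rows


def run_ensemble(
    trees: Sequence[DatedTree],
    records: Sequence[TraitRecord],
    models: Sequence[ContModelSpec],
    variant: str = "mean",
    congeneric_swaps=None,
) -> EnsembleResult:
    """Fit every model on every tree; per-(tree) Akaike weights included."""
    tipsets = {tuple(sorted(t.tip_labels)) for t in trees}
    if len(tipsets) > 1:
        raise ValueError("all ensemble trees must share one tip set")
    all_rows = []
    for i, tree in enumerate(trees):
        traits, _ = map_to_tips(records, tree, variant, congeneric_swaps)
        all_rows.extend(_fit_all_models(tree, traits, models, tree_id=i))
        log.info("ensemble tree %d/%d fitted", i + 1, len(trees))
    return EnsembleResult(pd.DataFrame(all_rows))


def make_jackknife_plan(
    tree: DatedTree,
    records: Sequence[TraitRecord],
    group: str,
    n_steps: int = 10,
    n_reps: int = 20,
    seed: int = 0,
    cap: int | None = None,
) -> JackknifePlan:
    """Removal plan: rounded equal increments from pool/n_steps up to ``cap``.

    For the fossil group the default cap is the whole pool; for the extant
    group it defaults to the fossil-pool size (matched removal magnitudes).
    """
    species = {r.species for r in records}
    fossils = [t for t in tree.extinct_labels() if t in species]
    extants = [t for t in tree.extant_labels() if t in species]
    pool = fossils if group == "fossil" else extants
    if not pool:
        raise ValueError(f"empty removal pool for group {group!r}")
    if cap is None:
        cap = len(fossils) if group == "fossil" else min(len(fossils), len(extants))
        cap = cap or len(pool)
    if cap > len(pool):
        raise ValueError(f"cap {cap} exceeds pool size {len(pool)}")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    sizes = np.unique(
        np.rint(np.linspace(cap / n_steps, cap, n_steps)).astype(int)
    )
    sizes = tuple(int(s) for s in sizes if s >= 1)
    return JackknifePlan(group=group, pool=tuple(sorted(pool)),
                         step_sizes=sizes, n_reps=n_reps, seed=seed)


def run_jackknife(
    trees: Sequence[DatedTree],
    records: Sequence[TraitRecord],
    plan: JackknifePlan,
    models: Sequence[ContModelSpec],
    variant: str = "mean",
    congeneric_swaps=None,
    include_full: bool = True,
    warm_starts: dict[str, float] | None = None,
) -> EnsembleResult:
    """Prune-and-refit over all (step, replicate) cells.

    Replicate r of each step removes a fresh random subset from the pool and
    refits all models on tree r mod n_trees. ``include_full`` adds the
    0-removed cell, which reproduces ``run_ensemble`` rows for the trees
    visited. Warm starts (full-data alpha/beta) are injected into the restart
    grids when given.
    """
    all_rows: list[dict] = []
    record_by_species = {r.species: r for r in records}
    steps = ((0,) if include_full else ()) + plan.step_sizes
    for step_i, n_removed in enumerate(steps):
        for rep in range(plan.n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=plan.seed, spawn_key=(step_i, rep))
            )
            tree = trees[rep % len(trees)]
            if n_removed > 0:
                removed = set(
                    rng.choice(plan.pool, size=n_removed, replace=False).tolist()
                )
                keep = [t for t in tree.tip_labels if t not in removed]
                sub = prune_to_taxa(tree, keep)
            else:
                sub = tree
            kept_records = [record_by_species[t] for t in sub.tip_labels]
            traits, _ = map_to_tips(kept_records, sub, variant, congeneric_swaps)
            rows = _fit_all_models(
                sub, traits, models,
                tree_id=rep % len(trees), rep=rep, n_removed=n_removed,
                warm_starts=warm_starts,
            )
            if len(rows) < len(models):
                # incomplete cell: drop so medians stay comparable
                warnings.warn(
                    f"jackknife cell (n_removed={n_removed}, rep={rep}) incomplete; "
                    "skipped", RuntimeWarning, stacklevel=2)
                continue
            all_rows.extend(rows)
        log.info("jackknife step n_removed=%d done (%d reps)", n_removed, plan.n_reps)
    df = pd.DataFrame(all_rows)
    if not df.empty:
        pool_size = len(plan.pool)
        df["n_retained"] = pool_size - df["n_removed"]
    return EnsembleResult(df)


def run_mk_ensemble(
    trees: Sequence[DatedTree],
    records: Sequence[TraitRecord],
    variants: Sequence[str] = ("discrete", "discrete_min", "discrete_max"),
    root_prior: str = "uniform",
    alpha: float = 0.05,
    congeneric_swaps=None,
) -> pd.DataFrame:
    """Median MkS/MkA rates, lnL and the LRT per count variant across trees."""
    from .mkmodels import fit_mk, lrt

    rows = []
    for variant in variants:
        per_tree = []
        for i, tree in enumerate(trees):
            states, _ = map_to_tips(records, tree, variant, congeneric_swaps)
            sym = fit_mk(tree, states, symmetric=True, root_prior=root_prior, tree_id=i)
            asym = fit_mk(tree, states, symmetric=False, n_states=sym.n_states,
                          root_prior=root_prior, tree_id=i,
                          init_rates=(sym.spec.q_gain,))
            per_tree.append((sym, asym))
            log.info("mk variant %s tree %d/%d fitted", variant, i + 1, len(trees))
        sym_lnl = float(np.median([s.lnL for s, _ in per_tree]))
        asym_lnl = float(np.median([a.lnL for _, a in per_tree]))
        stat = max(0.0, 2.0 * (asym_lnl - sym_lnl))
        from scipy.stats import chi2

        p = float(chi2.sf(stat, df=1))
        rows.append({
            "variant": variant,
            "rate_sym": float(np.median([s.spec.q_gain for s, _ in per_tree])),
            "rate_gain": float(np.median([a.spec.q_gain for _, a in per_tree])),
            "rate_loss": float(np.median([a.spec.q_loss for _, a in per_tree])),
            "lnL_sym": sym_lnl,
            "lnL_asym": asym_lnl,
            "lrt_statistic": stat,
            "lrt_p": p,
            "significant": p < alpha,
            "n_states": per_tree[0][0].n_states,
        })
    return pd.DataFrame(rows)


def jackknife_summary(result: EnsembleResult) -> pd.DataFrame:
    """Per-(n_removed, model) medians and quartiles of weights and parameters."""
    df = result.table
    rows = []
    for (n_removed, model), g in df.groupby(["n_removed", "model"], sort=True):
        row = {
            "n_removed": n_removed,
            "n_retained": int(g["n_retained"].iloc[0]) if "n_retained" in g else np.nan,
            "model": model,
            "n_reps": g["rep"].nunique(),
            "weight_median": float(g["akaike_weight"].median()),
            "weight_q25": float(g["akaike_weight"].quantile(0.25)),
            "weight_q75": float(g["akaike_weight"].quantile(0.75)),
        }
        for p in PARAM_COLS:
            if p in g and g[p].notna().any():
                row[f"{p}_median"] = float(g[p].median())
        rows.append(row)
    return pd.DataFrame(rows)
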