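"""Run configuration, manifests and end-to-end orchestration helpers."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import platform
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .treekit import read_trees, prune_to_taxa, rescale_unit_height
from .traitio import read_trait_table, map_to_tips
from .contmodels import ContModelSpec, MODEL_NAMES
from .resampling import (
    run_ensemble,
    run_mk_ensemble,
    make_jackknife_plan,
    run_jackknife,
    jackknife_summary,
)
from .adequacy import pp_test

__all__ = ["RunConfig", "load_config", "prepare_inputs", "write_manifest",
           "cmd_fit", "cmd_mk", "cmd_adequacy", "cmd_jackknife"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    trees: str = ""
    traits: str = ""
    out_dir: str = "results"
    variant: str = "mean"
    models: tuple[str, ...] = MODEL_NAMES
    n_trees: int | None = None       # cap on ensemble size
    adequacy_model: str = "EB"
    adequacy_n_sim: int = 1000
    jackknife_group: str = "fossil"
    jackknife_steps: int = 10
    jackknife_reps: int = 20
    mk_root_prior: str = "uniform"
    unit_height: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("mean", "soft_min", "soft_max"):
            raise ValueError(f"invalid variant {self.variant!r}")
        for m in self.models:
            if m not in MODEL_NAMES:
                raise ValueError(f"unknown model {m!r}")


def load_config(path: str | None, **overrides) -> RunConfig:
    data: dict = {}
    if path:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "models" in data and isinstance(data["models"], (list, tuple)):
        data["models"] = tuple(data["models"])
    return RunConfig(**data)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(cfg: RunConfig, out_dir: str) -> str:
    manifest = {
        "config": asdict(cfg),
        "inputs": {
            p: _sha256(p) for p in (cfg.trees, cfg.traits) if p and os.path.exists(p)
        },
        "versions": {
            "paleotrait": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def prepare_inputs(cfg: RunConfig):
    """Read trees + traits, prune to shared taxa, optionally unit-rescale.

    Returns (trees, records) ready for model fitting.
    """
    trees = read_trees(cfg.trees)
    if cfg.n_trees:
        trees = trees[: cfg.n_trees]
    records = read_trait_table(cfg.traits)
    species = {r.species for r in records}
    prepared = []
    for t in trees:
        shared = [l for l in t.tip_labels if l in species]
        if len(shared) < len(t.tip_labels):
            t = prune_to_taxa(t, shared)
        if cfg.unit_height:
            t = rescale_unit_height(t)
        prepared.append(t)
    kept = set(prepared[0].tip_labels)
    records = [r for r in records if r.species in kept]
    return prepared, records


def _specs(names: Sequence[str]) -> list[ContModelSpec]:
    return [ContModelSpec(n) for n in names]


def cmd_fit(cfg: RunConfig) -> pd.DataFrame:
    trees, records = prepare_inputs(cfg)
    result = run_ensemble(trees, records, _specs(cfg.models), variant=cfg.variant)
    os.makedirs(cfg.out_dir, exist_ok=True)
    result.table.to_csv(os.path.join(cfg.out_dir, "fits.tsv"), sep="\t", index=False)
    summary = result.summary()
    summary.to_csv(os.path.join(cfg.out_dir, "fit_summary.tsv"), sep="\t", index=False)
    with open(os.path.join(cfg.out_dir, "fit_summary.json"), "w") as fh:
        json.dump(summary.to_dict(orient="records"), fh, indent=2)
    write_manifest(cfg, cfg.out_dir)
    return summary


def cmd_mk(cfg: RunConfig) -> pd.DataFrame:
    trees, records = prepare_inputs(cfg)
    table = run_mk_ensemble(trees, records, root_prior=cfg.mk_root_prior)
    os.makedirs(cfg.out_dir, exist_ok=True)
    table.to_csv(os.path.join(cfg.out_dir, "mk_summary.tsv"), sep="\t", index=False)
    write_manifest(cfg, cfg.out_dir)
    return table


def cmd_adequacy(cfg: RunConfig) -> pd.DataFrame:
    from .contmodels import fit_ml

    trees, records = prepare_inputs(cfg)
    tree = trees[0]
    traits, _ = map_to_tips(records, tree, cfg.variant)
    fit = fit_ml(ContModelSpec(cfg.adequacy_model), tree, traits)
    result = pp_test(fit, tree, traits, n_sim=cfg.adequacy_n_sim, seed=cfg.seed)
    rows = []
    for stat, p in result.p_values.items():
        null = result.null_distribution[stat]
        rows.append({
            "statistic": stat,
            "observed": getattr(result.observed, stat),
            "null_mean": float(np.mean(null)),
            "null_sd": float(np.std(null, ddof=1)),
            "p": p,
            "extreme_tail": result.extreme_tail[stat],
        })
    table = pd.DataFrame(rows)
    os.makedirs(cfg.out_dir, exist_ok=True)
    table.to_csv(os.path.join(cfg.out_dir, "adequacy.tsv"), sep="\t", index=False)
    write_manifest(cfg, cfg.out_dir)
    return table


def cmd_jackknife(cfg: RunConfig) -> pd.DataFrame:
    trees, records = prepare_inputs(cfg)
    plan = make_jackknife_plan(
        trees[0], records, cfg.jackknife_group,
        n_steps=cfg.jackknife_steps, n_reps=cfg.jackknife_reps, seed=cfg.seed,
    )
    result = run_jackknife(trees, records, plan, _specs(cfg.models),
                           variant=cfg.variant)
    summary = jackknife_summary(result)
    os.makedirs(cfg.out_dir, exist_ok=True)
    result.table.to_csv(os.path.join(cfg.out_dir, "jackknife.tsv"), sep="\t",
                        index=False)
    summary.to_csv(os.path.join(cfg.out_dir, "jackknife_summary.tsv"), sep="\t",
                   index=False)
    write_manifest(cfg, cfg.out_dir)
    return summary
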