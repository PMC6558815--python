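"""Synthetic data: birth-death trees with sampled fossil tips and trait tables.

Emulates the structure of the empirical inputs — a dated tree mixing extant
and extinct tips, stratigraphic intervals around fossil ages, and a count
table with point records and polymorphic ranges — so every pipeline stage can
be exercised at desk scale with known generating parameters.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Any

import numpy as np

from .treekit import DatedTree, Node, StratRange, write_trees
from .traitio import TraitRecord, write_trait_table
from .contmodels import ContModelSpec, ContParams, simulate_traits
from .mkmodels import OrderedMkSpec

__all__ = ["SynthConfig", "simulate_tree", "simulate_trait_table", "make_fixture"]


@dataclass(frozen=True)
class SynthConfig:
    n_extant: int = 32
    birth_rate: float = 1.0
    death_rate: float = 0.3
    fossil_keep_prob: float = 0.5
    strat_window: float = 1.0
    trait_model: ContModelSpec | OrderedMkSpec | None = None
    trait_params: ContParams | None = None
    root_state: int = 10          # Mk simulations start here
    range_noise: float = 0.2      # probability of a reported polymorphic range
    range_width_max: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_extant < 2:
            raise ValueError("n_extant must be >= 2")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be >= 0")
        for p in (self.fossil_keep_prob, self.range_noise):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Birth-death tree with sampled extinct tips


def simulate_tree(cfg: SynthConfig, max_tries: int = 100):
    """Forward birth-death simulation stopped when ``n_extant`` lineages live.

    Extinct lineages are retained as fossil tips with probability
    ``fossil_keep_prob``; each retained fossil gets a fad/lad interval
    bracketing its true age within ``strat_window``. Returns
    (DatedTree, list[StratRange], n_retries).
    """
    rng = np.random.default_rng(cfg.seed)
    for attempt in range(max_tries):
        result = _bd_once(cfg, rng)
        if result is not None:
            tree, ranges = result
            return tree, ranges, attempt
    raise RuntimeError(f"birth-death simulation failed {max_tries} times")


def _bd_once(cfg: SynthConfig, rng: np.random.Generator):
    birth, death = cfg.birth_rate, cfg.death_rate
    root = Node(length=0.0)
    # alive entries: (node, birth_time)
    first = root.add_child(Node(length=0.0))
    alive: list[tuple[Node, float]] = [(first, 0.0)]
    dead: list[tuple[Node, float, float]] = []  # (node, birth_time, death_time)
    t = 0.0
    while alive and len(alive) < cfg.n_extant:
        k = len(alive)
        rate = k * (birth + death)
        t += rng.exponential(1.0 / rate)
        i = int(rng.integers(k))
        node, t0 = alive.pop(i)
        node.length = t - t0
        if rng.random() < birth / (birth + death) or death == 0.0:
            for _ in range(2):
                alive.append((node.add_child(Node(length=0.0)), t))
        else:
            dead.append((node, t0, t))
    if not alive:
        return None
    # stop strictly between the last event and the next would-be event, so
    # the youngest lineages get positive terminal branches
    k = len(alive)
    present = t + rng.exponential(1.0 / (k * (birth + death))) if birth + death > 0 else t
    tip_id = 0
    for node, t0 in alive:
        node.length = present - t0
        node.label = f"ext{tip_id}"
        tip_id += 1
    ranges: list[StratRange] = []
    fossils: list[Node] = []
    drop: list[Node] = []
    for node, t0, t1 in dead:
        if node.children:  # died after splitting? cannot happen, guard anyway
            continue
        if rng.random() < cfg.fossil_keep_prob:
            node.label = f"fos{len(fossils)}"
            fossils.append(node)
            true_age = present - t1
            w = cfg.strat_window / 2.0
            fad = true_age + rng.uniform(0, w)
            lad = max(0.0, true_age - rng.uniform(0, w))
            ranges.append(StratRange(taxon=node.label, fad=fad, lad=lad))
        else:
            drop.append(node)
    _prune_nodes(root, drop)
    tree_root = _collapse_root(root)
    n_tips = sum(1 for _ in _iter_tips(tree_root))
    if n_tips < cfg.n_extant:  # everything extinct got pruned below the root
        return None
    return DatedTree(tree_root, resolve_polytomies=False), ranges


def _iter_tips(root: Node):
    stack = [root]
    while stack:
        n = stack.pop()
        if n.children:
            stack.extend(n.children)
        else:
            yield n


def _prune_nodes(root: Node, drop: list[Node]) -> None:
    """Remove tips in ``drop`` and suppress the resulting unary nodes."""
    for node in drop:
        parent = node.parent
        parent.children.remove(node)
        while parent is not None and parent.parent is not None and not parent.children:
            gp = parent.parent
            gp.children.remove(parent)
            parent = gp
    # suppress unary internals, merging branch lengths
    stack = [root]
    while stack:
        n = stack.pop()
        while len(n.children) == 1:
            only = n.children[0]
            n.children = only.children
            n.length += only.length
            n.label = only.label
            for c in n.children:
                c.parent = n
        stack.extend(n.children)


def _collapse_root(root: Node) -> Node:
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = 0.0
    return root


# ---------------------------------------------------------------------------
# Trait tables


def simulate_trait_table(
    tree: DatedTree,
    cfg: SynthConfig,
    ranges: list[StratRange] | None = None,
) -> tuple[list[TraitRecord], dict[str, Any]]:
    """Simulate a count table for ``tree`` under the configured trait model.

    Continuous models are drawn from their exact tip distribution and mapped
    to counts by round-half-up, floored at 0; ordered Mk traits are simulated
    exactly along branches by Gillespie event sampling. Returns
    (records, truth) where truth carries the generating parameters and the
    pre-rounding values.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    range_by_taxon = {r.taxon: r for r in (ranges or [])}
    truth: dict[str, Any] = {"seed": cfg.seed}
    if isinstance(cfg.trait_model, OrderedMkSpec):
        values = _gillespie_traits(tree, cfg.trait_model, cfg.root_state, rng)
        raw = values.astype(float)
        counts = values
        truth.update(
            model="Mk",
            symmetric=cfg.trait_model.symmetric,
            q_gain=cfg.trait_model.q_gain,
            q_loss=cfg.trait_model.q_loss,
            root_state=cfg.root_state,
        )
    else:
        if cfg.trait_model is None or cfg.trait_params is None:
            raise ValueError("trait_model and trait_params required")
        raw = simulate_traits(cfg.trait_model, cfg.trait_params, tree, 1, rng)[0]
        counts = np.maximum(np.floor(raw + 0.5), 0).astype(int)
        truth.update(model=cfg.trait_model.name,
                     params={k: v for k, v in vars(cfg.trait_params).items()
                             if v is not None})
    truth["raw_values"] = {lab: float(v) for lab, v in zip(tree.tip_labels, raw)}

    records = []
    for tip, c in zip(tree.tips, counts):
        c = int(c)
        extinct = tree.is_extinct(tip)
        sr = range_by_taxon.get(tip.label)
        if extinct and sr is None:
            age = tree.node_ages[tip.index]
            sr = StratRange(tip.label, fad=float(age), lad=float(age))
        if rng.random() < cfg.range_noise:
            lo = max(0, c - int(rng.integers(1, cfg.range_width_max + 1)))
            hi = c + int(rng.integers(1, cfg.range_width_max + 1))
            rec = TraitRecord(
                species=tip.label, old_label=tip.label,
                count_min=lo, count_max=hi, count_mean=(lo + hi) / 2.0,
                polymorphism_reported=True, extinct=extinct,
                fad=sr.fad if extinct else None,
                lad=sr.lad if extinct else None,
            )
        else:
            rec = TraitRecord(
                species=tip.label, old_label=tip.label,
                count_min=c, count_max=c, count_mean=float(c),
                polymorphism_reported=False, extinct=extinct,
                fad=sr.fad if extinct else None,
                lad=sr.lad if extinct else None,
            )
        records.append(rec)
    return records, truth


def _gillespie_traits(
    tree: DatedTree, spec: OrderedMkSpec, root_state: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact event-by-event simulation of the ordered chain along branches."""
    states: dict[int, int] = {tree.root.index: int(root_state)}
    for node in reversed(tree.nodes):  # preorder
        if node.parent is None:
            continue
        s = states[node.parent.index]
        t = node.length
        while True:
            gain = spec.q_gain
            loss = spec.q_loss if s > 0 else 0.0
            total = gain + loss
            if total <= 0:
                break
            t -= rng.exponential(1.0 / total)
            if t <= 0:
                break
            s += 1 if rng.random() < gain / total else -1
        states[node.index] = s
    return np.array([states[t.index] for t in tree.tips], dtype=int)


# ---------------------------------------------------------------------------
# Fixture bundles


def make_fixture(name: str, cfg: SynthConfig, out_dir) -> dict[str, str]:
    """Write a self-describing fixture: trees.tre + traits.csv + truth.json."""
    path = os.path.join(str(out_dir), name)
    os.makedirs(path, exist_ok=True)
    tree, ranges, retries = simulate_tree(cfg)
    records, truth = simulate_trait_table(tree, cfg, ranges)
    truth["n_retries"] = retries
    truth["n_tips"] = tree.n_tips
    truth["n_extinct"] = len(tree.extinct_labels())
    files = {
        "trees": os.path.join(path, "trees.tre"),
        "traits": os.path.join(path, "traits.csv"),
        "truth": os.path.join(path, "truth.json"),
    }
    write_trees([tree], files["trees"])
    write_trait_table(records, files["traits"])
    with open(files["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return files
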