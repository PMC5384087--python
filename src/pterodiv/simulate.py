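"""Seeded simulators for every stage of the analysis chain.

The generators produce data with exactly the statistical structure the
inference stages assume: birth-death chronograms with exponentially
time-varying rates (forward simulation with thinning, extinct lineages
pruned), Brownian-motion traits under lambda/delta covariance scalings, and
DEC range histories evolved along branches under per-epoch dispersal
multipliers with cladogenetic range inheritance. A single integer seed
deterministically spawns independent substreams per stage, so stage outputs
never depend on the order stages are run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biogeo import (
    AreaSystem,
    DECParams,
    DispersalSchedule,
    StateSpace,
    _cladogenesis_pairs,
)
from .trees import Chronogram
from .traits import transformed_covariance

__all__ = [
    "SimConfig",
    "stage_rng",
    "simulate_bd_tree",
    "simulate_yule_n_tips",
    "simulate_bm_trait",
    "simulate_dec_history",
    "make_species_table",
]

MAX_RESIM = 1000


@dataclass
class SimConfig:
    """One bundle of generator settings; the seed is mandatory."""

    seed: int
    # tree
    lambda0: float = 0.161  # /lineage/my at present
    alpha: float = 0.110  # /my; >0 = faster speciation in the past
    mu0: float = 0.0
    beta: float = 0.0
    crown_age: float = 10.6  # my
    sampling_fraction: float = 1.0
    # trait (elevation-like, metres)
    sigma2: float = 4.0e4  # m^2/my
    root_state: float = 1500.0  # m
    lam: float = 1.0
    delta: float = 1.0
    # ranges
    d: float = 0.05  # /area/my
    e: float = 0.01
    max_range_size: int = 4
    root_range: str | None = None

    def __post_init__(self) -> None:
        for name in ("lambda0", "mu0", "d", "e", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream of the global seed."""
    stages = ("tree", "trait", "ranges", "table", "extra")
    if stage not in stages:
        raise ValueError(f"unknown stage {stage!r}")
    children = np.random.SeedSequence(seed).spawn(len(stages))
    return np.random.default_rng(children[stages.index(stage)])


# ---------------------------------------------------------------------------
# birth-death chronograms
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("parent", "birth", "death", "children")

    def __init__(self, parent, birth):
        self.parent = parent
        self.birth = birth  # forward time from the crown
        self.death = None
        self.children = []


def _simulate_once(lambda0, alpha, mu0, beta, T, rng):
    """Forward Gillespie with thinning from a crown pair; forward time s in
    [0, T] maps to backward time t = T - s."""

    def lam(s):
        return lambda0 * np.exp(alpha * (T - s))

    def mu(s):
        return mu0 * np.exp(beta * (T - s))

    def rate_bound(s):
        # exponential rates are monotone: the max over [s, T] is an endpoint
        return max(lam(s), lam(T)) + max(mu(s), mu(T))

    root = _Lineage(None, 0.0)
    left = _Lineage(root, 0.0)
    right = _Lineage(root, 0.0)
    root.children = [left, right]
    root.death = 0.0
    alive = [left, right]
    s = 0.0
    while alive and s < T:
        k = len(alive)
        bound = k * rate_bound(s)
        if bound <= 0:
            break
        s = s + rng.exponential(1.0 / bound)
        if s >= T:
            break
        total = k * (lam(s) + mu(s))
        if rng.random() >= total / bound:
            continue  # thinned
        lineage = alive[rng.integers(k)]
        if rng.random() < lam(s) / (lam(s) + mu(s)):
            a, b = _Lineage(lineage, s), _Lineage(lineage, s)
            lineage.children = [a, b]
            lineage.death = s
            alive.remove(lineage)
            alive.extend([a, b])
        else:
            lineage.death = s
            alive.remove(lineage)
    for ln in alive:
        ln.death = T
    return root, alive


def _to_chronogram(root, T, sampled) -> Chronogram | None:
    """Prune to the sampled tip set and emit a Chronogram."""

    keep: set[int] = set()

    def mark(node):
        has = False
        if not node.children:
            has = node in sampled
        else:
            for c in node.children:
                if mark(c):
                    has = True
        if has:
            keep.add(id(node))
        return has

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(100000)
    try:
        mark(root)

        def collect(node, top):
            """Return (tips, internals) of the pruned subtree rooted at node;
            suppress unifurcations by extending from `top` (birth time)."""
            kids = [c for c in node.children if id(c) in keep]
            if not kids:
                return ("tip", top, node)
            if len(kids) == 1:
                return collect(kids[0], top)
            parts = [collect(c, node.death) for c in kids]
            return ("node", top, node.death, parts)

        if id(root) not in keep:
            return None
        tree = collect(root, 0.0)
        if tree[0] == "tip":
            return None  # fewer than 2 surviving tips

        tips: list[tuple[float, float]] = []  # (birth, death) per tip
        parents: list[int] = []
        lengths: list[float] = []
        labels: list[str] = []
        nodes: list[tuple[float, float]] = []

        flat_tips = []
        flat_internal = []

        def flatten(t):
            if t[0] == "tip":
                flat_tips.append(t)
                return ("tip", len(flat_tips) - 1)
            refs = [flatten(p) for p in t[3]]
            flat_internal.append((t[1], t[2], refs))
            return ("int", len(flat_internal) - 1)

        flatten(tree)
        n_tips = len(flat_tips)
        n_nodes = n_tips + len(flat_internal)
        parent_arr = np.full(n_nodes, -1, dtype=int)
        length_arr = np.zeros(n_nodes)
        for i, (_, top, node) in enumerate(flat_tips):
            length_arr[i] = node.death - top
            labels.append(f"sp{i + 1:04d}")
        for j, (top, death, refs) in enumerate(flat_internal):
            idx = n_tips + j
            length_arr[idx] = death - top
            for kind, r in refs:
                child = r if kind == "tip" else n_tips + r
                parent_arr[child] = idx
        return Chronogram(parent_arr, length_arr, labels,
                          check_ultrametric=False)
    finally:
        sys.setrecursionlimit(old)


def simulate_bd_tree(
    config: SimConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    return_full: bool = False,
    **overrides,
):
    """Reconstructed birth-death chronogram of fixed crown age.

    Whole-clade extinction (or < 2 sampled tips) triggers resimulation, up to
    1000 attempts; the attempt count is returned alongside when
    ``return_full`` is set.
    """
    if config is None:
        config = SimConfig(seed=seed if seed is not None else 0, **overrides)
    if rng is None:
        rng = stage_rng(config.seed, "tree")
    T = config.crown_age
    f = config.sampling_fraction
    for attempt in range(1, MAX_RESIM + 1):
        root, alive = _simulate_once(
            config.lambda0, config.alpha, config.mu0, config.beta, T, rng
        )
        if len(alive) < 2:
            continue
        if f < 1.0:
            sampled = {ln for ln in alive if rng.random() < f}
        else:
            sampled = set(alive)
        if len(sampled) < 2:
            continue
        tree = _to_chronogram(root, T, sampled)
        if tree is None or tree.n_tips < 2:
            continue
        if return_full:
            full = _to_chronogram(root, T, set(alive))
            return tree, {"attempts": attempt, "n_extant": len(alive),
                          "full_tree": full}
        return tree
    raise RuntimeError(
        f"no surviving clade in {MAX_RESIM} attempts "
        f"(lambda0={config.lambda0}, mu0={config.mu0}, T={T})"
    )


def simulate_yule_n_tips(n_tips: int, lam: float,
                         rng: np.random.Generator) -> Chronogram:
    """Pure-birth tree with exactly n tips: forward simulation stopped at the
    moment the (n+1)-th lineage would appear."""
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    # split times after the crown: lineage count k waits Exp(k * lam)
    waits = [rng.exponential(1.0 / (k * lam)) for k in range(2, n_tips + 1)]
    times = np.cumsum(waits)
    total = float(times[-1])  # stop when the (n+1)-th lineage would appear
    parent = np.full(2 * n_tips - 1, -1, dtype=int)
    lengths = np.zeros(2 * n_tips - 1)
    birth = {}  # internal node -> forward birth time
    crown = n_tips
    next_internal = crown + 1
    birth[crown] = 0.0
    open_stubs = [crown, crown]  # parent slots awaiting a child
    for t in times[:-1]:  # the splits that create lineages 3..n
        par = open_stubs.pop(rng.integers(len(open_stubs)))
        node = next_internal
        next_internal += 1
        birth[node] = float(t)
        parent[node] = par
        lengths[node] = float(t) - birth[par]
        open_stubs.extend([node, node])
    for tip, par in enumerate(open_stubs):
        parent[tip] = par
        lengths[tip] = total - birth[par]
    labels = [f"sp{i + 1:04d}" for i in range(n_tips)]
    return Chronogram(parent, lengths, labels, check_ultrametric=False)


# ---------------------------------------------------------------------------
# traits and ranges
# ---------------------------------------------------------------------------


def simulate_bm_trait(
    tree: Chronogram,
    sigma2: float,
    root_state: float,
    lam: float = 1.0,
    delta: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[str, float]:
    """Tip trait values drawn from the lambda/delta-scaled BM normal."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if rng is None:
        rng = stage_rng(seed if seed is not None else 0, "trait")
    if sigma2 == 0:
        return {t: float(root_state) for t in tree.tip_labels}
    C = transformed_covariance(tree.covariance(), lam, delta).matrix
    chol = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    y = root_state + np.sqrt(sigma2) * (chol @ rng.standard_normal(len(C)))
    return dict(zip(tree.tip_labels, map(float, y)))


def _anagenesis_rates(mask, space, d, e, mult):
    """(targets, rates) out of a range state under one epoch's multipliers."""
    occupied = [i for i in range(space.areas.n) if mask >> i & 1]
    targets, rates = [], []
    if len(occupied) < space.max_range_size:
        for j in range(space.areas.n):
            if mask >> j & 1:
                continue
            r = d * sum(mult[i, j] for i in occupied)
            if r > 0:
                targets.append(mask | (1 << j))
                rates.append(r)
    if e > 0:
        for i in occupied:
            targets.append(mask & ~(1 << i))
            rates.append(e)
    return targets, np.asarray(rates)


def simulate_dec_history(
    tree: Chronogram,
    params: DECParams,
    schedule: DispersalSchedule,
    areas: AreaSystem,
    max_range_size: int = 4,
    root_range: str | int | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    on_null: str = "record",
) -> dict:
    """Simulate ranges down the tree: Gillespie anagenesis within epochs,
    cladogenetic inheritance at nodes.

    Returns tip ranges (letters), true node ranges, and an event log. A
    lineage falling into the null range is recorded as extirpated (its whole
    subtree gets an empty range); ``on_null='resimulate'`` retries the whole
    history instead, up to 1000 attempts.
    """
    if on_null not in ("record", "resimulate"):
        raise ValueError("on_null must be 'record' or 'resimulate'")
    space = StateSpace(areas, max_range_size)
    if rng is None:
        rng = stage_rng(seed if seed is not None else 0, "ranges")
    ages = tree.node_ages()
    if root_range is None:
        root_mask_choices = space.observable
    else:
        root_mask = (root_range if isinstance(root_range, int)
                     else areas.mask_from_letters(str(root_range)))
        root_mask_choices = [root_mask]

    clado_cache = {m: _cladogenesis_pairs(space, m) for m in space.observable}

    for _ in range(MAX_RESIM):
        node_state = {}
        events = []
        root = tree.postorder[-1]
        node_state[root] = root_mask_choices[rng.integers(len(root_mask_choices))]
        any_null = False
        for node in reversed(tree.postorder):  # preorder: root outward
            state = node_state[node]
            kids = tree.children[node]
            if not kids:
                continue
            if state == 0:
                for c in kids:
                    node_state[c] = 0
                continue
            pairs = clado_cache[state]
            weights = np.array([w for _, _, w in pairs])
            pick = pairs[rng.choice(len(pairs), p=weights / weights.sum())]
            daughters = [pick[0], pick[1]]
            if len(kids) != 2:
                raise ValueError("range simulation requires a binary tree")
            for c, start in zip(kids, daughters):
                mask = start
                t = float(ages[node])  # backward time, decreasing to child age
                t_end = float(ages[c])
                while t > t_end + 1e-12 and mask != 0:
                    k = _slice_of(schedule, t)
                    floor = max(schedule.boundaries[k + 1], t_end)
                    targets, rates = _anagenesis_rates(
                        mask, space, params.d, params.e, schedule.multipliers[k]
                    )
                    total = float(rates.sum()) if len(rates) else 0.0
                    if total <= 0:
                        t = floor
                        continue
                    wait = rng.exponential(1.0 / total)
                    if t - wait <= floor:
                        t = floor  # no event before the epoch boundary / node
                        continue
                    t -= wait
                    mask = targets[rng.choice(len(targets), p=rates / total)]
                    events.append({
                        "branch_child": int(c),
                        "age": float(t),
                        "state": areas.letters_from_mask(mask),
                    })
                    if mask == 0:
                        any_null = True
                node_state[c] = mask
        if any_null and on_null == "resimulate":
            continue
        tip_ranges = {
            lab: areas.letters_from_mask(node_state[i])
            for i, lab in enumerate(tree.tip_labels)
        }
        return {
            "tip_ranges": tip_ranges,
            "node_ranges": {int(k): areas.letters_from_mask(v)
                            for k, v in node_state.items()},
            "events": events,
            "extirpated": [lab for lab, r in tip_ranges.items() if r == ""],
        }
    raise RuntimeError("range history hit the null range in every resimulation")


def _slice_of(schedule: DispersalSchedule, t: float) -> int:
    """Epoch index containing backward time t; ages beyond the oldest
    boundary use the oldest epoch."""
    b = schedule.boundaries
    for k in range(schedule.n_slices):
        if t > b[k + 1]:
            return k
    return schedule.n_slices - 1


def make_species_table(
    tree: Chronogram,
    traits: dict[str, dict[str, float]],
    ranges: dict[str, str],
    molecular: dict[str, bool] | None = None,
    morphology: dict[str, bool] | None = None,
    areas: AreaSystem = None,
) -> pd.DataFrame:
    """Assemble a species table (checklist schema) from simulated pieces.

    ``traits`` must provide 'mean', 'lower' and 'upper' maps; rows follow the
    tree's tip order. Ranges using letters outside the area system are
    refused.
    """
    from .biogeo import DEFAULT_AREAS

    areas = areas or DEFAULT_AREAS
    tips = list(tree.tip_labels)
    for key in ("mean", "lower", "upper"):
        if key not in traits:
            raise ValueError(f"traits must include {key!r}")
        if set(traits[key]) != set(tips):
            raise ValueError(f"trait {key!r} tip set mismatch")
    if set(ranges) != set(tips):
        raise ValueError("range tip set mismatch")
    rows = []
    for t in tips:
        rng_letters = ranges[t]
        areas.mask_from_letters(rng_letters)  # validates letters
        lo, mean, hi = traits["lower"][t], traits["mean"][t], traits["upper"][t]
        if not lo <= mean <= hi:
            raise ValueError(f"{t}: elevational ordering violated")
        rows.append({
            "species": t,
            "previous_name": "",
            "molecular": "x" if (molecular or {}).get(t, True) else "",
            "morphology": "x" if (morphology or {}).get(t, True) else "",
            "areas": rng_letters,
            "elev_mean": round(float(mean), 1),
            "elev_low": round(float(lo), 1),
            "elev_high": round(float(hi), 1),
        })
    return pd.DataFrame(rows)
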