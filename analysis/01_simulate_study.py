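#!/usr/bin/env python
"""Generate the synthetic study all later analyses consume.

Simulates a chronogram at the empirical study's scale (crown 10.6 my,
speciation decelerating toward the present: lambda0 = 0.161 /lineage/my,
alpha = 0.110 /my, no extinction), a delta-accelerated elevational trait
(delta = 2.5, sigma^2 = 4e4 m^2/my around a 1500 m root), and a nine-area
DEC range history (d = 0.05, e = 0.01 /my, Northern Andes root) under the
three-epoch dispersal schedule. Writes the tree, the species table, and the
true generating parameters under results/synthetic/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from pterodiv import biogeo, simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

TRUTH = {"lambda0": 0.161, "alpha": 0.110, "mu0": 0.0, "crown_age": 10.6,
         "delta": 2.5, "lambda_pagel": 1.0, "sigma2": 4.0e4, "root_elev": 1500.0,
         "d": 0.05, "e": 0.01, "root_range": "C", "seed": SEED}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([SEED, 1]))
    tree = None
    for _ in range(200):
        cand = simulate.simulate_bd_tree(
            seed=None, rng=rng, lambda0=TRUTH["lambda0"],
            alpha=TRUTH["alpha"], mu0=0.0, crown_age=TRUTH["crown_age"])
        if cand.n_tips >= 25:
            tree = cand
            break
    print(f"simulated chronogram: {tree.n_tips} tips, "
          f"crown {tree.crown_age:.2f} my")

    trait_rng = np.random.default_rng(np.random.SeedSequence([SEED, 2]))
    mean = simulate.simulate_bm_trait(
        tree, TRUTH["sigma2"], TRUTH["root_elev"], delta=TRUTH["delta"],
        rng=trait_rng)
    lower = {k: v - 400.0 for k, v in mean.items()}
    upper = {k: v + 400.0 for k, v in mean.items()}

    sched = biogeo.DispersalSchedule.default_three_class()
    range_rng = np.random.default_rng(np.random.SeedSequence([SEED, 3]))
    hist = simulate.simulate_dec_history(
        tree, biogeo.DECParams(TRUTH["d"], TRUTH["e"]), sched,
        biogeo.DEFAULT_AREAS, max_range_size=4,
        root_range=TRUTH["root_range"], rng=range_rng, on_null="resimulate")
    sizes = [len(r) for r in hist["tip_ranges"].values()]
    print(f"range sizes: mean {np.mean(sizes):.2f}, max {max(sizes)}; "
          f"{len(hist['events'])} anagenetic events simulated")

    (OUT / "tree.nwk").write_text(tree.to_newick() + "\n")
    table = simulate.make_species_table(
        tree, {"mean": mean, "lower": lower, "upper": upper},
        hist["tip_ranges"])
    table.to_csv(OUT / "species_table.csv", index=False)
    (OUT / "truth.json").write_text(json.dumps(TRUTH, indent=2) + "\n")
    print(f"wrote tree, species table and truth under {OUT}")


if __name__ == "__main__":
    main()
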