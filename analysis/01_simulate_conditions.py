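#!/usr/bin/env python
"""Simulate the paired benchmark conditions used throughout the analysis.

Renders one positive-condition (wild-type-like, 85% truly expelling) and one
negative-condition (knockout-like, apoptosis only) field of 150 cells each,
writes the movies plus ground truth under scratch/analysis/, and prints the
realized event counts.
"""

from pathlib import Path

from nucexpel.benchmark import derive_seed, ko_like_config, wt_like_config
from nucexpel.io import save_ground_truth, save_movie
from nucexpel.simulate import simulate_movie
import dataclasses

SEED = 1
OUT = Path("scratch/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for idx, (name, base) in enumerate(
        [("positive", wt_like_config()), ("negative", ko_like_config())]
    ):
        cfg = dataclasses.replace(base, calcium_enabled=True,
                                  seed=derive_seed(SEED, idx))
        movie, truth = simulate_movie(cfg)
        d = OUT / name
        d.mkdir(exist_ok=True)
        save_movie(movie, d / "movie.tif")
        save_ground_truth(truth, d)
        (d / "sim_config.json").write_text(cfg.to_json())
        n_exp = int(truth.cells["expelled"].sum())
        print(f"{name}: {truth.n_cells} cells, {n_exp} truly expelling "
              f"({100 * n_exp / truth.n_cells:.1f}%)")


if __name__ == "__main__":
    main()
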