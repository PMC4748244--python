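#!/usr/bin/env python
"""Automated gating of every simulated file, checked against truth labels.

Re-generates the experiment (same seed as 01), compensates, transforms,
pre-gates and applies each panel's built-in template — once at the default
KDE bandwidth ("automated") and once deliberately widened
("automated-perturbed", the stand-in comparator for a second analyst).
Writes the tidy population table and reports per-population F1 against the
per-event ground-truth labels.
"""

import argparse

import pandas as pd
from common import RESULTS, study_config

from cytostand.pipeline import gate_experiment, population_table
from cytostand.simulate import simulate_experiment, truth_masks


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = study_config(args.seed)
    exp = simulate_experiment(cfg)
    table = population_table(exp)  # automated + perturbed + truth rows
    RESULTS.mkdir(parents=True, exist_ok=True)
    table.to_csv(RESULTS / "population_table.csv", index=False)

    # F1 vs truth, per population (re-uses the automated gating pass)
    files = {(f.center, f.sample, f.replicate, f.panel): f for f in exp.files}
    rows = []
    for meta, tree in gate_experiment(exp):
        f = files[(meta["center"], meta["sample"], meta["replicate"], meta["panel"])]
        panel = exp.panels[f.panel]
        masks = truth_masks(panel, f.labels)
        for pop in panel.populations:
            g, t = tree.mask(pop.name), masks[pop.name]
            denom = 2 * (g & t).sum() + (g & ~t).sum() + (~g & t).sum()
            rows.append({
                "panel": f.panel, "population": pop.name, "center": f.center,
                "reliable": pop.reliable,
                "f1": 2 * (g & t).sum() / denom if denom else float("nan"),
            })
    f1 = pd.DataFrame(rows)
    f1.to_csv(RESULTS / "gating_f1.csv", index=False)

    summary = f1.groupby(["panel", "population", "reliable"])["f1"].agg(["mean", "min"])
    print(f"gated {len(files)} files x 2 gating passes "
          f"-> {RESULTS / 'population_table.csv'}")
    print("\nF1 vs ground truth (mean/min over files):")
    print(summary.round(4).to_string())
    rel = f1[f1["reliable"]]
    print(f"\nworst reliable-population F1: {rel['f1'].min():.4f} "
          f"(reliable populations are gated dependably; subsets flagged "
          f"unreliable, e.g. plasmablasts at ~30 events/file, are not)")


if __name__ == "__main__":
    main()
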