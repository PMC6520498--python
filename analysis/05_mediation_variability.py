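#!/usr/bin/env python
"""Auditory-mediation control and temporal-variability check.

Correlates the TUS-induced change in A1 (primary auditory cortex) coupling
with the change in the sonicated amygdala's coupling across the shared
fingerprint targets: a low correlation argues against an auditory artifact
mediating the target effects.  Also compares per-region BOLD temporal
variability between groups, which decoupling should leave untouched.
"""
import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from sonofc.connectivity import fingerprint_from_series
from sonofc.inference import (mediation_correlation,
                              temporal_variability_summary,
                              temporal_variability_test)
from sonofc.pipeline import condition_series
from sonofc.preprocess import clean_run, demean_and_concatenate
from sonofc.synth import ExperimentDesign, simulate_experiment

OUT = Path("results/analysis")


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = ExperimentDesign(volumes_per_run=200, delta=0.4)
    cohort, atlas, _ = simulate_experiment(design, rng_seed=seed)
    cleaned = [clean_run(r, c) for r, c in cohort]
    s_ctl = condition_series(cleaned, "control")
    s_tus = condition_series(cleaned, design.condition)

    target, a1 = design.target_node, "a1"
    common = [n for n in atlas.nodes_with_role("fingerprint_target")
              if n not in (a1, target)]

    def delta(seed_node: str) -> np.ndarray:
        fc = fingerprint_from_series(s_ctl, seed_node, atlas, targets=common)
        ft = fingerprint_from_series(s_tus, seed_node, atlas, targets=common)
        return ft.values - fc.values

    r, p = mediation_correlation(delta(a1), delta(target))
    print(f"A1 vs {target} coupling-change correlation over {len(common)} "
          f"targets: r = {r:.4f}, p = {p:.4f}")
    print("(with so few targets this correlation is a noisy descriptive "
          "statistic; A1's couplings are untouched by the simulated "
          "decoupling, so it carries no true mediation signal)")
    (OUT / "mediation.json").write_text(json.dumps(
        {"seed": seed, "r": r, "p_value": p, "n_targets": len(common)}, indent=1))

    ctl = [x for x in cleaned if x.condition == "control"]
    tus = [x for x in cleaned if x.condition != "control"]
    sums_ctl = [temporal_variability_summary(demean_and_concatenate([x]), atlas)
                for x in ctl]
    sums_tus = [temporal_variability_summary(demean_and_concatenate([x]), atlas)
                for x in tus]
    comp = temporal_variability_test(sums_ctl, sums_tus, rng_seed=seed)
    df = pd.DataFrame([{"node": n, **v} for n, v in comp.items()])
    df.to_csv(OUT / "temporal_variability.tsv", sep="\t", index=False,
              float_format="%.6g")
    n_sig = int((df["p_value"] < 0.05).sum())
    print(f"temporal variability: {n_sig}/{len(df)} regions differ at p<0.05 "
          "(decoupling preserves signal amplitude by construction; per-run "
          "summaries are strongly correlated across regions, so this count "
          "fluctuates as a block rather than binomially)")
    print(f"tables -> {OUT}/mediation.json, {OUT}/temporal_variability.tsv")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    main(ap.parse_args().seed)
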