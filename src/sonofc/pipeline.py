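"""End-to-end experiment driver: simulate (or load) a cohort, clean every
run, build per-run fingerprints, and run the inference battery, writing all
intermediates and a deterministic JSON report."""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import ExperimentConfig
from .connectivity import Fingerprint, fingerprint_from_series
from .core import ConfoundRecord, NodeAtlas, TimeSeriesRun
from .inference import (fingerprint_permutation_test, impact_heatmap,
                        mediation_correlation, temporal_variability_summary,
                        temporal_variability_test)
from .preprocess import clean_run, demean_and_concatenate
from .synth import simulate_experiment
from . import io as sio

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "clean_cohort", "per_run_fingerprints", "condition_series"]


def clean_cohort(
    cohort: list[tuple[TimeSeriesRun, ConfoundRecord]], cfg: ExperimentConfig
) -> list[TimeSeriesRun]:
    return [clean_run(run, conf, cfg.cleaning) for run, conf in cohort]


def per_run_fingerprints(
    runs: list[TimeSeriesRun], seed_node: str, atlas: NodeAtlas
) -> list[Fingerprint]:
    """Fingerprint of each cleaned run (demeaned per run before correlation)."""
    out = []
    for r in runs:
        series = demean_and_concatenate([r])
        out.append(fingerprint_from_series(series, seed_node, atlas,
                                           condition=r.condition,
                                           source=r.subject_id))
    return out


def condition_series(runs: list[TimeSeriesRun], condition: str) -> np.ndarray:
    """Concatenated (demeaned per run) series of all runs of one condition."""
    sel = [r for r in runs if r.condition == condition]
    if not sel:
        raise ValueError(f"no runs with condition {condition!r}")
    return demean_and_concatenate(sel)


def _split(runs: list[TimeSeriesRun]) -> tuple[list[TimeSeriesRun], list[TimeSeriesRun], str]:
    ctl = [r for r in runs if r.condition == "control"]
    tus = [r for r in runs if r.condition != "control"]
    if not ctl or not tus:
        raise ValueError("cohort must contain both control and TUS runs")
    return ctl, tus, tus[0].condition


def run_pipeline(cfg: ExperimentConfig, write_intermediates: bool = True) -> dict:
    """Execute simulate -> preprocess -> connectivity -> inference.

    Returns the report dict; writes the report, fingerprints, and the impact
    map under ``cfg.outdir``.  Identical config and seed give byte-identical
    reports.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.atlas_file:
        atlas = sio.read_atlas(cfg.atlas_file)
    else:
        atlas = None
    from .synth import default_network
    from .core import default_atlas

    atlas = atlas if atlas is not None else default_atlas(cfg.design.points_per_region)
    net = default_network(atlas, cfg.network.within_module_corr,
                          cfg.network.between_module_corr, cfg.network.ar_coef)
    cohort, atlas, net = simulate_experiment(
        cfg.design, rng_seed=cfg.seed, net=net, atlas=atlas,
        artifact_spec=cfg.artifacts)
    log.info("simulated %d runs", len(cohort))

    cleaned = clean_cohort(cohort, cfg)
    ctl, tus, tus_condition = _split(cleaned)

    target = cfg.design.target_node
    control_seed = cfg.inference.control_seed_node
    a1 = cfg.inference.auditory_node
    inf = cfg.inference

    report: dict = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "n_runs": {"control": len(ctl), "tus": len(tus)},
        "tus_condition": tus_condition,
        "permutation_tests": {},
    }

    fps_by_seed: dict[str, list[Fingerprint]] = {}
    for label, seed_node in (("target_seed", target), ("control_seed", control_seed)):
        fps_ctl = per_run_fingerprints(ctl, seed_node, atlas)
        fps_tus = per_run_fingerprints(tus, seed_node, atlas)
        fps_by_seed[seed_node] = fps_ctl + fps_tus
        res = fingerprint_permutation_test(
            fps_ctl, fps_tus, n_perm=inf.n_perm,
            exchange_unit=inf.exchange_unit, rng_seed=cfg.seed)
        report["permutation_tests"][label] = {
            "seed_node": seed_node,
            "observed_similarity": res.observed_similarity,
            "p_value": res.p_value,
            "n_perm": res.n_perm,
            "exhaustive": res.exhaustive,
            "exchange_unit": res.exchange_unit,
        }

    series_ctl = condition_series(cleaned, "control")
    series_tus = condition_series(cleaned, tus_condition)

    imap = impact_heatmap(series_ctl, series_tus, atlas)
    report["impact_map"] = {
        "region_set": imap.region_set,
        "argmax_point": int(np.argmax(imap.values)),
        "argmax_node": imap.argmax_node(atlas),
        "max_summed_delta_z": float(imap.values.max()),
        "mean_abs_summed_delta_z": float(np.abs(imap.values).mean()),
    }

    # auditory mediation: delta fingerprints over targets common to both seeds
    common = [n for n in atlas.nodes_with_role("fingerprint_target")
              if n not in (a1, target)]
    def mean_delta(seed_node: str) -> np.ndarray:
        fc = fingerprint_from_series(series_ctl, seed_node, atlas, targets=common)
        ft = fingerprint_from_series(series_tus, seed_node, atlas, targets=common)
        return ft.values - fc.values

    r, p = mediation_correlation(mean_delta(a1), mean_delta(target))
    report["mediation"] = {"auditory_node": a1, "target_node": target,
                          "n_targets": len(common), "r": r, "p_value": p}

    sums_ctl = [temporal_variability_summary(demean_and_concatenate([r_]), atlas) for r_ in ctl]
    sums_tus = [temporal_variability_summary(demean_and_concatenate([r_]), atlas) for r_ in tus]
    report["temporal_variability"] = temporal_variability_test(
        sums_ctl, sums_tus, rng_seed=cfg.seed)

    if write_intermediates:
        for seed_node, fps in fps_by_seed.items():
            sio.write_fingerprints(fps, outdir / f"fingerprints_{seed_node}.tsv")
        sio.write_impact_map(imap.values, imap.per_region, imap.region_set,
                             outdir / "impact_map.tsv")
        sio.write_atlas(atlas, outdir / "atlas.json")
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("report written to %s", outdir / "report.json")
    return report
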