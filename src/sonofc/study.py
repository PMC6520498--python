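"""Replication battery: the simulation studies that characterise the
pipeline's statistical behaviour (type-I calibration, power and specificity,
impact-map localisation, cleaning efficacy, filter contracts, determinism).

Each function runs the full simulate -> clean -> analyse chain at the study's
default cohort (9 control vs 4 TUS subjects, 3 runs per subject) and returns
plain numbers; run lengths are arguments so studies can be sized to the
machine at hand.
"""
from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .config import smoke_config
from .core import TimeSeriesRun, default_atlas
from .inference import fingerprint_permutation_test, impact_heatmap
from .pipeline import condition_series, per_run_fingerprints, run_pipeline
from .preprocess import (CleaningParams, build_nuisance_design, clean_run,
                         demean_and_concatenate, discard_initial_volumes,
                         despike_interpolate, dynamic_bandstop,
                         highpass_filter, lowpass_filter, regress_confounds)
from .synth import (ArtifactSpec, ExperimentDesign, default_network,
                    simulate_experiment, simulate_run)

__all__ = [
    "cohort_replicate", "rejection_rates", "localization_rate",
    "cleaning_comparison", "cleaning_improvement_rate", "filter_contracts",
    "pipeline_determinism",
]


def cohort_replicate(
    rng_seed: int,
    delta: float,
    volumes_per_run: int = 200,
    n_perm: int = 1000,
    seed_nodes: tuple[str, ...] = ("amygdala",),
    with_impact: bool = False,
) -> dict:
    """One full study replicate; returns permutation p per seed node and,
    optionally, the impact-map argmax node."""
    design = ExperimentDesign(volumes_per_run=volumes_per_run, delta=delta)
    cohort, atlas, _ = simulate_experiment(design, rng_seed=rng_seed)
    cleaned = [clean_run(r, c) for r, c in cohort]
    ctl = [r for r in cleaned if r.condition == "control"]
    tus = [r for r in cleaned if r.condition != "control"]
    out: dict = {"p": {}}
    for node in seed_nodes:
        fa = per_run_fingerprints(ctl, node, atlas)
        fb = per_run_fingerprints(tus, node, atlas)
        res = fingerprint_permutation_test(fa, fb, n_perm=n_perm, rng_seed=rng_seed)
        out["p"][node] = res.p_value
    if with_impact:
        imap = impact_heatmap(condition_series(cleaned, "control"),
                              condition_series(cleaned, design.condition), atlas)
        out["argmax_node"] = imap.argmax_node(atlas)
    return out


def rejection_rates(
    n_replicates: int,
    delta: float,
    rng_seed: int,
    alpha: float = 0.05,
    volumes_per_run: int = 200,
    n_perm: int = 1000,
    seed_nodes: tuple[str, ...] = ("amygdala",),
) -> dict[str, float]:
    """Fraction of replicates with p < alpha, per seed node."""
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_replicates) % (2**31)
    counts = {node: 0 for node in seed_nodes}
    for s in seeds:
        rep = cohort_replicate(int(s), delta, volumes_per_run, n_perm, seed_nodes)
        for node in seed_nodes:
            counts[node] += rep["p"][node] < alpha
    return {node: counts[node] / n_replicates for node in seed_nodes}


def localization_rate(
    n_replicates: int,
    delta: float,
    rng_seed: int,
    volumes_per_run: int = 200,
    target_node: str = "amygdala",
) -> float:
    """Fraction of replicates whose impact-map argmax lies in the decoupled
    node's points."""
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_replicates) % (2**31)
    hits = 0
    for s in seeds:
        rep = cohort_replicate(int(s), delta, volumes_per_run, n_perm=10,
                               seed_nodes=(), with_impact=True)
        hits += rep["argmax_node"] == target_node
    return hits / n_replicates


# -- cleaning efficacy ---------------------------------------------------

def cleaning_comparison(rng_seed: int, n_volumes: int = 800) -> dict[str, float]:
    """Simulate one artifact-laden run; compare the node-correlation error of
    the raw vs the cleaned data against the generative ground truth, and
    measure residual-design orthogonality right after nuisance regression.
    """
    atlas = default_atlas()
    net = default_network(atlas)
    spec = ArtifactSpec(drift_slope=1e-3, cyclic=((0.3, 1.0),),
                        spikes=((60, 10.0), (150, 10.0)), confound_weight=1.0)
    run, conf = simulate_run(net, atlas, n_volumes=n_volumes,
                             artifact_spec=spec, rng_seed=rng_seed)

    node_idx = atlas.node_of_point()
    def node_corr(data: np.ndarray) -> np.ndarray:
        series = np.column_stack([data[:, node_idx == k].mean(axis=1)
                                  for k in range(atlas.n_nodes)])
        return np.corrcoef(series, rowvar=False)

    truth = net.sigma  # unit variances: covariance equals correlation
    err_raw = float(np.abs(node_corr(run.data) - truth).max())

    # run the chain step-by-step so orthogonality is checked where it holds
    p = CleaningParams()
    r = discard_initial_volumes(run, p.n_discard)
    c = conf.trimmed(p.n_discard)
    r, _ = despike_interpolate(r, p.spike_z)
    r = highpass_filter(r, p.highpass_seconds)
    r, _ = dynamic_bandstop(r, p.bandstop_band, p.bandstop_k_mad, p.notch_halfwidth_hz)
    design = build_nuisance_design(c)
    r = regress_confounds(r, design)
    cols = design.columns / np.linalg.norm(design.columns, axis=0, keepdims=True)
    ortho = float(np.abs(cols.T @ r.data).max() / max(1.0, np.abs(r.data).max()))
    r = lowpass_filter(r, p.lowpass_seconds)
    cleaned = r.data - r.data.mean(axis=0, keepdims=True)
    err_clean = float(np.abs(node_corr(cleaned) - truth).max())
    return {"err_raw": err_raw, "err_clean": err_clean, "orthogonality": ortho}


def cleaning_improvement_rate(n_replicates: int, rng_seed: int,
                              n_volumes: int = 800) -> dict[str, float]:
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_replicates) % (2**31)
    wins = 0
    worst_ortho = 0.0
    for s in seeds:
        rep = cleaning_comparison(int(s), n_volumes)
        wins += rep["err_clean"] < rep["err_raw"]
        worst_ortho = max(worst_ortho, rep["orthogonality"])
    return {"improvement_rate": wins / n_replicates, "max_orthogonality": worst_ortho}


# -- filter contracts ----------------------------------------------------

def _amplitude(x: np.ndarray) -> float:
    return float(np.sqrt(2.0) * np.std(x))


def filter_contracts(rng_seed: int = 0, n_volumes: int = 795,
                     tr: float = 2.0, n_white_trials: int = 100) -> dict[str, float]:
    """Measured filter behaviour on synthesised probes.

    Returns trend-removal and passband-preservation percentages for the
    high-pass, stopband attenuation for the low-pass, the band-stop notch
    depth (dB) on an injected cyclic peak, and the number of white-noise
    trials (out of ``n_white_trials``) on which the dynamic band-stop
    spuriously triggered.
    """
    rng = np.random.default_rng(rng_seed)
    t = np.arange(n_volumes) * tr
    mk = lambda x: TimeSeriesRun(x[:, None], tr)

    trend = 0.01 * t
    resid = highpass_filter(mk(trend - trend.mean())).data[:, 0]
    hp_trend_removal = 100.0 * (1.0 - _amplitude(resid) / _amplitude(trend))

    slow = np.sin(2 * np.pi * 0.05 * t)
    hp_keep = 100.0 * _amplitude(highpass_filter(mk(slow)).data[:, 0]) / _amplitude(slow)

    # cosine phase so the probe is representable at the Nyquist frequency
    fast = np.cos(2 * np.pi * 0.25 * t)
    lp_atten = 100.0 * (1.0 - _amplitude(lowpass_filter(mk(fast)).data[:, 0]) / _amplitude(fast))
    slow2 = np.sin(2 * np.pi * 0.02 * t)
    lp_keep = 100.0 * _amplitude(lowpass_filter(mk(slow2)).data[:, 0]) / _amplitude(slow2)

    # band-stop notch depth at an injected cyclic peak, 20 points
    noise = rng.standard_normal((n_volumes, 20))
    peak = 5.0 * np.sin(2 * np.pi * 0.2 * t)
    run = TimeSeriesRun(noise + peak[:, None], tr)
    filtered, notched = dynamic_bandstop(run)
    freqs, p_before = sps.periodogram(run.data.mean(axis=1), fs=1.0 / tr)
    _, p_after = sps.periodogram(filtered.data.mean(axis=1), fs=1.0 / tr)
    i = int(np.argmax(p_before))  # the injected peak's bin
    notch_db = float(10.0 * np.log10(p_before[i] / max(p_after[i], 1e-300)))

    white_triggers = 0
    for _ in range(n_white_trials):
        w = TimeSeriesRun(rng.standard_normal((n_volumes, 20)), tr)
        _, applied = dynamic_bandstop(w)
        white_triggers += bool(applied)

    return {
        "highpass_trend_removal_pct": hp_trend_removal,
        "highpass_passband_pct": hp_keep,
        "lowpass_stopband_attenuation_pct": lp_atten,
        "lowpass_passband_pct": lp_keep,
        "bandstop_notch_db": notch_db,
        "bandstop_n_detected": len(notched),
        "bandstop_white_noise_triggers": white_triggers,
    }


def pipeline_determinism(rng_seed: int, outdir: str | Path) -> bool:
    """Run the smoke pipeline twice; True iff the JSON reports are
    byte-identical."""
    outdir = Path(outdir)
    cfg = smoke_config(outdir=str(outdir)).with_seed(rng_seed)
    texts = []
    for _ in range(2):
        run_pipeline(cfg)
        texts.append((outdir / "report.json").read_bytes())
    return texts[0] == texts[1]
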