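"""Synthetic BOLD cohorts with a known inter-regional covariance.

Node signals follow a stationary lag-1 autoregressive Gaussian process whose
stationary covariance equals a prescribed network covariance ``sigma``; each
atlas point observes its node's signal plus independent Gaussian noise plus
injected artifacts (slow drift, cyclic respirator-like components, spike
volumes, weighted nuisance traces).  A "sonication" intervention is modelled
as decoupling: the target node retains only a fraction ``delta`` of its
shared-signal variance, scaling its cross-covariances by sqrt(delta) while
leaving its own variance unchanged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .core import ConfoundRecord, NodeAtlas, TimeSeriesRun, default_atlas

log = logging.getLogger(__name__)

__all__ = [
    "GroundTruthNetwork",
    "ArtifactSpec",
    "ExperimentDesign",
    "build_network",
    "apply_decoupling",
    "simulate_run",
    "simulate_experiment",
    "default_network",
]


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Ground-truth generative model for node time series.

    ``sigma`` is the stationary covariance of the node signals; ``ar_coef``
    the per-node lag-1 autoregressive coefficient; ``decoupling`` records the
    retained shared-variance fraction delta applied to ``target_node`` (1.0
    means untouched).
    """

    n_nodes: int
    sigma: np.ndarray
    ar_coef: np.ndarray
    node_names: tuple[str, ...]
    target_node: str | None = None
    decoupling: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        ar = np.broadcast_to(np.asarray(self.ar_coef, dtype=float), (self.n_nodes,)).copy()
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "ar_coef", ar)
        if sigma.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("sigma shape does not match n_nodes")
        if not np.allclose(sigma, sigma.T, atol=1e-12):
            raise ValueError("sigma must be symmetric")
        w = np.linalg.eigvalsh(sigma)
        if w[0] <= 0:
            raise ValueError(f"sigma is not positive definite (min eigenvalue {w[0]:.3e})")
        if np.any(np.abs(ar) >= 1):
            raise ValueError("autoregressive coefficients must satisfy |phi| < 1")
        if len(self.node_names) != self.n_nodes:
            raise ValueError("node_names length must equal n_nodes")
        if not 0.0 <= self.decoupling <= 1.0:
            raise ValueError("decoupling delta must lie in [0, 1]")

    def node_index(self, node: str) -> int:
        try:
            return self.node_names.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None


@dataclass(frozen=True)
class ArtifactSpec:
    """Artifacts injected into every point's series.

    drift_slope
        Linear drift in signal units per second, common to all points.
    cyclic
        Sequence of (frequency_hz, amplitude) sinusoids, sampled at scan
        times; frequencies above Nyquist appear at their alias.
    spikes
        Sequence of (volume_index, amplitude) global spike volumes.
    confound_weight
        Scale of the injected linear combination of the recorded B0/WM/CSF
        traces (0 disables).
    """

    drift_slope: float = 0.0
    cyclic: tuple[tuple[float, float], ...] = ()
    spikes: tuple[tuple[int, float], ...] = ()
    confound_weight: float = 0.0

    @staticmethod
    def none() -> "ArtifactSpec":
        return ArtifactSpec()

    @staticmethod
    def default() -> "ArtifactSpec":
        # Respirator-like 0.3 Hz component (aliases to 0.2 Hz at TR = 2 s),
        # slow scanner drift, and unit-weight nuisance leakage.
        return ArtifactSpec(
            drift_slope=1e-3,
            cyclic=((0.3, 1.0),),
            spikes=((20, 8.0),),
            confound_weight=1.0,
        )


def build_network(
    n_nodes: int,
    within_module_corr: float,
    between_module_corr: float,
    modules: Sequence[Sequence[int]],
    rng_seed: int = 0,
    node_names: Sequence[str] | None = None,
    ar_coef: float | Sequence[float] = 0.4,
) -> GroundTruthNetwork:
    """Block-structured unit-variance covariance over ``n_nodes`` nodes.

    ``modules`` partitions node indices; correlations are
    ``within_module_corr`` inside a block and ``between_module_corr`` across
    blocks.  Raises if the implied matrix is not positive definite.
    """
    for c in (within_module_corr, between_module_corr):
        if not 0.0 <= c < 1.0:
            raise ValueError("correlations must lie in [0, 1)")
    flat = sorted(i for m in modules for i in m)
    if flat != list(range(n_nodes)):
        raise ValueError("modules must partition the node indices exactly")
    labels = np.empty(n_nodes, dtype=int)
    for k, m in enumerate(modules):
        labels[list(m)] = k
    same = labels[:, None] == labels[None, :]
    sigma = np.where(same, within_module_corr, between_module_corr)
    np.fill_diagonal(sigma, 1.0)
    w = np.linalg.eigvalsh(sigma)
    if w[0] <= 0:
        raise ValueError(
            f"requested block structure is not positive definite "
            f"(min eigenvalue {w[0]:.6e})"
        )
    names = tuple(node_names) if node_names is not None else tuple(
        f"node{i}" for i in range(n_nodes)
    )
    return GroundTruthNetwork(
        n_nodes=n_nodes,
        sigma=sigma,
        ar_coef=np.asarray(ar_coef, dtype=float),
        node_names=names,
        rng_seed=rng_seed,
    )


def default_network(
    atlas: NodeAtlas | None = None,
    within_module_corr: float = 0.6,
    between_module_corr: float = 0.15,
    ar_coef: float = 0.4,
    rng_seed: int = 0,
) -> GroundTruthNetwork:
    """Default 14-node network over the default atlas's functional modules."""
    from .core import DEFAULT_MODULES

    atlas = atlas if atlas is not None else default_atlas()
    idx = {n: i for i, n in enumerate(atlas.nodes)}
    modules = [[idx[n] for n in members if n in idx] for members in DEFAULT_MODULES.values()]
    covered = sorted(i for m in modules for i in m)
    if covered != list(range(atlas.n_nodes)):
        # custom atlas: unlisted nodes form one extra module
        rest = [i for i in range(atlas.n_nodes) if i not in covered]
        if rest:
            modules.append(rest)
    return build_network(
        atlas.n_nodes,
        within_module_corr,
        between_module_corr,
        modules,
        rng_seed=rng_seed,
        node_names=tuple(atlas.nodes),
        ar_coef=ar_coef,
    )


def apply_decoupling(net: GroundTruthNetwork, node: str, delta: float) -> GroundTruthNetwork:
    """Retain fraction ``delta`` of ``node``'s shared-signal variance.

    Mixture construction: the node's signal becomes sqrt(delta) * shared +
    sqrt(1 - delta) * independent, so its cross-covariances scale by
    sqrt(delta), its variance is unchanged, and the result is positive
    definite for every delta in [0, 1].
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    k = net.node_index(node)
    sigma = net.sigma.copy()
    scale = np.sqrt(delta)
    row = sigma[k, :] * scale
    row[k] = net.sigma[k, k]
    sigma[k, :] = row
    sigma[:, k] = row
    return replace(net, sigma=sigma, target_node=node, decoupling=delta)


def _ar1_node_signals(net: GroundTruthNetwork, n_volumes: int, rng: np.random.Generator) -> np.ndarray:
    """Draw stationary AR(1) node signals with stationary covariance sigma."""
    phi = net.ar_coef
    # Innovation covariance solving sigma = Phi sigma Phi + Q for diagonal Phi.
    q = net.sigma * (1.0 - np.outer(phi, phi))
    wq = np.linalg.eigvalsh(q)
    if wq[0] < -1e-10 * max(1.0, wq[-1]):
        raise ValueError(
            "innovation covariance implied by sigma and ar_coef is not PSD "
            f"(min eigenvalue {wq[0]:.3e}); use less heterogeneous ar_coef"
        )
    # Eigen factorisation tolerates the numerically semi-definite case.
    w, v = np.linalg.eigh(q)
    lq = v * np.sqrt(np.clip(w, 0.0, None))
    ls = np.linalg.cholesky(net.sigma)
    innov = rng.standard_normal((n_volumes, net.n_nodes)) @ lq.T
    x0 = ls @ rng.standard_normal(net.n_nodes)
    out = np.empty((n_volumes, net.n_nodes))
    # per-node recursion x_t = phi x_{t-1} + e_t run as an IIR filter
    for j in range(net.n_nodes):
        zi = np.array([phi[j] * x0[j]])
        out[:, j], _ = sps.lfilter([1.0], [1.0, -phi[j]], innov[:, j], zi=zi)
    return out


def _make_confounds(n_volumes: int, tr: float, rng: np.random.Generator,
                    n_wm: int = 5, n_csf: int = 5) -> ConfoundRecord:
    """Generate B0 parameter traces and WM/CSF compartment signals.

    B0 traces are smoothed random walks (slow field drift); each compartment
    is a few shared smooth latents plus white noise, so its mean and leading
    principal components carry the structured part.
    """
    def smooth(x: np.ndarray, width: int) -> np.ndarray:
        kern = np.hanning(width)
        kern /= kern.sum()
        pad = np.pad(x, ((width, width), (0, 0)), mode="edge")
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            out[:, j] = np.convolve(pad[:, j], kern, mode="same")[width:-width]
        return out

    walk = np.cumsum(rng.standard_normal((n_volumes, 6)), axis=0) / np.sqrt(n_volumes)
    b0 = smooth(walk, max(4, int(20 / tr)))
    latents = smooth(rng.standard_normal((n_volumes, 3)), max(4, int(10 / tr)))
    mix_wm = rng.standard_normal((3, n_wm))
    mix_csf = rng.standard_normal((3, n_csf))
    wm = latents @ mix_wm + 0.3 * rng.standard_normal((n_volumes, n_wm))
    csf = latents @ mix_csf + 0.3 * rng.standard_normal((n_volumes, n_csf))
    return ConfoundRecord(b0, wm, csf)


def simulate_run(
    net: GroundTruthNetwork,
    atlas: NodeAtlas,
    n_volumes: int = 800,
    tr_seconds: float = 2.0,
    point_noise_sd: float = 1.0,
    artifact_spec: ArtifactSpec | None = None,
    rng_seed: int = 0,
    subject_id: str = "",
    run_index: int = 0,
    condition: str = "control",
) -> tuple[TimeSeriesRun, ConfoundRecord]:
    """Simulate one run: node AR(1) signals observed at atlas points plus
    noise and artifacts, together with the confound record as injected."""
    if n_volumes < 10:
        raise ValueError("n_volumes must be at least 10")
    if sorted(atlas.nodes) != sorted(net.node_names):
        raise ValueError("atlas nodes do not match network node names")
    spec = artifact_spec if artifact_spec is not None else ArtifactSpec.none()
    rng = np.random.default_rng(rng_seed)

    nodes = _ar1_node_signals(net, n_volumes, rng)
    node_col = np.array([net.node_index(n) for n in np.array(atlas.nodes)[atlas.node_of_point()]])
    data = nodes[:, node_col].copy()
    if point_noise_sd > 0:
        data += point_noise_sd * rng.standard_normal(data.shape)

    t = np.arange(n_volumes) * tr_seconds
    if spec.drift_slope:
        data += (spec.drift_slope * t)[:, None]
    for freq, amp in spec.cyclic:
        phase = rng.uniform(0, 2 * np.pi)
        data += (amp * np.sin(2 * np.pi * freq * t + phase))[:, None]
    for vol, amp in spec.spikes:
        if not 0 <= int(vol) < n_volumes:
            raise ValueError(f"spike volume {vol} outside run")
        data[int(vol), :] += amp

    confounds = _make_confounds(n_volumes, tr_seconds, rng)
    if spec.confound_weight:
        coef = rng.standard_normal(6)
        shared = (
            confounds.b0_params @ coef
            + confounds.wm_signals.mean(axis=1)
            + confounds.csf_signals.mean(axis=1)
        )
        loading = 1.0 + 0.3 * rng.standard_normal(data.shape[1])
        data += spec.confound_weight * np.outer(shared, loading)

    run = TimeSeriesRun(data, tr_seconds, subject_id=subject_id,
                        run_index=run_index, condition=condition)
    return run, confounds


@dataclass(frozen=True)
class ExperimentDesign:
    """Cohort layout: control vs TUS groups, runs and volumes per subject."""

    n_control: int = 9
    n_tus: int = 4
    runs_per_subject: int = 3
    volumes_per_run: int = 800
    tr_seconds: float = 2.0
    condition: str = "amygdala_tus"
    delta: float = 1.0
    target_node: str = "amygdala"
    point_noise_sd: float = 1.0
    points_per_region: int = 5

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_tus, self.runs_per_subject) < 1:
            raise ValueError("subject and run counts must be >= 1")
        if self.condition not in ("amygdala_tus", "acc_tus"):
            raise ValueError("TUS condition must be amygdala_tus or acc_tus")


def simulate_experiment(
    design: ExperimentDesign,
    rng_seed: int = 0,
    net: GroundTruthNetwork | None = None,
    atlas: NodeAtlas | None = None,
    artifact_spec: ArtifactSpec | None = None,
) -> tuple[list[tuple[TimeSeriesRun, ConfoundRecord]], NodeAtlas, GroundTruthNetwork]:
    """Simulate a full two-group cohort.

    Control subjects draw from ``net`` unchanged; TUS subjects draw from the
    decoupled network (delta applied at ``design.target_node``).  Seeding is
    deterministic: every run's seed derives from ``rng_seed`` via a spawned
    SeedSequence, so identical seeds give identical cohorts.
    """
    atlas = atlas if atlas is not None else default_atlas(design.points_per_region)
    net = net if net is not None else default_network(atlas)
    spec = artifact_spec if artifact_spec is not None else ArtifactSpec.default()
    tus_net = apply_decoupling(net, design.target_node, design.delta)

    n_runs = (design.n_control + design.n_tus) * design.runs_per_subject
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_runs) % (2**31)
    cohort: list[tuple[TimeSeriesRun, ConfoundRecord]] = []
    k = 0
    for grp, n_subj, g_net, cond in (
        ("ctl", design.n_control, net, "control"),
        ("tus", design.n_tus, tus_net, design.condition),
    ):
        for s in range(n_subj):
            for r in range(design.runs_per_subject):
                run, conf = simulate_run(
                    g_net, atlas,
                    n_volumes=design.volumes_per_run,
                    tr_seconds=design.tr_seconds,
                    point_noise_sd=design.point_noise_sd,
                    artifact_spec=spec,
                    rng_seed=int(seeds[k]),
                    subject_id=f"{grp}{s:02d}",
                    run_index=r,
                    condition=cond,
                )
                cohort.append((run, conf))
                k += 1
    return cohort, atlas, net
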