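"""Statistical machinery: cosine-similarity permutation tests on connectivity
fingerprints, whole-brain impact heat-maps, auditory-mediation correlation,
and a temporal-variability control.

The permutation test compares the cosine similarity of two condition-mean
fingerprints against a null built by re-assigning run (or subject) labels,
one-tailed toward dissimilarity: the p-value is the proportion of null draws
at least as dissimilar as observed.  When the balanced-relabeling space is
small enough the null is enumerated exhaustively.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .connectivity import Fingerprint, fisher_z
from .core import NodeAtlas

log = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "ImpactMap",
    "cosine_similarity",
    "fingerprint_permutation_test",
    "impact_heatmap",
    "mediation_correlation",
    "temporal_variability_summary",
    "temporal_variability_test",
]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (|a| |b|); shape-sensitive, amplitude-invariant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclass
class PermutationResult:
    observed_similarity: float
    null_similarities: np.ndarray
    p_value: float
    n_perm: int
    exchange_unit: str
    rng_seed: int
    exhaustive: bool = False


def _cosine_rows(means_a: np.ndarray, means_b: np.ndarray) -> np.ndarray:
    num = np.einsum("ij,ij->i", means_a, means_b)
    den = np.linalg.norm(means_a, axis=1) * np.linalg.norm(means_b, axis=1)
    return num / den


def fingerprint_permutation_test(
    runs_a: Sequence[Fingerprint],
    runs_b: Sequence[Fingerprint],
    n_perm: int = 10_000,
    exchange_unit: str = "run",
    rng_seed: int = 0,
    method: str = "auto",
    plus_one: bool = False,
    tail: str = "dissimilar",
) -> PermutationResult:
    """Permutation test on the cosine similarity of condition-mean fingerprints.

    The observed statistic is the cosine similarity between the mean
    fingerprint of condition A runs and that of condition B runs.  The null
    re-assigns labels at the ``exchange_unit`` level ("run" or "subject",
    the latter keeping each subject's runs together), preserving group
    sizes.  With ``method="auto"`` the label space is enumerated exhaustively
    when it has at most ``n_perm`` distinct balanced relabelings; "exact" and
    "monte_carlo" force either route.  ``plus_one`` switches to the
    (b+1)/(n+1) p-value convention; default is the plain proportion.
    """
    if len(runs_a) < 2 or len(runs_b) < 2:
        raise ValueError("need at least two runs per condition")
    targets = runs_a[0].targets
    for fp in list(runs_a) + list(runs_b):
        if fp.targets != targets:
            raise ValueError("inconsistent fingerprint target ordering")
    if exchange_unit not in ("run", "subject"):
        raise ValueError("exchange_unit must be 'run' or 'subject'")
    if tail not in ("dissimilar", "two_sided"):
        raise ValueError("tail must be 'dissimilar' or 'two_sided'")

    fa = np.vstack([fp.values for fp in runs_a])
    fb = np.vstack([fp.values for fp in runs_b])
    pooled = np.vstack([fa, fb])
    observed = cosine_similarity(fa.mean(axis=0), fb.mean(axis=0))

    if np.allclose(pooled, pooled[0], atol=1e-12):
        warnings.warn("all fingerprints identical; permutation test degenerate")
        return PermutationResult(1.0, np.ones(1), 1.0, 1, exchange_unit, rng_seed, True)

    if exchange_unit == "subject":
        subj = [fp.source for fp in list(runs_a) + list(runs_b)]
        units: list[str] = []
        for s in subj:
            if s not in units:
                units.append(s)
        unit_rows = [np.flatnonzero([s == u for s in subj]) for u in units]
        n_units_a = len({fp.source for fp in runs_a})
    else:
        units = list(range(pooled.shape[0]))  # type: ignore[assignment]
        unit_rows = [np.array([i]) for i in range(pooled.shape[0])]
        n_units_a = fa.shape[0]

    n_units = len(units)
    space = math.comb(n_units, n_units_a)
    exhaustive = method == "exact" or (method == "auto" and space <= n_perm)
    rng = np.random.default_rng(rng_seed)

    def stat_for(a_units: np.ndarray) -> float:
        mask = np.zeros(n_units, dtype=bool)
        mask[a_units] = True
        rows_a = np.concatenate([unit_rows[i] for i in np.flatnonzero(mask)])
        rows_b = np.concatenate([unit_rows[i] for i in np.flatnonzero(~mask)])
        return cosine_similarity(pooled[rows_a].mean(axis=0), pooled[rows_b].mean(axis=0))

    if exhaustive:
        null = np.array([stat_for(np.array(c)) for c in combinations(range(n_units), n_units_a)])
        log.info("permutation test: exhaustive enumeration of %d relabelings", null.size)
    elif exchange_unit == "run":
        # vectorised Monte-Carlo over run relabelings
        order = np.argsort(rng.random((n_perm, n_units)), axis=1)
        mask = np.zeros((n_perm, n_units))
        np.put_along_axis(mask, order[:, :n_units_a], 1.0, axis=1)
        means_a = (mask @ pooled) / n_units_a
        means_b = ((1.0 - mask) @ pooled) / (n_units - n_units_a)
        null = _cosine_rows(means_a, means_b)
    else:
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = stat_for(rng.choice(n_units, size=n_units_a, replace=False))

    eps = 1e-12
    if tail == "dissimilar":
        b = int(np.sum(null <= observed + eps))
    else:
        centre = np.median(null)
        b = int(np.sum(np.abs(null - centre) >= np.abs(observed - centre) - eps))
    n = null.size
    p = (b + 1) / (n + 1) if plus_one else b / n
    return PermutationResult(observed, null, float(p), n, exchange_unit, rng_seed, exhaustive)


@dataclass
class ImpactMap:
    values: np.ndarray          # per point, summed delta Fisher z (control - TUS)
    per_region: np.ndarray      # points x regions, unsummed deltas
    region_set: list[str]
    conditions: tuple[str, str]

    def argmax_node(self, atlas: NodeAtlas) -> str:
        return atlas.nodes[atlas.node_of_point()[int(np.argmax(self.values))]]


def _point_region_coupling(series: np.ndarray, atlas: NodeAtlas,
                           region_set: Sequence[str]) -> np.ndarray:
    """points x regions matrix of mean Fisher-z coupling, hemisphere-averaged."""
    from .connectivity import _standardise

    x = _standardise(np.asarray(series, dtype=float))
    t = x.shape[0]
    out = np.empty((x.shape[1], len(region_set)))
    for j, node in enumerate(region_set):
        hemi_means = []
        for reg in atlas.regions_of(node):
            r = (x[:, list(reg.points)].T @ x) / t
            hemi_means.append(np.asarray(fisher_z(r)).mean(axis=0))
        out[:, j] = np.mean(hemi_means, axis=0)
    return out


def impact_heatmap(
    series_control: np.ndarray,
    series_tus: np.ndarray,
    atlas: NodeAtlas,
    region_set: Sequence[str] | None = None,
) -> ImpactMap:
    """Whole-brain TUS impact map: per point, the summed change (control
    minus TUS) in Fisher-z coupling with the a-priori region set.

    ``region_set`` defaults to the atlas nodes flagged ``apriori_heatmap``
    and must exclude the sonicated targets.  Positive values mean a net
    coupling reduction after TUS.
    """
    if region_set is None:
        region_set = atlas.nodes_with_role("apriori_heatmap")
    region_set = list(region_set)
    sonicated = set(atlas.nodes_with_role("sonication_target"))
    bad = sonicated.intersection(region_set)
    if bad:
        raise ValueError(f"region_set must exclude sonicated target(s): {sorted(bad)}")
    zc = _point_region_coupling(series_control, atlas, region_set)
    zt = _point_region_coupling(series_tus, atlas, region_set)
    delta = zc - zt
    return ImpactMap(delta.sum(axis=1), delta, region_set, ("control", "tus"))


def mediation_correlation(
    delta_fp_a1: np.ndarray,
    delta_fp_target: np.ndarray,
    method: str = "parametric",
    n_perm: int = 10_000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Pearson correlation across fingerprint targets between the TUS-induced
    coupling change of the auditory control seed (A1) and of the sonicated
    seed, with a two-sided p-value (parametric default; permutation option).
    """
    a = np.asarray(delta_fp_a1, dtype=float)
    b = np.asarray(delta_fp_target, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("delta fingerprints must be equal-length vectors, length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance delta fingerprint")
    if method == "parametric":
        r, p = stats.pearsonr(a, b)
        return float(r), float(p)
    if method == "permutation":
        res = stats.pearsonr(a, b, method=stats.PermutationMethod(
            n_resamples=n_perm, rng=np.random.default_rng(rng_seed)))
        return float(res.statistic), float(res.pvalue)
    raise ValueError("method must be 'parametric' or 'permutation'")


def temporal_variability_summary(series: np.ndarray, atlas: NodeAtlas) -> dict[str, float]:
    """Per region (node), the mean over points of the per-point temporal SD."""
    series = np.asarray(series, dtype=float)
    if series.shape[1] != atlas.n_points:
        raise ValueError("series point count does not match atlas")
    sd = series.std(axis=0)
    return {node: float(sd[atlas.points_of(node)].mean()) for node in atlas.nodes}


def temporal_variability_test(
    summaries_a: Sequence[dict[str, float]],
    summaries_b: Sequence[dict[str, float]],
    n_perm: int = 2000,
    rng_seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Descriptive group comparison of per-run variability summaries with a
    two-sided permutation p per region (difference of group means)."""
    if not summaries_a or not summaries_b:
        raise ValueError("need summaries for both groups")
    nodes = list(summaries_a[0])
    rng = np.random.default_rng(rng_seed)
    out: dict[str, dict[str, float]] = {}
    na = len(summaries_a)
    for node in nodes:
        va = np.array([s[node] for s in summaries_a])
        vb = np.array([s[node] for s in summaries_b])
        obs = va.mean() - vb.mean()
        pooled = np.concatenate([va, vb])
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            null[i] = perm[:na].mean() - perm[na:].mean()
        p = float(np.mean(np.abs(null) >= abs(obs) - 1e-15))
        out[node] = {"mean_a": float(va.mean()), "mean_b": float(vb.mean()),
                     "difference": float(obs), "p_value": p}
    return out
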