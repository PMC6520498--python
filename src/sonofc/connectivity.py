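"""Seed-based Fisher-z coupling maps and bilateral connectivity fingerprints.

A seed-coupling map holds, for every point in the data, the mean Fisher-z
correlation with the seed region's points (both hemispheres pooled at the
node level).  A fingerprint condenses a map to one hemisphere-averaged value
per target region.  Perfect and self correlations are clipped at
``|r| = R_CLIP`` before the arctanh transform so maps stay finite.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import NodeAtlas

log = logging.getLogger(__name__)

R_CLIP = 0.999999

__all__ = ["R_CLIP", "SeedMap", "Fingerprint", "fisher_z", "seed_coupling_map",
           "extract_fingerprint", "fingerprint_from_series"]


@dataclass
class SeedMap:
    values: np.ndarray  # Fisher z per point
    seed_region: str
    condition: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("seed map contains non-finite values")


@dataclass
class Fingerprint:
    targets: list[str]
    values: np.ndarray
    seed_region: str
    condition: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.targets),):
            raise ValueError("fingerprint length must equal target count")


def fisher_z(r, clip: float = R_CLIP):
    """Variance-stabilising arctanh transform of a Pearson correlation.

    Values with |r| beyond ``clip`` (e.g. self-correlations at exactly 1)
    are clipped so the result stays finite; |r| > 1 is an error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    out = np.arctanh(np.clip(arr, -clip, clip))
    return out if out.ndim else float(out)


def _standardise(series: np.ndarray) -> np.ndarray:
    """Column z-scores; zero-variance columns become all-zero (r = 0)."""
    x = series - series.mean(axis=0, keepdims=True)
    sd = x.std(axis=0)
    dead = sd == 0
    if np.any(dead):
        log.warning("%d zero-variance point(s); their correlations set to 0",
                    int(dead.sum()))
        sd = np.where(dead, 1.0, sd)
        x[:, dead] = 0.0
    return x / sd


def seed_coupling_map(
    series: np.ndarray,
    seed: str,
    atlas: NodeAtlas,
    condition: str = "",
    source: str = "",
    clip: float = R_CLIP,
) -> SeedMap:
    """Mean Fisher-z coupling of every point with the seed node's points.

    Pearson r between each seed point and each data point is Fisher
    z-transformed and averaged over the seed's points (both hemispheres),
    giving the bilateral seed's coupling map.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[1] != atlas.n_points:
        raise ValueError("series point count does not match atlas")
    seed_pts = atlas.points_of(seed)
    x = _standardise(series)
    t = series.shape[0]
    r = (x[:, seed_pts].T @ x) / t  # n_seed x n_points
    z = fisher_z(r, clip=clip)
    return SeedMap(np.asarray(z).mean(axis=0), seed, condition, source)


def extract_fingerprint(
    seed_map: SeedMap, targets: list[str], atlas: NodeAtlas
) -> Fingerprint:
    """Condense a seed map to one value per target node.

    Per target: mean map value over each hemisphere region's points, then
    the average of the two hemisphere means (bilateral targets contribute a
    single entry).  The seed is excluded from its own fingerprint.
    """
    targets = [t for t in targets if t != seed_map.seed_region]
    if not targets:
        raise ValueError("no fingerprint targets after excluding the seed")
    vals = np.empty(len(targets))
    for i, node in enumerate(targets):
        region_means = [seed_map.values[list(reg.points)].mean()
                        for reg in atlas.regions_of(node)]
        vals[i] = float(np.mean(region_means))
    return Fingerprint(targets, vals, seed_map.seed_region,
                       seed_map.condition, seed_map.source)


def fingerprint_from_series(
    series: np.ndarray,
    seed: str,
    atlas: NodeAtlas,
    targets: list[str] | None = None,
    condition: str = "",
    source: str = "",
) -> Fingerprint:
    """Convenience: seed map + fingerprint extraction in one call.

    ``targets`` defaults to the atlas nodes flagged ``fingerprint_target``
    (the seed itself is always excluded).
    """
    if targets is None:
        targets = atlas.nodes_with_role("fingerprint_target")
    smap = seed_coupling_map(series, seed, atlas, condition, source)
    return extract_fingerprint(smap, list(targets), atlas)
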