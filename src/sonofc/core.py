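"""Core containers for the connectivity pipeline.

The pipeline operates on abstract "points" (voxels or surface vertices after
masking) grouped into named brain regions by a :class:`NodeAtlas`.  Bilateral
structures are represented as two regions (one per hemisphere) sharing a single
network *node*; hemisphere averaging in the fingerprint analysis happens at the
node level.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

CONDITIONS = ("control", "amygdala_tus", "acc_tus")

__all__ = [
    "CONDITIONS",
    "TimeSeriesRun",
    "ConfoundRecord",
    "Region",
    "NodeAtlas",
    "default_atlas",
]


@dataclass
class TimeSeriesRun:
    """One run's BOLD matrix, time x points, plus acquisition metadata."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    run_index: int = 0
    condition: str = "control"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("run data must be 2-D (time x points)")
        if self.data.shape[0] < 1:
            raise ValueError("run must contain at least one volume")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("run data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "TimeSeriesRun":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class ConfoundRecord:
    """Per-run nuisance traces: six B0 parameters plus WM/CSF compartments."""

    b0_params: np.ndarray
    wm_signals: np.ndarray
    csf_signals: np.ndarray

    def __post_init__(self) -> None:
        self.b0_params = np.atleast_2d(np.asarray(self.b0_params, dtype=float))
        self.wm_signals = np.atleast_2d(np.asarray(self.wm_signals, dtype=float))
        self.csf_signals = np.atleast_2d(np.asarray(self.csf_signals, dtype=float))
        t = self.b0_params.shape[0]
        if self.wm_signals.shape[0] != t or self.csf_signals.shape[0] != t:
            raise ValueError("confound traces disagree on time length")

    @property
    def n_volumes(self) -> int:
        return self.b0_params.shape[0]

    def trimmed(self, start: int = 0, stop: int | None = None) -> "ConfoundRecord":
        return ConfoundRecord(
            self.b0_params[start:stop],
            self.wm_signals[start:stop],
            self.csf_signals[start:stop],
        )


@dataclass(frozen=True)
class Region:
    name: str
    node: str
    hemisphere: str  # left | right | midline
    points: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right", "midline"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")
        if len(self.points) == 0:
            raise ValueError(f"region {self.name} has no points")


class NodeAtlas:
    """Named regions -> point indices, with hemisphere pairing and role flags.

    Parameters
    ----------
    regions
        Regions in display order.  A bilateral node contributes two regions
        (hemisphere "left" and "right") that share the same ``node`` id; a
        midline node contributes a single region.
    roles
        Map node id -> set of flags.  Recognised flags: ``sonication_target``,
        ``fingerprint_target``, ``apriori_heatmap``, ``control``.
    """

    def __init__(self, regions: Sequence[Region], roles: Mapping[str, Iterable[str]] | None = None):
        self.regions = list(regions)
        seen: set[int] = set()
        for reg in self.regions:
            overlap = seen.intersection(reg.points)
            if overlap:
                raise ValueError(f"point(s) {sorted(overlap)} assigned to more than one region")
            seen.update(reg.points)
        self.nodes: list[str] = []
        for reg in self.regions:
            if reg.node not in self.nodes:
                self.nodes.append(reg.node)
        self._by_node: dict[str, list[Region]] = {n: [] for n in self.nodes}
        for reg in self.regions:
            self._by_node[reg.node].append(reg)
        for node, regs in self._by_node.items():
            hemis = sorted(r.hemisphere for r in regs)
            if hemis not in (["midline"], ["left", "right"]):
                raise ValueError(
                    f"node {node!r} must be either one midline region or a "
                    f"left/right pair, got hemispheres {hemis}"
                )
        self.roles: dict[str, set[str]] = {n: set() for n in self.nodes}
        for node, flags in (roles or {}).items():
            if node not in self._by_node:
                raise KeyError(f"role assigned to unknown node {node!r}")
            self.roles[node].update(flags)

    # -- lookups ---------------------------------------------------------
    def regions_of(self, node: str) -> list[Region]:
        try:
            return self._by_node[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def points_of(self, node: str) -> np.ndarray:
        return np.concatenate([np.asarray(r.points, dtype=int) for r in self.regions_of(node)])

    def node_index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_points(self) -> int:
        return sum(len(r.points) for r in self.regions)

    @property
    def bilateral_pairs(self) -> dict[str, str]:
        """Map left-region name -> right-region name."""
        pairs: dict[str, str] = {}
        for regs in self._by_node.values():
            if len(regs) == 2:
                left = next(r for r in regs if r.hemisphere == "left")
                right = next(r for r in regs if r.hemisphere == "right")
                pairs[left.name] = right.name
        return pairs

    def nodes_with_role(self, role: str) -> list[str]:
        return [n for n in self.nodes if role in self.roles[n]]

    def node_of_point(self) -> np.ndarray:
        """Node index for every point (length n_points, order = point index)."""
        out = np.empty(self.n_points, dtype=int)
        for reg in self.regions:
            out[np.asarray(reg.points, dtype=int)] = self.nodes.index(reg.node)
        return out


# Default node list mimicking a macaque amygdala/ACC fingerprint constellation.
# Cingulate structures are treated as midline; everything else is bilateral.
_DEFAULT_NODES: list[tuple[str, bool]] = [
    ("amygdala", True),
    ("acc", False),
    ("ofc", True),
    ("lofc_47_12o", True),
    ("dlpfc", True),
    ("frontal_pole", True),
    ("mid_cingulate", False),
    ("post_cingulate", False),
    ("ant_temporal", True),
    ("striatum", True),
    ("m1", True),
    ("pips", True),
    ("f5c", True),
    ("a1", True),
]

# A priori functional grouping used for the ground-truth covariance blocks:
# a limbic/prefrontal module strongly coupled with amygdala and ACC, and a
# sensorimotor/auditory module with weak coupling to it.
DEFAULT_MODULES: dict[str, list[str]] = {
    "limbic_prefrontal": [
        "amygdala", "acc", "ofc", "lofc_47_12o", "dlpfc", "frontal_pole",
        "mid_cingulate", "post_cingulate", "ant_temporal", "striatum",
    ],
    "sensorimotor": ["m1", "pips", "f5c", "a1"],
}


def default_atlas(points_per_region: int = 5) -> NodeAtlas:
    """Build the default 14-node atlas with ``points_per_region`` points per
    hemisphere region (bilateral nodes thus have twice that many points)."""
    if points_per_region < 1:
        raise ValueError("points_per_region must be >= 1")
    regions: list[Region] = []
    nxt = 0
    for node, bilateral in _DEFAULT_NODES:
        if bilateral:
            for hemi, suffix in (("left", "L"), ("right", "R")):
                pts = tuple(range(nxt, nxt + points_per_region))
                nxt += points_per_region
                regions.append(Region(f"{node}.{suffix}", node, hemi, pts))
        else:
            pts = tuple(range(nxt, nxt + points_per_region))
            nxt += points_per_region
            regions.append(Region(node, node, "midline", pts))
    roles = {node: {"fingerprint_target"} for node, _ in _DEFAULT_NODES}
    roles["amygdala"].add("sonication_target")
    roles["acc"].add("sonication_target")
    for node, _ in _DEFAULT_NODES:
        if node not in ("amygdala", "acc"):
            roles[node].add("apriori_heatmap")
    roles["f5c"].add("control")
    return NodeAtlas(regions, roles)
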