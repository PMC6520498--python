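"""Text-format adapters: TSV run/confound matrices with JSON sidecars, atlas
files (JSON or YAML), fingerprint/heat-map tables, and a read-only NIfTI
adapter that flattens masked voxels to points."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import Fingerprint, SeedMap
from .core import ConfoundRecord, NodeAtlas, Region, TimeSeriesRun

__all__ = [
    "write_run", "read_run", "write_confounds", "read_confounds",
    "write_atlas", "read_atlas", "write_fingerprints", "read_fingerprints",
    "write_impact_map", "read_nifti_run",
]

_FLOAT_FMT = "%.10g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_run(run: TimeSeriesRun, path: str | Path) -> Path:
    """Write a run as a TSV matrix (time x points) plus a JSON sidecar."""
    path = Path(path)
    cols = [f"p{j}" for j in range(run.n_points)]
    pd.DataFrame(run.data, columns=cols).to_csv(path, sep="\t", index=False,
                                                float_format=_FLOAT_FMT)
    meta = {"tr_seconds": run.tr_seconds, "subject_id": run.subject_id,
            "run_index": run.run_index, "condition": run.condition}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_run(path: str | Path) -> TimeSeriesRun:
    path = Path(path)
    try:
        data = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"malformed run matrix in {path}: {exc}") from exc
    meta = json.loads(_sidecar_path(path).read_text())
    return TimeSeriesRun(data, meta["tr_seconds"], meta["subject_id"],
                         meta["run_index"], meta["condition"])


def write_confounds(conf: ConfoundRecord, path: str | Path) -> Path:
    path = Path(path)
    cols: dict[str, np.ndarray] = {}
    for i in range(conf.b0_params.shape[1]):
        cols[f"b0_{i + 1}"] = conf.b0_params[:, i]
    for i in range(conf.wm_signals.shape[1]):
        cols[f"wm_{i + 1}"] = conf.wm_signals[:, i]
    for i in range(conf.csf_signals.shape[1]):
        cols[f"csf_{i + 1}"] = conf.csf_signals[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_confounds(path: str | Path) -> ConfoundRecord:
    df = pd.read_csv(Path(path), sep="\t")
    pick = lambda pre: df[[c for c in df.columns if c.startswith(pre)]].to_numpy(float)
    return ConfoundRecord(pick("b0_"), pick("wm_"), pick("csf_"))


def write_atlas(atlas: NodeAtlas, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "regions": [
            {"name": r.name, "node": r.node, "hemisphere": r.hemisphere,
             "points": list(r.points)}
            for r in atlas.regions
        ],
        "roles": {n: sorted(f) for n, f in atlas.roles.items() if f},
    }
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=1))
    return path


def read_atlas(path: str | Path) -> NodeAtlas:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    regions = [Region(r["name"], r["node"], r["hemisphere"], tuple(r["points"]))
               for r in doc["regions"]]
    return NodeAtlas(regions, doc.get("roles", {}))


def write_fingerprints(fps: list[Fingerprint], path: str | Path) -> Path:
    """One row per fingerprint; metadata columns then one column per target."""
    if not fps:
        raise ValueError("no fingerprints to write")
    targets = fps[0].targets
    rows = []
    for fp in fps:
        if fp.targets != targets:
            raise ValueError("fingerprints disagree on target ordering")
        row = {"seed": fp.seed_region, "condition": fp.condition, "source": fp.source}
        row.update(dict(zip(targets, fp.values)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    df = pd.read_csv(Path(path), sep="\t")
    meta = ["seed", "condition", "source"]
    targets = [c for c in df.columns if c not in meta]
    out = []
    for _, row in df.iterrows():
        out.append(Fingerprint(targets, row[targets].to_numpy(float),
                               row["seed"], str(row["condition"]), str(row["source"])))
    return out


def write_impact_map(values: np.ndarray, per_region: np.ndarray,
                     region_set: list[str], path: str | Path) -> Path:
    df = pd.DataFrame(per_region, columns=region_set)
    df.insert(0, "summed_delta_z", values)
    df.insert(0, "point", np.arange(len(values)))
    df.to_csv(Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_nifti_run(path: str | Path, mask_path: str | Path,
                   tr_seconds: float | None = None, **meta) -> TimeSeriesRun:
    """Flatten a 4-D NIfTI to a time x points matrix using a 3-D mask.

    Point order follows C-order iteration over mask voxels.  ``tr_seconds``
    defaults to the NIfTI header's repetition time.
    """
    import nibabel as nib

    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image, got {img.ndim}-D")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.shape != img.shape[:3]:
        raise ValueError(f"mask shape {mask.shape} does not match image grid {img.shape[:3]}")
    data = np.asarray(img.dataobj)[mask].T  # (T, n_masked)
    if tr_seconds is None:
        tr_seconds = float(img.header.get_zooms()[3])
    return TimeSeriesRun(data.astype(float), tr_seconds, **meta)
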