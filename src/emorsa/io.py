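"""Reading and writing the pipeline's on-disk formats.

Volumes are NIfTI-1 (nibabel) with a diagonal affine at the voxel size;
events and nuisance regressors are tab-separated tables; RDMs are CSV with
condition-label headers and empty cells on the masked diagonal; cluster
tables are CSV.  Specs serialize to JSON or YAML.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .rdm import RDM
from .searchlight import ClusterTable
from .synth import PlantedRegion, SyntheticSpec

__all__ = [
    "save_volume",
    "load_volume",
    "save_events",
    "load_events",
    "save_table",
    "save_rdm",
    "load_rdm",
    "save_cluster_table",
    "load_spec",
    "save_spec",
]


def save_volume(
    data: np.ndarray, path: str | Path, voxel_size_mm: float = 3.0
) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def load_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def save_rdm(rdm: RDM, path: str | Path) -> None:
    pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels).to_csv(path)


def load_rdm(path: str | Path) -> RDM:
    df = pd.read_csv(path, index_col=0)
    return RDM(values=df.to_numpy(dtype=float), labels=tuple(df.columns))


def save_cluster_table(clusters: ClusterTable, path: str | Path) -> None:
    table = clusters.table.drop(columns=["voxels"]).copy()
    table["peak_ijk"] = table["peak_ijk"].map(lambda p: " ".join(map(str, p)))
    table.to_csv(path, index=False)


def _spec_to_dict(spec: SyntheticSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["planted_regions"] = [dataclasses.asdict(r) for r in spec.planted_regions]
    return d


def save_spec(spec: SyntheticSpec, path: str | Path) -> None:
    path = Path(path)
    d = _spec_to_dict(spec)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_spec(path: str | Path) -> SyntheticSpec:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    regions = tuple(
        PlantedRegion(
            center=tuple(r["center"]),
            radius_vox=r["radius_vox"],
            effect_amplitude=r.get("effect_amplitude", 1.0),
            share_fraction=r.get("share_fraction", 0.8),
        )
        for r in d.pop("planted_regions", [])
    )
    for key in ("grid_shape", "emotions", "stim_types"):
        if key in d:
            d[key] = tuple(d[key])
    return SyntheticSpec(planted_regions=regions, **d)
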