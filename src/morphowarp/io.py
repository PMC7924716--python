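"""File formats: landmark CSVs, flat landmark tables, scheme files, metadata.

Flat table dialect: one row per specimen, an ``id`` column, then
``<name>_x, <name>_y, <name>_z`` columns in scheme order — 3k coordinate
columns (1,500 for the default 500-landmark facial scheme).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .mesh import TriangleMesh, read_obj
from .sliding import LandmarkConfiguration, TemplateScheme

_AXES = ("x", "y", "z")


# ---------------------------------------------------------------------- #
# Landmark CSV (per specimen): header name,x,y,z in mm
# ---------------------------------------------------------------------- #

def write_landmark_csv(path, names: Sequence[str], coords: np.ndarray) -> None:
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    df = pd.DataFrame(
        {"name": list(names), "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2]}
    )
    df.to_csv(path, index=False)


def read_landmark_csv(path) -> Tuple[List[str], np.ndarray]:
    df = pd.read_csv(path)
    return list(df["name"]), df[["x", "y", "z"]].to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------- #
# Flat landmark tables
# ---------------------------------------------------------------------- #

def flat_columns(names: Sequence[str]) -> List[str]:
    return [f"{n}_{a}" for n in names for a in _AXES]


def configs_to_table(configs: Sequence[LandmarkConfiguration], names: Sequence[str]):
    rows = []
    for cfg in configs:
        rows.append([cfg.specimen_id] + list(cfg.coords.ravel()))
    return pd.DataFrame(rows, columns=["id"] + flat_columns(names))


def table_names(df: pd.DataFrame) -> List[str]:
    """Landmark names recovered from a flat table's coordinate columns."""
    names = []
    for col in df.columns:
        if col.endswith("_x"):
            names.append(col[:-2])
    return names


def table_to_array(df: pd.DataFrame, names: Sequence[str] = None) -> np.ndarray:
    """(n, k, 3) coordinate array from a flat table (scheme column order)."""
    if names is None:
        names = table_names(df)
    cols = flat_columns(names)
    return df[cols].to_numpy(dtype=np.float64).reshape(len(df), len(names), 3)


def write_flat_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_flat_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------- #
# Scheme files (structured text, YAML)
# ---------------------------------------------------------------------- #

def save_scheme(scheme: TemplateScheme, path, mesh_path) -> None:
    """Write the scheme as YAML; the template mesh is referenced by path
    (relative paths resolve against the scheme file's directory)."""
    landmarks = []
    member_curve: Dict[int, str] = {
        i: cid for cid, members in scheme.curves.items() for i in members
    }
    for i, (name, kind) in enumerate(zip(scheme.landmark_names, scheme.kinds)):
        entry = {
            "name": name,
            "kind": kind,
            "x": float(scheme.coords[i, 0]),
            "y": float(scheme.coords[i, 1]),
            "z": float(scheme.coords[i, 2]),
        }
        if i in member_curve:
            entry["curve"] = member_curve[i]
        landmarks.append(entry)
    doc = {
        "template_mesh": str(mesh_path),
        "prominent": scheme.prominent_name,
        "landmarks": landmarks,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scheme(path) -> TemplateScheme:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    mesh_path = Path(doc["template_mesh"])
    if not mesh_path.is_absolute():
        mesh_path = path.parent / mesh_path
    mesh = read_obj(mesh_path)
    names, kinds, coords = [], [], []
    curves: Dict[str, List[int]] = {}
    for i, entry in enumerate(doc["landmarks"]):
        names.append(str(entry["name"]))
        kinds.append(str(entry["kind"]))
        coords.append([entry["x"], entry["y"], entry["z"]])
        if "curve" in entry:
            curves.setdefault(str(entry["curve"]), []).append(i)
    return TemplateScheme(
        mesh=mesh,
        landmark_names=names,
        kinds=kinds,
        coords=np.array(coords),
        curves=curves,
        prominent_name=doc.get("prominent", "pr"),
    )


# ---------------------------------------------------------------------- #
# Metadata
# ---------------------------------------------------------------------- #

METADATA_COLUMNS = ["id", "population", "individual", "replicate", "template"]


def write_metadata(df: pd.DataFrame, path) -> None:
    df[METADATA_COLUMNS].to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path)
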