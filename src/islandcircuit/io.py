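"""Readers and writers for skeletons (SWC), synapse tables (CSV) and datasets.

A dataset directory contains one ``<cell_id>.swc`` per skeleton, a
``synapses.csv`` table, a ``provenance.json``, and a ``manifest.json`` that
lists the files and flags orphan cell ids.  All files are plain text; the
round trip ``read_dataset(write_dataset(ds))`` reproduces every field to
within float-formatting precision (1e-6 nm).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CELL_CLASSES,
    IDENTITY_SCALING,
    SYNAPSE_COLUMNS,
    CircuitDataset,
    NeuronSkeleton,
    SwcParseError,
    VoxelScaling,
    validate_synapse_table,
)

__all__ = [
    "read_skeleton",
    "write_skeleton",
    "read_synapse_table",
    "write_synapse_table",
    "write_dataset",
    "read_dataset",
]

_FLOAT_FMT = "%.6f"


def read_skeleton(
    path: str | Path,
    scaling: VoxelScaling = IDENTITY_SCALING,
    cell_class: str | None = None,
) -> NeuronSkeleton:
    """Read one SWC file into a :class:`NeuronSkeleton`.

    The SWC dialect is the de-facto standard: 7 whitespace-separated columns
    ``id type x y z radius parent``, ``#`` comments, parent ``-1`` for the
    root.  Positions are multiplied component-wise by ``scaling`` so that the
    returned skeleton is in nanometres.

    ``cell_class`` defaults to a ``# CLASS <tok>`` header comment if present,
    else ``"other"``.
    """
    path = Path(path)
    node_ids, parents, pos, radii, codes = [], [], [], [], []
    header_class = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                tok = line.lstrip("#").split()
                if len(tok) == 2 and tok[0] == "CLASS" and tok[1] in CELL_CLASSES:
                    header_class = tok[1]
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                code = int(parts[1])
                xyz = [float(parts[2]), float(parts[3]), float(parts[4])]
                rad = float(parts[5])
                par = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"{path.name}:{lineno}: non-numeric field ({exc})") from exc
            node_ids.append(nid)
            codes.append(code)
            pos.append(xyz)
            radii.append(rad)
            parents.append(par)
    positions = scaling.apply(np.asarray(pos, dtype=float).reshape(-1, 3))
    return NeuronSkeleton(
        cell_id=path.stem,
        cell_class=cell_class or header_class or "other",
        node_ids=np.asarray(node_ids),
        parent_ids=np.asarray(parents),
        positions=positions,
        radii=np.asarray(radii, dtype=float) * float(np.mean(scaling.array)),
        structure_codes=np.asarray(codes),
    )


def write_skeleton(skeleton: NeuronSkeleton, path: str | Path) -> Path:
    """Write a skeleton to SWC (nanometre units, unit scaling on re-read)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# CLASS {skeleton.cell_class}\n")
        fh.write("# id type x y z radius parent (units: nm)\n")
        for i in range(skeleton.n_nodes):
            x, y, z = skeleton.positions[i]
            fh.write(
                f"{int(skeleton.node_ids[i])} {int(skeleton.structure_codes[i])} "
                f"{x:.6f} {y:.6f} {z:.6f} {skeleton.radii[i]:.6f} "
                f"{int(skeleton.parent_ids[i])}\n"
            )
    return path


def read_synapse_table(
    path: str | Path, scaling: VoxelScaling = IDENTITY_SCALING
) -> pd.DataFrame:
    """Read and validate a synapse table; positions are scaled to nm."""
    df = pd.read_csv(path, dtype={"synapse_id": str, "pre_cell": str, "post_cell": str})
    if len(df) == 0 and set(SYNAPSE_COLUMNS) <= set(df.columns):
        return df.loc[:, list(SYNAPSE_COLUMNS)]
    df = validate_synapse_table(df)
    s = scaling.array
    df["x_nm"] = df["x_nm"].astype(float) * s[0]
    df["y_nm"] = df["y_nm"].astype(float) * s[1]
    df["z_nm"] = df["z_nm"].astype(float) * s[2]
    return df


def write_synapse_table(synapses: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_synapse_table(synapses).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_dataset(dataset: CircuitDataset, out_dir: str | Path) -> dict:
    """Write a dataset directory and return (and save) its manifest.

    The manifest lists every file plus the orphan pre/post cell ids — cells
    that appear in the synapse table without a skeleton (allowed; retinal
    axons are typically represented by boutons only).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset.validate()
    skeleton_files = []
    for cid in sorted(dataset.skeletons):
        fname = f"{cid}.swc"
        write_skeleton(dataset.skeletons[cid], out_dir / fname)
        skeleton_files.append(fname)
    write_synapse_table(dataset.synapses, out_dir / "synapses.csv")
    provenance = dict(dataset.provenance)
    provenance["scaling_nm_per_voxel"] = list(dataset.scaling.scale)
    provenance["coordinate_units"] = "nm"
    with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest = {
        "skeletons": skeleton_files,
        "synapse_table": "synapses.csv",
        "provenance": "provenance.json",
        "n_synapses": int(len(dataset.synapses)),
        "orphan_pre_cells": dataset.orphan_pre_cells(),
        "orphan_post_cells": dataset.orphan_post_cells(),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def read_dataset(in_dir: str | Path) -> CircuitDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Files on disk are already in nanometres, so no further voxel scaling is
    applied; the original scaling is recovered from provenance for reference.
    """
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path, "r", encoding="utf-8") as fh:
            manifest = json.load(fh)
        skel_files = manifest["skeletons"]
    else:
        skel_files = sorted(p.name for p in in_dir.glob("*.swc"))
    skeletons = {}
    for fname in skel_files:
        fpath = in_dir / fname
        if not fpath.exists():
            raise FileNotFoundError(f"manifest lists missing skeleton file: {fpath}")
        sk = read_skeleton(fpath)
        skeletons[sk.cell_id] = sk
    synapses = read_synapse_table(in_dir / "synapses.csv")
    provenance = {}
    prov_path = in_dir / "provenance.json"
    if prov_path.exists():
        with open(prov_path, "r", encoding="utf-8") as fh:
            provenance = json.load(fh)
    scaling = VoxelScaling(tuple(provenance.get("scaling_nm_per_voxel", (1.0, 1.0, 1.0))))
    return CircuitDataset(
        skeletons=skeletons, synapses=synapses, scaling=scaling, provenance=provenance
    )
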