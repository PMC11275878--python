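"""Domain model for reconstructed retinogeniculate circuits.

The objects here mirror what a volumetric-EM reconstruction of dLGN tissue
provides: neuron skeletons (rooted trees of 3D nodes with radii), a table of
synaptic contacts between cells, and the voxel scaling that converts image
coordinates to physical nanometres.

Conventions
-----------
* All internal coordinates are nanometres, in (x, y, z) order matching SWC
  column order. Voxel scaling is applied exactly once, when raw voxel-unit
  files are loaded.
* SWC structure codes: 1 = soma, 2 = axon, 3 = dendrite; other codes are
  preserved but unused.
* One :class:`SynapseRecord` row represents one counted synaptic input.
  Retinal (RGC) axons may be represented by boutons only — their ``pre_cell``
  ids need not resolve to a skeleton ("orphan" presynaptic cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CELL_CLASSES",
    "PRE_CLASSES",
    "POST_CLASSES",
    "SYNAPSE_COLUMNS",
    "VoxelScaling",
    "IDENTITY_SCALING",
    "EM_VOXEL_SCALING",
    "NeuronSkeleton",
    "CircuitDataset",
    "SkeletonStructureError",
    "SwcParseError",
    "SynapseValidationError",
    "ConfigurationError",
    "MissingSomaError",
    "NoRGCInputsError",
    "validate_synapse_table",
]

CELL_CLASSES = frozenset({"RGC", "TC", "LIN", "other"})
PRE_CLASSES = frozenset({"RGC", "LIN", "cortical", "other"})
POST_CLASSES = frozenset({"TC", "LIN", "other"})

#: Canonical synapse-table column order (CSV dialect: comma separated, UTF-8,
#: header row mandatory, one contact per row).
SYNAPSE_COLUMNS = (
    "synapse_id",
    "pre_cell",
    "post_cell",
    "x_nm",
    "y_nm",
    "z_nm",
    "pre_class",
    "post_class",
)

SOMA_CODE = 1
AXON_CODE = 2
DENDRITE_CODE = 3


class SkeletonStructureError(ValueError):
    """Skeleton violates the rooted-tree contract (cycle, missing parent...)."""


class SwcParseError(ValueError):
    """Malformed SWC content (non-numeric field, wrong column count)."""


class SynapseValidationError(ValueError):
    """Synapse table violates the record contract (unknown class token...)."""


class ConfigurationError(ValueError):
    """Infeasible or inconsistent run / generator configuration."""


class MissingSomaError(SkeletonStructureError):
    """Operation requires a soma node but the skeleton has none."""


class NoRGCInputsError(ValueError):
    """Operation requires at least one retinal input to the cell."""


@dataclass(frozen=True)
class VoxelScaling:
    """Per-axis nm-per-voxel factors applied on load.

    The EM volume used for circuit reconstruction is anisotropic: section
    cutting compresses the tissue, so the nominal pixel size does not equal
    the physical voxel size.  :data:`EM_VOXEL_SCALING` carries the standard
    26 x 20 x 40 nm correction.
    """

    scale: tuple[float, float, float]

    def __post_init__(self) -> None:
        s = np.asarray(self.scale, dtype=float)
        if s.shape != (3,) or not np.all(np.isfinite(s)) or np.any(s <= 0):
            raise ConfigurationError(
                f"voxel scaling must be 3 positive finite factors, got {self.scale!r}"
            )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.scale, dtype=float)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Convert voxel-unit coordinates to nanometres."""
        return np.asarray(xyz, dtype=float) * self.array

    def invert(self, xyz_nm: np.ndarray) -> np.ndarray:
        """Convert nanometre coordinates back to voxel units."""
        return np.asarray(xyz_nm, dtype=float) / self.array


IDENTITY_SCALING = VoxelScaling((1.0, 1.0, 1.0))
EM_VOXEL_SCALING = VoxelScaling((26.0, 20.0, 40.0))


@dataclass
class NeuronSkeleton:
    """A single reconstructed cell as a rooted tree of 3D nodes.

    Parameters
    ----------
    cell_id:
        Unique identifier (conventionally the SWC file stem).
    cell_class:
        One of ``RGC``, ``TC``, ``LIN``, ``other``.
    node_ids, parent_ids:
        Integer node ids and parent ids; the root's parent is ``-1``.
    positions:
        ``(n, 3)`` array of node positions in nanometres.
    radii:
        Node radii in nanometres.
    structure_codes:
        SWC type codes per node (1 = soma).
    """

    cell_id: str
    cell_class: str
    node_ids: np.ndarray
    parent_ids: np.ndarray
    positions: np.ndarray
    radii: np.ndarray
    structure_codes: np.ndarray
    _index: dict[int, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.parent_ids = np.asarray(self.parent_ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.structure_codes = np.asarray(self.structure_codes, dtype=int)
        self._index = {int(n): i for i, n in enumerate(self.node_ids)}
        self.validate()

    # ------------------------------------------------------------------ #
    # invariants
    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        n = len(self.node_ids)
        if n == 0:
            raise SkeletonStructureError(f"{self.cell_id}: empty skeleton")
        if self.cell_class not in CELL_CLASSES:
            raise SkeletonStructureError(
                f"{self.cell_id}: unknown cell class {self.cell_class!r}; "
                f"allowed: {sorted(CELL_CLASSES)}"
            )
        if len(self._index) != n:
            raise SkeletonStructureError(f"{self.cell_id}: duplicate node ids")
        if self.positions.shape != (n, 3):
            raise SkeletonStructureError(f"{self.cell_id}: positions must be (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise SkeletonStructureError(f"{self.cell_id}: non-finite node position")
        if np.any(self.radii < 0) or not np.all(np.isfinite(self.radii)):
            raise SkeletonStructureError(f"{self.cell_id}: radii must be finite and >= 0")

        roots = np.flatnonzero(self.parent_ids == -1)
        if len(roots) != 1:
            raise SkeletonStructureError(
                f"{self.cell_id}: expected exactly one root, found {len(roots)}"
            )
        for nid, pid in zip(self.node_ids, self.parent_ids):
            if pid != -1 and int(pid) not in self._index:
                raise SkeletonStructureError(
                    f"{self.cell_id}: node {int(nid)} references missing parent {int(pid)}"
                )
        # Cycle check by pointer chasing with a visited-depth bound.
        depth_cache: dict[int, int] = {}
        for nid in self.node_ids:
            seen: list[int] = []
            cur = int(nid)
            while cur != -1 and cur not in depth_cache:
                seen.append(cur)
                if len(seen) > n:
                    raise SkeletonStructureError(
                        f"{self.cell_id}: cyclic parent references involving node {int(nid)}"
                    )
                cur = int(self.parent_ids[self._index[cur]])
                if cur in seen:
                    raise SkeletonStructureError(
                        f"{self.cell_id}: cyclic parent references involving node {cur}"
                    )
            base = 0 if cur == -1 else depth_cache[cur]
            for i, node in enumerate(reversed(seen)):
                depth_cache[node] = base + i + 1
        if self.cell_class in ("TC", "LIN") and len(self.soma_node_ids) == 0:
            raise MissingSomaError(f"{self.cell_id}: {self.cell_class} cell has no soma node")

    # ------------------------------------------------------------------ #
    # tree navigation
    # ------------------------------------------------------------------ #
    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parent_ids == -1)[0])

    @property
    def soma_node_ids(self) -> set[int]:
        return {int(n) for n in self.node_ids[self.structure_codes == SOMA_CODE]}

    @property
    def soma_indices(self) -> np.ndarray:
        return np.flatnonzero(self.structure_codes == SOMA_CODE)

    def soma_centroid(self) -> np.ndarray:
        idx = self.soma_indices
        if len(idx) == 0:
            raise MissingSomaError(f"{self.cell_id}: no soma nodes")
        return self.positions[idx].mean(axis=0)

    def parent_index(self, i: int) -> int:
        pid = int(self.parent_ids[i])
        return -1 if pid == -1 else self._index[pid]

    def children_map(self) -> dict[int, list[int]]:
        """Map node index -> list of child node indices."""
        out: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for i in range(self.n_nodes):
            p = self.parent_index(i)
            if p != -1:
                out[p].append(i)
        return out

    def subtree_indices(self, root: int) -> np.ndarray:
        """All node indices in the subtree rooted at node index ``root``."""
        children = self.children_map()
        stack, out = [root], []
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(children[i])
        return np.array(sorted(out), dtype=int)

    def primary_subtrees(self) -> list[np.ndarray]:
        """Soma-adjacent subtrees: one array of node indices per neurite
        emerging from the soma.  The unit of the capture null model."""
        soma = set(self.soma_indices.tolist())
        if not soma:
            raise MissingSomaError(f"{self.cell_id}: no soma nodes")
        children = self.children_map()
        roots = []
        for s in sorted(soma):
            for c in children[s]:
                if c not in soma:
                    roots.append(c)
        # also handle a non-soma root whose parent chain starts at the root
        return [self.subtree_indices(r) for r in sorted(roots)]

    def edge_lengths(self) -> np.ndarray:
        """Per-node length of the edge to the parent (0 for the root)."""
        out = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            p = self.parent_index(i)
            if p != -1:
                out[i] = float(np.linalg.norm(self.positions[i] - self.positions[p]))
        return out

    def path_length_from_root(self) -> np.ndarray:
        """Cumulative along-tree distance of every node from the root."""
        lengths = self.edge_lengths()
        out = np.zeros(self.n_nodes)
        order = self._topological_order()
        for i in order:
            p = self.parent_index(i)
            if p != -1:
                out[i] = out[p] + lengths[i]
        return out

    def _topological_order(self) -> list[int]:
        children = self.children_map()
        order, stack = [], [self.root_index]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(children[i])
        return order

    def nearest_node(self, points: np.ndarray, exclude_soma: bool = False):
        """Nearest skeleton node to each query point.

        Returns ``(indices, distances)`` into this skeleton's node arrays.
        """
        from scipy.spatial import cKDTree

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if exclude_soma:
            keep = np.flatnonzero(self.structure_codes != SOMA_CODE)
            if len(keep) == 0:
                keep = np.arange(self.n_nodes)
        else:
            keep = np.arange(self.n_nodes)
        tree = cKDTree(self.positions[keep])
        dist, sub = tree.query(pts)
        return keep[np.atleast_1d(sub)], np.atleast_1d(dist)


def validate_synapse_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a synapse table against the record contract.

    Checks column presence, class enums, finite positions, pre != post and
    unique synapse ids.  Returns the table with columns in canonical order.
    """
    missing = [c for c in SYNAPSE_COLUMNS if c not in df.columns]
    if missing:
        raise SynapseValidationError(f"synapse table missing columns: {missing}")
    df = df.loc[:, list(SYNAPSE_COLUMNS)].copy()
    if len(df) == 0:
        return df
    if df["synapse_id"].duplicated().any():
        dup = df.loc[df["synapse_id"].duplicated(), "synapse_id"].iloc[0]
        raise SynapseValidationError(f"duplicate synapse_id {dup!r}")
    bad_pre = sorted(set(df["pre_class"]) - PRE_CLASSES)
    if bad_pre:
        raise SynapseValidationError(
            f"unknown pre_class token(s) {bad_pre}; allowed: {sorted(PRE_CLASSES)}"
        )
    bad_post = sorted(set(df["post_class"]) - POST_CLASSES)
    if bad_post:
        raise SynapseValidationError(
            f"unknown post_class token(s) {bad_post}; allowed: {sorted(POST_CLASSES)}"
        )
    pos = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pos)):
        raise SynapseValidationError("non-finite synapse position")
    self_syn = df["pre_cell"] == df["post_cell"]
    if self_syn.any():
        sid = df.loc[self_syn, "synapse_id"].iloc[0]
        raise SynapseValidationError(f"synapse {sid!r} has pre_cell == post_cell")
    return df


@dataclass
class CircuitDataset:
    """A reconstructed (or synthetic) circuit: skeletons + synapse table.

    ``synapses`` is a pandas DataFrame with the :data:`SYNAPSE_COLUMNS`
    dialect; it is the package's collection-of-SynapseRecord container.
    """

    skeletons: dict[str, NeuronSkeleton]
    synapses: pd.DataFrame
    scaling: VoxelScaling = IDENTITY_SCALING
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.synapses = validate_synapse_table(self.synapses)

    def validate(self) -> None:
        for cid, sk in self.skeletons.items():
            if sk.cell_id != cid:
                raise SkeletonStructureError(
                    f"skeleton key {cid!r} != cell_id {sk.cell_id!r}"
                )
            sk.validate()
        validate_synapse_table(self.synapses)

    # Orphans are allowed: RGC axons may be represented by boutons only.
    def orphan_pre_cells(self) -> list[str]:
        return sorted(set(self.synapses["pre_cell"]) - set(self.skeletons))

    def orphan_post_cells(self) -> list[str]:
        return sorted(set(self.synapses["post_cell"]) - set(self.skeletons))

    def rgc_boutons(self) -> pd.DataFrame:
        """All retinal-bouton contacts (pre_class == RGC), one row per bouton."""
        return self.synapses[self.synapses["pre_class"] == "RGC"].reset_index(drop=True)

    def rgc_bouton_positions(self) -> tuple[list[str], np.ndarray]:
        b = self.rgc_boutons()
        return list(b["synapse_id"]), b[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)

    def synapses_onto(self, cell_id: str) -> pd.DataFrame:
        return self.synapses[self.synapses["post_cell"] == cell_id]

    def synapses_from(self, cell_id: str) -> pd.DataFrame:
        return self.synapses[self.synapses["pre_cell"] == cell_id]

    def cells_of_class(self, cell_class: str) -> list[str]:
        return sorted(
            cid for cid, sk in self.skeletons.items() if sk.cell_class == cell_class
        )
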