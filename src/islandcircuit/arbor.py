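"""Exclusion-zone crossing analysis and LIN neurite taxonomy.

LINs (local inhibitory neurons) carry three kinds of neurite: long
input/output shaft dendrites spanning hundreds of micrometres, short
(~20 um) synapse-dense targeted dendrites that hug nearby retinal axons,
and small output-only axon-like branches.  The analysis decomposes a
skeleton into branch units, tests each unit's polyline against the
exclusion-shell region implied by a bouton-field labeling, and tallies
island / non-island synaptic inputs per unit.

Classification precedence: shaft (by length) -> axon-like (output-only) ->
targeted (short and synapse-dense) -> unclassified; an output-only short
branch is therefore axon-like, not targeted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import BoutonFieldLabeling
from .model import MissingSomaError, NeuronSkeleton, SynapseValidationError

__all__ = [
    "NeuriteSegmentProfile",
    "zone_crossings",
    "classify_lin_neurites",
    "field_purity",
]

NEURITE_TYPES = (
    "tc_proximal",
    "tc_distal",
    "lin_shaft",
    "lin_targeted",
    "lin_axon_like",
    "unclassified",
)

ARC_STEP_NM = 200.0  # polyline sampling step for point-in-shell tests
TC_PROXIMAL_RADIUS_NM = 800.0


@dataclass
class NeuriteSegmentProfile:
    """Per-branch geometry, synapse counts, and zone-crossing flag."""

    cell_id: str
    branch_id: int
    root_node_id: int
    path_length: float
    mean_radius: float
    n_inputs_island: int
    n_inputs_nonisland: int
    n_inputs_ambiguous: int
    n_inputs_other: int
    n_outputs: int
    crosses_zone: bool
    neurite_type: str

    @property
    def n_inputs_total(self) -> int:
        return (
            self.n_inputs_island
            + self.n_inputs_nonisland
            + self.n_inputs_ambiguous
            + self.n_inputs_other
        )

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "branch_id": int(self.branch_id),
            "root_node_id": int(self.root_node_id),
            "path_length_nm": float(self.path_length),
            "mean_radius_nm": float(self.mean_radius),
            "n_inputs_island": int(self.n_inputs_island),
            "n_inputs_nonisland": int(self.n_inputs_nonisland),
            "n_inputs_ambiguous": int(self.n_inputs_ambiguous),
            "n_inputs_other": int(self.n_inputs_other),
            "n_outputs": int(self.n_outputs),
            "crosses_zone": bool(self.crosses_zone),
            "neurite_type": self.neurite_type,
        }


def field_purity(profile: NeuriteSegmentProfile) -> float:
    """Fraction of field-assignable inputs from the dominant field.

    ``max(island, nonisland) / (island + nonisland)``; ambiguous inputs are
    excluded.  Returns NaN (missing) when no field input exists.
    """
    total = profile.n_inputs_island + profile.n_inputs_nonisland
    if total == 0:
        return float("nan")
    return max(profile.n_inputs_island, profile.n_inputs_nonisland) / total


# --------------------------------------------------------------------------- #
# shared helpers
# --------------------------------------------------------------------------- #
def _sample_edges(skeleton: NeuronSkeleton, node_subset: np.ndarray, arc_step: float):
    """Sample points along every parent edge of the subset at <= arc_step."""
    pts = []
    subset = set(int(i) for i in node_subset)
    for i in subset:
        p = skeleton.parent_index(i)
        if p == -1:
            pts.append(skeleton.positions[i])
            continue
        a, b = skeleton.positions[p], skeleton.positions[i]
        dist = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(dist / arc_step)))
        t = (np.arange(n) + 1.0) / n
        pts.append(a + (b - a) * t[:, None])
    return np.vstack([np.atleast_2d(x) for x in pts]) if pts else np.zeros((0, 3))


def _branch_of_node(skeleton: NeuronSkeleton, branches: list[np.ndarray]) -> np.ndarray:
    out = np.full(skeleton.n_nodes, -1, dtype=int)
    for b, sub in enumerate(branches):
        out[sub] = b
    return out


def _count_synapses(
    skeleton: NeuronSkeleton,
    synapses: pd.DataFrame,
    labeling: BoutonFieldLabeling,
    branch_of_node: np.ndarray,
    n_branches: int,
):
    """Attribute input/output synapses of this cell to branches.

    Inputs with pre_class RGC take the bouton's field label from the
    labeling (falling back to the geometric region for unlabeled positions);
    other inputs are tallied separately.  Returns per-branch count arrays
    (island, nonisland, ambiguous, other, outputs).
    """
    for col in ("pre_cell", "post_cell"):
        if col not in synapses.columns:
            raise SynapseValidationError(
                "synapse table lacks pre/post cell identity; export synapses "
                "per cell so input/output direction can be derived"
            )
    n = n_branches
    isl = np.zeros(n, int)
    non = np.zeros(n, int)
    amb = np.zeros(n, int)
    oth = np.zeros(n, int)
    out = np.zeros(n, int)

    inputs = synapses[synapses["post_cell"] == skeleton.cell_id]
    outputs = synapses[synapses["pre_cell"] == skeleton.cell_id]

    def branch_of_positions(rows):
        pos = rows[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        node_idx, _ = skeleton.nearest_node(pos, exclude_soma=True)
        return branch_of_node[node_idx]

    if len(inputs):
        b_in = branch_of_positions(inputs)
        is_rgc = (inputs["pre_class"] == "RGC").to_numpy()
        sids = inputs["synapse_id"].to_numpy()
        pos = inputs[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        regions = labeling.point_region(pos)
        for j in range(len(inputs)):
            b = b_in[j]
            if b < 0:
                continue
            if is_rgc[j]:
                try:
                    lb = labeling.label_of(sids[j])
                except KeyError:
                    lb = {"island": "island", "nonisland_field": "nonisland"}.get(
                        regions[j], "ambiguous"
                    )
                if lb == "island":
                    isl[b] += 1
                elif lb == "nonisland":
                    non[b] += 1
                else:
                    amb[b] += 1
            else:
                oth[b] += 1
    if len(outputs):
        b_out = branch_of_positions(outputs)
        for b in b_out:
            if b >= 0:
                out[b] += 1
    return isl, non, amb, oth, out


# --------------------------------------------------------------------------- #
# zone crossings (TC-oriented; works for any skeleton with a soma)
# --------------------------------------------------------------------------- #
def zone_crossings(
    skeleton: NeuronSkeleton,
    labeling: BoutonFieldLabeling,
    synapses: pd.DataFrame,
    arc_step: float = ARC_STEP_NM,
) -> list[NeuriteSegmentProfile]:
    """Test each soma-adjacent branch for intersection with the exclusion
    shell and attribute the cell's synapses to branch and field.

    A skeleton entirely outside the labeled analysis volume yields an empty
    list with a warning rather than an error.
    """
    node_regions = labeling.point_region(skeleton.positions)
    if np.all(node_regions == "outside"):
        warnings.warn(
            f"{skeleton.cell_id}: skeleton entirely outside the analysis volume",
            stacklevel=2,
        )
        return []
    branches = skeleton.primary_subtrees()
    branch_of_node = _branch_of_node(skeleton, branches)
    isl, non, amb, oth, out = _count_synapses(
        skeleton, synapses, labeling, branch_of_node, len(branches)
    )
    lengths = skeleton.edge_lengths()
    profiles = []
    for b, sub in enumerate(branches):
        samples = _sample_edges(skeleton, sub, arc_step)
        crosses = bool(np.any(labeling.point_region(samples) == "shell"))
        path_length = float(lengths[sub].sum())
        mean_radius = float(skeleton.radii[sub].mean())
        if skeleton.cell_class == "TC":
            rgc_inputs = isl[b] + non[b] + amb[b]
            ntype = (
                "tc_proximal"
                if (mean_radius >= TC_PROXIMAL_RADIUS_NM or rgc_inputs >= 1)
                else "tc_distal"
            )
        else:
            ntype = "unclassified"
        profiles.append(
            NeuriteSegmentProfile(
                cell_id=skeleton.cell_id,
                branch_id=b,
                root_node_id=int(skeleton.node_ids[sub[0]]) if len(sub) else -1,
                path_length=path_length,
                mean_radius=mean_radius,
                n_inputs_island=int(isl[b]),
                n_inputs_nonisland=int(non[b]),
                n_inputs_ambiguous=int(amb[b]),
                n_inputs_other=int(oth[b]),
                n_outputs=int(out[b]),
                crosses_zone=crosses,
                neurite_type=ntype,
            )
        )
    return profiles


# --------------------------------------------------------------------------- #
# LIN neurite taxonomy
# --------------------------------------------------------------------------- #
def _lin_units(skeleton: NeuronSkeleton):
    """Decompose a LIN skeleton into trunk and side-branch units.

    For each soma-adjacent subtree the trunk is the along-tree path to the
    farthest node; every subtree hanging off the trunk is one side unit.
    Returns tuples ``(root_index, node_index_array, cable_length, reach)``
    where reach is the maximum along-tree distance from the unit's
    attachment point.
    """
    lengths = skeleton.edge_lengths()
    dist_root = skeleton.path_length_from_root()
    children = skeleton.children_map()
    units = []
    for sub in skeleton.primary_subtrees():
        sub_set = set(int(i) for i in sub)
        far = int(sub[np.argmax(dist_root[sub])])
        trunk = []
        cur = far
        while cur in sub_set:
            trunk.append(cur)
            cur = skeleton.parent_index(cur)
        trunk_set = set(trunk)
        trunk_arr = np.array(sorted(trunk_set), dtype=int)
        trunk_len = float(lengths[trunk_arr].sum())
        units.append((int(trunk[-1]), trunk_arr, trunk_len, trunk_len))
        for t in trunk:
            for c in children[t]:
                if c in sub_set and c not in trunk_set:
                    side = skeleton.subtree_indices(c)
                    cable = float(lengths[side].sum())
                    reach = float((dist_root[side] - dist_root[t]).max())
                    units.append((int(c), side, cable, reach))
    return units


def classify_lin_neurites(
    lin: NeuronSkeleton,
    synapses: pd.DataFrame,
    labeling: BoutonFieldLabeling,
    targeted_reach: float = 20000.0,
    reach_tolerance: float = 2.0,
    density_threshold: float = 0.0002,
    shaft_min_length: float = 100000.0,
    arc_step: float = ARC_STEP_NM,
) -> list[NeuriteSegmentProfile]:
    """Classify every neurite unit of a LIN as shaft, targeted, axon-like or
    unclassified, with per-unit island/non-island input counts.

    * shaft: along-tree reach at least ``shaft_min_length`` (default 100 um),
      regardless of synapse density;
    * axon-like: carries outputs but no inputs;
    * targeted: reach within ``reach_tolerance x targeted_reach`` (default
      2 x 20 um) and synapse linear density at least ``density_threshold``
      (default 0.2 per um).
    """
    if lin.cell_class != "LIN":
        raise ValueError(f"{lin.cell_id}: classify_lin_neurites expects a LIN skeleton")
    if len(lin.soma_node_ids) == 0:
        raise MissingSomaError(f"{lin.cell_id}: LIN has no soma node")
    units = _lin_units(lin)
    branch_of_node = np.full(lin.n_nodes, -1, dtype=int)
    for b, (_, nodes, _, _) in enumerate(units):
        branch_of_node[nodes] = b
    isl, non, amb, oth, out = _count_synapses(
        lin, synapses, labeling, branch_of_node, len(units)
    )
    profiles = []
    for b, (root_idx, nodes, cable, reach) in enumerate(units):
        n_in = int(isl[b] + non[b] + amb[b] + oth[b])
        n_out = int(out[b])
        density = (n_in + n_out) / cable if cable > 0 else 0.0
        if reach >= shaft_min_length:
            ntype = "lin_shaft"
        elif n_out > 0 and n_in == 0:
            ntype = "lin_axon_like"
        elif reach <= reach_tolerance * targeted_reach and density >= density_threshold:
            ntype = "lin_targeted"
        else:
            ntype = "unclassified"
        samples = _sample_edges(lin, nodes, arc_step)
        crosses = bool(np.any(labeling.point_region(samples) == "shell"))
        profiles.append(
            NeuriteSegmentProfile(
                cell_id=lin.cell_id,
                branch_id=b,
                root_node_id=int(lin.node_ids[root_idx]),
                path_length=cable,
                mean_radius=float(lin.radii[nodes].mean()),
                n_inputs_island=int(isl[b]),
                n_inputs_nonisland=int(non[b]),
                n_inputs_ambiguous=int(amb[b]),
                n_inputs_other=int(oth[b]),
                n_outputs=n_out,
                crosses_zone=crosses,
                neurite_type=ntype,
            )
        )
    return profiles
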