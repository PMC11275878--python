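"""Synthetic circuit generator with ground truth.

Emulates the geometry the segregation analysis assumes: a dense ellipsoidal
island of retinal boutons, a surrounding uniform non-island field, a
bouton-free exclusion shell between them, thalamocortical (TC) somata
scattered across the shell with a handful of primary dendrites each, and
local inhibitory neurons (LINs) whose long shaft neurites cross the shell
while short synapse-dense targeted neurites stay within one field.

The ``segregation`` knob controls how exclusively each TC's dendrites draw
from one field: at 1 every dendrite follows the cell's home field, at 0
every dendrite picks a field independently with probability 1/2 — exactly
the independent-dendrite null model, so the generator doubles as the null
sampler's end-to-end check.

Dendrites are piecewise-linear paths from the soma to nearby boutons of the
assigned field; tortuosity and branching-angle realism are deliberately not
modeled — only what the analysis consumes (tree topology and synapse
positions).  All randomness flows from a single seeded generator and the
seed is recorded in provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CircuitDataset,
    ConfigurationError,
    NeuronSkeleton,
    SYNAPSE_COLUMNS,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "degrade"]

SOMA_RADIUS_TC = 5000.0
SOMA_RADIUS_LIN = 4000.0
DENDRITE_RADIUS_TC = 900.0
SHAFT_RADIUS = 700.0
TARGETED_RADIUS = 350.0
SEGMENT_STEP = 4000.0  # nm between generated skeleton nodes


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic circuit.

    Defaults reflect the reconstructed-tissue regime: nine TCs with primary
    dendrite counts (2,2,3,4,4,4,5,5,7), per-TC retinal input counts spanning
    0-118, targeted LIN neurites reaching ~20 um.  Island size, shell width
    and bouton counts are self-consistent choices (island radii >> shell
    width >> bouton spacing), not measured values.
    """

    seed: int = 0
    volume_extent: tuple[float, float, float] = (70000.0, 70000.0, 70000.0)
    island_center: tuple[float, float, float] | None = None
    island_radii: tuple[float, float, float] = (15000.0, 12000.0, 10000.0)
    exclusion_width: float = 12000.0
    island_bouton_count: int = 1500
    nonisland_bouton_count: int = 9000
    tc_count: int = 9
    dendrites_per_tc: tuple[int, ...] = (2, 2, 3, 4, 4, 4, 5, 5, 7)
    boutons_per_tc_range: tuple[int, int] = (0, 118)
    segregation: float = 1.0
    lin_count: int = 2
    targeted_neurite_reach: float = 20000.0
    targeted_neurites_per_lin: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.exclusion_width <= 0:
            raise ConfigurationError("exclusion_width must be > 0")
        if not 0.0 <= self.segregation <= 1.0:
            raise ConfigurationError("segregation must be in [0, 1]")
        if any(k < 1 for k in self.dendrites_per_tc):
            raise ConfigurationError("dendrites_per_tc entries must be >= 1")
        lo, hi = self.boutons_per_tc_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("boutons_per_tc_range must satisfy 0 <= lo <= hi")
        extent = np.asarray(self.volume_extent, dtype=float)
        radii = np.asarray(self.island_radii, dtype=float)
        if np.any(extent <= 0) or np.any(radii <= 0):
            raise ConfigurationError("volume extent and island radii must be positive")
        center = self.center_array
        outer = radii + self.exclusion_width
        if np.any(center - outer < 0) or np.any(center + outer > extent):
            raise ConfigurationError(
                "island ellipsoid plus exclusion shell does not fit in the volume"
            )
        box_vol = float(np.prod(extent))
        outer_vol = 4.0 / 3.0 * np.pi * float(np.prod(outer))
        free_frac = (box_vol - outer_vol) / box_vol
        if self.nonisland_bouton_count > 0 and free_frac < 0.02:
            raise ConfigurationError(
                "requested non-island bouton count infeasible: free volume "
                f"fraction is only {free_frac:.3f}"
            )

    @property
    def center_array(self) -> np.ndarray:
        if self.island_center is None:
            return np.asarray(self.volume_extent, dtype=float) / 2.0
        return np.asarray(self.island_center, dtype=float)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["island_center"] = None if self.island_center is None else list(self.island_center)
        for key in ("volume_extent", "island_radii", "dendrites_per_tc", "boutons_per_tc_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("volume_extent", "island_radii", "dendrites_per_tc", "boutons_per_tc_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("island_center") is not None:
            d["island_center"] = tuple(d["island_center"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually built, for end-to-end recovery tests."""

    bouton_field: dict  # synapse_id -> "island" | "nonisland" (RGC boutons)
    tc_capture: dict  # tc_id -> true capture class
    tc_dendrite_fields: dict  # tc_id -> list of (field, n_boutons) per dendrite
    lin_neurites: list  # dicts: cell_id, root_node_id, type, field
    island_center: list
    island_radii: list
    exclusion_width: float
    segregation: float

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, sort_keys=True)
            fh.write("\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


# --------------------------------------------------------------------------- #
# geometry helpers
# --------------------------------------------------------------------------- #
def _ellipsoid_q(points: np.ndarray, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Quadratic form; <= 1 means inside the ellipsoid."""
    return np.sum(((np.atleast_2d(points) - center) / radii) ** 2, axis=1)


class _BoutonPool:
    """Bouton positions with true field labels and one-use bookkeeping."""

    def __init__(self, positions: np.ndarray, fields: np.ndarray):
        self.positions = positions
        self.fields = fields
        self.used = np.zeros(len(positions), dtype=bool)
        self.ids = [f"b{i:06d}" for i in range(len(positions))]

    def available(self, fld: str) -> np.ndarray:
        return np.flatnonzero((self.fields == fld) & ~self.used)

    def draw_near(self, fld: str, m: int, anchor: np.ndarray, rng, spread: int = 2):
        """Draw ``m`` unused boutons of field ``fld``, sampled among the
        ``spread * m`` nearest to ``anchor`` (local, like a real dendrite)."""
        avail = self.available(fld)
        if len(avail) < m:
            raise ConfigurationError(
                f"bouton pool exhausted for field {fld!r}: need {m}, have {len(avail)}"
            )
        d = np.linalg.norm(self.positions[avail] - anchor, axis=1)
        nearest = avail[np.argsort(d)[: min(len(avail), spread * m)]]
        chosen = rng.choice(nearest, size=m, replace=False)
        self.used[chosen] = True
        return np.sort(chosen)

    def draw_within(self, fld: str, anchor: np.ndarray, radius: float, m: int):
        """Up to ``m`` nearest unused boutons of ``fld`` within ``radius``."""
        avail = self.available(fld)
        if len(avail) == 0:
            return np.zeros(0, dtype=int)
        d = np.linalg.norm(self.positions[avail] - anchor, axis=1)
        order = np.argsort(d)
        sel = avail[order][d[order] <= radius][:m]
        self.used[sel] = True
        return sel


class _SkeletonBuilder:
    """Incremental node-list builder for one cell."""

    def __init__(self, cell_id: str, cell_class: str):
        self.cell_id = cell_id
        self.cell_class = cell_class
        self.node_ids: list[int] = []
        self.parents: list[int] = []
        self.pos: list[np.ndarray] = []
        self.radii: list[float] = []
        self.codes: list[int] = []

    def add(self, position, radius: float, code: int, parent: int) -> int:
        nid = len(self.node_ids) + 1
        self.node_ids.append(nid)
        self.parents.append(parent)
        self.pos.append(np.asarray(position, dtype=float))
        self.radii.append(radius)
        self.codes.append(code)
        return nid

    def add_path(self, start_node: int, waypoints, radius: float, code: int,
                 step: float = SEGMENT_STEP) -> list[int]:
        """Polyline from ``start_node`` through ``waypoints``, subdividing
        long segments; returns the node id at each waypoint."""
        prev = start_node
        prev_pos = self.pos[start_node - 1]
        out = []
        for wp in waypoints:
            wp = np.asarray(wp, dtype=float)
            seg = wp - prev_pos
            dist = float(np.linalg.norm(seg))
            n_sub = max(1, int(np.ceil(dist / step)))
            for s in range(1, n_sub + 1):
                p = prev_pos + seg * (s / n_sub)
                prev = self.add(p, radius, code, prev)
            prev_pos = wp
            out.append(prev)
        return out

    def build(self) -> NeuronSkeleton:
        return NeuronSkeleton(
            cell_id=self.cell_id,
            cell_class=self.cell_class,
            node_ids=np.asarray(self.node_ids),
            parent_ids=np.asarray(self.parents),
            positions=np.asarray(self.pos),
            radii=np.asarray(self.radii),
            structure_codes=np.asarray(self.codes),
        )


# --------------------------------------------------------------------------- #
# generation
# --------------------------------------------------------------------------- #
def generate(config: GeneratorConfig) -> tuple[CircuitDataset, GroundTruth]:
    """Generate one circuit with ground truth.  Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    extent = np.asarray(config.volume_extent, dtype=float)
    center = config.center_array
    radii = np.asarray(config.island_radii, dtype=float)
    w = float(config.exclusion_width)
    outer = radii + w

    # --- bouton fields ---------------------------------------------------- #
    n_isl = config.island_bouton_count
    dirs = rng.normal(size=(n_isl, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    u = rng.random(n_isl) ** (1.0 / 3.0)
    island_pts = center + radii * dirs * u[:, None]

    non_pts = np.empty((0, 3))
    tries = 0
    while len(non_pts) < config.nonisland_bouton_count:
        tries += 1
        if tries > 200:
            raise ConfigurationError("non-island bouton sampling did not converge")
        batch = rng.random((max(2 * config.nonisland_bouton_count, 1000), 3)) * extent
        keep = _ellipsoid_q(batch, center, outer) > 1.0
        non_pts = np.vstack([non_pts, batch[keep]])
    non_pts = non_pts[: config.nonisland_bouton_count]

    pool = _BoutonPool(
        positions=np.vstack([island_pts, non_pts]),
        fields=np.asarray(["island"] * n_isl + ["nonisland"] * len(non_pts), dtype=object),
    )

    skeletons: dict[str, NeuronSkeleton] = {}
    syn_rows: list[tuple] = []
    syn_counter = [0]

    def add_synapse(pre_cell, post_cell, position, pre_class, post_class):
        sid = f"s{syn_counter[0]:06d}"
        syn_counter[0] += 1
        syn_rows.append(
            (sid, pre_cell, post_cell, float(position[0]), float(position[1]),
             float(position[2]), pre_class, post_class)
        )
        return sid

    bouton_sid: dict[int, str] = {}  # pool index -> synapse id

    def add_bouton_synapse(pool_idx: int, post_cell: str, post_class: str) -> str:
        sid = add_synapse(
            pool.ids[pool_idx], post_cell, pool.positions[pool_idx], "RGC", post_class
        )
        bouton_sid[pool_idx] = sid
        return sid

    # --- thalamocortical cells ------------------------------------------- #
    k_list = [
        config.dendrites_per_tc[i % len(config.dendrites_per_tc)]
        for i in range(config.tc_count)
    ]
    tc_ids = [f"tc{i + 1:02d}" for i in range(config.tc_count)]
    tc_dendrite_fields: dict[str, list] = {}
    tc_capture: dict[str, str] = {}
    lo_b, hi_b = config.boutons_per_tc_range

    for tc_id, k in zip(tc_ids, k_list):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        soma_pos = center + (radii + w / 2.0) * d
        builder = _SkeletonBuilder(tc_id, "TC")
        soma_node = builder.add(soma_pos, SOMA_RADIUS_TC, 1, -1)

        home = "island" if rng.random() < 0.5 else "nonisland"
        dend_fields = []
        for _ in range(k):
            if rng.random() < config.segregation:
                dend_fields.append(home)
            else:
                dend_fields.append("island" if rng.random() < 0.5 else "nonisland")

        total_b = int(rng.integers(lo_b, hi_b + 1))
        alloc = rng.multinomial(total_b, np.full(k, 1.0 / k)) if total_b > 0 else np.zeros(k, int)

        per_dendrite = []
        for fld, m in zip(dend_fields, alloc):
            if m > 0:
                idx = pool.draw_near(fld, int(m), soma_pos, rng)
                order = np.argsort(np.linalg.norm(pool.positions[idx] - soma_pos, axis=1))
                waypoints = pool.positions[idx][order]
                nodes = builder.add_path(soma_node, waypoints, DENDRITE_RADIUS_TC, 3)
                for b in idx[order]:
                    add_bouton_synapse(int(b), tc_id, "TC")
            else:
                # dendrite stub with no retinal input
                toward = center - soma_pos if fld == "island" else soma_pos - center
                toward = toward / np.linalg.norm(toward)
                jitter = rng.normal(size=3) * 0.3
                stub_dir = toward + jitter
                stub_dir /= np.linalg.norm(stub_dir)
                builder.add_path(
                    soma_node, [soma_pos + stub_dir * 10000.0], DENDRITE_RADIUS_TC, 3
                )
            per_dendrite.append((fld, int(m)))
        tc_dendrite_fields[tc_id] = per_dendrite
        realized = [fld for fld, m in per_dendrite if m > 0]
        if not realized:
            tc_capture[tc_id] = "no_rgc"
        elif all(f == "island" for f in realized):
            tc_capture[tc_id] = "pure_island"
        elif all(f == "nonisland" for f in realized):
            tc_capture[tc_id] = "pure_nonisland"
        else:
            tc_capture[tc_id] = "mixed"
        skeletons[tc_id] = builder.build()

    # --- local inhibitory neurons ----------------------------------------- #
    lin_truth: list[dict] = []
    inner_margin = radii * 0.85  # clearly inside the island
    for j in range(config.lin_count):
        lin_id = f"lin{j + 1:02d}"
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        soma_pos = center + (radii + w / 2.0) * d
        builder = _SkeletonBuilder(lin_id, "LIN")
        soma_node = builder.add(soma_pos, SOMA_RADIUS_LIN, 1, -1)

        arm_specs = [(center - soma_pos), (soma_pos - center)]
        arm_nodes_all: list[list[int]] = []
        for arm_i, init_vec in enumerate(arm_specs):
            init_dir = init_vec / np.linalg.norm(init_vec)
            path = _wander_path(
                soma_pos, init_dir, extent, rng,
                length_target=float(rng.uniform(115000.0, 150000.0)),
                through=center if arm_i == 0 else None,
            )
            nodes = builder.add_path(soma_node, path, SHAFT_RADIUS, 3, step=SEGMENT_STEP)
            first = _first_path_node(builder, soma_node, nodes)
            lin_truth.append(
                {"cell_id": lin_id, "root_node_id": first, "type": "lin_shaft", "field": None}
            )
            arm_nodes_all.append(_chain_nodes(builder, soma_node, nodes[-1]))

        # shaft synapses, kept clear of the exclusion shell
        for chain in arm_nodes_all:
            acc_in, acc_out = 0.0, 0.0
            prev_p = builder.pos[soma_node - 1]
            for nid in chain:
                p = builder.pos[nid - 1]
                steplen = float(np.linalg.norm(p - prev_p))
                prev_p = p
                acc_in += steplen
                acc_out += steplen
                fld = _field_of_point(p, center, radii, outer, margin=2000.0)
                if fld is None:
                    continue
                if acc_in >= 8000.0:
                    idx = pool.draw_within(fld, p, 4000.0, 1)
                    if len(idx):
                        add_bouton_synapse(int(idx[0]), lin_id, "LIN")
                        acc_in = 0.0
                if acc_out >= 10000.0:
                    tgt = tc_ids[int(rng.integers(len(tc_ids)))]
                    add_synapse(lin_id, tgt, p, "LIN", "TC")
                    acc_out = 0.0

        # targeted neurites: short, synapse-dense, single-field
        sites = _targeted_sites(
            builder, arm_nodes_all, center, radii, outer, config.targeted_neurites_per_lin
        )
        for site_node in sites:
            p0 = builder.pos[site_node - 1]
            fld = _field_of_point(p0, center, radii, outer, margin=3000.0)
            if fld is None:
                continue
            idx = pool.draw_within(fld, p0, min(8000.0, config.targeted_neurite_reach / 2.5), 8)
            if len(idx) < 3:
                continue
            waypoints, budget = [], 1.6 * config.targeted_neurite_reach
            remaining = list(idx)
            cur = p0
            total = 0.0
            while remaining:
                dists = [np.linalg.norm(pool.positions[b] - cur) for b in remaining]
                b = remaining.pop(int(np.argmin(dists)))
                hop = float(np.linalg.norm(pool.positions[b] - cur))
                if total + hop > budget:
                    pool.used[b] = False  # return unreachable bouton to the pool
                    continue
                total += hop
                waypoints.append((b, pool.positions[b]))
                cur = pool.positions[b]
            if len(waypoints) < 3:
                for b, _ in waypoints:
                    pool.used[b] = False
                continue
            nodes = builder.add_path(
                site_node, [wp for _, wp in waypoints], TARGETED_RADIUS, 3, step=2000.0
            )
            first = _first_path_node(builder, site_node, nodes)
            for b, _ in waypoints:
                add_bouton_synapse(int(b), lin_id, "LIN")
            for q, nid in enumerate(nodes):
                if q % 2 == 1:
                    tgt = tc_ids[int(rng.integers(len(tc_ids)))]
                    add_synapse(lin_id, tgt, builder.pos[nid - 1], "LIN", "TC")
            lin_truth.append(
                {"cell_id": lin_id, "root_node_id": first, "type": "lin_targeted", "field": fld}
            )

        # one small output-only axon-like branch off the second arm
        if arm_nodes_all[1]:
            anchor = arm_nodes_all[1][min(3, len(arm_nodes_all[1]) - 1)]
            p0 = builder.pos[anchor - 1]
            adir = rng.normal(size=3)
            adir /= np.linalg.norm(adir)
            nodes = builder.add_path(
                anchor, [p0 + adir * 5000.0, p0 + adir * 10000.0], 250.0, 2, step=2500.0
            )
            first = _first_path_node(builder, anchor, nodes)
            for nid in _chain_nodes(builder, anchor, nodes[-1]):
                tgt = tc_ids[int(rng.integers(len(tc_ids)))]
                add_synapse(lin_id, tgt, builder.pos[nid - 1], "LIN", "TC")
            lin_truth.append(
                {"cell_id": lin_id, "root_node_id": first, "type": "lin_axon_like", "field": None}
            )

        skeletons[lin_id] = builder.build()

    # --- remaining boutons become neuropil-targeted records --------------- #
    for i in np.flatnonzero(~pool.used):
        add_bouton_synapse(int(i), "npl", "other")

    synapses = pd.DataFrame(syn_rows, columns=list(SYNAPSE_COLUMNS))
    bouton_field = {
        bouton_sid[i]: str(pool.fields[i]) for i in sorted(bouton_sid)
    }
    dataset = CircuitDataset(
        skeletons=skeletons,
        synapses=synapses,
        provenance={
            "generator": "islandcircuit.synthetic.generate",
            "seed": int(config.seed),
            "config": config.to_dict(),
            "counting_convention": "one synapse record = one counted retinal input",
        },
    )
    truth = GroundTruth(
        bouton_field=bouton_field,
        tc_capture=tc_capture,
        tc_dendrite_fields={k: [[f, m] for f, m in v] for k, v in tc_dendrite_fields.items()},
        lin_neurites=lin_truth,
        island_center=center.tolist(),
        island_radii=radii.tolist(),
        exclusion_width=w,
        segregation=float(config.segregation),
    )
    return dataset, truth


def _field_of_point(p, center, radii, outer, margin: float) -> str | None:
    """True field of a point with a safety margin around the shell; None
    when the point is in or near the exclusion shell."""
    if _ellipsoid_q(p, center, np.maximum(radii - margin, 1.0))[0] <= 1.0:
        return "island"
    if _ellipsoid_q(p, center, outer + margin)[0] > 1.0:
        return "nonisland"
    return None


def _wander_path(start, init_dir, extent, rng, length_target: float, through=None):
    """Persistent random-walk waypoints, reflected off the volume walls.

    When ``through`` is given the path first heads straight there (the shaft
    must cross the island), then wanders.
    """
    margin = 2500.0
    waypoints = []
    pos = np.asarray(start, dtype=float).copy()
    length = 0.0
    if through is not None:
        through = np.asarray(through, dtype=float)
        length += float(np.linalg.norm(through - pos))
        waypoints.append(through.copy())
        d = through - pos
        pos = through.copy()
        init_dir = d / np.linalg.norm(d)
    direction = np.asarray(init_dir, dtype=float).copy()
    step = SEGMENT_STEP
    while length < length_target:
        direction = direction + 0.22 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        nxt = pos + direction * step
        for a in range(3):
            if nxt[a] < margin:
                nxt[a] = 2 * margin - nxt[a]
                direction[a] = abs(direction[a])
            elif nxt[a] > extent[a] - margin:
                nxt[a] = 2 * (extent[a] - margin) - nxt[a]
                direction[a] = -abs(direction[a])
        length += float(np.linalg.norm(nxt - pos))
        pos = nxt
        waypoints.append(pos.copy())
    return waypoints


def _first_path_node(builder: _SkeletonBuilder, attach: int, waypoint_nodes: list[int]) -> int:
    """First node of the path added after ``attach`` (its direct child)."""
    nid = waypoint_nodes[0]
    while builder.parents[nid - 1] != attach:
        nid = builder.parents[nid - 1]
    return nid


def _chain_nodes(builder: _SkeletonBuilder, attach: int, last: int) -> list[int]:
    """All node ids from just after ``attach`` to ``last``, in path order."""
    chain = []
    nid = last
    while nid != attach and nid != -1:
        chain.append(nid)
        nid = builder.parents[nid - 1]
    return chain[::-1]


def _targeted_sites(builder, arm_nodes_all, center, radii, outer, n_sites: int) -> list[int]:
    """Branch sites on the shaft that sit clearly inside one field, limited
    to the proximal 60% of each arm (keeps the arm the longest path)."""
    candidates = []
    for chain in arm_nodes_all:
        cutoff = int(0.6 * len(chain))
        for nid in chain[2:cutoff]:
            p = builder.pos[nid - 1]
            if _field_of_point(p, center, radii, outer, margin=3000.0) is not None:
                candidates.append(nid)
    if not candidates:
        return []
    stride = max(1, len(candidates) // max(n_sites, 1))
    return candidates[::stride][:n_sites]


# --------------------------------------------------------------------------- #
# degradation harness
# --------------------------------------------------------------------------- #
def degrade(
    dataset: CircuitDataset,
    drop_fraction: float,
    jitter_sd: float,
    seed: int,
) -> CircuitDataset:
    """Robustness harness emulating partial reconstruction: drop synapses
    i.i.d. with ``drop_fraction`` and jitter positions with isotropic
    Gaussian noise of s.d. ``jitter_sd`` (nm).  Skeletons are untouched."""
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    syn = dataset.synapses.copy()
    if drop_fraction > 0:
        keep = rng.random(len(syn)) >= drop_fraction
        syn = syn[keep].reset_index(drop=True)
    if jitter_sd > 0 and len(syn):
        noise = rng.normal(0.0, jitter_sd, size=(len(syn), 3))
        syn[["x_nm", "y_nm", "z_nm"]] = syn[["x_nm", "y_nm", "z_nm"]].to_numpy() + noise
    provenance = dict(dataset.provenance)
    provenance["degraded"] = {
        "drop_fraction": float(drop_fraction),
        "jitter_sd_nm": float(jitter_sd),
        "seed": int(seed),
    }
    return CircuitDataset(
        skeletons=dataset.skeletons,
        synapses=syn,
        scaling=dataset.scaling,
        provenance=provenance,
    )
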