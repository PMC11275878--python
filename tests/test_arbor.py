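"""Zone crossings, LIN neurite taxonomy, field purity."""

import numpy as np
import pandas as pd
import pytest

import islandcircuit as ic
import islandcircuit.capture as cap
from islandcircuit import arbor
from islandcircuit.model import NeuronSkeleton, SYNAPSE_COLUMNS

from conftest import SMALL_GENERATOR


@pytest.fixture(scope="module")
def circuit_with_labeling():
    ds, truth = ic.generate(ic.GeneratorConfig(seed=2))
    ids, pos = ds.rgc_bouton_positions()
    lab = ic.classify_boutons(pos, ids=ids)
    return ds, truth, lab


def _chain(cell_id, cell_class, node_positions, soma_pos, radius=400.0):
    n = len(node_positions)
    return NeuronSkeleton(
        cell_id, cell_class,
        np.arange(1, n + 2),
        np.concatenate([[-1], np.arange(1, n + 1)]),
        np.vstack([[soma_pos], node_positions]),
        np.full(n + 1, radius),
        np.r_[1, np.full(n, 3)],
    )


class TestZoneCrossings:
    def test_island_base_then_nonisland_branch(self, circuit_with_labeling):
        """A single LIN dendrite that picks up 4 island boutons near its base,
        crosses the exclusion zone, then receives 42 non-island inputs —
        counted (4, 42) on the same branch."""
        _, truth, lab = circuit_with_labeling
        c = np.array(truth.island_center)
        r = np.array(truth.island_radii)
        w = truth.exclusion_width
        u = np.array([0.0, 0.0, 1.0])  # smallest island radius: room beyond shell
        node_pos, syn_pos = [c + 0.5 * r * u, c + 0.75 * r * u], []
        for i in range(4):
            p = c + (0.80 + 0.03 * i) * r * u + np.array([500.0 * i, -300.0 * i, 0.0])
            node_pos.append(p)
            syn_pos.append(p)
        z0 = r[2] + w + 5000.0
        for i in range(42):
            p = c + u * (z0 + (i % 3) * 900.0) + np.array(
                [(i % 7 - 3) * 1500.0, ((i // 7) % 6 - 2.5) * 1500.0, 0.0]
            )
            node_pos.append(p)
            syn_pos.append(p)
        sk = _chain("linx", "LIN", node_pos, c - 0.2 * r * u)
        rows = [
            (f"x{i:04d}", f"bx{i:04d}", "linx", p[0], p[1], p[2], "RGC", "LIN")
            for i, p in enumerate(syn_pos)
        ]
        syn = pd.DataFrame(rows, columns=list(SYNAPSE_COLUMNS))
        (prof,) = arbor.zone_crossings(sk, lab, syn)
        assert (prof.n_inputs_island, prof.n_inputs_nonisland) == (4, 42)
        assert prof.n_inputs_ambiguous == 0
        assert prof.crosses_zone
        np.testing.assert_allclose(arbor.field_purity(prof), 42 / 46, atol=1e-12)

    def test_branch_confined_to_island_does_not_cross(self, circuit_with_labeling):
        _, truth, lab = circuit_with_labeling
        c = np.array(truth.island_center)
        r = np.array(truth.island_radii)
        pts = [c + r * 0.3 * np.array([t, 0, 0]) for t in (0.2, 0.5, 0.9)]
        sk = _chain("tcq", "TC", pts, c)
        (prof,) = arbor.zone_crossings(
            sk, lab, pd.DataFrame(columns=list(SYNAPSE_COLUMNS))
        )
        assert not prof.crosses_zone

    def test_skeleton_outside_volume_yields_empty_flagged(self, circuit_with_labeling):
        _, _, lab = circuit_with_labeling
        far = np.array([5e6, 5e6, 5e6])
        sk = _chain("tcf", "TC", [far + [1000 * i, 0, 0] for i in (1, 2)], far)
        with pytest.warns(UserWarning, match="outside"):
            out = arbor.zone_crossings(sk, lab, pd.DataFrame(columns=list(SYNAPSE_COLUMNS)))
        assert out == []

    def test_branch_counts_conserve_profile_totals(self, circuit_with_labeling):
        ds, _, lab = circuit_with_labeling
        for tc_id in ds.cells_of_class("TC"):
            tc = ds.skeletons[tc_id]
            prof = cap.profile_tc(tc, ds.synapses, lab)
            branches = arbor.zone_crossings(tc, lab, ds.synapses)
            sums = (
                sum(b.n_inputs_island for b in branches),
                sum(b.n_inputs_nonisland for b in branches),
                sum(b.n_inputs_ambiguous for b in branches),
            )
            assert sums == (prof.n_island, prof.n_nonisland, prof.n_ambiguous)


class TestLINTaxonomy:
    def test_generated_neurite_types_recovered(self):
        """Shaft / targeted / axon-like recovery on synthetic LINs."""
        match = total = 0
        for seed in (0, 2, 4):
            ds, truth = ic.generate(ic.GeneratorConfig(seed=seed, **SMALL_GENERATOR))
            ids, pos = ds.rgc_bouton_positions()
            lab = ic.classify_boutons(pos, ids=ids)
            pred = {}
            for lin_id in ds.cells_of_class("LIN"):
                for p in arbor.classify_lin_neurites(ds.skeletons[lin_id], ds.synapses, lab):
                    pred[(p.cell_id, p.root_node_id)] = p.neurite_type
            for gt in truth.lin_neurites:
                total += 1
                match += pred.get((gt["cell_id"], gt["root_node_id"])) == gt["type"]
        assert total >= 9
        assert match / total >= 0.95

    def test_shafts_cross_zone_without_shell_synapses(self, circuit_with_labeling):
        ds, _, lab = circuit_with_labeling
        shafts = []
        for lin_id in ds.cells_of_class("LIN"):
            shafts += [
                p
                for p in arbor.classify_lin_neurites(ds.skeletons[lin_id], ds.synapses, lab)
                if p.neurite_type == "lin_shaft"
            ]
        assert shafts
        for p in shafts:
            assert p.crosses_zone
            assert p.n_inputs_ambiguous == 0
            assert p.path_length >= 100_000.0

    def test_targeted_neurites_are_field_specific(self, circuit_with_labeling):
        ds, truth, lab = circuit_with_labeling
        targeted = []
        for lin_id in ds.cells_of_class("LIN"):
            targeted += [
                p
                for p in arbor.classify_lin_neurites(ds.skeletons[lin_id], ds.synapses, lab)
                if p.neurite_type == "lin_targeted"
            ]
        assert targeted
        purities = [arbor.field_purity(p) for p in targeted]
        assert all(pu >= 0.9 for pu in purities)

    def test_increasing_reach_never_converts_targeted_to_shaft(self, circuit_with_labeling):
        ds, _, lab = circuit_with_labeling
        lin_id = ds.cells_of_class("LIN")[0]
        lin = ds.skeletons[lin_id]
        short = arbor.classify_lin_neurites(lin, ds.synapses, lab, targeted_reach=20000.0)
        long = arbor.classify_lin_neurites(lin, ds.synapses, lab, targeted_reach=100000.0)
        for a, b in zip(short, long):
            assert a.root_node_id == b.root_node_id
            if a.neurite_type == "lin_targeted":
                assert b.neurite_type != "lin_shaft"

    def test_non_lin_skeleton_rejected(self, circuit_with_labeling):
        ds, _, lab = circuit_with_labeling
        tc = ds.skeletons[ds.cells_of_class("TC")[0]]
        with pytest.raises(ValueError, match="LIN"):
            arbor.classify_lin_neurites(tc, ds.synapses, lab)


class TestFieldPurity:
    def test_examples(self):
        def prof(i, n, a=0):
            return arbor.NeuriteSegmentProfile(
                "c", 0, 1, 1000.0, 500.0, i, n, a, 0, 0, False, "unclassified"
            )

        assert arbor.field_purity(prof(10, 0)) == 1.0
        assert arbor.field_purity(prof(5, 5)) == 0.5
        assert np.isnan(arbor.field_purity(prof(0, 0, 7)))
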