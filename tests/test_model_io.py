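"""Domain types, SWC and synapse-table readers/writers, round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import islandcircuit as ic
from islandcircuit import io
from islandcircuit.model import (
    PRE_CLASSES,
    POST_CLASSES,
    SYNAPSE_COLUMNS,
    SkeletonStructureError,
    SwcParseError,
    SynapseValidationError,
    validate_synapse_table,
)

CHAIN_SWC = """# CLASS TC
1 1 0 0 0 5.0 -1
2 3 10 20 30 1.0 1
3 3 20 40 60 1.0 2
"""


def _write(tmp_path, text, name="cell1.swc"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSkeleton:
    def test_chain_with_unit_scaling(self, tmp_path):
        sk = io.read_skeleton(_write(tmp_path, CHAIN_SWC))
        assert sk.n_nodes == 3
        assert sk.cell_class == "TC"
        root = sk.root_index
        assert sk.parent_ids[root] == -1 and sk.node_ids[root] == 1
        np.testing.assert_allclose(sk.positions[1], [10, 20, 30])

    def test_anisotropic_voxel_scaling_applies_per_axis(self, tmp_path):
        sk = io.read_skeleton(_write(tmp_path, CHAIN_SWC), scaling=ic.EM_VOXEL_SCALING)
        np.testing.assert_allclose(sk.positions[1], [10 * 26, 20 * 20, 30 * 40])
        np.testing.assert_allclose(sk.positions[2], [20 * 26, 40 * 20, 60 * 40])

    def test_missing_parent_names_offending_node(self, tmp_path):
        bad = "1 1 0 0 0 5 -1\n2 3 1 1 1 1 99\n"
        with pytest.raises(SkeletonStructureError, match="node 2.*parent 99"):
            io.read_skeleton(_write(tmp_path, bad))

    def test_cycle_detected(self, tmp_path):
        bad = "1 1 0 0 0 5 -1\n2 3 1 1 1 1 3\n3 3 2 2 2 1 2\n"
        with pytest.raises(SkeletonStructureError, match="cycl"):
            io.read_skeleton(_write(tmp_path, bad))

    def test_non_numeric_field_reports_line_number(self, tmp_path):
        bad = "1 1 0 0 0 5 -1\n2 3 x 1 1 1 1\n"
        with pytest.raises(SwcParseError, match=":2:"):
            io.read_skeleton(_write(tmp_path, bad))

    def test_two_roots_rejected(self, tmp_path):
        bad = "1 1 0 0 0 5 -1\n2 3 1 1 1 1 -1\n"
        with pytest.raises(SkeletonStructureError, match="root"):
            io.read_skeleton(_write(tmp_path, bad))


class TestSynapseTable:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=list(SYNAPSE_COLUMNS))

    def test_read_two_rows(self, tmp_path):
        p = tmp_path / "syn.csv"
        self._table(
            [
                ("s1", "b1", "tc1", 1.0, 2.0, 3.0, "RGC", "TC"),
                ("s2", "b2", "tc1", 4.0, 5.0, 6.0, "RGC", "TC"),
            ]
        ).to_csv(p, index=False)
        df = io.read_synapse_table(p)
        assert len(df) == 2 and set(df["pre_class"]) == {"RGC"}

    def test_positions_scaled_on_read(self, tmp_path):
        p = tmp_path / "syn.csv"
        self._table([("s1", "b1", "tc1", 1.0, 1.0, 1.0, "RGC", "TC")]).to_csv(p, index=False)
        df = io.read_synapse_table(p, scaling=ic.EM_VOXEL_SCALING)
        np.testing.assert_allclose(df.loc[0, ["x_nm", "y_nm", "z_nm"]].astype(float),
                                   [26.0, 20.0, 40.0])

    def test_unknown_class_token_lists_allowed(self, tmp_path):
        p = tmp_path / "syn.csv"
        self._table([("s1", "b1", "tc1", 0.0, 0.0, 0.0, "axon7", "TC")]).to_csv(p, index=False)
        with pytest.raises(SynapseValidationError, match="axon7") as exc:
            io.read_synapse_table(p)
        for tok in sorted(PRE_CLASSES):
            assert tok in str(exc.value)

    def test_empty_table_with_header_ok(self, tmp_path):
        p = tmp_path / "syn.csv"
        self._table([]).to_csv(p, index=False)
        assert len(io.read_synapse_table(p)) == 0

    def test_self_synapse_rejected(self):
        with pytest.raises(SynapseValidationError, match="pre_cell == post_cell"):
            validate_synapse_table(
                self._table([("s1", "c1", "c1", 0.0, 0.0, 0.0, "RGC", "TC")])
            )

    @given(
        pre=st.sampled_from(sorted(PRE_CLASSES) + ["axonX", "rgc", ""]),
        post=st.sampled_from(sorted(POST_CLASSES) + ["tc", "soma"]),
    )
    def test_validation_accepts_iff_enums_valid(self, pre, post):
        table = self._table([("s1", "a", "b", 0.0, 0.0, 0.0, pre, post)])
        if pre in PRE_CLASSES and post in POST_CLASSES:
            assert len(validate_synapse_table(table)) == 1
        else:
            with pytest.raises(SynapseValidationError):
                validate_synapse_table(table)


class TestDatasetRoundTrip:
    def test_round_trip_preserves_everything(self, small_circuit, tmp_path):
        dataset, _ = small_circuit
        manifest = io.write_dataset(dataset, tmp_path / "ds")
        back = io.read_dataset(tmp_path / "ds")
        assert set(back.skeletons) == set(dataset.skeletons)
        for cid, sk in dataset.skeletons.items():
            sk2 = back.skeletons[cid]
            assert sk2.cell_class == sk.cell_class
            np.testing.assert_allclose(sk2.positions, sk.positions, atol=1e-6)
            np.testing.assert_allclose(sk2.radii, sk.radii, atol=1e-6)
            np.testing.assert_array_equal(sk2.parent_ids, sk.parent_ids)
            np.testing.assert_array_equal(sk2.structure_codes, sk.structure_codes)
        assert list(back.synapses["synapse_id"]) == list(dataset.synapses["synapse_id"])
        np.testing.assert_allclose(
            back.synapses[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
            dataset.synapses[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
            atol=1e-6,
        )
        assert manifest["n_synapses"] == len(dataset.synapses)

    def test_orphan_boutons_flagged_in_manifest(self, small_circuit, tmp_path):
        dataset, _ = small_circuit
        manifest = io.write_dataset(dataset, tmp_path / "ds2")
        # retinal boutons are represented without skeletons -> orphan pre cells
        assert any(c.startswith("b") for c in manifest["orphan_pre_cells"])
        assert "npl" in manifest["orphan_post_cells"]

    def test_missing_manifest_file_raises_with_name(self, small_circuit, tmp_path):
        dataset, _ = small_circuit
        io.write_dataset(dataset, tmp_path / "ds3")
        victim = sorted((tmp_path / "ds3").glob("tc*.swc"))[0]
        victim.unlink()
        with pytest.raises(FileNotFoundError, match=victim.name):
            io.read_dataset(tmp_path / "ds3")


class TestScaling:
    @given(st.integers(0, 10_000))
    def test_scale_unscale_identity(self, seed):
        rng = np.random.default_rng(seed)
        xyz = rng.uniform(-1e6, 1e6, size=(5, 3))
        s = ic.VoxelScaling(tuple(rng.uniform(0.1, 100.0, size=3)))
        np.testing.assert_allclose(s.invert(s.apply(xyz)), xyz, rtol=1e-9)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ic.ConfigurationError):
            ic.VoxelScaling((26.0, 0.0, 40.0))
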