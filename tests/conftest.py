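import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import islandcircuit as ic

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Scaled-down generator conditions for fast unit tests: same geometric
#: regime as the defaults (island density >> field density, shell width
#: >> bouton spacing), smaller volume and counts.
SMALL_GENERATOR = dict(
    volume_extent=(50000.0, 50000.0, 50000.0),
    island_radii=(10000.0, 9000.0, 8000.0),
    exclusion_width=12000.0,
    island_bouton_count=400,
    nonisland_bouton_count=3000,
    boutons_per_tc_range=(5, 30),
    lin_count=1,
)


@pytest.fixture(scope="session")
def small_circuit():
    """One small synthetic circuit shared across read-only tests."""
    return ic.generate(ic.GeneratorConfig(seed=42, **SMALL_GENERATOR))


@pytest.fixture(scope="session")
def small_labeling(small_circuit):
    dataset, _ = small_circuit
    ids, pos = dataset.rgc_bouton_positions()
    return ic.classify_boutons(pos, ids=ids), pos


class StubLabeling:
    """Minimal labeling stand-in keyed by synapse id (synthetic; for unit
    tests that need field labels without running the spatial classifier)."""

    def __init__(self, mapping):
        self.mapping = mapping

    def label_of(self, sid):
        return self.mapping[sid]


@pytest.fixture
def stub_labeling_factory():
    return StubLabeling


def make_chain_skeleton(cell_id="tc_test", cell_class="TC", n_dendrites=2,
                        nodes_per_dendrite=3, step=2000.0):
    """Soma at origin with ``n_dendrites`` straight chains along distinct axes."""
    axes = np.eye(3).tolist() + [[-1, 0, 0], [0, -1, 0], [0, 0, -1]]
    node_ids, parents, pos, radii, codes = [1], [-1], [[0.0, 0.0, 0.0]], [5000.0], [1]
    nid = 1
    for d in range(n_dendrites):
        ax = np.asarray(axes[d % len(axes)], dtype=float)
        parent = 1
        for j in range(1, nodes_per_dendrite + 1):
            nid += 1
            node_ids.append(nid)
            parents.append(parent)
            pos.append((ax * step * j).tolist())
            radii.append(600.0)
            codes.append(3)
            parent = nid
    return ic.NeuronSkeleton(
        cell_id=cell_id, cell_class=cell_class,
        node_ids=np.array(node_ids), parent_ids=np.array(parents),
        positions=np.array(pos), radii=np.array(radii),
        structure_codes=np.array(codes),
    )
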