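"""Per-TC innervation profiles, capture classification, and the
independent-dendrite null model.

The null model: a thalamocortical cell (TC) with ``k`` primary dendrites that
receive retinal input is "captured" when all ``k`` dendrites connect to the
same bouton field.  Under the null hypothesis of no selection, each dendrite
independently picks island or non-island with probability 1/2, so

    P(captured | k) = 2 ** (1 - k)

and the number of captured TCs across cells with dendrite counts
``(k_1, ..., k_n)`` follows a Poisson-binomial distribution with
``p_i = 2 ** (1 - k_i)``.  ``exact_capture_distribution`` computes it by
sequential convolution; ``monte_carlo_null`` samples it the way the
reconstruction was originally compared against its null (100,000 trials,
report the smallest m whose empirical CDF reaches each level).

No significance claim is attached to the comparison: ``compare_observed_to_null``
reports tail probabilities and threshold positions only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MissingSomaError, NeuronSkeleton, NoRGCInputsError

__all__ = [
    "CAPTURE_CLASSES",
    "REFERENCE_DENDRITE_COUNTS",
    "InnervationProfile",
    "NullModelResult",
    "SomaSynapseVector",
    "capture_probability",
    "exact_capture_distribution",
    "exact_capture_mean",
    "monte_carlo_null",
    "empirical_quantile",
    "exact_quantile",
    "compare_observed_to_null",
    "classify_tc",
    "profile_tc",
    "soma_synapse_vector",
    "cumulative_bouton_curve",
    "capture_summary",
]

CAPTURE_CLASSES = ("pure_island", "pure_nonisland", "mixed", "ambiguous_zone", "no_rgc")

#: Primary-dendrite counts of the nine reference TCs whose somata sit in the
#: exclusion zone of the reconstructed albino-dLGN volume.
REFERENCE_DENDRITE_COUNTS = (2, 2, 3, 4, 4, 4, 5, 5, 7)


# --------------------------------------------------------------------------- #
# null model
# --------------------------------------------------------------------------- #
def capture_probability(k: int) -> float:
    """Probability that all ``k`` independent fair binary dendrites agree."""
    if k < 1:
        raise ValueError(f"dendrite count must be >= 1, got {k}")
    return 2.0 ** (1 - int(k))


def exact_capture_distribution(dendrite_counts) -> np.ndarray:
    """Exact Poisson-binomial distribution of the captured-TC count.

    Computed by sequential convolution of per-cell Bernoulli factors
    (O(n^2) in the number of cells; n is at most tens here).  Returns a
    vector over 0..n that sums to 1 within 1e-12.  An empty count list
    yields a distribution concentrated at zero.
    """
    dist = np.array([1.0])
    for k in dendrite_counts:
        p = capture_probability(k)
        dist = np.convolve(dist, [1.0 - p, p])
    return dist


def exact_capture_mean(dendrite_counts) -> float:
    """Closed-form mean of the null capture count: sum of 2**(1 - k_i)."""
    return float(sum(capture_probability(k) for k in dendrite_counts))


def empirical_quantile(histogram: np.ndarray, trials: int, level: float) -> int:
    """Smallest m whose empirical CDF reaches ``level`` ("m or fewer")."""
    cdf = np.cumsum(histogram) / float(trials)
    return int(np.searchsorted(cdf, level))


def exact_quantile(distribution: np.ndarray, level: float) -> int:
    cdf = np.cumsum(distribution)
    return int(np.searchsorted(cdf, min(level, cdf[-1])))


@dataclass
class NullModelResult:
    """Monte Carlo and exact null distributions of the captured-TC count."""

    dendrite_counts: tuple[int, ...]
    trials: int
    seed: int
    captured_count_histogram: np.ndarray
    empirical_quantile_thresholds: dict[float, int]
    exact_distribution: np.ndarray
    exact_mean: float

    @property
    def n_tc(self) -> int:
        return len(self.dendrite_counts)

    @property
    def empirical_distribution(self) -> np.ndarray:
        return self.captured_count_histogram / float(self.trials)

    def to_dict(self) -> dict:
        return {
            "dendrite_counts": list(self.dendrite_counts),
            "trials": int(self.trials),
            "seed": int(self.seed),
            "captured_count_histogram": [int(c) for c in self.captured_count_histogram],
            "empirical_quantile_thresholds": {
                str(level): int(m)
                for level, m in sorted(self.empirical_quantile_thresholds.items())
            },
            "exact_distribution": [float(p) for p in self.exact_distribution],
            "exact_mean": float(self.exact_mean),
        }


def monte_carlo_null(
    dendrite_counts,
    trials: int = 100_000,
    seed: int = 0,
    levels=(0.99,),
) -> NullModelResult:
    """Sample the independent-dendrite null.

    Per trial, every primary dendrite of every cell is assigned island or
    non-island with probability 1/2; a cell is captured when all its
    dendrites share one label.  Deterministic given ``seed``.
    """
    counts = tuple(int(k) for k in dendrite_counts)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    for k in counts:
        if k < 1:
            raise ValueError(f"dendrite count must be >= 1, got {k}")
    rng = np.random.default_rng(seed)
    n_tc = len(counts)
    captured_total = np.zeros(trials, dtype=np.int64)
    for k in counts:
        bits = rng.integers(0, 2, size=(trials, k))
        s = bits.sum(axis=1)
        captured_total += (s == 0) | (s == k)
    histogram = np.bincount(captured_total, minlength=n_tc + 1)
    thresholds = {float(lv): empirical_quantile(histogram, trials, lv) for lv in levels}
    return NullModelResult(
        dendrite_counts=counts,
        trials=trials,
        seed=int(seed),
        captured_count_histogram=histogram,
        empirical_quantile_thresholds=thresholds,
        exact_distribution=exact_capture_distribution(counts),
        exact_mean=exact_capture_mean(counts),
    )


def compare_observed_to_null(observed_captured: int, null: NullModelResult) -> dict:
    """Exceedance report: exact and empirical P(X >= observed).

    Reporting only — the comparison quantifies how far the observed capture
    count sits in the null's tail; it is not framed as a significance test.
    """
    obs = int(observed_captured)
    if not 0 <= obs <= null.n_tc:
        raise ValueError(f"observed count {obs} outside 0..{null.n_tc}")
    exact_tail = float(null.exact_distribution[obs:].sum())
    empirical_tail = float(null.captured_count_histogram[obs:].sum()) / null.trials
    return {
        "observed_captured": obs,
        "n_tc": null.n_tc,
        "exact_tail": exact_tail,
        "empirical_tail": empirical_tail,
        "exact_mean": null.exact_mean,
        "thresholds": {
            str(level): {
                "threshold": int(m),
                "observed_exceeds": bool(obs > m),
                "threshold_fraction_pct": 100.0 * m / null.n_tc,
            }
            for level, m in sorted(null.empirical_quantile_thresholds.items())
        },
    }


# --------------------------------------------------------------------------- #
# per-TC profiling
# --------------------------------------------------------------------------- #
def classify_tc(
    n_island: int,
    n_nonisland: int,
    n_ambiguous: int,
    ambiguous_fraction: float = 0.5,
) -> str:
    """Capture class from field-wise retinal input counts.

    ``no_rgc`` for zero inputs; ``ambiguous_zone`` when more than
    ``ambiguous_fraction`` of inputs (or all field-assignable inputs) are
    ambiguous; ``pure_island`` / ``pure_nonisland`` when exactly one field is
    represented; ``mixed`` otherwise.  Exhaustive and mutually exclusive over
    non-negative count triples.
    """
    if min(n_island, n_nonisland, n_ambiguous) < 0:
        raise ValueError("counts must be non-negative")
    total = n_island + n_nonisland + n_ambiguous
    if total == 0:
        return "no_rgc"
    if n_island == 0 and n_nonisland == 0:
        return "ambiguous_zone"
    if n_ambiguous / total > ambiguous_fraction:
        return "ambiguous_zone"
    if n_island > 0 and n_nonisland == 0:
        return "pure_island"
    if n_nonisland > 0 and n_island == 0:
        return "pure_nonisland"
    return "mixed"


@dataclass
class InnervationProfile:
    """Field-wise retinal input counts of one TC and its capture class."""

    tc_id: str
    n_island: int
    n_nonisland: int
    n_ambiguous: int
    primary_dendrite_count: int
    capture_class: str
    attachment_distances_nm: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_total_rgc(self) -> int:
        return self.n_island + self.n_nonisland + self.n_ambiguous

    @property
    def is_captured(self) -> bool:
        return self.capture_class in ("pure_island", "pure_nonisland")

    def to_dict(self) -> dict:
        return {
            "tc_id": self.tc_id,
            "n_island": int(self.n_island),
            "n_nonisland": int(self.n_nonisland),
            "n_ambiguous": int(self.n_ambiguous),
            "n_total_rgc": int(self.n_total_rgc),
            "primary_dendrite_count": int(self.primary_dendrite_count),
            "capture_class": self.capture_class,
        }


def profile_tc(
    tc: NeuronSkeleton,
    synapses: pd.DataFrame,
    labeling,
    ambiguous_fraction: float = 0.5,
    attachment_tolerance_nm: float = 500.0,
) -> InnervationProfile:
    """Count a TC's retinal inputs by bouton field and find how many primary
    dendrites carry retinal input.

    ``labeling`` is a :class:`~islandcircuit.fields.BoutonFieldLabeling`; the
    field of each input is looked up by synapse id.  A primary dendrite counts
    as innervated when any node of its soma-adjacent subtree is the nearest
    attachment point of a retinal synapse.  Inputs farther than
    ``attachment_tolerance_nm`` from every node raise a warning but are still
    counted — partial reconstructions are expected.
    """
    rows = synapses[(synapses["post_cell"] == tc.cell_id) & (synapses["pre_class"] == "RGC")]
    if len(rows) == 0:
        return InnervationProfile(tc.cell_id, 0, 0, 0, 0, "no_rgc")
    labels = [labeling.label_of(sid) for sid in rows["synapse_id"]]
    n_island = sum(1 for lb in labels if lb == "island")
    n_non = sum(1 for lb in labels if lb == "nonisland")
    n_amb = sum(1 for lb in labels if lb == "ambiguous")

    positions = rows[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    node_idx, dist = tc.nearest_node(positions, exclude_soma=True)
    too_far = dist > attachment_tolerance_nm
    if np.any(too_far):
        warnings.warn(
            f"{tc.cell_id}: {int(too_far.sum())} retinal synapse(s) farther than "
            f"{attachment_tolerance_nm:.0f} nm from any node (max "
            f"{dist.max():.0f} nm); counted anyway",
            stacklevel=2,
        )
    subtree_of_node = np.full(tc.n_nodes, -1, dtype=int)
    for b, sub in enumerate(tc.primary_subtrees()):
        subtree_of_node[sub] = b
    innervated = {int(subtree_of_node[i]) for i in node_idx if subtree_of_node[i] >= 0}
    return InnervationProfile(
        tc_id=tc.cell_id,
        n_island=n_island,
        n_nonisland=n_non,
        n_ambiguous=n_amb,
        primary_dendrite_count=len(innervated),
        capture_class=classify_tc(n_island, n_non, n_amb, ambiguous_fraction),
        attachment_distances_nm=dist,
    )


# --------------------------------------------------------------------------- #
# soma-to-synapse arbor asymmetry
# --------------------------------------------------------------------------- #
@dataclass
class SomaSynapseVector:
    """Offset between a TC's soma and the centroid of its retinal inputs.

    ``signed_offset_along_island_normal`` projects the offset onto the
    outward normal of the island boundary nearest the soma; positive values
    point away from the island.
    """

    tc_id: str
    soma_position: np.ndarray
    mean_synapse_position: np.ndarray
    offset: np.ndarray
    offset_norm: float
    signed_offset_along_island_normal: float | None = None

    def to_dict(self) -> dict:
        return {
            "tc_id": self.tc_id,
            "soma_position": [float(v) for v in self.soma_position],
            "mean_synapse_position": [float(v) for v in self.mean_synapse_position],
            "offset": [float(v) for v in self.offset],
            "offset_norm": float(self.offset_norm),
            "signed_offset_along_island_normal": (
                None
                if self.signed_offset_along_island_normal is None
                else float(self.signed_offset_along_island_normal)
            ),
        }


def soma_synapse_vector(
    tc: NeuronSkeleton,
    rgc_positions: np.ndarray,
    island_centroid: np.ndarray | None = None,
) -> SomaSynapseVector:
    """Soma-to-mean-synapse offset for one TC.

    The soma position is the centroid of its soma nodes.  When
    ``island_centroid`` is given, the offset is also projected onto the
    outward island-boundary normal nearest the soma, approximated as the
    direction from the island centroid to the soma (adequate for convex-ish
    islands); positive = away from the island.
    """
    pts = np.atleast_2d(np.asarray(rgc_positions, dtype=float))
    if pts.size == 0:
        raise NoRGCInputsError(f"{tc.cell_id}: no retinal inputs")
    soma = tc.soma_centroid()  # raises MissingSomaError separately
    mean_pos = pts.mean(axis=0)
    offset = mean_pos - soma
    signed = None
    if island_centroid is not None:
        normal = soma - np.asarray(island_centroid, dtype=float)
        nn = np.linalg.norm(normal)
        if nn > 0:
            signed = float(np.dot(offset, normal / nn))
    return SomaSynapseVector(
        tc_id=tc.cell_id,
        soma_position=soma,
        mean_synapse_position=mean_pos,
        offset=offset,
        offset_norm=float(np.linalg.norm(offset)),
        signed_offset_along_island_normal=signed,
    )


# --------------------------------------------------------------------------- #
# cohort summaries
# --------------------------------------------------------------------------- #
def cumulative_bouton_curve(profiles) -> pd.DataFrame:
    """Per-TC retinal bouton counts sorted ascending, with the running
    cumulative total (the cumulative innervation curve)."""
    rows = sorted(
        ((p.n_total_rgc, p.tc_id, p.capture_class) for p in profiles),
        key=lambda r: (r[0], r[1]),
    )
    counts = [r[0] for r in rows]
    return pd.DataFrame(
        {
            "tc_id": [r[1] for r in rows],
            "n_rgc_boutons": counts,
            "capture_class": [r[2] for r in rows],
            "cumulative_boutons": np.cumsum(counts),
        }
    )


def capture_summary(profiles) -> dict:
    """Cohort-level capture statistics over a list of profiles.

    Eligible cells are those with at least one retinal input; the capture
    fraction is captured / eligible.
    """
    by_class = {c: 0 for c in CAPTURE_CLASSES}
    for p in profiles:
        by_class[p.capture_class] += 1
    eligible = [p for p in profiles if p.capture_class != "no_rgc"]
    captured = [p for p in eligible if p.is_captured]
    return {
        "n_tc": len(list(profiles)),
        "n_eligible": len(eligible),
        "n_captured": len(captured),
        "capture_fraction": (len(captured) / len(eligible)) if eligible else float("nan"),
        "class_counts": by_class,
        "dendrite_counts": sorted(
            p.primary_dendrite_count for p in eligible if p.primary_dendrite_count >= 1
        ),
    }
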