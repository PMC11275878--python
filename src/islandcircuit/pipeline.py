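"""One-command orchestration: generate/load -> classify -> capture -> neurites.

``run_pipeline`` executes the full segregation analysis and writes a report
bundle (``summary.json`` + CSV tables + a resolved-config copy + run log)
into the output directory.  Outputs are deterministic for a given config and
seed; figures are produced separately by :func:`make_figures`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import arbor, capture as cap, fields, io, synthetic
from .model import CircuitDataset, ConfigurationError

__all__ = ["RunConfig", "PipelineResult", "PipelineError", "run_pipeline",
           "make_figures", "validate_summary", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"
logger = logging.getLogger("islandcircuit")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Exactly one of ``generator`` (a :class:`GeneratorConfig` dict) or
    ``dataset_dir`` must be set.  ``seed`` drives both the generator and the
    Monte Carlo null.
    """

    out_dir: str
    generator: dict | None = None
    dataset_dir: str | None = None
    seed: int = 0
    bandwidth: float | None = None
    level_fraction: float = 0.1
    angular_resolution: float = 3.0
    n_rays: int = 300
    trials: int = 100_000
    levels: tuple[float, ...] = (0.99,)
    ambiguous_fraction: float = 0.5
    targeted_reach: float = 20000.0
    shaft_min_length: float = 100000.0
    density_threshold: float = 0.0002
    save_labeling: bool = False

    def validate(self) -> None:
        if (self.generator is None) == (self.dataset_dir is None):
            raise ConfigurationError("set exactly one of 'generator' or 'dataset_dir'")
        if self.dataset_dir is not None and not Path(self.dataset_dir).is_dir():
            raise ConfigurationError(f"dataset_dir does not exist: {self.dataset_dir}")
        if not 0.0 < self.level_fraction < 1.0:
            raise ConfigurationError("level_fraction must be in (0, 1)")
        if self.trials < 1:
            raise ConfigurationError("trials must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "levels" in d:
            d["levels"] = tuple(d["levels"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run computed."""

    config: RunConfig
    dataset: CircuitDataset
    ground_truth: synthetic.GroundTruth | None
    labeling: fields.BoutonFieldLabeling
    projection: fields.SeparationProjection | None
    gap: fields.GapStatistics | None
    tc_profiles: list
    null: cap.NullModelResult | None
    exceedance: dict | None
    soma_vectors: list
    neurite_profiles: list
    summary: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                logger.error("stage %s: FAILED: %s", name, exc)
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s: done (%.2f s)", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("load")
def _load(config: RunConfig):
    if config.generator is not None:
        gen_cfg = dict(config.generator)
        gen_cfg["seed"] = config.seed
        dataset, truth = synthetic.generate(synthetic.GeneratorConfig.from_dict(gen_cfg))
        return dataset, truth
    return io.read_dataset(config.dataset_dir), None


@_stage("classify")
def _classify(config: RunConfig, dataset: CircuitDataset):
    ids, pos = dataset.rgc_bouton_positions()
    return fields.classify_boutons(
        pos, bandwidth=config.bandwidth, level_fraction=config.level_fraction, ids=ids
    ), pos


@_stage("project")
def _project(config: RunConfig, labeling, pos):
    return fields.find_separation_projection(
        labeling, pos, angular_resolution=config.angular_resolution
    )

@_stage("gap")
def _gap(config: RunConfig, labeling, pos):
    return fields.measure_exclusion_zone(labeling, pos, n_rays=config.n_rays)


@_stage("capture")
def _capture(config: RunConfig, dataset, labeling):
    profiles = []
    vectors = []
    island_centroid = labeling._island_centroid
    for tc_id in dataset.cells_of_class("TC"):
        tc = dataset.skeletons[tc_id]
        prof = cap.profile_tc(
            tc, dataset.synapses, labeling, ambiguous_fraction=config.ambiguous_fraction
        )
        profiles.append(prof)
        if prof.n_total_rgc > 0:
            rows = dataset.synapses[
                (dataset.synapses["post_cell"] == tc_id)
                & (dataset.synapses["pre_class"] == "RGC")
            ]
            vectors.append(
                cap.soma_synapse_vector(
                    tc,
                    rows[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float),
                    island_centroid=island_centroid,
                )
            )
    summary = cap.capture_summary(profiles)
    null = None
    exceedance = None
    if summary["dendrite_counts"]:
        null = cap.monte_carlo_null(
            summary["dendrite_counts"],
            trials=config.trials,
            seed=config.seed,
            levels=config.levels,
        )
        exceedance = cap.compare_observed_to_null(summary["n_captured"], null)
    return profiles, vectors, summary, null, exceedance


@_stage("neurites")
def _neurites(config: RunConfig, dataset, labeling):
    profiles = []
    for tc_id in dataset.cells_of_class("TC"):
        profiles.extend(arbor.zone_crossings(dataset.skeletons[tc_id], labeling, dataset.synapses))
    for lin_id in dataset.cells_of_class("LIN"):
        profiles.extend(
            arbor.classify_lin_neurites(
                dataset.skeletons[lin_id],
                dataset.synapses,
                labeling,
                targeted_reach=config.targeted_reach,
                shaft_min_length=config.shaft_min_length,
                density_threshold=config.density_threshold,
            )
        )
    return profiles


def _ground_truth_eval(labeling, truth: synthetic.GroundTruth, tc_profiles) -> dict:
    agree = 0
    total = 0
    for sid, true_field in truth.bouton_field.items():
        total += 1
        if labeling.label_of(sid) == true_field:
            agree += 1
    capture_match = sum(
        1 for p in tc_profiles if truth.tc_capture.get(p.tc_id) == p.capture_class
    )
    return {
        "bouton_label_accuracy": agree / total if total else float("nan"),
        "n_boutons_evaluated": total,
        "tc_capture_agreement": capture_match / max(len(tc_profiles), 1),
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        dataset, truth = _load(config)
        labeling, pos = _classify(config, dataset)
        projection = None
        gap = None
        if not labeling.no_split:
            projection = _project(config, labeling, pos)
            gap = _gap(config, labeling, pos)
        else:
            logger.warning("single bouton component (no-split); skipping projection/gap")
        tc_profiles, vectors, cap_summary, null, exceedance = _capture(
            config, dataset, labeling
        )
        neurites = _neurites(config, dataset, labeling)

        curve = cap.cumulative_bouton_curve(tc_profiles)
        purities = [arbor.field_purity(p) for p in neurites
                    if p.neurite_type == "lin_targeted"]
        purities = [p for p in purities if not np.isnan(p)]
        summary = {
            "schema_version": SCHEMA_VERSION,
            "seed": int(config.seed),
            "provenance": dataset.provenance,
            "bouton_counts": labeling.counts | {"no_split": labeling.no_split},
            "gap": gap.to_dict() if gap else None,
            "projection": projection.to_dict() if projection else None,
            "capture": {
                **cap_summary,
                "null": null.to_dict() if null else None,
                "exceedance": exceedance,
            },
            "tc_profiles": [p.to_dict() for p in tc_profiles],
            "soma_vectors": [v.to_dict() for v in vectors],
            "neurites": {
                "type_counts": {
                    t: sum(1 for p in neurites if p.neurite_type == t)
                    for t in arbor.NEURITE_TYPES
                },
                "n_crossing_zone": sum(1 for p in neurites if p.crosses_zone),
                "targeted_field_purity_mean": float(np.mean(purities)) if purities else None,
            },
        }
        if truth is not None:
            summary["ground_truth_eval"] = _ground_truth_eval(labeling, truth, tc_profiles)
        validate_summary(summary)

        with open(out_dir / "resolved_config.json", "w", encoding="utf-8") as fh:
            json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        pd.DataFrame([p.to_dict() for p in tc_profiles]).to_csv(
            out_dir / "tc_profiles.csv", index=False
        )
        pd.DataFrame([p.to_dict() for p in neurites]).to_csv(
            out_dir / "neurite_profiles.csv", index=False
        )
        curve.to_csv(out_dir / "cumulative_boutons.csv", index=False)
        if truth is not None:
            truth.to_json(out_dir / "ground_truth.json")
        if config.save_labeling:
            labeling.to_json(out_dir / "labeling.json")
        return PipelineResult(
            config=config,
            dataset=dataset,
            ground_truth=truth,
            labeling=labeling,
            projection=projection,
            gap=gap,
            tc_profiles=tc_profiles,
            null=null,
            exceedance=exceedance,
            soma_vectors=vectors,
            neurite_profiles=neurites,
            summary=summary,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


# --------------------------------------------------------------------------- #
# schema
# --------------------------------------------------------------------------- #
def _load_schema() -> dict:
    with resources.files("islandcircuit").joinpath("summary.schema.json").open() as fh:
        return json.load(fh)


def validate_summary(summary: dict) -> None:
    """Check the summary against the shipped schema (required keys/types)."""
    schema = _load_schema()
    if summary.get("schema_version") != schema["schema_version"]:
        raise ValueError(
            f"summary schema_version {summary.get('schema_version')!r} != "
            f"{schema['schema_version']!r}"
        )
    type_map = {"str": str, "int": int, "dict": dict, "list": list}
    for key, spec in schema["required"].items():
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
        expected = type_map[spec["type"]]
        if summary[key] is None and spec.get("nullable"):
            continue
        if not isinstance(summary[key], expected):
            raise ValueError(
                f"summary key {key!r} has type {type(summary[key]).__name__}, "
                f"expected {spec['type']}"
            )


# --------------------------------------------------------------------------- #
# figures
# --------------------------------------------------------------------------- #
def make_figures(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Emit the four standard figures from a completed run.

    (a) best-projection two-color bouton scatter, (b) cumulative bouton-count
    curve, (c) null histogram with observed marker and level threshold,
    (d) soma-to-mean-synapse vectors.  Missing sections are skipped with a
    warning rather than failing.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    colors = {"island": "#2ca02c", "nonisland": "#d62a9d", "ambiguous": "#9a9a9a"}

    _, pos = result.dataset.rgc_bouton_positions()
    labels = result.labeling.labels

    if result.projection is not None:
        fig, ax = plt.subplots(figsize=(5, 5))
        xy = result.projection.project(pos)
        for lb in ("nonisland", "island", "ambiguous"):
            m = labels == lb
            if m.any():
                ax.scatter(xy[m, 0] / 1000, xy[m, 1] / 1000, s=3, c=colors[lb], label=lb)
        ax.set_xlabel("separation axis (um)")
        ax.set_ylabel("orthogonal axis (um)")
        ax.set_title(f"margin = {result.projection.margin / 1000:.1f} um")
        ax.legend(markerscale=3, fontsize=8)
        p = out_dir / "projection_scatter.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("no projection available; skipping projection figure")

    curve = cap.cumulative_bouton_curve(result.tc_profiles)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(range(1, len(curve) + 1), curve["cumulative_boutons"], where="mid")
    for i, row in curve.iterrows():
        col = {"pure_island": colors["island"], "pure_nonisland": colors["nonisland"]}.get(
            row["capture_class"], "#555555"
        )
        ax.plot(i + 1, row["cumulative_boutons"], "o", color=col, ms=5)
    ax.set_xlabel("TC (sorted by input count)")
    ax.set_ylabel("cumulative RGC boutons")
    p = out_dir / "cumulative_boutons.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    if result.null is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        n_tc = result.null.n_tc
        xs = np.arange(n_tc + 1)
        ax.bar(xs, result.null.empirical_distribution, color="#7799bb",
               label=f"null ({result.null.trials:,} trials)")
        for level, m in result.null.empirical_quantile_thresholds.items():
            ax.axvline(m + 0.5, color="red", ls="--", lw=1,
                       label=f"{level:.0%} threshold ({m})")
        obs = result.exceedance["observed_captured"] if result.exceedance else None
        if obs is not None:
            ax.axvline(obs, color="black", lw=2, label=f"observed ({obs})")
        ax.set_xlim(-0.5, n_tc + 0.5)
        ax.set_xlabel("captured TCs")
        ax.set_ylabel("probability")
        ax.legend(fontsize=8)
        p = out_dir / "null_histogram.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("no null model available; skipping null histogram")

    if result.soma_vectors:
        fig, ax = plt.subplots(figsize=(5, 5))
        R = (result.projection.rotation if result.projection is not None
             else np.eye(3))
        for v in result.soma_vectors:
            s = (R @ v.soma_position)[:2] / 1000
            m = (R @ v.mean_synapse_position)[:2] / 1000
            ax.plot(*s, "o", color="#1f77b4", ms=6)
            ax.plot(*m, "o", color="black", ms=4)
            ax.annotate("", xy=m, xytext=s,
                        arrowprops=dict(arrowstyle="->", lw=0.8))
        ax.set_xlabel("axis 1 (um)")
        ax.set_ylabel("axis 2 (um)")
        ax.set_title("soma (blue) to mean RGC input (black)")
        p = out_dir / "soma_vectors.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("no soma vectors available; skipping vector figure")
    return written
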