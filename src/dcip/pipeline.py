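"""End-to-end orchestration: simulate (or load) -> segment -> quantify ->
score -> compare, driven by one experiment-design config.

A design names its treatments (each either a simulation spec or a list of
stack files mapped to plant/FOV), exactly one control treatment, an optional
reference treatment for normalization, and the replicate structure
(plants x fields of view).  Runs are reproducible: the RNG substream of every
simulated stack is keyed by (master seed, treatment index, plant, fov), and
all output files are deterministic functions of the design.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dcip import io_formats
from dcip.quantify import measure_nuclei
from dcip.scoring import ScoreResult, score_experiment
from dcip.segmentation import SegmentationParams, segment_chloroplasts, segment_nuclei
from dcip.simulate import SimulationConfig, generate_leaf_stack
from dcip.stats import dunn_pairwise, kruskal_wallis

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """The experiment design failed validation."""


@dataclass
class TreatmentSpec:
    """One treatment arm: either simulated (positive_fraction + overrides)
    or a list of stack entries ``{path, plant, fov}``."""

    label: str
    positive_fraction: float = 0.0
    sim_overrides: dict = field(default_factory=dict)
    stacks: list[dict] | None = None


@dataclass
class ExperimentDesign:
    experiment: str
    treatments: list[TreatmentSpec]
    control: str
    reference: str | None = None
    n_plants: int = 3
    n_fov: int = 2
    simulation: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    threshold_level: float = 0.99
    threshold_mode: str = "distribution"
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "ExperimentDesign":
        cfg = dict(cfg)
        treatments = [
            TreatmentSpec(**t) if isinstance(t, dict) else t
            for t in cfg.pop("treatments", [])
        ]
        return cls(treatments=treatments, **cfg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        return cls.from_dict(io_formats.load_config(path))


def validate_design(design: ExperimentDesign) -> list[str]:
    """Return every violation found in the design (empty list = valid)."""
    errors: list[str] = []
    labels = [t.label for t in design.treatments]
    if not labels:
        errors.append("design has no treatments")
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        errors.append(f"duplicate treatment labels: {sorted(dupes)}")
    if design.control not in labels:
        errors.append(f"control treatment {design.control!r} is not among treatments {labels}")
    if design.reference is not None and design.reference not in labels:
        errors.append(f"reference treatment {design.reference!r} is not among treatments {labels}")
    if design.n_plants < 1:
        errors.append("n_plants must be >= 1")
    if design.n_fov < 1:
        errors.append("n_fov must be >= 1")
    if not 0.0 < design.threshold_level < 1.0:
        errors.append("threshold_level must be in (0, 1)")
    if design.threshold_mode not in ("distribution", "sem"):
        errors.append("threshold_mode must be 'distribution' or 'sem'")
    for t in design.treatments:
        if not 0.0 <= t.positive_fraction <= 1.0:
            errors.append(f"treatment {t.label!r}: positive_fraction must be in [0, 1]")
        if t.stacks is not None:
            seen = set()
            for entry in t.stacks:
                if "path" not in entry:
                    errors.append(f"treatment {t.label!r}: stack entry missing 'path'")
                    continue
                if not Path(entry["path"]).exists():
                    errors.append(f"treatment {t.label!r}: stack file not found: {entry['path']}")
                key = (entry.get("plant"), entry.get("fov"))
                if key in seen:
                    errors.append(
                        f"treatment {t.label!r}: duplicate (plant, fov) mapping {key}"
                    )
                seen.add(key)
    try:
        SimulationConfig(**design.simulation)
    except (TypeError, ValueError) as exc:
        errors.append(f"simulation config invalid: {exc}")
    try:
        SegmentationParams(**design.segmentation)
    except (TypeError, ValueError) as exc:
        errors.append(f"segmentation config invalid: {exc}")
    return errors


@dataclass
class PipelineResult:
    measurements: pd.DataFrame
    score: ScoreResult
    stats: pd.DataFrame
    outputs: dict[str, Path]


def _measure_one(stack, seg_params, stack_id):
    labels = segment_nuclei(stack, seg_params)
    mask = segment_chloroplasts(stack, seg_params)
    return measure_nuclei(labels, stack, mask, stack_id=stack_id)


def run_pipeline(design: ExperimentDesign, outdir: str | Path) -> PipelineResult:
    """Run the full analysis for one experiment design and write the result
    bundle (measurements.csv, summary.csv, stats.csv, threshold.json) into
    ``outdir``.  Stage failures abort with the stage name and offending input.
    """
    errors = validate_design(design)
    if errors:
        raise DesignError("; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seg_params = SegmentationParams(**design.segmentation)
    base_cfg = SimulationConfig(**design.simulation)
    master_seed = design.seed % 2**31

    frames = []
    for ti, treatment in enumerate(design.treatments):
        if treatment.stacks is not None:
            for entry in treatment.stacks:
                path = entry["path"]
                stack_id = f"{treatment.label}_p{entry.get('plant', 0)}_f{entry.get('fov', 0)}"
                try:
                    stack = io_formats.read_stack(path)
                    df = _measure_one(stack, seg_params, stack_id)
                except Exception as exc:
                    raise RuntimeError(f"stage segment/quantify failed on {path}: {exc}") from exc
                df["treatment"] = treatment.label
                df["plant"] = entry.get("plant", 0)
                df["fov"] = entry.get("fov", 0)
                frames.append(df)
            continue
        cfg = dataclasses.replace(
            base_cfg, positive_fraction=treatment.positive_fraction, **treatment.sim_overrides
        )
        for plant in range(design.n_plants):
            for fov in range(design.n_fov):
                rng = np.random.default_rng([master_seed, ti, plant, fov])
                stack_id = f"{treatment.label}_p{plant}_f{fov}"
                try:
                    stack, _ = generate_leaf_stack(cfg, rng=rng)
                    df = _measure_one(stack, seg_params, stack_id)
                except Exception as exc:
                    raise RuntimeError(
                        f"stage simulate/segment/quantify failed on {stack_id}: {exc}"
                    ) from exc
                df["treatment"] = treatment.label
                df["plant"] = plant
                df["fov"] = fov
                frames.append(df)

    measurements = pd.concat(frames, ignore_index=True)
    measurements = measurements[list(io_formats.MEASUREMENT_COLUMNS)]

    try:
        score = score_experiment(
            measurements,
            control=design.control,
            reference=design.reference,
            level=design.threshold_level,
            mode=design.threshold_mode,
        )
    except Exception as exc:
        raise RuntimeError(f"stage score failed: {exc}") from exc

    stats_df = _group_comparisons(score.summary, design.control)

    outputs = {
        "measurements": io_formats.write_measurements(measurements, outdir / "measurements.csv"),
        "summary": outdir / "summary.csv",
        "stats": outdir / "stats.csv",
        "threshold": outdir / "threshold.json",
    }
    score.summary.to_csv(outputs["summary"], index=False, float_format="%.17g")
    stats_df.to_csv(outputs["stats"], index=False, float_format="%.17g")
    outputs["threshold"].write_text(
        json.dumps(score.threshold.to_dict(), indent=2, sort_keys=True)
    )
    logger.info(
        "pipeline %s: %d nuclei, %d summary rows, threshold=%.6g",
        design.experiment, len(measurements), len(score.summary), score.threshold.threshold,
    )
    return PipelineResult(measurements, score, stats_df, outputs)


def _group_comparisons(summary: pd.DataFrame, control: str) -> pd.DataFrame:
    """Omnibus Kruskal-Wallis on per-plant percent positive, then Dunn's
    pairwise tests; returns a tidy (test, group1, group2, statistic, pvalue)
    table.  Skipped (empty table) when fewer than 2 treatments have data."""
    groups = {
        t: grp["percent_positive"].dropna().to_numpy()
        for t, grp in summary.groupby("treatment", sort=True)
    }
    groups = {t: v for t, v in groups.items() if v.size > 0}
    cols = ["test", "group1", "group2", "statistic", "pvalue"]
    if len(groups) < 2 or sum(v.size for v in groups.values()) < 3:
        return pd.DataFrame(columns=cols)
    kw = kruskal_wallis(groups)
    rows = [("kruskal-wallis", "all", "all", kw.statistic, kw.pvalue)]
    dunn = dunn_pairwise(groups)
    for _, r in dunn.iterrows():
        rows.append(("dunn", r["group1"], r["group2"], r["z"], r["pvalue"]))
    return pd.DataFrame(rows, columns=cols)
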