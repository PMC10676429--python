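"""End-to-end analysis pipeline: ingest/simulate -> GPA -> PCA -> reports.

Every artifact is plain CSV / JSON / fcsv so a run directory can be
inspected, diffed and re-read with the package's own readers.  A run is
idempotent: the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contribution import (axis_variance_decomposition, render_contribution_report,
                           weighted_landmark_magnitudes)
from .gpa import align_to_reference, gpa
from .io import Dataset, read_dataset, read_flat_csv, write_fcsv, write_flat_csv
from .io import LandmarkConfiguration
from .morphospace import (fit_pca, group_occupancy, nearest_to_mean,
                          shape_at_pc, species_means)
from .scheme import default_scheme
from .synthetic import (default_fauna_spec, default_template, generate,
                        write_fixtures)

logger = logging.getLogger("fishmorph")

INPUT_MODES = ("fcsv-manifest", "flat-csv", "simulate")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input mode is used: an fcsv manifest, a flat coordinate
    CSV, or the synthetic fauna generator.  ``K`` fixes the number of
    retained components; when ``None`` the smallest K reaching
    ``retention_threshold`` cumulative variance is used.
    """

    input_mode: str = "simulate"
    input_path: str | None = None
    output_dir: str = "fishmorph_run"
    seed: int = 0
    gpa_tolerance: float = 1e-8
    gpa_max_iterations: int = 100
    project_to_tangent: bool = False
    K: int | None = None
    retention_threshold: float = 0.95
    hull_pc_pair: tuple[int, int] = (1, 2)
    table_decimals: int = 3
    percent_decimals: int = 2
    simulate_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}, "
                             f"got {self.input_mode!r}")
        if self.input_mode != "simulate" and not self.input_path:
            raise ValueError(f"input_mode {self.input_mode!r} requires input_path")
        if not 0 < self.retention_threshold <= 1:
            raise ValueError("retention_threshold must be in (0, 1]")
        if self.gpa_tolerance <= 0 or self.gpa_max_iterations < 1:
            raise ValueError("invalid GPA settings")
        self.hull_pc_pair = tuple(self.hull_pc_pair)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_dataset(config: PipelineConfig, run_dir: Path) -> Dataset:
    if config.input_mode == "simulate":
        spec = default_fauna_spec(seed=config.seed, **config.simulate_overrides)
        dataset, truth = generate(spec)
        write_fixtures(dataset, truth, run_dir / "simulated_input")
        return dataset
    if config.input_mode == "fcsv-manifest":
        return read_dataset(config.input_path)
    return read_flat_csv(config.input_path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and write artifacts into the run directory.

    Artifacts: ``aligned.csv`` (flat Procrustes coordinates),
    ``consensus.fcsv``, ``convergence.json``, ``scores.csv`` and
    ``species_scores.csv``, ``eigen.csv`` (eigenvalues and variance
    fractions), ``contribution_table.csv``, ``axis_decomposition.json``,
    ``hulls.json``, PC endpoint shapes, and ``run_log.json`` recording
    versions, seed and parameters.
    """
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    scheme = default_scheme()

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("ingest")
        dataset = _load_dataset(config, run_dir)

        stage("align")
        alignment = gpa(dataset, tolerance=config.gpa_tolerance,
                        max_iterations=config.gpa_max_iterations,
                        project_to_tangent=config.project_to_tangent)
        if config.input_mode == "simulate":
            # nuisance rotations leave the GPA frame arbitrary; re-anchor to
            # the template so the anatomical axes stay interpretable
            alignment = align_to_reference(alignment, default_template(scheme))
    except Exception as err:
        raise RuntimeError(f"pipeline failed in ingest/align: {err}") from err

    aligned_ds = Dataset(scheme, [
        LandmarkConfiguration(sid, coords, scheme, species=sp, group=grp)
        for sid, sp, grp, coords in zip(alignment.specimen_ids, alignment.species,
                                        alignment.groups, alignment.aligned)
    ])
    write_flat_csv(aligned_ds, run_dir / "aligned.csv")
    consensus_config = LandmarkConfiguration("consensus", alignment.consensus,
                                             scheme, species="consensus")
    write_fcsv(consensus_config, run_dir / "consensus.fcsv")
    with open(run_dir / "convergence.json", "w") as fh:
        json.dump({"iterations": alignment.iterations,
                   "final_change": alignment.final_change,
                   "tolerance": alignment.tolerance,
                   "max_iterations": alignment.max_iterations,
                   "objective_history": alignment.objective_history}, fh, indent=2)

    stage("pca")
    model = fit_pca(alignment, retention_threshold=config.retention_threshold)
    K = config.K or model.K_retained

    scores = pd.DataFrame(model.scores[:, :K],
                          columns=[f"PC{k}" for k in range(1, K + 1)])
    scores.insert(0, "group", model.groups)
    scores.insert(0, "species", model.species)
    scores.insert(0, "specimen_id", model.specimen_ids)
    scores.to_csv(run_dir / "scores.csv", index=False, float_format="%.10g")

    summaries = species_means(model)
    sp_scores = pd.DataFrame([s.mean_scores[:K] for s in summaries],
                             columns=[f"PC{k}" for k in range(1, K + 1)])
    sp_scores.insert(0, "n_specimens", [s.n_specimens for s in summaries])
    sp_scores.insert(0, "group", [s.group for s in summaries])
    sp_scores.insert(0, "species", [s.species for s in summaries])
    sp_scores.to_csv(run_dir / "species_scores.csv", index=False,
                     float_format="%.10g")

    eigen = pd.DataFrame({
        "PC": np.arange(1, model.n_components + 1),
        "eigenvalue": model.eigenvalues,
        "variance_fraction": model.variance_fractions,
        "cumulative_fraction": np.cumsum(model.variance_fractions),
    })
    eigen.to_csv(run_dir / "eigen.csv", index=False, float_format="%.10g")

    for k in range(1, min(K, 3) + 1):
        for sign, tag in ((-2.0, "neg"), (2.0, "pos")):
            endpoint = shape_at_pc(model, k, sd_units=sign)
            write_fcsv(LandmarkConfiguration(f"PC{k}_{tag}", endpoint, scheme),
                       run_dir / f"pc{k}_{tag}2sd.fcsv")

    stage("contributions")
    table = weighted_landmark_magnitudes(model, scheme, K=K)
    decomposition = axis_variance_decomposition(alignment, scheme)
    render_contribution_report(table, decomposition, run_dir)

    stage("occupancy")
    occupancy = group_occupancy(model, pc_pair=config.hull_pc_pair)
    hulls = {
        group: {"area": info["area"], "n_species": info["n_species"],
                "hull": np.asarray(info["hull"]).tolist()}
        for group, info in occupancy.items()
    }
    with open(run_dir / "hulls.json", "w") as fh:
        json.dump({"pc_pair": list(config.hull_pc_pair), "groups": hulls},
                  fh, indent=2)

    stage("report")
    log = {
        "fishmorph_version": __version__,
        "seed": config.seed,
        "input_mode": config.input_mode,
        "input_path": config.input_path,
        "n_specimens": alignment.n_specimens,
        "n_landmarks": alignment.n_landmarks,
        "gpa": {"tolerance": config.gpa_tolerance,
                "max_iterations": config.gpa_max_iterations,
                "iterations": alignment.iterations,
                "final_change": alignment.final_change,
                "tangent_projected": config.project_to_tangent},
        "K": K,
        "retention_threshold": config.retention_threshold,
        "variance_fractions": model.variance_fractions[:K].tolist(),
        "axis_percentages": decomposition.as_percentages(),
        "nearest_to_mean_species": nearest_to_mean(model, level="species"),
    }
    with open(run_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return run_dir
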