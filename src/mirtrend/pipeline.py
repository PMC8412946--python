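"""End-to-end pipeline runner with a validated YAML configuration.

A run executes optional simulation, optional locus assembly, the screen, and
report writing, and leaves a machine-readable manifest (inputs, config hash,
seed, version) next to the outputs so results can be reproduced bit for bit
from the same config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, io
from .errors import MirtrendError, ValidationError
from .loci import annotate_loci, assemble_loci
from .screen import ScreenConfig, calls_to_frame, run_screen
from .synthetic import default_screen_spec, generate_trajectory_matrix

log = logging.getLogger(__name__)


class ScreenSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tolerance: float = 0.10
    coverage_cutoff: float = 6.0
    min_changing_steps: int = 1
    pseudocount: float = 0.0
    rank_by: str = "expression_at_first_timepoint"
    use_column_sums: bool = False


class QpcrSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ct_cutoff: float = 36.0
    housekeeping: list[str] = Field(default_factory=lambda: ["U6"])
    control_group: str = "young"


class SimulateSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    n_down: int = 30
    step_fold: float = 0.85
    noise_model: str = "none"
    noise_sigma: float = 0.0
    nb_dispersion: float = 0.0


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    screen: ScreenSettings = Field(default_factory=ScreenSettings)
    qpcr: QpcrSettings = Field(default_factory=QpcrSettings)
    simulate: SimulateSettings = Field(default_factory=SimulateSettings)
    matrix: str | None = None
    reads: str | None = None
    annotation: str | None = None
    out_dir: str = "mirtrend_out"
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    screen_cfg = ScreenConfig(
        tolerance=config.screen.tolerance,
        coverage_cutoff=config.screen.coverage_cutoff,
        min_changing_steps=config.screen.min_changing_steps,
        pseudocount=config.screen.pseudocount,
        rank_by=config.screen.rank_by,
    )
    log.info("effective screen parameters: tolerance=%g coverage_cutoff=%g "
             "pseudocount=%g; qPCR Ct cutoff=%g",
             screen_cfg.tolerance, screen_cfg.coverage_cutoff,
             screen_cfg.pseudocount, config.qpcr.ct_cutoff)

    inputs: dict[str, str] = {}
    try:
        if config.simulate.enabled:
            spec = default_screen_spec(
                n_down=config.simulate.n_down,
                step_fold=config.simulate.step_fold,
                noise_model=config.simulate.noise_model,
                noise_sigma=config.simulate.noise_sigma,
                nb_dispersion=config.simulate.nb_dispersion,
                seed=config.seed,
            )
            matrix, truth = generate_trajectory_matrix(spec)
            io.write_expression_tsv(matrix, out_dir / "simulated_matrix.tsv")
            io.write_tsv(truth.to_frame(), out_dir / "simulated_truth.tsv")
            inputs["matrix"] = "simulated"
        elif config.reads is not None:
            if config.annotation is None:
                raise ValidationError("reads input requires an annotation file")
            reads = io.read_bed(config.reads)
            loci = assemble_loci(reads)
            ann = (io.read_annotation_gff3(config.annotation)
                   if str(config.annotation).endswith((".gff", ".gff3"))
                   else io.read_annotation_bed(config.annotation))
            annotated = annotate_loci(loci, ann)
            io.write_loci_bed(annotated, out_dir / "loci.bed")
            raise MirtrendError(
                "stage 'screen': a single read set gives one timepoint; supply a "
                "matrix (or simulate) for the longitudinal screen")
        elif config.matrix is not None:
            matrix = io.read_expression_tsv(config.matrix)
            inputs["matrix"] = str(config.matrix)
        else:
            raise ValidationError("config must set simulate.enabled, reads, or matrix")

        result = run_screen(matrix, screen_cfg,
                            use_column_sums=config.screen.use_column_sums)
    except MirtrendError as exc:
        raise MirtrendError(f"stage 'screen' failed: {exc}") from exc

    io.write_tsv(calls_to_frame(result.calls), out_dir / "trend_calls.tsv")
    io.write_tsv(result.candidates, out_dir / "candidates.tsv")
    io.write_tsv(result.log2_ratios, out_dir / "log2_ratios.tsv")
    io.write_tsv(pd.DataFrame(result.filter_log, columns=["feature", "reason"]),
                 out_dir / "filter_log.tsv")

    manifest = {
        "package": "mirtrend",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.model_dump(),
        "inputs": inputs,
        "outputs": ["trend_calls.tsv", "candidates.tsv", "log2_ratios.tsv",
                    "filter_log.tsv"],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir
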