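"""End-to-end pipeline: load → medium → curation edits → screen → reports.

The pipeline is the library's orchestration layer; the ``gea`` command-line
tool is a thin wrapper over :func:`run_pipeline`. Reports are a
machine-readable JSON summary plus tab-separated gene/pair tables, with
pinned ordering and float formatting so identical configurations produce
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import curation, screen as screen_mod
from .fba import SolverConfig
from .model import MetabolicModel, model_to_dict, read_model
from .synthetic import build_polyamine_minimodel

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("polygea")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run. Exactly one model source."""

    model_path: str | None = None
    fixture: str | None = None  # "polyamine" or "polyamine-corrected"
    biomass_spec_path: str | None = None
    add_polyamines: bool = False
    polyamine_coefficient: float = curation.DEFAULT_POLYAMINE_COEFFICIENT
    threshold: float = screen_mod.DEFAULT_THRESHOLD
    solver: SolverConfig = field(default_factory=SolverConfig)
    mode: str = "single"  # single | double | differential
    correct_pnp: bool = False
    xdh: bool = False
    candidates: tuple[str, ...] | None = None
    output_dir: str = "gea_out"

    def __post_init__(self):
        if (self.model_path is None) == (self.fixture is None):
            raise PipelineError("config", "exactly one model source required")
        if self.threshold <= 0:
            raise PipelineError("config", "threshold must be positive")
        if self.mode not in ("single", "double", "differential"):
            raise PipelineError("config", f"unknown mode {self.mode!r}")


def _load_model(config: RunConfig) -> MetabolicModel:
    if config.fixture is not None:
        if config.fixture not in ("polyamine", "polyamine-corrected"):
            raise PipelineError("load", f"unknown fixture {config.fixture!r}")
        return build_polyamine_minimodel(
            corrected_pnp=config.fixture == "polyamine-corrected",
            include_polyamines_in_biomass=False,
        )
    return read_model(config.model_path)


def _model_checksum(model: MetabolicModel) -> str:
    blob = json.dumps(model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _json_dump(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; write reports to the output directory.

    Returns the summary dictionary that was written to ``summary.json``.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    changelog: dict[str, object] = {}

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                stages[stage] = time.perf_counter() - self.t0
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(stage, str(exc)) from exc

        return _T()

    with timed("load"):
        model = _load_model(config)
        model.validate()
    log.info("model %s: checksum %s", model.id, _model_checksum(model))

    with timed("curation"):
        if config.add_polyamines:
            model = curation.augment_biomass(
                model, curation.polyamine_biomass_spec(config.polyamine_coefficient)
            )
            changelog["biomass_polyamines"] = config.polyamine_coefficient
        if config.biomass_spec_path:
            spec_data = json.loads(Path(config.biomass_spec_path).read_text())
            model = curation.augment_biomass(model, curation.BiomassSpec(spec_data))
            changelog["biomass_spec"] = spec_data
        if config.correct_pnp:
            model, removed = curation.correct_pnp_annotation(model)
            changelog["pnp_removed_reactions"] = removed
        if config.xdh:
            model = curation.add_xdh_branch(model, enabled=True)
            changelog["xdh_branch"] = True
    log.info(
        "curated model checksum %s, threshold %g, backend %s",
        _model_checksum(model), config.threshold, config.solver.backend,
    )

    with timed("screen"):
        if config.mode == "single":
            result = screen_mod.single_deletion_screen(
                model, config.threshold, config.solver
            )
        elif config.mode == "double":
            result = screen_mod.double_deletion_screen(
                model, config.threshold, config.solver, candidates=config.candidates
            )
        else:  # differential: unamended vs polyamine-amended biomass
            base_model = _load_model(config)
            if config.correct_pnp:
                base_model, _ = curation.correct_pnp_annotation(base_model)
            base = screen_mod.double_deletion_screen(
                base_model, config.threshold, config.solver
            )
            result = screen_mod.double_deletion_screen(
                model, config.threshold, config.solver
            )
            diff = screen_mod.differential_essentials(base, result)
            changelog["differential"] = {
                "gained_essential": sorted(diff.gained_essential),
                "gained_synthetic_lethal": [
                    list(p) for p in sorted(diff.gained_synthetic_lethal)
                ],
            }

    with timed("report"):
        summary = screen_mod.screen_summary(result)
        summary["model_id"] = model.id
        summary["model_checksum"] = _model_checksum(model)
        summary["solver_backend"] = config.solver.backend
        summary["changelog"] = changelog
        _json_dump(summary, out / "summary.json")
        screen_mod.write_gene_report(result, out / "genes.tsv")
        if result.pair_growth:
            screen_mod.write_pair_report(result, out / "pairs.tsv")

    for stage, dt in stages.items():
        log.info("stage %-8s %.3f s", stage, dt)
    return summary
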