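"""End-to-end pipeline: QC -> calibrate/score -> compare -> report.

A run is described by a :class:`RunConfig` (constructed in code, from a
YAML config file, or by the CLI).  Two input modes exist: a named synthetic
preset (the cohort, controls and calibration sets are simulated from the
run seed) or user files (expression matrix, annotations, control
annotation and a directory of serialized pathway models).  Every output is
TSV; a manifest lists each artifact with its SHA-256 hash so reruns can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from .genesets import example_pathway_definitions, read_gmt, read_probe_map
from .io import read_expression_matrix, write_annotations, write_pas_matrix
from .model import PathwayActivityModel, calibrate_model, score_matrix
from .qc import QCThresholds, apply_qc, qc_matrix, read_control_annotation
from .simulate import (CalibrationSpec, control_annotation, preset_scenario,
                       simulate_calibration, simulate_cohort)
from .stats import build_significance_table, compare_pas_groups, comparisons_to_frame

logger = logging.getLogger(__name__)

# stage-named exit codes
EXIT_CONFIG = 2
EXIT_QC = 3
EXIT_MODEL = 4
EXIT_STATS = 5


class StageError(RuntimeError):
    def __init__(self, stage: str, exit_code: int, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class RunConfig:
    """Configuration of one pipeline run (flags override file values)."""

    out_dir: str = "stpscore_run"
    seed: int = 0
    # preset mode
    preset: str | None = None
    n_per_group: int = 20
    effect_size: float = 1.0
    noise_sd: float = 0.5
    calibration_n_per_class: int = 100
    # file mode
    matrix_path: str | None = None
    annotation_path: str | None = None
    controls_path: str | None = None
    gene_sets_path: str | None = None
    probe_map_path: str | None = None
    models_dir: str | None = None
    # model parameters
    pseudocount: float = 1.0
    prior_active: float = 0.5
    # statistics
    test: str = "auto"
    adjust: str = "none"
    contrasts: list[list[str]] = field(default_factory=list)
    # QC
    max_fraction_negative: float = 0.0
    max_fraction_saturated: float = 0.01
    max_degradation_slope: float | None = None
    skip_qc: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise StageError("config", EXIT_CONFIG,
                             f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            max_fraction_negative=self.max_fraction_negative,
            max_fraction_saturated=self.max_fraction_saturated,
            max_degradation_slope=self.max_degradation_slope,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _default_contrasts(preset: str) -> list[tuple[str, str, str, str]]:
    """(name, label_a, label_b, group_column) per preset."""
    if preset == "diagnosis":
        return [(f"{g}_vs_healthy", g, "healthy", "group")
                for g in ("CDc", "CDi", "UC")]
    if preset == "anti_tnf_response":
        return [("pre_responder_vs_nonresponder",
                 "responder_pre", "nonresponder_pre", "group"),
                ("post_responder_vs_nonresponder",
                 "responder_post", "nonresponder_post", "group")]
    return [("A_vs_B", "A", "B", "group")]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the pipeline; returns a mapping of artifact name -> path.

    Deterministic given config and seed: rerunning writes byte-identical
    artifacts.  Raises :class:`StageError` (with a stage-named exit code)
    on failure; no partial outputs are left for configuration errors.
    """
    # ---- configuration / inputs ---------------------------------------
    if config.preset is None and config.matrix_path is None:
        raise StageError("config", EXIT_CONFIG,
                         "either preset or matrix_path is required")
    for name in ("matrix_path", "annotation_path", "controls_path",
                 "gene_sets_path", "probe_map_path", "models_dir"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            raise StageError("config", EXIT_CONFIG, f"{name} {value!r} not found")

    models: list[PathwayActivityModel] | None = None
    if config.preset is not None:
        scenario = preset_scenario(config.preset, n_per_group=config.n_per_group,
                                   effect_size=config.effect_size,
                                   noise_sd=config.noise_sd, seed=config.seed)
        definitions = (read_gmt(config.gene_sets_path)
                       if config.gene_sets_path else example_pathway_definitions())
        if config.probe_map_path:
            pm = read_probe_map(config.probe_map_path)
            definitions = [d.with_probe_map(pm) for d in definitions]
        expression, annotations, truth = simulate_cohort(scenario, definitions)
        controls = control_annotation()
        contrasts = (config.contrasts
                     and [(f"{a}_vs_{b}", a, b, "group") for a, b in
                          ((c[0], c[1]) for c in config.contrasts)]
                     or _default_contrasts(config.preset))
    else:
        if config.annotation_path is None:
            raise StageError("config", EXIT_CONFIG,
                             "annotation_path required with matrix_path")
        if config.models_dir is None:
            raise StageError("config", EXIT_CONFIG,
                             "models_dir (calibrated models) required with matrix_path")
        expression, annotations = read_expression_matrix(
            config.matrix_path, config.annotation_path)
        controls = (read_control_annotation(config.controls_path)
                    if config.controls_path else None)
        model_files = sorted(Path(config.models_dir).glob("*.model.tsv"))
        if not model_files:
            raise StageError("config", EXIT_CONFIG,
                             f"no *.model.tsv files in {config.models_dir}")
        models = [PathwayActivityModel.load(p) for p in model_files]
        if not config.contrasts:
            raise StageError("config", EXIT_CONFIG,
                             "contrasts required in file mode")
        contrasts = [(f"{a}_vs_{b}", a, b, "group") for a, b in
                     ((c[0], c[1]) for c in config.contrasts)]

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # ---- QC -------------------------------------------------------------
    try:
        if config.skip_qc:
            filtered, removed = expression, []
        else:
            report = qc_matrix(expression, controls, config.qc_thresholds())
            filtered, removed, annotations = apply_qc(expression, report, annotations)
            artifacts["qc_report"] = out_dir / "qc_report.tsv"
            report.to_tsv(artifacts["qc_report"])
        if filtered.shape[1] == 0:
            raise StageError("qc", EXIT_QC, "every sample failed QC")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("qc", EXIT_QC, str(exc)) from exc

    # ---- calibrate / score ---------------------------------------------
    try:
        if models is None:
            models = []
            for i, definition in enumerate(definitions):
                spec = CalibrationSpec(
                    definition=definition,
                    cpt={g: (0.9, 0.1) for g in definition.target_genes},
                    level_low=scenario.baseline,
                    level_high=scenario.baseline + max(scenario.effect_size, 0.5),
                    noise_sd=scenario.noise_sd,
                )
                calib = simulate_calibration(spec, config.calibration_n_per_class,
                                             seed=config.seed + 10_000 + i)
                models.append(calibrate_model(
                    definition, calib.expression, calib.labels,
                    pseudocount=config.pseudocount,
                    prior_active=config.prior_active))
            models_dir = out_dir / "models"
            models_dir.mkdir(exist_ok=True)
            for model in models:
                safe = model.definition.name.replace("/", "-")
                path = models_dir / f"{safe}.model.tsv"
                model.save(path)
                artifacts[f"model_{safe}"] = path
        pas = score_matrix(models, filtered)
        artifacts["pas_matrix"] = out_dir / "pas_matrix.tsv"
        write_pas_matrix(pas, artifacts["pas_matrix"])
        artifacts["annotations"] = out_dir / "annotations.tsv"
        write_annotations(annotations, artifacts["annotations"])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("model", EXIT_MODEL, str(exc)) from exc

    # ---- compare / report ----------------------------------------------
    try:
        comparison_sets = {}
        frames = []
        for name, label_a, label_b, column in contrasts:
            comps = compare_pas_groups(pas, annotations, (label_a, label_b),
                                       test=config.test, group_column=column,
                                       adjust=config.adjust)
            comparison_sets[name] = comps
            frame = comparisons_to_frame(comps)
            frame.insert(0, "contrast", name)
            frames.append(frame)
        artifacts["comparisons"] = out_dir / "comparisons.tsv"
        pd.concat(frames, ignore_index=True).to_csv(
            artifacts["comparisons"], sep="\t", index=False, float_format="%.6g")
        table = build_significance_table(comparison_sets)
        artifacts["significance_table"] = out_dir / "significance_table.tsv"
        table.to_tsv(artifacts["significance_table"])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("stats", EXIT_STATS, str(exc)) from exc

    # ---- manifest -------------------------------------------------------
    manifest = out_dir / "manifest.tsv"
    with manifest.open("w") as handle:
        handle.write(f"stpscore_version\t{__version__}\n")
        handle.write(f"seed\t{config.seed}\n")
        for f in fields(config):
            handle.write(f"config.{f.name}\t{getattr(config, f.name)}\n")
        if removed:
            handle.write(f"qc_removed_samples\t{','.join(removed)}\n")
        for name in sorted(artifacts):
            path = artifacts[name]
            handle.write(f"file\t{path.name}\t{_sha256(path)}\n")
    artifacts["manifest"] = manifest
    return artifacts
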