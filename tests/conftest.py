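import numpy as np
import pytest

from stpscore import (CalibrationSpec, PathwayActivityModel, PathwayDefinition,
                      calibrate_model, example_pathway_definitions,
                      simulate_calibration)


@pytest.fixture(scope="session")
def definitions():
    return example_pathway_definitions()


@pytest.fixture
def two_gene_model():
    """Symmetric two-gene model: prior 0.5, both genes (0.8, 0.2)."""
    d = PathwayDefinition("X", ("G1", "G2"),
                          probe_map={"G1": ("G1_at",), "G2": ("G2_at",)})
    return PathwayActivityModel.from_parameters(
        d, {"G1": (0.8, 0.2), "G2": (0.8, 0.2)},
        thresholds={"G1_at": 7.0, "G2_at": 7.0})


@pytest.fixture
def random_model_factory():
    """Seeded factory for random models (and optional random evidence)."""

    def make(rng: np.random.Generator, n_genes: int, prior: float | None = None):
        genes = tuple(f"G{i}" for i in range(n_genes))
        d = PathwayDefinition("R", genes,
                              probe_map={g: (f"{g}_at",) for g in genes})
        cpt = {g: (float(rng.uniform(0.05, 0.95)), float(rng.uniform(0.05, 0.95)))
               for g in genes}
        prior = float(rng.uniform(0.1, 0.9)) if prior is None else prior
        return PathwayActivityModel.from_parameters(d, cpt, prior_active=prior)

    return make


def random_evidence(rng: np.random.Generator, model) -> dict:
    return {g: rng.choice(["high", "low", "missing"])
            for g in model.definition.target_genes}


def fit_default_models(definitions, seed: int, n_per_class: int = 100,
                       effect_size: float = 1.0, noise_sd: float = 0.5,
                       baseline: float = 7.0):
    """Calibrate one model per pathway on simulated calibration cohorts."""
    models = []
    for i, d in enumerate(definitions):
        spec = CalibrationSpec(d, {g: (0.9, 0.1) for g in d.target_genes},
                               level_low=baseline,
                               level_high=baseline + effect_size,
                               noise_sd=noise_sd)
        calib = simulate_calibration(spec, n_per_class, seed=seed + i)
        models.append(calibrate_model(d, calib.expression, calib.labels))
    return models
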