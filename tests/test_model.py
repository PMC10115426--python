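import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stpscore import (PathwayActivityModel, PathwayDefinition, calibrate_model,
                      discretize_expression, enumerate_posterior_oracle,
                      score_matrix, score_sample)
from tests.conftest import random_evidence


def _simple_def(*genes):
    return PathwayDefinition("P", tuple(genes),
                             probe_map={g: (f"{g}_at",) for g in genes})


# ---------------------------------------------------------------------------
# scoring closed forms

def test_uninformative_model_scores_zero(two_gene_model):
    d = two_gene_model.definition
    m = PathwayActivityModel.from_parameters(
        d, {g: (0.6, 0.6) for g in d.target_genes})
    for ev in ({"G1": "high", "G2": "high"}, {"G1": "low", "G2": "high"}, {}):
        assert score_sample(m, ev) == pytest.approx(0.0, abs=1e-12)


def test_two_symmetric_genes_both_high_scores_four(two_gene_model):
    ev = {"G1": "high", "G2": "high"}
    # independent enumeration oracle first, then the model against it
    assert enumerate_posterior_oracle(two_gene_model, ev) == pytest.approx(4.0, abs=1e-12)
    assert score_sample(two_gene_model, ev) == pytest.approx(4.0, abs=1e-12)


def test_symmetric_genes_one_high_one_low_cancel(two_gene_model):
    assert score_sample(two_gene_model, {"G1": "high", "G2": "low"}) == \
        pytest.approx(0.0, abs=1e-12)


def test_single_gene_closed_form():
    m = PathwayActivityModel.from_parameters(
        _simple_def("G"), {"G": (0.7, 0.3)}, prior_active=0.4)
    expected = math.log2(0.4 / 0.6) + math.log2(0.7 / 0.3)
    assert score_sample(m, {"G": "high"}) == pytest.approx(expected, abs=1e-12)
    assert enumerate_posterior_oracle(m, {"G": "high"}) == \
        pytest.approx(expected, abs=1e-12)


def test_missing_gene_contributes_nothing(two_gene_model):
    assert score_sample(two_gene_model, {"G1": "high"}) == \
        score_sample(two_gene_model, {"G1": "high", "G2": "missing"}) == \
        pytest.approx(2.0)


def test_invalid_evidence_state_and_foreign_gene_error(two_gene_model):
    with pytest.raises(ValueError, match="invalid evidence state"):
        score_sample(two_gene_model, {"G1": "banana"})
    with pytest.raises(ValueError, match="non-target"):
        score_sample(two_gene_model, {"OTHER": "high"})


# ---------------------------------------------------------------------------
# oracle equivalence and structural properties

def test_oracle_matches_scorer_on_random_models(random_model_factory):
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(100):
        m = random_model_factory(rng, int(rng.integers(1, 7)))
        ev = random_evidence(rng, m)
        worst = max(worst, abs(score_sample(m, ev)
                               - enumerate_posterior_oracle(m, ev)))
    assert worst <= 1e-9


def test_oracle_refuses_large_models():
    genes = tuple(f"G{i}" for i in range(13))
    m = PathwayActivityModel.from_parameters(
        PathwayDefinition("big", genes), {g: (0.6, 0.4) for g in genes})
    with pytest.raises(ValueError, match="12"):
        enumerate_posterior_oracle(m, {})


@settings(derandomize=True, max_examples=40, deadline=None)
@given(p_active=st.floats(0.05, 0.95), p_inactive=st.floats(0.05, 0.95),
       prior=st.floats(0.05, 0.95))
def test_flipping_informative_gene_low_to_high_raises_pas(p_active, p_inactive, prior):
    """With p_high_active > p_high_inactive, high evidence must score above low."""
    if p_active <= p_inactive:
        p_active, p_inactive = max(p_active, p_inactive + 1e-3), p_inactive
    if p_active >= 1:
        p_active = 0.999
    m = PathwayActivityModel.from_parameters(
        _simple_def("A", "B"), {"A": (p_active, p_inactive), "B": (0.7, 0.2)},
        prior_active=prior)
    low = score_sample(m, {"A": "low", "B": "high"})
    high = score_sample(m, {"A": "high", "B": "high"})
    assert high > low


def test_neutral_gene_never_changes_pas(random_model_factory):
    rng = np.random.default_rng(7)
    base = random_model_factory(rng, 3, prior=0.3)
    genes = base.definition.target_genes + ("NEUTRAL",)
    cpt = {g: tuple(base.cpt_.loc[g]) for g in base.definition.target_genes}
    cpt["NEUTRAL"] = (0.42, 0.42)
    extended = PathwayActivityModel.from_parameters(
        PathwayDefinition("R", genes), cpt, prior_active=0.3)
    for _ in range(20):
        ev = random_evidence(rng, base)
        for state in ("high", "low", "missing"):
            assert score_sample(extended, {**ev, "NEUTRAL": state}) == \
                pytest.approx(score_sample(base, ev), abs=1e-12)


def test_prior_shift_moves_every_pas_by_log_odds(random_model_factory):
    rng = np.random.default_rng(11)
    base = random_model_factory(rng, 4, prior=0.5)
    for p in (0.2, 0.5, 0.9):
        shifted = PathwayActivityModel.from_parameters(
            base.definition, base.cpt_, prior_active=p)
        for _ in range(10):
            ev = random_evidence(rng, base)
            assert score_sample(shifted, ev) - score_sample(base, ev) == \
                pytest.approx(math.log2(p / (1 - p)), abs=1e-10)


# ---------------------------------------------------------------------------
# discretization

def test_discretize_thresholds_and_tie_rule():
    d = _simple_def("A", "B", "C")  # C has no probe on this platform
    X = pd.DataFrame({"A_at": [8.1, 6.9, 7.0], "B_at": [5.0, 9.0, 7.0]},
                     index=["s1", "s2", "s3"])
    ev = discretize_expression(X, d, {"A_at": 7.0, "B_at": 7.0})
    assert ev.loc["s1", "A"] == "high" and ev.loc["s2", "A"] == "low"
    assert ev.loc["s3", "A"] == "high"  # tie goes high
    assert (ev["C"] == "missing").all()


def test_discretize_aggregates_probes_by_mean():
    d = PathwayDefinition("P", ("A",), probe_map={"A": ("p1", "p2")})
    X = pd.DataFrame({"p1": [6.0, 8.0], "p2": [8.1, 5.0]}, index=["s1", "s2"])
    ev = discretize_expression(X, d, {"p1": 7.0, "p2": 7.0})
    assert ev.loc["s1", "A"] == "high"   # mean 7.05 >= 7.0
    assert ev.loc["s2", "A"] == "low"    # mean 6.5


def test_no_probe_for_any_gene_is_an_error():
    d = _simple_def("A")
    X = pd.DataFrame({"other": [1.0]}, index=["s1"])
    with pytest.raises(ValueError, match="no target gene"):
        discretize_expression(X, d, {"other": 0.0})


# ---------------------------------------------------------------------------
# calibration

def _calibration_fixture():
    """15 samples on one gene: 8/10 active high (at 10), all others at 0."""
    d = _simple_def("G")
    values = [10.0] * 8 + [0.0] * 2 + [0.0] * 5
    samples = [f"s{i}" for i in range(15)]
    expr = pd.DataFrame({s: {"G_at": v} for s, v in zip(samples, values)})
    labels = pd.Series(["active"] * 10 + ["inactive"] * 5, index=samples)
    return d, expr, labels


def test_laplace_smoothing_arithmetic():
    d, expr, labels = _calibration_fixture()
    m = calibrate_model(d, expr, labels, pseudocount=1.0)
    assert m.thresholds_["G_at"] == 10.0  # pooled median (8th of 15 sorted)
    assert m.cpt_.loc["G", "p_high_active"] == pytest.approx(9 / 12)
    assert m.cpt_.loc["G", "p_high_inactive"] == pytest.approx(1 / 7)


def test_label_swap_swaps_cpt_exactly():
    d, expr, labels = _calibration_fixture()
    swapped = labels.map({"active": "inactive", "inactive": "active"})
    m = calibrate_model(d, expr, labels)
    m2 = calibrate_model(d, expr, swapped)
    assert m2.cpt_.loc["G", "p_high_active"] == m.cpt_.loc["G", "p_high_inactive"]
    assert m2.cpt_.loc["G", "p_high_inactive"] == m.cpt_.loc["G", "p_high_active"]


def test_calibration_validation_errors():
    d, expr, labels = _calibration_fixture()
    with pytest.raises(ValueError, match="per class"):
        calibrate_model(d, expr, pd.Series("active", index=labels.index))
    with pytest.raises(ValueError, match="alpha"):
        calibrate_model(d, expr, labels, pseudocount=0.0)
    with pytest.raises(ValueError, match="not in the matrix"):
        calibrate_model(d, expr, pd.Series({"ghost": "active"}))
    fitted = calibrate_model(d, expr, labels)
    probs = fitted.cpt_.to_numpy()
    assert np.all((probs > 0) & (probs < 1))


# ---------------------------------------------------------------------------
# matrix scoring

def test_score_matrix_shape_order_and_permutation(two_gene_model, random_model_factory):
    rng = np.random.default_rng(3)
    other = random_model_factory(rng, 3)
    probes = sorted({p for m in (two_gene_model, other)
                     for ps in m.definition.probe_map.values() for p in ps})
    samples = ["s1", "s2", "s3"]
    expr = pd.DataFrame(rng.normal(7, 1, (len(probes), 3)),
                        index=probes, columns=samples)
    # both models share pathway-name uniqueness requirement
    other_named = type(other).from_parameters(
        PathwayDefinition("Y", other.definition.target_genes,
                          probe_map=other.definition.probe_map),
        other.cpt_, other.thresholds_, other.prior_active_)
    pas = score_matrix([two_gene_model, other_named], expr)
    assert pas.shape == (2, 3)
    assert list(pas.columns) == samples
    shuffled = score_matrix([two_gene_model, other_named],
                            expr[["s3", "s1", "s2"]])
    pd.testing.assert_frame_equal(pas[["s3", "s1", "s2"]], shuffled)


def test_matrix_at_calibration_medians_scores_all_high(definitions):
    """Values equal to the thresholds discretize high (tie rule), so the PAS
    equals the all-high score given by the enumeration oracle."""
    from tests.conftest import fit_default_models
    models = fit_default_models(definitions[:2], seed=5)
    for m in models:
        probes = list(m.thresholds_.index)
        expr = pd.DataFrame({"s": m.thresholds_.values}, index=probes)
        pas = score_matrix([m], expr)
        all_high = {g: "high" for g in m.definition.target_genes}
        assert pas.iloc[0, 0] == pytest.approx(
            enumerate_posterior_oracle(m, all_high), abs=1e-9)


# ---------------------------------------------------------------------------
# serialization

def test_text_serialization_round_trip(tmp_path, random_model_factory):
    rng = np.random.default_rng(9)
    m = random_model_factory(rng, 4, prior=0.35)
    path = tmp_path / "m.model.tsv"
    m.save(path)
    loaded = PathwayActivityModel.load(path)
    pd.testing.assert_frame_equal(loaded.cpt_, m.cpt_)
    assert loaded.prior_active_ == m.prior_active_
    assert loaded.definition == m.definition
    ev = random_evidence(rng, m)
    assert score_sample(loaded, ev) == score_sample(m, ev)


def test_unsupported_format_version_rejected():
    with pytest.raises(ValueError, match="format version"):
        PathwayActivityModel.from_text("format_version\t99\npathway\tX\n")
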