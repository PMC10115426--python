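import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stpscore import (build_significance_table, classify_p, compare_pas_groups,
                      mann_whitney_u, patient_deltas, t_tests)
from stpscore.stats import GroupComparison


def brute_force_u(a, b):
    """Independent pair-counting oracle: U = #{a<b} + half ties."""
    u = 0.0
    for x, y in itertools.product(a, b):
        if x < y:
            u += 1.0
        elif x == y:
            u += 0.5
    return u


# ---------------------------------------------------------------------------
# Mann-Whitney

def test_complete_separation():
    u, p, auc = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 9 and auc == 1.0


def test_interleaved_groups_brute_force_value():
    # oracle: pairs (1,2),(1,4),(3,4) satisfy a<b -> U=3 of 4 cross pairs
    u, p, auc = mann_whitney_u([1, 3], [2, 4])
    assert u == brute_force_u([1, 3], [2, 4]) == 3
    assert auc == pytest.approx(0.75)


def test_identical_groups_auc_half():
    u, p, auc = mann_whitney_u([1, 2, 2, 5], [1, 2, 2, 5])
    assert auc == pytest.approx(0.5)
    assert p == pytest.approx(1.0)


def test_u_and_auc_match_brute_force_on_random_small_groups():
    rng = np.random.default_rng(2024)
    for n_a in range(1, 9):
        for n_b in range(1, 9):
            for values in (rng.normal(size=n_a + n_b),
                           rng.integers(0, 4, size=n_a + n_b).astype(float)):
                a, b = values[:n_a], values[n_a:]
                u, p, auc = mann_whitney_u(a, b)
                expected = brute_force_u(a, b)
                assert u == pytest.approx(expected)
                assert auc == pytest.approx(expected / (n_a * n_b))
                assert 0.0 < p <= 1.0


def test_auc_reflection_and_u_complement():
    rng = np.random.default_rng(5)
    a, b = rng.normal(size=12), rng.normal(size=9)
    u_ab, _, auc_ab = mann_whitney_u(a, b)
    u_ba, _, auc_ba = mann_whitney_u(b, a)
    assert auc_ab == pytest.approx(1.0 - auc_ba)
    assert u_ab + u_ba == pytest.approx(len(a) * len(b))  # tie-free


def test_exact_and_normal_p_agree_for_moderate_n():
    rng = np.random.default_rng(8)
    for _ in range(20):
        a = rng.normal(size=15)
        b = rng.normal(0.5, 1.0, size=15)
        _, p_asym, _ = mann_whitney_u(a, b)  # 225 pairs -> asymptotic path
        p_exact = sps.mannwhitneyu(b, a, alternative="two-sided",
                                   method="exact").pvalue
        assert abs(p_asym - p_exact) <= 0.02


def test_empty_group_is_an_error():
    with pytest.raises(ValueError, match="non-empty"):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# t-tests

def test_identical_paired_vectors_give_null_result():
    stat, p = t_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
    assert stat == 0.0 and p == 1.0


def test_constant_shift_paired_is_perfect_separation():
    with pytest.warns(RuntimeWarning, match="perfect separation"):
        stat, p = t_tests([2.0, 3.0, 4.0], [1.0, 2.0, 3.0], paired=True)
    assert np.isinf(stat) and p == 0.0


def test_two_zero_variance_groups():
    assert t_tests([5.0, 5.0], [5.0, 5.0]) == (0.0, 1.0)
    with pytest.warns(RuntimeWarning):
        stat, p = t_tests([5.0, 5.0], [3.0, 3.0])
    assert stat == np.inf and p == 0.0


def test_welch_matches_scipy_on_regular_data():
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=10), rng.normal(1, 2, size=14)
    stat, p = t_tests(a, b)
    ref = sps.ttest_ind(a, b, equal_var=False)
    assert stat == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_null_t_test_p_values_are_uniform():
    rng = np.random.default_rng(77)
    hits = sum(t_tests(rng.normal(size=10), rng.normal(size=10))[1] < 0.05
               for _ in range(1000))
    assert abs(hits / 1000 - 0.05) <= 0.02


# ---------------------------------------------------------------------------
# group comparison over a PAS matrix

def _toy_pas():
    samples = [f"s{i}" for i in range(8)]
    pas = pd.DataFrame(
        {s: [1.0, float(i)] for i, s in enumerate(samples)},
        index=["FLAT", "RISING"])
    ann = pd.DataFrame({"group": ["A"] * 4 + ["B"] * 4}, index=samples)
    return pas, ann


def test_identical_pathway_gives_null_comparison():
    pas, ann = _toy_pas()
    comps = compare_pas_groups(pas, ann, ("A", "B"), test="mann_whitney")
    flat = next(c for c in comps if c.pathway == "FLAT")
    assert flat.mean_delta == 0.0 and flat.auc == 0.5
    assert len(comps) == 2


def test_small_groups_default_to_t_test_and_label_swap_reflects():
    pas, ann = _toy_pas()
    comps = compare_pas_groups(pas, ann, ("A", "B"), test="auto")
    assert all(c.test == "t_test" for c in comps)  # n=4 < 8
    fwd = next(c for c in comps if c.pathway == "RISING")
    rev = next(c for c in compare_pas_groups(pas, ann, ("B", "A"))
               if c.pathway == "RISING")
    assert rev.mean_delta == pytest.approx(-fwd.mean_delta)
    assert rev.auc == pytest.approx(1.0 - fwd.auc)
    assert rev.p_value == pytest.approx(fwd.p_value)


def test_comparison_invariant_to_sample_order():
    pas, ann = _toy_pas()
    perm = ["s3", "s7", "s0", "s4", "s1", "s5", "s2", "s6"]
    a = compare_pas_groups(pas, ann, ("A", "B"))
    b = compare_pas_groups(pas[perm], ann.loc[perm], ("A", "B"))
    assert [c.to_row() for c in a] == [c.to_row() for c in b]


def test_absent_label_errors_by_name():
    pas, ann = _toy_pas()
    with pytest.raises(ValueError, match="ghost"):
        compare_pas_groups(pas, ann, ("A", "ghost"))


def test_bh_adjustment_never_decreases_p():
    pas, ann = _toy_pas()
    raw = compare_pas_groups(pas, ann, ("A", "B"))
    adj = compare_pas_groups(pas, ann, ("A", "B"), adjust="bh")
    for r, q in zip(raw, adj):
        assert q.p_value >= r.p_value - 1e-12


# ---------------------------------------------------------------------------
# paired deltas

def _paired_pas(post_shift):
    rows = []
    samples, ann = [], []
    for resp, prefix, shift in (("responder", "R", post_shift),
                                ("nonresponder", "N", 0.0)):
        for i in range(4):
            for tp in ("pre", "post"):
                sid = f"{prefix}{i}_{tp}"
                samples.append(sid)
                rows.append(5.0 - (shift if tp == "post" else 0.0) + 0.1 * i)
                ann.append({"sample_id": sid, "patient_id": f"{prefix}{i}",
                            "timepoint": tp, "response": resp})
    pas = pd.DataFrame([rows], index=["P"], columns=samples)
    return pas, pd.DataFrame(ann).set_index("sample_id")


def test_pre_equals_post_gives_zero_deltas():
    pas, ann = _paired_pas(post_shift=0.0)
    (res,) = patient_deltas(pas, ann)
    assert (res.deltas["delta"] == 0.0).all()
    assert res.paired_p["responder"] == 1.0


def test_responder_decrease_shows_positive_delta_and_group_difference():
    pas, ann = _paired_pas(post_shift=3.0)
    (res,) = patient_deltas(pas, ann)
    assert res.mean_delta_by_response["responder"] == pytest.approx(3.0)
    assert res.mean_delta_by_response["nonresponder"] == pytest.approx(0.0)
    assert res.between_auc == 0.0  # responder deltas all larger
    assert res.between_p < 0.05


def test_incomplete_patient_excluded_and_reported():
    pas, ann = _paired_pas(post_shift=1.0)
    ann = ann.drop(index="R0_post")
    (res,) = patient_deltas(pas, ann)
    assert "R0" in res.incomplete_patients
    assert "R0" not in res.deltas.index


def test_duplicate_timepoint_is_an_error():
    pas, ann = _paired_pas(post_shift=1.0)
    ann.loc["R0_pre", "timepoint"] = "post"
    with pytest.raises(ValueError, match="duplicate patient/timepoint"):
        patient_deltas(pas, ann)


# ---------------------------------------------------------------------------
# significance table

@pytest.mark.parametrize("p,expected", [
    (0.004, "significant"), (0.03, "marginal"), (0.2, "ns"),
    (0.0099, "significant"), (0.01, "marginal"), (0.05, "ns"),
])
def test_p_value_categories(p, expected):
    assert classify_p(p) == expected


def test_significance_table_layout_and_export(tmp_path):
    def comp(pathway, p):
        return GroupComparison(pathway, "A", "B", 3, 3, 1.0, 0.0, 1.0,
                               9.0, 1.0, p, "mann_whitney")
    table = build_significance_table({
        "c1": [comp("WNT", 0.004), comp("MAPK", 0.3)],
        "c2": [comp("WNT", 0.03)],
    })
    assert list(table.categories.index) == ["c1", "c2"]
    assert table.cell("c1", "WNT") == "significant"
    assert table.cell("c2", "WNT") == "marginal"
    assert table.cell("c1", "MAPK") == "ns"
    assert table.significant_pathways("c1") == ["WNT"]
    out = tmp_path / "table.tsv"
    table.to_tsv(out)
    assert "significant (p=0.004)" in out.read_text()
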