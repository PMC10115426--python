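"""Cohort-level comparison of pathway activity scores.

Group contrasts (diagnosis groups, responders vs non-responders) are tested
per pathway with the two-sided Mann-Whitney-Wilcoxon test by default, or
Welch's two-sided t-test for small groups; paired pre/post dynamics are
summarized as per-patient deltas (pre minus post, so positive = decrease
under treatment) with paired t-tests within response groups and a
Mann-Whitney contrast of deltas between them.  Significance convention:
p < 0.01 significant, 0.01 <= p < 0.05 marginal, otherwise ns.

The U statistic is oriented so that large U means group B is
stochastically larger: U counts cross pairs (a, b) with a < b, plus half
of the ties; AUC = U / (n_A * n_B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "PairedDeltaResult",
    "SignificanceTable",
    "mann_whitney_u",
    "t_tests",
    "compare_pas_groups",
    "patient_deltas",
    "build_significance_table",
    "classify_p",
]

SIGNIFICANT_P = 0.01
MARGINAL_P = 0.05

#: groups smaller than this default to the t-test ("low sample numbers")
SMALL_GROUP_N = 8


@dataclass
class GroupComparison:
    """Per-pathway two-group summary: means, delta, U, AUC, p."""

    pathway: str
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    mean_delta: float  # mean_a - mean_b
    u_stat: float
    auc: float
    p_value: float
    test: str  # "mann_whitney" | "t_test"

    def to_row(self) -> dict:
        return {
            "pathway": self.pathway, "group_a": self.label_a,
            "group_b": self.label_b, "n_a": self.n_a, "n_b": self.n_b,
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "mean_delta": self.mean_delta, "u_stat": self.u_stat,
            "auc": self.auc, "p_value": self.p_value, "test": self.test,
        }


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.to_row() for c in comparisons])


def mann_whitney_u(values_a, values_b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Returns ``(U, p, AUC)`` with U counting pairs where a < b (plus half
    ties), so AUC = U/(n_A*n_B) estimates P(A < B).  The p-value is exact
    when n_A*n_B <= 200 and the pooled values are tie-free, otherwise a
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 200 and not has_ties) else "asymptotic"
    # scipy's statistic for (b, a) counts pairs with b > a (+ half ties),
    # which is exactly the a < b orientation required here.
    res = sps.mannwhitneyu(b, a, alternative="two-sided", method=method,
                           use_continuity=True)
    u = float(res.statistic)
    auc = u / (a.size * b.size)
    return u, float(res.pvalue), auc


def t_tests(values_a, values_b, paired: bool = False) -> tuple[float, float]:
    """Two-sided t-test: Welch's for independent groups, paired otherwise.

    Degenerate inputs are resolved explicitly rather than returned as NaN:
    zero variance with equal means gives ``(0.0, 1.0)``; zero variance with
    a nonzero difference is perfect separation — a warning is emitted and
    ``(±inf, 0.0)`` returned.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal-length vectors")
        if a.size < 2:
            raise ValueError("paired test needs >= 2 pairs")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            d = float(diffs.mean())
            if d == 0.0:
                return 0.0, 1.0
            warnings.warn("zero-variance nonzero paired differences: "
                          "perfect separation", RuntimeWarning, stacklevel=2)
            return math_inf_signed(d), 0.0
        res = sps.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired test needs >= 2 samples per group")
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        d = float(a.mean() - b.mean())
        if d == 0.0:
            return 0.0, 1.0
        warnings.warn("two zero-variance groups with different means: "
                      "perfect separation", RuntimeWarning, stacklevel=2)
        return math_inf_signed(d), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def math_inf_signed(delta: float) -> float:
    return float(np.inf) if delta > 0 else float(-np.inf)


def _select_test(n_a: int, n_b: int, requested: str) -> str:
    if requested == "auto":
        return "t_test" if min(n_a, n_b) < SMALL_GROUP_N else "mann_whitney"
    if requested in ("mann_whitney", "mw"):
        return "mann_whitney"
    if requested in ("t_test", "t"):
        return "t_test"
    raise ValueError(f"unknown test {requested!r}")


def compare_pas_groups(pas: pd.DataFrame, annotations: pd.DataFrame,
                       contrast: tuple[str, str], test: str = "auto",
                       group_column: str = "group",
                       adjust: str = "none") -> list[GroupComparison]:
    """Compare PAS between two labeled sample groups, per pathway.

    ``pas`` is pathways x samples; ``annotations`` is indexed by sample id
    with ``group_column`` holding the labels.  ``test`` is ``"auto"``
    (Mann-Whitney unless a group has fewer than 8 samples, then t-test),
    ``"mann_whitney"`` or ``"t_test"``.  U and AUC are always reported from
    the rank statistics regardless of which test supplies the p-value.
    ``adjust="bh"`` applies Benjamini-Hochberg across pathways (off by
    default: raw p-values against the p < 0.01 bar are the convention here).
    """
    label_a, label_b = contrast
    groups = annotations[group_column]
    samples_a = [s for s in pas.columns if groups.get(s) == label_a]
    samples_b = [s for s in pas.columns if groups.get(s) == label_b]
    for label, members in ((label_a, samples_a), (label_b, samples_b)):
        if not members:
            raise ValueError(f"no annotated samples with label {label!r}")
    chosen = _select_test(len(samples_a), len(samples_b), test)
    comparisons: list[GroupComparison] = []
    for pathway in pas.index:
        a = pas.loc[pathway, samples_a].to_numpy(dtype=float)
        b = pas.loc[pathway, samples_b].to_numpy(dtype=float)
        u, p_mw, auc = mann_whitney_u(a, b)
        if chosen == "t_test":
            _, p = t_tests(a, b, paired=False)
        else:
            p = p_mw
        comparisons.append(GroupComparison(
            pathway=str(pathway), label_a=label_a, label_b=label_b,
            n_a=a.size, n_b=b.size, mean_a=float(a.mean()),
            mean_b=float(b.mean()), mean_delta=float(a.mean() - b.mean()),
            u_stat=u, auc=auc, p_value=float(p), test=chosen,
        ))
    if adjust == "bh":
        pvals = [c.p_value for c in comparisons]
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        for c, q in zip(comparisons, adjusted):
            c.p_value = float(q)
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return comparisons


@dataclass
class PairedDeltaResult:
    """Per-pathway pre/post treatment dynamics.

    ``deltas`` has one row per patient with both timepoints: columns
    ``patient_id``, ``response``, ``pas_pre``, ``pas_post``, ``delta``
    (pre - post; positive = decrease under treatment).  ``paired_p`` maps a
    response group to the paired t-test p of pre vs post within it;
    ``between_*`` compare deltas of the first vs second response label with
    Mann-Whitney.  Patients lacking a timepoint are excluded from deltas
    and listed in ``incomplete_patients``.
    """

    pathway: str
    deltas: pd.DataFrame
    paired_p: dict[str, float]
    mean_delta_by_response: dict[str, float]
    between_u: float | None
    between_p: float | None
    between_auc: float | None
    incomplete_patients: list[str] = field(default_factory=list)


def patient_deltas(pas: pd.DataFrame, annotations: pd.DataFrame,
                   response_contrast: tuple[str, str] = ("responder", "nonresponder"),
                   ) -> list[PairedDeltaResult]:
    """Per-patient pre-minus-post PAS deltas and their group statistics.

    ``annotations`` must carry ``patient_id``, ``timepoint`` in
    {``pre``, ``post``} and ``response``.  A patient with a duplicated
    timepoint is an error; a patient missing one timepoint is excluded and
    reported.
    """
    required = {"patient_id", "timepoint", "response"}
    missing_cols = required - set(annotations.columns)
    if missing_cols:
        raise ValueError(f"annotations missing columns: {sorted(missing_cols)}")
    ann = annotations.loc[[s for s in annotations.index if s in pas.columns]]
    bad_tp = set(ann["timepoint"].dropna()) - {"pre", "post"}
    if bad_tp:
        raise ValueError(f"timepoint values must be pre/post; got {sorted(bad_tp)}")
    dup = ann.groupby(["patient_id", "timepoint"]).size()
    dup = dup[dup > 1]
    if len(dup):
        raise ValueError(f"duplicate patient/timepoint pairs: {list(dup.index)}")

    by_patient: dict[str, dict[str, str]] = {}
    response_of: dict[str, str] = {}
    for sample_id, row in ann.iterrows():
        by_patient.setdefault(row["patient_id"], {})[row["timepoint"]] = sample_id
        response_of[row["patient_id"]] = row["response"]
    complete = {p: tp for p, tp in by_patient.items() if {"pre", "post"} <= set(tp)}
    incomplete = sorted(set(by_patient) - set(complete))
    if not complete:
        raise ValueError("no patient has both pre and post samples")

    results: list[PairedDeltaResult] = []
    label_r, label_n = response_contrast
    for pathway in pas.index:
        rows = []
        for patient, tp in complete.items():
            pre = float(pas.loc[pathway, tp["pre"]])
            post = float(pas.loc[pathway, tp["post"]])
            rows.append({"patient_id": patient, "response": response_of[patient],
                         "pas_pre": pre, "pas_post": post, "delta": pre - post})
        deltas = pd.DataFrame(rows).set_index("patient_id")
        paired_p: dict[str, float] = {}
        mean_delta: dict[str, float] = {}
        for response, sub in deltas.groupby("response"):
            mean_delta[str(response)] = float(sub["delta"].mean())
            if len(sub) >= 2:
                _, p = t_tests(sub["pas_pre"], sub["pas_post"], paired=True)
                paired_p[str(response)] = p
        d_r = deltas.loc[deltas["response"] == label_r, "delta"].to_numpy()
        d_n = deltas.loc[deltas["response"] == label_n, "delta"].to_numpy()
        if d_r.size and d_n.size:
            u, p, auc = mann_whitney_u(d_r, d_n)
        else:
            u = p = auc = None
        results.append(PairedDeltaResult(
            pathway=str(pathway), deltas=deltas, paired_p=paired_p,
            mean_delta_by_response=mean_delta, between_u=u, between_p=p,
            between_auc=auc, incomplete_patients=incomplete,
        ))
    return results


def classify_p(p: float) -> str:
    """Categorize a p-value: significant (<0.01), marginal (<0.05), ns."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of range: {p}")
    if p < SIGNIFICANT_P:
        return "significant"
    if p < MARGINAL_P:
        return "marginal"
    return "ns"


class SignificanceTable:
    """Contrasts x pathways grid of significance categories with p-values."""

    def __init__(self, categories: pd.DataFrame, p_values: pd.DataFrame):
        self.categories = categories
        self.p_values = p_values

    def cell(self, contrast: str, pathway: str) -> str:
        return str(self.categories.loc[contrast, pathway])

    def significant_pathways(self, contrast: str) -> list[str]:
        row = self.categories.loc[contrast]
        return [p for p in self.categories.columns if row[p] == "significant"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.categories.copy()
        for contrast in out.index:
            for pathway in out.columns:
                out.loc[contrast, pathway] = (
                    f"{self.categories.loc[contrast, pathway]}"
                    f" (p={self.p_values.loc[contrast, pathway]:.3g})")
        out.to_csv(path, sep="\t", index_label="contrast")


def build_significance_table(
        comparison_sets: Mapping[str, Sequence[GroupComparison]]) -> SignificanceTable:
    """Build the contrasts x pathways significance grid.

    ``comparison_sets`` maps a contrast name (table row) to its per-pathway
    comparisons; row order follows the mapping, column order the first
    appearance of each pathway.
    """
    contrasts = list(comparison_sets)
    pathways: list[str] = []
    for comps in comparison_sets.values():
        for c in comps:
            if c.pathway not in pathways:
                pathways.append(c.pathway)
    categories = pd.DataFrame("ns", index=contrasts, columns=pathways, dtype=object)
    p_values = pd.DataFrame(np.nan, index=contrasts, columns=pathways, dtype=float)
    for contrast, comps in comparison_sets.items():
        for c in comps:
            categories.loc[contrast, c.pathway] = classify_p(c.p_value)
            p_values.loc[contrast, c.pathway] = c.p_value
    categories.index.name = "contrast"
    return SignificanceTable(categories, p_values)
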