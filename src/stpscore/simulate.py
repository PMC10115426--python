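"""Synthetic expression cohorts with known pathway-activity ground truth.

The generator emulates the structure the analysis assumes: multi-group
cohorts (healthy controls and IBD subtypes, or responder/non-responder
patients sampled pre and post anti-TNFa treatment), target genes of active
pathways shifted up by an effect size on the log2 scale, additive Gaussian
noise, off-target noise probes, Affymetrix-style control probes
(housekeeping 3'/5' pairs, spike-in series, degradation-position probes),
and injectable QC failures.  Every draw is reproducible from its seed, and
the emitted ground truth is the oracle for end-to-end tests.

Activity states per (group, pathway): ``active`` shifts that pathway's
target genes by the full effect size, ``partial`` by half of it (used for
marginally elevated pathways), ``inactive`` not at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genesets import PathwayDefinition, default_probe_map, example_pathway_definitions

__all__ = [
    "GroupSpec",
    "ScenarioConfig",
    "GroundTruth",
    "CalibrationSpec",
    "CalibrationSet",
    "PRESETS",
    "QC_FAILURE_KINDS",
    "control_annotation",
    "simulate_cohort",
    "preset_scenario",
    "simulate_calibration",
    "inject_qc_failures",
]

logger = logging.getLogger(__name__)

ACTIVITY_STATES = ("active", "partial", "inactive")

QC_FAILURE_KINDS = ("negative_values", "saturation", "degraded_rna",
                    "bad_spike_order", "high_3p5p_ratio")

#: control-probe layout: (probe_id, role, target, rank, position, log2 level)
_CONTROL_LAYOUT = [
    ("AFFX_GAPDH_3_at", "housekeeping_3prime", "GAPDH", None, None, 12.0),
    ("AFFX_GAPDH_5_at", "housekeeping_5prime", "GAPDH", None, None, 12.0),
    ("AFFX_ACTB_3_at", "housekeeping_3prime", "ACTB", None, None, 12.5),
    ("AFFX_ACTB_5_at", "housekeeping_5prime", "ACTB", None, None, 12.5),
    ("AFFX_BIOB_at", "hyb_spike", "BioB", 1, None, 8.0),
    ("AFFX_BIOC_at", "hyb_spike", "BioC", 2, None, 10.0),
    ("AFFX_BIOD_at", "hyb_spike", "BioD", 3, None, 12.0),
    ("AFFX_CRE_at", "hyb_spike", "Cre", 4, None, 14.0),
    ("AFFX_LYS_at", "polyA_spike", "Lys", 1, None, 7.0),
    ("AFFX_PHE_at", "polyA_spike", "Phe", 2, None, 9.0),
    ("AFFX_THR_at", "polyA_spike", "Thr", 3, None, 11.0),
    ("AFFX_DAP_at", "polyA_spike", "Dap", 4, None, 13.0),
] + [
    (f"AFFX_DEGPOS_{i:02d}_at", "degradation", "DEG", None, i, 10.0)
    for i in range(1, 12)
]

#: noise applied to control probes; kept small so spike ordering is stable
CONTROL_NOISE_SD = 0.1


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: name, size, optional timepoint/response labels."""

    name: str
    n: int
    timepoint: str | None = None
    response: str | None = None
    patient_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.name!r}: n must be >= 1")
        if self.patient_ids is not None and len(self.patient_ids) != self.n:
            raise ValueError(f"group {self.name!r}: need {self.n} patient ids")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a synthetic cohort.

    ``pathway_states`` maps group name -> pathway -> activity state
    (pathways omitted from a group's mapping are inactive).  ``effect_size``
    is the log2-intensity shift added to target genes of active pathways
    (half of it for partial), ``noise_sd`` the Gaussian noise on log2
    intensities, ``baseline`` the background log2 level, ``n_offtarget``
    the number of non-target noise probes.
    """

    groups: tuple[GroupSpec, ...]
    pathway_states: Mapping[str, Mapping[str, str]]
    effect_size: float = 1.0
    noise_sd: float = 0.5
    baseline: float = 7.0
    n_offtarget: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for group, states in self.pathway_states.items():
            if group not in {g.name for g in self.groups}:
                raise ValueError(f"pathway_states for unknown group {group!r}")
            for pathway, state in states.items():
                if state not in ACTIVITY_STATES:
                    raise ValueError(
                        f"invalid activity state {state!r} for {group}/{pathway}")


@dataclass
class GroundTruth:
    """What the generator actually did, for use as a test oracle."""

    annotations: pd.DataFrame
    pathway_states: pd.DataFrame  # samples x pathways, activity-state strings
    qc_failures: dict[str, str] = field(default_factory=dict)

    def samples_with_state(self, pathway: str, state: str) -> list[str]:
        col = self.pathway_states[pathway]
        return list(col.index[col == state])

    def to_tsv(self, path: str | Path) -> None:
        out = self.annotations.join(self.pathway_states)
        out["qc_failure"] = [self.qc_failures.get(s, "") for s in out.index]
        out.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def control_annotation() -> pd.DataFrame:
    """Control-probe annotation matching the simulator's control layout."""
    frame = pd.DataFrame(
        [(p, role, target, rank, pos) for p, role, target, rank, pos, _ in _CONTROL_LAYOUT],
        columns=["probe_id", "role", "target", "rank", "position"],
    )
    return frame.set_index("probe_id")


def _sample_ids(group: GroupSpec) -> tuple[list[str], list[str]]:
    ids, patients = [], []
    for i in range(group.n):
        patient = (group.patient_ids[i] if group.patient_ids is not None
                   else f"{group.name}_p{i + 1:02d}")
        patients.append(patient)
        suffix = f"_{group.timepoint}" if group.timepoint else ""
        ids.append(f"{group.name}_{i + 1:02d}{suffix}")
    return ids, patients


def simulate_cohort(config: ScenarioConfig,
                    definitions: Sequence[PathwayDefinition] | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a synthetic cohort.

    Returns ``(expression, annotations, ground_truth)`` where expression is
    probes x samples log2 intensities.  Probe layout: one ``<GENE>_at``
    probe per pathway target gene (in definition order), ``n_offtarget``
    off-target probes at baseline, and the fixed control-probe block.
    """
    definitions = list(definitions) if definitions is not None \
        else example_pathway_definitions()
    known = {d.name for d in definitions}
    for group, states in config.pathway_states.items():
        unknown = set(states) - known
        if unknown:
            raise ValueError(
                f"group {group!r} references undefined pathways {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    gene_to_pathway: dict[str, str] = {}
    target_probes: list[str] = []
    for d in definitions:
        pm = d.probe_map or default_probe_map([d])
        for g in d.target_genes:
            gene_to_pathway[g] = d.name
            for probe in pm.get(g, (f"{g}_at",)):
                target_probes.append(probe)
    probe_gene = {p: p[:-3] if p.endswith("_at") else p for p in target_probes}
    offtarget = [f"OFFT_{i + 1:04d}_at" for i in range(config.n_offtarget)]
    control_probes = [p for p, *_ in _CONTROL_LAYOUT]
    control_level = {p: lvl for p, _, _, _, _, lvl in _CONTROL_LAYOUT}
    probes = target_probes + offtarget + control_probes

    columns: dict[str, np.ndarray] = {}
    ann_rows = []
    state_rows = []
    for group in config.groups:
        states = dict(config.pathway_states.get(group.name, {}))
        sample_ids, patients = _sample_ids(group)
        for sid, patient in zip(sample_ids, patients):
            values = np.empty(len(probes))
            for i, probe in enumerate(target_probes):
                pathway = gene_to_pathway[probe_gene[probe]]
                state = states.get(pathway, "inactive")
                shift = {"active": config.effect_size,
                         "partial": config.effect_size / 2.0,
                         "inactive": 0.0}[state]
                values[i] = config.baseline + shift
            values[len(target_probes):len(target_probes) + len(offtarget)] = config.baseline
            noise = rng.normal(0.0, config.noise_sd,
                               len(target_probes) + len(offtarget))
            values[:len(noise)] += noise
            for j, probe in enumerate(control_probes):
                values[len(noise) + j] = (control_level[probe]
                                          + rng.normal(0.0, CONTROL_NOISE_SD))
            columns[sid] = values
            ann_rows.append({"sample_id": sid, "group": group.name,
                             "patient_id": patient,
                             "timepoint": group.timepoint or "",
                             "response": group.response or ""})
            state_rows.append({"sample_id": sid,
                               **{d.name: states.get(d.name, "inactive")
                                  for d in definitions}})

    expression = pd.DataFrame(columns, index=probes)
    expression.index.name = "probe_id"
    annotations = pd.DataFrame(ann_rows).set_index("sample_id")
    truth = GroundTruth(
        annotations=annotations.copy(),
        pathway_states=pd.DataFrame(state_rows).set_index("sample_id"),
    )
    return expression, annotations, truth


# ---------------------------------------------------------------------------
# presets

_DIAGNOSIS_STATES: dict[str, dict[str, str]] = {
    "healthy": {},
    "CDc": {"AR": "active", "MAPK": "active", "NFKB": "active",
            "JAK-STAT3": "active", "WNT": "active"},
    "CDi": {"MAPK": "active", "NFKB": "partial", "JAK-STAT1/2": "active",
            "WNT": "partial"},
    "UC": {"AR": "active", "MAPK": "active", "NFKB": "active",
           "TGFB": "active", "JAK-STAT3": "active", "WNT": "active"},
}

#: pathways elevated pre-treatment in anti-TNFa non-responders
RESPONSE_PREDICTIVE_PATHWAYS = ("NFKB", "TGFB", "JAK-STAT3")

#: disease pathways active in responders that normalize on successful treatment
_RESPONDER_BASELINE = ("AR", "MAPK", "WNT")

_ANTI_TNF_STATES: dict[str, dict[str, str]] = {
    "responder_pre": {**{p: "active" for p in _RESPONDER_BASELINE},
                      **{p: "partial" for p in RESPONSE_PREDICTIVE_PATHWAYS}},
    "responder_post": {},
    "nonresponder_pre": {**{p: "active" for p in _RESPONDER_BASELINE},
                         **{p: "active" for p in RESPONSE_PREDICTIVE_PATHWAYS}},
    "nonresponder_post": {**{p: "active" for p in _RESPONDER_BASELINE},
                          **{p: "active" for p in RESPONSE_PREDICTIVE_PATHWAYS}},
}

PRESETS = ("diagnosis", "anti_tnf_response", "null")


def preset_scenario(name: str, n_per_group: int = 20, effect_size: float = 1.0,
                    noise_sd: float = 0.5, seed: int = 0) -> ScenarioConfig:
    """Built-in scenario configurations.

    ``diagnosis``
        healthy / CDc / CDi / UC groups with the subtype-specific activity
        pattern (MAPK active in every disease group, JAK-STAT1/2 only in
        CDi, AR only in the colon-localized groups, TGFB only in UC;
        marginally elevated pathways are partial).
    ``anti_tnf_response``
        responder / non-responder patients sampled pre and post treatment:
        NFKB, TGFB and JAK-STAT3 fully elevated only in non-responders
        pre-treatment (marginal in responders), and post-treatment
        normalization of all pathways only in responders; pre/post samples
        of a patient share a patient id.
    ``null``
        two groups, every pathway inactive.
    """
    if name == "diagnosis":
        groups = tuple(GroupSpec(g, n_per_group)
                       for g in ("healthy", "CDc", "CDi", "UC"))
        states = _DIAGNOSIS_STATES
    elif name == "anti_tnf_response":
        groups = []
        for response, prefix in (("responder", "R"), ("nonresponder", "N")):
            patients = tuple(f"{prefix}{i + 1:02d}" for i in range(n_per_group))
            for timepoint in ("pre", "post"):
                groups.append(GroupSpec(f"{response}_{timepoint}", n_per_group,
                                        timepoint=timepoint, response=response,
                                        patient_ids=patients))
        groups = tuple(groups)
        states = _ANTI_TNF_STATES
    elif name == "null":
        groups = (GroupSpec("A", n_per_group), GroupSpec("B", n_per_group))
        states = {"A": {}, "B": {}}
    else:
        raise ValueError(f"unknown preset {name!r}; valid presets: {PRESETS}")
    return ScenarioConfig(groups=groups, pathway_states=states,
                          effect_size=effect_size, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# calibration sets

@dataclass(frozen=True)
class CalibrationSpec:
    """Generating model for a calibration set.

    Evidence for each gene is drawn from its conditional probability pair
    ``(p_high_active, p_high_inactive)`` given the sample's class, then
    mapped to intensities: high -> ``level_high``, low -> ``level_low``,
    plus Gaussian noise.  With balanced classes and complementary
    probabilities the pooled per-probe median falls between the two levels,
    which is what the median-threshold calibration rule assumes.
    """

    definition: PathwayDefinition
    cpt: Mapping[str, tuple[float, float]]
    level_low: float = 7.0
    level_high: float = 9.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        missing = set(self.definition.target_genes) - set(self.cpt)
        if missing:
            raise ValueError(f"CPT missing genes {sorted(missing)}")
        for gene, (p_a, p_i) in self.cpt.items():
            if not (0.0 < p_a < 1.0 and 0.0 < p_i < 1.0):
                raise ValueError(f"{gene}: probabilities must be in (0,1)")
        if self.level_high <= self.level_low:
            raise ValueError("level_high must exceed level_low")


@dataclass
class CalibrationSet:
    """Expression matrix plus per-sample ground-truth activity labels."""

    expression: pd.DataFrame  # probes x samples
    labels: pd.Series  # sample id -> "active"/"inactive"
    evidence_truth: pd.DataFrame | None = None  # samples x genes, drawn evidence


def simulate_calibration(spec: CalibrationSpec, n_per_class: int,
                         seed: int = 0) -> CalibrationSet:
    """Draw a labeled calibration cohort from a known generating model."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    d = spec.definition
    pm = d.probe_map or default_probe_map([d])
    sample_ids, labels, ev_rows, cols = [], [], [], {}
    for klass, tag in (("active", "act"), ("inactive", "ina")):
        for i in range(n_per_class):
            sid = f"calib_{tag}_{i + 1:04d}"
            sample_ids.append(sid)
            labels.append(klass)
            values: dict[str, float] = {}
            ev: dict[str, str] = {}
            for gene in d.target_genes:
                p_a, p_i = spec.cpt[gene]
                p = p_a if klass == "active" else p_i
                high = bool(rng.random() < p)
                ev[gene] = "high" if high else "low"
                level = spec.level_high if high else spec.level_low
                for probe in pm.get(gene, (f"{gene}_at",)):
                    values[probe] = level + rng.normal(0.0, spec.noise_sd)
            cols[sid] = values
            ev_rows.append(ev)
    expression = pd.DataFrame(cols)
    expression.index.name = "probe_id"
    return CalibrationSet(
        expression=expression,
        labels=pd.Series(labels, index=sample_ids, name="label"),
        evidence_truth=pd.DataFrame(ev_rows, index=sample_ids),
    )


# ---------------------------------------------------------------------------
# QC-failure injection

def inject_qc_failures(expression: pd.DataFrame, kinds: Sequence[str],
                       fraction: float, seed: int = 0,
                       ground_truth: GroundTruth | None = None,
                       ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Corrupt a fraction of samples with named QC-failure modes.

    Returns a corrupted copy of the matrix and a mapping of corrupted
    sample id -> failure kind (also recorded on ``ground_truth`` when
    given).  Kinds are assigned round-robin over the chosen samples, which
    are drawn without replacement.
    """
    kinds = list(kinds)
    unknown = set(kinds) - set(QC_FAILURE_KINDS)
    if unknown:
        raise ValueError(f"unknown QC failure kinds {sorted(unknown)}")
    if not kinds:
        raise ValueError("kinds must be non-empty")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    n_samples = expression.shape[1]
    n_fail = int(round(fraction * n_samples))
    if n_fail == 0:
        logger.warning("fraction %.3g of %d samples rounds to zero; no-op",
                       fraction, n_samples)
        return expression.copy(), {}
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_samples, size=n_fail, replace=False)
    corrupted = expression.copy()
    failures: dict[str, str] = {}
    for i, col_idx in enumerate(sorted(chosen)):
        sample_id = expression.columns[int(col_idx)]
        kind = kinds[i % len(kinds)]
        _corrupt(corrupted, sample_id, kind, rng)
        failures[sample_id] = kind
    if ground_truth is not None:
        ground_truth.qc_failures.update(failures)
    return corrupted, failures


def _corrupt(expression: pd.DataFrame, sample_id: str, kind: str,
             rng: np.random.Generator) -> None:
    controls = control_annotation()
    non_control = [p for p in expression.index if p not in controls.index]
    if kind == "negative_values":
        # non-positive linear readings have no log2 representation -> NaN
        n_bad = max(2, int(0.02 * len(non_control)))
        bad = rng.choice(len(non_control), size=n_bad, replace=False)
        expression.loc[[non_control[int(i)] for i in bad], sample_id] = np.nan
    elif kind == "saturation":
        n_bad = max(3, int(0.03 * len(non_control)))
        bad = rng.choice(len(non_control), size=n_bad, replace=False)
        expression.loc[[non_control[int(i)] for i in bad], sample_id] = 16.5
    elif kind == "degraded_rna":
        deg = controls[controls["role"] == "degradation"]
        for probe in deg.index:
            if probe in expression.index:
                pos = float(deg.loc[probe, "position"])
                expression.loc[probe, sample_id] += 0.4 * (pos - 1.0)
    elif kind == "bad_spike_order":
        spikes = controls[controls["role"] == "hyb_spike"].sort_values("rank")
        present = [p for p in spikes.index if p in expression.index]
        vals = expression.loc[present, sample_id].to_numpy()
        expression.loc[present, sample_id] = vals[::-1]
    elif kind == "high_3p5p_ratio":
        for probe, row in controls.iterrows():
            if probe not in expression.index:
                continue
            if row["role"] == "housekeeping_3prime":
                expression.loc[probe, sample_id] += 2.5
            elif row["role"] == "housekeeping_5prime":
                expression.loc[probe, sample_id] -= 2.5
    else:  # pragma: no cover - guarded upstream
        raise ValueError(kind)
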