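"""Naive-Bayes log2-odds pathway activity scoring.

The pathway activity score (PAS) of a sample is the log2 of the posterior
odds that the pathway's transcription factor is active versus inactive,
given binary high/low expression evidence on its target genes.  The model is
a two-layer naive Bayes: a latent TF state and, conditionally independent
given that state, one binary evidence node per target gene.  With prior
``pi`` on the active state and per-gene conditional probabilities
``p_high_active[g]`` / ``p_high_inactive[g]``,

    PAS = log2(pi / (1 - pi)) + sum_g log2(L_g),

where ``L_g`` is the likelihood ratio of gene g's observed evidence
(``p_high_active/p_high_inactive`` for high, the one-complement ratio for
low) and unmeasured (missing) genes contribute nothing.

Interpretation contracts carried by the score:

* each pathway has its own PAS range, so scores are **not** comparable
  across pathways on the same sample;
* absolute values are interpretable only against a calibration with known
  activity states — otherwise only differences between samples are;
* a negative PAS does not by itself mean the pathway is off.

Calibration (``fit``) estimates, from samples with known active/inactive
state: per-probe discretization thresholds (the pooled median) and
Laplace-smoothed conditional probability tables.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genesets import PathwayDefinition

__all__ = [
    "EVIDENCE_STATES",
    "PathwayActivityModel",
    "discretize_expression",
    "calibrate_model",
    "score_sample",
    "score_matrix",
    "enumerate_posterior_oracle",
]

EVIDENCE_STATES = ("high", "low", "missing")

ACTIVE, INACTIVE = "active", "inactive"

MODEL_FORMAT_VERSION = "1"


def _as_label_array(y) -> np.ndarray:
    y = np.asarray(y, dtype=object)
    bad = set(map(str, y)) - {ACTIVE, INACTIVE}
    if bad:
        raise ValueError(f"labels must be 'active'/'inactive'; got {sorted(bad)}")
    return y.astype(str)


def _gene_level(X: pd.DataFrame, definition: PathwayDefinition,
                thresholds: pd.Series) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Aggregate probes to gene level (mean log2 intensity, mean threshold).

    X is samples x probes.  Returns (values samples x mapped genes,
    per-gene thresholds, list of unmapped/missing genes).
    """
    values: dict[str, pd.Series] = {}
    gene_thr: dict[str, float] = {}
    missing: list[str] = []
    for gene in definition.target_genes:
        probes = [p for p in definition.probe_map.get(gene, ()) if p in X.columns]
        probes = [p for p in probes if p in thresholds.index]
        if not probes:
            missing.append(gene)
            continue
        values[gene] = X[probes].mean(axis=1)
        gene_thr[gene] = float(thresholds[probes].mean())
    if not values:
        raise ValueError(
            f"pathway {definition.name!r}: no target gene has a probe on this platform"
        )
    frame = pd.DataFrame(values, index=X.index)
    return frame, pd.Series(gene_thr), missing


class PathwayActivityModel(BaseEstimator):
    """Per-pathway naive-Bayes scorer with a scikit-learn estimator surface.

    Parameters
    ----------
    definition:
        :class:`~stpscore.genesets.PathwayDefinition` naming the target genes
        and their probes.
    prior_active:
        Prior probability in (0, 1) that the transcription factor is active.
        The default 0.5 makes the PAS a pure evidence score (zero prior
        log-odds).
    pseudocount:
        Laplace smoothing pseudocount ``alpha > 0`` applied when estimating
        the conditional probability tables; keeps every probability strictly
        inside (0, 1) and hence every PAS finite.

    Fitted attributes
    -----------------
    thresholds_ : pandas.Series
        Per-probe log2-intensity cut (pooled median over calibration
        samples) separating low from high evidence; ties go high.
    cpt_ : pandas.DataFrame
        Index = target genes, columns ``p_high_active`` / ``p_high_inactive``.
    prior_active_ : float
    classes_ : ndarray of ("inactive", "active")

    Notes
    -----
    ``X`` follows the scikit-learn convention (samples as rows, probe ids as
    columns), i.e. the transpose of the probes x samples TSV layout used by
    the I/O helpers.
    """

    def __init__(self, definition: PathwayDefinition | None = None,
                 prior_active: float = 0.5, pseudocount: float = 1.0):
        self.definition = definition
        self.prior_active = prior_active
        self.pseudocount = pseudocount

    # -- validation ------------------------------------------------------
    def _validate_params_(self) -> None:
        if self.definition is None:
            raise ValueError("definition is required")
        if not (0.0 < float(self.prior_active) < 1.0):
            raise ValueError("prior_active must lie strictly inside (0, 1)")
        if not float(self.pseudocount) > 0.0:
            raise ValueError("pseudocount (Laplace alpha) must be > 0")

    @staticmethod
    def _check_x(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame with probe-id columns")
        if X.columns.duplicated().any():
            raise ValueError("duplicate probe ids in X")
        return X

    # -- calibration -----------------------------------------------------
    def fit(self, X: pd.DataFrame, y: Sequence[str]) -> "PathwayActivityModel":
        """Calibrate thresholds and CPTs on samples with known pathway state.

        ``y`` holds ``"active"`` / ``"inactive"`` per sample; both classes
        must be present.
        """
        self._validate_params_()
        X = self._check_x(X)
        y = _as_label_array(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        n_active = int((y == ACTIVE).sum())
        n_inactive = int((y == INACTIVE).sum())
        if n_active == 0 or n_inactive == 0:
            raise ValueError("calibration requires at least one sample per class")

        mapped_probes = sorted(
            {p for g in self.definition.target_genes
             for p in self.definition.probe_map.get(g, ()) if p in X.columns}
        )
        if not mapped_probes:
            raise ValueError(
                f"pathway {self.definition.name!r}: no target-gene probe present"
            )
        thresholds = X[mapped_probes].median(axis=0)
        evidence = discretize_expression(X, self.definition, thresholds)

        alpha = float(self.pseudocount)
        rows = {}
        for gene in self.definition.target_genes:
            if gene in evidence.columns:
                ev = evidence[gene]
                k_a = int(((ev == "high") & (y == ACTIVE)).sum())
                k_i = int(((ev == "high") & (y == INACTIVE)).sum())
            else:  # unmeasured gene: smoothing alone -> uninformative CPT
                k_a = k_i = 0
            rows[gene] = (
                (k_a + alpha) / (n_active + 2 * alpha),
                (k_i + alpha) / (n_inactive + 2 * alpha),
            )
        self.cpt_ = pd.DataFrame.from_dict(
            rows, orient="index", columns=["p_high_active", "p_high_inactive"]
        ).reindex(list(self.definition.target_genes))
        self.thresholds_ = thresholds.astype(float)
        self.prior_active_ = float(self.prior_active)
        self.classes_ = np.array([INACTIVE, ACTIVE])
        self.n_features_in_ = X.shape[1]
        return self

    @classmethod
    def from_parameters(cls, definition: PathwayDefinition,
                        cpt: Mapping[str, tuple[float, float]] | pd.DataFrame,
                        thresholds: Mapping[str, float] | pd.Series | None = None,
                        prior_active: float = 0.5,
                        pseudocount: float = 1.0) -> "PathwayActivityModel":
        """Build an already-calibrated model from explicit parameters."""
        model = cls(definition=definition, prior_active=prior_active,
                    pseudocount=pseudocount)
        model._validate_params_()
        if isinstance(cpt, pd.DataFrame):
            frame = cpt[["p_high_active", "p_high_inactive"]].astype(float).copy()
        else:
            frame = pd.DataFrame.from_dict(
                {g: tuple(v) for g, v in cpt.items()}, orient="index",
                columns=["p_high_active", "p_high_inactive"],
            ).astype(float)
        missing = set(definition.target_genes) - set(frame.index)
        if missing:
            raise ValueError(f"CPT missing genes: {sorted(missing)}")
        frame = frame.reindex(list(definition.target_genes))
        vals = frame.to_numpy()
        if not np.all((vals > 0.0) & (vals < 1.0)):
            raise ValueError("all CPT probabilities must lie strictly inside (0, 1)")
        model.cpt_ = frame
        if thresholds is None:
            thresholds = {p: 0.0 for g in definition.target_genes
                          for p in definition.probe_map.get(g, ())}
        model.thresholds_ = pd.Series(dict(thresholds), dtype=float)
        if not np.all(np.isfinite(model.thresholds_.to_numpy())) :
            raise ValueError("thresholds must be finite")
        model.prior_active_ = float(prior_active)
        model.classes_ = np.array([INACTIVE, ACTIVE])
        model.n_features_in_ = len(model.thresholds_)
        return model

    def _check_fitted(self) -> None:
        if not hasattr(self, "cpt_"):
            raise AttributeError("model is not calibrated; call fit() first")

    # -- scoring ---------------------------------------------------------
    def score_evidence(self, evidence: Mapping[str, str]) -> float:
        """PAS (log2 odds) for one sample's evidence vector.

        ``evidence`` maps target genes to ``high``/``low``/``missing``; genes
        absent from the mapping count as missing.  Keys outside the
        pathway's target genes are an error.
        """
        self._check_fitted()
        extra = set(evidence) - set(self.definition.target_genes)
        if extra:
            raise ValueError(f"evidence for non-target genes: {sorted(extra)}")
        pas = math.log2(self.prior_active_ / (1.0 - self.prior_active_))
        for gene in self.definition.target_genes:
            state = evidence.get(gene, "missing")
            if state not in EVIDENCE_STATES:
                raise ValueError(f"invalid evidence state {state!r} for {gene!r}")
            if state == "missing":
                continue
            p_a, p_i = self.cpt_.loc[gene]
            if state == "high":
                pas += math.log2(p_a / p_i)
            else:
                pas += math.log2((1.0 - p_a) / (1.0 - p_i))
        return pas

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """PAS per sample for expression input (samples x probes, log2)."""
        self._check_fitted()
        X = self._check_x(X)
        evidence = discretize_expression(X, self.definition, self.thresholds_)
        out = np.empty(len(X), dtype=float)
        for i, (_, row) in enumerate(evidence.iterrows()):
            out[i] = self.score_evidence(row.to_dict())
        return out

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Column vector of PAS values (pipeline-friendly)."""
        return self.decision_function(X).reshape(-1, 1)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Hard call: ``active`` iff the posterior favors the active state.

        Provided for the estimator surface; the assay's deliverable is the
        continuous PAS, and a negative score does not by itself mean the
        pathway is off.
        """
        pas = self.decision_function(X)
        return np.where(pas > 0, ACTIVE, INACTIVE)

    # -- serialization ---------------------------------------------------
    def to_text(self) -> str:
        """Serialize to a versioned, diffable plain-text key-value format."""
        self._check_fitted()
        lines = [
            f"format_version\t{MODEL_FORMAT_VERSION}",
            f"pathway\t{self.definition.name}",
            f"description\t{self.definition.description}",
            f"prior_active\t{self.prior_active_!r}",
            f"pseudocount\t{float(self.pseudocount)!r}",
        ]
        for gene in self.definition.target_genes:
            p_a, p_i = self.cpt_.loc[gene]
            probes = ",".join(self.definition.probe_map.get(gene, ()))
            lines.append(f"gene\t{gene}\t{p_a!r}\t{p_i!r}\t{probes}")
        for probe, thr in self.thresholds_.items():
            lines.append(f"threshold\t{probe}\t{thr!r}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "PathwayActivityModel":
        meta: dict[str, str] = {}
        genes: list[tuple[str, float, float, tuple[str, ...]]] = []
        thresholds: dict[str, float] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            key = fields[0]
            if key == "gene":
                probes = tuple(p for p in fields[4].split(",") if p) if len(fields) > 4 else ()
                genes.append((fields[1], float(fields[2]), float(fields[3]), probes))
            elif key == "threshold":
                thresholds[fields[1]] = float(fields[2])
            else:
                meta[key] = fields[1] if len(fields) > 1 else ""
        if meta.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {meta.get('format_version')!r}")
        definition = PathwayDefinition(
            meta["pathway"], tuple(g for g, *_ in genes), meta.get("description", ""),
            {g: probes for g, _, _, probes in genes},
        )
        cpt = {g: (p_a, p_i) for g, p_a, p_i, _ in genes}
        return cls.from_parameters(
            definition, cpt, thresholds or None,
            prior_active=float(meta.get("prior_active", 0.5)),
            pseudocount=float(meta.get("pseudocount", 1.0)),
        )

    @classmethod
    def load(cls, path) -> "PathwayActivityModel":
        with open(path) as handle:
            return cls.from_text(handle.read())


def discretize_expression(X: pd.DataFrame, definition: PathwayDefinition,
                          thresholds: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """Discretize expression to per-gene evidence states.

    ``X`` is samples x probes (log2).  Probes of a gene are aggregated by
    mean intensity, thresholds by mean threshold, then compared: intensity
    >= threshold is ``high`` (ties high by convention), below is ``low``.
    Genes without any probe on the platform come back as ``missing``.
    Non-finite aggregated intensities also yield ``missing``.
    """
    thresholds = pd.Series(dict(thresholds) if not isinstance(thresholds, pd.Series)
                           else thresholds, dtype=float)
    values, gene_thr, unmapped = _gene_level(X, definition, thresholds)
    ev = pd.DataFrame("missing", index=X.index,
                      columns=list(definition.target_genes), dtype=object)
    for gene in values.columns:
        v = values[gene]
        ok = np.isfinite(v.to_numpy(dtype=float))
        ev.loc[ok, gene] = np.where(v[ok] >= gene_thr[gene], "high", "low")
    return ev


def calibrate_model(definition: PathwayDefinition, expression: pd.DataFrame,
                    labels: Mapping[str, str] | pd.Series,
                    pseudocount: float = 1.0,
                    prior_active: float = 0.5) -> PathwayActivityModel:
    """Calibrate a pathway model from a labeled calibration set.

    ``expression`` is probes x samples (the TSV layout); ``labels`` maps
    sample id -> ``active``/``inactive`` and must cover samples present in
    the matrix only.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    unknown = set(labels.index) - set(expression.columns)
    if unknown:
        raise ValueError(f"labels refer to samples not in the matrix: {sorted(unknown)}")
    X = expression[labels.index.tolist()].T
    return PathwayActivityModel(definition, prior_active=prior_active,
                                pseudocount=pseudocount).fit(X, labels.to_numpy())


def score_sample(model: PathwayActivityModel, evidence: Mapping[str, str]) -> float:
    """Functional alias for :meth:`PathwayActivityModel.score_evidence`."""
    return model.score_evidence(evidence)


def score_matrix(models: Iterable[PathwayActivityModel],
                 expression: pd.DataFrame) -> pd.DataFrame:
    """Score every pathway on every sample.

    ``expression`` is probes x samples.  Returns the PAS matrix (pathways x
    samples, log2-odds units), complete over the cross product with sample
    order preserved.  Scores are on each pathway's own scale and must not be
    compared across pathways within a sample.
    """
    models = list(models)
    names = [m.definition.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError("duplicate pathway names among models")
    X = expression.T
    rows = {}
    for model in models:
        try:
            rows[model.definition.name] = model.decision_function(X)
        except Exception as exc:
            raise RuntimeError(
                f"scoring pathway {model.definition.name!r} failed: {exc}"
            ) from exc
    pas = pd.DataFrame(rows, index=expression.columns).T
    pas.index.name = "pathway"
    pas.columns.name = "sample"
    pas.attrs["model_format_version"] = MODEL_FORMAT_VERSION
    pas.attrs["units"] = "log2_odds"
    return pas


def enumerate_posterior_oracle(model: PathwayActivityModel,
                               evidence: Mapping[str, str]) -> float:
    """Brute-force PAS by enumerating the full joint distribution.

    Independent cross-check of :func:`score_sample`: builds the explicit
    joint P(TF state, evidence configuration) over all 2^n high/low
    configurations of the target genes, conditions on the observed evidence
    by summation (missing genes are marginalized), and returns the log2
    posterior odds.  Refuses models with more than 12 genes.
    """
    model._check_fitted()
    genes = list(model.definition.target_genes)
    if len(genes) > 12:
        raise ValueError("enumeration oracle limited to <= 12 target genes")
    for gene, state in evidence.items():
        if gene not in model.definition.target_genes:
            raise ValueError(f"evidence for non-target gene {gene!r}")
        if state not in EVIDENCE_STATES:
            raise ValueError(f"invalid evidence state {state!r}")
    observed = {g: evidence.get(g, "missing") for g in genes}
    p_high = {
        ACTIVE: {g: float(model.cpt_.loc[g, "p_high_active"]) for g in genes},
        INACTIVE: {g: float(model.cpt_.loc[g, "p_high_inactive"]) for g in genes},
    }
    prior = {ACTIVE: model.prior_active_, INACTIVE: 1.0 - model.prior_active_}
    total = {ACTIVE: 0.0, INACTIVE: 0.0}
    for state in (ACTIVE, INACTIVE):
        for config in itertools.product(("high", "low"), repeat=len(genes)):
            if any(observed[g] != "missing" and c != observed[g]
                   for g, c in zip(genes, config)):
                continue
            prob = prior[state]
            for g, c in zip(genes, config):
                prob *= p_high[state][g] if c == "high" else 1.0 - p_high[state][g]
            total[state] += prob
    return math.log2(total[ACTIVE] / total[INACTIVE])
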