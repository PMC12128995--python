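"""Cross-validated binary molecular classifiers.

Four phenotype classifiers are trained on expression features: low function
(eGFR <= 30 mL/min/1.73m2), proteinuria positivity, fibrosis (ci lesion
score > 1) and atrophy (ct lesion score > 1). Each is a stratified k-fold
pipeline — univariate feature filter and a regularized logistic model, both
fitted strictly inside the training fold — that yields out-of-fold
probabilities for labeled biopsies, a refit full-data model for projecting
unlabeled biopsies, and the out-of-fold AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .io import ExpressionMatrix, SampleMetadata

#: label_name -> (metadata column, rule description)
LABEL_RULES = {
    "lowGFR": ("egfr", "eGFR <= 30"),
    "proteinuria": ("proteinuria_pos", "proteinuria positive"),
    "ci_gt1": ("ci_score", "ci > 1"),
    "ct_gt1": ("ct_score", "ct > 1"),
}

#: classifier name -> canonical score-table column
PROB_COLUMNS = {
    "lowGFR": "lowGFR_Prob",
    "proteinuria": "Prot_Prob",
    "ci_gt1": "ci_gt1_Prob",
    "ct_gt1": "ct_gt1_Prob",
}


@dataclass
class ClassifierSpec:
    """Recipe for one binary classifier."""

    label_name: str
    n_folds: int = 10
    n_top_features: int = 30
    model_family: str = "logistic"
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label_name not in LABEL_RULES:
            raise ValueError(
                f"unknown label {self.label_name!r}; expected one of {sorted(LABEL_RULES)}"
            )
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.model_family != "logistic":
            raise ValueError(f"unsupported model family {self.model_family!r}")


@dataclass
class ClassifierResult:
    """Out-of-fold probabilities, projections, AUC, and fold bookkeeping."""

    spec: ClassifierSpec
    oof_probs: pd.Series
    projected_probs: pd.Series
    auc: float
    fold_assignments: pd.Series
    fold_features: list[list[str]] = field(default_factory=list)
    final_model: Pipeline | None = None
    feature_names: list[str] | None = None

    def predict(self, expr: ExpressionMatrix, sample_ids=None) -> pd.Series:
        """Probabilities for arbitrary samples through the full-data model."""
        ids = sample_ids if sample_ids is not None else expr.biopsy_ids
        X = expr.values[ids].T[self.feature_names].to_numpy()
        return pd.Series(
            self.final_model.predict_proba(X)[:, 1], index=ids, name=self.spec.label_name
        )


def derive_label(meta: SampleMetadata, spec: ClassifierSpec):
    """Binary labels plus an eligibility mask from the phenotype rule.

    Biopsies with a missing phenotype are ineligible for training but remain
    available for projection. Labels must contain both classes.
    """
    column, _ = LABEL_RULES[spec.label_name]
    if column not in meta.df.columns:
        raise ValueError(f"metadata lacks phenotype column {column!r}")
    values = pd.to_numeric(meta.df[column], errors="coerce")
    eligible = values.notna()
    if not eligible.any():
        raise ValueError(f"phenotype {column!r} is missing for every biopsy")
    if spec.label_name == "lowGFR":
        labels = (values <= 30).astype(float)
    elif spec.label_name == "proteinuria":
        labels = (values > 0).astype(float)
    else:  # ci_gt1 / ct_gt1
        labels = (values > 1).astype(float)
    labels[~eligible] = np.nan
    present = labels.dropna().unique()
    if len(present) < 2:
        raise ValueError(
            f"label {spec.label_name!r} has a single class; cannot train"
        )
    return labels, eligible


def _make_pipeline(spec: ClassifierSpec, n_features: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("select", SelectKBest(f_classif, k=min(spec.n_top_features, n_features))),
            (
                "model",
                LogisticRegression(C=spec.C, max_iter=2000, random_state=spec.seed),
            ),
        ]
    )


def train_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    spec: ClassifierSpec,
) -> ClassifierResult:
    """Stratified k-fold training with in-fold feature selection.

    ``features`` is samples x probes; ``labels`` is aligned, with NaN marking
    biopsies to project but not train on. Feature selection and scaling are
    fitted inside each training fold only, so out-of-fold probabilities come
    from models that never saw the held-out biopsy.
    """
    labels = labels.reindex(features.index)
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    labeled = labels.notna().to_numpy()
    y = labels.to_numpy(dtype=float)
    classes, counts = np.unique(y[labeled], return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < spec.n_folds:
        raise ValueError(
            f"minority class has {counts.min()} members < n_folds={spec.n_folds}"
        )

    lab_idx = np.flatnonzero(labeled)
    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    oof = np.full(len(features), np.nan)
    fold_of = np.full(len(features), -1)
    fold_features: list[list[str]] = []
    for f, (tr, te) in enumerate(skf.split(X[lab_idx], y[lab_idx])):
        tr_idx, te_idx = lab_idx[tr], lab_idx[te]
        pipe = _make_pipeline(spec, X.shape[1])
        pipe.fit(X[tr_idx], y[tr_idx])
        oof[te_idx] = pipe.predict_proba(X[te_idx])[:, 1]
        fold_of[te_idx] = f
        mask = pipe.named_steps["select"].get_support()
        fold_features.append(list(features.columns[mask]))

    final = _make_pipeline(spec, X.shape[1])
    final.fit(X[lab_idx], y[lab_idx])
    unlab_idx = np.flatnonzero(~labeled)
    projected = pd.Series(
        final.predict_proba(X[unlab_idx])[:, 1] if len(unlab_idx) else [],
        index=features.index[unlab_idx],
        dtype=float,
    )
    oof_series = pd.Series(oof, index=features.index).dropna()
    result_auc = auc(oof[labeled], y[labeled])
    return ClassifierResult(
        spec=spec,
        oof_probs=oof_series,
        projected_probs=projected,
        auc=result_auc,
        fold_assignments=pd.Series(fold_of, index=features.index),
        fold_features=fold_features,
        final_model=final,
        feature_names=list(features.columns),
    )


def auc(probs, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (ties count 1/2)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def classifier_probabilities(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    n_folds: int = 10,
    n_top_features: int = 30,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, ClassifierResult]]:
    """Train all four classifiers and assemble their probability columns.

    Labeled biopsies get their out-of-fold probability (never a prediction
    from a model that saw them); unlabeled biopsies get the full-data model's
    projection.
    """
    ids = sample_ids if sample_ids is not None else expr.biopsy_ids
    ids = [s for s in ids if s in set(meta.sample_ids)]
    features = expr.values[ids].T
    results: dict[str, ClassifierResult] = {}
    cols: dict[str, pd.Series] = {}
    for name, col in PROB_COLUMNS.items():
        spec = ClassifierSpec(
            label_name=name, n_folds=n_folds, n_top_features=n_top_features, seed=seed
        )
        labels, _ = derive_label(SampleMetadata(meta.df.loc[ids]), spec)
        res = train_cv(features, labels, spec)
        results[name] = res
        cols[col] = pd.concat([res.oof_probs, res.projected_probs]).reindex(ids)
    return pd.DataFrame(cols, index=pd.Index(ids, name="sample_id")), results
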