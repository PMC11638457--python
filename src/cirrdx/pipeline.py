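"""End-to-end orchestration shared by the CLI, tests and the acceptance
script: preprocessing a cohort into slice packs, training the CNN ensemble
and the combined random-forest model, and scoring held-out cases with the
CNN, combined, FIB-4 and APRI comparators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import cnn as cnn_mod
from . import fusion, serum
from .errors import DegenerateInputError
from .phantom import ANALYTES, PhantomCase
from .preprocess import AugmentConfig, MriStudy, preprocess_stack

log = logging.getLogger(__name__)

__all__ = ["PipelineArtifacts", "stratified_split", "build_packs",
           "feature_matrix", "train_pipeline", "score_cases"]

FEATURE_COLUMNS = ["cnn_prob", *ANALYTES]


@dataclass
class PipelineArtifacts:
    ensemble: cnn_mod.CnnEnsemble
    combined: fusion.CombinedModel
    vif_report: fusion.VifReport
    selected_features: list[str]
    selection_importances: pd.Series
    cnn_cutoff: float
    extras: dict = field(default_factory=dict)


def stratified_split(labels, fraction: float = 0.9, seed: int = 0):
    """Index split (train, test) stratified by label."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("both classes required to stratify")
    idx = np.arange(labels.size)
    train, test = train_test_split(idx, train_size=fraction, stratify=labels,
                                   random_state=seed)
    return np.sort(train), np.sort(test)


def build_packs(studies: list[MriStudy], labels, size: int = 64,
                sequences: tuple[str, ...] = ("T1pre", "T2")):
    """Preprocess each study into (case_id, channel array, label)."""
    cohort = []
    for study, label in zip(studies, labels):
        pack = preprocess_stack(study, size=size, sequences=sequences)
        cohort.append((study.case_id, pack.slices, int(label)))
    return cohort


def feature_matrix(frame: pd.DataFrame, cnn_probs: pd.Series) -> pd.DataFrame:
    """Combined-model candidate features: CNN probability, age and the eight
    serum biomarkers, indexed by case id."""
    X = frame.set_index("case_id")[list(ANALYTES)].astype(float)
    X.insert(0, "cnn_prob", cnn_probs.reindex(X.index))
    if X["cnn_prob"].isna().any():
        missing = list(X.index[X["cnn_prob"].isna()])
        raise DegenerateInputError(f"no CNN probability for cases {missing[:5]}")
    return X


def train_pipeline(studies: list[MriStudy], frame: pd.DataFrame,
                   train_config: cnn_mod.TrainConfig,
                   augment_cfg: AugmentConfig | None = None,
                   rf_grid: dict | None = None) -> PipelineArtifacts:
    """Train the CNN ensemble then the combined model on one cohort.

    Combined-model features for training cases use out-of-fold CNN
    probabilities so the fusion stage never sees resubstitution scores.
    """
    labels = frame.set_index("case_id")["label"]
    cohort = build_packs(studies, [labels[s.case_id] for s in studies],
                         size=train_config.image_size, sequences=train_config.sequences)
    ensemble = cnn_mod.crossval_train(cohort, train_config, augment_cfg=augment_cfg)
    oof = pd.Series(ensemble.oof_probs)

    from .evalstats import ScoredCohort, youden_cutoff

    y = labels.reindex(oof.index).to_numpy()
    cnn_cutoff = youden_cutoff(ScoredCohort(oof.to_numpy(), y))

    X = feature_matrix(frame, oof)
    y_all = labels.reindex(X.index).to_numpy()
    X_reduced, vif_report = fusion.resolve_collinearity(X, y_all)
    selected, importances = fusion.select_features_gini(
        X_reduced, y_all, seed=train_config.seed)
    combined = fusion.fit_combined(X_reduced[selected], y_all, grid=rf_grid,
                                   seed=train_config.seed)
    return PipelineArtifacts(ensemble=ensemble, combined=combined,
                             vif_report=vif_report, selected_features=selected,
                             selection_importances=importances, cnn_cutoff=float(cnn_cutoff))


def score_cases(artifacts: PipelineArtifacts, studies: list[MriStudy],
                frame: pd.DataFrame,
                serum_cfg: serum.SerumConfig = serum.SerumConfig()) -> pd.DataFrame:
    """Score held-out cases with every comparator.

    Returns a frame indexed by case id with columns label, cnn_prob,
    combined_prob, fib4, apri.
    """
    config = artifacts.ensemble.config
    labels = frame.set_index("case_id")["label"]
    rows = {}
    for study in studies:
        pack = preprocess_stack(study, size=config.image_size, sequences=config.sequences)
        rows[study.case_id] = cnn_mod.predict_proba(artifacts.ensemble, pack)
    cnn_probs = pd.Series(rows, name="cnn_prob")
    X = feature_matrix(frame[frame["case_id"].isin(cnn_probs.index)], cnn_probs)
    combined_probs = fusion.predict_combined(artifacts.combined, X)
    out = pd.DataFrame({
        "label": labels.reindex(X.index).astype(int),
        "cnn_prob": X["cnn_prob"],
        "combined_prob": combined_probs,
    })
    indexed = serum.add_serum_indices(frame.set_index("case_id").loc[out.index],
                                      serum_cfg)
    out["fib4"] = indexed["fib4"]
    out["apri"] = indexed["apri"]
    return out
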