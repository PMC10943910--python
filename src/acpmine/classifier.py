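"""Linear max-margin ACP/non-ACP classifier with a calibrated [0,1] score.

A soft-margin linear SVM on z-standardized composition features, with the
raw decision values mapped to [0,1] by a logistic (Platt-style) calibration
fitted on the training decision values. Standardization statistics, weights
and the calibration map are frozen into the model at train time and never
recomputed at predict time. Models serialize to a versioned structured-text
file with an integrity checksum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .features import (ACP, FEATURE_IDS, LABEL_COLUMN, NON_ACP,
                       composition_vector, select_features, selected_feature_ids)

MODEL_FORMAT_VERSION = "1.0"


@dataclass(frozen=True)
class TrainConfig:
    """Training settings; the seed is mandatory for reproducibility."""

    seed: int
    C: float = 1.0
    alpha: float = 0.05          # Bonferroni level for feature selection
    use_selected_only: bool = True
    threshold: float = 0.5
    equal_var: bool = False


class ACPClassifier(BaseEstimator, ClassifierMixin):
    """sklearn estimator: linear SVM + Platt calibration on composition features.

    Parameters mirror :class:`TrainConfig`. ``fit`` takes a numeric feature
    matrix (columns in the frozen contract order, or ``feature_ids`` given
    explicitly) and string labels {ACP, nonACP}. Prediction is ACP iff the
    calibrated score strictly exceeds ``threshold``.
    """

    def __init__(self, C: float = 1.0, threshold: float = 0.5,
                 random_state: int = 0, feature_ids: Sequence[str] | None = None):
        self.C = C
        self.threshold = threshold
        self.random_state = random_state
        self.feature_ids = feature_ids

    def fit(self, X, y) -> "ACPClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        labels = set(y)
        if labels != {ACP, NON_ACP}:
            raise ValueError(f"need both classes {{{ACP!r},{NON_ACP!r}}}, got {sorted(labels)}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")
        ids = list(self.feature_ids) if self.feature_ids is not None else list(FEATURE_IDS[: X.shape[1]])
        if len(ids) != X.shape[1]:
            raise ValueError("feature_ids length does not match X columns")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if np.any(np.isclose(sd, 0.0)):
            degenerate = [ids[i] for i in np.flatnonzero(np.isclose(sd, 0.0))]
            raise ValueError(f"constant feature(s) after selection: {degenerate[:5]}")
        Z = (X - mean) / sd
        ybin = (y == ACP).astype(int)
        svc = LinearSVC(C=self.C, random_state=self.random_state)
        svc.fit(Z, ybin)
        decision = svc.decision_function(Z)
        calib = LogisticRegression(C=1e6, random_state=self.random_state)
        calib.fit(decision.reshape(-1, 1), ybin)

        self.classes_ = np.array([NON_ACP, ACP])
        self.feature_ids_ = ids
        self.mean_ = mean
        self.scale_ = sd
        self.coef_ = svc.coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        self.calib_slope_ = float(calib.coef_[0, 0])
        self.calib_intercept_ = float(calib.intercept_[0])
        self.n_features_in_ = X.shape[1]
        self.n_per_class_ = {ACP: int(ybin.sum()), NON_ACP: int(len(ybin) - ybin.sum())}
        return self

    # -- scoring ---------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_ids_):
            raise ValueError(f"model expects {len(self.feature_ids_)} features, got {X.shape[1]}")
        Z = (X - self.mean_) / self.scale_
        return Z @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        d = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-(self.calib_slope_ * d + self.calib_intercept_)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return np.where(p > self.threshold, ACP, NON_ACP)

    # -- peptide-level convenience --------------------------------------
    def _vectorize(self, peptide: str) -> np.ndarray:
        full = dict(zip(FEATURE_IDS, composition_vector(peptide)))
        try:
            return np.array([[full[f] for f in self.feature_ids_]])
        except KeyError as exc:
            raise ValueError(f"model feature {exc} is not a composition feature") from exc

    def score_peptide(self, peptide: str) -> float:
        """Calibrated ACP propensity of one peptide, in [0, 1]."""
        return float(self.predict_proba(self._vectorize(peptide))[0, 1])

    def score_peptides(self, peptides: Sequence[str],
                       chunk_size: int = 20000) -> np.ndarray:
        """Batch version of :meth:`score_peptide`; chunked to bound memory."""
        check_is_fitted(self, "coef_")
        feat_index = {f: i for i, f in enumerate(FEATURE_IDS)}
        cols = np.array([feat_index[f] for f in self.feature_ids_])
        out = np.empty(len(peptides))
        for start in range(0, len(peptides), chunk_size):
            chunk = peptides[start : start + chunk_size]
            X = np.vstack([composition_vector(p) for p in chunk])[:, cols]
            out[start : start + len(chunk)] = self.predict_proba(X)[:, 1]
        return out

    def predict_peptide(self, peptide: str) -> str:
        """ACP iff the score strictly exceeds the threshold, else nonACP."""
        return ACP if self.score_peptide(peptide) > self.threshold else NON_ACP


def train(table: pd.DataFrame, config: TrainConfig) -> ACPClassifier:
    """Train on a labelled feature table, with Bonferroni feature selection.

    When ``use_selected_only`` (default), only Bonferroni-significant
    features enter the model; if none survive, all testable features are
    used. Deterministic given (table, config).
    """
    feats = [c for c in table.columns if c != LABEL_COLUMN]
    selection = select_features(table, alpha=config.alpha, equal_var=config.equal_var)
    if config.use_selected_only:
        keep = selected_feature_ids(selection)
        if not keep:
            keep = selection.loc[selection["testable"], "feature_id"].tolist()
    else:
        keep = selection.loc[selection["testable"], "feature_id"].tolist()
    if not keep:
        raise ValueError("no usable features: every composition feature is "
                         "constant within both classes")
    model = ACPClassifier(C=config.C, threshold=config.threshold,
                          random_state=config.seed, feature_ids=keep)
    model.fit(table[keep].to_numpy(dtype=float), table[LABEL_COLUMN].to_numpy())
    model.train_config_ = config
    return model


# -- serialization --------------------------------------------------------

def _payload(model: ACPClassifier) -> dict:
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_ids": list(model.feature_ids_),
        "mean": model.mean_.tolist(),
        "scale": model.scale_.tolist(),
        "weights": model.coef_.tolist(),
        "bias": model.intercept_,
        "calibration": {"slope": model.calib_slope_, "intercept": model.calib_intercept_},
        "threshold": model.threshold,
        "C": model.C,
        "random_state": model.random_state,
        "n_per_class": model.n_per_class_,
    }


def save_model(model: ACPClassifier, path: str | Path) -> None:
    """Write a versioned JSON model file with a sha256 integrity checksum."""
    payload = _payload(model)
    body = json.dumps(payload, sort_keys=True)
    doc = {"checksum": hashlib.sha256(body.encode()).hexdigest(), "model": payload}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> ACPClassifier:
    """Load a model file; verifies checksum and major format version."""
    doc = json.loads(Path(path).read_text())
    payload = doc["model"]
    body = json.dumps(payload, sort_keys=True)
    if hashlib.sha256(body.encode()).hexdigest() != doc["checksum"]:
        raise ValueError(f"{path}: checksum mismatch (corrupted model file)")
    major = str(payload["format_version"]).split(".")[0]
    if major != MODEL_FORMAT_VERSION.split(".")[0]:
        raise ValueError(f"{path}: unsupported model format version {payload['format_version']}")
    model = ACPClassifier(C=payload["C"], threshold=payload["threshold"],
                          random_state=payload["random_state"],
                          feature_ids=payload["feature_ids"])
    model.classes_ = np.array([NON_ACP, ACP])
    model.feature_ids_ = list(payload["feature_ids"])
    model.mean_ = np.asarray(payload["mean"], dtype=float)
    model.scale_ = np.asarray(payload["scale"], dtype=float)
    model.coef_ = np.asarray(payload["weights"], dtype=float)
    model.intercept_ = float(payload["bias"])
    model.calib_slope_ = float(payload["calibration"]["slope"])
    model.calib_intercept_ = float(payload["calibration"]["intercept"])
    model.n_features_in_ = len(model.feature_ids_)
    model.n_per_class_ = payload["n_per_class"]
    return model


# -- evaluation -----------------------------------------------------------

def cross_validate(table: pd.DataFrame, config: TrainConfig, k: int = 5) -> pd.DataFrame:
    """Stratified k-fold evaluation; returns per-fold and mean metrics.

    Feature selection and training are re-run inside each training fold so
    the reported metrics are free of selection leakage.
    """
    y = table[LABEL_COLUMN].to_numpy()
    counts = pd.Series(y).value_counts()
    if k < 2:
        raise ValueError("k must be >= 2")
    if (counts < k).any():
        raise ValueError(f"k={k} exceeds the size of the smallest class ({counts.min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = train(table.iloc[tr], config)
        X_te = table.iloc[te][model.feature_ids_].to_numpy(dtype=float)
        pred = model.predict(X_te)
        truth = y[te]
        tp = int(((pred == ACP) & (truth == ACP)).sum())
        tn = int(((pred == NON_ACP) & (truth == NON_ACP)).sum())
        fp = int(((pred == ACP) & (truth == NON_ACP)).sum())
        fn = int(((pred == NON_ACP) & (truth == ACP)).sum())
        rows.append({
            "fold": fold,
            "accuracy": (tp + tn) / len(te),
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        })
    df = pd.DataFrame(rows)
    mean = df.drop(columns="fold").mean().to_dict()
    df.loc[len(df)] = {"fold": "mean", **mean}
    return df
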