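"""Composition features and discriminative feature selection.

The feature space is the 20 mono-residue frequencies (alphabetical,
A..Y) followed by the 400 overlapping-dipeptide frequencies (lexicographic,
AA..YY). This 420-column ordering is a frozen contract: trained models store
feature ids and refuse to score under a different ordering.

Class-discriminative features are found by per-feature two-sided t-tests
(Welch by default) with Bonferroni family-wise correction, mirroring the
standard workflow for composition-based peptide classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .seqio import PROTEIN_ALPHABET, validate_peptide

MONO_FEATURES: tuple[str, ...] = tuple(PROTEIN_ALPHABET)
DI_FEATURES: tuple[str, ...] = tuple(a + b for a in PROTEIN_ALPHABET for b in PROTEIN_ALPHABET)
FEATURE_IDS: tuple[str, ...] = MONO_FEATURES + DI_FEATURES  # frozen 420-column contract
_MONO_INDEX = {aa: i for i, aa in enumerate(MONO_FEATURES)}
_DI_INDEX = {di: i for i, di in enumerate(DI_FEATURES)}

LABEL_COLUMN = "label"
ACP, NON_ACP = "ACP", "nonACP"


def mono_composition(peptide: str) -> np.ndarray:
    """Residue frequencies (20-vector, alphabetical order), summing to 1."""
    pep = validate_peptide(peptide)
    v = np.zeros(20)
    for aa in pep:
        v[_MONO_INDEX[aa]] += 1.0
    return v / len(pep)


def dipeptide_composition(peptide: str) -> np.ndarray:
    """Overlapping-bigram frequencies (400-vector, lexicographic order).

    Normalized by (length - 1); a length-1 peptide yields the all-zero vector.
    """
    pep = validate_peptide(peptide)
    v = np.zeros(400)
    if len(pep) < 2:
        return v
    for i in range(len(pep) - 1):
        v[_DI_INDEX[pep[i : i + 2]]] += 1.0
    return v / (len(pep) - 1)


def composition_vector(peptide: str) -> np.ndarray:
    """Full 420-dimensional feature vector (20 mono then 400 di)."""
    return np.concatenate([mono_composition(peptide), dipeptide_composition(peptide)])


class CompositionFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer mapping peptide strings to 420-d vectors."""

    def fit(self, X: Sequence[str], y=None) -> "CompositionFeaturizer":
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        return np.vstack([composition_vector(p) for p in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_IDS, dtype=object)


def featurize_set(peptides: Iterable[str], labels: Iterable[str],
                  ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Build the labelled feature table (rows = peptides, 420 feature columns).

    Column order is the frozen contract (20 mono then 400 di) plus a trailing
    ``label`` column; row order follows the input.
    """
    peptides = list(peptides)
    labels = list(labels)
    if len(peptides) != len(labels):
        raise ValueError("peptides and labels differ in length")
    bad = set(labels) - {ACP, NON_ACP}
    if bad:
        raise ValueError(f"labels must be in {{{ACP!r}, {NON_ACP!r}}}, got {sorted(bad)}")
    X = CompositionFeaturizer().fit_transform(peptides)
    index = list(ids) if ids is not None else pd.RangeIndex(len(peptides))
    df = pd.DataFrame(X, columns=list(FEATURE_IDS), index=index)
    df[LABEL_COLUMN] = labels
    return df


def welch_t_test(group_a: np.ndarray, group_b: np.ndarray,
                 equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided two-sample t-test: returns (t, df, p_raw).

    Welch (unequal variances, Welch-Satterthwaite df) by default; Student's
    pooled-variance variant with ``equal_var=True``. Two constant and equal
    groups are defined as t = 0, p = 1 (no evidence, not an error).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    if np.isnan(t):  # both groups constant
        if np.isclose(a.mean(), b.mean()):
            return 0.0, df if np.isfinite(df) else float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate test: zero variance with unequal means")
    return t, df, p


@dataclass(frozen=True)
class FeatureTestResult:
    feature_id: str
    t_stat: float
    df: float
    p_raw: float
    p_adj: float
    selected: bool


def select_features(table: pd.DataFrame, alpha: float = 0.05,
                    equal_var: bool = False) -> pd.DataFrame:
    """Per-feature t-tests with Bonferroni correction over the testable features.

    Features with zero variance in both groups are untestable and excluded
    from the Bonferroni multiplier m; for the rest, ``p_adj = min(1, m * p_raw)``
    and ``selected`` iff ``p_adj < alpha``. Returns a DataFrame with columns
    (feature_id, t_stat, df, p_raw, p_adj, selected, testable).
    """
    if LABEL_COLUMN not in table.columns:
        raise ValueError(f"table must carry a {LABEL_COLUMN!r} column")
    groups = table[LABEL_COLUMN]
    present = set(groups)
    if present != {ACP, NON_ACP}:
        raise ValueError(f"both labels required, found {sorted(present)}")
    feats = [c for c in table.columns if c != LABEL_COLUMN]
    A = table.loc[groups == ACP, feats].to_numpy(dtype=float)
    B = table.loc[groups == NON_ACP, feats].to_numpy(dtype=float)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each class needs at least 2 rows")

    res = stats.ttest_ind(A, B, equal_var=equal_var, axis=0)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)
    testable = ~(np.isclose(A.var(axis=0), 0.0) & np.isclose(B.var(axis=0), 0.0))
    m = int(testable.sum())
    p_adj = np.minimum(1.0, m * p)
    out = pd.DataFrame({
        "feature_id": feats,
        "t_stat": np.where(testable, t, 0.0),
        "df": np.where(testable, df, np.nan),
        "p_raw": np.where(testable, p, np.nan),
        "p_adj": np.where(testable, p_adj, np.nan),
        "testable": testable,
    })
    out["selected"] = testable & (p_adj < alpha)
    return out


def selected_feature_ids(selection: pd.DataFrame) -> list[str]:
    return selection.loc[selection["selected"], "feature_id"].tolist()


class WelchBonferroniSelector(SelectorMixin, BaseEstimator):
    """sklearn feature selector: keep Bonferroni-significant Welch-t features.

    Operates on numeric feature matrices in the frozen 420-column order (or
    any consistent column set passed via ``feature_ids``). If no feature
    survives correction, all features are kept (the selection step then
    becomes a no-op rather than emptying the design matrix).
    """

    def __init__(self, alpha: float = 0.05, equal_var: bool = False,
                 feature_ids: Sequence[str] | None = None):
        self.alpha = alpha
        self.equal_var = equal_var
        self.feature_ids = feature_ids

    def fit(self, X, y) -> "WelchBonferroniSelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        ids = list(self.feature_ids) if self.feature_ids is not None else list(FEATURE_IDS[: X.shape[1]])
        if len(ids) != X.shape[1]:
            raise ValueError("feature_ids length does not match X")
        table = pd.DataFrame(X, columns=ids)
        table[LABEL_COLUMN] = y
        self.results_ = select_features(table, alpha=self.alpha, equal_var=self.equal_var)
        mask = self.results_["selected"].to_numpy()
        if not mask.any():
            mask = np.ones(X.shape[1], dtype=bool)
        self.support_mask_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_mask_")
        return self.support_mask_
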