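"""Pairwise protein-protein interaction prediction.

A protein pair is summarised by symmetric features computed from shared
annotation resources — co-expression across a compendium, Jaccard overlap
of molecular-function / biological-process / localisation term sets,
same-chromosome indicator and log genomic proximity — and classified as
interacting or non-interacting by a random-forest ensemble whose
predicted probability is the interaction score.  Predicted partners are
called at score strictly greater than 0.5.

Missing annotations are imputed with neutral zeros and counted in an
``n_missing`` feature, so sparsely annotated genes are scored rather than
discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.metrics import precision_score, recall_score, roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .io import EdgeRecord, ValidationError, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationResource",
    "PairFeatureVector",
    "FEATURE_NAMES",
    "compute_pair_features",
    "PairInteractionClassifier",
    "train",
    "predict_candidates",
]

FEATURE_NAMES = (
    "coexpr",
    "mf_jaccard",
    "bp_jaccard",
    "loc_jaccard",
    "same_chrom",
    "log_prox",
    "n_missing",
)


@dataclass
class AnnotationResource:
    """Per-gene annotation sets, genomic coordinates and an expression
    compendium (genes x conditions), any of which may be sparse."""

    localization: dict[str, frozenset[str]] = field(default_factory=dict)
    mf_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    bp_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    chromosome: dict[str, str] = field(default_factory=dict)
    position: dict[str, int] = field(default_factory=dict)
    expression: pd.DataFrame | None = None  # genes x conditions


@dataclass(frozen=True)
class PairFeatureVector:
    coexpr: float
    mf_jaccard: float
    bp_jaccard: float
    loc_jaccard: float
    same_chrom: float
    log_prox: float
    n_missing: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def _jaccard(a: frozenset | None, b: frozenset | None) -> tuple[float, int]:
    if not a or not b:
        return 0.0, 1
    inter = len(a & b)
    union = len(a | b)
    return inter / union, 0


def compute_pair_features(a: str, b: str, res: AnnotationResource) -> PairFeatureVector:
    """Symmetric feature vector for an unordered gene pair."""
    a, b = normalize_symbol(a), normalize_symbol(b)
    if a == b:
        raise ValidationError("cannot compute pair features for a self-pair")
    n_missing = 0

    coexpr = 0.0
    expr = res.expression
    if expr is not None and a in expr.index and b in expr.index:
        xa = expr.loc[a].to_numpy(dtype=float)
        xb = expr.loc[b].to_numpy(dtype=float)
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() >= 3 and np.std(xa[ok]) > 0 and np.std(xb[ok]) > 0:
            coexpr = float(np.corrcoef(xa[ok], xb[ok])[0, 1])
        else:
            n_missing += 1
    else:
        n_missing += 1

    mf, m1 = _jaccard(res.mf_terms.get(a), res.mf_terms.get(b))
    bp, m2 = _jaccard(res.bp_terms.get(a), res.bp_terms.get(b))
    loc, m3 = _jaccard(res.localization.get(a), res.localization.get(b))
    n_missing += m1 + m2 + m3

    ca, cb = res.chromosome.get(a), res.chromosome.get(b)
    if ca is None or cb is None:
        same_chrom, log_prox = 0.0, 0.0
        n_missing += 1
    elif ca == cb:
        same_chrom = 1.0
        pa, pb = res.position.get(a), res.position.get(b)
        log_prox = math.log10(1 + abs(pa - pb)) if pa is not None and pb is not None else 0.0
    else:
        same_chrom, log_prox = 0.0, 0.0

    return PairFeatureVector(coexpr, mf, bp, loc, same_chrom, log_prox, n_missing)


def _feature_matrix(pairs, res: AnnotationResource) -> np.ndarray:
    return np.vstack([compute_pair_features(a, b, res).as_array() for a, b in pairs])


class PairInteractionClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest classifier over pair feature vectors.

    scikit-learn compatible: ``fit(X, y)`` on a feature matrix with
    columns in ``FEATURE_NAMES`` order, ``predict_proba`` / ``score_pairs``
    for interaction scores in [0, 1].
    """

    def __init__(self, n_estimators: int = 500, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValidationError("training data must contain both classes")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.feature_names_ = FEATURE_NAMES
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(X, dtype=float))

    def score_pairs(self, pairs, res: AnnotationResource) -> np.ndarray:
        """Interaction score (probability of the positive class) per pair."""
        check_is_fitted(self, "forest_")
        X = _feature_matrix(pairs, res)
        pos = list(self.classes_).index(1)
        return self.predict_proba(X)[:, pos]


def train(
    pairs,
    res: AnnotationResource,
    seed: int = 0,
    n_trees: int = 500,
    balance: bool = True,
) -> tuple[PairInteractionClassifier, dict]:
    """Train a pair classifier on labelled pairs and report 5-fold CV metrics.

    ``pairs`` is an iterable of ((gene_a, gene_b), label) with label 1 for
    interacting and 0 for non-interacting.  By default the larger class is
    downsampled (seeded) to a 1:1 ratio.
    """
    pairs = list(pairs)
    pos = [p for p, lab in pairs if lab == 1]
    neg = [p for p, lab in pairs if lab == 0]
    if not pos or not neg:
        raise ValidationError("training data must contain both classes")
    if min(len(pos), len(neg)) < 10:
        raise ValidationError("need at least 10 examples per class")
    rng = np.random.default_rng(seed)
    if balance:
        m = min(len(pos), len(neg))
        pos = [pos[i] for i in rng.choice(len(pos), m, replace=False)]
        neg = [neg[i] for i in rng.choice(len(neg), m, replace=False)]
    all_pairs = pos + neg
    y = np.array([1] * len(pos) + [0] * len(neg))
    X = _feature_matrix(all_pairs, res)

    clf = PairInteractionClassifier(n_estimators=n_trees, random_state=seed)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    proba = cross_val_predict(clf, X, y, cv=cv, method="predict_proba")[:, 1]
    pred = (proba > 0.5).astype(int)
    report = {
        "n_pos": int(len(pos)),
        "n_neg": int(len(neg)),
        "seed": int(seed),
        "cv_precision": float(precision_score(y, pred, zero_division=0)),
        "cv_recall": float(recall_score(y, pred)),
        "cv_auroc": float(roc_auc_score(y, proba)),
        "feature_order": list(FEATURE_NAMES),
    }
    clf.fit(X, y)
    return clf, report


def predict_candidates(
    model: PairInteractionClassifier,
    seeds,
    candidates,
    res: AnnotationResource,
    threshold: float = 0.5,
) -> list[EdgeRecord]:
    """Score every (seed, candidate) pair and return those with score
    strictly above the threshold, sorted by descending score."""
    check_is_fitted(model, "forest_")
    seeds = [normalize_symbol(s) for s in seeds]
    candidates = [normalize_symbol(c) for c in candidates]
    if not candidates:
        return []
    pairs = sorted({tuple(sorted((s, c))) for s in seeds for c in candidates if s != c})
    scores = model.score_pairs(pairs, res)
    records = [
        EdgeRecord.make(a, b, provenance="novel", source_tag="predicted", score=float(sc))
        for (a, b), sc in zip(pairs, scores)
        if sc > threshold
    ]
    return sorted(records, key=lambda e: (-(e.score or 0.0), e.pair))
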