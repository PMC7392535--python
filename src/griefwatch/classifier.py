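"""Relevance labeling of candidate tweets.

Annotation rules (codified from the coding protocol): a tweet is *relevant*
when it has at least one grief keyword hit and one territory hit, and is not
about a celebrity death, not about an out-of-city event, and its grief
keyword does not come solely from a mentioned handle. A supervised binary
classifier trained on masked, normalized token features generalizes these
judgements; masking makes the model territory-agnostic (sentinels such as
``_IDENTIFIER_`` are legitimate features). Inter-annotator and model-vs-rule
agreement are measured with Cohen's kappa.
"""

from __future__ import annotations

import pickle
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np

from .preprocessing import NormalizedTweet

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class RelevanceLabel:
    tweet_id: str
    label: str
    source: str  # rule | human | model
    score: float | None = None

    def __post_init__(self) -> None:
        if self.label not in (RELEVANT, IRRELEVANT):
            raise ValueError(f"bad label {self.label!r}")
        if self.source == "model":
            if self.score is None:
                raise ValueError("model labels require a score")
        elif self.score is not None:
            raise ValueError("score only allowed for model labels")


def rule_label(
    tweet_id: str,
    grief_hits: frozenset[str] | set[str],
    territory_hits: frozenset[str] | set[str],
    flags: dict,
) -> RelevanceLabel:
    """Deterministic annotation rule.

    ``flags`` must carry ``celebrity_subject``, ``out_of_city`` and
    ``keyword_only_in_handle`` context booleans (supplied by the synthetic
    generator or annotation tooling); rule labeling is undefined without them.
    """
    required = ("celebrity_subject", "out_of_city", "keyword_only_in_handle")
    missing = [k for k in required if k not in flags]
    if missing:
        raise ValueError(f"missing context flags: {missing}")
    relevant = (
        bool(grief_hits)
        and bool(territory_hits)
        and not flags["celebrity_subject"]
        and not flags["out_of_city"]
        and not flags["keyword_only_in_handle"]
    )
    return RelevanceLabel(tweet_id, RELEVANT if relevant else IRRELEVANT, "rule")


def _identity_analyzer(doc):
    """Token lists are already analyzed; module-level so models pickle."""
    return doc


@dataclass
class ClassifierModel:
    """Fitted linear relevance model over token-count features."""

    vectorizer: object
    estimator: object
    threshold: float = 0.5
    seed: int = 0
    version: int = MODEL_FORMAT_VERSION
    classes_: tuple[str, ...] = field(default=(IRRELEVANT, RELEVANT))

    def predict_proba_relevant(self, token_lists: Sequence[Sequence[str]]) -> np.ndarray:
        X = self.vectorizer.transform(token_lists)
        proba = self.estimator.predict_proba(X)
        rel_col = list(self.estimator.classes_).index(RELEVANT)
        return proba[:, rel_col]

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls) or model.version != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model file")
        return model


def train_classifier(
    labeled: Sequence[tuple[NormalizedTweet, RelevanceLabel]],
    seed: int = 0,
    threshold: float = 0.5,
    C: float = 1.0,
) -> ClassifierModel:
    """Fit an L2-regularized logistic regression on token-count features.

    Requires both classes present and at least 20 examples; reproducible for a
    fixed seed (the optimizer itself is deterministic — the seed is recorded
    and used for any downstream resampling).
    """
    from sklearn.feature_extraction.text import CountVectorizer
    from sklearn.linear_model import LogisticRegression

    if len(labeled) < 20:
        raise ValueError(f"need >= 20 labeled examples, got {len(labeled)}")
    y = [lab.label for _, lab in labeled]
    if len(set(y)) < 2:
        raise ValueError("training set must contain both classes")
    docs = [list(tw.tokens) for tw, _ in labeled]
    vectorizer = CountVectorizer(analyzer=_identity_analyzer, lowercase=False)
    X = vectorizer.fit_transform(docs)
    # liblinear solves the L2-regularized problem deterministically
    estimator = LogisticRegression(
        C=C, max_iter=1000, random_state=seed, solver="liblinear"
    )
    estimator.fit(X, y)
    return ClassifierModel(
        vectorizer=vectorizer, estimator=estimator, threshold=threshold, seed=seed
    )


def predict_relevance(
    model: ClassifierModel, tweets: NormalizedTweet | Sequence[NormalizedTweet]
) -> RelevanceLabel | list[RelevanceLabel]:
    """Label one tweet or a batch; batch output preserves order and length.

    An empty token list is scored from the intercept alone — never an error.
    """
    single = isinstance(tweets, NormalizedTweet)
    batch = [tweets] if single else list(tweets)
    if model.vectorizer is None or model.estimator is None:
        raise ValueError("model is not fitted")
    scores = model.predict_proba_relevant([list(t.tokens) for t in batch])
    labels = [
        RelevanceLabel(
            t.tweet_id,
            RELEVANT if s >= model.threshold else IRRELEVANT,
            "model",
            score=float(s),
        )
        for t, s in zip(batch, scores)
    ]
    return labels[0] if single else labels


def cohen_kappa(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e).

    ``p_o`` is the observed agreement rate; ``p_e`` the chance agreement
    implied by each rater's marginal label frequencies. Returns 1.0 for
    perfect agreement; when the marginals make chance agreement certain
    (p_e = 1) the statistic is undefined and 0.0 is returned with a warning.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label sequences differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    n = len(labels_a)
    if n == 0:
        raise ValueError("label sequences are empty")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    if p_o == 1.0:
        return 1.0
    ca, cb = Counter(labels_a), Counter(labels_b)
    cats = set(ca) | set(cb)
    p_e = sum((ca[c] / n) * (cb[c] / n) for c in cats)
    if p_e >= 1.0:
        warnings.warn(
            "kappa undefined: chance agreement is 1 (degenerate marginals); returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return (p_o - p_e) / (1 - p_e)


def confusion_matrix(
    truth: Sequence[str], predicted: Sequence[str]
) -> dict[tuple[str, str], int]:
    """(truth, predicted) -> count; entries sum to the evaluation-set size."""
    if len(truth) != len(predicted):
        raise ValueError("length mismatch")
    out: dict[tuple[str, str], int] = {}
    for t, p in zip(truth, predicted):
        out[(t, p)] = out.get((t, p), 0) + 1
    return out
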