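"""Per-user feature extraction and depression-detection classifiers.

Feature families per user (computed over the user's concatenated token
stream):

1. topic keywords      — relative frequency of each of 30 TF-IDF keywords
2. posting behavior    — mean post length (tokens) and total post count
3. first-person usage  — first-person pronoun tokens per 1000 tokens
4. linguistic style    — mean word-embedding vector of the user's tokens
5. lexicon usage       — depressive / nondepressive lexicon-word tokens per
                         1000 tokens (the two columns dropped by the
                         lexicon-free ablation)

Classifiers follow the usual screening line-up: naive Bayes, decision tree,
logistic regression, random forest, SVM; an ``L-`` prefixed variant of a
model is the same estimator with the lexicon columns included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from lexiprop.corpus_io import Corpus
from lexiprop.embeddings import EmbeddingSpace
from lexiprop.graph_lpa import Lexicon

__all__ = [
    "UserFeatures",
    "DEFAULT_PRONOUNS",
    "extract_features",
    "build_feature_table",
    "run_detection",
    "imbalance_sweep",
]

# first-person pronouns, English + Chinese defaults
DEFAULT_PRONOUNS = ("i", "me", "my", "we", "our", "us",
                    "我", "我们", "咱", "咱们", "俺")

LEXICON_COLUMNS = ("lexicon_dep_rate", "lexicon_nondep_rate")


@dataclass
class UserFeatures:
    user_id: str
    topic_keyword_freqs: np.ndarray
    avg_post_length: float
    total_posts: int
    first_person_rate: float
    style_vector: np.ndarray
    lexicon_dep_rate: float
    lexicon_nondep_rate: float

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {"user_id": self.user_id}
        for i, v in enumerate(self.topic_keyword_freqs):
            row[f"kw_{i:02d}"] = float(v)
        row["avg_post_length"] = self.avg_post_length
        row["total_posts"] = float(self.total_posts)
        row["first_person_rate"] = self.first_person_rate
        for i, v in enumerate(self.style_vector):
            row[f"style_{i:03d}"] = float(v)
        row["lexicon_dep_rate"] = self.lexicon_dep_rate
        row["lexicon_nondep_rate"] = self.lexicon_nondep_rate
        return row


def extract_features(
    corpus: Corpus,
    user_id: str,
    keywords: Sequence[str],
    space: EmbeddingSpace,
    lexicon: Lexicon,
    pronouns: Sequence[str] = DEFAULT_PRONOUNS,
) -> UserFeatures:
    """Compute one user's feature vector.

    Rates are per 1000 tokens; the style vector averages embedding vectors
    of in-vocabulary tokens (zero vector if none).  Raises for a user with
    no tokens.
    """
    idx = corpus.by_user.get(user_id)
    if not idx:
        raise ValueError(f"unknown user {user_id!r}")
    docs = [corpus.posts[i].tokens for i in idx]
    if any(d is None for d in docs):
        raise ValueError("corpus is not tokenized")
    tokens = [t for d in docs for t in d]
    if not tokens:
        raise ValueError(f"user {user_id!r} has no tokens")
    n = len(tokens)

    kw_counts = np.zeros(len(keywords))
    kw_index = {w: i for i, w in enumerate(keywords)}
    pronoun_set = set(pronouns)
    dep_words = set(lexicon.depressive)
    non_words = set(lexicon.nondepressive)
    n_pron = n_dep = n_non = 0
    style = np.zeros(space.dim)
    n_in_vocab = 0
    for t in tokens:
        i = kw_index.get(t)
        if i is not None:
            kw_counts[i] += 1
        if t in pronoun_set:
            n_pron += 1
        if t in dep_words:
            n_dep += 1
        elif t in non_words:
            n_non += 1
        if t in space:
            style += space[t]
            n_in_vocab += 1
    if n_in_vocab:
        style /= n_in_vocab

    return UserFeatures(
        user_id=user_id,
        topic_keyword_freqs=kw_counts / n,
        avg_post_length=n / len(docs),
        total_posts=len(docs),
        first_person_rate=1000.0 * n_pron / n,
        style_vector=style,
        lexicon_dep_rate=1000.0 * n_dep / n,
        lexicon_nondep_rate=1000.0 * n_non / n,
    )


def build_feature_table(
    corpus: Corpus,
    keywords: Sequence[str],
    space: EmbeddingSpace,
    lexicon: Lexicon,
    pronouns: Sequence[str] = DEFAULT_PRONOUNS,
) -> pd.DataFrame:
    """Feature rows for every user in the corpus, indexed by user_id."""
    rows = [extract_features(corpus, uid, keywords, space, lexicon, pronouns).to_row()
            for uid in corpus.by_user]
    return pd.DataFrame(rows).set_index("user_id")


def _make_models(rng_seed: int) -> dict[str, object]:
    return {
        "NB": GaussianNB(),
        "DT": DecisionTreeClassifier(random_state=rng_seed),
        "LR": make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000, random_state=rng_seed)),
        "RF": RandomForestClassifier(random_state=rng_seed),
        "SVM": make_pipeline(StandardScaler(), SVC(random_state=rng_seed)),
    }


def _feature_matrix(features: pd.DataFrame, with_lexicon: bool) -> pd.DataFrame:
    if with_lexicon:
        return features
    return features.drop(columns=list(LEXICON_COLUMNS))


def run_detection(
    features: pd.DataFrame,
    labels: Mapping[str, str],
    models: Sequence[str] = ("NB", "DT", "LR", "RF", "SVM"),
    with_lexicon: bool = True,
    folds: int = 5,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold cross-validated detection metrics per model.

    ``labels`` maps user_id to 'depressed' / 'nondepressed'; depressed is
    the positive class.  Returns a DataFrame indexed by model name with
    precision, recall, F1 and accuracy, computed from pooled
    cross-validation predictions.  With ``with_lexicon=False`` the two
    lexicon-rate columns are dropped (exact column subset otherwise).
    """
    y = np.array([labels[u] == "depressed" for u in features.index])
    if y.all() or not y.any():
        raise ValueError("both user classes must be present")
    X = _feature_matrix(features, with_lexicon).to_numpy(dtype=np.float64)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    all_models = _make_models(rng_seed)
    rows = {}
    for name in models:
        est = all_models[name.upper()]
        pred = cross_val_predict(est, X, y, cv=cv)
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = int(np.sum(~pred & y))
        p = tp / (tp + fp) if tp + fp else np.nan
        r = tp / (tp + fn) if tp + fn else np.nan
        f1 = 2 * p * r / (p + r) if p + r else np.nan
        rows[name.upper()] = {"precision": p, "recall": r, "F1": f1,
                              "accuracy": float(np.mean(pred == y))}
    return pd.DataFrame.from_dict(rows, orient="index")


def imbalance_sweep(
    features: pd.DataFrame,
    labels: Mapping[str, str],
    proportions: Sequence[float],
    model: str = "LR",
    folds: int = 5,
    rng_seed: int = 0,
    with_lexicon: bool = True,
) -> pd.DataFrame:
    """Cross-validated AUC at varying depressed-user proportions.

    For each proportion p the full nondepressed pool is kept and
    round(p/(1-p) * n_nondepressed) depressed users are subsampled
    deterministically; infeasible or degenerate cells are skipped with a
    warning.  Returns rows (proportion, n_depressed, n_nondepressed, AUC).
    """
    rng = np.random.default_rng(rng_seed)
    dep_users = [u for u in features.index if labels[u] == "depressed"]
    non_users = [u for u in features.index if labels[u] != "depressed"]
    dep_order = list(dep_users)
    rng.shuffle(dep_order)
    rows = []
    for p in proportions:
        if not 0 < p < 1:
            warnings.warn(f"proportion {p} out of (0,1); skipped")
            continue
        n_dep = round(p / (1 - p) * len(non_users))
        if n_dep < folds or n_dep > len(dep_order):
            warnings.warn(f"proportion {p} infeasible with {len(dep_order)} depressed users; skipped")
            continue
        users = dep_order[:n_dep] + non_users
        sub = features.loc[users]
        y = np.array([labels[u] == "depressed" for u in users])
        X = _feature_matrix(sub, with_lexicon).to_numpy(dtype=np.float64)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        est = _make_models(rng_seed)[model.upper()]
        try:
            score = cross_val_predict(est, X, y, cv=cv, method="predict_proba")[:, 1]
        except (AttributeError, ValueError):
            # margin classifiers without calibrated probabilities; rank AUC
            # only needs a monotone score
            score = cross_val_predict(est, X, y, cv=cv, method="decision_function")
        rows.append({"proportion": p, "n_depressed": n_dep,
                     "n_nondepressed": len(non_users),
                     "AUC": float(roc_auc_score(y, score))})
    return pd.DataFrame(rows, columns=["proportion", "n_depressed", "n_nondepressed", "AUC"])
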