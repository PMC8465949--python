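"""Supervised feature selection: which variables let a classifier tell
baseline from post-surgery records?

The harness trains a heterogeneous panel of eight classifiers to assign
each patient-occasion record to its acquisition time (baseline vs
post-surgery) over Monte-Carlo cross-validation: repeated class-
proportional random splits into disjoint training (2/3) and test (1/3)
subsets. Within every split the variables are left out of training one at
a time and the drop in test accuracy, dAcc = Acc_complete - Acc_reduced,
is the importance of the omitted variable. The positive part of each
split's dAcc vector is categorized by computed ABC analysis and membership
in subset "A" is counted over the runs; a classifier's selected set has the
modal "A" size and contains the most frequently A-placed variables.

Classifier selections are merged by a weighted consensus: each classifier
votes with weight

    w_c = median balanced accuracy_c x max(0, CI_low_c - 50) / 50,

so chance-level classifiers (whose 95% CI of accuracy reaches down to the
guessing level of 50%) get zero weight; the weighted A-counts are again
ABC-partitioned and subset A is the consensus. The category knockout
repeats the whole selection after removing the entire variable category
selected in the previous round, until accuracy drops to guessing. A
negative control permutes every training column independently within each
split, which must push all classifiers to ~50% accuracy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .abc_analysis import abc_partition
from .instruments import Schema

__all__ = [
    "ClassifierSpec",
    "default_classifier_specs",
    "make_classifier",
    "mc_splits",
    "run_harness",
    "performance_summary",
    "PerformanceSummary",
    "ImportanceProfile",
    "consensus_vote",
    "ConsensusResult",
    "knockout_loop",
    "KnockoutRound",
    "permutation_control",
    "extract_simple_rule",
    "SimpleRule",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("random_forest", "logistic_a", "logistic_b", "svm_linear",
                    "knn", "naive_bayes", "cart", "rule_tree")

METRICS = ("sensitivity", "specificity", "ppv", "npv", "f1", "accuracy",
           "balanced_accuracy", "roc_auc")

GUESSING_LEVEL = 50.0  # percent accuracy of coin flipping with equal classes


@dataclass(frozen=True)
class ClassifierSpec:
    """One panel member: an algorithm kind plus its hyperparameters."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")


def default_classifier_specs(forest_trees: int = 1500, knn_k: int = 7
                             ) -> list[ClassifierSpec]:
    """The eight-member panel.

    Random forest with 1500 trees (the out-of-bag error plateaus long
    before that and extra trees carry no penalty), two logistic-regression
    variants (unpenalized and weakly ridge-penalized, emulating two
    independent implementations), a linear-kernel SVM, kNN with Euclidean
    distance and k = 7, Gaussian naive Bayes, CART, and an entropy-split
    rule-generating tree standing in for hierarchical rule learners of the
    C5.0 family.
    """
    return [
        ClassifierSpec("random_forest", {"n_estimators": forest_trees}),
        ClassifierSpec("logistic_a"),
        ClassifierSpec("logistic_b"),
        ClassifierSpec("svm_linear"),
        ClassifierSpec("knn", {"n_neighbors": knn_k}),
        ClassifierSpec("naive_bayes"),
        ClassifierSpec("cart"),
        ClassifierSpec("rule_tree"),
    ]


def _bare_classifier(spec: ClassifierSpec, seed: int = 0):
    """Estimator without standardization (input already standardized)."""
    kind, p = spec.kind, spec.params
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=p.get("n_estimators", 1500),
                                      random_state=seed, n_jobs=1)
    if kind == "logistic_a":
        return LogisticRegression(C=np.inf, max_iter=2000)
    if kind == "logistic_b":
        return LogisticRegression(C=100.0, max_iter=2000)
    if kind == "svm_linear":
        return SVC(kernel="linear")
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 7),
                                    metric="euclidean")
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "cart":
        return DecisionTreeClassifier(random_state=seed)
    if kind == "rule_tree":
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)
    raise ValueError(kind)


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate a fit/predict estimator for a spec.

    Distance- and margin-based members are wrapped with standardization so
    that variables on different instrument scales contribute comparably.
    """
    est = _bare_classifier(spec, seed)
    if spec.kind in ("logistic_a", "logistic_b", "svm_linear", "knn"):
        return make_pipeline(StandardScaler(), est)
    return est


def _split_standardize(x_all: np.ndarray, train: np.ndarray
                       ) -> np.ndarray:
    """Standardize all rows by the training mean/SD, column-wise.

    Column-wise scaling commutes with dropping a column, so the harness
    can scale once per split and slice columns afterwards; trees and
    Gaussian naive Bayes are unaffected by per-column affine maps while
    the distance- and margin-based members get comparable scales.
    """
    mean = x_all[train].mean(axis=0)
    sd = x_all[train].std(axis=0)
    sd[sd == 0] = 1.0
    return (x_all - mean) / sd


# ---------------------------------------------------------------------------
# Monte-Carlo resampling
# ---------------------------------------------------------------------------

def mc_splits(labels, train_fraction: float = 2 / 3, runs: int = 1000,
              seed: int | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Class-proportional random train/test index splits.

    Each split places ``round(train_fraction x n_class)`` members of every
    class in the training subset and the remainder in the disjoint test
    subset.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need two classes, got {classes.size}")
    if counts.min() < 3:
        raise ValueError("every class needs at least 3 members")
    rng = np.random.default_rng(seed)
    per_class = [np.flatnonzero(y == c) for c in classes]
    n_train = [round(train_fraction * idx.size) for idx in per_class]
    splits = []
    for _ in range(runs):
        train_parts, test_parts = [], []
        for idx, k in zip(per_class, n_train):
            perm = rng.permutation(idx)
            train_parts.append(perm[:k])
            test_parts.append(perm[k:])
        splits.append((np.sort(np.concatenate(train_parts)),
                       np.sort(np.concatenate(test_parts))))
    return splits


# ---------------------------------------------------------------------------
# Performance metrics
# ---------------------------------------------------------------------------

def _confusion_metrics(truth: np.ndarray, pred: np.ndarray,
                       scores: np.ndarray | None) -> dict | None:
    """Percent-scale confusion metrics for one run; None if undefined."""
    if np.unique(truth).size < 2:
        return None
    tp = int(((pred == 1) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())

    def frac(num, den):
        return 100.0 * num / den if den else np.nan

    sens = frac(tp, tp + fn)
    spec = frac(tn, tn + fp)
    ppv = frac(tp, tp + fp)
    npv = frac(tn, tn + fn)
    f1 = frac(2 * tp, 2 * tp + fp + fn)
    acc = frac(tp + tn, tp + tn + fp + fn)
    bal = (sens + spec) / 2
    auc = np.nan
    if scores is not None:
        from sklearn.metrics import roc_auc_score
        auc = 100.0 * roc_auc_score(truth, scores)
    return dict(zip(METRICS, (sens, spec, ppv, npv, f1, acc, bal, auc)))


@dataclass
class PerformanceSummary:
    """Median and 95% percentile interval of each metric over the runs."""

    table: pd.DataFrame            # index METRICS, columns median/ci_low/ci_high
    n_runs: int
    n_excluded: int = 0

    def median(self, metric: str = "accuracy") -> float:
        return float(self.table.loc[metric, "median"])

    def ci_low(self, metric: str = "accuracy") -> float:
        return float(self.table.loc[metric, "ci_low"])

    def ci_high(self, metric: str = "accuracy") -> float:
        return float(self.table.loc[metric, "ci_high"])


def performance_summary(per_run_metrics: list[dict | None]) -> PerformanceSummary:
    """Aggregate per-run confusion metrics; runs with single-class truth
    (recorded as None) are excluded but counted."""
    valid = [m for m in per_run_metrics if m is not None]
    n_excluded = len(per_run_metrics) - len(valid)
    if not valid:
        raise ValueError("no valid runs to summarize")
    rows = []
    for metric in METRICS:
        vals = np.array([m[metric] for m in valid], float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            rows.append((metric, np.nan, np.nan, np.nan))
            continue
        lo, hi = np.percentile(vals, [2.5, 97.5])
        rows.append((metric, float(np.median(vals)), float(lo), float(hi)))
    table = pd.DataFrame(rows, columns=["metric", "median", "ci_low", "ci_high"]
                         ).set_index("metric")
    return PerformanceSummary(table=table, n_runs=len(valid), n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Drop-one-variable importance harness
# ---------------------------------------------------------------------------

@dataclass
class ImportanceProfile:
    """Per-classifier record of the drop-one importance runs."""

    kind: str
    variables: tuple
    delta_acc: np.ndarray          # runs x d, percent
    a_counts: np.ndarray           # d, membership counts in ABC subset A
    modal_a_size: int
    selected: tuple
    n_failed: int = 0


def _coerce_labels(labels) -> np.ndarray:
    """Binary 0/1 vector with 1 = baseline (the positive class)."""
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        return (y == "baseline").astype(int)
    return (y == np.max(y)).astype(int) if y.dtype.kind != "b" else y.astype(int)


def _predict_scores(model, x_test: np.ndarray) -> np.ndarray | None:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x_test)[:, 1]
    if hasattr(model, "decision_function"):
        return model.decision_function(x_test)
    return None


def run_harness(design: pd.DataFrame, labels, specs, splits, seed: int = 0,
                ) -> dict[str, tuple[ImportanceProfile, PerformanceSummary]]:
    """Drop-one-variable importance over Monte-Carlo splits, per classifier.

    Within each split every classifier is fitted with all d variables
    (giving Acc_complete and the full-model performance metrics), then once
    per variable with that variable withheld (giving Acc_reduced); the
    positive part of the dAcc vector is ABC-partitioned and subset-A
    membership is recorded. A classifier's selected set contains the
    top-k* variables by A-membership count, k* being the modal A size;
    ties break by mean dAcc, then by name.
    """
    variables = tuple(design.columns)
    x_all = design.to_numpy(float)
    y = _coerce_labels(labels)
    d = len(variables)
    scaled = [_split_standardize(x_all, train) for train, _ in splits]
    keep_cols = [np.array([k for k in range(d) if k != j]) for j in range(d)]
    results = {}
    for spec in specs:
        delta_rows = []
        a_hits = np.zeros(d)
        a_sizes = []
        metrics_per_run = []
        n_failed = 0
        for si, (train, test) in enumerate(splits):
            model_seed = (seed + 7919 * si) % (2**31)
            xs = scaled[si]
            try:
                model = _bare_classifier(spec, seed=model_seed)
                model.fit(xs[train], y[train])
                pred = model.predict(xs[test])
                scores = _predict_scores(model, xs[test])
                acc_complete = 100.0 * (pred == y[test]).mean()
                metrics_per_run.append(_confusion_metrics(y[test], pred, scores))

                if d == 1:
                    delta_rows.append(np.zeros(1))
                    a_hits[0] += 1
                    a_sizes.append(1)
                    continue
                deltas = np.empty(d)
                for j in range(d):
                    cols = keep_cols[j]
                    m2 = _bare_classifier(spec, seed=model_seed)
                    m2.fit(xs[np.ix_(train, cols)], y[train])
                    acc_reduced = 100.0 * (m2.predict(xs[np.ix_(test, cols)])
                                           == y[test]).mean()
                    deltas[j] = acc_complete - acc_reduced
                delta_rows.append(deltas)
                positive = np.clip(deltas, 0.0, None)
                if d >= 3 and positive.max() > 0:
                    part = abc_partition(positive, labels=variables)
                    members = part.a
                elif positive.max() > 0:
                    members = tuple(np.flatnonzero(positive == positive.max()))
                else:
                    members = ()
                for j in members:
                    a_hits[j] += 1
                a_sizes.append(len(members))
            except Exception:
                n_failed += 1
                metrics_per_run.append(None)
                continue

        delta_acc = np.vstack(delta_rows) if delta_rows else np.zeros((0, d))
        if a_sizes:
            size_counts = Counter(a_sizes)
            top = max(size_counts.values())
            modal = min(s for s, c in size_counts.items() if c == top)
        else:
            modal = 0
        mean_delta = delta_acc.mean(axis=0) if delta_acc.size else np.zeros(d)
        order = sorted(range(d),
                       key=lambda j: (-a_hits[j], -mean_delta[j], variables[j]))
        selected = tuple(variables[j] for j in order[:modal])
        profile = ImportanceProfile(kind=spec.kind, variables=variables,
                                    delta_acc=delta_acc, a_counts=a_hits,
                                    modal_a_size=modal, selected=selected,
                                    n_failed=n_failed)
        results[spec.kind] = (profile, performance_summary(metrics_per_run))
    return results


# ---------------------------------------------------------------------------
# Weighted cross-classifier consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    selected: tuple
    scores: pd.Series              # weighted A-counts per variable
    weights: dict                  # classifier kind -> weight
    chance_level: bool = False


def consensus_vote(profiles: dict[str, ImportanceProfile],
                   summaries: dict[str, PerformanceSummary]) -> ConsensusResult:
    """Merge per-classifier selections into one weighted consensus set.

    Classifier weight = median balanced accuracy x the normalized distance
    of the accuracy CI lower bound above the 50% guessing level; weighted
    per-variable A-counts are summed across classifiers and the ABC subset
    "A" of those scores is the consensus (ordered by decreasing score).
    """
    if not profiles:
        raise ValueError("no classifier profiles")
    kinds = list(profiles)
    variables = profiles[kinds[0]].variables
    weights = {}
    for kind in kinds:
        s = summaries[kind]
        w = s.median("balanced_accuracy") * max(0.0, s.ci_low("accuracy")
                                                - GUESSING_LEVEL) / GUESSING_LEVEL
        weights[kind] = float(w)
    score = np.zeros(len(variables))
    for kind in kinds:
        score += profiles[kind].a_counts * weights[kind]
    scores = pd.Series(score, index=variables)
    if all(w == 0.0 for w in weights.values()):
        return ConsensusResult(selected=(), scores=scores, weights=weights,
                               chance_level=True)
    if (score > 0).sum() == 0:
        return ConsensusResult(selected=(), scores=scores, weights=weights,
                               chance_level=True)
    if len(variables) >= 3:
        part = abc_partition(score, labels=variables)
        chosen = part.subset_labels("A")
    else:
        chosen = [v for v, s in scores.items() if s > 0]
    chosen = sorted(chosen, key=lambda v: -scores[v])
    return ConsensusResult(selected=tuple(chosen), scores=scores, weights=weights)


# ---------------------------------------------------------------------------
# Category knockout loop
# ---------------------------------------------------------------------------

@dataclass
class KnockoutRound:
    variables: tuple               # design columns available this round
    consensus: ConsensusResult
    summaries: dict                # classifier kind -> PerformanceSummary (selected set)
    category_dropped: str | None   # category removed after this round
    chance_level: bool


def _column_category(column: str, schema: Schema) -> str:
    name = column.split("=", 1)[0]
    return schema[name].category


def evaluate_feature_set(design: pd.DataFrame, labels, features, specs, splits,
                         seed: int = 0) -> dict[str, PerformanceSummary]:
    """Refit every classifier on a fixed feature subset over the splits."""
    x = design[list(features)].to_numpy(float)
    y = _coerce_labels(labels)
    out = {}
    for spec in specs:
        metrics = []
        for si, (train, test) in enumerate(splits):
            model = make_classifier(spec, seed=(seed + 7919 * si) % (2**31))
            try:
                model.fit(x[train], y[train])
                pred = model.predict(x[test])
                metrics.append(_confusion_metrics(y[test], pred,
                                                  _predict_scores(model, x[test])))
            except Exception:
                metrics.append(None)
        out[spec.kind] = performance_summary(metrics)
    return out


def knockout_loop(design: pd.DataFrame, labels, schema: Schema, specs, splits,
                  seed: int = 0, max_rounds: int | None = None
                  ) -> list[KnockoutRound]:
    """Iterated selection with whole-category knockout.

    Round 1 runs on all design columns. After each round the entire
    variable category of the top consensus variable is removed and the
    selection repeats on the remainder. The loop stops when the consensus
    is empty, when even the best classifier restricted to the consensus set
    no longer beats guessing (accuracy CI lower bound <= 50%), or when no
    variables remain.
    """
    current = design
    rounds: list[KnockoutRound] = []
    while current.shape[1] > 0:
        harness = run_harness(current, labels, specs, splits, seed=seed)
        profiles = {k: v[0] for k, v in harness.items()}
        summaries = {k: v[1] for k, v in harness.items()}
        consensus = consensus_vote(profiles, summaries)
        if not consensus.selected:
            rounds.append(KnockoutRound(tuple(current.columns), consensus, {},
                                        None, chance_level=True))
            break
        sel_summaries = evaluate_feature_set(current, labels, consensus.selected,
                                             specs, splits, seed=seed)
        best_ci_low = max(s.ci_low("accuracy") for s in sel_summaries.values())
        chance = best_ci_low <= GUESSING_LEVEL
        top_cat = _column_category(consensus.selected[0], schema)
        remaining = [c for c in current.columns
                     if _column_category(c, schema) != top_cat]
        done = chance or not remaining or (max_rounds and len(rounds) + 1 >= max_rounds)
        rounds.append(KnockoutRound(tuple(current.columns), consensus,
                                    sel_summaries,
                                    None if done else top_cat,
                                    chance_level=chance))
        if done:
            break
        current = current[remaining]
    return rounds


# ---------------------------------------------------------------------------
# Negative control
# ---------------------------------------------------------------------------

def permutation_control(design: pd.DataFrame, labels, specs, splits,
                        seed: int = 0) -> dict[str, PerformanceSummary]:
    """Chance-level control: permute each training column independently.

    Within every split each column of the training block is shuffled
    across rows (destroying all feature-label association while preserving
    the marginals); the test block stays untouched. Any classifier that
    still beats guessing would indicate leakage or overfitting.
    """
    x_all = design.to_numpy(float)
    y = _coerce_labels(labels)
    rng = np.random.default_rng(seed)
    permuted_per_split = []
    for train, test in splits:
        x_train = x_all[train].copy()
        for j in range(x_train.shape[1]):
            x_train[:, j] = x_train[rng.permutation(x_train.shape[0]), j]
        permuted_per_split.append(x_train)
    out = {}
    for spec in specs:
        metrics = []
        for si, (train, test) in enumerate(splits):
            model = make_classifier(spec, seed=(seed + 7919 * si) % (2**31))
            try:
                model.fit(permuted_per_split[si], y[train])
                pred = model.predict(x_all[test])
                metrics.append(_confusion_metrics(y[test], pred,
                                                  _predict_scores(model, x_all[test])))
            except Exception:
                metrics.append(None)
        out[spec.kind] = performance_summary(metrics)
    return out


# ---------------------------------------------------------------------------
# Depth-1 threshold rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimpleRule:
    """IF feature >= threshold THEN predict ``class_ge`` ELSE the other."""

    feature: str
    threshold: float
    class_ge: int                  # 1 = baseline
    train_accuracy: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        ge = x >= self.threshold
        return np.where(ge, self.class_ge, 1 - self.class_ge)


def extract_simple_rule(design: pd.DataFrame, labels, feature: str,
                        train_fraction: float = 0.8, boots: int = 1000,
                        seed: int | None = None
                        ) -> tuple[SimpleRule, dict]:
    """Learn a depth-1 threshold rule once and bootstrap-validate it.

    The rule is fitted on a class-proportional ``train_fraction`` share of
    the records (threshold and direction minimizing training
    misclassification; ties resolved toward the smallest threshold) and
    evaluated by accuracy on ``boots`` bootstrap resamples of the held-out
    share. Returns the rule and a dict with the median accuracy and its
    2.5/97.5 percentile interval.
    """
    x = design[feature].to_numpy(float)
    y = _coerce_labels(labels)
    if np.ptp(x) == 0:
        raise ValueError(f"feature {feature!r} is constant")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for c in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == c))
        k = round(train_fraction * idx.size)
        train_parts.append(idx[:k])
        test_parts.append(idx[k:])
    train = np.concatenate(train_parts)
    test = np.concatenate(test_parts)

    xs = np.sort(np.unique(x[train]))
    cut_candidates = (xs[:-1] + xs[1:]) / 2.0
    best = None
    for thr in cut_candidates:
        for class_ge in (1, 0):
            pred = np.where(x[train] >= thr, class_ge, 1 - class_ge)
            err = (pred != y[train]).mean()
            key = (err, thr, -class_ge)
            if best is None or key < best[0]:
                best = (key, thr, class_ge)
    _, thr, class_ge = best
    rule = SimpleRule(feature=feature, threshold=float(thr), class_ge=class_ge,
                      train_accuracy=float(
                          100.0 * (np.where(x[train] >= thr, class_ge, 1 - class_ge)
                                   == y[train]).mean()))

    accs = np.empty(boots)
    for b in range(boots):
        take = test[rng.integers(0, test.size, test.size)]
        accs[b] = 100.0 * (rule.predict(x[take]) == y[take]).mean()
    lo, hi = np.percentile(accs, [2.5, 97.5])
    summary = {"median_accuracy": float(np.median(accs)),
               "ci_low": float(lo), "ci_high": float(hi), "n_boot": boots}
    return rule, summary
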