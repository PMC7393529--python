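"""Random-forest feature significance with OOB permutation tests.

Which of the 33 articulatory features discriminate each sound category?
Every class is turned into a one-versus-all (OVA) binary problem; since
OVA is inherently imbalanced, balanced bootstrap samples (r draws per
class, with replacement) are taken, repeated N times to remove sampling
bias.  Each repeat fits a bagged random forest (t trees, minimum leaf
size 20, sqrt-of-features per split) on a stratified 90% split and
keeps out-of-bag (OOB) bookkeeping: each row is predicted by the
majority vote of the trees that did not see it in their bootstrap.

Feature significance is assessed by permutation: a feature column is
shuffled, OOB votes are recomputed, and the change in the
correct/incorrect counts relative to the unpermuted forest is
accumulated into a 2x2 contingency table over repeated permutations; a
plain Pearson chi-square test of independence (no continuity
correction) on the pooled table gives the feature's p-value.  Per-class
p-values are pooled across the N bootstrap repeats by their median and
Benjamini-Hochberg adjusted across the 33 features; adjusted p below
alpha (default 0.05) flags a feature as significant.  A post-hoc table
then compares class-conditional means of the significant features.

The forest fit itself comes from scikit-learn; OOB vote bookkeeping,
the permutation contingency machinery and the balanced-bootstrap OVA
loop are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .config import RFConfig
from .errors import InvalidArgumentError

__all__ = [
    "LabeledFeatureTable",
    "SignificanceResult",
    "make_ova_labels",
    "balanced_bootstrap",
    "train_rf_oob",
    "OOBForest",
    "permutation_feature_significance",
    "benjamini_hochberg",
    "run_significance_analysis",
]


@dataclass
class LabeledFeatureTable:
    """Feature matrix (tokens x features) with one class label per row."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise InvalidArgumentError("X must be 2-D (rows x features)")
        if len(self.y) != len(self.X):
            raise InvalidArgumentError("labels must match rows")
        if not np.all(np.isfinite(self.X)):
            raise InvalidArgumentError("feature table contains missing values")
        if not self.feature_names:
            self.feature_names = [f"feature_{j + 1}" for j in range(self.X.shape[1])]
        counts = pd.Series(self.y).value_counts()
        if len(counts) < 2:
            raise InvalidArgumentError("need at least 2 classes")
        if counts.min() < 2:
            raise InvalidArgumentError("every class needs at least 2 rows")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_col: str,
                   feature_cols: list[str] | None = None) -> "LabeledFeatureTable":
        if feature_cols is None:
            feature_cols = [c for c in frame.columns
                            if c != label_col
                            and np.issubdtype(frame[c].dtype, np.number)]
        return cls(X=frame[feature_cols].to_numpy(float),
                   y=frame[label_col].to_numpy(),
                   feature_names=list(feature_cols))

    @property
    def classes(self) -> list:
        return sorted(pd.unique(self.y).tolist())


def make_ova_labels(labels: np.ndarray, target_class) -> np.ndarray:
    """One-versus-all relabeling: 1 for the target class, 0 for the rest."""
    labels = np.asarray(labels)
    if target_class not in labels:
        raise InvalidArgumentError(f"class {target_class!r} absent from labels")
    return (labels == target_class).astype(int)


def balanced_bootstrap(y: np.ndarray, r: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw exactly r row indices per class, with replacement.

    Equalizes the class counts that OVA relabeling skews; deterministic
    given the generator state.
    """
    y = np.asarray(y)
    idx = []
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        if rows.size == 0:
            raise InvalidArgumentError(f"class {cls!r} is empty")
        idx.append(rng.choice(rows, size=r, replace=True))
    return np.concatenate(idx)


class OOBForest:
    """A fitted random forest with out-of-bag vote bookkeeping.

    Wraps a scikit-learn forest together with, per tree, the rows it
    never saw (its OOB set) and its predictions on the full training
    matrix, so that OOB majority votes can be recomputed cheaply after a
    feature column is permuted: only trees that actually split on the
    permuted feature need re-prediction.
    """

    def __init__(self, forest: RandomForestClassifier, X: np.ndarray,
                 y: np.ndarray):
        self.forest = forest
        self.X = X
        self.y = y
        n = len(X)
        n_trees = len(forest.estimators_)
        # float32 copy for the low-level tree predict path
        self._X32 = np.ascontiguousarray(X, dtype=np.float32)
        self._classes = forest.classes_.astype(int)
        self.oob_mask = np.ones((n_trees, n), dtype=bool)
        for t, sample_idx in enumerate(forest.estimators_samples_):
            self.oob_mask[t, sample_idx] = False
        self.tree_preds = np.stack([self._tree_predict(est, self._X32)
                                    for est in forest.estimators_])
        self.tree_features = [np.unique(est.tree_.feature[est.tree_.feature >= 0])
                              for est in forest.estimators_]
        self.oob_counts = self.oob_mask.sum(axis=0)
        self.valid = self.oob_counts > 0
        self.oob_pred = self._vote(self.tree_preds)
        self.baseline_correct = int(np.sum(
            (self.oob_pred == y) & self.valid))
        self.baseline_incorrect = int(self.valid.sum()) - self.baseline_correct

    def _tree_predict(self, est, X32: np.ndarray) -> np.ndarray:
        """Class predictions of one tree, bypassing per-call validation."""
        votes = est.tree_.predict(X32)
        votes = votes.reshape(len(X32), -1)
        return self._classes[np.argmax(votes, axis=1)]

    def _vote(self, tree_preds: np.ndarray) -> np.ndarray:
        """OOB majority vote per row; ties and never-OOB rows -> class 0."""
        pos_votes = np.sum(tree_preds * self.oob_mask, axis=0)
        return (2 * pos_votes > self.oob_counts).astype(int)

    @property
    def oob_accuracy(self) -> float:
        total = self.baseline_correct + self.baseline_incorrect
        return self.baseline_correct / total if total else float("nan")

    def permuted_counts(self, feature_index: int,
                        rng: np.random.Generator) -> tuple[int, int]:
        """(correct, incorrect) OOB counts after permuting one feature."""
        n_features = self.X.shape[1]
        if not 0 <= feature_index < n_features:
            raise InvalidArgumentError("feature index out of range")
        affected = [t for t in range(len(self.tree_features))
                    if feature_index in self.tree_features[t]]
        if not affected:
            return self.baseline_correct, self.baseline_incorrect
        Xp = self._X32.copy()
        Xp[:, feature_index] = rng.permutation(Xp[:, feature_index])
        preds = self.tree_preds.copy()
        for t in affected:
            preds[t] = self._tree_predict(self.forest.estimators_[t], Xp)
        vote = self._vote(preds)
        correct = int(np.sum((vote == self.y) & self.valid))
        return correct, int(self.valid.sum()) - correct

    def permutation_stats(self, feature_index: int, repeats: int,
                          rng: np.random.Generator,
                          ) -> tuple[float, np.ndarray]:
        """Mean OOB accuracy drop and the pooled 2x2 contingency table.

        The table rows are (permuted, unpermuted), columns (correct,
        incorrect); permuted counts are summed over the repeats and the
        unpermuted baseline is scaled to the same total.
        """
        perm_correct = perm_incorrect = 0
        drops = np.empty(repeats)
        total = self.baseline_correct + self.baseline_incorrect
        for k in range(repeats):
            c, i = self.permuted_counts(feature_index, rng)
            perm_correct += c
            perm_incorrect += i
            drops[k] = (self.baseline_correct - c) / total if total else 0.0
        table = np.array([
            [perm_correct, perm_incorrect],
            [self.baseline_correct * repeats, self.baseline_incorrect * repeats],
        ], dtype=float)
        return float(drops.mean()), table


def train_rf_oob(X: np.ndarray, y: np.ndarray, config: RFConfig | None = None,
                 rng: np.random.Generator | None = None,
                 compute_importance: bool = True) -> OOBForest:
    """Fit the bagged forest and (optionally) OOB permutation importance.

    Trees use bootstrap row sampling and sqrt-of-features split
    candidates with leaves of at least ``min_leaf`` rows; importance is
    the mean drop in OOB vote accuracy when a feature is permuted,
    averaged over ``importance_iterations`` re-estimates, stored on the
    returned forest as ``importances_``.
    """
    config = config or RFConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("y must contain both classes")
    rng = rng or np.random.default_rng(config.seed)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_leaf,
        max_features="sqrt",
        bootstrap=True,
        random_state=int(rng.integers(2 ** 31 - 1)),
        n_jobs=1,
    )
    forest.fit(X, y)
    oob = OOBForest(forest, X, y)
    if compute_importance:
        importances = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            drop, _ = oob.permutation_stats(j, config.importance_iterations, rng)
            importances[j] = drop
        oob.importances_ = importances
    return oob


def permutation_feature_significance(oob: OOBForest, feature_index: int,
                                     config: RFConfig | None = None,
                                     rng: np.random.Generator | None = None,
                                     ) -> float:
    """Raw p-value for one feature from the pooled permutation table.

    Pearson chi-square test of independence (no continuity correction)
    between permutation status and classification outcome.  A feature
    the forest never split on leaves the votes unchanged, so the table
    rows are proportional and p = 1.
    """
    config = config or RFConfig()
    rng = rng or np.random.default_rng(config.seed)
    _, table = oob.permutation_stats(feature_index, config.permutation_repeats, rng)
    return _pearson_p(table)


def _pearson_p(table: np.ndarray) -> float:
    """Pearson chi-square p for a 2x2 table, no continuity correction.

    Uses the closed form n (ad - bc)^2 / (r1 r2 c1 c2), which equals
    scipy's ``chi2_contingency(..., correction=False)`` on 2x2 tables;
    degenerate margins give p = 1.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if n == 0 or 0 in (r1, r2, c1, c2):
        return 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2.sf(stat, df=1))


def benjamini_hochberg(pvalues: np.ndarray, alpha: float = 0.05,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH false-discovery-rate adjustment.

    Returns (adjusted p-values, significance flags); a flag is set when
    the adjusted p-value is below alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise InvalidArgumentError("alpha must be in (0, 1)")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


@dataclass
class SignificanceResult:
    """Per-class feature significance plus the post-hoc magnitude table.

    ``per_class[c]`` is a DataFrame with columns (feature,
    importance_mean, p_raw, p_adj, significant); ``posthoc`` compares
    target-class and rest means of every significant feature.
    """

    per_class: dict
    posthoc: pd.DataFrame
    test_accuracy: dict
    config: RFConfig
    seed: int

    def significant_features(self, target_class) -> list[str]:
        frame = self.per_class[target_class]
        return frame.loc[frame["significant"], "feature"].tolist()


def _stratified_split(y: np.ndarray, train_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for cls in np.unique(y):
        rows = rng.permutation(np.flatnonzero(y == cls))
        n_train = max(1, int(round(train_fraction * rows.size)))
        n_train = min(n_train, rows.size - 1) if rows.size > 1 else n_train
        train.append(rows[:n_train])
        test.append(rows[n_train:])
    return np.concatenate(train), np.concatenate(test)


def run_significance_analysis(table: LabeledFeatureTable,
                              config: RFConfig | None = None,
                              classes: list | None = None,
                              ) -> SignificanceResult:
    """The full two-step analysis over every class.

    Step one, per class: N balanced-bootstrap repeats of (stratified
    train/test split, forest fit, OOB permutation importance and
    contingency p-value per feature); median p-values across repeats are
    BH-adjusted over the features.  Step two: for each significant
    feature, the post-hoc table reports the target-class mean, the
    rest-of-classes mean and their difference, giving the direction and
    magnitude of the articulatory difference.

    All randomness derives from ``config.seed`` through per-class,
    per-repeat child generators, so results are bit-reproducible.
    ``classes`` restricts the analysis to a subset of target classes
    (default: all).
    """
    config = config or RFConfig()
    config.validate()
    per_class = {}
    posthoc_rows = []
    test_accuracy = {}
    all_classes = table.classes
    if classes is None:
        classes = all_classes
    else:
        missing = [c for c in classes if c not in all_classes]
        if missing:
            raise InvalidArgumentError(f"unknown class(es) {missing}")
    class_seeds = np.random.SeedSequence(config.seed).spawn(len(classes))

    for cls, cls_seed in zip(classes, class_seeds):
        y_ova = make_ova_labels(table.y, cls)
        n_features = table.X.shape[1]
        pvals = np.empty((config.n_bootstrap, n_features))
        imps = np.empty((config.n_bootstrap, n_features))
        accs = np.empty(config.n_bootstrap)
        for it, it_seed in enumerate(cls_seed.spawn(config.n_bootstrap)):
            rng = np.random.default_rng(it_seed)
            sample = balanced_bootstrap(y_ova, config.r, rng)
            Xb, yb = table.X[sample], y_ova[sample]
            train_idx, test_idx = _stratified_split(yb, config.train_fraction, rng)
            oob = train_rf_oob(Xb[train_idx], yb[train_idx], config, rng,
                               compute_importance=False)
            est = oob.forest
            accs[it] = float(np.mean(est.predict(Xb[test_idx]) == yb[test_idx]))
            for j in range(n_features):
                drop, tab = oob.permutation_stats(
                    j, config.permutation_repeats, rng)
                imps[it, j] = drop
                pvals[it, j] = _pearson_p(tab)
        p_med = np.median(pvals, axis=0)
        p_adj, flags = benjamini_hochberg(p_med, config.alpha)
        per_class[cls] = pd.DataFrame({
            "feature": table.feature_names,
            "importance_mean": imps.mean(axis=0),
            "p_raw": p_med,
            "p_adj": p_adj,
            "significant": flags,
        })
        test_accuracy[cls] = float(accs.mean())
        in_cls = table.y == cls
        for j in np.flatnonzero(flags):
            mean_t = float(table.X[in_cls, j].mean())
            mean_r = float(table.X[~in_cls, j].mean())
            posthoc_rows.append({
                "class": cls, "feature": table.feature_names[j],
                "mean_target": mean_t, "mean_rest": mean_r,
                "difference": mean_t - mean_r,
            })

    posthoc = pd.DataFrame(
        posthoc_rows,
        columns=["class", "feature", "mean_target", "mean_rest", "difference"])
    return SignificanceResult(per_class=per_class, posthoc=posthoc,
                              test_accuracy=test_accuracy, config=config,
                              seed=config.seed)
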