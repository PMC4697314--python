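"""Group statistics and the two-variable classification score.

Group differences in EEG features are assessed with permutation tests
(one-way ANOVA F or two-sample t statistic, 10,000 label permutations by
default); the family-wise error across features is controlled with the
max-statistic method: within each permutation the maximum statistic over
all features is recorded, and a feature's corrected p-value is the
proportion of permutations whose maximum reaches its observed statistic.
P-values use the inclusive estimator (1 + #{exceedances}) / (1 + n_perm),
which can never be zero.

Classification follows a two-stage design: a logistic regression with
backward elimination (likelihood-ratio removal criterion) is fitted on one
group pair, the resulting linear score is applied to another pair, and the
operating point is chosen by the maximal Youden index (ties broken toward
higher specificity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupStudy",
    "StatResult",
    "ClassifierModel",
    "Evaluation",
    "permutation_test",
    "correlate_features_domains",
    "logistic_backward",
    "evaluate_score",
    "apply_score",
    "confusion_rates",
]


@dataclass
class GroupStudy:
    """Per-subject group labels with features and six domain z-scores.

    ``recordings``/``ground_truths`` are populated by the synthetic
    generator; ``features`` is filled once the EEG stages have run.
    """

    groups: list
    features: pd.DataFrame | None = None
    domain_scores: pd.DataFrame | None = None
    recordings: list = field(default_factory=list)
    ground_truths: list = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.groups)) < 2:
            raise ValueError("need at least 2 groups")


@dataclass
class StatResult:
    feature_names: list[str]
    statistic: np.ndarray
    p_raw: np.ndarray
    p_corrected: np.ndarray
    test_name: str
    n_permutations: int
    seed: int


@dataclass
class ClassifierModel:
    """Linear score from a (possibly backward-eliminated) logistic fit."""

    predictors: list[str]
    coefficients: np.ndarray
    intercept: float = 0.0
    threshold: float | None = None
    positive_class: object = 1
    separation: bool = False
    evaluation: "Evaluation | None" = None


@dataclass
class Evaluation:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fn: int
    tn: int
    fp: int


# ---------------------------------------------------------------------------
# Permutation tests


def _f_stat(X: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """One-way ANOVA F per column (vectorized over features)."""
    n, _ = X.shape
    k = len(group_idx)
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for idx in group_idx:
        g = X[idx]
        gm = g.mean(axis=0)
        ssb += idx.size * (gm - grand) ** 2
        ssw += ((g - gm) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    return f


def _t_stat(X: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """|two-sample t| (pooled variance) per column."""
    a, b = X[group_idx[0]], X[group_idx[1]]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / (sp * np.sqrt(1 / na + 1 / nb))
    return np.abs(t)


def permutation_test(
    feature_matrix,
    groups,
    stat: str = "anova",
    n_perm: int = 10000,
    seed: int = 0,
) -> StatResult:
    """Permutation ANOVA/t test per feature with max-statistic correction."""
    X = np.atleast_2d(np.asarray(
        feature_matrix.values if hasattr(feature_matrix, "values") else feature_matrix,
        dtype=float,
    ))
    names = (list(feature_matrix.columns) if hasattr(feature_matrix, "columns")
             else [f"f{i}" for i in range(X.shape[1])])
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if stat == "t" and labels.size != 2:
        raise ValueError("t statistic requires exactly 2 groups")
    stat_fn = {"anova": _f_stat, "t": _t_stat}[stat]

    constant = X.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant feature(s) {list(np.asarray(names)[constant])}: p set to 1",
            stacklevel=2,
        )

    n = X.shape[0]
    idx_of = [np.flatnonzero(groups == g) for g in labels]
    observed = stat_fn(X, idx_of)
    observed = np.where(constant, -np.inf, observed)

    rng = np.random.default_rng(seed)
    sizes = np.cumsum([i.size for i in idx_of])[:-1]
    exceed = np.zeros(X.shape[1])
    exceed_max = np.zeros(X.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pidx = np.split(perm, sizes)
        s = stat_fn(X, pidx)
        s = np.where(np.isfinite(s), s, 0.0)
        exceed += s >= observed
        exceed_max += s.max() >= observed
    p_raw = (1.0 + exceed) / (1.0 + n_perm)
    p_corr = (1.0 + exceed_max) / (1.0 + n_perm)
    p_raw = np.where(constant, 1.0, np.minimum(p_raw, 1.0))
    p_corr = np.where(constant, 1.0, np.maximum(np.minimum(p_corr, 1.0), p_raw))
    return StatResult(feature_names=names, statistic=np.where(constant, np.nan, observed),
                      p_raw=p_raw, p_corrected=p_corr,
                      test_name=f"permutation-{stat}", n_permutations=n_perm, seed=seed)


def _corr_matrix(X: np.ndarray, D: np.ndarray) -> np.ndarray:
    zx = (X - X.mean(axis=0)) / X.std(axis=0)
    zd = (D - D.mean(axis=0)) / D.std(axis=0)
    return zx.T @ zd / X.shape[0]


def correlate_features_domains(
    feature_matrix, domain_scores, n_perm: int = 10000, seed: int = 0
) -> StatResult:
    """Pearson r for every (feature, domain) pair, permutation p-values and
    max-|r| family-wise correction across all pairs."""
    X = np.atleast_2d(np.asarray(
        feature_matrix.values if hasattr(feature_matrix, "values") else feature_matrix,
        dtype=float,
    ))
    D = np.atleast_2d(np.asarray(
        domain_scores.values if hasattr(domain_scores, "values") else domain_scores,
        dtype=float,
    ))
    if X.shape[0] != D.shape[0] or X.shape[0] < 4:
        raise ValueError("need >= 4 paired observations")
    fnames = (list(feature_matrix.columns) if hasattr(feature_matrix, "columns")
              else [f"f{i}" for i in range(X.shape[1])])
    dnames = (list(domain_scores.columns) if hasattr(domain_scores, "columns")
              else [f"d{j}" for j in range(D.shape[1])])
    if (X.std(axis=0) == 0).any() or (D.std(axis=0) == 0).any():
        warnings.warn("constant column(s); correlations undefined there", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_obs = np.abs(_corr_matrix(X, D)).ravel()
    r_obs_cmp = np.where(np.isfinite(r_obs), r_obs, np.inf)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(r_obs.size)
    exceed_max = np.zeros(r_obs.size)
    n = X.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.abs(_corr_matrix(X, D[perm])).ravel()
        r = np.where(np.isfinite(r), r, 0.0)
        exceed += r >= r_obs_cmp
        exceed_max += r.max() >= r_obs_cmp
    p_raw = np.where(np.isfinite(r_obs), (1 + exceed) / (1 + n_perm), 1.0)
    p_corr = np.maximum(np.where(np.isfinite(r_obs), (1 + exceed_max) / (1 + n_perm), 1.0),
                        p_raw)
    names = [f"{f}~{d}" for f in fnames for d in dnames]
    return StatResult(feature_names=names,
                      statistic=np.where(np.isfinite(r_obs), r_obs, np.nan),
                      p_raw=p_raw, p_corrected=p_corr,
                      test_name="permutation-correlation",
                      n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Logistic score


def _fit_logit(X: np.ndarray, y: np.ndarray):
    import statsmodels.api as sm

    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(disp=0, maxiter=200)


def logistic_backward(
    features, labels, removal_alpha: float = 0.05
) -> ClassifierModel:
    """Backward elimination: drop the predictor with the largest
    likelihood-ratio p until all retained predictors have p < removal_alpha.

    Perfect separation is flagged and the coefficients refitted with a
    ridge-penalized logistic regression.
    """
    X_df = pd.DataFrame(features).astype(float)
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    y = (y_raw == classes[1]).astype(float)
    retained = list(X_df.columns)

    def lr_pvalues(cols):
        from scipy.stats import chi2

        full = _fit_logit(X_df[cols].values, y)
        ps = {}
        for c in cols:
            rest = [cc for cc in cols if cc != c]
            if rest:
                red = _fit_logit(X_df[rest].values, y)
                llr = 2 * (full.llf - red.llf)
            else:
                import statsmodels.api as sm
                null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
                llr = 2 * (full.llf - null.llf)
            ps[c] = float(chi2.sf(max(llr, 0.0), df=1))
        return full, ps

    separation = False
    fit = None
    try:
        while retained:
            fit, ps = lr_pvalues(retained)
            worst = max(retained, key=lambda c: ps[c])
            if ps[worst] < removal_alpha:
                break
            retained.remove(worst)
        if not retained:
            warnings.warn("all predictors eliminated", stacklevel=2)
            return ClassifierModel(predictors=[], coefficients=np.empty(0),
                                   intercept=0.0, positive_class=classes[1])
        coef = np.asarray(fit.params[1:], dtype=float)
        intercept = float(fit.params[0])
        if not np.all(np.isfinite(coef)) or np.abs(coef).max() > 1e4:
            raise np.linalg.LinAlgError("divergent fit (separation)")
    except Exception:
        # perfect separation: penalized fallback keeps the score usable
        separation = True
        from sklearn.linear_model import LogisticRegression

        if not retained:
            retained = list(X_df.columns)
        clf = LogisticRegression(C=1.0).fit(X_df[retained].values, y)
        coef = clf.coef_.ravel()
        intercept = float(clf.intercept_[0])
        warnings.warn("perfect separation detected; ridge-penalized coefficients",
                      stacklevel=2)
    return ClassifierModel(predictors=retained, coefficients=coef,
                           intercept=intercept, positive_class=classes[1],
                           separation=separation)


def confusion_rates(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity, specificity, PPV and NPV (fractions) of one confusion matrix."""
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }


def evaluate_score(scores, labels, threshold="auto") -> Evaluation:
    """ROC AUC and the maximal-Youden operating point of a score.

    Subjects with score >= threshold are classified positive.  With
    ``threshold="auto"`` the threshold maximizing J = sensitivity +
    specificity - 1 is chosen; ties go to the higher-specificity point.
    """
    from sklearn.metrics import roc_auc_score

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need both classes present")
    pos = y == classes[1]
    auc = float(roc_auc_score(pos, s))

    def confusion(thr):
        pred = s >= thr
        tp = int(np.sum(pred & pos))
        fp = int(np.sum(pred & ~pos))
        fn = int(np.sum(~pred & pos))
        tn = int(np.sum(~pred & ~pos))
        return tp, fn, tn, fp

    if threshold == "auto":
        candidates = np.unique(s)
        best = None
        for thr in candidates:
            tp, fn, tn, fp = confusion(thr)
            r = confusion_rates(tp, fn, tn, fp)
            j = r["sensitivity"] + r["specificity"] - 1.0
            key = (j, r["specificity"])
            if best is None or key > best[0]:
                best = (key, float(thr))
        threshold = best[1]
    tp, fn, tn, fp = confusion(float(threshold))
    r = confusion_rates(tp, fn, tn, fp)
    return Evaluation(auc=auc, threshold=float(threshold), tp=tp, fn=fn, tn=tn, fp=fp,
                      **r)


def apply_score(model: ClassifierModel, new_features) -> tuple[np.ndarray, np.ndarray | None]:
    """Linear score per subject; classification if the model has a threshold.

    Scores at exactly the threshold classify positive (>= convention).
    """
    X_df = pd.DataFrame(new_features)
    missing = [c for c in model.predictors if c not in X_df.columns]
    if missing:
        raise ValueError(f"missing predictor(s): {missing}")
    scores = X_df[model.predictors].values.astype(float) @ model.coefficients \
        + model.intercept
    if model.threshold is None:
        return scores, None
    return scores, scores >= model.threshold
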