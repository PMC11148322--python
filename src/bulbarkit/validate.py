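"""Validation layer: screening, factor model, reliability, ML harness, and
summary-statistic group tests.

The construct-validity stage is a confirmatory factor analysis (CFA) with a
simple-structure measurement model: each retained feature loads on exactly
one of up to 10 construct factors (prosody, pause, connectivity, acoustic/
EMG amplitude, rhythm, complexity, regularity), factors are freely
correlated, and estimation is maximum likelihood on the sample covariance
of z-scored features. Fit is summarized by CFI and RMSEA against the
independence baseline, features loading below 0.5 are pruned with a single
refit, and per-sample factor scores are computed with the Bartlett
(weighted-least-squares) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from statsmodels.stats.multitest import multipletests

# ---------------------------------------------------------------------------
# Effect-size screening
# ---------------------------------------------------------------------------

def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled-SD denominator."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ZeroDivisionError("zero pooled SD")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def cohens_d_screen(
    table: pd.DataFrame, labels, cutoff: float = 0.5
):
    """Retain features with between-group |d| > cutoff.

    Missing values are dropped per feature (pairwise). Features with zero
    pooled SD are flagged and excluded. Returns (retained, discarded,
    d_values) where d_values maps feature -> d (NaN when undefined).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)  # sorted, so d's sign is label-deterministic
    if groups.size != 2:
        raise ValueError("screening expects exactly two groups")
    retained, discarded, d_values = [], [], {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        a = x[ok & (labels == groups[0])]
        b = x[ok & (labels == groups[1])]
        if a.size < 2 or b.size < 2:
            d_values[col] = np.nan
            discarded.append(col)
            continue
        try:
            d = cohens_d(a, b)
        except ZeroDivisionError:
            warnings.warn(f"feature {col!r} has zero pooled SD; excluded")
            d_values[col] = np.nan
            discarded.append(col)
            continue
        d_values[col] = d
        (retained if abs(d) > cutoff else discarded).append(col)
    return retained, discarded, d_values


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item var)/var(item sum))."""
    X = np.asarray(item_matrix, dtype=float)
    X = X[np.all(np.isfinite(X), axis=1)]
    n, k = X.shape
    if k < 2:
        raise ValueError("Cronbach's alpha requires at least 2 items")
    if n < 3:
        raise ValueError("need at least 3 observations")
    item_vars = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ZeroDivisionError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


# ---------------------------------------------------------------------------
# Confirmatory factor analysis
# ---------------------------------------------------------------------------

@dataclass
class FactorSpec:
    """Assignment of features to factors; each feature belongs to one factor."""

    assignment: dict  # factor name -> tuple of feature names
    loading_cutoff: float = 0.5

    def __post_init__(self):
        seen = {}
        for fac, feats in self.assignment.items():
            for f in feats:
                if f in seen:
                    raise ValueError(
                        f"feature {f!r} assigned to both {seen[f]!r} and {fac!r}")
                seen[f] = fac

    @property
    def features(self):
        return [f for feats in self.assignment.values() for f in feats]


def default_factor_spec(columns) -> FactorSpec:
    """Map the standard feature inventory onto the 10 construct factors."""
    cols = list(columns)

    def pick(pred):
        return tuple(c for c in cols if pred(c))

    assignment = {
        "Pros_a": pick(lambda c: c.endswith("F0.st")),
        "Pause_a": pick(lambda c: "intrapause" in c),
        "IMC_e": pick(lambda c: c.startswith("IMC_")),
        "Amp_e": pick(lambda c: c.startswith("density_") and c != "density_audio"),
        "Amp_a": pick(lambda c: c == "density_audio"),
        "Rhy_e": pick(lambda c: (c.startswith("mod_depth") or c.startswith("PSI"))),
        "Rhy_a": pick(lambda c: c.startswith("hbenvlp_")),
        "Comp_e": pick(lambda c: c.startswith("DET_") and "mfcc" not in c),
        "Comp_a": pick(lambda c: c.startswith("DET_mfcc")),
        "Reg_e": pick(lambda c: c.startswith("ShanEn_") and c != "ShanEn_audio"),
    }
    assignment = {k: v for k, v in assignment.items() if v}
    return FactorSpec(assignment=assignment)


@dataclass
class FactorModelFit:
    loadings: pd.Series  # standardized, indexed by feature
    uniqueness: pd.Series
    factor_corr: pd.DataFrame
    cfi: float
    rmsea: float
    scores: pd.DataFrame  # Bartlett factor scores per row
    pruned: list
    spec: FactorSpec
    n_obs: int
    chi2: float
    df: int
    heywood: list = field(default_factory=list)


def _ml_discrepancy(S, lam, psi, phi, pattern):
    Lam = np.zeros((len(lam), phi.shape[0]))
    Lam[np.arange(len(lam)), pattern] = lam
    Sigma = Lam @ phi @ Lam.T + np.diag(psi)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf, None
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    F = logdet + np.trace(np.linalg.solve(Sigma, S)) - logdet_s - p
    return F, Sigma


def _fit_cfa_ml(S, pattern, k, n_obs, fixed_lam=None):
    """Minimize the ML discrepancy for a simple-structure model.

    ``pattern[i]`` is the factor index of feature i. ``fixed_lam`` marks
    single-indicator features whose loading is fixed at 1 with uniqueness
    ~0 for identification.
    """
    p = len(pattern)
    fixed_lam = fixed_lam or {}
    free_idx = [i for i in range(p) if i not in fixed_lam]
    tril = np.tril_indices(k, -1)
    n_phi = len(tril[0])

    def unpack(theta):
        lam = np.empty(p)
        psi = np.empty(p)
        for i in fixed_lam:
            lam[i] = 1.0
            psi[i] = 1e-6
        lam[free_idx] = theta[: len(free_idx)]
        psi[free_idx] = np.exp(theta[len(free_idx): 2 * len(free_idx)])
        z = theta[2 * len(free_idx):]
        phi = np.eye(k)
        if n_phi:
            phi[tril] = np.tanh(z)
            phi[(tril[1], tril[0])] = np.tanh(z)
        return lam, psi, phi

    def objective(theta):
        lam, psi, phi = unpack(theta)
        # keep phi positive definite by shrinking toward identity if needed
        w, _ = np.linalg.eigh(phi)
        if w.min() < 1e-6:
            return 1e6 + abs(w.min())
        F, _ = _ml_discrepancy(S, lam, psi, phi, pattern)
        return F if np.isfinite(F) else 1e6

    lam0 = np.full(len(free_idx), 0.7)
    psi0 = np.log(np.full(len(free_idx), 0.5))
    phi0 = np.zeros(n_phi)
    theta0 = np.concatenate([lam0, psi0, phi0])
    res = optimize.minimize(objective, theta0, method="L-BFGS-B")
    if not res.success and res.fun > 1e5:
        raise RuntimeError(f"CFA did not converge: {res.message}")
    lam, psi, phi = unpack(res.x)
    return lam, psi, phi, res.fun


def _fit_indices(F_min, S, p, n_free, n_obs):
    chi2_m = (n_obs - 1) * F_min
    df_m = p * (p + 1) // 2 - n_free
    # independence baseline on the correlation structure
    D = np.sqrt(np.diag(S))
    R = S / np.outer(D, D)
    sign, logdetR = np.linalg.slogdet(R)
    F_b = -logdetR
    chi2_b = (n_obs - 1) * F_b
    df_b = p * (p - 1) // 2
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_m - df_m, chi2_b - df_b, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    rmsea = 0.0 if df_m <= 0 else float(
        np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * (n_obs - 1))))
    return float(cfi), rmsea, float(chi2_m), int(df_m)


def bartlett_scores(Z: np.ndarray, Lam: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Bartlett WLS factor scores: (L'P^-1 L)^-1 L'P^-1 z per row."""
    Pinv = np.diag(1.0 / psi)
    A = Lam.T @ Pinv @ Lam
    W = np.linalg.solve(A, Lam.T @ Pinv)
    return Z @ W.T


def fit_cfa(
    table: pd.DataFrame,
    spec: FactorSpec | None = None,
    prune: bool = True,
) -> FactorModelFit:
    """ML confirmatory factor analysis of a (z-scored) feature table.

    Features are z-scored internally; loadings below the cutoff are pruned
    and the model refit once. Factors reduced to a single indicator are
    identified by fixing that loading at 1 with near-zero uniqueness
    (saturated), so their Bartlett score reproduces the feature itself.
    """
    spec = spec or default_factor_spec(table.columns)
    feats = [f for f in spec.features if f in table.columns]
    data = table[feats].astype(float)
    data = data.loc[np.all(np.isfinite(data.to_numpy()), axis=1)]
    n_obs = len(data)
    if n_obs < 5 * len(feats):
        warnings.warn(
            f"only {n_obs} complete rows for {len(feats)} features; "
            "CFA estimates may be unstable")

    def build(feat_list):
        factors = [fac for fac, fs in spec.assignment.items()
                   if any(f in feat_list for f in fs)]
        pattern = []
        for f in feat_list:
            fac = next(fac for fac, fs in spec.assignment.items() if f in fs)
            pattern.append(factors.index(fac))
        counts = np.bincount(pattern, minlength=len(factors))
        fixed = {i: 1.0 for i, g in enumerate(pattern) if counts[g] == 1}
        return factors, np.asarray(pattern), fixed

    def run(feat_list):
        Z = stats.zscore(data[feat_list].to_numpy(), ddof=1)
        S = np.cov(Z, rowvar=False)
        factors, pattern, fixed = build(feat_list)
        lam, psi, phi, F_min = _fit_cfa_ml(S, pattern, len(factors), n_obs,
                                           fixed_lam=fixed)
        n_free = (len(feat_list) - len(fixed)) * 2 + len(factors) * (len(factors) - 1) // 2
        cfi, rmsea, chi2, df = _fit_indices(F_min, S, len(feat_list), n_free, n_obs)
        return Z, factors, pattern, lam, psi, phi, cfi, rmsea, chi2, df

    current = list(feats)
    Z, factors, pattern, lam, psi, phi, cfi, rmsea, chi2, df = run(current)
    pruned = []
    if prune:
        keep = [f for f, l in zip(current, lam) if abs(l) >= spec.loading_cutoff]
        pruned = [f for f in current if f not in keep]
        # never empty a factor below one indicator entirely by pruning all
        if pruned and keep:
            current = keep
            Z, factors, pattern, lam, psi, phi, cfi, rmsea, chi2, df = run(current)

    heywood = [f for f, u in zip(current, psi) if u <= 1e-5]
    if heywood:
        warnings.warn(f"Heywood case(s) (near-zero uniqueness): {heywood}")
    Lam = np.zeros((len(current), len(factors)))
    Lam[np.arange(len(current)), pattern] = lam
    scores = bartlett_scores(Z, Lam, np.maximum(psi, 1e-6))
    return FactorModelFit(
        loadings=pd.Series(lam, index=current),
        uniqueness=pd.Series(psi, index=current),
        factor_corr=pd.DataFrame(phi, index=factors, columns=factors),
        cfi=cfi, rmsea=rmsea,
        scores=pd.DataFrame(scores, columns=factors, index=data.index),
        pruned=pruned, spec=spec, n_obs=n_obs, chi2=chi2, df=df,
        heywood=heywood,
    )


# ---------------------------------------------------------------------------
# Summary-statistic group tests
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2 or self.sd < 0:
            raise ValueError("need n >= 2 and sd >= 0")


def summary_f_test(a: GroupSummary, b: GroupSummary):
    """Pooled-variance one-way ANOVA from two groups' (M, SD, n)."""
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if sp2 <= 0:
        raise ZeroDivisionError("zero pooled variance")
    F = (a.mean - b.mean) ** 2 / (sp2 * (1.0 / a.n + 1.0 / b.n))
    df = (1, a.n + b.n - 2)
    p = float(stats.f.sf(F, *df))
    return float(F), df, p


def chi2_yates(counts):
    """Yates-corrected chi-square for a 2x2 contingency table."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ZeroDivisionError("zero margin")
    chi2, p, _, expected = stats.chi2_contingency(counts, correction=True)
    if np.any(expected <= 0):
        raise ZeroDivisionError("zero expected count")
    return float(chi2), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Cross-validated ML harness
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    folds: int = 5
    repeats: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


def _make_learner(task: str, learner: str, seed: int):
    if task == "regression":
        if learner == "rf":
            return RandomForestRegressor(n_estimators=500, random_state=seed)
        if learner == "svm_rbf":
            return make_pipeline(StandardScaler(),
                                 SVR(kernel="rbf", gamma="scale", C=1.0))
        if learner == "mlr":
            return LinearRegression()
    else:
        if learner == "rf":
            return RandomForestClassifier(n_estimators=500, random_state=seed)
        if learner == "svm_rbf":
            return make_pipeline(
                StandardScaler(),
                SVC(kernel="rbf", gamma="scale", C=1.0,
                    decision_function_shape="ovr"))
        if learner == "mlr":
            return make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
    raise ValueError(f"unknown learner {learner!r} for task {task!r}")


def _binary_metrics(y, pred, score, positive):
    tp = np.sum((pred == positive) & (y == positive))
    tn = np.sum((pred != positive) & (y != positive))
    fp = np.sum((pred == positive) & (y != positive))
    fn = np.sum((pred != positive) & (y == positive))
    return {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
        "auc": roc_auc_score((y == positive).astype(int), score),
    }


def cv_evaluate(
    X, y, task: str, learner: str, cv: CVConfig | None = None
) -> dict:
    """Repeated k-fold cross-validation of one learner.

    Out-of-fold predictions are pooled within each repeat, metrics computed
    per repeat and averaged across repeats. Regression reports R^2 and
    RMSE; binary classification reports accuracy/sensitivity/specificity
    (positive class = lexicographically last label) and ROC AUC; multiclass
    adds per-pair metrics and an overall one-vs-one AUC. RF feature
    importances (mean impurity decrease, full-data fit) are attached.
    """
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if task == "regression":
        y = y.astype(float)
    else:
        classes = np.unique(y)
        if classes.size < 2 or np.min(np.bincount(
                np.searchsorted(classes, y))) < cv.folds:
            raise ValueError("each class needs at least `folds` members")

    per_repeat = []
    for r in range(cv.repeats):
        seed = cv.seed + r
        if task == "regression" or not cv.stratified:
            splitter = KFold(cv.folds, shuffle=True, random_state=seed)
            splits = splitter.split(X)
        else:
            splitter = StratifiedKFold(cv.folds, shuffle=True, random_state=seed)
            splits = splitter.split(X, y)
        oof_pred = np.empty(y.shape[0], dtype=object)
        oof_score = None
        for tr, te in splits:
            model = _make_learner(task, learner, seed)
            model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
            for i, v in zip(te, pred):
                oof_pred[i] = v
            if task != "regression":
                if hasattr(model, "predict_proba"):
                    sc = model.predict_proba(X[te])
                elif hasattr(model, "decision_function"):
                    sc = model.decision_function(X[te])
                    if sc.ndim == 1:
                        sc = sc[:, None]
                if oof_score is None:
                    oof_score = np.zeros((y.shape[0], sc.shape[1]))
                oof_score[te] = sc

        if task == "regression":
            pred = oof_pred.astype(float)
            ss_res = np.sum((y - pred) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            per_repeat.append({
                "r2": 1.0 - ss_res / ss_tot,
                "rmse": float(np.sqrt(ss_res / y.size)),
            })
        elif np.unique(y).size == 2:
            classes = np.unique(y)
            positive = classes[-1]
            score = (oof_score[:, -1] if oof_score.shape[1] > 1
                     else oof_score[:, 0])
            per_repeat.append(_binary_metrics(y, oof_pred, score, positive))
        else:
            classes = np.unique(y)
            m = {}
            aucs = []
            for i in range(classes.size):
                for j in range(i + 1, classes.size):
                    ci, cj = classes[i], classes[j]
                    mask = (y == ci) | (y == cj)
                    sub_pred = oof_pred[mask]
                    sub_y = y[mask]
                    # restrict predictions to the pair for pairwise metrics
                    correct = sub_pred == sub_y
                    key = f"{ci}_vs_{cj}"
                    tp = np.sum((sub_y == cj) & correct)
                    tn = np.sum((sub_y == ci) & correct)
                    m[f"accuracy_{key}"] = correct.mean()
                    m[f"sensitivity_{key}"] = tp / max(np.sum(sub_y == cj), 1)
                    m[f"specificity_{key}"] = tn / max(np.sum(sub_y == ci), 1)
                    if oof_score.shape[1] == classes.size:
                        si = oof_score[mask][:, j] - oof_score[mask][:, i]
                        aucs.append(roc_auc_score((sub_y == cj).astype(int), si))
            if aucs:
                m["auc"] = float(np.mean(aucs))
            per_repeat.append(m)

    metrics = {
        k: float(np.mean([rep[k] for rep in per_repeat]))
        for k in per_repeat[0]
    }
    out = {"metrics": metrics, "per_repeat": per_repeat}
    if learner == "rf":
        model = _make_learner(task, learner, cv.seed)
        model.fit(X, y)
        out["importance"] = np.asarray(model.feature_importances_)
    return out


# ---------------------------------------------------------------------------
# Printed-table reproduction helpers
# ---------------------------------------------------------------------------

def table1_statistics() -> dict:
    """Group comparisons of the study cohort from its printed summaries.

    13 ALS vs. 10 control participants: pooled one-way ANOVA from (M, SD, n)
    for age, speech intelligibility, and speaking rate; Yates-corrected
    chi-square for the sex split (5/13 vs. 7/10 women).
    """
    als_n, ctl_n = 13, 10
    out = {}
    rows = {
        "age_years": ((59.54, 12.78), (66.80, 13.02)),
        "intelligibility_pct": ((87.34, 25.03), (99.45, 0.56)),
        "speaking_rate_wpm": ((135.02, 41.27), (183.65, 23.02)),
    }
    for name, ((m1, s1), (m2, s2)) in rows.items():
        F, df, p = summary_f_test(GroupSummary(m1, s1, als_n),
                                  GroupSummary(m2, s2, ctl_n))
        out[name] = {"F": F, "df": df, "p": p}
    women_als = round(0.3846 * als_n)   # 5
    women_ctl = round(0.70 * ctl_n)     # 7
    chi2, p = chi2_yates([[women_als, als_n - women_als],
                          [women_ctl, ctl_n - women_ctl]])
    out["sex"] = {"chi2": chi2, "p": p}
    return out
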