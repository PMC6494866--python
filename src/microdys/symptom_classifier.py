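"""Random-forest symptom index, shadow-feature selection, and covariate tests.

The symptom index (SI) of a sample is the out-of-bag (OOB) vote fraction
for the symptomatic class from a random forest trained on normalized
abundances: a sample's score is computed only from trees whose bootstrap
did not contain it, which prevents overtraining without a held-out set.

Also provided: AUC with a DeLong confidence interval, an all-relevant
shadow-feature ("Boruta"-style) selector, per-covariate linear-regression
association tests with BH FDR, and Fisher's exact tests (2x2 exact;
r x c by Monte-Carlo simulation under fixed margins).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln
from scipy.stats import binomtest, fisher_exact, norm, rankdata
from scipy.stats.contingency import odds_ratio
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SEVEN_COVARIATES = ("age", "sex", "bmi", "antibiotics_recent", "ppi", "gi_surgery", "sibo")


@dataclass
class SymptomIndexResult:
    si: pd.Series                 # per-sample OOB probability of "symptomatic"
    auc: float
    ci_low: float
    ci_high: float
    auc_p: float                  # two-sided DeLong test against AUC = 0.5
    n_trees: int
    max_features: str
    seed: int | None


@dataclass
class FeatureSelection:
    """Outcome of shadow-feature selection."""

    status: pd.Series             # per feature: confirmed / tentative / rejected
    importance_history: pd.DataFrame  # iterations x features (real importances)
    n_iterations: int

    @property
    def confirmed(self) -> list:
        return list(self.status.index[self.status == "confirmed"])


def fit_symptom_index(
    features: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int | None = 0,
    positive_class: str = "symptomatic",
) -> SymptomIndexResult:
    """Fit the OOB-probability symptom index.

    Parameters
    ----------
    features : DataFrame (samples x features)
        Normalized abundances (see differential_power.normalize_counts).
    labels : Series of {"healthy", "symptomatic"} aligned to features.
    """
    labels = pd.Series(labels).reindex(features.index)
    classes, counts = np.unique(labels.to_numpy(), return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 5:
        raise ValueError("need at least 5 samples per class")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        max_features="sqrt",
        random_state=seed,
    )
    rf.fit(features.to_numpy(), labels.to_numpy())
    pos = list(rf.classes_).index(positive_class)
    oob = rf.oob_decision_function_[:, pos]
    oob = np.nan_to_num(oob, nan=0.5)
    si = pd.Series(oob, index=features.index, name="si")
    auc = evaluate_auc(si, labels, positive_class=positive_class)
    return SymptomIndexResult(
        si, auc["auc"], auc["ci_low"], auc["ci_high"], auc["p_value"], n_trees, "sqrt", seed
    )


def _delong_variance(pos_scores: np.ndarray, neg_scores: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from the structural-component decomposition."""
    m, n = len(pos_scores), len(neg_scores)
    all_scores = np.concatenate([pos_scores, neg_scores])
    r_all = rankdata(all_scores)
    r_pos = rankdata(pos_scores)
    r_neg = rankdata(neg_scores)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_pos) / n          # placement of each positive among negatives
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # placement of each negative among positives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def evaluate_auc(scores, labels, positive_class: str = "symptomatic", level: float = 0.95) -> dict:
    """AUC (Mann–Whitney) with DeLong CI and two-sided test vs. 0.5."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive_class
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        logger.warning("evaluate_auc: constant scores; AUC 0.5 with degenerate CI")
        return {"auc": 0.5, "ci_low": 0.5, "ci_high": 0.5, "p_value": 1.0}
    auc, var = _delong_variance(scores[y], scores[~y])
    se = math.sqrt(var) if var > 0 else 0.0
    zq = norm.ppf(0.5 + level / 2)
    if se > 0:
        p = 2 * norm.sf(abs(auc - 0.5) / se)
        lo, hi = auc - zq * se, auc + zq * se
    else:
        p = 0.0 if auc != 0.5 else 1.0
        lo = hi = auc
    return {
        "auc": float(auc),
        "ci_low": float(max(0.0, lo)),
        "ci_high": float(min(1.0, hi)),
        "p_value": float(p),
    }


def boruta_select(
    features: pd.DataFrame,
    labels,
    max_iter: int = 100,
    alpha: float = 0.01,
    seed: int | None = 0,
    n_trees: int = 500,
) -> FeatureSelection:
    """All-relevant feature selection with shuffled shadow features.

    Each iteration appends a shuffled copy of every still-undecided feature,
    fits a random forest, and scores a "hit" for each real feature whose
    impurity importance exceeds the maximum shadow importance.  A cumulative
    binomial test at ``alpha`` (null: hit probability 1/2) confirms features
    with significantly many hits and rejects those with significantly few;
    features still undecided after ``max_iter`` iterations stay tentative.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1); alpha >= 1 confirms everything vacuously")
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    X = features.to_numpy()
    names = list(features.columns)
    status = pd.Series("tentative", index=names)
    hits = pd.Series(0, index=names)
    trials = pd.Series(0, index=names)
    history = []
    for it in range(max_iter):
        active = [n for n in names if status[n] != "rejected"]
        if not active:
            break
        idx = [names.index(n) for n in active]
        Xa = X[:, idx]
        shadows = Xa.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31)),
        )
        rf.fit(np.hstack([Xa, shadows]), y)
        imp = rf.feature_importances_
        real_imp, shadow_imp = imp[: len(idx)], imp[len(idx):]
        shadow_max = shadow_imp.max()
        row = pd.Series(np.nan, index=names)
        row[active] = real_imp
        history.append(row)
        for n_, im in zip(active, real_imp):
            trials[n_] += 1
            if im > shadow_max:
                hits[n_] += 1
        # Bonferroni adjustment over the features still in play, as in the
        # reference implementation of the shadow-feature algorithm.
        adj_alpha = alpha / len(active)
        for n_ in active:
            if binomtest(hits[n_], trials[n_], 0.5, alternative="greater").pvalue < adj_alpha:
                status[n_] = "confirmed"
            elif binomtest(hits[n_], trials[n_], 0.5, alternative="less").pvalue < adj_alpha:
                if status[n_] != "confirmed":
                    status[n_] = "rejected"
        if (status != "tentative").all():
            break
    return FeatureSelection(status, pd.DataFrame(history, columns=names), len(history))


def covariate_regression(
    si: pd.Series,
    metadata: pd.DataFrame,
    covariates=SEVEN_COVARIATES,
    fdr_level: float = 0.1,
) -> dict:
    """Per-covariate simple linear regression of the SI, BH across covariates.

    Binary/categorical covariates are coded 0/1 (sex: M=1); the ``sibo``
    covariate is derived from ``sibo_cfu`` >= 1e5 when absent.  Missing
    values are dropped listwise per covariate (n used is reported).  The
    combined model refits jointly on the covariates passing q < fdr_level
    and reports its R².

    Returns dict with ``table`` (DataFrame) and ``combined_r2``,
    ``combined_covariates``.
    """
    si = pd.Series(si, dtype=float)
    meta = metadata.loc[si.index].copy()
    if "sibo" not in meta.columns and "sibo_cfu" in meta.columns:
        meta["sibo"] = (meta["sibo_cfu"] >= 1e5).astype(float)
    design = {}
    for cov in covariates:
        if cov not in meta.columns:
            logger.warning("covariate_regression: %r not in metadata; skipped", cov)
            continue
        x = meta[cov]
        if x.dtype == object or x.dtype.name in ("category", "bool"):
            if cov == "sex":
                x = (x == "M").astype(float)
            else:
                x = x.astype(bool).astype(float)
        design[cov] = pd.to_numeric(x, errors="coerce")
    rows = []
    for cov, x in design.items():
        mask = x.notna() & si.notna()
        if x[mask].nunique() < 2:
            logger.warning("covariate_regression: %r constant; skipped", cov)
            continue
        Xd = sm.add_constant(x[mask].to_numpy())
        fit = sm.OLS(si[mask].to_numpy(), Xd).fit()
        rows.append(
            {
                "covariate": cov,
                "effect": float(fit.params[1]),
                "se": float(fit.bse[1]),
                "p": float(fit.pvalues[1]),
                "n": int(mask.sum()),
            }
        )
    table = pd.DataFrame(rows).set_index("covariate")
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    selected = list(table.index[table["q"] < fdr_level])
    combined_r2 = np.nan
    if selected:
        Xc = pd.DataFrame({c: design[c] for c in selected})
        mask = Xc.notna().all(axis=1) & si.notna()
        fit = sm.OLS(si[mask].to_numpy(), sm.add_constant(Xc[mask].to_numpy())).fit()
        combined_r2 = float(fit.rsquared)
    return {"table": table, "combined_r2": combined_r2, "combined_covariates": selected}


def _table_log_prob(tab: np.ndarray) -> float:
    """Log conditional (hypergeometric) probability of an r x c table."""
    rs, cs, n = tab.sum(axis=1), tab.sum(axis=0), tab.sum()
    return float(
        gammaln(rs + 1).sum()
        + gammaln(cs + 1).sum()
        - gammaln(n + 1)
        - gammaln(tab + 1).sum()
    )


def categorical_association(table, n_mc: int = 10000, seed=None) -> dict:
    """Fisher's exact association test for a contingency table.

    2x2 tables get the exact two-sided hypergeometric p (summing tables with
    probability <= observed) and the conditional-MLE odds ratio with 95% CI.
    Larger r x c tables get a Monte-Carlo p: tables are sampled under fixed
    margins by permuting individual-level labels and compared by conditional
    probability (add-one estimator).
    """
    tab = np.asarray(table, dtype=np.int64)
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("empty row/column margin")
    if tab.shape == (2, 2):
        p = float(fisher_exact(tab).pvalue)
        orr = odds_ratio(tab)
        ci = orr.confidence_interval()
        return {
            "p_value": p,
            "odds_ratio": float(orr.statistic),
            "ci_low": float(ci.low),
            "ci_high": float(ci.high),
            "method": "exact",
        }
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    obs_lp = _table_log_prob(tab)
    rows = np.repeat(np.arange(tab.shape[0]), tab.sum(axis=1))
    cols = np.repeat(np.arange(tab.shape[1]), tab.sum(axis=0))
    hits = 0
    for _ in range(int(n_mc)):
        perm = rng.permutation(cols)
        t = np.zeros_like(tab)
        np.add.at(t, (rows, perm), 1)
        if _table_log_prob(t) <= obs_lp + 1e-9:
            hits += 1
    p = (1 + hits) / (1 + int(n_mc))
    return {"p_value": float(p), "odds_ratio": None, "method": f"monte-carlo({n_mc})"}
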