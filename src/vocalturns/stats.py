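"""Response-probability and response-delay models.

Whether a call receives a response is modelled with a mixed-effects logistic
regression (per-call predictors as fixed effects, caller and partner identity
as random intercepts), reported as odds ratios with a marginal R².  Response
delay uses the same structure with a linear link.  Predictability is
additionally assessed with cross-validated classifiers (logistic regression
and random forest) with per-predictor importances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests


def counterbalance(rows: pd.DataFrame, seed: int = 0,
                   label: str = "response") -> pd.DataFrame:
    """Per session, subsample the majority class (without replacement) to the
    minority count; sessions lacking either class are dropped.  Row contents
    are never altered, only membership."""
    rng = np.random.default_rng(seed)
    kept = []
    for _, grp in rows.groupby("session_id", sort=True):
        pos = grp[grp[label] == 1]
        neg = grp[grp[label] == 0]
        k = min(len(pos), len(neg))
        if k == 0:
            continue
        for cls in (pos, neg):
            idx = (cls.index if len(cls) == k
                   else rng.choice(cls.index, size=k, replace=False))
            kept.append(cls.loc[np.sort(idx)])
    if not kept:
        return rows.iloc[0:0]
    return pd.concat(kept).sort_index().reset_index(drop=True)


def _standardize(rows: pd.DataFrame, predictors) -> pd.DataFrame:
    out = rows.copy()
    for p in predictors:
        sd = out[p].std()
        out[p] = (out[p] - out[p].mean()) / sd if sd > 0 else 0.0
    return out


@dataclass
class MixedLogisticResult:
    table: pd.DataFrame          # predictor, beta, se, odds_ratio, CI, p, holm
    marginal_r2: float
    converged: bool
    standardized: bool = True

    def odds_ratio(self, predictor: str) -> float:
        return float(self.table.set_index("predictor")
                     .loc[predictor, "odds_ratio"])


def fit_mixed_logistic(rows: pd.DataFrame, predictors=None,
                       label: str = "response",
                       standardize: bool = True) -> MixedLogisticResult:
    """Mixed-effects logistic regression of response on per-call predictors.

    Random intercepts for caller and partner identity; fit by variational
    Bayes (statsmodels ``BinomialBayesMixedGLM``).  Predictors are z-scored
    by default so odds ratios are per SD.  The marginal R² follows the
    variance-partition definition for a logistic mixed model:
    var(Xb) / (var(Xb) + sum of random-intercept variances + pi^2/3).
    """
    if predictors is None:
        predictors = rows.attrs.get("predictors")
    if predictors is None:
        raise ValueError("predictors must be given")
    data = rows.dropna(subset=list(predictors)).reset_index(drop=True)
    if standardize:
        data = _standardize(data, predictors)
    for g in ("caller_id", "partner_id"):
        if data[g].nunique() < 2:
            raise ValueError(f"grouping factor {g} needs >= 2 levels")
    formula = f"{label} ~ " + " + ".join(predictors)
    vcf = {"caller": "0 + C(caller_id)", "partner": "0 + C(partner_id)"}
    model = BinomialBayesMixedGLM.from_formula(formula, vcf, data)
    converged = True
    try:
        fit = model.fit_vb()
    except Exception:
        fit = model.fit_map()
        converged = False
    names = fit.model.exog_names
    beta = np.asarray(fit.fe_mean)
    se = np.asarray(fit.fe_sd)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * sps.norm.sf(np.abs(z))
    tab = pd.DataFrame({
        "predictor": names,
        "beta": beta,
        "se": se,
        "odds_ratio": np.exp(beta),
        "or_lo": np.exp(beta - 1.96 * se),
        "or_hi": np.exp(beta + 1.96 * se),
        "p_value": p,
    })
    fixed = tab["predictor"] != "Intercept"
    holm = np.zeros(len(tab), bool)
    holm[fixed.to_numpy()] = multipletests(
        tab.loc[fixed, "p_value"], method="holm")[0]
    tab["holm_significant"] = holm
    # marginal R^2 (variance partition on the latent logistic scale)
    X = fit.model.exog
    var_fixed = float(np.var(X @ beta))
    vc_sd = np.exp(np.asarray(fit.vcp_mean))
    var_random = float(np.sum(vc_sd ** 2))
    r2 = var_fixed / (var_fixed + var_random + np.pi ** 2 / 3)
    return MixedLogisticResult(tab, r2, converged, standardize)


@dataclass
class DelayModelResult:
    table: pd.DataFrame
    converged: bool


def fit_delay_model(rows: pd.DataFrame, predictors=None,
                    label: str = "delay",
                    standardize: bool = True) -> DelayModelResult:
    """Linear mixed model for response delay, same effects structure as the
    logistic model (crossed random intercepts for caller and partner)."""
    if predictors is None:
        predictors = rows.attrs.get("predictors")
    data = rows.dropna(subset=list(predictors) + [label]).reset_index(drop=True)
    if len(data) == 0:
        raise ValueError("no rows with defined delay")
    if standardize:
        data = _standardize(data, predictors)
    data = data.assign(_one=1)
    formula = f"{label} ~ " + " + ".join(predictors)
    vcf = {"caller": "0 + C(caller_id)", "partner": "0 + C(partner_id)"}
    model = MixedLM.from_formula(formula, data, re_formula="0",
                                 vc_formula=vcf, groups="_one")
    try:
        fit = model.fit(reml=True)
        converged = bool(fit.converged)
    except Exception:
        fit = model.fit(reml=False, method="lbfgs")
        converged = False
    keep = [n for n in fit.fe_params.index]
    ci = fit.conf_int().loc[keep]
    tab = pd.DataFrame({
        "predictor": keep,
        "estimate": fit.fe_params.values,
        "ci_lo": ci[0].values,
        "ci_hi": ci[1].values,
        "p_value": fit.pvalues.loc[keep].values,
    })
    return DelayModelResult(tab, converged)


@dataclass
class ClassifierResult:
    method: str
    fold_accuracies: np.ndarray
    accuracy: float
    p_vs_chance: float
    importance: pd.Series  # indexed by predictor, normalized to max 1

    def top_predictor(self) -> str:
        return str(self.importance.idxmax())


def classify_response(rows: pd.DataFrame, method: str = "forest",
                      predictors=None, label: str = "response",
                      k_folds: int = 5, seed: int = 0,
                      n_estimators: int = 100) -> ClassifierResult:
    """Cross-validated response classifier with per-predictor importance.

    ``linear`` is a logistic regression on standardized predictors with
    importance = mean absolute standardized weight; ``forest`` is a random
    forest with permutation importance measured on each held-out fold.
    Fold accuracies are tested against chance (0.5) with a one-sample t-test.
    Input rows should already be counterbalanced.
    """
    if predictors is None:
        predictors = rows.attrs.get("predictors")
    data = rows.dropna(subset=list(predictors)).reset_index(drop=True)
    y = data[label].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    X = data[list(predictors)].to_numpy()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs, imps = [], []
    for train, test in skf.split(X, y):
        if method == "linear":
            clf = make_pipeline(StandardScaler(),
                                LogisticRegression(max_iter=1000))
            clf.fit(X[train], y[train])
            accs.append(clf.score(X[test], y[test]))
            imps.append(np.abs(clf[-1].coef_[0]))
        elif method == "forest":
            clf = RandomForestClassifier(n_estimators=n_estimators,
                                         random_state=seed, n_jobs=1)
            clf.fit(X[train], y[train])
            accs.append(clf.score(X[test], y[test]))
            pi = permutation_importance(clf, X[test], y[test], n_repeats=3,
                                        random_state=seed, n_jobs=1)
            imps.append(pi.importances_mean)
        else:
            raise ValueError("method must be 'linear' or 'forest'")
    accs = np.array(accs)
    imp = np.mean(imps, axis=0)
    if np.max(np.abs(imp)) > 0:
        imp = imp / np.max(np.abs(imp))
    t = sps.ttest_1samp(accs, 0.5, alternative="greater")
    return ClassifierResult(method, accs, float(accs.mean()),
                            float(t.pvalue),
                            pd.Series(imp, index=list(predictors)))
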