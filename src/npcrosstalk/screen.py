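"""Lasso screening of neuropeptides, single-gene ROC/AUC and group-comparison
boxplot statistics.

The screen fits an L1-penalized regression of case/control status on the
standardized neuropeptide expression matrix over a log-spaced λ grid, picks λ
by stratified K-fold cross-validation (λ_min by default; λ_1se — the largest
λ whose CV loss is within one standard error of the minimum — by option), and
reports the genes with nonzero coefficients at the chosen penalty.  Per-gene
discriminative power is summarized by the ROC curve and the rank-statistic
AUC (the probability that a random case sample exceeds a random control
sample, ties counted half).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .bundle import GROUP_CASE, GROUP_CONTROL, ExpressionBundle

logger = logging.getLogger(__name__)


@dataclass
class LassoScreenResult:
    disease: str
    lambdas: np.ndarray              # decreasing λ grid
    cv_mean: np.ndarray              # mean CV loss per λ
    cv_se: np.ndarray                # standard error of the CV loss per λ
    lambda_min: float
    lambda_1se: float
    selected: list[str]              # nonzero-coefficient genes at chosen λ
    selected_1se: list[str]
    coef_path: pd.DataFrame = field(repr=False)  # genes × λ coefficients


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int, ratio: float) -> np.ndarray:
    """Log-spaced grid from the smallest λ that zeroes every coefficient
    (max absolute gradient of the unpenalized loss at β=0) down by *ratio*."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _fit_at_lambda(X, y, lam, model: str):
    n = len(y)
    if model == "logistic":
        # fixed random_state: liblinear's dual solver shuffles internally and
        # bit-reproducibility of the CV curve is part of the pipeline contract
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", max_iter=2000,
            tol=1e-6, random_state=0,
        )
        clf.fit(X, y)
        return clf.coef_.ravel(), clf
    # linear lasso on the 0/1 response
    reg = Lasso(alpha=lam, max_iter=20000, tol=1e-8)
    reg.fit(X, y)
    return reg.coef_.ravel(), reg


def _cv_loss(model_obj, X, y, model: str, cv_loss: str) -> float:
    if model == "logistic":
        prob = model_obj.predict_proba(X)[:, 1]
    else:
        prob = np.clip(model_obj.predict(X), 0.0, 1.0)
    if cv_loss == "mse":
        return float(((y - prob) ** 2).mean())
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    # binomial deviance (2 × negative log-likelihood per sample)
    return float(-2.0 * (y * np.log(prob) + (1 - y) * np.log(1 - prob)).mean())


def lasso_screen(
    bundle: ExpressionBundle,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 50,
    lambda_ratio: float = 1e-3,
    model: str = "logistic",
    cv_loss: str = "deviance",
    lambda_choice: str = "min",
) -> LassoScreenResult:
    """Cross-validated L1 screen of the bundle's genes as predictors of
    case/control status.

    The bundle should already be restricted to the candidate panel (e.g. the
    neuropeptide genes).  Features are z-scored internally.
    """
    if model not in {"logistic", "linear"}:
        raise ValueError("model must be 'logistic' or 'linear'")
    if cv_loss not in {"deviance", "mse"}:
        raise ValueError("cv_loss must be 'deviance' or 'mse'")
    if lambda_choice not in {"min", "1se"}:
        raise ValueError("lambda_choice must be 'min' or '1se'")
    y = (bundle.metadata["group"] == GROUP_CASE).to_numpy(float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need ≥2 samples per class")

    raw = bundle.matrix.to_numpy(float).T  # samples × genes
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    sd[sd == 0] = 1.0
    X = (raw - mean) / sd
    genes = list(bundle.genes)

    lambdas = _lambda_grid(X, y, n_lambda, lambda_ratio)
    folds = min(folds, int(min((y == c).sum() for c in classes)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    losses = np.zeros((folds, len(lambdas)))
    for f, (train, test) in enumerate(skf.split(X, y)):
        for j, lam in enumerate(lambdas):
            _, fitted = _fit_at_lambda(X[train], y[train], lam, model)
            losses[f, j] = _cv_loss(fitted, X[test], y[test], model, cv_loss)
    cv_mean = losses.mean(axis=0)
    cv_se = losses.std(axis=0, ddof=1) / np.sqrt(folds)

    j_min = int(np.argmin(cv_mean))
    lambda_min = float(lambdas[j_min])
    within = cv_mean <= cv_mean[j_min] + cv_se[j_min]
    j_1se = int(np.flatnonzero(within).min())  # grid is decreasing: smallest index = largest λ
    lambda_1se = float(lambdas[j_1se])

    path = np.column_stack(
        [_fit_at_lambda(X, y, lam, model)[0] for lam in lambdas]
    )
    coef_path = pd.DataFrame(path, index=genes, columns=[f"{l:.6g}" for l in lambdas])
    sel_min = [g for g, c in zip(genes, path[:, j_min]) if c != 0]
    sel_1se = [g for g, c in zip(genes, path[:, j_1se]) if c != 0]
    chosen = sel_min if lambda_choice == "min" else sel_1se
    logger.info(
        "%s lasso screen: %d genes at lambda_min=%.4g, %d at lambda_1se=%.4g",
        bundle.disease, len(sel_min), lambda_min, len(sel_1se), lambda_1se,
    )
    return LassoScreenResult(
        disease=bundle.disease,
        lambdas=lambdas,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=lambda_min,
        lambda_1se=lambda_1se,
        selected=sorted(chosen),
        selected_1se=sorted(sel_1se),
        coef_path=coef_path,
    )


def intersect_selected(sel_a, sel_b) -> list[str]:
    """Sorted intersection of two per-disease selections."""
    return sorted(set(sel_a) & set(sel_b))


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocResult:
    gene: str
    disease: str
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


def roc_auc(values: np.ndarray, labels: np.ndarray, gene: str = "", disease: str = "") -> RocResult:
    """Single-gene ROC with rank-statistic AUC.

    AUC = P(case value > control value) + ½·P(tie), computed from the
    Mann–Whitney U statistic (midranks handle ties).  Positive class is
    case; the value is reported as-is, with no direction flipping.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    case = values[labels == 1]
    ctrl = values[labels == 0]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both classes must be present")
    if np.ptp(values) == 0:
        warnings.warn(f"constant values for {gene or 'gene'}; AUC set to 0.5")
        return RocResult(gene, disease, 0.5, np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    u_stat = stats.mannwhitneyu(case, ctrl, alternative="two-sided").statistic
    auc = float(u_stat / (len(case) * len(ctrl)))
    fpr, tpr, _ = _sk_roc_curve(labels, values)
    return RocResult(gene, disease, auc, fpr, tpr)


def roc_table(bundle: ExpressionBundle, genes) -> pd.DataFrame:
    """Per-gene AUC for the listed genes of one bundle."""
    labels = (bundle.metadata["group"] == GROUP_CASE).to_numpy(int)
    rows = []
    for gene in genes:
        res = roc_auc(bundle.matrix.loc[gene].to_numpy(), labels, gene, bundle.disease)
        rows.append((gene, bundle.disease, res.auc))
    return pd.DataFrame(rows, columns=["gene", "disease", "auc"])


# ---------------------------------------------------------------------------
# boxplot statistics


STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Boundary-inclusive star code: p ≤ 0.0001 '****', ≤ 0.001 '***',
    ≤ 0.01 '**', ≤ 0.05 '*', otherwise 'ns'."""
    for cut, stars in STAR_THRESHOLDS:
        if p <= cut:
            return stars
    return "ns"


def group_stats(values: np.ndarray, labels: np.ndarray) -> dict:
    """Median/quartile summary per group plus a two-sided Wilcoxon rank-sum
    p-value and its star code."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    case = values[labels == 1]
    ctrl = values[labels == 0]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both classes must be present")
    p = float(stats.mannwhitneyu(case, ctrl, alternative="two-sided").pvalue)
    out = {"p": p, "stars": significance_stars(p)}
    for name, vals in ((GROUP_CASE, case), (GROUP_CONTROL, ctrl)):
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[name] = {"median": float(med), "q1": float(q1), "q3": float(q3), "n": int(len(vals))}
    return out


def boxplot_table(bundle: ExpressionBundle, genes) -> pd.DataFrame:
    labels = (bundle.metadata["group"] == GROUP_CASE).to_numpy(int)
    rows = []
    for gene in genes:
        s = group_stats(bundle.matrix.loc[gene].to_numpy(), labels)
        rows.append(
            (
                gene, bundle.disease,
                s["case"]["median"], s["case"]["q1"], s["case"]["q3"],
                s["control"]["median"], s["control"]["q1"], s["control"]["q3"],
                s["p"], s["stars"],
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "disease", "case_median", "case_q1", "case_q3",
            "control_median", "control_q1", "control_q3", "p", "stars",
        ],
    )
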