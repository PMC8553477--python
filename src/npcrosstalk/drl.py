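"""Correlation screening of crosstalk–neuropeptide pairs and the
differentially-regulated-link (DRL) statistic.

For a crosstalk gene *x* and neuropeptide *y* within one disease cohort,
ordinary least squares is fitted separately in the case and control groups,

    y ~ β·x + β0,

yielding per-group slopes β_case, β_control with standard errors sd_case,
sd_control (sd = s_resid / sqrt(Σ(x−x̄)²)).  With CC_all the Pearson
correlation of the pair over all samples of the disease, the DRL score is

    DRL = (β_case − β_control) / sqrt(sd_case² + sd_control²) + CC_all.

The first term is a Wald-type contrast of the two regression slopes; a
positive DRL is read as consistent regulation of the pair in case and control
samples, a negative one as opposite regulation modes.  Pairs enter the DRL
stage only if they pass the correlation screen |CC| > cc_cut (strict), by
default evaluated on the case group of each disease.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import GROUP_CASE, GROUP_CONTROL, ExpressionBundle

logger = logging.getLogger(__name__)

SIGN_CONSISTENT = "consistent"
SIGN_OPPOSITE = "opposite"


@dataclass(frozen=True)
class GroupFit:
    slope: float
    intercept: float
    slope_se: float


# ---------------------------------------------------------------------------
# correlations


def pairwise_correlation(
    bundle: ExpressionBundle,
    genes_a: list[str],
    genes_b: list[str],
    sample_subset=None,
) -> pd.DataFrame:
    """Pearson r for every (a, b) pair over the chosen sample subset.

    Zero-variance genes in the subset yield NaN correlations (the pair is
    excluded from screening) with a logged warning.  Returns a DataFrame
    indexed by genes_a with columns genes_b.
    """
    samples = list(sample_subset) if sample_subset is not None else list(bundle.samples)
    if len(samples) < 3:
        raise ValueError("need ≥3 samples to compute correlations")
    sub_a = bundle.matrix.loc[genes_a, samples].to_numpy(float)
    sub_b = bundle.matrix.loc[genes_b, samples].to_numpy(float)

    def _standardize(mat: np.ndarray, names: list[str]) -> np.ndarray:
        centered = mat - mat.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        flat = norms == 0
        if flat.any():
            bad = [names[i] for i in np.flatnonzero(flat)]
            logger.warning("zero-variance gene(s) in subset, correlations undefined: %s", bad)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = centered / norms[:, None]
        z[flat] = np.nan
        return z

    za = _standardize(sub_a, list(genes_a))
    zb = _standardize(sub_b, list(genes_b))
    r = np.clip(za @ zb.T, -1.0, 1.0)
    return pd.DataFrame(r, index=pd.Index(genes_a, name="gene_a"), columns=genes_b)


def screen_pairs(correlations: pd.DataFrame, cc_cut: float = 0.5) -> list[tuple[str, str, float]]:
    """Keep pairs with |r| strictly greater than cc_cut; NaN pairs excluded.

    Returns sorted (gene_a, gene_b, r) tuples.
    """
    out = []
    values = correlations.to_numpy()
    for i, a in enumerate(correlations.index):
        for j, b in enumerate(correlations.columns):
            r = values[i, j]
            if np.isfinite(r) and abs(r) > cc_cut:
                out.append((a, b, float(r)))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


# ---------------------------------------------------------------------------
# per-group regressions and DRL


def _ols_simple(x: np.ndarray, y: np.ndarray) -> GroupFit:
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        raise ValueError("constant predictor within group")
    slope = float(((x - xbar) * (y - ybar)).sum() / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - (slope * x + intercept)
    s_sq = float((resid**2).sum()) / (n - 2)
    return GroupFit(slope=slope, intercept=intercept, slope_se=math.sqrt(max(s_sq, 0.0) / sxx))


def fit_group_regressions(
    bundle: ExpressionBundle, crosstalk_gene: str, neuropeptide: str
) -> tuple[GroupFit, GroupFit]:
    """Per-group OLS of neuropeptide (y) on crosstalk gene (x).

    Returns (case fit, control fit); each group needs ≥3 samples and a
    non-constant predictor.
    """
    fits = []
    for group in (GROUP_CASE, GROUP_CONTROL):
        mask = bundle.group_mask(group)
        if mask.sum() < 3:
            raise ValueError(f"group {group!r} has <3 samples")
        x = bundle.matrix.loc[crosstalk_gene].to_numpy(float)[mask]
        y = bundle.matrix.loc[neuropeptide].to_numpy(float)[mask]
        try:
            fits.append(_ols_simple(x, y))
        except ValueError as err:
            raise ValueError(
                f"pair ({crosstalk_gene}, {neuropeptide}), group {group}: {err}"
            ) from err
    return fits[0], fits[1]


def compute_drl(
    beta_case: float,
    beta_control: float,
    sd_case: float,
    sd_control: float,
    cc_all: float,
) -> tuple[float, str]:
    """DRL = (β_case − β_control)/sqrt(sd_case² + sd_control²) + CC_all.

    Returns (value, sign class).  Raises when both slope standard errors are
    zero (noise-free fixture; the Wald term is undefined).
    """
    denom_sq = sd_case**2 + sd_control**2
    if denom_sq <= 0:
        raise ZeroDivisionError("both slope standard errors are zero; DRL undefined")
    value = (beta_case - beta_control) / math.sqrt(denom_sq) + cc_all
    sign = SIGN_OPPOSITE if value < 0 else SIGN_CONSISTENT
    return value, sign


# ---------------------------------------------------------------------------
# full table


def drl_table(
    bundle: ExpressionBundle,
    crosstalk: list[str],
    neuropeptides: list[str],
    cc_cut: float = 0.5,
    screen_on: str = "case",
) -> pd.DataFrame:
    """Screen all crosstalk × neuropeptide pairs of one disease and score the
    survivors with the DRL statistic.

    ``screen_on`` selects the sample subset for the |CC| screen: ``"case"``
    (default — the case-group correlation) or ``"all"`` (all samples).
    CC_all in the DRL formula always uses all samples of the disease.
    """
    if screen_on not in {"case", "all"}:
        raise ValueError("screen_on must be 'case' or 'all'")
    crosstalk = [g for g in crosstalk if g in bundle.matrix.index]
    neuropeptides = [g for g in neuropeptides if g in bundle.matrix.index]
    cols = [
        "disease", "crosstalk", "neuropeptide", "beta_case", "beta_control",
        "sd_case", "sd_control", "cc_case", "cc_all", "drl", "sign",
    ]
    if not crosstalk or not neuropeptides:
        return pd.DataFrame(columns=cols)

    case_samples = list(bundle.case_samples())
    cc_case = pairwise_correlation(bundle, crosstalk, neuropeptides, case_samples)
    cc_all = pairwise_correlation(bundle, crosstalk, neuropeptides, None)
    screen_source = cc_case if screen_on == "case" else cc_all
    kept = screen_pairs(screen_source, cc_cut)
    logger.info(
        "%s: %d/%d pairs pass |CC|>%g screen (%s-group correlations)",
        bundle.disease, len(kept), len(crosstalk) * len(neuropeptides), cc_cut, screen_on,
    )

    rows = []
    for gene_c, gene_n, _ in kept:
        try:
            fit_case, fit_ctrl = fit_group_regressions(bundle, gene_c, gene_n)
            value, sign = compute_drl(
                fit_case.slope, fit_ctrl.slope, fit_case.slope_se, fit_ctrl.slope_se,
                float(cc_all.loc[gene_c, gene_n]),
            )
        except (ValueError, ZeroDivisionError) as err:
            logger.warning("pair (%s, %s) dropped: %s", gene_c, gene_n, err)
            continue
        rows.append(
            (
                bundle.disease, gene_c, gene_n,
                fit_case.slope, fit_ctrl.slope, fit_case.slope_se, fit_ctrl.slope_se,
                float(cc_case.loc[gene_c, gene_n]), float(cc_all.loc[gene_c, gene_n]),
                value, sign,
            )
        )
    table = pd.DataFrame(rows, columns=cols)
    return table.sort_values(["crosstalk", "neuropeptide"], kind="mergesort").reset_index(drop=True)


def join_disease_tables(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Inner join of two per-disease DRL tables on the (crosstalk,
    neuropeptide) pair, for cross-disease comparison of regulation strength."""
    keys = ["crosstalk", "neuropeptide"]
    a = table_a.set_index(keys)
    b = table_b.set_index(keys)
    joined = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    return joined.sort_index().reset_index()
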