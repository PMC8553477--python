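"""Moderated-t differential expression with per-disease threshold presets.

Per gene, a two-group comparison on the log2 matrix: log2FC is the difference
of group means (case − control), and the t statistic uses an empirical-Bayes
posterior variance that shrinks each gene's pooled residual variance s_g²
toward a common prior s_0² fitted across genes (the limma-style scaled
inverse-chi-square model):

    s̃_g² = (d0·s0² + dg·sg²) / (d0 + dg),
    t_g  = log2FC_g / (s̃_g · sqrt(1/n1 + 1/n2)),  df = dg + d0.

The prior parameters (d0, s0²) are fitted by matching moments of the log
sample variances (Smyth's construction).  No multiple-testing correction is
applied: genes are filtered on the raw p-value, matching the original
screening thresholds (case/control studies of this kind commonly report raw
p < 0.05 with a fold-change cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .bundle import GROUP_CASE, GROUP_CONTROL, ExpressionBundle

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NS = "ns"


@dataclass(frozen=True)
class DEGThresholds:
    """DEG selection cutoffs.

    ``lfc_inclusive`` chooses between ``|log2FC| ≥ lfc_cut`` (inclusive) and
    ``|log2FC| > lfc_cut`` (strict).  The two study presets:

    - MDD: p < 0.05 and |log2FC| > 0 (strict; any nonzero fold change)
    - PD:  p < 0.05 and |log2FC| ≥ 0.5 (inclusive)
    """

    p_cut: float = 0.05
    lfc_cut: float = 0.0
    lfc_inclusive: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_cut < 1):
            raise ValueError("p_cut must lie in (0,1)")
        if self.lfc_cut < 0:
            raise ValueError("lfc_cut must be non-negative")


MDD_PRESET = DEGThresholds(p_cut=0.05, lfc_cut=0.0, lfc_inclusive=False)
PD_PRESET = DEGThresholds(p_cut=0.05, lfc_cut=0.5, lfc_inclusive=True)

PRESETS = {"mdd": MDD_PRESET, "pd": PD_PRESET}


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0); trigamma is decreasing."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    f = lambda x: special.polygamma(1, x) - y
    lo, hi = 1e-8, 1e8
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def fit_variance_prior(sample_vars: np.ndarray, df: float) -> tuple[float, float]:
    """Fit (d0, s0²) of the scaled inverse-chi-square variance prior by
    moment matching on log sample variances.  Returns d0 = inf when the
    observed spread of log variances is no wider than sampling noise alone
    (complete shrinkage: all genes share s0²)."""
    positive = sample_vars[sample_vars > 0]
    if positive.size < 2:
        raise ValueError("need ≥2 positive gene variances to fit the prior")
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return math.inf, math.exp(e_mean)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_sq


def fit_moderated_ttest(bundle: ExpressionBundle, shrink: bool = True) -> pd.DataFrame:
    """Per-gene moderated t-test of case vs control.

    Parameters
    ----------
    shrink
        Disable to obtain the ordinary pooled-variance Student t (d0 = 0),
        used for oracle comparison.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2FC``, ``t``, ``p``,
    ``s2_post``, ``df_total``.
    """
    case = bundle.matrix.loc[:, bundle.group_mask(GROUP_CASE)].to_numpy(float)
    ctrl = bundle.matrix.loc[:, bundle.group_mask(GROUP_CONTROL)].to_numpy(float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need ≥2 samples per group (got case={n1}, control={n2})")
    dg = n1 + n2 - 2

    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    sg_sq = ss / dg
    if np.all(sg_sq <= 0):
        raise ValueError("all genes have zero residual variance; degenerate input")

    if shrink:
        d0, s0_sq = fit_variance_prior(sg_sq, dg)
        if math.isinf(d0):
            s_post = np.full_like(sg_sq, s0_sq)
            df_total = np.inf
        else:
            s_post = (d0 * s0_sq + dg * sg_sq) / (d0 + dg)
            df_total = dg + d0
    else:
        s_post = sg_sq
        df_total = dg

    scale = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(scale > 0, lfc / scale, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    return pd.DataFrame(
        {"log2FC": lfc, "t": t, "p": p, "s2_post": s_post, "df_total": df_total},
        index=bundle.genes,
    )


def select_degs(table: pd.DataFrame, thr: DEGThresholds) -> tuple[set[str], set[str]]:
    """Split genes into up/down sets by the thresholds; everything else is ns."""
    if table.empty:
        raise ValueError("empty DEG table")
    sig = table["p"] < thr.p_cut
    if thr.lfc_inclusive:
        up = sig & (table["log2FC"] >= thr.lfc_cut)
        down = sig & (table["log2FC"] <= -thr.lfc_cut)
        if thr.lfc_cut == 0:
            # inclusive cutoff 0 would put log2FC == 0 in both sets; break
            # the tie by requiring a nonzero fold change
            up &= table["log2FC"] != 0
            down &= table["log2FC"] != 0
    else:
        up = sig & (table["log2FC"] > thr.lfc_cut)
        down = sig & (table["log2FC"] < -thr.lfc_cut)
    return set(table.index[up]), set(table.index[down])


def classify_degs(table: pd.DataFrame, thr: DEGThresholds) -> pd.Series:
    up, down = select_degs(table, thr)
    direction = pd.Series(DIRECTION_NS, index=table.index, name="direction")
    direction[list(up)] = DIRECTION_UP
    direction[list(down)] = DIRECTION_DOWN
    return direction


def volcano_table(table: pd.DataFrame, thr: DEGThresholds) -> pd.DataFrame:
    """Per-gene (log2FC, −log10 p, class) export backing a volcano plot."""
    if table.empty:
        raise ValueError("empty DEG table")
    return pd.DataFrame(
        {
            "log2FC": table["log2FC"],
            "neg_log10_p": -np.log10(table["p"]),
            "class": classify_degs(table, thr),
        },
        index=table.index,
    )
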