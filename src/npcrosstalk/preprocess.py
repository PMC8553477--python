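"""Probe collapsing, multi-dataset merging, empirical-Bayes batch correction
and PCA-based before/after QC.

The batch correction implements the parametric empirical-Bayes location/scale
model of Johnson, Li & Rabinovic (the ComBat model): per gene, expression in
batch *i* is

    y_ijg = alpha_g + X beta_g + gamma_ig + delta_ig * eps_ijg

Gene-wise batch effects ``gamma_ig`` (additive) and ``delta_ig²``
(multiplicative) are estimated on standardized data and shrunk toward
batch-level normal / inverse-gamma priors fitted by method of moments, then
removed.  The biological group covariate can be protected so the correction
does not absorb the case/control signal.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .bundle import ExpressionBundle, ProbeMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# probe collapsing and merging


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: ProbeMap) -> pd.DataFrame:
    """Collapse a probe × sample matrix to gene × sample by averaging probes.

    Each gene's expression in a sample is the arithmetic mean of its mapped
    probes in that sample; unmapped probes are dropped.  Gene order in the
    output is lexicographic.
    """
    if len(probe_map) == 0:
        raise ValueError("probe map is empty")
    symbols = probe_matrix.index.map(lambda p: probe_map.get(str(p)))
    keep = symbols.notna()
    if not keep.any():
        raise ValueError("no probe in the matrix maps to a gene symbol")
    mapped = probe_matrix.loc[keep].copy()
    mapped.index = pd.Index(symbols[keep], name="gene")
    collapsed = mapped.groupby(level=0).mean()
    return collapsed.sort_index()


def merge_datasets(bundles: list[ExpressionBundle]) -> ExpressionBundle:
    """Combine per-dataset bundles of one disease into a single cohort.

    Genes are intersected across datasets, samples concatenated, and the batch
    label set to the source dataset id (taken from each bundle's single batch
    label).  Sample ids colliding across datasets are prefixed by the batch id.
    """
    if not bundles:
        raise ValueError("need at least one bundle")
    diseases = {b.disease for b in bundles}
    if len(diseases) > 1:
        raise ValueError(f"bundles span multiple diseases: {sorted(diseases)}")
    shared = bundles[0].genes
    for b in bundles[1:]:
        shared = shared.intersection(b.genes)
    if len(shared) == 0:
        raise ValueError("empty gene intersection across datasets")
    shared = shared.sort_values()

    matrices, metas = [], []
    seen: set[str] = set()
    for bundle in bundles:
        mat = bundle.matrix.loc[shared]
        meta = bundle.metadata.copy()
        batch_ids = meta["batch"].astype(str)
        rename = {}
        for sid, bid in zip(meta.index, batch_ids):
            new = sid if sid not in seen else f"{bid}:{sid}"
            if new in seen:
                raise ValueError(f"cannot disambiguate sample id {sid!r}")
            rename[sid] = new
            seen.add(new)
        matrices.append(mat.rename(columns=rename))
        metas.append(meta.rename(index=rename))
    merged = ExpressionBundle(
        matrix=pd.concat(matrices, axis=1),
        metadata=pd.concat(metas, axis=0),
        disease=bundles[0].disease,
    )
    logger.info(
        "merged %d dataset(s): %d genes x %d samples", len(bundles), merged.n_genes, merged.n_samples
    )
    return merged


# ---------------------------------------------------------------------------
# ComBat


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """EB iteration for one batch (sva's it.sol): s_data is samples × genes."""
    n = s_data.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((s_data - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.maximum(np.abs(g_old), 1e-12).max(),
            np.abs(d_new - d_old).max() / np.maximum(np.abs(d_old), 1e-12).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(bundle: ExpressionBundle, protect_group: bool = True) -> ExpressionBundle:
    """Remove batch effects with parametric empirical-Bayes adjustment.

    Parameters
    ----------
    bundle
        Cohort with ≥2 batches of ≥2 samples each.  A single-batch bundle is
        returned unchanged with a warning.
    protect_group
        Include the case/control indicator in the standardization design so
        group differences are not removed along with batch effects.

    Returns
    -------
    ExpressionBundle of identical shape with batch effects removed.
    """
    batches = bundle.metadata["batch"].astype(str)
    batch_levels = sorted(batches.unique())
    if len(batch_levels) < 2:
        warnings.warn("single batch: nothing to correct, returning input unchanged")
        logger.warning("combat_adjust called with a single batch; returning input unchanged")
        return bundle.copy()
    counts = batches.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"each batch needs ≥2 samples; too small: {dict(small)}")

    groups = (bundle.metadata["group"] == "case").astype(float).to_numpy()
    batch_onehot = np.column_stack([(batches == b).to_numpy(float) for b in batch_levels])
    n_batch = len(batch_levels)
    n_samples = bundle.n_samples
    batch_sizes = batch_onehot.sum(axis=0)

    if protect_group:
        # confounding check: group constant within every batch ⇒ group lies in
        # the span of the batch indicators and the design is singular
        confounded = all(
            len(np.unique(groups[batch_onehot[:, i] == 1])) == 1 for i in range(n_batch)
        )
        if confounded:
            raise ValueError(
                "batch is confounded 1:1 with case/control group; "
                "cannot protect the group covariate"
            )
        design = np.column_stack([batch_onehot, groups])
    else:
        design = batch_onehot

    data = bundle.matrix.to_numpy(float).T  # samples × genes
    beta_hat, *_ = np.linalg.lstsq(design, data, rcond=None)
    grand_mean = (batch_sizes / n_samples) @ beta_hat[:n_batch, :]
    fitted = design @ beta_hat
    var_pooled = ((data - fitted) ** 2).mean(axis=0)
    if np.all(var_pooled <= 0):
        raise ValueError("all genes have zero residual variance; cannot standardize")
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = np.tile(grand_mean, (n_samples, 1))
    if protect_group:
        stand_mean = stand_mean + np.outer(design[:, n_batch], beta_hat[n_batch, :])
    s_data = (data - stand_mean) / np.sqrt(var_pooled)[None, :]

    # batch-wise EB shrinkage of location (gamma) and scale (delta²)
    gamma_star = np.zeros((n_batch, data.shape[1]))
    delta_star = np.ones((n_batch, data.shape[1]))
    for i, level in enumerate(batch_levels):
        rows = batch_onehot[:, i] == 1
        sub = s_data[rows]
        gamma_hat = sub.mean(axis=0)
        delta_hat = sub.var(axis=0, ddof=1)
        g_bar, t2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        a, b = _aprior(delta_hat), _bprior(delta_hat)
        gamma_star[i], delta_star[i] = _it_sol(sub, gamma_hat, delta_hat, g_bar, t2, a, b)

    adjusted = s_data.copy()
    for i in range(n_batch):
        rows = batch_onehot[:, i] == 1
        adjusted[rows] = (adjusted[rows] - gamma_star[i][None, :]) / np.sqrt(
            np.maximum(delta_star[i], 1e-12)
        )[None, :]
    adjusted = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean

    out = bundle.copy()
    out.matrix = pd.DataFrame(adjusted.T, index=bundle.genes, columns=bundle.samples)
    logger.info("combat_adjust: corrected %d batches over %d genes", n_batch, out.n_genes)
    return out


# ---------------------------------------------------------------------------
# PCA QC


def pca_scores(bundle: ExpressionBundle, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the first *k* principal components of gene-centered data.

    Returns (scores DataFrame samples × k, explained-variance fractions).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(bundle.n_genes, bundle.n_samples):
        raise ValueError("k exceeds matrix rank bound")
    data = bundle.matrix.to_numpy(float).T  # samples × genes
    centered = data - data.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :k] * s[:k]
    total = (s**2).sum()
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=bundle.samples, columns=cols), frac


def batch_variance_fraction(scores: pd.Series, batches: pd.Series) -> float:
    """Fraction of a score vector's variance explained by batch (R² of the
    one-way batch ANOVA); used to quantify batch effect before/after correction."""
    scores = scores.astype(float)
    grand = scores.mean()
    total = ((scores - grand) ** 2).sum()
    if total == 0:
        return 0.0
    between = 0.0
    for _, vals in scores.groupby(batches):
        between += len(vals) * (vals.mean() - grand) ** 2
    return float(between / total)


# ---------------------------------------------------------------------------
# optional GEO Series Matrix loader


def read_series_matrix(
    path, disease: str = "", group_rule=None, keep_title_substrings=None
) -> ExpressionBundle:
    """Minimal GEO Series Matrix text parser.

    Reads ``!Sample_title`` / ``!Sample_geo_accession`` headers and the table
    between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.

    Parameters
    ----------
    group_rule
        Callable mapping a sample title to ``"case"``, ``"control"`` or
        ``None`` (drop the sample).
    keep_title_substrings
        If given, keep only samples whose title contains one of these
        substrings (e.g. week-0 ids for longitudinal series).
    """
    from pathlib import Path as _P
    import io as _io

    titles, accessions = [], []
    table_lines: list[str] = []
    in_table = False
    for line in _P(path).read_text().splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(line)
        elif line.startswith("!Sample_title"):
            titles = [f.strip().strip('"') for f in line.split("\t")[1:]]
        elif line.startswith("!Sample_geo_accession"):
            accessions = [f.strip().strip('"') for f in line.split("\t")[1:]]
    if not table_lines:
        raise ValueError("no series matrix table found")
    matrix = pd.read_csv(_io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    matrix.columns = [c.strip().strip('"') for c in matrix.columns]
    matrix.index = [str(i).strip().strip('"') for i in matrix.index]
    if not accessions:
        accessions = list(matrix.columns)
    if not titles:
        titles = list(accessions)
    title_of = dict(zip(accessions, titles))

    keep, group_col = [], []
    for acc in matrix.columns:
        title = title_of.get(acc, acc)
        if keep_title_substrings is not None and not any(
            s in title for s in keep_title_substrings
        ):
            continue
        group = group_rule(title) if group_rule else None
        if group_rule is not None and group is None:
            continue
        keep.append(acc)
        group_col.append(group or "control")
    if not keep:
        raise ValueError("no samples retained after title filtering")
    meta = pd.DataFrame(
        {"group": group_col, "batch": _P(path).stem}, index=pd.Index(keep, name="sample_id")
    )
    return ExpressionBundle(matrix=matrix[keep], metadata=meta, disease=disease)
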