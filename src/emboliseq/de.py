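"""Negative-binomial differential expression between PA-E and CTR.

A compact DESeq2-style core: median-of-ratios size factors, per-gene
method-of-moments dispersion shrunk toward a mean–dispersion trend, and a
Wald test on the group coefficient of a two-parameter NB log-linear model.
Genes are called differentially expressed at BH-adjusted p < 0.05.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .models import CASE_GROUP, CountMatrix, PipelineError, TranscriptModel
from .stats import benjamini_hochberg

DISPERSION_FLOOR = 1e-8
DEG_PADJ_THRESHOLD = 0.05

FPKM_HIGH = 100.0
FPKM_MEDIUM = 10.0


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    For genes with positive counts in every sample, each sample's factor is
    the median ratio of its counts to the gene-wise geometric means.
    """
    mat = counts.counts.astype(float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise PipelineError(
            "no gene has positive counts in all samples; filter the matrix first"
        )
    sub = mat[positive]
    log_geo_mean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo_mean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise PipelineError("degenerate size factors")
    return factors


def estimate_dispersion(counts: CountMatrix, sf: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion: method of moments, shrunk toward a trend.

    The raw estimate on normalized counts is ``max(floor, (s² − μ)/μ²)``;
    a hyperbolic trend ``a0 + a1/μ`` is fit by least squares to genes with a
    positive raw estimate, and each gene is moved half-way (on the raw
    scale) toward the trend value at its mean.  All-zero genes get NaN.
    """
    norm = counts.counts / sf[None, :]
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu) / mu**2
    raw = np.where(mu > 0, np.maximum(raw, DISPERSION_FLOOR), np.nan)

    usable = np.isfinite(raw) & (raw > DISPERSION_FLOOR) & (mu > 0)
    if usable.sum() >= 10:
        X = np.column_stack([np.ones(usable.sum()), 1.0 / mu[usable]])
        coef, *_ = np.linalg.lstsq(X, raw[usable], rcond=None)
        a0, a1 = coef
    else:  # too few informative genes for a trend; fall back to the mean
        a0 = np.nanmean(raw[np.isfinite(raw)]) if np.isfinite(raw).any() else 0.1
        a1 = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = np.maximum(a0 + a1 / mu, DISPERSION_FLOOR)
    shrunk = 0.5 * raw + 0.5 * trend
    shrunk = np.where(np.isfinite(raw), np.maximum(shrunk, DISPERSION_FLOOR), np.nan)
    return shrunk


def _nb_glm_wald(y: np.ndarray, sf: np.ndarray, case: np.ndarray, alpha: float,
                 max_iter: int = 50, tol: float = 1e-8):
    """Fit count ~ NB(s_j exp(b0 + b1·case), alpha) by IRLS; Wald on b1.

    Returns (log2fc, se_log2, stat, p) or None when the fit is degenerate
    (a group with zero total count).
    """
    mean_case = y[case].sum() / sf[case].sum()
    mean_ctrl = y[~case].sum() / sf[~case].sum()
    if mean_case <= 0 or mean_ctrl <= 0:
        return None
    b0 = np.log(mean_ctrl)
    b1 = np.log(mean_case) - np.log(mean_ctrl)
    X = np.column_stack([np.ones_like(sf), case.astype(float)])
    offset = np.log(sf)
    beta = np.array([b0, b1])
    for _ in range(max_iter):
        eta = offset + X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha * mu)
        z = eta - offset + (y - mu) / mu
        XtW = X.T * w
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return None
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = offset + X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha * mu)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    se = np.sqrt(cov[1, 1])
    log2fc = beta[1] / np.log(2.0)
    se2 = se / np.log(2.0)
    if se2 <= 0 or not np.isfinite(se2):
        return None
    stat = log2fc / se2
    p = 2.0 * stats.norm.sf(abs(stat))
    return log2fc, se2, stat, p


def wald_test(counts: CountMatrix, dispersions: Optional[np.ndarray] = None,
              sf: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-gene NB Wald test of PA-E vs CTR.

    Returns a DataFrame with columns gene_id, base_mean, log2fc, se, stat,
    pvalue, padj, is_deg, direction.  Genes with an all-zero group or
    undefined dispersion get NaN p-values and are excluded from the BH
    correction.
    """
    if sf is None:
        sf = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, sf)
    case = counts.design.group_mask(CASE_GROUP)
    norm = counts.counts / sf[None, :]
    base_mean = norm.mean(axis=1)

    n = len(counts.gene_ids)
    log2fc = np.full(n, np.nan)
    se = np.full(n, np.nan)
    stat = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    for i in range(n):
        alpha = dispersions[i]
        if not np.isfinite(alpha):
            continue
        res = _nb_glm_wald(counts.counts[i].astype(float), sf, case, alpha)
        if res is None:
            continue
        log2fc[i], se[i], stat[i], pval[i] = res

    padj = benjamini_hochberg(pval)
    is_deg = (padj < DEG_PADJ_THRESHOLD) & ~np.isnan(padj)
    direction = np.where(log2fc > 0, "up", "down")
    direction = np.where(np.isnan(log2fc), "na", direction)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "is_deg": is_deg,
            "direction": direction,
        }
    )


def run_de(counts: CountMatrix) -> pd.DataFrame:
    """Full DE stage: size factors, dispersion, Wald test."""
    sf = size_factors(counts)
    disp = estimate_dispersion(counts, sf)
    return wald_test(counts, dispersions=disp, sf=sf)


def deg_partition(de_table: pd.DataFrame) -> tuple[int, int, int]:
    """(total DEGs, upregulated, downregulated); up + down == total."""
    degs = de_table[de_table["is_deg"]]
    up = int((degs["direction"] == "up").sum())
    down = int((degs["direction"] == "down").sum())
    return up + down, up, down


def compute_fpkm(counts: CountMatrix, models: list[TranscriptModel]) -> pd.DataFrame:
    """FPKM per gene and sample plus the expression class of the FPKM sum.

    FPKM_gj = count · 10⁹ / (exonic length_g · library total_j); genes are
    binned by the FPKM sum over all libraries: high > 100, medium > 10,
    else low (strict inequalities).
    """
    lengths: dict[str, int] = {}
    for tm in models:
        # gene exonic length: union of exon intervals over its transcripts
        lengths.setdefault(tm.gene_id, 0)
    per_gene_exons: dict[str, list[tuple[int, int]]] = {}
    for tm in models:
        per_gene_exons.setdefault(tm.gene_id, []).extend(tm.exons)
    for gid, exons in per_gene_exons.items():
        merged: list[list[int]] = []
        for s, e in sorted(exons):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        lengths[gid] = sum(e - s for s, e in merged)

    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise PipelineError(f"no transcript model for gene(s): {missing[:5]}")
    zero = [g for g in counts.gene_ids if lengths[g] == 0]
    if zero:
        raise PipelineError(f"zero exonic length for gene(s): {zero[:5]}")

    length_vec = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    lib_totals = counts.counts.sum(axis=0).astype(float)
    fpkm = counts.counts * 1e9 / (length_vec[:, None] * lib_totals[None, :])
    total = fpkm.sum(axis=1)
    cls = np.where(total > FPKM_HIGH, "high", np.where(total > FPKM_MEDIUM, "medium", "low"))
    df = pd.DataFrame(fpkm, index=counts.gene_ids, columns=counts.sample_ids)
    df.insert(0, "gene_id", counts.gene_ids)
    df["fpkm_sum"] = total
    df["expression_class"] = cls
    return df.reset_index(drop=True)
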