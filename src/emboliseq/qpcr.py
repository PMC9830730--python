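"""Pfaffl-method relative qPCR quantification with dual reference genes.

Technical replicates are collapsed with an outlier rule, per-sample RQ is
the efficiency-corrected ratio normalized to the control-group mean Cq,
the two reference genes are combined by geometric mean, and groups are
compared with a two-tailed Student t-test on log2 RQ with GraphPad-style
significance stars.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import CASE_GROUP, CTRL_GROUP, PipelineError

#: p-value upper bounds for the star classes
STAR_THRESHOLDS = (
    (0.0001, "****"),
    (0.0002, "***"),
    (0.0021, "**"),
    (0.0332, "*"),
)

TECH_OUTLIER_CYCLES = 1.0
DEFAULT_EFFICIENCY = 2.0


def star_class(p: float) -> str:
    if not np.isfinite(p):
        return "ns"
    for bound, stars in STAR_THRESHOLDS:
        if p < bound:
            return stars
    return "ns"


def collapse_technical(cqs) -> float:
    """Mean Cq over technical replicates, dropping |Cq − median| > 1 cycle.

    Returns NaN (with a warning) when fewer than two replicates survive.
    """
    vals = np.asarray(list(cqs), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    med = np.median(vals)
    keep = vals[np.abs(vals - med) <= TECH_OUTLIER_CYCLES]
    if keep.size < 2:
        warnings.warn("fewer than 2 technical replicates survive outlier removal")
        return float("nan")
    return float(keep.mean())


def _per_sample_cq(cq_table: pd.DataFrame, gene: str) -> pd.Series:
    sub = cq_table[cq_table["gene"] == gene]
    if sub.empty:
        raise PipelineError(f"no Cq rows for gene {gene!r}")
    return sub.groupby("sample")["cq"].apply(collapse_technical)


def pfaffl_rq(cq_table: pd.DataFrame, target: str, references: list[str],
              efficiencies: dict[str, float] | None = None) -> pd.Series:
    """Per-sample relative quantity of ``target`` by the Pfaffl method.

    RQ = E_t^ΔCq_t / ref-term, with ΔCq = (mean control Cq) − (sample Cq)
    and the reference term the geometric mean of E_r^ΔCq_r over the
    reference genes.  Control samples therefore average to RQ ≈ 1 by
    construction.
    """
    if not references:
        raise PipelineError("at least one reference gene required")
    eff = {g: DEFAULT_EFFICIENCY for g in [target, *references]}
    if efficiencies:
        eff.update(efficiencies)
    for g, e in eff.items():
        if not 1.0 < e <= 2.2:
            raise PipelineError(f"amplification efficiency {e} for {g!r} out of (1, 2.2]")

    groups = cq_table[["sample", "group"]].drop_duplicates().set_index("sample")["group"]
    ctrl_samples = groups[groups == CTRL_GROUP].index

    def ratio(gene: str) -> pd.Series:
        cq = _per_sample_cq(cq_table, gene)
        ctrl_mean = cq.loc[[s for s in ctrl_samples if s in cq.index]].mean()
        return eff[gene] ** (ctrl_mean - cq)

    target_ratio = ratio(target)
    ref_ratios = pd.concat([ratio(r) for r in references], axis=1)
    ref_term = np.exp(np.log(ref_ratios).mean(axis=1))  # geometric mean
    return target_ratio / ref_term


def test_rq(case_rqs, ctrl_rqs, log_scale: bool = True) -> tuple[float, str]:
    """Two-tailed Student t on (log2) RQ; returns (p, star class)."""
    case = np.asarray(list(case_rqs), dtype=float)
    ctrl = np.asarray(list(ctrl_rqs), dtype=float)
    case = case[np.isfinite(case)]
    ctrl = ctrl[np.isfinite(ctrl)]
    if case.size < 2 or ctrl.size < 2:
        return float("nan"), "ns"
    if log_scale:
        if (case <= 0).any() or (ctrl <= 0).any():
            raise PipelineError("non-positive RQ on log scale")
        case, ctrl = np.log2(case), np.log2(ctrl)
    if np.var(case) == 0 and np.var(ctrl) == 0 and case.mean() == ctrl.mean():
        return 1.0, "ns"
    p = float(sps.ttest_ind(case, ctrl, equal_var=True).pvalue)
    return p, star_class(p)


def analyze_qpcr(cq_table: pd.DataFrame, targets: list[str],
                 references: list[str],
                 efficiencies: dict[str, float] | None = None,
                 log_scale: bool = True) -> pd.DataFrame:
    """RQ summary per target gene: group means ± SD, fold change, p, stars."""
    groups = cq_table[["sample", "group"]].drop_duplicates().set_index("sample")["group"]
    rows = []
    for gene in targets:
        rq = pfaffl_rq(cq_table, gene, references, efficiencies)
        case = rq[[s for s in rq.index if groups.get(s) == CASE_GROUP]]
        ctrl = rq[[s for s in rq.index if groups.get(s) == CTRL_GROUP]]
        p, stars = test_rq(case, ctrl, log_scale=log_scale)
        rows.append(
            {
                "gene": gene,
                "mean_rq_case": float(case.mean()),
                "sd_rq_case": float(case.std(ddof=1)),
                "mean_rq_ctrl": float(ctrl.mean()),
                "sd_rq_ctrl": float(ctrl.std(ddof=1)),
                "fold_change": float(case.mean() / ctrl.mean()),
                "pvalue": p,
                "stars": stars,
            }
        )
    return pd.DataFrame(rows)
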