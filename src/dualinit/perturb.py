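"""Component-wise differential response between treated and control libraries.

For each gene with both initiation components detected, the treated/control
tag totals of the YC and YR components form a 2x2 contingency table tested
with a two-sided Fisher exact test (the odds ratio quantifies the relative
shift of YC vs YR usage), with Benjamini-Hochberg correction across genes.
Component log2 fold changes (with a pseudocount) feed a two-sample
Kolmogorov-Smirnov comparison of the YC and YR response distributions and a
quadrant summary of response directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PerturbResponse:
    gene_id: str
    yc_treat: float
    yc_ctrl: float
    yr_treat: float
    yr_ctrl: float
    or_: float
    p: float
    padj: float = np.nan
    lfc_yc: float = np.nan
    lfc_yr: float = np.nan


def component_lfc(treat: float, ctrl: float, pseudocount: float = 0.5) -> float:
    """log2((treat + pc) / (ctrl + pc))."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((treat + pseudocount) / (ctrl + pseudocount)))


def per_gene_fisher(yc_treat: float, yc_ctrl: float,
                    yr_treat: float, yr_ctrl: float) -> tuple[float, float]:
    """Two-sided Fisher exact test on the rounded component 2x2 table.

    Normalized expression values are rounded to the nearest integer (the
    exact test requires counts).  A zero margin yields p = 1 and an
    undefined (NaN) odds ratio.
    """
    table = np.rint([[yc_treat, yc_ctrl], [yr_treat, yr_ctrl]]).astype(np.int64)
    if table.min() < 0:
        raise ValueError("negative counts in contingency table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ks_compare(lfc_a, lfc_b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test on fold-change sets."""
    a = np.asarray(lfc_a, dtype=float)
    b = np.asarray(lfc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def perturb_responses(
    component_counts: pd.DataFrame,
    pseudocount: float = 0.5,
) -> list[PerturbResponse]:
    """Per-gene Fisher tests with BH correction over the tested universe.

    ``component_counts`` needs columns ``gene_id, yc_treat, yc_ctrl,
    yr_treat, yr_ctrl``; the universe is all rows (genes with both
    components detected in both conditions should be selected upstream).
    """
    responses = []
    for row in component_counts.itertuples(index=False):
        or_, p = per_gene_fisher(row.yc_treat, row.yc_ctrl,
                                 row.yr_treat, row.yr_ctrl)
        responses.append(PerturbResponse(
            gene_id=row.gene_id,
            yc_treat=row.yc_treat, yc_ctrl=row.yc_ctrl,
            yr_treat=row.yr_treat, yr_ctrl=row.yr_ctrl,
            or_=or_, p=p,
            lfc_yc=component_lfc(row.yc_treat, row.yc_ctrl, pseudocount),
            lfc_yr=component_lfc(row.yr_treat, row.yr_ctrl, pseudocount),
        ))
    padj = bh_adjust([r.p for r in responses])
    for r, q in zip(responses, padj):
        r.padj = float(q)
    return responses


def direction_summary(responses: list[PerturbResponse],
                      lfc_threshold: float = 0.0) -> dict:
    """Fractions of genes per response quadrant (counts alongside)."""
    if not responses:
        raise ValueError("no responses to summarize")
    n = len(responses)
    yc_up = sum(r.lfc_yc > lfc_threshold for r in responses)
    yr_down = sum(r.lfc_yr < -lfc_threshold for r in responses)
    quads = {
        "yc_up_yr_down": sum(r.lfc_yc > lfc_threshold
                             and r.lfc_yr < -lfc_threshold
                             for r in responses),
        "yc_up_yr_up": sum(r.lfc_yc > lfc_threshold
                           and r.lfc_yr > lfc_threshold for r in responses),
        "yc_down_yr_down": sum(r.lfc_yc < -lfc_threshold
                               and r.lfc_yr < -lfc_threshold
                               for r in responses),
        "yc_down_yr_up": sum(r.lfc_yc < -lfc_threshold
                             and r.lfc_yr > lfc_threshold for r in responses),
    }
    out = {
        "n_genes": n,
        "yc_up_count": int(yc_up),
        "yr_down_count": int(yr_down),
        "yc_up_fraction": yc_up / n,
        "yr_down_fraction": yr_down / n,
    }
    for k, v in quads.items():
        out[f"{k}_count"] = int(v)
        out[f"{k}_fraction"] = v / n
    return out


def responses_to_frame(responses: list[PerturbResponse]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "gene_id": r.gene_id,
            "yc_treat": r.yc_treat, "yc_ctrl": r.yc_ctrl,
            "yr_treat": r.yr_treat, "yr_ctrl": r.yr_ctrl,
            "odds_ratio": r.or_, "p": r.p, "padj": r.padj,
            "lfc_yc": r.lfc_yc, "lfc_yr": r.lfc_yr,
        }
        for r in responses
    ])
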