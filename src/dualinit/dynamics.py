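"""Developmental dynamics of promoter components and snoRNA coupling.

For each dual-initiation gene the YR and YC components form a pair of
per-stage expression profiles.  Profiles are min-max scaled per gene and
component, concatenated and clustered with a small batch self-organizing map
(SOM); genes whose two components move in opposite directions across
development are ranked by the Pearson correlation between the raw component
vectors, with r <= -0.5 flagged as divergent.

snoRNA output of host genes is related to the components through log2 fold
changes between adjacent stages, pooled over genes and stage transitions,
and through a dominance-matched comparison of snoRNA levels between
YC-dominant and YR-dominant hosts at matched total promoter expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class ExpressionProfile:
    gene_id: str
    component: str              # "YR" or "YC"
    raw: np.ndarray
    scaled: np.ndarray
    constant: bool = False      # raw was constant; scaled set to all 0.5


def scale_profile(raw) -> tuple[np.ndarray, bool]:
    """Min-max scale to [0, 1]; constant vectors map to all 0.5 (flagged)."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full_like(raw, 0.5), True
    return (raw - lo) / (hi - lo), False


def build_profiles(calls, stages: list[str]) -> list[tuple[ExpressionProfile,
                                                           ExpressionProfile]]:
    """Paired YR/YC profiles for DUAL genes; all-zero components excluded."""
    pairs = []
    for c in calls:
        if c.di_status != "DUAL":
            continue
        if len(c.stages) != len(stages):
            raise ValueError(f"{c.gene_id}: stage count mismatch")
        if not np.any(c.yr_tpm) or not np.any(c.yc_tpm):
            logger.info("%s: constant-zero component, excluded from profiles",
                        c.gene_id)
            continue
        yr_s, yr_flag = scale_profile(c.yr_tpm)
        yc_s, yc_flag = scale_profile(c.yc_tpm)
        pairs.append((
            ExpressionProfile(c.gene_id, "YR", np.asarray(c.yr_tpm, float),
                              yr_s, yr_flag),
            ExpressionProfile(c.gene_id, "YC", np.asarray(c.yc_tpm, float),
                              yc_s, yc_flag),
        ))
    return pairs


# ---------------------------------------------------------------------------
# self-organizing map
# ---------------------------------------------------------------------------

@dataclass
class SomResult:
    grid_rows: int
    grid_cols: int
    node_of_gene: dict[str, int]        # node index = row * grid_cols + col
    prototypes: np.ndarray              # nodes x features
    seed: int
    gene_ids: list[str] = field(default_factory=list)

    def node_mean_profiles(self, n_stages: int) -> np.ndarray:
        """Per-node (YR mean, YC mean) trajectories, nodes x 2 x stages."""
        return self.prototypes.reshape(len(self.prototypes), 2, n_stages)


def som_cluster(
    profile_pairs,
    grid: tuple[int, int] = (4, 4),
    seed: int = 0,
    epochs: int = 30,
) -> SomResult:
    """Batch SOM over concatenated (YR || YC) scaled profiles.

    Batch updates with a Gaussian neighborhood whose radius decays linearly
    across epochs; assignments are independent of gene order and
    deterministic given the seed.
    """
    rows, cols = grid
    n_nodes = rows * cols
    if not profile_pairs:
        raise ValueError("no profiles to cluster")
    X = np.array([np.concatenate([yr.scaled, yc.scaled])
                  for yr, yc in profile_pairs])
    gene_ids = [yr.gene_id for yr, _ in profile_pairs]
    if len(X) < n_nodes:
        raise ValueError(
            f"grid {grid} has more nodes ({n_nodes}) than genes ({len(X)})")

    rng = np.random.default_rng(seed)
    prototypes = X[rng.choice(len(X), size=n_nodes, replace=False)].astype(float)
    node_rc = np.array([(i // cols, i % cols) for i in range(n_nodes)])
    # squared grid distances between nodes
    grid_d2 = ((node_rc[:, None, :] - node_rc[None, :, :]) ** 2).sum(axis=2)

    radius0 = max(rows, cols) / 2.0
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        radius = max(radius0 * (1.0 - frac), 0.5)
        d2 = ((X[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
        bmu = d2.argmin(axis=1)
        h = np.exp(-grid_d2[bmu] / (2.0 * radius ** 2))    # samples x nodes
        denom = h.sum(axis=0)
        numer = h.T @ X
        nonzero = denom > 1e-12
        prototypes[nonzero] = numer[nonzero] / denom[nonzero, None]

    d2 = ((X[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
    bmu = d2.argmin(axis=1)
    return SomResult(
        grid_rows=rows, grid_cols=cols,
        node_of_gene=dict(zip(gene_ids, bmu.astype(int).tolist())),
        prototypes=prototypes, seed=seed, gene_ids=gene_ids,
    )


# ---------------------------------------------------------------------------
# anticorrelation ranking
# ---------------------------------------------------------------------------

def anticorrelation_rank(profile_pairs,
                         threshold: float = -0.5) -> pd.DataFrame:
    """Pearson correlation between raw YR and YC vectors, ranked ascending.

    Genes at or below ``threshold`` are flagged divergent (the threshold is
    inclusive).  Zero-variance components are excluded with a flag column.
    """
    rows = []
    for yr, yc in profile_pairs:
        if np.std(yr.raw) == 0 or np.std(yc.raw) == 0:
            rows.append((yr.gene_id, np.nan, False, True))
            continue
        r = float(stats.pearsonr(yr.raw, yc.raw).statistic)
        # inclusive threshold with a float-rounding guard
        rows.append((yr.gene_id, r, r <= threshold + 1e-12, False))
    df = pd.DataFrame(rows, columns=["gene_id", "r", "divergent",
                                     "zero_variance"])
    return df.sort_values("r", na_position="last",
                          kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# fold changes and snoRNA coupling
# ---------------------------------------------------------------------------

def lfc(vector, pseudocount: float = 0.5) -> np.ndarray:
    """log2 fold change between adjacent stages with a pseudocount."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    v = np.asarray(vector, dtype=float)
    return np.log2((v[1:] + pseudocount) / (v[:-1] + pseudocount))


def snorna_component_correlation(
    snorna_expr: np.ndarray,
    yr_expr: np.ndarray,
    yc_expr: np.ndarray,
    pseudocount: float = 0.5,
    per_gene: bool = False,
):
    """Correlate snoRNA output with each host component across development.

    Inputs are genes x stages matrices of snoRNA expression (e.g. RPM) and
    host YR/YC component expression (TPM).  Log2 fold changes between
    adjacent stages are pooled over all gene x transition pairs and the
    Pearson correlation against each component's fold changes returned as
    ``(r_yc, r_yr)``.  With ``per_gene=True``, per-gene correlations are
    averaged instead.
    """
    sno = np.atleast_2d(np.asarray(snorna_expr, dtype=float))
    yr = np.atleast_2d(np.asarray(yr_expr, dtype=float))
    yc = np.atleast_2d(np.asarray(yc_expr, dtype=float))
    if not (sno.shape == yr.shape == yc.shape):
        raise ValueError("snoRNA and component matrices must share shape")
    l_sno = np.apply_along_axis(lfc, 1, sno, pseudocount)
    l_yr = np.apply_along_axis(lfc, 1, yr, pseudocount)
    l_yc = np.apply_along_axis(lfc, 1, yc, pseudocount)
    if per_gene:
        r_yc = np.nanmean([stats.pearsonr(a, b).statistic
                           for a, b in zip(l_sno, l_yc)])
        r_yr = np.nanmean([stats.pearsonr(a, b).statistic
                           for a, b in zip(l_sno, l_yr)])
        return float(r_yc), float(r_yr)
    if l_sno.size < 3:
        raise ValueError("need at least 3 gene x transition pairs")
    r_yc = stats.pearsonr(l_sno.ravel(), l_yc.ravel()).statistic
    r_yr = stats.pearsonr(l_sno.ravel(), l_yr.ravel()).statistic
    return float(r_yc), float(r_yr)


# ---------------------------------------------------------------------------
# snoRNA filtering
# ---------------------------------------------------------------------------

@dataclass
class SnoRnaRecord:
    snorna_id: str
    host_gene: str
    chrom: str
    start: int                  # 1-based inclusive
    end: int
    strand: str
    length: int
    counts: np.ndarray          # per stage
    flags: set = field(default_factory=set)

    @property
    def total_reads(self) -> float:
        return float(np.sum(self.counts))


def _tree(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    return trees


def snorna_filter(
    candidates: list[SnoRnaRecord],
    min_reads: int = 5,
    min_len: int = 51,
    exon_intervals=(),
    repeat_intervals=(),
) -> tuple[list[SnoRnaRecord], list[SnoRnaRecord]]:
    """Drop low-read, short, exon- or repeat-overlapping snoRNA candidates.

    Intervals are (chrom, start, end) 1-based inclusive; any overlap drops
    the candidate.  Returns ``(retained, dropped)``; every dropped record
    carries the flag(s) that triggered its exclusion.
    """
    exons = _tree(exon_intervals)
    repeats = _tree(repeat_intervals)
    retained, dropped = [], []
    for rec in candidates:
        rec.flags = set()
        if rec.total_reads < min_reads:
            rec.flags.add("low_reads")
        if rec.length < min_len:
            rec.flags.add("short")
        if rec.chrom in exons and exons[rec.chrom].overlap(rec.start,
                                                           rec.end + 1):
            rec.flags.add("exonic_overlap")
        if rec.chrom in repeats and repeats[rec.chrom].overlap(rec.start,
                                                               rec.end + 1):
            rec.flags.add("repeat_overlap")
        (dropped if rec.flags else retained).append(rec)
    return retained, dropped


# ---------------------------------------------------------------------------
# dominance-matched comparison
# ---------------------------------------------------------------------------

def dominance_matched_compare(
    host_calls,
    snorna_rpm: dict[str, float],
    stage_index: int,
    caliper: float = 0.25,
    min_group: int = 5,
) -> dict:
    """Compare snoRNA output between YC- and YR-dominant hosts.

    Hosts are labeled by stage dominance; pairs are matched greedily by
    nearest log10 total promoter TPM within ``caliper`` (without
    replacement).  The matched groups' snoRNA levels are compared with a
    two-sided Mann-Whitney rank-sum test.
    """
    groups = {"YR_DOM": [], "YC_DOM": []}
    for c in host_calls:
        if c.gene_id not in snorna_rpm:
            continue
        label = c.dominance[stage_index]
        if label is None:
            continue
        total = float(c.yr_tpm[stage_index] + c.yc_tpm[stage_index])
        if total <= 0:
            continue
        groups[label].append((c.gene_id, np.log10(total),
                              snorna_rpm[c.gene_id]))
    yc_group = sorted(groups["YC_DOM"], key=lambda t: t[1])
    yr_pool = sorted(groups["YR_DOM"], key=lambda t: t[1])
    matched_yc, matched_yr = [], []
    used = np.zeros(len(yr_pool), dtype=bool)
    for gid, logt, rpm in yc_group:
        best, best_d = None, None
        for j, (gid2, logt2, rpm2) in enumerate(yr_pool):
            if used[j]:
                continue
            d = abs(logt - logt2)
            if d <= caliper and (best_d is None or d < best_d):
                best, best_d = j, d
        if best is not None:
            used[best] = True
            matched_yc.append(rpm)
            matched_yr.append(yr_pool[best][2])
    if len(matched_yc) < min_group or len(matched_yr) < min_group:
        raise ValueError(
            f"matching left fewer than {min_group} pairs "
            f"({len(matched_yc)} matched)")
    test = stats.mannwhitneyu(matched_yc, matched_yr, alternative="two-sided")
    return {
        "n_pairs": len(matched_yc),
        "median_yc_dom": float(np.median(matched_yc)),
        "median_yr_dom": float(np.median(matched_yr)),
        "direction": "YC_DOM_higher"
        if np.median(matched_yc) > np.median(matched_yr) else "YR_DOM_higher",
        "statistic": float(test.statistic),
        "p": float(test.pvalue),
    }
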