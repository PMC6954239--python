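"""Promoter-level analysis: gene assignment, dual-initiation calls, features.

Tag clusters are assigned to annotated promoters (a window from 500 nt
upstream to 300 nt downstream of the annotated TSS, in transcript
orientation).  Per gene, the expression of the YR and YC components is the
per-stage sum over assigned clusters of each class.  A component is robust
when it reaches ``min_tpm`` (default 3 TPM) in at least ``min_stages``
(default 2) stages; genes with both components robust carry a dual-initiation
(DI) promoter.  Dominance in a stage follows the >50% rule and the signed
distance between the dominant YC and YR sites (negative = YC upstream) is
reported in transcript orientation.

Sequence features around dominant sites: the uninterrupted pyrimidine run
containing the +1 base of a YC site (the 5'-TOP hallmark), 5'-UTR length in
transcript coordinates, and positional C+T / dinucleotide-class profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctss import TagCluster
from .io import GeneModel

logger = logging.getLogger(__name__)

DI_STATUSES = ("YR_ONLY", "YC_ONLY", "DUAL", "NONE")

_PYRIMIDINES = {"C", "T"}
_PURINES = {"A", "G"}


@dataclass
class PromoterCall:
    """Per-gene YR/YC component summary."""

    gene_id: str
    strand: str
    stages: list[str]
    yr_tpm: np.ndarray
    yc_tpm: np.ndarray
    di_status: str = "NONE"
    dominant_yr_pos: int | None = None
    dominant_yc_pos: int | None = None
    yc_offset: int | None = None
    utr5_len: int | None = None
    n_ctss_yr: int = 0
    n_ctss_yc: int = 0
    dominance: list = field(default_factory=list)   # per stage, None if both 0


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def promoter_window(gene: GeneModel, upstream: int = 500,
                    downstream: int = 300) -> tuple[int, int]:
    """Genomic 1-based inclusive promoter window, strand-aware."""
    if gene.strand == "+":
        return gene.tss - upstream, gene.tss + downstream
    return gene.tss - downstream, gene.tss + upstream


def assign_clusters(
    clusters: list[TagCluster],
    genes: list[GeneModel],
    upstream: int = 500,
    downstream: int = 300,
) -> list[str | None]:
    """Assign each cluster to at most one gene by its dominant position.

    A cluster whose dominant CTSS lies inside several promoter windows goes
    to the gene with the nearest annotated TSS; exact distance ties break
    deterministically to the smallest gene id (logged).  Returns one gene id
    (or None) per cluster, in order.
    """
    by_key: dict[tuple[str, str], list] = {}
    for g in genes:
        lo, hi = promoter_window(g, upstream, downstream)
        by_key.setdefault((g.chrom, g.strand), []).append((lo, hi, g))

    assignment: list[str | None] = []
    for cl in clusters:
        dom = cl.dominant_pos
        candidates = [
            g for lo, hi, g in by_key.get((cl.chrom, cl.strand), [])
            if lo <= dom <= hi
        ]
        if not candidates:
            assignment.append(None)
            continue
        dists = [abs(dom - g.tss) for g in candidates]
        best = min(dists)
        tied = sorted(g.gene_id for g, d in zip(candidates, dists) if d == best)
        if len(tied) > 1:
            logger.info("cluster %s:%d equidistant between %s; assigned to %s",
                        cl.chrom, dom, tied, tied[0])
        assignment.append(tied[0])
    return assignment


# ---------------------------------------------------------------------------
# DI calling
# ---------------------------------------------------------------------------

def component_robust(tpm: np.ndarray, min_tpm: float = 3.0,
                     min_stages: int = 2) -> bool:
    return int((np.asarray(tpm, dtype=float) >= min_tpm).sum()) >= min_stages


def call_di(yr_tpm, yc_tpm, min_tpm: float = 3.0, min_stages: int = 2) -> str:
    """Dual-initiation status from per-stage component expression."""
    yr_ok = component_robust(yr_tpm, min_tpm, min_stages)
    yc_ok = component_robust(yc_tpm, min_tpm, min_stages)
    if yr_ok and yc_ok:
        return "DUAL"
    if yr_ok:
        return "YR_ONLY"
    if yc_ok:
        return "YC_ONLY"
    return "NONE"


def classify_dominance(yr_tpm: float, yc_tpm: float) -> str | None:
    """>50% rule; exact ties default to YR_DOM; both-zero is undefined."""
    if yr_tpm == 0 and yc_tpm == 0:
        return None
    return "YR_DOM" if yr_tpm >= yc_tpm else "YC_DOM"


def dominant_distance(yr_pos: int, yc_pos: int, strand: str) -> int:
    """Signed dominant-YC minus dominant-YR distance, transcript orientation.

    Negative values mean the YC site is upstream of the YR site.
    """
    d = yc_pos - yr_pos
    return d if strand == "+" else -d


def _dominant_in_class(clusters: list[TagCluster], strand: str,
                       stage: str | None = None) -> int | None:
    """Highest-expressed CTSS across a gene's clusters of one class."""
    positions, tpms = [], []
    for cl in clusters:
        positions.append(cl.positions)
        if stage is None:
            tpms.append(cl.pooled_member_tpm)
        else:
            tpms.append(cl.tpm[:, cl.stages.index(stage)])
    if not positions:
        return None
    pos = np.concatenate(positions)
    tpm = np.concatenate(tpms)
    if tpm.max() <= 0:
        return None
    tied = pos[tpm == tpm.max()]
    return int(tied.min() if strand == "+" else tied.max())


def build_promoter_calls(
    clusters: list[TagCluster],
    assignment: list[str | None],
    genes: list[GeneModel],
    min_tpm: float = 3.0,
    min_stages: int = 2,
    offset_stage: str | None = None,
) -> list[PromoterCall]:
    """Aggregate assigned clusters into per-gene promoter calls.

    ``offset_stage`` selects the stage in which dominant positions (and
    hence the YC-YR offset) are determined; None pools all stages.
    """
    by_gene: dict[str, dict[str, list[TagCluster]]] = {}
    for cl, gid in zip(clusters, assignment):
        if gid is None:
            continue
        by_gene.setdefault(gid, {"YR": [], "YC": []})[cl.iclass].append(cl)

    stages = clusters[0].stages if clusters else []
    n = len(stages)
    calls = []
    for g in genes:
        cl_yr = by_gene.get(g.gene_id, {}).get("YR", [])
        cl_yc = by_gene.get(g.gene_id, {}).get("YC", [])
        yr = (np.sum([c.tpm_by_sample for c in cl_yr], axis=0)
              if cl_yr else np.zeros(n))
        yc = (np.sum([c.tpm_by_sample for c in cl_yc], axis=0)
              if cl_yc else np.zeros(n))
        status = call_di(yr, yc, min_tpm, min_stages)
        dom_yr = _dominant_in_class(cl_yr, g.strand, offset_stage)
        dom_yc = _dominant_in_class(cl_yc, g.strand, offset_stage)
        offset = (dominant_distance(dom_yr, dom_yc, g.strand)
                  if status == "DUAL" and dom_yr is not None
                  and dom_yc is not None else None)
        if dom_yr is not None and (yr.sum() >= yc.sum() or dom_yc is None):
            dom_overall = dom_yr
        else:
            dom_overall = dom_yc
        utr5 = utr5_length(g, dom_overall) if dom_overall is not None else None
        calls.append(PromoterCall(
            gene_id=g.gene_id,
            strand=g.strand,
            stages=list(stages),
            yr_tpm=yr,
            yc_tpm=yc,
            di_status=status,
            dominant_yr_pos=dom_yr,
            dominant_yc_pos=dom_yc,
            yc_offset=offset,
            utr5_len=utr5,
            n_ctss_yr=int(sum(c.n_ctss for c in cl_yr)),
            n_ctss_yc=int(sum(c.n_ctss for c in cl_yc)),
            dominance=[classify_dominance(a, b) for a, b in zip(yr, yc)],
        ))
    return calls


def calls_to_frame(calls: list[PromoterCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "gene_id": c.gene_id,
            "strand": c.strand,
            "di_status": c.di_status,
            "dominant_yr_pos": c.dominant_yr_pos,
            "dominant_yc_pos": c.dominant_yc_pos,
            "yc_offset": c.yc_offset,
            "utr5_len": c.utr5_len,
            "n_ctss_yr": c.n_ctss_yr,
            "n_ctss_yc": c.n_ctss_yc,
        }
        for s, v in zip(c.stages, c.yr_tpm):
            row[f"yr_tpm_{s}"] = v
        for s, v in zip(c.stages, c.yc_tpm):
            row[f"yc_tpm_{s}"] = v
        for s, v in zip(c.stages, c.dominance):
            row[f"dominance_{s}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence / shape features
# ---------------------------------------------------------------------------

def py_run_length(genome, chrom: str, pos: int, strand: str) -> int:
    """Length of the uninterrupted pyrimidine run containing the +1 base.

    The run is read on the transcript strand and extends in both directions
    until a purine or N.  Raises if the +1 base is not a pyrimidine.
    """
    seq = genome[chrom]
    # pyrimidine on the transcript strand == purine on the plus strand for -
    good = _PYRIMIDINES if strand == "+" else _PURINES
    i = pos - 1
    if seq[i] not in good:
        raise ValueError(
            f"{chrom}:{pos}({strand}) +1 base {seq[i]!r} is not a pyrimidine "
            "on the transcript strand"
        )
    lo = i
    while lo > 0 and seq[lo - 1] in good:
        lo -= 1
    hi = i
    while hi < len(seq) - 1 and seq[hi + 1] in good:
        hi += 1
    return hi - lo + 1


def utr5_length(gene: GeneModel, dominant_pos: int) -> int | None:
    """Transcript-coordinate distance from a dominant TSS to the CDS start.

    Counts exonic positions (introns excluded) from the dominant TSS up to,
    but not including, the CDS start.  Positions upstream of the annotated
    TSS (inside the promoter but before exon 1) count as unspliced leader.
    Returns None (flagged) when the CDS start is not downstream of the
    dominant TSS in transcript orientation.
    """
    sign = 1 if gene.strand == "+" else -1

    def before(a: int, b: int) -> bool:       # a strictly upstream of b
        return sign * (a - b) < 0

    if not before(dominant_pos, gene.cds_start):
        logger.info("%s: dominant TSS %d not upstream of CDS start %d; "
                    "5'-UTR undefined", gene.gene_id, dominant_pos,
                    gene.cds_start)
        return None

    # work on the oriented axis f(p) = sign * p, where larger f = downstream
    f = lambda p: sign * p
    tx_start = gene.tss
    total = 0
    if before(dominant_pos, tx_start):
        total += f(tx_start) - f(dominant_pos)      # unspliced leader
        start_f = f(tx_start)
    else:
        start_f = f(dominant_pos)
    cds_f = f(gene.cds_start)
    for s, e in gene.exons:
        lo_f, hi_f = min(f(s), f(e)), max(f(s), f(e))
        total += max(0, min(hi_f, cds_f - 1) - max(lo_f, start_f) + 1)
    return total


def mapping_rate(
    classified: pd.DataFrame,
    stage_cols: list[str],
    genes: list[GeneModel],
    upstream: int = 500,
    downstream: int = 300,
) -> dict[str, float]:
    """Fraction of class-specific CTSS expression inside promoter windows."""
    windows: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in genes:
        windows.setdefault((g.chrom, g.strand), []).append(
            promoter_window(g, upstream, downstream))
    expr = classified[stage_cols].sum(axis=1).to_numpy(dtype=float)
    inside = np.zeros(len(classified), dtype=bool)
    for i, (chrom, pos, strand) in enumerate(
            zip(classified["chrom"], classified["pos"], classified["strand"])):
        inside[i] = any(lo <= pos <= hi
                        for lo, hi in windows.get((chrom, strand), []))
    out = {}
    for iclass in ("YR", "YC"):
        mask = (classified["iclass"] == iclass).to_numpy()
        total = expr[mask].sum()
        out[iclass] = float(expr[mask & inside].sum() / total) if total > 0 \
            else float("nan")
    return out


_W = {"A", "T"}
_S = {"C", "G"}
_Y = {"C", "T"}

_COMP = str.maketrans("ACGTN", "TGCAN")


def _transcript_window(genome, chrom: str, pos: int, strand: str,
                       flank: int) -> str | None:
    """Sequence from -flank to +flank (plus one base for dinucleotides)."""
    seq = genome[chrom]
    if strand == "+":
        lo, hi = pos - 1 - flank, pos - 1 + flank + 1   # inclusive 0-based
        if lo < 0 or hi >= len(seq):
            return None
        return seq[lo:hi + 1]
    lo, hi = pos - 1 - flank - 1, pos - 1 + flank
    if lo < 0 or hi >= len(seq):
        return None
    return seq[lo:hi + 1].translate(_COMP)[::-1]


def positional_profiles(
    genome,
    sites: list[tuple[str, int, str]],
    flank: int = 50,
) -> tuple[pd.DataFrame, int]:
    """Per-position base-class profiles around a set of dominant TSSs.

    Returns a frame indexed by position relative to the +1 base (-flank ..
    +flank) with columns: ``ct`` (C+T fraction of the single base) and
    dinucleotide-class frequencies at (pos, pos+1): the W/S partition
    ``WW, SS, WS`` (mixed pairs grouped) and the Y/R partition
    ``YY, YR, RY, RR``; each partition sums to 1 at positions without N.
    Sites too close to a contig edge are dropped; the number used is
    returned alongside.
    """
    if not sites:
        raise ValueError("empty site list")
    offsets = np.arange(-flank, flank + 1)
    counts = {k: np.zeros(len(offsets)) for k in
              ("ct", "WW", "SS", "WS", "YY", "YR", "RY", "RR")}
    denom_base = np.zeros(len(offsets))
    denom_di = np.zeros(len(offsets))
    n_used = 0
    for chrom, pos, strand in sites:
        win = _transcript_window(genome, chrom, pos, strand, flank)
        if win is None:
            continue
        n_used += 1
        for j in range(len(offsets)):
            b1, b2 = win[j], win[j + 1]
            if b1 in "ACGT":
                denom_base[j] += 1
                if b1 in _Y:
                    counts["ct"][j] += 1
            if b1 in "ACGT" and b2 in "ACGT":
                denom_di[j] += 1
                if b1 in _W and b2 in _W:
                    counts["WW"][j] += 1
                elif b1 in _S and b2 in _S:
                    counts["SS"][j] += 1
                else:
                    counts["WS"][j] += 1
                key = ("Y" if b1 in _Y else "R") + ("Y" if b2 in _Y else "R")
                counts[key][j] += 1
    if n_used == 0:
        raise ValueError("no usable sites within contig bounds")
    with np.errstate(invalid="ignore", divide="ignore"):
        data = {"ct": counts["ct"] / denom_base}
        for k in ("WW", "SS", "WS", "YY", "YR", "RY", "RR"):
            data[k] = counts[k] / denom_di
    df = pd.DataFrame(data, index=pd.Index(offsets, name="rel_pos"))
    return df, n_used
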