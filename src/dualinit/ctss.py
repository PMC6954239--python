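"""CTSS ingestion, normalization, initiator classification and tag clustering.

A CTSS (CAGE transcription start site) is a single genomic base observed as
the capped 5' end of transcripts, with a tag count per sample.  Each CTSS is
classified by the dinucleotide spanning its -1 and +1 positions (read on the
transcript strand):

* ``YR`` -- pyrimidine at -1, purine at +1 (canonical initiator),
* ``YC`` -- pyrimidine at -1, C at +1 (non-canonical TCT/5'-TOP initiator),
* ``OTHER`` -- everything else, including the GG context of recapped
  post-transcriptional processing products and any position touching an N
  or a contig edge.

Same-class, same-strand CTSSs are merged into tag clusters by single linkage
with a maximum inter-position gap (20 nt by default); the highest-expressed
member of a cluster is its dominant TSS and the span of members its width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

YR_DINUCS = frozenset({"CA", "CG", "TA", "TG"})
YC_DINUCS = frozenset({"CC", "TC"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class CtssParseError(ValueError):
    """Malformed CTSS table line (carries the 1-based line number)."""


# ---------------------------------------------------------------------------
# I/O and normalization
# ---------------------------------------------------------------------------

def read_ctss_table(path, sample: str | None = None) -> pd.DataFrame:
    """Read a 4-column CTSS TSV (chrom, 1-based pos, strand, count).

    Duplicate (chrom, pos, strand) keys are summed.  Returns a frame with
    columns ``chrom, pos, strand, count`` sorted by (chrom, strand, pos).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise CtssParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            chrom, pos_s, strand, count_s = parts
            if strand not in ("+", "-"):
                raise CtssParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            try:
                pos = int(pos_s)
                count = int(count_s)
            except ValueError as exc:
                raise CtssParseError(f"{path}:{lineno}: {exc}") from exc
            if pos < 1:
                raise CtssParseError(f"{path}:{lineno}: position must be >= 1, got {pos}")
            if count < 0:
                raise CtssParseError(f"{path}:{lineno}: negative count {count}")
            rows.append((chrom, pos, strand, count))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    if df.empty:
        return df
    df = (
        df.groupby(["chrom", "pos", "strand"], as_index=False, sort=False)["count"]
        .sum()
        .sort_values(["chrom", "strand", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    if sample is not None:
        df.attrs["sample"] = sample
    return df


def write_ctss_table(df: pd.DataFrame, path, count_col: str = "count") -> None:
    df[["chrom", "pos", "strand", count_col]].to_csv(
        path, sep="\t", header=False, index=False
    )


def merge_stages(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-stage CTSS tables into one wide frame.

    Result has columns ``chrom, pos, strand`` plus one count column per stage
    (missing positions filled with 0), sorted by (chrom, strand, pos).
    """
    pieces = []
    for stage, df in tables.items():
        piece = df.set_index(["chrom", "pos", "strand"])["count"].rename(stage)
        pieces.append(piece)
    wide = pd.concat(pieces, axis=1).fillna(0)
    wide = wide.reset_index().sort_values(["chrom", "strand", "pos"], kind="stable")
    stage_cols = list(tables)
    wide[stage_cols] = wide[stage_cols].astype(np.int64)
    return wide.reset_index(drop=True)


def normalize_tpm(counts) -> np.ndarray:
    """Tags-per-million: count * 1e6 / library total.  Errors on a zero total."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot TPM-normalize a library with zero total tags")
    return counts * 1e6 / total


def fit_powerlaw_slope(counts, fit_lo: int = 10, fit_hi: int = 1000):
    """Fit the reverse-cumulative tag-count distribution on log-log scale.

    Returns ``(alpha, log10_intercept, n_points)`` where the fitted model is
    ``log10 revcum(c) = intercept - alpha * log10 c`` over distinct count
    values in [fit_lo, fit_hi].
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    values = np.unique(counts)
    revcum = np.array([(counts >= v).sum() for v in values], dtype=float)
    mask = (values >= fit_lo) & (values <= fit_hi)
    if mask.sum() < 3:
        return None, None, int(mask.sum())
    x = np.log10(values[mask])
    y = np.log10(revcum[mask])
    slope, intercept = np.polyfit(x, y, 1)
    return -slope, intercept, int(mask.sum())


def powerlaw_normalize(
    counts,
    alpha_ref: float = 1.22,
    fit_lo: int = 10,
    fit_hi: int = 1000,
    total_ref: float = 1e6,
) -> np.ndarray:
    """Power-law normalization of raw CTSS counts.

    The reverse-cumulative count distribution is fitted on log-log scale
    within [fit_lo, fit_hi] and each raw count is mapped monotonically onto a
    referent power law with slope ``alpha_ref`` and total ``total_ref``
    (raising counts to alpha_fit/alpha_ref turns an alpha_fit-law into an
    alpha_ref-law; a final multiplicative rescale fixes the total).  Rank
    order is always preserved.  With fewer than 3 fit points the function
    falls back to plain TPM with a logged warning.
    """
    counts = np.asarray(counts, dtype=float)
    alpha_fit, _, n_points = fit_powerlaw_slope(counts, fit_lo, fit_hi)
    if alpha_fit is None or alpha_fit <= 0:
        logger.warning(
            "power-law fit not possible (%d usable points); falling back to TPM",
            n_points,
        )
        return normalize_tpm(counts)
    mapped = np.power(counts, alpha_fit / alpha_ref)
    return mapped * total_ref / mapped.sum()


# ---------------------------------------------------------------------------
# Initiator classification
# ---------------------------------------------------------------------------

def dinucleotide_at(genome, chrom: str, pos: int, strand: str) -> str:
    """Return the (-1, +1) dinucleotide of a CTSS on its transcript strand.

    ``pos`` is the 1-based coordinate of the +1 base.  Positions lacking a
    -1 base (contig edge) yield an ``N`` in that slot.
    """
    seq = genome[chrom]
    n = len(seq)
    if strand == "+":
        plus1 = seq[pos - 1] if 1 <= pos <= n else "N"
        minus1 = seq[pos - 2] if pos >= 2 else "N"
        return (minus1 + plus1).upper()
    # minus strand: -1 base is genomic pos+1, +1 base is genomic pos, both
    # complemented
    plus1 = seq[pos - 1] if 1 <= pos <= n else "N"
    minus1 = seq[pos] if pos <= n - 1 else "N"
    return (minus1 + plus1).upper().translate(_COMPLEMENT)


def classify_dinucleotide(dinuc: str) -> str:
    if dinuc in YR_DINUCS:
        return "YR"
    if dinuc in YC_DINUCS:
        return "YC"
    return "OTHER"


def classify_initiator(genome, chrom: str, pos: int, strand: str):
    """Classify one CTSS; returns ``(iclass, dinucleotide)``."""
    dinuc = dinucleotide_at(genome, chrom, pos, strand)
    return classify_dinucleotide(dinuc), dinuc


def classify_table(genome, df: pd.DataFrame) -> pd.DataFrame:
    """Add ``dinucleotide`` and ``iclass`` columns to a CTSS frame."""
    dinucs = [
        dinucleotide_at(genome, c, p, s)
        for c, p, s in zip(df["chrom"], df["pos"], df["strand"])
    ]
    out = df.copy()
    out["dinucleotide"] = dinucs
    out["iclass"] = [classify_dinucleotide(d) for d in dinucs]
    return out


# ---------------------------------------------------------------------------
# Expression filtering
# ---------------------------------------------------------------------------

def filter_ctss(
    tpm: pd.DataFrame,
    stage_cols: list[str],
    primary_tpm: float = 1.0,
    rescue_tpm: float = 0.5,
) -> pd.DataFrame:
    """Two-level CTSS expression filter across stages.

    A position qualifies if its TPM reaches ``primary_tpm`` in at least one
    stage.  At qualifying positions, per-stage signal is retained where it
    reaches ``rescue_tpm`` and zeroed otherwise; non-qualifying positions are
    dropped.
    """
    vals = tpm[stage_cols].to_numpy(dtype=float)
    qualifies = (vals >= primary_tpm).any(axis=1)
    out = tpm.loc[qualifies].copy()
    kept = out[stage_cols].to_numpy(dtype=float)
    kept[kept < rescue_tpm] = 0.0
    out[stage_cols] = kept
    logger.info(
        "filter_ctss: %d/%d positions qualify (primary=%g, rescue=%g)",
        int(qualifies.sum()), len(tpm), primary_tpm, rescue_tpm,
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tag clustering
# ---------------------------------------------------------------------------

@dataclass
class TagCluster:
    """A maximal run of same-class, same-strand CTSSs with gaps <= max_gap."""

    chrom: str
    strand: str
    iclass: str
    positions: np.ndarray          # sorted ascending, 1-based
    tpm: np.ndarray                # members x stages
    stages: list[str] = field(default_factory=list)

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1])

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def n_ctss(self) -> int:
        return len(self.positions)

    @property
    def tpm_by_sample(self) -> np.ndarray:
        return self.tpm.sum(axis=0)

    @property
    def pooled_member_tpm(self) -> np.ndarray:
        return self.tpm.sum(axis=1)

    @property
    def pooled_tpm(self) -> float:
        return float(self.tpm.sum())

    @property
    def dominant_pos(self) -> int:
        return dominant_ctss(self)

    @property
    def dominant_tpm(self) -> float:
        member = self.pooled_member_tpm
        return float(member[self._dominant_index(member)])

    def _dominant_index(self, member: np.ndarray) -> int:
        best = member.max()
        tied = np.flatnonzero(member == best)
        # ties break toward the 5'-most position in transcript orientation
        return int(tied[0] if self.strand == "+" else tied[-1])


def dominant_ctss(cluster: TagCluster, stage: str | None = None) -> int:
    """Position of the highest-expressed member (pooled, or one stage).

    Ties break toward the 5'-most position in transcript orientation.
    """
    if cluster.n_ctss == 0:
        raise ValueError("empty tag cluster")
    if stage is None:
        member = cluster.pooled_member_tpm
    else:
        member = cluster.tpm[:, cluster.stages.index(stage)]
    return int(cluster.positions[cluster._dominant_index(member)])


def cluster_ctss(
    df: pd.DataFrame,
    stage_cols: list[str],
    max_gap: int = 20,
) -> list[TagCluster]:
    """Single-linkage clustering of classified CTSSs.

    YR and YC positions are clustered independently per (chrom, strand);
    consecutive member positions differ by at most ``max_gap``.  OTHER-class
    CTSSs are ignored.
    """
    clusters: list[TagCluster] = []
    usable = df[df["iclass"].isin(("YR", "YC"))]
    for (chrom, strand, iclass), grp in usable.groupby(
        ["chrom", "strand", "iclass"], sort=True
    ):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy(dtype=np.int64)
        tpm = grp[stage_cols].to_numpy(dtype=float)
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for chunk_idx in np.split(np.arange(len(pos)), breaks):
            clusters.append(
                TagCluster(
                    chrom=chrom,
                    strand=strand,
                    iclass=iclass,
                    positions=pos[chunk_idx],
                    tpm=tpm[chunk_idx],
                    stages=list(stage_cols),
                )
            )
    return clusters


def clusters_to_frame(clusters: list[TagCluster]) -> pd.DataFrame:
    """BED6+-style summary of tag clusters (start0 is 0-based half-open)."""
    rows = []
    for cl in clusters:
        rows.append(
            {
                "chrom": cl.chrom,
                "start0": cl.start - 1,
                "end": cl.end,
                "name": cl.iclass,
                "score": cl.pooled_tpm,
                "strand": cl.strand,
                "dominant_pos": cl.dominant_pos,
                "dominant_tpm": cl.dominant_tpm,
                "n_ctss": cl.n_ctss,
                "width": cl.width,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start0", "end", "name", "score", "strand",
            "dominant_pos", "dominant_tpm", "n_ctss", "width",
        ],
    )
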