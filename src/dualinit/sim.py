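"""Synthetic multi-stage CTSS data with configurable YR/YC promoter architecture.

The generator emulates the statistical structure of a developmental CAGE
promoterome:

* promoters carrying canonical YR initiation, non-canonical YC (TCT/5'-TOP)
  initiation, or both (dual initiation), with the YC +1 base embedded in a
  planted polypyrimidine run;
* a configurable fraction of dual promoters with the dominant YC site exactly
  1 nt upstream of the dominant YR site (the -1 spike), remaining offsets
  uniform on the core-promoter scale;
* per-component maternal / zygotic / constant temporal profiles over a
  12-stage grid, with the maternal-to-zygotic switch after the 7th stage;
* multinomial position sampling within a stage (dominant site carries the
  peak, minor sites decay geometrically) on top of gamma-overdispersed
  per-gene totals;
* snoRNA counts coupled to the host gene's YC and/or YR component, and
  treated/control CTSS pairs with component-specific fold changes.

Every dataset is reproducible from its seed and is accompanied by a
machine-readable ground-truth record (:class:`SimTruth`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ctss import YR_DINUCS

DEFAULT_STAGES = [
    "fertilized_egg", "cell64", "cell512", "high", "oblong", "sphere",
    "dome", "epiboly30", "shield", "epiboly75", "prim5", "prim16",
]

#: stage index at which zygotic transcription takes over (stages before it
#: are "maternal", stages from it on are "zygotic")
DEFAULT_SWITCH_INDEX = 7

#: residual expression of the silent phase relative to the active phase
PROFILE_FLOOR = 0.05

PROMOTER_CLASSES = ("YR_ONLY", "YC_ONLY", "DUAL")
PROFILES = ("MATERNAL", "ZYGOTIC", "CONSTANT")

_SLOT = 2000          # genomic span reserved per gene
_MARGIN = 1000        # padding at both genome ends
_ANCHOR_IN_SLOT = 1000


class SizingError(ValueError):
    """Requested genome too short for the promoter layout."""


@dataclass
class ArchitectureSpec:
    """Generating parameters of one synthetic promoter."""

    gene_id: str
    promoter_class: str
    yr_dominant_pos: int        # genomic anchor (dominant site of the gene)
    yc_offset: int              # dominant YC minus dominant YR, transcript orientation
    yc_fraction: float
    spread_decay: float
    pyrimidine_run: int
    temporal_profile_yr: str
    temporal_profile_yc: str
    base_expression: float
    chrom: str = "chr1"
    strand: str = "+"
    # genomic positions of planted CTSS sites, dominant first
    yr_sites: list[int] = field(default_factory=list)
    yc_sites: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.promoter_class not in PROMOTER_CLASSES:
            raise ValueError(f"unknown promoter class {self.promoter_class!r}")
        if self.promoter_class == "YC_ONLY" and self.yc_fraction != 1.0:
            raise ValueError("YC_ONLY requires yc_fraction == 1")
        if self.promoter_class == "YR_ONLY" and self.yc_fraction != 0.0:
            raise ValueError("YR_ONLY requires yc_fraction == 0")
        if abs(self.yc_offset) > 40:
            raise ValueError("|yc_offset| must be <= 40 (core-promoter scale)")
        if not (0.0 < self.spread_decay < 1.0):
            raise ValueError("spread_decay must lie in (0, 1)")
        if self.pyrimidine_run < 1:
            raise ValueError("pyrimidine_run must be >= 1")
        if self.base_expression <= 0:
            raise ValueError("base_expression must be positive")


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset; round-trips through JSON."""

    genes: list[ArchitectureSpec]
    snorna_coupling: float = 0.5
    perturb_effect_yc: float = 1.0
    perturb_effect_yr: float = 1.0
    rng_seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    switch_index: int = DEFAULT_SWITCH_INDEX
    intergenic_sites: list[int] = field(default_factory=list)
    intergenic_fraction: float = 0.0

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = [ArchitectureSpec(**g) for g in payload.pop("genes")]
        return cls(genes=genes, **payload)


# ---------------------------------------------------------------------------
# temporal profiles
# ---------------------------------------------------------------------------

def profile_multipliers(profile: str, n_stages: int,
                        switch_index: int = DEFAULT_SWITCH_INDEX) -> np.ndarray:
    """Expected expression multiplier per stage for one temporal class."""
    if profile not in PROFILES:
        raise ValueError(f"unknown temporal profile {profile!r}")
    idx = np.arange(n_stages)
    if profile == "CONSTANT":
        return np.ones(n_stages)
    active = idx < switch_index if profile == "MATERNAL" else idx >= switch_index
    return np.where(active, 1.0, PROFILE_FLOOR)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _sample_offset(rng: np.random.Generator, minus1_fraction: float,
                   max_offset: int = 30) -> int:
    """Dominant-YC offset: -1 with the spike probability, else uniform.

    The uniform pool excludes 0 and +1 (impossible by the dinucleotide
    definitions: the YC +1 base would have to be the YR purine) and -1
    (reserved for the spike).
    """
    if rng.random() < minus1_fraction:
        return -1
    pool = [o for o in range(-max_offset, max_offset + 1) if o not in (-1, 0, 1)]
    return int(rng.choice(pool))


def _plant(seq: np.ndarray, anchor: int, strand: str, rel: int, base: str) -> None:
    """Write ``base`` at transcript-relative position ``rel`` of a promoter.

    ``seq`` is the plus-strand genome as a byte array; ``anchor`` is the
    0-based plus-strand index of transcript position 0.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if strand == "+":
        seq[anchor + rel] = ord(base)
    else:
        seq[anchor - rel] = ord(comp[base])


def _layout_sites(spec: ArchitectureSpec, n_minor_yr: int, n_minor_yc: int):
    """Transcript-relative site positions and the pyrimidine-run interval.

    Returns ``(yr_rel, yc_rel, run_interval)`` with dominant sites first.
    ``run_interval`` is ``(lo, hi)`` inclusive in transcript coordinates, or
    ``None`` for YR-only promoters.
    """
    yr_rel: list[int] = []
    yc_rel: list[int] = []
    off = spec.yc_offset
    if spec.promoter_class in ("YR_ONLY", "DUAL"):
        yr_rel.append(0)
        # minor YR sites on the side away from the YC block
        step = 3 if (spec.promoter_class == "YR_ONLY" or off < 0) else -3
        yr_rel.extend(step * k for k in range(1, n_minor_yr + 1))
    if spec.promoter_class == "YC_ONLY":
        off = 0
    if spec.promoter_class in ("YC_ONLY", "DUAL"):
        yc_rel.append(off)
        if spec.promoter_class == "YC_ONLY" or spec.yc_offset < 0:
            yc_rel.extend(off - 3 * k for k in range(1, n_minor_yc + 1))
            lo = min(off - spec.pyrimidine_run + 1, min(yc_rel) - 1)
            run = (lo, off)
        else:
            yc_rel.extend(off + 3 * k for k in range(1, n_minor_yc + 1))
            hi = max(off + spec.pyrimidine_run - 2, max(yc_rel))
            run = (off - 1, hi)
    else:
        run = None
    return yr_rel, yc_rel, run


def generate_reference(
    n_genes: int,
    genome_length: int | None = None,
    gc_content: float = 0.4,
    seed: int = 0,
    *,
    dual_fraction: float = 0.20,
    yc_only_fraction: float = 0.05,
    minus1_fraction: float = 0.18,
    spread_decay: float = 0.35,
    pyrimidine_run: tuple[int, int] = (4, 12),
    base_expression_log_mean: float = np.log(400.0),
    base_expression_log_sd: float = 1.0,
    divergent_fraction: float = 0.25,
    n_minor_yr: int = 2,
    n_minor_yc: int = 2,
    stages: list[str] | None = None,
    switch_index: int = DEFAULT_SWITCH_INDEX,
    intergenic_fraction: float = 0.0,
):
    """Generate a genome, gene models and ground truth for ``n_genes`` promoters.

    Promoters are laid out on alternating strands in non-overlapping slots.
    Each YR site is planted with a pyrimidine at -1 and a purine at +1; each
    YC site sits inside a contiguous pyrimidine run (its +1 base a C) of at
    least ``pyrimidine_run`` nt (drawn per gene from the given range).  Among
    dual promoters, ``minus1_fraction`` receive a dominant-YC offset of -1;
    the rest draw uniformly from the admissible core-promoter offsets.
    ``divergent_fraction`` of dual promoters get opposing maternal/zygotic
    profiles for their two components.

    Returns ``(genome, gene_models, truth)``.
    """
    from .io import GeneModel

    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    needed = 2 * _MARGIN + n_genes * _SLOT
    if genome_length is None:
        genome_length = needed
    elif genome_length < needed:
        raise SizingError(
            f"genome of {genome_length} nt cannot hold {n_genes} promoters "
            f"(need >= {needed})"
        )
    rng = np.random.default_rng(seed)
    stages = list(DEFAULT_STAGES) if stages is None else list(stages)

    # background sequence at the requested GC content
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                     size=genome_length, p=p).copy()

    genes: list[ArchitectureSpec] = []
    models: list[GeneModel] = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    for i in range(n_genes):
        u = rng.random()
        if u < dual_fraction:
            pclass = "DUAL"
        elif u < dual_fraction + yc_only_fraction:
            pclass = "YC_ONLY"
        else:
            pclass = "YR_ONLY"
        strand = "+" if i % 2 == 0 else "-"
        anchor0 = _MARGIN + i * _SLOT + _ANCHOR_IN_SLOT     # 0-based
        anchor = anchor0 + 1                                # 1-based genomic

        if pclass == "DUAL":
            yc_offset = _sample_offset(rng, minus1_fraction)
            yc_fraction = float(rng.uniform(0.15, 0.5))
        elif pclass == "YC_ONLY":
            yc_offset = 0
            yc_fraction = 1.0
        else:
            yc_offset = 0
            yc_fraction = 0.0

        if pclass == "DUAL" and rng.random() < divergent_fraction:
            prof_yr, prof_yc = ("MATERNAL", "ZYGOTIC") if rng.random() < 0.5 \
                else ("ZYGOTIC", "MATERNAL")
        else:
            prof_yr = prof_yc = str(rng.choice(PROFILES))

        spec = ArchitectureSpec(
            gene_id=f"g{i:05d}",
            promoter_class=pclass,
            yr_dominant_pos=anchor,
            yc_offset=yc_offset,
            yc_fraction=yc_fraction,
            spread_decay=spread_decay,
            pyrimidine_run=int(rng.integers(pyrimidine_run[0],
                                            pyrimidine_run[1] + 1)),
            temporal_profile_yr=prof_yr,
            temporal_profile_yc=prof_yc,
            base_expression=float(rng.lognormal(base_expression_log_mean,
                                                base_expression_log_sd)),
            chrom="chr1",
            strand=strand,
        )

        yr_rel, yc_rel, run = _layout_sites(spec, n_minor_yr, n_minor_yc)

        # plant the pyrimidine run first, then site-specific bases on top
        if run is not None:
            lo, hi = run
            for r in range(lo, hi + 1):
                _plant(seq, anchor0, strand, r,
                       "C" if rng.random() < 0.5 else "T")
            # purine guards so the planted run does not extend by accident;
            # skip positions that are themselves constrained (YR -1 or +1)
            for guard in (lo - 1, hi + 1):
                if guard == 0:
                    continue            # YR dominant +1, planted below
                if guard == -1 and yr_rel:
                    continue            # YR dominant -1 must stay a pyrimidine
                _plant(seq, anchor0, strand, guard,
                       "A" if rng.random() < 0.5 else "G")
        for r in yc_rel:
            _plant(seq, anchor0, strand, r, "C")            # +1 of a YC site
        for r in yr_rel:
            dinuc = str(rng.choice(sorted(YR_DINUCS)))
            if r - 1 == spec.yc_offset and yc_rel:
                # -1 of this YR site is the YC +1 base (offset -1 spike):
                # keep it a C, which satisfies the Y at -1 requirement
                _plant(seq, anchor0, strand, r, str(rng.choice(["A", "G"])))
            else:
                _plant(seq, anchor0, strand, r - 1, dinuc[0])
                _plant(seq, anchor0, strand, r, dinuc[1])

        def to_genomic(rel: int) -> int:
            return anchor + rel if strand == "+" else anchor - rel

        spec.yr_sites = [to_genomic(r) for r in yr_rel]
        spec.yc_sites = [to_genomic(r) for r in yc_rel]
        genes.append(spec)

        # gene model: exon1 = transcript 0..99, exon2 = 300..699, CDS in exon2
        cds_t = int(rng.integers(310, 500))
        if strand == "+":
            exons = ((anchor, anchor + 99), (anchor + 300, anchor + 699))
            cds_start = anchor + cds_t
        else:
            exons = ((anchor - 699, anchor - 300), (anchor - 99, anchor))
            cds_start = anchor - cds_t
        models.append(GeneModel(spec.gene_id, "chr1", strand, anchor,
                                cds_start, exons))

    truth = SimTruth(
        genes=genes, rng_seed=seed, stages=stages, switch_index=switch_index,
        intergenic_sites=_plant_intergenic(seq, rng, n_genes,
                                           intergenic_fraction),
        intergenic_fraction=intergenic_fraction,
    )
    genome = {"chr1": seq.tobytes().decode("ascii")}
    return genome, models, truth


def _plant_intergenic(seq, rng, n_genes: int, fraction: float) -> list[int]:
    """Plant YR contexts in slot gaps, outside every promoter window."""
    if fraction <= 0:
        return []
    sites = []
    for i in range(n_genes):
        pos0 = _MARGIN + i * _SLOT + 100        # 0-based, far from any window
        seq[pos0 - 1] = ord("T")
        seq[pos0] = ord("A")
        sites.append(pos0 + 1)                  # 1-based, plus strand
    return sites


# ---------------------------------------------------------------------------
# CTSS simulation
# ---------------------------------------------------------------------------

def _site_table(truth: SimTruth) -> pd.DataFrame:
    """All planted CTSS positions with within-gene relative weights."""
    rows = []
    for g in truth.genes:
        for comp, sites, frac in (
            ("YR", g.yr_sites, 1.0 - g.yc_fraction),
            ("YC", g.yc_sites, g.yc_fraction),
        ):
            if frac <= 0 or not sites:
                continue
            # within-component position share only; the component fraction
            # enters through expected_stage_weights
            w = g.spread_decay ** np.arange(len(sites))
            w = w / w.sum()
            for pos, wi in zip(sites, w):
                rows.append((g.chrom, int(pos), g.strand, g.gene_id, comp,
                             float(wi)))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "gene_id", "component",
                       "weight"])


def expected_stage_weights(truth: SimTruth,
                           stages: list[str] | None = None) -> pd.DataFrame:
    """Expected (unnormalized) expression weight per gene x component x stage."""
    stages = truth.stages if stages is None else stages
    n = len(stages)
    rows = []
    for g in truth.genes:
        for comp, frac, prof in (
            ("YR", 1.0 - g.yc_fraction, g.temporal_profile_yr),
            ("YC", g.yc_fraction, g.temporal_profile_yc),
        ):
            if frac <= 0:
                continue
            mult = profile_multipliers(prof, n, truth.switch_index)
            for s, m in zip(stages, mult):
                rows.append((g.gene_id, comp, s,
                             g.base_expression * frac * m))
    return pd.DataFrame(rows, columns=["gene_id", "component", "stage",
                                       "weight"])


def expected_component_tpm(truth: SimTruth,
                           stages: list[str] | None = None) -> pd.DataFrame:
    """Noise-free expected TPM per gene x component x stage.

    Intergenic planted sites (if any) are included in the normalizing total,
    so these values match what deep sampling converges to.
    """
    stages = truth.stages if stages is None else stages
    w = expected_stage_weights(truth, stages)
    inter = getattr(truth, "intergenic_sites", [])
    f = getattr(truth, "intergenic_fraction", 0.0)
    out = []
    for s, grp in w.groupby("stage", sort=False):
        total = grp["weight"].sum()
        if inter and f > 0:
            total = total / (1.0 - f)
        g = grp.copy()
        g["tpm"] = g["weight"] / total * 1e6
        out.append(g)
    return pd.concat(out, ignore_index=True)[
        ["gene_id", "component", "stage", "tpm"]]


def simulate_ctss_counts(
    truth: SimTruth,
    stages: list[str] | None = None,
    depth: int = 1_000_000,
    seed: int | None = None,
    gene_dispersion: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """Draw per-stage CTSS tables (chrom, pos, strand, count).

    Per stage, a single gamma factor with the given dispersion multiplies
    each gene's expected weight (overdispersed totals; within-gene component
    and position shares are untouched), then ``depth`` tags are distributed
    multinomially over all planted positions.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    stages = truth.stages if stages is None else list(stages)
    unknown = set(stages) - set(truth.stages)
    if unknown:
        raise ValueError(f"unknown stage label(s): {sorted(unknown)}")
    rng = np.random.default_rng(truth.rng_seed + 1 if seed is None else seed)

    sites = _site_table(truth)
    stage_w = expected_stage_weights(truth, stages)
    gene_ids = [g.gene_id for g in truth.genes]
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    inter = getattr(truth, "intergenic_sites", [])
    f_inter = getattr(truth, "intergenic_fraction", 0.0)

    out: dict[str, pd.DataFrame] = {}
    for s in stages:
        w_s = stage_w[stage_w["stage"] == s]
        comp_w = {(r.gene_id, r.component): r.weight
                  for r in w_s.itertuples(index=False)}
        if gene_dispersion > 0:
            factors = rng.gamma(1.0 / gene_dispersion, gene_dispersion,
                                size=len(gene_ids))
        else:
            factors = np.ones(len(gene_ids))
        w = np.array([
            comp_w.get((g, c), 0.0) * wi * factors[gene_index[g]]
            for g, c, wi in zip(sites["gene_id"], sites["component"],
                                sites["weight"])
        ])
        table = sites[["chrom", "pos", "strand"]].copy()
        if inter and f_inter > 0:
            wi_total = w.sum() * f_inter / (1.0 - f_inter)
            inter_tab = pd.DataFrame({
                "chrom": "chr1", "pos": inter, "strand": "+",
            })
            table = pd.concat([table, inter_tab], ignore_index=True)
            w = np.concatenate([w, np.full(len(inter),
                                           wi_total / len(inter))])
        counts = rng.multinomial(depth, w / w.sum())
        table = table.assign(count=counts)
        table = (table[table["count"] > 0]
                 .groupby(["chrom", "pos", "strand"], as_index=False)["count"]
                 .sum()
                 .sort_values(["chrom", "strand", "pos"], kind="stable")
                 .reset_index(drop=True))
        out[s] = table
    return out


# ---------------------------------------------------------------------------
# snoRNA and perturbation simulation
# ---------------------------------------------------------------------------

def simulate_snorna_counts(
    truth: SimTruth,
    yc_expr,
    yr_expr,
    dispersion: float = 0.1,
    seed: int | None = None,
    scale: float = 1.0,
):
    """snoRNA counts coupled to host-gene components.

    ``yc_expr``/``yr_expr`` are per-stage expression vectors (1-D for one
    host, 2-D genes x stages).  The mean is
    ``scale * (coupling * yc + (1 - coupling) * yr)`` with
    ``coupling = truth.snorna_coupling``; counts follow a gamma-Poisson
    (negative-binomial-type) law with the given dispersion.  With
    ``dispersion == 0`` the exact expected values are returned (continuous),
    so limit-case identities hold exactly.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    yc = np.asarray(yc_expr, dtype=float)
    yr = np.asarray(yr_expr, dtype=float)
    if yc.shape != yr.shape:
        raise ValueError("yc_expr and yr_expr must have the same shape")
    c = truth.snorna_coupling
    mean = scale * (c * yc + (1.0 - c) * yr)
    if dispersion == 0:
        return mean
    rng = np.random.default_rng(truth.rng_seed + 2 if seed is None else seed)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam).astype(np.int64)


def simulate_perturbation(
    truth: SimTruth,
    baseline: pd.DataFrame,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resample a baseline CTSS table into a (control, treated) pair.

    Treated expectations are the baseline counts multiplied by
    ``truth.perturb_effect_yc`` at planted YC positions and
    ``truth.perturb_effect_yr`` at planted YR positions (other positions are
    unaffected); both tables are Poisson-resampled.
    """
    if truth.perturb_effect_yc <= 0 or truth.perturb_effect_yr <= 0:
        raise ValueError("perturbation effects must be positive")
    rng = np.random.default_rng(truth.rng_seed + 3 if seed is None else seed)
    sites = _site_table(truth)
    key = sites.set_index(["chrom", "pos", "strand"])["component"]
    comp = pd.MultiIndex.from_frame(
        baseline[["chrom", "pos", "strand"]]).map(key)
    effect = np.where(comp == "YC", truth.perturb_effect_yc,
                      np.where(comp == "YR", truth.perturb_effect_yr, 1.0))
    base = baseline["count"].to_numpy(dtype=float)
    control = baseline.assign(count=rng.poisson(base))
    treated = baseline.assign(count=rng.poisson(base * effect))
    return (control[control["count"] > 0].reset_index(drop=True),
            treated[treated["count"] > 0].reset_index(drop=True))
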