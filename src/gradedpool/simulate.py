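"""F2 graded-pool sequencing simulator and power harness.

Emulates the full experiment: an F2 population from a cross of two inbred
parents (Haldane/no-interference recombination, crossovers Poisson in map
length), additive + dominance QTL effects with Gaussian environmental
noise, ranking of individuals into ordinal bulks (with optional
misclassification), and pooled short-read sampling (Poisson pool depth,
binomial allele draw with a symmetric sequencing-error rate).

Genome defaults are rice-like: 12 chromosomes of 30 Mb at 4 cM/Mb, 2,000
uniformly placed SNPs per chromosome, 900 F2 individuals split into three
graded bulks of 300 sequenced at 0.7x per individual (pool depth ~210x).
The alternate allele is, by convention, the high-parent allele, so the two
simulated parents are homozygous alt (high) and ref (low) everywhere.

All randomness fans out from a single seed into named substreams (genome,
gametes, phenotype, misclassification, reads) so each stage is
independently reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .ordinal import test_track
from .pool_io import (
    GT_HOM_ALT, GT_HOM_REF, BulkDesign, GradeSpec, VariantTable,
)
from .scan import ScanConfig, call_intervals, window_ratio

__all__ = ["QTL", "SimConfig", "SimTruth", "simulate_f2", "grade_population",
           "pool_reads", "evaluate_detection", "DetectionResult", "power_grid"]

_STREAMS = ("genome", "gametes", "phenotype", "misclass", "reads")


@dataclass(frozen=True)
class QTL:
    """One causal locus: chromosome index (1-based), position, additive
    effect a (half the difference between homozygotes) and dominance d
    (heterozygote deviation from the homozygote midpoint), in trait units."""

    chrom: int
    pos_bp: int
    a: float
    d: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    n_chrom: int = 12
    chrom_len_bp: int = 30_000_000
    n_snps_per_chrom: int = 2_000
    cM_per_Mb: float = 4.0
    n_f2: int = 900
    qtls: tuple = ()
    env_sd: float = 1.0
    bulk_fractions: tuple = (1 / 3, 1 / 3, 1 / 3)
    phenotype_cuts: Optional[tuple] = None  # ascending trait-value cut points
    per_individual_coverage: float = 0.7
    seq_error: float = 0.001
    misclass_rate: float = 0.0
    misclass_bulk: Optional[int] = None  # 1-based grade; None = all bulks
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.bulk_fractions, float)
        if (fr <= 0).any() or (fr > 1).any() or fr.sum() > 1 + 1e-9:
            raise ValueError("bulk fractions must be in (0,1] and sum to <= 1")
        if self.per_individual_coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must be in [0, 0.5)")
        if not (0 <= self.misclass_rate < 1):
            raise ValueError("misclass_rate must be in [0, 1)")
        for q in self.qtls:
            if not (1 <= q.chrom <= self.n_chrom):
                raise ValueError(f"QTL chromosome {q.chrom} outside 1..{self.n_chrom}")
            if not (1 <= q.pos_bp <= self.chrom_len_bp):
                raise ValueError(f"QTL position {q.pos_bp} outside chromosome")

    @property
    def k(self) -> int:
        return len(self.bulk_fractions)

    def chrom_name(self, idx: int) -> str:
        return f"chr{idx}"


@dataclass
class SimTruth:
    """Simulated ground truth for one replicate."""

    chrom: np.ndarray            # per SNP
    pos: np.ndarray              # per SNP, 1-based bp
    dosage: np.ndarray           # (n_f2, n_snps) copies of the high-parent allele
    qtl_dosage: np.ndarray       # (n_f2, n_qtls)
    phenotypes: np.ndarray
    qtls: tuple
    true_labels: np.ndarray      # grade 1..k, 0 = unassigned
    observed_labels: np.ndarray  # after misclassification
    config: SimConfig


def _rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _snp_positions(rng, n: int, length: int) -> np.ndarray:
    """n distinct uniform positions in 1..length, sorted."""
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n]


def _gamete(rng, positions: np.ndarray, chrom_len_bp: int, cM_per_Mb: float) -> np.ndarray:
    """Alleles (0/1) transmitted by one F1 gamete at the given positions.

    Crossover count ~ Poisson(map length in Morgans), breakpoints uniform,
    no interference (Haldane); the starting parental phase is fair."""
    morgans = chrom_len_bp / 1e6 * cM_per_Mb / 100.0
    n_co = rng.poisson(morgans)
    start = rng.integers(2)
    if n_co == 0:
        return np.full(len(positions), start, dtype=np.int8)
    breaks = np.sort(rng.uniform(0, chrom_len_bp, size=n_co))
    crossings = np.searchsorted(breaks, positions)
    return ((start + crossings) % 2).astype(np.int8)


def simulate_f2(cfg: SimConfig) -> SimTruth:
    """Simulate genotypes, phenotypes and bulk assignment for one F2 population."""
    rngs = _rngs(cfg.seed)
    g_rng, gam_rng, ph_rng = rngs["genome"], rngs["gametes"], rngs["phenotype"]

    chrom_pos = [_snp_positions(g_rng, cfg.n_snps_per_chrom, cfg.chrom_len_bp)
                 for _ in range(cfg.n_chrom)]
    qtl_by_chrom = [[] for _ in range(cfg.n_chrom)]
    for qi, q in enumerate(cfg.qtls):
        qtl_by_chrom[q.chrom - 1].append((qi, q.pos_bp))

    n = cfg.n_f2
    m = cfg.n_chrom * cfg.n_snps_per_chrom
    dosage = np.empty((n, m), dtype=np.int8)
    qtl_dosage = np.zeros((n, len(cfg.qtls)), dtype=np.int8)

    col = 0
    for ci in range(cfg.n_chrom):
        pos = chrom_pos[ci]
        extra = np.array([p for _, p in qtl_by_chrom[ci]], dtype=np.int64)
        eval_pos = np.concatenate([pos, extra]) if len(extra) else pos
        n_snp = len(pos)
        for ind in range(n):
            g1 = _gamete(gam_rng, eval_pos, cfg.chrom_len_bp, cfg.cM_per_Mb)
            g2 = _gamete(gam_rng, eval_pos, cfg.chrom_len_bp, cfg.cM_per_Mb)
            d = g1 + g2
            dosage[ind, col:col + n_snp] = d[:n_snp]
            for slot, (qi, _) in enumerate(qtl_by_chrom[ci]):
                qtl_dosage[ind, qi] = d[n_snp + slot]
        col += n_snp

    y = ph_rng.normal(0.0, cfg.env_sd, size=n)
    for qi, q in enumerate(cfg.qtls):
        d = qtl_dosage[:, qi].astype(float)
        y += q.a * (d - 1.0) + q.d * (d == 1.0)

    chrom = np.concatenate([
        np.full(cfg.n_snps_per_chrom, cfg.chrom_name(ci + 1), dtype=object)
        for ci in range(cfg.n_chrom)
    ])
    pos_all = np.concatenate(chrom_pos)

    true_labels, observed = grade_population(y, cfg, rng=rngs["misclass"])
    return SimTruth(chrom=chrom, pos=pos_all, dosage=dosage, qtl_dosage=qtl_dosage,
                    phenotypes=y, qtls=tuple(cfg.qtls), true_labels=true_labels,
                    observed_labels=observed, config=cfg)


def grade_population(phenotypes: np.ndarray, cfg: SimConfig,
                     rng: Optional[np.random.Generator] = None):
    """Assign individuals to ordinal bulks, then apply misclassification.

    Fraction mode (default): rank by phenotype descending; the top
    fraction_1 goes to grade 1, the next fraction_2 to grade 2, ...;
    individuals beyond the fraction sum stay unassigned (label 0).
    Boundary mode (``phenotype_cuts`` set): explicit ascending trait cut
    points; values above the top cut are grade 1.

    Misclassification swaps floor(m * n_b) uniformly chosen members of the
    target bulk (all bulks when misclass_bulk is None) with uniformly
    chosen individuals outside it.
    """
    y = np.asarray(phenotypes, float)
    n = len(y)
    labels = np.zeros(n, dtype=np.int64)
    if cfg.phenotype_cuts is not None:
        cuts = np.asarray(cfg.phenotype_cuts, float)
        if not (np.diff(cuts) > 0).all():
            raise ValueError("phenotype_cuts must be strictly ascending")
        k = len(cuts) + 1
        # grade 1 = above the highest cut
        labels = k - np.digitize(y, cuts, right=False)
    else:
        fr = np.asarray(cfg.bulk_fractions, float)
        if fr.sum() > 1 + 1e-9:
            raise ValueError("bulk fractions sum above 1")
        order = np.argsort(-y, kind="stable")
        bounds = np.round(np.cumsum(fr) * n).astype(int)
        start = 0
        for g, stop in enumerate(bounds, start=1):
            labels[order[start:stop]] = g
            start = stop
    true_labels = labels.copy()

    observed = labels.copy()
    if cfg.misclass_rate > 0:
        if rng is None:
            rng = _rngs(cfg.seed)["misclass"]
        targets = ([cfg.misclass_bulk] if cfg.misclass_bulk is not None
                   else list(range(1, cfg.k + 1)))
        for b in targets:
            members = np.flatnonzero(observed == b)
            outsiders = np.flatnonzero(observed != b)
            n_swap = int(np.floor(cfg.misclass_rate * len(members)))
            if n_swap == 0 or len(outsiders) == 0:
                continue
            out_pick = rng.choice(members, size=n_swap, replace=False)
            in_pick = rng.choice(outsiders, size=n_swap, replace=False)
            observed[out_pick], observed[in_pick] = (
                observed[in_pick].copy(), observed[out_pick].copy())
    return true_labels, observed


def pool_reads(truth: SimTruth, cfg: Optional[SimConfig] = None,
               labels: Optional[np.ndarray] = None) -> VariantTable:
    """Sample pooled read counts from the bulked individuals.

    Per SNP and bulk: pool depth ~ Poisson(n_b * per-individual coverage);
    the alternate (high-parent) allele is read with probability
    f (1 - eps) + (1 - f) eps where f is the bulk's true allele frequency
    (mean dosage / 2 over its observed members) and eps the sequencing-error
    rate.  Parent genotypes are attached (high parent hom-alt, low hom-ref)
    so the full filter path can run on simulated data.
    """
    cfg = cfg or truth.config
    if labels is None:
        labels = truth.observed_labels
    rng = _rngs(cfg.seed)["reads"]
    m = len(truth.pos)
    k = cfg.k
    ref_counts = np.empty((m, k), dtype=np.int64)
    alt_counts = np.empty((m, k), dtype=np.int64)
    n_per_bulk = []
    for g in range(1, k + 1):
        members = np.flatnonzero(labels == g)
        if len(members) == 0:
            raise ValueError(f"bulk {g} is empty")
        n_per_bulk.append(len(members))
        f = truth.dosage[members].mean(axis=0) / 2.0
        p_alt = f * (1 - cfg.seq_error) + (1 - f) * cfg.seq_error
        depth = rng.poisson(len(members) * cfg.per_individual_coverage, size=m)
        alt = rng.binomial(depth, p_alt)
        alt_counts[:, g - 1] = alt
        ref_counts[:, g - 1] = depth - alt

    design = BulkDesign(
        grades=tuple(GradeSpec(g, f"grade{g}", n_per_bulk[g - 1]) for g in range(1, k + 1)),
        parent_high="P_HIGH", parent_low="P_LOW",
    )
    return VariantTable(
        chrom=truth.chrom.copy(), pos=truth.pos.copy(),
        ref=np.full(m, "A", dtype=object), alt=np.full(m, "G", dtype=object),
        qual=np.full(m, 100.0),
        ref_counts=ref_counts, alt_counts=alt_counts,
        design=design,
        parent_gt_high=np.full(m, GT_HOM_ALT, dtype=np.int8),
        parent_gt_low=np.full(m, GT_HOM_REF, dtype=np.int8),
        meta={"source": "simulate", "filters_applied": [],
              "contig_lengths": {cfg.chrom_name(i + 1): cfg.chrom_len_bp
                                 for i in range(cfg.n_chrom)}},
    )


@dataclass
class DetectionResult:
    hits: list            # per QTL: True if some interval lies within tolerance
    hit_ranks: list       # rank of the best hitting interval (None on miss)
    n_false_positives: int


def evaluate_detection(intervals: Sequence, truth: SimTruth,
                       window_bp: int = 400_000,
                       tolerance_windows: int = 1) -> DetectionResult:
    """Score called intervals against the planted QTLs.

    A QTL is detected when some interval on its chromosome comes within
    ``tolerance_windows`` windows of the QTL position; intervals near no
    QTL count as false positives.
    """
    tol_bp = tolerance_windows * window_bp
    hits, ranks = [], []
    used = set()
    for q in truth.qtls:
        cname = truth.config.chrom_name(q.chrom)
        best = None
        for i, iv in enumerate(intervals):
            if iv.chrom != cname:
                continue
            if iv.start - tol_bp <= q.pos_bp - 1 < iv.end + tol_bp:
                if best is None or iv.rank < intervals[best].rank:
                    best = i
        hits.append(best is not None)
        if best is not None:
            ranks.append(intervals[best].rank)
            used.add(best)
        else:
            ranks.append(None)
    # any interval within tolerance of any QTL is not a false positive
    fp = 0
    for i, iv in enumerate(intervals):
        near = False
        for q in truth.qtls:
            if iv.chrom == truth.config.chrom_name(q.chrom) and \
                    iv.start - tol_bp <= q.pos_bp - 1 < iv.end + tol_bp:
                near = True
                break
        fp += not near
    return DetectionResult(hits=hits, hit_ranks=ranks, n_false_positives=fp)


def _rep_seeds(seed: int, n_reps: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint32) % (2 ** 31)


def run_replicate(cfg: SimConfig, scan_cfg: ScanConfig, method: str = "ridit",
                  effective_pool: bool = False, tolerance_windows: int = 1,
                  truth: Optional[SimTruth] = None):
    """One simulate -> pool -> test -> scan -> evaluate pass.

    A pre-simulated ``truth`` may be supplied to share the population across
    analysis settings (common random numbers)."""
    if truth is None:
        truth = simulate_f2(cfg)
    table = pool_reads(truth, cfg)
    track = test_track(table, method=method, effective_pool=effective_pool)
    ratios = window_ratio(track, scan_cfg)
    intervals = call_intervals(ratios, scan_cfg)
    det = evaluate_detection(intervals, truth, window_bp=scan_cfg.window_bp,
                             tolerance_windows=tolerance_windows)
    return truth, intervals, det


def power_grid(base: SimConfig, grid: dict, n_reps: int, seed: int,
               scan_cfg: Optional[ScanConfig] = None,
               tolerance_windows: int = 1):
    """Detection power / rank / false positives over a parameter grid.

    ``grid`` maps SimConfig field names (plus the pseudo-parameter
    ``method``) to value lists; the full product is evaluated.  Replicate r
    uses the same derived seed in every cell, so cells share random numbers
    and power comparisons across a single axis are paired.
    Returns a pandas DataFrame with one row per cell.
    """
    import pandas as pd

    scan_cfg = scan_cfg or ScanConfig(top_n=1)
    keys = list(grid)
    seeds = _rep_seeds(seed, n_reps)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        cell = dict(zip(keys, values))
        method = cell.pop("method", "ridit")
        n_hit = 0
        ranks = []
        fps = 0
        for r in range(n_reps):
            cfg = replace(base, seed=int(seeds[r]), **cell)
            _, _, det = run_replicate(cfg, scan_cfg, method=method,
                                      tolerance_windows=tolerance_windows)
            n_hit += all(det.hits) if det.hits else 0
            ranks += [rk for rk in det.hit_ranks if rk is not None]
            fps += det.n_false_positives
        row = dict(zip(keys, values))
        row.update({
            "power": n_hit / n_reps,
            "mean_hit_rank": float(np.mean(ranks)) if ranks else np.nan,
            "false_positives_per_rep": fps / n_reps,
            "n_reps": n_reps,
        })
        rows.append(row)
    return pd.DataFrame(rows)
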