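"""Noise-reduction genome scan: window significance ratios and interval calls.

Per-SNP p-values are noisy in wide crosses, so instead of thresholding
single SNPs the scan tiles each chromosome with non-overlapping windows
(default 400 kb) and scores each window by the fraction of its SNPs whose
p-value passes a per-SNP significance cut.  Windows holding fewer than
``min_snps`` SNPs (default 10) are skipped.  Candidate QTL intervals are the
top-ranked windows; adjacent called windows merge into one interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .filters import FilterConfig, run_filters
from .ordinal import PValueTrack, test_track
from .pool_io import BulkDesign, _natural_key, read_pooled_vcf, write_tracks

__all__ = ["ScanConfig", "RatioTrack", "QTLInterval", "assign_windows",
           "window_ratio", "call_intervals", "scan"]


@dataclass(frozen=True)
class ScanConfig:
    """Window scan settings.

    window_bp: non-overlapping window width (bp).
    alpha: per-SNP significance cut used in the ratio numerator.  The ratio
        statistic absorbs a permissive cut, but results do depend on it.
    min_snps: windows with fewer total SNPs are skipped.
    top_n / min_ratio: interval-calling rules (both may be set).
    merge_adjacent: merge touching called windows into one interval.
    """

    window_bp: int = 400_000
    alpha: float = 1e-3
    min_snps: int = 10
    top_n: Optional[int] = 10
    min_ratio: Optional[float] = None
    merge_adjacent: bool = True

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


@dataclass
class RatioTrack:
    """Per-window counts and significance ratios.

    ``df`` columns: chrom, start, end (0-based half-open), n_snps,
    n_significant, ratio (NaN when skipped), skipped, midpoint.
    """

    df: pd.DataFrame
    alpha: float
    window_bp: int

    def __len__(self) -> int:
        return len(self.df)

    @property
    def unskipped(self) -> pd.DataFrame:
        return self.df[~self.df["skipped"]]


@dataclass(frozen=True)
class QTLInterval:
    chrom: str
    start: int  # 0-based half-open, bp
    end: int
    peak_ratio: float
    n_snps: int
    rank: int

    @property
    def width(self) -> int:
        return self.end - self.start


def assign_windows(track: PValueTrack, cfg: ScanConfig) -> np.ndarray:
    """Window index of each SNP: a 1-based position p falls in window
    floor((p - 1) / window_bp), i.e. windows tile from coordinate 0."""
    return (np.asarray(track.pos, dtype=np.int64) - 1) // cfg.window_bp


def window_ratio(track: PValueTrack, cfg: Optional[ScanConfig] = None) -> RatioTrack:
    """Score every window by its fraction of significant SNPs.

    Windows are emitted for each chromosome from 0 up to the last window
    containing a SNP; windows with fewer than ``min_snps`` SNPs (including
    empty ones) are flagged skipped and excluded from ranking.
    """
    cfg = cfg or ScanConfig()
    rows = []
    if len(track) > 0:
        widx = assign_windows(track, cfg)
        sig = np.asarray(track.p) < cfg.alpha
        nlp = track.neg_log_p
        chroms = pd.unique(np.asarray(track.chrom))
        for c in sorted(chroms, key=lambda x: _natural_key(str(x))):
            on = np.asarray(track.chrom) == c
            w = widx[on]
            s = sig[on]
            n_win = int(w.max()) + 1
            n_snps = np.bincount(w, minlength=n_win)
            n_sig = np.bincount(w, weights=s.astype(float), minlength=n_win).astype(int)
            sum_nlp = np.bincount(w, weights=nlp[on], minlength=n_win)
            for i in range(n_win):
                skipped = n_snps[i] < cfg.min_snps
                rows.append({
                    "chrom": c,
                    "start": i * cfg.window_bp,
                    "end": (i + 1) * cfg.window_bp,
                    "n_snps": int(n_snps[i]),
                    "n_significant": int(n_sig[i]),
                    "ratio": (n_sig[i] / n_snps[i]) if not skipped else np.nan,
                    "mean_neg_ln_p": (sum_nlp[i] / n_snps[i]) if n_snps[i] else np.nan,
                    "skipped": bool(skipped),
                })
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                     "n_significant", "ratio", "mean_neg_ln_p",
                                     "skipped"])
    df["midpoint"] = (df["start"] + df["end"]) // 2 if len(df) else df.get("start")
    return RatioTrack(df=df, alpha=cfg.alpha, window_bp=cfg.window_bp)


def call_intervals(ratios: RatioTrack, cfg: Optional[ScanConfig] = None) -> list:
    """Rank unskipped windows and call candidate QTL intervals.

    Ranking: ratio descending; ties broken by the window's mean -ln p, then
    n_significant, then genome order.  The mean -ln p tie-break matters when
    a strong QTL saturates the ratio at 1.0 over a multi-window plateau: the
    per-SNP evidence still peaks at the QTL window, so ranking inside the
    plateau by it keeps single-window resolution.  Selection: windows with
    ratio >= min_ratio (when set), truncated to the top_n best (when set).
    Adjacent called windows on a chromosome merge into one interval carrying
    the maximum ratio and the best rank.
    """
    cfg = cfg or ScanConfig()
    cand = ratios.unskipped.copy()
    if len(cand) == 0:
        import logging
        logging.getLogger(__name__).warning("all windows skipped; no intervals called")
        return []
    cand["_ckey"] = [tuple(_natural_key(str(c))) for c in cand["chrom"]]
    cand = cand.sort_values(
        by=["ratio", "mean_neg_ln_p", "n_significant", "_ckey", "start"],
        ascending=[False, False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    cand["rank"] = np.arange(1, len(cand) + 1)
    if cfg.min_ratio is not None:
        cand = cand[cand["ratio"] >= cfg.min_ratio]
    if cfg.top_n is not None:
        cand = cand.head(cfg.top_n)
    if len(cand) == 0:
        return []

    picked = cand.sort_values(by=["_ckey", "start"], kind="mergesort")
    intervals = []
    cur = None
    for rec in picked.itertuples(index=False):
        if (cfg.merge_adjacent and cur is not None
                and rec.chrom == cur["chrom"] and rec.start == cur["end"]):
            cur["end"] = rec.end
            cur["peak_ratio"] = max(cur["peak_ratio"], rec.ratio)
            cur["n_snps"] += rec.n_snps
            cur["rank"] = min(cur["rank"], rec.rank)
        else:
            if cur is not None:
                intervals.append(cur)
            cur = {"chrom": rec.chrom, "start": rec.start, "end": rec.end,
                   "peak_ratio": rec.ratio, "n_snps": rec.n_snps, "rank": rec.rank}
    if cur is not None:
        intervals.append(cur)
    intervals.sort(key=lambda d: d["rank"])
    out = []
    for new_rank, d in enumerate(intervals, start=1):
        out.append(QTLInterval(chrom=str(d["chrom"]), start=int(d["start"]),
                               end=int(d["end"]), peak_ratio=float(d["peak_ratio"]),
                               n_snps=int(d["n_snps"]), rank=new_rank))
    return out


def scan(vcf_path, design: BulkDesign,
         filter_cfg: Optional[FilterConfig] = None,
         scan_cfg: Optional[ScanConfig] = None,
         method: str = "ridit",
         effective_pool: bool = False,
         out_prefix=None):
    """Full pipeline: read VCF -> filter -> test -> window -> call.

    Returns (PValueTrack, RatioTrack, intervals, FilterReport); when
    ``out_prefix`` is given, also writes the TSV/BED artifacts.
    """
    scan_cfg = scan_cfg or ScanConfig()
    table = read_pooled_vcf(vcf_path, design)
    filtered, report = run_filters(table, filter_cfg)
    pvals = test_track(filtered, method=method, effective_pool=effective_pool)
    ratios = window_ratio(pvals, scan_cfg)
    intervals = call_intervals(ratios, scan_cfg)
    if out_prefix is not None:
        write_tracks(pvals, ratios, intervals, out_prefix)
    return pvals, ratios, intervals, report
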