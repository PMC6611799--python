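"""Staged filtering of pooled variants before statistical testing.

Four stages, applied in order: (1) drop low-QUAL variants; (2) keep
variants whose per-pool depth sits in a window around that pool's median
depth; (3) optionally keep only sites where both parents are homozygous for
different alleles; (4) drop sites where every pool shows only non-reference
reads (and, under a flag, the all-reference mirror image).

Depth medians are computed per grade on the table entering stage (2), i.e.
after the quality cut; the report records per-stage in/out counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .pool_io import GT_HOM_ALT, GT_HOM_REF, VariantTable

log = logging.getLogger(__name__)

__all__ = ["FilterConfig", "FilterReport", "filter_quality", "filter_depth",
           "filter_parent_informative", "filter_fixed_nonref", "run_filters"]


@dataclass(frozen=True)
class FilterConfig:
    """Settings for the four filter stages.

    min_qual: Phred-scaled QUAL floor (records with qual >= min_qual kept).
    depth_low_frac / depth_high_frac: closed per-pool depth window as
        fractions of the pool's median depth.
    require_parent_informative: True forces stage 3, False skips it, None
        applies it exactly when parent genotypes are attached.
    drop_all_alt: stage 4 as literally stated (all pools non-reference).
    drop_all_ref: also drop the all-reference mirror (off by default).
    """

    min_qual: float = 30.0
    depth_low_frac: float = 0.5
    depth_high_frac: float = 2.0
    require_parent_informative: Optional[bool] = None
    drop_all_alt: bool = True
    drop_all_ref: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.depth_low_frac < self.depth_high_frac):
            raise ValueError("need 0 < depth_low_frac < depth_high_frac")
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")


@dataclass
class FilterReport:
    stages: list = field(default_factory=list)  # (name, n_in, n_out)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if self.stages and n_in != self.stages[-1][2]:
            raise ValueError("stage input does not match previous stage output")
        if n_out > n_in:
            raise ValueError("a filter stage cannot add records")
        self.stages.append((name, n_in, n_out))

    @property
    def n_input(self) -> int:
        return self.stages[0][1] if self.stages else 0

    @property
    def n_output(self) -> int:
        return self.stages[-1][2] if self.stages else 0

    @property
    def retention(self) -> float:
        return self.n_output / self.n_input if self.n_input else float("nan")

    def to_tsv(self) -> str:
        lines = ["#stage\tn_in\tn_out"]
        lines += [f"{n}\t{i}\t{o}" for n, i, o in self.stages]
        return "\n".join(lines) + "\n"


def filter_quality(table: VariantTable, min_qual: float) -> VariantTable:
    """Stage 1: keep records with qual >= min_qual (NaN qual never passes
    a positive threshold)."""
    with np.errstate(invalid="ignore"):
        mask = table.qual >= min_qual
    return table.subset(mask, note=f"quality>={min_qual:g}")


def filter_depth(table: VariantTable, cfg: FilterConfig) -> VariantTable:
    """Stage 2: per-pool depth inside [low_frac, high_frac] x pool median.

    The window is closed on both ends; medians come from the input table.
    """
    if len(table) == 0:
        return table.subset(np.zeros(0, dtype=bool), note="depth")
    depth = table.depths
    med = np.median(depth, axis=0)
    if (med == 0).any():
        bad = [table.design.grades[j].sample for j in np.flatnonzero(med == 0)]
        raise ValueError(f"degenerate pool(s) with zero median depth: {bad}")
    lo = cfg.depth_low_frac * med
    hi = cfg.depth_high_frac * med
    mask = ((depth >= lo) & (depth <= hi)).all(axis=1)
    return table.subset(mask, note=f"depth in [{cfg.depth_low_frac},{cfg.depth_high_frac}]x median")


def filter_parent_informative(table: VariantTable) -> VariantTable:
    """Stage 3: both parents homozygous, for different alleles."""
    if table.parent_gt_high is None or table.parent_gt_low is None:
        raise ValueError(
            "no parent genotypes attached; disable the parent-informative stage "
            "(require_parent_informative=False) for parent-free runs"
        )
    ph, pl = table.parent_gt_high, table.parent_gt_low
    hom = np.isin(ph, (GT_HOM_REF, GT_HOM_ALT)) & np.isin(pl, (GT_HOM_REF, GT_HOM_ALT))
    mask = hom & (ph != pl)
    return table.subset(mask, note="parent-informative")


def filter_fixed_nonref(table: VariantTable, cfg: FilterConfig) -> VariantTable:
    """Stage 4: drop sites where every pool shows only non-reference reads;
    under drop_all_ref, also the all-reference mirror."""
    mask = np.ones(len(table), dtype=bool)
    if cfg.drop_all_alt:
        mask &= ~(table.ref_counts == 0).all(axis=1)
    if cfg.drop_all_ref:
        mask &= ~(table.alt_counts == 0).all(axis=1)
    return table.subset(mask, note="fixed-nonref")


def run_filters(table: VariantTable, cfg: Optional[FilterConfig] = None):
    """Apply stages (1)-(4) in order; returns (filtered table, FilterReport)."""
    cfg = cfg or FilterConfig()
    report = FilterReport()

    n0 = len(table)
    table = filter_quality(table, cfg.min_qual)
    report.add("quality", n0, len(table))

    n1 = len(table)
    if n1:
        table = filter_depth(table, cfg)
    report.add("depth", n1, len(table))

    want_parent = cfg.require_parent_informative
    if want_parent is None:
        want_parent = table.parent_gt_high is not None
    n2 = len(table)
    if want_parent:
        table = filter_parent_informative(table)
    report.add("parent_informative", n2, len(table))

    n3 = len(table)
    table = filter_fixed_nonref(table, cfg)
    report.add("fixed_nonref", n3, len(table))

    log.info("filters: %d -> %d variants (%.1f%% retained)",
             report.n_input, report.n_output, 100 * report.retention
             if report.n_input else float("nan"))
    return table, report
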