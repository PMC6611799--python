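"""Formats and containers: bulk designs, pooled variant tables, VCF and track I/O.

The pipeline consumes a multi-sample VCF (one sample per graded bulk, with
per-sample allele depths, optionally two parent samples) plus a small design
file binding sample names to ordinal grade indices.  Internally every site is
a biallelic SNP with a k-vector of (ref, alt) read-count pairs in grade
order.  Window coordinates are 0-based half-open internally and in BED
output; VCF/TSV positions stay 1-based.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

# parent genotype codes
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1


class DesignError(ValueError):
    """Invalid bulk design or design/VCF mismatch."""


@dataclass(frozen=True)
class GradeSpec:
    """One ordinal bulk: grade 1 is the highest phenotype class."""

    grade: int
    sample: str
    n_individuals: int


@dataclass(frozen=True)
class BulkDesign:
    """Ordered graded bulks plus optional parent sample names."""

    grades: tuple[GradeSpec, ...]
    parent_high: Optional[str] = None
    parent_low: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.grades) < 2:
            raise DesignError("a bulk design needs at least 2 grades")
        idx = [g.grade for g in self.grades]
        if idx != list(range(1, len(idx) + 1)):
            raise DesignError(
                f"grade indices must be 1..k strictly increasing, got {idx}"
            )
        names = [g.sample for g in self.grades]
        if len(set(names)) != len(names):
            raise DesignError(f"duplicate sample names in design: {names}")
        for g in self.grades:
            if g.n_individuals < 1:
                raise DesignError(f"grade {g.grade}: n_individuals must be >= 1")
        if (self.parent_high is None) != (self.parent_low is None):
            raise DesignError("name both parents or neither")

    @property
    def k(self) -> int:
        return len(self.grades)

    @property
    def sample_names(self) -> list[str]:
        return [g.sample for g in self.grades]

    @property
    def n_individuals(self) -> np.ndarray:
        return np.array([g.n_individuals for g in self.grades])

    @property
    def n_total(self) -> int:
        return int(self.n_individuals.sum())

    def bulk_shares(self) -> np.ndarray:
        """Fraction of the pooled population in each bulk."""
        n = self.n_individuals
        return n / n.sum()


@dataclass(frozen=True)
class PooledVariant:
    """A single biallelic SNP with per-grade (ref, alt) read counts."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    counts: tuple[tuple[int, int], ...]  # ((ref, alt), ...) in grade order
    qual: float = float("nan")
    parent_gt_high: int = GT_MISSING
    parent_gt_low: int = GT_MISSING

    @property
    def depths(self) -> tuple[int, ...]:
        return tuple(r + a for r, a in self.counts)


def _natural_key(chrom: str):
    return [int(p) if p.isdigit() else p for p in re.split(r"(\d+)", chrom)]


@dataclass
class VariantTable:
    """Columnar table of pooled variants, sorted by (chrom, pos), unique sites.

    ``ref_counts`` / ``alt_counts`` are (n_sites, k) integer arrays in grade
    order; parent genotype arrays use the GT_* codes and are None when the
    design names no parents.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    design: BulkDesign
    parent_gt_high: Optional[np.ndarray] = None
    parent_gt_low: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.pos)
        for name in ("chrom", "ref", "alt", "qual"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"column {name} length mismatch")
        if self.ref_counts.shape != (m, self.design.k):
            raise ValueError("ref_counts shape must be (n_sites, k)")
        if self.alt_counts.shape != (m, self.design.k):
            raise ValueError("alt_counts shape must be (n_sites, k)")
        order = sorted(range(m), key=lambda i: (_natural_key(str(self.chrom[i])), int(self.pos[i])))
        if order != list(range(m)):
            self._reorder(np.array(order, dtype=int))
        keys = list(zip(self.chrom.tolist(), self.pos.tolist()))
        if len(set(keys)) != m:
            raise ValueError("duplicate (chrom, pos) sites in table")

    def _reorder(self, idx: np.ndarray) -> None:
        for name in ("chrom", "pos", "ref", "alt", "qual", "ref_counts", "alt_counts",
                     "parent_gt_high", "parent_gt_low"):
            col = getattr(self, name)
            if col is not None:
                object.__setattr__(self, name, col[idx])

    def __len__(self) -> int:
        return len(self.pos)

    def __getitem__(self, i: int) -> PooledVariant:
        return PooledVariant(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref_allele=str(self.ref[i]),
            alt_allele=str(self.alt[i]),
            counts=tuple(
                (int(r), int(a))
                for r, a in zip(self.ref_counts[i], self.alt_counts[i])
            ),
            qual=float(self.qual[i]),
            parent_gt_high=int(self.parent_gt_high[i]) if self.parent_gt_high is not None else GT_MISSING,
            parent_gt_low=int(self.parent_gt_low[i]) if self.parent_gt_low is not None else GT_MISSING,
        )

    def __iter__(self) -> Iterator[PooledVariant]:
        return (self[i] for i in range(len(self)))

    @property
    def depths(self) -> np.ndarray:
        """(n_sites, k) total read depth per grade."""
        return self.ref_counts + self.alt_counts

    def subset(self, mask: np.ndarray, note: Optional[str] = None) -> "VariantTable":
        mask = np.asarray(mask)
        meta = dict(self.meta)
        if note:
            meta["filters_applied"] = list(meta.get("filters_applied", [])) + [note]
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            qual=self.qual[mask],
            ref_counts=self.ref_counts[mask],
            alt_counts=self.alt_counts[mask],
            design=self.design,
            parent_gt_high=None if self.parent_gt_high is None else self.parent_gt_high[mask],
            parent_gt_low=None if self.parent_gt_low is None else self.parent_gt_low[mask],
            meta=meta,
        )

    def to_dataframe(self):
        import pandas as pd

        d = {"chrom": self.chrom, "pos": self.pos, "ref": self.ref,
             "alt": self.alt, "qual": self.qual}
        for j, g in enumerate(self.design.grades):
            d[f"ref_{g.sample}"] = self.ref_counts[:, j]
            d[f"alt_{g.sample}"] = self.alt_counts[:, j]
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# bulk design file

def read_bulk_design(path) -> BulkDesign:
    """Parse a bulk-design file.

    Tab- or whitespace-separated table with header ``grade sample n``
    (column order free); optional directive lines ``#parent_high: NAME`` and
    ``#parent_low: NAME`` before the table.
    """
    path = Path(path)
    parent_high = parent_low = None
    rows: list[tuple[int, str, int]] = []
    header: Optional[list[str]] = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*parent_(high|low)\s*[:=]\s*(\S+)", line)
            if m:
                if m.group(1) == "high":
                    parent_high = m.group(2)
                else:
                    parent_low = m.group(2)
            continue
        fields = re.split(r"[\t ]+", line)
        if header is None:
            header = [f.lower() for f in fields]
            wanted = {"grade", "sample", "n"}
            if not wanted.issubset(header):
                raise DesignError(
                    f"design header must contain columns {sorted(wanted)}, got {header}"
                )
            continue
        rec = dict(zip(header, fields))
        rows.append((int(rec["grade"]), rec["sample"], int(rec["n"])))
    if header is None:
        raise DesignError(f"no design table found in {path}")
    seen = [g for g, _, _ in rows]
    if len(set(seen)) != len(seen):
        raise DesignError(f"duplicate grade indices in {path}: {seen}")
    rows.sort(key=lambda r: r[0])
    grades = tuple(GradeSpec(g, s, n) for g, s, n in rows)
    return BulkDesign(grades=grades, parent_high=parent_high, parent_low=parent_low)


def write_bulk_design(design: BulkDesign, path) -> None:
    lines = []
    if design.parent_high:
        lines.append(f"#parent_high: {design.parent_high}")
        lines.append(f"#parent_low: {design.parent_low}")
    lines.append("grade\tsample\tn")
    for g in design.grades:
        lines.append(f"{g.grade}\t{g.sample}\t{g.n_individuals}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF

def _gt_code(alleles: Sequence[int]) -> int:
    a = [x for x in alleles if x is not None and x >= 0]
    if len(a) < 2:
        return GT_MISSING
    if a[0] == a[1] == 0:
        return GT_HOM_REF
    if a[0] == a[1] == 1:
        return GT_HOM_ALT
    if set(a) == {0, 1}:
        return GT_HET
    return GT_MISSING


def read_pooled_vcf(path, design: BulkDesign, include_indels: bool = False) -> VariantTable:
    """Read a multi-sample VCF into a :class:`VariantTable`.

    Per-sample AD is the sole source of read counts; records lacking AD for
    any bulk sample are dropped and counted.  Multi-allelic records and (by
    default) indels are excluded and counted in ``meta``.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    needed = list(design.sample_names)
    if design.parent_high:
        needed += [design.parent_high, design.parent_low]
    missing = [s for s in needed if s not in samples]
    if missing:
        raise DesignError(
            f"design sample(s) {missing} not present in VCF {path}; VCF has {samples}"
        )
    bulk_idx = [samples.index(s) for s in design.sample_names]
    ph_idx = samples.index(design.parent_high) if design.parent_high else None
    pl_idx = samples.index(design.parent_low) if design.parent_low else None

    chrom, pos, ref, alt, qual = [], [], [], [], []
    refc, altc, gth, gtl = [], [], [], []
    counters = {"n_records": 0, "n_multiallelic": 0, "n_non_snp": 0, "n_missing_ad": 0}
    for v in vcf:
        counters["n_records"] += 1
        if len(v.ALT) != 1:
            counters["n_multiallelic"] += 1
            continue
        if not include_indels and not (len(v.REF) == 1 and len(v.ALT[0]) == 1):
            counters["n_non_snp"] += 1
            continue
        ad = v.format("AD")
        if ad is None:
            counters["n_missing_ad"] += 1
            continue
        sub = ad[bulk_idx]
        if sub.shape[1] < 2 or (sub[:, :2] < 0).any():
            counters["n_missing_ad"] += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        refc.append(sub[:, 0])
        altc.append(sub[:, 1])
        if ph_idx is not None:
            g = v.genotypes
            gth.append(_gt_code(g[ph_idx][:2]))
            gtl.append(_gt_code(g[pl_idx][:2]))
    if counters["n_missing_ad"]:
        log.warning("%d records dropped for missing AD", counters["n_missing_ad"])
    m = len(pos)
    meta = {"source": path, **counters, "filters_applied": []}
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qual=np.array(qual, dtype=float),
        ref_counts=np.array(refc, dtype=np.int64).reshape(m, design.k),
        alt_counts=np.array(altc, dtype=np.int64).reshape(m, design.k),
        design=design,
        parent_gt_high=np.array(gth, dtype=np.int8) if ph_idx is not None else None,
        parent_gt_low=np.array(gtl, dtype=np.int8) if ph_idx is not None else None,
        meta=meta,
    )


_GT_STR = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", GT_MISSING: "./."}


def write_pooled_vcf(table: VariantTable, path, contig_lengths: Optional[dict] = None) -> None:
    """Write a VariantTable as a minimal VCF 4.2 with per-bulk AD.

    Bulk samples carry ``GT:AD`` with GT ./. (pools have no single genotype);
    parent samples, when the design names them, carry their genotype codes.
    """
    design = table.design
    chroms = []
    for c in table.chrom:
        if c not in chroms:
            chroms.append(c)
    if contig_lengths is None:
        contig_lengths = table.meta.get("contig_lengths", {})
    lines = ["##fileformat=VCFv4.2", "##source=gradedpool"]
    depths = table.depths
    for c in chroms:
        ln = contig_lengths.get(c)
        if ln is None:
            ln = int(table.pos[table.chrom == c].max()) + 1
        lines.append(f"##contig=<ID={c},length={ln}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    samples = list(design.sample_names)
    has_parents = design.parent_high is not None and table.parent_gt_high is not None
    if has_parents:
        samples += [design.parent_high, design.parent_low]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for i in range(len(table)):
        q = table.qual[i]
        qs = "." if np.isnan(q) else f"{q:g}"
        cells = [
            f"./.:{table.ref_counts[i, j]},{table.alt_counts[i, j]}"
            for j in range(design.k)
        ]
        if has_parents:
            # parents get a token AD consistent with their genotype
            for code in (table.parent_gt_high[i], table.parent_gt_low[i]):
                gt = _GT_STR[int(code)]
                ad = {GT_HOM_REF: "20,0", GT_HOM_ALT: "0,20",
                      GT_HET: "10,10", GT_MISSING: "."}[int(code)]
                cells.append(f"{gt}:{ad}")
        lines.append(
            f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t{table.alt[i]}"
            f"\t{qs}\tPASS\t.\tGT:AD\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# track output

def write_tracks(pvals, ratios, intervals, out_prefix) -> dict:
    """Write per-SNP TSV, per-window BED and interval BED files.

    TSV keeps 1-based SNP positions; both BEDs are 0-based half-open with the
    window/interval ratio as score.  Returns the paths written.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    snp_path = out_prefix.with_name(out_prefix.name + ".snps.tsv")
    win_path = out_prefix.with_name(out_prefix.name + ".windows.bed")
    int_path = out_prefix.with_name(out_prefix.name + ".intervals.bed")

    with open(snp_path, "w") as fh:
        fh.write("#chrom\tpos\ttest\tstatistic\tp\tneg_ln_p\n")
        nlp = pvals.neg_log_p
        for i in range(len(pvals.pos)):
            fh.write(
                f"{pvals.chrom[i]}\t{pvals.pos[i]}\t{pvals.method}\t"
                f"{pvals.statistic[i]:.6g}\t{pvals.p[i]:.6g}\t{nlp[i]:.6g}\n"
            )
    with open(win_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tratio\tn_snps\tn_significant\tskipped\n")
        for rec in ratios.df.itertuples(index=False):
            ratio = "." if rec.skipped else f"{rec.ratio:.6g}"
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{ratio}\t"
                f"{rec.n_snps}\t{rec.n_significant}\t{int(rec.skipped)}\n"
            )
    with open(int_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tpeak_ratio\tn_snps\trank\n")
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.peak_ratio:.6g}\t"
                f"{iv.n_snps}\t{iv.rank}\n"
            )
    return {"snps": snp_path, "windows": win_path, "intervals": int_path}
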