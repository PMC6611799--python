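import numpy as np
import pytest
from hypothesis import settings

from gradedpool.pool_io import (
    GT_HET, GT_HOM_ALT, GT_HOM_REF, BulkDesign, GradeSpec, VariantTable,
)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def design3():
    """Three graded bulks mirroring a real grain-weight pool design."""
    return BulkDesign(grades=(
        GradeSpec(1, "G1", 351), GradeSpec(2, "G2", 348), GradeSpec(3, "G3", 347),
    ))


@pytest.fixture
def design3_parents():
    return BulkDesign(
        grades=(GradeSpec(1, "G1", 100), GradeSpec(2, "G2", 100), GradeSpec(3, "G3", 100)),
        parent_high="PH", parent_low="PL",
    )


def make_table(design, records, parents=None):
    """Build a VariantTable from (chrom, pos, qual, [(ref, alt), ...]) tuples."""
    m = len(records)
    k = design.k
    chrom = np.array([r[0] for r in records], dtype=object)
    pos = np.array([r[1] for r in records], dtype=np.int64)
    qual = np.array([r[2] for r in records], dtype=float)
    ref_counts = np.array([[c[0] for c in r[3]] for r in records], dtype=np.int64).reshape(m, k)
    alt_counts = np.array([[c[1] for c in r[3]] for r in records], dtype=np.int64).reshape(m, k)
    kw = {}
    if parents is not None:
        kw["parent_gt_high"] = np.array([p[0] for p in parents], dtype=np.int8)
        kw["parent_gt_low"] = np.array([p[1] for p in parents], dtype=np.int8)
    return VariantTable(
        chrom=chrom, pos=pos,
        ref=np.full(m, "A", dtype=object), alt=np.full(m, "G", dtype=object),
        qual=qual, ref_counts=ref_counts, alt_counts=alt_counts,
        design=design, meta={"filters_applied": []}, **kw,
    )


@pytest.fixture
def ten_record_table(design3_parents):
    """Hand-enumerable 10-record fixture exercising every filter stage.

    Stage-by-stage survivors (hand count):
      quality (min_qual 30): drops #2 (qual 10)            -> 9
      depth [0.5, 2] x per-pool median: drops #3 (depth 40 in pool 1,
        median 100) and #4 (depth 250 in pool 2, median 100) -> 7
      parent-informative: drops #5 (het parent) and #6 (identical
        homozygous parents)                                  -> 5
      fixed non-reference: drops #7 (all pools ref_reads 0)  -> 4
    Survivors: records 1, 8, 9, 10.
    """
    base = [(50, 50), (50, 50), (50, 50)]
    recs = [
        ("chr1", 1_000, 50.0, base),                                   # 1 keep
        ("chr1", 2_000, 10.0, base),                                   # 2 quality
        ("chr1", 3_000, 50.0, [(20, 20), (50, 50), (50, 50)]),         # 3 low depth
        ("chr1", 4_000, 50.0, [(50, 50), (150, 100), (50, 50)]),       # 4 high depth
        ("chr1", 5_000, 50.0, base),                                   # 5 het parent
        ("chr1", 6_000, 50.0, base),                                   # 6 same parents
        ("chr1", 7_000, 50.0, [(0, 100), (0, 100), (0, 100)]),         # 7 all-alt
        ("chr1", 8_000, 50.0, [(30, 70), (50, 50), (70, 30)]),         # 8 keep
        ("chr2", 1_000, 30.0, base),                                   # 9 keep (boundary qual)
        ("chr2", 2_000, 50.0, [(100, 0), (100, 0), (100, 0)]),         # 10 keep (all-ref ok)
    ]
    parents = [(GT_HOM_ALT, GT_HOM_REF)] * 10
    parents[4] = (GT_HET, GT_HOM_REF)
    parents[5] = (GT_HOM_REF, GT_HOM_REF)
    return make_table(design3_parents, recs, parents=parents)
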