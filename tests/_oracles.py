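"""Independent brute-force oracles used by the test suite.

These deliberately take the slow, literal route (expanding grouped counts
into individual observations and ranking them with scipy) so that they
share no code path with the grouped-count implementations they check.
"""

import numpy as np
from scipy.stats import norm, rankdata


def expand_table(ref_counts, alt_counts):
    """Expand a 2 x k table into per-observation (grade value, allele group)."""
    vals, grp = [], []
    for j, (r, a) in enumerate(zip(ref_counts, alt_counts)):
        vals += [j] * (r + a)
        grp += [0] * r + [1] * a
    return np.asarray(vals), np.asarray(grp)


def ranksum_z(ref_counts, alt_counts):
    """Tie-corrected normal-approximation Wilcoxon rank-sum z of the
    reference-allele group, computed on the expanded observations."""
    vals, grp = expand_table(ref_counts, alt_counts)
    n = len(vals)
    n1 = int((grp == 0).sum())
    n2 = n - n1
    ranks = rankdata(vals)
    w1 = ranks[grp == 0].sum()
    expect = n1 * (n + 1) / 2.0
    _, t = np.unique(vals, return_counts=True)
    var = n1 * n2 / 12.0 * ((n + 1) - (t ** 3 - t).sum() / (n * (n - 1)))
    return (w1 - expect) / np.sqrt(var)


def ranksum_p(ref_counts, alt_counts):
    z = ranksum_z(ref_counts, alt_counts)
    return 2.0 * norm.sf(abs(z))


def permutation_p(ref_counts, alt_counts, n_perm, rng):
    """Two-sided Monte-Carlo permutation p of the mean-ridit (rank-sum)
    difference between the two allele rows."""
    vals, grp = expand_table(ref_counts, alt_counts)
    n = len(vals)
    n1 = int((grp == 0).sum())
    ranks = rankdata(vals)
    expect = n1 * (n + 1) / 2.0
    obs = abs(ranks[grp == 0].sum() - expect)
    keys = rng.random((n_perm, n))
    idx = np.argsort(keys, axis=1)[:, :n1]
    w1 = ranks[idx].sum(axis=1)
    # add-one rule keeps the Monte-Carlo p valid (never exactly 0)
    return (1 + (np.abs(w1 - expect) >= obs - 1e-9).sum()) / (n_perm + 1)


def random_table(rng, max_k=6, max_count=60):
    """A random 2 x k table with both allele rows non-empty."""
    while True:
        k = int(rng.integers(2, max_k + 1))
        ref = rng.integers(0, max_count + 1, size=k)
        alt = rng.integers(0, max_count + 1, size=k)
        if ref.sum() > 0 and alt.sum() > 0 and (ref + alt).sum() > 1:
            return ref, alt
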