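"""Naive reference implementations used to validate the pipeline.

These are deliberately independent of the production code paths: counting
by a per-site membership scan, the pooled-variance t-test from its closed
form, and a permutation test.  They trade speed for transparency and are
meant for small validation instances.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import t as t_dist

from .models import GeneModel


def brute_force_counts(sites, genes: list[GeneModel]) -> dict[str, tuple[int, int]]:
    """Per-gene (transposon count, read count) by scanning every site
    against every gene interval."""
    out = {g.gene_id: [0, 0] for g in genes}
    for s in sites:
        for g in genes:
            if s.chrom == g.chrom and g.start <= s.pos < g.end:
                out[g.gene_id][0] += 1
                out[g.gene_id][1] += s.reads
    return {k: (v[0], v[1]) for k, v in out.items()}


def pooled_ttest(a, b) -> tuple[float, float]:
    """Two-sided equal-variance two-sample t-test from the closed form:
    t = (mean_a - mean_b) / sqrt(s_p^2 (1/n_a + 1/n_b)), df = n_a + n_b - 2,
    s_p^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("pooled t-test requires n >= 2 in both samples")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    tstat = (a.mean() - b.mean()) / se
    p = 2.0 * t_dist.sf(abs(tstat), df)
    return float(tstat), float(p)


def permutation_pvalue(a, b, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p-value for a difference in means (with the
    +1 correction so p is never 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na = len(a)
    obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
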