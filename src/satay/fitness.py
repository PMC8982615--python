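"""Depth normalization and library-set fitness comparisons.

The fitness readout of a SATAY screen is the number of transposons (and
supporting reads) each gene tolerates after ~13-15 growth cycles of
selection.  Counts are made comparable across libraries by normalizing to
the total number of transposons/reads mapped per library (expressed here
per 10^6 mapped events).  A "volcano" comparison contrasts the mean
normalized count of a test library set against a reference set gene by
gene: log2 fold change plus a two-sided Student's (pooled-variance)
two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import GeneCountMatrix, LibraryMeta

SCALE = 1e6

#: Volcano classification labels.
REQUIRED = "required"
DISPENSABLE = "dispensable"
NEUTRAL = "neutral"
UNTESTABLE = "untestable"


@dataclass
class NormalizedMatrix:
    """Gene x library matrix of depth-normalized counts (per 10^6 mapped).

    ``pseudocount`` raw counts were added per gene per library before
    normalization; with pseudocount 0 each column sums to 10^6 times the
    genic fraction of mapped events.
    """

    values: pd.DataFrame
    source: str
    pseudocount: float
    libraries: list[LibraryMeta]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return [m.library for m in self.libraries]

    def meta_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([m.to_dict() for m in self.libraries]).set_index("library")
        df["group_tags"] = [frozenset(t) for t in df["group_tags"]]
        return df


def normalize(matrix: GeneCountMatrix, source: str = "tn",
              pseudocount: float = 1.0) -> NormalizedMatrix:
    """Normalize counts to the per-library total of mapped events.

    value[g, l] = (count[g, l] + pseudocount) / (total[l] + pseudocount * G) * 10^6
    where G is the number of genes.  Totals include intergenic events.
    """
    counts = matrix.counts(source)
    totals = matrix.totals(source)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero mapped-event total for libraries: {list(zero.index)}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    G = counts.shape[0]
    values = (counts + pseudocount).div(totals + pseudocount * G, axis=1) * SCALE
    return NormalizedMatrix(values=values, source=source,
                            pseudocount=pseudocount, libraries=list(matrix.libraries))


def _pooled_ttest(a: np.ndarray, b: np.ndarray, equal_var: bool = True) -> np.ndarray:
    """Row-wise two-sided two-sample t-test p-values with the volcano
    degenerate-case contract: p undefined (NaN) when either set has n < 2,
    or when both sets have zero variance with unequal means; p = 1 when
    both sets are constant at the same value."""
    n1, n2 = a.shape[1], b.shape[1]
    p = np.full(a.shape[0], np.nan)
    if n1 < 2 or n2 < 2:
        return p
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a scipy precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    both_const = (v1 == 0) & (v2 == 0)
    same_mean = np.isclose(a.mean(axis=1), b.mean(axis=1), rtol=0, atol=0)
    p[both_const & same_mean] = 1.0
    p[both_const & ~same_mean] = np.nan
    return p


def compare_sets(norm: NormalizedMatrix, test_ids: Sequence[str],
                 ref_ids: Sequence[str], welch: bool = False) -> pd.DataFrame:
    """Per-gene volcano comparison of a test library set vs a reference set.

    Returns a DataFrame indexed by gene with columns mean_test, mean_ref,
    log2fc, p_value, bh_fdr, n_test, n_ref.  The fold change is the mean of
    the test set divided by that of the reference set; p-values come from a
    two-sided Student's (equal-variance) t-test — Welch's unequal-variance
    form behind the ``welch`` flag — and are NaN (undefined) when either
    set has fewer than two libraries.
    """
    test_ids, ref_ids = list(test_ids), list(ref_ids)
    if not test_ids or not ref_ids:
        raise ValueError("test and reference sets must be non-empty")
    overlap = set(test_ids) & set(ref_ids)
    if overlap:
        raise ValueError(f"test and reference sets overlap: {sorted(overlap)}")
    known = set(norm.library_ids)
    unknown = (set(test_ids) | set(ref_ids)) - known
    if unknown:
        raise ValueError(f"unknown library ids: {sorted(unknown)}")

    a = norm.values[test_ids].to_numpy(dtype=float)
    b = norm.values[ref_ids].to_numpy(dtype=float)
    mean_test = a.mean(axis=1)
    mean_ref = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_test / mean_ref)
    p = _pooled_ttest(a, b, equal_var=not welch)

    bh = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        bh[ok] = multipletests(p[ok], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "mean_test": mean_test,
            "mean_ref": mean_ref,
            "log2fc": log2fc,
            "p_value": p,
            "bh_fdr": bh,
            "n_test": len(test_ids),
            "n_ref": len(ref_ids),
        },
        index=norm.values.index,
    )


def classify_volcano(records: pd.DataFrame, fc_cut: float = -0.5,
                     p_cut: float = 0.05,
                     dispensable_cut: float = 2.0) -> pd.DataFrame:
    """Attach a class_label column: required / dispensable / neutral /
    untestable.  Defaults follow the screen's volcano thresholds
    (p < 0.05 with log2FC < -0.5 for required, log2FC > 2 for dispensable);
    genes with undefined p-values are untestable."""
    out = records.copy()
    p = out["p_value"].to_numpy()
    fc = out["log2fc"].to_numpy()
    label = np.full(len(out), NEUTRAL, dtype=object)
    sig = np.isfinite(p) & (p < p_cut)
    label[sig & (fc < fc_cut)] = REQUIRED
    label[sig & (fc > dispensable_cut)] = DISPENSABLE
    label[~np.isfinite(p)] = UNTESTABLE
    out["class_label"] = label
    return out


def relative_to_gene_mean(norm: NormalizedMatrix) -> pd.DataFrame:
    """log2 of each gene's normalized count relative to its mean across
    libraries (the heatmap transform).  Requires strictly positive gene
    means, which a pseudocount > 0 guarantees."""
    means = norm.values.mean(axis=1)
    if (means <= 0).any():
        bad = list(means.index[means <= 0][:5])
        raise ValueError(
            f"zero gene mean (use a pseudocount > 0); first offenders: {bad}"
        )
    return np.log2(norm.values.div(means, axis=0))


def sem(values) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("sem requires a 1-D sample with n >= 2")
    return float(arr.std(ddof=1) / np.sqrt(arr.size))
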