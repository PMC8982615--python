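"""Library clustering and gene co-essentiality profiles.

Ward-clusters the 24 libraries of the simulated screen on normalized
transposon counts, then builds the gene-gene Pearson correlation
clusterogram over the most variable genes and checks that the planted
conditionally essential genes cluster away from the neutral background.
Writes dendrograms (Newick), leaf orders, the heatmap matrix, and the
reordered correlation matrix under results/profiles/.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from satay.fitness import normalize, relative_to_gene_mean
from satay.insertion_io import read_count_matrix
from satay.profiles import (
    cluster_correlation,
    cluster_libraries,
    gene_correlation,
    select_variable_genes,
)
from satay.synthetic import CONDITIONAL, EssentialityTruth

ROOT = Path(__file__).resolve().parents[1]
SCREEN = ROOT / "results" / "screen"
OUT = ROOT / "results" / "profiles"
TOP_K = 100


def main() -> None:
    counts = read_count_matrix(SCREEN / "counts.tsv")
    truth = EssentialityTruth.from_tsv(SCREEN / "truth.tsv")
    norm = normalize(counts, source="tn", pseudocount=1.0)

    OUT.mkdir(parents=True, exist_ok=True)
    lib_dend = cluster_libraries(norm)
    (OUT / "libraries.nwk").write_text(lib_dend.to_newick() + "\n")
    heat = relative_to_gene_mean(norm)
    heat.index.name = "gene_id"
    heat.to_csv(OUT / "heatmap_log2_rel_gene_mean.tsv", sep="\t",
                float_format="%.6g", lineterminator="\n")

    # Libraries sharing the planted conditional essentiality (the three
    # depleted OFF conditions) have correlated insertion profiles and
    # should form a contiguous block; all-neutral libraries are
    # exchangeable sampling noise and carry no clusterable signal.
    order = lib_dend.leaf_order
    pos = {lib: i for i, lib in enumerate(order)}
    depleted_conds = [c for c in truth.states.columns
                      if (truth.states[c] == CONDITIONAL).any()]
    depleted_libs = [m.library for m in counts.libraries
                     if m.condition in depleted_conds]
    span = max(pos[l] for l in depleted_libs) - min(pos[l] for l in depleted_libs)
    print(f"library clustering: the {len(depleted_libs)} libraries sharing the "
          f"planted depletion span {span + 1} adjacent leaves "
          f"(contiguous block = {span == len(depleted_libs) - 1})")

    var = select_variable_genes(norm, TOP_K)
    corr = gene_correlation(norm, var)
    dend, reordered = cluster_correlation(corr)
    reordered.index.name = "gene_id"
    reordered.to_csv(OUT / "correlation.tsv", sep="\t", float_format="%.6g",
                     lineterminator="\n")
    (OUT / "genes.nwk").write_text(dend.to_newick() + "\n")

    planted = set(truth.states.index[(truth.states == CONDITIONAL).any(axis=1)])
    in_top = planted & set(var.gene_ids)
    sub = corr.r.loc[sorted(in_top), sorted(in_top)].to_numpy()
    mean_within = float(np.nanmean(sub[np.triu_indices(len(sub), k=1)]))
    print(f"variable-gene set (k={TOP_K}) contains {len(in_top)}/{len(planted)} "
          f"planted conditional genes")
    print(f"mean pairwise r among planted genes: {mean_within:.3f} "
          f"(shared essentiality pattern -> strong co-essentiality)")
    print(f"wrote dendrograms, heatmap, correlation -> {OUT}")


if __name__ == "__main__":
    main()
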