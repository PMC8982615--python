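"""Simulate the rewired-lipid-synthesis transposon screen.

Generates the study design — 12 rewired genotypes (Psd target x Pmt
target) grown in Kennedy ON and OFF, 24 libraries — over a 1000-gene
synthetic genome at 1e5 insertions per library, with 50 genes made
conditionally essential (depletion 0.05) in three Kennedy-OFF conditions.
Writes the count matrix, annotation, and ground truth under
results/screen/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from satay.insertion_io import write_count_matrix, write_gff3
from satay.synthetic import (
    CONDITIONAL,
    EssentialityTruth,
    SimulationConfig,
    default_design,
    simulate_experiment,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "screen"
SEED = 1
N_GENES = 1000
N_CONDITIONAL = 50
DEPLETION = 0.05


def main() -> None:
    cfg = SimulationConfig(n_genes=N_GENES, insertions_per_library=100_000,
                           seed=SEED)
    design = default_design()
    conds = sorted({m.condition for m in design})
    gene_ids = [f"G{i + 1:05d}" for i in range(N_GENES)]
    truth = EssentialityTruth.neutral(gene_ids, conds)
    off_conds = sorted({m.condition for m in design if m.kennedy == "OFF"})[:3]
    truth.set_state(gene_ids[:N_CONDITIONAL], off_conds, CONDITIONAL, DEPLETION)

    screen = simulate_experiment(cfg, truth=truth, design=design)
    OUT.mkdir(parents=True, exist_ok=True)
    write_count_matrix(screen.counts, OUT / "counts.tsv")
    write_gff3(screen.genes, OUT / "annotation.gff3", screen.chrom_lengths)
    truth.to_tsv(OUT / "truth.tsv")

    totals = screen.counts.totals_tn
    print(f"simulated {len(design)} libraries x {N_GENES} genes (seed {SEED})")
    print(f"retained insertions/library: {totals.min()}-{totals.max()} "
          f"(target 100000 before selection)")
    print(f"{N_CONDITIONAL} genes conditionally essential in: {off_conds}")
    print(f"wrote counts, annotation, truth -> {OUT}")


if __name__ == "__main__":
    main()
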