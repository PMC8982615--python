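"""Volcano comparison: Kennedy OFF vs ON in the depleted genotypes.

Loads the screen from 01, compares the three OFF libraries carrying the
planted conditional essentiality against their ON partners (3 vs 3), and
scores recovery of the ground truth at the default thresholds
(p < 0.05, log2FC < -0.5).  Writes the volcano table and a confusion
summary under results/volcano/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from satay.fitness import REQUIRED, classify_volcano, compare_sets, normalize
from satay.insertion_io import read_count_matrix
from satay.synthetic import CONDITIONAL, EssentialityTruth

ROOT = Path(__file__).resolve().parents[1]
SCREEN = ROOT / "results" / "screen"
OUT = ROOT / "results" / "volcano"


def main() -> None:
    counts = read_count_matrix(SCREEN / "counts.tsv")
    truth = EssentialityTruth.from_tsv(SCREEN / "truth.tsv")

    off_conds = [c for c in truth.states.columns
                 if (truth.states[c] == CONDITIONAL).any()]
    test = [m.library for m in counts.libraries if m.condition in off_conds]
    genotypes = {(m.psd_target, m.pmt_target) for m in counts.libraries
                 if m.condition in off_conds}
    ref = [m.library for m in counts.libraries
           if m.kennedy == "ON" and (m.psd_target, m.pmt_target) in genotypes]

    norm = normalize(counts, source="tn", pseudocount=1.0)
    records = classify_volcano(compare_sets(norm, test, ref))

    truly = set(truth.states.index[(truth.states[off_conds] == CONDITIONAL).any(axis=1)])
    called = set(records.index[records["class_label"] == REQUIRED])
    neutral = set(records.index) - truly
    sensitivity = len(called & truly) / len(truly)
    fpr = len(called & neutral) / len(neutral)

    OUT.mkdir(parents=True, exist_ok=True)
    out = records.reset_index(names="gene_id")
    out["truly_conditional"] = out["gene_id"].isin(truly)
    out.to_csv(OUT / "kennedy_off_vs_on.tsv", sep="\t", index=False,
               float_format="%.10g", lineterminator="\n")

    print(f"compared {len(test)} OFF vs {len(ref)} ON libraries "
          f"({len(records)} genes)")
    print(f"'required' calls: {len(called)}; planted conditional genes: {len(truly)}")
    print(f"sensitivity = {sensitivity:.3f}, neutral-gene FPR = {fpr:.4f}")
    print(f"wrote volcano table -> {OUT / 'kennedy_off_vs_on.tsv'}")


if __name__ == "__main__":
    main()
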