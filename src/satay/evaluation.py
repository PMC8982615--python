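"""End-to-end validation experiments on synthetic ground truth.

Each function here runs one self-contained experiment through the public
pipeline — generate inputs with known truth, execute the stage under
study, measure recovery — and returns plain numbers.  They back both the
test suite and the reproduction script.
"""

from __future__ import annotations

import filecmp
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .fitness import REQUIRED, classify_volcano, compare_sets, normalize
from .insertion_io import count_per_gene
from .lipidomics import flux_ratios, saturation_fractions
from .models import GeneModel, InsertionSite, LibraryMeta
from .profiles import cluster_correlation, gene_correlation, select_variable_genes
from .reference import brute_force_counts, permutation_pvalue, pooled_ttest
from .synthetic import (
    CONDITIONAL,
    EssentialityTruth,
    LabelingParams,
    LipidomeParams,
    SimulationConfig,
    default_design,
    simulate_experiment,
    simulate_labeling,
    simulate_lipidome,
)


# ---------------------------------------------------------------------------
# Counting vs brute force
# ---------------------------------------------------------------------------

def random_counting_instance(rng: np.random.Generator):
    """One random genome (possibly overlapping genes, multiple chromosomes)
    plus random sites, for exact counting validation."""
    n_chrom = rng.integers(1, 4)
    chroms = [f"c{i}" for i in range(n_chrom)]
    n_genes = int(rng.integers(1, 51))
    genes = []
    for i in range(n_genes):
        chrom = chroms[rng.integers(0, n_chrom)]
        start = int(rng.integers(0, 5000))
        end = start + int(rng.integers(1, 800))
        genes.append(GeneModel(gene_id=f"g{i}", chrom=chrom, start=start, end=end))
    n_sites = int(rng.integers(1, 10_001))
    libs = [f"L{i}" for i in range(int(rng.integers(1, 4)))]
    sites = [
        InsertionSite(
            chrom=chroms[rng.integers(0, n_chrom)],
            pos=int(rng.integers(0, 6000)),
            strand="+" if rng.random() < 0.5 else "-",
            reads=int(rng.integers(0, 50)),
            library=libs[rng.integers(0, len(libs))],
        )
        for _ in range(n_sites)
    ]
    return sites, genes, libs


def counting_oracle_check(n_instances: int = 100, seed: int = 0) -> dict:
    """Fraction of random instances where pipeline counting agrees exactly
    with the brute-force per-site membership scan."""
    rng = np.random.default_rng([seed, 11])
    agree = 0
    for _ in range(n_instances):
        sites, genes, libs = random_counting_instance(rng)
        matrix = count_per_gene(sites, genes,
                                libraries=[LibraryMeta(library=lb) for lb in libs])
        ok = True
        for lib in libs:
            lib_sites = [s for s in sites if s.library == lib]
            # merge duplicates the way the counting contract does
            merged: dict[tuple, int] = {}
            for s in lib_sites:
                merged[(s.chrom, s.pos, s.strand)] = merged.get(
                    (s.chrom, s.pos, s.strand), 0) + s.reads
            merged_sites = [
                InsertionSite(chrom=c, pos=p, strand=st, reads=r, library=lib)
                for (c, p, st), r in merged.items()
            ]
            expect = brute_force_counts(merged_sites, genes)
            for g in genes:
                tn, rd = expect[g.gene_id]
                if (matrix.tn.at[g.gene_id, lib] != tn
                        or matrix.reads.at[g.gene_id, lib] != rd):
                    ok = False
            if matrix.totals_tn[lib] != len(merged_sites):
                ok = False
            if matrix.totals_reads[lib] != sum(s.reads for s in merged_sites):
                ok = False
        agree += ok
    return {"agreement_fraction": agree / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# t-test dual route
# ---------------------------------------------------------------------------

def ttest_oracle_check(n_closed: int = 1000, n_perm_instances: int = 100,
                       n_perm: int = 4000, seed: int = 0) -> dict:
    """Volcano p-values vs the closed-form pooled t (max |diff|) and rank
    agreement (Spearman rho) with a permutation oracle."""
    rng = np.random.default_rng([seed, 22])
    max_diff = 0.0
    for _ in range(n_closed):
        n1 = int(rng.integers(2, 8))
        n2 = int(rng.integers(2, 8))
        a = rng.normal(rng.normal(0, 2), 1 + rng.random(), size=n1)
        b = rng.normal(0, 1 + rng.random(), size=n2)
        values = pd.DataFrame(
            np.concatenate([a, b])[None, :],
            index=["g"],
            columns=[f"t{i}" for i in range(n1)] + [f"r{i}" for i in range(n2)],
        )
        norm = _norm_from_values(values)
        rec = compare_sets(norm, [f"t{i}" for i in range(n1)],
                           [f"r{i}" for i in range(n2)])
        _, p_ref = pooled_ttest(a, b)
        max_diff = max(max_diff, abs(float(rec["p_value"].iloc[0]) - p_ref))

    # Instances span effect sizes from null to moderate so p-values cover a
    # wide range while staying above the permutation resolution floor of
    # 1/(n_perm + 1); beyond that floor all strong effects tie and rank
    # agreement is no longer informative.
    p_t, p_perm = [], []
    for _ in range(n_perm_instances):
        shift = rng.uniform(-1.5, 1.5)
        a = rng.normal(shift, 1, size=6)
        b = rng.normal(0, 1, size=6)
        _, p = pooled_ttest(a, b)
        p_t.append(p)
        p_perm.append(permutation_pvalue(a, b, n_perm, rng))
    rho = float(spearmanr(p_t, p_perm).statistic)
    return {"max_abs_p_diff": float(max_diff), "spearman_rho": rho,
            "n_closed": n_closed, "n_perm": n_perm_instances}


def _norm_from_values(values: pd.DataFrame):
    """Wrap a plain value matrix as a NormalizedMatrix (for direct tests
    of the comparison stage)."""
    from .fitness import NormalizedMatrix

    libs = [LibraryMeta(library=c) for c in values.columns]
    return NormalizedMatrix(values=values, source="tn", pseudocount=0.0,
                            libraries=libs)


# ---------------------------------------------------------------------------
# Depth invariance
# ---------------------------------------------------------------------------

def depth_invariance_check(seed: int = 0) -> dict:
    """Scale one library's counts and totals by c in {0.1, 10}: maximum
    deviation of normalized values, log2fc, and p-values (pseudocount 0)."""
    cfg = SimulationConfig(n_genes=150, insertions_per_library=20_000, seed=seed)
    design = default_design()[:6]
    screen = simulate_experiment(cfg, design=design)
    libs = screen.counts.library_ids
    test, ref = libs[:3], libs[3:]
    base_norm = normalize(screen.counts, pseudocount=0.0)
    base = compare_sets(base_norm, test, ref)
    worst = 0.0
    for c in (0.1, 10.0):
        counts = screen.counts
        scaled_tn = counts.tn.astype(float).copy()
        scaled_tn[libs[0]] *= c
        totals = counts.totals_tn.astype(float).copy()
        totals[libs[0]] *= c
        values = scaled_tn.div(totals, axis=1) * 1e6
        norm = _norm_from_values(values)
        rec = compare_sets(norm, test, ref)
        worst = max(
            worst,
            float(np.nanmax(np.abs(values - base_norm.values))),
            float(np.nanmax(np.abs(rec["log2fc"] - base["log2fc"]))),
            float(np.nanmax(np.abs(rec["p_value"] - base["p_value"]))),
        )
    return {"max_abs_deviation": worst, "n": len(base)}


# ---------------------------------------------------------------------------
# Conditional-essentiality recovery (the headline simulation)
# ---------------------------------------------------------------------------

def conditional_recovery_check(seed: int = 1, n_genes: int = 1000,
                               insertions: int = 100_000,
                               n_conditional: int = 50,
                               depletion: float = 0.05) -> dict:
    """12 genotypes x Kennedy ON/OFF; conditional genes depleted in 3 OFF
    conditions; volcano of those 3 OFF libraries vs their 3 ON partners at
    default thresholds.  Returns sensitivity and neutral-gene FPR."""
    cfg = SimulationConfig(n_genes=n_genes, insertions_per_library=insertions,
                           seed=seed)
    design = default_design()
    conds = sorted({m.condition for m in design})
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    truth = EssentialityTruth.neutral(gene_ids, conds)
    off_conds = sorted({m.condition for m in design if m.kennedy == "OFF"})[:3]
    cond_genes = gene_ids[:n_conditional]
    truth.set_state(cond_genes, off_conds, CONDITIONAL, depletion)

    screen = simulate_experiment(cfg, truth=truth, design=design)
    norm = normalize(screen.counts)
    test = [m.library for m in design if m.condition in off_conds]
    genotypes = {(m.psd_target, m.pmt_target) for m in design if m.condition in off_conds}
    ref = [m.library for m in design
           if m.kennedy == "ON" and (m.psd_target, m.pmt_target) in genotypes]
    records = classify_volcano(compare_sets(norm, test, ref))
    called = set(records.index[records["class_label"] == REQUIRED])
    sensitivity = len(called & set(cond_genes)) / len(cond_genes)
    neutral = set(gene_ids) - set(cond_genes)
    fpr = len(called & neutral) / len(neutral)
    return {"sensitivity": sensitivity, "fpr": fpr, "n_genes": n_genes,
            "n_test": len(test), "n_ref": len(ref)}


def type1_calibration_check(n_seeds: int = 10, n_genes: int = 300,
                            insertions: int = 20_000, seed: int = 0) -> dict:
    """All-neutral screens: fraction of genes called required at default
    thresholds, per seed; reports the mean rate and the binomial bound."""
    rates = []
    for s in range(n_seeds):
        cfg = SimulationConfig(n_genes=n_genes, insertions_per_library=insertions,
                               seed=seed * 1000 + s)
        design = default_design()[:12]
        screen = simulate_experiment(cfg, design=design)
        norm = normalize(screen.counts)
        libs = screen.counts.library_ids
        test = [l for l, m in zip(libs, design) if m.kennedy == "OFF"]
        ref = [l for l, m in zip(libs, design) if m.kennedy == "ON"]
        records = classify_volcano(compare_sets(norm, test, ref))
        rates.append(float((records["class_label"] == REQUIRED).mean()))
    rate = float(np.mean(rates))
    bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / (n_genes * n_seeds))
    return {"required_rate": rate, "bound": float(bound),
            "max_seed_rate": float(np.max(rates)), "n_seeds": n_seeds,
            "n_genes": n_genes}


# ---------------------------------------------------------------------------
# Co-essentiality module recovery
# ---------------------------------------------------------------------------

MODULE_SIZES = (4, 4, 3)


def _planted_module_screen(seed: int, n_genes: int = 200,
                           insertions: int = 50_000):
    """24-library screen with 3 planted co-essential modules: each module
    shares a distinct condition-essentiality pattern.

    Modules are planted in genes of near-median length: variable-gene
    selection ranks by absolute StdDev of normalized counts, so the
    recovery experiment reads out profile correlation on representative
    genes rather than the (real) hard case of very short genes whose
    depletion signal is below counting noise.
    """
    from .synthetic import simulate_genome

    cfg = SimulationConfig(n_genes=n_genes, insertions_per_library=insertions,
                           seed=seed)
    design = default_design()
    conds = sorted({m.condition for m in design})
    genes, _ = simulate_genome(cfg)
    gene_ids = [g.gene_id for g in genes]
    truth = EssentialityTruth.neutral(gene_ids, conds)
    lengths = pd.Series({g.gene_id: g.length for g in genes})
    median_order = (lengths - lengths.median()).abs().sort_values().index
    members_pool = list(median_order[: sum(MODULE_SIZES)])

    psd_groups = (("ER",), ("MIM",), ("endo", "LD"))
    modules = []
    start = 0
    for size, psds in zip(MODULE_SIZES, psd_groups):
        members = members_pool[start:start + size]
        start += size
        mod_conds = sorted({m.condition for m in design
                            if m.kennedy == "OFF" and m.psd_target in psds})
        truth.set_state(members, mod_conds, CONDITIONAL, 0.05)
        modules.append(members)
    screen = simulate_experiment(cfg, truth=truth, design=design)
    return screen, modules


def module_recovery_check(n_seeds: int = 10, seed: int = 0, top_k: int = 50) -> dict:
    """Across seeds: do `correlate` leaf orders place every planted module
    contiguously, and does within-module mean r exceed between-module mean
    r in every run?"""
    contiguous_runs = 0
    within_gt_between_runs = 0
    for s in range(n_seeds):
        screen, modules = _planted_module_screen(seed * 1000 + s)
        norm = normalize(screen.counts)
        var = select_variable_genes(norm, top_k)
        corr = gene_correlation(norm, var)
        dend, _ = cluster_correlation(corr)
        order = dend.leaf_order
        pos = {g: i for i, g in enumerate(order)}
        contiguous = all(
            max(pos[g] for g in mod) - min(pos[g] for g in mod) == len(mod) - 1
            for mod in modules
            if all(g in pos for g in mod)
        ) and all(all(g in pos for g in mod) for mod in modules)
        contiguous_runs += contiguous

        r = corr.r
        present = [[g for g in mod if g in r.index] for mod in modules]
        within, between = [], []
        for i, mod_a in enumerate(present):
            sub = r.loc[mod_a, mod_a].to_numpy()
            within.extend(sub[np.triu_indices(len(mod_a), k=1)])
            for mod_b in present[i + 1:]:
                between.extend(r.loc[mod_a, mod_b].to_numpy().ravel())
        within_gt_between_runs += float(np.nanmean(within)) > float(np.nanmean(between))
    return {
        "contiguous_fraction": contiguous_runs / n_seeds,
        "within_gt_between_fraction": within_gt_between_runs / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Lipidomics
# ---------------------------------------------------------------------------

def saturation_toy_fraction() -> dict:
    """Pooled more-unsaturated fraction on the reference toy table
    (PE 28:0 -> 10, 28:1 -> 30, 34:1 -> 20, 34:2 -> 20)."""
    table = pd.DataFrame(
        [
            ("PE", 28, 0, "unlabeled", "s", 10.0),
            ("PE", 28, 1, "unlabeled", "s", 30.0),
            ("PE", 34, 1, "unlabeled", "s", 20.0),
            ("PE", 34, 2, "unlabeled", "s", 20.0),
        ],
        columns=["lipid_class", "carbons", "double_bonds", "label", "sample",
                 "intensity"],
    )
    fracs, _ = saturation_fractions(table)
    return {"fraction": float(fracs["frac_more_unsaturated"].iloc[0]), "n": len(table)}


def remodeling_recovery_check(n_seeds: int = 10, seed: int = 0,
                              delta: float = 0.10) -> dict:
    """Programmed cold shift delta (WT) and 0 (mutant), n = 3, CV 5%:
    recovered shifts and the WT-vs-mutant 16C rejection rate."""
    params = LipidomeParams(cold_shift=delta,
                            beta={"wt": 1.0, "csf1dC": 0.0})
    wt_errs, mut_shifts, rejected = [], [], 0
    for s in range(n_seeds):
        table = simulate_lipidome(params, seed=seed * 1000 + s)
        fracs, _ = saturation_fractions(table)
        per_rep = fracs.merge(
            table[["sample", "genotype", "temperature", "replicate"]].drop_duplicates(),
            on="sample",
        )
        shifts = {}
        for gt, sub in per_rep.groupby("genotype"):
            cold = sub.loc[sub["temperature"] == params.cold_label,
                           "frac_more_unsaturated"].mean()
            warm = sub.loc[sub["temperature"] == params.warm_label,
                           "frac_more_unsaturated"].mean()
            shifts[gt] = cold - warm
        wt_errs.append(abs(shifts["wt"] - delta))
        mut_shifts.append(abs(shifts["csf1dC"]))

        # one test: per-replicate mean fraction across classes, WT vs mutant at 16C
        cold = per_rep[per_rep["temperature"] == params.cold_label]
        rep_means = cold.groupby(["genotype", "replicate"])[
            "frac_more_unsaturated"].mean().reset_index()
        a = rep_means.loc[rep_means["genotype"] == "wt", "frac_more_unsaturated"]
        b = rep_means.loc[rep_means["genotype"] == "csf1dC", "frac_more_unsaturated"]
        _, p = pooled_ttest(a, b)
        rejected += p < 0.05
    return {
        "max_wt_shift_error": float(np.max(wt_errs)),
        "max_mutant_shift": float(np.max(mut_shifts)),
        "rejection_fraction": rejected / n_seeds,
        "n_seeds": n_seeds,
    }


def flux_invariance_check() -> dict:
    """Two genotypes differing only in absolute label uptake: maximum
    difference between their precursor-normalized traces."""
    params = LabelingParams(uptake={"wt": 1.0, "slow": 0.35})
    table = simulate_labeling(params)
    traces = flux_ratios(table, by=["genotype"])
    piv = traces.pivot_table(index=["lipid_class", "timepoint"],
                             columns="genotype", values="ratio_to_precursor")
    diff = (piv["wt"] - piv["slow"]).abs()
    return {"max_abs_trace_diff": float(np.nanmax(diff.to_numpy())),
            "n_points": int(diff.notna().sum())}


# ---------------------------------------------------------------------------
# CLI determinism
# ---------------------------------------------------------------------------

def cli_determinism_check(seed: int = 1) -> dict:
    """Run `satay simulate` (and a volcano on its output) twice with the
    same seed; count files that differ byte-wise."""
    from click.testing import CliRunner

    from .cli import main as cli_main

    runner = CliRunner()
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        cfg = tmp / "cfg.yaml"
        cfg.write_text(
            "screen:\n  n_genes: 60\n  insertions_per_library: 4000\n"
            "truth:\n  conditional_genes: 5\n  depletion: 0.05\n"
            "  conditions: ['kennedy=OFF&psd_target=ER']\n"
        )
        # Rerun each subcommand with identical arguments into sibling
        # directories and compare every produced file byte-wise.
        sim_dirs = [tmp / "sim1", tmp / "sim2"]
        for d in sim_dirs:
            res = runner.invoke(cli_main, ["simulate", "--config", str(cfg),
                                           "--seed", str(seed), "--out", str(d)])
            if res.exit_code != 0:
                raise RuntimeError(f"simulate failed: {res.output}")
        volc_dirs = [tmp / "v1", tmp / "v2"]
        for d in volc_dirs:
            res = runner.invoke(cli_main, [
                "volcano", "--counts", str(sim_dirs[0] / "counts.tsv"),
                "--test", "kennedy=OFF", "--ref", "kennedy=ON",
                "--out", str(d / "volcano.tsv"),
            ])
            if res.exit_code != 0:
                raise RuntimeError(f"volcano failed: {res.output}")

        n_files = 0
        n_differing = 0
        for d1, d2 in (sim_dirs, volc_dirs):
            files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
            files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
            if files1 != files2:
                return {"n_files": n_files, "n_differing": -1}
            # manifests echo identical configs here except the simulate
            # output path is not recorded, so every file must match
            n_files += len(files1)
            n_differing += sum(
                not filecmp.cmp(d1 / f, d2 / f, shallow=False) for f in files1
            )
        return {"n_files": n_files, "n_differing": n_differing}
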