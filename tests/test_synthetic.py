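"""Ground-truth generator: determinism, uniformity, depletion semantics,
and the lipidome/labeling models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from satay.fitness import normalize
from satay.lipidomics import flux_ratios, saturation_fractions
from satay.models import LibraryMeta
from satay.synthetic import (
    CONDITIONAL,
    EssentialityTruth,
    LabelingParams,
    LipidomeParams,
    SimulationConfig,
    default_design,
    simulate_experiment,
    simulate_genome,
    simulate_labeling,
    simulate_library,
    simulate_lipidome,
)


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_genes=10, seed=1)
        assert simulate_genome(cfg) == simulate_genome(cfg)

    def test_gene_span_fits_genome(self):
        cfg = SimulationConfig(n_genes=50, seed=2)
        genes, chrom_lengths = simulate_genome(cfg)
        span = sum(g.length for g in genes)
        assert span < sum(chrom_lengths.values())
        assert all(g.length > 0 for g in genes)
        for chrom, length in chrom_lengths.items():
            assert max((g.end for g in genes if g.chrom == chrom), default=0) <= length

    def test_genes_do_not_overlap(self):
        cfg = SimulationConfig(n_genes=100, seed=3)
        genes, _ = simulate_genome(cfg)
        by_chrom: dict[str, list] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for members in by_chrom.values():
            members.sort(key=lambda g: g.start)
            for a, b in zip(members, members[1:]):
                assert a.end <= b.start

    def test_too_small_genome_is_error(self):
        cfg = SimulationConfig(n_genes=100, genome_length=1000, seed=1)
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(cfg)

    def test_median_length_near_target(self):
        cfg = SimulationConfig(n_genes=2000, seed=4)
        genes, _ = simulate_genome(cfg)
        med = np.median([g.length for g in genes])
        assert 1200 < med < 1650  # log-normal, median ~1.4 kb


def neutral_truth(genes, conditions=("c1",), cycles=13):
    return EssentialityTruth.neutral([g.gene_id for g in genes], list(conditions),
                                     growth_cycles=cycles)


class TestSimulateLibrary:
    def test_lethal_gene_has_zero_insertions(self):
        cfg = SimulationConfig(n_genes=20, insertions_per_library=30_000, seed=5)
        genes, chrom_lengths = simulate_genome(cfg)
        truth = neutral_truth(genes)
        truth.set_state([genes[0].gene_id], ["c1"], "essential", 0.0)
        sites = simulate_library(genes, chrom_lengths, truth, "c1", cfg, "L1")
        g = genes[0]
        inside = sites[(sites["chrom"] == g.chrom)
                       & (sites["pos"] >= g.start) & (sites["pos"] < g.end)]
        assert len(inside) == 0

    def test_neutral_counts_proportional_to_gene_length(self):
        """With depletion 1 everywhere, per-gene TN counts follow gene
        length (chi-square goodness of fit p > 0.01 at 1e5 insertions)."""
        from satay.insertion_io import count_per_gene

        cfg = SimulationConfig(n_genes=40, insertions_per_library=100_000, seed=6)
        genes, chrom_lengths = simulate_genome(cfg)
        truth = neutral_truth(genes)
        sites = simulate_library(genes, chrom_lengths, truth, "c1", cfg, "L1")
        m = count_per_gene(sites, genes, libraries=[LibraryMeta(library="L1")])
        observed = m.tn["L1"].to_numpy()
        lengths = np.array([g.length for g in genes], dtype=float)
        expected = observed.sum() * lengths / lengths.sum()
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.01

    def test_depletion_compounds_with_growth_cycles(self):
        """A gene at depletion factor f retains ~f^(cycles/13) of its
        insertions relative to the neutral condition (checked in a
        low-density regime where site merging is negligible)."""
        from satay.insertion_io import count_per_gene

        depletion = 0.2
        for cycles, seed in ((13, 11), (26, 11)):
            cfg = SimulationConfig(n_genes=300, insertions_per_library=100_000,
                                   seed=seed, growth_cycles=cycles)
            genes, chrom_lengths = simulate_genome(cfg)
            truth = EssentialityTruth.neutral(
                [g.gene_id for g in genes], ["on", "off"], growth_cycles=cycles)
            depleted = [g.gene_id for g in genes[:50]]
            truth.set_state(depleted, ["off"], CONDITIONAL, depletion)
            m = count_per_gene(
                pd.concat([
                    simulate_library(genes, chrom_lengths, truth, "on", cfg, "on", 1),
                    simulate_library(genes, chrom_lengths, truth, "off", cfg, "off", 2),
                ]),
                genes,
                libraries=[LibraryMeta(library="on"), LibraryMeta(library="off")],
            )
            # aggregate over 50 depleted genes to average out counting noise
            ratio = m.tn.loc[depleted, "off"].sum() / m.tn.loc[depleted, "on"].sum()
            expected = depletion ** (cycles / 13)
            assert ratio == pytest.approx(expected, rel=0.2)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_genes=15, insertions_per_library=5000, seed=8)
        genes, chrom_lengths = simulate_genome(cfg)
        truth = neutral_truth(genes)
        s1 = simulate_library(genes, chrom_lengths, truth, "c1", cfg, "L1")
        s2 = simulate_library(genes, chrom_lengths, truth, "c1", cfg, "L1")
        pd.testing.assert_frame_equal(s1, s2)


class TestSimulateExperiment:
    def test_replicate_libraries_correlate_on_neutral_genes(self):
        """Same condition, independent streams: normalized neutral-gene
        counts correlate r > 0.95 at 1e5 insertions."""
        design = [
            LibraryMeta(library="r1", kennedy="ON"),
            LibraryMeta(library="r2", kennedy="ON"),
        ]
        cfg = SimulationConfig(n_genes=300, insertions_per_library=100_000, seed=9)
        screen = simulate_experiment(cfg, design=design)
        norm = normalize(screen.counts, pseudocount=0.0)
        r = np.corrcoef(norm.values["r1"], norm.values["r2"])[0, 1]
        assert r > 0.95

    def test_neutral_genes_unbiased_across_conditions(self):
        """Mean log2 fold change over neutral genes is within +-0.05 of 0."""
        design = default_design()[:6]
        cfg = SimulationConfig(n_genes=300, insertions_per_library=100_000, seed=10)
        screen = simulate_experiment(cfg, design=design)
        norm = normalize(screen.counts)
        from satay.fitness import compare_sets

        libs = screen.counts.library_ids
        rec = compare_sets(norm, libs[:3], libs[3:])
        assert abs(rec["log2fc"].mean()) < 0.05

    def test_truth_round_trips_through_serialization(self, tmp_path):
        truth = EssentialityTruth.neutral(["g1", "g2", "g3"], ["on", "off"])
        truth.set_state(["g2"], ["off"], CONDITIONAL, 0.05)
        truth.to_tsv(tmp_path / "truth.tsv")
        back = EssentialityTruth.from_tsv(tmp_path / "truth.tsv")
        pd.testing.assert_frame_equal(back.factors, truth.factors,
                                      check_names=False)
        pd.testing.assert_frame_equal(back.states, truth.states, check_names=False)
        assert back.growth_cycles == truth.growth_cycles


class TestSimulateLipidome:
    def test_blunted_mutant_shows_no_cold_shift(self):
        """beta = 0 removes the cold shift for that genotype."""
        params = LipidomeParams(cv=0.0, beta={"wt": 1.0, "mut": 0.0})
        table = simulate_lipidome(params, seed=1)
        fracs, _ = saturation_fractions(table)
        per = fracs.merge(
            table[["sample", "genotype", "temperature"]].drop_duplicates(),
            on="sample")
        mut = per[per["genotype"] == "mut"].groupby("temperature")[
            "frac_more_unsaturated"].mean()
        wt = per[per["genotype"] == "wt"].groupby("temperature")[
            "frac_more_unsaturated"].mean()
        assert mut["16C"] == pytest.approx(mut["30C"], abs=1e-12)
        assert wt["16C"] - wt["30C"] == pytest.approx(params.cold_shift, abs=1e-12)

    def test_invalid_weights_are_error(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LipidomeParams(low_carbon_weights={28: 0.7, 30: 0.7}).validate()

    def test_deterministic_under_seed(self):
        params = LipidomeParams()
        pd.testing.assert_frame_equal(
            simulate_lipidome(params, seed=3), simulate_lipidome(params, seed=3))


class TestSimulateLabeling:
    def test_blocked_conversion_keeps_product_unlabeled(self):
        """k(PE->PC) = 0: labeled PC stays 0 at all timepoints."""
        params = LabelingParams(k_pe_pc=0.0)
        table = simulate_labeling(params)
        pc = table[(table["lipid_class"] == "PC") & (table["label"] == "15N")]
        assert np.allclose(pc["intensity"], 0.0)

    def test_precursor_ratios_independent_of_uptake(self):
        params = LabelingParams(uptake={"fast": 2.0, "slow": 0.25})
        traces = flux_ratios(simulate_labeling(params), by=["genotype"])
        piv = traces.pivot_table(index=["lipid_class", "timepoint"],
                                 columns="genotype", values="ratio_to_precursor")
        assert np.allclose(piv["fast"].dropna(), piv["slow"].dropna(), atol=1e-8)

    def test_unlabeled_ratio_scales_with_uptake(self):
        params = LabelingParams(uptake={"fast": 2.0, "slow": 1.0})
        traces = flux_ratios(simulate_labeling(params), by=["genotype"])
        piv = traces.pivot_table(index=["lipid_class", "timepoint"],
                                 columns="genotype", values="ratio_to_unlabeled")
        late = piv.dropna()
        late = late[late["slow"] > 0]
        assert np.allclose(late["fast"] / late["slow"], 2.0)
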