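"""Synthetic SATAY screens and lipidomes with known ground truth.

The generator emulates the study conditions of a rewired-phospholipid
transposon screen: millions of transposition events per library (desk
scale defaults to 1e5, the published 2e6-1.5e7 scale is a parameter) laid
uniformly over a gene-annotated genome, depletion of insertions in
(conditionally) essential genes compounding over ~13 growth cycles of
selection, overdispersed (negative-binomial) read counts per insertion,
and a lipidome whose double-bond distribution shifts under cold with a
genotype-dependent blunting of the shift.

Determinism: every draw derives from the config seed; identical config +
seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .insertion_io import count_per_gene
from .models import GeneCountMatrix, GeneModel, LibraryMeta

NEUTRAL = "neutral"
ESSENTIAL = "essential"
CONDITIONAL = "conditionally_essential"
ADVANTAGED = "advantaged"

#: Growth-cycle count the depletion exponent is normalized to: a state's
#: depletion factor is the retention multiplier after this many cycles.
REFERENCE_CYCLES = 13


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class EssentialityTruth:
    """Gene x condition fitness ground truth.

    ``factors`` holds the retention multiplier on expected insertion
    counts after ``REFERENCE_CYCLES`` growth cycles (neutral = 1, fully
    essential ~ 0); ``states`` the matching label.
    """

    factors: pd.DataFrame
    states: pd.DataFrame
    growth_cycles: int = REFERENCE_CYCLES

    def __post_init__(self) -> None:
        if (self.factors.to_numpy() < 0).any():
            raise ValueError("depletion factors must be >= 0")
        if not self.factors.index.equals(self.states.index) or list(
            self.factors.columns
        ) != list(self.states.columns):
            raise ValueError("factors and states must share genes and conditions")

    @classmethod
    def neutral(cls, genes: Sequence[str], conditions: Sequence[str],
                growth_cycles: int = REFERENCE_CYCLES) -> "EssentialityTruth":
        factors = pd.DataFrame(1.0, index=list(genes), columns=list(conditions))
        states = pd.DataFrame(NEUTRAL, index=list(genes), columns=list(conditions))
        return cls(factors=factors, states=states, growth_cycles=growth_cycles)

    def set_state(self, genes: Iterable[str], conditions: Iterable[str],
                  state: str, factor: float) -> None:
        genes, conditions = list(genes), list(conditions)
        self.factors.loc[genes, conditions] = factor
        self.states.loc[genes, conditions] = state

    def genes_in_state(self, condition: str, state: str) -> list[str]:
        col = self.states[condition]
        return list(col.index[col == state])

    def to_tsv(self, path: str | Path) -> None:
        """Sparse serialization: the gene/condition universe in header
        comments, then one row per non-neutral (gene, condition) entry."""
        with open(path, "w") as fh:
            fh.write(f"#growth_cycles={self.growth_cycles}\n")
            fh.write("#genes=" + ",".join(self.factors.index) + "\n")
            fh.write("#conditions=" + ",".join(self.factors.columns) + "\n")
            fh.write("gene_id\tcondition\tfactor\tstate\n")
            for cond in self.factors.columns:
                col_f, col_s = self.factors[cond], self.states[cond]
                nondefault = col_f.index[(col_f != 1.0) | (col_s != NEUTRAL)]
                for g in nondefault:
                    fh.write(f"{g}\t{cond}\t{col_f[g]:.10g}\t{col_s[g]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EssentialityTruth":
        header: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].rstrip("\n").partition("=")
                header[key] = value
        genes = header["genes"].split(",")
        conditions = header["conditions"].split(",")
        truth = cls.neutral(genes, conditions,
                            growth_cycles=int(header["growth_cycles"]))
        long = pd.read_csv(path, sep="\t", comment="#")
        for row in long.itertuples(index=False):
            truth.factors.at[row.gene_id, row.condition] = row.factor
            truth.states.at[row.gene_id, row.condition] = row.state
        return truth


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs for the transposon-screen generator.

    Desk-scale defaults: 1e5 insertions/library over a ~2 Mb, 1000-gene
    genome; the published scale (2e6-1.5e7 events over the 12 Mb yeast
    genome) is reached by raising ``insertions_per_library`` and
    ``n_genes``.  ``read_dispersion`` is the negative-binomial size
    parameter for reads per insertion (PCR/sequencing jackpots make read
    counts strongly overdispersed).
    """

    n_genes: int = 1000
    genome_length: int | None = None  # default: ~1.45x total gene span
    n_chromosomes: int = 3
    gene_length_median: float = 1400.0
    gene_length_sigma: float = 0.55
    insertions_per_library: int = 100_000
    read_mean: float = 20.0
    read_dispersion: float = 0.5
    growth_cycles: int = REFERENCE_CYCLES
    seed: int = 0


def _rng(config_seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, *stream])


def simulate_genome(config: SimulationConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Draw a gene-annotated genome: log-normal gene lengths (median
    ~1.4 kb) laid on chromosomes with random intergenic gaps."""
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(config.seed, 0)
    lengths = np.maximum(
        150,
        np.round(
            rng.lognormal(np.log(config.gene_length_median),
                          config.gene_length_sigma, config.n_genes)
        ).astype(int),
    )
    span = int(lengths.sum())
    genome_length = config.genome_length or int(round(span * 1.45))
    n_gaps = config.n_genes + config.n_chromosomes
    intergenic = genome_length - span
    if intergenic < n_gaps:
        raise ValueError(
            f"genome_length {genome_length} too small for {config.n_genes} genes "
            f"spanning {span} bp"
        )
    gaps = rng.multinomial(intergenic - n_gaps, np.full(n_gaps, 1.0 / n_gaps)) + 1

    # Distribute genes over chromosomes as evenly as possible.
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    gi = 0
    gap_i = 0
    for ci, n_on_chrom in enumerate(per_chrom):
        chrom = f"chr{ci + 1:02d}"
        pos = 0
        for _ in range(n_on_chrom):
            pos += int(gaps[gap_i])
            gap_i += 1
            start, end = pos, pos + int(lengths[gi])
            genes.append(
                GeneModel(
                    gene_id=f"G{gi + 1:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            pos = end
            gi += 1
        pos += int(gaps[gap_i])
        gap_i += 1
        chrom_lengths[chrom] = pos
    return genes, chrom_lengths


def simulate_library(
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
    truth: EssentialityTruth,
    condition: str,
    config: SimulationConfig,
    library_id: str,
    stream: int = 1,
) -> pd.DataFrame:
    """Simulate one library's retained insertion sites as a DataFrame.

    Insertions land uniformly on the genome; one landing in gene g
    survives selection with probability factor(g, condition)^(cycles/13)
    (capped at 1) so fitness effects compound over growth cycles;
    intergenic insertions are always retained.  Reads per retained
    insertion are 1 + NegBin(size, mean read_mean - 1).
    """
    if condition not in truth.factors.columns:
        raise ValueError(f"condition {condition!r} absent from truth")
    factors = truth.factors[condition].reindex([g.gene_id for g in genes])
    if factors.isna().any():
        raise ValueError("truth does not cover all genes for this condition")
    rng = _rng(config.seed, stream)

    chroms = sorted(chrom_lengths)
    clens = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(clens)])
    L = int(offsets[-1])

    order = sorted(range(len(genes)), key=lambda i: (genes[i].chrom, genes[i].start))
    chrom_off = {c: offsets[i] for i, c in enumerate(chroms)}
    gstart = np.array([chrom_off[genes[i].chrom] + genes[i].start for i in order])
    gend = np.array([chrom_off[genes[i].chrom] + genes[i].end for i in order])
    retention = np.minimum(
        1.0, factors.to_numpy()[order] ** (config.growth_cycles / REFERENCE_CYCLES)
    )

    pos = rng.integers(0, L, size=config.insertions_per_library)
    gi = np.searchsorted(gstart, pos, side="right") - 1
    in_gene = (gi >= 0) & (pos < gend[np.clip(gi, 0, None)])
    keep_p = np.ones(len(pos))
    keep_p[in_gene] = retention[gi[in_gene]]
    keep = rng.random(len(pos)) < keep_p
    pos = pos[keep]

    m = max(config.read_mean - 1.0, 1e-9)
    size = config.read_dispersion
    reads = 1 + rng.negative_binomial(size, size / (size + m), size=len(pos))
    strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")

    ci = np.searchsorted(offsets, pos, side="right") - 1
    frame = pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[ci],
            "pos": pos - offsets[ci],
            "strand": strand,
            "reads": reads,
            "library": library_id,
        }
    )
    # Two events at the same position/strand are indistinguishable sites.
    frame = (
        frame.groupby(["chrom", "pos", "strand"], as_index=False)
        .agg(reads=("reads", "sum"), library=("library", "first"))
        [["chrom", "pos", "strand", "reads", "library"]]
        .sort_values(["chrom", "pos", "strand"], kind="stable")
        .reset_index(drop=True)
    )
    return frame


def default_design() -> list[LibraryMeta]:
    """The study design: 12 rewired genotypes (Psd target x Pmt target),
    each grown in Kennedy ON and OFF -> 24 libraries."""
    design = []
    for psd in ("ER", "MIM", "endo", "LD"):
        for pmt in ("ER", "pex", "MM"):
            for kennedy in ("ON", "OFF"):
                design.append(
                    LibraryMeta(
                        library=f"psd{psd}-pmt{pmt}-{kennedy}",
                        psd_target=psd,
                        pmt_target=pmt,
                        kennedy=kennedy,
                    )
                )
    return design


@dataclass
class SimulatedScreen:
    counts: GeneCountMatrix
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    truth: EssentialityTruth
    sites: dict[str, pd.DataFrame]


def simulate_experiment(
    config: SimulationConfig,
    truth: EssentialityTruth | None = None,
    design: Sequence[LibraryMeta] | None = None,
) -> SimulatedScreen:
    """Simulate a full multi-library screen and count it per gene.

    One library per design row; each library draws from an independent,
    seed-derived stream.  The result carries the ground truth so recovery
    can be scored downstream.
    """
    design = list(design) if design is not None else default_design()
    genes, chrom_lengths = simulate_genome(config)
    gene_ids = [g.gene_id for g in genes]
    if truth is None:
        truth = EssentialityTruth.neutral(
            gene_ids, sorted({m.condition for m in design}),
            growth_cycles=config.growth_cycles,
        )
    sites: dict[str, pd.DataFrame] = {}
    for i, meta in enumerate(design):
        sites[meta.library] = simulate_library(
            genes, chrom_lengths, truth, meta.condition, config,
            meta.library, stream=i + 1,
        )
    all_sites = pd.concat(sites.values(), ignore_index=True)
    counts = count_per_gene(all_sites, genes, libraries=design)
    return SimulatedScreen(counts=counts, genes=genes, chrom_lengths=chrom_lengths,
                           truth=truth, sites=sites)


# ---------------------------------------------------------------------------
# Lipidome simulation
# ---------------------------------------------------------------------------

@dataclass
class LipidomeParams:
    """Cold-remodeling lipidome generator.

    Per class, species sit on a grid of saturation pairs (28/30 carbons
    with 0/1 double bonds; 32/34 carbons with 1/2) plus an outside-pair
    species.  At the warm temperature the more-unsaturated pair members
    carry ``baseline_frac_more`` of each pair; cold shifts that fraction
    by ``cold_shift`` in the wild type and by ``beta * cold_shift`` in the
    mutant (beta = 0 reproduces a remodeling-blind mutant).  Replicate
    intensities get log-normal noise of coefficient of variation ``cv``.
    """

    classes: tuple[str, ...] = ("PA", "PS", "PE", "PI", "PC")
    baseline_frac_more: float = 0.40
    cold_shift: float = 0.10
    beta: Mapping[str, float] = field(
        default_factory=lambda: {"wt": 1.0, "csf1dC": 0.0}
    )
    warm_label: str = "30C"
    cold_label: str = "16C"
    n_replicates: int = 3
    cv: float = 0.05
    class_total: float = 1e6
    outside_share: float = 0.10
    low_carbon_weights: Mapping[int, float] = field(
        default_factory=lambda: {28: 0.5, 30: 0.5}
    )
    high_carbon_weights: Mapping[int, float] = field(
        default_factory=lambda: {32: 0.5, 34: 0.5}
    )

    def validate(self) -> None:
        for name, w in (("low", self.low_carbon_weights), ("high", self.high_carbon_weights)):
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}_carbon_weights must sum to 1")
        if not 0 <= self.outside_share < 1:
            raise ValueError("outside_share must be in [0, 1)")
        for gt, b in self.beta.items():
            f = self.baseline_frac_more + b * self.cold_shift
            if not 0 < f < 1:
                raise ValueError(f"cold fraction for {gt} outside (0, 1): {f}")
        if not 0 < self.baseline_frac_more < 1:
            raise ValueError("baseline_frac_more must be in (0, 1)")


def simulate_lipidome(params: LipidomeParams, seed: int = 0) -> pd.DataFrame:
    """Generate a long-format steady-state lipid species table for the
    cold-adaptation experiment (genotype x temperature x replicate)."""
    params.validate()
    rng = np.random.default_rng([seed, 100])
    sigma = np.sqrt(np.log(1.0 + params.cv**2))
    rows = []
    pair_share = params.class_total * (1.0 - params.outside_share) / 2.0
    for genotype, beta in params.beta.items():
        for temp in (params.warm_label, params.cold_label):
            shift = beta * params.cold_shift if temp == params.cold_label else 0.0
            frac = params.baseline_frac_more + shift
            for rep in range(1, params.n_replicates + 1):
                sample = f"{genotype}_{temp}_r{rep}"
                group = f"{genotype}_{temp}"
                for cls in params.classes:
                    specs = []
                    for carbons, w in params.low_carbon_weights.items():
                        specs.append((carbons, 0, pair_share * w * (1 - frac)))
                        specs.append((carbons, 1, pair_share * w * frac))
                    for carbons, w in params.high_carbon_weights.items():
                        specs.append((carbons, 1, pair_share * w * (1 - frac)))
                        specs.append((carbons, 2, pair_share * w * frac))
                    specs.append((36, 3, params.class_total * params.outside_share))
                    for carbons, db, mean_int in specs:
                        noise = rng.lognormal(-0.5 * sigma**2, sigma)
                        rows.append(
                            (cls, carbons, db, "unlabeled", sample, group,
                             genotype, temp, rep, mean_int * noise)
                        )
    return pd.DataFrame(
        rows,
        columns=["lipid_class", "carbons", "double_bonds", "label", "sample",
                 "group", "genotype", "temperature", "replicate", "intensity"],
    )


@dataclass
class LabelingParams:
    """Linear three-compartment 15N labeling chain PS -> PE -> PC.

    d[PS]/dt = uptake - k_ps_pe * [PS];  d[PE]/dt = k_ps_pe * [PS] - k_pe_pc * [PE];
    d[PC]/dt = k_pe_pc * [PE].  Labeled pools start at zero, so every pool
    is proportional to ``uptake`` and precursor-normalized ratios depend
    only on the conversion rates — the structure that lets two genotypes
    with different absolute label uptake show identical precursor traces.
    """

    uptake: Mapping[str, float] = field(default_factory=lambda: {"wt": 1.0, "csf1dC": 0.7})
    k_ps_pe: float = 1.2
    k_pe_pc: float = 0.6
    unlabeled_pools: Mapping[str, float] = field(
        default_factory=lambda: {"PS": 2e5, "PE": 6e5, "PC": 9e5}
    )
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)
    scale: float = 1e5  # intensity units per unit uptake


def labeled_chain_profile(params: LabelingParams) -> np.ndarray:
    """Unit-uptake labeled pools [PS, PE, PC] at each timepoint (matrix
    exponential of the augmented linear system; exact for any rates,
    including degenerate equal-rate chains)."""
    k1, k2 = params.k_ps_pe, params.k_pe_pc
    A = np.array(
        [
            [-k1, 0.0, 0.0, 1.0],
            [k1, -k2, 0.0, 0.0],
            [0.0, k2, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    x0 = np.array([0.0, 0.0, 0.0, 1.0])
    return np.array([(expm(A * t) @ x0)[:3] for t in params.timepoints])


def simulate_labeling(params: LabelingParams | None = None) -> pd.DataFrame:
    """Deterministic 15N pulse-labeling time series per genotype.

    Labeled intensities scale linearly with each genotype's uptake;
    unlabeled class pools are constant over the chase.
    """
    if params is None:
        params = LabelingParams()
    base = labeled_chain_profile(params)  # timepoints x (PS, PE, PC)
    classes = ("PS", "PE", "PC")
    rows = []
    for genotype, u in params.uptake.items():
        for ti, t in enumerate(params.timepoints):
            for cj, cls in enumerate(classes):
                rows.append((genotype, cls, "15N", t, params.scale * u * base[ti, cj]))
                rows.append((genotype, cls, "unlabeled", t, params.unlabeled_pools[cls]))
    return pd.DataFrame(
        rows, columns=["genotype", "lipid_class", "label", "timepoint", "intensity"]
    )
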