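"""Lipidomic adaptation scoring: saturation-pair remodeling, abundance
grids, TLC fractions, and stable-isotope flux ratios.

Cold-adapted yeast remodels its phospholipids toward shorter, more
unsaturated acyl chains (homeoviscous adaptation).  The remodeling
readout used here compares, within each phospholipid class, the
0- vs 1-double-bond species for lipids with <= 30 total acyl carbons and
the 1- vs 2-double-bond species for lipids with >= 32 carbons; the
fraction of the pair total carried by the more unsaturated member is the
per-class saturation index.

Flux through the CDP-DAG pathway (PS -> PE -> PC) is traced by 15N
pulse labeling: the labeled abundance of each product normalized to its
labeled precursor isolates conversion/transport efficiency from label
uptake, and normalization to the unlabeled same-class species tracks
overall incorporation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LESS_UNSATURATED = "less_unsaturated"
MORE_UNSATURATED = "more_unsaturated"
OUTSIDE_PAIR = "outside_pair"

LABEL_15N = "15N"
LABEL_UNLABELED = "unlabeled"

#: Sequential order of the CDP-DAG pathway: product -> precursor.
DEFAULT_PRECURSOR_MAP = {"PE": "PS", "PC": "PE"}

REQUIRED_COLUMNS = ("lipid_class", "carbons", "double_bonds", "label", "sample", "intensity")


def validate_species_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"lipid table missing columns: {sorted(missing)}")
    if (table["intensity"] < 0).any():
        raise ValueError("negative lipid intensities")
    odd = table[(table["carbons"] < 20) | (table["carbons"] % 2 != 0)]
    if len(odd):
        logger.warning(
            "%d species with <20 or odd total acyl carbons (unusual for yeast)",
            len(odd),
        )
    return table


def parse_species(name: str) -> tuple[str, int, int]:
    """Parse 'CLASS C:D' nomenclature, e.g. 'PE 34:2' -> ('PE', 34, 2)."""
    try:
        cls, cd = name.rsplit(" ", 1)
        c, d = cd.split(":")
        return cls, int(c), int(d)
    except ValueError as exc:
        raise ValueError(f"cannot parse lipid species {name!r} as 'CLASS C:D'") from exc


def tlc_fractions(lane_quantities: Mapping[str, float]) -> dict[str, float]:
    """Express each species as a fraction of the total quantified in the lane."""
    total = float(sum(lane_quantities.values()))
    if any(q < 0 for q in lane_quantities.values()):
        raise ValueError("negative lane quantity")
    if total <= 0:
        raise ValueError("all-zero lane: no quantified lipid signal")
    return {species: q / total for species, q in lane_quantities.items()}


def classify_saturation_pair(carbons: int, double_bonds: int) -> str:
    """Assign a species to its saturation comparison pair.

    <= 30 carbons: 0 double bonds -> less unsaturated, 1 -> more unsaturated;
    >= 32 carbons: 1 -> less unsaturated, 2 -> more unsaturated; everything
    else (including 31-carbon odd chains) lies outside both pairs.
    """
    if carbons <= 30:
        if double_bonds == 0:
            return LESS_UNSATURATED
        if double_bonds == 1:
            return MORE_UNSATURATED
    elif carbons >= 32:
        if double_bonds == 1:
            return LESS_UNSATURATED
        if double_bonds == 2:
            return MORE_UNSATURATED
    return OUTSIDE_PAIR


def saturation_fractions(
    table: pd.DataFrame,
    group_col: str = "group",
    compare: tuple[str, str] | None = None,
    pooled: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-class, per-sample fraction of the saturation-pair total carried
    by the more unsaturated member, plus an optional group comparison.

    With ``pooled=True`` (default) the <=30C and >=32C pairs are pooled
    (intensity-weighted) into one fraction per class and sample; with
    ``pooled=False`` fractions are reported per carbon-chain group.
    ``compare=(group_a, group_b)`` adds per-class two-sided two-sample
    Student's t-tests over the replicate fractions of the two groups
    (undefined when a group has < 2 replicates).
    """
    table = validate_species_table(table)
    sub = table[table["label"] == LABEL_UNLABELED] if "label" in table else table
    sub = sub.copy()
    sub["pair_member"] = [
        classify_saturation_pair(c, d)
        for c, d in zip(sub["carbons"], sub["double_bonds"])
    ]
    sub = sub[sub["pair_member"] != OUTSIDE_PAIR]
    if sub.empty:
        raise ValueError("no species fall inside a saturation comparison pair")
    keys = ["lipid_class", "sample"]
    if group_col in sub.columns:
        keys.append(group_col)
    if not pooled:
        sub["chain_group"] = np.where(sub["carbons"] <= 30, "<=30C", ">=32C")
        keys.append("chain_group")

    # No fill: a sample missing one pair member entirely yields an undefined
    # fraction (NaN), not an implicit zero that would bias remodeling estimates.
    agg = (
        sub.pivot_table(index=keys, columns="pair_member", values="intensity",
                        aggfunc="sum")
        .reindex(columns=[LESS_UNSATURATED, MORE_UNSATURATED])
        .reset_index()
    )
    agg["pair_total"] = agg[LESS_UNSATURATED] + agg[MORE_UNSATURATED]
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["frac_more_unsaturated"] = np.where(
            agg["pair_total"] > 0, agg[MORE_UNSATURATED] / agg["pair_total"], np.nan
        )

    comparison = None
    if compare is not None:
        if group_col not in agg.columns:
            raise ValueError(f"comparison requested but no {group_col!r} column present")
        ga, gb = compare
        rows = []
        for cls, cls_df in agg.groupby("lipid_class"):
            fa = cls_df.loc[cls_df[group_col] == ga, "frac_more_unsaturated"].dropna()
            fb = cls_df.loc[cls_df[group_col] == gb, "frac_more_unsaturated"].dropna()
            if len(fa) >= 2 and len(fb) >= 2:
                p = float(stats.ttest_ind(fa, fb, equal_var=True).pvalue)
            else:
                p = np.nan  # undefined with < 2 replicates; fractions still reported
            rows.append(
                {
                    "lipid_class": cls,
                    "group_a": ga,
                    "group_b": gb,
                    "mean_frac_a": fa.mean() if len(fa) else np.nan,
                    "mean_frac_b": fb.mean() if len(fb) else np.nan,
                    "difference": (fa.mean() - fb.mean()) if len(fa) and len(fb) else np.nan,
                    "n_a": len(fa),
                    "n_b": len(fb),
                    "p_value": p,
                }
            )
        comparison = pd.DataFrame(rows)
    return agg, comparison


def per_species_abundance_grid(
    table: pd.DataFrame,
    group_col: str = "group",
    compare: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Within-class species shares per sample, averaged per group, with
    optional per-species two-sample t-tests between two groups.

    The share of a species is its intensity divided by the class total in
    the same sample, so shares within a class sum to 1 per sample and are
    invariant to global intensity rescaling.
    """
    table = validate_species_table(table)
    sub = table[table["label"] == LABEL_UNLABELED].copy()
    class_tot = sub.groupby(["sample", "lipid_class"])["intensity"].transform("sum")
    empty = class_tot == 0
    if empty.any():
        skipped = sub.loc[empty, ["sample", "lipid_class"]].drop_duplicates()
        logger.warning("skipping %d empty class/sample groups", len(skipped))
        sub = sub[~empty]
        class_tot = class_tot[~empty]
    sub["share"] = sub["intensity"] / class_tot

    keys = ["lipid_class", "carbons", "double_bonds"]
    if group_col not in sub.columns:
        return sub.groupby(keys, as_index=False)["share"].mean()
    out = (
        sub.groupby(keys + [group_col], as_index=False)["share"]
        .mean()
        .pivot_table(index=keys, columns=group_col, values="share")
        .add_prefix("mean_share_")
        .reset_index()
    )
    if compare is not None:
        ga, gb = compare
        pvals = []
        for _, row in out.iterrows():
            sel = (
                (sub["lipid_class"] == row["lipid_class"])
                & (sub["carbons"] == row["carbons"])
                & (sub["double_bonds"] == row["double_bonds"])
            )
            xa = sub.loc[sel & (sub[group_col] == ga), "share"]
            xb = sub.loc[sel & (sub[group_col] == gb), "share"]
            if len(xa) >= 2 and len(xb) >= 2:
                pvals.append(float(stats.ttest_ind(xa, xb, equal_var=True).pvalue))
            else:
                pvals.append(np.nan)
        out["p_value"] = pvals
    return out


@dataclass
class FluxTrace:
    """Labeled-lipid ratios per timepoint for one class (and group)."""

    lipid_class: str
    timepoints: np.ndarray
    ratio_to_precursor: np.ndarray
    ratio_to_unlabeled: np.ndarray


def flux_ratios(
    table: pd.DataFrame,
    precursor_map: Mapping[str, str] | None = None,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Compute labeling ratios along the PS -> PE -> PC conversion chain.

    For each class X at each timepoint: ratio_to_unlabeled = 15N-X / 14N-X,
    and, when X has a precursor P in ``precursor_map``,
    ratio_to_precursor = 15N-X / 15N-P.  PS, the chain entry point, has no
    precursor ratio.  Zero denominators yield NaN (logged).

    ``by`` lists extra grouping columns (e.g. genotype) kept separate.
    The input is a long table with columns lipid_class, label, timepoint,
    intensity (class-level totals; carbons/double_bonds are ignored if
    present by summing over them).
    """
    if precursor_map is None:
        precursor_map = DEFAULT_PRECURSOR_MAP
    needed = {"lipid_class", "label", "timepoint", "intensity"} | set(by)
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"flux table missing columns: {sorted(missing)}")
    keys = list(by) + ["lipid_class", "label", "timepoint"]
    tot = table.groupby(keys, as_index=False)["intensity"].sum()
    wide = tot.pivot_table(
        index=list(by) + ["lipid_class", "timepoint"],
        columns="label", values="intensity", fill_value=0.0,
    ).reset_index()
    for col in (LABEL_15N, LABEL_UNLABELED):
        if col not in wide.columns:
            wide[col] = 0.0

    with np.errstate(invalid="ignore", divide="ignore"):
        wide["ratio_to_unlabeled"] = np.where(
            wide[LABEL_UNLABELED] > 0, wide[LABEL_15N] / wide[LABEL_UNLABELED], np.nan
        )

    # Precursor-normalized ratio: join each product row to its precursor's
    # labeled intensity at the same timepoint (and group).
    prec = wide[list(by) + ["lipid_class", "timepoint", LABEL_15N]].rename(
        columns={"lipid_class": "_precursor", LABEL_15N: "_precursor_15n"}
    )
    wide["_precursor"] = wide["lipid_class"].map(dict(precursor_map))
    wide = wide.merge(prec, how="left", on=list(by) + ["_precursor", "timepoint"])
    with np.errstate(invalid="ignore", divide="ignore"):
        wide["ratio_to_precursor"] = np.where(
            wide["_precursor_15n"] > 0, wide[LABEL_15N] / wide["_precursor_15n"], np.nan
        )
    n_undef = int(
        (wide["_precursor"].notna() & ~(wide["_precursor_15n"] > 0)).sum()
    )
    if n_undef:
        logger.info("%d precursor ratios undefined (zero labeled precursor)", n_undef)
    wide.loc[wide["_precursor"].isna(), "ratio_to_precursor"] = np.nan
    out = wide[
        list(by)
        + ["lipid_class", "timepoint", LABEL_15N, LABEL_UNLABELED,
           "ratio_to_precursor", "ratio_to_unlabeled"]
    ].rename(columns={LABEL_15N: "labeled", LABEL_UNLABELED: "unlabeled"})
    return out.sort_values(list(by) + ["lipid_class", "timepoint"]).reset_index(drop=True)
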