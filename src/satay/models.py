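"""Core containers for SATAY screen data.

A screen is a set of transposon-insertion libraries, one per (genotype,
Kennedy-pathway state) condition.  Each mapped insertion site carries the
number of sequencing reads supporting it; per-gene transposon and read
counts, together with per-library totals over *all* mapped sites, are the
currency of every downstream fitness computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Strand marker used when the insertion orientation is unknown (WIG input).
STRAND_UNKNOWN = "."

VALID_STRANDS = {"+", "-", STRAND_UNKNOWN}

KENNEDY_STATES = ("ON", "OFF")


@dataclass(frozen=True)
class InsertionSite:
    """One mapped transposon insertion in one library.

    Coordinates are 0-based.  ``reads`` is the number of sequencing reads
    supporting the insertion, a proxy for clone abundance after selection.
    """

    chrom: str
    pos: int
    strand: str
    reads: int
    library: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"insertion position must be >= 0, got {self.pos}")
        if self.reads < 0:
            raise ValueError(f"read count must be >= 0, got {self.reads}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    common_name: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LibraryMeta:
    """Metadata for one transposon library.

    ``psd_target``/``pmt_target`` name the organelle the chimeric PE-/PC-
    synthesizing enzyme is directed to (ER, MIM, MM, endo, LD, pex, or
    ``none``).  ``kennedy`` records whether ethanolamine + choline were
    supplied (Kennedy pathway ON) or not (OFF).  ``condition`` is the key
    into a ground-truth essentiality table for simulated libraries; it
    defaults to a genotype x Kennedy label.
    """

    library: str
    psd_target: str = "none"
    pmt_target: str = "none"
    kennedy: str = "ON"
    group_tags: frozenset[str] = field(default_factory=frozenset)
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.kennedy not in KENNEDY_STATES:
            raise ValueError(f"kennedy must be ON or OFF, got {self.kennedy!r}")
        if self.condition is None:
            object.__setattr__(self, "condition", self.default_condition())
        if not isinstance(self.group_tags, frozenset):
            object.__setattr__(self, "group_tags", frozenset(self.group_tags))

    def default_condition(self) -> str:
        return f"psd-{self.psd_target}_pmt-{self.pmt_target}_{self.kennedy}"

    def to_dict(self) -> dict:
        return {
            "library": self.library,
            "psd_target": self.psd_target,
            "pmt_target": self.pmt_target,
            "kennedy": self.kennedy,
            "group_tags": sorted(self.group_tags),
            "condition": self.condition,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LibraryMeta":
        return cls(
            library=d["library"],
            psd_target=d.get("psd_target", "none"),
            pmt_target=d.get("pmt_target", "none"),
            kennedy=d.get("kennedy", "ON"),
            group_tags=frozenset(d.get("group_tags", ())),
            condition=d.get("condition"),
        )


@dataclass
class GeneCountMatrix:
    """Gene x library matrices of transposon counts and read counts.

    ``totals_tn``/``totals_reads`` are per-library totals over *all* mapped
    sites, genic and intergenic, and are the denominators for depth
    normalization.  Because genes may overlap (a site inside k overlapping
    genes increments all k), per-library column sums may exceed the totals
    only in annotations with overlaps; with a non-overlapping annotation
    the column sum is <= the total.
    """

    tn: pd.DataFrame
    reads: pd.DataFrame
    libraries: list[LibraryMeta]
    totals_tn: pd.Series
    totals_reads: pd.Series

    def __post_init__(self) -> None:
        lib_ids = [m.library for m in self.libraries]
        if len(set(lib_ids)) != len(lib_ids):
            raise ValueError("duplicate library identifiers")
        for name, df in (("tn", self.tn), ("reads", self.reads)):
            if list(df.columns) != lib_ids:
                raise ValueError(f"{name} columns do not match library metadata order")
            if (df.to_numpy() < 0).any():
                raise ValueError(f"negative counts in {name} matrix")
        if not self.tn.index.equals(self.reads.index):
            raise ValueError("tn and reads matrices index different genes")
        for name, tot in (("totals_tn", self.totals_tn), ("totals_reads", self.totals_reads)):
            if list(tot.index) != lib_ids:
                raise ValueError(f"{name} index does not match library metadata order")
            if (tot.to_numpy() < 0).any():
                raise ValueError(f"negative values in {name}")

    @property
    def genes(self) -> list[str]:
        return list(self.tn.index)

    @property
    def library_ids(self) -> list[str]:
        return [m.library for m in self.libraries]

    def meta_frame(self) -> pd.DataFrame:
        """Library metadata as a DataFrame indexed by library id."""
        rows = [m.to_dict() for m in self.libraries]
        df = pd.DataFrame(rows).set_index("library")
        df["group_tags"] = [frozenset(t) for t in df["group_tags"]]
        return df

    def counts(self, source: str) -> pd.DataFrame:
        if source == "tn":
            return self.tn
        if source == "reads":
            return self.reads
        raise ValueError(f"source must be 'tn' or 'reads', got {source!r}")

    def totals(self, source: str) -> pd.Series:
        return self.totals_tn if source == "tn" else self.totals_reads


def sites_to_frame(sites: Iterable[InsertionSite] | pd.DataFrame) -> pd.DataFrame:
    """Normalize a site collection to a DataFrame with canonical columns."""
    if isinstance(sites, pd.DataFrame):
        missing = {"chrom", "pos", "strand", "reads", "library"} - set(sites.columns)
        if missing:
            raise ValueError(f"sites frame missing columns: {sorted(missing)}")
        return sites
    return pd.DataFrame(
        [(s.chrom, s.pos, s.strand, s.reads, s.library) for s in sites],
        columns=["chrom", "pos", "strand", "reads", "library"],
    )
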