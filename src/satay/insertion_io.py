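"""Reading and writing SATAY interval data, and per-gene counting.

File dialects honored at the boundary, one internal convention inside:

* BED: 0-based half-open, column 5 = score = read count (absent -> 1).
* WIG: fixed/variableStep, 1-based positions, value = read count.
* GFF3: 1-based inclusive; converted to 0-based half-open on load.

Counting is strand-agnostic: a transposon disrupts a gene regardless of
its orientation, so strand is provenance only.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import yaml

from .models import (
    STRAND_UNKNOWN,
    GeneCountMatrix,
    GeneModel,
    InsertionSite,
    LibraryMeta,
    sites_to_frame,
)

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("#", "track", "browser")


def _merge_sites(records: list[tuple[str, int, str, int]], library_id: str) -> list[InsertionSite]:
    """Merge duplicate (chrom, pos, strand) records by summing reads."""
    merged: dict[tuple[str, int, str], int] = {}
    for chrom, pos, strand, reads in records:
        key = (chrom, pos, strand)
        merged[key] = merged.get(key, 0) + reads
    n_merged = len(records) - len(merged)
    if n_merged:
        logger.info("%s: merged %d duplicate insertion records", library_id, n_merged)
    return [
        InsertionSite(chrom=c, pos=p, strand=s, reads=r, library=library_id)
        for (c, p, s), r in sorted(merged.items())
    ]


def parse_bed(path: str | Path, library_id: str) -> list[InsertionSite]:
    """Parse a BED file of insertion sites (score column = read count).

    Duplicate records at an identical (chrom, pos, strand) are merged by
    summing reads.  A missing or '.' score defaults to 1 read so that
    transposon counting works on minimal 3-column files.
    """
    records: list[tuple[str, int, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start = int(fields[1])
                int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start coordinate")
            reads = 1
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    reads = int(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer score") from exc
                if reads < 0:
                    raise ValueError(f"{path}:{lineno}: negative score")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else STRAND_UNKNOWN
            records.append((chrom, start, strand, reads))
    if not records:
        logger.warning("%s: no insertion records found", path)
    return _merge_sites(records, library_id)


def parse_wig(path: str | Path, library_id: str) -> list[InsertionSite]:
    """Parse a fixed/variableStep WIG file of per-position read counts.

    WIG positions are 1-based and converted to 0-based; strand is unknown.
    Positions with value 0 carry no insertion evidence and are omitted.
    Re-declaring a position already seen is an error (ill-formed input).
    """
    records: list[tuple[str, int, str, int]] = []
    seen: set[tuple[str, int]] = set()
    chrom: str | None = None
    mode: str | None = None
    fixed_pos = 0
    step = 1

    def add(chrom: str, pos1: int, value: float, lineno: int) -> None:
        if value < 0:
            raise ValueError(f"{path}:{lineno}: negative read count")
        if float(value) != int(value):
            raise ValueError(f"{path}:{lineno}: non-integer read count {value}")
        key = (chrom, pos1)
        if key in seen:
            raise ValueError(f"{path}:{lineno}: position {chrom}:{pos1} declared twice")
        seen.add(key)
        if int(value) == 0:
            return
        records.append((chrom, pos1 - 1, STRAND_UNKNOWN, int(value)))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("variableStep", "fixedStep")):
                attrs = dict(tok.split("=", 1) for tok in line.split()[1:])
                if "chrom" not in attrs:
                    raise ValueError(f"{path}:{lineno}: step header lacks chrom=")
                chrom = attrs["chrom"]
                if int(attrs.get("span", 1)) != 1:
                    raise ValueError(f"{path}:{lineno}: only span=1 WIG is supported")
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    fixed_pos = int(attrs["start"])
                    step = int(attrs.get("step", 1))
                else:
                    mode = "variable"
                continue
            if mode is None:
                raise ValueError(f"{path}:{lineno}: data before a variableStep/fixedStep header")
            if mode == "variable":
                toks = line.split()
                if len(toks) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'position value'")
                pos1 = int(toks[0])
                if pos1 < 1:
                    raise ValueError(f"{path}:{lineno}: WIG positions are 1-based (>=1)")
                add(chrom, pos1, float(toks[1]), lineno)
            else:
                add(chrom, fixed_pos, float(line), lineno)
                fixed_pos += step
    if not records:
        logger.warning("%s: no insertion records found", path)
    return _merge_sites(records, library_id)


def load_annotation(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Load gene models from GFF3, converting to 0-based half-open intervals.

    ``gene_id`` is taken from the ID attribute; an optional common name from
    the Name (or gene) attribute.  Duplicate IDs and records lacking an ID
    are errors.
    """
    # Pre-scan raw lines so errors can name line numbers, which the sqlite
    # layer cannot report.
    ids_seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            if cols[2] != feature_type:
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer GFF3 coordinates") from exc
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end < start")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise ValueError(f"{path}:{lineno}: {feature_type} record lacks an ID attribute")
            if attrs["ID"] in ids_seen:
                raise ValueError(f"{path}:{lineno}: duplicate ID {attrs['ID']!r}")
            ids_seen.add(attrs["ID"])

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        common = feat.attributes.get("Name", feat.attributes.get("gene", [None]))[0]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                common_name=common,
            )
        )
    return genes


def count_per_gene(
    sites,
    genes: list[GeneModel],
    libraries: list[LibraryMeta] | None = None,
    truncate_fraction: float = 0.0,
) -> GeneCountMatrix:
    """Count transposons and reads per gene, per library.

    A site with gene.start <= pos < gene.end increments that gene's
    transposon count by 1 and its read count by the site's reads, in the
    site's library; a site inside k overlapping genes increments all k.
    Totals are computed over ALL sites, genic and intergenic.  Sites on
    chromosomes absent from the annotation count only toward the totals
    (warned once per chromosome).

    ``truncate_fraction`` shrinks each gene interval by that fraction of
    its length at both termini before counting (some insertion-screen
    pipelines exclude gene ends where disruption may be tolerated);
    default 0 counts the full interval.
    """
    if not 0.0 <= truncate_fraction < 0.5:
        raise ValueError("truncate_fraction must be in [0, 0.5)")
    if truncate_fraction > 0:
        genes = [
            GeneModel(
                gene_id=g.gene_id,
                chrom=g.chrom,
                start=g.start + int(g.length * truncate_fraction),
                end=g.end - int(g.length * truncate_fraction),
                strand=g.strand,
                common_name=g.common_name,
            )
            for g in genes
        ]
    frame = sites_to_frame(sites)
    if libraries is None:
        libraries = [LibraryMeta(library=lib) for lib in sorted(frame["library"].unique())]
    lib_ids = [m.library for m in libraries]
    unknown_libs = set(frame["library"].unique()) - set(lib_ids)
    if unknown_libs:
        raise ValueError(f"sites reference libraries absent from metadata: {sorted(unknown_libs)}")

    # Merge duplicate (chrom, pos, strand, library) records by summing reads.
    frame = (
        frame.groupby(["library", "chrom", "pos", "strand"], as_index=False)["reads"].sum()
    )

    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene_id in annotation")
    tn = pd.DataFrame(0, index=gene_ids, columns=lib_ids, dtype=np.int64)
    rd = pd.DataFrame(0, index=gene_ids, columns=lib_ids, dtype=np.int64)
    totals_tn = pd.Series(0, index=lib_ids, dtype=np.int64)
    totals_reads = pd.Series(0, index=lib_ids, dtype=np.int64)

    # Per-chromosome gene interval arrays (row indices into the matrices).
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {g.chrom for g in genes}:
        idx = np.array([i for i, g in enumerate(genes) if g.chrom == chrom])
        starts = np.array([genes[i].start for i in idx])
        ends = np.array([genes[i].end for i in idx])
        by_chrom[chrom] = (idx, starts, ends)
    warned: set[str] = set()

    tn_arr = tn.to_numpy()
    rd_arr = rd.to_numpy()
    col_of = {lib: j for j, lib in enumerate(lib_ids)}
    for lib, sub in frame.groupby("library"):
        totals_tn[lib] = len(sub)
        totals_reads[lib] = int(sub["reads"].sum())
        j = col_of[lib]
        for chrom, chrom_sites in sub.groupby("chrom"):
            if chrom not in by_chrom:
                if chrom not in warned:
                    logger.warning(
                        "chromosome %r has insertions but no annotated genes; "
                        "counted toward totals only",
                        chrom,
                    )
                    warned.add(chrom)
                continue
            order = np.argsort(chrom_sites["pos"].to_numpy(), kind="stable")
            pos = chrom_sites["pos"].to_numpy()[order]
            reads = chrom_sites["reads"].to_numpy()[order]
            cum = np.concatenate([[0], np.cumsum(reads)])
            idx, starts, ends = by_chrom[chrom]
            i0 = np.searchsorted(pos, starts, side="left")
            i1 = np.searchsorted(pos, ends, side="left")
            tn_arr[idx, j] += i1 - i0
            rd_arr[idx, j] += cum[i1] - cum[i0]
    tn.loc[:, :] = tn_arr
    rd.loc[:, :] = rd_arr
    return GeneCountMatrix(
        tn=tn, reads=rd, libraries=list(libraries),
        totals_tn=totals_tn, totals_reads=totals_reads,
    )


# ---------------------------------------------------------------------------
# Count-matrix serialization: TSV of per-gene counts plus a YAML sidecar
# carrying library metadata and the all-sites totals.
# ---------------------------------------------------------------------------

def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_count_matrix(matrix: GeneCountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV (one tn/reads column pair per library)
    with a YAML metadata sidecar.  ``read_count_matrix`` is its inverse."""
    for lib in matrix.library_ids:
        if ":" in lib:
            raise ValueError(f"library id {lib!r} may not contain ':'")
    out = pd.DataFrame(index=matrix.tn.index)
    out.index.name = "gene_id"
    for lib in matrix.library_ids:
        out[f"{lib}:tn"] = matrix.tn[lib]
        out[f"{lib}:reads"] = matrix.reads[lib]
    out.to_csv(path, sep="\t", lineterminator="\n")
    meta = {
        "libraries": [m.to_dict() for m in matrix.libraries],
        "totals_tn": {lib: int(matrix.totals_tn[lib]) for lib in matrix.library_ids},
        "totals_reads": {lib: int(matrix.totals_reads[lib]) for lib in matrix.library_ids},
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_count_matrix(path: str | Path) -> GeneCountMatrix:
    with open(_sidecar_path(path)) as fh:
        meta = yaml.safe_load(fh)
    libraries = [LibraryMeta.from_dict(d) for d in meta["libraries"]]
    lib_ids = [m.library for m in libraries]
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    header_libs = []
    for col in df.columns:
        lib, _, kind = col.rpartition(":")
        if kind not in ("tn", "reads"):
            raise ValueError(f"unexpected column {col!r} in count matrix")
        if lib not in header_libs:
            header_libs.append(lib)
    if set(header_libs) != set(lib_ids):
        raise ValueError(
            "library mismatch between count-matrix header and metadata sidecar: "
            f"{sorted(set(header_libs) ^ set(lib_ids))}"
        )
    tn = df[[f"{lib}:tn" for lib in lib_ids]].copy()
    tn.columns = lib_ids
    rd = df[[f"{lib}:reads" for lib in lib_ids]].copy()
    rd.columns = lib_ids
    return GeneCountMatrix(
        tn=tn,
        reads=rd,
        libraries=libraries,
        totals_tn=pd.Series(meta["totals_tn"], dtype=np.int64).reindex(lib_ids),
        totals_reads=pd.Series(meta["totals_reads"], dtype=np.int64).reindex(lib_ids),
    )


# ---------------------------------------------------------------------------
# Writers for the formats the pipeline consumes (used by the simulator).
# ---------------------------------------------------------------------------

def write_bed(sites, path: str | Path) -> None:
    """Write insertion sites as BED (one 1-bp record per site, score = reads)."""
    frame = sites_to_frame(sites).sort_values(["chrom", "pos", "strand"], kind="stable")
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            strand = row.strand if row.strand in ("+", "-") else "+"
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t.\t{row.reads}\t{strand}\n")


def write_wig(sites, path: str | Path) -> None:
    """Write per-position read counts as variableStep WIG (1-based)."""
    frame = sites_to_frame(sites)
    # WIG has no strand: collapse to per-position totals.
    per_pos = frame.groupby(["chrom", "pos"], as_index=False)["reads"].sum()
    with open(path, "w") as fh:
        for chrom, sub in per_pos.groupby("chrom"):
            fh.write(f"variableStep chrom={chrom}\n")
            for row in sub.sort_values("pos").itertuples(index=False):
                fh.write(f"{row.pos + 1} {row.reads}\n")


def write_gff3(genes: list[GeneModel], path: str | Path,
               chrom_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom, length in sorted(chrom_lengths.items()):
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.common_name:
                attrs += f";Name={g.common_name}"
            fh.write(
                f"{g.chrom}\tsatay\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
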