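"""Readers and writers for the plain-text formats the pipeline consumes.

Formats covered: BED3 regions, BED6 read placements, GFF3 / BED6+family
transposon annotations, CX-style per-cytosine methylation reports
(1-based TSV), bedGraph signal tracks, and feature count tables.  SAM is
read through :mod:`pysam` so the same code path handles BAM where an index
is available.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    METHYLATION_CONTEXTS,
    TE_SUPERFAMILIES,
    MethylationCalls,
    ReadPlacements,
    RegionSet,
    TEAnnotation,
    ValidationError,
)


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


# ---------------------------------------------------------------------------
# regions (BED)
# ---------------------------------------------------------------------------

def read_regions_bed(path, label: str = "") -> RegionSet:
    """Read a 3+ column BED file into a :class:`RegionSet` (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if end <= start:
                raise ValidationError(
                    f"{path}: line {lineno}: end <= start ({start}, {end})"
                )
            rows.append((fields[0], start, end))
    return RegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end"]), label=label
    )


def write_regions_bed(regions: RegionSet, path, scores=None) -> None:
    t = regions.table
    with open(path, "w") as fh:
        for i, row in enumerate(t.itertuples(index=False)):
            if scores is not None:
                name = regions.label or "region"
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{name}_{i}\t"
                    f"{scores[i]:.4g}\n"
                )
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


# ---------------------------------------------------------------------------
# TE annotation (GFF3 or BED6+family)
# ---------------------------------------------------------------------------

_FAMILY_ATTRS = ("family", "Family", "superfamily", "Superfamily", "Alias")


def _parse_gff3_attributes(text: str) -> dict:
    attrs = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            key, value = item.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def read_te_annotation(path, format: str = "gff3") -> TEAnnotation:
    """Read a TE annotation.

    ``gff3``: 1-based closed coordinates are converted to 0-based half-open;
    the identifier comes from the ``ID`` attribute and the superfamily from
    the first of ``family``/``Family``/``superfamily``/``Alias`` present.
    ``bed``: BED6 plus a 7th column holding the superfamily label.
    Entries without a family label are kept as ``"Unknown"`` with a warning.
    """
    rows = []
    n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gff3":
                if len(fields) < 9:
                    raise ParseError(
                        f"{path}: line {lineno}: GFF3 needs 9 columns"
                    )
                attrs = _parse_gff3_attributes(fields[8])
                te_id = attrs.get("ID") or attrs.get("Name")
                if te_id is None:
                    raise ParseError(
                        f"{path}: line {lineno}: missing ID attribute"
                    )
                family = next(
                    (attrs[k] for k in _FAMILY_ATTRS if k in attrs), None
                )
                start = int(fields[3]) - 1  # GFF3 is 1-based closed
                end = int(fields[4])
                strand = fields[6] if fields[6] in "+-" else "+"
            elif format == "bed":
                if len(fields) < 7:
                    raise ParseError(
                        f"{path}: line {lineno}: BED6+family needs 7 columns"
                    )
                te_id = fields[3]
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5] if fields[5] in "+-" else "+"
                family = fields[6] or None
            else:
                raise ValueError(f"unknown TE annotation format: {format!r}")
            if family is None:
                family = "Unknown"
                n_unknown += 1
            rows.append((te_id, fields[0], start, end, family, strand))
    if n_unknown:
        warnings.warn(
            f"{path}: {n_unknown} entries without a family label "
            "(labelled 'Unknown')"
        )
    table = pd.DataFrame(
        rows, columns=["te_id", "chrom", "start", "end", "superfamily", "strand"]
    )
    known = set(TE_SUPERFAMILIES)
    extra = set(table["superfamily"].unique()) - known
    if extra:
        warnings.warn(
            f"{path}: superfamilies outside the declared vocabulary: "
            f"{sorted(extra)}"
        )
    return TEAnnotation(table)


def write_te_gff3(tes: TEAnnotation, path, source: str = "rerepseq") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in tes.table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\ttransposable_element\t"
                f"{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t"
                f"ID={row.te_id};family={row.superfamily}\n"
            )


# ---------------------------------------------------------------------------
# read placements (BED6 or SAM)
# ---------------------------------------------------------------------------

def read_placements(
    path,
    format: str = "bed",
    sample_id: str | None = None,
    chrom_sizes: dict | None = None,
) -> ReadPlacements:
    """Read aligned read placements, keeping only the 5'-most base per read.

    For minus-strand BED records the 5' end is ``end - 1``.  SAM records
    flagged unmapped are skipped.  When ``chrom_sizes`` is given, records
    on unknown chromosomes are skipped with a warning giving the count.
    """
    sample_id = sample_id or Path(path).stem
    chroms: list = []
    pos5: list = []
    strands: list = []
    n_skipped_chrom = 0
    if format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ParseError(
                        f"{path}: line {lineno}: BED6 needs 6 columns"
                    )
                chrom = fields[0]
                if chrom_sizes is not None and chrom not in chrom_sizes:
                    n_skipped_chrom += 1
                    continue
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5]
                if strand not in "+-":
                    raise ParseError(
                        f"{path}: line {lineno}: invalid strand {strand!r}"
                    )
                chroms.append(chrom)
                pos5.append(start if strand == "+" else end - 1)
                strands.append(strand)
    elif format == "sam":
        import pysam

        with pysam.AlignmentFile(str(path), check_sq=False) as sam:
            for aln in sam.fetch(until_eof=True):
                if aln.is_unmapped:
                    continue
                chrom = aln.reference_name
                if chrom_sizes is not None and chrom not in chrom_sizes:
                    n_skipped_chrom += 1
                    continue
                if aln.is_reverse:
                    chroms.append(chrom)
                    pos5.append(aln.reference_end - 1)
                    strands.append("-")
                else:
                    chroms.append(chrom)
                    pos5.append(aln.reference_start)
                    strands.append("+")
    else:
        raise ValueError(f"unknown placement format: {format!r}")
    if n_skipped_chrom:
        warnings.warn(
            f"{path}: skipped {n_skipped_chrom} records on unknown chromosomes"
        )
    return ReadPlacements.from_arrays(
        sample_id,
        np.array(chroms, dtype=object),
        np.array(pos5, dtype=np.int64),
        np.array(strands, dtype=object),
    )


def write_placements_bed(reads: ReadPlacements, path) -> None:
    """Write placements as 1-bp BED6 intervals (round-trips through
    :func:`read_placements`)."""
    t = reads.table
    with open(path, "w") as fh:
        for i, row in enumerate(t.itertuples(index=False)):
            fh.write(
                f"{row.chrom}\t{row.pos5}\t{row.pos5 + 1}\t"
                f"{reads.sample_id}_{i}\t0\t{row.strand}\n"
            )


def dedup_placements(
    reads: ReadPlacements, ignore_strand: bool = False
) -> ReadPlacements:
    """Collapse reads mapping to identical positions into single reads.

    Identity is (chrom, pos5, strand) by default; with ``ignore_strand``
    the strand is dropped from the key (the first-seen strand is kept).
    """
    keys = ["chrom", "pos5"] if ignore_strand else ["chrom", "pos5", "strand"]
    table = reads.table.drop_duplicates(subset=keys).reset_index(drop=True)
    return ReadPlacements(reads.sample_id, table)


# ---------------------------------------------------------------------------
# CX methylation report
# ---------------------------------------------------------------------------

def read_cx_report(path) -> MethylationCalls:
    """Read a 6-column CX-style TSV: chrom, pos (1-based), strand, context,
    #C, #T.  Positions are converted to 0-based."""
    try:
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "strand", "context", "count_c", "count_t"],
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "context": str,
                "count_c": np.int64,
                "count_t": np.int64,
            },
            comment="#",
        )
    except pd.errors.EmptyDataError:
        table = pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "count_c", "count_t"]
        )
    if len(table):
        bad = set(table["context"].unique()) - set(METHYLATION_CONTEXTS)
        if bad:
            raise ValidationError(f"{path}: invalid contexts {sorted(bad)}")
        if (table[["count_c", "count_t"]].to_numpy() < 0).any():
            raise ValidationError(f"{path}: negative counts")
        table["pos"] = table["pos"] - 1
    return MethylationCalls(table)


def write_cx_report(calls: MethylationCalls, path) -> None:
    out = calls.table.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bedGraph and chrom sizes
# ---------------------------------------------------------------------------

def write_bedgraph(signal, path) -> None:
    """Serialize a BinnedSignal (one line per bin; NaN bins skipped)."""
    w = signal.bin_width
    with open(path, "w") as fh:
        for chrom in sorted(signal.values):
            v = signal.values[chrom]
            for i, x in enumerate(v):
                if np.isnan(x):
                    continue
                fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{x:.6g}\n")


def read_bedgraph(path, bin_width: int, chrom_sizes: dict):
    """Read a bedGraph whose intervals align to ``bin_width`` bins."""
    from .signal import BinnedSignal

    values = {
        c: np.full(-(-size // bin_width), np.nan)
        for c, size in chrom_sizes.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            start = int(start)
            if start % bin_width:
                raise ParseError(
                    f"{path}: line {lineno}: interval not aligned to "
                    f"{bin_width}-bp bins"
                )
            if chrom not in values:
                raise ParseError(f"{path}: line {lineno}: unknown chrom {chrom}")
            values[chrom][start // bin_width] = float(value)
    return BinnedSignal(values=values, bin_width=bin_width)


def read_chrom_sizes(path) -> dict:
    """Two-column TSV: chrom, length."""
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(chrom_sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def write_count_table(table, path) -> None:
    """Write a CountTable as TSV.  Library sizes go into '# lib_size' header
    comments so the file stays self-contained."""
    with open(path, "w") as fh:
        for sample, size in table.lib_sizes.items():
            fh.write(f"# lib_size\t{sample}\t{int(size)}\n")
        out = table.counts.copy()
        out.insert(0, "length_bp", table.lengths.reindex(out.index))
        out.to_csv(fh, sep="\t", index_label="feature_id")


def read_count_table(path):
    from .expression import CountTable

    lib_sizes = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# lib_size"):
                _, sample, size = line.rstrip("\n").split("\t")
                lib_sizes[sample] = int(size)
                header_lines += 1
            else:
                break
    frame = pd.read_csv(path, sep="\t", skiprows=header_lines, index_col=0)
    lengths = frame.pop("length_bp")
    return CountTable(
        counts=frame.astype(np.int64),
        lengths=lengths.astype(np.int64),
        lib_sizes=pd.Series(lib_sizes, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# FACS events and truth JSON
# ---------------------------------------------------------------------------

def read_facs_tsv(path) -> np.ndarray:
    """One intensity per line (header lines starting with '#' ignored)."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            values.append(float(line.split("\t")[0]))
    return np.asarray(values, dtype=float)


def write_facs_tsv(intensities: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for x in intensities:
            fh.write(f"{x:.4f}\n")


def write_truth_json(truth: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=_default)
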