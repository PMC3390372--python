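"""Core genomic containers shared by every analysis module.

All coordinates are 0-based half-open internally.  File readers convert at
the boundary (GFF3 and CX reports are 1-based on disk; BED is passed
through unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METHYLATION_CONTEXTS = ("CG", "CHG", "CHH")

#: Transposon superfamily vocabulary used by the annotation readers and the
#: simulator.  Unknown labels are accepted with a warning by the readers so
#: that real annotations with richer vocabularies still load.
TE_SUPERFAMILIES = (
    "LTR/Gypsy",
    "LTR/Copia",
    "LINE/L1",
    "DNA/MuDR",
    "DNA/En-Spm",
    "RC/Helitron",
    "Unknown",
)


class ValidationError(ValueError):
    """Raised when an input container or file violates its invariants."""


@dataclass
class ReadPlacements:
    """Deduplicated-or-not uniquely mapped read placements for one library.

    A read is represented only by its 5'-most aligned base and strand;
    fragment length is irrelevant because every downstream statistic counts
    reads per bin rather than per-base coverage.
    """

    sample_id: str
    table: pd.DataFrame  # columns: chrom (str), pos5 (int), strand ("+"/"-")

    def __post_init__(self) -> None:
        required = {"chrom", "pos5", "strand"}
        if not required.issubset(self.table.columns):
            raise ValidationError(
                f"placement table needs columns {sorted(required)}"
            )
        if len(self.table) and (self.table["pos5"].to_numpy() < 0).any():
            raise ValidationError("pos5 must be non-negative")
        bad = set(self.table["strand"].unique()) - {"+", "-"}
        if bad:
            raise ValidationError(f"invalid strand values: {sorted(bad)}")

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        chrom: np.ndarray,
        pos5: np.ndarray,
        strand: np.ndarray,
    ) -> "ReadPlacements":
        return cls(
            sample_id,
            pd.DataFrame(
                {
                    "chrom": np.asarray(chrom, dtype=object),
                    "pos5": np.asarray(pos5, dtype=np.int64),
                    "strand": np.asarray(strand, dtype=object),
                }
            ),
        )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def library_size_millions(self) -> float:
        """Library size in millions of placements (post-dedup by convention)."""
        return len(self.table) / 1e6


@dataclass
class RegionSet:
    """A set of genomic intervals, 0-based half-open, sorted by position."""

    table: pd.DataFrame  # columns: chrom, start, end
    label: str = ""

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"region table needs columns {sorted(required)}")
        if len(self.table):
            starts = self.table["start"].to_numpy()
            ends = self.table["end"].to_numpy()
            if (ends <= starts).any():
                bad = int(np.argmax(ends <= starts))
                raise ValidationError(
                    f"interval with end <= start at row {bad}: "
                    f"{self.table.iloc[bad].tolist()}"
                )
        self.table = (
            self.table.sort_values(["chrom", "start", "end"])
            .reset_index(drop=True)
        )

    @classmethod
    def from_tuples(cls, regions, label: str = "") -> "RegionSet":
        return cls(
            pd.DataFrame(list(regions), columns=["chrom", "start", "end"]),
            label=label,
        )

    def __len__(self) -> int:
        return len(self.table)

    def total_bp(self) -> int:
        merged = self.merge()
        t = merged.table
        return int((t["end"] - t["start"]).sum())

    def merge(self, gap: int = 0) -> "RegionSet":
        """Merge intervals whose gap is <= ``gap`` bp (overlap/adjacency merge
        at gap=0)."""
        if not len(self.table):
            return RegionSet(self.table.copy(), label=self.label)
        rows = []
        for chrom, grp in self.table.groupby("chrom", sort=True):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            cur_s, cur_e = int(starts[0]), int(ends[0])
            for s, e in zip(starts[1:], ends[1:]):
                if s - cur_e <= gap:
                    cur_e = max(cur_e, int(e))
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = int(s), int(e)
            rows.append((chrom, cur_s, cur_e))
        return RegionSet.from_tuples(rows, label=self.label)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: does position i fall inside any interval?"""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.zeros(len(pos), dtype=bool)
        merged = self.merge()
        for c, grp in merged.table.groupby("chrom", sort=False):
            sel = chrom == c
            if not sel.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            idx = np.searchsorted(starts, pos[sel], side="right") - 1
            ok = idx >= 0
            ok[ok] &= pos[sel][ok] < ends[idx[ok]]
            out[sel] = ok
        return out


def intersection_bp(a: RegionSet, b: RegionSet) -> int:
    """Total overlap in bp between two region sets (each merged first)."""
    ta, tb = a.merge().table, b.merge().table
    total = 0
    for chrom in sorted(set(ta["chrom"]) & set(tb["chrom"])):
        ga = ta[ta["chrom"] == chrom]
        gb = tb[tb["chrom"] == chrom]
        sa, ea = ga["start"].to_numpy(), ga["end"].to_numpy()
        sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return total


def region_jaccard(a: RegionSet, b: RegionSet) -> float:
    """Jaccard index of base-pair overlap between two region sets."""
    inter = intersection_bp(a, b)
    union = a.total_bp() + b.total_bp() - inter
    if union == 0:
        return float("nan")
    return inter / union


@dataclass
class TEAnnotation:
    """Transposable-element intervals with identifier and superfamily label."""

    table: pd.DataFrame  # columns: te_id, chrom, start, end, superfamily[, strand]

    def __post_init__(self) -> None:
        required = {"te_id", "chrom", "start", "end", "superfamily"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"TE table needs columns {sorted(required)}")
        if self.table["te_id"].duplicated().any():
            dup = self.table["te_id"][self.table["te_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate te_id: {dup!r}")
        if len(self.table):
            if (self.table["end"].to_numpy() <= self.table["start"].to_numpy()).any():
                raise ValidationError("TE interval with end <= start")
        if "strand" not in self.table.columns:
            self.table = self.table.assign(strand="+")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def te_ids(self) -> list:
        return self.table["te_id"].tolist()

    def lengths_bp(self) -> pd.Series:
        t = self.table
        return pd.Series(
            (t["end"] - t["start"]).to_numpy(), index=t["te_id"], name="length_bp"
        )

    def as_regions(self, label: str = "TE") -> RegionSet:
        return RegionSet(
            self.table[["chrom", "start", "end"]].copy(), label=label
        )


@dataclass
class MethylationCalls:
    """Per-cytosine counts of unconverted (#C) vs converted (#T) reads."""

    table: pd.DataFrame  # columns: chrom, pos, strand, context, count_c, count_t

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand", "context", "count_c", "count_t"}
        if not required.issubset(self.table.columns):
            raise ValidationError(
                f"methylation table needs columns {sorted(required)}"
            )
        if len(self.table):
            bad = set(self.table["context"].unique()) - set(METHYLATION_CONTEXTS)
            if bad:
                raise ValidationError(f"invalid context values: {sorted(bad)}")
            counts = self.table[["count_c", "count_t"]].to_numpy()
            if (counts < 0).any():
                raise ValidationError("negative methylation counts")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)
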