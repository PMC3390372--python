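"""TE/gene expression quantification and derepression calling.

Expression is measured as RPKM.  Differential expression per replicate
pair uses Fisher's exact test on raw counts (feature vs rest-of-library)
with Benjamini-Hochberg correction; a feature is derepressed when the
zero-replaced RPKM ratio exceeds the fold-change cutoff AND the adjusted
p-value is below the significance cutoff in every replicate pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ReadPlacements, TEAnnotation
from .signal import BinnedSignal, bin_counts


@dataclass
class CountTable:
    """Per-feature read counts across sample replicates.

    ``lib_sizes`` holds the total mapped reads per replicate (the RPKM
    denominator), which generally exceeds the column sums because most
    library reads map outside the annotated features.
    """

    counts: pd.DataFrame  # index feature_id, columns sample names
    lengths: pd.Series  # feature_id -> length in bp
    lib_sizes: pd.Series  # sample -> total mapped reads

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.lengths.reindex(self.counts.index) <= 0).any():
            raise ValueError("non-positive feature length")
        if (self.lib_sizes <= 0).any():
            raise ValueError("non-positive library size")

    @property
    def features(self) -> list:
        return self.counts.index.tolist()


def rpkm(count, length_bp, lib_size_reads):
    """Reads per kilobase of feature per million mapped reads."""
    length_bp = np.asarray(length_bp, dtype=float)
    lib = np.asarray(lib_size_reads, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("feature length must be positive")
    if np.any(lib <= 0):
        raise ValueError("library size must be positive")
    return np.asarray(count, dtype=float) / (length_bp / 1e3) / (lib / 1e6)


def rpkm_table(table: CountTable) -> pd.DataFrame:
    lengths = table.lengths.reindex(table.counts.index).to_numpy()
    out = {}
    for sample in table.counts.columns:
        out[sample] = rpkm(
            table.counts[sample].to_numpy(),
            lengths,
            table.lib_sizes[sample],
        )
    return pd.DataFrame(out, index=table.counts.index)


def replace_zeros(values) -> np.ndarray:
    """Replace zeros with the smallest non-zero value of the same sample."""
    v = np.asarray(values, dtype=float).copy()
    nonzero = v[v > 0]
    if len(nonzero) == 0:
        raise ValueError("all values are zero: no floor defined")
    v[v == 0] = nonzero.min()
    return v


# Relative tolerance for probability ties in the two-sided sum: outcomes
# structurally tied with the observed one (mirror tables) must be included
# even though their log-pmf differs by gammaln rounding noise.
_TIE_RTOL = 1e-11


def fisher_de(count_mut, count_wt, lib_mut, lib_wt) -> float:
    """Two-sided Fisher's exact p for one feature between two libraries.

    Table: [[count_mut, lib_mut - count_mut], [count_wt, lib_wt - count_wt]].
    The two-sided p sums, over the hypergeometric support with the table's
    margins fixed, every outcome no more probable than the observed one.
    """
    return float(
        fisher_de_many(
            np.array([count_mut]), np.array([count_wt]), lib_mut, lib_wt
        )[0]
    )


def fisher_de_many(
    counts_mut: np.ndarray, counts_wt: np.ndarray, lib_mut: int, lib_wt: int
) -> np.ndarray:
    """Vectorized two-sided Fisher's exact test, one table per feature.

    Enumerates the hypergeometric support directly (log-space pmf via
    ``gammaln``), which is fast because the support size equals the
    feature's total count across the two libraries, not the library size.
    """
    from scipy.special import gammaln

    a = np.asarray(counts_mut, dtype=np.int64)
    b = np.asarray(counts_wt, dtype=np.int64)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative counts")
    if (a > lib_mut).any() or (b > lib_wt).any():
        raise ValueError("counts exceed library size")
    n_total = lib_mut + lib_wt
    out = np.empty(len(a), dtype=float)
    lg_n = gammaln(n_total + 1)
    lg_libm = gammaln(lib_mut + 1)
    lg_libw = gammaln(lib_wt + 1)
    for i in range(len(a)):
        big_k = int(a[i] + b[i])  # feature margin
        if big_k == 0:
            out[i] = 1.0
            continue
        k = np.arange(max(0, big_k - lib_wt), min(big_k, lib_mut) + 1)
        # log pmf of k successes in the mutant library
        lp = (
            lg_libm
            - gammaln(k + 1)
            - gammaln(lib_mut - k + 1)
            + lg_libw
            - gammaln(big_k - k + 1)
            - gammaln(lib_wt - big_k + k + 1)
            - (lg_n - gammaln(big_k + 1) - gammaln(n_total - big_k + 1))
        )
        lp_obs = lp[int(a[i]) - k[0]]
        include = lp <= lp_obs + _TIE_RTOL
        out[i] = min(1.0, float(np.exp(lp[include]).sum()))
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DerepressionResult:
    per_pair: dict  # (wt_sample, mut_sample) -> DataFrame of per-feature stats
    called: set
    fc_cut: float
    p_cut: float
    use_adjusted: bool

    def frame(self) -> pd.DataFrame:
        """Wide per-feature summary across replicate pairs plus final call."""
        pieces = []
        for (wt_s, mut_s), df in self.per_pair.items():
            pieces.append(df.add_prefix(f"{mut_s}_vs_{wt_s}."))
        out = pd.concat(pieces, axis=1)
        out["derepressed"] = [f in self.called for f in out.index]
        return out


def call_derepressed(
    table: CountTable,
    pairs,
    fc_cut: float = 4.0,
    p_cut: float = 0.01,
    use_adjusted: bool = True,
) -> DerepressionResult:
    """Call consistently derepressed features across replicate pairs.

    ``pairs`` is a list of (wt_sample, mut_sample) column-name pairs;
    a feature is called iff in *every* pair the zero-replaced RPKM ratio
    exceeds ``fc_cut`` and the (BH-adjusted by default) Fisher p-value is
    below ``p_cut``.  Counts are never zero-replaced: the floor applies to
    RPKM only.
    """
    if not pairs:
        raise ValueError("at least one (wt, mut) replicate pair required")
    for wt_s, mut_s in pairs:
        for s in (wt_s, mut_s):
            if s not in table.counts.columns:
                raise ValueError(f"sample {s!r} not in count table")
    rpkms = rpkm_table(table)
    per_pair = {}
    called = set(table.features)
    for wt_s, mut_s in pairs:
        r_wt = replace_zeros(rpkms[wt_s].to_numpy())
        r_mut = replace_zeros(rpkms[mut_s].to_numpy())
        fc = r_mut / r_wt
        lib_wt = int(table.lib_sizes[wt_s])
        lib_mut = int(table.lib_sizes[mut_s])
        c_wt = table.counts[wt_s].to_numpy()
        c_mut = table.counts[mut_s].to_numpy()
        p_raw = fisher_de_many(c_mut, c_wt, lib_mut, lib_wt)
        p_adj = bh_adjust(p_raw)
        df = pd.DataFrame(
            {
                "rpkm_wt": r_wt,
                "rpkm_mut": r_mut,
                "fold_change": fc,
                "p_raw": p_raw,
                "p_adj": p_adj,
            },
            index=table.counts.index,
        )
        per_pair[(wt_s, mut_s)] = df
        p_used = p_adj if use_adjusted else p_raw
        # p_cut >= 1 disables the significance filter (p can equal 1 exactly)
        p_ok = p_used < p_cut if p_cut < 1 else np.ones(len(df), dtype=bool)
        passing = set(df.index[(fc > fc_cut) & p_ok])
        called &= passing
    return DerepressionResult(
        per_pair=per_pair,
        called=called,
        fc_cut=fc_cut,
        p_cut=p_cut,
        use_adjusted=use_adjusted,
    )


class OverlapResult(NamedTuple):
    n_intersection: int
    n_a_only: int
    n_b_only: int
    p_enrichment: float


def overlap_sets(set_a, set_b, universe) -> OverlapResult:
    """Set overlap with an upper-tail hypergeometric enrichment p-value."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    # P(X >= k) for X ~ Hypergeom(N=|U|, K=|A|, n=|B|)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return OverlapResult(k, len(a - b), len(b - a), min(p, 1.0))


def family_composition(feature_ids, tes: TEAnnotation) -> pd.DataFrame:
    """Superfamily counts and fractions of a TE set, sorted by count."""
    ids = list(feature_ids)
    known = set(tes.te_ids)
    missing = [f for f in ids if f not in known]
    if missing:
        raise ValueError(f"features outside the annotation: {missing[:5]}")
    if not ids:
        return pd.DataFrame(columns=["count", "fraction"])
    fam = tes.table.set_index("te_id").loc[ids, "superfamily"]
    counts = fam.value_counts()
    return pd.DataFrame(
        {"count": counts, "fraction": counts / counts.sum()}
    )


def browser_bins(
    reads: ReadPlacements, chrom_sizes: dict, bin_bp: int = 20
) -> BinnedSignal:
    """RPKM-scale expression density in fixed non-overlapping bins."""
    counts = bin_counts(reads, chrom_sizes, bin_bp)
    m = reads.library_size_millions
    kb = bin_bp / 1000.0
    return counts.map(lambda v: v / kb / m, semantics="density")
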