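"""Synthetic genomes, read placements, RNA-seq counts, methylomes and FACS
events with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
multi-chromosome genome with TE-dense pericentromeric heterochromatin
patches; a mutant whose genomic DNA coverage is elevated by a uniform
per-patch copy factor kappa (re-replication seen as aggregate coverage
gain); RNA-seq counts with a planted set of strongly upregulated TEs;
context-specific methylomes elevated inside heterochromatin; and a
mixture of Gaussian ploidy peaks for flow cytometry.  Every generator is
deterministic given its seed, and the planted truth is retained so
downstream callers can be scored without re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    MethylationCalls,
    ReadPlacements,
    RegionSet,
    TEAnnotation,
)
from .expression import CountTable

_BIN = 100  # coverage model granularity (bp); patches align to this grid


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generators.

    Defaults describe a desk-scale genome: two 2.5-Mb chromosomes with ten
    heterochromatin patches of 20-100 kb in total, wild-type coverage of
    50 reads per 100-bp bin, a twofold copy gain in mutant heterochromatin,
    two RNA-seq replicates of 5 million mapped reads with 50 TEs planted
    at 8-fold upregulation, heavily methylated heterochromatin
    (CG 0.8 / CHG 0.4 / CHH 0.1 vs 0.2 / 0.05 / 0.02 outside), and
    10,000 flow-cytometry events over four ploidy peaks of 5% CV.
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 2_500_000
    n_patches: int = 10
    patch_size_range: tuple = (20_000, 100_000)
    min_patch_gap: int = 120_000
    # transposons
    tes_per_mb_in_patch: float = 60.0
    tes_per_mb_outside: float = 12.0
    te_length_range: tuple = (500, 5_000)
    family_proportions: dict = field(
        default_factory=lambda: {
            "LTR/Gypsy": 0.5,
            "LTR/Copia": 0.3,
            "LINE/L1": 0.2,
        }
    )
    # genomic DNA coverage
    mean_coverage: float = 50.0  # reads per 100-bp bin, wild type
    copy_factor: float = 2.0  # kappa: coverage multiplier in mutant patches
    # RNA-seq
    n_replicates: int = 2
    lib_size: int = 5_000_000  # total mapped reads per replicate
    n_planted: int = 50
    planted_fc: float = 8.0
    dispersion: float = 0.05  # NB overdispersion (0 -> Poisson)
    silent_fraction: float = 0.3  # TEs with zero baseline expression
    baseline_log_mean: float = np.log(2.0)  # lognormal baseline RPKM
    baseline_log_sd: float = 1.2
    # methylome
    meth_depth: int = 20
    meth_means: dict = field(
        default_factory=lambda: {
            "CG": (0.8, 0.2),  # (heterochromatin, euchromatin)
            "CHG": (0.4, 0.05),
            "CHH": (0.1, 0.02),
        }
    )
    sites_per_kb: float = 2.0  # cytosines simulated per kb per context
    # flow cytometry
    facs_peak_means: tuple = (100.0, 200.0, 400.0, 800.0)
    facs_peak_cvs: tuple = (5.0, 5.0, 5.0, 5.0)
    facs_peak_weights: tuple = (0.35, 0.30, 0.20, 0.15)
    facs_n_events: int = 10_000

    def validate(self) -> None:
        if self.chrom_length <= 0 or self.n_chroms < 1:
            raise ValueError("invalid genome dimensions")
        if self.mean_coverage <= 0 or self.copy_factor < 1:
            raise ValueError("mean coverage must be > 0 and kappa >= 1")
        props = sum(self.family_proportions.values())
        if abs(props - 1.0) > 1e-9:
            raise ValueError("family proportions must sum to 1")
        for ctx, (het, eu) in self.meth_means.items():
            if not (0 <= het <= 1 and 0 <= eu <= 1):
                raise ValueError(f"methylation means for {ctx} outside [0,1]")
        if any(cv <= 0 for cv in self.facs_peak_cvs):
            raise ValueError("FACS peak CVs must be positive")


def expression_study_config(seed: int = 0, n_planted: int = 50) -> SimConfig:
    """Annotation-scale genome (~2,000 TEs over 50 Mb) for RNA-seq
    derepression-recovery studies; DNA coverage is not meant to be
    simulated at this scale."""
    return SimConfig(
        seed=seed,
        n_chroms=5,
        chrom_length=10_000_000,
        n_patches=10,
        tes_per_mb_in_patch=100.0,
        tes_per_mb_outside=40.0,
        n_planted=n_planted,
    )


@dataclass
class GenomeModel:
    """Synthetic genome plus the planted truth used to score callers."""

    chrom_sizes: dict
    het_patches: RegionSet
    te_annotation: TEAnnotation
    truth: dict
    config: SimConfig


def _spawn(seed: int, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_genome(config: SimConfig, seed: int | None = None) -> GenomeModel:
    """Lay out chromosomes, heterochromatin patches and TE annotation.

    Patch coordinates are aligned to the 100-bp coverage grid.  TEs are
    placed at higher density inside patches; superfamilies are drawn from
    the configured proportions.  The truth records per-patch copy factors,
    baseline TE expression and the planted upregulated TE set.
    """
    config.validate()
    rng = _spawn(config.seed if seed is None else seed, 0)
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    chrom_names = list(chrom_sizes)

    # --- heterochromatin patches, round-robin over chromosomes ---
    lo, hi = config.patch_size_range
    sizes = rng.integers(lo // _BIN, hi // _BIN + 1, size=config.n_patches) * _BIN
    per_chrom: dict = {c: [] for c in chrom_names}
    for i, s in enumerate(sizes):
        per_chrom[chrom_names[i % len(chrom_names)]].append(int(s))
    patch_rows = []
    for chrom in chrom_names:
        chrom_patches = per_chrom[chrom]
        if not chrom_patches:
            continue
        k = len(chrom_patches)
        need = sum(chrom_patches) + (k + 1) * config.min_patch_gap
        if need > chrom_sizes[chrom]:
            raise ValueError(
                f"patches do not fit on {chrom}: need {need} bp of "
                f"{chrom_sizes[chrom]}"
            )
        free = chrom_sizes[chrom] - sum(chrom_patches) - (k + 1) * config.min_patch_gap
        # distribute the leftover space as random extra gaps
        extra = rng.multinomial(free // _BIN, np.ones(k + 1) / (k + 1)) * _BIN
        pos = 0
        for j, size in enumerate(chrom_patches):
            pos += config.min_patch_gap + int(extra[j])
            start = (pos // _BIN) * _BIN
            patch_rows.append((chrom, start, start + size))
            pos = start + size
    het_patches = RegionSet.from_tuples(patch_rows, label="heterochromatin")

    # --- transposons ---
    te_rows = []
    te_counter = 0
    families = list(config.family_proportions)
    probs = np.array([config.family_proportions[f] for f in families])
    t_lo, t_hi = config.te_length_range
    for chrom in chrom_names:
        patches = het_patches.table[het_patches.table["chrom"] == chrom]
        patch_bp = int((patches["end"] - patches["start"]).sum())
        out_bp = chrom_sizes[chrom] - patch_bp
        n_in = rng.poisson(config.tes_per_mb_in_patch * patch_bp / 1e6)
        n_out = rng.poisson(config.tes_per_mb_outside * out_bp / 1e6)
        starts_in = []
        for p in patches.itertuples(index=False):
            w = (p.end - p.start) / max(patch_bp, 1)
            n_p = int(round(n_in * w))
            starts_in.extend(
                rng.integers(p.start, max(p.end - t_lo, p.start + 1), size=n_p)
            )
        starts_out = rng.integers(0, chrom_sizes[chrom] - t_hi, size=n_out)
        # crude rejection of outside starts that fall into a patch
        if len(patches):
            mask = het_patches.contains(
                np.array([chrom] * len(starts_out), dtype=object),
                np.asarray(starts_out, dtype=np.int64),
            )
            starts_out = np.asarray(starts_out)[~mask]
        for start in list(starts_in) + list(starts_out):
            length = int(rng.integers(t_lo, t_hi + 1))
            end = min(int(start) + length, chrom_sizes[chrom])
            if end <= start:
                continue
            te_counter += 1
            te_rows.append(
                (
                    f"TE{te_counter:05d}",
                    chrom,
                    int(start),
                    end,
                    families[rng.choice(len(families), p=probs)],
                    "+" if rng.random() < 0.5 else "-",
                )
            )
    te_table = pd.DataFrame(
        te_rows,
        columns=["te_id", "chrom", "start", "end", "superfamily", "strand"],
    )
    tes = TEAnnotation(te_table)

    # --- planted expression truth ---
    n_tes = len(te_table)
    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_tes)
    )
    silent = rng.random(n_tes) < config.silent_fraction
    baseline[silent] = 0.0
    expressed = np.flatnonzero(~silent)
    # planted TEs need a real baseline: an 8-fold gain of nothing is nothing
    floor = np.median(baseline[expressed]) if len(expressed) else 0.0
    eligible = np.flatnonzero(baseline >= floor)
    n_planted = min(config.n_planted, len(eligible))
    planted_idx = rng.choice(eligible, size=n_planted, replace=False)
    planted_ids = te_table["te_id"].to_numpy()[planted_idx].tolist()

    truth = {
        "patch_copy_factor": {
            f"{r.chrom}:{r.start}-{r.end}": config.copy_factor
            for r in het_patches.table.itertuples(index=False)
        },
        "baseline_rpkm": dict(
            zip(te_table["te_id"], baseline.round(6).tolist())
        ),
        "planted_te_ids": sorted(planted_ids),
        "planted_fc": config.planted_fc,
        "meth_means": {k: list(v) for k, v in config.meth_means.items()},
    }
    return GenomeModel(
        chrom_sizes=chrom_sizes,
        het_patches=het_patches,
        te_annotation=tes,
        truth=truth,
        config=config,
    )


def simulate_dna_reads(
    genome: GenomeModel,
    sample: str,
    mean_coverage: float | None = None,
    copy_factor: float | None = None,
    seed: int = 0,
) -> ReadPlacements:
    """Poisson read placements per 100-bp bin, duplicate-free.

    The per-bin count is Poisson with mean ``mean_coverage`` outside
    heterochromatin and ``copy_factor * mean_coverage`` inside (mutant
    only).  Positions within a bin are sampled uniformly *without
    replacement* over the (position, strand) slots, so deduplication is a
    no-op and the planted coverage is exact.
    """
    if sample not in ("wt", "mutant"):
        raise ValueError("sample must be 'wt' or 'mutant'")
    cfg = genome.config
    mean_coverage = cfg.mean_coverage if mean_coverage is None else mean_coverage
    copy_factor = cfg.copy_factor if copy_factor is None else copy_factor
    if copy_factor < 1:
        raise ValueError("copy factor must be >= 1")
    rng = _spawn(seed, 1 if sample == "wt" else 2)
    slots = 2 * _BIN  # positions x strands per bin
    chroms_out = []
    pos_out = []
    strand_out = []
    for chrom, size in genome.chrom_sizes.items():
        n_bins = size // _BIN
        lam = np.full(n_bins, float(mean_coverage))
        if sample == "mutant":
            patches = genome.het_patches.table
            for p in patches[patches["chrom"] == chrom].itertuples(index=False):
                lam[p.start // _BIN : p.end // _BIN] *= copy_factor
        counts = np.minimum(rng.poisson(lam), slots)
        # rank random keys to draw per-bin slots without replacement
        keys = rng.random((n_bins, slots))
        order = np.argsort(keys, axis=1)
        take = np.arange(slots)[None, :] < counts[:, None]
        chosen = order[take]  # row-major: first counts[i] slots of bin i
        bin_starts = np.repeat(np.arange(n_bins, dtype=np.int64) * _BIN, counts)
        pos_out.append(bin_starts + chosen % _BIN)
        strand_out.append(np.where(chosen // _BIN == 0, "+", "-"))
        chroms_out.append(np.full(int(counts.sum()), chrom, dtype=object))
    return ReadPlacements.from_arrays(
        f"{sample}_gdna",
        np.concatenate(chroms_out),
        np.concatenate(pos_out),
        np.concatenate(strand_out).astype(object),
    )


def simulate_rnaseq_counts(
    genome: GenomeModel,
    n_replicates: int | None = None,
    lib_sizes=None,
    planted_fc: float | None = None,
    dispersion: float | None = None,
    seed: int = 0,
) -> CountTable:
    """Negative-binomial TE counts for paired WT/mutant replicates.

    Expected count for TE i in library j is
    ``baseline_rpkm_i * length_kb_i * lib_size_j / 1e6`` (times the planted
    fold change for planted TEs in mutant libraries), so the expected
    mutant/WT RPKM ratio equals the planted fold change exactly.  Counts
    are Poisson-gamma with the configured dispersion (0 gives Poisson).
    """
    cfg = genome.config
    n_replicates = cfg.n_replicates if n_replicates is None else n_replicates
    planted_fc = cfg.planted_fc if planted_fc is None else planted_fc
    dispersion = cfg.dispersion if dispersion is None else dispersion
    if lib_sizes is None:
        lib_sizes = [cfg.lib_size] * (2 * n_replicates)
    lib_sizes = list(lib_sizes)
    if len(lib_sizes) != 2 * n_replicates:
        raise ValueError("need one library size per WT and mutant replicate")
    rng = _spawn(seed, 3)
    te_table = genome.te_annotation.table
    te_ids = te_table["te_id"].to_numpy()
    lengths_kb = (te_table["end"] - te_table["start"]).to_numpy() / 1000.0
    baseline = np.array(
        [genome.truth["baseline_rpkm"][t] for t in te_ids], dtype=float
    )
    planted = np.isin(te_ids, genome.truth["planted_te_ids"])
    samples = [f"wt_{i + 1}" for i in range(n_replicates)] + [
        f"mut_{i + 1}" for i in range(n_replicates)
    ]
    counts = {}
    for j, sample in enumerate(samples):
        lam = baseline * lengths_kb * (lib_sizes[j] / 1e6)
        if sample.startswith("mut"):
            lam = lam * np.where(planted, planted_fc, 1.0)
        if dispersion > 0:
            shape = 1.0 / dispersion
            lam_pos = np.where(lam > 0, lam, 0.0)
            rate = rng.gamma(shape, 1.0, size=len(lam)) / shape * lam_pos
            counts[sample] = rng.poisson(rate)
        else:
            counts[sample] = rng.poisson(lam)
    return CountTable(
        counts=pd.DataFrame(counts, index=te_ids, dtype=np.int64),
        lengths=pd.Series(
            (te_table["end"] - te_table["start"]).to_numpy(),
            index=te_ids,
            dtype=np.int64,
        ),
        lib_sizes=pd.Series(dict(zip(samples, lib_sizes)), dtype=np.int64),
    )


def simulate_methylome(
    genome: GenomeModel,
    depth: int | None = None,
    means: dict | None = None,
    sites_per_kb: float | None = None,
    seed: int = 0,
) -> MethylationCalls:
    """Binomial per-cytosine methylation calls, context- and
    compartment-specific.

    ``count_c ~ Binomial(depth, mean[context][compartment])`` where the
    compartment is heterochromatin inside patches, euchromatin outside.
    """
    cfg = genome.config
    depth = cfg.meth_depth if depth is None else depth
    means = cfg.meth_means if means is None else means
    sites_per_kb = cfg.sites_per_kb if sites_per_kb is None else sites_per_kb
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _spawn(seed, 4)
    contexts = list(means)
    frames = []
    for chrom, size in genome.chrom_sizes.items():
        n_per_ctx = int(size / 1000 * sites_per_kb)
        n_total = n_per_ctx * len(contexts)
        if n_total == 0:
            continue
        pos = rng.choice(size, size=min(n_total, size), replace=False)
        pos.sort()
        ctx = np.repeat(contexts, n_per_ctx)[: len(pos)]
        rng.shuffle(ctx)
        strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        in_het = genome.het_patches.contains(
            np.full(len(pos), chrom, dtype=object), pos
        )
        p = np.empty(len(pos))
        for c in contexts:
            het_mean, eu_mean = means[c]
            sel = ctx == c
            p[sel] = np.where(in_het[sel], het_mean, eu_mean)
        count_c = rng.binomial(depth, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "strand": strand,
                    "context": ctx,
                    "count_c": count_c.astype(np.int64),
                    "count_t": (depth - count_c).astype(np.int64),
                }
            )
        )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "count_c", "count_t"]
        )
    return MethylationCalls(table)


def simulate_facs(
    peak_means=None,
    peak_cvs=None,
    peak_weights=None,
    n_events: int | None = None,
    seed: int = 0,
    config: SimConfig | None = None,
):
    """Gaussian-mixture ploidy-peak intensities.

    Component standard deviation is ``cv * mean / 100``.  Returns
    ``(intensities, labels)`` with the component index of every event kept
    as ground truth.
    """
    cfg = config or SimConfig()
    peak_means = np.asarray(
        cfg.facs_peak_means if peak_means is None else peak_means, dtype=float
    )
    peak_cvs = np.asarray(
        cfg.facs_peak_cvs if peak_cvs is None else peak_cvs, dtype=float
    )
    peak_weights = np.asarray(
        cfg.facs_peak_weights if peak_weights is None else peak_weights,
        dtype=float,
    )
    n_events = cfg.facs_n_events if n_events is None else n_events
    if (peak_cvs <= 0).any():
        raise ValueError("peak CVs must be positive")
    if len(peak_means) != len(peak_cvs) or len(peak_means) != len(peak_weights):
        raise ValueError("peak parameter lengths differ")
    rng = _spawn(seed, 5)
    if n_events == 0:
        return np.array([], dtype=float), np.array([], dtype=np.int64)
    weights = peak_weights / peak_weights.sum()
    labels = rng.choice(len(peak_means), size=n_events, p=weights)
    sds = peak_cvs * peak_means / 100.0
    intensities = rng.normal(peak_means[labels], sds[labels])
    intensities = np.clip(intensities, 1e-6, None)
    return intensities, labels


def simulate_all(config: SimConfig, outdir) -> GenomeModel:
    """Run every generator and write the io_formats files plus truth JSON."""
    from pathlib import Path

    from . import io as rio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    wt = simulate_dna_reads(genome, "wt", seed=config.seed)
    mut = simulate_dna_reads(genome, "mutant", seed=config.seed)
    counts = simulate_rnaseq_counts(genome, seed=config.seed)
    meth = simulate_methylome(genome, seed=config.seed)
    intens, labels = simulate_facs(config=config, seed=config.seed)

    rio.write_chrom_sizes(genome.chrom_sizes, outdir / "chrom.sizes")
    rio.write_regions_bed(genome.het_patches, outdir / "het_patches.bed")
    rio.write_te_gff3(genome.te_annotation, outdir / "tes.gff3")
    rio.write_placements_bed(wt, outdir / "wt_gdna.bed")
    rio.write_placements_bed(mut, outdir / "mut_gdna.bed")
    rio.write_count_table(counts, outdir / "te_counts.tsv")
    rio.write_cx_report(meth, outdir / "methylation.cx.tsv")
    rio.write_facs_tsv(intens, outdir / "facs_events.tsv")
    truth = dict(genome.truth)
    truth["facs_labels"] = labels
    rio.write_truth_json(truth, outdir / "truth.json")
    return genome
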