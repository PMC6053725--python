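"""Synthetic datasets with planted mark-to-expression associations.

Generates a small genome annotation, per-track read intervals, peak calls,
replicated expression tables and a truth label table, so that the whole
pipeline is testable without any external download. A planted subset of
genes is differentially expressed between the two conditions, and the same
genes carry a coverage shift (``effect_size`` on the log2 scale) in the
responsive genotype and the informative marks only.

Read counts per gene are negative binomial (ChIP-seq tag counts are
overdispersed); reads are fixed-length intervals placed uniformly within
the gene's enriched window; no sequence content is simulated.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from chipdeg import io
from chipdeg.peaks import Peak
from chipdeg.segments import GeneModel
from chipdeg.util import round_half_up


@dataclass
class SimulationConfig:
    n_genes: int = 1000
    n_chromosomes: int = 2
    genotypes: tuple[str, ...] = ("C", "e")
    marks: tuple[str, ...] = ("K9", "K14", "K23")
    conditions: tuple[str, str] = ("A", "C")
    frac_up: float = 0.15
    frac_down: float = 0.15
    effect_size: float = 2.0
    informative_marks: Optional[tuple[str, ...]] = None
    responsive_genotype: str = "C"
    read_depth: int = 50000
    noise_dispersion: float = 0.1
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.genotypes = tuple(self.genotypes)
        self.marks = tuple(self.marks)
        self.conditions = tuple(self.conditions)
        if self.n_genes <= 0 or self.n_chromosomes <= 0:
            raise ValueError("n_genes and n_chromosomes must be positive")
        if not self.marks:
            raise ValueError("mark list must not be empty")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.informative_marks is None:
            self.informative_marks = self.marks
        else:
            self.informative_marks = tuple(self.informative_marks)
        if not set(self.informative_marks) <= set(self.marks):
            raise ValueError("informative_marks must be a subset of marks")
        if self.responsive_genotype not in self.genotypes:
            raise ValueError("responsive_genotype must be one of the genotypes")
        if self.read_depth <= 0 or self.noise_dispersion <= 0:
            raise ValueError("read_depth and noise_dispersion must be positive")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SyntheticBundle:
    """In-memory result of :func:`generate_dataset`."""

    config: SimulationConfig
    genes: list[GeneModel]
    chromosome_lengths: dict[str, int]
    # (genotype, mark, condition) -> (chroms, starts, ends)
    reads: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray, np.ndarray]]
    peaks: dict[tuple[str, str, str], list[Peak]]
    expression: dict[str, pd.DataFrame]
    truth: pd.DataFrame
    enrichment: pd.DataFrame = field(repr=False, default=None)

    def read_tracks(self) -> dict[tuple[str, str, str], io.ReadTrack]:
        return {
            key: io.ReadTrack.from_intervals(chroms, starts, ends)
            for key, (chroms, starts, ends) in self.reads.items()
        }


def _track_keys(config: SimulationConfig) -> list[tuple[str, str, str]]:
    return [
        (g, m, c)
        for g in config.genotypes
        for m in config.marks
        for c in config.conditions
    ]


def _make_genes(config: SimulationConfig, rng: np.random.Generator):
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    idx = 0
    for ci, count in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = 2000
        for _ in range(count):
            n_exons = int(rng.integers(1, 6))
            exon_lens = rng.integers(200, 801, n_exons)
            intron_lens = rng.integers(100, 501, max(0, n_exons - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            cursor = pos
            for j in range(n_exons):
                exons.append((cursor, cursor + int(exon_lens[j])))
                cursor = exons[-1][1]
                if j < n_exons - 1:
                    cursor += int(intron_lens[j])
            start, end = exons[0][0], exons[-1][1]
            d1 = int(rng.integers(30, 150))
            d2 = int(rng.integers(30, 150))
            d2 = min(d2, end - start - d1 - 10)  # keep CDS non-empty
            genes.append(
                GeneModel(
                    gene_id=f"g{idx:05d}",
                    transcript_id=f"g{idx:05d}.1",
                    chromosome=chrom,
                    strand=strand,
                    exons=tuple(exons),
                    cds_start=start + d1,
                    cds_end=end - d2,
                )
            )
            idx += 1
            # intergenic gap >= 3 kb keeps nearest-gene assignment unambiguous
            pos = end + 3000 + int(rng.integers(0, 2001))
        chrom_lengths[chrom] = pos + 3000
    return genes, chrom_lengths


def _plant_labels(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n_up = round_half_up(config.frac_up * config.n_genes)
    n_down = round_half_up(config.frac_down * config.n_genes)
    labels = np.array(["none"] * config.n_genes, dtype=object)
    perm = rng.permutation(config.n_genes)
    labels[perm[:n_up]] = "up"
    labels[perm[n_up : n_up + n_down]] = "down"
    return labels


def _negative_binomial(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, dispersion) with variance ``mean + dispersion * mean**2``."""
    r = 1.0 / dispersion
    p = r / (r + np.maximum(means, 1e-12))
    return rng.negative_binomial(r, p)


def generate_dataset(config: SimulationConfig) -> SyntheticBundle:
    """Deterministic synthetic bundle; every stochastic component draws from
    an independent stream derived from the master seed."""
    root = np.random.SeedSequence(config.seed)
    n_streams = 4 + len(_track_keys(config)) + len(config.genotypes)
    children = root.spawn(n_streams)
    it = iter(children)
    rng_genes = np.random.default_rng(next(it))
    rng_labels = np.random.default_rng(next(it))
    rng_weights = np.random.default_rng(next(it))
    _rng_spare = np.random.default_rng(next(it))

    genes, chrom_lengths = _make_genes(config, rng_genes)
    labels = _plant_labels(config, rng_labels)
    gene_ids = [g.gene_id for g in genes]
    up_mask = labels == "up"
    down_mask = labels == "down"

    # per gene x mark base enrichment, shared across genotypes/conditions
    enrich = pd.DataFrame(
        rng_weights.lognormal(mean=0.0, sigma=0.5, size=(config.n_genes, len(config.marks))),
        index=gene_ids,
        columns=list(config.marks),
    )

    genome_size = sum(chrom_lengths.values())
    reads: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    peaks: dict[tuple[str, str, str], list[Peak]] = {}
    for key in _track_keys(config):
        g, m, cond = key
        rng = np.random.default_rng(next(it))
        mult = np.ones(config.n_genes)
        if (
            g == config.responsive_genotype
            and m in config.informative_marks
            and cond == config.conditions[1]
        ):
            mult[up_mask] = 2.0**config.effect_size
            mult[down_mask] = 2.0**-config.effect_size
        lam = enrich[m].to_numpy() * mult
        fg_total = 0.9 * config.read_depth
        means = fg_total * lam / lam.sum()
        counts = _negative_binomial(rng, means, config.noise_dispersion)

        chroms_out: list[str] = []
        starts_out: list[np.ndarray] = []
        track_peaks: list[Peak] = []
        bg_density = 0.1 * config.read_depth / genome_size
        for gi, gene in enumerate(genes):
            win_lo = max(0, gene.start - 1500)
            win_hi = min(chrom_lengths[gene.chromosome], gene.end + 200)
            k = int(counts[gi])
            if k > 0:
                starts = rng.integers(
                    win_lo, max(win_lo + 1, win_hi - config.read_length), k
                )
                starts_out.append(np.sort(starts))
                chroms_out.extend([gene.chromosome] * k)
            density = k / (win_hi - win_lo)
            fe = density / bg_density if bg_density > 0 else 0.0
            if fe > 2.0:
                track_peaks.append(
                    Peak(
                        chromosome=gene.chromosome,
                        start=max(0, gene.tss - 200) if gene.strand == "+" else gene.tss - 500,
                        end=gene.tss + 500 if gene.strand == "+" else gene.tss + 200,
                        name=f"{g}{m}{cond}_{gene.gene_id}",
                        fold_enrichment=fe,
                    )
                )
        # uniform background reads across the genome
        bg_n = config.read_depth - int(fg_total)
        bg_chrom_names = sorted(chrom_lengths)
        bg_sizes = np.array([chrom_lengths[c] for c in bg_chrom_names], dtype=float)
        bg_counts = rng.multinomial(bg_n, bg_sizes / bg_sizes.sum())
        for cname, bc in zip(bg_chrom_names, bg_counts):
            if bc > 0:
                starts = rng.integers(0, chrom_lengths[cname] - config.read_length, bc)
                starts_out.append(np.sort(starts))
                chroms_out.extend([cname] * int(bc))
        all_starts = (
            np.concatenate(starts_out) if starts_out else np.empty(0, dtype=np.int64)
        )
        all_chroms = np.asarray(chroms_out, dtype=object)
        order = np.lexsort((all_starts, all_chroms))
        all_chroms, all_starts = all_chroms[order], all_starts[order]
        reads[key] = (all_chroms, all_starts, all_starts + config.read_length)
        peaks[key] = sorted(track_peaks, key=lambda p: (p.chromosome, p.start))

    # expression tables: planted fold changes in the responsive genotype only
    cond_a, cond_c = config.conditions
    expression: dict[str, pd.DataFrame] = {}
    for genotype in config.genotypes:
        rng = np.random.default_rng(next(it))
        base = rng.lognormal(mean=math.log(3.0), sigma=1.0, size=config.n_genes)
        planted = up_mask | down_mask
        base[planted] = np.maximum(base[planted], rng.uniform(3.0, 10.0, planted.sum()))
        if genotype == config.responsive_genotype:
            shift = rng.uniform(1.2, 2.8, config.n_genes)
            log2fc = np.where(up_mask, shift, np.where(down_mask, -shift, 0.0))
            wobble = rng.uniform(-0.45, 0.45, config.n_genes)
            log2fc = np.where(planted, log2fc, wobble)
        else:
            log2fc = rng.uniform(-0.3, 0.3, config.n_genes)
        mean_a = base
        mean_c = base * 2.0**log2fc
        table = {}
        for cond, mean in ((cond_a, mean_a), (cond_c, mean_c)):
            for rep in (1, 2):
                noise = rng.lognormal(mean=0.0, sigma=0.05, size=config.n_genes)
                table[f"rpkm_rep{rep}_{cond}"] = mean * noise
        expression[genotype] = pd.DataFrame(
            table, index=pd.Index(gene_ids, name="gene_id")
        )

    truth = pd.DataFrame({"label": labels}, index=pd.Index(gene_ids, name="gene_id"))
    return SyntheticBundle(
        config=config,
        genes=genes,
        chromosome_lengths=chrom_lengths,
        reads=reads,
        peaks=peaks,
        expression=expression,
        truth=truth,
        enrichment=enrich,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | os.PathLike) -> Path:
    """Write the bundle in standard formats plus a ready-to-run pipeline
    config (``pipeline.yaml``); byte-identical for identical config+seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config

    io.write_gff3(bundle.genes, out / "annotation.gff3")
    io.write_bed12(bundle.genes, out / "annotation.bed12")

    track_files: dict[str, dict[str, dict[str, str]]] = {}
    peak_files: dict[str, dict[str, dict[str, str]]] = {}
    for (g, m, c), (chroms, starts, ends) in bundle.reads.items():
        fname = f"reads_{g}{m}{c}.bed"
        io.write_reads_bed(out / fname, chroms, starts, ends)
        track_files.setdefault(g, {}).setdefault(m, {})[c] = fname
    for (g, m, c), track_peaks in bundle.peaks.items():
        fname = f"peaks_{g}{m}{c}.narrowPeak"
        io.write_narrowpeak(track_peaks, out / fname)
        peak_files.setdefault(g, {}).setdefault(m, {})[c] = fname

    expr_files = {}
    for genotype, table in bundle.expression.items():
        fname = f"expression_{genotype}.tsv"
        io.write_expression(table, out / fname)
        expr_files[genotype] = fname
    io.write_label_table(bundle.truth, out / "truth_labels.tsv")

    pipeline_cfg = {
        "annotation": "annotation.gff3",
        "tracks": track_files,
        "peaks": peak_files,
        "expression": expr_files,
        "truth": "truth_labels.tsv",
        "genotypes": list(cfg.genotypes),
        "marks": list(cfg.marks),
        "conditions": list(cfg.conditions),
        "responsive_genotype": cfg.responsive_genotype,
        "seed": cfg.seed,
        "simulation": asdict(cfg),
    }
    with open(out / "pipeline.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    return out


def simulate_feature_matrix(
    n_genes: int = 1000,
    n_features: int = 100,
    n_informative: int = 10,
    effect_size: float = 2.0,
    seed: int = 0,
    class_balance: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature-matrix-level synthetic instance for classifier benchmarking.

    Informative features are shifted by ``+effect_size/2`` for up genes and
    ``-effect_size/2`` for down genes on top of unit Gaussian noise; the rest
    are pure noise. Labels are up/down only (the classification task of the
    pipeline is among differentially expressed genes).
    """
    if not 0 <= n_informative <= n_features:
        raise ValueError("n_informative must be within [0, n_features]")
    rng = np.random.default_rng(seed)
    n_up = round_half_up(class_balance * n_genes)
    y = np.array(["up"] * n_up + ["down"] * (n_genes - n_up), dtype=object)
    rng.shuffle(y)
    X = rng.normal(size=(n_genes, n_features))
    signal = np.where(y == "up", effect_size / 2.0, -effect_size / 2.0)
    X[:, :n_informative] += signal[:, None]
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    cols = [f"inf{j:03d}" for j in range(n_informative)] + [
        f"noise{j:03d}" for j in range(n_features - n_informative)
    ]
    return (
        pd.DataFrame(X, index=pd.Index(gene_ids, name="gene_id"), columns=cols),
        pd.Series(y, index=gene_ids, name="label"),
    )
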