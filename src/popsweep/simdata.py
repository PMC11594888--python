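"""Two-population genotype/phenotype simulator.

Per-variant ancestral frequencies are drawn Uniform(0.05, 0.95); each
population's frequency comes from the Balding-Nichols Beta with mean equal
to the ancestral frequency and dispersion set by the background Fst
(alpha = p(1-F)/F, beta = (1-p)(1-F)/F).  Inside a configured sweep region
the focal population's frequency is pushed toward fixation by the
differentiation boost, which depletes diversity there and inflates Fst.
Diploid genotypes are binomial(2, frequency); sites are independent (no
linkage).  Leg length is additive in the causal SNP dosage plus Gaussian
noise, and height minus chest depth reproduces it exactly.

All randomness flows from a single generator seeded once, so identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GeneModel, write_gff3
from .variants import GenotypeMatrix, MISSING, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    focal_pop: str  # "TL" or "SL"
    boost: float  # differentiation boost in (0, 1]


@dataclass
class CausalSnp:
    chrom: str
    pos: int
    effect: float  # cm per alt allele


@dataclass
class SimConfig:
    n_tall: int = 15
    n_short: int = 15
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_variants: int = 20_000
    background_fst: float = 0.03
    sweep_regions: list[SweepRegion] = field(
        default_factory=lambda: [
            SweepRegion("chr1", 1_000_001, 1_150_000, "SL", 0.9),
            SweepRegion("chr2", 2_000_001, 2_150_000, "SL", 0.9),
            SweepRegion("chr2", 3_500_001, 3_650_000, "SL", 0.9),
        ]
    )
    causal_snp: CausalSnp = field(
        default_factory=lambda: CausalSnp("chr1", 2_500_001, 3.0)
    )
    pheno_mean: float = 28.0
    pheno_sd: float = 1.0
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if self.n_tall <= 0 or self.n_short <= 0:
            raise ValueError("both populations must be nonempty")
        if not 0.0 < self.background_fst < 1.0:
            raise ValueError("background_fst must lie in (0, 1)")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        for r in self.sweep_regions:
            if r.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep region on unknown chromosome {r.chrom}")
            if not 1 <= r.start <= r.end <= self.chrom_lengths[r.chrom]:
                raise ValueError(f"sweep region outside chromosome: {r}")
            if not 0.0 < r.boost <= 1.0:
                raise ValueError("sweep boost must lie in (0, 1]")
            if r.focal_pop not in ("TL", "SL"):
                raise ValueError("focal population must be TL or SL")
        c = self.causal_snp
        if c.chrom not in self.chrom_lengths or not 1 <= c.pos <= self.chrom_lengths[c.chrom]:
            raise ValueError("causal SNP outside the genome")


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # sample, group, height_cm, chest_depth_cm
    reference: dict[str, str]
    gene_models: list[GeneModel]
    truth: dict  # sweep_regions, causal_snp
    pop_frequencies: dict[str, np.ndarray]


def _plan_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Unique sorted variant positions, with the causal site force-included."""
    total_len = sum(config.chrom_lengths.values())
    rows = []
    remaining = config.n_variants
    chroms = list(config.chrom_lengths)
    for idx, chrom in enumerate(chroms):
        L = config.chrom_lengths[chrom]
        if idx == len(chroms) - 1:
            k = remaining
        else:
            k = int(round(config.n_variants * L / total_len))
            k = min(k, remaining)
        remaining -= k
        pos = set()
        if chrom == config.causal_snp.chrom:
            pos.add(config.causal_snp.pos)
        while len(pos) < k:
            draw = rng.integers(1, L + 1, size=k - len(pos))
            pos.update(int(x) for x in draw)
        for p in sorted(pos):
            rows.append((chrom, p))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def simulate_population_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray, dict[str, np.ndarray]]:
    """Draw per-variant ancestral and per-population allele frequencies.

    Returns (variant positions, ancestral frequencies, {"TL": f, "SL": f}).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    variants = _plan_positions(config, rng)
    m = len(variants)
    p_anc = rng.uniform(0.05, 0.95, size=m)

    causal_mask = (
        (variants["chrom"] == config.causal_snp.chrom)
        & (variants["pos"] == config.causal_snp.pos)
    ).to_numpy()
    # intermediate ancestral frequency at the causal site keeps it informative
    p_anc[causal_mask] = 0.5

    F = config.background_fst
    freqs = {}
    for pop in ("TL", "SL"):
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        freqs[pop] = rng.beta(a, b)

    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()
    for r in config.sweep_regions:
        in_region = (chrom_arr == r.chrom) & (pos_arr >= r.start) & (pos_arr <= r.end)
        f = freqs[r.focal_pop]
        target = (f[in_region] >= 0.5).astype(float)
        f[in_region] = (1.0 - r.boost) * f[in_region] + r.boost * target
    return variants, p_anc, freqs


def simulate_genotypes_and_phenotypes(config: SimConfig) -> SimOutput:
    """Run the full simulation from a single seeded RNG stream."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    variants, p_anc, freqs = simulate_population_frequencies(config, rng)
    m = len(variants)

    samples = [f"TL{i + 1}" for i in range(config.n_tall)] + [
        f"SL{i + 1}" for i in range(config.n_short)
    ]
    groups = ["TL"] * config.n_tall + ["SL"] * config.n_short

    calls = np.empty((len(samples), m), dtype=np.int8)
    calls[: config.n_tall] = rng.binomial(
        2, freqs["TL"][None, :], size=(config.n_tall, m)
    )
    calls[config.n_tall :] = rng.binomial(
        2, freqs["SL"][None, :], size=(config.n_short, m)
    )

    causal_mask = (
        (variants["chrom"] == config.causal_snp.chrom)
        & (variants["pos"] == config.causal_snp.pos)
    ).to_numpy()
    causal_idx = int(np.flatnonzero(causal_mask)[0])
    causal_dosage = calls[:, causal_idx].astype(float).copy()

    if config.missing_rate > 0:
        miss = rng.random((len(samples), m)) < config.missing_rate
        miss[:, causal_idx] = False  # the phenotype contract needs the dosage
        calls[miss] = MISSING

    depth = rng.poisson(12.0, size=(len(samples), m)).astype(float)
    qual = rng.uniform(30.0, 60.0, size=m)

    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    reference = {
        chrom: base_bytes[rng.integers(0, 4, size=length)].tobytes().decode()
        for chrom, length in config.chrom_lengths.items()
    }
    ref_alleles = np.array(
        [
            reference[c][p - 1]
            for c, p in zip(variants["chrom"], variants["pos"])
        ]
    )
    # alt allele: a uniformly random different base
    shift = rng.integers(1, 4, size=m)
    base_idx = np.searchsorted(_BASES, ref_alleles)
    alt_alleles = _BASES[(base_idx + shift) % 4]

    vtable = variants.copy()
    vtable["ref"] = ref_alleles
    vtable["alt"] = alt_alleles
    vtable["qual"] = qual
    genotypes = GenotypeMatrix(
        samples=samples, variants=vtable, calls=calls, depth=depth
    )
    genotypes.validate()

    leg = (
        config.pheno_mean
        + config.causal_snp.effect * causal_dosage
        + rng.normal(0.0, config.pheno_sd, size=len(samples))
    )
    chest = rng.normal(30.0, 1.5, size=len(samples))
    phenotypes = pd.DataFrame(
        dict(
            sample=samples,
            group=groups,
            height_cm=np.round(chest + leg, 6),
            chest_depth_cm=np.round(chest, 6),
        )
    )

    gene_models = _make_gene_models(config, reference)
    truth = dict(sweep_regions=list(config.sweep_regions), causal_snp=config.causal_snp)
    return SimOutput(
        genotypes=genotypes,
        phenotypes=phenotypes,
        reference=reference,
        gene_models=gene_models,
        truth=truth,
        pop_frequencies=freqs,
    )


def _make_gene_models(config: SimConfig, reference: dict[str, str]) -> list[GeneModel]:
    """Deterministic gene tiling: one ~21 kb three-exon gene every 200 kb,
    alternating strand, CDS equal to exons (lengths divisible by 3)."""
    models = []
    i = 0
    for chrom, length in config.chrom_lengths.items():
        start = 50_001
        while start + 21_000 <= length:
            i += 1
            exons = [
                (start, start + 2_999),
                (start + 9_000, start + 11_999),
                (start + 18_000, start + 20_999),
            ]
            models.append(
                GeneModel(
                    gene_id=f"G{i:04d}",
                    chrom=chrom,
                    strand="+" if i % 2 else "-",
                    start=start,
                    end=start + 20_999,
                    exons=exons,
                    cds=list(exons),
                )
            )
            start += 200_000
    return models


def write_outputs(sim: SimOutput, directory: str) -> dict[str, str]:
    """Emit VCF, phenotype TSV, FASTA reference, GFF3 gene models and a
    truth TSV; returns the mapping of artifact name to path."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": os.path.join(directory, "genotypes.vcf"),
        "phenotypes": os.path.join(directory, "phenotypes.tsv"),
        "reference": os.path.join(directory, "reference.fa"),
        "gff3": os.path.join(directory, "genes.gff3"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    write_vcf(sim.genotypes, paths["vcf"])
    sim.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    with open(paths["reference"], "w") as fh:
        for chrom, seq in sim.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_gff3(sim.gene_models, paths["gff3"])
    rows = [
        dict(
            kind="sweep",
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            focal_pop=r.focal_pop,
            value=r.boost,
        )
        for r in sim.truth["sweep_regions"]
    ]
    c = sim.truth["causal_snp"]
    rows.append(
        dict(kind="causal", chrom=c.chrom, start=c.pos, end=c.pos, focal_pop="", value=c.effect)
    )
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_phenotypes(path: str) -> pd.DataFrame:
    """Load a phenotype TSV and derive leg length (height - chest depth)."""
    df = pd.read_csv(path, sep="\t")
    df["leg_length_cm"] = df["height_cm"] - df["chest_depth_cm"]
    return df
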