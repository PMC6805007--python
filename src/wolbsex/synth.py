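"""Synthetic data generators with ground truth.

Every pipeline stage can be exercised offline: a stochastic individual-based
population simulator (the sampling analogue of the deterministic genotype
recursion), an XY-male genome with a small planted Y-specific region plus
male/female read sets, multi-generation pedigrees with Mendelian sex
chromosome segregation and genotype-dependent maternal transmission, and
per-contig SNP tables with group-specific densities.

All generators draw from a single numpy Generator; passing the same seed
reproduces outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    GenotypeState,
    TransmissionRates,
    _step,
)

__all__ = [
    "PopulationSim",
    "simulate_population",
    "GenomeConfig",
    "synth_genome_and_reads",
    "PedigreeConfig",
    "synth_pedigree",
    "synth_brood",
    "SnpConfig",
    "synth_snp_table",
]

_CLASSES = ["g1", "g2", "g3", "g4", "g6", "g8"]


@dataclass
class PopulationSim:
    """Result of an individual-based simulation: per-generation class counts
    and a termination status."""

    counts: pd.DataFrame  # columns generation, g1..g8, n
    status: Literal["completed", "males_extinct", "females_extinct"]


def simulate_population(
    rates: TransmissionRates,
    n_pop: int,
    n_gen: int,
    seed: int,
    start: GenotypeState | None = None,
) -> PopulationSim:
    """Stochastic oracle for the deterministic recursion.

    Each generation computes the deterministic offspring class probabilities
    from the current class frequencies and draws the next generation as a
    multinomial sample of ``n_pop`` individuals.  As n_pop grows the sampled
    frequencies converge to the recursion (binomial sampling noise).
    """
    if n_pop < 2:
        raise ValueError("n_pop must be >= 2")
    if start is None:
        start = GenotypeState(g1=0.5, g2=0.49, g4=0.01)
    rng = np.random.default_rng(seed)
    counts = np.round(start.as_array() * n_pop).astype(int)
    counts[0] += n_pop - counts.sum()  # make counts total exactly n_pop
    rows = [dict(generation=0, **dict(zip(_CLASSES, counts)), n=n_pop)]
    status: str = "completed"
    for gen in range(1, n_gen + 1):
        freqs = counts / counts.sum()
        males = freqs[0] + freqs[2]
        females = freqs[1] + freqs[3] + freqs[4] + freqs[5]
        if males <= 0:
            status = "males_extinct"
            break
        if females <= 0:
            status = "females_extinct"
            break
        probs = np.asarray(_step(tuple(freqs), rates.t_x, rates.t_xy, rates.t_y))
        probs = np.clip(probs, 0, None)
        probs /= probs.sum()
        counts = rng.multinomial(n_pop, probs)
        rows.append(dict(generation=gen, **dict(zip(_CLASSES, counts)), n=n_pop))
    return PopulationSim(counts=pd.DataFrame(rows), status=status)


# ---------------------------------------------------------------------------
# genome + reads


@dataclass(frozen=True)
class GenomeConfig:
    """Synthetic XY-male genome layout.

    The assembly comprises autosomal contigs, X-linked contigs and a small
    set of Y-specific contigs (novel sequence totaling ``y_specific_fraction``
    of the assembly).  The male genome carries two copies of each autosome,
    one X, and a Y that is an identical X homolog plus the Y-specific
    contigs — emulating a young, undifferentiated sex chromosome pair.  The
    female genome carries two autosome copies and two X.
    """

    assembly_length: int = 2_000_000
    n_autosomal_contigs: int = 40
    n_x_contigs: int = 4
    n_y_contigs: int = 2
    y_specific_fraction: float = 0.001
    x_fraction: float = 0.1
    coverage: float = 20.0
    read_length: int = 100
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.y_specific_fraction <= 0.05:
            raise ValueError("y_specific_fraction must be in (0, 0.05]")
        if self.coverage <= 0 or self.read_length < 20:
            raise ValueError("invalid read parameters")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _split_lengths(total: int, n: int, rng: np.random.Generator) -> list[int]:
    """Partition ``total`` bp into n contig lengths, moderately uneven."""
    w = rng.dirichlet(np.full(n, 4.0))
    lens = np.maximum((w * total).astype(int), 200)
    lens[-1] += total - lens.sum()
    return [int(x) for x in np.maximum(lens, 200)]


def _sample_reads(
    copies: list[str],
    coverage: float,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
) -> list[str]:
    genome_bases = sum(len(s) for s in copies)
    n_reads = int(np.ceil(genome_bases * coverage / read_length))
    lens = np.array([max(len(s) - read_length + 1, 0) for s in copies], dtype=float)
    if lens.sum() == 0:
        raise ValueError("all templates shorter than the read length")
    per_copy = rng.multinomial(n_reads, lens / lens.sum())
    reads: list[str] = []
    # starts may overhang both template ends (reads are clipped), so contig
    # termini are covered like any fragmented library covers them
    for seq, cnt in zip(copies, per_copy):
        if cnt == 0:
            continue
        starts = rng.integers(-(read_length - 1), len(seq), size=cnt)
        for s in starts:
            r = seq[max(s, 0) : s + read_length]
            if len(r) >= 20:
                reads.append(r)
    if error_rate > 0:
        mutated = []
        for r in reads:
            arr = np.frombuffer(r.encode("ascii"), dtype=np.uint8).copy()
            hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
            if hits.size:
                arr[hits] = _BASES[(np.searchsorted(_BASES, arr[hits]) + rng.integers(1, 4, hits.size)) % 4]
            mutated.append(arr.tobytes().decode("ascii"))
        reads = mutated
    return reads


def synth_genome_and_reads(
    config: GenomeConfig, seed: int
) -> tuple[dict[str, str], list[str], list[str], pd.DataFrame]:
    """Generate (assembly contigs, male reads, female reads, truth table).

    Truth labels each contig autosomal / X_linked / Y_specific_bearing.
    """
    rng = np.random.default_rng(seed)
    y_total = max(int(config.assembly_length * config.y_specific_fraction), 200)
    x_total = int(config.assembly_length * config.x_fraction)
    a_total = config.assembly_length - y_total - x_total
    contigs: dict[str, str] = {}
    truth_rows = []
    for i, length in enumerate(_split_lengths(a_total, config.n_autosomal_contigs, rng)):
        cid = f"contig_a{i:03d}"
        contigs[cid] = _random_seq(rng, length)
        truth_rows.append(dict(contig_id=cid, length=length, truth="autosomal"))
    for i, length in enumerate(_split_lengths(x_total, config.n_x_contigs, rng)):
        cid = f"contig_x{i:03d}"
        contigs[cid] = _random_seq(rng, length)
        truth_rows.append(dict(contig_id=cid, length=length, truth="X_linked"))
    for i, length in enumerate(_split_lengths(y_total, config.n_y_contigs, rng)):
        cid = f"contig_y{i:03d}"
        contigs[cid] = _random_seq(rng, length)
        truth_rows.append(dict(contig_id=cid, length=length, truth="Y_specific_bearing"))
    autosomes = [s for c, s in contigs.items() if c.startswith("contig_a")]
    x_seqs = [s for c, s in contigs.items() if c.startswith("contig_x")]
    y_seqs = [s for c, s in contigs.items() if c.startswith("contig_y")]
    # Y haplotype = identical X homolog + Y-specific segments
    male_copies = autosomes * 2 + x_seqs + x_seqs + y_seqs
    female_copies = autosomes * 2 + x_seqs * 2
    male_reads = _sample_reads(male_copies, config.coverage, config.read_length,
                               config.error_rate, rng)
    female_reads = _sample_reads(female_copies, config.coverage, config.read_length,
                                 config.error_rate, rng)
    return contigs, male_reads, female_reads, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# pedigrees


@dataclass(frozen=True)
class PedigreeConfig:
    """Multi-generation pedigree under feminization and genotype-dependent
    maternal transmission.

    Brood sizes follow a negative binomial loosely spanning the 13-68 range
    observed in real isopod broods (mean ~40); observation masking and qPCR
    noise emulate incomplete molecular testing.
    """

    rates: TransmissionRates = field(default_factory=lambda: TransmissionRates(0.9, 0.9, 0.0))
    n_generations: int = 3
    mothers_per_generation: int = 2
    brood_mean: float = 40.0
    brood_dispersion: float = 12.0
    tested_fraction: float = 1.0
    qpcr_fraction: float = 0.0
    qpcr_sigma: float = 0.05
    founder_genotype: str = "XY"
    founder_infected: bool = True


_QPCR_TRUE = {"XX": 0.0, "XY": 0.5, "YY": 1.0}


def _offspring(
    mother_g: str, father_g: str, mother_infected: bool, t: float,
    size: int, rng: np.random.Generator,
) -> pd.DataFrame:
    mat = rng.choice(list(mother_g), size=size)
    pat = rng.choice(list(father_g), size=size)
    geno = np.array(["".join(sorted(m + p)) for m, p in zip(mat, pat)])
    infected = (
        rng.random(size) < t if mother_infected else np.zeros(size, dtype=bool)
    )
    sex = np.where(infected | (geno == "XX"), "female", "male")
    return pd.DataFrame(dict(genotype=geno, infected=infected, sex=sex))


def synth_brood(
    mother_genotype: str,
    t: float,
    brood_size: int,
    rng: np.random.Generator,
    father_genotype: str = "XY",
    mother_infected: bool = True,
) -> pd.DataFrame:
    """One brood with truth columns genotype/infected/sex."""
    return _offspring(mother_genotype, father_genotype, mother_infected, t, brood_size, rng)


def _brood_size(config: PedigreeConfig, rng: np.random.Generator) -> int:
    r = config.brood_dispersion
    p = r / (r + config.brood_mean)
    return max(int(rng.negative_binomial(r, p)), 1)


def synth_pedigree(
    config: PedigreeConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (observations, truth) for a multi-generation pedigree.

    Observations use the schema consumed by genotype inference
    (individual_id, family_id, mother_id, father_id, sex, y_marker,
    wolbachia, qpcr_ratio); truth carries the real genotype and infection of
    every individual.  Mothers of the next generation are drawn from the
    current females (infected ones when available, as in real crossing
    designs); fathers are unrelated uninfected XY males.
    """
    rng = np.random.default_rng(seed)
    obs_rows: list[dict] = []
    truth_rows: list[dict] = []
    counter = 0

    def new_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:04d}"

    def record(iid, fam, mid, fid, sex, genotype, infected, founder=False):
        tested = founder or rng.random() < config.tested_fraction
        marker = ("positive" if "Y" in genotype else "negative") if tested else "untested"
        wol = ("infected" if infected else "uninfected") if tested else "untested"
        qpcr = np.nan
        if tested and rng.random() < config.qpcr_fraction:
            qpcr = max(0.0, _QPCR_TRUE[genotype] + rng.normal(0.0, config.qpcr_sigma))
        obs_rows.append(dict(individual_id=iid, family_id=fam, mother_id=mid,
                             father_id=fid, sex=sex, y_marker=marker,
                             wolbachia=wol, qpcr_ratio=qpcr))
        truth_rows.append(dict(individual_id=iid, genotype=genotype, infected=infected))

    founder_id = new_id("F0_")
    record(founder_id, "F0", None, None, "female", config.founder_genotype,
           config.founder_infected, founder=True)
    mothers = [(founder_id, config.founder_genotype, config.founder_infected)]
    t_by_g = {"XX": config.rates.t_x, "XY": config.rates.t_xy, "YY": config.rates.t_y}
    for gen in range(1, config.n_generations + 1):
        next_pool: list[tuple[str, str, bool]] = []
        for mid, mg, minf in mothers:
            fid = new_id(f"SIRE_G{gen}_")
            record(fid, f"G{gen}", None, None, "male", "XY", False, founder=True)
            fam = f"G{gen}_{mid}"
            brood = _offspring(mg, "XY", minf, t_by_g[mg], _brood_size(config, rng), rng)
            for _, child in brood.iterrows():
                cid = new_id(f"IND_G{gen}_")
                record(cid, fam, mid, fid, child["sex"], child["genotype"], bool(child["infected"]))
                if child["sex"] == "female":
                    next_pool.append((cid, child["genotype"], bool(child["infected"])))
        if not next_pool:
            break
        infected_pool = [x for x in next_pool if x[2]]
        pool = infected_pool if infected_pool else next_pool
        k = min(config.mothers_per_generation, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        mothers = [pool[i] for i in idx]
    obs = pd.DataFrame(obs_rows)
    truth = pd.DataFrame(truth_rows)
    return obs, truth


# ---------------------------------------------------------------------------
# SNP tables


@dataclass(frozen=True)
class SnpConfig:
    """Per-contig heterozygous-SNP table with two contig groups at distinct
    densities (per kb), Poisson counts, optional masked intervals."""

    n_contigs_group: int = 40
    n_contigs_rest: int = 60
    contig_length: int = 10_000
    rate_group: float = 2.61
    rate_rest: float = 2.55
    mask_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_group < 0 or self.rate_rest < 0:
            raise ValueError("snp rates must be >= 0")


def synth_snp_table(
    config: SnpConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (variants, mask, truth) tables.

    Variants: chrom, pos (1-based), ref, alt, het.  Mask: chrom, start, end
    (0-based half-open), one leading interval per contig when
    ``mask_fraction`` > 0.  Truth: per-contig group and generating rate.
    """
    rng = np.random.default_rng(seed)
    variants = []
    mask_rows = []
    truth_rows = []
    bases = np.array(list("ACGT"))
    for group, n, rate in (
        ("group", config.n_contigs_group, config.rate_group),
        ("rest", config.n_contigs_rest, config.rate_rest),
    ):
        for i in range(n):
            cid = f"{group}_{i:04d}"
            length = config.contig_length
            mask_len = int(length * config.mask_fraction)
            if mask_len > 0:
                mask_rows.append(dict(chrom=cid, start=0, end=mask_len))
            open_len = length - mask_len
            n_snp = rng.poisson(rate * open_len / 1000.0)
            pos = np.sort(rng.choice(open_len, size=min(n_snp, open_len), replace=False)) + mask_len + 1
            for p in pos:
                ref, alt = rng.choice(4, size=2, replace=False)
                variants.append(dict(chrom=cid, pos=int(p), ref=bases[ref], alt=bases[alt], het=True))
            truth_rows.append(dict(contig_id=cid, group=group, rate=rate,
                                   length=length, unmasked_length=open_len,
                                   n_snps=int(len(pos))))
    variants_df = pd.DataFrame(variants, columns=["chrom", "pos", "ref", "alt", "het"])
    mask_df = pd.DataFrame(mask_rows, columns=["chrom", "start", "end"])
    return variants_df, mask_df, pd.DataFrame(truth_rows)
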