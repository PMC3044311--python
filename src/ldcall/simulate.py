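"""Seeded generators for panels, diploid individuals and read pileups.

The generator mirrors the model the caller assumes: panel haplotypes are
recombination mosaics of a small set of founder haplotypes; a diploid
individual draws two haplotypes independently (random mating); shotgun
coverage per SNP is Poisson; base errors follow a Phred-style error model.
A reference-allele bias knob skews which chromosome heterozygous-site reads
are sampled from, emulating the platform bias seen in real datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evidence import AlleleObservation, ReadData, SitePileup, phred_to_error
from .panel import HaplotypeHMM, HaplotypePanel, ParentalModels, SnpLocus


@dataclass
class SimConfig:
    """Synthetic-study settings.

    ``phred_dist`` is a discrete distribution over Phred qualities as
    ``(quality, probability)`` pairs; the default is a constant Phred 20
    (1% base error).  ``ref_bias`` is the probability that a read at a
    heterozygous site is sampled from the chromosome carrying allele 0
    (the designated reference allele); 0.5 is unbiased.
    """

    n_snps: int = 1000
    n_panel_haplotypes: int = 120
    n_founders_true: int = 10
    recomb_switch_prob: float = 0.01
    mutation_flip_prob: float = 0.005
    mean_coverage: float = 6.0
    phred_dist: tuple[tuple[int, float], ...] = ((20, 1.0),)
    ref_bias: float = 0.5
    seed: int | None = 0

    def __post_init__(self) -> None:
        for name in ("recomb_switch_prob", "mutation_flip_prob", "ref_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")
        total = sum(p for _, p in self.phred_dist)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("phred_dist probabilities must sum to 1")


def _default_loci(n: int) -> list[SnpLocus]:
    return [SnpLocus(i, "sim", i + 1, "A", "C") for i in range(n)]


def simulate_panel(
    config: SimConfig, seed=None
) -> tuple[HaplotypePanel, np.ndarray]:
    """Draw founder haplotypes and a mosaic panel.

    Each panel haplotype copies a uniformly chosen founder, switches to a
    random founder with ``recomb_switch_prob`` at each step, and flips each
    copied allele with ``mutation_flip_prob``.  Returns the panel and the
    true founder matrix (n_founders_true x n_snps).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, F = config.n_snps, config.n_founders_true
    if F > 2**n:
        import warnings

        warnings.warn("more founders than distinct haplotypes", stacklevel=2)
    founders = (rng.random((F, n)) < 0.5).astype(np.int8)
    N = config.n_panel_haplotypes
    # vectorised mosaic: cumulative count of switch events segments each row
    switches = rng.random((N, n)) < config.recomb_switch_prob
    switches[:, 0] = True
    seg = np.cumsum(switches, axis=1) - 1
    n_seg = int(seg.max()) + 1
    founder_choice = rng.integers(0, F, size=(N, n_seg))
    source = founder_choice[np.arange(N)[:, None], seg]
    haps = founders[source, np.arange(n)[None, :]]
    flips = rng.random((N, n)) < config.mutation_flip_prob
    haps = np.where(flips, 1 - haps, haps).astype(np.int8)
    return HaplotypePanel(loci=_default_loci(n), haplotypes=haps), founders


def simulate_individual(source, seed=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a diploid individual: (maternal h, paternal h', genotype g).

    ``source`` may be a ParentalModels / HaplotypeHMM (haplotypes sampled
    from the chains) or a HaplotypePanel (two distinct panel rows drawn
    uniformly, i.e. random mating within the panel population; drawing the
    same row twice would make the individual a complete homozygote).  The
    two haplotypes are independent; g_i = h_i + h'_i.
    """
    rng = np.random.default_rng(seed)
    if isinstance(source, HaplotypeHMM):
        source = ParentalModels.from_single(source)
    if isinstance(source, ParentalModels):
        h = source.maternal.simulate_haplotypes(1, seed=rng)[0]
        hp = source.paternal.simulate_haplotypes(1, seed=rng)[0]
    elif isinstance(source, HaplotypePanel):
        rows = rng.choice(source.n_haplotypes, size=2, replace=False)
        h = source.haplotypes[rows[0]].copy()
        hp = source.haplotypes[rows[1]].copy()
    else:
        raise TypeError(f"cannot simulate an individual from {type(source)!r}")
    return h, hp, h.astype(int) + hp


def simulate_reads(g: np.ndarray, config: SimConfig, seed=None) -> ReadData:
    """Generate per-SNP allele observations for true genotypes ``g``.

    Coverage is Poisson(``mean_coverage``) per locus.  At homozygous loci
    every read samples the single true allele; at heterozygous loci each
    read samples the allele-0 chromosome with probability ``ref_bias``.
    The reported allele then flips with the error probability implied by a
    Phred quality drawn from ``phred_dist``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    g = np.asarray(g)
    quals = np.array([q for q, _ in config.phred_dist])
    qprobs = np.array([p for _, p in config.phred_dist])
    errs = np.array([phred_to_error(q) for q in quals])
    pileups: list[SitePileup] = []
    coverage = rng.poisson(config.mean_coverage, size=g.shape[0])
    for i, gi in enumerate(g):
        obs: list[AlleleObservation] = []
        for _ in range(int(coverage[i])):
            if gi == 1:
                true_allele = 0 if rng.random() < config.ref_bias else 1
            else:
                true_allele = gi // 2
            qi = rng.choice(len(quals), p=qprobs)
            allele = true_allele
            if rng.random() < errs[qi]:
                allele = 1 - allele
            obs.append(
                AlleleObservation(
                    allele=int(allele), error_prob=errs[qi], phred=int(quals[qi])
                )
            )
        pileups.append(SitePileup(i, obs))
    return ReadData(pileups)


def downsample_reads(
    data: ReadData, fraction: float, seed=None, exact: bool = False
) -> ReadData:
    """Random subset of the observations, as in coverage-titration studies.

    Default mode keeps each observation independently with probability
    ``fraction``.  ``exact=True`` ranks observations by a seeded uniform
    key and keeps the first ``floor(m * fraction)``; with a fixed seed the
    kept sets are nested across fractions (m/16 within m/8 within ...).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return ReadData(
            [SitePileup(p.locus_index, list(p.observations)) for p in data.pileups]
        )
    rng = np.random.default_rng(seed)
    keys = rng.random(data.m)
    if exact:
        keep_n = int(np.floor(data.m * fraction))
        order = np.argsort(keys, kind="stable")
        keep = np.zeros(data.m, dtype=bool)
        keep[order[:keep_n]] = True
    else:
        keep = keys < fraction
    pileups: list[SitePileup] = []
    pos = 0
    for p in data.pileups:
        kept = [o for j, o in enumerate(p.observations) if keep[pos + j]]
        pos += p.coverage
        pileups.append(SitePileup(p.locus_index, kept))
    return ReadData(pileups)


# ---------------------------------------------------------------------------
# truth I/O


def write_truth(h: np.ndarray, hp: np.ndarray, path, loci=None) -> None:
    g = np.asarray(h).astype(int) + np.asarray(hp)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\th_maternal\th_paternal\tg\n")
        for i in range(len(g)):
            if loci is not None:
                chrom, pos = loci[i].chromosome, loci[i].position
            else:
                chrom, pos = "sim", i + 1
            fh.write(f"{chrom}\t{pos}\t{int(h[i])}\t{int(hp[i])}\t{int(g[i])}\n")


def load_truth(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h, hp = [], []
    with open(path) as fh:
        header = fh.readline().split()
        if header[:5] != ["chrom", "pos", "h_maternal", "h_paternal", "g"]:
            raise ValueError(f"{path}: unexpected truth header")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            h.append(int(parts[2]))
            hp.append(int(parts[3]))
    h = np.array(h, dtype=np.int8)
    hp = np.array(hp, dtype=np.int8)
    return h, hp, h.astype(int) + hp


@dataclass
class SimulatedStudy:
    """A complete synthetic dataset: panel, truth and reads, all seeded."""

    config: SimConfig
    panel: HaplotypePanel
    founders: np.ndarray
    h_maternal: np.ndarray
    h_paternal: np.ndarray
    genotypes: np.ndarray
    reads: ReadData


def simulate_study(
    config: SimConfig,
    panel_seed=None,
    individual_seed=None,
    read_seed=None,
) -> SimulatedStudy:
    """Panel + one panel-drawn individual + reads, with per-stage seeds.

    Unset stage seeds are spawned deterministically from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    defaults = ss.spawn(3)
    panel, founders = simulate_panel(
        config, seed=panel_seed if panel_seed is not None else defaults[0]
    )
    h, hp, g = simulate_individual(
        panel, seed=individual_seed if individual_seed is not None else defaults[1]
    )
    reads = simulate_reads(
        g, config, seed=read_seed if read_seed is not None else defaults[2]
    )
    return SimulatedStudy(config, panel, founders, h, hp, g, reads)
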