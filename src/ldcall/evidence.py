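"""Read evidence: pileups, genotype likelihoods and LD-oblivious callers.

Each aligned read contributes one allele observation per SNP it covers.
For a site with genotype g and a read reporting allele ``a`` with error
probability ``eps``:

* homozygous matching genotype: factor ``1 - eps``
* homozygous mismatching genotype: factor ``eps``
* heterozygous: the read was sampled from the chromosome carrying ``a`` and
  sequenced correctly, or from the other chromosome and mis-sequenced, so
  the factor is ``(1 - eps)/2 + eps/2 = 1/2`` exactly, for every ``eps``.

A mapping confidence ``m in (0, 1]`` raises the read's factor to the power
``m`` — equivalent to observing an ``m`` fraction of a perfectly mapped
read; the resulting quantities are likelihood weights, not probabilities,
when ``m < 1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .panel import GenotypePrior, SnpLocus

logger = logging.getLogger(__name__)

#: sentinel genotype for a no-call
NO_CALL = -1


def phred_to_error(q: int | float) -> float:
    """Convert a Phred quality to an error probability, capped at 0.5.

    The cap keeps q=0 from yielding the meaningless error probability 1.
    """
    if q < 0:
        raise ValueError(f"negative Phred quality {q}")
    return min(10.0 ** (-q / 10.0), 0.5)


@dataclass(frozen=True)
class AlleleObservation:
    """One read's allele call at one SNP locus."""

    allele: int
    error_prob: float
    phred: int | None = None
    map_conf: float = 1.0

    def __post_init__(self) -> None:
        if self.allele not in (0, 1):
            raise ValueError(f"allele must be 0 or 1, got {self.allele}")
        if not 0.0 <= self.error_prob <= 0.5:
            raise ValueError(f"error_prob {self.error_prob} outside [0, 0.5]")
        if not 0.0 < self.map_conf <= 1.0:
            raise ValueError(f"map_conf {self.map_conf} outside (0, 1]")

    @classmethod
    def from_phred(
        cls, allele: int, phred: int, map_conf: float = 1.0
    ) -> "AlleleObservation":
        return cls(
            allele=allele,
            error_prob=phred_to_error(phred),
            phred=phred,
            map_conf=map_conf,
        )


@dataclass
class SitePileup:
    """All allele observations covering one locus (arbitrary order)."""

    locus_index: int
    observations: list[AlleleObservation] = field(default_factory=list)

    @property
    def coverage(self) -> int:
        return len(self.observations)

    def allele_counts(self) -> tuple[int, int]:
        c1 = sum(o.allele for o in self.observations)
        return len(self.observations) - c1, c1


@dataclass
class ReadData:
    """One pileup per locus; ``m`` is the total observation count."""

    pileups: list[SitePileup]

    def __post_init__(self) -> None:
        for i, p in enumerate(self.pileups):
            if p.locus_index != i:
                raise ValueError("pileups must be ordered by locus index")

    @property
    def n(self) -> int:
        return len(self.pileups)

    @property
    def m(self) -> int:
        return sum(p.coverage for p in self.pileups)


@dataclass
class GenotypeLikelihoods:
    """Per-locus likelihood triples L_i(g) = P(r_i | g), shape (n, 3).

    A locus with no coverage has the uninformative triple (1, 1, 1).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("likelihoods must have shape (n, 3)")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("likelihood entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.values.shape[0])


@dataclass
class GenotypeCall:
    """A called genotype (or no-call) with its posterior triple."""

    locus_index: int
    genotype: int
    posterior: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.posterior = np.asarray(self.posterior, dtype=float)
        if self.genotype not in (NO_CALL, 0, 1, 2):
            raise ValueError(f"invalid genotype {self.genotype}")

    @property
    def is_called(self) -> bool:
        return self.genotype != NO_CALL


def site_likelihoods(pileup: SitePileup) -> np.ndarray:
    """Likelihood triple (L(0), L(1), L(2)) for one pileup.

    Accumulated in log space; the reported triple is linear.  Invariant
    under permutation of the observations.
    """
    log_l = np.zeros(3)
    with np.errstate(divide="ignore"):
        for obs in pileup.observations:
            eps = obs.error_prob
            mismatch = np.log(eps) if eps > 0 else -np.inf
            m = obs.map_conf
            if obs.allele == 0:
                log_l[0] += m * np.log(1.0 - eps)
                log_l[2] += m * mismatch
            else:
                log_l[2] += m * np.log(1.0 - eps)
                log_l[0] += m * mismatch
            log_l[1] += m * np.log(0.5)
    return np.exp(log_l)


def genotype_likelihoods(data: ReadData) -> GenotypeLikelihoods:
    """Likelihood triples for every locus; O(m) over all observations."""
    values = np.ones((data.n, 3))
    for i, pileup in enumerate(data.pileups):
        if pileup.coverage:
            values[i] = site_likelihoods(pileup)
    return GenotypeLikelihoods(values)


def _argmax_with_ties(post: np.ndarray, prior: np.ndarray) -> int:
    """Argmax over genotypes; ties go to the larger prior, then genotype 0."""
    best = post.max()
    tied = np.flatnonzero(post == best)
    if len(tied) == 1:
        return int(tied[0])
    tied = tied[prior[tied] == prior[tied].max()]
    return int(tied[0])


def single_snp_call(
    likelihoods, prior, locus_index: int = 0, method: str = "single_snp"
) -> GenotypeCall:
    """Bayesian single-locus call: posterior(g) ∝ L(g) * prior(g).

    Returns a no-call (with a warning) when every numerator is zero, which
    can only happen when the prior vetoes exactly the genotypes the reads
    allow.
    """
    L = np.asarray(likelihoods, dtype=float)
    prior = np.asarray(prior, dtype=float)
    num = L * prior
    total = num.sum()
    if total == 0.0:
        warnings.warn(
            f"locus {locus_index}: prior and likelihood have disjoint "
            "support; emitting no-call",
            stacklevel=2,
        )
        return GenotypeCall(locus_index, NO_CALL, np.full(3, np.nan), method)
    post = num / total
    return GenotypeCall(locus_index, _argmax_with_ties(post, prior), post, method)


def single_snp_call_all(
    likelihoods: GenotypeLikelihoods, prior: GenotypePrior
) -> list[GenotypeCall]:
    """Independent single-SNP calls at every locus."""
    if likelihoods.n != prior.n:
        raise ValueError("likelihoods and prior cover different locus counts")
    return [
        single_snp_call(likelihoods.values[i], prior.probs[i], locus_index=i)
        for i in range(likelihoods.n)
    ]


def binomial_baseline_call(
    pileup: SitePileup, alpha: float = 0.01, min_allele_cov: int = 1
) -> GenotypeCall:
    """LD-oblivious baseline: exact binomial test of allele balance.

    A site is called heterozygous when both alleles are covered at least
    ``min_allele_cov`` times and the two-sided exact binomial test of the
    minor-allele count against p=0.5 does not reject at ``alpha``; otherwise
    the majority-allele homozygote is called.  Zero coverage yields a
    no-call.  The posterior triple is a degenerate indicator.
    """
    c0, c1 = pileup.allele_counts()
    c = c0 + c1
    if c == 0:
        return GenotypeCall(pileup.locus_index, NO_CALL, np.full(3, np.nan), "binomial")
    minor = min(c0, c1)
    post = np.zeros(3)
    if minor >= min_allele_cov:
        pval = binomtest(minor, c, 0.5, alternative="two-sided").pvalue
        if pval > alpha:
            post[1] = 1.0
            return GenotypeCall(pileup.locus_index, 1, post, "binomial")
    g = 0 if c0 >= c1 else 2
    post[g] = 1.0
    return GenotypeCall(pileup.locus_index, g, post, "binomial")


# ---------------------------------------------------------------------------
# pileup / calls I/O

_PILEUP_COLUMNS = ("chrom", "pos", "allele", "phred")


def load_pileup(
    path, loci: list[SnpLocus] | None = None, n_loci: int | None = None
) -> ReadData:
    """Read a pileup TSV into :class:`ReadData`.

    Columns (with header): ``chrom pos allele phred`` plus optional
    ``map_conf`` and ``read_id``.  When ``loci`` is given, rows are mapped to
    locus indices by (chrom, pos); otherwise ``pos`` is taken as the 1-based
    locus rank and ``n_loci`` is required.  Rows whose allele code is not 0
    or 1 are dropped (non-panel alleles are ignored); the dropped count is
    logged.
    """
    if loci is None and n_loci is None:
        raise ValueError("either loci or n_loci is required")
    if loci is not None:
        index = {(l.chromosome, l.position): l.index for l in loci}
        n = len(loci)
    else:
        n = int(n_loci)
    pileups = [SitePileup(i) for i in range(n)]
    dropped = 0
    with open(path) as fh:
        header = fh.readline().split()
        if header[:4] != list(_PILEUP_COLUMNS):
            raise ValueError(
                f"{path}: expected pileup header starting with "
                f"{' '.join(_PILEUP_COLUMNS)}"
            )
        has_map_conf = "map_conf" in header
        mc_col = header.index("map_conf") if has_map_conf else None
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom, pos, allele, phred = parts[:4]
            if allele not in ("0", "1"):
                dropped += 1
                continue
            if loci is not None:
                key = (chrom, int(pos))
                if key not in index:
                    dropped += 1
                    continue
                i = index[key]
            else:
                i = int(pos) - 1
                if not 0 <= i < n:
                    raise ValueError(f"{path}: position {pos} outside 1..{n}")
            map_conf = float(parts[mc_col]) if has_map_conf else 1.0
            pileups[i].observations.append(
                AlleleObservation.from_phred(int(allele), int(phred), map_conf)
            )
    if dropped:
        logger.info("dropped %d pileup rows with non-panel alleles", dropped)
    return ReadData(pileups)


def write_pileup(data: ReadData, path, loci: list[SnpLocus] | None = None) -> None:
    """Write :class:`ReadData` as a pileup TSV (inverse of load_pileup)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tallele\tphred\tmap_conf\n")
        for pileup in data.pileups:
            if loci is not None:
                loc = loci[pileup.locus_index]
                chrom, pos = loc.chromosome, loc.position
            else:
                chrom, pos = "sim", pileup.locus_index + 1
            for obs in pileup.observations:
                phred = obs.phred
                if phred is None:
                    eps = max(obs.error_prob, 1e-10)
                    phred = int(round(-10 * np.log10(eps)))
                fh.write(
                    f"{chrom}\t{pos}\t{obs.allele}\t{phred}\t{obs.map_conf:g}\n"
                )


def write_calls(
    calls: list[GenotypeCall], path, loci: list[SnpLocus] | None = None
) -> None:
    """Write genotype calls as a TSV: chrom pos call p0 p1 p2 method."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tcall\tp0\tp1\tp2\tmethod\n")
        for call in calls:
            if loci is not None:
                loc = loci[call.locus_index]
                chrom, pos = loc.chromosome, loc.position
            else:
                chrom, pos = "sim", call.locus_index + 1
            g = "." if call.genotype == NO_CALL else str(call.genotype)
            p = call.posterior
            ptxt = "\t".join(
                "nan" if np.isnan(x) else f"{x:.6f}" for x in p
            )
            fh.write(f"{chrom}\t{pos}\t{g}\t{ptxt}\t{call.method}\n")


def load_calls(path) -> list[GenotypeCall]:
    """Read a calls TSV written by :func:`write_calls`."""
    calls: list[GenotypeCall] = []
    with open(path) as fh:
        header = fh.readline().split()
        if header[:7] != ["chrom", "pos", "call", "p0", "p1", "p2", "method"]:
            raise ValueError(f"{path}: unexpected calls header")
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            g = NO_CALL if parts[2] == "." else int(parts[2])
            post = np.array([float(x) for x in parts[3:6]])
            calls.append(GenotypeCall(i, g, post, parts[6]))
    return calls


def write_calls_vcf(
    calls: list[GenotypeCall], path, loci: list[SnpLocus], sample: str = "SAMPLE"
) -> None:
    """Write a minimal VCF with GT and GQ = -10*log10(1 - max posterior)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", NO_CALL: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description='
            '"Genotype quality">\n'
        )
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for call in calls:
            loc = loci[call.locus_index]
            if call.is_called and np.isfinite(call.posterior).all():
                err = max(1.0 - float(call.posterior.max()), 1e-10)
                gq = int(round(-10 * np.log10(err)))
                field = f"{gt_map[call.genotype]}:{min(gq, 99)}"
            else:
                field = "./.:0"
            fh.write(
                f"{loc.chromosome}\t{loc.position}\tsnp{loc.index}\t"
                f"{loc.allele0}\t{loc.allele1}\t.\tPASS\t.\tGT:GQ\t{field}\n"
            )
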