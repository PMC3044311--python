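"""Domain types for SNP loci, phased haplotype panels and founder-haplotype HMMs.

A haplotype panel is an ``N_hap x n`` 0/1 matrix of phased haplotypes over
``n`` ordered biallelic SNPs.  A :class:`HaplotypeHMM` is a left-to-right
hidden Markov model over ``K`` latent founder haplotypes with locus-indexed
(inhomogeneous) transition and emission probabilities; each observed
haplotype is modelled as a recombination mosaic of the founders.  Two such
models (maternal and paternal) form :class:`ParentalModels`, the LD prior of
the genotype caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: tolerance for stochastic-vector normalisation checks
STOCHASTIC_ATOL = 1e-9


class PanelFormatError(ValueError):
    """Raised when a panel or model file violates its format contract."""


@dataclass(frozen=True)
class SnpLocus:
    """A biallelic SNP: 0-based vector index, 1-based genomic coordinate."""

    index: int
    chromosome: str
    position: int
    allele0: str
    allele1: str

    def __post_init__(self) -> None:
        if self.allele0 == self.allele1:
            raise ValueError(
                f"locus {self.chromosome}:{self.position}: allele0 == allele1 "
                f"({self.allele0!r})"
            )


@dataclass
class HaplotypePanel:
    """An ordered list of SNP loci plus an ``N_hap x n`` phased 0/1 matrix."""

    loci: list[SnpLocus]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[1] != len(self.loci):
            raise ValueError(
                f"haplotype row length {self.haplotypes.shape[1]} != "
                f"number of loci {len(self.loci)}"
            )
        if self.haplotypes.shape[0] < 2:
            raise ValueError("a panel needs at least 2 haplotypes")
        bad = ~np.isin(self.haplotypes, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise PanelFormatError(
                f"non-binary allele code {self.haplotypes[r, c]} at "
                f"haplotype {r}, locus {c}"
            )
        for j, locus in enumerate(self.loci):
            if locus.index != j:
                raise ValueError("locus indices must be contiguous from 0")
        for a, b in zip(self.loci, self.loci[1:]):
            if a.chromosome == b.chromosome and b.position <= a.position:
                raise ValueError(
                    f"loci not strictly increasing: {a.chromosome}:"
                    f"{a.position} then {b.position}"
                )

    @property
    def n(self) -> int:
        return len(self.loci)

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    def allele1_frequencies(self) -> np.ndarray:
        """Per-locus frequency of allele 1 across the panel."""
        return self.haplotypes.mean(axis=0)


def _check_stochastic(arr: np.ndarray, what: str) -> None:
    if (arr < 0).any():
        raise ValueError(f"{what}: negative probability")
    sums = arr.sum(axis=-1)
    if not np.allclose(sums, 1.0, rtol=0, atol=STOCHASTIC_ATOL):
        worst = float(np.abs(sums - 1.0).max())
        raise ValueError(f"{what}: rows deviate from 1 by {worst:.3e}")


@dataclass
class HaplotypeHMM:
    """Left-to-right founder HMM over ``n`` loci with ``K`` founder states.

    Parameters
    ----------
    initial : (K,) initial founder distribution P(f_1).
    transitions : (n-1, K, K) per-locus row-stochastic transition matrices
        P(f_{i+1} | f_i).
    emissions : (n, K, 2) per-locus row-stochastic allele emission
        probabilities P(h_i | f_i).
    """

    initial: np.ndarray
    transitions: np.ndarray
    emissions: np.ndarray

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        K = self.initial.shape[0]
        n = self.emissions.shape[0]
        if self.emissions.shape != (n, K, 2):
            raise ValueError("emissions must have shape (n, K, 2)")
        if self.transitions.shape != (max(n - 1, 0), K, K):
            raise ValueError("transitions must have shape (n-1, K, K)")
        _check_stochastic(self.initial, "initial distribution")
        if n > 1:
            _check_stochastic(self.transitions, "transition matrices")
        _check_stochastic(self.emissions, "emission matrices")

    @property
    def K(self) -> int:
        return int(self.initial.shape[0])

    @property
    def n(self) -> int:
        return int(self.emissions.shape[0])

    def founder_marginals(self) -> np.ndarray:
        """Data-free chain marginals P(f_i), shape (n, K)."""
        out = np.empty((self.n, self.K))
        out[0] = self.initial
        for i in range(self.n - 1):
            out[i + 1] = self.transitions[i].T @ out[i]
        return out

    def simulate_haplotypes(self, n_haplotypes: int, seed=None) -> np.ndarray:
        """Sample haplotypes from the model; shape (n_haplotypes, n)."""
        rng = np.random.default_rng(seed)
        H = np.empty((n_haplotypes, self.n), dtype=np.int8)
        for r in range(n_haplotypes):
            f = rng.choice(self.K, p=self.initial)
            for i in range(self.n):
                if i > 0:
                    f = rng.choice(self.K, p=self.transitions[i - 1][f])
                H[r, i] = rng.random() < self.emissions[i, f, 1]
        return H


@dataclass
class ParentalModels:
    """The maternal (M) and paternal (M') founder HMMs of the caller.

    The two chains are independent (random mating); their founder counts may
    differ.  When only one panel is available the same trained model is used
    for both sides.
    """

    maternal: HaplotypeHMM
    paternal: HaplotypeHMM

    def __post_init__(self) -> None:
        if self.maternal.n != self.paternal.n:
            raise ValueError(
                f"maternal n={self.maternal.n} != paternal n={self.paternal.n}"
            )

    @classmethod
    def from_single(cls, hmm: HaplotypeHMM) -> "ParentalModels":
        return cls(maternal=hmm, paternal=hmm)

    @property
    def n(self) -> int:
        return self.maternal.n


@dataclass
class GenotypePrior:
    """Per-locus genotype prior P(G_i = g), shape (n, 3)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ValueError("genotype prior must have shape (n, 3)")
        _check_stochastic(self.probs, "genotype prior")

    @property
    def n(self) -> int:
        return int(self.probs.shape[0])


# ---------------------------------------------------------------------------
# panel I/O


def load_hap_legend(hap_path, legend_path=None) -> HaplotypePanel:
    """Read a panel from a legend TSV and a hap file.

    The legend has columns ``id chrom pos allele0 allele1`` (with header);
    the hap file has one whitespace-separated 0/1 row per haplotype.
    """
    hap_path = Path(hap_path)
    if legend_path is None:
        legend_path = hap_path.with_suffix(".legend")
    loci: list[SnpLocus] = []
    with open(legend_path) as fh:
        header = fh.readline().split()
        if header[:5] != ["id", "chrom", "pos", "allele0", "allele1"]:
            raise PanelFormatError(
                f"{legend_path}: expected header 'id chrom pos allele0 allele1'"
            )
        for j, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            _, chrom, pos, a0, a1 = parts[:5]
            loci.append(SnpLocus(j, chrom, int(pos), a0, a1))
    n = len(loci)
    rows = []
    with open(hap_path) as fh:
        for r, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != n:
                raise PanelFormatError(
                    f"{hap_path}: haplotype row {r} has {len(parts)} entries, "
                    f"expected {n}"
                )
            try:
                row = [int(x) for x in parts]
            except ValueError as exc:
                raise PanelFormatError(
                    f"{hap_path}: non-integer allele code in row {r}"
                ) from exc
            if any(x not in (0, 1) for x in row):
                raise PanelFormatError(
                    f"{hap_path}: allele code outside {{0,1}} in row {r}"
                )
            rows.append(row)
    return HaplotypePanel(loci=loci, haplotypes=np.array(rows, dtype=np.int8))


def save_hap_legend(panel: HaplotypePanel, hap_path, legend_path=None) -> None:
    hap_path = Path(hap_path)
    if legend_path is None:
        legend_path = hap_path.with_suffix(".legend")
    with open(legend_path, "w") as fh:
        fh.write("id\tchrom\tpos\tallele0\tallele1\n")
        for loc in panel.loci:
            fh.write(
                f"snp{loc.index}\t{loc.chromosome}\t{loc.position}\t"
                f"{loc.allele0}\t{loc.allele1}\n"
            )
    with open(hap_path, "w") as fh:
        for row in panel.haplotypes:
            fh.write(" ".join(str(int(x)) for x in row) + "\n")


def load_vcf_panel(path) -> HaplotypePanel:
    """Read a phased, biallelic-SNP VCF into a panel (two rows per sample)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    n_samples = len(vcf.samples)
    loci: list[SnpLocus] = []
    cols: list[np.ndarray] = []
    for j, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise PanelFormatError(
                f"{var.CHROM}:{var.POS}: not biallelic (ALT={var.ALT})"
            )
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise PanelFormatError(f"{var.CHROM}:{var.POS}: not a SNP")
        col = np.empty(2 * n_samples, dtype=np.int8)
        for s, gt in enumerate(var.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if not phased:
                raise PanelFormatError(
                    f"{var.CHROM}:{var.POS}: unphased genotype for sample "
                    f"{vcf.samples[s]}"
                )
            if a < 0 or b < 0:
                raise PanelFormatError(
                    f"{var.CHROM}:{var.POS}: missing allele for sample "
                    f"{vcf.samples[s]}"
                )
            col[2 * s] = a
            col[2 * s + 1] = b
        loci.append(SnpLocus(j, var.CHROM, var.POS, var.REF, var.ALT[0]))
        cols.append(col)
    if not loci:
        raise PanelFormatError(f"{path}: no records")
    return HaplotypePanel(loci=loci, haplotypes=np.column_stack(cols))


def load_panel(path, format: str = "hap_legend", legend_path=None) -> HaplotypePanel:
    """Load a phased reference panel from disk.

    ``format`` is ``"hap_legend"`` (legend TSV + row-per-haplotype hap file)
    or ``"vcf"`` (phased biallelic VCF; each sample contributes its left
    then right haplotype).
    """
    if format == "hap_legend":
        return load_hap_legend(path, legend_path)
    if format == "vcf":
        return load_vcf_panel(path)
    raise ValueError(f"unknown panel format {format!r}")


# ---------------------------------------------------------------------------
# genotype priors


def genotype_prior_from_panel(
    panel: HaplotypePanel, mode: str = "hwe", pseudocount: float = 1.0
) -> GenotypePrior:
    """Estimate per-locus genotype priors from the reference panel.

    ``mode="hwe"`` computes smoothed allele-1 frequencies
    ``p = (count_1 + pseudocount) / (N_hap + 2*pseudocount)`` and returns the
    Hardy-Weinberg triple ``((1-p)^2, 2p(1-p), p^2)``.  ``mode="count"``
    counts genotype frequencies over consecutive haplotype pairs (rows 2k,
    2k+1 form individual k) with a Laplace pseudocount.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if mode == "hwe":
        counts = panel.haplotypes.sum(axis=0).astype(float)
        p = (counts + pseudocount) / (panel.n_haplotypes + 2 * pseudocount)
        probs = np.column_stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        return GenotypePrior(probs)
    if mode == "count":
        if panel.n_haplotypes % 2 != 0:
            raise ValueError(
                "mode='count' needs an even number of haplotypes "
                "(consecutive pairs form individuals)"
            )
        g = panel.haplotypes[0::2].astype(int) + panel.haplotypes[1::2]
        n_ind = g.shape[0]
        counts = np.stack([(g == k).sum(axis=0) for k in range(3)], axis=1)
        probs = (counts + pseudocount) / (n_ind + 3 * pseudocount)
        return GenotypePrior(probs)
    raise ValueError(f"unknown prior mode {mode!r}")


# ---------------------------------------------------------------------------
# model persistence (versioned JSON)

_MODEL_FORMAT = "ldcall-founder-hmm"
_MODEL_VERSION = 1


def save_model(hmm: HaplotypeHMM, path) -> None:
    """Write a founder HMM to a versioned JSON file (full precision)."""
    doc = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "K": hmm.K,
        "n": hmm.n,
        "initial": hmm.initial.tolist(),
        "transitions": hmm.transitions.tolist(),
        "emissions": hmm.emissions.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> HaplotypeHMM:
    """Read a founder HMM written by :func:`save_model`."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise PanelFormatError(f"{path}: truncated or invalid model file") from exc
    if doc.get("format") != _MODEL_FORMAT:
        raise PanelFormatError(f"{path}: not a {_MODEL_FORMAT} file")
    K, n = doc["K"], doc["n"]
    initial = np.asarray(doc["initial"], dtype=float)
    transitions = np.asarray(doc["transitions"], dtype=float)
    emissions = np.asarray(doc["emissions"], dtype=float)
    if transitions.size == 0:
        transitions = transitions.reshape(max(n - 1, 0), K, K)
    if initial.shape != (K,) or emissions.shape != (n, K, 2) or transitions.shape != (
        max(n - 1, 0),
        K,
        K,
    ):
        raise PanelFormatError(f"{path}: parameter shapes inconsistent with K,n")
    return HaplotypeHMM(initial=initial, transitions=transitions, emissions=emissions)
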