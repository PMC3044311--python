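"""Evaluation harness: concordance against a gold standard, no-call
tradeoff curves, reference-allele bias diagnostics and method comparison
across coverage subsets.

Concordance follows the microarray convention: no-called loci are excluded
from both the numerator and denominator of the accuracy fractions but
counted against the call rate.  Accuracy is reported separately for
homozygous (truth 0 or 2) and heterozygous (truth 1) loci, the split where
low-coverage callers differ most.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import LDGenotypeModel
from .evidence import (
    NO_CALL,
    GenotypeCall,
    ReadData,
    binomial_baseline_call,
    genotype_likelihoods,
    single_snp_call_all,
)
from .panel import GenotypePrior, HaplotypePanel, ParentalModels, genotype_prior_from_panel
from .simulate import downsample_reads


def _as_genotype_array(calls) -> np.ndarray:
    if isinstance(calls, np.ndarray):
        return calls.astype(int)
    if all(isinstance(c, GenotypeCall) for c in calls):
        return np.array([c.genotype for c in calls], dtype=int)
    return np.asarray(calls, dtype=int)


@dataclass
class ConcordanceReport:
    """Accuracy of genotype calls against a gold standard."""

    n_eval: int
    call_rate: float
    overall: float
    homozygous: float
    heterozygous: float
    confusion: np.ndarray  # 3 x 4: truth x (called 0,1,2, no-call)
    mean_ref_ratio: float | None = None

    def summary(self) -> str:
        lines = [
            "Genotype concordance report",
            "=" * 36,
            f"evaluated loci:       {self.n_eval}",
            f"call rate:            {self.call_rate:.4f}",
            f"overall concordance:  {self.overall:.4f}",
            f"homozygous:           {self.homozygous:.4f}",
            f"heterozygous:         {self.heterozygous:.4f}",
        ]
        if self.mean_ref_ratio is not None:
            lines.append(f"mean het ref ratio:   {self.mean_ref_ratio:.4f}")
        lines.append("confusion (rows truth 0/1/2; cols called 0/1/2/no-call):")
        for row in self.confusion:
            lines.append("  " + "  ".join(f"{int(x):6d}" for x in row))
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_eval": [self.n_eval],
                "call_rate": [self.call_rate],
                "overall": [self.overall],
                "homozygous": [self.homozygous],
                "heterozygous": [self.heterozygous],
            }
        )


def concordance(
    calls, truth, nocall_as_error: bool = False
) -> ConcordanceReport:
    """Compare calls with true genotypes, aligned by locus index.

    With ``nocall_as_error`` no-calls count as discordant instead of being
    excluded from the accuracy denominators.
    """
    called_g = _as_genotype_array(calls)
    truth = np.asarray(truth, dtype=int)
    if called_g.shape != truth.shape:
        raise ValueError("calls and truth must cover the same loci")
    n_eval = len(truth)
    if n_eval == 0:
        raise ValueError("no loci to evaluate")
    confusion = np.zeros((3, 4), dtype=int)
    for t, c in zip(truth, called_g):
        confusion[t, 3 if c == NO_CALL else c] += 1
    called_mask = called_g != NO_CALL
    call_rate = float(called_mask.mean())

    def _rate(mask: np.ndarray) -> float:
        """NaN marks an empty stratum (e.g. every het locus no-called)."""
        denom_mask = mask if nocall_as_error else (mask & called_mask)
        denom = int(denom_mask.sum())
        if denom == 0:
            return float("nan")
        hits = int((called_g[denom_mask] == truth[denom_mask]).sum())
        return hits / denom

    hom_mask = (truth == 0) | (truth == 2)
    het_mask = truth == 1
    if not called_mask.any() and not nocall_as_error:
        raise ValueError("all loci are no-calls; nothing to evaluate")
    return ConcordanceReport(
        n_eval=n_eval,
        call_rate=call_rate,
        overall=_rate(np.ones_like(truth, dtype=bool)),
        homozygous=_rate(hom_mask),
        heterozygous=_rate(het_mask),
        confusion=confusion,
    )


def tradeoff_curve(
    posteriors: np.ndarray, genotypes: np.ndarray, truth, thresholds
) -> pd.DataFrame:
    """Call rate vs concordance along a grid of no-call thresholds."""
    from .caller import apply_no_call_threshold

    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("threshold grid must be sorted ascending")
    rows = []
    for t in thresholds:
        g_t = apply_no_call_threshold(genotypes, posteriors, t)
        rep = concordance(g_t, truth)
        rows.append(
            {
                "threshold": t,
                "call_rate": rep.call_rate,
                "overall": rep.overall,
                "homozygous": rep.homozygous,
                "heterozygous": rep.heterozygous,
            }
        )
    return pd.DataFrame(rows)


def ref_allele_ratio_distribution(
    data: ReadData, truth
) -> tuple[np.ndarray, float]:
    """Per-locus reference-allele (allele 0) coverage ratios at het loci.

    Returns the ratio for every truth-heterozygous locus with coverage >= 1
    and their mean.  An unbiased platform gives a mean near 0.5.
    """
    truth = np.asarray(truth, dtype=int)
    ratios = []
    for pileup in data.pileups:
        if truth[pileup.locus_index] != 1 or pileup.coverage == 0:
            continue
        c0, c1 = pileup.allele_counts()
        ratios.append(c0 / (c0 + c1))
    if not ratios:
        raise ValueError("no covered heterozygous loci")
    ratios = np.array(ratios)
    return ratios, float(ratios.mean())


def call_with_method(
    method: str,
    data: ReadData,
    models: ParentalModels | None = None,
    prior: GenotypePrior | None = None,
    threshold: float = 0.0,
) -> np.ndarray:
    """Genotype vector from one of the three callers (hmm / single_snp / binomial)."""
    if method == "hmm":
        if models is None:
            raise ValueError("hmm method needs trained models")
        return LDGenotypeModel(models, data).fit(threshold=threshold).genotypes
    if method == "single_snp":
        if prior is None:
            raise ValueError("single_snp method needs a genotype prior")
        calls = single_snp_call_all(genotype_likelihoods(data), prior)
        return _as_genotype_array(calls)
    if method == "binomial":
        return np.array(
            [binomial_baseline_call(p).genotype for p in data.pileups], dtype=int
        )
    raise ValueError(f"unknown method {method!r}")


def compare_methods(
    data: ReadData,
    truth,
    models: ParentalModels | None = None,
    panel: HaplotypePanel | None = None,
    prior: GenotypePrior | None = None,
    coverage_fractions=(1.0,),
    methods=("hmm", "single_snp", "binomial"),
    seed=0,
    nested: bool = True,
) -> pd.DataFrame:
    """Concordance of each caller at each coverage fraction (tidy table).

    Coverage subsets are drawn by exact downsampling; with ``nested`` they
    share one seeded key ranking, so smaller subsets are contained in larger
    ones, mirroring how coverage-titration subsets are built.
    """
    if prior is None and panel is not None:
        prior = genotype_prior_from_panel(panel)
    rows = []
    for frac in coverage_fractions:
        sub = downsample_reads(data, frac, seed=seed, exact=nested)
        for method in methods:
            g = call_with_method(method, sub, models=models, prior=prior)
            rep = concordance(g, truth)
            rows.append(
                {
                    "method": method,
                    "fraction": frac,
                    "m": sub.m,
                    "call_rate": rep.call_rate,
                    "overall": rep.overall,
                    "homozygous": rep.homozygous,
                    "heterozygous": rep.heterozygous,
                }
            )
    return pd.DataFrame(rows)
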