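"""Baum-Welch estimation of founder-haplotype HMMs from phased panels.

The founder model is a left-to-right HMM with per-locus transition and
emission matrices, so the E step runs a scaled forward-backward pass over
every panel haplotype (vectorised across haplotypes) and the M step
re-normalises per-locus expected counts.  The per-iteration total
log-likelihood is monotone non-decreasing, the standard EM guarantee.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import HaplotypeHMM, HaplotypePanel


@dataclass
class TrainingConfig:
    """Baum-Welch settings.

    K is the founder count (default 7).  ``pseudocount`` is added to every
    expected count before renormalisation so that no emission or transition
    probability collapses to exactly zero — a zero emission would make any
    read carrying the unseen allele impossible downstream.
    """

    K: int = 7
    max_iter: int = 100
    tol: float = 1e-6
    seed: int | None = 0
    pseudocount: float = 1e-6
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def _random_stochastic(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Uniform rows mixed with a Dirichlet(1) draw to break symmetry."""
    k = shape[-1]
    flat = rng.dirichlet(np.ones(k), size=int(np.prod(shape[:-1])))
    rows = 0.9 / k + 0.1 * flat
    return (rows / rows.sum(axis=-1, keepdims=True)).reshape(shape)


def _normalise_counts(counts: np.ndarray, pc: float) -> np.ndarray:
    """Row-normalise expected counts; tiny negative round-off is clipped and
    a row with no mass at all (an unoccupied founder state under zero
    pseudocount) falls back to uniform."""
    counts = np.maximum(counts, 0.0) + pc
    sums = counts.sum(axis=-1, keepdims=True)
    k = counts.shape[-1]
    return np.where(sums > 0.0, counts / np.where(sums > 0.0, sums, 1.0), 1.0 / k)


def _init_model(n: int, K: int, rng: np.random.Generator) -> HaplotypeHMM:
    return HaplotypeHMM(
        initial=_random_stochastic(rng, (K,)),
        transitions=_random_stochastic(rng, (max(n - 1, 0), K, K)),
        emissions=_random_stochastic(rng, (n, K, 2)),
    )


def _forward_backward_panel(hmm: HaplotypeHMM, H: np.ndarray):
    """Scaled forward-backward over all haplotype rows at once.

    Returns (alpha, beta, scale, B) with alpha/beta of shape (n, N, K),
    scale (n, N) and B[i, h, k] = P(H[h, i] | f=k).
    """
    N, n = H.shape
    K = hmm.K
    B = np.empty((n, N, K))
    for i in range(n):
        B[i] = hmm.emissions[i][:, H[:, i]].T
    alpha = np.empty((n, N, K))
    scale = np.empty((n, N))
    a = hmm.initial[None, :] * B[0]
    scale[0] = a.sum(axis=1)
    alpha[0] = a / scale[0][:, None]
    for i in range(1, n):
        a = (alpha[i - 1] @ hmm.transitions[i - 1]) * B[i]
        scale[i] = a.sum(axis=1)
        alpha[i] = a / scale[i][:, None]
    beta = np.empty((n, N, K))
    beta[n - 1] = 1.0
    for i in range(n - 2, -1, -1):
        core = B[i + 1] * beta[i + 1]
        beta[i] = (core @ hmm.transitions[i].T) / scale[i + 1][:, None]
    return alpha, beta, scale, B


def panel_loglik(hmm: HaplotypeHMM, panel: HaplotypePanel) -> float:
    """Total log-likelihood of all panel haplotypes under the model."""
    _, _, scale, _ = _forward_backward_panel(hmm, panel.haplotypes)
    return float(np.log(scale).sum())


def haplotype_loglik(hmm: HaplotypeHMM, h) -> float:
    """log P(h | M) by the scaled forward algorithm.

    Per-locus scaling keeps the recursion stable for chromosome-scale n.
    """
    h = np.asarray(h)
    if h.shape != (hmm.n,):
        raise ValueError(f"haplotype length {h.shape} != model n={hmm.n}")
    if not np.isin(h, (0, 1)).all():
        raise ValueError("haplotype entries must be 0/1")
    _, _, scale, _ = _forward_backward_panel(hmm, h[None, :])
    return float(np.log(scale).sum())


def baum_welch(
    panel: HaplotypePanel, config: TrainingConfig | None = None
) -> tuple[HaplotypeHMM, list[float]]:
    """Train a K-founder HMM on a phased panel.

    Returns the trained model and the per-iteration log-likelihood trace
    (evaluated at the parameters entering each iteration).  With
    ``n_restarts > 1`` the restart with the best final log-likelihood wins.
    """
    if config is None:
        config = TrainingConfig()
    if panel.n_haplotypes == 0 or panel.n == 0:
        raise ValueError("panel is empty")
    n_distinct = len({tuple(row) for row in panel.haplotypes.tolist()})
    if config.K > n_distinct:
        warnings.warn(
            f"K={config.K} exceeds the {n_distinct} distinct panel haplotypes",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    best: tuple[float, HaplotypeHMM, list[float]] | None = None
    for _ in range(max(config.n_restarts, 1)):
        model, trace = _baum_welch_once(panel, config, rng)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], model, trace)
    return best[1], best[2]


def _baum_welch_once(panel, config, rng) -> tuple[HaplotypeHMM, list[float]]:
    H = panel.haplotypes
    N, n = H.shape
    K = config.K
    pc = config.pseudocount
    model = _init_model(n, K, rng)
    trace: list[float] = []
    for _ in range(config.max_iter):
        alpha, beta, scale, B = _forward_backward_panel(model, H)
        ll = float(np.log(scale).sum())
        if trace and ll - trace[-1] < config.tol:
            trace.append(ll)
            break
        trace.append(ll)
        gamma = alpha * beta  # (n, N, K); rows sum to 1 per haplotype
        new_initial = _normalise_counts(gamma[0].sum(axis=0)[None, :], pc)[0]
        new_trans = np.empty_like(model.transitions)
        for i in range(n - 1):
            core = (B[i + 1] * beta[i + 1]) / scale[i + 1][:, None]
            xi = (alpha[i].T @ core) * model.transitions[i]
            new_trans[i] = _normalise_counts(xi, pc)
        new_emis = np.empty_like(model.emissions)
        for i in range(n):
            ones = H[:, i].astype(float)
            c1 = gamma[i].T @ ones
            c0 = gamma[i].sum(axis=0) - c1
            new_emis[i] = _normalise_counts(np.column_stack([c0, c1]), pc)
        model = HaplotypeHMM(new_initial, new_trans, new_emis)
    return model, trace


class FounderHMM:
    """Founder-haplotype HMM model bound to a phased reference panel.

    Parameters
    ----------
    panel : HaplotypePanel
        Phased haplotypes to fit the model to.
    K : int
        Number of latent founder haplotypes (default 7).

    Examples
    --------
    >>> res = FounderHMM(panel, K=7).fit(seed=0)
    >>> res.hmm          # trained HaplotypeHMM parameters
    >>> res.loglik_trace  # monotone EM trace
    """

    def __init__(self, panel: HaplotypePanel, K: int = 7):
        self.panel = panel
        self.K = K

    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-6,
        seed: int | None = 0,
        pseudocount: float = 1e-6,
        n_restarts: int = 1,
    ) -> "FounderHMMResults":
        config = TrainingConfig(
            K=self.K,
            max_iter=max_iter,
            tol=tol,
            seed=seed,
            pseudocount=pseudocount,
            n_restarts=n_restarts,
        )
        hmm, trace = baum_welch(self.panel, config)
        return FounderHMMResults(self, hmm, trace, config)


@dataclass
class FounderHMMResults:
    """Trained founder HMM: parameters, likelihood trace and simulation."""

    model: FounderHMM
    hmm: HaplotypeHMM
    loglik_trace: list[float]
    config: TrainingConfig

    @property
    def converged(self) -> bool:
        if len(self.loglik_trace) < 2:
            return False
        return (self.loglik_trace[-1] - self.loglik_trace[-2]) < self.config.tol

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)

    def haplotype_loglik(self, h) -> float:
        return haplotype_loglik(self.hmm, h)

    def simulate(self, n_haplotypes: int, seed=None) -> np.ndarray:
        """Draw haplotypes from the fitted model."""
        return self.hmm.simulate_haplotypes(n_haplotypes, seed=seed)

    def summary(self) -> str:
        lines = [
            "Founder haplotype HMM (Baum-Welch fit)",
            "=" * 42,
            f"loci (n):              {self.hmm.n}",
            f"founders (K):          {self.hmm.K}",
            f"panel haplotypes:      {self.model.panel.n_haplotypes}",
            f"EM iterations:         {self.n_iter}",
            f"converged:             {self.converged}",
            f"final log-likelihood:  {self.loglik_trace[-1]:.4f}",
            f"mean loglik/haplotype: "
            f"{self.loglik_trace[-1] / self.model.panel.n_haplotypes:.4f}",
        ]
        return "\n".join(lines)

    def plot_loglik(self, ax=None):
        """Plot the EM log-likelihood trace."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(len(self.loglik_trace)), self.loglik_trace, marker=".")
        ax.set_xlabel("EM iteration")
        ax.set_ylabel("panel log-likelihood")
        return ax
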