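"""Two-compartment mixture of codon usage and the single-parameter fit.

A genome's codon frequencies are modelled as the algebraic sum of two
compartments mixed in proportion alpha,

    y = alpha * y1 + (1 - alpha) * y2,

where compartment 1 carries the truncated-Gaussian (weak-bias)
sequence and compartment 2 the empirical (strong-bias) sequence. An
observed genome does not reveal which codon occupies which rank within
each compartment, so the rank-to-codon assignment of compartment 2 is
randomized before the scaled sequences are summed and re-ordered. The
mean over many such randomizations is the theoretical frequency/rank
curve; individual randomizations scatter about it with an rms of order
1e-3, which sets the attainable residual floor of any fit.

Because the compartments are paired at independent random ranks, the
squared deviations about the uniform frequency add in quadrature,
giving the closed-form bias of the mixture,

    B(alpha) = sqrt( (N-1) * (alpha^2 s1^2 + (1-alpha)^2 s2^2) ),

with N = 64 and s1, s2 the compartment standard deviations about 1/64.

``CodonMixture`` is the model object: constructed from an observed
ordered sequence (or a count table) plus the two compartment
sequences, its :meth:`CodonMixture.fit` scans and refines alpha to
minimize the rms residual between observed and mean theoretical
frequencies, returning a :class:`MixtureFitResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bias import OrderedFrequencySequence, bias, order_descending
from .gaussian import (N_CODONS, UNIFORM, CompartmentSequence,
                       expected_ordered_sequence_exact, solve_mu)
from .io import CodonCountTable, FrequencyVector

DEFAULT_TRIALS = 100
DEFAULT_SWAP_CYCLES = 10_000


def theoretical_B(alpha: float, s1: float, s2: float, n_codons: int = N_CODONS) -> float:
    """Bias of the mixture from the compartment sds (variance composition)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if s1 < 0 or s2 < 0:
        raise ValueError("compartment sds must be non-negative")
    return float(np.sqrt((n_codons - 1) * (alpha ** 2 * s1 ** 2 + (1 - alpha) ** 2 * s2 ** 2)))


def scramble_permutation(rng: np.random.Generator,
                         swap_cycles: int = DEFAULT_SWAP_CYCLES,
                         method: str = "swaps") -> np.ndarray:
    """Random rank-to-codon assignment for compartment 2.

    ``method="swaps"`` transposes randomly chosen pairs of ranks for
    ``swap_cycles`` cycles (the construction used to scramble the
    compartment-2 colors); ``method="permutation"`` draws a uniform
    random permutation directly, which is statistically equivalent and
    faster.
    """
    if method == "permutation":
        return rng.permutation(N_CODONS)
    if method != "swaps":
        raise ValueError(f"unknown scramble method {method!r}")
    perm = np.arange(N_CODONS)
    pairs = rng.integers(0, N_CODONS, size=(swap_cycles, 2))
    for i, j in pairs:
        perm[i], perm[j] = perm[j], perm[i]
    return perm


def merge_once(comp1: CompartmentSequence, comp2: CompartmentSequence,
               alpha: float, rng: np.random.Generator,
               swap_cycles: int = DEFAULT_SWAP_CYCLES,
               scramble: str = "swaps") -> OrderedFrequencySequence:
    """One randomized merge of the two compartments at proportion alpha.

    Compartment 1 keeps its rank order; compartment 2's rank-to-codon
    assignment is scrambled; the scaled frequencies are summed per
    codon and re-ordered descending.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    perm = scramble_permutation(rng, swap_cycles, scramble)
    y = alpha * comp1.values + (1.0 - alpha) * comp2.values[perm]
    return order_descending(y)


class _MergeEngine:
    """Precomputed randomizations for evaluating mean merged sequences.

    The trial permutations depend only on (seed, trials, swap_cycles,
    scramble), not on alpha, so one engine serves every candidate
    alpha with common random numbers — the objective is then
    deterministic and smooth in alpha.
    """

    def __init__(self, comp1: CompartmentSequence, comp2: CompartmentSequence,
                 trials: int = DEFAULT_TRIALS, seed: int = 0,
                 swap_cycles: int = DEFAULT_SWAP_CYCLES, scramble: str = "swaps"):
        if trials < 1:
            raise ValueError("trials must be >= 1")
        self.comp1, self.comp2 = comp1, comp2
        self.trials = trials
        rng = np.random.default_rng(seed)
        perms = np.stack([scramble_permutation(rng, swap_cycles, scramble)
                          for _ in range(trials)])
        self._c2_scrambled = comp2.values[perms]  # (trials, 64)

    def trial_sequences(self, alpha: float) -> np.ndarray:
        """All trial sequences at alpha, each sorted descending; (trials, 64)."""
        y = alpha * self.comp1.values + (1.0 - alpha) * self._c2_scrambled
        return -np.sort(-y, axis=1)

    def mean_sequence(self, alpha: float) -> tuple[np.ndarray, float]:
        """Mean theoretical sequence and the trial scatter about it."""
        trials = self.trial_sequences(alpha)
        m = trials.mean(axis=0)
        m = -np.sort(-m)
        sample_rms = float(np.sqrt(np.mean((trials - m) ** 2)))
        return m / m.sum(), sample_rms


def mean_merged(comp1: CompartmentSequence, comp2: CompartmentSequence,
                alpha: float, trials: int = DEFAULT_TRIALS, seed: int = 0,
                swap_cycles: int = DEFAULT_SWAP_CYCLES,
                scramble: str = "swaps") -> tuple[OrderedFrequencySequence, float]:
    """Mean over ``trials`` independent merges (each re-ordered before
    averaging) and the rms scatter of individual trials about the mean.
    """
    if trials < 2:
        raise ValueError("trials must be >= 2")
    engine = _MergeEngine(comp1, comp2, trials, seed, swap_cycles, scramble)
    m, rms = engine.mean_sequence(alpha)
    return OrderedFrequencySequence(m), rms


@dataclass
class MixtureFitResults:
    """Results of fitting the mixture proportion alpha to one genome.

    Attributes
    ----------
    alpha_hat : float
        Fitted proportion of the weak-bias (Gaussian) compartment.
    rms_residual : float
        sqrt(mean over 64 ranks of squared residuals) at alpha_hat.
    theoretical_sequence : OrderedFrequencySequence
        Mean theoretical frequency/rank curve at alpha_hat.
    observed_B, predicted_B : float
        Bias of the observed sequence and the closed-form mixture bias
        at alpha_hat.
    sample_rms : float
        Trial scatter about the mean theoretical curve at alpha_hat —
        the residual floor set by unknown codon ranks.
    residuals : ndarray
        observed minus theoretical frequency, per rank.
    """

    alpha_hat: float
    rms_residual: float
    theoretical_sequence: OrderedFrequencySequence
    observed_B: float
    predicted_B: float
    sample_rms: float
    residuals: np.ndarray
    grid_step: float
    trials: int
    seed: int
    genome_id: str = ""
    model: "CodonMixture | None" = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Two-compartment codon usage mixture fit",
            "=======================================",
            f"genome:                {self.genome_id or '<unnamed>'}",
            f"alpha (Gaussian frac): {self.alpha_hat:.3f}  (grid {self.grid_step}, refined to 1e-3)",
            f"rms residual:          {self.rms_residual:.3e}",
            f"residual floor (rank scatter): {self.sample_rms:.3e}",
            f"observed bias B:       {self.observed_B:.4f}",
            f"predicted bias B(alpha): {self.predicted_B:.4f}",
            f"trials: {self.trials}   seed: {self.seed}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs theoretical frequency/rank curves with residuals."""
        from .plotting import plot_fit
        return plot_fit(self, ax=ax)


class CodonMixture:
    """Model: an observed ordered codon frequency sequence explained as a
    two-compartment mixture with a single free proportion alpha.

    Parameters
    ----------
    observed : OrderedFrequencySequence | FrequencyVector | array-like
        The genome's 64 codon frequencies (ordered internally).
    comp1 : CompartmentSequence, optional
        Weak-bias compartment; defaults to the exact expected sequence
        of the truncated Gaussian with ``sigma`` (mu from the mean
        constraint).
    comp2 : CompartmentSequence, optional
        Strong-bias compartment; defaults to the packaged synthetic
        stand-in (sd 0.0207).
    trials, swap_cycles, seed, scramble
        Randomization settings for the mean theoretical curve.
    """

    def __init__(self, observed, comp1: CompartmentSequence | None = None,
                 comp2: CompartmentSequence | None = None, *,
                 sigma: float = 0.009, trials: int = DEFAULT_TRIALS,
                 swap_cycles: int = DEFAULT_SWAP_CYCLES, seed: int = 0,
                 scramble: str = "swaps", genome_id: str = ""):
        if isinstance(observed, (FrequencyVector, OrderedFrequencySequence)):
            self.observed = order_descending(observed)
        else:
            v = np.asarray(observed, dtype=float)
            self.observed = order_descending(v / v.sum())
        if comp1 is None:
            comp1 = expected_ordered_sequence_exact(solve_mu(sigma))
        if comp2 is None:
            from .empirical import load_packaged_strong_compartment
            comp2 = load_packaged_strong_compartment()
        self.comp1, self.comp2 = comp1, comp2
        self.trials, self.swap_cycles = trials, swap_cycles
        self.seed, self.scramble = seed, scramble
        self.genome_id = genome_id
        self._engine: _MergeEngine | None = None

    @classmethod
    def from_counts(cls, table: CodonCountTable, **kwargs) -> "CodonMixture":
        kwargs.setdefault("genome_id", table.genome_id)
        return cls(table.to_frequencies(), **kwargs)

    @property
    def engine(self) -> _MergeEngine:
        if self._engine is None:
            self._engine = _MergeEngine(self.comp1, self.comp2, self.trials,
                                        self.seed, self.swap_cycles, self.scramble)
        return self._engine

    def _rms(self, alpha: float) -> float:
        m, _ = self.engine.mean_sequence(alpha)
        return float(np.sqrt(np.mean((self.observed.values - m) ** 2)))

    def fit(self, grid_step: float = 0.01, refine_tol: float = 1e-3) -> MixtureFitResults:
        """Grid-scan alpha over [0, 1], then golden-section refine.

        The same trial randomizations are used for every candidate
        alpha, making the rms objective a deterministic function of
        alpha; the grid minimum is refined on the flanking interval.
        """
        if not 0 < grid_step <= 0.1:
            raise ValueError("grid_step must lie in (0, 0.1]")
        grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
        grid = np.clip(grid, 0.0, 1.0)
        vals = np.array([self._rms(a) for a in grid])
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        alpha_hat = _golden_section(self._rms, lo, hi, refine_tol)

        m, sample_rms = self.engine.mean_sequence(alpha_hat)
        resid = self.observed.values - m
        rms = float(np.sqrt(np.mean(resid ** 2)))
        pred_B = theoretical_B(alpha_hat, self.comp1.sd, self.comp2.sd)
        return MixtureFitResults(
            alpha_hat=float(alpha_hat), rms_residual=rms,
            theoretical_sequence=OrderedFrequencySequence(m),
            observed_B=bias(self.observed), predicted_B=pred_B,
            sample_rms=sample_rms, residuals=resid,
            grid_step=grid_step, trials=self.trials, seed=self.seed,
            genome_id=self.genome_id, model=self,
        )


def _golden_section(f, lo: float, hi: float, tol: float) -> float:
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def fit_alpha(observed, comp1: CompartmentSequence, comp2: CompartmentSequence,
              grid_step: float = 0.01, trials: int = DEFAULT_TRIALS,
              seed: int = 0, swap_cycles: int = DEFAULT_SWAP_CYCLES,
              scramble: str = "swaps") -> MixtureFitResults:
    """Functional wrapper around :class:`CodonMixture` + :meth:`fit`."""
    model = CodonMixture(observed, comp1, comp2, trials=trials,
                         swap_cycles=swap_cycles, seed=seed, scramble=scramble)
    return model.fit(grid_step=grid_step)
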