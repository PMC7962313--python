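"""Phased (codon-position-aware) Markov chain models of coding DNA.

The model conditions the distribution of each base on the previous ``m``
bases (the context) and on the codon position ("phase", 0/1/2) of the
emitted base.  It is the background model used both to synthesize genomes
with a controlled compositional signature and to score word exceptionality
on real or simulated coding sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabet import encode

N_PHASES = 3

_GC_MASK = np.array([0.0, 1.0, 1.0, 0.0])  # A C G T


@dataclass
class PhasedMarkovModel:
    """Order-``m`` Markov chain with phase-dependent transition rows.

    Parameters
    ----------
    order:
        Number of previous bases conditioned on (m >= 0).
    probs:
        Array of shape ``(3, 4**m, 4)``; ``probs[phase, context, base]`` is
        the probability of emitting ``base`` at codon position ``phase``
        given the ``m`` preceding bases encoded as ``context``.
    row_counts:
        Optional ``(3, 4**m)`` array of training observations per row; rows
        with zero count are "unobserved" and carry no usable probabilities.
    """

    order: int
    probs: np.ndarray
    row_counts: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        expected_shape = (N_PHASES, 4**self.order, 4)
        if self.probs.shape != expected_shape:
            raise ValueError(
                f"probs shape {self.probs.shape} != {expected_shape} for order {self.order}"
            )
        self.validate()

    @property
    def n_contexts(self) -> int:
        return 4**self.order

    def observed_rows(self) -> np.ndarray:
        """Boolean (3, 4**m) mask of rows with usable probabilities."""
        if self.row_counts is None:
            return np.ones((N_PHASES, self.n_contexts), dtype=bool)
        return self.row_counts > 0

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.probs < -atol) or np.any(self.probs > 1 + atol):
            raise ValueError("transition probabilities outside [0, 1]")
        sums = self.probs.sum(axis=2)
        bad = ~np.isclose(sums, 1.0, atol=atol) & self.observed_rows()
        if np.any(bad):
            raise ValueError("observed transition rows must sum to 1")

    def copy(self) -> "PhasedMarkovModel":
        rc = None if self.row_counts is None else self.row_counts.copy()
        return PhasedMarkovModel(self.order, self.probs.copy(), rc)

    # -- stationary behaviour -------------------------------------------------

    def stationary_distribution(self, n_iter: int = 2000, tol: float = 1e-13) -> np.ndarray:
        """Stationary distribution over (phase, context) states.

        The chain over states (phase, context) is deterministic in phase
        (phase advances by 1 mod 3 every step), so the stationary vector is
        computed by power iteration on the full state space and averages the
        three phase-conditional context distributions with weight 1/3 each.
        """
        S = self.n_contexts
        v = np.full((N_PHASES, S), 1.0 / (N_PHASES * S))
        new_ctx = (np.arange(S)[:, None] * 4 + np.arange(4)[None, :]) % S
        for _ in range(n_iter):
            nxt = np.zeros_like(v)
            for phase in range(N_PHASES):
                flow = v[phase][:, None] * self.probs[phase]  # (S, 4)
                np.add.at(nxt[(phase + 1) % N_PHASES], new_ctx.ravel(), flow.ravel())
            if np.abs(nxt - v).max() < tol:
                v = nxt
                break
            v = nxt
        return v / v.sum()

    def stationary_gc(self) -> float:
        """Long-run expected G+C fraction of sequences emitted by the model."""
        v = self.stationary_distribution()
        p_gc = self.probs @ _GC_MASK  # (3, S)
        return float((v * p_gc).sum())

    # -- emission -------------------------------------------------------------

    def sample(
        self,
        n: int,
        rng: np.random.Generator,
        start_phase: int = 0,
        start_context: int | None = None,
    ) -> np.ndarray:
        """Emit ``n`` base codes starting at the given phase."""
        if n < 0:
            raise ValueError("n must be >= 0")
        S = self.n_contexts
        cum = np.cumsum(self.probs, axis=2)
        ctx = int(rng.integers(S)) if start_context is None else int(start_context)
        phase = start_phase % N_PHASES
        u = rng.random(n)
        out = np.empty(n, dtype=np.int8)
        for i in range(n):
            row = cum[phase, ctx]
            a = int(np.searchsorted(row, u[i], side="right"))
            if a > 3:
                a = 3
            out[i] = a
            ctx = (ctx * 4 + a) % S
            phase = (phase + 1) % N_PHASES
        return out


def uniform_model(order: int = 2) -> PhasedMarkovModel:
    """Model emitting i.i.d. uniform bases regardless of phase and context."""
    probs = np.full((N_PHASES, 4**order, 4), 0.25)
    return PhasedMarkovModel(order, probs)


def fit_phased_markov(cds: str, m: int = 2) -> PhasedMarkovModel:
    """Maximum-likelihood phased Markov fit on a concatenated coding sequence.

    For every phase ``phi`` (position mod 3 in the concatenated CDS) and
    context ``c`` of length ``m``, the transition probability is the ratio of
    phased transition counts ``N_phi(c, a) / N_phi(c, .)``.  Rows never
    observed in the sequence keep a zero count and are flagged unobserved.

    The sequence length must be a multiple of 3 (whole codons) so that
    phases are well defined across the whole concatenation.
    """
    if len(cds) == 0:
        raise ValueError("empty coding sequence")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if m < 0:
        raise ValueError("order must be >= 0")
    if len(cds) < 10 * 4 ** (m + 1):
        warnings.warn(
            f"CDS length {len(cds)} is short for order {m}; "
            f">= {10 * 4 ** (m + 1)} positions recommended",
            stacklevel=2,
        )
    codes = encode(cds)
    if np.any(codes < 0):
        raise ValueError("coding sequence contains non-ACGT characters")
    S = 4**m
    counts = np.zeros((N_PHASES, S, 4), dtype=np.int64)
    L = len(codes)
    if L <= m:
        raise ValueError("sequence shorter than order + 1")
    # context code at every emission position t in [m, L)
    ctx = np.zeros(L - m, dtype=np.int64)
    for j in range(m):
        ctx = ctx * 4 + codes[j : j + L - m]
    nxt = codes[m:].astype(np.int64)
    phases = (np.arange(m, L) % N_PHASES).astype(np.int64)
    np.add.at(counts, (phases, ctx, nxt), 1)
    row_counts = counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / row_counts[:, :, None]
    probs[row_counts == 0] = 0.0
    return PhasedMarkovModel(m, probs, row_counts)
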