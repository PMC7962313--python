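"""Word exceptionality scores on coding regions under a phased Markov model.

The second profile type of the analysis: for each k-mer, a Gaussian
standardized deviation between its observed count in a genome's
concatenated coding regions and the count expected under a phase-aware
(3-phase) Markov chain of order ``m`` fitted on that same concatenation.
Because the background model conditions on the phased short-word (codon)
composition, a large positive or negative score flags a word that is
unexpectedly frequent or rare *given* the codon usage of the genome, not
merely frequent or rare.

Conventions
-----------
* A word occurrence is assigned the phase of its start position in the
  concatenated CDS (position mod 3, 0-based).  CDS concatenation preserves
  frame, so phases are consistent across gene boundaries.
* The expected count conditions on the *observed* phased prefix counts:

    E(w) = sum_phi N_phi(w[0:m]) * prod_{j=m..k-1}
           pi_{(phi+j) mod 3}(w[j] | w[j-m:j])

  where ``N_phi(p)`` counts occurrences of the m-mer ``p`` at word-start
  positions of phase ``phi`` (positions 0 .. L-k).
* The default variance is the Poisson plug-in V(w) = E(w); words with
  E(w) = 0 or with an unobserved required context get a missing (NaN)
  score, never a silent 0.  Missing scores are imputed as 0 only at matrix
  assembly, with per-genome missingness logged and capped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import encode, kmer_strings
from .io import GenomeRecord, NoCodingSequenceError, extract_cds
from .markov import N_PHASES, PhasedMarkovModel, fit_phased_markov
from .profiles import count_kmers

logger = logging.getLogger(__name__)

__all__ = [
    "ExceptionalityProfile",
    "fit_phased_markov",
    "phased_prefix_counts",
    "expected_counts",
    "exceptionality_profile",
    "exceptionality_matrix",
]


@dataclass
class ExceptionalityProfile:
    genome_id: str
    k: int
    scores: np.ndarray  # length 4**k; NaN where the score is undefined
    expected: np.ndarray
    observed: np.ndarray
    model: PhasedMarkovModel
    n_positions: int  # usable word start positions

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.scores)


def phased_prefix_counts(cds: str, k: int, m: int) -> np.ndarray:
    """Counts N_phi(p) of m-mer prefixes at word-start positions per phase.

    Start positions run over 0 .. L-k so that a full k-word fits; the phase
    of a start position is its index mod 3.  For m=0 the "prefix" is empty
    and the count is simply the number of start positions at each phase.
    """
    codes = encode(cds)
    L = len(codes)
    n_start = L - k + 1
    if n_start <= 0:
        raise ValueError(f"sequence length {L} < k = {k}")
    counts = np.zeros((N_PHASES, 4**m), dtype=np.int64)
    prefix = np.zeros(n_start, dtype=np.int64)
    valid = np.ones(n_start, dtype=bool)
    for j in range(m):
        col = codes[j : j + n_start]
        prefix = prefix * 4 + col
        valid &= col >= 0
    phases = np.arange(n_start) % N_PHASES
    np.add.at(counts, (phases[valid], prefix[valid]), 1)
    return counts


def expected_counts(
    model: PhasedMarkovModel, prefix_counts: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Chain-rule expected counts of all 4**k words, summed over start phases.

    Returns ``(expected, missing)``: NaN marks words that require a
    transition row the model never observed (from a prefix that does occur),
    and ``missing`` is the corresponding boolean mask.
    """
    m = model.order
    if k < m + 1:
        raise ValueError(f"word length k={k} must be >= order + 1 = {m + 1}")
    n_words = 4**k
    words = np.arange(n_words)

    def digit(j: int) -> np.ndarray:
        # base at 0-based position j of each word (first base most significant)
        return (words >> (2 * (k - 1 - j))) & 3

    prefix_code = words >> (2 * (k - m))  # first m bases
    observed = model.observed_rows()
    # log-probability of the transition chain per phase, NaN-propagating
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(observed[..., None], np.log(model.probs), np.nan)
    expected = np.zeros(n_words)
    missing = np.zeros(n_words, dtype=bool)
    ctx = np.zeros(n_words, dtype=np.int64)
    mask = 4**m
    # context codes at each emission position j (the m bases before j)
    ctx_codes = []
    for j in range(m, k):
        c = (words >> (2 * (k - j))) % mask if m > 0 else np.zeros(n_words, dtype=np.int64)
        ctx_codes.append(c)
    for phi in range(N_PHASES):
        n_pre = prefix_counts[phi][prefix_code].astype(float)
        log_chain = np.zeros(n_words)
        for j in range(m, k):
            log_chain = log_chain + logp[(phi + j) % N_PHASES, ctx_codes[j - m], digit(j)]
        contrib = n_pre * np.exp(log_chain)
        # prefixes absent at this phase contribute exactly 0, even if the
        # chain would be undefined there
        contrib = np.where(n_pre == 0, 0.0, contrib)
        phase_missing = (n_pre > 0) & np.isnan(contrib)
        missing |= phase_missing
        expected = expected + np.where(phase_missing, 0.0, contrib)
    expected = np.where(missing, np.nan, expected)
    return expected, missing


def exceptionality_profile(
    genome: "GenomeRecord | str",
    k: int = 5,
    m: int = 2,
    variance_mode: str = "poisson_plugin",
    genome_id: str = "",
) -> ExceptionalityProfile:
    """Exceptionality scores of all k-mers of a genome's coding regions.

    ``genome`` is a GenomeRecord with CDS annotation or a raw in-frame
    coding sequence.  Scores are (O - E) / sqrt(V); with the default
    ``poisson_plugin`` variance V = E.  The ``conditional`` mode (the exact
    conditional Gaussian variance accounting for model estimation) is
    reserved and not implemented.
    """
    if variance_mode == "conditional":
        raise NotImplementedError(
            "conditional Gaussian variance is reserved; use 'poisson_plugin'"
        )
    if variance_mode != "poisson_plugin":
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    if isinstance(genome, str):
        cds = genome
        gid = genome_id
    else:
        cds = extract_cds(genome)
        gid = genome.id
    model = fit_phased_markov(cds, m=m)
    prefix = phased_prefix_counts(cds, k, m)
    expected, missing = expected_counts(model, prefix, k)
    observed = count_kmers(cds, k).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (observed - expected) / np.sqrt(expected)
    zero_e = ~missing & np.isfinite(expected) & (expected == 0)
    scores[zero_e] = np.nan
    n_positions = len(cds) - k + 1
    return ExceptionalityProfile(
        genome_id=gid,
        k=k,
        scores=scores,
        expected=expected,
        observed=observed,
        model=model,
        n_positions=n_positions,
    )


def exceptionality_matrix(
    records: list[GenomeRecord],
    k: int = 5,
    m: int = 2,
    max_missing_frac: float = 0.05,
) -> pd.DataFrame:
    """Per-genome exceptionality score vectors stacked into a matrix.

    Genomes without CDS annotation are excluded (logged).  Missing word
    scores are imputed as 0 at assembly, but a genome whose missing
    fraction exceeds ``max_missing_frac`` is excluded instead.
    """
    ids, rows = [], []
    for rec in records:
        try:
            prof = exceptionality_profile(rec, k=k, m=m)
        except NoCodingSequenceError:
            logger.warning("genome %s has no CDS annotation; excluded", rec.id)
            continue
        frac = float(prof.missing.mean())
        if frac > max_missing_frac:
            logger.warning(
                "genome %s: %.1f%% missing word scores (> %.1f%%); excluded",
                rec.id, 100 * frac, 100 * max_missing_frac,
            )
            continue
        if frac > 0:
            logger.info(
                "genome %s: imputing %d missing word scores as 0",
                rec.id, int(prof.missing.sum()),
            )
        rows.append(np.nan_to_num(prof.scores, nan=0.0))
        ids.append(rec.id)
    if len(rows) < 2:
        raise ValueError(f"need >= 2 usable genomes, got {len(rows)}")
    return pd.DataFrame(np.vstack(rows), index=ids, columns=kmer_strings(k))
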