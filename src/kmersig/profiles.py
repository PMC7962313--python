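"""Whole-genome k-mer profiles and coding-region codon profiles.

A k-mer profile is the vector of the 4**k overlapping k-mer frequencies of
a genome (single strand by default, with optional canonical collapsing);
a codon profile is the vector of 64 in-frame triplet frequencies of the
concatenated coding regions.  Feature vectors are always indexed
lexicographically (A < C < G < T).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .alphabet import encode, kmer_strings, revcomp_codes

logger = logging.getLogger(__name__)


class EmptyProfileError(ValueError):
    """No valid k-mer window in the sequence."""


def count_kmers(sequence: str, k: int, canonical: bool = False) -> np.ndarray:
    """Count all overlapping k-mer windows (step 1) on the given strand.

    Windows containing N are skipped.  With ``canonical=True`` each window
    is pooled with its reverse complement under the lexicographically
    smaller of the two codes (the larger code's slot stays 0).
    """
    if k <= 0:
        raise ValueError(f"k must be >= 1, got {k}")
    n_feat = 4**k
    codes = encode(sequence)
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(n_feat, dtype=np.int64)
    window = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        window = window * 4 + col
        valid &= col >= 0
    counts = np.bincount(window[valid], minlength=n_feat).astype(np.int64)
    if canonical:
        rc = revcomp_codes(k)
        canon = np.minimum(np.arange(n_feat), rc)
        pooled = np.zeros(n_feat, dtype=np.int64)
        np.add.at(pooled, canon, counts)
        counts = pooled
    return counts


def to_frequencies(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total <= 0:
        raise EmptyProfileError("profile has zero total count")
    return counts / total


def codon_frequencies(cds: str) -> np.ndarray:
    """Non-overlapping in-frame triplet frequencies of a coding sequence.

    Equivalent to the phase-0 3-mer frequency profile of the CDS; stop
    codons are counted as observed.
    """
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a positive multiple of 3")
    codes = encode(cds)
    triplets = codes[0::3] * 16 + codes[1::3] * 4 + codes[2::3]
    valid = (codes[0::3] >= 0) & (codes[1::3] >= 0) & (codes[2::3] >= 0)
    counts = np.bincount(triplets[valid], minlength=64)
    return to_frequencies(counts)


def profile_matrix(
    genomes,
    k: int = 5,
    mode: str = "kmer",
    canonical: bool = False,
) -> pd.DataFrame:
    """Stack per-genome profiles into a (genomes x features) frequency matrix.

    ``genomes`` is an iterable of ``(id, sequence)`` pairs or GenomeRecords;
    in ``codon`` mode the sequences must be in-frame coding sequences.
    Genomes with empty profiles are dropped with a log entry; fewer than two
    usable rows is an error.
    """
    if mode not in ("kmer", "codon"):
        raise ValueError(f"unknown mode {mode!r}")
    ids, rows = [], []
    for g in genomes:
        gid, seq = (g.id, g.sequence) if hasattr(g, "sequence") else g
        try:
            if mode == "codon":
                freqs = codon_frequencies(seq)
            else:
                freqs = to_frequencies(count_kmers(seq, k, canonical=canonical))
        except (EmptyProfileError, ValueError) as exc:
            logger.warning("dropping genome %s from profile matrix: %s", gid, exc)
            continue
        ids.append(gid)
        rows.append(freqs)
    if len(rows) < 2:
        raise ValueError(f"need >= 2 usable genomes, got {len(rows)}")
    columns = kmer_strings(3 if mode == "codon" else k)
    return pd.DataFrame(np.vstack(rows), index=ids, columns=columns)
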