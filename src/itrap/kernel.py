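"""BLOSUM k-mer string-kernel similarity between CDR3 sequences.

The raw kernel between sequences s and t sums, over the configured k-mer
lengths, the products of position-wise substitution kernels over every pair
of k-mers (one from each sequence):

    K(s, t) = sum_k sum_{a in kmers_k(s)} sum_{b in kmers_k(t)} prod_i kappa(a_i, b_i)

with kappa(x, y) = exp(beta * BLOSUM62(x, y)), a positive substitution kernel.
The reported similarity is the cosine-normalized K(s, t) / sqrt(K(s,s) K(t,t)),
which is 1 for identical sequences and symmetric.  The similarity between two
paired-chain TCRs is the sum of their alpha-alpha and beta-beta chain
similarities, bounded by [0, 2].
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ConfigError

DEFAULT_BETA = 0.11387
DEFAULT_K = (1, 2, 3)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


@lru_cache(maxsize=8)
def _kappa_matrix(beta: float) -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.empty((len(_AA), len(_AA)))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            m[i, j] = np.exp(beta * blosum[a][b])
    return m


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ConfigError(f"non-IUPAC residue {exc.args[0]!r} in sequence {seq!r}")


def raw_kernel(s: str, t: str, k_lengths=DEFAULT_K, beta: float = DEFAULT_BETA) -> float:
    """Unnormalized k-mer substitution kernel between two sequences."""
    if not s or not t:
        raise ConfigError("kernel similarity requires non-empty sequences")
    kappa = _kappa_matrix(beta)
    si, ti = _encode(s), _encode(t)
    m = kappa[np.ix_(si, ti)]
    total = 0.0
    prod = m
    for k in range(1, max(k_lengths) + 1):
        if k > 1:
            if prod.shape[0] < 2 or prod.shape[1] < 2:
                break
            prod = prod[:-1, :-1] * m[k - 1:, k - 1:]
        if k in k_lengths:
            total += float(prod.sum())
    return total


@lru_cache(maxsize=500_000)
def _chain_similarity_cached(s: str, t: str, k_lengths: tuple, beta: float) -> float:
    num = raw_kernel(s, t, k_lengths, beta)
    den = np.sqrt(raw_kernel(s, s, k_lengths, beta) * raw_kernel(t, t, k_lengths, beta))
    return float(num / den)


def chain_similarity(s: str, t: str, k_lengths=DEFAULT_K,
                     beta: float = DEFAULT_BETA) -> float:
    """Normalized kernel similarity between two CDR3 chains, in [0, 1]."""
    if not s or not t:
        raise ConfigError("kernel similarity requires non-empty sequences")
    a, b = (s, t) if s <= t else (t, s)   # symmetric; canonical cache key
    return _chain_similarity_cached(a, b, tuple(k_lengths), float(beta))


def paired_similarity(tcr1, tcr2, k_lengths=DEFAULT_K,
                      beta: float = DEFAULT_BETA) -> float:
    """Summed alpha + beta chain similarity of two (cdr3_a, cdr3_b) TCRs, in [0, 2]."""
    a1, b1 = tcr1
    a2, b2 = tcr2
    if not all((a1, b1, a2, b2)):
        raise ConfigError("paired similarity requires both chains of both TCRs")
    return (chain_similarity(a1, a2, k_lengths, beta)
            + chain_similarity(b1, b2, k_lengths, beta))
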