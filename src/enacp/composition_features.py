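"""Amino-acid-composition encoders: k-mer, distance-based residue pairs (DR),
and distance pairs over reduced alphabets.

All three count residue words or ordered residue pairs along the sequence.
Layout is deterministic: words and pairs are enumerated lexicographically
over the fixed alphabet "ACDEFGHIKLMNPQRSTVWY" (or over cluster ids for a
reduced alphabet), and distance blocks are concatenated in increasing d.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from itertools import product

import numpy as np

from .core import AA_INDEX, AMINO_ACIDS, FeatureVector, ReducedAlphabet
from .seqio import PeptideRecord


def _seq_codes(sequence: str) -> np.ndarray:
    return np.array([AA_INDEX[aa] for aa in sequence], dtype=np.int64)


def kmer_names(k: int) -> tuple[str, ...]:
    """The 20^k words in lexicographic order."""
    return tuple("".join(w) for w in product(AMINO_ACIDS, repeat=k))


def kmer_encode(record: PeptideRecord, k: int = 2, normalize: bool = True) -> FeatureVector:
    """Occurrence counts (or frequencies) of the 20^k length-k words.

    Slides a window over the L-k+1 positions; entry for word w is its count,
    divided by L-k+1 when ``normalize`` so the vector sums to 1. Requires
    L >= k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    L = record.length
    if L < k:
        raise ValueError(f"{record.id}: length {L} < k={k}")
    codes = _seq_codes(record.sequence)
    dim = 20**k
    # word index = sum codes[i+j] * 20^(k-1-j): lexicographic over the alphabet
    idx = np.zeros(L - k + 1, dtype=np.int64)
    for j in range(k):
        idx = idx * 20 + codes[j : L - k + 1 + j]
    values = np.bincount(idx, minlength=dim).astype(float)
    if normalize:
        values /= L - k + 1
    return FeatureVector("kmer", {"k": k, "normalize": normalize}, values)


def _pair_blocks(codes: np.ndarray, m: int, dmax: int, normalize: bool) -> np.ndarray:
    """Monomer block followed by one ordered-pair block per distance 1..dmax."""
    L = codes.size
    blocks = [np.bincount(codes, minlength=m).astype(float)]
    for d in range(1, dmax + 1):
        if L > d:
            pair_idx = codes[: L - d] * m + codes[d:]
            block = np.bincount(pair_idx, minlength=m * m).astype(float)
        else:
            block = np.zeros(m * m)
        blocks.append(block)
    if normalize:
        for block in blocks:
            total = block.sum()
            if total > 0:
                block /= total
    return np.concatenate(blocks)


def dr_encode(record: PeptideRecord, dmax: int = 3, normalize: bool = False) -> FeatureVector:
    """Distance-based residue-pair counts, dim 20 + 400*dmax.

    Block d=0 holds the 20 single-residue counts; block d (1 <= d <= dmax)
    holds counts of ordered pairs (Ri, Ri+d). With ``normalize`` each block
    is divided by its own total (blocks with zero total — distances beyond
    the sequence length — stay zero).
    """
    if dmax < 0:
        raise ValueError("dmax must be >= 0")
    values = _pair_blocks(_seq_codes(record.sequence), 20, dmax, normalize)
    return FeatureVector("dr", {"dmax": dmax, "normalize": normalize}, values)


def distance_pair_encode(
    record: PeptideRecord,
    dmax: int = 3,
    alphabet: ReducedAlphabet | None = None,
    normalize: bool = False,
) -> FeatureVector:
    """DR counting over a reduced alphabet, dim m + m^2*dmax.

    Each residue is first mapped through the cluster alphabet (default:
    the bundled 14-cluster scheme); pair counting is then identical to
    :func:`dr_encode`. With the identity alphabet the output equals DR.
    """
    if dmax < 0:
        raise ValueError("dmax must be >= 0")
    if alphabet is None:
        alphabet = load_reduced_alphabet("cp14")
    codes = np.array([alphabet.mapping[aa] for aa in record.sequence], dtype=np.int64)
    values = _pair_blocks(codes, alphabet.m, dmax, normalize)
    params = {"dmax": dmax, "alphabet": alphabet.name, "normalize": normalize}
    return FeatureVector("distance_pair", params, values)


@lru_cache(maxsize=None)
def load_reduced_alphabet(name: str = "cp14") -> ReducedAlphabet:
    """Load one of the bundled cluster alphabets (cp13, cp14, cp19, cp20)."""
    text = resources.files("enacp.data").joinpath("reduced_alphabets.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        alph_name, _m, clusters = line.split("\t")
        if alph_name == name:
            return ReducedAlphabet.from_clusters(name, clusters.split("-"))
    raise KeyError(f"no bundled reduced alphabet named {name!r}")
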