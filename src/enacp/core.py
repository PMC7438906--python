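"""Shared domain types: the amino-acid alphabet and feature-vector container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

#: The 20 natural amino acids in the fixed lexicographic order used by every
#: encoder. Feature layouts (k-mer words, residue pairs, profile columns) are
#: always enumerated in this order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue letter -> 0-based column index.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Letters that appear in real-world FASTA but are not one of the 20 natural
#: amino acids (ambiguity codes, rare residues); their presence disqualifies
#: a peptide from the benchmark datasets.
NON_NATURAL: frozenset[str] = frozenset("BJOUXZ")


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric encoding of one peptide.

    Tagged with the encoder identity and the parameters that determined its
    layout, so matrices assembled from many peptides can assert they were
    produced under identical settings.
    """

    encoder_name: str
    params: Mapping[str, Any]
    values: np.ndarray
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("feature vector must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError(
                f"{self.encoder_name}: non-finite feature values"
            )
        if self.names is not None and len(self.names) != values.size:
            raise ValueError("feature names do not match vector length")

    @property
    def dim(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ReducedAlphabet:
    """A clustering of the 20 amino acids into ``m`` residue classes.

    ``mapping`` sends every letter to a cluster id in ``0..m-1`` (stored
    0-based; cluster numbering in descriptions is 1-based).
    """

    name: str
    mapping: Mapping[str, int] = field(hash=False)
    m: int = 20

    def __post_init__(self) -> None:
        missing = [aa for aa in AMINO_ACIDS if aa not in self.mapping]
        if missing:
            raise ValueError(
                f"reduced alphabet {self.name!r} lacks letters {missing}"
            )
        ids = sorted(set(self.mapping[aa] for aa in AMINO_ACIDS))
        if ids != list(range(self.m)):
            raise ValueError(
                f"reduced alphabet {self.name!r}: cluster ids must be "
                f"contiguous 0..{self.m - 1}, got {ids}"
            )

    @classmethod
    def identity(cls) -> "ReducedAlphabet":
        return cls(name="identity", mapping=dict(AA_INDEX), m=20)

    @classmethod
    def from_clusters(cls, name: str, clusters: list[str]) -> "ReducedAlphabet":
        mapping = {aa: cid for cid, group in enumerate(clusters) for aa in group}
        return cls(name=name, mapping=mapping, m=len(clusters))
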