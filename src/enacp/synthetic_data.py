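"""Synthetic labeled peptide datasets with controllable class signal.

Emulates the structure of anticancer-peptide benchmarks — two classes of
short peptides (lengths uniform on [5, 50] by default) — without any real
biology. Negatives are drawn i.i.d. from a background residue distribution
(uniform over the 20 letters by default, which makes null-calibration
tests exact). Positives can differ through up to three channels:

* composition: the positive residue distribution is the mixture
  (1 - delta) * background + delta * target, where the target puts all
  its mass on lysine — the polycationic enrichment that is the single
  most characteristic compositional feature of natural anticancer
  peptides;
* order: positives alternate cationic and hydrophobic residues in
  two-letter periods while negatives carry the same letters shuffled, so
  composition is matched and only residue order separates the classes;
* profile: synthetic position-specific profiles are sharper (more
  conserved) for positives than negatives.

delta = 0 makes the classes exchangeable. Generation is fully
deterministic given the seed, and the generating (ground-truth)
parameters are returned with the dataset so recovery tests are
self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import AA_INDEX, AMINO_ACIDS
from .profile_features import Pssm, frequencies_to_scores
from .seqio import LabeledDataset, PeptideRecord

#: Residues enriched in positives on the composition channel.
TARGET_RESIDUES: str = "K"

#: Residue pools for the order channel's periodic (amphipathic-like) motif.
CATIONIC: str = "KRH"
HYDROPHOBIC: str = "LFIAV"


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings: sizes, lengths, effect size, signal channels."""

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (5, 50)
    effect: float = 0.3
    signal_channels: frozenset[str] = frozenset({"composition"})
    seed: int = 0
    background: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        lmin, lmax = self.length_range
        if not (1 <= lmin <= lmax):
            raise ValueError(f"invalid length range {self.length_range}")
        if not (0.0 <= self.effect <= 1.0):
            raise ValueError("effect size must lie in [0, 1]")
        bad = set(self.signal_channels) - {"composition", "order", "profile"}
        if bad:
            raise ValueError(f"unknown signal channels {sorted(bad)}")
        if self.background is not None and len(self.background) != 20:
            raise ValueError("background must have 20 probabilities")


def _distributions(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    if spec.background is None:
        bg = np.full(20, 1 / 20)
    else:
        bg = np.asarray(spec.background, dtype=float)
        bg = bg / bg.sum()
    target = np.zeros(20)
    for aa in TARGET_RESIDUES:
        target[AA_INDEX[aa]] = 1 / len(TARGET_RESIDUES)
    if "composition" in spec.signal_channels:
        pos = (1 - spec.effect) * bg + spec.effect * target
    else:
        pos = bg.copy()
    return bg, pos


def _draw_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    codes = rng.choice(20, size=length, p=probs)
    return "".join(AMINO_ACIDS[c] for c in codes)


def _ordered_positive(rng: np.random.Generator, length: int, probs: np.ndarray,
                      effect: float) -> str:
    """Positive with a planted two-period cationic/hydrophobic alternation.

    Each position is motif-constrained with probability ``effect``:
    even positions draw from the hydrophobic pool, odd from the cationic
    pool; the rest draw from the composition-channel distribution.
    """
    out = []
    for i in range(length):
        if rng.random() < effect:
            pool = HYDROPHOBIC if i % 2 == 0 else CATIONIC
            out.append(pool[rng.integers(len(pool))])
        else:
            out.append(AMINO_ACIDS[rng.choice(20, p=probs)])
    return "".join(out)


def generate_peptide_dataset(
    spec: SyntheticSpec,
) -> tuple[LabeledDataset, dict]:
    """Draw a labeled dataset; returns (dataset, ground truth).

    Lengths are uniform on the length range; negatives are i.i.d. from
    the background distribution. On the order channel, negatives are
    letter-shuffled copies of matched motif-bearing positives so that the
    two classes share marginal composition exactly.
    """
    rng = np.random.default_rng(spec.seed)
    bg, pos_probs = _distributions(spec)
    lmin, lmax = spec.length_range
    order = "order" in spec.signal_channels

    records: list[PeptideRecord] = []
    labels: list[int] = []
    for i in range(spec.n_pos):
        length = int(rng.integers(lmin, lmax + 1))
        if order:
            seq = _ordered_positive(rng, length, pos_probs, spec.effect)
        else:
            seq = _draw_sequence(rng, length, pos_probs)
        records.append(PeptideRecord(id=f"pos_{i:04d}", sequence=seq))
        labels.append(1)
    for i in range(spec.n_neg):
        length = int(rng.integers(lmin, lmax + 1))
        if order:
            # same letter pool as a motif-bearing draw, order destroyed
            letters = list(_ordered_positive(rng, length, pos_probs, spec.effect))
            rng.shuffle(letters)
            seq = "".join(letters)
        else:
            seq = _draw_sequence(rng, length, bg)
        records.append(PeptideRecord(id=f"neg_{i:04d}", sequence=seq))
        labels.append(0)

    dataset = LabeledDataset(records=records, labels=np.array(labels),
                             name=f"synthetic(seed={spec.seed})")
    truth = {
        "spec": spec,
        "background": bg,
        "positive_composition": pos_probs,
        "target_residues": TARGET_RESIDUES,
    }
    return dataset, truth


def generate_synthetic_pssm(
    record: PeptideRecord, sharpness: float = 50.0, seed: int = 0
) -> Pssm:
    """A synthetic profile centered on the true sequence.

    Each row is a Dirichlet draw whose concentration puts weight
    ``sharpness`` on the position's true residue and 1 on every other
    letter, so sharpness -> infinity approaches the one-hot profile.
    Scores are the inverse of the score->frequency transform, making
    write/read round-trips exact to numerical precision.
    """
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    rng = np.random.default_rng(seed)
    freqs = np.empty((record.length, 20))
    for i, aa in enumerate(record.sequence):
        alpha = np.ones(20)
        alpha[AA_INDEX[aa]] = sharpness
        freqs[i] = rng.dirichlet(alpha)
    return Pssm(record.id, frequencies_to_scores(freqs),
                freqs / freqs.sum(axis=1, keepdims=True))


def generate_pssm_set(
    dataset: LabeledDataset,
    sharpness_pos: float = 50.0,
    sharpness_neg: float | None = None,
    seed: int = 0,
) -> dict[str, Pssm]:
    """Profiles for every record; the profile channel uses sharper
    (more conserved) profiles for positives when sharpness_neg differs."""
    if sharpness_neg is None:
        sharpness_neg = sharpness_pos
    out: dict[str, Pssm] = {}
    for i, (rec, label) in enumerate(zip(dataset.records, dataset.labels)):
        sharp = sharpness_pos if label == 1 else sharpness_neg
        out[rec.id] = generate_synthetic_pssm(rec, sharpness=sharp,
                                              seed=(seed * 100003 + i) % (2**31))
    return out
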