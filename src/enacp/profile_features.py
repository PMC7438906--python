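"""Profile-based encoders over position-specific scoring matrices (PSSMs).

A PSSM assigns every sequence position a 20-vector of log-odds scores
(PSI-BLAST column order, which this package keeps in its own fixed
alphabet order "ACDEFGHIKLMNPQRSTVWY"). Scores are mapped to a
row-stochastic frequency profile by the bounded logistic transform

    f'(i, j) = 1 / (1 + 2^(-score(i, j))),   f(i, j) = f'(i, j) / sum_j f'(i, j)

after which eight encoders summarize the profile:

* Top-n-gram: at each position the n most probable residues (ties broken
  alphabetically) form an n-tuple; the encoder counts tuple occurrences.
* DT (distance-based Top-n-gram): counts ordered Top-n-gram pairs at
  distances 1..dmax.
* PDT-Profile: mean squared row difference at each lag.
* AC-/CC-/ACC-PSSM: treat the 20 profile columns as physicochemical
  signals and compute auto/cross covariance at lags 1..dmax.
* PSSM-DT: expected ordered residue-pair occurrence at each distance,
  sum_i f(i,a) * f(i+d,b) / (L-d).
* PSSM-RT: binarize scores at a threshold and count positions where both
  members of an ordered residue pair exceed it at distance d, / (L-d).

On a one-hot profile (frequency 1 at the true residue) these reduce to
their sequence-space counterparts: Top-1-gram to single-residue
composition, DT and PSSM-DT to the distance-pair blocks of the DR encoder.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

from .core import AA_INDEX, AMINO_ACIDS, FeatureVector
from .seqio import PeptideRecord


def scores_to_frequencies(scores: np.ndarray) -> np.ndarray:
    """Logistic map 1/(1+2^-s) per cell, then row renormalization."""
    logistic = 1.0 / (1.0 + np.exp2(-np.asarray(scores, dtype=float)))
    return logistic / logistic.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class Pssm:
    """An L x 20 score matrix plus its derived frequency profile."""

    peptide_id: str
    scores: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "frequencies", freqs)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(f"{self.peptide_id}: scores must be L x 20")
        if freqs.shape != scores.shape:
            raise ValueError(f"{self.peptide_id}: frequency shape mismatch")
        if np.any(freqs < 0) or np.any(freqs > 1):
            raise ValueError(f"{self.peptide_id}: frequencies outside [0, 1]")
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.peptide_id}: frequency rows must sum to 1")

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])

    @classmethod
    def from_scores(cls, peptide_id: str, scores: np.ndarray) -> "Pssm":
        scores = np.asarray(scores, dtype=float)
        return cls(peptide_id, scores, scores_to_frequencies(scores))

    @classmethod
    def from_frequencies(cls, peptide_id: str, frequencies: np.ndarray) -> "Pssm":
        """Build from an explicit row-stochastic profile; scores are the
        inverse logistic of the half-scaled rows (see write_pssm)."""
        freqs = np.asarray(frequencies, dtype=float)
        return cls(peptide_id, frequencies_to_scores(freqs), freqs)


def frequencies_to_scores(frequencies: np.ndarray) -> np.ndarray:
    """Invert the score->frequency map up to row normalization.

    Rows are rescaled so the largest cell maps to logistic value 1/2
    (score 0); renormalizing the logistic image then recovers the input
    row exactly. Cells at 0 get a large negative sentinel score.
    """
    freqs = np.asarray(frequencies, dtype=float)
    scaled = 0.5 * freqs / freqs.max(axis=1, keepdims=True)
    scores = np.full_like(scaled, -64.0)
    pos = scaled > 2.0**-60
    scores[pos] = -np.log2(1.0 / scaled[pos] - 1.0)
    return scores


def read_pssm(path: str | Path, peptide_id: str | None = None) -> Pssm:
    """Parse a PSI-BLAST ASCII PSSM (-out_ascii_pssm layout).

    Accepts the usual dialect: two header lines, a column-header line of
    residue letters, then one row per position starting with the position
    number and residue, followed by 20 score columns (an optional further
    20 percentage columns and trailing statistics are ignored). Scores are
    reordered from the file's residue-letter header into this package's
    fixed alphabet order. Malformed rows raise with their line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    col_order: list[int] | None = None
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(lines, 1):
        parts = line.split()
        if not parts:
            continue
        if col_order is None:
            # the column-header line: 20 (or 40) single residue letters
            if len(parts) >= 20 and all(p in AA_INDEX for p in parts[:20]):
                col_order = [AA_INDEX[p] for p in parts[:20]]
            continue
        if not parts[0].isdigit():
            continue  # trailing K/lambda statistics block
        if len(parts) < 22:
            raise ValueError(
                f"{path}:{lineno}: expected position, residue and 20 scores, "
                f"got {len(parts)} fields"
            )
        try:
            raw = np.array([float(v) for v in parts[2:22]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric score cell") from exc
        row = np.empty(20)
        row[col_order] = raw
        rows.append(row)
    if col_order is None or not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    scores = np.vstack(rows)
    return Pssm.from_scores(peptide_id or path.stem, scores)


def write_pssm(pssm: Pssm, path: str | Path, sequence: str | None = None) -> None:
    """Write a PSI-BLAST-style ASCII PSSM readable by :func:`read_pssm`."""
    path = Path(path)
    seq = sequence or "A" * pssm.length
    lines = ["", "Last position-specific scoring matrix computed",
             "            " + "   ".join(AMINO_ACIDS)]
    for i in range(pssm.length):
        cells = " ".join(f"{v:11.6f}" for v in pssm.scores[i])
        lines.append(f"{i + 1:5d} {seq[i]} {cells}")
    path.write_text("\n".join(lines) + "\n")


def _check_lag(pssm: Pssm, dmax: int) -> None:
    if dmax < 1:
        raise ValueError("dmax must be >= 1")
    if pssm.length <= dmax:
        raise ValueError(
            f"{pssm.peptide_id}: length {pssm.length} <= dmax={dmax}"
        )


def top_n_grams(pssm: Pssm, n: int = 1) -> list[tuple[str, ...]]:
    """Per-position tuple of the n most probable residues.

    Sorted by descending frequency with alphabetical tie-breaking (the
    fixed alphabet order makes a stable argsort on (-freq, letter) exact).
    """
    if not (1 <= n <= 20):
        raise ValueError("n must lie in 1..20")
    grams = []
    for row in pssm.frequencies:
        order = np.lexsort((np.arange(20), -row))[:n]
        grams.append(tuple(AMINO_ACIDS[j] for j in order))
    return grams


def _gram_codes(grams: list[tuple[str, ...]], n: int) -> np.ndarray:
    codes = np.zeros(len(grams), dtype=np.int64)
    for pos, gram in enumerate(grams):
        c = 0
        for aa in gram:
            c = c * 20 + AA_INDEX[aa]
        codes[pos] = c
    return codes


def top_n_gram_encode(pssm: Pssm, n: int = 1, normalize: bool = True) -> FeatureVector:
    """Counts (or frequencies) of each possible Top-n-gram, dim 20^n."""
    grams = top_n_grams(pssm, n)
    codes = _gram_codes(grams, n)
    values = np.bincount(codes, minlength=20**n).astype(float)
    if normalize:
        values /= pssm.length
    return FeatureVector("top_n_gram", {"n": n, "normalize": normalize}, values)


def dt_encode(pssm: Pssm, n: int = 1, dmax: int = 2, normalize: bool = False) -> FeatureVector:
    """Ordered Top-n-gram pair counts at distances 1..dmax, dim 20^(2n)*dmax.

    Block d holds counts of (gram at i, gram at i+d); with ``normalize``
    each block is divided by its own total, matching the DR convention.
    """
    _check_lag(pssm, dmax)
    codes = _gram_codes(top_n_grams(pssm, n), n)
    L = codes.size
    m = 20**n
    blocks = []
    for d in range(1, dmax + 1):
        pair_idx = codes[: L - d] * m + codes[d:]
        block = np.bincount(pair_idx, minlength=m * m).astype(float)
        if normalize and block.sum() > 0:
            block /= block.sum()
        blocks.append(block)
    return FeatureVector(
        "dt", {"n": n, "dmax": dmax, "normalize": normalize}, np.concatenate(blocks)
    )


def pdt_profile_encode(pssm: Pssm, dmax: int = 2) -> FeatureVector:
    """Profile distance transformation, dim dmax.

    PDTp(d) = (1/(L-d)) * sum_i (1/20) * sum_j (f(i,j) - f(i+d,j))^2.
    """
    _check_lag(pssm, dmax)
    f = pssm.frequencies
    L = pssm.length
    values = np.array([
        float(((f[: L - d] - f[d:]) ** 2).sum()) / (20 * (L - d))
        for d in range(1, dmax + 1)
    ])
    return FeatureVector("pdt_profile", {"dmax": dmax}, values)


def pssm_covariance_encode(pssm: Pssm, dmax: int = 2, mode: str = "ACC") -> FeatureVector:
    """Auto/cross covariance over the 20 profile columns.

    Each column j is a length-L signal with mean p_bar(j) over all rows;
    AC(j, d) = sum_i (p(i,j) - p_bar(j)) * (p(i+d,j) - p_bar(j)) / (L-d),
    CC likewise over ordered column pairs j != j'. Entry order: AC by
    (column, lag); CC by (ordered pair, lag); ACC concatenates AC then CC.
    Dims: 20*dmax / 380*dmax / 400*dmax.
    """
    if mode not in ("AC", "CC", "ACC"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_lag(pssm, dmax)
    f = pssm.frequencies
    L = pssm.length
    centered = f - f.mean(axis=0, keepdims=True)
    out: list[float] = []
    if mode in ("AC", "ACC"):
        for j in range(20):
            for d in range(1, dmax + 1):
                out.append(float(centered[: L - d, j] @ centered[d:, j]) / (L - d))
    if mode in ("CC", "ACC"):
        for j in range(20):
            for jp in range(20):
                if j == jp:
                    continue
                for d in range(1, dmax + 1):
                    out.append(
                        float(centered[: L - d, j] @ centered[d:, jp]) / (L - d)
                    )
    return FeatureVector(
        f"pssm_covariance_{mode.lower()}", {"dmax": dmax, "mode": mode}, np.array(out)
    )


def pssm_dt_encode(pssm: Pssm, dmax: int = 2) -> FeatureVector:
    """Expected ordered residue-pair occurrence per distance, dim 400*dmax.

    Entry for pair (a, b) at distance d is
    sum_i f(i, a) * f(i+d, b) / (L - d); on a one-hot profile this equals
    the per-block-normalized DR pair count.
    """
    _check_lag(pssm, dmax)
    f = pssm.frequencies
    L = pssm.length
    blocks = []
    for d in range(1, dmax + 1):
        pair = f[: L - d].T @ f[d:] / (L - d)  # 20 x 20, rows = first residue
        blocks.append(pair.ravel())
    return FeatureVector("pssm_dt", {"dmax": dmax}, np.concatenate(blocks))


def pssm_rt_encode(pssm: Pssm, dmax: int = 2, threshold: float = 0.0) -> FeatureVector:
    """Relation transformation: co-occurrence of above-threshold scores.

    Scores are binarized (score > threshold -> 1); entry for pair (a, b)
    at distance d counts positions i where both b(i, a) and b(i+d, b) are
    1, normalized by (L - d). Dim 400*dmax. The binarize-and-co-count rule
    is this package's explicit construction for the relation-transform
    family (threshold default 0, i.e. residues scored above background).
    """
    _check_lag(pssm, dmax)
    b = (pssm.scores > threshold).astype(float)
    L = pssm.length
    blocks = []
    for d in range(1, dmax + 1):
        pair = b[: L - d].T @ b[d:] / (L - d)
        blocks.append(pair.ravel())
    return FeatureVector(
        "pssm_rt", {"dmax": dmax, "threshold": threshold}, np.concatenate(blocks)
    )


def one_hot_pssm(record: PeptideRecord) -> Pssm:
    """The degenerate profile that puts all mass on the true residue."""
    freqs = np.zeros((record.length, 20))
    for i, aa in enumerate(record.sequence):
        freqs[i, AA_INDEX[aa]] = 1.0
    return Pssm.from_frequencies(record.id, freqs)


def load_pssm_directory(
    directory: str | Path, records: list[PeptideRecord]
) -> dict[str, Pssm]:
    """Match per-peptide PSSM files to records by filename stem.

    Accepts a directory of ``<id>.pssm`` / ``<id>.txt`` files or a
    ``manifest.tsv`` of (id, path) rows inside it. Records without a
    matching profile are simply absent from the result.
    """
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    paths: dict[str, Path] = {}
    if manifest.exists():
        for line in manifest.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            rid, rel = line.split("\t")[:2]
            paths[rid] = directory / rel
    else:
        for p in sorted(directory.iterdir()):
            if p.suffix in (".pssm", ".txt", ".mat"):
                paths[p.stem] = p
    out: dict[str, Pssm] = {}
    for rec in records:
        if rec.id in paths:
            out[rec.id] = read_pssm(paths[rec.id], peptide_id=rec.id)
    return out
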