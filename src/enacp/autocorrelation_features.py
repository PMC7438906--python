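"""Physicochemical autocorrelation encoders.

A peptide P = R1 R2 ... RL is mapped to a numeric signal by a per-residue
physicochemical index I_u; the encoders summarize how that signal co-varies
with itself (AC), with a second index (CC), or how it differs at a lag
(PDT, the physicochemical distance transformation):

    AC(u, d)    = sum_{i=1}^{L-d} (I_u(R_i) - mean_u)(I_u(R_{i+d}) - mean_u) / (L - d)
    CC(u, v, d) = sum_{i=1}^{L-d} (I_u(R_i) - mean_u)(I_v(R_{i+d}) - mean_v) / (L - d)
    PDT(u, d)   = sum_{i=1}^{L-d} (I_u(R_i) - I_u(R_{i+d}))^2 / (L - d)

with mean_u the average index value over the whole sequence. ACC is the AC
block followed by the CC block. All indices are standardized to zero mean
and unit population spread over the 20 letters before use, so scales of
wildly different magnitude (mass in daltons vs. charge fractions)
contribute comparably.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import AMINO_ACIDS, FeatureVector
from .seqio import PeptideRecord


@dataclass(frozen=True)
class PhysicochemicalIndex:
    """One named amino-acid index: raw values and the standardized form."""

    name: str
    raw_values: Mapping[str, float]
    standardized_values: Mapping[str, float]

    def signal(self, sequence: str) -> np.ndarray:
        """The standardized index values along a sequence."""
        return np.array([self.standardized_values[aa] for aa in sequence])


def standardize_index(name: str, raw_values: Mapping[str, float]) -> PhysicochemicalIndex:
    """Standardize a 20-value index: (raw - mean) / population sd.

    Mean and sd are taken over the 20 letters (divide by 20, the convention
    the pseudo-amino-acid-composition literature uses for the same tables).
    Raises on a constant index, which carries no signal.
    """
    missing = [aa for aa in AMINO_ACIDS if aa not in raw_values]
    if missing:
        raise ValueError(f"index {name!r} lacks values for {missing}")
    raw = np.array([float(raw_values[aa]) for aa in AMINO_ACIDS])
    if not np.all(np.isfinite(raw)):
        raise ValueError(f"index {name!r} has non-finite values")
    sd = raw.std()  # population sd (ddof=0)
    if sd == 0:
        raise ValueError(f"index {name!r} is constant; cannot standardize")
    std = (raw - raw.mean()) / sd
    return PhysicochemicalIndex(
        name=name,
        raw_values={aa: float(v) for aa, v in zip(AMINO_ACIDS, raw)},
        standardized_values={aa: float(v) for aa, v in zip(AMINO_ACIDS, std)},
    )


@dataclass(frozen=True)
class AutocorrParams:
    """Index panel and maximum lag for the autocorrelation encoders."""

    indices: tuple[PhysicochemicalIndex, ...]
    dmax: int = 2

    def __post_init__(self) -> None:
        if self.dmax < 1:
            raise ValueError("dmax must be >= 1")
        if not self.indices:
            raise ValueError("at least one physicochemical index required")


def autocorrelation_encode(
    record: PeptideRecord, params: AutocorrParams, mode: str = "ACC"
) -> FeatureVector:
    """Auto covariance (AC), cross covariance (CC), or both (ACC).

    Layout: AC entries ordered by (index u, lag d); CC entries by (ordered
    pair u != v in panel order, lag d); ACC is AC followed by CC. Dims are
    n*dmax, n*(n-1)*dmax, and n^2*dmax for an n-index panel. Requires
    L > dmax so every lag has at least one term, and >= 2 indices for CC.
    """
    if mode not in ("AC", "CC", "ACC"):
        raise ValueError(f"unknown mode {mode!r}")
    L = record.length
    if L <= params.dmax:
        raise ValueError(f"{record.id}: length {L} <= dmax={params.dmax}")
    if mode in ("CC", "ACC") and len(params.indices) < 2:
        raise ValueError("CC requires at least two indices")
    signals = [idx.signal(record.sequence) for idx in params.indices]
    centered = [s - s.mean() for s in signals]
    out: list[float] = []
    if mode in ("AC", "ACC"):
        for c in centered:
            for d in range(1, params.dmax + 1):
                out.append(float(c[: L - d] @ c[d:]) / (L - d))
    if mode in ("CC", "ACC"):
        for iu, cu in enumerate(centered):
            for iv, cv in enumerate(centered):
                if iu == iv:
                    continue
                for d in range(1, params.dmax + 1):
                    out.append(float(cu[: L - d] @ cv[d:]) / (L - d))
    names = tuple(idx.name for idx in params.indices)
    return FeatureVector(
        f"autocorrelation_{mode.lower()}",
        {"indices": names, "dmax": params.dmax, "mode": mode},
        np.array(out),
    )


def pdt_encode(record: PeptideRecord, params: AutocorrParams) -> FeatureVector:
    """Physicochemical distance transformation, dim n_indices * dmax.

    Mean squared difference of the standardized index signal at each lag
    d = 1..dmax, one entry per (index, lag). Requires L > dmax.
    """
    L = record.length
    if L <= params.dmax:
        raise ValueError(f"{record.id}: length {L} <= dmax={params.dmax}")
    out: list[float] = []
    for idx in params.indices:
        s = idx.signal(record.sequence)
        for d in range(1, params.dmax + 1):
            diff = s[: L - d] - s[d:]
            out.append(float(diff @ diff) / (L - d))
    names = tuple(idx.name for idx in params.indices)
    return FeatureVector(
        "pdt", {"indices": names, "dmax": params.dmax}, np.array(out)
    )


@lru_cache(maxsize=1)
def default_index_panel() -> tuple[PhysicochemicalIndex, ...]:
    """The bundled eight-index panel, standardized."""
    text = resources.files("enacp.data").joinpath("aaindex_panel.tsv").read_text()
    return _parse_index_table(text)


def load_index_file(path: str | Path) -> tuple[PhysicochemicalIndex, ...]:
    """Parse an AAindex-style flat table: header of index names, one row
    per amino acid (aa<TAB>value...), comments starting with '#'."""
    return _parse_index_table(Path(path).read_text())


def _parse_index_table(text: str) -> tuple[PhysicochemicalIndex, ...]:
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = rows[0].split("\t")
    if header[0] != "aa":
        raise ValueError("index table must start with an 'aa' header column")
    names = header[1:]
    raw: dict[str, dict[str, float]] = {n: {} for n in names}
    for ln in rows[1:]:
        parts = ln.split("\t")
        aa = parts[0]
        for n, val in zip(names, parts[1:]):
            raw[n][aa] = float(val)
    return tuple(standardize_index(n, raw[n]) for n in names)
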