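"""Pseudo amino acid composition (PseAAC) encoders.

PseAAC augments the 20 amino-acid occurrence frequencies f_1..f_20 with
lambda sequence-order correlation factors theta_j built from standardized
physicochemical properties, then normalizes everything jointly:

    x_u = f_u / (sum_i f_i + w * sum_j theta_j)           u = 1..20
    x_u = w * theta_{u-20} / (sum_i f_i + w * sum_j theta_j)   u > 20

with weight w in (0, 1]. Two correlation flavors are implemented:

* parallel (PC-PseAAC): theta_j averages the correlation function
  Theta(Ri, Ri+j) = mean of squared standardized property differences
  over the property set (hydrophobicity, hydrophilicity, side-chain mass
  by default), giving lambda factors and dim 20 + lambda;
* series (SC-PseAAC): one factor per (lag, property) from products of
  standardized property values h(Ri) * h(Ri+j) — hydrophobicity then
  hydrophilicity per lag by default — giving 2*lambda factors and dim
  20 + 2*lambda.

The General variants accept any user-supplied property panel in either
flavor. Sequences with L <= lambda raise rather than silently lowering
lambda, which would make feature dimensions inconsistent across a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from .autocorrelation_features import PhysicochemicalIndex, _parse_index_table
from .core import AA_INDEX, FeatureVector
from .seqio import PeptideRecord


@lru_cache(maxsize=1)
def builtin_pseaac_properties() -> tuple[PhysicochemicalIndex, ...]:
    """The canonical (hydrophobicity, hydrophilicity, side-chain mass)
    tables, standardized over the 20 letters."""
    text = resources.files("enacp.data").joinpath("pseaac_properties.tsv").read_text()
    return _parse_index_table(text)


def _default_properties() -> tuple[PhysicochemicalIndex, ...]:
    return builtin_pseaac_properties()


@dataclass(frozen=True)
class PseaacParams:
    """lambda (highest correlation tier), weight w, and the property panel."""

    lam: int = 4
    w: float = 0.05
    property_set: tuple[PhysicochemicalIndex, ...] = field(
        default_factory=_default_properties
    )

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lambda must be >= 1")
        if not (0 < self.w <= 1):
            raise ValueError("w must lie in (0, 1]")
        if not self.property_set:
            raise ValueError("property set must be non-empty")


def _check_length(record: PeptideRecord, lam: int) -> None:
    if record.length <= lam:
        raise ValueError(
            f"{record.id}: length {record.length} <= lambda={lam}; "
            "every correlation tier needs at least one residue pair"
        )


def parallel_correlation_factors(record: PeptideRecord, params: PseaacParams) -> np.ndarray:
    """theta_1..theta_lambda, parallel flavor.

    theta_j = (1/(L-j)) * sum_{i=1}^{L-j} Theta(R_i, R_{i+j}), where Theta
    averages squared standardized property differences over the panel.
    """
    _check_length(record, params.lam)
    L = record.length
    signals = [p.signal(record.sequence) for p in params.property_set]
    theta = np.empty(params.lam)
    for j in range(1, params.lam + 1):
        acc = np.zeros(L - j)
        for s in signals:
            acc += (s[: L - j] - s[j:]) ** 2
        theta[j - 1] = acc.mean() / len(signals)
    return theta


def series_correlation_factors(record: PeptideRecord, params: PseaacParams) -> np.ndarray:
    """lambda * n_properties factors, series flavor, ordered (lag, property).

    Tier for lag j and property h is (1/(L-j)) * sum h(R_i) * h(R_{i+j}).
    With the default two properties this yields the classic 2*lambda
    factors: odd tiers from hydrophobicity, even from hydrophilicity.
    """
    _check_length(record, params.lam)
    L = record.length
    signals = [p.signal(record.sequence) for p in params.property_set]
    out = np.empty(params.lam * len(signals))
    pos = 0
    for j in range(1, params.lam + 1):
        for s in signals:
            out[pos] = float(s[: L - j] @ s[j:]) / (L - j)
            pos += 1
    return out


def _compose(record: PeptideRecord, theta: np.ndarray, w: float, name: str,
             params: dict) -> FeatureVector:
    freqs = np.zeros(20)
    for aa in record.sequence:
        freqs[AA_INDEX[aa]] += 1
    freqs /= record.length
    denom = freqs.sum() + w * theta.sum()
    if denom <= 0:
        raise ValueError(
            f"{record.id}: degenerate pseudo-composition encoding "
            f"(denominator {denom:.3g} <= 0; series correlation factors "
            "can be negative)"
        )
    values = np.concatenate([freqs, w * theta]) / denom
    return FeatureVector(name, params, values)


def pc_pseaac_encode(record: PeptideRecord, params: PseaacParams | None = None) -> FeatureVector:
    """Parallel-correlation PseAAC, dim 20 + lambda.

    Uses the canonical hydrophobicity / hydrophilicity / side-chain-mass
    panel; the parallel correlation function is a mean of squared
    differences, so all entries are nonnegative and sum to 1.
    """
    if params is None:
        params = PseaacParams()
    theta = parallel_correlation_factors(record, params)
    return _compose(record, theta, params.w, "pc_pseaac",
                    {"lambda": params.lam, "w": params.w})


def sc_pseaac_encode(record: PeptideRecord, params: PseaacParams | None = None) -> FeatureVector:
    """Series-correlation PseAAC, dim 20 + 2*lambda.

    Correlation tiers come from products of standardized hydrophobicity and
    hydrophilicity (per lag, in that order). Products can be negative, so a
    pathological sequence can zero the normalizing denominator; such a
    sequence raises with its id rather than emitting non-finite features.
    """
    if params is None:
        params = PseaacParams(property_set=builtin_pseaac_properties()[:2])
    elif len(params.property_set) != 2:
        params = PseaacParams(lam=params.lam, w=params.w,
                              property_set=builtin_pseaac_properties()[:2])
    theta = series_correlation_factors(record, params)
    return _compose(record, theta, params.w, "sc_pseaac",
                    {"lambda": params.lam, "w": params.w})


def general_pseaac_encode(
    record: PeptideRecord, params: PseaacParams, mode: str = "parallel"
) -> FeatureVector:
    """PseAAC over an arbitrary property panel.

    ``parallel`` averages squared differences over the panel (dim
    20 + lambda); ``series`` emits one tier per (lag, property) (dim
    20 + lambda * n_properties). With the canonical three-property panel,
    parallel mode reproduces :func:`pc_pseaac_encode` exactly.
    """
    if mode == "parallel":
        theta = parallel_correlation_factors(record, params)
    elif mode == "series":
        theta = series_correlation_factors(record, params)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    names = tuple(p.name for p in params.property_set)
    return _compose(
        record, theta, params.w, f"{mode}_pseaac_general",
        {"lambda": params.lam, "w": params.w, "properties": names, "mode": mode},
    )
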