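"""Mono-exponential kurtosis signal model and its parameter sensitivities.

The diffusion-weighted signal is modelled as

    S(b) = S0 * exp(-b*D + K*(b*D)**2 / 6)

where ``S0`` is the signal at b = 0, ``D`` the apparent diffusion
coefficient (um^2/ms) and ``K`` the (dimensionless) excess kurtosis.
Because the exponent depends on b and D only through the product ``bD``,
protocols can be expressed either in physical units (s/mm^2) or directly
as dimensionless ``bD`` values; all downstream error analysis is invariant
under the rescaling (b, D) -> (c*b, D/c).

This module provides the signal model, the rows of the noise-scaled
design (sensitivity) matrix used by the covariance analysis, and unit
conversion between the two protocol conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DIMENSIONLESS_BD",
    "S_PER_MM2",
    "TissueParams",
    "Protocol",
    "DesignMatrix",
    "predict_signal",
    "sensitivity_row",
    "build_design_matrix",
    "to_dimensionless",
    "to_physical",
]

#: Unit flag: b values are dimensionless b*D products.
DIMENSIONLESS_BD = "dimensionless_bD"
#: Unit flag: b values are physical diffusion weightings in s/mm^2.
S_PER_MM2 = "s_per_mm2"

# b [s/mm^2] * D [um^2/ms] * 1e-3 is dimensionless
_B_PHYSICAL_TO_BD = 1e-3


class DomainError(ValueError):
    """An argument violates the physical domain of the model."""


@dataclass(frozen=True)
class TissueParams:
    """Target tissue parameters of the kurtosis model.

    Parameters
    ----------
    s0 : float
        Baseline signal at b = 0 (arbitrary units), > 0.
    d : float
        Apparent diffusion coefficient, um^2/ms, > 0.
    k : float
        Excess kurtosis, dimensionless, >= 0. ``k = 0`` recovers the
        mono-exponential (Gaussian) decay.
    t2 : float, optional
        Transverse relaxation time in ms; only used when rescaling
        coefficients of variation for echo-time changes.
    """

    s0: float
    d: float
    k: float
    t2: float | None = None

    def __post_init__(self) -> None:
        if not self.s0 > 0:
            raise DomainError(f"s0 must be > 0, got {self.s0}")
        if not self.d > 0:
            raise DomainError(f"d must be > 0, got {self.d}")
        if self.k < 0:
            raise DomainError(f"k must be >= 0, got {self.k}")
        if self.t2 is not None and not self.t2 > 0:
            raise DomainError(f"t2 must be > 0 when given, got {self.t2}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.d, self.k], dtype=float)


@dataclass(frozen=True)
class Protocol:
    """An acquisition protocol: a multiset of b values plus the SNR at b = 0.

    ``bvalues`` may contain repeats; a repeated b value means the
    acquisition is averaged (each repeat is an independent measurement
    and a separate row of the design matrix).
    """

    bvalues: tuple[float, ...]
    unit: str = DIMENSIONLESS_BD
    snr: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bvalues", tuple(float(b) for b in self.bvalues))
        if len(self.bvalues) < 1:
            raise DomainError("protocol needs at least one b value")
        if any(b < 0 for b in self.bvalues):
            raise DomainError(f"negative b value in protocol: {self.bvalues}")
        if self.unit not in (DIMENSIONLESS_BD, S_PER_MM2):
            raise DomainError(f"unknown unit {self.unit!r}")
        if not self.snr > 0:
            raise DomainError(f"snr must be > 0, got {self.snr}")

    def __len__(self) -> int:
        return len(self.bvalues)

    def bd_values(self, d: float) -> np.ndarray:
        """The dimensionless b*D products of this protocol for diffusivity ``d``."""
        b = np.asarray(self.bvalues, dtype=float)
        if self.unit == DIMENSIONLESS_BD:
            return b
        return b * d * _B_PHYSICAL_TO_BD


@dataclass(frozen=True)
class DesignMatrix:
    """Noise-scaled sensitivity matrix A with one row per acquisition.

    ``entries[i] = (1/sigma0) * (dS/dS0, dS/dD, dS/dK)`` evaluated at the
    i-th b value.  The column order fixes the meaning of the covariance
    matrix Q = (A^T A)^{-1}: Q[1,1] is var(D) and Q[2,2] is var(K).
    """

    entries: np.ndarray
    sigma0: float

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2 or entries.shape[1] != 3:
            raise DomainError(f"design matrix must be m x 3, got {entries.shape}")
        object.__setattr__(self, "entries", entries)
        if not self.sigma0 > 0:
            raise DomainError(f"sigma0 must be > 0, got {self.sigma0}")

    @property
    def m(self) -> int:
        return self.entries.shape[0]


def _bd(b, params: TissueParams, unit: str) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise DomainError(f"negative b value: {b}")
    if unit == DIMENSIONLESS_BD:
        return b
    if unit == S_PER_MM2:
        return b * params.d * _B_PHYSICAL_TO_BD
    raise DomainError(f"unknown unit {unit!r}")


def predict_signal(b, params: TissueParams, unit: str = DIMENSIONLESS_BD):
    """Noise-free kurtosis-model signal S0 * exp(-bD + K (bD)^2 / 6).

    Parameters
    ----------
    b : float or array
        Diffusion weighting(s); dimensionless bD by default or s/mm^2
        when ``unit`` is ``S_PER_MM2``.
    params : TissueParams
    unit : str
        Interpretation of ``b``.
    """
    bd = _bd(b, params, unit)
    out = params.s0 * np.exp(-bd + params.k * bd**2 / 6.0)
    return out if np.ndim(b) else float(out)


def sensitivity_row(
    b, params: TissueParams, sigma0: float, unit: str = DIMENSIONLESS_BD
) -> np.ndarray:
    """One row of the design matrix: (1/sigma0)*(dS/dS0, dS/dD, dS/dK).

    The derivatives are taken with respect to the physical parameters
    (S0, D, K) at fixed b, so the row depends on the unit in which b is
    supplied (the D column carries a factor of b, not bD).
    """
    if not sigma0 > 0:
        raise DomainError(f"sigma0 must be > 0, got {sigma0}")
    bd = _bd(b, params, unit)
    # physical b in units reciprocal to d (ms/um^2): bd = b_eff * d
    b_eff = bd / params.d
    e = np.exp(-bd + params.k * bd**2 / 6.0)
    row = np.stack(
        [
            e,
            params.s0 * (-b_eff + 2.0 * b_eff**2 * params.d * params.k / 6.0) * e,
            params.s0 * (b_eff**2 * params.d**2 / 6.0) * e,
        ],
        axis=-1,
    )
    return row / sigma0


def build_design_matrix(protocol: Protocol, params: TissueParams) -> DesignMatrix:
    """Assemble the m x 3 design matrix for a protocol.

    The noise SD is sigma0 = s0 / SNR (SNR defined at b = 0); every b
    value of the protocol contributes one row, repeats included.
    """
    if len(protocol) < 1:
        raise DomainError("empty protocol")
    sigma0 = params.s0 / protocol.snr
    b = np.asarray(protocol.bvalues, dtype=float)
    rows = sensitivity_row(b, params, sigma0, unit=protocol.unit)
    return DesignMatrix(entries=np.atleast_2d(rows), sigma0=sigma0)


def to_dimensionless(protocol: Protocol, d: float) -> Protocol:
    """Convert a physical (s/mm^2) protocol to dimensionless bD values."""
    if protocol.unit == DIMENSIONLESS_BD:
        return protocol
    if not d > 0:
        raise DomainError(f"d must be > 0, got {d}")
    bd = tuple(b * d * _B_PHYSICAL_TO_BD for b in protocol.bvalues)
    return replace(protocol, bvalues=bd, unit=DIMENSIONLESS_BD)


def to_physical(protocol: Protocol, d: float) -> Protocol:
    """Convert a dimensionless-bD protocol back to physical s/mm^2 units."""
    if protocol.unit == S_PER_MM2:
        return protocol
    if not d > 0:
        raise DomainError(f"d must be > 0, got {d}")
    b = tuple(bd / (d * _B_PHYSICAL_TO_BD) for bd in protocol.bvalues)
    return replace(protocol, bvalues=b, unit=S_PER_MM2)
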