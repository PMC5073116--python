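"""Covariance-matrix (Cramer-Rao style) error analysis.

For a protocol with design matrix A (rows scaled by 1/sigma0), the
covariance matrix of the nonlinear-least-squares estimates of
(S0, D, K) is approximated by Q = (A^T A)^{-1}.  The per-parameter
coefficient of variation is CoV_i = sqrt(Q_ii) / a_i and the overall
mean-square error is trace(Q).

Because A scales linearly with SNR, every CoV scales exactly as 1/SNR;
signal fading with echo time enters the same way through the factor
exp(-TE/T2).  ``rescale_cov`` applies both rules without recomputing Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DesignMatrix, Protocol, TissueParams, build_design_matrix

__all__ = [
    "SingularDesignError",
    "CovarianceResult",
    "covariance_matrix",
    "coefficients_of_variation",
    "evaluate_protocol",
    "rescale_cov",
]

#: Designs whose information matrix has a condition number above this are
#: rejected as singular (e.g. fewer than 3 distinct b values).
DEFAULT_COND_THRESHOLD = 1e12


class SingularDesignError(ValueError):
    """The design matrix carries no (or numerically no) information about
    one or more parameters, so Q = (A^T A)^{-1} is meaningless."""


@dataclass(frozen=True)
class CovarianceResult:
    """Covariance matrix Q and the derived error measures.

    Attributes
    ----------
    q : (3, 3) ndarray
        Parameter covariance matrix, ordered (S0, D, K).
    cov_s0, cov_d, cov_k : float
        Coefficients of variation sqrt(Q_ii)/a_i.  ``cov_k`` is ``inf``
        when the target kurtosis is 0.
    mse : float
        trace(Q), the total mean-square error.
    """

    q: np.ndarray
    cov_s0: float
    cov_d: float
    cov_k: float
    mse: float

    @property
    def cov_sum_dk(self) -> float:
        """The design objective CoV_D + CoV_K."""
        return self.cov_d + self.cov_k


def covariance_matrix(
    a: DesignMatrix, cond_threshold: float = DEFAULT_COND_THRESHOLD
) -> np.ndarray:
    """Q = (A^T A)^{-1}, with a loud failure for singular designs.

    Raises
    ------
    SingularDesignError
        If m < 3 or cond(A^T A) exceeds ``cond_threshold`` (for example
        a protocol with fewer than three distinct b values).
    """
    if a.m < 3:
        raise SingularDesignError(
            f"need at least 3 acquisitions to estimate 3 parameters, got m={a.m}"
        )
    ata = a.entries.T @ a.entries
    cond = np.linalg.cond(ata)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise SingularDesignError(
            f"singular design (cond(A^T A) = {cond:.3g}); the protocol does not "
            "contain 3 sufficiently distinct b values"
        )
    q = np.linalg.solve(ata, np.eye(3))
    return 0.5 * (q + q.T)  # symmetrize away round-off


def coefficients_of_variation(q: np.ndarray, params: TissueParams) -> CovarianceResult:
    """Coefficients of variation CoV_i = sqrt(Q_ii)/a_i and MSE = trace(Q).

    The normalizing values a_i are the target parameters (S0, D, K).
    A target kurtosis of 0 has no scale, so ``cov_k`` is reported as
    ``inf`` rather than dividing by zero.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (3, 3):
        raise ValueError(f"q must be 3x3, got {q.shape}")
    diag = np.diag(q)
    if np.any(diag <= 0):
        raise SingularDesignError(f"covariance diagonal not positive: {diag}")
    sd = np.sqrt(diag)
    cov_k = float(sd[2] / params.k) if params.k > 0 else float("inf")
    return CovarianceResult(
        q=q,
        cov_s0=float(sd[0] / params.s0),
        cov_d=float(sd[1] / params.d),
        cov_k=cov_k,
        mse=float(diag.sum()),
    )


def evaluate_protocol(
    protocol: Protocol,
    params: TissueParams,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> CovarianceResult:
    """Build the design matrix of a protocol and return its CoVs."""
    a = build_design_matrix(protocol, params)
    try:
        q = covariance_matrix(a, cond_threshold=cond_threshold)
    except SingularDesignError as err:
        raise SingularDesignError(f"{err}; protocol b values: {protocol.bvalues}") from None
    return coefficients_of_variation(q, params)


def rescale_cov(
    result: CovarianceResult,
    snr_from: float,
    snr_to: float,
    te: float | None = None,
    t2: float | None = None,
) -> CovarianceResult:
    """Rescale CoVs for a different SNR and (optionally) echo time.

    CoV scales as 1/SNR, and signal fading at echo time TE multiplies
    every CoV by exp(TE/T2).  The covariance matrix is scaled by the
    square of the combined factor.
    """
    if not (snr_from > 0 and snr_to > 0):
        raise ValueError("snr_from and snr_to must be > 0")
    factor = snr_from / snr_to
    if te is not None:
        if t2 is None or not t2 > 0:
            raise ValueError("t2 must be > 0 when te is given")
        if te < 0:
            raise ValueError(f"te must be >= 0, got {te}")
        factor *= float(np.exp(te / t2))
    return CovarianceResult(
        q=result.q * factor**2,
        cov_s0=result.cov_s0 * factor,
        cov_d=result.cov_d * factor,
        cov_k=result.cov_k * factor,
        mse=result.mse * factor**2,
    )
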