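"""Discrete grid search for b-value designs minimizing estimation error.

The search variable is the dimensionless product bD, scanned on a regular
grid (default step 0.05) from 0 up to an upper bound.  The physically
meaningful bound is (bD)_max = 3/K, the largest weighting for which the
truncated kurtosis expansion remains a valid signal model; a scanner's
maximum b value can tighten it further.

Two enumeration modes are provided:

``exhaustive``
    every multiset of n grid points (stars-and-bars; feasible for n = 3
    and for coarse grids at larger n);
``support_points``
    every design with at most 3 distinct b values (classical
    optimal-design support bound for a 3-parameter model), with
    multiplicities summing to n.  All known optima obey this bound, and
    it keeps n = 4, 5 searches tractable.

Candidate designs are scored by a vectorized covariance evaluation
(closed-form 3x3 inverse via cofactors); the winning design is then
re-verified with the exact, condition-checked covariance routine.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .crlb import (
    DEFAULT_COND_THRESHOLD,
    CovarianceResult,
    SingularDesignError,
    coefficients_of_variation,
    evaluate_protocol,
)
from .model import DIMENSIONLESS_BD, Protocol, TissueParams, sensitivity_row

__all__ = [
    "OptimizationSpec",
    "OptimizationResult",
    "max_allowable_bd",
    "enumerate_designs",
    "optimize_protocol",
    "equally_spaced_protocol",
    "robustness_sweep",
    "SweepPoint",
]

logger = logging.getLogger(__name__)

_OBJECTIVES = ("cov_d", "cov_k", "cov_d_plus_cov_k", "mse")
_CHUNK = 1 << 18


def max_allowable_bd(k: float) -> float:
    """Maximum allowable weighting (bD)_max = 3/K for the kurtosis model.

    Beyond this point the truncated cumulant expansion stops decaying
    monotonically and is no longer a valid description of the signal.
    """
    if not k > 0:
        raise ValueError(
            f"k must be > 0 for a finite model bound (got {k}); "
            "supply a scanner b limit instead"
        )
    return 3.0 / k


@dataclass(frozen=True)
class OptimizationSpec:
    """Search specification for the protocol optimizer.

    Parameters
    ----------
    n : int
        Number of acquisitions (>= 3).
    grid_step : float
        bD grid increment; the default 0.05 resolves all published optima.
    bd_max : float, optional
        Upper bound of the search grid in bD units.  Defaults to the
        model bound 3/K of the target tissue, possibly tightened by
        ``scanner_b_max``.
    objective : str
        One of ``cov_d``, ``cov_k``, ``cov_d_plus_cov_k`` (default; the
        joint D-and-K criterion), ``mse``.
    scanner_b_max : float, optional
        Hardware limit on b, s/mm^2; converted to bD via the target D.
    search_mode : str
        ``exhaustive``, ``support_points``, or ``auto`` (exhaustive for
        n = 3, support points for n >= 4).
    """

    n: int
    grid_step: float = 0.05
    bd_max: float | None = None
    objective: str = "cov_d_plus_cov_k"
    scanner_b_max: float | None = None
    search_mode: str = "auto"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"need n >= 3 acquisitions, got {self.n}")
        if not self.grid_step > 0:
            raise ValueError(f"grid_step must be > 0, got {self.grid_step}")
        if self.bd_max is not None and not self.bd_max > 0:
            raise ValueError(f"bd_max must be > 0, got {self.bd_max}")
        if self.objective not in _OBJECTIVES:
            raise ValueError(f"objective must be one of {_OBJECTIVES}")
        if self.search_mode not in ("auto", "exhaustive", "support_points"):
            raise ValueError(f"unknown search_mode {self.search_mode!r}")

    def effective_bd_max(self, params: TissueParams) -> float:
        """Search bound: min(3/K, scanner bound, explicit bd_max)."""
        bounds = []
        if self.bd_max is not None:
            bounds.append(self.bd_max)
        if params.k > 0:
            bounds.append(max_allowable_bd(params.k))
        if self.scanner_b_max is not None:
            bounds.append(self.scanner_b_max * params.d * 1e-3)
        if not bounds:
            raise ValueError(
                "no finite search bound: k = 0 and neither bd_max nor "
                "scanner_b_max supplied"
            )
        return min(bounds)

    def resolved_mode(self) -> str:
        if self.search_mode != "auto":
            return self.search_mode
        return "exhaustive" if self.n == 3 else "support_points"

    def grid(self, params: TissueParams) -> np.ndarray:
        bd_max = self.effective_bd_max(params)
        g = np.round(np.arange(0.0, bd_max + 1e-9, self.grid_step), 10)
        if g[-1] < bd_max - 1e-9:  # keep the bound itself reachable
            g = np.append(g, round(bd_max, 10))
        if len(g) < 3:
            raise ValueError(
                f"grid too coarse: only {len(g)} points in [0, {bd_max}] at "
                f"step {self.grid_step}; need at least 3 distinct values"
            )
        return g


@dataclass(frozen=True)
class OptimizationResult:
    """Winning design of a grid search."""

    best_protocol: Protocol
    covs: CovarianceResult
    n_evaluated: int
    objective_value: float
    n_singular: int = 0


def _compositions(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    """Ordered compositions of ``total`` into ``parts`` positive integers."""
    if parts == 1:
        yield (total,)
        return
    for first in range(1, total - parts + 2):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def enumerate_designs(
    spec: OptimizationSpec, params: TissueParams
) -> Iterator[tuple[float, ...]]:
    """Yield every candidate design (as a sorted tuple of bD values).

    Exhaustive mode yields all multisets of n grid points; support-points
    mode yields all designs with at most 3 distinct values.  The order is
    deterministic and free of duplicates.
    """
    g = spec.grid(params)
    if spec.resolved_mode() == "exhaustive":
        yield from itertools.combinations_with_replacement(tuple(g), spec.n)
        return
    for n_distinct in (1, 2, 3):
        if n_distinct > spec.n:
            continue
        mults = list(_compositions(spec.n, n_distinct))
        for points in itertools.combinations(tuple(g), n_distinct):
            for m in mults:
                design: tuple[float, ...] = ()
                for p, c in zip(points, m):
                    design += (p,) * c
                yield design


def _grid_rows(g: np.ndarray, params: TissueParams, snr: float) -> np.ndarray:
    sigma0 = params.s0 / snr
    return sensitivity_row(g, params, sigma0, unit=DIMENSIONLESS_BD)


def _objective_from_ata(
    ata: np.ndarray, params: TissueParams, objective: str
) -> np.ndarray:
    """Vectorized objective over a stack of 3x3 information matrices.

    Uses the cofactor form of the 3x3 inverse; candidates whose
    information matrix is (numerically) singular get +inf.
    """
    a = ata[:, 0, 0]
    b = ata[:, 0, 1]
    c = ata[:, 0, 2]
    d = ata[:, 1, 1]
    e = ata[:, 1, 2]
    f = ata[:, 2, 2]
    det = a * (d * f - e * e) - b * (b * f - e * c) + c * (b * e - d * c)
    scale = (np.abs(a) + np.abs(d) + np.abs(f)) / 3.0
    valid = det > 1e-9 * scale**3
    safe_det = np.where(valid, det, 1.0)
    q11 = (d * f - e * e) / safe_det
    q22 = (a * f - c * c) / safe_det
    q33 = (a * d - b * b) / safe_det
    valid &= (q11 > 0) & (q22 > 0) & (q33 > 0)
    q11 = np.where(valid, q11, 1.0)
    q22 = np.where(valid, q22, 1.0)
    q33 = np.where(valid, q33, 1.0)
    if objective == "cov_d":
        obj = np.sqrt(q22) / params.d
    elif objective == "cov_k":
        obj = np.sqrt(q33) / params.k
    elif objective == "cov_d_plus_cov_k":
        obj = np.sqrt(q22) / params.d + np.sqrt(q33) / params.k
    else:  # mse
        obj = q11 + q22 + q33
    return np.where(valid, obj, np.inf)


def _candidate_chunks(
    spec: OptimizationSpec, g: np.ndarray
) -> Iterator[np.ndarray]:
    """Index arrays (chunk, n) into the grid, covering all candidates."""
    n = spec.n
    if spec.resolved_mode() == "exhaustive":
        it = itertools.combinations_with_replacement(range(len(g)), n)
        while True:
            chunk = list(itertools.islice(it, _CHUNK))
            if not chunk:
                return
            yield np.asarray(chunk, dtype=np.intp)
    else:
        for n_distinct in (1, 2, 3):
            if n_distinct > n:
                continue
            mults = list(_compositions(n, n_distinct))
            pts_iter = itertools.combinations(range(len(g)), n_distinct)
            while True:
                pts = np.asarray(
                    list(itertools.islice(pts_iter, _CHUNK // len(mults) + 1)),
                    dtype=np.intp,
                )
                if pts.size == 0:
                    break
                for m in mults:
                    cols = [
                        pts[:, j] for j in range(n_distinct) for _ in range(m[j])
                    ]
                    yield np.stack(cols, axis=1)


def optimize_protocol(
    spec: OptimizationSpec,
    params: TissueParams,
    snr: float = 20.0,
) -> OptimizationResult:
    """Grid-search the design minimizing the chosen error objective.

    Singular candidates (fewer than 3 distinct b values, or numerically
    rank-deficient) are skipped.  Ties are broken by the lexicographically
    smallest sorted design, making the result fully deterministic.
    """
    if spec.objective == "cov_k" and params.k == 0:
        raise ValueError("objective cov_k undefined for k = 0")
    g = spec.grid(params)
    rows = _grid_rows(g, params, snr)
    outer = np.einsum("gi,gj->gij", rows, rows)

    best_obj = np.inf
    best_designs: list[tuple[float, ...]] = []
    n_eval = 0
    n_singular = 0
    for idx in _candidate_chunks(spec, g):
        ata = outer[idx].sum(axis=1)
        obj = _objective_from_ata(ata, params, spec.objective)
        n_eval += len(obj)
        n_singular += int(np.isinf(obj).sum())
        lo = float(np.min(obj))
        if lo > best_obj:
            continue
        if lo < best_obj:
            best_obj = lo
            best_designs = []
        if np.isinf(lo):
            continue
        for i in np.flatnonzero(obj == lo):
            best_designs.append(tuple(sorted(g[idx[i]])))
    if not np.isfinite(best_obj) or not best_designs:
        raise SingularDesignError(
            "every candidate design was singular; grid or n too small"
        )
    logger.debug(
        "optimizer: %d candidates, %d singular skipped", n_eval, n_singular
    )
    best = min(best_designs)
    protocol = Protocol(bvalues=best, unit=DIMENSIONLESS_BD, snr=snr)
    covs = evaluate_protocol(protocol, params)
    value = {
        "cov_d": covs.cov_d,
        "cov_k": covs.cov_k,
        "cov_d_plus_cov_k": covs.cov_sum_dk,
        "mse": covs.mse,
    }[spec.objective]
    return OptimizationResult(
        best_protocol=protocol,
        covs=covs,
        n_evaluated=n_eval,
        objective_value=float(value),
        n_singular=n_singular,
    )


def equally_spaced_protocol(n: int, bd_max: float, snr: float = 20.0) -> Protocol:
    """Reference design with n b values uniform on [0, bd_max]."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if not bd_max > 0:
        raise ValueError(f"bd_max must be > 0, got {bd_max}")
    bvalues = tuple(i * bd_max / (n - 1) for i in range(n))
    return Protocol(bvalues=bvalues, unit=DIMENSIONLESS_BD, snr=snr)


@dataclass(frozen=True)
class SweepPoint:
    """One evaluation of a fixed protocol at a perturbed tissue value."""

    value: float
    result: CovarianceResult | None
    error: str | None = None


def robustness_sweep(
    protocol: Protocol,
    params: TissueParams,
    vary: str,
    values: Sequence[float],
) -> list[SweepPoint]:
    """Evaluate a fixed protocol while sweeping the true D or K.

    The protocol is held fixed (it was designed at the target values);
    each swept value yields the CoVs the design would deliver if the
    true tissue parameter were there instead.  Values violating the
    model domain are flagged rather than raised.
    """
    if vary not in ("d", "k"):
        raise ValueError(f"vary must be 'd' or 'k', got {vary!r}")
    out: list[SweepPoint] = []
    for v in values:
        try:
            p = TissueParams(
                s0=params.s0,
                d=v if vary == "d" else params.d,
                k=v if vary == "k" else params.k,
                t2=params.t2,
            )
            res = evaluate_protocol(protocol, p)
        except (ValueError, SingularDesignError) as err:
            out.append(SweepPoint(value=float(v), result=None, error=str(err)))
            continue
        out.append(SweepPoint(value=float(v), result=res))
    return out
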