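"""Monte-Carlo verification of the covariance-matrix error predictions.

Noise-free kurtosis signals for a protocol are perturbed with Gaussian or
Rician noise (sigma = S0/SNR, the noise SD at b = 0), refitted by
nonlinear least squares, and the empirical coefficients of variation of
the parameter estimates are compared with the covariance-matrix values.

Rician draws use the modulus-of-complex-Gaussian construction
sqrt((S + x)^2 + y^2) with x, y ~ N(0, sigma), which is exactly the
Rician magnitude distribution of MR data.

The refitter is a batched, bound-constrained Levenberg-Marquardt solver
that iterates all repetitions simultaneously (each iteration solves one
3x3 system per repetition), so a 10^4-repetition sweep takes a fraction
of a second instead of 10^4 optimizer calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DIMENSIONLESS_BD, Protocol, TissueParams

__all__ = [
    "MonteCarloSpec",
    "MonteCarloResult",
    "add_gaussian_noise",
    "sample_rician",
    "fit_kurtosis_model",
    "mc_coefficients_of_variation",
    "FitFailure",
]

_EXP_CLIP = 50.0  # cost of absurd trial steps still finite and rejectable


class FitFailure(RuntimeError):
    """Raised when a configuration produces mostly failed fits."""


@dataclass(frozen=True)
class MonteCarloSpec:
    """Settings of a Monte-Carlo coefficient-of-variation run.

    Parameters
    ----------
    n_reps : int
        Number of independent noise realizations.  10^4 gives a standard
        error on a CoV of about CoV/sqrt(2e4) ~ 0.7%.
    noise_kind : str
        ``gaussian`` or ``rician``.
    seed : int
        Seed for the pseudo-random generator; runs are fully reproducible
        from (seed, spec).
    fit_init : str
        ``perturbed`` starts every fit at the true parameters inflated by
        ``init_perturbation`` (isolates estimator noise from global-search
        failures); ``log_linear`` starts from a quadratic fit of the
        log-signal in b.
    fit_bounds : tuple of (lo, hi) pairs, optional
        Box bounds on (S0, D, K).  Defaults to (0, 10*s0], (0, 10*d],
        [0, 10].
    failure_policy : str
        ``discard`` drops non-converged fits from the CoV (counted in
        ``n_failed``); ``flag`` keeps them.
    """

    n_reps: int = 10_000
    noise_kind: str = "gaussian"
    seed: int = 0
    fit_init: str = "perturbed"
    fit_bounds: tuple[tuple[float, float], ...] | None = None
    failure_policy: str = "discard"
    init_perturbation: float = 0.10
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if self.noise_kind not in ("gaussian", "rician"):
            raise ValueError(f"noise_kind must be gaussian|rician, got {self.noise_kind!r}")
        if self.fit_init not in ("perturbed", "log_linear"):
            raise ValueError(f"fit_init must be perturbed|log_linear, got {self.fit_init!r}")
        if self.failure_policy not in ("discard", "flag"):
            raise ValueError(f"failure_policy must be discard|flag, got {self.failure_policy!r}")

    def bounds_for(self, params: TissueParams) -> tuple[np.ndarray, np.ndarray]:
        if self.fit_bounds is not None:
            bounds = np.asarray(self.fit_bounds, dtype=float)
            lo, hi = bounds[:, 0], bounds[:, 1]
        else:
            lo = np.array([1e-12, 1e-12, 0.0])
            hi = np.array([10.0 * params.s0, 10.0 * params.d, 10.0])
        true = params.as_array()
        if np.any(true < lo) or np.any(true > hi):
            raise ValueError(
                f"fit bounds {list(zip(lo, hi))} do not contain the true parameters {true}"
            )
        return lo, hi


@dataclass(frozen=True)
class MonteCarloResult:
    """Empirical per-parameter errors from repeated noisy refits.

    ``cov_*`` are sample SD divided by the TRUE parameter (the same
    normalization the covariance analysis uses); ``cov_*_of_mean`` divide
    by the sample mean instead.  ``n_bounded`` counts fits pinned at a
    box bound (these converge, but to a constrained optimum).
    """

    cov_s0: float
    cov_d: float
    cov_k: float
    cov_s0_of_mean: float
    cov_d_of_mean: float
    cov_k_of_mean: float
    mean: np.ndarray
    sd: np.ndarray
    n_reps: int
    n_failed: int
    n_bounded: int


def add_gaussian_noise(signals, sigma: float, rng: np.random.Generator):
    """Add zero-mean Gaussian noise of SD ``sigma`` to each signal."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    signals = np.asarray(signals, dtype=float)
    return signals + rng.normal(0.0, 1.0, signals.shape) * sigma


def sample_rician(signal, sigma: float, rng: np.random.Generator):
    """Draw from the Rician magnitude distribution around ``signal``.

    Constructed as |signal + complex Gaussian noise|, i.e.
    sqrt((S + x)^2 + y^2) with independent x, y ~ N(0, sigma).  For
    signal = 0 this is a Rayleigh draw; for sigma -> 0 it tends to the
    noise-free signal.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("Rician noise is defined for non-negative signals")
    x = rng.normal(0.0, 1.0, signal.shape) * sigma
    y = rng.normal(0.0, 1.0, signal.shape) * sigma
    return np.hypot(signal + x, y)


def _model_batch(b_eff: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Kurtosis signal for a batch of parameter vectors; theta (..., 3)."""
    s0 = theta[..., 0:1]
    d = theta[..., 1:2]
    k = theta[..., 2:3]
    expo = np.minimum(-b_eff * d + k * (b_eff * d) ** 2 / 6.0, _EXP_CLIP)
    return s0 * np.exp(expo)


def _jacobian_batch(b_eff: np.ndarray, theta: np.ndarray) -> np.ndarray:
    s0 = theta[..., 0:1]
    d = theta[..., 1:2]
    k = theta[..., 2:3]
    expo = np.minimum(-b_eff * d + k * (b_eff * d) ** 2 / 6.0, _EXP_CLIP)
    e = np.exp(expo)
    return np.stack(
        [
            e,
            s0 * (-b_eff + 2.0 * b_eff**2 * d * k / 6.0) * e,
            s0 * (b_eff**2 * d**2 / 6.0) * e,
        ],
        axis=-1,
    )


def _batch_lm(
    b_eff: np.ndarray,
    y: np.ndarray,
    theta0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    max_iter: int = 200,
    ftol: float = 1e-12,
    gtol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Bound-constrained Levenberg-Marquardt over a batch of curve fits.

    Every repetition is advanced in lockstep with a per-problem damping
    parameter; steps are accepted only if they reduce the cost.  Bounds
    are handled with an active set: a coordinate sitting on a bound with
    the gradient pointing outward is frozen for the step (its row/column
    of the normal equations is masked), so boundary optima are reached
    and recognized.  Returns the estimates and a convergence flag per
    problem (small projected gradient or stalled cost improvement).
    """
    theta = np.clip(theta0, lo, hi).astype(float, copy=True)
    n = theta.shape[0]
    lam = np.full(n, 1e-3)
    r = y - _model_batch(b_eff, theta)
    cost = np.einsum("nm,nm->n", r, r)
    converged = np.zeros(n, dtype=bool)
    eye = np.eye(3)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        th_a = theta[active]
        r_a = r[active]
        j = _jacobian_batch(b_eff, th_a)
        g = np.einsum("nmi,nm->ni", j, r_a)
        h = np.einsum("nmi,nmj->nij", j, j)

        # active set: freeze coordinates pinned at a bound whose descent
        # direction (+g) points out of the box
        fixed = ((th_a <= lo + 1e-14) & (g < 0)) | ((th_a >= hi - 1e-14) & (g > 0))
        g = np.where(fixed, 0.0, g)
        free = ~fixed
        h = h * (free[:, :, None] & free[:, None, :])
        h += fixed[:, :, None] * eye  # unit diagonal on frozen coords

        diag = np.einsum("nii->ni", h)
        aug = h + lam[active, None, None] * (diag[:, :, None] * eye) + 1e-30 * eye
        try:
            step = np.linalg.solve(aug, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(
                aug.reshape(-1, 3, 3).astype(float), g[..., None], rcond=None
            )[0][..., 0]
        th_new = np.clip(th_a + step, lo, hi)
        r_new = y[active] - _model_batch(b_eff, th_new)
        cost_new = np.einsum("nm,nm->n", r_new, r_new)
        better = cost_new <= cost[active]
        improvement = np.where(
            better, cost[active] - cost_new, 0.0
        ) / np.maximum(cost[active], 1e-300)

        idx = np.flatnonzero(active)
        acc = idx[better]
        theta[acc] = th_new[better]
        r[acc] = r_new[better]
        cost[acc] = cost_new[better]
        lam[idx] = np.where(better, lam[idx] * 0.33, lam[idx] * 4.0)
        lam[idx] = np.clip(lam[idx], 1e-12, 1e14)

        gnorm = np.abs(g).max(axis=1)  # projected gradient after masking
        small_grad = gnorm < gtol * np.maximum(1.0, np.sqrt(cost[active]))
        stalled = better & (improvement < ftol)
        converged[idx[small_grad | stalled]] = True
        # problems stuck at max damping without improvement stay unconverged
    return theta, converged


def _log_linear_init(
    b_eff: np.ndarray, y: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Quadratic fit of log-signal in b: exponent is linear in the
    parameters (log S0, D, K D^2/6), giving a cheap starting point."""
    y_safe = np.maximum(y, 1e-6)
    v = np.vander(b_eff, 3, increasing=True)  # 1, b, b^2
    coef, *_ = np.linalg.lstsq(v, np.log(y_safe).T, rcond=None)
    s0 = np.exp(coef[0])
    d = np.maximum(-coef[1], 1e-6)
    k = 6.0 * coef[2] / d**2
    theta = np.stack([s0, d, k], axis=-1)
    return np.clip(theta, lo, hi)


def fit_kurtosis_model(
    bvalues,
    signals,
    spec: MonteCarloSpec | None = None,
    init: TissueParams | None = None,
    unit: str = DIMENSIONLESS_BD,
    d_ref: float = 1.0,
):
    """Nonlinear least-squares fit of (S0, D, K) to one set of signals.

    Parameters
    ----------
    bvalues : sequence
        Diffusion weightings (>= 3 distinct values required).
    signals : sequence
        Measured signals, same length.
    spec : MonteCarloSpec, optional
        Supplies bounds, initialization policy and iteration limits.
    init : TissueParams, optional
        Explicit starting point; required reference for the ``perturbed``
        policy (otherwise the log-linear start is used).
    unit, d_ref :
        Unit of ``bvalues``; for dimensionless bD values ``d_ref`` maps
        them back to a b axis (b_eff = bD / d_ref) so the fitted D is on
        the physical scale.

    Returns
    -------
    (TissueParams, bool)
        The estimate and a convergence flag.
    """
    spec = spec or MonteCarloSpec()
    b = np.asarray(bvalues, dtype=float)
    y = np.asarray(signals, dtype=float)
    if b.shape != y.shape or b.ndim != 1:
        raise ValueError("bvalues and signals must be 1-d of equal length")
    if len(np.unique(b)) < 3:
        raise ValueError(
            f"need at least 3 distinct b values to fit 3 parameters, got {np.unique(b)}"
        )
    if unit == DIMENSIONLESS_BD:
        b_eff = b / d_ref
    else:
        b_eff = b * 1e-3  # s/mm^2 -> ms/um^2
    ref = init or TissueParams(s0=max(float(y.max()), 1e-6), d=d_ref, k=1.0)
    if spec.fit_bounds is not None:
        bounds = np.asarray(spec.fit_bounds, dtype=float)
        lo, hi = bounds[:, 0], bounds[:, 1]
    else:
        lo = np.array([1e-12, 1e-12, 0.0])
        hi = np.array([10.0 * ref.s0, 10.0 * ref.d, 10.0])
    if init is not None and spec.fit_init == "perturbed":
        theta0 = init.as_array() * (1.0 + spec.init_perturbation)
    else:
        theta0 = _log_linear_init(b_eff, y[None, :], lo, hi)[0]
    theta, ok = _batch_lm(
        b_eff, y[None, :], theta0[None, :], lo, hi, max_iter=spec.max_iter
    )
    est = TissueParams(
        s0=float(max(theta[0, 0], 1e-12)),
        d=float(max(theta[0, 1], 1e-12)),
        k=float(max(theta[0, 2], 0.0)),
    )
    return est, bool(ok[0])


def mc_coefficients_of_variation(
    protocol: Protocol,
    params: TissueParams,
    spec: MonteCarloSpec | None = None,
) -> MonteCarloResult:
    """Empirical CoVs of (S0, D, K) over repeated noisy refits.

    Simulates the noise-free signals of ``protocol`` at ``params``, adds
    ``spec.n_reps`` independent noise realizations (sigma = s0/SNR),
    refits each, and summarizes the estimates.

    Raises
    ------
    FitFailure
        If more than half the fits fail to converge.
    """
    spec = spec or MonteCarloSpec()
    bd = protocol.bd_values(params.d)
    if len(np.unique(bd)) < 3:
        raise ValueError("protocol needs >= 3 distinct b values for refitting")
    b_eff = bd / params.d
    true = params.as_array()
    clean = _model_batch(b_eff, true[None, :])[0]
    sigma = params.s0 / protocol.snr

    rng = np.random.default_rng(spec.seed)
    if spec.noise_kind == "gaussian":
        y = clean[None, :] + rng.normal(0.0, 1.0, (spec.n_reps, len(bd))) * sigma
    else:
        x = rng.normal(0.0, 1.0, (spec.n_reps, len(bd))) * sigma
        yy = rng.normal(0.0, 1.0, (spec.n_reps, len(bd))) * sigma
        y = np.hypot(clean[None, :] + x, yy)

    lo, hi = spec.bounds_for(params)
    if spec.fit_init == "perturbed":
        theta0 = np.tile(true * (1.0 + spec.init_perturbation), (spec.n_reps, 1))
        theta0 = np.clip(theta0, lo, hi)
    else:
        theta0 = _log_linear_init(b_eff, y, lo, hi)

    theta, ok = _batch_lm(b_eff, y, theta0, lo, hi, max_iter=spec.max_iter)
    n_failed = int((~ok).sum())
    if n_failed > spec.n_reps // 2:
        raise FitFailure(
            f"{n_failed}/{spec.n_reps} fits failed to converge; "
            "pathological protocol or noise configuration"
        )
    keep = ok if spec.failure_policy == "discard" else np.ones(len(ok), dtype=bool)
    est = theta[keep]
    at_bound = np.any((est <= lo + 1e-10) | (est >= hi - 1e-10), axis=1)
    mean = est.mean(axis=0)
    sd = est.std(axis=0, ddof=1) if len(est) > 1 else np.zeros(3)
    cov_true = sd / true if params.k > 0 else np.array(
        [sd[0] / true[0], sd[1] / true[1], np.inf]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        cov_mean = np.where(mean != 0, sd / np.abs(mean), np.inf)
    return MonteCarloResult(
        cov_s0=float(cov_true[0]),
        cov_d=float(cov_true[1]),
        cov_k=float(cov_true[2]),
        cov_s0_of_mean=float(cov_mean[0]),
        cov_d_of_mean=float(cov_mean[1]),
        cov_k_of_mean=float(cov_mean[2]),
        mean=mean,
        sd=sd,
        n_reps=spec.n_reps,
        n_failed=n_failed,
        n_bounded=int(at_bound.sum()),
    )
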