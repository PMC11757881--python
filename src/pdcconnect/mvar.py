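"""Multivariate autoregressive (MVAR) modelling and partial directed coherence.

Two objects mirror the statsmodels VAR/VARProcess split:

``MVARProcess``
    A *known-parameter* vector-autoregression
    ``y(t) = Σ_ζ C_ζ y(t−ζ) + ϵ(t)`` with Gaussian innovations — used to
    simulate ground-truth EEG-like cohorts and to evaluate the *analytic*
    PDC, the oracle against which estimators are tested.

``MVAR`` / ``MVARResults``
    The estimator: ordinary-least-squares coefficient fits on a
    channels × samples segment, BIC order selection, the spectral
    coefficient transform Ā(ω) = I − Σ_ζ C_ζ e^(−jωζ), and the squared,
    column-normalized partial directed coherence

        PDC_vw(ω) = |Ā_vw(ω)|² / Σ_v' |Ā_v'w(ω)|²,

    which measures the directed influence of channel ``w`` (source,
    column) on channel ``v`` (target, row) at frequency ω, normalized so
    each source's outgoing influence sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class UnstableModelError(ValueError):
    """Raised when an operation requires a stable MVAR model and gets an unstable one."""


def _as_coeff_array(coeffs) -> np.ndarray:
    """Validate and stack per-lag coefficient matrices into (order, S, S)."""
    arr = np.asarray(coeffs, dtype=float)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError(
            f"coeffs must be an ordered list of square matrices, got shape {arr.shape}"
        )
    return arr


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of the lag polynomial; stability <=> spectral radius < 1."""
    coeffs = _as_coeff_array(coeffs)
    order, n, _ = coeffs.shape
    comp = np.zeros((order * n, order * n))
    comp[:n, :] = np.concatenate(list(coeffs), axis=1)
    if order > 1:
        comp[n:, :-n] = np.eye((order - 1) * n)
    return comp


def spectral_radius(coeffs: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(companion_matrix(coeffs))).max())


def transfer_function(coeffs: np.ndarray, omegas: np.ndarray) -> np.ndarray:
    """Ā(ω) = I − Σ_ζ C_ζ e^(−jωζ) for each ω; returns (n_omega, S, S) complex."""
    coeffs = _as_coeff_array(coeffs)
    order, n, _ = coeffs.shape
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    lags = np.arange(1, order + 1)
    phase = np.exp(-1j * omegas[:, None] * lags[None, :])  # (n_omega, order)
    a_bar = np.eye(n)[None, :, :] - np.einsum("wz,zvs->wvs", phase, coeffs)
    return a_bar


def pdc_from_transfer(a_bar: np.ndarray, squared: bool = True) -> np.ndarray:
    """Column-normalized PDC from Ā(ω); input (..., S, S), output same shape in [0,1].

    Entry (v, w) = |Ā_vw|² / Σ_v' |Ā_v'w|² (or its square root if
    ``squared=False``).  Columns sum to one (squared form) at every ω.
    """
    power = np.abs(a_bar) ** 2
    colsum = power.sum(axis=-2, keepdims=True)
    if np.any(colsum <= 0):
        raise ValueError("degenerate zero column in spectral coefficients")
    out = power / colsum
    return out if squared else np.sqrt(out)


@dataclass(frozen=True)
class SpectralCoefficients:
    """Spectral coefficient matrices Ā(ω) on an angular-frequency grid."""

    omega_grid: np.ndarray  # (n_omega,) in [0, π]
    a_bar: np.ndarray  # (n_omega, S, S) complex

    def pdc(self, squared: bool = True) -> np.ndarray:
        return pdc_from_transfer(self.a_bar, squared=squared)


class MVARProcess:
    """A stable known-parameter MVAR process (the ground-truth generator).

    Parameters
    ----------
    coeffs : sequence of (S, S) arrays
        Per-lag coefficient matrices ``C_1 .. C_ρ``; row = target channel,
        column = source channel.
    noise_cov : (S, S) array, optional
        Innovation covariance Σ_ϵ (symmetric positive definite).
        Defaults to the identity.
    """

    def __init__(self, coeffs, noise_cov=None):
        self.coeffs = _as_coeff_array(coeffs)
        self.order, self.n_channels, _ = self.coeffs.shape
        if noise_cov is None:
            noise_cov = np.eye(self.n_channels)
        noise_cov = np.asarray(noise_cov, dtype=float)
        if noise_cov.shape != (self.n_channels, self.n_channels):
            raise ValueError("noise_cov shape does not match channel count")
        if np.abs(noise_cov - noise_cov.T).max() > 1e-10:
            raise ValueError("noise_cov must be symmetric (tol 1e-10)")
        try:
            self._chol = np.linalg.cholesky(noise_cov)
        except np.linalg.LinAlgError:
            raise ValueError("noise_cov must be positive definite") from None
        self.noise_cov = noise_cov

    @property
    def spectral_radius(self) -> float:
        return spectral_radius(self.coeffs)

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0

    def _require_stable(self) -> None:
        if not self.is_stable:
            raise UnstableModelError(
                f"MVAR process is unstable (companion spectral radius "
                f"{self.spectral_radius:.4f} >= 1)"
            )

    def simulate(self, n_samples: int, burn_in: int = 1000, seed=None) -> np.ndarray:
        """Simulate the process; returns (S, n_samples) after discarding burn-in.

        Deterministic given ``seed`` (an int or a ``numpy.random.Generator``).
        """
        self._require_stable()
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        order, n = self.order, self.n_channels
        total = n_samples + burn_in
        innov = rng.standard_normal((total, n)) @ self._chol.T
        y = np.zeros((total + order, n))
        coeffs = self.coeffs
        for t in range(total):
            acc = innov[t]
            base = t + order
            for z in range(order):
                acc = acc + coeffs[z] @ y[base - 1 - z]
            y[base] = acc
        return y[order + burn_in:].T.copy()

    def transfer(self, omegas) -> np.ndarray:
        return transfer_function(self.coeffs, omegas)

    def analytic_pdc(self, omega, squared: bool = True) -> np.ndarray:
        """Ground-truth PDC at angular frequency ω ∈ [0, π], directly from C_ζ."""
        self._require_stable()
        omega_arr = np.atleast_1d(np.asarray(omega, dtype=float))
        if np.any(omega_arr < 0) or np.any(omega_arr > np.pi + 1e-12):
            raise ValueError("omega must lie in [0, pi]")
        out = pdc_from_transfer(self.transfer(omega_arr), squared=squared)
        return out[0] if np.isscalar(omega) or np.ndim(omega) == 0 else out

    def analytic_band_pdc(self, fs: float, k: int = 4, squared: bool = True) -> np.ndarray:
        """Analytic band-averaged PDC on the 64-band grid; (64, S, S)."""
        from . import bands

        self._require_stable()
        freqs = np.concatenate([bands.band_frequencies(b, k) for b in range(1, bands.N_BANDS + 1)])
        pdc = pdc_from_transfer(self.transfer(bands.hz_to_omega(freqs, fs)), squared=squared)
        return pdc.reshape(bands.N_BANDS, k, *pdc.shape[1:]).mean(axis=1)


class MVAR:
    """OLS estimator of an MVAR model on a channels × samples data matrix.

    Channel means are removed before fitting (the model has no intercept
    term; band-passed EEG is zero-mean up to segment-level drift).
    """

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite samples")
        self.endog = data - data.mean(axis=1, keepdims=True)
        self.n_channels, self.n_samples = data.shape

    def _design(self, order: int, offset: int):
        """Lagged design matrix starting at sample ``offset`` (>= order)."""
        y = self.endog.T  # (n, S)
        n = self.n_samples
        targets = y[offset:]
        blocks = [y[offset - z: n - z] for z in range(1, order + 1)]
        x = np.concatenate(blocks, axis=1)  # (n - offset, order*S)
        return x, targets

    def _ols(self, order: int, offset: int):
        x, targets = self._design(order, offset)
        n_eff, n_params = x.shape
        if n_eff <= n_params:
            raise ValueError(
                f"too few samples ({n_eff}) for order {order} on "
                f"{self.n_channels} channels ({n_params} regressors)"
            )
        beta, _, rank, _ = np.linalg.lstsq(x, targets, rcond=None)
        if rank < n_params:
            raise np.linalg.LinAlgError(
                f"rank-deficient regressor matrix (rank {rank} < {n_params})"
            )
        resid = targets - x @ beta
        sigma_ml = resid.T @ resid / n_eff
        coeffs = beta.T.reshape(self.n_channels, order, self.n_channels).transpose(1, 0, 2)
        return coeffs, sigma_ml, resid, n_eff

    def _bic(self, sigma_ml: np.ndarray, n_eff: int, order: int) -> float:
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            return np.inf
        k = order * self.n_channels ** 2
        return logdet + k * np.log(n_eff) / n_eff

    def select_order(self, max_order: int = 20) -> int:
        """Order minimizing BIC over 1..max_order on a common sample window."""
        bics = []
        for order in range(1, max_order + 1):
            coeffs, sigma_ml, _, n_eff = self._ols(order, max_order)
            bics.append(self._bic(sigma_ml, n_eff, order))
        return int(np.argmin(bics)) + 1

    def fit(self, order: int | str = "auto", max_order: int = 20) -> "MVARResults":
        if order == "auto":
            order = self.select_order(max_order)
        order = int(order)
        if order < 1:
            raise ValueError("order must be >= 1")
        coeffs, sigma_ml, resid, n_eff = self._ols(order, order)
        dof = n_eff - order * self.n_channels
        sigma_u = resid.T @ resid / max(dof, 1)
        bic = self._bic(sigma_ml, n_eff, order)
        return MVARResults(model=self, order=order, coeffs=coeffs,
                           sigma_u=sigma_u, nobs=n_eff, bic=bic)


@dataclass
class MVARResults:
    """Fitted MVAR coefficients plus the spectral/PDC machinery."""

    model: MVAR
    order: int
    coeffs: np.ndarray  # (order, S, S)
    sigma_u: np.ndarray  # residual covariance, df-adjusted
    nobs: int
    bic: float
    _radius: float | None = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def spectral_radius(self) -> float:
        if self._radius is None:
            self._radius = spectral_radius(self.coeffs)
        return self._radius

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0

    def spectral_transform(self, omega_grid) -> SpectralCoefficients:
        omega_grid = np.atleast_1d(np.asarray(omega_grid, dtype=float))
        if omega_grid.size == 0:
            raise ValueError("empty frequency grid")
        return SpectralCoefficients(omega_grid=omega_grid,
                                    a_bar=transfer_function(self.coeffs, omega_grid))

    def pdc(self, omega_grid, squared: bool = True) -> np.ndarray:
        """Estimated PDC on an angular-frequency grid; (n_omega, S, S)."""
        return self.spectral_transform(omega_grid).pdc(squared=squared)

    def band_pdc(self, fs: float, k: int = 4, squared: bool = True) -> np.ndarray:
        """Band-averaged PDC on the 64-band grid: mean squared PDC over ``k``
        equally spaced intra-band frequencies; returns (64, S, S) in [0, 1]."""
        from . import bands

        if bands.F_HI >= fs / 2:
            raise ValueError(
                f"band grid upper edge {bands.F_HI} Hz is at or above Nyquist ({fs / 2} Hz)"
            )
        freqs = np.concatenate([bands.band_frequencies(b, k) for b in range(1, bands.N_BANDS + 1)])
        pdc = self.pdc(bands.hz_to_omega(freqs, fs), squared=squared)
        return pdc.reshape(bands.N_BANDS, k, self.n_channels, self.n_channels).mean(axis=1)

    def to_process(self, use_sigma: bool = True) -> MVARProcess:
        """Estimated parameters as an MVARProcess (e.g. for parametric bootstrap)."""
        sigma = self.sigma_u if use_sigma else None
        return MVARProcess(self.coeffs, sigma)

    def summary(self) -> str:
        lines = [
            "MVAR model results",
            "==================",
            f"channels:        {self.n_channels}",
            f"order (lags):    {self.order}",
            f"effective nobs:  {self.nobs}",
            f"BIC:             {self.bic:.4f}",
            f"spectral radius: {self.spectral_radius:.4f} "
            f"({'stable' if self.is_stable else 'UNSTABLE'})",
            f"max |coef|:      {np.abs(self.coeffs).max():.4f}",
            f"mean resid var:  {np.diag(self.sigma_u).mean():.4g}",
        ]
        return "\n".join(lines)
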