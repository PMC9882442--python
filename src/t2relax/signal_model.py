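"""Normalized mono-exponential signal model with Rician noise.

The decay of a multi-echo magnitude MRI measurement is modelled as

    S(eta) = S0 * exp(-eta / T),

where ``eta = TE / TE_max`` is the echo time normalized by the maximum echo
time of the acquisition, ``T = T2 / TE_max`` is the normalized relaxation
time constant, and ``S0`` is the (extrapolated) signal at ``eta = 0``.
Working on the normalized grid makes the estimation problem independent of
the particular echo spacing, and applies equally to other mono-exponential
processes (e.g. diffusion).

Magnitude images carry Rician rather than Gaussian noise: complex Gaussian
noise of standard deviation ``sigma`` per channel is added to the noiseless
signal and the magnitude is taken, so the measured signal plateaus at a
noise floor instead of decaying to zero at long echo times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingGrid",
    "DecayParameters",
    "NoiseSpec",
    "default_grid",
    "normalize_sampling",
    "decay_signal",
    "rician_corrupt",
    "snr_db",
    "SNR_DB_FLOOR",
]

#: Finite floor applied to -inf SNR values inside binning routines (dB).
SNR_DB_FLOOR = -40.0

_ETA_TOL = 1e-9


@dataclass(frozen=True)
class SamplingGrid:
    """Normalized sampling grid eta = TE / TE_max.

    Parameters
    ----------
    eta:
        Strictly increasing values in (0, 1]; the largest must equal 1.0.
    te_ms, te_max_ms:
        Optional original echo times and the normalization constant, in ms.
    """

    eta: np.ndarray
    te_ms: np.ndarray | None = None
    te_max_ms: float | None = None

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta, dtype=float)
        if eta.ndim != 1 or eta.size < 1:
            raise ValueError("eta must be a non-empty 1D vector")
        if np.any(eta <= 0):
            raise ValueError("eta values must be positive")
        if np.any(np.diff(eta) <= 0):
            raise ValueError("eta must be strictly increasing")
        if abs(eta[-1] - 1.0) > _ETA_TOL:
            raise ValueError(f"max(eta) must be 1.0, got {eta[-1]!r}")
        object.__setattr__(self, "eta", eta)

    @property
    def n(self) -> int:
        """Number N of eta values."""
        return int(self.eta.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SamplingGrid):
            return NotImplemented
        return self.eta.shape == other.eta.shape and np.allclose(
            self.eta, other.eta, atol=1e-8
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(tuple(np.round(self.eta, 8)))


@dataclass(frozen=True)
class DecayParameters:
    """Mono-exponential parameters (S0, T) with the derived rate R = 1/T."""

    s0: float
    t: float

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.t <= 0:
            raise ValueError("t must be positive")

    @property
    def r(self) -> float:
        """Decay rate R = 1/T, the parameter fitted in practice."""
        return 1.0 / self.t


@dataclass(frozen=True)
class NoiseSpec:
    """Standard deviation of each complex-Gaussian noise channel plus a seed."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def default_grid() -> SamplingGrid:
    """The 10-echo grid eta = k/11, k = 2..11 (i.e. 0.182, 0.272, ..., 1.0).

    This matches a TE = 13.2..145.2 ms multi-echo protocol after discarding
    the first echo.
    """
    return SamplingGrid(eta=np.arange(2, 12) / 11.0)


def normalize_sampling(te_ms, te_max_ms: float) -> SamplingGrid:
    """Normalize echo times by the maximum echo time.

    Parameters
    ----------
    te_ms:
        Strictly increasing, positive echo times in ms whose maximum equals
        ``te_max_ms``.
    te_max_ms:
        The normalization constant TE_max in ms.
    """
    te = np.asarray(te_ms, dtype=float)
    if te_max_ms <= 0:
        raise ValueError("te_max_ms must be positive")
    if te.ndim != 1 or te.size < 1:
        raise ValueError("te_ms must be a non-empty 1D vector")
    if np.any(te <= 0):
        raise ValueError("echo times must be positive")
    if te.size > 1 and np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    if abs(te[-1] - te_max_ms) > _ETA_TOL * te_max_ms:
        raise ValueError("max(te_ms) must equal te_max_ms")
    return SamplingGrid(eta=te / te_max_ms, te_ms=te, te_max_ms=float(te_max_ms))


def decay_signal(s0, t, grid: SamplingGrid | np.ndarray) -> np.ndarray:
    """Evaluate S(eta) = S0 exp(-eta/T) on a sampling grid.

    ``s0`` and ``t`` may be scalars or arrays of any matching shape; the
    result gains a trailing eta axis: shape ``s0.shape + (n,)``.
    """
    eta = grid.eta if isinstance(grid, SamplingGrid) else np.asarray(grid, float)
    s0 = np.asarray(s0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    if np.any(s0 < 0):
        raise ValueError("s0 must be non-negative")
    return s0[..., None] * np.exp(-eta / t[..., None])


def rician_corrupt(signal, noise: NoiseSpec | float, rng: np.random.Generator | None = None) -> np.ndarray:
    """Corrupt a noiseless signal with Rician noise.

    The signal is treated as the real channel of a complex measurement;
    i.i.d. Gaussian noise N(0, sigma^2) is added to the real and imaginary
    channels and the magnitude is taken:

        m = sqrt((s + n_r)^2 + n_i^2).

    Accepts a :class:`NoiseSpec` (whose seed is used when ``rng`` is not
    given) or a bare sigma with an explicit generator.
    """
    signal = np.asarray(signal, dtype=float)
    if isinstance(noise, NoiseSpec):
        sigma = noise.sigma
        if rng is None:
            rng = np.random.default_rng(noise.seed)
    else:
        sigma = float(noise)
        if rng is None:
            raise ValueError("an explicit rng is required when sigma is a bare float")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return signal.copy()
    n_r = rng.normal(0.0, sigma, size=signal.shape)
    n_i = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(signal + n_r, n_i)


def snr_db(signal, sigma: float, axis: int = -1):
    """Per-curve SNR in decibels: 20 log10(||S||_2 / (sigma sqrt(N))).

    The denominator sigma*sqrt(N) is the RMS L2-norm of the N-sample noise
    vector; an all-zero signal yields -inf.  ``axis`` selects the eta axis,
    so maps of decay curves produce SNR maps.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    signal = np.asarray(signal, dtype=float)
    norm = np.linalg.norm(signal, axis=axis)
    n = signal.shape[axis]
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(norm / (sigma * np.sqrt(n)))
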