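"""Core in-memory containers: image series and parameter maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import SamplingGrid

__all__ = ["ImageSeries", "ParameterMap"]


@dataclass
class ImageSeries:
    """An H x W x N_eta magnitude image series on a normalized sampling grid.

    Arrays are indexed ``[row, column, echo]``; echo index 0 is the shortest
    retained echo time.  ``normalization`` records the global maximum the
    data was divided by (1.0 if never normalized); ``provenance`` is a free
    text source path or synthesis-manifest reference.
    """

    data: np.ndarray
    grid: SamplingGrid
    normalization: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("series data must be H x W x N_eta")
        if data.shape[2] != self.grid.n:
            raise ValueError(
                f"series has {data.shape[2]} echoes but grid has {self.grid.n}"
            )
        if np.any(data < 0):
            raise ValueError("magnitude data must be non-negative")
        self.data = data

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def normalized(self) -> "ImageSeries":
        """Return a copy scaled so the maximum over all three dims is 1.0.

        Idempotent: re-normalizing an already normalized series is a no-op.
        """
        peak = float(self.data.max())
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero series")
        return ImageSeries(
            data=self.data / peak,
            grid=self.grid,
            normalization=self.normalization * peak,
            provenance=self.provenance,
        )


@dataclass
class ParameterMap:
    """Per-pixel (S0, T) estimates or ground truth.

    ``sigma`` optionally holds a per-pixel Rician noise-scale estimate;
    ``converged`` and ``at_bound`` are per-pixel flags from fitting; both are
    None for maps that did not come from an iterative fit.
    """

    s0: np.ndarray
    t: np.ndarray
    sigma: np.ndarray | None = None
    converged: np.ndarray | None = None
    at_bound: np.ndarray | None = None
    method: str = ""

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.s0.shape != self.t.shape:
            raise ValueError("s0 and t maps must share a shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s0.shape

    @property
    def rate(self) -> np.ndarray:
        """Decay-rate map R = 1/T."""
        return 1.0 / self.t
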