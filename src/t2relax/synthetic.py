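"""Physics-based synthetic relaxometry corpora with known ground truth.

Two styles of gold-standard (S0, T) maps are generated:

``naturalistic``
    Spatially correlated grayscale images — by default from a procedural
    generator combining a Gaussian-smoothed random field with randomly
    placed ellipses and rectangles; any directory of photographs can be
    plugged in instead via ``source_provider``.  Each image is min-max
    scaled onto its target parameter range, so estimators that exploit
    correlations between neighbouring pixels (convolutional networks) can
    benefit from the spatial structure.

``urand``
    Pixel-wise independent uniform draws over the same ranges.  Spatially
    adjacent pixels carry no mutual information, so any accuracy advantage
    a convolutional estimator shows on naturalistic data but not here can
    be attributed to learned spatial priors.

From a truth map pair, a noisy decay series is simulated with the forward
model and a single per-series Rician noise level sigma ~ U[0.001, 0.1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .series import ImageSeries
from .signal_model import SamplingGrid, decay_signal, default_grid, rician_corrupt

__all__ = [
    "GroundTruthMaps",
    "SyntheticSample",
    "DatasetManifest",
    "SyntheticDataset",
    "procedural_image",
    "generate_truth_maps",
    "synthesize_sample",
    "build_dataset",
    "load_dataset",
    "directory_image_provider",
]

T_RANGE_DEFAULT = (0.045, 4.0)
S0_RANGE_DEFAULT = (0.0, 1.0)
SIGMA_RANGE_DEFAULT = (0.001, 0.1)


@dataclass
class GroundTruthMaps:
    """Gold-standard S0 and T maps for one synthetic series."""

    s0_map: np.ndarray
    t_map: np.ndarray
    style: str = "urand"

    def __post_init__(self) -> None:
        self.s0_map = np.asarray(self.s0_map, dtype=float)
        self.t_map = np.asarray(self.t_map, dtype=float)
        if self.s0_map.shape != self.t_map.shape:
            raise ValueError("s0 and t maps must share a shape")
        if self.style not in ("naturalistic", "urand"):
            raise ValueError(f"unknown style {self.style!r}")
        if np.any(self.t_map <= 0):
            raise ValueError("t map must be strictly positive")
        if np.any(self.s0_map < 0):
            raise ValueError("s0 map must be non-negative")


@dataclass
class SyntheticSample:
    """One simulated image series together with its generating truth."""

    series: ImageSeries
    truth: GroundTruthMaps
    sigma: float
    seed: int | None = None


@dataclass
class DatasetManifest:
    """Recipe for a reproducible synthetic corpus."""

    n_series: int
    shape: tuple[int, int] = (128, 128)
    style: str = "naturalistic"
    t_range: tuple[float, float] = T_RANGE_DEFAULT
    s0_range: tuple[float, float] = S0_RANGE_DEFAULT
    sigma_range: tuple[float, float] = SIGMA_RANGE_DEFAULT
    master_seed: int = 0
    grid: SamplingGrid = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        if self.n_series < 1:
            raise ValueError("n_series must be >= 1")
        for lo, hi in (self.t_range, self.s0_range, self.sigma_range):
            if hi < lo:
                raise ValueError("ranges must be non-empty (lo <= hi)")

    def to_yaml(self, path: str | Path) -> Path:
        import yaml

        doc = {
            "n_series": self.n_series,
            "shape": list(self.shape),
            "style": self.style,
            "t_range": list(self.t_range),
            "s0_range": list(self.s0_range),
            "sigma_range": list(self.sigma_range),
            "master_seed": self.master_seed,
            "eta": [float(v) for v in self.grid.eta],
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetManifest":
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            n_series=int(doc["n_series"]),
            shape=tuple(doc["shape"]),
            style=doc["style"],
            t_range=tuple(doc["t_range"]),
            s0_range=tuple(doc["s0_range"]),
            sigma_range=tuple(doc["sigma_range"]),
            master_seed=int(doc["master_seed"]),
            grid=SamplingGrid(eta=np.asarray(doc["eta"], dtype=float)),
        )


def procedural_image(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated grayscale stand-in for a photographic image.

    The image is the sum of a Gaussian-smoothed random field (smoothing
    length ~H/16) and 5-20 randomly placed soft-edged ellipses and
    rectangles of random intensity, min-max rescaled to [0, 1].  The output
    has lag-1 spatial autocorrelation well above 0.5, mimicking the
    correlation structure of natural images.
    """
    h, w = shape
    if h < 8 or w < 8:
        raise ValueError("procedural images require shape >= 8 x 8")

    img = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=h / 16.0)
    std = img.std()
    if std > 0:
        img /= std

    shapes = np.zeros((h, w))
    rows, cols = np.ogrid[:h, :w]
    for _ in range(int(rng.integers(5, 21))):
        intensity = rng.uniform(-1.5, 1.5)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        if rng.random() < 0.5:  # ellipse
            ry = rng.uniform(h / 16, h / 3)
            rx = rng.uniform(w / 16, w / 3)
            mask = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
        else:  # rectangle
            hy = rng.uniform(h / 16, h / 3)
            hx = rng.uniform(w / 16, w / 3)
            mask = (np.abs(rows - cy) <= hy) & (np.abs(cols - cx) <= hx)
        shapes += intensity * mask
    # soften shape edges (anti-aliasing)
    shapes = ndimage.gaussian_filter(shapes, sigma=1.0)

    img = img + shapes
    lo, hi = img.min(), img.max()
    if hi == lo:  # pathologically flat draw
        return np.full(shape, 0.5)
    return (img - lo) / (hi - lo)


def _to_grayscale(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:  # unweighted channel mean
        image = image.mean(axis=2)
    if image.ndim != 2:
        raise ValueError("source images must be 2D grayscale or HxWxC color")
    return image


def center_crop(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Center-crop a 2D array to ``shape`` (floor convention for odd margins)."""
    h, w = image.shape[:2]
    ch, cw = shape
    if h < ch or w < cw:
        raise ValueError(f"image {image.shape} smaller than crop size {shape}")
    r0 = (h - ch) // 2
    c0 = (w - cw) // 2
    return image[r0 : r0 + ch, c0 : c0 + cw]


def _scale_to_range(image: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mn, mx = image.min(), image.max()
    if mx == mn:
        warnings.warn(
            "degenerate (constant) source image: mapping to range midpoint",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.full(image.shape, 0.5 * (lo + hi))
    return lo + (image - mn) * (hi - lo) / (mx - mn)


def directory_image_provider(path: str | Path):
    """Image supplier reading PNG/JPEG files from a directory.

    Returns a callable ``provider(rng) -> 2D float array``; files are chosen
    uniformly at random with the supplied generator.
    """
    from skimage import io as skio

    paths = sorted(
        p for p in Path(path).iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not paths:
        raise ValueError(f"no PNG/JPEG images found in {path}")

    def provider(rng: np.random.Generator) -> np.ndarray:
        p = paths[int(rng.integers(len(paths)))]
        return _to_grayscale(skio.imread(p))

    return provider


def generate_truth_maps(
    style: str,
    shape: tuple[int, int],
    rng: np.random.Generator,
    t_range: tuple[float, float] = T_RANGE_DEFAULT,
    s0_range: tuple[float, float] = S0_RANGE_DEFAULT,
    source_provider=None,
) -> GroundTruthMaps:
    """Draw an independent (S0, T) gold-standard map pair.

    naturalistic: two independent source images (from ``source_provider`` or
    the procedural generator), grayscale, center-cropped to ``shape`` and
    min-max scaled onto their target ranges.  urand: i.i.d. uniform pixels.
    """
    if style == "urand":
        s0 = rng.uniform(*s0_range, size=shape)
        t = rng.uniform(*t_range, size=shape)
    elif style == "naturalistic":
        maps = []
        for lo, hi in (s0_range, t_range):
            if source_provider is not None:
                img = center_crop(_to_grayscale(source_provider(rng)), shape)
            else:
                img = procedural_image(shape, rng)
            maps.append(_scale_to_range(img, lo, hi))
        s0, t = maps
    else:
        raise ValueError(f"unknown style {style!r}")
    # guard against t touching 0 when a custom range starts at 0
    t = np.maximum(t, np.finfo(float).tiny)
    return GroundTruthMaps(s0_map=s0, t_map=t, style=style)


def synthesize_sample(
    truth: GroundTruthMaps,
    grid: SamplingGrid,
    rng: np.random.Generator,
    sigma_range: tuple[float, float] = SIGMA_RANGE_DEFAULT,
    seed: int | None = None,
) -> SyntheticSample:
    """Forward-model a truth map pair into a noisy magnitude series.

    A single sigma, uniform over ``sigma_range``, corrupts the whole series
    (one noise level per simulated acquisition).
    """
    sigma = float(rng.uniform(*sigma_range))
    clean = decay_signal(truth.s0_map, truth.t_map, grid)
    noisy = rician_corrupt(clean, sigma, rng) if sigma > 0 else clean
    series = ImageSeries(data=noisy, grid=grid, provenance=f"synthetic:{truth.style}")
    return SyntheticSample(series=series, truth=truth, sigma=sigma, seed=seed)


@dataclass
class SyntheticDataset:
    """In-memory synthetic corpus (arrays stacked over series)."""

    images: np.ndarray  # (n, H, W, N_eta)
    s0: np.ndarray  # (n, H, W)
    t: np.ndarray  # (n, H, W)
    sigma: np.ndarray  # (n,)
    grid: SamplingGrid
    style: str = "urand"
    master_seed: int | None = None

    def __len__(self) -> int:
        return self.images.shape[0]

    def sample(self, i: int) -> SyntheticSample:
        truth = GroundTruthMaps(self.s0[i], self.t[i], style=self.style)
        series = ImageSeries(self.images[i], self.grid, provenance=f"dataset[{i}]")
        return SyntheticSample(series=series, truth=truth, sigma=float(self.sigma[i]))


def generate_dataset(
    manifest: DatasetManifest, source_provider=None
) -> SyntheticDataset:
    """Generate ``manifest.n_series`` samples with unique truth and noise.

    Per-series RNG streams are spawned from the master seed, so the corpus
    is reproducible and each series independent.
    """
    n = manifest.n_series
    h, w = manifest.shape
    n_eta = manifest.grid.n
    images = np.empty((n, h, w, n_eta), dtype=np.float32)
    s0 = np.empty((n, h, w), dtype=np.float32)
    t = np.empty((n, h, w), dtype=np.float32)
    sigma = np.empty(n, dtype=np.float32)
    streams = np.random.SeedSequence(manifest.master_seed).spawn(n)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        truth = generate_truth_maps(
            manifest.style,
            manifest.shape,
            rng,
            t_range=manifest.t_range,
            s0_range=manifest.s0_range,
            source_provider=source_provider,
        )
        sample = synthesize_sample(
            truth, manifest.grid, rng, sigma_range=manifest.sigma_range
        )
        images[i] = sample.series.data
        s0[i] = truth.s0_map
        t[i] = truth.t_map
        sigma[i] = sample.sigma
    return SyntheticDataset(
        images=images,
        s0=s0,
        t=t,
        sigma=sigma,
        grid=manifest.grid,
        style=manifest.style,
        master_seed=manifest.master_seed,
    )


def build_dataset(
    manifest: DatasetManifest, out_path: str | Path, source_provider=None
) -> Path:
    """Generate a corpus and archive it as HDF5 (32-bit floats).

    Layout: datasets ``images[n,H,W,Neta]``, ``s0[n,H,W]``, ``t[n,H,W]``,
    ``sigma[n]``, ``eta[Neta]`` plus manifest attributes.  Object timestamps
    are disabled so identical manifests produce byte-identical archives.
    """
    import h5py

    ds = generate_dataset(manifest, source_provider=source_provider)
    out_path = Path(out_path)
    try:
        with h5py.File(out_path, "w") as f:
            for name, arr in (
                ("images", ds.images),
                ("s0", ds.s0),
                ("t", ds.t),
                ("sigma", ds.sigma),
                ("eta", manifest.grid.eta.astype(np.float32)),
            ):
                f.create_dataset(name, data=arr, track_times=False)
            f.attrs["n_series"] = manifest.n_series
            f.attrs["style"] = manifest.style
            f.attrs["t_range"] = manifest.t_range
            f.attrs["s0_range"] = manifest.s0_range
            f.attrs["sigma_range"] = manifest.sigma_range
            f.attrs["master_seed"] = manifest.master_seed
    except OSError as exc:
        raise OSError(f"failed writing dataset archive {out_path}: {exc}") from exc
    return out_path


def load_dataset(path: str | Path) -> SyntheticDataset:
    """Load an HDF5 corpus written by :func:`build_dataset`."""
    import h5py

    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            grid = SamplingGrid(eta=np.asarray(f["eta"], dtype=float))
            return SyntheticDataset(
                images=np.asarray(f["images"]),
                s0=np.asarray(f["s0"]),
                t=np.asarray(f["t"]),
                sigma=np.asarray(f["sigma"]),
                grid=grid,
                style=str(f.attrs.get("style", "urand")),
                master_seed=int(f.attrs.get("master_seed", -1)),
            )
    except OSError as exc:
        raise OSError(f"failed reading dataset archive {path}: {exc}") from exc
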