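"""Real-data ingestion and on-disk export of parameter maps.

Multi-echo magnitude acquisitions arrive either as a directory of DICOM
files or as a 4D NIfTI volume (X, Y, Z, echo).  Each axial slice is
treated as an independent image series.  Preprocessing mirrors common
multi-echo spin-echo practice: the first echo is discarded (stimulated
echo contamination), images are spatially center-cropped to 128x128, and
each series is normalized so its maximum over all three dimensions is
1.0.  The eta grid is computed from the original echo times (TE_max is
unaffected by discarding the first echo), so a TE = 13.2..145.2 ms
protocol yields eta starting at 0.182.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .series import ImageSeries, ParameterMap
from .signal_model import SamplingGrid, normalize_sampling
from .synthetic import center_crop

__all__ = ["ingest_invivo", "write_parameter_map_nifti", "read_parameter_map_nifti"]

_CROP_DEFAULT = 128


def _load_nifti_echoes(path: Path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI (X, Y, Z, echo); got shape {data.shape}")
    return data


def _load_dicom_series(path: Path):
    """Group DICOM files by slice position; sort echoes by EchoTime."""
    import pydicom

    frames: dict[tuple, list] = {}
    for f in sorted(path.iterdir()):
        if f.is_dir():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        pos = tuple(float(v) for v in getattr(ds, "ImagePositionPatient", (0, 0, 0)))
        frames.setdefault(pos, []).append(ds)
    if not frames:
        raise ValueError(f"no readable DICOM files in {path}")
    slices = []
    te_ref = None
    for pos in sorted(frames):
        dsets = sorted(frames[pos], key=lambda d: float(d.EchoTime))
        te = np.array([float(d.EchoTime) for d in dsets])
        if te_ref is None:
            te_ref = te
        elif te.shape != te_ref.shape or not np.allclose(te, te_ref):
            raise ValueError("inconsistent echo times across slices")
        stack = np.stack(
            [d.pixel_array.astype(float) * float(getattr(d, "RescaleSlope", 1.0)) for d in dsets],
            axis=-1,
        )
        slices.append(stack)
    return slices, te_ref


def ingest_invivo(
    path: str | Path,
    te_ms=None,
    discard_first_echo: bool = True,
    crop: int | None = _CROP_DEFAULT,
) -> list[ImageSeries]:
    """Read a DICOM series directory or 4D NIfTI into per-slice series.

    ``te_ms`` (full echo-time vector, ms) must be supplied for NIfTI input
    and overrides DICOM metadata when given.  Inputs smaller than the crop
    size are rejected; pass ``crop=None`` to skip cropping.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"input path does not exist: {path}")
    if path.is_dir():
        slices, te_meta = _load_dicom_series(path)
        te = np.asarray(te_ms, float) if te_ms is not None else te_meta
    else:
        data = _load_nifti_echoes(path)
        slices = [data[:, :, z, :] for z in range(data.shape[2])]
        if te_ms is None:
            raise ValueError(
                "echo times are not recoverable from NIfTI; pass te_ms explicitly"
            )
        te = np.asarray(te_ms, float)

    if te is None or len(te) != slices[0].shape[-1]:
        raise ValueError("echo-time vector length must match the echo dimension")
    grid_full = normalize_sampling(te, float(te.max()))
    eta = grid_full.eta
    first = 1 if discard_first_echo else 0
    if eta.size - first < 2:
        raise ValueError("fewer than 2 echoes would remain after discarding")
    grid = SamplingGrid(
        eta=eta[first:], te_ms=te[first:], te_max_ms=grid_full.te_max_ms
    )

    out = []
    for z, stack in enumerate(slices):
        stack = stack[..., first:]
        if crop is not None:
            stack = center_crop(stack, (crop, crop))
        series = ImageSeries(
            data=np.maximum(stack, 0.0),
            grid=grid,
            provenance=f"{path}[slice={z}]",
        ).normalized()
        out.append(series)
    return out


def write_parameter_map_nifti(pmap: ParameterMap, prefix: str | Path) -> list[Path]:
    """Write one NIfTI volume per parameter: <prefix>_s0.nii.gz, _t.nii.gz."""
    import nibabel as nib

    prefix = Path(prefix)
    written = []
    for name, arr in (("s0", pmap.s0), ("t", pmap.t)):
        p = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), np.eye(4)), str(p))
        written.append(p)
    return written


def read_parameter_map_nifti(prefix: str | Path, method: str = "") -> ParameterMap:
    """Read maps written by :func:`write_parameter_map_nifti`."""
    import nibabel as nib

    prefix = Path(prefix)
    arrays = {}
    for name in ("s0", "t"):
        p = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        arrays[name] = np.asarray(nib.load(str(p)).dataobj, dtype=float)
    return ParameterMap(s0=arrays["s0"], t=arrays["t"], method=method)
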