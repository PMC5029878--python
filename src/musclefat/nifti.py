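"""NIfTI-1 reading and writing for images, masks and complex echo series.

Arrays in memory are ``(n_slices, ny, nx)`` (or 2D in-plane); on disk they
are stored in the conventional ``(x, y, z)`` voxel order with an affine
built from the pixel size and the slice-centre spacing.  Complex echoes use
a two-volume dialect -- one real-part and one imaginary-part file per echo,
``<prefix><k>_real.nii.gz`` / ``<prefix><k>_imag.nii.gz`` -- documented in
each header's ``descrip`` field for maximal reader compatibility.
"""

from __future__ import annotations

import re
from pathlib import Path

import nibabel as nib
import numpy as np

from .dixon import EchoSeries

__all__ = [
    "write_image",
    "read_image",
    "write_labels",
    "read_labels",
    "write_echoes",
    "read_echoes",
]


def _affine(pixel_size: tuple[float, float], slice_spacing: float) -> np.ndarray:
    return np.diag([pixel_size[1], pixel_size[0], slice_spacing, 1.0])


def _to_disk_order(data: np.ndarray) -> np.ndarray:
    """(n_slices, ny, nx) -> (nx, ny, n_slices); 2D input gets one slice."""
    if data.ndim == 2:
        data = data[None]
    return np.transpose(data, (2, 1, 0))


def _from_disk_order(data: np.ndarray) -> np.ndarray:
    return np.transpose(data, (2, 1, 0))


def write_image(
    data: np.ndarray,
    path: str | Path,
    pixel_size: tuple[float, float] = (0.56, 0.56),
    slice_spacing: float = 18.0,
    descrip: str = "",
    dtype=np.float64,
) -> Path:
    """Write one scalar volume; returns the path."""
    path = Path(path)
    img = nib.Nifti1Image(
        _to_disk_order(np.asarray(data)).astype(dtype),
        _affine(pixel_size, slice_spacing),
    )
    img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, path)
    return path


def read_image(path: str | Path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Read one scalar volume -> (array (n_slices, ny, nx), pixel_size, spacing)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    data = _from_disk_order(np.asarray(img.dataobj))
    return data, (float(zooms[1]), float(zooms[0])), float(zooms[2])


def write_labels(labels: np.ndarray, path: str | Path, **kw) -> Path:
    return write_image(labels, path, dtype=np.int16,
                       descrip=kw.pop("descrip", "muscle-group labels 1..10"), **kw)


def read_labels(path: str | Path) -> tuple[np.ndarray, tuple[float, float], float]:
    data, px, sp = read_image(path)
    return data.astype(np.int16), px, sp


def write_echoes(echoes: EchoSeries, outdir: str | Path, prefix: str = "echo",
                 slice_spacing: float = 18.0) -> list[Path]:
    """Write the three complex echoes as real/imag volume pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, s in enumerate((echoes.S1, echoes.S2, echoes.S3), start=1):
        te = echoes.echo_times[k - 1]
        for part, arr in (("real", s.real), ("imag", s.imag)):
            p = outdir / f"{prefix}{k}_{part}.nii.gz"
            write_image(
                arr, p, pixel_size=echoes.pixel_size, slice_spacing=slice_spacing,
                descrip=f"complex dialect: {part} part, echo {k}, TE={te}ms",
            )
            paths.append(p)
    return paths


_TE_RE = re.compile(r"TE=([0-9.]+)ms")


def read_echoes(outdir: str | Path, prefix: str = "echo") -> EchoSeries:
    """Read a real/imag echo-pair directory back into an EchoSeries."""
    outdir = Path(outdir)
    echoes = []
    times = []
    pixel_size = None
    for k in (1, 2, 3):
        re_p = outdir / f"{prefix}{k}_real.nii.gz"
        im_p = outdir / f"{prefix}{k}_imag.nii.gz"
        if not re_p.exists() or not im_p.exists():
            raise FileNotFoundError(f"missing echo {k} real/imag pair under {outdir}")
        rdata, px, _ = read_image(re_p)
        idata, _, _ = read_image(im_p)
        pixel_size = px
        echoes.append(rdata + 1j * idata)
        descrip = nib.load(str(re_p)).header["descrip"].item().decode()
        m = _TE_RE.search(descrip)
        if not m:
            raise ValueError(f"no echo time recorded in header of {re_p}")
        times.append(float(m.group(1)))
    return EchoSeries(
        S1=echoes[0], S2=echoes[1], S3=echoes[2],
        echo_times=tuple(times), pixel_size=pixel_size,
    )
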