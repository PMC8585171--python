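"""Reading and writing image volumes, curves and FE fields.

Supported volume inputs: a DICOM series directory (slices sorted by
position, rescale slope/intercept applied), a multi-page TIFF stack
(spacing must be supplied — TIFF carries no reliable 3-D metadata), or
a NIfTI file (spacing from the header).  Voxel spacing must be isotropic.
FE fields are written as legacy-ASCII VTK unstructured grids readable by
ParaView.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional

import numpy as np

from .volume import ImageVolume

__all__ = ["read_volume", "write_volume", "write_vtk"]

_ISO_RTOL = 1e-3


def _check_isotropic(zooms, path) -> float:
    zooms = np.asarray(zooms, dtype=float)
    if np.any(~np.isfinite(zooms)) or np.any(zooms <= 0):
        raise ValueError(f"{path}: invalid voxel spacing {zooms}")
    if np.ptp(zooms) > _ISO_RTOL * zooms.mean():
        raise ValueError(
            f"{path}: anisotropic spacing {tuple(zooms)} — resample to "
            "isotropic voxels before analysis")
    return float(zooms.mean())


def _read_nifti(path: Path) -> ImageVolume:
    import nibabel as nib
    img = nib.load(str(path))
    spacing = _check_isotropic(img.header.get_zooms()[:3], path)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    # store as (z, y, x); NIfTI is (x, y, z)
    return ImageVolume(np.transpose(data, (2, 1, 0)), spacing,
                       {"source": str(path), "format": "nifti"})


def _read_tiff(path: Path, spacing: Optional[float]) -> ImageVolume:
    import tifffile
    if spacing is None:
        raise ValueError(
            f"{path}: TIFF stacks carry no voxel-size metadata; pass "
            "spacing explicitly (config key 'spacing')")
    data = tifffile.imread(str(path)).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D TIFF stack")
    return ImageVolume(data, float(spacing),
                       {"source": str(path), "format": "tiff"})


def _read_dicom_dir(path: Path) -> ImageVolume:
    import pydicom
    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"{path}: no readable DICOM slices")
    def zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))
    slices.sort(key=zpos)
    arrs = []
    for ds in slices:
        a = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        arrs.append(a * slope + inter)
    vol = np.stack(arrs, axis=0)
    ds0 = slices[0]
    ps = getattr(ds0, "PixelSpacing", None)
    if ps is None:
        raise ValueError(f"{path}: DICOM series lacks PixelSpacing")
    if len(slices) > 1:
        dz = abs(zpos(slices[1]) - zpos(slices[0]))
    else:
        dz = float(getattr(ds0, "SliceThickness", ps[0]))
    spacing = _check_isotropic([dz, float(ps[0]), float(ps[1])], path)
    return ImageVolume(vol, spacing, {"source": str(path), "format": "dicom"})


def read_volume(path, spacing: Optional[float] = None) -> ImageVolume:
    """Load a 3-D HU volume as (z, y, x) with isotropic spacing in mm."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if suffixes.endswith((".tif", ".tiff")):
        return _read_tiff(path, spacing)
    raise ValueError(f"unrecognized volume format: {path}")


def write_volume(volume: ImageVolume, path) -> None:
    """Write NIfTI (.nii/.nii.gz, spacing in the header) or TIFF stack."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        affine = np.diag([volume.spacing] * 3 + [1.0])
        data = np.transpose(volume.voxels, (2, 1, 0))
        nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
    elif name.endswith((".tif", ".tiff")):
        import tifffile
        tifffile.imwrite(str(path), volume.voxels.astype(np.float32))
    else:
        raise ValueError(f"unrecognized output format: {path}")


def write_vtk(solution, path) -> None:
    """Dump an FE solution as a legacy-ASCII VTK unstructured grid:
    nodal displacements as point data, von Mises and the Voigt stress
    tensor as cell data."""
    mesh = solution.mesh
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("trabmech micro-FE solution\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        np.savetxt(fh, mesh.nodes, fmt="%.6g")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {ne * 9}\n")
        cells = np.column_stack([np.full(ne, 8), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {ne}\n")
        np.savetxt(fh, np.full(ne, 12), fmt="%d")  # VTK_HEXAHEDRON
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write("VECTORS displacement float\n")
        np.savetxt(fh, solution.displacements, fmt="%.6g")
        fh.write(f"CELL_DATA {ne}\n")
        fh.write("SCALARS von_mises float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, solution.mises, fmt="%.6g")
        fh.write("FIELD stress 1\nstress_voigt 6 "
                 f"{ne} float\n")
        np.savetxt(fh, solution.stress, fmt="%.6g")
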