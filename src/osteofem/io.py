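"""File I/O: volumes (TIFF/NIfTI + JSON sidecar), curves (CSV), fields (VTK).

The VTK writer emits legacy ASCII unstructured-grid files (hexahedron cell
type 12) with nodal displacement and HMH/stress cell data, readable by
ParaView and VTK-based tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .curves import ForceCurve
from .densitometry import CTVolume
from .fem import FEMesh, FEResult


def save_volume(volume: CTVolume, path: str | Path, sidecar: dict | None = None) -> None:
    """Write a volume as a TIFF stack (.tif) or NIfTI (.nii/.nii.gz), with a
    JSON sidecar carrying voxel size and any extra metadata."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, volume.voxels.astype(np.float32))
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        vs_mm = volume.voxel_size_mm
        img = nib.Nifti1Image(volume.voxels.astype(np.float32),
                              affine=np.diag([vs_mm, vs_mm, vs_mm, 1.0]))
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    meta = {"voxel_size_um": volume.voxel_size}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_volume(path: str | Path) -> CTVolume:
    path = Path(path)
    sidecar = path.with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if path.suffix in (".tif", ".tiff"):
        voxels = np.asarray(tifffile.imread(path))
        voxel_size = meta.get("voxel_size_um", 17.5)
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        voxels = np.asarray(img.dataobj)
        voxel_size = meta.get("voxel_size_um", float(img.header.get_zooms()[0]) * 1000)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return CTVolume(voxels=voxels, voxel_size=voxel_size)


def save_curves(curves: list[ForceCurve], path: str | Path) -> None:
    """Write replicate curves as CSV: displacement_mm, force_N, replicate."""
    frames = [pd.DataFrame({"displacement_mm": c.displacement,
                            "force_N": c.force,
                            "replicate": c.replicate_id}) for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_curves(path: str | Path) -> list[ForceCurve]:
    df = pd.read_csv(path)
    out = []
    for rep, g in df.groupby("replicate", sort=True):
        out.append(ForceCurve(displacement=g["displacement_mm"].to_numpy(),
                              force=g["force_N"].to_numpy(),
                              replicate_id=int(rep)))
    return out


def write_vtk(mesh: FEMesh, path: str | Path, result: FEResult | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with optional solution fields."""
    lines = ["# vtk DataFile Version 3.0", "osteofem fields", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double"]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in mesh.nodes]
    ne = len(mesh.elements)
    lines.append(f"CELLS {ne} {9 * ne}")
    lines += ["8 " + " ".join(map(str, e)) for e in mesh.elements]
    lines.append(f"CELL_TYPES {ne}")
    lines += ["12"] * ne
    if result is not None:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("VECTORS displacement double")
        lines += [" ".join(f"{v:.9g}" for v in u) for u in result.displacement]
        lines.append("SCALARS hmh_nodal double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in result.nodal_hmh]
        lines.append(f"CELL_DATA {ne}")
        lines.append("SCALARS hmh double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in result.hmh]
        lines.append("TENSORS stress double")
        for s in result.element_stress:  # Voigt (xx,yy,zz,yz,xz,xy) -> full
            lines.append(f"{s[0]:.9g} {s[5]:.9g} {s[4]:.9g}")
            lines.append(f"{s[5]:.9g} {s[1]:.9g} {s[3]:.9g}")
            lines.append(f"{s[4]:.9g} {s[3]:.9g} {s[2]:.9g}")
            lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")
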