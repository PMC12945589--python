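"""NIfTI / gradient-table / TSV round-trip I/O and provenance records.

Conventions: scalar maps are 3-D NIfTI-1; strain tensors are 4-D with six
components in lower-triangular order (xx, xy, yy, xz, yz, zz), announced in
the header ``descrip`` field; DWI is 4-D with FSL-style ``.bval``/``.bvec``
sidecars; masks are 0/1 volumes; tables are TSV with fixed column names.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .dwi import DWIDataset
from .grid import ScalarMap, StrainTensorField, TENSOR_COMPONENT_ORDER, VoxelGrid

__all__ = [
    "save_scalar_map",
    "load_scalar_map",
    "save_tensor_field",
    "load_tensor_field",
    "save_mask",
    "load_mask",
    "save_dwi",
    "load_dwi",
    "save_response",
    "load_response",
    "save_table",
    "load_table",
    "ProvenanceRecord",
    "config_hash",
]

_TENSOR_DESCRIP = b"symtensor:" + ",".join(TENSOR_COMPONENT_ORDER).encode()


def _grid_of(img: nib.Nifti1Image) -> VoxelGrid:
    zooms = img.header.get_zooms()[:3]
    return VoxelGrid(shape=img.shape[:3], voxel_size=zooms, affine=img.affine)


def save_scalar_map(smap: ScalarMap, path) -> None:
    img = nib.Nifti1Image(smap.values.astype(np.float32), smap.grid.affine)
    img.header["descrip"] = f"kind:{smap.kind}".encode()[:79]
    nib.save(img, str(path))


def load_scalar_map(path, mask: np.ndarray | None = None, kind: str | None = None
                    ) -> ScalarMap:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D scalar volume, got {img.ndim}-D")
    grid = _grid_of(img)
    data = np.asarray(img.dataobj, dtype=float)
    if kind is None:
        descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
        kind = descrip.removeprefix("kind:") if descrip.startswith("kind:") else "scalar"
    if mask is None:
        mask = np.isfinite(data)
    return ScalarMap(grid=grid, values=np.nan_to_num(data), mask=mask, kind=kind)


def save_tensor_field(tfield: StrainTensorField, path) -> None:
    img = nib.Nifti1Image(tfield.components.astype(np.float32), tfield.grid.affine)
    img.header["descrip"] = _TENSOR_DESCRIP[:79]
    nib.save(img, str(path))


def load_tensor_field(tfield_path, mask: np.ndarray) -> StrainTensorField:
    img = nib.load(str(tfield_path))
    if img.ndim != 4 or img.shape[3] != 6:
        raise ValueError(
            f"{tfield_path}: expected 4-D volume with 6 tensor components in "
            f"lower-triangular order {TENSOR_COMPONENT_ORDER}, got shape {img.shape}"
        )
    grid = _grid_of(img)
    return StrainTensorField(grid=grid, components=np.asarray(img.dataobj, dtype=float),
                             mask=mask)


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_mask(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask volume")
    return np.asarray(img.dataobj) > 0, _grid_of(img)


def save_dwi(dwi: DWIDataset, prefix) -> None:
    """Write <prefix>.nii.gz plus FSL-style <prefix>.bval / <prefix>.bvec."""
    prefix = Path(prefix)
    nib.save(nib.Nifti1Image(dwi.signals.astype(np.float32), dwi.grid.affine),
             str(prefix) + ".nii.gz")
    np.savetxt(str(prefix) + ".bval", dwi.bvals[None, :], fmt="%.1f")
    np.savetxt(str(prefix) + ".bvec", dwi.bvecs.T, fmt="%.8f")


def load_dwi(prefix, mask: np.ndarray | None = None) -> DWIDataset:
    prefix = Path(prefix)
    img = nib.load(str(prefix) + ".nii.gz")
    if img.ndim != 4:
        raise ValueError(f"{prefix}: expected 4-D DWI volume")
    bvals = np.loadtxt(str(prefix) + ".bval").ravel()
    bvecs = np.loadtxt(str(prefix) + ".bvec")
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    grid = _grid_of(img)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    return DWIDataset(grid=grid, signals=np.asarray(img.dataobj, dtype=float),
                      bvals=bvals, bvecs=bvecs, mask=mask)


def save_response(response, path) -> None:
    """Response as a small text file: one 'l coefficient' pair per line."""
    with open(path, "w") as fh:
        fh.write("# single-fiber response, m=0 even-order SH coefficients\n")
        fh.write(f"# calibration_n={response.calibration_n} "
                 f"fa_threshold={response.fa_threshold}\n")
        for j, l in enumerate(range(0, response.lmax + 1, 2)):
            fh.write(f"{l} {response.sh_coeffs[j]:.10e}\n")


def load_response(path):
    from .csd import ResponseFunction

    meta = {"calibration_n": 0, "fa_threshold": np.nan}
    ls, coeffs = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            for token in line.lstrip("# ").split():
                if "=" in token:
                    k, v = token.split("=")
                    if k in meta:
                        meta[k] = float(v)
            continue
        l, c = line.split()
        ls.append(int(l))
        coeffs.append(float(c))
    return ResponseFunction(sh_coeffs=np.asarray(coeffs), lmax=max(ls),
                            calibration_n=int(meta["calibration_n"]),
                            fa_threshold=meta["fa_threshold"])


def save_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping (key order independent)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ProvenanceRecord:
    """Reproducibility sidecar written next to every pipeline output."""

    tool_version: str = __version__
    config_hash: str = ""
    input_hashes: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    timestamp: str = ""
    stage_parameters: dict = field(default_factory=dict)

    @classmethod
    def create(cls, config: dict, seeds: dict, stage_parameters: dict,
               input_files: list | None = None) -> "ProvenanceRecord":
        hashes = {}
        for f in input_files or []:
            p = Path(f)
            if p.exists():
                hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        return cls(
            config_hash=config_hash(config),
            input_hashes=hashes,
            seeds=seeds,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
            stage_parameters=stage_parameters,
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))
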