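"""Volume and ensemble I/O: NIfTI signal volumes, HDF5 ensembles, manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .components import DiscreteDistribution
from .inversion import SolutionEnsemble

__all__ = ["read_signal_volume", "write_signal_volume", "write_maps",
           "write_ensembles", "read_ensembles", "write_manifest"]

_FIELDS = ("weights", "r2", "d_par", "d_perp", "theta", "phi")


def read_signal_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4D NIfTI as (data, affine) with axes (x, y, z, measurement)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume "
                         f"(x, y, z, measurement); got {data.ndim}D")
    return data, img.affine


def write_signal_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             str(path))


def write_maps(maps: dict[str, np.ndarray], affine: np.ndarray,
               out_dir) -> None:
    """One float32 NIfTI per named statistic map, plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = {}
    for name, vol in maps.items():
        fname = f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine),
                 str(out_dir / fname))
        index[name] = fname
    (out_dir / "maps.json").write_text(json.dumps(index, indent=1))


def write_ensembles(ensembles: list[SolutionEnsemble], path) -> None:
    """Store per-voxel ensembles in one HDF5 container.

    Layout: one long table per field with (voxel, member) index columns, so
    files stay compact for sparse solutions.
    """
    rows = {f: [] for f in _FIELDS}
    vox_idx, mem_idx = [], []
    ssr = np.empty((len(ensembles),
                    len(ensembles[0]) if ensembles else 0))
    repaired = np.zeros(len(ensembles), dtype=bool)
    for v, ens in enumerate(ensembles):
        ssr[v] = ens.residual_ssr
        repaired[v] = ens.repaired
        for m, sol in enumerate(ens.solutions):
            k = len(sol)
            vox_idx.extend([v] * k)
            mem_idx.extend([m] * k)
            for f in _FIELDS:
                rows[f].extend(getattr(sol, f))
    with h5py.File(path, "w") as h5:
        h5.create_dataset("voxel", data=np.array(vox_idx, dtype=np.int64))
        h5.create_dataset("member", data=np.array(mem_idx, dtype=np.int64))
        for f in _FIELDS:
            h5.create_dataset(f, data=np.array(rows[f], dtype=float))
        h5.create_dataset("residual_ssr", data=ssr)
        h5.create_dataset("repaired", data=repaired)


def read_ensembles(path) -> list[SolutionEnsemble]:
    with h5py.File(path, "r") as h5:
        vox = h5["voxel"][...]
        mem = h5["member"][...]
        cols = {f: h5[f][...] for f in _FIELDS}
        ssr = h5["residual_ssr"][...]
        repaired = h5["repaired"][...]
    ensembles = []
    for v in range(ssr.shape[0]):
        sols = []
        for m in range(ssr.shape[1]):
            sel = (vox == v) & (mem == m)
            sols.append(DiscreteDistribution(
                cols["r2"][sel], cols["d_par"][sel], cols["d_perp"][sel],
                cols["theta"][sel], cols["phi"][sel], cols["weights"][sel]))
        ensembles.append(SolutionEnsemble(sols, ssr[v],
                                          repaired=bool(repaired[v])))
    return ensembles


def write_manifest(out_dir, seed, config: dict) -> Path:
    """Record run provenance: package version, seed, config hash."""
    from . import __version__
    payload = {
        "rd5d_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(payload, indent=1, default=str))
    return out
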