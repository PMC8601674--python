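"""File interchange: NIfTI images, k-space containers, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import RadialKSpace, RadialTrajectory

__all__ = ["save_nifti", "load_nifti", "save_kspace", "load_kspace"]


def save_nifti(path, image: np.ndarray, pixel_size_mm: float, meta: dict | None = None):
    """Write a 2D map as NIfTI; generation parameters go to a JSON sidecar."""
    affine = np.diag([pixel_size_mm, pixel_size_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), affine), str(path))
    if meta is not None:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))


def load_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(abs(img.affine[0, 0]))


def save_kspace(path, kspace: RadialKSpace) -> None:
    """Serialize radial k-space to an .npz container with a JSON header."""
    t = kspace.trajectory
    header = {
        "n_spokes": t.n_spokes,
        "samples_per_spoke": t.samples_per_spoke,
        "k_max": t.k_max,
        "echo_index": t.echo_index,
        "echo_times_ms": list(kspace.echo_times_ms),
        "fov_mm": kspace.fov_mm,
        "noise_sigma": kspace.noise_sigma,
        "seed": kspace.seed,
        "provenance": kspace.provenance,
    }
    np.savez_compressed(
        path,
        data=kspace.data,
        angles_rad=t.angles_rad,
        spoke_times_s=t.spoke_times_s,
        header=json.dumps(header, default=str),
    )


def load_kspace(path) -> RadialKSpace:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        traj = RadialTrajectory(
            n_spokes=header["n_spokes"],
            samples_per_spoke=header["samples_per_spoke"],
            angles_rad=z["angles_rad"],
            k_max=header["k_max"],
            spoke_times_s=z["spoke_times_s"],
            echo_index=header.get("echo_index", 0),
        )
        return RadialKSpace(
            data=z["data"],
            trajectory=traj,
            echo_times_ms=tuple(header["echo_times_ms"]),
            fov_mm=header["fov_mm"],
            noise_sigma=header["noise_sigma"],
            seed=header["seed"],
            provenance=header.get("provenance", {}),
        )
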