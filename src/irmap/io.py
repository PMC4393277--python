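"""HDF5 acquisition container, NIfTI map export and CSV ROI tables."""

from __future__ import annotations

import csv
import hashlib
import json
import platform
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .coils import PhaseMaps
from .dictfit import ParameterMaps
from .pipeline import ROIStats
from .radial import RadialAcquisition, RadialTrajectory
from .relaxometry import SequenceParams

__all__ = [
    "save_acquisition",
    "load_acquisition",
    "save_parameter_maps_nifti",
    "save_parameter_maps_h5",
    "load_parameter_maps_h5",
    "load_map_nifti",
    "save_label_map_nifti",
    "save_phase_maps_nifti",
    "save_roi_stats_csv",
    "write_provenance",
]


def save_acquisition(path, acq: RadialAcquisition, fov: float = 200.0) -> None:
    """Write a radial acquisition to the package's HDF5 layout.

    Datasets: ``/samples`` (complex, coil x projection x readout),
    ``/angles`` (deg), ``/ti`` (ms), ``/segment``; root attributes carry the
    sequence parameters (TR, TE, alpha, FoV, readout offsets span).
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=acq.samples)
        f.create_dataset("angles", data=acq.trajectory.angles)
        f.create_dataset("ti", data=acq.trajectory.ti)
        f.create_dataset("segment", data=acq.segment_index)
        f.create_dataset("readout_offsets", data=acq.trajectory.readout_offsets)
        f.attrs["TR"] = acq.seq.tr
        f.attrs["TE"] = acq.seq.te
        f.attrs["alpha"] = acq.seq.alpha_nominal
        f.attrs["FoV"] = fov
        f.attrs["n_projections"] = acq.seq.n_projections
        f.attrs["n_readout"] = acq.seq.n_readout
        f.attrs["inversion_delay"] = acq.seq.inversion_delay


def load_acquisition(path) -> RadialAcquisition:
    """Read an acquisition written by :func:`save_acquisition`."""
    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        traj = RadialTrajectory(
            angles=f["angles"][()],
            readout_offsets=f["readout_offsets"][()],
            ti=f["ti"][()],
        )
        seq = SequenceParams(
            tr=float(f.attrs["TR"]),
            te=float(f.attrs["TE"]),
            alpha_nominal=float(f.attrs["alpha"]),
            n_projections=int(f.attrs["n_projections"]),
            n_readout=int(f.attrs["n_readout"]),
            inversion_delay=float(f.attrs.get("inversion_delay", 15000.0)),
        )
        segment = f["segment"][()]
    return RadialAcquisition(samples=samples, trajectory=traj, seq=seq, segment_index=segment)


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))


def save_parameter_maps_nifti(path, maps: ParameterMaps) -> None:
    """Export parameter maps as one 4D NIfTI (T1, T1*, M0*, M0, valid, residual)."""
    stack = np.stack(
        [
            np.nan_to_num(maps.t1),
            np.nan_to_num(maps.t1_star),
            np.nan_to_num(maps.m0_star),
            np.nan_to_num(maps.m0),
            maps.valid.astype(float),
            np.nan_to_num(maps.residual),
        ],
        axis=-1,
    )
    nib.save(_nifti(stack), str(path))


def load_map_nifti(path, volume: int = 0) -> np.ndarray:
    """Load one volume of a map exported by this package (default: T1)."""
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if data.ndim == 2:
        return data
    return data[..., volume]


def save_parameter_maps_h5(path, maps: ParameterMaps, group: str = "maps") -> None:
    """Write parameter maps as a flat HDF5 group (one dataset per map)."""
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for name in ("t1", "t1_star", "m0_star", "m0", "residual"):
            g.create_dataset(name, data=getattr(maps, name))
        g.create_dataset("valid", data=maps.valid.astype(np.uint8))


def load_parameter_maps_h5(path, group: str = "maps") -> ParameterMaps:
    with h5py.File(path, "r") as f:
        g = f[group]
        return ParameterMaps(
            t1_star=g["t1_star"][()],
            m0_star=g["m0_star"][()],
            m0=g["m0"][()],
            t1=g["t1"][()],
            valid=g["valid"][()].astype(bool),
            residual=g["residual"][()],
        )


def save_label_map_nifti(path, labels: np.ndarray) -> None:
    nib.save(_nifti(labels.astype(float)), str(path))


def save_phase_maps_nifti(path, phi: PhaseMaps) -> None:
    nib.save(_nifti(np.moveaxis(phi.phi, 0, -1)), str(path))


def save_roi_stats_csv(path, stats: dict[int, ROIStats]) -> None:
    """Write a ROI table with columns roi,mean_ms,std_ms,snr,n_pixels."""
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["roi", "mean_ms", "std_ms", "snr", "n_pixels"])
        for label in sorted(stats):
            s = stats[label]
            writer.writerow([s.label, f"{s.mean:.6g}", f"{s.std:.6g}", f"{s.snr:.6g}", s.n_pixels])


def write_provenance(path, config: dict, seed=None) -> None:
    """Record a JSON provenance sidecar (config hash, seed, versions)."""
    import irmap

    payload = {
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "versions": {
            "irmap": irmap.__version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
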