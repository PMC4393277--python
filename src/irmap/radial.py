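"""Golden-angle radial trajectory, gridding and k-space consistency.

The reconstruction operates on one Cartesian k-space grid per time frame
(one frame per projection in single-inversion mode).  Each radial spoke is
gridded onto its own frame with a nearest-cell assignment — the surrogate for
GRAPPA-operator gridding that preserves the property the iteration relies
on: every acquired sample owns an identifiable Cartesian cell whose value is
re-substituted during the data-consistency step.

Conventions
-----------
* Square ``side x side`` grids, DC at index ``side // 2`` (0-based).
* The centered 2D DFT is unitary: ``fftshift . fft2(norm='ortho') . ifftshift``.
* Radial samples at half-integer cell radii round to the nearest integer
  cell; exact ties round toward minus infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft

from .relaxometry import SequenceParams

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "RadialTrajectory",
    "RadialAcquisition",
    "CartesianSeries",
    "golden_angle_trajectory",
    "spoke_cell_indices",
    "grid_radial_frames",
    "grid_projections",
    "ungrid_radial_frames",
    "centered_dft2",
    "temporal_interp_init",
    "data_consistency",
]

#: Golden-ratio angular increment, 180 * 2/(1+sqrt 5) = 111.2461... degrees.
GOLDEN_ANGLE_DEG = 360.0 / (1.0 + math.sqrt(5.0))


@dataclass
class RadialTrajectory:
    """Per-projection spoke geometry and timing.

    Attributes
    ----------
    angles : (P,) float array, degrees
    readout_offsets : (R,) float array
        Signed sample positions along each spoke in k-space-cell units,
        spanning ``[-R/2, R/2)`` and symmetric about 0.
    ti : (P,) float array, ms
        Inversion time of each projection (time since the inversion pulse of
        its segment).
    """

    angles: np.ndarray
    readout_offsets: np.ndarray
    ti: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.readout_offsets = np.asarray(self.readout_offsets, dtype=float)
        self.ti = np.asarray(self.ti, dtype=float)
        if self.angles.shape != self.ti.shape:
            raise ValueError("one angle and one TI required per projection")

    @property
    def n_projections(self) -> int:
        return self.angles.size

    @property
    def n_readout(self) -> int:
        return self.readout_offsets.size


@dataclass
class RadialAcquisition:
    """Raw (measured or simulated) multi-coil radial IR-LL data.

    ``samples`` is complex with shape ``(n_coils, n_projections, n_readout)``;
    ``segment_index`` labels each projection with its inversion segment.
    """

    samples: np.ndarray
    trajectory: RadialTrajectory
    seq: SequenceParams
    segment_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 3:
            raise ValueError("samples must have shape (coil, projection, readout)")
        n_coils, n_proj, n_read = self.samples.shape
        if n_coils < 1:
            raise ValueError("at least one coil required")
        if n_proj != self.trajectory.n_projections:
            raise ValueError("sample/trajectory projection count mismatch")
        if n_read != self.trajectory.n_readout:
            raise ValueError("sample/trajectory readout length mismatch")
        if self.segment_index is None:
            self.segment_index = np.zeros(n_proj, dtype=int)
        else:
            self.segment_index = np.asarray(self.segment_index, dtype=int)
            if self.segment_index.shape != (n_proj,):
                raise ValueError("segment_index must have one entry per projection")

    @property
    def n_coils(self) -> int:
        return self.samples.shape[0]

    @property
    def n_segments(self) -> int:
        return int(self.segment_index.max()) + 1


@dataclass
class CartesianSeries:
    """Per-frame, per-coil Cartesian k-space grids with sampling masks.

    Attributes
    ----------
    kspaces : (C, F, N, N) complex array
    mask : (F, N, N) bool array — cells populated by the gridder.
    acquired : (C, F, N, N) complex array or None
        The gridded measured values on masked cells (zero elsewhere); for a
        freshly gridded series this aliases ``kspaces``.
    frame_times : (F,) float array, ms.
    """

    kspaces: np.ndarray
    mask: np.ndarray
    frame_times: np.ndarray
    acquired: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kspaces.ndim != 4:
            raise ValueError("kspaces must have shape (coil, frame, ky, kx)")
        c, f, ny, nx = self.kspaces.shape
        if ny != nx:
            raise ValueError("k-space grids must be square")
        if self.mask.shape != (f, ny, nx):
            raise ValueError("mask shape mismatch")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (f,):
            raise ValueError("one frame time per frame required")

    @property
    def n_coils(self) -> int:
        return self.kspaces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.kspaces.shape[1]

    @property
    def side(self) -> int:
        return self.kspaces.shape[-1]


def golden_angle_trajectory(
    n_projections: int,
    n_readout: int,
    seq: SequenceParams,
    ti_offset: float | None = None,
) -> RadialTrajectory:
    """Golden-ratio radial trajectory with one projection per time frame.

    ``angle(i) = (i * 111.2461...) mod 360``; ``TI(i) = ti_offset + i * TR``
    with ``ti_offset`` defaulting to the echo time.  Readout offsets span
    ``[-n_readout/2, n_readout/2)`` in unit steps.
    """
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    if n_readout < 2:
        raise ValueError("n_readout must be >= 2")
    idx = np.arange(n_projections)
    angles = (idx * GOLDEN_ANGLE_DEG) % 360.0
    if ti_offset is None:
        ti_offset = seq.te
    ti = ti_offset + idx * seq.tr
    offsets = np.arange(-(n_readout // 2), n_readout - n_readout // 2, dtype=float)
    return RadialTrajectory(angles=angles, readout_offsets=offsets, ti=ti)


def spoke_cell_indices(angle_deg: float, offsets: np.ndarray, side: int):
    """Nearest Cartesian cell of each sample along one spoke.

    Returns ``(iy, ix, valid)`` where ``valid`` marks samples landing inside
    the grid.  Ties at half-integer positions round toward minus infinity.
    """
    theta = np.deg2rad(angle_deg)
    kx = offsets * np.cos(theta)
    ky = offsets * np.sin(theta)
    center = side // 2
    ix = np.ceil(kx - 0.5).astype(np.intp) + center
    iy = np.ceil(ky - 0.5).astype(np.intp) + center
    valid = (ix >= 0) & (ix < side) & (iy >= 0) & (iy < side)
    return iy, ix, valid


_GRIDDERS = ("nearest_cell",)


def _accumulate_spokes(samples, angles, offsets, side, frame_of, n_frames, dtype):
    """Nearest-cell gridding of spokes into per-frame grids with averaging.

    ``samples``: (C, P, R); ``frame_of``: (P,) target frame of each spoke.
    Returns (kspaces (C, F, N, N), mask (F, N, N)).
    """
    n_coils = samples.shape[0]
    acc = np.zeros((n_coils, n_frames, side, side), dtype=np.complex128)
    counts = np.zeros((n_frames, side, side), dtype=np.int64)
    for p in range(len(angles)):
        iy, ix, valid = spoke_cell_indices(angles[p], offsets, side)
        f = frame_of[p]
        iyv, ixv = iy[valid], ix[valid]
        np.add.at(counts[f], (iyv, ixv), 1)
        vals = samples[:, p, valid]
        for c in range(n_coils):
            np.add.at(acc[c, f], (iyv, ixv), vals[c])
    mask = counts > 0
    np.divide(acc, counts[None], out=acc, where=mask[None])
    return acc.astype(dtype, copy=False), mask


def grid_radial_frames(
    acq: RadialAcquisition,
    grid_side: int | None = None,
    gridder: str = "nearest_cell",
    frame_of: np.ndarray | None = None,
    dtype=np.complex128,
) -> CartesianSeries:
    """Grid each radial projection onto its own frame's Cartesian k-space.

    With the default ``nearest_cell`` gridder every sample lands in exactly
    one cell; collisions (several samples of the same frame mapping to one
    cell) are averaged.  ``frame_of`` optionally reassigns projections to
    frames (used by the segmented reference, where the spokes of all
    segments sharing a readout slot build one fully sampled frame); the
    default is one frame per projection in acquisition order.
    """
    if gridder not in _GRIDDERS:
        raise ValueError(f"unknown gridder {gridder!r}; available: {_GRIDDERS}")
    traj = acq.trajectory
    side = traj.n_readout if grid_side is None else int(grid_side)
    if frame_of is None:
        frame_of = np.arange(traj.n_projections)
        frame_times = traj.ti.copy()
    else:
        frame_of = np.asarray(frame_of, dtype=int)
        frame_times = np.zeros(frame_of.max() + 1)
        frame_times[frame_of] = traj.ti
    n_frames = int(frame_of.max()) + 1
    kspaces, mask = _accumulate_spokes(
        acq.samples, traj.angles, traj.readout_offsets, side, frame_of, n_frames, dtype
    )
    return CartesianSeries(
        kspaces=kspaces, mask=mask, frame_times=frame_times, acquired=kspaces
    )


def grid_projections(
    samples: np.ndarray,
    angles: np.ndarray,
    offsets: np.ndarray,
    side: int,
    dtype=np.complex128,
):
    """Grid a set of spokes into a single k-space per coil (collision-averaged).

    Used e.g. for the fully sampled tail image behind the coil phase maps.
    Returns ``(kspaces (C, N, N), mask (N, N))``.
    """
    frame_of = np.zeros(len(angles), dtype=int)
    k, mask = _accumulate_spokes(samples, angles, offsets, side, frame_of, 1, dtype)
    return k[:, 0], mask[0]


def ungrid_radial_frames(series: CartesianSeries, trajectory: RadialTrajectory):
    """Adjoint of :func:`grid_radial_frames` (nearest-cell with averaging).

    Sample ``i`` of spoke ``p`` reads ``kspaces[frame p, cell(i)] / n_cell``
    where ``n_cell`` is the number of spoke samples averaged into that cell;
    out-of-grid samples read 0.  Together with the unitary DFT this forms the
    adjoint pair exercised by the inner-product test.
    """
    side = series.side
    n_coils = series.n_coils
    P, R = trajectory.n_projections, trajectory.n_readout
    out = np.zeros((n_coils, P, R), dtype=series.kspaces.dtype)
    for p in range(P):
        iy, ix, valid = spoke_cell_indices(
            trajectory.angles[p], trajectory.readout_offsets, side
        )
        iyv, ixv = iy[valid], ix[valid]
        counts = np.zeros((side, side), dtype=np.int64)
        np.add.at(counts, (iyv, ixv), 1)
        out[:, p, valid] = series.kspaces[:, p, iyv, ixv] / counts[iyv, ixv]
    return out


def centered_dft2(data: np.ndarray, direction: str = "forward") -> np.ndarray:
    """Unitary centered 2D DFT over the last two (square) axes.

    ``forward . inverse`` is the identity to machine precision, the norm is
    preserved (Parseval), and the DC term sits at index ``side // 2`` on both
    axes.  Batch dimensions are transformed independently.
    """
    data = np.asarray(data)
    if data.ndim < 2 or data.shape[-1] != data.shape[-2]:
        raise ValueError("centered_dft2 requires square trailing axes")
    axes = (-2, -1)
    shifted = scipy.fft.ifftshift(data, axes=axes)
    if direction == "forward":
        out = scipy.fft.fft2(shifted, axes=axes, norm="ortho")
    elif direction == "inverse":
        out = scipy.fft.ifft2(shifted, axes=axes, norm="ortho")
    else:
        raise ValueError("direction must be 'forward' or 'inverse'")
    return scipy.fft.fftshift(out, axes=axes)


def temporal_interp_init(series: CartesianSeries) -> CartesianSeries:
    """Fill unacquired frames of each acquired cell by temporal interpolation.

    For every grid cell acquired in at least one frame, values at unacquired
    frames between two acquisitions are linearly interpolated (real and
    imaginary parts independently) against frame time; before the first and
    after the last acquisition the nearest acquired value is held.  Cells
    never acquired stay 0.  Masks are not altered, and acquired cells keep
    their exact values at their own frames.
    """
    if not series.mask.any():
        raise ValueError("series has no acquired samples")
    F = series.n_frames
    N = series.side
    t = series.frame_times
    mask = series.mask.reshape(F, N * N)
    frame_idx = np.arange(F)[:, None]

    # Index of the most recent acquired frame <= f (-1 if none), per cell.
    prev_idx = np.where(mask, frame_idx, -1)
    np.maximum.accumulate(prev_idx, axis=0, out=prev_idx)
    # Index of the next acquired frame >= f (F if none), per cell.
    next_idx = np.where(mask, frame_idx, F)
    next_idx = np.minimum.accumulate(next_idx[::-1], axis=0)[::-1]

    has_prev = prev_idx >= 0
    has_next = next_idx < F
    prev_c = np.clip(prev_idx, 0, F - 1)
    next_c = np.clip(next_idx, 0, F - 1)
    cell = np.arange(N * N)[None, :]

    t_prev = t[prev_c]
    t_next = t[next_c]
    denom = t_next - t_prev
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, (t[:, None] - t_prev) / np.where(denom > 0, denom, 1.0), 0.0)

    out = np.empty_like(series.kspaces)
    for c_i in range(series.n_coils):
        k = series.kspaces[c_i].reshape(F, N * N)
        v_prev = k[prev_c, cell]
        v_next = k[next_c, cell]
        filled = v_prev + (v_next - v_prev) * w.astype(v_prev.real.dtype)
        # hold-nearest outside the acquired span; zero where never acquired
        filled = np.where(has_prev, filled, np.where(has_next, v_next, 0))
        filled = np.where(has_next, filled, np.where(has_prev, v_prev, 0))
        out[c_i] = filled.reshape(F, N, N)
    return CartesianSeries(
        kspaces=out,
        mask=series.mask,
        frame_times=series.frame_times,
        acquired=series.acquired,
    )


def data_consistency(
    model: CartesianSeries, measured: CartesianSeries, out: np.ndarray | None = None
) -> CartesianSeries:
    """Substitute measured values on acquired cells of the model k-spaces.

    On masked cells the output equals the gridded measured value bit-exactly;
    unmasked cells pass through unchanged.  The operation is an orthogonal
    projection (idempotent).
    """
    if model.kspaces.shape != measured.kspaces.shape or not np.array_equal(
        model.mask, measured.mask
    ):
        raise ValueError("model and measured series must share geometry and masks")
    if out is None:
        out = model.kspaces.copy()
    elif out is not model.kspaces:
        np.copyto(out, model.kspaces)
    src = measured.acquired if measured.acquired is not None else measured.kspaces
    out[:, measured.mask] = src[:, measured.mask]
    return CartesianSeries(
        kspaces=out,
        mask=measured.mask,
        frame_times=model.frame_times,
        acquired=measured.acquired,
    )
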