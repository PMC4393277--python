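"""Digital phantoms and exact forward simulation of radial IR-LL acquisitions.

Stands in for the scanner: rasterized phantoms with known (T1, M0, alpha)
per compartment, smooth complex coil sensitivities, and a projection-by-
projection forward model.  Each projection sees the transient IR-LL
magnetization at its own inversion time; its spoke is evaluated with a
nonuniform DFT of the instantaneous coil image (an exact, separable
evaluation is the oracle; an FFT-based fast path must agree with it).

By default spoke samples are evaluated *at the nearest Cartesian cell
positions* (``snap_to_cells=True``).  This emulates the behavior of
GRAPPA-operator gridding, which shifts every acquired sample accurately onto
its nearest cell before reconstruction; with snapping enabled the fast FFT
path is exact.  Set ``snap_to_cells=False`` for true off-grid radial
sampling (used by the gridding-accuracy oracle tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radial import (
    GOLDEN_ANGLE_DEG,
    RadialAcquisition,
    RadialTrajectory,
    centered_dft2,
    spoke_cell_indices,
)
from .relaxometry import SequenceParams, effective_t1, steady_state_magnetization

__all__ = [
    "Compartment",
    "PhantomSpec",
    "GroundTruth",
    "VIAL_T1_DEFAULTS",
    "BRAIN_T1_DEFAULTS",
    "make_vial_phantom",
    "make_brain_phantom",
    "simulate_coil_sensitivities",
    "simulate_radial_irll",
    "segment_start_longitudinal",
    "nudft_spoke",
]

#: Reference vial T1 values (ms) of the seven-vial validation phantom.
VIAL_T1_DEFAULTS = (208.0, 573.0, 998.0, 1659.0, 2123.0, 2560.0, 2929.0)

#: Brain-like compartment T1 values (ms): white matter, grey matter, CSF.
BRAIN_T1_DEFAULTS = {"WM": 722.0, "GM": 1432.0, "CSF": 4350.0}


@dataclass(frozen=True)
class Compartment:
    """One geometric phantom compartment with homogeneous parameters."""

    shape: str  # "disk" or "ellipse"
    center: tuple[float, float]  # (y, x) in pixels
    radii: tuple[float, float]  # (ry, rx) in pixels
    t1: float  # ms
    m0: float = 1.0
    alpha: float | None = None  # degrees; None -> sequence nominal
    label: str = ""

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.m0 <= 0:
            raise ValueError("compartment T1 and M0 must be positive")
        if self.shape not in ("disk", "ellipse"):
            raise ValueError(f"unknown compartment shape {self.shape!r}")


@dataclass
class PhantomSpec:
    """Phantom geometry: compartments painted in order onto a square grid."""

    grid_side: int
    compartments: list[Compartment]
    fov: float = 200.0  # mm
    background_t1: float = 300.0
    background_m0: float = 0.0


@dataclass
class GroundTruth:
    """Rasterized per-pixel truth maps and the compartment label map."""

    t1: np.ndarray
    m0: np.ndarray
    alpha: np.ndarray
    labels: np.ndarray


def _compartment_mask(comp: Compartment, side: int) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    cy, cx = comp.center
    ry, rx = comp.radii
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def rasterize_phantom(spec: PhantomSpec, alpha_nominal: float = 7.0) -> GroundTruth:
    """Paint compartments (in list order, later on top) into truth maps."""
    side = spec.grid_side
    t1 = np.full((side, side), spec.background_t1)
    m0 = np.full((side, side), spec.background_m0)
    alpha = np.full((side, side), alpha_nominal)
    labels = np.zeros((side, side), dtype=np.int32)
    for i, comp in enumerate(spec.compartments, start=1):
        m = _compartment_mask(comp, side)
        t1[m] = comp.t1
        m0[m] = comp.m0
        alpha[m] = comp.alpha if comp.alpha is not None else alpha_nominal
        labels[m] = i
    return GroundTruth(t1=t1, m0=m0, alpha=alpha, labels=labels)


def make_vial_phantom(
    grid_side: int = 128,
    t1_values=None,
    background_m0: float = 0.05,
    alpha_nominal: float = 7.0,
):
    """Ring of up to nine disk 'vials' inside a low-signal background.

    Vials are placed on a circle around the grid center (a single vial sits
    at the center); the label map carries background label 0 plus one label
    per vial (A, B, ... in list order).  Overlapping vials raise.
    """
    if grid_side < 32:
        raise ValueError("grid_side must be >= 32")
    t1_values = VIAL_T1_DEFAULTS if t1_values is None else tuple(t1_values)
    n = len(t1_values)
    if not 1 <= n <= 9:
        raise ValueError("between 1 and 9 vials supported")
    c = (grid_side - 1) / 2.0
    r_vial = 0.11 * grid_side
    comps = []
    if n == 1:
        centers = [(c, c)]
    else:
        ring = 0.30 * grid_side
        # shrink the vials when many are requested so they stay disjoint
        r_vial = min(r_vial, 0.8 * ring * np.sin(np.pi / n))
        centers = [
            (c + ring * np.sin(2 * np.pi * k / n), c + ring * np.cos(2 * np.pi * k / n))
            for k in range(n)
        ]
        for a in range(n):
            for b in range(a + 1, n):
                d = np.hypot(centers[a][0] - centers[b][0], centers[a][1] - centers[b][1])
                if d <= 2 * r_vial:
                    raise ValueError("vials overlap; reduce their number or radius")
    for k, (cy, cx) in enumerate(centers):
        comps.append(
            Compartment(
                shape="disk",
                center=(cy, cx),
                radii=(r_vial, r_vial),
                t1=float(t1_values[k]),
                m0=1.0,
                label=chr(ord("A") + k),
            )
        )
    spec = PhantomSpec(
        grid_side=grid_side, compartments=comps, background_m0=background_m0
    )
    return spec, rasterize_phantom(spec, alpha_nominal)


def make_brain_phantom(grid_side: int = 128, t1_values: dict | None = None):
    """Brain-like phantom: elliptical GM ribbon, WM interior, CSF ventricles.

    Three tissue labels plus background; ground-truth T1 is constant within
    each tissue (WM 722 ms, GM 1432 ms, CSF 4350 ms by default).
    """
    if grid_side < 64:
        raise ValueError("grid_side must be >= 64")
    t1v = dict(BRAIN_T1_DEFAULTS)
    if t1_values:
        t1v.update(t1_values)
    c = (grid_side - 1) / 2.0
    s = grid_side
    comps = [
        # outer head ellipse painted as GM, WM painted on top, CSF on top of WM
        Compartment("ellipse", (c, c), (0.42 * s, 0.34 * s), t1v["GM"], 0.9, label="GM"),
        Compartment("ellipse", (c, c), (0.33 * s, 0.25 * s), t1v["WM"], 0.8, label="WM"),
        Compartment(
            "ellipse", (c - 0.04 * s, c - 0.09 * s), (0.085 * s, 0.04 * s), t1v["CSF"], 1.0, label="CSF"
        ),
        Compartment(
            "ellipse", (c - 0.04 * s, c + 0.09 * s), (0.085 * s, 0.04 * s), t1v["CSF"], 1.0, label="CSF"
        ),
    ]
    spec = PhantomSpec(grid_side=grid_side, compartments=comps, background_m0=0.0)
    truth = rasterize_phantom(spec)
    # merge the two ventricles into one CSF label; relabel WM=1, GM=2, CSF=3
    lab = truth.labels
    merged = np.zeros_like(lab)
    merged[lab == 2] = 1  # WM
    merged[lab == 1] = 2  # GM ribbon (outer ellipse minus overpainted interior)
    merged[(lab == 3) | (lab == 4)] = 3  # CSF
    truth.labels = merged
    return spec, truth


def simulate_coil_sensitivities(grid_side: int, n_coils: int, seed: int = 0):
    """Smooth complex coil sensitivity maps, SoS-normalized to unit magnitude.

    One coil yields a constant map of 1.  Multiple coils get Gaussian
    magnitude profiles centered around the FOV periphery with distinct smooth
    (linear-ramp) phases; the magnitude sum of squares is exactly 1
    everywhere.  Bit-reproducible for a fixed seed.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if n_coils == 1:
        return np.ones((1, grid_side, grid_side), dtype=np.complex128)
    rng = np.random.default_rng(seed)
    c = (grid_side - 1) / 2.0
    yy, xx = np.mgrid[0:grid_side, 0:grid_side].astype(float)
    sigma = 0.55 * grid_side
    maps = np.empty((n_coils, grid_side, grid_side), dtype=np.complex128)
    for g in range(n_coils):
        ang = 2 * np.pi * g / n_coils + rng.uniform(-0.2, 0.2)
        cy = c + 0.62 * grid_side * np.sin(ang)
        cx = c + 0.62 * grid_side * np.cos(ang)
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        phase = (
            rng.uniform(-np.pi, np.pi)
            + rng.uniform(-1.5, 1.5) * (xx - c) / grid_side
            + rng.uniform(-1.5, 1.5) * (yy - c) / grid_side
        )
        maps[g] = mag * np.exp(1j * phase)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return maps / sos[None]


def nudft_spoke(image: np.ndarray, angle_deg: float, offsets: np.ndarray,
                snap_to_cells: bool = False) -> np.ndarray:
    """Exact nonuniform DFT of image(s) along one radial spoke.

    Matches the centered unitary DFT convention: sample at continuous
    k-position (kx, ky) equals ``(1/N) sum_j image[y, x] exp(-2 pi i (kx
    (x-c) + ky (y-c)) / N)`` with ``c = N // 2``.  Leading batch axes of
    ``image`` are carried through.  The DC sample (offset 0) equals the image
    mean times ``N / N = sum / N``.
    """
    image = np.asarray(image)
    N = image.shape[-1]
    theta = np.deg2rad(angle_deg)
    kx = offsets * np.cos(theta)
    ky = offsets * np.sin(theta)
    if snap_to_cells:
        kx = np.ceil(kx - 0.5)
        ky = np.ceil(ky - 0.5)
    c = N // 2
    coord = np.arange(N) - c
    ey = np.exp(-2j * np.pi * ky[:, None] * coord[None, :] / N)  # (R, Ny)
    ex = np.exp(-2j * np.pi * kx[:, None] * coord[None, :] / N)  # (R, Nx)
    tmp = np.einsum("rn,...nm->...rm", ey, image)  # sum over y
    return np.einsum("rm,...rm->...r", ex, tmp) / N


def segment_start_longitudinal(
    t1, m0, alpha, seq: SequenceParams, n_segments: int,
    incomplete_recovery: bool = True, delay: float | None = None,
):
    """Longitudinal magnetization right after each segment's inversion pulse.

    Tracks the steady-state drive over one segment, the free recovery during
    the inter-segment gap, and the (perfect) inversion.  With complete
    recovery every segment starts at ``-M0``; with ``incomplete_recovery``
    long-T1 compartments start later segments at a reduced magnitude — the
    mechanism behind drifting CSF estimates in repeated acquisitions.
    Returns an array of shape ``(n_segments,) + shape(t1)``.
    """
    t1 = np.asarray(t1, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    t1_star = effective_t1(t1, seq.tr, alpha)
    m0_star = steady_state_magnetization(m0, t1_star, t1)
    if delay is None:
        delay = seq.inversion_delay
    t_end = seq.te + (seq.n_projections - 1) * seq.tr
    starts = np.empty((n_segments,) + t1.shape)
    mz = -m0
    for s in range(n_segments):
        starts[s] = mz
        if not incomplete_recovery:
            mz = -m0
            continue
        m_end = m0_star + (mz - m0_star) * np.exp(-t_end / t1_star)
        m_rec = m0 + (m_end - m0) * np.exp(-delay / t1)
        mz = -m_rec
    return starts


def simulate_radial_irll(
    truth: GroundTruth,
    sens: np.ndarray,
    traj: RadialTrajectory,
    seq: SequenceParams,
    noise_sigma: float = 0.0,
    seed: int = 0,
    segments: int = 1,
    mode: str = "fast",
    snap_to_cells: bool = True,
    incomplete_recovery: bool = False,
    recovery_delay: float | None = None,
) -> RadialAcquisition:
    """Forward-simulate a (possibly segmented) radial IR-LL acquisition.

    For every projection the per-pixel transient magnetization at that
    projection's inversion time is computed from the per-pixel (T1, M0,
    alpha) truth, multiplied by the coil sensitivities, and sampled along the
    spoke.  ``mode='exact'`` evaluates the nonuniform DFT directly (the
    oracle); ``mode='fast'`` samples the FFT of each frame, which is exact
    when ``snap_to_cells`` is on and interpolates on a 2x zero-padded grid
    otherwise.  I.i.d. complex Gaussian noise with per-component standard
    deviation ``noise_sigma`` is added to every sample.

    In segmented mode (``segments > 1``) the given trajectory describes one
    segment; spoke angles continue the golden-angle sweep across segments
    (global projection counter) while the inversion clock restarts.  With
    ``incomplete_recovery`` the inter-segment gap (default
    ``seq.inversion_delay``) leaves long-T1 magnetization incompletely
    recovered before the next inversion.
    """
    if mode not in ("exact", "fast"):
        raise ValueError(f"unknown simulation mode {mode!r}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    sens = np.asarray(sens, dtype=np.complex128)
    if sens.ndim != 3 or sens.shape[1:] != truth.t1.shape:
        raise ValueError("sensitivities must have shape (coil, N, N)")
    N = truth.t1.shape[0]
    P = traj.n_projections
    R = traj.n_readout
    C = sens.shape[0]
    rng = np.random.default_rng(seed)

    t1_star = effective_t1(truth.t1, seq.tr, truth.alpha)
    with np.errstate(invalid="ignore"):
        m0_star = np.where(
            truth.m0 > 0,
            steady_state_magnetization(np.maximum(truth.m0, 1e-30), t1_star, truth.t1),
            0.0,
        )
    starts = segment_start_longitudinal(
        truth.t1, np.maximum(truth.m0, 1e-30), truth.alpha, seq, segments,
        incomplete_recovery=incomplete_recovery, delay=recovery_delay,
    )
    starts = np.where(truth.m0[None] > 0, starts, 0.0)

    total = segments * P
    samples = np.empty((C, total, R), dtype=np.complex128)
    angles = np.empty(total)
    ti = np.empty(total)
    seg_idx = np.empty(total, dtype=int)
    for s in range(segments):
        if s == 0:
            seg_angles = traj.angles
        else:
            seg_angles = (traj.angles + s * P * GOLDEN_ANGLE_DEG) % 360.0
        sl = slice(s * P, (s + 1) * P)
        angles[sl] = seg_angles
        ti[sl] = traj.ti
        seg_idx[sl] = s
        mz0 = starts[s]
        for j in range(P):
            t = traj.ti[j]
            m_t = m0_star + (mz0 - m0_star) * np.exp(-t / t1_star)
            coil_imgs = sens * m_t[None]
            gi = s * P + j
            if mode == "exact":
                samples[:, gi] = nudft_spoke(
                    coil_imgs, seg_angles[j], traj.readout_offsets, snap_to_cells
                )
            else:
                samples[:, gi] = _fft_spoke(
                    coil_imgs, seg_angles[j], traj.readout_offsets, snap_to_cells
                )
    if noise_sigma > 0:
        noise = rng.standard_normal((C, total, R)) + 1j * rng.standard_normal(
            (C, total, R)
        )
        samples += noise_sigma * noise

    full_traj = RadialTrajectory(angles=angles, readout_offsets=traj.readout_offsets, ti=ti)
    return RadialAcquisition(
        samples=samples, trajectory=full_traj, seq=seq, segment_index=seg_idx
    )


def _fft_spoke(coil_imgs, angle_deg, offsets, snap_to_cells):
    """FFT-based spoke sampling (cell read-out when snapped, else 2x-padded
    bilinear interpolation)."""
    N = coil_imgs.shape[-1]
    if snap_to_cells:
        k = centered_dft2(coil_imgs, "forward")
        theta = np.deg2rad(angle_deg)
        # wrap aliased cells (e.g. +N/2 == -N/2): the NUDFT at integer cell
        # positions is N-periodic, so the FFT read-out stays exact
        ix = (np.ceil(offsets * np.cos(theta) - 0.5).astype(np.intp) + N // 2) % N
        iy = (np.ceil(offsets * np.sin(theta) - 0.5).astype(np.intp) + N // 2) % N
        return k[..., iy, ix]
    pad = 8
    Np = pad * N
    big = np.zeros(coil_imgs.shape[:-2] + (Np, Np), dtype=complex)
    lo = (Np - N) // 2
    big[..., lo : lo + N, lo : lo + N] = coil_imgs
    k = centered_dft2(big, "forward") * pad  # keep 1/N scaling of the original grid
    theta = np.deg2rad(angle_deg)
    kx = offsets * np.cos(theta) * pad + Np // 2
    ky = offsets * np.sin(theta) * pad + Np // 2
    x0 = np.clip(np.floor(kx).astype(int), 0, Np - 2)
    y0 = np.clip(np.floor(ky).astype(int), 0, Np - 2)
    fx = kx - x0
    fy = ky - y0
    v00 = k[..., y0, x0]
    v01 = k[..., y0, x0 + 1]
    v10 = k[..., y0 + 1, x0]
    v11 = k[..., y0 + 1, x0 + 1]
    return (
        v00 * (1 - fy) * (1 - fx)
        + v01 * (1 - fy) * fx
        + v10 * fy * (1 - fx)
        + v11 * fy * fx
    )
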