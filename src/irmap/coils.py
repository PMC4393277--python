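"""Multi-coil handling of signed inversion-recovery image series.

An inversion produces negative as well as positive longitudinal
magnetization, so a plain magnitude sum-of-squares combination would destroy
the sign of the relaxation curve.  Instead: per-coil phase maps are taken
from a fully sampled image built out of the late (post-zero-crossing) tail
of the acquisition, each coil series is rotated onto the real axis
(``realify``), the coils are merged with a sign-dependent sum of squares,
and after model enforcement the combined model is re-separated into coil
models with per-pixel complex least-squares weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radial import RadialAcquisition, centered_dft2, grid_projections

__all__ = [
    "PhaseMaps",
    "CoilWeights",
    "phase_maps_from_tail",
    "realify",
    "sign_dependent_sos",
    "reseparate_coils",
]


@dataclass
class PhaseMaps:
    """Per-pixel, per-coil phase (radians, in (-pi, pi]); shape (C, N, N)."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi)
        if self.phi.ndim != 3:
            raise ValueError("phi must have shape (coil, y, x)")


@dataclass
class CoilWeights:
    """Per-pixel complex coil weights c_gamma(j) with a low-energy flag map."""

    c: np.ndarray
    flagged: np.ndarray


def phase_maps_from_tail(
    acq: RadialAcquisition,
    n_tail: int = 200,
    grid_side: int | None = None,
) -> PhaseMaps:
    """Coil phase maps from the last ``n_tail`` projections of the scan.

    The tail projections postdate the zero crossing (the magnetization is
    near its steady state with a stable contrast), so gridding them into one
    fully sampled k-space per coil and transforming to image space yields an
    image whose pixel-wise phase is the coil phase.
    """
    P = acq.trajectory.n_projections
    if n_tail > P:
        raise ValueError(f"n_tail={n_tail} exceeds n_projections={P}")
    if n_tail < 1:
        raise ValueError("n_tail must be >= 1")
    side = acq.trajectory.n_readout if grid_side is None else int(grid_side)
    k, _ = grid_projections(
        acq.samples[:, P - n_tail :],
        acq.trajectory.angles[P - n_tail :],
        acq.trajectory.readout_offsets,
        side,
    )
    images = centered_dft2(k, "inverse")
    return PhaseMaps(phi=np.angle(images))


def realify(images: np.ndarray, phi: PhaseMaps) -> np.ndarray:
    """Rotate per-coil complex series onto the real axis and keep the real part.

    ``Real{ M_gamma(j, t) * exp(-i phi_gamma(j)) }`` for ``images`` of shape
    (C, F, N, N); the orthogonal (imaginary) residual is discarded.
    """
    images = np.asarray(images)
    phi_arr = phi.phi if isinstance(phi, PhaseMaps) else np.asarray(phi)
    if images.shape[0] != phi_arr.shape[0] or images.shape[-2:] != phi_arr.shape[-2:]:
        raise ValueError("image/phase-map geometry mismatch")
    # Real{ M e^{-i phi} } = Re(M) cos(phi) + Im(M) sin(phi), kept in real
    # arithmetic to avoid a full complex temporary
    rdt = images.real.dtype
    cos = np.cos(phi_arr).astype(rdt)[:, None]
    sin = np.sin(phi_arr).astype(rdt)[:, None]
    return images.real * cos + images.imag * sin


def _sign(x: np.ndarray) -> np.ndarray:
    # sign(0) := +1 so the combination is total and deterministic
    return np.where(x >= 0, 1.0, -1.0).astype(x.dtype, copy=False)


def sign_dependent_sos(real_images: np.ndarray) -> np.ndarray:
    """Sign-preserving sum-of-squares coil combination.

    ``theta(j,t) = sum_gamma sign(M_gamma) |M_gamma|^2``;
    output ``= sign(theta) sqrt(|theta|)``.  Reduces to the plain magnitude
    SoS when every input is non-negative, and to the identity for one coil.
    """
    real_images = np.asarray(real_images)
    if real_images.ndim < 1:
        raise ValueError("expected per-coil real image series")
    # sign(x) |x|^2 == x |x|
    theta = np.einsum("c...,c...->...", real_images, np.abs(real_images))
    out = np.sqrt(np.abs(theta))
    np.negative(out, out=out, where=theta < 0)
    return out


def reseparate_coils(
    model: np.ndarray, images: np.ndarray, eps: float | None = None
):
    """Split a combined real model series back into per-coil complex models.

    Per pixel ``j`` and coil ``gamma`` the complex weight is the least-squares
    fit of ``images_gamma(j, .) ~ c * model(j, .)`` over time:
    ``c = sum_t images(j,t) model(j,t) / sum_t model(j,t)^2``.  Pixels whose
    model energy falls below ``eps`` (default ``1e-8 * max energy``) get
    ``c = 0`` and are flagged.  Returns ``(CoilWeights, coil model series)``
    with the coil models ``c_gamma(j) * model(j, t)``.
    """
    model = np.asarray(model)
    images = np.asarray(images)
    if images.shape[1:] != model.shape:
        raise ValueError("model/images geometry mismatch")
    energy = np.sum(model.astype(np.float64) ** 2, axis=0)
    if eps is None:
        eps = 1e-8 * float(energy.max(initial=0.0))
    num = np.einsum("cfyx,fyx->cyx", images, model.astype(images.real.dtype))
    low = energy < max(eps, np.finfo(np.float64).tiny)
    denom = np.where(low, 1.0, energy)
    c = num / denom.astype(num.real.dtype)
    c[:, low] = 0
    coil_models = c[:, None] * model[None].astype(c.real.dtype)
    return CoilWeights(c=c, flagged=low), coil_models
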