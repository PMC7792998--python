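"""Oversampled diffraction forward model.

The measured intensity is the modulus squared of the discrete Fourier
transform of the complex particle density, I(Q) = |F[s(r) exp(i phi(r))]|^2.
All reciprocal-space arrays are zero-frequency centered (detector-image
convention): transforms are computed as fftshift(fft(ifftshift(x))) with the
unnormalized forward DFT, so Parseval reads sum(I)/N^d == sum(|rho|^2).

A 2D detector slice through the center of the 3D intensity distribution is,
by the Fourier slice theorem, exactly the 2D diffraction of the complex
projection of the particle along the slice normal; that identity is this
module's primary self-check and makes the 2D ground-truth images of the
learned inverter well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import ComplexImage2D, ComplexObject3D, DiffractionPattern

__all__ = [
    "Intensity3D",
    "cfftn",
    "cifftn",
    "cfft2",
    "cifft2",
    "diffract_3d",
    "central_slice",
    "project",
    "diffract_2d",
    "friedel_violation",
    "embed_centered",
    "crop_center",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class Intensity3D:
    """3D diffraction intensity on the reciprocal grid, zero-frequency centered."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("Intensity3D requires a 3D array")
        if self.values.min() < 0:
            raise ValueError("intensity must be nonnegative")


def cfftn(x: np.ndarray) -> np.ndarray:
    """Centered unnormalized n-D forward DFT."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x)))


def cifftn(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(x)))


def cfft2(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x)))


def cifft2(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x)))


def diffract_3d(obj: ComplexObject3D) -> Intensity3D:
    """I(Q) = |F rho|^2 on the full 3D reciprocal grid."""
    F = cfftn(obj.density)
    return Intensity3D(values=(F.real**2 + F.imag**2))


def central_slice(intensity: Intensity3D, axis: str = "z") -> DiffractionPattern:
    """The zero-frequency plane perpendicular to ``axis``.

    This is the plane a 2D detector records when only the central slice of
    the 3D distribution is measured (the single-shot imaging geometry).
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    ax = _AXES[axis]
    n = intensity.values.shape[ax]
    plane = np.take(intensity.values, n // 2, axis=ax)
    return DiffractionPattern(intensity=np.ascontiguousarray(plane))


def project(
    obj: ComplexObject3D, axis: str = "z", support_eps: float = 1e-3
) -> tuple[np.ndarray, ComplexImage2D]:
    """Complex line-sum of the particle density along ``axis``.

    Returns the raw full-frame complex projection (whose 2D diffraction
    equals the central intensity slice exactly) together with the central
    half-frame crop as a ComplexImage2D: modulus renormalized to max 1,
    phase masked to the projected support (pixels whose modulus falls below
    ``support_eps`` of the maximum are zeroed).
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    full = obj.density.sum(axis=_AXES[axis])
    crop = crop_center(full, obj.grid.half)
    amp = np.abs(crop)
    peak = amp.max()
    if peak > 0:
        amp = amp / peak
    mask = amp >= support_eps
    amp = np.where(mask, amp, 0.0)
    phase = np.where(mask, np.angle(crop), 0.0)
    return full, ComplexImage2D(amplitude=amp, phase=phase)


def diffract_2d(img: np.ndarray) -> DiffractionPattern:
    """|centered 2D DFT|^2 of a square complex image."""
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image must be square")
    F = cfft2(img)
    return DiffractionPattern(intensity=(F.real**2 + F.imag**2))


def _centro_flip(x: np.ndarray) -> np.ndarray:
    # maps index i -> (-i) mod n on every axis, i.e. Q -> -Q about the
    # zero-frequency pixel of a centered even-size array
    out = x[(slice(None, None, -1),) * x.ndim]
    return np.roll(out, shift=(1,) * x.ndim, axis=tuple(range(x.ndim)))


def friedel_violation(pattern: DiffractionPattern) -> float:
    """Relative centrosymmetry breaking ||I(Q) - I(-Q)|| / ||I||.

    Zero for a real (zero-phase) object; strictly positive for strong-phase
    particles, whose multicentered patterns visibly break Friedel symmetry.
    """
    I = pattern.intensity
    flip = _centro_flip(I)
    denom = np.linalg.norm(I)
    if denom == 0:
        raise ValueError("empty pattern")
    return float(np.linalg.norm(I - flip) / denom)


def embed_centered(img: np.ndarray, n: int) -> np.ndarray:
    """Zero-pad a small square array into the center of an n x n frame."""
    m = img.shape[0]
    if img.shape != (m, m) or m > n:
        raise ValueError("image must be square and no larger than the frame")
    out = np.zeros((n, n), dtype=img.dtype)
    lo = (n - m) // 2
    out[lo : lo + m, lo : lo + m] = img
    return out


def crop_center(arr: np.ndarray, m: int) -> np.ndarray:
    """Central m x m (or m^d) crop of a square (cubic) array."""
    n = arr.shape[0]
    lo = (n - m) // 2
    sl = (slice(lo, lo + m),) * arr.ndim
    return np.ascontiguousarray(arr[sl])
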