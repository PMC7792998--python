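"""Synthetic strong-phase particles and their oversampled diffraction data.

Builds the training corpus for learned diffraction inversion: randomized
superellipsoid particles carrying a Gaussian-correlated internal phase,
randomly oriented in 3D, from which central-slice diffraction patterns and
projected complex ground-truth images are computed.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter

__all__ = [
    "GridSpec",
    "SuperellipsoidParams",
    "PhaseFieldParams",
    "Orientation",
    "ComplexObject3D",
    "ComplexImage2D",
    "DiffractionPattern",
    "TrainingSample",
    "Dataset",
    "SimulatorConfig",
    "voxelize_superellipsoid",
    "sample_phase_field",
    "assemble_object",
    "rotate_object",
    "random_orientation",
    "sample_random_particle",
    "make_training_sample",
    "simulate_dataset",
]


# --------------------------------------------------------------------------
# grid and parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Cubic object grid and square detector grid.

    The detector matches the object grid (``n_det == n_obj``) and the
    particle is confined to the central ``n_obj/2`` cube, which realises
    an oversampling ratio of at least two per dimension — the condition
    under which the phase problem is well-posed.  The learned inversion
    consequently outputs images of ``n_obj/2 x n_obj/2`` pixels, one
    quarter of the area of the input pattern.
    """

    n_obj: int = 64
    n_det: int = 64

    def __post_init__(self) -> None:
        if self.n_obj % 2 or self.n_det % 2:
            raise ValueError("grid sizes must be even")
        if self.n_det != self.n_obj:
            raise ValueError("n_det must equal n_obj")

    @property
    def half(self) -> int:
        return self.n_obj // 2

    @property
    def center(self) -> float:
        # geometric center of the voxel grid; rotations and voxelization
        # use this so that coordinate negation maps the grid onto itself
        return (self.n_obj - 1) / 2.0

    def axis_coords(self) -> np.ndarray:
        return np.arange(self.n_obj) - self.center

    def central_cube(self) -> tuple[slice, slice, slice]:
        lo = self.n_obj // 4
        return (slice(lo, lo + self.half),) * 3  # type: ignore[return-value]


@dataclass(frozen=True)
class SuperellipsoidParams:
    """Semi-axes (voxels) and roundedness exponents of a superellipsoid.

    ``e`` controls the roundedness in the equatorial (x-y) plane and ``n``
    in the meridional direction; (e, n) = (1, 1) is an ellipsoid and
    (2, 2) an octahedron.
    """

    a: float
    b: float
    c: float
    e: float
    n: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "e", "n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"superellipsoid parameter {name} must be > 0")


@dataclass(frozen=True)
class PhaseFieldParams:
    """Correlation lengths (voxels) and target span of the interior phase."""

    L_x: float
    L_y: float
    L_z: float
    phase_span: float = 2 * np.pi
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.L_x, self.L_y, self.L_z) <= 0:
            raise ValueError("correlation lengths must be positive")
        if not (0 < self.phase_span <= 2 * np.pi):
            raise ValueError("phase_span must lie in (0, 2*pi]")


@dataclass(frozen=True)
class Orientation:
    """Unit quaternion (w, x, y, z) describing a 3D rotation."""

    q: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.q) - 1.0) > 1e-12:
            raise ValueError("quaternion must have unit norm")

    @property
    def matrix(self) -> np.ndarray:
        w, x, y, z = self.q
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )


IDENTITY_ORIENTATION = Orientation((1.0, 0.0, 0.0, 0.0))


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class ComplexObject3D:
    """Voxelized particle rho(r) = s(r) * exp(i * phi(r)).

    ``amplitude`` is the (edge-smoothed) shape function in [0, 1] and
    ``phase`` the interior phase in [-pi, pi], defined as 0 outside the
    support.  Nonzero voxels are confined to the central half-cube.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase shapes differ")
        if self.amplitude.shape != (self.grid.n_obj,) * 3:
            raise ValueError("arrays do not match the grid")

    @property
    def density(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)

    @property
    def support(self) -> np.ndarray:
        return self.amplitude > 0


@dataclass
class ComplexImage2D:
    """Projected amplitude + phase image (half the detector size)."""

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase shapes differ")

    @property
    def density(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class DiffractionPattern:
    """2D oversampled diffraction intensity, zero frequency at the center."""

    intensity: np.ndarray

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity)
        if inten.ndim != 2 or inten.shape[0] != inten.shape[1]:
            raise ValueError("intensity must be a square 2D array")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensity must be finite")
        if inten.min() < 0:
            raise ValueError("intensity must be nonnegative")

    @property
    def modulus(self) -> np.ndarray:
        return np.sqrt(self.intensity)


@dataclass
class TrainingSample:
    pattern: DiffractionPattern
    target_amplitude: np.ndarray
    target_phase_scaled: np.ndarray
    provenance: dict


@dataclass
class Dataset:
    samples: list[TrainingSample]
    train_idx: np.ndarray
    val_idx: np.ndarray
    meta: dict

    def __len__(self) -> int:
        return len(self.samples)

    def patterns(self, idx: Sequence[int] | None = None) -> np.ndarray:
        idx = range(len(self.samples)) if idx is None else idx
        return np.stack([self.samples[i].pattern.intensity for i in idx])

    def amplitudes(self, idx: Sequence[int] | None = None) -> np.ndarray:
        idx = range(len(self.samples)) if idx is None else idx
        return np.stack([self.samples[i].target_amplitude for i in idx])

    def phases_scaled(self, idx: Sequence[int] | None = None) -> np.ndarray:
        idx = range(len(self.samples)) if idx is None else idx
        return np.stack([self.samples[i].target_phase_scaled for i in idx])


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def voxelize_superellipsoid(grid: GridSpec, params: SuperellipsoidParams) -> np.ndarray:
    """Binary occupancy of the superellipsoid implicit solid.

    The implicit form is the standard two-exponent one,

        (( |x/a|^(2/e) + |y/b|^(2/e) )^(e/n) + |z/c|^(2/n)) <= 1,

    which reduces to the ellipsoid for e = n = 1 and to the octahedron
    |x/a| + |y/b| + |z/c| <= 1 for e = n = 2.
    """
    quarter = grid.n_obj / 4.0
    for name in ("a", "b", "c"):
        if getattr(params, name) > quarter:
            raise ValueError(
                f"semi-axis {name}={getattr(params, name)} exceeds n_obj/4="
                f"{quarter}; the particle would break the oversampling bound"
            )
    x = grid.axis_coords()[:, None, None]
    y = grid.axis_coords()[None, :, None]
    z = grid.axis_coords()[None, None, :]
    with np.errstate(divide="ignore"):
        eq = (
            np.abs(x / params.a) ** (2.0 / params.e)
            + np.abs(y / params.b) ** (2.0 / params.e)
        ) ** (params.e / params.n) + np.abs(z / params.c) ** (2.0 / params.n)
    return eq <= 1.0


def sample_phase_field(grid: GridSpec, params: PhaseFieldParams) -> np.ndarray:
    """Gaussian-correlated random field for the interior phase.

    Uncorrelated Gaussian noise is convolved with the separable kernel
    exp(-x^2/L_x^2 - y^2/L_y^2 - z^2/L_z^2); the resulting field has a
    Gaussian autocorrelation whose 1/e half-width is sqrt(2)*L along each
    axis.  The field is affinely rescaled so its values span
    [-phase_span/2, +phase_span/2]; the span attained inside a particular
    particle support is therefore at most phase_span, approaching it as
    the particle volume grows.
    """
    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal((grid.n_obj,) * 3)
    sigma = np.array([params.L_x, params.L_y, params.L_z]) / np.sqrt(2.0)
    fld = gaussian_filter(noise, sigma=sigma, mode="wrap")
    lo, hi = fld.min(), fld.max()
    if hi - lo < 1e-30:
        return np.zeros_like(fld)
    return (fld - (hi + lo) / 2.0) * (params.phase_span / (hi - lo))


def assemble_object(
    mask: np.ndarray,
    phase_field: np.ndarray,
    smoothing_sigma: float = 1.0,
    grid: GridSpec | None = None,
) -> ComplexObject3D:
    """Combine a shape mask and phase field into a complex particle.

    The amplitude is the Gaussian-smoothed mask (renormalized to max 1);
    the phase is the field restricted to the unsmoothed mask.  Amplitude
    outside the central half-cube is zeroed so the oversampling support
    bound holds exactly even when the smoothing tail would leak past it.
    """
    if mask.shape != phase_field.shape:
        raise ValueError("mask and phase field shapes differ")
    if grid is None:
        grid = GridSpec(mask.shape[0], mask.shape[0])
    if not mask.any():
        raise ValueError("empty particle mask")
    if smoothing_sigma > 0:
        amp = gaussian_filter(mask.astype(float), sigma=smoothing_sigma)
    else:
        amp = mask.astype(float)
    keep = np.zeros_like(amp, dtype=bool)
    keep[grid.central_cube()] = True
    amp[~keep] = 0.0
    amp[amp < 1e-8] = 0.0
    amp /= amp.max()
    phase = np.where(mask & (amp > 0), phase_field, 0.0)
    return ComplexObject3D(amplitude=amp, phase=phase, grid=grid)


def random_orientation(rng: np.random.Generator) -> Orientation:
    # Shoemake's subgroup algorithm: uniform on SO(3)
    u1, u2, u3 = rng.uniform(size=3)
    q = (
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
    )
    q = tuple(np.asarray(q) / np.linalg.norm(q))
    return Orientation(q)


def rotate_object(obj: ComplexObject3D, orientation: Orientation) -> ComplexObject3D:
    """Rigidly rotate amplitude and phase about the grid center.

    Trilinear resampling with zero fill; both arrays are resampled
    identically and the phase is re-masked so amplitude == 0 still
    implies phase == 0.
    """
    grid = obj.grid
    rot = orientation.matrix
    c = np.full(3, grid.center)
    # affine_transform maps output coords through `matrix` to input coords
    inv = rot.T
    offset = c - inv @ c
    amp = affine_transform(obj.amplitude, inv, offset=offset, order=1, mode="constant", cval=0.0)
    phase = affine_transform(obj.phase, inv, offset=offset, order=1, mode="constant", cval=0.0)
    amp = np.clip(amp, 0.0, None)
    keep = np.zeros_like(amp, dtype=bool)
    keep[grid.central_cube()] = True
    amp[~keep] = 0.0
    amp[amp < 1e-8] = 0.0
    phase[amp == 0] = 0.0
    return ComplexObject3D(amplitude=amp, phase=phase, grid=grid)


# --------------------------------------------------------------------------
# randomized particle sampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatorConfig:
    """Sampling ranges for the randomized particle generator.

    Defaults scale with the grid: semi-axes up to n_obj/4 (the oversampling
    bound), roundedness exponents in [0.5, 3] spanning boxy-to-pointy
    shapes, correlation lengths from 2 voxels up to n_obj/4.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    semi_axis_range: tuple[float, float] | None = None
    exponent_range: tuple[float, float] = (0.5, 3.0)
    corr_length_range: tuple[float, float] | None = None
    phase_span: float = 2 * np.pi
    smoothing_sigma: float = 1.0
    train_fraction: float = 0.95

    def resolved_semi_axis_range(self) -> tuple[float, float]:
        r = self.semi_axis_range or (4.0, self.grid.n_obj / 4.0)
        if r[0] >= r[1]:
            raise ValueError("empty semi-axis range")
        return r

    def resolved_corr_length_range(self) -> tuple[float, float]:
        r = self.corr_length_range or (2.0, self.grid.n_obj / 4.0)
        if r[0] >= r[1]:
            raise ValueError("empty correlation-length range")
        return r

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = {"n_obj": self.grid.n_obj, "n_det": self.grid.n_det}
        d["semi_axis_range"] = list(self.resolved_semi_axis_range())
        d["corr_length_range"] = list(self.resolved_corr_length_range())
        return d


def sample_random_particle(
    config: SimulatorConfig, seed: int
) -> tuple[ComplexObject3D, dict]:
    """Draw one random particle; deterministic in (config, seed).

    Shapes whose circumscribed radius would leave the central half-cube
    under rotation (possible for boxy exponents e, n < 1) are isotropically
    shrunk to fit; the provenance records the final semi-axes.
    """
    grid = config.grid
    rng = np.random.default_rng(seed)
    lo_a, hi_a = config.resolved_semi_axis_range()
    lo_e, hi_e = config.exponent_range
    lo_L, hi_L = config.resolved_corr_length_range()
    a, b, c = rng.uniform(lo_a, hi_a, size=3)
    e, n = rng.uniform(lo_e, hi_e, size=2)
    Ls = rng.uniform(lo_L, hi_L, size=3)
    orientation = random_orientation(rng)
    field_seed = int(rng.integers(0, 2**31 - 1))

    se = SuperellipsoidParams(a=a, b=b, c=c, e=e, n=n)
    mask = voxelize_superellipsoid(grid, se)
    # rotation safety: keep the circumscribed sphere inside the half-cube
    # with room for the smoothing tail and trilinear resampling
    limit = grid.n_obj / 4.0 - 2.0 * config.smoothing_sigma - 1.0
    coords = np.argwhere(mask) - grid.center
    radius = float(np.sqrt((coords**2).sum(axis=1).max())) if len(coords) else 0.0
    if radius > limit > 0:
        shrink = limit / radius
        se = SuperellipsoidParams(a=a * shrink, b=b * shrink, c=c * shrink, e=e, n=n)
        mask = voxelize_superellipsoid(grid, se)
    if not mask.any():
        # degenerate draw (tiny shrunk shape): fall back to a minimal ball
        se = SuperellipsoidParams(a=lo_a, b=lo_a, c=lo_a, e=1.0, n=1.0)
        mask = voxelize_superellipsoid(grid, se)

    pf = PhaseFieldParams(
        L_x=Ls[0], L_y=Ls[1], L_z=Ls[2], phase_span=config.phase_span, seed=field_seed
    )
    fld = sample_phase_field(grid, pf)
    obj = assemble_object(mask, fld, config.smoothing_sigma, grid)
    obj = rotate_object(obj, orientation)
    provenance = {
        "seed": seed,
        "a": se.a, "b": se.b, "c": se.c, "e": se.e, "n": se.n,
        "L_x": pf.L_x, "L_y": pf.L_y, "L_z": pf.L_z,
        "phase_span": config.phase_span,
        "field_seed": field_seed,
        "quaternion": list(orientation.q),
    }
    return obj, provenance


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

def scale_phase(phase: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Fixed affine map of phase [-pi, pi] -> (0, 1), zero outside support."""
    return np.where(support, (phase + np.pi) / (2 * np.pi), 0.0)


def unscale_phase(phase_scaled: np.ndarray, support: np.ndarray) -> np.ndarray:
    return np.where(support, 2 * np.pi * phase_scaled - np.pi, 0.0)


def make_training_sample(
    obj: ComplexObject3D, provenance: dict | None = None, axis: str = "z"
) -> TrainingSample:
    """Pattern + half-frame ground truth for one particle.

    The pattern is the central slice of the 3D intensity; by the Fourier
    slice theorem it equals the 2D diffraction of the complex projection
    along the same axis, so that projection (cropped to the central
    half-frame) is the self-consistent ground truth.
    """
    from . import forward_model as fm  # local import: fm uses these containers

    pattern = fm.central_slice(fm.diffract_3d(obj), axis=axis)
    _, image = fm.project(obj, axis=axis)
    support = image.amplitude > 0
    return TrainingSample(
        pattern=pattern,
        target_amplitude=image.amplitude,
        target_phase_scaled=scale_phase(image.phase, support),
        provenance=provenance or {},
    )


def simulate_dataset(config: SimulatorConfig, n_samples: int, seed: int) -> Dataset:
    """Generate ``n_samples`` pattern/ground-truth pairs with a train/val split."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    root = np.random.default_rng(seed)
    sample_seeds = root.integers(0, 2**31 - 1, size=n_samples)
    samples = []
    for s in sample_seeds:
        obj, prov = sample_random_particle(config, int(s))
        samples.append(make_training_sample(obj, prov))
    n_train = int(round(config.train_fraction * n_samples))
    n_train = min(max(n_train, 0), n_samples)
    idx = np.arange(n_samples)
    meta = {
        "seed": seed,
        "n_samples": n_samples,
        "config": config.to_dict(),
    }
    return Dataset(
        samples=samples,
        train_idx=idx[:n_train],
        val_idx=idx[n_train:],
        meta=meta,
    )
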