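"""Classical iterative phase retrieval in 2D.

Error reduction (ER) alternates projections between the Fourier-modulus
constraint (replace the modulus of the transform with the measured one,
keep the phase) and the support constraint (zero outside the support).
Hybrid input-output (HIO) relaxes the support projection with a feedback
parameter beta to escape stagnation.  Shrink-wrap periodically re-estimates
the support by blurring the current amplitude and thresholding at a fraction
of its maximum, letting the support both grow and shrink.

The per-iteration error is the modulus-domain chi^2 recorded before each
magnitude projection.  No positivity constraint is applied by default: the
targets here are complex strong-phase objects for which real-space
positivity is wrong.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .baselines import chi2_modulus
from .forward_model import cfft2, cifft2, crop_center, embed_centered
from .simulator import ComplexImage2D, DiffractionPattern

__all__ = [
    "Support",
    "PRState",
    "ScheduleStep",
    "ShrinkwrapSpec",
    "ErrorTrace",
    "er_step",
    "hio_step",
    "shrink_wrap",
    "support_from_amplitude",
    "rectangle_support",
    "default_schedule",
    "run_schedule",
    "state_to_image",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class Support:
    """Binary real-space mask of where the object may be nonzero."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("support must be nonempty")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class PRState:
    """One iterate of the retrieval loop.

    ``measured_modulus`` (the square root of the recorded intensity) is
    fixed for the lifetime of a run; ``iterate`` is the current complex
    real-space estimate on the full detector frame.
    """

    iterate: np.ndarray
    support: Support
    measured_modulus: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        if self.iterate.shape != self.measured_modulus.shape:
            raise ValueError("iterate and measured modulus shapes differ")
        if self.iterate.shape != self.support.mask.shape:
            raise ValueError("iterate and support shapes differ")
        if not np.all(np.isfinite(self.iterate)):
            raise ValueError("iterate must be finite")
        if self.measured_modulus.min() < 0:
            raise ValueError("measured modulus must be nonnegative")
        if self.measured_modulus.max() == 0:
            raise ValueError("measured modulus is identically zero")


@dataclass(frozen=True)
class ShrinkwrapSpec:
    """Periodic support re-estimation: blur |iterate| and threshold."""

    period: int = 30
    sigma: float = 3.0
    threshold_fraction: float = 0.1
    sigma_decay: float = 0.95
    sigma_min: float = 1.0


@dataclass(frozen=True)
class ScheduleStep:
    algorithm: str  # "ER" | "HIO"
    n_iter: int
    beta: float = 0.9
    shrinkwrap: ShrinkwrapSpec | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ("ER", "HIO"):
            raise ValueError("algorithm must be 'ER' or 'HIO'")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not (0 <= self.beta <= 1):
            raise ValueError("beta must lie in [0, 1]")


@dataclass
class ErrorTrace:
    chi2: list[float] = field(default_factory=list)
    algorithm: list[str] = field(default_factory=list)

    def append(self, value: float, label: str) -> None:
        self.chi2.append(float(value))
        self.algorithm.append(label)

    def __len__(self) -> int:
        return len(self.chi2)


# --------------------------------------------------------------------------
# projections and update rules
# --------------------------------------------------------------------------

def _magnitude_projection(
    iterate: np.ndarray, measured: np.ndarray
) -> tuple[np.ndarray, float]:
    """Fourier-domain modulus replacement; returns (projected, chi^2).

    chi^2 is evaluated on the pre-projection modulus, the conventional
    error-versus-iteration quantity.
    """
    F = cfft2(iterate)
    mod = np.abs(F)
    err = chi2_modulus(mod, measured)
    with np.errstate(invalid="ignore", divide="ignore"):
        phase_factor = np.where(mod > 0, F / mod, 1.0)
    return cifft2(measured * phase_factor), err


def er_step(state: PRState) -> tuple[PRState, float]:
    """One error-reduction iteration (magnitude projection, then support)."""
    projected, err = _magnitude_projection(state.iterate, state.measured_modulus)
    new = np.where(state.support.mask, projected, 0.0)
    return (
        PRState(new, state.support, state.measured_modulus, state.iteration + 1),
        err,
    )


def hio_step(state: PRState, beta: float = 0.9) -> tuple[PRState, float]:
    """One hybrid input-output iteration.

    Inside the support the magnitude-projected value is kept; outside, the
    previous iterate minus beta times the projected value.
    """
    if not (0 <= beta <= 1):
        raise ValueError("beta must lie in [0, 1]")
    projected, err = _magnitude_projection(state.iterate, state.measured_modulus)
    new = np.where(state.support.mask, projected, state.iterate - beta * projected)
    return (
        PRState(new, state.support, state.measured_modulus, state.iteration + 1),
        err,
    )


def shrink_wrap(state: PRState, sigma: float, threshold_fraction: float) -> Support:
    """Re-estimate the support from the blurred amplitude of the iterate."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    amp = np.abs(state.iterate)
    blurred = gaussian_filter(amp, sigma=sigma) if sigma > 0 else amp
    mask = blurred >= threshold_fraction * blurred.max()
    if not mask.any():
        raise ValueError(
            "shrink-wrap produced an empty support; lower threshold_fraction"
        )
    return Support(mask=mask)


def support_from_amplitude(
    amp: np.ndarray, threshold_fraction: float, frame_size: int | None = None
) -> Support:
    """Binarize a (predicted) amplitude into a support mask.

    The mask keeps pixels at or above ``threshold_fraction`` of the maximum
    and is zero-embedded centered into the full detector frame when
    ``frame_size`` exceeds the amplitude frame.
    """
    amp = np.asarray(amp, dtype=float)
    if amp.min() < 0:
        raise ValueError("amplitude must be nonnegative")
    if amp.max() == 0:
        raise ValueError("amplitude is identically zero")
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    mask = amp >= threshold_fraction * amp.max()
    if frame_size is not None and frame_size != amp.shape[0]:
        mask = embed_centered(mask.astype(np.uint8), frame_size).astype(bool)
    return Support(mask=mask)


def rectangle_support(n_det: int) -> Support:
    """The central n_det/2 square: the generic oversampling support."""
    mask = embed_centered(np.ones((n_det // 2, n_det // 2), dtype=np.uint8), n_det)
    return Support(mask=mask.astype(bool))


# --------------------------------------------------------------------------
# schedules
# --------------------------------------------------------------------------

def default_schedule(
    beta: float = 0.9, shrinkwrap: ShrinkwrapSpec | None = None
) -> list[ScheduleStep]:
    """20 ER, then 5 cycles of (100 HIO + 20 ER): 620 iterations total.

    Standard CDI practice: an ER warm-up, long HIO stretches to escape
    local minima, short ER blocks to settle, ER at the end.  Shrink-wrap,
    when supplied, is applied at its period within every step.
    """
    steps = [ScheduleStep("ER", 20, beta, shrinkwrap)]
    for _ in range(5):
        steps.append(ScheduleStep("HIO", 100, beta, shrinkwrap))
        steps.append(ScheduleStep("ER", 20, beta, shrinkwrap))
    return steps


def state_to_image(state: PRState, support_eps: float = 1e-3) -> ComplexImage2D:
    """Central half-frame crop of the iterate as an amplitude/phase image."""
    half = state.iterate.shape[0] // 2
    crop = crop_center(state.iterate, half)
    amp = np.abs(crop)
    peak = amp.max()
    if peak > 0:
        amp = amp / peak
    mask = amp >= support_eps
    amp = np.where(mask, amp, 0.0)
    phase = np.where(mask, np.angle(crop), 0.0)
    return ComplexImage2D(amplitude=amp, phase=phase)


def run_schedule(
    pattern: DiffractionPattern,
    init_phase: np.ndarray | str,
    init_support: Support,
    schedule: list[ScheduleStep],
    seed: int = 0,
    init_image: np.ndarray | None = None,
) -> tuple[ComplexImage2D, ErrorTrace]:
    """Execute an algorithm switch schedule from a chosen initialization.

    Initialization options:
      * ``init_phase="random"`` — uniform random Fourier phase in (-pi, pi]
        applied to the measured modulus (seeded);
      * ``init_phase`` an array — that Fourier phase applied to the modulus;
      * ``init_image`` — a complex real-space starting image (e.g. the CNN
        or NNS prediction), zero-embedded centered to the detector frame;
        overrides ``init_phase``.

    Returns the central half-frame reconstruction and the chi^2-per-iteration
    trace.  Deterministic given (inputs, seed).
    """
    if not schedule:
        raise ValueError("schedule must contain at least one step")
    measured = pattern.modulus
    n = measured.shape[0]
    if init_support.mask.shape != measured.shape:
        raise ValueError("support and pattern shapes differ")

    if init_image is not None:
        img = np.asarray(init_image, dtype=complex)
        iterate = img if img.shape == measured.shape else embed_centered(img, n)
    elif isinstance(init_phase, str):
        if init_phase != "random":
            raise ValueError("init_phase must be an array or 'random'")
        rng = np.random.default_rng(seed)
        theta = rng.uniform(-np.pi, np.pi, size=measured.shape)
        iterate = cifft2(measured * np.exp(1j * theta))
    else:
        theta = np.asarray(init_phase, dtype=float)
        if theta.shape != measured.shape:
            raise ValueError("init_phase shape does not match the pattern")
        iterate = cifft2(measured * np.exp(1j * theta))

    state = PRState(iterate, copy.deepcopy(init_support), measured)
    trace = ErrorTrace()
    for step in schedule:
        for k in range(step.n_iter):
            if step.algorithm == "ER":
                state, err = er_step(state)
            else:
                state, err = hio_step(state, step.beta)
            trace.append(err, step.algorithm)
            sw = step.shrinkwrap
            if sw is not None and state.iteration % sw.period == 0:
                n_events = state.iteration // sw.period
                sigma = max(sw.sigma * sw.sigma_decay ** (n_events - 1), sw.sigma_min)
                state = PRState(
                    state.iterate,
                    shrink_wrap(state, sigma, sw.threshold_fraction),
                    state.measured_modulus,
                    state.iteration,
                )
    return state_to_image(state), trace
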