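"""Error metrics, ambiguity alignment, the nearest-neighbour-search baseline,
Gamma-distribution error summaries and 2D phase unwrapping.

The quality metric throughout is the normalized quadratic misfit

    chi^2 = sum((calc - meas)^2) / sum(meas^2),

applied to diffraction moduli in reciprocal space and to amplitude / scaled
phase images in real space.  Iterative reconstructions are compared to truth
only after removing the trivial ambiguities of the phase problem (integer
translation, global phase offset, conjugate twin); CNN outputs live in a
fixed centered frame and are compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.restoration import unwrap_phase as _sk_unwrap

from .simulator import ComplexImage2D, Dataset, DiffractionPattern

__all__ = [
    "chi2_modulus",
    "chi2_real",
    "align_reconstruction",
    "NNSIndex",
    "build_nns_index",
    "nns_query",
    "GammaFit",
    "fit_gamma",
    "wrap_phase",
    "unwrap_phase_2d",
]


# --------------------------------------------------------------------------
# chi^2 metrics
# --------------------------------------------------------------------------

def chi2_modulus(calc: np.ndarray, meas: np.ndarray) -> float:
    """Normalized quadratic misfit between two nonnegative modulus arrays."""
    calc = np.asarray(calc, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if calc.shape != meas.shape:
        raise ValueError("shape mismatch")
    if calc.min() < 0 or meas.min() < 0:
        raise ValueError("moduli must be nonnegative")
    denom = float((meas**2).sum())
    if denom == 0:
        raise ValueError("measured modulus is identically zero")
    return float(((calc - meas) ** 2).sum() / denom)


def chi2_real(
    pred: np.ndarray | ComplexImage2D,
    truth: np.ndarray | ComplexImage2D,
    align: bool = False,
) -> float:
    """chi^2 on real-space images (amplitude or scaled phase).

    With ``align=True`` the arguments must be ComplexImage2D and the
    prediction is first brought onto the truth frame by removing the
    trivial phase-retrieval ambiguities; the metric is then evaluated on
    the complex densities.
    """
    if align:
        if not isinstance(pred, ComplexImage2D) or not isinstance(truth, ComplexImage2D):
            raise TypeError("alignment requires ComplexImage2D inputs")
        aligned = align_reconstruction(pred, truth)
        p = aligned.density
        t = truth.density
        denom = float((np.abs(t) ** 2).sum())
        if denom == 0:
            raise ValueError("truth image is identically zero")
        return float((np.abs(p - t) ** 2).sum() / denom)
    p = pred.amplitude if isinstance(pred, ComplexImage2D) else np.asarray(pred, dtype=float)
    t = truth.amplitude if isinstance(truth, ComplexImage2D) else np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    denom = float((t**2).sum())
    if denom == 0:
        raise ValueError("truth image is identically zero")
    return float(((p - t) ** 2).sum() / denom)


# --------------------------------------------------------------------------
# trivial-ambiguity alignment
# --------------------------------------------------------------------------

def _twin(z: np.ndarray) -> np.ndarray:
    # conjugate of the coordinate-inverted image: the indistinguishable
    # twin solution of the modulus-only problem.  Inversion about the
    # zero-frequency-consistent center i -> (-i) mod n.
    flip = z[::-1, ::-1]
    return np.conj(np.roll(flip, shift=(1, 1), axis=(0, 1)))


def _best_shift(cand: np.ndarray, truth: np.ndarray) -> tuple[tuple[int, int], complex, float]:
    """Integer translation + global phase minimizing ||shift(cand)*e^{ia} - truth||^2.

    The cross-correlation over all cyclic shifts is computed by FFT; for a
    given shift the optimal global phase is the argument of the correlation
    and the residual is ||cand||^2 + ||truth||^2 - 2|corr|.
    """
    F_c = np.fft.fft2(cand)
    F_t = np.fft.fft2(truth)
    corr = np.fft.ifft2(F_c * np.conj(F_t))  # corr[s] = sum_x cand[x+s] conj(truth[x])
    mag = np.abs(corr)
    s = np.unravel_index(int(np.argmax(mag)), mag.shape)
    phase = np.exp(-1j * np.angle(corr[s]))
    resid = float((np.abs(cand) ** 2).sum() + (np.abs(truth) ** 2).sum() - 2 * mag[s])
    # corr is maximal for cand shifted *back* by s
    return (-s[0] % cand.shape[0], -s[1] % cand.shape[1]), phase, resid


def _subpixel_shift(z: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Cyclically translate a complex image by a real-valued shift."""
    n0, n1 = z.shape
    k0 = np.fft.fftfreq(n0)[:, None]
    k1 = np.fft.fftfreq(n1)[None, :]
    ramp = np.exp(-2j * np.pi * (k0 * shift[0] + k1 * shift[1]))
    return np.fft.ifft2(np.fft.fft2(z) * ramp)


def _refine_shift(cand: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """Sub-pixel translation + global phase minimizing the complex L2 residual.

    A fractional translation multiplies the Fourier transform by a pure
    phase ramp and therefore preserves the modulus exactly: it is part of
    the translation ambiguity of the phase problem even though integer
    cross-correlation cannot see it.  The cross-correlation magnitude is
    maximised over real-valued shifts with a local simplex search seeded
    at zero (the integer alignment having already been applied).
    """
    from scipy.optimize import minimize

    X = np.fft.fft2(cand) * np.conj(np.fft.fft2(truth))
    n0, n1 = cand.shape
    k0 = np.fft.fftfreq(n0)[:, None]
    k1 = np.fft.fftfreq(n1)[None, :]

    def corr(s):
        # corr(s) = sum_x cand(x + s) conj(truth(x))
        return (X * np.exp(2j * np.pi * (k0 * s[0] + k1 * s[1]))).sum() / (n0 * n1)

    res = minimize(
        lambda s: -np.abs(corr(s)), x0=np.zeros(2), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12},
    )
    s = res.x
    c = corr(s)
    out = _subpixel_shift(cand, (-s[0], -s[1])) * np.exp(-1j * np.angle(c))
    resid = float(
        (np.abs(cand) ** 2).sum() + (np.abs(truth) ** 2).sum() - 2 * np.abs(c)
    )
    return out, resid


def align_reconstruction(
    recon: ComplexImage2D, truth: ComplexImage2D, subpixel: bool = True
) -> ComplexImage2D:
    """Remove translation, global phase and twin ambiguities against truth.

    Searches {recon, conjugate-inverted recon} x cyclic translations x
    global phase offsets for the candidate closest to truth in complex L2.
    Integer translations are found exactly by FFT cross-correlation; with
    ``subpixel=True`` the shift is then refined to sub-pixel precision
    (a modulus-preserving ambiguity of the phase problem).
    """
    t = truth.density
    best = None
    for cand in (recon.density, _twin(recon.density)):
        shift, phase, resid = _best_shift(cand, t)
        if best is None or resid < best[3]:
            best = (cand, shift, phase, resid)
    cand, shift, phase, resid = best
    out = np.roll(cand, shift=shift, axis=(0, 1)) * phase
    if subpixel:
        refined, r_resid = _refine_shift(np.roll(cand, shift=shift, axis=(0, 1)), t)
        if r_resid < resid:
            out = refined
    amp = np.abs(out)
    ang = np.where(amp > 0, np.angle(out), 0.0)
    return ComplexImage2D(amplitude=amp, phase=ang)


# --------------------------------------------------------------------------
# nearest-neighbour-search baseline
# --------------------------------------------------------------------------

@dataclass
class NNSIndex:
    """Brute-force lookup table of reference diffraction moduli.

    Moduli are max-normalized (the same normalization applied to queries);
    each reference keeps a handle to its ground-truth amplitude / scaled
    phase images so a match can seed iterative refinement.
    """

    moduli: np.ndarray  # (n_ref, n*n), max-normalized, flattened
    amplitudes: np.ndarray  # (n_ref, n/2, n/2)
    phases_scaled: np.ndarray  # (n_ref, n/2, n/2)
    ref_ids: np.ndarray  # indices into the source dataset

    def __post_init__(self) -> None:
        if len(self.moduli) < 1:
            raise ValueError("NNS index needs at least one reference")

    def __len__(self) -> int:
        return len(self.moduli)


def _norm_modulus(intensity: np.ndarray) -> np.ndarray:
    m = np.sqrt(np.asarray(intensity, dtype=float))
    peak = m.max()
    if peak == 0:
        raise ValueError("empty pattern")
    return m / peak


def build_nns_index(dataset: Dataset, indices: np.ndarray | None = None) -> NNSIndex:
    idx = dataset.train_idx if indices is None else np.asarray(indices)
    moduli = np.stack(
        [_norm_modulus(dataset.samples[i].pattern.intensity).ravel() for i in idx]
    )
    return NNSIndex(
        moduli=moduli,
        amplitudes=dataset.amplitudes(idx),
        phases_scaled=dataset.phases_scaled(idx),
        ref_ids=np.asarray(idx),
    )


def nns_query(index: NNSIndex, pattern: DiffractionPattern) -> tuple[dict, float]:
    """Exhaustive scan for the reference modulus with minimum chi^2.

    Returns the matched record (ground-truth amplitude / scaled phase and
    its dataset id) and the chi^2 of the match.
    """
    q = _norm_modulus(pattern.intensity).ravel()
    if q.size != index.moduli.shape[1]:
        raise ValueError("query pattern shape does not match the index")
    R = index.moduli
    denom = (R**2).sum(axis=1)
    chi2 = np.maximum(((q**2).sum() - 2 * R @ q + denom) / denom, 0.0)
    k = int(np.argmin(chi2))
    record = {
        "ref_id": int(index.ref_ids[k]),
        "amplitude": index.amplitudes[k],
        "phase_scaled": index.phases_scaled[k],
    }
    return record, float(chi2[k])


# --------------------------------------------------------------------------
# Gamma error summaries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaFit:
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Gamma parameters must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale


def fit_gamma(errors: np.ndarray) -> GammaFit:
    """Maximum-likelihood Gamma fit of an error population (loc fixed at 0)."""
    x = np.asarray(errors, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 error values for a Gamma fit")
    if np.any(x <= 0):
        raise ValueError("Gamma fit requires strictly positive errors")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) error population; Gamma fit undefined")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    return GammaFit(shape=float(shape), scale=float(scale))


# --------------------------------------------------------------------------
# 2D phase unwrapping
# --------------------------------------------------------------------------

def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap into [-pi, pi)."""
    return (np.asarray(phase) + np.pi) % (2 * np.pi) - np.pi


def unwrap_phase_2d(phase: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Reliability-ordered region-growing 2D unwrapping inside ``mask``.

    Adds integer multiples of 2*pi pointwise so the in-mask field varies
    continuously; pixels outside the mask are returned unchanged.  Fields
    containing residues are unwrapped best-effort.
    """
    phase = np.asarray(phase, dtype=float)
    if mask is None:
        mask = np.ones(phase.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != phase.shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        return phase.copy()
    marr = np.ma.array(phase, mask=~mask)
    out = np.asarray(_sk_unwrap(marr))
    # snap the added offsets to exact multiples of 2*pi
    k = np.round((out - phase) / (2 * np.pi))
    res = phase + 2 * np.pi * k
    return np.where(mask, res, phase)
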