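"""Four-arm comparison of iterative phase retrieval initializations.

For each held-out pattern the same algorithm switch schedule is run from:

  (i)   random Fourier phase + the generic central rectangle support;
  (ii)  random Fourier phase + the support binarized from the CNN amplitude;
  (iii) the CNN amplitude and phase as the starting image + CNN support;
  (iv)  the NNS best match (amplitude, phase) as starting image + its support.

Random arms are repeated over independent seeds; the report records the
starting and final modulus-domain chi^2 of every run and the mean trace per
arm.  The hybrid arm (iii) is the CNN-seeded refinement whose final error is
compared against what the CNN and the iterative method reach alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import NNSIndex, nns_query
from .neural_inverter import TrainedModel, _chi2_modulus_of_image, infer
from .phase_retrieval import (
    ScheduleStep,
    Support,
    default_schedule,
    rectangle_support,
    run_schedule,
    support_from_amplitude,
)
from .simulator import ComplexImage2D, Dataset, unscale_phase

__all__ = ["ArmResult", "BenchmarkReport", "run_benchmark", "ARM_LABELS"]

ARM_LABELS = {
    "random_box": "random phase + rectangle support",
    "random_cnn_support": "random phase + CNN support",
    "cnn_init": "CNN phase + CNN support (hybrid)",
    "nns_init": "NNS match as initialization",
}


@dataclass
class ArmResult:
    label: str
    start_chi2: list[float] = field(default_factory=list)
    final_chi2: list[float] = field(default_factory=list)
    traces: list[list[float]] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "start_mean": float(np.mean(self.start_chi2)),
            "start_sd": float(np.std(self.start_chi2)),
            "final_mean": float(np.mean(self.final_chi2)),
            "final_sd": float(np.std(self.final_chi2)),
            "n_runs": len(self.final_chi2),
        }

    def mean_trace(self) -> np.ndarray:
        return np.mean(np.asarray(self.traces), axis=0)

    def sd_trace(self) -> np.ndarray:
        return np.std(np.asarray(self.traces), axis=0)


@dataclass
class BenchmarkReport:
    arms: dict[str, ArmResult]
    cnn_chi2: list[float]
    nns_chi2: list[float]
    n_queries: int
    replicates: int
    seed: int

    def summary(self) -> dict:
        out = {name: arm.summary() for name, arm in self.arms.items()}
        out["cnn_alone"] = {
            "final_mean": float(np.mean(self.cnn_chi2)),
            "final_sd": float(np.std(self.cnn_chi2)),
            "n_runs": len(self.cnn_chi2),
        }
        out["nns_alone"] = {
            "final_mean": float(np.mean(self.nns_chi2)),
            "final_sd": float(np.std(self.nns_chi2)),
            "n_runs": len(self.nns_chi2),
        }
        return out


def _image_from_record(record: dict) -> ComplexImage2D:
    amp = record["amplitude"]
    support = amp > 0
    return ComplexImage2D(
        amplitude=amp, phase=unscale_phase(record["phase_scaled"], support)
    )


def run_benchmark(
    dataset: Dataset,
    trained: TrainedModel,
    index: NNSIndex,
    n_queries: int = 4,
    replicates: int = 8,
    seed: int = 0,
    schedule: list[ScheduleStep] | None = None,
    support_threshold: float = 0.1,
) -> BenchmarkReport:
    """Run all four arms on the first ``n_queries`` validation patterns."""
    if len(dataset.val_idx) < n_queries:
        raise ValueError("not enough validation samples for the requested queries")
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(seed)
    n_det = dataset.samples[0].pattern.intensity.shape[0]
    arms = {name: ArmResult(label=lbl) for name, lbl in ARM_LABELS.items()}
    cnn_chi2: list[float] = []
    nns_chi2: list[float] = []

    for qi in dataset.val_idx[:n_queries]:
        sample = dataset.samples[int(qi)]
        pattern = sample.pattern
        cnn_image, _ = infer(trained, pattern)
        cnn_chi2.append(_chi2_modulus_of_image(cnn_image, pattern))
        cnn_support = support_from_amplitude(
            cnn_image.amplitude, support_threshold, frame_size=n_det
        )
        record, nns_err = nns_query(index, pattern)
        nns_chi2.append(nns_err)
        nns_image = _image_from_record(record)
        nns_support = support_from_amplitude(
            np.asarray(record["amplitude"]), support_threshold, frame_size=n_det
        )
        box = rectangle_support(n_det)

        for _ in range(replicates):
            run_seed = int(rng.integers(0, 2**31 - 1))
            _run_arm(arms["random_box"], pattern, "random", box, schedule, run_seed)
            _run_arm(
                arms["random_cnn_support"], pattern, "random", cnn_support,
                schedule, run_seed,
            )
        _run_arm(
            arms["cnn_init"], pattern, None, cnn_support, schedule, 0,
            init_image=cnn_image.density,
        )
        _run_arm(
            arms["nns_init"], pattern, None, nns_support, schedule, 0,
            init_image=nns_image.density,
        )

    return BenchmarkReport(
        arms=arms, cnn_chi2=cnn_chi2, nns_chi2=nns_chi2,
        n_queries=n_queries, replicates=replicates, seed=seed,
    )


def _run_arm(
    arm: ArmResult,
    pattern,
    init_phase,
    support: Support,
    schedule,
    seed: int,
    init_image=None,
) -> None:
    _, trace = run_schedule(
        pattern,
        init_phase if init_phase is not None else "random",
        support,
        schedule,
        seed=seed,
        init_image=init_image,
    )
    # a random-phase start sits exactly on the modulus constraint, so its
    # first recorded chi^2 is zero by construction; the meaningful starting
    # error for every arm is the one after the first full iteration, once
    # both constraints have acted on the iterate
    start = trace.chi2[1] if len(trace.chi2) > 1 else trace.chi2[0]
    arm.start_chi2.append(start)
    arm.final_chi2.append(trace.chi2[-1])
    arm.traces.append(trace.chi2)
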