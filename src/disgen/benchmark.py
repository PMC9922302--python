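"""Sampling-efficiency benchmarking.

Compares how quickly the generator and the simulator approximate a long
reference ensemble's radius-of-gyration distribution.  For a growing number
of samples n, KLD_r of the first-n sample against the reference is traced
over elapsed compute time; the generator trace plateaus at KLD_r_top after
t_gen seconds, and t_MD is the time at which the simulator's trace first
improves on that value.  Timing values are recorded, never asserted: the
plateau/crossing rules operate on traces and are fully testable with
scripted inputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .ensembles_io import ConformationalEnsemble
from .metrics import kld_r

PLATEAU_TOL = 1e-3  # absolute tolerance on "KLD_r did not decrease"


@dataclass
class EfficiencyTrace:
    """Ordered (n_samples, elapsed seconds, KLD_r) points for one source."""

    source: str                      # "generator" | "simulator"
    n_samples: List[int] = field(default_factory=list)
    times: List[float] = field(default_factory=list)
    kld: List[float] = field(default_factory=list)

    def append(self, n: int, t: float, k: float) -> None:
        if self.n_samples and n <= self.n_samples[-1]:
            raise ValueError("sample sizes must be strictly increasing")
        if self.times and t < self.times[-1]:
            raise ValueError("times must be non-decreasing")
        self.n_samples.append(int(n))
        self.times.append(float(t))
        self.kld.append(float(k))

    def __len__(self) -> int:
        return len(self.n_samples)


def generator_trace(
    sample_fn: Callable[[int], ConformationalEnsemble],
    reference_ens: ConformationalEnsemble,
    sample_schedule: Sequence[int],
) -> EfficiencyTrace:
    """KLD_r convergence of generated ensembles of growing size.

    ``sample_fn(n)`` must return n conformations; wall time of each call is
    accumulated (metric evaluation is not counted as sampling time).
    """
    _check_schedule(sample_schedule)
    trace = EfficiencyTrace("generator")
    elapsed = 0.0
    for n in sample_schedule:
        t0 = time.perf_counter()
        ens = sample_fn(n)
        elapsed += time.perf_counter() - t0
        if len(ens) != n:
            raise ValueError(f"sampler returned {len(ens)} conformations, expected {n}")
        trace.append(n, elapsed, kld_r(reference_ens, ens))
    return trace


def simulator_trace(
    sim_ens: ConformationalEnsemble,
    reference_ens: ConformationalEnsemble,
    sample_schedule: Sequence[int],
    time_per_frame: float,
) -> EfficiencyTrace:
    """KLD_r of growing prefixes of a simulated trajectory.

    ``time_per_frame`` is the measured (or recorded) simulation cost per
    saved frame in seconds; the prefix of n frames is charged n times that.
    """
    _check_schedule(sample_schedule)
    if sample_schedule[-1] > len(sim_ens):
        raise ValueError(
            f"schedule requests {sample_schedule[-1]} frames, trajectory has {len(sim_ens)}"
        )
    trace = EfficiencyTrace("simulator")
    for n in sample_schedule:
        prefix = ConformationalEnsemble(sim_ens.sequence, sim_ens.xyz[:n], sim_ens.provenance)
        trace.append(n, n * time_per_frame, kld_r(reference_ens, prefix))
    return trace


def kld_r_convergence_trace(source, reference_ens: ConformationalEnsemble,
                            sample_schedule: Sequence[int],
                            time_per_frame: Optional[float] = None) -> EfficiencyTrace:
    """Dispatch: a callable source is a generator; an ensemble is a simulator."""
    if callable(source):
        return generator_trace(source, reference_ens, sample_schedule)
    if time_per_frame is None:
        raise ValueError("simulator source requires time_per_frame")
    return simulator_trace(source, reference_ens, sample_schedule, time_per_frame)


def _check_schedule(schedule: Sequence[int]) -> None:
    if not schedule or any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("sample schedule must be non-empty and strictly increasing")


@dataclass
class PlateauResult:
    kld_r_top: float
    t_gen: float
    n_at_plateau: int
    converged: bool


def detect_plateau(trace: EfficiencyTrace, window: int = 1000) -> PlateauResult:
    """First point whose running-minimum KLD_r is not improved within ``window``
    further samples (absolute tolerance ``PLATEAU_TOL``).

    Returns the minimum KLD_r up to that point and its elapsed time.  If the
    trace never covers a full window without improvement, the final point is
    returned flagged as not converged.
    """
    n = np.asarray(trace.n_samples)
    k = np.asarray(trace.kld)
    t = np.asarray(trace.times)
    run_min = np.minimum.accumulate(k)
    for i in range(len(trace)):
        horizon = n[i] + window
        later = (n > n[i]) & (n <= horizon)
        if n[-1] < horizon:
            break  # window not fully covered by the trace
        if not np.any(k[later] < run_min[i] - PLATEAU_TOL):
            j = int(np.argmin(k[: i + 1]))
            return PlateauResult(float(run_min[i]), float(t[j]), int(n[i]), True)
    j = int(np.argmin(k))
    return PlateauResult(float(k[j]), float(t[j]), int(n[-1]), False)


@dataclass
class CrossingResult:
    t_md: Optional[float]
    n_at_crossing: Optional[int]
    crossed: bool


def simulator_crossing_time(trace: EfficiencyTrace, kld_r_top: float) -> CrossingResult:
    """Elapsed time at the first prefix with KLD_r strictly below ``kld_r_top``."""
    for n, t, k in zip(trace.n_samples, trace.times, trace.kld):
        if k < kld_r_top:
            return CrossingResult(float(t), int(n), True)
    return CrossingResult(None, None, False)


@dataclass
class EfficiencyReport:
    kld_r_top: float
    t_gen: float
    t_md: Optional[float]
    ratio: Optional[float]
    converged: bool
    crossed: bool
    ratio_min: Optional[float] = None
    ratio_max: Optional[float] = None
    n_runs: int = 1

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, blob: str) -> "EfficiencyReport":
        return cls(**json.loads(blob))


def efficiency_report(plateau: PlateauResult, crossing: CrossingResult,
                      repeats: Sequence[Tuple[PlateauResult, CrossingResult]] = (),
                      ) -> EfficiencyReport:
    """t_MD / t_gen ratio with min/max over repeated runs; partial when flagged."""
    ratio = (crossing.t_md / plateau.t_gen
             if crossing.crossed and plateau.t_gen > 0 else None)
    ratios = [ratio] if ratio is not None else []
    for p, c in repeats:
        if c.crossed and p.t_gen > 0:
            ratios.append(c.t_md / p.t_gen)
    return EfficiencyReport(
        kld_r_top=plateau.kld_r_top,
        t_gen=plateau.t_gen,
        t_md=crossing.t_md,
        ratio=ratio,
        converged=plateau.converged,
        crossed=crossing.crossed,
        ratio_min=min(ratios) if ratios else None,
        ratio_max=max(ratios) if ratios else None,
        n_runs=1 + len(repeats),
    )
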