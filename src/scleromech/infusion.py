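"""Whole-globe infusion testing: Friedenwald ocular rigidity.

A bolus of fluid is injected into the posterior chamber of an enucleated
globe at constant flow while IOP is recorded.  Friedenwald's pressure-volume
relation models the globe as exponentially stiffening:

    K = ln(IOP / IOP0) / (V - V0)        [per µL]

where IOP0 is the stable baseline pressure and V - V0 the injected volume.
Because larger eyes are intrinsically less rigid, the volume-normalised
rigidity k = V0 * K (dimensionless) removes the size confound.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PressureTrace",
    "RigidityResult",
    "simulate_infusion",
    "estimate_rigidity",
    "write_trace",
    "read_trace",
]


@dataclass
class PressureTrace:
    """Sampled IOP during a constant-flow infusion.

    ``time`` is a uniform grid (s); ``iop`` in mmHg; ``injected_volume`` is
    the cumulative injected volume (µL) implied by the flow schedule.
    Infusion runs over [onset, onset + duration].
    """

    time: np.ndarray
    iop: np.ndarray
    injected_volume: np.ndarray
    baseline_iop: float
    sample_rate: float
    onset: float
    duration: float
    flow: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.iop = np.asarray(self.iop, dtype=float)
        self.injected_volume = np.asarray(self.injected_volume, dtype=float)
        if self.time.shape != self.iop.shape:
            raise ValueError("time and iop must have the same shape")
        if np.any(self.iop <= 0):
            raise ValueError("IOP must stay positive throughout the trace")
        if np.any(np.diff(self.injected_volume) < -1e-12):
            raise ValueError("injected volume must be non-decreasing")

    @property
    def dv(self) -> float:
        """Total injected volume, µL."""
        return float(self.injected_volume[-1] - self.injected_volume[0])


@dataclass(frozen=True)
class RigidityResult:
    """Friedenwald rigidity estimate for one infusion (or mean of replicates)."""

    K: float            # per µL
    k_norm: float       # dimensionless, V0 * K
    iop0: float         # mmHg, baseline-window mean
    iop_peak: float     # mmHg, plateau-window mean
    dV: float           # µL
    n_infusions: int = 1


def simulate_infusion(
    K: float,
    V0: float,
    iop0: float,
    flow: float = 15.0,
    duration: float = 1.0,
    sample_rate: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    baseline_window: float = 5.0,
    post_window: float = 3.0,
) -> PressureTrace:
    """Simulate a constant-flow bolus infusion of a Friedenwald globe.

    During infusion IOP follows ``iop0 * exp(K * flow * t)``; before onset
    the trace sits at baseline and after the bolus it holds the peak
    (equilibration drift is out of scope).  Additive Gaussian noise with SD
    ``noise_sd`` (mmHg) models the pressure sensor.

    Defaults follow the study protocol: 15 µL/s for 1 s from a stable
    15 mmHg baseline.
    """
    if min(K, V0, iop0, flow, duration, sample_rate) <= 0:
        raise ValueError("K, V0, iop0, flow, duration and sample_rate must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    total = baseline_window + duration + post_window
    n = int(round(total * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    onset = baseline_window
    tau = np.clip(t - onset, 0.0, duration)
    iop = iop0 * np.exp(K * flow * tau)
    if noise_sd > 0:
        iop = iop + rng.normal(0.0, noise_sd, size=n)
    iop = np.maximum(iop, 1e-6)
    vol = flow * tau
    return PressureTrace(
        time=t, iop=iop, injected_volume=vol, baseline_iop=iop0,
        sample_rate=sample_rate, onset=onset, duration=duration, flow=flow,
    )


def estimate_rigidity(
    trace: PressureTrace,
    V0: float,
    baseline_window: float | None = None,
    plateau_window: tuple[float, float] = (1.0, 3.0),
) -> RigidityResult:
    """Estimate Friedenwald rigidity K and normalised rigidity k from a trace.

    ``iop0`` is the mean over the pre-onset baseline window (default: the
    whole pre-onset segment); ``iop_peak`` the mean over
    ``plateau_window`` seconds after the end of infusion.  K = ln(peak /
    baseline) / dV and k = V0 * K.
    """
    if V0 <= 0:
        raise ValueError("V0 must be positive")
    dv = trace.dv
    if dv <= 0:
        raise ValueError("injected volume must be positive to estimate rigidity")
    t = trace.time
    if baseline_window is None:
        base_mask = t < trace.onset
    else:
        base_mask = (t >= trace.onset - baseline_window) & (t < trace.onset)
    end = trace.onset + trace.duration
    lo, hi = plateau_window
    peak_mask = (t >= end + lo) & (t <= end + hi)
    if not peak_mask.any():  # short trace: fall back to everything after the bolus
        peak_mask = t >= end
    if not base_mask.any() or not peak_mask.any():
        raise ValueError("trace lacks a baseline or plateau window")
    iop0 = float(trace.iop[base_mask].mean())
    iop_peak = float(trace.iop[peak_mask].mean())
    if iop_peak <= iop0:
        raise ValueError("non-physical trace: plateau IOP does not exceed baseline")
    K = float(np.log(iop_peak / iop0) / dv)
    return RigidityResult(K=K, k_norm=V0 * K, iop0=iop0, iop_peak=iop_peak, dV=dv)


def mean_rigidity(results: list[RigidityResult], V0: float) -> RigidityResult:
    """Combine replicate infusions on one eye by averaging K (protocol runs two)."""
    if not results:
        raise ValueError("need at least one replicate")
    K = float(np.mean([r.K for r in results]))
    return RigidityResult(
        K=K,
        k_norm=V0 * K,
        iop0=float(np.mean([r.iop0 for r in results])),
        iop_peak=float(np.mean([r.iop_peak for r in results])),
        dV=float(np.mean([r.dV for r in results])),
        n_infusions=len(results),
    )


# -- delimited-text I/O -------------------------------------------------------

def write_trace(trace: PressureTrace, path: str | Path) -> None:
    """Write a trace as two-column text with a ``#`` header block."""
    header = (
        f"baseline_iop_mmHg={trace.baseline_iop}\n"
        f"sample_rate_hz={trace.sample_rate}\n"
        f"onset_s={trace.onset}\nduration_s={trace.duration}\n"
        f"flow_uL_per_s={trace.flow}\ncolumns=time_s,iop_mmHg"
    )
    np.savetxt(path, np.column_stack([trace.time, trace.iop]), header=header)


def read_trace(path: str | Path) -> PressureTrace:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").strip().partition("=")
            if key != "columns":
                meta[key] = float(val)
    data = np.loadtxt(path)
    t, iop = data[:, 0], data[:, 1]
    onset, dur, flow = meta["onset_s"], meta["duration_s"], meta["flow_uL_per_s"]
    vol = flow * np.clip(t - onset, 0.0, dur)
    return PressureTrace(
        time=t, iop=iop, injected_volume=vol,
        baseline_iop=meta["baseline_iop_mmHg"], sample_rate=meta["sample_rate_hz"],
        onset=onset, duration=dur, flow=flow,
    )
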