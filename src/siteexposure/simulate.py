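"""Synthetic single-molecule FRET data for the three-state site-exposure model.

Generates exact continuous-time Markov-chain state paths (Gillespie), renders
them into camera-binned FRET traces with Gaussian noise, builds whole
per-concentration trace cohorts, and produces noisy ensemble binding-isotherm
titrations.  These emulate the study conditions of the smFRET experiments:
~400 molecules per concentration, 0.1 s frames, 120 s traces, and a
short-lived exposed intermediate (rewrapping on the 10 ms scale) that is
invisible at frame resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import RateSet

__all__ = [
    "EmissionModel",
    "StatePath",
    "FretTrace",
    "TitrationCurve",
    "simulate_state_path",
    "render_fret_trace",
    "simulate_experiment",
    "generate_titration",
    "default_titration_grid",
]


@dataclass(frozen=True)
class EmissionModel:
    """Two-level Gaussian emission model for camera-binned FRET traces.

    State 1 (fully wrapped) emits at ``e_high``; states 2 and 3 (unwrapped,
    with or without TF) both emit at ``e_low`` since the dye separation is
    set by the unwrapped DNA geometry.  Defaults are arbitrary but
    representative two-level settings; the levels in real data depend on the
    labelling positions and must be configured.
    """

    e_high: float = 0.75
    e_low: float = 0.15
    noise_sd: float = 0.08
    frame_time: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.e_low < self.e_high <= 1.0):
            raise ValueError("require 0 <= e_low < e_high <= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")


@dataclass(frozen=True)
class StatePath:
    """A continuous-time state trajectory.

    ``entry_times[i]`` is when the path enters ``states[i]``; the final state
    persists until ``duration``.  ``absorbed`` flags a path that reached a
    state with zero total exit rate.
    """

    entry_times: np.ndarray
    states: np.ndarray
    duration: float
    absorbed: bool = False

    def __post_init__(self) -> None:
        t, s = np.asarray(self.entry_times), np.asarray(self.states)
        if len(t) != len(s) or len(t) == 0 or t[0] != 0.0:
            raise ValueError("entry_times/states must be equal-length, starting at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("entry times must be strictly increasing")
        if len(s) > 1 and np.any(np.abs(np.diff(s)) != 1):
            raise ValueError(
                "consecutive states must differ and move only along 1<->2, 2<->3"
            )

    def segment_durations(self) -> np.ndarray:
        edges = np.append(self.entry_times, self.duration)
        return np.diff(edges)

    def occupancy(self) -> np.ndarray:
        """Fraction of total time spent in states 1, 2, 3."""
        seg = self.segment_durations()
        occ = np.array([seg[self.states == k].sum() for k in (1, 2, 3)])
        return occ / self.duration


@dataclass(frozen=True)
class FretTrace:
    """A camera-binned FRET-efficiency time series for one molecule."""

    trace_id: str
    conc: float
    times: np.ndarray  # frame start times, s
    efficiency: np.ndarray
    frame_time: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.efficiency):
            raise ValueError("times and efficiency must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(np.abs(dt - self.frame_time) > 0.01 * self.frame_time):
                raise ValueError("frame spacing must be uniform within 1%")
        if not np.all(np.isfinite(self.efficiency)):
            raise ValueError("efficiencies must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TitrationCurve:
    """Ensemble FRET titration points (conc in nM, efficiency, replicate)."""

    conc: np.ndarray
    efficiency: np.ndarray
    replicate: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if not (len(self.conc) == len(self.efficiency) == len(self.replicate)):
            raise ValueError("columns must have equal length")
        if np.any(np.asarray(self.conc) < 0):
            raise ValueError("concentrations must be >= 0")

    def n_distinct_conc(self) -> int:
        return len(np.unique(self.conc))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_path(
    rates: RateSet,
    conc: float,
    duration: float,
    seed=None,
    start_state: int = 1,
) -> StatePath:
    """Exact stochastic (Gillespie) simulation of the three-state chain.

    Holding times are exponential with the state's total exit rate (state 1:
    k12; state 2: k21 + k23*conc; state 3: k32); the next state is chosen
    proportionally to the edge rates.  Reproducible given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if start_state not in (1, 2, 3):
        raise ValueError("start_state must be 1, 2 or 3")
    rng = _as_rng(seed)
    b = rates.k23 * conc
    exit_rate = {1: rates.k12, 2: rates.k21 + b, 3: rates.k32}
    # branch probability of 2 -> 3 given a jump out of state 2
    p23 = b / (rates.k21 + b) if (rates.k21 + b) > 0 else 0.0

    times = [0.0]
    states = [start_state]
    t = 0.0
    s = start_state
    absorbed = False
    while True:
        lam = exit_rate[s]
        if lam <= 0.0:
            absorbed = True
            break
        t += rng.exponential(1.0 / lam)
        if t >= duration:
            break
        if s == 1:
            s = 2
        elif s == 3:
            s = 2
        else:
            s = 3 if rng.random() < p23 else 1
        times.append(t)
        states.append(s)
    return StatePath(
        entry_times=np.array(times),
        states=np.array(states, dtype=int),
        duration=float(duration),
        absorbed=absorbed,
    )


def _frame_average(path: StatePath, emission: EmissionModel, n_frames: int) -> np.ndarray:
    """Occupancy-time-weighted mean emission level per frame (noiseless)."""
    level = {1: emission.e_high, 2: emission.e_low, 3: emission.e_low}
    seg_e = np.array([level[int(s)] for s in path.states])
    edges_seg = np.append(path.entry_times, path.duration)
    # cumulative integral of E(t); piecewise linear in t between segment edges
    cum = np.concatenate([[0.0], np.cumsum(seg_e * np.diff(edges_seg))])
    frame_edges = np.arange(n_frames + 1) * emission.frame_time
    frame_edges = np.minimum(frame_edges, path.duration)
    cum_at = np.interp(frame_edges, edges_seg, cum)
    return np.diff(cum_at) / emission.frame_time


def render_fret_trace(
    path: StatePath,
    emission: EmissionModel,
    seed=None,
    trace_id: str = "trace",
    conc: float | None = None,
    bleach_time: float | None = None,
) -> FretTrace:
    """Render a state path into a noisy camera-binned FRET trace.

    Each frame records the occupancy-time-weighted average of the state
    emission levels plus i.i.d. Gaussian noise.  Sub-frame excursions through
    the exposed intermediate therefore perturb a single frame by far less
    than the level gap and stay hidden, reproducing the observability
    constraint of the real measurement.  If ``bleach_time`` is given, frames
    after it emit at zero (dye bleached) — used to exercise truncation.
    """
    n_frames = int(np.floor(path.duration / emission.frame_time + 1e-9))
    if n_frames < 1:
        raise ValueError("path must span at least one frame")
    rng = _as_rng(seed)
    eff = _frame_average(path, emission, n_frames)
    times = np.arange(n_frames) * emission.frame_time
    if bleach_time is not None:
        eff = np.where(times + emission.frame_time <= bleach_time, eff, 0.0)
    eff = eff + rng.normal(0.0, emission.noise_sd, size=n_frames)
    return FretTrace(
        trace_id=trace_id,
        conc=float(conc) if conc is not None else 0.0,
        times=times,
        efficiency=eff,
        frame_time=emission.frame_time,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def simulate_experiment(
    rates: RateSet,
    conc_list,
    n_traces: int,
    duration: float = 120.0,
    emission: EmissionModel = EmissionModel(),
    seed: int = 0,
    label: str = "cohort",
) -> tuple[list[FretTrace], dict]:
    """Simulate a full per-concentration cohort of FRET traces.

    Per-trace random streams are spawned deterministically from the master
    seed (``numpy.random.SeedSequence.spawn``), so the cohort is reproducible
    and any single trace can be regenerated in isolation.

    Returns the trace list and a metadata dict recording all parameters.
    """
    conc_list = list(conc_list)
    if not conc_list:
        raise ValueError("conc_list must not be empty")
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(conc_list) * n_traces)
    traces: list[FretTrace] = []
    k = 0
    for ci, conc in enumerate(conc_list):
        for ti in range(n_traces):
            rng = np.random.default_rng(children[k])
            k += 1
            path = simulate_state_path(rates, conc, duration, seed=rng)
            tr = render_fret_trace(
                path,
                emission,
                seed=rng,
                trace_id=f"{label}_c{ci}_t{ti}",
                conc=conc,
            )
            traces.append(tr)
    meta = {
        "label": label,
        "rates": {"k12": rates.k12, "k21": rates.k21, "k23": rates.k23, "k32": rates.k32},
        "conc_list_nM": [float(c) for c in conc_list],
        "n_traces_per_conc": n_traces,
        "duration_s": float(duration),
        "emission": {
            "e_high": emission.e_high,
            "e_low": emission.e_low,
            "noise_sd": emission.noise_sd,
            "frame_time": emission.frame_time,
        },
        "seed": seed,
    }
    return traces, meta


def default_titration_grid() -> np.ndarray:
    """12-point logarithmic concentration grid, 0.1-3000 nM."""
    return np.geomspace(0.1, 3000.0, 12)


def generate_titration(
    s_values,
    amplitudes,
    e0: float = 0.75,
    conc_grid=None,
    noise_sd: float = 0.02,
    replicates: int = 3,
    seed=None,
    label: str = "",
) -> TitrationCurve:
    """Generate a noisy ensemble titration from a 1- or 2-event isotherm.

    The noiseless curve is ``E(c) = e0 - sum_i dE_i * c / (S_i + c)``; each
    replicate adds i.i.d. Gaussian noise.
    """
    s_values = np.atleast_1d(np.asarray(s_values, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if len(s_values) not in (1, 2) or len(amplitudes) != len(s_values):
        raise ValueError("need 1 or 2 events with matching amplitudes")
    if np.any(s_values <= 0):
        raise ValueError("S-values must be > 0")
    if amplitudes.sum() > e0:
        raise ValueError("amplitudes exceed e0: efficiency would go negative")
    conc = default_titration_grid() if conc_grid is None else np.asarray(conc_grid, float)
    if len(np.unique(conc)) < 6:
        raise ValueError("need >= 6 distinct concentrations")
    rng = _as_rng(seed)
    mean = e0 - (amplitudes[None, :] * conc[:, None] / (s_values[None, :] + conc[:, None])).sum(axis=1)
    cc, ee, rr = [], [], []
    for rep in range(replicates):
        noise = rng.normal(0.0, noise_sd, size=len(conc)) if noise_sd > 0 else 0.0
        cc.append(conc)
        ee.append(mean + noise)
        rr.append(np.full(len(conc), rep, dtype=int))
    return TitrationCurve(
        conc=np.concatenate(cc),
        efficiency=np.concatenate(ee),
        replicate=np.concatenate(rr),
        label=label,
    )
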