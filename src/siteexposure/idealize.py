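"""Two-state idealization of noisy FRET traces.

Converts each trace into a high/low step function from which dwell times are
harvested.  The primary idealizer is a two-state Gaussian hidden Markov model
fit by maximum-likelihood EM with most-probable-path (Viterbi) decoding; a
simple threshold idealizer serves as a cross-check, and a truncation rule
handles photobleached tails.  The number of states is fixed at two: real
traces can show several low-FRET sub-states, but they are collapsed into a
single low state for dwell analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .simulate import EmissionModel, FretTrace

__all__ = [
    "HIGH",
    "LOW",
    "IdealizedTrace",
    "idealize_hmm",
    "idealize_threshold",
    "truncate_trace",
]

HIGH, LOW = 1, 0


@dataclass(frozen=True)
class IdealizedTrace:
    """Two-state step-function annotation of a FRET trace.

    ``labels`` holds HIGH (1) / LOW (0) per frame.  ``degenerate`` marks a
    single-state result (constant trace or collapsed EM); ``fallback`` marks
    a threshold-idealized result after EM failure.
    """

    trace_id: str
    conc: float
    times: np.ndarray
    labels: np.ndarray
    mean_high: float
    mean_low: float
    sd_high: float
    sd_low: float
    frame_time: float
    log_likelihood: float = float("nan")
    truncation_index: int | None = None
    degenerate: bool = False
    fallback: bool = False
    method: str = "hmm"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.times):
            raise ValueError("labels and times must have equal length")
        if not self.degenerate and not (self.mean_high > self.mean_low):
            raise ValueError("mean_high must exceed mean_low")
        if self.truncation_index is not None and self.truncation_index > len(self.labels):
            raise ValueError("truncation index exceeds trace length")

    @property
    def n_transitions(self) -> int:
        return int(np.sum(self.labels[1:] != self.labels[:-1]))


def _canonical(labels: np.ndarray, means: np.ndarray, sds: np.ndarray):
    """Order states so index HIGH has the larger mean."""
    if means[1] >= means[0]:
        return labels, (means[1], means[0]), (sds[1], sds[0])
    return 1 - labels, (means[0], means[1]), (sds[0], sds[1])


def idealize_hmm(
    trace: FretTrace,
    init: dict | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 3,
    seed: int = 0,
) -> IdealizedTrace:
    """Fit a two-state Gaussian HMM by maximum-likelihood EM and decode.

    Initial means default to the 10th/90th percentiles of the trace, equal
    state standard deviations to the trace sd, and symmetric transition
    probability 0.05; restarts jitter this initialization.  The EM
    log-likelihood is non-decreasing by construction; labels come from the
    most probable (Viterbi) path under the fitted parameters.  If EM
    degenerates (a state empties or the levels collapse) the idealizer
    retries from perturbed starts and finally falls back to a midpoint
    threshold with ``fallback=True``.
    """
    y = np.asarray(trace.efficiency, dtype=float)
    if len(y) < 20:
        raise ValueError("trace must have at least 20 frames")
    sd = float(np.std(y))
    lo, hi = np.percentile(y, [10, 90])
    # constant-level input: no two-level structure to fit
    if sd < 1e-12 or (hi - lo) < 1e-12:
        return IdealizedTrace(
            trace_id=trace.trace_id,
            conc=trace.conc,
            times=trace.times,
            labels=np.full(len(y), HIGH),
            mean_high=float(np.mean(y)),
            mean_low=float(np.mean(y)),
            sd_high=sd,
            sd_low=sd,
            frame_time=trace.frame_time,
            degenerate=True,
        )
    if init is not None:
        means0 = np.asarray(init["means"], float)
        sds0 = np.asarray(init.get("sds", [sd, sd]), float)
        p_tr = float(init.get("transition_prob", 0.05))
    else:
        means0 = np.array([lo, hi])
        sds0 = np.array([sd, sd])
        p_tr = 0.05

    rng = np.random.default_rng(seed)
    best = None
    X = y[:, None]
    for attempt in range(n_restarts):
        m0 = means0.copy()
        s0 = sds0.copy()
        if attempt > 0:
            m0 = m0 + rng.normal(0, 0.25 * sd, size=2)
            s0 = np.abs(s0 * rng.uniform(0.5, 1.5, size=2)) + 1e-6
        model = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            init_params="",
            params="stmc",
            n_iter=max_iter,
            tol=tol,
            min_covar=1e-8,
        )
        model.startprob_ = np.array([0.5, 0.5])
        model.transmat_ = np.array([[1 - p_tr, p_tr], [p_tr, 1 - p_tr]])
        model.means_ = m0[:, None]
        model.covars_ = np.maximum(s0**2, 1e-8)[:, None]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X)
                ll = float(model.score(X))
                labels = model.predict(X)  # Viterbi decoding
        except Exception:
            continue
        counts = np.bincount(labels, minlength=2)
        means = model.means_.ravel()
        sds_fit = np.sqrt(np.asarray(model.covars_).ravel())
        # states must be separated beyond the fitted noise: otherwise EM has
        # split a single level (e.g. a trace with no genuine transitions)
        collapsed = (
            counts.min() == 0
            or abs(means[1] - means[0]) < 3.0 * 0.5 * (sds_fit[0] + sds_fit[1])
        )
        if not collapsed and (best is None or ll > best[0]):
            best = (ll, labels, means, sds_fit)
        if not collapsed and attempt == 0:
            break  # a clean fit from the default start is enough
    if best is None:
        # no separable two-state fit: either a genuinely single-state trace
        # (flagged degenerate) or an EM failure on two-level data (threshold
        # fallback).  Robust noise scale from the median absolute deviation.
        sigma = 1.4826 * float(np.median(np.abs(y - np.median(y)))) + 1e-12
        if (hi - lo) < 5.0 * sigma:
            return IdealizedTrace(
                trace_id=trace.trace_id,
                conc=trace.conc,
                times=trace.times,
                labels=np.full(len(y), HIGH),
                mean_high=float(np.mean(y)),
                mean_low=float(np.mean(y)),
                sd_high=sd,
                sd_low=sd,
                frame_time=trace.frame_time,
                degenerate=True,
            )
        cutoff = 0.5 * (lo + hi)
        out = idealize_threshold(trace, cutoff)
        return IdealizedTrace(
            **{**out.__dict__, "fallback": True, "method": "threshold-fallback"}
        )
    ll, labels, means, sds_fit = best
    labels, (mh, ml), (sh, sl) = _canonical(np.asarray(labels), means, sds_fit)
    return IdealizedTrace(
        trace_id=trace.trace_id,
        conc=trace.conc,
        times=trace.times,
        labels=labels.astype(int),
        mean_high=float(mh),
        mean_low=float(ml),
        sd_high=float(sh),
        sd_low=float(sl),
        frame_time=trace.frame_time,
        log_likelihood=ll,
    )


def _remove_blips(labels: np.ndarray) -> np.ndarray:
    """Merge single-frame runs into their surroundings (interior only)."""
    labels = labels.copy()
    n = len(labels)
    i = 1
    while i < n - 1:
        if labels[i] != labels[i - 1] and labels[i] != labels[i + 1]:
            labels[i] = labels[i - 1]
        i += 1
    return labels


def idealize_threshold(
    trace: FretTrace, cutoff: float, blip_filter: bool = False
) -> IdealizedTrace:
    """Threshold idealizer: label HIGH iff efficiency > cutoff.

    ``blip_filter`` merges isolated single-frame excursions into their
    neighbours, removing two transitions per blip.
    """
    y = np.asarray(trace.efficiency, dtype=float)
    if not (np.min(y) < cutoff < np.max(y)):
        raise ValueError("cutoff must lie strictly inside the observed range")
    labels = (y > cutoff).astype(int)
    if blip_filter:
        labels = _remove_blips(labels)
    sel_h, sel_l = labels == HIGH, labels == LOW
    mh = float(np.mean(y[sel_h])) if sel_h.any() else float(np.max(y))
    ml = float(np.mean(y[sel_l])) if sel_l.any() else float(np.min(y))
    return IdealizedTrace(
        trace_id=trace.trace_id,
        conc=trace.conc,
        times=trace.times,
        labels=labels,
        mean_high=mh,
        mean_low=ml,
        sd_high=float(np.std(y[sel_h])) if sel_h.any() else 0.0,
        sd_low=float(np.std(y[sel_l])) if sel_l.any() else 0.0,
        frame_time=trace.frame_time,
        degenerate=not (sel_h.any() and sel_l.any()),
        method="threshold",
    )


def truncate_trace(
    trace: FretTrace,
    bleach_detection: bool = False,
    max_duration: float | None = None,
    emission: EmissionModel | None = None,
    min_run: int = 10,
) -> int:
    """Return the number of frames to retain from the start of the trace.

    With ``bleach_detection`` on, truncates at the first frame of a sustained
    (>= ``min_run`` frames) drop below ``e_low - 3 * noise_sd`` — the
    signature of dye photobleaching, which sends the apparent efficiency
    below any genuine FRET level.  Otherwise the full length is kept, capped
    at ``max_duration``.
    """
    n = len(trace)
    idx = n
    if max_duration is not None:
        idx = min(idx, int(round(max_duration / trace.frame_time)))
    if bleach_detection:
        em = emission if emission is not None else EmissionModel(frame_time=trace.frame_time)
        floor = em.e_low - 3.0 * em.noise_sd
        below = np.asarray(trace.efficiency) < floor
        run = 0
        for i, b in enumerate(below):
            run = run + 1 if b else 0
            if run >= min_run:
                idx = min(idx, i - min_run + 1)
                break
    return idx
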