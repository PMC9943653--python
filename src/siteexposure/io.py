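"""Reading and writing the pipeline's tabular formats.

Traces travel as tidy CSV (``trace_id, conc_nM, frame, time_s, fret_e``)
with an optional JSON sidecar of generation parameters; titrations as CSV
(``conc_nM, fret_e, replicate``); dwell tables as CSV
(``trace_id, state, duration_s, censored``); rate series as CSV
(``conc_nM, kHL, kHL_se, kLH, kLH_se, n_events``).  Trace tables may carry
``donor``/``acceptor`` intensity columns instead of ``fret_e``, converted as
``E = acceptor / (donor + acceptor)``.

Readers for external trace archives (e.g. deposited per-movie formats)
would plug in beside :func:`load_trace_table` by converting to the same
tidy schema; no such format is committed to here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dwell import RatePoint, RateSeries
from .simulate import FretTrace, TitrationCurve

__all__ = [
    "write_traces_csv",
    "load_trace_table",
    "write_titration_csv",
    "read_titration_csv",
    "write_dwells_csv",
    "write_rate_series_csv",
    "read_rate_series_csv",
]

TRACE_COLUMNS = ["trace_id", "conc_nM", "frame", "time_s", "fret_e"]


def write_traces_csv(traces: list[FretTrace], path, meta: dict | None = None) -> None:
    """Write a trace cohort as tidy CSV, plus a JSON parameter sidecar."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "conc_nM": tr.conc,
                    "frame": np.arange(len(tr)),
                    "time_s": tr.times,
                    "fret_e": tr.efficiency,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if meta is not None:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_trace_table(path) -> list[FretTrace]:
    """Load a trace cohort CSV into FretTrace objects.

    Accepts either a precomputed ``fret_e`` column or raw ``donor`` /
    ``acceptor`` intensities.  Frame spacing must be uniform within 1% per
    trace; violations raise with the offending trace named.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    required = {"trace_id", "conc_nM", "frame", "time_s"}
    missing = required - cols
    if missing:
        raise ValueError(f"trace table missing column(s): {sorted(missing)}")
    if "fret_e" not in cols:
        if not {"donor", "acceptor"} <= cols:
            raise ValueError("trace table missing column(s): ['fret_e'] "
                             "(or 'donor'+'acceptor')")
        total = df["donor"] + df["acceptor"]
        if np.any(total <= 0):
            raise ValueError("donor + acceptor must be > 0 to form efficiencies")
        df = df.assign(fret_e=df["acceptor"] / total)
    traces = []
    for tid, g in df.groupby("trace_id", sort=False):
        g = g.sort_values("frame")
        t = g["time_s"].to_numpy(float)
        if len(t) > 1:
            dt = np.diff(t)
            ft = float(np.median(dt))
            if np.any(np.abs(dt - ft) > 0.01 * ft):
                raise ValueError(f"non-uniform frame spacing in trace {tid!r}")
        else:
            ft = 1.0
        traces.append(
            FretTrace(
                trace_id=str(tid),
                conc=float(g["conc_nM"].iloc[0]),
                times=t,
                efficiency=g["fret_e"].to_numpy(float),
                frame_time=ft,
            )
        )
    return traces


def write_dwells_csv(dwell_sets: list[dict], path) -> None:
    """Write per-trace dwell tables (``extract_dwells`` outputs) as CSV."""
    rows = []
    for d in dwell_sets:
        for st in ("high", "low"):
            ds = d[st]
            if ds.empty:
                continue
            ids = ds.trace_ids if ds.trace_ids is not None else [""] * len(ds.durations)
            for tid, dur, cen in zip(ids, ds.durations, ds.censored):
                rows.append((tid, st, float(dur), bool(cen)))
    pd.DataFrame(rows, columns=["trace_id", "state", "duration_s", "censored"]).to_csv(
        path, index=False
    )


def write_titration_csv(curve: TitrationCurve, path) -> None:
    pd.DataFrame(
        {"conc_nM": curve.conc, "fret_e": curve.efficiency, "replicate": curve.replicate}
    ).to_csv(path, index=False)


def read_titration_csv(path, label: str = "") -> TitrationCurve:
    df = pd.read_csv(path)
    missing = {"conc_nM", "fret_e", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"titration table missing column(s): {sorted(missing)}")
    return TitrationCurve(
        conc=df["conc_nM"].to_numpy(float),
        efficiency=df["fret_e"].to_numpy(float),
        replicate=df["replicate"].to_numpy(int),
        label=label,
    )


def write_rate_series_csv(series: RateSeries, path) -> None:
    pd.DataFrame(
        {
            "conc_nM": series.conc,
            "kHL": series.column("k_hl"),
            "kHL_se": series.column("k_hl_se"),
            "kLH": series.column("k_lh"),
            "kLH_se": series.column("k_lh_se"),
            "n_events": series.column("n_events").astype(int),
        }
    ).to_csv(path, index=False)


def read_rate_series_csv(path, label: str = "") -> RateSeries:
    df = pd.read_csv(path)
    missing = {"conc_nM", "kHL", "kLH"} - set(df.columns)
    if missing:
        raise ValueError(f"rate series missing column(s): {sorted(missing)}")
    points = []
    for _, row in df.iterrows():
        points.append(
            RatePoint(
                conc=float(row["conc_nM"]),
                k_hl=float(row["kHL"]),
                k_lh=float(row["kLH"]),
                k_hl_se=float(row.get("kHL_se", np.nan)),
                k_lh_se=float(row.get("kLH_se", np.nan)),
                n_events=int(row.get("n_events", 0)),
            )
        )
    return RateSeries(points=tuple(points), label=label)
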