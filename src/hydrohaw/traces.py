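"""Immersed-weight trace processing and session quality control.

A weighing trial produces a continuously sampled apparent-weight signal
with two plateaus: chin at the water line (head above water, HAW) and
full submersion (head below water, HBW).  This module segments the
signal, extracts the 100-sample window with the smallest weight
fluctuation in each phase, applies the per-session exclusion rules
(>= 3 trials, no pair of trial means differing by more than 0.5 kg,
stable weight for 3 s), and consolidates repeated head measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeightTrace",
    "StableSegment",
    "TrialResult",
    "SessionResult",
    "RemeasureSignal",
    "find_stable_window",
    "segment_trial",
    "extract_trial",
    "qc_session",
    "consolidate_repeats",
    "fluctuation_stats",
    "read_traces_csv",
    "read_trace_json",
    "sessions_to_frame",
]

DEFAULT_SAMPLE_RATE = 40.0   # Hz; 100 samples ~ 2.5 s of weighing
DEFAULT_WINDOW = 100         # samples averaged per phase

# Relative tolerance for declaring two window variances tied (earliest start
# wins); guards the tie-break against float round-off on e.g. linear ramps.
_TIE_RTOL = 1e-9


@dataclass
class WeightTrace:
    """Sampled apparent-weight signal for one weighing trial."""

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    subject_id: Optional[str] = None
    trial_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not self.sample_rate > 0:
            raise ValueError(f"sample rate must be positive, got {self.sample_rate}")
        if np.isnan(self.samples).any():
            raise ValueError(
                "trace contains missing samples; fill gaps or reject the trace"
            )

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class StableSegment:
    """A minimal-fluctuation averaging window within one phase."""

    start_index: int
    length: int
    mean: float
    sd: float


@dataclass
class TrialResult:
    """Per-phase stable-window extraction for one trial."""

    haw: StableSegment
    hbw: Optional[StableSegment] = None
    haw_stable_s: float = 0.0
    hbw_stable_s: float = 0.0
    trial_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.hbw is not None and not self.hbw.mean < self.haw.mean:
            raise ValueError(
                f"HBW mean {self.hbw.mean} must lie below HAW mean {self.haw.mean}"
            )


@dataclass
class SessionResult:
    """QC decision and consolidated immersed weights for one subject session."""

    trials: list[TrialResult]
    qc_pass: bool
    qc_reasons: list[str] = field(default_factory=list)
    mw_haw_kg: Optional[float] = None
    mw_hbw_kg: Optional[float] = None
    subject_id: Optional[str] = None


class RemeasureSignal(Exception):
    """Repeated head measurements are discordant; the caller must re-measure.

    ``kind`` is ``"third"`` (two discordant values, take a third) or
    ``"restart"`` (three mutually discordant values, repeat the procedure).
    """

    def __init__(self, kind: str, values: Sequence[float]):
        self.kind = kind
        self.values = list(values)
        super().__init__(f"head measurements {self.values} discordant: {kind}")


def _rolling_mean_var(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Means and sample (n-1) variances of every contiguous window, O(n).

    The trace is centered on its grand mean before the cumulative sums so
    the incremental formula stays well conditioned for near-constant
    plateaus around tens of kg.
    """
    xc = x - x.mean()
    c1 = np.concatenate(([0.0], np.cumsum(xc)))
    c2 = np.concatenate(([0.0], np.cumsum(xc * xc)))
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    means = s1 / window + x.mean()
    var = (s2 - s1 * s1 / window) / (window - 1)
    return means, np.maximum(var, 0.0)


def find_stable_window(trace: WeightTrace | np.ndarray, window: int = DEFAULT_WINDOW,
                       search_bounds: Optional[tuple[int, int]] = None) -> StableSegment:
    """Locate the ``window``-sample segment with the smallest sample SD.

    Ties (within relative tolerance 1e-9 of the minimum variance) are broken
    by the earliest start index.  ``search_bounds`` is a half-open index
    range restricting the search; the window must fit inside it.
    """
    x = trace.samples if isinstance(trace, WeightTrace) else np.asarray(trace, float)
    lo, hi = search_bounds if search_bounds is not None else (0, len(x))
    lo, hi = int(lo), int(hi)
    if not 0 <= lo < hi <= len(x):
        raise ValueError(f"search bounds ({lo}, {hi}) invalid for trace of {len(x)}")
    if window < 2:
        raise ValueError("window must contain at least 2 samples")
    if hi - lo < window:
        raise ValueError(
            f"search range of {hi - lo} samples shorter than window of {window}"
        )
    seg = x[lo:hi]
    means, var = _rolling_mean_var(seg, window)
    vmin = var.min()
    tied = var <= vmin * (1.0 + _TIE_RTOL) + 1e-30
    start = int(np.argmax(tied))  # earliest index among ties
    # recompute directly at the winner to shed any cumulative-sum round-off
    win = seg[start:start + window]
    return StableSegment(start_index=lo + start, length=window,
                         mean=float(win.mean()), sd=float(win.std(ddof=1)))


def segment_trial(trace: WeightTrace,
                  manual_cursors: Optional[tuple[tuple[int, int], tuple[int, int]]] = None,
                  rolling_width: int = 25,
                  min_separation_kg: float = 0.5,
                  ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Split a trial into (HAW range, HBW range) as half-open index ranges.

    Manual cursors (the operator's choice) pass through untouched.
    Automatic mode thresholds a centered rolling mean at the midpoint of
    its 5th and 95th percentiles and returns the longest above-threshold
    run (HAW) and the longest below-threshold run (HBW).
    """
    if manual_cursors is not None:
        haw, hbw = manual_cursors
        return (int(haw[0]), int(haw[1])), (int(hbw[0]), int(hbw[1]))
    x = trace.samples
    if len(x) < 2 * rolling_width:
        raise ValueError("trace too short for automatic segmentation")
    kernel = np.ones(rolling_width) / rolling_width
    # edge-pad before the moving average so trace ends don't dip toward zero
    left = np.full(rolling_width // 2, x[0])
    right = np.full(rolling_width - rolling_width // 2 - 1, x[-1])
    smooth = np.convolve(np.concatenate((left, x, right)), kernel, mode="valid")
    p5, p95 = np.percentile(smooth, [5, 95])
    if p95 - p5 < min_separation_kg:
        raise ValueError(
            f"level spread {p95 - p5:.3f} kg below {min_separation_kg} kg: "
            "no two distinguishable plateaus; supply manual cursors"
        )
    threshold = (p5 + p95) / 2.0
    above = smooth > threshold

    def longest_run(mask: np.ndarray) -> Optional[tuple[int, int]]:
        best, start = None, None
        padded = np.concatenate((mask, [False]))
        for i, flag in enumerate(padded):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                if best is None or i - start > best[1] - best[0]:
                    best = (start, i)
                start = None
        return best

    haw_range = longest_run(above)
    hbw_range = longest_run(~above)
    if haw_range is None or hbw_range is None:
        raise ValueError("could not find two weight plateaus; supply manual cursors")
    # trim half the smoothing kernel off each edge to avoid transition bleed
    pad = rolling_width // 2

    def trim(rng: tuple[int, int]) -> tuple[int, int]:
        a, b = rng
        return (min(a + pad, b - 1), max(b - pad, a + 1))

    return trim(haw_range), trim(hbw_range)


def _stable_duration(x: np.ndarray, phase: tuple[int, int], seg: StableSegment,
                     min_stable_s: float, sample_rate: float,
                     stability_factor: float = 2.0) -> float:
    """Seconds of qualifying stability around the selected window.

    The window is extended (symmetrically, clipped to the phase range) to
    ``min_stable_s``; the extension qualifies if its sample SD stays below
    ``stability_factor`` times the window SD (absolute floor 1e-6 kg so a
    noiseless plateau qualifies).
    """
    target = int(round(min_stable_s * sample_rate))
    lo, hi = phase
    if hi - lo < target:
        return seg.length / sample_rate
    extra = target - seg.length
    start = max(lo, min(seg.start_index - extra // 2, hi - target))
    ext = x[start:start + target]
    limit = max(stability_factor * seg.sd, 1e-6)
    if float(np.std(ext, ddof=1)) <= limit:
        return target / sample_rate
    return seg.length / sample_rate


def extract_trial(trace: WeightTrace, window: int = DEFAULT_WINDOW,
                  manual_cursors=None, min_stable_s: float = 3.0,
                  stability_factor: float = 2.0) -> TrialResult:
    """Segment a two-phase trial and extract both stable windows."""
    haw_range, hbw_range = segment_trial(trace, manual_cursors=manual_cursors)
    haw = find_stable_window(trace, window, haw_range)
    hbw = find_stable_window(trace, window, hbw_range)
    x = trace.samples
    return TrialResult(
        haw=haw,
        hbw=hbw,
        haw_stable_s=_stable_duration(x, haw_range, haw, min_stable_s,
                                      trace.sample_rate, stability_factor),
        hbw_stable_s=_stable_duration(x, hbw_range, hbw, min_stable_s,
                                      trace.sample_rate, stability_factor),
        trial_id=trace.trial_id,
    )


def qc_session(trials: Sequence[TrialResult], max_pairwise_diff: float = 0.5,
               min_trials: int = 3, min_stable_s: float = 3.0,
               subject_id: Optional[str] = None) -> SessionResult:
    """Apply the per-session exclusion rules and consolidate trial means.

    Failure reasons (QC failure is a result state, never an exception):
    fewer than ``min_trials`` trials carrying a phase; any pairwise
    difference of a phase's trial means strictly exceeding
    ``max_pairwise_diff``; any trial's stable duration below
    ``min_stable_s``.  On pass, the session weights are the arithmetic
    means of the per-trial phase means.
    """
    reasons: list[str] = []
    phases = {
        "MW_HAW": [(t.haw.mean, t.haw_stable_s) for t in trials],
        "MW_HBW": [(t.hbw.mean, t.hbw_stable_s) for t in trials if t.hbw is not None],
    }
    means: dict[str, float] = {}
    for name, entries in phases.items():
        if len(entries) < min_trials:
            reasons.append(f"fewer than {min_trials} trials with {name}")
            continue
        values = np.array([m for m, _ in entries])
        spread = float(values.max() - values.min())
        if spread > max_pairwise_diff:
            reasons.append(
                f"{name} trial means differ by {spread:.3f} kg "
                f"(> {max_pairwise_diff} kg)"
            )
        for i, (_, dur) in enumerate(entries):
            if dur < min_stable_s:
                reasons.append(
                    f"{name} trial {i} stable for only {dur:.2f} s "
                    f"(< {min_stable_s} s)"
                )
        means[name] = float(values.mean())
    ok = not reasons
    return SessionResult(
        trials=list(trials),
        qc_pass=ok,
        qc_reasons=reasons,
        mw_haw_kg=means.get("MW_HAW") if ok else None,
        mw_hbw_kg=means.get("MW_HBW") if ok else None,
        subject_id=subject_id,
    )


def consolidate_repeats(values: Sequence[float], tol: float = 0.5) -> float:
    """Reduce 2–3 repeated head measurements (cm) to the recorded value.

    Two values closer than ``tol`` → their mean.  Three values → the third,
    provided it agrees (difference < ``tol``) with at least one of the first
    two.  Otherwise a :class:`RemeasureSignal` tells the caller to take a
    third measurement or restart the procedure.
    """
    vals = [float(v) for v in values]
    if len(vals) == 2:
        if abs(vals[0] - vals[1]) < tol:
            return (vals[0] + vals[1]) / 2.0
        raise RemeasureSignal("third", vals)
    if len(vals) == 3:
        if min(abs(vals[2] - vals[0]), abs(vals[2] - vals[1])) < tol:
            return vals[2]
        raise RemeasureSignal("restart", vals)
    raise ValueError(f"expected 2 or 3 repeated measurements, got {len(vals)}")


def fluctuation_stats(trials: Sequence[TrialResult]) -> pd.DataFrame:
    """Per-trial, per-phase stable-window SDs for the fluctuation comparison.

    Returns a tidy frame (trial, phase, window sd, window mean) feeding the
    paired comparison of head-above vs head-below weight fluctuation.
    """
    rows = []
    for i, t in enumerate(trials):
        tid = t.trial_id if t.trial_id is not None else str(i)
        rows.append({"trial_id": tid, "phase": "HAW",
                     "window_sd_kg": t.haw.sd, "window_mean_kg": t.haw.mean})
        if t.hbw is not None:
            rows.append({"trial_id": tid, "phase": "HBW",
                         "window_sd_kg": t.hbw.sd, "window_mean_kg": t.hbw.mean})
    return pd.DataFrame(rows, columns=["trial_id", "phase", "window_sd_kg",
                                       "window_mean_kg"])


def read_traces_csv(path: str | Path) -> list[WeightTrace]:
    """Read traces from long CSV (subject_id, trial_id, t_s, weight_kg)."""
    df = pd.read_csv(path)
    required = {"subject_id", "trial_id", "t_s", "weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for (subject, trial), grp in df.groupby(["subject_id", "trial_id"], sort=False):
        grp = grp.sort_values("t_s")
        t = grp["t_s"].to_numpy()
        if len(t) > 1:
            dt = np.diff(t)
            rate = 1.0 / float(np.median(dt))
        else:
            rate = DEFAULT_SAMPLE_RATE
        traces.append(WeightTrace(samples=grp["weight_kg"].to_numpy(),
                                  sample_rate=rate,
                                  subject_id=str(subject), trial_id=str(trial)))
    return traces


def read_trace_json(path: str | Path) -> WeightTrace:
    """Read a single trace from JSON {sample_rate, samples[, ids]}."""
    with open(path) as fh:
        payload = json.load(fh)
    return WeightTrace(samples=np.asarray(payload["samples"], float),
                       sample_rate=float(payload.get("sample_rate", DEFAULT_SAMPLE_RATE)),
                       subject_id=payload.get("subject_id"),
                       trial_id=payload.get("trial_id"))


def sessions_to_frame(sessions: Sequence[SessionResult]) -> pd.DataFrame:
    """One row per subject: consolidated weights, per-phase SDs, QC flags."""
    rows = []
    for s in sessions:
        fluct = fluctuation_stats(s.trials)
        by_phase = fluct.groupby("phase")["window_sd_kg"].mean()
        rows.append({
            "subject_id": s.subject_id,
            "mw_haw_kg": s.mw_haw_kg,
            "mw_hbw_kg": s.mw_hbw_kg,
            "haw_window_sd_kg": by_phase.get("HAW", np.nan),
            "hbw_window_sd_kg": by_phase.get("HBW", np.nan),
            "n_trials": len(s.trials),
            "qc_pass": s.qc_pass,
            "qc_reasons": "; ".join(s.qc_reasons),
        })
    return pd.DataFrame(rows)
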