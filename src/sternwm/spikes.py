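"""Firing-rate windows, per-trial period rates, PSTHs and ISI statistics.

All windows are half-open ``[t0, t1)``.  Period windows follow the
analysis conventions: 200-1000 ms after stimulus/probe onset, the first
0-2500 ms of the maintenance period, and the first 500 ms of fixation
as baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnalysisConfig, SessionRecord, TrialSternberg, UnitRecord


def rate_in_window(spikes: np.ndarray, t0: float, t1: float) -> float:
    """Spike count in ``[t0, t1)`` divided by the window length, Hz."""
    if not t1 > t0:
        raise ValueError(f"window [{t0}, {t1}) has non-positive length")
    spikes = np.asarray(spikes)
    count = np.searchsorted(spikes, t1, side="left") - np.searchsorted(spikes, t0, side="left")
    return float(count) / (t1 - t0)


def counts_in_windows(spikes: np.ndarray, starts: np.ndarray,
                      ends: np.ndarray) -> np.ndarray:
    """Vectorized spike counts in many half-open windows."""
    spikes = np.asarray(spikes)
    return (np.searchsorted(spikes, ends, side="left")
            - np.searchsorted(spikes, starts, side="left")).astype(float)


def trial_period_rates(unit: UnitRecord, trials: list[TrialSternberg],
                       config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-trial firing rates for every task period of one unit.

    Columns: ``baseline_hz``, ``enc1_hz..enc3_hz`` (NaN when the slot is
    absent), ``maintenance_hz``, ``probe_hz``; indexed by trial id.
    Absent periods stay NaN, never zero.
    """
    cfg = config or AnalysisConfig()
    s0, s1 = cfg.window_stim_on
    m0, m1 = cfg.window_maintenance
    p0, p1 = cfg.window_probe
    rows = []
    for tr in trials:
        if cfg.baseline_last:
            # last 0.5 s of fixation: fixation ends at the first encoding onset
            b1 = tr.ts_enc1
            b0 = b1 - cfg.window_baseline
        else:
            b0 = tr.ts_fixation
            b1 = b0 + cfg.window_baseline
        row = {
            "trial_id": tr.trial_id,
            "baseline_hz": rate_in_window(unit.spike_times, b0, b1),
            "maintenance_hz": rate_in_window(unit.spike_times,
                                             tr.ts_maintenance + m0,
                                             tr.ts_maintenance + m1),
            "probe_hz": rate_in_window(unit.spike_times, tr.ts_probe + p0,
                                       tr.ts_probe + p1),
        }
        onsets = (tr.ts_enc1, tr.ts_enc2, tr.ts_enc3)
        for k in range(3):
            row[f"enc{k + 1}_hz"] = (
                rate_in_window(unit.spike_times, onsets[k] + s0, onsets[k] + s1)
                if k < tr.load else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows).set_index("trial_id")


@dataclass
class Psth:
    """Peristimulus time histogram averaged over alignment events."""

    bin_edges: np.ndarray  # seconds relative to alignment, len n_bins+1
    counts_hz: np.ndarray  # smoothed mean rate per bin
    raw_hz: np.ndarray  # unsmoothed mean rate per bin
    n_events: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def psth(spikes: np.ndarray, align_times: np.ndarray,
         window: tuple[float, float], bin_width: float = 0.050,
         smooth_sd: float = 0.075, smooth_fwhm: bool = False) -> Psth:
    """Event-aligned histogram of firing rate.

    Spikes are binned relative to each alignment time over ``window``,
    averaged over events, and smoothed with a Gaussian kernel of SD
    ``smooth_sd`` seconds (interpreted as FWHM when ``smooth_fwhm``).
    The unsmoothed rates conserve the aligned spike count exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    align_times = np.atleast_1d(np.asarray(align_times, dtype=float))
    if align_times.size == 0:
        raise ValueError("need at least one alignment event")
    spikes = np.asarray(spikes, dtype=float)
    w0, w1 = window
    n_bins = int(np.round((w1 - w0) / bin_width))
    edges = w0 + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for t in align_times:
        rel = spikes[(spikes >= t + w0) & (spikes < t + edges[-1])] - t
        idx = np.floor((rel - w0) / bin_width).astype(int)
        np.add.at(counts, np.clip(idx, 0, n_bins - 1), 1.0)
    raw_hz = counts / (bin_width * align_times.size)

    if smooth_sd > 0:
        sd = smooth_sd / 2.3548200450309493 if smooth_fwhm else smooth_sd
        sd_bins = sd / bin_width
        half = max(1, int(np.ceil(8 * sd_bins)))
        x = np.arange(-half, half + 1)
        kernel = np.exp(-0.5 * (x / sd_bins) ** 2)
        kernel /= kernel.sum()
        smoothed = np.convolve(raw_hz, kernel, mode="same")
    else:
        smoothed = raw_hz.copy()
    return Psth(bin_edges=edges, counts_hz=smoothed, raw_hz=raw_hz,
                n_events=int(align_times.size))


def isi_metrics(spikes: np.ndarray, threshold: float = 0.003) -> dict:
    """Percentage of inter-spike intervals below ``threshold`` seconds.

    Returns ``{"pct_below": float | nan, "n_isi": int}``; the percentage
    is NaN for fewer than two spikes.
    """
    spikes = np.asarray(spikes)
    if spikes.size < 2:
        return {"pct_below": float("nan"), "n_isi": 0}
    isis = np.diff(spikes)
    return {"pct_below": 100.0 * float(np.mean(isis < threshold)),
            "n_isi": int(isis.size)}


def cv2_score(spikes: np.ndarray) -> float:
    """Local ISI variability: mean of ``2|a-b|/(a+b)`` over consecutive
    ISI pairs.  0 for a perfectly regular train, ~1 for Poisson firing.
    NaN for fewer than three spikes."""
    spikes = np.asarray(spikes)
    if spikes.size < 3:
        return float("nan")
    isis = np.diff(spikes)
    a, b = isis[:-1], isis[1:]
    return float(np.mean(2.0 * np.abs(a - b) / (a + b)))


def session_mean_rate(unit: UnitRecord, session: SessionRecord) -> float:
    """Mean firing rate over the task span (first to last event), Hz."""
    ts = session.events.timestamps
    if ts.size < 2 or ts[-1] <= ts[0]:
        raise ValueError("session has no positive-length task span")
    t0, t1 = float(ts[0]), float(ts[-1])
    return rate_in_window(unit.spike_times, t0, t1)
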