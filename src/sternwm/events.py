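"""TTL event-stream parsing and reconciliation against stored trial tables.

The Sternberg stream grammar per trial is::

    11 (fixation)  ->  1 [5 2 [5 3]] (pictures with transitions)
    ->  6 (end of encoding / maintenance onset)  ->  7 (probe)
    ->  8 (response)

bracketed by a single 61 (start) and 60 (end).  The screening stream is
pairs of 1 (picture on) / 3 (picture off) with occasional 4 (control
response).  Picture codes 1-3 encode the *position* in the encoding
sequence, not image identity; identity lives in the stimulus
presentation list and the trial table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (NULL_IMAGE_INDEX, SCREENING_CODES, STERNBERG_CODES,
                    EventStream, TrialSternberg)


class EventParseError(ValueError):
    """Grammar violation; carries the offending stream offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (stream offset {offset})")
        self.offset = offset


@dataclass
class ParsedTrial:
    """Trial structure recovered purely from the TTL stream."""

    load: int
    ts_fixation: float
    enc_onsets: list[float]
    enc_ends: list[float]
    ts_maintenance: float
    ts_probe: float
    ts_response: float
    enc_pic_ids: Optional[tuple[int, ...]] = None  # filled by reconciliation
    probe_pic_id: Optional[int] = None


def parse_sternberg_events(events: EventStream) -> list[ParsedTrial]:
    """Parse the Sternberg TTL grammar into one record per trial."""
    C = STERNBERG_CODES
    codes = events.codes
    ts = events.timestamps
    allowed = set(C.values())
    for i, c in enumerate(codes):
        if int(c) not in allowed:
            raise EventParseError(f"unknown TTL code {c}", i)
    if ts.size and np.any(np.diff(ts) < 0):
        raise EventParseError("timestamps decrease",
                              int(np.argmax(np.diff(ts) < 0)) + 1)

    trials: list[ParsedTrial] = []
    i = 0
    n = codes.size
    pic_codes = (C["pic1"], C["pic2"], C["pic3"])
    while i < n:
        c = int(codes[i])
        if c in (C["start"], C["end"]):
            i += 1
            continue
        if c != C["fixation"]:
            raise EventParseError(f"expected fixation (11), got {c}", i)
        ts_fix = ts[i]
        i += 1
        enc_onsets: list[float] = []
        enc_ends: list[float] = []
        # pictures with 5-separators, terminated by 6
        while True:
            if i >= n:
                raise EventParseError("stream ended inside encoding", n - 1)
            c = int(codes[i])
            expected_pic = pic_codes[len(enc_onsets)] if len(enc_onsets) < 3 else None
            if c != expected_pic:
                raise EventParseError(
                    f"expected picture code {expected_pic}, got {c}", i)
            enc_onsets.append(float(ts[i]))
            i += 1
            if i >= n:
                raise EventParseError("stream ended inside encoding", n - 1)
            c = int(codes[i])
            if c == C["transition"]:
                enc_ends.append(float(ts[i]))
                i += 1
                continue
            if c == C["maintenance"]:
                enc_ends.append(float(ts[i]))
                ts_maint = float(ts[i])
                i += 1
                break
            raise EventParseError(
                f"expected transition (5) or end-of-encoding (6), got {c}", i)
        if i >= n or int(codes[i]) != C["probe"]:
            raise EventParseError("expected probe (7) after maintenance",
                                  min(i, n - 1))
        ts_probe = float(ts[i])
        i += 1
        if i >= n or int(codes[i]) != C["response"]:
            raise EventParseError("expected response (8) after probe",
                                  min(i, n - 1))
        ts_resp = float(ts[i])
        i += 1
        trials.append(ParsedTrial(load=len(enc_onsets), ts_fixation=float(ts_fix),
                                  enc_onsets=enc_onsets, enc_ends=enc_ends,
                                  ts_maintenance=ts_maint, ts_probe=ts_probe,
                                  ts_response=ts_resp))
    return trials


@dataclass
class ScreeningEvents:
    presentations: list[tuple[float, float]]  # (onset, offset)
    responses: list[float]


def parse_screening_events(events: EventStream) -> ScreeningEvents:
    """Parse the screening TTL stream into presentations and responses."""
    C = SCREENING_CODES
    codes = events.codes
    ts = events.timestamps
    if codes.size == 0:
        raise EventParseError("empty event stream", 0)
    pres: list[tuple[float, float]] = []
    resp: list[float] = []
    open_onset: Optional[float] = None
    for i, c in enumerate(codes):
        c = int(c)
        if c in (C["start"], C["end"]):
            continue
        if c == C["pic_on"]:
            if open_onset is not None:
                raise EventParseError("picture onset while previous still open", i)
            open_onset = float(ts[i])
        elif c == C["pic_off"]:
            if open_onset is None:
                raise EventParseError("picture offset without onset", i)
            if not ts[i] > open_onset:
                raise EventParseError("picture offset not after onset", i)
            pres.append((open_onset, float(ts[i])))
            open_onset = None
        elif c == C["response"]:
            resp.append(float(ts[i]))
        else:
            raise EventParseError(f"unknown TTL code {c}", i)
    if open_onset is not None:
        raise EventParseError("presentation start without end", codes.size - 1)
    return ScreeningEvents(presentations=pres, responses=resp)


@dataclass
class Discrepancy:
    trial_index: Optional[int]
    field: str
    parsed: object
    stored: object

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = "" if self.trial_index is None else f" (trial {self.trial_index})"
        return f"{self.field}{loc}: parsed={self.parsed} stored={self.stored}"


_TS_FIELDS = ("ts_fixation", "ts_maintenance", "ts_probe", "ts_response")


def reconcile_trials(parsed: list[ParsedTrial], stored: list[TrialSternberg],
                     tol: float = 1e-9,
                     presentations: Optional[list[tuple[int, float]]] = None
                     ) -> list[Discrepancy]:
    """Compare TTL-derived trials against the stored trial table.

    Empty iff counts, loads, and every period timestamp agree within
    ``tol``.  When the session's stimulus presentation list is supplied,
    picture identities are recovered from it (template index + 1, null
    image excluded) and compared as well.
    """
    out: list[Discrepancy] = []
    if len(parsed) != len(stored):
        out.append(Discrepancy(None, "n_trials", len(parsed), len(stored)))
        return out

    pres_t = pres_idx = None
    if presentations is not None:
        pres_idx = np.array([i for i, _t in presentations], dtype=int)
        pres_t = np.array([t for _i, t in presentations], dtype=float)

    def pic_at(t: float) -> Optional[int]:
        j = np.argmin(np.abs(pres_t - t))
        if abs(pres_t[j] - t) > tol or pres_idx[j] == NULL_IMAGE_INDEX:
            return None
        return int(pres_idx[j]) + 1

    for i, (p, s) in enumerate(zip(parsed, stored)):
        if p.load != s.load:
            out.append(Discrepancy(i, "load", p.load, s.load))
            continue
        for fld in _TS_FIELDS:
            a, b = getattr(p, fld), getattr(s, fld)
            if abs(a - b) > tol:
                out.append(Discrepancy(i, fld, a, b))
        s_on = s.enc_onsets()
        s_off = s.enc_ends()
        for k in range(p.load):
            if abs(p.enc_onsets[k] - s_on[k]) > tol:
                out.append(Discrepancy(i, f"ts_enc{k + 1}", p.enc_onsets[k], s_on[k]))
            if abs(p.enc_ends[k] - s_off[k]) > tol:
                out.append(Discrepancy(i, f"ts_enc{k + 1}_end", p.enc_ends[k], s_off[k]))
        if pres_t is not None:
            for k in range(p.load):
                pid = pic_at(p.enc_onsets[k])
                if pid != s.enc_pic_ids[k]:
                    out.append(Discrepancy(i, f"enc{k + 1}_pic_id", pid,
                                           s.enc_pic_ids[k]))
            probe_pid = pic_at(p.ts_probe)
            if probe_pid != s.probe_pic_id:
                out.append(Discrepancy(i, "probe_pic_id", probe_pid, s.probe_pic_id))
    return out
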