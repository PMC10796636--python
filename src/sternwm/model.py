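"""Domain model for human single-neuron Sternberg / screening sessions.

A session is one task run for one subject: electrode metadata, sorted
single units (spike times plus per-spike waveforms), the raw TTL event
stream, the trial table (Sternberg only), and the presented stimuli.

Conventions
-----------
* All times are seconds on a single session clock with arbitrary origin.
* Analysis windows are half-open ``[t0, t1)`` so a spike lands in exactly
  one of two adjacent windows.
* Picture identity in trials uses 1-5 with 0 meaning "no picture in this
  slot"; stimulus-template indices are 0-based with index 5 reserved for
  the null image in the Sternberg task.  ``pic_id = template_index + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

TASKS = ("screening", "sternberg")
BRAIN_AREAS = ("Hipp", "Amg", "dACC", "preSMA", "vmPFC", "other")
#: Region groups used for dataset-level summaries.
MTL_AREAS = frozenset({"Hipp", "Amg"})
MFC_AREAS = frozenset({"dACC", "preSMA", "vmPFC"})

GROUND_TRUTH_CLASSES = ("concept", "maintenance", "probe", "null")

#: TTL codes of the Sternberg task event stream.
STERNBERG_CODES = {
    "start": 61,
    "fixation": 11,
    "pic1": 1,
    "pic2": 2,
    "pic3": 3,
    "transition": 5,
    "maintenance": 6,
    "probe": 7,
    "response": 8,
    "end": 60,
}

#: TTL codes of the screening task event stream.
SCREENING_CODES = {
    "start": 61,
    "pic_on": 1,
    "pic_off": 3,
    "response": 4,
    "end": 60,
}

NULL_IMAGE_INDEX = 5  # 0-based template index of the Sternberg null image


@dataclass
class SubjectMeta:
    """De-identified subject metadata for one session."""

    subject_id: str
    native_id: str
    age: int
    sex: str  # "M" or "F"
    task: str  # "screening" or "sternberg"


@dataclass
class ElectrodeInfo:
    electrode_id: int
    brain_area: str
    mni_xyz: tuple[float, float, float]
    orig_channel: int


@dataclass
class EventStream:
    """Raw TTL markers aligning behavior with the neural clock."""

    timestamps: np.ndarray  # seconds, non-decreasing
    codes: np.ndarray  # integer TTL values

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.codes = np.asarray(self.codes, dtype=int)


@dataclass
class TrialSternberg:
    """One Sternberg trial: load, picture identities, outcome, period times.

    Absent encoding slots carry picture id 0 and timestamp 0.0.
    """

    trial_id: int
    load: int
    enc_pic_ids: tuple[int, int, int]
    probe_pic_id: int
    probe_in_out: int
    response_accuracy: int
    ts_fixation: float
    ts_enc1: float
    ts_enc2: float
    ts_enc3: float
    ts_enc1_end: float
    ts_enc2_end: float
    ts_enc3_end: float
    ts_maintenance: float
    ts_probe: float
    ts_response: float

    def enc_onsets(self) -> tuple[float, ...]:
        return (self.ts_enc1, self.ts_enc2, self.ts_enc3)[: self.load]

    def enc_ends(self) -> tuple[float, ...]:
        return (self.ts_enc1_end, self.ts_enc2_end, self.ts_enc3_end)[: self.load]

    def encoded_ids(self) -> tuple[int, ...]:
        return tuple(p for p in self.enc_pic_ids if p != 0)


@dataclass
class UnitRecord:
    """One sorted putative single neuron."""

    unit_id: int
    electrode_id: int
    spike_times: np.ndarray  # seconds, strictly increasing
    waveforms: Optional[np.ndarray] = None  # n_spikes x n_samples, microvolts
    ground_truth: Optional[str] = None  # synthetic sessions only
    preferred_image: Optional[int] = None  # 1-based pic id, synthetic only

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.waveforms is not None:
            self.waveforms = np.asarray(self.waveforms, dtype=float)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class StimulusSet:
    """Images shown in the session, 0-indexed; Sternberg includes a null image."""

    images: list[np.ndarray]
    null_index: Optional[int] = None

    @property
    def n_images(self) -> int:
        return len(self.images)


@dataclass
class SessionRecord:
    subject: SubjectMeta
    electrodes: list[ElectrodeInfo]
    units: list[UnitRecord]
    events: EventStream
    trials: list[TrialSternberg]
    stimuli: StimulusSet
    presentations: list[tuple[int, float]]  # (template index, onset time)

    def electrode_ids(self) -> set[int]:
        return {e.electrode_id for e in self.electrodes}

    def unit(self, unit_id: int) -> UnitRecord:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(f"no unit with id {unit_id}")


@dataclass
class AnalysisConfig:
    """Analysis constants shared by all selection and metric routines.

    Windows are (offset_start, offset_end) in seconds relative to the
    period onset; the baseline window is the first ``window_baseline``
    seconds after fixation onset (the fixation cross lasts 0.9-1.0 s).
    """

    window_stim_on: tuple[float, float] = (0.200, 1.000)
    window_maintenance: tuple[float, float] = (0.0, 2.500)
    window_baseline: float = 0.500
    window_probe: tuple[float, float] = (0.200, 1.000)
    alpha: float = 0.05
    n_perm: int = 1000
    psth_bin: float = 0.050
    psth_smooth: float = 0.075
    isi_violation_threshold: float = 0.003
    rng_seed: int = 0
    #: if True the concept ANOVA uses encoding presentations only; the
    #: default pools encoding and probe presentations of each image.
    encoding_only: bool = False
    #: if True the concept max-vs-rest step is one t-test against the
    #: pooled non-preferred responses; the default requires the preferred
    #: image to beat every other image individually.
    maxvsrest_pooled: bool = False
    #: if True the baseline window is the last 0.5 s of fixation instead
    #: of the first (fixation duration is needed per trial; approximated
    #: by the encoding-1 onset).
    baseline_last: bool = False

    def validate(self) -> None:
        for name in ("window_stim_on", "window_maintenance", "window_probe"):
            w = getattr(self, name)
            if not w[1] > w[0]:
                raise ValueError(f"{name} must have positive length, got {w}")
        if self.window_baseline <= 0:
            raise ValueError("window_baseline must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.psth_bin <= 0:
            raise ValueError("psth_bin must be positive")


@dataclass
class Violation:
    """One invariant violation found by :func:`validate_session`."""

    type_name: str
    field: str
    index: Optional[int]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f"[{self.index}]" if self.index is not None else ""
        return f"{self.type_name}.{self.field}{loc}: {self.message}"


def _check_trial(trial: TrialSternberg, i: int, n_images: int) -> list[Violation]:
    out: list[Violation] = []

    def bad(fld: str, msg: str) -> None:
        out.append(Violation("TrialSternberg", fld, i, msg))

    if trial.load not in (1, 2, 3):
        bad("load", f"load {trial.load} not in {{1,2,3}}")
    nonzero = [p for p in trial.enc_pic_ids if p != 0]
    if len(nonzero) != trial.load:
        bad("enc_pic_ids", f"{len(nonzero)} nonzero picture ids for load {trial.load}")
    for p in nonzero + [trial.probe_pic_id]:
        if not 1 <= p <= n_images:
            bad("enc_pic_ids", f"picture id {p} outside 1..{n_images}")
            break
    if trial.probe_in_out not in (0, 1):
        bad("probe_in_out", f"{trial.probe_in_out} not in {{0,1}}")
    if trial.response_accuracy not in (0, 1):
        bad("response_accuracy", f"{trial.response_accuracy} not in {{0,1}}")
    if trial.probe_in_out == 1 and trial.probe_pic_id not in nonzero:
        bad("probe_pic_id", "probe marked 'in' but not among encoded pictures")
    # present timestamps must be strictly increasing in task order
    seq = [("ts_fixation", trial.ts_fixation)]
    for k, (on, off) in enumerate(
        zip(
            (trial.ts_enc1, trial.ts_enc2, trial.ts_enc3),
            (trial.ts_enc1_end, trial.ts_enc2_end, trial.ts_enc3_end),
        ),
        start=1,
    ):
        if k <= trial.load:
            seq.append((f"ts_enc{k}", on))
            seq.append((f"ts_enc{k}_end", off))
        elif on != 0.0 or off != 0.0:
            bad(f"ts_enc{k}", "timestamp present for absent encoding slot")
    seq += [
        ("ts_maintenance", trial.ts_maintenance),
        ("ts_probe", trial.ts_probe),
        ("ts_response", trial.ts_response),
    ]
    for (fa, ta), (fb, tb) in zip(seq, seq[1:]):
        # the end-of-encoding TTL doubles as the maintenance onset, so
        # equality is legal at that joint; everywhere else order is strict
        ok = tb >= ta if fb == "ts_maintenance" else tb > ta
        if not ok:
            bad(fb, f"{fb}={tb} not after {fa}={ta}")
            break
    return out


def validate_session(session: SessionRecord) -> list[Violation]:
    """Check every modelled invariant; returns violations, never raises.

    The result is empty iff the session is internally consistent:
    controlled vocabularies, unique/resolvable electrode references,
    ordered timestamps, trial structure, and stimulus-set shape.
    """
    out: list[Violation] = []
    sub = session.subject
    if sub.task not in TASKS:
        out.append(Violation("SubjectMeta", "task", None, f"unknown task {sub.task!r}"))
    if not sub.age > 0:
        out.append(Violation("SubjectMeta", "age", None, f"age {sub.age} not positive"))
    if sub.sex not in ("M", "F"):
        out.append(Violation("SubjectMeta", "sex", None, f"sex {sub.sex!r} not in {{M,F}}"))

    seen_ids: set[int] = set()
    for j, el in enumerate(session.electrodes):
        if el.brain_area not in BRAIN_AREAS:
            out.append(Violation("ElectrodeInfo", "brain_area", j, f"unknown area {el.brain_area!r}"))
        if not np.all(np.isfinite(el.mni_xyz)):
            out.append(Violation("ElectrodeInfo", "mni_xyz", j, "non-finite MNI coordinate"))
        if el.electrode_id in seen_ids:
            out.append(Violation("ElectrodeInfo", "electrode_id", j, f"duplicate id {el.electrode_id}"))
        seen_ids.add(el.electrode_id)

    ev = session.events
    if ev.timestamps.shape != ev.codes.shape:
        out.append(Violation("EventStream", "codes", None, "codes/timestamps length mismatch"))
    elif ev.timestamps.size and np.any(np.diff(ev.timestamps) < 0):
        idx = int(np.argmax(np.diff(ev.timestamps) < 0))
        out.append(Violation("EventStream", "timestamps", idx, "timestamps decrease"))
    code_table = STERNBERG_CODES if sub.task == "sternberg" else SCREENING_CODES
    allowed = set(code_table.values())
    bad_codes = set(np.unique(ev.codes)) - allowed
    if bad_codes:
        out.append(Violation("EventStream", "codes", None, f"codes {sorted(bad_codes)} not in task code table"))

    n_img = session.stimuli.n_images
    if sub.task == "sternberg":
        if n_img != 6 or session.stimuli.null_index != NULL_IMAGE_INDEX:
            out.append(
                Violation("StimulusSet", "null_index", None,
                          f"Sternberg needs 6 images with null_index {NULL_IMAGE_INDEX}")
            )
        n_pics = 5
    else:
        if not 54 <= n_img <= 64 or session.stimuli.null_index is not None:
            out.append(Violation("StimulusSet", "images", None,
                                 f"screening needs 54-64 images and no null image, got {n_img}"))
        n_pics = n_img

    for i, tr in enumerate(session.trials):
        out.extend(_check_trial(tr, i, n_pics))

    for j, u in enumerate(session.units):
        if u.spike_times.size > 1 and np.any(np.diff(u.spike_times) <= 0):
            out.append(Violation("UnitRecord", "spike_times", j, "spike times not strictly increasing"))
        if u.waveforms is not None and u.waveforms.shape[0] != u.n_spikes:
            out.append(
                Violation("UnitRecord", "waveforms", j,
                          f"{u.waveforms.shape[0]} waveform rows for {u.n_spikes} spikes")
            )
        if u.electrode_id not in seen_ids:
            out.append(Violation("UnitRecord", "electrode_id", j, f"electrode {u.electrode_id} not in table"))
        if u.ground_truth is not None and u.ground_truth not in GROUND_TRUTH_CLASSES:
            out.append(Violation("UnitRecord", "ground_truth", j, f"unknown class {u.ground_truth!r}"))

    for j, (idx, _t) in enumerate(session.presentations):
        if not 0 <= idx < n_img:
            out.append(Violation("SessionRecord", "presentations", j, f"stimulus index {idx} out of range"))
    pres_t = np.array([t for _i, t in session.presentations])
    if pres_t.size > 1 and np.any(np.diff(pres_t) <= 0):
        out.append(Violation("SessionRecord", "presentations", None, "presentation times not strictly increasing"))
    return out


def sessions_equal(a: SessionRecord, b: SessionRecord, rtol: float = 0.0, atol: float = 1e-12) -> bool:
    """Deep field-wise equality (floats to ``atol``), used by round-trip tests."""
    if (a.subject != b.subject) or (a.electrodes != b.electrodes):
        return False
    if len(a.units) != len(b.units) or len(a.trials) != len(b.trials):
        return False
    if not (np.array_equal(a.events.codes, b.events.codes)
            and np.allclose(a.events.timestamps, b.events.timestamps, rtol=rtol, atol=atol)):
        return False
    for ua, ub in zip(a.units, b.units):
        if (ua.unit_id, ua.electrode_id, ua.ground_truth, ua.preferred_image) != (
                ub.unit_id, ub.electrode_id, ub.ground_truth, ub.preferred_image):
            return False
        if not np.allclose(ua.spike_times, ub.spike_times, rtol=rtol, atol=atol):
            return False
        if (ua.waveforms is None) != (ub.waveforms is None):
            return False
        if ua.waveforms is not None and not np.allclose(ua.waveforms, ub.waveforms, rtol=rtol, atol=atol):
            return False
    for ta, tb in zip(a.trials, b.trials):
        if ta != tb:
            return False
    if a.stimuli.null_index != b.stimuli.null_index or a.stimuli.n_images != b.stimuli.n_images:
        return False
    for ia, ib in zip(a.stimuli.images, b.stimuli.images):
        if not np.array_equal(ia, ib):
            return False
    if len(a.presentations) != len(b.presentations):
        return False
    for (ja, ta_), (jb, tb_) in zip(a.presentations, b.presentations):
        if ja != jb or abs(ta_ - tb_) > atol:
            return False
    return True
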