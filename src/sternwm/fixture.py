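"""Plain-file session fixtures: YAML metadata plus columnar text tables.

The fixture is a directory::

    meta.yaml            version, subject, stimulus shape/null index
    electrodes.csv
    trials.csv
    events.csv           (timestamp, code)
    presentations.csv    (stimulus_index, onset)
    units.csv            (unit_id, electrode_id, ground_truth, preferred_image,
                          n_spikes, has_waveforms)
    spikes_<unit_id>.txt         one spike time per line
    waveforms_<unit_id>.txt      whitespace matrix, n_spikes x n_samples
    images.txt           one flattened image per row

Floats are written with 17 significant digits so the round trip is exact;
integers are bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (ElectrodeInfo, EventStream, SessionRecord, StimulusSet,
                    SubjectMeta, TrialSternberg, UnitRecord, validate_session)

FIXTURE_VERSION = "1"
_FLOAT_FMT = "%.17g"

TRIAL_COLUMNS = [
    "trial_id", "load", "enc1_pic_id", "enc2_pic_id", "enc3_pic_id",
    "probe_pic_id", "probe_in_out", "response_accuracy",
    "ts_fixation", "ts_enc1", "ts_enc2", "ts_enc3",
    "ts_enc1_end", "ts_enc2_end", "ts_enc3_end",
    "ts_maintenance", "ts_probe", "ts_response",
]


class FixtureVersionError(ValueError):
    """Raised when a fixture directory carries an unknown version marker."""


def trials_to_frame(trials: list[TrialSternberg]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(dict(
            trial_id=t.trial_id, load=t.load,
            enc1_pic_id=t.enc_pic_ids[0], enc2_pic_id=t.enc_pic_ids[1],
            enc3_pic_id=t.enc_pic_ids[2], probe_pic_id=t.probe_pic_id,
            probe_in_out=t.probe_in_out, response_accuracy=t.response_accuracy,
            ts_fixation=t.ts_fixation, ts_enc1=t.ts_enc1, ts_enc2=t.ts_enc2,
            ts_enc3=t.ts_enc3, ts_enc1_end=t.ts_enc1_end,
            ts_enc2_end=t.ts_enc2_end, ts_enc3_end=t.ts_enc3_end,
            ts_maintenance=t.ts_maintenance, ts_probe=t.ts_probe,
            ts_response=t.ts_response,
        ))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialSternberg]:
    out = []
    for r in df.itertuples(index=False):
        out.append(TrialSternberg(
            trial_id=int(r.trial_id), load=int(r.load),
            enc_pic_ids=(int(r.enc1_pic_id), int(r.enc2_pic_id), int(r.enc3_pic_id)),
            probe_pic_id=int(r.probe_pic_id), probe_in_out=int(r.probe_in_out),
            response_accuracy=int(r.response_accuracy),
            ts_fixation=float(r.ts_fixation), ts_enc1=float(r.ts_enc1),
            ts_enc2=float(r.ts_enc2), ts_enc3=float(r.ts_enc3),
            ts_enc1_end=float(r.ts_enc1_end), ts_enc2_end=float(r.ts_enc2_end),
            ts_enc3_end=float(r.ts_enc3_end), ts_maintenance=float(r.ts_maintenance),
            ts_probe=float(r.ts_probe), ts_response=float(r.ts_response),
        ))
    return out


def save_fixture(session: SessionRecord, directory: str | Path) -> Path:
    """Write ``session`` as a plain-file fixture; returns the directory path.

    The session must pass :func:`validate_session`.
    """
    violations = validate_session(session)
    if violations:
        raise ValueError(f"session fails validation: {violations[0]}")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    img_shape = list(session.stimuli.images[0].shape) if session.stimuli.images else []
    meta = dict(
        version=FIXTURE_VERSION,
        subject=dict(subject_id=session.subject.subject_id,
                     native_id=session.subject.native_id,
                     age=int(session.subject.age), sex=session.subject.sex,
                     task=session.subject.task),
        stimuli=dict(n_images=session.stimuli.n_images,
                     null_index=session.stimuli.null_index,
                     image_shape=img_shape),
    )
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    pd.DataFrame(
        [dict(electrode_id=e.electrode_id, brain_area=e.brain_area,
              x=e.mni_xyz[0], y=e.mni_xyz[1], z=e.mni_xyz[2],
              orig_channel=e.orig_channel) for e in session.electrodes]
    ).to_csv(d / "electrodes.csv", index=False, float_format=_FLOAT_FMT)

    trials_to_frame(session.trials).to_csv(d / "trials.csv", index=False,
                                           float_format=_FLOAT_FMT)
    pd.DataFrame({"timestamp": session.events.timestamps,
                  "code": session.events.codes}
                 ).to_csv(d / "events.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame([{"stimulus_index": i, "onset": t} for i, t in session.presentations],
                 columns=["stimulus_index", "onset"]
                 ).to_csv(d / "presentations.csv", index=False, float_format=_FLOAT_FMT)

    pd.DataFrame(
        [dict(unit_id=u.unit_id, electrode_id=u.electrode_id,
              ground_truth=u.ground_truth or "",
              preferred_image=-1 if u.preferred_image is None else u.preferred_image,
              n_spikes=u.n_spikes,
              has_waveforms=int(u.waveforms is not None)) for u in session.units],
        columns=["unit_id", "electrode_id", "ground_truth", "preferred_image",
                 "n_spikes", "has_waveforms"],
    ).to_csv(d / "units.csv", index=False)

    for u in session.units:
        np.savetxt(d / f"spikes_{u.unit_id}.txt", u.spike_times, fmt=_FLOAT_FMT)
        if u.waveforms is not None:
            np.savetxt(d / f"waveforms_{u.unit_id}.txt",
                       u.waveforms.reshape(u.n_spikes, -1), fmt=_FLOAT_FMT)

    if session.stimuli.images:
        np.savetxt(d / "images.txt",
                   np.stack([im.ravel() for im in session.stimuli.images]),
                   fmt=_FLOAT_FMT)
    return d


def load_fixture(directory: str | Path) -> SessionRecord:
    """Inverse of :func:`save_fixture`."""
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    if str(meta.get("version")) != FIXTURE_VERSION:
        raise FixtureVersionError(
            f"unknown fixture version {meta.get('version')!r}, expected {FIXTURE_VERSION!r}")

    s = meta["subject"]
    subject = SubjectMeta(subject_id=s["subject_id"], native_id=s["native_id"],
                          age=int(s["age"]), sex=s["sex"], task=s["task"])

    edf = pd.read_csv(d / "electrodes.csv", float_precision="round_trip")
    electrodes = [ElectrodeInfo(int(r.electrode_id), str(r.brain_area),
                                (float(r.x), float(r.y), float(r.z)),
                                int(r.orig_channel))
                  for r in edf.itertuples(index=False)]

    tdf = pd.read_csv(d / "trials.csv", float_precision="round_trip")
    trials = frame_to_trials(tdf) if len(tdf) else []

    evdf = pd.read_csv(d / "events.csv", float_precision="round_trip")
    events = EventStream(evdf["timestamp"].to_numpy(float),
                         evdf["code"].to_numpy(int))

    pdf = pd.read_csv(d / "presentations.csv", float_precision="round_trip")
    presentations = [(int(r.stimulus_index), float(r.onset))
                     for r in pdf.itertuples(index=False)]

    udf = pd.read_csv(d / "units.csv", keep_default_na=False)
    units = []
    for r in udf.itertuples(index=False):
        spikes = np.loadtxt(d / f"spikes_{int(r.unit_id)}.txt", ndmin=1)
        wf = None
        if int(r.has_waveforms):
            wf = np.loadtxt(d / f"waveforms_{int(r.unit_id)}.txt", ndmin=2)
        units.append(UnitRecord(
            unit_id=int(r.unit_id), electrode_id=int(r.electrode_id),
            spike_times=spikes, waveforms=wf,
            ground_truth=str(r.ground_truth) or None,
            preferred_image=None if int(r.preferred_image) < 0 else int(r.preferred_image)))

    stim_meta = meta["stimuli"]
    images: list[np.ndarray] = []
    if stim_meta["n_images"]:
        flat = np.loadtxt(d / "images.txt", ndmin=2)
        shape = tuple(stim_meta["image_shape"])
        images = [row.reshape(shape) for row in flat]
    stimuli = StimulusSet(images=images, null_index=stim_meta["null_index"])

    return SessionRecord(subject=subject, electrodes=electrodes, units=units,
                         events=events, trials=trials, stimuli=stimuli,
                         presentations=presentations)
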