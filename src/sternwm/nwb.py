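"""Adapter between :class:`~sternwm.model.SessionRecord` and NWB-layout HDF5.

The released dataset stores each session as an NWB:N 2.x HDF5 file with
groups ``general`` (subject + electrode tables), ``acquisition/events``
(TTL stream), ``intervals/trials``, ``stimulus`` (templates and
presentation order) and ``units`` (jagged spike-time and waveform
arrays).  This module reads that layout directly through h5py and can
write session records back into the same group structure, which is what
the synthetic-session round-trip tests exercise.  The writer aims for
structural fidelity to the published layout, not for full NWB schema
compliance.

Jagged arrays use the standard exclusive cumulative-offset convention:
``spike_times_index[i]`` is one past the last spike of unit *i*, so the
spike count of unit *i* is ``index[i] - index[i-1]``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .fixture import frame_to_trials, trials_to_frame
from .model import (ElectrodeInfo, EventStream, SessionRecord, StimulusSet,
                    SubjectMeta, UnitRecord)

#: NWB trial-table column names, in the released files' vocabulary.
_NWB_TRIAL_COLS = {
    "load": "loads",
    "enc1_pic_id": "loadsEnc1_PicIDs",
    "enc2_pic_id": "loadsEnc2_PicIDs",
    "enc3_pic_id": "loadsEnc3_PicIDs",
    "probe_pic_id": "loadsProbe_PicIDs",
    "probe_in_out": "probe_in_out",
    "response_accuracy": "response_accuracy",
    "ts_fixation": "timestamps_FixationCross",
    "ts_enc1": "timestamps_Encoding1",
    "ts_enc2": "timestamps_Encoding2",
    "ts_enc3": "timestamps_Encoding3",
    "ts_enc1_end": "timestamps_Encoding1_end",
    "ts_enc2_end": "timestamps_Encoding2_end",
    "ts_enc3_end": "timestamps_Encoding3_end",
    "ts_maintenance": "timestamps_Maintenance",
    "ts_probe": "timestamps_Probe",
    "ts_response": "timestamps_Response",
}


class NwbLoadError(ValueError):
    """A required group or dataset is missing from the file."""


class NwbIntegrityError(ValueError):
    """The file is present but internally inconsistent (jagged indices)."""


def _require(h5: h5py.File | h5py.Group, path: str):
    if path not in h5:
        raise NwbLoadError(f"required NWB group/dataset {path!r} is missing")
    return h5[path]


def _as_str(x) -> str:
    if isinstance(x, bytes):
        return x.decode()
    if isinstance(x, np.ndarray):
        return _as_str(x[()] if x.shape == () else x[0])
    return str(x)


def load_nwb_session(path: str | Path) -> SessionRecord:
    """Read one session file in the released NWB layout.

    Raises :class:`NwbLoadError` naming the first missing group, and
    :class:`NwbIntegrityError` on inconsistent jagged-array indices.
    """
    with h5py.File(path, "r") as f:
        sub = _require(f, "general/subject")
        identifier = _as_str(f.attrs.get("identifier", ""))
        task = "sternberg"
        if identifier.startswith("SC"):
            task = "screening"
        elif not identifier.startswith("SB") and "intervals/trials" not in f:
            task = "screening"
        subject = SubjectMeta(
            subject_id=_as_str(sub["subject_id"][()]),
            native_id=_as_str(sub["native_id"][()]) if "native_id" in sub
            else _as_str(sub["subject_id"][()]),
            age=int(sub["age"][()]),
            sex=_as_str(sub["sex"][()]),
            task=task,
        )

        etab = _require(f, "general/extracellular_ephys/electrodes")
        eids = np.asarray(etab["id"]) if "id" in etab else np.arange(len(etab["x"]))
        electrodes = [
            ElectrodeInfo(
                electrode_id=int(eids[i]),
                brain_area=_as_str(np.asarray(etab["location"])[i]),
                mni_xyz=(float(etab["x"][i]), float(etab["y"][i]), float(etab["z"][i])),
                orig_channel=int(etab["origChannel"][i]) if "origChannel" in etab else int(eids[i]),
            )
            for i in range(len(eids))
        ]

        ev = _require(f, "acquisition/events")
        events = EventStream(np.asarray(ev["timestamps"], dtype=float),
                             np.asarray(ev["data"], dtype=int))

        trials = []
        if task == "sternberg":
            tgrp = _require(f, "intervals/trials")
            import pandas as pd
            data = {"trial_id": np.asarray(tgrp["id"], dtype=int)}
            for ours, theirs in _NWB_TRIAL_COLS.items():
                data[ours] = np.asarray(_require(tgrp, theirs))
            trials = frame_to_trials(pd.DataFrame(data))

        tmpl = _require(f, "stimulus/templates/StimulusTemplates")
        keys = sorted(tmpl.keys(), key=lambda k: int(k.split("_")[-1]))
        images = [np.asarray(tmpl[k]) for k in keys]
        null_index = tmpl.attrs.get("null_index")
        stimuli = StimulusSet(images=images,
                              null_index=None if null_index is None else int(null_index))

        pres = _require(f, "stimulus/presentation/StimulusPresentation")
        presentations = list(zip(np.asarray(pres["data"], dtype=int).tolist(),
                                 np.asarray(pres["timestamps"], dtype=float).tolist()))

        ugrp = _require(f, "units")
        spike_times = np.asarray(_require(ugrp, "spike_times"), dtype=float)
        st_index = np.asarray(_require(ugrp, "spike_times_index"), dtype=int)
        unit_ids = np.asarray(ugrp["id"], dtype=int) if "id" in ugrp else np.arange(st_index.size)
        uelec = np.asarray(_require(ugrp, "electrodes"), dtype=int)

        if st_index.size and (np.any(np.diff(st_index) < 0) or st_index[-1] != spike_times.size):
            raise NwbIntegrityError(
                f"spike_times_index inconsistent: last index {st_index[-1] if st_index.size else 0} "
                f"vs {spike_times.size} stored spikes")

        waveforms = wf_index = None
        if "waveforms" in ugrp and "waveforms_index" in ugrp:
            waveforms = np.asarray(ugrp["waveforms"], dtype=float)
            wf_index = np.asarray(ugrp["waveforms_index"], dtype=int)
            if wf_index.size and wf_index[-1] != waveforms.shape[0]:
                raise NwbIntegrityError("waveforms_index inconsistent with waveforms store")

        gt = None
        if "ground_truth" in ugrp:
            gt = [_as_str(g) for g in np.asarray(ugrp["ground_truth"])]
        pref = np.asarray(ugrp["preferred_image"], dtype=int) if "preferred_image" in ugrp else None

        units = []
        starts = np.concatenate([[0], st_index[:-1]])
        for i in range(st_index.size):
            wf = None
            if waveforms is not None:
                w0 = 0 if i == 0 else wf_index[i - 1]
                wf = waveforms[w0:wf_index[i]]
            units.append(UnitRecord(
                unit_id=int(unit_ids[i]),
                electrode_id=int(eids[uelec[i]]),
                spike_times=spike_times[starts[i]:st_index[i]],
                waveforms=wf,
                ground_truth=None if gt is None or gt[i] == "" else gt[i],
                preferred_image=None if pref is None or pref[i] < 0 else int(pref[i]),
            ))

    return SessionRecord(subject=subject, electrodes=electrodes, units=units,
                         events=events, trials=trials, stimuli=stimuli,
                         presentations=presentations)


def write_nwb_session(session: SessionRecord, path: str | Path) -> Path:
    """Write a session into the released dataset's HDF5 group layout.

    Ground-truth labels of synthetic units are stored in extra ``units``
    columns so a round trip through this writer is lossless for the
    internal model.
    """
    path = Path(path)
    task_id = "SB" if session.subject.task == "sternberg" else "SC"
    ekey = {e.electrode_id: i for i, e in enumerate(session.electrodes)}
    with h5py.File(path, "w") as f:
        f.attrs["identifier"] = f"{task_id}_{session.subject.subject_id}_{session.subject.native_id}"
        f.attrs["session_description"] = f"{session.subject.task} session"

        sub = f.create_group("general/subject")
        sub["subject_id"] = session.subject.subject_id
        sub["native_id"] = session.subject.native_id
        sub["age"] = session.subject.age
        sub["sex"] = session.subject.sex

        etab = f.create_group("general/extracellular_ephys/electrodes")
        etab["id"] = np.array([e.electrode_id for e in session.electrodes], dtype=np.int64)
        etab["location"] = np.array([e.brain_area for e in session.electrodes],
                                    dtype=h5py.string_dtype())
        for k, axis in enumerate("xyz"):
            etab[axis] = np.array([e.mni_xyz[k] for e in session.electrodes])
        etab["origChannel"] = np.array([e.orig_channel for e in session.electrodes],
                                       dtype=np.int64)

        ev = f.create_group("acquisition/events")
        ev["data"] = session.events.codes.astype(np.int64)
        ev["timestamps"] = session.events.timestamps

        if session.subject.task == "sternberg":
            tgrp = f.create_group("intervals/trials")
            df = trials_to_frame(session.trials)
            tgrp["id"] = df["trial_id"].to_numpy(np.int64)
            for ours, theirs in _NWB_TRIAL_COLS.items():
                col = df[ours].to_numpy()
                tgrp[theirs] = col.astype(np.int64) if col.dtype.kind in "iu" else col.astype(float)
            tgrp["start_time"] = df["ts_fixation"].to_numpy(float)
            tgrp["stop_time"] = df["ts_response"].to_numpy(float)

        tmpl = f.create_group("stimulus/templates/StimulusTemplates")
        for i, img in enumerate(session.stimuli.images):
            tmpl[f"image_{i}"] = img
        if session.stimuli.null_index is not None:
            tmpl.attrs["null_index"] = session.stimuli.null_index

        pres = f.create_group("stimulus/presentation/StimulusPresentation")
        pres["data"] = np.array([i for i, _t in session.presentations], dtype=np.int64)
        pres["timestamps"] = np.array([t for _i, t in session.presentations], dtype=float)

        ugrp = f.create_group("units")
        ugrp["id"] = np.array([u.unit_id for u in session.units], dtype=np.int64)
        ugrp["electrodes"] = np.array([ekey[u.electrode_id] for u in session.units],
                                      dtype=np.int64)
        counts = np.array([u.n_spikes for u in session.units], dtype=np.int64)
        ugrp["spike_times_index"] = np.cumsum(counts)
        ugrp["spike_times"] = (np.concatenate([u.spike_times for u in session.units])
                               if session.units else np.empty(0))
        if any(u.waveforms is not None for u in session.units):
            wf_counts = np.array([0 if u.waveforms is None else u.waveforms.shape[0]
                                  for u in session.units], dtype=np.int64)
            ugrp["waveforms_index"] = np.cumsum(wf_counts)
            ugrp["waveforms_index_index"] = np.arange(1, len(session.units) + 1, dtype=np.int64)
            ugrp["waveforms"] = np.concatenate(
                [u.waveforms for u in session.units if u.waveforms is not None])
            n_samp = next(u.waveforms.shape[1] for u in session.units
                          if u.waveforms is not None)
            ugrp["waveform_mean"] = np.stack([
                (u.waveforms.mean(axis=0) if u.waveforms is not None and u.waveforms.size
                 else np.zeros(n_samp)) for u in session.units])
            ugrp["waveform_sd"] = np.stack([
                (u.waveforms.std(axis=0) if u.waveforms is not None and u.waveforms.size
                 else np.zeros(n_samp)) for u in session.units])
        ugrp["ground_truth"] = np.array([u.ground_truth or "" for u in session.units],
                                        dtype=h5py.string_dtype())
        ugrp["preferred_image"] = np.array(
            [-1 if u.preferred_image is None else u.preferred_image for u in session.units],
            dtype=np.int64)
    return path
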