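"""Ground-truth synthetic screening and Sternberg sessions.

The generator emulates the structure the analyses assume: the Sternberg
trial grammar and its TTL stream (fixation 0.9-1.0 s, one to three 1 s
encoding images separated by 1-200 ms blanks, a 2.5-2.8 s maintenance
period, a probe shown until the response), the screening task (54-64
images, six 1 s presentations each, 16-200 ms inter-stimulus intervals,
occasional control questions), and four unit classes spiking as
inhomogeneous Poisson processes with an absolute refractory dead time:

``concept``
    baseline firing, elevated to ``preferred_hz`` while the preferred
    image is on screen (with a fixed visual-response latency), and —
    when ``concept_persistence`` — elevated to ``concept_maintenance_hz``
    during the delay of trials whose encoding set contains the image.
``maintenance``
    elevated to ``maintenance_hz`` during every maintenance period.
``probe``
    elevated to ``probe_hz`` after every probe onset.
``null``
    homogeneous Poisson at ``baseline_hz``.

Per-spike waveforms are a fixed biphasic template scaled to the unit's
amplitude plus white noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (NULL_IMAGE_INDEX, SCREENING_CODES, STERNBERG_CODES,
                    ElectrodeInfo, EventStream, SessionRecord, StimulusSet,
                    SubjectMeta, TrialSternberg, UnitRecord)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic session.

    Timing ranges mirror the task as run in the clinic; rates are the
    planted effect sizes the selection analyses are expected to recover.
    """

    n_trials: int = 108
    n_images: int = 5  # Sternberg: 5; screening: 54-64
    load_probabilities: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    # timing (seconds)
    fixation_range: tuple[float, float] = (0.900, 1.000)
    image_duration: float = 1.0
    blank_range: tuple[float, float] = (0.001, 0.200)
    maintenance_range: tuple[float, float] = (2.5, 2.8)
    screening_isi_range: tuple[float, float] = (0.016, 0.200)
    screening_repeats: int = 6
    iti_range: tuple[float, float] = (1.0, 2.0)
    response_latency: float = 0.200  # visual response latency of units

    # firing rates (Hz)
    baseline_hz: float = 2.0
    preferred_hz: float = 10.0
    maintenance_hz: float = 8.0
    probe_hz: float = 8.0
    concept_maintenance_hz: float = 5.0
    dead_time: float = 0.003

    # behavior
    p_correct: float = 0.9
    rt_shift: float = 0.2
    rt_medians: tuple[float, float, float] = (0.85, 0.95, 1.05)
    rt_sigma: float = 0.3

    # unit population
    n_concept: int = 2
    n_maintenance: int = 2
    n_probe: int = 2
    n_null: int = 4
    concept_persistence: bool = True
    allow_encoding_repeats: bool = False
    units_per_electrode: int = 2

    # waveforms
    with_waveforms: bool = True
    n_samples: int = 256
    amplitude_uv: float = 60.0
    noise_sd_uv: float = 10.0

    control_question_every: int = 8  # mean presentations between questions
    seed: int = 0

    def validate(self, task: str = "sternberg") -> None:
        rates = (self.baseline_hz, self.preferred_hz, self.maintenance_hz,
                 self.probe_hz, self.concept_maintenance_hz)
        if any(r < 0 for r in rates):
            raise ConfigError("all rates must be >= 0")
        if self.dead_time < 0:
            raise ConfigError("dead_time must be >= 0")
        p = np.asarray(self.load_probabilities, dtype=float)
        if np.any(p < 0) or np.any(p > 1) or not np.isclose(p.sum(), 1.0):
            raise ConfigError("load_probabilities must be in [0,1] and sum to 1")
        if not 0 <= self.p_correct <= 1:
            raise ConfigError("p_correct must be in [0,1]")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if task == "screening" and not 54 <= self.n_images <= 64:
            raise ConfigError(f"screening needs 54-64 images, got {self.n_images}")
        if task == "sternberg" and self.n_images != 5:
            raise ConfigError("Sternberg sessions use exactly 5 images")


class PiecewiseRate:
    """Piecewise-constant firing-rate profile r(t), Hz."""

    def __init__(self, edges: np.ndarray, rates: np.ndarray):
        self.edges = np.asarray(edges, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if self.edges.size != self.rates.size + 1:
            raise ValueError("need len(edges) == len(rates) + 1")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @classmethod
    def from_intervals(cls, span: tuple[float, float], baseline: float,
                       intervals: list[tuple[float, float, float]]) -> "PiecewiseRate":
        """Baseline rate over ``span`` overridden by ``(t0, t1, rate)``
        intervals; overlaps resolve to the maximum rate."""
        t0, t1 = span
        cuts = {t0, t1}
        for a, b, _r in intervals:
            if t0 < a < t1:
                cuts.add(a)
            if t0 < b < t1:
                cuts.add(b)
        edges = np.array(sorted(cuts))
        rates = np.full(edges.size - 1, baseline, dtype=float)
        for a, b, r in intervals:
            i0 = np.searchsorted(edges, max(a, t0), side="left")
            i1 = np.searchsorted(edges, min(b, t1), side="left")
            if i1 > i0:
                rates[i0:i1] = np.maximum(rates[i0:i1], r)
        return cls(edges, rates)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.edges, t, side="right") - 1,
                      0, self.rates.size - 1)
        return self.rates[idx]

    @property
    def max_rate(self) -> float:
        return float(self.rates.max()) if self.rates.size else 0.0

    @property
    def span(self) -> tuple[float, float]:
        return float(self.edges[0]), float(self.edges[-1])


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_unit_spikes(rate_profile: PiecewiseRate, span: tuple[float, float],
                         dead_time: float, seed) -> np.ndarray:
    """Thinned inhomogeneous Poisson spike train with an absolute dead time.

    Returns strictly increasing spike times in ``[t0, t1)`` whose ISIs
    are all >= ``dead_time``.
    """
    t0, t1 = span
    if not t1 > t0:
        raise ValueError("span must have positive length")
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    rng = _as_rng(seed)
    rmax = rate_profile.max_rate
    if rmax == 0.0:
        return np.empty(0)
    n = rng.poisson(rmax * (t1 - t0))
    times = np.sort(t0 + rng.random(n) * (t1 - t0))
    keep = rng.random(n) < rate_profile(times) / rmax
    times = times[keep]
    if dead_time > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= dead_time:
                kept.append(t)
        times = np.array(kept)
    return times


def waveform_template(template_id: int, n_samples: int) -> np.ndarray:
    """Biphasic action-potential template normalized to unit peak."""
    t = np.linspace(0.0, 1.0, n_samples)
    widths = [(0.045, 0.11), (0.060, 0.14), (0.035, 0.09)]
    w1, w2 = widths[template_id % len(widths)]
    shape = np.exp(-((t - 0.30) / w1) ** 2) - 0.55 * np.exp(-((t - 0.48) / w2) ** 2)
    return shape / np.max(np.abs(shape))


def simulate_waveforms(n: int, template_id: int, amplitude: float,
                       noise_sd: float, n_samples: int, seed) -> np.ndarray:
    """``n`` spike waveforms: scaled template plus additive white noise (uV)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(seed)
    base = amplitude * waveform_template(template_id, n_samples)
    out = np.tile(base, (n, 1))
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=(n, n_samples))
    return out


def make_gaussian_feature_clouds(n_cluster: int, n_noise: int, dim: int,
                                 mean_offset, covariances, seed
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Two multivariate-normal point clouds: cluster at the origin, noise at
    ``mean_offset``; oracle inputs for the sorting-quality metrics.

    ``covariances`` is a pair ``(cov_cluster, cov_noise)``; either entry may
    be a full matrix or a scalar variance.
    """
    rng = _as_rng(seed)
    offset = np.asarray(mean_offset, dtype=float)
    if offset.shape != (dim,):
        raise ValueError(f"mean_offset must have shape ({dim},)")

    def full_cov(c):
        c = np.asarray(c, dtype=float)
        if c.ndim == 0:
            c = float(c) * np.eye(dim)
        if c.shape != (dim, dim):
            raise ValueError("covariance has wrong shape")
        try:
            np.linalg.cholesky(c + 1e-12 * np.eye(dim))
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance is not positive semi-definite") from exc
        return c

    cov_c, cov_n = (full_cov(covariances[0]), full_cov(covariances[1]))
    cluster = rng.multivariate_normal(np.zeros(dim), cov_c, size=n_cluster,
                                      method="cholesky")
    noise = rng.multivariate_normal(offset, cov_n, size=n_noise, method="cholesky")
    return cluster, noise


def _placeholder_images(n: int, rng: np.random.Generator) -> list[np.ndarray]:
    return [rng.integers(0, 256, size=(8, 8)).astype(float) for _ in range(n)]


def _unit_classes(config: GeneratorConfig, task: str) -> list[str]:
    if task == "screening":
        return ["concept"] * config.n_concept + ["null"] * config.n_null
    return (["concept"] * config.n_concept
            + ["maintenance"] * config.n_maintenance
            + ["probe"] * config.n_probe
            + ["null"] * config.n_null)


_AREA_BY_CLASS = {"concept": ("Hipp", "Amg"),
                  "maintenance": ("dACC", "preSMA"),
                  "probe": ("preSMA", "dACC"),
                  "null": ("Hipp", "Amg", "dACC", "preSMA", "vmPFC")}


def _build_population(config: GeneratorConfig, task: str,
                      rng: np.random.Generator
                      ) -> tuple[list[ElectrodeInfo], list[tuple[int, str, int]]]:
    """Assign classes to units and units to electrodes.

    Returns the electrode table and ``(unit_id, class, electrode_id)``
    triples; units of the same class share electrodes so projection and
    isolation metrics are defined.
    """
    classes = _unit_classes(config, task)
    electrodes: list[ElectrodeInfo] = []
    assignment: list[tuple[int, str, int]] = []
    uid = 0
    eid = 0
    per = max(1, config.units_per_electrode)
    i = 0
    while i < len(classes):
        group = classes[i:i + per]
        eid += 1
        area_pool = _AREA_BY_CLASS[group[0]]
        area = area_pool[(eid - 1) % len(area_pool)]
        electrodes.append(ElectrodeInfo(
            electrode_id=eid, brain_area=area,
            mni_xyz=tuple(np.round(rng.uniform(-40, 40, size=3), 2)),
            orig_channel=eid))
        for cls in group:
            uid += 1
            assignment.append((uid, cls, eid))
        i += per
    return electrodes, assignment


def _shifted_lognormal_rt(config: GeneratorConfig, load: int,
                          rng: np.random.Generator) -> float:
    median = config.rt_medians[load - 1]
    mu = np.log(max(median - config.rt_shift, 1e-3))
    return config.rt_shift + float(rng.lognormal(mu, config.rt_sigma))


def generate_sternberg_session(config: GeneratorConfig) -> SessionRecord:
    """One fully labelled synthetic Sternberg session."""
    config.validate("sternberg")
    rng = np.random.default_rng(config.seed)
    C = STERNBERG_CODES

    ev_t: list[float] = []
    ev_c: list[int] = []

    def emit(t: float, code: int) -> None:
        ev_t.append(t)
        ev_c.append(code)

    t = 0.0
    emit(t, C["start"])
    t += 1.0

    trials: list[TrialSternberg] = []
    presentations: list[tuple[int, float]] = []
    pic_ids = np.arange(1, config.n_images + 1)

    for trial_id in range(1, config.n_trials + 1):
        load = int(rng.choice((1, 2, 3), p=config.load_probabilities))
        enc = rng.choice(pic_ids, size=load, replace=config.allow_encoding_repeats)
        probe_in = int(rng.random() < 0.5)
        uniq = np.unique(enc)
        if probe_in:
            probe = int(rng.choice(uniq))
        else:
            out_pool = np.setdiff1d(pic_ids, uniq)
            probe = int(rng.choice(out_pool))

        ts_fix = t
        emit(ts_fix, C["fixation"])
        t = ts_fix + rng.uniform(*config.fixation_range)

        onsets = [0.0, 0.0, 0.0]
        ends = [0.0, 0.0, 0.0]
        for k in range(load):
            onsets[k] = t
            emit(t, C[f"pic{k + 1}"])
            ends[k] = t + config.image_duration
            if k < load - 1:
                emit(ends[k], C["transition"])
                t = ends[k] + rng.uniform(*config.blank_range)
            else:
                emit(ends[k], C["maintenance"])
                t = ends[k]
        ts_maint = t
        ts_probe = ts_maint + rng.uniform(*config.maintenance_range)
        emit(ts_probe, C["probe"])
        rt = _shifted_lognormal_rt(config, load, rng)
        ts_resp = ts_probe + rt
        emit(ts_resp, C["response"])
        t = ts_resp + rng.uniform(*config.iti_range)

        enc3 = tuple(int(enc[k]) if k < load else 0 for k in range(3))
        trials.append(TrialSternberg(
            trial_id=trial_id, load=load, enc_pic_ids=enc3, probe_pic_id=probe,
            probe_in_out=probe_in,
            response_accuracy=int(rng.random() < config.p_correct),
            ts_fixation=ts_fix,
            ts_enc1=onsets[0], ts_enc2=onsets[1], ts_enc3=onsets[2],
            ts_enc1_end=ends[0], ts_enc2_end=ends[1], ts_enc3_end=ends[2],
            ts_maintenance=ts_maint, ts_probe=ts_probe, ts_response=ts_resp))

        # stimulus presentation list: 3 encoding slots (null image for
        # absent slots, offset 10 ms from the previous entry) plus probe
        prev = 0.0
        for k in range(3):
            if k < load:
                presentations.append((enc3[k] - 1, onsets[k]))
                prev = onsets[k]
            else:
                prev = prev + 0.010
                presentations.append((NULL_IMAGE_INDEX, prev))
        presentations.append((probe - 1, ts_probe))

    emit(t + 1.0, C["end"])
    span = (0.0, t + 2.0)

    electrodes, assignment = _build_population(config, "sternberg", rng)
    units = _spike_units(config, "sternberg", trials, presentations,
                         assignment, span, rng)

    images = _placeholder_images(config.n_images + 1, rng)
    subject = SubjectMeta(subject_id="S1", native_id="SYN01",
                          age=int(rng.integers(18, 70)),
                          sex=("M", "F")[int(rng.integers(0, 2))],
                          task="sternberg")
    return SessionRecord(subject=subject, electrodes=electrodes, units=units,
                         events=EventStream(np.array(ev_t), np.array(ev_c)),
                         trials=trials,
                         stimuli=StimulusSet(images=images,
                                             null_index=NULL_IMAGE_INDEX),
                         presentations=presentations)


def _spike_units(config: GeneratorConfig, task: str,
                 trials: list[TrialSternberg],
                 presentations: list[tuple[int, float]],
                 assignment: list[tuple[int, str, int]],
                 span: tuple[float, float],
                 rng: np.random.Generator) -> list[UnitRecord]:
    lat = config.response_latency
    dur = config.image_duration
    units: list[UnitRecord] = []
    for unit_id, cls, eid in assignment:
        preferred: int | None = None
        intervals: list[tuple[float, float, float]] = []
        if cls == "concept":
            if task == "sternberg":
                preferred = int(rng.integers(1, config.n_images + 1))
                tidx = preferred - 1
            else:
                tidx = int(rng.integers(0, config.n_images))
                preferred = tidx + 1
            for idx, onset in presentations:
                if idx == tidx:
                    intervals.append((onset + lat, onset + dur + lat,
                                      config.preferred_hz))
            if task == "sternberg" and config.concept_persistence:
                for tr in trials:
                    if preferred in tr.encoded_ids():
                        intervals.append((tr.ts_maintenance, tr.ts_probe,
                                          config.concept_maintenance_hz))
        elif cls == "maintenance":
            for tr in trials:
                intervals.append((tr.ts_maintenance, tr.ts_probe,
                                  config.maintenance_hz))
        elif cls == "probe":
            for tr in trials:
                intervals.append((tr.ts_probe + lat, tr.ts_probe + dur + lat,
                                  config.probe_hz))
        profile = PiecewiseRate.from_intervals(span, config.baseline_hz, intervals)
        spikes = simulate_unit_spikes(profile, span, config.dead_time, rng)
        wf = None
        if config.with_waveforms:
            wf = simulate_waveforms(spikes.size, template_id=unit_id,
                                    amplitude=config.amplitude_uv * rng.uniform(0.7, 1.3),
                                    noise_sd=config.noise_sd_uv,
                                    n_samples=config.n_samples, seed=rng)
        units.append(UnitRecord(unit_id=unit_id, electrode_id=eid,
                                spike_times=spikes, waveforms=wf,
                                ground_truth=cls, preferred_image=preferred))
    return units


def generate_screening_session(config: GeneratorConfig) -> SessionRecord:
    """One synthetic screening session: every image shown exactly six times."""
    config.validate("screening")
    rng = np.random.default_rng(config.seed)
    C = SCREENING_CODES

    order = np.repeat(np.arange(config.n_images), config.screening_repeats)
    rng.shuffle(order)

    ev_t: list[float] = []
    ev_c: list[int] = []
    presentations: list[tuple[int, float]] = []
    t = 0.0
    ev_t.append(t)
    ev_c.append(C["start"])
    t += 1.0
    since_question = 0
    for idx in order:
        onset = t
        presentations.append((int(idx), onset))
        ev_t.append(onset)
        ev_c.append(C["pic_on"])
        off = onset + config.image_duration
        ev_t.append(off)
        ev_c.append(C["pic_off"])
        t = off
        since_question += 1
        if since_question >= config.control_question_every and rng.random() < 0.5:
            resp = t + rng.uniform(0.5, 1.5)
            ev_t.append(resp)
            ev_c.append(C["response"])
            t = resp
            since_question = 0
        t += rng.uniform(*config.screening_isi_range)
    ev_t.append(t + 1.0)
    ev_c.append(C["end"])
    span = (0.0, t + 2.0)

    electrodes, assignment = _build_population(config, "screening", rng)
    units = _spike_units(config, "screening", [], presentations, assignment,
                         span, rng)
    subject = SubjectMeta(subject_id="S1", native_id="SYN01",
                          age=int(rng.integers(18, 70)),
                          sex=("M", "F")[int(rng.integers(0, 2))],
                          task="screening")
    return SessionRecord(subject=subject, electrodes=electrodes, units=units,
                         events=EventStream(np.array(ev_t), np.array(ev_c)),
                         trials=[],
                         stimuli=StimulusSet(
                             images=_placeholder_images(config.n_images, rng),
                             null_index=None),
                         presentations=presentations)
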