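"""Permutation-based selection of concept, maintenance and probe cells.

A *concept cell* fires selectively for picture identity: a permuted
one-way ANOVA over the per-presentation responses (200-1000 ms after
stimulus onset) with image as the factor must be significant, and the
response to the empirically maximal image must exceed that to all other
images (one-sided permutation t-tests against each other image; the
reported max-vs-rest p is the worst pairwise p, so a unit responding
equally to two images fails).  ``AnalysisConfig.maxvsrest_pooled``
switches to a single test against the pooled non-preferred responses.

A *maintenance cell* fires more during the working-memory delay
(0-2500 ms of the maintenance period) than during the fixation baseline
(first 500 ms), invariant to memory content: a concept cell must pass
the same contrast restricted to trials that do not contain its
preferred image.

A *probe cell* fires more after probe onset (200-1000 ms) than during
both encoding and maintenance.

All permutation p-values follow the add-one convention
``p = (1 + #{permuted >= observed}) / (n_perm + 1)`` and are exactly
reproducible given the seed; ``exact=True`` enumerates every distinct
assignment instead.  Permuted statistics that tie the observed one count
as extreme; a small relative guard (1e-9) keeps mathematical ties from
being dropped to floating-point jitter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import AnalysisConfig, SessionRecord, UnitRecord
from .spikes import counts_in_windows, trial_period_rates


@dataclass
class PermTestResult:
    statistic: float  # F for the ANOVA, mean difference for the t-type test
    p: float
    n_perm: int
    seed: Optional[int]
    exact: bool = False


def _anova_f(V: np.ndarray, G: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Row-wise one-way ANOVA F for value matrix V (m x n)."""
    n = V.shape[1]
    k = counts.size
    total = V.sum(axis=1)
    gs = V @ G
    ss_between = (gs ** 2 / counts).sum(axis=1) - total ** 2 / n
    ss_total = (V ** 2).sum(axis=1) - total ** 2 / n
    ss_within = ss_total - ss_between
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / (k - 1)) / (ss_within / (n - k))
    # 0/0 (all values identical) defines F = 0; x/0 stays +inf so a
    # noiseless perfectly-grouped observation still beats its permutations
    return np.where(np.isnan(F), 0.0, F)


def _at_least(permuted: np.ndarray, observed: float) -> np.ndarray:
    """Tie-tolerant 'as extreme as observed' (ties count as extreme)."""
    if np.isinf(observed):
        return permuted >= observed
    return permuted >= observed - 1e-9 * max(1.0, abs(observed))


def permutation_anova(values: Sequence[float], groups: Sequence,
                      n_perm: int = 1000, seed=0,
                      exact: bool = False) -> PermTestResult:
    """Permuted one-way ANOVA: F on observed labels, p by label shuffling."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    k = labels.size
    n = values.size
    if k < 2:
        raise ValueError("need at least two groups")
    if n != groups.size:
        raise ValueError("values and groups must have equal length")
    G = np.zeros((n, k))
    G[np.arange(n), inv] = 1.0
    counts = G.sum(axis=0)
    obs = float(_anova_f(values[None, :], G, counts)[0])

    if exact:
        if n > 10:
            raise ValueError("exact enumeration is limited to n <= 10")
        count = total = 0
        chunk: list = []
        for perm in itertools.permutations(range(n)):
            chunk.append(perm)
            if len(chunk) == 50000:
                Fp = _anova_f(values[np.asarray(chunk)], G, counts)
                count += int(np.sum(_at_least(Fp, obs)))
                total += len(chunk)
                chunk = []
        if chunk:
            Fp = _anova_f(values[np.asarray(chunk)], G, counts)
            count += int(np.sum(_at_least(Fp, obs)))
            total += len(chunk)
        return PermTestResult(statistic=obs, p=count / total, n_perm=total,
                              seed=None, exact=True)

    rng = np.random.default_rng(seed)
    V = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
    Fp = _anova_f(V, G, counts)
    p = (1 + int(np.sum(_at_least(Fp, obs)))) / (n_perm + 1)
    return PermTestResult(statistic=obs, p=p, n_perm=n_perm,
                          seed=seed if isinstance(seed, int) else None)


def permutation_ttest(a: Sequence[float], b: Sequence[float],
                      alternative: str = "greater", n_perm: int = 1000,
                      seed=0, exact: bool = False) -> PermTestResult:
    """Permutation test on the difference of means ``mean(a) - mean(b)``.

    ``alternative='greater'`` counts permuted differences >= observed;
    ``'two-sided'`` compares absolute values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    obs = float(a.mean() - b.mean())

    def extreme(s: np.ndarray) -> np.ndarray:
        if alternative == "greater":
            return _at_least(s, obs)
        return _at_least(np.abs(s), abs(obs))

    if exact:
        count = total = 0
        for combo in itertools.combinations(range(n), na):
            total += 1
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            s = pooled[sel].mean() - pooled[~sel].mean()
            count += bool(extreme(np.array([s]))[0])
        return PermTestResult(statistic=obs, p=count / total, n_perm=total,
                              seed=None, exact=True)

    rng = np.random.default_rng(seed)
    V = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    s = V[:, :na].mean(axis=1) - V[:, na:].mean(axis=1)
    p = (1 + int(np.sum(extreme(s)))) / (n_perm + 1)
    return PermTestResult(statistic=obs, p=p, n_perm=n_perm,
                          seed=seed if isinstance(seed, int) else None)


@dataclass
class ClassificationResult:
    """Per-unit cell-type labels and their component p-values."""

    unit_id: int
    is_concept: bool = False
    is_maintenance: bool = False
    is_probe: bool = False
    preferred_image: Optional[int] = None
    anova_f: float = float("nan")
    anova_p: float = float("nan")
    maxvsrest_p: float = float("nan")
    maint_p: float = float("nan")
    maint_nonpref_p: float = float("nan")
    probe_vs_enc_p: float = float("nan")
    probe_vs_maint_p: float = float("nan")


def _unit_rng_seed(config: AnalysisConfig, unit_id: int, stage: int) -> list[int]:
    # derived per (unit, stage) so classification is invariant to unit order
    return [config.rng_seed, int(unit_id), stage]


def image_responses(unit: UnitRecord, session: SessionRecord,
                    config: AnalysisConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-presentation window responses (Hz) and their image labels (1-based).

    Sternberg sessions take one response per encoding presentation and —
    unless ``config.encoding_only`` — one per probe presentation; the
    screening task takes one per image presentation.
    """
    s0, s1 = config.window_stim_on
    onsets: list[float] = []
    labels: list[int] = []
    if session.subject.task == "screening":
        for idx, t in session.presentations:
            onsets.append(t)
            labels.append(idx + 1)
    else:
        for tr in session.trials:
            for k, onset in enumerate(tr.enc_onsets()):
                onsets.append(onset)
                labels.append(tr.enc_pic_ids[k])
            if not config.encoding_only:
                onsets.append(tr.ts_probe)
                labels.append(tr.probe_pic_id)
    onsets = np.asarray(onsets)
    rates = counts_in_windows(unit.spike_times, onsets + s0, onsets + s1) / (s1 - s0)
    return rates, np.asarray(labels, dtype=int)


def preferred_image(rates: np.ndarray, labels: np.ndarray) -> int:
    """Image (label) with the maximal mean response; ties break to the
    lowest image id."""
    if rates.size == 0:
        raise ValueError("no presentations")
    uniq = np.unique(labels)
    means = np.array([rates[labels == u].mean() for u in uniq])
    return int(uniq[np.argmax(means)])


def classify_concept_cells(session: SessionRecord,
                           config: AnalysisConfig | None = None
                           ) -> dict[int, ClassificationResult]:
    """Two-step concept-cell test for every unit in the session."""
    cfg = config or AnalysisConfig()
    out: dict[int, ClassificationResult] = {}
    for unit in session.units:
        res = ClassificationResult(unit_id=unit.unit_id)
        rates, labels = image_responses(unit, session, cfg)
        if np.unique(labels).size >= 2:
            anova = permutation_anova(rates, labels, n_perm=cfg.n_perm,
                                      seed=_unit_rng_seed(cfg, unit.unit_id, 1))
            res.anova_f = anova.statistic
            res.anova_p = anova.p
            pref = preferred_image(rates, labels)
            res.preferred_image = pref
            if cfg.maxvsrest_pooled:
                mvr_p = permutation_ttest(
                    rates[labels == pref], rates[labels != pref],
                    alternative="greater", n_perm=cfg.n_perm,
                    seed=_unit_rng_seed(cfg, unit.unit_id, 2)).p
            else:
                # intersection-union: preferred must beat every other image
                mvr_p = max(
                    permutation_ttest(
                        rates[labels == pref], rates[labels == other],
                        alternative="greater", n_perm=cfg.n_perm,
                        seed=_unit_rng_seed(cfg, unit.unit_id, 2) + [int(other)]).p
                    for other in np.unique(labels) if other != pref)
            res.maxvsrest_p = mvr_p
            res.is_concept = (anova.p < cfg.alpha) and (mvr_p < cfg.alpha)
        out[unit.unit_id] = res
    return out


def classify_maintenance_cells(session: SessionRecord,
                               config: AnalysisConfig | None = None,
                               concept: Optional[dict[int, ClassificationResult]] = None
                               ) -> dict[int, ClassificationResult]:
    """Maintenance-vs-baseline test; concept cells additionally must pass
    it on trials not containing their preferred image."""
    cfg = config or AnalysisConfig()
    concept = concept if concept is not None else classify_concept_cells(session, cfg)
    for unit in session.units:
        res = concept[unit.unit_id]
        pr = trial_period_rates(unit, session.trials, cfg)
        maint = pr["maintenance_hz"].to_numpy()
        base = pr["baseline_hz"].to_numpy()
        tt = permutation_ttest(maint, base, alternative="greater",
                               n_perm=cfg.n_perm,
                               seed=_unit_rng_seed(cfg, unit.unit_id, 3))
        res.maint_p = tt.p
        passed = tt.p < cfg.alpha
        if passed and res.is_concept and res.preferred_image is not None:
            nonpref = np.array([res.preferred_image not in tr.encoded_ids()
                                for tr in session.trials])
            if nonpref.sum() == 0:
                passed = False
            else:
                tt2 = permutation_ttest(maint[nonpref], base[nonpref],
                                        alternative="greater", n_perm=cfg.n_perm,
                                        seed=_unit_rng_seed(cfg, unit.unit_id, 4))
                res.maint_nonpref_p = tt2.p
                passed = tt2.p < cfg.alpha
        res.is_maintenance = bool(passed)
    return concept


def classify_probe_cells(session: SessionRecord,
                         config: AnalysisConfig | None = None,
                         results: Optional[dict[int, ClassificationResult]] = None
                         ) -> dict[int, ClassificationResult]:
    """Probe-period elevation against both encoding and maintenance."""
    cfg = config or AnalysisConfig()
    results = results if results is not None else {
        u.unit_id: ClassificationResult(unit_id=u.unit_id) for u in session.units}
    for unit in session.units:
        res = results[unit.unit_id]
        pr = trial_period_rates(unit, session.trials, cfg)
        probe = pr["probe_hz"].to_numpy()
        enc = pr[["enc1_hz", "enc2_hz", "enc3_hz"]].to_numpy().ravel()
        enc = enc[~np.isnan(enc)]
        maint = pr["maintenance_hz"].to_numpy()
        t_enc = permutation_ttest(probe, enc, alternative="greater",
                                  n_perm=cfg.n_perm,
                                  seed=_unit_rng_seed(cfg, unit.unit_id, 5))
        t_maint = permutation_ttest(probe, maint, alternative="greater",
                                    n_perm=cfg.n_perm,
                                    seed=_unit_rng_seed(cfg, unit.unit_id, 6))
        res.probe_vs_enc_p = t_enc.p
        res.probe_vs_maint_p = t_maint.p
        res.is_probe = (t_enc.p < cfg.alpha) and (t_maint.p < cfg.alpha)
    return results


def classify_session(session: SessionRecord,
                     config: AnalysisConfig | None = None
                     ) -> dict[int, ClassificationResult]:
    """Run all three classifiers (Sternberg) or the concept test only
    (screening)."""
    cfg = config or AnalysisConfig()
    results = classify_concept_cells(session, cfg)
    if session.subject.task == "sternberg":
        classify_maintenance_cells(session, cfg, results)
        classify_probe_cells(session, cfg, results)
    return results


def screening_image_selection(session: SessionRecord,
                              config: AnalysisConfig | None = None,
                              k: int = 5) -> list[int]:
    """Choose the ``k`` images to carry into the Sternberg task.

    Significantly selective units contribute their preferred images,
    ranked by ANOVA F; remaining slots are filled by the images with the
    strongest across-unit peak mean response.
    """
    cfg = config or AnalysisConfig()
    if session.stimuli.n_images < k:
        raise ValueError(f"need at least {k} images, session has "
                         f"{session.stimuli.n_images}")
    sig: list[tuple[float, int]] = []  # (F, preferred image)
    mean_by_image: dict[int, list[float]] = {}
    for unit in session.units:
        rates, labels = image_responses(unit, session, cfg)
        anova = permutation_anova(rates, labels, n_perm=cfg.n_perm,
                                  seed=_unit_rng_seed(cfg, unit.unit_id, 7))
        pref = preferred_image(rates, labels)
        if anova.p < cfg.alpha:
            sig.append((anova.statistic, pref))
        for u in np.unique(labels):
            mean_by_image.setdefault(int(u), []).append(
                float(rates[labels == u].mean()))
    chosen: list[int] = []
    for _f, img in sorted(sig, key=lambda t: (-t[0], t[1])):
        if img not in chosen:
            chosen.append(img)
        if len(chosen) == k:
            return chosen
    # fallback: strongest non-selective responses (across-unit peak mean)
    peak = {img: max(v) for img, v in mean_by_image.items()}
    for img in sorted(peak, key=lambda i: (-peak[i], i)):
        if img not in chosen:
            chosen.append(img)
        if len(chosen) == k:
            break
    return chosen


def persistence_contrast(session: SessionRecord,
                         results: dict[int, ClassificationResult],
                         config: AnalysisConfig | None = None) -> dict:
    """Population test of concept-cell persistent activity.

    For each concept cell, the mean maintenance-period rate over trials
    whose encoding set contains its preferred image is paired against
    the mean over trials that do not; a one-sided paired t-test asks
    whether preferred-trial delay activity is higher.
    """
    cfg = config or AnalysisConfig()
    concept_units = [u for u in session.units
                     if results[u.unit_id].is_concept]
    if len(concept_units) < 2:
        raise ValueError("need at least two concept cells")
    pref_means = []
    nonpref_means = []
    for unit in concept_units:
        pref_img = results[unit.unit_id].preferred_image
        pr = trial_period_rates(unit, session.trials, cfg)
        maint = pr["maintenance_hz"].to_numpy()
        mask = np.array([pref_img in tr.encoded_ids() for tr in session.trials])
        if mask.sum() == 0 or (~mask).sum() == 0:
            continue
        pref_means.append(float(maint[mask].mean()))
        nonpref_means.append(float(maint[~mask].mean()))
    if len(pref_means) < 2:
        raise ValueError("need at least two concept cells with both conditions")
    t = stats.ttest_rel(pref_means, nonpref_means, alternative="greater")
    return {"mean_pref_hz": float(np.mean(pref_means)),
            "mean_nonpref_hz": float(np.mean(nonpref_means)),
            "p": float(t.pvalue), "n_cells": len(pref_means)}
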