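"""Permutation tests (against exhaustive-enumeration oracles) and the
concept / maintenance / probe cell classifiers."""

import dataclasses
import itertools

import numpy as np
import pytest
from scipy import stats

from sternwm.model import AnalysisConfig
from sternwm.selection import (classify_concept_cells,
                               classify_maintenance_cells,
                               classify_probe_cells, classify_session,
                               permutation_anova, permutation_ttest,
                               persistence_contrast, preferred_image,
                               screening_image_selection)
from sternwm.synth import GeneratorConfig, generate_screening_session, \
    generate_sternberg_session


def results_equal(a, b):
    """Field-wise equality of two classification dicts, NaN-tolerant."""
    if set(a) != set(b):
        return False
    for uid in a:
        for field in dataclasses.fields(a[uid]):
            va = getattr(a[uid], field.name)
            vb = getattr(b[uid], field.name)
            if isinstance(va, float) and np.isnan(va) and np.isnan(vb):
                continue
            if va != vb:
                return False
    return True


def tie_ge(stat, obs):
    """Tie-tolerant 'as extreme' comparison (ties count as extreme)."""
    return stat >= obs - 1e-9 * max(1.0, abs(obs))


def exhaustive_anova_p(values, groups):
    """Brute-force permutation ANOVA p over all orderings."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    def f_stat(v):
        samples = [v[groups == g] for g in np.unique(groups)]
        f = stats.f_oneway(*samples).statistic
        return f if np.isfinite(f) else 0.0
    obs = f_stat(values)
    perms = [f_stat(values[list(p)]) for p in
             itertools.permutations(range(values.size))]
    return np.mean([tie_ge(f, obs) for f in perms])


def exhaustive_ttest_p(a, b, alternative="greater"):
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    obs = np.mean(a) - np.mean(b)
    count = total = 0
    for combo in itertools.combinations(range(n), na):
        total += 1
        sel = np.zeros(n, bool)
        sel[list(combo)] = True
        s = pooled[sel].mean() - pooled[~sel].mean()
        hit = tie_ge(s, obs) if alternative == "greater" \
            else tie_ge(abs(s), abs(obs))
        count += hit
    return count / total


class TestPermutationAnova:
    def test_identical_values_give_p_one(self):
        res = permutation_anova([3.0] * 8, [1, 1, 2, 2, 3, 3, 4, 4],
                                n_perm=200, seed=0)
        assert res.p == 1.0

    def test_exact_mode_matches_enumeration_oracle(self):
        values = np.array([4.0, 7.0, 1.0, 2.0], dtype=float)
        groups = np.array([0, 0, 1, 1])
        res = permutation_anova(values, groups, exact=True)
        assert res.p == pytest.approx(exhaustive_anova_p(values, groups),
                                      abs=1e-12)

    def test_monte_carlo_close_to_exact(self):
        values = np.array([5.0, 6.0, 9.0, 1.0, 2.0, 3.0])
        groups = np.array([0, 0, 0, 1, 1, 1])
        exact = permutation_anova(values, groups, exact=True).p
        mc = permutation_anova(values, groups, n_perm=2000, seed=3).p
        se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(mc - exact) < 4 * se + 1e-3

    def test_statistic_is_anova_f(self, rng):
        values = rng.normal(size=12)
        groups = np.repeat([0, 1, 2], 4)
        res = permutation_anova(values, groups, n_perm=100, seed=0)
        expected = stats.f_oneway(*[values[groups == g] for g in range(3)])
        assert res.statistic == pytest.approx(expected.statistic, rel=1e-9)

    def test_deterministic_given_seed(self, rng):
        values = rng.normal(size=20)
        groups = np.repeat([0, 1], 10)
        a = permutation_anova(values, groups, n_perm=500, seed=42)
        b = permutation_anova(values, groups, n_perm=500, seed=42)
        assert a.p == b.p

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_anova([1.0, 2.0], [1, 1])


class TestPermutationTtest:
    def test_identical_samples_give_p_one(self):
        res = permutation_ttest([2.0, 2.0, 2.0], [2.0, 2.0, 2.0],
                                n_perm=200, seed=0)
        assert res.p == 1.0

    @pytest.mark.parametrize("alternative", ["greater", "two-sided"])
    def test_exact_mode_matches_enumeration_oracle(self, alternative):
        a = np.array([5.0, 7.0, 6.0])
        b = np.array([1.0, 2.0, 3.0])
        res = permutation_ttest(a, b, alternative=alternative, exact=True)
        assert res.p == pytest.approx(
            exhaustive_ttest_p(a, b, alternative), abs=1e-12)

    def test_monte_carlo_close_to_exact(self):
        a = np.array([4.0, 9.0, 2.0])
        b = np.array([1.0, 3.0, 5.0])
        exact = permutation_ttest(a, b, exact=True).p
        mc = permutation_ttest(a, b, n_perm=2000, seed=5).p
        se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(mc - exact) < 4 * se + 1e-3

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            permutation_ttest([], [1.0])

    def test_add_one_lower_bound(self, rng):
        # the add-one convention bounds p below by 1/(n_perm+1)
        a = rng.normal(10, 0.1, 50)
        b = rng.normal(0, 0.1, 50)
        res = permutation_ttest(a, b, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)


class TestPreferredImage:
    def test_max_mean_selected(self):
        rates = np.array([10.0, 10.0, 2.0, 2.0, 2.0, 2.0])
        labels = np.array([3, 3, 1, 1, 2, 2])
        assert preferred_image(rates, labels) == 3

    def test_tie_breaks_to_lowest_id(self):
        rates = np.array([5.0, 5.0, 1.0])
        labels = np.array([4, 2, 1])
        assert preferred_image(rates, labels) == 2

    def test_matches_groupby_oracle(self, rng):
        rates = rng.normal(5, 1, 60)
        labels = rng.integers(1, 6, 60)
        uniq = np.unique(labels)
        means = {u: rates[labels == u].mean() for u in uniq}
        assert preferred_image(rates, labels) == max(
            sorted(means), key=lambda u: means[u])


class TestClassifiers:
    def test_equal_two_image_responder_is_not_concept(self, fast_config):
        """A unit responding identically and noiselessly to its two best
        images fails the max-vs-rest step."""
        cfg = GeneratorConfig(seed=61, n_trials=60, n_concept=0,
                              n_maintenance=0, n_probe=0, n_null=1,
                              with_waveforms=False)
        s = generate_sternberg_session(cfg)
        # replace the null unit's spikes: one spike burst of equal size in
        # every encoding window of images 1 and 2, silence elsewhere
        spikes = []
        for tr in s.trials:
            for k, onset in enumerate(tr.enc_onsets()):
                if tr.enc_pic_ids[k] in (1, 2):
                    spikes.extend(onset + 0.3 + 0.01 * np.arange(8))
            if tr.probe_pic_id in (1, 2):
                spikes.extend(tr.ts_probe + 0.3 + 0.01 * np.arange(8))
        unit = dataclasses.replace(s.units[0],
                                   spike_times=np.sort(np.array(spikes)),
                                   waveforms=None)
        s = dataclasses.replace(s, units=[unit])
        res = classify_concept_cells(s, fast_config)[unit.unit_id]
        assert res.anova_p < fast_config.alpha  # strongly image-selective
        assert not res.is_concept  # but no unique maximal image
        assert res.maxvsrest_p >= fast_config.alpha

    def test_probe_encoding_equal_unit_is_not_probe(self, fast_config):
        cfg = GeneratorConfig(seed=62, n_trials=60, n_concept=0,
                              n_maintenance=0, n_probe=0, n_null=1,
                              with_waveforms=False)
        s = generate_sternberg_session(cfg)
        spikes = []
        for tr in s.trials:  # same elevated burst in probe AND encoding
            for onset in tr.enc_onsets():
                spikes.extend(onset + 0.3 + 0.02 * np.arange(10))
            spikes.extend(tr.ts_probe + 0.3 + 0.02 * np.arange(10))
        unit = dataclasses.replace(s.units[0],
                                   spike_times=np.sort(np.array(spikes)),
                                   waveforms=None)
        s = dataclasses.replace(s, units=[unit])
        res = classify_probe_cells(s, fast_config)[unit.unit_id]
        assert not res.is_probe
        assert res.probe_vs_enc_p >= fast_config.alpha

    def test_preferred_only_persistence_is_not_maintenance(self, fast_config):
        """A concept cell persistent only on preferred trials must fail the
        non-preferred maintenance-vs-baseline test."""
        cfg = GeneratorConfig(seed=63, n_trials=108, n_concept=4,
                              n_maintenance=0, n_probe=0, n_null=0,
                              concept_persistence=True,
                              concept_maintenance_hz=9.0,
                              with_waveforms=False)
        s = generate_sternberg_session(cfg)
        results = classify_session(s, fast_config)
        concept_hits = [r for r in results.values() if r.is_concept]
        assert len(concept_hits) >= 3
        for r in concept_hits:
            assert not r.is_maintenance

    def test_classification_invariant_to_unit_order_and_time_shift(self):
        cfg = GeneratorConfig(seed=64, n_trials=30, n_concept=1,
                              n_maintenance=1, n_probe=1, n_null=1,
                              with_waveforms=False)
        s = generate_sternberg_session(cfg)
        ac = AnalysisConfig(n_perm=200, rng_seed=9)
        base = classify_session(s, ac)

        reordered = dataclasses.replace(s, units=list(reversed(s.units)))
        assert results_equal(classify_session(reordered, ac), base)

        shift = 1000.0
        shifted = dataclasses.replace(
            s,
            units=[dataclasses.replace(u, spike_times=u.spike_times + shift)
                   for u in s.units],
            trials=[dataclasses.replace(
                t, **{f: getattr(t, f) + shift for f in
                      ("ts_fixation", "ts_enc1", "ts_enc2", "ts_enc3",
                       "ts_enc1_end", "ts_enc2_end", "ts_enc3_end",
                       "ts_maintenance", "ts_probe", "ts_response")
                      if getattr(t, f) != 0.0})
                for t in s.trials],
            presentations=[(i, t + shift) for i, t in s.presentations])
        moved = classify_session(shifted, ac)
        # labels and preferred images are shift-invariant; p-values may move
        # by a hair when a spike sits exactly on a rounded window edge
        for uid, r in base.items():
            m = moved[uid]
            assert (m.is_concept, m.is_maintenance, m.is_probe,
                    m.preferred_image) == (r.is_concept, r.is_maintenance,
                                           r.is_probe, r.preferred_image)
            for field in ("anova_p", "maxvsrest_p", "maint_p",
                          "probe_vs_enc_p", "probe_vs_maint_p"):
                va, vb = getattr(r, field), getattr(m, field)
                assert (np.isnan(va) and np.isnan(vb)) or abs(va - vb) < 0.05


class TestScreeningSelection:
    def test_planted_units_pick_their_images(self, screening_session,
                                             fast_config):
        planted = {u.preferred_image for u in screening_session.units
                   if u.ground_truth == "concept"}
        chosen = screening_image_selection(screening_session, fast_config)
        assert len(chosen) == 5
        assert planted <= set(chosen)

    def test_no_selective_units_falls_back_to_strongest(self, fast_config):
        cfg = GeneratorConfig(seed=65, n_images=54, n_concept=0, n_null=4,
                              with_waveforms=False)
        s = generate_screening_session(cfg)
        chosen = screening_image_selection(s, fast_config)
        assert len(chosen) == len(set(chosen)) == 5
        # deterministic given the analysis seed
        assert chosen == screening_image_selection(s, fast_config)

    def test_too_few_images_rejected(self, sternberg_session, fast_config):
        with pytest.raises(ValueError):
            screening_image_selection(sternberg_session, fast_config, k=7)


class TestPersistenceContrast:
    def test_planted_population_prefers_preferred(self, fast_config):
        cfg = GeneratorConfig(seed=66, n_trials=108, n_concept=6,
                              n_maintenance=0, n_probe=0, n_null=0,
                              with_waveforms=False)
        s = generate_sternberg_session(cfg)
        results = classify_session(s, fast_config)
        out = persistence_contrast(s, results, fast_config)
        assert out["mean_pref_hz"] > out["mean_nonpref_hz"]
        assert out["p"] < 0.01

    def test_single_concept_cell_rejected(self, fast_config):
        cfg = GeneratorConfig(seed=67, n_trials=40, n_concept=1,
                              n_maintenance=0, n_probe=0, n_null=1,
                              with_waveforms=False)
        s = generate_sternberg_session(cfg)
        results = classify_session(s, fast_config)
        only = [uid for uid, r in results.items() if r.is_concept]
        for uid, r in results.items():
            r.is_concept = uid == only[0] if only else False
        with pytest.raises(ValueError):
            persistence_contrast(s, results, fast_config)
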