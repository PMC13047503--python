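"""Synthetic cohort generator: presets, sampling, simulators, dataset layout."""

import numpy as np
import pytest

from oxymet.nirs import NirsProtocol
from oxymet.synth import (
    CohortPreset,
    TruncatedNormal,
    builtin_presets,
    generate_cohort,
    sample_animal,
    simulate_asl_stack,
    simulate_disease_course,
    simulate_nirs_timeseries,
)
from oxymet.synth import _sto2_trajectory


class TestTruncatedNormal:
    def test_moment_matching_reproduces_observed_moments(self, rng):
        dist = TruncatedNormal(63.8, 14.8, lower=0.0, upper=100.0)
        draws = dist.sample(rng, size=100_000)
        assert draws.mean() == pytest.approx(63.8, abs=0.15)
        assert draws.std(ddof=1) == pytest.approx(14.8, abs=0.15)
        assert draws.min() >= 0.0 and draws.max() <= 100.0

    def test_far_bounds_leave_parameters_unchanged(self):
        dist = TruncatedNormal(100.0, 10.0, lower=30.0)
        assert dist.parent_params == (100.0, 10.0)

    def test_zero_sd_is_degenerate_point_mass(self, rng):
        dist = TruncatedNormal(5.0, 0.0)
        assert dist.sample(rng) == 5.0
        assert np.all(dist.sample(rng, size=4) == 5.0)

    def test_mean_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            TruncatedNormal(120.0, 5.0, lower=0.0, upper=100.0)


class TestPresets:
    def test_three_arms_with_reported_sizes(self, presets):
        assert set(presets) == {"naive", "cfa_ptx", "eae"}
        assert [presets[g].n for g in ("naive", "cfa_ptx", "eae")] == [15, 14, 13]

    def test_eae_sto2_preset(self, presets):
        assert presets["eae"].sto2.mean == 63.8
        assert presets["eae"].sto2.sd == 14.8

    def test_control_arms_have_no_disease_course(self, presets):
        assert presets["naive"].disease is None
        assert presets["cfa_ptx"].disease is None
        assert presets["eae"].disease is not None

    def test_invalid_preset_rejected(self, presets):
        base = presets["naive"]
        with pytest.raises(ValueError):
            CohortPreset(
                name="bad", n=0, cbf=base.cbf, sto2=base.sto2,
                tot_cco=base.tot_cco, oxidized_fraction=base.oxidized_fraction,
            )


class TestAnimalSampling:
    def test_same_seed_is_deterministic(self, presets):
        a = sample_animal(presets["eae"], 123)
        b = sample_animal(presets["eae"], 123)
        assert a == b

    def test_law_of_large_numbers_on_sto2(self, presets):
        draws = [sample_animal(presets["naive"], s).sto2 for s in range(10_000)]
        assert np.mean(draws) == pytest.approx(presets["naive"].sto2.mean, abs=0.2)

    def test_zero_variance_preset_collapses_to_means(self, presets):
        base = presets["naive"]
        frozen = CohortPreset(
            name="frozen", n=3,
            cbf=TruncatedNormal(250.0, 0.0, lower=0.0),
            sto2=TruncatedNormal(80.0, 0.0, lower=0.0, upper=100.0),
            tot_cco=TruncatedNormal(4.5, 0.0, lower=0.0),
            oxidized_fraction=TruncatedNormal(0.75, 0.0, lower=0.0, upper=1.0),
            thb=TruncatedNormal(100.0, 0.0, lower=0.0),
            pathlength=TruncatedNormal(1.8, 0.0, lower=0.0),
        )
        animals = [sample_animal(frozen, s) for s in (1, 2, 3)]
        assert all(a.cbf == 250.0 and a.sto2 == 80.0 for a in animals)

    def test_derived_quantities_consistent(self, presets):
        a = sample_animal(presets["eae"], 7)
        assert a.dhb == pytest.approx(a.thb * (1 - a.sto2 / 100), rel=1e-12)
        assert a.re_cco == pytest.approx(a.tot_cco - a.ox_cco, rel=1e-12)
        assert a.hbo2 + a.dhb == pytest.approx(a.thb, rel=1e-12)

    def test_correlated_arms_produce_cbf_sto2_correlation(self, presets):
        animals = [sample_animal(presets["eae"], s) for s in range(2000)]
        cbf = np.array([a.cbf for a in animals])
        sto2 = np.array([a.sto2 for a in animals])
        r = np.corrcoef(cbf, sto2)[0, 1]
        assert r == pytest.approx(presets["eae"].rho_cbf_sto2, abs=0.08)


class TestNirsSimulator:
    def test_full_rate_frame_count(self, presets, table, protocol):
        ph = sample_animal(presets["naive"], 1)
        rec = simulate_nirs_timeseries(ph, table, protocol, noise_sd_od=0.0, seed=0)
        assert rec.times.size == 9000  # 6 Hz x 25 min

    def test_saturation_collapses_during_anoxia(self, presets, protocol):
        ph = sample_animal(presets["naive"], 1)
        times = np.arange(0.0, protocol.total_duration, 1 / 6)
        sto2_t = _sto2_trajectory(times, ph, protocol)
        before = times < protocol.anoxia_window[0]
        assert np.all(sto2_t[before] == ph.sto2)
        end_idx = np.searchsorted(times, protocol.anoxia_window[1]) - 1
        assert sto2_t[end_idx] < 0.01 * ph.sto2  # dHb ~ tHb at plateau

    def test_deterministic_per_seed(self, presets, table, short_protocol):
        ph = sample_animal(presets["naive"], 1)
        a = simulate_nirs_timeseries(ph, table, short_protocol, 1e-3, seed=5)
        b = simulate_nirs_timeseries(ph, table, short_protocol, 1e-3, seed=5)
        np.testing.assert_array_equal(a.attenuation, b.attenuation)

    def test_negative_noise_rejected(self, presets, table, short_protocol):
        ph = sample_animal(presets["naive"], 1)
        with pytest.raises(ValueError):
            simulate_nirs_timeseries(ph, table, short_protocol, -1.0, seed=0)


class TestAslSimulator:
    def test_tr_grid_and_geometry(self, presets):
        ph = sample_animal(presets["naive"], 1)
        sim = simulate_asl_stack(ph, noise_sd=0.0, seed=0)
        assert sim.stack.tr_list == (0.1, 0.5, 1.0, 3.0, 7.5)
        assert sim.stack.controls.shape == (2, 128, 128)
        assert sim.stack.geometry.fov_mm == (25.6, 25.6)

    def test_tags_below_controls_noise_free(self, presets):
        ph = sample_animal(presets["naive"], 1)
        sim = simulate_asl_stack(ph, noise_sd=0.0, seed=0)
        assert np.all(sim.stack.tags <= sim.stack.controls + 1e-12)

    def test_cortex_mask_nonempty_and_mean_preserving(self, presets):
        ph = sample_animal(presets["naive"], 1)
        sim = simulate_asl_stack(ph, noise_sd=0.0, seed=0)
        assert sim.cortex_mask.sum() > 500
        assert sim.true_cbf_map[sim.cortex_mask].mean() == pytest.approx(ph.cbf, rel=1e-12)


class TestDiseaseCourse:
    def test_control_course_is_all_zero(self, presets):
        course = simulate_disease_course(presets["cfa_ptx"], 3)
        assert np.all(course.total == 0)

    def test_components_resum_and_stay_in_range(self, presets):
        for seed in range(20):
            course = simulate_disease_course(presets["eae"], seed)
            np.testing.assert_array_equal(
                course.total, course.tail + course.limbs.sum(axis=1)
            )
            assert course.total.max() <= 14

    def test_zero_before_onset_and_plateau_at_peak(self, presets):
        course = simulate_disease_course(presets["eae"], 5)
        assert np.all(course.total[course.days < 10] == 0)
        peak = course.total[(course.days >= 15) & (course.days <= 17)]
        assert np.all(peak == peak[0]) and peak[0] > 0

    def test_cohort_peak_mean_near_preset_plateau(self, presets):
        scores = []
        for seed in range(200):
            course = simulate_disease_course(presets["eae"], seed)
            sel = (course.days >= 15) & (course.days <= 17)
            scores.append(course.total[sel].mean())
        assert np.mean(scores) == pytest.approx(7.9, abs=0.3)


@pytest.fixture(scope="module")
def tiny_presets(presets):
    out = {}
    for name in ("naive", "eae"):
        p = presets[name]
        out[name] = CohortPreset(
            name=p.name, n=2, cbf=p.cbf, sto2=p.sto2, tot_cco=p.tot_cco,
            oxidized_fraction=p.oxidized_fraction, thb=p.thb, sao2=p.sao2,
            rho_cbf_sto2=p.rho_cbf_sto2, pathlength=p.pathlength, disease=p.disease,
        )
    return out


class TestCohortGeneration:
    def test_dataset_layout_and_determinism(self, tiny_presets, table, short_protocol, tmp_path):
        m1 = generate_cohort(tiny_presets, tmp_path / "a", seed=9, table=table,
                             protocol=short_protocol, decimation=1)
        m2 = generate_cohort(tiny_presets, tmp_path / "b", seed=9, table=table,
                             protocol=short_protocol, decimation=1)
        assert len(m1) == 4
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()
        adir = tmp_path / "a" / "naive" / "naive_01"
        for f in ("spectra.csv", "scores.csv", "sidecar.json"):
            assert (adir / f).exists()
        for f in ("controls", "tags", "tr_series", "cortex_mask"):
            assert (adir / "asl" / f"{f}.nii.gz").exists()

    def test_manifest_satisfies_physiology_invariants(self, tiny_presets, table,
                                                      short_protocol, tmp_path):
        m = generate_cohort(tiny_presets, tmp_path / "c", seed=4, table=table,
                            protocol=short_protocol, decimation=1)
        assert np.allclose(m["dhb"], m["thb"] * (1 - m["sto2"] / 100))
        assert np.allclose(m["tot_cco"], m["ox_cco"] + m["re_cco"])
        assert (m["sto2"].between(0, 100)).all()
        assert (m["pathlength_cm"] > 0).all()
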