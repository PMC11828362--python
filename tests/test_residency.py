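"""Residency analytics: track starts, RI, periods, diel, PAM, AMDR, GLM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seamount_oasis import residency as rz
from seamount_oasis import synthetic as syn


def log_from_days(days, tag="A", receiver="GR01", seamount="Grattan"):
    base = pd.Timestamp("2017-06-01 08:00", tz="UTC")
    return pd.DataFrame({
        "timestamp": [base + pd.Timedelta(days=int(d)) for d in days],
        "receiver_id": receiver,
        "seamount_id": seamount,
        "tag_id": tag,
    })


class TestTrackStart:
    def test_first_consecutive_pair_wins(self):
        ev = log_from_days([3, 4, 9])
        assert rz.track_start(ev, "A") == pd.Timestamp("2017-06-04", tz="UTC")

    def test_no_consecutive_pair_returns_none(self):
        ev = log_from_days([2, 5, 8])
        assert rz.track_start(ev, "A") is None

    def test_daily_detections_start_on_first_day(self):
        ev = log_from_days(range(10))
        assert rz.track_start(ev, "A") == pd.Timestamp("2017-06-01", tz="UTC")


class TestResidencyIndex:
    def test_every_day_detected_gives_one(self):
        ev = log_from_days(range(50))
        end = pd.Timestamp("2017-06-01", tz="UTC") + pd.Timedelta(days=49)
        assert rz.residency_index(ev, "A", study_end=end) == 1.0

    def test_30_of_300_days(self):
        ev = log_from_days(range(30))
        end = pd.Timestamp("2017-06-01", tz="UTC") + pd.Timedelta(days=299)
        assert rz.residency_index(ev, "A", study_end=end) == pytest.approx(0.1)

    def test_union_of_disjoint_day_sets_is_additive(self):
        d1, d2 = set(range(0, 20)), set(range(40, 55))
        ev = log_from_days(sorted(d1 | d2))
        end = pd.Timestamp("2017-06-01", tz="UTC") + pd.Timedelta(days=99)
        ri = rz.residency_index(ev, "A", study_end=end)
        assert ri == pytest.approx((len(d1) + len(d2)) / 100)

    def test_empty_window_rejected(self):
        ev = log_from_days(range(5))
        with pytest.raises(ValueError):
            rz.residency_index(ev, "A", window=("2017-06-10", "2017-06-01"))

    def test_transient_generator_truth(self, detection_log):
        events, truth, _ = detection_log
        end = pd.Timestamp("2017-06-01", tz="UTC") + pd.Timedelta(days=299)
        ri = rz.residency_index(events, "TRA1", study_end=end)
        assert ri == pytest.approx(0.1, abs=0.01)   # departs day 30 of 300


class TestResidencyPeriods:
    def test_twenty_day_run_is_one_period(self):
        ev = log_from_days(range(20))
        assert len(rz.residency_periods(ev, "A")) == 1

    def test_thirteen_day_run_is_no_period(self):
        ev = log_from_days(range(13))
        assert rz.residency_periods(ev, "A") == []

    def test_two_qualifying_runs(self):
        ev = log_from_days(list(range(15)) + list(range(20, 34)))
        periods = rz.residency_periods(ev, "A")
        assert len(periods) == 2
        lens = [(e - s).days + 1 for s, e in periods]
        assert lens == [15, 14]


class TestAttrition:
    def test_all_residents_flat_at_one(self):
        ev = pd.concat([log_from_days(range(60), tag=t)
                        for t in ("A", "B", "C")], ignore_index=True)
        out = rz.attrition_curve(ev, study_days=60)
        assert np.allclose(out.proportion, 1.0)

    def test_biphasic_mixture_stabilizes_near_half(self):
        animals = pd.DataFrame({
            "tag_id": [f"R{i}" for i in range(5)] + [f"T{i}" for i in range(5)],
            "profile": ["resident"] * 5 + ["transient"] * 5,
            "departure_day": [np.inf] * 5 + [20.0, 40.0, 60.0, 80.0, 85.0],
            "p_daily": 0.97,
        })
        ev, _, _ = syn.gen_detection_log(
            syn.DetectionConfig(seed=3, study_days=300, animals=animals))
        out = rz.attrition_curve(ev, study_days=300)
        late = out[out.day > 100].proportion
        assert np.allclose(late, 0.5, atol=0.05)

    def test_single_animal_is_step_function(self):
        ev = log_from_days(range(30))
        with pytest.warns(UserWarning):
            out = rz.attrition_curve(ev, study_days=60, smooth=False)
        assert set(out.proportion.unique()) == {0.0, 1.0}


class TestDielProfile:
    def test_flat_generator_profile_is_flat(self):
        ev, _, _ = syn.gen_detection_log(
            syn.DetectionConfig(seed=4, n_residents=4, n_transients=0,
                                study_days=80, diel_amplitude=0.0,
                                detections_per_day=10))
        periods = {t: rz.residency_periods(ev, t)
                   for t in ev.tag_id.unique()}
        hourly, fitted = rz.diel_profile(ev, periods)
        assert fitted.ri.max() - fitted.ri.min() < 0.15

    def test_nocturnal_absence_recovered(self):
        ev, _, _ = syn.gen_detection_log(
            syn.DetectionConfig(seed=5, n_residents=4, n_transients=0,
                                study_days=80, diel_amplitude=1.0,
                                diel_peak_hour=12.0, detections_per_day=8))
        periods = {t: rz.residency_periods(ev, t)
                   for t in ev.tag_id.unique()}
        hourly, fitted = rz.diel_profile(ev, periods)
        trough = fitted.loc[fitted.ri.idxmin(), "hour"]
        assert trough < 5 or trough > 19       # minimum in night hours

    def test_cyclic_fit_continuous_at_midnight(self):
        ev, _, _ = syn.gen_detection_log(
            syn.DetectionConfig(seed=6, n_residents=3, n_transients=0,
                                study_days=60, diel_amplitude=0.6,
                                detections_per_day=8))
        periods = {t: rz.residency_periods(ev, t)
                   for t in ev.tag_id.unique()}
        _, fitted = rz.diel_profile(ev, periods)
        sp = fitted.attrs["spline"]
        res = fitted.attrs["model"]
        X0 = sp.design(np.array([0.0]))
        X24 = sp.design(np.array([24.0]))
        assert np.allclose(X0, X24, atol=1e-10)

    def test_no_period_days_rejected(self):
        with pytest.raises(ValueError):
            rz.diel_profile(log_from_days(range(3)), {"A": []})


class TestReceiverUse:
    def test_single_receiver_degenerate(self):
        ev = log_from_days(range(20))
        out = rz.receiver_use(ev, {"A": [(ev.timestamp.min().floor("D"),
                                          ev.timestamp.max().floor("D"))]})
        assert out.mean_proportion.tolist() == [1.0]

    def test_planted_70_30_split_recovered(self):
        cfg = syn.DetectionConfig(seed=7, n_residents=8, n_transients=0,
                                  study_days=120, detections_per_day=12,
                                  receiver_split=(0.7, 0.3, 0, 0, 0, 0, 0))
        # single-seamount array so every animal sees the same receiver set
        recs = syn.default_receivers()
        recs = recs[recs.seamount_id == "Grattan"].reset_index(drop=True)
        ev, _, _ = syn.gen_detection_log(cfg, receivers=recs)
        periods = {t: rz.residency_periods(ev, t)
                   for t in ev.tag_id.unique()}
        out = rz.receiver_use(ev, periods, n_boot=500, seed=1)
        top = out.nlargest(2, "mean_proportion").mean_proportion.to_numpy()
        assert top[0] == pytest.approx(0.7, abs=0.05)
        assert top[1] == pytest.approx(0.3, abs=0.05)

    def test_proportions_sum_to_one(self, detection_log):
        ev, _, _ = detection_log
        periods = {t: rz.residency_periods(ev, t)
                   for t in ev.tag_id.unique()}
        out = rz.receiver_use(ev, periods, n_boot=100, seed=2)
        assert out.mean_proportion.sum() == pytest.approx(1.0)


class TestPAM:
    def brute_force(self, x, k=2):
        best, cost = None, np.inf
        for combo in itertools.combinations(range(len(x)), k):
            c = np.abs(np.asarray(x)[:, None]
                       - np.asarray(x)[list(combo)][None, :]).min(1).sum()
            if c < cost - 1e-12:
                best, cost = combo, c
        return cost

    def test_two_obvious_groups(self):
        labels, medoids = rz.cluster_ri([0.1, 0.2, 0.9, 1.0])
        assert labels.tolist() == [0, 0, 1, 1]
        assert medoids.tolist() in ([0.1, 0.9], [0.1, 1.0], [0.2, 0.9],
                                    [0.2, 1.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False, width=32),
                    min_size=4, max_size=12))
    def test_matches_brute_force_cost(self, values):
        labels, medoids = rz.cluster_ri(values, k=2)
        x = np.asarray(values, dtype=float)
        cost = np.abs(x[:, None] - np.asarray(medoids)[None, :]).min(1).sum()
        assert cost == pytest.approx(self.brute_force(values), abs=1e-9)

    def test_equal_values_deterministic(self):
        l1, m1 = rz.cluster_ri([0.5] * 6)
        l2, m2 = rz.cluster_ri([0.5] * 6)
        assert np.array_equal(l1, l2) and np.array_equal(m1, m2)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            rz.cluster_ri([0.1, 0.9], k=3)

    def test_resident_transient_generator_labels(self):
        """PAM on generator RIs recovers the planted behaviour groups."""
        animals = pd.DataFrame({
            "tag_id": [f"R{i}" for i in range(5)] + [f"T{i}" for i in range(5)],
            "profile": ["resident"] * 5 + ["transient"] * 5,
            "departure_day": [np.inf] * 5 + [30, 45, 60, 20, 50],
            "p_daily": 0.95,
        })
        ev, truth, _ = syn.gen_detection_log(
            syn.DetectionConfig(seed=8, study_days=300, animals=animals))
        end = pd.Timestamp("2017-06-01", tz="UTC") + pd.Timedelta(days=299)
        ris, profiles = [], []
        for t in truth.tag_id:
            ris.append(rz.residency_index(ev, t, study_end=end))
            profiles.append(truth.set_index("tag_id").profile[t])
        labels, _ = rz.cluster_ri(ris)
        planted = np.array([p == "resident" for p in profiles])
        assert np.array_equal(labels == 1, planted)


class TestMoves:
    def test_transition_counting(self):
        ev = pd.concat([
            log_from_days([0, 1], seamount="Grattan"),
            log_from_days([2, 3], seamount="Young", receiver="YO01"),
            log_from_days([4], seamount="Grattan"),
        ], ignore_index=True)
        out = rz.inter_seamount_moves(ev)
        assert out.n_moves.iloc[0] == 2 and bool(out.switcher.iloc[0])

    def test_single_seamount_no_moves(self):
        out = rz.inter_seamount_moves(log_from_days(range(5)))
        assert out.n_moves.iloc[0] == 0

    def test_switcher_percentage(self):
        frames = []
        for i in range(14):
            if i < 5:
                frames.append(pd.concat([
                    log_from_days([0], tag=f"S{i}"),
                    log_from_days([1], tag=f"S{i}", seamount="Young"),
                ]))
            else:
                frames.append(log_from_days([0, 1], tag=f"S{i}"))
        out = rz.inter_seamount_moves(pd.concat(frames, ignore_index=True))
        assert round(out.attrs["percent_switchers"]) == 36

    def test_unmapped_receiver_rejected(self):
        ev = log_from_days([0, 1]).drop(columns=["seamount_id"])
        with pytest.raises(KeyError):
            rz.inter_seamount_moves(ev, receiver_map={"OTHER": "Grattan"})


class TestAMDR:
    def test_logistic_truth_recovered(self, environment):
        res = rz.amdr(environment["range_test"], site_col=None)
        truth = environment["truth"]["range_p05_m"]
        assert not res["censored"]
        assert res["amdr_m"] == pytest.approx(truth, rel=0.10)

    def test_perfect_detection_censored(self):
        rng = np.random.default_rng(0)
        d = np.sort(rng.uniform(0, 800, 200))
        series = pd.DataFrame({"distance_m": d, "expected": 18,
                               "received": 18})
        res = rz.amdr(series, site_col=None)
        assert res["censored"]

    def test_steeper_slope_means_smaller_radius(self):
        out = {}
        for scale in (40.0, 160.0):
            env = syn.gen_environment(syn.EnvironmentConfig(
                seed=9, logistic_scale_m=scale, range_bins=300))
            out[scale] = rz.amdr(env["range_test"], site_col=None)["amdr_m"]
        assert out[40.0] < out[160.0]


class TestRIComparison:
    def make_records(self, seed, gap=True):
        rng = np.random.default_rng(seed)
        n1, n2 = 15, 14
        mu1, mu2 = (0.97, 0.68) if gap else (0.8, 0.8)
        ri1 = np.clip(rng.normal(mu1, 0.05, n1), 0.02, 0.999)
        ri2 = np.clip(rng.normal(mu2, 0.15, n2), 0.02, 0.999)
        return pd.DataFrame({
            "RI": np.r_[ri1, ri2],
            "species": ["galapagos"] * n1 + ["silky"] * n2,
            "sex": list(np.where(rng.random(n1 + n2) < 0.5, "F", "M")),
        })

    def test_planted_species_gap_detected(self):
        hits = sum(
            rz.compare_ri_glm(self.make_records(s), ["species"]).p.iloc[0]
            < 0.05
            for s in range(10))
        assert hits >= 9

    def test_null_rarely_significant(self):
        hits = sum(
            rz.compare_ri_glm(self.make_records(s, gap=False),
                              ["species"]).p.iloc[0] < 0.05
            for s in range(10))
        assert hits <= 2

    def test_single_level_covariate_rejected(self):
        rec = self.make_records(0)
        rec["species"] = "silky"
        with pytest.raises(ValueError):
            rz.compare_ri_glm(rec, ["species"])
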