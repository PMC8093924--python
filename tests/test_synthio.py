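"""Synthetic cohort, task and source-signal generator tests."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.signal import butter, sosfiltfilt

from srcflow import synthio


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


class TestCohort:
    def test_sizes_and_columns(self):
        c = synthio.generate_cohort(35, 60, seed=0)
        assert len(c) == 95
        assert (c["group"] == "HC").sum() == 35
        assert (c["group"] == "CTD").sum() == 60
        assert list(c.columns) == synthio.COHORT_COLUMNS

    def test_deterministic(self):
        a = synthio.generate_cohort(10, 12, seed=5)
        b = synthio.generate_cohort(10, 12, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = synthio.generate_cohort(10, 12, seed=6)
        assert not a.equals(c)

    def test_group_differences_at_scale(self):
        c = synthio.generate_cohort(800, 800, seed=1)
        hc = c[c["group"] == "HC"]
        ctd = c[c["group"] == "CTD"]
        # CTD severity instruments populated, HC near floor
        assert ctd["ygtss_total"].mean() > 15
        assert hc["ygtss_total"].max() == 0
        # latent RT shift: CTD faster on average
        assert ctd["rt_mean_ms"].mean() < hc["rt_mean_ms"].mean() - 30
        # male enrichment in CTD
        assert (ctd["gender"] == "M").mean() > (hc["gender"] == "M").mean()

    def test_instrument_ranges(self):
        c = synthio.generate_cohort(300, 300, seed=2)
        assert (c["ygtss_total"] >= 0).all() and (c["ygtss_total"] <= 50).all()
        assert (c["age"] >= 8).all() and (c["age"] <= 12).all()


# ---------------------------------------------------------------------------
# trial table
# ---------------------------------------------------------------------------


class TestTrials:
    def test_counts_and_no_response(self):
        row = {"group": "CTD", "rt_mean_ms": 520.0}
        tr = synthio.generate_trial_table(row, seed=0)
        assert (tr["condition"] == "congruent").sum() == 72
        assert (tr["condition"] == "incongruent").sum() == 144
        # no-response trials carry NaN RT and are marked incorrect
        nr = tr["rt"].isna()
        assert nr.any()
        assert not tr.loc[nr, "correct"].any()
        # responded trials are all within the deadline
        assert (tr.loc[~nr, "rt"] <= synthio.TaskSpec().rt_deadline_ms).all()

    def test_deterministic(self):
        row = {"group": "HC", "rt_mean_ms": 560.0}
        a = synthio.generate_trial_table(row, seed=9)
        b = synthio.generate_trial_table(row, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_accuracy_tracks_condition(self):
        row = {"group": "HC", "rt_mean_ms": 560.0}
        trs = [synthio.generate_trial_table(row, seed=s) for s in range(40)]
        tr = pd.concat(trs)
        acc = tr.groupby("condition")["correct"].mean()
        assert acc["congruent"] > acc["incongruent"]


# ---------------------------------------------------------------------------
# ground-truth networks
# ---------------------------------------------------------------------------


class TestNetwork:
    def test_validation(self):
        ok = np.zeros((1, 2, 2))
        with pytest.raises(ValueError, match="symmetric"):
            synthio.GroundTruthNetwork(ok, np.array([[1.0, 0.5], [0.2, 1.0]]), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="positive definite"):
            synthio.GroundTruthNetwork(ok, -np.eye(2), np.zeros((2, 3)))
        unstable = np.zeros((1, 2, 2))
        unstable[0] = np.eye(2) * 1.05
        with pytest.raises(ValueError, match="unstable"):
            synthio.GroundTruthNetwork(unstable, np.eye(2), np.zeros((2, 3)))

    def test_companion_radius_ar1(self):
        A = np.zeros((1, 1, 1))
        A[0, 0, 0] = 0.8
        assert synthio.companion_spectral_radius(A) == pytest.approx(0.8)

    def test_stable_random_network(self):
        net = synthio.stable_random_network(6, order=2, seed=4)
        assert synthio.companion_spectral_radius(net.coeffs) < 1.0
        assert net.coeffs.shape == (2, 6, 6)
        # same seed reproduces
        net2 = synthio.stable_random_network(6, order=2, seed=4)
        np.testing.assert_array_equal(net.coeffs, net2.coeffs)

    def test_ensure_edges(self):
        net = synthio.stable_random_network(
            5, order=2, density=0.0, seed=0, ensure_edges=((0, 1), (2, 3))
        )
        assert net.coeffs[0, 1, 0] != 0.0
        assert net.coeffs[0, 3, 2] != 0.0
        with pytest.raises(ValueError, match="off-diagonal"):
            synthio.stable_random_network(5, ensure_edges=((1, 1),))


# ---------------------------------------------------------------------------
# source epochs
# ---------------------------------------------------------------------------


def _quick_trials(n=30):
    return pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "condition": ["incongruent"] * n,
            "correct": [True] * n,
            "rt": [500.0] * n,
        }
    )


class TestSourceEpochs:
    def test_shape_and_determinism(self):
        net = synthio.stable_random_network(3, seed=1)
        row = {"group": "HC", "subject_id": "a"}
        ep1 = synthio.generate_source_epochs(row, net, _quick_trials(), fs=100.0, seed=2)
        ep2 = synthio.generate_source_epochs(row, net, _quick_trials(), fs=100.0, seed=2)
        assert ep1.activations.shape == (3, 400, 30)
        np.testing.assert_array_equal(ep1.activations, ep2.activations)
        assert ep1.times_ms[0] == -2000.0
        assert set(ep1.variance_rank) == {1, 2, 3}

    def test_burn_in_stationarity(self):
        """No start-up transient: early and late variance agree for HC."""
        net = synthio.stable_random_network(2, seed=3)
        row = {"group": "HC", "subject_id": "a"}
        ep = synthio.generate_source_epochs(row, net, _quick_trials(200), fs=100.0, seed=4)
        v_head = ep.activations[:, :100, :].var()
        v_tail = ep.activations[:, -100:, :].var()
        assert v_head / v_tail == pytest.approx(1.0, abs=0.1)

    def test_group_effect_changes_only_window(self):
        net = synthio.stable_random_network(2, density=0.0, seed=5, ensure_edges=((0, 1),))
        truth = dataclasses.replace(
            net,
            group_effects=(
                synthio.GroupEffect(edge=(0, 1), multiplier=3.0, window_ms=(0.0, 500.0)),
            ),
        )
        hc = synthio.generate_source_epochs(
            {"group": "HC"}, truth, _quick_trials(), fs=100.0, seed=6
        )
        ctd = synthio.generate_source_epochs(
            {"group": "CTD"}, truth, _quick_trials(), fs=100.0, seed=6
        )
        t = hc.times_ms
        pre = t < 0
        # identical innovations and identical pre-stimulus coefficients
        np.testing.assert_allclose(
            hc.activations[:, pre], ctd.activations[:, pre], atol=1e-12
        )
        # effect window must differ
        win = (t >= 0) & (t <= 500)
        assert not np.allclose(hc.activations[:, win], ctd.activations[:, win])

    def test_power_effect_band_and_window(self):
        net = synthio.GroundTruthNetwork(
            np.zeros((1, 2, 2)),
            np.eye(2),
            np.zeros((2, 3)),
            power_effects=(
                synthio.PowerEffect(0, (8.0, 12.0), (250.0, 600.0), {"HC": 2.0}),
            ),
        )
        ep = synthio.generate_source_epochs(
            {"group": "HC"}, net, _quick_trials(300), fs=250.0, seed=1
        )
        t = ep.times_ms
        sos = butter(4, [8, 12], "bandpass", fs=250, output="sos")
        xf = sosfiltfilt(sos, ep.activations[0], axis=0)
        interior = (t >= 300) & (t <= 550)
        base = (t >= -1500) & (t <= -100)
        gain_db = 10 * np.log10((xf[interior] ** 2).mean() / (xf[base] ** 2).mean())
        # calibration is approximate (band-edge losses); see docs/methods.md
        assert gain_db == pytest.approx(2.0, abs=0.75)
        # untargeted source unchanged in band power
        xf1 = sosfiltfilt(sos, ep.activations[1], axis=0)
        gain1 = 10 * np.log10((xf1[interior] ** 2).mean() / (xf1[base] ** 2).mean())
        assert abs(gain1) < 0.5

    def test_select_trials(self):
        ep = synthio.generate_source_epochs(
            {"group": "HC"}, synthio.stable_random_network(2, seed=0),
            _quick_trials(20), fs=100.0, seed=0,
        )
        mask = np.zeros(20, dtype=bool)
        mask[[2, 5, 7]] = True
        sub = ep.select_trials(mask)
        assert sub.n_trials == 3
        np.testing.assert_array_equal(sub.activations, ep.activations[:, :, mask])


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


class TestIo:
    def test_epochs_roundtrip(self, tmp_path):
        net = synthio.stable_random_network(2, seed=0)
        eps = [
            synthio.generate_source_epochs(
                {"group": "HC", "subject_id": f"s{i}"}, net, _quick_trials(5),
                fs=100.0, seed=i,
            )
            for i in range(3)
        ]
        path = tmp_path / "ep.h5"
        synthio.save_epochs(path, eps)
        back = synthio.load_epochs(path)
        assert len(back) == 3
        got = {e.subject_id: e for e in back}
        for e in eps:
            b = got[e.subject_id]
            np.testing.assert_allclose(b.activations, e.activations)
            np.testing.assert_allclose(b.dipole_mni, e.dipole_mni)
            assert b.fs == e.fs
        only = synthio.load_epochs(path, subject_id="s1")
        assert len(only) == 1 and only[0].subject_id == "s1"

    def test_table_roundtrip(self, tmp_path):
        tab = synthio.generate_cohort(4, 5, seed=0)
        synthio.save_table(tmp_path / "c.tsv", tab)
        back = synthio.load_table(tmp_path / "c.tsv")
        assert list(back.columns) == list(tab.columns)
        assert len(back) == len(tab)
        np.testing.assert_allclose(back["age"], tab["age"])
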