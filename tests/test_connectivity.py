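"""CCH construction, baseline, deconvolution, STG, and detection."""

import numpy as np
import pytest

from polarspike import connectivity as cn
from polarspike import synth


def poisson_pair(rate1=10.0, rate2=5.0, duration=500.0, p=0.0, seed=0, **kw):
    couplings = [synth.Coupling(0, 1, p, **kw)] if p > 0 else []
    trains, gt = synth.synth_spike_trains(2, [rate1, rate2], duration,
                                          couplings=couplings, seed=seed)
    return trains, gt


class TestComputeCCH:
    def test_fixed_offset_counts_in_one_bin(self):
        ref = np.arange(0.0, 100.0, 0.5)
        tgt = ref + 0.00115  # mid-bin offset, away from any bin edge
        cch = cn.compute_cch(ref, tgt)
        i = int(np.argmax(cch.counts))
        assert cch.counts[i] == ref.size
        assert cch.centers_ms[i] == pytest.approx(1.15)

    def test_independent_poisson_flat_expectation(self):
        trains, _ = synth.synth_spike_trains(2, 20.0, 500.0, refractory_ms=0.0, seed=1)
        cch = cn.compute_cch(trains[0], trains[1])
        expected = 20.0 * 20.0 * 500.0 * 1e-4  # r1*r2*T*bin
        assert cch.counts.mean() == pytest.approx(expected, rel=0.05)

    def test_ach_refractory_core_empty(self):
        trains, _ = synth.synth_spike_trains(1, 20.0, 300.0, refractory_ms=2.0, seed=2)
        ach = cn.compute_cch(trains[0], trains[0], auto=True)
        c = ach.centers_ms
        core = np.abs(c) < 2.0
        assert ach.counts[core].sum() == 0

    def test_matches_quadratic_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        ref = np.sort(rng.uniform(0, 30, 800))
        tgt = np.sort(rng.uniform(0, 30, 900))
        cch = cn.compute_cch(ref, tgt)
        # O(n^2) oracle
        diffs = (tgt[None, :] - ref[:, None]).ravel() * 1e3
        oracle = np.histogram(diffs, bins=cch.edges_ms)[0]
        np.testing.assert_array_equal(cch.counts, oracle)

    def test_symmetry_between_orders(self):
        trains, _ = poisson_pair(seed=4)
        ab = cn.compute_cch(trains[0], trains[1])
        ba = cn.compute_cch(trains[1], trains[0])
        np.testing.assert_array_equal(ab.counts, ba.counts[::-1])

    def test_mass_conservation(self):
        rng = np.random.default_rng(5)
        ref = np.sort(rng.uniform(0, 10, 300))
        tgt = np.sort(rng.uniform(0, 10, 300))
        cch = cn.compute_cch(ref, tgt, half_window_ms=50.0)
        diffs = np.abs(tgt[None, :] - ref[:, None]) * 1e3
        n_in = np.sum((diffs < 50.0) | np.isclose(diffs, 50.0) & (tgt[None, :] < ref[:, None]))
        # count every pair difference in (-50, 50] ms
        d = ((tgt[None, :] - ref[:, None]) * 1e3).ravel()
        assert cch.counts.sum() == np.sum((d > -50.0) & (d <= 50.0))

    def test_empty_train_warns_zero(self):
        with pytest.warns(UserWarning):
            cch = cn.compute_cch(np.array([]), np.array([1.0]))
        assert cch.counts.sum() == 0


class TestBaseline:
    def test_flat_cch_identity(self):
        cch = cn.CCH(np.full(1000, 7), 0.1, 50.0)
        np.testing.assert_allclose(cn.baseline_hollowed_median(cch), 7.0)

    def test_single_bin_spike_ignored(self):
        counts = np.full(1000, 5)
        counts[500] = 500
        cch = cn.CCH(counts, 0.1, 50.0)
        base = cn.baseline_hollowed_median(cch)
        assert base[500] == 5.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(10, size=200)
        cch = cn.CCH(counts, 0.1, 10.0)
        base = cn.baseline_hollowed_median(cch, window_ms=6.0, hollow_bins=3)
        half = 30
        for i in [0, 1, 17, 100, 150, 199]:
            lo, hi = max(0, i - half), min(200, i + half + 1)
            idx = [j for j in range(lo, hi) if abs(j - i) > 3]
            assert base[i] == np.median(counts[idx])

    def test_window_smaller_than_hollow_raises(self):
        cch = cn.CCH(np.ones(100), 0.1, 5.0)
        with pytest.raises(ValueError):
            cn.baseline_hollowed_median(cch, window_ms=0.4, hollow_bins=5)


class TestDeconvolve:
    def test_poisson_reference_is_near_identity(self):
        trains, _ = poisson_pair(rate1=10.0, rate2=10.0, duration=1000.0, seed=7)
        cch = cn.compute_cch(trains[0], trains[1])
        ach = cn.compute_cch(trains[0], trains[0], auto=True)
        dc = cn.deconvolve_cch(cch, ach)
        resid = np.abs(np.asarray(dc.counts) - cch.counts)
        assert resid.mean() < 0.1 * cch.counts.mean()

    def test_mode_off_is_identity(self):
        trains, _ = poisson_pair(seed=8)
        cch = cn.compute_cch(trains[0], trains[1])
        ach = cn.compute_cch(trains[0], trains[0], auto=True)
        assert cn.deconvolve_cch(cch, ach, mode="off") is cch

    def test_mass_preserved_within_1pct(self):
        trains, _ = poisson_pair(p=0.3, seed=9)
        cch = cn.compute_cch(trains[0], trains[1])
        ach = cn.compute_cch(trains[0], trains[0], auto=True)
        dc = cn.deconvolve_cch(cch, ach)
        assert np.asarray(dc.counts).sum() == pytest.approx(cch.counts.sum(), rel=0.01)

    def test_burst_echo_suppressed_5x(self):
        rng = np.random.default_rng(10)
        base, _ = synth.synth_spike_trains(1, 8.0, 1500.0, seed=11)
        pre = base[0]
        doub = pre[rng.random(pre.size) < 0.6]
        doub = doub + 0.003 + rng.normal(0, 4e-4, doub.size)
        pre_b = np.sort(np.concatenate([pre, doub]))
        other, _ = synth.synth_spike_trains(1, 5.0, 1500.0, seed=12)
        sel = rng.random(pre_b.size) < 0.3
        tgt = np.sort(np.concatenate(
            [other[0], pre_b[sel] + 0.001 + rng.normal(0, 2e-4, sel.sum())]
        ))
        cch = cn.compute_cch(pre_b, tgt)
        ach = cn.compute_cch(pre_b, pre_b, auto=True)
        bl = cn.baseline_hollowed_median(cch)
        dc = cn.deconvolve_cch(cch, ach)
        c = cch.centers_ms
        for band in [(-2.8, -1.2), (3.2, 4.8)]:  # echoes at 1 -/+ 3 ms
            m = (c >= band[0]) & (c <= band[1])
            raw_excess = (cch.counts - bl)[m].sum()
            dc_excess = (np.asarray(dc.counts) - bl)[m].sum()
            assert raw_excess > 5 * max(dc_excess, 1.0)

    def test_zero_ach_raises(self):
        cch = cn.CCH(np.ones(1000), 0.1, 50.0, n_ref=100)
        ach = cn.CCH(np.zeros(1000), 0.1, 50.0, n_ref=0)
        with pytest.raises(ValueError):
            cn.deconvolve_cch(cch, ach)


class TestSTG:
    @pytest.mark.parametrize("p", [0.05, 0.1, 0.3, 1.0])
    def test_injected_probability_recovered(self, p):
        trains, gt = synth.synth_spike_trains(
            2, [10.0, 5.0], 1000.0,
            couplings=[synth.Coupling(0, 1, p, lag_ms=1.0, jitter_ms=0.2)],
            seed=int(p * 1000),
        )
        assert gt.n_pre[0] > 9000  # ~1e4 presynaptic spikes
        cch = cn.compute_cch(trains[0], trains[1])
        ach = cn.compute_cch(trains[0], trains[0], auto=True)
        res = cn.detect_connection(cch, ach)
        assert res.sign == cn.EXC
        assert res.stg == pytest.approx(gt.n_added[0] / gt.n_pre[0], abs=0.05)

    def test_independent_trains_stg_near_zero(self):
        trains, _ = poisson_pair(rate1=10.0, rate2=10.0, duration=1000.0, seed=13)
        cch = cn.compute_cch(trains[0], trains[1])
        ach = cn.compute_cch(trains[0], trains[0], auto=True)
        res = cn.detect_connection(cch, ach)
        assert res.sign == cn.NONE
        assert abs(res.stg) < 0.01

    def test_roi_is_causal(self):
        trains, _ = poisson_pair(p=0.5, seed=14)
        cch = cn.compute_cch(trains[0], trains[1])
        ach = cn.compute_cch(trains[0], trains[0], auto=True)
        res = cn.detect_connection(cch, ach)
        assert res.roi[0] >= cch.n_bins // 2
        assert 0 < res.lag_ms <= 5.0

    def test_no_causal_bins_raises(self):
        with pytest.raises(ValueError):
            cn.stg_from_curve(np.ones(10), 100, 0.1, roi_ms=50.0)


class TestDetect:
    def test_inhibitory_deletion_coupling(self):
        trains, _ = synth.synth_spike_trains(
            2, [10.0, 25.0], 1000.0,
            couplings=[synth.Coupling(0, 1, 0.9, lag_ms=1.0, sign="inhibitory")],
            seed=15,
        )
        cch = cn.compute_cch(trains[0], trains[1])
        ach = cn.compute_cch(trains[0], trains[0], auto=True)
        res = cn.detect_connection(cch, ach)
        assert res.sign == cn.INH
        assert res.stg < 0

    def test_session_fractions_recover_coupled_pairs(self):
        from polarspike import waveforms as wf

        # 4 vINTs x 5 BIPs; couple 3 of the 20 ordered pairs
        n_int, n_bip = 4, 5
        rates = [12.0] * n_int + [8.0] * n_bip
        coupled = [(0, 4), (1, 6), (2, 8)]
        couplings = [synth.Coupling(a, b, 0.9, lag_ms=1.0, sign="inhibitory")
                     for a, b in coupled]
        trains, _ = synth.synth_spike_trains(len(rates), rates, 600.0,
                                             couplings=couplings, seed=16)
        units = []
        for i, t in enumerate(trains):
            u = wf.Unit(unit_id=i, shank=0, spike_times=t, waveforms={})
            u.unit_type = wf.INT if i < n_int else wf.BIP
            units.append(u)
        achs = {i: cn.compute_cch(trains[i], trains[i], auto=True) for i in range(len(trains))}
        conns = []
        for a in range(n_int):
            for b in range(n_int, n_int + n_bip):
                cch = cn.compute_cch(trains[a], trains[b], ref_id=a, tgt_id=b)
                conns.append(cn.detect_connection(cch, achs[a]))
        summary = cn.session_fractions(units, conns)
        assert summary["n_inhibitory"] == len(coupled)
        # only INTs verified by a CCH trough count as vINTs (3 of the 4)
        assert summary["n_vint"] == 3
        assert summary["frac_inhibitory"] == pytest.approx(3 / 15)
        assert summary["p_binomial"] < 0.001
        assert set(map(tuple, summary["pairs"][["ref", "tgt"]].values)) == set(coupled)

    def test_zero_couplings_binomial_p_near_one(self):
        from polarspike import waveforms as wf

        units = [wf.Unit(0, 0, np.array([0.0]), {}), wf.Unit(1, 0, np.array([0.0]), {})]
        units[0].unit_type = wf.INT
        units[1].unit_type = wf.BIP
        summary = cn.session_fractions(units, [])
        assert summary["n_pairs"] == 0 or summary["p_binomial"] > 0.9
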