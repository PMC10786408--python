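import numpy as np
import pytest

from spinocereb import JointState, Topology, TopologyError, CheckpointError
from spinocereb.cerebellum import (LIFParams,
                                   PlasticityParams, WorkingRanges,
                                   build_network, instructive_signal,
                                   _lif_pop_step)


def unit_ranges():
    return WorkingRanges(pos_lo=np.zeros(2), pos_hi=np.ones(2),
                         vel_lo=-np.ones(2), vel_hi=np.ones(2))


@pytest.fixture(scope="module")
def tiny_net(tiny_topology):
    net = build_network(topology=tiny_topology, seed=7)
    net.set_working_ranges(unit_ranges())
    return net


class TestTopology:
    def test_default_scale_matches_printed_counts(self):
        t = Topology()
        assert (t.n_mf, t.n_gc, t.n_pc, t.n_dcn) == (80, 20000, 200, 200)
        c = t.synapse_counts()
        assert c["mf_gc"] == 80_000
        assert c["gc_pc"] == 4_000_000
        assert c["mf_dcn"] == 16_000
        assert c["pc_dcn"] == c["cf_pc"] == 200
        assert c["cf_dcn_ampa"] == c["cf_dcn_nmda"] == 200

    def test_reduced_scale_combinatorial_count(self):
        t = Topology(n_mf_per_signal=3, n_pc=8)
        assert t.n_gc == 2 * 3**4 == 162
        assert t.synapse_counts()["mf_gc"] == 648

    def test_indivisible_pc_count_rejected(self):
        with pytest.raises(TopologyError):
            Topology(n_pc=10).validate()


class TestWiring:
    def test_each_gc_has_one_mf_per_signal_unique_combos(self, tiny_net):
        t = tiny_net.top
        per = t.n_mf_per_signal
        for mc in range(2):
            rows = tiny_net.gc_mf[mc * per**4:(mc + 1) * per**4]
            # afferent k lies in signal k's index block of this microcomplex
            for k in range(4):
                lo = mc * 4 * per + k * per
                assert np.all((rows[:, k] >= lo) & (rows[:, k] < lo + per))
            assert len({tuple(r) for r in rows}) == per**4

    def test_same_seed_reproduces_network(self, tiny_topology):
        a = build_network(topology=tiny_topology, seed=3)
        b = build_network(topology=tiny_topology, seed=3)
        assert np.array_equal(a.gc_mf, b.gc_mf)
        assert np.array_equal(a.W, b.W)

    def test_weight_init_modes(self, tiny_topology):
        r = build_network(topology=tiny_topology, seed=0, weight_init="random")
        assert r.W.min() >= 4.3 and r.W.max() <= 5.2
        h = build_network(topology=tiny_topology, seed=0,
                          weight_init="homogeneous")
        assert np.all(h.W == 4.8)
        with pytest.raises(ValueError):
            build_network(topology=tiny_topology, weight_init="nope")


class TestMossyEncoding:
    def test_exactly_four_active_per_microcomplex(self, tiny_net):
        rng = np.random.default_rng(0)
        per = tiny_net.top.n_mf_per_signal
        for _ in range(500):
            d = JointState(rng.uniform(0, 1, 2), rng.uniform(-1, 1, 2))
            a = JointState(rng.uniform(0, 1, 2), rng.uniform(-1, 1, 2))
            act = tiny_net.encode_mossy(d, a)
            assert act.shape == (8,)
            for mc in range(2):
                sub = act[mc * 4:(mc + 1) * 4]
                blocks = (sub - mc * 4 * per) // per
                assert np.array_equal(blocks, np.arange(4))

    def test_deterministic(self, tiny_net):
        d = JointState([0.3, 0.6], [0.1, -0.2])
        a = JointState([0.31, 0.59], [0.12, -0.18])
        assert np.array_equal(tiny_net.encode_mossy(d, a),
                              tiny_net.encode_mossy(d, a))

    def test_half_open_bin_edges_match_brute_force(self, tiny_net):
        per = tiny_net.top.n_mf_per_signal

        def brute_bin(v, lo, hi, n):
            edges = lo + (hi - lo) * np.arange(1, n) / n
            b = 0
            for e in edges:
                if v >= e:   # half-open [lo, hi): edge goes to higher bin
                    b += 1
            return b

        for v in [0.0, 1 / 3, 0.5, 2 / 3, 0.9999, 1.0, 1.7, -0.4]:
            d = JointState([v if 0 <= v <= 1 else 0.5, 0.5], [0, 0])
            act = tiny_net.encode_mossy(d, d)
            vv = d.q[0]
            expected = min(max(brute_bin(vv, 0.0, 1.0, per), 0), per - 1)
            assert act[0] % per == expected

    def test_out_of_range_clamps_to_edge_bins(self, tiny_net):
        per = tiny_net.top.n_mf_per_signal
        low = JointState([-5.0, -5.0], [-9.0, -9.0])
        high = JointState([5.0, 5.0], [9.0, 9.0])
        assert tiny_net.encode_mossy(low, low)[0] % per == 0
        assert tiny_net.encode_mossy(high, high)[0] % per == per - 1

    def test_distinct_patterns_select_distinct_gcs(self, tiny_net):
        # univocal recoding: the fully-matched GC differs for every distinct
        # active-MF combination (brute force at reduced scale)
        rng = np.random.default_rng(1)
        seen = {}
        for _ in range(300):
            d = JointState(rng.uniform(0, 1, 2), rng.uniform(-1, 1, 2))
            a = JointState(rng.uniform(0, 1, 2), rng.uniform(-1, 1, 2))
            act = tiny_net.encode_mossy(d, a)
            matches = (tiny_net.gc_mf == act[None, :4]).sum(axis=1) + \
                      (tiny_net.gc_mf == act[None, 4:]).sum(axis=1)
            full = np.nonzero(matches == 4)[0]
            assert len(full) == 2  # one per microcomplex
            seen[tuple(act)] = tuple(full)
        # injectivity: distinct MF patterns never share a GC pair
        assert len(set(seen.values())) == len(seen)


class TestInstructiveSignal:
    def test_zero_error(self):
        s = JointState([0.5, 0.5], [0.1, 0.1])
        np.testing.assert_allclose(instructive_signal(s, s), 0.0)

    def test_position_gain(self):
        d = JointState([0.6, 0.5], [0.0, 0.0])
        a = JointState([0.5, 0.5], [0.0, 0.0])
        np.testing.assert_allclose(instructive_signal(d, a), [0.3, 0.0])

    def test_velocity_gain(self):
        d = JointState([0.5, 0.5], [0.2, 0.0])
        a = JointState([0.5, 0.5], [0.0, 0.0])
        np.testing.assert_allclose(instructive_signal(d, a), [0.2, 0.0])


class TestClimbingFibers:
    def test_zero_error_never_spikes(self, tiny_net):
        for _ in range(200):
            assert not tiny_net.encode_climbing(np.zeros(2)).any()

    def test_saturated_rate_matches_maximum(self, tiny_topology):
        net = build_network(topology=tiny_topology, seed=11)
        n_steps = 10_000
        count = 0
        region = net.region_slices[0]
        n_cf_region = region.stop - region.start
        for _ in range(n_steps):
            count += net.encode_climbing(np.array([50.0, 0.0]))[region].sum()
        p = net.cf_params.max_rate * net.dt
        expected = n_steps * n_cf_region * p
        sd = np.sqrt(n_steps * n_cf_region * p * (1 - p))
        assert abs(count - expected) < 4 * sd

    def test_sign_routes_to_agonist_or_antagonist(self, tiny_net):
        ag = tiny_net.region_slices[0]
        an = tiny_net.region_slices[1]
        pos = np.zeros(tiny_net.top.n_cf, dtype=bool)
        neg = np.zeros_like(pos)
        for _ in range(500):
            pos |= tiny_net.encode_climbing(np.array([10.0, 0.0]))
            neg |= tiny_net.encode_climbing(np.array([-10.0, 0.0]))
        assert pos[ag].any() and not pos[an].any()
        assert neg[an].any() and not neg[ag].any()
        # other joint's microcomplex stays silent either way
        assert not pos[tiny_net.region_slices[2]].any()
        assert not neg[tiny_net.region_slices[3]].any()


class TestLIF:
    def test_rest_is_silent(self, tiny_topology):
        net = build_network(topology=tiny_topology, seed=0)
        net.set_working_ranges(unit_ranges())
        no_mf = np.full(8, -1, dtype=np.int64)  # matches no afferent
        cf = np.zeros(net.top.n_cf, dtype=bool)
        total = 0
        for _ in range(1000):
            g, p, d = net.lif_step(no_mf, cf)
            total += g.sum() + p.sum() + d.sum()
        assert total == 0

    def test_interspike_interval_matches_analytic_lif(self):
        # single neuron, constant conductance drive g0: the membrane relaxes
        # toward V* = (gL EL + g0 Eex)/(gL + g0) with tau* = C/(gL + g0);
        # ISI = ref + tau* ln((V* - Vres)/(V* - Vth))
        p = LIFParams(tau_m=0.010, g_leak=4.0, tau_ampa=1e9)
        dt = 1e-5
        par = p.pack(dt)
        g0 = 3.0
        v = np.array([p.E_L])
        ga, gg, gn = np.array([g0]), np.zeros(1), np.zeros(1)
        ref = np.zeros(1, dtype=np.int64)
        spk = np.zeros(1, dtype=np.bool_)
        zeros = np.zeros(1)
        times = []
        for k in range(200_000):
            _lif_pop_step(v, ga, gg, gn, ref, zeros, zeros, zeros, par, dt, spk)
            if spk[0]:
                times.append(k * dt)
        isi = np.diff(times)
        C = p.g_leak * p.tau_m
        tau_eff = C / (p.g_leak + g0)
        v_inf = (p.g_leak * p.E_L + g0 * p.E_exc) / (p.g_leak + g0)
        expected = p.t_ref + tau_eff * np.log(
            (v_inf - p.V_reset) / (v_inf - p.V_th))
        assert isi.mean() == pytest.approx(expected, rel=0.01)

    def test_purkinje_inhibition_suppresses_dcn(self, tiny_topology):
        # drive the network identically, but once with the GC-PC weights at
        # maximum (PCs fire hard) and once at zero (PCs silent): DCN spikes
        # must be fewer in the strongly inhibited case
        def dcn_count(wlev):
            net = build_network(topology=tiny_topology, seed=5,
                                weight_init="homogeneous")
            net.set_working_ranges(unit_ranges())
            net.W[:] = wlev
            d = JointState([0.5, 0.5], [0.0, 0.0])
            act = net.encode_mossy(d, d)
            cf = np.zeros(net.top.n_cf, dtype=bool)
            n = 0
            for _ in range(800):
                _, _, dcn = net.lif_step(act, cf)
                n += dcn.sum()
            return n

        assert dcn_count(15.0) < dcn_count(0.0)

    def test_coarse_dt_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            tiny_net.lif_step(np.zeros(8, dtype=np.int64),
                              np.zeros(tiny_net.top.n_cf, dtype=bool),
                              dt=0.002)


class TestPlasticity:
    def make_net(self, topo, **kw):
        net = build_network(topology=topo, seed=0, weight_init="homogeneous",
                            plasticity=PlasticityParams(**kw))
        net.set_working_ranges(unit_ranges())
        return net

    def test_single_pf_spike_adds_alpha(self, tiny_topology):
        net = self.make_net(tiny_topology)
        W0 = net.W.copy()
        gc_spk = np.zeros(net.top.n_gc, dtype=bool)
        gc_spk[17] = True
        net.stdp_update(gc_spk, np.zeros(net.top.n_cf, dtype=bool))
        dW = net.W - W0
        np.testing.assert_allclose(dW[17, :], 0.006)
        dW[17, :] = 0
        assert not dW.any()

    def test_cf_with_empty_pf_history_changes_nothing(self, tiny_topology):
        net = self.make_net(tiny_topology)
        W0 = net.W.copy()
        cf = np.zeros(net.top.n_cf, dtype=bool)
        cf[3] = True
        net.stdp_update(np.zeros(net.top.n_gc, dtype=bool), cf)
        assert np.array_equal(net.W, W0)

    def test_ltp_saturates_at_weight_ceiling(self, tiny_topology):
        net = self.make_net(tiny_topology)
        gc_spk = np.zeros(net.top.n_gc, dtype=bool)
        gc_spk[0] = True
        no_cf = np.zeros(net.top.n_cf, dtype=bool)
        for _ in range(3000):  # 4.8 + 3000*0.006 would be 22.8 unclipped
            net.stdp_update(gc_spk, no_cf)
        assert net.W[0].max() == 15.0
        assert net.W[0].min() == 15.0

    def test_weights_stay_bounded_under_adversarial_trains(self, tiny_topology):
        net = self.make_net(tiny_topology)
        rng = np.random.default_rng(0)
        for _ in range(400):
            gc = rng.random(net.top.n_gc) < 0.3
            cf = rng.random(net.top.n_cf) < 0.5
            net.stdp_update(gc, cf)
            assert net.W.min() >= 0.0 and net.W.max() <= 15.0

    def test_ltd_depresses_by_kernel_weighted_history(self, tiny_topology):
        net = self.make_net(tiny_topology)
        gc_spk = np.zeros(net.top.n_gc, dtype=bool)
        gc_spk[5] = True
        no_cf = np.zeros(net.top.n_cf, dtype=bool)
        net.stdp_update(gc_spk, no_cf)  # one PF spike enters the trace
        none = np.zeros(net.top.n_gc, dtype=bool)
        lag = net.plast.kernel_peak_time
        n_lag = int(round(lag / net.dt)) - 1
        for _ in range(n_lag):
            net.stdp_update(none, no_cf)
        W_before = net.W.copy()
        cf = np.zeros(net.top.n_cf, dtype=bool)
        cf[2] = True
        net.stdp_update(none, cf)
        dw = net.W[5, 2] - W_before[5, 2]
        # at the kernel peak the eligibility equals kernel_gain per spike
        assert dw == pytest.approx(net.plast.beta * net.plast.kernel_gain,
                                   rel=1e-3)
        # synapses from silent GCs onto the same PC are untouched
        assert net.W[6, 2] == W_before[6, 2]

    def test_total_ltp_equals_alpha_times_deliveries(self, tiny_topology):
        net = self.make_net(tiny_topology)
        rng = np.random.default_rng(2)
        W0 = net.W.copy()
        deliveries = 0
        no_cf = np.zeros(net.top.n_cf, dtype=bool)
        for _ in range(50):
            gc = rng.random(net.top.n_gc) < 0.1
            deliveries += gc.sum() * net.top.n_pc
            net.stdp_update(gc, no_cf)
        total = (net.W - W0).sum()
        assert total == pytest.approx(0.006 * deliveries, rel=1e-9)

    def test_no_teaching_signal_keeps_pc_columns_identical(self, tiny_topology):
        # without CF input every PC receives the same LTP stream, so no
        # PC-to-PC differentiation can develop from a homogeneous start
        net = self.make_net(tiny_topology)
        rng = np.random.default_rng(4)
        no_cf = np.zeros(net.top.n_cf, dtype=bool)
        for _ in range(200):
            net.stdp_update(rng.random(net.top.n_gc) < 0.2, no_cf)
        assert np.all(net.W == net.W[:, :1])

    def test_invalid_plasticity_params_rejected(self):
        with pytest.raises(ValueError):
            PlasticityParams(alpha=-1.0)
        with pytest.raises(ValueError):
            PlasticityParams(beta=0.001)


class TestDecoder:
    def feed(self, net, mask, steps=400):
        out = None
        for _ in range(steps):
            out = net.decode_dcn(mask)
        return out

    def test_silence_decodes_to_zero(self, tiny_topology):
        net = build_network(topology=tiny_topology, seed=0)
        m_f, m_e = self.feed(net, np.zeros(net.top.n_dcn, dtype=bool))
        np.testing.assert_allclose(m_f, 0.0)
        np.testing.assert_allclose(m_e, 0.0)

    def test_max_rate_decodes_to_one(self, tiny_topology):
        net = build_network(topology=tiny_topology, seed=0)
        m_f, m_e = self.feed(net, np.ones(net.top.n_dcn, dtype=bool))
        np.testing.assert_allclose(m_f, 1.0)
        np.testing.assert_allclose(m_e, 1.0)

    def test_linear_below_saturation(self, tiny_topology):
        # a region firing every k-th step decodes to rate/max_rate
        net = build_network(topology=tiny_topology, seed=0)
        sl = net.region_slices[0]
        vals = {}
        for k in (10, 5):
            net.reset_state()
            acc = []
            for i in range(2000):
                mask = np.zeros(net.top.n_dcn, dtype=bool)
                if i % k == 0:
                    mask[sl] = True
                m_f, _ = net.decode_dcn(mask)
                if i >= 1000:
                    acc.append(m_f[0])
            vals[k] = np.mean(acc)  # average out the smoothing ripple
        assert vals[5] == pytest.approx(2 * vals[10], rel=0.02)
        assert vals[10] == pytest.approx(
            (1000 / 10) / net.dec.max_rate, rel=0.02)


class TestCheckpoint:
    def test_round_trip_and_bounds(self, tiny_topology, tmp_path):
        net = build_network(topology=tiny_topology, seed=1)
        net.W[:] = np.random.default_rng(0).uniform(0, 15, net.W.shape)
        p = tmp_path / "w.npz"
        net.save_checkpoint(p, trial=42)
        other = build_network(topology=tiny_topology, seed=99)
        trial = other.load_checkpoint(p)
        assert trial == 42
        assert np.array_equal(other.W, net.W)
        assert other.W.min() >= 0.0 and other.W.max() <= 15.0

    def test_topology_mismatch_rejected(self, tiny_topology, tmp_path):
        net = build_network(topology=tiny_topology, seed=1)
        p = tmp_path / "w.npz"
        net.save_checkpoint(p)
        other = build_network(topology=Topology(n_mf_per_signal=4, n_pc=8),
                              seed=1)
        with pytest.raises(CheckpointError):
            other.load_checkpoint(p)
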