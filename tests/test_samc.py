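"""Flat-histogram sampler: gain schedule, acceptance, updates, reproducibility."""

import numpy as np
import pytest

from sfcopoly import (
    DoSGrid, GainSchedule, MacrostateKey, average_dos, gain, make_model,
    production_run, refine, run_samc, samc_accept, samc_update,
)
from sfcopoly.oracles import PhantomSpec, phantom_dos


class TestGain:
    @pytest.mark.parametrize("t, g0, t0, expect", [
        (500, 1.0, 1_000, 1.0),
        (10**5, 0.01, 10**4, 0.001),
        (1_000, 1.0, 1_000, 1.0),       # boundary t = t0
        (2_000, 1.0, 1_000, 0.5),
    ])
    def test_schedule_values(self, t, g0, t0, expect):
        assert gain(t, GainSchedule(g0, t0)) == pytest.approx(expect)

    def test_invalid_index_raises(self):
        with pytest.raises(ValueError):
            gain(0, GainSchedule(1.0, 10))


class TestAcceptance:
    def test_equal_and_downhill_always_accept(self, rng):
        assert all(samc_accept(0.0, 0.0, rng) for _ in range(100))
        assert all(samc_accept(0.0, -5.0, rng) for _ in range(100))

    def test_uphill_frequency_matches_ratio(self):
        rng = np.random.default_rng(77)
        n = 40_000
        acc = sum(samc_accept(0.0, np.log(2.0), rng) for _ in range(n))
        se = np.sqrt(0.5 * 0.5 / n)
        assert acc / n == pytest.approx(0.5, abs=4 * se)


class TestUpdate:
    def make_dos(self):
        return DoSGrid(env_raw=np.array([0, -1]), nst=np.array([0, 0]),
                       log_g=np.zeros(2), visits=np.zeros(2, dtype=np.int64))

    def test_single_update(self):
        dos = samc_update(self.make_dos(), MacrostateKey(0, 0), 0.01)
        assert dos.log_g[0] == pytest.approx(0.01)
        assert dos.visits[0] == 1
        assert dos.log_g[1] == 0.0 and dos.visits[1] == 0

    def test_additivity(self):
        dos = self.make_dos()
        for _ in range(7):
            samc_update(dos, MacrostateKey(-1, 0), 0.25)
        assert dos.log_g[1] == pytest.approx(7 * 0.25)
        assert dos.visits[1] == 7

    def test_unseen_key_registered_at_minimum(self):
        dos = self.make_dos()
        dos.log_g[:] = [-2.0, 1.0]
        samc_update(dos, MacrostateKey(-3, 0), 0.5)
        i = dos.index_of(MacrostateKey(-3, 0))
        assert dos.log_g[i] == pytest.approx(-2.0 + 0.5)


class TestRunSamc:
    def test_deterministic_given_seed(self, s_attract_small):
        a = run_samc(s_attract_small, GainSchedule(1.0, 100), 2_000, seed=5)
        b = run_samc(s_attract_small, GainSchedule(1.0, 100), 2_000, seed=5)
        assert np.array_equal(a.dos.log_g, b.dos.log_g)
        assert np.array_equal(a.dos.visits, b.dos.visits)
        assert np.array_equal(a.conformation.coords, b.conformation.coords)

    def test_zero_mcs_returns_input_dos(self, s_attract_small):
        first = run_samc(s_attract_small, GainSchedule(1.0, 100), 1_000, seed=5)
        again = run_samc(s_attract_small, GainSchedule(1.0, 100), 0, seed=5,
                         initial=first.dos)
        d0, d1 = first.dos.anchored(), again.dos.anchored()
        common = set(zip(d0.env_raw, d0.nst)) & set(zip(d1.env_raw, d1.nst))
        assert len(common) == d0.n_keys
        for k in list(common)[:20]:
            key = MacrostateKey(*map(int, k))
            assert d0.log_g[d0.index_of(key)] == pytest.approx(
                d1.log_g[d1.index_of(key)])

    def test_refine_single_stage_equals_run_samc(self, s_attract_small):
        sch = GainSchedule(1.0, 100)
        a = run_samc(s_attract_small, sch, 3_000, seed=9)
        b = refine(s_attract_small, [sch], [3_000], seed=9)
        assert np.array_equal(a.dos.log_g, b.dos.log_g)

    def test_fingerprint_mismatch_rejected(self, s_attract_small):
        other = make_model("F-attract-stronger", N=8, b=4)
        res = run_samc(s_attract_small, GainSchedule(1.0, 100), 500, seed=1)
        with pytest.raises(ValueError, match="fingerprint"):
            run_samc(other, GainSchedule(1.0, 100), 500, seed=1,
                     initial=res.dos)

    def test_checkpoint_resume_bit_identical(self, s_attract_small, tmp_path):
        sch = GainSchedule(0.5, 500)
        full = run_samc(s_attract_small, sch, 4_000, seed=2)
        part = run_samc(s_attract_small, sch, 1_000, seed=2)
        from sfcopoly.samc import load_checkpoint, save_checkpoint

        ck = tmp_path / "state.ckpt.json"
        save_checkpoint(part.state, ck)
        resumed = run_samc(s_attract_small, sch, 3_000,
                           state=load_checkpoint(ck))
        assert np.array_equal(full.dos.log_g, resumed.dos.log_g)
        assert np.array_equal(full.dos.visits, resumed.dos.visits)
        assert np.array_equal(full.conformation.coords,
                              resumed.conformation.coords)

    def test_restore_without_checkpoint_errors(self, tmp_path):
        from sfcopoly.samc import load_checkpoint

        with pytest.raises(FileNotFoundError):
            load_checkpoint(tmp_path / "missing.json")


class TestAverageDos:
    def two_runs(self, s_attract_small):
        return [run_samc(s_attract_small, GainSchedule(1.0, 100), 2_000,
                         seed=s).dos for s in (3, 4)]

    def test_mean_of_two_values(self):
        mk = lambda lg: DoSGrid(env_raw=np.array([0, -1]), nst=np.zeros(2, int),
                                log_g=np.array([0.0, lg]),
                                visits=np.ones(2, dtype=np.int64),
                                fingerprint="x")
        avg = average_dos([mk(-1.0), mk(-1.2)])
        i = avg.index_of(MacrostateKey(-1, 0))
        assert avg.log_g[i] - avg.log_g.max() == pytest.approx(-1.1)
        assert avg.std_log_g[i] == pytest.approx(np.std([-1.0, -1.2], ddof=1))

    def test_identical_inputs_identity(self, s_attract_small):
        d = self.two_runs(s_attract_small)[0]
        avg = average_dos([d, d])
        assert np.allclose(np.sort(avg.log_g), np.sort(d.anchored().log_g))

    def test_quorum_drops_rare_keys(self):
        a = DoSGrid(env_raw=np.array([0, -1]), nst=np.zeros(2, int),
                    log_g=np.zeros(2), visits=np.ones(2, dtype=np.int64),
                    fingerprint="x")
        b = DoSGrid(env_raw=np.array([0]), nst=np.zeros(1, int),
                    log_g=np.zeros(1), visits=np.ones(1, dtype=np.int64),
                    fingerprint="x")
        avg = average_dos([a, b], quorum=2)
        assert avg.n_keys == 1 and avg.env_raw[0] == 0

    def test_fingerprint_mismatch(self, s_attract_small):
        d1, d2 = self.two_runs(s_attract_small)
        d2.fingerprint = "different"
        with pytest.raises(ValueError, match="fingerprint"):
            average_dos([d1, d2])


class TestMergeObservables:
    def make_table(self, env, nst, count, val):
        from sfcopoly.samc import ObservableTable
        from sfcopoly._kernel import N_OBS, OBS_COLUMNS

        k = len(env)
        means = np.full((k, N_OBS), float(val))
        return ObservableTable(env_raw=np.array(env, dtype=np.int64),
                               nst=np.array(nst, dtype=np.int64),
                               count=np.array(count, dtype=np.int64),
                               means=means, columns=OBS_COLUMNS,
                               fingerprint="x")

    def test_single_table_identity(self):
        from sfcopoly.samc import merge_observables

        t = self.make_table([-1, 0], [0, 0], [7, 5], 2.0)  # key-sorted order
        out = merge_observables([t])
        assert np.array_equal(out.count, t.count)
        assert np.array_equal(out.means, t.means)

    def test_weighted_pooling(self):
        from sfcopoly.samc import merge_observables

        a = self.make_table([0], [0], [10], 1.0)
        b = self.make_table([0], [0], [30], 5.0)
        out = merge_observables([a, b])
        assert out.count[0] == 40
        assert out.means[0, 0] == pytest.approx((10 * 1.0 + 30 * 5.0) / 40)

    def test_disjoint_keys_union(self):
        from sfcopoly.samc import merge_observables

        a = self.make_table([0], [0], [10], 1.0)
        b = self.make_table([-2], [1], [3], 4.0)
        out = merge_observables([a, b])
        assert out.n_keys == 2

    def test_fingerprint_mismatch(self):
        from sfcopoly.samc import merge_observables

        a = self.make_table([0], [0], [10], 1.0)
        b = self.make_table([0], [0], [10], 1.0)
        b.fingerprint = "y"
        with pytest.raises(ValueError, match="fingerprint"):
            merge_observables([a, b])


class TestProduction:
    def test_nst_column_mean_is_exact(self, phantom_allS6):
        res = refine(phantom_allS6, n_mcs=(20_000, 50_000), seed=1)
        table = production_run(phantom_allS6, res.dos, 20_000, seed=2,
                               sample_floor=10)
        np.testing.assert_allclose(table.column("nst"),
                                   table.nst.astype(float))

    def test_low_count_report(self, phantom_allS6):
        res = refine(phantom_allS6, n_mcs=(20_000, 50_000), seed=1)
        table = production_run(phantom_allS6, res.dos, 500, seed=2,
                               sample_floor=10**6)
        assert len(table.low_count_keys()) == table.n_keys

    def test_flat_histogram_under_exact_dos(self, phantom_allS6):
        """With the exact binomial DoS, production visits are ~uniform."""
        exact = phantom_dos(PhantomSpec(4))
        dos = DoSGrid(env_raw=np.zeros(5, dtype=np.int64),
                      nst=np.arange(5, dtype=np.int64),
                      log_g=np.log(exact),
                      visits=np.ones(5, dtype=np.int64),
                      fingerprint=phantom_allS6.fingerprint())
        table = production_run(phantom_allS6, dos, 150_000, seed=3,
                               sample_floor=1)
        counts = table.count.astype(float)
        frac = counts / counts.sum()
        # multinomial 3 sigma with n_eff reduced by autocorrelation; allow 5x
        assert np.all(np.abs(frac - 0.2) < 0.05)
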