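"""Chain geometry, energies, validity and trial moves."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sfcopoly import (
    ContactCounts, count_contacts, energy, initial_conformation, make_model,
    propose_end_regrow, propose_local_move, validate,
)
from sfcopoly.model import Conformation, random_bond_vector

from conftest import random_valid_conformation


def brute_force_counts(conf, model):
    """Oracle: all-pairs double loop + direct angle scan."""
    x = conf.coords
    t = model.types
    nss = nff = nsf = 0
    if not model.phantom:
        for i in range(model.N):
            for j in range(i + 2, model.N):
                if np.linalg.norm(x[i] - x[j]) <= model.R_cut:
                    if t[i] == 0 and t[j] == 0:
                        nss += 1
                    elif t[i] == 1 and t[j] == 1:
                        nff += 1
                    else:
                        nsf += 1
    nst = 0
    for j in range(1, model.N - 1):
        if not (t[j - 1] == 0 and t[j] == 0 and t[j + 1] == 0):
            continue
        a, c = x[j] - x[j - 1], x[j + 1] - x[j]
        theta = math.degrees(math.acos(np.clip(
            -(a @ c) / (np.linalg.norm(a) * np.linalg.norm(c)), -1, 1)))
        if model.theta_min <= theta <= model.theta_max:
            nst += 1
    return ContactCounts(nss=nss, nff=nff, nsf=nsf, nst=nst)


class TestMakeModel:
    def test_s_attract_preset(self):
        m = make_model("S-attract-stronger", N=64, b=8)
        assert (m.eps_ss, m.eps_sf, m.eps_ff) == (-4.0, -2.0, -1.0)
        assert m.raw_scale == 1.0
        assert list(m.eps_raw) == [-4, -2, -1]

    def test_f_attract_preset_rescaled(self):
        m = make_model("F-attract-stronger", N=64, b=8)
        assert (m.eps_ss, m.eps_sf, m.eps_ff) == (-0.25, -0.5, -1.0)
        assert m.raw_scale == 0.25
        assert list(m.eps_raw) == [-1, -2, -4]

    def test_lorentz_berthelot_fills_eps_sf(self):
        m = make_model(N=8, b=4, eps_ss=-4.0, eps_ff=-1.0)
        assert m.eps_sf == -2.0

    def test_lorentz_berthelot_violation_raises(self):
        with pytest.raises(ValueError, match="Lorentz"):
            make_model(N=8, b=4, eps_ss=-4.0, eps_ff=-1.0, eps_sf=-3.0)

    def test_block_pattern_and_composition(self):
        m = make_model("non-selective", N=16, b=4)
        assert m.pattern == "SSSSFFFFSSSSFFFF"
        assert m.nst_max == (m.b - 2) * m.N // (2 * m.b)

    @pytest.mark.parametrize("kwargs", [
        {"N": 10, "b": 4},                    # N not divisible by 2b
        {"N": 8, "b": 4, "l_max": 1.5},       # bonds could cross
        {"N": 8, "b": 4, "theta_min": 200.0},
        {"N": 8, "b": 4, "eps_st": 1.0},
    ])
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            make_model("non-selective", **kwargs)


class TestCountsAndEnergy:
    def test_contact_at_1p2_sigma_counts_once(self):
        m = make_model("non-selective", N=4, b=2)
        x = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0.6, 1, 0.8]])
        # beads 0 and 3: distance sqrt(.36+1+.64)=sqrt(2) ~ 1.414 <= 1.5
        c = count_contacts(Conformation(x), m)
        assert c.total_contacts >= 1

    def test_beyond_cutoff_is_no_contact(self):
        m = make_model("non-selective", N=3, pattern="SSS")
        x = np.array([[0, 0, 0], [1.0, 0, 0], [1.0, 1.0, 0]])
        x[2] = [1.6, 0, 1.0]  # bead 2 vs bead 0: sqrt(2.56+1) = 1.887
        assert count_contacts(Conformation(x), m).total_contacts == 0

    def test_straight_chain_has_no_favorable_angles(self):
        m = make_model("non-selective", N=6, pattern="SSSSSS")
        x = np.zeros((6, 3))
        x[:, 0] = np.arange(6.0)
        assert count_contacts(Conformation(x), m).nst == 0

    def test_two_angles_at_160_degrees(self):
        m = make_model("non-selective", N=4, pattern="SSSS")
        x = np.zeros((4, 3))
        x[1] = [1, 0, 0]
        th = math.radians(180 - 160)   # exterior angle between bond directions
        x[2] = x[1] + [math.cos(th), math.sin(th), 0]
        x[3] = x[2] + [math.cos(2 * th), math.sin(2 * th), 0]
        assert count_contacts(Conformation(x), m).nst == 2

    def test_angles_outside_s_blocks_do_not_count(self):
        # junction triplet SSF and pure-F triplets are ineligible
        m = make_model("non-selective", N=4, b=2)  # SSFF
        assert m.nst_max == 0

    def test_env_arithmetic_s_attract(self):
        m = make_model("S-attract-stronger", N=8, b=4)
        e = energy(ContactCounts(nss=2, nff=1, nsf=3), m)
        assert e.Env == -15.0 and e.Env_raw == -15

    def test_zero_counts_zero_energy(self):
        m = make_model("F-attract-stronger", N=8, b=4)
        e = energy(ContactCounts(0, 0, 0, 0), m)
        assert (e.Env, e.Est, e.U) == (0.0, 0.0, 0.0)

    def test_total_energy_sum(self):
        m = make_model("S-attract-stronger", N=8, b=4, eps_st=-2.0)
        c = ContactCounts(nss=2, nff=1, nsf=3, nst=7)
        e = energy(c, m)
        assert e.U == pytest.approx(-15.0 + (-2.0) * 7) == pytest.approx(-29.0)

    def test_f_attract_raw_scaling(self):
        m = make_model("F-attract-stronger", N=8, b=4)
        e = energy(ContactCounts(nss=1, nff=1, nsf=1), m)
        assert e.Env_raw == -7
        assert e.Env == pytest.approx(-1.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_count_contacts_matches_double_loop(self, seed):
        m = make_model("S-attract-stronger", N=12, b=2, eps_st=-1.0)
        conf = random_valid_conformation(m, seed)
        assert count_contacts(conf, m) == brute_force_counts(conf, m)

    @pytest.mark.parametrize("seed", range(3))
    def test_energy_invariant_under_rigid_motion(self, seed):
        m = make_model("S-attract-stronger", N=12, b=2, eps_st=-1.0)
        conf = random_valid_conformation(m, seed + 10)
        rot = Rotation.random(random_state=seed).as_matrix()
        moved = Conformation(conf.coords @ rot.T + np.array([3.0, -2.0, 11.0]))
        c0, c1 = count_contacts(conf, m), count_contacts(moved, m)
        assert c0 == c1
        assert energy(c0, m) == energy(c1, m)


class TestValidate:
    def setup_method(self):
        self.m = make_model("non-selective", N=4, b=2)

    def test_bonded_interpenetration_allowed(self):
        x = np.array([[0, 0, 0], [0.9, 0, 0], [0.9, 1, 0], [0.9, 2, 0.2]])
        assert validate(Conformation(x), self.m)

    def test_nonbonded_overlap_rejected(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0.2, 0.43, 0.3]])
        # bond 2-3 length ~ 1.03 (valid); bead 3 vs bead 0 ~ 0.56 < sigma
        rep = validate(Conformation(x), self.m)
        assert not rep and "hard-sphere" in rep.message

    def test_long_bond_rejected(self):
        x = np.array([[0, 0, 0], [1.3, 0, 0], [1.3, 1, 0], [1.3, 2, 0]])
        rep = validate(Conformation(x), self.m)
        assert not rep and "bond" in rep.message


class TestMoves:
    def test_local_move_bounded_and_reproducible(self, s_attract_small):
        conf = initial_conformation(s_attract_small, seed=3)
        c1, i1 = propose_local_move(conf, s_attract_small,
                                    np.random.default_rng(7))
        c2, i2 = propose_local_move(conf, s_attract_small,
                                    np.random.default_rng(7))
        assert i1 == i2 and np.array_equal(c1.coords, c2.coords)
        d = np.abs(c1.coords - conf.coords)
        assert d[np.arange(len(d)) != i1].max() == 0.0
        assert d[i1].max() <= 0.05

    def test_regrow_k1_moves_only_terminal_bead(self, s_attract_small):
        conf = initial_conformation(s_attract_small, seed=3)
        rng = np.random.default_rng(0)
        for _ in range(50):
            cand, k = propose_end_regrow(conf, s_attract_small, rng, k_max=1)
            assert k == 1
            changed = np.where(
                np.any(cand.coords != conf.coords, axis=1))[0]
            assert len(changed) == 1
            assert changed[0] in (0, s_attract_small.N - 1)

    def test_regrown_bond_lengths_in_window(self, s_attract_small):
        conf = initial_conformation(s_attract_small, seed=3)
        rng = np.random.default_rng(5)
        for _ in range(200):
            cand, _ = propose_end_regrow(conf, s_attract_small, rng)
            bl = np.linalg.norm(np.diff(cand.coords, axis=0), axis=1)
            assert bl.min() >= 0.8 - 1e-12 and bl.max() <= 1.25 + 1e-12

    def test_shell_sampling_mean_bond_length(self, rng):
        # density prop. to r^2 on [0.8, 1.25]:
        # E[r] = (int r^3 dr)/(int r^2 dr) = 0.50795.../0.480375 = 1.0574...
        expect = ((1.25**4 - 0.8**4) / 4) / ((1.25**3 - 0.8**3) / 3)
        n = 40_000
        r = np.array([np.linalg.norm(random_bond_vector(rng, 0.8, 1.25))
                      for _ in range(n)])
        assert r.mean() == pytest.approx(expect, abs=4 * r.std() / math.sqrt(n))
        assert expect == pytest.approx(1.057406, abs=1e-5)

    def test_phantom_angle_statistics_binomial(self):
        # i.i.d. uniform bond directions: each eligible angle favorable with
        # p0 = (cos 150 - cos 170)/2; nst ~ Binomial(n_angles, p0)
        from sfcopoly.oracles import phantom_p0

        p0 = phantom_p0()
        assert p0 == pytest.approx(0.059391, abs=1e-6)
        rng = np.random.default_rng(42)
        n_chains, n_beads = 20_000, 8
        d = rng.normal(size=(n_chains, n_beads - 1, 3))
        d /= np.linalg.norm(d, axis=2, keepdims=True)
        cosang = -np.sum(d[:, :-1] * d[:, 1:], axis=2)
        lo, hi = math.cos(math.radians(170)), math.cos(math.radians(150))
        nst = np.sum((cosang >= lo) & (cosang <= hi), axis=1)
        n_ang = n_beads - 2
        se = math.sqrt(n_ang * p0 * (1 - p0) / n_chains)
        assert nst.mean() == pytest.approx(n_ang * p0, abs=3 * se)

    def test_bond_geometry_cannot_create_overlap(self):
        # with l_max < sqrt(2) sigma, consecutive bonds cannot bring
        # second-nearest neighbours closer than... they CAN, but bonded pairs
        # are exempt; stress: long random walks never violate bond bounds
        m = make_model("non-selective", N=16, b=8, phantom=True)
        conf = initial_conformation(m, seed=0)
        rng = np.random.default_rng(9)
        for _ in range(300):
            cand, _ = propose_end_regrow(conf, m, rng, k_max=8)
            bl = np.linalg.norm(np.diff(cand.coords, axis=0), axis=1)
            assert ((bl >= m.l_min - 1e-12) & (bl <= m.l_max + 1e-12)).all()
            conf = cand
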