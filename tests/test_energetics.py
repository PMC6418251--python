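"""Coulomb/LJ pair potentials and per-residue interaction-energy decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from epistat.energetics import (
    COULOMB_CONSTANT,
    NonbondedParams,
    aggregate_replicas,
    coulomb_energy,
    lj_energy,
    residue_interaction_energy,
)
from epistat.errors import MissingParameterError, UsageError
from epistat.trajectory import Trajectory

from conftest import build_model


class TestPairPotentials:
    def test_zero_charge_gives_zero(self):
        for r in (0.5, 3.0, 25.0):
            assert coulomb_energy(0.0, 1.0, r) == 0.0

    def test_unit_charges_at_three_angstrom(self):
        # f * (+1)(-1) / 3.0 with f = 1389.35458 kJ A / (mol e^2)
        assert coulomb_energy(1.0, -1.0, 3.0) == pytest.approx(-463.118, abs=1e-3)

    @settings(max_examples=25, derandomize=True)
    @given(hst.floats(0.1, 50.0), hst.floats(0.01, 2.0), hst.floats(0.01, 2.0))
    def test_sign_follows_charge_product(self, r, q1, q2):
        assert coulomb_energy(q1, q2, r) > 0
        assert coulomb_energy(q1, -q2, r) < 0

    def test_singularity_rejected(self):
        with pytest.raises(UsageError):
            coulomb_energy(1.0, 1.0, 0.0)
        with pytest.raises(UsageError):
            lj_energy(3.0, 0.5, 0.0)

    def test_lj_node_and_minimum(self):
        assert lj_energy(3.4, 0.7, 3.4) == pytest.approx(0.0, abs=1e-12)
        r_min = 2.0 ** (1.0 / 6.0) * 3.4
        assert lj_energy(3.4, 0.7, r_min) == pytest.approx(-0.7, abs=1e-12)

    def test_lj_hand_evaluation_at_twice_sigma(self):
        # 4 * 0.5 * (2^-12 - 2^-6)
        expect = 4 * 0.5 * (2.0 ** -12 - 2.0 ** -6)
        assert lj_energy(3.5, 0.5, 7.0) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(-0.0307617, abs=1e-7)


def _lattice_points(n, rng, spacing=3.5, jitter=0.3):
    """n positions on a jittered cubic lattice: pairwise separation >= ~2.9 A."""
    k = math.ceil(n ** (1 / 3))
    pts = []
    for x in range(k):
        for y in range(k):
            for z in range(k):
                if len(pts) < n:
                    base = spacing * np.array([x, y, z], dtype=float)
                    pts.append(base + rng.uniform(-jitter, jitter, 3))
    return pts


def _two_vs_three_system():
    """2-atom 'residue' on chain A vs 3-atom 'chain' B with static frames."""
    model = build_model({
        ("A", 1, "LYS"): {"NZ": (0.0, 0.0, 0.0), "CE": (0.0, 1.4, 0.0)},
        ("B", 2, "ASP"): {"CG": (3.0, 0.0, 0.0), "OD1": (4.0, 0.8, 0.0),
                          "OD2": (4.0, -0.8, 0.0)},
    })
    table = {
        ("A", 1, "", "NZ"): (1.0, 3.2, 0.4),
        ("A", 1, "", "CE"): (-0.2, 3.6, 0.3),
        ("B", 2, "", "CG"): (0.4, 3.4, 0.5),
        ("B", 2, "", "OD1"): (-0.7, 3.0, 0.6),
        ("B", 2, "", "OD2"): (-0.7, 3.0, 0.6),
    }
    params = NonbondedParams(table=table)
    coords = model.coords()
    frames = np.repeat(coords[None], 5, axis=0)
    traj = Trajectory(model, frames, np.arange(5) * 0.01)
    return model, params, traj, table


class TestResidueEnergy:
    def test_matches_hand_summed_pairs(self):
        model, params, traj, table = _two_vs_three_system()
        coords = model.coords()
        flat = model.flat_index()
        coul = lj = 0.0
        for a_name in ("NZ", "CE"):
            for b_name in ("CG", "OD1", "OD2"):
                qa, sa, ea = table[("A", 1, "", a_name)]
                qb, sb, eb = table[("B", 2, "", b_name)]
                r = float(np.linalg.norm(coords[flat[("A", 1, "", a_name)]]
                                         - coords[flat[("B", 2, "", b_name)]]))
                coul += coulomb_energy(qa, qb, r)
                lj += lj_energy(0.5 * (sa + sb), math.sqrt(ea * eb), r)
        bd = residue_interaction_energy(traj, params, model.find_residue("A", 1),
                                        ["B"], cutoff=12.0)
        assert bd.coulomb == pytest.approx(coul, abs=1e-9)
        assert bd.lj == pytest.approx(lj, abs=1e-9)
        assert bd.total == pytest.approx(coul + lj, abs=1e-9)

    def test_neutral_zero_epsilon_residue_has_zero_energy(self):
        model, params, traj, table = _two_vs_three_system()
        dead = {k: (0.0, s, 0.0 if k[0] == "A" else e)
                for k, (q, s, e) in table.items()}
        bd = residue_interaction_energy(traj, NonbondedParams(table=dead),
                                        model.find_residue("A", 1), ["B"])
        assert bd.total == 0.0

    def test_partner_beyond_cutoff_contributes_nothing(self):
        model, params, traj, _ = _two_vs_three_system()
        far = traj.frames.copy()
        b_idx = [i for i, (k, _) in enumerate(model.atoms()) if k.chain_id == "B"]
        far[:, b_idx, :] += 200.0
        traj_far = Trajectory(model, far, traj.times)
        bd = residue_interaction_energy(traj_far, params,
                                        model.find_residue("A", 1), ["B"],
                                        cutoff=12.0)
        assert bd.total == 0.0

    def test_pair_symmetry(self):
        model, params, traj, _ = _two_vs_three_system()
        e_ab = residue_interaction_energy(traj, params,
                                          model.find_residue("A", 1), ["B"])
        e_ba = residue_interaction_energy(traj, params,
                                          model.find_residue("B", 2), ["A"])
        assert e_ab.total == pytest.approx(e_ba.total, abs=1e-9)

    def test_charge_doubling_quadruples_coulomb_only(self):
        model, params, traj, table = _two_vs_three_system()
        doubled = NonbondedParams(table={k: (2 * q, s, e)
                                         for k, (q, s, e) in table.items()})
        base = residue_interaction_energy(traj, params,
                                          model.find_residue("A", 1), ["B"])
        big = residue_interaction_energy(traj, doubled,
                                         model.find_residue("A", 1), ["B"])
        assert big.coulomb == pytest.approx(4.0 * base.coulomb, abs=1e-9)
        assert big.lj == pytest.approx(base.lj, abs=1e-9)

    def test_agrees_with_no_cutoff_brute_force_on_random_system(self, rng):
        # <= 200 atoms on a jittered lattice (no steric collisions), cutoff
        # beyond the system diameter
        coords = iter(_lattice_points(46, rng))
        residues = {("A", 1, "LYS"): {f"X{i}": next(coords) for i in range(6)}}
        for j in range(10):
            residues[("B", 10 + j, "ALA")] = {f"Y{i}": next(coords)
                                              for i in range(4)}
        model = build_model(residues)
        table = {}
        for key, atoms in model.residues.items():
            for atom in atoms:
                table[(key.chain_id, key.res_seq, "", atom.name)] = (
                    float(rng.normal(0, 0.5)), float(rng.uniform(2.5, 4.0)),
                    float(rng.uniform(0.1, 1.0)))
        params = NonbondedParams(table=table)
        coords = model.coords()
        frames = coords[None] + rng.normal(0, 0.2, (3, *coords.shape))
        traj = Trajectory(model, frames, np.arange(3) * 0.01)

        flat = list(model.atoms())
        a_idx = [i for i, (k, _) in enumerate(flat) if k.chain_id == "A"]
        b_idx = [i for i, (k, _) in enumerate(flat) if k.chain_id == "B"]
        per_frame = []
        for frame in frames:
            tot = 0.0
            for i in a_idx:
                ki, ai = flat[i]
                qa, sa, ea = table[(ki.chain_id, ki.res_seq, "", ai.name)]
                for j in b_idx:
                    kj, aj = flat[j]
                    qb, sb, eb = table[(kj.chain_id, kj.res_seq, "", aj.name)]
                    r = float(np.linalg.norm(frame[i] - frame[j]))
                    tot += coulomb_energy(qa, qb, r)
                    tot += lj_energy(0.5 * (sa + sb), math.sqrt(ea * eb), r)
            per_frame.append(tot)
        bd = residue_interaction_energy(traj, params, model.find_residue("A", 1),
                                        ["B"], cutoff=1e4)
        assert bd.total == pytest.approx(float(np.mean(per_frame)), abs=1e-9)

    def test_unparameterized_atoms_refused_with_listing(self):
        model, params, traj, table = _two_vs_three_system()
        short = dict(table)
        del short[("B", 2, "", "OD1")]
        with pytest.raises(MissingParameterError, match="OD1"):
            residue_interaction_energy(traj, NonbondedParams(table=short),
                                       model.find_residue("A", 1), ["B"])

    def test_own_chain_as_partner_rejected(self):
        model, params, traj, _ = _two_vs_three_system()
        with pytest.raises(UsageError):
            residue_interaction_energy(traj, params, model.find_residue("A", 1),
                                       ["A", "B"])

    def test_pair_overrides_take_precedence(self):
        model, params, traj, table = _two_vs_three_system()
        # kill LJ between NZ and CG only, via an explicit pair entry
        override = {frozenset({("A", 1, "", "NZ"), ("B", 2, "", "CG")}):
                    (3.3, 0.0)}
        custom = NonbondedParams(table=table, pair_overrides=override)
        base = residue_interaction_energy(traj, params,
                                          model.find_residue("A", 1), ["B"])
        mod = residue_interaction_energy(traj, custom,
                                         model.find_residue("A", 1), ["B"])
        assert mod.coulomb == pytest.approx(base.coulomb, abs=1e-9)
        assert mod.lj != pytest.approx(base.lj, abs=1e-9)


class TestReplicaAggregation:
    def test_mean_and_standard_error(self):
        model, params, traj, table = _two_vs_three_system()
        key = model.find_residue("A", 1)
        reps = []
        for scale in (1.0, 2.0, 3.0):
            scaled = NonbondedParams(table={k: (q * scale, s, e)
                                            for k, (q, s, e) in table.items()})
            reps.append(residue_interaction_energy(traj, scaled, key, ["B"]))
        agg = aggregate_replicas(reps)
        totals = [b.total for b in reps]
        assert agg.total == pytest.approx(np.mean(totals))
        assert agg.se == pytest.approx(np.std(totals, ddof=1) / math.sqrt(3))
        assert agg.n_replicas == 3
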