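"""Energy terms: wells, oracles, electrostatics, decomposition identity."""
import copy

import numpy as np
import pytest

from pkfold import (
    BasePairMap,
    EnergyFlags,
    ForceFieldParams,
    IonCondition,
    Sequence,
    annotate_stems,
    bonded_energy,
    coaxial_energy,
    debye_length,
    detect_base_pairs,
    effective_charge_fraction,
    electrostatic_energy,
    evaluate_state,
    excluded_volume_energy,
    pairing_energy,
    sequence_to_random_chain,
    stacking_energy,
    total_energy,
    water_dielectric,
)
from pkfold.cg_model import BeadChain
from pkfold.forcefield import ParameterError, bjerrum_length
from pkfold.synthetic import (
    helix_strand_coords,
    ideal_hairpin_chain,
    ideal_helix_chain,
)


def _modified_params(params, **sections):
    raw = copy.deepcopy(params.raw)
    for sec, upd in sections.items():
        raw[sec].update(upd)
    return ForceFieldParams(raw)


class TestParams:
    def test_default_loads_and_validates(self, params):
        assert params.pairing["depth"]["GC"] >= params.pairing["depth"]["AU"]

    def test_invalid_depth_ordering_rejected(self, params):
        with pytest.raises(ParameterError):
            _modified_params(params, pairing={"depth": {"GC": 1, "AU": 2, "GU": 3}})

    def test_every_wc_step_resolves(self, params):
        bases = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for x, xp in bases.items():
            for y, yp in bases.items():
                dh, ds = params.stack_step(x + y, yp + xp)
                assert dh < 0 and ds < 0

    def test_checksum_stable(self, params):
        assert params.checksum() == ForceFieldParams.default().checksum()


class TestBondedEnergy:
    def test_ideal_helix_is_at_the_helical_minimum(self, helix8, params):
        U_b, U_a, U_d = bonded_energy(helix8, np.ones(8, bool), params)
        assert U_b == pytest.approx(0.0, abs=1e-4)
        assert U_a == pytest.approx(0.0, abs=1e-4)
        assert U_d == pytest.approx(0.0, abs=1e-6)

    def test_bond_stretch_is_harmonic(self, helix8, params):
        delta = 0.25
        chain = helix8.copy()
        # stretch the terminal C-N bond along its own axis
        u = chain.coords[7, 2] - chain.coords[7, 1]
        d0 = np.linalg.norm(u)
        u /= d0
        chain.coords[7, 2] += delta * u
        U0 = bonded_energy(helix8, np.ones(8, bool), params)[0]
        U1 = bonded_energy(chain, np.ones(8, bool), params)[0]
        eq, k = params.bonded["helical"]["bonds"]["CN"]
        expected = k * ((d0 + delta - eq) ** 2 - (d0 - eq) ** 2)
        assert U1 - U0 == pytest.approx(expected, rel=1e-9)

    def test_matches_independent_per_term_loop(self, params):
        """Vectorized bonded energy equals a hand-written per-term loop."""
        chain = sequence_to_random_chain(Sequence("GCAUGGCAUC"), 7, params)
        mask = np.array([0, 1, 1, 0, 0, 1, 0, 1, 1, 0], bool)

        def ang(a, b, c):
            u, v = a - b, c - b
            return np.arccos(np.clip(
                np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1))

        def dih(a, b, c, d):
            b1, b2, b3 = b - a, c - b, d - c
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            m = np.cross(n1, b2 / np.linalg.norm(b2))
            return np.arctan2(np.dot(m, n2), np.dot(n1, n2))

        def pset(i):
            return params.bonded["helical" if mask[i] else "nonhelical"]

        P, C, N = chain.P, chain.C, chain.N
        n = len(chain)
        U_b = U_a = U_d = 0.0
        for i in range(n):
            for key, d in (("PC", np.linalg.norm(P[i] - C[i])),
                           ("CN", np.linalg.norm(C[i] - N[i]))):
                eq, k = pset(i)["bonds"][key]
                U_b += k * (d - eq) ** 2
            eq, k = pset(i)["angles"]["PCN"]
            U_a += k * (ang(P[i], C[i], N[i]) - np.deg2rad(eq)) ** 2
            if i + 1 < n:
                eq, k = pset(i)["bonds"]["CP"]
                U_b += k * (np.linalg.norm(C[i] - P[i + 1]) - eq) ** 2
                for key, th in (("PCP", ang(P[i], C[i], P[i + 1])),
                                ("NCP", ang(N[i], C[i], P[i + 1]))):
                    eq, k = pset(i)["angles"][key]
                    U_a += k * (th - np.deg2rad(eq)) ** 2
                eq, k = pset(i + 1)["angles"]["CPC"]
                U_a += k * (ang(C[i], P[i + 1], C[i + 1]) - np.deg2rad(eq)) ** 2
                for key, ph in (("PCPC", dih(P[i], C[i], P[i + 1], C[i + 1])),
                                ("NCPC", dih(N[i], C[i], P[i + 1], C[i + 1]))):
                    eq, k = pset(i)["dihedrals"][key]
                    U_d += k * (1 - np.cos(ph - np.deg2rad(eq)))
            if i + 2 < n:
                eq, k = pset(i + 1)["dihedrals"]["CPCP"]
                U_d += k * (1 - np.cos(
                    dih(C[i], P[i + 1], C[i + 1], P[i + 2]) - np.deg2rad(eq)))

        got = bonded_energy(chain, mask, params)
        assert got[0] == pytest.approx(U_b, rel=1e-9)
        assert got[1] == pytest.approx(U_a, rel=1e-9)
        assert got[2] == pytest.approx(U_d, rel=1e-9)


class TestExcludedVolume:
    def test_zero_beyond_contact(self, params):
        seq = Sequence("AU")
        coords = np.zeros((2, 3, 3))
        coords[0] = [[0, 0, 0], [4, 0, 0], [8, 0, 0]]
        coords[1] = [[30, 0, 0], [34, 0, 0], [38, 0, 0]]
        assert excluded_volume_energy(BeadChain(seq, coords), params) == 0.0

    def test_monotone_in_overlap(self, params):
        """Probe the N(0)-N(1) contact (4.4 A): deeper overlap, higher energy."""
        seq = Sequence("AU")
        energies = []
        for gap in (5.0, 4.0, 3.0, 2.5, 2.0):
            coords = np.zeros((2, 3, 3))
            coords[0] = [[0, 0, 0], [4, 0, 0], [8, 0, 0]]
            coords[1] = [[30, 0, 0], [34, 0, 0], [8 + gap, 0, 0]]
            energies.append(excluded_volume_energy(BeadChain(seq, coords), params))
        diffs = np.diff(energies)
        assert all(d >= 0 for d in diffs) and energies[-1] > 0

    def test_matches_brute_force_double_loop(self, params):
        chain = sequence_to_random_chain(Sequence("GCAUGCA"), 3, params)
        # compress to force overlaps
        chain = BeadChain(chain.sequence, chain.coords * 0.55)
        eps = params.excluded_volume["epsilon"]
        radii = params.bead_radii_array(chain.sequence)
        pos = chain.flat
        from pkfold.forcefield import _exclusion_mask

        excl = _exclusion_mask(len(chain))
        U = 0.0
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                if excl[a, b]:
                    continue
                d = np.linalg.norm(pos[a] - pos[b])
                s = radii[a] + radii[b]
                if d < s:
                    U += eps * ((s / d) ** 12 - 2 * (s / d) ** 6 + 1)
        assert excluded_volume_energy(chain, params) == pytest.approx(U, rel=1e-9)


class TestPairingEnergy:
    def test_single_gc_pair_at_minimum_equals_depth(self, params):
        chain = ideal_hairpin_chain("G", "AAAA", params)
        bp = BasePairMap.from_pairs([(0, 5)], 6)
        U = pairing_energy(chain, bp, params)
        assert U == pytest.approx(-params.pairing["depth"]["GC"], rel=1e-6)

    def test_far_pair_contributes_zero(self, params):
        chain = ideal_hairpin_chain("G", "AAAA", params)
        chain.coords[5] += 50.0
        bp = BasePairMap.from_pairs([(0, 5)], 6)
        assert pairing_energy(chain, bp, params) == 0.0

    def test_non_complementary_pair_raises(self, params):
        chain = ideal_hairpin_chain("GA", "AAAA", params)
        # residues 0 (G) and 5 (A) cannot pair canonically
        bp = BasePairMap.from_pairs([(0, 5)], 8)
        with pytest.raises(ValueError, match="not complementary"):
            pairing_energy(chain, bp, params)

    def test_helix_is_sum_of_independent_pairs(self, params):
        chain = ideal_hairpin_chain("GCG", "AAAA", params)
        n = len(chain)
        pairs = [(i, n - 1 - i) for i in range(3)]
        total = pairing_energy(chain, BasePairMap.from_pairs(pairs, n), params)
        singles = sum(
            pairing_energy(chain, BasePairMap.from_pairs([p], n), params)
            for p in pairs)
        assert total == pytest.approx(singles, rel=1e-12)


class TestStackingEnergy:
    def test_zero_at_compensation_temperature(self, params, ion_1m):
        """A step contributes nothing where dH - T*dS crosses zero."""
        dh, ds = params.stack_step("AA", "UU")
        T0 = dh / (ds * 1e-3)
        assert 250 < T0 < 450
        chain = ideal_hairpin_chain("AA", "AAAA", params)
        bp = BasePairMap.from_pairs([(0, 7), (1, 6)], 8)
        U = stacking_energy(chain, bp, IonCondition(T0, 1000.0), params)
        assert U == pytest.approx(0.0, abs=1e-9)

    def test_gc_step_stronger_than_au_step_at_37C(self, params):
        T = 310.15
        g_gc = params.step_free_energy("GC", "GC", T)
        g_au = params.step_free_energy("AU", "AU", T)
        assert abs(g_gc) > abs(g_au)
        assert g_gc < 0 and g_au < 0

    def test_all_steps_weaker_at_90C_than_25C(self, params):
        steps = ["AA/UU", "AU/AU", "UA/UA", "CU/AG", "CA/UG", "GU/AC",
                 "GA/UC", "CG/CG", "GG/CC", "GC/GC"]
        for key in steps:
            top, bottom = key.split("/")
            g_cold = params.step_free_energy(top, bottom, 298.15)
            g_hot = params.step_free_energy(top, bottom, 363.15)
            assert g_hot > g_cold

    def test_stacking_applies_to_formed_steps_only(self, params, ion_1m):
        chain = ideal_hairpin_chain("GCG", "AAAA", params)
        n = len(chain)
        ladder = BasePairMap.from_pairs([(0, 9), (1, 8), (2, 7)], n)
        lone = BasePairMap.from_pairs([(0, 9), (2, 7)], n)
        assert stacking_energy(chain, ladder, ion_1m, params) < -1.0
        assert stacking_energy(chain, lone, ion_1m, params) == 0.0


class TestCoaxialEnergy:
    @pytest.fixture()
    def two_stem_chain(self, params):
        """Two 3-bp stems on one continuous template helix, 1-nt junction.

        Axis positions: stem A pairs (0,10),(1,9),(2,8) at axis 0-2, stem B
        pairs (4,14),(5,13),(6,12) at axis 3-5; loop residues parked far away.
        """
        seq = Sequence("GGGAGGGACCCACCC")
        coords = np.full((15, 3, 3), 500.0)
        s1a = helix_strand_coords(params, [0, 1, 2], strand=1)
        s1b = helix_strand_coords(params, [2, 1, 0], strand=2)
        s2a = helix_strand_coords(params, [3, 4, 5], strand=1)
        s2b = helix_strand_coords(params, [5, 4, 3], strand=2)
        coords[0:3] = s1a
        coords[8:11] = s1b
        coords[4:7] = s2a
        coords[12:15] = s2b
        # park the loop residues in a spread-out line to avoid clashes
        for k, res in enumerate((3, 7, 11)):
            coords[res] = 500.0 + 20.0 * k + np.array(
                [[0, 0, 0], [4, 0, 0], [8, 0, 0]])
        return BeadChain(seq, coords)

    def test_quasi_continuous_stems_get_the_interface_step_energy(
            self, two_stem_chain, params, ion_1m):
        bp = BasePairMap.from_pairs(
            [(0, 10), (1, 9), (2, 8), (4, 14), (5, 13), (6, 12)], 15)
        stems = annotate_stems(bp, 15)
        assert stems.n_stems == 2
        U = coaxial_energy(two_stem_chain, stems, ion_1m, params)
        # interface pairs are (0,10) and (4,14): pseudo-step GG/CC
        expected = (params.coaxial["scale"]
                    * params.step_free_energy("GG", "CC", ion_1m.T))
        assert U == pytest.approx(expected, rel=1e-3)

    def test_long_junction_gives_zero(self, two_stem_chain, params, ion_1m):
        # pretend the stems are 5 nt apart in sequence: rebuild the map with
        # stem B shifted out of junction range by dropping its closest pair
        bp = BasePairMap.from_pairs(
            [(0, 10), (1, 9), (2, 8), (4, 14), (5, 13), (6, 12)], 15)
        stems = annotate_stems(bp, 15)
        far = _modified_params(params, coaxial={"max_junction_loop": 0})
        # junction is 1 nt here, so max 0 disables it
        assert coaxial_energy(two_stem_chain, stems, ion_1m, far) == 0.0

    def test_ablation_flag_disables(self, two_stem_chain, params, ion_1m):
        bp = BasePairMap.from_pairs(
            [(0, 10), (1, 9), (2, 8), (4, 14), (5, 13), (6, 12)], 15)
        stems = annotate_stems(bp, 15)
        assert coaxial_energy(two_stem_chain, stems, ion_1m, params,
                              enabled=False) == 0.0


class TestElectrostatics:
    def test_debye_length_1M_25C(self, params):
        lam = debye_length(IonCondition.from_celsius(25.0, 1000.0), params)
        assert lam == pytest.approx(3.04, abs=0.01)

    def test_quartering_ionic_strength_doubles_debye_length(self, params):
        l1 = debye_length(IonCondition.from_celsius(25.0, 1000.0), params)
        l2 = debye_length(IonCondition.from_celsius(25.0, 250.0), params)
        assert l2 == pytest.approx(2 * l1, rel=1e-9)

    def test_divalent_shortens_debye_length(self, params):
        base = debye_length(IonCondition.from_celsius(25.0, 100.0), params)
        lam = debye_length(IonCondition.from_celsius(25.0, 100.0, 10.0), params)
        assert lam < base

    def test_charge_fraction_monovalent_limit(self, params):
        ion = IonCondition.from_celsius(25.0, 100.0)
        b = params.electrostatics["manning_spacing"]["coil"]
        xi = bjerrum_length(ion.T, params) / b
        assert effective_charge_fraction(ion, "coil", params) == pytest.approx(
            1.0 / xi)

    def test_charge_fraction_divalent_limits_and_interpolation(self, params):
        c1 = 50.0
        mono = effective_charge_fraction(IonCondition.from_celsius(25, c1))
        huge = effective_charge_fraction(
            IonCondition.from_celsius(25, c1, 1e5), "coil", params)
        ion25 = IonCondition.from_celsius(25, c1)
        di_limit = 0.5 * effective_charge_fraction(ion25, "coil", params)
        assert huge < mono
        assert huge == pytest.approx(di_limit, rel=0.05)
        prev = mono
        for c2 in np.logspace(-2, 3, 12):
            q = effective_charge_fraction(
                IonCondition.from_celsius(25, c1, float(c2)), "coil", params)
            assert di_limit - 1e-9 <= q <= mono + 1e-9
            assert q <= prev + 1e-12  # monotone non-increasing in c2
            prev = q

    def test_two_phosphates_match_closed_form(self, params):
        seq = Sequence("AUG")
        coords = np.zeros((3, 3, 3))
        coords[0] = [[0, 0, 0], [4, 0, 0], [8, 0, 0]]
        coords[1] = [[50, 0, 0], [54, 0, 0], [58, 0, 0]]
        coords[2] = [[12, 30, 0], [16, 30, 0], [20, 30, 0]]
        chain = BeadChain(seq, coords)
        ion = IonCondition.from_celsius(25.0, 150.0)
        lam = debye_length(ion, params)
        Q = effective_charge_fraction(ion, "coil", params)
        eps_r = water_dielectric(ion.T)
        kC = params.electrostatics["coulomb_const"]
        # only the |i-j| >= 2 pair contributes (adjacent P's are bonded-range)
        expected = 0.0
        for a, b in [(0, 2)]:
            d = np.linalg.norm(coords[a, 0] - coords[b, 0])
            expected += kC * Q * Q / eps_r * np.exp(-d / lam) / d
        assert electrostatic_energy(chain, ion, params) == pytest.approx(
            expected, rel=1e-9)

    def test_adjacent_phosphates_excluded(self, params):
        chain = sequence_to_random_chain(Sequence("AU"), 0, params)
        ion = IonCondition.from_celsius(25.0, 100.0)
        assert electrostatic_energy(chain, ion, params) == 0.0

    def test_high_salt_kills_repulsion(self, params):
        chain = sequence_to_random_chain(Sequence("GGGAAAUCCC"), 1, params)
        lo = electrostatic_energy(chain, IonCondition.from_celsius(25, 10), params)
        hi = electrostatic_energy(chain, IonCondition.from_celsius(25, 3000), params)
        assert hi < lo / 50

    def test_divalent_reduces_repulsion(self, params):
        chain = sequence_to_random_chain(Sequence("GGGAAAUCCC"), 1, params)
        base = electrostatic_energy(chain, IonCondition.from_celsius(25, 50), params)
        withmg = electrostatic_energy(
            chain, IonCondition.from_celsius(25, 50, 5.0), params)
        assert withmg < base

    def test_monovalent_only_formulation_is_bitwise_limit(self, params):
        ion0 = IonCondition.from_celsius(37.0, 120.0, 0.0)
        ion = IonCondition.from_celsius(37.0, 120.0)
        chain = sequence_to_random_chain(Sequence("GCGCAAAAGCGC"), 4, params)
        assert electrostatic_energy(chain, ion0, params) == \
            electrostatic_energy(chain, ion, params)
        assert debye_length(ion0, params) == debye_length(ion, params)


class TestTotalEnergy:
    def test_breakdown_sums_to_total(self, params, ion_1m):
        chain = sequence_to_random_chain(Sequence("GGGGUGGCUCCCCUAACAGCCG"),
                                         2, params)
        e, bp, stems = evaluate_state(chain, ion_1m, params)
        manual = (e.U_b + e.U_a + e.U_d + e.U_exc + e.U_bp + e.U_bs
                  + e.U_cs + e.U_el)
        assert e.U_total == pytest.approx(manual, rel=1e-12)

    def test_rigid_motion_invariance(self, params, ion_1m):
        from scipy.spatial.transform import Rotation

        chain = sequence_to_random_chain(Sequence("GGCGAAAUCGCC"), 9, params)
        e0, bp, stems = evaluate_state(chain, ion_1m, params)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        moved = BeadChain(chain.sequence,
                          rot.apply(chain.flat).reshape(-1, 3, 3) + 13.7)
        e1, _, _ = evaluate_state(moved, ion_1m, params)
        assert e1.U_total == pytest.approx(e0.U_total, rel=1e-8, abs=1e-8)

    def test_isolated_ideal_residue_pair_only_bonded_terms(self, params, ion_1m):
        chain = ideal_helix_chain(Sequence("GA"), params)
        bp = BasePairMap.from_pairs([], 2)
        stems = annotate_stems(bp, 2)
        e = total_energy(chain, bp, stems, ion_1m, params,
                         EnergyFlags(electrostatics=False),
                         np.ones(2, bool))
        assert e.U_bp == e.U_bs == e.U_cs == e.U_el == 0.0
        assert e.U_total == pytest.approx(e.U_b + e.U_a + e.U_d + e.U_exc)

    def test_ablation_flags_zero_their_terms(self, params, ion_1m):
        chain = sequence_to_random_chain(Sequence("GGGAGGGACCCACCC"), 3, params)
        e, _, _ = evaluate_state(chain, ion_1m, params,
                                 EnergyFlags(coaxial=False,
                                             electrostatics=False))
        assert e.U_cs == 0.0 and e.U_el == 0.0
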