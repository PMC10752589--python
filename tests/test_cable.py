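import numpy as np
import pytest

from starburst.cable import (CompartmentalModel, MembraneSpec, RecordingSite,
                             SynapseSite, dc_transfer_ratio,
                             inject_current_step, perisomatic_modification,
                             place_bipolar_synapses, run_visual_trial)
from starburst.morphology import Morphology

from conftest import cylinder_morphology, random_tree_morphology


def single_compartment(radius=5.0):
    return Morphology(np.zeros((1, 3)), np.array([radius]),
                      np.array([-1]), np.array([1]))


class TestPassiveDC:
    def test_identity_transfer(self, sac_morph):
        model = CompartmentalModel(sac_morph)
        assert dc_transfer_ratio(model, 50, 50) == pytest.approx(1.0)

    def test_cylinder_matches_cosh_form(self):
        model = CompartmentalModel(cylinder_morphology(), MembraneSpec(),
                                   max_dx=1.0)
        e = np.zeros(model.n_comp)
        e[0] = 1.0
        v = model.dc_voltage(e)
        lam = np.sqrt((1e-4 / 4) * (1 / 4e-4) / 150.0) * 1e4   # um
        X = model.comp_mid[:, 0] / lam
        L = 500.0 / lam
        pred = np.cosh(L - X) / np.cosh(L)
        assert np.abs(v / v[0] - pred)[1:].max() < 1e-4

    def test_transfer_reciprocity_random_tree(self):
        model = CompartmentalModel(random_tree_morphology(50, seed=3))
        rng = np.random.default_rng(0)
        for _ in range(8):
            a, b = rng.integers(1, model.n_comp, size=2)
            za = model.transfer_impedance(int(a), int(b))
            zb = model.transfer_impedance(int(b), int(a))
            assert za == pytest.approx(zb, rel=1e-6)

    def test_attenuation_geometry_on_sac(self, sac_morph):
        """Signals crossing the soma are attenuated more than 20-fold,
        far more than signals to the sister branch sharing the last
        bifurcation."""
        model = CompartmentalModel(sac_morph)
        tips = model.tip_comps()
        xs = model.comp_xyz[tips, 0]
        src = int(tips[np.argmax(xs)])            # right-most tip
        opposite = int(tips[np.argmin(xs)])       # across the soma
        # sister tip: diverges at the deepest bifurcation on src's path
        path = [src]
        while model.comp_parent[path[-1]] >= 0:
            path.append(int(model.comp_parent[path[-1]]))
        path_set = set(path)
        sister, best_depth = None, -1.0
        for t2 in tips:
            t2 = int(t2)
            if t2 == src:
                continue
            q = t2
            while q >= 0 and q not in path_set:
                q = int(model.comp_parent[q])
            if q >= 0 and model.comp_path[q] > best_depth:
                best_depth, sister = model.comp_path[q], t2
        across_ratio = dc_transfer_ratio(model, src, opposite)
        sister_ratio = dc_transfer_ratio(model, src, sister)
        assert 1.0 / across_ratio > 20.0
        assert sister_ratio > 5.0 * across_ratio


class TestCurrentStep:
    def test_zero_amplitude_stays_at_rest(self, sac_morph):
        model = CompartmentalModel(sac_morph)
        res = inject_current_step(model, 10, amplitude=0.0)
        np.testing.assert_allclose(res.v, -60.0, atol=1e-9)

    def test_single_compartment_rc_steady_state(self):
        model = CompartmentalModel(single_compartment(),
                                   MembraneSpec(g_can=0.0))
        res = inject_current_step(model, 0, amplitude=10.0, duration=400.0,
                                  delay=10.0, dt=0.05, t_stop=420.0)
        dv = res.v[0].max() + 60.0
        expect = (10.0e-3) / model.g_leak[0]      # I/g in mV
        assert dv == pytest.approx(expect, rel=1e-6)

    def test_within_branch_fraction_substantial(self, sac_morph):
        """A sizeable fraction of a distal injection is visible at a
        within-branch recording site."""
        model = CompartmentalModel(sac_morph)
        tips = model.tip_comps()
        src = int(tips[0])
        # sibling tip: shares the last bifurcation
        sib = int(tips[1])
        r = dc_transfer_ratio(model, src, sib)
        assert r > 0.2


class TestVisualTrial:
    def test_zero_drive_is_rest(self, sac_morph):
        model = CompartmentalModel(sac_morph)
        syns = place_bipolar_synapses(model, n=20, seed=0)
        drive = np.zeros((500, 20))
        res = run_visual_trial(model, syns, drive, model.recording_sites(),
                               dt=0.25)
        # a vanishing CaN window current leaves a sub-microvolt voltage
        # offset and a ~0.01 nM calcium offset at rest
        np.testing.assert_allclose(res.v, -60.0, atol=1e-3)
        np.testing.assert_allclose(res.ca, 100.0, atol=0.05)

    def test_conductance_divider_steady_state(self):
        model = CompartmentalModel(single_compartment(),
                                   MembraneSpec(g_can=0.0))
        g_max = 0.5   # nS
        syn = [SynapseSite(0, 0.0, 0.0, 0.0, g_max)]
        drive = np.ones((3000, 1))
        res = run_visual_trial(model, syn, drive,
                               [RecordingSite(0, 0.0, 0.0, 1)], dt=0.05)
        g_us = g_max * 1e-3
        expect = (g_us * 0.0 + model.g_leak[0] * -60.0) / (g_us + model.g_leak[0])
        assert res.v[0, -1] == pytest.approx(expect, rel=1e-6)

    def test_calcium_pool_closed_form(self):
        """Constant calcium current: Ca_ss = Ca_rest + k * I * tau."""
        spec = MembraneSpec(g_can=1e-4, can_vhalf=-200.0)  # fully open at rest
        model = CompartmentalModel(single_compartment(), spec)
        syn = [SynapseSite(0, 0.0, 0.0, 0.0, 0.0)]
        drive = np.zeros((3000, 1))
        res = run_visual_trial(model, syn, drive,
                               [RecordingSite(0, 0.0, 0.0, 1)], dt=0.05)
        v_ss = res.v[0, -1]
        i_ca = model.g_can_us[0] * 1.0 * (v_ss - spec.e_ca)   # nA (m = 1)
        expect = spec.ca_rest + model.ca_scale[0] * (-i_ca) * spec.ca_tau
        assert res.ca[0, -1] == pytest.approx(expect, rel=1e-6)

    def test_excitation_never_hyperpolarizes(self, sac_morph):
        model = CompartmentalModel(sac_morph)
        syns = place_bipolar_synapses(model, n=50, seed=1, g_max=0.05)
        rng = np.random.default_rng(0)
        drive = np.clip(rng.random((800, 50)), 0, 1)
        res = run_visual_trial(model, syns, drive, model.recording_sites(),
                               dt=0.25)
        assert res.v.min() >= -60.0 - 1e-9

    def test_refinement_convergence(self, sac_morph):
        """Halving the spatial and temporal steps moves the peak
        depolarization by less than 1% (same physical synapse positions
        mapped onto each discretization)."""
        coarse = CompartmentalModel(sac_morph, max_dx=8.0)
        pos = [(s.x, s.y) for s in
               place_bipolar_synapses(coarse, n=30, seed=2)]
        t = np.arange(600)
        wave = np.clip(np.sin(t / 80.0), 0, 1)
        peaks = []
        for max_dx, dt in ((8.0, 0.2), (4.0, 0.1)):
            model = CompartmentalModel(sac_morph, max_dx=max_dx)
            syns = [SynapseSite(model.nearest_comp(x, y), x, y, 0.0, 0.05)
                    for x, y in pos]
            rec = [RecordingSite(model.nearest_comp(118.0, 0.0), 118.0, 0.0, 1)]
            res = run_visual_trial(model, syns,
                                   np.tile(wave[:, None], (1, 30)), rec, dt=dt)
            peaks.append(res.v.max())
        assert abs(peaks[1] - peaks[0]) / (peaks[1] + 60.0) < 0.01


class TestSynapsePlacement:
    def test_within_max_distance_and_deterministic(self, sac_morph):
        model = CompartmentalModel(sac_morph)
        syns = place_bipolar_synapses(model, n=200, max_dist=110.0, seed=9)
        assert all(s.path_dist <= 110.0 for s in syns)
        again = place_bipolar_synapses(model, n=200, max_dist=110.0, seed=9)
        assert [s.comp for s in syns] == [s.comp for s in again]

    def test_density_proportional_to_length(self, sac_morph):
        from scipy.stats import chisquare
        model = CompartmentalModel(sac_morph)
        syns = place_bipolar_synapses(model, n=10000, seed=5)
        eligible = np.flatnonzero((model.comp_path <= 110.0) &
                                  (model.comp_type != 1))
        # coarse spatial bins by path distance
        bins = np.linspace(0.0, 110.0, 6)
        counts, _ = np.histogram([s.path_dist for s in syns], bins)
        length, _ = np.histogram(model.comp_path[eligible], bins,
                                 weights=model.comp_length[eligible])
        expected = length / length.sum() * counts.sum()
        _, p = chisquare(counts, expected)
        assert p > 1e-3

    def test_error_when_no_eligible_length(self, sac_morph):
        model = CompartmentalModel(sac_morph)
        with pytest.raises(ValueError):
            place_bipolar_synapses(model, n=10, max_dist=0.1)


class TestPerisomaticModification:
    def test_unit_factors_are_identity(self, sac_morph):
        model = CompartmentalModel(sac_morph)
        mod = perisomatic_modification(model, 1.0, 1.0)
        tips = model.tip_comps()
        assert dc_transfer_ratio(mod, int(tips[0]), 0) == pytest.approx(
            dc_transfer_ratio(model, int(tips[0]), 0), rel=1e-12)

    def test_increasing_ra_monotonically_decouples(self, sac_morph):
        model = CompartmentalModel(sac_morph)
        tips = model.tip_comps()
        xs = model.comp_xyz[tips, 0]
        src, dst = int(tips[np.argmax(xs)]), int(tips[np.argmin(xs)])
        ratios = [dc_transfer_ratio(
            perisomatic_modification(model, f, 1.0), src, dst)
            for f in (1.0, 5.0, 25.0, 125.0)]
        assert all(np.diff(ratios) < 0.0)

    def test_rejects_nonpositive_factors(self, sac_morph):
        model = CompartmentalModel(sac_morph)
        with pytest.raises(ValueError):
            perisomatic_modification(model, 0.0, 1.0)
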