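"""Solver correctness against closed forms and an independent ODE oracle,
plus the EPSP measurement protocols."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from glomsim import cablesim as cs
from glomsim.cablesim import (
    MembraneParams,
    SynapseParams,
    conductance_peak_time,
    conductance_waveform,
    input_resistance,
    measure_mepsps,
    measure_uepsp,
    membrane_preset,
    simulate,
    summation_efficacy,
    time_averaged_voltage,
    transfer_resistance,
)
from glomsim.morphology import CableSegment, build_compartmental_model, remesh, space_constant

from conftest import make_chain


class TestWaveform:
    def test_peak_time_closed_form(self):
        assert conductance_peak_time(0.2, 1.1) == pytest.approx(0.417, abs=5e-4)

    def test_normalization_exact_at_peak(self):
        p = SynapseParams()
        tstar = conductance_peak_time(p.tau_rise, p.tau_decay)
        assert conductance_waveform(np.array([0.0]), p)[0] == 0.0
        assert conductance_waveform(np.array([tstar]), p)[0] == pytest.approx(p.g_max, rel=1e-12)

    def test_zero_gmax_identically_zero(self):
        p = SynapseParams(g_max=0.0)
        t = np.linspace(0, 10, 100)
        assert np.all(conductance_waveform(t, p) == 0.0)

    def test_alpha_function_limit_equal_taus(self):
        p = SynapseParams(tau_rise=0.5, tau_decay=0.5)
        t = np.linspace(0, 5, 500)
        g = conductance_waveform(t, p)
        assert g.max() == pytest.approx(p.g_max, rel=1e-3)
        assert t[g.argmax()] == pytest.approx(0.5, abs=0.02)


class TestMembrane:
    def test_preset_cell3_published_values(self):
        m = membrane_preset("cell3")
        assert (m.r_m, m.c_m, m.r_a) == (20.8, 0.8, 266.1)

    def test_unpublished_presets_require_values(self):
        with pytest.raises(ValueError, match="no published values"):
            membrane_preset("cell1")
        m = membrane_preset("cell1", r_m=15.0, c_m=1.0, r_a=200.0)
        assert m.tau_m == pytest.approx(15.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MembraneParams(r_m=-1)
        with pytest.raises(ValueError):
            SynapseParams(tau_rise=1.2, tau_decay=1.1)


class TestSolver:
    def test_no_events_stays_at_rest(self, chain_model, syn):
        tr = simulate(chain_model, [], syn, duration=5.0)
        assert np.allclose(tr.values, chain_model.membrane.e_rest)

    def test_single_compartment_time_constant(self, membrane):
        model = remesh([], membrane, soma_radius=4.0)
        tr = simulate(model, [], SynapseParams(g_max=0.0), duration=200.0, i_inj=(0, 0.01))
        v = tr.values - tr.e_rest
        vinf = v[-1]
        mask = (tr.times > 0) & (v > 0) & (v < 0.95 * vinf)
        tau = -1.0 / np.polyfit(tr.times[mask], np.log(1 - v[mask] / vinf), 1)[0]
        assert tau == pytest.approx(membrane.tau_m, rel=0.01)  # R_m·C_m = 16.64 ms
        # steady state matches the analytic leak resistance
        assert vinf / 0.01 == pytest.approx(input_resistance(model, 0), rel=1e-3)

    def test_dt_convergence_of_peak(self, chain_model, syn):
        comp = chain_model.n_compartments // 2
        peaks = {}
        for dt in (0.025, 0.0125):
            tr = simulate(chain_model, [(comp, 1.0)], syn, duration=30.0, dt=dt)
            peaks[dt] = tr.amplitude()
        assert abs(peaks[0.025] - peaks[0.0125]) / peaks[0.0125] < 0.002

    def test_matches_dense_ode_oracle(self, membrane, syn):
        """Somatic response to one event vs an independent stiff ODE solve."""
        morph = make_chain(20, spacing=10.0, radius=0.5)
        model = build_compartmental_model(morph, membrane)
        assert model.n_compartments <= 50
        comp = model.n_compartments - 1
        tr = simulate(model, [(comp, 0.0)], syn, duration=20.0, dt=0.01)

        cap, g_leak, g_ax = cs._electrical_arrays(model)
        n = model.n_compartments
        A = np.zeros((n, n))
        for i in range(1, n):
            p = model.parent[i]
            A[i, i] -= g_ax[i]
            A[p, p] -= g_ax[i]
            A[i, p] += g_ax[i]
            A[p, i] += g_ax[i]
        e_rest = membrane.e_rest

        def rhs(t, v):
            g = conductance_waveform(np.array([t]), syn)[0] * 1e-3  # nS → µS
            dv = (A @ v - g_leak * (v - e_rest)) / cap
            dv[comp] += g * (syn.e_syn - v[comp]) / cap[comp]
            return dv

        sol = solve_ivp(rhs, (0, 20.0), np.full(n, e_rest), method="LSODA",
                        rtol=1e-8, atol=1e-10, dense_output=True)
        ref_peak = sol.y[model.soma_index].max() - e_rest
        assert tr.amplitude() == pytest.approx(ref_peak, rel=0.005)

    def test_transfer_resistance_reciprocity(self, chain_model):
        i, j = 3, chain_model.n_compartments - 2
        rij = transfer_resistance(chain_model, i, j)
        rji = transfer_resistance(chain_model, j, i)
        assert rij == pytest.approx(rji, rel=1e-3)

    def test_mesh_refinement_changes_uepsp_little(self, membrane, syn):
        from glomsim.synthetic import CircuitSpec, MorphologySpec, generate_morphology

        morph = generate_morphology(MorphologySpec(target_path_length=500.0, seed=5))
        peaks = {}
        for bound in (0.1, 0.05):
            model = build_compartmental_model(morph, membrane, elec_upper=bound)
            comps = model.cable_middle_compartments()[:10]
            tr = simulate(model, [(int(c), 0.0) for c in comps], syn, duration=30.0)
            peaks[bound] = tr.amplitude()
        assert abs(peaks[0.1] - peaks[0.05]) / peaks[0.05] < 0.005


class TestInputResistance:
    def test_rall_sealed_cylinder_coth(self, membrane):
        """R_in at the end of a sealed cable matches R_∞·coth(L/λ)."""
        lam = space_constant(1.0, membrane.r_m, membrane.r_a)
        for L_elec in (0.5, 1.0, 2.0):
            cab = CableSegment(index=0, parent_cable=-1, length=L_elec * lam, diameter=1.0)
            model = remesh([cab], membrane, soma_radius=1e-3, elec_upper=0.01)
            r_in = input_resistance(model, 1)  # proximal end of the cable
            r_inf = (2 / math.pi) * math.sqrt(membrane.r_m * 1e3 * membrane.r_a) * (1e-4) ** -1.5
            rall = r_inf / math.tanh(L_elec) / 1e6
            assert r_in == pytest.approx(rall, rel=0.01)

    def test_decreases_with_diameter(self, membrane):
        vals = []
        for d in (0.5, 1.0, 2.0):
            cab = CableSegment(index=0, parent_cable=-1, length=200.0, diameter=d)
            model = remesh([cab], membrane, soma_radius=1e-3)
            vals.append(input_resistance(model, 1))
        assert vals[0] > vals[1] > vals[2]

    def test_distal_tip_exceeds_mid_cable(self, chain_model):
        mid = chain_model.n_compartments // 2
        tip = chain_model.n_compartments - 1
        assert input_resistance(chain_model, tip) >= input_resistance(chain_model, mid)


class TestEPSPProtocols:
    def test_somatic_synapse_attenuation_is_one(self, chain_model, syn):
        df = measure_mepsps(chain_model, [chain_model.soma_index], syn)
        assert df["attenuation"].iloc[0] == pytest.approx(1.0)
        assert df["somatic_mv"].iloc[0] > 0

    def test_somatic_amplitude_decreases_distally(self, chain_model, syn):
        comps = list(range(1, chain_model.n_compartments, 8))
        df = measure_mepsps(chain_model, comps, syn)
        som = df.sort_values("compartment")["somatic_mv"].values
        assert (np.diff(som) <= 1e-9).all()
        # and attenuation weakens with distance as well
        att = df.sort_values("compartment")["attenuation"].values
        assert att[-1] < att[0] <= 1.0

    def test_single_synapse_uepsp_equals_mepsp(self, chain_model, syn):
        comp = chain_model.n_compartments // 2
        u = measure_uepsp(chain_model, [comp], syn)
        m = measure_mepsps(chain_model, [comp], syn)["somatic_mv"].iloc[0]
        assert u == pytest.approx(m, rel=1e-9)

    def test_uepsp_sublinear(self, chain_model, syn):
        n = chain_model.n_compartments
        comps = list(np.linspace(1, n - 1, 8).astype(int))
        u = measure_uepsp(chain_model, comps, syn)
        lin = measure_mepsps(chain_model, comps, syn)["somatic_mv"].sum()
        assert 0 < u < lin

    def test_efficacy_single_site_is_one(self, chain_model, syn):
        assert summation_efficacy(chain_model, [10], syn) == pytest.approx(1.0, rel=1e-9)

    def test_efficacy_linear_limit_small_conductance(self, chain_model, small_bundle):
        """Efficacy approaches 1 as g→0.

        For co-located synapses the limit is exact; for spatially spread
        synapses a small residual (<3% here) remains because somatic mEPSP
        peaks occur at slightly different times, so the peak of the sum is
        below the sum of the peaks even under perfect linear superposition.
        """
        weak = SynapseParams(g_max=1e-3)
        co = [chain_model.n_compartments // 2] * 8
        assert summation_efficacy(chain_model, co, weak) == pytest.approx(1.0, abs=0.01)
        pn = "PN_L1"
        model, sites = small_bundle.models[pn], small_bundle.sites[pn]
        orn = sorted({s.orn_id for s in sites})[0]
        ss = [s for s in sites if s.orn_id == orn]
        eff_weak = summation_efficacy(model, ss, weak)
        eff_strong = summation_efficacy(model, ss, SynapseParams())
        assert eff_strong < eff_weak <= 1.0
        assert eff_weak == pytest.approx(1.0, abs=0.03)

    def test_colocated_less_efficient_than_dispersed(self, small_bundle, syn):
        """Piling a connection's synapses onto one compartment saturates the
        local driving force, so efficacy drops below the dispersed layout."""
        pn = "PN_L1"
        model, sites = small_bundle.models[pn], small_bundle.sites[pn]
        orn = max(
            {s.orn_id for s in sites},
            key=lambda o: sum(s.orn_id == o for s in sites),
        )
        ss = [s for s in sites if s.orn_id == orn]
        mid = ss[len(ss) // 2].compartment_index
        co = [mid] * len(ss)
        assert summation_efficacy(model, co, syn) < summation_efficacy(model, ss, syn)

    def test_uepsp_calibration_about_five_millivolts(self, small_bundle, syn):
        """Default synthetic PNs produce unitary EPSPs of realistic (~5 mV) size."""
        from glomsim.synthetic import CircuitSpec, MorphologySpec, make_bundle

        bundle = make_bundle(seed=0)  # default 2000 µm morphology spec
        pn = "PN_L1"
        model, sites = bundle.models[pn], bundle.sites[pn]
        side = bundle.table.pn_side[pn]
        ipsi = {o for o in bundle.table.orns_on(side)}
        vals = []
        for orn in sorted({s.orn_id for s in sites if s.orn_id in ipsi}):
            ss = [s for s in sites if s.orn_id == orn]
            vals.append(measure_uepsp(model, ss, syn))
        assert np.mean(vals) == pytest.approx(5.0, rel=0.30)


class TestTimeAveragedVoltage:
    def _trace(self, values):
        v = np.asarray(values, dtype=float)
        return cs.VoltageTrace(np.arange(len(v), dtype=float), v, e_rest=-60.0)

    def test_constant_at_rest_is_zero(self):
        tr = self._trace(np.full(11, -60.0))
        assert time_averaged_voltage(tr, (0, 10)) == 0.0

    def test_rectangular_half_window(self):
        v = np.full(10, -60.0)
        v[5:] = -59.0
        tr = self._trace(v)
        assert time_averaged_voltage(tr, (0, 9)) == pytest.approx(0.5)

    def test_lengthweighted_additivity(self):
        rng = np.random.default_rng(0)
        tr = self._trace(-60 + rng.uniform(0, 2, 21))
        a = time_averaged_voltage(tr, (0, 9))
        b = time_averaged_voltage(tr, (10, 20))
        whole = time_averaged_voltage(tr, (0, 20))
        assert whole == pytest.approx((10 * a + 11 * b) / 21, rel=1e-9)

    def test_empty_window_rejected(self):
        tr = self._trace(np.full(5, -60.0))
        with pytest.raises(ValueError):
            time_averaged_voltage(tr, (100, 200))


class TestRobustnessToMembraneFit:
    def test_ipsi_contra_uepsp_sign_stable_across_fits(self, small_bundle):
        """The ipsilateral uEPSP surplus survives sizeable membrane-parameter changes."""
        table = small_bundle.table
        pn = "PN_R1"
        sites = small_bundle.sites[pn]
        morph = small_bundle.morphologies[pn]
        side = table.pn_side[pn]
        variants = [
            MembraneParams(),
            MembraneParams(r_m=20.8 * 0.7, c_m=0.8, r_a=266.1 * 1.2),
            MembraneParams(r_m=20.8 * 1.3, c_m=0.8, r_a=266.1 * 0.8),
        ]
        syn = SynapseParams()
        for mem in variants:
            model = build_compartmental_model(morph, mem)
            ipsi_vals, contra_vals = [], []
            for orn in sorted({s.orn_id for s in sites}):
                ss = [s for s in sites if s.orn_id == orn]
                # rebind compartments for this mesh via cable/offset
                ev = [(model.locate(s.cable_index, s.offset), 0.0) for s in ss]
                tr = simulate(model, ev, syn, duration=40.0)
                amp = tr.amplitude()
                (ipsi_vals if table.orn_side[orn] == side else contra_vals).append(amp)
            assert np.mean(ipsi_vals) > np.mean(contra_vals)
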