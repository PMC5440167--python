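"""Generators: morphology growth, circuit statistics, synapse placement, sizes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glomsim import connectivity as cn
from glomsim.cablesim import MembraneParams
from glomsim.morphology import build_compartmental_model, total_path_length
from glomsim.synthetic import (
    CircuitSpec,
    MorphologySpec,
    generate_circuit,
    generate_morphology,
    generate_synapse_sizes,
    make_bundle,
    place_synapses,
)

from conftest import make_y_tree


class TestMorphologyGenerator:
    def test_total_length_within_five_percent(self):
        m = generate_morphology(MorphologySpec(target_path_length=1000.0, seed=1))
        assert 950.0 <= total_path_length(m) <= 1050.0

    def test_deterministic_given_seed(self):
        spec = MorphologySpec(target_path_length=1000.0, seed=1)
        a, b = generate_morphology(spec), generate_morphology(spec)
        np.testing.assert_array_equal(a.parents, b.parents)
        np.testing.assert_allclose(a.xyz, b.xyz)
        np.testing.assert_allclose(a.radius, b.radius)

    def test_zero_branch_rate_gives_unbranched_cable(self):
        m = generate_morphology(MorphologySpec(target_path_length=1000.0, branch_rate=0.0, seed=2))
        kids = m.children()
        assert max(len(k) for k in kids) == 1
        assert total_path_length(m) == pytest.approx(1000.0, rel=0.05)

    def test_radii_non_increasing_along_paths(self):
        m = generate_morphology(MorphologySpec(target_path_length=1500.0, seed=3))
        for i in range(1, m.n_nodes):
            p = m.parents[i]
            if m.labels[p] != 1:  # skip soma→neurite transition
                assert m.radius[i] <= m.radius[p] + 1e-12

    def test_unreachable_target_raises(self):
        spec = MorphologySpec(
            target_path_length=50_000.0,
            branch_rate=0.5,
            radius_root=0.08,
            radius_taper=0.5,
            seed=4,
        )
        with pytest.raises(RuntimeError, match="unreachable"):
            generate_morphology(spec)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_length_property_across_seeds(self, seed):
        m = generate_morphology(MorphologySpec(target_path_length=400.0, seed=seed))
        assert total_path_length(m) == pytest.approx(400.0, rel=0.05)


class TestCircuitGenerator:
    def test_default_layout_matches_reconstruction_shape(self):
        t = generate_circuit(CircuitSpec(seed=7))
        assert t.counts.shape == (53, 5)
        # 265 cells minus the unilateral axons' far-side cells (2 + 3)
        assert (t.counts.values > 0).sum() == 260
        assert (~t.orn_bilateral).sum() == 2

    def test_degenerate_homogeneous_circuit(self):
        spec = CircuitSpec(
            ipsi_contra_ratio=1.0,
            side_factor_sd=0.0,
            connection_cv=0.0,
            unilateral_orns_per_side=0,
            pn_size_factors=(1.0,) * 5,
            seed=1,
        )
        t = generate_circuit(spec)
        assert t.counts.values.min() == t.counts.values.max()

    def test_infeasible_cv_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_circuit(CircuitSpec(connection_cv=0.05, side_factor_sd=0.3))

    def test_unilateral_orns_home_side_only(self):
        t = generate_circuit(CircuitSpec(seed=3))
        for orn in t.counts.index:
            if not t.orn_bilateral[orn]:
                contra = [p for p in t.counts.columns if t.pn_side[p] != t.orn_side[orn]]
                assert t.counts.loc[orn, contra].sum() == 0
                ipsi = [p for p in t.counts.columns if t.pn_side[p] == t.orn_side[orn]]
                assert (t.counts.loc[orn, ipsi] > 0).all()

    def test_ipsi_contra_ratio_calibration_monte_carlo(self):
        ratios = []
        for seed in range(200):
            t = generate_circuit(CircuitSpec(seed=seed))
            ic = cn.ipsi_contra_comparison(t)
            ratios.append(ic["grand_mean_ipsi"] / ic["grand_mean_contra"])
        assert np.mean(ratios) == pytest.approx(1.35, rel=0.03)

    def test_determinism(self):
        a = generate_circuit(CircuitSpec(seed=9))
        b = generate_circuit(CircuitSpec(seed=9))
        assert a.counts.equals(b.counts)


class TestPlaceSynapses:
    @pytest.fixture(scope="class")
    def fork_model(self):
        """Two-branch tree with 300/700 µm arms for occupancy checks."""
        import numpy as np

        from glomsim.morphology import SWC_DENDRITE, SWC_SOMA, Morphology

        rows = [(0.0, 0.0, 0.0, 4.0, -1, SWC_SOMA)]
        # branch A along +x: 300 µm in 30 nodes; branch B along +y: 700 µm in 70
        parent_a = 0
        for k in range(1, 31):
            rows.append((k * 10.0, 0.0, 0.0, 0.5, parent_a, SWC_DENDRITE))
            parent_a = len(rows) - 1
        parent_b = 0
        for k in range(1, 71):
            rows.append((0.0, k * 10.0, 0.0, 0.5, parent_b, SWC_DENDRITE))
            parent_b = len(rows) - 1
        morph = Morphology(
            ids=np.arange(1, len(rows) + 1),
            parents=np.array([r[4] for r in rows]),
            xyz=np.array([[r[0], r[1], r[2]] for r in rows]),
            radius=np.array([r[3] for r in rows]),
            labels=np.array([r[5] for r in rows]),
        )
        return build_compartmental_model(morph, MembraneParams())

    def _one_orn_table(self, count):
        import pandas as pd

        from glomsim.connectivity import ConnectivityTable

        return ConnectivityTable(
            pd.DataFrame({"PN_L1": [count]}, index=["ORN_L01"]),
            pd.Series({"ORN_L01": "L"}),
            pd.Series({"PN_L1": "L"}),
        )

    def test_exact_site_count(self, fork_model):
        sites = place_synapses(fork_model, self._one_orn_table(10), "PN_L1", seed=0)
        assert len(sites) == 10
        assert all(s.compartment_index > 0 for s in sites)  # on the dendrite, not soma

    def test_branch_occupancy_proportional_to_length(self, fork_model):
        sites = place_synapses(fork_model, self._one_orn_table(10_000), "PN_L1", seed=1)
        # branch A is cable 0 (300 µm), branch B cable 1 (700 µm)
        lengths = {c.index: c.length for c in fork_model.cables}
        short = min(lengths, key=lengths.get)
        frac_short = np.mean([s.cable_index == short for s in sites])
        assert frac_short == pytest.approx(0.3, abs=0.02)

    def test_deterministic(self, fork_model):
        t = self._one_orn_table(50)
        a = place_synapses(fork_model, t, "PN_L1", seed=5)
        b = place_synapses(fork_model, t, "PN_L1", seed=5)
        assert [(s.compartment_index, s.offset) for s in a] == [
            (s.compartment_index, s.offset) for s in b
        ]

    def test_missing_pn_raises(self, fork_model):
        with pytest.raises(KeyError):
            place_synapses(fork_model, self._one_orn_table(5), "PN_R9", seed=0)


class TestSynapseSizes:
    def test_per_connection_mean_cv_follows_averaging_law(self):
        geom = generate_synapse_sizes(400, 25, seed=0, cv=0.5)
        stats = cn.synapse_size_stats(geom)
        assert stats["cv_tbar_volume"] == pytest.approx(0.5, rel=0.1)
        # means over 25 synapses shrink the CV toward 0.5/√25 = 0.1
        assert stats["cv_mean_tbar_volume"] == pytest.approx(0.1, rel=0.2)

    def test_zero_cv_identical_sizes(self):
        geom = generate_synapse_sizes(5, 4, seed=1, cv=0.0)
        assert geom["tbar_volume_nm3"].nunique() == 1
        assert geom["contact_area_nm2"].nunique() == 1

    def test_uncorrelated_when_rho_zero(self):
        geom = generate_synapse_sizes(100, 10, seed=2, cv=0.5, rho=0.0)
        stats = cn.synapse_size_stats(geom)
        assert abs(stats["r_volume_area"]) < 0.1

    def test_positive_volume_area_correlation_by_default(self):
        geom = generate_synapse_sizes(100, 10, seed=3)
        assert cn.synapse_size_stats(geom)["r_volume_area"] > 0.3

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            generate_synapse_sizes(10, 10, cv=-0.1)


class TestBundle:
    def test_bundle_consistency(self, small_bundle):
        b = small_bundle
        assert set(b.models) == set(b.table.counts.columns)
        for pn, sites in b.sites.items():
            col = b.table.counts[pn]
            counts = {}
            for s in sites:
                counts[s.orn_id] = counts.get(s.orn_id, 0) + 1
            for orn, c in col.items():
                assert counts.get(orn, 0) == c
            n = b.models[pn].n_compartments
            assert all(0 <= s.compartment_index < n for s in sites)

    def test_side_with_fewer_pns_has_larger_dendrites(self, small_bundle):
        pl = small_bundle.path_lengths()
        left = np.mean([v for p, v in pl.items() if "L" in p])
        right = np.mean([v for p, v in pl.items() if "R" in p])
        assert right > left
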