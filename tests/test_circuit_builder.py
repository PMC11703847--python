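"""Network specification, validation, seeded instantiation and input sums."""

from dataclasses import replace

import numpy as np
import pytest

import fearsim as fs
from fearsim import (
    ConnectionSpec,
    HormoneState,
    NetworkSpec,
    RegionSpec,
    build_network,
    init_weights,
    region_input,
    validate_spec,
)
from fearsim.errors import ConfigError


def micro_spec(**kwargs):
    """Three-region toy circuit with deterministic weights."""
    defaults = replace(fs.NeuronParams(), noise_sd=0.0)
    regions = (
        RegionSpec(name="A", n_neurons=2),
        RegionSpec(name="B", n_neurons=2),
        RegionSpec(name="C", n_neurons=2),
    )
    connections = (
        ConnectionSpec("A", "B", 1, 1.0, weight_sd=0.0),
        ConnectionSpec("B", "C", 1, 2.0, weight_sd=0.0),
        ConnectionSpec("A", "C", -1, 0.5, weight_sd=0.0),
    )
    base = dict(
        name="micro", regions=regions, connections=connections, defaults=defaults
    )
    base.update(kwargs)
    return NetworkSpec(**base)


class TestValidation:
    def test_packaged_default_spec_has_no_errors(self, full_spec):
        assert validate_spec(full_spec).ok

    def test_connection_to_undeclared_region_is_named(self):
        spec = micro_spec(
            connections=(ConnectionSpec("A", "XYZ", 1, 1.0),)
        )
        report = validate_spec(spec)
        assert not report.ok
        assert any("XYZ" in e for e in report.errors)

    def test_duplicate_connection_rejected(self):
        spec = micro_spec(
            connections=(
                ConnectionSpec("A", "B", 1, 1.0),
                ConnectionSpec("A", "B", 1, 2.0),
            )
        )
        assert not validate_spec(spec).ok

    def test_sign_conflict_with_template_warns(self, full_spec):
        flipped = tuple(
            replace(c, sign=-c.sign) if c.key == ("US", "LA") else c
            for c in full_spec.connections
        )
        report = validate_spec(replace(full_spec, connections=flipped))
        assert any("US->LA" in w for w in report.warnings)

    def test_k_exceeding_population_rejected(self):
        spec = micro_spec(
            regions=(
                RegionSpec(name="A", n_neurons=2, k=5),
                RegionSpec(name="B", n_neurons=2),
                RegionSpec(name="C", n_neurons=2),
            )
        )
        assert not validate_spec(spec).ok


class TestDefaultArchitecture:
    def test_region_sizes_match_the_published_circuit(self, full_spec):
        sizes = {r.name: r.n_neurons for r in full_spec.regions}
        assert sizes["DG"] == 500
        assert sizes["CeM"] == 2
        assert sizes["EC_II"] == 50
        assert sizes["BA_F"] == 80
        assert sum(sizes.values()) == 1112

    def test_shock_projection_weight_mean(self, full_spec):
        conn = {c.key: c for c in full_spec.connections}[("US", "LA")]
        assert conn.weight_mean == pytest.approx(1.52)

    def test_every_region_receives_at_least_one_input(self, full_spec):
        targets = {c.target for c in full_spec.connections}
        assert targets == set(full_spec.region_names)

    def test_input_terms_are_unique_per_region(self, full_spec):
        keys = [c.key for c in full_spec.connections]
        assert len(keys) == len(set(keys))


class TestInitWeights:
    def test_zero_sd_gives_exact_mean(self, rng):
        conn = ConnectionSpec("A", "B", 1, 1.2, weight_sd=0.0)
        w = init_weights(conn, 5, 4, rng)
        assert np.all(w == 1.2)

    def test_sample_mean_within_three_standard_errors(self):
        conn = ConnectionSpec("A", "B", 1, 1.2, weight_sd=0.3)
        w = init_weights(conn, 500, 50, np.random.default_rng(0))
        se = 0.3 / np.sqrt(w.size)
        assert abs(w.mean() - 1.2) < 3 * se

    def test_same_seed_gives_identical_matrices(self):
        conn = ConnectionSpec("A", "B", 1, 1.0, weight_sd=0.3, connectivity=0.6)
        w1 = init_weights(conn, 20, 10, np.random.default_rng(42))
        w2 = init_weights(conn, 20, 10, np.random.default_rng(42))
        assert np.array_equal(w1, w2)

    def test_connectivity_masks_the_expected_fraction(self):
        conn = ConnectionSpec("A", "B", 1, 1.0, weight_sd=0.0, connectivity=0.5)
        w = init_weights(conn, 100, 100, np.random.default_rng(1))
        wired = (w > 0).mean()
        assert 0.45 < wired < 0.55


class TestBuildNetwork:
    def test_quarter_scale_populations(self, quarter_spec):
        net = build_network(quarter_spec, 1)
        assert net.sizes["DG"] == 125
        assert net.sizes["CeM"] == 2

    def test_build_is_reproducible(self, quarter_spec):
        h1 = build_network(quarter_spec, 9).state_hash()
        h2 = build_network(quarter_spec, 9).state_hash()
        assert h1 == h2
        assert h1 != build_network(quarter_spec, 10).state_hash()

    def test_plastic_weights_respect_dynamic_range(self, quarter_spec):
        net = build_network(quarter_spec, 3)
        for c in quarter_spec.connections:
            if c.plastic:
                eff = net.stdp_for(c)
                w = net.weights[c.key]
                assert w.min() >= eff.w_min and w.max() <= eff.w_max

    def test_shock_depth_zero_for_sensory_targets(self, quarter_spec):
        net = build_network(quarter_spec, 1)
        depths = net.layer_depths("US")
        assert depths["LA"] == 0
        assert depths["LA_CCK"] == 0
        assert depths["BA_F"] >= 1


class TestRegionInput:
    def test_silent_network_gives_zero_current(self):
        net = build_network(micro_spec(), 0)
        out = region_input("C", net, {}, HormoneState())
        assert np.allclose(out, 0.0)

    def test_hand_computed_signed_sum(self):
        net = build_network(micro_spec(), 0)
        # both A and B neurons spiked last step
        net.states["A"].spiked[:] = True
        net.states["B"].spiked[:] = True
        p = net.params["C"]
        v = net.states["C"].v  # at rest
        out = region_input("C", net, {}, HormoneState())
        g_exc = 2.0 * 2 / 2  # B->C: two active, mean weight 2, norm 2
        g_inh = 0.5 * 2 / 2  # A->C inhibitory
        expected = (
            g_exc * (p.exc_reversal - v) + g_inh * (p.inh_reversal - v)
        ) * p.leak_conductance
        assert np.allclose(out, expected)

    def test_inhibitory_only_drive_is_non_positive(self, quarter_spec):
        net = build_network(quarter_spec, 1)
        net.states["CeL_OFF"].spiked[:] = True
        out = region_input("CeM", net, {}, HormoneState())
        assert np.all(out <= 0.0)

    def test_unknown_region_raises(self):
        net = build_network(micro_spec(), 0)
        with pytest.raises(ConfigError):
            region_input("nope", net, {}, HormoneState())

    def test_locus_coeruleus_drive_scales_with_norepinephrine(self, quarter_spec):
        net = build_network(quarter_spec, 1)
        calm = region_input("PL", net, {"LC": 1.0}, HormoneState())
        stressed = region_input(
            "PL", net, {"LC": 1.0}, HormoneState(beta_ne=1.0)
        )
        assert np.all(stressed >= calm)
        assert stressed.sum() == pytest.approx(2 * calm.sum())
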