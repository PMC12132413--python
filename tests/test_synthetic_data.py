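"""Thermodynamic expression model and count/read simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regfoot import (DesignConfig, EnergyMatrix, RegArchitecture, RegSite,
                     expression_rate, mutate_variants, simulate_counts,
                     simulate_reads, site_energy)
from regfoot.coords import label_to_index
from regfoot.synthetic_data import (architecture_from_json,
                                    architecture_to_json, barcode_map_frame,
                                    repressor_architecture)
from regfoot.thermo import mismatch_matrix
from tests.conftest import make_dataset, random_region


def _rnap_only(p_weight=0.1, L=20):
    site = RegSite(name="rnap", kind="rnap", start=0, end=L,
                   matrix=EnergyMatrix(np.zeros((4, L))), weight=p_weight)
    return RegArchitecture(promoter_id="p", sites=[site])


class TestSiteEnergy:
    def test_zero_matrix_returns_reference_energy(self):
        site = RegSite(name="s", kind="rnap", start=0, end=6,
                       matrix=EnergyMatrix(np.zeros((4, 6)), reference_energy=2.5))
        assert site_energy("ACGTAC", site) == pytest.approx(2.5)

    def test_mismatch_counting(self):
        site = RegSite(name="s", kind="rnap", start=0, end=6,
                       matrix=mismatch_matrix("ACGTAC", 1.0))
        assert site_energy("ACGTAC", site) == pytest.approx(0.0)
        assert site_energy("TCGTAG", site) == pytest.approx(2.0)  # 2 mismatches

    def test_single_mutation_additivity(self):
        rng = np.random.default_rng(0)
        eps = rng.normal(size=(4, 8))
        site = RegSite(name="s", kind="rnap", start=0, end=8,
                       matrix=EnergyMatrix(eps))
        seq = "ACGTACGT"
        mutant = "AGGTACGT"  # C->G at position 1
        delta = site_energy(mutant, site) - site_energy(seq, site)
        assert delta == pytest.approx(eps[2, 1] - eps[1, 1])

    def test_window_shorter_than_site_errors(self):
        site = RegSite(name="s", kind="rnap", start=0, end=6,
                       matrix=EnergyMatrix(np.zeros((4, 6))))
        with pytest.raises(ValueError):
            site_energy("ACG", site)


class TestExpressionRate:
    def test_bare_promoter_closed_form(self):
        # p = 0.1 -> p_bound = 0.1 / 1.1
        arch = _rnap_only(0.1)
        assert expression_rate("A" * 20, arch, "c") == pytest.approx(0.1 / 1.1)

    def test_single_repressor_closed_form_and_fold_change(self):
        rep = RegSite(name="r", kind="repressor", start=0, end=20,
                      matrix=EnergyMatrix(np.zeros((4, 20))), weight=9.0)
        arch = RegArchitecture("p", [_rnap_only(0.1).sites[0], rep],
                               {"c": {"r": 1.0}, "off": {"r": 0.0}})
        on = expression_rate("A" * 20, arch, "c")
        off = expression_rate("A" * 20, arch, "off")
        assert on == pytest.approx(0.1 / 10.1)
        assert on / off == pytest.approx(1.1 / 10.1)

    def test_inactive_repressor_equals_no_repressor(self):
        rep = RegSite(name="r", kind="repressor", start=0, end=20,
                      matrix=EnergyMatrix(np.zeros((4, 20))), weight=5.0)
        arch = RegArchitecture("p", [_rnap_only(0.2).sites[0], rep],
                               {"off": {"r": 0.0}})
        assert expression_rate("A" * 20, arch, "off") == pytest.approx(
            expression_rate("A" * 20, _rnap_only(0.2), "any"))

    @given(w=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_p_bound_decreases_with_repressor_weight(self, w):
        def rate(weight):
            rep = RegSite(name="r", kind="repressor", start=0, end=20,
                          matrix=EnergyMatrix(np.zeros((4, 20))), weight=weight)
            arch = RegArchitecture("p", [_rnap_only(0.3).sites[0], rep])
            return expression_rate("A" * 20, arch, "c")
        assert rate(w * 1.5) < rate(w)

    @given(omega=st.floats(1.0, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_p_bound_increases_with_activator_omega(self, omega):
        def rate(om):
            act = RegSite(name="a", kind="activator", start=0, end=20,
                          matrix=EnergyMatrix(np.zeros((4, 20))), weight=1.0,
                          interaction_omega=om)
            arch = RegArchitecture("p", [_rnap_only(0.05).sites[0], act])
            return expression_rate("A" * 20, arch, "c")
        assert rate(omega * 1.5 + 0.1) > rate(omega)

    def test_all_tf_activities_zero_reduces_to_rnap_only(self):
        rng = np.random.default_rng(1)
        region = random_region(55)
        lib = mutate_variants(region, DesignConfig(n_variants=20, rng_seed=3))
        arch = repressor_architecture(lib, rng, active_conditions=[],
                                      inactive_conditions=["off"])
        bare = RegArchitecture("p", [arch.rnap])
        for seq in lib.sequences[:10]:
            assert expression_rate(seq, arch, "off") == pytest.approx(
                expression_rate(seq, bare, "any"))


class TestSimulateCounts:
    def test_dna_counts_conserve_depth(self, small_library):
        _, lib, bmap = small_library
        rng = np.random.default_rng(0)
        arch = repressor_architecture(lib, rng, ["A"])
        table = simulate_counts(lib, bmap, arch, ["A"], depth_dna=5000,
                                depth_rna=3000, seed=1, n_replicates=2)
        sums = table.groupby(["condition", "replicate"])[
            ["dna_count", "rna_count"]].sum()
        assert (sums["dna_count"] == 5000).all()
        assert (sums["rna_count"] == 3000).all()

    def test_same_seed_identical_table(self, small_library):
        _, lib, bmap = small_library
        rng = np.random.default_rng(0)
        arch = repressor_architecture(lib, rng, ["A"])
        a = simulate_counts(lib, bmap, arch, ["A"], 1000, 1000, seed=9)
        b = simulate_counts(lib, bmap, arch, ["A"], 1000, 1000, seed=9)
        assert a.equals(b)

    def test_flat_expression_gives_uniform_rna_dna_ratio(self):
        data = make_dataset(61, architecture="null", conditions=("A",),
                            depth=10 ** 6, n_variants=200)
        vc = data["variant_counts"]
        ratio = (vc["rna_count"] + 0.5) / (vc["dna_count"] + 0.5)
        # no sequence dependence: spread is pure counting noise
        assert ratio.std() / ratio.mean() < 0.2

    def test_repressor_effect_is_condition_specific(self):
        """Mutating a repressor site raises expression only where the
        repressor is active."""
        seed = 62
        rng = np.random.default_rng(seed)
        region = random_region(seed)
        lib = mutate_variants(region, DesignConfig(rng_seed=seed), rng=rng)
        from regfoot import assign_barcodes, draw_barcode_counts
        from regfoot.barcode_pipeline import aggregate_variant_counts
        cfg = DesignConfig(rng_seed=seed)
        bmap = barcode_map_frame(assign_barcodes(
            lib, draw_barcode_counts(len(lib), 3, rng), cfg, rng=rng))
        arch = repressor_architecture(lib, rng, ["A"], ["B"])
        counts = simulate_counts(lib, bmap, arch, ["A", "B"], 10 ** 6, 10 ** 6,
                                 seed=seed)
        vc = aggregate_variant_counts(counts, bmap)
        rep = arch.sites[1]
        hit = lib.masks[:, rep.start:rep.end].any(axis=1)
        hit_ids = {v for v, h in zip(lib.variant_ids, hit) if h}
        ratios = {}
        for cond in ("A", "B"):
            grp = vc[(vc["condition"] == cond) & (vc["replicate"] == 1)]
            rho = (grp["rna_count"] + 0.5) / (grp["dna_count"] + 0.5)
            is_hit = grp["variant_id"].isin(hit_ids)
            ratios[cond] = rho[is_hit].mean() / rho[~is_hit].mean()
        assert ratios["A"] > 1.5          # relief of repression
        assert ratios["B"] == pytest.approx(1.0, abs=0.1)

    def test_zero_depth_rejected(self, small_library):
        _, lib, bmap = small_library
        arch = repressor_architecture(lib, np.random.default_rng(0), ["A"])
        with pytest.raises(ValueError):
            simulate_counts(lib, bmap, arch, ["A"], 0, 100, seed=1)


class TestSimulateReads:
    def test_error_free_reads_match_designs(self, small_library):
        _, lib, bmap = small_library
        reads = simulate_reads(lib, bmap, n_reads=200, error_rate=0.0, seed=3)
        designed = dict(zip(bmap["barcode"], bmap["variant_id"]))
        seq_of = dict(zip(lib.variant_ids, lib.sequences))
        for r in reads.itertuples():
            assert r.variant_read == seq_of[designed[r.barcode_read]]

    def test_mean_mismatches_matches_binomial_mean(self, small_library):
        _, lib, bmap = small_library
        reads = simulate_reads(lib, bmap, n_reads=2000, error_rate=0.01, seed=4)
        seq_of = dict(zip(lib.variant_ids, lib.sequences))
        # compare each read against the designed sequence of its true variant;
        # barcode-side errors make a few lookups fail -- skip those
        designed = dict(zip(bmap["barcode"], bmap["variant_id"]))
        mismatches = [sum(a != b for a, b in zip(r.variant_read,
                                                 seq_of[designed[r.barcode_read]]))
                      for r in reads.itertuples() if r.barcode_read in designed]
        assert np.mean(mismatches) == pytest.approx(1.6, rel=0.15)

    def test_zero_reads_empty_output(self, small_library):
        _, lib, bmap = small_library
        reads = simulate_reads(lib, bmap, n_reads=0, error_rate=0.0, seed=5)
        assert reads.empty


def test_architecture_json_round_trip(small_library):
    _, lib, _ = small_library
    rng = np.random.default_rng(2)
    arch = repressor_architecture(lib, rng, ["A"], ["B"])
    restored = architecture_from_json(architecture_to_json(arch))
    assert restored.promoter_id == arch.promoter_id
    assert restored.condition_activity == arch.condition_activity
    for a, b in zip(arch.sites, restored.sites):
        assert a.name == b.name and a.kind == b.kind
        np.testing.assert_allclose(a.matrix.epsilon, b.matrix.epsilon)
    seq = lib.sequences[5]
    assert expression_rate(seq, restored, "A") == pytest.approx(
        expression_rate(seq, arch, "A"))
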