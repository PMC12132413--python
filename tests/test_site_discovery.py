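"""Footprint classification, HMM segmentation and emergent-TSS detection."""

import itertools

import numpy as np
import pytest

from regfoot import (ClassifierConfig, call_sites, classify_footprint,
                     expression_shift_matrix, fit_two_state_hmm,
                     information_footprint, jaccard, scan_minus10_creations)
from regfoot.footprint_stats import Footprint, smooth_footprint
from regfoot.site_discovery import (ACTIVE, EMERGENT, INACTIVE, EmergentTss,
                                    detect_emergent_tss, forward_backward,
                                    minus10_completing_events, transform_mi)
from tests.conftest import make_dataset


def _fp(mi):
    mi = np.asarray(mi, float)
    return Footprint("p", "c", 1, mi, np.ones(mi.size))


class TestClassification:
    def test_iid_noise_is_inactive(self):
        rng = np.random.default_rng(0)
        fp = _fp(np.abs(rng.normal(0, 1e-5, 160)))  # null-level MI
        assert classify_footprint(fp) == INACTIVE

    def test_block_of_high_mi_is_active(self):
        mi = np.full(160, 1e-5)
        mi[60:70] = 0.05
        assert classify_footprint(_fp(mi)) == ACTIVE

    def test_single_spike_is_emergent_tss_candidate(self):
        mi = np.full(160, 1e-5)
        mi[90] = 0.3
        assert classify_footprint(_fp(mi)) == EMERGENT

    def test_zero_footprint_is_inactive(self):
        assert classify_footprint(_fp(np.zeros(160))) == INACTIVE

    def test_spike_block_decision_is_scale_invariant(self):
        """Above the activity gate, rescaling never flips spike vs block."""
        block = np.full(160, 1e-5)
        block[60:70] = 0.05
        spike = np.full(160, 1e-5)
        spike[90] = 0.3
        for k in (1.0, 3.0, 10.0, 100.0):
            assert classify_footprint(_fp(block * k)) == ACTIVE
            assert classify_footprint(_fp(spike * k)) == EMERGENT


class TestTwoStateHMM:
    def _two_population_fp(self, seed=0):
        rng = np.random.default_rng(seed)
        mi = np.exp(rng.normal(-12.0, 0.8, 160))
        for s, e in ((30, 55), (90, 130)):
            mi[s:e] = np.exp(rng.normal(-3.0, 0.5, e - s))
        return _fp(mi), (-12.0, -3.0)

    def test_emission_means_recover_populations(self):
        fp, (lo, hi) = self._two_population_fp()
        hmm = fit_two_state_hmm(fp)
        assert not hmm.fallback
        assert hmm.means[0] == pytest.approx(lo, rel=0.1)
        assert hmm.means[1] == pytest.approx(hi, rel=0.1)

    def test_constant_footprint_takes_fallback_path(self):
        hmm = fit_two_state_hmm(_fp(np.full(160, 0.01)))
        assert hmm.fallback

    def test_loglik_nondecreasing_over_em_iterations(self):
        fp, _ = self._two_population_fp(3)
        hmm = fit_two_state_hmm(fp)
        ll = np.array(hmm.log_likelihoods)
        assert len(ll) >= 2
        deltas = np.diff(ll)
        assert (deltas >= -1e-6 * np.abs(ll[:-1])).all()

    def test_posterior_equals_exhaustive_path_enumeration(self):
        """Forward-backward marginals match summing over all 2^L paths."""
        rng = np.random.default_rng(1)
        L = 10
        x = rng.normal(0, 2, L)
        pi = np.array([0.7, 0.3])
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        means = np.array([-1.0, 1.5])
        var = np.array([0.5, 1.2])

        def emis(s, t):
            return (np.exp(-(x[t] - means[s]) ** 2 / (2 * var[s]))
                    / np.sqrt(2 * np.pi * var[s]))

        post = np.zeros((L, 2))
        for path in itertools.product((0, 1), repeat=L):
            w = pi[path[0]] * emis(path[0], 0)
            for t in range(1, L):
                w *= A[path[t - 1], path[t]] * emis(path[t], t)
            for t in range(L):
                post[t, path[t]] += w
        post /= post.sum(axis=1, keepdims=True)

        logB = np.stack([np.log([emis(0, t), emis(1, t)]) for t in range(L)])
        gamma = forward_backward(np.log(pi), np.log(A), logB)
        np.testing.assert_allclose(gamma, post, atol=1e-9)


class TestCallSites:
    def test_planted_repressor_recovered(self):
        data = make_dataset(101, architecture="default", conditions=("A",),
                            active=("A",))
        lib, arch = data["library"], data["architecture"]
        vc = data["variant_counts"]
        fp = information_footprint(vc, lib)
        shifts = expression_shift_matrix(vc, lib)
        sm = smooth_footprint(fp, 1.5)
        calls = call_sites(sm, fit_two_state_hmm(sm), shifts)
        rep = next(s for s in arch.sites if s.kind == "repressor")
        overlap = [c for c in calls if c.start < rep.end and c.end > rep.start]
        assert overlap and overlap[0].sign == "repressor-like"
        truth = [(s.start, s.end) for s in arch.sites]
        assert jaccard(calls, truth) >= 0.6

    def test_activator_called_only_in_active_condition(self):
        data = make_dataset(103, conditions=("ara", "glc"), active=("ara",),
                            include_repressor=False)
        lib, arch = data["library"], data["architecture"]
        act = next(s for s in arch.sites if s.kind == "activator")
        hits = {}
        for cond in ("ara", "glc"):
            grp = data["variant_counts"].query("condition == @cond")
            fp = information_footprint(grp, lib)
            sm = smooth_footprint(fp, 1.5)
            calls = call_sites(sm, fit_two_state_hmm(sm),
                               expression_shift_matrix(grp, lib))
            hits[cond] = any(c.start < act.end and c.end > act.start
                             for c in calls)
        assert hits["ara"] and not hits["glc"]

    def test_empty_posterior_gives_no_calls(self):
        from regfoot.site_discovery import TwoStateHMM
        hmm = TwoStateHMM(initial=np.array([1.0, 0.0]),
                          transition=np.array([[1.0, 0.0], [0.5, 0.5]]),
                          means=np.array([0.0, 100.0]),
                          variances=np.array([1.0, 1.0]))
        fp = _fp(np.full(160, 1e-6))
        assert call_sites(fp, hmm, None) == []

    def test_short_segments_dropped_and_gaps_merged(self):
        from regfoot.site_discovery import _segments
        on = np.zeros(30, bool)
        on[5:8] = True          # too short on its own ...
        on[10:20] = True        # ... but merges across the 2-gap? no: gap is 2
        assert _segments(on, merge_gap=2, min_length=4) == [(5, 20)]
        on2 = np.zeros(30, bool)
        on2[3:6] = True
        assert _segments(on2, merge_gap=2, min_length=4) == []


class TestEmergentTss:
    def test_completing_mutation_in_catAAT_frame(self):
        seq = "GGGG" + "CATAAT" + "GGGG"
        events = minus10_completing_events(seq, 4, "T")
        assert any(e.hexamer_start == 4 for e in events)
        ev = next(e for e in events if e.hexamer_start == 4)
        assert ev.post_match == (True, True, True)
        assert ev.pre_match == (False, True, True)

    def test_already_consensus_hexamer_yields_nothing(self):
        seq = "GGGG" + "TATAAT" + "GGGG"
        for base in "ACG":
            assert minus10_completing_events(seq, 4, base) == []

    def test_rule_equals_bruteforce_enumeration_at_full_length(self):
        """Every single mutant x frame over a 160-base window, enumerated
        independently, matches the rule."""
        rng = np.random.default_rng(9)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 160))

        def triple_ok(hexamer):
            return hexamer[0] == "T" and hexamer[1] == "A" and hexamer[5] == "T"

        expected = set()
        for pos in range(160):
            for base in "ACGT":
                if base == seq[pos]:
                    continue
                mut = seq[:pos] + base + seq[pos + 1:]
                for start in range(155):
                    if not (start <= pos < start + 6):
                        continue
                    if triple_ok(mut[start:start + 6]) and \
                            not triple_ok(seq[start:start + 6]):
                        expected.add((pos, base, start))
        got = {(e.position, e.creating_base, e.hexamer_start)
               for e in scan_minus10_creations(seq)}
        assert got == expected

    def test_detection_gated_by_positive_shift(self):
        seq = "GGGG" + "CATAAT" + "GGGG"
        shifts = np.full((4, len(seq)), np.nan)
        wt = np.array([2, 2, 2, 2, 1, 0, 3, 0, 0, 3, 2, 2, 2, 2])
        from regfoot.footprint_stats import ExpressionShiftMatrix
        sm = ExpressionShiftMatrix("p", "c", 1, shifts, wt)
        # no shift information -> nothing reported
        assert detect_emergent_tss(seq, sm, 4) == []
        shifts[3, 4] = 3.0  # strong expression gain for C->T at the spike
        events = detect_emergent_tss(seq, sm, 4)
        assert events and all(e.creating_base == "T" for e in events)

    def test_spike_from_simulated_minus10_creation(self):
        """A planted cryptic promoter: one substitution far from the native
        TSS strongly activates expression, the footprint shows an isolated
        spike, and the spike screens positive for a -10-completing event."""
        from regfoot import (DesignConfig, assign_barcodes, draw_barcode_counts,
                             mutate_variants, simulate_counts)
        from regfoot.barcode_pipeline import aggregate_variant_counts
        from regfoot.coords import label_to_index
        from regfoot.library_design import ints_to_seq
        from regfoot.synthetic_data import barcode_map_frame
        from regfoot.thermo import (EnergyMatrix, RegArchitecture, RegSite,
                                    mismatch_matrix)

        rng = np.random.default_rng(31)
        base = ints_to_seq(rng.integers(0, 4, 160))
        pos = label_to_index(-68)
        wt_seq = base[:pos - 1] + "CATAAT" + base[pos + 5:]
        from regfoot.library_design import PromoterRegion
        region = PromoterRegion("araB_like", "g", 115, "+", wt_seq)
        cfg = DesignConfig(rng_seed=31)
        lib = mutate_variants(region, cfg, rng=rng)
        bmap = barcode_map_frame(assign_barcodes(
            lib, draw_barcode_counts(len(lib), 3, rng), cfg, rng=rng))
        # weak native polymerase; a cryptic activator bound only when the
        # C at the spike becomes T (10 k_BT penalty on the wild-type base)
        eps = np.zeros((4, 1))
        eps[[0, 1, 2], 0] = 10.0
        sites = [
            RegSite("rnap", "rnap", label_to_index(-40),
                    label_to_index(-40) + 20,
                    EnergyMatrix(np.zeros((4, 20))), weight=0.02),
            RegSite("cryptic", "activator", pos - 1, pos,
                    EnergyMatrix(eps), weight=50.0, interaction_omega=60.0),
        ]
        arch = RegArchitecture("araB_like", sites)
        counts = simulate_counts(lib, bmap, arch, ["xylose"], 10 ** 6, 10 ** 6,
                                 seed=32)
        vc = aggregate_variant_counts(counts, bmap)
        fp = information_footprint(vc, lib)
        assert classify_footprint(fp) == EMERGENT
        spike = int(np.argmax(fp.mi))
        assert spike == pos - 1
        shifts = expression_shift_matrix(vc, lib)
        events = detect_emergent_tss(wt_seq, shifts, spike)
        assert any(e.creating_base == "T" and e.hexamer_start == pos - 1
                   for e in events)
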