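"""Pair extraction, the 4r estimator, bootstrap CI, corrections, genetic correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimevolve import heritability as herit
from mimevolve import synthetic
from mimevolve.heritability import (
    GGPair,
    apply_inheritance_correction,
    estimate_genetic_correlation,
    estimate_heritability,
    extract_gg_pairs,
)
from mimevolve.pedigree import Individual, Pedigree


class TestExtractPairs:
    def test_toy_pedigree_definition_walk(self, toy_pedigree):
        mat = extract_gg_pairs(toy_pedigree, "maternal")
        pat = extract_gg_pairs(toy_pedigree, "paternal")
        assert [(p.grandmother_id, p.granddaughter_id) for p in mat] == [("GM", "D")]
        assert [(p.grandmother_id, p.granddaughter_id) for p in pat] == [("PGM", "D")]
        assert mat[0].g_value == 0.10 and mat[0].d_value == 0.11
        assert mat[0].family_id == "GM"

    def test_unknown_father_emits_no_paternal_pair(self, toy_pedigree):
        toy_pedigree["D"].father_id = None
        assert extract_gg_pairs(toy_pedigree, "paternal") == []
        assert len(extract_gg_pairs(toy_pedigree, "maternal")) == 1

    def test_matches_brute_force_double_loop(self):
        ped = synthetic.simulate_pedigree(
            synthetic.PedigreeSimSpec(offspring_per_pair=4, seed=8)
        )
        for lineage in ("maternal", "paternal"):
            pairs = extract_gg_pairs(ped, lineage)
            brute = set()
            for gm in ped:
                if gm.sex != "F" or gm.white_rel is None:
                    continue
                for gd in ped:
                    if gd.sex != "F" or gd.white_rel is None:
                        continue
                    link = (
                        ped.mother(gd.id) if lineage == "maternal" else ped.father(gd.id)
                    )
                    if link is not None and link.mother_id == gm.id:
                        brute.add((gm.id, gd.id))
            assert {(p.grandmother_id, p.granddaughter_id) for p in pairs} == brute


class TestQuadruplingRule:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.60, 2.40), (0.28, 1.12), (0.1875, 0.75), (-0.375, -1.50)],
    )
    def test_reported_worked_examples(self, r, expected):
        pairs = synthetic.pairs_with_correlation(r, n=12, seed=1)
        est = estimate_heritability(pairs, "paternal", n_boot=50, seed=0)
        assert est.estimate == pytest.approx(expected, abs=1e-9)
        assert est.r == pytest.approx(r, abs=1e-12)

    def test_null_pairs_give_zero_estimate_and_flat_p(self):
        pairs = synthetic.pairs_with_correlation(0.0, n=30, seed=2)
        est = estimate_heritability(pairs, "maternal", n_boot=50, seed=0)
        assert est.estimate == pytest.approx(0.0, abs=1e-9)
        assert est.p_value == pytest.approx(1.0, abs=1e-6)

    @given(st.floats(-0.95, 0.95), st.integers(5, 40))
    @settings(max_examples=20, deadline=None)
    def test_estimate_is_exactly_four_r(self, r, n):
        pairs = synthetic.pairs_with_correlation(r, n=n, seed=3)
        est = estimate_heritability(pairs, "maternal", n_boot=10, seed=0)
        assert est.estimate == 4.0 * est.r

    def test_degenerate_inputs_rejected(self):
        pairs = [
            GGPair("a", "x", "maternal", 0.1, 0.2, "a"),
            GGPair("b", "y", "maternal", 0.1, 0.3, "b"),
            GGPair("c", "z", "maternal", 0.1, 0.4, "c"),
        ]
        with pytest.raises(ValueError, match="degenerate"):
            estimate_heritability(pairs, "maternal", n_boot=10, seed=0)
        with pytest.raises(ValueError, match=">= 3"):
            estimate_heritability(pairs[:2], "maternal", n_boot=10, seed=0)


class TestBootstrap:
    def test_ci_matches_independent_resampling_loop(self):
        """The cluster bootstrap must agree bit-for-bit with a plainly coded
        reference loop using the same seed and resampling scheme."""
        pairs = synthetic.pairs_with_correlation(0.4, n=12, seed=4)
        # give some grandmothers two granddaughters to exercise clustering
        extra = [
            GGPair(p.grandmother_id, p.granddaughter_id + "b", p.lineage,
                   p.g_value, p.d_value + 0.01, p.family_id)
            for p in pairs[:4]
        ]
        all_pairs = pairs + extra
        est = estimate_heritability(all_pairs, "maternal", n_boot=1000, seed=1)

        g = np.array([p.g_value for p in all_pairs])
        d = np.array([p.d_value for p in all_pairs])
        fams = list(dict.fromkeys(p.family_id for p in all_pairs))
        idx = {f: [i for i, p in enumerate(all_pairs) if p.family_id == f] for f in fams}
        rng = np.random.default_rng(1)
        boots = []
        for _ in range(1000):
            pick = rng.integers(0, len(fams), size=len(fams))
            rows = [i for k in pick for i in idx[fams[k]]]
            gg, dd = g[rows], d[rows]
            if np.allclose(gg, gg[0]) or np.allclose(dd, dd[0]):
                boots.append(np.nan)
            else:
                boots.append(4.0 * np.corrcoef(gg, dd)[0, 1])
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        assert est.ci_low == lo and est.ci_high == hi

    def test_ci_coverage_under_autosomal_truth(self):
        """95% cluster-bootstrap CI should cover the true h2 in 90-99% of
        simulated breeding designs (the cluster bootstrap is approximate)."""
        tot = 5.0e-4
        h2 = 0.5
        covered = 0
        n_rep = 120
        for rep in range(n_rep):
            ped = synthetic.simulate_pedigree(
                synthetic.PedigreeSimSpec(
                    inheritance_mode="autosomal",
                    genetic_variance=h2 * tot,
                    environmental_variance=(1 - h2) * tot,
                    offspring_per_pair=4,
                    seed=1000 + rep,
                )
            )
            pairs = extract_gg_pairs(ped, "maternal")
            est = estimate_heritability(pairs, "maternal", n_boot=600, seed=rep)
            covered += est.ci_low <= h2 <= est.ci_high
        assert 0.90 <= covered / n_rep <= 0.99


class TestCorrection:
    def test_w_or_organelle_divides_by_four(self):
        pairs = synthetic.pairs_with_correlation(0.60, n=12, seed=5)
        est = estimate_heritability(pairs, "maternal", n_boot=100, seed=0)
        corr = apply_inheritance_correction(est, "w_or_organelle")
        assert corr.corrected_estimate == pytest.approx(est.estimate / 4)
        assert corr.ci_low == pytest.approx(est.ci_low / 4)
        assert corr.ci_high == pytest.approx(est.ci_high / 4)

    def test_autosomal_is_identity_and_negative_scales_linearly(self):
        pairs = synthetic.pairs_with_correlation(-0.375, n=12, seed=6)
        est = estimate_heritability(pairs, "maternal", n_boot=100, seed=0)
        assert est.estimate == pytest.approx(-1.50, abs=1e-9)
        auto = apply_inheritance_correction(est, "autosomal")
        assert auto.corrected_estimate == est.estimate
        w = apply_inheritance_correction(est, "w_or_organelle")
        assert w.corrected_estimate == pytest.approx(-0.375, abs=1e-9)

    def test_unknown_mode_rejected(self):
        pairs = synthetic.pairs_with_correlation(0.2, n=12, seed=7)
        est = estimate_heritability(pairs, "maternal", n_boot=10, seed=0)
        with pytest.raises(ValueError):
            apply_inheritance_correction(est, "mitochondrial")


class TestGeneticCorrelation:
    def _cross_identity_pedigree(self):
        """Granddaughter red equals grandmother white and vice versa."""
        ped = Pedigree()
        rng = np.random.default_rng(0)
        for i in range(8):
            w, r = rng.uniform(0.05, 0.15), rng.uniform(0.02, 0.08)
            gm, gf = f"GM{i}", f"GF{i}"
            m, f_ = f"M{i}", f"F{i}"
            d = f"D{i}"
            ped.add(Individual(gm, "F", generation=0, white_rel=w, red_rel=r))
            ped.add(Individual(gf, "M", generation=0))
            ped.add(Individual(m, "F", gm, gf, 1, white_rel=w, red_rel=r))
            ped.add(Individual(f_, "M", generation=1))
            ped.add(Individual(d, "F", m, f_, 2, white_rel=r, red_rel=w))
        return ped

    def test_perfect_cross_identity(self):
        ped = self._cross_identity_pedigree()
        gc = estimate_genetic_correlation(ped, "maternal", n_boot=100, seed=0)
        assert gc.r_cross == pytest.approx(1.0, abs=1e-9)
        assert gc.direction_detail["gm_white_gd_red"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_traits_have_null_cross_correlation(self):
        ped = synthetic.simulate_pedigree(
            synthetic.PedigreeSimSpec(
                n_founder_females=64, offspring_per_pair=6, seed=9
            )
        )
        gc = estimate_genetic_correlation(ped, "maternal", n_boot=100, seed=0)
        assert gc.n_pairs >= 500
        assert abs(gc.r_cross) < 0.1

    def test_matches_hand_computed_mean_of_directions(self, toy_pedigree):
        # enlarge the toy pedigree to 4 independent maternal triples
        ped = Pedigree()
        vals = [(0.10, 0.05, 0.11, 0.06), (0.12, 0.04, 0.09, 0.05),
                (0.08, 0.06, 0.10, 0.04), (0.11, 0.03, 0.12, 0.07)]
        for i, (gw, gr, dw, dr) in enumerate(vals):
            ped.add(Individual(f"GM{i}", "F", generation=0, white_rel=gw, red_rel=gr))
            ped.add(Individual(f"GF{i}", "M", generation=0))
            ped.add(Individual(f"M{i}", "F", f"GM{i}", f"GF{i}", 1, white_rel=0.1, red_rel=0.05))
            ped.add(Individual(f"F{i}", "M", generation=1))
            ped.add(Individual(f"D{i}", "F", f"M{i}", f"F{i}", 2, white_rel=dw, red_rel=dr))
        gc = estimate_genetic_correlation(ped, "maternal", n_boot=50, seed=0)
        gw = np.array([v[0] for v in vals])
        gr = np.array([v[1] for v in vals])
        dw = np.array([v[2] for v in vals])
        dr = np.array([v[3] for v in vals])
        expected = (np.corrcoef(gw, dr)[0, 1] + np.corrcoef(gr, dw)[0, 1]) / 2
        assert gc.r_cross == pytest.approx(expected, abs=1e-12)
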