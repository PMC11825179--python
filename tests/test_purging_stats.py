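"""ROHf/non-ROHf, Rxy, conservation-weighted load and SFS."""

import numpy as np
import pandas as pd
import pytest

from purgekit.load_annotation import ANCESTRAL_REF, PolarizedTable
from purgekit.purging_stats import (
    ConservationTrack,
    gerp_relative_load,
    rohf_statistics,
    rxy,
    sfs,
    sites_in_roh,
)
from purgekit.roh import ROHSegment
from purgekit.synthetic_data import make_worked_toy
from purgekit.variants_io import SamplePanel
from conftest import build_vt
from oracles import sfs_enumeration


def _polar_ref_ancestral(m_by_pop, s_by_pop):
    n = len(next(iter(m_by_pop.values())))
    return PolarizedTable(
        ancestral=np.full(n, ANCESTRAL_REF, dtype=np.int8),
        m={k: np.asarray(v) for k, v in m_by_pop.items()},
        s={k: np.asarray(v) for k, v in s_by_pop.items()},
        focal_population=next(iter(m_by_pop)),
    )


def _effects_frame(classes):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, len(classes) + 1) * 1000,
            "effect": classes,
            "aa_ref": None,
            "aa_alt": None,
            "dnssnp": False,
            "term": "",
        }
    )


class TestSitesInRoh:
    def test_closed_interval_membership(self):
        chroms = np.array(["chr1"] * 4)
        pos = np.array([99, 100, 200, 201])
        segs = [ROHSegment("s", "chr1", 100, 200, 5)]
        assert sites_in_roh(chroms, pos, segs).tolist() == [False, True, True, False]


class TestRohf:
    def _setup(self, lof_gt, syn_gt, roh_end=5_000):
        """One individual; LoF sites at 1..4 kb, synonymous at 1..8 kb."""
        classes = ["LoF"] * len(lof_gt) + ["synonymous"] * len(syn_gt)
        gt = np.array(lof_gt + syn_gt, dtype=np.int8)[:, None]
        pos = np.arange(1, len(classes) + 1) * 1000
        vt = build_vt(gt, pos=pos, samples=["ind"])
        panel = SamplePanel({"ind": "pop"})
        eff = _effects_frame(classes)
        polar = _polar_ref_ancestral({"pop": gt[:, 0]}, {"pop": np.full(len(classes), 2)})
        segs = {"ind": [ROHSegment("ind", "chr1", 1, roh_end, 5)]}
        return vt, eff, polar, panel, segs

    def test_direct_formula(self):
        # inside ROH (pos <= 5000): LoF carriers at sites 1-3, syn at 5;
        # choose counts giving ROHf = 3/1 inside and 0/6 outside? use clean case:
        vt, eff, polar, panel, segs = self._setup(
            lof_gt=[1, 1, 1, 0], syn_gt=[2, 2, 2, 2, 2, 2]
        )
        res = rohf_statistics(vt, eff, polar, panel, segs, categories=("LoF",))
        row = res.per_individual.iloc[0]
        # ROH covers pos 1000..5000: LoF sites 1-3 carried, syn site at 5000
        assert row["n_del_in_roh"] == 3 and row["n_syn_in_roh"] == 1
        assert row["rohf"] == pytest.approx(3.0)
        assert row["n_del_out_roh"] == 0 and row["n_syn_out_roh"] == 5
        assert row["nonrohf"] == 0.0

    def test_three_lof_six_syn_inside(self):
        vt, eff, polar, panel, segs = self._setup(
            lof_gt=[1, 1, 1], syn_gt=[2] * 6, roh_end=10_000
        )
        res = rohf_statistics(vt, eff, polar, panel, segs, categories=("LoF",))
        assert res.per_individual["rohf"].iloc[0] == pytest.approx(0.5)

    def test_zero_synonymous_in_roh_undefined(self):
        vt, eff, polar, panel, segs = self._setup(
            lof_gt=[1, 1], syn_gt=[0, 0], roh_end=10_000
        )
        res = rohf_statistics(vt, eff, polar, panel, segs, categories=("LoF",))
        assert np.isnan(res.per_individual["rohf"].iloc[0])

    def test_forced_purging_toy_rohf_below_nonrohf(self):
        """Deleterious carriers placed only outside ROH force ROHf < nonROHf."""
        rng = np.random.default_rng(0)
        n = 200
        classes = rng.permutation(["LoF"] * 50 + ["synonymous"] * 150)
        pos = np.arange(1, n + 1) * 1000
        in_roh = pos <= 100_000
        gt = np.ones(n, dtype=np.int8)
        gt[(classes == "LoF") & in_roh] = 0      # purged inside ROH
        vt = build_vt(gt[:, None], pos=pos, samples=["ind"])
        panel = SamplePanel({"ind": "pop"})
        polar = _polar_ref_ancestral({"pop": gt}, {"pop": np.full(n, 2)})
        segs = {"ind": [ROHSegment("ind", "chr1", 1, 100_000, 5)]}
        res = rohf_statistics(vt, _effects_frame(list(classes)), polar, panel,
                              segs, categories=("LoF",))
        row = res.per_individual.iloc[0]
        assert row["rohf"] == 0.0 < row["nonrohf"]


class TestRxy:
    def test_identical_counts_give_exactly_one(self):
        rng = np.random.default_rng(1)
        n = 100
        m = rng.integers(0, 10, n)
        s = np.full(n, 20)
        polar = _polar_ref_ancestral({"X": m, "Y": m.copy()},
                                     {"X": s, "Y": s.copy()})
        cat = np.zeros(n, dtype=bool)
        cat[:50] = True
        res = rxy(polar, "X", "Y", cat, ~cat)
        assert res.r == 1.0

    def test_reciprocity(self):
        rng = np.random.default_rng(2)
        n = 80
        polar = _polar_ref_ancestral(
            {"X": rng.integers(0, 10, n), "Y": rng.integers(0, 10, n)},
            {"X": np.full(n, 20), "Y": np.full(n, 20)},
        )
        cat = np.arange(n) < 40
        r_xy = rxy(polar, "X", "Y", cat, ~cat).r
        r_yx = rxy(polar, "Y", "X", cat, ~cat).r
        assert r_xy * r_yx == pytest.approx(1.0, rel=1e-12)

    def test_private_excess_in_x_gives_r_above_one(self):
        n = 40
        m_x = np.concatenate([np.full(20, 5), np.full(20, 5)])
        m_y = np.concatenate([np.full(20, 1), np.full(20, 5)])
        polar = _polar_ref_ancestral(
            {"X": m_x, "Y": m_y}, {"X": np.full(n, 20), "Y": np.full(n, 20)}
        )
        cat = np.arange(n) < 20
        assert rxy(polar, "X", "Y", cat, ~cat).r > 1.0

    def test_worked_toy_hand_evaluation(self):
        toy = make_worked_toy()["rxy"]
        res = rxy(toy["polar"], "X", "Y", toy["category_sites"],
                  toy["intergenic_sites"], n_blocks=2)
        assert res.l_x == pytest.approx(toy["expected_l_x"])
        assert res.l_y == pytest.approx(toy["expected_l_y"])
        assert res.r == pytest.approx(toy["expected_r"])

    def test_zero_intergenic_denominator_errors(self):
        n = 4
        polar = _polar_ref_ancestral(
            {"X": np.array([1, 1, 0, 0]), "Y": np.array([1, 1, 0, 0])},
            {"X": np.full(n, 10), "Y": np.full(n, 10)},
        )
        cat = np.array([True, True, False, False])
        with pytest.raises(ZeroDivisionError):
            rxy(polar, "X", "Y", cat, ~cat)

    def test_zero_called_sites_skipped(self):
        polar = _polar_ref_ancestral(
            {"X": np.array([2, 0, 3, 3]), "Y": np.array([1, 4, 3, 3])},
            {"X": np.array([10, 0, 10, 10]), "Y": np.array([10, 10, 10, 10])},
        )
        cat = np.array([True, True, False, False])
        res = rxy(polar, "X", "Y", cat, ~cat, n_blocks=2)
        # site 2 has s_X = 0 and must not contribute to either sum
        polar2 = _polar_ref_ancestral(
            {"X": np.array([2, 3, 3]), "Y": np.array([1, 3, 3])},
            {"X": np.array([10, 10, 10]), "Y": np.array([10, 10, 10])},
        )
        cat2 = np.array([True, False, False])
        assert res.r == pytest.approx(rxy(polar2, "X", "Y", cat2, ~cat2, 2).r)

    def test_jackknife_se_positive_under_heterogeneity(self):
        rng = np.random.default_rng(3)
        n = 400
        polar = _polar_ref_ancestral(
            {"X": rng.integers(0, 10, n), "Y": rng.integers(0, 10, n)},
            {"X": np.full(n, 20), "Y": np.full(n, 20)},
        )
        cat = np.arange(n) < 200
        res = rxy(polar, "X", "Y", cat, ~cat)
        assert res.se > 0 and res.n_blocks == 20


class TestConservationLoad:
    def test_direct_formula(self):
        # top site (score 5) hom; total derived dose 10
        scores = np.array([5.0, 1.0, 1.0, 1.0, 1.0])
        track = ConservationTrack(scores, quantile=0.2)
        assert track.top_mask.tolist() == [True, False, False, False, False]
        gt = np.array([[2], [2], [2], [2], [2]], dtype=np.int8)
        vt = build_vt(gt, samples=["ind"])
        panel = SamplePanel({"ind": "pop"})
        polar = _polar_ref_ancestral({"pop": gt[:, 0] * 1}, {"pop": np.full(5, 2)})
        res = gerp_relative_load(vt, polar, track, panel)
        assert res.per_individual["relative_load"].iloc[0] == pytest.approx(
            (2 * 5.0) / 10
        )

    def test_no_derived_in_top_quantile_is_zero(self):
        scores = np.array([5.0, 1.0, 1.0, 1.0, 1.0])
        track = ConservationTrack(scores, quantile=0.2)
        gt = np.array([[0], [2], [2], [2], [2]], dtype=np.int8)
        vt = build_vt(gt, samples=["ind"])
        panel = SamplePanel({"ind": "pop"})
        polar = _polar_ref_ancestral({"pop": gt[:, 0]}, {"pop": np.full(5, 2)})
        res = gerp_relative_load(vt, polar, track, panel)
        assert res.per_individual["relative_load"].iloc[0] == 0.0

    def test_scale_equivariance_and_below_threshold_invariance(self):
        rng = np.random.default_rng(6)
        n = 50
        scores = rng.normal(0, 2, n)
        gt = rng.choice([0, 1, 2], size=(n, 1)).astype(np.int8)
        vt = build_vt(gt, samples=["ind"])
        panel = SamplePanel({"ind": "pop"})
        polar = _polar_ref_ancestral({"pop": gt[:, 0]}, {"pop": np.full(n, 2)})
        r1 = gerp_relative_load(vt, polar, ConservationTrack(scores, 0.1), panel)
        r2 = gerp_relative_load(vt, polar, ConservationTrack(2 * scores, 0.1), panel)
        assert r2.per_individual["relative_load"].iloc[0] == pytest.approx(
            2 * r1.per_individual["relative_load"].iloc[0]
        )
        # permuting scores strictly below the threshold changes nothing
        track = ConservationTrack(scores, 0.1)
        below = ~track.top_mask
        perm = scores.copy()
        perm[below] = rng.permutation(scores[below])
        r3 = gerp_relative_load(vt, polar, ConservationTrack(perm, 0.1), panel)
        assert r3.per_individual["relative_load"].iloc[0] == pytest.approx(
            r1.per_individual["relative_load"].iloc[0]
        )

    def test_zero_derived_alleles_undefined(self):
        gt = np.zeros((5, 1), dtype=np.int8)
        vt = build_vt(gt, samples=["ind"])
        panel = SamplePanel({"ind": "pop"})
        polar = _polar_ref_ancestral({"pop": gt[:, 0]}, {"pop": np.full(5, 2)})
        res = gerp_relative_load(vt, polar, ConservationTrack(np.ones(5), 0.2), panel)
        assert np.isnan(res.per_individual["relative_load"].iloc[0])

    def test_mask_size_is_ceil(self):
        track = ConservationTrack(np.arange(10.0), quantile=0.25)
        assert track.top_mask.sum() == 3  # ceil(2.5)


class TestSfs:
    def _polar_and_effects(self, m, s, cls="intergenic"):
        n = len(m)
        polar = _polar_ref_ancestral({"pop": m}, {"pop": s})
        eff = _effects_frame([cls] * n)
        panel = SamplePanel({"ind": "pop"})
        return polar, eff, panel

    def test_enumeration_pmf_s4_m2_k2(self):
        polar, eff, panel = self._polar_and_effects([2], [4])
        res = sfs(polar, eff, panel, "pop", 2)
        expected = sfs_enumeration(2, 4, 2)
        assert res.spectra["neutral"] == pytest.approx(expected)
        assert expected == pytest.approx([1 / 6, 2 / 3, 1 / 6])

    def test_fixed_and_absent_degenerate_bins(self):
        polar, eff, panel = self._polar_and_effects([4, 0], [4, 4])
        res = sfs(polar, eff, panel, "pop", 2)
        assert res.spectra["neutral"] == pytest.approx([0.5, 0.0, 0.5])

    def test_sites_below_subsample_size_skipped(self):
        polar, eff, panel = self._polar_and_effects([1, 2], [2, 4])
        res = sfs(polar, eff, panel, "pop", 4)
        assert res.n_sites["neutral"] == 1

    def test_odd_subsample_rejected(self):
        polar, eff, panel = self._polar_and_effects([1], [4])
        with pytest.raises(ValueError):
            sfs(polar, eff, panel, "pop", 3)

    def test_spectrum_sums_to_one_per_class(self):
        rng = np.random.default_rng(8)
        s = np.full(30, 10)
        m = rng.integers(0, 11, 30)
        polar, eff, panel = self._polar_and_effects(m, s)
        res = sfs(polar, eff, panel, "pop", 4)
        assert res.spectra["neutral"].sum() == pytest.approx(1.0)

    def test_monte_carlo_matches_expected_within_3se(self):
        rng = np.random.default_rng(12)
        n = 40
        s = np.full(n, 12)
        m = rng.integers(0, 13, n)
        polar, eff, panel = self._polar_and_effects(m, s)
        expected = sfs(polar, eff, panel, "pop", 6).spectra["neutral"]
        draws = np.zeros((200, 7))
        for rep in range(200):
            draws[rep] = sfs(polar, eff, panel, "pop", 6, mode="mc",
                             seed=rep).spectra["neutral"]
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(200)
        assert np.all(np.abs(mean - expected) <= 3 * se + 1e-12)

    def test_proportion_fixed_counting(self):
        m = np.full(25, 2)
        m[:2] = 4
        polar, eff, panel = self._polar_and_effects(m, np.full(25, 4))
        res = sfs(polar, eff, panel, "pop", 4)
        assert res.proportion_fixed()["neutral"] == pytest.approx(2 / 25)

    def test_worked_toy(self):
        toy = make_worked_toy()["sfs"]
        polar, eff, panel = self._polar_and_effects(toy["m"], toy["s"])
        pmf = sfs(polar, eff, panel, "pop", toy["subsample_2n"])
        single = sfs_enumeration(2, 4, toy["subsample_2n"])
        assert single == pytest.approx(toy["expected_single_site_pmf"])
        res = sfs(polar, eff, panel, "pop", toy["fixed_subsample_2n"])
        assert res.proportion_fixed()["neutral"] == pytest.approx(
            toy["expected_fixed_fraction"]
        )
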