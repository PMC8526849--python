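"""Instrument selection, harmonization, meta-analysis, scores and F statistics."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm

import drugtarget_mr as dm
from drugtarget_mr.sumstats_io import COMPLEMENT, ValidationError

from conftest import make_variant


def _candidates(pvals, chrom="5", start_pos=74_600_000):
    return [
        make_variant(snp_id=f"snp{i + 1}", chrom=chrom, pos=start_pos + 1000 * i,
                     beta=-0.05, se=0.005, pval=p)
        for i, p in enumerate(pvals)
    ]


class TestSelection:
    def test_greedy_rule_matches_exhaustive_expectation(self):
        # five candidates; only snp3-snp1 exceed the prune threshold; snp5 fails p
        cands = _candidates([1e-80, 1e-20, 1e-11, 1e-9, 1e-6])
        ids = [c.snp_id for c in cands]
        r = np.eye(5)
        r[0, 2] = r[2, 0] = np.sqrt(0.5)
        ld = dm.LDMatrix(ids, r)
        score = dm.select_instruments(cands, None, p_thresh=5e-8, r2_prune=0.2, ld=ld)
        assert score.snp_ids == ["snp1", "snp2", "snp4"]

    def test_window_boundary_is_inclusive(self):
        region = dm.GeneRegion("G", "5", 1_000_000, 1_001_000, flank=100_000)
        inside = make_variant(snp_id="in", pos=900_000, pval=1e-20)
        outside = make_variant(snp_id="out", pos=899_999, pval=1e-40)
        score = dm.select_instruments([inside, outside], region)
        assert score.snp_ids == ["in"]

    def test_hmgcr_table_yields_four_snps(self):
        cands = dm.datasets.ldl_lowering_variants()  # all 14, mixed genes
        ld = dm.LDMatrix.identity([c.snp_id for c in cands])
        score = dm.select_instruments(cands, dm.datasets.GENE_REGIONS["HMGCR"],
                                      ld=ld, name="HMGCR")
        assert sorted(score.snp_ids) == sorted(
            ["rs12916", "rs17648288", "rs3857388", "rs10064936"])
        # weights are positive lowering magnitudes
        assert np.all(score.weights > 0)
        w = dict(zip(score.snp_ids, score.weights))
        assert w["rs12916"] == pytest.approx(0.073)

    def test_selection_invariant_to_input_order(self):
        cands = _candidates([1e-80, 1e-20, 1e-11, 1e-9, 1e-12])
        ids = [c.snp_id for c in cands]
        r = np.eye(5)
        r[1, 4] = r[4, 1] = 0.6
        ld = dm.LDMatrix(ids, r)
        reference = dm.select_instruments(cands, None, ld=ld).snp_ids
        for perm in itertools.permutations(range(5)):
            shuffled = [cands[i] for i in perm]
            assert dm.select_instruments(shuffled, None, ld=ld).snp_ids == reference

    def test_equal_pvalue_tie_broken_by_snp_id(self):
        cands = _candidates([1e-20, 1e-20])
        r = np.array([[1.0, 0.8], [0.8, 1.0]])
        ld = dm.LDMatrix([c.snp_id for c in cands], r)
        score = dm.select_instruments(cands, None, ld=ld)
        assert score.snp_ids == ["snp1"]

    def test_multi_population_prune_requires_every_panel(self):
        cands = _candidates([1e-80, 1e-20])
        ids = [c.snp_id for c in cands]
        eur = dm.LDMatrix(ids, np.eye(2))
        eas = dm.LDMatrix(ids, [[1, 0.7], [0.7, 1]])  # fails r2 <= 0.2 here
        both = dm.select_instruments(cands, None, ld=[eur, eas])
        assert both.snp_ids == ["snp1"]
        one = dm.select_instruments(cands, None, ld=eur)
        assert one.snp_ids == ["snp1", "snp2"]

    def test_no_candidate_passing_p_is_empty_score_not_error(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="drugtarget_mr"):
            score = dm.select_instruments(_candidates([1e-4]), None)
        assert len(score) == 0 and "no candidate" in caplog.text

    def test_candidate_missing_from_ld_is_named(self):
        cands = _candidates([1e-80, 1e-20])
        ld = dm.LDMatrix.identity(["snp1"])
        with pytest.raises(KeyError, match="snp2"):
            dm.select_instruments(cands, None, ld=ld)


class TestProxy:
    def _ld(self, r2s):
        ids = ["target"] + [f"p{i}" for i in range(len(r2s))]
        r = np.eye(len(ids))
        for i, r2 in enumerate(r2s):
            r[0, i + 1] = r[i + 1, 0] = np.sqrt(r2)
        return dm.LDMatrix(ids, r), ids[1:]

    def test_returns_highest_r2_candidate(self):
        ld, cands = self._ld([0.98, 0.92])
        assert dm.find_proxy("target", cands, ld) == "p0"

    def test_none_when_below_threshold(self):
        ld, cands = self._ld([0.80])
        assert dm.find_proxy("target", cands, ld, r2_min=0.9) is None

    def test_tie_broken_lexicographically(self):
        ld, cands = self._ld([0.95, 0.95])
        assert dm.find_proxy("target", list(reversed(cands)), ld) == "p0"

    def test_missing_target_is_an_error(self):
        ld, cands = self._ld([0.95])
        with pytest.raises(KeyError, match="zzz"):
            dm.find_proxy("zzz", cands, ld)


class TestMetaAnalysis:
    def _cohorts(self, betas, ses):
        return [make_variant(beta=b, se=s, pval=0.5) for b, s in zip(betas, ses)]

    def test_closed_form_pooling(self):
        pooled = dm.meta_analyze_fixed(self._cohorts([0.1, 0.3], [0.1, 0.1]))
        assert pooled.beta == pytest.approx(0.2, abs=1e-12)
        assert pooled.se == pytest.approx(0.0707107, abs=1e-6)

    def test_single_cohort_identity(self):
        rec = self._cohorts([0.1], [0.1])[0]
        pooled = dm.meta_analyze_fixed([rec])
        assert pooled.beta == pytest.approx(rec.beta, rel=1e-14)
        assert pooled.se == pytest.approx(rec.se, rel=1e-14)

    def test_infinite_variance_cohort_has_zero_weight(self):
        pooled = dm.meta_analyze_fixed(self._cohorts([0.1, 5.0], [0.1, 1e8]))
        assert pooled.beta == pytest.approx(0.1, abs=1e-10)
        assert pooled.se == pytest.approx(0.1, rel=1e-10)

    def test_matches_wls_intercept_only_oracle(self):
        rng = np.random.default_rng(4)
        betas = rng.normal(0, 1, 6)
        ses = rng.uniform(0.05, 0.5, 6)
        pooled = dm.meta_analyze_fixed(self._cohorts(betas, ses))
        wls = sm.WLS(betas, np.ones_like(betas), weights=1 / ses**2).fit()
        assert pooled.beta == pytest.approx(wls.params[0], abs=1e-12)

    def test_allele_mismatch_is_an_error(self):
        a = make_variant(ea="T", oa="C")
        b = make_variant(ea="C", oa="T")
        with pytest.raises(ValidationError, match="harmonize first"):
            dm.meta_analyze_fixed([a, b])


def _single_snp_score(ea="T", oa="C", weight=0.073):
    return dm.ScoreDefinition("s", ["rs1"], np.array([weight]), [ea], [oa])


class TestHarmonize:
    def test_sign_algebra_over_all_allele_configurations(self):
        """Brute force: every representation of the same physical association
        must harmonize to the identical (bx, by)."""
        score = _single_snp_score()  # counted lowering allele T (other C)
        exp = make_variant(ea="T", oa="C", beta=-0.073)
        base_by = -0.05  # outcome log-odds per T allele
        representations = []
        for ea, oa, sign in [("T", "C", 1), ("C", "T", -1),
                             ("A", "G", 1), ("G", "A", -1)]:
            representations.append(
                make_variant(ea=ea, oa=oa, beta=sign * base_by, se=0.01,
                             trait_kind="binary"))
        for out in representations:
            iset = dm.harmonize(score, [exp], [out])
            assert iset.bx[0] == pytest.approx(0.073)
            assert iset.by[0] == pytest.approx(-0.05)

    def test_outcome_effect_allele_is_exposures_other_allele(self):
        # counted T lowers LDL by 0.073; outcome reported per A allele (+0.05)
        score = dm.ScoreDefinition("s", ["rs1"], np.array([0.073]), ["T"], ["A"])
        exp = make_variant(ea="T", oa="A", eaf=0.2, beta=-0.073)
        out = make_variant(ea="A", oa="T", eaf=0.8, beta=0.05, se=0.01,
                           trait_kind="binary")
        iset = dm.harmonize(score, [exp], [out])
        assert iset.bx[0] == pytest.approx(0.073)
        assert iset.by[0] == pytest.approx(-0.05)

    def test_palindromic_with_ambiguous_eaf_dropped(self):
        score = dm.ScoreDefinition(
            "s", ["rs1", "rs2"], np.array([0.073, 0.05]), ["T", "T"], ["A", "C"])
        exp = [make_variant(ea="T", oa="A", eaf=0.50, beta=-0.073),
               make_variant(snp_id="rs2", ea="T", oa="C", eaf=0.3, beta=-0.05)]
        out = [make_variant(ea="T", oa="A", eaf=0.5, beta=-0.02, trait_kind="binary"),
               make_variant(snp_id="rs2", ea="T", oa="C", eaf=0.3, beta=-0.02,
                            trait_kind="binary")]
        iset = dm.harmonize(score, exp, out)
        assert iset.snp_ids == ["rs2"]

    def test_palindromic_with_informative_eaf_kept(self):
        score = dm.ScoreDefinition("s", ["rs1"], np.array([0.073]), ["T"], ["A"])
        exp = [make_variant(ea="T", oa="A", eaf=0.2, beta=-0.073)]
        out = [make_variant(ea="T", oa="A", eaf=0.2, beta=-0.02, trait_kind="binary")]
        assert dm.harmonize(score, exp, out).snp_ids == ["rs1"]

    def test_irreconcilable_alleles_named(self):
        score = _single_snp_score(ea="A", oa="C")
        exp = [make_variant(ea="A", oa="C", beta=-0.05)]
        out = [make_variant(ea="A", oa="G", beta=0.01, trait_kind="binary")]
        with pytest.raises(ValidationError, match="rs1"):
            dm.harmonize(score, exp, out)

    def test_harmonization_is_involution_safe(self):
        score = _single_snp_score()
        exp = [make_variant(ea="T", oa="C", beta=-0.073)]
        out = [make_variant(ea="T", oa="C", beta=-0.04, se=0.01, trait_kind="binary")]
        once = dm.harmonize(score, exp, out)
        # re-express the harmonized set as records and harmonize again
        exp2 = [make_variant(ea="T", oa="C", beta=-float(once.bx[0]))]
        out2 = [make_variant(ea="T", oa="C", beta=float(once.by[0]),
                             se=float(once.sy[0]), trait_kind="binary")]
        twice = dm.harmonize(score, exp2, out2)
        np.testing.assert_allclose(once.bx, twice.bx)
        np.testing.assert_allclose(once.by, twice.by)

    def test_counted_allele_flip_leaves_estimators_unchanged(self):
        """Orientation invariance: storing the raising allele for one SNP must
        not change any downstream MR estimate."""
        rng = np.random.default_rng(8)
        k = 4
        ids = [f"rs{i}" for i in range(k)]
        exp = [make_variant(snp_id=ids[i], ea="T", oa="C", beta=-0.05 - 0.01 * i,
                            se=0.004, pval=1e-30) for i in range(k)]
        out = [make_variant(snp_id=ids[i], ea="T", oa="C",
                            beta=float(rng.normal(0.02, 0.01)), se=0.01,
                            trait_kind="binary") for i in range(k)]
        r = np.eye(k)
        r[0, 1] = r[1, 0] = 0.4
        ld = dm.LDMatrix(ids, r)
        base = dm.ScoreDefinition("s", ids, np.array([0.05 + 0.01 * i for i in range(k)]),
                                  ["T"] * k, ["C"] * k)
        flipped = dm.ScoreDefinition("s", ids, base.weights.copy(),
                                     ["C"] + ["T"] * (k - 1), ["T"] + ["C"] * (k - 1))
        iset_a = dm.harmonize(base, exp, out, ld=ld)
        iset_b = dm.harmonize(flipped, exp, out, ld=ld)
        for fn in (dm.ivw, dm.max_likelihood):
            assert fn(iset_a).beta == pytest.approx(fn(iset_b).beta, abs=1e-12)
            assert fn(iset_a).se == pytest.approx(fn(iset_b).se, abs=1e-12)
        ega, egb = dm.egger(iset_a), dm.egger(iset_b)
        assert ega.slope.beta == pytest.approx(egb.slope.beta, abs=1e-12)
        assert ega.intercept == pytest.approx(egb.intercept, abs=1e-12)


class TestWeightedScore:
    def _score(self):
        return dm.ScoreDefinition(
            "HMGCR", [f"s{i}" for i in range(4)],
            np.array([0.073, 0.057, 0.042, 0.035]), ["T"] * 4, ["C"] * 4)

    def _cohort(self, dosages):
        d = np.asarray(dosages, dtype=float)
        return dm.CohortMatrix(d, np.zeros(d.shape[0], dtype=int),
                               [f"s{i}" for i in range(d.shape[1])],
                               [f"id{i}" for i in range(d.shape[0])])

    def test_worked_example(self):
        vals = dm.weighted_score(self._cohort([[2, 1, 0, 1]]), self._score())
        assert vals[0] == pytest.approx(0.238, abs=1e-12)

    def test_zero_dosages_zero_score(self):
        assert dm.weighted_score(self._cohort([[0, 0, 0, 0]]), self._score())[0] == 0

    def test_linearity_in_weights(self):
        score = self._score()
        doubled = dm.ScoreDefinition("x2", score.snp_ids, 2 * score.weights,
                                     score.effect_alleles, score.other_alleles)
        cohort = self._cohort([[2, 1, 0, 1], [1, 2, 2, 0]])
        np.testing.assert_allclose(dm.weighted_score(cohort, doubled),
                                   2 * dm.weighted_score(cohort, score))

    def test_missing_snp_is_an_error(self):
        cohort = self._cohort([[1, 1, 1]])
        with pytest.raises(KeyError, match="s3"):
            dm.weighted_score(cohort, self._score())


class TestFStatistic:
    def test_rs12916_from_published_interval(self):
        rec = next(r for r in dm.datasets.ldl_lowering_variants("HMGCR")
                   if r.snp_id == "rs12916")
        f = dm.f_statistic(rec)
        # se back-derived from the 95% CI (-0.081, -0.066)
        se = ((-0.066) - (-0.081)) / (2 * 1.959964)
        assert f == pytest.approx((0.073 / se) ** 2, rel=1e-4)
        assert f == pytest.approx(363.9, abs=0.2)

    def test_null_effect_is_flagged_weak(self, two_snp_iset):
        rec = make_variant(beta=0.0, se=0.1, pval=0.9)
        assert dm.f_statistic(rec) == 0.0

    def test_boundary_f_of_ten_is_flagged(self):
        # F must strictly exceed 10 to pass; the closest float at/below 10 is flagged
        ratio = float(np.nextafter(np.sqrt(10.0), 0.0))
        iset = dm.InstrumentSet(
            ["a"], [ratio * 0.01], [0.01], [0.0], [0.1],
            dm.LDMatrix.identity(["a"]))
        res = dm.f_statistic(iset)
        assert res.per_snp["a"] == pytest.approx(10.0)
        assert res.weak == ["a"] and not res.all_strong

    def test_set_level_report(self):
        iset = dm.InstrumentSet(
            ["a", "b"], [0.073, 0.01], [0.0038, 0.009], [0.0, 0.0], [0.1, 0.1],
            dm.LDMatrix.identity(["a", "b"]))
        res = dm.f_statistic(iset)
        assert res.min_f == pytest.approx((0.01 / 0.009) ** 2)
        assert res.weak == ["b"]
        # selection at genome-wide significance implies F above this bound
        assert res.p_threshold_bound == pytest.approx(29.72, abs=0.01)
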