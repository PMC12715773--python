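"""Carrier coding, cohort filters, and the three association analyses."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from strqc.association import (
    CARRIER,
    MISSING,
    NON_CARRIER,
    ThresholdSpec,
    best_threshold_scan,
    carrier_series,
    carrier_status,
    cohort_filter,
    distribution_analysis,
    external_frequency_comparison,
    literature_threshold_analysis,
    motif_count_comparison,
    results_frame,
    sensitivity_no_inheritance,
    specs_from_loci,
)
from strqc.io import LocusDefinition, MotifCountRecord
from strqc.simulate import SimulationConfig, als_panel, generate_cohort


def brute_carrier(sizes, lower, upper, inheritance, path_thr):
    """Independent enumeration-based carrier coder (no missing alleles)."""
    in_range = [lower <= s < upper for s in sizes]
    if upper != math.inf and any(s >= path_thr for s in sizes):
        return NON_CARRIER  # premutation excludes pathogenic-allele carriers
    if inheritance == "AD" or (inheritance == "XR" and len(sizes) == 1):
        return CARRIER if any(in_range) else NON_CARRIER
    return CARRIER if all(in_range) else NON_CARRIER


class TestCarrierCoding:
    @pytest.mark.parametrize(
        "sizes,kind,lower,upper,inh,expected",
        [
            ((12, 45), "pathogenic", 30, math.inf, "AD", CARRIER),
            ((12, 45), "pathogenic", 30, math.inf, "AR", NON_CARRIER),
            ((31, 45), "pathogenic", 30, math.inf, "AR", CARRIER),
            ((25, 45), "premutation", 24, 30, "AD", NON_CARRIER),  # pathogenic allele wins
            ((25, 27), "premutation", 24, 30, "AD", CARRIER),
            ((40,), "pathogenic", 38, math.inf, "XR", CARRIER),
        ],
    )
    def test_rule_examples(self, sizes, kind, lower, upper, inh, expected):
        spec = ThresholdSpec("L", kind, lower, upper)
        assert carrier_status(sizes, spec, inh, sex="male", pathogenic_threshold=30) == expected

    def test_exhaustive_agreement_with_enumeration(self):
        """All diploid genotypes with sizes <= 60, three inheritance modes."""
        spec_p = ThresholdSpec("L", "pathogenic", 30)
        spec_m = ThresholdSpec("L", "premutation", 24, 30)
        sizes = range(0, 61, 3)
        for a, b in itertools.combinations_with_replacement(sizes, 2):
            for inh in ("AD", "AR", "XR"):
                for spec in (spec_p, spec_m):
                    got = carrier_status((a, b), spec, inh, sex="female", pathogenic_threshold=30)
                    want = brute_carrier((a, b), spec.lower, spec.upper, inh, 30)
                    assert got == want, (a, b, inh, spec.kind)

    def test_missing_allele_propagates_when_determination_depends_on_it(self):
        spec = ThresholdSpec("L", "pathogenic", 30)
        assert carrier_status((12, None), spec, "AD") == MISSING
        assert carrier_status((45, None), spec, "AD") == CARRIER
        assert carrier_status((12, None), spec, "AR") == NON_CARRIER
        assert carrier_status((45, None), spec, "AR") == MISSING
        prem = ThresholdSpec("L", "premutation", 24, 30)
        assert carrier_status((25, None), prem, "AD", pathogenic_threshold=30) == MISSING

    def test_sex_required_for_diploid_x_locus(self):
        spec = ThresholdSpec("L", "pathogenic", 30)
        assert carrier_status((31, 31), spec, "XR", sex=None) == MISSING

    def test_fragment_limited_allele_counts_as_pathogenic(self):
        spec = ThresholdSpec("L", "pathogenic", 60)
        assert carrier_status(
            (10, 50), spec, "AD", fragment_limited=[False, True]
        ) == CARRIER
        assert carrier_status(
            (10, 50), spec, "AD", fragment_limited=[False, True],
            treat_limited_as_expanded=False,
        ) == NON_CARRIER

    def test_vectorized_series_matches_scalar(self, rng):
        rows = []
        for i in range(300):
            k = 1 if i % 7 == 0 else 2
            for j in range(k):
                rows.append(
                    {"sample_id": f"S{i:03d}", "locus_id": "L", "allele_index": j,
                     "size": int(rng.integers(0, 60)),
                     "missing": bool(rng.random() < 0.1),
                     "fragment_limited": bool(rng.random() < 0.05)}
                )
        alleles = pd.DataFrame(rows)
        sex = pd.Series("male", index=sorted(alleles["sample_id"].unique()))
        for kind, lower, upper in (("pathogenic", 30, math.inf), ("premutation", 24, 30)):
            spec = ThresholdSpec("L", kind, lower, upper)
            for inh in ("AD", "AR", "XR"):
                series = carrier_series(alleles, spec, inh, sex, pathogenic_threshold=30)
                for sid, grp in alleles.groupby("sample_id"):
                    grp = grp.sort_values("allele_index")
                    sizes = [None if m else s for s, m in zip(grp["size"], grp["missing"])]
                    want = carrier_status(
                        sizes, spec, inh, "male", list(grp["fragment_limited"]),
                        pathogenic_threshold=30,
                    )
                    assert series[sid] == want, (sid, inh, kind)


class TestCohortFilter:
    def _meta(self, rows):
        df = pd.DataFrame(rows)
        for i in range(1, 11):
            df[f"pc{i}"] = 0.0
        return df

    def test_filters_onset_and_country_deceased_fraction(self):
        rows = []
        # country A: 60% deceased; country B: 25% deceased
        for i in range(10):
            rows.append({"sample_id": f"A{i}", "status": 1, "sex": "male", "country": "A",
                         "onset_age": 50.0, "survival_months": 20.0, "event": i < 6})
        for i in range(8):
            rows.append({"sample_id": f"B{i}", "status": 1, "sex": "male", "country": "B",
                         "onset_age": 50.0, "survival_months": 20.0, "event": i < 2})
        rows.append({"sample_id": "young", "status": 1, "sex": "male", "country": "A",
                     "onset_age": 16.0, "survival_months": 20.0, "event": True})
        rows.append({"sample_id": "ctrl", "status": 0, "sex": "male", "country": "A",
                     "onset_age": np.nan, "survival_months": np.nan, "event": np.nan})
        out = cohort_filter(self._meta(rows))
        assert set(out["sample_id"]) == {f"A{i}" for i in range(10)}

    def test_invalid_survival_records_dropped(self):
        rows = [
            {"sample_id": "ok", "status": 1, "sex": "male", "country": "A",
             "onset_age": 50.0, "survival_months": 12.0, "event": True},
            {"sample_id": "neg", "status": 1, "sex": "male", "country": "A",
             "onset_age": 50.0, "survival_months": -3.0, "event": True},
            {"sample_id": "noonset", "status": 1, "sex": "male", "country": "A",
             "onset_age": np.nan, "survival_months": 12.0, "event": True},
        ]
        out = cohort_filter(self._meta(rows))
        assert list(out["sample_id"]) == ["ok"]


@pytest.fixture(scope="module")
def planted_cohort():
    cfg = SimulationConfig(n_cases=2600, n_controls=900, loci=als_panel(), seed=31)
    return generate_cohort(cfg, with_reads=False)


class TestLiteratureAnalysis:
    def test_planted_or_lies_within_fitted_ci(self, planted_cohort):
        c = planted_cohort
        res = literature_threshold_analysis(c.alleles, c.meta, c.loci, "susceptibility")
        df = results_frame(res)
        row = df[(df.locus_id == "C9L") & (df.kind == "pathogenic")].iloc[0]
        assert row["ci_low"] <= 16.0 <= row["ci_high"]
        assert row["p_bonferroni"] < 1e-3

    def test_null_loci_not_significant(self, planted_cohort):
        c = planted_cohort
        res = literature_threshold_analysis(c.alleles, c.meta, c.loci, "susceptibility")
        df = results_frame(res)
        null_rows = df[(df.locus_id.isin(["R1L", "XRL"])) & ~df.untestable]
        assert (null_rows["p_bonferroni"] > 0.05).all()

    def test_survival_hr_recovered(self, planted_cohort):
        c = planted_cohort
        res = literature_threshold_analysis(c.alleles, c.meta, c.loci, "survival")
        df = results_frame(res)
        row = df[(df.locus_id == "C9L") & (df.kind == "pathogenic")].iloc[0]
        assert row["ci_low"] <= 1.51 <= row["ci_high"]

    def test_onset_shift_recovered(self, planted_cohort):
        c = planted_cohort
        res = literature_threshold_analysis(c.alleles, c.meta, c.loci, "onset")
        df = results_frame(res)
        row = df[(df.locus_id == "C9L") & (df.kind == "pathogenic")].iloc[0]
        assert row["ci_low"] <= -2.4 <= row["ci_high"]

    def test_sparse_categories_untestable_for_progression(self, planted_cohort):
        c = planted_cohort
        res = literature_threshold_analysis(c.alleles, c.meta, c.loci, "survival")
        df = results_frame(res)
        sparse = df[df.n_carriers_case + df.n_carriers_control < 5]
        assert sparse["untestable"].all()


class TestSensitivityNoInheritance:
    def test_ar_locus_recoded_as_dominant(self):
        locus = LocusDefinition("ARL", "ARL", "CAG", "chr1", 0, 100, "AR", 30)
        alleles = pd.DataFrame(
            [
                {"sample_id": "S0", "locus_id": "ARL", "allele_index": 0, "size": 31,
                 "missing": False, "fragment_limited": False},
                {"sample_id": "S0", "locus_id": "ARL", "allele_index": 1, "size": 12,
                 "missing": False, "fragment_limited": False},
            ]
        )
        spec = specs_from_loci([locus])[0]
        assert carrier_series(alleles, spec, "AR")["S0"] == NON_CARRIER
        assert carrier_series(alleles, spec, "AD")["S0"] == CARRIER

    def test_ad_loci_unchanged(self, planted_cohort):
        c = planted_cohort
        primary = results_frame(
            literature_threshold_analysis(c.alleles, c.meta, c.loci, "susceptibility")
        )
        recoded = results_frame(
            sensitivity_no_inheritance(c.alleles, c.meta, c.loci, "susceptibility")
        )
        ad = primary.locus_id.isin(["C9L", "A2L"])
        pd.testing.assert_frame_equal(
            primary[ad].reset_index(drop=True), recoded[ad].reset_index(drop=True)
        )


class TestBestThresholdScan:
    def test_dosage_counting_examples(self):
        alleles = pd.DataFrame(
            [
                {"sample_id": "S0", "locus_id": "L", "allele_index": 0, "size": 10, "missing": False},
                {"sample_id": "S0", "locus_id": "L", "allele_index": 1, "size": 32, "missing": False},
            ]
        )
        from strqc.association import _dosage_matrix

        _, sizes, _ = _dosage_matrix(alleles, "L")
        assert np.nansum(sizes >= 30) == 1
        assert np.nansum(sizes >= 5) == 2
        assert np.nansum(sizes >= 40) == 0

    def test_dosage_totals_non_increasing_in_threshold(self, planted_cohort):
        from strqc.association import _dosage_matrix

        _, sizes, _ = _dosage_matrix(planted_cohort.alleles, "C9L")
        totals = [np.nansum(sizes >= t) for t in range(0, 60)]
        assert totals == sorted(totals, reverse=True)

    def test_recovers_planted_threshold(self, planted_cohort):
        c = planted_cohort
        sub = c.alleles[c.alleles.locus_id == "C9L"]
        _, best = best_threshold_scan(sub, c.meta, "susceptibility")
        assert abs(best["C9L"].threshold - 30) <= 2

    def test_agrees_with_literature_carrier_test_at_the_threshold(self, planted_cohort):
        """At the literature threshold of an AD locus with fully observed diploid
        genotypes, a positive dosage is exactly literature carrier status."""
        c = planted_cohort
        sub = c.alleles[c.alleles.locus_id == "C9L"]
        allr, _ = best_threshold_scan(sub, c.meta, "susceptibility")
        at30 = [r for r in allr if r.threshold == 30][0]
        lit = literature_threshold_analysis(
            c.alleles, c.meta, c.loci, "susceptibility",
            specs=[ThresholdSpec("C9L", "pathogenic", 30)],
            treat_limited_as_expanded=False,
        )[0]
        assert at30.n_carriers_case == lit.n_carriers_case
        assert at30.n_carriers_control == lit.n_carriers_control


class TestDistributionAnalysis:
    def test_max_and_sum_statistics(self):
        alleles = pd.DataFrame(
            [
                {"sample_id": "S0", "locus_id": "L", "allele_index": 0, "size": 10, "missing": False},
                {"sample_id": "S0", "locus_id": "L", "allele_index": 1, "size": 25, "missing": False},
                {"sample_id": "S1", "locus_id": "L", "allele_index": 0, "size": 7, "missing": True},
                {"sample_id": "S1", "locus_id": "L", "allele_index": 1, "size": 12, "missing": False},
            ]
        )
        from strqc.association import _dosage_matrix

        idx, sizes, n_called = _dosage_matrix(alleles, "L")
        n_obs = np.isfinite(sizes).sum(axis=1)
        assert np.nanmax(sizes[idx.get_loc("S0")]) == 25 and np.nansum(sizes[idx.get_loc("S0")]) == 35
        # S1 has a missing allele: max uses the observed one, sum is undefined
        assert n_obs[idx.get_loc("S1")] == 1 and n_called[idx.get_loc("S1")] == 2

    def test_planted_shift_detected_with_power(self, rng):
        n = 2500
        status = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        meta = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(n)], "status": status,
             "sex": np.where(rng.random(n) < 0.5, "male", "female"), "country": "NL"}
        )
        for i in range(1, 11):
            meta[f"pc{i}"] = rng.normal(size=n)
        base = rng.normal(20, 5, (n, 2)) + 1.5 * status[:, None]  # +0.3 SD in cases
        rows = []
        for i in range(n):
            for j in range(2):
                rows.append({"sample_id": f"S{i}", "locus_id": "L", "allele_index": j,
                             "size": max(int(base[i, j]), 1), "missing": False})
        res = distribution_analysis(pd.DataFrame(rows), meta, "susceptibility")
        df = results_frame(res)
        assert (df["p_bonferroni"] < 0.05).all()

    def test_log_transform_on_lognormal_sizes_at_least_as_powerful(self, rng):
        wins = 0
        for rep in range(6):
            r = np.random.default_rng(rep)
            n = 1200
            status = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
            meta = pd.DataFrame(
                {"sample_id": [f"S{i}" for i in range(n)], "status": status,
                 "sex": "male", "country": "NL"}
            )
            for i in range(1, 11):
                meta[f"pc{i}"] = 0.0
            log_sizes = r.normal(2.5, 0.8, (n, 2)) + 0.25 * status[:, None]
            rows = []
            for i in range(n):
                for j in range(2):
                    rows.append({"sample_id": f"S{i}", "locus_id": "L", "allele_index": j,
                                 "size": int(np.exp(log_sizes[i, j])) + 1, "missing": False})
            alleles = pd.DataFrame(rows)
            p_id = results_frame(distribution_analysis(alleles, meta, "susceptibility", "identity"))
            p_log = results_frame(distribution_analysis(alleles, meta, "susceptibility", "log"))
            wins += (p_log["p_raw"] <= p_id["p_raw"]).all()
        assert wins >= 4


class TestExternalComparison:
    def _panel(self, n, freq, rng, locus="L", thr=30.0):
        return pd.DataFrame(
            {"locus_id": locus, "threshold": thr, "kind": "pathogenic",
             "carrier": (rng.random(n) < freq).astype(int),
             "sex": np.where(rng.random(n) < 0.5, "male", "female")}
        )

    def test_identical_frequencies_not_significant(self, rng):
        internal = self._panel(1500, 0.05, rng)
        external = self._panel(1500, 0.05, rng)
        (res,) = external_frequency_comparison(internal, external)
        assert res.p_bonferroni > 0.05

    def test_direction_of_planted_frequency_difference(self, rng):
        internal = self._panel(1700, 0.045, rng)
        external = self._panel(4000, 0.028, rng)
        (res,) = external_frequency_comparison(internal, external)
        assert res.effect < 1.0  # carriers rarer in the external panel

    def test_zero_carriers_in_one_panel_still_finite(self, rng):
        internal = self._panel(300, 0.08, rng)
        external = self._panel(300, 0.0, rng)
        (res,) = external_frequency_comparison(internal, external)
        assert np.isfinite(res.effect) and res.effect < 1.0


class TestMotifComparison:
    def _records(self, counts_by_sample, motif="GGC", contig="chr1", start=10, end=90):
        return [
            MotifCountRecord(s, contig, start, end, motif, c)
            for s, c in counts_by_sample.items()
        ]

    def _meta(self, n, rng):
        meta = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(n)],
             "status": np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)],
             "sex": np.where(rng.random(n) < 0.5, "male", "female"), "country": "NL"}
        )
        for i in range(1, 11):
            meta[f"pc{i}"] = rng.normal(size=n)
        return meta

    def test_single_nucleotide_motifs_excluded(self, rng):
        loci = [LocusDefinition("L", "L", "GGC", "chr1", 0, 100, "AD", 30)]
        meta = self._meta(40, rng)
        records = self._records({f"S{i}": 5 for i in range(10)}, motif="CCCCC")
        assert motif_count_comparison(records, meta, loci) == []

    def test_overlapping_motif_tested_non_overlapping_skipped(self, rng):
        loci = [LocusDefinition("L", "L", "GGC", "chr1", 0, 100, "AD", 30)]
        meta = self._meta(60, rng)
        inside = self._records({f"S{i}": int(rng.integers(1, 9)) for i in range(20)}, motif="GGCCTG")
        outside = self._records({f"S{i}": 5 for i in range(20)}, motif="AAG", contig="chr2")
        results = motif_count_comparison(inside + outside, meta, loci)
        assert len(results) == 1 and results[0].kind == "GGCCTG"

    def test_null_counts_not_significant(self, rng):
        loci = [LocusDefinition("L", "L", "GGC", "chr1", 0, 100, "AD", 30)]
        meta = self._meta(200, rng)
        records = self._records(
            {f"S{i}": int(rng.integers(1, 10)) for i in range(200)}, motif="GGCCTG"
        )
        (res,) = motif_count_comparison(records, meta, loci)
        assert res.p_raw > 0.001
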