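"""Allele counting, cutoff derivation, calling rules and concordance."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gbmas.align import SiteObservation
from gbmas.call import (CALL_HET, CALL_HOM_NEG, CALL_HOM_POS, CALL_NO_CONTROL,
                        CALL_NO_DEPTH, CALL_NULL, CallingConfig,
                        call_genotype, call_rate, concordance, count_alleles,
                        derive_cutoffs, percent_favorable)
from gbmas.panel import BarcodeRecord, VariantSite

SITE = VariantSite("SNP10", 10, "A", "T")
CFG = CallingConfig()


def counts(n_A=0, n_C=0, n_G=0, n_T=0, n_N=0):
    d = {"n_A": n_A, "n_C": n_C, "n_G": n_G, "n_T": n_T, "n_N": n_N}
    d["total"] = sum(d.values())
    return d


class TestCountAlleles:
    def test_exact_tabulation(self):
        obs = [SiteObservation("S1", "M1", "SNP10", "A", 1.0)] * 6 \
            + [SiteObservation("S1", "M1", "SNP10", "T", 1.0)] * 4
        df = count_alleles(obs)
        row = df.iloc[0]
        assert (row["n_A"], row["n_T"], row["total"]) == (6, 4, 10)

    def test_zero_observation_keys_present_with_panel(self, toy_panel):
        df = count_alleles([], panel=toy_panel)
        assert len(df) == 2 * 2  # 2 samples x 2 markers x 1 site each
        assert (df["total"] == 0).all()

    def test_n_observations_counted_in_total(self):
        obs = [SiteObservation("S1", "M1", "SNP10", "N", 1.0)] * 3
        df = count_alleles(obs)
        assert df.iloc[0]["n_N"] == 3 and df.iloc[0]["total"] == 3


class TestPercentFavorable:
    def test_half(self):
        assert percent_favorable(counts(n_A=50, n_T=50), "A") == 50.0

    def test_one_in_six_full_precision(self):
        pct = percent_favorable(counts(n_A=1, n_T=5), "A")
        assert pct == pytest.approx(100 / 6)
        assert round(pct, 1) == 16.7

    def test_total_zero_is_undefined_not_zero(self):
        assert percent_favorable(counts(), "A") is None

    def test_n_reads_dilute_the_percent(self):
        assert percent_favorable(counts(n_A=5, n_N=5), "A") == 50.0


class TestDeriveCutoffs:
    def _table(self, rows):
        return pd.DataFrame([{"sample_id": s, "marker_id": "MK1", "site_id": SITE.site_id,
                              **counts(**c)} for s, c in rows])

    def _panel(self, toy_panel):
        return toy_panel

    def test_minimum_across_control_replicates(self, toy_panel):
        mk = toy_panel.markers[0]
        site = mk.sites[0]
        fav = site.favorable_base
        table = pd.DataFrame([
            {"sample_id": "S01", "marker_id": mk.marker_id, "site_id": site.site_id,
             **counts(**{f"n_{fav}": 521, "n_N": 479})},   # 52.1%
            {"sample_id": "S02", "marker_id": mk.marker_id, "site_id": site.site_id,
             **counts(**{f"n_{fav}": 503, "n_N": 497})},   # 50.3%
        ])
        samples = [BarcodeRecord("S01", "ACACACACAC", (mk.marker_id,)),
                   BarcodeRecord("S02", "GTGTGTGTGT", (mk.marker_id,))]
        cutoffs = derive_cutoffs(table, samples, toy_panel)
        by_key = {(c.marker_id, c.site_id): c for c in cutoffs}
        assert by_key[(mk.marker_id, site.site_id)].cutoff_percent == pytest.approx(50.3)

    def test_single_control_degenerates_to_its_value(self, toy_panel):
        mk = toy_panel.markers[0]
        site = mk.sites[0]
        fav = site.favorable_base
        table = pd.DataFrame([{"sample_id": "S01", "marker_id": mk.marker_id,
                               "site_id": site.site_id,
                               **counts(**{f"n_{fav}": 40, "n_N": 60})}])
        samples = [BarcodeRecord("S01", "ACACACACAC", (mk.marker_id,))]
        cutoffs = derive_cutoffs(table, samples, toy_panel)
        assert cutoffs[0].cutoff_percent == pytest.approx(40.0)

    def test_low_depth_control_yields_no_cutoff(self, toy_panel):
        mk = toy_panel.markers[0]
        site = mk.sites[0]
        fav = site.favorable_base
        table = pd.DataFrame([{"sample_id": "S01", "marker_id": mk.marker_id,
                               "site_id": site.site_id,
                               **counts(**{f"n_{fav}": 5})}])  # depth 5 < 10
        samples = [BarcodeRecord("S01", "ACACACACAC", (mk.marker_id,))]
        cutoffs = derive_cutoffs(table, samples, toy_panel)
        assert [(c.marker_id, c.site_id) for c in cutoffs if c.marker_id == mk.marker_id] == []


class TestCallGenotype:
    def test_above_cutoff_is_positive(self):
        call = call_genotype(counts(n_A=60, n_T=40), SITE, cutoff=50.0)
        assert call.call == CALL_HOM_POS

    def test_exactly_at_cutoff_is_positive(self):
        # "equal to or greater" — ties pass
        call = call_genotype(counts(n_A=50, n_T=50), SITE, cutoff=50.0)
        assert call.call == CALL_HOM_POS

    def test_below_cutoff_is_negative(self):
        call = call_genotype(counts(n_A=49, n_T=51), SITE, cutoff=50.0)
        assert call.call == CALL_HOM_NEG

    def test_depth_9_no_call_depth_10_called(self):
        low = call_genotype(counts(n_A=9), SITE, cutoff=50.0)
        assert low.call == CALL_NO_DEPTH
        ok = call_genotype(counts(n_A=10), SITE, cutoff=50.0)
        assert ok.call == CALL_HOM_POS

    def test_missing_cutoff_is_no_call_with_reason(self):
        call = call_genotype(counts(n_A=100), SITE, cutoff=None)
        assert call.call == CALL_NO_CONTROL
        assert "control" in call.reason

    def test_dominant_zero_depth_is_cautioned_null(self):
        call = call_genotype(counts(), SITE, cutoff=None, marker_mode="dominant_null")
        assert call.call == CALL_NULL
        assert call.caution_flag
        assert call.percent_favorable is None

    def test_dominant_present_is_positive_and_never_negative(self):
        call = call_genotype(counts(n_T=30), SITE, cutoff=None,
                             marker_mode="dominant_null")
        assert call.call == CALL_HOM_POS

    def test_dominant_trickle_is_no_call(self):
        call = call_genotype(counts(n_A=4), SITE, cutoff=None,
                             marker_mode="dominant_null")
        assert call.call == CALL_NO_DEPTH

    def test_het_band_requires_explicit_enabling(self):
        with pytest.raises(ValueError):
            CallingConfig(het_calling_enabled=True)
        cfg = CallingConfig(het_calling_enabled=True, het_band=(20.0, 35.0))
        call = call_genotype(counts(n_A=25, n_T=75), SITE, cutoff=50.0, config=cfg)
        assert call.call == CALL_HET

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n_fav=st.integers(0, 200), n_other=st.integers(0, 200),
           cut_lo=st.floats(0, 100), delta=st.floats(0, 50))
    def test_raising_cutoff_never_turns_negative_into_positive(
            self, n_fav, n_other, cut_lo, delta):
        c = counts(n_A=n_fav, n_T=n_other)
        lo = call_genotype(c, SITE, cutoff=cut_lo).call
        hi = call_genotype(c, SITE, cutoff=min(100.0, cut_lo + delta)).call
        if lo == CALL_HOM_NEG:
            assert hi == CALL_HOM_NEG
        if hi == CALL_HOM_POS:
            assert lo == CALL_HOM_POS


class TestCallRate:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "marker_id", "site_id",
                                           "call"])

    def test_all_called_is_100(self):
        rows = [(f"S{i}", "M1", "SNP1", CALL_HOM_POS) for i in range(24)]
        rate = call_rate(self._calls(rows))
        assert rate.iloc[0]["call_rate_percent"] == 100.0

    def test_one_no_call_of_24(self):
        rows = [(f"S{i}", "M1", "SNP1", CALL_HOM_POS) for i in range(23)]
        rows.append(("S23", "M1", "SNP1", CALL_NO_DEPTH))
        rate = call_rate(self._calls(rows))
        assert rate.iloc[0]["call_rate_percent"] == pytest.approx(95.8, abs=0.05)

    def test_all_no_call_is_0(self):
        rows = [(f"S{i}", "M1", "SNP1", CALL_NO_DEPTH) for i in range(5)]
        assert call_rate(self._calls(rows)).iloc[0]["call_rate_percent"] == 0.0

    def test_null_calls_count_as_confident(self):
        rows = [("S1", "M1", "SNP1", CALL_NULL), ("S2", "M1", "SNP1", CALL_HOM_POS)]
        assert call_rate(self._calls(rows)).iloc[0]["call_rate_percent"] == 100.0


class TestConcordance:
    def _table(self, calls):
        return pd.DataFrame([{"sample_id": f"S{i}", "marker_id": "M1", "call": c}
                             for i, c in enumerate(calls)])

    def test_identical_tables_fully_concordant(self):
        t = self._table([CALL_HOM_POS] * 10 + [CALL_HOM_NEG] * 14)
        result = concordance(t, t)
        assert result.overall == 1.0
        assert result.n_compared == 24

    def test_19_of_24_matched(self):
        a = self._table([CALL_HOM_POS] * 24)
        b = self._table([CALL_HOM_POS] * 19 + [CALL_HOM_NEG] * 5)
        result = concordance(a, b)
        assert result.overall == pytest.approx(19 / 24, abs=1e-9)
        assert round(result.overall, 3) == 0.792

    def test_disjoint_keys_undefined_with_warning(self):
        a = self._table([CALL_HOM_POS] * 3)
        b = self._table([CALL_HOM_POS] * 3)
        b["sample_id"] = ["X1", "X2", "X3"]
        with pytest.warns(UserWarning, match="undefined"):
            result = concordance(a, b)
        assert result.overall is None

    def test_no_call_excluded_by_default_included_on_flag(self):
        a = self._table([CALL_HOM_POS, CALL_HOM_POS, CALL_NO_DEPTH])
        b = self._table([CALL_HOM_POS, CALL_HOM_NEG, CALL_HOM_POS])
        default = concordance(a, b)
        assert default.n_compared == 2
        assert default.overall == 0.5
        included = concordance(a, b, include_no_call=True)
        assert included.n_compared == 3
        assert included.overall == pytest.approx(1 / 3)
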