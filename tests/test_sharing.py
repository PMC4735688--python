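import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarecoal.sharing import (
    CarrierCalls,
    Panel,
    PanelSite,
    ancestry_fraction,
    ancestry_fraction_se,
    build_sharing,
    call_carriers,
    group_summary,
    make_panel,
    panel_frequencies,
    projection,
    ratio_curve,
    read_counts_tsv,
    read_panel_tsv,
    resample_haploid,
    write_panel_tsv,
    write_read_counts_tsv,
)


def toy_panel():
    sites = [
        PanelSite("1", 100, "A", "C", (2, 0), 2),
        PanelSite("1", 200, "G", "T", (1, 1), 2),
        PanelSite("1", 300, "A", "G", (0, 3), 3),
        PanelSite("1", 400, "C", "T", (4, 1), 5),
    ]
    return make_panel(("NED", "IBS"), sites)


class TestCarrierCalling:
    def test_two_reads_is_a_carrier(self):
        calls = call_carriers({("1", 100): (2, 7)}, toy_panel())
        assert ("1", 100) in calls.sites

    def test_one_read_is_not(self):
        calls = call_carriers({("1", 100): (1, 9)}, toy_panel())
        assert not calls.sites

    def test_empty_read_map(self):
        assert call_carriers({}, toy_panel()).sites == set()

    def test_non_panel_site_ignored_and_tallied(self):
        calls = call_carriers({("1", 999): (5, 5)}, toy_panel())
        assert calls.ignored == 1 and not calls.sites

    @given(
        st.dictionaries(
            st.tuples(st.just("1"), st.sampled_from([100, 200, 300, 400])),
            st.tuples(st.integers(0, 30), st.integers(0, 30)).map(
                lambda t: (min(t), max(t))
            ),
            max_size=4,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_raising_min_support_never_adds_carriers(self, reads):
        lo = call_carriers(reads, toy_panel(), min_support=2).sites
        hi = call_carriers(reads, toy_panel(), min_support=3).sites
        assert hi <= lo


class TestSharingTable:
    def test_counts_enter_their_stratum(self):
        calls = CarrierCalls("s", {("1", 100)})
        t = build_sharing(calls, toy_panel())
        assert t.stratum("NED", 2) == 2 and t.stratum("IBS", 2) == 0

    def test_no_calls_gives_zero_table(self):
        t = build_sharing(CarrierCalls("s", set()), toy_panel())
        assert t.counts.sum() == 0

    def test_same_stratum_accumulates(self):
        calls = CarrierCalls("s", {("1", 100), ("1", 200)})
        t = build_sharing(calls, toy_panel())
        assert t.stratum("NED", 2) == 3 and t.stratum("IBS", 2) == 1


class TestCurvesAndProjection:
    def table(self, ned, ibs, stratum=1):
        t = build_sharing(CarrierCalls("s", set()), toy_panel())
        t.counts[0, stratum - 1] = ned
        t.counts[1, stratum - 1] = ibs
        return t

    def test_ratio_and_propagated_se(self):
        t = self.table(100, 50)
        row = ratio_curve(t, "NED", "IBS")[0]
        assert row["ratio"] == pytest.approx(2.0)
        assert row["se"] == pytest.approx(2.0 * math.sqrt(1 / 100 + 1 / 50))

    def test_equal_counts_ratio_one(self):
        assert ratio_curve(self.table(7, 7), "NED", "IBS")[0]["ratio"] == 1.0

    def test_zero_denominator_omitted(self):
        rows = ratio_curve(self.table(5, 0), "NED", "IBS")
        assert rows[0]["omitted"] is True

    def test_projection_values(self):
        assert projection(self.table(300, 100), "NED", "IBS").f == 0.75
        assert projection(self.table(5, 5), "NED", "IBS").f == 0.5
        assert projection(self.table(0, 9), "NED", "IBS").f == 0.0

    def test_projection_uses_only_low_strata(self):
        t = self.table(10, 10, stratum=1)
        t.counts[0, 6] = 1000  # stratum 7 ignored at max_stratum=5
        assert projection(t, "NED", "IBS", max_stratum=5).f == 0.5

    def test_projection_zero_total_errors(self):
        with pytest.raises(ValueError):
            projection(self.table(0, 0), "NED", "IBS")

    def test_clustered_se_reduces_to_binomial_for_singleton_sites(self):
        # when every called site carries exactly one shared allele, the
        # site-clustered variance equals the binomial f(1-f)/(N+I) rule
        sites = [
            PanelSite("1", i + 1, "A", "C", (1, 0) if i % 3 else (0, 1), 1)
            for i in range(60)
        ]
        panel = make_panel(("NED", "IBS"), sites)
        t = build_sharing(CarrierCalls("s", set(panel.sites)), panel)
        p = projection(t, "NED", "IBS")
        tot = t.counts[:2, :5].sum()
        assert p.se == pytest.approx(math.sqrt(p.f * (1 - p.f) / tot))

    def test_clustered_se_exceeds_binomial_for_clumped_sites(self):
        # alleles arriving in per-site clumps inflate the variance above
        # the allele-level binomial value
        sites = [
            PanelSite("1", i + 1, "A", "C", (4, 0) if i % 2 else (0, 4), 4)
            for i in range(40)
        ]
        panel = make_panel(("NED", "IBS"), sites)
        t = build_sharing(CarrierCalls("s", set(panel.sites)), panel)
        p = projection(t, "NED", "IBS")
        tot = t.counts[:2, :5].sum()
        assert p.se > math.sqrt(p.f * (1 - p.f) / tot)


class TestAncestryFraction:
    def test_midpoint(self):
        assert ancestry_fraction(0.5, 0.4, 0.6) == pytest.approx(50.0)

    def test_anchors(self):
        assert ancestry_fraction(0.4, 0.4, 0.6) == 0.0
        assert ancestry_fraction(0.6, 0.4, 0.6) == 100.0

    def test_no_clipping(self):
        assert ancestry_fraction(0.7, 0.4, 0.6) == pytest.approx(150.0)

    def test_equal_anchors_error(self):
        with pytest.raises(ValueError):
            ancestry_fraction(0.5, 0.4, 0.4)

    def test_se_propagation_reduces_to_query_term(self):
        se = ancestry_fraction_se(0.5, 0.02, 0.4, 0.0, 0.6, 0.0)
        assert se == pytest.approx(100 * 0.02 / 0.2)


class TestGroupSummary:
    def test_mean_and_spread(self):
        s = group_summary({"a": 30, "b": 40, "c": 50})
        assert s["mean"] == 40 and (s["min"], s["max"]) == (30, 50)

    def test_exclusion(self):
        s = group_summary({"a": 30, "b": 40, "c": 50}, exclusions=["c"])
        assert s["mean"] == 35 and s["excluded"] == ["c"]

    def test_all_excluded_errors(self):
        with pytest.raises(ValueError):
            group_summary({"a": 1}, exclusions=["a"])


class TestResampling:
    def test_extremes(self):
        freqs0 = {("1", i): 0.0 for i in range(50)}
        freqs1 = {("1", i): 1.0 for i in range(50)}
        assert resample_haploid(freqs0, seed=1).sites == set()
        assert len(resample_haploid(freqs1, seed=1).sites) == 50

    def test_binomial_expectation(self):
        rng = np.random.default_rng(3)
        freqs = {("1", i): float(f) for i, f in enumerate(rng.uniform(0, 0.5, 400))}
        mu = sum(freqs.values())
        sd = math.sqrt(sum(f * (1 - f) for f in freqs.values()))
        draws = [len(resample_haploid(freqs, seed=s).sites) for s in range(30)]
        assert abs(np.mean(draws) - mu) < 3 * sd

    def test_directional_sanity(self):
        # a pseudo-individual resampled from the NED panel shares more with
        # NED than one resampled from IBS
        rng = np.random.default_rng(0)
        sites = []
        for i in range(600):
            ned = int(rng.integers(0, 4))
            ibs = int(rng.integers(0, 4))
            if 1 <= ned + ibs <= 9:
                sites.append(PanelSite("1", i + 1, "A", "C", (ned, ibs), ned + ibs))
        panel = make_panel(("NED", "IBS"), sites)
        f = {}
        for pop in ("NED", "IBS"):
            calls = resample_haploid(panel_frequencies(panel, pop, 40), seed=11,
                                     sample_id=pop)
            t = build_sharing(calls, panel)
            f[pop] = projection(t, "NED", "IBS").f
        assert f["NED"] > f["IBS"]


class TestTsvRoundTrips:
    def test_panel(self):
        p = toy_panel()
        p2 = read_panel_tsv(write_panel_tsv(p))
        assert p2.populations == p.populations
        assert p2.sites == p.sites

    def test_read_counts(self):
        rc = {("1", 100): (2, 7), ("2", 5): (0, 3)}
        assert read_counts_tsv(write_read_counts_tsv(rc)) == rc
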