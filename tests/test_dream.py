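"""Signature classification, site profiling and the differential filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import radiomethyl as rm
from radiomethyl.dream import DreamConfig, classify_read


def pooled_t_oracle(a, b):
    """Textbook pooled two-sample t, independent of scipy.ttest_ind."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


class TestClassifyRead:
    @pytest.mark.parametrize(
        "read,expected",
        [
            ("CCGGGATTA", "methylated"),
            ("GGGTACCA", "unmethylated"),
            ("ATGGG", "invalid"),
            ("CCGGGGGG", "methylated"),  # meth prefix wins over GGG
            ("N", "invalid"),
        ],
    )
    def test_prefix_rule(self, read, expected):
        assert classify_read(read) == expected

    @pytest.mark.parametrize("bad", ["", "ccggg", "CCGGX"])
    def test_rejects_unnormalized_input(self, bad):
        with pytest.raises(ValueError):
            classify_read(bad)


class TestProfileSites:
    def test_simple_fraction(self, catalog):
        flank = catalog["flank"].iloc[0]
        reads = pd.DataFrame({
            "sample_id": ["s"] * 8,
            "site_id": [catalog["site_id"].iloc[0]] * 8,
            "read": ["CCGGG" + flank] * 6 + ["GGG" + flank] * 2,
        })
        prof, _ = rm.profile_sites(reads, catalog, DreamConfig(min_depth=1))
        row = prof[(prof.site_id == catalog["site_id"].iloc[0]) &
                   (prof.sample_id == "s")].iloc[0]
        assert row.n_meth == 6 and row.n_unmeth == 2
        assert row.fraction == pytest.approx(0.75)

    def test_counts_partition_reads(self, profiled):
        profiles, qc, _, _ = profiled
        total = (profiles.n_meth + profiles.n_unmeth + profiles.n_invalid).sum()
        assert total + qc.n_unmapped.sum() == 200 * 20 * 16

    def test_zero_read_site_excluded(self, catalog):
        reads = pd.DataFrame({
            "sample_id": ["s"], "site_id": [catalog["site_id"].iloc[0]],
            "read": ["CCGGG" + catalog["flank"].iloc[0]],
        })
        prof, _ = rm.profile_sites(reads, catalog, DreamConfig(min_depth=1))
        other = prof[prof.site_id == catalog["site_id"].iloc[1]].iloc[0]
        assert other.excluded and np.isnan(other.fraction)

    def test_below_min_depth_has_undefined_fraction(self, catalog):
        sid, flank = catalog[["site_id", "flank"]].iloc[0]
        reads = pd.DataFrame({"sample_id": ["s"] * 5, "site_id": [sid] * 5,
                              "read": ["CCGGG" + flank] * 5})
        prof, _ = rm.profile_sites(reads, catalog, DreamConfig(min_depth=20))
        row = prof[(prof.site_id == sid)].iloc[0]
        assert row.excluded and np.isnan(row.fraction)

    def test_fraction_recovers_binomial_truth(self, small_genome, catalog):
        truth = rm.TruthMethylation(
            pd.DataFrame({"site_id": ["site_0003"], "sample_id": ["s1"],
                          "fraction": [0.30]}),
            {"s1": "g"},
        )
        tags = rm.generate_dream_tags(small_genome, truth, depth=5000, seed=8)
        prof, _ = rm.profile_sites(tags, catalog)
        frac = prof.loc[prof.site_id == "site_0003", "fraction"].iloc[0]
        assert abs(frac - 0.30) < 3 * np.sqrt(0.3 * 0.7 / 5000)

    def test_flank_lookup_matches_provenance(self, small_genome, catalog):
        truth = rm.TruthMethylation(
            pd.DataFrame({"site_id": ["site_0001", "site_0002"],
                          "sample_id": ["s1", "s1"], "fraction": [0.1, 0.9]}),
            {"s1": "g"},
        )
        tags = rm.generate_dream_tags(small_genome, truth, depth=100, seed=9)
        by_id, _ = rm.profile_sites(tags, catalog)
        by_flank, _ = rm.profile_sites(tags.drop(columns="site_id"), catalog)
        cols = ["site_id", "sample_id", "n_meth", "n_unmeth"]
        a = by_id[cols].sort_values(cols[:2]).reset_index(drop=True)
        b = by_flank[cols].sort_values(cols[:2]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_unmapped_reads_are_counted_not_dropped(self, catalog):
        reads = pd.DataFrame({
            "sample_id": ["s", "s"],
            "read": ["CCGGG" + "T" * 40, "GGG" + "A" * 40],
        })
        _, qc = rm.profile_sites(reads, catalog)
        assert qc.n_unmapped.iloc[0] == 2


class TestExcludeRepetitive:
    @pytest.fixture()
    def site_frame(self):
        cat = pd.DataFrame({"site_id": ["a", "b", "c"], "contig": ["c1"] * 3,
                            "pos": [100, 150, 400]})
        res = pd.DataFrame({"site_id": ["a", "b", "c"], "x": [1, 2, 3]})
        return cat, res

    def test_half_open_boundaries(self, site_frame):
        cat, res = site_frame
        out = rm.exclude_repetitive(res, cat, [("c1", 50, 150)])
        assert list(out.site_id) == ["b", "c"]  # 100 removed, 150 kept

    def test_empty_repeats_is_identity(self, site_frame):
        cat, res = site_frame
        out = rm.exclude_repetitive(res, cat, [])
        pd.testing.assert_frame_equal(out, res)


class TestDifferentialTags:
    def test_identical_groups_fail_filter(self, catalog):
        rows = []
        for s in range(8):
            rows.append(("site_0000", f"a{s}", 0.4))
            rows.append(("site_0000", f"b{s}", 0.4))
        prof = pd.DataFrame(rows, columns=["site_id", "sample_id", "fraction"])
        prof[["n_meth", "n_unmeth"]] = 40, 60
        groups = {f"a{s}": "A" for s in range(8)} | {f"b{s}": "B" for s in range(8)}
        res = rm.differential_tags(prof, groups)
        assert res.difference_pp.iloc[0] == 0
        assert not res.passes_filter.iloc[0]

    def test_t_on_fractions_matches_textbook_oracle(self):
        gen = np.random.default_rng(12)
        fa, fb = gen.uniform(0.2, 0.4, 8), gen.uniform(0.3, 0.6, 8)
        rows = [("s0", f"a{i}", f) for i, f in enumerate(fa)]
        rows += [("s0", f"b{i}", f) for i, f in enumerate(fb)]
        prof = pd.DataFrame(rows, columns=["site_id", "sample_id", "fraction"])
        prof[["n_meth", "n_unmeth"]] = 50, 50
        groups = {f"a{i}": "A" for i in range(8)} | {f"b{i}": "B" for i in range(8)}
        res = rm.differential_tags(prof, groups)
        _, p_oracle = pooled_t_oracle(fa, fb)
        assert res.p_value.iloc[0] == pytest.approx(p_oracle, abs=1e-10)

    def test_underpowered_site_marked_untested(self):
        prof = pd.DataFrame(
            [("s0", "a0", 0.2), ("s0", "b0", 0.5), ("s0", "b1", 0.6)],
            columns=["site_id", "sample_id", "fraction"],
        )
        prof[["n_meth", "n_unmeth"]] = 10, 10
        res = rm.differential_tags(prof, {"a0": "A", "b0": "B", "b1": "B"})
        assert not res.tested.iloc[0] and not res.passes_filter.iloc[0]

    def test_fisher_variant_runs_on_pooled_counts(self):
        prof = pd.DataFrame(
            [("s0", "a0", 0.1, 10, 90), ("s0", "a1", 0.1, 10, 90),
             ("s0", "b0", 0.5, 50, 50), ("s0", "b1", 0.5, 50, 50)],
            columns=["site_id", "sample_id", "fraction", "n_meth", "n_unmeth"],
        )
        groups = {"a0": "A", "a1": "A", "b0": "B", "b1": "B"}
        res = rm.differential_tags(
            prof, groups, DreamConfig(test_kind="fisher_on_pooled_counts")
        )
        oracle = stats.fisher_exact([[20, 180], [100, 100]]).pvalue
        assert res.p_value.iloc[0] == pytest.approx(oracle, abs=1e-12)
        assert res.passes_filter.iloc[0]

    def test_filter_monotone_in_thresholds(self, profiled):
        profiles, _, truth, _ = profiled
        base = rm.differential_tags(profiles, truth.groups, DreamConfig())
        stricter = rm.differential_tags(
            profiles, truth.groups, DreamConfig(diff_threshold=10.0, p_threshold=0.01)
        )
        passed_strict = set(stricter.loc[stricter.passes_filter, "site_id"])
        passed_base = set(base.loc[base.passes_filter, "site_id"])
        assert passed_strict <= passed_base

    def test_planted_differential_sites_detected(self, profiled):
        profiles, _, truth, diff_sites = profiled
        res = rm.differential_tags(profiles, truth.groups)
        detected = set(res.loc[res.passes_filter, "site_id"])
        assert set(diff_sites) <= detected
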