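"""Island detection against a brute-force oracle; promoter annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import radiomethyl as rm
from radiomethyl.annotate import detect_islands, gc_fraction, obs_exp_cpg


def brute_force_islands(seq, min_gc=0.6, min_oe=0.6, w=200):
    """Enumerate every window by direct string counting, then merge."""
    passing = []
    for i in range(len(seq) - w + 1):
        win = seq[i : i + w]
        non_n = w - win.count("N")
        c, g = win.count("C"), win.count("G")
        if non_n == 0 or c == 0 or g == 0:
            continue
        gc = (c + g) / non_n
        oe = win.count("CG") * w / (c * g)
        if gc > min_gc and oe > min_oe:
            passing.append((i, i + w))
    merged = []
    for s, e in passing:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


class TestComposition:
    @pytest.mark.parametrize("seq,expected", [
        ("ATAT", 0.0), ("GCGC", 1.0), ("ACGTN", 0.5),
    ])
    def test_gc_fraction(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_gc_fraction_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_fraction("NNNN")

    @pytest.mark.parametrize("seq,expected", [
        ("CGCG", 2.0), ("CCGG", 1.0), ("CATG", 0.0),
    ])
    def test_obs_exp_cpg(self, seq, expected):
        assert obs_exp_cpg(seq) == pytest.approx(expected)

    def test_obs_exp_undefined_without_c_and_g(self):
        with pytest.raises(ValueError):
            obs_exp_cpg("AAAA")


class TestDetectIslands:
    def test_cg_repeat_is_one_island_spanning_sequence(self):
        seq = "CG" * 150
        isl = detect_islands(seq)
        assert [(i.start, i.end) for i in isl] == [(0, 300)]

    def test_at_repeat_has_no_islands(self):
        assert detect_islands("AT" * 150) == []

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            detect_islands("ACGT" * 10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_mosaics(self, seed):
        gen = np.random.default_rng(seed)
        # mosaic of AT-rich background and CpG-rich patches, <= 2 kb
        parts = []
        for _ in range(gen.integers(2, 6)):
            if gen.random() < 0.5:
                parts.append("".join(gen.choice(list("ACGT"), size=gen.integers(100, 400),
                                                p=[0.3, 0.2, 0.2, 0.3])))
            else:
                n = int(gen.integers(100, 300))
                parts.append("".join(gen.choice(["CG", "C", "G", "A", "T"],
                                                size=n, p=[0.3, 0.2, 0.2, 0.15, 0.15])))
        seq = "".join(parts)[:2000]
        if len(seq) < 200:
            seq = seq + "A" * (200 - len(seq))
        got = [(i.start, i.end) for i in detect_islands(seq)]
        assert got == brute_force_islands(seq)

    def test_sorted_and_non_overlapping(self, small_genome):
        isl = detect_islands(small_genome.sequences["contig_0"])
        spans = [(i.start, i.end) for i in isl]
        assert spans == sorted(spans)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))


class TestPromoterHits:
    def hits(self, site_pos, tss_pos, strand):
        sites = pd.DataFrame({"site_id": ["s"], "contig": ["c"], "pos": [site_pos]})
        tss = pd.DataFrame({"gene": ["G"], "contig": ["c"], "pos": [tss_pos],
                            "strand": [strand]})
        return rm.promoter_hits(sites, tss).iloc[0]

    def test_upstream_on_plus_strand(self):
        h = self.hits(5_000, 5_800, "+")
        assert h.distance == -800 and h.within_window

    def test_beyond_window_on_plus_strand(self):
        h = self.hits(5_000, 6_100, "+")
        assert h.distance == -1_100 and not h.within_window

    def test_inclusive_boundary_on_minus_strand(self):
        h = self.hits(5_000, 4_000, "-")
        assert h.distance == -1_000 and h.within_window

    def test_unknown_contig_raises(self):
        sites = pd.DataFrame({"site_id": ["s"], "contig": ["weird"], "pos": [5]})
        tss = pd.DataFrame({"gene": ["G"], "contig": ["c"], "pos": [1],
                            "strand": ["+"]})
        with pytest.raises(KeyError):
            rm.promoter_hits(sites, tss, contigs={"c"})


def _narrowing_fixture(n_passing=40, n_qualifying=6):
    """Passing tags with exactly n_qualifying island+promoter sites."""
    rows, cat, tss, islands = [], [], [], []
    for i in range(n_passing):
        sid = f"t{i:03d}"
        if i < n_qualifying:  # in island and near TSS
            pos = 10_000 + i * 5_000
            islands.append(("c", pos - 50, pos + 150))
            tss.append((f"G{i}", "c", pos + 400, "+"))
        elif i % 3 == 0:  # island, no TSS nearby
            pos = 400_000 + i * 5_000
            islands.append(("c", pos - 50, pos + 150))
        elif i % 3 == 1:  # TSS nearby, no island
            pos = 700_000 + i * 5_000
            tss.append((f"H{i}", "c", pos + 300, "-"))
        else:  # neither
            pos = 900_000 + i * 5_000
        cat.append((sid, "c", pos))
        rows.append((sid, 0.2, 0.4, 20.0, 0.01, True, True))
    differential = pd.DataFrame(
        rows, columns=["site_id", "mean_a", "mean_b", "difference_pp",
                       "p_value", "tested", "passes_filter"])
    catalog = pd.DataFrame(cat, columns=["site_id", "contig", "pos"])
    tss_tab = pd.DataFrame(tss, columns=["gene", "contig", "pos", "strand"])
    return differential, catalog, islands, tss_tab


class TestSelectPromoterTags:
    def test_exactly_the_planted_tags_are_retained(self):
        differential, catalog, islands, tss = _narrowing_fixture()
        out = rm.select_promoter_tags(differential, catalog, islands, tss)
        assert sorted(out.site_id) == [f"t{i:03d}" for i in range(6)]

    def test_output_subset_of_passing_input(self):
        differential, catalog, islands, tss = _narrowing_fixture()
        differential.loc[0, "passes_filter"] = False
        out = rm.select_promoter_tags(differential, catalog, islands, tss)
        assert "t000" not in set(out.site_id)

    def test_adding_a_tss_never_removes_a_tag(self):
        differential, catalog, islands, tss = _narrowing_fixture()
        before = set(rm.select_promoter_tags(differential, catalog, islands, tss).site_id)
        extra = pd.concat([tss, pd.DataFrame(
            [("NEW", "c", 400_000 + 3 * 5_000 + 100, "+")], columns=tss.columns)],
            ignore_index=True)
        after = set(rm.select_promoter_tags(differential, catalog, islands, extra).site_id)
        assert before <= after

    def test_disjunction_mode_keeps_window_only_tags(self):
        differential, catalog, islands, tss = _narrowing_fixture()
        out = rm.select_promoter_tags(differential, catalog, islands, tss,
                                      require_island=False)
        assert any(s.startswith("t") and int(s[1:]) % 3 == 1 and int(s[1:]) >= 6
                   for s in out.site_id)
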