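import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from famcons import conservation_scan as cs
from famcons.conservation_scan import (
    HcrSet,
    ScanParams,
    bh_adjust,
    call_hcrs,
    chrom_background,
    count_window,
    enumerate_windows,
    fisher_exact_2x2,
    genes_in_regions,
    scan_contig,
)
from famcons.genome_io import GeneTable, HET, SNV

from conftest import brute_force_window_counts, make_callset, random_toy_panel

import pandas as pd


class TestScanParams:
    def test_defaults_and_tile(self):
        p = ScanParams()
        assert (p.bin_size, p.step_size) == (100_000, 10_000)
        assert p.tile_offset == 45_000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"step_size": 0},
            {"step_size": 200_000},
            {"coverage_fraction": 1.0},
            {"alpha_adj": 0.0},
            {"mode": "bogus"},
        ],
    )
    def test_rejects_bad_params(self, kwargs):
        with pytest.raises(ValueError):
            ScanParams(**kwargs)


class TestEnumerateWindows:
    @pytest.mark.parametrize(
        "length,expected_n",
        [(1_000_000, 91), (99_999, 0), (100_000, 1), (109_999, 1), (110_000, 2)],
    )
    def test_window_count_closed_form(self, length, expected_n):
        w = enumerate_windows(length, ScanParams())
        assert len(w) == expected_n
        if expected_n:
            assert w[0] == 0
            assert w[-1] + 100_000 <= length

    def test_first_and_last_window(self):
        w = enumerate_windows(1_000_000, ScanParams())
        assert w[0] == 0 and w[-1] == 900_000


class TestCountWindow:
    def test_all_conserved_without_variants(self):
        panel = [
            make_callset("a", [], mask={"chr1": [(0, 100_000)]}),
            make_callset("b", [], mask={"chr1": [(0, 100_000)]}),
        ]
        assert count_window(("chr1", 0, 100_000), panel) == (100_000, 0, 100_000)

    def test_het_union_over_species(self):
        het_a = [("chr1", p, HET, SNV) for p in (10, 20, 30, 40, 50)]
        het_b = [("chr1", p, HET, SNV) for p in (10, 20)]
        panel = [
            make_callset("a", het_a, mask={"chr1": [(0, 100_000)]}),
            make_callset("b", het_b, mask={"chr1": [(0, 100_000)]}),
        ]
        assert count_window(("chr1", 0, 100_000), panel) == (99_995, 5, 100_000)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            count_window(("chr1", 0, 100), [])

    def test_matches_brute_force_on_random_panels(self, rng):
        for _ in range(10):
            panel = random_toy_panel(rng)
            got = count_window(("chr1", 0, 10_000), panel)
            assert got == brute_force_window_counts(("chr1", 0, 10_000), panel)

    def test_hom_alt_does_not_break_zygosity_mode(self):
        from famcons.genome_io import HOM_ALT

        panel = [
            make_callset("a", [("chr1", 5, HOM_ALT, SNV)], mask={"chr1": [(0, 100)]}),
            make_callset("b", [], mask={"chr1": [(0, 100)]}),
        ]
        assert count_window(("chr1", 0, 100), panel) == (100, 0, 100)
        # identity mode: differing homozygous states break conservation
        got = count_window(("chr1", 0, 100), panel, ScanParams(mode="identity"))
        assert got == (99, 1, 100)


class TestChromBackground:
    def test_equals_single_window_on_window_sized_contig(self, rng):
        panel = random_toy_panel(rng, length=10_000)
        bg = chrom_background("chr1", 10_000, panel)
        cons, noncons, _ = count_window(("chr1", 0, 10_000), panel)
        assert (bg.n_conserved_total, bg.n_nonconserved_total) == (cons, noncons)

    def test_no_coverage_is_degenerate_not_fatal(self):
        panel = [make_callset("a", [], mask={"chr1": []})]
        bg = chrom_background("chr1", 1_000, panel)
        assert (bg.n_conserved_total, bg.n_nonconserved_total) == (0, 0)
        assert math.isnan(bg.nonconserved_fraction)


class TestFisher:
    def test_modal_table_gives_one(self):
        assert fisher_exact_2x2(5, 5, 50, 50) == pytest.approx(1.0)

    def test_extreme_table_enumeration_value(self):
        # support a in 0..10; only the two extreme tables are as improbable
        assert fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(2 / 184756, rel=1e-9)

    def test_empty_table_convention(self):
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0
        assert fisher_exact_2x2(3, 0, 5, 0) == 1.0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_agrees_with_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 120, 4))
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                scipy_fisher([[a, b], [c, d]])[1], rel=1e-7, abs=1e-12
            )

    def test_agrees_with_scipy_on_large_tables(self, rng):
        for _ in range(20):
            a = int(rng.integers(50_000, 100_000))
            b = int(rng.integers(100, 2_000))
            c = int(rng.integers(1_000_000, 5_000_000))
            d = int(rng.integers(5_000, 60_000))
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                scipy_fisher([[a, b], [c, d]])[1], rel=1e-6, abs=1e-12
            )


class TestBH:
    def test_step_up_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.5]).tolist() == [0.5]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=200)
    def test_monotone_and_dominates_raw(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _windows_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "n_conserved", "n_nonconserved",
            "n_covered", "usable", "p_raw", "p_adj",
        ],
    )


class TestCallHcrs:
    BG = {"chr1": cs.ChromBackground("chr1", 1_000_000, 10_000)}

    def test_middle_tile_extraction(self):
        w = _windows_frame(
            [("chr1", 0, 100_000, 99_000, 10, 99_010, True, 1e-9, 1e-6)]
        )
        h = call_hcrs(w, ScanParams(), self.BG)
        assert h.intervals["chr1"].tolist() == [[45_000, 55_000]]
        assert h.total_length == 10_000

    def test_adjacent_tiles_merge(self):
        w = _windows_frame(
            [
                ("chr1", 0, 100_000, 99_000, 10, 99_010, True, 1e-9, 1e-6),
                ("chr1", 10_000, 110_000, 99_000, 10, 99_010, True, 1e-9, 1e-6),
            ]
        )
        h = call_hcrs(w, ScanParams(), self.BG)
        assert h.intervals["chr1"].tolist() == [[45_000, 65_000]]
        assert h.total_length == 20_000
        assert h.unmerged_total == 20_000

    def test_no_calls(self):
        w = _windows_frame(
            [("chr1", 0, 100_000, 99_000, 10, 99_010, True, 0.5, 0.9)]
        )
        h = call_hcrs(w, ScanParams(), self.BG)
        assert h.intervals == {} and h.total_length == 0

    def test_require_reduced_blocks_elevated_windows(self):
        # window *more* variable than background: significant but not reduced
        w = _windows_frame(
            [("chr1", 0, 100_000, 90_000, 9_000, 99_000, True, 1e-9, 1e-6)]
        )
        assert call_hcrs(w, ScanParams(), self.BG).total_length == 0
        relaxed = ScanParams(require_reduced=False)
        assert call_hcrs(w, relaxed, self.BG).total_length == 10_000

    def test_unusable_window_never_called(self):
        w = _windows_frame(
            [("chr1", 0, 100_000, 70_000, 7, 70_007, False, 1e-9, 1e-6)]
        )
        assert call_hcrs(w, ScanParams(), self.BG).total_length == 0

    def test_total_is_multiple_of_step_and_order_invariant(self, rng):
        rows = []
        for s in rng.choice(200, size=30, replace=False) * 10_000:
            rows.append(("chr1", int(s), int(s) + 100_000, 99_000, 10, 99_010, True, 1e-9, 1e-6))
        w = _windows_frame(rows)
        h1 = call_hcrs(w, ScanParams(), self.BG)
        h2 = call_hcrs(w.sample(frac=1, random_state=7), ScanParams(), self.BG)
        assert h1.total_length % 10_000 == 0
        assert {c: a.tolist() for c, a in h1.intervals.items()} == {
            c: a.tolist() for c, a in h2.intervals.items()
        }


class TestScanContig:
    def test_usable_threshold_is_strict(self):
        # exactly 80% joint coverage -> excluded
        panel = [make_callset("a", [], mask={"chr1": [(0, 80_000)]})]
        df, _ = scan_contig("chr1", 100_000, panel, ScanParams())
        assert not df["usable"].iloc[0]
        panel = [make_callset("a", [], mask={"chr1": [(0, 80_001)]})]
        df, _ = scan_contig("chr1", 100_000, panel, ScanParams())
        assert df["usable"].iloc[0]

    def test_window_invariant_and_background_consistency(self, rng):
        panel = random_toy_panel(rng, length=10_000)
        p = ScanParams(bin_size=1_000, step_size=200)
        df, bg = scan_contig("chr1", 10_000, panel, p)
        assert (df["n_conserved"] + df["n_nonconserved"] == df["n_covered"]).all()
        assert (df["n_covered"] <= p.bin_size).all()
        cons, noncons, _ = count_window(("chr1", 0, 10_000), panel, p)
        assert (bg.n_conserved_total, bg.n_nonconserved_total) == (cons, noncons)


def _mk_gene_table(rows):
    return GeneTable(
        genes=pd.DataFrame(
            rows, columns=["gene_id", "contig", "start", "end", "symbol"]
        )
    )


class TestGenesInRegions:
    def test_overlap_semantics_half_open(self):
        hcr = HcrSet("fam1", {"chr1": np.array([[45_000, 55_000]])})
        genes = _mk_gene_table(
            [
                ("g1", "chr1", 50_000, 60_000, "A"),  # overlaps by 5 kb
                ("g2", "chr1", 55_000, 60_000, "B"),  # touches only: out
            ]
        )
        out = genes_in_regions({"fam1": hcr}, {"fam1": genes})
        assert out["per_family"]["fam1"] == {"A"}

    def test_three_family_partition_matches_hand_enumeration(self):
        hcrs = {
            f: HcrSet(f, {"chr1": np.array([[0, 1_000]])})
            for f in ("felidae", "hominidae", "bovidae")
        }
        tables = {
            "felidae": _mk_gene_table(
                [("f1", "chr1", 0, 10, "SHARED"), ("f2", "chr1", 20, 30, "CATONLY"),
                 ("f3", "chr1", 40, 50, "CATAPE"), ("f4", "chr1", 5_000, 5_100, "FAROFF")]
            ),
            "hominidae": _mk_gene_table(
                [("h1", "chr1", 0, 10, "SHARED"), ("h2", "chr1", 20, 30, "CATAPE"),
                 ("h3", "chr1", 40, 50, "APEONLY")]
            ),
            "bovidae": _mk_gene_table(
                [("b1", "chr1", 0, 10, "SHARED"), ("b2", "chr1", 20, 30, "COWONLY")]
            ),
        }
        out = genes_in_regions(hcrs, tables)
        assert out["shared"] == {"SHARED"}
        assert out["specific"] == {
            "felidae": {"CATONLY"},
            "hominidae": {"APEONLY"},
            "bovidae": {"COWONLY"},
        }
        assert out["per_family"]["felidae"] == {"SHARED", "CATONLY", "CATAPE"}
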