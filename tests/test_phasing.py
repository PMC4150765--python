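"""Promoter windows, phasing labels, NFR widths, and TSS-relative geometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nucleoshift.core import Nucleosome, TSSRecord
from nucleoshift.phasing import (
    assign_and_label,
    nfr_table,
    nfr_width,
    occupancy_expression_correlation,
    promoter_window,
    promoter_windows_frame,
    repositioned_tss_profile,
    tss_relative_position,
)


def _windows(*tss_records):
    return promoter_windows_frame(list(tss_records))


class TestPromoterWindow:
    def test_plus_strand_span(self):
        w = promoter_window(TSSRecord("G", "chr1", 100_000, "+"))
        assert (w.interval.start, w.interval.end) == (92_500, 102_500)

    def test_minus_strand_mirrors(self):
        w = promoter_window(TSSRecord("G", "chr1", 100_000, "-"))
        assert (w.interval.start, w.interval.end) == (97_500, 107_500)

    def test_clipped_at_chromosome_start(self):
        w = promoter_window(TSSRecord("G", "chr1", 5000, "+"))
        assert (w.interval.start, w.interval.end) == (0, 7_500)
        assert w.interval.contains(w.tss)


class TestRelativePosition:
    @pytest.mark.parametrize(
        "center,tss,strand,expected",
        [(99_800, 100_000, "+", -200), (100_300, 100_000, "-", -300), (100_000, 100_000, "+", 0)],
    )
    def test_signed_distance(self, center, tss, strand, expected):
        t = TSSRecord("G", "chr1", tss, strand)
        assert tss_relative_position(center, t) == expected

    def test_chromosome_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tss_relative_position(Nucleosome("chr2", 500), TSSRecord("G", "chr1", 100, "+"))


class TestLabels:
    def _label_one_gene(self, rel_positions, strand="+"):
        tss = 100_000
        t = TSSRecord("G", "chr1", tss, strand)
        centers = [tss + r if strand == "+" else tss - r for r in rel_positions]
        nucs = [Nucleosome("chr1", c) for c in centers]
        phased, freq, _ = assign_and_label(nucs, _windows(t))
        return phased.sort_values("rel_pos"), freq

    def test_sequential_labels_outward_from_tss(self):
        phased, _ = self._label_one_gene([-180, 50, 250, 450])
        assert list(phased["label"]) == [-1, 1, 2, 3]

    def test_downstream_only_gene_has_no_minus_one(self):
        phased, _ = self._label_one_gene([50, 250])
        assert list(phased["label"]) == [1, 2]

    def test_tss_centered_nucleosome_is_plus_one(self):
        phased, _ = self._label_one_gene([0, -100])
        assert dict(zip(phased["rel_pos"], phased["label"])) == {-100: -1, 0: 1}

    def test_label_frequencies_sum_to_100(self, small_dataset, small_windows):
        _, freq, _ = assign_and_label(small_dataset.nucleosomes_before, small_windows)
        assert freq.sum() == pytest.approx(100.0)

    def test_labels_match_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            tss = 50_000
            strand = rng.choice(["+", "-"])
            t = TSSRecord("G", "chr1", tss, str(strand))
            rel = rng.choice(np.arange(-7400, 2400), size=rng.integers(1, 50), replace=False)
            centers = tss + rel if strand == "+" else tss - rel
            nucs = [Nucleosome("chr1", int(c)) for c in centers]
            phased, _, _ = assign_and_label(nucs, _windows(t))
            # oracle: sort rel positions, enumerate outward from the TSS
            srt = sorted(rel)
            n_up = sum(1 for r in srt if r < 0)
            expected = {r: (i - n_up if i < n_up else i - n_up + 1) for i, r in enumerate(srt)}
            got = dict(zip(phased["rel_pos"], phased["label"]))
            assert got == expected

    def test_strand_symmetry_under_mirroring(self):
        tss = 50_000
        rel = [-300, -150, 40, 230]
        plus = TSSRecord("G", "chr1", tss, "+")
        phased_p, _, _ = assign_and_label(
            [Nucleosome("chr1", tss + r) for r in rel], _windows(plus))
        mirror = 1_000_000
        minus = TSSRecord("G", "chr1", mirror - tss, "-")
        phased_m, _, _ = assign_and_label(
            [Nucleosome("chr1", mirror - (tss + r)) for r in rel], _windows(minus))
        key = ["rel_pos", "label"]
        assert phased_p.sort_values("rel_pos")[key].to_numpy().tolist() == \
            phased_m.sort_values("rel_pos")[key].to_numpy().tolist()
        assert nfr_width(phased_p) == nfr_width(phased_m)


class TestNfrWidth:
    def _phased(self, rel_labels):
        return pd.DataFrame(
            {"gene_id": "G", "rel_pos": list(rel_labels), "label": [(-1 if r < 0 else 1) for r in rel_labels]}
        )

    def test_edge_to_edge_gap(self):
        assert nfr_width(self._phased([-180, 50])) == 83

    def test_abutting_footprints_give_zero(self):
        assert nfr_width(self._phased([-70, 77])) == 0

    def test_missing_minus_one_is_undefined(self):
        assert nfr_width(self._phased([50])) is None

    def test_synthetic_closed_form(self, small_dataset, small_windows):
        cfg = small_dataset.config
        phased, _, _ = assign_and_label(small_dataset.nucleosomes_before, small_windows)
        widths = nfr_table(phased).dropna().unique()
        assert list(widths) == [2 * cfg.nfr_halfwidth + cfg.spacing - cfg.footprint]


class TestOccupancyExpressionCorrelation:
    def test_perfect_anticorrelation(self):
        r, _ = occupancy_expression_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            occupancy_expression_correlation([1, 2, 3, 4], [5, 5, 5, 5])

    def test_matches_product_moment_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        r, _ = occupancy_expression_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        direct = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(direct, abs=1e-12)


class TestRepositionedProfile:
    def _calls(self, rel_positions, status="repositioned"):
        return pd.DataFrame({"rel_pos": rel_positions, "status": status})

    def _windows(self):
        return _windows(TSSRecord("G", "chr1", 50_000, "+"))

    def test_single_event_lands_in_its_bin(self):
        profile = repositioned_tss_profile(self._calls([-50]), self._windows())
        assert profile.loc[pd.Interval(-100, 0, closed="left")] == 1
        assert profile.sum() == 1

    def test_empty_calls_give_zero_histogram(self):
        profile = repositioned_tss_profile(self._calls([]), self._windows())
        assert profile.sum() == 0

    def test_counts_are_conserved(self):
        rng = np.random.default_rng(5)
        rel = rng.integers(-7500, 2500, size=200)
        profile = repositioned_tss_profile(self._calls(list(rel)), self._windows())
        assert profile.sum() == 200

    def test_nonpositive_bin_rejected(self):
        with pytest.raises(ValueError):
            repositioned_tss_profile(self._calls([0]), self._windows(), bin_size=0)
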