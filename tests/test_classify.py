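"""Binding-site uniqueness, nucleosome-context classification, gene aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from nucleoshift.classify import (
    CATEGORIES,
    aggregate_genes,
    category_summary,
    classify_sites,
    depletion_ratio_profile,
    minus_one_shift,
    nearest_nucleosome_distance,
    peaks_near_tss,
    unique_induced_peaks,
)
from nucleoshift.core import Nucleosome, Peak, TSSRecord
from nucleoshift.phasing import promoter_windows_frame


def _peaks(*summits, width=200):
    return [Peak("chr1", s - width // 2, s + width // 2, summit=s) for s in summits]


def _nucs(*centers):
    return [Nucleosome("chr1", c) for c in centers]


class TestUniqueInducedPeaks:
    def test_one_bp_overlap_disqualifies(self):
        after = [Peak("chr1", 100, 200)]
        assert len(unique_induced_peaks(after, [Peak("chr1", 199, 250)])) == 0
        assert len(unique_induced_peaks(after, [Peak("chr1", 200, 250)])) == 1

    def test_matches_quadratic_overlap_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            mk = lambda n: [
                Peak("chr1", int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 2000, n), rng.integers(50, 300, n))
            ]
            after, before = mk(15), mk(10)
            got = unique_induced_peaks(after, before)
            expected = [
                p for p in after
                if not any(p.interval.overlaps(q.interval) for q in before)
            ]
            assert len(got) == len(expected)
            assert list(got["start"]) == [p.start for p in expected]


class TestNearestNucleosomeDistance:
    def test_nearest_center_distance(self):
        d = nearest_nucleosome_distance(pd.DataFrame({"chrom": ["chr1"], "summit": [5000]}),
                                        _nucs(5100, 6000))
        assert d[0] == 100

    def test_summit_inside_footprint_is_zero(self):
        d = nearest_nucleosome_distance(pd.DataFrame({"chrom": ["chr1"], "summit": [5060]}),
                                        _nucs(5000))
        assert d[0] == 0

    def test_empty_chromosome_is_infinite(self):
        d = nearest_nucleosome_distance(pd.DataFrame({"chrom": ["chr2"], "summit": [5000]}),
                                        _nucs(5000))
        assert math.isinf(d[0])


class TestClassifySites:
    @pytest.mark.parametrize(
        "before_center,after_center,category",
        [
            (5100, 5500, "repositioning_coupled"),   # d=100 then d=500
            (5100, 5050, "co_occupied"),             # d=100 then d=50
            (5700, 5600, "nucleosome_independent"),  # d=700 then d=600
            (5400, 5050, "nucleosome_gained"),       # d=400 then d=50
        ],
    )
    def test_quadrants_of_the_300bp_rule(self, before_center, after_center, category):
        out = classify_sites(_peaks(5000), _nucs(before_center), _nucs(after_center))
        assert out.loc[0, "category"] == category

    def test_category_independent_of_interval_width(self):
        wide = [Peak("chr1", 3000, 8000, summit=5000)]
        narrow = [Peak("chr1", 4990, 5010, summit=5000)]
        b, a = _nucs(5100), _nucs(5500)
        assert classify_sites(wide, b, a).loc[0, "category"] == \
            classify_sites(narrow, b, a).loc[0, "category"]

    def test_planted_categories_recovered_exactly(self, small_dataset):
        ds = small_dataset
        unique = unique_induced_peaks(ds.peaks_after, ds.peaks_before)
        out = classify_sites(unique, ds.nucleosomes_before, ds.nucleosomes_after)
        truth = ds.truth.peaks
        merged = out.merge(truth, on="summit", suffixes=("_called", "_planted"))
        planted_unique = truth[truth["category"] != "shared"]
        assert len(merged) == len(planted_unique) == len(unique)
        assert (merged["category_called"] == merged["category_planted"]).all()

    def test_categories_partition_unique_peaks(self, small_dataset):
        ds = small_dataset
        unique = unique_induced_peaks(ds.peaks_after, ds.peaks_before)
        out = classify_sites(unique, ds.nucleosomes_before, ds.nucleosomes_after)
        assert out["category"].isin(CATEGORIES).all()
        assert out["category"].value_counts().sum() == len(unique)


class TestDepletionRatioProfile:
    def test_ratio_and_undefined_bins(self):
        before = _nucs(5050, 5060, 5400)   # bin [0,300): 2, bin [300,600): 1
        after = _nucs(5080)                # bin [0,300): 1
        prof = depletion_ratio_profile(before, after, _peaks(5000), window=300, span=900)
        assert prof.loc[0, "ratio"] == pytest.approx(0.5)
        assert prof.loc[1, "ratio"] == pytest.approx(0.0)
        assert math.isnan(prof.loc[2, "ratio"])  # zero before-count

    def test_counts_match_bruteforce_binning(self):
        rng = np.random.default_rng(29)
        summits = [3000, 9000]
        before = _nucs(*rng.integers(0, 12_000, 80))
        after = _nucs(*rng.integers(0, 12_000, 70))
        prof = depletion_ratio_profile(before, after, _peaks(*summits), window=300, span=3000)
        for nucs, col in ((before, "n_before"), (after, "n_after")):
            dists = [min(abs(n.center - s) for s in summits) for n in nucs]
            for i, (lo, hi) in enumerate(zip(prof["bin_start"], prof["bin_end"])):
                assert prof.loc[i, col] == sum(lo <= d < hi for d in dists)


class TestPeaksNearTss:
    def test_10kb_boundary(self):
        ann = [TSSRecord("G1", "chr1", 50_000, "+")]
        assert "G1" in peaks_near_tss(_peaks(59_999), ann)
        assert peaks_near_tss(_peaks(60_001), ann) == {}

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(31)
        ann = [TSSRecord(f"G{i}", "chr1", int(p), "+")
               for i, p in enumerate(rng.integers(0, 10**6, 20))]
        summits = rng.integers(0, 10**6, 50)
        got = peaks_near_tss(_peaks(*summits), ann)
        for t in ann:
            expected = [i for i, s in enumerate(summits) if abs(int(s) - t.tss) <= 10_000]
            assert got.get(t.gene_id, []) == expected


class TestGeneAggregation:
    def test_multi_category_gene_counted_in_each(self):
        windows = promoter_windows_frame([TSSRecord("G1", "chr1", 50_000, "+")])
        classified = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "summit": [49_000, 51_000],
                "category": ["co_occupied", "repositioning_coupled"],
            }
        )
        records, summary = aggregate_genes(classified, windows, {"G1": True})
        assert records.loc[0, "categories"] == ["co_occupied", "repositioning_coupled"]
        s = summary.set_index("category")
        assert s.loc["co_occupied", "n_genes"] == 1
        assert s.loc["repositioning_coupled", "n_genes"] == 1
        assert s.loc["co_occupied", "de_percent"] == 100.0

    def test_zero_de_genes_give_zero_percent(self):
        summary = category_summary({"co_occupied": (10, 0)})
        assert summary.loc[0, "de_percent"] == 0.0


class TestMinusOneShift:
    def _phased(self, rel):
        return pd.DataFrame({"gene_id": ["G1"], "label": [-1], "rel_pos": [rel]})

    def test_shift_away_from_tss_is_negative(self):
        assert minus_one_shift(self._phased(-200), self._phased(-240), ["G1"]) == -40.0

    def test_identical_maps_give_zero(self):
        assert minus_one_shift(self._phased(-200), self._phased(-200), ["G1"]) == 0.0

    def test_no_eligible_gene_rejected(self):
        with pytest.raises(ValueError):
            minus_one_shift(self._phased(-200), self._phased(-240), ["G2"])

    def test_matches_direct_mean(self):
        rng = np.random.default_rng(37)
        genes = [f"G{i}" for i in range(20)]
        before = pd.DataFrame({"gene_id": genes, "label": -1,
                               "rel_pos": rng.integers(-500, -100, 20)})
        after = pd.DataFrame({"gene_id": genes, "label": -1,
                              "rel_pos": rng.integers(-500, -100, 20)})
        got = minus_one_shift(before, after, genes)
        assert got == pytest.approx(
            float(np.mean(after["rel_pos"].to_numpy() - before["rel_pos"].to_numpy()))
        )
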