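"""The synthetic-data generator: determinism, planted truth, calibration."""

import numpy as np
import pandas as pd
import pytest

from nucleoshift.expression import differential_expression
from nucleoshift.motif import motif_scan, PWM
from nucleoshift.phasing import promoter_windows_frame
from nucleoshift.repositioning import match_and_call
from nucleoshift.simulate import (
    SimulationConfig,
    TruthTable,
    generate_annotation,
    generate_expression,
    generate_nucleosome_maps,
    generate_peak_sequences,
    simulate_dataset,
)


class TestConfigValidation:
    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimulationConfig(n_genes=0)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError, match="reposition_fraction"):
            SimulationConfig(reposition_fraction=1.5)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            SimulationConfig(n_replicates=1)

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chrom_length"):
            generate_annotation(SimulationConfig(n_genes=10, chrom_length=1000))


class TestAnnotation:
    def test_promoter_windows_disjoint(self):
        ann = generate_annotation(SimulationConfig(n_genes=50, seed=3))
        w = promoter_windows_frame(ann).sort_values("start")
        assert (w["start"].to_numpy()[1:] >= w["end"].to_numpy()[:-1]).all()

    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_genes=20, seed=9)
        assert generate_annotation(cfg) == generate_annotation(cfg)


class TestNucleosomeMaps:
    def test_null_plant_leaves_map_unchanged(self):
        cfg = SimulationConfig(n_genes=40, reposition_fraction=0.0, jitter_sd=0.0, seed=5)
        ann = generate_annotation(cfg)
        before, after, truth = generate_nucleosome_maps(cfg, ann)
        assert before["center"].tolist() == after["center"].tolist()
        windows = promoter_windows_frame(ann)
        calls = match_and_call(before, after, windows)
        assert (calls["status"] == "stable").all()

    def test_full_plant_moves_everything_beyond_300(self):
        cfg = SimulationConfig(n_genes=40, reposition_fraction=1.0, jitter_sd=0.0,
                               min_shift=301, seed=5)
        ann = generate_annotation(cfg)
        _, _, truth = generate_nucleosome_maps(cfg, ann)
        t = truth.nucleosomes
        assert (t["status"] == "repositioned").all()
        assert (np.abs(t["after_center"] - t["before_center"]) > 300).all()

    def test_every_nucleosome_has_one_truth_row(self):
        cfg = SimulationConfig(n_genes=30, seed=7)
        ann = generate_annotation(cfg)
        before, after, truth = generate_nucleosome_maps(cfg, ann)
        t = truth.nucleosomes
        assert len(t) == len(before) == len(after)
        assert t["nuc_id"].is_unique

    def test_planted_fraction_recovered_small_scale(self):
        # jitter-free plant at p=0.3 over 12,500 nucleosomes; the caller must
        # agree with the truth table row-by-row, so the recovered fraction is
        # exactly the planted one
        cfg = SimulationConfig(n_genes=2500, reposition_fraction=0.3, jitter_sd=0.0, seed=13)
        ann = generate_annotation(cfg)
        before, after, truth = generate_nucleosome_maps(cfg, ann)
        calls = match_and_call(before, after, promoter_windows_frame(ann))
        called = (calls["status"] == "repositioned").mean()
        planted = (truth.nucleosomes["status"] == "repositioned").mean()
        assert called == pytest.approx(planted)

    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(n_genes=25, seed=17)
        a1 = generate_nucleosome_maps(cfg, generate_annotation(cfg))
        a2 = generate_nucleosome_maps(cfg, generate_annotation(cfg))
        pd.testing.assert_frame_equal(a1[0], a2[0])
        pd.testing.assert_frame_equal(a1[1], a2[1])
        pd.testing.assert_frame_equal(a1[2].nucleosomes, a2[2].nucleosomes)


class TestPeaks:
    def test_no_unique_peaks_means_identical_sets(self):
        ds = simulate_dataset(SimulationConfig(n_genes=30, frac_peaks_unique=0.0, seed=19))
        cols = ["chrom", "start", "end", "summit"]
        pd.testing.assert_frame_equal(
            ds.peaks_before[cols].reset_index(drop=True),
            ds.peaks_after[cols].reset_index(drop=True),
        )

    def test_independent_peaks_clear_of_all_nucleosomes(self, small_dataset):
        ds = small_dataset
        indep = ds.truth.peaks[ds.truth.peaks["category"] == "nucleosome_independent"]
        centers = np.concatenate([
            ds.nucleosomes_before["center"].to_numpy(),
            ds.nucleosomes_after["center"].to_numpy(),
        ])
        for s in indep["summit"]:
            assert np.abs(centers - s).min() > 300

    def test_every_peak_has_one_truth_row(self, small_dataset):
        truth = small_dataset.truth.peaks
        assert truth["peak_id"].is_unique
        assert len(truth) == len(small_dataset.peaks_after)


class TestExpressionGenerator:
    def _truth(self, genes, coupled):
        peaks = pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(len(coupled))],
             "gene_id": coupled, "summit": 0, "category": "repositioning_coupled"}
        )
        return TruthTable(nucleosomes=pd.DataFrame(), peaks=peaks)

    def test_strong_effect_gives_full_power(self):
        cfg = SimulationConfig(n_genes=200, effect_size=5.0, noise_sd=0.5,
                               alpha_null=0.0, seed=23)
        ann = generate_annotation(cfg)
        genes = [t.gene_id for t in ann]
        table, cond, truth = generate_expression(cfg, ann, self._truth(genes, genes[:100]))
        de = differential_expression(table, cond)
        assert de.loc[genes[:100], "de"].mean() == pytest.approx(1.0)

    def test_same_seed_identical_table(self):
        cfg = SimulationConfig(n_genes=50, seed=29)
        ann = generate_annotation(cfg)
        t1, _, _ = generate_expression(cfg, ann, self._truth([], []))
        t2, _, _ = generate_expression(cfg, ann, self._truth([], []))
        pd.testing.assert_frame_equal(t1, t2)


class TestPeakSequences:
    def test_zero_mutation_embeds_exact_consensus(self):
        cfg = SimulationConfig(n_genes=30, motif_mutation_rate=0.0,
                               embed_probability=1.0, seed=31)
        peaks = pd.DataFrame({"peak_id": [f"p{i}" for i in range(30)]})
        records, truth = generate_peak_sequences(cfg, peaks)
        for rec, off in zip(records, truth["offset"]):
            assert str(rec.seq)[off:off + len(cfg.motif)] == cfg.motif

    def test_zero_embedding_probability_plants_nothing(self):
        cfg = SimulationConfig(n_genes=10, embed_probability=0.0, seed=31)
        peaks = pd.DataFrame({"peak_id": [f"p{i}" for i in range(10)]})
        _, truth = generate_peak_sequences(cfg, peaks)
        assert (truth["offset"] == -1).all()

    def test_too_short_sequences_rejected(self):
        with pytest.raises(ValueError, match="motif length"):
            SimulationConfig(seq_length=5)

    def test_scan_localizes_planted_sites(self, small_dataset):
        # best scan hit overlaps the planted 12-mer in nearly all embedded sequences
        ds = small_dataset
        cfg = ds.config
        probs = np.full((12, 4), 0.01 / 3)
        for i, b in enumerate(cfg.motif):
            probs[i, "ACGT".index(b)] = 0.99
        pwm = PWM(probs / probs.sum(axis=1, keepdims=True), np.full(4, 0.25))
        hits, _ = motif_scan(pwm, ds.sequences)
        truth = ds.truth.sequences.set_index("seq_id")
        planted = truth.loc[hits["seq_id"], "offset"].to_numpy()
        mask = planted >= 0
        overlap = (hits["offset"].to_numpy()[mask] < planted[mask] + 12) & \
            (planted[mask] < hits["offset"].to_numpy()[mask] + 12)
        assert overlap.mean() >= 0.95
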