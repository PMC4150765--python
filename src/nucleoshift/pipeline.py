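"""End-to-end orchestration: simulate → phasing → reposition → classify → DE → motif.

Every stage writes a TSV under the output directory with a header comment
recording the package version and a hash of the configuration, and the run
ends with a per-category summary (sites, genes, DE genes, DE%, mean −1
shift, mean NFR change) in the style of a binding-site/nucleosome/expression
cross-table.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    CATEGORIES,
    aggregate_genes,
    classify_sites,
    depletion_ratio_profile,
    minus_one_shift,
    unique_induced_peaks,
)
from .expression import condition_mean_z, de_flags, differential_expression
from .motif import gibbs_sample_motif, motif_scan
from .phasing import (
    assign_and_label,
    nfr_table,
    occupancy_expression_correlation,
    promoter_windows_frame,
    repositioned_tss_profile,
)
from .repositioning import displacement_distribution, match_and_call, repositioned_fraction
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("nucleoshift")


@dataclass
class PipelineConfig:
    """Thresholds and paths for one pipeline run; defaults follow the study."""

    outdir: str = "nucleoshift_out"
    seed: int = 0
    vicinity: int = 300            # bp; repositioning/classification rule
    promoter_upstream: int = 7500
    promoter_downstream: int = 2500
    de_alpha: float = 0.05
    near_tss: int = 10_000
    motif_width: int = 12
    motif_iterations: int = 150
    motif_restarts: int = 3
    simulation: Optional[SimulationConfig] = None   # synthetic-input mode

    def __post_init__(self) -> None:
        for name in ("vicinity", "promoter_upstream", "promoter_downstream", "near_tss",
                     "motif_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.de_alpha < 1:
            raise ValueError("de_alpha must be in (0, 1)")

    def config_hash(self) -> str:
        values = asdict(self)
        values.pop("outdir", None)  # where results land is not part of what they are
        payload = repr(sorted(values.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: str, cfg: PipelineConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# nucleoshift {__version__} config={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig):
    """Run every stage in dependency order; returns the result bundle.

    With ``config.simulation`` set, the inputs come from the synthetic-data
    generator (seeded from the pipeline seed); every stage error names the
    stage it came from.
    """
    cfg = config
    os.makedirs(cfg.outdir, exist_ok=True)
    results: dict[str, object] = {}

    sim_cfg = cfg.simulation or SimulationConfig(seed=cfg.seed)
    stage = "simulate"
    try:
        ds = simulate_dataset(sim_cfg)
        results["dataset"] = ds
        log.info("simulate: %d genes, %d/%d nucleosomes, %d/%d peaks",
                 len(ds.annotation), len(ds.nucleosomes_before), len(ds.nucleosomes_after),
                 len(ds.peaks_before), len(ds.peaks_after))

        stage = "phasing"
        windows = promoter_windows_frame(
            ds.annotation, cfg.promoter_upstream, cfg.promoter_downstream
        )
        phased_before, freq_before, drop_b = assign_and_label(ds.nucleosomes_before, windows)
        phased_after, freq_after, drop_a = assign_and_label(ds.nucleosomes_after, windows)
        log.info("phasing: %d/%d nucleosomes outside all windows", drop_b, drop_a)
        results["phased_before"], results["phased_after"] = phased_before, phased_after
        _write(pd.DataFrame({"label": freq_before.index,
                             "percent_before": freq_before.to_numpy(),
                             "percent_after": freq_after.reindex(freq_before.index).to_numpy()}),
               os.path.join(cfg.outdir, "phasing_label_frequencies.tsv"), cfg)

        stage = "reposition"
        calls = match_and_call(ds.nucleosomes_before, ds.nucleosomes_after, windows,
                               threshold=cfg.vicinity)
        frac = repositioned_fraction(calls)
        dist = displacement_distribution(calls)
        profile = repositioned_tss_profile(calls, windows)
        results["calls"], results["repositioned_fraction"] = calls, frac
        log.info("reposition: %.2f%% of %d promoter nucleosomes", 100 * frac, len(calls))
        _write(calls, os.path.join(cfg.outdir, "repositioning_calls.tsv"), cfg)
        _write(dist.rename_axis("bin").reset_index(),
               os.path.join(cfg.outdir, "displacement_distribution.tsv"), cfg)
        _write(profile.rename_axis("bin").reset_index().astype(str),
               os.path.join(cfg.outdir, "repositioned_tss_profile.tsv"), cfg)

        stage = "de"
        de_table = differential_expression(ds.expression, ds.sample_conditions,
                                           alpha=cfg.de_alpha)
        flags = de_flags(de_table)
        log.info("de: %d/%d genes at P < %g", int(de_table["de"].sum()), len(de_table),
                 cfg.de_alpha)
        _write(de_table, os.path.join(cfg.outdir, "differential_expression.tsv"), cfg,
               index=True)

        stage = "classify"
        unique = unique_induced_peaks(ds.peaks_after, ds.peaks_before)
        classified = classify_sites(unique, ds.nucleosomes_before, ds.nucleosomes_after,
                                    threshold=cfg.vicinity)
        gene_records, summary = aggregate_genes(classified, windows, flags)
        depletion = depletion_ratio_profile(ds.nucleosomes_before, ds.nucleosomes_after,
                                            ds.peaks_after, window=cfg.vicinity)
        results["classified"], results["gene_records"] = classified, gene_records
        log.info("classify: %d unique induced peaks (%s)", len(classified),
                 ", ".join(f"{c}={int((classified['category'] == c).sum())}"
                           for c in CATEGORIES))
        _write(classified, os.path.join(cfg.outdir, "site_classification.tsv"), cfg)
        _write(gene_records.assign(categories=gene_records["categories"].map(",".join)),
               os.path.join(cfg.outdir, "gene_categories.tsv"), cfg)
        _write(depletion, os.path.join(cfg.outdir, "depletion_ratio_profile.tsv"), cfg)

        stage = "occupancy-expression"
        counts_b = phased_before.groupby("gene_id").size()
        z = condition_mean_z(ds.expression, ds.sample_conditions)
        shared_genes = counts_b.index.intersection(z.index)
        try:
            corr = occupancy_expression_correlation(
                counts_b.loc[shared_genes], z.loc[shared_genes, "before"]
            )
            log.info("occupancy-expression: r=%.3f (P=%.3g)", *corr)
        except ValueError as err:
            # e.g. a fixed per-promoter nucleosome count: correlation undefined
            corr = None
            log.info("occupancy-expression: skipped (%s)", err)
        results["occupancy_expression_r"] = corr

        stage = "motif"
        pwm, sites, score = gibbs_sample_motif(
            ds.sequences, width=cfg.motif_width, iterations=cfg.motif_iterations,
            restarts=cfg.motif_restarts, seed=cfg.seed,
        )
        hits, scan_summary = motif_scan(pwm, ds.sequences)
        results["pwm"], results["motif_hits"], results["motif_summary"] = pwm, hits, scan_summary
        log.info("motif: consensus %s, %.0f%% of sequences with a hit", pwm.consensus,
                 100 * scan_summary["fraction_with_hit"])
        _write(pwm.to_frame(), os.path.join(cfg.outdir, "motif_pwm.tsv"), cfg, index=True)
        _write(hits, os.path.join(cfg.outdir, "motif_hits.tsv"), cfg)

        stage = "summary"
        nfr_b = nfr_table(phased_before)
        nfr_a = nfr_table(phased_after)
        rows = []
        for cat in CATEGORIES:
            in_cat = gene_records[gene_records["categories"].map(lambda c: cat in c)]
            genes = list(in_cat["gene_id"])
            n_de = int(in_cat["de"].sum())
            try:
                shift = minus_one_shift(phased_before, phased_after, genes)
            except ValueError:
                shift = np.nan
            both = nfr_b.index.intersection(nfr_a.index).intersection(genes)
            nfr_change = float((nfr_a.loc[both] - nfr_b.loc[both]).mean()) if len(both) else np.nan
            rows.append(
                {
                    "category": cat,
                    "n_sites": int((classified["category"] == cat).sum()),
                    "n_genes": len(genes),
                    "n_de": n_de,
                    "de_percent": 100.0 * n_de / len(genes) if genes else 0.0,
                    "mean_minus1_shift": shift,
                    "mean_nfr_change": nfr_change,
                }
            )
        summary = pd.DataFrame(rows)
        results["summary"] = summary
        _write(summary, os.path.join(cfg.outdir, "summary.tsv"), cfg)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
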