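"""Synthetic condition-paired datasets with planted truth.

The generator emulates the statistical structure the pipeline is built for:
TSS-anchored phased nucleosome arrays with an NFR, a planted fraction of
>300-bp repositioning events between the "before" and "after" states, a TF
peak set partly unique to the induced state with category-controlled
placement relative to nucleosomes, replicate expression in which
repositioning-coupled genes carry condition effects, and peak sequences with
an embedded 12-mer motif near the summit.

Planting detail that matters: the promoter array splits at the NFR into an
upstream block ({−1}) and a downstream block ({+1..+4}). Repositioning is
planted per block — each block moves wholesale with probability
``reposition_fraction`` — because a nucleosome moved out of a 190-bp-spaced
array while its neighbors stay would be invisible to a nearest-neighbor
300-bp caller (the stable neighbor sits closer than the threshold). Blocks
are the smallest units whose mutual gaps exceed the threshold, so per-block
planting keeps the per-nucleosome marginal probability exactly
``reposition_fraction`` while making every planted event detectable.
Planted shifts are drawn from [min_shift, max_shift] restricted to land
more than 300 bp from every before-state dyad of the promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .core import NUCLEOSOME_FOOTPRINT, TSSRecord
from .phasing import PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM
from .repositioning import REPOSITION_THRESHOLD

DEFAULT_MOTIF = "TGACGTCATCGA"


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_genes: int = 1000
    chrom: str = "chrS"
    chrom_length: Optional[int] = None          # derived when None
    promoter_upstream: int = PROMOTER_UPSTREAM   # bp upstream of TSS
    promoter_downstream: int = PROMOTER_DOWNSTREAM
    intergenic_gap: int = 2000                   # bp between promoter windows

    # nucleosome architecture
    nfr_halfwidth: int = 70       # bp; NFR template half-width
    spacing: int = 190            # bp; inter-dyad distance in the phased array
    n_upstream: int = 1           # nucleosomes upstream of the NFR (−1, −2, …)
    n_downstream: int = 4         # nucleosomes downstream (+1..+4)
    footprint: int = NUCLEOSOME_FOOTPRINT
    jitter_sd: float = 15.0       # bp; positional noise per dyad

    # repositioning plant
    reposition_fraction: float = 0.114
    min_shift: int = 301          # bp; > threshold so planted events violate the rule
    max_shift: int = 800

    # TF peaks
    n_peaks_after: Optional[int] = None      # default: 2 per promoter
    frac_peaks_unique: float = 0.36          # unique to the induced state
    frac_unique_near_nucleosome: float = 0.31  # within 300 bp of a before-dyad
    frac_near_repositioned: float = 0.70     # of those, near a repositioned dyad
    peak_width: int = 200

    # motif / sequences
    motif: str = DEFAULT_MOTIF
    motif_mutation_rate: float = 0.10
    embed_probability: float = 0.8
    seq_length: int = 200
    offset_sd: float = 15.0       # sd of planted offset around the summit-centered position

    # expression
    n_replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    effect_size: float = 5.0      # shift for repositioning-coupled genes
    noise_sd: float = 0.5
    alpha_null: float = 0.10      # fraction of non-coupled genes given effects

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reposition_fraction", "frac_peaks_unique",
                     "frac_unique_near_nucleosome", "frac_near_repositioned",
                     "embed_probability", "motif_mutation_rate", "alpha_null"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 < self.min_shift <= self.max_shift:
            raise ValueError("need 0 < min_shift <= max_shift")
        if self.seq_length < len(self.motif):
            raise ValueError("seq_length must be >= motif length")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition (t-test undefined)")
        if self.spacing <= 0 or self.nfr_halfwidth < 0:
            raise ValueError("spacing must be positive and nfr_halfwidth >= 0")

    @property
    def resolved_n_peaks_after(self) -> int:
        return 2 * self.n_genes if self.n_peaks_after is None else self.n_peaks_after

    @property
    def promoter_pitch(self) -> int:
        return self.promoter_upstream + self.promoter_downstream + self.intergenic_gap

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-keyed child generator fanned out from the single seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class TruthTable:
    """Planted ground truth: one row per synthetic record."""

    nucleosomes: pd.DataFrame   # nuc_id, gene_id, block, before/after centers, status, shift
    peaks: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    sequences: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_annotation(cfg: SimulationConfig) -> list[TSSRecord]:
    """Non-overlapping promoter slots along one synthetic chromosome."""
    pitch = cfg.promoter_pitch
    required = cfg.n_genes * pitch
    if cfg.chrom_length is not None and cfg.chrom_length < required:
        raise ValueError(
            f"chrom_length {cfg.chrom_length} too small for {cfg.n_genes} genes "
            f"(need >= {required})"
        )
    rng = cfg.rng(0)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    records = []
    for i in range(cfg.n_genes):
        slot = i * pitch
        if strands[i] == "+":
            tss = slot + cfg.promoter_upstream
        else:
            tss = slot + cfg.promoter_downstream
        records.append(TSSRecord(f"G{i:05d}", cfg.chrom, int(tss), str(strands[i])))
    return records


def _template_rel(cfg: SimulationConfig) -> np.ndarray:
    """TSS-relative dyad template: −n_up..−1 upstream, +1..+n_down downstream."""
    anchor = cfg.nfr_halfwidth + cfg.spacing // 2
    up = [-(anchor + k * cfg.spacing) for k in range(cfg.n_upstream - 1, -1, -1)]
    down = [anchor + k * cfg.spacing for k in range(cfg.n_downstream)]
    return np.array(up + down, dtype=np.int64)


def _rel_to_genomic(rel: np.ndarray, tss: int, strand: str) -> np.ndarray:
    return tss + rel if strand == "+" else tss - rel


def generate_nucleosome_maps(
    cfg: SimulationConfig, annotation: list[TSSRecord]
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Before/after promoter nucleosome maps with per-block planted repositioning."""
    rng = cfg.rng(1)
    template = _template_rel(cfg)
    m = template.size
    block_of = np.array([0] * cfg.n_upstream + [1] * cfg.n_downstream)
    margin = cfg.footprint // 2 + 1
    lo_rel = -cfg.promoter_upstream + margin
    hi_rel = cfg.promoter_downstream - margin
    mags = np.arange(cfg.min_shift, cfg.max_shift + 1)

    rows = []
    nuc_id = 0
    for t in annotation:
        jit_b = np.rint(rng.normal(0.0, cfg.jitter_sd, m)).astype(np.int64) \
            if cfg.jitter_sd > 0 else np.zeros(m, dtype=np.int64)
        rel_before = template + jit_b
        block_hit = rng.random(2) < cfg.reposition_fraction
        repositioned = block_hit[block_of]
        jit_a = np.rint(rng.normal(0.0, cfg.jitter_sd, m)).astype(np.int64) \
            if cfg.jitter_sd > 0 else np.zeros(m, dtype=np.int64)
        rel_after = rel_before + jit_a
        for i in np.flatnonzero(repositioned):
            r = rel_before[i]
            cand = np.concatenate([r - mags, r + mags])
            clear = np.abs(cand[:, None] - rel_before[None, :]).min(axis=1) > REPOSITION_THRESHOLD
            valid = cand[clear & (cand >= lo_rel) & (cand <= hi_rel)]
            if valid.size == 0:
                raise ValueError(
                    f"cannot place a planted repositioning event in promoter {t.gene_id}"
                )
            rel_after[i] = valid[rng.integers(valid.size)]
        for i in range(m):
            rows.append(
                (
                    nuc_id, t.gene_id, "upstream" if block_of[i] == 0 else "downstream",
                    int(rel_before[i]), int(rel_after[i]),
                    int(_rel_to_genomic(rel_before[i], t.tss, t.strand)),
                    int(_rel_to_genomic(rel_after[i], t.tss, t.strand)),
                    "repositioned" if repositioned[i] else "stable",
                    int(abs(rel_after[i] - rel_before[i])) if repositioned[i] else 0,
                )
            )
            nuc_id += 1
    truth_nuc = pd.DataFrame(
        rows,
        columns=["nuc_id", "gene_id", "block", "rel_before", "rel_after",
                 "before_center", "after_center", "status", "shift"],
    )
    before = pd.DataFrame(
        {"chrom": cfg.chrom, "center": truth_nuc["before_center"], "footprint": cfg.footprint}
    )
    after = pd.DataFrame(
        {"chrom": cfg.chrom, "center": truth_nuc["after_center"], "footprint": cfg.footprint}
    )
    return before, after, TruthTable(nucleosomes=truth_nuc)


def _place_summit_near(
    rng: np.random.Generator,
    center: int,
    other_centers: np.ndarray,
    max_offset: int = 100,
    min_clear: int = REPOSITION_THRESHOLD,
    retries: int = 50,
) -> int:
    """Summit within ±max_offset of `center` and > min_clear from `other_centers`."""
    for _ in range(retries):
        summit = center + int(rng.integers(-max_offset, max_offset + 1))
        if other_centers.size == 0 or np.abs(other_centers - summit).min() > min_clear:
            return summit
    return center  # guaranteed clear for planted repositioned dyads


def generate_peaks(
    cfg: SimulationConfig,
    annotation: list[TSSRecord],
    maps: tuple[pd.DataFrame, pd.DataFrame],
    truth: TruthTable,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Before/after peak sets; unique induced peaks follow planted categories."""
    rng = cfg.rng(2)
    tnuc = truth.nucleosomes
    by_gene = {t.gene_id: t for t in annotation}
    half = cfg.peak_width // 2

    n_total = cfg.resolved_n_peaks_after
    n_unique = int(round(cfg.frac_peaks_unique * n_total))
    n_shared = n_total - n_unique
    n_near = int(round(cfg.frac_unique_near_nucleosome * n_unique))
    n_coupled = int(round(cfg.frac_near_repositioned * n_near))
    n_co = n_near - n_coupled
    n_indep = n_unique - n_near

    repositioned_pool = tnuc[tnuc["status"] == "repositioned"]
    stable_pool = tnuc[tnuc["status"] == "stable"]
    if len(repositioned_pool) < n_coupled:
        raise ValueError(
            f"cannot place {n_coupled} repositioning-coupled peaks: only "
            f"{len(repositioned_pool)} planted repositioned nucleosomes"
        )
    if len(stable_pool) < n_co:
        raise ValueError(
            f"cannot place {n_co} co-occupied peaks: only {len(stable_pool)} stable nucleosomes"
        )

    after_centers_by_gene = {
        g: grp["after_center"].to_numpy(np.int64) for g, grp in tnuc.groupby("gene_id")
    }
    before_centers_by_gene = {
        g: grp["before_center"].to_numpy(np.int64) for g, grp in tnuc.groupby("gene_id")
    }

    peak_rows = []     # (peak_id, gene_id, summit, category)

    chosen = repositioned_pool.sample(n=n_coupled, random_state=rng.integers(2**31), replace=False)
    for row in chosen.itertuples(index=False):
        summit = _place_summit_near(
            rng, row.before_center, after_centers_by_gene[row.gene_id]
        )
        peak_rows.append((row.gene_id, summit, "repositioning_coupled"))

    chosen = stable_pool.sample(n=n_co, random_state=rng.integers(2**31), replace=False)
    for row in chosen.itertuples(index=False):
        summit = row.before_center + int(rng.integers(-100, 101))
        peak_rows.append((row.gene_id, summit, "co_occupied"))

    genes = list(by_gene)
    for _ in range(n_indep):
        placed = False
        for _attempt in range(100):
            g = genes[rng.integers(len(genes))]
            t = by_gene[g]
            rel = int(rng.integers(-cfg.promoter_upstream + cfg.peak_width,
                                   -(cfg.max_shift + _template_rel(cfg).max() + 400)))
            summit = int(_rel_to_genomic(np.int64(rel), t.tss, t.strand))
            clear_b = np.abs(before_centers_by_gene[g] - summit).min() > REPOSITION_THRESHOLD
            clear_a = np.abs(after_centers_by_gene[g] - summit).min() > REPOSITION_THRESHOLD
            if clear_b and clear_a:
                peak_rows.append((g, summit, "nucleosome_independent"))
                placed = True
                break
        if not placed:
            raise ValueError(f"cannot place a nucleosome-independent peak (last promoter {g})")

    # shared peaks exist identically in both conditions; keep them clear of
    # unique-peak intervals so interval overlap defines uniqueness cleanly
    occupied: dict[str, list[tuple[int, int]]] = {}
    for g, summit, _cat in peak_rows:
        occupied.setdefault(g, []).append((summit - half, summit + half))
    shared_rows = []
    for _ in range(n_shared):
        placed = False
        for _attempt in range(100):
            g = genes[rng.integers(len(genes))]
            t = by_gene[g]
            rel = int(rng.integers(-cfg.promoter_upstream + cfg.peak_width,
                                   cfg.promoter_downstream - cfg.peak_width))
            summit = int(_rel_to_genomic(np.int64(rel), t.tss, t.strand))
            iv = (summit - half, summit + half)
            if all(iv[1] <= s or iv[0] >= e for s, e in occupied.get(g, [])):
                occupied.setdefault(g, []).append(iv)
                shared_rows.append((g, summit))
                placed = True
                break
        if not placed:
            raise ValueError(f"cannot place a shared peak (last promoter {g})")

    def frame(rows, condition):
        return pd.DataFrame(
            {
                "chrom": cfg.chrom,
                "start": [s - half for _, s in rows],
                "end": [s + half for _, s in rows],
                "summit": [s for _, s in rows],
                "condition": condition,
            }
        )

    unique_simple = [(g, s) for g, s, _ in peak_rows]
    after_peaks = frame(unique_simple + shared_rows, "after")
    after_peaks["peak_id"] = [f"peak{i:05d}" for i in range(len(after_peaks))]
    before_peaks = frame(shared_rows, "before")
    before_peaks["peak_id"] = [
        f"peak{i + len(unique_simple):05d}" for i in range(len(before_peaks))
    ]
    truth_peaks = pd.DataFrame(
        {
            "peak_id": after_peaks["peak_id"],
            "gene_id": [g for g, _, _ in peak_rows] + [g for g, _ in shared_rows],
            "summit": after_peaks["summit"],
            "category": [c for _, _, c in peak_rows] + ["shared"] * len(shared_rows),
        }
    )
    truth.peaks = truth_peaks
    return before_peaks, after_peaks, truth


def generate_expression(
    cfg: SimulationConfig, annotation: list[TSSRecord], truth: TruthTable
) -> tuple[pd.DataFrame, dict[str, str], TruthTable]:
    """Replicate expression: coupled genes carry effects, alpha_null of the rest."""
    rng = cfg.rng(3)
    genes = [t.gene_id for t in annotation]
    coupled = set()
    if len(truth.peaks):
        coupled = set(
            truth.peaks.loc[truth.peaks["category"] == "repositioning_coupled", "gene_id"]
        )
    effect = np.zeros(len(genes))
    planted = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        if g in coupled:
            planted[i] = True
        elif rng.random() < cfg.alpha_null:
            planted[i] = True
    signs = rng.choice([-1.0, 1.0], size=len(genes))
    effect[planted] = cfg.effect_size * signs[planted]

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, len(genes))
    n = cfg.n_replicates
    cols = [f"before_{i+1}" for i in range(n)] + [f"after_{i+1}" for i in range(n)]
    noise = rng.normal(0.0, cfg.noise_sd, (len(genes), 2 * n))
    values = baseline[:, None] + noise
    values[:, n:] += effect[:, None]
    table = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cols)
    sample_conditions = {c: ("before" if c.startswith("before") else "after") for c in cols}
    truth.genes = pd.DataFrame(
        {
            "gene_id": genes,
            "coupled": [g in coupled for g in genes],
            "de_planted": planted,
            "effect": effect,
        }
    )
    return table, sample_conditions, truth


def generate_peak_sequences(
    cfg: SimulationConfig, peaks: pd.DataFrame, truth: Optional[TruthTable] = None
):
    """Uniform-background sequences with the mutated consensus embedded near center.

    One sequence per peak row (id = peak_id when present). Returns
    ``(records, truth_offsets)`` — Biopython SeqRecords plus a table with the
    planted offset (−1 when no site was embedded).
    """
    from .io import make_seq_record

    rng = cfg.rng(4)
    w = len(cfg.motif)
    L = cfg.seq_length
    if L < w:
        raise ValueError("sequence length < motif length")
    motif_idx = np.array(["ACGT".index(b) for b in cfg.motif.upper()], dtype=np.int8)
    ids = peaks["peak_id"] if "peak_id" in peaks else [f"peak{i:05d}" for i in range(len(peaks))]
    records, rows = [], []
    for sid in ids:
        enc = rng.integers(0, 4, L).astype(np.int8)
        offset = -1
        if rng.random() < cfg.embed_probability:
            offset = int(np.clip(round(rng.normal((L - w) / 2.0, cfg.offset_sd)), 0, L - w))
            site = motif_idx.copy()
            mutate = rng.random(w) < cfg.motif_mutation_rate
            for j in np.flatnonzero(mutate):
                site[j] = (site[j] + rng.integers(1, 4)) % 4
            enc[offset:offset + w] = site
        seq = "".join("ACGT"[b] for b in enc)
        records.append(make_seq_record(seq, str(sid)))
        rows.append((str(sid), offset))
    truth_seq = pd.DataFrame(rows, columns=["seq_id", "offset"])
    if truth is not None:
        truth.sequences = truth_seq
    return records, truth_seq


@dataclass
class SyntheticDataset:
    """Everything one run of the generator produces."""

    config: SimulationConfig
    annotation: list[TSSRecord]
    nucleosomes_before: pd.DataFrame
    nucleosomes_after: pd.DataFrame
    peaks_before: pd.DataFrame
    peaks_after: pd.DataFrame
    expression: pd.DataFrame
    sample_conditions: dict[str, str]
    sequences: list
    truth: TruthTable


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage under the single top-level seed."""
    annotation = generate_annotation(cfg)
    before, after, truth = generate_nucleosome_maps(cfg, annotation)
    pb, pa, truth = generate_peaks(cfg, annotation, (before, after), truth)
    expr, sample_conditions, truth = generate_expression(cfg, annotation, truth)
    unique_peaks = pa[pa["peak_id"].isin(
        truth.peaks.loc[truth.peaks["category"] != "shared", "peak_id"]
    )]
    sequences, _ = generate_peak_sequences(cfg, unique_peaks, truth)
    return SyntheticDataset(
        config=cfg,
        annotation=annotation,
        nucleosomes_before=before,
        nucleosomes_after=after,
        peaks_before=pb,
        peaks_after=pa,
        expression=expr,
        sample_conditions=sample_conditions,
        sequences=sequences,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every piece of a dataset as plain text; returns name → path."""
    import os

    from .io import write_expression, write_fasta, write_tss

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def bed_path(name):
        p = os.path.join(outdir, name)
        paths[name] = p
        return p

    for name, df in (
        ("nucleosomes_before.bed", ds.nucleosomes_before),
        ("nucleosomes_after.bed", ds.nucleosomes_after),
    ):
        half = ds.config.footprint // 2
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["center"] - half,
                "end": df["center"] - half + ds.config.footprint,
            }
        )
        out.to_csv(bed_path(name), sep="\t", header=False, index=False)
    for name, df in (("peaks_before.bed", ds.peaks_before), ("peaks_after.bed", ds.peaks_after)):
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": df["peak_id"],
                "score": 0,
                "strand": ".",
                "summit_offset": df["summit"] - df["start"],
            }
        )
        out.to_csv(bed_path(name), sep="\t", header=False, index=False)
    write_tss(ds.annotation, bed_path("tss.bed"))
    write_expression(ds.expression, bed_path("expression.tsv"))
    with open(bed_path("sample_conditions.tsv"), "w") as fh:
        for s, c in ds.sample_conditions.items():
            fh.write(f"{s}\t{c}\n")
    write_fasta(ds.sequences, bed_path("peak_sequences.fasta"))
    ds.truth.nucleosomes.to_csv(bed_path("truth_nucleosomes.tsv"), sep="\t", index=False)
    ds.truth.peaks.to_csv(bed_path("truth_peaks.tsv"), sep="\t", index=False)
    ds.truth.genes.to_csv(bed_path("truth_genes.tsv"), sep="\t", index=False)
    ds.truth.sequences.to_csv(bed_path("truth_sequences.tsv"), sep="\t", index=False)
    with open(bed_path("config.txt"), "w") as fh:
        for k, v in asdict(ds.config).items():
            fh.write(f"{k} = {v}\n")
    return paths
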