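"""Synthetic data with the statistical structure the clone design assumes.

The generators emulate the study design the pipeline targets: three
trisomy-8 single-cell clones, three disomy-8 clones from the same patient,
and two unrelated references (one XY, one XX).  On the trisomic chromosome a
configurable fraction of genes (default 65%) carries a single-copy dosage
effect of log2(3/2); BAC clones with few or no genes are hypomethylated only
on the trisomic chromosome in the trisomic clones; promoter tracks carry
localized enrichment peaks and optional chromosome-wide offsets (5hmC
depletion).  Every injected effect is recorded in a :class:`SimulationTruth`
so that parameter-recovery tests can compare estimates against it.

Defaults are desk-scale (≈5,000 expression genes, ≈600 BAC clones, ≈20,000
promoter probes); the full array sizes are reachable through the size
arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    GROUP_DISOMY,
    GROUP_REFERENCE,
    GROUP_TRISOMY,
    CloneTable,
    Config,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    ProbeTrack,
    SampleSheet,
    ValidationError,
)

#: single-copy dosage shift, log2(3/2)
DOSAGE_LOG2_EFFECT = math.log2(1.5)

#: default 8-sample clone design: 3 trisomic, 3 disomic, XY and XX references
DEFAULT_SAMPLES = (
    ("T1", GROUP_TRISOMY, "XY"),
    ("T2", GROUP_TRISOMY, "XY"),
    ("T3", GROUP_TRISOMY, "XY"),
    ("D1", GROUP_DISOMY, "XY"),
    ("D2", GROUP_DISOMY, "XY"),
    ("D3", GROUP_DISOMY, "XY"),
    ("R1", GROUP_REFERENCE, "XY"),
    ("R2", GROUP_REFERENCE, "XX"),
)

DEFAULT_GENES_PER_CHROM = {
    "chr1": 1200,
    "chr2": 1000,
    "chr7": 900,
    "chr8": 800,
    "chr17": 500,
    "chrX": 600,
}

DEFAULT_CLONES_PER_CHROM = {"chr2": 130, "chr7": 150, "chr8": 200, "chrX": 120}

#: gene-count distribution over 0..20 for BAC clones on the trisomic
#: chromosome: 45% of clones carry no gene, most carry 0-3.
DEFAULT_GENE_COUNT_WEIGHTS = {
    0: 0.45, 1: 0.18, 2: 0.12, 3: 0.08, 4: 0.05, 5: 0.035, 6: 0.025,
    7: 0.015, 8: 0.012, 9: 0.008, 10: 0.006, 11: 0.004, 12: 0.004,
    13: 0.003, 14: 0.003, 15: 0.002, 16: 0.002, 17: 0.002, 18: 0.002,
    19: 0.001, 20: 0.001,
}


@dataclass
class SimulationTruth:
    """Ground truth of the effects a generator injected."""

    dosage_genes: set[str] = field(default_factory=set)
    dosage_log2_effect: float = DOSAGE_LOG2_EFFECT
    deregulated_trans_genes: dict[str, float] = field(default_factory=dict)
    reference_marker_genes: dict[str, float] = field(default_factory=dict)
    hypomethylated_bins: dict[tuple[str, int], float] = field(default_factory=dict)
    enriched_promoter_genes: dict[str, float] = field(default_factory=dict)
    chrom_offsets: dict[str, dict[str, float]] = field(default_factory=dict)


def default_sample_sheet(duration: str = "short") -> SampleSheet:
    rows = [
        {"sample_id": sid, "group": grp, "sex": sex, "culture_duration": duration}
        for sid, grp, sex in DEFAULT_SAMPLES
    ]
    return SampleSheet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    config: Config | None = None,
    n_genes_per_chrom: Mapping[str, int] | None = None,
    dosage_fraction: float = 0.65,
    noise_sd: float = 0.25,
    seed: int = 0,
    dosage_log2_effect: float = DOSAGE_LOG2_EFFECT,
    trans_effects: Sequence[float] | None = None,
    n_trans: int = 30,
    n_reference_markers: int = 150,
    reference_marker_range: tuple[float, float] = (0.3, 0.8),
    baseline_mean: float = 7.0,
    baseline_sd: float = 2.0,
    mirna_every: int = 20,
) -> tuple[ExpressionMatrix, SampleSheet, SimulationTruth]:
    """Simulate a log2 expression matrix for the 8-sample clone design.

    A random ``dosage_fraction`` of the genes on the trisomic chromosome gets
    ``dosage_log2_effect`` added in the trisomy-group samples.  ``trans_effects``
    (default: ``n_trans`` draws of ±Uniform(0.5, 1.0)) are applied to random
    genes off the trisomic chromosome, again in the trisomy group.  Because
    the references come from unrelated individuals (not the patient's own
    clones), ``n_reference_markers`` random genes additionally carry a
    reference-specific inter-individual signature (± uniform shifts in the
    reference samples); set it to 0 for a two-population design.  Gaussian
    ``noise_sd`` is added i.i.d. per cell.
    """
    config = config or Config()
    genes_per_chrom = dict(n_genes_per_chrom or DEFAULT_GENES_PER_CHROM)
    trisomic = config.trisomic_chrom
    if trisomic not in genes_per_chrom:
        raise ValidationError(f"n_genes_per_chrom lacks the trisomic chromosome {trisomic}")
    if not (0.0 < dosage_fraction <= 1.0):
        raise ValidationError(f"dosage_fraction must lie in (0, 1], got {dosage_fraction}")
    rng = np.random.default_rng(seed)
    sheet = default_sample_sheet()
    samples = sheet.sample_ids
    tri_samples = sheet.samples_in_group(GROUP_TRISOMY)
    tri_mask = np.array([s in tri_samples for s in samples])

    rows = []
    for chrom in sorted(genes_per_chrom):
        n = int(genes_per_chrom[chrom])
        for i in range(n):
            gene = f"{chrom}_G{i:04d}"
            rows.append(
                {
                    "probe_id": f"P_{gene}",
                    "gene_symbol": gene,
                    "chrom": chrom,
                    "position": 50_000 * (i + 1),
                    "biotype": "miRNA" if (i % mirna_every) == mirna_every - 1 else "coding",
                }
            )
    annot = pd.DataFrame(rows).set_index("probe_id")
    n_probes = len(annot)

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_probes)
    values = np.tile(baseline[:, None], (1, len(samples)))

    truth = SimulationTruth(dosage_log2_effect=dosage_log2_effect)

    tri_probes = np.flatnonzero((annot["chrom"] == trisomic).to_numpy())
    n_dosage = int(round(dosage_fraction * len(tri_probes)))
    dosage_idx = rng.choice(tri_probes, size=n_dosage, replace=False)
    values[np.ix_(dosage_idx, np.flatnonzero(tri_mask))] += dosage_log2_effect
    truth.dosage_genes = set(annot.iloc[dosage_idx]["gene_symbol"])

    off_probes = np.flatnonzero((annot["chrom"] != trisomic).to_numpy())
    if trans_effects is None:
        n_trans = min(n_trans, len(off_probes))
        magnitudes = rng.uniform(0.5, 1.0, size=n_trans)
        signs = rng.choice([-1.0, 1.0], size=n_trans)
        trans_effects = list(signs * magnitudes)
    trans_idx = rng.choice(off_probes, size=len(trans_effects), replace=False)
    for idx, shift in zip(trans_idx, trans_effects):
        values[idx, tri_mask] += shift
        truth.deregulated_trans_genes[annot.iloc[idx]["gene_symbol"]] = float(shift)

    if n_reference_markers > 0:
        ref_samples = sheet.samples_in_group(GROUP_REFERENCE)
        ref_mask = np.array([s in ref_samples for s in samples])
        marker_idx = rng.choice(
            n_probes, size=min(n_reference_markers, n_probes), replace=False
        )
        lo, hi = reference_marker_range
        shifts = rng.uniform(lo, hi, size=len(marker_idx)) * rng.choice(
            [-1.0, 1.0], size=len(marker_idx)
        )
        values[np.ix_(marker_idx, np.flatnonzero(ref_mask))] += shifts[:, None]
        truth.reference_marker_genes = {
            annot.iloc[i]["gene_symbol"]: float(sh)
            for i, sh in zip(marker_idx, shifts)
        }

    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=annot.index, columns=samples), annot
    )
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# BAC methylation
# ---------------------------------------------------------------------------


def simulate_bac_methylation(
    config: Config | None = None,
    clones_per_chrom: Mapping[str, int] | None = None,
    gene_count_distribution: Mapping[int, float] | None = None,
    hypo_effect: float = -0.3,
    sigma: float = 0.15,
    seed: int = 0,
    clone_length: int = 150_000,
    gene_poor_max_genes: int | None = None,
) -> tuple[CloneTable, list[GeneModel], SimulationTruth]:
    """Simulate a BAC-clone methylation table plus matching gene models.

    Clone log2 ratios are Normal(0, sigma) in every sample, except gene-poor
    clones (gene_count <= ``gene_poor_max_genes``, default from config) on the
    trisomic chromosome, which are shifted by ``hypo_effect`` in the trisomy
    group.  Gene models are placed fully inside their clone so that
    ``annotate_gene_counts`` recovers the drawn counts exactly.
    """
    config = config or Config()
    clones_per_chrom = dict(clones_per_chrom or DEFAULT_CLONES_PER_CHROM)
    weights = dict(gene_count_distribution or DEFAULT_GENE_COUNT_WEIGHTS)
    if gene_poor_max_genes is None:
        gene_poor_max_genes = config.gene_poor_max_genes
    for chrom, n in clones_per_chrom.items():
        if n <= 0:
            raise ValidationError(f"empty chromosome {chrom!r} in clones_per_chrom")
    counts_support = np.array(sorted(weights), dtype=int)
    probs = np.array([weights[c] for c in counts_support], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    sheet = default_sample_sheet()
    samples = sheet.sample_ids
    tri_samples = set(sheet.samples_in_group(GROUP_TRISOMY))
    trisomic = config.trisomic_chrom

    truth = SimulationTruth()
    clone_rows = []
    genes: list[GeneModel] = []
    for chrom in sorted(clones_per_chrom):
        n_clones = int(clones_per_chrom[chrom])
        gene_counts = rng.choice(counts_support, size=n_clones, p=probs)
        for i in range(n_clones):
            start = i * (clone_length + 1000)  # 1-kb gap: clones never touch
            end = start + clone_length
            clone_id = f"{chrom}_BAC{i:04d}"
            count = int(gene_counts[i])
            # genes strictly inside [start, end): counts recoverable exactly
            if count > 0:
                span = clone_length // count
                for g in range(count):
                    gs = start + g * span + 100
                    ge = gs + max(span // 2, 200)
                    gid = f"{clone_id}_gene{g}"
                    genes.append(GeneModel(gid, GenomicInterval(chrom, gs, min(ge, end)), gid))
            ratios = rng.normal(0.0, sigma, size=len(samples))
            if chrom == trisomic and count <= gene_poor_max_genes and hypo_effect != 0:
                for j, s in enumerate(samples):
                    if s in tri_samples:
                        ratios[j] += hypo_effect
                truth.hypomethylated_bins[(chrom, count)] = float(hypo_effect)
            row = {"clone_id": clone_id, "chrom": chrom, "start": start, "end": end,
                   "gene_count": count}
            row.update({s: ratios[j] for j, s in enumerate(samples)})
            clone_rows.append(row)

    clones = CloneTable(pd.DataFrame(clone_rows), list(samples))
    return clones, genes, truth


# ---------------------------------------------------------------------------
# promoter tiling tracks
# ---------------------------------------------------------------------------


def simulate_promoter_track(
    config: Config | None = None,
    n_probes: int = 20_000,
    probe_spacing_bp: int = 100,
    peak_genes: int | Sequence[str] = 0,
    peak_height: float = 1.5,
    peak_halfwidth_bp: int = 400,
    chrom_depletion: Mapping[str, float | Mapping[str, float]] | None = None,
    seed: int = 0,
    mark: str = "5mC",
    sigma: float = 0.3,
    probes_per_promoter: int = 15,
    chrom_weights: Mapping[str, float] | None = None,
    center_offset: float = 0.0,
) -> tuple[ProbeTrack, SimulationTruth]:
    """Simulate a promoter tiling-probe track for one mark.

    Probes are laid out in consecutive promoter blocks of
    ``probes_per_promoter`` probes (one gene each, recorded in the promoter
    map).  Background ratios are Normal(``center_offset``, sigma).  Probes
    within ``peak_halfwidth_bp`` of a peak gene's promoter center get
    ``peak_height`` added in every sample.  ``chrom_depletion`` maps a
    chromosome to either a log2 offset applied to all samples, or a
    {group-or-sex: offset} mapping applied to the matching samples only.
    """
    config = config or Config()
    # genome-like shares: any single chromosome is a small minority of the
    # array, as on a genome-wide promoter array (chr8 holds ~4% of genes)
    chrom_weights = dict(chrom_weights or {
        "chr1": 0.30, "chr2": 0.25, "chr7": 0.18, "chr17": 0.12,
        "chr8": 0.08, "chrX": 0.07,
    })
    rng = np.random.default_rng(seed)
    sheet = default_sample_sheet()
    samples = sheet.sample_ids

    total_w = sum(chrom_weights.values())
    rows = []
    promoter_map: dict[str, str] = {}
    gene_center: dict[str, tuple[str, int]] = {}
    for chrom in sorted(chrom_weights):
        n_chrom = max(probes_per_promoter, int(round(n_probes * chrom_weights[chrom] / total_w)))
        n_genes = max(1, n_chrom // probes_per_promoter)
        probe_i = 0
        for g in range(n_genes):
            gene = f"{chrom}_PR{g:04d}"
            # promoters separated by a 5-kb gap so peaks never bleed over
            block_start = g * (probes_per_promoter * probe_spacing_bp + 5000)
            positions = [block_start + k * probe_spacing_bp for k in range(probes_per_promoter)]
            gene_center[gene] = (chrom, positions[len(positions) // 2])
            for pos in positions:
                pid = f"{chrom}_p{probe_i:05d}"
                probe_i += 1
                rows.append({"probe_id": pid, "chrom": chrom, "position": pos,
                             "gene": gene})
                promoter_map[pid] = gene

    frame = pd.DataFrame(rows)
    n = len(frame)
    values = rng.normal(center_offset, sigma, size=(n, len(samples)))

    truth = SimulationTruth()
    genes_all = sorted(gene_center)
    if isinstance(peak_genes, int):
        chosen = [str(g) for g in rng.choice(genes_all, size=peak_genes, replace=False)] if peak_genes else []
    else:
        chosen = list(peak_genes)
        missing = [g for g in chosen if g not in gene_center]
        if missing:
            raise ValidationError(f"peak genes without promoter_map entry: {missing}")
    for gene in chosen:
        chrom, center = gene_center[gene]
        mask = (
            (frame["chrom"] == chrom)
            & (frame["position"] - center).abs().le(peak_halfwidth_bp)
        ).to_numpy()
        if peak_height != 0:
            values[mask, :] += peak_height
            truth.enriched_promoter_genes[gene] = float(peak_height)

    if chrom_depletion:
        for chrom, offset in chrom_depletion.items():
            cmask = (frame["chrom"] == chrom).to_numpy()
            if isinstance(offset, Mapping):
                per_sample = {}
                for key, off in offset.items():
                    if key in (GROUP_TRISOMY, GROUP_DISOMY, GROUP_REFERENCE):
                        hit = sheet.samples_in_group(key)
                    else:
                        hit = sheet.samples_with_sex(key)
                    for s in hit:
                        per_sample[s] = per_sample.get(s, 0.0) + float(off)
                for j, s in enumerate(samples):
                    if s in per_sample:
                        values[cmask, j] += per_sample[s]
                truth.chrom_offsets[chrom] = per_sample
            else:
                values[cmask, :] += float(offset)
                truth.chrom_offsets[chrom] = {s: float(offset) for s in samples}

    for j, s in enumerate(samples):
        frame[s] = values[:, j]
    track = ProbeTrack(mark, frame.drop(columns=["gene"]), list(samples), promoter_map)
    return track, truth


# ---------------------------------------------------------------------------
# FISH
# ---------------------------------------------------------------------------


def simulate_fish_counts(
    n_nuclei: int = 300,
    true_trisomy_fraction: float = 0.0,
    seed: int = 0,
    n_clones: int = 1,
) -> pd.DataFrame:
    """Binomial draw of trisomic nuclei per single-cell clone.

    Every nucleus is scored as either trisomic or disomic (dual-probe
    interphase counting), so ``n_disomic = n_nuclei - n_trisomic``.
    """
    if n_nuclei <= 0:
        raise ValidationError(f"n_nuclei must be positive, got {n_nuclei}")
    if not (0.0 <= true_trisomy_fraction <= 1.0):
        raise ValidationError("true_trisomy_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_tri = rng.binomial(n_nuclei, true_trisomy_fraction, size=n_clones)
    return pd.DataFrame(
        {
            "clone_id": [f"clone{i}" for i in range(n_clones)],
            "n_total": n_nuclei,
            "n_trisomic": n_tri,
            "n_disomic": n_nuclei - n_tri,
        }
    )
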