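"""Genome-wide BAC-array methylation analysis.

Chain: smooth log2 ratios along the genome (factor 0.33 three-point
kernel), count annotated genes per clone, group clones per chromosome by
gene count (keeping bins holding >= 0.1% of the chromosome's clones),
test each bin with one-way unequal-n ANOVA over clone x sample
observations, and localize group differences with Tukey HSD
(Tukey-Kramer for unequal n).  A (chromosome, gene-count) bin is flagged
when the focal group differs from every other group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    GROUP_TRISOMY,
    GROUPS,
    CloneTable,
    Config,
    GeneModel,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)


def smooth_clone_ratios(clones: CloneTable, factor: float = 0.33) -> CloneTable:
    """Three-point weighted moving average along genomic order, per sample.

    Each clone's value becomes (f*left + center + f*right) / (1 + 2f); at
    chromosome ends the missing neighbor's weight is dropped and the
    remaining weights renormalize to sum 1, so constants are preserved
    everywhere.  factor 0 is the identity.
    """
    if factor < 0:
        raise ValidationError("smoothing factor must be >= 0")
    out = clones.copy()
    df = out.frame
    for chrom in out.chroms:
        idx = df.index[df["chrom"] == chrom]
        starts = df.loc[idx, "start"].to_numpy()
        if not (np.diff(starts) >= 0).all():
            raise ValidationError(f"clones not position-sorted on {chrom}")
        X = df.loc[idx, out.sample_ids].to_numpy(dtype=float)
        n = len(idx)
        if n == 1 or factor == 0:
            continue
        sm = np.empty_like(X)
        center = X
        left = np.vstack([np.zeros((1, X.shape[1])), X[:-1]])
        right = np.vstack([X[1:], np.zeros((1, X.shape[1]))])
        has_left = np.ones((n, 1))
        has_left[0] = 0.0
        has_right = np.ones((n, 1))
        has_right[-1] = 0.0
        weight_sum = 1.0 + factor * (has_left + has_right)
        sm = (center + factor * (left * has_left + right * has_right)) / weight_sum
        df.loc[idx, out.sample_ids] = sm
    return out


def annotate_gene_counts(clones: CloneTable, genes: Sequence[GeneModel]) -> CloneTable:
    """Count gene intervals overlapping each clone (any overlap, half-open).

    Uses the sorted-endpoint identity: overlaps = #(gene.start < clone.end)
    - #(gene.end <= clone.start), per chromosome.  Counts are stored uncapped.
    """
    out = clones.copy()
    df = out.frame
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {g.interval.chrom for g in genes}:
        members = [g for g in genes if g.interval.chrom == chrom]
        starts = np.sort(np.array([g.interval.start for g in members]))
        ends = np.sort(np.array([g.interval.end for g in members]))
        by_chrom[chrom] = (starts, ends)
    counts = np.zeros(len(df), dtype=int)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            logger.warning(
                "annotate_gene_counts: no gene annotation for %s; counts set to 0", chrom
            )
            continue
        starts, ends = by_chrom[chrom]
        c_start = sub["start"].to_numpy()
        c_end = sub["end"].to_numpy()
        n_before_end = np.searchsorted(starts, c_end, side="left")
        n_ended = np.searchsorted(ends, c_start, side="right")
        counts[sub.index.to_numpy()] = n_before_end - n_ended
    df["gene_count"] = counts
    return out


@dataclass
class GeneCountBin:
    """One (chromosome, gene-count) group of BAC clones with its test results."""

    chrom: str
    gene_count: int
    clone_ids: list[str]
    fraction_of_chrom: float
    group_means: dict[str, float] = field(default_factory=dict)
    anova_F: float = float("nan")
    anova_p: float = float("nan")
    tukey: dict[tuple[str, str], float] = field(default_factory=dict)
    flagged: bool = False


def bin_by_gene_count(clones: CloneTable, min_fraction: float = 0.001) -> list[GeneCountBin]:
    """One bin per (chrom, gene_count) holding >= min_fraction of that
    chromosome's clones (boundary inclusive); smaller bins are logged and dropped."""
    bins: list[GeneCountBin] = []
    for chrom in clones.chroms:
        sub = clones.on_chrom(chrom)
        total = len(sub)
        for count, grp in sub.groupby("gene_count", sort=True):
            fraction = len(grp) / total
            if fraction < min_fraction:
                logger.info(
                    "bin_by_gene_count: dropping %s count=%d (%.4f%% < %.4f%%)",
                    chrom, count, 100 * fraction, 100 * min_fraction,
                )
                continue
            bins.append(
                GeneCountBin(chrom, int(count), grp["clone_id"].tolist(), fraction)
            )
    return bins


def _bin_observations(
    bin_: GeneCountBin, clones: CloneTable, sheet: SampleSheet, group_by: str = "group"
) -> dict[str, np.ndarray]:
    """Clone x sample observations per group (or per sex) for one bin."""
    sub = clones.frame[clones.frame["clone_id"].isin(bin_.clone_ids)]
    out: dict[str, np.ndarray] = {}
    if group_by == "group":
        keys = [g for g in GROUPS if sheet.samples_in_group(g)]
        cols = {g: sheet.samples_in_group(g) for g in keys}
    elif group_by == "sex":
        keys = [s for s in ("XX", "XY") if sheet.samples_with_sex(s)]
        cols = {s: sheet.samples_with_sex(s) for s in keys}
    else:
        raise ValidationError(f"group_by must be 'group' or 'sex', got {group_by!r}")
    for key in keys:
        use = [c for c in cols[key] if c in clones.sample_ids]
        if use:
            out[key] = sub[use].to_numpy().ravel()
    return out


def bin_group_anova(
    bin_: GeneCountBin, clones: CloneTable, sheet: SampleSheet, group_by: str = "group"
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over the bin's clone x sample observations.

    Unequal group sizes receive the standard observation-count weighting of
    one-way ANOVA.  Identical groups return (F=0, p=1).
    """
    obs = _bin_observations(bin_, clones, sheet, group_by)
    groups = [v for v in obs.values() if len(v) >= 2]
    if len(groups) < 2:
        raise ValidationError(
            f"bin {bin_.chrom}:{bin_.gene_count} has <2 groups with >=2 observations"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*groups)
    if np.isnan(F):  # all observations identical
        F, p = 0.0, 1.0
    bin_.anova_F, bin_.anova_p = float(F), float(p)
    bin_.group_means = {k: float(np.mean(v)) for k, v in obs.items()}
    return float(F), float(p)


def tukey_hsd(
    bin_: GeneCountBin, clones: CloneTable, sheet: SampleSheet,
    group_by: str = "group",
) -> dict[tuple[str, str], float]:
    """Tukey-Kramer studentized-range pairwise comparisons for the bin."""
    obs = _bin_observations(bin_, clones, sheet, group_by)
    keys = [k for k, v in obs.items() if len(v) >= 2]
    if len(keys) < 2:
        raise ValidationError("Tukey HSD needs >=2 groups with >=2 observations")
    arrays = [obs[k] for k in keys]
    if all(np.allclose(a, arrays[0][0]) for a in arrays):
        result_p = {
            (keys[i], keys[j]): 1.0
            for i in range(len(keys))
            for j in range(i + 1, len(keys))
        }
        bin_.tukey = result_p
        return result_p
    res = stats.tukey_hsd(*arrays)
    out: dict[tuple[str, str], float] = {}
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            out[(keys[i], keys[j])] = float(res.pvalue[i, j])
    bin_.tukey = out
    return out


def gene_density_scan(
    clones: CloneTable,
    sheet: SampleSheet,
    config: Config | None = None,
    genes: Sequence[GeneModel] | None = None,
    group_by: str = "group",
    focal_group: str | None = None,
) -> tuple[list[GeneCountBin], pd.DataFrame]:
    """Full chain: smooth -> (annotate) -> bin -> ANOVA -> Tukey -> flag.

    A bin is flagged when its ANOVA p < alpha and the focal group (trisomy8
    for the culture-group contrast, XX for the sex contrast) differs from
    every other group at alpha in the Tukey comparisons.  Also returns the
    per-chromosome gene-count proportion curve with per-group bin means.
    """
    config = config or Config()
    if focal_group is None:
        focal_group = GROUP_TRISOMY if group_by == "group" else "XX"
    smoothed = smooth_clone_ratios(clones, config.smoothing_factor)
    if genes is not None:
        smoothed = annotate_gene_counts(smoothed, genes)
    bins = bin_by_gene_count(smoothed, config.bin_min_fraction)
    rows = []
    for b in bins:
        try:
            bin_group_anova(b, smoothed, sheet, group_by)
            tukey_hsd(b, smoothed, sheet, group_by)
        except ValidationError:
            continue
        focal_pairs = [p for pair, p in b.tukey.items() if focal_group in pair]
        b.flagged = (
            b.anova_p < config.alpha
            and len(focal_pairs) > 0
            and all(p < config.alpha for p in focal_pairs)
        )
        row = {
            "chrom": b.chrom,
            "gene_count": b.gene_count,
            "n_clones": len(b.clone_ids),
            "fraction_of_chrom": b.fraction_of_chrom,
            "anova_F": b.anova_F,
            "anova_p": b.anova_p,
            "flagged": b.flagged,
        }
        for k, v in b.group_means.items():
            row[f"mean_{k}"] = v
        for (a, c), p in b.tukey.items():
            row[f"tukey_{a}_vs_{c}"] = p
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(["chrom", "gene_count"]).reset_index(drop=True)
    return bins, table
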