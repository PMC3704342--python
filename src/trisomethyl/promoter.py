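"""Promoter tiling-array analysis of 5mC / 5hmC enrichment.

Steps: robust centering of log2 IP/input ratios by subtracting Tukey's
biweight mean per sample; a windowed one-sided Kolmogorov-Smirnov probe
score (750-bp window around each probe, tested against all other probes
on the array, score = -log10 p); an exact L0 (Potts) piecewise-constant
segmentation of promoter score tracks (penalty per jump, minimum segment
size); enriched-gene calling by size-targeted thresholding of segment
means; and chromosome-level promoter comparisons (trisomy depletion, X
versus autosomes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    GROUP_DISOMY,
    GROUP_REFERENCE,
    GROUP_TRISOMY,
    GROUPS,
    Config,
    ProbeTrack,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)

LOG10_E = math.log10(math.e)


# ---------------------------------------------------------------------------
# biweight centering
# ---------------------------------------------------------------------------


def biweight_mean(values: np.ndarray, c: float = 9.0, tol: float = 1e-8,
                  max_iter: int = 100) -> float:
    """Tukey's biweight (bisquare) location estimate.

    Scale is c * MAD about the median; observations beyond it get zero
    weight, others weight (1 - u^2)^2.  MAD 0 (more than half the data
    identical) returns the median.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("biweight_mean of empty array")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        return med
    scale = c * mad
    t = med
    for _ in range(max_iter):
        u = (x - t) / scale
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0.0:
            return t
        t_new = float(np.sum(w * x) / w.sum())
        if abs(t_new - t) < tol:
            return t_new
        t = t_new
    return t


def biweight_scale(track: ProbeTrack) -> ProbeTrack:
    """Center each sample's log2 ratios by subtracting its biweight mean.

    Stores the result as the track's ``scaled`` block; idempotent to
    numerical tolerance because the biweight mean of centered data is ~0.
    """
    scaled = {}
    for s in track.sample_ids:
        col = track.frame[s].to_numpy(dtype=float)
        scaled[s] = col - biweight_mean(col)
    out = ProbeTrack(
        track.mark, track.frame.copy(), list(track.sample_ids), dict(track.promoter_map)
    )
    out.scaled = pd.DataFrame(scaled, index=track.frame.index)[track.sample_ids]
    return out


# ---------------------------------------------------------------------------
# windowed one-sided KS scoring
# ---------------------------------------------------------------------------


def one_sided_ks_dplus(window: np.ndarray, background: np.ndarray) -> float:
    """D+ = sup_t [F_background(t) - F_window(t)].

    Positive when the window values sit above the background; the supremum
    of the right-continuous ECDF difference is attained just below a window
    jump (or is 0), so only window points need evaluating.
    """
    w = np.sort(np.asarray(window, dtype=float))
    m, n = len(w), len(background)
    if m == 0 or n == 0:
        return 0.0
    bg_sorted = np.sort(np.asarray(background, dtype=float))
    win_less = np.searchsorted(w, w, side="left")
    bg_less = np.searchsorted(bg_sorted, w, side="left")
    diffs = bg_less / n - win_less / m
    return float(max(0.0, diffs.max()))


def ks_score_from_dplus(d_plus: float, m: int, n: int, cap: float = 300.0) -> float:
    """-log10 of the asymptotic one-sided p = exp(-2 m n D+^2 / (m+n))."""
    if m == 0 or n == 0:
        return 0.0
    score = 2.0 * m * n * d_plus**2 / (m + n) * LOG10_E
    return float(min(score, cap))


@dataclass
class ScoreTrack:
    """-log10 p KS scores per probe, one column per sample or group."""

    mark: str
    frame: pd.DataFrame  # probe_id, chrom, position + score columns
    score_columns: list[str]
    promoter_map: dict[str, str]

    def scores(self, column: str) -> np.ndarray:
        return self.frame[column].to_numpy()


def acme_ks_scores(
    track: ProbeTrack,
    sheet: SampleSheet | None = None,
    window_bp: float = 750.0,
    by: str = "group",
    direction: str = "greater",
    score_cap: float = 300.0,
    background: str = "array",
) -> ScoreTrack:
    """Windowed one-sided KS enrichment score around each consecutive probe.

    For each probe the in-window set holds the probes within window_bp/2 of
    its center on the same chromosome; the one-sided two-sample KS statistic
    D+ asks whether the window's scaled ratios are drawn from a more
    positive distribution than all out-of-window probes on the array
    (``background="chromosome"`` restricts the comparison set).  The score
    is -log10 of the asymptotic p = exp(-2 m n D+^2/(m+n)), capped.
    ``by="group"`` scores per-group mean scaled tracks (requires a sample
    sheet); ``by="sample"`` scores each sample.  Windows with fewer than 2
    probes score 0.
    """
    if direction != "greater":
        raise ValidationError("only direction='greater' (peaks) is supported")
    scaled = track.require_scaled()
    if by == "group":
        if sheet is None:
            raise ValidationError("per-group scoring requires a sample sheet")
        columns = {}
        for g in GROUPS:
            cols = [s for s in sheet.samples_in_group(g) if s in scaled.columns]
            if cols:
                columns[g] = scaled[cols].mean(axis=1).to_numpy()
    elif by == "sample":
        columns = {s: scaled[s].to_numpy() for s in track.sample_ids}
    else:
        raise ValidationError("by must be 'group' or 'sample'")

    frame = track.frame
    positions = frame["position"].to_numpy()
    chroms = frame["chrom"].to_numpy()
    N = len(frame)
    half = window_bp / 2.0

    # window bounds per probe (inclusive), probes sorted by (chrom, position)
    lo = np.empty(N, dtype=int)
    hi = np.empty(N, dtype=int)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        lo[idx] = idx[0] + np.searchsorted(pos, pos - half, side="left")
        hi[idx] = idx[0] + np.searchsorted(pos, pos + half, side="right")

    out = frame[["probe_id", "chrom", "position"]].copy()
    small_windows = 0
    for name, values in columns.items():
        values = np.asarray(values, dtype=float)
        all_sorted = np.sort(values)
        chrom_sorted = {c: np.sort(values[chroms == c]) for c in pd.unique(chroms)}
        scores = np.zeros(N)
        for i in range(N):
            w = values[lo[i]:hi[i]]
            m = len(w)
            if m < 2:
                small_windows += 1
                continue
            if background == "array":
                pool, total = all_sorted, N
            else:
                pool, total = chrom_sorted[chroms[i]], len(chrom_sorted[chroms[i]])
            n = total - m
            if n <= 0:
                continue
            w_sorted = np.sort(w)
            win_less = np.searchsorted(w_sorted, w_sorted, side="left")
            all_less = np.searchsorted(pool, w_sorted, side="left")
            d_plus = max(0.0, float((( all_less - win_less) / n - win_less / m).max()))
            scores[i] = ks_score_from_dplus(d_plus, m, n, cap=score_cap)
        out[name] = scores
    if small_windows:
        logger.warning("acme_ks_scores: %d windows with <2 probes scored 0", small_windows)
    return ScoreTrack(track.mark, out, list(columns), dict(track.promoter_map))


# ---------------------------------------------------------------------------
# Potts (L0) segmentation
# ---------------------------------------------------------------------------


@dataclass
class SegmentationResult:
    """Piecewise-constant fit: segment boundaries, means and attained cost."""

    breakpoints: list[int]  # start index of each segment except the first
    segments: list[tuple[int, int]]  # half-open [start, end) index ranges
    segment_means: list[float]
    objective: float

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def fitted(self, n: int) -> np.ndarray:
        y = np.empty(n)
        for (a, b), mu in zip(self.segments, self.segment_means):
            y[a:b] = mu
        return y


def potts_smooth(values, gamma: float = 2.0, min_segment: int = 2) -> SegmentationResult:
    """Exact minimizer of sum of squared residuals + gamma * (segments - 1).

    Dynamic program over segment end positions, O(n^2), with every segment
    constrained to at least ``min_segment`` points; cost ties break toward
    fewer segments.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < min_segment:
        raise ValidationError(f"need at least {min_segment} values, got {n}")
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:  # cost of segment [i, j)
        s = s1[j] - s1[i]
        return max(0.0, (s2[j] - s2[i]) - s * s / (j - i))

    INF = float("inf")
    best_cost = np.full(n + 1, INF)
    best_nseg = np.full(n + 1, 0)
    back = np.full(n + 1, -1)
    best_cost[0], best_nseg[0] = 0.0, 0
    for j in range(min_segment, n + 1):
        for i in range(0, j - min_segment + 1):
            if i != 0 and i < min_segment:
                continue  # prefix of length < min_segment cannot be segmented
            if best_cost[i] == INF:
                continue
            cost = best_cost[i] + sse(i, j) + (gamma if i > 0 else 0.0)
            nseg = best_nseg[i] + 1
            if cost < best_cost[j] - 1e-12 or (
                cost <= best_cost[j] + 1e-12 and nseg < best_nseg[j]
            ):
                best_cost[j], best_nseg[j], back[j] = cost, nseg, i
    # reconstruct
    bounds = []
    j = n
    while j > 0:
        i = int(back[j])
        bounds.append((i, j))
        j = i
    bounds.reverse()
    means = [float((s1[b] - s1[a]) / (b - a)) for a, b in bounds]
    return SegmentationResult(
        breakpoints=[a for a, _ in bounds[1:]],
        segments=bounds,
        segment_means=means,
        objective=float(best_cost[n]),
    )


# ---------------------------------------------------------------------------
# enriched-gene calling
# ---------------------------------------------------------------------------


@dataclass
class EnrichedGeneSet:
    mark: str
    group: str
    genes: pd.DataFrame  # gene_id, score; ranked by score descending
    threshold: float

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()


def call_enriched_genes(
    score_track: ScoreTrack,
    group: str,
    target_range: tuple[int, int] = (150, 200),
    gamma: float = 2.0,
    min_segment: int = 2,
    score_threshold: float | None = None,
) -> EnrichedGeneSet:
    """Rank genes by the maximum Potts-segment mean of their promoter scores.

    Each gene's promoter probe scores are segmented with the edge-preserving
    Potts filter; its aggregate score is the largest segment mean, and the
    supporting segment necessarily spans >= min_segment probes.  Genes with
    fewer than min_segment probes cannot support a call and are skipped.
    The call threshold is either fixed (``score_threshold``) or chosen so
    the called set size lands inside ``target_range`` (midpoint when
    attainable), and is reported.
    """
    if group not in score_track.score_columns:
        raise ValidationError(f"no score column for group {group!r}")
    pm = score_track.promoter_map
    if not pm:
        logger.warning("call_enriched_genes: empty promoter map; no genes to call")
        return EnrichedGeneSet(score_track.mark, group,
                               pd.DataFrame(columns=["gene_id", "score"]), float("nan"))
    frame = score_track.frame
    gene_of = frame["probe_id"].map(pm)
    scores = frame[group].to_numpy()
    records = []
    for gene, idx in frame.groupby(gene_of, sort=True).groups.items():
        vals = scores[frame.index.get_indexer(idx)]
        if len(vals) < min_segment:
            continue
        seg = potts_smooth(vals, gamma=gamma, min_segment=min_segment)
        records.append((gene, max(seg.segment_means)))
    ranked = pd.DataFrame(records, columns=["gene_id", "score"]).sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)

    if score_threshold is not None:
        called = ranked[ranked["score"] >= score_threshold]
        threshold = float(score_threshold)
    else:
        lo, hi = target_range
        target = min((lo + hi) // 2, len(ranked))
        if target == 0:
            called = ranked.iloc[:0]
            threshold = float("nan")
        else:
            threshold = float(ranked["score"].iloc[target - 1])
            called = ranked.iloc[:target]
            if len(ranked) < lo:
                logger.warning(
                    "call_enriched_genes: only %d scorable genes (< target %d)",
                    len(ranked), lo,
                )
    return EnrichedGeneSet(score_track.mark, group, called.reset_index(drop=True), threshold)


# ---------------------------------------------------------------------------
# chromosome-level comparisons
# ---------------------------------------------------------------------------


def _promoter_levels(track: ProbeTrack, columns: dict[str, list[str]]) -> pd.DataFrame:
    """Per-gene mean scaled level for each named sample pool."""
    scaled = track.require_scaled()
    gene_of = track.frame["probe_id"].map(track.promoter_map)
    chrom_of = track.frame.groupby(gene_of)["chrom"].first()
    out = pd.DataFrame({"chrom": chrom_of})
    for name, cols in columns.items():
        pooled = scaled[cols].mean(axis=1)
        out[name] = pooled.groupby(gene_of).mean()
    out.index.name = "gene_id"
    return out


def chromosome_promoter_comparison(
    track: ProbeTrack,
    sheet: SampleSheet,
    chrom: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Compare per-promoter levels on a chromosome: trisomy vs disomy+reference.

    Per promoter, the group-average scaled level is computed for both arms,
    median-centered across all promoters on the array (per arm), then the
    chromosome's promoters are compared between arms with a two-sided paired
    t-test.  Returns (per-promoter table on that chromosome, p).
    """
    tri = sheet.samples_in_group(GROUP_TRISOMY)
    rest = sheet.samples_in_group((GROUP_DISOMY, GROUP_REFERENCE))
    levels = _promoter_levels(track, {"trisomy8": tri, "rest": rest})
    for arm in ("trisomy8", "rest"):
        levels[arm] = levels[arm] - levels[arm].median()
    sub = levels[levels["chrom"] == chrom]
    if len(sub) < 2:
        raise ValidationError(f"chromosome {chrom!r} has fewer than 2 promoters")
    res = stats.ttest_rel(sub["trisomy8"], sub["rest"])
    table = sub.reset_index()[["gene_id", "chrom", "trisomy8", "rest"]]
    table["difference"] = table["trisomy8"] - table["rest"]
    return table, float(res.pvalue)


def x_vs_autosome_comparison(
    track: ProbeTrack, sheet: SampleSheet, x_chrom: str = "chrX"
) -> pd.DataFrame:
    """Per sample: Welch t-test of X promoter levels against pooled autosomes.

    Returns one row per sample with mean levels, t, p and the rank-plot data
    hook (median-centered X-promoter levels, sorted) accessible via
    :func:`x_rank_plot_data`.
    """
    levels = _promoter_levels(track, {s: [s] for s in track.sample_ids})
    on_x = levels["chrom"] == x_chrom
    if not on_x.any() or on_x.all():
        raise ValidationError("need promoters both on and off the X chromosome")
    rows = []
    for s in track.sample_ids:
        x_vals = levels.loc[on_x, s]
        a_vals = levels.loc[~on_x, s]
        t, p = stats.ttest_ind(x_vals, a_vals, equal_var=False)
        rows.append(
            {
                "sample_id": s,
                "group": sheet.group_of(s),
                "mean_X": float(x_vals.mean()),
                "mean_autosome": float(a_vals.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def x_rank_plot_data(
    track: ProbeTrack, sheet: SampleSheet, x_chrom: str = "chrX"
) -> pd.DataFrame:
    """Median-centered X-promoter levels ranked per sample (a permutation of
    the input levels; no value is invented)."""
    levels = _promoter_levels(track, {s: [s] for s in track.sample_ids})
    sub = levels[levels["chrom"] == x_chrom]
    out = {}
    for s in track.sample_ids:
        centered = sub[s] - levels[s].median()
        out[s] = np.sort(centered.to_numpy())
    return pd.DataFrame(out)
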