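"""Expression-side statistics for the trisomic-versus-disomic clone design.

Covers FISH-based clone classification, variance filtering, median
centering, row standardization, group-significant probe selection
(one-way ANOVA with Benjamini-Hochberg correction), hierarchical
clustering, SAM (significance analysis of microarrays, permutation FDR),
Welch t-tests, signed fold changes, the intersection rule for
trisomy-associated calls, chromosome dosage profiles, a correlation-matrix
PCA diagnostic, and the comparative-CT qPCR check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .core_io import (
    GROUP_DISOMY,
    GROUP_REFERENCE,
    GROUP_TRISOMY,
    GROUPS,
    Config,
    ExpressionMatrix,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# clone classification (FISH)
# ---------------------------------------------------------------------------


def classify_clone_by_fish(
    n_total: int, n_trisomic: int, n_disomic: int, fraction: float = 0.95
) -> str:
    """Designate a single-cell clone from interphase FISH nucleus counts.

    A clone is called trisomic (or disomic) when at least ``fraction``
    (default 95%, i.e. 285 of 300 nuclei) of scored nuclei show the
    corresponding signal pattern; anything else is rejected as mosaic.
    """
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if n_trisomic < 0 or n_disomic < 0:
        raise ValidationError("nucleus counts must be non-negative")
    if n_trisomic + n_disomic > n_total:
        raise ValidationError("n_trisomic + n_disomic exceeds n_total")
    if n_trisomic / n_total >= fraction:
        return GROUP_TRISOMY
    if n_disomic / n_total >= fraction:
        return GROUP_DISOMY
    return "reject"


# ---------------------------------------------------------------------------
# filtering / normalization
# ---------------------------------------------------------------------------


def variance_filter(matrix: ExpressionMatrix, fraction: float = 0.5) -> ExpressionMatrix:
    """Retain the ceil(fraction * n) probes with largest across-sample SD.

    Ties at the cut are broken toward the lexicographically smaller
    probe id, so the result is deterministic.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError(f"fraction must lie in (0, 1], got {fraction}")
    if matrix.values.shape[1] < 2:
        raise ValidationError("variance filter needs at least 2 samples")
    sd = matrix.values.std(axis=1, ddof=1)
    k = math.ceil(fraction * matrix.n_probes)
    # sort on (-sd, probe_id): ties at the cut keep the smaller id
    order = (
        pd.DataFrame({"sd": sd.to_numpy(), "pid": sd.index.to_numpy()})
        .sort_values(["sd", "pid"], ascending=[False, True], kind="stable")
    )
    keep = order["pid"].iloc[:k]
    return matrix.subset_probes(keep)


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each probe row's across-sample median (idempotent)."""
    centered = matrix.values.sub(matrix.values.median(axis=1), axis=0)
    return ExpressionMatrix(centered, matrix.annotation.copy())


def standardize_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each row to mean 0, SD 1 (population SD); drop constant rows."""
    mean = matrix.values.mean(axis=1)
    sd = matrix.values.std(axis=1, ddof=0)
    zero = sd == 0
    if zero.any():
        logger.warning("standardize_rows: dropping %d zero-variance rows", int(zero.sum()))
    kept = matrix.values.loc[~zero]
    z = kept.sub(mean[~zero], axis=0).div(sd[~zero], axis=0)
    return ExpressionMatrix(z, matrix.annotation.loc[~zero].copy())


# ---------------------------------------------------------------------------
# group-significant probes (ANOVA + BH)
# ---------------------------------------------------------------------------


def _group_columns(matrix: ExpressionMatrix, sheet: SampleSheet,
                   min_per_group: int = 2) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for g in GROUPS:
        cols = [s for s in sheet.samples_in_group(g) if s in matrix.sample_ids]
        if cols:
            groups[g] = cols
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups with samples")
    for g, cols in groups.items():
        if len(cols) < min_per_group:
            raise ValidationError(f"group {g!r} has fewer than {min_per_group} samples")
    return groups


def select_group_significant(
    matrix: ExpressionMatrix, sheet: SampleSheet, alpha: float = 0.05
) -> pd.DataFrame:
    """Probes whose expression differs among the culture groups.

    Per-probe one-way ANOVA F-test across groups on row-standardized data,
    Benjamini-Hochberg adjusted; returns probes with q < alpha sorted by
    (q, probe_id), with columns p and q.
    """
    std = standardize_rows(matrix)
    groups = _group_columns(std, sheet)
    arrays = [std.values[cols].to_numpy() for cols in groups.values()]
    f, p = stats.f_oneway(*arrays, axis=1)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"probe_id": std.probe_ids, "F": f, "p": p, "q": q})
    out = out[out["q"] < alpha].sort_values(["q", "probe_id"], kind="stable")
    return out.reset_index(drop=True)


def pca_scores(matrix: ExpressionMatrix, n_components: int = 3
               ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Correlation-matrix PCA of samples (diagnostic view, no test).

    Rows are standardized (so the sample-sample cross-product is the Pearson
    correlation structure); returns (scores, loadings, explained_variance).
    """
    std = standardize_rows(matrix)
    X = std.values.to_numpy()  # probes x samples, rows mean 0 sd 1
    corr = np.corrcoef(X.T)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1][:n_components]
    evals, evecs = evals[order], evecs[:, order]
    scores = pd.DataFrame(
        evecs * np.sqrt(np.maximum(evals, 0.0)),
        index=std.sample_ids,
        columns=[f"PC{i+1}" for i in range(len(order))],
    )
    loadings = pd.DataFrame(
        (X @ evecs) / max(len(X), 1),
        index=std.probe_ids,
        columns=scores.columns,
    )
    return scores, loadings, evals


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class DendrogramResult:
    sample_linkage: np.ndarray
    feature_linkage: np.ndarray | None
    sample_ids: list[str]
    probe_ids: list[str]
    sample_labels: dict[str, int]  # flat clusters at the requested cut


def hca(
    matrix: ExpressionMatrix,
    k: int = 3,
    sample_metric: str = "euclidean",
    feature_metric: str = "correlation",
    linkage_method: str = "average",
    cluster_features: bool = True,
) -> DendrogramResult:
    """Average-linkage clustering: Euclidean over samples, 1 - Pearson over genes."""
    X = matrix.values.to_numpy()
    if X.shape[1] < 2 or X.shape[0] < 1:
        raise ValidationError("hca needs at least 2 samples and 1 probe")
    sample_link = hierarchy.linkage(X.T, method=linkage_method, metric=sample_metric)
    feature_link = None
    if cluster_features and X.shape[0] >= 2:
        feature_link = hierarchy.linkage(X, method=linkage_method, metric=feature_metric)
    flat = hierarchy.fcluster(sample_link, t=k, criterion="maxclust")
    labels = dict(zip(matrix.sample_ids, (int(c) for c in flat)))
    return DendrogramResult(sample_link, feature_link, matrix.sample_ids,
                            list(matrix.probe_ids), labels)


def cluster_is_pure(result: DendrogramResult, sheet: SampleSheet,
                    group: str = GROUP_TRISOMY) -> bool:
    """True when the group's samples form exactly one flat cluster by themselves."""
    members = set(sheet.samples_in_group(group)) & set(result.sample_ids)
    labels = {result.sample_labels[s] for s in members}
    if len(labels) != 1:
        return False
    label = labels.pop()
    cluster = {s for s, c in result.sample_labels.items() if c == label}
    return cluster == members


# ---------------------------------------------------------------------------
# t-tests and fold changes
# ---------------------------------------------------------------------------


def two_class_t_test(
    matrix: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.Series:
    """Two-sided Welch t-test per probe; returns p-values indexed by probe.

    The degenerate all-constant case (zero variance in both groups with
    identical means) returns p = 1 by convention; zero variance with
    different means returns p = 0.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    A = matrix.values[list(group_a)].to_numpy()
    B = matrix.values[list(group_b)].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(A.mean(axis=1), B.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return pd.Series(p, index=matrix.probe_ids, name="p")


def fold_change(mean_log2_a: float, mean_log2_b: float):
    """Signed linear fold change from two mean log2 levels.

    delta = A - B; 2**delta when delta >= 0, else -2**(-delta), so the
    magnitude is always >= 1 and fold_change(a, b) == -fold_change(b, a)
    for a != b.
    """
    delta = np.asarray(mean_log2_a, dtype=float) - np.asarray(mean_log2_b, dtype=float)
    out = np.where(delta >= 0, np.power(2.0, delta), -np.power(2.0, -delta))
    if out.ndim == 0:
        return float(out)
    return out


def delta_delta_ct(
    ct_target_sample: float,
    ct_control_sample: float,
    ct_target_calibrator: float,
    ct_control_calibrator: float,
) -> float:
    """Comparative-CT fold expression: 2**(-ddCT).

    ddCT = (CT_target,sample - CT_control,sample)
         - (CT_target,calibrator - CT_control,calibrator).
    """
    ddct = (ct_target_sample - ct_control_sample) - (
        ct_target_calibrator - ct_control_calibrator
    )
    return float(2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# SAM: significance analysis of microarrays
# ---------------------------------------------------------------------------


def _two_class_stats(X: np.ndarray, mask_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tusher two-class relative difference r and pooled scatter s per row."""
    A, B = X[:, mask_a], X[:, ~mask_a]
    na, nb = A.shape[1], B.shape[1]
    r = A.mean(axis=1) - B.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (B - B.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * ss / (na + nb - 2))
    return r, s


def _multiclass_stats(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F-like contrast: r = sqrt(between-group MS), s = sqrt(within MS)."""
    classes = np.unique(labels)
    k = len(classes)
    n = X.shape[1]
    grand = X.mean(axis=1)
    between = np.zeros(X.shape[0])
    within = np.zeros(X.shape[0])
    for c in classes:
        sub = X[:, labels == c]
        nc = sub.shape[1]
        m = sub.mean(axis=1)
        between += nc * (m - grand) ** 2
        within += ((sub - m[:, None]) ** 2).sum(axis=1)
    r = np.sqrt(between / (k - 1))
    s = np.sqrt(within / (n - k))
    return r, s


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Tusher percentile minimization: s0 = the percentile of s minimizing the
    coefficient of variation of the d-statistic's scale across s-quantile bins."""
    percentiles = np.arange(0, 101, 5)
    candidates = np.percentile(s, percentiles)
    n_bins = min(100, max(5, len(s) // 20))
    edges = np.percentile(s, np.linspace(0, 100, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    best_cv, best_s0 = np.inf, float(candidates[0])
    for s0 in candidates:
        d = r / (s + s0)
        mads = []
        for b in range(n_bins):
            sel = bin_idx == b
            if sel.sum() >= 2:
                db = d[sel]
                mads.append(np.median(np.abs(db - np.median(db))) / 0.6745)
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _resolve_contrast_columns(sheet: SampleSheet, spec) -> list[str]:
    if isinstance(spec, str):
        spec = (spec,)
    return sheet.samples_in_group(list(spec))


def sam(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    contrast=("trisomy8", "disomy8"),
    n_permutations: int = 1000,
    seed: int = 0,
    s0_method: str = "tusher-percentile",
) -> pd.DataFrame:
    """SAM moderated statistic with permutation-based median-FDR q-values.

    ``contrast`` is either a pair (class A spec, class B spec) — each a group
    label or tuple of group labels — or the string ``"multiclass"`` for an
    F-like statistic over all three groups.  d_i = r_i / (s_i + s0) with s0
    chosen by Tusher's percentile minimization (``s0_method="zero"`` disables
    it).  The null distribution comes from label permutations: all distinct
    assignments when there are fewer than ``n_permutations``, otherwise a
    seeded sample.  q_i is the median number of null exceedances of |d_i|
    scaled by the pi0 estimate, monotonized to be non-increasing in |d|.
    Returns a DataFrame with columns d, s, q indexed by probe.
    """
    if n_permutations < 50:
        raise ValidationError("n_permutations < 50 gives unstable FDR estimates")
    rng = np.random.default_rng(seed)

    if contrast == "multiclass":
        groups = _group_columns(matrix, sheet)
        cols = [c for g in groups.values() for c in g]
        labels = np.concatenate(
            [np.full(len(g), i) for i, g in enumerate(groups.values())]
        )
        X = matrix.values[cols].to_numpy()
        r, s = _multiclass_stats(X, labels)
        s0 = _choose_s0(r, s) if s0_method == "tusher-percentile" else 0.0
        d = r / (s + s0)

        perms = _label_permutations(labels, n_permutations, rng)
        d_perm = np.empty((len(perms), len(d)))
        for b, lab in enumerate(perms):
            rp, sp = _multiclass_stats(X, lab)
            d_perm[b] = rp / (sp + s0)
    else:
        spec_a, spec_b = contrast
        cols_a = _resolve_contrast_columns(sheet, spec_a)
        cols_b = _resolve_contrast_columns(sheet, spec_b)
        cols_a = [c for c in cols_a if c in matrix.sample_ids]
        cols_b = [c for c in cols_b if c in matrix.sample_ids]
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ValidationError("each SAM class needs at least 2 samples")
        X = matrix.values[cols_a + cols_b].to_numpy()
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[: len(cols_a)] = True
        r, s = _two_class_stats(X, mask)
        s0 = _choose_s0(r, s) if s0_method == "tusher-percentile" else 0.0
        d = r / (s + s0)

        masks = _two_class_permutations(len(cols_a), X.shape[1], n_permutations, rng)
        d_perm = np.empty((len(masks), len(d)))
        for b, m in enumerate(masks):
            rp, sp = _two_class_stats(X, m)
            d_perm[b] = rp / (sp + s0)

    q = _sam_q_values(d, d_perm)
    return pd.DataFrame({"d": d, "s": s, "q": q}, index=matrix.probe_ids)


def _two_class_permutations(na: int, n: int, n_permutations: int,
                            rng: np.random.Generator) -> list[np.ndarray]:
    total = math.comb(n, na)
    if total <= n_permutations:
        masks = []
        for combo in combinations(range(n), na):
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            masks.append(m)
        return masks
    seen: set[tuple[int, ...]] = set()
    masks = []
    while len(masks) < n_permutations:
        combo = tuple(sorted(rng.choice(n, size=na, replace=False)))
        if combo in seen:
            continue
        seen.add(combo)
        m = np.zeros(n, dtype=bool)
        m[list(combo)] = True
        masks.append(m)
    return masks


def _label_permutations(labels: np.ndarray, n_permutations: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    n = len(labels)
    total = math.factorial(n)
    if total <= n_permutations * 10:  # enumerate distinct label arrangements
        from itertools import permutations as iperm

        seen: set[tuple[int, ...]] = set()
        out = []
        for p in iperm(range(n)):
            key = tuple(labels[list(p)])
            if key not in seen:
                seen.add(key)
                out.append(labels[list(p)])
                if len(out) >= n_permutations:
                    break
        return out
    return [rng.permutation(labels) for _ in range(n_permutations)]


def _sam_q_values(d: np.ndarray, d_perm: np.ndarray) -> np.ndarray:
    """Median-FDR q-values from the permutation null, monotone in |d|."""
    m = len(d)
    abs_d = np.abs(d)
    order = np.argsort(-abs_d, kind="stable")  # rank 1 = largest |d|
    thresholds = abs_d[order]

    # pi0: fraction of null-looking statistics, from the permuted quartiles
    flat = d_perm.ravel()
    q25, q75 = np.percentile(flat, [25, 75])
    pi0 = min(1.0, ((d > q25) & (d < q75)).sum() / max(0.5 * m, 1.0))

    sorted_abs_perm = np.sort(np.abs(d_perm), axis=1)
    counts = np.empty((d_perm.shape[0], m))
    for b in range(d_perm.shape[0]):
        counts[b] = m - np.searchsorted(sorted_abs_perm[b], thresholds, side="left")
    median_false = np.median(counts, axis=0)
    called = np.arange(1, m + 1)
    fdr = np.clip(pi0 * median_false / called, 0.0, 1.0)
    # monotone: q non-increasing in |d| == non-decreasing in rank
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(m)
    q[order] = fdr
    return q


# ---------------------------------------------------------------------------
# intersection calling and dosage profile
# ---------------------------------------------------------------------------


def call_trisomy_genes(
    matrix: ExpressionMatrix, sheet: SampleSheet, config: Config | None = None
) -> pd.DataFrame:
    """Trisomy-associated genes by the four-way intersection rule.

    Computes Welch-t p and SAM q for both contrasts — trisomy8 vs the
    patient's disomy8 clones, and trisomy8 vs disomy8 + reference combined —
    and flags probes passing p < alpha AND q <= sam_q_max in both.  Fold
    change is reported against the combined disomy + reference group.
    """
    config = config or Config()
    tri = [s for s in sheet.samples_in_group(GROUP_TRISOMY) if s in matrix.sample_ids]
    dis = [s for s in sheet.samples_in_group(GROUP_DISOMY) if s in matrix.sample_ids]
    rest = [
        s
        for s in sheet.samples_in_group((GROUP_DISOMY, GROUP_REFERENCE))
        if s in matrix.sample_ids
    ]
    p_vs_disomy = two_class_t_test(matrix, tri, dis)
    p_vs_all = two_class_t_test(matrix, tri, rest)
    rng = np.random.SeedSequence(config.seed).generate_state(2)
    q_vs_disomy = sam(
        matrix, sheet, contrast=(GROUP_TRISOMY, GROUP_DISOMY),
        n_permutations=config.n_permutations, seed=int(rng[0] % (2**31)),
    )["q"]
    q_vs_all = sam(
        matrix, sheet, contrast=(GROUP_TRISOMY, (GROUP_DISOMY, GROUP_REFERENCE)),
        n_permutations=config.n_permutations, seed=int(rng[1] % (2**31)),
    )["q"]
    log2_fc = matrix.values[tri].mean(axis=1) - matrix.values[rest].mean(axis=1)
    fc = fold_change(matrix.values[tri].mean(axis=1), matrix.values[rest].mean(axis=1))
    associated = (
        (p_vs_disomy < config.alpha)
        & (p_vs_all < config.alpha)
        & (q_vs_disomy <= config.sam_q_max)
        & (q_vs_all <= config.sam_q_max)
    )
    out = pd.DataFrame(
        {
            "gene_symbol": matrix.annotation["gene_symbol"],
            "chrom": matrix.annotation["chrom"],
            "log2_fc": log2_fc,
            "fold_change_signed": fc,
            "t_p_vs_disomy": p_vs_disomy,
            "t_p_vs_all": p_vs_all,
            "sam_q_vs_disomy": q_vs_disomy,
            "sam_q_vs_all": q_vs_all,
            "trisomy_associated": associated,
        },
        index=matrix.probe_ids,
    )
    return out


def chromosome_expression_profile(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    chrom: str,
    overexpression_margin: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Positional dosage profile of one chromosome plus the overexpressed fraction.

    Returns (profile, fraction).  The profile lists the chromosome's genes in
    positional order with per-group means of median-centered expression.  A
    gene counts as overexpressed when its trisomy-group median exceeds the
    disomy-group median by more than ``overexpression_margin`` (default half
    the single-copy dosage shift, log2(1.5)/2): the midpoint decision
    threshold between "no change" and the 3:2 dosage ratio.
    """
    if overexpression_margin is None:
        overexpression_margin = Config().overexpression_margin
    on_chrom = matrix.annotation["chrom"] == chrom
    if not on_chrom.any():
        raise ValidationError(f"no probes annotated on chromosome {chrom!r}")
    sub = matrix.subset_probes(matrix.probe_ids[on_chrom])
    centered = median_center(sub)
    order = np.argsort(sub.annotation["position"].to_numpy(), kind="stable")
    probe_order = sub.probe_ids[order]

    tri = sheet.samples_in_group(GROUP_TRISOMY)
    dis = sheet.samples_in_group(GROUP_DISOMY)
    ref = sheet.samples_in_group(GROUP_REFERENCE)
    prof = pd.DataFrame(
        {
            "gene_symbol": sub.annotation.loc[probe_order, "gene_symbol"],
            "position": sub.annotation.loc[probe_order, "position"],
            "mean_trisomy8": centered.values.loc[probe_order, tri].mean(axis=1),
            "mean_disomy8": centered.values.loc[probe_order, dis].mean(axis=1),
            "mean_reference": centered.values.loc[probe_order, ref].mean(axis=1),
        }
    )
    med_diff = (
        sub.values[tri].median(axis=1) - sub.values[dis].median(axis=1)
    )
    fraction = float((med_diff > overexpression_margin).mean())
    return prof, fraction
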