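"""Shared data model, readers/writers and validation for the pipeline.

All genomic coordinates are 0-based half-open (BED convention) internally;
1-based sources must be converted at the boundary.  Tiling-probe ``position``
is the probe center.  Missing values in numeric matrices are a hard error:
none of the downstream procedures define missing-data handling.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The three culture groups of the clone design.
GROUP_TRISOMY = "trisomy8"
GROUP_DISOMY = "disomy8"
GROUP_REFERENCE = "reference"
GROUPS = (GROUP_TRISOMY, GROUP_DISOMY, GROUP_REFERENCE)

SEXES = ("XX", "XY")
DURATIONS = ("short", "long")
MARKS = ("5mC", "5hmC")
BIOTYPES = ("coding", "miRNA", "other")

#: float formatting used by every writer (6 significant digits)
FLOAT_FMT = "%.6g"


class ValidationError(ValueError):
    """Raised when an input file or container violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap test under half-open arithmetic."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    symbol: str


@dataclass
class SampleSheet:
    """Sample → (group, sex, culture duration) assignment.

    ``group`` is one of trisomy8 / disomy8 / reference; sample ids are unique.
    """

    frame: pd.DataFrame  # columns: sample_id, group, sex, culture_duration

    REQUIRED = ("sample_id", "group", "sex", "culture_duration")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("sample sheet is empty")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicated sample ids: {dups}")
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(f"unknown group labels: {bad} (allowed {GROUPS})")
        bad_sex = sorted(set(df["sex"]) - set(SEXES))
        if bad_sex:
            raise ValidationError(f"unknown sex labels: {bad_sex}")
        bad_dur = sorted(set(df["culture_duration"]) - set(DURATIONS))
        if bad_dur:
            raise ValidationError(f"unknown culture_duration labels: {bad_dur}")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def samples_in_group(self, group: str | Sequence[str]) -> list[str]:
        """Sample ids in one group, or in a union of groups."""
        groups = [group] if isinstance(group, str) else list(group)
        bad = sorted(set(groups) - set(GROUPS))
        if bad:
            raise ValidationError(f"unknown group labels: {bad}")
        mask = self.frame["group"].isin(groups)
        return self.frame.loc[mask, "sample_id"].tolist()

    def samples_with_sex(self, sex: str) -> list[str]:
        if sex not in SEXES:
            raise ValidationError(f"unknown sex {sex!r}")
        return self.frame.loc[self.frame["sex"] == sex, "sample_id"].tolist()

    def group_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["group"].iloc[0]


@dataclass
class ExpressionMatrix:
    """log2 expression values (probes × samples) with per-probe annotation.

    ``annotation`` is indexed by probe_id with columns gene_symbol, chrom,
    position, biotype; probes lacking annotation carry nulls there.
    """

    values: pd.DataFrame  # index: probe_id, columns: sample_id
    annotation: pd.DataFrame  # index: probe_id

    ANNOT_COLS = ("gene_symbol", "chrom", "position", "biotype")

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicated probe ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated sample ids in matrix: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric cells")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                "non-finite expression value at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        # align annotation to value index; unannotated probes retained with nulls
        annot = self.annotation.reindex(self.values.index)
        for col in self.ANNOT_COLS:
            if col not in annot.columns:
                annot[col] = np.nan
        self.annotation = annot[list(self.ANNOT_COLS)]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return len(self.values)

    def subset_probes(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = pd.Index(probe_ids)
        return ExpressionMatrix(self.values.loc[ids], self.annotation.loc[ids])

    def validate_against(self, sheet: SampleSheet) -> None:
        missing = set(self.sample_ids) - set(sheet.sample_ids)
        if missing:
            raise ValidationError(
                f"matrix samples absent from sample sheet: {sorted(missing)}"
            )


@dataclass
class CloneTable:
    """BAC clones as genomic intervals carrying per-sample log2 ratios.

    ``frame`` columns: clone_id, chrom, start, end, gene_count, then one
    column per sample.  Rows are kept position-sorted within chromosome,
    which the smoothing step relies on.
    """

    frame: pd.DataFrame
    sample_ids: list[str]

    META_COLS = ("clone_id", "chrom", "start", "end", "gene_count")

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("clone_id", "chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"clone table missing column {col!r}")
        if "gene_count" not in df.columns:
            df = df.assign(gene_count=0)
        if df["clone_id"].duplicated().any():
            raise ValidationError("duplicated clone ids")
        if (df["end"] <= df["start"]).any():
            bad = df.loc[df["end"] <= df["start"], "clone_id"].tolist()
            raise ValidationError(f"clones with end <= start: {bad[:5]}")
        if (df["gene_count"] < 0).any():
            raise ValidationError("negative gene_count")
        missing = [s for s in self.sample_ids if s not in df.columns]
        if missing:
            raise ValidationError(f"clone table missing sample columns: {missing}")
        vals = df[self.sample_ids].to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite clone log2 ratio")
        df = df.sort_values(["chrom", "start", "end", "clone_id"], kind="stable")
        self.frame = df.reset_index(drop=True)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.frame["chrom"].unique())

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]

    def copy(self) -> "CloneTable":
        return CloneTable(self.frame.copy(), list(self.sample_ids))


@dataclass
class ProbeTrack:
    """Ordered promoter tiling probes with per-sample log2 IP/input ratios.

    ``frame`` columns: probe_id, chrom, position (0-based probe center), then
    raw log2 ratio columns named after samples.  ``scaled`` (same shape as the
    raw block) and ``scores`` are filled in by the promoter-analysis steps.
    ``promoter_map`` assigns probes inside an annotated promoter/CpG island to
    a gene id.
    """

    mark: str
    frame: pd.DataFrame
    sample_ids: list[str]
    promoter_map: Mapping[str, str] = field(default_factory=dict)
    scaled: pd.DataFrame | None = None  # index aligned with frame rows

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValidationError(f"mark must be one of {MARKS}, got {self.mark!r}")
        df = self.frame
        for col in ("probe_id", "chrom", "position"):
            if col not in df.columns:
                raise ValidationError(f"probe track missing column {col!r}")
        missing = [s for s in self.sample_ids if s not in df.columns]
        if missing:
            raise ValidationError(f"probe track missing sample columns: {missing}")
        if df["probe_id"].duplicated().any():
            raise ValidationError("duplicated probe ids in track")
        df = df.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["position"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValidationError(
                    f"probe positions not strictly increasing on {chrom}"
                )
        self.frame = df

    @property
    def n_probes(self) -> int:
        return len(self.frame)

    def require_scaled(self) -> pd.DataFrame:
        if self.scaled is None:
            raise ValidationError(
                "track has no scaled ratios; run biweight_scale first"
            )
        return self.scaled

    def genes(self) -> list[str]:
        return sorted(set(self.promoter_map.values()))

    def probes_of_gene(self, gene_id: str) -> list[str]:
        return [p for p, g in self.promoter_map.items() if g == gene_id]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """Pipeline constants.

    The defaults are the procedure's operating points: 50% variance filter,
    alpha 0.05, SAM q <= 10%, +/-0.5 log2 expression-class cut-offs, 95% FISH
    cut-off, 0.33 smoothing factor, 0.1% bin-inclusion rule, 750-bp KS window,
    Potts penalty 2 with minimum segment 2, and a 150-200 enriched-gene target
    (midpoint 175).
    """

    variance_filter_fraction: float = 0.5
    alpha: float = 0.05
    sam_q_max: float = 0.10
    fc_log2_cut: float = 0.5
    fish_fraction: float = 0.95
    smoothing_factor: float = 0.33
    bin_min_fraction: float = 0.001
    ks_window_bp: float = 750.0
    potts_gamma: float = 2.0
    potts_min_segment: int = 2
    enriched_gene_target: int = 175
    n_permutations: int = 1000
    seed: int = 0
    # secondary knobs
    score_cap: float = 300.0  # cap on -log10 p KS scores
    score_floor: float = 1.3  # "significant" promoter score, p <= 0.05
    overexpression_margin: float = 0.5 * math.log2(1.5)
    gene_poor_max_genes: int = 1  # gene counts <= this are "gene-poor"
    trisomic_chrom: str = "chr8"

    def __post_init__(self) -> None:
        for name in ("variance_filter_fraction", "alpha", "sam_q_max",
                     "fish_fraction", "bin_min_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must lie in (0, 1], got {v}")
        if self.ks_window_bp <= 0 or self.potts_gamma <= 0:
            raise ValidationError("ks_window_bp and potts_gamma must be positive")
        if self.potts_min_segment < 1:
            raise ValidationError("potts_min_segment must be >= 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers / writers (TSV, UTF-8, '#'-comment lines ignored)
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_expression_matrix(path, annotation_path=None) -> ExpressionMatrix:
    """Read a tab-delimited probe × sample matrix plus optional annotation.

    The matrix header row carries sample ids; the first column is probe_id.
    The annotation file maps probe_id → gene_symbol, chrom, position, biotype.
    Non-numeric cells and duplicated probe/sample ids are hard errors.
    """
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
        else:
            raise ValidationError(f"{path}: empty file")
    dup_headers = {h for h in header if header.count(h) > 1}
    if dup_headers:
        raise ValidationError(f"{path}: header repeats sample_id {sorted(dup_headers)}")
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: expected probe_id column plus samples")
    probe_col = raw.columns[0]
    if raw[probe_col].duplicated().any():
        dup = raw.loc[raw[probe_col].duplicated(), probe_col].iloc[0]
        raise ValidationError(f"{path}: duplicated probe_id {dup!r}")
    values = raw.set_index(probe_col)
    values.index.name = "probe_id"
    if values.columns.duplicated().any():
        dup = values.columns[values.columns.duplicated()][0]
        raise ValidationError(f"{path}: header repeats sample_id {dup!r}")
    numeric = pd.DataFrame(index=values.index)
    for col in values.columns:
        converted = pd.to_numeric(values[col], errors="coerce")
        bad = converted.isna() & values[col].notna()
        if bad.any():
            row = values.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{path}: non-numeric value at probe {row!r}, sample {col!r}"
            )
        if converted.isna().any():
            row = values.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ValidationError(f"{path}: missing value at probe {row!r}, sample {col!r}")
        numeric[col] = converted.astype(float)

    if annotation_path is not None:
        annot = _read_tsv(annotation_path)
        if "probe_id" not in annot.columns:
            raise ValidationError(f"{annotation_path}: missing probe_id column")
        annot = annot.set_index("probe_id")
        if "position" in annot.columns:
            annot["position"] = pd.to_numeric(annot["position"], errors="raise")
    else:
        annot = pd.DataFrame(index=numeric.index)
    return ExpressionMatrix(numeric, annot)


def write_expression_matrix(matrix: ExpressionMatrix, path, annotation_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="probe_id")
    if annotation_path is not None:
        matrix.annotation.to_csv(
            annotation_path, sep="\t", float_format=FLOAT_FMT, index_label="probe_id"
        )


def read_intervals_bed(path) -> list[tuple[str, GenomicInterval]]:
    """Read a 3+ column BED file into (id, interval) pairs.

    Output is sorted by (chrom, start, end), stable for ties; nameless lines
    get ids ``interval_<lineno>``.
    """
    out: list[tuple[str, GenomicInterval]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            name = parts[3] if len(parts) > 3 and parts[3] else f"interval_{lineno}"
            out.append((name, GenomicInterval(chrom, start, end)))
    out.sort(key=lambda item: (item[1].chrom, item[1].start, item[1].end))
    return out


def write_intervals_bed(intervals: Sequence[tuple[str, GenomicInterval]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_gene_models_bed(path) -> list[GeneModel]:
    """Genes from a BED file; the name column doubles as gene id and symbol."""
    return [GeneModel(name, iv, name) for name, iv in read_intervals_bed(path)]


def read_sample_sheet(path) -> SampleSheet:
    df = _read_tsv(path)
    if df.empty:
        raise ValidationError(f"{path}: sample sheet is empty")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_clone_table(path, sample_ids: Sequence[str] | None = None) -> CloneTable:
    """Read a BAC clone table: clone_id, chrom, start, end[, gene_count], samples."""
    df = pd.read_csv(path, sep="\t", comment="#")
    meta = [c for c in CloneTable.META_COLS if c in df.columns]
    if sample_ids is None:
        sample_ids = [c for c in df.columns if c not in meta]
    for col in ("start", "end"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    if "gene_count" in df.columns:
        df["gene_count"] = pd.to_numeric(df["gene_count"], errors="raise").astype(int)
    for s in sample_ids:
        df[s] = pd.to_numeric(df[s], errors="raise").astype(float)
    return CloneTable(df, list(sample_ids))


def write_clone_table(clones: CloneTable, path) -> None:
    cols = [c for c in CloneTable.META_COLS if c in clones.frame.columns]
    cols += clones.sample_ids
    clones.frame[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_probe_track(path, mark: str, sample_ids: Sequence[str] | None = None,
                     promoter_map_path=None) -> ProbeTrack:
    """Read a promoter tiling track: probe_id, chrom, position, one column per sample."""
    df = pd.read_csv(path, sep="\t", comment="#")
    meta = ["probe_id", "chrom", "position"]
    if sample_ids is None:
        sample_ids = [c for c in df.columns if c not in meta]
    df["position"] = pd.to_numeric(df["position"], errors="raise").astype(int)
    for s in sample_ids:
        df[s] = pd.to_numeric(df[s], errors="raise").astype(float)
    promoter_map: dict[str, str] = {}
    if promoter_map_path is not None:
        pm = pd.read_csv(promoter_map_path, sep="\t", comment="#", dtype=str)
        if not {"probe_id", "gene_id"} <= set(pm.columns):
            raise ValidationError(
                f"{promoter_map_path}: needs probe_id and gene_id columns"
            )
        promoter_map = dict(zip(pm["probe_id"], pm["gene_id"]))
    return ProbeTrack(mark, df, list(sample_ids), promoter_map)


def write_probe_track(track: ProbeTrack, path, promoter_map_path=None) -> None:
    cols = ["probe_id", "chrom", "position"] + track.sample_ids
    track.frame[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    if promoter_map_path is not None:
        pm = pd.DataFrame(
            sorted(track.promoter_map.items()), columns=["probe_id", "gene_id"]
        )
        pm.to_csv(promoter_map_path, sep="\t", index=False)
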