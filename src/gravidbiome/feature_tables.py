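"""Feature tables, sample metadata, and study-design encodings.

A feature table is a taxa x samples matrix of non-negative integer counts,
each taxon carrying a Silva-style semicolon-delimited lineage string.
Sample metadata lives in a plain :class:`pandas.DataFrame` (one row per
sample) with the required design columns ``sample_id, subject_id, site,
arm, week, batch``; any further columns are treated as covariates or
biomarkers.

Library-level filtering drops samples below a minimum read depth
(default 3,700, inclusive).  Taxon-level filtering retains a taxon only if
it is present in at least 5% of samples *and* exceeds relative abundance
0.001 (strictly) in at least one sample; both thresholds are evaluated on
the whole analysis set, not per site.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITES = ("DRC", "Guatemala", "India", "Pakistan")
WEEKS = (12, 34)
ARMS = (1, 2, 3)

#: Columns every sample-metadata frame must provide.
REQUIRED_METADATA = ("sample_id", "subject_id", "site", "arm", "week", "batch")

#: Canonical rank order for semicolon-delimited lineage strings.
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class FeatureTableError(ValueError):
    """Malformed feature table or metadata input."""


@dataclass
class CountTable:
    """Taxa x samples count matrix with per-taxon lineage strings.

    Parameters
    ----------
    data:
        DataFrame of non-negative integers, indexed by taxon id with one
        column per sample id.
    lineages:
        Series mapping taxon id -> semicolon-delimited lineage string.
    """

    data: pd.DataFrame
    lineages: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FeatureTableError(f"duplicate taxon id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FeatureTableError(f"duplicate sample id {dup!r}")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FeatureTableError("counts must be integers")
            self.data = self.data.round().astype(np.int64)
            arr = self.data.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FeatureTableError(
                f"negative count at taxon {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        self.lineages = self.lineages.reindex(self.data.index)
        missing = self.lineages.isna() | (self.lineages.astype(str).str.strip() == "")
        if missing.any():
            raise FeatureTableError(
                f"taxon {self.lineages.index[missing][0]!r} has an empty lineage"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def depths(self) -> pd.Series:
        """Per-sample read depth (column sums)."""
        return self.data.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Columns scaled to sum to one; all-zero samples raise."""
        depths = self.depths()
        if (depths == 0).any():
            zero = depths.index[depths == 0][0]
            raise FeatureTableError(f"sample {zero!r} has zero total count")
        return self.data / depths

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[:, list(sample_ids)], self.lineages.copy())

    def subset_taxa(self, taxon_ids) -> "CountTable":
        return CountTable(self.data.loc[list(taxon_ids)], self.lineages.loc[list(taxon_ids)])

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy(), self.lineages.copy())


@dataclass
class FilterReport:
    """Audit record of one filtering step."""

    step: str
    thresholds: dict
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_taxa_in: int = 0
    n_taxa_out: int = 0
    removed_sample_ids: dict = field(default_factory=dict)
    removed_taxon_ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples_in - len(self.removed_sample_ids) != self.n_samples_out:
            raise ValueError("sample bookkeeping does not balance")
        if self.n_taxa_in - len(self.removed_taxon_ids) != self.n_taxa_out:
            raise ValueError("taxon bookkeeping does not balance")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def read_feature_table(path, transposed: bool = False) -> CountTable:
    """Read a tab-delimited feature table.

    First column holds the taxon lineage, remaining columns one sample
    each (or the transpose when ``transposed=True``).  Cells must be
    non-negative integers; violations raise with the offending row and
    column named.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for name in header:  # pandas mangles duplicate headers, so check first
        if name in seen:
            raise FeatureTableError(f"duplicate column {name!r} in {path}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transposed:
        df = df.T
    if df.index.duplicated().any():
        raise FeatureTableError(
            f"duplicate taxon id {df.index[df.index.duplicated()][0]!r} in {path}"
        )
    if df.columns.duplicated().any():
        raise FeatureTableError(
            f"duplicate sample id {df.columns[df.columns.duplicated()][0]!r} in {path}"
        )
    counts = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = df.index[numeric.isna()][0]
            raise FeatureTableError(
                f"non-numeric cell at taxon {row!r}, sample {col!r}"
            )
        if (numeric < 0).any():
            row = df.index[numeric < 0][0]
            raise FeatureTableError(
                f"negative count at taxon {row!r}, sample {col!r}"
            )
        if not np.allclose(numeric, np.round(numeric)):
            row = df.index[~np.isclose(numeric, np.round(numeric))][0]
            raise FeatureTableError(
                f"non-integer cell at taxon {row!r}, sample {col!r}"
            )
        counts[col] = numeric.astype(np.int64)
    lineages = pd.Series(counts.index, index=counts.index, name="lineage")
    return CountTable(counts, lineages)


def write_feature_table(table: CountTable, path) -> None:
    out = table.data.copy()
    out.index = table.lineages.values
    out.index.name = "lineage"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read a tab-delimited sample-metadata table and validate the design."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_sample_frame(frame)


def write_metadata(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def validate_sample_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and the one-sample-per-subject-week design."""
    missing = [c for c in REQUIRED_METADATA if c not in frame.columns]
    if missing:
        raise FeatureTableError(f"metadata missing required columns {missing}")
    if frame["sample_id"].duplicated().any():
        dup = frame["sample_id"][frame["sample_id"].duplicated()].iloc[0]
        raise FeatureTableError(f"duplicate sample_id {dup!r}")
    dup_sw = frame.duplicated(subset=["subject_id", "week"])
    if dup_sw.any():
        subj = frame.loc[dup_sw, "subject_id"].iloc[0]
        raise FeatureTableError(f"subject {subj!r} has >1 sample in one week")
    per_subject = frame.groupby("subject_id")[["site", "arm"]].nunique()
    bad = per_subject[(per_subject > 1).any(axis=1)]
    if len(bad):
        raise FeatureTableError(
            f"subject {bad.index[0]!r} maps to more than one site or arm"
        )
    return frame


def filter_min_depth(
    table: CountTable, frame: pd.DataFrame, min_reads: int = 3700
) -> tuple[CountTable, pd.DataFrame, FilterReport]:
    """Drop samples with read depth below ``min_reads`` (inclusive keep).

    The boundary is inclusive: a library with exactly ``min_reads`` reads
    is retained.  Table and metadata are subset consistently; removing
    every sample is an error rather than an empty result.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depths = table.depths()
    keep = depths.index[depths >= min_reads]
    removed = {
        s: f"depth {int(depths[s])} < {min_reads}" for s in depths.index if s not in set(keep)
    }
    if len(keep) == 0:
        raise FeatureTableError(
            f"all samples removed: no library reaches {min_reads} reads"
        )
    report = FilterReport(
        step="min_depth",
        thresholds={"min_reads": min_reads},
        n_samples_in=len(depths),
        n_samples_out=len(keep),
        n_taxa_in=table.shape[0],
        n_taxa_out=table.shape[0],
        removed_sample_ids=removed,
    )
    out_frame = frame[frame["sample_id"].isin(set(keep))].reset_index(drop=True)
    return table.subset_samples(keep), out_frame, report


def filter_taxa(
    table: CountTable, prevalence: float = 0.05, max_rel_abund: float = 0.001
) -> tuple[CountTable, FilterReport]:
    """Retain taxa present in >= ``prevalence`` of samples that also exceed
    ``max_rel_abund`` relative abundance (strictly) in at least one sample.

    Prevalence uses an inclusive boundary via ``ceil(prevalence * n)``;
    the abundance test is a strict ``>``.
    """
    n = table.shape[1]
    if n == 0:
        raise FeatureTableError("empty table")
    min_present = math.ceil(prevalence * n)
    present_in = (table.data > 0).sum(axis=1)
    rel = table.relative_abundance()
    abundant_somewhere = (rel > max_rel_abund).any(axis=1)
    keep_mask = (present_in >= min_present) & abundant_somewhere
    removed = {}
    for taxon in table.data.index[~keep_mask]:
        reasons = []
        if present_in[taxon] < min_present:
            reasons.append(f"present in {int(present_in[taxon])}/{n} < {min_present}")
        if not abundant_somewhere[taxon]:
            reasons.append(f"max rel. abundance <= {max_rel_abund}")
        removed[taxon] = "; ".join(reasons)
    keep = table.data.index[keep_mask]
    report = FilterReport(
        step="taxon_filter",
        thresholds={"prevalence": prevalence, "max_rel_abund": max_rel_abund},
        n_samples_in=n,
        n_samples_out=n,
        n_taxa_in=table.shape[0],
        n_taxa_out=int(keep_mask.sum()),
        removed_taxon_ids=removed,
    )
    return table.subset_taxa(keep), report


def parse_lineage(lineage: str) -> dict:
    """Split a semicolon-delimited lineage into named ranks."""
    parts = [p.strip() for p in str(lineage).split(";") if p.strip()]
    return dict(zip(LINEAGE_RANKS, parts))


def rank_label(lineage: str, rank: str) -> str:
    """Label of ``lineage`` at ``rank``; ``unclassified <parent>`` if unresolved."""
    if rank not in LINEAGE_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {LINEAGE_RANKS}")
    parsed = parse_lineage(lineage)
    if rank in parsed:
        return parsed[rank]
    parts = [p.strip() for p in str(lineage).split(";") if p.strip()]
    parent = parts[-1] if parts else "root"
    return f"unclassified {parent}"


def aggregate_rank(table: CountTable, rank: str) -> CountTable:
    """Sum counts over taxa sharing the same label at ``rank``.

    Taxa unresolved at the requested rank fall into an
    ``unclassified <deepest resolved parent>`` bucket; per-sample totals
    are preserved exactly.
    """
    labels = table.lineages.map(lambda lin: rank_label(lin, rank))
    grouped = table.data.groupby(labels.values, sort=False).sum()
    # lineage of a rank group: truncate at the rank (or parent + unclassified tag)
    new_lineages = {}
    for taxon, label in labels.items():
        if label in new_lineages:
            continue
        parts = [p.strip() for p in str(table.lineages[taxon]).split(";") if p.strip()]
        depth = LINEAGE_RANKS.index(rank) + 1
        new_lineages[label] = ";".join(parts[:depth]) if len(parts) >= depth else ";".join(
            parts + [label]
        )
    return CountTable(grouped, pd.Series(new_lineages).reindex(grouped.index))


def supplement_status(arm: int, week: int) -> int:
    """Trial supplement indicator as a function of arm and gestational week.

    Arm 1 is supplemented at both visits; Arm 2 starts the supplement
    after the 12-week visit; Arm 3 (never supplemented during pregnancy)
    is sampled only at 34 weeks, so (arm 3, week 12) is a design error.
    """
    if arm not in ARMS or week not in WEEKS:
        raise ValueError(f"invalid design cell (arm={arm}, week={week})")
    if arm == 3 and week == 12:
        raise ValueError("design has no Arm 3 samples at 12 weeks")
    if week == 12:
        return 1 if arm == 1 else 0
    return 1 if arm in (1, 2) else 0


def standardized_depth(depths) -> np.ndarray:
    """Z-score read depths (sample sd, ddof=1), preserving order."""
    arr = np.asarray(depths, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 samples to standardize depth")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("constant read depths cannot be standardized")
    return (arr - arr.mean()) / sd


def attach_design(frame: pd.DataFrame, depths: pd.Series | None = None) -> pd.DataFrame:
    """Add ``time`` (12->0, 34->1), ``supplement_status`` and, when depths
    are given, ``read_depth``/``standardized_depth`` columns."""
    out = frame.copy()
    out["time"] = (out["week"].astype(int) == 34).astype(int)
    out["supplement_status"] = [
        supplement_status(int(a), int(w)) for a, w in zip(out["arm"], out["week"])
    ]
    if depths is not None:
        out["read_depth"] = out["sample_id"].map(depths).astype(float)
        out["standardized_depth"] = standardized_depth(out["read_depth"].to_numpy())
    return out
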