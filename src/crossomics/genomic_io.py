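"""Interval algebra and on-disk formats.

Everything in the package speaks one coordinate convention internally:
0-based, half-open ``[start, end)`` — the BED convention.  The only format
that differs on disk is the Bismark-style cytosine report, whose positions
are 1-based; conversion happens exactly once, at the I/O boundary.

Formats handled here:

* Bismark-style cytosine reports (TSV: chrom, 1-based position, strand,
  methylated count, unmethylated count, trailing context columns ignored);
* BED3/BED6 (+ extra columns for DMR output);
* feature x sample integer count matrices (TSV, first column = feature id);
* differential-result tables with a fixed, documented header;
* sample sheets (sample id, path, group, sex, tissue, exposure).

Interval sets are plain :class:`pandas.DataFrame` objects with ``chrom``,
``start``, ``end`` columns (plus optional ``name``/``score``/``strand``/
``direction``); the two core interval operations — pairwise intersection
with a minimum-overlap rule and gap-tolerant merging — are implemented as a
single sort-and-sweep pass per chromosome.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "ParseError",
    "SchemaError",
    "CytosineReport",
    "CountMatrix",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_bed",
    "write_bed",
    "intersect_regions",
    "merge_regions",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "DIFFERENTIAL_COLUMNS",
    "read_differential_table",
    "write_differential_table",
    "interval_key",
    "parse_interval_key",
    "check_chromosome_compatibility",
]

VALID_STRANDS = {"+", "-", "."}

#: Required columns of a differential table, in on-disk order.
DIFFERENTIAL_COLUMNS = ["feature", "log2fc", "p", "padj", "significant", "direction"]


class ParseError(ValueError):
    """A malformed line in an on-disk file; the message names the line."""


class SchemaError(ValueError):
    """A table is missing required columns; the message lists them."""


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path) -> pd.DataFrame:
    """Read a Bismark-style per-CpG cytosine report.

    Returns a DataFrame with columns ``chrom`` (str), ``pos`` (int, 0-based),
    ``strand``, ``meth``, ``unmeth``.  On-disk positions are 1-based and are
    shifted here, the only place the conversion happens.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 tab-separated fields")
            chrom, pos_s, strand, meth_s, unmeth_s = fields[:5]
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer position or count fields"
                ) from None
            if pos <= 0:
                raise ParseError(f"{path}:{lineno}: position must be >= 1 (1-based)")
            if strand not in VALID_STRANDS:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative read count")
            rows.append((chrom, pos - 1, strand, meth, unmeth))
    if not rows:
        warnings.warn(f"empty cytosine report: {path}")
        return pd.DataFrame(columns=["chrom", "pos", "strand", "meth", "unmeth"]).astype(
            {"pos": np.int64, "meth": np.int64, "unmeth": np.int64}
        )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth"])
    if df.duplicated(["chrom", "pos"]).any():
        raise ParseError(f"{path}: duplicate (chrom, position) records")
    return df


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    """Write records (internal 0-based) back to the 1-based on-disk format."""
    out = df.loc[:, ["chrom", "pos", "strand", "meth", "unmeth"]].copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CytosineReport:
    """A per-sample cytosine table plus its sample label."""

    sample: str
    records: pd.DataFrame


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _validate_intervals(df: pd.DataFrame, where: str = "interval set") -> None:
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise SchemaError(f"{where}: missing required column {col!r}")
    if len(df):
        if (df["start"].to_numpy() < 0).any():
            raise ValueError(f"{where}: negative start coordinate")
        if (df["start"].to_numpy() >= df["end"].to_numpy()).any():
            raise ValueError(f"{where}: start >= end (empty or inverted interval)")


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ into an interval DataFrame (0-based half-open, as on disk)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 fields")
            rows.append(fields[:6])
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    width = max(len(r) for r in rows)
    df = pd.DataFrame([r + [None] * (width - len(r)) for r in rows],
                      columns=names[:width])
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except (TypeError, ValueError):
        raise ParseError(f"{path}: non-integer start/end coordinates") from None
    _validate_intervals(df, where=str(path))
    return df


def write_bed(df: pd.DataFrame, path, parameters: dict | None = None) -> None:
    """Write an interval DataFrame as BED, sorted by (chrom, start, end).

    A single ``#`` comment line records the tool version and any parameters.
    """
    _validate_intervals(df)
    cols = ["chrom", "start", "end"]
    for extra in df.columns:
        if extra not in cols:
            cols.append(extra)
    out = df.loc[:, cols].sort_values(["chrom", "start", "end"], kind="mergesort")
    with open(path, "w") as fh:
        params = " ".join(f"{k}={v}" for k, v in (parameters or {}).items())
        fh.write(f"# crossomics v{__version__}{(' ' + params) if params else ''}\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def intersect_regions(a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1) -> pd.DataFrame:
    """All pairs (x in a, y in b) overlapping by at least ``min_overlap`` bp.

    Returns a DataFrame with columns ``a_index``, ``b_index`` (labels into
    the input frames), ``chrom`` and ``overlap`` (bp).  Overlap length is
    ``max(0, min(ends) - max(starts))`` on the half-open convention, so
    bookended intervals do not match.  One sorted sweep per chromosome.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    _validate_intervals(a, "a")
    _validate_intervals(b, "b")
    if not len(a) or not len(b):
        return pd.DataFrame(columns=["a_index", "b_index", "chrom", "overlap"])
    check_chromosome_compatibility(a, b)
    out_a, out_b, out_c, out_len = [], [], [], []
    b_by_chrom = {c: g.sort_values("start", kind="mergesort") for c, g in b.groupby("chrom")}
    for chrom, ga in a.groupby("chrom"):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        bs = gb["start"].to_numpy(np.int64)
        be = gb["end"].to_numpy(np.int64)
        bidx = gb.index.to_numpy()
        # sweep in a-start order; candidates are b-intervals starting before
        # the a-end minus the required overlap
        ga = ga.sort_values("start", kind="mergesort")
        for ai, s, e in zip(ga.index, ga["start"].to_numpy(np.int64),
                            ga["end"].to_numpy(np.int64)):
            hi = np.searchsorted(bs, e - min_overlap, side="right")
            if hi == 0:
                continue
            ov = np.minimum(be[:hi], e) - np.maximum(bs[:hi], s)
            keep = ov >= min_overlap
            if keep.any():
                k = int(keep.sum())
                out_a.extend([ai] * k)
                out_b.extend(bidx[:hi][keep].tolist())
                out_c.extend([chrom] * k)
                out_len.extend(ov[keep].tolist())
    return pd.DataFrame(
        {"a_index": out_a, "b_index": out_b, "chrom": out_c, "overlap": out_len}
    )


def merge_regions(df: pd.DataFrame, max_gap: int = 0,
                  require_same_direction: bool = False) -> pd.DataFrame:
    """Merge intervals whose gap is <= ``max_gap`` (transitive closure).

    With ``require_same_direction`` the closure runs separately within each
    value of the ``direction`` column, so an opposite-direction interval
    sitting between two same-direction ones never bridges them and never
    blocks their (gap-permitting) merge.  Returns merged intervals sorted by
    (chrom, start) with a ``members`` column listing constituent input index
    labels, plus ``direction`` when grouped by it.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    _validate_intervals(df)
    if not len(df):
        cols = ["chrom", "start", "end", "members"]
        if require_same_direction:
            cols.insert(3, "direction")
        return pd.DataFrame(columns=cols)
    if require_same_direction and "direction" not in df.columns:
        raise SchemaError("require_same_direction needs a 'direction' column")
    group_cols = ["chrom", "direction"] if require_same_direction else ["chrom"]
    merged = []
    for gkey, g in df.groupby(group_cols):
        g = g.sort_values(["start", "end"], kind="mergesort")
        starts = g["start"].to_numpy(np.int64)
        ends = g["end"].to_numpy(np.int64)
        labels = g.index.to_numpy()
        cur_s, cur_e, members = starts[0], ends[0], [labels[0]]
        chrom = gkey[0] if isinstance(gkey, tuple) else gkey
        direction = gkey[1] if require_same_direction else None
        for s, e, lab in zip(starts[1:], ends[1:], labels[1:]):
            if s <= cur_e + max_gap:
                cur_e = max(cur_e, e)
                members.append(lab)
            else:
                merged.append((chrom, cur_s, cur_e, direction, members))
                cur_s, cur_e, members = s, e, [lab]
        merged.append((chrom, cur_s, cur_e, direction, members))
    out = pd.DataFrame(merged, columns=["chrom", "start", "end", "direction", "members"])
    if not require_same_direction:
        out = out.drop(columns="direction")
    return out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def check_chromosome_compatibility(a: pd.DataFrame, b: pd.DataFrame) -> None:
    """Warn when two interval sets name entirely disjoint chromosomes.

    Chromosome comparison is exact string match throughout the package (no
    ``chr`` prefix normalisation), so disjoint naming is almost always an
    input mix-up worth surfacing.
    """
    ca, cb = set(a["chrom"].unique()), set(b["chrom"].unique())
    if ca and cb and not (ca & cb):
        warnings.warn(
            "interval sets share no chromosome names: "
            f"{sorted(ca)[:4]} vs {sorted(cb)[:4]} (exact string comparison)"
        )


# ---------------------------------------------------------------------------
# count matrices and sample sheets
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample", "group", "sex", "tissue", "exposure"]


@dataclass
class CountMatrix:
    """Feature x sample integer counts plus per-sample metadata.

    ``counts`` is features (index) x samples (columns); ``samples`` is
    indexed by sample id with columns group / sex / tissue / exposure.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"sample metadata missing for: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def group_samples(self, group: str) -> list[str]:
        sel = self.samples.loc[list(self.counts.columns)]
        return list(sel.index[sel["group"] == group])


def write_count_matrix(cm: CountMatrix, counts_path, samples_path) -> None:
    cm.counts.rename_axis("feature").to_csv(counts_path, sep="\t")
    cm.samples.rename_axis("sample").to_csv(samples_path, sep="\t")


def read_count_matrix(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    samples = read_sample_sheet(samples_path)
    return CountMatrix(counts=counts, samples=samples)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample").to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns and c != "sample"]
    if "sample" not in df.columns:
        raise SchemaError(f"{path}: sample sheet missing 'sample' column")
    if missing:
        raise SchemaError(f"{path}: sample sheet missing columns {missing}")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df.set_index("sample")


# ---------------------------------------------------------------------------
# differential tables
# ---------------------------------------------------------------------------

def write_differential_table(df: pd.DataFrame, path, parameters: dict | None = None) -> None:
    """Write a differential table TSV with the fixed documented header."""
    missing = [c for c in DIFFERENTIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"differential table missing columns: {missing}")
    extra = [c for c in df.columns if c not in DIFFERENTIAL_COLUMNS]
    out = df.loc[:, DIFFERENTIAL_COLUMNS + extra]
    with open(path, "w") as fh:
        params = " ".join(f"{k}={v}" for k, v in (parameters or {}).items())
        fh.write(f"# crossomics v{__version__}{(' ' + params) if params else ''}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_differential_table(path) -> pd.DataFrame:
    """Read a differential table, validating the required schema.

    Rows with ``padj < p`` are kept but reported with a warning: they are
    numerically suspicious (BH never decreases a p-value) but may arise from
    rounding in third-party output.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in DIFFERENTIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df["feature"] = df["feature"].astype(str)
    bad = df["padj"].notna() & df["p"].notna() & (df["padj"] < df["p"])
    if bad.any():
        warnings.warn(f"{path}: {int(bad.sum())} rows with padj < p (kept)")
    return df


def interval_key(chrom, start, end) -> str:
    """Canonical string key for an interval-identified feature."""
    return f"{chrom}:{int(start)}-{int(end)}"


def parse_interval_key(key: str) -> tuple[str, int, int]:
    chrom, _, span = key.rpartition(":")
    lo, _, hi = span.partition("-")
    if not chrom or not lo or not hi:
        raise ValueError(f"not an interval key: {key!r}")
    return chrom, int(lo), int(hi)


def intervals_from_keys(keys: Iterable[str]) -> pd.DataFrame:
    """Interval DataFrame from 'chrom:start-end' feature keys (index = key)."""
    parsed = [parse_interval_key(k) for k in keys]
    df = pd.DataFrame(parsed, columns=["chrom", "start", "end"],
                      index=pd.Index(keys, name="feature"))
    _validate_intervals(df, "interval keys")
    return df
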