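"""Cross-exposure, cross-sex and cross-tissue concordance statistics.

Feature matching rules differ by feature kind and mirror how such features
are identified in practice:

* genes (``DEG``): exact id / gene-symbol equality;
* accessibility regions (``DAR``): identical genomic coordinates by default
  (the regions live on a common consensus-region coordinate space), with an
  optional >= k bp overlap mode;
* methylation regions (``DMR``): >= 1 bp genomic intersection, because the
  two compared calls were made independently and never share boundaries.

Shared-feature statistics reported per comparison: side-only and shared
counts, the fraction of shared pairs with the same effect direction, the
Pearson (optionally Spearman) correlation of effect sizes over shared
features (missing, never 0, when fewer than 3), and an upper-tail
hypergeometric p-value for the amount of sharing, together with the
universe size it was computed against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .genomic_io import intersect_regions, intervals_from_keys
from .stats import UndefinedCorrelationError, hypergeom_tail, pearson_r

__all__ = [
    "FeatureKind",
    "FeatureSetCollection",
    "exposure_sharing_profile",
    "sex_concordance",
    "cross_tissue_match",
    "direction_concordance",
    "cross_tissue_sharing_test",
    "region_set_annotation",
]

FeatureKind = Literal["DEG", "DAR", "DMR"]
INTERVAL_KINDS = ("DAR", "DMR")

#: effect-size column per feature kind (log2 fold change for counts,
#: methylation difference for DMRs)
EFFECT_COLUMN = {"DEG": "log2fc", "DAR": "log2fc", "DMR": "delta"}


def _effect(table: pd.DataFrame, kind: str) -> pd.Series:
    col = EFFECT_COLUMN[kind]
    if col not in table.columns:
        raise KeyError(f"{kind} table lacks effect column {col!r}")
    return table[col]


def _significant(table: pd.DataFrame) -> pd.DataFrame:
    return table.loc[table["significant"].astype(bool)]


def _tested_keys(table: pd.DataFrame) -> set[str]:
    tested = table["p"].notna() if "p" in table.columns else pd.Series(True, index=table.index)
    return set(table.loc[tested, "feature"].astype(str))


@dataclass
class FeatureSetCollection:
    """Differential tables keyed by (exposure, sex, tissue, kind).

    Tables are the *full* tested tables with ``significant`` flags; most
    statistics restrict to the significant subset themselves and use the
    tested remainder as the enrichment universe.
    """

    tables: dict[tuple[str, str, str, str], pd.DataFrame] = field(default_factory=dict)

    def add(self, exposure: str, sex: str, tissue: str, kind: str,
            table: pd.DataFrame) -> None:
        key = (exposure, sex, tissue, kind)
        if key in self.tables:
            raise ValueError(f"duplicate table for {key}")
        self.tables[key] = table

    def get(self, exposure: str, sex: str, tissue: str, kind: str) -> pd.DataFrame:
        return self.tables[(exposure, sex, tissue, kind)]

    def exposures(self) -> list[str]:
        return sorted({k[0] for k in self.tables})

    def subset(self, *, sex: str | None = None, tissue: str | None = None,
               kind: str | None = None) -> dict[str, pd.DataFrame]:
        """Map exposure -> table for one (sex, tissue, kind) slice."""
        out = {}
        for (e, s, t, k), table in self.tables.items():
            if (sex is None or s == sex) and (tissue is None or t == tissue) \
                    and (kind is None or k == kind):
                out[e] = table
        return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# cross-exposure sharing
# ---------------------------------------------------------------------------

def exposure_sharing_profile(
    collection: FeatureSetCollection, sex: str, tissue: str, kind: str
) -> dict:
    """How many exposures each significant feature recurs in.

    Gene/accessibility features are matched across exposures by key;
    methylation regions by >= 1 bp intersection (features overlapping across
    exposures are clustered into connected components and the component is
    the recurring feature).  Returns per-feature counts (any direction and
    same direction as the feature's own call) and the binned summary used
    for sharing profiles: fractions of distinct features seen in exactly 1,
    2, 3 and > 3 exposures, plus the fraction shared by >= 2.
    """
    tables = collection.subset(sex=sex, tissue=tissue, kind=kind)
    if len(tables) < 2:
        raise ValueError(f"need >= 2 exposures, found {len(tables)}")
    parts = []
    for exposure, table in tables.items():
        sig = _significant(table)
        parts.append(pd.DataFrame({
            "exposure": exposure,
            "feature": sig["feature"].astype(str).to_numpy(),
            "effect": _effect(sig, kind).to_numpy(float),
        }))
    rec = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["exposure", "feature", "effect"])
    if not len(rec):
        summary = {"n_features": 0, "fraction_shared_ge2": np.nan,
                   "fraction_by_count": {}}
        return {"per_feature": rec.assign(group=pd.Series(dtype=object),
                                          n_exposures_any=pd.Series(dtype=int),
                                          n_exposures_same_direction=pd.Series(dtype=int)),
                "summary": summary}
    if kind in INTERVAL_KINDS and kind == "DMR":
        rec["group"] = _cluster_intervals(rec["feature"])
    else:
        rec["group"] = rec["feature"]
    rec["direction"] = np.where(rec["effect"] > 0, "up",
                                np.where(rec["effect"] < 0, "down", "none"))
    any_counts = rec.groupby("group")["exposure"].nunique()
    same_counts = rec.groupby(["group", "direction"])["exposure"].nunique()
    rec["n_exposures_any"] = rec["group"].map(any_counts)
    rec["n_exposures_same_direction"] = [
        int(same_counts.loc[(g, d)]) for g, d in zip(rec["group"], rec["direction"])
    ]
    per_group = any_counts
    n = len(per_group)
    bins = {
        "1": float((per_group == 1).mean()),
        "2": float((per_group == 2).mean()),
        "3": float((per_group == 3).mean()),
        ">3": float((per_group > 3).mean()),
    }
    summary = {
        "n_features": int(n),
        "fraction_shared_ge2": float((per_group >= 2).mean()),
        "fraction_by_count": bins,
    }
    return {"per_feature": rec, "summary": summary}


def _cluster_intervals(keys: pd.Series) -> pd.Series:
    """Connected components (>= 1 bp overlap) over interval-keyed features."""
    uniq = pd.Index(keys.unique())
    iv = intervals_from_keys(uniq).reset_index()
    pairs = intersect_regions(iv, iv, min_overlap=1)
    parent = {i: i for i in range(len(iv))}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for ai, bi in zip(pairs["a_index"], pairs["b_index"]):
        ra, rb = find(int(ai)), find(int(bi))
        if ra != rb:
            parent[rb] = ra
    roots = {i: find(i) for i in range(len(iv))}
    label = {iv.loc[i, "feature"]: f"cluster_{roots[i]}" for i in range(len(iv))}
    return keys.map(label)


# ---------------------------------------------------------------------------
# pairwise comparisons
# ---------------------------------------------------------------------------

def cross_tissue_match(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    kind: str,
    dar_mode: str = "exact",
    dar_min_overlap: int = 1,
) -> pd.DataFrame:
    """Match significant features of two tables under the kind's rule.

    Returns one row per matched pair with the features and signed effects
    from each side.  A methylation region intersecting several partners
    yields one row per partner; count-level statistics over such
    many-to-many matches should count distinct features per side (both are
    reported by :func:`compare_tables`).
    """
    if kind not in EFFECT_COLUMN:
        raise ValueError(f"unknown feature kind {kind!r}")
    sig_a = _significant(table_a)
    sig_b = _significant(table_b)
    eff_a = _effect(sig_a, kind)
    eff_b = _effect(sig_b, kind)
    if kind == "DEG" or (kind == "DAR" and dar_mode == "exact"):
        keys_a = sig_a["feature"].astype(str)
        keys_b = sig_b["feature"].astype(str)
        if kind == "DAR":
            # exact-coordinate identity is exactly string-key identity
            intervals_from_keys(keys_a.unique())
            intervals_from_keys(keys_b.unique())
        a = pd.DataFrame({"feature_a": keys_a, "effect_a": eff_a.to_numpy()})
        b = pd.DataFrame({"feature_b": keys_b, "effect_b": eff_b.to_numpy()})
        pairs = a.merge(b, left_on="feature_a", right_on="feature_b", how="inner")
    elif kind == "DMR" or (kind == "DAR" and dar_mode == "overlap"):
        min_ov = 1 if kind == "DMR" else dar_min_overlap
        iv_a = intervals_from_keys(sig_a["feature"].astype(str)).reset_index()
        iv_b = intervals_from_keys(sig_b["feature"].astype(str)).reset_index()
        hits = intersect_regions(iv_a, iv_b, min_overlap=min_ov)
        ia = hits["a_index"].to_numpy(dtype=int)
        ib = hits["b_index"].to_numpy(dtype=int)
        pairs = pd.DataFrame(
            {
                "feature_a": iv_a["feature"].to_numpy()[ia],
                "feature_b": iv_b["feature"].to_numpy()[ib],
                "effect_a": eff_a.to_numpy()[ia],
                "effect_b": eff_b.to_numpy()[ib],
            }
        )
    else:
        raise ValueError(f"unknown dar_mode {dar_mode!r}")
    return pairs.reset_index(drop=True)


def direction_concordance(pairs: pd.DataFrame) -> tuple[float, int]:
    """Fraction of matched pairs whose effect signs agree.

    Pairs with a zero effect on either side are excluded from the fraction
    and returned as the second element.  An empty pair set yields NaN (a
    missing value, never 0).
    """
    if not len(pairs):
        return float("nan"), 0
    sa = np.sign(pairs["effect_a"].to_numpy(float))
    sb = np.sign(pairs["effect_b"].to_numpy(float))
    nonzero = (sa != 0) & (sb != 0)
    n_zero = int((~nonzero).sum())
    if not nonzero.any():
        return float("nan"), n_zero
    return float((sa[nonzero] == sb[nonzero]).mean()), n_zero


def cross_tissue_sharing_test(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    universe: str | int | Iterable[str] = "intersection",
) -> dict:
    """Hypergeometric upper-tail test of key-matched sharing.

    ``universe`` selects N: ``"intersection"`` (default) uses features
    tested in both tables, ``"union"`` features tested in either, an int
    supplies N directly, and any other iterable is an explicit universe key
    set.  Both significant sets are intersected with the universe before
    counting; significant features falling outside an explicit universe are
    an error, because sharing outside the universe is undefined.
    """
    tested_a = _tested_keys(table_a)
    tested_b = _tested_keys(table_b)
    sig_a = set(_significant(table_a)["feature"].astype(str))
    sig_b = set(_significant(table_b)["feature"].astype(str))
    shared = sig_a & sig_b
    if isinstance(universe, str):
        if universe == "intersection":
            uni = tested_a & tested_b
        elif universe == "union":
            uni = tested_a | tested_b
        else:
            raise ValueError(f"unknown universe policy {universe!r}")
        sig_a &= uni
        sig_b &= uni
        shared = sig_a & sig_b
        N = len(uni)
    elif isinstance(universe, int):
        N = universe
        if N < len(sig_a | sig_b):
            raise ValueError("explicit N smaller than the union of significant sets")
    else:
        uni = set(map(str, universe))
        outside = (sig_a | sig_b) - uni
        if outside:
            raise ValueError(
                f"{len(outside)} significant features outside the supplied universe"
            )
        N = len(uni)
    K, n, s = len(sig_a), len(sig_b), len(shared)
    p = hypergeom_tail(N, K, n, s) if N > 0 else float("nan")
    return {"p": p, "N": N, "K": K, "n": n, "s": s}


def compare_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    kind: str,
    correlation: str = "pearson",
    universe: str | int | Iterable[str] = "intersection",
    dar_mode: str = "exact",
) -> dict:
    """Full two-set comparison: counts, direction concordance, correlation
    of shared effect sizes, and (for key-matched kinds) the hypergeometric
    sharing p-value with its universe size.

    This single routine backs both the female-vs-male and the blood-vs-liver
    comparisons; only the inputs differ.
    """
    pairs = cross_tissue_match(table_a, table_b, kind, dar_mode=dar_mode)
    n_sig_a = int(_significant(table_a).shape[0])
    n_sig_b = int(_significant(table_b).shape[0])
    shared_a = pairs["feature_a"].nunique()
    shared_b = pairs["feature_b"].nunique()
    frac, n_zero = direction_concordance(pairs)
    r = float("nan")
    if len(pairs) >= 3:
        try:
            if correlation == "pearson":
                r = pearson_r(pairs["effect_a"], pairs["effect_b"])
            elif correlation == "spearman":
                r = float(spearmanr(pairs["effect_a"], pairs["effect_b"]).statistic)
            else:
                raise ValueError(f"unknown correlation {correlation!r}")
        except UndefinedCorrelationError:
            r = float("nan")
    report = {
        "kind": kind,
        "n_significant_a": n_sig_a,
        "n_significant_b": n_sig_b,
        "n_pairs": int(len(pairs)),
        "n_shared_a": int(shared_a),
        "n_shared_b": int(shared_b),
        "a_only": n_sig_a - int(shared_a),
        "b_only": n_sig_b - int(shared_b),
        "direction_concordance": frac,
        "n_zero_effect_pairs": n_zero,
        "correlation": r,
        "hypergeom_p": float("nan"),
        "universe_N": np.nan,
    }
    if kind == "DEG" or (kind == "DAR" and dar_mode == "exact"):
        hg = cross_tissue_sharing_test(table_a, table_b, universe=universe)
        report["hypergeom_p"] = hg["p"]
        report["universe_N"] = hg["N"]
    return report


def sex_concordance(
    collection: FeatureSetCollection, exposure: str, tissue: str, kind: str, **kw
) -> dict:
    """Female-vs-male comparison for one (exposure, tissue, kind)."""
    a = collection.get(exposure, "female", tissue, kind)
    b = collection.get(exposure, "male", tissue, kind)
    report = compare_tables(a, b, kind, **kw)
    report.update({"exposure": exposure, "tissue": tissue,
                   "side_a": "female", "side_b": "male"})
    return report


def region_set_annotation(features: pd.DataFrame, regions: pd.DataFrame) -> tuple[pd.Series, int]:
    """Flag interval-keyed features overlapping (>= 1 bp) a region set.

    Returns (per-feature boolean flags indexed by feature key, total count);
    a feature overlapping several regions counts once.
    """
    keys = features["feature"].astype(str)
    flags = pd.Series(False, index=pd.Index(keys, name="feature"))
    if len(regions) and len(keys):
        iv = intervals_from_keys(keys.unique()).reset_index()
        hits = intersect_regions(iv, regions, min_overlap=1)
        hit_keys = set(iv.loc[hits["a_index"].unique(), "feature"])
        flags.loc[flags.index.isin(hit_keys)] = True
    return flags, int(flags.sum())
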