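"""End-to-end orchestration: simulate -> call -> concordance -> score.

A single structured config (dict or YAML file) drives the whole run.  Every
stage writes plain-text artefacts (TSV/BED/JSON) under the output directory
and the run manifest records the seed, tool version, per-stage parameters
and output paths, so two runs with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import (
    FeatureSetCollection,
    compare_tables,
    exposure_sharing_profile,
)
from .diff import DEG_PARAMS, DiffParams, nb_wald_test
from .dmr import DmrParams, call_dmrs, dmr_bed_frame
from .genomic_io import (
    intersect_regions,
    interval_key,
    intervals_from_keys,
    write_bed,
    write_count_matrix,
    write_cytosine_report,
    write_differential_table,
    write_sample_sheet,
)
from .simulate import (
    CrossTissueConfig,
    WgbsConfig,
    simulate_cross_tissue_scenario,
    simulate_wgbs,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "score_dmrs",
    "score_features",
]

REPORT_SCHEMA_VERSION = 1


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs; nested generator/caller parameter blocks."""

    seed: int = 0
    out_dir: str = "crossomics_run"
    cross: CrossTissueConfig = dataclasses.field(default_factory=CrossTissueConfig)
    wgbs: WgbsConfig = dataclasses.field(default_factory=WgbsConfig)
    dmr: DmrParams = dataclasses.field(default_factory=DmrParams)
    deg: DiffParams = dataclasses.field(default_factory=DEG_PARAMS)
    include_wgbs: bool = True
    write_intermediates: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        for key, sub in (("cross", CrossTissueConfig), ("wgbs", WgbsConfig),
                         ("dmr", DmrParams), ("deg", DiffParams)):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = sub(**kw[key])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def score_features(truth: pd.DataFrame, table: pd.DataFrame) -> dict:
    """Sensitivity and FDR of a keyed differential call against truth.

    Sensitivity = planted features called significant / planted; FDR =
    significant features not planted / significant (NaN when nothing is
    called).
    """
    planted = set(truth["feature"].astype(str))
    called = set(table.loc[table["significant"].astype(bool), "feature"].astype(str))
    sens = len(planted & called) / len(planted) if planted else float("nan")
    fdr = len(called - planted) / len(called) if called else float("nan")
    return {"sensitivity": sens, "fdr": fdr,
            "n_planted": len(planted), "n_called": len(called)}


def score_dmrs(truth: pd.DataFrame, dmrs: pd.DataFrame) -> dict:
    """Interval-level scoring of DMR calls against planted regions.

    Sensitivity = fraction of planted regions intersected (>= 1 bp) by a
    called region of matching direction; FDR = fraction of called regions
    intersecting no planted region (any direction).
    """
    n_planted = len(truth)
    n_called = len(dmrs)
    if n_planted == 0:
        sens = float("nan")
    elif n_called == 0:
        sens = 0.0
    else:
        hits = intersect_regions(truth, dmrs, min_overlap=1)
        if len(hits):
            same = [
                truth.loc[a, "direction"] == dmrs.loc[b, "direction"]
                for a, b in zip(hits["a_index"], hits["b_index"])
            ]
            recovered = hits.loc[same, "a_index"].nunique()
        else:
            recovered = 0
        sens = recovered / n_planted
    if n_called == 0:
        fdr = float("nan")
    elif n_planted == 0:
        fdr = 1.0
    else:
        hits = intersect_regions(dmrs, truth, min_overlap=1)
        fdr = 1.0 - hits["a_index"].nunique() / n_called
    return {"sensitivity": sens, "fdr": fdr,
            "n_planted": int(n_planted), "n_called": int(n_called)}


def run_pipeline(config: PipelineConfig | dict | str | Path,
                 out_dir: str | Path | None = None) -> dict:
    """Run simulate -> call -> concordance -> score and write the report.

    Returns the manifest dict; the machine-readable report lands at
    ``<out_dir>/report.json`` (sorted keys, fixed float formatting) and the
    concordance table at ``<out_dir>/concordance.tsv``.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "crossomics",
        "version": __version__,
        "seed": config.seed,
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": _params_dump(config),
        "stages": {},
        "outputs": {},
    }
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed}
    stage = "simulate"
    try:
        ss = np.random.SeedSequence(config.seed)
        s_cross, s_wgbs = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
        cross_cfg = dataclasses.replace(config.cross, seed=s_cross)
        bundle, truth = simulate_cross_tissue_scenario(cross_cfg)
        wgbs_data = None
        if config.include_wgbs:
            wgbs_cfg = dataclasses.replace(config.wgbs, seed=s_wgbs)
            wgbs_data = simulate_wgbs(wgbs_cfg)
        manifest["stages"][stage] = "ok"

        stage = "call"
        collection = FeatureSetCollection()
        scores = {}
        for (tissue, sex, exposure), cm in sorted(bundle.items()):
            table = nb_wald_test(cm, params=config.deg)
            collection.add(exposure, sex, tissue, "DEG", table)
            sub_truth = truth.loc[
                (truth["tissue"] == tissue) & (truth["sex"] == sex)
                & (truth["exposure"] == exposure)
            ]
            scores[f"DEG/{tissue}/{sex}/{exposure}"] = score_features(sub_truth, table)
            if config.write_intermediates:
                prefix = out / f"deg_{tissue}_{sex}_{exposure}"
                write_differential_table(table, f"{prefix}.tsv",
                                         {"seed": config.seed})
        dmr_result = None
        if wgbs_data is not None:
            samples, dmr_truth = wgbs_data
            groups = {s: ("control" if s.startswith("control") else "exposed")
                      for s in samples}
            windows, dmrs = call_dmrs(samples, groups,
                                      config.wgbs.chrom_sizes, config.dmr)
            dmr_result = (windows, dmrs, dmr_truth)
            scores["DMR"] = score_dmrs(dmr_truth, dmrs)
            if config.write_intermediates:
                write_bed(dmr_bed_frame(dmrs), out / "dmrs.bed",
                          {"seed": config.seed})
                windows.to_csv(out / "dmr_windows.tsv", sep="\t", index=False)
        manifest["stages"][stage] = "ok"

        stage = "concordance"
        rows = []
        t0, t1 = config.cross.tissues
        for sex in config.cross.sexes:
            for exposure in config.cross.exposures:
                rep = compare_tables(
                    collection.get(exposure, sex, t0, "DEG"),
                    collection.get(exposure, sex, t1, "DEG"),
                    "DEG",
                )
                rep.update({"comparison": "cross_tissue", "exposure": exposure,
                            "sex": sex, "side_a": t0, "side_b": t1})
                rows.append(rep)
        for tissue in config.cross.tissues:
            for exposure in config.cross.exposures:
                rep = compare_tables(
                    collection.get(exposure, "female", tissue, "DEG"),
                    collection.get(exposure, "male", tissue, "DEG"),
                    "DEG",
                )
                rep.update({"comparison": "cross_sex", "exposure": exposure,
                            "tissue": tissue, "side_a": "female", "side_b": "male"})
                rows.append(rep)
        sharing = {}
        for tissue in config.cross.tissues:
            for sex in config.cross.sexes:
                prof = exposure_sharing_profile(collection, sex, tissue, "DEG")
                sharing[f"{tissue}/{sex}"] = prof["summary"]
        conc = pd.DataFrame(rows)
        conc_cols = ["comparison", "exposure", "sex", "tissue", "side_a", "side_b"]
        conc = conc.loc[:, [c for c in conc_cols if c in conc.columns]
                        + [c for c in conc.columns if c not in conc_cols]]
        conc = conc.sort_values([c for c in ("comparison", "exposure", "sex", "tissue")
                                 if c in conc.columns], kind="mergesort")
        conc.to_csv(out / "concordance.tsv", sep="\t", index=False, na_rep="NA")
        manifest["stages"][stage] = "ok"

        stage = "score_structure"
        # realized planted cross-structure (truth-joined): these are the
        # pipeline's estimates of the generator's sharing/direction rates,
        # free of caller-sensitivity bias
        t0_rows = truth.loc[truth["tissue"] == t0]
        t1_rows = truth.loc[truth["tissue"] == t1]
        per_combo = {}
        agree_tot = share_tot = planted_tot = shared_n_tot = 0
        for sex in config.cross.sexes:
            for exposure in config.cross.exposures:
                a = t0_rows.loc[(t0_rows["sex"] == sex) & (t0_rows["exposure"] == exposure)]
                b = t1_rows.loc[(t1_rows["sex"] == sex) & (t1_rows["exposure"] == exposure)]
                shared = a.loc[a["cross_tissue_shared"]].merge(
                    b, on="feature", suffixes=("_a", "_b"))
                n_shared = len(shared)
                agree = int((np.sign(shared["log2fc_a"]) == np.sign(shared["log2fc_b"])).sum())
                per_combo[f"{sex}/{exposure}"] = {
                    "planted": int(len(a)),
                    "shared": n_shared,
                    "sharing_fraction": n_shared / len(a) if len(a) else float("nan"),
                    "same_direction_fraction": agree / n_shared if n_shared else float("nan"),
                }
                planted_tot += len(a)
                share_tot += n_shared
                agree_tot += agree
                shared_n_tot += n_shared
        report["planted_structure"] = {
            "per_combo": per_combo,
            "tissue_sharing_fraction": share_tot / planted_tot if planted_tot else float("nan"),
            "same_direction_fraction": agree_tot / shared_n_tot if shared_n_tot else float("nan"),
        }
        manifest["stages"][stage] = "ok"

        stage = "report"
        report["feature_counts"] = {
            f"{t}/{s}/{e}": int(collection.get(e, s, t, "DEG")["significant"].sum())
            for t in config.cross.tissues for s in config.cross.sexes
            for e in config.cross.exposures
        }
        report["exposure_sharing"] = sharing
        report["concordance"] = conc.to_dict(orient="records")
        report["scores"] = scores
        _write_json(report, out / "report.json")
        manifest["outputs"]["report"] = str(out / "report.json")
        manifest["outputs"]["concordance"] = str(out / "concordance.tsv")
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        _write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_json(manifest, out / "manifest.json")
    return manifest


def _params_dump(config: PipelineConfig) -> dict:
    def enc(v):
        if dataclasses.is_dataclass(v):
            return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, tuple):
            return list(v)
        return v

    return {f.name: enc(getattr(config, f.name))
            for f in dataclasses.fields(config)}


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default,
                  allow_nan=True)
        fh.write("\n")


def export_simulation(bundle, truth, out_dir: str | Path) -> None:
    """Write a simulated cross-tissue bundle as a directory of TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheets = []
    for (tissue, sex, exposure), cm in sorted(bundle.items()):
        prefix = f"{tissue}_{sex}_{exposure}"
        write_count_matrix(cm, out / f"counts_{prefix}.tsv",
                           out / f"samples_{prefix}.tsv")
        sheets.append(prefix)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    (out / "MANIFEST.txt").write_text("\n".join(sheets) + "\n")
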