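"""Seeded generators emulating the study's data structure.

Three layers, each returning its planted ground truth so callers can be
scored for sensitivity and false discovery rate:

* a WGBS layer: CpG positions along small chromosomes, per-sample read
  coverage, and beta-binomial methylation counts around group-level
  methylation levels, with differentially methylated regions planted at a
  configurable width, |Δβ| and hyper:hypo mix;
* a count layer: negative-binomial feature x sample matrices (expression-
  or accessibility-like) with a planted fraction of fold-changed features;
* a cross-structure layer: a full two-tissue x two-sex x multi-exposure
  bundle in which the fractions of differential features shared across
  tissues, with the same direction, shared across sexes, and recurring
  across exposures all hold in expectation.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so every artefact is reproducible
and sub-streams are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CountMatrix, interval_key

__all__ = [
    "WgbsConfig",
    "CountsConfig",
    "CrossTissueConfig",
    "simulate_genome_cpgs",
    "simulate_wgbs",
    "simulate_counts",
    "simulate_cross_tissue_scenario",
]


# ---------------------------------------------------------------------------
# WGBS
# ---------------------------------------------------------------------------

@dataclass
class WgbsConfig:
    """Parameters of the WGBS generator.

    Defaults mirror the study's design where it states one (n = 6
    replicates per group) and desk-scale choices elsewhere: ~2 Mb of
    genome at one CpG per 100 bp (~20k CpGs), mean 10 reads per CpG per
    sample, a bimodal baseline methylation landscape (25% low-methylated
    CpGs around β ≈ 0.15, 75% high around β ≈ 0.85) and mild beta-binomial
    replicate overdispersion ρ = 0.01.
    """

    seed: int = 0
    n_replicates: int = 6
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    cpg_rate: float = 1 / 100  # CpGs per bp, islands + background combined
    cluster_fraction: float = 0.7  # fraction of CpGs living in island blocks
    island_length: int = 800
    island_spacing: float = 25.0
    coverage_mean: float = 10.0
    meth_rho: float = 0.01
    low_meth_fraction: float = 0.25
    beta_low: tuple = (1.5, 8.5)   # Beta params, mean ~0.15
    beta_high: tuple = (8.5, 1.5)  # mean ~0.85
    n_dmrs: int = 20
    dmr_width: int = 600
    dmr_delta: float = 0.3
    hyper_fraction: float = 0.5
    dmr_cpg_spacing: float = 30.0  # guaranteed island spacing inside planted DMRs

    def __post_init__(self) -> None:
        if self.cpg_rate <= 0:
            raise ValueError("cpg_rate must be > 0")
        if self.n_dmrs and self.dmr_width / self.dmr_cpg_spacing < 2:
            raise ValueError(
                "planted DMRs would contain < 2 CpGs; widen them or raise density"
            )
        if not (0 <= self.hyper_fraction <= 1):
            raise ValueError("hyper_fraction must lie in [0, 1]")


def _place_dmrs(cfg: WgbsConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping planted regions, alternating window-aligned and
    window-straddling starts so that merging across window boundaries is
    exercised by construction."""
    slots = []
    margin = 5_000
    spacing = max(4 * cfg.dmr_width, 4_000)
    for chrom, length in cfg.chrom_sizes.items():
        start = margin
        while start + cfg.dmr_width < length - margin:
            slots.append((chrom, start))
            start += spacing
    if len(slots) < cfg.n_dmrs:
        raise ValueError(f"genome holds only {len(slots)} DMR slots, need {cfg.n_dmrs}")
    pick = rng.choice(len(slots), size=cfg.n_dmrs, replace=False)
    pick.sort()
    rows = []
    for i, idx in enumerate(pick):
        chrom, start = slots[idx]
        start = (start // 200) * 200 + (0 if i % 2 == 0 else 100)  # align / straddle
        direction = "hyper" if rng.random() < cfg.hyper_fraction else "hypo"
        delta = cfg.dmr_delta if direction == "hyper" else -cfg.dmr_delta
        rows.append((chrom, start, start + cfg.dmr_width, direction, delta))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "delta"])


def simulate_genome_cpgs(
    cfg: WgbsConfig,
    rng: np.random.Generator,
    dmrs: pd.DataFrame | None = None,
) -> dict[str, np.ndarray]:
    """Strictly increasing CpG positions per chromosome.

    CpGs are placed as a mixture emulating the clustered CpG landscape of a
    mammalian genome: a ``cluster_fraction`` of sites lives in island
    blocks of ~``island_length`` bp with ~``island_spacing`` bp internal
    spacing (islands sit on a jittered grid so the overall density stays at
    ``cpg_rate``), the rest follows a sparse Poisson background.  Setting
    ``cluster_fraction = 0`` recovers a uniform landscape.  Inside planted
    regions an island block with ~``dmr_cpg_spacing`` bp spacing is always
    superimposed so every planted region holds enough CpGs to be callable.
    """
    out = {}
    for chrom, length in cfg.chrom_sizes.items():
        n_total = length * cfg.cpg_rate
        n_bg = rng.poisson(n_total * (1.0 - cfg.cluster_fraction))
        pos = rng.integers(0, length, size=n_bg)
        if cfg.cluster_fraction > 0:
            per_island = max(2, int(cfg.island_length / cfg.island_spacing))
            n_islands = max(1, int(round(n_total * cfg.cluster_fraction / per_island)))
            slot = length / n_islands
            jitter_room = max(1, int(slot) - cfg.island_length)
            starts = (np.arange(n_islands) * slot).astype(np.int64) + rng.integers(
                0, jitter_room, size=n_islands
            )
            offsets = np.arange(per_island) * cfg.island_spacing
            island_pos = (starts[:, None] + offsets[None, :]).ravel()
            island_pos = island_pos + rng.integers(-4, 5, size=island_pos.size)
            pos = np.concatenate([pos, np.clip(island_pos, 0, length - 1).astype(np.int64)])
        if dmrs is not None:
            for _, d in dmrs.loc[dmrs["chrom"] == chrom].iterrows():
                island = np.arange(d["start"] + 5, d["end"], cfg.dmr_cpg_spacing,
                                   dtype=np.int64)
                jitter = rng.integers(-5, 6, size=island.size)
                pos = np.concatenate([pos, np.clip(island + jitter, 0, length - 1)])
        out[chrom] = np.unique(pos)
    return out


def simulate_wgbs(cfg: WgbsConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate per-sample cytosine tables and the planted-DMR truth.

    Returns (samples, truth): ``samples`` maps sample ids
    (control_1..n, exposed_1..n) to internal-coordinate cytosine tables;
    ``truth`` is the planted-region table (chrom, start, end, direction, Δβ,
    empty when ``n_dmrs == 0``).
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_place, r_pos, r_beta, r_reads = [np.random.default_rng(s) for s in ss.spawn(4)]
    dmrs = _place_dmrs(cfg, r_place) if cfg.n_dmrs else pd.DataFrame(
        columns=["chrom", "start", "end", "direction", "delta"])
    cpgs = simulate_genome_cpgs(cfg, r_pos, dmrs if cfg.n_dmrs else None)

    frames_per_sample: dict[str, list[pd.DataFrame]] = {}
    sample_names = [f"control_{i+1}" for i in range(cfg.n_replicates)] + [
        f"exposed_{i+1}" for i in range(cfg.n_replicates)
    ]
    for chrom, pos in cpgs.items():
        m = pos.size
        low = r_beta.random(m) < cfg.low_meth_fraction
        base = np.where(
            low,
            r_beta.beta(*cfg.beta_low, size=m),
            r_beta.beta(*cfg.beta_high, size=m),
        )
        delta = np.zeros(m)
        for _, d in dmrs.loc[dmrs["chrom"] == chrom].iterrows():
            inside = (pos >= d["start"]) & (pos < d["end"])
            # draw the baseline of planted CpGs from a range that leaves
            # room for the full shift, so the planted |Δβ| is honest
            if d["direction"] == "hyper":
                base[inside] = 0.15 + 0.45 * r_beta.random(int(inside.sum()))
            else:
                base[inside] = 0.40 + 0.45 * r_beta.random(int(inside.sum()))
            delta[inside] = d["delta"]
        beta_control = np.clip(base, 0.02, 0.98)
        beta_exposed = np.clip(base + delta, 0.02, 0.98)
        for sample in sample_names:
            beta = beta_control if sample.startswith("control") else beta_exposed
            cov = r_reads.poisson(cfg.coverage_mean, size=m)
            if cfg.meth_rho > 0:
                conc = 1.0 / cfg.meth_rho - 1.0
                p = r_reads.beta(beta * conc, (1.0 - beta) * conc)
            else:
                p = beta
            meth = r_reads.binomial(cov, p)
            frames_per_sample.setdefault(sample, []).append(
                pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+",
                              "meth": meth, "unmeth": cov - meth})
            )
    samples = {
        name: pd.concat(parts, ignore_index=True)
        for name, parts in frames_per_sample.items()
    }
    return samples, dmrs


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountsConfig:
    """Negative-binomial count-matrix generator parameters.

    Baseline means are log-normal (median ~55, heavy right tail), NB
    dispersion 0.05, n = 6 per group, 5% of features planted at |log2FC| = 1
    with an even up:down mix, and no extra per-sample depth variation unless
    requested.
    """

    seed: int = 0
    n_features: int = 10_000
    n_replicates: int = 6
    mean_log_mu: float = 4.0
    mean_log_sigma: float = 1.5
    dispersion: float = 0.05
    planted_fraction: float = 0.05
    log2fc: float = 1.0
    up_fraction: float = 0.5
    depth_log_sigma: float = 0.0
    feature_prefix: str = "gene"
    interval_features: bool = False
    interval_chrom: str = "chr1"
    interval_width: int = 500

    def __post_init__(self) -> None:
        if not (0 <= self.planted_fraction <= 1):
            raise ValueError("planted_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _feature_ids(cfg: CountsConfig) -> list[str]:
    if cfg.interval_features:
        return [
            interval_key(cfg.interval_chrom, i * cfg.interval_width * 2,
                         i * cfg.interval_width * 2 + cfg.interval_width)
            for i in range(cfg.n_features)
        ]
    return [f"{cfg.feature_prefix}{i:05d}" for i in range(cfg.n_features)]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    cfg: CountsConfig,
    planted: pd.DataFrame | None = None,
    sample_meta: dict | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a CountMatrix and its planted-feature truth table.

    ``planted`` (feature, log2fc) can be supplied to impose an externally
    drawn differential assignment (the cross-structure layer does this);
    otherwise a fraction ``planted_fraction`` of features is drawn here.
    Truth has columns feature, log2fc, direction.
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_base, r_plant, r_counts = [np.random.default_rng(s) for s in ss.spawn(3)]
    features = _feature_ids(cfg)
    mu0 = np.exp(r_base.normal(cfg.mean_log_mu, cfg.mean_log_sigma, size=cfg.n_features))
    lfc = np.zeros(cfg.n_features)
    if planted is not None:
        idx = {f: i for i, f in enumerate(features)}
        for f, v in zip(planted["feature"], planted["log2fc"]):
            lfc[idx[str(f)]] = v
    elif cfg.planted_fraction > 0:
        n_planted = int(round(cfg.planted_fraction * cfg.n_features))
        chosen = r_plant.choice(cfg.n_features, size=n_planted, replace=False)
        signs = np.where(r_plant.random(n_planted) < cfg.up_fraction, 1.0, -1.0)
        lfc[chosen] = signs * cfg.log2fc
    mu1 = mu0 * 2.0**lfc
    names = [f"control_{i+1}" for i in range(cfg.n_replicates)] + [
        f"exposed_{i+1}" for i in range(cfg.n_replicates)
    ]
    depth = (
        np.exp(r_counts.normal(0.0, cfg.depth_log_sigma, size=len(names)))
        if cfg.depth_log_sigma > 0
        else np.ones(len(names))
    )
    cols = {}
    for j, name in enumerate(names):
        mu = (mu0 if name.startswith("control") else mu1) * depth[j]
        cols[name] = _nb_draw(r_counts, mu, cfg.dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(features, name="feature"))
    meta = sample_meta or {}
    samples = pd.DataFrame(
        {
            "group": ["control"] * cfg.n_replicates + ["exposed"] * cfg.n_replicates,
            "sex": meta.get("sex", "female"),
            "tissue": meta.get("tissue", "liver"),
            "exposure": meta.get("exposure", "exposureA"),
        },
        index=pd.Index(names, name="sample"),
    )
    truth_mask = lfc != 0
    truth = pd.DataFrame(
        {
            "feature": np.asarray(features)[truth_mask],
            "log2fc": lfc[truth_mask],
            "direction": np.where(lfc[truth_mask] > 0, "up", "down"),
        }
    )
    return CountMatrix(counts=counts, samples=samples), truth


# ---------------------------------------------------------------------------
# cross-tissue scenario
# ---------------------------------------------------------------------------

@dataclass
class CrossTissueConfig:
    """Two tissues x two sexes x >= 2 exposures with planted cross-structure.

    Sharing semantics (all in expectation, recorded exactly in the truth):

    * ``tissue_sharing``: probability that a feature planted in the first
      tissue is also planted in the second (remaining second-tissue slots
      are filled from unshared features so both tissues plant
      ``n_planted`` features);
    * ``same_direction``: probability that a tissue-shared pair keeps the
      first tissue's sign;
    * ``sex_sharing``: probability that a female-planted feature is also
      planted in the male set (same refill rule);
    * ``exposure_sharing``: probability that a planted feature is drawn
      from a per-(sex,tissue) recurring pool rather than fresh.

    The planted effect is strong (|log2FC| = 2 on well-expressed features)
    so concordance estimates measured on *called* features track the planted
    rates rather than caller noise.
    """

    seed: int = 0
    exposures: tuple = ("toxA", "toxB")
    n_features: int = 8_000
    n_planted: int = 2_000
    tissue_sharing: float = 0.05
    same_direction: float | None = 0.62
    sex_sharing: float = 0.2
    exposure_sharing: float = 0.3
    up_fraction: float = 0.5
    log2fc: float = 2.0
    n_replicates: int = 6
    dispersion: float = 0.05
    mean_log_mu: float = 5.0
    mean_log_sigma: float = 1.0
    tissues: tuple = ("liver", "blood")
    sexes: tuple = ("female", "male")

    def __post_init__(self) -> None:
        for name in ("tissue_sharing", "sex_sharing", "exposure_sharing", "up_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.same_direction is not None:
            if not (0 <= self.same_direction <= 1):
                raise ValueError("same_direction must lie in [0, 1] or None")
            if self.tissue_sharing == 0 and self.same_direction != 0:
                raise ValueError(
                    "same_direction is meaningless with tissue_sharing = 0"
                )
        if len(self.exposures) < 2:
            raise ValueError("need >= 2 exposures")
        if self.n_planted > self.n_features // 2:
            raise ValueError("n_planted must leave room for unshared refills")


def _plant_assignments(cfg: CrossTissueConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the planted (tissue, sex, exposure, feature, log2fc) table."""
    all_feats = np.arange(cfg.n_features)
    rows = []
    t0, t1 = cfg.tissues
    s0, s1 = cfg.sexes
    for sex in cfg.sexes:
        pool = rng.choice(all_feats, size=cfg.n_planted, replace=False)  # recurring pool
        for exposure in cfg.exposures:
            take_pool = rng.random(cfg.n_planted) < cfg.exposure_sharing
            n_fresh = int((~take_pool).sum())
            from_pool = pool[take_pool]
            fresh_space = np.setdiff1d(all_feats, from_pool, assume_unique=False)
            fresh = rng.choice(fresh_space, size=n_fresh, replace=False)
            feats_t0 = np.concatenate([from_pool, fresh])
            signs_t0 = np.where(rng.random(cfg.n_planted) < cfg.up_fraction, 1.0, -1.0)
            # second tissue: shared subset keeps/flips sign, refill the rest
            shared_mask = rng.random(cfg.n_planted) < cfg.tissue_sharing
            shared = feats_t0[shared_mask]
            keep = rng.random(shared.size) < (
                cfg.same_direction if cfg.same_direction is not None else cfg.up_fraction
            )
            signs_shared = np.where(keep, signs_t0[shared_mask], -signs_t0[shared_mask])
            refill_space = np.setdiff1d(all_feats, feats_t0)
            refill = rng.choice(refill_space, size=cfg.n_planted - shared.size,
                                replace=False)
            signs_refill = np.where(rng.random(refill.size) < cfg.up_fraction, 1.0, -1.0)
            for tissue, feats, signs, shared_flags in (
                (t0, feats_t0, signs_t0, shared_mask),
                (t1, np.concatenate([shared, refill]),
                 np.concatenate([signs_shared, signs_refill]),
                 np.concatenate([np.ones(shared.size, bool),
                                 np.zeros(refill.size, bool)])),
            ):
                for f, sg, sh in zip(feats, signs, shared_flags):
                    rows.append((tissue, sex, exposure, int(f), sg * cfg.log2fc, bool(sh)))
    df = pd.DataFrame(rows, columns=["tissue", "sex", "exposure", "feature_idx",
                                     "log2fc", "cross_tissue_shared"])
    return df


def simulate_cross_tissue_scenario(
    cfg: CrossTissueConfig,
) -> tuple[dict[tuple[str, str, str], CountMatrix], pd.DataFrame]:
    """Generate count matrices for every (tissue, sex, exposure) plus truth.

    Returns (bundle, truth): bundle maps (tissue, sex, exposure) to a
    CountMatrix over one shared feature space; truth lists every planted
    feature with its signed log2FC and a cross-tissue sharing flag.  Both
    sexes and exposures of a tissue reuse the same baseline means so that
    feature identity is meaningful across the whole bundle.
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_plant = np.random.default_rng(ss.spawn(1)[0])
    plan = _plant_assignments(cfg, r_plant)
    features = [f"gene{i:05d}" for i in range(cfg.n_features)]
    plan["feature"] = [features[i] for i in plan["feature_idx"]]
    bundle = {}
    combos = [
        (t, s, e) for t in cfg.tissues for s in cfg.sexes for e in cfg.exposures
    ]
    child_seeds = ss.spawn(len(combos))
    for (tissue, sex, exposure), child in zip(combos, child_seeds):
        sub = plan.loc[
            (plan["tissue"] == tissue) & (plan["sex"] == sex)
            & (plan["exposure"] == exposure),
            ["feature", "log2fc"],
        ]
        ccfg = CountsConfig(
            seed=int(child.generate_state(1)[0] % (2**31)),
            n_features=cfg.n_features,
            n_replicates=cfg.n_replicates,
            mean_log_mu=cfg.mean_log_mu,
            mean_log_sigma=cfg.mean_log_sigma,
            dispersion=cfg.dispersion,
        )
        cm, _ = simulate_counts(
            ccfg, planted=sub,
            sample_meta={"sex": sex, "tissue": tissue, "exposure": exposure},
        )
        bundle[(tissue, sex, exposure)] = cm
    truth = plan.drop(columns="feature_idx").loc[
        :, ["tissue", "sex", "exposure", "feature", "log2fc", "cross_tissue_shared"]
    ].reset_index(drop=True)
    truth["direction"] = np.where(truth["log2fc"] > 0, "up", "down")
    return bundle, truth
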