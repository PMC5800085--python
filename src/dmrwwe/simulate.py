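"""Seeded beta-binomial simulator of two-group bisulfite count data.

The generator emulates the structure of the published artificial RRBS/WGBS
benchmarks: two groups of replicates, per-site coverage drawn from a
negative-binomial model, per-replicate methylation fractions drawn from a
Beta distribution around a latent site mean (the beta-binomial model), and
a set of planted, non-overlapping differentially methylated regions whose
group-B mean is shifted by a known effect size.  The planted truth is
returned as an :class:`~dmrwwe.benchmark.IntervalSet` for benchmarking.

Randomness is organised so that datasets differing only in effect size
share coordinates, coverages and monotonically coupled counts: every
per-site draw consumes a uniform from a seed-derived stream that does not
depend on the effect size, mapped through the appropriate inverse CDF.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .benchmark import IntervalSet
from .containers import SITE_COLUMNS, SiteTable
from .io import DIALECTS, write_sample


class ConfigError(ValueError):
    """An impossible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic two-group methylation dataset.

    Defaults mirror the published artificial benchmarks: 10 replicates per
    group, narrow negative-binomial coverage around 30x, a bimodal
    Beta(0.5, 0.5) background methylome, mild within-group beta-binomial
    dispersion (rho = 0.01), and geometric CpN spacing with mean gap
    100 nt.

    Attributes
    ----------
    n_sites : int
        Total number of simulated CpN.
    spacing : {"geometric", "fixed", "clustered"}
        Gap model between consecutive CpN. "clustered" emulates RRBS-like
        fragments: tight runs of sites separated by long gaps.
    mean_gap : int
        Mean (geometric) or fixed step between sites, nucleotides.
    r_a, r_b : int
        Replicates per group.
    coverage_mean, coverage_dispersion : float
        Negative-binomial coverage model: mean and size (shape) parameter.
        Large size = narrow artificial-data-like spread; size ~2 emulates
        the wide real-WGBS coverage distribution.
    background_alpha, background_beta : float
        Beta law of the latent background methylation level.
    n_dmrs, dmr_length : int
        Number and length (in CpN) of planted regions.
    effect_size : float
        Difference of group mean methylation inside planted regions
        (group B minus group A for "hyper" regions; direction is random
        per region).  The group-B mean is clipped to [0, 1] as a
        safeguard; planted baselines are drawn from U(0.1, 0.3) so the
        nominal effect is realised without clipping for effects <= 0.7.
    rho : float
        Within-group beta-binomial dispersion; the replicate fraction is
        Beta with mean mu and parameters a = mu(1-rho)/rho,
        b = (1-mu)(1-rho)/rho.  rho = 0 is a point mass at mu.
    """

    n_sites: int = 50_000
    spacing: str = "geometric"
    mean_gap: int = 100
    r_a: int = 10
    r_b: int = 10
    coverage_mean: float = 30.0
    coverage_dispersion: float = 20.0
    background_alpha: float = 0.5
    background_beta: float = 0.5
    n_dmrs: int = 20
    dmr_length: int = 10
    effect_size: float = 0.6
    rho: float = 0.01
    chrom: str = "chr1"
    origin: int = 1_000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.r_a < 1 or self.r_b < 1:
            raise ConfigError("n_sites and replicate counts must be >= 1")
        if not (-1.0 <= self.effect_size <= 1.0):
            raise ConfigError("effect_size must lie in [-1, 1]")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError("rho must lie in [0, 1)")
        if self.coverage_mean < 1:
            raise ConfigError("coverage_mean must be >= 1")
        if self.spacing not in ("geometric", "fixed", "clustered"):
            raise ConfigError(f"unknown spacing model {self.spacing!r}")
        if self.n_dmrs * (self.dmr_length + 1) > self.n_sites:
            raise ConfigError("planted DMRs do not fit without overlapping")

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_text(self) -> str:
        return "".join(f"{k}={v}\n" for k, v in asdict(self).items())


@dataclass(frozen=True)
class SyntheticDataset:
    """Simulated samples plus the planted truth and the config echo."""

    group_a: tuple[SiteTable, ...]
    group_b: tuple[SiteTable, ...]
    truth: IntervalSet
    truth_effects: tuple[float, ...]
    config: SimulationConfig


def _positions(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.spacing == "fixed":
        gaps = np.full(cfg.n_sites, cfg.mean_gap, dtype=np.int64)
    elif cfg.spacing == "geometric":
        gaps = rng.geometric(1.0 / cfg.mean_gap, size=cfg.n_sites)
    else:  # clustered: runs of ~20 sites 2 nt apart, long gaps between runs
        cluster = 20
        gaps = np.where(np.arange(cfg.n_sites) % cluster == 0,
                        rng.geometric(1.0 / (cfg.mean_gap * cluster),
                                      size=cfg.n_sites),
                        1 + rng.geometric(0.5, size=cfg.n_sites))
    return cfg.origin + np.cumsum(gaps)


def _plant_regions(cfg: SimulationConfig, rng: np.random.Generator):
    """Non-overlapping planted site-index runs: one per equal block."""
    if cfg.n_dmrs == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    block = cfg.n_sites // cfg.n_dmrs
    offsets = rng.integers(0, block - cfg.dmr_length + 1, size=cfg.n_dmrs)
    starts = np.arange(cfg.n_dmrs) * block + offsets
    return starts, starts + cfg.dmr_length - 1


def _beta_fractions(mu: np.ndarray, rho: float,
                    u: np.ndarray) -> np.ndarray:
    """Inverse-CDF beta draws around per-site means (shape broadcast to u)."""
    if rho == 0.0:
        return np.broadcast_to(mu[:, None], u.shape).copy()
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    frac = np.empty_like(u)
    interior = (mu > 0.0) & (mu < 1.0)
    frac[~interior] = np.broadcast_to(mu[:, None], u.shape)[~interior]
    if interior.any():
        frac[interior] = sps.beta.ppf(u[interior],
                                      np.broadcast_to(a[:, None], u.shape)[interior],
                                      np.broadcast_to(b[:, None], u.shape)[interior])
    return frac


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate one seeded two-group dataset with planted DMRs.

    Identical configs produce byte-identical datasets; configs differing
    only in ``effect_size`` share coordinates, coverages and coupled
    counts (larger effects give stochastically larger methylation shifts
    at the same sites).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (ss_coord, ss_cov, ss_plant, ss_bg,
     ss_beta_a, ss_beta_b, ss_binom_a, ss_binom_b) = ss.spawn(8)

    pos = _positions(cfg, np.random.default_rng(ss_coord))
    rng_plant = np.random.default_rng(ss_plant)
    starts, ends = _plant_regions(cfg, rng_plant)
    directions = rng_plant.choice([1.0, -1.0], size=cfg.n_dmrs)
    baselines = rng_plant.uniform(0.1, 0.3, size=cfg.n_dmrs)

    mu = np.random.default_rng(ss_bg).beta(
        cfg.background_alpha, cfg.background_beta, size=cfg.n_sites)
    mu_a = mu.copy()
    mu_b = mu.copy()
    effects = []
    for k in range(cfg.n_dmrs):
        sl = slice(starts[k], ends[k] + 1)
        if directions[k] > 0:
            mu_a[sl] = baselines[k]
            mu_b[sl] = np.clip(baselines[k] + cfg.effect_size, 0.0, 1.0)
        else:
            mu_a[sl] = np.clip(baselines[k] + cfg.effect_size, 0.0, 1.0)
            mu_b[sl] = baselines[k]
        effects.append(float(mu_b[sl][0] - mu_a[sl][0]))

    rng_cov = np.random.default_rng(ss_cov)
    size = cfg.coverage_dispersion
    p_nb = size / (size + cfg.coverage_mean)
    cov_a = rng_cov.negative_binomial(size, p_nb, size=(cfg.n_sites, cfg.r_a))
    cov_b = rng_cov.negative_binomial(size, p_nb, size=(cfg.n_sites, cfg.r_b))

    def counts(mu_g, cov, ss_beta, ss_binom, r):
        u_beta = np.random.default_rng(ss_beta).uniform(size=(cfg.n_sites, r))
        u_binom = np.random.default_rng(ss_binom).uniform(size=(cfg.n_sites, r))
        frac = _beta_fractions(mu_g, cfg.rho, u_beta)
        meth = sps.binom.ppf(u_binom, cov, frac)
        return np.nan_to_num(meth).astype(np.int64)

    meth_a = counts(mu_a, cov_a, ss_beta_a, ss_binom_a, cfg.r_a)
    meth_b = counts(mu_b, cov_b, ss_beta_b, ss_binom_b, cfg.r_b)

    def tables(meth, cov, label, r):
        out = []
        for j in range(r):
            df = pd.DataFrame({
                "chrom": cfg.chrom, "pos": pos, "strand": "+",
                "meth": meth[:, j], "coverage": cov[:, j],
            }, columns=list(SITE_COLUMNS))
            out.append(SiteTable(sample_id=f"{label}{j + 1}", data=df))
        return tuple(out)

    truth = IntervalSet((cfg.chrom, int(pos[starts[k]]), int(pos[ends[k]]))
                        for k in range(cfg.n_dmrs))
    return SyntheticDataset(
        group_a=tables(meth_a, cov_a, "A", cfg.r_a),
        group_b=tables(meth_b, cov_b, "B", cfg.r_b),
        truth=truth, truth_effects=tuple(effects), config=cfg,
    )


def difficulty_series(base: SimulationConfig,
                      levels: Sequence[float]) -> list[SyntheticDataset]:
    """One dataset per effect size, sharing coordinates, seeds and truth.

    ``levels`` must be in descending order (strongest effect first),
    mirroring graded-difficulty benchmark subsets.
    """
    if list(levels) != sorted(levels, reverse=True):
        raise ConfigError("difficulty levels must be descending")
    return [simulate(base.replace(effect_size=d)) for d in levels]


def export_fixtures(dataset: SyntheticDataset, dialects: Sequence[str],
                    directory) -> dict:
    """Write every sample in every dialect, plus truth BED and config echo.

    Returns a manifest mapping roles to the written paths.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    manifest: dict = {"samples": {}, "truth": None, "config": None}
    for table in dataset.group_a + dataset.group_b:
        for name in dialects:
            if name not in DIALECTS:
                raise ValueError(f"unknown dialect {name!r}")
            path = os.path.join(directory, f"{table.sample_id}.{name}.txt")
            write_sample(table, path, name)
            manifest["samples"].setdefault(table.sample_id, {})[name] = path
    truth_path = os.path.join(directory, "truth.bed")
    with open(truth_path, "w") as fh:
        for (c, s, e), d in zip(dataset.truth, dataset.truth_effects):
            fh.write(f"{c}\t{s - 1}\t{e}\tplanted\t{int(abs(d) * 1000)}\t"
                     f"{'+' if d >= 0 else '-'}\n")
    manifest["truth"] = truth_path
    cfg_path = os.path.join(directory, "config.txt")
    with open(cfg_path, "w") as fh:
        fh.write(dataset.config.to_text())
    manifest["config"] = cfg_path
    return manifest
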