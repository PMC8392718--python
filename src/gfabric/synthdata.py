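"""Seeded generator of spot-level microarray datasets with known ground truth.

The generator emulates a replicated two-channel expression-profiling design:
a small number of regions (tissues) x phenotypes (mouse lines) x biological
replicas (animals), with each gene probed by a few redundant spots per array.
Abundances are lognormal across genes; biological replicate noise is
multiplicative lognormal with a gene-specific coefficient of variation (CV);
spot-level technical noise is a smaller multiplicative term.  Co-regulation
is induced by additive latent factors on the log scale, either per dataset
(co-regulation blocks) or per animal shared across regions (cross-region
synchrony).  A configurable fraction of spots is corrupted (quality flag) or
washed out (foreground below twice the background), exercising both QC
filter rules downstream.

Loading semantics
-----------------
A block with loading ``l`` gives each member gene the biological log-noise
``sigma_i * (l*f + (1-l)*eps) / sqrt(l^2 + (1-l)^2)`` where ``f`` is the
block factor (one draw per array) and ``eps`` is private noise.  Two member
genes therefore correlate ``l^2 / (l^2 + (1-l)^2)`` on the log scale
(0.997 at l = 0.95), while the marginal CV stays at the configured value.
The same scheme drives cross-region genes from a per-animal factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .ingest import SPOT_COLUMNS, read_spot_table, write_spot_table


def gene_names(n_genes: int) -> list[str]:
    """Canonical synthetic gene identifiers g00000, g00001, ..."""
    return [f"g{i:05d}" for i in range(n_genes)]


@dataclass
class SynthConfig:
    """Full description of one synthetic experiment.

    Defaults mirror the profiled study design: 2 regions x 3 phenotypes x 4
    biological replicas, 2 redundant spots per gene, lognormal abundances,
    biological CV drawn uniformly from 10-40%, 2% spot-level technical CV,
    and 1% corrupted plus 1% low-signal spots.
    """

    n_genes: int = 100
    regions: tuple[str, ...] = ("cortex", "hippocampus")
    phenotypes: tuple[str, ...] = ("MRL_lpr", "Fn14ko", "MRL_plus")
    n_replicas: int = 4
    spots_per_gene: int | dict = 2
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    cv_range: tuple[float, float] = (0.10, 0.40)
    spot_cv: float = 0.02
    #: gene -> (test_phenotype, ref_phenotype, true fold-change > 0)
    regulated_genes: dict = field(default_factory=dict)
    #: list of (member gene list, loading in (0, 1])
    coregulation_blocks: list = field(default_factory=list)
    #: genes driven by a per-animal factor shared across regions
    cross_region_shared_genes: list = field(default_factory=list)
    cross_region_loading: float = 0.95
    #: gene -> biological CV, overriding the cv_range draw
    cv_overrides: dict = field(default_factory=dict)
    frac_corrupted_spots: float = 0.01
    frac_low_signal_spots: float = 0.01
    background_range: tuple[float, float] = (1.0, 3.0)
    gain: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes: must be >= 1")
        if self.n_replicas < 2:
            raise ConfigError("n_replicas: must be >= 2")
        if not self.regions or not self.phenotypes:
            raise ConfigError("regions/phenotypes: must be non-empty")
        if len(set(self.regions)) != len(self.regions):
            raise ConfigError("regions: duplicate labels")
        if len(set(self.phenotypes)) != len(self.phenotypes):
            raise ConfigError("phenotypes: duplicate labels")
        for name in ("frac_corrupted_spots", "frac_low_signal_spots"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1], got {v}")
        lo, hi = self.cv_range
        if not 0.0 < lo <= hi:
            raise ConfigError(f"cv_range: need 0 < lo <= hi, got {self.cv_range}")
        if self.spot_cv < 0:
            raise ConfigError("spot_cv: must be >= 0")
        known = set(gene_names(self.n_genes))
        for gene, spec in self.regulated_genes.items():
            if gene not in known:
                raise ConfigError(f"regulated_genes: unknown gene {gene!r}")
            test, ref, fold = spec
            if test not in self.phenotypes or ref not in self.phenotypes:
                raise ConfigError(f"regulated_genes[{gene}]: unknown phenotype in {spec}")
            if test == ref:
                raise ConfigError(f"regulated_genes[{gene}]: test == ref phenotype")
            if not fold > 0:
                raise ConfigError(f"regulated_genes[{gene}]: fold-change must be > 0")
        in_block: set[str] = set()
        for genes, loading in self.coregulation_blocks:
            if not 0.0 < loading <= 1.0:
                raise ConfigError(f"coregulation_blocks: loading {loading} not in (0, 1]")
            for g in genes:
                if g not in known:
                    raise ConfigError(f"coregulation_blocks: unknown gene {g!r}")
                if g in in_block:
                    raise ConfigError(f"coregulation_blocks: gene {g!r} in two blocks")
                in_block.add(g)
        for g in self.cross_region_shared_genes:
            if g not in known:
                raise ConfigError(f"cross_region_shared_genes: unknown gene {g!r}")
            if g in in_block:
                raise ConfigError(f"cross_region_shared_genes: gene {g!r} also in a block")
        if not 0.0 < self.cross_region_loading <= 1.0:
            raise ConfigError("cross_region_loading: must be in (0, 1]")
        for g, cv in self.cv_overrides.items():
            if g not in known:
                raise ConfigError(f"cv_overrides: unknown gene {g!r}")
            if not cv > 0:
                raise ConfigError(f"cv_overrides[{g}]: CV must be > 0")
        if isinstance(self.spots_per_gene, dict):
            for g, r in self.spots_per_gene.items():
                if g not in known:
                    raise ConfigError(f"spots_per_gene: unknown gene {g!r}")
                if int(r) < 1:
                    raise ConfigError(f"spots_per_gene[{g}]: must be >= 1")
        elif int(self.spots_per_gene) < 1:
            raise ConfigError("spots_per_gene: must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        for tup in ("regions", "phenotypes", "cv_range", "background_range"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        if "regulated_genes" in raw:
            raw["regulated_genes"] = {g: tuple(v) for g, v in raw["regulated_genes"].items()}
        if "coregulation_blocks" in raw:
            raw["coregulation_blocks"] = [(list(g), float(l)) for g, l in raw["coregulation_blocks"]]
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for tup in ("regions", "phenotypes", "cv_range", "background_range"):
            d[tup] = list(d[tup])
        d["regulated_genes"] = {g: list(v) for g, v in d["regulated_genes"].items()}
        d["coregulation_blocks"] = [[list(g), float(l)] for g, l in d["coregulation_blocks"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class GroundTruth:
    """Machine-readable record of what the generator planted."""

    fold_changes: dict  # gene -> [test, ref, fold]
    cv: dict  # gene -> biological CV
    blocks: list  # [[genes], loading]
    cross_region_genes: list
    cross_region_loading: float
    animal_latents: dict  # phenotype -> [per-replica factor]
    corrupted_spots: list  # "gene|spot|region|phenotype|replica"
    low_signal_spots: list

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _spot_counts(config: SynthConfig) -> np.ndarray:
    genes = gene_names(config.n_genes)
    if isinstance(config.spots_per_gene, dict):
        default = 1
        return np.array([int(config.spots_per_gene.get(g, default)) for g in genes])
    return np.full(config.n_genes, int(config.spots_per_gene))


def generate_experiment(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one full experiment.

    Returns the spot table (one row per gene x spot x array, including the
    corrupted and low-signal rows, flagged/degraded accordingly) and the
    ground truth.  Identical configs produce identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = gene_names(config.n_genes)
    n_g, n_r = config.n_genes, len(config.regions)
    n_p, n_x = len(config.phenotypes), config.n_replicas

    # fixed draw order => seed determinism regardless of config details
    log_base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_g)
    cv = rng.uniform(config.cv_range[0], config.cv_range[1], n_g)
    for g, v in config.cv_overrides.items():
        cv[genes.index(g)] = float(v)
    sigma = np.sqrt(np.log1p(cv**2))
    spot_sigma = np.sqrt(np.log1p(config.spot_cv**2))

    animal = rng.standard_normal((n_p, n_x))
    block_f = rng.standard_normal((max(len(config.coregulation_blocks), 1), n_r, n_p, n_x))
    eps = rng.standard_normal((n_g, n_r, n_p, n_x))

    # biological log-noise per (gene, region, phenotype, replica)
    delta = sigma[:, None, None, None] * eps
    for b, (members, loading) in enumerate(config.coregulation_blocks):
        idx = [genes.index(g) for g in members]
        norm = np.hypot(loading, 1.0 - loading)
        mix = loading * block_f[b][None] + (1.0 - loading) * eps[idx]
        delta[idx] = sigma[idx, None, None, None] * mix / norm
    if config.cross_region_shared_genes:
        l = config.cross_region_loading
        idx = [genes.index(g) for g in config.cross_region_shared_genes]
        norm = np.hypot(l, 1.0 - l)
        shared = animal[None, None, :, :]  # same factor in every region
        mix = l * shared + (1.0 - l) * eps[idx]
        delta[idx] = sigma[idx, None, None, None] * mix / norm

    log_mu = log_base[:, None, None, None] + delta
    for g, (test, _ref, fold) in config.regulated_genes.items():
        log_mu[genes.index(g), :, config.phenotypes.index(test), :] += np.log(fold)

    r_i = _spot_counts(config)
    total_spots = int(r_i.sum())
    gene_row = np.repeat(np.arange(n_g), r_i)  # spot row -> gene index
    spot_label = np.concatenate([[f"s{k:02d}" for k in range(r)] for r in r_i])

    eta = rng.standard_normal((total_spots, n_r, n_p, n_x))
    expr = np.exp(log_mu[gene_row] + spot_sigma * eta)

    background = rng.uniform(*config.background_range, size=expr.shape)
    foreground = background + config.gain * expr
    corrupted = rng.random(expr.shape) < config.frac_corrupted_spots
    low = (~corrupted) & (rng.random(expr.shape) < config.frac_low_signal_spots)
    foreground = np.where(low, background * rng.uniform(1.0, 1.95, size=expr.shape), foreground)

    rows = {
        "gene_id": np.broadcast_to(
            np.array([genes[i] for i in gene_row])[:, None, None, None], expr.shape
        ).ravel(),
        "spot_id": np.broadcast_to(np.array(spot_label)[:, None, None, None], expr.shape).ravel(),
        "region": np.broadcast_to(
            np.array(config.regions)[None, :, None, None], expr.shape
        ).ravel(),
        "phenotype": np.broadcast_to(
            np.array(config.phenotypes)[None, None, :, None], expr.shape
        ).ravel(),
        "replica": np.broadcast_to(
            np.array([f"r{x + 1}" for x in range(n_x)])[None, None, None, :], expr.shape
        ).ravel(),
        "foreground": foreground.ravel(),
        "background": background.ravel(),
        "flag_corrupted": corrupted.astype(int).ravel(),
    }
    table = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    table = table.sort_values(
        ["region", "phenotype", "replica", "gene_id", "spot_id"], kind="stable"
    ).reset_index(drop=True)

    def spot_keys(mask: np.ndarray) -> list[str]:
        flat = pd.DataFrame({k: rows[k] for k in ("gene_id", "spot_id", "region", "phenotype", "replica")})
        hit = flat.loc[mask.ravel()]
        return ["|".join(t) for t in hit.itertuples(index=False, name=None)]

    truth = GroundTruth(
        fold_changes={g: list(v) for g, v in config.regulated_genes.items()},
        cv={g: float(c) for g, c in zip(genes, cv)},
        blocks=[[list(g), float(l)] for g, l in config.coregulation_blocks],
        cross_region_genes=list(config.cross_region_shared_genes),
        cross_region_loading=float(config.cross_region_loading),
        animal_latents={p: animal[j].tolist() for j, p in enumerate(config.phenotypes)},
        corrupted_spots=spot_keys(corrupted),
        low_signal_spots=spot_keys(low),
    )
    return table, truth


def write_fixture(table: pd.DataFrame, truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Write ``spots.tsv`` + ``truth.json`` under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"spots": outdir / "spots.tsv", "truth": outdir / "truth.json"}
    write_spot_table(table, paths["spots"])
    truth.write(paths["truth"])
    return paths


def read_fixture(outdir: str | Path) -> tuple[pd.DataFrame, GroundTruth]:
    outdir = Path(outdir)
    return read_spot_table(outdir / "spots.tsv"), GroundTruth.read(outdir / "truth.json")
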