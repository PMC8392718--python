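"""End-to-end orchestration: generate/load -> ingest -> metrics -> regulation
-> coordination, plus dataset bookkeeping and report writing.

A run is described by a :class:`RunConfig` (YAML-loadable).  All randomness
flows from the single seed through the synthetic generator; reruns of the
same config produce identical result files.  Every run writes a manifest
recording the config, the formula-variant switches and the bookkeeping
counts, so the provenance of each table is auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict
from math import comb
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .fabric_metrics import GCH_VARIANTS, gene_summary, rank_hierarchy
from .ingest import ExpressionTensor, FilterReport, ingest_spot_table, read_spot_table
from .coordination import (
    compare_expected_relations,
    concordance_summary,
    coordination_network,
    cross_region_phase,
    read_expected_relations,
)
from .regulation import (
    WPR_VARIANTS,
    Comparison,
    compute_regulation,
    pathway_regulation_table,
    read_gmt,
)
from .synthdata import SynthConfig, generate_experiment, write_fixture


@dataclass
class DatasetBookkeeping:
    """Closed-form counts of the workable values a design yields."""

    n_genes: int
    n_regions: int
    n_phenotypes: int
    n_replicas: int

    @property
    def n_samples(self) -> int:
        return self.n_regions * self.n_phenotypes * self.n_replicas

    @property
    def n_datasets(self) -> int:
        return self.n_regions * self.n_phenotypes

    @property
    def n_ave(self) -> int:
        return self.n_genes * self.n_datasets

    @property
    def n_rev(self) -> int:
        return self.n_genes * self.n_datasets

    @property
    def n_cor_pairs(self) -> int:
        """Distinct within-dataset gene pairs, summed over datasets."""
        return self.n_datasets * comb(self.n_genes, 2)

    @property
    def n_cross_region(self) -> int:
        """Same-gene between-region correlations (per phenotype, region pair)."""
        return self.n_genes * self.n_phenotypes * comb(self.n_regions, 2)

    @property
    def amplification_ratio(self) -> float:
        """Total workable values over the traditional AVE-only count."""
        total = self.n_ave + self.n_rev + self.n_cor_pairs + self.n_cross_region
        return total / self.n_ave

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
            "n_datasets": self.n_datasets,
            "n_ave": self.n_ave,
            "n_rev": self.n_rev,
            "n_cor_pairs": self.n_cor_pairs,
            "n_cross_region": self.n_cross_region,
            "amplification_ratio": self.amplification_ratio,
        }


def bookkeeping(tensors: dict) -> DatasetBookkeeping:
    """Counts from assembled tensors (closed form, no enumeration)."""
    if not tensors:
        raise ConfigError("bookkeeping needs at least one tensor")
    first = next(iter(tensors.values()))
    regions = sorted({t.region for t in tensors.values()})
    phenotypes = sorted({t.phenotype for t in tensors.values()})
    return DatasetBookkeeping(
        n_genes=first.n_genes,
        n_regions=len(regions),
        n_phenotypes=len(phenotypes),
        n_replicas=first.n_replicas,
    )


@dataclass
class RunConfig:
    """One pipeline run: input, contrasts, gene sets and formula switches."""

    synth: SynthConfig | None = None
    fixture_path: str | None = None
    #: list of (region, test_phenotype, ref_phenotype)
    comparisons: list = field(default_factory=list)
    pathways_gmt: str | None = None
    expectations_tsv: str | None = None
    alpha: float = 0.05
    gch_variant: str = "offset"
    wpr_variant: str = "mean_abs"
    outdir: str = "results/run"
    seed: int = 0

    def validate(self) -> None:
        if (self.synth is None) == (self.fixture_path is None):
            raise ConfigError("exactly one of synth config or fixture_path is required")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha: must be in (0, 1), got {self.alpha}")
        if self.gch_variant not in GCH_VARIANTS:
            raise ConfigError(f"gch_variant: must be one of {GCH_VARIANTS}")
        if self.wpr_variant not in WPR_VARIANTS:
            raise ConfigError(f"wpr_variant: must be one of {WPR_VARIANTS}")
        if self.synth is not None:
            self.synth.validate()
            for region, test, ref in self.comparisons:
                if region not in self.synth.regions:
                    raise ConfigError(f"comparisons: unknown region {region!r}")
                for p in (test, ref):
                    if p not in self.synth.phenotypes:
                        raise ConfigError(f"comparisons: unknown phenotype {p!r}")
                if test == ref:
                    raise ConfigError(f"comparisons: test == ref in {region!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigError(f"unknown run-config fields: {sorted(unknown)}")
        if raw.get("synth") is not None:
            synth = dict(raw["synth"])
            for tup in ("regions", "phenotypes", "cv_range", "background_range"):
                if tup in synth:
                    synth[tup] = tuple(synth[tup])
            if "regulated_genes" in synth:
                synth["regulated_genes"] = {
                    g: tuple(v) for g, v in synth["regulated_genes"].items()
                }
            if "coregulation_blocks" in synth:
                synth["coregulation_blocks"] = [
                    (list(g), float(l)) for g, l in synth["coregulation_blocks"]
                ]
            raw["synth"] = SynthConfig(**synth)
        if "comparisons" in raw:
            raw["comparisons"] = [tuple(c) for c in raw["comparisons"]]
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _dataset_tag(region: str, phenotype: str) -> str:
    return f"{region}__{phenotype}"


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all result files; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "gfabric_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "alpha": config.alpha,
        "gch_variant": config.gch_variant,
        "wpr_variant": config.wpr_variant,
        "stages": [],
    }

    # -- stage 1: obtain spot table ---------------------------------------
    if config.synth is not None:
        synth = config.synth
        if synth.seed != config.seed:
            synth = SynthConfig(**{**asdict(synth), "seed": config.seed})
            for f in ("regions", "phenotypes", "cv_range", "background_range"):
                setattr(synth, f, tuple(getattr(synth, f)))
            synth.regulated_genes = {g: tuple(v) for g, v in synth.regulated_genes.items()}
            synth.coregulation_blocks = [
                (list(g), float(l)) for g, l in synth.coregulation_blocks
            ]
        table, truth = generate_experiment(synth)
        write_fixture(table, truth, outdir / "fixture")
        manifest["stages"].append({"stage": "simulate", "n_rows": int(len(table))})
    else:
        table = read_spot_table(Path(config.fixture_path) / "spots.tsv")
        manifest["stages"].append({"stage": "load", "n_rows": int(len(table))})

    # -- stage 2: ingest ---------------------------------------------------
    tensors, report = ingest_spot_table(table)
    report.write(outdir / "filter_report.json")
    for (region, phenotype), tensor in tensors.items():
        tensor.write(outdir / f"tensor__{_dataset_tag(region, phenotype)}.tsv")
    books = bookkeeping(tensors)
    manifest["stages"].append(
        {"stage": "ingest", "n_arrays": len(report.array_medians), "n_tensors": len(tensors)}
    )
    manifest["bookkeeping"] = books.to_dict()

    # -- stage 3: fabric metrics -------------------------------------------
    summaries = {}
    for key, tensor in tensors.items():
        summary = gene_summary(tensor, alpha=config.alpha, variant=config.gch_variant)
        summaries[key] = summary
        ranked = rank_hierarchy(summary)
        ranked.to_csv(outdir / f"gene_summary__{_dataset_tag(*key)}.tsv", sep="\t")
    manifest["stages"].append({"stage": "metrics", "n_datasets": len(summaries)})

    # -- stage 4: regulation -----------------------------------------------
    pathways = read_gmt(config.pathways_gmt) if config.pathways_gmt else []
    regulations = {}
    for region, test, ref in config.comparisons:
        comp = Comparison(region, test, ref)
        t_test = tensors.get((region, test))
        t_ref = tensors.get((region, ref))
        if t_test is None or t_ref is None:
            raise ConfigError(f"comparisons: dataset missing for {comp.label}")
        rec = compute_regulation(t_test, t_ref, alpha=config.alpha)
        regulations[comp.label] = rec
        rec.reindex(rec["WIR"].abs().sort_values(ascending=False).index).to_csv(
            outdir / f"regulation__{comp.label.replace(':', '__')}.tsv", sep="\t"
        )
        if pathways:
            pw = pathway_regulation_table(pathways, rec, variant=config.wpr_variant)
            pw.to_csv(outdir / f"pathways__{comp.label.replace(':', '__')}.tsv", sep="\t")
    manifest["stages"].append({"stage": "regulate", "n_comparisons": len(regulations)})

    # -- stage 5: coordination & synchrony ----------------------------------
    if config.expectations_tsv:
        relations = read_expected_relations(config.expectations_tsv)
        rel_genes = sorted({r.member_gene for r in relations} | {r.target_gene for r in relations})
        concord = {}
        for key, tensor in tensors.items():
            edges, _skipped = coordination_network(tensor, rel_genes, alpha=config.alpha)
            edges.to_csv(outdir / f"edges__{_dataset_tag(*key)}.tsv", sep="\t", index=False)
            comparison = compare_expected_relations(edges, relations)
            comparison.to_csv(
                outdir / f"concordance__{_dataset_tag(*key)}.tsv", sep="\t", index=False
            )
            concord[_dataset_tag(*key)] = concordance_summary(comparison)
        manifest["concordance"] = concord
        manifest["stages"].append({"stage": "coordinate", "n_datasets": len(concord)})

    regions = sorted({k[0] for k in tensors})
    phenotypes = sorted({k[1] for k in tensors})
    if len(regions) >= 2:
        phase_summaries = {}
        pathway_genes = sorted({g for pw in pathways for g in pw.genes}) if pathways else None
        for phenotype in phenotypes:
            for i, ra in enumerate(regions):
                for rb in regions[i + 1 :]:
                    ta, tb = tensors[(ra, phenotype)], tensors[(rb, phenotype)]
                    phase, summary = cross_region_phase(
                        ta, tb, gene_set=pathway_genes, alpha=config.alpha
                    )
                    tag = f"{ra}__{rb}__{phenotype}"
                    phase.to_csv(outdir / f"phase__{tag}.tsv", sep="\t")
                    phase_summaries[tag] = summary
        (outdir / "phase_summary.json").write_text(json.dumps(phase_summaries, indent=2))
        manifest["phase"] = phase_summaries
        manifest["stages"].append({"stage": "phase", "n_analyses": len(phase_summaries)})

    write_reports(summaries, regulations, outdir)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_reports(
    summaries: dict, regulations: dict, outdir: str | Path, top_k: int = 20
) -> None:
    """Headline tables: top AVE, top |WIR| per comparison, top GCH per dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, summary in summaries.items():
        tag = _dataset_tag(*key)
        top_ave = summary.sort_values("AVE", ascending=False).head(top_k)
        top_ave.to_csv(outdir / f"top_ave__{tag}.tsv", sep="\t")
        top_gch = rank_hierarchy(summary).head(top_k)
        top_gch.to_csv(outdir / f"top_gch__{tag}.tsv", sep="\t")
    for label, rec in regulations.items():
        order = rec["WIR"].abs().sort_values(ascending=False).index
        rec.reindex(order).head(top_k).to_csv(
            outdir / f"top_wir__{label.replace(':', '__')}.tsv", sep="\t"
        )
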