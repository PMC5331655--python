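"""End-to-end orchestration: from annotation/read files to report tables.

Stages: build repeat catalogs per species (parse, join, coding filter),
quantify TE expression per species, lift the query catalog to each target
and classify sequence conservation, aggregate per-family expression
conservation with hypergeometric enrichment, then build the lncRNA catalog
and its TE annotation, contribution statistics and cross-species
conservation tiers. Every stage logs record counts; the canonical output is
a JSON manifest plus TSV report tables. Deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import (
    conservation_enrichment as ce,
    expression_quant as eq,
    lncrna_pipeline as lp,
    orthology_lift as ol,
    repeat_catalog as rc,
)
from .errors import TeconsexError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one query-vs-targets analysis run."""

    query: str
    targets: list[str]
    repeats: dict[str, str]
    coding: dict[str, str]
    chains: dict[str, str]
    reads: dict[str, list[str]]
    gtf: str
    output_dir: str
    genome_length: int
    fasta: str | None = None
    library_sizes: dict[str, list[int]] | None = None
    min_match: float = 0.1
    rpkm_cutoff: float = 1.0
    min_exon_fraction: float = 0.1
    min_total: int = 100
    min_expressed_query: int = 30
    min_conserved: int = 10
    coding_potential_cutoff: float = lp.DEFAULT_CODING_POTENTIAL_CUTOFF
    biotype_blacklist: list[str] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as out:
            yaml.safe_dump(data, out, sort_keys=True)

    def enrichment_filters(self) -> ce.EnrichmentFilters:
        return ce.EnrichmentFilters(
            min_total=self.min_total,
            min_expressed_query=self.min_expressed_query,
            min_conserved=self.min_conserved,
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of human-readable violations (empty means valid)."""
    violations: list[str] = []
    if not config.targets:
        violations.append("targets: empty target-species list")
    if not 0.0 < config.min_match <= 1.0:
        violations.append(f"min_match outside (0,1]: {config.min_match}")
    if config.rpkm_cutoff < 0:
        violations.append(f"rpkm_cutoff negative: {config.rpkm_cutoff}")
    if not 0.0 <= config.min_exon_fraction <= 1.0:
        violations.append(f"min_exon_fraction outside [0,1]: {config.min_exon_fraction}")
    if config.genome_length <= 0:
        violations.append(f"genome_length not positive: {config.genome_length}")
    species = [config.query, *config.targets]
    for sp in species:
        for group in ("repeats", "coding"):
            path = getattr(config, group).get(sp)
            if path is None:
                violations.append(f"{group}: no file for species {sp}")
            elif not Path(path).exists():
                violations.append(f"{group}: missing file {path}")
        paths = config.reads.get(sp)
        if not paths:
            violations.append(f"reads: no replicates for species {sp}")
        else:
            for p in paths:
                if not Path(p).exists():
                    violations.append(f"reads: missing file {p}")
    for target in config.targets:
        path = config.chains.get(target)
        if path is None:
            violations.append(f"chains: no chain file for target {target}")
        elif not Path(path).exists():
            violations.append(f"chains: missing file {path}")
    if not Path(config.gtf).exists():
        violations.append(f"gtf: missing file {config.gtf}")
    if config.fasta is not None and not Path(config.fasta).exists():
        violations.append(f"fasta: missing file {config.fasta}")
    return violations


@dataclass
class SpeciesData:
    instances: list[rc.TEInstance]
    noncoding: list[rc.TEInstance]
    reads: list[list[tuple[str, int, int]]]
    library_sizes: list[int]
    expression: pd.DataFrame
    expressed: dict[str, bool]


@dataclass
class PipelineResult:
    species_data: dict[str, SpeciesData]
    flags_by_target: dict[str, list[ce.InstanceFlags]]
    summaries_by_target: dict[str, list[ce.FamilySummary]]
    enrichment_by_target: dict[str, pd.DataFrame]
    combined: pd.DataFrame
    age_tables: dict[str, pd.DataFrame]
    catalog_result: lp.CatalogFilterResult
    annotations: list[lp.TEOverlapAnnotation]
    contribution: lp.ContributionStats | None
    lnc_conservation: pd.DataFrame
    tiers: dict[str, str]
    manifest: dict


def _load_species(config: PipelineConfig, sp: str) -> SpeciesData:
    fragments = rc.parse_repeatmasker_out(config.repeats[sp])
    instances = rc.join_nested_repeats(fragments)
    coding = rc.read_bed_intervals(config.coding[sp])
    noncoding = rc.filter_coding_overlap(instances, coding)
    logger.info(
        "%s: %d fragments -> %d instances, %d after coding filter",
        sp, len(fragments), len(instances), len(noncoding),
    )
    reads = [eq.read_reads_bed(p) for p in config.reads[sp]]
    if config.library_sizes and sp in config.library_sizes:
        libs = list(config.library_sizes[sp])
    else:
        libs = [len(r) for r in reads]
    features = [(i.instance_id, i.chrom, i.start, i.end) for i in noncoding]
    lengths = {i.instance_id: i.length_bp for i in noncoding}
    table = eq.expression_table(
        features, reads, libs, feature_lengths=lengths, mode="te", cutoff=config.rpkm_cutoff
    )
    expressed = dict(zip(table["feature_id"], table["expressed"]))
    return SpeciesData(
        instances=instances,
        noncoding=noncoding,
        reads=reads,
        library_sizes=libs,
        expression=table,
        expressed=expressed,
    )


def run_te_conservation(
    config: PipelineConfig, species_data: dict[str, SpeciesData]
) -> tuple[dict, dict, dict, dict]:
    """TE stages: lift + classify per target, family summaries, tables."""
    qdata = species_data[config.query]
    flags_by_target: dict[str, list[ce.InstanceFlags]] = {}
    summaries_by_target: dict[str, list[ce.FamilySummary]] = {}
    enrichment_by_target: dict[str, pd.DataFrame] = {}
    age_tables: dict[str, pd.DataFrame] = {}
    ages = rc.family_ages(qdata.noncoding)
    for target in config.targets:
        chains = ol.parse_chain(config.chains[target])
        tdata = species_data[target]
        records = ol.classify_conservation(
            qdata.noncoding, chains, tdata.instances, config.min_match, target
        )
        flags = []
        for rec in records:
            expressed_target = bool(
                rec.matched_target_instance
                and tdata.expressed.get(rec.matched_target_instance, False)
            )
            flags.append(
                ce.InstanceFlags(
                    instance_id=rec.instance_id,
                    family=rec.family,
                    te_class=rec.te_class,
                    expressed_query=qdata.expressed.get(rec.instance_id, False),
                    lifted=rec.lifted,
                    te_annotated_in_target=rec.te_annotated_in_target,
                    expressed_in_target=expressed_target,
                )
            )
        flags_by_target[target] = flags
        summaries = ce.summarize_families(flags)
        summaries_by_target[target] = summaries
        enrichment_by_target[target] = ce.family_enrichment_table(
            summaries, config.enrichment_filters()
        )
        age_tables[target] = ce.age_vs_conservation(
            ages, summaries, config.min_expressed_query
        )
        logger.info(
            "%s -> %s: %d instances, %d lifted",
            config.query, target, len(flags), sum(f.lifted for f in flags),
        )
    return flags_by_target, summaries_by_target, enrichment_by_target, age_tables


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write report tables plus a JSON manifest."""
    violations = validate_config(config)
    if violations:
        raise TeconsexError("invalid configuration: " + "; ".join(violations))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    species_data = {sp: _load_species(config, sp) for sp in [config.query, *config.targets]}
    flags_by_target, summaries_by_target, enrichment_by_target, age_tables = (
        run_te_conservation(config, species_data)
    )
    combined = ce.combined_conservation(summaries_by_target)

    # lncRNA stages
    sequences = {}
    if config.fasta:
        from Bio import SeqIO

        sequences = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(config.fasta, "fasta")
        }
    transcripts = lp.read_transcripts_gtf(config.gtf, sequences)
    blacklist = (
        frozenset(config.biotype_blacklist)
        if config.biotype_blacklist is not None
        else lp.DEFAULT_BIOTYPE_BLACKLIST
    )
    catalog_result = lp.build_lncrna_catalog(
        transcripts, blacklist, config.coding_potential_cutoff
    )
    catalog = catalog_result.catalog
    query_instances = species_data[config.query].instances
    annotations = lp.annotate_te_overlap(catalog, query_instances, config.min_exon_fraction)
    try:
        contribution = lp.contribution_stats(
            annotations, catalog, query_instances, config.genome_length
        )
    except TeconsexError:
        contribution = None
    chains_by_target = {t: ol.parse_chain(config.chains[t]) for t in config.targets}
    reads_by_target = {
        t: lp.TargetReads(
            reads_per_replicate=species_data[t].reads,
            library_sizes=species_data[t].library_sizes,
        )
        for t in config.targets
    }
    te_by_target = {t: species_data[t].instances for t in config.targets}
    lnc_conservation, tiers = lp.lncrna_conservation(
        catalog,
        chains_by_target,
        reads_by_target,
        te_by_target,
        config.min_match,
        config.min_exon_fraction,
        config.rpkm_cutoff,
    )

    manifest = _build_manifest(
        config, species_data, flags_by_target, summaries_by_target,
        catalog_result, annotations, lnc_conservation, tiers,
    )
    _write_outputs(
        out_dir, config, species_data, enrichment_by_target, combined, age_tables,
        catalog, annotations, contribution, lnc_conservation, tiers, manifest,
    )
    return PipelineResult(
        species_data=species_data,
        flags_by_target=flags_by_target,
        summaries_by_target=summaries_by_target,
        enrichment_by_target=enrichment_by_target,
        combined=combined,
        age_tables=age_tables,
        catalog_result=catalog_result,
        annotations=annotations,
        contribution=contribution,
        lnc_conservation=lnc_conservation,
        tiers=tiers,
        manifest=manifest,
    )


def _build_manifest(
    config, species_data, flags_by_target, summaries_by_target,
    catalog_result, annotations, lnc_conservation, tiers,
) -> dict:
    manifest: dict = {
        "query": config.query,
        "targets": list(config.targets),
        "species": {},
        "conservation": {},
        "lncrna": {
            "filter_counts": catalog_result.counts,
            "n_te_overlapping": sum(a.has_te for a in annotations),
            "tier_counts": {
                tier: sum(v == tier for v in tiers.values())
                for tier in (lp.TIER_ALL_SPECIES, lp.TIER_SOME_NHP, lp.TIER_QUERY_ONLY)
            },
            "conservation_rows": lnc_conservation.to_dict(orient="records"),
        },
    }
    for sp, data in species_data.items():
        manifest["species"][sp] = {
            "n_instances": len(data.instances),
            "n_noncoding": len(data.noncoding),
            "n_expressed": int(sum(data.expressed.values())),
            "library_sizes": list(data.library_sizes),
        }
    for target, flags in flags_by_target.items():
        manifest["conservation"][target] = {
            "n_lifted": int(sum(f.lifted for f in flags)),
            "n_conserved": int(sum(f.conserved for f in flags)),
            "n_both_expressed": int(
                sum(f.conserved and f.expressed_query and f.expressed_in_target for f in flags)
            ),
            "families": {
                s.family: {
                    "total": s.total,
                    "query_expressed": s.n_expressed_query,
                    "conserved": s.n_conserved,
                    "both_expressed": s.n_both_expressed,
                }
                for s in summaries_by_target[target]
            },
        }
    return manifest


def _write_outputs(
    out_dir, config, species_data, enrichment_by_target, combined, age_tables,
    catalog, annotations, contribution, lnc_conservation, tiers, manifest,
) -> None:
    for sp, data in species_data.items():
        rc.write_instances_bed(data.noncoding, out_dir / f"{sp}.instances.bed")
        data.expression.to_csv(out_dir / f"{sp}.expression.tsv", sep="\t", index=False)
    for target, table in enrichment_by_target.items():
        ce.format_enrichment_table(table).to_csv(
            out_dir / f"enrichment.{target}.tsv", sep="\t", index=False
        )
    combined.to_csv(out_dir / "enrichment.combined.tsv", sep="\t", index=False)
    for target, table in age_tables.items():
        table.to_csv(out_dir / f"age_vs_conservation.{target}.tsv", sep="\t", index=False)
    lp.write_catalog_gtf(catalog, out_dir / "lncrna.catalog.gtf")
    rows = [
        {
            "transcript_id": a.transcript_id,
            "has_te": a.has_te,
            "dominant_family": a.dominant_family or "",
            "dominant_instance": a.dominant_instance or "",
            "tier": tiers.get(a.transcript_id, ""),
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(out_dir / "lncrna.te_annotation.tsv", sep="\t", index=False)
    if contribution is not None:
        contribution.class_table.to_csv(
            out_dir / "lncrna.class_contribution.tsv", sep="\t", index=False
        )
        contribution.family_table.to_csv(
            out_dir / "lncrna.family_contribution.tsv", sep="\t", index=False
        )
    lnc_conservation.to_csv(out_dir / "lncrna.conservation.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=1, sort_keys=True)


def config_from_dataset(dataset, output_dir: str | Path) -> PipelineConfig:
    """Build a PipelineConfig pointing at a :class:`SimulatedDataset`'s files."""
    species = dataset.species
    query, targets = species[0], species[1:]
    return PipelineConfig(
        query=query,
        targets=list(targets),
        repeats=dict(dataset.files["repeats"]),
        coding=dict(dataset.files["coding"]),
        chains=dict(dataset.files["chains"]),
        reads={sp: list(paths) for sp, paths in dataset.files["reads"].items()},
        gtf=dataset.files["gtf"][query],
        fasta=dataset.files["fasta"][query],
        library_sizes={sp: list(v) for sp, v in dataset.ground_truth.library_sizes.items()},
        output_dir=str(output_dir),
        genome_length=dataset.config.genome_length,
        seed=dataset.config.seed,
    )
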