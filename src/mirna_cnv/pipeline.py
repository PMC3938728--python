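"""End-to-end pipeline: QC -> annotate -> burden -> trio -> hotspot -> frequency.

One configuration object carries every module threshold; a run writes all
stage tables (TSV), the overlap graph (GraphML) and a run manifest with
input hashes, package version and seed, so a run is reproducible from the
manifest alone. Re-running with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from . import annotate as _annotate
from . import burden as _burden
from . import frequency as _frequency
from . import hotspot as _hotspot
from . import io as _io
from . import trio as _trio
from .model import ConfigError

log = logging.getLogger("mirna_cnv")


@dataclass
class PipelineConfig:
    calls: str
    genes: str
    manifest: str
    out_dir: str
    reference: Optional[str] = None
    qc_min_size: int = 1000
    qc_min_probes: int = 5
    qc_require_probes: bool = True
    reference_reciprocal: float = 0.5
    annotate_min_gene_overlap_bp: int = 1
    trio_tol_bp: int = 0
    trio_collapse_ambiguous: Optional[str] = None
    hotspot_merge: float = 0.40
    hotspot_family: float = 0.99
    hotspot_min_events: int = 5
    hotspot_overlap_mode: str = "reciprocal"
    frequency_tol_bp: int = 0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.hotspot_family < self.hotspot_merge:
            raise ConfigError(
                f"hotspot.family ({self.hotspot_family}) must be >= "
                f"hotspot.merge ({self.hotspot_merge})")
        if not 0 < self.hotspot_merge <= 1:
            raise ConfigError("hotspot.merge must be in (0, 1]")
        if not 0 <= self.reference_reciprocal <= 1:
            raise ConfigError("reference reciprocal threshold must be in [0, 1]")
        if min(self.qc_min_size, self.qc_min_probes, self.trio_tol_bp,
               self.frequency_tol_bp) < 0:
            raise ConfigError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order; returns the output directory.

    Any stage failure raises with the stage name in the message before
    later stages run; missing input files fail up front.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    for name in ("calls", "genes", "manifest"):
        p = getattr(config, name)
        if not Path(p).is_file():
            raise FileNotFoundError(f"input '{name}' not found: {p}")
    if config.reference and not Path(config.reference).is_file():
        raise FileNotFoundError(f"input 'reference' not found: {config.reference}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    calls, rejected = _io.read_cnv_table(config.calls)
    genes = _io.read_gene_annotation(config.genes)
    individuals = _io.read_manifest(config.manifest)
    log.info("stage io: %d calls (%d rejected rows), %d genes, %d individuals",
             len(calls), len(rejected), len(genes), len(individuals))

    kept, dropped = _annotate.qc_filter(
        calls, config.qc_min_size, config.qc_min_probes, config.qc_require_probes)
    log.info("stage qc: kept %d, dropped %d CNVs", len(kept), len(dropped))

    validated = None
    if config.reference:
        ref_genes = _io.read_gene_annotation(config.reference, format="bed")
        reference = [_annotate.ReferenceInterval(g.chrom, g.start, g.end)
                     for g in ref_genes]
        validated = _annotate.validate_against_reference(
            kept, reference, config.reference_reciprocal)
        log.info("stage validate: %d/%d calls reference-validated",
                 sum(validated.values()), len(kept))

    sex_of = {i.individual_id: i.sex for i in individuals}
    annotated = _annotate.annotate_mirna(
        kept, genes, sex_of=sex_of,
        min_gene_overlap_bp=config.annotate_min_gene_overlap_bp,
        validated=validated)
    mirna = [a for a in annotated if a.is_mirna_cnv]
    acc = _annotate.gene_accounting(annotated)
    log.info("stage annotate: %d miRNA-CNVs, %d gene hits, %d distinct genes",
             len(mirna), acc.total_gene_hits, len(acc.singleton_genes))

    tables: dict[str, pd.DataFrame] = {}
    tables["annotated"] = pd.DataFrame([{
        "call_id": a.call_id, "individual_id": a.individual_id,
        "chrom": a.call.chrom, "start": a.call.start, "end": a.call.end,
        "size": a.call.size, "cn_state": a.call.cn_state,
        "n_probes": a.call.n_probes, "cnv_type": a.cnv_type,
        "is_mirna_cnv": a.is_mirna_cnv, "genes": ",".join(a.genes),
        "reference_validated": ("" if a.reference_validated is None
                                else str(a.reference_validated)),
    } for a in annotated])
    tables["qc_dropped"] = pd.DataFrame(
        [{"call_id": c.call_id, "individual_id": c.individual_id, "chrom": c.chrom,
          "start": c.start, "end": c.end, "size": c.size, "n_probes": c.n_probes}
         for c in dropped],
        columns=["call_id", "individual_id", "chrom", "start", "end", "size",
                 "n_probes"])

    tables["population_summary"] = _burden.summarize_all(annotated, individuals)
    tables["cn_states"] = _burden.cn_state_spectrum(annotated, individuals)
    tables["sex_bias"] = _burden.sex_bias(annotated, individuals)
    tables["chrom_distribution"] = _burden.chromosome_distribution(annotated, individuals)
    tables["gene_sharing_circos"] = _io.circos_gene_sharing(annotated, genes, individuals)
    log.info("stage burden: %d populations summarized", len(tables["population_summary"]))

    inh = _trio.classify_cohort(kept, individuals, tol_bp=config.trio_tol_bp,
                                collapse_ambiguous=config.trio_collapse_ambiguous)
    mirna_ids = {a.call_id for a in mirna}
    tables["inheritance_calls"] = _trio.inheritance_table(inh)
    tables["inheritance_rates"] = _trio.inheritance_rates(inh, individuals)
    tables["inheritance_rates_mirna"] = _trio.inheritance_rates(
        inh, individuals, mirna_call_ids=mirna_ids)
    log.info("stage trio: %d proband calls classified", len(inh))

    mirna_calls = [a.call for a in mirna]
    graph = _hotspot.build_overlap_graph(
        mirna_calls, config.hotspot_merge, config.hotspot_overlap_mode)
    pop_of = {i.individual_id: i.population for i in individuals}
    regions = _hotspot.find_merged_regions(graph, population_of=pop_of)
    regions = _hotspot.attach_families(regions, mirna_calls,
                                       config.hotspot_family, config.hotspot_merge)
    labels = _hotspot.classify_events(regions, mirna_calls, config.hotspot_min_events)
    tables["merged_regions"] = _hotspot.regions_table(regions)
    tables["families"] = _hotspot.families_table(regions)
    tables["event_labels"] = pd.DataFrame(
        sorted(labels.items()), columns=["call_id", "label"])
    _hotspot.write_graphml(graph, out / "overlap_graph.graphml")
    log.info("stage hotspot: %d merged regions from %d miRNA-CNVs",
             len(regions), len(mirna_calls))

    groups = _frequency.group_breakpoints(annotated, individuals,
                                          tol_bp=config.frequency_tol_bp)
    denoms = _frequency.mirna_carrier_counts(annotated, individuals)
    groups = _frequency.compute_frequencies(groups, denoms)
    pops = sorted(denoms)
    tables["recurrent_breakpoints"] = _frequency.frequency_table(groups, pops)
    tables["tiers"] = _frequency.shared_population_tiers(groups)
    log.info("stage frequency: %d breakpoint groups", len(groups))

    _io.write_tables(tables, out)
    manifest = {
        "package": "mirna-cnv",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {name: {"path": str(getattr(config, name)),
                          "sha256": _sha256(Path(getattr(config, name)))}
                   for name in ("calls", "genes", "manifest")
                   if getattr(config, name)},
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return out


def demo(seed: int, out_dir: str | Path, sim_config=None) -> dict:
    """Generate a synthetic cohort, run the full pipeline on it, and
    compare pipeline output against the generator's ground truth.

    Returns (and writes as ``demo_report.json``) recovery metrics: the
    fraction of planted trio class labels recovered, the observed vs
    configured duplication fraction, and hotspot carrier recovery.
    """
    from . import simulate as _sim

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = sim_config or _sim.SimConfig(n_trios_per_population=5, seed=seed)
    if sim_config is None:
        cfg.seed = seed
    individuals, calls, genes, truth = _sim.generate_cohort(cfg)

    inputs = out / "inputs"
    inputs.mkdir(exist_ok=True)
    _io.write_cnv_table(calls, inputs / "calls.tsv")
    _io.write_gene_bed(genes, inputs / "mirna_genes.bed")
    _io.write_manifest(individuals, inputs / "cohort.ped")
    _sim.generate_trio_truth_table(truth).to_csv(
        inputs / "trio_truth.tsv", sep="\t", index=False, lineterminator="\n")

    pcfg = PipelineConfig(
        calls=str(inputs / "calls.tsv"),
        genes=str(inputs / "mirna_genes.bed"),
        manifest=str(inputs / "cohort.ped"),
        out_dir=str(out / "results"),
        seed=seed,
    )
    run_pipeline(pcfg)

    inh = pd.read_csv(out / "results" / "inheritance_calls.tsv", sep="\t")
    found = dict(zip(inh.proband_call_id, inh.label)) if len(inh) else {}
    planted = truth.trio_classes
    n_match = sum(1 for cid, t in planted.items() if found.get(cid) == t.label)
    annotated_df = pd.read_csv(out / "results" / "annotated.tsv", sep="\t")
    mirna_df = annotated_df[annotated_df.is_mirna_cnv]
    typed = mirna_df[mirna_df.cnv_type.isin(["duplication", "deletion"])]
    dup_frac = (float((typed.cnv_type == "duplication").mean())
                if len(typed) else float("nan"))
    hotspot_recovered = {}
    labels = pd.read_csv(out / "results" / "event_labels.tsv", sep="\t")
    label_of = dict(zip(labels.call_id, labels.label)) if len(labels) else {}
    for k, ids in truth.hotspot_carriers.items():
        present = [label_of.get(cid) for cid in ids]
        hotspot_recovered[str(k)] = {
            "n_planted": len(ids),
            "n_labelled_hotspot": sum(1 for v in present if v == "hotspot"),
        }
    report = {
        "seed": seed,
        "n_individuals": len(individuals),
        "n_calls": len(calls),
        "trio_planted": len(planted),
        "trio_recovered": n_match,
        "trio_recovery_pct": 100.0 * n_match / len(planted) if planted else float("nan"),
        "dup_fraction_observed": dup_frac,
        "dup_fraction_configured": cfg.dup_fraction,
        "hotspot_recovery": hotspot_recovered,
    }
    (out / "demo_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return report
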