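"""Seeded synthetic cohort generator for the miRNA-CNV burden pipeline.

The generator emulates the data structure of a multi-population array-CNV
cohort: a manifest of founders and parent-parent-child trios, a miRNA
gene annotation, and per-individual CNV calls mixing

* recurrent hotspot events — breakpoint-identical calls at a configured
  locus carried by a configured fraction of each population (one miRNA
  gene is always placed inside each hotspot locus, so hotspot calls are
  miRNA-CNVs by construction, mirroring a 22q11-type recurrent locus);
* background events placed across the genome, a configurable fraction of
  them positioned over a miRNA gene, with type drawn from
  ``dup_fraction`` and CN state drawn conditionally on type (deletions
  from {0, 1}, duplications from {3, 4});
* planted trio events: inherited calls copy a parental call's exact
  breakpoints into the proband; "unknown" calls share exactly one
  parental endpoint with the other endpoint shifted; de novo calls avoid
  every parental interval. Probands carry only planted events, so the
  truth table is exhaustive for them.

Everything is driven by one :class:`numpy.random.Generator`; the same
seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import CnvCall, ConfigError, GeneFeature, Individual

# Default genome: the chromosomes where the recurrent miRNA loci of
# interest live (22: mir650-type, 15, 16, 3) plus one quiet autosome.
DEFAULT_GENOME: tuple[tuple[str, int], ...] = (
    ("3", 198_000_000),
    ("5", 181_000_000),
    ("15", 102_000_000),
    ("16", 90_000_000),
    ("22", 51_000_000),
)


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    n_individuals: int
    n_males: int


@dataclass(frozen=True)
class HotspotLocus:
    chrom: str
    start: int
    end: int
    # one fraction for every population, or a per-population mapping
    carrier_fraction: Union[float, Mapping[str, float]] = 0.3

    def fraction_for(self, population: str) -> float:
        if isinstance(self.carrier_fraction, Mapping):
            return float(self.carrier_fraction.get(population, 0.0))
        return float(self.carrier_fraction)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the cohort the pipeline was built for: duplications
    make up 87.6% of miRNA-CNVs; deletions split 60/40 between complete
    (CN 0) and hemizygous (CN 1) loss and duplications 94/6 between CN 3
    and CN 4; duplication sizes 10-400 kb and deletion sizes 10-700 kb
    (deletions dominate the size burden); about 2.3 background events per
    individual (4007 miRNA-CNVs over 1715 individuals); trio planting
    rates from the printed trio clusters (175 inherited / 668 de novo /
    298 one-endpoint over ~60 trio probands -> 2.9 / 11.1 / 5.0 per
    proband).
    """

    populations: Sequence[PopulationSpec] = (
        PopulationSpec("YRI", 90, 45),
        PopulationSpec("CEU", 90, 45),
        PopulationSpec("TIBET", 31, 16),
        PopulationSpec("TAIWAN", 184, 92),
    )
    n_trios_per_population: int = 0
    genome: Sequence[tuple[str, int]] = DEFAULT_GENOME
    n_mirna_genes: int = 60
    hotspot_loci: Sequence[HotspotLocus] = (
        HotspotLocus("22", 23_040_138, 23_255_556, 0.3),
    )
    dup_fraction: float = 0.876
    cn_state_weights: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.6, 1: 0.4, 3: 0.94, 4: 0.06})
    rate_inherited: float = 2.9
    rate_denovo: float = 11.1
    rate_unknown: float = 5.0
    size_range_dup: tuple[int, int] = (10_000, 400_000)
    size_range_del: tuple[int, int] = (10_000, 700_000)
    background_rate: float = 2.3
    frac_mirna_targeted: float = 0.85
    sex_chrom_events: bool = False
    seed: int = 0

    def validate(self) -> None:
        lengths = dict(self.genome)
        for h in self.hotspot_loci:
            if h.chrom not in lengths or h.start < 1 or h.end > lengths[h.chrom]:
                raise ConfigError(
                    f"hotspot {h.chrom}:{h.start}-{h.end} outside genome bounds")
            fracs = (h.carrier_fraction.values()
                     if isinstance(h.carrier_fraction, Mapping)
                     else [h.carrier_fraction])
            if any(not 0 <= f <= 1 for f in fracs):
                raise ConfigError("hotspot carrier_fraction must be in [0, 1]")
        if not 0 <= self.dup_fraction <= 1 or not 0 <= self.frac_mirna_targeted <= 1:
            raise ConfigError("fractions must lie in [0, 1]")
        for p in self.populations:
            if p.n_males > p.n_individuals or p.n_males < 0:
                raise ConfigError(f"population {p.label}: n_males out of range")
        if min(self.rate_inherited, self.rate_denovo, self.rate_unknown,
               self.background_rate) < 0:
            raise ConfigError("event rates must be non-negative")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "populations" in d:
            d["populations"] = [
                p if isinstance(p, PopulationSpec) else PopulationSpec(*p)
                if isinstance(p, (list, tuple)) else PopulationSpec(**p)
                for p in d["populations"]]
        if "hotspot_loci" in d:
            d["hotspot_loci"] = [
                h if isinstance(h, HotspotLocus) else HotspotLocus(*h)
                if isinstance(h, (list, tuple)) else HotspotLocus(**h)
                for h in d["hotspot_loci"]]
        if "genome" in d:
            d["genome"] = [tuple(g) for g in d["genome"]]
        if "cn_state_weights" in d:
            d["cn_state_weights"] = {int(k): float(v)
                                     for k, v in d["cn_state_weights"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class TrioTruth:
    call_id: str
    label: str  # inherited | de_novo | unknown
    origin: str  # mother | father | none
    parent_call_id: Optional[str]
    matched_endpoint: str  # both | start_only | end_only | none


@dataclass
class TruthRecord:
    """Ground truth of every planted structure, for recovery tests."""

    trio_classes: dict[str, TrioTruth] = field(default_factory=dict)
    hotspot_carriers: dict[int, list[str]] = field(default_factory=dict)  # locus index -> call_ids
    event_type: dict[str, str] = field(default_factory=dict)  # call_id -> duplication|deletion
    genes: list[GeneFeature] = field(default_factory=list)


class _CohortBuilder:
    def __init__(self, config: SimConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.chrom_names = [c for c, _ in config.genome]
        self.chrom_len = dict(config.genome)
        total = sum(l for _, l in config.genome)
        self.chrom_p = np.array([l / total for _, l in config.genome]) if total else None
        self.calls: list[CnvCall] = []
        self.truth = TruthRecord()
        self._next_call = 0

    # -- identifiers ----------------------------------------------------
    def new_call_id(self) -> str:
        self._next_call += 1
        return f"c{self._next_call:06d}"

    # -- primitives -----------------------------------------------------
    def draw_type(self) -> str:
        return "duplication" if self.rng.random() < self.cfg.dup_fraction else "deletion"

    def draw_cn(self, cnv_type: str) -> int:
        states = (3, 4) if cnv_type == "duplication" else (0, 1)
        w = np.array([self.cfg.cn_state_weights.get(s, 0.0) for s in states], float)
        if w.sum() == 0:
            w = np.ones(len(states))
        return int(self.rng.choice(states, p=w / w.sum()))

    def draw_interval(self, cnv_type: str, chrom: Optional[str] = None,
                      around_gene: Optional[GeneFeature] = None) -> tuple[str, int, int]:
        lo, hi = (self.cfg.size_range_dup if cnv_type == "duplication"
                  else self.cfg.size_range_del)
        size = int(self.rng.integers(lo, hi + 1))
        if around_gene is not None:
            chrom = around_gene.chrom
            # position so the gene lies inside the event
            left_min = max(1, around_gene.end - size + 1)
            left_max = min(around_gene.start, self.chrom_len[chrom] - size + 1)
            if left_max < left_min:
                left_max = left_min
            start = int(self.rng.integers(left_min, left_max + 1))
        else:
            if chrom is None:
                chrom = str(self.rng.choice(self.chrom_names, p=self.chrom_p))
            start = int(self.rng.integers(1, max(2, self.chrom_len[chrom] - size + 1)))
        end = min(start + size - 1, self.chrom_len[chrom])
        return chrom, start, end

    def n_probes_for(self, size: int) -> int:
        # ~550 bp median inter-probe spacing on the emulated arrays
        return max(6, size // 550)

    def add_call(self, individual_id: str, chrom: str, start: int, end: int,
                 cn: int, cnv_type: str) -> CnvCall:
        call = CnvCall(individual_id=individual_id, chrom=chrom, start=start,
                       end=end, cn_state=cn, n_probes=self.n_probes_for(end - start + 1),
                       call_id=self.new_call_id())
        self.calls.append(call)
        self.truth.event_type[call.call_id] = cnv_type
        return call

    # -- stages ---------------------------------------------------------
    def build_individuals(self) -> tuple[list[Individual], list[Individual]]:
        founders: list[Individual] = []
        probands: list[Individual] = []
        for pop in self.cfg.populations:
            for i in range(pop.n_individuals):
                sex = "male" if i < pop.n_males else "female"
                founders.append(Individual(f"{pop.label}_{i:04d}", pop.label, sex))
            for t in range(self.cfg.n_trios_per_population):
                fid = f"{pop.label}_T{t:03d}_F"
                mid = f"{pop.label}_T{t:03d}_M"
                pid = f"{pop.label}_T{t:03d}_P"
                founders.append(Individual(fid, pop.label, "male"))
                founders.append(Individual(mid, pop.label, "female"))
                probands.append(Individual(
                    pid, pop.label,
                    "male" if self.rng.random() < 0.5 else "female",
                    father_id=fid, mother_id=mid))
        return founders, probands

    def build_genes(self) -> list[GeneFeature]:
        genes: list[GeneFeature] = []
        for k, h in enumerate(self.cfg.hotspot_loci):
            mid = (h.start + h.end) // 2
            genes.append(GeneFeature(f"MIRSIM{k + 1:04d}", h.chrom, mid, mid + 99,
                                     strand="+"))
        n_extra = max(0, self.cfg.n_mirna_genes - len(genes))
        for j in range(n_extra):
            chrom = str(self.rng.choice(self.chrom_names, p=self.chrom_p))
            length = int(self.rng.integers(70, 151))
            start = int(self.rng.integers(1, self.chrom_len[chrom] - length))
            genes.append(GeneFeature(
                f"MIRSIM{len(self.cfg.hotspot_loci) + j + 1:04d}",
                chrom, start, start + length - 1,
                strand="+" if self.rng.random() < 0.5 else "-"))
        self.truth.genes = genes
        return genes

    def plant_hotspots(self, founders: Sequence[Individual]) -> None:
        by_pop: dict[str, list[Individual]] = {}
        for ind in founders:
            by_pop.setdefault(ind.population, []).append(ind)
        for k, h in enumerate(self.cfg.hotspot_loci):
            planted: list[str] = []
            for pop in self.cfg.populations:
                members = by_pop.get(pop.label, [])
                n_carriers = round(h.fraction_for(pop.label) * len(members))
                if n_carriers == 0:
                    continue
                chosen = self.rng.choice(len(members), size=n_carriers, replace=False)
                for idx in sorted(chosen):
                    cnv_type = self.draw_type()
                    call = self.add_call(members[idx].individual_id, h.chrom,
                                         h.start, h.end, self.draw_cn(cnv_type),
                                         cnv_type)
                    planted.append(call.call_id)
            self.truth.hotspot_carriers[k] = planted

    def plant_background(self, individuals: Sequence[Individual],
                         genes: Sequence[GeneFeature]) -> None:
        for ind in individuals:
            n = int(self.rng.poisson(self.cfg.background_rate))
            for _ in range(n):
                cnv_type = self.draw_type()
                gene = None
                if genes and self.rng.random() < self.cfg.frac_mirna_targeted:
                    gene = genes[int(self.rng.integers(len(genes)))]
                chrom, start, end = self.draw_interval(cnv_type, around_gene=gene)
                self.add_call(ind.individual_id, chrom, start, end,
                              self.draw_cn(cnv_type), cnv_type)

    # trio planting -----------------------------------------------------
    def _parent_calls(self, trio: Individual) -> list[CnvCall]:
        ids = {trio.father_id, trio.mother_id}
        return [c for c in self.calls if c.individual_id in ids]

    def _new_parental_call(self, parent_id: str) -> CnvCall:
        cnv_type = self.draw_type()
        chrom, start, end = self.draw_interval(cnv_type)
        return self.add_call(parent_id, chrom, start, end,
                             self.draw_cn(cnv_type), cnv_type)

    def plant_trio_events(self, probands: Sequence[Individual]) -> None:
        for trio in probands:
            n_inh = int(self.rng.poisson(self.cfg.rate_inherited))
            n_unk = int(self.rng.poisson(self.cfg.rate_unknown))
            n_dnv = int(self.rng.poisson(self.cfg.rate_denovo))
            for _ in range(n_inh):
                self._plant_inherited(trio)
            for _ in range(n_unk):
                self._plant_unknown(trio)
            for _ in range(n_dnv):
                self._plant_denovo(trio)

    def _pick_parent(self, trio: Individual) -> tuple[str, str]:
        if self.rng.random() < 0.5:
            return trio.mother_id, "mother"
        return trio.father_id, "father"

    def _plant_inherited(self, trio: Individual) -> None:
        parent_id, role = self._pick_parent(trio)
        src = self._new_parental_call(parent_id)
        other_id = trio.father_id if role == "mother" else trio.mother_id
        # origin is unambiguous unless the other parent happens to carry an
        # identical call; regenerate in that (vanishingly rare) case
        for c in self.calls:
            if (c.individual_id == other_id and c.chrom == src.chrom
                    and c.start == src.start and c.end == src.end):
                self.calls.remove(src)
                return self._plant_inherited(trio)
        child = self.add_call(trio.individual_id, src.chrom, src.start, src.end,
                              src.cn_state, self.truth.event_type[src.call_id])
        self.truth.trio_classes[child.call_id] = TrioTruth(
            child.call_id, "inherited", role, src.call_id, "both")

    def _plant_unknown(self, trio: Individual) -> None:
        parent_id, role = self._pick_parent(trio)
        for _ in range(100):
            src = self._new_parental_call(parent_id)
            keep_start = bool(self.rng.random() < 0.5)
            shift = int(self.rng.integers(1_000, 50_001))
            if keep_start:
                start, end = src.start, min(src.end + shift, self.chrom_len[src.chrom])
                endpoint = "start_only"
            else:
                start, end = max(1, src.start - shift), src.end
                endpoint = "end_only"
            parent_calls = self._parent_calls(trio)
            # must not match BOTH endpoints of any parental call, and must
            # still match exactly one endpoint of the source
            bad = (start, end) == (src.start, src.end) or any(
                c.chrom == src.chrom and c.start == start and c.end == end
                for c in parent_calls)
            if not bad:
                child = self.add_call(trio.individual_id, src.chrom, start, end,
                                      self.draw_cn(self.truth.event_type[src.call_id]),
                                      self.truth.event_type[src.call_id])
                self.truth.trio_classes[child.call_id] = TrioTruth(
                    child.call_id, "unknown", role, src.call_id, endpoint)
                return
            self.calls.remove(src)
        raise RuntimeError("could not place an 'unknown' trio event")

    def _plant_denovo(self, trio: Individual) -> None:
        parent_calls = self._parent_calls(trio)
        for _ in range(1000):
            cnv_type = self.draw_type()
            chrom, start, end = self.draw_interval(cnv_type)
            clash = any(c.chrom == chrom and min(end, c.end) >= max(start, c.start)
                        for c in parent_calls)
            if not clash:
                child = self.add_call(trio.individual_id, chrom, start, end,
                                      self.draw_cn(cnv_type), cnv_type)
                self.truth.trio_classes[child.call_id] = TrioTruth(
                    child.call_id, "de_novo", "none", None, "none")
                return
        raise RuntimeError("could not place a de novo trio event")


def generate_cohort(
    config: SimConfig,
) -> tuple[list[Individual], list[CnvCall], list[GeneFeature], TruthRecord]:
    """Generate (individuals, calls, genes, truth) for a synthetic cohort.

    Fully deterministic under ``config.seed``: the same configuration
    regenerates identical output, byte for byte once written.
    """
    b = _CohortBuilder(config)
    founders, probands = b.build_individuals()
    genes = b.build_genes()
    b.plant_hotspots(founders)
    b.plant_background(founders, genes)
    b.plant_trio_events(probands)
    individuals = founders + probands
    return individuals, b.calls, genes, b.truth


def generate_trio_truth_table(truth: TruthRecord) -> pd.DataFrame:
    """TSV-ready truth table: one row per planted proband event."""
    rows = [{
        "call_id": t.call_id,
        "class": t.label,
        "parental_origin": t.origin,
        "parent_call_id": t.parent_call_id or "",
        "matched_endpoint": t.matched_endpoint,
    } for t in sorted(truth.trio_classes.values(), key=lambda t: t.call_id)]
    return pd.DataFrame(rows, columns=["call_id", "class", "parental_origin",
                                       "parent_call_id", "matched_endpoint"])
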