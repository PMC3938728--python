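"""Core data model for CNV burden analysis on miRNA genes.

Coordinates are 1-based, fully closed intervals throughout the package:
a call spanning positions 100..200 has ``start=100, end=200`` and size
``end - start + 1 = 101`` bp. BED input/output converts at the boundary.

Copy-number (CN) states are integer calls in {0, 1, 2, 3, 4}. Whether a
state is a deletion or a duplication depends on the expected ploidy of the
chromosome for the carrier's sex (2 on autosomes; X: 1 in males, 2 in
females; Y: 1 in males, 0 in females).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_CN_STATES = frozenset({0, 1, 2, 3, 4})
SEXES = ("male", "female", "unknown")


class FormatError(ValueError):
    """An input file does not match the expected tabular format."""


class ConfigError(ValueError):
    """A parameter or configuration value is outside its valid domain."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name: strip a leading ``chr`` and uppercase X/Y.

    >>> normalize_chrom("chr22")
    '22'
    >>> normalize_chrom("chrx")
    'X'
    """
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.lower() in ("x", "y", "mt", "m"):
        name = name.upper()
    return name


def expected_ploidy(chrom: str, sex: str) -> int:
    """Expected copy number for a chromosome given carrier sex.

    Autosomes are diploid. On X the expectation is 1 for males and 2
    otherwise; on Y it is 1 for males and 0 for females. Unknown sex falls
    back to 2 on X and 1 on Y (the call is then typed conservatively).
    """
    if chrom == "X":
        return 1 if sex == "male" else 2
    if chrom == "Y":
        return 0 if sex == "female" else 1
    return 2


@dataclass(frozen=True, slots=True)
class CnvCall:
    """One CNV event in one individual (1-based closed interval)."""

    individual_id: str
    chrom: str
    start: int
    end: int
    cn_state: int
    n_probes: int = 0  # 0 = unknown
    call_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.cn_state not in VALID_CN_STATES:
            raise ValueError(f"cn_state must be in {{0..4}}, got {self.cn_state}")
        if self.n_probes < 0:
            raise ValueError(f"n_probes must be >= 0, got {self.n_probes}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class GeneFeature:
    """A miRNA gene locus (1-based closed interval)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"strand must be +, - or unknown, got {self.strand!r}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class Individual:
    """Cohort member with population label, sex and parental links."""

    individual_id: str
    population: str
    sex: str = "unknown"
    father_id: Optional[str] = None
    mother_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")

    @property
    def has_both_parents(self) -> bool:
        return self.father_id is not None and self.mother_id is not None


@dataclass(frozen=True, slots=True)
class AnnotatedCall:
    """A QC-passed CNV call intersected with the miRNA gene annotation.

    ``genes`` lists every miRNA gene overlapping the call by at least the
    configured number of bases; ``is_mirna_cnv`` is true iff that list is
    non-empty. ``cnv_type`` compares the CN state against the sex-aware
    expected ploidy: "duplication" above, "deletion" below, "none" at it.
    """

    call: CnvCall
    genes: tuple[str, ...] = ()
    cnv_type: str = "none"
    qc_pass: bool = True
    reference_validated: Optional[bool] = None  # None = not assessed

    @property
    def is_mirna_cnv(self) -> bool:
        return len(self.genes) > 0

    @property
    def call_id(self) -> str:
        return self.call.call_id

    @property
    def individual_id(self) -> str:
        return self.call.individual_id
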