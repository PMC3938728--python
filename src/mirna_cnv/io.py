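"""Readers and writers for CNV call tables, gene annotation and manifests.

All tabular input and output is tab-separated UTF-8 with one header row.
Internal coordinates are 1-based closed; BED input (0-based half-open) is
converted at the boundary, so a BED line ``22 23040000 23050000 MIR650``
becomes the closed interval 23040001..23050000.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    VALID_CN_STATES,
    AnnotatedCall,
    CnvCall,
    FormatError,
    GeneFeature,
    Individual,
    normalize_chrom,
)

CNV_REQUIRED_COLUMNS = ("individual_id", "chrom", "start", "end", "cn_state")
MANIFEST_COLUMNS = ("family", "individual", "father", "mother", "sex", "population")


@dataclass(frozen=True)
class RejectedRow:
    """A row that failed type or domain coercion, with the reason."""

    line_no: int
    reason: str
    raw: tuple


def read_cnv_table(
    path: str | os.PathLike,
    dialect: Optional[Mapping[str, str]] = None,
) -> tuple[list[CnvCall], list[RejectedRow]]:
    """Read a per-individual CNV call table.

    Parameters
    ----------
    path
        TSV file with required columns ``individual_id, chrom, start, end,
        cn_state`` and optional ``n_probes`` and ``call_id``.
    dialect
        Optional mapping from internal column names to the file's header
        names, for tables exported under caller-specific headers.

    Returns
    -------
    (calls, rejected)
        Parsed calls, and a report of rows that failed coercion (bad
        integer fields, CN state outside 0–4, end < start). Rows are never
        silently dropped. Missing ``call_id`` values are assigned
        sequentially as ``c000001`` etc.
    """
    dialect = dict(dialect or {})
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty CNV table: {path}", stacklevel=2)
        return [], []
    rename = {v: k for k, v in dialect.items()}
    df = df.rename(columns=rename)
    for col in CNV_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"CNV table {path} is missing required column {col!r}")

    calls: list[CnvCall] = []
    rejected: list[RejectedRow] = []
    seen_ids: set[str] = set()
    counter = 0
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            start = int(rec["start"])
            end = int(rec["end"])
            cn = int(rec["cn_state"])
            n_probes = int(rec.get("n_probes") or 0)
        except (TypeError, ValueError) as exc:
            rejected.append(RejectedRow(line_no, f"type coercion failed: {exc}", tuple(row)))
            continue
        call_id = str(rec.get("call_id") or "")
        if not call_id:
            counter += 1
            call_id = f"c{counter:06d}"
        if call_id in seen_ids:
            rejected.append(RejectedRow(line_no, f"duplicate call_id {call_id!r}", tuple(row)))
            continue
        try:
            call = CnvCall(
                individual_id=str(rec["individual_id"]),
                chrom=normalize_chrom(rec["chrom"]),
                start=start,
                end=end,
                cn_state=cn,
                n_probes=n_probes,
                call_id=call_id,
            )
        except ValueError as exc:
            rejected.append(RejectedRow(line_no, str(exc), tuple(row)))
            continue
        seen_ids.add(call_id)
        calls.append(call)
    return calls, rejected


def write_cnv_table(calls: Iterable[CnvCall], path: str | os.PathLike) -> None:
    """Write calls as a TSV readable back by :func:`read_cnv_table`."""
    rows = [
        {
            "individual_id": c.individual_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "cn_state": c.cn_state,
            "n_probes": c.n_probes,
            "call_id": c.call_id,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=["individual_id", "chrom", "start", "end",
                                     "cn_state", "n_probes", "call_id"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _gene_from_bed_fields(fields: Sequence[str], line_no: int) -> GeneFeature:
    if len(fields) < 4 or not fields[3].strip():
        raise FormatError(f"BED line {line_no}: name column (4th) is required")
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "unknown"
    return GeneFeature(
        gene_id=fields[3].strip(),
        chrom=normalize_chrom(fields[0]),
        start=int(fields[1]) + 1,  # BED is 0-based half-open
        end=int(fields[2]),
        strand=strand,
    )


def _read_bed_genes(path: str | os.PathLike) -> list[GeneFeature]:
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            genes.append(_gene_from_bed_fields(line.split("\t"), line_no))
    return genes


_GFF_MIRNA_TYPES = {"miRNA", "miRNA_gene", "miRNA_primary_transcript", "pre_miRNA"}


def _read_gff3_genes(path: str | os.PathLike) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.all_features():
        biotype = (feat.attributes.get("gene_biotype") or feat.attributes.get("biotype") or [""])[0]
        if feat.featuretype not in _GFF_MIRNA_TYPES and biotype != "miRNA":
            continue
        name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [feat.id])[0]
        genes.append(GeneFeature(
            gene_id=name,
            chrom=normalize_chrom(feat.seqid),
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in ("+", "-") else "unknown",
        ))
    return genes


def read_gene_annotation(path: str | os.PathLike, format: Optional[str] = None) -> list[GeneFeature]:
    """Read a miRNA gene annotation from GFF3 or BED.

    GFF3 records are filtered to miRNA-typed features (``miRNA``,
    ``miRNA_primary_transcript`` or a ``miRNA`` biotype attribute); BED is
    taken as-is and its 4th (name) column is required. Records duplicated
    on the same locus under the same identifier are collapsed to one.
    """
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "bed" if suffix == ".bed" else "gff3"
    if format == "bed":
        genes = _read_bed_genes(path)
    elif format == "gff3":
        genes = _read_gff3_genes(path)
    else:
        raise FormatError(f"unknown gene annotation format {format!r}")
    out: list[GeneFeature] = []
    seen = set()
    for g in genes:
        key = (g.gene_id, g.chrom, g.start, g.end)
        if key in seen:
            continue
        seen.add(key)
        out.append(g)
    return out


def write_gene_bed(genes: Iterable[GeneFeature], path: str | os.PathLike) -> None:
    """Write gene features as 6-column BED (coordinates converted back)."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{strand}\n")


_SEX_CODES = {"1": "male", "2": "female"}


def read_manifest(path: str | os.PathLike) -> list[Individual]:
    """Read a PED-like cohort manifest.

    Expected columns: ``family, individual, father, mother, sex,
    population`` (header row required). Sex codes follow PED: 1 = male,
    2 = female, anything else = unknown; a parent id of ``0`` means none.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty manifest: {path}", stacklevel=2)
        return []
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"manifest {path} is missing required column {col!r}")
    individuals: list[Individual] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        iid = str(rec["individual"])
        if iid in seen:
            raise FormatError(f"duplicate individual_id {iid!r} in manifest {path}")
        seen.add(iid)
        father = str(rec["father"]) or "0"
        mother = str(rec["mother"]) or "0"
        individuals.append(Individual(
            individual_id=iid,
            population=str(rec["population"]),
            sex=_SEX_CODES.get(str(rec["sex"]).strip(), "unknown"),
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
        ))
    return individuals


def write_manifest(individuals: Iterable[Individual], path: str | os.PathLike) -> None:
    sex_back = {"male": "1", "female": "2", "unknown": "0"}
    rows = [
        {
            "family": ind.individual_id.rsplit("_", 1)[0],
            "individual": ind.individual_id,
            "father": ind.father_id or "0",
            "mother": ind.mother_id or "0",
            "sex": sex_back[ind.sex],
            "population": ind.population,
        }
        for ind in individuals
    ]
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def write_tables(results: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike) -> list[Path]:
    """Write a mapping of named DataFrames as ``<name>.tsv`` files.

    Output is deterministic: column order as given, one header row, UTF-8,
    tab-separated, ``\\n`` line endings; re-running with identical inputs
    produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        path = out_dir / f"{name}.tsv"
        results[name].to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
    return written


def circos_gene_sharing(
    annotated: Sequence[AnnotatedCall],
    genes: Sequence[GeneFeature],
    individuals: Sequence[Individual],
) -> pd.DataFrame:
    """Gene-sharing table (chrom, start, end, population, count) for plotting.

    One row per (miRNA gene locus, population) giving the number of gene
    hits that population contributes at that locus — a plain-table stand-in
    for a Circos link track.
    """
    pop_of = {ind.individual_id: ind.population for ind in individuals}
    locus = {g.gene_id: g for g in genes}
    counts: dict[tuple[str, int, int, str], int] = {}
    for ac in annotated:
        pop = pop_of.get(ac.individual_id, "unknown")
        for gid in ac.genes:
            g = locus.get(gid)
            if g is None:
                continue
            key = (g.chrom, g.start, g.end, pop)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"chrom": c, "start": s, "end": e, "population": p, "count": n}
        for (c, s, e, p), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "population", "count"])
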