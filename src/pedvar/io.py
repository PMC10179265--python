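"""File readers and writers.

Formats handled: 6(+2)-column whitespace PED, VCFv4.2 (GT only), and
header-bearing TSV files for annotations, frequency tables, gene panels,
and interaction edge lists. VCF parsing is delegated to cyvcf2; the
writers emit plain text so every artifact round-trips through version
control.
"""

from __future__ import annotations

import json
import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from cyvcf2 import VCF

from .types import (
    AnnotationBundle,
    AnnotationTable,
    FilterTrace,
    GenotypeCall,
    Individual,
    InteractionGraph,
    Pedigree,
    PedigreeError,
    Phenotype,
    Sex,
    VariantRecord,
    variant_key,
)

__all__ = [
    "read_ped",
    "write_ped",
    "read_cohort_vcf",
    "write_vcf",
    "read_annotation_table",
    "write_annotation_table",
    "read_frequency_table",
    "write_frequency_table",
    "read_panel",
    "write_panel",
    "read_edges",
    "write_edges",
    "write_report",
]

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO_CODES = {"2": Phenotype.AFFECTED, "1": Phenotype.UNAFFECTED}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_OUT = {
    Phenotype.AFFECTED: "2",
    Phenotype.UNAFFECTED: "1",
    Phenotype.UNKNOWN: "0",
}

_MISSING_TOKENS = {"", ".", "-", "NA", "NaN", "nan", "None"}


def read_ped(path: str) -> Pedigree:
    """Read a whitespace-delimited PED file.

    Columns: family (ignored), id, father, mother, sex, phenotype,
    optionally sequenced flag (0/1) and sampled flag (0/1). Parent code
    "0" means unknown; phenotype code 0 (or -9) maps to *unknown* —
    individuals with a benign/uninformative status are coded this way so
    they contribute no segregation evidence.
    """
    individuals: List[Individual] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}:{line_no}: expected >=6 columns, got {len(fields)}"
                )
            _fam, iid, father, mother, sex, pheno = fields[:6]
            sequenced = len(fields) > 6 and fields[6] == "1"
            sampled = fields[7] == "1" if len(fields) > 7 else sequenced
            individuals.append(
                Individual(
                    id=iid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                    phenotype=_PHENO_CODES.get(pheno, Phenotype.UNKNOWN),
                    sequenced=sequenced,
                    sampled=sampled,
                )
            )
    if not individuals:
        raise PedigreeError("no individuals")
    return Pedigree(individuals)


def write_ped(pedigree: Pedigree, path: str, family_id: str = "FAM1") -> None:
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write(
                "\t".join(
                    [
                        family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_OUT[ind.sex],
                        _PHENO_OUT[ind.phenotype],
                        "1" if ind.sequenced else "0",
                        "1" if ind.sampled else "0",
                    ]
                )
                + "\n"
            )


def _normalize(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Minimal representation: trim shared suffix, then shared prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def read_cohort_vcf(path: str, pedigree: Optional[Pedigree] = None) -> List[VariantRecord]:
    """Read a multi-sample VCF into biallelic, normalized VariantRecords.

    Multi-allelic sites are split into one record per alternate allele,
    with genotypes recoded relative to that allele. Records are
    deduplicated by (chrom, pos, ref, alt) and sorted by (chrom, pos).
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    if pedigree is not None:
        unknown = [s for s in samples if s not in pedigree]
        if unknown:
            raise ValueError(
                f"VCF samples absent from pedigree: {', '.join(sorted(unknown))}"
            )
    records: Dict[tuple, VariantRecord] = {}
    for v in vcf:
        gts = v.genotypes  # [[a, b, phased], ...]
        gene = _info_str(v, "GENE")
        consequence = _info_str(v, "CSQ")
        for alt_index, alt in enumerate(v.ALT, start=1):
            if alt in (None, ".", "*"):
                continue
            pos, ref, alt_norm = _normalize(v.POS, v.REF, alt)
            genotypes = {}
            for sample, gt in zip(samples, gts):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    call = GenotypeCall.MISSING
                else:
                    n_alt = int(a == alt_index) + int(b == alt_index)
                    call = (GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_ALT)[n_alt]
                genotypes[sample] = call
            rec = VariantRecord(
                chrom=v.CHROM,
                pos=pos,
                ref=ref,
                alt=alt_norm,
                gene=gene,
                consequence=consequence,
                genotypes=genotypes,
            )
            records.setdefault(rec.key, rec)
    return sorted(records.values(), key=lambda r: (r.chrom, r.pos, r.ref, r.alt))


def _info_str(variant, tag: str) -> str:
    value = variant.INFO.get(tag)
    if value is None:
        return ""
    if isinstance(value, bytes):
        return value.decode()
    return str(value)


def write_vcf(records: Sequence[VariantRecord], sample_ids: Sequence[str], path: str) -> None:
    """Write records as an uncompressed VCFv4.2 with a GT FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for rec in records:
            if rec.chrom not in chroms:
                chroms.append(rec.chrom)
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            info_parts = []
            if rec.gene:
                info_parts.append(f"GENE={rec.gene}")
            if rec.consequence:
                info_parts.append(f"CSQ={rec.consequence}")
            info = ";".join(info_parts) or "."
            gts = "\t".join(rec.genotype(s).to_vcf() for s in sample_ids)
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{info}\tGT\t{gts}\n"
            )


def _parse_optional_float(token) -> Optional[float]:
    if token is None:
        return None
    text = str(token).strip()
    if text in _MISSING_TOKENS:
        return None
    return float(text)


def read_annotation_table(path: str) -> AnnotationTable:
    """Read a wide per-variant annotation TSV.

    Expected columns: chrom, pos, ref, alt, then any of gene, consequence,
    expression_tpm, ``freq_<db>`` and ``score_<name>`` columns. Empty or
    "."/"-" cells are recorded as absent (not zero).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    freq_cols = [c for c in df.columns if c.startswith("freq_")]
    score_cols = [c for c in df.columns if c.startswith("score_")]
    table = AnnotationTable(
        dbs={c[len("freq_"):] for c in freq_cols},
        score_names={c[len("score_"):] for c in score_cols},
    )
    for _, row in df.iterrows():
        key = variant_key(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        frequencies = {}
        for col in freq_cols:
            value = _parse_optional_float(row[col])
            if value is not None:
                frequencies[col[len("freq_"):]] = value
        scores = {}
        for col in score_cols:
            value = _parse_optional_float(row[col])
            if value is not None:
                scores[col[len("score_"):]] = value
        tpm = _parse_optional_float(row["expression_tpm"]) if "expression_tpm" in df.columns else None
        table.bundles[key] = AnnotationBundle(
            frequencies=frequencies, scores=scores, expression_tpm=tpm
        )
    return table


def write_annotation_table(table: AnnotationTable, path: str) -> None:
    dbs = sorted(table.dbs)
    scores = sorted(table.score_names)
    columns = ["chrom", "pos", "ref", "alt"] + [f"freq_{d}" for d in dbs] + [
        f"score_{s}" for s in scores
    ] + ["expression_tpm"]
    rows = []
    for key in sorted(table.bundles):
        bundle = table.bundles[key]
        row = {
            "chrom": key[0],
            "pos": key[1],
            "ref": key[2],
            "alt": key[3],
            "expression_tpm": "" if bundle.expression_tpm is None else repr(bundle.expression_tpm),
        }
        for db in dbs:
            value = bundle.frequencies.get(db)
            row[f"freq_{db}"] = "" if value is None else repr(value)
        for name in scores:
            value = bundle.scores.get(name)
            row[f"score_{name}"] = "" if value is None else repr(value)
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_frequency_table(path: str) -> Dict[str, Dict[tuple, float]]:
    """Read a long-format frequency TSV (chrom, pos, ref, alt, db, freq).

    Returns a db-keyed map of variant-key -> allele frequency. Raises on
    frequencies outside [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: Dict[str, Dict[tuple, float]] = {}
    for _, row in df.iterrows():
        freq = float(row["freq"])
        if not (0.0 <= freq <= 1.0):
            raise ValueError(
                f"frequency outside [0,1]: {freq} at {row['chrom']}:{row['pos']}"
            )
        key = variant_key(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        out.setdefault(row["db"], {})[key] = freq
    return out


def write_frequency_table(freqs: Dict[str, Dict[tuple, float]], path: str) -> None:
    rows = []
    for db in sorted(freqs):
        for key in sorted(freqs[db]):
            rows.append(
                {
                    "chrom": key[0],
                    "pos": key[1],
                    "ref": key[2],
                    "alt": key[3],
                    "db": db,
                    "freq": repr(freqs[db][key]),
                }
            )
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "db", "freq"]).to_csv(
        path, sep="\t", index=False
    )


def read_panel(path: str) -> set:
    """Read a one-gene-per-line panel file into a set."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def write_panel(genes: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for gene in sorted(genes):
            fh.write(gene + "\n")


def read_edges(path: str) -> InteractionGraph:
    """Read a TSV edge list (gene_a, gene_b, evidence) into a graph."""
    graph = InteractionGraph()
    with open(path) as fh:
        header = fh.readline()
        if header and not header.lower().startswith("gene_a"):
            # header-less file: treat the first line as data
            _add_edge_line(graph, header)
        for line in fh:
            _add_edge_line(graph, line)
    return graph


def _add_edge_line(graph: InteractionGraph, line: str) -> None:
    line = line.strip()
    if not line or line.startswith("#"):
        return
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 2:
        raise ValueError(f"edge line needs >=2 columns: {line!r}")
    evidence = fields[2] if len(fields) > 2 else ""
    graph.add_edge(fields[0], fields[1], evidence)


def write_edges(graph: InteractionGraph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tevidence\n")
        for a, b, evidence in graph.edges:
            fh.write(f"{a}\t{b}\t{evidence}\n")


def write_report(
    records: Sequence[VariantRecord],
    trace: Optional[FilterTrace],
    path: str,
    extra_columns: Optional[Dict[tuple, Dict[str, str]]] = None,
) -> None:
    """Write a TSV report: one row per surviving variant plus the filter
    trace as a commented block. ``extra_columns`` maps variant key ->
    {column: value} for e.g. tier, segregation, or path annotations."""
    extra_names: List[str] = []
    if extra_columns:
        seen = set()
        for cols in extra_columns.values():
            for name in cols:
                if name not in seen:
                    seen.add(name)
                    extra_names.append(name)
    with open(path, "w") as fh:
        header = ["chrom", "pos", "ref", "alt", "gene", "consequence"] + extra_names
        fh.write("\t".join(header) + "\n")
        for rec in records:
            row = [rec.chrom, str(rec.pos), rec.ref, rec.alt, rec.gene, rec.consequence]
            extras = (extra_columns or {}).get(rec.key, {})
            row += [str(extras.get(name, "")) for name in extra_names]
            fh.write("\t".join(row) + "\n")
        if trace is not None:
            fh.write("#\n# filter_trace\n# stage\tcount_in\tcount_out\n")
            for name, count_in, count_out in trace.as_rows():
                fh.write(f"# {name}\t{count_in}\t{count_out}\n")


def write_trace_json(trace: FilterTrace, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"stages": trace.to_dict()}, fh, indent=2)
        fh.write("\n")
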