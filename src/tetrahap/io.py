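"""Readers and writers for the pipeline's plain-text formats.

All tabular formats are UTF-8 TSV with a header row, ``NA`` for missing
values and deterministic column order, so outputs diff cleanly between
runs. Haplotype sequences travel as FASTA with record ids
``amplicon|haplotype``; trees as Newick; statistics and manifests as JSON.
A minimal VCF export (dosage in a ``DS``-style per-sample field) is
provided for interoperability; VCF is never the internal model.
"""

from __future__ import annotations

import dataclasses
import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Amplicon,
    DosageMatrix,
    HaplotypePanel,
    PedigreeRecord,
    PedigreeTable,
    TagRule,
    TagRuleSet,
    TetraGenotype,
    parse_variant_id,
)

__all__ = [
    "write_fasta_panel",
    "read_fasta_panel",
    "write_panel_table",
    "read_panel_table",
    "write_dosage",
    "read_dosage",
    "write_genotypes",
    "read_genotypes",
    "write_pedigree",
    "read_pedigree",
    "write_phenotypes",
    "read_phenotypes",
    "write_rules",
    "read_rules",
    "write_clusters",
    "write_newick",
    "write_json",
    "export_vcf",
    "to_jsonable",
]

NA = "NA"


# ---------------------------------------------------------------- FASTA ----


def write_fasta_panel(panel: HaplotypePanel, path) -> None:
    """One record per haplotype per amplicon, id ``amplicon|haplotype``."""
    records = [
        SeqRecord(
            Seq(panel.sequences[h][amp.id]), id=f"{amp.id}|{h}", description=""
        )
        for amp in panel.amplicons
        for h in panel.names
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_panel(
    path,
    frequencies: dict[str, float] | None = None,
    grouping: dict[str, str] | None = None,
) -> HaplotypePanel:
    seqs: dict[str, dict[str, str]] = {}
    amp_lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        amp, hap = rec.id.split("|", 1)
        seqs.setdefault(hap, {})[amp] = str(rec.seq)
        amp_lengths.setdefault(amp, len(rec.seq))
    amps = [Amplicon(a, l) for a, l in amp_lengths.items()]
    if frequencies is None:
        frequencies = {h: 1.0 / len(seqs) for h in seqs}
    return HaplotypePanel(
        amplicons=amps,
        sequences=seqs,
        frequencies=frequencies,
        grouping=grouping or {},
    )


def write_panel_table(panel: HaplotypePanel, path) -> None:
    df = pd.DataFrame(
        {
            "haplotype": panel.names,
            "frequency": [panel.frequencies.get(h, np.nan) for h in panel.names],
            "group": [panel.group_of(h) for h in panel.names],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_panel_table(path) -> tuple[dict[str, float], dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"haplotype": str, "group": str})
    freqs = dict(zip(df["haplotype"], df["frequency"].astype(float)))
    grouping = {
        h: g for h, g in zip(df["haplotype"], df["group"]) if g != h and pd.notna(g)
    }
    return freqs, grouping


# --------------------------------------------------------------- dosages ----


def write_dosage(matrix: DosageMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "variant"
    out.to_csv(path, sep="\t", na_rep=NA, float_format="%.6g")


def read_dosage(path, amplicon_id: str | None = None) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", index_col="variant", na_values=[NA])
    if amplicon_id is None:
        amplicon_id = parse_variant_id(df.index[0])[0]
    return DosageMatrix(amplicon_id=amplicon_id, values=df.astype(float))


# ------------------------------------------------------------- genotypes ----


def write_genotypes(genotypes: list[TetraGenotype], path) -> None:
    rows = []
    for g in genotypes:
        alleles = list(g.alleles) + [NA] * (4 - len(g.alleles))
        rows.append(
            {
                "id": g.individual,
                **{f"allele{i + 1}": a for i, a in enumerate(alleles[:4])},
                "class": g.gallais if g.alleles else NA,
                "status": g.status,
                "support": ";".join(g.support) if g.support else NA,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> list[TetraGenotype]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        alleles = tuple(
            row[f"allele{i}"]
            for i in range(1, 5)
            if f"allele{i}" in row and row[f"allele{i}"] not in ("", NA)
        )
        support = (
            tuple(row["support"].split(";"))
            if row.get("support", NA) not in ("", NA)
            else ()
        )
        out.append(
            TetraGenotype(
                individual=row["id"],
                alleles=alleles,
                status=row.get("status", "resolved"),
                support=support,
            )
        )
    return out


# -------------------------------------------------------------- pedigree ----


def write_pedigree(pedigree: PedigreeTable, path) -> None:
    """``id<TAB>mother<TAB>father`` with ``0`` for an unknown parent."""
    rows = [
        {
            "id": r.individual,
            "mother": r.mother or "0",
            "father": r.father or "0",
        }
        for r in pedigree.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    gen: dict[str, int] = {}
    records = []
    for _, row in df.iterrows():
        mother = None if row["mother"] in ("0", "", NA) else row["mother"]
        father = None if row["father"] in ("0", "", NA) else row["father"]
        g = 1 + max(
            (gen.get(p, 0) for p in (mother, father) if p is not None), default=-1
        )
        gen[row["id"]] = g
        records.append(PedigreeRecord(row["id"], mother, father, g))
    return PedigreeTable(records)


# ------------------------------------------------------------ phenotypes ----


def write_phenotypes(phenotypes: pd.Series, path) -> None:
    df = phenotypes.rename("value").rename_axis("id").reset_index()
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")


def read_phenotypes(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    return pd.Series(
        df["value"].astype(float).to_numpy(), index=df["id"].astype(str), name="value"
    )


# ----------------------------------------------------------------- rules ----


def write_rules(rulesets: dict[str, TagRuleSet] | TagRuleSet, path) -> None:
    """Columns: haplotype (unit), amplicon, base_variant, subtract_list
    (semicolon-separated), members (semicolon-separated for identical-in-
    state units). Row order is the rule evaluation order."""
    if isinstance(rulesets, TagRuleSet):
        rulesets = {rulesets.amplicon_id: rulesets}
    rows = []
    for amp, rs in rulesets.items():
        for rule in rs.rules:
            rows.append(
                {
                    "haplotype": rule.target,
                    "amplicon": amp,
                    "base_variant": rule.variant or ".",
                    "subtract_list": ";".join(rule.subtract),
                    "members": ";".join(rs.members.get(rule.target, (rule.target,))),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rules(path) -> dict[str, TagRuleSet]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, TagRuleSet] = {}
    for amp, sub in df.groupby("amplicon", sort=False):
        rules = []
        members = {}
        for _, row in sub.iterrows():
            subtract = tuple(s for s in row["subtract_list"].split(";") if s)
            variant = None if row["base_variant"] == "." else row["base_variant"]
            rules.append(TagRule(row["haplotype"], variant, subtract))
            mem = row.get("members", "")
            members[row["haplotype"]] = (
                tuple(mem.split(";")) if mem else (row["haplotype"],)
            )
        out[amp] = TagRuleSet(
            amplicon_id=amp, incidence=pd.DataFrame(), rules=rules, members=members
        )
    return out


def write_clusters(clusters: list[list[str]], path) -> None:
    rows = [
        {"cluster": i + 1, "variant": v}
        for i, cluster in enumerate(clusters)
        for v in cluster
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ misc ----


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick.rstrip("\n") + "\n", encoding="utf-8")


def to_jsonable(obj):
    """Recursively convert dataclasses / numpy / pandas values to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [to_jsonable(v) for v in sorted(obj)] if isinstance(
            obj, (set, frozenset)
        ) else [to_jsonable(v) for v in obj]
    if isinstance(obj, Fraction):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {
            str(idx): {str(c): to_jsonable(v) for c, v in row.items()}
            for idx, row in obj.iterrows()
        }
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(to_jsonable(obj), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def export_vcf(
    matrices: dict[str, DosageMatrix] | list[DosageMatrix],
    path,
    reference_base: str = "N",
) -> None:
    """Minimal VCF 4.2 export of variant sites with dosages in a DS field.

    Export-only convenience: CHROM is the amplicon id, POS the 1-based
    amplicon position, ALT the variant base; genotype calls are omitted.
    """
    if isinstance(matrices, list):
        matrices = {m.amplicon_id: m for m in matrices}
    individuals = next(iter(matrices.values())).individuals
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(individuals),
    ]
    for amp in sorted(matrices):
        mat = matrices[amp]
        for vid in mat.variants:
            _, pos, base = parse_variant_id(vid)
            vals = mat.values.loc[vid]
            ds = "\t".join(
                "." if pd.isna(vals[i]) else f"{vals[i]:.3f}" for i in individuals
            )
            lines.append(
                f"{amp}\t{pos}\t{vid}\t{reference_base}\t{base}\t.\t.\t.\tDS\t{ds}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
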