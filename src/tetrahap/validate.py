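"""Schema and cross-reference validation for pipeline input files.

Report-only: every problem becomes a line-numbered message; nothing raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["ValidationMessage", "ValidationReport", "validate_inputs"]


@dataclass(frozen=True)
class ValidationMessage:
    severity: str  # warning | error
    file: str
    line: int | None
    message: str

    def __str__(self) -> str:
        loc = f"{self.file}:{self.line}" if self.line else self.file
        return f"{self.severity.upper()} {loc}: {self.message}"


@dataclass
class ValidationReport:
    messages: list[ValidationMessage] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.messages

    def add(self, severity, file, line, message) -> None:
        self.messages.append(ValidationMessage(severity, str(file), line, message))


def _check_dosage(path, report: ValidationReport) -> None:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "variant" not in df.columns:
        report.add("error", path, 1, "missing 'variant' header column")
        return
    dup = df["variant"][df["variant"].duplicated()]
    for idx, v in dup.items():
        report.add("error", path, idx + 2, f"duplicate variant id {v!r}")
    values = df.drop(columns=["variant"])
    for row_i, (_, row) in enumerate(values.iterrows()):
        bad = row[(row < 0) | (row > 4)]
        for col, val in bad.items():
            report.add(
                "warning",
                path,
                row_i + 2,
                f"dosage {val} for {col!r} outside [0, 4]",
            )


def _ids_of_genotypes(path) -> set[str]:
    return set(pd.read_csv(path, sep="\t", dtype=str)["id"])


def validate_inputs(
    dosage: list | None = None,
    genotypes=None,
    phenotypes=None,
    pedigree=None,
) -> ValidationReport:
    """Validate whichever input files are given; cross-reference ids.

    Checks column names, dosage/phenotype value ranges, duplicate ids, and
    that phenotype and pedigree ids refer to genotyped individuals.
    """
    report = ValidationReport()
    for p in dosage or []:
        _check_dosage(p, report)
    geno_ids: set[str] | None = None
    if genotypes is not None:
        df = pd.read_csv(genotypes, sep="\t", dtype=str)
        missing = {"id", "status"} - set(df.columns)
        if missing:
            report.add(
                "error", genotypes, 1, f"missing genotype columns {sorted(missing)}"
            )
        else:
            geno_ids = set(df["id"])
            for idx, v in df["id"][df["id"].duplicated()].items():
                report.add("error", genotypes, idx + 2, f"duplicate id {v!r}")
    if phenotypes is not None:
        df = pd.read_csv(phenotypes, sep="\t", na_values=["NA"])
        if not {"id", "value"} <= set(df.columns):
            report.add("error", phenotypes, 1, "expected columns 'id' and 'value'")
        else:
            for idx, val in df["value"].items():
                if pd.notna(val) and val <= 0:
                    report.add(
                        "warning",
                        phenotypes,
                        idx + 2,
                        f"non-positive phenotype value {val}",
                    )
            if geno_ids is not None:
                for idx, i in df["id"].astype(str).items():
                    if i not in geno_ids:
                        report.add(
                            "warning",
                            phenotypes,
                            idx + 2,
                            f"phenotype id {i!r} absent from genotypes",
                        )
    if pedigree is not None:
        df = pd.read_csv(pedigree, sep="\t", dtype=str, keep_default_na=False)
        if not {"id", "mother", "father"} <= set(df.columns):
            report.add(
                "error", pedigree, 1, "expected columns 'id', 'mother', 'father'"
            )
        else:
            known = set(df["id"])
            for idx, row in df.iterrows():
                for parent in (row["mother"], row["father"]):
                    if parent not in ("0", "") and parent not in known:
                        report.add(
                            "warning",
                            pedigree,
                            idx + 2,
                            f"parent {parent!r} not itself a pedigree entry",
                        )
    return report
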