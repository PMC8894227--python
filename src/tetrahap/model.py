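"""Core domain types shared across the tetrahap pipeline.

The central objects are a panel of named gene haplotypes (aligned amplicon
sequences with population frequencies), per-individual allele-copy-number
("dosage") matrices, tag-SNP rule sets mapping variant dosages to haplotype
copy numbers, and four-allele tetraploid genotypes with their Gallais class.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Amplicon",
    "HaplotypePanel",
    "DosageMatrix",
    "TagRule",
    "TagRuleSet",
    "TetraGenotype",
    "PedigreeRecord",
    "PedigreeTable",
    "gallais_class",
    "GALLAIS_CLASSES",
    "variant_id",
    "parse_variant_id",
]

#: Gallais nomenclature for tetraploid genotype classes, keyed by the sorted
#: multiplicity pattern of the 4-allele multiset.
GALLAIS_CLASSES = {
    (4,): "monogenic",
    (1, 3): "digenic-simplex",
    (2, 2): "digenic-duplex",
    (1, 1, 2): "trigenic",
    (1, 1, 1, 1): "tetragenic",
}

#: Diploid analogues, used for validation populations.
DIPLOID_CLASSES = {(2,): "homozygous", (1, 1): "heterozygous"}


def gallais_class(alleles) -> str:
    """Genotype class from the multiplicity pattern of an allele multiset.

    Tetraploid multisets map to the five Gallais classes (monogenic aaaa,
    digenic-simplex aaab, digenic-duplex aabb, trigenic aabc, tetragenic
    abcd); diploid multisets map to homozygous/heterozygous.
    """
    alleles = tuple(alleles)
    pattern = tuple(sorted(Counter(alleles).values()))
    if len(alleles) == 4:
        return GALLAIS_CLASSES[pattern]
    if len(alleles) == 2:
        return DIPLOID_CLASSES[pattern]
    raise ValueError(f"unsupported ploidy {len(alleles)}")


def variant_id(amplicon: str, pos: int, base: str) -> str:
    """Canonical variant-allele id ``amplicon:pos:base`` (1-based position)."""
    return f"{amplicon}:{pos}:{base}"


def parse_variant_id(vid: str) -> tuple[str, int, str]:
    amp, pos, base = vid.rsplit(":", 2)
    return amp, int(pos), base


@dataclass(frozen=True)
class Amplicon:
    """A sequenced gene region with its aligned length in bp."""

    id: str
    length: int


@dataclass
class HaplotypePanel:
    """Named haplotype sequences per amplicon with population frequencies.

    Parameters
    ----------
    amplicons
        Ordered amplicon definitions.
    sequences
        ``{haplotype: {amplicon_id: aligned DNA string}}``. Within an
        amplicon all sequences must have equal aligned length (gaps ``-``).
    frequencies
        ``{haplotype: proportion}``, non-negative, summing to 1 (tol 1e-9).
    grouping
        Optional map from haplotype name to a group label; haplotypes that
        cannot always be told apart (identical-in-state in one amplicon) are
        analysed at group resolution when needed.
    """

    amplicons: list[Amplicon]
    sequences: dict[str, dict[str, str]]
    frequencies: dict[str, float]
    grouping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.sequences)
        if len(set(names)) != len(names):
            raise ValueError("duplicate haplotype names")
        for amp in self.amplicons:
            for h, seqs in self.sequences.items():
                if len(seqs[amp.id]) != amp.length:
                    raise ValueError(
                        f"haplotype {h} length {len(seqs[amp.id])} != "
                        f"amplicon {amp.id} length {amp.length}"
                    )
        if self.frequencies:
            freqs = np.array([self.frequencies[h] for h in names], dtype=float)
            if (freqs < 0).any():
                raise ValueError("negative haplotype frequency")
            if abs(freqs.sum() - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {freqs.sum()}, not 1")

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def group_of(self, name: str) -> str:
        return self.grouping.get(name, name)

    def sequence(self, haplotype: str, amplicon_id: str) -> str:
        return self.sequences[haplotype][amplicon_id]

    def concatenated(self, haplotype: str) -> str:
        return "".join(self.sequences[haplotype][a.id] for a in self.amplicons)

    def incidence(self, amplicon_id: str) -> pd.DataFrame:
        """Binary haplotype × variant-allele incidence matrix for one amplicon.

        The reference base per aligned column is the (frequency-weighted when
        frequencies are given, else unweighted) majority base; every non-
        reference base at a polymorphic column yields one variant row, so
        multi-allelic sites get one column per alternate base. Gap characters
        are treated as ordinary states but never become variant alleles.
        """
        names = self.names
        amp = next(a for a in self.amplicons if a.id == amplicon_id)
        seqs = [self.sequences[h][amplicon_id] for h in names]
        weights = (
            [self.frequencies.get(h, 0.0) for h in names]
            if self.frequencies
            else [1.0] * len(names)
        )
        cols: dict[str, list[int]] = {}
        for pos in range(amp.length):
            bases = [s[pos] for s in seqs]
            if len(set(bases)) == 1:
                continue
            tally: dict[str, float] = {}
            for b, w in zip(bases, weights):
                tally[b] = tally.get(b, 0.0) + w + 1e-12
            ref = max(sorted(tally), key=lambda b: tally[b])
            for alt in sorted(set(bases) - {ref}):
                if alt == "-":
                    continue
                vid = variant_id(amplicon_id, pos + 1, alt)
                cols[vid] = [1 if b == alt else 0 for b in bases]
        return pd.DataFrame(cols, index=names, dtype=int)


@dataclass
class DosageMatrix:
    """Quantitatively scored variant-allele copy numbers for one amplicon.

    ``values`` is a variants × individuals DataFrame; entries are real
    numbers in [0, 4] (possibly noisy) or NaN for missing calls. Variant ids
    follow ``amplicon:pos:base`` with 1-based positions from amplicon start.
    """

    amplicon_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate variant ids: {dups}")

    @property
    def variants(self) -> list[str]:
        return list(self.values.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.values.columns)

    def positions(self) -> dict[str, int]:
        return {v: parse_variant_id(v)[1] for v in self.variants}


@dataclass(frozen=True)
class TagRule:
    """How one resolvable unit's copy number is read from dosages.

    ``copies(target) = dosage(variant) − Σ copies(subtract)``; an empty
    ``subtract`` means ``variant`` is a unique tag of the target.
    """

    target: str
    variant: str
    subtract: tuple[str, ...] = ()


@dataclass
class TagRuleSet:
    """Ordered tag/subtraction rules plus the incidence they derive from.

    ``rules`` are in a valid evaluation (topological) order: every unit
    subtracted by a rule is resolved by an earlier rule. ``members`` expands
    a unit label to its member haplotypes (singleton for a plain haplotype;
    several for an identical-in-state group within this amplicon).
    """

    amplicon_id: str
    incidence: pd.DataFrame
    rules: list[TagRule]
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rule in self.rules:
            missing = [h for h in rule.subtract if h not in seen]
            if missing:
                raise ValueError(
                    f"rule for {rule.target} subtracts unresolved units {missing}"
                )
            seen.add(rule.target)
        for unit in seen:
            self.members.setdefault(unit, (unit,))

    @property
    def targets(self) -> list[str]:
        return [r.target for r in self.rules]


@dataclass(frozen=True)
class TetraGenotype:
    """An individual's unordered allele multiset with bookkeeping.

    ``status`` is ``resolved`` (full allele-level call), ``grouped-only``
    (some alleles known only to group resolution), ``failed`` (dosages could
    not be reconciled) or ``unresolved``. ``support`` flags which amplicons
    contributed to the call.
    """

    individual: str
    alleles: tuple[str, ...]
    status: str = "resolved"
    support: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    @property
    def gallais(self) -> str:
        return gallais_class(self.alleles)

    def counts(self) -> Counter:
        return Counter(self.alleles)

    def grouped(self, grouping: dict[str, str]) -> "TetraGenotype":
        return replace(
            self, alleles=tuple(sorted(grouping.get(a, a) for a in self.alleles))
        )

    def pairs(self):
        return itertools.combinations(self.alleles, 2)


@dataclass(frozen=True)
class PedigreeRecord:
    individual: str
    mother: str | None
    father: str | None
    generation: int = 0

    @property
    def is_founder(self) -> bool:
        return self.mother is None and self.father is None


@dataclass
class PedigreeTable:
    """Trio records; acyclic, parents listed before offspring."""

    records: list[PedigreeRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            for parent in (rec.mother, rec.father):
                if parent is not None and parent not in seen:
                    raise ValueError(
                        f"parent {parent} of {rec.individual} not listed earlier"
                    )
            if rec.individual in seen:
                raise ValueError(f"duplicate individual {rec.individual}")
            seen.add(rec.individual)

    @property
    def individuals(self) -> list[str]:
        return [r.individual for r in self.records]

    def offspring_records(self) -> list[PedigreeRecord]:
        return [r for r in self.records if not r.is_founder]
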