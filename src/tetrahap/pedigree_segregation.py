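"""Transmission consistency checks and offspring predictions for tetraploids.

Under random chromosome segregation a tetraploid parent transmits one of
its six unordered chromosome pairs to each gamete with equal probability
(no double reduction). An offspring is compatible with its parents when its
four-allele multiset can be split into one gamete from each parent; with a
single genotyped parent (duo), when some 2-sub-multiset of the offspring is
contained in that parent. Genotypes resolved only to group level (e.g. an
"A" that may be any of the A subtypes) are compared at group resolution to
avoid false mismatches.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction

from .model import PedigreeTable, TetraGenotype, gallais_class

__all__ = [
    "GameteDistribution",
    "TrioVerdict",
    "TransmissionReport",
    "OffspringDistribution",
    "enumerate_gametes",
    "check_trio",
    "scan_pedigree",
    "predict_offspring_classes",
]

GameteDistribution = dict[tuple[str, ...], Fraction]


def enumerate_gametes(parent: TetraGenotype | tuple[str, ...]) -> GameteDistribution:
    """Gamete distribution of a parent under random chromosome segregation.

    Each of the six unordered chromosome pairs of a tetraploid (or each
    single allele of a diploid) is equally likely; identical multisets are
    merged with summed probability.
    """
    alleles = parent.alleles if isinstance(parent, TetraGenotype) else tuple(parent)
    if isinstance(parent, TetraGenotype) and parent.status == "failed":
        raise ValueError(f"genotype of {parent.individual} is unresolved")
    dist: GameteDistribution = {}
    if len(alleles) == 4:
        for i, j in itertools.combinations(range(4), 2):
            g = tuple(sorted((alleles[i], alleles[j])))
            dist[g] = dist.get(g, Fraction(0)) + Fraction(1, 6)
    elif len(alleles) == 2:
        for a in alleles:
            dist[(a,)] = dist.get((a,), Fraction(0)) + Fraction(1, 2)
    else:
        raise ValueError(f"unsupported ploidy {len(alleles)}")
    return dist


def _grouped_alleles(
    alleles: tuple[str, ...], grouping: dict[str, str]
) -> tuple[str, ...]:
    return tuple(sorted(grouping.get(a, a) for a in alleles))


def _needs_group_resolution(
    alleles: tuple[str, ...], grouping: dict[str, str]
) -> bool:
    group_labels = set(grouping.values())
    return any(a in group_labels for a in alleles)


def _contains(sub: tuple[str, ...], multiset: tuple[str, ...]) -> bool:
    c = Counter(multiset)
    c.subtract(Counter(sub))
    return all(v >= 0 for v in c.values())


@dataclass
class TrioVerdict:
    offspring: str
    mother: str | None
    father: str | None
    verdict: str  # compatible | incompatible | untestable
    witness: tuple | None = None
    reason: str | None = None


def check_trio(
    offspring: TetraGenotype,
    mother: TetraGenotype | None,
    father: TetraGenotype | None,
    grouping: dict[str, str] | None = None,
) -> TrioVerdict:
    """Compatibility verdict for one offspring against its genotyped parent(s).

    With both parents: compatible iff the offspring multiset equals the
    union of one gamete from each parent (checked by enumerating the 6×6
    gamete pairs). With one parent (duo): compatible iff some gamete-sized
    sub-multiset of the offspring is contained in that parent. When any
    participant is resolved only to group level, all alleles are compared at
    group resolution.
    """
    grouping = grouping or {}

    def usable(g: TetraGenotype | None) -> bool:
        return g is not None and g.status != "failed" and bool(g.alleles)

    m_ok, f_ok = usable(mother), usable(father)
    if not usable(offspring) or (not m_ok and not f_ok):
        return TrioVerdict(
            offspring.individual,
            mother.individual if mother else None,
            father.individual if father else None,
            "untestable",
            reason="offspring or both parents unresolved",
        )
    participants = [offspring] + [g for g in (mother, father) if usable(g)]
    use_groups = any(
        _needs_group_resolution(g.alleles, grouping) for g in participants
    )

    def labels(g: TetraGenotype) -> tuple[str, ...]:
        return _grouped_alleles(g.alleles, grouping) if use_groups else g.alleles

    off = labels(offspring)
    if m_ok and f_ok:
        for gm in enumerate_gametes(labels(mother)):
            for gf in enumerate_gametes(labels(father)):
                if tuple(sorted(gm + gf)) == off:
                    return TrioVerdict(
                        offspring.individual,
                        mother.individual,
                        father.individual,
                        "compatible",
                        witness=(gm, gf),
                    )
        return TrioVerdict(
            offspring.individual,
            mother.individual,
            father.individual,
            "incompatible",
            reason="no gamete pair reproduces the offspring genotype",
        )
    parent = mother if m_ok else father
    par = labels(parent)
    gamete_size = len(off) // 2
    for sub in set(itertools.combinations(off, gamete_size)):
        if _contains(sub, par):
            return TrioVerdict(
                offspring.individual,
                mother.individual if mother else None,
                father.individual if father else None,
                "compatible",
                witness=(tuple(sorted(sub)),),
            )
    return TrioVerdict(
        offspring.individual,
        mother.individual if mother else None,
        father.individual if father else None,
        "incompatible",
        reason=f"no {gamete_size}-sub-multiset of offspring within parent "
        f"{parent.individual}",
    )


@dataclass
class TransmissionReport:
    verdicts: list[TrioVerdict]
    mismatches_per_parent: dict[str, int] = field(default_factory=dict)
    recurrent_offenders: list[str] = field(default_factory=list)

    @property
    def n_tested(self) -> int:
        return sum(v.verdict != "untestable" for v in self.verdicts)

    @property
    def n_incompatible(self) -> int:
        return sum(v.verdict == "incompatible" for v in self.verdicts)


def scan_pedigree(
    pedigree: PedigreeTable,
    genotypes: dict[str, TetraGenotype],
    grouping: dict[str, str] | None = None,
    offender_threshold: int = 3,
) -> TransmissionReport:
    """Test every genotyped offspring with at least one genotyped parent.

    Mismatches are aggregated per implicated parent; parents involved in
    ``offender_threshold`` or more mismatching pairs are reported as
    recurrent offenders (repeated mismatches point at a wrong parental
    genotype or pedigree record rather than at the offspring).
    """
    verdicts: list[TrioVerdict] = []
    per_parent: Counter = Counter()
    for rec in pedigree.offspring_records():
        off = genotypes.get(rec.individual)
        if off is None:
            continue
        mother = genotypes.get(rec.mother) if rec.mother else None
        father = genotypes.get(rec.father) if rec.father else None
        if mother is None and father is None:
            continue
        v = check_trio(off, mother, father, grouping=grouping)
        verdicts.append(v)
        if v.verdict == "incompatible":
            for parent in (v.mother, v.father):
                if parent is not None and parent in genotypes:
                    per_parent[parent] += 1
    offenders = sorted(
        p for p, c in per_parent.items() if c >= offender_threshold
    )
    return TransmissionReport(
        verdicts=verdicts,
        mismatches_per_parent=dict(per_parent),
        recurrent_offenders=offenders,
    )


@dataclass
class OffspringDistribution:
    genotype_probs: dict[tuple[str, ...], Fraction]
    focal: str | None = None
    focal_dosage_probs: dict[int, Fraction] | None = None

    def class_probs(self) -> dict[str, Fraction]:
        out: dict[str, Fraction] = {}
        for g, p in self.genotype_probs.items():
            c = gallais_class(g)
            out[c] = out.get(c, Fraction(0)) + p
        return out


def predict_offspring_classes(
    parent_a: TetraGenotype | tuple[str, ...],
    parent_b: TetraGenotype | tuple[str, ...] | None = None,
    selfing: bool = False,
    focal: str | None = None,
    grouping: dict[str, str] | None = None,
) -> OffspringDistribution:
    """Offspring genotype distribution of a cross (or selfing) by convolving
    the parental gamete distributions; optionally marginalized to the copy
    number of a focal allele (group labels allowed via ``grouping``)."""
    if selfing:
        parent_b = parent_a
    if parent_b is None:
        raise ValueError("need a second parent or selfing=True")
    ga, gb = enumerate_gametes(parent_a), enumerate_gametes(parent_b)
    probs: dict[tuple[str, ...], Fraction] = {}
    for g1, p1 in ga.items():
        for g2, p2 in gb.items():
            child = tuple(sorted(g1 + g2))
            probs[child] = probs.get(child, Fraction(0)) + p1 * p2
    focal_probs = None
    if focal is not None:
        grouping = grouping or {}
        focal_probs = {}
        for g, p in probs.items():
            d = sum(1 for a in g if a == focal or grouping.get(a, a) == focal)
            focal_probs[d] = focal_probs.get(d, Fraction(0)) + p
    return OffspringDistribution(
        genotype_probs=probs, focal=focal, focal_dosage_probs=focal_probs
    )
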