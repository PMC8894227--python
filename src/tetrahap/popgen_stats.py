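"""Autotetraploid diversity statistics, nucleotide diversity, codon effects
and a distance-based dendrogram of the haplotype panel.

Observed heterozygosity Ho follows the within-individual definition natural
to autotetraploids: the fraction of the six unordered allele pairs inside a
genotype that are heterozygous, giving class weights 1 (tetragenic abcd),
5/6 (trigenic aabc), 4/6 (digenic-duplex aabb), 3/6 (digenic-simplex aaab)
and 0 (monogenic aaaa). Expected heterozygosity He uses the bias-corrected
gene diversity (n/(n−1))(1 − Σp²) over allele copies under random
chromosome segregation; F = 1 − Ho/He; a permutation test (shuffling allele
copies among individuals in blocks of four) assesses deviation from
tetrasomic Hardy–Weinberg equilibrium.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .model import HaplotypePanel, TetraGenotype

__all__ = [
    "DiversityStats",
    "ClassSummary",
    "PiEstimate",
    "CodonTally",
    "NjResult",
    "diversity",
    "genotypic_class_summary",
    "nucleotide_diversity",
    "snp_spacing",
    "codon_effects",
    "ExonInterval",
    "jc_distance",
    "nj_tree",
]

log = logging.getLogger(__name__)


@dataclass
class DiversityStats:
    ai: float
    ho: float
    he: float
    f: float
    hwe_p: float | None
    n_individuals: int
    n_allele_copies: int
    n_excluded: int
    #: analytic chi-squared approximation (N·F²·(k−1), df k(k−1)/2); offered
    #: only as a labelled approximation next to the permutation test
    hwe_chi2: float | None = None
    hwe_chi2_df: int | None = None
    hwe_chi2_p: float | None = None


def _usable(genotypes: list[TetraGenotype]) -> list[TetraGenotype]:
    return [g for g in genotypes if g.alleles and g.status != "failed"]


def _ho_from_codes(codes: np.ndarray) -> float:
    """Mean heterozygous fraction of the within-individual allele pairs.

    ``codes`` is an (individuals × ploidy) integer array.
    """
    m = codes.shape[1]
    pairs = list(itertools.combinations(range(m), 2))
    eq = np.zeros(codes.shape[0], dtype=float)
    for i, j in pairs:
        eq += codes[:, i] == codes[:, j]
    return float(np.mean(1.0 - eq / len(pairs)))


def diversity(
    genotypes: list[TetraGenotype],
    grouping: dict[str, str] | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> DiversityStats:
    """Ai, Ho, He, fixation index and an HWE permutation test for a cohort.

    Unresolved/failed genotypes are excluded (count logged and reported).
    With ``grouping``, alleles are first collapsed to group labels. Setting
    ``n_permutations=0`` skips the permutation test.
    """
    usable = _usable(genotypes)
    n_excluded = len(genotypes) - len(usable)
    if n_excluded:
        log.info("diversity: excluded %d unresolved genotypes", n_excluded)
    if len(usable) < 2:
        raise ValueError("need at least 2 resolved genotypes")
    if grouping:
        usable = [g.grouped(grouping) for g in usable]
    labels = sorted({a for g in usable for a in g.alleles})
    code = {a: i for i, a in enumerate(labels)}
    codes = np.array([[code[a] for a in g.alleles] for g in usable])
    n_ind, ploidy = codes.shape
    n_copies = n_ind * ploidy

    ai = float(np.mean([len(set(g.alleles)) for g in usable]))
    ho = _ho_from_codes(codes)
    counts = np.bincount(codes.ravel(), minlength=len(labels))
    p = counts / n_copies
    he = (n_copies / (n_copies - 1)) * (1.0 - float(np.sum(p**2)))
    f = 1.0 - ho / he if he > 0 else float("nan")

    hwe_p = None
    if n_permutations > 0 and he > 0:
        rng = np.random.default_rng(seed)
        flat = codes.ravel()
        perms = np.stack(
            [rng.permutation(flat) for _ in range(n_permutations)]
        ).reshape(n_permutations, n_ind, ploidy)
        pairs = list(itertools.combinations(range(ploidy), 2))
        eq = np.zeros((n_permutations, n_ind), dtype=float)
        for i, j in pairs:
            eq += perms[:, :, i] == perms[:, :, j]
        ho_perm = np.mean(1.0 - eq / len(pairs), axis=1)
        f_perm = np.abs(1.0 - ho_perm / he)
        hwe_p = float((1 + np.sum(f_perm >= abs(f) - 1e-12)) / (n_permutations + 1))

    k = len(labels)
    chi2 = n_ind * f**2 * (k - 1)
    df = k * (k - 1) // 2
    return DiversityStats(
        ai=ai,
        ho=ho,
        he=he,
        f=f,
        hwe_p=hwe_p,
        n_individuals=n_ind,
        n_allele_copies=n_copies,
        n_excluded=n_excluded,
        hwe_chi2=float(chi2),
        hwe_chi2_df=df,
        hwe_chi2_p=float(sps.chi2.sf(chi2, df)) if df > 0 else None,
    )


@dataclass
class ClassSummary:
    class_counts: pd.Series  # genotypic class (sorted multiset) → count
    gallais_counts: dict[str, int]
    n_genotypes: int
    n_classes: int
    mean_per_class: float
    min_per_class: int
    max_per_class: int


def genotypic_class_summary(genotypes: list[TetraGenotype]) -> ClassSummary:
    """Counts per genotypic class (sorted allele multiset) and per Gallais class."""
    usable = _usable(genotypes)
    if not usable:
        raise ValueError("no resolved genotypes")
    keys = [",".join(g.alleles) for g in usable]
    counts = pd.Series(Counter(keys)).sort_values(ascending=False)
    counts = counts.sort_index(kind="stable").sort_values(
        ascending=False, kind="stable"
    )
    gallais = Counter(g.gallais for g in usable)
    return ClassSummary(
        class_counts=counts,
        gallais_counts=dict(gallais),
        n_genotypes=len(usable),
        n_classes=len(counts),
        mean_per_class=len(usable) / len(counts),
        min_per_class=int(counts.min()),
        max_per_class=int(counts.max()),
    )


@dataclass
class PiEstimate:
    pi_unweighted: float
    pi_weighted: float
    spacing_unweighted: int | None
    spacing_weighted: int | None
    accessible_length: int
    n_haplotypes: int


def snp_spacing(pi: float) -> int:
    """Average base-pair spacing between segregating sites, 1/π."""
    if pi <= 0:
        raise ValueError("pi must be positive")
    return round(1.0 / pi)


def _p_distance(a: str, b: str) -> float:
    """Per-site mismatch proportion; columns with a gap in either sequence
    are excluded pairwise."""
    diff = same = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        same += 1
        if x != y:
            diff += 1
    if same == 0:
        raise ValueError("no comparable (gap-free) columns")
    return diff / same


def nucleotide_diversity(panel: HaplotypePanel) -> PiEstimate:
    """Unweighted and frequency-weighted nucleotide diversity of the panel.

    π (unweighted) is the mean pairwise per-site p-distance over the
    haplotype sequences (amplicons concatenated); the weighted variant is
    Σ_{i≠j} p_i p_j d_ij, the expected distance between two allele copies
    drawn at the population frequencies.
    """
    names = panel.names
    if len(names) < 2:
        raise ValueError("need at least 2 haplotypes")
    seqs = {h: panel.concatenated(h) for h in names}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("haplotype sequences are not aligned to equal length")
    d = np.zeros((len(names), len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        d[i, j] = d[j, i] = _p_distance(seqs[names[i]], seqs[names[j]])
    pairs = [d[i, j] for i, j in itertools.combinations(range(len(names)), 2)]
    pi_u = float(np.mean(pairs))
    freqs = np.array([panel.frequencies.get(h, 0.0) for h in names])
    pi_w = float(freqs @ d @ freqs)  # diagonal is zero, counts i≠j both ways
    acc = sum(
        1
        for col in zip(*seqs.values())
        if "-" not in col
    )
    return PiEstimate(
        pi_unweighted=pi_u,
        pi_weighted=pi_w,
        spacing_unweighted=snp_spacing(pi_u) if pi_u > 0 else None,
        spacing_weighted=snp_spacing(pi_w) if pi_w > 0 else None,
        accessible_length=acc,
        n_haplotypes=len(names),
    )


@dataclass(frozen=True)
class ExonInterval:
    """A coding interval of an amplicon: 1-based inclusive start/end and the
    codon phase of the first base (0 = starts a codon)."""

    amplicon_id: str
    start: int
    end: int
    phase: int = 0

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError("phase must be 0, 1 or 2")
        if self.start < 1 or self.end < self.start:
            raise ValueError("bad exon interval")


@dataclass
class CodonChange:
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa

    @property
    def dysfunctional(self) -> bool:
        return self.alt_aa == "*" and self.ref_aa != "*"


@dataclass
class CodonTally:
    n_codons: int
    n_polymorphic_codons: int
    n_synonymous: int
    n_nonsynonymous: int
    n_intronic: int
    changes: list[CodonChange] = field(default_factory=list)
    dysfunctional: list[CodonChange] = field(default_factory=list)


def codon_effects(
    panel: HaplotypePanel,
    gene_model: list[ExonInterval],
    reference: str | None = None,
) -> CodonTally:
    """Classify coding polymorphisms as synonymous / non-synonymous.

    The exon intervals (in amplicon order) are concatenated into a coding
    sequence using the reference haplotype (default: the most frequent).
    Every alternate base observed among the haplotypes at a coding position
    is evaluated in its reference codon context; a distinct (codon, mutated
    codon) pair counts once. Variants outside every exon are tallied as
    intronic. Codons truncated at the ends of the modelled sequence are
    skipped; premature stops are flagged dysfunctional.
    """
    from Bio.Seq import Seq

    names = panel.names
    if reference is None:
        reference = (
            max(names, key=lambda h: panel.frequencies.get(h, 0.0))
            if panel.frequencies
            else names[0]
        )
    for ex in gene_model:
        amp = next(a for a in panel.amplicons if a.id == ex.amplicon_id)
        if ex.end > amp.length:
            raise ValueError(f"exon {ex} exceeds amplicon length {amp.length}")

    # concatenated CDS coordinates: phase of the first interval shifts the
    # frame so that codon boundaries line up across intervals
    cds_pos_of: dict[tuple[str, int], int] = {}  # (amplicon, 1-based pos) → CDS index
    cds_bases: list[str] = []
    offset = (3 - gene_model[0].phase) % 3 if gene_model else 0
    cursor = offset  # positions before the first complete codon are skipped
    ref_seq = {a.id: panel.sequence(reference, a.id) for a in panel.amplicons}
    skip = gene_model[0].phase if gene_model else 0
    cds_index = 0
    for ex in gene_model:
        for pos in range(ex.start, ex.end + 1):
            if skip > 0:  # incomplete leading codon
                skip -= 1
                continue
            cds_pos_of[(ex.amplicon_id, pos)] = cds_index
            cds_bases.append(ref_seq[ex.amplicon_id][pos - 1])
            cds_index += 1
    n_codons = len(cds_bases) // 3
    cds = "".join(cds_bases)

    changes: dict[tuple[int, str], CodonChange] = {}
    n_intronic = 0
    for amp in panel.amplicons:
        seqs = {h: panel.sequence(h, amp.id) for h in names}
        length = amp.length
        for pos in range(1, length + 1):
            bases = {seqs[h][pos - 1] for h in names}
            bases.discard("-")
            if len(bases) <= 1:
                continue
            ref_base = ref_seq[amp.id][pos - 1]
            alts = sorted(bases - {ref_base})
            if (amp.id, pos) not in cds_pos_of:
                n_intronic += len(alts)
                continue
            ci = cds_pos_of[(amp.id, pos)]
            codon_idx, within = divmod(ci, 3)
            if codon_idx >= n_codons:
                n_intronic += 0  # truncated trailing codon: skip silently
                continue
            ref_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
            for alt in alts:
                alt_codon = (
                    ref_codon[:within] + alt + ref_codon[within + 1 :]
                )
                key = (codon_idx, alt_codon)
                if key in changes:
                    continue
                changes[key] = CodonChange(
                    codon_index=codon_idx,
                    ref_codon=ref_codon,
                    alt_codon=alt_codon,
                    ref_aa=str(Seq(ref_codon).translate()),
                    alt_aa=str(Seq(alt_codon).translate()),
                )
    ordered = [changes[k] for k in sorted(changes)]
    return CodonTally(
        n_codons=n_codons,
        n_polymorphic_codons=len({c.codon_index for c in ordered}),
        n_synonymous=sum(c.synonymous for c in ordered),
        n_nonsynonymous=sum(not c.synonymous for c in ordered),
        n_intronic=n_intronic,
        changes=ordered,
        dysfunctional=[c for c in ordered if c.dysfunctional],
    )


def jc_distance(p: float) -> float:
    """Jukes–Cantor distance d = −(3/4)·ln(1 − 4p/3) from a p-distance."""
    if p < 0:
        raise ValueError("p-distance must be non-negative")
    if p >= 0.75:
        raise ValueError(f"saturated pair: p-distance {p} >= 3/4, JC undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class NjResult:
    tree: TreeNode
    support: dict[frozenset, float]
    newick: str


def _distance_matrix(seqs: dict[str, str], jc: bool = True) -> DistanceMatrix:
    names = list(seqs)
    n = len(names)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p = _p_distance(seqs[names[i]], seqs[names[j]])
        d[i, j] = d[j, i] = jc_distance(p) if jc else p
    return DistanceMatrix(d, ids=names)


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split
        out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def nj_tree(
    panel_or_seqs: HaplotypePanel | dict[str, str],
    outgroup: str | None = None,
    bootstrap_n: int = 0,
    seed: int = 0,
    jc: bool = True,
) -> NjResult:
    """Neighbor-joining tree of the haplotype sequences with bootstrap support.

    Distances are Jukes–Cantor by default (p-distance with ``jc=False``);
    bootstrap replicates resample alignment columns of the concatenated
    amplicons with replacement, and each internal edge's support is the
    percentage of replicate trees containing the same taxon bipartition.
    The tree is rooted at the outgroup branch when an outgroup is given.
    """
    if isinstance(panel_or_seqs, HaplotypePanel):
        seqs = {h: panel_or_seqs.concatenated(h) for h in panel_or_seqs.names}
    else:
        seqs = dict(panel_or_seqs)
    if outgroup is not None and outgroup not in seqs:
        raise ValueError(f"outgroup {outgroup!r} not among sequences")
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    taxa = frozenset(seqs)
    tree = nj(_distance_matrix(seqs, jc=jc))

    support: dict[frozenset, float] = {}
    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        names = list(seqs)
        cols = np.array([list(seqs[h]) for h in names])  # taxa × sites
        length = cols.shape[1]
        counts: Counter = Counter()
        for _ in range(bootstrap_n):
            pick = rng.integers(0, length, size=length)
            boot = {h: "".join(cols[i, pick]) for i, h in enumerate(names)}
            btree = nj(_distance_matrix(boot, jc=jc))
            for bp in _bipartitions(btree, taxa):
                counts[bp] += 1
        support = {bp: 100.0 * c / bootstrap_n for bp, c in counts.items()}
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            other = taxa - side
            if len(side) < 2 or len(other) < 2:
                continue
            key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
            node.name = str(int(round(support.get(key, 0.0))))

    if outgroup is not None:
        og = tree.find(outgroup)
        try:
            tree = tree.root_at(og.parent, above=False)
        except TypeError:  # older/newer scikit-bio signatures
            tree = tree.root_at(og.parent)
    import io as _io

    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return NjResult(tree=tree, support=support, newick=buf.getvalue().strip())
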