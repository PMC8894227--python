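"""Infer four-allele haplotype genotypes from noisy SNP dosage matrices.

The calling strategy mirrors quantitative amplicon genotyping practice:

1. squared Pearson correlation (r²) between the copy numbers of all variant
   alleles identifies sets of co-segregating SNPs (``compute_dosage_r2`` /
   ``cluster_cosegregating``);
2. each co-segregation cluster is a putative haplotype or a composite of
   haplotypes; composites are eliminated by dosage-profile algebra and each
   remaining putative haplotype gets a tag SNP (``select_tag_snps``);
3. ordered tag/subtraction rules convert per-variant dosages into per-
   haplotype copy numbers summing to the ploidy (``resolve_genotypes``),
   with cross-amplicon concordance checks and identical-in-state group
   handling when only one amplicon is informative.

When the haplotype panel is known, ``rules_from_incidence`` derives the
rule set directly from the haplotype × variant incidence matrix, including
subtraction chains for haplotypes without a unique tag SNP (a haplotype
defined by a shared SNP minus the copies of already-tagged haplotypes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    DosageMatrix,
    HaplotypePanel,
    TagRule,
    TagRuleSet,
    TetraGenotype,
    gallais_class,
    parse_variant_id,
)

__all__ = [
    "R2Report",
    "compute_dosage_r2",
    "cluster_cosegregating",
    "select_tag_snps",
    "rules_from_incidence",
    "resolve_genotypes",
    "call_de_novo",
    "resolve_with_panel",
    "classify_genotype",
    "largest_remainder_round",
]

classify_genotype = gallais_class


@dataclass
class R2Report:
    """Symmetric r² matrix plus the variants with zero dosage variance."""

    r2: pd.DataFrame
    monomorphic: list[str]


def compute_dosage_r2(matrix: DosageMatrix, min_shared: int = 3) -> R2Report:
    """Squared Pearson correlation of dosages over pairwise-complete individuals.

    Pairs sharing fewer than ``min_shared`` non-missing individuals and pairs
    involving a zero-variance (monomorphic) variant are reported as missing.
    The diagonal is 1 for polymorphic variants.
    """
    if len(matrix.variants) < 2:
        raise ValueError("need at least 2 variants")
    df = matrix.values.T  # individuals × variants
    stds = df.std(ddof=0)
    monomorphic = list(stds.index[(stds == 0) | stds.isna()])
    r = df.corr(min_periods=min_shared)
    r2 = r**2
    np.fill_diagonal(r2.values, 1.0)
    r2.loc[monomorphic, :] = np.nan
    r2.loc[:, monomorphic] = np.nan
    return R2Report(r2=r2, monomorphic=monomorphic)


def cluster_cosegregating(
    r2: R2Report | pd.DataFrame, threshold: float = 0.9
) -> list[list[str]]:
    """Partition variants into connected components of the r² ≥ threshold graph.

    Connected components (rather than complete linkage) are used so that a
    single noisy pair cannot split an otherwise coherent haplotype block.
    Singleton components are allowed; missing r² values contribute no edge.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    mat = r2.r2 if isinstance(r2, R2Report) else r2
    g = nx.Graph()
    g.add_nodes_from(mat.index)
    vals = mat.to_numpy()
    idx = list(mat.index)
    ii, jj = np.where(np.triu(vals >= threshold, k=1))
    g.add_edges_from((idx[i], idx[j]) for i, j in zip(ii, jj))
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


def _best_variant(candidates: list[str], matrix: DosageMatrix | None) -> str:
    """Tag choice: minimal missingness, then maximal dosage variance, then
    lowest position — the 'best quantifiable SNP'."""
    if matrix is None:
        return min(candidates, key=lambda v: parse_variant_id(v)[1:])

    def key(v: str):
        col = matrix.values.loc[v]
        return (int(col.isna().sum()), -float(col.var(ddof=0) or 0.0),
                parse_variant_id(v)[1])

    return min(candidates, key=key)


def _cluster_representative(
    cluster: list[str], matrix: DosageMatrix, ploidy: int
) -> str:
    """The variant carrying the cluster's *haplotype* dosage signal.

    A co-segregation cluster can contain, besides the haplotype's own
    (private) variants, shared variants of the haplotype plus a rare ally
    (whose r² with the private signal stays above threshold) and
    complement-encoded variants (the minority base at a site where the
    haplotype's base is the majority). Among near-minimal total-dosage
    variants — the haplotype's own signal is pointwise smallest — the best
    quantifiable one (min missingness, max variance, min position) is chosen.
    """
    sums = {
        v: float(np.nansum(np.rint(matrix.values.loc[v]))) for v in cluster
    }
    lo = min(sums.values())
    candidates = [v for v in cluster if sums[v] <= lo + 2]
    return _best_variant(candidates, matrix)


def select_tag_snps(
    clusters: list[list[str]],
    matrix: DosageMatrix,
    mismatch_tol: float = 0.02,
    name_prefix: str | None = None,
    ploidy: int = 4,
) -> TagRuleSet:
    """Derive putative haplotypes and tag rules from co-segregation clusters.

    Each cluster is represented by its best quantifiable minimal-dosage
    variant. A cluster whose (integer-rounded) dosage profile equals the
    sum of two surviving clusters' profiles — or the ploidy-complement of
    such a sum, for sites where the shared base is the majority — is a SNP
    block shared by multiple haplotypes, not a haplotype, and is peeled
    away. Profiles may disagree on up to ``mismatch_tol`` (fraction of
    individuals, at least 2) entries to tolerate occasional rounding flips.
    The survivors are the putative haplotypes; their representatives become
    unique tag SNPs.
    """
    covered = {v for c in clusters for v in c}
    missing = set(matrix.variants) - covered
    if missing:
        raise ValueError(f"clusters do not cover variants: {sorted(missing)}")
    reps: list[str] = []
    live: list[list[str]] = []
    for cluster in clusters:
        rep = _cluster_representative(cluster, matrix, ploidy)
        col = matrix.values.loc[rep]
        if float(col.var(ddof=0) or 0.0) == 0.0:
            continue  # monomorphic cluster cannot define a haplotype
        reps.append(rep)
        live.append(sorted(cluster))
    if not reps:
        raise ValueError("no polymorphic clusters")
    profiles = np.rint(matrix.values.loc[reps].to_numpy())  # clusters × individuals
    obs = ~np.isnan(profiles)

    # merge clusters with (near-)identical integer profiles: the same
    # underlying haplotype whose variants failed to reach the r² threshold
    # (low-frequency alleles have little dosage variance relative to noise)
    merged_live: list[list[str]] = []
    merged_idx: list[int] = []
    for ci in range(len(reps)):
        hit = None
        for mi, pi in enumerate(merged_idx):
            joint = obs[ci] & obs[pi]
            if joint.sum() >= 3 and np.sum(profiles[ci, joint] != profiles[pi, joint]) <= 1:
                hit = mi
                break
        if hit is None:
            merged_idx.append(ci)
            merged_live.append(list(live[ci]))
        else:
            merged_live[hit].extend(live[ci])
    if len(merged_idx) < len(reps):
        live = [sorted(c) for c in merged_live]
        reps = [_cluster_representative(c, matrix, ploidy) for c in live]
        profiles = np.rint(matrix.values.loc[reps].to_numpy())
        obs = ~np.isnan(profiles)

    n_ind = profiles.shape[1]
    tol = max(3, math.ceil(mismatch_tol * n_ind))

    # Iteratively peel composites: a cluster whose profile equals the sum
    # (or ploidy-complement of the sum) of two *currently surviving*
    # clusters is a shared SNP block, not a haplotype. Restricting
    # decompositions to survivors keeps the relation acyclic.
    n_c = len(reps)
    active = set(range(n_c))
    decomposition: dict[int, tuple[str, int, int]] = {}  # kind, a, b
    changed = True
    psum = np.nansum(profiles, axis=1)
    while changed and len(active) >= 3:
        changed = False
        # visit big clusters first: a composite (and especially a complement
        # block) always has a larger total dosage than the atoms it hides,
        # so this order never peels a true atom in a symmetric relation
        for c in sorted(active, key=lambda i: (-psum[i], i)):
            found: tuple[str, int, int] | None = None
            others = sorted(active - {c})
            for ai, a in enumerate(others):
                for b in others[ai:]:
                    joint = obs[c] & obs[a] & obs[b]
                    if joint.sum() < 3:
                        continue
                    sum_ab = profiles[a, joint] + profiles[b, joint]
                    if np.sum(profiles[c, joint] != sum_ab) <= tol:
                        found = ("sum", a, b)
                        break
                    if np.sum(profiles[c, joint] != ploidy - sum_ab) <= tol:
                        found = ("complement", a, b)
                        break
                if found:
                    break
            if found:
                decomposition[c] = found
                active.remove(c)
                changed = True
    atoms = sorted(active)

    prefix = name_prefix or f"{matrix.amplicon_id}.P"
    order = sorted(atoms, key=lambda i: -np.nansum(profiles[i]))
    names = {i: f"{prefix}{r + 1:02d}" for r, i in enumerate(order)}

    def expand(i: int) -> set[int]:
        """Atoms whose copies a cluster's dosage *adds up* (sum relations
        recursed; a complement block counts the atoms outside the sum)."""
        if i not in decomposition:
            return {i}
        kind, a, b = decomposition[i]
        inner = expand(a) | expand(b)
        return inner if kind == "sum" else set(atoms) - inner

    incidence = pd.DataFrame(
        0,
        index=[names[i] for i in order],
        columns=[v for c in live for v in c],
        dtype=int,
    )
    for ci, cluster in enumerate(live):
        for atom in expand(ci):
            if atom in names:
                incidence.loc[names[atom], cluster] = 1
    rules = [TagRule(names[i], reps[i], ()) for i in order]
    return TagRuleSet(
        amplicon_id=matrix.amplicon_id, incidence=incidence, rules=rules
    )


def rules_from_incidence(
    incidence: pd.DataFrame,
    matrix: DosageMatrix | None = None,
    merge_identical: bool = True,
    amplicon_id: str | None = None,
) -> TagRuleSet:
    """Ordered tag/subtraction rules from a haplotype × variant incidence matrix.

    Haplotypes with identical incidence rows are identical-in-state within
    this amplicon; with ``merge_identical`` they are merged into one
    resolvable unit (resolved to group level only), otherwise an error is
    raised. A unit with a variant carried by it alone gets a unique tag
    rule; a unit without one is resolved by subtraction: a shared variant's
    dosage minus the copies of the already-resolved co-carriers. A single
    unit carrying no variant at all is resolved last as the ploidy
    complement. Mutually dependent units with no valid evaluation order
    raise an error naming the offending set.
    """
    amp = amplicon_id or (matrix.amplicon_id if matrix is not None else "amplicon")
    # merge identical rows into identical-in-state units
    sig_to_haps: dict[tuple, list[str]] = {}
    for h in incidence.index:
        sig = tuple(incidence.loc[h])
        sig_to_haps.setdefault(sig, []).append(h)
    members: dict[str, tuple[str, ...]] = {}
    unit_rows: dict[str, np.ndarray] = {}
    for sig, haps in sig_to_haps.items():
        if len(haps) > 1 and not merge_identical:
            raise ValueError(
                f"haplotypes {sorted(haps)} are indistinguishable in {amp} "
                "(identical incidence rows)"
            )
        unit = haps[0] if len(haps) == 1 else "/".join(sorted(haps))
        members[unit] = tuple(sorted(haps))
        unit_rows[unit] = np.asarray(sig, dtype=int)
    units = list(unit_rows)
    cols = list(incidence.columns)
    carriers = {
        v: [u for u in units if unit_rows[u][ci] == 1] for ci, v in enumerate(cols)
    }

    rules: list[TagRule] = []
    resolved: set[str] = set()
    empty_units = [u for u in units if unit_rows[u].sum() == 0]
    if len(empty_units) > 1:
        raise ValueError(
            f"haplotypes {sorted(empty_units)} carry no variant allele in {amp}"
        )
    pending = [u for u in units if u not in empty_units]
    while pending:
        progressed = False
        for u in list(pending):
            candidates = [
                v
                for v in cols
                if u in carriers[v]
                and all(o in resolved for o in carriers[v] if o != u)
            ]
            if not candidates:
                continue
            uniques = [v for v in candidates if len(carriers[v]) == 1]
            pick = _best_variant(uniques or candidates, matrix)
            subtract = tuple(o for o in carriers[pick] if o != u)
            rules.append(TagRule(u, pick, subtract))
            resolved.add(u)
            pending.remove(u)
            progressed = True
        if not progressed:
            raise ValueError(
                f"cyclic tag-SNP dependency in {amp}: cannot order units {sorted(pending)}"
            )
    for u in empty_units:
        rules.append(TagRule(u, None, tuple(x for x in units if x != u)))
    return TagRuleSet(amplicon_id=amp, incidence=incidence, rules=rules, members=members)


def largest_remainder_round(raw: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing to ``total``.

    Largest-remainder method: floor everything, then hand out the remaining
    units to the largest fractional parts (ties to the lower index); when
    the floors already exceed ``total``, positive entries with the smallest
    fractional parts are decremented.
    """
    raw = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    base = np.floor(raw).astype(int)
    rem = raw - base
    deficit = total - int(base.sum())
    if deficit > 0:
        while deficit > 0:
            order = sorted(range(len(raw)), key=lambda i: (-rem[i], i))
            for i in order[:deficit]:
                base[i] += 1
                deficit -= 1
    elif deficit < 0:
        while deficit < 0:
            order = sorted(
                (i for i in range(len(raw)) if base[i] > 0),
                key=lambda i: (rem[i], i),
            )
            for i in order[:-deficit]:
                base[i] -= 1
                deficit += 1
    return base


def _evaluate_rules(
    rules: TagRuleSet,
    column: pd.Series,
    ploidy: int,
    round_inputs: bool,
) -> dict[str, float] | None:
    """Raw per-unit copy numbers for one individual in one amplicon.

    Returns None when the amplicon carries no information at all for this
    individual; units whose tag dosage (or dependency) is missing are
    omitted from the result.
    """
    if column.isna().all():
        return None
    out: dict[str, float] = {}
    for rule in rules.rules:
        if rule.variant is None:
            if all(u in out for u in rule.subtract):
                out[rule.target] = ploidy - sum(out[u] for u in rule.subtract)
            continue
        dose = column.get(rule.variant, np.nan)
        if np.isnan(dose) or any(u not in out for u in rule.subtract):
            continue
        if round_inputs:
            dose = float(np.rint(dose))
        out[rule.target] = dose - sum(out[u] for u in rule.subtract)
    return out


def resolve_genotypes(
    matrices: dict[str, DosageMatrix] | list[DosageMatrix],
    rules: dict[str, TagRuleSet] | list[TagRuleSet],
    ploidy: int = 4,
    round_inputs: bool = True,
    grouping: dict[str, str] | None = None,
    sum_tolerance: float = 0.5,
) -> list[TetraGenotype]:
    """Evaluate tag rules per amplicon and reconcile into final genotypes.

    Per amplicon, rule outputs are repaired to integers summing to the
    ploidy by largest-remainder rounding; an amplicon whose raw copies
    deviate from the ploidy by more than ``sum_tolerance`` is discarded as
    failed rather than silently fixed. Amplicons must agree on every
    haplotype copy number they both resolve, otherwise the individual is
    flagged ``failed``. A haplotype resolvable only as part of an
    identical-in-state unit yields a group-level allele label and status
    ``grouped-only`` (the grouping map supplies the label when all unit
    members share a group).
    """
    if isinstance(matrices, list):
        matrices = {m.amplicon_id: m for m in matrices}
    if isinstance(rules, list):
        rules = {r.amplicon_id: r for r in rules}
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    grouping = grouping or {}
    amp_ids = [a for a in matrices if a in rules]
    if not amp_ids:
        raise ValueError("no amplicon has both dosages and rules")
    individuals: list[str] = list(
        dict.fromkeys(i for a in amp_ids for i in matrices[a].individuals)
    )

    out: list[TetraGenotype] = []
    for ind in individuals:
        per_amp: dict[str, dict[str, int]] = {}
        failed = False
        for amp in amp_ids:
            if ind not in matrices[amp].values.columns:
                continue
            col = matrices[amp].values[ind]
            raw = _evaluate_rules(rules[amp], col, ploidy, round_inputs)
            if raw is None:
                continue
            ruleset = rules[amp]
            if len(raw) == len(ruleset.rules):
                total = sum(raw.values())
                if abs(total - ploidy) > sum_tolerance:
                    failed = True
                    continue
                units = list(raw)
                ints = largest_remainder_round(
                    np.array([raw[u] for u in units]), ploidy
                )
                per_amp[amp] = dict(zip(units, ints.tolist()))
            else:  # partial: round what we have, no sum repair possible
                per_amp[amp] = {
                    u: int(np.clip(np.rint(v), 0, ploidy)) for u, v in raw.items()
                }

        # per-haplotype consensus across amplicons
        hap_copies: dict[str, int] = {}
        group_units: list[tuple[str, tuple[str, ...], int]] = []
        for amp, unit_copies in per_amp.items():
            mem = rules[amp].members
            for unit, c in unit_copies.items():
                haps = mem.get(unit, (unit,))
                if len(haps) == 1:
                    h = haps[0]
                    if h in hap_copies and hap_copies[h] != c:
                        failed = True
                    hap_copies.setdefault(h, c)
                else:
                    group_units.append((amp, haps, c))
        # identical-in-state units: rescued if the other amplicon resolved
        # the members individually, else contribute group-level alleles
        group_alleles: list[str] = []
        for amp, haps, c in group_units:
            if all(h in hap_copies for h in haps):
                if sum(hap_copies[h] for h in haps) != c:
                    failed = True
                continue
            groups = {grouping.get(h, h) for h in haps}
            label = groups.pop() if len(groups) == 1 else "/".join(sorted(haps))
            group_alleles.extend([label] * c)

        alleles = [h for h, c in hap_copies.items() for _ in range(c)]
        alleles.extend(group_alleles)
        support = tuple(sorted(per_amp))
        if failed or len(alleles) != ploidy or not per_amp:
            out.append(TetraGenotype(ind, (), status="failed", support=support))
        elif group_alleles:
            out.append(
                TetraGenotype(ind, tuple(alleles), status="grouped-only", support=support)
            )
        else:
            out.append(
                TetraGenotype(ind, tuple(alleles), status="resolved", support=support)
            )
    return out


def _match_across_amplicons(
    rulesets: dict[str, TagRuleSet],
    matrices: dict[str, DosageMatrix],
    min_agreement: float = 0.98,
) -> dict[str, TagRuleSet]:
    """Unify putative haplotype names across amplicons by dosage-profile match.

    De-novo putative haplotypes carry per-amplicon names; two putative
    haplotypes from different amplicons that show the same integer dosage
    profile across individuals are the same underlying allele and receive a
    common canonical name (P01, P02, ... by decreasing total copy number).
    """
    amp_ids = list(rulesets)
    profiles: dict[tuple[str, str], pd.Series] = {}
    for amp in amp_ids:
        rs = rulesets[amp]
        resolved: dict[str, pd.Series] = {}
        for rule in rs.rules:  # rules are in evaluation order
            if rule.variant is None:
                prof = 4.0 - sum(resolved[u] for u in rule.subtract)
            else:
                prof = np.rint(matrices[amp].values.loc[rule.variant])
                for other in rule.subtract:
                    prof = prof - resolved[other]
            resolved[rule.target] = prof
            profiles[(amp, rule.target)] = prof

    ref_amp = amp_ids[0]
    canonical: dict[tuple[str, str], str] = {}
    ref_units = [r.target for r in rulesets[ref_amp].rules]
    ref_units.sort(key=lambda u: -np.nansum(profiles[(ref_amp, u)]))
    for i, u in enumerate(ref_units):
        canonical[(ref_amp, u)] = f"P{i + 1:02d}"
    fresh = len(ref_units)
    for amp in amp_ids[1:]:
        taken: set[str] = set()
        for u in [r.target for r in rulesets[amp].rules]:
            prof = profiles[(amp, u)]
            best_name, best_score = None, min_agreement
            for ru in ref_units:
                name = canonical[(ref_amp, ru)]
                if name in taken:
                    continue
                ref_prof = profiles[(ref_amp, ru)]
                joint = ref_prof.notna() & prof.notna()
                if joint.sum() == 0:
                    continue
                score = float((ref_prof[joint] == prof[joint]).mean())
                if score >= best_score:
                    best_name, best_score = name, score
            if best_name is None:
                fresh += 1
                best_name = f"P{fresh:02d}"
            taken.add(best_name)
            canonical[(amp, u)] = best_name

    renamed: dict[str, TagRuleSet] = {}
    for amp in amp_ids:
        rs = rulesets[amp]
        mapping = {u: canonical[(amp, u)] for u in (r.target for r in rs.rules)}
        renamed[amp] = TagRuleSet(
            amplicon_id=amp,
            incidence=rs.incidence.rename(index=mapping),
            rules=[
                TagRule(mapping[r.target], r.variant,
                        tuple(mapping[s] for s in r.subtract))
                for r in rs.rules
            ],
            members={mapping[u]: (mapping[u],) for u in mapping},
        )
    return renamed


def call_de_novo(
    matrices: dict[str, DosageMatrix] | list[DosageMatrix],
    ploidy: int = 4,
    r2_threshold: float = 0.9,
) -> tuple[list[TetraGenotype], dict[str, TagRuleSet]]:
    """Full de-novo pipeline: r² clustering → tag selection → resolution.

    Putative haplotype names are unified across amplicons by dosage-profile
    matching before resolution, so cross-amplicon concordance is enforced.
    """
    if isinstance(matrices, list):
        matrices = {m.amplicon_id: m for m in matrices}
    rulesets: dict[str, TagRuleSet] = {}
    for amp, mat in matrices.items():
        report = compute_dosage_r2(mat)
        clusters = cluster_cosegregating(report, threshold=r2_threshold)
        rulesets[amp] = select_tag_snps(clusters, mat)
    if len(rulesets) > 1:
        rulesets = _match_across_amplicons(rulesets, matrices)
    genotypes = resolve_genotypes(matrices, rulesets, ploidy=ploidy)
    return genotypes, rulesets


def resolve_with_panel(
    matrices: dict[str, DosageMatrix] | list[DosageMatrix],
    panel: HaplotypePanel,
    ploidy: int = 4,
    round_inputs: bool = True,
) -> list[TetraGenotype]:
    """Resolve genotypes using rules derived from a known haplotype panel."""
    if isinstance(matrices, list):
        matrices = {m.amplicon_id: m for m in matrices}
    rules = {
        amp: rules_from_incidence(panel.incidence(amp), matrices.get(amp), amplicon_id=amp)
        for amp in matrices
    }
    return resolve_genotypes(
        matrices, rules, ploidy=ploidy, round_inputs=round_inputs,
        grouping=panel.grouping,
    )
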