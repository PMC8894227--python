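"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: genotype resolution by
exhaustive search over all allele multisets, transmission checks by full
gamete-pair enumeration, and four-taxon tree reconstruction by scoring the
three possible unrooted topologies.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np


def exhaustive_resolve(dosage_columns, incidences, names, ploidy=4):
    """Best allele multiset by least-squares against observed dosages.

    ``dosage_columns``: {amplicon: 1-D array of dosages in incidence column
    order}; ``incidences``: {amplicon: (haplotype × variant) 0/1 DataFrame
    with rows in ``names`` order}. Every multiset of size ``ploidy`` over
    ``names`` is scored by the squared deviation of predicted from observed
    dosages summed over amplicons.
    """
    best, best_score = None, np.inf
    for combo in itertools.combinations_with_replacement(range(len(names)), ploidy):
        counts = np.zeros(len(names))
        for i in combo:
            counts[i] += 1
        score = 0.0
        for amp, inc in incidences.items():
            pred = counts @ inc.to_numpy()
            obs = dosage_columns[amp]
            mask = ~np.isnan(obs)
            score += float(np.sum((pred[mask] - obs[mask]) ** 2))
        if score < best_score - 1e-12:
            best_score = score
            best = tuple(sorted(names[i] for i in combo))
    return best, best_score


def gamete_pairs(parent):
    """All 6 unordered chromosome pairs of a 4-allele tuple (with repeats)."""
    return [
        tuple(sorted((parent[i], parent[j])))
        for i, j in itertools.combinations(range(4), 2)
    ]


def trio_compatible(offspring, mother, father):
    """Offspring multiset reproducible from one gamete of each parent?"""
    target = Counter(offspring)
    for gm in gamete_pairs(mother):
        for gf in gamete_pairs(father):
            if Counter(gm + gf) == target:
                return True
    return False


def offspring_distribution(mother, father):
    """Exact offspring genotype distribution from 6 × 6 gamete pairs."""
    out: Counter = Counter()
    for gm in gamete_pairs(mother):
        for gf in gamete_pairs(father):
            out[tuple(sorted(gm + gf))] += 1
    total = sum(out.values())
    return {g: c / total for g, c in out.items()}


def best_quartet_topology(dm, taxa):
    """Four-point-condition fit over the three unrooted quartet topologies.

    Returns the pair grouped together in the best topology and the fitted
    internal branch length (0 for a star)."""
    a, b, c, d = taxa
    # topology ab|cd: internal edge = (d_ac + d_bd + d_ad + d_bc - 2 d_ab - 2 d_cd)/4... use
    # the standard split metric: for additive distances the true split has
    # the *smallest* sum d(x1,x2)+d(y1,y2) over the pairing.
    sums = {
        (a, b): dm[a][b] + dm[c][d],
        (a, c): dm[a][c] + dm[b][d],
        (a, d): dm[a][d] + dm[b][c],
    }
    pair = min(sums, key=lambda k: sums[k])
    others = [t for t in taxa if t not in pair]
    internal = (min(v for k, v in sums.items() if k != pair) - sums[pair]) / 2
    return frozenset(pair), frozenset(others), internal
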