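"""Synthetic panels, cohorts, pedigrees, dosage matrices and phenotypes.

This module generates data with the statistical structure the downstream
stages assume, so that every stage of the pipeline can be exercised against
known ground truth:

* a panel of divergent gene haplotypes over one or more amplicons, tuned to
  a target nucleotide diversity, each haplotype carrying private tag sites;
* cohorts of autotetraploid individuals drawn under tetrasomic
  Hardy-Weinberg equilibrium (four allele copies i.i.d. from the panel
  frequencies, i.e. random chromosome segregation, no double reduction);
* pedigrees in which each gamete receives one of the parent's six unordered
  chromosome pairs with equal probability;
* quantitatively scored SNP dosage matrices with Gaussian observation noise,
  random missingness and whole-amplicon dropout;
* starch-phosphate-like phenotypes with a negative grouped-A allele effect,
  a positive H allele effect, unlinked background QTLs and a configurable
  heritability.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    Amplicon,
    DosageMatrix,
    HaplotypePanel,
    PedigreeRecord,
    PedigreeTable,
    TetraGenotype,
)

__all__ = [
    "PhenotypeModel",
    "SimConfig",
    "REFERENCE_ALLELE_FREQ_PCT",
    "preset_frequencies",
    "generate_haplotypes",
    "sample_cohort",
    "simulate_pedigree",
    "observe_dosages",
    "simulate_phenotypes",
    "calibrate_effects",
    "genotype_dosages",
]

#: Published-style allele-frequency spectrum (percent) of the 16 GWD
#: haplotypes in a ~400-cultivar tetraploid panel. Kept verbatim as
#: reference data: ten haplotypes sit below 5%, six above.
REFERENCE_ALLELE_FREQ_PCT = {
    "A1": 3.00,
    "A2": 3.50,
    "A3": 31.80,
    "A4": 2.30,
    "A5": 0.10,
    "B": 20.80,
    "C": 7.30,
    "D": 8.90,
    "E": 7.60,
    "F": 8.30,
    "G": 0.40,
    "H": 2.70,
    "I": 0.20,
    "J": 0.50,
    "K": 2.40,
    "L": 0.10,
}

#: Haplotypes grouped as "A": similar subtypes that can be
#: identical-in-state within a single amplicon.
A_GROUP = {"A1": "A", "A2": "A", "A3": "A", "A4": "A", "A5": "A"}

#: Simulation presets never drop an allele below this fraction. An allele at
#: 0.1% is absent from a 400-individual cohort with probability ~0.2, and an
#: allele with only a handful of carriers cannot be separated from a shared
#: SNP block by co-segregation statistics at all (the published ultra-rare
#: haplotypes were confirmed by cloned-amplicon sequencing, outside what
#: dosage data can show). At 1% every allele has ~16 expected copies in a
#: 400-individual cohort, enough for the r²/profile algebra to identify it;
#: the floored spectrum still has ten alleles below 5% and six above.
MIN_SIM_FREQ_PCT = 1.0


def preset_frequencies(floor_pct: float = MIN_SIM_FREQ_PCT) -> dict[str, float]:
    """Simulation allele frequencies: reference spectrum, floored and renormalized."""
    raw = {h: max(p, floor_pct) for h, p in REFERENCE_ALLELE_FREQ_PCT.items()}
    total = sum(raw.values())
    return {h: p / total for h, p in raw.items()}


@dataclass
class PhenotypeModel:
    """Additive phenotype model ``y = μ + β_A·x_A + β_H·x_H + Σ_q g_q + ε``.

    ``x_A`` is the summed dosage of the grouped effect alleles, ``x_H`` the
    dosage of the focal positive-effect allele. ``frac_a``/``frac_h`` are the
    *marginal* fractions of total phenotypic variance each dosage explains;
    ``h2`` is the broad-sense heritability, with ``n_background`` unlinked
    additive loci absorbing the remaining genetic variance. Genetic terms are
    mean-centred so the population mean equals ``mean`` exactly.
    """

    mean: float = 22.5
    sd: float = 4.3
    frac_a: float = 0.134
    frac_h: float = 0.047
    h2: float = 0.83
    n_background: int = 2
    effect_group: str = "A"
    effect_hap: str = "H"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("phenotype sd must be non-negative")
        for name in ("frac_a", "frac_h"):
            f = getattr(self, name)
            if not 0 <= f < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        if self.frac_a + self.frac_h > self.h2:
            raise ValueError(
                "requested marginal variance fractions exceed the heritable variance"
            )


@dataclass
class SimConfig:
    """All knobs of the simulator; identical configs give identical outputs."""

    seed: int = 0
    n_haplotypes: int = 16
    amplicon_lengths: tuple[int, ...] = (627, 606)
    target_pi: float = 0.0185
    cohort_size: int = 398
    dosage_noise_sd: float = 0.15
    missing_rate: float = 0.0
    amplicon_failure_rate: float = 0.035
    pedigree_founders: int = 12
    pedigree_generations: int = 2
    pedigree_offspring: int = 40
    frequencies: dict[str, float] | None = None
    grouping: dict[str, str] | None = None
    private_tags_per_amplicon: bool = True
    double_reduction: bool = False
    phenotype: PhenotypeModel = field(default_factory=PhenotypeModel)

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")
        if any(l < 50 for l in self.amplicon_lengths):
            raise ValueError("amplicon lengths must be >= 50 bp")
        if self.dosage_noise_sd < 0:
            raise ValueError("dosage_noise_sd must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.double_reduction:
            raise NotImplementedError(
                "double reduction is reserved but not implemented; "
                "transmission assumes random chromosome segregation"
            )

    @classmethod
    def preset(cls, name: str = "panel-2012", **overrides) -> "SimConfig":
        """Named presets; ``panel-2012`` is the default 16-haplotype panel,
        two amplicons of 627 and 606 bp, reference-like frequencies,
        n = 398 with 3.5% whole-amplicon dropout."""
        if name != "panel-2012":
            raise ValueError(f"unknown preset {name!r}")
        cfg = cls(
            frequencies=preset_frequencies(),
            grouping=dict(A_GROUP),
        )
        return replace(cfg, **overrides)

    def haplotype_names(self) -> list[str]:
        if self.frequencies is not None:
            return list(self.frequencies)
        if self.n_haplotypes == 16:
            return list(REFERENCE_ALLELE_FREQ_PCT)
        return [f"H{i + 1:02d}" for i in range(self.n_haplotypes)]

    def resolved_frequencies(self) -> dict[str, float]:
        if self.frequencies is not None:
            total = sum(self.frequencies.values())
            return {h: f / total for h, f in self.frequencies.items()}
        names = self.haplotype_names()
        return {h: 1.0 / len(names) for h in names}

    def resolved_grouping(self) -> dict[str, str]:
        if self.grouping is not None:
            return dict(self.grouping)
        names = self.haplotype_names()
        return {h: g for h, g in A_GROUP.items() if h in names}


BASES = np.array(list("ACGT"))


def _draw_alt(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(len(choices))]


def generate_haplotypes(config: SimConfig) -> HaplotypePanel:
    """Generate an aligned haplotype panel tuned to a target diversity.

    Segregating sites are added one at a time until the realized unweighted
    nucleotide diversity (mean pairwise per-site difference over haplotypes)
    matches ``target_pi`` as closely as site granularity allows. Private
    (single-carrier) sites come first — when ``private_tags_per_amplicon``
    is set, one per haplotype per amplicon, so every haplotype carries a
    unique tag SNP in every amplicon — followed by sites shared by a random
    pair of haplotypes, mimicking co-segregating SNP blocks.

    Raises ``ValueError`` when the target diversity is infeasible for the
    sequence length (more distinct sites needed than positions available) or
    cannot be approached within 10% relative error.
    """
    rng = np.random.default_rng(config.seed)
    names = config.haplotype_names()
    k = len(names)
    lengths = config.amplicon_lengths
    amp_ids = [f"amp{i + 1}" for i in range(len(lengths))]
    l_tot = sum(lengths)
    n_pairs = k * (k - 1) // 2

    # target number of (site, haplotype-pair) mismatches
    d_target = config.target_pi * l_tot * n_pairs

    # Site queue: (amplicon index, carrier tuple). Private sites first.
    queue: list[tuple[int, tuple[int, ...]]] = []
    if config.private_tags_per_amplicon:
        for ai in range(len(lengths)):
            for hi in range(k):
                queue.append((ai, (hi,)))
    else:
        # minimal distinguishability: k-1 private sites on the largest amplicon
        ai = int(np.argmax(lengths))
        for hi in range(k - 1):
            queue.append((ai, (hi,)))

    capacity = [l - sum(1 for a, _ in queue if a == ai) for ai, l in enumerate(lengths)]
    # shared-pair sites to fill the remaining diversity budget
    per_private = k - 1
    per_pair = 2 * (k - 2) if k > 2 else 1
    d_after_privates = len(queue) * per_private
    n_shared = max(0, math.ceil((d_target - d_after_privates) / per_pair))
    pair_list = list(itertools.combinations(range(k), 2))
    for _ in range(n_shared + 2):  # +2 slack, trimmed below
        open_amps = [ai for ai in range(len(lengths)) if capacity[ai] > 0]
        if not open_amps:
            break
        weights = np.array([capacity[ai] for ai in open_amps], dtype=float)
        ai = open_amps[rng.choice(len(open_amps), p=weights / weights.sum())]
        capacity[ai] -= 1
        pair = pair_list[rng.integers(len(pair_list))] if k > 2 else (0,)
        queue.append((ai, tuple(pair)))

    # realize sites sequentially, stopping at the best approximation of d_target;
    # the first k-1 singleton sites already make every haplotype pair distinct,
    # so prefixes shorter than that are never accepted
    contrib = [len(c) * (k - len(c)) for _, c in queue]
    best_n, best_err = 0, abs(d_target)
    running = 0.0
    min_sites = k - 1
    for i, c in enumerate(contrib):
        running += c
        if i + 1 >= min_sites and abs(running - d_target) <= best_err:
            best_err = abs(running - d_target)
            best_n = i + 1
    sites = queue[:best_n]
    d_real = sum(contrib[:best_n])
    realized_pi = d_real / (l_tot * n_pairs)
    if config.target_pi > 0 and abs(realized_pi - config.target_pi) > 0.1 * config.target_pi:
        raise ValueError(
            f"target_pi {config.target_pi} infeasible: sequence length {l_tot} "
            f"allows realized pi {realized_pi:.4g} at best "
            f"({best_n} segregating sites)"
        )

    # lay sites onto positions and build sequences
    refs = [rng.choice(BASES, size=l) for l in lengths]
    seqs = {h: [ref.copy() for ref in refs] for h in names}
    n_per_amp = [sum(1 for ai, _ in sites if ai == a) for a in range(len(lengths))]
    for ai, need in enumerate(n_per_amp):
        if need > lengths[ai]:
            raise ValueError("more segregating sites than positions in amplicon")
    positions = [
        rng.choice(lengths[ai], size=n_per_amp[ai], replace=False)
        for ai in range(len(lengths))
    ]
    cursor = [0] * len(lengths)
    for ai, carriers in sites:
        pos = positions[ai][cursor[ai]]
        cursor[ai] += 1
        ref_base = refs[ai][pos]
        alt = _draw_alt(rng, ref_base)
        for hi in carriers:
            seqs[names[hi]][ai][pos] = alt

    sequences = {
        h: {amp_ids[ai]: "".join(arr[ai]) for ai in range(len(lengths))}
        for h, arr in seqs.items()
    }
    return HaplotypePanel(
        amplicons=[Amplicon(a, l) for a, l in zip(amp_ids, lengths)],
        sequences=sequences,
        frequencies=config.resolved_frequencies(),
        grouping=config.resolved_grouping(),
    )


def sample_cohort(
    panel: HaplotypePanel,
    n: int,
    seed: int | np.random.Generator = 0,
    ploidy: int = 4,
    prefix: str = "ind",
) -> list[TetraGenotype]:
    """Draw ``n`` individuals under tetrasomic HWE.

    Each individual's ``ploidy`` allele copies are i.i.d. draws from the
    panel frequencies (random chromosome segregation / panmixia).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if not panel.frequencies:
        raise ValueError("panel has no frequency table")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = panel.names
    probs = np.array([panel.frequencies[h] for h in names])
    draws = rng.choice(len(names), size=(n, ploidy), p=probs)
    width = max(4, len(str(n)))
    return [
        TetraGenotype(
            individual=f"{prefix}{i + 1:0{width}d}",
            alleles=tuple(names[j] for j in row),
        )
        for i, row in enumerate(draws)
    ]


def draw_gamete(parent: tuple[str, ...], rng: np.random.Generator) -> tuple[str, str]:
    """One gamete under random chromosome segregation: a uniform draw among
    the parent's 6 unordered chromosome pairs (no double reduction)."""
    i, j = _PAIRS[rng.integers(6)]
    return parent[i], parent[j]


_PAIRS = list(itertools.combinations(range(4), 2))


def simulate_pedigree(
    panel: HaplotypePanel, config: SimConfig, seed: int | None = None
) -> tuple[PedigreeTable, dict[str, TetraGenotype]]:
    """Simulate a multi-generation pedigree with Mendelian tetrasomic transmission.

    Founders are HWE draws from the panel; every non-founder genotype is the
    union of one 2-allele gamete from each parent.
    """
    if config.pedigree_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    founders = sample_cohort(
        panel, config.pedigree_founders, seed=rng, prefix="fnd"
    )
    records = [PedigreeRecord(g.individual, None, None, 0) for g in founders]
    genotypes = {g.individual: g for g in founders}
    current = [g.individual for g in founders]
    for gen in range(1, config.pedigree_generations + 1):
        nxt = []
        for i in range(config.pedigree_offspring):
            mother, father = (
                current[j] for j in rng.choice(len(current), size=2, replace=False)
            )
            child_id = f"g{gen}o{i + 1:03d}"
            alleles = draw_gamete(genotypes[mother].alleles, rng) + draw_gamete(
                genotypes[father].alleles, rng
            )
            genotypes[child_id] = TetraGenotype(child_id, alleles)
            records.append(PedigreeRecord(child_id, mother, father, gen))
            nxt.append(child_id)
        current = nxt
    return PedigreeTable(records), genotypes


def _copies_matrix(
    genotypes: list[TetraGenotype], names: list[str]
) -> np.ndarray:
    idx = {h: i for i, h in enumerate(names)}
    out = np.zeros((len(genotypes), len(names)), dtype=int)
    for r, g in enumerate(genotypes):
        for a in g.alleles:
            out[r, idx[a]] += 1
    return out


def observe_dosages(
    genotypes: list[TetraGenotype],
    panel: HaplotypePanel,
    noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    amplicon_failure_rate: float = 0.0,
) -> dict[str, DosageMatrix]:
    """Quantitative SNP scoring: incidence × copies plus Gaussian noise.

    For each variant allele the observed value is the sum of copies of the
    haplotypes carrying it, plus ``N(0, noise_sd)`` noise, clipped to the
    physical range [0, 4]; entries are set missing independently with
    ``missing_rate``, and with ``amplicon_failure_rate`` an individual loses
    an entire amplicon (emulating a failed sequencing run). One matrix per
    amplicon is returned.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = panel.names
    copies = _copies_matrix(genotypes, names)  # individuals × haplotypes
    individuals = [g.individual for g in genotypes]
    out: dict[str, DosageMatrix] = {}
    for amp in panel.amplicons:
        inc = panel.incidence(amp.id)  # haplotypes × variants (0/1)
        true = copies @ inc.to_numpy()  # individuals × variants
        obs = true.astype(float)
        if noise_sd > 0:
            obs = obs + rng.normal(0.0, noise_sd, size=obs.shape)
        obs = np.clip(obs, 0.0, 4.0)
        if missing_rate > 0:
            obs[rng.random(obs.shape) < missing_rate] = np.nan
        if amplicon_failure_rate > 0:
            failed = rng.random(len(individuals)) < amplicon_failure_rate
            obs[failed, :] = np.nan
        out[amp.id] = DosageMatrix(
            amplicon_id=amp.id,
            values=pd.DataFrame(
                obs.T, index=list(inc.columns), columns=individuals
            ),
        )
    return out


def genotype_dosages(
    genotypes: list[TetraGenotype],
    allele: str,
    grouping: dict[str, str] | None = None,
) -> pd.Series:
    """Per-individual copy number of ``allele`` (after optional grouping)."""
    grouping = grouping or {}
    vals = {
        g.individual: sum(1 for a in g.alleles if grouping.get(a, a) == allele)
        for g in genotypes
    }
    return pd.Series(vals, name=allele)


def calibrate_effects(
    panel: HaplotypePanel, model: PhenotypeModel, ploidy: int = 4
) -> dict[str, float]:
    """Solve for allele effects hitting the configured marginal variance fractions.

    Under HWE the grouped-A dosage ``x_A`` and the H dosage ``x_H`` are
    jointly multinomial with Var(x) = m·p(1−p) and Cov(x_A, x_H) = −m·p_A·p_H
    (m = ploidy). The marginal R² of a single-dosage regression involves both
    direct effects through this covariance, so the two effect sizes are
    obtained from the linear system

        v_A·β_A + c·β_H = −sqrt(f_A · v_A · V)
        c·β_A + v_H·β_H = +sqrt(f_H · v_H · V)

    (negative A effect, positive H effect). Background-locus and residual
    variances then absorb h²·V and (1−h²)·V.
    """
    freqs = panel.frequencies
    grouping = panel.grouping
    p_a = sum(f for h, f in freqs.items() if grouping.get(h, h) == model.effect_group)
    p_h = freqs.get(model.effect_hap, 0.0)
    if model.frac_a > 0 and p_a == 0:
        raise ValueError(f"effect group {model.effect_group!r} absent from panel")
    if model.frac_h > 0 and p_h == 0:
        raise ValueError(f"effect haplotype {model.effect_hap!r} absent from panel")
    v_total = model.sd**2
    v_a = ploidy * p_a * (1 - p_a)
    v_h = ploidy * p_h * (1 - p_h)
    cov = -ploidy * p_a * p_h
    beta_a = beta_h = 0.0
    if v_total > 0:
        if model.frac_a > 0 and model.frac_h > 0:
            rhs = np.array(
                [
                    -math.sqrt(model.frac_a * v_a * v_total),
                    math.sqrt(model.frac_h * v_h * v_total),
                ]
            )
            mat = np.array([[v_a, cov], [cov, v_h]])
            beta_a, beta_h = np.linalg.solve(mat, rhs)
        elif model.frac_a > 0:
            beta_a = -math.sqrt(model.frac_a * v_total / v_a)
        elif model.frac_h > 0:
            beta_h = math.sqrt(model.frac_h * v_total / v_h)
    g_direct = beta_a**2 * v_a + beta_h**2 * v_h + 2 * beta_a * beta_h * cov
    bg_total = model.h2 * v_total - g_direct
    if bg_total < -1e-9:
        raise ValueError("direct allele effects exceed the heritable variance")
    bg_total = max(bg_total, 0.0)
    n_bg = model.n_background
    bg_each = bg_total / n_bg if n_bg else 0.0
    resid = (1 - model.h2) * v_total
    return {
        "beta_a": float(beta_a),
        "beta_h": float(beta_h),
        "mean_a": ploidy * p_a,
        "mean_h": ploidy * p_h,
        "bg_var_each": float(bg_each),
        "resid_var": float(resid),
    }


def simulate_phenotypes(
    genotypes: list[TetraGenotype],
    model: PhenotypeModel,
    panel: HaplotypePanel,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Simulate phenotypes for a cohort under the additive model.

    Genetic terms are centred at their HWE expectations so that the
    population mean equals ``model.mean`` regardless of effect sizes.
    Background QTLs are unlinked biallelic loci at frequency 0.5 with
    dosages Binomial(ploidy, 0.5).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ploidy = genotypes[0].ploidy if genotypes else 4
    cal = calibrate_effects(panel, model, ploidy=ploidy)
    x_a = genotype_dosages(genotypes, model.effect_group, panel.grouping).to_numpy(
        dtype=float
    )
    x_h = genotype_dosages(genotypes, model.effect_hap).to_numpy(dtype=float)
    n = len(genotypes)
    y = np.full(n, model.mean, dtype=float)
    y += cal["beta_a"] * (x_a - cal["mean_a"])
    y += cal["beta_h"] * (x_h - cal["mean_h"])
    if model.n_background and cal["bg_var_each"] > 0:
        beta_q = math.sqrt(cal["bg_var_each"] / (ploidy * 0.25))
        for _ in range(model.n_background):
            dos = rng.binomial(ploidy, 0.5, size=n).astype(float)
            y += beta_q * (dos - ploidy / 2)
    if cal["resid_var"] > 0:
        y += rng.normal(0.0, math.sqrt(cal["resid_var"]), size=n)
    return pd.Series(y, index=[g.individual for g in genotypes], name="phenotype")
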