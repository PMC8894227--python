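"""Allele-dosage association with a quantitative phenotype.

The joint model regresses the phenotype on the per-haplotype allele copy
numbers (0–4) as fixed effects in ordinary least squares, omitting the most
frequent haplotype to break the sum-to-ploidy collinearity. Haplotype
subtypes that form a group (e.g. A1–A5 grouped as A) enter as one summed
group dosage plus nested subtype-deviation terms. Marginal explained
variance for one haplotype is the R² of the single-regressor model,
expressed in percent. Class summaries compare each genotypic class against
the rest with Welch tests; segregating-population comparisons bin the
offspring by focal-allele dosage and add a linear trend test.

Population-structure correction is deliberately not applied: the model is
plain fixed-effects OLS, validated against permutation p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .model import TetraGenotype

__all__ = [
    "AssociationResult",
    "MarginalResult",
    "fit_joint_model",
    "marginal_r2",
    "class_summary",
    "dosage_class_comparison",
    "dosage_design",
    "prepare_phenotypes",
]

log = logging.getLogger(__name__)


def prepare_phenotypes(phenotypes: pd.Series | pd.DataFrame) -> pd.Series:
    """Average replicate measurements per individual into a single value."""
    if isinstance(phenotypes, pd.DataFrame):
        if phenotypes.shape[1] != 1:
            raise ValueError("phenotype table must have a single value column")
        phenotypes = phenotypes.iloc[:, 0]
    if phenotypes.index.duplicated().any():
        phenotypes = phenotypes.groupby(level=0).mean()
    return phenotypes.astype(float)


def _dosage_table(genotypes: list[TetraGenotype]) -> pd.DataFrame:
    usable = [g for g in genotypes if g.alleles and g.status != "failed"]
    haps = sorted({a for g in usable for a in g.alleles})
    data = {
        g.individual: {h: g.alleles.count(h) for h in haps} for g in usable
    }
    return pd.DataFrame(data, index=haps).T.fillna(0).astype(int)


def dosage_design(
    genotypes: list[TetraGenotype],
    grouping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Individual × term dosage design: plain haplotype dosages, plus for
    each group a summed group dosage and nested subtype deviations (the most
    frequent subtype in each group is the nested reference)."""
    dos = _dosage_table(genotypes)
    grouping = grouping or {}
    groups: dict[str, list[str]] = {}
    for h in dos.columns:
        if h in grouping:
            groups.setdefault(grouping[h], []).append(h)
    out = pd.DataFrame(index=dos.index)
    for grp, members in sorted(groups.items()):
        out[grp] = dos[members].sum(axis=1)
        ref = max(members, key=lambda h: dos[h].sum())
        for h in sorted(members):
            if h != ref:
                out[f"{grp}.{h}"] = dos[h]
    for h in dos.columns:
        if h not in grouping:
            out[h] = dos[h]
    return out


@dataclass
class AssociationResult:
    effects: pd.DataFrame  # index term; columns beta, se, t, p
    r_squared_pct: float
    n: int
    reference: str
    dropped: list[str] = field(default_factory=list)

    def effect(self, term: str) -> pd.Series:
        return self.effects.loc[term]


def _align(
    genotypes: list[TetraGenotype], phenotypes: pd.Series | pd.DataFrame
) -> tuple[list[TetraGenotype], pd.Series]:
    pheno = prepare_phenotypes(phenotypes)
    usable = [g for g in genotypes if g.alleles and g.status != "failed"]
    ids = [g.individual for g in usable]
    common = [i for i in ids if i in pheno.index]
    if len(common) < len(ids) or len(common) < len(pheno):
        warnings.warn(
            f"phenotype/genotype id mismatch: using {len(common)} shared "
            f"individuals of {len(ids)} genotyped / {len(pheno)} phenotyped",
            stacklevel=3,
        )
    keep = set(common)
    return [g for g in usable if g.individual in keep], pheno.loc[common]


def fit_joint_model(
    genotypes: list[TetraGenotype],
    phenotypes: pd.Series | pd.DataFrame,
    grouping: dict[str, str] | None = None,
    reference: str | None = None,
    min_n: int = 20,
) -> AssociationResult:
    """OLS of phenotype on all haplotype dosages simultaneously.

    One reference term (default: the plain term with the largest total
    dosage) is omitted because dosages sum to the ploidy. If the design is
    rank-deficient beyond that planned omission the fit is refused and the
    offending columns are named — silent dropping would reassign effects.
    """
    geno, y = _align(genotypes, phenotypes)
    if len(geno) < min_n:
        raise ValueError(f"need at least {min_n} phenotyped resolved individuals")
    design = dosage_design(geno, grouping)
    plain = [c for c in design.columns if "." not in c]
    if reference is None:
        # most frequent ungrouped haplotype; a group-sum term is never the
        # reference because grouped effects are what the model reports
        group_labels = set((grouping or {}).values())
        candidates = [c for c in plain if c not in group_labels] or plain
        reference = max(candidates, key=lambda c: design[c].sum())
    if reference not in design.columns:
        raise ValueError(f"reference {reference!r} not a design term")
    x = design.drop(columns=[reference])
    x = x.loc[:, x.std() > 0]
    dropped = [c for c in design.columns if c != reference and c not in x.columns]
    if dropped:
        log.info("dropping constant dosage terms: %s", dropped)
    xmat = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(xmat.to_numpy())
    if rank < xmat.shape[1]:
        offenders = []
        for col in x.columns:
            reduced = xmat.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(reduced) == rank:
                offenders.append(col)
        raise ValueError(
            f"design matrix rank-deficient beyond the planned omission of "
            f"{reference!r}; offending columns: {offenders}"
        )
    fit = sm.OLS(y.to_numpy(), xmat).fit()
    effects = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).drop(index="const")
    return AssociationResult(
        effects=effects,
        r_squared_pct=100.0 * float(fit.rsquared),
        n=len(y),
        reference=reference,
        dropped=dropped,
    )


@dataclass
class MarginalResult:
    haplotype: str
    r2_pct: float | None
    beta: float | None
    p: float | None
    n: int
    status: str = "ok"  # ok | untestable


def marginal_r2(
    genotypes: list[TetraGenotype],
    phenotypes: pd.Series | pd.DataFrame,
    haplotype: str,
    grouping: dict[str, str] | None = None,
) -> MarginalResult:
    """Percent phenotypic variance explained by one haplotype's dosage alone.

    ``haplotype`` may be a group label; dosages are summed over the group.
    A constant dosage makes the regression undefined (status untestable).
    """
    geno, y = _align(genotypes, phenotypes)
    grouping = grouping or {}
    x = np.array(
        [
            sum(1 for a in g.alleles if a == haplotype or grouping.get(a, a) == haplotype)
            for g in geno
        ],
        dtype=float,
    )
    if len(x) < 3 or np.std(x) == 0:
        return MarginalResult(haplotype, None, None, None, len(x), "untestable")
    res = sps.linregress(x, y.to_numpy())
    return MarginalResult(
        haplotype=haplotype,
        r2_pct=100.0 * float(res.rvalue**2),
        beta=float(res.slope),
        p=float(res.pvalue),
        n=len(x),
    )


def class_summary(
    genotypes: list[TetraGenotype],
    phenotypes: pd.Series | pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: bool = True,
    min_class_n: int = 4,
) -> pd.DataFrame:
    """Phenotype mean/SD/SE/n per genotypic class with one-vs-rest Welch tests.

    Classes are keyed by the sorted allele multiset. Only classes with at
    least ``min_class_n`` members are tested: the Welch statistic is
    unreliable below that (with two members whose values happen to agree,
    its standard-error estimate collapses and the family-wise error rate
    explodes several-fold). Smaller classes are reported descriptively
    ('singleton'/'small'). The flag column marks classes whose mean differs
    significantly from the rest ('low'/'high'), Bonferroni-corrected across
    tested classes by default.
    """
    geno, y = _align(genotypes, phenotypes)
    keys = pd.Series(
        {g.individual: ",".join(g.alleles) for g in geno}, name="class"
    )
    df = pd.DataFrame({"y": y, "class": keys.loc[y.index]})
    rows = []
    classes = sorted(df["class"].unique())
    testable = [c for c in classes if (df["class"] == c).sum() >= min_class_n]
    m = len(testable) if bonferroni else 1
    for c in classes:
        vals = df.loc[df["class"] == c, "y"]
        rest = df.loc[df["class"] != c, "y"]
        row = {
            "class": c,
            "n": len(vals),
            "mean": vals.mean(),
            "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            "se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
            "p": np.nan,
            "flag": "",
        }
        if c in testable and len(rest) >= 2:
            t, p = sps.ttest_ind(vals, rest, equal_var=False)
            row["p"] = p
            if p * m < alpha:
                row["flag"] = "low" if vals.mean() < rest.mean() else "high"
        elif len(vals) == 1:
            row["flag"] = "singleton"
        else:
            row["flag"] = "small"
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


@dataclass
class SegTestResult:
    focal: str
    bins: pd.DataFrame  # index dosage; n, mean, sd, se
    pairwise_p: pd.DataFrame | None
    trend_slope: float | None
    trend_p: float | None
    status: str = "ok"  # ok | untestable
    excluded_bins: list[int] = field(default_factory=list)


def dosage_class_comparison(
    genotypes: list[TetraGenotype],
    phenotypes: pd.Series | pd.DataFrame,
    focal: str,
    grouping: dict[str, str] | None = None,
) -> SegTestResult:
    """Compare phenotypes across focal-allele dosage groups of a population.

    Offspring are binned by copies of ``focal`` (group labels allowed);
    pairwise Welch tests run between bins with at least two members, and a
    regression of phenotype on dosage provides the trend test. With a single
    occupied bin the comparison is untestable.
    """
    geno, y = _align(genotypes, phenotypes)
    grouping = grouping or {}
    dose = pd.Series(
        {
            g.individual: sum(
                1 for a in g.alleles if a == focal or grouping.get(a, a) == focal
            )
            for g in geno
        }
    ).loc[y.index]
    bins = (
        pd.DataFrame({"y": y, "dose": dose})
        .groupby("dose")["y"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
    )
    bins["se"] = bins["sd"] / np.sqrt(bins["n"])
    excluded = [int(d) for d in bins.index[bins["n"] < 2]]
    if len(bins) < 2:
        return SegTestResult(focal, bins, None, None, None, "untestable", excluded)
    tested = [d for d in bins.index if bins.loc[d, "n"] >= 2]
    pw = pd.DataFrame(np.nan, index=tested, columns=tested)
    for i, a in enumerate(tested):
        for b in tested[i + 1 :]:
            _, p = sps.ttest_ind(
                y[dose == a], y[dose == b], equal_var=False
            )
            pw.loc[a, b] = pw.loc[b, a] = p
    res = sps.linregress(dose.to_numpy(dtype=float), y.to_numpy())
    return SegTestResult(
        focal=focal,
        bins=bins,
        pairwise_p=pw,
        trend_slope=float(res.slope),
        trend_p=float(res.pvalue),
        excluded_bins=excluded,
    )
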