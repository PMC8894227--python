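"""End-to-end pipeline: simulate → callhap → popgen → pedigree → assoc.

Every run writes a manifest (JSON) capturing the configuration snapshot,
seeds, stage list, output paths and record counts; identical configurations
produce byte-identical outputs, manifest included (no timestamps).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, association, haplotype_calling, io, popgen_stats
from . import pedigree_segregation as peds
from . import synthetic_data as syn

__all__ = ["RunManifest", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "callhap", "popgen", "pedigree", "assoc")


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[str]
    outputs: dict[str, dict] = field(default_factory=dict)  # stage → files/counts
    version: str = __version__
    status: str = "ok"
    failed_stage: str | None = None
    error: str | None = None


def _record(manifest: RunManifest, stage: str, files: dict[str, Path], **counts):
    manifest.outputs[stage] = {
        "files": {k: str(v.name) for k, v in files.items()},
        "counts": dict(sorted(counts.items())),
    }


def run_pipeline(
    config: syn.SimConfig,
    out_dir,
    stages: tuple[str, ...] = ALL_STAGES,
    de_novo: bool = False,
    bootstrap: int = 0,
    r2_threshold: float = 0.9,
) -> RunManifest:
    """Run the selected stages in dependency order under one output directory.

    ``callhap`` resolves genotypes with panel-derived rules by default (the
    labels then match the simulated haplotype names, which downstream
    association needs); ``de_novo=True`` switches to blind co-segregation
    calling. A stage failure is recorded in the manifest, which is written
    before the error propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = [s for s in ALL_STAGES if s in stages]
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    manifest = RunManifest(
        config=dataclasses.asdict(config), seed=config.seed, stages=order
    )
    try:
        _run_stages(config, out, order, manifest, de_novo, bootstrap, r2_threshold)
    except Exception as exc:
        manifest.status = "failed"
        manifest.error = str(exc)
        io.write_json(manifest, out / "manifest.json")
        raise
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs missing upstream output {name!r}"
        )
    return p


def _run_stages(config, out, order, manifest, de_novo, bootstrap, r2_threshold):
    for stage in order:
        log.info("stage %s", stage)
        manifest.failed_stage = stage
        if stage == "simulate":
            panel = syn.generate_haplotypes(config)
            cohort = syn.sample_cohort(panel, config.cohort_size, seed=config.seed + 1)
            dosages = syn.observe_dosages(
                cohort,
                panel,
                noise_sd=config.dosage_noise_sd,
                missing_rate=config.missing_rate,
                seed=config.seed + 2,
                amplicon_failure_rate=config.amplicon_failure_rate,
            )
            phenos = syn.simulate_phenotypes(
                cohort, config.phenotype, panel, seed=config.seed + 3
            )
            pedigree, ped_geno = syn.simulate_pedigree(
                panel, config, seed=config.seed + 4
            )
            files = {"panel_fasta": out / "panel.fasta", "panel": out / "panel.tsv"}
            io.write_fasta_panel(panel, files["panel_fasta"])
            io.write_panel_table(panel, files["panel"])
            for amp, mat in dosages.items():
                files[f"dosage_{amp}"] = out / f"dosage_{amp}.tsv"
                io.write_dosage(mat, files[f"dosage_{amp}"])
            files["phenotypes"] = out / "phenotypes.tsv"
            io.write_phenotypes(phenos, files["phenotypes"])
            files["truth_genotypes"] = out / "truth_genotypes.tsv"
            io.write_genotypes(cohort, files["truth_genotypes"])
            files["pedigree"] = out / "pedigree.tsv"
            io.write_pedigree(pedigree, files["pedigree"])
            files["pedigree_genotypes"] = out / "pedigree_genotypes.tsv"
            io.write_genotypes(list(ped_geno.values()), files["pedigree_genotypes"])
            _record(
                manifest, stage, files,
                haplotypes=len(panel.names),
                individuals=len(cohort),
                pedigree_individuals=len(ped_geno),
            )
        elif stage == "callhap":
            panel = io.read_fasta_panel(
                _require(out, "panel.fasta", stage),
                *io.read_panel_table(_require(out, "panel.tsv", stage)),
            )
            matrices = {
                amp.id: io.read_dosage(_require(out, f"dosage_{amp.id}.tsv", stage))
                for amp in panel.amplicons
            }
            files = {"genotypes": out / "genotypes.tsv"}
            if de_novo:
                genotypes, rulesets = haplotype_calling.call_de_novo(
                    matrices, r2_threshold=r2_threshold
                )
            else:
                rulesets = {
                    amp: haplotype_calling.rules_from_incidence(
                        panel.incidence(amp), matrices[amp], amplicon_id=amp
                    )
                    for amp in matrices
                }
                genotypes = haplotype_calling.resolve_genotypes(
                    matrices, rulesets, grouping=panel.grouping
                )
            io.write_genotypes(genotypes, files["genotypes"])
            files["rules"] = out / "rules.tsv"
            io.write_rules(rulesets, files["rules"])
            resolved = sum(g.status == "resolved" for g in genotypes)
            _record(
                manifest, stage, files,
                individuals=len(genotypes), resolved=resolved,
            )
        elif stage == "popgen":
            panel = io.read_fasta_panel(
                _require(out, "panel.fasta", stage),
                *io.read_panel_table(_require(out, "panel.tsv", stage)),
            )
            genotypes = io.read_genotypes(_require(out, "genotypes.tsv", stage))
            div = popgen_stats.diversity(
                genotypes, grouping=panel.grouping, seed=config.seed + 5
            )
            classes = popgen_stats.genotypic_class_summary(genotypes)
            pi = popgen_stats.nucleotide_diversity(panel)
            files = {"stats": out / "popgen_stats.json"}
            io.write_json(
                {"diversity": div, "pi": pi,
                 "gallais_counts": classes.gallais_counts,
                 "n_classes": classes.n_classes,
                 "mean_per_class": classes.mean_per_class},
                files["stats"],
            )
            files["classes"] = out / "genotypic_classes.tsv"
            classes.class_counts.rename("count").rename_axis("class").reset_index().to_csv(
                files["classes"], sep="\t", index=False
            )
            tree = popgen_stats.nj_tree(
                panel, bootstrap_n=bootstrap, seed=config.seed + 6
            )
            files["tree"] = out / "haplotypes.nwk"
            io.write_newick(tree.newick, files["tree"])
            _record(manifest, stage, files, individuals=div.n_individuals)
        elif stage == "pedigree":
            pedigree = io.read_pedigree(_require(out, "pedigree.tsv", stage))
            genotypes = {
                g.individual: g
                for g in io.read_genotypes(
                    _require(out, "pedigree_genotypes.tsv", stage)
                )
            }
            report = peds.scan_pedigree(pedigree, genotypes)
            files = {"report": out / "transmission_report.tsv"}
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "offspring": v.offspring,
                        "mother": v.mother or "0",
                        "father": v.father or "0",
                        "verdict": v.verdict,
                        "detail": str(v.witness or v.reason or ""),
                    }
                    for v in report.verdicts
                ]
            ).to_csv(files["report"], sep="\t", index=False)
            files["edges"] = out / "pedigree_edges.tsv"
            pd.DataFrame(
                [
                    {"offspring": v.offspring, "parent": p, "verdict": v.verdict}
                    for v in report.verdicts
                    for p in (v.mother, v.father)
                    if p is not None
                ]
            ).to_csv(files["edges"], sep="\t", index=False)
            _record(
                manifest, stage, files,
                tested=report.n_tested, incompatible=report.n_incompatible,
            )
        elif stage == "assoc":
            panel = io.read_fasta_panel(
                _require(out, "panel.fasta", stage),
                *io.read_panel_table(_require(out, "panel.tsv", stage)),
            )
            genotypes = io.read_genotypes(_require(out, "genotypes.tsv", stage))
            phenos = io.read_phenotypes(_require(out, "phenotypes.tsv", stage))
            joint = association.fit_joint_model(
                genotypes, phenos, grouping=panel.grouping
            )
            pheno_model = config.phenotype
            marginals = {
                h: association.marginal_r2(
                    genotypes, phenos, h, grouping=panel.grouping
                )
                for h in (pheno_model.effect_group, pheno_model.effect_hap)
            }
            files = {"assoc": out / "association.json"}
            io.write_json({"joint": joint, "marginal": marginals}, files["assoc"])
            files["effects"] = out / "association_effects.tsv"
            joint.effects.rename_axis("term").reset_index().to_csv(
                files["effects"], sep="\t", index=False, float_format="%.6g"
            )
            _record(manifest, stage, files, individuals=joint.n)
    manifest.failed_stage = None
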