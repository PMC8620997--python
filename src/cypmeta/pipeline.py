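"""Stage orchestration: simulate -> QC -> phenotype -> cohorts -> association.

Each stage is a pure function of its inputs plus the run config; a manifest
records input hashes and the seed so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .association import (
    ModelSpec,
    apply_thresholds,
    fit_model,
    fit_stratified,
    test_interaction,
    violin_plot,
)
from .cohorts import (
    AnalysisCohort,
    DrugKnowledge,
    apply_exclusions,
    build_cohorts,
    flag_inhibitors,
    normalize_medications,
    participants_to_frame,
    read_participants,
)
from .config import RunConfig
from .phenotyper import (
    assign_phenotypes,
    call_diplotypes_from_vcf,
    diplotypes_to_frame,
    phenotype_frequencies,
)
from .simulate import SimulationConfig, simulate_cohort
from .star_alleles import (
    AlleleDefinitionTable,
    builtin_table,
    load_allele_definitions,
)
from .variant_qc import (
    QCThresholds,
    SampleQCRecord,
    VariantRecord,
    exclude_samples,
    qc_variants,
)
from .star_alleles import VariantSite

logger = logging.getLogger(__name__)

#: the six antidepressants analysed singly in the reference design
SINGLE_DRUG_FAMILY = {
    "amitriptyline", "citalopram", "fluoxetine",
    "sertraline", "paroxetine", "venlafaxine",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_tables(cfg: RunConfig) -> dict[str, AlleleDefinitionTable]:
    if cfg.allele_definitions:
        return {
            gene: load_allele_definitions(path)
            for gene, path in cfg.allele_definitions.items()
        }
    return {gene: builtin_table(gene) for gene in ("CYP2D6", "CYP2C19")}


def _load_knowledge(cfg: RunConfig) -> DrugKnowledge:
    if cfg.knowledge_dir is None:
        return DrugKnowledge.builtin()
    d = cfg.knowledge_dir
    return DrugKnowledge.from_tsvs(
        d / "drug_synonyms.tsv", d / "cyp_substrates.tsv",
        d / "cyp_inhibitors.tsv", d / "drug_classes.tsv",
    )


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    sim = cfg.simulate
    sim_cfg = SimulationConfig(
        n_participants=sim.n_participants,
        n_antidiabetic_without_diabetes=sim.n_antidiabetic_without_diabetes,
        residual_sd=sim.residual_sd,
        proprietary_rate=sim.proprietary_rate,
        seed=cfg.seed,
    )
    tables = _load_tables(cfg)
    knowledge = _load_knowledge(cfg)
    synonym_pool: dict[str, list[str]] = {}
    for prop, gen in knowledge.synonym_map.items():
        synonym_pool.setdefault(gen, []).append(prop)
    simdir = outdir / "sim"
    truth = simulate_cohort(sim_cfg, tables, simdir, synonym_pool)
    cfg.vcf = simdir / "genotypes.vcf"
    cfg.participants = simdir / "participants.tsv"
    cfg.variant_metrics = simdir / "variant_metrics.tsv"
    cfg.sample_qc = simdir / "sample_qc.tsv"
    cfg.kinship = simdir / "kinship.tsv"
    return {"n_participants": sim.n_participants, "n_clipped": truth.n_clipped}


def stage_qc(cfg: RunConfig, outdir: Path) -> dict:
    t = QCThresholds(**cfg.qc.model_dump())
    metrics = pd.read_csv(cfg.variant_metrics, sep="\t")
    variants = [
        VariantRecord(
            site=VariantSite(r.variant_id, str(r.chrom), int(r.pos), r.ref, r.alt),
            maf=float(r.maf),
            info_score=float(r.info_score),
            genotyped=bool(r.genotyped),
            is_star_defining=bool(r.is_star_defining),
            cluster_review_pass=bool(r.cluster_review_pass),
        )
        for r in metrics.itertuples(index=False)
    ]
    retained, vlog = qc_variants(variants, t)

    sample_qc = pd.read_csv(cfg.sample_qc, sep="\t", dtype={"sample_id": str})
    samples = [
        SampleQCRecord(r.sample_id, float(r.missingness),
                       bool(r.sex_mismatch), bool(r.excess_relatedness))
        for r in sample_qc.itertuples(index=False)
    ]
    kin = pd.read_csv(cfg.kinship, sep="\t", dtype={"id1": str, "id2": str})
    pairs = [(r.id1, r.id2, float(r.kinship)) for r in kin.itertuples(index=False)]
    kept_ids, slog = exclude_samples(samples, pairs, t)

    qcdir = outdir / "qc"
    qcdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"variant_id": [v.site.id for v in retained]}).to_csv(
        qcdir / "retained_variants.tsv", sep="\t", index=False
    )
    pd.DataFrame({"sample_id": kept_ids}).to_csv(
        qcdir / "retained_samples.tsv", sep="\t", index=False
    )
    for name, log in [("variant_exclusions", vlog), ("sample_exclusions", slog)]:
        log.to_frame().to_csv(qcdir / f"{name}.tsv", sep="\t", index=False)
    return {
        "variants_retained": len(retained),
        "variant_exclusions": vlog.counts(),
        "samples_retained": len(kept_ids),
        "sample_exclusions": slog.counts(),
    }


def stage_phenotype(cfg: RunConfig, outdir: Path) -> dict:
    tables = _load_tables(cfg)
    qcdir = outdir / "qc"
    retained = set(
        pd.read_csv(qcdir / "retained_variants.tsv", sep="\t")["variant_id"]
    )
    kept_samples = list(
        pd.read_csv(qcdir / "retained_samples.tsv", sep="\t",
                    dtype={"sample_id": str})["sample_id"]
    )
    frames = []
    for gene, table in tables.items():
        dips = call_diplotypes_from_vcf(
            cfg.vcf, table, samples=kept_samples, retained_variant_ids=retained
        )
        options = (
            {"mapping": cfg.model.activity_mapping}
            if gene == "CYP2D6"
            else {"none_plus_increased": cfg.model.none_plus_increased}
        )
        phens = assign_phenotypes(dips, table, **options)
        frames.append(diplotypes_to_frame(dips, phens))
    pheno = pd.concat(frames, ignore_index=True)
    phedir = outdir / "phenotypes"
    phedir.mkdir(parents=True, exist_ok=True)
    pheno.to_csv(phedir / "phenotypes.tsv", sep="\t", index=False)

    from .phenotyper import MetabolicPhenotype

    freq = phenotype_frequencies(
        [
            MetabolicPhenotype(r.sample_id, r.gene, r.phenotype)
            for r in pheno.itertuples(index=False)
        ]
    )
    freq.to_csv(phedir / "phenotype_frequencies.tsv", sep="\t", index=False)
    return {
        "samples_phenotyped": int(pheno["sample_id"].nunique()),
        "frequencies": freq.to_dict("records"),
    }


def stage_cohorts(cfg: RunConfig, outdir: Path) -> tuple[dict, list[AnalysisCohort], pd.DataFrame]:
    knowledge = _load_knowledge(cfg)
    records = read_participants(cfg.participants)
    kept_ids = set(
        pd.read_csv(outdir / "qc" / "retained_samples.tsv", sep="\t",
                    dtype={"sample_id": str})["sample_id"]
    )
    records = [r for r in records if r.sample_id in kept_ids]

    unmatched: list[str] = []
    from dataclasses import replace as dc_replace

    records = [
        dc_replace(
            r, medications=tuple(normalize_medications(r.medications, knowledge,
                                                       unmatched))
        )
        for r in records
    ]
    records = [flag_inhibitors(r, knowledge) for r in records]
    records, excl = apply_exclusions(records, require_hba1c=cfg.cohorts.require_hba1c)
    cohorts = build_cohorts(
        records,
        knowledge,
        single_drug_min=cfg.cohorts.single_drug_min,
        strict_greater=cfg.cohorts.strict_greater,
        pinned_drugs=cfg.cohorts.pinned_drugs,
    )
    pheno = pd.read_csv(outdir / "phenotypes" / "phenotypes.tsv", sep="\t",
                        dtype={"sample_id": str})
    frame = participants_to_frame(records, pheno)

    codir = outdir / "cohorts"
    codir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"cohort": c.label, "genes": ";".join(c.genes), "n": c.n}
            for c in cohorts
        ]
    ).to_csv(codir / "cohort_summary.tsv", sep="\t", index=False)
    membership = pd.DataFrame(
        [
            {"cohort": c.label, "sample_id": m.sample_id}
            for c in cohorts
            for m in c.members
        ]
    )
    membership.to_csv(codir / "cohort_members.tsv", sep="\t", index=False)
    report = {
        "exclusions": excl,
        "unmatched_medications": len(unmatched),
        "cohorts": {c.label: c.n for c in cohorts},
    }
    return report, cohorts, frame


def stage_association(
    cfg: RunConfig,
    outdir: Path,
    cohorts: list[AnalysisCohort],
    frame: pd.DataFrame,
    min_level_n: int = 2,
) -> dict:
    assocdir = outdir / "association"
    assocdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    for cohort in cohorts:
        ids = {m.sample_id for m in cohort.members}
        df = frame[frame["sample_id"].isin(ids)]
        family = "single_drug" if cohort.label in SINGLE_DRUG_FAMILY else "grouped"
        spec = ModelSpec(
            cohort=cohort.label,
            genes=cohort.genes,
            robust_se=cfg.model.robust_se,
        )
        entry: dict = {"n": len(df), "family": family}
        try:
            pooled = fit_model(df, spec)
            decision = (
                test_interaction(pooled, cfg.model.interaction_alpha)
                if pooled.interaction_terms
                else "pooled"
            )
            entry["interaction_decision"] = decision
            pooled.to_table().to_csv(
                assocdir / f"{cohort.label}_pooled.tsv", sep="\t", index=False
            )
            verdict = apply_thresholds(pooled, family)
            entry["verdicts"] = verdict.labels
            entry["r2_adj"] = round(pooled.r2_adj, 4)
            if decision == "stratify":
                diab, nondiab = fit_stratified(df, spec)
                for res, tag in [(diab, "diabetes"), (nondiab, "no_diabetes")]:
                    res.to_table().to_csv(
                        assocdir / f"{cohort.label}_{tag}.tsv", sep="\t", index=False
                    )
            if cfg.model.make_plots:
                for gene in cohort.genes:
                    violin_plot(
                        df, gene, str(assocdir / f"{cohort.label}_{gene}.png")
                    )
        except ValueError as err:
            entry["error"] = str(err)
            logger.warning("cohort %s not modelled: %s", cohort.label, err)
        report[cohort.label] = entry
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order and write the run report + manifest."""
    simulated = cfg.simulate is not None
    cfg.check_inputs(simulated=simulated)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "version": __version__, "stages": {}}
    try:
        if simulated:
            report["stages"]["simulate"] = stage_simulate(cfg, outdir)
        cfg.check_inputs(simulated=False)
        report["stages"]["qc"] = stage_qc(cfg, outdir)
        report["stages"]["phenotype"] = stage_phenotype(cfg, outdir)
        cohort_report, cohorts, frame = stage_cohorts(cfg, outdir)
        report["stages"]["cohorts"] = cohort_report
        report["stages"]["association"] = stage_association(cfg, outdir, cohorts, frame)
    except StageError:
        raise
    except Exception as err:
        (outdir / "INCOMPLETE").write_text(str(err))
        stage = max(report["stages"], default="validate")
        raise StageError(stage, err) from err

    manifest = {
        "seed": cfg.seed,
        "version": __version__,
        "inputs": {
            label: _sha256(Path(p))
            for label, p in [
                ("vcf", cfg.vcf), ("participants", cfg.participants),
                ("variant_metrics", cfg.variant_metrics),
                ("sample_qc", cfg.sample_qc), ("kinship", cfg.kinship),
            ]
            if p is not None and Path(p).exists()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
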