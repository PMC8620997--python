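"""Synthetic biobank-extract generator.

Emulates the inputs the pipeline expects from a population biobank:

* phased haplotypes for the two pharmacogene regions, drawn per gene as two
  independent star-allele draws per participant (Hardy-Weinberg), rendered
  as a phased VCF carrying exactly each allele's defining variants (plus
  optional decoy sites for the QC stage);
* a participant table with free-text medications (a configurable fraction
  appear under proprietary names to exercise normalization), diabetes and
  antidiabetic flags, and the usual covariates;
* HbA1c generated from the study's linear-model structure
  ``y = X beta + eps`` with i.i.d. Gaussian noise, clipped to the assay
  analytical range (clip events are counted).

Default star-allele frequencies are European-like, so phenotype shares come
out near the published biobank distribution (CYP2D6 PM ~5%, CYP2C19 PM
~3.4%, RM ~25%, UM ~4%).  Everything is driven by one seed; a fixed seed
reproduces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .association import ModelSpec, build_design
from .cohorts import HBA1C_ASSAY_RANGE
from .phenotyper import (
    Diplotype,
    assign_phenotypes,
    call_diplotypes,
)
from .star_alleles import AlleleDefinitionTable, haplotype_from_alleles

#: European-like star-allele frequencies; chosen so that the implied
#: Hardy-Weinberg phenotype shares resemble a large UK cohort.
DEFAULT_ALLELE_FREQS: dict[str, dict[str, float]] = {
    "CYP2D6": {
        "*1": 0.635, "*3": 0.01, "*4": 0.19, "*6": 0.015,
        "*9": 0.03, "*10": 0.02, "*17": 0.02, "*41": 0.08,
    },
    "CYP2C19": {"*1": 0.61, "*2": 0.18, "*3": 0.005, "*17": 0.205},
}

DEFAULT_ANCESTRY_PROBS = {
    "european": 0.938, "admixed_european": 0.025, "african": 0.009,
    "east_asian": 0.001, "south_asian": 0.012, "other": 0.015,
}

DEFAULT_DRUG_PROBS = {
    "amitriptyline": 0.26, "citalopram": 0.20, "fluoxetine": 0.17,
    "sertraline": 0.12, "paroxetine": 0.061, "venlafaxine": 0.060,
    "clomipramine": 0.01, "imipramine": 0.008, "doxepin": 0.006,
    "trimipramine": 0.005, "duloxetine": 0.02, "mirtazapine": 0.03,
    "olanzapine": 0.016, "risperidone": 0.008, "haloperidol": 0.005,
    "aripiprazole": 0.005, "prochlorperazine": 0.027,
    "omeprazole": 0.20, "lansoprazole": 0.05,
    "amiodarone": 0.03, "terbinafine": 0.02, "bupropion": 0.012,
}

#: generative coefficients for the HbA1c model (mmol/mol per unit)
DEFAULT_COEFFICIENTS = {
    "Intercept": 22.0,
    "diabetes": 6.85,
    "CYP2D6 IM": 0.0,
    "CYP2D6 PM": 0.0,
    "CYP2D6 inhibitor": 0.5,
    "CYP2C19 inhibitor": 0.4,
    "takes_antidiabetic": 4.0,
    "bmi": 0.35,
    "age": 0.08,
    "sex[male]": 0.6,
    "ancestry[admixed_european]": 0.3,
    "ancestry[african]": 1.5,
    "ancestry[east_asian]": 0.8,
    "ancestry[south_asian]": 1.2,
    "ancestry[other]": 0.4,
}


@dataclass
class SimulationConfig:
    n_participants: int = 2000
    allele_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(f) for g, f in DEFAULT_ALLELE_FREQS.items()}
    )
    #: optional per-ancestry frequency overrides: {ancestry: {gene: {allele: p}}}
    per_ancestry_freqs: Optional[dict[str, dict[str, dict[str, float]]]] = None
    ancestry_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANCESTRY_PROBS)
    )
    drug_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_PROBS)
    )
    proprietary_rate: float = 0.10
    diabetes_prevalence: float = 0.089
    antidiabetic_given_diabetes: float = 0.70
    n_antidiabetic_without_diabetes: int = 0
    age_range: tuple[float, float] = (40.0, 70.0)
    bmi_mean: float = 28.8
    bmi_sd: float = 5.66
    female_prob: float = 0.689
    missing_hba1c_rate: float = 0.0
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    residual_sd: float = 5.7
    n_decoy_variants: int = 4
    seed: int = 0

    def validate(self) -> None:
        for gene, freqs in self.allele_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{gene} allele frequencies sum to {total}, not 1")
        if self.per_ancestry_freqs:
            for anc, genes in self.per_ancestry_freqs.items():
                for gene, freqs in genes.items():
                    total = sum(freqs.values())
                    if abs(total - 1.0) > 1e-6:
                        raise ValueError(
                            f"{anc}/{gene} allele frequencies sum to {total}"
                        )
        for name, p in [
            ("proprietary_rate", self.proprietary_rate),
            ("diabetes_prevalence", self.diabetes_prevalence),
            ("antidiabetic_given_diabetes", self.antidiabetic_given_diabetes),
            ("female_prob", self.female_prob),
            ("missing_hba1c_rate", self.missing_hba1c_rate),
            *[(f"drug_probs[{d}]", p) for d, p in self.drug_probs.items()],
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth retained from a simulation for round-trip checks."""

    diplotypes: dict[str, dict[str, tuple[str, str]]]  # sample -> gene -> pair
    phenotypes: dict[str, dict[str, str]]
    linear_predictor: dict[str, float]
    n_clipped: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "diplotypes": self.diplotypes,
                "phenotypes": self.phenotypes,
                "linear_predictor": self.linear_predictor,
                "n_clipped": self.n_clipped,
            },
            indent=2,
            sort_keys=True,
        )


def _sample_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# haplotypes

def simulate_haplotypes(
    cfg: SimulationConfig,
    tables: Mapping[str, AlleleDefinitionTable],
    rng: np.random.Generator,
    ancestry: Optional[Sequence[str]] = None,
) -> dict[str, dict[str, tuple[str, str]]]:
    """Draw two star alleles per gene per participant (Hardy-Weinberg).

    Returns ``{sample_id: {gene: (allele_a, allele_b)}}`` with the pair in
    chromosome order (unsorted), so phase is meaningful downstream.
    """
    cfg.validate()
    ids = _sample_ids(cfg.n_participants)
    out: dict[str, dict[str, tuple[str, str]]] = {s: {} for s in ids}
    for gene, table in tables.items():
        base = cfg.allele_freqs[gene]
        missing = set(base) - {a.name for a in table.alleles}
        if missing:
            raise ValueError(
                f"{gene}: frequencies reference undefined alleles {sorted(missing)}"
            )
        for i, s in enumerate(ids):
            freqs = base
            if cfg.per_ancestry_freqs and ancestry is not None:
                freqs = cfg.per_ancestry_freqs.get(ancestry[i], {}).get(gene, base)
            names = list(freqs)
            probs = np.asarray([freqs[n] for n in names])
            a, b = rng.choice(names, size=2, p=probs / probs.sum())
            out[s][gene] = (str(a), str(b))
    return out


def write_phased_vcf(
    path: str | Path,
    tables: Mapping[str, AlleleDefinitionTable],
    hap_alleles: Mapping[str, Mapping[str, tuple[str, str]]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Render star-allele draws as a phased VCF; return variant metrics.

    Every defining variant of every allele a participant carries appears on
    the corresponding haplotype.  ``n_decoy_variants`` non-star sites per
    gene region are added with random low frequencies to give the QC stage
    something to filter.  Metrics (MAF from the realized genotypes, a
    simulated imputation information score, genotyped/star-defining flags)
    are returned as a DataFrame and written by the caller.
    """
    samples = list(hap_alleles)
    sites = []  # (chrom, pos, id, ref, alt, gene, star_defining)
    for gene, table in tables.items():
        for v in table.variant_sites:
            sites.append((v.chrom, v.pos, v.id, v.ref, v.alt, gene, True))
        chrom = table.region[0] if table.region else table.variant_sites[0].chrom
        lo = min(v.pos for v in table.variant_sites)
        for j in range(cfg.n_decoy_variants):
            pos = int(lo - 5000 - 200 * j)
            sites.append((chrom, pos, f"{gene.lower()}_decoy{j}", "A", "G", gene, False))
    sites.sort(key=lambda s: (s[0], s[1]))

    # per-sample haplotype variant sets
    carries: dict[str, tuple[set[str], set[str]]] = {}
    for s in samples:
        hap0: set[str] = set()
        hap1: set[str] = set()
        for gene, (a, b) in hap_alleles[s].items():
            table = tables[gene]
            hap0.update(v.id for v in table.allele(a).defining_variants)
            hap1.update(v.id for v in table.allele(b).defining_variants)
        carries[s] = (hap0, hap1)

    header = pysam.VariantHeader()
    header.add_line("##genome_build=" + next(iter(tables.values())).build)
    for contig in sorted({s[0] for s in sites}):
        header.add_line(f"##contig=<ID={contig},length=250000000>")
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    for s in samples:
        header.add_sample(s)

    metrics_rows = []
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, pos, vid, ref, alt, gene, star in sites:
            if star:
                gts = {
                    s: (int(vid in carries[s][0]), int(vid in carries[s][1]))
                    for s in samples
                }
                info_score = round(float(rng.uniform(0.85, 0.99)), 3)
                genotyped = False
            else:
                p = float(rng.uniform(0.001, 0.05))
                draws = rng.random((len(samples), 2)) < p
                gts = {s: (int(d[0]), int(d[1])) for s, d in zip(samples, draws)}
                info_score = round(float(rng.uniform(0.1, 0.9)), 3)
                genotyped = bool(rng.random() < 0.5)
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, alleles=(ref, alt), id=vid
            )
            rec.qual = 100
            for s in samples:
                rec.samples[s]["GT"] = gts[s]
                rec.samples[s].phased = True
            vcf.write(rec)
            af = sum(a + b for a, b in gts.values()) / (2 * len(samples))
            maf = min(af, 1 - af)
            metrics_rows.append(
                {
                    "variant_id": vid, "chrom": chrom, "pos": pos, "ref": ref,
                    "alt": alt, "gene": gene, "maf": round(maf, 6),
                    "info_score": info_score, "genotyped": genotyped,
                    "is_star_defining": star,
                    "cluster_review_pass": genotyped,
                }
            )
    return pd.DataFrame(metrics_rows)


# ---------------------------------------------------------------------------
# participants

def simulate_participants(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    synonym_pool: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Draw medications, diagnosis flags and covariates for every sample.

    Medications are independent Bernoulli draws per drug; samples drawing
    nothing get one drug assigned from the normalized probability vector so
    that every participant is a psychotropic user, as in the source extract.
    A ``proprietary_rate`` fraction of mentions are swapped for a
    proprietary synonym; ``n_antidiabetic_without_diabetes`` rows violate
    the antidiabetic/diabetes consistency rule on purpose.  HbA1c is filled
    in later from the genetic truth (see :func:`simulate_cohort`).
    """
    cfg.validate()
    n = cfg.n_participants
    ids = _sample_ids(n)
    drugs = list(cfg.drug_probs)
    probs = np.asarray([cfg.drug_probs[d] for d in drugs])

    taken = rng.random((n, len(drugs))) < probs
    none = ~taken.any(axis=1)
    if none.any() and probs.sum() > 0:
        fallback = rng.choice(len(drugs), size=int(none.sum()), p=probs / probs.sum())
        for row, j in zip(np.flatnonzero(none), fallback):
            taken[row, j] = True

    ancestry = rng.choice(
        list(cfg.ancestry_probs),
        size=n,
        p=np.asarray(list(cfg.ancestry_probs.values()))
        / sum(cfg.ancestry_probs.values()),
    )
    diabetes = rng.random(n) < cfg.diabetes_prevalence
    antidiabetic = diabetes & (rng.random(n) < cfg.antidiabetic_given_diabetes)
    # inject inconsistent rows (taking antidiabetics while denying diabetes)
    eligible = np.flatnonzero(~diabetes)
    n_bad = min(cfg.n_antidiabetic_without_diabetes, len(eligible))
    bad = rng.choice(eligible, size=n_bad, replace=False)
    antidiabetic[bad] = True

    age = rng.uniform(*cfg.age_range, size=n)
    bmi = np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=n), 13.0, None)
    sex = np.where(rng.random(n) < cfg.female_prob, "F", "M")

    med_lists = []
    for i in range(n):
        meds = [drugs[j] for j in np.flatnonzero(taken[i])]
        if synonym_pool and cfg.proprietary_rate > 0:
            meds = [
                str(rng.choice(synonym_pool[m]))
                if m in synonym_pool and rng.random() < cfg.proprietary_rate
                else m
                for m in meds
            ]
        med_lists.append(";".join(meds))

    return pd.DataFrame(
        {
            "sample_id": ids,
            "medications": med_lists,
            "hba1c": np.nan,
            "diabetes": diabetes,
            "takes_antidiabetic": antidiabetic,
            "bmi": np.round(bmi, 2),
            "age": np.round(age, 1),
            "sex": sex,
            "ancestry": ancestry,
        }
    )


# ---------------------------------------------------------------------------
# outcome

def simulate_hba1c(
    design: pd.DataFrame,
    coefficients: Mapping[str, float],
    residual_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Generate HbA1c as ``X beta + eps`` and clip to the assay range.

    Every coefficient name must correspond to a design column; the clip
    count is returned so extreme simulations can be audited.
    """
    unknown = [c for c in coefficients if c not in design.columns]
    if unknown:
        raise ValueError(f"coefficients without design columns: {unknown}")
    eta = np.zeros(len(design))
    for name, beta in coefficients.items():
        eta += beta * design[name].to_numpy(dtype=float)
    y = eta + rng.normal(0.0, residual_sd, size=len(design))
    lo, hi = HBA1C_ASSAY_RANGE
    n_clipped = int(((y < lo) | (y > hi)).sum())
    return np.clip(y, lo, hi), n_clipped


def linear_predictor(
    df: pd.DataFrame, coefficients: Mapping[str, float], spec: ModelSpec
) -> np.ndarray:
    """Evaluate the generative linear predictor on a participant frame."""
    X, _, _ = build_design(df, spec)
    eta = np.zeros(len(df))
    for name, beta in coefficients.items():
        if name in X.columns:
            eta += beta * X[name].to_numpy()
    return eta


# ---------------------------------------------------------------------------
# one-call cohort simulation

def simulate_cohort(
    cfg: SimulationConfig,
    tables: Mapping[str, AlleleDefinitionTable],
    outdir: str | Path,
    synonym_pool: Optional[Mapping[str, Sequence[str]]] = None,
) -> SyntheticTruth:
    """Simulate a full fixture directory: VCF, metrics, participants, truth.

    Writes ``genotypes.vcf``, ``variant_metrics.tsv``, ``sample_qc.tsv``,
    ``kinship.tsv``, ``participants.tsv``, ``truth.json`` and
    ``sim_config.json`` under ``outdir``.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    participants = simulate_participants(cfg, rng, synonym_pool)
    hap_alleles = simulate_haplotypes(
        cfg, tables, rng, ancestry=list(participants["ancestry"])
    )
    metrics = write_phased_vcf(
        outdir / "genotypes.vcf", tables, hap_alleles, cfg, rng
    )

    # true diplotypes and phenotypes straight from the draws
    diplotypes: dict[str, dict[str, tuple[str, str]]] = {}
    phenotypes: dict[str, dict[str, str]] = {}
    pheno_cols: dict[str, list[str]] = {}
    for gene, table in tables.items():
        phased = {
            s: (
                haplotype_from_alleles([hap_alleles[s][gene][0]], table),
                haplotype_from_alleles([hap_alleles[s][gene][1]], table),
            )
            for s in hap_alleles
        }
        dips = call_diplotypes(phased, table)
        phens = assign_phenotypes(dips, table)
        pheno_cols[f"{gene.lower()}_phenotype"] = [p.label for p in phens]
        for d, p in zip(dips, phens):
            diplotypes.setdefault(d.sample_id, {})[gene] = tuple(
                sorted([d.call_a.allele_name, d.call_b.allele_name])
            )
            phenotypes.setdefault(p.sample_id, {})[gene] = p.label

    frame = participants.assign(**pheno_cols)
    spec = ModelSpec(
        cohort="synthetic",
        genes=tuple(tables),
        include_interactions=any(":" in c for c in cfg.coefficients),
    )
    X, _, _ = build_design(frame, spec)
    coeffs = {c: b for c, b in cfg.coefficients.items() if c in X.columns}
    y, n_clipped = simulate_hba1c(X, coeffs, cfg.residual_sd, rng)
    eta = np.zeros(len(frame))
    for name, beta in coeffs.items():
        eta += beta * X[name].to_numpy()
    participants["hba1c"] = np.round(y, 1)
    if cfg.missing_hba1c_rate > 0:
        drop = rng.random(len(participants)) < cfg.missing_hba1c_rate
        participants.loc[drop, "hba1c"] = np.nan

    truth = SyntheticTruth(
        diplotypes=diplotypes,
        phenotypes=phenotypes,
        linear_predictor={
            s: round(float(e), 4) for s, e in zip(participants["sample_id"], eta)
        },
        n_clipped=n_clipped,
    )

    participants.to_csv(outdir / "participants.tsv", sep="\t", index=False)
    metrics.to_csv(outdir / "variant_metrics.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": participants["sample_id"],
            "missingness": 0.0,
            "sex_mismatch": False,
            "excess_relatedness": False,
        }
    ).to_csv(outdir / "sample_qc.tsv", sep="\t", index=False)
    (outdir / "kinship.tsv").write_text("id1\tid2\tkinship\n")
    (outdir / "truth.json").write_text(truth.to_json())
    (outdir / "sim_config.json").write_text(cfg.to_json())
    return truth
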