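"""Diplotype calling and metabolizer-phenotype assignment.

Phased per-sample genotypes are matched haplotype-by-haplotype against a
star-allele definition table, producing one unordered diplotype per sample
per gene.  CYP2D6 diplotypes are binned by Gaedigk activity score
(0 -> poor, 0.5-1 -> intermediate, 1.5-2 -> normal metabolizer); without
copy-number input no ultra-rapid CYP2D6 call is possible and
increased-function CYP2D6 alleles are refused rather than silently binned.
CYP2C19 phenotypes come from the pair of function classes (two no-function
alleles -> PM, one -> IM, normal/normal -> NM, normal/increased -> RM,
increased/increased -> UM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import pysam

from .star_alleles import (
    AlleleDefinitionTable,
    HaplotypeCall,
    Haplotype,
    activity_score,
    match_haplotype,
)

CYP2D6_LABELS = ("NM", "IM", "PM")
CYP2C19_LABELS = ("NM", "IM", "PM", "RM", "UM")

#: Gaedigk activity-score bins contemporary with pre-2019 guidance.
ACTIVITY_PHENOTYPE_MAPS: dict[str, dict[float, str]] = {
    "gaedigk": {0.0: "PM", 0.5: "IM", 1.0: "IM", 1.5: "NM", 2.0: "NM"},
    # post-2019 recalibration: identical at 0.5-step granularity, but the
    # IM ceiling is defined at 1.0 and NM starts at 1.25
    "cpic2019": {0.0: "PM", 0.5: "IM", 1.0: "IM", 1.5: "NM", 2.0: "NM"},
}


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of haplotype calls for one sample at one gene."""

    sample_id: str
    gene: str
    call_a: HaplotypeCall
    call_b: HaplotypeCall
    activity: Optional[float] = None  # CYP2D6 only

    def __post_init__(self) -> None:
        # canonical order makes (a, b) == (b, a)
        if self.call_a.allele_name > self.call_b.allele_name:
            a, b = self.call_a, self.call_b
            object.__setattr__(self, "call_a", b)
            object.__setattr__(self, "call_b", a)

    @property
    def name(self) -> str:
        a, b = sorted([self.call_a.allele_name, self.call_b.allele_name])
        return f"{a}/{b}"


@dataclass(frozen=True)
class MetabolicPhenotype:
    sample_id: str
    gene: str
    label: str

    def __post_init__(self) -> None:
        valid = CYP2D6_LABELS if self.gene == "CYP2D6" else CYP2C19_LABELS
        if self.label not in valid:
            raise ValueError(f"{self.label!r} is not a {self.gene} phenotype label")


# ---------------------------------------------------------------------------
# diplotype calling

PhasedGenotypes = Mapping[str, tuple[Haplotype, Haplotype]]


def call_diplotypes(
    phased: PhasedGenotypes, table: AlleleDefinitionTable
) -> list[Diplotype]:
    """Call one diplotype per sample from resolved haplotype pairs."""
    out = []
    for sample_id, (hap_a, hap_b) in phased.items():
        call_a = match_haplotype(hap_a, table)
        call_b = match_haplotype(hap_b, table)
        activity = None
        if table.gene == "CYP2D6":
            activity = activity_score(call_a.allele_name, call_b.allele_name, table)
        out.append(Diplotype(sample_id, table.gene, call_a, call_b, activity))
    return out


def read_phased_haplotypes(
    vcf_path: str | Path,
    table: AlleleDefinitionTable,
    samples: Optional[Sequence[str]] = None,
    retained_variant_ids: Optional[set[str]] = None,
) -> dict[str, tuple[dict[str, Optional[int]], dict[str, Optional[int]]]]:
    """Extract the two per-sample haplotypes over a table's defining sites.

    Sites are matched by variant id first, then by (chrom, pos, ref, alt).
    Heterozygous genotypes must be phased ("|" separator); an unphased het
    raises with the offending sample and site.  Defining sites absent from
    the VCF (or excluded by QC via ``retained_variant_ids``) are recorded as
    missing and treated as reference during matching.
    """
    sites = table.variant_sites
    if retained_variant_ids is not None:
        sites = [s for s in sites if s.id in retained_variant_ids]
    by_id = {s.id: s for s in sites}
    by_coord = {(s.chrom, s.pos, s.ref, s.alt): s.id for s in sites}

    with pysam.VariantFile(str(vcf_path)) as vcf:
        build = vcf.header.records and _header_build(vcf.header)
        if build and build != table.build:
            warnings.warn(
                f"VCF genome build {build!r} does not match definition table "
                f"build {table.build!r}"
            )
        vcf_samples = list(vcf.header.samples)
        if samples is None:
            samples = vcf_samples
        haps: dict[str, tuple[dict, dict]] = {
            s: ({sid: None for sid in by_id}, {sid: None for sid in by_id})
            for s in samples
        }
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else None
            site_id = None
            if rec.id in by_id:
                site_id = rec.id
            elif alt is not None:
                site_id = by_coord.get((str(rec.chrom), rec.pos, rec.ref, alt))
            if site_id is None:
                continue
            for s in samples:
                gt = rec.samples[s]
                alleles = gt["GT"]
                if alleles is None or any(a is None for a in alleles):
                    continue  # missing genotype stays None
                if len(alleles) != 2:
                    raise ValueError(f"sample {s} site {site_id}: not diploid")
                if alleles[0] != alleles[1] and not gt.phased:
                    raise ValueError(
                        f"sample {s} site {site_id}: unphased heterozygous genotype"
                    )
                haps[s][0][site_id] = int(alleles[0] > 0)
                haps[s][1][site_id] = int(alleles[1] > 0)
    return haps


def _header_build(header: pysam.VariantHeader) -> Optional[str]:
    for rec in header.records:
        if rec.key == "genome_build":
            return str(rec.value)
    return None


def call_diplotypes_from_vcf(
    vcf_path: str | Path,
    table: AlleleDefinitionTable,
    samples: Optional[Sequence[str]] = None,
    retained_variant_ids: Optional[set[str]] = None,
) -> list[Diplotype]:
    haps = read_phased_haplotypes(vcf_path, table, samples, retained_variant_ids)
    return call_diplotypes(haps, table)


# ---------------------------------------------------------------------------
# phenotype assignment

def assign_cyp2d6_phenotype(
    d: Diplotype, mapping: str | Mapping[float, str] = "gaedigk"
) -> MetabolicPhenotype:
    """Bin a CYP2D6 diplotype's activity score into PM/IM/NM."""
    if d.gene != "CYP2D6":
        raise ValueError(f"expected a CYP2D6 diplotype, got {d.gene}")
    if d.activity is None:
        raise ValueError(f"{d.sample_id}: diplotype has no activity score")
    bins = ACTIVITY_PHENOTYPE_MAPS[mapping] if isinstance(mapping, str) else mapping
    try:
        label = bins[d.activity]
    except KeyError:
        raise ValueError(
            f"{d.sample_id}: activity {d.activity} outside the mapping "
            f"{sorted(bins)}"
        ) from None
    return MetabolicPhenotype(d.sample_id, "CYP2D6", label)


def assign_cyp2c19_phenotype(
    d: Diplotype,
    table: AlleleDefinitionTable,
    none_plus_increased: str = "IM",
) -> MetabolicPhenotype:
    """Assign a CYP2C19 phenotype from the pair of allele function classes.

    ``none_plus_increased`` controls the no-function/increased-function
    combination (e.g. *2/*17), conventionally binned IM.
    """
    if d.gene != "CYP2C19":
        raise ValueError(f"expected a CYP2C19 diplotype, got {d.gene}")
    funcs = sorted(
        table.allele(c.allele_name).function_class
        for c in (d.call_a, d.call_b)
    )
    known = {"none", "normal", "increased"}
    if not set(funcs) <= known:
        raise ValueError(f"{d.sample_id}: unmapped function classes {funcs}")
    pair = tuple(funcs)
    if pair == ("none", "none"):
        label = "PM"
    elif pair == ("none", "normal"):
        label = "IM"
    elif pair == ("increased", "none"):
        label = none_plus_increased
    elif pair == ("normal", "normal"):
        label = "NM"
    elif pair == ("increased", "normal"):
        label = "RM"
    elif pair == ("increased", "increased"):
        label = "UM"
    else:  # pragma: no cover - exhaustive over the known classes
        raise ValueError(f"{d.sample_id}: unexpected function pair {pair}")
    return MetabolicPhenotype(d.sample_id, "CYP2C19", label)


def assign_phenotypes(
    diplotypes: Sequence[Diplotype],
    table: AlleleDefinitionTable,
    **options,
) -> list[MetabolicPhenotype]:
    if table.gene == "CYP2D6":
        return [assign_cyp2d6_phenotype(d, **options) for d in diplotypes]
    return [assign_cyp2c19_phenotype(d, table, **options) for d in diplotypes]


def phenotype_frequencies(
    phenotypes: Sequence[MetabolicPhenotype],
    sample_ids: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Count/percentage table per gene per label, biobank-report style.

    ``sample_ids`` optionally restricts to a cohort.  Percentages are within
    gene and rounded to one decimal, with a ``formatted`` column rendered as
    ``count (pct%)``.
    """
    rows = [
        p for p in phenotypes
        if sample_ids is None or p.sample_id in sample_ids
    ]
    if not rows:
        warnings.warn("empty cohort: no phenotypes to tabulate")
        return pd.DataFrame(columns=["gene", "label", "count", "pct", "formatted"])
    df = pd.DataFrame({"gene": [p.gene for p in rows], "label": [p.label for p in rows]})
    out = []
    for gene, g in df.groupby("gene"):
        labels = CYP2D6_LABELS if gene == "CYP2D6" else CYP2C19_LABELS
        total = len(g)
        for label in labels:
            count = int((g["label"] == label).sum())
            pct = round(100.0 * count / total, 1)
            out.append(
                {"gene": gene, "label": label, "count": count, "pct": pct,
                 "formatted": f"{count} ({pct}%)"}
            )
    return pd.DataFrame(out)


def diplotypes_to_frame(
    diplotypes: Sequence[Diplotype], phenotypes: Sequence[MetabolicPhenotype]
) -> pd.DataFrame:
    """Merge diplotypes and phenotype labels into the output table layout."""
    pheno = {(p.sample_id, p.gene): p.label for p in phenotypes}
    return pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in diplotypes],
            "gene": [d.gene for d in diplotypes],
            "diplotype": [d.name for d in diplotypes],
            "activity": pd.array(
                [d.activity for d in diplotypes], dtype="float64"
            ),
            "phenotype": [pheno.get((d.sample_id, d.gene)) for d in diplotypes],
        }
    )
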