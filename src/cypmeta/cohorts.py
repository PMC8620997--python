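"""Analysis-cohort construction from a raw participant table.

Free-text medication names are folded to lower case and mapped to generic
names through a proprietary-name synonym table; unmatched names pass through
and are logged.  Exclusions remove participants who report antidiabetic
medication without a diabetes diagnosis (uncertain status) and, when the
outcome is required, participants without an HbA1c measurement.

Cohorts follow the study design for biobank psychotropic users: every
antidepressant taken by at least ``single_drug_min`` participants (default
1800) gets its own cohort; the remaining tricyclics form a grouped cohort
that deliberately excludes amitriptyline so the most common drug cannot
dominate the group; and all CYP2D6-substrate antipsychotics form one cohort.
Tricyclic substrates of both enzymes are modelled with both genes' phenotype
terms in a single model, so their cohorts carry both genes.  A participant
taking several study drugs contributes to every matching cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from importlib import resources

logger = logging.getLogger(__name__)

HBA1C_ASSAY_RANGE = (15.0, 184.0)  # analytical range, mmol/mol


@dataclass(frozen=True)
class ParticipantRecord:
    sample_id: str
    medications: tuple[str, ...] = ()
    hba1c: Optional[float] = None
    diabetes: bool = False
    takes_antidiabetic: bool = False
    bmi: Optional[float] = None
    age: Optional[float] = None
    sex: Optional[str] = None  # "F" / "M"
    ancestry: Optional[str] = None
    takes_cyp2d6_inhibitor: bool = False
    takes_cyp2c19_inhibitor: bool = False

    def __post_init__(self) -> None:
        if self.hba1c is not None and not (
            HBA1C_ASSAY_RANGE[0] <= self.hba1c <= HBA1C_ASSAY_RANGE[1]
        ):
            raise ValueError(
                f"{self.sample_id}: HbA1c {self.hba1c} outside the assay range "
                f"{HBA1C_ASSAY_RANGE}"
            )
        if self.bmi is not None and self.bmi <= 0:
            raise ValueError(f"{self.sample_id}: BMI must be positive")


@dataclass
class DrugKnowledge:
    """Synonym, substrate, inhibitor and drug-class lookups (generic names)."""

    synonym_map: dict[str, str]
    cyp2d6_substrates: set[str]
    cyp2c19_substrates: set[str]
    cyp2d6_inhibitors: set[str]
    cyp2c19_inhibitors: set[str]
    drug_class: dict[str, str]

    def __post_init__(self) -> None:
        generics = set(self.synonym_map.values()) | set(self.drug_class)
        for name, pool in [
            ("substrate", self.cyp2d6_substrates | self.cyp2c19_substrates),
            ("inhibitor", self.cyp2d6_inhibitors | self.cyp2c19_inhibitors),
        ]:
            stray = pool - generics
            if stray:
                raise ValueError(f"{name} names not known as generics: {sorted(stray)}")

    def substrates(self, gene: str) -> set[str]:
        return self.cyp2d6_substrates if gene == "CYP2D6" else self.cyp2c19_substrates

    @classmethod
    def from_tsvs(
        cls,
        synonyms: str | Path,
        substrates: str | Path,
        inhibitors: str | Path,
        classes: str | Path,
    ) -> "DrugKnowledge":
        syn = pd.read_csv(synonyms, sep="\t")
        sub = pd.read_csv(substrates, sep="\t")
        inh = pd.read_csv(inhibitors, sep="\t")
        cls_df = pd.read_csv(classes, sep="\t")
        for df in (syn, sub, inh, cls_df):
            if df.empty:
                raise ValueError("empty drug-knowledge table")
        return cls(
            synonym_map=dict(zip(syn["proprietary"].str.lower(), syn["generic"].str.lower())),
            cyp2d6_substrates=set(sub.loc[sub["gene"] == "CYP2D6", "drug"].str.lower()),
            cyp2c19_substrates=set(sub.loc[sub["gene"] == "CYP2C19", "drug"].str.lower()),
            cyp2d6_inhibitors=set(inh.loc[inh["gene"] == "CYP2D6", "drug"].str.lower()),
            cyp2c19_inhibitors=set(inh.loc[inh["gene"] == "CYP2C19", "drug"].str.lower()),
            drug_class=dict(zip(cls_df["drug"].str.lower(), cls_df["drug_class"])),
        )

    @classmethod
    def builtin(cls) -> "DrugKnowledge":
        data = resources.files("cypmeta") / "data"
        return cls.from_tsvs(
            str(data / "drug_synonyms.tsv"),
            str(data / "cyp_substrates.tsv"),
            str(data / "cyp_inhibitors.tsv"),
            str(data / "drug_classes.tsv"),
        )


@dataclass
class AnalysisCohort:
    label: str
    genes: tuple[str, ...]
    members: list[ParticipantRecord] = field(default_factory=list)
    drugs: frozenset[str] = frozenset()

    @property
    def n(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# operations

def normalize_medications(
    raw_names: Iterable[str], k: DrugKnowledge, unmatched_log: Optional[list[str]] = None
) -> list[str]:
    """Fold free-text names to generic names, case-insensitively.

    Proprietary names map through the synonym table; names already generic
    pass through; anything else passes through lower-cased and is logged.
    """
    known_generics = set(k.synonym_map.values()) | set(k.drug_class)
    out = []
    for raw in raw_names:
        name = raw.strip().lower()
        if not name:
            continue
        if name in k.synonym_map:
            out.append(k.synonym_map[name])
        elif name in known_generics:
            out.append(name)
        else:
            logger.info("unmatched medication name: %r", raw)
            if unmatched_log is not None:
                unmatched_log.append(raw)
            out.append(name)
    return out


def flag_inhibitors(record: ParticipantRecord, k: DrugKnowledge) -> ParticipantRecord:
    """Set the enzyme-inhibitor exposure flags from normalized medications."""
    meds = set(record.medications)
    return replace(
        record,
        takes_cyp2d6_inhibitor=bool(meds & k.cyp2d6_inhibitors),
        takes_cyp2c19_inhibitor=bool(meds & k.cyp2c19_inhibitors),
    )


def apply_exclusions(
    records: Sequence[ParticipantRecord], require_hba1c: bool = True
) -> tuple[list[ParticipantRecord], dict[str, int]]:
    """Remove uncertain-diagnosis and (optionally) missing-outcome records.

    A participant reporting antidiabetic medication while denying diabetes
    has an uncertain diagnosis and is removed; missing HbA1c removes the
    record when the outcome is required.  One reason per removal, checked in
    that order.
    """
    kept: list[ParticipantRecord] = []
    log = {"antidiabetic_without_diabetes": 0, "missing_hba1c": 0}
    for r in records:
        if r.takes_antidiabetic and not r.diabetes:
            log["antidiabetic_without_diabetes"] += 1
        elif require_hba1c and (r.hba1c is None or math.isnan(r.hba1c)):
            log["missing_hba1c"] += 1
        else:
            kept.append(r)
    return kept, log


ANTIDEPRESSANT_CLASSES = {"SSRI", "SNRI", "TCA", "other_antidepressant"}


def build_cohorts(
    records: Sequence[ParticipantRecord],
    k: DrugKnowledge,
    single_drug_min: int = 1800,
    strict_greater: bool = False,
    pinned_drugs: Optional[Sequence[str]] = None,
) -> list[AnalysisCohort]:
    """Build the single-drug, grouped-tricyclic and antipsychotic cohorts.

    ``pinned_drugs`` forces single-drug cohorts for the named antidepressants
    regardless of observed counts (useful for reproducing a fixed published
    grouping on a synthetic cohort of any size).  ``strict_greater`` switches
    the threshold comparator from ``>=`` to ``>``.
    """
    if not k.drug_class:
        raise ValueError("empty drug-knowledge tables")

    def genes_for(drug: str) -> tuple[str, ...]:
        genes = []
        if drug in k.cyp2d6_substrates:
            genes.append("CYP2D6")
        if drug in k.cyp2c19_substrates:
            genes.append("CYP2C19")
        return tuple(genes)

    counts: dict[str, int] = {}
    for r in records:
        for drug in set(r.medications):
            if k.drug_class.get(drug) in ANTIDEPRESSANT_CLASSES:
                counts[drug] = counts.get(drug, 0) + 1

    def above(n: int) -> bool:
        return n > single_drug_min if strict_greater else n >= single_drug_min

    single = sorted(
        d for d, n in counts.items()
        if (above(n) or (pinned_drugs is not None and d in pinned_drugs))
        and genes_for(d)
    )

    cohorts: list[AnalysisCohort] = []
    for drug in single:
        members = [r for r in records if drug in r.medications]
        cohorts.append(
            AnalysisCohort(drug, genes_for(drug), members, frozenset({drug}))
        )

    tca_drugs = {
        d for d, c in k.drug_class.items() if c == "TCA" and d != "amitriptyline"
    }
    tca_members = [r for r in records if set(r.medications) & tca_drugs]
    if tca_members:
        cohorts.append(
            AnalysisCohort(
                "tricyclics_excl_amitriptyline",
                ("CYP2D6", "CYP2C19"),
                tca_members,
                frozenset(tca_drugs),
            )
        )

    ap_drugs = {
        d for d, c in k.drug_class.items()
        if c == "antipsychotic" and d in k.cyp2d6_substrates
    }
    ap_members = [r for r in records if set(r.medications) & ap_drugs]
    if ap_members:
        cohorts.append(
            AnalysisCohort(
                "antipsychotics_cyp2d6", ("CYP2D6",), ap_members, frozenset(ap_drugs)
            )
        )
    return cohorts


# ---------------------------------------------------------------------------
# table I/O

PARTICIPANT_COLUMNS = [
    "sample_id", "medications", "hba1c", "diabetes", "takes_antidiabetic",
    "bmi", "age", "sex", "ancestry",
]


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read a participant TSV (medications as a ';'-separated list)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(PARTICIPANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"participant table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        meds = () if pd.isna(row.medications) or not row.medications else tuple(
            m for m in str(row.medications).split(";") if m
        )
        hba1c = None if pd.isna(row.hba1c) else float(row.hba1c)
        records.append(
            ParticipantRecord(
                sample_id=str(row.sample_id),
                medications=meds,
                hba1c=hba1c,
                diabetes=bool(row.diabetes),
                takes_antidiabetic=bool(row.takes_antidiabetic),
                bmi=float(row.bmi) if not pd.isna(row.bmi) else None,
                age=float(row.age) if not pd.isna(row.age) else None,
                sex=str(row.sex),
                ancestry=str(row.ancestry),
            )
        )
    return records


def participants_to_frame(
    records: Sequence[ParticipantRecord],
    phenotypes: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Flatten records (plus optional per-gene phenotype labels) for modelling.

    ``phenotypes`` is the phenotyper output table (sample_id, gene,
    phenotype); labels arrive as ``cyp2d6_phenotype`` / ``cyp2c19_phenotype``
    columns.
    """
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "medications": [";".join(r.medications) for r in records],
            "hba1c": [r.hba1c for r in records],
            "diabetes": [r.diabetes for r in records],
            "takes_antidiabetic": [r.takes_antidiabetic for r in records],
            "bmi": [r.bmi for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "ancestry": [r.ancestry for r in records],
            "takes_cyp2d6_inhibitor": [r.takes_cyp2d6_inhibitor for r in records],
            "takes_cyp2c19_inhibitor": [r.takes_cyp2c19_inhibitor for r in records],
        }
    )
    if phenotypes is not None:
        for gene in ("CYP2D6", "CYP2C19"):
            sub = phenotypes.loc[phenotypes["gene"] == gene,
                                 ["sample_id", "phenotype"]]
            sub = sub.rename(columns={"phenotype": f"{gene.lower()}_phenotype"})
            df = df.merge(sub, on="sample_id", how="left")
    return df
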