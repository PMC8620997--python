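"""Run configuration: one validated YAML file drives a whole pipeline run."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class QCSection(BaseModel):
    maf_min: float = 0.01
    info_min: float = 0.3
    rare_rescue_info_min: float = 0.6
    sample_missingness_max: float = 0.10
    kinship_max: float = 0.083

    @model_validator(mode="after")
    def _ordered(self) -> "QCSection":
        if self.rare_rescue_info_min < self.info_min:
            raise ValueError("rare_rescue_info_min must be >= info_min")
        return self


class CohortSection(BaseModel):
    single_drug_min: int = 1800
    strict_greater: bool = False
    pinned_drugs: Optional[list[str]] = None
    require_hba1c: bool = True


class ModelSection(BaseModel):
    activity_mapping: str = "gaedigk"
    none_plus_increased: str = "IM"
    interaction_alpha: float = 0.05
    robust_se: bool = False
    make_plots: bool = False


class SimulateSection(BaseModel):
    n_participants: int = 500
    n_antidiabetic_without_diabetes: int = 0
    residual_sd: float = 5.7
    proprietary_rate: float = 0.10


class RunConfig(BaseModel):
    """Paths plus per-stage options; all paths checked at validation time."""

    output_dir: Path
    seed: int = 0
    vcf: Optional[Path] = None
    participants: Optional[Path] = None
    variant_metrics: Optional[Path] = None
    sample_qc: Optional[Path] = None
    kinship: Optional[Path] = None
    allele_definitions: dict[str, Path] = Field(default_factory=dict)
    knowledge_dir: Optional[Path] = None
    qc: QCSection = Field(default_factory=QCSection)
    cohorts: CohortSection = Field(default_factory=CohortSection)
    model: ModelSection = Field(default_factory=ModelSection)
    simulate: Optional[SimulateSection] = None

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        return v

    def check_inputs(self, simulated: bool = False) -> None:
        """Verify every referenced input file exists before any compute."""
        paths = {
            "vcf": self.vcf,
            "participants": self.participants,
            "variant_metrics": self.variant_metrics,
            "sample_qc": self.sample_qc,
            "kinship": self.kinship,
        }
        for gene, p in self.allele_definitions.items():
            paths[f"allele_definitions[{gene}]"] = p
        if self.knowledge_dir is not None:
            for name in ("drug_synonyms.tsv", "cyp_substrates.tsv",
                         "cyp_inhibitors.tsv", "drug_classes.tsv"):
                paths[f"knowledge_dir/{name}"] = self.knowledge_dir / name
        for label, p in paths.items():
            if p is None:
                continue
            if simulated and label in {"vcf", "participants", "variant_metrics",
                                       "sample_qc", "kinship"}:
                continue  # produced by the simulate stage
            if not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
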