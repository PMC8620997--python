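"""Post-imputation variant filters and sample exclusion rules.

Two-tier variant QC as used for biobank-scale imputed pharmacogene data:

* common-variant rule — keep variants with MAF >= 1% and imputation
  (Fisher) information score >= 0.3;
* rare-variant rescue — star-allele-defining variants failing the common
  rule are not discarded outright: imputed ones are kept at a stricter
  information threshold (0.6), directly genotyped ones are kept when their
  intensity clusters passed manual review (an upstream boolean here).

Sample exclusions run in a fixed order (missingness, sex mismatch, excess
relatedness, then kinship-pair pruning) so that every removed sample carries
exactly one primary reason.  Kinship pruning removes one member of each pair
above the third-degree cut-off (0.083) greedily by graph degree, which
retains the maximum number of samples on chains and stars of relatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .star_alleles import VariantSite


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.01
    info_min: float = 0.3
    rare_rescue_info_min: float = 0.6
    sample_missingness_max: float = 0.10
    kinship_max: float = 0.083

    def __post_init__(self) -> None:
        for name in ("maf_min", "info_min", "rare_rescue_info_min",
                     "sample_missingness_max", "kinship_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rare_rescue_info_min < self.info_min:
            raise ValueError("rare_rescue_info_min must be >= info_min")


@dataclass(frozen=True)
class VariantRecord:
    site: VariantSite
    maf: float
    info_score: float
    genotyped: bool = False
    is_star_defining: bool = False
    cluster_review_pass: Optional[bool] = None  # genotyped rare variants only

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.site.id}: MAF {self.maf} outside [0, 0.5]")
        if not 0.0 <= self.info_score <= 1.0:
            raise ValueError(f"{self.site.id}: info {self.info_score} outside [0, 1]")


@dataclass(frozen=True)
class SampleQCRecord:
    sample_id: str
    missingness: float = 0.0
    sex_mismatch: bool = False
    excess_relatedness: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError(f"{self.sample_id}: missingness outside [0, 1]")


@dataclass
class ExclusionLog:
    """One row per excluded item, with a single primary reason code."""

    rows: list[dict] = field(default_factory=list)

    def add(self, item_id: str, reason: str, **extra) -> None:
        self.rows.append({"id": item_id, "reason": reason, **extra})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["id", "reason"] if not self.rows else None)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rows:
            out[r["reason"]] = out.get(r["reason"], 0) + 1
        return out


def filter_variants(
    variants: Sequence[VariantRecord], t: QCThresholds = QCThresholds()
) -> tuple[list[VariantRecord], list[VariantRecord], ExclusionLog]:
    """Apply the common-variant rule.

    Returns ``(retained, rescue_candidates, log)``.  A variant is retained
    when MAF >= ``maf_min`` and info >= ``info_min``.  Star-allele-defining
    variants failing the common rule are diverted to the rescue queue rather
    than logged as excluded; everything else failing gets one reason
    (``maf`` checked before ``info``).
    """
    retained: list[VariantRecord] = []
    rescue: list[VariantRecord] = []
    log = ExclusionLog()
    for v in variants:
        passes = v.maf >= t.maf_min and v.info_score >= t.info_min
        if passes:
            retained.append(v)
        elif v.is_star_defining:
            rescue.append(v)
        else:
            reason = "maf" if v.maf < t.maf_min else "info"
            log.add(v.site.id, reason, maf=v.maf, info=v.info_score)
    return retained, rescue, log


def rescue_rare_variants(
    candidates: Sequence[VariantRecord], t: QCThresholds = QCThresholds()
) -> tuple[list[VariantRecord], ExclusionLog]:
    """Rescue rule for rare star-allele-defining variants.

    Imputed candidates are kept at the stricter information threshold;
    genotyped candidates are kept iff their intensity-cluster review passed
    (the review itself happens upstream and arrives as a flag).
    """
    retained: list[VariantRecord] = []
    log = ExclusionLog()
    for v in candidates:
        if not v.is_star_defining:
            raise ValueError(
                f"{v.site.id}: rescue is only defined for star-defining variants"
            )
        if v.genotyped:
            if v.cluster_review_pass:
                retained.append(v)
            else:
                log.add(v.site.id, "cluster_review")
        elif v.info_score >= t.rare_rescue_info_min:
            retained.append(v)
        else:
            log.add(v.site.id, "rescue_info", info=v.info_score)
    return retained, log


def qc_variants(
    variants: Sequence[VariantRecord], t: QCThresholds = QCThresholds()
) -> tuple[list[VariantRecord], ExclusionLog]:
    """Common rule plus rescue in one pass; retained order follows input."""
    retained, rescue, log = filter_variants(variants, t)
    rescued, rescue_log = rescue_rare_variants(rescue, t)
    log.rows.extend(rescue_log.rows)
    keep_ids = {v.site.id for v in retained} | {v.site.id for v in rescued}
    return [v for v in variants if v.site.id in keep_ids], log


def per_ancestry_maf(dosages: pd.DataFrame, ancestry: pd.Series) -> pd.DataFrame:
    """Minor-allele frequency per variant per ancestry stratum.

    ``dosages`` has one row per sample and one 0/1/2 column per variant;
    ``ancestry`` is aligned on the same index.  QC is intended to run within
    each stratum, so frequencies are computed that way too.
    """
    out = {}
    for group, idx in dosages.groupby(ancestry).groups.items():
        af = dosages.loc[idx].mean(axis=0) / 2.0
        out[group] = af.where(af <= 0.5, 1.0 - af)
    return pd.DataFrame(out)


def exclude_samples(
    samples: Sequence[SampleQCRecord],
    kin_pairs: Iterable[tuple[str, str, float]],
    t: QCThresholds = QCThresholds(),
) -> tuple[list[str], ExclusionLog]:
    """Sample-level exclusions followed by kinship-pair pruning.

    Reasons are applied in the fixed order missingness -> sex mismatch ->
    excess relatedness -> kinship pair; a sample is logged once, under the
    first reason that applies.  Kinship pruning repeatedly drops the
    highest-degree sample in the residual over-threshold kinship graph
    (ties broken by smaller sample id), so no retained pair exceeds the
    threshold and chains A-B-C lose only the shared middle member.
    """
    log = ExclusionLog()
    kept: list[str] = []
    known = {s.sample_id for s in samples}
    for s in samples:
        if s.missingness > t.sample_missingness_max:
            log.add(s.sample_id, "missingness", missingness=s.missingness)
        elif s.sex_mismatch:
            log.add(s.sample_id, "sex_mismatch")
        elif s.excess_relatedness:
            log.add(s.sample_id, "excess_relatedness")
        else:
            kept.append(s.sample_id)

    adjacency: dict[str, set[str]] = {}
    for a, b, k in kin_pairs:
        if a not in known or b not in known:
            raise ValueError(f"kinship pair ({a}, {b}) references unknown sample id")
        if not 0.0 <= k <= 0.5:
            raise ValueError(f"kinship {k} for ({a}, {b}) outside [0, 0.5]")
        if k > t.kinship_max and a in kept and b in kept:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)

    kept_set = set(kept)
    while True:
        live = {s: nb & kept_set for s, nb in adjacency.items()
                if s in kept_set and nb & kept_set}
        if not live:
            break
        victim = min(live, key=lambda s: (-len(live[s]), s))
        kept_set.discard(victim)
        log.add(victim, "kinship_pair", degree=len(live[victim]))

    return [s for s in kept if s in kept_set], log
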