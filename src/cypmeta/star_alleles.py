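"""Star-allele nomenclature model for CYP2D6/CYP2C19 haplotypes.

A *star allele* is a named haplotype of a pharmacogene defined by a fixed set
of variants and carrying an assigned functional status.  ``*1`` is the
wild-type default: it has no defining variants and is assigned to any
haplotype on which no other allele's full variant set is observed.  CYP2D6
alleles additionally carry a Gaedigk activity value (0 = no function,
0.5 = decreased, 1 = normal); the activity score of a diplotype is the sum
over its two haplotypes.

The bundled definition tables are deliberately SNV-only reconstructions of
the core European alleles (no copy-number or hybrid-gene alleles), matching
what array genotyping plus imputation can resolve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from importlib import resources

logger = logging.getLogger(__name__)

GENES = ("CYP2D6", "CYP2C19")

#: function class -> CYP2D6 activity value under the Gaedigk scheme
FUNCTION_ACTIVITY = {"none": 0.0, "decreased": 0.5, "normal": 1.0}

#: ordering used for conservative tie-breaks (lower = less functional)
_FUNCTION_RANK = {"none": 0, "decreased": 1, "normal": 2, "increased": 3}


class DefinitionError(ValueError):
    """Raised when an allele definition table violates its invariants."""


@dataclass(frozen=True)
class VariantSite:
    """One star-allele-defining variant site (1-based, VCF-style)."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise DefinitionError(f"{self.id}: position must be positive")
        if self.ref == self.alt:
            raise DefinitionError(f"{self.id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class StarAlleleDefinition:
    """A named allele, its defining variants and its functional status."""

    name: str
    gene: str
    defining_variants: tuple[VariantSite, ...]
    function_class: str
    activity_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.function_class not in _FUNCTION_RANK:
            raise DefinitionError(
                f"{self.gene} {self.name}: unknown function class "
                f"{self.function_class!r}"
            )
        if self.name == "*1":
            if self.defining_variants:
                raise DefinitionError("*1 must have no defining variants")
            if self.function_class != "normal":
                raise DefinitionError("*1 must be normal-function")
        elif not self.defining_variants:
            raise DefinitionError(f"{self.name}: non-*1 allele needs >=1 defining variant")
        if self.activity_value is not None:
            expected = FUNCTION_ACTIVITY.get(self.function_class)
            if expected is None or abs(self.activity_value - expected) > 1e-9:
                raise DefinitionError(
                    f"{self.gene} {self.name}: activity {self.activity_value} "
                    f"inconsistent with function {self.function_class!r}"
                )


@dataclass(frozen=True)
class HaplotypeCall:
    """Result of matching one phased haplotype against a definition table."""

    allele_name: str
    matched_variants: int
    is_default_wildtype: bool = False
    missing_defining_sites: int = 0

    def __post_init__(self) -> None:
        if self.is_default_wildtype and (self.allele_name != "*1" or self.matched_variants):
            raise ValueError("default wild-type call must be *1 with 0 matched variants")


@dataclass
class AlleleDefinitionTable:
    """Validated set of star-allele definitions for one gene."""

    gene: str
    alleles: list[StarAlleleDefinition]
    build: str = "GRCh37"
    region: Optional[tuple[str, int, int]] = None  # chrom, start, end incl. flanks
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [a.name for a in self.alleles]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DefinitionError(f"duplicate allele names: {sorted(dupes)}")
        if names.count("*1") != 1:
            raise DefinitionError(f"{self.gene}: exactly one *1 row required")
        if any(a.gene != self.gene for a in self.alleles):
            raise DefinitionError("mixed genes in one definition table")
        # a variant id must always refer to one physical site
        seen: dict[str, VariantSite] = {}
        for a in self.alleles:
            for v in a.defining_variants:
                if v.id in seen and seen[v.id] != v:
                    raise DefinitionError(
                        f"variant id {v.id} maps to conflicting sites"
                    )
                seen[v.id] = v
        if self.region is not None:
            chrom, start, end = self.region
            for v in seen.values():
                if v.chrom != chrom or not (start <= v.pos <= end):
                    raise DefinitionError(
                        f"variant {v.id} at {v.chrom}:{v.pos} lies outside the "
                        f"extraction region {chrom}:{start}-{end}"
                    )

    # -- convenience lookups -------------------------------------------------

    def allele(self, name: str) -> StarAlleleDefinition:
        for a in self.alleles:
            if a.name == name:
                return a
        raise LookupError(f"unknown {self.gene} allele {name!r}")

    @property
    def variant_sites(self) -> list[VariantSite]:
        """All distinct defining sites, sorted by position."""
        seen: dict[str, VariantSite] = {}
        for a in self.alleles:
            for v in a.defining_variants:
                seen[v.id] = v
        return sorted(seen.values(), key=lambda v: (v.chrom, v.pos, v.id))


def load_allele_definitions(source: str | Path, metadata: str | Path | None = None) -> AlleleDefinitionTable:
    """Load and validate an allele definition table.

    ``source`` is a TSV with columns gene, allele, rsid, chrom, pos, ref, alt,
    function, activity_value; alleles without defining variants (i.e. *1) use
    one row with empty variant fields.  ``metadata`` is a JSON sidecar with
    gene/build/region fields; by default ``<source>.json`` next to the TSV
    (``foo.tsv`` -> ``foo.json``) is used when present.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    meta: dict = {}
    meta_path = Path(metadata) if metadata is not None else source.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())

    rows: list[dict[str, str]] = []
    with open(source) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"gene", "allele", "rsid", "chrom", "pos", "ref", "alt", "function"}
        missing = required - set(header)
        if missing:
            raise DefinitionError(f"definition table missing columns {sorted(missing)}")
        for line in fh:
            if not line.strip():
                continue
            values = line.rstrip("\n").split("\t")
            values += [""] * (len(header) - len(values))
            rows.append(dict(zip(header, values)))
    if not rows:
        raise DefinitionError("empty definition table")

    gene = meta.get("gene", rows[0]["gene"])
    by_allele: dict[str, list[dict[str, str]]] = {}
    order: list[str] = []
    previous = None
    for r in rows:
        name = r["allele"]
        if name not in by_allele:
            order.append(name)
        elif name != previous:
            # rows of one allele must be contiguous; a second block means
            # the allele was defined twice
            raise DefinitionError(f"duplicate allele definition for {name}")
        by_allele.setdefault(name, []).append(r)
        previous = name

    alleles: list[StarAlleleDefinition] = []
    for name in order:
        group = by_allele[name]
        functions = {g["function"] for g in group}
        if len(functions) != 1:
            raise DefinitionError(f"{name}: conflicting function classes {functions}")
        variants = tuple(
            VariantSite(g["rsid"], g["chrom"], int(g["pos"]), g["ref"], g["alt"])
            for g in group
            if g["rsid"]
        )
        activities = {g.get("activity_value", "") for g in group}
        activity = None
        if activities and activities != {""}:
            if len(activities) != 1:
                raise DefinitionError(f"{name}: conflicting activity values")
            activity = float(next(iter(activities)))
        alleles.append(
            StarAlleleDefinition(
                name=name,
                gene=group[0]["gene"],
                defining_variants=variants,
                function_class=functions.pop(),
                activity_value=activity,
            )
        )

    region = None
    if {"chrom", "gene_start", "gene_end"} <= meta.keys():
        flank = int(meta.get("region_flank", 1_000_000))
        region = (
            str(meta["chrom"]),
            int(meta["gene_start"]) - flank,
            int(meta["gene_end"]) + flank,
        )
    return AlleleDefinitionTable(
        gene=gene,
        alleles=alleles,
        build=meta.get("build", "GRCh37"),
        region=region,
        metadata=meta,
    )


def builtin_table(gene: str) -> AlleleDefinitionTable:
    """Load one of the definition tables shipped with the package."""
    if gene not in GENES:
        raise ValueError(f"no bundled table for {gene!r}")
    data = resources.files("cypmeta") / "data"
    return load_allele_definitions(
        str(data / f"{gene.lower()}_alleles.tsv"),
        str(data / f"{gene.lower()}_alleles.json"),
    )


# ---------------------------------------------------------------------------
# haplotype matching

Haplotype = Mapping[str, Optional[int]]  # variant id -> 0 (ref) / 1 (alt) / None


def match_haplotype(hap: Haplotype, table: AlleleDefinitionTable) -> HaplotypeCall:
    """Match one phased haplotype against a definition table.

    ``hap`` maps variant ids to the allele observed on this haplotype
    (0 reference, 1 alternate, ``None`` missing).  Missing or absent sites
    cannot support a match and are treated as reference; their count is
    reported on the call so that the wild-type misclassification risk can be
    audited downstream.

    An allele matches when *all* of its defining variants carry the alternate
    allele.  If several alleles fully match, the one with the most defining
    variants wins (most specific); residual ties go to the least functional
    allele, then lexicographically, and every tie is logged.  When nothing
    matches, the call defaults to *1 (wild-type).
    """
    n_missing = sum(
        1 for site in table.variant_sites if hap.get(site.id) is None
    )
    matches = [
        a
        for a in table.alleles
        if a.defining_variants
        and all(hap.get(v.id) == 1 for v in a.defining_variants)
    ]
    if not matches:
        return HaplotypeCall("*1", 0, is_default_wildtype=True,
                             missing_defining_sites=n_missing)

    def key(a: StarAlleleDefinition) -> tuple:
        return (-len(a.defining_variants), _FUNCTION_RANK[a.function_class], a.name)

    matches.sort(key=key)
    best = matches[0]
    rivals = [
        a for a in matches[1:]
        if len(a.defining_variants) == len(best.defining_variants)
    ]
    if rivals:
        logger.info(
            "%s haplotype tie: %s chosen over %s",
            table.gene, best.name, [a.name for a in rivals],
        )
    return HaplotypeCall(best.name, len(best.defining_variants),
                         missing_defining_sites=n_missing)


def activity_score(
    allele_a: str, allele_b: str, table: AlleleDefinitionTable
) -> float:
    """Gaedigk activity score of a diplotype: sum of per-allele values.

    Only defined for CYP2D6 (CYP2C19 phenotypes are assigned from function
    classes directly).  Raises ``LookupError`` for unknown allele names and
    ``ValueError`` for alleles without an activity value (e.g. increased-
    function alleles, which cannot be scored without copy-number data).
    """
    if table.gene != "CYP2D6":
        raise ValueError("activity scoring applies to CYP2D6 only")
    total = 0.0
    for name in (allele_a, allele_b):
        a = table.allele(name)
        if a.activity_value is None:
            raise ValueError(f"allele {name} has no activity value")
        total += a.activity_value
    return total


def haplotype_from_alleles(
    allele_names: Sequence[str], table: AlleleDefinitionTable
) -> dict[str, int]:
    """Render the haplotype carrying exactly the given alleles' variants."""
    hap = {site.id: 0 for site in table.variant_sites}
    for name in allele_names:
        for v in table.allele(name).defining_variants:
            hap[v.id] = 1
    return hap
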