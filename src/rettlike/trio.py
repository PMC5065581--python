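"""Quality-gated de novo calling on trios, and recessive-mode analysis
(homozygous recessive genotypes, compound heterozygosity) for families with
more than one affected child.

A de novo call demands the definitional genotype configuration — child
heterozygous, both parents confidently homozygous reference — plus quality
gates on all three members: minimum depth, minimum genotype quality and a
child allele-balance window. Anomalies are fail reasons, never exceptions,
so every examined variant leaves an auditable record.

The recessive analyses run on the record set *before* parental subtraction
(inherited variants are their whole point): a homozygous-recessive
candidate has every affected child 1/1 with both parents 0/1; a
compound-het candidate gene carries at least two rare qualifying
heterozygous variants shared by all affected children with, where parental
genotypes settle the origin, at least one inherited from each parent
(trans). Genes whose variants all come from one parent are rejected (cis);
configurations the parental genotypes cannot settle are flagged
phase-ambiguous rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import Family, GenotypeCall, VariantRecord
from pydantic import BaseModel, model_validator

__all__ = [
    "QualityGate",
    "DenovoCall",
    "RecessiveCandidate",
    "call_denovo",
    "find_homozygous_recessive",
    "find_compound_het",
]

Key = tuple[str, int, str, str]

PASS = "pass"


class QualityGate(BaseModel):
    """Numeric thresholds for accepting a de novo candidate.

    Defaults follow common trio-sequencing practice: depth >= 10 in all
    three members, genotype quality >= 20, and a child alternate-allele
    balance within [0.25, 0.75].
    """

    min_depth: int = 10
    min_genotype_quality: float = 20.0
    child_ab_range: tuple[float, float] = (0.25, 0.75)

    @model_validator(mode="after")
    def _check(self) -> "QualityGate":
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        lo, hi = self.child_ab_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("child_ab_range must satisfy 0 < lower < upper < 1")
        return self


@dataclass(frozen=True)
class DenovoCall:
    """Outcome of examining one variant in one trio."""

    key: Key
    family_id: str
    child_id: str
    status: str  # "pass" or "fail"
    reason: Optional[str] = None  # first violated check, when failing
    metrics: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.status == PASS


def call_denovo(
    record: VariantRecord,
    child: Optional[GenotypeCall],
    father: Optional[GenotypeCall],
    mother: Optional[GenotypeCall],
    family_id: str,
    child_id: str,
    gate: QualityGate = QualityGate(),
) -> DenovoCall:
    """Evaluate one cascade-surviving variant as a de novo candidate.

    Checks run in a fixed order and the first violation becomes the fail
    reason: trio completeness, parental reference genotypes, child
    heterozygosity, depths, genotype qualities, child allele balance.
    """
    metrics: dict = {}

    def fail(reason: str) -> DenovoCall:
        return DenovoCall(record.key, family_id, child_id, "fail", reason, metrics)

    trio = {"child": child, "father": father, "mother": mother}
    for role, call in trio.items():
        if call is None or call.is_nocall:
            return fail(f"incomplete trio ({role} missing)")

    assert child and father and mother  # for the type checker
    metrics = {
        "child_dp": child.depth,
        "father_dp": father.depth,
        "mother_dp": mother.depth,
        "child_gq": child.genotype_quality,
        "father_gq": father.genotype_quality,
        "mother_gq": mother.genotype_quality,
        "child_ab": child.alt_fraction,
    }

    if father.carries_alt or mother.carries_alt:
        return fail("parent carries alt")
    if not child.is_het:
        return fail("child not heterozygous")
    for role, call in trio.items():
        if call.depth < gate.min_depth:  # type: ignore[union-attr]
            return fail(f"{role} depth {call.depth} < {gate.min_depth}")  # type: ignore[union-attr]
    for role, call in trio.items():
        if call.genotype_quality < gate.min_genotype_quality:  # type: ignore[union-attr]
            return fail(
                f"{role} GQ {call.genotype_quality:g} < {gate.min_genotype_quality:g}"  # type: ignore[union-attr]
            )
    ab = child.alt_fraction
    lo, hi = gate.child_ab_range
    if ab is None:
        return fail("child allele balance unavailable")
    if not lo <= ab <= hi:
        return fail(f"child allele balance {ab:.3f} outside [{lo}, {hi}]")

    return DenovoCall(record.key, family_id, child_id, PASS, None, metrics)


@dataclass(frozen=True)
class RecessiveCandidate:
    """A gene-level recessive hypothesis for a multiplex family."""

    gene: Optional[str]
    mode: str  # "homozygous_recessive" | "compound_het"
    keys: tuple[Key, ...]
    phase_support: str = "trans_confirmed"  # or "phase_ambiguous"

    def __post_init__(self) -> None:
        if self.mode == "compound_het" and len(set(self.keys)) < 2:
            raise ValueError("compound het needs >= 2 distinct variant keys")


def _family_calls(
    calls: Mapping[Key, Mapping[str, GenotypeCall]],
    key: Key,
    sample_id: str,
) -> Optional[GenotypeCall]:
    site = calls.get(key)
    if site is None:
        return None
    return site.get(sample_id)


def find_homozygous_recessive(
    family: Family,
    calls: Mapping[Key, Mapping[str, GenotypeCall]],
    records: Sequence[VariantRecord],
) -> list[RecessiveCandidate]:
    """Variants where every affected child is homozygous alternate and both
    parents are heterozygous carriers.

    ``records`` should be the post-impact, post-frequency set (NOT
    parentally subtracted — these variants are inherited by construction).
    """
    out: list[RecessiveCandidate] = []
    affected = [c.sample_id for c in family.affected_children]
    for rec in records:
        fa = _family_calls(calls, rec.key, family.father_id)
        mo = _family_calls(calls, rec.key, family.mother_id)
        if fa is None or mo is None or not (fa.is_het and mo.is_het):
            continue
        child_calls = [_family_calls(calls, rec.key, c) for c in affected]
        if all(c is not None and c.is_hom_alt for c in child_calls):
            out.append(
                RecessiveCandidate(rec.gene, "homozygous_recessive", (rec.key,))
            )
    return out


def find_compound_het(
    family: Family,
    calls: Mapping[Key, Mapping[str, GenotypeCall]],
    records: Sequence[VariantRecord],
) -> list[RecessiveCandidate]:
    """Genes with two or more heterozygous variants shared by all affected
    children, requiring trans configuration where parental origin is
    determined.

    Per variant, the origin evidence is which parents carry it: exactly the
    father → paternal; exactly the mother → maternal; both → undetermined.
    Variants carried by neither parent are not inherited and do not count.
    A gene is a candidate when a paternal-only and a maternal-only variant
    coexist (``trans_confirmed``), or when undetermined-origin variants
    leave a trans configuration possible but unproven
    (``phase_ambiguous``). Genes whose variants are all attributable to one
    parent are rejected as cis.
    """
    affected = [c.sample_id for c in family.affected_children]
    by_gene: dict[str, list[VariantRecord]] = {}
    for rec in records:
        if rec.gene is None:
            continue
        child_calls = [_family_calls(calls, rec.key, c) for c in affected]
        if not all(c is not None and c.is_het for c in child_calls):
            continue
        by_gene.setdefault(rec.gene, []).append(rec)

    out: list[RecessiveCandidate] = []
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        paternal, maternal, undetermined = [], [], []
        for rec in recs:
            fa = _family_calls(calls, rec.key, family.father_id)
            mo = _family_calls(calls, rec.key, family.mother_id)
            fa_carries = fa is not None and fa.carries_alt
            mo_carries = mo is not None and mo.carries_alt
            if fa_carries and mo_carries:
                undetermined.append(rec)
            elif fa_carries:
                paternal.append(rec)
            elif mo_carries:
                maternal.append(rec)
            # carried by neither parent: not inherited, ignore
        inherited = paternal + maternal + undetermined
        if len(inherited) < 2:
            continue
        if paternal and maternal:
            support = "trans_confirmed"
        elif undetermined and (paternal or maternal or len(undetermined) >= 2):
            # a trans pair cannot be excluded from genotypes alone
            support = "phase_ambiguous"
        else:
            continue  # all variants from one parent: cis, rejected
        keys = tuple(sorted(r.key for r in inherited))
        out.append(RecessiveCandidate(gene, "compound_het", keys, support))
    return out
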