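"""Sequential variant-reduction cascade for one family.

The four stages, in narrative order: restrict to consequences with a
predicted functional impact; remove common polymorphisms (allele frequency
of 1% or higher in any configured population source, boundary inclusive);
subtract variants carried by the proband's own parents; subtract variants
carried by any parent in the pooled cohort-wide control panel.

Each stage is a pure predicate or set subtraction over canonical variant
keys, so the final candidate set is invariant under stage order; the
intermediate per-stage counts, recorded in the :class:`CascadeReport`, are
what depends on the order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    ConfigurationError,
    Family,
    GenotypeCall,
    Pedigree,
    VariantRecord,
)

__all__ = [
    "DEFAULT_QUALIFYING_CONSEQUENCES",
    "DEFAULT_AF_THRESHOLD",
    "StageEntry",
    "CascadeReport",
    "CascadeConfig",
    "filter_functional_impact",
    "filter_population_frequency",
    "filter_parental",
    "filter_pooled_controls",
    "run_cascade",
]

#: Standard reading of "non-synonymous variants predicted to have a
#: functional impact": protein-altering and canonical splice-site terms.
DEFAULT_QUALIFYING_CONSEQUENCES = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)

#: The classic polymorphism definition: AF of 1% or higher is removed.
DEFAULT_AF_THRESHOLD = 0.01

Key = tuple[str, int, str, str]


@dataclass
class CascadeConfig:
    qualifying_consequences: frozenset[str] = DEFAULT_QUALIFYING_CONSEQUENCES
    af_threshold: float = DEFAULT_AF_THRESHOLD
    af_sources: Optional[Sequence[str]] = None  # None = every source present
    declared_af_sources: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.af_threshold <= 1.0:
            raise ConfigurationError("af_threshold must be in (0, 1]")


def filter_functional_impact(
    records: Iterable[VariantRecord],
    qualifying_consequences: Iterable[str] = DEFAULT_QUALIFYING_CONSEQUENCES,
) -> list[VariantRecord]:
    """Keep records whose consequence term is in the qualifying set.

    Records with no consequence annotation are dropped: an unannotated
    variant cannot be claimed to alter the protein.
    """
    qualifying = frozenset(qualifying_consequences)
    if not qualifying:
        raise ConfigurationError("qualifying consequence set is empty")
    return [r for r in records if r.consequence is not None and r.consequence in qualifying]


def filter_population_frequency(
    records: Iterable[VariantRecord],
    af_sources: Optional[Sequence[str]] = None,
    threshold: float = DEFAULT_AF_THRESHOLD,
    declared_sources: Optional[Sequence[str]] = None,
) -> list[VariantRecord]:
    """Remove records at or above ``threshold`` frequency in ANY configured
    source; the boundary is inclusive ("1% or higher" is a polymorphism).

    Records absent from every source are retained — novel variants must
    survive. ``af_sources=None`` consults every source present on a record;
    naming a source not in ``declared_sources`` (when given) is a
    configuration error.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigurationError("threshold must be in (0, 1]")
    if af_sources is not None and declared_sources is not None:
        unknown = set(af_sources) - set(declared_sources)
        if unknown:
            raise ConfigurationError(
                f"unknown AF source(s) requested: {sorted(unknown)}; "
                f"declared: {sorted(declared_sources)}"
            )
    out = []
    for r in records:
        top = r.max_af(af_sources)
        if top is None or top < threshold:
            out.append(r)
    return out


def filter_parental(
    child_records: Iterable[VariantRecord],
    father_calls: Mapping[Key, GenotypeCall],
    mother_calls: Mapping[Key, GenotypeCall],
) -> list[VariantRecord]:
    """Remove any child record whose key has a called non-reference genotype
    in either parent. A missing or no-call parental genotype never counts as
    "present in parent"."""
    out = []
    for r in child_records:
        fa = father_calls.get(r.key)
        mo = mother_calls.get(r.key)
        if (fa is not None and fa.carries_alt) or (mo is not None and mo.carries_alt):
            continue
        out.append(r)
    return out


def filter_pooled_controls(
    records: Iterable[VariantRecord],
    control_carried_keys: set[Key],
) -> list[VariantRecord]:
    """Remove records carried (non-reference call) by any individual of the
    pooled control panel — all healthy parents in the study, the proband's
    own included (harmless duplication after the parental stage)."""
    if not control_carried_keys:
        warnings.warn(
            "pooled control panel is empty; pooled-control stage is an identity filter",
            stacklevel=2,
        )
        return list(records)
    return [r for r in records if r.key not in control_carried_keys]


@dataclass
class StageEntry:
    stage: str
    variants_in: int
    variants_out: int
    removed_sample: list[Key] = field(default_factory=list)  # first few removed keys


@dataclass
class CascadeReport:
    """Per-stage accounting of one family's variant reduction."""

    family_id: str
    stages: list[StageEntry] = field(default_factory=list)
    final_keys: set[Key] = field(default_factory=set)
    final_gene_count: int = 0

    def record_stage(
        self,
        name: str,
        before: Sequence[VariantRecord],
        after: Sequence[VariantRecord],
        sample_size: int = 5,
    ) -> None:
        if len(after) > len(before):
            raise ValueError(f"stage {name} grew the record set")
        if self.stages and self.stages[-1].variants_out != len(before):
            raise ValueError(f"stage {name} input does not chain from previous stage")
        after_keys = {r.key for r in after}
        removed = [r.key for r in before if r.key not in after_keys]
        self.stages.append(
            StageEntry(name, len(before), len(after), removed[:sample_size])
        )

    def finalize(self, final_records: Sequence[VariantRecord]) -> None:
        self.final_keys = {r.key for r in final_records}
        self.final_gene_count = len(
            {r.gene for r in final_records if r.gene is not None}
        )

    def to_rows(self) -> list[dict]:
        return [
            {
                "family": self.family_id,
                "stage": s.stage,
                "variants_in": s.variants_in,
                "variants_out": s.variants_out,
            }
            for s in self.stages
        ]


def child_record_set(
    records_calls: Sequence[tuple[VariantRecord, Mapping[str, GenotypeCall]]],
    family: Family,
) -> list[VariantRecord]:
    """The family's starting set: variants with a called non-reference
    genotype in at least one affected child."""
    affected = [c.sample_id for c in family.affected_children]
    out = []
    for rec, calls in records_calls:
        for sid in affected:
            call = calls.get(sid)
            if call is not None and call.carries_alt:
                out.append(rec)
                break
    return out


def carried_key_set(
    records_calls: Sequence[tuple[VariantRecord, Mapping[str, GenotypeCall]]],
    sample_ids: Sequence[str],
) -> set[Key]:
    """Keys carried by any of the given samples (used for the pooled
    parental control panel)."""
    out: set[Key] = set()
    for rec, calls in records_calls:
        for sid in sample_ids:
            call = calls.get(sid)
            if call is not None and call.carries_alt:
                out.add(rec.key)
                break
    return out


def calls_by_key(
    records_calls: Sequence[tuple[VariantRecord, Mapping[str, GenotypeCall]]],
    sample_id: str,
) -> dict[Key, GenotypeCall]:
    out: dict[Key, GenotypeCall] = {}
    for rec, calls in records_calls:
        call = calls.get(sample_id)
        if call is not None:
            out[rec.key] = call
    return out


def run_cascade(
    family: Family,
    records_calls: Sequence[tuple[VariantRecord, Mapping[str, GenotypeCall]]],
    pedigree: Pedigree,
    config: CascadeConfig = CascadeConfig(),
) -> CascadeReport:
    """Apply the four filters in order to one family's variants and return
    the per-stage report.

    The pooled control panel is built from every parental sample in
    ``pedigree``; stage errors propagate unchanged.
    """
    report = CascadeReport(family_id=family.family_id)
    current = child_record_set(records_calls, family)

    after = filter_functional_impact(current, config.qualifying_consequences)
    report.record_stage("functional_impact", current, after)
    current = after

    after = filter_population_frequency(
        current,
        af_sources=config.af_sources,
        threshold=config.af_threshold,
        declared_sources=config.declared_af_sources,
    )
    report.record_stage("population_frequency", current, after)
    current = after

    father_calls = calls_by_key(records_calls, family.father_id)
    mother_calls = calls_by_key(records_calls, family.mother_id)
    after = filter_parental(current, father_calls, mother_calls)
    report.record_stage("parental", current, after)
    current = after

    pool = carried_key_set(records_calls, pedigree.parent_ids)
    after = filter_pooled_controls(current, pool)
    report.record_stage("pooled_controls", current, after)

    report.finalize(after)
    return report
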