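"""Evidence scoring and ranking of surviving candidate variants.

Evidence per candidate: the consensus of four in-silico damage predictors
(SIFT, PolyPhen2, PROVEAN, MutationTaster2), discretized to P (likely
pathogenic) / B (likely benign) / NA; cross-vertebrate nucleotide
conservation on a 0–1000 scale; novelty (absence from every population
frequency source); and whether the gene is already associated with a
neurodevelopmental disorder in the bundled knowledge map.

Predictor evidence is a *ranking* signal, not a hard filter: real cohorts
retain all-benign candidates (a variant with four B calls and conservation
0 can still be the reported hit), so ranking never removes entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _ilres
from typing import Iterable, Mapping, Optional, Union

from .model import PredictionProfile, VariantRecord

__all__ = [
    "PredictionProfile",
    "KnownGeneMap",
    "CandidateRank",
    "NOVEL",
    "score_predictions",
    "classify_known_association",
    "rank_candidates",
    "chromosome_sort_key",
]

NOVEL = "novel"


def score_predictions(profile: PredictionProfile) -> tuple[int, int]:
    """Count pathogenic calls and available (non-NA) calls.

    Returns ``(pathogenic_support, predictor_coverage)``; an all-NA profile
    yields ``(0, 0)`` rather than raising — no evidence is a valid state.
    """
    labels = profile.labels
    coverage = sum(1 for x in labels if x != "NA")
    support = sum(1 for x in labels if x == "P")
    return support, coverage


class KnownGeneMap:
    """Gene symbol → known disorder association(s).

    The bundled default holds the neurodevelopmental-disorder genes with a
    Rett-overlapping presentation (HCN1, SCN1A, TCF4, GRIN2B, SLC6A1); user
    maps extend or replace it via :meth:`from_tsv` / :meth:`update`.
    Looking up an unmapped gene returns ``"novel"``.
    """

    def __init__(self, mapping: Optional[Mapping[str, str]] = None) -> None:
        self._map: dict[str, str] = dict(mapping or {})

    @classmethod
    def bundled(cls) -> "KnownGeneMap":
        path = _ilres.files("rettlike.data").joinpath("known_ndd_genes.tsv")
        return cls._parse(path.read_text())

    @classmethod
    def from_tsv(cls, path) -> "KnownGeneMap":
        with open(path) as fh:
            return cls._parse(fh.read())

    @classmethod
    def _parse(cls, text: str) -> "KnownGeneMap":
        mapping: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene\t"):
                continue
            gene, disorder = line.split("\t", 1)
            if gene in mapping:
                raise ValueError(f"duplicate gene symbol {gene!r} in map")
            mapping[gene] = disorder
        return cls(mapping)

    def update(self, other: Mapping[str, str]) -> None:
        self._map.update(other)

    def __contains__(self, gene: str) -> bool:
        return gene in self._map

    def __len__(self) -> int:
        return len(self._map)

    def classify(self, gene: str) -> str:
        return classify_known_association(gene, self)

    def get(self, gene: str) -> Optional[str]:
        return self._map.get(gene)


def classify_known_association(gene: str, gene_map: KnownGeneMap) -> str:
    """The mapped disorder for a known gene, ``"novel"`` otherwise."""
    if not gene:
        raise ValueError("gene symbol must be non-empty")
    known = gene_map.get(gene)
    return known if known is not None else NOVEL


@dataclass(frozen=True)
class CandidateRank:
    """Ranking evidence for one candidate variant."""

    key: tuple[str, int, str, str]
    gene: Optional[str]
    pathogenic_support: int
    predictor_coverage: int
    conservation: Optional[int]
    novel: bool  # absent from all population AF sources
    known_ndd: str  # mapped disorder, or "novel"

    def __post_init__(self) -> None:
        if not 0 <= self.pathogenic_support <= self.predictor_coverage <= 4:
            raise ValueError(
                f"inconsistent predictor counts "
                f"({self.pathogenic_support}/{self.predictor_coverage})"
            )

    @classmethod
    def from_record(
        cls, record: VariantRecord, gene_map: KnownGeneMap
    ) -> "CandidateRank":
        profile = record.prediction or PredictionProfile()
        support, coverage = score_predictions(profile)
        return cls(
            key=record.key,
            gene=record.gene,
            pathogenic_support=support,
            predictor_coverage=coverage,
            conservation=profile.conservation,
            novel=len(record.af_map) == 0,
            known_ndd=(
                classify_known_association(record.gene, gene_map)
                if record.gene
                else NOVEL
            ),
        )


def chromosome_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural chromosome order: 1..22, then X, Y, MT, then others."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c.upper() in special:
        return (0, special[c.upper()], "")
    return (1, 0, c)


def rank_candidates(candidates: Iterable[CandidateRank]) -> list[CandidateRank]:
    """Stable descending order by (pathogenic support, conservation with
    absent as 0, novelty first), ties broken by genomic coordinates.

    Ranking is a permutation — nothing is ever removed.
    """
    def sort_key(c: CandidateRank):
        chrom, pos, ref, alt = c.key
        return (
            -c.pathogenic_support,
            -(c.conservation if c.conservation is not None else 0),
            0 if c.novel else 1,
            chromosome_sort_key(chrom),
            pos,
            ref,
            alt,
        )

    return sorted(candidates, key=sort_key)
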