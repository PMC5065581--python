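"""End-to-end orchestration: cascade → de novo / recessive → prioritization
→ clinical summary, with per-stage structured logging and a cohort-level
JSON manifest whose counts are re-derivable from the emitted tables.

All randomness flows from the run seed; rerunning an identical
configuration produces byte-identical outputs (no timestamps in the
manifest).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cascade import (
    CascadeConfig,
    calls_by_key,
    child_record_set,
    filter_functional_impact,
    filter_population_frequency,
    run_cascade,
)
from .clinical import percentage, read_profiles, summarize_cohort
from .model import (
    AnnotationConfig,
    DEFAULT_ANNOTATION,
    Pedigree,
    RettlikeError,
    VariantRecord,
    read_pedigree,
    read_vcf,
)
from .prioritize import CandidateRank, KnownGeneMap, rank_candidates
from .trio import QualityGate, call_denovo, find_compound_het, find_homozygous_recessive

__all__ = [
    "RunConfig",
    "run_pipeline",
    "summarize_variant_classes",
    "summarize_locomotion",
]

logger = logging.getLogger("rettlike")


class RunConfig(BaseModel):
    """Paths, thresholds and toggles for one reproducible pipeline run."""

    vcf: Path
    ped: Path
    out_dir: Path
    clinical_csv: Optional[Path] = None
    known_gene_map: Optional[Path] = None
    annotation: AnnotationConfig = Field(default_factory=AnnotationConfig)
    gate: QualityGate = Field(default_factory=QualityGate)
    af_threshold: float = 0.01
    run_recessive: bool = True
    seed: int = 0

    def validate_paths(self) -> None:
        for name in ("vcf", "ped"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        for name in ("clinical_csv", "known_gene_map"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every family and write the report bundle.

    Emits per-family cascade TSVs, de novo call tables (with status and
    fail reason), recessive candidates for multiplex families, a ranked
    candidate table, an optional clinical summary, and ``manifest.json``.
    Returns the manifest. A stage failure aborts with the stage and family
    named.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pedigree = read_pedigree(config.ped)
    if len(pedigree) == 0:
        raise RettlikeError("pedigree is empty; nothing to analyze")
    records_calls = read_vcf(config.vcf, config.annotation)

    gene_map = (
        KnownGeneMap.from_tsv(config.known_gene_map)
        if config.known_gene_map
        else KnownGeneMap.bundled()
    )
    cascade_cfg = CascadeConfig(
        af_threshold=config.af_threshold,
        declared_af_sources=config.annotation.af_sources,
    )

    manifest: dict = {
        "tool": "rettlike",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "af_threshold": config.af_threshold,
            "gate": config.gate.model_dump(mode="json"),
        },
        "families": {},
    }

    cascade_rows: list[dict] = []
    denovo_rows: list[dict] = []
    recessive_rows: list[dict] = []
    all_candidates: list[CandidateRank] = []
    probands_with_candidates = 0

    by_key = {rec.key: rec for rec, _ in records_calls}

    for family in pedigree:
        try:
            report = run_cascade(family, records_calls, pedigree, cascade_cfg)
        except RettlikeError as exc:
            raise RettlikeError(
                f"cascade failed for family {family.family_id}: {exc}"
            ) from exc
        cascade_rows.extend(report.to_rows())
        for entry in report.stages:
            logger.info(
                "family=%s stage=%s in=%d out=%d",
                family.family_id, entry.stage, entry.variants_in, entry.variants_out,
            )

        final_records = [by_key[k] for k in sorted(report.final_keys)]
        father_calls = calls_by_key(records_calls, family.father_id)
        mother_calls = calls_by_key(records_calls, family.mother_id)

        fam_pass = 0
        for child in family.affected_children:
            child_calls = calls_by_key(records_calls, child.sample_id)
            for rec in final_records:
                call = call_denovo(
                    rec,
                    child_calls.get(rec.key),
                    father_calls.get(rec.key),
                    mother_calls.get(rec.key),
                    family.family_id,
                    child.sample_id,
                    config.gate,
                )
                chrom, pos, ref, alt = rec.key
                denovo_rows.append(
                    {
                        "family": family.family_id,
                        "child": child.sample_id,
                        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                        "gene": rec.gene,
                        "status": call.status,
                        "reason": call.reason or "",
                    }
                )
                if call.passed:
                    fam_pass += 1
                    all_candidates.append(CandidateRank.from_record(rec, gene_map))
            if any(
                r["status"] == "pass"
                for r in denovo_rows
                if r["family"] == family.family_id and r["child"] == child.sample_id
            ):
                probands_with_candidates += 1

        fam_recessive = 0
        if config.run_recessive and len(family.affected_children) >= 2:
            # recessive mode uses the pre-parental-subtraction set: rare,
            # impact-qualifying variants carried by the affected children
            base = filter_population_frequency(
                filter_functional_impact(child_record_set(records_calls, family)),
                threshold=config.af_threshold,
            )
            site_calls = {
                rec.key: calls for rec, calls in records_calls
            }
            hom = find_homozygous_recessive(family, site_calls, base)
            comp = find_compound_het(family, site_calls, base)
            for cand in hom + comp:
                fam_recessive += 1
                recessive_rows.append(
                    {
                        "family": family.family_id,
                        "gene": cand.gene,
                        "mode": cand.mode,
                        "phase_support": cand.phase_support,
                        "n_variants": len(cand.keys),
                        "keys": ";".join(
                            f"{c}:{p}:{r}>{a}" for c, p, r, a in cand.keys
                        ),
                    }
                )

        manifest["families"][family.family_id] = {
            "stages": {s.stage: [s.variants_in, s.variants_out] for s in report.stages},
            "final_candidates": len(report.final_keys),
            "final_genes": report.final_gene_count,
            "denovo_pass": fam_pass,
            "recessive_candidates": fam_recessive,
        }

    ranked = rank_candidates(all_candidates)
    manifest["n_families"] = len(pedigree)
    manifest["n_probands"] = sum(len(f.affected_children) for f in pedigree)
    manifest["probands_with_candidates"] = probands_with_candidates
    manifest["candidate_variants"] = _dedup_count(ranked)
    manifest["class_tally"] = summarize_variant_classes(
        [by_key[c.key] for c in ranked], gene_map
    )

    pd.DataFrame(
        cascade_rows, columns=["family", "stage", "variants_in", "variants_out"]
    ).to_csv(out / "cascade_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        denovo_rows,
        columns=["family", "child", "chrom", "pos", "ref", "alt", "gene", "status", "reason"],
    ).to_csv(out / "denovo_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        recessive_rows,
        columns=["family", "gene", "mode", "phase_support", "n_variants", "keys"],
    ).to_csv(out / "recessive_candidates.tsv", sep="\t", index=False)
    _write_ranked(ranked, by_key, out / "ranked_candidates.tsv")

    if config.clinical_csv is not None:
        profiles = read_profiles(config.clinical_csv)
        summary = summarize_cohort(profiles)
        summary.to_csv(out / "clinical_summary.tsv", sep="\t", index=False)
        manifest["clinical"] = {
            row["trait"]: f'{row["count"]}/{row["denominator"]} ({row["percent"]}%)'
            for _, row in summary.iterrows()
        }

    with open(out / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _dedup_count(ranked: Sequence[CandidateRank]) -> int:
    return len({c.key for c in ranked})


def _write_ranked(ranked, by_key, path: Path) -> None:
    rows = []
    seen = set()
    for c in ranked:
        if c.key in seen:
            continue
        seen.add(c.key)
        rec = by_key[c.key]
        chrom, pos, ref, alt = c.key
        pred = rec.prediction
        rows.append(
            {
                "gene": c.gene,
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "variant_class": rec.variant_class,
                "hgvs_c": rec.hgvs_c or "",
                "hgvs_p": rec.hgvs_p or "",
                "exac_af": pred.exac_af if pred and pred.exac_af is not None else "",
                "sift": pred.sift if pred else "NA",
                "polyphen2": pred.polyphen2 if pred else "NA",
                "provean": pred.provean if pred else "NA",
                "mutation_taster2": pred.mutation_taster2 if pred else "NA",
                "conservation": (
                    pred.conservation
                    if pred and pred.conservation is not None
                    else ""
                ),
                "pathogenic_support": c.pathogenic_support,
                "predictor_coverage": c.predictor_coverage,
                "novel": c.novel,
                "known_ndd": c.known_ndd,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "pos", "ref", "alt", "variant_class", "hgvs_c",
            "hgvs_p", "exac_af", "sift", "polyphen2", "provean",
            "mutation_taster2", "conservation", "pathogenic_support",
            "predictor_coverage", "novel", "known_ndd",
        ],
    ).to_csv(path, sep="\t", index=False)


def summarize_variant_classes(
    records: Iterable[VariantRecord],
    gene_map: Optional[KnownGeneMap] = None,
) -> dict:
    """Tally candidates by variant class (SNV / insertion / deletion) and by
    known-NDD vs novel gene category, with one-decimal percentages.

    An empty input yields an all-zero tally.
    """
    records = list(records)
    if gene_map is None:
        gene_map = KnownGeneMap.bundled()
    tally = {
        "n": len(records),
        "SNV": 0,
        "insertion": 0,
        "deletion": 0,
        "indel": 0,
        "known_ndd": 0,
        "novel": 0,
    }
    for rec in records:
        tally[rec.variant_class] += 1
        if rec.gene is not None and rec.gene in gene_map:
            tally["known_ndd"] += 1
        else:
            tally["novel"] += 1
    tally["indel"] = tally["insertion"] + tally["deletion"]
    n = tally["n"]
    if n:
        tally["known_ndd_percent"] = percentage(tally["known_ndd"], n)
        tally["novel_percent"] = percentage(tally["novel"], n)
    else:
        tally["known_ndd_percent"] = 0.0
        tally["novel_percent"] = 0.0
    return tally


def summarize_locomotion(table: pd.DataFrame) -> dict:
    """Fraction of ortholog mutants classified locomotion-defective in the
    C. elegans phenotype table."""
    n = len(table)
    defective = int(
        (table["locomotion_phenotype"].str.strip() == "locomotion defective").sum()
    )
    return {
        "defective": defective,
        "n": n,
        "percent": percentage(defective, n) if n else 0.0,
    }
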