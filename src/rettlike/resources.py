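"""Loaders for the small reference tables bundled with the package:

- the known neurodevelopmental-disorder gene map,
- the 22-variant candidate table of the motivating Rett-like cohort
  (gene, coordinates, alleles, ExAC frequency, four predictor calls,
  conservation),
- the clinical severity profiles of that cohort's unambiguously printed
  probands, and
- the C. elegans ortholog locomotion phenotype table used as a worked
  example of downstream functional triage.
"""

from __future__ import annotations

from importlib import resources as _ilres
from io import StringIO

import pandas as pd

from .model import PredictionProfile, VariantRecord
from .prioritize import KnownGeneMap

__all__ = [
    "load_known_gene_map",
    "load_candidate_table",
    "candidate_records",
    "load_clinical_profiles_csv",
    "load_celegans_table",
]


def _read(name: str) -> str:
    return _ilres.files("rettlike.data").joinpath(name).read_text()


def load_known_gene_map() -> KnownGeneMap:
    return KnownGeneMap.bundled()


def load_candidate_table() -> pd.DataFrame:
    """The cohort's 22 de novo candidate variants as a DataFrame."""
    return pd.read_csv(StringIO(_read("candidate_variants.tsv")), sep="\t", na_values=["."])


def candidate_records() -> list[VariantRecord]:
    """The candidate table as normalized :class:`VariantRecord` objects."""
    df = load_candidate_table()
    records = []
    for _, row in df.iterrows():
        exac = None if pd.isna(row["exac_af"]) else float(row["exac_af"])
        cons = None if pd.isna(row["conservation"]) else int(row["conservation"])
        labels = {
            slot: (row[slot] if isinstance(row[slot], str) else "NA")
            for slot in ("sift", "polyphen2", "provean", "mutation_taster2")
        }
        has_pred = any(v != "NA" for v in labels.values()) or cons is not None
        af_map = {} if exac is None else {"ExAC": exac}
        records.append(
            VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                consequence=(
                    "missense_variant"
                    if len(row["ref"]) == len(row["alt"])
                    else "frameshift_variant"
                ),
                hgvs_c=row["hgvs_c"],
                hgvs_p=row["hgvs_p"],
                af_map=af_map,
                prediction=(
                    PredictionProfile(**labels, exac_af=exac, conservation=cons)
                    if has_pred
                    else None
                ),
            )
        )
    return records


def load_clinical_profiles_csv() -> StringIO:
    """The bundled clinical CSV as a file-like object for
    :func:`rettlike.clinical.read_profiles` (which also takes paths)."""
    return StringIO(_read("clinical_profiles.csv"))


def load_celegans_table() -> pd.DataFrame:
    return pd.read_csv(StringIO(_read("celegans_locomotion.tsv")), sep="\t")
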