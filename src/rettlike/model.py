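"""Core data model: variants, genotype calls, pedigrees, VCF/PED ingest.

Positions are 1-based throughout, following the VCF convention. Multiallelic
sites are split into one record per alternate allele, and indel alleles are
trimmed to their minimal representation, before any filtering — so that
``(chrom, pos, ref, alt)`` is a canonical key usable for set subtraction
between family members and against the pooled parental control panel.

Annotation (gene symbol, consequence term, population allele frequencies,
pathogenicity predictor calls, conservation) is *consumed*, never computed:
it is read from INFO keys named by an :class:`AnnotationConfig`, so VCFs
annotated with different dialects can be mapped onto one data model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, TextIO, Union

from pydantic import BaseModel, Field

__all__ = [
    "SNV",
    "INSERTION",
    "DELETION",
    "PREDICTOR_NAMES",
    "PredictionProfile",
    "VariantRecord",
    "GenotypeCall",
    "Child",
    "Family",
    "Pedigree",
    "AnnotationConfig",
    "RettlikeError",
    "VcfParseError",
    "PedigreeError",
    "ConfigurationError",
    "classify_variant",
    "normalize_allele_pair",
    "variant_key",
    "read_vcf",
    "write_vcf",
    "read_pedigree",
]

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

#: The four in-silico damage predictors whose discretized calls are consumed.
PREDICTOR_NAMES = ("sift", "polyphen2", "provean", "mutation_taster2")

_PRED_LABELS = frozenset({"P", "B", "NA"})


class RettlikeError(Exception):
    """Base class for all package errors."""


class VcfParseError(RettlikeError):
    """A VCF stream could not be parsed."""


class PedigreeError(RettlikeError):
    """A PED file is structurally invalid."""


class ConfigurationError(RettlikeError):
    """An annotation/filter configuration is inconsistent with the data."""


def classify_variant(ref: str, alt: str) -> str:
    """Classify an allele pair as SNV, insertion or deletion.

    Both alleles are required non-empty and distinct; equal-length
    multi-nucleotide substitutions are outside the supported vocabulary
    and raise.
    """
    if not ref or not alt:
        raise ValueError("ref and alt alleles must be non-empty")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r}); not a variant")
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if len(alt) > len(ref):
        return INSERTION
    if len(ref) > len(alt):
        return DELETION
    raise ValueError(
        f"equal-length substitution {ref!r}>{alt!r} is not representable "
        "as SNV/insertion/deletion"
    )


def normalize_allele_pair(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim an allele pair to minimal representation (shared suffix, then
    shared prefix), adjusting the 1-based position.

    This is the reference-free part of left normalization; full
    left-alignment through repeat tracts requires the reference genome and
    is out of scope here.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    return (str(chrom), int(pos), str(ref), str(alt))


@dataclass(frozen=True)
class PredictionProfile:
    """Discretized evidence for one variant: four predictor calls
    (P = likely pathogenic, B = likely benign, NA = not available), the
    ExAC allele frequency if observed, and a 0–1000 nucleotide conservation
    score (higher = more conserved across vertebrates)."""

    sift: str = "NA"
    polyphen2: str = "NA"
    provean: str = "NA"
    mutation_taster2: str = "NA"
    exac_af: Optional[float] = None
    conservation: Optional[int] = None

    def __post_init__(self) -> None:
        for name in PREDICTOR_NAMES:
            label = getattr(self, name)
            if label not in _PRED_LABELS:
                raise ValueError(
                    f"predictor {name} label {label!r} not in {sorted(_PRED_LABELS)}"
                )
        if self.exac_af is not None and not 0.0 <= self.exac_af <= 1.0:
            raise ValueError(f"exac_af {self.exac_af} outside [0, 1]")
        if self.conservation is not None and not 0 <= self.conservation <= 1000:
            raise ValueError(f"conservation {self.conservation} outside [0, 1000]")

    @property
    def labels(self) -> tuple[str, str, str, str]:
        return (self.sift, self.polyphen2, self.provean, self.mutation_taster2)


@dataclass
class VariantRecord:
    """One normalized biallelic variant with its annotations.

    ``af_map`` maps an allele-frequency source name (e.g. ``dbSNP``,
    ``1000G``, ``ExAC``) to a frequency in [0, 1]; a missing key means the
    variant was not observed in that source.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequence: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    af_map: dict[str, float] = field(default_factory=dict)
    prediction: Optional[PredictionProfile] = None

    def __post_init__(self) -> None:
        self.pos = int(self.pos)
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1 (coordinates are 1-based)")
        # raises on empty/equal alleles and sets the class invariant
        self.variant_class = classify_variant(self.ref, self.alt)
        for source, af in self.af_map.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} for {source} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    def max_af(self, sources: Optional[Iterable[str]] = None) -> Optional[float]:
        """Highest frequency across the requested sources; None if absent
        from all of them (a novel variant)."""
        if sources is None:
            values = list(self.af_map.values())
        else:
            values = [self.af_map[s] for s in sources if s in self.af_map]
        return max(values) if values else None


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid call at one biallelic site.

    ``alleles`` is an ordered pair over {0, 1, None}; any None makes the
    call a no-call, which never counts as carrying the variant.
    """

    sample_id: str
    alleles: tuple[Optional[int], Optional[int]]
    depth: int = 0
    genotype_quality: float = 0.0
    allele_depths: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.genotype_quality < 0:
            raise ValueError("genotype_quality must be >= 0")
        ref_n, alt_n = self.allele_depths
        if ref_n < 0 or alt_n < 0 or ref_n + alt_n > self.depth:
            raise ValueError(
                f"allele depths {self.allele_depths} inconsistent with depth {self.depth}"
            )
        for a in self.alleles:
            if a not in (0, 1, None):
                raise ValueError(f"allele {a!r} not in {{0, 1, None}}")

    @property
    def is_nocall(self) -> bool:
        return self.alleles[0] is None or self.alleles[1] is None

    @property
    def n_alt(self) -> int:
        """Number of alternate alleles in the call; 0 for no-calls."""
        if self.is_nocall:
            return 0
        return int(self.alleles[0]) + int(self.alleles[1])  # type: ignore[arg-type]

    @property
    def carries_alt(self) -> bool:
        return self.n_alt > 0

    @property
    def is_hom_ref(self) -> bool:
        return not self.is_nocall and self.n_alt == 0

    @property
    def is_het(self) -> bool:
        return not self.is_nocall and self.n_alt == 1

    @property
    def is_hom_alt(self) -> bool:
        return not self.is_nocall and self.n_alt == 2

    @property
    def alt_fraction(self) -> Optional[float]:
        """Fraction of reads supporting the alternate allele (allele
        balance); None when no allele depths were recorded."""
        ref_n, alt_n = self.allele_depths
        total = ref_n + alt_n
        if total == 0:
            return None
        return alt_n / total


@dataclass(frozen=True)
class Child:
    sample_id: str
    affected: bool
    sex: str = "unknown"  # "female" | "male" | "unknown"


@dataclass
class Family:
    family_id: str
    father_id: str
    mother_id: str
    children: list[Child]

    @property
    def affected_children(self) -> list[Child]:
        return [c for c in self.children if c.affected]

    @property
    def member_ids(self) -> list[str]:
        return [self.father_id, self.mother_id] + [c.sample_id for c in self.children]


@dataclass
class Pedigree:
    families: list[Family] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam in self.families:
            for sid in fam.member_ids:
                if sid in seen and sid not in (fam.father_id, fam.mother_id):
                    raise PedigreeError(f"duplicate sample id {sid!r}")
                seen.add(sid)

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families)

    def family(self, family_id: str) -> Family:
        for fam in self.families:
            if fam.family_id == family_id:
                return fam
        raise KeyError(family_id)

    @property
    def parent_ids(self) -> list[str]:
        """All parental sample ids across the cohort (the control pool)."""
        out: list[str] = []
        for fam in self.families:
            out.extend([fam.father_id, fam.mother_id])
        return out


class AnnotationConfig(BaseModel):
    """Maps the pipeline's annotation slots onto the INFO keys of a
    particular VCF dialect. The defaults match the VCFs written by this
    package's simulator and writer."""

    gene_key: str = "GENE"
    consequence_key: str = "CONSEQ"
    hgvs_c_key: str = "HGVSC"
    hgvs_p_key: str = "HGVSP"
    af_keys: dict[str, str] = Field(
        default_factory=lambda: {
            "dbSNP": "AF_DBSNP",
            "1000G": "AF_1KG",
            "ExAC": "AF_EXAC",
        }
    )
    predictor_keys: dict[str, str] = Field(
        default_factory=lambda: {
            "sift": "SIFT",
            "polyphen2": "POLYPHEN2",
            "provean": "PROVEAN",
            "mutation_taster2": "MTASTER2",
        }
    )
    conservation_key: str = "CONS"

    @property
    def af_sources(self) -> list[str]:
        return list(self.af_keys)


DEFAULT_ANNOTATION = AnnotationConfig()

# ---------------------------------------------------------------------------
# VCF ingest


def _canon_af(value: float) -> float:
    # 6 significant digits: stable through htslib's float32 INFO storage,
    # so write → read round-trips to field-by-field equality.
    return float(f"{float(value):.6g}")


def _per_alt(value, alt_idx: int, n_alts: int, key: str):
    """Resolve an INFO value that may be scalar (site-wide) or per-alt."""
    if isinstance(value, (tuple, list)):
        if len(value) != n_alts:
            raise ConfigurationError(
                f"INFO key {key} has {len(value)} values for {n_alts} alt alleles"
            )
        return value[alt_idx]
    if isinstance(value, str) and "," in value:
        parts = value.split(",")
        if len(parts) != n_alts:
            raise ConfigurationError(
                f"INFO key {key} has {len(parts)} values for {n_alts} alt alleles"
            )
        return parts[alt_idx]
    return value


def _decode(value):
    if isinstance(value, bytes):
        return value.decode()
    return value


def _locate_malformed_line(path: Path) -> Optional[int]:
    """Best-effort scan for the first structurally broken data line, so the
    parse error can cite a line number (htslib does not report one)."""
    try:
        with open(path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 8:
                    return lineno
                if not cols[1].isdigit():
                    return lineno
    except OSError:
        return None
    return None


def read_vcf(
    source: Union[str, Path, TextIO],
    annotation: AnnotationConfig = DEFAULT_ANNOTATION,
    tmp_dir: Optional[Path] = None,
) -> list[tuple[VariantRecord, dict[str, GenotypeCall]]]:
    """Read a VCF 4.x file (plain or gzip) into normalized records.

    Multiallelic sites are split into one record per alternate allele
    (genotype allele indices remapped: this record's alt → 1, reference and
    any *other* alt → 0) and indel alleles trimmed to minimal
    representation. Unknown INFO keys are ignored.

    Returns a list of ``(VariantRecord, {sample_id: GenotypeCall})`` in file
    order. File-like sources are spooled to a temporary file because the
    underlying htslib reader requires a path.
    """
    import tempfile

    from cyvcf2 import VCF

    if hasattr(source, "read"):
        with tempfile.NamedTemporaryFile(
            "wt", suffix=".vcf", dir=tmp_dir, delete=False
        ) as tmp:
            tmp.write(source.read())  # type: ignore[union-attr]
            path = Path(tmp.name)
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)

    out: list[tuple[VariantRecord, dict[str, GenotypeCall]]] = []
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare Exceptions
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    try:
        for v in vcf:
            out.extend(_split_site(v, samples, annotation))
    except (RettlikeError, ValueError):
        raise
    except Exception as exc:
        lineno = _locate_malformed_line(path)
        where = f" at line {lineno}" if lineno is not None else ""
        raise VcfParseError(f"malformed VCF record{where}: {exc}") from exc
    finally:
        vcf.close()
    return out


def _split_site(v, samples, annotation):
    alts = list(v.ALT)
    n_alts = len(alts)
    if n_alts == 0:
        return []
    genotypes = v.genotypes  # [[a0, a1, phased], ...]
    depths = v.gt_depths
    quals = v.gt_quals
    try:
        ad = v.format("AD")
    except KeyError:
        ad = None

    results = []
    for alt_idx, alt in enumerate(alts):
        if alt is None or alt in (".", "*", "<NON_REF>"):
            continue
        pos, ref, alt_t = normalize_allele_pair(v.POS, v.REF, alt)

        af_map: dict[str, float] = {}
        for source, key in annotation.af_keys.items():
            raw = v.INFO.get(key)
            if raw is None:
                continue
            value = _per_alt(raw, alt_idx, n_alts, key)
            if value is None:
                continue
            af_map[source] = _canon_af(value)

        pred_labels = {}
        any_pred = False
        for slot, key in annotation.predictor_keys.items():
            raw = _decode(v.INFO.get(key))
            if raw is None:
                pred_labels[slot] = "NA"
            else:
                pred_labels[slot] = str(_per_alt(raw, alt_idx, n_alts, key))
                any_pred = True
        cons_raw = v.INFO.get(annotation.conservation_key)
        conservation = (
            int(_per_alt(cons_raw, alt_idx, n_alts, annotation.conservation_key))
            if cons_raw is not None
            else None
        )
        exac = af_map.get("ExAC")
        prediction = None
        if any_pred or conservation is not None:
            prediction = PredictionProfile(
                **pred_labels, exac_af=exac, conservation=conservation
            )

        record = VariantRecord(
            chrom=str(v.CHROM),
            pos=pos,
            ref=ref,
            alt=alt_t,
            gene=_opt_str(v.INFO.get(annotation.gene_key), alt_idx, n_alts, annotation.gene_key),
            consequence=_opt_str(
                v.INFO.get(annotation.consequence_key), alt_idx, n_alts, annotation.consequence_key
            ),
            hgvs_c=_opt_str(v.INFO.get(annotation.hgvs_c_key), alt_idx, n_alts, annotation.hgvs_c_key),
            hgvs_p=_opt_str(v.INFO.get(annotation.hgvs_p_key), alt_idx, n_alts, annotation.hgvs_p_key),
            af_map=af_map,
            prediction=prediction,
        )

        calls: dict[str, GenotypeCall] = {}
        for i, sample in enumerate(samples):
            raw_gt = genotypes[i]
            pair = tuple(
                None if a < 0 else (1 if a == alt_idx + 1 else 0) for a in raw_gt[:2]
            )
            depth = int(depths[i]) if depths[i] >= 0 else 0
            gq = float(quals[i]) if quals[i] >= 0 else 0.0
            if ad is not None and ad.shape[1] > alt_idx + 1:
                ref_n = int(ad[i, 0]) if ad[i, 0] >= 0 else 0
                alt_n = int(ad[i, alt_idx + 1]) if ad[i, alt_idx + 1] >= 0 else 0
            else:
                ref_n = alt_n = 0
            if ref_n + alt_n > depth:
                depth = ref_n + alt_n
            calls[sample] = GenotypeCall(
                sample_id=sample,
                alleles=pair,  # type: ignore[arg-type]
                depth=depth,
                genotype_quality=gq,
                allele_depths=(ref_n, alt_n),
            )
        results.append((record, calls))
    return results


def _opt_str(raw, alt_idx, n_alts, key) -> Optional[str]:
    raw = _decode(raw)
    if raw is None:
        return None
    return str(_per_alt(raw, alt_idx, n_alts, key))


# ---------------------------------------------------------------------------
# VCF output

_VCF_HEADER_LINES = [
    '##INFO=<ID={gene},Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID={conseq},Number=1,Type=String,Description="Consequence term">',
    '##INFO=<ID={hgvsc},Number=1,Type=String,Description="HGVS cDNA change">',
    '##INFO=<ID={hgvsp},Number=1,Type=String,Description="HGVS protein change">',
    '##INFO=<ID={cons},Number=1,Type=Integer,Description="Conservation score 0-1000">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
]


def write_vcf(
    records_calls: Iterable[tuple[VariantRecord, Mapping[str, GenotypeCall]]],
    samples: list[str],
    dest: Union[str, Path, TextIO],
    annotation: AnnotationConfig = DEFAULT_ANNOTATION,
) -> None:
    """Write normalized records back out as a plain-text multi-sample VCF."""
    records_calls = list(records_calls)
    chroms: list[str] = []
    for rec, _ in records_calls:
        if rec.chrom not in chroms:
            chroms.append(rec.chrom)

    own = isinstance(dest, (str, Path))
    fh: TextIO = open(dest, "wt") if own else dest  # type: ignore[assignment]
    try:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rettlike\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom},length=536870912>\n")
        for source, key in annotation.af_keys.items():
            fh.write(
                f'##INFO=<ID={key},Number=A,Type=Float,Description='
                f'"Allele frequency in {source}">\n'
            )
        for slot, key in annotation.predictor_keys.items():
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=String,Description='
                f'"{slot} call: P/B/NA">\n'
            )
        for line in _VCF_HEADER_LINES:
            fh.write(
                line.format(
                    gene=annotation.gene_key,
                    conseq=annotation.consequence_key,
                    hgvsc=annotation.hgvs_c_key,
                    hgvsp=annotation.hgvs_p_key,
                    cons=annotation.conservation_key,
                )
                + "\n"
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec, calls in records_calls:
            fh.write(_format_record(rec, calls, samples, annotation))
    finally:
        if own:
            fh.close()


def _format_record(rec, calls, samples, annotation) -> str:
    info_parts: list[str] = []
    if rec.gene is not None:
        info_parts.append(f"{annotation.gene_key}={rec.gene}")
    if rec.consequence is not None:
        info_parts.append(f"{annotation.consequence_key}={rec.consequence}")
    if rec.hgvs_c is not None:
        info_parts.append(f"{annotation.hgvs_c_key}={rec.hgvs_c}")
    if rec.hgvs_p is not None:
        info_parts.append(f"{annotation.hgvs_p_key}={rec.hgvs_p}")
    for source, key in annotation.af_keys.items():
        if source in rec.af_map:
            info_parts.append(f"{key}={rec.af_map[source]:.6g}")
    if rec.prediction is not None:
        p = rec.prediction
        for slot, key in annotation.predictor_keys.items():
            label = getattr(p, slot)
            if label != "NA":
                info_parts.append(f"{key}={label}")
        if p.conservation is not None:
            info_parts.append(f"{annotation.conservation_key}={p.conservation}")
    info = ";".join(info_parts) if info_parts else "."

    fields = [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, "999", "PASS", info, "GT:DP:GQ:AD"]
    for sample in samples:
        call = calls.get(sample)
        if call is None:
            fields.append("./.:0:0:0,0")
            continue
        a0, a1 = call.alleles
        gt = f"{'.' if a0 is None else a0}/{'.' if a1 is None else a1}"
        ref_n, alt_n = call.allele_depths
        fields.append(f"{gt}:{call.depth}:{int(call.genotype_quality)}:{ref_n},{alt_n}")
    return "\t".join(fields) + "\n"


# ---------------------------------------------------------------------------
# PED ingest


def read_pedigree(source: Union[str, Path, TextIO]) -> Pedigree:
    """Read a 6-column PED file (family, sample, father, mother, sex,
    phenotype) into a :class:`Pedigree`.

    Founders have father/mother ``0``; phenotype ``2`` marks affected.
    A child referencing an absent parent, or a duplicated sample id, is an
    error. An empty file yields an empty pedigree (downstream stages refuse
    to run on it).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()

    rows: list[tuple[str, str, str, str, str, str]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedigreeError(f"PED line {lineno}: expected 6 columns, got {len(cols)}")
        fam, sid, father, mother, sex, pheno = cols[:6]
        if sid in seen:
            raise PedigreeError(f"PED line {lineno}: duplicate sample {sid!r}")
        seen.add(sid)
        rows.append((fam, sid, father, mother, sex, pheno))

    sex_map = {"1": "male", "2": "female"}
    families: dict[str, Family] = {}
    for fam, sid, father, mother, sex, pheno in rows:
        if father == "0" and mother == "0":
            continue  # founder
        for parent in (father, mother):
            if parent != "0" and parent not in seen:
                raise PedigreeError(
                    f"sample {sid!r} references unknown parent {parent!r}"
                )
        child = Child(
            sample_id=sid,
            affected=(pheno == "2"),
            sex=sex_map.get(sex, "unknown"),
        )
        if fam not in families:
            families[fam] = Family(
                family_id=fam, father_id=father, mother_id=mother, children=[]
            )
        families[fam].children.append(child)

    for fam in families.values():
        if not fam.affected_children:
            raise PedigreeError(
                f"family {fam.family_id!r} has no affected child; "
                "trio analysis requires at least one"
            )
    return Pedigree(families=list(families.values()))
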