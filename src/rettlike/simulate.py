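"""Synthetic trio-cohort generator.

Emulates the statistical structure that the variant-reduction cascade
assumes, at desk scale: a panel of exome sites with a population allele
frequency spectrum mixing common polymorphisms (AF >= 1%), rare known
variants and novel variants absent from every frequency source; parental
genotypes drawn from those frequencies under Hardy–Weinberg equilibrium;
children genotyped by Mendelian transmission; and planted events on top —
per-child de novo coding variants, variants recurring in the pooled
parental control panel, and (for one family with two affected siblings) a
homozygous-recessive site plus a compound-heterozygous gene pair.
Genotyping errors can be injected at a configurable per-call rate.

Everything is reproducible from one master seed. Randomness is organized as
hierarchical substreams keyed by purpose (site panel / control plantings /
per-family genotypes / per-family emission), so changing one family's
plantings leaves every other family's genotypes and quality fields
byte-identical. The price of that locality: a family's samples receive
constant "solid reference" quality fields at sites planted for *other*
families, rather than freshly drawn ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .model import (
    AnnotationConfig,
    ConfigurationError,
    DEFAULT_ANNOTATION,
    GenotypeCall,
    VariantRecord,
    write_vcf,
)

__all__ = [
    "AFSpectrum",
    "CohortConfig",
    "TruthTable",
    "TruthRow",
    "CohortPaths",
    "TRUTH_LABELS",
    "generate_cohort",
    "inject_genotype_errors",
]

TRUTH_LABELS = (
    "common_polymorphism",
    "rare_inherited",
    "control_shared",
    "de_novo_planted",
    "hom_recessive_planted",
    "compound_het_planted",
    "error_artifact",
)

_BASES = ("A", "C", "G", "T")
FUNCTIONAL_CONSEQUENCE = "missense_variant"

# quality fields for a sample that is a confident non-carrier at a site
# planted for some other family (constant, for substream locality)
_SOLID_REF = (50, 99.0, (50, 0))


class AFSpectrum(BaseModel):
    """Allele-frequency spectrum for the background site panel.

    Rare sites draw from a beta distribution concentrated below
    ``max_rare_af``; a ``novel_fraction`` of them is additionally omitted
    from every frequency source (simulating variants absent from dbSNP /
    1000 Genomes / ExAC) while still segregating at ``novel_sim_af`` in the
    simulated population.
    """

    beta_a: float = 0.3
    beta_b: float = 60.0
    max_rare_af: float = 0.0099
    novel_fraction: float = 0.25
    novel_sim_af: float = 0.002
    common_low: float = 0.05
    common_high: float = 0.5


class CohortConfig(BaseModel):
    """Study conditions for one synthetic cohort.

    Defaults give five families (the last with two affected daughters
    carrying the planted recessive candidates) over a 10,000-site exome
    panel — a desk-scale stand-in for the hundreds of thousands of raw
    variants of a real exome cohort.
    """

    n_families: int = 5
    n_sites: int = 10_000
    frac_common: float = 0.30
    af_spectrum: AFSpectrum = Field(default_factory=AFSpectrum)
    n_denovo_per_child: int = 2
    n_control_shared: int = 2
    recessive_family: bool = True
    genotype_error_rate: float = 0.0
    # background consequence mix; planted candidates are always missense
    consequence_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "intron_variant": 0.60,
            "synonymous_variant": 0.35,
            "missense_variant": 0.05,
        }
    )
    indel_fraction: float = 0.02
    depth_mean: float = 50.0
    gq_pass: int = 99
    borderline_fraction: float = 0.0  # fraction of calls emitted below-gate
    sites_per_gene: int = 5
    master_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if not 0.0 <= self.frac_common <= 1.0:
            raise ConfigurationError("frac_common must be in [0, 1]")
        if not 0.0 <= self.genotype_error_rate < 1.0:
            raise ConfigurationError("genotype_error_rate must be in [0, 1)")
        for name in ("n_sites", "n_denovo_per_child", "n_control_shared"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_families < 1:
            raise ConfigurationError("need at least one family")
        planted = (
            self.n_denovo_per_child
            + self.n_control_shared
            + (3 if self.recessive_family else 0)
        )
        if self.n_sites < max(planted, 1):
            raise ConfigurationError(
                f"n_sites={self.n_sites} too small to host {planted} planted events"
            )
        if self.n_control_shared > 0 and self.n_families < 3:
            raise ConfigurationError(
                "control-shared planting needs >= 3 families "
                "(a carrier child plus parents of >= 2 other families)"
            )
        if sum(self.consequence_mix.values()) <= 0:
            raise ConfigurationError("consequence_mix must have positive weight")
        return self


@dataclass(frozen=True)
class TruthRow:
    key: tuple[str, int, str, str]
    family_id: str  # "*" for cohort-wide site-class labels
    sample_id: str
    label: str


@dataclass
class TruthTable:
    """Ground-truth labels for every emitted variant.

    Site-class labels (common polymorphism / rare inherited) are cohort-wide
    rows with family and sample ``*``; planted events and error artifacts
    carry the family (and, where meaningful, the child) they concern.
    """

    rows: list[TruthRow] = field(default_factory=list)

    def add(self, key, family_id, sample_id, label) -> None:
        if label not in TRUTH_LABELS:
            raise ValueError(f"unknown truth label {label!r}")
        self.rows.append(TruthRow(tuple(key), family_id, sample_id, label))

    def keys_with_label(
        self,
        label: str,
        family_id: Optional[str] = None,
        sample_id: Optional[str] = None,
    ) -> set[tuple[str, int, str, str]]:
        return {
            r.key
            for r in self.rows
            if r.label == label
            and (family_id is None or r.family_id == family_id)
            and (sample_id is None or r.sample_id == sample_id)
        }

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rows:
            out[r.label] = out.get(r.label, 0) + 1
        return out

    def write(self, path: Path | str) -> None:
        with open(path, "wt") as fh:
            fh.write("chrom\tpos\tref\talt\tfamily\tsample\tlabel\n")
            for r in self.rows:
                chrom, pos, ref, alt = r.key
                fh.write(
                    f"{chrom}\t{pos}\t{ref}\t{alt}\t{r.family_id}\t{r.sample_id}\t{r.label}\n"
                )

    @classmethod
    def read(cls, path: Path | str) -> "TruthTable":
        table = cls()
        with open(path) as fh:
            next(fh)
            for line in fh:
                chrom, pos, ref, alt, fam, sample, label = line.rstrip("\n").split("\t")
                table.add((chrom, int(pos), ref, alt), fam, sample, label)
        return table


@dataclass(frozen=True)
class CohortPaths:
    vcf: Path
    ped: Path
    truth: Path


# ---------------------------------------------------------------------------
# genotype-error injection (public per-call API; the generator uses the same
# perturbation scheme on its genotype matrices)


def inject_genotype_errors(
    calls: Sequence[GenotypeCall], rate: float, seed: int
) -> list[GenotypeCall]:
    """Independently perturb each call with probability ``rate``.

    Perturbations move one step in alt-allele count (0/0 <-> 0/1 and
    0/1 <-> 1/1, hets flipping either way with equal probability); allele
    depths are redrawn to match the perturbed genotype. No-calls are left
    untouched. ``rate`` must lie in [0, 1): a certain error is not a
    genotyping model.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"error rate {rate} outside [0, 1)")
    rng = np.random.default_rng(seed)
    if rate == 0.0:
        return list(calls)
    out: list[GenotypeCall] = []
    flips = rng.random(len(calls)) < rate
    for call, flip in zip(calls, flips):
        if not flip or call.is_nocall:
            out.append(call)
            continue
        n_alt = call.n_alt
        if n_alt in (0, 2):
            new = 1
        else:
            new = 0 if rng.random() < 0.5 else 2
        out.append(_with_genotype(call, new, rng))
    return out


def _with_genotype(call: GenotypeCall, n_alt: int, rng: np.random.Generator) -> GenotypeCall:
    alleles = [(0, 0), (0, 1), (1, 1)][n_alt]
    depth = call.depth if call.depth > 0 else 30
    alt_n = _alt_depth(n_alt, depth, rng)
    return GenotypeCall(
        sample_id=call.sample_id,
        alleles=alleles,  # type: ignore[arg-type]
        depth=depth,
        genotype_quality=call.genotype_quality,
        allele_depths=(depth - alt_n, alt_n),
    )


def _alt_depth(n_alt: int, depth: int, rng: np.random.Generator) -> int:
    if n_alt == 0:
        return 0
    if n_alt == 2:
        return depth
    # het: keep allele balance comfortably inside the usual [0.25, 0.75] gate
    return int(round(depth * rng.uniform(0.35, 0.65)))


# ---------------------------------------------------------------------------
# internal layout


@dataclass
class _FamilyLayout:
    family_id: str
    father: str
    mother: str
    children: list[str]

    @property
    def members(self) -> list[str]:
        return [self.father, self.mother] + self.children


@dataclass
class _Panel:
    pos: np.ndarray
    ref: list[str]
    alt: list[str]
    af: np.ndarray       # simulated population AF (always > 0)
    known: np.ndarray    # bool: present in AF sources
    common: np.ndarray   # bool: AF >= 1% class
    gene: list[str]
    consequence: list[str]


@dataclass
class _PlantedSite:
    pos: int
    ref: str
    alt: str
    gene: str
    label: str
    family_idx: Optional[int]  # None for cohort-level (control-shared) sites
    carriers: dict[str, int]   # sample -> alt-allele count; others hom-ref

    @property
    def key(self) -> tuple[str, int, str, str]:
        return ("1", self.pos, self.ref, self.alt)


def _stream(master_seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=spawn_key)
    )


def _family_layout(config: CohortConfig) -> list[_FamilyLayout]:
    families = []
    for i in range(config.n_families):
        fid = f"FAM{i + 1:02d}"
        two_kids = config.recessive_family and i == config.n_families - 1
        children = [f"{fid}_C1"] + ([f"{fid}_C2"] if two_kids else [])
        families.append(_FamilyLayout(fid, f"{fid}_FA", f"{fid}_MO", children))
    return families


def _family_block_start(config: CohortConfig, fam_idx: int) -> int:
    return 1_000 + 10 * config.n_sites + fam_idx * 10_000


def _control_block_start(config: CohortConfig) -> int:
    return _family_block_start(config, config.n_families)


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(0, 4))
    s = int(rng.integers(1, 4))
    return _BASES[i], _BASES[(i + s) % 4]


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    config: CohortConfig,
    out_dir: Path | str,
    annotation: AnnotationConfig = DEFAULT_ANNOTATION,
) -> tuple[CohortPaths, TruthTable]:
    """Generate one cohort: a multi-sample VCF, a PED file and a truth table.

    Layout: families ``FAM01..``; members ``<fam>_FA``, ``<fam>_MO`` and
    children ``<fam>_C1`` (``_C2`` for the two-affected-siblings family,
    which is always the last family when ``recessive_family`` is set).
    All children are affected girls, as in a Rett-spectrum cohort.
    Deterministic: the same config (including ``master_seed``) yields
    byte-identical output files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    panel = _build_panel(config, _stream(config.master_seed, 0))
    families = _family_layout(config)
    truth = TruthTable()

    geno: dict[str, np.ndarray] = {}
    planted: list[_PlantedSite] = []
    for fam_idx, fam in enumerate(families):
        rng = _stream(config.master_seed, 2, fam_idx)
        _simulate_family(config, panel, fam, fam_idx, rng, geno, planted, truth)
    _plant_control_shared(config, families, _stream(config.master_seed, 1), planted, truth)

    # cohort-wide site-class truth rows for the background panel
    for i in range(config.n_sites):
        label = "common_polymorphism" if panel.common[i] else "rare_inherited"
        truth.add(("1", int(panel.pos[i]), panel.ref[i], panel.alt[i]), "*", "*", label)

    sample_order = [s for fam in families for s in fam.members]
    records_calls = _emit(config, panel, planted, geno, families)

    paths = CohortPaths(
        vcf=out_dir / "cohort.vcf",
        ped=out_dir / "cohort.ped",
        truth=out_dir / "truth.tsv",
    )
    write_vcf(records_calls, sample_order, paths.vcf, annotation)
    _write_ped(families, paths.ped)
    truth.write(paths.truth)
    return paths, truth


def _build_panel(config: CohortConfig, rng: np.random.Generator) -> _Panel:
    n = config.n_sites
    spec = config.af_spectrum
    pos = 1_000 + 10 * np.arange(n)
    common = rng.random(n) < config.frac_common
    af = np.empty(n)
    af[common] = rng.uniform(spec.common_low, spec.common_high, int(common.sum()))
    rare = ~common
    raw = rng.beta(spec.beta_a, spec.beta_b, int(rare.sum()))
    af[rare] = np.clip(raw, 1e-4, spec.max_rare_af)
    known = np.ones(n, dtype=bool)
    novel = rare & (rng.random(n) < spec.novel_fraction)
    known[novel] = False
    af[novel] = spec.novel_sim_af
    af = np.array([float(f"{x:.6g}") for x in af])

    ref_idx = rng.integers(0, 4, n)
    alt_shift = rng.integers(1, 4, n)
    ref = [_BASES[i] for i in ref_idx]
    alt = [_BASES[(i + s) % 4] for i, s in zip(ref_idx, alt_shift)]
    is_indel = rng.random(n) < config.indel_fraction
    extra = rng.integers(0, 4, n)
    ins_or_del = rng.random(n) < 0.5
    for i in np.flatnonzero(is_indel):
        if ins_or_del[i]:
            alt[i] = ref[i] + _BASES[extra[i]]      # insertion
        else:
            ref[i] = ref[i] + _BASES[extra[i]]      # deletion
            alt[i] = ref[i][0]

    genes = [f"GENE{i // config.sites_per_gene:05d}" for i in range(n)]
    terms = list(config.consequence_mix)
    weights = np.array([config.consequence_mix[t] for t in terms], dtype=float)
    weights /= weights.sum()
    consequence = [terms[i] for i in rng.choice(len(terms), n, p=weights)]
    return _Panel(pos, ref, alt, af, known, common, genes, consequence)


def _mendelian_child(
    father: np.ndarray, mother: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    pa = rng.random(father.shape) < father / 2.0
    ma = rng.random(mother.shape) < mother / 2.0
    return pa.astype(np.int8) + ma.astype(np.int8)


def _simulate_family(
    config: CohortConfig,
    panel: _Panel,
    fam: _FamilyLayout,
    fam_idx: int,
    rng: np.random.Generator,
    geno: dict[str, np.ndarray],
    planted: list[_PlantedSite],
    truth: TruthTable,
) -> None:
    n = config.n_sites
    father = rng.binomial(2, panel.af).astype(np.int8)
    mother = rng.binomial(2, panel.af).astype(np.int8)
    geno[fam.father] = father
    geno[fam.mother] = mother
    children = {c: _mendelian_child(father, mother, rng) for c in fam.children}
    geno.update(children)

    # genotyping errors on the background panel (per-family substream)
    if config.genotype_error_rate > 0:
        for sid in fam.members:
            g = geno[sid]
            idx = np.flatnonzero(rng.random(n) < config.genotype_error_rate)
            for i in idx:
                g[i] = 1 if g[i] in (0, 2) else (0 if rng.random() < 0.5 else 2)
        # apparent de novos created by the flips become error artifacts
        for child in fam.children:
            g = children[child]
            apparent = (g == 1) & (father == 0) & (mother == 0)
            for i in np.flatnonzero(apparent):
                key = ("1", int(panel.pos[i]), panel.ref[i], panel.alt[i])
                truth.add(key, fam.family_id, child, "error_artifact")

    # planted de novo coding variants, one coordinate block per family
    block = _family_block_start(config, fam_idx)
    offset = 0
    for child in fam.children:
        for k in range(config.n_denovo_per_child):
            pos = block + 10 * offset
            offset += 1
            ref, alt = _snv_alleles(rng)
            gene = f"GENE_DN_{fam.family_id}_{child.rsplit('_', 1)[1]}_{k}"
            planted.append(
                _PlantedSite(pos, ref, alt, gene, "de_novo_planted", fam_idx, {child: 1})
            )
            truth.add(("1", pos, ref, alt), fam.family_id, child, "de_novo_planted")

    # recessive plantings: the two-affected-siblings family
    if config.recessive_family and fam_idx == config.n_families - 1 and len(fam.children) >= 2:
        pos = block + 10 * offset
        offset += 1
        ref, alt = _snv_alleles(rng)
        carriers = {fam.father: 1, fam.mother: 1}
        carriers.update({c: 2 for c in fam.children})
        planted.append(
            _PlantedSite(pos, ref, alt, f"GENE_HR_{fam.family_id}",
                         "hom_recessive_planted", fam_idx, carriers)
        )
        truth.add(("1", pos, ref, alt), fam.family_id, "*", "hom_recessive_planted")

        ch_gene = f"GENE_CH_{fam.family_id}"
        for parent in (fam.father, fam.mother):
            pos = block + 10 * offset
            offset += 1
            ref, alt = _snv_alleles(rng)
            carriers = {parent: 1}
            carriers.update({c: 1 for c in fam.children})
            planted.append(
                _PlantedSite(pos, ref, alt, ch_gene,
                             "compound_het_planted", fam_idx, carriers)
            )
            truth.add(("1", pos, ref, alt), fam.family_id, "*", "compound_het_planted")


def _plant_control_shared(
    config: CohortConfig,
    families: list[_FamilyLayout],
    rng: np.random.Generator,
    planted: list[_PlantedSite],
    truth: TruthTable,
) -> None:
    """Rare variants carried by a child *and* by parents of two other
    families: they survive the within-family subtraction but fall to the
    pooled parental control panel."""
    base = _control_block_start(config)
    for k in range(config.n_control_shared):
        pos = base + 10 * k
        ref, alt = _snv_alleles(rng)
        fam = families[k % len(families)]
        child = fam.children[0]
        others = [f for f in families if f.family_id != fam.family_id]
        carriers = {child: 1}
        for j in range(2):
            pf = others[(k + j) % len(others)]
            carriers[pf.father if j % 2 == 0 else pf.mother] = 1
        planted.append(
            _PlantedSite(pos, ref, alt, f"GENE_CS_{k}", "control_shared", None, carriers)
        )
        truth.add(("1", pos, ref, alt), fam.family_id, child, "control_shared")


def _emit(
    config: CohortConfig,
    panel: _Panel,
    planted: list[_PlantedSite],
    geno: dict[str, np.ndarray],
    families: list[_FamilyLayout],
) -> list[tuple[VariantRecord, dict[str, GenotypeCall]]]:
    """Assemble VariantRecords and per-sample calls for the whole cohort.

    Quality-field randomness is drawn from per-family emission substreams
    with a fixed draw count per member over the panel (so it is independent
    of genotypes and plantings), from the per-family stream for the family's
    own planted sites, and from a cohort-level stream for control-shared
    sites; non-carrier samples at foreign planted sites get constant
    solid-reference fields.
    """
    n = config.n_sites
    sample_order = [s for fam in families for s in fam.members]

    # per-sample panel emission fields
    depth: dict[str, np.ndarray] = {}
    gq: dict[str, np.ndarray] = {}
    ab: dict[str, np.ndarray] = {}
    for fam_idx, fam in enumerate(families):
        erng = _stream(config.master_seed, 3, fam_idx)
        for sid in fam.members:
            d = np.maximum(erng.poisson(config.depth_mean, n), 8)
            g = np.full(n, float(config.gq_pass))
            border = erng.random(n) < config.borderline_fraction
            low_d = erng.integers(2, 9, n)
            low_g = erng.integers(3, 15, n)
            d[border] = low_d[border]
            g[border] = low_g[border]
            depth[sid] = d
            gq[sid] = g
            ab[sid] = erng.uniform(0.35, 0.65, n)

    records: list[tuple[VariantRecord, dict[str, GenotypeCall]]] = []
    for i in range(n):
        af = float(panel.af[i])
        af_map = {"dbSNP": af, "1000G": af} if panel.known[i] else {}
        rec = VariantRecord(
            chrom="1",
            pos=int(panel.pos[i]),
            ref=panel.ref[i],
            alt=panel.alt[i],
            gene=panel.gene[i],
            consequence=panel.consequence[i],
            af_map=af_map,
        )
        calls = {
            sid: _make_call(
                sid, int(geno[sid][i]), int(depth[sid][i]),
                float(gq[sid][i]), float(ab[sid][i]),
            )
            for sid in sample_order
        }
        records.append((rec, calls))

    # planted sites: carriers drawn from the owning stream, others constant
    fam_prngs = [_stream(config.master_seed, 4, i) for i in range(len(families))]
    control_rng = _stream(config.master_seed, 5)
    for site in planted:
        rng = control_rng if site.family_idx is None else fam_prngs[site.family_idx]
        rec = VariantRecord(
            chrom="1",
            pos=site.pos,
            ref=site.ref,
            alt=site.alt,
            gene=site.gene,
            consequence=FUNCTIONAL_CONSEQUENCE,
            af_map={},
        )
        calls: dict[str, GenotypeCall] = {}
        for sid in sample_order:
            n_alt = site.carriers.get(sid, 0)
            if sid in site.carriers or (
                site.family_idx is not None
                and sid in families[site.family_idx].members
            ):
                # drawn from the passing region of the quality gates, so
                # recovery at zero error rate is exact
                d = int(rng.integers(30, 80))
                calls[sid] = _make_call(
                    sid, n_alt, d, float(config.gq_pass), float(rng.uniform(0.35, 0.65))
                )
            else:
                d, q, ad = _SOLID_REF
                calls[sid] = GenotypeCall(
                    sample_id=sid, alleles=(0, 0), depth=d,
                    genotype_quality=q, allele_depths=ad,
                )
        records.append((rec, calls))

    records.sort(key=lambda rc: (rc[0].chrom, rc[0].pos, rc[0].ref, rc[0].alt))
    return records


def _make_call(
    sample: str, n_alt: int, depth: int, gq: float, ab_draw: float
) -> GenotypeCall:
    if n_alt == 0:
        alt_n = 0
    elif n_alt == 2:
        alt_n = depth
    else:
        alt_n = int(round(depth * ab_draw))
    alleles = [(0, 0), (0, 1), (1, 1)][n_alt]
    return GenotypeCall(
        sample_id=sample,
        alleles=alleles,  # type: ignore[arg-type]
        depth=depth,
        genotype_quality=gq,
        allele_depths=(depth - alt_n, alt_n),
    )


def _write_ped(families: list[_FamilyLayout], path: Path) -> None:
    with open(path, "wt") as fh:
        for fam in families:
            fh.write(f"{fam.family_id}\t{fam.father}\t0\t0\t1\t1\n")
            fh.write(f"{fam.family_id}\t{fam.mother}\t0\t0\t2\t1\n")
            for child in fam.children:
                fh.write(
                    f"{fam.family_id}\t{child}\t{fam.father}\t{fam.mother}\t2\t2\n"
                )
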