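import pytest

from rettlike.model import read_pedigree, read_vcf
from rettlike.simulate import CohortConfig, generate_cohort

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1,length=1000000>\n"
    '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
    '##INFO=<ID=CONSEQ,Number=1,Type=String,Description="consequence">\n'
    '##INFO=<ID=AF_DBSNP,Number=A,Type=Float,Description="af">\n'
    '##INFO=<ID=AF_1KG,Number=A,Type=Float,Description="af">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="gq">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
)


def make_vcf(body_lines, samples=("S1",)):
    header = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    header += "\t".join(samples) + "\n"
    return header + "".join(line + "\n" for line in body_lines)


def small_config(**overrides):
    """Shared desk-scale study conditions for the synthetic-cohort tests:
    three families (the last with two affected sisters), 400 background
    sites, two planted de novos per child, two control-shared variants."""
    base = dict(
        n_families=3,
        n_sites=400,
        n_denovo_per_child=2,
        n_control_shared=2,
        recessive_family=True,
        master_seed=11,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Error-free small cohort: (paths, truth, records_calls, pedigree)."""
    out = tmp_path_factory.mktemp("cohort")
    paths, truth = generate_cohort(small_config(), out)
    records_calls = read_vcf(paths.vcf)
    pedigree = read_pedigree(paths.ped)
    return paths, truth, records_calls, pedigree
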