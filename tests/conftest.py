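import textwrap

import pytest

import isledv

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=1000000>
    ##contig=<ID=chr2,length=1000000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    """
)


def write_vcf(path, records, samples=("s1",)):
    """records: list of (chrom, pos, ref, alt, qual, [call, ...]) where call
    is a 'GT:GQ:DP' string."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, qual, calls in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\tGT:GQ:DP\t" + "\t".join(calls) + "\n"
            )
    return str(path)


@pytest.fixture(scope="session")
def default_archipelago(tmp_path_factory):
    """The default synthetic archipelago (fixed master seed) plus the full
    pipeline result — shared across the integration and acceptance tests."""
    out = tmp_path_factory.mktemp("archipelago") / "default"
    cfg = isledv.ArchipelagoConfig()
    truth = isledv.build_archipelago(cfg, str(out))
    result = isledv.run_pipeline(str(out))
    return cfg, truth, result
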