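import numpy as np
import pytest

from lohmap.model import ArmMap, Thresholds


@pytest.fixture
def arm_map() -> ArmMap:
    return ArmMap({"chr18": (15_400_000, 19_000_001)})


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()


def make_vcf(path, rows, samples=("normal", "tumor")):
    """Write a minimal AD-only VCF. rows: (chrom, pos, ref, alt, ad_strings)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr18,length=78077248>",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, ref, alt, ads in rows:
        fmt = "AD" if any(a != "." for a in ads) else "AD"
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t" + "\t".join(ads)
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture
def vcf_factory(tmp_path):
    def _make(rows, samples=("normal", "tumor"), name="test.vcf"):
        return make_vcf(tmp_path / name, rows, samples)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240918)
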