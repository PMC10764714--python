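import numpy as np
import pytest

from iqsmerge import simulate
from iqsmerge.vcf_io import ImputedDataset, TruthGenotypes, VariantKey


def make_keys(n, chrom="1", start=100, step=100):
    return [VariantKey(chrom, start + i * step, "A", "G") for i in range(n)]


def point_mass_gp(calls):
    """Trios that put all mass on the given hard calls (MISSING -> NaN)."""
    calls = np.asarray(calls)
    gp = np.zeros(calls.shape + (3,))
    for g in range(3):
        gp[..., g] = calls == g
    gp[calls < 0] = np.nan
    return gp


@pytest.fixture
def tiny_imputed():
    keys = make_keys(3)
    gp = np.array(
        [
            [[0.95, 0.05, 0.00], [0.20, 0.50, 0.30]],
            [[0.10, 0.10, 0.80], [1.00, 0.00, 0.00]],
            [[np.nan, np.nan, np.nan], [0.33, 0.33, 0.34]],
        ]
    )
    return ImputedDataset(keys, ["s1", "s2"], gp, source="tiny")


@pytest.fixture
def tiny_truth():
    keys = make_keys(3)
    calls = np.array([[0, 1], [2, 0], [1, 1]], dtype=np.int8)
    return TruthGenotypes(keys, ["s1", "s2"], calls)


@pytest.fixture(scope="session")
def scenario():
    """One shared benchmark simulation (module-expensive, read-only)."""
    return simulate.france_scenario(12345)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


VCF_HEADER = [
    "##fileformat=VCFv4.2",
    "##contig=<ID=1>",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Posterior">',
]


def imputed_vcf_lines(samples, records):
    """records: list of (chrom, pos, ref, alt, [per-sample 'GT:GP' strings])."""
    lines = list(VCF_HEADER)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for chrom, pos, ref, alt, entries in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT:GP\t" + "\t".join(entries)
        )
    return lines
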