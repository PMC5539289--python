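import numpy as np
import pytest

from regblock.core_io import BASES, Pwm
from regblock.synthetic import SyntheticScenario, generate_scenario


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic cohort (seed 1), shared across tests."""
    outdir = tmp_path_factory.mktemp("cohort")
    return generate_scenario(SyntheticScenario(seed=1), outdir)


@pytest.fixture(scope="session")
def sharp_pwm():
    """High-information 6-bp PWM with consensus ACGTAC."""
    consensus = "ACGTAC"
    probs = np.full((6, 4), 0.04)
    for i, b in enumerate(consensus):
        probs[i, BASES.index(b)] = 0.88
    return Pwm(tf_name="SHARP", pwm_id="SHARP1", probs=probs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_fasta(path, seqs):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def write_vcf(path, records, chrom_lengths=None):
    """records: iterable of (chrom, pos, ref, alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (chrom_lengths or {"1": 100000}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
    return path
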