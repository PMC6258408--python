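import numpy as np
import pytest

from burdenrank.scoring import VariantCall


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_call(
    ind="i1",
    gene="G1",
    chrom="1",
    pos=100,
    ref="A",
    alt="T",
    s=0.5,
    alt_cov=None,
    ref_cov=None,
    phase_group=None,
):
    return VariantCall(
        individual_id=ind,
        gene_id=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        s=s,
        alt_coverage=alt_cov,
        ref_coverage=ref_cov,
        phase_group=phase_group,
    )


@pytest.fixture
def tiny_panel():
    """Three genes, handful of alleles, one multi-allelic site."""
    import pandas as pd

    from burdenrank.simulate import FrequencyPanel

    df = pd.DataFrame(
        [
            ("1", 1000, "A", "T", "G1", 20.0, 0.002),
            ("1", 1000, "A", "G", "G1", 15.0, 0.005),
            ("1", 2000, "C", "T", "G1", 30.0, 0.001),
            ("2", 5000, "G", "A", "G2", 10.0, 0.004),
            ("2", 6000, "T", "C", "G2", 25.0, 0.02),
            ("3", 9000, "A", "C", "G3", 5.0, 0.0),
        ],
        columns=["chrom", "pos", "ref", "alt", "gene", "score", "adjusted"],
    )
    return FrequencyPanel(df, ["adjusted"])
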