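import textwrap

import pytest

from genoconcord.synthetic import SyntheticCohortConfig, simulate_cohort


@pytest.fixture
def toy_maf(tmp_path):
    """Three-variant MAF: a missense SNP, a silent SNP, a frameshift DEL."""
    text = textwrap.dedent(
        """\
        Hugo_Symbol\tTumor_Sample_Barcode\tChromosome\tStart_position\tReference_Allele\tTumor_Seq_Allele2\tVariant_Classification\tVariant_Type\tt_alt_count\tt_ref_count\tFlank5\tFlank3
        BRAF\tS1\t7\t140453136\tA\tT\tMissense_Mutation\tSNP\t4\t36\tC\tG
        BRAF\tS1\t7\t140453200\tC\tT\tSilent\tSNP\t10\t10\tT\tA
        TP53\tS2\t17\t7577120\tAG\tA\tFrame_Shift_Del\tDEL\t12\t20\t\t
        """
    )
    p = tmp_path / "toy.maf"
    p.write_text(text)
    return p


@pytest.fixture
def toy_seg(tmp_path):
    text = textwrap.dedent(
        """\
        Sample\tChromosome\tStart\tEnd\tSegment_Mean
        S1\tchr17\t1000\t2000\t0.5
        S1\t17\t2001\t5000\t-0.1
        S2\t1\t100\t600\t0.7
        S2\t2\t100\t600\t0.0
        """
    )
    p = tmp_path / "toy.seg"
    p.write_text(text)
    return p


@pytest.fixture(scope="session")
def default_cohort():
    """One shared default synthetic cohort for read-only tests."""
    return simulate_cohort(SyntheticCohortConfig(seed=20240917))


@pytest.fixture(scope="session")
def default_cohort_dir(default_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    paths = default_cohort.write(out)
    return out, paths
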