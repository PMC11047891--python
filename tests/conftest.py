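import math

import pytest
from hypothesis import HealthCheck, settings

from l1pd import synthdata
from l1pd.seqio import L1AnnotationRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: scaled-down element for fixtures where probe-generation mapping cost matters
SMALL_ELEMENT = dict(
    len_utr5=120, len_orf1=240, len_spacer=30, len_orf2=480, len_utr3=60
)


@pytest.fixture(scope="session")
def small_truth():
    """Five intact + two truncated full-size copies in a 60 kb genome."""
    cfg = synthdata.SimConfig(seed=11, genome_length=60_000, n_intact=5, n_truncated=2)
    return synthdata.simulate(cfg)


@pytest.fixture(scope="session")
def small_probes(small_truth):
    return synthdata.ancestral_probes(small_truth, 50)


@pytest.fixture(scope="session")
def small_params(small_probes):
    from l1pd.patternmatch import DetectionParams

    return DetectionParams(e=5, t=100, m=math.ceil(0.7 * len(small_probes)))


@pytest.fixture(scope="session")
def zero_div_truth():
    """Zero-divergence scaled fixture (identical copies) for probe generation."""
    cfg = synthdata.SimConfig(
        seed=5,
        genome_length=8_000,
        n_intact=4,
        n_truncated=0,
        sub_rate=0.0,
        indel_rate=0.0,
        **SMALL_ELEMENT,
    )
    return synthdata.simulate(cfg)


def make_record(
    chrom="chr1",
    l1_start=1,
    strand="+",
    utr5=909,
    orf1=1017,
    spacer=63,
    orf2=3828,
    utr3=205,
    total=None,
):
    """Build a consistent annotation record from component lengths."""
    utr5_s, utr5_e = 1, utr5
    orf1_s, orf1_e = utr5_e + 1, utr5_e + orf1
    orf2_s, orf2_e = orf1_e + spacer + 1, orf1_e + spacer + orf2
    utr3_s, utr3_e = orf2_e + 1, orf2_e + utr3
    if total is None:
        total = utr3_e
    return L1AnnotationRecord(
        chrom=chrom,
        l1_start=l1_start,
        l1_end=l1_start + total - 1,
        strand=strand,
        utr5_start=utr5_s,
        utr5_end=utr5_e,
        orf1_start=orf1_s,
        orf1_end=orf1_e,
        orf2_start=orf2_s,
        orf2_end=orf2_e,
        utr3_start=utr3_s,
        utr3_end=utr3_e,
    )
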