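import pytest

from twindiscord.types import (
    AlleleAnnotation,
    AnnotatedVariant,
    Cohort,
    GenotypeCall,
    TwinPair,
)


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt=("G",),
    qual=500.0,
    genotypes=None,
    gq=99,
    dp=30,
    ann=None,
):
    """Construct an AnnotatedVariant from a {sample: (a, b) | None} map."""
    genotypes = genotypes or {"S1_A": (0, 1), "S1_U": (0, 0)}
    calls = {
        s: GenotypeCall(s, g, gq=gq, dp=dp) for s, g in genotypes.items()
    }
    anns = ann if ann is not None else tuple(AlleleAnnotation() for _ in alt)
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=tuple(alt), qual=qual,
        calls=calls, annotations=anns,
    )


@pytest.fixture
def pair():
    return TwinPair(
        pair_id="S1", twin1_id="S1_A", twin2_id="S1_U", affected_id="S1_A",
        diagnoses={"S1_A": "SCZ", "S1_U": "None"},
    )


@pytest.fixture
def two_pair_cohort(pair):
    other = TwinPair(
        pair_id="S2", twin1_id="S2_A", twin2_id="S2_U", affected_id="S2_A",
        diagnoses={"S2_A": "BD", "S2_U": "None"},
    )
    return Cohort([pair, other])
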