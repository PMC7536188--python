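import numpy as np
import pytest

from enoc_strat.io_model import (
    ClinVar,
    Consequence,
    PolyPhen,
    Sift,
    VariantCall,
)


def make_call(
    sample_id="S1",
    chrom="1",
    pos=100,
    ref="C",
    alt="T",
    gene="TP53",
    consequence=Consequence.MISSENSE,
    depth=100,
    alt_depth=40,
    **kw,
):
    return VariantCall(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        gene=gene, consequence=consequence, depth=depth, alt_depth=alt_depth,
        **kw,
    )


@pytest.fixture
def call_factory():
    return make_call


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


TOY_MAF = """sample_id\tchrom\tpos\tref\talt\tgene\tconsequence\tdepth\talt_depth
S1\t1\t100\tC\tT\tTP53\tmissense\t100\t40
S1\t2\t200\tAT\tA\tARID1A\tframeshift_indel\t80\t20
S2\t3\t300\tG\tA\tCTNNB1\tmissense\t60\t30
"""


@pytest.fixture
def toy_maf(tmp_path):
    p = tmp_path / "toy.maf.tsv"
    p.write_text(TOY_MAF)
    return p


@pytest.fixture
def annotated_call():
    def _make(consequence, clinvar=ClinVar.UNKNOWN, polyphen=PolyPhen.MISSING,
              sift=Sift.MISSING):
        ref, alt = ("AT", "A") if consequence is Consequence.FRAMESHIFT_INDEL else ("C", "T")
        return make_call(
            ref=ref, alt=alt, consequence=consequence,
            clinvar=clinvar, polyphen=polyphen, sift=sift,
        )
    return _make
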