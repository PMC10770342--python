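import pytest

from ctdna_mrd.cohort_io import Impact, Source, VariantCall


def make_call(pid="P1", source=Source.PLASMA, chrom="chr17", pos=7577001,
              ref="C", alt="T", gene="TP53", vaf_pct=None, ta=200, tr=9800,
              to=0, rf=0.95, day=40, impact=Impact.MODERATE, sample=None):
    """Variant-call factory; ``vaf_pct`` overrides ta/tr at depth 10000."""
    if vaf_pct is not None:
        ta = round(10000 * vaf_pct / 100.0)
        tr, to = 10000 - ta, 0
    return VariantCall(
        participant_id=pid,
        sample_id=sample or f"{pid}-{source.value}-d{day}",
        source=source, collection_day=day, chrom=chrom, pos=pos,
        ref=ref, alt=alt, gene=gene, ta=ta, tr=tr, to=to,
        rf_score=rf, impact=impact,
    )


@pytest.fixture
def call_factory():
    return make_call
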