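import numpy as np
import pytest

from retra.annotation_model import (
    Annotation,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from retra import synthetic_data as sd


@pytest.fixture(scope="session")
def small_truth():
    """A modest planted truth set shared across read-only tests."""
    genome = sd.make_genome(101, n_chroms=3, chrom_len=80_000)
    return sd.make_annotation(
        genome, 202, n_genes=30, isoform_weights=(0.5, 0.3, 0.2), mono_fraction=0.15
    )


@pytest.fixture()
def tiny_annotation():
    t1 = TranscriptModel(
        "t1", "g1",
        [GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 300, 400, "+")],
    )
    t2 = TranscriptModel(
        "t2", "g1",
        [GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 300, 450, "+")],
    )
    t3 = TranscriptModel("t3", "g2", [GenomicInterval("chr1", 1000, 1500, "-")])
    return Annotation(
        genes=[GeneModel("g1", [t1, t2]), GeneModel("g2", [t3])], provenance="tiny"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
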