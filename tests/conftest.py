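import numpy as np
import pytest

from truthseq.ground_truth import (
    PanelSynthesisSpec,
    sample_ground_truth,
    synthesize_reference_panel,
)
from truthseq.library_builder import build_library, synthesize_transcripts


@pytest.fixture(scope="session")
def small_spec():
    return PanelSynthesisSpec(
        n_genes=40, n_major=3, subs_per_major=1, markers_per_sub=2, seed=7
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    panel = synthesize_reference_panel(small_spec)
    return sample_ground_truth(panel, 10, seed=11)


@pytest.fixture(scope="session")
def small_reference(small_truth):
    return synthesize_transcripts(small_truth.gene_ids, mean_length=300, seed=13)


@pytest.fixture(scope="session")
def small_library(small_truth, small_reference):
    return build_library(small_truth, small_reference, seed=17)
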