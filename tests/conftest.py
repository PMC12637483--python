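import numpy as np
import pytest

import loopquant as lq
from loopquant import quant


@pytest.fixture
def analysis_config():
    return lq.AnalysisConfig(ploidy=2)


@pytest.fixture
def clean_dataset():
    """Small dataset with perfect detection: every allele yields spots."""
    cfg = lq.SimulationConfig(
        n_cells=300, ploidy=2, p_loop=0.2, spot_detection_prob=1.0,
        false_spot_rate=0.0, seed=7,
    )
    return lq.generate_fish_dataset(cfg), cfg


def run_quant(nuclei, spots, config):
    """QC -> ploidy -> match -> contacts -> summaries, as one helper."""
    kept, _ = quant.qc_filter_nuclei(nuclei, config)
    kept, _ = quant.ploidy_filter(kept, spots, config)
    pairs = quant.match_all_nuclei(kept, spots, config)
    pairs = quant.attach_condition(pairs, kept)
    cells = quant.summarize_cells(kept, pairs,
                                  spots[spots["channel"] == "rna"])
    return kept, pairs, cells


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
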