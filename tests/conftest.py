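import numpy as np
import pytest

from primenet.io_formats import (EfficiencyTriple, GenomicAnchor, RegionSpans,
                                 TargetRecord)
from primenet.network import ModelConfig, PrimeNet
from primenet.simdata import make_fixture

SMALL_CONFIG = ModelConfig(
    mixconv_out_channels_per_branch=4,
    compress_channels=8,
    conv_channels=(8, 8),
    trunk_widths=(32,),
    branch_widths=(16,),
)


@pytest.fixture
def simple_record():
    """A 99-nt record with the worked-example region layout."""
    rng = np.random.default_rng(42)
    bases = "ACGT"
    wild = "".join(bases[i] for i in rng.integers(0, 4, 99))
    # protospacer [30,50), PAM [50,53), nick at 47, PBS 13 nt, RT 15 nt
    spans = RegionSpans(protospacer=(30, 50), pam=(50, 53), pbs=(34, 47),
                        rt=(47, 62))
    edited = wild[:51] + ("G" if wild[51] != "G" else "A") + wild[52:]
    return TargetRecord(
        record_id="rec1", wild_seq=wild, edited_seq=edited, spans=spans,
        anchor=GenomicAnchor("chr1", 1000, "+"),
        observed=EfficiencyTriple(35.11, 38.86, 26.03),
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def smoke_dataset():
    return make_fixture("smoke")


@pytest.fixture(scope="session")
def small_model():
    return PrimeNet(SMALL_CONFIG, seed=0)


@pytest.fixture(scope="session")
def trained_toy_model(smoke_dataset):
    """A small model briefly trained on the smoke fixture."""
    from primenet.training import TrainConfig
    from primenet.workflows import run_recovery_pipeline

    records, dnase, methyl, _ = smoke_dataset
    res = run_recovery_pipeline(
        records, dnase, methyl, seed=0,
        model_config=SMALL_CONFIG,
        train_config=TrainConfig(max_epochs=5, seed=0, batch_size=64),
    )
    return res
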