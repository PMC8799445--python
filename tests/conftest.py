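import pytest

from lfadev.design import DeckLayout, DesignSpec, FactorSpec, enumerate_conditions, split_into_runs
from lfadev.schedule import Protocol, ProtocolStep


@pytest.fixture
def small_design() -> DesignSpec:
    """2 detection antibodies x 2 matrices, duplicated: 8 strips."""
    return DesignSpec(
        factors=(
            FactorSpec("detection", ("D1", "D2"), role="detection_antibody"),
            FactorSpec("matrix", ("blank", "ag1"), role="sample_matrix"),
        ),
        replicates=2,
    )


@pytest.fixture
def strip_deck() -> DeckLayout:
    return DeckLayout(holders=(("H1", 16),))


@pytest.fixture
def small_run(small_design, strip_deck):
    conditions = enumerate_conditions(small_design)
    return split_into_runs(conditions, strip_deck)[0]


@pytest.fixture
def three_step_protocol() -> Protocol:
    """Conjugate, sample (2 min after), image at 30 min after sample."""
    return Protocol(
        name="standard",
        steps=(
            ProtocolStep(0, "dispense_reagent", reagent_ref="det_{detection}",
                         volume=10.0, destination="conjugate_well", duration=20),
            ProtocolStep(1, "dispense_sample", reagent_ref="sample_{matrix}",
                         volume=50.0, destination="sample_port",
                         min_delay_after_previous=120, duration=20),
            ProtocolStep(2, "image", target_time_after_sample=1800, duration=10),
        ),
        imaging_tolerance_s=60,
    )


@pytest.fixture
def small_sources():
    names = ["det_D1", "det_D2", "sample_blank", "sample_ag1"]
    return {n: ("stocks", n) for n in names}
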