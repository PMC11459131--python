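import numpy as np
import pytest

from tiplink.mechanics import FitParams, extension_at_force
from tiplink.simulate import (
    DomainUnit,
    RampProtocol,
    SimulationConfig,
    simulate_cycle,
    simulate_dataset,
)

# Saturation-spring parameter sets quoted in the figure captions
# (x_E nm, F_half pN, K pN/nm), used for noiseless self-consistency refits.
CAPTION_PARAMS = [
    (39.9, 1.4, 3.7),
    (40.9, 1.5, 3.7),
    (63.8, 2.4, 2.5),
    (63.1, 2.4, 2.5),
    (55.2, 4.1, 2.4),
    (59.6, 4.1, 2.4),
    (78.8, 4.1, 2.4),
    (84.5, 5.1, 2.4),
    (34.9, 2.4, 3.2),
    (44.0, 2.4, 3.2),
    (91.6, 2.4, 3.2),
    (99.5, 4.0, 3.2),
    (48.1, 2.1, 2.1),
    (68.6, 2.1, 2.1),
    (98.6, 2.1, 2.1),
    (110.9, 6.4, 2.1),
    (130.9, 3.7, 1.6),
    (157.6, 3.7, 1.6),
    (174.0, 3.7, 1.6),
    (188.2, 6.2, 1.6),
]


def single_unit_config(
    gain: float = 17.0,
    k0: float = 0.0,
    dx_act: float = 0.5,
    refold: float = 1.0,
    noise_sd: float = 0.0,
    params: FitParams = FitParams(40.0, 2.0, 2.5),
    protocol: RampProtocol = RampProtocol(),
    seed: int = 0,
) -> SimulationConfig:
    """A minimal one-unit simulation config for targeted tests."""
    return SimulationConfig(
        base_params=params,
        ladder=(DomainUnit("unit", gain, k0, dx_act, refold),),
        noise_sd=noise_sd,
        protocol=protocol,
        seed=seed,
    )


def noiseless_model_cycle(params: FitParams, protocol: RampProtocol = RampProtocol()):
    """A cycle that follows the saturation-spring model exactly (no steps)."""
    return simulate_cycle(single_unit_config(k0=0.0, params=params, protocol=protocol))


@pytest.fixture(scope="session")
def small_dataset():
    """A modest noisy dataset with events, shared across read-only tests."""
    from tiplink.simulate import condition_presets
    from dataclasses import replace

    cfg = replace(condition_presets("V507D", "20 uM"), seed=42)
    return simulate_dataset(cfg, 12, dataset_id="shared-small")
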