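"""In-memory containers for force-ramp trajectories.

A *cycle* is one triangular force ramp (extension phase up to the force
peak, relaxation phase back down) recorded as per-sample time, applied
force and end-to-end extension.  A *dataset* is the ordered sequence of
cycles recorded from one tethered molecule under one (construct, Ca2+)
condition, exactly the unit over which refolding statistics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

PHASE_EXTENSION = "extension"
PHASE_RELAXATION = "relaxation"
PHASE_REST = "rest"

CONSTRUCTS = ("wild-type", "V507D")
CALCIUM_CONDITIONS = ("3 mM", "20 uM", "0 M EDTA")


@dataclass(frozen=True)
class GroundTruthEvent:
    """One simulated unfolding event, as logged by the generator.

    ``contour_gain`` is the programmed increase of the entropic extension
    x_E (nm); ``observed_step`` is the realized jump in end-to-end distance
    at the event force, ``contour_gain * F / (F + F_half)``, which is what a
    step detector sees in the trace.
    """

    phase: str
    sample_index: int
    force: float
    unit_index: int
    unit_name: str
    contour_gain: float
    observed_step: float


@dataclass
class ForceRampCycle:
    """One extension-relaxation cycle of a force-ramp experiment."""

    time: np.ndarray        # s
    force: np.ndarray       # pN
    extension: np.ndarray   # nm
    phase: np.ndarray       # per-sample label: extension | relaxation | rest
    cycle_index: int = 0
    dataset_id: str = ""
    construct: str = CONSTRUCTS[0]
    calcium: str = CALCIUM_CONDITIONS[0]
    events: List[GroundTruthEvent] = field(default_factory=list)
    folded_start: Optional[Tuple[bool, ...]] = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.force) == len(self.extension) == len(self.phase) == n):
            raise ValueError("time, force, extension and phase must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def ramp_mask(self) -> np.ndarray:
        """Boolean mask of the ramp (non-rest) samples."""
        return self.phase != PHASE_REST

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "force_pN": self.force,
                "extension_nm": self.extension,
                "phase": self.phase,
            }
        )


@dataclass
class Dataset:
    """All cycles recorded from one molecule under one condition."""

    cycles: List[ForceRampCycle]
    dataset_id: str
    construct: str
    calcium: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cycles:
            raise ValueError("a dataset must contain at least one cycle")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def all_events(self) -> List[GroundTruthEvent]:
        return [ev for cyc in self.cycles for ev in cyc.events]
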