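"""Reading, writing and basic reshaping of force-ramp datasets.

The on-disk format of record is plain text for inspectability: one
tab-delimited table per cycle (columns ``time_s``, ``force_pN``,
``extension_nm``, ``phase``) plus a single ``metadata.json`` sidecar per
dataset that carries identity, condition labels, the acquisition
protocol and — for synthetic data — the ground-truth event log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .containers import (
    PHASE_REST,
    Dataset,
    ForceRampCycle,
    GroundTruthEvent,
)

__all__ = ["write_dataset", "read_dataset", "split_phases", "build_heatmap", "Heatmap"]

_REQUIRED_COLUMNS = ("time_s", "force_pN", "extension_nm", "phase")


def write_dataset(dataset: Dataset, path) -> Path:
    """Write a dataset to directory ``path`` (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cycle_entries = []
    for i, cyc in enumerate(dataset.cycles):
        fname = f"cycle_{i:04d}.tsv"
        # %.17g guarantees bit-exact float round-trips through text
        cyc.to_frame().to_csv(path / fname, sep="\t", index=False, float_format="%.17g")
        cycle_entries.append(
            {
                "file": fname,
                "cycle_index": cyc.cycle_index,
                "folded_start": list(cyc.folded_start) if cyc.folded_start is not None else None,
                "events": [
                    {
                        "phase": ev.phase,
                        "sample_index": ev.sample_index,
                        "force_pN": ev.force,
                        "unit_index": ev.unit_index,
                        "unit_name": ev.unit_name,
                        "contour_gain_nm": ev.contour_gain,
                        "observed_step_nm": ev.observed_step,
                    }
                    for ev in cyc.events
                ],
            }
        )
    meta = {
        "dataset_id": dataset.dataset_id,
        "construct": dataset.construct,
        "calcium": dataset.calcium,
        "n_cycles": dataset.n_cycles,
        "metadata": dataset.metadata,
        "cycles": cycle_entries,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    return path


def read_dataset(path) -> Dataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.json in {path}")
    meta = json.loads(meta_path.read_text())
    entries = meta.get("cycles", [])
    if not entries:
        raise ValueError(f"dataset at {path} contains no cycles (empty dataset is invalid)")
    cycles = []
    for entry in entries:
        fpath = path / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"cycle file {fpath} listed in metadata but missing")
        df = pd.read_csv(fpath, sep="\t", float_precision="round_trip")
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"cycle file {fpath.name} is missing required column {col!r}")
        events = [
            GroundTruthEvent(
                phase=ev["phase"],
                sample_index=int(ev["sample_index"]),
                force=float(ev["force_pN"]),
                unit_index=int(ev["unit_index"]),
                unit_name=ev["unit_name"],
                contour_gain=float(ev["contour_gain_nm"]),
                observed_step=float(ev["observed_step_nm"]),
            )
            for ev in entry.get("events", [])
        ]
        folded = entry.get("folded_start")
        cycles.append(
            ForceRampCycle(
                time=df["time_s"].to_numpy(),
                force=df["force_pN"].to_numpy(),
                extension=df["extension_nm"].to_numpy(),
                phase=df["phase"].to_numpy(dtype="<U10"),
                cycle_index=int(entry["cycle_index"]),
                dataset_id=meta["dataset_id"],
                construct=meta["construct"],
                calcium=meta["calcium"],
                events=events,
                folded_start=tuple(bool(f) for f in folded) if folded is not None else None,
            )
        )
    return Dataset(
        cycles=cycles,
        dataset_id=meta["dataset_id"],
        construct=meta["construct"],
        calcium=meta["calcium"],
        metadata=meta.get("metadata", {}),
    )


def split_phases(cycle: ForceRampCycle, median_window: int = 5) -> Tuple[np.ndarray, np.ndarray]:
    """Index arrays of the extension and relaxation phases of one cycle.

    The split point is the force maximum of the ramp, located on a
    median-filtered copy of the force signal (default window 5 samples) so
    isolated noise spikes cannot masquerade as the peak.  The peak sample
    itself is assigned to the extension phase.  Raises if the trace has no
    identifiable peak (near-constant force).
    """
    ramp = np.flatnonzero(cycle.phase != PHASE_REST)
    force = cycle.force[ramp]
    if len(force) < 3:
        raise ValueError("cycle too short to split into phases")
    if np.ptp(force) < 1e-9 * max(1.0, abs(force[0])):
        raise ValueError("force is constant; no extension/relaxation peak to split at")
    window = min(median_window, len(force) if len(force) % 2 else len(force) - 1)
    smoothed = medfilt(force, kernel_size=window) if window >= 3 else force
    # the median filter flattens the apex, so refine on the raw signal in a
    # small neighbourhood of the smoothed maximum
    i0 = int(np.argmax(smoothed))
    lo = max(i0 - median_window, 0)
    hi = min(i0 + median_window + 1, len(force))
    i_peak = lo + int(np.argmax(force[lo:hi]))
    if i_peak == 0 or i_peak == len(force) - 1:
        raise ValueError("force peak lies at the trace boundary; not an extension-relaxation cycle")
    return ramp[: i_peak + 1], ramp[i_peak + 1 :]


@dataclass
class Heatmap:
    """Occupancy histogram over (extension, force).

    ``counts[i, j]`` is the number of samples in extension bin ``i`` and
    force bin ``j``; brighter cells correspond to more frequently occupied
    conformations when rendered.
    """

    counts: np.ndarray
    extension_edges: np.ndarray
    force_edges: np.ndarray
    total: int

    def plot(self, ax=None, log: bool = True, cmap: str = "inferno"):
        """Render with force on the abscissa, extension on the ordinate."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.counts.astype(float)
        if log:
            c = np.log1p(c)
        ax.pcolormesh(self.force_edges, self.extension_edges, c, cmap=cmap)
        ax.set_xlabel("Force (pN)")
        ax.set_ylabel("Extension (nm)")
        return ax


def build_heatmap(
    cycles: Iterable[ForceRampCycle],
    bin_width_force: float = 0.5,
    bin_width_ext: float = 1.0,
) -> Heatmap:
    """Superimpose the ramp samples of every cycle into one 2-D histogram.

    Both the extension and relaxation phases of every cycle contribute.
    The bin grids are anchored at multiples of the bin widths, so the
    histogram is independent of cycle order and additive over cycles.
    """
    if bin_width_force <= 0 or bin_width_ext <= 0:
        raise ValueError("bin widths must be positive")
    cycles = list(cycles)
    if not cycles:
        raise ValueError("need at least one cycle")
    forces = np.concatenate([c.force[c.ramp_mask()] for c in cycles])
    exts = np.concatenate([c.extension[c.ramp_mask()] for c in cycles])

    def _edges(values: np.ndarray, width: float) -> np.ndarray:
        lo = np.floor(values.min() / width) * width
        hi = np.ceil(values.max() / width) * width
        if hi <= lo:
            hi = lo + width
        return np.arange(lo, hi + width / 2, width)

    ext_edges = _edges(exts, bin_width_ext)
    force_edges = _edges(forces, bin_width_force)
    counts, _, _ = np.histogram2d(exts, forces, bins=[ext_edges, force_edges])
    return Heatmap(
        counts=counts.astype(int),
        extension_edges=ext_edges,
        force_edges=force_edges,
        total=len(forces),
    )
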