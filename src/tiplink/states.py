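"""Conformational states, transition maps and refolding statistics.

Trajectory segments are reduced to their fitted maximal entropic
extension x_E.  Pooled relaxation-phase values from all conditions are
clustered into six states by one-dimensional k-means; the labelled pool
then serves as the reference set for k-nearest-neighbour (k = 3)
classification of every segment.  States are numbered 1..6 in ascending
mean x_E: states 1-2 are compatible with a fully folded molecule, and
the gaps between higher states correspond to partial- or full-domain
unfolding.  Interstate transition maps, occupancy fractions, the
refolding summary (a cycle that reached state >= 3 refolds fully if the
next cycle starts in state 1 or 2) and per-state entropic stiffness
versus force are all derived from the classified segment table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import PHASE_EXTENSION, PHASE_RELAXATION, Dataset

__all__ = [
    "StateModel",
    "TransitionMap",
    "RefoldingEntry",
    "define_states",
    "classify_segment",
    "state_differences",
    "build_transition_map",
    "refolding_summary",
    "entropic_stiffness_by_state",
    "tether_statistics",
]


@dataclass
class StateModel:
    """Six-state (by default) description of the x_E landscape.

    ``reference_x`` / ``reference_labels`` retain the labelled training
    pool for kNN classification.  State labels run 1..n_states in strictly
    ascending order of mean x_E.
    """

    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray
    reference_x: np.ndarray
    reference_labels: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.means)


def define_states(x_values: Sequence[float], n_states: int = 6, random_state: int = 0) -> StateModel:
    """Cluster pooled relaxation-phase x_E values into ordered states.

    One-dimensional k-means with a seeded deterministic initialization;
    the values are sorted first, so the model is invariant to input
    order.  Raises if fewer than ``10 * n_states`` values are supplied or
    if any cluster comes out empty (e.g. all values identical).
    """
    x = np.sort(np.asarray(x_values, dtype=float))
    if len(x) < 10 * n_states:
        raise ValueError(f"need at least {10 * n_states} fitted values, got {len(x)}")
    km = KMeans(n_clusters=n_states, random_state=random_state, n_init=10).fit(x.reshape(-1, 1))
    labels = km.labels_
    uniq = np.unique(labels)
    if len(uniq) < n_states:
        raise ValueError(f"clustering produced {len(uniq)} non-empty clusters for {n_states} states")
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    relabel = np.empty(n_states, dtype=int)
    relabel[order] = np.arange(1, n_states + 1)
    new_labels = relabel[labels]
    means = np.empty(n_states)
    sems = np.empty(n_states)
    counts = np.empty(n_states, dtype=int)
    for s in range(1, n_states + 1):
        member = x[new_labels == s]
        means[s - 1] = member.mean()
        counts[s - 1] = len(member)
        sems[s - 1] = member.std(ddof=1) / np.sqrt(len(member)) if len(member) > 1 else 0.0
    if np.any(np.diff(means) <= 0):
        raise ValueError("state means are not strictly increasing")
    return StateModel(means=means, sems=sems, counts=counts, reference_x=x, reference_labels=new_labels)


def classify_segment(model: StateModel, x_e: float, k: int = 3) -> int:
    """Assign a state by majority vote among the k nearest references.

    Distance is |x_E - reference|; ties in distance and ties in the vote
    are both broken toward the lower state (conservative about claiming
    unfolding).
    """
    if model.reference_x is None or len(model.reference_x) == 0:
        raise ValueError("state model has no reference set")
    if k < 1 or k > len(model.reference_x):
        raise ValueError(f"k must be in [1, {len(model.reference_x)}]")
    d = np.abs(model.reference_x - x_e)
    # lexicographic sort: distance first, then label (lower state first)
    order = np.lexsort((model.reference_labels, d))[:k]
    votes = model.reference_labels[order]
    states, counts = np.unique(votes, return_counts=True)
    return int(states[np.argmax(counts)])  # np.unique is sorted, argmax takes first max


def state_differences(model: StateModel) -> List[Tuple[float, float]]:
    """Successive differences of state means with SEMs added in quadrature."""
    out = []
    for i in range(model.n_states - 1):
        delta = float(model.means[i + 1] - model.means[i])
        sem = float(np.hypot(model.sems[i + 1], model.sems[i]))
        out.append((delta, sem))
    return out


@dataclass
class TransitionMap:
    """Interstate transition counts and state occupancy.

    ``counts`` is a table with columns (ordinal, from_state, to_state,
    count): the transition from the segment at that ordinal to the next
    one within the same cycle and phase, in ascending order of force.
    ``occupancy`` maps state -> fraction of segments (or of samples when
    sample-weighted) and sums to 1.
    """

    counts: pd.DataFrame
    occupancy: Dict[int, float]
    n_segments: int
    n_groups: int

    def matrix(self, n_states: int) -> np.ndarray:
        """Aggregate (from, to) counts over all ordinals."""
        m = np.zeros((n_states, n_states), dtype=int)
        for _, row in self.counts.iterrows():
            m[int(row.from_state) - 1, int(row.to_state) - 1] += int(row["count"])
        return m


def build_transition_map(segments: pd.DataFrame, sample_weighted: bool = False) -> TransitionMap:
    """Transition counts and occupancy from a classified segment table.

    ``segments`` needs columns ``dataset_id``, ``cycle_index``, ``phase``,
    ``ordinal``, ``state`` (and ``n_samples`` for the sample-weighted
    occupancy variant).  Transitions are counted between consecutive
    ordinals within each (dataset, cycle, phase); occupancy is the
    fraction of segments per state (segment-weighted by default).
    """
    required = {"dataset_id", "cycle_index", "phase", "ordinal", "state"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    if segments["state"].isna().any():
        raise ValueError("all segments must be classified before building a transition map")
    rows = []
    n_groups = 0
    for _, grp in segments.groupby(["dataset_id", "cycle_index", "phase"], sort=True):
        n_groups += 1
        grp = grp.sort_values("ordinal")
        states = grp["state"].to_numpy(dtype=int)
        ordinals = grp["ordinal"].to_numpy(dtype=int)
        for i in range(len(grp) - 1):
            rows.append((int(ordinals[i]), int(states[i]), int(states[i + 1])))
    if rows:
        counts = (
            pd.DataFrame(rows, columns=["ordinal", "from_state", "to_state"])
            .value_counts()
            .rename("count")
            .reset_index()
            .sort_values(["ordinal", "from_state", "to_state"])
            .reset_index(drop=True)
        )
    else:
        counts = pd.DataFrame(columns=["ordinal", "from_state", "to_state", "count"])
    if sample_weighted:
        if "n_samples" not in segments.columns:
            raise ValueError("sample-weighted occupancy needs an n_samples column")
        w = segments.groupby("state")["n_samples"].sum()
        occ = (w / w.sum()).to_dict()
    else:
        occ = (segments["state"].value_counts(normalize=True)).to_dict()
    occupancy = {int(s): float(f) for s, f in sorted(occ.items())}
    return TransitionMap(counts=counts, occupancy=occupancy, n_segments=len(segments), n_groups=n_groups)


@dataclass(frozen=True)
class RefoldingEntry:
    """Percent of full refolding for one (construct, condition).

    ``percent`` is the mean over datasets of the per-dataset percentage of
    qualifying cycles (those that reached state >= 3) whose successor
    cycle began in state 1 or 2.  ``percent is None`` marks the condition
    as undefined: no dataset had a qualifying cycle.
    """

    percent: Optional[float]
    sem: Optional[float]
    n_datasets: int

    @property
    def defined(self) -> bool:
        return self.percent is not None


def folded_threshold_from_means(state_means: Sequence[float], folded_span_nm: float = 25.0) -> int:
    """Highest state still consistent with a fully folded molecule.

    States whose mean x_E lies within ``folded_span_nm`` of the lowest
    state's mean are "folded": their extra extension (default < 25 nm) is
    attributable to linker straightening and is smaller than the gain from
    unfolding a complete EC domain (~30 nm).  With the canonical
    clustering this returns 2 (states 1 and 2 are the folded states).
    """
    means = np.asarray(state_means, dtype=float)
    if len(means) == 0:
        raise ValueError("no state means")
    return int(np.sum(means - means[0] < folded_span_nm))


def refolding_summary(
    segments: pd.DataFrame,
    folded_threshold_state: int = 2,
    state_means: Optional[Sequence[float]] = None,
    folded_span_nm: float = 25.0,
) -> Dict[Tuple[str, str], RefoldingEntry]:
    """Full-refolding percentages per (construct, calcium) condition.

    For each dataset, cycles are scanned in temporal order.  A cycle
    qualifies if any of its segments was classified above the folded
    threshold (default state 2, the highest state consistent with a fully
    folded molecule); it counts as a full refolding if the first
    extension-phase segment of the *next* cycle is back at or below that
    threshold.  When ``state_means`` is supplied the threshold is derived
    from the state geometry instead (:func:`folded_threshold_from_means`),
    which keeps the folded/unfolded boundary below a full-domain gain even
    when the clustering splits the folded trajectories differently.
    Per-dataset percentages are averaged within each condition
    (mean +/- SEM over datasets).
    """
    if state_means is not None:
        folded_threshold_state = folded_threshold_from_means(state_means, folded_span_nm)
    required = {"dataset_id", "construct", "calcium", "cycle_index", "phase", "ordinal", "state"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    out: Dict[Tuple[str, str], RefoldingEntry] = {}
    for (construct, calcium), cond_grp in segments.groupby(["construct", "calcium"], sort=True):
        percents = []
        for _, ds_grp in cond_grp.groupby("dataset_id"):
            max_state = ds_grp.groupby("cycle_index")["state"].max()
            first_ext = (
                ds_grp[(ds_grp["phase"] == PHASE_EXTENSION) & (ds_grp["ordinal"] == 1)]
                .set_index("cycle_index")["state"]
            )
            cycle_ids = sorted(max_state.index)
            n_qualifying = 0
            n_refolded = 0
            for a, b in zip(cycle_ids[:-1], cycle_ids[1:]):
                if b != a + 1 or b not in first_ext.index:
                    continue  # need the immediately following cycle's start
                if max_state.loc[a] > folded_threshold_state:
                    n_qualifying += 1
                    if first_ext.loc[b] <= folded_threshold_state:
                        n_refolded += 1
            if n_qualifying > 0:
                percents.append(100.0 * n_refolded / n_qualifying)
        if percents:
            arr = np.asarray(percents)
            sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
            out[(construct, calcium)] = RefoldingEntry(float(arr.mean()), sem, len(arr))
        else:
            out[(construct, calcium)] = RefoldingEntry(None, None, cond_grp["dataset_id"].nunique())
    return out


def entropic_stiffness_by_state(
    datasets: Iterable[Dataset],
    segments: pd.DataFrame,
    force_bin_edges: Sequence[float],
    min_samples_per_bin: int = 5,
) -> pd.DataFrame:
    """Per-state stiffness (inverse slope of extension vs force) by force bin.

    For every classified segment, the extension-force relation is fitted
    linearly within each force bin the segment spans; the inverse slope is
    one stiffness determination.  Determinations are averaged per (state,
    bin).  Bins with no determinations for a state are simply absent from
    the output, not reported as zero.

    Returns a table with columns ``state``, ``force_bin_center``,
    ``stiffness``, ``sem``, ``n``.
    """
    edges = np.asarray(force_bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("force_bin_edges must be increasing with at least two edges")
    cycles = {}
    for ds in datasets:
        for cyc in ds.cycles:
            cycles[(ds.dataset_id, cyc.cycle_index)] = cyc
    acc: Dict[Tuple[int, int], List[float]] = {}
    for _, row in segments.iterrows():
        key = (row["dataset_id"], row["cycle_index"])
        if key not in cycles or pd.isna(row["state"]):
            continue
        cyc = cycles[key]
        f = cyc.force[int(row["start"]) : int(row["stop"])]
        x = cyc.extension[int(row["start"]) : int(row["stop"])]
        for b in range(len(edges) - 1):
            mask = (f >= edges[b]) & (f < edges[b + 1])
            if mask.sum() < min_samples_per_bin:
                continue
            fb, xb = f[mask], x[mask]
            if np.ptp(fb) < 0.25 * (edges[b + 1] - edges[b]):
                continue
            slope = np.polyfit(fb, xb, 1)[0]
            if slope > 1e-6:
                acc.setdefault((int(row["state"]), b), []).append(1.0 / slope)
    rows = []
    for (state, b), vals in sorted(acc.items()):
        arr = np.asarray(vals)
        sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        rows.append(
            {
                "state": state,
                "force_bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "stiffness": float(arr.mean()),
                "sem": sem,
                "n": len(arr),
            }
        )
    return pd.DataFrame(rows, columns=["state", "force_bin_center", "stiffness", "sem", "n"])


def tether_statistics(n_beads_tested: int, n_beads_tethered: int) -> float:
    """Probability that a tethered bead carries exactly one tether.

    Tether formation is Poisson across beads: from the observed tethering
    fraction p = tethered/tested, the Poisson mean is
    lambda = -ln(1 - p), and the chance that a bead with at least one
    tether has exactly one is  lambda e^-lambda / (1 - e^-lambda).  A high
    value justifies treating trajectories as single molecules.
    """
    if n_beads_tested <= 0 or n_beads_tethered <= 0:
        raise ValueError("counts must be positive")
    if n_beads_tethered > n_beads_tested:
        raise ValueError("tethered count cannot exceed tested count")
    if n_beads_tethered == n_beads_tested:
        raise ValueError("all beads tethered: Poisson rate is unbounded")
    lam = -np.log1p(-n_beads_tethered / n_beads_tested)
    return float(lam * np.exp(-lam) / (1.0 - np.exp(-lam)))
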