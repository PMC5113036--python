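"""Classification of cell states into fully/partially active/inactive,
and hierarchical clustering of steady-state expression profiles.

Internal DLL alone cannot separate the partial states from their full
counterparts: a partially inactive (pI) cell keeps more active receptor
(VR2) than a fully inactive one, and a partially active (pA) cell keeps
more notch-driven HE than a fully active one.  Clustering therefore uses
all eight species on a variance-stabilised scale: concentrations span
several decades (and the DLL pool can be slightly overdrawn below
zero), so each species is asinh-transformed — log-like for large
values, linear and sign-preserving near zero — and then z-scored so
that no single high-magnitude species dominates the distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .model import N_SPECIES, SPECIES
from .steady_state import EquilibriumBranch

__all__ = [
    "StateProfile",
    "ClusterResult",
    "collect_profiles",
    "cluster_profiles",
    "label_state",
    "label_timepoints",
    "threshold_label",
]

_DLL = SPECIES.index("DLL")
_VR2 = SPECIES.index("VR2")
_HE = SPECIES.index("HE")

#: HE level separating the inhibited (pI) from the active-leaning (pA)
#: side of the intermediate-DLL band; geometric midpoint of the basal
#: (~1 c.u.) and saturated (~theta/phi = 100 c.u.) HE levels.
HE_SPLIT = 10.0


@dataclass
class StateProfile:
    """All-species snapshot of one cell at one verified stable state."""

    condition_id: str
    species_vector: np.ndarray  # (8,) in SPECIES order

    def __post_init__(self) -> None:
        self.species_vector = np.asarray(self.species_vector, float)
        if self.species_vector.shape != (N_SPECIES,):
            raise ValueError(f"species_vector must have length {N_SPECIES}")


@dataclass
class ClusterResult:
    """Agglomerative clustering of profiles with the four-class mapping."""

    labels: np.ndarray  # cluster id per profile (1..k)
    linkage: np.ndarray  # scipy linkage matrix
    class_map: dict[int, str] | None  # cluster id -> A/pA/pI/I (k == 4 only)
    profiles: list[StateProfile]
    mean: np.ndarray  # per-species mean of the asinh-transformed data
    std: np.ndarray

    def transform(self, vec: np.ndarray) -> np.ndarray:
        """Map a raw profile into the standardised clustering space."""
        return (np.arcsinh(np.asarray(vec, float)) - self.mean) / self.std

    @property
    def class_labels(self) -> list[str | None]:
        if self.class_map is None:
            return [None] * len(self.labels)
        return [self.class_map[int(c)] for c in self.labels]

    def cluster_mean(self, cluster_id: int) -> np.ndarray:
        rows = np.array(
            [p.species_vector for p, c in zip(self.profiles, self.labels) if c == cluster_id]
        )
        return rows.mean(axis=0)

    def to_newick(self) -> str:
        """Dendrogram as a Newick string (leaf names = condition ids)."""
        tree = hierarchy.to_tree(self.linkage)
        names = [p.condition_id for p in self.profiles]

        def walk(node) -> str:
            if node.is_leaf():
                return f"{names[node.id]}:{node.dist:.6g}"
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

        return walk(tree) + ";"


def collect_profiles(
    branches: Sequence[EquilibriumBranch],
    picks: Sequence[float] | None = None,
    per_segment: int = 5,
) -> list[StateProfile]:
    """Harvest per-cell profiles from the stable points of branch runs.

    By default every stable segment of every branch contributes
    ``per_segment`` evenly spaced points; ``picks`` adds the stable
    points nearest the given parameter coordinates.  Each sampled
    equilibrium yields two profiles (one per cell).  Duplicate condition
    ids are dropped.
    """
    out: list[StateProfile] = []
    seen: set[str] = set()

    def add(branch_idx: int, p: float, state: np.ndarray) -> None:
        for cell in (1, 2):
            cid = f"b{branch_idx}/p={p:.5g}/cell{cell}"
            if cid in seen:
                continue
            seen.add(cid)
            lo = (cell - 1) * N_SPECIES
            out.append(StateProfile(cid, state[lo : lo + N_SPECIES]))

    for bi, branch in enumerate(branches):
        stable_pts = [
            (p, e) for p, e in zip(branch.parameter_values, branch.equilibria) if e.stable
        ]
        if not stable_pts:
            continue
        for pvals, eqs in branch.segments():
            pts = [(p, e) for p, e in zip(pvals, eqs) if e.stable]
            if not pts:
                continue
            idx = np.unique(np.linspace(0, len(pts) - 1, min(per_segment, len(pts))).astype(int))
            for i in idx:
                add(bi, pts[i][0], pts[i][1].state)
        if picks is not None:
            for target in picks:
                p, e = min(stable_pts, key=lambda pe: abs(pe[0] - target))
                add(bi, p, e.state)
    if not out:
        raise ValueError("no stable equilibria to harvest")
    return out


def cluster_profiles(profiles: Sequence[StateProfile], k: int = 4) -> ClusterResult:
    """Average-linkage hierarchical clustering of standardised profiles.

    For ``k = 4`` the clusters are mapped onto the four phenotype
    classes: the two highest-DLL clusters are the active side (pA being
    the one with more HE), the two lowest are the inactive side (pI
    being the one with more VR2).
    """
    profiles = list(profiles)
    if k > len(profiles):
        raise ValueError(f"requested {k} clusters from {len(profiles)} profiles")
    X = np.array([p.species_vector for p in profiles])
    T = np.arcsinh(X)
    mean = T.mean(axis=0)
    std = T.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Z = hierarchy.linkage((T - mean) / std, method="average", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    class_map = None
    if k == 4 and len(set(labels)) == 4:
        means = {c: X[labels == c].mean(axis=0) for c in sorted(set(labels))}
        by_dll = sorted(means, key=lambda c: means[c][_DLL])
        low, high = by_dll[:2], by_dll[2:]
        pi = max(low, key=lambda c: means[c][_VR2])
        full_i = low[0] if low[1] == pi else low[1]
        pa = max(high, key=lambda c: means[c][_HE])
        full_a = high[0] if high[1] == pa else high[1]
        class_map = {full_a: "A", pa: "pA", full_i: "I", pi: "pI"}
    return ClusterResult(labels, Z, class_map, profiles, mean, std)


def threshold_label(dll: float, he: float) -> str:
    """A / pA / pI / I by the DLL thresholds, with HE splitting the partials."""
    from .simulate import ACTIVE_DLL, INACTIVE_DLL

    if dll > ACTIVE_DLL:
        return "A"
    if dll < INACTIVE_DLL:
        return "I"
    return "pI" if he >= HE_SPLIT else "pA"


def label_state(
    cell_profile: StateProfile | np.ndarray,
    reference: ClusterResult | None = None,
) -> str:
    """Classify one cell profile.

    With a fitted :class:`ClusterResult` the profile is assigned to the
    nearest cluster centroid (in the reference's standardised space);
    otherwise the DLL/HE threshold rule is applied.
    """
    vec = (
        cell_profile.species_vector
        if isinstance(cell_profile, StateProfile)
        else np.asarray(cell_profile, float)
    )
    if reference is None:
        return threshold_label(vec[_DLL], vec[_HE])
    if reference.class_map is None:
        raise ValueError("reference clustering has no class map (need k = 4)")
    z = reference.transform(vec)
    best, best_d = None, np.inf
    for c in reference.class_map:
        cz = reference.transform(reference.cluster_mean(c))
        dist = float(np.linalg.norm(z - cz))
        if dist < best_d:
            best, best_d = c, dist
    return reference.class_map[best]


def default_branches(params=None) -> list[EquilibriumBranch]:
    """The standard branch harvest used for the four-class clustering.

    Three neighbour-overtaking (D_ext) continuations at Sirt1 = 0.5, 1
    and 2, plus three Sirt1 continuations at fixed D_ext = (1, 2) with
    Lfng = 0.5, 1 and 2 — together they visit every stable region the
    bifurcation analyses expose (full and partial, active and inactive).
    """
    from .model import ModelParams, Modulators
    from .steady_state import DextPath, ModulatorPath, continue_branch, find_equilibria

    if params is None:
        params = ModelParams()
    branches = []
    for s1 in (0.5, 1.0, 2.0):
        path = DextPath(mods=Modulators(sirt1=s1))
        eqs = find_equilibria(path.inputs_at(0.0), params, path.mods_at(0.0), n_seeds=2)
        start = max(
            (e for e in eqs if e.stable), key=lambda e: e.state[_DLL], default=None
        )
        if start is None:
            continue
        branches.append(continue_branch(start, path, params=params))
    for lf in (0.5, 1.0, 2.0):
        mp = ModulatorPath("sirt1", span=(0.1, 10.0), other=lf)
        eqs = find_equilibria(mp.inputs, params, Modulators(sirt1=0.1, lfng=lf), n_seeds=2)
        start = max(
            (e for e in eqs if e.stable), key=lambda e: e.state[_DLL], default=None
        )
        if start is None:
            continue
        branches.append(continue_branch(start, mp, params=params))
    return branches


def label_timepoints(traj) -> pd.DataFrame:
    """Per-time-point threshold labels for both cells of a trajectory."""
    d1 = traj.states[:, _DLL]
    h1 = traj.states[:, _HE]
    d2 = traj.states[:, N_SPECIES + _DLL]
    h2 = traj.states[:, N_SPECIES + _HE]
    return pd.DataFrame(
        {
            "time": traj.times,
            "cell1": [threshold_label(d, h) for d, h in zip(d1, h1)],
            "cell2": [threshold_label(d, h) for d, h in zip(d2, h2)],
        }
    )
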