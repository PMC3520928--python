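"""Native-similarity coordinates and macrobasin discretization.

q over a pair subset is the mean of Gaussian terms
exp(-(r_ij - r_ij^N)^2 / (2 sigma_ij^2)); it is 1 at the native frame and
tends to 0 as pairs leave their native distances.  Per-foldon q uses every
contact pair with at least one endpoint inside the foldon (cross-boundary
pairs therefore contribute to both flanking foldons); the global coordinate
uses all pairs.  A frame's macrobasin label sets bit f to 1 iff foldon f's
q strictly exceeds the foldedness threshold, leftmost bit = N-terminal
foldon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from foldonkinetics.structure import ContactSet, FoldonPartition


class CoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class FrameObservables:
    """Per-frame foldon q values, global Q, and (optionally) model energy."""

    foldon_q: np.ndarray  # (n_foldons,), each in [0, 1]
    global_q: float
    potential_energy: float | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.foldon_q, dtype=float).ravel()
        if np.any(q < 0) or np.any(q > 1):
            raise CoordinateError("foldon q values must lie in [0, 1]")
        if not 0.0 <= self.global_q <= 1.0:
            raise CoordinateError("global q must lie in [0, 1]")
        object.__setattr__(self, "foldon_q", q)

    @property
    def n_foldons(self) -> int:
        return len(self.foldon_q)


def compute_q(
    frame_coords: np.ndarray,
    contacts: ContactSet,
    pair_subset: np.ndarray | None = None,
) -> float:
    """Native similarity over a subset of contact pairs.

    ``pair_subset`` holds indices into ``contacts.pairs``; ``None`` means all
    pairs.  An empty subset has no normalizer and is an error.
    """
    coords = np.asarray(frame_coords, dtype=float)
    if pair_subset is None:
        idx = np.arange(contacts.n_pairs)
    else:
        idx = np.asarray(pair_subset, dtype=int).ravel()
    if len(idx) == 0:
        raise CoordinateError("empty pair subset: q undefined")
    pairs = contacts.pairs[idx]
    if coords.shape[0] < pairs.max():
        raise CoordinateError("frame coordinates do not cover all pair residues")
    r = np.linalg.norm(coords[pairs[:, 0] - 1] - coords[pairs[:, 1] - 1], axis=1)
    dr = r - contacts.native_distance[idx]
    sigma = contacts.width[idx]
    return float(np.mean(np.exp(-(dr**2) / (2.0 * sigma**2))))


def foldon_pair_indices(
    contacts: ContactSet, partition: FoldonPartition
) -> list[np.ndarray]:
    """Per-foldon index lists: pairs with >= 1 endpoint inside the foldon."""
    member = partition.membership()  # residue -> foldon, 0-based
    fi = member[contacts.pairs[:, 0] - 1]
    fj = member[contacts.pairs[:, 1] - 1]
    out = []
    for f in range(partition.n_foldons):
        idx = np.where((fi == f) | (fj == f))[0]
        if len(idx) == 0:
            raise CoordinateError(
                f"foldon {partition.names[f]} has no eligible contact pairs"
            )
        out.append(idx)
    return out


def compute_foldon_qs(
    frame_coords: np.ndarray,
    contacts: ContactSet,
    partition: FoldonPartition,
    potential_energy: float | None = None,
) -> FrameObservables:
    """Per-foldon q plus global Q (all unique pairs) for one frame."""
    subsets = foldon_pair_indices(contacts, partition)
    foldon_q = np.array(
        [compute_q(frame_coords, contacts, idx) for idx in subsets]
    )
    global_q = compute_q(frame_coords, contacts, None)
    return FrameObservables(
        foldon_q=foldon_q,
        global_q=global_q,
        potential_energy=potential_energy,
    )


def assign_macrobasin(obs: FrameObservables, threshold: float = 0.6) -> str:
    """Binary macrobasin label; bit f = 1 iff foldon_q[f] > threshold.

    The comparison is strict, so q exactly at the threshold reads unfolded.
    """
    if not 0.0 < threshold < 1.0:
        raise CoordinateError("threshold must lie in (0, 1)")
    return "".join("1" if q > threshold else "0" for q in obs.foldon_q)


def label_trajectory(
    frames: list[FrameObservables], threshold: float = 0.6
) -> tuple[list[str], Counter]:
    """Labels aligned to frames plus the census of observed macrobasins."""
    if not frames:
        raise CoordinateError("empty frame sequence")
    n = frames[0].n_foldons
    labels = []
    for k, obs in enumerate(frames):
        if obs.n_foldons != n:
            raise CoordinateError(
                f"frame {k} has {obs.n_foldons} foldons, expected {n}"
            )
        labels.append(assign_macrobasin(obs, threshold))
    return labels, Counter(labels)
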