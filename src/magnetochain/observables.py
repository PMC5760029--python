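"""Structure classification and rupture-event detection.

Assembled configurations are summarised through a contact graph: two
particles are neighbours when their centre distance is within
``cutoff_factor`` (default 1.2) times the pair contact distance
R_i + R_j + d.  The factor tolerates thermal rattle around contact while
excluding second neighbours, which sit near twice the contact distance
in a straight chain.  Connected components are classified as

* chain  — a simple path of >= 2 particles (all degrees <= 2, no cycle),
* ring   — a single cycle with every degree exactly 2,
* handle — one cycle plus a pendant path grafted onto a single cycle
  node (a ring and a chain sharing one particle),
* other  — anything else, including isolated particles.

Rupture events in a field-rotation trace are located by change-point
detection on the number of bound particles and the net-moment angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .params import ModelParams
from .state import SystemState

DEFAULT_CUTOFF_FACTOR = 1.2


@dataclass
class StructureReport:
    """Cluster taxonomy of one configuration."""

    n_chains: int
    n_rings: int
    n_handles: int
    n_other: int
    clusters: list            # list of (label, [particle indices])
    bound_count: int
    theta_m_deg: Optional[float]   # None when the net moment vanishes

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def config_label(self) -> str:
        """Label of the whole configuration: the type of its unique
        non-singleton cluster, or 'other' for anything composite."""
        big = [lab for lab, members in self.clusters if len(members) >= 2]
        if len(big) == 1:
            return big[0]
        return "other"


@dataclass
class CriticalAngles:
    """Field angles of the two rupture events (degrees), when present."""

    first_critical: Optional[float] = None
    second_critical: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.first_critical is not None and self.second_critical is not None
                and not self.first_critical < self.second_critical):
            raise ValueError("first critical angle must precede the second")


def neighbor_graph(state: SystemState, params: ModelParams,
                   cutoff_factor: float = DEFAULT_CUTOFF_FACTOR) -> nx.Graph:
    """Contact graph: edge (i, j) iff r_ij <= cutoff_factor * (R_i + R_j + d)."""
    g = nx.Graph()
    g.add_nodes_from(range(state.n))
    if state.n < 2:
        return g
    iu, ju = np.triu_indices(state.n, k=1)
    r = np.linalg.norm(state.positions[ju] - state.positions[iu], axis=1)
    cut = cutoff_factor * (state.radii[iu] + state.radii[ju] + params.membrane_gap)
    for i, j in zip(iu[r <= cut], ju[r <= cut]):
        g.add_edge(int(i), int(j))
    return g


def _classify_component(sub: nx.Graph) -> str:
    n = sub.number_of_nodes()
    m = sub.number_of_edges()
    degs = sorted(d for _, d in sub.degree())
    if n >= 2 and m == n - 1 and degs[-1] <= 2:
        return "chain"
    if n >= 3 and m == n and degs[0] == 2 and degs[-1] == 2:
        return "ring"
    if n >= 4 and m == n and degs.count(1) == 1 and degs.count(3) == 1 \
            and degs.count(2) == n - 2:
        # exactly one cycle (m == n) with a single pendant path: the
        # degree-3 node is where the path is grafted onto the cycle
        return "handle"
    return "other"


def classify_structures(graph: nx.Graph, state: Optional[SystemState] = None) -> StructureReport:
    """Classify every connected component of a contact graph.

    When ``state`` is given, the bound count and net-moment angle are
    filled in; otherwise they default to 0 / None.
    """
    counts = {"chain": 0, "ring": 0, "handle": 0, "other": 0}
    clusters = []
    for comp in nx.connected_components(graph):
        label = _classify_component(graph.subgraph(comp))
        counts[label] += 1
        clusters.append((label, sorted(comp)))
    bound_count = state.bound_count() if state is not None else 0
    theta = chain_moment_angle(state) if state is not None else None
    return StructureReport(
        n_chains=counts["chain"], n_rings=counts["ring"],
        n_handles=counts["handle"], n_other=counts["other"],
        clusters=clusters, bound_count=bound_count, theta_m_deg=theta,
    )


def chain_moment_angle(state: SystemState) -> Optional[float]:
    """Angle theta_m between the net moment sum_i m_i and the filament
    axis (+x), degrees in [0, 180]; None if the net moment vanishes.

    This is the whole-cell moment, the quantity a bulk magnetometry or
    diffraction experiment tracks.
    """
    m = state.net_moment()
    norm = float(np.linalg.norm(m))
    if norm == 0.0:
        return None
    c = float(np.clip(m[0] / norm, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def detect_critical_angles(theta_b: Sequence[float],
                           bound_count: Sequence[float],
                           theta_m: Sequence[float],
                           n_particles: int,
                           window_deg: float = 2.0,
                           first_drop: float = 2.0,
                           second_drop: Optional[float] = None,
                           theta_m_jump: float = 15.0) -> CriticalAngles:
    """Locate the two rupture events in a field-rotation trace.

    The first critical angle is the smallest theta_B at which the bound
    count has dropped by >= ``first_drop`` relative to some earlier point
    within a ``window_deg`` window (the two chain ends detaching).  The
    second is the smallest subsequent angle with either a bound-count
    drop >= ``second_drop`` (default N/4) or a net-moment-angle jump
    >= ``theta_m_jump`` within the window (chain fragmentation).

    theta_B must be monotone increasing and span at least one window.
    """
    tb = np.asarray(theta_b, dtype=float)
    bc = np.asarray(bound_count, dtype=float)
    tm = np.asarray(theta_m, dtype=float)
    if not (len(tb) == len(bc) == len(tm)):
        raise ValueError("trace columns must have equal length")
    if np.any(np.diff(tb) <= 0):
        raise ValueError("theta_B must be strictly increasing")
    if len(tb) < 2 or tb[-1] - tb[0] < window_deg:
        raise ValueError("trace shorter than the detection window")
    if second_drop is None:
        second_drop = n_particles / 4.0

    first: Optional[float] = None
    second: Optional[float] = None
    for k in range(1, len(tb)):
        lo = np.searchsorted(tb, tb[k] - window_deg, side="left")
        back = slice(lo, k)
        if back.start >= k:
            continue
        max_drop = float(np.max(bc[back]) - bc[k])
        max_jump = float(tm[k] - np.min(tm[back]))
        if first is None:
            if max_drop >= first_drop:
                first = float(tb[k])
        elif second is None and tb[k] > first:
            if max_drop >= second_drop or max_jump >= theta_m_jump:
                second = float(tb[k])
                break
    return CriticalAngles(first_critical=first, second_critical=second)
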