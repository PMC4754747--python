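"""Dynamic residue-interaction networks.

A residue pair is connected when it satisfies two criteria simultaneously:
(i) correlated motion — the angle between the two residues' motion
directions in a chosen PC mode is below ``angle_threshold`` (default 45
degrees), and (ii) persistent contact — at least one heavy-atom pair of the
two residues is closer than ``distance_threshold`` (default 4.5 Angstrom,
strict) in at least ``occupancy_threshold`` (default 75%, inclusive) of the
frames.  Networks are built per chain with intra-chain edges by default;
topology summaries (node/edge counts, average degree, average clustering
coefficient), geodesic path reports and a frame-bootstrap robustness
protocol mirror the downstream comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core import (
    ResidueSelection,
    TrajectoryEnsemble,
    ValidationError,
)
from .modes import ModeSet, residue_direction


# ---------------------------------------------------------------------------
# Contact occupancy
# ---------------------------------------------------------------------------


@dataclass
class ContactFrames:
    """Per-frame contact indicators for every residue pair ever in contact."""

    pairs: dict  # ((chain,res),(chain,res)) sorted pair -> bool array (F,)
    threshold_distance: float
    frame_count: int


@dataclass
class ContactOccupancy:
    pairs: dict  # sorted residue pair -> occupancy fraction in [0,1]
    threshold_distance: float
    frame_count: int

    def occupancy(self, res_a: tuple, res_b: tuple) -> float:
        key = tuple(sorted([tuple(res_a), tuple(res_b)]))
        return self.pairs.get(key, 0.0)


def _sorted_pair(a: tuple, b: tuple) -> tuple:
    return tuple(sorted([(str(a[0]), int(a[1])), (str(b[0]), int(b[1]))]))


def contact_frames(
    traj: TrajectoryEnsemble,
    distance: float = 4.5,
    selection: str = "heavy",
) -> ContactFrames:
    """Per-frame residue-pair contacts: a pair is in contact in a frame iff
    its minimal inter-atom distance (over the selection) is strictly below
    ``distance``."""
    from .core import select as _select

    model = traj.model
    atoms = _select(model, selection)
    atom_res = [
        (str(model.chain_ids[i]), int(model.residue_indices[i])) for i in atoms
    ]
    pairs: dict[tuple, np.ndarray] = {}
    for t in range(traj.n_frames):
        coords = traj.frames[t, atoms]
        tree = cKDTree(coords)
        frame_pairs = set()
        for i, j in tree.query_pairs(distance):
            ri, rj = atom_res[i], atom_res[j]
            if ri == rj:
                continue
            # query_pairs is inclusive of the radius at exact equality only
            # up to float noise; enforce the strict inequality explicitly.
            if np.linalg.norm(coords[i] - coords[j]) < distance:
                frame_pairs.add(tuple(sorted([ri, rj])))
        # Sorted insertion keeps pair order (and everything downstream that
        # iterates the dict) independent of hash randomization.
        for key in sorted(frame_pairs):
            if key not in pairs:
                pairs[key] = np.zeros(traj.n_frames, dtype=bool)
            pairs[key][t] = True
    return ContactFrames(
        pairs=pairs, threshold_distance=distance, frame_count=traj.n_frames
    )


def contact_occupancy(
    traj: TrajectoryEnsemble,
    distance: float = 4.5,
    selection: str = "heavy",
) -> ContactOccupancy:
    """Fraction of frames each residue pair spends in contact."""
    cf = contact_frames(traj, distance=distance, selection=selection)
    return occupancy_from_frames(cf)


def occupancy_from_frames(
    cf: ContactFrames, frame_subset: np.ndarray | None = None
) -> ContactOccupancy:
    if frame_subset is None:
        n = cf.frame_count
        occ = {k: float(v.mean()) for k, v in cf.pairs.items()}
    else:
        frame_subset = np.asarray(frame_subset, dtype=int)
        n = len(frame_subset)
        occ = {k: float(v[frame_subset].mean()) for k, v in cf.pairs.items()}
    return ContactOccupancy(
        pairs=occ, threshold_distance=cf.threshold_distance, frame_count=n
    )


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


@dataclass
class ResidueNetwork:
    chain_id: str
    graph: nx.Graph  # nodes: (chain, residue); only residues with >= 1 edge
    parameters: dict

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list:
        return list(self.graph.edges)


def build_network(
    modes: ModeSet,
    mode_index: int,
    occupancy: ContactOccupancy,
    angle_threshold: float = 45.0,
    occupancy_threshold: float = 0.75,
    scope: str = "intra-chain",
    exclude_sequence_window: int = 0,
) -> list[ResidueNetwork]:
    """One residue-interaction network per chain.

    An edge requires (i) both residues' motion directions defined in the
    mode and their cosine above cos(angle_threshold), and (ii) contact
    occupancy >= occupancy_threshold.  ``exclude_sequence_window`` > 0 drops
    pairs with |i - j| <= window within a chain (default: none dropped).
    ``scope="inter-chain"`` adds a single network holding only cross-chain
    edges.
    """
    if scope not in ("intra-chain", "inter-chain"):
        raise ValidationError(f"unknown network scope {scope!r}")
    cos_floor = float(np.cos(np.deg2rad(angle_threshold)))
    directions: dict[tuple, np.ndarray | None] = {}
    for key in modes.residue_keys:
        directions[key] = residue_direction(modes, mode_index, key)

    params = {
        "angle_threshold_deg": angle_threshold,
        "distance_threshold_A": occupancy.threshold_distance,
        "occupancy_threshold": occupancy_threshold,
        "mode_index": mode_index,
        "scope": scope,
        "exclude_sequence_window": exclude_sequence_window,
    }

    chains = []
    for key in modes.residue_keys:
        if key[0] not in chains:
            chains.append(key[0])

    def _edge_cosine(ra: tuple, rb: tuple, occ: float) -> float | None:
        """Direction cosine when the pair satisfies both criteria, else None."""
        if occ < occupancy_threshold:
            return None
        da, db = directions.get(ra), directions.get(rb)
        if da is None or db is None:
            return None
        cosine = float(np.dot(da, db))
        return cosine if cosine > cos_floor else None

    networks = []
    if scope == "intra-chain":
        for chain in chains:
            g = nx.Graph()
            for (ra, rb), occ in occupancy.pairs.items():
                if ra[0] != chain or rb[0] != chain:
                    continue
                if exclude_sequence_window and abs(ra[1] - rb[1]) <= exclude_sequence_window:
                    continue
                cosine = _edge_cosine(ra, rb, occ)
                if cosine is not None:
                    g.add_edge(ra, rb, occupancy=occ, direction_cosine=cosine)
            networks.append(ResidueNetwork(chain_id=chain, graph=g, parameters=params))
    else:
        g = nx.Graph()
        for (ra, rb), occ in occupancy.pairs.items():
            if ra[0] == rb[0]:
                continue
            cosine = _edge_cosine(ra, rb, occ)
            if cosine is not None:
                g.add_edge(ra, rb, occupancy=occ, direction_cosine=cosine)
        networks.append(ResidueNetwork(chain_id="+".join(chains), graph=g, parameters=params))
    return networks


# ---------------------------------------------------------------------------
# Topology summary
# ---------------------------------------------------------------------------


@dataclass
class NetworkSummary:
    chain_id: str
    n_nodes: int
    n_edges: int
    degree_of: dict  # residue -> degree
    average_degree: float
    average_clustering_coefficient: float


def summarize(network: ResidueNetwork) -> NetworkSummary:
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot summarize an empty network")
    degrees = dict(g.degree())
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    return NetworkSummary(
        chain_id=network.chain_id,
        n_nodes=n_nodes,
        n_edges=n_edges,
        degree_of=degrees,
        average_degree=2.0 * n_edges / n_nodes,
        average_clustering_coefficient=float(nx.average_clustering(g)),
    )


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------


@dataclass
class PathReport:
    source: tuple
    targets: list
    lengths: dict  # target -> int path length in edges, or None if unreachable
    n_paths: dict  # target -> number of distinct geodesics (0 if unreachable)
    example_paths: dict  # target -> one geodesic as a residue list, or None


def _geodesic_counts(g: nx.Graph, source) -> tuple[dict, dict]:
    """BFS distances and geodesic counts from ``source`` (Brandes-style
    sigma accumulation)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = [source]
    while queue:
        next_queue = []
        for u in queue:
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0
                    next_queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        queue = next_queue
    return dist, sigma


def shortest_paths(
    networks: list[ResidueNetwork] | ResidueNetwork,
    source: tuple,
    targets: ResidueSelection,
) -> PathReport:
    """Geodesic lengths, geodesic counts, and one example shortest path from
    ``source`` to each target residue.  Targets absent from the network or
    disconnected from the source are flagged unreachable (length None)."""
    if isinstance(networks, ResidueNetwork):
        networks = [networks]
    g = nx.Graph()
    for net in networks:
        g.add_edges_from(net.graph.edges)
    source = (str(source[0]), int(source[1]))
    if source not in g:
        raise ValidationError(f"source residue {source} is not a network node")
    dist, sigma = _geodesic_counts(g, source)
    lengths: dict = {}
    n_paths: dict = {}
    examples: dict = {}
    for target in targets:
        if target not in g or target not in dist:
            lengths[target] = None
            n_paths[target] = 0
            examples[target] = None
            continue
        lengths[target] = dist[target]
        n_paths[target] = sigma[target]
        examples[target] = nx.shortest_path(g, source, target)
    return PathReport(
        source=source,
        targets=list(targets),
        lengths=lengths,
        n_paths=n_paths,
        example_paths=examples,
    )


# ---------------------------------------------------------------------------
# Bootstrap robustness
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    summaries: list  # one list of NetworkSummary per repeat
    mean: dict  # chain -> property -> mean over repeats
    sd: dict  # chain -> property -> SD over repeats


_BOOT_PROPS = (
    "n_nodes",
    "n_edges",
    "average_degree",
    "average_clustering_coefficient",
)


def bootstrap_networks(
    traj: TrajectoryEnsemble,
    modes: ModeSet,
    mode_index: int,
    fraction: float = 0.8,
    repeats: int = 10,
    seed: int = 0,
    distance: float = 4.5,
    angle_threshold: float = 45.0,
    occupancy_threshold: float = 0.75,
    scope: str = "intra-chain",
    exclude_sequence_window: int = 0,
    precomputed_contacts: ContactFrames | None = None,
) -> BootstrapResult:
    """Robustness of the network topology under frame resampling.

    Each repeat draws ``floor(fraction * F)`` distinct frames without
    replacement, recomputes contact occupancies on that subset, and rebuilds
    the networks on the SAME mode (the mode is not recomputed).  Reports
    per-chain mean and SD of the topology properties across repeats.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must be in (0, 1]")
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    cf = precomputed_contacts or contact_frames(traj, distance=distance)
    rng = np.random.default_rng(seed)
    n_take = int(np.floor(fraction * traj.n_frames))
    if n_take < 1:
        raise ValidationError("fraction selects zero frames")
    all_summaries: list[list[NetworkSummary]] = []
    for _ in range(repeats):
        subset = rng.choice(traj.n_frames, size=n_take, replace=False)
        occ = occupancy_from_frames(cf, frame_subset=subset)
        nets = build_network(
            modes,
            mode_index,
            occ,
            angle_threshold=angle_threshold,
            occupancy_threshold=occupancy_threshold,
            scope=scope,
            exclude_sequence_window=exclude_sequence_window,
        )
        all_summaries.append([summarize(n) for n in nets if n.graph.number_of_nodes()])
    mean: dict = {}
    sd: dict = {}
    chains = {s.chain_id for reps in all_summaries for s in reps}
    for chain in sorted(chains):
        mean[chain] = {}
        sd[chain] = {}
        for prop in _BOOT_PROPS:
            vals = np.array(
                [
                    getattr(s, prop)
                    for reps in all_summaries
                    for s in reps
                    if s.chain_id == chain
                ],
                dtype=float,
            )
            mean[chain][prop] = float(vals.mean())
            sd[chain][prop] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return BootstrapResult(summaries=all_summaries, mean=mean, sd=sd)
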