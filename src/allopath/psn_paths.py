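"""Protein structure networks, correlated motions, and communication paths.

A protein structure network (PSN) has residues as nodes.  For a residue pair
(i, j) the interaction strength is the normalized percentage of side-chain
heavy-atom pairs within a distance cutoff,

    I_ij = 100 · n_ij / sqrt(N_i · N_j),

and the pair is connected whenever I_ij meets the interaction cutoff I_min
(and at least one atom pair is actually in contact).  Dynamic
cross-correlations (DCC) over an ensemble,

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>)  ∈ [−1, 1],

gate the network: communication paths are searched by Dijkstra on the
subgraph whose edges also satisfy |C_ij| ≥ corr_min, minimizing hop count
with summed interaction strength and lexicographic order as tie-breakers.
Per-frame shortest paths between two residue pockets are pooled into a
frequency tally; paths supported by at least ``freq_min`` of the frames
(default 30%) are the reported communication pathways.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .cluster_reps import kabsch_superpose
from .structure_io import Ensemble, ResidueSelection, select_residues

__all__ = [
    "PSNConfig",
    "InteractionMatrix",
    "DCCMatrix",
    "Path",
    "PathTally",
    "interaction_matrix",
    "build_psn",
    "frame_graphs",
    "dcc_matrix",
    "shortest_path",
    "tally_paths",
]

logger = logging.getLogger(__name__)

ResKey = tuple[str, int, str]


@dataclass(frozen=True)
class PSNConfig:
    """Parameters of protein-structure-network construction.

    ``distance_cutoff`` is the side-chain heavy-atom contact distance (Å);
    ``i_min`` the interaction-strength threshold in percent.  Normalization
    ``"uniform"`` uses N = 100 for every residue type, making I_ij a scaled
    pair count; ``"table"`` reads per-residue-type N values from
    ``normalization_table``.  ``normalization="product"`` switches from the
    default sqrt form to the literal product N_i·N_j.  Glycine, which has no
    side chain, contributes its Cα instead.  Sequence-adjacent residues of
    the same chain are excluded from edges unless ``include_adjacent``.
    """

    distance_cutoff: float = 4.5
    i_min: float = 3.0
    normalization_mode: str = "uniform"
    normalization: str = "sqrt"
    normalization_table: dict = field(default_factory=dict)
    include_adjacent: bool = False
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be > 0")
        if self.i_min < 0:
            raise ValueError("i_min must be ≥ 0")
        if self.normalization_mode not in ("uniform", "table"):
            raise ValueError("normalization_mode must be 'uniform' or 'table'")
        if self.normalization not in ("sqrt", "product"):
            raise ValueError("normalization must be 'sqrt' or 'product'")

    def norm_factor(self, residue_name: str) -> float:
        if self.normalization_mode == "uniform":
            return 100.0
        try:
            return float(self.normalization_table[residue_name])
        except KeyError:
            raise KeyError(
                f"residue type {residue_name!r} missing from the normalization "
                "table") from None


@dataclass
class InteractionMatrix:
    """Per-frame symmetric residue×residue interaction strengths.

    ``i`` holds I_ij in percent, ``n`` the raw side-chain atom-pair counts;
    ``residues`` maps matrix rows to residue keys.
    """

    residues: list[ResKey]
    i: np.ndarray
    n: np.ndarray

    def index(self, residue: ResKey) -> int:
        return self.residues.index(residue)


@dataclass
class DCCMatrix:
    """Residue–residue dynamic cross-correlations in [−1, 1].

    Rows/columns of residues whose displacement variance is zero are flagged
    and zeroed; they are excluded from correlation-filtered path searches.
    """

    residues: list[ResKey]
    c: np.ndarray
    flagged: np.ndarray  # boolean, True where variance was zero

    def value(self, r1: ResKey, r2: ResKey) -> float:
        return float(self.c[self.residues.index(r1), self.residues.index(r2)])


@dataclass
class Path:
    """One communication path: an ordered residue sequence with edge stats."""

    residues: tuple[ResKey, ...]
    hops: int
    total_interaction: float
    mean_abs_corr: float


@dataclass
class PathTally:
    """Cross-frame pooling of shortest communication paths.

    ``frequencies`` maps each distinct residue sequence to the fraction of
    frames in which it occurred as a shortest source→sink path (counted once
    per frame).  ``n_frequent`` counts sequences at or above ``freq_min``;
    ``top`` is the highest-frequency path (ties: lexicographic), or None.
    """

    frequencies: dict[tuple[ResKey, ...], float]
    n_frames: int
    freq_min: float
    n_frequent: int
    top: tuple[ResKey, ...] | None

    def frequent_paths(self) -> list[tuple[tuple[ResKey, ...], float]]:
        items = [(p, f) for p, f in self.frequencies.items() if f >= self.freq_min]
        return sorted(items, key=lambda pf: (-pf[1], pf[0]))


# ---------------------------------------------------------------------------
# Interaction matrix and graph construction


def _sidechain_atoms_by_residue(ensemble: Ensemble, config: PSNConfig,
                                ) -> tuple[list[ResKey], list[np.ndarray], list[str]]:
    """Group side-chain heavy-atom indices by residue (Gly → Cα)."""
    groups: dict[ResKey, list[int]] = {}
    names: dict[ResKey, str] = {}
    order: list[ResKey] = []
    for idx, rec in enumerate(ensemble.topology):
        key = rec.residue_key
        if key not in groups:
            groups[key] = []
            names[key] = rec.residue_name
            order.append(key)
        if rec.element.upper() == "H" and not config.include_hydrogens:
            continue
        is_backbone = rec.atom_name in ("N", "CA", "C", "O")
        if rec.residue_name == "GLY":
            if rec.atom_name == "CA":
                groups[key].append(idx)
        elif not is_backbone:
            groups[key].append(idx)
    return order, [np.asarray(groups[k], int) for k in order], [names[k] for k in order]


def interaction_matrix(ensemble: Ensemble, frame: int,
                       config: PSNConfig | None = None) -> InteractionMatrix:
    """Side-chain contact interaction strengths I_ij for one frame.

    ``n_ij`` counts side-chain heavy-atom pairs within
    ``config.distance_cutoff``; ``I_ij = 100·n_ij/sqrt(N_i·N_j)`` (or the
    product form).  Sequence-adjacent pairs of the same chain get I = n = 0
    unless ``config.include_adjacent``.
    """
    config = config or PSNConfig()
    order, groups, resnames = _sidechain_atoms_by_residue(ensemble, config)
    n_res = len(order)
    norm = np.array([config.norm_factor(rn) for rn in resnames])

    # atom → residue row lookup over the pooled side-chain atoms
    atom_idx = np.concatenate([g for g in groups if g.size]) if any(
        g.size for g in groups) else np.empty(0, int)
    atom_res = np.concatenate([np.full(g.size, r) for r, g in enumerate(groups)
                               if g.size]) if atom_idx.size else np.empty(0, int)

    counts = np.zeros((n_res, n_res), dtype=int)
    if atom_idx.size:
        xyz = ensemble.coords[frame][atom_idx]
        tree = cKDTree(xyz)
        for a, b in tree.query_pairs(config.distance_cutoff):
            ra, rb = atom_res[a], atom_res[b]
            if ra == rb:
                continue
            counts[ra, rb] += 1
            counts[rb, ra] += 1

    if not config.include_adjacent:
        for r in range(n_res - 1):
            (c1, n1, _), (c2, n2, _) = order[r], order[r + 1]
            if c1 == c2 and abs(n1 - n2) == 1:
                counts[r, r + 1] = counts[r + 1, r] = 0

    if config.normalization == "sqrt":
        denom = np.sqrt(np.outer(norm, norm))
    else:
        denom = np.outer(norm, norm)
    i_mat = 100.0 * counts / denom
    np.fill_diagonal(i_mat, 0.0)
    return InteractionMatrix(residues=order, i=i_mat, n=counts)


def build_psn(interactions: InteractionMatrix,
              config: PSNConfig | None = None) -> nx.Graph:
    """Threshold an interaction matrix into an undirected PSN.

    An edge exists iff ``I_ij ≥ i_min`` **and** ``n_ij ≥ 1``; edges carry
    ``weight`` (I_ij) and ``n_pairs`` attributes.
    """
    config = config or PSNConfig()
    g = nx.Graph()
    g.add_nodes_from(interactions.residues)
    rows, cols = np.nonzero(
        np.triu((interactions.i >= config.i_min) & (interactions.n >= 1), k=1))
    for r, c in zip(rows, cols):
        g.add_edge(interactions.residues[r], interactions.residues[c],
                   weight=float(interactions.i[r, c]),
                   n_pairs=int(interactions.n[r, c]))
    return g


def frame_graphs(ensemble: Ensemble, config: PSNConfig | None = None,
                 frames: list[int] | None = None) -> list[nx.Graph]:
    """Per-frame PSNs for an ensemble (all frames by default)."""
    config = config or PSNConfig()
    frames = range(ensemble.n_frames) if frames is None else frames
    return [build_psn(interaction_matrix(ensemble, f, config), config)
            for f in frames]


# ---------------------------------------------------------------------------
# Dynamic cross-correlation


def dcc_matrix(ensemble: Ensemble, atom_sel: np.ndarray | dict,
               superpose: bool = True) -> DCCMatrix:
    """Dynamic cross-correlation of Cα (one atom per residue) displacements.

    ``atom_sel`` is either a residue-grouped mapping (as returned by
    :func:`~allopath.structure_io.select_residues` with ``atoms="calpha"``)
    or a flat index array with one atom per residue.  With ``superpose`` the
    frames are first least-squares fitted onto the ensemble mean (two
    passes, refitting the mean in between) so that rigid-body motion does
    not masquerade as correlation.

    Residues with zero displacement variance are flagged, their rows and
    columns set to 0 (diagonal included), and later excluded from
    correlation-filtered path searches.
    """
    if isinstance(atom_sel, dict):
        res_keys = list(atom_sel.keys())
        idx = []
        for k, v in atom_sel.items():
            v = np.asarray(v, int)
            if v.size != 1:
                raise ValueError(
                    f"dcc_matrix needs exactly one atom per residue; {k} has {v.size}")
            idx.append(int(v[0]))
        idx = np.asarray(idx, int)
    else:
        idx = np.asarray(atom_sel, int)
        res_keys = [ensemble.topology[i].residue_key for i in idx]
    if idx.size == 0:
        raise ValueError("empty atom selection")
    if ensemble.n_frames < 2:
        raise ValueError("DCC needs at least 2 frames")

    coords = ensemble.coords[:, idx, :].astype(float)
    if superpose:
        for _ in range(2):  # fit → new mean → refit
            mean = coords.mean(axis=0)
            try:
                coords = np.stack([
                    kabsch_superpose(frame, mean)[0] for frame in coords])
            except Exception as exc:  # degenerate (e.g. < 3 atoms): skip fitting
                logger.warning("superposition skipped: %s", exc)
                break

    delta = coords - coords.mean(axis=0)
    cov = np.einsum("fix,fjx->ij", delta, delta) / ensemble.n_frames
    var = np.diag(cov).copy()
    flagged = var <= 1e-300
    if flagged.all():
        warnings.warn("all residues have zero displacement variance "
                      "(identical frames); DCC is all zero")
    denom = np.sqrt(np.where(flagged, 1.0, var))
    c = cov / np.outer(denom, denom)
    c[flagged, :] = 0.0
    c[:, flagged] = 0.0
    np.fill_diagonal(c, np.where(flagged, 0.0, 1.0))
    c = np.clip(c, -1.0, 1.0)
    return DCCMatrix(residues=res_keys, c=c, flagged=flagged)


# ---------------------------------------------------------------------------
# Shortest paths and tallies


def _corr_subgraph(graph: nx.Graph, dcc: DCCMatrix | None,
                   corr_min: float) -> nx.Graph:
    """Drop edges with |C_ij| < corr_min and nodes with flagged variance."""
    if dcc is None or corr_min <= 0:
        return graph
    lookup = {r: i for i, r in enumerate(dcc.residues)}
    keep = []
    for u, v, data in graph.edges(data=True):
        iu, iv = lookup.get(u), lookup.get(v)
        if iu is None or iv is None:
            continue
        if dcc.flagged[iu] or dcc.flagged[iv]:
            continue
        if abs(dcc.c[iu, iv]) >= corr_min:
            keep.append((u, v, data))
    sub = nx.Graph()
    sub.add_nodes_from(graph.nodes)
    sub.add_edges_from(keep)
    return sub


def shortest_path(graph: nx.Graph, dcc: DCCMatrix | None,
                  source: ResKey, sink: ResKey,
                  corr_min: float = 0.3) -> Path | None:
    """Correlation-filtered minimum-hop path from source to sink.

    Dijkstra with unit edge cost on the subgraph whose edges satisfy
    ``|C_ij| ≥ corr_min``; among equal-hop paths the one with the largest
    summed interaction strength wins, then the lexicographically smallest
    residue sequence.  Returns None when source and sink are disconnected.
    """
    for node in (source, sink):
        if node not in graph:
            raise KeyError(f"residue {node} is not a network node")
    if source == sink:
        return Path(residues=(source,), hops=0, total_interaction=0.0,
                    mean_abs_corr=0.0)
    sub = _corr_subgraph(graph, dcc, corr_min)
    seq = _best_min_hop_path(sub, source, sink)
    if seq is None:
        return None
    return _path_from_sequence(seq, sub, dcc)


def _best_min_hop_path(g: nx.Graph, source: ResKey,
                       sink: ResKey) -> tuple[ResKey, ...] | None:
    """Min-hop path, maximizing summed edge weight then lexicographic order.

    BFS fixes the hop distance from both endpoints; edges on *some* shortest
    path form a layered DAG, over which a backward dynamic program selects
    the best continuation at every node under the tie rules.
    """
    if source not in g or sink not in g:
        return None
    try:
        d_src = nx.single_source_shortest_path_length(g, source)
    except nx.NetworkXError:  # pragma: no cover
        return None
    if sink not in d_src:
        return None
    d_snk = nx.single_source_shortest_path_length(g, sink)
    total = d_src[sink]

    # best[u] = (max summed weight u→sink, lexicographically best sequence)
    best: dict[ResKey, tuple[float, tuple[ResKey, ...]]] = {sink: (0.0, (sink,))}
    # process nodes by decreasing distance-to-sink layer
    layer_nodes: dict[int, list[ResKey]] = {}
    for u, ds in d_src.items():
        if u in d_snk and ds + d_snk[u] == total:
            layer_nodes.setdefault(d_snk[u], []).append(u)
    for dist in range(1, total + 1):
        for u in layer_nodes.get(dist, []):
            cand: tuple[float, tuple[ResKey, ...]] | None = None
            for v in g.neighbors(u):
                # v must be a shortest-path node one layer closer to the sink
                if v not in best or d_snk.get(v) != dist - 1:
                    continue
                w = g[u][v].get("weight", 0.0) + best[v][0]
                seq = (u,) + best[v][1]
                if cand is None or (-w, seq) < (-cand[0], cand[1]):
                    cand = (w, seq)
            if cand is not None:
                best[u] = cand
    if source not in best:
        return None
    return best[source][1]


def _path_from_sequence(seq: tuple[ResKey, ...], g: nx.Graph,
                        dcc: DCCMatrix | None) -> Path:
    total_i = sum(g[u][v].get("weight", 0.0) for u, v in zip(seq, seq[1:]))
    if dcc is not None and len(seq) > 1:
        lookup = {r: i for i, r in enumerate(dcc.residues)}
        corrs = [abs(dcc.c[lookup[u], lookup[v]]) for u, v in zip(seq, seq[1:])
                 if u in lookup and v in lookup]
        mean_c = float(np.mean(corrs)) if corrs else 0.0
    else:
        mean_c = 0.0
    return Path(residues=seq, hops=len(seq) - 1, total_interaction=float(total_i),
                mean_abs_corr=mean_c)


def tally_paths(per_frame_graphs: list[nx.Graph], dcc: DCCMatrix | None,
                sources: ResidueSelection, sinks: ResidueSelection,
                corr_min: float = 0.3, freq_min: float = 0.30) -> PathTally:
    """Pool per-frame shortest source→sink paths into a frequency tally.

    For every frame and every (source residue, sink residue) pair the
    correlation-filtered shortest path is computed; identical residue
    sequences are pooled, each counted at most once per frame.  The tally
    reports each sequence's supporting-frame fraction, the number of
    distinct sequences with frequency ≥ ``freq_min``, and the single
    highest-frequency path.
    """
    if not per_frame_graphs:
        raise ValueError("need at least one frame graph")
    if len(sources) == 0 or len(sinks) == 0:
        raise ValueError("source and sink pockets must be nonempty")

    src_keys = [(c, n) for c, n, _ in sources.entries]
    snk_keys = [(c, n) for c, n, _ in sinks.entries]

    support: dict[tuple[ResKey, ...], int] = {}
    for g in per_frame_graphs:
        sub = _corr_subgraph(g, dcc, corr_min)
        node_by_short = {(c, n): (c, n, i) for (c, n, i) in sub.nodes}
        seen: set[tuple[ResKey, ...]] = set()
        for s_short, t_short in itertools.product(src_keys, snk_keys):
            s = node_by_short.get(s_short)
            t = node_by_short.get(t_short)
            if s is None or t is None or s == t:
                continue
            seq = _best_min_hop_path(sub, s, t)
            if seq is not None and len(seq) > 1:
                seen.add(seq)
        for seq in seen:
            support[seq] = support.get(seq, 0) + 1

    n_frames = len(per_frame_graphs)
    freqs = {seq: cnt / n_frames for seq, cnt in support.items()}
    frequent = [s for s, f in freqs.items() if f >= freq_min]
    top = None
    if freqs:
        top = min(freqs, key=lambda s: (-freqs[s], s))
    return PathTally(frequencies=freqs, n_frames=n_frames, freq_min=freq_min,
                     n_frequent=len(frequent), top=top)
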