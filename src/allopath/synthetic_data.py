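"""Synthetic ensembles, score sets and energy tables with known ground truth.

Every pipeline stage downstream of molecular dynamics and docking can be
exercised against analytically known answers:

* :func:`make_gnm_ensemble` samples Cα frames from a Gaussian network model
  (GNM), whose Kirchhoff-matrix pseudo-inverse gives the exact residue–residue
  correlation matrix that a dynamic cross-correlation calculation should
  recover.
* :func:`make_planted_path_dimer` builds a two-chain pseudo-atom ensemble in
  which one known residue chain connects a source pocket to a sink pocket
  through side-chain contacts present in an exact, prescribed fraction of
  frames — the ground truth for network construction and path tallying.
* :func:`make_screening_scores` draws active/decoy docking scores from
  shifted Gaussians, for which the expected ROC AUC is the closed form
  Φ(d/√2).
* :func:`make_energy_table` draws per-frame MM-PBSA component energies.

All generators are pure functions of their spec plus a seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .structure_io import (
    AtomRecord,
    Ensemble,
    ENERGY_COLUMNS,
    ResidueSelection,
    TableSchemaError,
)

__all__ = [
    "GnmSpec",
    "PlantedPathSpec",
    "ScoreSimSpec",
    "make_gnm_ensemble",
    "make_planted_path_dimer",
    "make_screening_scores",
    "make_energy_table",
    "default_planted_spec",
    "DisconnectedNetworkError",
    "expected_gaussian_auc",
]

logger = logging.getLogger(__name__)


class DisconnectedNetworkError(ValueError):
    """The GNM contact graph fell apart into components at the given cutoff."""


@dataclass(frozen=True)
class GnmSpec:
    """Parameters of a Gaussian-network-model ensemble.

    ``scale`` multiplies the Kirchhoff pseudo-inverse, setting the mean-square
    fluctuation amplitude (Å² per Cartesian axis).
    """

    n_residues: int = 30
    n_chains: int = 1
    cutoff: float = 7.0
    scale: float = 1.0
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be ≥ 2")
        if self.scale < 0:
            raise ValueError("scale must be ≥ 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.n_chains not in (1, 2):
            raise ValueError("n_chains must be 1 or 2")
        if self.n_residues < 2:
            raise ValueError("n_residues must be ≥ 2")


def _self_avoiding_chain(n: int, rng: np.random.Generator,
                         bond: float = 3.8, clash: float = 3.4,
                         max_tries: int = 200) -> np.ndarray:
    """Grow a self-avoiding pseudo-Cα walk with fixed bond length."""
    pos = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(max_tries):
            step = rng.normal(size=3)
            step *= bond / np.linalg.norm(step)
            cand = pos[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(pos[: i - 1] - cand, axis=1)) >= clash:
                pos[i] = cand
                break
        else:  # pragma: no cover - extremely unlikely with these parameters
            raise RuntimeError("self-avoiding walk failed to place a residue")
    return pos


def kirchhoff_matrix(positions: np.ndarray, cutoff: float) -> np.ndarray:
    """GNM connectivity (Kirchhoff) matrix at a distance cutoff."""
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    contact = (dist <= cutoff) & ~np.eye(len(positions), dtype=bool)
    gamma = -contact.astype(float)
    np.fill_diagonal(gamma, contact.sum(axis=1))
    return gamma


def make_gnm_ensemble(spec: GnmSpec) -> tuple[Ensemble, np.ndarray]:
    """Sample a Cα ensemble from a GNM and return the analytic correlations.

    Frames are drawn (per Cartesian axis, independently) from the zero-mean
    Gaussian with covariance ``scale × pinv(Kirchhoff)`` around a
    self-avoiding mean chain.  Returns ``(ensemble, corr)`` where ``corr`` is
    the analytic residue–residue correlation matrix implied by that
    covariance — the exact expectation of a dynamic cross-correlation map
    computed on infinitely many frames.

    Raises
    ------
    DisconnectedNetworkError
        If the contact graph at ``spec.cutoff`` is not connected (the
        Kirchhoff matrix then has more than one rigid zero mode).
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_frames = (np.random.default_rng(s) for s in ss.spawn(2))

    n_total = spec.n_residues * spec.n_chains
    mean = _self_avoiding_chain(n_total, rng_geom)

    gamma = kirchhoff_matrix(mean, spec.cutoff)
    evals, evecs = np.linalg.eigh(gamma)
    # a connected graph has exactly one zero eigenvalue (the rigid mode)
    tol = max(1e-9, 1e-9 * evals[-1])
    n_zero = int(np.sum(evals < tol))
    if n_zero > 1:
        raise DisconnectedNetworkError(
            f"contact graph at cutoff {spec.cutoff} Å has {n_zero} zero modes; "
            "increase the cutoff so the chain stays connected")
    inv = np.zeros_like(evals)
    inv[n_zero:] = 1.0 / evals[n_zero:]
    cov = spec.scale * (evecs * inv) @ evecs.T

    d = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(d, d)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)

    if spec.scale == 0:
        frames = np.repeat(mean[None], spec.n_frames, axis=0)
    else:
        # sample via the spectral square root, once per Cartesian axis
        root = evecs[:, n_zero:] * np.sqrt(spec.scale * inv[n_zero:])
        z = rng_frames.standard_normal((spec.n_frames, 3, root.shape[1]))
        frames = mean[None] + np.einsum("nr,fxr->fnx", root, z)

    topology = []
    for i in range(n_total):
        chain = "A" if i < spec.n_residues else "B"
        resnum = i + 1 if i < spec.n_residues else i - spec.n_residues + 1
        topology.append(AtomRecord(serial=i + 1, atom_name="CA", element="C",
                                   residue_name="ALA", chain_id=chain,
                                   residue_number=resnum))
    return Ensemble(topology, frames), corr


# ---------------------------------------------------------------------------
# Planted-path dimer


@dataclass(frozen=True)
class PlantedPathSpec:
    """A two-chain ensemble with one known source→sink communication path.

    ``planted_chain`` lists the residues of the path in order; its endpoints
    must lie in the source and sink pockets.  ``persistence`` is the exact
    fraction of frames in which every planted side-chain contact is within
    the network distance cutoff (the whole path switches together, so the
    path's tallied frequency equals the persistence).  ``decoy_density`` adds
    persistent contacts among filler residues, as edges per residue; decoys
    never touch the pockets or the planted chain, so the planted path is the
    unique source→sink route.
    """

    source_pocket: ResidueSelection
    sink_pocket: ResidueSelection
    planted_chain: tuple
    persistence: float = 1.0
    decoy_density: float = 0.15
    n_filler: int = 12

    def __post_init__(self) -> None:
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must lie in [0, 1]")
        if len(self.planted_chain) < 2:
            raise ValueError("planted_chain needs at least source and sink residues")
        src = {(c, n) for c, n, _ in self.source_pocket.entries}
        snk = {(c, n) for c, n, _ in self.sink_pocket.entries}
        first, last = self.planted_chain[0], self.planted_chain[-1]
        if tuple(first) not in src:
            raise ValueError(f"planted chain start {first} is not in the source pocket")
        if tuple(last) not in snk:
            raise ValueError(f"planted chain end {last} is not in the sink pocket")
        for (c1, n1), (c2, n2) in zip(self.planted_chain, self.planted_chain[1:]):
            if c1 == c2 and abs(n1 - n2) == 1:
                raise ValueError(
                    f"planted residues {c1}{n1}-{c2}{n2} are sequence-adjacent; "
                    "such contacts are excluded from networks by default")


def default_planted_spec(persistence: float = 1.0,
                         decoy_density: float = 0.15) -> PlantedPathSpec:
    """A dimer spec emulating an interface-pocket → orthosteric-pocket path.

    The source pocket sits on the dimer-interface side of chain A, the sink
    pocket on the same chain's ligand-binding side, and the planted chain
    threads six non-sequence-adjacent residues between them.
    """
    source = ResidueSelection([("A", 195, None), ("A", 198, None), ("A", 199, None)],
                              label="interface_pocket")
    sink = ResidueSelection([("A", 25, None), ("A", 28, None), ("A", 30, None)],
                            label="orthosteric_A")
    chain = (("A", 195), ("A", 190), ("A", 196), ("A", 200), ("A", 262), ("A", 28))
    return PlantedPathSpec(source_pocket=source, sink_pocket=sink,
                           planted_chain=chain, persistence=persistence,
                           decoy_density=decoy_density)


# geometric constants of the planted construction (Å)
_SPACING = 9.0          # base distance between contacting residues
_COMPONENT_GAP = 30.0   # separation between unrelated contact components
_TIP_ON = (2.6, 3.0)    # side-chain extension in contact ("on") frames
_TIP_OFF = (0.9, 1.3)   # retracted extension in "off" frames
_JITTER_SD = 0.05       # per-atom thermal jitter
_COHERENT_SD = 0.3      # shared displacement of planted residues per frame


def make_planted_path_dimer(spec: PlantedPathSpec, n_frames: int,
                            seed: int = 0) -> tuple[Ensemble, dict]:
    """Build the planted-path dimer ensemble.

    Returns ``(ensemble, truth)`` where ``truth`` records the planted residue
    sequence, the exact on-frame fraction, and the contact guarantees
    (every planted edge has ≥ 3 side-chain pseudo-atom pairs within 4.5 Å in
    "on" frames and none within cutoff in "off" frames).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be ≥ 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    planted = [tuple(r) for r in spec.planted_chain]
    pocket_res = ([(c, n) for c, n, _ in spec.source_pocket.entries]
                  + [(c, n) for c, n, _ in spec.sink_pocket.entries])
    filler = [("A", 500 + 2 * i) for i in range(spec.n_filler)] \
        + [("B", 500 + 2 * i) for i in range(spec.n_filler)]

    residues: list[tuple[str, int]] = []
    for r in planted + pocket_res + filler:
        if r not in residues:
            residues.append(r)

    n_decoy_edges = int(round(spec.decoy_density * len(residues)))
    free = [r for r in filler if r not in planted and r not in pocket_res]
    rng.shuffle(free)
    decoy_pairs = []
    while len(decoy_pairs) < n_decoy_edges and len(free) >= 2:
        decoy_pairs.append((free.pop(), free.pop()))

    # components: the planted path, each decoy pair, each remaining singleton
    components: list[list[tuple[str, int]]] = [list(planted)]
    components += [list(p) for p in decoy_pairs]
    in_component = {r for comp in components for r in comp}
    components += [[r] for r in residues if r not in in_component]

    base: dict[tuple[str, int], np.ndarray] = {}
    directions: dict[tuple[str, int], list[int]] = {r: [] for r in residues}
    always_on: set[tuple[tuple[str, int], int]] = set()
    for ci, comp in enumerate(components):
        for xi, r in enumerate(comp):
            base[r] = np.array([xi * _SPACING, ci * _COMPONENT_GAP, 0.0])
            if xi > 0:
                directions[r].append(-1)
            if xi < len(comp) - 1:
                directions[r].append(+1)
        if ci > 0 and len(comp) == 2:   # decoy contacts persist in every frame
            for r in comp:
                always_on.update((r, d) for d in directions[r])

    # topology: backbone N/CA/C/O plus 2 side-chain pseudo-atoms per contact
    # direction (3 when the residue has at most one direction)
    topology: list[AtomRecord] = []
    sidechain_slots: list[tuple[tuple[str, int], int, int]] = []  # (res, dir, rank)
    serial = 1

    def _add(r, name, element="C"):
        nonlocal serial
        chain, resnum = r
        topology.append(AtomRecord(serial=serial, atom_name=name, element=element,
                                   residue_name="ALA", chain_id=chain,
                                   residue_number=resnum))
        serial += 1

    backbone_offsets = {"N": np.array([-0.6, 0.0, 1.0]),
                        "CA": np.array([0.0, 0.0, 0.0]),
                        "C": np.array([0.6, 0.0, 1.0]),
                        "O": np.array([0.6, 0.0, 2.2])}
    sc_names = ("CB", "CG", "CD")
    for r in residues:
        for name in ("N", "CA", "C", "O"):
            _add(r, name, "N" if name == "N" else "O" if name == "O" else "C")
        dirs = directions[r]
        slots: list[tuple[int, int]] = []
        if not dirs:
            slots = [(0, 0), (0, 1), (0, 2)]       # inert stub pointing +z
        elif len(dirs) == 1:
            slots = [(dirs[0], 0), (dirs[0], 1), (dirs[0], 2)]
        else:
            slots = [(dirs[0], 0), (dirs[0], 1), (dirs[1], 0), (dirs[1], 1)]
        for k, (d, rank) in enumerate(slots):
            name = (sc_names + ("CE",))[k]
            _add(r, name)
            sidechain_slots.append((r, d, rank))

    atom_res = []
    for rec in topology:
        atom_res.append((rec.chain_id, rec.residue_number))

    n_on = int(round(spec.persistence * n_frames))
    on_frames = np.zeros(n_frames, dtype=bool)
    on_frames[rng.permutation(n_frames)[:n_on]] = True

    planted_set = set(planted)
    planted_atoms = np.array([ar in planted_set for ar in atom_res])

    def _sidechain_offset(d: int, rank: int, on: bool) -> np.ndarray:
        if d == 0:
            return np.array([0.0, 0.0, 1.5 + rank])
        ext = (_TIP_ON if on else _TIP_OFF) + (2.8,)
        z = (0.0, 0.3, 0.6)
        return np.array([d * ext[rank], 0.0, z[rank]])

    coords = np.empty((n_frames, len(topology), 3))
    for f in range(n_frames):
        xyz = np.empty((len(topology), 3))
        ai = 0
        si = 0
        for r in residues:
            b = base[r]
            for name in ("N", "CA", "C", "O"):
                xyz[ai] = b + backbone_offsets[name]
                ai += 1
            n_slots = 3 if len(directions[r]) <= 1 else 4
            for _ in range(n_slots):
                rr, d, rank = sidechain_slots[si]
                on = on_frames[f] if (rr in planted_set and d != 0) else True
                if (rr, d) in always_on:
                    on = True
                xyz[ai] = b + _sidechain_offset(d, rank, on)
                ai += 1
                si += 1
        xyz += rng.normal(scale=_JITTER_SD, size=xyz.shape)
        xyz[planted_atoms] += rng.normal(scale=_COHERENT_SD, size=3)
        coords[f] = xyz

    ensemble = Ensemble(topology, coords)
    truth = {
        "planted_path": [f"{c}:{n}" for c, n in planted],
        "planted_path_keys": [(c, n, "") for c, n in planted],
        "persistence_requested": spec.persistence,
        "persistence_exact": n_on / n_frames,
        "on_frames": np.flatnonzero(on_frames).tolist(),
        "contact_cutoff": 4.5,
        "min_contact_pairs": 3,
        "decoy_pairs": [[f"{c}:{n}" for c, n in p] for p in decoy_pairs],
        "source_pocket": [f"{c}:{n}" for c, n, _ in spec.source_pocket.entries],
        "sink_pocket": [f"{c}:{n}" for c, n, _ in spec.sink_pocket.entries],
    }
    return ensemble, truth


# ---------------------------------------------------------------------------
# Screening scores and energy tables


@dataclass(frozen=True)
class ScoreSimSpec:
    """Active/decoy score simulation with closed-form expected AUC.

    Decoy scores are N(0, 1); active scores are N(−d, 1) under the
    lower-is-better docking convention, so the probability that a random
    active outranks a random decoy — the expected AUC — is Φ(d/√2).
    """

    n_active: int = 40
    n_decoy: int = 1440
    effect_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_decoy < 1:
            raise ValueError("need at least one active and one decoy")

    @property
    def expected_auc(self) -> float:
        return expected_gaussian_auc(self.effect_size)


def expected_gaussian_auc(d: float) -> float:
    """Expected AUC for unit-variance Gaussian scores separated by ``d``."""
    return float(norm.cdf(d / math.sqrt(2.0)))


def make_screening_scores(spec: ScoreSimSpec) -> pd.DataFrame:
    """Draw a seeded active/decoy score table (lower score = better).

    The returned frame carries ``attrs["expected_auc"]`` with the analytic
    ground truth Φ(d/√2).  A negative effect size (anti-enrichment) is
    allowed but logged.
    """
    if spec.effect_size < 0:
        logger.warning("effect size %g < 0: actives score worse than decoys "
                       "(expected AUC %.3f)", spec.effect_size, spec.expected_auc)
    rng = np.random.default_rng(spec.seed)
    active = rng.normal(loc=-spec.effect_size, scale=1.0, size=spec.n_active)
    decoy = rng.normal(loc=0.0, scale=1.0, size=spec.n_decoy)
    df = pd.DataFrame({
        "ligand_id": [f"act_{i:05d}" for i in range(spec.n_active)]
                     + [f"dec_{i:05d}" for i in range(spec.n_decoy)],
        "score": np.concatenate([active, decoy]),
        "label": ["active"] * spec.n_active + ["decoy"] * spec.n_decoy,
    })
    df.attrs["expected_auc"] = spec.expected_auc
    return df


def make_energy_table(n_frames: int, means: dict[str, float],
                      sds: dict[str, float] | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Draw a per-frame MM-PBSA component table from Gaussians.

    ``means``/``sds`` are keyed by component name; unnamed components default
    to 0 mean and 0 sd.  Unknown component names raise a schema error.
    """
    sds = dict(sds or {})
    for name in list(means) + list(sds):
        if name not in ENERGY_COLUMNS:
            raise TableSchemaError(
                f"unknown energy component {name!r}; expected one of {ENERGY_COLUMNS}")
    if any(s < 0 for s in sds.values()):
        raise ValueError("standard deviations must be ≥ 0")
    if n_frames < 1:
        raise ValueError("n_frames must be ≥ 1")
    rng = np.random.default_rng(seed)
    data = {}
    for col in ENERGY_COLUMNS:
        mu = float(means.get(col, 0.0))
        sd = float(sds.get(col, 0.0))
        data[col] = mu + sd * rng.standard_normal(n_frames) if sd > 0 \
            else np.full(n_frames, mu)
    return pd.DataFrame(data)
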