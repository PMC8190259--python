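"""Coarse-grained representation and Bayesian crosslink scoring.

A complex is represented as beads: residues resolved in a crystal structure
become one-residue beads constrained into rigid bodies; unresolved regions
become flexible chains of multi-residue beads (default 20 aa per bead).
Models are ranked by a score that is the negative logarithm of
likelihood x priors: the likelihood is a sigmoidal forward model of
crosslink formation given the model distance, mixed with a per-class
false-positive rate psi; the priors penalize broken sequence connectivity
and excluded-volume overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ms_filters import WeightedCrossLink
from .seqchem import ResidueRangeSet

__all__ = [
    "RepresentationConfig",
    "CoarseGrainedSystem",
    "NuisanceParameters",
    "ScoreBreakdown",
    "ForwardModel",
    "build_representation",
    "system_from_truth",
    "crosslink_loglik",
    "prior_score",
    "total_score",
]

RIGID_BEAD_RADIUS = 2.3  # Å, one-residue bead
FLEX_BEAD_SIZE = 20  # residues per flexible bead
CONNECTIVITY_SLACK = 4.0  # Å per sqrt(residues spanned), added to the bond cap
EXCLUDED_VOLUME_K = 1.0  # score units / Å^2
CONNECTIVITY_K = 1.0  # score units / Å^2


@dataclass(frozen=True)
class ForwardModel:
    """Sigmoidal crosslink formation probability f(d) = 1/(1+exp((d-d0)/lam)).

    d0 defaults to 25 Å — the Cα–Cα reach of a BS3 crosslinker (11.4 Å
    spacer plus two lysine side chains); lam sets the switching width and
    absorbs the positional uncertainty sigma.
    """

    d0: float = 25.0
    lam: float = 2.5

    def __call__(self, d: np.ndarray | float) -> np.ndarray | float:
        return 1.0 / (1.0 + np.exp((np.asarray(d, dtype=float) - self.d0) / self.lam))


@dataclass(frozen=True)
class NuisanceParameters:
    """Noise-model parameters: per-ld-class false-positive rate and sigma.

    ``psi[c]`` is the prior probability that a class-c crosslink is spurious;
    higher-confidence classes get lower psi. ``sigma`` (Å) is positional
    uncertainty; by default it is folded into the forward-model width.
    """

    psi: tuple[float, ...] = (0.30, 0.10, 0.05)
    sigma: float = 2.5

    def __post_init__(self) -> None:
        if not all(0.0 < p < 1.0 for p in self.psi):
            raise ValueError("psi values must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def psi_for_class(self, ld_class: int) -> float:
        return self.psi[min(max(ld_class, 0), len(self.psi) - 1)]


@dataclass
class RepresentationConfig:
    """Where each protein's rigid and flexible parts come from.

    ``rigid_sources`` maps protein -> list of (structure_path, chain,
    residue range or None); ``flexible_regions`` maps protein ->
    ResidueRangeSet of residues absent from the structures; ``fixed_proteins``
    names proteins whose rigid body stays put during sampling (the alignment
    reference). ``conjugation_edges`` lists extra bond-like edges, e.g. the
    triazole tether between the ubiquitin C-terminus and its acceptor lysine.
    """

    rigid_sources: dict[str, list[tuple[str, str, tuple[int, int] | None]]] = field(
        default_factory=dict
    )
    flexible_regions: dict[str, ResidueRangeSet] = field(default_factory=dict)
    flexible_bead_size: int = FLEX_BEAD_SIZE
    fixed_proteins: tuple[str, ...] = ()
    conjugation_edges: tuple[tuple[str, int, str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.flexible_bead_size < 1:
            raise ValueError("flexible bead size must be >= 1")


@dataclass
class CoarseGrainedSystem:
    """Bead model with rigid-body, chain-topology and mobility bookkeeping.

    Arrays are parallel over beads: ``coords`` (n, 3) Å, ``radii`` (n,),
    ``proteins`` (n,) object, ``res_start``/``res_end`` (n,) 1-based
    inclusive. ``rigid_bodies`` are disjoint index arrays; ``fixed_bodies``
    flags bodies excluded from rigid-body moves. ``topology`` lists
    (i, j, n_res_spanned) adjacency edges, including rigid-flexible
    junctions and any conjugation tether.
    """

    coords: np.ndarray
    radii: np.ndarray
    proteins: np.ndarray
    res_start: np.ndarray
    res_end: np.ndarray
    rigid_bodies: list[np.ndarray]
    fixed_bodies: list[bool]
    topology: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        if not (len(self.radii) == len(self.proteins) == len(self.res_start) == len(self.res_end) == n):
            raise ValueError("bead arrays must be parallel")
        seen: set[int] = set()
        for body in self.rigid_bodies:
            overlap = seen.intersection(body.tolist())
            if overlap:
                raise ValueError(f"bead(s) {sorted(overlap)} in more than one rigid body")
            seen.update(body.tolist())

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def copy(self) -> "CoarseGrainedSystem":
        return CoarseGrainedSystem(
            coords=self.coords.copy(),
            radii=self.radii,
            proteins=self.proteins,
            res_start=self.res_start,
            res_end=self.res_end,
            rigid_bodies=self.rigid_bodies,
            fixed_bodies=self.fixed_bodies,
            topology=self.topology,
        )

    def flexible_beads(self) -> np.ndarray:
        """Indices of beads not in any rigid body (moved individually)."""
        in_rigid = np.zeros(self.n_beads, dtype=bool)
        for body in self.rigid_bodies:
            in_rigid[body] = True
        return np.nonzero(~in_rigid)[0]

    def mobile_bodies(self) -> list[np.ndarray]:
        return [b for b, fixed in zip(self.rigid_bodies, self.fixed_bodies) if not fixed]

    def bead_for_residue(self, protein: str, residue: int) -> int:
        hits = np.nonzero(
            (self.proteins == protein)
            & (self.res_start <= residue)
            & (self.res_end >= residue)
        )[0]
        if hits.size == 0:
            raise KeyError(f"residue {protein}:{residue} maps to no bead")
        return int(hits[0])

    def protein_beads(self, protein: str) -> np.ndarray:
        return np.nonzero(self.proteins == protein)[0]

    def nonbonded_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle pairs excluding bonded pairs and intra-rigid pairs."""
        n = self.n_beads
        exclude = np.zeros((n, n), dtype=bool)
        for i, j, _ in self.topology:
            exclude[i, j] = exclude[j, i] = True
        for body in self.rigid_bodies:
            exclude[np.ix_(body, body)] = True
        iu, ju = np.triu_indices(n, k=1)
        keep = ~exclude[iu, ju]
        return iu[keep], ju[keep]


def _flex_bead_radius(n_res: int) -> float:
    # volume-equivalent scaling from the one-residue bead
    return RIGID_BEAD_RADIUS * float(n_res) ** (1.0 / 3.0)


def _read_ca_coords(path: str, chains: Sequence[str], res_range: tuple[int, int] | None):
    """Extract Cα coordinates per residue from a PDB file (first MODEL only)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1)
    ca = atoms[(atoms.atom_name == "CA") & np.isin(atoms.chain_id, list(chains))]
    out: dict[int, np.ndarray] = {}
    for i in range(ca.array_length()):
        res_id = int(ca.res_id[i])
        if res_range is not None and not (res_range[0] <= res_id <= res_range[1]):
            continue
        out.setdefault(res_id, ca.coord[i])
    return out


def build_representation(
    config: RepresentationConfig,
    sequences: dict[str, str] | dict[str, int] | None = None,
    structures: dict[str, dict[int, np.ndarray]] | None = None,
) -> CoarseGrainedSystem:
    """Build the bead system from structures plus flexible-region definitions.

    ``structures`` may pre-supply per-protein {residue: Cα xyz} maps (used in
    tests and synthetic runs); otherwise they are read from the PDB files
    named in ``config.rigid_sources``. Rigid beads sit at Cα positions;
    each flexible region of length L becomes ceil(L / bead_size) beads laid
    out on a line extending from the nearest rigid bead of the same protein
    (or the origin if the protein has no rigid part).
    """
    coords: list[np.ndarray] = []
    radii: list[float] = []
    proteins: list[str] = []
    res_start: list[int] = []
    res_end: list[int] = []
    rigid_bodies: list[np.ndarray] = []
    fixed_bodies: list[bool] = []

    all_proteins = sorted(
        set(config.rigid_sources)
        | set(config.flexible_regions)
        | (set(structures) if structures is not None else set())
    )
    per_protein_rigid: dict[str, dict[int, np.ndarray]] = {}
    for prot in all_proteins:
        res_map: dict[int, np.ndarray] = {}
        if structures is not None and prot in structures:
            res_map = dict(structures[prot])
        elif prot in config.rigid_sources:
            for path, chain, rng in config.rigid_sources[prot]:
                got = _read_ca_coords(path, [chain], rng)
                missing = [] if rng is None else [
                    r for r in range(rng[0], rng[1] + 1) if r not in got
                ]
                if rng is not None and len(missing) == rng[1] - rng[0] + 1:
                    raise ValueError(
                        f"build error: residues {rng} of {prot} absent from {path} chain {chain}"
                    )
                res_map.update(got)
        per_protein_rigid[prot] = res_map

    for prot in all_proteins:
        res_map = per_protein_rigid[prot]
        body_idx: list[int] = []
        for res_id in sorted(res_map):
            body_idx.append(len(coords))
            coords.append(np.asarray(res_map[res_id], dtype=float))
            radii.append(RIGID_BEAD_RADIUS)
            proteins.append(prot)
            res_start.append(res_id)
            res_end.append(res_id)
        if body_idx:
            rigid_bodies.append(np.asarray(body_idx, dtype=int))
            fixed_bodies.append(prot in config.fixed_proteins)

        flex = config.flexible_regions.get(prot)
        if flex is not None:
            anchor = (
                np.mean([res_map[r] for r in res_map], axis=0)
                if res_map
                else np.zeros(3)
            )
            for start, end in flex.intervals:
                overlap = [r for r in range(start, end + 1) if r in res_map]
                if overlap:
                    raise ValueError(
                        f"flexible region {start}-{end} of {prot} overlaps rigid residues"
                    )
                length = end - start + 1
                n_beads = -(-length // config.flexible_bead_size)
                for b in range(n_beads):
                    s = start + b * config.flexible_bead_size
                    e = min(start + (b + 1) * config.flexible_bead_size - 1, end)
                    r = _flex_bead_radius(e - s + 1)
                    # initial chain extending outward from the rigid anchor
                    offset = np.array([0.0, 0.0, (b + 1) * 2 * r])
                    coords.append(anchor + offset + np.array([len(rigid_bodies) * 1.0, 0, 0]))
                    radii.append(r)
                    proteins.append(prot)
                    res_start.append(s)
                    res_end.append(e)

    system = CoarseGrainedSystem(
        coords=np.asarray(coords, dtype=float),
        radii=np.asarray(radii, dtype=float),
        proteins=np.asarray(proteins, dtype=object),
        res_start=np.asarray(res_start, dtype=int),
        res_end=np.asarray(res_end, dtype=int),
        rigid_bodies=rigid_bodies,
        fixed_bodies=fixed_bodies,
        topology=[],
    )
    system.topology = _build_topology(system, config)
    return system


def _build_topology(
    system: CoarseGrainedSystem, config: RepresentationConfig
) -> list[tuple[int, int, int]]:
    """Sequence-adjacency edges per protein plus conjugation tethers."""
    edges: list[tuple[int, int, int]] = []
    for prot in np.unique(system.proteins):
        idx = system.protein_beads(str(prot))
        order = idx[np.argsort(system.res_start[idx], kind="stable")]
        for a, b in zip(order[:-1], order[1:]):
            gap = int(system.res_start[b] - system.res_end[a])
            if gap == 1:  # sequence-adjacent (covers rigid-flexible junctions)
                span = int(
                    (system.res_end[a] - system.res_start[a] + 1)
                    + (system.res_end[b] - system.res_start[b] + 1)
                ) // 2
                edges.append((int(a), int(b), max(span, 1)))
    for prot_a, res_a, prot_b, res_b in config.conjugation_edges:
        i = system.bead_for_residue(prot_a, res_a)
        j = system.bead_for_residue(prot_b, res_b)
        edges.append((i, j, 1))
    return edges


def system_from_truth(
    truth,
    fixed: Sequence[str] = ("body0",),
    randomize: np.random.Generator | None = None,
    init_radius: float | None = None,
) -> CoarseGrainedSystem:
    """Build a rigid-bodies-only system from a GroundTruthSystem.

    Bodies named in ``fixed`` keep their true pose and are flagged fixed;
    the others are optionally re-placed at a uniform random orientation and
    position within a bounding sphere (1.5x the system diameter by default)
    to start sampling from a random configuration.
    """
    coords: list[np.ndarray] = []
    radii: list[float] = []
    proteins: list[str] = []
    res_start: list[int] = []
    res_end: list[int] = []
    rigid_bodies: list[np.ndarray] = []
    fixed_bodies: list[bool] = []
    all_xyz = truth.coords()
    diameter = float(np.max(np.linalg.norm(all_xyz - all_xyz.mean(axis=0), axis=1))) * 2
    bound = init_radius if init_radius is not None else 0.75 * 1.5 * diameter
    center = all_xyz.mean(axis=0)
    for name, xyz in truth.bodies.items():
        xyz = np.asarray(xyz, dtype=float)
        if randomize is not None and name not in fixed:
            from .sampler import random_rotation_matrix

            rot = random_rotation_matrix(randomize, np.pi)
            local = xyz - xyz.mean(axis=0)
            shift = center + randomize.uniform(-bound, bound, size=3)
            xyz = local @ rot.T + shift
        idx = list(range(len(coords), len(coords) + len(xyz)))
        coords.extend(xyz)
        radii.extend([truth.bead_radius] * len(xyz))
        proteins.extend([name] * len(xyz))
        res_start.extend(range(1, len(xyz) + 1))
        res_end.extend(range(1, len(xyz) + 1))
        rigid_bodies.append(np.asarray(idx, dtype=int))
        fixed_bodies.append(name in fixed)
    return CoarseGrainedSystem(
        coords=np.asarray(coords, dtype=float),
        radii=np.asarray(radii, dtype=float),
        proteins=np.asarray(proteins, dtype=object),
        res_start=np.asarray(res_start, dtype=int),
        res_end=np.asarray(res_end, dtype=int),
        rigid_bodies=rigid_bodies,
        fixed_bodies=fixed_bodies,
        topology=[],
    )


@dataclass(frozen=True)
class ScoreBreakdown:
    """Total score and its components on the -log scale."""

    total: float
    crosslink_loglik: float
    connectivity: float
    excluded_volume: float


def crosslink_loglik(
    system: CoarseGrainedSystem,
    links: Iterable[WeightedCrossLink],
    nuisance: NuisanceParameters = NuisanceParameters(),
    forward: ForwardModel = ForwardModel(),
    coords: np.ndarray | None = None,
) -> float:
    """Sum over links of weight * log[psi_c + (1 - psi_c) f(d)].

    ``coords`` may override the system coordinates (same bead order) so the
    sampler can score proposals without mutating the system.
    """
    xyz = system.coords if coords is None else coords
    total = 0.0
    for link in links:
        try:
            i = system.bead_for_residue(link.protein_a, link.residue_a)
            j = system.bead_for_residue(link.protein_b, link.residue_b)
        except KeyError as err:
            raise KeyError(f"crosslink {link} has an unmapped residue") from err
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        psi = nuisance.psi_for_class(link.ld_class)
        total += link.weight * float(np.log(psi + (1.0 - psi) * forward(d)))
    return total


def prior_score(
    system: CoarseGrainedSystem, coords: np.ndarray | None = None
) -> tuple[float, float]:
    """Connectivity and excluded-volume penalty terms (both >= 0).

    Connectivity: upper-harmonic k (d - cap)^2 for sequence-adjacent bead
    pairs beyond cap = r_i + r_j + 4 sqrt(residues spanned). Excluded
    volume: soft-sphere k (r_i + r_j - d)^2 for overlapping non-bonded
    pairs outside rigid bodies.
    """
    xyz = system.coords if coords is None else coords
    conn = 0.0
    for i, j, span in system.topology:
        cap = system.radii[i] + system.radii[j] + CONNECTIVITY_SLACK * np.sqrt(span)
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if d > cap:
            conn += CONNECTIVITY_K * (d - cap) ** 2
    iu, ju = system.nonbonded_pairs()
    if iu.size:
        d = np.linalg.norm(xyz[iu] - xyz[ju], axis=1)
        overlap = system.radii[iu] + system.radii[ju] - d
        ev = float(EXCLUDED_VOLUME_K * np.sum(np.clip(overlap, 0.0, None) ** 2))
    else:
        ev = 0.0
    return conn, ev


def total_score(
    system: CoarseGrainedSystem,
    links: Iterable[WeightedCrossLink],
    nuisance: NuisanceParameters = NuisanceParameters(),
    forward: ForwardModel = ForwardModel(),
    coords: np.ndarray | None = None,
) -> ScoreBreakdown:
    """Total score = -crosslink log-likelihood + connectivity + excluded volume."""
    loglik = crosslink_loglik(system, links, nuisance, forward, coords=coords)
    conn, ev = prior_score(system, coords=coords)
    return ScoreBreakdown(
        total=-loglik + conn + ev,
        crosslink_loglik=loglik,
        connectivity=conn,
        excluded_volume=ev,
    )
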