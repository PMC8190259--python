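"""Replica-exchange Metropolis Monte Carlo over rigid bodies and flexible beads.

Moves are random translations (uniform direction, magnitude uniform up to a
maximum of 10 Å) and rotations about a random axis through the body centroid
(angle uniform up to 1 radian) for mobile rigid bodies, and individual
translations for flexible beads. Replicas run at a geometric temperature
ladder between t_min and t_max (technical units) and attempt
adjacent-temperature swaps with the standard exchange criterion every
``swap_every`` sweeps. The best-scoring fraction of all frames of a run,
pooled across replicas, is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .cg_model import (
    CONNECTIVITY_K,
    CONNECTIVITY_SLACK,
    EXCLUDED_VOLUME_K,
    CoarseGrainedSystem,
    ForwardModel,
    NuisanceParameters,
)
from .ms_filters import WeightedCrossLink

__all__ = [
    "SamplerConfig",
    "SavedModels",
    "CompiledScore",
    "random_rotation_matrix",
    "mc_sweep",
    "run_replica_exchange",
    "select_best_fraction",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Replica-exchange sampling parameters.

    Defaults are the production protocol: 32 replicas x 15000 frames at
    temperatures 1.0-2.5, rigid-body moves of at most 10 Å / 1 rad, the 25%
    best-scoring frames saved, three independent runs. Scaled-down configs
    (fewer replicas/frames) are used for desk-size problems.
    """

    n_replicas: int = 32
    n_frames: int = 15000
    t_min: float = 1.0
    t_max: float = 2.5
    max_translation: float = 10.0
    max_rotation: float = 1.0
    max_flex_translation: float = 10.0
    save_fraction: float = 0.25
    n_runs: int = 3
    swap_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.save_fraction <= 1.0):
            raise ValueError("save fraction must be in (0, 1]")
        if self.t_min > self.t_max:
            raise ValueError("t_min must be <= t_max")
        if min(self.n_replicas, self.n_frames) < 1:
            raise ValueError("counts must be >= 1")

    def temperatures(self) -> np.ndarray:
        """Geometric ladder from t_min to t_max."""
        if self.n_replicas == 1:
            return np.array([self.t_min])
        return self.t_min * (self.t_max / self.t_min) ** (
            np.arange(self.n_replicas) / (self.n_replicas - 1)
        )


@dataclass
class SavedModels:
    """Retained frames of one or more runs.

    ``coords`` has shape (n_models, n_beads, 3); ``scores`` (n_models,);
    ``replica``, ``frame``, ``run`` identify provenance.
    """

    coords: np.ndarray
    scores: np.ndarray
    replica: np.ndarray
    frame: np.ndarray
    run: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)

    def sorted_by_score(self) -> "SavedModels":
        order = np.lexsort((self.frame, self.replica, self.run, self.scores))
        return SavedModels(
            self.coords[order], self.scores[order],
            self.replica[order], self.frame[order], self.run[order],
        )

    def scores_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"run": self.run, "replica": self.replica, "frame": self.frame, "score": self.scores}
        )

    @staticmethod
    def concatenate(parts: Sequence["SavedModels"]) -> "SavedModels":
        return SavedModels(
            np.concatenate([p.coords for p in parts]),
            np.concatenate([p.scores for p in parts]),
            np.concatenate([p.replica for p in parts]),
            np.concatenate([p.frame for p in parts]),
            np.concatenate([p.run for p in parts]),
        )


class CompiledScore:
    """Vectorized total score bound to one system's topology and links.

    Precomputes link bead indices, bonded-pair caps and the non-bonded pair
    list so that per-proposal evaluation is a handful of NumPy operations.
    Returns the same value as :func:`h1ub.cg_model.total_score` (unit-tested
    against a naive re-implementation).
    """

    def __init__(
        self,
        system: CoarseGrainedSystem,
        links: Iterable[WeightedCrossLink] = (),
        nuisance: NuisanceParameters = NuisanceParameters(),
        forward: ForwardModel = ForwardModel(),
    ):
        self.system = system
        links = list(links)
        self.link_i = np.array(
            [system.bead_for_residue(l.protein_a, l.residue_a) for l in links], dtype=int
        )
        self.link_j = np.array(
            [system.bead_for_residue(l.protein_b, l.residue_b) for l in links], dtype=int
        )
        self.link_w = np.array([l.weight for l in links], dtype=float)
        self.link_psi = np.array(
            [nuisance.psi_for_class(l.ld_class) for l in links], dtype=float
        )
        self.forward = forward
        topo = system.topology
        self.bond_i = np.array([t[0] for t in topo], dtype=int)
        self.bond_j = np.array([t[1] for t in topo], dtype=int)
        self.bond_cap = np.array(
            [
                system.radii[i] + system.radii[j] + CONNECTIVITY_SLACK * np.sqrt(span)
                for i, j, span in topo
            ],
            dtype=float,
        )
        self.nb_i, self.nb_j = system.nonbonded_pairs()
        self.nb_sumr = system.radii[self.nb_i] + system.radii[self.nb_j]

    def __call__(self, coords: np.ndarray) -> float:
        total = 0.0
        if self.link_i.size:
            d = np.linalg.norm(coords[self.link_i] - coords[self.link_j], axis=1)
            f = self.forward(d)
            total -= float(
                np.sum(self.link_w * np.log(self.link_psi + (1.0 - self.link_psi) * f))
            )
        if self.bond_i.size:
            d = np.linalg.norm(coords[self.bond_i] - coords[self.bond_j], axis=1)
            total += float(CONNECTIVITY_K * np.sum(np.clip(d - self.bond_cap, 0.0, None) ** 2))
        if self.nb_i.size:
            d = np.linalg.norm(coords[self.nb_i] - coords[self.nb_j], axis=1)
            total += float(EXCLUDED_VOLUME_K * np.sum(np.clip(self.nb_sumr - d, 0.0, None) ** 2))
        return total


def random_rotation_matrix(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    """Rotation about a uniform random axis by an angle uniform in [0, max]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _random_translation(rng: np.random.Generator, max_dist: float) -> np.ndarray:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return direction * rng.uniform(0.0, max_dist)


def mc_sweep(
    coords: np.ndarray,
    score: Callable[[np.ndarray], float],
    current_score: float,
    system: CoarseGrainedSystem,
    temperature: float,
    rng: np.random.Generator,
    config: SamplerConfig = SamplerConfig(),
) -> tuple[np.ndarray, float, int, int]:
    """One Metropolis sweep: a proposal per mobile rigid body and flexible bead.

    Returns (coords, score, n_accepted, n_proposed). Proposals with
    non-positive score change are always accepted; otherwise acceptance is
    exp(-delta/T). Fixed bodies are never moved.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    accepted = proposed = 0
    for body in system.mobile_bodies():
        proposal = coords.copy()
        sub = proposal[body]
        centroid = sub.mean(axis=0)
        rot = random_rotation_matrix(rng, config.max_rotation)
        proposal[body] = (sub - centroid) @ rot.T + centroid + _random_translation(
            rng, config.max_translation
        )
        new_score = score(proposal)
        if not np.isfinite(new_score):
            raise FloatingPointError("non-finite score encountered during sampling")
        proposed += 1
        delta = new_score - current_score
        if delta <= 0 or rng.random() < np.exp(-delta / temperature):
            coords, current_score = proposal, new_score
            accepted += 1
    for bead in system.flexible_beads():
        proposal = coords.copy()
        proposal[bead] = proposal[bead] + _random_translation(rng, config.max_flex_translation)
        new_score = score(proposal)
        if not np.isfinite(new_score):
            raise FloatingPointError("non-finite score encountered during sampling")
        proposed += 1
        delta = new_score - current_score
        if delta <= 0 or rng.random() < np.exp(-delta / temperature):
            coords, current_score = proposal, new_score
            accepted += 1
    return coords, current_score, accepted, proposed


def run_replica_exchange(
    system: CoarseGrainedSystem,
    score: Callable[[np.ndarray], float],
    config: SamplerConfig,
    run_id: int = 0,
    rng: np.random.Generator | None = None,
) -> SavedModels:
    """One replica-exchange run; returns the best save_fraction of all frames.

    Each replica carries an independent RNG stream spawned from the master
    seed (plus the run id), performs ``n_frames`` sweeps at its ladder
    temperature, and every ``swap_every`` sweeps a random adjacent pair
    attempts a configuration swap with acceptance
    min(1, exp((1/T_i - 1/T_j)(S_i - S_j))). Frames are recorded after every
    sweep; retention is pooled across replicas (per the production
    bookkeeping: 0.25 x 32 x 15000 = 120000 models per run).
    """
    temperatures = config.temperatures()
    master = (
        rng
        if rng is not None
        else np.random.default_rng(np.random.SeedSequence([config.seed, run_id]))
    )
    streams = master.spawn(config.n_replicas + 1)
    swap_rng = streams[-1]
    states = [system.coords.copy() for _ in range(config.n_replicas)]
    scores = [float(score(c)) for c in states]

    n_total = config.n_frames * config.n_replicas
    n_beads = system.n_beads
    frame_coords = np.empty((n_total, n_beads, 3), dtype=np.float32)
    frame_scores = np.empty(n_total, dtype=float)
    frame_replica = np.empty(n_total, dtype=np.int32)
    frame_index = np.empty(n_total, dtype=np.int32)

    pos = 0
    for sweep in range(config.n_frames):
        for r in range(config.n_replicas):
            states[r], scores[r], _, _ = mc_sweep(
                states[r], score, scores[r], system, temperatures[r], streams[r], config
            )
            frame_coords[pos] = states[r]
            frame_scores[pos] = scores[r]
            frame_replica[pos] = r
            frame_index[pos] = sweep
            pos += 1
        if config.n_replicas > 1 and (sweep + 1) % config.swap_every == 0:
            i = int(swap_rng.integers(0, config.n_replicas - 1))
            j = i + 1
            beta_i, beta_j = 1.0 / temperatures[i], 1.0 / temperatures[j]
            log_alpha = (beta_i - beta_j) * (scores[i] - scores[j])
            if log_alpha >= 0 or swap_rng.random() < np.exp(log_alpha):
                states[i], states[j] = states[j], states[i]
                scores[i], scores[j] = scores[j], scores[i]

    frames = SavedModels(
        coords=frame_coords,
        scores=frame_scores,
        replica=frame_replica,
        frame=frame_index,
        run=np.full(n_total, run_id, dtype=np.int32),
    )
    return select_best_fraction(frames, config.save_fraction)


def select_best_fraction(frames: SavedModels, fraction: float) -> SavedModels:
    """Retain the round(fraction * N) lowest-score frames, stable tie-break.

    Ties are broken by (run, replica, frame) order. fraction = 1.0 is the
    identity (up to ordering).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n = len(frames)
    if n == 0:
        return frames
    n_keep = int(round(fraction * n))
    ordered = frames.sorted_by_score()
    return SavedModels(
        ordered.coords[:n_keep].copy(),
        ordered.scores[:n_keep].copy(),
        ordered.replica[:n_keep].copy(),
        ordered.frame[:n_keep].copy(),
        ordered.run[:n_keep].copy(),
    )
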