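"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one experimental input: crosslink identification
tables from a known two-body pose, AP-MS protein-group intensity matrices
with planted enrichment and missing-not-at-random dropout, two-channel
droplet images, FRAP traces with acquisition photobleaching, and
nucleosome-positioning DNA arrays. All generators draw from a single
explicitly seeded NumPy Generator and are bitwise deterministic under a
fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqchem import clean_sequence

__all__ = [
    "GroundTruthSystem",
    "SyntheticSpec",
    "make_toy_complex",
    "simulate_crosslinks",
    "simulate_apms_matrix",
    "simulate_condensate_image",
    "simulate_frap_trace",
    "build_601_array",
    "REPEAT_601_207BP",
    "ATTO390_TEMPLATE",
]

# 207 bp repeat unit of the 12-mer nucleosome-positioning array (based on the
# Widom 601 sequence); contains one PacI site (TTAATTAA) in the linker DNA.
REPEAT_601_207BP = (
    "CTAGTTCGGACCCTATACGCGGCCGCCCTGGAGAATCCCGGTGCCGAGGCCGCTCAATTGGTCGTAGCAAGC"
    "TCTAGCACCGCTTAAACGCACGTACGCGCTGTCCCCCGCGTTTTAACCGCCAAGGGGATTACTCCCTAGTCT"
    "CCAGGCACGTGTCAGATATATACATCCTGTGCATGTGGATCCGAATACATATTAATTAATACG"
)

# 601-derived template amplified with an Atto-390-labeled primer for the
# condensate-formation assays (fixture metadata).
ATTO390_TEMPLATE = (
    "CTATACGCGGCCGCCCTGGAGAATCCCGGTGCCGAGGCCGCTCAATTGGTCGTAGCAAGCTCTAGCACCGCT"
    "TAAACGCACGTACGCGCTGTCCCCCGCGTTTTAACCGCCAAGGGGATTACTCCCTAGTCTCCAGGCACGTGT"
    "CAGATATATACATCCTGTGCATGTGGATCCGAAT"
)


@dataclass
class GroundTruthSystem:
    """A known bead assembly: the reference truth for modeling-stage tests.

    ``bodies`` maps body name -> (n, 3) coordinates in Å, already placed in
    the true pose. ``true_pose`` records the rotation matrix and translation
    applied to each body relative to its local frame. ``linkable_pairs`` is a
    DataFrame of residue pairs with their true inter-bead distance.
    """

    bodies: dict[str, np.ndarray]
    true_pose: dict[str, tuple[np.ndarray, np.ndarray]]
    bead_radius: float = 2.3

    def __post_init__(self) -> None:
        names = list(self.bodies)
        if len(set(names)) != len(names):
            raise ValueError("body names must be unique")
        for name, xyz in self.bodies.items():
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite coordinates in body {name!r}")

    @property
    def body_names(self) -> list[str]:
        return list(self.bodies)

    def coords(self) -> np.ndarray:
        return np.concatenate([self.bodies[n] for n in self.bodies], axis=0)

    def bead_index(self, body: str, residue: int) -> int:
        """Flat bead index of 1-based ``residue`` within ``body``."""
        offset = 0
        for name, xyz in self.bodies.items():
            if name == body:
                if not 1 <= residue <= len(xyz):
                    raise KeyError(f"residue {residue} not in body {body!r}")
                return offset + residue - 1
            offset += len(xyz)
        raise KeyError(f"unknown body {body!r}")

    def linkable_pairs(self, d_max: float) -> pd.DataFrame:
        """All inter-body residue pairs with true distance ≤ ``d_max`` Å."""
        rows = []
        names = list(self.bodies)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                d = np.linalg.norm(
                    self.bodies[a][:, None, :] - self.bodies[b][None, :, :], axis=-1
                )
                ra, rb = np.nonzero(d <= d_max)
                for x, y in zip(ra, rb):
                    rows.append((a, int(x) + 1, b, int(y) + 1, float(d[x, y])))
        return pd.DataFrame(
            rows, columns=["protein_a", "residue_a", "protein_b", "residue_b", "distance"]
        )


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the experimental design: three biological replicates for
    crosslinking, a six-condition AP-MS layout measured as technical
    duplicates (3 biological x 2 technical columns per condition), BS3-scale
    crosslinkable distance, and FRAP kinetics on the seconds scale.
    """

    seed: int = 0
    # crosslink simulation
    noise_rate: float = 0.05
    n_replicates: int = 3
    d_max: float = 25.0
    n_links: int = 100
    replicate_presence: float = 0.9
    ld_true_mean: float = 38.0
    ld_decoy_mean: float = 24.0
    ld_sd: float = 5.0
    # AP-MS matrix
    n_proteins: int = 500
    n_groups: int = 6
    n_biological: int = 3
    n_technical: int = 2
    effect_size_sd: float = 4.0
    enriched_fraction: float = 0.1
    dropout_rate: float = 0.1
    base_mean: float = 25.0
    base_sd: float = 1.0
    # condensate images
    image_shape: tuple[int, int] = (256, 256)
    droplet_intensity: float = 100.0
    background_intensity: float = 10.0
    image_noise_sd: float = 1.0
    # FRAP
    frap_k: float = 0.05
    frap_y_inf: float = 0.8
    frap_y0: float = 0.2
    acq_bleach_rate: float = 0.002
    frap_noise_sd: float = 0.0
    n_prebleach: int = 10
    frap_duration: float = 400.0
    frap_interval: float = 1.0

    def __post_init__(self) -> None:
        for name in ("noise_rate", "replicate_presence", "dropout_rate", "enriched_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size_sd < 0:
            raise ValueError("effect size must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _packed_blob(
    rng: np.random.Generator, n_beads: int, extent: float, bead_radius: float
) -> np.ndarray:
    """Compact non-overlapping bead blob within a sphere, centered at origin."""
    local = np.zeros((n_beads, 3))
    placed = 0
    attempts = 0
    while placed < n_beads:
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError("bead packing failed; extent too small for bead count")
        cand = rng.uniform(-extent, extent, size=3)
        if np.linalg.norm(cand) > extent:
            continue
        if placed and np.min(np.linalg.norm(local[:placed] - cand, axis=1)) < 2 * bead_radius:
            continue
        local[placed] = cand
        placed += 1
    return local - local.mean(axis=0)


def make_toy_complex(
    n_bodies: int = 2,
    beads_per_body: int = 30,
    seed: int = 0,
    bead_radius: float = 2.3,
    receptor_beads: int = 80,
    receptor_radius: float = 26.0,
    contact_gap: float = 0.2,
) -> GroundTruthSystem:
    """Build a receptor-cleft complex in a documented, identifiable pose.

    ``body0`` is a large receptor: beads packed on an open concave shell of
    radius ``receptor_radius`` Å (a binding cleft, open toward +z). Each
    further body is a compact blob of ``beads_per_body`` beads seated inside
    the cleft in van-der-Waals contact with the receptor (lowered along -z
    until the closest inter-body bead gap is ``contact_gap``). This mimics a
    bound protein complex: the docked pose is at steric contact, and
    crosslinkable pairs to anchors spread across the cleft surround the
    mobile body, which is what makes the pose recoverable from distance
    restraints. Deterministic under ``seed``.
    """
    if n_bodies < 2:
        raise ValueError(f"n_bodies must be >= 2, got {n_bodies}")
    if beads_per_body < 1:
        raise ValueError("beads_per_body must be >= 1")
    rng = np.random.default_rng(seed)
    # receptor shell: directions with z <= 0.1 (open top)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < receptor_beads:
        attempts += 1
        if attempts > 500_000:
            raise RuntimeError("receptor packing failed")
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if v[2] > 0.1:
            continue
        p = v * receptor_radius * rng.uniform(0.95, 1.15)
        if pts and np.min(np.linalg.norm(np.asarray(pts) - p, axis=1)) < 2 * bead_radius:
            continue
        pts.append(p)
    receptor = np.asarray(pts)
    bodies: dict[str, np.ndarray] = {"body0": receptor}
    pose: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "body0": (np.eye(3), np.zeros(3))
    }
    # mobile blobs: extent scales with bead count (loose random packing)
    extent = 4.5 * float(beads_per_body) ** (1.0 / 3.0)
    for k in range(1, n_bodies):
        local = _packed_blob(rng, beads_per_body, extent, bead_radius)
        rot = _random_rotation(rng)
        blob = local @ rot.T
        # lateral offset separates multiple mobile bodies within the cleft
        lateral = np.zeros(3)
        if n_bodies > 2:
            angle = 2 * np.pi * (k - 1) / (n_bodies - 1)
            lateral = 0.35 * receptor_radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        blob = blob + lateral
        others = np.concatenate([bodies[name] for name in bodies], axis=0)
        z = 0.0
        while z > -3 * receptor_radius:
            trial = blob + np.array([0.0, 0.0, z - 0.25])
            dmin = np.min(np.linalg.norm(others[:, None] - trial[None], axis=-1))
            if dmin < 2 * bead_radius + contact_gap:
                break
            z -= 0.25
        trans = lateral + np.array([0.0, 0.0, z])
        bodies[f"body{k}"] = blob + np.array([0.0, 0.0, z])
        pose[f"body{k}"] = (rot, trans)
    return GroundTruthSystem(bodies=bodies, true_pose=pose, bead_radius=bead_radius)


def _stratified_pairs(close: pd.DataFrame, n: int, rng: np.random.Generator) -> list[int]:
    """Pick crosslinkable pairs round-robin over mobile residues.

    Real crosslinks come from reactive lysines distributed over the whole
    protein surface; sampling in a round-robin over the mobile-side residue
    reproduces that coverage instead of piling links onto one hotspot.
    """
    groups: dict[int, list[int]] = {}
    for pos, res in zip(range(len(close)), close["residue_b"].to_numpy()):
        groups.setdefault(int(res), []).append(pos)
    keys = list(groups)
    rng.shuffle(keys)
    chosen: list[int] = []
    while len(chosen) < n and keys:
        for key in list(keys):
            if len(chosen) >= n:
                break
            bucket = groups[key]
            if not bucket:
                keys.remove(key)
                continue
            chosen.append(bucket.pop(int(rng.integers(len(bucket)))))
    return chosen


def simulate_crosslinks(truth: GroundTruthSystem, spec: SyntheticSpec) -> pd.DataFrame:
    """Emulate a crosslink-identification table from a known pose.

    True links are drawn from inter-body residue pairs with true distance
    ≤ ``spec.d_max``, stratified across mobile-side residues the way
    reactive lysines cover a protein surface; decoys are drawn uniformly
    from all inter-body pairs. Quality scores separate the two populations:
    true links draw their ld score from N(ld_true_mean, ld_sd), decoys from
    N(ld_decoy_mean, ld_sd), so that threshold filters are exercised.
    Replicate presence is an independent Bernoulli(replicate_presence) draw
    per unique site pair and replicate. The returned table carries a hidden
    ``is_decoy`` truth column.
    """
    if spec.d_max <= 0:
        raise ValueError("d_max must be > 0")
    rng = spec.rng()
    close = truth.linkable_pairs(spec.d_max)
    all_pairs = truth.linkable_pairs(np.inf)
    if close.empty:
        warnings.warn("no residue pair within d_max; returning empty table", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "protein_a", "residue_a", "protein_b", "residue_b",
                "ld_score", "deltaS", "fdr", "replicate", "is_decoy", "distance",
            ]
        )
    n_decoy = int(rng.binomial(spec.n_links, spec.noise_rate))
    n_true = spec.n_links - n_decoy
    rows = []
    chosen_true = _stratified_pairs(close, min(n_true, len(close)), rng)
    chosen_decoy = rng.integers(0, len(all_pairs), size=n_decoy)
    for idx, is_decoy in [(i, False) for i in chosen_true] + [(i, True) for i in chosen_decoy]:
        pair = (all_pairs if is_decoy else close).iloc[idx]
        mean = spec.ld_decoy_mean if is_decoy else spec.ld_true_mean
        for rep in range(1, spec.n_replicates + 1):
            if rng.random() > spec.replicate_presence:
                continue
            rows.append(
                {
                    "protein_a": pair.protein_a,
                    "residue_a": int(pair.residue_a),
                    "protein_b": pair.protein_b,
                    "residue_b": int(pair.residue_b),
                    "ld_score": float(rng.normal(mean, spec.ld_sd)),
                    "deltaS": float(rng.uniform(0.1, 0.9)),
                    "fdr": float(rng.uniform(0.0, 0.04)),
                    "replicate": rep,
                    "is_decoy": bool(is_decoy),
                    "distance": float(pair.distance),
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["link_type"] = np.where(
            table.protein_a == table.protein_b, "intra", "inter"
        )
    return table


def simulate_apms_matrix(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a log2 protein-group intensity matrix with planted enrichment.

    Returns ``(matrix, truth)``. The matrix has one column per sample
    (``{group}_b{bio}_t{tech}``) and NaN for dropped-out values; dropout is
    missing-not-at-random, concentrated in the lowest-intensity cells.
    ``truth`` labels each protein 'null' or 'enriched' and lists the groups
    whose means were shifted by ``effect_size_sd`` standard deviations.
    """
    if spec.n_groups < 2 or spec.n_biological * spec.n_technical < 2:
        raise ValueError("need >= 2 groups and >= 2 replicates per group")
    if spec.effect_size_sd < 0:
        raise ValueError("effect size must be >= 0")
    rng = spec.rng()
    n_per_group = spec.n_biological * spec.n_technical
    columns = [
        f"g{g}_b{b}_t{t}"
        for g in range(spec.n_groups)
        for b in range(spec.n_biological)
        for t in range(spec.n_technical)
    ]
    n_samples = len(columns)
    base = rng.normal(spec.base_mean, 2.0, size=spec.n_proteins)
    data = base[:, None] + rng.normal(0.0, spec.base_sd, size=(spec.n_proteins, n_samples))

    n_enriched = int(round(spec.enriched_fraction * spec.n_proteins))
    enriched_idx = rng.choice(spec.n_proteins, size=n_enriched, replace=False)
    labels = np.full(spec.n_proteins, "null", dtype=object)
    target_groups: list[tuple[int, ...]] = [() for _ in range(spec.n_proteins)]
    if spec.effect_size_sd > 0:
        labels[enriched_idx] = "enriched"
        for i in enriched_idx:
            k = int(rng.integers(1, max(2, spec.n_groups // 2 + 1)))
            groups = tuple(sorted(rng.choice(spec.n_groups, size=k, replace=False).tolist()))
            target_groups[i] = groups
            for g in groups:
                cols = slice(g * n_per_group, (g + 1) * n_per_group)
                data[i, cols] += spec.effect_size_sd * spec.base_sd
    else:
        labels[:] = "null"

    # Missing-not-at-random dropout: cells are censored with probability
    # decaying exponentially with their intensity rank, so missingness is
    # concentrated in the low-intensity tail (below-detection-limit model).
    if spec.dropout_rate > 0:
        flat = data.ravel()
        ranks = np.argsort(np.argsort(flat)) / flat.size
        weights = np.exp(-ranks / 0.08)
        weights /= weights.sum()
        n_drop = int(round(spec.dropout_rate * flat.size))
        drop = rng.choice(flat.size, size=n_drop, replace=False, p=weights)
        mask = np.zeros(flat.size, dtype=bool)
        mask[drop] = True
        data = np.where(mask.reshape(data.shape), np.nan, data)

    matrix = pd.DataFrame(
        data, index=[f"P{i:04d}" for i in range(spec.n_proteins)], columns=columns
    )
    truth = pd.DataFrame(
        {
            "label": labels,
            "target_groups": [",".join(map(str, g)) for g in target_groups],
        },
        index=matrix.index,
    )
    return matrix, truth


def simulate_condensate_image(
    spec: SyntheticSpec,
    n_droplets: int = 10,
    radius_range: tuple[float, float] = (4.0, 12.0),
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a two-channel droplet image with a ground-truth mask.

    Returns ``(image, truth_mask, droplets)``: ``image`` is a
    (2, H, W) float array (protein and DNA channel, the DNA channel at 60%
    contrast), ``truth_mask`` a labeled integer mask, and ``droplets`` a
    table of center/radius per droplet. Droplets are disks of
    ``droplet_intensity`` on ``background_intensity`` plus additive Gaussian
    noise; droplets are placed fully inside the image (a droplet that would
    overlap the border is rejected and redrawn).
    """
    if radius_range[0] < 1:
        raise ValueError("droplet radii must be >= 1 px")
    rng = spec.rng()
    h, w = spec.image_shape
    mask = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    attempts = 0
    label = 0
    while label < n_droplets:
        attempts += 1
        if attempts > 1000 * max(n_droplets, 1):
            raise RuntimeError("could not place droplets without border overlap")
        r = rng.uniform(*radius_range)
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        if cy - r < 1 or cy + r > h - 1 or cx - r < 1 or cx + r > w - 1:
            continue  # reject droplets overlapping the image border
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if np.any(mask[disk]):
            continue
        label += 1
        mask[disk] = label
        rows.append({"label": label, "cy": cy, "cx": cx, "radius": r})
    protein = np.where(mask > 0, spec.droplet_intensity, spec.background_intensity).astype(float)
    dna = np.where(
        mask > 0, 0.6 * spec.droplet_intensity, 0.6 * spec.background_intensity
    ).astype(float)
    image = np.stack([protein, dna])
    if spec.image_noise_sd > 0:
        image = image + rng.normal(0.0, spec.image_noise_sd, size=image.shape)
    droplets = pd.DataFrame(rows, columns=["label", "cy", "cx", "radius"])
    return image, mask, droplets


def frap_recovery(t: np.ndarray, k: float, y_inf: float, y0: float) -> np.ndarray:
    """Asymptotic-regression recovery: y(t) = y_inf + (y0 - y_inf) exp(-k t)."""
    return y_inf + (y0 - y_inf) * np.exp(-k * np.asarray(t, dtype=float))


def simulate_frap_trace(spec: SyntheticSpec) -> pd.DataFrame:
    """Simulate bleached-ROI, reference-ROI and pre-bleach FRAP series.

    The bleached ROI follows the asymptotic recovery model multiplied by an
    acquisition-photobleaching decay exp(-b t) shared with the reference ROI.
    Ten pre-bleach frames at 1 s intervals precede the bleach (t < 0); the
    bleach occurs at t = 0. Columns: ``time_s``, ``bleach``, ``reference``,
    ``phase`` ('pre' or 'post').
    """
    if spec.frap_k <= 0:
        raise ValueError("k must be > 0")
    if not 0 <= spec.frap_y0 <= spec.frap_y_inf:
        raise ValueError("need 0 <= y0 <= y_inf")
    rng = spec.rng()
    t_pre = -np.arange(spec.n_prebleach, 0, -1, dtype=float)  # -10 ... -1 s
    t_post = np.arange(0.0, spec.frap_duration + 1e-9, spec.frap_interval)
    t_all = np.concatenate([t_pre, t_post])
    # acquisition bleaching acts from the first acquired frame
    decay = np.exp(-spec.acq_bleach_rate * (t_all - t_all[0]))
    i_bleach0, i_ref0 = 1000.0, 800.0
    bleach = np.where(
        t_all < 0,
        i_bleach0,
        i_bleach0 * frap_recovery(np.clip(t_all, 0, None), spec.frap_k, spec.frap_y_inf, spec.frap_y0),
    ) * decay
    reference = i_ref0 * decay
    if spec.frap_noise_sd > 0:
        bleach = bleach + rng.normal(0, spec.frap_noise_sd * i_bleach0, size=bleach.shape)
        reference = reference + rng.normal(0, spec.frap_noise_sd * i_ref0, size=reference.shape)
    return pd.DataFrame(
        {
            "time_s": t_all,
            "bleach": bleach,
            "reference": reference,
            "phase": np.where(t_all < 0, "pre", "post"),
        }
    )


def build_601_array(repeat_seq: str = REPEAT_601_207BP, n_repeats: int = 12) -> str:
    """Concatenate ``n_repeats`` copies of a nucleosome-positioning repeat unit.

    The default repeat is the 207 bp unit used for 12-mer nucleosome and
    chromatosome arrays; each copy carries one PacI site (TTAATTAA) in its
    linker DNA, so the 12-mer contains 12 sites.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seq = clean_sequence(repeat_seq, "dna")
    return seq * n_repeats
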