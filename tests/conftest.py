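import numpy as np
import pandas as pd
import pytest

from h1ub import cg_model, synthetic
from h1ub.ms_filters import WeightedCrossLink


@pytest.fixture(scope="session")
def toy_truth():
    return synthetic.make_toy_complex(seed=1)


@pytest.fixture(scope="session")
def small_truth():
    """A quick-to-build complex for bookkeeping-level tests."""
    return synthetic.make_toy_complex(n_bodies=2, beads_per_body=10, seed=3)


@pytest.fixture()
def six_row_table():
    """Three unique sites, one of them present in all three replicates.

    Site S1: ld 35, deltaS 0.5 — passes every threshold, in replicates 1-3.
    Site S2: ld 25, deltaS 0.5 — fails the strict ld > 30 cut only.
    Site S3: ld 31, deltaS 0.99 — fails the deltaS cut.
    """
    rows = [
        dict(protein_a="H1", residue_a=10, protein_b="S1", residue_b=100,
             ld_score=35.0, deltaS=0.5, fdr=0.01, replicate=1),
        dict(protein_a="H1", residue_a=20, protein_b="S1", residue_b=200,
             ld_score=25.0, deltaS=0.5, fdr=0.01, replicate=1),
        dict(protein_a="H1", residue_a=30, protein_b="S1", residue_b=300,
             ld_score=31.0, deltaS=0.99, fdr=0.01, replicate=1),
        dict(protein_a="H1", residue_a=10, protein_b="S1", residue_b=100,
             ld_score=34.0, deltaS=0.5, fdr=0.01, replicate=1),
        dict(protein_a="H1", residue_a=10, protein_b="S1", residue_b=100,
             ld_score=33.0, deltaS=0.5, fdr=0.01, replicate=2),
        dict(protein_a="H1", residue_a=10, protein_b="S1", residue_b=100,
             ld_score=36.0, deltaS=0.5, fdr=0.01, replicate=3),
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def five_bead_system():
    """Two small rigid bodies plus one flexible bead, with one crosslink."""
    coords = np.array(
        [[0.0, 0, 0], [4.0, 0, 0], [20.0, 0, 0], [24.0, 0, 0], [10.0, 5, 0]]
    )
    system = cg_model.CoarseGrainedSystem(
        coords=coords,
        radii=np.array([2.3, 2.3, 2.3, 2.3, 3.0]),
        proteins=np.array(["A", "A", "B", "B", "A"], dtype=object),
        res_start=np.array([1, 2, 1, 2, 3]),
        res_end=np.array([1, 2, 1, 2, 10]),
        rigid_bodies=[np.array([0, 1]), np.array([2, 3])],
        fixed_bodies=[True, False],
        topology=[(0, 1, 1), (1, 4, 4), (2, 3, 1)],
    )
    links = [
        WeightedCrossLink("A", 1, "B", 2, weight=3, best_ld=38.0, ld_class=2),
        WeightedCrossLink("A", 2, "B", 1, weight=1, best_ld=22.0, ld_class=0),
    ]
    return system, links
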