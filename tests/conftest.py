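import numpy as np
import pytest

from msmpath import (
    GroundTruthChain,
    Trajectory,
    double_well_spec,
    embed_path_as_structure,
    estimate_msm,
    fit_pca,
    kmeans_fit,
    pairwise_ca_distances,
    pcca_plus,
    simulate_brownian,
    superpose_trajectory,
)
from msmpath.synthetic import basin_labels, random_template


@pytest.fixture(scope="session")
def chain4():
    """Symmetric 4-state birth-death chain with analytic spectrum."""
    T = np.array([
        [0.8, 0.2, 0.0, 0.0],
        [0.2, 0.6, 0.2, 0.0],
        [0.0, 0.2, 0.6, 0.2],
        [0.0, 0.0, 0.2, 0.8],
    ])
    return GroundTruthChain(T)


@pytest.fixture(scope="session")
def doublewell_analysis():
    """End-to-end double-well analysis shared by the slow recovery tests.

    Brownian path (free-energy gap 1 kT) -> 3-D embedding -> alignment ->
    distance features -> PCA -> k-means -> reversible MSM -> PCCA+.
    """
    pot = double_well_spec(1.0)
    path = simulate_brownian(
        pot, n_steps=400_000, dt=0.01, x0=pot.well_centers[0], seed=2025, stride=10
    )
    labels = basin_labels(pot, path)
    emb = embed_path_as_structure(
        path, random_template(30, seed=2026), labels=labels, seed=2027
    )
    traj = Trajectory(emb.coordinates, frame_interval=0.1)
    feats = pairwise_ca_distances(superpose_trajectory(traj))
    proj = fit_pca(feats).transform(feats)
    states = kmeans_fit(proj, k=50, seed=2025)
    dtraj = states.assignments[0]
    model = estimate_msm(dtraj, lag=10, frame_interval=0.1)
    lumping = pcca_plus(model, 2)
    return {
        "potential": pot,
        "path": path,
        "labels": labels,
        "trajectory": traj,
        "projected": proj,
        "dtraj": dtraj,
        "model": model,
        "lumping": lumping,
    }


def make_pdb(path, n_residues=3, altloc=False):
    """Write a tiny synthetic Cα-only PDB fixture."""
    rng = np.random.default_rng(7)
    coords = rng.uniform(0, 30, size=(n_residues, 3))
    lines = []
    serial = 1
    for i, (x, y, z) in enumerate(coords, start=1):
        alts = [" "] if not (altloc and i == 1) else ["A", "B"]
        for a in alts:
            lines.append(
                f"ATOM  {serial:5d}  CA {a}ALA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return coords
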