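import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fovdesign as fd

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def tiny_ds():
    """Nine points, three labels, on a 100x100 um square."""
    x = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90], dtype=float)
    y = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90], dtype=float)
    labels = np.array(["A", "A", "A", "A", "A", "A", "B", "B", "C"], dtype=object)
    return fd.SpatialDataset(x, y, labels, bounds=(0, 0, 100, 100))


@pytest.fixture(scope="session")
def hpp_small():
    """Sparse two-phenotype HPP tissue in the resolvable-tau regime."""
    return fd.generate_hpp_tissue(
        fd.HppSpec(densities={"A": 3e-6, "B": 6e-6}, extent=(0, 0, 6000, 6000), seed=11)
    )


@pytest.fixture(scope="session")
def segregated_dense():
    """Patchy tissue with dense patches.

    Within-patch density 0.03/um^2 over radius-100 disks means a recovery
    threshold of 20-70 cells corresponds to only 2-7% of a patch's points,
    so recovery is governed by patch geometry rather than the threshold.
    """
    return fd.generate_segregated_tissue(
        fd.PatchSpec(
            n_patches=220, patch_radius=100.0, within_patch_density=0.03,
            label_pool=[f"P{i}" for i in range(12)],
            background_density=5e-5, extent=(0, 0, 4000, 4000), seed=42,
        )
    )


@pytest.fixture(scope="session")
def segregated_sparse():
    """Patchy tissue in the sparse-recovery regime (N(1) << N_O).

    Few patches per phenotype keep the single-window recovery probability
    around 20% or less at 600 um, the validity condition of the shrinkage
    estimator's log approximation.
    """
    return fd.generate_segregated_tissue(
        fd.PatchSpec(
            n_patches=180, patch_radius=70.0, within_patch_density=0.02,
            label_pool=[f"P{i}" for i in range(30)],
            background_density=3e-5, extent=(0, 0, 4000, 4000), seed=43,
        )
    )
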