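"""Shared fixtures: small deterministic meshes and a reduced phantom.

The reduced ("mini") phantom keeps every structural feature of the default
one (both bones, gap, nail with clearance and locking screws, membrane,
plate) at ~25 % of the element count so solver-backed tests stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from fracwindow.config import RunConfig, default_config
from fracwindow.fem import TetMesh, voxel_to_tetmesh
from fracwindow.phantom import LabeledVoxelGrid, PhantomConfig


def box_grid(nx: int, ny: int, nz: int, voxel: float = 1.0, label: int = 1) -> LabeledVoxelGrid:
    """Homogeneous solid box grid."""
    labels = np.full((nx, ny, nz), label, dtype=np.uint8)
    return LabeledVoxelGrid(
        grayscale=np.zeros((nx, ny, nz)),
        labels=labels,
        voxel_size_mm=voxel,
        origin_mm=np.zeros(3),
    )


def box_mesh(
    nx: int, ny: int, nz: int, voxel: float = 1.0, E: float = 1000.0, nu: float = 0.3
) -> TetMesh:
    mesh = voxel_to_tetmesh(box_grid(nx, ny, nz, voxel))
    mesh.element_E = np.full(mesh.n_elements, E)
    mesh.element_nu = np.full(mesh.n_elements, nu)
    return mesh


@pytest.fixture(scope="session")
def bar():
    """4x4x16 voxel prismatic bar, nu = 0 so clamping does not disturb the
    uniform uniaxial state."""
    return box_mesh(4, 4, 16, E=2000.0, nu=0.0)


@pytest.fixture(scope="session")
def mini_config() -> RunConfig:
    """Reduced-size study configuration for solver-backed unit tests."""
    cfg = default_config(seed=3)
    cfg.phantom = PhantomConfig(voxel_size_mm=2.5, seed=3).scaled(0.75)
    return cfg


@pytest.fixture(scope="session")
def mini_fibop(mini_config):
    from fracwindow.pipeline import build_arm, boundary_sets

    mesh = build_arm(mini_config, "FibOP")
    fixed, plateau = boundary_sets(mesh)
    return mesh, fixed, plateau
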