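"""Voxel-to-tetrahedron meshing and small-strain linear-elastic FE solution.

Each retained voxel (optionally coarsened into blocks) is split into the six
Freudenthal/Kuhn tetrahedra sharing the cell's main diagonal; this
subdivision is translation-invariant, so faces between neighbouring cells
conform without parity bookkeeping.  Elements are linear (constant-strain)
tet4 with isotropic Hooke's law per element; the classification stage
consumes element-level strain, which constant-strain elements provide
natively.

Units: mm, N, MPa, N*mm.  Displacements in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with per-element segment label and material."""

    nodes: np.ndarray  # (N, 3) mm
    elements: np.ndarray  # (M, 4) int
    element_label: np.ndarray  # (M,) segment id
    element_E: np.ndarray | None = None  # (M,) MPa
    element_nu: np.ndarray | None = None  # (M,)
    _volumes: np.ndarray | None = field(default=None, repr=False)
    _bfaces: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volume(self) -> np.ndarray:
        if self._volumes is None:
            p = self.nodes[self.elements]
            a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
            self._volumes = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
        return self._volumes

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def validate(self) -> None:
        vol = self.element_volume()
        if np.any(vol <= 0):
            raise ValueError(f"{np.count_nonzero(vol <= 0)} elements have non-positive volume")
        used = np.unique(self.elements)
        if used.size != self.n_nodes:
            raise ValueError("mesh contains unreferenced nodes")

    def boundary_faces(self) -> np.ndarray:
        """Faces belonging to exactly one tetrahedron, as (F, 3) node triples."""
        if self._bfaces is not None:
            return self._bfaces
        conn = self.elements
        faces = np.concatenate(
            [
                conn[:, [0, 1, 2]],
                conn[:, [0, 1, 3]],
                conn[:, [0, 2, 3]],
                conn[:, [1, 2, 3]],
            ]
        )
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        self._bfaces = faces[counts[inv] == 1]
        return self._bfaces

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces())

    def select_nodes(self, predicate) -> np.ndarray:
        """Node ids whose coordinates satisfy ``predicate(xyz) -> bool array``."""
        return np.nonzero(predicate(self.nodes))[0]


@dataclass
class LoadCase:
    """Boundary conditions for one instant of the gait cycle.

    ``point_loads`` and ``moments`` are lists of (node_ids, vector) pairs;
    each resultant is spread over its node set by a statically equivalent
    minimum-norm distribution (moments realised as force couples about the
    set's weighted centroid).  ``prescribed`` optionally imposes nonzero
    displacements as (node_ids, (n, 3) values).
    """

    name: str
    fixed_nodes: np.ndarray
    point_loads: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    moments: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    prescribed: tuple[np.ndarray, np.ndarray] | None = None
    scale: float = 1.0
    time_s: float | None = None

    def __post_init__(self) -> None:
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=int)
        if self.prescribed is None and self.fixed_nodes.size == 0:
            raise ValueError("load case needs a non-empty fixed node set")
        for _, vec in list(self.point_loads) + list(self.moments):
            if not np.all(np.isfinite(vec)):
                raise ValueError("loads must be finite")

    def scaled(self, factor: float) -> "LoadCase":
        return LoadCase(
            name=self.name,
            fixed_nodes=self.fixed_nodes,
            point_loads=[(n, np.asarray(v) * factor) for n, v in self.point_loads],
            moments=[(n, np.asarray(v) * factor) for n, v in self.moments],
            prescribed=self.prescribed,
            scale=self.scale,
            time_s=self.time_s,
        )


@dataclass
class DisplacementField:
    """Per-node displacement plus solver diagnostics."""

    u: np.ndarray  # (N, 3) mm
    residual: float
    reactions: np.ndarray  # (N, 3) N; nonzero only on constrained nodes
    applied: np.ndarray  # (N, 3) N assembled external loads

    def reaction_sum(self) -> np.ndarray:
        return self.reactions.sum(axis=0)

    def applied_sum(self) -> np.ndarray:
        return self.applied.sum(axis=0)


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

# Freudenthal subdivision: six tets sharing the main diagonal (0,0,0)-(1,1,1),
# one per permutation of the axis order.  Local corner id = x + 2y + 4z.
_PERMS = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))
_AXIS_BIT = (1, 2, 4)


def _freudenthal_corners() -> np.ndarray:
    tets = []
    for perm in _PERMS:
        c = [0]
        acc = 0
        for ax in perm:
            acc |= _AXIS_BIT[ax]
            c.append(acc)
        tets.append(c)
    return np.asarray(tets)  # (6, 4) local corner ids


_TET_CORNERS = _freudenthal_corners()


def coarsen_labels(labels: np.ndarray, factor: int, priority: Sequence[int]) -> np.ndarray:
    """Block-majority downsampling; ties resolved by ``priority`` (first wins)."""
    if factor == 1:
        return labels
    shape = labels.shape
    pad = [(0, (-s) % factor) for s in shape]
    lab = np.pad(labels, pad, constant_values=0)
    nb = tuple(s // factor for s in lab.shape)
    blocks = lab.reshape(nb[0], factor, nb[1], factor, nb[2], factor)
    values = sorted(np.unique(lab).tolist())
    counts = np.stack(
        [(blocks == v).sum(axis=(1, 3, 5)) for v in values]
    )  # (V, nbx, nby, nbz)
    rank = {seg: i for i, seg in enumerate(priority)}
    tie_break = np.array([-rank.get(v, len(priority)) for v in values], dtype=float)
    score = counts + 1e-3 * tie_break[:, None, None, None]
    best = np.argmax(score, axis=0)
    return np.asarray(values, dtype=labels.dtype)[best]


def voxel_to_tetmesh(grid, target_edge_mm: float | None = None, priority=None) -> TetMesh:
    """Subdivide every non-background voxel (or coarsened block) into 6 tets."""
    from .phantom import DEFAULT_PRIORITY

    labels = grid.labels
    h = grid.voxel_size_mm
    if target_edge_mm is not None:
        factor = max(1, int(round(target_edge_mm / h)))
        labels = coarsen_labels(labels, factor, priority or [int(s) for s in DEFAULT_PRIORITY])
        h = h * factor
    if not np.any(labels):
        raise ValueError("grid is empty: no foreground voxels to mesh")

    ii, jj, kk = np.nonzero(labels)
    cell_label = labels[ii, jj, kk]
    nxp, nyp, nzp = (labels.shape[0] + 1, labels.shape[1] + 1, labels.shape[2] + 1)

    def nid(i, j, k):
        return (i * nyp + j) * nzp + k

    corner_ids = np.empty((len(ii), 8), dtype=np.int64)
    for c in range(8):
        dx, dy, dz = c & 1, (c >> 1) & 1, (c >> 2) & 1
        corner_ids[:, c] = nid(ii + dx, jj + dy, kk + dz)

    elements = corner_ids[:, _TET_CORNERS].reshape(-1, 4)  # (6M, 4)
    element_label = np.repeat(cell_label, 6)

    used, inverse = np.unique(elements, return_inverse=True)
    elements = inverse.reshape(-1, 4).astype(np.int64)
    ku = used % nzp
    ju = (used // nzp) % nyp
    iu = used // (nzp * nyp)
    nodes = np.column_stack([iu, ju, ku]).astype(float) * h + grid.origin_mm

    mesh = TetMesh(nodes=nodes, elements=elements, element_label=element_label.astype(np.int64))
    # flip negatively oriented tets (depends on permutation parity)
    vol = mesh.element_volume()
    neg = vol < 0
    if neg.any():
        mesh.elements[neg] = mesh.elements[neg][:, [0, 1, 3, 2]]
        mesh._volumes = None
        mesh.element_volume()
    mesh.validate()
    return mesh


def check_load_path(mesh: TetMesh, nodes_a: np.ndarray, nodes_b: np.ndarray) -> None:
    """Raise if the two node sets are not joined through solid elements."""
    e = mesh.elements
    rows = np.concatenate([e[:, 0], e[:, 0], e[:, 0], e[:, 1], e[:, 1], e[:, 2]])
    cols = np.concatenate([e[:, 1], e[:, 2], e[:, 3], e[:, 2], e[:, 3], e[:, 3]])
    adj = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    n_comp, comp = csgraph.connected_components(adj, directed=False)
    comp_a = set(comp[np.asarray(nodes_a, dtype=int)].tolist())
    comp_b = set(comp[np.asarray(nodes_b, dtype=int)].tolist())
    if not (comp_a & comp_b):
        sizes = np.bincount(comp)
        raise ValueError(
            "disconnected load path: loaded nodes lie in component(s) "
            f"{sorted(comp_b)} but fixed nodes in {sorted(comp_a)} "
            f"({n_comp} components, sizes {sizes.tolist()[:10]}...)"
        )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def element_b_matrices(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Constant strain-displacement matrices.

    Returns ``(B, vol)`` with B of shape (M, 6, 12) in Voigt order
    (xx, yy, zz, xy, yz, zx) with engineering shear.
    """
    p = mesh.nodes[mesh.elements]  # (M, 4, 3)
    X = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=2)
    vol = np.linalg.det(X) / 6.0
    gradN = np.empty((len(p), 4, 3))
    gradN[:, 1:, :] = np.linalg.inv(X)  # row a of X^-1 is grad of barycentric coord a
    gradN[:, 0, :] = -gradN[:, 1:, :].sum(axis=1)

    M = len(p)
    B = np.zeros((M, 6, 12))
    for a in range(4):
        gx, gy, gz = gradN[:, a, 0], gradN[:, a, 1], gradN[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B, vol


def isotropic_D(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Isotropic Hooke matrices (M, 6, 6) for Voigt engineering-shear strain."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((len(E), 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
    for i in range(3, 6):
        D[:, i, i] = mu
    return D


def assemble(mesh: TetMesh) -> sp.csr_matrix:
    """Global stiffness matrix (3N x 3N, CSR), symmetric PSD before constraints."""
    if mesh.element_E is None or mesh.element_nu is None:
        raise ValueError("mesh has no materials assigned")
    if np.any(np.asarray(mesh.element_E) <= 0):
        raise ValueError("non-positive Young's modulus on some elements")

    B, vol = element_b_matrices(mesh)
    D = isotropic_D(mesh.element_E, mesh.element_nu)
    Ke = np.einsum("mki,mkl,mlj->mij", B, D, B, optimize=True) * vol[:, None, None]

    dof = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)
    ).tocsr()
    K.sum_duplicates()
    return K


# ---------------------------------------------------------------------------
# load distribution
# ---------------------------------------------------------------------------


def face_node_weights(mesh: TetMesh, node_set: np.ndarray) -> np.ndarray:
    """Tributary-area weights over a surface node set.

    Each boundary triangle fully contained in the set contributes a third of
    its area to each of its nodes; this makes an equally distributed
    resultant consistent with a uniform traction.  Falls back to equal
    weights when the set spans no boundary triangle.
    """
    node_set = np.asarray(node_set, dtype=int)
    in_set = np.zeros(mesh.n_nodes, dtype=bool)
    in_set[node_set] = True
    faces = mesh.boundary_faces()
    faces = faces[in_set[faces].all(axis=1)]
    w = np.zeros(mesh.n_nodes)
    if len(faces):
        p = mesh.nodes[faces]
        area = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
        np.add.at(w, faces.ravel(), np.repeat(area / 3.0, 3))
    weights = w[node_set]
    if weights.sum() <= 0:
        weights = np.ones(len(node_set))
    return weights / weights.sum()


def distribute_load(
    points: np.ndarray,
    force: np.ndarray,
    moment: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Statically equivalent nodal forces realising (force, moment).

    Minimises the weighted norm sum |f_i|^2 / w_i subject to
    sum f_i = force and sum r_i x f_i = moment, with r_i measured from the
    weighted centroid of the set (so the moment is about that centroid).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float) / np.sum(weights)
    centroid = weights @ points
    r = points - centroid

    C = np.zeros((6, 3 * n))
    eye = np.eye(3)
    for i in range(n):
        C[0:3, 3 * i : 3 * i + 3] = eye
        rx, ry, rz = r[i]
        C[3:6, 3 * i : 3 * i + 3] = [[0, -rz, ry], [rz, 0, -rx], [-ry, rx, 0]]
    W = np.repeat(weights, 3)
    b = np.concatenate([np.asarray(force, dtype=float), np.asarray(moment, dtype=float)])
    CW = C * W[None, :]
    lam = np.linalg.solve(CW @ C.T + 1e-12 * np.eye(6), b)
    return (W * (C.T @ lam)).reshape(n, 3)


def build_rhs(mesh: TetMesh, case: LoadCase) -> np.ndarray:
    """Assemble the external nodal force vector (N, 3) for a load case."""
    f = np.zeros((mesh.n_nodes, 3))
    groups: dict[tuple, dict] = {}
    for nodes, F in case.point_loads:
        key = tuple(np.asarray(nodes, dtype=int).tolist())
        groups.setdefault(key, {"F": np.zeros(3), "M": np.zeros(3)})["F"] += np.asarray(F, float)
    for nodes, Mv in case.moments:
        key = tuple(np.asarray(nodes, dtype=int).tolist())
        groups.setdefault(key, {"F": np.zeros(3), "M": np.zeros(3)})["M"] += np.asarray(Mv, float)
    for key, fm in groups.items():
        ids = np.asarray(key, dtype=int)
        w = face_node_weights(mesh, ids)
        f[ids] += distribute_load(mesh.nodes[ids], fm["F"], fm["M"], w)
    return f * case.scale


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------


def _dirichlet(mesh: TetMesh, case: LoadCase) -> tuple[np.ndarray, np.ndarray]:
    """Constrained dof ids and their prescribed values."""
    ndof = 3 * mesh.n_nodes
    dirichlet = np.zeros(ndof)
    mask = np.zeros(ndof, dtype=bool)
    for n in case.fixed_nodes:
        mask[3 * n : 3 * n + 3] = True
    if case.prescribed is not None:
        pn, pv = case.prescribed
        pv = np.asarray(pv, dtype=float)
        for i, n in enumerate(np.asarray(pn, dtype=int)):
            mask[3 * n : 3 * n + 3] = True
            dirichlet[3 * n : 3 * n + 3] = pv[i]
    return np.nonzero(mask)[0], dirichlet[mask]


def solve(
    mesh: TetMesh,
    case: LoadCase,
    K: sp.csr_matrix | None = None,
    rtol: float = 1e-8,
) -> DisplacementField:
    """Direct sparse solution of K u = f with fixed dofs eliminated."""
    if K is None:
        K = assemble(mesh)
    fixed, fixed_vals = _dirichlet(mesh, case)
    f = build_rhs(mesh, case).ravel()

    ndof = K.shape[0]
    free = np.setdiff1d(np.arange(ndof), fixed, assume_unique=False)
    u = np.zeros(ndof)
    u[fixed] = fixed_vals

    Kff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, fixed] @ fixed_vals
    if rhs.size:
        try:
            lu = spla.splu(Kff)
        except RuntimeError as err:
            raise ValueError(f"singular system (insufficient constraints?): {err}") from err
        u[free] = lu.solve(rhs)
        res = np.linalg.norm(Kff @ u[free] - rhs)
        ref = max(np.linalg.norm(rhs), 1.0)
        if res / ref > rtol:
            raise ValueError(f"solver residual {res / ref:.2e} exceeds tolerance {rtol:.1e}")
        residual = res / ref
    else:
        residual = 0.0

    r_all = K @ u - f
    reactions = np.zeros(ndof)
    reactions[fixed] = r_all[fixed]
    return DisplacementField(
        u=u.reshape(-1, 3),
        residual=float(residual),
        reactions=reactions.reshape(-1, 3),
        applied=f.reshape(-1, 3),
    )


def gait_cycle_solve(
    mesh: TetMesh,
    load_cases: Sequence[LoadCase],
    K: sp.csr_matrix | None = None,
) -> list[DisplacementField]:
    """Solve a sequence of frames reusing one factorisation of K.

    All frames must share the same constrained dof set (the stiffness is
    constant over a linear gait cycle, so the factorisation is reused).
    """
    cases = list(load_cases)
    if not cases:
        return []
    if K is None:
        K = assemble(mesh)
    fixed0, vals0 = _dirichlet(mesh, cases[0])
    ndof = K.shape[0]
    free = np.setdiff1d(np.arange(ndof), fixed0)
    Kff = K[free][:, free].tocsc()
    Kfc = K[free][:, fixed0]
    lu = spla.splu(Kff)

    out = []
    for case in cases:
        fixed, vals = _dirichlet(mesh, case)
        if not np.array_equal(fixed, fixed0):
            raise ValueError("all frames of a gait cycle must share the constrained dof set")
        f = build_rhs(mesh, case).ravel()
        u = np.zeros(ndof)
        u[fixed] = vals
        rhs = f[free] - Kfc @ vals
        u[free] = lu.solve(rhs)
        res = np.linalg.norm(Kff @ u[free] - rhs) / max(np.linalg.norm(rhs), 1.0)
        r_all = K @ u - f
        reactions = np.zeros(ndof)
        reactions[fixed] = r_all[fixed]
        out.append(
            DisplacementField(
                u=u.reshape(-1, 3),
                residual=float(res),
                reactions=reactions.reshape(-1, 3),
                applied=f.reshape(-1, 3),
            )
        )
    return out
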