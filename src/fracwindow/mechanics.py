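"""Per-element strain tensors, invariants and stress measures.

Strains are evaluated at element level (constant per tet4 element), which
is exactly the granularity the mechanoregulation classification consumes:

* hydrostatic strain      eps_h   = tr(eps) / 3
* octahedral shear strain gam_oct = (2/3) sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2)
* von Mises stress        svm     = sqrt(3 J2(sigma)) from isotropic Hooke's law

All three are invariant under rigid rotation of the coordinate frame;
gam_oct and svm are absolutely homogeneous of degree 1 in the load, eps_h
is linear in it.
"""

from __future__ import annotations

import numpy as np

from .fem import DisplacementField, TetMesh, element_b_matrices, isotropic_D


def element_strains(mesh: TetMesh, field: DisplacementField) -> np.ndarray:
    """Small-strain tensors per element, Voigt (xx, yy, zz, xy, yz, zx) with
    engineering shear, shape (M, 6)."""
    B, vol = element_b_matrices(mesh)
    if np.any(np.abs(vol) < 1e-14):
        raise ValueError("degenerate element encountered (near-zero volume)")
    ue = field.u[mesh.elements].reshape(len(mesh.elements), 12)
    return np.einsum("mij,mj->mi", B, ue)


def voigt_to_tensor(eps_voigt: np.ndarray) -> np.ndarray:
    """(..., 6) engineering-shear Voigt strain to (..., 3, 3) tensors."""
    e = np.asarray(eps_voigt, dtype=float)
    t = np.zeros(e.shape[:-1] + (3, 3))
    t[..., 0, 0] = e[..., 0]
    t[..., 1, 1] = e[..., 1]
    t[..., 2, 2] = e[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = e[..., 3] / 2.0
    t[..., 1, 2] = t[..., 2, 1] = e[..., 4] / 2.0
    t[..., 0, 2] = t[..., 2, 0] = e[..., 5] / 2.0
    return t


def tensor_to_voigt(eps_tensor: np.ndarray) -> np.ndarray:
    t = np.asarray(eps_tensor, dtype=float)
    return np.stack(
        [
            t[..., 0, 0],
            t[..., 1, 1],
            t[..., 2, 2],
            2.0 * t[..., 0, 1],
            2.0 * t[..., 1, 2],
            2.0 * t[..., 0, 2],
        ],
        axis=-1,
    )


def strain_invariants(eps_voigt: np.ndarray, E, nu) -> dict[str, np.ndarray]:
    """Principal strains, eps_h, gam_oct and von Mises stress.

    Parameters
    ----------
    eps_voigt : (M, 6) or (6,) engineering-shear Voigt strains.
    E, nu : scalars or (M,) element material parameters (MPa, -).
    """
    e = np.atleast_2d(np.asarray(eps_voigt, dtype=float))
    squeeze = np.asarray(eps_voigt).ndim == 1
    tens = voigt_to_tensor(e)

    principal = np.linalg.eigvalsh(tens)[:, ::-1]  # e1 >= e2 >= e3
    e1, e2, e3 = principal[:, 0], principal[:, 1], principal[:, 2]
    eps_h = (e1 + e2 + e3) / 3.0
    gam_oct = (2.0 / 3.0) * np.sqrt((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2)

    D = isotropic_D(np.broadcast_to(E, (len(e),)), np.broadcast_to(nu, (len(e),)))
    sig = np.einsum("mij,mj->mi", D, e)  # Voigt stress (sxx, syy, szz, sxy, syz, szx)
    sxx, syy, szz, sxy, syz, szx = sig.T
    svm = np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )

    out = {
        "principal": principal,
        "eps_h": eps_h,
        "gamma_oct": gam_oct,
        "svm": svm,
        "sigma_voigt": sig,
    }
    if squeeze:
        out = {k: v[0] for k, v in out.items()}
    return out


def element_invariants(mesh: TetMesh, field: DisplacementField) -> dict[str, np.ndarray]:
    """Convenience: strains then invariants for a solved displacement field."""
    eps = element_strains(mesh, field)
    inv = strain_invariants(eps, mesh.element_E, mesh.element_nu)
    inv["eps_voigt"] = eps
    return inv


def implant_stress_summary(
    mesh: TetMesh, svm: np.ndarray, segment: int
) -> dict[str, float | np.ndarray]:
    """Max and 99th-percentile von Mises stress over one implant segment.

    The maximum is taken over all elements of the segment; with constant-
    strain tets the surface elements dominate the extremes anyway.
    """
    sel = np.asarray(mesh.element_label) == segment
    if not sel.any():
        raise ValueError(f"segment {segment} not present in mesh")
    vals = np.asarray(svm)[sel]
    imax_local = int(np.argmax(vals))
    ids = np.nonzero(sel)[0]
    return {
        "max_MPa": float(vals.max()),
        "p99_MPa": float(np.percentile(vals, 99.0)),
        "max_element": int(ids[imax_local]),
        "max_location_mm": mesh.element_centroids()[ids[imax_local]],
    }
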