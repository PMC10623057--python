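"""Small-strain plane-stress linear elasticity on a seam-crack mesh.

Bilinear quadrilaterals (2x2 Gauss) and constant-strain triangles, assembled
into a sparse stiffness matrix and solved directly.  The loading is a uniform
outward normal traction of magnitude ``sigma0`` on all four plate edges
(equibiaxial tension); the seam faces remain traction-free and unconstrained,
so the incision opens under load.

The cornea is treated as a simple linear material: isotropic with stiffness
``E`` (default 9.82 MPa, porcine cornea at a 3 mm/min strain rate) or
orthotropic with moduli ``E_x``/``E_y`` to mimic fibril anisotropy.  The
critical energy release rate ``G_c`` (default 5.40 kJ/m^2, same source and
rate) rides along on the material for the Griffith verdicts downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import CrackMesh

__all__ = [
    "Material",
    "LoadCase",
    "PlaneStressSolution",
    "OpeningProfile",
    "assemble_and_solve",
    "crack_opening",
    "ElasticityError",
]

#: default tissue stiffness [Pa]
E_CORNEA = 9.82e6
#: default critical energy release rate [J/m^2]
G_C_CORNEA = 5.40e3
#: default Poisson ratio (near-incompressible soft tissue; not a measured
#: corneal constant -- configurable, and the headline results are insensitive)
NU_DEFAULT = 0.49

_GP = 1.0 / math.sqrt(3.0)
_QUAD_GPTS = np.array([(-_GP, -_GP), (_GP, -_GP), (_GP, _GP), (-_GP, _GP)])


class ElasticityError(RuntimeError):
    """Singular system, unstable material, or failed solve."""


@dataclass(frozen=True)
class Material:
    """Plane-stress elastic constants plus fracture toughness.

    For the orthotropic case only the modulus ratio is physically motivated;
    the auxiliary constants default to ``nu_xy = nu * sqrt(E_x/E_y)`` (capped
    for thermodynamic stability) and a geometric-mean shear modulus estimate
    ``G_xy = sqrt(E_x E_y) / (2 (1 + sqrt(nu_xy nu_yx)))``.
    """

    kind: str = "isotropic"
    E: float = E_CORNEA
    nu: float = NU_DEFAULT
    E_x: float | None = None
    E_y: float | None = None
    nu_xy: float | None = None
    G_xy: float | None = None
    G_c: float = G_C_CORNEA

    def __post_init__(self) -> None:
        if self.kind not in ("isotropic", "orthotropic"):
            raise ElasticityError(f"unknown material kind {self.kind!r}")
        if not self.G_c > 0:
            raise ElasticityError("G_c must be positive")
        if self.kind == "isotropic":
            if not self.E > 0:
                raise ElasticityError("E must be positive")
            if not (0.0 <= self.nu < 0.5):
                raise ElasticityError("nu must lie in [0, 0.5)")
        else:
            if self.E_x is None or self.E_y is None:
                raise ElasticityError("orthotropic material needs E_x and E_y")
            if not (self.E_x > 0 and self.E_y > 0):
                raise ElasticityError("moduli must be positive")
            nuxy = self.resolved_nu_xy
            if nuxy**2 >= self.E_x / self.E_y:
                raise ElasticityError(
                    f"orthotropic stability violated: nu_xy^2 = {nuxy**2:.3g} "
                    f">= E_x/E_y = {self.E_x / self.E_y:.3g}"
                )

    @classmethod
    def isotropic(cls, E: float = E_CORNEA, nu: float = NU_DEFAULT,
                  G_c: float = G_C_CORNEA) -> "Material":
        return cls(kind="isotropic", E=E, nu=nu, G_c=G_c)

    @classmethod
    def orthotropic(cls, E_x: float, E_y: float, nu_xy: float | None = None,
                    G_xy: float | None = None, nu: float = NU_DEFAULT,
                    G_c: float = G_C_CORNEA) -> "Material":
        return cls(kind="orthotropic", E_x=E_x, E_y=E_y, nu_xy=nu_xy,
                   G_xy=G_xy, nu=nu, G_c=G_c)

    @property
    def eta(self) -> float:
        """Orthotropy ratio E_x / E_y (1 for isotropic)."""
        if self.kind == "isotropic":
            return 1.0
        return self.E_x / self.E_y

    @property
    def resolved_nu_xy(self) -> float:
        if self.nu_xy is not None:
            return self.nu_xy
        # scale the base ratio with sqrt(eta) (reciprocity-symmetric guess),
        # capped below the stability limit
        guess = self.nu * math.sqrt(self.E_x / self.E_y)
        cap = 0.95 * math.sqrt(self.E_x / self.E_y)
        return min(guess, cap)

    @property
    def resolved_G_xy(self) -> float:
        if self.G_xy is not None:
            return self.G_xy
        nuxy = self.resolved_nu_xy
        nuyx = nuxy * self.E_y / self.E_x
        return math.sqrt(self.E_x * self.E_y) / (2.0 * (1.0 + math.sqrt(nuxy * nuyx)))

    def stiffness(self) -> np.ndarray:
        """3x3 plane-stress stiffness (Voigt: xx, yy, xy with engineering shear)."""
        if self.kind == "isotropic":
            f = self.E / (1.0 - self.nu**2)
            return f * np.array([
                [1.0, self.nu, 0.0],
                [self.nu, 1.0, 0.0],
                [0.0, 0.0, (1.0 - self.nu) / 2.0],
            ])
        nuxy = self.resolved_nu_xy
        nuyx = nuxy * self.E_y / self.E_x
        den = 1.0 - nuxy * nuyx
        return np.array([
            [self.E_x / den, nuxy * self.E_y / den, 0.0],
            [nuxy * self.E_y / den, self.E_y / den, 0.0],
            [0.0, 0.0, self.resolved_G_xy],
        ])


@dataclass(frozen=True)
class LoadCase:
    """Uniform outward normal traction sigma0 [Pa] on all four outer edges."""

    sigma0: float

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise ElasticityError("sigma0 must be positive")


@dataclass
class PlaneStressSolution:
    """Solved displacement field plus derived element data."""

    u: np.ndarray  # (N, 2) nodal displacements [m]
    mesh: CrackMesh = field(repr=False, default=None)  # type: ignore[assignment]
    material: Material = None  # type: ignore[assignment]
    load: LoadCase = None  # type: ignore[assignment]
    stress: np.ndarray = field(repr=False, default=None)  # (n_elem, 3) mean Voigt stress
    strain: np.ndarray = field(repr=False, default=None)  # (n_elem, 3)
    energy_density: np.ndarray = field(repr=False, default=None)  # (n_elem,)
    strain_energy: float = 0.0
    external_work: float = 0.0
    residual_rel: float = 0.0

    def von_mises(self) -> np.ndarray:
        s = self.stress
        return np.sqrt(s[:, 0] ** 2 - s[:, 0] * s[:, 1] + s[:, 1] ** 2 + 3.0 * s[:, 2] ** 2)


@dataclass
class OpeningProfile:
    """Seam-pair separations projected on the local crack normal."""

    arclengths: np.ndarray  # distance of each pair from the left tip [m]
    separation: np.ndarray  # [m]
    midpoint: float  # separation at the incision midpoint [m]
    maximum: float
    interpenetration: bool  # any negative separation (invalid load direction)


# ---------------------------------------------------------------------------
# element kernels (vectorized over all elements of one type)
# ---------------------------------------------------------------------------

def _quad_gradients(xe: np.ndarray):
    """Shape-function gradients and Jacobians for Q4 at the 2x2 Gauss points.

    xe: (n, 4, 2).  Returns dNdx (n, 4, 4, 2) and detJ (n, 4) indexed
    [element, gauss point, node, direction].
    """
    n = len(xe)
    dNdx = np.empty((n, 4, 4, 2))
    detJ = np.empty((n, 4))
    for g, (xi, eta) in enumerate(_QUAD_GPTS):
        dN = 0.25 * np.array([
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ])  # (4 nodes, 2 ref dirs)
        J = np.einsum("ar,nad->nrd", dN, xe)  # (n, 2, 2)
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        Jinv = np.empty_like(J)
        Jinv[:, 0, 0] = J[:, 1, 1]
        Jinv[:, 1, 1] = J[:, 0, 0]
        Jinv[:, 0, 1] = -J[:, 0, 1]
        Jinv[:, 1, 0] = -J[:, 1, 0]
        Jinv /= det[:, None, None]
        # chain rule: dN/dx_d = dN/dxi_r * dxi_r/dx_d with dxi_r/dx_d = Jinv[d, r]
        dNdx[:, g] = np.einsum("ar,ndr->nad", dN, Jinv)
        detJ[:, g] = det
    return dNdx, detJ


def _tri_gradients(xe: np.ndarray):
    """Constant gradients for T3.  Returns dNdx (n, 3, 2) and areas (n,)."""
    v1 = xe[:, 1] - xe[:, 0]
    v2 = xe[:, 2] - xe[:, 0]
    det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]  # 2*area
    dNdx = np.empty((len(xe), 3, 2))
    dNdx[:, 0, 0] = (xe[:, 1, 1] - xe[:, 2, 1]) / det
    dNdx[:, 0, 1] = (xe[:, 2, 0] - xe[:, 1, 0]) / det
    dNdx[:, 1, 0] = (xe[:, 2, 1] - xe[:, 0, 1]) / det
    dNdx[:, 1, 1] = (xe[:, 0, 0] - xe[:, 2, 0]) / det
    dNdx[:, 2, 0] = (xe[:, 0, 1] - xe[:, 1, 1]) / det
    dNdx[:, 2, 1] = (xe[:, 1, 0] - xe[:, 0, 0]) / det
    return dNdx, det / 2.0


def _element_stiffness(dNdx: np.ndarray, w: np.ndarray, D: np.ndarray) -> np.ndarray:
    """K_e for elements with per-gp gradients dNdx (n, G, A, 2) and weights
    w (n, G) (detJ * gauss weight); returns (n, 2A, 2A)."""
    n, G, A, _ = dNdx.shape
    B = np.zeros((n, G, 3, 2 * A))
    B[:, :, 0, 0::2] = dNdx[..., 0]
    B[:, :, 1, 1::2] = dNdx[..., 1]
    B[:, :, 2, 0::2] = dNdx[..., 1]
    B[:, :, 2, 1::2] = dNdx[..., 0]
    return np.einsum("ngia,ij,ngjb,ng->nab", B, D, B, w, optimize=True)


def default_constraints(mesh: CrackMesh) -> list[tuple[int, int]]:
    """Mirror-symmetric rigid-body gauge.

    Pins ``u_x`` at the top-center and bottom-center boundary nodes and
    ``u_y`` at the top-center node: exactly three constraints, compatible with
    the x-mirror-symmetric solution, so symmetry survives to solver precision.
    """
    hw = mesh.plate.width / 2.0
    hh = mesh.plate.height / 2.0
    boundary = np.unique(np.concatenate([v.ravel() for v in mesh.boundary_edges.values()]))
    pts = mesh.nodes[boundary]
    top = int(boundary[np.argmin(np.hypot(pts[:, 0], pts[:, 1] - hh))])
    bot = int(boundary[np.argmin(np.hypot(pts[:, 0], pts[:, 1] + hh))])
    return [(top, 0), (bot, 0), (top, 1)]


def assemble_and_solve(mesh: CrackMesh, mat: Material, load: LoadCase,
                       constraints: list[tuple[int, int]] | None = None
                       ) -> PlaneStressSolution:
    """Assemble the plane-stress system and solve for nodal displacements.

    ``constraints`` is a list of (node id, dof) pairs pinned to zero; the
    default removes exactly the three planar rigid-body modes with a
    mirror-symmetric gauge.  Seam pairs are left fully independent, so the
    crack faces are free to separate.
    """
    D = mat.stiffness()
    N = mesh.n_nodes
    ndof = 2 * N

    rows, cols, vals = [], [], []

    def _accumulate(conn: np.ndarray, Ke: np.ndarray) -> None:
        A = conn.shape[1]
        dofs = np.empty((len(conn), 2 * A), dtype=int)
        dofs[:, 0::2] = 2 * conn
        dofs[:, 1::2] = 2 * conn + 1
        rows.append(np.repeat(dofs, 2 * A, axis=1).ravel())
        cols.append(np.tile(dofs, (1, 2 * A)).ravel())
        vals.append(Ke.ravel())

    quad_data = tri_data = None
    if len(mesh.quads):
        xe = mesh.nodes[mesh.quads]
        dNdx, detJ = _quad_gradients(xe)
        Ke = _element_stiffness(dNdx, detJ, D)  # gauss weights are 1
        _accumulate(mesh.quads, Ke)
        quad_data = (dNdx, detJ)
    if len(mesh.tris):
        xe = mesh.nodes[mesh.tris]
        dNdx, area = _tri_gradients(xe)
        Ke = _element_stiffness(dNdx[:, None], area[:, None], D)
        _accumulate(mesh.tris, Ke)
        tri_data = (dNdx, area)

    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()

    # consistent nodal loads from the edge tractions
    f = np.zeros(ndof)
    normals = {"left": (-1.0, 0.0), "right": (1.0, 0.0),
               "top": (0.0, 1.0), "bottom": (0.0, -1.0)}
    for side, edges in mesh.boundary_edges.items():
        if not len(edges):
            continue
        nx, ny = normals[side]
        p1 = mesh.nodes[edges[:, 0]]
        p2 = mesh.nodes[edges[:, 1]]
        L = np.linalg.norm(p2 - p1, axis=1)
        for col in (0, 1):
            np.add.at(f, 2 * edges[:, col], load.sigma0 * nx * L / 2.0)
            np.add.at(f, 2 * edges[:, col] + 1, load.sigma0 * ny * L / 2.0)

    if constraints is None:
        constraints = default_constraints(mesh)
    fixed = np.array([2 * n + d for n, d in constraints], dtype=int)
    if len(np.unique(fixed)) < 3:
        raise ElasticityError("constraints must remove three rigid-body modes")
    # nodes referenced by no element (e.g. orphaned seam partners after a
    # merge) carry no stiffness: pin them
    referenced = np.zeros(N, dtype=bool)
    if len(mesh.tris):
        referenced[mesh.tris.ravel()] = True
    if len(mesh.quads):
        referenced[mesh.quads.ravel()] = True
    orphan_dofs = np.concatenate([2 * np.where(~referenced)[0],
                                  2 * np.where(~referenced)[0] + 1])
    fixed = np.union1d(fixed, orphan_dofs)
    free = np.setdiff1d(np.arange(ndof), fixed)

    Kff = K[free][:, free].tocsc()
    try:
        uf = spla.spsolve(Kff, f[free])
    except Exception as exc:  # pragma: no cover - scipy raises various types
        raise ElasticityError(f"linear solve failed: {exc}") from exc
    if not np.all(np.isfinite(uf)):
        raise ElasticityError("singular system (insufficient constraints?)")

    u = np.zeros(ndof)
    u[free] = uf
    res = np.linalg.norm(Kff @ uf - f[free]) / max(np.linalg.norm(f[free]), 1e-300)

    sol = PlaneStressSolution(u=u.reshape(-1, 2), mesh=mesh, material=mat, load=load)
    sol.residual_rel = float(res)

    # element-average stress/strain/energy + energy bookkeeping
    n_elem = mesh.n_elements
    stress = np.zeros((n_elem, 3))
    strain = np.zeros((n_elem, 3))
    wdens = np.zeros(n_elem)
    U = 0.0
    nt = len(mesh.tris)
    if tri_data is not None:
        dNdx, area = tri_data
        ue = sol.u[mesh.tris]  # (n, 3, 2)
        eps = np.empty((len(mesh.tris), 3))
        eps[:, 0] = np.einsum("na,na->n", dNdx[..., 0], ue[..., 0])
        eps[:, 1] = np.einsum("na,na->n", dNdx[..., 1], ue[..., 1])
        eps[:, 2] = (np.einsum("na,na->n", dNdx[..., 1], ue[..., 0])
                     + np.einsum("na,na->n", dNdx[..., 0], ue[..., 1]))
        sig = eps @ D.T
        W = 0.5 * np.einsum("ni,ni->n", sig, eps)
        strain[:nt], stress[:nt], wdens[:nt] = eps, sig, W
        U += float(np.sum(W * area))
    if quad_data is not None:
        dNdx, detJ = quad_data
        ue = sol.u[mesh.quads]  # (n, 4, 2)
        eps_g = np.empty((len(mesh.quads), 4, 3))
        eps_g[..., 0] = np.einsum("nga,na->ng", dNdx[..., 0], ue[..., 0])
        eps_g[..., 1] = np.einsum("nga,na->ng", dNdx[..., 1], ue[..., 1])
        eps_g[..., 2] = (np.einsum("nga,na->ng", dNdx[..., 1], ue[..., 0])
                         + np.einsum("nga,na->ng", dNdx[..., 0], ue[..., 1]))
        sig_g = np.einsum("ngi,ji->ngj", eps_g, D)
        W_g = 0.5 * np.einsum("ngi,ngi->ng", sig_g, eps_g)
        strain[nt:] = eps_g.mean(axis=1)
        stress[nt:] = sig_g.mean(axis=1)
        wdens[nt:] = W_g.mean(axis=1)
        U += float(np.einsum("ng,ng->", W_g, detJ))
    sol.strain, sol.stress, sol.energy_density = strain, stress, wdens
    sol.strain_energy = U
    sol.external_work = float(0.5 * f @ u)

    if abs(U - sol.external_work) > 1e-6 * max(abs(U), 1e-300):
        warnings.warn(
            f"work-energy imbalance: U = {U:.6e}, W_ext = {sol.external_work:.6e}",
            stacklevel=2,
        )
    return sol


def crack_opening(sol: PlaneStressSolution, mesh: CrackMesh | None = None
                  ) -> OpeningProfile:
    """Seam separation profile (upper minus lower displacement, along the
    local crack normal) with midpoint and maximum values."""
    mesh = mesh or sol.mesh
    if not mesh.has_seam or not len(mesh.seam_pairs):
        raise ElasticityError("mesh has no seam: no opening to measure")
    du = sol.u[mesh.seam_pairs[:, 0]] - sol.u[mesh.seam_pairs[:, 1]]
    sep = np.einsum("pi,pi->p", du, mesh.seam_normals)
    mid_idx = int(np.where(mesh.seam_pairs[:, 0] == mesh.midpoint_pair[0])[0][0])
    interp = bool(np.any(sep < -1e-12 * max(1.0, np.max(np.abs(sep)))))
    if interp:
        warnings.warn("crack faces interpenetrate: load direction invalid for "
                      "this contact-free model", stacklevel=2)
    return OpeningProfile(
        arclengths=mesh.seam_arclengths.copy(),
        separation=sep,
        midpoint=float(sep[mid_idx]),
        maximum=float(np.max(sep)),
        interpenetration=interp,
    )
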