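"""Per-residue molecular interaction energy components (MIEC).

The interaction free energy between each receptor residue and the ligand is
decomposed into four additive terms,

    dG(residue) = dG_vdw + dG_ele + dG_gb + dG_sa ,

evaluated at a single optimized geometry:

* ``dG_ele`` — Coulomb interaction between residue and ligand partial charges
  screened by a uniform interior dielectric (default eps_in = 4, the value
  that works well for kinase binding sites).
* ``dG_vdw`` — 12-6 Lennard-Jones interaction with Lorentz-Berthelot style
  combination (Rmin_ij = Rmin/2_i + Rmin/2_j, eps_ij = sqrt(eps_i eps_j)).
* ``dG_gb`` — polar solvation contribution from the generalized Born model
  with Onufriev-Bashford-Case (OBC) rescaled effective radii; only the
  residue-ligand cross pairs are summed, so the term vanishes at infinite
  separation like the other interaction components.
* ``dG_sa`` — nonpolar solvation from the solvent-accessible surface area
  buried on complex formation, sampled with points distributed on a
  subdivided icosahedron (an icosphere), gamma * dSASA per residue.

The module also contains the pose utilities built on the decomposition
(rescoring, top-1 vs best-of-top-3 selection) and a three-phase restrained
minimizer over a toy force field (nonbonded + harmonic bonds).

All energies are kcal/mol, lengths angstrom, charges in units of the
elementary charge.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.distance import cdist

from .io import AtomRecord, ReceptorLigandComplex, ResidueEnergyTable, PoseSet
import pandas as pd

__all__ = [
    "EnergyParams",
    "MinimizationProtocol",
    "MinimizationResult",
    "SingularGeometryError",
    "BornRadiusError",
    "electrostatic_component",
    "vdw_component",
    "born_radii",
    "hct_integrals",
    "gb_component",
    "sasa",
    "sphere_points",
    "sa_component",
    "ligand_sa_term",
    "decompose",
    "rescore_pose",
    "select_pose",
    "minimize",
]


class SingularGeometryError(ValueError):
    """Two interacting atoms coincide (r_ij = 0)."""


class BornRadiusError(FloatingPointError):
    """The OBC rescaling produced a non-positive effective radius."""


@dataclass
class EnergyParams:
    """Physical constants and model parameters for the decomposition.

    Defaults follow the common MM/GBSA setup for kinases: interior dielectric
    4, water dielectric 80, OBC-II rescaling coefficients, a 0.09 A Born
    radius offset, a 1.4 A solvent probe and a surface tension of
    0.0072 kcal/(mol A^2).  ``nb_cutoff`` applies only inside the minimizer
    (the decomposition itself is cutoff-free so residue rankings do not
    depend on a truncation radius).
    """

    eps_in: float = 4.0
    eps_out: float = 80.0
    coulomb_constant: float = 332.0637  # kcal A / (mol e^2)
    gb_offset: float = 0.09  # A
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85
    probe_radius: float = 1.4  # A
    sasa_gamma: float = 0.0072  # kcal / (mol A^2)
    sasa_points: int = 320
    nb_cutoff: float | None = 8.0  # A, minimizer only

    def __post_init__(self) -> None:
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ValueError("require eps_out > eps_in >= 1")
        if self.sasa_points < 12:
            raise ValueError("sasa_points must be >= 12")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")


@dataclass
class MinimizationProtocol:
    """Ordered restrained-minimization phases.

    Each phase is (restraint_k in kcal/(mol A^2) applied to backbone atoms,
    steepest-descent cycles, conjugate-gradient cycles).  The default mirrors
    the usual complex-relaxation scheme: 50 -> 10 -> 0 restraints with
    500 SD + 500 CG cycles in the restrained phases and 1500 + 1500 in the
    free phase.
    """

    phases: list[tuple[float, int, int]] = field(
        default_factory=lambda: [(50.0, 500, 500), (10.0, 500, 500), (0.0, 1500, 1500)]
    )

    def __post_init__(self) -> None:
        ks = [k for k, _, _ in self.phases]
        if any(k2 > k1 for k1, k2 in zip(ks, ks[1:])):
            raise ValueError("restraint_k must be non-increasing across phases")
        for k, ns, nc in self.phases:
            if k < 0 or ns < 0 or nc < 0:
                raise ValueError("restraint and cycle counts must be >= 0")


@dataclass
class MinimizationResult:
    complex: ReceptorLigandComplex
    energy_trajectory: list[np.ndarray]  # accepted-step energies, one array per phase
    initial_energy: float
    final_energy: float


# ---------------------------------------------------------------------------
# pairwise helpers
# ---------------------------------------------------------------------------


def _cross_distances(complex_: ReceptorLigandComplex) -> np.ndarray:
    return cdist(complex_.receptor_coords(), complex_.ligand_coords())


def _per_residue(complex_: ReceptorLigandComplex, per_atom: np.ndarray) -> np.ndarray:
    """Sum a per-receptor-atom quantity into residue_order bins."""
    out = np.zeros(len(complex_.residue_order))
    np.add.at(out, complex_.residue_of_receptor_atoms(), per_atom)
    return out


# ---------------------------------------------------------------------------
# electrostatics and van der Waals
# ---------------------------------------------------------------------------


def electrostatic_component(
    complex_: ReceptorLigandComplex, params: EnergyParams
) -> np.ndarray:
    """Screened Coulomb residue-ligand energies, kcal/mol per residue.

    dG_ele(r) = sum_{i in r, j in ligand} k q_i q_j / (eps_in r_ij).
    """
    d = _cross_distances(complex_)
    if np.any(d == 0):
        i, j = np.argwhere(d == 0)[0]
        raise SingularGeometryError(
            f"receptor atom {complex_.receptor_atoms[i].atom_id} coincides "
            f"with ligand atom {complex_.ligand_atoms[j].atom_id}"
        )
    q_rec = np.array([a.charge for a in complex_.receptor_atoms])
    q_lig = np.array([a.charge for a in complex_.ligand_atoms])
    pair = params.coulomb_constant * np.outer(q_rec, q_lig) / (params.eps_in * d)
    return _per_residue(complex_, pair.sum(axis=1))


def vdw_component(complex_: ReceptorLigandComplex, params: EnergyParams) -> np.ndarray:
    """12-6 Lennard-Jones residue-ligand energies, kcal/mol per residue.

    dG_vdw(r) = sum pairs eps_ij [ (Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6 ].
    """
    d = _cross_distances(complex_)
    if np.any(d == 0):
        raise SingularGeometryError("coincident receptor/ligand atoms (r_ij = 0)")
    rh_rec = np.array([a.lj_rmin_half for a in complex_.receptor_atoms])
    rh_lig = np.array([a.lj_rmin_half for a in complex_.ligand_atoms])
    e_rec = np.array([a.lj_epsilon for a in complex_.receptor_atoms])
    e_lig = np.array([a.lj_epsilon for a in complex_.ligand_atoms])
    rmin = rh_rec[:, None] + rh_lig[None, :]
    eps = np.sqrt(np.outer(e_rec, e_lig))
    s6 = (rmin / d) ** 6
    pair = eps * (s6 * s6 - 2.0 * s6)
    return _per_residue(complex_, pair.sum(axis=1))


# ---------------------------------------------------------------------------
# generalized Born (HCT descreening + OBC rescaling)
# ---------------------------------------------------------------------------


def hct_integrals(atoms: list[AtomRecord], params: EnergyParams) -> np.ndarray:
    """Pairwise-descreening integrals I_i (1/A) for every atom.

    Analytic integral of r^-4 over each neighbour's reduced sphere
    (rho_j - offset), summed over neighbours; no heavy-atom scaling factors
    are applied (S_j = 1).
    """
    rho = np.array([a.gb_radius for a in atoms], dtype=float)
    rho_t = rho - params.gb_offset
    if np.any(rho_t <= 0):
        k = int(np.argmax(rho_t <= 0))
        raise BornRadiusError(
            f"atom {atoms[k].atom_id}: gb_radius {rho[k]} <= offset {params.gb_offset}"
        )
    xyz = np.array([a.xyz for a in atoms], dtype=float)
    n = len(atoms)
    r = cdist(xyz, xyz)

    ri = rho_t[:, None]  # descreened atom's reduced radius
    sk = rho_t[None, :]  # neighbour's reduced radius
    np.fill_diagonal(r, np.inf)  # exclude self

    with np.errstate(divide="ignore", invalid="ignore"):
        U = r + sk
        L = np.maximum(ri, np.abs(r - sk))
        inv_l = 1.0 / L
        inv_u = 1.0 / U
        term = (
            inv_l
            - inv_u
            + 0.25 * r * (inv_u**2 - inv_l**2)
            + (0.5 / r) * np.log(L / U)
            + (0.25 * sk**2 / r) * (inv_l**2 - inv_u**2)
        )
        # atom i entirely inside neighbour j
        inside = ri < (sk - r)
        term = term + np.where(inside, 2.0 * (1.0 / ri - inv_l), 0.0)
        term = np.where(ri < U, term, 0.0)
        term = np.where(np.isfinite(r), term, 0.0)
    return 0.5 * term.sum(axis=1)


def born_radii(atoms: list[AtomRecord], params: EnergyParams) -> np.ndarray:
    """Effective Born radii (A) via OBC tanh rescaling.

    R_i^-1 = rho_t_i^-1 - rho_i^-1 tanh(alpha Psi - beta Psi^2 + gamma Psi^3)
    with Psi = I_i rho_t_i and rho_t_i = rho_i - offset.  An isolated atom
    (I = 0) therefore has R = rho - offset.
    """
    rho = np.array([a.gb_radius for a in atoms], dtype=float)
    rho_t = rho - params.gb_offset
    I = hct_integrals(atoms, params)
    psi = I * rho_t
    inv_R = 1.0 / rho_t - np.tanh(
        params.obc_alpha * psi - params.obc_beta * psi**2 + params.obc_gamma * psi**3
    ) / rho
    if np.any(inv_R <= 0) or not np.all(np.isfinite(inv_R)):
        k = int(np.argmax((inv_R <= 0) | ~np.isfinite(inv_R)))
        raise BornRadiusError(
            f"atom {atoms[k].atom_id}: OBC rescaling gave non-positive "
            f"effective Born radius"
        )
    return 1.0 / inv_R


def gb_component(
    complex_: ReceptorLigandComplex, radii: np.ndarray, params: EnergyParams
) -> np.ndarray:
    """Generalized Born cross-term energies, kcal/mol per residue.

    dG_gb(r) = -(1/eps_in - 1/eps_out) k
               sum_{i in r, j in ligand} q_i q_j / f_gb(r_ij)
    with f_gb = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))).  Only
    residue-ligand cross pairs enter; self/desolvation terms are excluded so
    the component reads as an interaction energy and vanishes at infinite
    separation.  ``radii`` must come from :func:`born_radii` on the full
    complex (receptor atoms first, ligand atoms last).
    """
    n_rec = len(complex_.receptor_atoms)
    n_all = n_rec + len(complex_.ligand_atoms)
    radii = np.asarray(radii, dtype=float)
    if radii.shape != (n_all,):
        raise ValueError(
            f"need one Born radius per complex atom ({n_all}), got {radii.shape}"
        )
    d = _cross_distances(complex_)
    q_rec = np.array([a.charge for a in complex_.receptor_atoms])
    q_lig = np.array([a.charge for a in complex_.ligand_atoms])
    RiRj = np.outer(radii[:n_rec], radii[n_rec:])
    f = np.sqrt(d**2 + RiRj * np.exp(-(d**2) / (4.0 * RiRj)))
    prefactor = -(1.0 / params.eps_in - 1.0 / params.eps_out) * params.coulomb_constant
    pair = prefactor * np.outer(q_rec, q_lig) / f
    return _per_residue(complex_, pair.sum(axis=1))


# ---------------------------------------------------------------------------
# SASA (icosphere point sampling)
# ---------------------------------------------------------------------------

_GOLDEN = (1.0 + math.sqrt(5.0)) / 2.0


def _icosahedron():
    p = _GOLDEN
    verts = np.array(
        [
            [-1, p, 0], [1, p, 0], [-1, -p, 0], [1, -p, 0],
            [0, -1, p], [0, 1, p], [0, -1, -p], [0, 1, -p],
            [p, 0, -1], [p, 0, 1], [-p, 0, -1], [-p, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    return verts, faces


def sphere_points(n: int) -> np.ndarray:
    """Unit-sphere direction set with ``n`` points.

    When ``n = 20 * 4^k`` the points are centroids of a k-times subdivided
    icosahedron's faces (the icosphere construction); for other counts a
    Fibonacci lattice of the requested size is used.
    """
    if n < 12:
        raise ValueError("need at least 12 sphere points")
    k = 0
    m = 20
    while m < n:
        m *= 4
        k += 1
    if m == n:
        verts, faces = _icosahedron()
        tris = [tuple(verts[i] for i in f) for f in faces]
        for _ in range(k):
            new = []
            for a, b, c in tris:
                ab = (a + b) / 2.0
                bc = (b + c) / 2.0
                ca = (c + a) / 2.0
                ab /= np.linalg.norm(ab)
                bc /= np.linalg.norm(bc)
                ca /= np.linalg.norm(ca)
                new.extend([(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)])
            tris = new
        pts = np.array([(a + b + c) / 3.0 for a, b, c in tris])
        return pts / np.linalg.norm(pts, axis=1)[:, None]
    # Fibonacci lattice fallback for arbitrary counts
    i = np.arange(n) + 0.5
    phi = 2.0 * math.pi * i / _GOLDEN
    cos_t = 1.0 - 2.0 * i / n
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def sasa(atoms: list[AtomRecord], params: EnergyParams) -> np.ndarray:
    """Per-atom solvent-accessible surface area, A^2.

    Shrake-Rupley style point sampling: each atom's solvent-expanded sphere
    (rho + probe) carries ``sasa_points`` sample points; a point is buried if
    it lies strictly inside any other atom's expanded sphere.
    """
    pts = sphere_points(params.sasa_points)
    xyz = np.array([a.xyz for a in atoms], dtype=float)
    radii = np.array([a.gb_radius for a in atoms], dtype=float) + params.probe_radius
    n = len(atoms)
    out = np.zeros(n)
    for i in range(n):
        surface = xyz[i] + radii[i] * pts
        exposed = np.ones(len(pts), dtype=bool)
        for j in range(n):
            if j == i or not exposed.any():
                continue
            # cheap sphere-sphere prescreen
            dij = np.linalg.norm(xyz[j] - xyz[i])
            if dij >= radii[i] + radii[j]:
                continue
            dist = np.linalg.norm(surface - xyz[j], axis=1)
            exposed &= dist >= radii[j]
        out[i] = exposed.mean() * 4.0 * math.pi * radii[i] ** 2
    return out


def sa_component(complex_: ReceptorLigandComplex, params: EnergyParams) -> np.ndarray:
    """Nonpolar (surface-burial) energies, kcal/mol per residue.

    dG_sa(r) = gamma * sum_{i in r} (SASA_complex,i - SASA_receptor-alone,i),
    i.e. only receptor-side burial is attributed to residues; ligand burial is
    available separately via :func:`ligand_sa_term`.
    """
    n_rec = len(complex_.receptor_atoms)
    sasa_complex = sasa(complex_.all_atoms(), params)[:n_rec]
    sasa_alone = sasa(complex_.receptor_atoms, params)
    return params.sasa_gamma * _per_residue(complex_, sasa_complex - sasa_alone)


def ligand_sa_term(complex_: ReceptorLigandComplex, params: EnergyParams) -> float:
    """Ligand-side burial energy, kcal/mol (not attributed to residues)."""
    n_rec = len(complex_.receptor_atoms)
    sasa_complex = sasa(complex_.all_atoms(), params)[n_rec:]
    sasa_alone = sasa(complex_.ligand_atoms, params)
    return float(params.sasa_gamma * (sasa_complex - sasa_alone).sum())


# ---------------------------------------------------------------------------
# decomposition, rescoring, pose selection
# ---------------------------------------------------------------------------


def decompose(
    complex_: ReceptorLigandComplex,
    params: EnergyParams | None = None,
    ligand_id: str = "ligand",
    pose_rank: int = 1,
) -> ResidueEnergyTable:
    """Full four-component per-residue decomposition for one geometry.

    Emits one row per receptor residue (in residue_order), including residues
    whose every component is zero.
    """
    if params is None:
        params = EnergyParams()
    ele = electrostatic_component(complex_, params)
    vdw = vdw_component(complex_, params)
    radii = born_radii(complex_.all_atoms(), params)
    gb = gb_component(complex_, radii, params)
    sa = sa_component(complex_, params)
    rows = pd.DataFrame(
        {
            "residue_index": [ri for ri, _ in complex_.residue_order],
            "residue_name": [rn for _, rn in complex_.residue_order],
            "dG_vdw": vdw,
            "dG_ele": ele,
            "dG_gb": gb,
            "dG_sa": sa,
        }
    )
    rows["dG_total"] = rows[["dG_vdw", "dG_ele", "dG_gb", "dG_sa"]].sum(axis=1)
    return ResidueEnergyTable(ligand_id=ligand_id, pose_rank=pose_rank, rows=rows)


def rescore_pose(
    complex_: ReceptorLigandComplex,
    pose_coords: np.ndarray,
    params: EnergyParams | None = None,
) -> float:
    """MM/GBSA rescoring: total interaction energy of a pose, kcal/mol."""
    table = decompose(complex_.with_ligand_coords(pose_coords), params)
    return float(table.rows["dG_total"].sum())


def select_pose(
    pose_set: PoseSet,
    complex_: ReceptorLigandComplex,
    params: EnergyParams | None = None,
    strategy: str = "top1",
) -> int:
    """Choose a pose rank: docking's top pose, or the best-rescored of the
    top three (ties to the lower rank)."""
    if not pose_set.poses:
        raise ValueError("empty pose set")
    if strategy == "top1":
        return 1
    if strategy == "best_of_top3":
        candidates = pose_set.poses[: min(3, len(pose_set.poses))]
        scores = [
            rescore_pose(complex_, p.ligand_coordinates, params) for p in candidates
        ]
        best = int(np.argmin(scores))  # argmin keeps first (lowest rank) on ties
        return candidates[best].pose_rank
    raise ValueError(f"unknown strategy '{strategy}' (use 'top1' or 'best_of_top3')")


# ---------------------------------------------------------------------------
# three-phase restrained minimization (toy force field)
# ---------------------------------------------------------------------------


def _toy_forcefield(
    complex_: ReceptorLigandComplex,
    params: EnergyParams,
    bonds: list[tuple[int, int, float, float]] | None,
    restraint_k: float,
    reference: np.ndarray,
):
    """Return energy+gradient callable over flat coordinates.

    Terms: Coulomb (eps_in) + LJ over non-bonded pairs within nb_cutoff,
    harmonic bonds k (r - r0)^2, harmonic positional restraints on backbone
    atoms toward ``reference``.
    """
    atoms = complex_.all_atoms()
    n = len(atoms)
    id_to_idx = {a.atom_id: i for i, a in enumerate(atoms)}
    q = np.array([a.charge for a in atoms])
    rh = np.array([a.lj_rmin_half for a in atoms])
    le = np.array([a.lj_epsilon for a in atoms])
    backbone = np.array([a.is_backbone for a in atoms])

    bond_idx = []
    bond_k = []
    bond_r0 = []
    excluded = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(excluded, True)
    if bonds:
        for a_id, b_id, kb, r0 in bonds:
            i, j = id_to_idx[a_id], id_to_idx[b_id]
            bond_idx.append((i, j))
            bond_k.append(kb)
            bond_r0.append(r0)
            excluded[i, j] = excluded[j, i] = True
    bond_idx = np.array(bond_idx, dtype=int).reshape(-1, 2)
    bond_k = np.array(bond_k)
    bond_r0 = np.array(bond_r0)

    qq = params.coulomb_constant * np.outer(q, q) / params.eps_in
    rmin = rh[:, None] + rh[None, :]
    epsij = np.sqrt(np.outer(le, le))
    iu = np.triu_indices(n, k=1)
    pair_mask = ~excluded[iu]

    cutoff = params.nb_cutoff

    def energy_and_grad(x: np.ndarray):
        xyz = x.reshape(n, 3)
        grad = np.zeros_like(xyz)
        e = 0.0

        dvec = xyz[iu[0]] - xyz[iu[1]]
        d = np.linalg.norm(dvec, axis=1)
        active = pair_mask & (d < cutoff if cutoff is not None else True)
        if np.any(d[pair_mask] == 0):
            raise SingularGeometryError("coincident atoms during minimization")
        ii, jj = iu[0][active], iu[1][active]
        dv, dd = dvec[active], d[active]
        # Coulomb
        qq_a = qq[ii, jj]
        e += float(np.sum(qq_a / dd))
        dEdr = -qq_a / dd**2
        # LJ
        s6 = (rmin[ii, jj] / dd) ** 6
        e += float(np.sum(epsij[ii, jj] * (s6 * s6 - 2.0 * s6)))
        dEdr += epsij[ii, jj] * 12.0 * (-(s6 * s6) + s6) / dd
        g = (dEdr / dd)[:, None] * dv
        np.add.at(grad, ii, g)
        np.add.at(grad, jj, -g)

        if len(bond_idx):
            bv = xyz[bond_idx[:, 0]] - xyz[bond_idx[:, 1]]
            bd = np.linalg.norm(bv, axis=1)
            e += float(np.sum(bond_k * (bd - bond_r0) ** 2))
            dEdr_b = 2.0 * bond_k * (bd - bond_r0)
            gb_ = (dEdr_b / bd)[:, None] * bv
            np.add.at(grad, bond_idx[:, 0], gb_)
            np.add.at(grad, bond_idx[:, 1], -gb_)

        if restraint_k > 0:
            disp = xyz[backbone] - reference.reshape(n, 3)[backbone]
            e += float(restraint_k * np.sum(disp**2))
            grad[backbone] += 2.0 * restraint_k * disp

        if not np.isfinite(e) or not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite energy or gradient")
        return e, grad.ravel()

    return energy_and_grad


def _steepest_descent(fun, x0, n_steps, gtol=1e-8):
    """Backtracking steepest descent; only energy-lowering steps accepted."""
    x = x0.copy()
    energies = []
    step = 0.02
    e, g = fun(x)
    energies.append(e)
    for _ in range(n_steps):
        gnorm = np.linalg.norm(g)
        if gnorm < gtol:
            break
        direction = -g / gnorm
        accepted = False
        while step > 1e-14:
            xn = x + step * direction
            try:
                en, gn = fun(xn)
            except (FloatingPointError, SingularGeometryError):
                step *= 0.5
                continue
            if en < e:
                x, e, g = xn, en, gn
                energies.append(e)
                step = min(step * 1.2, 1.0)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return x, np.array(energies)


def minimize(
    complex_: ReceptorLigandComplex,
    protocol: MinimizationProtocol | None = None,
    params: EnergyParams | None = None,
    bonds: list[tuple[int, int, float, float]] | None = None,
) -> MinimizationResult:
    """Three-phase restrained minimization of the whole complex.

    Each phase runs steepest descent then conjugate gradient under a harmonic
    positional restraint (stiffness = phase restraint_k) on backbone-flagged
    atoms, referenced to the input coordinates.  Bonds are
    (atom_id_a, atom_id_b, k, r0) harmonic terms; bonded pairs are excluded
    from the nonbonded sums.  Aborts with the failing step index on
    non-finite energies.
    """
    if protocol is None:
        protocol = MinimizationProtocol()
    if params is None:
        params = EnergyParams()

    atoms = complex_.all_atoms()
    x = np.array([a.xyz for a in atoms], dtype=float).ravel()
    reference = x.copy()

    trajectories: list[np.ndarray] = []
    fun0 = _toy_forcefield(complex_, params, bonds, protocol.phases[0][0], reference)
    initial_energy, _ = fun0(x)

    for phase_i, (k, n_sd, n_cg) in enumerate(protocol.phases):
        fun = _toy_forcefield(complex_, params, bonds, k, reference)
        phase_energies: list[float] = []
        try:
            x, sd_e = _steepest_descent(fun, x, n_sd)
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"phase {phase_i}: steepest descent failed: {exc}"
            ) from exc
        phase_energies.extend(sd_e.tolist())
        if n_cg > 0:
            cg_track: list[float] = []

            def _cb(xk, fun=fun, track=cg_track):
                track.append(fun(xk)[0])

            try:
                res = _scipy_minimize(
                    fun,
                    x,
                    jac=True,
                    method="CG",
                    callback=_cb,
                    options={"maxiter": n_cg, "gtol": 1e-8},
                )
            except (FloatingPointError, SingularGeometryError) as exc:
                raise FloatingPointError(
                    f"phase {phase_i}: conjugate gradient failed: {exc}"
                ) from exc
            # keep only energy-lowering accepted iterates
            e_now = phase_energies[-1] if phase_energies else fun(x)[0]
            if res.fun <= e_now:
                x = res.x
                for e in cg_track:
                    if e <= e_now:
                        phase_energies.append(e)
                        e_now = e
        trajectories.append(np.array(phase_energies))

    fun_final = _toy_forcefield(complex_, params, bonds, 0.0, reference)
    final_energy, _ = fun_final(x)
    new_complex = complex_.with_all_coords(x.reshape(-1, 3))
    return MinimizationResult(
        complex=new_complex,
        energy_trajectory=trajectories,
        initial_energy=float(initial_energy),
        final_energy=float(final_energy),
    )
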