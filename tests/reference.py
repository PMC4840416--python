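"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written as plain double loops over atoms /
sample pairs, sharing no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def coulomb_per_residue(complex_, params) -> dict[int, float]:
    out: dict[int, float] = {ri: 0.0 for ri, _ in complex_.residue_order}
    for a in complex_.receptor_atoms:
        for b in complex_.ligand_atoms:
            r = math.dist(a.xyz, b.xyz)
            out[a.residue_index] += (
                params.coulomb_constant * a.charge * b.charge / (params.eps_in * r)
            )
    return out


def lj_per_residue(complex_, params) -> dict[int, float]:
    out: dict[int, float] = {ri: 0.0 for ri, _ in complex_.residue_order}
    for a in complex_.receptor_atoms:
        for b in complex_.ligand_atoms:
            r = math.dist(a.xyz, b.xyz)
            rmin = a.lj_rmin_half + b.lj_rmin_half
            eps = math.sqrt(a.lj_epsilon * b.lj_epsilon)
            out[a.residue_index] += eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
    return out


def gb_per_residue(complex_, radii, params) -> dict[int, float]:
    out: dict[int, float] = {ri: 0.0 for ri, _ in complex_.residue_order}
    n_rec = len(complex_.receptor_atoms)
    pref = -(1.0 / params.eps_in - 1.0 / params.eps_out) * params.coulomb_constant
    for i, a in enumerate(complex_.receptor_atoms):
        for j, b in enumerate(complex_.ligand_atoms):
            r2 = sum((x - y) ** 2 for x, y in zip(a.xyz, b.xyz))
            Ri, Rj = radii[i], radii[n_rec + j]
            f = math.sqrt(r2 + Ri * Rj * math.exp(-r2 / (4.0 * Ri * Rj)))
            out[a.residue_index] += pref * a.charge * b.charge / f
    return out


def sasa_per_atom(atoms, params, points) -> np.ndarray:
    """Shrake-Rupley with a caller-supplied unit point set (matched oracle)."""
    out = np.zeros(len(atoms))
    for i, a in enumerate(atoms):
        ra = a.gb_radius + params.probe_radius
        exposed = 0
        for p in points:
            pos = np.asarray(a.xyz) + ra * np.asarray(p)
            buried = False
            for j, b in enumerate(atoms):
                if j == i:
                    continue
                rb = b.gb_radius + params.probe_radius
                if math.dist(pos, b.xyz) < rb:
                    buried = True
                    break
            if not buried:
                exposed += 1
        out[i] = exposed / len(points) * 4.0 * math.pi * ra**2
    return out


def descreening_integral_pair(d: float, rho_i: float, rho_j: float) -> float:
    """Numerical I = (1/4pi) int over ball(rho_j at distance d) of r^-4 dV,
    taken around atom i, for the non-overlapping case d > rho_i + rho_j.

    Axial symmetry: I = 1/2 int_{-1}^{1} (1/r_minus - 1/r_plus) du where
    r_+- solve r^2 - 2 d r u + d^2 = rho_j^2 along the ray at cos(theta)=u.
    """
    if d <= rho_i + rho_j:
        raise ValueError("only the non-overlapping case is integrated here")

    def integrand(u):
        disc = rho_j**2 - d**2 * (1.0 - u**2)
        if disc <= 0:
            return 0.0
        lo = d * u - math.sqrt(disc)
        hi = d * u + math.sqrt(disc)
        if hi <= 0:
            return 0.0
        lo = max(lo, 0.0)
        return 1.0 / lo - 1.0 / hi if lo > 0 else 0.0

    u_min = math.sqrt(max(0.0, 1.0 - (rho_j / d) ** 2))
    val, _ = quad(integrand, u_min, 1.0, limit=400, epsabs=1e-12, epsrel=1e-12)
    return 0.5 * val


def auc_pairwise(scores, labels) -> float:
    """AUC as the Mann-Whitney pair statistic (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def leader_clusters_bruteforce(fingerprints, threshold: float) -> list[int]:
    """Leader walk over a precomputed full pairwise similarity matrix."""
    n = len(fingerprints)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a = np.asarray(fingerprints[i], dtype=bool)
            b = np.asarray(fingerprints[j], dtype=bool)
            union = np.sum(a | b)
            sim[i, j] = (np.sum(a & b) / union) if union else 0.0
    leaders: list[int] = []
    assign = [-1] * n
    for i in range(n):
        for cid, li in enumerate(leaders):
            if sim[i, li] > threshold:
                assign[i] = cid
                break
        else:
            assign[i] = len(leaders)
            leaders.append(i)
    return assign


def confusion_formulas(tp, fp, tn, fn):
    """Direct spreadsheet-style evaluation of SE/SP/Q+/Q-/MCC."""
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    qp = tp / (tp + fp)
    qm = tn / (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    return se, sp, qp, qm, mcc
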