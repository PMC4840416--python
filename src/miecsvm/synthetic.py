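"""Seeded synthetic fixtures for every pipeline stage.

Nothing here attempts to mimic real kinase pockets or chemotypes; the
generators produce structurally valid, fully parameterized inputs whose
statistical structure matches the study conditions — a ~1:20
inhibitor:background imbalance, a subset of "vital" residues whose
interaction energies separate the classes, docking poses as rigid
perturbations of an input pose, and compound libraries whose descriptors
straddle the Lipinski boundaries.

Every generator is a deterministic function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import EnergyParams, rescore_pose
from .io import AtomRecord, Pose, PoseSet, ReceptorLigandComplex, ResidueEnergyTable
from .miec import COMPONENT_ORDER, MIECMatrix, build_matrix, get_combo
from .screening import FINGERPRINT_BITS, CompoundRecord

__all__ = [
    "SyntheticSpec",
    "MIECDataset",
    "make_toy_complex",
    "make_pose_set",
    "make_miec_dataset",
    "make_screening_library",
    "library_featurizer",
]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generators.

    Defaults follow the modelled screening scenario: a 30-residue pseudo
    pocket, a 1:20 inhibitor:non-inhibitor imbalance, ten signal-bearing
    residues, a 2 kcal/mol mean energy gap and 1 kcal/mol residue-energy
    noise.
    """

    n_residues: int = 30
    atoms_per_residue: int = 4
    n_ligand_atoms: int = 8
    n_inhibitors: int = 25
    n_noninhibitors: int = 500
    k_informative: int = 10
    effect_size: float = 2.0  # kcal/mol gap in mean total energy
    noise_sd: float = 1.0  # kcal/mol
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative > self.n_residues:
            raise ValueError("k_informative cannot exceed n_residues")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


# ---------------------------------------------------------------------------
# structures and poses
# ---------------------------------------------------------------------------


def make_toy_complex(spec: SyntheticSpec) -> ReceptorLigandComplex:
    """Pseudo-pocket: residues on a hemisphere around a central ligand.

    Half of the residues sit at contact range (4.5-6 A from the origin),
    the rest are distal (9-15 A), so distance decay of the interaction
    energies is testable.  Charges, Born radii and LJ parameters are drawn
    from bounded distributions; every atom is fully parameterized.
    """
    rng = np.random.default_rng(spec.seed)

    ligand_atoms = []
    for i in range(spec.n_ligand_atoms):
        xyz = rng.normal(0.0, 0.8, size=3)
        ligand_atoms.append(
            AtomRecord(
                atom_id=10000 + i + 1,
                name=f"L{i + 1}",
                residue_index=0,
                residue_name="LIG",
                chain_tag="L",
                xyz=xyz,
                charge=float(rng.uniform(-0.4, 0.4)),
                gb_radius=float(rng.uniform(1.3, 1.8)),
                lj_rmin_half=float(rng.uniform(1.4, 1.9)),
                lj_epsilon=float(rng.uniform(0.05, 0.2)),
            )
        )

    receptor_atoms = []
    residue_order = []
    atom_id = 0
    n_contact = spec.n_residues - spec.n_residues // 2
    for r in range(spec.n_residues):
        # hemisphere direction (z >= 0)
        v = rng.normal(size=3)
        v[2] = abs(v[2])
        v /= np.linalg.norm(v)
        dist = rng.uniform(4.5, 6.0) if r < n_contact else rng.uniform(9.0, 15.0)
        center = v * dist
        resname = f"R{r + 1:02d}"
        residue_order.append((r, resname))
        for a in range(spec.atoms_per_residue):
            atom_id += 1
            receptor_atoms.append(
                AtomRecord(
                    atom_id=atom_id,
                    name=f"A{a + 1}",
                    residue_index=r,
                    residue_name=resname,
                    chain_tag="A",
                    xyz=center + rng.normal(0.0, 0.7, size=3),
                    charge=float(rng.uniform(-0.5, 0.5)),
                    gb_radius=float(rng.uniform(1.2, 1.9)),
                    lj_rmin_half=float(rng.uniform(1.4, 2.0)),
                    lj_epsilon=float(rng.uniform(0.05, 0.2)),
                    is_backbone=(a == 0),
                )
            )
    return ReceptorLigandComplex(receptor_atoms, ligand_atoms, residue_order)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_pose_set(
    complex_: ReceptorLigandComplex,
    n_poses: int = 3,
    jitter_sd: float = 0.5,
    seed: int = 0,
    params: EnergyParams | None = None,
    ligand_id: str = "ligand",
) -> PoseSet:
    """Docking-pose stand-in: pose 1 is the input geometry, later poses are
    rigid jitters (small rotation about the centroid + translation); docking
    scores are the MM/GBSA rescoring totals plus seeded noise."""
    rng = np.random.default_rng(seed)
    base = complex_.ligand_coords()
    centroid = base.mean(axis=0)
    poses = []
    for rank in range(1, n_poses + 1):
        if rank == 1 or jitter_sd == 0.0:
            coords = base.copy()
        else:
            angle_scale = min(jitter_sd, 1.0)
            R = _random_rotation(rng)
            # blend toward identity for small jitter
            R = (1 - angle_scale) * np.eye(3) + angle_scale * R
            u, _, vt = np.linalg.svd(R)
            R = u @ vt
            shift = rng.normal(0.0, jitter_sd, size=3)
            coords = (base - centroid) @ R.T + centroid + shift
        score = rescore_pose(complex_, coords, params) + float(
            rng.normal(0.0, 0.5)
        )
        poses.append(Pose(pose_rank=rank, ligand_coordinates=coords, docking_score=score))
    return PoseSet(ligand_id=ligand_id, poses=poses)


# ---------------------------------------------------------------------------
# MIEC-level signal planting
# ---------------------------------------------------------------------------


@dataclass
class MIECDataset:
    """Synthetic per-sample energy tables with class-separating residues."""

    spec: SyntheticSpec
    tables: list[ResidueEnergyTable]
    labels: np.ndarray  # +1 / -1
    sample_ids: list[str]
    informative_residues: list[int]
    residue_baseline: np.ndarray = field(repr=False)

    def matrix(self, residue_ids=None, combo="all4") -> MIECMatrix:
        if residue_ids is None:
            residue_ids = list(range(self.spec.n_residues))
        return build_matrix(
            self.tables, self.labels, list(residue_ids), combo, self.sample_ids
        )


def _sample_component_energies(
    rng: np.random.Generator, mean_total: np.ndarray, noise_sd: float
) -> np.ndarray:
    """Split per-residue total means across the four components with noise.

    Each component carries a quarter of the mean and half of the noise SD,
    so the summed total has SD = noise_sd.
    """
    n_res = len(mean_total)
    comp = np.empty((n_res, 4))
    for c in range(4):
        comp[:, c] = rng.normal(mean_total / 4.0, noise_sd / 2.0)
    return comp


def make_miec_dataset(spec: SyntheticSpec) -> MIECDataset:
    """Energy tables for n_inhibitors + n_noninhibitors samples.

    Each residue has a baseline mean total energy drawn once from
    U(-2, 0) kcal/mol (shared by both classes).  The ``k_informative``
    randomly chosen residues additionally contribute ``-effect_size`` to
    inhibitor samples only, spread evenly over the four components; all
    other columns are identically distributed across classes.
    """
    rng = np.random.default_rng(spec.seed)
    baseline = rng.uniform(-2.0, 0.0, size=spec.n_residues)
    informative = sorted(
        rng.choice(spec.n_residues, size=spec.k_informative, replace=False).tolist()
    )
    shift = np.zeros(spec.n_residues)
    shift[informative] = -spec.effect_size

    labels = np.concatenate(
        [np.ones(spec.n_inhibitors, dtype=int), -np.ones(spec.n_noninhibitors, dtype=int)]
    )
    sample_ids = [
        f"inh{i + 1:04d}" for i in range(spec.n_inhibitors)
    ] + [f"bg{i + 1:04d}" for i in range(spec.n_noninhibitors)]

    tables = []
    for sid, lab in zip(sample_ids, labels):
        mean_total = baseline + (shift if lab == 1 else 0.0)
        comp = _sample_component_energies(rng, mean_total, spec.noise_sd)
        rows = pd.DataFrame(
            {
                "residue_index": np.arange(spec.n_residues),
                "residue_name": [f"R{r + 1:02d}" for r in range(spec.n_residues)],
                "dG_ele": comp[:, 0],
                "dG_vdw": comp[:, 1],
                "dG_gb": comp[:, 2],
                "dG_sa": comp[:, 3],
            }
        )
        rows["dG_total"] = rows[["dG_vdw", "dG_ele", "dG_gb", "dG_sa"]].sum(axis=1)
        tables.append(ResidueEnergyTable(ligand_id=sid, pose_rank=1, rows=rows))

    return MIECDataset(
        spec=spec,
        tables=tables,
        labels=labels,
        sample_ids=sample_ids,
        informative_residues=informative,
        residue_baseline=baseline,
    )


# ---------------------------------------------------------------------------
# screening libraries
# ---------------------------------------------------------------------------


def _feature_row(
    rng: np.random.Generator, template: MIECDataset, is_active: bool
) -> np.ndarray:
    spec = template.spec
    shift = np.zeros(spec.n_residues)
    if is_active:
        shift[template.informative_residues] = -spec.effect_size
    mean_total = template.residue_baseline + shift
    comp = _sample_component_energies(rng, mean_total, spec.noise_sd)
    # residue-major (ele, vdw, gb, sa) — matches build_matrix on "all4"
    return comp.ravel()


def make_screening_library(
    n: int,
    n_planted_actives: int,
    seed: int,
    template: MIECDataset,
    similarity_block_size: int = 1,
) -> tuple[list[CompoundRecord], dict[str, np.ndarray], list[str]]:
    """Compound library with descriptors, fingerprints and MIEC features.

    Planted actives draw their MIEC feature rows from the template's
    inhibitor distribution, get modestly better docking scores and drug-like
    descriptors; background compounds draw from the non-inhibitor
    distribution with descriptors straddling the Lipinski boundaries.
    ``similarity_block_size > 1`` groups background fingerprints into blocks
    of near-duplicates (pairwise Tanimoto > 0.8) to exercise clustering.

    Returns (records, features_by_id, planted_ids); features are full
    all4-combo rows over every template residue.
    """
    rng = np.random.default_rng(seed)
    records: list[CompoundRecord] = []
    features: dict[str, np.ndarray] = {}
    planted_ids: list[str] = []

    block_proto: np.ndarray | None = None
    block_left = 0
    for i in range(n):
        cid = f"cmpd{i + 1:05d}"
        is_active = i < n_planted_actives
        if is_active:
            planted_ids.append(cid)
            docking = float(rng.normal(-9.0, 0.8))
            mw = float(rng.uniform(320.0, 480.0))
            logp = float(rng.uniform(1.0, 4.5))
            hbd = int(rng.integers(0, 4))
            hba = int(rng.integers(2, 8))
            fp = rng.random(FINGERPRINT_BITS) < 0.3
        else:
            docking = float(rng.normal(-7.0, 1.0))
            mw = float(rng.normal(480.0, 120.0))
            logp = float(rng.normal(4.0, 1.8))
            hbd = int(rng.integers(0, 9))
            hba = int(rng.integers(0, 14))
            if similarity_block_size > 1:
                if block_left == 0:
                    block_proto = rng.random(FINGERPRINT_BITS) < 0.5
                    block_left = similarity_block_size
                fp = block_proto.copy()
                flip = rng.choice(FINGERPRINT_BITS, size=2, replace=False)
                fp[flip] = ~fp[flip]
                block_left -= 1
            else:
                fp = rng.random(FINGERPRINT_BITS) < 0.3
        records.append(
            CompoundRecord(
                compound_id=cid,
                docking_score=docking,
                MW=mw,
                logP=logp,
                HBD=hbd,
                HBA=hba,
                fingerprint=fp,
            )
        )
        features[cid] = _feature_row(rng, template, is_active)

    return records, features, planted_ids


def library_featurizer(
    features_by_id: dict[str, np.ndarray],
    residue_ids: list[int],
    combo="all4",
):
    """Callable mapping compound ids to the model's feature schema.

    Library feature rows are stored residue-major over *all* template
    residues with all four components; this slices out the columns for the
    chosen top residues and component combo, in the same order
    :func:`miecsvm.miec.build_matrix` uses.
    """
    combo = get_combo(combo)
    comp_pos = {c: k for k, c in enumerate(COMPONENT_ORDER)}
    cols = [
        ri * len(COMPONENT_ORDER) + comp_pos[c]
        for ri in residue_ids
        for c in combo.members
    ]

    def featurize(compound_ids: list[str]) -> np.ndarray:
        return np.array([features_by_id[cid][cols] for cid in compound_ids])

    return featurize
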