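"""Readers and writers for receptor-ligand structures, docking poses and
per-residue interaction-energy tables.

File formats (UTF-8, whitespace/tab separated, ``.`` decimal separator):

Structure — PQR dialect, one ``ATOM`` record per atom::

    ATOM <atom_id> <name> <residue_name> <chain> <residue_seq> <x> <y> <z> <charge> <gb_radius>

``residue_seq`` is 1-based in files and 0-based internally.  Ligand atoms
carry the residue name ``LIG``; everything else is receptor.  Coordinates are
Cartesian angstroms with no periodic cell.

Lennard-Jones parameters and backbone membership do not fit in a PQR record,
so they travel in a sidecar TSV with columns
``residue_name  atom_name  lj_rmin_half  lj_epsilon  is_backbone``.

Poses — a multi-``MODEL`` coordinate file (``MODEL n`` / ``ATOM`` records /
``ENDMDL``) plus a TSV score table with columns ``pose_rank  docking_score``.

Energy tables — TSV with header
``residue_index  residue_name  dG_vdw  dG_ele  dG_gb  dG_sa  dG_total``
(1-based residue indices in the file, 0-based in memory).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ReceptorLigandComplex",
    "Pose",
    "PoseSet",
    "ResidueEnergyTable",
    "ComplexFormatError",
    "ParameterLookupError",
    "read_complex",
    "write_complex",
    "read_pose_set",
    "write_pose_set",
    "read_energy_table",
    "write_energy_table",
]

LIGAND_RESIDUE_NAME = "LIG"

ENERGY_TABLE_COLUMNS = [
    "residue_index",
    "residue_name",
    "dG_vdw",
    "dG_ele",
    "dG_gb",
    "dG_sa",
    "dG_total",
]

ADDITIVITY_TOL = 1e-9


class ComplexFormatError(ValueError):
    """Malformed structure / pose / table record (reported with line number)."""


class ParameterLookupError(KeyError):
    """An atom has no row in the Lennard-Jones parameter table."""


@dataclass
class AtomRecord:
    """One atom: identity, coordinates and nonbonded parameters.

    ``gb_radius`` is the intrinsic Born radius rho (A), ``lj_rmin_half`` the
    Lennard-Jones Rmin/2 (A) and ``lj_epsilon`` the well depth (kcal/mol).
    """

    atom_id: int
    name: str
    residue_index: int
    residue_name: str
    chain_tag: str
    xyz: np.ndarray
    charge: float
    gb_radius: float
    lj_rmin_half: float
    lj_epsilon: float
    is_backbone: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError(f"atom {self.atom_id}: xyz must be a 3-vector")
        if self.atom_id < 1:
            raise ValueError(f"atom_id must be >= 1, got {self.atom_id}")
        if self.residue_index < 0:
            raise ValueError(f"atom {self.atom_id}: residue_index must be >= 0")
        if not self.gb_radius > 0:
            raise ValueError(f"atom {self.atom_id}: gb_radius must be > 0")
        if self.lj_rmin_half < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.atom_id}: LJ parameters must be >= 0")


@dataclass
class ReceptorLigandComplex:
    """Receptor atoms grouped into residues plus one ligand.

    ``residue_order`` fixes the order in which residues appear in every
    per-residue quantity downstream (energy tables, feature columns).
    """

    receptor_atoms: list[AtomRecord]
    ligand_atoms: list[AtomRecord]
    residue_order: list[tuple[int, str]]

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.receptor_atoms + self.ligand_atoms]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate atom_id(s): {dup}")
        indices = [ri for ri, _ in self.residue_order]
        if len(indices) != len(set(indices)):
            raise ValueError("residue_order contains duplicate residue indices")
        known = set(indices)
        for a in self.receptor_atoms:
            if a.residue_index not in known:
                raise ValueError(
                    f"receptor atom {a.atom_id} has residue_index "
                    f"{a.residue_index} absent from residue_order"
                )

    def receptor_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.receptor_atoms], dtype=float)

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.ligand_atoms], dtype=float)

    def all_atoms(self) -> list[AtomRecord]:
        return list(self.receptor_atoms) + list(self.ligand_atoms)

    def residue_of_receptor_atoms(self) -> np.ndarray:
        """Position of each receptor atom's residue within residue_order."""
        pos = {ri: k for k, (ri, _) in enumerate(self.residue_order)}
        return np.array([pos[a.residue_index] for a in self.receptor_atoms])

    def with_ligand_coords(self, coords: np.ndarray) -> "ReceptorLigandComplex":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.ligand_atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.ligand_atoms)} ligand atoms"
            )
        new_lig = [
            AtomRecord(**{**a.__dict__, "xyz": xyz.copy()})
            for a, xyz in zip(self.ligand_atoms, coords)
        ]
        return ReceptorLigandComplex(
            receptor_atoms=list(self.receptor_atoms),
            ligand_atoms=new_lig,
            residue_order=list(self.residue_order),
        )

    def with_all_coords(self, coords: np.ndarray) -> "ReceptorLigandComplex":
        coords = np.asarray(coords, dtype=float)
        n_rec = len(self.receptor_atoms)
        if coords.shape != (n_rec + len(self.ligand_atoms), 3):
            raise ValueError("coordinate array does not match atom count")
        new_rec = [
            AtomRecord(**{**a.__dict__, "xyz": coords[i].copy()})
            for i, a in enumerate(self.receptor_atoms)
        ]
        new_lig = [
            AtomRecord(**{**a.__dict__, "xyz": coords[n_rec + i].copy()})
            for i, a in enumerate(self.ligand_atoms)
        ]
        return ReceptorLigandComplex(new_rec, new_lig, list(self.residue_order))


@dataclass
class Pose:
    pose_rank: int
    ligand_coordinates: np.ndarray  # N x 3, A
    docking_score: float  # kcal/mol

    def __post_init__(self) -> None:
        self.ligand_coordinates = np.asarray(self.ligand_coordinates, dtype=float)


@dataclass
class PoseSet:
    """Docking poses for one ligand, sorted by pose_rank ascending."""

    ligand_id: str
    poses: list[Pose]

    def __post_init__(self) -> None:
        self.poses = sorted(self.poses, key=lambda p: p.pose_rank)
        ranks = [p.pose_rank for p in self.poses]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"pose ranks must be contiguous from 1, got {ranks}")
        counts = {p.ligand_coordinates.shape[0] for p in self.poses}
        if len(counts) > 1:
            raise ValueError(f"poses disagree on atom count: {sorted(counts)}")


@dataclass
class ResidueEnergyTable:
    """Per-residue interaction energy components for one pose (kcal/mol).

    The total of every row equals the sum of its four components; this is
    enforced on construction and again before writing.
    """

    ligand_id: str
    pose_rank: int
    rows: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        missing = [c for c in ENERGY_TABLE_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"energy table missing columns: {missing}")
        self.rows = self.rows[ENERGY_TABLE_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        comp_sum = (
            self.rows["dG_vdw"]
            + self.rows["dG_ele"]
            + self.rows["dG_gb"]
            + self.rows["dG_sa"]
        )
        bad = (comp_sum - self.rows["dG_total"]).abs() > ADDITIVITY_TOL
        if bad.any():
            res = self.rows.loc[bad, "residue_index"].tolist()
            raise ValueError(
                f"additivity violated (|sum - total| > {ADDITIVITY_TOL}) "
                f"for residue(s) {res}"
            )

    def totals(self) -> pd.Series:
        return self.rows.set_index("residue_index")["dG_total"]


# ---------------------------------------------------------------------------
# structure IO
# ---------------------------------------------------------------------------

# ATOM id name resname chain resseq x y z charge radius
_N_STRUCTURE_FIELDS = 11


def _read_params_table(params_path: Path):
    df = pd.read_csv(params_path, sep="\t")
    required = {"residue_name", "atom_name", "lj_rmin_half", "lj_epsilon", "is_backbone"}
    missing = required - set(df.columns)
    if missing:
        raise ComplexFormatError(f"{params_path}: missing columns {sorted(missing)}")
    table = {}
    for _, row in df.iterrows():
        table[(str(row["residue_name"]), str(row["atom_name"]))] = (
            float(row["lj_rmin_half"]),
            float(row["lj_epsilon"]),
            bool(row["is_backbone"]),
        )
    return table


def read_complex(structure_path, params_path) -> ReceptorLigandComplex:
    """Read a PQR-dialect structure plus its LJ/backbone parameter table.

    Every atom must have a parameter row; an atom with no parameters raises
    :class:`ParameterLookupError` rather than being silently defaulted.
    """
    structure_path = Path(structure_path)
    params_path = Path(params_path)
    params = _read_params_table(params_path)

    receptor: list[AtomRecord] = []
    ligand: list[AtomRecord] = []
    residue_order: list[tuple[int, str]] = []
    seen_residues: dict[int, str] = {}

    with open(structure_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "REMARK", "END")):
                continue
            fields = stripped.split()
            if fields[0] != "ATOM":
                raise ComplexFormatError(
                    f"{structure_path}:{lineno}: unexpected record '{fields[0]}'"
                )
            if len(fields) != _N_STRUCTURE_FIELDS:
                raise ComplexFormatError(
                    f"{structure_path}:{lineno}: expected "
                    f"{_N_STRUCTURE_FIELDS} fields, got {len(fields)}"
                )
            try:
                atom_id = int(fields[1])
                name = fields[2]
                resname = fields[3]
                chain = fields[4]
                resseq = int(fields[5])
                xyz = np.array([float(fields[6]), float(fields[7]), float(fields[8])])
                charge = float(fields[9])
                gb_radius = float(fields[10])
            except ValueError as exc:
                raise ComplexFormatError(
                    f"{structure_path}:{lineno}: {exc}"
                ) from exc

            key = (resname, name)
            if key not in params:
                raise ParameterLookupError(
                    f"atom {atom_id} ({resname}/{name}) has no row in the "
                    f"parameter table {params_path}"
                )
            rmin_half, epsilon, is_backbone = params[key]
            atom = AtomRecord(
                atom_id=atom_id,
                name=name,
                residue_index=resseq - 1,
                residue_name=resname,
                chain_tag=chain,
                xyz=xyz,
                charge=charge,
                gb_radius=gb_radius,
                lj_rmin_half=rmin_half,
                lj_epsilon=epsilon,
                is_backbone=is_backbone,
            )
            if resname == LIGAND_RESIDUE_NAME:
                ligand.append(atom)
            else:
                receptor.append(atom)
                if atom.residue_index not in seen_residues:
                    seen_residues[atom.residue_index] = resname
                    residue_order.append((atom.residue_index, resname))

    return ReceptorLigandComplex(receptor, ligand, residue_order)


def write_complex(complex_: ReceptorLigandComplex, structure_path, params_path) -> None:
    """Write structure + parameter table; inverse of :func:`read_complex`."""
    structure_path = Path(structure_path)
    params_path = Path(params_path)

    with open(structure_path, "w", encoding="utf-8") as fh:
        fh.write("# PQR dialect: ATOM id name resname chain resseq(1-based) "
                 "x y z charge gb_radius\n")
        for a in complex_.all_atoms():
            fh.write(
                f"ATOM {a.atom_id} {a.name} {a.residue_name} {a.chain_tag} "
                f"{a.residue_index + 1} {a.xyz[0]:.6f} {a.xyz[1]:.6f} "
                f"{a.xyz[2]:.6f} {a.charge:.6f} {a.gb_radius:.6f}\n"
            )

    rows = []
    seen = set()
    for a in complex_.all_atoms():
        key = (a.residue_name, a.name)
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {
                "residue_name": a.residue_name,
                "atom_name": a.name,
                "lj_rmin_half": a.lj_rmin_half,
                "lj_epsilon": a.lj_epsilon,
                "is_backbone": a.is_backbone,
            }
        )
    pd.DataFrame(rows).to_csv(params_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pose IO
# ---------------------------------------------------------------------------


def read_pose_set(path, score_table, ligand_id: str = "ligand") -> PoseSet:
    """Read a multi-MODEL coordinate file and its docking-score table.

    Raises :class:`ComplexFormatError` if the number of models and the number
    of score rows disagree.
    """
    path = Path(path)
    scores = pd.read_csv(score_table, sep="\t")
    for col in ("pose_rank", "docking_score"):
        if col not in scores.columns:
            raise ComplexFormatError(f"{score_table}: missing column '{col}'")
    score_by_rank = dict(
        zip(scores["pose_rank"].astype(int), scores["docking_score"].astype(float))
    )

    models: list[tuple[int, np.ndarray]] = []
    current_rank = None
    current: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            tag = fields[0]
            if tag == "MODEL":
                if current_rank is not None:
                    raise ComplexFormatError(f"{path}:{lineno}: nested MODEL")
                try:
                    current_rank = int(fields[1])
                except (IndexError, ValueError) as exc:
                    raise ComplexFormatError(f"{path}:{lineno}: bad MODEL record") from exc
                current = []
            elif tag == "ATOM":
                if current_rank is None:
                    raise ComplexFormatError(f"{path}:{lineno}: ATOM outside MODEL")
                try:
                    current.append([float(fields[-3]), float(fields[-2]), float(fields[-1])])
                except ValueError as exc:
                    raise ComplexFormatError(f"{path}:{lineno}: {exc}") from exc
            elif tag == "ENDMDL":
                if current_rank is None:
                    raise ComplexFormatError(f"{path}:{lineno}: ENDMDL outside MODEL")
                models.append((current_rank, np.array(current, dtype=float)))
                current_rank = None
            elif tag == "END":
                continue
            else:
                raise ComplexFormatError(f"{path}:{lineno}: unexpected record '{tag}'")
    if current_rank is not None:
        raise ComplexFormatError(f"{path}: MODEL {current_rank} not closed")

    if len(models) != len(score_by_rank):
        raise ComplexFormatError(
            f"pose count mismatch: {len(models)} models in {path} but "
            f"{len(score_by_rank)} scores in {score_table}"
        )
    poses = []
    for rank, coords in models:
        if rank not in score_by_rank:
            raise ComplexFormatError(f"no docking score for pose_rank {rank}")
        poses.append(Pose(rank, coords, score_by_rank[rank]))
    return PoseSet(ligand_id=ligand_id, poses=poses)


def write_pose_set(pose_set: PoseSet, path, score_table) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for pose in pose_set.poses:
            fh.write(f"MODEL {pose.pose_rank}\n")
            for i, xyz in enumerate(pose.ligand_coordinates, start=1):
                fh.write(
                    f"ATOM {i} X {LIGAND_RESIDUE_NAME} L 1 "
                    f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
    pd.DataFrame(
        {
            "pose_rank": [p.pose_rank for p in pose_set.poses],
            "docking_score": [p.docking_score for p in pose_set.poses],
        }
    ).to_csv(score_table, sep="\t", index=False)


# ---------------------------------------------------------------------------
# energy table IO
# ---------------------------------------------------------------------------


def write_energy_table(table: ResidueEnergyTable, path) -> None:
    """Write a TSV energy table (1-based residue indices in the file)."""
    table.validate()
    out = table.rows.copy()
    out["residue_index"] = out["residue_index"].astype(int) + 1
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# ligand_id={table.ligand_id} pose_rank={table.pose_rank}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_energy_table(path) -> ResidueEnergyTable:
    path = Path(path)
    ligand_id, pose_rank = "ligand", 1
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        meta = dict(
            kv.split("=", 1) for kv in first.lstrip("# ").split() if "=" in kv
        )
        ligand_id = meta.get("ligand_id", ligand_id)
        pose_rank = int(meta.get("pose_rank", pose_rank))
    rows = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ENERGY_TABLE_COLUMNS if c not in rows.columns]
    if missing:
        raise ComplexFormatError(f"{path}: missing columns {missing}")
    rows["residue_index"] = rows["residue_index"].astype(int) - 1
    return ResidueEnergyTable(ligand_id=ligand_id, pose_rank=pose_rank, rows=rows)
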