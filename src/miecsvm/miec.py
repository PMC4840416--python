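"""MIEC feature-matrix assembly.

Residues are ranked by their mean total interaction energy over the known
inhibitors (most favourable, i.e. most negative, first), the top k are kept,
and the per-residue energy components are concatenated residue-major into a
samples x (k * m) feature matrix.  Features stay raw kcal/mol energies — no
scaling or dimension reduction — so every column keeps its physical meaning.

Five component combinations are supported: the four two-component pairings
(ele+vdw, gb+sa, ele+gb, vdw+sa) and all four components together; with
k in {20, 25, 30} and two pose strategies this yields the 30 model protocols
enumerated by :func:`enumerate_protocols`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ResidueEnergyTable

__all__ = [
    "COMPONENT_ORDER",
    "COMBOS",
    "ComponentCombo",
    "ResidueRanking",
    "MIECMatrix",
    "rank_residues",
    "select_top_k",
    "build_matrix",
    "enumerate_protocols",
    "POSE_STRATEGIES",
    "K_VALUES",
]

COMPONENT_ORDER = ("ele", "vdw", "gb", "sa")
_COMPONENT_COLUMN = {"ele": "dG_ele", "vdw": "dG_vdw", "gb": "dG_gb", "sa": "dG_sa"}

POSE_STRATEGIES = ("top1", "best_of_top3")
K_VALUES = (20, 25, 30)


@dataclass(frozen=True)
class ComponentCombo:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        for m in self.members:
            if m not in COMPONENT_ORDER:
                raise ValueError(f"unknown component '{m}'")
        # keep the fixed component order regardless of how members were given
        ordered = tuple(c for c in COMPONENT_ORDER if c in self.members)
        object.__setattr__(self, "members", ordered)


COMBOS: dict[str, ComponentCombo] = {
    "ele+vdw": ComponentCombo("ele+vdw", ("ele", "vdw")),
    "gb+sa": ComponentCombo("gb+sa", ("gb", "sa")),
    "ele+gb": ComponentCombo("ele+gb", ("ele", "gb")),
    "vdw+sa": ComponentCombo("vdw+sa", ("vdw", "sa")),
    "all4": ComponentCombo("all4", COMPONENT_ORDER),
}


def get_combo(combo: str | ComponentCombo) -> ComponentCombo:
    if isinstance(combo, ComponentCombo):
        return combo
    try:
        return COMBOS[combo]
    except KeyError:
        raise ValueError(
            f"unknown combo '{combo}'; expected one of {sorted(COMBOS)}"
        ) from None


@dataclass
class ResidueRanking:
    """Residues ordered by mean inhibitor interaction energy (ascending)."""

    entries: list[tuple[int, float]]  # (residue_index, mean_total_energy)

    def __post_init__(self) -> None:
        means = [m for _, m in self.entries]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ValueError("ranking must be sorted ascending by mean energy")

    def residue_ids(self) -> list[int]:
        return [ri for ri, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MIECMatrix:
    """Samples x (k residues x m components) energy feature matrix."""

    sample_ids: list[str]
    labels: np.ndarray  # +1 inhibitor / -1 non-inhibitor
    features: np.ndarray  # n_samples x (k * m), kcal/mol
    residue_ids: list[int]
    combo: ComponentCombo

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.features = np.asarray(self.features, dtype=float)
        n = len(self.sample_ids)
        if self.labels.shape != (n,):
            raise ValueError("label/sample count mismatch")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 or -1")
        expected = len(self.residue_ids) * len(self.combo.members)
        if self.features.shape != (n, expected):
            raise ValueError(
                f"feature matrix shape {self.features.shape} != "
                f"({n}, {expected}) for k={len(self.residue_ids)} "
                f"x m={len(self.combo.members)}"
            )

    @property
    def feature_names(self) -> list[str]:
        return [
            f"res{ri}_{comp}" for ri in self.residue_ids for comp in self.combo.members
        ]

    def subset(self, idx: np.ndarray) -> "MIECMatrix":
        idx = np.asarray(idx)
        return MIECMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            features=self.features[idx],
            residue_ids=list(self.residue_ids),
            combo=self.combo,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, combo: str | ComponentCombo) -> "MIECMatrix":
        combo = get_combo(combo)
        feat_cols = [c for c in df.columns if c not in ("sample_id", "label")]
        m = len(combo.members)
        residue_ids = [int(c.split("_")[0][3:]) for c in feat_cols[::m]]
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            labels=df["label"].to_numpy(),
            features=df[feat_cols].to_numpy(dtype=float),
            residue_ids=residue_ids,
            combo=combo,
        )


def rank_residues(tables: list[ResidueEnergyTable]) -> ResidueRanking:
    """Rank residues by mean total energy over the inhibitor tables.

    All tables must share the residue set.  Most negative mean first; ties
    broken by lower residue index.
    """
    if not tables:
        raise ValueError("need at least one inhibitor energy table")
    ref = set(tables[0].rows["residue_index"])
    totals = []
    for t in tables:
        s = t.totals()
        if set(s.index) != ref:
            raise ValueError(
                f"table for {t.ligand_id} has a different residue set"
            )
        totals.append(s)
    mean = pd.concat(totals, axis=1).mean(axis=1)
    ordered = sorted(mean.items(), key=lambda kv: (kv[1], kv[0]))
    return ResidueRanking([(int(ri), float(m)) for ri, m in ordered])


def select_top_k(ranking: ResidueRanking, k: int) -> list[int]:
    """First k residue indices of the ranking (the 'top contributed')."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds ranking length {len(ranking)}")
    return ranking.residue_ids()[:k]


def build_matrix(
    tables: list[ResidueEnergyTable],
    labels,
    residue_ids: list[int],
    combo: str | ComponentCombo,
    sample_ids: list[str] | None = None,
) -> MIECMatrix:
    """Assemble the residue-major feature matrix for the chosen combo.

    Column order is residue-major with components in the fixed order
    (ele, vdw, gb, sa) filtered by the combo.  A sample table missing any of
    the selected residues is an error.
    """
    combo = get_combo(combo)
    labels = np.asarray(labels, dtype=int)
    if len(tables) != len(labels):
        raise ValueError(
            f"label/sample count mismatch: {len(tables)} tables, {len(labels)} labels"
        )
    if sample_ids is None:
        sample_ids = [t.ligand_id for t in tables]
    cols = [_COMPONENT_COLUMN[c] for c in combo.members]
    rows = []
    for t in tables:
        indexed = t.rows.set_index("residue_index")
        missing = [ri for ri in residue_ids if ri not in indexed.index]
        if missing:
            raise ValueError(
                f"table for {t.ligand_id} is missing residue(s) {missing}"
            )
        rows.append(indexed.loc[residue_ids, cols].to_numpy(dtype=float).ravel())
    return MIECMatrix(
        sample_ids=list(sample_ids),
        labels=labels,
        features=np.array(rows),
        residue_ids=list(residue_ids),
        combo=combo,
    )


def enumerate_protocols(
    k_values: tuple[int, ...] = K_VALUES,
    combos: tuple[str, ...] = tuple(COMBOS),
    pose_strategies: tuple[str, ...] = POSE_STRATEGIES,
) -> list[tuple[int, str, str]]:
    """All (k, combo, pose_strategy) model protocols in deterministic order.

    With the defaults this is the full 3 x 5 x 2 = 30 protocol sweep.
    """
    return [
        (k, combo, strategy)
        for strategy in pose_strategies
        for k in k_values
        for combo in combos
    ]
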