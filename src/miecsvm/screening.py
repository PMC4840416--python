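"""Hierarchical virtual-screening stage.

The pipeline mirrors the practical constraint that per-residue energy
decomposition is expensive while docking scores are cheap:

1. keep the ``prefilter_n`` best docking scores from the library,
2. score that pool with the fitted MIEC-SVM model and keep the top
   ``rank_pool_n`` by the chosen rank criterion (SVM inhibitor probability,
   or docking score for the baseline arm),
3. drop compounds with two or more violations of Lipinski's rules of five
   (MW > 500, logP > 5, H-bond donors > 5, acceptors > 10),
4. cluster the survivors by MACCS-style fingerprint Tanimoto similarity at
   0.80 to maximize chemical diversity, and
5. return the top ``final_n`` cluster leaders.

Clustering uses a leader algorithm on the ranked list: walking best-first,
each compound joins the first cluster whose leader is more similar than the
threshold, else founds a new cluster.  This makes "the top molecule in each
group" canonical by construction; single-linkage is available behind
``method="single"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "ScreeningConfig",
    "prefilter_by_docking",
    "lipinski_violations",
    "tanimoto",
    "cluster_by_similarity",
    "select_final",
    "run_screen",
]

FINGERPRINT_BITS = 166  # MACCS-style key count


@dataclass
class CompoundRecord:
    """One library compound with docking score, descriptors and fingerprint."""

    compound_id: str
    docking_score: float  # kcal/mol, lower is better
    MW: float | None = None  # Da
    logP: float | None = None
    HBD: int | None = None
    HBA: int | None = None
    fingerprint: np.ndarray | None = None  # fixed-length boolean bit set
    svm_probability: float | None = None
    logS: float | None = None
    drug_likeness: float | None = None  # optional external score hook
    cluster_id: int | None = None
    final_rank: int | None = None

    def __post_init__(self) -> None:
        if self.fingerprint is not None:
            self.fingerprint = np.asarray(self.fingerprint, dtype=bool)
        for name in ("HBD", "HBA"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.compound_id}: {name} must be >= 0")


@dataclass
class ScreeningConfig:
    prefilter_n: int = 30000
    rank_pool_n: int = 300
    lipinski_max_violations: int = 1  # >= 2 violations eliminated
    tanimoto_threshold: float = 0.80
    final_n: int = 50
    rank_by: str = "svm_probability"  # or "docking_score"
    cluster_method: str = "leader"  # or "single"

    def __post_init__(self) -> None:
        if self.rank_by not in ("svm_probability", "docking_score"):
            raise ValueError("rank_by must be 'svm_probability' or 'docking_score'")
        if self.cluster_method not in ("leader", "single"):
            raise ValueError("cluster_method must be 'leader' or 'single'")


def _rank_key(config: ScreeningConfig):
    if config.rank_by == "svm_probability":
        def key(r: CompoundRecord):
            if r.svm_probability is None:
                raise ValueError(f"{r.compound_id}: svm_probability not set")
            return (-r.svm_probability, r.compound_id)
    else:
        def key(r: CompoundRecord):
            return (r.docking_score, r.compound_id)
    return key


def prefilter_by_docking(
    library: list[CompoundRecord], n: int
) -> list[CompoundRecord]:
    """The n most favourable (lowest) docking scores; ties by compound id."""
    if n > len(library):
        warnings.warn(
            f"prefilter n={n} exceeds library size {len(library)}; keeping all"
        )
        n = len(library)
    return sorted(library, key=lambda r: (r.docking_score, r.compound_id))[:n]


def lipinski_violations(rec: CompoundRecord) -> int:
    """Count of rule-of-five violations (0..4).

    Missing descriptors are an error — a compound is never silently treated
    as violation-free.
    """
    for name in ("MW", "logP", "HBD", "HBA"):
        v = getattr(rec, name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"{rec.compound_id}: descriptor {name} is missing")
    return int(rec.MW > 500) + int(rec.logP > 5) + int(rec.HBD > 5) + int(rec.HBA > 10)


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Bit-set Tanimoto similarity |a & b| / |a | b|; two empty sets -> 0."""
    fp_a = np.asarray(fp_a, dtype=bool)
    fp_b = np.asarray(fp_b, dtype=bool)
    if fp_a.shape != fp_b.shape:
        raise ValueError(f"fingerprint length mismatch: {fp_a.shape} vs {fp_b.shape}")
    union = int(np.sum(fp_a | fp_b))
    if union == 0:
        warnings.warn("both fingerprints empty; Tanimoto defined as 0")
        return 0.0
    return float(np.sum(fp_a & fp_b) / union)


def cluster_by_similarity(
    ranked: list[CompoundRecord],
    threshold: float,
    method: str = "leader",
) -> list[int]:
    """Cluster ids (0-based, in order of founding) for a ranked list.

    ``ranked`` must already be sorted best-first by the rank criterion.
    Leader method: join the first existing cluster whose *leader* has
    Tanimoto > threshold, else found a new cluster.  Single-linkage method:
    any pair > threshold shares a cluster (union-find over all pairs).
    """
    n = len(ranked)
    for r in ranked:
        if r.fingerprint is None:
            raise ValueError(f"{r.compound_id}: fingerprint missing")
    if method == "leader":
        leaders: list[int] = []  # indices into ranked
        assign = [-1] * n
        for i, rec in enumerate(ranked):
            for cid, li in enumerate(leaders):
                if tanimoto(rec.fingerprint, ranked[li].fingerprint) > threshold:
                    assign[i] = cid
                    break
            else:
                assign[i] = len(leaders)
                leaders.append(i)
        return assign
    if method == "single":
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(n):
            for j in range(i + 1, n):
                if tanimoto(ranked[i].fingerprint, ranked[j].fingerprint) > threshold:
                    parent[find(j)] = find(i)
        # relabel roots by first appearance so ids follow ranked order
        relabel: dict[int, int] = {}
        assign = []
        for i in range(n):
            root = find(i)
            if root not in relabel:
                relabel[root] = len(relabel)
            assign.append(relabel[root])
        return assign
    raise ValueError(f"unknown clustering method '{method}'")


def select_final(
    ranked: list[CompoundRecord],
    cluster_ids: list[int],
    config: ScreeningConfig,
) -> list[CompoundRecord]:
    """Top ``final_n`` cluster leaders, ordered by the rank criterion.

    The leader of each cluster is its best-ranked member (the first in the
    ranked list).  Fewer clusters than final_n returns them all with a
    warning.
    """
    seen: set[int] = set()
    leaders: list[CompoundRecord] = []
    for rec, cid in zip(ranked, cluster_ids):
        if cid not in seen:
            seen.add(cid)
            leaders.append(replace(rec, cluster_id=cid))
        # non-leaders keep their cluster id on the full table, handled by caller
    if len(leaders) < config.final_n:
        warnings.warn(
            f"only {len(leaders)} cluster leaders available "
            f"(requested {config.final_n})"
        )
    out = leaders[: config.final_n]
    for rank, rec in enumerate(out, start=1):
        rec.final_rank = rank
    return out


def run_screen(
    library: list[CompoundRecord],
    model,
    featurizer,
    config: ScreeningConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Execute the full hierarchical screen.

    ``featurizer(compound_ids) -> (n, d) array`` supplies the MIEC feature
    rows for the docking-prefiltered pool (the expensive decomposition step);
    ``model`` is a fitted :class:`~miecsvm.modeling.MIECSVMClassifier`.
    Returns the screening table for the final selection plus per-stage
    survivor counts.
    """
    counts = {"library": len(library)}

    pool = prefilter_by_docking(library, config.prefilter_n)
    counts["docking_prefilter"] = len(pool)

    if config.rank_by == "svm_probability" or any(
        r.svm_probability is None for r in pool
    ):
        X = featurizer([r.compound_id for r in pool])
        proba = model.inhibitor_probability(X)
        pool = [replace(r, svm_probability=float(p)) for r, p in zip(pool, proba)]

    ranked = sorted(pool, key=_rank_key(config))[: config.rank_pool_n]
    counts["rank_pool"] = len(ranked)

    survivors = [
        r for r in ranked if lipinski_violations(r) <= config.lipinski_max_violations
    ]
    counts["lipinski"] = len(survivors)

    cluster_ids = cluster_by_similarity(
        survivors, config.tanimoto_threshold, method=config.cluster_method
    )
    counts["clusters"] = len(set(cluster_ids))

    final = select_final(survivors, cluster_ids, config)
    counts["final"] = len(final)

    table = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in final],
            "final_rank": [r.final_rank for r in final],
            "cluster_id": [r.cluster_id for r in final],
            "docking_score": [r.docking_score for r in final],
            "svm_probability": [r.svm_probability for r in final],
            "MW": [r.MW for r in final],
            "logP": [r.logP for r in final],
            "HBD": [r.HBD for r in final],
            "HBA": [r.HBA for r in final],
        }
    )
    return table, counts
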