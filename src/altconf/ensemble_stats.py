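"""Per-residue ensemble statistics and misfolded-model exclusion.

Two per-residue measures drive the flexibility comparison: the Cα
displacement of each residue between the two superimposed experimental end
states, and the RMSF of each residue across the aligned model ensemble.
Their squared Pearson correlation quantifies how well the ensemble's
predicted flexibility tracks the dynamics implied by the experimental pair.
Residues with pLDDT <= 75 are excluded by default before correlating.

Misfolded decoys fail to cocluster with well-folded models: average-linkage
agglomerative clustering of the pairwise Cα-RMSD matrix, cut at a distance
threshold, leaves them in undersized clusters which are then excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from altconf.errors import DomainError, UndefinedCorrelationError
from altconf.structures import ResidueMap, StructureModel
from altconf.superpose import kabsch, tm_score


@dataclass
class ResidueProfile:
    """A per-residue scalar map (Å for distances, [0, 100] for confidence)."""

    values: dict[int, float]

    def __len__(self) -> int:
        return len(self.values)

    def indices(self) -> np.ndarray:
        return np.array(sorted(self.values), dtype=int)

    def as_array(self, indices: np.ndarray | None = None) -> np.ndarray:
        idx = self.indices() if indices is None else indices
        return np.array([self.values[i] for i in idx], dtype=float)


@dataclass
class OutlierReport:
    """Partition of an ensemble into kept models and excluded outliers."""

    kept: list[str]
    excluded: list[tuple[str, str]]
    cluster_labels: dict[str, int] = field(default_factory=dict)


def displacement_profile(
    ref1: StructureModel, ref2: StructureModel, residue_map: ResidueMap
) -> ResidueProfile:
    """Per-residue Cα distance between the two superimposed references.

    ``ref2`` is superposed onto ``ref1`` by least squares over the mapped
    pairs; indices in the returned profile are ``ref1`` author numbers.
    """
    if len(residue_map) == 0:
        raise DomainError("empty residue map")
    pos1 = ref1.positions_of(residue_map.a_ids)
    pos2 = ref2.positions_of(residue_map.b_ids)
    a = ref1.coords[pos1]
    b = ref2.coords[pos2]
    if len(a) == 1:
        # a single pair is centred exactly onto itself
        return ResidueProfile({int(residue_map.a_ids[0]): 0.0})
    if len(a) == 2:
        d = abs(np.linalg.norm(a[1] - a[0]) - np.linalg.norm(b[1] - b[0])) / 2.0
        return ResidueProfile({int(r): float(d) for r in residue_map.a_ids})
    sup = kabsch(a, b)
    dist = np.linalg.norm(sup.apply(b) - a, axis=1)
    return ResidueProfile(
        {int(r): float(d) for r, d in zip(residue_map.a_ids, dist)}
    )


def rmsf_profile(aligned: list[StructureModel]) -> ResidueProfile:
    """Root mean square fluctuation of each shared residue's Cα across an
    ensemble already placed in a common frame (see ``align_ensemble``).

    RMSF_i = sqrt(mean_m |x_mi - mean_m x_mi|^2).
    """
    if len(aligned) < 2:
        raise DomainError("RMSF needs >= 2 models")
    shared = aligned[0].residue_ids
    for m in aligned[1:]:
        shared = np.intersect1d(shared, m.residue_ids)
    if len(shared) == 0:
        raise DomainError("no shared residues across the ensemble")
    stack = np.stack([m.coords[m.positions_of(shared)] for m in aligned])
    mean = stack.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0))
    return ResidueProfile({int(r): float(v) for r, v in zip(shared, rmsf)})


def confidence_filter(
    profile: ResidueProfile, plddt: ResidueProfile, threshold: float = 75.0
) -> ResidueProfile:
    """Drop residues whose pLDDT is <= ``threshold`` (inclusive boundary).

    Residues absent from the confidence profile are dropped too.  An empty
    result is returned with a warning rather than raised.
    """
    kept = {
        i: v
        for i, v in profile.values.items()
        if i in plddt.values and plddt.values[i] > threshold
    }
    if not kept:
        warnings.warn("confidence filter removed every residue", stacklevel=2)
    return ResidueProfile(kept)


def profile_correlation(x: ResidueProfile, y: ResidueProfile, kind: str = "r_squared") -> float:
    """Pearson correlation between two profiles on their shared residues.

    ``kind``: ``'pearson_r'`` or ``'r_squared'``.  Raises
    :class:`UndefinedCorrelationError` when either profile is constant.
    """
    shared = sorted(set(x.values) & set(y.values))
    if len(shared) < 3:
        raise DomainError(f"only {len(shared)} shared residues; >= 3 required")
    xv = np.array([x.values[i] for i in shared])
    yv = np.array([y.values[i] for i in shared])
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedCorrelationError("zero variance in a profile")
    r = float(pearsonr(xv, yv).statistic)
    if kind == "pearson_r":
        return r
    if kind == "r_squared":
        return r * r
    raise DomainError(f"unknown correlation kind '{kind}'")


def pairwise_rmsd_matrix(ensemble: list[StructureModel]) -> np.ndarray:
    """Symmetric matrix of per-pair Kabsch Cα RMSDs on shared residues."""
    shared = ensemble[0].residue_ids
    for m in ensemble[1:]:
        shared = np.intersect1d(shared, m.residue_ids)
    if len(shared) < 3:
        raise DomainError("fewer than 3 shared residues")
    coords = [m.coords[m.positions_of(shared)] for m in ensemble]
    n = len(ensemble)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch(coords[i], coords[j]).rmsd
    return mat


def filter_misfolded(
    ensemble: list[StructureModel],
    linkage_cutoff: float = 5.0,
    min_cluster: int = 3,
    *,
    metric: str = "rmsd",
) -> OutlierReport:
    """Exclude models that fail to cocluster with the rest of the ensemble.

    Average-linkage agglomerative clustering of the pairwise distance matrix
    (Cα RMSD by default; ``metric='tm'`` uses 1 - TM-score), cut at
    ``linkage_cutoff``.  Models in clusters smaller than ``min_cluster`` are
    excluded with reason "singleton/undersized cluster".
    """
    if len(ensemble) < 3:
        raise DomainError("misfold filtering needs >= 3 models")
    if metric == "rmsd":
        mat = pairwise_rmsd_matrix(ensemble)
    elif metric == "tm":
        n = len(ensemble)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = 1.0 - tm_score(ensemble[i], ensemble[j]).score
    else:
        raise DomainError(f"unknown metric '{metric}'")
    labels = fcluster(linkage(squareform(mat, checks=False), method="average"),
                      t=linkage_cutoff, criterion="distance")
    sizes = {c: int(np.sum(labels == c)) for c in set(labels)}
    kept, excluded = [], []
    cluster_labels = {}
    for m, lab in zip(ensemble, labels):
        cluster_labels[m.model_id] = int(lab)
        if sizes[lab] >= min_cluster:
            kept.append(m.model_id)
        else:
            excluded.append((m.model_id, "singleton/undersized cluster"))
    return OutlierReport(kept=kept, excluded=excluded, cluster_labels=cluster_labels)
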