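"""Conformational landscape: PCA over aligned Cα coordinates.

Models are flattened to 3N-vectors of masked Cα coordinates (after iterative
mean-structure alignment) and decomposed by PCA.  The first principal
component is the ensemble's dominant conformational mode; experimental
reference structures are projected into the same basis after the fit
(references never influence the fit).  Models at the extremes of PC1 are the
natural candidates for each conformational end state, and the correlation
between PC1 and TM-score quantifies how well that selection tracks accuracy.

Long loops are conformationally noisy without being informative, so residues
not assigned helix/strand by a Cα-geometry heuristic are masked out by
default; user-supplied masks override.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from altconf.errors import DomainError, InputError, UndefinedCorrelationError
from altconf.structures import ResidueMap, StructureModel
from altconf.superpose import kabsch


@dataclass
class Landscape:
    """PCA basis over masked Cα coordinates of an aligned ensemble.

    ``components`` rows are orthonormal 3M-vectors (M = masked residues),
    sorted by explained variance; ``variance_fractions`` are non-negative,
    non-increasing and sum to 1; ``projections`` are centred on the ensemble
    mean.  ``mask_residues`` records the author residue numbers used.
    """

    mean_coords: np.ndarray
    components: np.ndarray
    variance_fractions: np.ndarray
    projections: dict[str, np.ndarray]
    mask_residues: np.ndarray
    reference_projections: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def pc1(self) -> dict[str, float]:
        return {mid: float(p[0]) for mid, p in self.projections.items()}

    def flip_component(self, k: int) -> None:
        """Negate component k and every stored projection along it."""
        self.components[k] *= -1
        for p in self.projections.values():
            p[k] *= -1
        for p in self.reference_projections.values():
            p[k] *= -1

    def orient(self, reference_id: str | None = None) -> None:
        """Fix the sign of PC1 so the given (or first-stored) reference
        projects negative; deterministic reporting convention."""
        refs = self.reference_projections
        if not refs:
            return
        rid = reference_id if reference_id is not None else next(iter(refs))
        if refs[rid][0] > 0:
            self.flip_component(0)


def secondary_structure_mask(model: StructureModel) -> np.ndarray:
    """Author numbers of residues assigned helix or strand by Cα geometry.

    A residue i is helical when the i->i+3 and i->i+4 Cα distances fall in
    the canonical alpha-helix windows (4.5-6.5 Å and 4.2-7.3 Å), and
    strand-like when the trace is locally extended (i->i+2 in 6.0-7.5 Å and
    i->i+3 in 9.0-11.0 Å).  Everything else is treated as loop.
    """
    xyz = model.coords
    n = len(model)
    is_ss = np.zeros(n, dtype=bool)
    for i in range(n):
        d = {}
        for k in (2, 3, 4):
            if i + k < n:
                d[k] = np.linalg.norm(xyz[i + k] - xyz[i])
        helix = 3 in d and 4 in d and 4.5 <= d[3] <= 6.5 and 4.2 <= d[4] <= 7.3
        strand = 2 in d and 3 in d and 6.0 <= d[2] <= 7.5 and 9.0 <= d[3] <= 11.0
        if helix or strand:
            is_ss[i : i + (4 if helix else 3) + 1] = True
    return model.residue_ids[is_ss[:n]]


def fit_landscape(
    aligned: list[StructureModel],
    include_mask: np.ndarray | None = None,
) -> Landscape:
    """PCA of the masked Cα coordinates of an aligned ensemble.

    ``aligned`` must already share a common frame (``align_ensemble``).
    ``include_mask`` is a set of author residue numbers; ``None`` applies the
    secondary-structure heuristic to the first model.  Eigendecomposition is
    via SVD of the centred coordinate matrix; all components with nonzero
    variance are retained, so reconstruction from the full basis is exact.
    """
    if len(aligned) < 3:
        raise DomainError("landscape fit needs >= 3 models")
    shared = aligned[0].residue_ids
    for m in aligned[1:]:
        shared = np.intersect1d(shared, m.residue_ids)
    if include_mask is None:
        include_mask = secondary_structure_mask(aligned[0])
    mask = np.intersect1d(np.asarray(include_mask, dtype=int), shared)
    if len(mask) == 0:
        raise DomainError("residue mask is empty after intersection with the ensemble")
    x = np.stack([m.coords[m.positions_of(mask)].ravel() for m in aligned])
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD of the centred data matrix; singular values give the variances
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / len(aligned)
    keep = var > max(var.max(), 1e-300) * 1e-12
    if not keep.any():
        keep[0] = True
    components = vt[keep]
    var = var[keep]
    fractions = var / var.sum()
    # deterministic base sign: largest-magnitude loading positive
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1
    proj = xc @ components.T
    return Landscape(
        mean_coords=mean,
        components=components,
        variance_fractions=fractions,
        projections={m.model_id: proj[i].copy() for i, m in enumerate(aligned)},
        mask_residues=mask,
    )


def project_reference(
    landscape: Landscape,
    reference: StructureModel,
    residue_map: ResidueMap | None = None,
    *,
    store: bool = True,
) -> np.ndarray:
    """Project an experimental reference into the fitted basis.

    ``residue_map`` maps ensemble residue numbers (a side) to reference
    numbers (b side); identity when omitted.  The reference is first
    superposed onto the ensemble mean over the masked residues, then its
    centred masked coordinate vector is projected onto the components.
    Raises :class:`InputError` listing masked residues the reference lacks.
    """
    if residue_map is not None:
        mapping = dict(residue_map.pairs)
        missing = [int(r) for r in landscape.mask_residues if r not in mapping]
        ref_ids = np.array([mapping[r] for r in landscape.mask_residues if r in mapping])
    else:
        have = set(reference.residue_ids.tolist())
        missing = [int(r) for r in landscape.mask_residues if r not in have]
        ref_ids = landscape.mask_residues
    if missing:
        raise InputError(
            f"reference '{reference.model_id}' lacks masked residues {missing}"
        )
    xyz = reference.coords[reference.positions_of(ref_ids)]
    mean_xyz = landscape.mean_coords.reshape(-1, 3)
    sup = kabsch(mean_xyz, xyz)
    vec = sup.apply(xyz).ravel() - landscape.mean_coords
    coords = vec @ landscape.components.T
    if store:
        landscape.reference_projections[reference.model_id] = coords.copy()
    return coords


def select_extremes(landscape: Landscape, k: int, side: str = "high") -> list[str]:
    """The k model ids with the most extreme PC1 values on one side,
    outermost first; ties broken lexicographically by model id."""
    if side not in ("low", "high"):
        raise DomainError(f"side must be 'low' or 'high', got '{side}'")
    pc1 = landscape.pc1()
    if k > len(pc1):
        raise DomainError(f"k={k} exceeds ensemble size {len(pc1)}")
    sign = -1.0 if side == "high" else 1.0
    order = sorted(pc1, key=lambda mid: (sign * pc1[mid], mid))
    return order[:k]


def pc_tm_correlation(landscape: Landscape, tm_by_model: dict[str, float]) -> float:
    """Pearson r between PC1 projections and per-model TM-scores."""
    shared = sorted(set(landscape.projections) & set(tm_by_model))
    if len(shared) < 3:
        raise DomainError(f"only {len(shared)} models with both PC1 and TM values")
    pc1 = np.array([landscape.projections[m][0] for m in shared])
    tm = np.array([tm_by_model[m] for m in shared])
    if np.ptp(pc1) == 0 or np.ptp(tm) == 0:
        raise UndefinedCorrelationError("zero variance in PC1 or TM values")
    return float(pearsonr(pc1, tm).statistic)
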