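"""Synthetic two-state fixtures: toy proteins, ensembles, and alignments.

These stand in for the real benchmark inputs (pairs of experimental
inward/outward-facing structures and GPU-predicted model ensembles) so that
every analysis stage can be exercised deterministically on a laptop.

The toy protein is an idealized Cα coil (exact 3.8 Å virtual bonds, 30° turn
and 1.5 Å rise per residue) whose end state B differs from A by a rigid
rotation of a hinge segment about the chord through its anchor residues —
a one-dimensional conformational mode of controllable amplitude, the toy
analogue of a rocking-bundle transition.  Ensembles interpolate between the
end states with isotropic Gaussian noise and a controllable number of
misfolded decoys (self-avoiding random walks).  Interpolation coordinates
are confined to [inset, 1 - inset] (default inset 0.05): predicted models in
practice fall *inside* the bracket spanned by the experimental structures,
and this margin reproduces that geometry.

Emulated pLDDT is a monotone proxy for the local positional error (95 for a
clean residue, dropping linearly to 55 at 4 Å of displacement); decoys carry
a flat low confidence of 40.  This suffices to test confidence-filter mechanics; it does not emulate
any empirical relation between confidence and flexibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from altconf.errors import DomainError, InputError
from altconf.msa import Alignment
from altconf.structures import StructureModel
from altconf.superpose import kabsch

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

BOND_LENGTH = 3.8
_TURN = np.deg2rad(30.0)
_RISE = 1.5
_RADIUS = np.sqrt(BOND_LENGTH**2 - _RISE**2) / (2 * np.sin(_TURN / 2))
_MIN_CLEARANCE = 1.0  # Å, nonadjacent Cα pairs below this abort generation
_PLDDT_ERROR_SCALE = 4.0  # Å of positional error mapping to the full 40-point confidence drop


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic two-state system.

    ``hinge_range`` is an inclusive interval of 1-based residue numbers; the
    residues just outside it act as hinge anchors and must exist.
    ``state_weights`` split the non-intermediate draws between the two end
    states; ``intermediate_fraction`` of models get a uniform interpolation
    coordinate instead; ``end_state_inset`` keeps every draw inside the
    experimental bracket.
    """

    n_residues: int = 60
    hinge_range: tuple[int, int] = (18, 47)
    hinge_amplitude: float = 10.0
    n_models: int = 50
    state_weights: tuple[float, float] = (0.5, 0.5)
    noise_sigma: float = 0.5
    n_decoys: int = 2
    seed: int = 0
    intermediate_fraction: float = 0.2
    end_state_inset: float = 0.10

    def __post_init__(self) -> None:
        lo, hi = self.hinge_range
        if not (1 <= lo <= hi <= self.n_residues):
            raise InputError(f"hinge range {self.hinge_range} outside [1, {self.n_residues}]")
        if lo < 2 or hi > self.n_residues - 1:
            raise InputError("hinge needs an anchor residue on each side")
        if abs(sum(self.state_weights) - 1.0) > 1e-9:
            raise InputError("state weights must sum to 1")
        if self.noise_sigma < 0:
            raise InputError("noise_sigma must be >= 0")
        if not 0 <= self.intermediate_fraction <= 1:
            raise InputError("intermediate_fraction must be in [0, 1]")


def _sequence(spec: FixtureSpec) -> str:
    rng = np.random.default_rng(spec.seed)
    return "".join(rng.choice(_AA20, size=spec.n_residues))


def _ideal_trace(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack(
        [_RADIUS * np.cos(i * _TURN), _RADIUS * np.sin(i * _TURN), i * _RISE]
    )


def _check_clearance(coords: np.ndarray, what: str) -> None:
    d = np.linalg.norm(coords[None, :, :] - coords[:, None, :], axis=-1)
    n = len(coords)
    mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= 2
    if d[mask].min() < _MIN_CLEARANCE:
        raise InputError(
            f"{what}: nonadjacent Cα pair closer than {_MIN_CLEARANCE} Å (self-overlap)"
        )


def make_end_states(spec: FixtureSpec) -> tuple[StructureModel, StructureModel]:
    """The two noiseless end states of the hinge mode.

    State A is the ideal trace; state B rotates the hinge residues rigidly
    about the chord through the two anchor residues, by the angle that makes
    the largest Cα displacement equal ``hinge_amplitude``.  Both carry
    pLDDT 100.
    """
    a = _ideal_trace(spec.n_residues)
    lo, hi = spec.hinge_range
    pivot = a[lo - 2]  # anchor before the hinge (0-based)
    anchor2 = a[hi]  # anchor after the hinge
    axis = anchor2 - pivot
    axis /= np.linalg.norm(axis)
    seg = slice(lo - 1, hi)  # hinge residues, 0-based
    rel = a[seg] - pivot

    def build(theta: float) -> tuple[np.ndarray, np.ndarray]:
        # hinge rotation, then symmetrization of both states about their
        # midpoint so the mode carries no net rigid motion on either side
        # (otherwise ensemble alignment bends the interpolation path and
        # PC1 does not recover the injected mode)
        b = a.copy()
        b[seg] = pivot + Rotation.from_rotvec(axis * theta).apply(rel)
        sa, sb = a.copy(), b
        for _ in range(50):
            mid = 0.5 * (sa + sb)
            na = kabsch(mid, sa).apply(sa)
            nb = kabsch(mid, sb).apply(sb)
            shift = max(np.abs(na - sa).max(), np.abs(nb - sb).max())
            sa, sb = na, nb
            if shift < 1e-10:
                break
        return sa, sb

    def peak_displacement(theta: float) -> float:
        sa, sb = build(theta)
        return float(np.linalg.norm(sb - sa, axis=1).max())

    if spec.hinge_amplitude == 0:
        b = a.copy()
    else:
        theta_cap = 0.9 * np.pi
        if peak_displacement(theta_cap) < spec.hinge_amplitude:
            raise InputError(
                f"amplitude {spec.hinge_amplitude} Å unreachable: hinge geometry "
                f"allows at most {peak_displacement(theta_cap):.2f} Å"
            )
        t_lo, t_hi = 0.0, theta_cap
        for _ in range(60):  # bisection: peak displacement is monotone in theta
            mid = 0.5 * (t_lo + t_hi)
            if peak_displacement(mid) < spec.hinge_amplitude:
                t_lo = mid
            else:
                t_hi = mid
        a, b = build(0.5 * (t_lo + t_hi))
        _check_clearance(b, "state B")
    seq = _sequence(spec)
    plddt = np.full(spec.n_residues, 100.0)
    ids = np.arange(1, spec.n_residues + 1)
    return (
        StructureModel("stateA", ids, seq, a, plddt.copy()),
        StructureModel("stateB", ids, seq, b, plddt.copy()),
    )


def make_ensemble(
    spec: FixtureSpec,
) -> tuple[list[StructureModel], dict[str, str]]:
    """A labelled synthetic model ensemble.

    ``n_models`` structures at interpolation coordinates t between the end
    states — end-state draws at t = inset or 1 - inset per ``state_weights``,
    intermediates uniform on [inset, 1 - inset] — each with isotropic
    Gaussian Cα noise of ``noise_sigma`` Å, plus ``n_decoys`` self-avoiding
    random walks with native bond lengths.  Labels partition the ensemble
    into stateA / stateB / intermediate / decoy.  Deterministic in the seed.
    """
    if spec.n_models < 2:
        raise DomainError("ensemble needs >= 2 models")
    state_a, state_b = make_end_states(spec)
    rng = np.random.default_rng(spec.seed + 1)
    eps = spec.end_state_inset
    models: list[StructureModel] = []
    labels: dict[str, str] = {}
    for k in range(spec.n_models):
        if rng.random() < spec.intermediate_fraction:
            t = rng.uniform(eps, 1.0 - eps)
            label = "intermediate"
        elif rng.random() < spec.state_weights[0]:
            t, label = eps, "stateA"
        else:
            t, label = 1.0 - eps, "stateB"
        clean = (1.0 - t) * state_a.coords + t * state_b.coords
        noise = rng.normal(0.0, spec.noise_sigma, clean.shape) if spec.noise_sigma > 0 else 0.0
        coords = clean + noise
        if spec.noise_sigma > 0:
            # confidence decays with absolute positional error: 95 for a
            # clean residue, 55 at >= 4 Å displacement (clamped)
            local = np.linalg.norm(np.atleast_2d(noise), axis=1)
            plddt = 95.0 - 40.0 * np.minimum(local / _PLDDT_ERROR_SCALE, 1.0)
        else:
            plddt = np.full(spec.n_residues, 95.0)
        mid = f"model_{k:03d}"
        models.append(
            StructureModel(mid, state_a.residue_ids, state_a.sequence, coords, plddt)
        )
        labels[mid] = label
    for k in range(spec.n_decoys):
        coords = _self_avoiding_walk(spec.n_residues, rng)
        did = f"decoy_{k:03d}"
        models.append(
            StructureModel(
                did, state_a.residue_ids, state_a.sequence, coords,
                np.full(spec.n_residues, 40.0),
            )
        )
        labels[did] = "decoy"
    return models, labels


def _self_avoiding_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random Cα trace with 3.8 Å steps and >= 3.0 Å nonadjacent clearance."""
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= BOND_LENGTH / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(coords[: i - 1] - cand, axis=1)) >= 3.0:
                coords[i] = cand
                break
        else:  # pragma: no cover - walk stuck; restart from a straight step
            coords[i] = coords[i - 1] + np.array([BOND_LENGTH, 0, 0])
    return coords


def make_msa(
    n_rows: int,
    length: int,
    mutation_rate: float,
    seed: int,
    *,
    gap_rate: float = 0.0,
    insertion_rate: float = 0.0,
) -> Alignment:
    """Synthetic query-anchored alignment.

    Each non-query row mutates every position independently with
    ``mutation_rate`` (substitutions drawn from the other 19 letters), turns
    positions into deletions with ``gap_rate``, and appends short lowercase
    insertions after a position with ``insertion_rate`` — enough to exercise
    the A3M dialect.  Deterministic in the seed.
    """
    for name, rate in (("mutation_rate", mutation_rate), ("gap_rate", gap_rate),
                       ("insertion_rate", insertion_rate)):
        if not 0.0 <= rate <= 1.0:
            raise DomainError(f"{name} must be in [0, 1], got {rate}")
    if n_rows < 1:
        raise DomainError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    query = rng.choice(_AA20, size=length)
    rows: list[tuple[str, str]] = [("query", "".join(query))]
    for k in range(1, n_rows):
        chars: list[str] = []
        for pos in range(length):
            if gap_rate and rng.random() < gap_rate:
                chars.append("-")
            elif rng.random() < mutation_rate:
                pool = _AA20[_AA20 != query[pos]]
                chars.append(str(rng.choice(pool)))
            else:
                chars.append(str(query[pos]))
            if insertion_rate and rng.random() < insertion_rate:
                ins_len = int(rng.integers(1, 4))
                chars.extend(str(c).lower() for c in rng.choice(_AA20, size=ins_len))
        rows.append((f"seq_{k:04d}", "".join(chars)))
    return Alignment(rows=rows)
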