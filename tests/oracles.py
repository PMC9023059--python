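"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive (enumeration, dense random restarts,
definitional formulas) and shares no code with the implementation paths it
checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def enumerate_global_alignments(seq_a: str, seq_b: str):
    """Yield every global alignment of two short sequences as a list of
    (i, j) column pairs with -1 marking a gap."""

    def rec(i: int, j: int, cols):
        if i == len(seq_a) and j == len(seq_b):
            yield list(cols)
            return
        if i < len(seq_a) and j < len(seq_b):
            yield from rec(i + 1, j + 1, cols + [(i, j)])
        if i < len(seq_a):
            yield from rec(i + 1, j, cols + [(i, -1)])
        if j < len(seq_b):
            yield from rec(i, j + 1, cols + [(-1, j)])

    yield from rec(0, 0, [])


def affine_score(cols, seq_a, seq_b, matrix, gap_open, gap_extend):
    """Score one alignment under affine gap penalties (open charged on the
    first gap column of a run, extend on every subsequent one)."""
    score = 0
    prev = None  # 'a' = gap in a, 'b' = gap in b
    for i, j in cols:
        if i == -1:
            score += gap_extend if prev == "a" else gap_open
            prev = "a"
        elif j == -1:
            score += gap_extend if prev == "b" else gap_open
            prev = "b"
        else:
            alph = matrix.get_alphabet1()
            score += matrix.score_matrix()[
                alph.encode(seq_a[i]), alph.encode(seq_b[j])
            ]
            prev = None
    return score


def best_alignments_brute_force(seq_a, seq_b, matrix, gap_open=-11, gap_extend=-1):
    """All maximum-score global alignments by exhaustive enumeration."""
    best = -np.inf
    winners = []
    for cols in enumerate_global_alignments(seq_a, seq_b):
        s = affine_score(cols, seq_a, seq_b, matrix, gap_open, gap_extend)
        if s > best:
            best, winners = s, [cols]
        elif s == best:
            winners.append(cols)
    return best, winners


def identity_of(cols, seq_a, seq_b) -> float:
    ident = sum(1 for i, j in cols if i >= 0 and j >= 0 and seq_a[i] == seq_b[j])
    return 100.0 * ident / len(cols)


def min_rmsd_over_proper_rotations(a: np.ndarray, b: np.ndarray, n_grid: int = 20000,
                                   seed: int = 0) -> float:
    """Dense random sampling of proper rotations + local refinement,
    minimizing centred RMSD of b onto a."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def rmsd_of(rotvec):
        moved = Rotation.from_rotvec(rotvec).apply(b)
        return np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1)))

    rots = Rotation.random(n_grid, rng=np.random.default_rng(seed))
    moved = np.einsum("nij,kj->nki", rots.as_matrix(), b)
    vals = np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=-1), axis=-1))
    best = np.inf
    for idx in np.argsort(vals)[:10]:
        res = minimize(rmsd_of, rots[int(idx)].as_rotvec(), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)


def max_tm_sum_random_restarts(ref: np.ndarray, mob: np.ndarray, d0: float,
                               n_restarts: int = 200, seed: int = 0) -> float:
    """Maximize the TM sum over rigid transforms of mob by dense random
    restarts with local refinement; returns the best (unnormalized) sum."""
    rng = np.random.default_rng(seed)
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)

    def neg_tm(params):
        rot = Rotation.from_rotvec(params[:3])
        moved = rot.apply(mob_c) + params[3:]
        d2 = np.sum((moved - ref_c) ** 2, axis=1)
        return -np.sum(1.0 / (1.0 + d2 / d0**2))

    best = np.inf
    for k in range(n_restarts):
        start = np.concatenate([
            Rotation.random(rng=rng).as_rotvec(),
            rng.normal(0, 3.0, 3),
        ])
        res = minimize(neg_tm, start, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        best = min(best, res.fun)
    return -best


def pearson_definitional(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r straight from the definitional formula."""
    xm = x - np.mean(x)
    ym = y - np.mean(y)
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
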