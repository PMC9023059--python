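"""Structure I/O and residue bookkeeping.

A :class:`StructureModel` is a single chain reduced to its Cα trace: ordered
author residue numbers, one-letter codes, coordinates, and (for predicted
models) per-residue pLDDT confidence read from the B-factor column.  All
per-residue statistics downstream are computed on the intersection of
resolved, sequence-mapped residues, established here by :func:`correspond`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import TextIO

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
import biotite.sequence as bseq
import biotite.sequence.align as balign

from altconf.errors import DomainError, InputError, ParseError
from altconf import msa as _msa

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
_ONE_TO_THREE = {v: k for k, v in reversed(_THREE_TO_ONE.items())}


@dataclass
class StructureModel:
    """One chain as an ordered Cα trace.

    ``residue_ids`` are author residue numbers (strictly increasing),
    ``sequence`` the one-letter codes, ``coords`` an (N, 3) array in Å, and
    ``plddt`` an optional (N,) array of per-residue confidence in [0, 100].
    """

    model_id: str
    residue_ids: np.ndarray
    sequence: str
    coords: np.ndarray
    plddt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_ids)
        if n == 0:
            raise DomainError(f"model '{self.model_id}' has no residues")
        if len(self.sequence) != n or self.coords.shape != (n, 3):
            raise InputError(
                f"model '{self.model_id}': inconsistent lengths "
                f"(ids {n}, sequence {len(self.sequence)}, coords {self.coords.shape})"
            )
        if np.any(np.diff(self.residue_ids) <= 0):
            raise InputError(f"model '{self.model_id}': residue numbers not strictly increasing")
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if self.plddt.shape != (n,):
                raise InputError(f"model '{self.model_id}': plddt length mismatch")
            if np.any((self.plddt < 0) | (self.plddt > 100)):
                raise InputError(f"model '{self.model_id}': plddt outside [0, 100]")

    def __len__(self) -> int:
        return len(self.residue_ids)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def positions_of(self, residue_ids: np.ndarray) -> np.ndarray:
        """Array positions of the given author residue numbers."""
        lookup = {rid: i for i, rid in enumerate(self.residue_ids)}
        try:
            return np.array([lookup[r] for r in residue_ids], dtype=int)
        except KeyError as exc:
            raise InputError(f"model '{self.model_id}' lacks residue {exc.args[0]}") from None


@dataclass
class ResidueMap:
    """Order-preserving residue correspondence between two models.

    ``pairs`` holds (author number in a, author number in b), strictly
    increasing in both coordinates; ``coverage`` is the mapped fraction of
    a's residues.
    """

    pairs: list[tuple[int, int]]
    coverage: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.pairs, dtype=int)
        if len(arr) and (np.any(np.diff(arr[:, 0]) <= 0) or np.any(np.diff(arr[:, 1]) <= 0)):
            raise InputError("residue map pairs must be strictly increasing in both coordinates")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_ids(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def b_ids(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


def identity_map(model: StructureModel) -> ResidueMap:
    """The self-correspondence of a model (coverage 1)."""
    return ResidueMap([(int(r), int(r)) for r in model.residue_ids], 1.0)


def read_pdb(
    source: TextIO | str,
    chain: str = "A",
    *,
    model_id: str | None = None,
    is_prediction: bool = False,
) -> StructureModel:
    """Read one chain's Cα trace from PDB-format text.

    ``is_prediction=True`` surfaces the B-factor column as pLDDT (the
    convention of predicted-model files).  Residues lacking a Cα are skipped
    with a warning.  Raises :class:`ParseError` for unreadable records and
    :class:`InputError` for a missing chain.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
        default_id = source.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    else:
        text = source if isinstance(source, str) else source.read()
        default_id = "model"
    try:
        pdb = PDBFile.read(io.StringIO(text))
        arr = pdb.get_structure(model=1, extra_fields=["b_factor"])
    except Exception as exc:  # biotite reports the offending line
        raise ParseError(f"unreadable PDB record: {exc}") from exc
    arr = arr[struc.filter_amino_acids(arr) | np.isin(arr.res_name, list(_THREE_TO_ONE))]
    chains = set(arr.chain_id)
    if chain not in chains:
        raise InputError(f"chain '{chain}' not found (available: {sorted(chains)})")
    arr = arr[arr.chain_id == chain]
    ca = arr[arr.atom_name == "CA"]
    # warn about residues present without a Cα
    all_res = set(zip(arr.res_id.tolist(), arr.res_name.tolist()))
    ca_res = set(zip(ca.res_id.tolist(), ca.res_name.tolist()))
    missing = all_res - ca_res
    if missing:
        warnings.warn(
            f"chain {chain}: skipped {len(missing)} residue(s) lacking a CA atom",
            stacklevel=2,
        )
    if len(ca) == 0:
        raise ParseError(f"chain '{chain}' contains no CA atoms")
    # keep first altloc occurrence per residue id
    _, first = np.unique(ca.res_id, return_index=True)
    ca = ca[np.sort(first)]
    seq = "".join(_THREE_TO_ONE.get(rn, "X") for rn in ca.res_name)
    return StructureModel(
        model_id=model_id or default_id,
        residue_ids=ca.res_id,
        sequence=seq,
        coords=ca.coord,
        plddt=ca.b_factor if is_prediction else None,
    )


def write_pdb(model: StructureModel, sink: TextIO | None = None) -> str:
    """Serialize the Cα trace as single-atom-per-residue PDB records.

    pLDDT (when present) is written to the B-factor column; coordinates keep
    the format's fixed 3-decimal precision.
    """
    n = len(model)
    arr = struc.AtomArray(n)
    arr.coord = model.coords
    arr.chain_id = np.full(n, "A")
    arr.res_id = model.residue_ids
    arr.res_name = np.array([_ONE_TO_THREE.get(c, "UNK") for c in model.sequence])
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.set_annotation("b_factor", model.plddt if model.plddt is not None else np.zeros(n))
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    text = buf.getvalue()
    if sink is not None:
        sink.write(text)
    return text


def truncate(model: StructureModel, drop_ranges: list[tuple[int, int]]) -> StructureModel:
    """Remove residues inside any inclusive author-number interval.

    Mirrors terminal truncations such as dropping residues 1-131 and 401-461
    before modelling.  Dropping everything is an error.
    """
    keep = np.ones(len(model), dtype=bool)
    for lo, hi in drop_ranges:
        if lo > hi:
            raise InputError(f"inverted interval {lo}-{hi}")
        keep &= ~((model.residue_ids >= lo) & (model.residue_ids <= hi))
    if not keep.any():
        raise DomainError("truncation removed every residue")
    return StructureModel(
        model_id=model.model_id,
        residue_ids=model.residue_ids[keep],
        sequence="".join(c for c, k in zip(model.sequence, keep) if k),
        coords=model.coords[keep],
        plddt=model.plddt[keep] if model.plddt is not None else None,
    )


def correspond(a: StructureModel, b: StructureModel) -> ResidueMap:
    """Residue correspondence by global sequence alignment.

    Needleman-Wunsch (same scoring defaults as :func:`altconf.msa.global_identity`)
    on the two one-letter sequences; matched columns become map pairs.  Since
    a :class:`StructureModel` holds only resolved Cα residues, every matched
    column is resolved in both.  Raises :class:`DomainError` when nothing maps.
    """
    sa = bseq.ProteinSequence(a.sequence.replace("U", "C").replace("O", "K"))
    sb = bseq.ProteinSequence(b.sequence.replace("U", "C").replace("O", "K"))
    aln = balign.align_optimal(
        sa, sb, _msa._BLOSUM62, gap_penalty=(-11, -1), terminal_penalty=True
    )[0]
    pairs = [
        (int(a.residue_ids[i]), int(b.residue_ids[j]))
        for i, j in aln.trace
        if i != -1 and j != -1
    ]
    if not pairs:
        raise DomainError(
            f"no aligned residue pairs between '{a.model_id}' and '{b.model_id}'"
        )
    return ResidueMap(pairs, coverage=len(pairs) / len(a))
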