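"""Multiple sequence alignments: A3M/FASTA I/O, depth subsampling, identity.

The MSA is the protocol's key experimental knob: restricting the depth of the
alignment handed to the prediction network (to as few as 16 sequences)
diversifies the sampled conformations, while deep alignments collapse the
ensemble onto a single state.  Subsampling here is uniform without
replacement, seeded, and always retains the query.

A3M dialect: '>'-headers; lowercase letters are insertions relative to the
query; '-' is a deletion.  After removing lowercase characters every row must
have the same number of match columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import TextIO

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

from altconf.errors import DomainError, InputError, ParseError

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXJUO")
_MSA_CHARS = AA_ALPHABET | {"-"} | {c.lower() for c in AA_ALPHABET}


@dataclass(frozen=True)
class SubsampleSpec:
    """Depth parameters for one stochastic subsample.

    ``extra_depth`` is the total row budget (the prediction engine's
    ``max_extra_msa``); ``cluster_count`` is carried as metadata for the run
    specification (``max_msa_clusters``) and does not stratify the draw.
    """

    extra_depth: int
    cluster_count: int
    seed: int

    def __post_init__(self) -> None:
        if self.extra_depth < 1 or self.cluster_count < 1:
            raise DomainError("extra_depth and cluster_count must both be >= 1")
        if self.cluster_count > self.extra_depth:
            raise DomainError(
                f"cluster_count ({self.cluster_count}) must not exceed "
                f"extra_depth ({self.extra_depth})"
            )


@dataclass
class Alignment:
    """A query-anchored MSA; row 0 is always the query."""

    rows: list[tuple[str, str]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ParseError("alignment must contain at least the query row")
        ncols = {len(_strip_insertions(s)) for _, s in self.rows}
        if len(ncols) != 1:
            bad = next(
                rid for rid, s in self.rows
                if len(_strip_insertions(s)) != len(_strip_insertions(self.rows[0][1]))
            )
            raise ParseError(f"inconsistent match-column count in record '{bad}'")
        for rid, s in self.rows:
            illegal = set(s) - _MSA_CHARS
            if illegal:
                raise ParseError(
                    f"record '{rid}' contains non-alignment characters: {sorted(illegal)}"
                )

    @property
    def query_id(self) -> str:
        return self.rows[0][0]

    @property
    def depth(self) -> int:
        """Number of rows, query included."""
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        """Match columns (insertion characters excluded)."""
        return len(_strip_insertions(self.rows[0][1]))

    def row_ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]


def _strip_insertions(seq: str) -> str:
    return "".join(c for c in seq if not c.islower())


def read_a3m(source: TextIO | str) -> Alignment:
    """Parse an A3M or aligned-FASTA stream into an :class:`Alignment`.

    The first record is taken as the query.  Raises :class:`ParseError`
    naming the offending record for malformed headers, inconsistent column
    counts, or an empty stream.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    rows: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if header is not None:
                rows.append((header, "".join(chunks)))
            header = line[1:].split()[0] if len(line) > 1 else ""
            if not header:
                raise ParseError(f"empty header at line {lineno}")
            chunks = []
        else:
            if header is None:
                raise ParseError(f"sequence data before first header at line {lineno}")
            chunks.append(line.strip())
    if header is not None:
        rows.append((header, "".join(chunks)))
    if not rows:
        raise ParseError("empty alignment stream")
    return Alignment(rows=rows)


def write_a3m(alignment: Alignment, sink: TextIO | None = None) -> str:
    """Serialize back to A3M; one sequence line per record (no wrapping)."""
    text = "".join(f">{rid}\n{seq}\n" for rid, seq in alignment.rows)
    if sink is not None:
        sink.write(text)
    return text


def subsample(msa: Alignment, spec: SubsampleSpec) -> Alignment:
    """Draw ``min(spec.extra_depth, msa.depth)`` rows uniformly without
    replacement, always keeping the query as row 0.

    Deterministic in ``(msa, spec)``.  Requesting more rows than available is
    a degenerate pass-through returning the full alignment.  The spec is
    recorded in the output metadata.
    """
    n_keep = min(spec.extra_depth, msa.depth)
    rng = np.random.default_rng(spec.seed)
    # query is row 0 and always retained; the remaining budget is drawn
    # uniformly from the non-query rows
    others = np.arange(1, msa.depth)
    chosen = rng.choice(others, size=n_keep - 1, replace=False) if n_keep > 1 else []
    picked = [msa.rows[0]] + [msa.rows[i] for i in sorted(chosen)]
    meta = dict(msa.metadata)
    meta["subsample"] = {
        "extra_depth": spec.extra_depth,
        "cluster_count": spec.cluster_count,
        "seed": spec.seed,
    }
    return Alignment(rows=picked, metadata=meta)


def default_cluster_count(extra_depth: int) -> int:
    """Cluster budget paired with a given depth: half the depth (floor),
    except 512 when the depth is 5120."""
    if extra_depth < 2:
        raise DomainError(f"extra_depth must be >= 2, got {extra_depth}")
    if extra_depth == 5120:
        return 512
    return extra_depth // 2


_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()


def global_identity(
    seq_a: str,
    seq_b: str,
    *,
    matrix: balign.SubstitutionMatrix = _BLOSUM62,
    gap_penalty: tuple[int, int] = (-11, -1),
    denominator: str = "alignment",
) -> float:
    """Percent identity from a Needleman-Wunsch global alignment.

    Defaults: BLOSUM62, gap open 11 / extend 1.  Identity is identical
    aligned pairs over the alignment length including gap columns
    (``denominator='alignment'``); ``'shorter'`` and ``'longer'`` divide by
    the shorter/longer sequence length instead.  Returns a value in [0, 100].
    """
    for name, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not s:
            raise InputError(f"{name} is empty")
        bad = set(s.upper()) - AA_ALPHABET
        if bad:
            raise InputError(f"{name} contains non-amino-acid characters: {sorted(bad)}")
    a = bseq.ProteinSequence(seq_a.upper())
    b = bseq.ProteinSequence(seq_b.upper())
    aln = balign.align_optimal(a, b, matrix, gap_penalty=gap_penalty, terminal_penalty=True)[0]
    trace = aln.trace
    identical = sum(
        1
        for i, j in trace
        if i != -1 and j != -1 and seq_a.upper()[i] == seq_b.upper()[j]
    )
    if denominator == "alignment":
        denom = len(trace)
    elif denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    elif denominator == "longer":
        denom = max(len(seq_a), len(seq_b))
    else:
        raise InputError(f"unknown denominator '{denominator}'")
    return 100.0 * identical / denom
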