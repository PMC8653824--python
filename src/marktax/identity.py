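"""Percent identity from alignments, and a self-contained global aligner.

Identity follows the SIAS family of definitions: the numerator is always the
number of alignment columns carrying the same residue in both rows (gaps and
the ambiguity letter X never match, X not even itself); the denominator is
selectable:

* ``ungapped_columns`` (default) — columns where neither row is gapped;
* ``shorter_sequence`` — residue count of the shorter of the two rows;
* ``alignment_length`` — columns where at least one row has a residue
  (columns gapped in both rows never count under any mode).

The aligner is a standard affine-gap (Gotoh) global alignment over a
substitution matrix, with a deterministic traceback that prefers
diagonal over up (gap in the second sequence) over left on score ties.
A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import IO, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ParseError, UndefinedIdentityError

GAP = "-"
_AA = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED = set(_AA) | {"X", GAP}

IDENTITY_MODES = ("ungapped_columns", "shorter_sequence", "alignment_length")


@dataclass
class Alignment:
    """A multiple (or pairwise) protein alignment: equal-length rows."""

    sequence_ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.sequence_ids) != len(self.rows):
            raise ConfigurationError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ConfigurationError("an alignment needs at least two rows")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ConfigurationError("sequence ids must be unique")
        width = len(self.rows[0])
        if width < 1:
            raise ConfigurationError("alignment rows must be non-empty")
        for sid, row in zip(self.sequence_ids, self.rows):
            if len(row) != width:
                raise ConfigurationError(
                    f"row {sid!r} has length {len(row)}, expected {width}"
                )
            bad = set(row) - _ALLOWED
            if bad:
                raise ConfigurationError(
                    f"row {sid!r} contains illegal characters: {sorted(bad)}"
                )
        self._index = {sid: k for k, sid in enumerate(self.sequence_ids)}

    def row(self, sequence_id: str) -> str:
        return self.rows[self._index[sequence_id]]

    @classmethod
    def from_fasta(cls, handle: IO[str] | str) -> "Alignment":
        from Bio import SeqIO

        ids, rows = [], []
        for record in SeqIO.parse(handle, "fasta"):
            ids.append(record.id)
            rows.append(str(record.seq).upper())
        return cls(ids, rows)


def _match_and_denominators(a: str, b: str) -> tuple[int, int, int, int]:
    """(matches, ungapped_cols, shorter_len, aligned_cols) for two rows."""
    matches = ungapped = aligned = 0
    len_a = len_b = 0
    for x, y in zip(a, b):
        xg, yg = x == GAP, y == GAP
        if xg and yg:
            continue
        aligned += 1
        if not xg:
            len_a += 1
        if not yg:
            len_b += 1
        if not xg and not yg:
            ungapped += 1
            if x == y and x != "X":
                matches += 1
    return matches, ungapped, min(len_a, len_b), aligned


def pairwise_identity(
    aln: Alignment, i: str, j: str, mode: str = "ungapped_columns"
) -> float:
    """Percent identity between two alignment rows under the given mode."""
    if mode not in IDENTITY_MODES:
        raise ConfigurationError(f"unknown identity mode: {mode!r}")
    if i == j:
        raise ConfigurationError("pairwise identity needs two distinct ids")
    matches, ungapped, shorter, aligned = _match_and_denominators(
        aln.row(i), aln.row(j)
    )
    denom = {"ungapped_columns": ungapped,
             "shorter_sequence": shorter,
             "alignment_length": aligned}[mode]
    if denom == 0:
        raise UndefinedIdentityError(
            f"identity of {i!r} vs {j!r} is undefined (zero {mode} denominator)"
        )
    return 100.0 * matches / denom


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix; missing cells are NaN."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ConfigurationError("identity matrix shape does not match ids")
        self._index = {sid: k for k, sid in enumerate(self.ids)}

    def get(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(len(self.ids), dtype=bool)
        return bool(np.isnan(self.values[off]).any())

    def to_tsv(self, handle: IO[str]) -> None:
        handle.write("id\t" + "\t".join(self.ids) + "\n")
        for sid, row in zip(self.ids, self.values):
            handle.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def read_tsv(cls, handle: IO[str] | str) -> "IdentityMatrix":
        close = isinstance(handle, str)
        fh = open(handle) if close else handle
        try:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                if line.strip():
                    rows.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
            return cls(header, np.array(rows))
        finally:
            if close:
                fh.close()


def identity_matrix(aln: Alignment, mode: str = "ungapped_columns") -> IdentityMatrix:
    """All-vs-all identities; each unordered pair is computed once.

    Undefined pairs (zero denominator) become NaN cells with a warning.
    The inner comparison is vectorized over columns.
    """
    if mode not in IDENTITY_MODES:
        raise ConfigurationError(f"unknown identity mode: {mode!r}")
    n = len(aln.rows)
    enc = np.frombuffer("".join(aln.rows).encode("ascii"), dtype=np.uint8)
    enc = enc.reshape(n, len(aln.rows[0]))
    gap = ord(GAP)
    unknown = ord("X")
    nongap = enc != gap
    res_len = nongap.sum(axis=1)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    n_undefined = 0
    for a in range(n):
        for b in range(a + 1, n):
            both = nongap[a] & nongap[b]
            matches = int(
                (both & (enc[a] == enc[b]) & (enc[a] != unknown)).sum()
            )
            if mode == "ungapped_columns":
                denom = int(both.sum())
            elif mode == "shorter_sequence":
                denom = int(min(res_len[a], res_len[b]))
            else:
                denom = int((nongap[a] | nongap[b]).sum())
            if denom == 0:
                n_undefined += 1
                continue
            values[a, b] = values[b, a] = 100.0 * matches / denom
    if n_undefined:
        warnings.warn(
            f"{n_undefined} pair(s) had undefined identity; cells left missing",
            stacklevel=2,
        )
    return IdentityMatrix(list(aln.sequence_ids), values)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    from Bio.Align import substitution_matrices

    try:
        return substitution_matrices.load(name)
    except FileNotFoundError:
        raise ConfigurationError(f"unknown substitution matrix: {name!r}") from None


@dataclass
class AlignParams:
    """Affine-gap alignment parameters (protein defaults: BLOSUM62, -11/-1)."""

    substitution_matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    #: optional explicit matrix: mapping (aa, aa) -> score; overrides the name
    matrix: Mapping[tuple[str, str], float] | None = field(default=None, repr=False)

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend < 0):
            raise ConfigurationError(
                "require gap_open <= gap_extend < 0 "
                f"(got open={self.gap_open}, extend={self.gap_extend})"
            )

    def score(self, a: str, b: str) -> float:
        if self.matrix is not None:
            return float(self.matrix[a, b]) if (a, b) in self.matrix else float(
                self.matrix[b, a]
            )
        return float(_load_matrix(self.substitution_matrix_name)[a, b])


def _check_protein(seq: str, which: str) -> None:
    if not seq:
        raise ConfigurationError(f"{which} sequence is empty")
    for pos, ch in enumerate(seq):
        if ch not in _ALLOWED or ch == GAP:
            raise ConfigurationError(
                f"illegal character {ch!r} at position {pos + 1} of {which} sequence"
            )


def global_align(
    query: str,
    ref: str,
    params: AlignParams | None = None,
    query_id: str = "query",
    ref_id: str = "ref",
) -> tuple[Alignment, float, float]:
    """Optimal global alignment of two protein sequences (Gotoh, affine gaps).

    Returns ``(pairwise alignment, percent identity, score)``; identity uses
    the default ungapped-columns denominator. Traceback is deterministic: on
    score ties it prefers diagonal, then up (gap in ``ref``), then left, the
    preference being applied at each step walking from the alignment end
    backward.
    """
    p = params or AlignParams()
    _check_protein(query, "query")
    _check_protein(ref, "ref")
    n, m = len(query), len(ref)
    neg = float("-inf")

    # state matrices: M ends in a substitution, X in a gap in ref (consumes
    # query, "up"), Y in a gap in query ("left")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = p.gap_open + (i - 1) * p.gap_extend
    for j in range(1, m + 1):
        Y[0, j] = p.gap_open + (j - 1) * p.gap_extend

    sub = np.empty((n, m))
    for i, qa in enumerate(query):
        for j, rb in enumerate(ref):
            sub[i, j] = p.score(qa, rb)

    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        subi = sub[i - 1]
        for j in range(1, m + 1):
            Xi[j] = max(Mi1[j] + p.gap_open, Xi1[j] + p.gap_extend,
                        Yi1[j] + p.gap_open)
            Yi[j] = max(Mi[j - 1] + p.gap_open, Xi[j - 1] + p.gap_open,
                        Yi[j - 1] + p.gap_extend)
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            if best_prev > neg:
                Mi[j] = best_prev + subi[j - 1]

    def pick(i: int, j: int, order: tuple[str, ...]) -> str:
        table = {"M": M, "X": X, "Y": Y}
        best = max(table[s][i, j] for s in order)
        for s in order:  # priority order implements the tie-break
            if table[s][i, j] == best:
                return s
        raise AssertionError

    # diagonal > up > left maps to state priority M > X > Y
    state = pick(n, m, ("M", "X", "Y"))
    score = {"M": M, "X": X, "Y": Y}[state][n, m]
    out_q: list[str] = []
    out_r: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            out_q.append(query[i - 1])
            out_r.append(ref[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            prev = {"M": M[i, j], "X": X[i, j], "Y": Y[i, j]}
            tgt = max(prev.values())
            state = next(s for s in ("M", "X", "Y") if prev[s] == tgt)
        elif state == "X":
            out_q.append(query[i - 1])
            out_r.append(GAP)
            i -= 1
            opts = (
                ("M", M[i, j] + p.gap_open),
                ("X", X[i, j] + p.gap_extend),
                ("Y", Y[i, j] + p.gap_open),
            )
            tgt = X[i + 1, j]
            state = next(s for s, v in opts if v == tgt)
        else:  # Y
            out_q.append(GAP)
            out_r.append(ref[j - 1])
            j -= 1
            opts = (
                ("M", M[i, j] + p.gap_open),
                ("X", X[i, j] + p.gap_open),
                ("Y", Y[i, j] + p.gap_extend),
            )
            tgt = Y[i, j + 1]
            state = next(s for s, v in opts if v == tgt)
        if i == 0 and j == 0:
            break

    aln = Alignment([query_id, ref_id], ["".join(reversed(out_q)),
                                         "".join(reversed(out_r))])
    ident = pairwise_identity(aln, query_id, ref_id, "ungapped_columns")
    return aln, ident, float(score)


@dataclass(frozen=True)
class PhylipExport:
    text: str
    name_map: dict[str, str]  # phylip name -> original id


def export_phylip(matrix: IdentityMatrix, relaxed: bool = False) -> PhylipExport:
    """Square PHYLIP distance matrix with distance = (100 - identity)/100.

    Names longer than 10 characters are truncated; truncation collisions are
    an error unless ``relaxed``, which substitutes generated names and
    returns the name map.
    """
    if matrix.has_missing:
        raise ConfigurationError("cannot export a matrix with missing cells")
    names = [sid[:10] for sid in matrix.ids]
    if len(set(names)) != len(names):
        if not relaxed:
            raise ConfigurationError(
                "duplicate names after 10-character truncation; use relaxed mode"
            )
        names = [f"T{k:07d}" for k in range(len(matrix.ids))]
    lines = [f"{len(matrix.ids)}"]
    for name, row in zip(names, matrix.values):
        dists = " ".join(f"{(100.0 - v) / 100.0:.6f}" for v in row)
        lines.append(f"{name:<10s} {dists}")
    return PhylipExport(text="\n".join(lines) + "\n",
                        name_map=dict(zip(names, matrix.ids)))
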