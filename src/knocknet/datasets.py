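"""Core containers and DREAM-dialect text I/O.

The on-disk formats are the tab-separated dialects used by the DREAM in
silico network challenges:

* expression tables — one row of wild-type steady states (1 x N) and a
  knockout table (N x N) whose row *i* is the steady state measured after
  knocking out gene *i*; an optional first row may carry gene labels;
* gold standards — one ``G<i>\\tG<j>\\t{0|1}`` line per candidate edge;
* ranked predictions — one ``G<i>\\tG<j>\\t<score>`` line per ordered gene
  pair, best first.

Gene labels are 1-based (``G1`` .. ``GN``) in every file; indices are
0-based everywhere in memory.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ParseError, ValidationError

__all__ = [
    "ExpressionDataset",
    "GeneNetwork",
    "ConfidenceMatrix",
    "EdgeRanking",
    "default_gene_names",
    "read_expression_files",
    "read_gold_standard",
    "read_prediction",
    "write_expression_files",
    "write_gold_standard",
    "write_prediction",
]

_LABEL_RE = re.compile(r"^G(\d+)$")


def default_gene_names(n: int) -> list[str]:
    """Standard ``G1`` .. ``GN`` labels."""
    return [f"G{i + 1}" for i in range(n)]


def _parse_label(label: str, n_genes: int, where: str) -> int:
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValidationError(f"{where}: gene label {label!r} is not of the form G<i>")
    idx = int(m.group(1)) - 1
    if not 0 <= idx < n_genes:
        raise ValidationError(
            f"{where}: gene label {label!r} outside G1..G{n_genes}"
        )
    return idx


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Wild-type steady state plus the full single-knockout compendium.

    Attributes
    ----------
    gene_names
        Ordered gene labels, length N.
    wildtype
        Length-N vector of unperturbed steady-state activities (arbitrary
        expression units, non-negative).
    knockout
        N x N matrix; ``knockout[i, j]`` is the steady-state activity of
        gene *j* after knocking out gene *i*.  A knocked-out gene has null
        expression, so the diagonal is identically zero.
    """

    gene_names: list[str]
    wildtype: np.ndarray
    knockout: np.ndarray

    def __post_init__(self) -> None:
        self.wildtype = np.asarray(self.wildtype, dtype=float).reshape(-1)
        self.knockout = np.asarray(self.knockout, dtype=float)
        n = len(self.gene_names)
        if self.knockout.ndim != 2:
            raise ValidationError("knockout table must be two-dimensional")
        if self.wildtype.shape != (n,) or self.knockout.shape != (n, n):
            raise ValidationError(
                "inconsistent shapes: "
                f"{n} gene names, wild-type {self.wildtype.shape}, "
                f"knockout {self.knockout.shape}"
            )
        if not (np.isfinite(self.wildtype).all() and np.isfinite(self.knockout).all()):
            raise ValidationError("expression values must be finite")
        if (self.wildtype < 0).any() or (self.knockout < 0).any():
            raise ValidationError("gene activities must be non-negative")
        diag = np.diagonal(self.knockout)
        if (diag != 0).any():
            bad = int(np.nonzero(diag)[0][0])
            raise ValidationError(
                f"knocked-out gene must have zero activity; "
                f"knockout[{bad}][{bad}] = {diag[bad]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)


@dataclass
class GeneNetwork:
    """Signed directed gene network.

    ``signs[i, j]`` is +1 for an activating edge i -> j, -1 for an
    inhibiting edge, 0 for no edge.  Gold standards are unsigned and use
    +1 throughout; signs only matter to the simulator.  No self-loops.
    """

    n_genes: int
    signs: np.ndarray

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs)
        if self.signs.shape != (self.n_genes, self.n_genes):
            raise ValidationError(
                f"sign matrix shape {self.signs.shape} does not match "
                f"n_genes={self.n_genes}"
            )
        if not np.isin(self.signs, (-1, 0, 1)).all():
            raise ValidationError("edge signs must be in {-1, 0, +1}")
        if np.diagonal(self.signs).any():
            raise ValidationError("networks have no self-interactions")
        self.signs = self.signs.astype(np.int8)

    @classmethod
    def from_edges(
        cls,
        n_genes: int,
        edges: Iterable[tuple[int, int] | tuple[int, int, int]],
    ) -> "GeneNetwork":
        """Build from 0-based ``(source, target[, sign])`` tuples."""
        signs = np.zeros((n_genes, n_genes), dtype=np.int8)
        for edge in edges:
            i, j = edge[0], edge[1]
            sign = edge[2] if len(edge) == 3 else 1
            if i == j:
                raise ValidationError(f"self-loop on gene index {i}")
            if not (0 <= i < n_genes and 0 <= j < n_genes):
                raise ValidationError(f"edge ({i}, {j}) outside [0, {n_genes})")
            signs[i, j] = sign
        return cls(n_genes=n_genes, signs=signs)

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Unsigned edge set as 0-based (source, target) pairs."""
        return {(int(i), int(j)) for i, j in zip(*np.nonzero(self.signs))}

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.signs))


#: valid confidence-matrix method tags
METHOD_TAGS = ("D", "ND", "ZD", "ZR", "downranked")


@dataclass
class ConfidenceMatrix:
    """N x N non-negative edge scores; ``scores[i, j]`` is the confidence
    that gene *i* directly regulates gene *j*.  Self-edges are never
    predicted, so the diagonal is zero."""

    scores: np.ndarray
    method_tag: str = "D"
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValidationError(f"confidence matrix must be square, got {self.scores.shape}")
        if self.method_tag not in METHOD_TAGS:
            raise ValidationError(
                f"method_tag {self.method_tag!r} not in {METHOD_TAGS}"
            )
        if not np.isfinite(self.scores).all():
            raise ValidationError("confidence scores must be finite")
        if (self.scores < 0).any():
            raise ValidationError("confidence scores must be non-negative")
        if np.diagonal(self.scores).any():
            raise ValidationError("self-edge confidences must be zero")
        if self.gene_names is None:
            self.gene_names = default_gene_names(self.scores.shape[0])

    @property
    def n_genes(self) -> int:
        return self.scores.shape[0]


@dataclass
class EdgeRanking:
    """All N(N-1) ordered gene pairs, best first.

    Entries are ``(source, target, score)`` with 0-based indices, sorted by
    descending score; ties are broken by ascending (source, target) so the
    ordering — and therefore any file written from it — is deterministic.
    """

    n_genes: int
    entries: list[tuple[int, int, float]]
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_names:
            self.gene_names = default_gene_names(self.n_genes)
        expected = self.n_genes * (self.n_genes - 1)
        if len(self.entries) != expected:
            raise ValidationError(
                f"ranking must cover all {expected} ordered off-diagonal "
                f"pairs, got {len(self.entries)}"
            )
        pairs = {(i, j) for i, j, _ in self.entries}
        if len(pairs) != expected or any(i == j for i, j in pairs):
            raise ValidationError("ranking pairs must be the distinct off-diagonal pairs")
        scores = [s for _, _, s in self.entries]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValidationError("ranking scores must be non-increasing")

    @classmethod
    def from_confidence(cls, w: ConfidenceMatrix) -> "EdgeRanking":
        n = w.n_genes
        entries = [
            (i, j, float(w.scores[i, j]))
            for i in range(n)
            for j in range(n)
            if i != j
        ]
        entries.sort(key=lambda e: (-e[2], e[0], e[1]))
        return cls(n_genes=n, entries=entries, gene_names=list(w.gene_names))

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, _, s in self.entries])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _read_numeric_table(path: str | Path) -> tuple[list[str] | None, np.ndarray]:
    """Read a tab-separated numeric table with an optional label header.

    The header is auto-detected: if any field of the first non-empty row
    fails to parse as a number, the row is taken as gene labels.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if line.strip() == "":
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ParseError(f"{path}: file contains no data")

    def try_floats(fields: Sequence[str]) -> list[float] | None:
        out = []
        for f in fields:
            try:
                out.append(float(f))
            except ValueError:
                return None
        return out

    header: list[str] | None = None
    first = try_floats(rows[0])
    if first is None:
        header = [f.strip() for f in rows[0]]
        rows = rows[1:]
        if not rows:
            raise ParseError(f"{path}: header row but no data rows")

    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=float)
    for r, fields in enumerate(rows):
        if len(fields) != width:
            raise ParseError(
                f"{path}: row {r + 1} has {len(fields)} columns, expected {width}"
            )
        for c, f in enumerate(fields):
            try:
                data[r, c] = float(f)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at row {r + 1}, column {c + 1}: {f!r}"
                ) from None
    if header is not None and len(header) != width:
        raise ParseError(
            f"{path}: header has {len(header)} labels for {width} columns"
        )
    return header, data


def read_expression_files(
    wildtype_path: str | Path, knockout_path: str | Path
) -> ExpressionDataset:
    """Read a wild-type vector file and an N x N knockout table file.

    Row *i* of the knockout file is the experiment in which gene *i* (the
    *i*-th column label) was deleted.
    """
    wt_header, wt = _read_numeric_table(wildtype_path)
    ko_header, ko = _read_numeric_table(knockout_path)
    if wt.shape[0] != 1:
        raise ValidationError(
            f"{wildtype_path}: expected a single wild-type row, got shape {wt.shape}"
        )
    wt = wt[0]
    if ko.shape[0] != ko.shape[1]:
        raise ValidationError(
            f"{knockout_path}: knockout table must be square "
            f"(one row per deleted gene), got shape {ko.shape}"
        )
    if wt.shape[0] != ko.shape[1]:
        raise ValidationError(
            f"dimension mismatch: wild-type has {wt.shape[0]} genes, "
            f"knockout table shape is {ko.shape}"
        )
    names = ko_header or wt_header or default_gene_names(len(wt))
    return ExpressionDataset(gene_names=list(names), wildtype=wt, knockout=ko)


def write_expression_files(
    data: ExpressionDataset,
    wildtype_path: str | Path,
    knockout_path: str | Path,
    header: bool = True,
) -> None:
    """Write the dataset back out in the tab-separated dialect."""

    def dump(path: str | Path, table: np.ndarray) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write("\t".join(data.gene_names) + "\n")
            for row in np.atleast_2d(table):
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")

    dump(wildtype_path, data.wildtype)
    dump(knockout_path, data.knockout)


def read_gold_standard(path: str | Path, n_genes: int) -> GeneNetwork:
    """Read a DREAM gold-standard edge list.

    Each line is ``G<i>\\tG<j>\\t{0|1}``; only indicator-1 pairs become
    edges, and pairs absent from the file are absent edges.
    """
    path = Path(path)
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected 3"
                )
            where = f"{path}: line {lineno}"
            src = _parse_label(fields[0], n_genes, where)
            dst = _parse_label(fields[1], n_genes, where)
            if fields[2] not in ("0", "1"):
                raise ParseError(f"{where}: indicator must be 0 or 1, got {fields[2]!r}")
            if fields[2] == "1":
                if src == dst:
                    raise ValidationError(f"{where}: self-interaction {fields[0]}")
                edges.append((src, dst))
    return GeneNetwork.from_edges(n_genes, edges)


def write_gold_standard(net: GeneNetwork, path: str | Path) -> None:
    """Write the edge set as indicator-1 lines (absent pairs are omitted)."""
    names = default_gene_names(net.n_genes)
    with open(path, "w") as fh:
        for i, j in sorted(net.edges):
            fh.write(f"{names[i]}\t{names[j]}\t1\n")


def write_prediction(ranking: EdgeRanking, path: str | Path) -> None:
    """Write a ranked prediction file, one ``G<i>\\tG<j>\\t<score>`` line per
    pair, best first.  Scores keep >= 6 significant digits so the ordering
    survives a round-trip."""
    with open(path, "w") as fh:
        for i, j, score in ranking.entries:
            fh.write(f"{ranking.gene_names[i]}\t{ranking.gene_names[j]}\t{score:.8g}\n")


def read_prediction(path: str | Path, n_genes: int | None = None) -> EdgeRanking:
    """Read a ranked prediction file written by :func:`write_prediction`.

    If ``n_genes`` is omitted it is inferred from the largest label seen.
    """
    path = Path(path)
    raw: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected 3"
                )
            try:
                score = float(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: bad score {fields[2]!r}"
                ) from None
            raw.append((fields[0], fields[1], score))
    if n_genes is None:
        n_genes = 0
        for a, b, _ in raw:
            for lab in (a, b):
                m = _LABEL_RE.match(lab)
                if not m:
                    raise ValidationError(f"{path}: gene label {lab!r} is not of the form G<i>")
                n_genes = max(n_genes, int(m.group(1)))
    entries = [
        (_parse_label(a, n_genes, str(path)), _parse_label(b, n_genes, str(path)), s)
        for a, b, s in raw
    ]
    return EdgeRanking(n_genes=n_genes, entries=entries)
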