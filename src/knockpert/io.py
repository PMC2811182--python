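"""Tab-delimited readers and writers for knockout / perturbation benchmarks.

The on-disk dialect mirrors the DREAM3 in silico challenge files:

* deletion matrix — header of gene labels (optionally preceded by a
  strain-label column header), one row labelled ``wt`` for the wild type and
  one row per deletion strain labelled by the deleted gene;
* time series — blocks separated by a blank line, each starting with a
  ``Time`` header followed by the gene labels, then rows of time stamp plus
  one expression value per gene;
* gold standard — ``G<i>\\tG<j>\\t<0|1>`` edge lines;
* predictions — ``G<i>\\tG<j>\\t<score>`` lines in descending confidence.

All matrices are strain-major / time-major: one row per strain or time
point, one column per gene. Gene order is defined by the file header and is
preserved everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DeletionDataset",
    "PerturbationDataset",
    "Trajectory",
    "GoldStandard",
    "ParseError",
    "read_deletion",
    "write_deletion",
    "read_timeseries",
    "write_timeseries",
    "read_gold_standard",
    "write_gold_standard",
    "read_predictions",
    "write_predictions",
    "default_labels",
]


class ParseError(ValueError):
    """Raised for malformed benchmark files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def default_labels(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


@dataclass
class DeletionDataset:
    """Steady-state expression of every gene in wild type and in each
    single-gene deletion strain.

    ``strains[i, j]`` is the observed level of gene ``j`` in the strain with
    gene ``i`` deleted; ``wild_type[j]`` is the observed wild-type level.
    ``zygosity`` is ``"homozygous"`` (null mutant) or ``"heterozygous"``
    (one copy deleted).
    """

    gene_labels: list[str]
    wild_type: np.ndarray
    strains: np.ndarray
    zygosity: str = "homozygous"

    def __post_init__(self):
        self.wild_type = np.asarray(self.wild_type, dtype=float)
        self.strains = np.asarray(self.strains, dtype=float)
        n = len(self.gene_labels)
        if self.strains.shape != (n, n):
            raise ValueError(
                f"strain matrix must be {n}x{n}, got {self.strains.shape}"
            )
        if self.wild_type.shape != (n,):
            raise ValueError("wild-type vector length must match gene labels")
        if not (np.isfinite(self.strains).all() and np.isfinite(self.wild_type).all()):
            raise ValueError("non-finite expression value")
        if self.zygosity not in ("homozygous", "heterozygous"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_labels)


@dataclass
class Trajectory:
    """One perturbation experiment: times (first stamp is the perturbation
    time 0) and a times-by-genes expression matrix."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.times.shape[0]:
            raise ValueError("values must be a times-by-genes matrix")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("non-increasing time stamps")


@dataclass
class PerturbationDataset:
    """A set of time-stamped expression trajectories of all genes after
    initial perturbations."""

    gene_labels: list[str]
    series: list[Trajectory]

    def __post_init__(self):
        n = len(self.gene_labels)
        for traj in self.series:
            if traj.values.shape[1] != n:
                raise ValueError("trajectory gene count does not match labels")

    @property
    def n_genes(self) -> int:
        return len(self.gene_labels)


@dataclass
class GoldStandard:
    """True signed directed edges: ``signs[(regulator, target)]`` in
    {+1, -1, 0} with 0 meaning sign unknown."""

    gene_labels: list[str]
    signs: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        for (a, b) in self.signs:
            if a == b:
                raise ValueError(f"self-pair {a}->{b} in gold standard")

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.signs)


def _lines(path) -> list[str]:
    return Path(path).read_text(encoding="utf-8").splitlines()


def read_deletion(path, zygosity: str = "homozygous") -> DeletionDataset:
    """Read a deletion steady-state matrix.

    The header carries the gene labels; a leading non-gene column header
    (e.g. ``strain``) is allowed. One row must be labelled ``wt``; every gene
    must have exactly one deletion-strain row labelled by the gene.
    """
    lines = _lines(path)
    if not lines:
        raise ParseError("empty file", 1)
    header = lines[0].rstrip("\n").split("\t")
    if not header or header == [""]:
        raise ParseError("malformed header", 1)
    rows: dict[str, np.ndarray] = {}
    labels: list[str] | None = None
    n_fields: int | None = None
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if n_fields is None:
            n_fields = len(parts)
            # resolve whether the header had a strain-label column
            if len(header) == n_fields:
                labels = header[1:]
            elif len(header) == n_fields - 1:
                labels = header
            else:
                raise ParseError(
                    f"header has {len(header)} fields but data rows have {n_fields}", 1
                )
            if len(set(labels)) != len(labels):
                raise ParseError("duplicate gene label in header", 1)
        elif len(parts) != n_fields:
            raise ParseError(f"expected {n_fields} fields, got {len(parts)}", lineno)
        strain = parts[0]
        if strain in rows:
            raise ParseError(f"duplicate strain label {strain!r}", lineno)
        try:
            rows[strain] = np.array([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"non-numeric cell ({exc})", lineno) from None
    if labels is None:
        raise ParseError("no data rows", 1)
    if "wt" not in rows:
        raise ParseError("missing wt row", len(lines))
    missing = [g for g in labels if g not in rows]
    if missing:
        raise ParseError(f"missing strain row(s) for {missing}", len(lines))
    strains = np.stack([rows[g] for g in labels])
    return DeletionDataset(list(labels), rows["wt"], strains, zygosity)


def write_deletion(data: DeletionDataset, path) -> None:
    out = ["strain\t" + "\t".join(data.gene_labels)]
    out.append("wt\t" + "\t".join(repr(float(v)) for v in data.wild_type))
    for g, row in zip(data.gene_labels, data.strains):
        out.append(g + "\t" + "\t".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_timeseries(path) -> PerturbationDataset:
    """Read a multi-block perturbation time-series file (blank-line-separated
    blocks, each with a ``Time`` + gene-labels header)."""
    lines = _lines(path)
    blocks: list[list[tuple[int, str]]] = [[]]
    for lineno, raw in enumerate(lines, start=1):
        if raw.strip():
            blocks[-1].append((lineno, raw))
        elif blocks[-1]:
            blocks.append([])
    blocks = [b for b in blocks if b]
    if not blocks:
        raise ParseError("no time-series blocks", 1)
    labels: list[str] | None = None
    series = []
    for block in blocks:
        lineno, head = block[0]
        parts = head.split("\t")
        if not parts or parts[0].lower() != "time":
            raise ParseError("block header must start with 'Time'", lineno)
        block_labels = parts[1:]
        if labels is None:
            labels = block_labels
        elif block_labels != labels:
            raise ParseError("inconsistent gene columns across blocks", lineno)
        times, values = [], []
        for lineno, raw in block[1:]:
            parts = raw.split("\t")
            if len(parts) != len(labels) + 1:
                raise ParseError(
                    f"expected {len(labels) + 1} fields, got {len(parts)}", lineno
                )
            try:
                times.append(float(parts[0]))
                values.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"non-numeric cell ({exc})", lineno) from None
        if len(times) >= 2 and np.any(np.diff(times) <= 0):
            raise ParseError("non-increasing time stamps", block[-1][0])
        series.append(Trajectory(np.array(times), np.array(values)))
    return PerturbationDataset(list(labels), series)


def write_timeseries(data: PerturbationDataset, path) -> None:
    chunks = []
    header = "Time\t" + "\t".join(data.gene_labels)
    for traj in data.series:
        rows = [header]
        for t, row in zip(traj.times, traj.values):
            rows.append(repr(float(t)) + "\t" + "\t".join(repr(float(v)) for v in row))
        chunks.append("\n".join(rows))
    Path(path).write_text("\n\n".join(chunks) + "\n", encoding="utf-8")


def read_gold_standard(path, gene_labels: Sequence[str] | None = None) -> GoldStandard:
    """Read a signed edge list ``regulator\\ttarget\\t<sign>`` where the third
    column is 1/-1 (signed) or 1/0 in the DREAM convention (1 = edge; pairs
    absent or 0 are non-edges)."""
    signs: dict[tuple[str, str], int] = {}
    seen_labels: list[str] = []
    for lineno, raw in enumerate(_lines(path), start=1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 3:
            raise ParseError("expected 3 tab-separated fields", lineno)
        a, b, s = parts
        for g in (a, b):
            if g not in seen_labels:
                seen_labels.append(g)
        try:
            val = int(float(s))
        except ValueError:
            raise ParseError(f"non-numeric sign {s!r}", lineno) from None
        if val == 0:
            continue
        if a == b:
            raise ParseError(f"self-pair {a}->{b}", lineno)
        if (a, b) in signs:
            raise ParseError(f"duplicate pair {a}->{b}", lineno)
        signs[(a, b)] = 1 if val > 0 else -1
    labels = list(gene_labels) if gene_labels is not None else sorted(
        seen_labels, key=lambda g: (len(g), g)
    )
    return GoldStandard(labels, signs)


def write_gold_standard(gold: GoldStandard, path, signed: bool = True) -> None:
    out = []
    for (a, b), s in sorted(gold.signs.items()):
        out.append(f"{a}\t{b}\t{s if signed else 1}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""), encoding="utf-8")


def write_predictions(ranked, path) -> None:
    """Write a ranked edge list, one ``regulator\\ttarget\\tscore`` line per
    candidate pair in descending confidence (DREAM submission convention).

    Batch-native scores are not comparable across batches, so the written
    score is the strictly decreasing rank score m, m-1, ..., 1.
    """
    m = len(ranked.entries)
    out = [
        f"{e.regulator}\t{e.target}\t{float(m - rank):.6g}"
        for rank, e in enumerate(ranked.entries)
    ]
    Path(path).write_text("\n".join(out) + ("\n" if out else ""), encoding="utf-8")


def read_predictions(path):
    """Read a ranked edge list back. Scores are kept to printed precision;
    batch/sign/provenance information is not stored on disk."""
    from .combine import PredictionEntry, RankedPredictions

    entries = []
    seen = set()
    for lineno, raw in enumerate(_lines(path), start=1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 3:
            raise ParseError("expected 3 tab-separated fields", lineno)
        a, b, s = parts
        if (a, b) in seen:
            raise ParseError(f"duplicate pair {a}->{b}", lineno)
        seen.add((a, b))
        try:
            entries.append(PredictionEntry(a, b, batch=0, score=float(s), sign=0))
        except ValueError:
            raise ParseError(f"non-numeric score {s!r}", lineno) from None
    return RankedPredictions(entries=entries, validate_partition=False)
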