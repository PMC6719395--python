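"""Plain-text file formats: frequency TSV, tree edge lists, constraint
files, solution JSON-lines, read-count TSVs, DOT export, run manifests.

Values are written exactly: a frequency is printed as a decimal when its
denominator divides a power of ten and as ``p/q`` otherwise, so a
write-then-read round trip reproduces the matrix bit for bit.  Readers
accept both forms (and any decimal string).  All writers sort keys and end
with a newline so outputs are stable across platforms.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .core import (
    CloneTree,
    FrequencyMatrix,
    Solution,
    ValidationError,
    validate_frequency_matrix,
    verify_solution,
)

__all__ = [
    "ParseError",
    "RunManifest",
    "format_fraction",
    "read_frequency_tsv",
    "write_frequency_tsv",
    "read_tree_edgelist",
    "write_tree_edgelist",
    "tree_to_dot",
    "read_pairs_file",
    "write_pairs_file",
    "read_cells_file",
    "write_cells_file",
    "write_solutions_jsonl",
    "read_solutions_jsonl",
    "write_read_counts_tsv",
    "frequency_matrix_hash",
    "write_manifest",
]


class ParseError(ValueError):
    """A file could not be parsed; the message carries the line number."""


def format_fraction(x: Fraction) -> str:
    """Exact text form: decimal if the denominator is 2^a 5^b, else p/q."""
    den = x.denominator
    while den % 2 == 0:
        den //= 2
    while den % 5 == 0:
        den //= 5
    if den == 1:
        # terminating decimal: scale to 10^k with k = max(twos, fives)
        d = x.denominator
        a = b = 0
        while d % 2 == 0:
            d //= 2
            a += 1
        while d % 5 == 0:
            d //= 5
            b += 1
        k = max(a, b)
        scaled = x.numerator * 10**k // x.denominator
        if k == 0:
            return str(scaled)
        s = str(scaled).rjust(k + 1, "0")
        return (s[:-k] + "." + s[-k:]).rstrip("0").rstrip(".") or "0"
    return f"{x.numerator}/{x.denominator}"


# ---------------------------------------------------------------------------
# Frequency matrices


def read_frequency_tsv(path) -> FrequencyMatrix:
    """Read a frequency TSV: header ``sample<TAB>mut...``, one row per
    sample, exact decimal or p/q values."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "sample":
        raise ParseError(f"{path}:1: header must be 'sample<TAB>mut_1<TAB>...'")
    mut_labels = header[1:]
    sample_labels = []
    values = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        sample_labels.append(cells[0])
        row = []
        for j, cell in enumerate(cells[1:]):
            try:
                f = Fraction(cell)
            except (ValueError, ZeroDivisionError) as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric value {cell!r} "
                    f"for mutation {mut_labels[j]!r}"
                ) from exc
            if not (0 <= f <= 1):
                raise ParseError(
                    f"{path}:{lineno}: value {cell} out of [0,1] "
                    f"for mutation {mut_labels[j]!r}"
                )
            row.append(f)
        values.append(row)
    try:
        return validate_frequency_matrix(values, sample_labels, mut_labels)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_frequency_tsv(F: FrequencyMatrix, path) -> None:
    F = validate_frequency_matrix(F)
    lines = ["sample\t" + "\t".join(F.mutation_labels)]
    for p, lab in enumerate(F.sample_labels):
        lines.append(lab + "\t" + "\t".join(format_fraction(v) for v in F.values[p]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trees


def read_tree_edgelist(path) -> CloneTree:
    """Two-column parent<TAB>child TSV; root inferred as the label never
    appearing as a child."""
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'parent<TAB>child'")
        edges.append((cells[0], cells[1]))
    if not edges:
        raise ParseError(f"{path}: no edges")
    try:
        return CloneTree.from_edges(edges)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_tree_edgelist(T: CloneTree, path) -> None:
    lines = [f"{p}\t{c}" for p, c in sorted(T.edges())]
    Path(path).write_text("\n".join(lines) + "\n")


def tree_to_dot(T: CloneTree, name: str = "clone_tree") -> str:
    out = [f"digraph {name} {{"]
    for v in sorted(T.vertices):
        out.append(f'  "{v}";')
    for p, c in sorted(T.edges()):
        out.append(f'  "{p}" -> "{c}";')
    out.append("}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Constraint files


def read_pairs_file(path) -> list[tuple[str, str]]:
    """One long-read pair per line: ``mut_a<TAB>mut_b``."""
    pairs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != 2 or cells[0] == cells[1]:
            raise ParseError(f"{path}:{lineno}: expected two distinct labels")
        pairs.append((cells[0], cells[1]))
    return pairs


def write_pairs_file(pairs: Iterable, path) -> None:
    lines = ["\t".join(sorted(p)) for p in pairs]
    Path(path).write_text("\n".join(sorted(lines)) + "\n" if lines else "")


def read_cells_file(path) -> list[frozenset[str]]:
    """One cell per line: comma-separated mutation labels."""
    cells = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        labels = [x.strip() for x in line.split(",") if x.strip()]
        if not labels:
            raise ParseError(f"{path}:{lineno}: empty cell")
        cells.append(frozenset(labels))
    return cells


def write_cells_file(cells: Iterable[Iterable[str]], path) -> None:
    lines = [",".join(sorted(c)) for c in cells]
    Path(path).write_text("\n".join(lines) + "\n" if lines else "")


# ---------------------------------------------------------------------------
# Solutions (JSON-lines)


def frequency_matrix_hash(F: FrequencyMatrix) -> str:
    F = validate_frequency_matrix(F)
    payload = json.dumps(
        {
            "samples": list(F.sample_labels),
            "mutations": list(F.mutation_labels),
            "values": [[format_fraction(v) for v in row] for row in F.values],
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_solutions_jsonl(solutions: Sequence[Solution], path) -> None:
    """One JSON record per solution: root, edges, exact U, provenance."""
    records = []
    for sol in solutions:
        F = sol.frequencies
        records.append(
            json.dumps(
                {
                    "root": sol.tree.root,
                    "edges": sorted(sol.tree.edges()),
                    "mixture": [
                        [format_fraction(u) for u in row]
                        for row in sol.mixture.values
                    ],
                    "instance_hash": frequency_matrix_hash(F),
                    "tool_version": __version__,
                },
                sort_keys=True,
            )
        )
    Path(path).write_text("\n".join(records) + "\n" if records else "")


def read_solutions_jsonl(path, F: FrequencyMatrix | None = None) -> list:
    """Read solution records; returns verified Solutions when F is given,
    otherwise bare CloneTrees."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            tree = CloneTree.from_edges([tuple(e) for e in rec["edges"]])
        except (json.JSONDecodeError, KeyError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: bad solution record: {exc}") from exc
        out.append(verify_solution(F, tree) if F is not None else tree)
    return out


def write_read_counts_tsv(counts, variant_path, total_path) -> None:
    for grid, path in ((counts.variant, variant_path), (counts.total, total_path)):
        lines = ["sample\t" + "\t".join(counts.mutation_labels)]
        for p, lab in enumerate(counts.sample_labels):
            lines.append(lab + "\t" + "\t".join(str(int(x)) for x in grid[p]))
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Run manifests


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record written next to every stochastic output."""

    tool_version: str
    subcommand: str
    parameters: dict
    seed: int | None
    input_hashes: dict
    timestamp: str


def write_manifest(
    path,
    subcommand: str,
    parameters: dict,
    seed: int | None,
    input_hashes: dict | None = None,
) -> RunManifest:
    manifest = RunManifest(
        tool_version=__version__,
        subcommand=subcommand,
        parameters=parameters,
        seed=seed,
        input_hashes=input_hashes or {},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    Path(path).write_text(json.dumps(asdict(manifest), sort_keys=True, indent=2) + "\n")
    return manifest
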