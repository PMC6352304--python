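"""Reading genomes and persisting tables.

All tabular artifacts are TSV (UTF-8, dot decimal separator): the parameter
table, species labels, similarity matrices, pair calls and ROC reports.
Parameter tables carry provenance as ``# key=value`` comment lines (tool
version, the A_cp position count N, whether rearrangement was applied) so a
precomputed database is self-describing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .delineation import SimilarityMatrix
from .parameters import PARAMETER_NAMES, GenomeParameters

__all__ = [
    "ParameterTable",
    "read_genome_fasta",
    "write_rearranged_fasta",
    "write_parameter_table",
    "read_parameter_table",
    "read_labels",
    "write_labels",
    "write_similarity_matrix",
    "read_similarity_matrix_frame",
]

_COLUMNS = ("genome_id", "length", *PARAMETER_NAMES)


@dataclass
class ParameterTable:
    """Ordered genome parameter records plus provenance metadata."""

    records: list[GenomeParameters]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.genome_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate genome ids: {dupes}")

    def merge(self, other: "ParameterTable") -> "ParameterTable":
        overlap = {r.genome_id for r in self.records} & {
            r.genome_id for r in other.records
        }
        if overlap:
            raise ValueError(f"overlapping genome ids in merge: {sorted(overlap)}")
        for key in ("a_cp_n_positions", "rearrangement"):
            a, b = self.provenance.get(key), other.provenance.get(key)
            if a is not None and b is not None and a != b:
                warnings.warn(
                    f"merging parameter tables with different {key}: {a} vs {b}",
                    stacklevel=2,
                )
        return ParameterTable(self.records + other.records, dict(self.provenance))

    def __len__(self) -> int:
        return len(self.records)


def read_genome_fasta(path, *, concatenate: bool = False) -> tuple[str, str]:
    """Read one whole-genome record from a FASTA file.

    Returns ``(genome_id, sequence)`` with the id taken from the header's
    first token.  Files with several records are rejected by default — the
    descriptors are only meaningful for closed single-sequence genomes, not
    multi-scaffold assemblies.  ``concatenate=True`` overrides by joining the
    records in file order without a spacer (with a warning).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        if not concatenate:
            raise ValueError(
                f"{path} contains {len(records)} records; the method requires a "
                "single closed genome per file (multi-scaffold assemblies are "
                "not comparable) — pass concatenate=True to join them anyway"
            )
        warnings.warn(
            f"concatenating {len(records)} records of {path} in file order; "
            "the result is sensitive to scaffold order and orientation",
            stacklevel=2,
        )
    seq = "".join(str(r.seq) for r in records).upper()
    return records[0].id, seq


def write_rearranged_fasta(path, genome_id: str, sequence: str, rotation_offset: int) -> None:
    """Write a rotated genome, noting the rotation offset in the description."""
    with open(path, "w") as fh:
        fh.write(f">{genome_id} rotated by {rotation_offset} bp to cumulated-phase minimum\n")
        for k in range(0, len(sequence), 80):
            fh.write(sequence[k : k + 80] + "\n")


def write_parameter_table(table: ParameterTable | list[GenomeParameters], path) -> None:
    """Serialize records as TSV with ``# key=value`` provenance comments.

    Floats are written with 17 significant digits, so a write/read round trip
    is lossless.
    """
    if isinstance(table, list):
        table = ParameterTable(table)
    prov = {
        "tool_version": __version__,
        "a_cp_n_positions": "10",
        "rearrangement": "true",
        **table.provenance,
    }
    with open(path, "w") as fh:
        for key, value in prov.items():
            fh.write(f"# {key}={value}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in table.records:
            fh.write(
                f"{r.genome_id}\t{r.length}\t{r.diff_p:.17g}\t{r.tr_0:.17g}"
                f"\t{r.tr_cg:.17g}\t{r.a_cp:.17g}\n"
            )


def read_parameter_table(path) -> ParameterTable:
    """Read a TSV parameter table written by :func:`write_parameter_table`."""
    provenance: dict[str, str] = {}
    rows: list[GenomeParameters] = []
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        stripped = line[1:].strip()
        if "=" in stripped:
            key, _, value = stripped.partition("=")
            provenance[key.strip()] = value.strip()
    if body_start >= len(lines):
        raise ValueError(f"{path}: no header row")
    header = lines[body_start].rstrip("\n").split("\t")
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    col = {name: header.index(name) for name in _COLUMNS}
    for lineno, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            rows.append(
                GenomeParameters(
                    genome_id=fields[col["genome_id"]],
                    length=int(fields[col["length"]]),
                    diff_p=float(fields[col["diff_p"]]),
                    tr_0=float(fields[col["tr_0"]]),
                    tr_cg=float(fields[col["tr_cg"]]),
                    a_cp=float(fields[col["a_cp"]]),
                )
            )
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from None
    return ParameterTable(rows, provenance)


def read_labels(path) -> dict[str, str]:
    """Read a two-column ``genome_id<TAB>species`` table (header optional)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: expected 2 tab-separated columns at line {lineno}")
            if lineno == 1 and fields[0] in ("genome_id", "id"):
                continue
            labels[fields[0]] = fields[1]
    if not labels:
        raise ValueError(f"{path}: no labels found")
    return labels


def write_labels(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tspecies\n")
        for gid, sp in labels.items():
            fh.write(f"{gid}\t{sp}\n")


def write_similarity_matrix(matrix: SimilarityMatrix, path) -> None:
    """Square similarity matrix as TSV with id header row and column."""
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.6f", index_label="genome_id")


def read_similarity_matrix_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
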