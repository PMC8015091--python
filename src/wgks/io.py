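"""Readers and writers for the pipeline's file formats.

FASTA input (plain or gzip) is parsed with Biopython; everything written
out is plain text: labeled TSV matrices, TSV cluster tables, Newick trees
and JSON diagnostics, all deterministic for a given input and config.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .cluster import ClusterReport, DiagnosticsReport
from .compare import CorrelationMatrix
from .exceptions import InvalidInputError
from .identity import AlignmentBlock
from .kmer import GenomeSequence, SignatureVector, rank_to_kmer
from .tree import TreeNode, write_newick

__all__ = [
    "read_genome_fasta",
    "read_alignment_fasta",
    "write_genome_fasta",
    "write_alignment_fasta",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_signature_tsv",
    "write_cluster_table_tsv",
    "write_diagnostics_json",
    "write_tree_newick",
]


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _check_fasta_header(path: Path) -> None:
    """Fail early, with a line number, on files that are not FASTA."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise InvalidInputError(
                    f"{path}:{lineno}: expected a FASTA header line starting with '>'"
                )
            return
    raise InvalidInputError(f"{path}: empty FASTA file")


def _read_records(path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    _check_fasta_header(path)
    with _open_text(path) as fh:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise InvalidInputError(f"{path}: no FASTA records")
    for rid, seq in records:
        if len(seq) == 0:
            raise InvalidInputError(f"{path}: record {rid!r} has an empty sequence")
    return records


def species_label_from_path(path) -> str:
    """Default species label: the file name without .fa/.fasta/.fna/.gz."""
    name = Path(path).name
    for suffix in (".gz", ".fa", ".fasta", ".fna"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def read_genome_fasta(path, species_label: str | None = None) -> GenomeSequence:
    """Read one species' (multi-record) genome from FASTA, plain or gzip."""
    records = _read_records(path)
    label = species_label if species_label is not None else species_label_from_path(path)
    return GenomeSequence(label, [seq for _, seq in records])


def read_alignment_fasta(path) -> AlignmentBlock:
    """Read an aligned FASTA; unequal row lengths are a parse error."""
    records = _read_records(path)
    width = len(records[0][1])
    for rid, seq in records:
        if len(seq) != width:
            raise InvalidInputError(
                f"{path}: aligned record {rid!r} has length {len(seq)}, expected {width}"
            )
    return AlignmentBlock(labels=[rid for rid, _ in records], rows=[s for _, s in records])


def _wrap(seq: str, width: int = 80) -> Iterable[str]:
    for i in range(0, len(seq), width):
        yield seq[i : i + width]


def write_genome_fasta(genome: GenomeSequence, path) -> None:
    with open(path, "wt") as fh:
        for i, rec in enumerate(genome.records, start=1):
            fh.write(f">{genome.species_label}_rec{i}\n")
            for line in _wrap(rec):
                fh.write(line + "\n")


def write_alignment_fasta(alignment: AlignmentBlock, path) -> None:
    with open(path, "wt") as fh:
        for label, row in zip(alignment.labels, alignment.rows):
            fh.write(f">{label}\n")
            for line in _wrap(row):
                fh.write(line + "\n")


def write_matrix_tsv(matrix: CorrelationMatrix, path, precision: int = 6) -> None:
    """Labeled square matrix as TSV (first row and column are labels)."""
    df = matrix.to_dataframe()
    df.to_csv(path, sep="\t", float_format=f"%.{precision}f", index_label="species")


def read_matrix_tsv(path, kind: str = "pcc") -> CorrelationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise InvalidInputError(f"{path}: matrix rows and columns disagree")
    values = df.to_numpy(dtype=float)
    # round-tripping through fixed-precision text perturbs symmetry/diagonal
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(labels=tuple(df.index), values=values, kind=kind)


def write_signature_tsv(signature: SignatureVector, path) -> None:
    """Two-column TSV (word, score) in lexicographic word order."""
    with open(path, "wt") as fh:
        fh.write(f"# species={signature.species_label}\tk={signature.k}\n")
        fh.write("word\tscore\n")
        for rank, score in enumerate(signature.scores):
            fh.write(f"{rank_to_kmer(rank, signature.k)}\t{score:.8g}\n")


def write_cluster_table_tsv(table: pd.DataFrame, reports: list[ClusterReport], path) -> None:
    """Cluster statistics table plus a members column, TSV."""
    out = table.copy()
    out["members"] = [";".join(r.members) for r in reports]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_diagnostics_json(diagnostics: DiagnosticsReport, path, extra: dict | None = None) -> None:
    payload = {
        "schema_version": 1,
        "hopkins": diagnostics.hopkins,
        "silhouette_by_k": {str(k): v for k, v in diagnostics.silhouette_by_k.items()},
        "wss_by_k": {str(k): v for k, v in diagnostics.wss_by_k.items()},
    }
    if diagnostics.silhouette_by_k:
        payload["best_k"] = diagnostics.best_k
    if extra:
        payload.update(extra)
    with open(path, "wt") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tree_newick(tree: TreeNode, path, precision: int = 6) -> None:
    with open(path, "wt") as fh:
        fh.write(write_newick(tree, precision=precision) + "\n")
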