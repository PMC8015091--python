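"""High-level analysis objects: build from data, ``fit()``, inspect results.

:class:`WgksAnalysis` runs the whole-genome k-mer signature study: genomes
-> signatures -> Pearson correlation matrix -> diagnostics, clusters with
p-values, UPGMA tree. :class:`IdentityAnalysis` runs the parallel
alignment stage: multiple alignment -> identity matrix -> diagnostics,
clusters, UPGMA and neighbor-joining trees. Both return a results object
carrying every artifact, a ``summary()`` table and writers for the
on-disk outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as wio
from .cluster import (
    ClusterReport,
    DiagnosticsReport,
    Linkage,
    PValueTest,
    cluster_table,
    hopkins_statistic,
    silhouette_sweep,
    wss_sweep,
)
from .compare import CorrelationMatrix, pcc_matrix
from .exceptions import InvalidInputError
from .identity import DEFAULT_DIALECT, AlignmentBlock, IdentityDialect, identity_matrix
from .kmer import GenomeSequence, K_DEFAULT, SignatureVector, wgks_signature
from .tree import TreeNode, neighbor_joining, upgma, write_newick

__all__ = ["WgksAnalysis", "WgksResults", "IdentityAnalysis", "IdentityResults"]


def _diagnose(
    matrix: CorrelationMatrix,
    silhouette_range: tuple[int, int],
    hopkins_fraction: float,
    seed: int,
    linkage: Linkage,
) -> DiagnosticsReport:
    k_min, k_max = silhouette_range
    k_max = min(k_max, matrix.n - 1)
    sil = silhouette_sweep(matrix, k_min, k_max, linkage) if k_max >= k_min else {}
    wss = wss_sweep(matrix, k_min, k_max, linkage) if k_max >= k_min else {}
    return DiagnosticsReport(
        hopkins=hopkins_statistic(matrix, hopkins_fraction, seed),
        silhouette_by_k=sil,
        wss_by_k=wss,
    )


@dataclass
class _ResultsBase:
    matrix: CorrelationMatrix
    diagnostics: DiagnosticsReport
    clusters: list[ClusterReport]
    cluster_table: pd.DataFrame
    upgma_tree: TreeNode
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [self._title, "=" * len(self._title)]
        lines.append(f"species: {self.matrix.n}    matrix kind: {self.matrix.kind}")
        lines.append(
            "params: " + ", ".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        )
        lines.append(f"Hopkins clustering tendency: {self.diagnostics.hopkins:.3f}")
        if self.diagnostics.silhouette_by_k:
            sil = ", ".join(
                f"k={k}: {v:.3f}" for k, v in sorted(self.diagnostics.silhouette_by_k.items())
            )
            lines.append(f"average silhouette width   : {sil}")
            lines.append(f"best cluster count by silhouette: {self.diagnostics.best_k}")
        lines.append("")
        lines.append("Per-cluster within-similarity statistics")
        lines.append(self.cluster_table.to_string(index=False, na_rep="NA",
                                                  float_format=lambda x: f"{x:.4g}"))
        lines.append("")
        for rep in self.clusters:
            lines.append(f"cluster {rep.cluster_id}: {', '.join(rep.members)}")
        lines.append("")
        lines.append("UPGMA tree: " + write_newick(self.upgma_tree, precision=4))
        return "\n".join(lines)

    def plot_heatmap(self, ax=None):
        """Similarity heatmap with species labels (basic rendering)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.matrix.values, vmin=self.matrix.values.min(), vmax=1.0,
                       cmap="viridis")
        ax.set_xticks(range(self.matrix.n), self.matrix.labels, rotation=90, fontsize=6)
        ax.set_yticks(range(self.matrix.n), self.matrix.labels, fontsize=6)
        ax.figure.colorbar(im, ax=ax, label=self.matrix.kind)
        return ax


@dataclass
class WgksResults(_ResultsBase):
    """Artifacts of a fitted whole-genome k-mer signature analysis."""

    signatures: list[SignatureVector] = field(default_factory=list)
    _title = "Whole-Genome K-mer Signature analysis"

    def save(self, outdir) -> dict[str, Path]:
        """Write all artifacts (TSV/JSON/Newick) into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pcc_matrix": outdir / "pcc_matrix.tsv",
            "clusters": outdir / "cluster_table.tsv",
            "diagnostics": outdir / "diagnostics.json",
            "upgma": outdir / "upgma.nwk",
        }
        wio.write_matrix_tsv(self.matrix, paths["pcc_matrix"])
        wio.write_cluster_table_tsv(self.cluster_table, self.clusters, paths["clusters"])
        wio.write_diagnostics_json(self.diagnostics, paths["diagnostics"],
                                   extra={"params": self.params})
        wio.write_tree_newick(self.upgma_tree, paths["upgma"])
        for sig in self.signatures:
            p = outdir / f"signature_{sig.species_label}.tsv"
            wio.write_signature_tsv(sig, p)
            paths[f"signature:{sig.species_label}"] = p
        return paths


@dataclass
class IdentityResults(_ResultsBase):
    """Artifacts of a fitted alignment-identity analysis."""

    nj_tree: TreeNode | None = None
    _title = "Sequence-identity analysis"

    def summary(self) -> str:
        text = super().summary()
        if self.nj_tree is not None:
            text += "\nNJ tree   : " + write_newick(self.nj_tree, precision=4)
        return text

    def save(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "identity_matrix": outdir / "identity_matrix.tsv",
            "clusters": outdir / "cluster_table.tsv",
            "diagnostics": outdir / "diagnostics.json",
            "upgma": outdir / "upgma.nwk",
        }
        wio.write_matrix_tsv(self.matrix, paths["identity_matrix"])
        wio.write_cluster_table_tsv(self.cluster_table, self.clusters, paths["clusters"])
        wio.write_diagnostics_json(self.diagnostics, paths["diagnostics"],
                                   extra={"params": self.params})
        wio.write_tree_newick(self.upgma_tree, paths["upgma"])
        if self.nj_tree is not None:
            paths["nj"] = outdir / "nj.nwk"
            wio.write_tree_newick(self.nj_tree, paths["nj"])
        return paths


class WgksAnalysis:
    """Whole-genome k-mer signature comparison of a set of species.

    Parameters
    ----------
    genomes : sequence of GenomeSequence
        One per species, unique labels.
    k : int, default 8
        Word length; the signature has 4**k entries (65,536 octamer scores
        at the default).
    canonical : bool, default False
        Count both strands (reverse-complement symmetrized) instead of the
        forward strand only.

    Examples
    --------
    >>> from wgks import WgksAnalysis, CladeSpec, generate_clade_genomes
    >>> genomes, truth = generate_clade_genomes(CladeSpec(seed=42))
    >>> res = WgksAnalysis(genomes, k=6).fit(n_clusters=3)
    >>> print(res.summary())                       # doctest: +SKIP
    """

    def __init__(self, genomes: Sequence[GenomeSequence], k: int = K_DEFAULT,
                 canonical: bool = False):
        genomes = list(genomes)
        if len(genomes) < 2:
            raise InvalidInputError("need at least two genomes")
        labels = [g.species_label for g in genomes]
        if len(set(labels)) != len(labels):
            raise InvalidInputError("genome labels must be unique")
        self.genomes = genomes
        self.k = k
        self.canonical = canonical

    @classmethod
    def from_fasta(cls, paths: Sequence, k: int = K_DEFAULT, canonical: bool = False
                   ) -> "WgksAnalysis":
        """Build from one FASTA file (plain or gzip) per species."""
        if len(paths) < 2:
            raise InvalidInputError("need at least two genome FASTA files")
        return cls([wio.read_genome_fasta(p) for p in paths], k=k, canonical=canonical)

    def fit(
        self,
        n_clusters: int | None = None,
        linkage: Linkage = "ward",
        pvalue_test: PValueTest = "welch_t",
        silhouette_range: tuple[int, int] = (2, 7),
        hopkins_fraction: float = 0.1,
        seed: int = 0,
    ) -> WgksResults:
        """Run signatures -> PCC matrix -> diagnostics -> clusters -> tree.

        ``n_clusters=None`` picks the cluster count maximizing the average
        silhouette width over ``silhouette_range``. Clustering uses
        ``linkage`` (Ward by default); the reported tree is always UPGMA.
        """
        signatures = [wgks_signature(g, self.k, canonical=self.canonical)
                      for g in self.genomes]
        matrix = pcc_matrix(signatures)
        diagnostics = _diagnose(matrix, silhouette_range, hopkins_fraction, seed,
                                linkage)
        if n_clusters is None:
            n_clusters = diagnostics.best_k if diagnostics.silhouette_by_k else 1
        reports, table = cluster_table(matrix, n_clusters, linkage, pvalue_test)
        params = dict(k=self.k, canonical=self.canonical, linkage=linkage,
                      n_clusters=n_clusters, pvalue_test=pvalue_test,
                      hopkins_fraction=hopkins_fraction, seed=seed)
        return WgksResults(
            matrix=matrix,
            diagnostics=diagnostics,
            clusters=reports,
            cluster_table=table,
            upgma_tree=upgma(matrix),
            params=params,
            signatures=signatures,
        )


class IdentityAnalysis:
    """Clustering and trees from a pairwise identity matrix of an alignment.

    The alignment itself is an input (produced by any aligner); this class
    derives the identity matrix under an explicit counting dialect and
    reuses the clustering/tree machinery of the k-mer stage.
    """

    def __init__(self, alignment: AlignmentBlock, dialect: IdentityDialect = DEFAULT_DIALECT):
        if alignment.n < 3:
            raise InvalidInputError("need at least three aligned sequences")
        self.alignment = alignment
        self.dialect = dialect

    @classmethod
    def from_fasta(cls, path, dialect: IdentityDialect = DEFAULT_DIALECT) -> "IdentityAnalysis":
        return cls(wio.read_alignment_fasta(path), dialect=dialect)

    def fit(
        self,
        n_clusters: int | None = None,
        linkage: Linkage = "single",
        pvalue_test: PValueTest = "welch_t",
        silhouette_range: tuple[int, int] = (2, 7),
        hopkins_fraction: float = 0.1,
        seed: int = 0,
    ) -> IdentityResults:
        """Identity matrix -> diagnostics -> clusters -> UPGMA and NJ trees.

        Single linkage is the clustering default for this stage; the
        neighbor-joining tree is built alongside the UPGMA tree.
        """
        matrix = identity_matrix(self.alignment, self.dialect)
        if float(matrix.values.min()) >= 1.0:
            raise InvalidInputError(
                "all aligned sequences are identical; clustering is undefined"
            )
        diagnostics = _diagnose(matrix, silhouette_range, hopkins_fraction, seed,
                                linkage)
        if n_clusters is None:
            n_clusters = diagnostics.best_k if diagnostics.silhouette_by_k else 1
        reports, table = cluster_table(matrix, n_clusters, linkage, pvalue_test)
        params = dict(linkage=linkage,
                      n_clusters=n_clusters, pvalue_test=pvalue_test,
                      hopkins_fraction=hopkins_fraction, seed=seed,
                      dialect=f"{self.dialect.both_gap}/{self.dialect.gap_letter}/"
                              f"{self.dialect.ambiguous}")
        return IdentityResults(
            matrix=matrix,
            diagnostics=diagnostics,
            clusters=reports,
            cluster_table=table,
            upgma_tree=upgma(matrix),
            params=params,
            nj_tree=neighbor_joining(matrix) if matrix.n >= 3 else None,
        )
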