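"""Bacterial single-copy-gene (SCG) census of an assembly or bin.

Nearly every bacterial genome carries each gene of the bundled 139-gene
collection exactly once, so the array of per-gene hit counts across a set
of scaffolds indexes how many complete bacterial genomes that set
contains.  The point estimate is the mode of the array: with G complete
genomes present, most genes are hit exactly G times, while spurious or
duplicated hits perturb only a minority of genes.  Completeness and
redundancy of a genome bin are the percentage of the collection hit at
least once, respectively more than once.

Hits come from an upstream ``hmmsearch`` run against the collection; this
module parses its ``--tblout`` output (or a plain 3-column TSV), applies a
significance cutoff and counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScgCollection",
    "ScgHitTable",
    "ScgCensus",
    "load_collection",
    "parse_hmm_tblout",
    "census",
    "bin_completeness_redundancy",
    "occurrence_report",
    "DEFAULT_EVALUE_MAX",
]

DEFAULT_EVALUE_MAX = 1e-10


@dataclass(frozen=True)
class ScgCollection:
    """An ordered, unique list of single-copy gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty SCG collection")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers in collection")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ScgHitTable:
    """Significant SCG hits: one row per (gene, split_name, evalue)."""

    table: pd.DataFrame  # columns: gene, split_name, evalue

    def __post_init__(self) -> None:
        required = {"gene", "split_name", "evalue"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"hit table needs columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ScgCensus:
    """Per-gene hit counts and the derived genome-count estimate."""

    collection: ScgCollection
    hit_counts: np.ndarray  # one entry per gene, collection order
    estimated_genomes: int
    multimodal: bool

    def to_series(self) -> pd.Series:
        return pd.Series(self.hit_counts, index=list(self.collection.genes), name="hit_count")


def load_collection(path: str | Path | None = None, name: str | None = None) -> ScgCollection:
    """Load a gene-names file (one identifier per line, '#' comments).

    With no path, loads the bundled 139-gene bacterial collection.
    """
    if path is None:
        ref = resources.files("binsift.data") / "bacterial_scg_139.txt"
        text = ref.read_text()
        name = name or "bacterial_139"
    else:
        text = Path(path).read_text()
        name = name or Path(path).stem
    genes = tuple(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )
    return ScgCollection(name=name, genes=genes)


def parse_hmm_tblout(path: str | Path, collection: ScgCollection,
                     evalue_max: float = DEFAULT_EVALUE_MAX) -> ScgHitTable:
    """Parse hmmsearch ``--tblout`` output or a 3-column TSV of hits.

    tblout rows are whitespace-separated with the aligned sequence (split)
    in column 1, the query profile (gene) in column 3 and the full-sequence
    e-value in column 5; '#' lines are comments.  The TSV dialect has
    tab-separated columns ``gene``, ``split_name``, ``evalue`` (header
    optional).  Hits above ``evalue_max`` are dropped; hits against genes
    outside the collection are skipped with a warning.
    """
    known = set(collection.genes)
    rows: list[tuple[str, str, float]] = []
    skipped: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tab_fields = line.split("\t")
            if len(tab_fields) == 3:
                gene, split_name, ev = tab_fields
                if (gene, split_name, ev) == ("gene", "split_name", "evalue"):
                    continue  # optional header
            else:
                fields = line.split()
                if len(fields) < 5:
                    raise ValueError(f"{path}:{lineno}: unparseable hit line: {line!r}")
                split_name, gene, ev = fields[0], fields[2], fields[4]
            try:
                evalue = float(ev)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad e-value {ev!r}") from exc
            if gene not in known:
                skipped.add(gene)
                continue
            if evalue <= evalue_max:
                rows.append((gene, split_name.strip(), evalue))
    if skipped:
        warnings.warn(
            f"{len(skipped)} gene name(s) not in collection {collection.name!r} "
            f"skipped: {sorted(skipped)[:5]}"
        )
    df = pd.DataFrame(rows, columns=["gene", "split_name", "evalue"])
    return ScgHitTable(table=df)


def census(hits: ScgHitTable, collection: ScgCollection,
           subset: set[str] | None = None) -> ScgCensus:
    """Count hits per gene and estimate the number of complete bacterial
    genomes as the mode of the count array.

    Ties for the maximal frequency return the smallest tied count and set
    ``multimodal`` (conservative: never overstates contamination).  Every
    hit row counts, so a tandem-duplicated gene contributes extra copies.
    """
    df = hits.table
    if subset is not None:
        df = df[df["split_name"].isin(subset)]
    per_gene = df.groupby("gene").size()
    counts = np.array([int(per_gene.get(g, 0)) for g in collection.genes])
    freq = np.bincount(counts)
    top = freq.max()
    modes = np.flatnonzero(freq == top)
    return ScgCensus(
        collection=collection,
        hit_counts=counts,
        estimated_genomes=int(modes.min()),
        multimodal=len(modes) > 1,
    )


def bin_completeness_redundancy(hits: ScgHitTable, collection: ScgCollection,
                                bin_splits: set[str]) -> tuple[float, float]:
    """Completeness and redundancy (%) of a genome bin.

    Completeness = share of collection genes hit at least once in the bin;
    redundancy = share hit at least twice.
    """
    counts = census(hits, collection, subset=bin_splits).hit_counts
    n = len(collection)
    return 100.0 * (counts >= 1).sum() / n, 100.0 * (counts >= 2).sum() / n


def occurrence_report(censuses: list[tuple[str, ScgCensus]],
                      table_path: str | Path | None = None,
                      plot_path: str | Path | None = None) -> pd.DataFrame:
    """Square-root-normalized SCG occurrence report across scaffold sets.

    Returns a long table (label, gene, hit_count, sqrt_hit_count); when
    ``plot_path`` is given, draws one bar panel per labeled census (bar
    heights = sqrt of hit counts) with a box-plot summary at its left.
    """
    if not censuses:
        raise ValueError("need at least one census")
    frames = []
    for label, cen in censuses:
        frames.append(
            pd.DataFrame(
                {
                    "label": label,
                    "gene": list(cen.collection.genes),
                    "hit_count": cen.hit_counts,
                    "sqrt_hit_count": np.sqrt(cen.hit_counts),
                }
            )
        )
    long = pd.concat(frames, ignore_index=True)
    if table_path is not None:
        long.to_csv(table_path, sep="\t", index=False)
    if plot_path is not None:
        _plot_occurrence(censuses, plot_path)
    return long


def _plot_occurrence(censuses: list[tuple[str, ScgCensus]], plot_path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(censuses)
    fig, axes = plt.subplots(
        n, 2, figsize=(12, 2.2 * n), squeeze=False,
        gridspec_kw={"width_ratios": [1, 10]},
    )
    for row, (label, cen) in enumerate(censuses):
        heights = np.sqrt(cen.hit_counts)
        box_ax, bar_ax = axes[row]
        box_ax.boxplot(heights)
        box_ax.set_ylabel("sqrt(hits)")
        box_ax.set_xticks([])
        bar_ax.bar(np.arange(len(heights)), heights, width=1.0)
        bar_ax.set_title(f"{label} — estimated genomes: {cen.estimated_genomes}", fontsize=9)
        bar_ax.set_xlim(-0.5, len(heights) - 0.5)
        bar_ax.set_xticks([])
    axes[-1][1].set_xlabel(f"single-copy genes (n={len(censuses[0][1].collection)})")
    fig.tight_layout()
    fig.savefig(plot_path, dpi=150)
    plt.close(fig)
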