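"""Bin selection, scaffold resolution, curation statistics and export.

A *bin selection* assigns splits to named genome bins (from ``cut_tree``
or an external TSV).  Because curation decisions and FASTA export operate
on whole scaffolds, split-level selections are lifted to scaffolds by a
split-length majority rule; ties leave the scaffold unassigned.

Per-bin reports collect the evidence a curator weighs: size and GC, mean
coverage and detection per library, the single-copy-gene census
(completeness, redundancy, estimated genome count), the fraction of the
assembly's RNA signal recruited by the bin, and overlap with an external
annotation list (e.g. scaffolds carrying proposed horizontal gene
transfers).  A separate flag table marks scaffolds detected only in an
auxiliary subset of libraries — the signature of library-specific
contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contigs import ContigsTable, read_assembly
from .profiling import CoverageMatrixSet
from .scg import ScgCollection, ScgHitTable, census

__all__ = [
    "BinSelection",
    "AnnotationList",
    "load_selection",
    "load_annotation_list",
    "selection_from_clusters",
    "resolve_scaffolds",
    "bin_report",
    "flag_library_restricted",
    "export_bins",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


@dataclass
class BinSelection:
    """Mapping from split name to bin label; unassigned splits are absent."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for split, label in self.assignments.items():
            if not label:
                raise ValueError(f"empty bin label for split {split!r}")

    @property
    def bins(self) -> list[str]:
        seen: list[str] = []
        for label in self.assignments.values():
            if label not in seen:
                seen.append(label)
        return seen

    def splits_of(self, bin_label: str) -> set[str]:
        return {s for s, b in self.assignments.items() if b == bin_label}


@dataclass
class AnnotationList:
    """Externally flagged scaffold names (e.g. a proposed-HGT list)."""

    names: set[str]


def load_selection(tsv_path: str | Path, contigs: ContigsTable) -> BinSelection:
    """Read a selection TSV with columns (split_name, bin)."""
    path = Path(tsv_path)
    text = path.read_text()
    assignments: dict[str, str] = {}
    unknown: list[str] = []
    known = set(contigs.split_names)
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        split_name, bin_label = fields
        if (split_name, bin_label) == ("split_name", "bin"):
            continue  # optional header
        if split_name not in known:
            unknown.append(split_name)
            continue
        prev = assignments.get(split_name)
        if prev is not None and prev != bin_label:
            raise ValueError(
                f"{path}:{lineno}: split {split_name!r} assigned to both "
                f"{prev!r} and {bin_label!r}"
            )
        assignments[split_name] = bin_label
    if unknown:
        raise ValueError(f"{path}: unknown split names: {unknown[:5]}")
    return BinSelection(assignments)


def load_annotation_list(path: str | Path) -> AnnotationList:
    names = {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    return AnnotationList(names=names)


def selection_from_clusters(clusters: dict[str, int], prefix: str = "bin") -> BinSelection:
    """Turn a ``cut_tree`` result into a bin selection (bin_1, bin_2, ...)."""
    return BinSelection({split: f"{prefix}_{cid}" for split, cid in clusters.items()})


def resolve_scaffolds(selection: BinSelection, contigs: ContigsTable) -> dict[str, str]:
    """Lift the split-level selection to scaffolds by length majority.

    A scaffold goes to the bin holding the strict majority of its assigned
    split length; ties leave it unassigned (with a warning), as do
    scaffolds with no assigned split.
    """
    out: dict[str, str] = {}
    for scaffold, split_names in contigs.scaffold_index.items():
        mass: dict[str, int] = {}
        for name in split_names:
            label = selection.assignments.get(name)
            if label is not None:
                mass[label] = mass.get(label, 0) + contigs.split(name).length
        if not mass:
            out[scaffold] = UNASSIGNED
            continue
        best = max(mass.values())
        winners = [b for b, m in mass.items() if m == best]
        if len(winners) > 1:
            warnings.warn(f"scaffold {scaffold!r}: bin tie {sorted(winners)}; left unassigned")
            out[scaffold] = UNASSIGNED
        else:
            out[scaffold] = winners[0]
    return out


def _weighted_mean(values: pd.Series, weights: np.ndarray) -> float:
    total = weights.sum()
    if total == 0:
        return 0.0
    return float(np.average(values.to_numpy(), weights=weights))


def bin_report(selection: BinSelection, contigs: ContigsTable, coverage: CoverageMatrixSet,
               hits: ScgHitTable, collection: ScgCollection,
               annotations: AnnotationList | None = None,
               rna_samples: list[str] | None = None) -> pd.DataFrame:
    """One curation-statistics row per bin, plus one for the unassigned rest.

    ``rna_recruitment`` of a bin is its share of the assembly-wide RNA
    detection x length mass — a proxy for the share of transcriptome reads
    the bin would recruit; rows sum to 1 whenever any RNA signal exists.
    """
    rna_samples = list(rna_samples) if rna_samples else []
    missing_rna = [s for s in rna_samples if s not in coverage.sample_ids]
    if missing_rna:
        raise ValueError(f"RNA sample(s) not in coverage: {missing_rna}")

    resolved = resolve_scaffolds(selection, contigs)
    split_lengths = pd.Series(
        {s.split_name: s.length for s in contigs.splits}, name="length"
    ).reindex(contigs.split_names)
    split_bin = pd.Series(
        {n: selection.assignments.get(n, UNASSIGNED) for n in contigs.split_names}
    ).reindex(contigs.split_names)

    if rna_samples:
        rna_det = coverage.detection_matrix[rna_samples].reindex(contigs.split_names)
        rna_mass = rna_det.mul(split_lengths, axis=0).sum(axis=1)
        total_rna = float(rna_mass.sum())
    else:
        rna_mass = pd.Series(0.0, index=contigs.split_names)
        total_rna = 0.0

    annotated_in_assembly: set[str] = set()
    if annotations is not None:
        annotated_in_assembly = annotations.names & set(contigs.scaffold_index)
        unmatched = annotations.names - annotated_in_assembly
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} annotated scaffold name(s) not in assembly "
                f"(e.g. {sorted(unmatched)[:3]})"
            )

    rows = []
    labels = selection.bins + [UNASSIGNED]
    for label in labels:
        member_splits = [n for n in contigs.split_names if split_bin[n] == label]
        member_scaffolds = [sc for sc, b in resolved.items() if b == label]
        lengths = split_lengths.loc[member_splits].to_numpy() if member_splits else np.array([])
        gcs = pd.Series([contigs.split(n).gc for n in member_splits], index=member_splits)
        row: dict = {
            "bin": label,
            "n_scaffolds": len(member_scaffolds),
            "n_splits": len(member_splits),
            "total_length": int(sum(contigs.scaffold_lengths[sc] for sc in member_scaffolds)),
            "mean_gc": _weighted_mean(gcs, lengths) if member_splits else 0.0,
        }
        for sample in coverage.sample_ids:
            mc = coverage.mean_matrix[sample].loc[member_splits] if member_splits else pd.Series(dtype=float)
            det = coverage.detection_matrix[sample].loc[member_splits] if member_splits else pd.Series(dtype=float)
            row[f"mean_coverage_{sample}"] = _weighted_mean(mc, lengths) if member_splits else 0.0
            row[f"mean_detection_{sample}"] = _weighted_mean(det, lengths) if member_splits else 0.0
        cen = census(hits, collection, subset=set(member_splits))
        row["completeness"] = 100.0 * (cen.hit_counts >= 1).sum() / len(collection)
        row["redundancy"] = 100.0 * (cen.hit_counts >= 2).sum() / len(collection)
        row["estimated_genomes"] = cen.estimated_genomes
        row["rna_recruitment"] = (
            float(rna_mass.loc[member_splits].sum()) / total_rna if total_rna > 0 else 0.0
        )
        n_annot = len(annotated_in_assembly & set(member_scaffolds))
        row["annotation_count"] = n_annot
        row["annotation_fraction"] = (
            n_annot / len(annotated_in_assembly) if annotated_in_assembly else 0.0
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")


def flag_library_restricted(contigs: ContigsTable, coverage: CoverageMatrixSet,
                            core_samples: list[str], aux_samples: list[str],
                            detection_min: float = 0.5,
                            selection: BinSelection | None = None) -> pd.DataFrame:
    """Flag each scaffold by where it is detected.

    ``aux_only`` — undetected in every core library but detected in at
    least one auxiliary library at ``detection_min`` (the library-specific
    contamination signature); ``core_supported`` — detected in a core
    library; ``undetected`` — detected nowhere.  Scaffold detection per
    library is the length-weighted mean over its splits.
    """
    core, aux = list(core_samples), list(aux_samples)
    if not core or not aux:
        raise ValueError("core_samples and aux_samples must both be non-empty")
    if set(core) & set(aux):
        raise ValueError("core and aux sample lists must be disjoint")
    unknown = [s for s in core + aux if s not in coverage.sample_ids]
    if unknown:
        raise ValueError(f"unknown sample names: {unknown}")

    det = coverage.detection_matrix
    lengths = pd.Series({s.split_name: s.length for s in contigs.splits})
    resolved = resolve_scaffolds(selection, contigs) if selection is not None else None
    rows = []
    for scaffold, split_names in contigs.scaffold_index.items():
        w = lengths.loc[split_names].to_numpy()
        sc_det = {
            s: float(np.average(det[s].loc[split_names].to_numpy(), weights=w))
            for s in core + aux
        }
        max_core = max(sc_det[s] for s in core)
        max_aux = max(sc_det[s] for s in aux)
        if max_core >= detection_min:
            flag = "core_supported"
        elif max_aux >= detection_min:
            flag = "aux_only"
        else:
            flag = "undetected"
        row = {"scaffold": scaffold, "flag": flag, "max_core_detection": max_core,
               "max_aux_detection": max_aux}
        if resolved is not None:
            row["bin"] = resolved[scaffold]
        rows.append(row)
    return pd.DataFrame(rows).set_index("scaffold")


def export_bins(selection: BinSelection, contigs: ContigsTable, assembly_fasta: str | Path,
                out_dir: str | Path) -> pd.DataFrame:
    """Write one FASTA of whole scaffolds per bin plus an index TSV.

    Scaffolds are exported intact (never as split fragments) to the bin
    they resolve to; the remainder goes to ``unassigned.fasta``.  Returns
    the index table (scaffold, bin, length).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = resolve_scaffolds(selection, contigs)
    records = {r.name: r for r in read_assembly(assembly_fasta, min_length=0)}
    missing = [sc for sc in resolved if sc not in records]
    if missing:
        raise ValueError(f"scaffold(s) missing from {assembly_fasta}: {missing[:5]}")

    by_bin: dict[str, list[str]] = {}
    for scaffold, label in resolved.items():
        by_bin.setdefault(label, []).append(scaffold)
    index_rows = []
    for label in selection.bins + [UNASSIGNED]:
        members = by_bin.get(label, [])
        if not members:
            warnings.warn(f"bin {label!r} resolved to no scaffolds; no FASTA written")
            continue
        safe = "".join(c if c.isalnum() or c in "-_." else "_" for c in label)
        with open(out / f"{safe}.fasta", "w") as fh:
            for scaffold in members:
                rec = records[scaffold]
                fh.write(f">{rec.name}\n")
                for i in range(0, len(rec.sequence), 80):
                    fh.write(rec.sequence[i : i + 80] + "\n")
                index_rows.append(
                    {"scaffold": scaffold, "bin": label, "length": rec.length}
                )
    index = pd.DataFrame(index_rows)
    index.to_csv(out / "bins_index.tsv", sep="\t", index=False)
    return index
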