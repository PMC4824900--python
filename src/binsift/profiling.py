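"""Per-library coverage profiling of splits.

For every split and every sequencing library two statistics are kept:

* **mean coverage** — average per-base read depth over the split, and
* **detection** (breadth of coverage) — the fraction of split positions
  covered by at least one read.

Mean coverage carries the quantitative abundance signal used for
differential-coverage clustering; detection is the robust presence/absence
signal used to ask *in which libraries* a sequence was seen at all, which
is what exposes library-restricted contamination.  RNA-seq alignments are
profiled identically to DNA (``kind="rna"``) and only their detection is
used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .contigs import ContigsTable

__all__ = [
    "SampleProfile",
    "CoverageMatrixSet",
    "profile_alignment",
    "profile_table",
    "merge_profiles",
]


@dataclass
class SampleProfile:
    """Mean coverage and detection of every split, for one library."""

    sample_id: str
    kind: str  # "dna" or "rna"
    mean_coverage: pd.Series  # index: split_name
    detection: pd.Series  # index: split_name, values in [0, 1]

    def __post_init__(self) -> None:
        if self.kind not in ("dna", "rna"):
            raise ValueError(f"kind must be 'dna' or 'rna', got {self.kind!r}")
        self.validate()

    def validate(self) -> None:
        mc, det = self.mean_coverage, self.detection
        if not mc.index.equals(det.index):
            raise ValueError("mean_coverage and detection must share the same split index")
        if (mc < 0).any() or not np.isfinite(mc).all():
            raise ValueError(f"sample {self.sample_id!r}: negative or non-finite mean coverage")
        if (det < 0).any() or (det > 1).any() or not np.isfinite(det).all():
            raise ValueError(f"sample {self.sample_id!r}: detection outside [0, 1]")
        bad = (det == 0) & (mc > 0)
        if bad.any():
            raise ValueError(
                f"sample {self.sample_id!r}: zero detection with nonzero coverage at "
                f"{list(det.index[bad])[:5]}"
            )

    def write(self, tsv_path: str | Path) -> None:
        pd.DataFrame(
            {"mean_coverage": self.mean_coverage, "detection": self.detection}
        ).rename_axis("split_name").to_csv(tsv_path, sep="\t")


@dataclass
class CoverageMatrixSet:
    """Merged splits x samples matrices of mean coverage and detection."""

    samples: list[SampleProfile]
    mean_matrix: pd.DataFrame
    detection_matrix: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.samples]

    def sample_ids_of_kind(self, kind: str) -> list[str]:
        return [p.sample_id for p in self.samples if p.kind == kind]

    @property
    def dna_samples(self) -> list[str]:
        return self.sample_ids_of_kind("dna")

    @property
    def rna_samples(self) -> list[str]:
        return self.sample_ids_of_kind("rna")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mean_matrix.rename_axis("split_name").to_csv(out / "mean_coverage.tsv", sep="\t")
        self.detection_matrix.rename_axis("split_name").to_csv(out / "detection.tsv", sep="\t")


def _keep_read(read: pysam.AlignedSegment) -> bool:
    # primary alignments only, any mapping quality
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary)


def profile_alignment(bam_path: str | Path, contigs: ContigsTable, sample_id: str,
                      kind: str = "dna") -> SampleProfile:
    """Profile a coordinate-sorted, indexed BAM against the contigs table.

    Depth is per-base (aligned-base pileup): positions deleted in a read
    (CIGAR ``D``) contribute nothing, insertions are ignored.  Secondary and
    supplementary records are excluded; mapping quality is not filtered.
    Scaffolds absent from the BAM header are profiled as zero and reported.
    """
    bam_path = Path(bam_path)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        try:
            bam.check_index()
        except (ValueError, AttributeError) as exc:
            raise FileNotFoundError(
                f"{bam_path} has no index; run `samtools index {bam_path}` first"
            ) from exc
        refs = set(bam.references)
        wanted = set(contigs.scaffold_index)
        if not refs & wanted:
            raise ValueError(
                f"{bam_path}: BAM reference names share nothing with the assembly "
                "(was this BAM mapped to a different reference?)"
            )
        missing = sorted(wanted - refs)
        if missing:
            import warnings

            warnings.warn(
                f"{len(missing)} scaffold(s) absent from {bam_path.name}; "
                f"profiled as zero coverage (e.g. {missing[:3]})"
            )
        mean_vals, det_vals = [], []
        for split in contigs.splits:
            if split.parent not in refs:
                mean_vals.append(0.0)
                det_vals.append(0.0)
                continue
            cov = bam.count_coverage(
                split.parent, split.start, split.end,
                quality_threshold=0, read_callback=_keep_read,
            )
            depth = np.asarray(cov).sum(axis=0)
            mean_vals.append(float(depth.sum()) / split.length)
            det_vals.append(float((depth > 0).sum()) / split.length)
    idx = pd.Index(contigs.split_names, name="split_name")
    return SampleProfile(sample_id, kind, pd.Series(mean_vals, index=idx),
                         pd.Series(det_vals, index=idx))


def profile_table(tsv_path: str | Path, contigs: ContigsTable, sample_id: str,
                  kind: str = "dna") -> SampleProfile:
    """Load a per-split profile from a TSV with columns
    ``split_name``, ``mean_coverage``, ``detection``."""
    df = pd.read_csv(tsv_path, sep="\t")
    required = {"split_name", "mean_coverage", "detection"}
    if not required.issubset(df.columns):
        raise ValueError(f"{tsv_path}: expected columns {sorted(required)}, got {list(df.columns)}")
    df = df.set_index("split_name")
    unknown = df.index.difference(contigs.split_names)
    if len(unknown):
        raise ValueError(f"{tsv_path}: unknown split names: {list(unknown[:5])}")
    missing = pd.Index(contigs.split_names).difference(df.index)
    if len(missing):
        raise ValueError(f"{tsv_path}: splits missing from table: {list(missing[:5])}")
    df = df.loc[contigs.split_names]
    return SampleProfile(sample_id, kind,
                         df["mean_coverage"].astype(float),
                         df["detection"].astype(float))


def merge_profiles(profiles: list[SampleProfile], contigs: ContigsTable) -> CoverageMatrixSet:
    """Combine per-library profiles into splits x samples matrices.

    Column order follows the input order; row order follows the contigs
    table.  Duplicate sample ids are rejected.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    idx = pd.Index(contigs.split_names, name="split_name")
    for p in profiles:
        if not p.mean_coverage.index.equals(idx):
            # allow same set in different order
            if set(p.mean_coverage.index) != set(idx):
                raise ValueError(f"profile {p.sample_id!r} does not match the contigs table")
    mean = pd.DataFrame({p.sample_id: p.mean_coverage.reindex(idx) for p in profiles})
    det = pd.DataFrame({p.sample_id: p.detection.reindex(idx) for p in profiles})
    return CoverageMatrixSet(samples=list(profiles), mean_matrix=mean, detection_matrix=det)
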