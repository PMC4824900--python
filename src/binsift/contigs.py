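"""Assembly ingestion, scaffold splitting, and per-split sequence statistics.

The unit of every downstream computation is the *split*: a section of a
scaffold of roughly a target size (default 20 kbp).  Long scaffolds are cut
into near-equal splits so that they contribute several observations to the
clustering instead of one, while short scaffolds pass through whole.  Each
split carries its GC-content and a tetranucleotide-frequency (TNF) vector,
the compositional signature used to organize splits by genome of origin.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "ScaffoldRecord",
    "SplitRecord",
    "ContigsTable",
    "FastaParseError",
    "read_assembly",
    "write_assembly",
    "plan_splits",
    "split_scaffold",
    "build_contigs",
    "gc_content",
    "tnf_vector",
    "canonical_kmers",
    "reverse_complement",
    "DEFAULT_MIN_LENGTH",
    "DEFAULT_SPLIT_TARGET",
    "DEFAULT_SPLIT_THRESHOLD",
]

DEFAULT_MIN_LENGTH = 1000
DEFAULT_SPLIT_TARGET = 20_000
DEFAULT_SPLIT_THRESHOLD = 40_000

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level encoding: A,C,G,T -> 0..3, anything else -> 4 (invalid)
_ENCODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be interpreted."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScaffoldRecord:
    """A named scaffold with an uppercase sequence over {A,C,G,T,N}."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SplitRecord:
    """One section of a scaffold, with its sequence statistics.

    Coordinates are 0-based, half-open on the parent scaffold; the splits
    of one scaffold tile it exactly.
    """

    split_name: str
    parent: str
    start: int
    end: int
    gc: float
    tnf: np.ndarray

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ContigsTable:
    """All splits of an assembly plus the parameters that produced them."""

    splits: list[SplitRecord]
    scaffold_index: dict[str, list[str]]
    scaffold_lengths: dict[str, int]
    params: dict = field(default_factory=dict)

    @property
    def split_names(self) -> list[str]:
        return [s.split_name for s in self.splits]

    @property
    def k(self) -> int:
        return int(self.params.get("k", 4))

    def split(self, name: str) -> SplitRecord:
        if not hasattr(self, "_by_name"):
            self._by_name = {s.split_name: s for s in self.splits}
        return self._by_name[name]

    def splits_of(self, scaffold: str) -> list[SplitRecord]:
        return [self.split(n) for n in self.scaffold_index[scaffold]]

    def tnf_matrix(self) -> pd.DataFrame:
        cols = canonical_kmers(self.k)
        data = np.vstack([s.tnf for s in self.splits]) if self.splits else np.empty((0, len(cols)))
        return pd.DataFrame(data, index=self.split_names, columns=cols)

    def to_dataframe(self) -> pd.DataFrame:
        base = pd.DataFrame(
            {
                "split_name": self.split_names,
                "parent": [s.parent for s in self.splits],
                "start": [s.start for s in self.splits],
                "end": [s.end for s in self.splits],
                "length": [s.length for s in self.splits],
                "gc": [s.gc for s in self.splits],
            }
        ).set_index("split_name")
        return base.join(self.tnf_matrix())

    def write(self, tsv_path: str | Path, params_path: str | Path | None = None) -> None:
        """Write the contigs table as TSV plus a YAML sidecar of parameters."""
        tsv_path = Path(tsv_path)
        self.to_dataframe().to_csv(tsv_path, sep="\t")
        if params_path is None:
            params_path = tsv_path.with_suffix(".params.yaml")
        with open(params_path, "w") as fh:
            yaml.safe_dump(self.params, fh)


def _open_text(path: str | Path):
    """Open a possibly gzip-compressed text file transparently."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_assembly(fasta_path: str | Path, min_length: int = DEFAULT_MIN_LENGTH) -> list[ScaffoldRecord]:
    """Read a scaffold FASTA, keeping records of length >= ``min_length``.

    Sequences are uppercased and characters outside {A,C,G,T} are mapped to
    N.  File order is preserved.  Duplicate record names and structurally
    malformed files raise :class:`FastaParseError`.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    with _open_text(fasta_path) as fh:
        head = fh.read(1)
        if head == "":
            return []
        if head != ">":
            raise FastaParseError(f"{fasta_path}: not a FASTA file (does not start with '>')")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FastaParseError(f"duplicate scaffold name: {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if not seq:
                raise FastaParseError(f"record {rec.id!r} has an empty sequence")
            seq = _sanitize(seq)
            if len(seq) >= min_length:
                records.append(ScaffoldRecord(rec.id, seq))
    return records


def write_assembly(records: Iterable[ScaffoldRecord], fasta_path: str | Path, width: int = 80) -> None:
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _sanitize(seq: str) -> str:
    """Map any character outside {A,C,G,T} to N."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    valid = (_ENCODE[arr] < 4)
    if not valid.all():
        arr[~valid] = ord("N")
        return arr.tobytes().decode("ascii")
    return seq


def plan_splits(length: int, split_target: int = DEFAULT_SPLIT_TARGET,
                split_threshold: int = DEFAULT_SPLIT_THRESHOLD) -> list[tuple[int, int]]:
    """Plan (start, end) windows cutting a scaffold of ``length`` bases.

    Scaffolds strictly longer than ``split_threshold`` are cut into
    ``floor(length / split_target)`` near-equal pieces (lengths differing by
    at most one base, none shorter than ``split_target``); everything else
    stays whole.
    """
    if split_target <= 0:
        raise ValueError("split_target must be > 0")
    if split_threshold < split_target:
        raise ValueError("split_threshold must be >= split_target")
    if length <= split_threshold:
        return [(0, length)]
    n = length // split_target
    bounds = [round(i * length / n) for i in range(n + 1)]
    return list(zip(bounds[:-1], bounds[1:]))


def split_scaffold(scaffold: ScaffoldRecord, split_target: int = DEFAULT_SPLIT_TARGET,
                   split_threshold: int = DEFAULT_SPLIT_THRESHOLD, k: int = 4) -> list[SplitRecord]:
    """Cut one scaffold into splits and compute per-split statistics."""
    windows = plan_splits(scaffold.length, split_target, split_threshold)
    out = []
    for ordinal, (start, end) in enumerate(windows, start=1):
        chunk = scaffold.sequence[start:end]
        name = f"{scaffold.name}_split_{ordinal:05d}"
        out.append(
            SplitRecord(
                split_name=name,
                parent=scaffold.name,
                start=start,
                end=end,
                gc=gc_content(chunk),
                tnf=tnf_vector(chunk, k=k),
            )
        )
    return out


def build_contigs(scaffolds: Iterable[ScaffoldRecord], min_length: int = DEFAULT_MIN_LENGTH,
                  split_target: int = DEFAULT_SPLIT_TARGET,
                  split_threshold: int = DEFAULT_SPLIT_THRESHOLD, k: int = 4) -> ContigsTable:
    """Build the contigs table over all scaffolds of at least ``min_length``."""
    splits: list[SplitRecord] = []
    index: dict[str, list[str]] = {}
    lengths: dict[str, int] = {}
    for sc in scaffolds:
        if sc.length < min_length:
            continue
        if sc.name in index:
            raise FastaParseError(f"duplicate scaffold name: {sc.name!r}")
        parts = split_scaffold(sc, split_target, split_threshold, k=k)
        splits.extend(parts)
        index[sc.name] = [p.split_name for p in parts]
        lengths[sc.name] = sc.length
    return ContigsTable(
        splits=splits,
        scaffold_index=index,
        scaffold_lengths=lengths,
        params={
            "min_length": min_length,
            "split_target": split_target,
            "split_threshold": split_threshold,
            "k": k,
        },
    )


def gc_content(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); 0.0 when no unambiguous base exists."""
    enc = _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n_valid = int((enc < 4).sum())
    if n_valid == 0:
        return 0.0
    n_gc = int(((enc == 1) | (enc == 2)).sum())
    return n_gc / n_valid


def canonical_kmers(k: int = 4) -> list[str]:
    """Sorted canonical k-mers: each k-mer collapsed with its reverse
    complement to the lexicographically smaller of the pair (136 for k=4)."""
    out = set()
    for tup in itertools.product("ACGT", repeat=k):
        kmer = "".join(tup)
        out.add(min(kmer, reverse_complement(kmer)))
    return sorted(out)


def _canonical_index(k: int) -> np.ndarray:
    """Lookup from base-4 k-mer code to index in the canonical feature list."""
    feats = canonical_kmers(k)
    pos = {f: i for i, f in enumerate(feats)}
    table = np.empty(4 ** k, dtype=np.int64)
    for tup in itertools.product(range(4), repeat=k):
        kmer = "".join("ACGT"[b] for b in tup)
        code = 0
        for b in tup:
            code = code * 4 + b
        table[code] = pos[min(kmer, reverse_complement(kmer))]
    return table


_CANON_CACHE: dict[int, np.ndarray] = {}


def tnf_vector(sequence: str, k: int = 4, collapse: bool = True) -> np.ndarray:
    """Canonical k-mer frequency vector of a sequence.

    A window of ``k`` slides over the sequence; windows containing any
    non-ACGT character are skipped.  Counts are collapsed across reverse
    complements (disable with ``collapse=False`` for the full 4**k features)
    and normalized to frequencies summing to 1.  A sequence with no valid
    window yields an all-zero vector.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_feat = len(canonical_kmers(k)) if collapse else 4 ** k
    enc = _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if enc.size < k:
        return np.zeros(n_feat)
    codes = np.zeros(enc.size - k + 1, dtype=np.int64)
    valid = np.ones(enc.size - k + 1, dtype=bool)
    for j in range(k):
        sub = enc[j : j + codes.size]
        codes = codes * 4 + np.where(sub < 4, sub, 0)
        valid &= sub < 4
    counts = np.bincount(codes[valid], minlength=4 ** k).astype(float)
    if collapse:
        if k not in _CANON_CACHE:
            _CANON_CACHE[k] = _canonical_index(k)
        counts = np.bincount(_CANON_CACHE[k], weights=counts, minlength=n_feat)
    total = counts.sum()
    if total == 0:
        return np.zeros(n_feat)
    return counts / total
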