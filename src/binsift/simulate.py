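"""Synthetic contaminated-assembly generator with ground truth.

Emulates the situation the screening workflow is built for: a large
eukaryotic "host" genome whose scaffolds share one compositional
signature, plus a handful of *complete* bacterial contaminant genomes,
each with a distinct signature, that entered the assembly through specific
library preparations.  Concretely the generator produces

* scaffold sequences sampled from per-genome order-``m`` Markov chains
  whose transition matrices are drawn from a Dirichlet prior (a smaller
  concentration means more divergent compositions);
* per-library coverage profiles in which the host is present in every
  library while each contaminant is present only in its subset of
  auxiliary (long-read-style) libraries — zero elsewhere;
* a single-copy-gene hit table in which each contaminant carries every
  collection gene exactly once and the host contributes sparse spurious
  hits;
* an RNA profile detecting only host scaffolds;
* a ground-truth table labeling every scaffold by source.

Coverage is simulated directly at the profile level (per-split lognormal
mean depth; detection follows the Poisson-coverage approximation
``1 - exp(-depth)``), which keeps datasets desk-scale; the BAM code path
is exercised separately with small read sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from numba import njit

from .contigs import ContigsTable, ScaffoldRecord, build_contigs, write_assembly
from .profiling import SampleProfile, merge_profiles
from .scg import ScgCollection, ScgHitTable, load_collection

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "random_transition_matrix",
    "generate_genome",
    "generate_coverage",
    "generate_scg_hits",
    "generate_dataset",
    "HOST",
]

HOST = "host"


@dataclass
class SimulationConfig:
    """Parameters of one synthetic contaminated assembly.

    Defaults describe the reference scenario used throughout the test
    suite: a 2 Mbp host, three 0.5 Mbp complete bacterial contaminants,
    three core (short-read-style) libraries carrying only the host, and
    six auxiliary (long-read-style) libraries that additionally carry the
    contaminants, each contaminant restricted to its own pair of auxiliary
    libraries.
    """

    seed: int = 0
    host_length: int = 2_000_000
    n_contaminants: int = 3
    contaminant_lengths: tuple[int, ...] | None = None  # default: 500 kbp each
    markov_order: int = 2
    composition_divergence: float = 1.0  # Dirichlet concentration; smaller = more divergent
    n_core_libraries: int = 3
    n_aux_libraries: int = 6
    host_depth: float = 30.0
    contaminant_depth: float = 30.0
    contaminant_library_pattern: dict[int, list[str]] | None = None
    coverage_noise_cv: float = 0.2
    scg_noise_rate: float = 0.05
    rna_host_detection: float = 0.9
    scaffold_mean_length: int = 20_000
    scaffold_sigma: float = 0.7

    def __post_init__(self) -> None:
        if self.contaminant_lengths is None:
            self.contaminant_lengths = tuple([500_000] * self.n_contaminants)
        self.contaminant_lengths = tuple(self.contaminant_lengths)
        if len(self.contaminant_lengths) != self.n_contaminants:
            raise ValueError("need one length per contaminant")
        if self.host_length <= 0 or any(l <= 0 for l in self.contaminant_lengths):
            raise ValueError("genome lengths must be positive")
        if not (0 <= self.rna_host_detection <= 1):
            raise ValueError("rna_host_detection must be in [0, 1]")
        if self.host_depth < 0 or self.contaminant_depth < 0:
            raise ValueError("depths must be >= 0")

    @property
    def core_libraries(self) -> list[str]:
        return [f"core_{i + 1:02d}" for i in range(self.n_core_libraries)]

    @property
    def aux_libraries(self) -> list[str]:
        return [f"aux_{i + 1:02d}" for i in range(self.n_aux_libraries)]

    @property
    def contaminant_labels(self) -> list[str]:
        return [f"contaminant_{i + 1}" for i in range(self.n_contaminants)]

    def library_pattern(self) -> dict[str, list[str]]:
        """Libraries in which each source has nonzero depth.

        The host is in every DNA library.  By default the auxiliary
        libraries are dealt round-robin to the contaminants so each
        contaminant appears in its own subset (distinct contamination
        sources); an explicit ``contaminant_library_pattern`` overrides
        this.
        """
        pattern: dict[str, list[str]] = {HOST: self.core_libraries + self.aux_libraries}
        aux = self.aux_libraries
        for i, label in enumerate(self.contaminant_labels):
            if self.contaminant_library_pattern and i in self.contaminant_library_pattern:
                pattern[label] = list(self.contaminant_library_pattern[i])
            elif self.n_contaminants > 0:
                pattern[label] = [a for j, a in enumerate(aux) if j % self.n_contaminants == i] or aux
        return pattern

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["contaminant_lengths"] = list(self.contaminant_lengths)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("contaminant_lengths") is not None:
            d["contaminant_lengths"] = tuple(d["contaminant_lengths"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Source label per scaffold plus each source's intended per-library depth."""

    scaffold_labels: dict[str, str]
    intended_depth: pd.DataFrame  # sources x libraries

    def scaffolds_of(self, label: str) -> list[str]:
        return [s for s, l in self.scaffold_labels.items() if l == label]

    def split_labels(self, contigs: ContigsTable) -> pd.Series:
        return pd.Series(
            {s.split_name: self.scaffold_labels[s.parent] for s in contigs.splits}
        ).reindex(contigs.split_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scaffold": list(self.scaffold_labels), "source": list(self.scaffold_labels.values())}
        )


@dataclass
class SyntheticDataset:
    """In-memory handles to everything one simulated assembly produced."""

    config: SimulationConfig
    scaffolds: list[ScaffoldRecord]
    contigs: ContigsTable
    profiles: list[SampleProfile]
    hits: ScgHitTable
    collection: ScgCollection
    truth: GroundTruth
    paths: dict[str, Path] = field(default_factory=dict)


@njit(cache=True)
def _markov_walk(n: int, cum: np.ndarray, u: np.ndarray, state: int) -> np.ndarray:  # pragma: no cover
    nstates = cum.shape[0]
    seq = np.empty(n, dtype=np.int8)
    for i in range(n):
        row = cum[state]
        x = u[i]
        b = 0
        while b < 3 and x > row[b]:
            b += 1
        seq[i] = b
        state = (state * 4 + b) % nstates
    return seq


def random_transition_matrix(rng: np.random.Generator, order: int = 2,
                             concentration: float = 1.0) -> np.ndarray:
    """Draw an order-``order`` nucleotide transition matrix from a
    symmetric Dirichlet; rows (one per k-mer context) sum to 1."""
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    return rng.dirichlet([concentration] * 4, size=4 ** order)


def _sample_sequence(rng: np.random.Generator, length: int, transition_matrix: np.ndarray) -> str:
    tm = np.asarray(transition_matrix, dtype=float)
    nstates = tm.shape[0]
    order = int(round(np.log(nstates) / np.log(4)))
    if tm.shape != (4 ** order, 4) or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix must be (4**order, 4) with rows summing to 1")
    cum = np.cumsum(tm, axis=1)
    u = rng.random(length)
    state = int(rng.integers(0, nstates))
    codes = _markov_walk(length, cum, u, state)
    return codes.tobytes().translate(bytes.maketrans(bytes(range(4)), b"ACGT")).decode("ascii")


def _scaffold_lengths(rng: np.random.Generator, total: int, mean_length: int,
                      sigma: float) -> list[int]:
    """Lognormal scaffold lengths truncated to sum to ``total``.

    Lengths are clamped to [2 kbp, total/5] so every scaffold survives the
    1 kbp profiling filter and no single scaffold swallows the genome; the
    spread puts a fair share of scaffolds above the 40 kbp split threshold.
    """
    mu = np.log(mean_length) - sigma ** 2 / 2
    lengths: list[int] = []
    acc = 0
    lo, hi = 2000, max(2000, total // 5)
    while acc < total:
        l = int(np.clip(rng.lognormal(mu, sigma), lo, hi))
        l = min(l, total - acc) if total - acc >= lo else total - acc
        if l < lo:  # merge a too-small remainder into the last scaffold
            if lengths:
                lengths[-1] += l
            else:  # genome smaller than the minimum scaffold size
                lengths.append(l)
            acc = total
            break
        lengths.append(l)
        acc += l
    return lengths


def generate_genome(rng: np.random.Generator | int, length: int, transition_matrix: np.ndarray,
                    name_prefix: str = "scaffold", mean_length: int = 20_000,
                    sigma: float = 0.7) -> list[ScaffoldRecord]:
    """Emit one genome as a set of scaffolds with a shared composition.

    Scaffold lengths are lognormal (truncated so the total matches
    ``length``); sequence content is an order-k Markov chain under
    ``transition_matrix``.  Deterministic given the RNG state or seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lengths = _scaffold_lengths(rng, length, mean_length, sigma)
    return [
        ScaffoldRecord(f"{name_prefix}_{i + 1:05d}", _sample_sequence(rng, l, transition_matrix))
        for i, l in enumerate(lengths)
    ]


def _lognormal_depth(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(size)
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def detection_from_depth(depth: np.ndarray | float) -> np.ndarray | float:
    """Poisson-coverage approximation: breadth = 1 - exp(-depth)."""
    return np.where(np.asarray(depth) > 0, -np.expm1(-np.asarray(depth)), 0.0)


def generate_coverage(truth: GroundTruth, contigs: ContigsTable, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> list[SampleProfile]:
    """Simulate per-split DNA coverage profiles for every library.

    Each split's mean coverage is lognormal around its source's intended
    depth in that library (zero where the source is absent); detection
    follows ``1 - exp(-depth)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    labels = truth.split_labels(contigs)
    idx = pd.Index(contigs.split_names, name="split_name")
    profiles = []
    for lib in config.core_libraries + config.aux_libraries:
        mean = np.zeros(len(idx))
        for source in truth.intended_depth.index:
            mask = (labels == source).to_numpy()
            d = float(truth.intended_depth.loc[source, lib])
            if mask.any() and d > 0:
                mean[mask] = _lognormal_depth(rng, d, config.coverage_noise_cv, int(mask.sum()))
        det = np.clip(detection_from_depth(mean), 0.0, 1.0)
        profiles.append(SampleProfile(lib, "dna", pd.Series(mean, index=idx),
                                      pd.Series(det, index=idx)))
    return profiles


def generate_rna_profile(truth: GroundTruth, contigs: ContigsTable, config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         sample_id: str = "rna") -> SampleProfile:
    """RNA detection restricted to host splits (contaminants get zero)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    labels = truth.split_labels(contigs)
    idx = pd.Index(contigs.split_names, name="split_name")
    det = np.zeros(len(idx))
    host_mask = (labels == HOST).to_numpy()
    if host_mask.any() and config.rna_host_detection > 0:
        jitter = rng.normal(config.rna_host_detection, 0.02, size=int(host_mask.sum()))
        det[host_mask] = np.clip(jitter, 0.01, 0.999)
    # mean depth consistent with the detection model
    mean = np.where(det > 0, -np.log1p(-det), 0.0)
    return SampleProfile(sample_id, "rna", pd.Series(mean, index=idx), pd.Series(det, index=idx))


def generate_scg_hits(truth: GroundTruth, contigs: ContigsTable, collection: ScgCollection,
                      config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> ScgHitTable:
    """Plant single-copy-gene hits: one per gene per contaminant, plus
    Poisson(``scg_noise_rate``) spurious host hits per gene.  All e-values
    fall below the default significance cutoff."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    labels = truth.split_labels(contigs)
    rows: list[tuple[str, str, float]] = []
    for label in config.contaminant_labels:
        splits = list(labels.index[labels == label])
        if not splits:
            continue
        for gene in collection.genes:
            rows.append((gene, splits[int(rng.integers(len(splits)))],
                         10.0 ** rng.uniform(-40, -15)))
    host_splits = list(labels.index[labels == HOST])
    if host_splits and config.scg_noise_rate > 0:
        for gene in collection.genes:
            for _ in range(int(rng.poisson(config.scg_noise_rate))):
                rows.append((gene, host_splits[int(rng.integers(len(host_splits)))],
                             10.0 ** rng.uniform(-20, -11)))
    return ScgHitTable(pd.DataFrame(rows, columns=["gene", "split_name", "evalue"]))


def _build_truth(config: SimulationConfig, scaffolds_by_source: dict[str, list[ScaffoldRecord]]) -> GroundTruth:
    labels = {
        rec.name: source for source, recs in scaffolds_by_source.items() for rec in recs
    }
    pattern = config.library_pattern()
    libs = config.core_libraries + config.aux_libraries
    depth = pd.DataFrame(0.0, index=list(scaffolds_by_source), columns=libs)
    for source in depth.index:
        d = config.host_depth if source == HOST else config.contaminant_depth
        for lib in pattern.get(source, []):
            depth.loc[source, lib] = d
    return GroundTruth(scaffold_labels=labels, intended_depth=depth)


def labels_only_scaffolding(config: SimulationConfig) -> tuple[GroundTruth, ContigsTable]:
    """Split/label scaffolding without sequences, for census-only simulations.

    Builds one single-split scaffold per ~20 kbp of each source so that
    :func:`generate_scg_hits` can run many cheap replicates (hit placement
    only depends on split labels, not on sequence content).
    """
    import numpy as _np

    from .contigs import SplitRecord, canonical_kmers

    zeros = _np.zeros(len(canonical_kmers(4)))
    splits: list[SplitRecord] = []
    index: dict[str, list[str]] = {}
    lengths: dict[str, int] = {}
    labels: dict[str, str] = {}
    counter = 0
    sources = [(HOST, config.host_length)] + list(
        zip(config.contaminant_labels, config.contaminant_lengths)
    )
    for label, total in sources:
        for _ in range(max(1, total // 20_000)):
            counter += 1
            name = f"scaffold_{counter:05d}"
            split = SplitRecord(f"{name}_split_00001", name, 0, 20_000, 0.0, zeros)
            splits.append(split)
            index[name] = [split.split_name]
            lengths[name] = 20_000
            labels[name] = label
    contigs = ContigsTable(splits=splits, scaffold_index=index, scaffold_lengths=lengths,
                           params={"min_length": 1000, "split_target": 20_000,
                                   "split_threshold": 40_000, "k": 4})
    return _build_truth(config, {
        label: [ScaffoldRecord(n, "") for n, l in labels.items() if l == label]
        for label in dict(sources)
    }), contigs


def generate_dataset(config: SimulationConfig, out_dir: str | Path | None = None,
                     collection: ScgCollection | None = None) -> SyntheticDataset:
    """Generate the full synthetic assembly and, optionally, write it out.

    Writes (when ``out_dir`` is given): ``assembly.fasta``, one profile
    TSV per DNA library, ``rna.tsv``, ``scg_hits.tsv``, ``truth.tsv``,
    ``config.yaml`` and a ``manifest.yaml``; fully reproducible from the
    config's seed.
    """
    if collection is None:
        collection = load_collection()
    root = np.random.SeedSequence(config.seed)
    ss_genomes, ss_cov, ss_rna, ss_scg = root.spawn(4)
    genome_rngs = [np.random.default_rng(s) for s in ss_genomes.spawn(config.n_contaminants + 1)]

    scaffolds_by_source: dict[str, list[ScaffoldRecord]] = {}
    counter = 0
    sources = [(HOST, config.host_length)] + list(
        zip(config.contaminant_labels, config.contaminant_lengths)
    )
    for (label, length), g_rng in zip(sources, genome_rngs):
        tm = random_transition_matrix(g_rng, config.markov_order, config.composition_divergence)
        recs = generate_genome(g_rng, length, tm, name_prefix="scaffold",
                               mean_length=config.scaffold_mean_length,
                               sigma=config.scaffold_sigma)
        renamed = []
        for rec in recs:
            counter += 1
            renamed.append(ScaffoldRecord(f"scaffold_{counter:05d}", rec.sequence))
        scaffolds_by_source[label] = renamed

    scaffolds = [r for recs in scaffolds_by_source.values() for r in recs]
    truth = _build_truth(config, scaffolds_by_source)
    contigs = build_contigs(scaffolds)
    dna = generate_coverage(truth, contigs, config, np.random.default_rng(ss_cov))
    rna = generate_rna_profile(truth, contigs, config, np.random.default_rng(ss_rna))
    hits = generate_scg_hits(truth, contigs, collection, config, np.random.default_rng(ss_scg))

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["assembly"] = out / "assembly.fasta"
        write_assembly(scaffolds, paths["assembly"])
        for prof in dna + [rna]:
            p = out / f"profile_{prof.sample_id}.tsv"
            prof.write(p)
            paths[f"profile_{prof.sample_id}"] = p
        paths["scg_hits"] = out / "scg_hits.tsv"
        hits.table.to_csv(paths["scg_hits"], sep="\t", index=False)
        paths["truth"] = out / "truth.tsv"
        truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
        paths["config"] = out / "config.yaml"
        config.to_yaml(paths["config"])
        manifest = {name: str(p.name) for name, p in paths.items()}
        manifest["samples"] = {p.sample_id: p.kind for p in dna + [rna]}
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)
        paths["manifest"] = out / "manifest.yaml"
    return SyntheticDataset(
        config=config, scaffolds=scaffolds, contigs=contigs, profiles=dna + [rna],
        hits=hits, collection=collection, truth=truth, paths=paths,
    )
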