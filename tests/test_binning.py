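import numpy as np
import pandas as pd
import pytest

from binsift.binning import (
    AnnotationList,
    BinSelection,
    UNASSIGNED,
    bin_report,
    export_bins,
    flag_library_restricted,
    load_annotation_list,
    load_selection,
    resolve_scaffolds,
    selection_from_clusters,
)
from binsift.clustering import build_feature_matrix, cluster_splits, cut_tree
from binsift.contigs import ScaffoldRecord, build_contigs, read_assembly, write_assembly
from binsift.profiling import SampleProfile, merge_profiles
from binsift.scg import ScgHitTable


def seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def empty_hits():
    return ScgHitTable(pd.DataFrame(columns=["gene", "split_name", "evalue"]))


def coverage_from(contigs, detection_by_sample, kinds=None):
    idx = pd.Index(contigs.split_names, name="split_name")
    profiles = []
    for sid, det in detection_by_sample.items():
        det = pd.Series(np.asarray(det, dtype=float), index=idx)
        mc = pd.Series(np.where(det > 0, 5.0, 0.0), index=idx)
        profiles.append(SampleProfile(sid, (kinds or {}).get(sid, "dna"), mc, det))
    return merge_profiles(profiles, contigs)


@pytest.fixture(scope="module")
def toy_contigs():
    """Three scaffolds: one splits in 3, one in 2, one stays whole."""
    rng = np.random.default_rng(0)
    scaffolds = [
        ScaffoldRecord("sc3", seq(rng, 63_000)),
        ScaffoldRecord("sc2", seq(rng, 50_000)),
        ScaffoldRecord("sc1", seq(rng, 5_000)),
    ]
    return build_contigs(scaffolds)


class TestLoadSelection:
    def test_empty_file(self, toy_contigs, tmp_path):
        path = tmp_path / "sel.tsv"
        path.write_text("")
        assert load_selection(path, toy_contigs).assignments == {}

    def test_all_splits_one_bin(self, toy_contigs, tmp_path):
        path = tmp_path / "sel.tsv"
        path.write_text("".join(f"{n}\tA\n" for n in toy_contigs.split_names))
        sel = load_selection(path, toy_contigs)
        assert len(sel.assignments) == len(toy_contigs.split_names)
        assert sel.bins == ["A"]

    def test_conflicting_assignment_rejected(self, toy_contigs, tmp_path):
        name = toy_contigs.split_names[0]
        path = tmp_path / "sel.tsv"
        path.write_text(f"{name}\tA\n{name}\tB\n")
        with pytest.raises(ValueError, match="both"):
            load_selection(path, toy_contigs)

    def test_unknown_split_rejected(self, toy_contigs, tmp_path):
        path = tmp_path / "sel.tsv"
        path.write_text("ghost\tA\n")
        with pytest.raises(ValueError, match="ghost"):
            load_selection(path, toy_contigs)


class TestResolveScaffolds:
    def test_majority_of_split_length_wins(self, toy_contigs):
        s = toy_contigs.scaffold_index["sc3"]
        sel = BinSelection({s[0]: "A", s[1]: "A", s[2]: "B"})
        assert resolve_scaffolds(sel, toy_contigs)["sc3"] == "A"

    def test_tie_leaves_unassigned(self, toy_contigs):
        s = toy_contigs.scaffold_index["sc2"]
        sel = BinSelection({s[0]: "A", s[1]: "B"})
        with pytest.warns(UserWarning, match="tie"):
            resolved = resolve_scaffolds(sel, toy_contigs)
        assert resolved["sc2"] == UNASSIGNED

    def test_unsplit_scaffold_keeps_its_bin(self, toy_contigs):
        s = toy_contigs.scaffold_index["sc1"]
        sel = BinSelection({s[0]: "Z"})
        resolved = resolve_scaffolds(sel, toy_contigs)
        assert resolved["sc1"] == "Z"
        assert resolved["sc3"] == UNASSIGNED  # no assigned splits


class TestBinReport:
    def test_rna_recruitment_mass_split(self):
        rng = np.random.default_rng(1)
        contigs = build_contigs(
            [ScaffoldRecord("a", seq(rng, 10_000)), ScaffoldRecord("b", seq(rng, 10_000))]
        )
        # detection x length mass 99 vs 1
        cov = coverage_from(
            contigs,
            {"dna": [0.9, 0.9], "rna": [0.99, 0.01]},
            kinds={"rna": "rna"},
        )
        sel = BinSelection({contigs.scaffold_index["a"][0]: "A",
                            contigs.scaffold_index["b"][0]: "B"})
        from binsift.scg import load_collection

        rep = bin_report(sel, contigs, cov, empty_hits(), load_collection(),
                         rna_samples=["rna"])
        assert rep.loc["A", "rna_recruitment"] == pytest.approx(0.99)
        assert rep.loc["B", "rna_recruitment"] == pytest.approx(0.01)

    def test_single_bin_recruits_everything(self, small_dataset):
        names = small_dataset.contigs.split_names
        sel = BinSelection({n: "all" for n in names})
        cov = merge_profiles(small_dataset.profiles, small_dataset.contigs)
        rep = bin_report(sel, small_dataset.contigs, cov, small_dataset.hits,
                         small_dataset.collection, rna_samples=["rna"])
        assert rep.loc["all", "rna_recruitment"] == pytest.approx(1.0)

    def test_recruitment_sums_to_one_and_length_conserved(self, small_dataset):
        ds = small_dataset
        cov = merge_profiles(ds.profiles, ds.contigs)
        fm = build_feature_matrix(ds.contigs, cov)
        k = ds.config.n_contaminants + 1
        sel = selection_from_clusters(cut_tree(cluster_splits(fm), k))
        rep = bin_report(sel, ds.contigs, cov, ds.hits, ds.collection, rna_samples=["rna"])
        assert rep["rna_recruitment"].sum() == pytest.approx(1.0)
        assert rep["total_length"].sum() == sum(ds.contigs.scaffold_lengths.values())

    def test_contaminant_bin_recruits_no_rna(self, small_dataset):
        ds = small_dataset
        labels = ds.truth.split_labels(ds.contigs)
        sel = BinSelection({n: ("host" if l == "host" else "contam")
                            for n, l in labels.items()})
        cov = merge_profiles(ds.profiles, ds.contigs)
        rep = bin_report(sel, ds.contigs, cov, ds.hits, ds.collection, rna_samples=["rna"])
        assert rep.loc["contam", "rna_recruitment"] == 0.0

    def test_annotation_overlap_counts(self, toy_contigs):
        sel = BinSelection({n: "A" for n in toy_contigs.scaffold_index["sc3"]})
        cov = coverage_from(toy_contigs, {"dna": np.full(len(toy_contigs.split_names), 0.9)})
        ann = AnnotationList({"sc3", "sc1", "not_in_assembly"})
        from binsift.scg import load_collection

        with pytest.warns(UserWarning, match="not in assembly"):
            rep = bin_report(sel, toy_contigs, cov, empty_hits(), load_collection(),
                             annotations=ann)
        assert rep.loc["A", "annotation_count"] == 1
        assert rep.loc["A", "annotation_fraction"] == pytest.approx(0.5)
        assert rep.loc[UNASSIGNED, "annotation_count"] == 1

    def test_missing_rna_sample_rejected(self, toy_contigs):
        sel = BinSelection({})
        cov = coverage_from(toy_contigs, {"dna": np.zeros(len(toy_contigs.split_names))})
        from binsift.scg import load_collection

        with pytest.raises(ValueError, match="RNA"):
            bin_report(sel, toy_contigs, cov, empty_hits(), load_collection(),
                       rna_samples=["rna"])


class TestFlags:
    def _cov(self, contigs, core_det, aux_det):
        n = len(contigs.split_names)
        return coverage_from(contigs, {"core": np.full(n, core_det),
                                       "aux": np.full(n, aux_det)})

    def test_aux_only(self, toy_contigs):
        flags = flag_library_restricted(toy_contigs, self._cov(toy_contigs, 0.0, 0.9),
                                        ["core"], ["aux"])
        assert (flags["flag"] == "aux_only").all()

    def test_core_supported(self, toy_contigs):
        flags = flag_library_restricted(toy_contigs, self._cov(toy_contigs, 0.9, 0.9),
                                        ["core"], ["aux"])
        assert (flags["flag"] == "core_supported").all()

    def test_undetected(self, toy_contigs):
        flags = flag_library_restricted(toy_contigs, self._cov(toy_contigs, 0.0, 0.0),
                                        ["core"], ["aux"])
        assert (flags["flag"] == "undetected").all()

    def test_unknown_or_overlapping_samples_rejected(self, toy_contigs):
        cov = self._cov(toy_contigs, 0.9, 0.9)
        with pytest.raises(ValueError, match="unknown"):
            flag_library_restricted(toy_contigs, cov, ["core"], ["ghost"])
        with pytest.raises(ValueError, match="disjoint"):
            flag_library_restricted(toy_contigs, cov, ["core"], ["core"])
        with pytest.raises(ValueError, match="non-empty"):
            flag_library_restricted(toy_contigs, cov, [], ["aux"])


class TestExportBins:
    def test_sequences_exported_intact_and_conserved(self, tmp_path):
        rng = np.random.default_rng(2)
        scaffolds = [ScaffoldRecord(f"s{i}", seq(rng, 3_000)) for i in range(4)]
        fasta = tmp_path / "asm.fasta"
        write_assembly(scaffolds, fasta)
        contigs = build_contigs(scaffolds)
        sel = BinSelection({contigs.scaffold_index["s0"][0]: "A",
                            contigs.scaffold_index["s1"][0]: "A",
                            contigs.scaffold_index["s2"][0]: "B"})
        out = tmp_path / "bins"
        index = export_bins(sel, contigs, fasta, out)
        a = {r.name: r.sequence for r in read_assembly(out / "A.fasta", min_length=0)}
        assert a == {"s0": scaffolds[0].sequence, "s1": scaffolds[1].sequence}
        exported = index.groupby("bin")["length"].sum().sum()
        assert exported == sum(s.length for s in scaffolds)
        assert set(index["bin"]) == {"A", "B", UNASSIGNED}

    def test_empty_bin_logged_not_written(self, tmp_path):
        rng = np.random.default_rng(3)
        scaffolds = [ScaffoldRecord("x", seq(rng, 60_000))]
        fasta = tmp_path / "asm.fasta"
        write_assembly(scaffolds, fasta)
        contigs = build_contigs(scaffolds)
        s = contigs.scaffold_index["x"]
        sel = BinSelection({s[0]: "A", s[1]: "A", s[2]: "B"})  # B loses the majority
        with pytest.warns(UserWarning, match="no scaffolds"):
            export_bins(sel, contigs, fasta, tmp_path / "bins")
        assert not (tmp_path / "bins" / "B.fasta").exists()

    def test_missing_scaffold_rejected(self, tmp_path):
        rng = np.random.default_rng(4)
        scaffolds = [ScaffoldRecord("x", seq(rng, 3_000)), ScaffoldRecord("y", seq(rng, 3_000))]
        fasta = tmp_path / "asm.fasta"
        write_assembly(scaffolds[:1], fasta)
        contigs = build_contigs(scaffolds)
        sel = BinSelection({contigs.scaffold_index["y"][0]: "A"})
        with pytest.raises(ValueError, match="missing"):
            export_bins(sel, contigs, fasta, tmp_path / "bins")


def test_load_annotation_list(tmp_path):
    path = tmp_path / "ann.txt"
    path.write_text("# proposed HGT scaffolds\nsc1\nsc2\n\n")
    assert load_annotation_list(path).names == {"sc1", "sc2"}
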