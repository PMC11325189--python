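"""Protocol orchestration: single-pass, MARC, FRAN."""

import copy

import pytest

from funfamkit.benchmark import adjusted_rand_index, funfams_to_labels
from funfamkit.core_model import AnnotationTable, DomainSequence, check_partition, parse_mda_string
from funfamkit.protocols import (
    ProtocolConfig,
    medoid,
    partition_by_mda,
    result_fingerprint,
    run,
    run_fran,
    run_marc,
    run_single,
)
from funfamkit.distance_engine import EmbeddingVector
from funfamkit.synthetic_data import SimConfig, generate_embeddings, generate_superfamily
from conftest import PLANTED_SEED
from oracles import partition_of


def truth_ari(funfams, truth):
    labels = funfams_to_labels(funfams)
    return adjusted_rand_index(labels, {s: truth.family_of[s] for s in labels})


class TestPartitionByMda:
    @staticmethod
    def _seqs(counts):
        out = []
        for mda, count in counts.items():
            for i in range(count):
                out.append(
                    DomainSequence(f"{mda}_{i}", "ACDE", mda=parse_mda_string(mda))
                )
        return out

    def test_single_mda_threshold_one_has_no_residual(self):
        partitions = partition_by_mda(self._seqs({"1.1.1.1": 4}), mda_min_size=1)
        assert list(partitions) == ["1.1.1.1"]

    def test_small_mda_falls_into_residual(self):
        partitions = partition_by_mda(self._seqs({"1.1.1.1": 10, "2.2.2.2": 2}), mda_min_size=5)
        assert set(partitions) == {"1.1.1.1", "pooled"}
        assert len(partitions["pooled"]) == 2

    def test_threshold_above_total_pools_everything(self):
        partitions = partition_by_mda(self._seqs({"1.1.1.1": 3, "2.2.2.2": 3}), mda_min_size=10)
        assert set(partitions) == {"pooled"}
        assert len(partitions["pooled"]) == 6

    def test_partitions_cover_input_disjointly(self):
        seqs = self._seqs({"1.1.1.1": 6, "2.2.2.2": 4, "3.3.3.3": 1})
        partitions = partition_by_mda(seqs, mda_min_size=4)
        ids = [s.seq_id for part in partitions.values() for s in part]
        assert sorted(ids) == sorted(s.seq_id for s in seqs)


class TestMedoid:
    def test_central_member_wins(self):
        vectors = {
            "a": EmbeddingVector("a", [0.0, 0.0]),
            "b": EmbeddingVector("b", [1.0, 0.0]),
            "c": EmbeddingVector("c", [-1.0, 0.1]),
        }
        assert medoid(["a", "b", "c"], vectors, metric="euclidean") == "a"

    def test_members_without_vectors_ignored(self):
        vectors = {"a": EmbeddingVector("a", [0.0, 1.0])}
        assert medoid(["a", "ghost"], vectors) == "a"

    def test_no_vectors_rejected(self):
        with pytest.raises(ValueError, match="no member"):
            medoid(["ghost"], {}, metric="cosine")


class TestRunSingle:
    def test_degenerate_single_cluster_short_circuits(self):
        seqs = [DomainSequence(f"s{i}", "ACDEFGHIKL") for i in range(3)]
        table = AnnotationTable()
        table.add_go("s0", "GO:0003824", "IDA")
        result = run_single(seqs, table, vectors={})
        assert len(result.funfams_final) == 1
        assert result.funfams_final[0].member_ids == {"s0", "s1", "s2"}

    def test_missing_representative_vector_names_id(self, small_dataset):
        seqs, annotations, _, _ = small_dataset
        with pytest.raises(ValueError, match="F0_s000|representative"):
            run_single(seqs, annotations, vectors={})

    def test_provenance_records_choices(self, planted_single_run):
        prov = planted_single_run.provenance
        assert prov["metric"] == "cosine"
        assert prov["identity_threshold"] == 0.90
        assert prov["d_max"] == 0

    def test_final_funfams_partition_filtered_input(self, planted, planted_single_run):
        seqs, _, _, _ = planted
        union = check_partition(planted_single_run.funfams_final)
        assert union == {s.seq_id for s in seqs}  # every cluster carries GO evidence

    def test_recovers_planted_families(self, planted, planted_single_run):
        _, _, truth, _ = planted
        assert truth_ari(planted_single_run.funfams_final, truth) >= 0.95


class TestRunMarc:
    def test_agrees_with_single_pass_for_one_mda(self, planted, planted_single_run):
        seqs, annotations, _, vectors = planted
        config = ProtocolConfig(mode="marc", seed=PLANTED_SEED, mda_min_size=1)
        result = run_marc(seqs, annotations, vectors, config)
        assert partition_of(result.funfams_final) == partition_of(
            planted_single_run.funfams_final
        )

    def test_family_split_across_small_mdas_reunited_by_residual_pool(self):
        config = SimConfig(
            n_families=2, seqs_per_family=8, seq_length=60, n_sdp=2,
            mutation_rate=0.01, embed_dim=8, seed=3,
            mda_assignment={1: "2.40.60.10"},
        )
        seqs, annotations, truth = generate_superfamily(config)
        vectors = {v.seq_id: v for v in generate_embeddings(truth, config)}
        # scatter family 0 over two rare MDA labels, both below the threshold
        for i, seq in enumerate(s for s in seqs if truth.family_of[s.seq_id] == 0):
            seq.mda = parse_mda_string("3.40.50.300" if i % 2 else "1.10.10.10")
        result = run_marc(seqs, annotations, vectors, ProtocolConfig(mode="marc", mda_min_size=5))
        fam0 = {s.seq_id for s in seqs if truth.family_of[s.seq_id] == 0}
        assert any(ff.member_ids == fam0 for ff in result.funfams_final)
        assert truth_ari(result.funfams_final, truth) == 1.0


class TestRunFran:
    def test_large_project_size_matches_single_pass_iteration1(self, planted, planted_single_run):
        seqs, annotations, _, vectors = planted
        k = len(planted_single_run.partitions["all"])
        config = ProtocolConfig(mode="fran", seed=PLANTED_SEED, fran_project_size=k)
        result = run_fran(seqs, annotations, vectors, config)
        assert partition_of(result.funfams_iter1) == partition_of(
            planted_single_run.funfams_final
        )

    def test_same_seed_reproduces_bitwise(self, small_dataset):
        seqs, annotations, _, vectors = small_dataset
        config = ProtocolConfig(mode="fran", seed=5, fran_project_size=2)
        a = run_fran(seqs, annotations, vectors, config)
        b = run_fran(seqs, annotations, vectors, config)
        assert result_fingerprint(a) == result_fingerprint(b)

    def test_second_iteration_merges_randomization_splits(self):
        # High mutation rate splinters each family into several S90 clusters,
        # and a small project size scatters them across projects.
        config = SimConfig(
            n_families=3, seqs_per_family=12, seq_length=60, n_sdp=2,
            mutation_rate=0.08, embed_dim=8, seed=2,
        )
        seqs, annotations, truth = generate_superfamily(config)
        vectors = {v.seq_id: v for v in generate_embeddings(truth, config)}
        result = run_fran(
            seqs, annotations, vectors,
            ProtocolConfig(mode="fran", seed=2, fran_project_size=3),
        )
        assert len(result.funfams_final) <= len(result.funfams_iter1)
        # some family was split across projects in iteration 1 ...
        labels1 = funfams_to_labels(result.funfams_iter1)
        projects_of_family = {
            f: {labels1[sid].split("|")[0] for sid in truth.family_of if truth.family_of[sid] == f}
            for f in range(3)
        }
        assert any(len(p) > 1 for p in projects_of_family.values())
        # ... and the merging second pass recovers at least as much truth
        assert truth_ari(result.funfams_final, truth) >= truth_ari(
            result.funfams_iter1, truth
        )

    def test_modes_agree_on_universe(self, planted, planted_single_run):
        seqs, annotations, _, vectors = planted
        fran = run(
            seqs, annotations, vectors,
            ProtocolConfig(mode="fran", seed=PLANTED_SEED, fran_project_size=10),
        )
        assert check_partition(fran.funfams_final) == check_partition(
            planted_single_run.funfams_final
        )
        assert len(fran.funfams_final) <= len(fran.funfams_iter1)


class TestDeterminism:
    @pytest.mark.parametrize("mode", ["single", "marc", "fran"])
    def test_repeated_runs_are_byte_identical(self, small_dataset, mode):
        seqs, annotations, _, vectors = small_dataset
        config = ProtocolConfig(mode=mode, seed=5, fran_project_size=2, mda_min_size=2)
        a = run(seqs, annotations, vectors, config)
        b = run(copy.deepcopy(seqs), annotations, vectors, config)
        assert result_fingerprint(a) == result_fingerprint(b)
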