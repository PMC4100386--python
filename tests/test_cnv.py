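import numpy as np
import pandas as pd
import pytest

from cnvaccord import cnv
from conftest import build_map, build_states


def brute_force_runs(states_row, chroms, min_snps=3):
    """Independent run-length oracle: scan every start/stop pair."""
    n = len(states_row)
    runs = []
    i = 0
    while i < n:
        j = i
        while (
            j + 1 < n
            and states_row[j + 1] == states_row[i]
            and chroms[j + 1] == chroms[i]
        ):
            j += 1
        if states_row[i] != 2 and (j - i + 1) >= min_snps:
            runs.append((i, j, int(states_row[i])))
        i = j + 1
    return runs


class TestCallRawCnvs:
    def test_null_individual_yields_nothing(self, small_map):
        m = build_states([[2] * 10], [[2] * 10])
        assert len(cnv.call_raw_cnvs(m, small_map)) == 0

    def test_minimal_three_snp_deletion(self):
        snp_map = build_map([(1, p) for p in (100, 200, 300, 400, 500)])
        m = build_states([[2, 1, 1, 1, 2]], [[2] * 5])
        segs = cnv.call_raw_cnvs(m, snp_map)
        assert len(segs) == 1
        seg = segs.iloc[0]
        assert (seg["state"], seg["n_snps"], seg["start_pos"], seg["end_pos"]) == (1, 3, 200, 400)

    def test_mixed_abnormal_states_not_merged(self):
        snp_map = build_map([(1, p) for p in (100, 200, 300, 400, 500)])
        m = build_states([[2, 1, 3, 1, 2]], [[2] * 5])
        assert len(cnv.call_raw_cnvs(m, snp_map)) == 0

    def test_runs_never_cross_chromosomes(self):
        snp_map = build_map([(1, 100), (1, 200), (1, 300), (2, 100), (2, 200), (2, 300)])
        m = build_states([[1, 1, 1, 1, 1, 1]], [[2] * 6])
        segs = cnv.call_raw_cnvs(m, snp_map)
        assert list(segs["chrom"]) == [1, 2]

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        snp_map = build_map(
            [(1, 1000 * (i + 1)) for i in range(100)] + [(2, 1000 * (i + 1)) for i in range(100)]
        )
        chroms = snp_map.chroms
        states = rng.choice([0, 1, 2, 2, 2, 3, 4], size=(200, 200)).astype(np.int8)
        m = build_states(states[:100], states[100:])
        segs = cnv.call_raw_cnvs(m, snp_map)
        got = {
            (r["individual_id"], r["first_snp_index"], r["last_snp_index"], r["state"])
            for _, r in segs.iterrows()
        }
        expected = set()
        for i in range(200):
            for a, b, s in brute_force_runs(states[i], chroms):
                expected.add((m.individual_ids[i], a, b, s))
        assert got == expected


class TestSummarizeRawCnvs:
    def test_single_segment_statistics(self):
        snp_map = build_map([(1, p) for p in (1000, 1500, 2000)])
        m = build_states([[1, 1, 1]], [[2, 2, 2]])
        segs = cnv.call_raw_cnvs(m, snp_map)
        with pytest.warns(UserWarning):  # empty control arm
            stats = cnv.summarize_raw_cnvs(segs, m)
        case = stats[stats["label"] == "case"].iloc[0]
        assert case["cnvs_per_individual"] == 1.0
        assert case["size_bp_avg"] == 1000.0

    def test_average_over_individuals(self):
        snp_map = build_map([(1, 100 * (i + 1)) for i in range(20)])
        row_a = [1] * 6 + [2] * 2 + [3] * 6 + [2] * 6  # 2 segments
        row_b = ([4] * 3 + [2]) * 4 + [2] * 4  # 4 segments of 3
        m = build_states([row_a, row_b], [[2] * 20])
        segs = cnv.call_raw_cnvs(m, snp_map)
        with pytest.warns(UserWarning):
            stats = cnv.summarize_raw_cnvs(segs, m)
        case = stats[stats["label"] == "case"].iloc[0]
        assert case["cnvs_per_individual"] == 3.0

    def test_min_avg_max_ordering_on_random_fixture(self, rng):
        snp_map = build_map([(1, 500 * (i + 1)) for i in range(60)])
        states = rng.choice([1, 2, 2, 3], size=(10, 60)).astype(np.int8)
        m = build_states(states[:5], states[5:])
        segs = cnv.call_raw_cnvs(m, snp_map)
        stats = cnv.summarize_raw_cnvs(segs, m)
        for _, row in stats.iterrows():
            assert row["snps_per_cnv_min"] <= row["snps_per_cnv_avg"] <= row["snps_per_cnv_max"]
            assert row["size_bp_min"] <= row["size_bp_avg"] <= row["size_bp_max"]


class TestCnvSizeKb:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(113681735, 113741162, 59.4), (56772821, 56803216, 30.4), (0, 1000, 1.0)],
    )
    def test_printed_convention(self, start, end, expected):
        assert cnv.cnv_size_kb(start, end) == expected

    def test_published_table_reproduces_exactly(self):
        table = cnv.load_published_cnvs()
        for _, row in table.iterrows():
            assert cnv.cnv_size_kb(row["start_pos"], row["end_pos"]) == row["size_kb"]

    def test_published_type_counts(self):
        table = cnv.load_published_cnvs()
        counts = table["cnv_type"].value_counts()
        assert len(table) == 22
        assert counts["Deletion"] == 18
        assert counts["Amplification"] == 3
        assert counts["Abnormal"] == 1


def loci_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "best_hypothesis"])


class TestBlocksToCnvs:
    def test_two_loci_stay_singular(self):
        loci = loci_frame([("a", 1, 100, "gain"), ("b", 1, 10_100, "gain")])
        records, singular = cnv.blocks_to_cnvs(loci)
        assert records == [] and len(singular) == 2

    def test_three_gain_loci_form_amplification(self):
        loci = loci_frame(
            [("a", 1, 100, "gain"), ("b", 1, 10_100, "gain"), ("c", 1, 20_100, "gain")]
        )
        records, singular = cnv.blocks_to_cnvs(loci)
        assert len(records) == 1 and len(singular) == 0
        rec = records[0]
        assert (rec.start_pos, rec.end_pos, rec.cnv_type) == (100, 20_100, "Amplification")
        assert rec.size_kb == 20.0

    def test_internal_gap_splits_chain(self):
        loci = loci_frame(
            [
                ("a", 1, 100, "loss"),
                ("b", 1, 10_100, "loss"),
                ("c", 1, 45_100, "loss"),  # 35 kb gap before this locus
                ("d", 1, 55_100, "loss"),
            ]
        )
        records, singular = cnv.blocks_to_cnvs(loci)
        assert records == [] and len(singular) == 4

    def test_mixed_hypotheses_yield_abnormal(self):
        loci = loci_frame(
            [("a", 1, 100, "loss"), ("b", 1, 10_100, "gain"), ("c", 1, 20_100, "loss")]
        )
        records, _ = cnv.blocks_to_cnvs(loci)
        assert records[0].cnv_type == "Abnormal"

    def test_matches_brute_force_chain_partition(self, rng):
        # random loci on two chromosomes, random gaps around the 30 kb rule
        rows, pos = [], 0
        for i in range(40):
            pos += int(rng.choice([5_000, 20_000, 35_000], p=[0.5, 0.3, 0.2]))
            rows.append((f"s{i}", 1 + (i % 2 == 0 and i > 20), pos, rng.choice(["loss", "gain"])))
        rows.sort(key=lambda r: (r[1], r[2]))
        loci = loci_frame(rows).reset_index(drop=True)
        records, singular = cnv.blocks_to_cnvs(loci)
        # oracle: quadratic chain partition
        chains, current = [], [0]
        for i in range(1, len(loci)):
            same = loci["chrom"][i] == loci["chrom"][i - 1]
            close = loci["pos"][i] - loci["pos"][i - 1] <= 30_000
            if same and close:
                current.append(i)
            else:
                chains.append(current)
                current = [i]
        chains.append(current)
        long_chains = [c for c in chains if len(c) >= 3]
        assert len(records) == len(long_chains)
        assert len(singular) == sum(len(c) for c in chains if len(c) < 3)
        for rec, chain in zip(records, long_chains):
            assert rec.start_pos == loci["pos"][chain[0]]
            assert rec.end_pos == loci["pos"][chain[-1]]

    def test_unsorted_input_rejected(self):
        loci = loci_frame([("a", 1, 200, "loss"), ("b", 1, 100, "loss")])
        with pytest.raises(ValueError):
            cnv.blocks_to_cnvs(loci)


class TestNeighboringGenes:
    def annotation(self):
        return pd.DataFrame(
            [(1, 50_000, 60_000, "GENE_A"), (1, 200_000, 210_000, "GENE_B"),
             (2, 10_000, 20_000, "GENE_C")],
            columns=["chrom", "start", "end", "name"],
        )

    def test_no_gene_within_flank(self):
        loci = pd.DataFrame({"chrom": [2], "pos": [500_000]})
        assert cnv.neighboring_genes(loci, self.annotation()) == []

    def test_boundary_gene_included(self):
        # gene starts exactly at pos + flank: closed-interval convention
        loci = pd.DataFrame({"chrom": [1], "pos": [100_000]})
        assert cnv.neighboring_genes(loci, self.annotation(), flank=100_000) == [
            "GENE_A",
            "GENE_B",
        ]

    def test_matches_quadratic_all_pairs_oracle(self, rng):
        genes = []
        for i in range(50):
            start = int(rng.integers(1, 1_000_000))
            genes.append((int(rng.integers(1, 3)), start, start + int(rng.integers(1, 50_000)), f"G{i}"))
        ann = pd.DataFrame(genes, columns=["chrom", "start", "end", "name"]).sort_values(
            ["chrom", "start"]
        ).reset_index(drop=True)
        loci = pd.DataFrame(
            {"chrom": rng.integers(1, 3, 20), "pos": rng.integers(1, 1_000_000, 20)}
        )
        flank = 30_000
        expected = set()
        for _, g in ann.iterrows():
            for _, l in loci.iterrows():
                if g["chrom"] == l["chrom"] and g["end"] >= l["pos"] - flank and g["start"] <= l["pos"] + flank:
                    expected.add(g["name"])
        assert cnv.neighboring_genes(loci, ann, flank) == sorted(expected)
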