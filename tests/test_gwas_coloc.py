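"""GWAS filtering boundaries, co-location clustering vs brute force, gene windows."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rootshift.gwas_coloc import (
    filter_hits,
    find_colocations,
    flag_significant,
    genes_in_window,
    read_gene_annotation,
    read_gwas_table,
)


def make_hits(rows):
    """rows: (season, chrom, pos, pvalue[, maf])"""
    recs = []
    for i, row in enumerate(rows):
        season, chrom, pos, pvalue = row[:4]
        rec = {
            "season": season,
            "snp_id": f"s{i}",
            "chrom": str(chrom),
            "pos": int(pos),
            "pvalue": float(pvalue),
        }
        if len(row) > 4:
            rec["maf"] = row[4]
        recs.append(rec)
    return pd.DataFrame(recs)


def brute_force_clusters(hits, window_bp):
    """All-pairs edges + connected components, independent of the pipeline."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(hits.index)
    for i, j in itertools.combinations(hits.index, 2):
        if hits.loc[i, "chrom"] == hits.loc[j, "chrom"] and abs(
            int(hits.loc[i, "pos"]) - int(hits.loc[j, "pos"])
        ) <= window_bp:
            g.add_edge(i, j)
    comps = []
    for comp in nx.connected_components(g):
        members = hits.loc[sorted(comp)]
        if members["season"].nunique() >= 2:
            comps.append(frozenset(members["snp_id"]))
    return set(comps)


class TestFilterHits:
    def test_neglog10p_boundary_inclusive(self):
        hits = make_hits([("2017", "1", 100, 1e-3), ("2017", "1", 200, 2e-3)])
        kept, removed = filter_hits(hits, min_neglog10p=3)
        assert list(kept["pos"]) == [100]
        assert removed["low_neglog10p"] == 1

    def test_maf_filter_and_missing_maf_passes(self):
        hits = make_hits(
            [("2017", "1", 100, 1e-5, 0.04), ("2017", "1", 200, 1e-5, 0.05)]
        )
        kept, removed = filter_hits(hits)
        assert list(kept["pos"]) == [200]
        assert removed["low_maf"] == 1
        no_maf = make_hits([("2017", "1", 300, 1e-5)])
        kept, _ = filter_hits(no_maf)
        assert len(kept) == 1

    def test_matches_brute_force_on_random_pvalues(self):
        rng = np.random.default_rng(0)
        pvals = rng.uniform(size=1000)
        hits = make_hits([("2017", "1", i + 1, p) for i, p in enumerate(pvals)])
        kept, _ = filter_hits(hits, min_neglog10p=3)
        expected = {i + 1 for i, p in enumerate(pvals) if -np.log10(p) >= 3}
        assert set(kept["pos"]) == expected


class TestFlagSignificant:
    def test_strict_boundary(self):
        hits = make_hits([("2017", "1", 1, 1e-4), ("2017", "1", 2, 9.9e-5)])
        out = flag_significant(hits)
        assert list(out["significant"]) == [False, True]

    def test_count_matches_brute_force(self):
        rng = np.random.default_rng(1)
        pvals = 10 ** rng.uniform(-6, 0, size=500)
        hits = make_hits([("2018", "2", i + 1, p) for i, p in enumerate(pvals)])
        out = flag_significant(hits, alpha=1e-4)
        assert out["significant"].sum() == int((pvals < 1e-4).sum())


class TestFindColocations:
    def test_two_hit_cross_season_cluster(self):
        hits = make_hits([("2017", "3", 1_000_000, 1e-4), ("2018", "3", 1_050_000, 1e-4)])
        clusters = find_colocations(hits)
        assert len(clusters) == 1
        assert clusters[0].interval == (1_000_000, 1_050_000)
        assert clusters[0].seasons == ("2017", "2018")

    def test_same_season_pair_is_not_a_cluster(self):
        hits = make_hits([("2017", "3", 1_000_000, 1e-4), ("2017", "3", 1_050_000, 1e-4)])
        assert find_colocations(hits) == []

    def test_window_boundary_inclusive(self):
        at = make_hits([("2017", "1", 1, 1e-4), ("2018", "1", 100_001, 1e-4)])
        beyond = make_hits([("2017", "1", 1, 1e-4), ("2018", "1", 100_002, 1e-4)])
        assert len(find_colocations(at, window_bp=100_000)) == 1
        assert len(find_colocations(beyond, window_bp=100_000)) == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 101))
            hits = make_hits(
                [
                    (
                        str(rng.choice(["2017", "2018", "2019"])),
                        str(rng.choice(["1", "2"])),
                        int(rng.integers(1, 2_000_000)),
                        1e-4,
                    )
                    for _ in range(n)
                ]
            )
            got = {
                frozenset(c.members["snp_id"]) for c in find_colocations(hits, 100_000)
            }
            assert got == brute_force_clusters(hits, 100_000)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(9)
        hits = make_hits(
            [
                (str(rng.choice(["2017", "2018"])), "1", int(rng.integers(1, 500_000)), 1e-4)
                for _ in range(40)
            ]
        )
        a = find_colocations(hits)
        b = find_colocations(hits.sample(frac=1, random_state=3))
        assert [(c.chrom, c.interval) for c in a] == [(c.chrom, c.interval) for c in b]

    def test_shrinking_window_never_grows_clusters(self):
        rng = np.random.default_rng(17)
        hits = make_hits(
            [
                (str(rng.choice(["2017", "2018"])), "1", int(rng.integers(1, 400_000)), 1e-4)
                for _ in range(50)
            ]
        )
        big = find_colocations(hits, 100_000)
        small = find_colocations(hits, 20_000)
        assert sum(c.n_hits for c in small) <= sum(c.n_hits for c in big)


class TestGenesInWindow:
    @pytest.fixture
    def annotation(self, tmp_path):
        path = tmp_path / "genes.csv"
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "chrom": ["1", "1", "2"],
                "start": [1_000, 550_000, 200_000],
                "end": [2_000, 560_000, 210_000],
                "description": ["", "", ""],
            }
        ).to_csv(path, index=False)
        return read_gene_annotation(path)

    def test_closed_interval_boundary_included(self, annotation):
        # gene gA ends at 2_000 == pos 102_000 - flank 100_000
        out = genes_in_window(("1", 102_000), annotation, flank_bp=100_000)
        assert "gA" in set(out["gene_id"])

    def test_other_chromosome_excluded(self, annotation):
        out = genes_in_window(("1", 205_000), annotation, flank_bp=100_000)
        assert "gC" not in set(out["gene_id"])

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(1, 1_000_000, size=500)
        ann = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(500)],
                "chrom": rng.choice(["1", "2"], size=500),
                "start": starts,
                "end": starts + rng.integers(100, 5_000, size=500),
                "description": "",
            }
        )
        lo, hi, flank = 400_000, 420_000, 100_000
        got = set(genes_in_window(("1", lo, hi), ann, flank)["gene_id"])
        expected = {
            r.gene_id
            for r in ann.itertuples()
            if r.chrom == "1" and r.start <= hi + flank and r.end >= lo - flank
        }
        assert got == expected

    def test_gff3_reader(self, tmp_path):
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\ttest\tgene\t1000\t2000\t.\t+\t.\tID=gene1;description=kinase\n"
            "2\ttest\tgene\t5000\t9000\t.\t-\t.\tID=gene2\n"
            "1\ttest\tmRNA\t1000\t2000\t.\t+\t.\tID=t1;Parent=gene1\n"
        )
        ann = read_gene_annotation(gff)
        assert list(ann["gene_id"]) == ["gene1", "gene2"]
        assert ann.loc[0, "description"] == "kinase"


class TestReadGwasTable:
    def test_read_and_validate(self, tmp_path):
        path = tmp_path / "gwas.csv"
        make_hits([("2017", "1", 10, 0.5, 0.2)]).to_csv(path, index=False)
        out = read_gwas_table(path)
        assert len(out) == 1

    def test_bad_pvalue_rejected(self, tmp_path):
        path = tmp_path / "gwas.csv"
        make_hits([("2017", "1", 10, 0.5)]).assign(pvalue=[1.5]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="p-value"):
            read_gwas_table(path)
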