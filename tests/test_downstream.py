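from itertools import product

import numpy as np
import pytest

from parafates.alignio import extract_paralog_pairs
from parafates.downstream import (
    CATEGORY_INDEPENDENT,
    CATEGORY_OTHER,
    CATEGORY_WGD,
    COMPARTMENTS,
    asymmetry_summary,
    build_logo,
    categorize_quartets,
    color_positions,
    localization_configuration,
    localization_summary,
    read_localization_table,
    read_wgd_table,
)
from parafates.networks import DuplicationClustering, cluster_editing, build_duplication_network
from parafates.scoring import (
    BootstrapEnsemble,
    fate_clustering_from_rows,
    jaccard_robust_clusters,
    score_quartets,
)
from parafates.simulate import SimConfig, simulate_family


@pytest.fixture(scope="module")
def analyzed_family():
    cfg = SimConfig(seed=21, target_peptide_len=20, loc_labels={1: "Cyto", 2: "Mito"})
    aln, mapping, truth = simulate_family(cfg)
    pairs = extract_paralog_pairs(aln, mapping)
    rows = score_quartets(aln, pairs, mode="parsimony", rng=0)
    dups = cluster_editing(build_duplication_network(rows))
    baseline = fate_clustering_from_rows(rows)
    robust = jaccard_robust_clusters(baseline, BootstrapEnsemble([], None))
    return aln, mapping, truth, pairs, rows, dups, robust


class TestCategorization:
    def test_matches_simulator_truth(self, analyzed_family):
        _, _, truth, _, rows, dups, _ = analyzed_family
        categories = categorize_quartets(rows, dups)
        blk = truth.block_of_species
        for row, cat in zip(rows, categories):
            independent = blk[row["species_x"]] != blk[row["species_y"]]
            assert (cat == CATEGORY_INDEPENDENT) == independent

    def test_wgd_annotation_splits_single_duplications(self, analyzed_family):
        _, _, _, _, rows, dups, _ = analyzed_family
        wgd = {"sp01": "WGD"}
        categories = categorize_quartets(rows, dups, wgd)
        for row, cat in zip(rows, categories):
            if dups.same_block(row["species_x"], row["species_y"]):
                involved = "sp01" in (row["species_x"], row["species_y"])
                assert cat == (CATEGORY_WGD if involved else CATEGORY_OTHER)
            else:
                assert cat == CATEGORY_INDEPENDENT


class TestAsymmetrySummary:
    def test_direct_proportion_and_se(self):
        rows = (
            [{"Z_F": 3.0, "Z_A": 3.0}] * 9
            + [{"Z_F": 3.0, "Z_A": 0.1}]
            + [{"Z_F": 0.5, "Z_A": 5.0}]
        )
        cats = ["independent_duplication"] * len(rows)
        s = asymmetry_summary(rows, cats)["independent_duplication"]
        assert s["n"] == 10 and s["k"] == 9
        assert s["fraction"] == pytest.approx(0.9)
        assert s["se"] == pytest.approx(np.sqrt(0.9 * 0.1 / 10))

    def test_empty_denominator(self):
        s = asymmetry_summary([{"Z_F": 0.1, "Z_A": 5.0}], ["x"])["x"]
        assert s["fraction"] is None

    def test_matches_independent_recount(self, analyzed_family):
        _, _, _, _, rows, dups, _ = analyzed_family
        cats = categorize_quartets(rows, dups)
        summary = asymmetry_summary(rows, cats)
        for cat in set(cats):
            sig = [r for r, c in zip(rows, cats)
                   if c == cat and r["Z_F"] is not None and abs(r["Z_F"]) > 1.96]
            k = sum(1 for r in sig if r["Z_A"] is not None and abs(r["Z_A"]) > 1.96)
            assert summary[cat]["n"] == len(sig)
            assert summary[cat]["k"] == k


def independent_config_oracle(locs, pairing):
    """Truth table by first principles, written independently of the library.

    With fate sides (by pairing) s1 = {genes matched to gene_a} etc., the
    label depends only on the multiset structure of the four compartments.
    """
    la, lb, lc, ld = locs
    if len({la, lb, lc, ld}) == 1:
        return "uniform"
    mates = (lc, ld) if pairing == "R" else (ld, lc)
    if la == mates[0] and lb == mates[1] and la != lb:
        return "consistent"
    if la == mates[1] and lb == mates[0] and la != lb:
        return "inconsistent"
    counts = sorted((la, lb, lc, ld).count(x) for x in {la, lb, lc, ld})
    if counts == [1, 3]:
        return "single_distinct"
    return "other"


class TestLocalizationConfiguration:
    def test_exhaustive_truth_table(self):
        # every 4-tuple of compartments under both pairings
        for pairing in ("R", "S"):
            for locs in product(COMPARTMENTS, repeat=4):
                table = {g: (loc, 1) for g, loc in zip("abcd", locs)}
                row = {"gene_a": "a", "gene_b": "b", "gene_c": "c", "gene_d": "d",
                       "pairing": pairing}
                got = localization_configuration(row, table)
                assert got == independent_config_oracle(locs, pairing), (locs, pairing)

    @pytest.mark.parametrize(
        "locs,pairing,expected",
        [
            (("Mito", "Cyto", "Mito", "Cyto"), "R", "consistent"),
            (("Mito", "Cyto", "Cyto", "Mito"), "R", "inconsistent"),
            (("Cyto", "Cyto", "Cyto", "Cyto"), "R", "uniform"),
            (("Mito", "Cyto", "Cyto", "Mito"), "S", "consistent"),
        ],
    )
    def test_named_examples(self, locs, pairing, expected):
        table = {g: (loc, 1) for g, loc in zip("abcd", locs)}
        row = {"gene_a": "a", "gene_b": "b", "gene_c": "c", "gene_d": "d",
               "pairing": pairing}
        assert localization_configuration(row, table) == expected

    def test_reliability_filter_excludes(self):
        table = {g: ("Mito", 3) for g in "abcd"}
        row = {"gene_a": "a", "gene_b": "b", "gene_c": "c", "gene_d": "d", "pairing": "R"}
        assert localization_configuration(row, table) is None

    def test_missing_gene_excludes(self):
        table = {g: ("Mito", 1) for g in "abc"}
        row = {"gene_a": "a", "gene_b": "b", "gene_c": "c", "gene_d": "d", "pairing": "R"}
        assert localization_configuration(row, table) is None

    def test_tables_read_from_tsv(self, tmp_path):
        loc = tmp_path / "loc.tsv"
        loc.write_text("gene_id\tcompartment\treliability_class\ng1\tMito\t1\ng2\tCyto\t4\n")
        table = read_localization_table(loc)
        assert table == {"g1": ("Mito", 1), "g2": ("Cyto", 4)}
        wgd = tmp_path / "wgd.tsv"
        wgd.write_text("species\tgene_a\tgene_b\tlabel\nsp01\ta\tb\tWGD\n")
        assert read_wgd_table(wgd) == {"sp01": "WGD"}


class TestColorPositions:
    def test_warm_columns_cover_diagnostics(self, analyzed_family):
        # family-consensus warm set: a pair votes warm at a column when the
        # column supports the fate prediction in a majority of that pair's
        # independent-duplication quartets; the column is warm when warm votes
        # beat cold votes. This must recover every diagnostic column. Drift on
        # post-duplication shared branches produces real recurrent one-sided
        # patterns at a low rate, so a small spurious fraction is intrinsic.
        aln, _, truth, pairs, rows, dups, robust = analyzed_family
        annotations = color_positions(aln, pairs, dups, robust)
        diag = set(truth.diagnostic_columns["fate1"]) | set(
            truth.diagnostic_columns["fate2"]
        )
        per_pair_quartets = 9  # 3 species in each of 3 other blocks
        need = -(-per_pair_quartets // 2)
        warm_set = set()
        for col in range(aln.length):
            w = c = 0
            for ann in annotations:
                sup = ann.class_counts[col, :3].sum()
                con = ann.class_counts[col, 3:].sum()
                if sup > con and sup >= need:
                    w += 1
                elif con > sup and con >= need:
                    c += 1
            if w > c and w > 0:
                warm_set.add(col)
        assert diag <= warm_set
        spurious = warm_set - diag - set(truth.extension_columns)
        assert len(spurious) <= 0.10 * aln.length

    def test_extension_block_warm(self, analyzed_family):
        aln, _, truth, pairs, rows, dups, robust = analyzed_family
        annotations = color_positions(aln, pairs, dups, robust)
        warm = {"yellow", "red", "pink"}
        for col in truth.extension_columns:
            for ann in annotations:
                assert ann.colors[col] in warm

    def test_logo_frequencies(self, analyzed_family, tmp_path):
        aln, _, truth, pairs, rows, dups, robust = analyzed_family
        annotations = color_positions(aln, pairs, dups, robust)
        freq = build_logo(annotations, plot_path=tmp_path / "logo.png")
        assert freq.shape == (aln.length, 6)
        assert np.all(freq.sum(axis=1) <= 1.0 + 1e-9)
        diag_support = freq[truth.diagnostic_columns["fate1"], :3].sum(axis=1)
        assert diag_support.mean() > 0.8
        assert (tmp_path / "logo.png").exists()

    def test_noiseless_diagnostics_carry_full_support(self):
        # zero branch lengths: fate signal is the only variation, so every
        # diagnostic column is pure symmetric support at frequency 1
        newick = "((a:0,b:0):0,(c:0,d:0):0);"
        cfg = SimConfig(
            species_tree=newick,
            duplication_placements=(("a", "b"), ("c", "d")),
            n_columns=60, n_diagnostic=10, seed=4,
        )
        aln, mapping, truth = simulate_family(cfg)
        pairs = extract_paralog_pairs(aln, mapping)
        rows = score_quartets(aln, pairs, mode="parsimony", rng=0)
        blocks = {}
        for sp, b in truth.block_of_species.items():
            blocks.setdefault(b, set()).add(sp)
        dups = DuplicationClustering(tuple(frozenset(v) for v in blocks.values()), 0.0)
        f1, f2 = truth.fate_sets()
        from parafates.scoring import RobustFateSet

        robust = RobustFateSet((frozenset(f1), frozenset(f2)), (1.0, 1.0))
        annotations = color_positions(aln, pairs, dups, robust)
        freq = build_logo(annotations)
        for col in truth.diagnostic_columns["fate1"] + truth.diagnostic_columns["fate2"]:
            assert freq[col, 0] == pytest.approx(1.0)  # symmetric support

    def test_order_invariance(self, analyzed_family):
        aln, _, _, pairs, rows, dups, robust = analyzed_family
        a1 = color_positions(aln, pairs, dups, robust)
        a2 = color_positions(aln, list(reversed(pairs)), dups, robust)
        by_pair_1 = {ann.pair: ann.classes for ann in a1}
        by_pair_2 = {ann.pair: ann.classes for ann in a2}
        assert by_pair_1 == by_pair_2


class TestLocalizationSummary:
    def test_consistent_for_relocalized_family(self, analyzed_family):
        _, _, truth, _, rows, dups, _ = analyzed_family
        table = {g: truth.localization[g] for g in truth.localization}
        cats = categorize_quartets(rows, dups)
        summary = localization_summary(rows, table, cats)
        indep = summary[CATEGORY_INDEPENDENT]["counts"]
        assert set(indep) == {"consistent"}
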