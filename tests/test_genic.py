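"""Gene-body masking, feature summaries, spinograms and ortholog joins."""

import numpy as np
import pandas as pd
import pytest

import pmeth
from pmeth.io import as_cpg_track


def calls_at(positions, fractions, chrom="chr1"):
    return as_cpg_track(
        pd.DataFrame({"chrom": chrom, "pos": positions, "fraction": fractions})
    )


class TestPromoters:
    def test_strand_aware_definition(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["gp", "gm"], "chrom": "chr1",
                "start": [10_000, 50_000], "end": [20_000, 60_000],
                "strand": ["+", "-"],
            }
        )
        prom = pmeth.promoters_from_genes(genes)
        p = prom.set_index("gene_id")
        # plus strand: 1000 bp upstream to 100 bp downstream of tx_start
        assert (p.loc["gp", "start"], p.loc["gp", "end"]) == (9_000, 10_100)
        # minus strand: [tx_end - 100, tx_end + 1000)
        assert (p.loc["gm", "start"], p.loc["gm", "end"]) == (59_900, 61_000)

    def test_clipped_at_zero(self):
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": "chr1", "start": [200], "end": [5000], "strand": ["+"]}
        )
        assert pmeth.promoters_from_genes(genes).loc[0, "start"] == 0


class TestGeneBodyMethylation:
    genes = pd.DataFrame(
        {"gene_id": ["g1"], "chrom": "chr1", "start": [10_000], "end": [40_000], "strand": ["+"]}
    )

    def test_promoter_only_gene_omitted(self):
        # all CpGs inside the promoter overlap [10_000, 10_100)
        calls = calls_at(np.arange(10_000, 10_100, 4), 0.5)
        res = pmeth.gene_body_methylation(calls, self.genes, min_cpgs=1)
        assert len(res.table) == 0 and res.n_genes_dropped == 1

    def test_island_masking_matches_brute_force(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(11_000, 40_000), 25, replace=False))
        frac = rng.random(25)
        islands = pd.DataFrame(
            {"chrom": "chr1", "start": [pos[5] - 1], "end": [pos[9] + 1], "label": "cpg_island"}
        )
        calls = calls_at(pos, frac)
        res = pmeth.gene_body_methylation(
            calls, self.genes, cpg_islands=islands, min_cpgs=20
        )
        in_island = (pos >= islands.loc[0, "start"]) & (pos < islands.loc[0, "end"])
        expected = frac[~in_island].mean()
        assert res.table.loc[0, "methylation"] == pytest.approx(expected, abs=1e-12)
        assert res.table.loc[0, "n_cpgs"] == int((~in_island).sum())

    def test_min_cpgs_filter(self):
        calls = calls_at(np.arange(12_000, 12_000 + 19 * 10, 10), 0.7)
        res = pmeth.gene_body_methylation(calls, self.genes, min_cpgs=20)
        assert len(res.table) == 0
        res = pmeth.gene_body_methylation(calls, self.genes, min_cpgs=19)
        assert res.table.loc[0, "methylation"] == pytest.approx(0.7)

    def test_masking_soundness_exhaustive(self):
        """No CpG in a promoter or island ever contributes to a body mean."""
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(50_000, 200, replace=False))
        frac = np.full(200, 0.2)
        islands = pd.DataFrame(
            {"chrom": "chr1", "start": [15_000], "end": [18_000], "label": "cpg_island"}
        )
        # poison masked sites with 1.0: result must still be exactly 0.2
        prom = pmeth.promoters_from_genes(self.genes)
        masked = ((pos >= prom.loc[0, "start"]) & (pos < prom.loc[0, "end"])) | (
            (pos >= 15_000) & (pos < 18_000)
        )
        frac[masked] = 1.0
        res = pmeth.gene_body_methylation(
            calls_at(pos, frac), self.genes, cpg_islands=islands, min_cpgs=1
        )
        assert res.table.loc[0, "methylation"] == pytest.approx(0.2, abs=1e-12)

    def test_expressed_genes_more_methylated(self, demo_bundle, demo_methylome):
        res = pmeth.gene_body_methylation(
            demo_methylome.calls, demo_bundle.genes,
            cpg_islands=demo_bundle.islands,
        )
        tab = res.table.merge(demo_methylome.gene_truth, on="gene_id")
        hi = tab.loc[tab["expressed"], "methylation"].mean()
        lo = tab.loc[~tab["expressed"], "methylation"].mean()
        assert hi > lo


class TestFeatureMethylation:
    def test_min_cpgs_exclusion(self):
        calls = calls_at(np.arange(0, 90, 10), 0.5)  # 9 CpGs
        feats = pd.DataFrame(
            {"chrom": "chr1", "start": [0], "end": [100], "label": "repeat:LINE"}
        )
        per_feature, per_class = pmeth.feature_methylation(calls, feats, min_cpgs=10)
        assert len(per_feature) == 0
        # class pool still counts the sites
        assert per_class.set_index("label").loc["repeat:LINE", "n_cpgs"] == 9

    def test_complement_class_without_repeats(self):
        calls = calls_at([10, 20, 30], [0.1, 0.5, 0.9])
        feats = pd.DataFrame(columns=["chrom", "start", "end", "label"])
        _, per_class = pmeth.feature_methylation(calls, feats)
        comp = per_class.set_index("label").loc["non_repetitive"]
        assert comp["n_cpgs"] == 3
        assert comp["methylation"] == pytest.approx(0.5)

    def test_class_pools_match_brute_force_and_order_invariance(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(100_000, 500, replace=False))
        frac = rng.random(500)
        calls = calls_at(pos, frac)
        feats = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(10) * 10_000,
                "end": np.arange(10) * 10_000 + 3_000,
                "label": ["repeat:LINE", "repeat:SINE"] * 5,
            }
        )
        _, per_class = pmeth.feature_methylation(calls, feats)
        for cls in ("repeat:LINE", "repeat:SINE"):
            sel = np.zeros(len(pos), dtype=bool)
            for _, f in feats[feats["label"] == cls].iterrows():
                sel |= (pos >= f["start"]) & (pos < f["end"])
            assert per_class.set_index("label").loc[cls, "methylation"] == pytest.approx(
                frac[sel].mean(), abs=1e-12
            )
        _, shuffled = pmeth.feature_methylation(calls, feats.sample(frac=1, random_state=3))
        pd.testing.assert_frame_equal(
            per_class.sort_values("label").reset_index(drop=True),
            shuffled.sort_values("label").reset_index(drop=True),
        )


class TestSpinogram:
    @staticmethod
    def _windows(meths, chrom="chr1"):
        n = len(meths)
        return pd.DataFrame(
            {
                "chrom": chrom, "start": np.arange(n) * 5_000,
                "end": (np.arange(n) + 1) * 5_000, "mean_meth": meths, "n_cpgs": 15,
            }
        )

    def test_complete_separation(self):
        # genic windows ~78%, intergenic ~22%
        meths = [0.78, 0.78, 0.22, 0.22, 0.78, 0.22]
        wins = self._windows(meths)
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b"], "chrom": "chr1",
                "start": [0, 20_000], "end": [10_000, 25_000], "strand": ["+", "+"],
            }
        )
        sp = pmeth.genic_spinogram(wins, genes)
        tab = sp.set_index("bin_lo")
        assert tab.loc[75.0, "p_genic"] == 1.0
        assert tab.loc[20.0, "p_genic"] == 0.0

    def test_conservation_identities(self, demo_bundle, demo_methylome):
        t5 = pmeth.window_methylation(
            demo_methylome.calls, 5_000, 10, chrom_sizes=demo_bundle.chrom_sizes
        )
        sp = pmeth.genic_spinogram(t5, demo_bundle.genes)
        assert sp["n_windows"].sum() == t5["mean_meth"].notna().sum()
        assert sp["fraction"].sum() == pytest.approx(1.0)
        assert (sp["n_genic"] <= sp["n_windows"]).all()

    def test_empty_bins_have_undefined_probability(self):
        wins = self._windows([0.5] * 10)
        genes = pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])
        sp = pmeth.genic_spinogram(wins, genes)
        empties = sp[sp["n_windows"] == 0]
        assert empties["p_genic"].isna().all()
        # no genes: genic probability is 0 where defined
        assert (sp.loc[sp["n_windows"] > 0, "p_genic"] == 0.0).all()


class TestOrthologMatrix:
    def test_identity_orthology_gives_identical_columns(self):
        tab = pd.DataFrame({"gene_id": ["g1", "g2"], "methylation": [0.3, 0.7], "n_cpgs": [30, 40]})
        pairs = pd.DataFrame({"gene_id_a": ["g1", "g2"], "gene_id_b": ["g1", "g2"]})
        mat = pmeth.build_ortholog_matrix(
            {"human": tab, "rhesus": tab}, {"rhesus": pairs}, pivot="human"
        )
        np.testing.assert_allclose(mat["human"], mat["rhesus"])

    def test_rows_with_single_species_dropped(self):
        hu = pd.DataFrame({"gene_id": ["g1", "g2"], "methylation": [0.3, 0.7], "n_cpgs": [30, 40]})
        rh = pd.DataFrame({"gene_id": ["m1"], "methylation": [0.4], "n_cpgs": [25]})
        pairs = pd.DataFrame({"gene_id_a": ["g1"], "gene_id_b": ["m1"]})
        mat = pmeth.build_ortholog_matrix({"human": hu, "rhesus": rh}, {"rhesus": pairs}, "human")
        assert list(mat.index) == ["g1"]

    def test_duplicate_orthologs_keep_highest_n_cpgs(self):
        hu = pd.DataFrame({"gene_id": ["g1"], "methylation": [0.3], "n_cpgs": [30]})
        rh = pd.DataFrame(
            {"gene_id": ["m1", "m2"], "methylation": [0.1, 0.9], "n_cpgs": [5, 50]}
        )
        pairs = pd.DataFrame({"gene_id_a": ["g1", "g1"], "gene_id_b": ["m1", "m2"]})
        mat = pmeth.build_ortholog_matrix({"human": hu, "rhesus": rh}, {"rhesus": pairs}, "human")
        assert mat.loc["g1", "rhesus"] == 0.9

    def test_shuffled_join_matches_hand_join(self):
        rng = np.random.default_rng(5)
        ids = [f"g{i}" for i in range(50)]
        other_ids = [f"m{i}" for i in range(50)]
        hu = pd.DataFrame({"gene_id": ids, "methylation": rng.random(50), "n_cpgs": 30})
        rh = pd.DataFrame({"gene_id": other_ids, "methylation": rng.random(50), "n_cpgs": 30})
        pairs = pd.DataFrame({"gene_id_a": ids, "gene_id_b": other_ids}).sample(
            frac=1, random_state=7
        )
        mat = pmeth.build_ortholog_matrix(
            {"hu": hu, "rh": rh}, {"rh": pairs}, pivot="hu"
        )
        hand = {a: rh.set_index("gene_id").loc[b, "methylation"]
                for a, b in zip(ids, other_ids)}
        for g in ids:
            assert mat.loc[g, "rh"] == pytest.approx(hand[g])
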