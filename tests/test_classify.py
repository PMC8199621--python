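"""The three classification approaches, consensus and the transgene test."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

from xenopsc.classify import (_rank_sum, build_reference_signature,
                              classify_by_clustering, classify_by_embedding,
                              classify_by_signature, consensus_labels,
                              integrate_and_embed, rank_marker_genes,
                              transgene_detection_test)
from xenopsc.io_formats import CountMatrix, GeneAxis
from xenopsc.synthetic import SimConfig, generate_xenograft_samples


def fisher_two_sided_oracle(table):
    """Brute-force two-sided Fisher p: sum of hypergeometric point masses
    no larger than the observed table's."""
    (a, b), (c, d) = table
    n1, m, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, m - (c + d)), min(n1, m)
    ks = np.arange(lo, hi + 1)
    pmf = scipy.stats.hypergeom.pmf(ks, n, n1, m)
    pa = scipy.stats.hypergeom.pmf(a, n, n1, m)
    return float(pmf[pmf <= pa * (1 + 1e-7)].sum())


class TestRankSum:
    def test_matches_scipy_per_gene(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(5, size=(20, 15)).astype(float)
        b = rng.poisson(7, size=(20, 12)).astype(float)
        z, p = _rank_sum(a, b)
        for g in range(20):
            res = scipy.stats.mannwhitneyu(a[g], b[g], alternative="two-sided",
                                           method="asymptotic")
            assert p[g] == pytest.approx(res.pvalue, rel=1e-6)

    def test_direction_sign(self):
        a = np.full((1, 10), 100.0) + np.arange(10)
        b = np.zeros((1, 10)) + np.arange(10)
        z, _ = _rank_sum(a, b)
        assert z[0] > 0


class TestIntegration:
    def _two_programs(self, rng, n=150, n_genes=120):
        base = rng.lognormal(1.0, 0.8, n_genes)
        prog_a, prog_b = base.copy(), base.copy()
        prog_a[:20] *= 6
        prog_b[20:40] *= 6
        cols, types = [], []
        for i in range(n):
            p = prog_a if i % 2 == 0 else prog_b
            cols.append(rng.poisson(p * 5))
            types.append("cancer" if i % 2 == 0 else "psc")
        return np.column_stack(cols), np.array(types), n_genes

    def _as_matrix(self, counts, label, n_genes):
        ids = [f"GRCh38_G{i}" for i in range(n_genes)]
        return CountMatrix(GeneAxis.from_ids(ids),
                           [f"{label}_b{i}" for i in range(counts.shape[1])],
                           label, sp.csr_matrix(counts))

    def test_single_sample_identity(self):
        rng = np.random.default_rng(1)
        counts, _, g = self._two_programs(rng)
        m = self._as_matrix(counts, "Cult", g)
        res = integrate_and_embed([m], seed=0, compute_umap=False)
        np.testing.assert_allclose(res["embedding"].pcs, res["pcs_uncorrected"])

    def test_constant_shift_removed(self):
        """A planted batch effect shrinks the between-sample centroid gap >=10x."""
        rng = np.random.default_rng(2)
        counts, _, g = self._two_programs(rng, n=200)
        # same cells up to a deterministic per-gene batch scaling
        batch = rng.lognormal(0.0, 0.8, g)
        shifted = np.round(counts * batch[:, None]).astype(int)
        m_ref = self._as_matrix(counts, "Cult", g)
        m_query = self._as_matrix(shifted, "MsBlood", g)
        res = integrate_and_embed([m_ref, m_query], seed=0, compute_umap=False)
        soc = res["sample_of_cell"]
        pre = res["pcs_uncorrected"]
        post = res["embedding"].pcs
        d_pre = np.linalg.norm(pre[soc == "Cult"].mean(0) - pre[soc == "MsBlood"].mean(0))
        d_post = np.linalg.norm(post[soc == "Cult"].mean(0) - post[soc == "MsBlood"].mean(0))
        assert d_post <= d_pre / 10

    def test_same_seed_same_embedding(self):
        rng = np.random.default_rng(3)
        counts, _, g = self._two_programs(rng, n=80)
        m = self._as_matrix(counts, "Cult", g)
        r1 = integrate_and_embed([m], seed=7)
        r2 = integrate_and_embed([m], seed=7)
        np.testing.assert_allclose(r1["embedding"].coords_2d,
                                   r2["embedding"].coords_2d)


class TestVoteClassifiers:
    def test_coincident_point_k1(self):
        coords = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]])
        is_ref = np.array([True, True, False])
        labels = classify_by_embedding(coords, is_ref,
                                       np.array(["psc", "cancer"]), k=1)
        assert labels[0] == "psc"

    def test_split_vote_unassigned(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 0.0]])
        is_ref = np.array([True, True, False])
        labels = classify_by_embedding(coords, is_ref,
                                       np.array(["psc", "cancer"]), k=2)
        assert labels[0] == "unassigned"

    def test_k_exceeding_reference_rejected(self):
        coords = np.zeros((3, 2))
        with pytest.raises(ValueError, match="reference"):
            classify_by_embedding(coords, np.array([True, False, False]),
                                  np.array(["psc"]), k=5)

    def test_cluster_without_reference_unassigned(self):
        from xenopsc.preprocess import build_knn
        rng = np.random.default_rng(4)
        ref = rng.normal(0, 0.3, size=(30, 2))
        far = rng.normal(20, 0.3, size=(30, 2))
        pcs = np.vstack([ref, far])
        is_ref = np.r_[np.ones(30), np.zeros(30)].astype(bool)
        idx, _ = build_knn(pcs, n_neighbors=10)
        labels = classify_by_clustering(idx, is_ref, np.array(["psc"] * 30),
                                        resolution=0.5, seed=0)
        assert (labels == "unassigned").all()


class TestReferenceSignature:
    def test_planted_marker_recall(self, clean_run):
        cfg, samples, truth = clean_run
        truth_i = truth.set_index("barcode")
        cult = samples["Cult"]
        types = truth_i.loc[cult.barcodes, "true_type"].to_numpy()
        sig = build_reference_signature(cult, types, n_top=cfg.n_marker_genes)
        m = cfg.n_marker_genes
        epithelial = set(cult.genes.gene_id[:m])
        myofib = set(cult.genes.gene_id[m:2 * m])
        recall_cancer = len(set(sig.cancer_genes) & epithelial) / m
        recall_psc = len(set(sig.psc_genes) & myofib) / m
        assert recall_cancer >= 0.95 and recall_psc >= 0.95

    def test_exclusive_gene_lands_in_its_list(self):
        rng = np.random.default_rng(5)
        n_genes, n_each = 30, 25
        ids = [f"GRCh38_G{i}" for i in range(n_genes)]
        cancer = rng.poisson(5, size=(n_genes, n_each))
        psc = cancer.copy()      # identical background (incl. equal depths)
        cancer[0], psc[0] = 0, 50   # psc-exclusive gene
        cancer[2], psc[2] = 50, 0   # cancer-exclusive gene balancing depth
        cancer[1] = psc[1] = 7      # identical across types
        counts = np.hstack([cancer, psc])
        m = CountMatrix(GeneAxis.from_ids(ids),
                        [f"b{i}" for i in range(2 * n_each)], "Cult",
                        sp.csr_matrix(counts))
        types = np.array(["cancer"] * n_each + ["psc"] * n_each)
        with pytest.warns(UserWarning):
            sig = build_reference_signature(m, types, n_top=10)
        assert ids[0] in sig.psc_genes
        assert ids[1] not in sig.cancer_genes and ids[1] not in sig.psc_genes


class TestSignatureClassifier:
    def test_mixture_proportions_recovered(self):
        """A 3:1 CTC:cPSC blood mixture is recovered within one cell."""
        comp = dict(SimConfig().composition)
        comp["MsBlood"] = (60, 20, 100)
        cfg = SimConfig(seed=9, composition=comp, alpha=0.0, delta=0.0)
        samples, truth = generate_xenograft_samples(cfg)
        truth_i = truth.set_index("barcode")
        cult = samples["Cult"]
        sig = build_reference_signature(
            cult, truth_i.loc[cult.barcodes, "true_type"].to_numpy(), n_top=300)
        blood = samples["MsBlood"]
        human = blood.subset_cells(np.array(
            [truth_i.loc[bc, "true_species"] == "human" for bc in blood.barcodes]))
        res = classify_by_signature(human, sig, seed=0)
        counts = res["label"].value_counts()
        assert abs(int(counts.get("cancer", 0)) - 60) <= 1
        assert abs(int(counts.get("psc", 0)) - 20) <= 1

    def test_pure_psc_cell_scores_positive_margin(self):
        ids = [f"GRCh38_G{i}" for i in range(20)]
        sig_scores = pd.DataFrame({"gene_id": ids})
        from xenopsc.classify import ReferenceSignature
        sig = ReferenceSignature(cancer_genes=ids[:10], psc_genes=ids[10:],
                                 scores=sig_scores)
        counts = np.zeros((20, 2))
        counts[10:, 0] = 5   # psc-gene-only cell
        counts[:10, 1] = 5   # cancer-gene-only cell
        m = CountMatrix(GeneAxis.from_ids(ids), ["p", "c"], "MsBlood",
                        sp.csr_matrix(counts))
        res = classify_by_signature(m, sig, seed=0).set_index("barcode")
        assert res.loc["p", "label"] == "psc"
        assert res.loc["p", "score_psc"] > res.loc["p", "score_cancer"]
        assert res.loc["c", "label"] == "cancer"

    def test_too_few_cells_rejected(self):
        ids = ["GRCh38_A", "GRCh38_B"]
        from xenopsc.classify import ReferenceSignature
        sig = ReferenceSignature(["GRCh38_A"], ["GRCh38_B"], pd.DataFrame())
        m = CountMatrix(GeneAxis.from_ids(ids), ["x"], "MsBlood",
                        sp.csr_matrix(np.array([[1], [1]])))
        with pytest.raises(ValueError, match="2 blood"):
            classify_by_signature(m, sig)


class TestConsensus:
    def test_unanimous_and_discordant(self):
        a1 = pd.Series({"b1": "psc", "b2": "psc", "b3": "cancer"})
        a2 = pd.Series({"b1": "psc", "b2": "cancer", "b3": "cancer"})
        a3 = pd.Series({"b1": "psc", "b2": "psc", "b3": "unassigned"})
        frame, venn = consensus_labels(a1, a2, a3)
        assert frame.loc["b1", "consensus"] == "psc"
        assert frame.loc["b2", "consensus"] == "discordant"
        assert frame.loc["b3", "consensus"] == "cancer"
        assert venn["a1_a2_a3"] == 1 and venn["a1_a3"] == 1

    def test_single_approach_not_enough(self):
        a1 = pd.Series({"b1": "psc"})
        a2 = pd.Series({"b1": "unassigned"})
        a3 = pd.Series({"b1": "unassigned"})
        frame, _ = consensus_labels(a1, a2, a3)
        assert frame.loc["b1", "consensus"] == "discordant"

    def test_consensus_subset_of_each_approach(self, pipeline_result):
        res, _ = pipeline_result
        labels = res["labels"]
        cons = set(labels.index[labels["consensus"] == "psc"])
        for col in ("label_a1", "label_a2", "label_a3"):
            labelled = labels[labels[col] != "unassigned"]
            approach_psc = set(labelled.index[labelled[col] == "psc"])
            assert cons & set(labelled.index) <= approach_psc

    def test_venn_counts_sum_to_union(self, pipeline_result):
        res, _ = pipeline_result
        labels, venn = res["labels"], res["venn"]
        union = set()
        for col in ("label_a1", "label_a2", "label_a3"):
            union |= set(labels.index[labels[col] == "psc"])
        assert sum(venn.values()) == len(union)

    def test_every_true_blood_psc_found_by_two_approaches(self, pipeline_result):
        res, truth_i = pipeline_result
        labels = res["labels"]
        blood = labels[labels["sample_label"] == "MsBlood"]
        for bc in blood.index:
            if bc in truth_i.index and truth_i.loc[bc, "true_type"] == "psc":
                n_psc = sum(blood.loc[bc, c] == "psc"
                            for c in ("label_a1", "label_a2", "label_a3"))
                assert n_psc >= 2


class TestTransgeneTest:
    def test_no_detection_anywhere_gives_p1(self):
        res = transgene_detection_test(np.zeros(16), np.zeros(60))
        assert res["p_value"] == pytest.approx(1.0)

    def test_specific_table_matches_enumeration(self):
        cpsc = np.zeros(16)
        cancer = np.r_[np.ones(30), np.zeros(30)]
        res = transgene_detection_test(cpsc, cancer)
        assert res["table"].tolist() == [[0, 16], [30, 30]]
        assert res["p_value"] == pytest.approx(
            fisher_two_sided_oracle(res["table"]), rel=1e-9)

    def test_complete_reversal_matches_enumeration(self):
        cpsc = np.ones(10)
        cancer = np.zeros(10)
        res = transgene_detection_test(cpsc, cancer)
        assert res["p_value"] == pytest.approx(
            fisher_two_sided_oracle(res["table"]), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            transgene_detection_test(np.array([]), np.ones(5))

    def test_synthetic_cpsc_nondetection_significant(self, pipeline_result):
        res, _ = pipeline_result
        t = res["transgene_test"]
        assert t is not None
        assert t["table"][0][0] == 0          # no cPSC expresses the transgene
        assert t["p_value"] < 0.05


class TestMarkerRanking:
    def test_planted_separated_marker_flagged(self):
        rng = np.random.default_rng(6)
        n_genes = 100
        ctc = rng.poisson(3, size=(n_genes, 62)).astype(float)
        cpsc = rng.poisson(3, size=(n_genes, 16)).astype(float)
        ctc[0] += 50  # complete separation
        table = rank_marker_genes(ctc, cpsc, [f"g{i}" for i in range(n_genes)],
                                  fdr=0.10)
        row = table.set_index("gene_id").loc["g0"]
        assert row["significant"] and row["direction"] == "ctc"

    def test_permuted_labels_yield_no_flags(self):
        rng = np.random.default_rng(7)
        pooled = rng.poisson(4, size=(200, 78)).astype(float)
        table = rank_marker_genes(pooled[:, :62], pooled[:, 62:],
                                  [f"g{i}" for i in range(200)], fdr=0.10)
        assert table["significant"].sum() <= 2

    def test_identical_groups_no_flags(self):
        x = np.tile(np.arange(10.0), (5, 1))
        table = rank_marker_genes(x, x.copy(), [f"g{i}" for i in range(5)])
        assert not table["significant"].any()
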