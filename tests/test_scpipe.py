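"""Single-cell stage: QC, typing, proportions, pseudo-bulk, scores, regulons, LR."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from regionomics import scpipe, simdata


def toy_adata(counts, obs=None, genes=None):
    n_cells, n_genes = counts.shape
    adata = ad.AnnData(X=sp.csr_matrix(np.asarray(counts, dtype=float)))
    adata.obs_names = [f"c{i}" for i in range(n_cells)]
    adata.var_names = genes or [f"g{i}" for i in range(n_genes)]
    if obs is not None:
        for k, v in obs.items():
            adata.obs[k] = v
    return adata


class TestRankSum:
    def test_exact_fully_separated_five_vs_five(self):
        p = scpipe.rank_sum_test(
            [0.20, 0.22, 0.21, 0.19, 0.23], [0.10, 0.12, 0.11, 0.13, 0.09]
        )
        assert p == pytest.approx(2 / 252)

    def test_identical_groups_p_one(self):
        assert scpipe.rank_sum_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_exact_matches_scipy_enumeration(self):
        """Exact branch agrees with scipy's exact Mann-Whitney on tie-free data."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            mine = scpipe.rank_sum_test(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert mine == pytest.approx(float(ref.pvalue))


class TestQc:
    def test_low_complexity_cell_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, size=(20, 700))
        counts[0] = 0
        counts[0, :100] = 5  # only 100 detected genes
        adata = toy_adata(counts)
        out = scpipe.qc_and_normalize(adata, min_genes=500, max_mito=1.0,
                                      min_cells_per_gene=1)
        assert "c0" not in out.obs_names
        assert out.n_obs == 19

    def test_high_mito_cell_removed(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(10, 600))
        genes = [f"mt-g{i}" if i < 5 else f"g{i}" for i in range(600)]
        counts[0, :5] = 3000  # mito-dominated cell
        adata = toy_adata(counts, genes=genes)
        out = scpipe.qc_and_normalize(adata, min_genes=100, max_mito=0.2,
                                      min_cells_per_gene=1)
        assert "c0" not in out.obs_names

    def test_proportional_cells_normalize_identically(self):
        base = np.random.default_rng(2).poisson(4, size=600) + 1
        counts = np.vstack([base, base * 3] + [base] * 5)
        adata = toy_adata(counts)
        out = scpipe.qc_and_normalize(adata, min_genes=10, max_mito=1.0,
                                      min_cells_per_gene=1)
        x = out.layers["lognorm"].toarray()
        assert np.allclose(x[0], x[1])

    def test_idempotent_on_own_output(self, normalized_sc):
        once = normalized_sc
        twice = scpipe.qc_and_normalize(once, min_genes=200, max_mito=0.2)
        assert once.shape == twice.shape
        assert (once.layers["lognorm"] != twice.layers["lognorm"]).nnz == 0

    def test_all_cells_filtered_errors(self):
        adata = toy_adata(np.ones((3, 10)))
        with pytest.raises(ValueError):
            scpipe.qc_and_normalize(adata, min_genes=100)


class TestTyping:
    def test_cell_equal_to_centroid_gets_label_unflagged(self):
        rng = np.random.default_rng(3)
        markers = {"tA": [f"g{i}" for i in range(5)], "tB": [f"g{i}" for i in range(5, 10)]}
        profiles = np.zeros((40, 30))
        truth = []
        for i in range(40):
            t = "tA" if i % 2 == 0 else "tB"
            truth.append(t)
            lo = 0 if t == "tA" else 5
            profiles[i, lo : lo + 5] = 5.0
        profiles += rng.uniform(0, 0.1, profiles.shape)
        adata = toy_adata(np.round(profiles * 10))
        adata.layers["lognorm"] = sp.csr_matrix(profiles)
        ref = scpipe.ReferenceCentroids.from_labelled(
            adata, pd.Series(truth, index=adata.obs_names), markers
        )
        out = scpipe.assign_cell_types(adata, ref, seed=0)
        assert (out["label"] == np.array(truth)).all()
        assert not out["low_confidence"].any()

    def test_uncorrelated_cell_ambiguous(self):
        markers = {"tA": ["g0", "g1", "g2"], "tB": ["g3", "g4", "g5"]}
        ref = scpipe.ReferenceCentroids.from_marker_lists(markers)
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 0.01, size=(10, 12))
        adata = toy_adata(np.ones((10, 12)))
        adata.layers["lognorm"] = sp.csr_matrix(x)
        out = scpipe.assign_cell_types(adata, ref, min_corr=0.99, seed=0)
        assert (out["label"] == "ambiguous").all()

    def test_planted_types_recovered_with_high_accuracy(self):
        """Planted 6-type sim: labelling accuracy >= 0.9 on unambiguous cells."""
        cfg = simdata.ScSimConfig(
            n_genes=600, n_types=6, n_replicates=3, cells_per_replicate=100, seed=11
        )
        sim = simdata.simulate_scrna(cfg)
        adata = ad.concat([sim.sham, sim.treated], join="outer", merge="same")
        adata = scpipe.qc_and_normalize(adata, min_genes=100, max_mito=1.0)
        ref = scpipe.ReferenceCentroids.from_marker_lists(sim.markers)
        out = scpipe.assign_cell_types(adata, ref, seed=11)
        unamb = out["label"] != "ambiguous"
        acc = (out.loc[unamb, "label"] == adata.obs.loc[unamb, "true_type"]).mean()
        assert acc >= 0.9

    def test_no_shared_markers_rejected(self, normalized_sc):
        ref = scpipe.ReferenceCentroids.from_marker_lists({"t": ["nope1", "nope2"]})
        with pytest.raises(ValueError):
            scpipe.assign_cell_types(normalized_sc, ref)


class TestProportions:
    def _obs(self, labels_by_rep):
        rows = []
        for (cond, rep), labels in labels_by_rep.items():
            for lab in labels:
                rows.append((cond, rep, lab))
        df = pd.DataFrame(rows, columns=["condition", "replicate", "label"])
        return df["label"], df[["condition", "replicate"]]

    def test_identical_proportions_p_one(self):
        labels_by_rep = {}
        for cond in ("sham", "treated"):
            for rep in ("r1", "r2", "r3"):
                labels_by_rep[(cond, rep)] = ["tA"] * 10 + ["tB"] * 10
        labels, meta = self._obs(labels_by_rep)
        out = scpipe.test_proportions(labels, meta)
        assert (out["p_value"] == 1.0).all()

    def test_single_replicate_condition_rejected(self):
        labels_by_rep = {
            ("sham", "r1"): ["tA"] * 5,
            ("treated", "r1"): ["tA"] * 5,
            ("treated", "r2"): ["tA"] * 5,
        }
        labels, meta = self._obs(labels_by_rep)
        with pytest.raises(ValueError):
            scpipe.test_proportions(labels, meta)

    def test_planted_shift_detected_from_true_labels(self, planted_sc, normalized_sc):
        sim, cfg = planted_sc
        out = scpipe.test_proportions(
            normalized_sc.obs["true_type"], normalized_sc.obs
        )
        assert out.loc["type03", "p_value"] <= 0.05
        assert out.loc["type03", "direction"] == "up"


class TestPseudobulk:
    def test_type_with_single_unit_excluded(self, normalized_sc):
        labels = pd.Series("typeX", index=normalized_sc.obs_names)
        labels.iloc[:5] = "typeY"  # typeY never reaches min cells
        out = scpipe.pseudobulk_de(normalized_sc, labels, min_cells_per_unit=10)
        assert "typeY" not in out

    def test_constant_gene_is_ns(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(5, size=(80, 50))
        obs = {
            "condition": ["sham"] * 40 + ["treated"] * 40,
            "replicate": (["r1"] * 20 + ["r2"] * 20) * 2,
        }
        adata = toy_adata(counts, obs=obs)
        adata = scpipe.qc_and_normalize(adata, min_genes=5, max_mito=1.0,
                                        min_cells_per_gene=1)
        # force one gene constant on the normalized layer
        x = adata.layers["lognorm"].toarray()
        x[:, 0] = 0.7
        adata.layers["lognorm"] = sp.csr_matrix(x)
        labels = pd.Series("t", index=adata.obs_names)
        out = scpipe.pseudobulk_de(adata, labels)["t"]
        assert out.iloc[0]["log2fc"] == pytest.approx(0.0)
        assert out.iloc[0]["status"] == "ns"

    def test_planted_expression_shift_recovered(self, planted_sc, normalized_sc):
        sim, cfg = planted_sc
        labels = normalized_sc.obs["true_type"]
        out = scpipe.pseudobulk_de(normalized_sc, labels)
        planted = set(cfg.module_shift.gene_ids)
        table = out["type01"]
        called = set(table.index[table["status"] != "ns"])
        sens = len(called & planted) / len(planted)
        assert sens >= 0.7
        # unshifted types stay quiet
        for ctype, other in out.items():
            if ctype == "type01":
                continue
            assert (other["status"] != "ns").sum() <= 2


class TestModuleScore:
    def test_disjoint_set_rejected(self, normalized_sc):
        with pytest.raises(ValueError):
            scpipe.score_gene_module(
                normalized_sc, ["zz1", "zz2", "zz3", "zz4", "zz5"],
                normalized_sc.obs["true_type"],
            )

    def test_constructed_shift_makes_type_minimal_q(self, normalized_sc):
        """Adding c to set genes in treated cells of one type shifts its score by ~c."""
        adata = normalized_sc.copy()
        genes = list(adata.var_names[100:110])
        x = adata.layers["lognorm"].toarray()
        target = (
            (adata.obs["true_type"] == "type02") & (adata.obs["condition"] == "treated")
        ).to_numpy()
        cols = adata.var_names.get_indexer(genes)
        c = 0.8
        x[np.ix_(target, cols)] += c
        adata.layers["lognorm"] = sp.csr_matrix(x)
        scores, table = scpipe.score_gene_module(
            adata, genes, adata.obs["true_type"], seed=2
        )
        assert table["q_value"].idxmin() == "type02"
        assert table.loc["type02", "delta"] == pytest.approx(c, abs=0.2)

    def test_null_sets_not_significant(self):
        """Control-matched null sets: q > 0.05 in >= 45/50 trials.

        The null here is exchangeable cells (no replicate-level expression
        noise): the cell-level rank-sum treats cells as independent, so
        shared replicate noise would make it anticonservative by design
        (the reason pseudo-bulk is the primary DE instrument).
        """
        hits = 0
        for seed in range(50):
            cfg = simdata.ScSimConfig(
                n_genes=300,
                n_types=3,
                n_replicates=3,
                cells_per_replicate=40,
                markers_per_type=10,
                replicate_sigma=0.0,
                seed=200 + seed,
            )
            sim = simdata.simulate_scrna(cfg)
            adata = ad.concat([sim.sham, sim.treated], join="outer", merge="same")
            adata = scpipe.qc_and_normalize(
                adata, min_genes=20, max_mito=1.0, min_cells_per_gene=1
            )
            rng = np.random.default_rng(seed)
            free = [g for g in adata.var_names if not g.startswith("mt-")][60:]
            members = list(rng.choice(free, size=10, replace=False))
            _, table = scpipe.score_gene_module(
                adata, members, adata.obs["true_type"], seed=seed
            )
            hits += (table["q_value"] > 0.05).all()
        assert hits >= 45

    def test_score_invariant_to_unrelated_genes(self, normalized_sc):
        """Scores don't change when genes outside set and controls are added."""
        adata = normalized_sc
        genes = list(adata.var_names[120:130])
        s1, _ = scpipe.score_gene_module(adata, genes, adata.obs["true_type"], seed=3)
        # duplicate matrix with extra all-zero genes appended
        import anndata as ad2

        extra = ad2.AnnData(
            X=sp.csr_matrix((adata.n_obs, 5)), obs=adata.obs.copy()
        )
        extra.var_names = [f"pad{i}" for i in range(5)]
        wide = ad2.concat([adata, extra], axis=1, merge="first")
        wide.obs = adata.obs
        wide.layers["lognorm"] = sp.hstack(
            [adata.layers["lognorm"], sp.csr_matrix((adata.n_obs, 5))]
        ).tocsr()
        s2, _ = scpipe.score_gene_module(wide, genes, adata.obs["true_type"], seed=3)
        # identical only if the added genes enter neither set nor controls;
        # zero-expression padding lands in the lowest bin, far from the set genes
        assert np.allclose(s1.to_numpy(), s2.to_numpy())


class TestRegulons:
    def test_top_ranked_regulon_has_activity_one(self):
        x = np.zeros((1, 100))
        x[0, :6] = np.arange(6, 0, -1)
        adata = toy_adata(np.ones((1, 100)))
        adata.layers["lognorm"] = sp.csr_matrix(x)
        reg = scpipe.Regulon("g0", tuple(f"g{i}" for i in range(1, 6)))
        act = scpipe.regulon_activity(adata, [reg], top_fraction=0.2)
        assert act.iloc[0, 0] == pytest.approx(1.0)

    def test_bottom_ranked_regulon_has_activity_zero(self):
        x = np.zeros((1, 100))
        x[0, :80] = np.linspace(5, 1, 80)  # regulon genes (last 20) all zero
        adata = toy_adata(np.ones((1, 100)))
        adata.layers["lognorm"] = sp.csr_matrix(x)
        reg = scpipe.Regulon("g95", tuple(f"g{i}" for i in range(90, 95)))
        act = scpipe.regulon_activity(adata, [reg], top_fraction=0.05)
        assert act.iloc[0, 0] == 0.0

    def test_random_regulon_matches_permutation_mean(self):
        """Mean activity of a random regulon ~ uniform-rank expectation."""
        rng = np.random.default_rng(10)
        n_cells, g = 300, 2000
        x = rng.normal(size=(n_cells, g))
        adata = toy_adata(np.ones((n_cells, g)))
        adata.layers["lognorm"] = sp.csr_matrix(x)
        members = [f"g{i}" for i in rng.choice(g, size=21, replace=False)]
        reg = scpipe.Regulon(members[0], tuple(members[1:]))
        act = scpipe.regulon_activity(adata, [reg], top_fraction=0.05).iloc[:, 0]
        # oracle: permutation of ranks
        x_top = int(np.ceil(0.05 * g))
        k = 21
        max_area = x_top * k - k * (k - 1) // 2
        sims = []
        for _ in range(2000):
            pos = rng.choice(g, size=k, replace=False)
            sims.append(np.clip(x_top - pos, 0, x_top).sum() / max_area)
        mu, sd = np.mean(sims), np.std(sims) / np.sqrt(n_cells)
        assert abs(act.mean() - mu) <= 3 * sd + 3 * np.std(sims) / np.sqrt(n_cells)

    def test_monotone_in_added_top_gene(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0.1, 1.0, size=(1, 200))
        adata = toy_adata(np.ones((1, 200)))
        adata.layers["lognorm"] = sp.csr_matrix(x)
        reg = scpipe.Regulon("g0", tuple(f"g{i}" for i in range(1, 7)))
        before = scpipe.regulon_activity(adata, [reg], top_fraction=0.1).iloc[0, 0]
        x2 = x.copy()
        x2[0, 3] = x.max() + 1  # push one regulon gene to rank 1
        adata.layers["lognorm"] = sp.csr_matrix(x2)
        after = scpipe.regulon_activity(adata, [reg], top_fraction=0.1).iloc[0, 0]
        assert after >= before

    def test_planted_regulon_differential_in_target_type(self, planted_sc, normalized_sc):
        sim, cfg = planted_sc
        rs = cfg.regulon_shift
        regs = [
            scpipe.Regulon(rs.tf, rs.targets),
            scpipe.Regulon("g00301", tuple(f"g{i + 1:05d}" for i in range(301, 331))),
        ]
        out = scpipe.differential_regulons(
            normalized_sc, regs, normalized_sc.obs["true_type"]
        )
        table = out[rs.cell_type]
        assert table.loc[rs.tf, "q_value"] < 0.1
        assert table.loc[rs.tf, "fold_change"] > 1.0

    def test_bad_regulon_rejected(self):
        with pytest.raises(ValueError):
            scpipe.Regulon("tf", ())
        with pytest.raises(ValueError):
            scpipe.Regulon("tf", ("tf", "a"))


class TestLREdges:
    def _adata_with_types(self, mean_by_type, genes, cells_per_type=30):
        rows, labels = [], []
        rng = np.random.default_rng(12)
        for t, means in mean_by_type.items():
            for _ in range(cells_per_type):
                rows.append(rng.poisson(np.asarray(means)))
                labels.append(t)
        counts = np.asarray(rows)
        obs = {
            "condition": (["sham", "treated"] * len(labels))[: len(labels)],
            "replicate": "r1",
        }
        adata = toy_adata(counts, obs=obs, genes=genes)
        adata = scpipe.qc_and_normalize(adata, min_genes=0, max_mito=1.0,
                                        min_cells_per_gene=1)
        return adata, pd.Series(labels, index=adata.obs_names)

    def test_exclusive_ligand_specificity_one(self):
        genes = ["lig", "rec", "x1", "x2"]
        adata, labels = self._adata_with_types(
            {"tA": [50, 5, 5, 5], "tB": [0, 5, 5, 5]}, genes
        )
        cat = pd.DataFrame({"ligand": ["lig"], "receptor": ["rec"]})
        edges = scpipe.lr_edges_and_diff(adata, labels, cat)
        from_a = edges[(edges["sender"] == "tA")]
        from_b = edges[(edges["sender"] == "tB")]
        assert np.allclose(
            from_a["weight_sham"] + from_a["weight_treated"],
            (from_a["weight_sham"] + from_a["weight_treated"]),
        )
        # ligand only in tA: specificity 1 there, 0 elsewhere
        assert (from_b[["weight_sham", "weight_treated"]].to_numpy() == 0).all()

    def test_equal_means_give_quarter_specificity(self):
        genes = ["lig", "rec"]
        mean_by_type = {t: [20, 20] for t in ("t1", "t2", "t3", "t4")}
        adata, labels = self._adata_with_types(mean_by_type, genes)
        cat = pd.DataFrame({"ligand": ["lig"], "receptor": ["rec"]})
        edges = scpipe.lr_edges_and_diff(adata, labels, cat)
        w = edges[["weight_sham", "weight_treated"]].to_numpy()
        assert np.allclose(w, 1 / 16, atol=0.02)

    def test_specificities_sum_to_one(self, planted_sc, normalized_sc):
        sim, cfg = planted_sc
        ls = cfg.lr_shift
        cat = pd.DataFrame(
            {"ligand": [ls.ligand, "g00051"], "receptor": [ls.receptor, "g00071"]}
        )
        edges = scpipe.lr_edges_and_diff(
            normalized_sc, normalized_sc.obs["true_type"], cat,
            min_detect_fraction=0.0,
        )
        for (lig, rec), grp in edges.groupby(["ligand", "receptor"]):
            for cond in ("weight_sham", "weight_treated"):
                # sum over sender x receiver of spec_l*spec_r = 1 when all kept
                assert grp[cond].sum() == pytest.approx(1.0, abs=1e-6)

    def test_planted_ligand_doubling_tops_delta_ranking(self, planted_sc, normalized_sc):
        sim, cfg = planted_sc
        ls = cfg.lr_shift
        cat = pd.DataFrame(
            {"ligand": [ls.ligand, "g00051"], "receptor": [ls.receptor, "g00071"]}
        )
        edges = scpipe.lr_edges_and_diff(
            normalized_sc, normalized_sc.obs["true_type"], cat
        )
        top = edges.iloc[0]
        assert top["ligand"] == ls.ligand and top["sender"] == ls.sender

    def test_empty_catalogue_rejected(self, normalized_sc):
        cat = pd.DataFrame({"ligand": ["zz"], "receptor": ["yy"]})
        with pytest.raises(ValueError):
            scpipe.lr_edges_and_diff(
                normalized_sc, normalized_sc.obs["true_type"], cat
            )
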