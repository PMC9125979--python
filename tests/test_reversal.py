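"""GSEA enrichment scores, the permutation null, dNES scoring and drug
clustering, including an exhaustive-null oracle on tiny rankings."""

import itertools

import numpy as np
import pandas as pd
import pytest

from moltax import reversal
from moltax.reversal import (
    DeltaNESKMeans,
    GeneSetPair,
    RankedList,
    delta_nes,
    enrichment_score,
    gsea_preranked,
    kmeans_elbow,
    make_ranked_list,
    score_matrix,
    signature_to_gene_sets,
    top_drugs_for_group,
)


def _ranked(scores, genes=None):
    genes = genes or [f"g{i + 1}" for i in range(len(scores))]
    return RankedList(
        genes=np.asarray(genes, dtype=object), scores=np.asarray(scores, float)
    )


def _sig(genes, log2fc, pvalue, sig_id="d1"):
    return pd.DataFrame(
        {"signature_id": sig_id, "gene": genes, "log2fc": log2fc, "pvalue": pvalue}
    )


class TestSignatureToGeneSets:
    def test_top_300_of_500_significant(self, rng):
        n = 500
        sig = _sig(
            [f"g{i}" for i in range(n)],
            rng.normal(0, 2, n),
            rng.uniform(0, 0.04, n),
        )
        pair = signature_to_gene_sets(sig, top_n=300)
        assert len(pair.up) + len(pair.down) == 300

    def test_few_significant_all_kept(self, rng):
        sig = _sig(
            [f"g{i}" for i in range(20)],
            rng.normal(0, 2, 20),
            [0.01] * 10 + [0.5] * 10,
        )
        pair = signature_to_gene_sets(sig, top_n=300)
        assert len(pair.up) + len(pair.down) == 10

    def test_sort_and_split_by_hand(self):
        sig = _sig(
            ["r1", "r2", "r3", "r4", "r5"],
            [5.0, -4.0, 3.0, -2.0, 1.0],
            [0.01] * 5,
        )
        pair = signature_to_gene_sets(sig, top_n=3)
        assert pair.up == ["r1", "r3"]
        assert pair.down == ["r2"]

    def test_zero_log2fc_discarded_and_empty_warns(self):
        sig = _sig(["a", "b"], [0.0, 0.0], [0.001, 0.001])
        with pytest.warns(UserWarning, match="no significant"):
            pair = signature_to_gene_sets(sig)
        assert not pair.usable


class TestEnrichmentScore:
    def test_hand_value_middle_gene(self):
        assert enrichment_score(_ranked([3, 2, 1, -1, -2]), {"g2"}) == pytest.approx(
            0.75
        )

    def test_hand_value_bottom_gene(self):
        assert enrichment_score(_ranked([3, 2, 1, -1, -2]), {"g5"}) == pytest.approx(
            -1.0
        )

    def test_top_gene_scores_one(self, rng):
        scores = np.sort(rng.normal(0, 2, 12))[::-1]
        assert enrichment_score(_ranked(scores), {"g1"}) == pytest.approx(1.0)

    def test_bounds_and_top_block_equality(self, rng):
        """|ES| <= 1 always; ES = 1 exactly when the set fills the top
        ranks with positive scores."""
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            k = int(rng.integers(1, n - 1))
            members = list(rng.choice(n, size=k, replace=False))
            genes = [f"g{i + 1}" for i in members]
            es = enrichment_score(_ranked(scores), genes)
            assert -1.0 <= es <= 1.0 + 1e-12
            if scores[k - 1] > 0 and sorted(members) == list(range(k)):
                assert es == pytest.approx(1.0)

    def test_degenerate_sets_rejected(self):
        ranked = _ranked([2, 1, -1])
        with pytest.raises(ValueError, match="no genes"):
            enrichment_score(ranked, {"zz"})
        with pytest.raises(ValueError, match="whole"):
            enrichment_score(ranked, {"g1", "g2", "g3"})


class TestPermutationOracle:
    @pytest.mark.parametrize("n,k", [(6, 2), (8, 3), (7, 1)])
    def test_exhaustive_null_matches_monte_carlo(self, n, k, rng):
        """NES and p from the exhaustive null of all C(N,k) sets agree with
        the Monte-Carlo estimates within 3 standard errors."""
        scores = np.sort(rng.normal(0, 1.5, n))[::-1]
        ranked = _ranked(scores)
        gene_set = [f"g{i + 1}" for i in rng.choice(n, size=k, replace=False)]
        es = enrichment_score(ranked, gene_set)

        null = np.array(
            [
                enrichment_score(ranked, [f"g{i + 1}" for i in combo])
                for combo in itertools.combinations(range(n), k)
            ]
        )
        same = null >= 0 if es >= 0 else null < 0
        exact_nes = es / np.abs(null[same]).mean()
        exact_p = (np.abs(null[same]) >= abs(es)).mean()

        n_perm = 10000
        res = gsea_preranked(ranked, gene_set, n_perm=n_perm, seed=123)

        p_frac = same.mean()  # chance a draw lands in the same-sign tail
        se_p = np.sqrt(exact_p * (1 - exact_p) / (n_perm * p_frac)) + 1.0 / n_perm
        assert res.pvalue == pytest.approx(exact_p, abs=max(3 * se_p, 1e-3))

        denom = np.abs(null[same])
        se_mean = denom.std(ddof=1) / np.sqrt(n_perm * p_frac) if len(denom) > 1 else 0
        se_nes = abs(exact_nes) * se_mean / denom.mean() + 1e-9
        assert res.nes == pytest.approx(exact_nes, abs=max(3 * se_nes, 1e-3))


class TestDeltaNES:
    def test_identical_sides_cancel_exactly(self):
        ranked = _ranked(np.linspace(3, -3, 10))
        pair = GeneSetPair("d", up=["g2", "g5"], down=["g2", "g5"])
        res = delta_nes(ranked, pair, n_perm=200, seed=11)
        assert res["delta_nes"] == 0.0

    def test_missing_side_contributes_zero(self):
        ranked = _ranked(np.linspace(3, -3, 10))
        pair = GeneSetPair("d", up=[], down=["g1", "g2"])
        res = delta_nes(ranked, pair, n_perm=200, seed=1)
        assert res["nes_up"] == 0.0
        assert "up:missing" in res["flags"]
        assert res["delta_nes"] == res["nes_down"]

    def test_both_sides_unusable_rejected(self):
        ranked = _ranked([1, -1, 2])
        with pytest.raises(ValueError, match="no usable"):
            delta_nes(ranked, GeneSetPair("d", up=[], down=[]), seed=0)

    def test_sign_antisymmetry(self):
        """Negating the ranking and swapping up/down leaves delta unchanged
        (shared seeds; same-size sides make the null identical)."""
        scores = np.linspace(4, -4, 12)
        genes = [f"g{i + 1}" for i in range(12)]
        pair = GeneSetPair("d", up=["g1", "g3"], down=["g10", "g12"])
        fwd = delta_nes(_ranked(scores, genes), pair, n_perm=500, seed=5)
        flipped = make_ranked_list(pd.Series(-scores, index=genes))
        swapped = GeneSetPair("d", up=pair.down, down=pair.up)
        rev = delta_nes(flipped, swapped, n_perm=500, seed=5)
        assert rev["delta_nes"] == pytest.approx(fwd["delta_nes"], abs=0.3)


class TestScoreMatrix:
    def _library(self, n_drugs, genes, rng):
        pairs = []
        for d in range(n_drugs):
            picks = rng.choice(genes, size=6, replace=False)
            pairs.append(
                GeneSetPair(f"d{d + 1:02d}", up=list(picks[:3]), down=list(picks[3:]))
            )
        return pairs

    def test_cross_product_rows(self, rng):
        genes = [f"g{i}" for i in range(40)]
        rankings = {
            f"G{j + 1}": _ranked(np.sort(rng.normal(size=40))[::-1], genes)
            for j in range(5)
        }
        lib = self._library(10, genes, rng)
        mat = score_matrix(rankings, lib, n_perm=100, seed=0)
        assert len(mat) == 50

    def test_library_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(30)]
        rankings = {"G1": _ranked(np.sort(rng.normal(size=30))[::-1], genes)}
        lib = self._library(5, genes, rng)
        a = score_matrix(rankings, lib, n_perm=100, seed=7)
        b = score_matrix(rankings, lib[::-1], n_perm=100, seed=7)
        merged = a.merge(b, on=["signature_id", "endotype"], suffixes=("_a", "_b"))
        assert np.allclose(merged.delta_nes_a, merged.delta_nes_b)


class TestKmeansElbow:
    def _matrix_from_values(self, values):
        return pd.DataFrame(
            {
                "signature_id": [f"d{i:02d}" for i in range(len(values))],
                "endotype": "G1",
                "delta_nes": values,
            }
        )

    def test_three_tight_triplets(self):
        vals = [0, 0.1, 0.2, 10, 10.1, 10.2, 20, 20.1, 20.2]
        labels, k, wss = kmeans_elbow(self._matrix_from_values(vals), k_range=range(1, 6))
        assert k == 3
        # second difference of the hand-computed WSS curve peaks at k=3
        assert wss[3] == pytest.approx(0.02 * 3, abs=1e-9)

    def test_identical_rows_degenerate(self):
        labels, k, wss = kmeans_elbow(
            self._matrix_from_values([1.0] * 6), k_range=range(1, 4)
        )
        assert k == 1
        assert wss[1] == pytest.approx(0.0, abs=1e-12)

    def test_label_stability_across_master_seeds(self):
        from sklearn.metrics import adjusted_rand_score

        vals = [0, 0.1, 0.2, 10, 10.1, 10.2, 20, 20.1, 20.2]
        out = []
        for seed in (1, 2):
            labels, k, _ = kmeans_elbow(
                self._matrix_from_values(vals), k_range=range(1, 6), seed=seed
            )
            out.append(labels)
        assert adjusted_rand_score(out[0], out[1]) == 1.0

    def test_missing_cells_excluded_with_warning(self):
        mat = self._matrix_from_values([0.0, 1.0, 2.0, np.nan])
        with pytest.warns(UserWarning, match="excluding"):
            labels, _, _ = kmeans_elbow(mat, k_range=range(1, 3))
        assert "d03" not in labels.index


class TestTopDrugs:
    def test_clamps_to_cluster_size(self):
        mat = pd.DataFrame(
            {
                "signature_id": [f"d{i}" for i in range(5)],
                "endotype": "G1",
                "delta_nes": [3.0, 2.5, 2.0, 1.5, 1.0],
            }
        )
        clusters = pd.Series(0, index=[f"d{i}" for i in range(5)])
        top = top_drugs_for_group(mat, clusters, "G1", n_top=50)
        assert len(top) == 5
        assert top.signature_id.tolist() == [f"d{i}" for i in range(5)]

    def test_absent_endotype_rejected(self):
        mat = pd.DataFrame(
            {"signature_id": ["d1"], "endotype": ["G1"], "delta_nes": [1.0]}
        )
        with pytest.raises(ValueError, match="G9"):
            top_drugs_for_group(mat, pd.Series(0, index=["d1"]), "G9")


class TestReverserRecovery:
    def test_noiseless_reverser_ranks_first(self, small_cohort):
        """An exact anti-signature tops its endotype's dNES column."""
        from moltax import diffexp, synthetic

        meta = small_cohort.sample_meta.set_index("sample_id")
        sigs = {
            e: diffexp.de_test(
                small_cohort.counts,
                meta.index[meta.true_endotype == e].tolist(),
                small_cohort.controls,
            )
            for e in ("E1", "E2")
        }
        lib = synthetic.generate_drug_library(
            synthetic.DrugLibrarySpec(
                n_drugs=8, n_reversers_per_endotype=1, noise_sd=0.0, seed=4
            ),
            sigs,
        )
        rankings = {e: make_ranked_list(s["wald"]) for e, s in sigs.items()}
        pairs = [
            signature_to_gene_sets(grp)
            for _, grp in lib.signatures.groupby("signature_id", sort=True)
        ]
        mat = score_matrix(rankings, pairs, n_perm=300, seed=4)
        for endo in rankings:
            best = (
                mat[mat.endotype == endo]
                .sort_values(["delta_nes", "signature_id"], ascending=[False, True])
                .signature_id.iloc[0]
            )
            assert lib.truth[best] == endo

    def test_delta_nes_monotone_in_reversal_effect(self, small_cohort):
        """Stronger planted reversal never weakens the reverser's dNES."""
        from moltax import diffexp, synthetic

        meta = small_cohort.sample_meta.set_index("sample_id")
        sig = {
            "E1": diffexp.de_test(
                small_cohort.counts,
                meta.index[meta.true_endotype == "E1"].tolist(),
                small_cohort.controls,
            )
        }
        ranking = {"E1": make_ranked_list(sig["E1"]["wald"])}
        deltas = []
        for effect in (0.5, 1.5, 3.0):
            lib = synthetic.generate_drug_library(
                synthetic.DrugLibrarySpec(
                    n_drugs=2,
                    n_reversers_per_endotype=1,
                    reversal_effect=effect,
                    noise_sd=0.3,
                    seed=9,
                ),
                sig,
            )
            rev = next(s for s, t in lib.truth.items() if t == "E1")
            pair = signature_to_gene_sets(
                lib.signatures[lib.signatures.signature_id == rev]
            )
            deltas.append(
                delta_nes(ranking["E1"], pair, n_perm=300, seed=2)["delta_nes"]
            )
        assert deltas[0] <= deltas[1] + 1e-9 <= deltas[2] + 2e-9
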