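import numpy as np
import pytest

import hergsuite as hs
from hergsuite.records_io import ActivityRecord
from oracles import pairwise_tanimoto_mean, tanimoto


def activity_records(triples):
    """(smiles, assay, pic50) -> records with a consistent molar value."""
    return [
        ActivityRecord(f"C{i}", smi, assay, "eq", 10.0 ** (-p), "M")
        for i, (smi, assay, p) in enumerate(triples)
    ]


class TestAssayCorrelation:
    def test_perfect_linear(self):
        recs = []
        for i, p in enumerate([4.0, 5.0, 6.0, 7.0, 8.0]):
            recs += activity_records([(f"{'C' * (i + 1)}O", "SP", p),
                                      (f"{'C' * (i + 1)}O", "HEK", 2 + p)])
        out = hs.assay_correlation(recs)
        r, p_val, n = out[("HEK", "SP")]
        assert r == pytest.approx(1.0)
        assert p_val < 0.001
        assert n == 5

    def test_hand_computed_cases(self):
        def corr(ys):
            recs = []
            for i, (x, y) in enumerate(zip([4.0, 5.0, 6.0], ys)):
                smi = "C" * (i + 1) + "O"
                recs += activity_records([(smi, "SP", x), (smi, "HEK", y)])
            return hs.assay_correlation(recs)[("HEK", "SP")][0]

        assert corr([8.0, 6.0, 4.0]) == pytest.approx(-1.0)
        assert corr([4.0, 6.0, 5.0]) == pytest.approx(0.5)

    def test_too_few_shared_compounds(self):
        recs = activity_records([("CCO", "SP", 5.0), ("CCO", "HEK", 5.0)])
        with pytest.raises(ValueError):
            hs.assay_correlation(recs)


class TestCrossSetTanimoto:
    def test_single_molecule_distinct_sets(self):
        fp = hs.fingerprint("c1ccccc1CCN", hs.FingerprintSpec())
        assert hs.cross_set_tanimoto([fp], [fp]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = np.zeros((2, 16)); a[:, :4] = 1
        b = np.zeros((3, 16)); b[:, 8:] = 1
        assert hs.cross_set_tanimoto(a, b) == 0.0

    def test_matches_double_loop_oracle(self):
        smiles_a = ["CCO", "CCN", "c1ccccc1O"]
        smiles_b = ["CCCl", "c1ccncc1"]
        A = hs.featurize_dataset(smiles_a, hs.FingerprintSpec()).bits
        B = hs.featurize_dataset(smiles_b, hs.FingerprintSpec()).bits
        assert hs.cross_set_tanimoto(A, B) == pytest.approx(
            pairwise_tanimoto_mean(A, B), abs=1e-12)

    def test_same_set_excludes_self_pairs(self):
        A = hs.featurize_dataset(["CCO", "CCN", "CCCO"], hs.FingerprintSpec()).bits
        assert hs.cross_set_tanimoto(A, A, same_set=True) == pytest.approx(
            pairwise_tanimoto_mean(A, A, exclude_self=True), abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            hs.cross_set_tanimoto(np.zeros((0, 8)), np.ones((2, 8)))


def small_dataset(pic50s, library=None):
    """Build a curated regression dataset directly from (smiles, pic50)."""
    from hergsuite.curation import (CurationConfig, CurationReport,
                                    CuratedCompound, CuratedDataset)
    library = library or hs.make_library(len(pic50s), seed=9)
    compounds = [CuratedCompound(smiles=s, pic50=p, label=p)
                 for s, p in zip(library, pic50s)]
    return CuratedDataset(compounds=compounds, task="regression",
                          report=CurationReport(), config=CurationConfig(task="regression"))


class TestFindCliffs:
    def test_opposing_pair_reported_and_identical_not(self):
        ds = small_dataset([7.0, 4.0], library=["CCCCCCCCO", "CCCCCCCCN"])
        spec = hs.FingerprintSpec(family="maccs")
        sims = hs.cross_set_tanimoto(
            hs.featurize_dataset(ds, spec).bits[:1],
            hs.featurize_dataset(ds, spec).bits[1:])
        cliffs = hs.find_cliffs(ds, spec, similarity_cutoff=min(0.8, sims - 1e-9))
        assert len(cliffs) == 1
        assert cliffs[0].potency_gap == pytest.approx(3.0)
        same = small_dataset([6.0, 6.0], library=["CCO", "CCO"])
        assert hs.find_cliffs(same, spec) == []

    def test_matches_bruteforce_pair_enumeration(self):
        rng = np.random.RandomState(5)
        library = hs.make_library(20, seed=5)
        pic50s = rng.uniform(3.5, 8.0, 20)
        ds = small_dataset(list(pic50s), library=library)
        spec = hs.FingerprintSpec(family="maccs")
        cutoff, gap = 0.5, 1.0
        got = {(c.smiles_a, c.smiles_b) for c in
               hs.find_cliffs(ds, spec, similarity_cutoff=cutoff,
                              potency_gap_min=gap)}
        fps = hs.featurize_dataset(ds, spec).bits
        want = set()
        for i in range(20):
            for j in range(i + 1, 20):
                sim = tanimoto(fps[i], fps[j])
                opposing = (pic50s[i] > 5.0) != (pic50s[j] > 5.0)
                if sim >= cutoff and (opposing or abs(pic50s[i] - pic50s[j]) >= gap):
                    want.add((library[i], library[j]))
        assert got == want


class TestContinuityDiscontinuity:
    def test_identical_potencies_have_zero_discontinuity(self):
        ds = small_dataset([6.0, 6.0, 6.0])
        _, disc, _, g_disc = hs.continuity_discontinuity(
            ds, hs.FingerprintSpec(family="maccs"), cutoff=0.0)
        assert np.nanmax(disc) == 0.0 and g_disc == 0.0

    def test_single_pair_hand_value(self):
        # two compounds, similarity s, |delta pIC50| = 3 -> disc = 3 * s
        ds = small_dataset([7.5, 4.5], library=["CCCCCCCCO", "CCCCCCCCN"])
        spec = hs.FingerprintSpec(family="maccs")
        fps = hs.featurize_dataset(ds, spec).bits
        s = tanimoto(fps[0], fps[1])
        _, disc, _, g_disc = hs.continuity_discontinuity(ds, spec, cutoff=s - 1e-9)
        assert g_disc == pytest.approx(3.0 * s)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.RandomState(8)
        library = hs.make_library(15, seed=8)
        pic50s = rng.uniform(4.0, 8.0, 15)
        ds = small_dataset(list(pic50s), library=library)
        spec = hs.FingerprintSpec(family="maccs")
        cutoff = 0.4
        cont, disc, _, _ = hs.continuity_discontinuity(ds, spec, cutoff=cutoff)
        fps = hs.featurize_dataset(ds, spec).bits
        for i in range(15):
            num = den = 0.0
            near = []
            for j in range(15):
                if j == i:
                    continue
                s = tanimoto(fps[i], fps[j])
                w = pic50s[i] * pic50s[j]
                if s > 0:
                    num += w / s
                    den += w
                if s >= cutoff:
                    near.append(abs(pic50s[i] - pic50s[j]) * s)
            if den > 0:
                assert cont[i] == pytest.approx(num / den, abs=1e-9)
            if near:
                assert disc[i] == pytest.approx(np.mean(near), abs=1e-9)

    def test_no_qualifying_pair_rejected(self):
        ds = small_dataset([4.0, 8.0], library=["CCCCCCCC", "c1ccncc1O"])
        with pytest.raises(ValueError):
            hs.continuity_discontinuity(ds, hs.FingerprintSpec(family="maccs"),
                                        cutoff=0.999)


class TestEmbed2D:
    def test_deterministic_and_shape(self):
        rng = np.random.RandomState(2)
        X = rng.randint(0, 2, (30, 64)).astype(float)
        c1 = hs.embed_2d(X, seed=11)
        c2 = hs.embed_2d(X, seed=11)
        assert c1.shape == (30, 2)
        assert np.array_equal(c1, c2)

    def test_separated_bit_clusters_stay_separated(self):
        X = np.zeros((40, 64))
        X[:20, :8] = 1
        X[20:, 56:] = 1
        rng = np.random.RandomState(0)
        X += 0.0  # binary clusters, no jitter needed
        coords = hs.embed_2d(X, seed=0, perplexity=10)
        a, b = coords[:20], coords[20:]
        intra = (np.linalg.norm(a - a.mean(0), axis=1).mean()
                 + np.linalg.norm(b - b.mean(0), axis=1).mean()) / 2
        inter = np.linalg.norm(a.mean(0) - b.mean(0))
        assert inter > intra

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            hs.embed_2d(np.eye(4), seed=0)
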