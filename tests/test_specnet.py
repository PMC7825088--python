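"""Spectral normalization, modified cosine, molecular networking."""

import numpy as np
import pytest

from npomics.specnet import (Spectrum, annotation_rate, build_network,
                             library_match, modified_cosine, normalize)
from oracles import exhaustive_modified_cosine


def spec(sid, mz, inten, precursor=500.0):
    return Spectrum(id=sid, precursor_mz=precursor, charge=1,
                    mz=np.asarray(mz, float), intensity=np.asarray(inten,
                                                                   float))


class TestNormalize:
    def test_single_peak_unit_intensity(self):
        s = normalize(spec("s", [100.0], [100.0]))
        assert s.intensity[0] == pytest.approx(1.0)

    def test_sqrt_then_unit_norm(self):
        s = normalize(spec("s", [100.0, 200.0], [4.0, 4.0]))
        assert np.allclose(s.intensity, [np.sqrt(0.5)] * 2)

    def test_idempotent_on_normalized(self):
        s = normalize(spec("s", [100.0, 200.0, 300.0], [1.0, 5.0, 2.0]))
        again = normalize(Spectrum(id=s.id, precursor_mz=s.precursor_mz,
                                   charge=1, mz=s.mz,
                                   intensity=s.intensity ** 2))
        assert np.allclose(again.intensity, s.intensity, atol=1e-12)

    def test_all_zero_intensities_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize(spec("s", [100.0], [0.0]))

    def test_empty_peak_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            spec("s", [], [])


class TestModifiedCosine:
    def test_identical_spectra_score_one(self):
        s = normalize(spec("a", [100.0, 150.0, 200.0], [1.0, 2.0, 3.0]))
        score, matched = modified_cosine(s, s, 0.02)
        assert score == pytest.approx(1.0)
        assert matched == 3

    def test_no_pairs_within_tolerance(self):
        a = normalize(spec("a", [100.0, 200.0], [1.0, 1.0], precursor=500))
        b = normalize(spec("b", [130.0, 260.0], [1.0, 1.0], precursor=500))
        assert modified_cosine(a, b, 0.02) == (0.0, 0)

    def test_precursor_shifted_peaks_match(self):
        # b is a shifted by +14 Da (precursor and fragments)
        a = normalize(spec("a", [100.0, 150.0, 200.0, 250.0], [1, 2, 3, 4],
                           precursor=500.0))
        b = normalize(spec("b", [114.0, 164.0, 214.0, 264.0], [1, 2, 3, 4],
                           precursor=514.0))
        score, matched = modified_cosine(a, b, 0.02)
        assert score == pytest.approx(1.0)
        assert matched == 4

    def test_symmetric_under_argument_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n1, n2 = rng.integers(3, 8, size=2)
            a = normalize(spec("a", np.sort(rng.uniform(100, 400, n1)),
                               rng.uniform(1, 10, n1),
                               precursor=rng.uniform(400, 600)))
            b = normalize(spec("b", np.sort(rng.uniform(100, 400, n2)),
                               rng.uniform(1, 10, n2),
                               precursor=rng.uniform(400, 600)))
            s_ab, m_ab = modified_cosine(a, b, 0.05)
            s_ba, m_ba = modified_cosine(b, a, 0.05)
            assert s_ab == pytest.approx(s_ba, abs=1e-12)
            assert m_ab == m_ba

    def test_greedy_equals_exhaustive_on_realistic_fixtures(self):
        # 200 small spectra pairs in the high-resolution regime: jittered
        # shared fragment pools, 0.02 Da tolerance
        rng = np.random.default_rng(1)
        for _ in range(200):
            n1, n2 = rng.integers(2, 7, size=2)
            pool = rng.uniform(100, 500, 6)
            a = normalize(spec(
                "a", rng.choice(pool, n1, False) + rng.normal(0, 0.005, n1),
                rng.uniform(1, 10, n1), precursor=400 + rng.uniform(-3, 3)))
            b = normalize(spec(
                "b", rng.choice(pool, n2, False) + rng.normal(0, 0.005, n2),
                rng.uniform(1, 10, n2), precursor=400 + rng.uniform(-3, 3)))
            greedy, _ = modified_cosine(a, b, 0.02)
            exact = exhaustive_modified_cosine(a, b, 0.02)
            assert greedy == pytest.approx(exact, abs=1e-12)

    def test_greedy_never_exceeds_exhaustive_on_dense_fixtures(self):
        # adversarial regime (every peak near every peak): greedy is a
        # lower bound on the optimal matching
        rng = np.random.default_rng(2)
        for _ in range(50):
            n1, n2 = rng.integers(2, 6, size=2)
            a = normalize(spec("a", rng.uniform(100, 101, n1),
                               rng.uniform(1, 10, n1),
                               precursor=400 + rng.uniform(-1, 1)))
            b = normalize(spec("b", rng.uniform(100, 101, n2),
                               rng.uniform(1, 10, n2),
                               precursor=400 + rng.uniform(-1, 1)))
            greedy, _ = modified_cosine(a, b, 0.2)
            exact = exhaustive_modified_cosine(a, b, 0.2)
            assert greedy <= exact + 1e-12

    def test_wider_tolerance_never_lowers_exhaustive_score(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n1, n2 = rng.integers(2, 6, size=2)
            a = normalize(spec("a", rng.uniform(100, 110, n1),
                               rng.uniform(1, 10, n1)))
            b = normalize(spec("b", rng.uniform(100, 110, n2),
                               rng.uniform(1, 10, n2)))
            s1 = exhaustive_modified_cosine(a, b, 0.01)
            s2 = exhaustive_modified_cosine(a, b, 0.1)
            assert s2 >= s1 - 1e-12

    def test_agrees_with_matchms_reference(self):
        matchms = pytest.importorskip("matchms")
        from matchms import Spectrum as MSpectrum
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(4)
        sim = ModifiedCosine(tolerance=0.02)
        for _ in range(30):
            n1, n2 = rng.integers(4, 9, size=2)
            pool = np.sort(rng.uniform(100, 500, 8))
            mza = np.sort(rng.choice(pool, n1, False)
                          + rng.normal(0, 0.003, n1))
            mzb = np.sort(rng.choice(pool, n2, False)
                          + rng.normal(0, 0.003, n2))
            ia, ib = rng.uniform(1, 10, n1), rng.uniform(1, 10, n2)
            pa, pb = rng.uniform(400, 600, 2)
            ours, _ = modified_cosine(normalize(spec("a", mza, ia, pa)),
                                      normalize(spec("b", mzb, ib, pb)),
                                      0.02)
            # matchms scores raw intensities; feed it the sqrt-transformed
            # values so both sides compute the same statistic
            ma = MSpectrum(mz=mza, intensities=np.sqrt(ia),
                           metadata={"precursor_mz": pa},
                           metadata_harmonization=False)
            mb = MSpectrum(mz=mzb, intensities=np.sqrt(ib),
                           metadata={"precursor_mz": pb},
                           metadata_harmonization=False)
            theirs = float(sim.pair(ma, mb)["score"])
            assert ours == pytest.approx(theirs, abs=1e-6)


class TestBuildNetwork:
    def test_identical_spectra_single_family(self):
        base = spec("x", [100.0, 150.0, 200.0, 250.0, 300.0],
                    [5, 4, 3, 2, 1])
        spectra = [Spectrum(id=f"s{i}", precursor_mz=500.0, charge=1,
                            mz=base.mz, intensity=base.intensity)
                   for i in range(4)]
        net = build_network(spectra)
        assert len(net.families) == 1
        assert sorted(next(iter(net.families.values()))) == \
            ["s0", "s1", "s2", "s3"]

    def test_dissimilar_spectra_all_singletons(self):
        rng = np.random.default_rng(5)
        spectra = [spec(f"s{i}", np.sort(rng.uniform(100 + 50 * i,
                                                     120 + 50 * i, 5)),
                        rng.uniform(1, 10, 5)) for i in range(4)]
        net = build_network(spectra)
        assert net.edges == []
        assert net.families == {}
        assert len(net.singletons) == 4

    def test_raising_cosine_min_never_adds_edges(self, small_dataset):
        spectra = small_dataset.spectra[:30]
        counts = [len(build_network(spectra, cosine_min=c).edges)
                  for c in (0.5, 0.7, 0.9)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_planted_families_recovered(self, small_dataset):
        from sklearn.metrics import adjusted_rand_score
        ds = small_dataset
        net = build_network(ds.spectra)
        label = {}
        for fid, members in net.families.items():
            for m in members:
                label[m] = fid
        for s in net.singletons:
            label[s] = s
        ids = [s.id for s in ds.spectra]
        ari = adjusted_rand_score([ds.truth_spectrum[i] for i in ids],
                                  [label[i] for i in ids])
        assert ari >= 0.9


class TestLibraryMatch:
    def test_identical_library_entry_scores_one(self):
        q = spec("query", [100.0, 150.0, 200.0, 250.0], [1, 2, 3, 4])
        lib = [spec("ref1", [100.0, 150.0, 200.0, 250.0], [1, 2, 3, 4]),
               spec("ref2", [300.0, 350.0, 420.0, 480.0], [1, 1, 1, 1])]
        ann = library_match([q], lib)
        assert ann["query"].library_id == "ref1"
        assert ann["query"].score == pytest.approx(1.0)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            library_match([spec("q", [100.0], [1.0])], [])

    def test_annotation_rate_arithmetic(self):
        from npomics.specnet import Annotation, MolecularNetwork
        nodes = [f"n{i}" for i in range(1442)]
        net = MolecularNetwork(
            nodes=nodes, edges=[], families={}, singletons=[],
            annotations={f"n{i}": Annotation("lib", 1.0, 5)
                         for i in range(68)})
        annotated, total, rate = annotation_rate(net)
        assert (annotated, total) == (68, 1442)
        assert round(100 * rate, 1) == 4.7

    def test_no_annotations_rate_zero(self):
        from npomics.specnet import MolecularNetwork
        net = MolecularNetwork(nodes=["a", "b"], edges=[], families={},
                               singletons=["a", "b"], annotations={})
        assert annotation_rate(net) == (0, 2, 0.0)
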