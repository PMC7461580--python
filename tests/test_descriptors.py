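"""Z-scale and fingerprint encoding, feature assembly, standardization."""

import numpy as np
import pytest

from arpcm.descriptors import (
    FINGERPRINT_BITS,
    Standardizer,
    assemble_features,
    featurize_pairs,
    fingerprint_encode,
    fit_standardizer,
    zscale_encode,
)
from arpcm.exceptions import AssemblyError, ChemistryError, DimensionError, EncodingError
from arpcm.mutants import parse_mutant_spec
from arpcm.zscales import load_zscale_table, zscale_version


class TestZScaleTable:
    def test_structure(self):
        table = load_zscale_table()
        assert len(table) == 20
        assert all(len(v) == 5 for v in table.values())
        assert zscale_version()

    def test_scores_behave_like_pca_scales(self):
        """z-scales come from a PCA of standardized properties, so each
        component is near zero-mean over the alphabet, and z1 orders
        hydrophobic below hydrophilic residues."""
        table = load_zscale_table()
        cols = np.array(list(table.values()))
        assert np.abs(cols.mean(axis=0)).max() < 0.6
        hydrophobic = [table[a][0] for a in "ILVFM"]
        hydrophilic = [table[a][0] for a in "RKDENQ"]
        assert max(hydrophobic) < 0 < min(hydrophilic)

    def test_spot_values(self):
        """Frozen spot-check against the published five-component table."""
        table = load_zscale_table()
        assert table["A"] == pytest.approx((0.24, -2.32, 0.60, -0.14, 1.30))
        assert table["W"] == pytest.approx((-4.36, 3.94, 0.59, 3.44, -1.59))
        assert table["G"] == pytest.approx((2.05, -4.06, 0.36, -0.82, -0.38))


class TestZScaleEncode:
    def test_lengths(self):
        assert zscale_encode("A").shape == (5,)
        assert zscale_encode("ACDEFGHIKL").shape == (50,)

    def test_residue_slot_order(self):
        table = load_zscale_table()
        vec = zscale_encode("WA")
        assert vec[:5] == pytest.approx(table["W"])
        assert vec[5:] == pytest.approx(table["A"])

    def test_concatenation_homomorphism(self, rng):
        from arpcm.mutants import AMINO_ACIDS

        s1 = "".join(rng.choice(list(AMINO_ACIDS), size=7))
        s2 = "".join(rng.choice(list(AMINO_ACIDS), size=4))
        np.testing.assert_array_equal(
            zscale_encode(s1 + s2),
            np.concatenate([zscale_encode(s1), zscale_encode(s2)]),
        )

    def test_unknown_residue(self):
        with pytest.raises(EncodingError, match="position 2"):
            zscale_encode("AXC")


class TestFingerprint:
    def test_valid_molecule(self):
        fp = fingerprint_encode("CCO")
        assert fp.shape == (2048,)
        assert set(np.unique(fp)) <= {0.0, 1.0}
        assert fp.sum() >= 1

    def test_smiles_equivalence(self):
        np.testing.assert_array_equal(
            fingerprint_encode("CCO"), fingerprint_encode("OCC")
        )

    def test_unparseable_smiles(self):
        with pytest.raises(ChemistryError, match="not_a_smiles"):
            fingerprint_encode("not_a_smiles")

    def test_custom_bits(self):
        assert fingerprint_encode("CCO", n_bits=1024).shape == (1024,)


class TestAssemble:
    def test_combined_length_and_boundary(self):
        fv = assemble_features(np.zeros(50), np.zeros(FINGERPRINT_BITS))
        assert len(fv) == 50 + 2048
        assert fv.boundary == 50

    def test_wrong_fp_length(self):
        with pytest.raises(AssemblyError):
            assemble_features(np.zeros(50), np.zeros(1024))

    def test_zvec_not_multiple_of_five(self):
        with pytest.raises(AssemblyError):
            assemble_features(np.zeros(7), np.zeros(FINGERPRINT_BITS))

    def test_non_binary_fingerprint(self):
        with pytest.raises(AssemblyError):
            assemble_features(np.zeros(5), np.full(FINGERPRINT_BITS, 0.5))


class TestStandardizer:
    def test_train_columns_become_standard(self, rng):
        X = rng.normal(3, 7, size=(40, 10))
        s = fit_standardizer(X, boundary=6)
        Z = s.transform(X)
        assert np.abs(Z[:, :6].mean(axis=0)).max() < 1e-8
        assert np.abs(Z[:, :6].var(axis=0) - 1).max() < 1e-8

    def test_fingerprint_block_untouched(self, rng):
        X = np.hstack([rng.normal(size=(20, 4)), rng.integers(0, 2, size=(20, 8))]).astype(float)
        Z = Standardizer(4).fit_transform(X)
        np.testing.assert_array_equal(Z[:, 4:], X[:, 4:])

    def test_zero_variance_maps_to_zero(self):
        X = np.ones((10, 3))
        Z = Standardizer(3).fit_transform(X)
        np.testing.assert_array_equal(Z, np.zeros_like(X))

    def test_heldout_uses_train_statistics(self, rng):
        """Held-out rows must be shifted by *train* means, which differ from
        their own column means in general."""
        train = rng.normal(0, 1, size=(20, 10))
        held = rng.normal(5, 1, size=(20, 10))
        s = fit_standardizer(train, boundary=10)
        Z = s.transform(held)
        # if held-out stats had been used, columns would be ~zero-mean
        assert np.abs(Z.mean(axis=0)).min() > 1.0

    def test_dimension_mismatch(self, rng):
        s = fit_standardizer(rng.normal(size=(5, 4)), boundary=2)
        with pytest.raises(DimensionError):
            s.transform(rng.normal(size=(5, 6)))

    def test_round_trip_serialization(self, rng):
        X = rng.normal(size=(12, 6))
        s = fit_standardizer(X, boundary=3)
        s2 = Standardizer.from_dict(s.to_dict())
        np.testing.assert_allclose(s.transform(X), s2.transform(X))


class TestFeaturizePairs:
    def test_deterministic_and_shaped(self):
        wt = "ACDEFGHIKLMNPQRSTVWY" * 3
        specs = [parse_mutant_spec("A21C"), parse_mutant_spec("C22A+G26W")]
        drugs = {"d1": "CCO", "d2": "c1ccccc1"}
        pairs = [("A21C", "d1"), ("C22A+G26W", "d2")]
        X1, b1, region = featurize_pairs(wt, specs, drugs, pairs)
        X2, b2, _ = featurize_pairs(wt, specs, drugs, pairs)
        np.testing.assert_array_equal(X1, X2)
        assert (region.start, region.end) == (21, 26)
        assert b1 == b2 == 5 * region.length
        assert X1.shape == (2, b1 + 2048)

    def test_mutation_changes_only_its_block(self):
        wt = "ACDEFGHIKL" * 4
        specs = [parse_mutant_spec("A11W"), parse_mutant_spec("C12A")]
        drugs = {"d": "CCO"}
        X, b, region = featurize_pairs(wt, specs, drugs, [("A11W", "d"), ("C12A", "d")])
        np.testing.assert_array_equal(X[0, b:], X[1, b:])  # same drug bits
        assert not np.array_equal(X[0, :b], X[1, :b])
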