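import numpy as np
import pytest

from misvote.datasets import LabeledDataset
from misvote.ensemble import fit_soft_voting
from misvote.features import FeatureManifest, FeatureSpec, default_manifest
from misvote.synthdata import generate_labeled_features, synthetic_aaindex_set


@pytest.fixture(scope="session")
def manifest113():
    return default_manifest()


@pytest.fixture(scope="session")
def small_manifest():
    """An 11-feature manifest spanning all categories, for fast fits."""
    specs = [
        FeatureSpec("maf_global", "MAF", "global", "MAF"),
        FeatureSpec("maf_afr", "MAF", "AFR", "MAF_AFR"),
        FeatureSpec("phylop_vertebrate", "conservation", "", "phyloP100way_vertebrate"),
        FeatureSpec("gerp_rs", "conservation", "", "GERP++_RS"),
        FeatureSpec("siphy", "conservation", "", "SiPhy_29way_logOdds"),
        FeatureSpec("ccrs", "functional", "", "CCRS"),
        FeatureSpec("aaindex_T1", "functional", "", "aaindex:T1"),
        FeatureSpec("aaindex_T2", "functional", "", "aaindex:T2"),
        FeatureSpec("sift", "predictor", "", "SIFT_score"),
        FeatureSpec("vest4", "predictor", "", "VEST4_score"),
        FeatureSpec("metalr", "predictor", "", "MetaLR_score"),
    ]
    return FeatureManifest(specs, version="test-11")


@pytest.fixture(scope="session")
def small_aaindex(small_manifest):
    return synthetic_aaindex_set(small_manifest.aaindex_ids(), seed=0)


@pytest.fixture(scope="session")
def separable_ds(small_manifest, small_aaindex) -> LabeledDataset:
    return generate_labeled_features(
        150, small_manifest, effect_size=3.0, noise_fraction=0.0,
        seed=11, aaindex_set=small_aaindex,
    )


@pytest.fixture(scope="session")
def trained_model(separable_ds):
    return fit_soft_voting(separable_ds, n_iter=2, cv_folds=3, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_dataset(X, y, feature_names=None) -> LabeledDataset:
    """Wrap a raw (X, y) pair into a LabeledDataset with dummy variant keys."""
    from misvote.features import FeatureMatrix, VariantKey

    X = np.asarray(X, dtype=float)
    n, m = X.shape
    names = feature_names or [f"f{j}" for j in range(m)]
    manifest = FeatureManifest(
        [FeatureSpec(nm, "conservation", "", nm) for nm in names], version="raw"
    )
    variants = [VariantKey("1", 100 + i, "A", "G") for i in range(n)]
    matrix = FeatureMatrix(variants, manifest, X, np.ones_like(X, dtype=bool))
    return LabeledDataset(matrix, np.asarray(y, int), ["test"] * n)
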