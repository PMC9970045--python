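import numpy as np
import pytest

import stainref as sr


@pytest.fixture(scope="session")
def small_cohort():
    """20 synthetic tiles with default (stratified, jittered) settings."""
    return sr.make_cohort(sr.SyntheticCohortSpec(n_images=20, seed=42))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six 32x32 tiles for fast pipeline-shape tests."""
    return sr.make_cohort(
        sr.SyntheticCohortSpec(n_images=6, tile_size=(32, 32), seed=7)
    )


@pytest.fixture(scope="session")
def cohort_fits(small_cohort):
    """Per-image stain-model fits of the 20-tile cohort."""
    fits = {}
    for item in small_cohort:
        od = sr.rgb_to_od(item.image)
        mask = sr.tissue_mask(od)
        fits[item.image_id] = sr.fit_stain_model(od, mask, seed=item.seed)
    return fits


@pytest.fixture(scope="session")
def cohort_hists(cohort_fits):
    """Shared-edge density histograms of the 20-tile cohort, per stain."""
    ids = list(cohort_fits)
    stains = ("hematoxylin", "eosin")
    dens = {
        s: [cohort_fits[i].concentrations.h[k] for i in ids]
        for k, s in enumerate(stains)
    }
    edges = sr.cohort_bin_spec(dens, m_max=256)
    hists = {
        s: [
            sr.build_density_histogram(d, edges[s], stain=s)
            for d in dens[s]
        ]
        for s in stains
    }
    return ids, hists


def random_histogram(rng, n_bins=8, stain="hematoxylin", edges=None):
    """A random unit-C histogram on [0, 1] for distance tests."""
    if edges is None:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    raw = rng.integers(0, 50, size=len(edges) - 1).astype(float)
    raw[rng.integers(0, len(raw))] += 50  # ensure non-constant counts
    lo, hi = raw.min(), raw.max()
    counts = (raw - lo) / (hi - lo)
    return sr.DensityHistogram(
        edges=np.asarray(edges, float),
        counts=counts,
        c_const=1.0,
        stain=stain,
        n_pixels_raw=int(raw.sum()),
    )
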