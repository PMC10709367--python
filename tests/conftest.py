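"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from coreinflam import AnalysisConfig, meta, study_de
from coreinflam.simulate import SimConfig, gen_cross_species_studies


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete cross-species compendium: 5 studies (3+2),
    1500 genes, 40 up + 15 down planted program genes."""
    cfg = SimConfig(n_genes=1500, n_studies_a=3, n_studies_b=2,
                    n_core_up=40, n_core_down=15, n_study_specific=15,
                    seed=11)
    bundles, omap, truth = gen_cross_species_studies(cfg)
    return bundles, omap, truth


@pytest.fixture(scope="session")
def small_de(small_sim):
    """Per-study DE tables for the small compendium."""
    bundles, omap, truth = small_sim
    des = []
    for b in bundles:
        sid = b.meta["study_id"].iloc[0]
        filt = study_de.prefilter(b)
        de = study_de.nb_wald(filt)
        de = study_de.independent_filter(de)
        de.table["study_id"] = sid
        de.table["comparison_id"] = sid
        des.append(de)
    return des


@pytest.fixture(scope="session")
def small_meta(small_de, small_sim):
    _, omap, _ = small_sim
    return meta.run_meta(small_de, AnalysisConfig(rank_cutoff=80), omap=omap)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_bundle():
    from coreinflam import StudyBundle
    counts = pd.DataFrame(
        [[10, 0, 5, 7], [0, 0, 0, 0], [3, 8, 2, 1], [1, 1, 1, 1]],
        index=["g1", "g2", "g3", "g4"],
        columns=["s1", "s2", "s3", "s4"])
    meta_df = pd.DataFrame(
        {"study_id": "st1",
         "condition": ["resting", "resting", "inflamed", "inflamed"],
         "species": "A"},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"))
    return StudyBundle(counts, meta_df)
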