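import numpy as np
import pytest

import embryoscan as es


@pytest.fixture
def tiny_haps(tmp_path):
    """Hand-written haps-matrix: 3 individuals x 4 SNPs."""
    text = (
        "s1 s2 s3 s4\n"
        "a_A 0 0 1 1\n"
        "a_B 0 1 1 0\n"
        "b_A 1 1 0 0\n"
        "b_B 0 0 1 1\n"
        "c_A 0 0 1 1\n"
        "c_B 0 0 1 1\n"
    )
    path = tmp_path / "tiny.haps"
    path.write_text(text)
    return path


@pytest.fixture
def trio_pedigree_csv(tmp_path):
    path = tmp_path / "ped.csv"
    path.write_text(
        "id,sire,dam,birth_year,sex,genotyped\n"
        "a,,,1990,M,1\n"
        "b,,,1990,F,1\n"
        "c,a,b,1993,F,1\n"
    )
    return path


@pytest.fixture(scope="session")
def small_lethal_dataset():
    """One integrated simulation with a fully lethal focal haplotype."""
    cfg = es.SimConfig(
        n_founders=150,
        n_years=10,
        matings_per_year=60,
        n_chromosomes=2,
        snps_per_chromosome=120,
        focal_chromosome=0,
        focal_start=40,
        focal_length=40,
        focal_founder_freq=0.3,
        s_embryo=1.0,
        seed=11,
    )
    return cfg, es.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def cohort_pedigree():
    """Neutral 29-cohort pedigree + observed focal states for gene-drop tests."""
    import embryoscan.studies as st

    res = es.simulate_dataset(st.cohort_study_config(0.0, seed=21))
    dosage = es.focal_dosage(res.genotypes, res.pedigree, res.truth)
    return res, dosage
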