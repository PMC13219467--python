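"""Shared fixtures: small synthetic trials with known architecture.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import pytest

import forestgs as fgs


@pytest.fixture(scope="session")
def small_trial() -> fgs.simdata.SimulatedTrial:
    """Moderate two-site trial: 10 families from 12 parents, ~240 trees,
    800 SNPs, additive-dominated trait."""
    arch = fgs.TraitArchitecture(
        n_qtl=120,
        additive_var=(0.5, 0.5),
        r_a=0.8,
        dominance_var=(0.15, 0.15),
        r_d=0.8,
        block_var=(0.1, 0.1),
        residual_var=(0.35, 0.35),
    )
    return fgs.simulate_trial(
        n_parents=12,
        n_families=10,
        offspring_per_family=24,
        n_snps=800,
        arch=arch,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_matrices(small_trial):
    """Blended genomic + pedigree matrices for the small trial."""
    A = fgs.build_A(small_trial.pedigree)
    D = fgs.build_D(small_trial.pedigree)
    Ga, Ga_inv = fgs.blend_and_invert(fgs.build_Ga(small_trial.genotypes), A, 0.02)
    Gd, Gd_inv = fgs.blend_and_invert(fgs.build_Gd(small_trial.genotypes), D, 0.02)
    return {"A": A, "D": D, "Ga": Ga, "Gd": Gd,
            "Ga_inv": Ga_inv, "Gd_inv": Gd_inv}


@pytest.fixture(scope="session")
def tiny_trial() -> fgs.simdata.SimulatedTrial:
    """60-tree fixture small enough for brute-force likelihood oracles."""
    return fgs.simulate_trial(
        n_parents=6,
        n_families=6,
        offspring_per_family=10,
        n_snps=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_fit(small_trial, small_matrices):
    fit, data = fgs.fit_model(
        small_trial.phenotypes,
        small_matrices["Ga"],
        small_matrices["Gd"],
        fgs.ModelSpec(method="gblup"),
    )
    return fit, data
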