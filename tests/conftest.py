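"""Shared fixtures: the default synthetic cohort and small fast cohorts."""

import numpy as np
import pytest

import signet


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-sized cohort (70 subjects x 1128 proteins), seed 0."""
    return signet.generate_cohort(signet.CohortConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast classifier property tests."""
    cfg = signet.CohortConfig(
        n_control=10,
        n_affected=14,
        n_proteins=80,
        n_markers=12,
        n_strong_markers=6,
        n_age_markers=4,
        n_treatment_markers=4,
        treated_fraction_of_affected=0.5,
        seed=1,
    )
    return signet.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_network(default_cohort):
    """Signaling + physical networks wired to the default cohort's markers."""
    dataset, truth = default_cohort
    signaling, physical, truth = signet.generate_network(
        n_nodes=400,
        n_tfs=15,
        mean_degree=4,
        truth_markers=truth.marker_genes,
        n_de_intermediates=10,
        seed=11,
        truth=truth,
        universe=dataset.mapped_genes(),
    )
    return signaling, physical, truth


def noise_dataset(n_control: int, n_affected: int, n_proteins: int, seed: int):
    """A cohort with no planted class effect at all (pure noise)."""
    rng = np.random.default_rng(seed)
    n = n_control + n_affected
    values = np.exp2(rng.uniform(8, 12, size=n_proteins)[None, :] + rng.normal(0, 0.5, size=(n, n_proteins)))
    pids = [f"A{j:03d}" for j in range(n_proteins)]
    return signet.ExpressionDataset(
        subject_ids=[f"S{i:03d}" for i in range(n)],
        protein_ids=pids,
        values=values,
        gene_map={p: [f"G{j:03d}"] for j, p in enumerate(pids)},
        class_labels=np.array(["control"] * n_control + ["affected"] * n_affected, dtype=object),
        ages=rng.uniform(4, 15, size=n),
        treated=np.zeros(n, dtype=bool),
    )
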