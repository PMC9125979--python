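"""Shared fixtures: full synthetic-study runs reused across test modules.

The heavy fixture (`study_runs`) executes the complete pipeline on the
default cohort for seeds 1-5 once per session; recovery-style tests read
from it instead of re-running the stages.
"""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from moltax import diffexp, pipeline, synthetic

#: drug-library conditions for the recovery runs: the weakest planted
#: reversal the reverser-recovery property is stated for
RECOVERY_LIBRARY = dict(n_drugs=20, reversal_effect=1.5, noise_sd=0.25)


@pytest.fixture(scope="session")
def study_runs():
    """Full pipeline on the paper-default cohort for seeds 1..5.

    Returns a list of dicts with per-seed cohort, stratification and
    drug-prediction results plus truth-agreement summaries.
    """
    runs = []
    for seed in range(1, 6):
        cohort = synthetic.generate_cohort(synthetic.paper_default(seed=seed))
        res = pipeline.stratify_cohort(cohort.counts, cohort.patients, seed=seed)

        labels = res.module_set.labels()
        gene_ari = adjusted_rand_score(cohort.gene_truth.loc[labels.index], labels)
        truth = cohort.sample_meta.set_index("sample_id").loc[
            cohort.patients, "true_endotype"
        ]
        sample_ari = adjusted_rand_score(truth, res.assignment.labels)

        signatures = {
            endo: diffexp.de_test(
                cohort.counts,
                res.assignment.labels.index[res.assignment.labels == endo].tolist(),
                cohort.controls,
            )
            for endo in sorted(res.assignment.labels.unique())
        }
        lib = synthetic.generate_drug_library(
            synthetic.DrugLibrarySpec(seed=seed, **RECOVERY_LIBRARY), signatures
        )
        drugs = pipeline.predict_drugs(
            cohort.counts,
            cohort.controls,
            res.assignment,
            library=lib.signatures,
            n_perm=1000,
            seed=seed,
        )
        runs.append(
            {
                "seed": seed,
                "cohort": cohort,
                "strat": res,
                "drugs": drugs,
                "gene_ari": gene_ari,
                "sample_ari": sample_ari,
                "library_truth": lib.truth,
            }
        )
    return runs


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 60-sample, 1,500-gene cohort with the full module structure."""
    return synthetic.generate_cohort(synthetic.PRESETS["small"](seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
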