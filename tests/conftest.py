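import numpy as np
import pytest

from mocamet import (
    CohortSpec,
    filter_dynamic_range,
    generate_cohort,
    impute_below_lod,
    normalize_by_weight,
    scale_blocks,
    fit_moca,
    orient_model,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (seed 7) with ground truth."""
    return generate_cohort(CohortSpec(seed=7))


def preprocess(plasma, aorta, min_fraction=0.70, strategy="half_min"):
    """Filter -> weight-normalize -> impute, returning analysis-ready blocks."""
    plasma, _ = filter_dynamic_range(plasma, min_fraction)
    aorta, _ = filter_dynamic_range(aorta, min_fraction)
    aorta = normalize_by_weight(aorta)
    plasma, _ = impute_below_lod(plasma, strategy)
    aorta, _ = impute_below_lod(aorta, strategy)
    return plasma, aorta


def fit_cohort(plasma, aorta, n_joint=2, n_unique=1, seed=0):
    """Scale and fit the two-block model, oriented on the group labels."""
    scaled, realizations = scale_blocks({"plasma": plasma, "aorta": aorta})
    model = fit_moca(
        scaled["plasma"],
        scaled["aorta"],
        n_joint=n_joint,
        n_unique_pl=n_unique,
        n_unique_ao=n_unique,
        metabolite_names={
            "plasma": plasma.metabolite_names,
            "aorta": aorta.metabolite_names,
        },
        scaling=realizations,
        rng=np.random.default_rng(seed),
    )
    return orient_model(model, plasma.groups), scaled


@pytest.fixture(scope="session")
def fitted_default(default_cohort):
    plasma, aorta, truth = default_cohort
    plasma, aorta = preprocess(plasma, aorta)
    model, scaled = fit_cohort(plasma, aorta)
    return plasma, aorta, model, scaled, truth
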