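import numpy as np
import pandas as pd
import pytest


def _response(dog_id, *, limp_end="no", limp_length="no", stiff="no", hair="no",
              painful="no", attribution="none"):
    return {
        "dog_id": dog_id,
        "sign_limp_end": limp_end,
        "sign_limp_length": limp_length,
        "sign_stiff_base": stiff,
        "sign_hair_on_end": hair,
        "sign_painful": painful,
        "attribution": attribution,
    }


def worked_example_responses():
    """The published reclassification inputs: 31 provisional cases of
    which 2 lack limpness, and 93 provisional controls of which 14 show
    signs — 3 with anal-gland attributions (two stiff-base, two
    limp-length profiles across three dogs), 2 with signs lacking
    limpness, and 9 with unexplained limpness.

    Returns (responses DataFrame, provisional dict).
    """
    rows, provisional = [], {}
    i = 0

    def add(prov, **kw):
        nonlocal i
        dog = f"W{i:03d}"
        rows.append(_response(dog, **kw))
        provisional[dog] = prov
        i += 1

    for _ in range(29):  # provisional cases with confirmed limpness
        add("case", limp_end="yes", stiff="yes")
    for _ in range(2):  # provisional cases with no limpness
        add("case", stiff="yes", painful="yes")
    # provisional controls: 3 anal-gland attributions (one dog with both
    # a stiff base and limp length, one stiff only, one limp-length only)
    add("control", stiff="yes", limp_length="yes", attribution="anal_glands")
    add("control", stiff="yes", attribution="anal_glands")
    add("control", limp_length="yes", attribution="anal_glands")
    for _ in range(2):  # signs without limpness
        add("control", stiff="yes", hair="yes")
    for _ in range(9):  # unexplained limpness -> promoted
        add("control", limp_end="yes")
    for _ in range(93 - 14):  # controls with no signs
        add("control")
    return pd.DataFrame(rows), provisional


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_responses()


@pytest.fixture(scope="session")
def small_cohort():
    """Pedigree-structured 600-dog cohort with simulated disease."""
    from limbertail import (
        RiskModelParams,
        generate_cohort,
        generate_pedigree,
        simulate_case_status,
    )

    pedigree = generate_pedigree(600, 60, 80, concentration=1.0, seed=11)
    cohort = generate_cohort(pedigree, seed=12)
    sim = simulate_case_status(cohort, RiskModelParams(), seed=13)
    return pedigree, cohort, sim


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One small end-to-end pipeline run shared across tests."""
    from limbertail import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("demo")
    cfg = RunConfig(seed=3, out_dir=str(out / "run"), n_dogs=500, n_sires=60,
                    n_dams=80, n_perm=500)
    return run_pipeline(cfg)
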