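import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from phenotyper import RunConfig, run_pipeline, synth
from phenotyper.io import ExperimentSchedule


@pytest.fixture(scope="session")
def default_genotype():
    return synth.GenotypeParams(flowering_onset_das=45, branches_k=3, flower_overlap=False)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """Small rendered cohort on disk: 3 genotypes x 1 rep/treatment x 3 days."""
    root = tmp_path_factory.mktemp("tiny_cohort")
    schedule = ExperimentSchedule(
        imaging_days=[45, 47, 49], treatment_window=(45, 49), treatment_map={}
    )
    cohort = synth.generate_cohort(3, 1, schedule, seed=21, out_dir=root)
    return cohort


def _run(cohort, out_dir, seed=1):
    config = RunConfig(
        root=cohort.root,
        metadata=cohort.metadata_path,
        labels=cohort.truth_path,
        out_dir=out_dir,
        registration=synth.NIR_REGISTRATION,
        rim_row=synth.SIDE_RIM_ROW,
        seed=seed,
    )
    manifest = run_pipeline(config)
    return config, manifest


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_out")
    config, manifest = _run(tiny_cohort, out)
    return {"cohort": tiny_cohort, "config": config, "manifest": manifest, "out": out}


@pytest.fixture(scope="session")
def recovery_cohort(tmp_path_factory):
    """Parameter-recovery cohort: 10 genotypes x 3 reps/treatment x 10 days."""
    root = tmp_path_factory.mktemp("recovery_cohort")
    schedule = ExperimentSchedule(
        imaging_days=list(range(39, 58, 2)), treatment_window=(39, 55), treatment_map={}
    )
    return synth.generate_cohort(10, 3, schedule, seed=1, out_dir=root)


@pytest.fixture(scope="session")
def recovery_pipeline(recovery_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("recovery_out")
    config, manifest = _run(recovery_cohort, out)
    reports = json.loads((out / "ml_report.json").read_text())
    return {
        "cohort": recovery_cohort,
        "config": config,
        "manifest": manifest,
        "out": out,
        "reports": reports,
        "flowers": pd.read_csv(out / "flowers.csv"),
        "truth": pd.read_csv(recovery_cohort.truth_path),
    }
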