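import numpy as np
import pandas as pd
import pytest

from oncodecon.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-patient, 300-gene cohort with effects, factors and missingness."""
    cfg = SimulationConfig(n_samples=80, n_normals=10, n_genes=300,
                           n_targets_per_lesion=20, seed=3)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    return small_cohort[0]


@pytest.fixture()
def tiny_tables(tmp_path):
    """Write a minimal 3-sample cohort to disk; returns the path dict."""
    d = tmp_path / "cohort"
    d.mkdir()
    samples = ["S1", "S2", "S3"]
    expr = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.5]], index=["gA", "gB"], columns=samples
    )
    expr.to_csv(d / "expression.tsv", sep="\t", index_label="gene")
    with open(d / "lesions.tsv", "w") as fh:
        fh.write("#classes\tgenetic\tcytogenetic\n")
        fh.write("sample\tmutA\tdelB\n")
        fh.write("S1\t1\t0\nS2\t0\t1\nS3\t0\t0\n")
    clin = pd.DataFrame({"hb": [10.0, 11.0, np.nan]}, index=samples)
    clin.to_csv(d / "clinical.tsv", sep="\t", index_label="sample", na_rep="NA")
    pd.DataFrame({"variable": ["hb"], "domain": ["positive"], "units": ["g/dl"]}).to_csv(
        d / "clinical_spec.tsv", sep="\t", index=False)
    demo = pd.DataFrame({"sex": [1, 0, 1], "age": [60, 70, 65], "normal": [0, 0, 1]},
                        index=samples)
    demo.to_csv(d / "demographics.tsv", sep="\t", index_label="sample")
    surv = pd.DataFrame({"time_days": [100.0, 250.0, 400.0], "status": [1, 0, 0]},
                        index=samples)
    surv.to_csv(d / "survival.tsv", sep="\t", index_label="sample")
    return {
        "expression": d / "expression.tsv",
        "lesions": d / "lesions.tsv",
        "clinical": d / "clinical.tsv",
        "clinical_spec": d / "clinical_spec.tsv",
        "demographics": d / "demographics.tsv",
        "survival": d / "survival.tsv",
    }
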