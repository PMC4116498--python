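"""Published study-cohort characteristics and their descriptive statistics.

The packaged table lists the 20 locally advanced breast cancer patients of
the clinical study this pipeline models: age, menopausal status, pre-treatment
tumour size, histology, receptor status and the ultimate clinical/pathologic
response category (Good = responder, Poor = non-responder).

Tumour size is the largest dimension of the lesion; for multifocal disease
the largest dimensions of the lesions are summed (RECIST-style total
extent).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_study_cohort() -> pd.DataFrame:
    """Load the packaged patient-characteristics table."""
    with resources.files("qustex.data").joinpath("study_cohort.csv").open() as fh:
        return pd.read_csv(fh)


def describe_study_cohort(table: pd.DataFrame | None = None) -> dict:
    """Descriptive statistics of the study cohort.

    SDs are sample standard deviations (ddof=1).
    """
    t = load_study_cohort() if table is None else table
    age = t["age"].to_numpy(float)
    size = t["tumor_size_cm"].to_numpy(float)
    return {
        "n_patients": int(len(t)),
        "age_mean_years": float(age.mean()),
        "age_sd_years": float(age.std(ddof=1)),
        "age_min_years": float(age.min()),
        "age_max_years": float(age.max()),
        "tumor_size_mean_cm": float(size.mean()),
        "tumor_size_sd_cm": float(size.std(ddof=1)),
        "tumor_size_min_cm": float(size.min()),
        "tumor_size_max_cm": float(size.max()),
        "n_responders": int((t["response"] == "Good").sum()),
        "n_nonresponders": int((t["response"] == "Poor").sum()),
        "n_invasive_ductal": int((t["histology"] == "ductal").sum()),
        "n_er_pr_positive": int((t["er_pr"] == "pos").sum()),
        "n_her2_positive": int((t["her2"] == "pos").sum()),
    }
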