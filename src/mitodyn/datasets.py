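"""Bundled datasets.

``nb_relapse_cohort_counts``: per-patient mitochondrial variant counts
from a published 16-patient neuroblastoma cohort with matched normal
tissue, primary tumor and relapse samples — tumor-specific and germline
variant numbers in the primary (P) and relapse (R) tumor (variants at
allele fraction >= 1%), plus the reported per-patient linear-regression
coefficient of germline counts over the normal -> primary -> relapse
stages.  These counts are the reference input for the trend statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cohort_counts"]


def load_cohort_counts() -> pd.DataFrame:
    """Per-patient variant counts of the bundled neuroblastoma relapse
    cohort (columns: patient_id, ts_p, ts_r, germ_p, germ_r,
    coefficient)."""
    with resources.files("mitodyn.data").joinpath(
        "nb_relapse_cohort_counts.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["patient_id"] = df["patient_id"].astype(str)
    return df
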