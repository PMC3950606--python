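"""Urinary C-peptide (UCP) indexing and sample-quality filters.

UCP, a by-product of insulin synthesis, indexes energetic status
non-invasively. Raw urinary concentrations depend on urine dilution, so
C-peptide (ng/ml) is divided by creatinine (mg/ml), giving ng C-peptide
per mg creatinine; any reconstitution or dilution applied equally to
both analytes cancels. Samples are excluded when creatinine falls below
the 0.1 mg/ml assay sensitivity or when they sat frozen for more than
8 months before lyophilisation (long storage degrades C-peptide).
"""

from __future__ import annotations

import pandas as pd

CREATININE_SENSITIVITY_MG_PER_ML = 0.1
MAX_STORAGE_MONTHS = 8.0


def ucp_index(sample: pd.Series | dict) -> dict:
    """Creatinine-indexed UCP (ng/mg) for one sample, with QC flags.

    Returns ``{"value": float | None, "qc_flags": set}``; a value is
    present only when the sample passes the creatinine-sensitivity
    filter.
    """
    creat = float(sample["creatinine_mg_per_ml"])
    cpep = float(sample["cpeptide_ng_per_ml"])
    flags: set[str] = set()
    if cpep < 0 or creat < 0:
        raise ValueError("concentrations must be non-negative")
    if creat < CREATININE_SENSITIVITY_MG_PER_ML:
        flags.add("creatinine_below_sensitivity")
        return {"value": None, "qc_flags": flags}
    return {"value": cpep / creat, "qc_flags": flags}


def filter_storage(samples: pd.DataFrame, max_months: float = MAX_STORAGE_MONTHS) -> tuple[pd.DataFrame, dict]:
    """Drop samples stored frozen for more than ``max_months`` before
    lyophilisation (strict: exactly 8 months is retained)."""
    keep = samples["storage_months_before_lyophilisation"] <= max_months
    report = {"n_in": int(len(samples)), "n_retained": int(keep.sum()), "n_excluded": int((~keep).sum())}
    return samples[keep].reset_index(drop=True), report


def process_samples(samples: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Storage filter then creatinine filter (order-independent); returns
    the measurement table (one row per retained sample, with the UCP
    index) and a QC report."""
    retained, report = filter_storage(samples)
    rows = []
    n_low_creat = 0
    for _, s in retained.iterrows():
        res = ucp_index(s)
        if res["value"] is None:
            n_low_creat += 1
            continue
        rows.append(
            {
                "male_id": s["male_id"],
                "collection_datetime": s["collection_datetime"],
                "ucp_ng_per_mg_creatinine": res["value"],
                "storage_months": s["storage_months_before_lyophilisation"],
            }
        )
    report["n_low_creatinine"] = n_low_creat
    report["n_measured"] = len(rows)
    cols = ["male_id", "collection_datetime", "ucp_ng_per_mg_creatinine", "storage_months"]
    return pd.DataFrame(rows, columns=cols), report
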