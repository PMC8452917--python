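"""Bundled reference datasets.

``stent_cohort.csv`` records the lesion and implanted-stent characteristics
of a published prospective PCI validation cohort (25 patients, 30 treated
vessels, 36 drug-eluting stents): per stent, the treated vessel, lesion
category, stent length L (mm), stent diameter D (mm), and the lesion's
percent diameter stenosis.  It serves as a realistic input table for the
virtual-stenting interfaces and as a worked-example fixture.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_stent_cohort() -> pd.DataFrame:
    """The bundled stent-cohort table (one row per implanted stent)."""
    with resources.files("coroflow.data").joinpath("stent_cohort.csv").open() as fh:
        return pd.read_csv(fh)


def stent_cohort_summary(df: pd.DataFrame | None = None) -> dict:
    """Aggregate statistics of a stent-cohort table: stent dimension
    mean +/- SD and per-vessel lesion-type counts."""
    if df is None:
        df = load_stent_cohort()
    vessels = df.drop_duplicates(subset=["patient_id", "vessel"])
    counts = vessels["lesion_type"].str.lower().value_counts().to_dict()
    return {
        "n_patients": int(df["patient_id"].nunique()),
        "n_vessels": int(len(vessels)),
        "n_stents": int(len(df)),
        "stent_length_mean_mm": float(df["L_mm"].mean()),
        "stent_length_sd_mm": float(df["L_mm"].std(ddof=1)),
        "stent_diameter_mean_mm": float(df["D_mm"].mean()),
        "stent_diameter_sd_mm": float(df["D_mm"].std(ddof=1)),
        "lesion_counts": counts,
    }
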