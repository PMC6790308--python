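"""Reference cohort tables and descriptive statistics.

Loads the bundled 50-patient awake-craniotomy cohort fixtures (clinical
covariates and per-patient laterality indices) and reproduces the study's
descriptive statistics: demographics, anxiety/success scores on a 0-10
visual-analogue scale, histology groupings, and the left-handed subgroup's
hemispheric dominance counts.
"""

from __future__ import annotations

import importlib.resources
import io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_cohort",
    "load_laterality_table",
    "histology_category",
    "summarize",
    "left_hander_summary",
    "compare_to_reference",
]

COHORT_COLUMNS = (
    "patient",
    "sex",
    "age",
    "lesion_side",
    "lesion_location",
    "histology",
    "language_disturbance",
    "anxiety",
    "success",
)

#: histology code -> (category, glial grade).  DNET is grouped with the
#: nontumoral lesions, following the clinical grouping of the source cohort.
GLIAL_HIGH = ("GB", "GS", "AA", "OA III", "OD")
GLIAL_LOW = ("XA", "OA II", "PA", "GG", "AB")


def _fixture(name: str) -> str:
    return (importlib.resources.files("langmap.data") / name).read_text()


def histology_category(code: str) -> tuple[str, str | None]:
    """(category, grade): glial (high/low grade), metastasis, or nontumoral."""
    c = code.strip()
    if "metastasis" in c.lower():
        return "metastasis", None
    head = c.split()[0]
    if head in ("GB", "GS", "AA", "OD"):
        return "glial", "high"
    if head == "OA":
        return "glial", ("high" if "III" in c else "low")
    if head in ("XA", "PA", "GG", "AB"):
        return "glial", "low"
    return "nontumoral", None


def load_cohort(path: str | Path | None = None) -> pd.DataFrame:
    """The cohort table; missing scores stay missing (never imputed)."""
    text = Path(path).read_text() if path else _fixture("table1_cohort.csv")
    if not text.strip():
        raise ValueError("empty cohort file")
    df = pd.read_csv(io.StringIO(text))
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"cohort schema mismatch; missing columns {missing}, unexpected {extra}"
        )
    if df["patient"].duplicated().any():
        dupes = df.loc[df["patient"].duplicated(), "patient"].tolist()
        raise ValueError(f"duplicated patient ids: {dupes}")
    for col in ("anxiety", "success"):
        bad = df[col].dropna()
        if ((bad < 0) | (bad > 10)).any():
            raise ValueError(f"{col} scores must lie in [0, 10]")
    return df


def load_laterality_table(path: str | Path | None = None) -> pd.DataFrame:
    """Per-patient Edinburgh handedness and task/rest laterality indices
    (all on the -100..+100 scale, positive = right)."""
    text = Path(path).read_text() if path else _fixture("table2_laterality.csv")
    df = pd.read_csv(io.StringIO(text))
    if df["patient"].duplicated().any():
        raise ValueError("duplicated patient ids in the laterality table")
    return df


def _mean_sd(series: pd.Series) -> tuple[float, float | None]:
    vals = series.dropna().astype(float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else None
    return mean, sd


def summarize(cohort: pd.DataFrame) -> dict:
    """Descriptive summary: mean +/- sd with listwise missing-value
    exclusion, and counts by sex, language disturbance, and histology."""
    if len(cohort) == 0:
        raise ValueError("summarize needs at least one record")
    cats = cohort["histology"].map(lambda c: histology_category(c)[0])
    grades = cohort["histology"].map(lambda c: histology_category(c)[1])
    mean_age, sd_age = _mean_sd(cohort["age"])
    mean_anx, sd_anx = _mean_sd(cohort["anxiety"])
    mean_suc, sd_suc = _mean_sd(cohort["success"])
    return {
        "n": int(len(cohort)),
        "n_male": int((cohort["sex"] == "M").sum()),
        "n_female": int((cohort["sex"] == "F").sum()),
        "mean_age": mean_age,
        "sd_age": sd_age,
        "mean_anxiety": mean_anx,
        "sd_anxiety": sd_anx,
        "n_anxiety": int(cohort["anxiety"].notna().sum()),
        "mean_success": mean_suc,
        "sd_success": sd_suc,
        "n_success": int(cohort["success"].notna().sum()),
        "n_language_disturbance": int((cohort["language_disturbance"] != "No").sum()),
        "n_glial": int((cats == "glial").sum()),
        "n_glial_high_grade": int(((cats == "glial") & (grades == "high")).sum()),
        "n_glial_low_grade": int(((cats == "glial") & (grades == "low")).sum()),
        "n_metastasis": int((cats == "metastasis").sum()),
        "n_nontumoral": int((cats == "nontumoral").sum()),
    }


def left_hander_summary(laterality: pd.DataFrame) -> dict:
    """The left-handed subgroup (Edinburgh < 0): size, mean handedness on
    the unit (-1..1) scale, and right-dominance counts per modality under
    the sign-only criterion."""
    left = laterality[laterality["edinburgh"] < 0]
    return {
        "n_left_handed": int(len(left)),
        "mean_edinburgh_unit": float((left["edinburgh"] / 100.0).mean()),
        "sd_edinburgh_unit": float((left["edinburgh"] / 100.0).std(ddof=1)),
        "n_right_dominant_rest": int((left["rest"] > 0).sum()),
        "n_right_dominant_task": int((left["tia"] > 0).sum()),
    }


def compare_to_reference(
    values: pd.Series | np.ndarray,
    reference_mean: float,
    reference_sd: float,
    reference_n: int,
) -> dict:
    """Welch two-sample t-test of observed scores against a reference group
    known only through its summary statistics."""
    if reference_n < 2:
        raise ValueError("reference group needs n >= 2")
    vals = pd.Series(values).dropna().astype(float)
    if vals.std(ddof=1) == 0 and reference_sd == 0:
        # degenerate: no variance anywhere; equal means give t = 0
        t = 0.0 if vals.mean() == reference_mean else np.inf * np.sign(vals.mean() - reference_mean)
        return {
            "t": float(t),
            "p": 1.0 if t == 0 else 0.0,
            "direction": "higher" if vals.mean() > reference_mean else "lower",
            "n_observed": int(len(vals)),
        }
    t, p = stats.ttest_ind_from_stats(
        mean1=float(vals.mean()),
        std1=float(vals.std(ddof=1)),
        nobs1=len(vals),
        mean2=reference_mean,
        std2=reference_sd,
        nobs2=reference_n,
        equal_var=False,
    )
    return {
        "t": float(t),
        "p": float(p),
        "direction": "higher" if vals.mean() > reference_mean else "lower",
        "n_observed": int(len(vals)),
    }
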