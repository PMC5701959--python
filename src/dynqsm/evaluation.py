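"""Repeatability and sensitivity analyses over pipeline outputs.

Test-retest agreement uses the intraclass correlation coefficient in its
two-way random-effects, single-measure, absolute-agreement form (ICC(A,1))
— the form that penalises a systematic offset between visits, unlike the
Pearson correlation — together with Bland-Altman limits of agreement.
Sweeps re-run only the stages a parameter touches: the CSF-reference
thresholds re-run selection + quantification on fixed reconstructions,
the regularisation sweep re-runs the dipole inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import InversionConfig, ReferenceConfig


@dataclass
class BlandAltman:
    mean_diff: float
    lower: float
    upper: float
    sd: float


def icc_absolute_agreement(v1: Sequence[float],
                           v2: Sequence[float]) -> float:
    """ICC(A,1): two-way random effects, single measure, absolute agreement.

    Computed from the ANOVA mean squares of the subjects x visits table:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    x = np.column_stack([np.asarray(v1, float), np.asarray(v2, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def bland_altman(v1: Sequence[float], v2: Sequence[float]) -> BlandAltman:
    """Mean difference (visit1 - visit2) and mean +- 1.96 SD limits."""
    d = np.asarray(v1, float) - np.asarray(v2, float)
    if d.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean_diff=mean, lower=mean - 1.96 * sd,
                       upper=mean + 1.96 * sd, sd=sd)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (subject, visit, region) uniqueness contract."""
    required = {"subject", "visit", "age", "region", "cbv"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    if table.duplicated(["subject", "visit", "region"]).any():
        raise ValueError("duplicate (subject, visit, region) rows")
    return table


def age_regression(cohort: pd.DataFrame,
                   region: str) -> Tuple[float, float, float]:
    """OLS of CBV on age for one region: (slope, intercept, r).

    Visits are averaged per subject before the regression.
    """
    validate_cohort(cohort)
    sub = cohort[cohort["region"] == region]
    per_subject = sub.groupby("subject").agg(
        age=("age", "mean"), cbv=("cbv", "mean"))
    if len(per_subject) < 3:
        raise ValueError("need at least 3 subjects")
    if per_subject["age"].nunique() < 2:
        raise ValueError("degenerate ages; regression undefined")
    from scipy import stats

    res = stats.linregress(per_subject["age"], per_subject["cbv"])
    return float(res.slope), float(res.intercept), float(res.rvalue)


def simulate_cohort_table(n_subjects: int = 20, seed: int = 0,
                          age_range: Tuple[float, float] = (25.0, 84.0),
                          slope: float = -0.025, intercept: float = 4.9,
                          between_sd: float = 1.4, within_sd: float = 0.45,
                          region: str = "gm",
                          n_discarded: int = 1) -> pd.DataFrame:
    """Synthetic two-visit cohort for repeatability/age-trend recovery tests.

    Each subject's true CBV is ``intercept + slope*age`` plus a
    between-subject deviation; each visit adds independent within-subject
    noise.  ``n_discarded`` measurements are dropped at random, emulating
    technically failed scans (a 20-subject, two-visit design with one loss
    gives n = 39 rows).
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, size=n_subjects)
    true = intercept + slope * ages + rng.normal(0, between_sd, n_subjects)
    rows = []
    for s in range(n_subjects):
        for visit in (1, 2):
            rows.append({"subject": s, "visit": visit, "age": ages[s],
                         "region": region,
                         "cbv": true[s] + rng.normal(0, within_sd)})
    table = pd.DataFrame(rows)
    if n_discarded:
        drop = rng.choice(len(table), size=n_discarded, replace=False)
        table = table.drop(index=drop).reset_index(drop=True)
    return validate_cohort(table)


def threshold_sweep(dataset: Iterable, range_grid: Sequence[float],
                    tailpeak_grid: Sequence[float],
                    base_cfg: ReferenceConfig | None = None,
                    region: str = "brain") -> pd.DataFrame:
    """Vary the CSF-selection thresholds one at a time over a test-retest
    dataset and report whole-brain ICC and mean CBV per grid point.

    ``dataset`` is a sequence of (visit1, visit2) reconstruction products
    (see :class:`dynqsm.pipeline.ReconProducts`); reconstructions are fixed
    and only reference selection + quantification are re-run, so each grid
    point equals an independent single run with the same seeds.
    """
    from .pipeline import cbv_from_products

    base_cfg = base_cfg or ReferenceConfig()
    dataset = list(dataset)
    rows = []

    def evaluate(cfg: ReferenceConfig, param: str, value: float) -> None:
        v1, v2 = [], []
        for visit1, visit2 in dataset:
            v1.append(cbv_from_products(visit1, cfg, region=region).cbv)
            v2.append(cbv_from_products(visit2, cfg, region=region).cbv)
        rows.append({
            "param": param, "value": value,
            "icc": icc_absolute_agreement(v1, v2),
            "mean_cbv": float(np.mean(v1 + v2)),
        })

    for tr in range_grid:
        evaluate(base_cfg.model_copy(update={"thresh_range": tr}),
                 "thresh_range", tr)
    for tp in tailpeak_grid:
        evaluate(base_cfg.model_copy(update={"thresh_tailpeak": tp}),
                 "thresh_tailpeak", tp)
    return pd.DataFrame(rows)


def lambda_sweep(products, lam_grid: Sequence[float],
                 base_cfg: InversionConfig | None = None) -> pd.DataFrame:
    """GM - WM CBV difference as a function of the regularisation weight.

    The difference (rather than the ratio) is reported because the global
    CSF-reference shift cancels in it.  Only the dipole inversion is
    re-run per grid point, on the baseline- and steady-state-window mean
    local fields.
    """
    from .pipeline import gm_wm_cbv_difference

    base_cfg = base_cfg or InversionConfig()
    if base_cfg.method != "medi_like":
        raise ValueError("lambda is a parameter of the medi_like method; "
                         "it is undefined for tkd")
    rows = []
    for lam in lam_grid:
        cfg = base_cfg.model_copy(update={"lam": float(lam)})
        diff = gm_wm_cbv_difference(products, cfg)
        rows.append({"lam": float(lam), "cbv_gm_minus_wm": diff})
    return pd.DataFrame(rows)
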