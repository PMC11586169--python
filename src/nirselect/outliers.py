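"""Monte-Carlo outlier detection for multivariate calibration.

Samples whose reference value or spectrum is inconsistent with the bulk of the
data degrade a PLSR calibration. The scan repeats many random
calibration/validation splits; in each run a PLS model (LV count chosen by inner
RMSECV, capped) is fitted on the calibration part and absolute prediction errors
are recorded for the held-out samples. Over hundreds of runs every sample
accumulates an error distribution; outliers show up with anomalously large mean
and/or standard deviation of their prediction error and are flagged by a k-sigma
rule on either statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pls
from .containers import ReferenceTable, SpectrumSet

__all__ = ["OutlierReport", "mc_scan", "flag", "remove"]


@dataclass
class OutlierReport:
    """Per-sample prediction-error statistics over the Monte-Carlo runs."""

    sample_ids: list[str]
    mean_error: np.ndarray  # mean |prediction error| over held-out runs, % SSC
    std_error: np.ndarray  # sd of those errors, % SSC
    times_in_validation: np.ndarray
    k_sigma: float
    flagged_ids: list[str]
    error_table: np.ndarray = field(repr=False)  # (n_runs, n) with NaN when not held out
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "mean_error": self.mean_error,
                "std_error": self.std_error,
                "times_in_validation": self.times_in_validation,
                "flagged": [s in set(self.flagged_ids) for s in self.sample_ids],
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "mean_error": self.mean_error.tolist(),
            "std_error": self.std_error.tolist(),
            "times_in_validation": self.times_in_validation.tolist(),
            "k_sigma": self.k_sigma,
            "flagged_ids": self.flagged_ids,
            "params": self.params,
        }


def mc_scan(X: np.ndarray, y: np.ndarray, n_runs: int = 500,
            validation_fraction: float = 0.25, max_lv: int = 15, seed: int = 0,
            inner_cv: str | tuple = "kfold:5", sample_ids: list[str] | None = None,
            k_sigma: float = 2.5, min_appearances: int = 20,
            signed: bool = False) -> OutlierReport:
    """Monte-Carlo prediction-error scan.

    Parameters
    ----------
    n_runs
        Number of random splits (>= 100).
    validation_fraction
        Fraction held out per run, in (0, 0.5).
    max_lv
        Cap on the inner RMSECV LV search (kept modest for scan speed; the
        final calibration re-selects its LV count freely).
    inner_cv
        CV scheme for per-run LV selection; seeded 5-fold by default, "loo"
        for the exhaustive variant.
    signed
        Aggregate signed errors instead of absolute ones.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X rows and y length differ")
    if n_runs < 100:
        raise ValueError("n_runs must be >= 100")
    if not 0 < validation_fraction < 0.5:
        raise ValueError("validation_fraction must be in (0, 0.5)")
    if n < 10:
        raise ValueError("need at least 10 samples")
    ids = [str(s) for s in sample_ids] if sample_ids is not None else [str(i) for i in range(n)]
    n_val = max(1, int(round(validation_fraction * n)))
    rng = np.random.default_rng(seed)
    errors = np.full((n_runs, n), np.nan)
    n_cal = n - n_val
    if inner_cv == "loo":
        min_train = n_cal - 1
    else:
        k = int(str(inner_cv[1]) if isinstance(inner_cv, tuple)
                else (inner_cv.split(":")[1] if ":" in str(inner_cv) else 5))
        min_train = n_cal - int(np.ceil(n_cal / k))
    cap = max(1, min(max_lv, min_train - 1, X.shape[1]))
    for run in range(n_runs):
        perm = rng.permutation(n)
        val, cal = perm[:n_val], perm[n_val:]
        cv = pls.rmsecv(X[cal], y[cal], cap, cv=inner_cv, seed=run)
        model = pls.fit(X[cal], y[cal], cv.chosen_lv)
        e = pls.predict(model, X[val]) - y[val]
        errors[run, val] = e if signed else np.abs(e)
    counts = np.sum(~np.isnan(errors), axis=0)
    if np.any(counts < max(min_appearances, 2)):
        worst = ids[int(np.argmin(counts))]
        raise ValueError(
            f"sample {worst} held out only {int(counts.min())} times "
            f"(< {min_appearances}); raise n_runs"
        )
    with np.errstate(invalid="ignore"):
        mean_e = np.nanmean(errors, axis=0)
        std_e = np.nanstd(errors, axis=0, ddof=1)
    report = OutlierReport(
        sample_ids=ids,
        mean_error=mean_e,
        std_error=std_e,
        times_in_validation=counts,
        k_sigma=k_sigma,
        flagged_ids=[],
        error_table=errors,
        params={
            "n_runs": n_runs,
            "validation_fraction": validation_fraction,
            "max_lv": max_lv,
            "seed": seed,
            "inner_cv": pls._scheme_name(inner_cv),
            "signed": signed,
            "min_appearances": min_appearances,
        },
    )
    report.flagged_ids = flag(report, k_sigma)
    return report


def flag(report: OutlierReport, k_sigma: float = 2.5) -> list[str]:
    """Flag samples anomalous in either error statistic.

    A sample is flagged when its mean error exceeds ``mean + k_sigma*sd`` of all
    mean errors, OR its error sd exceeds the analogous bound on the sds. Errors
    below 1e-9 %SSC (far beyond refractometer precision) are numerically zero
    and never flagged.
    """
    if len(report.sample_ids) == 0:
        raise ValueError("empty report")
    floor = 1e-9
    me, se = report.mean_error, report.std_error
    thr_mean = max(me.mean() + k_sigma * me.std(ddof=0), floor)
    thr_std = max(se.mean() + k_sigma * se.std(ddof=0), floor)
    mask = (me > thr_mean) | (se > thr_std)
    return [s for s, m in zip(report.sample_ids, mask) if m]


def remove(sset: SpectrumSet, ref: ReferenceTable, flagged_ids: list[str]):
    """Drop flagged samples consistently from spectra and reference table."""
    unknown = [s for s in flagged_ids if s not in set(sset.sample_ids)]
    if unknown:
        raise KeyError(f"unknown sample ids: {unknown}")
    drop = set(flagged_ids)
    keep = [i for i, s in enumerate(sset.sample_ids) if s not in drop]
    step = f"outlier_removal(n_removed={sset.n_samples - len(keep)})"
    return sset.select_samples(keep, step), ref.select_samples(keep)
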