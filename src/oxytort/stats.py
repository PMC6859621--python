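"""Cohort-level statistics.

Per-segment oximetry and tortuosity measurements are averaged per eye and
vessel type, outliers are removed (mean +/- 3 SD within each diagnosis x
vessel-type stratum), and linear mixed models are fit with diagnosis, eye
and vessel type as fixed effects, age and mean arterial pressure (MAP) as
adjustment covariates, and a per-subject random intercept — both eyes of a
subject enter the model and the random intercept absorbs their correlation.
Shannon entropy and mutual information (equal-width histograms, log base 2)
summarize the information content shared by the two tortuosity metrics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import InvalidVitalsError, JoinError, ModelError

log = logging.getLogger(__name__)

METRICS = ("o2_content", "vti", "vii")


def map_from_bp(sbp: float, dbp: float) -> float:
    """Mean arterial pressure, MAP = (SBP + 2*DBP) / 3, mmHg."""
    if dbp <= 0 or sbp <= 0:
        raise InvalidVitalsError("blood pressures must be positive")
    if dbp > sbp:
        raise InvalidVitalsError(f"DBP ({dbp}) exceeds SBP ({sbp})")
    return (sbp + 2.0 * dbp) / 3.0


@dataclass
class LmmResult:
    """Summary of one linear mixed model fit."""

    response: str
    params: dict[str, tuple[float, float, float]]  # term -> (beta, se, p)
    group_var: float
    n_obs: int
    n_subjects: int
    method: str = "REML"
    singular: bool = False

    def beta(self, term_substr: str) -> tuple[float, float, float]:
        """(beta, se, p) for the first term whose name contains the substring."""
        for name, trip in self.params.items():
            if term_substr in name:
                return trip
        raise KeyError(term_substr)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": {
                k: {"beta": b, "se": s, "p": p} for k, (b, s, p) in self.params.items()
            },
            "group_var": self.group_var,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "method": self.method,
            "singular": self.singular,
        }


def aggregate(
    oximetry: pd.DataFrame,
    tortuosity: pd.DataFrame,
    subjects: pd.DataFrame,
) -> pd.DataFrame:
    """Per subject x eye x vessel-type means of O2 content, VTI and VII.

    Both measurement tables must carry ``subject_id``, ``eye`` and
    ``vessel_type`` columns and unique segment ids; subjects supply
    diagnosis, age and vitals (MAP is derived here).  Strata with no
    segments are simply absent from the output.
    """
    for name, df in (("oximetry", oximetry), ("tortuosity", tortuosity)):
        if df["segment_id"].duplicated().any():
            dupes = df.loc[df["segment_id"].duplicated(), "segment_id"].tolist()
            raise JoinError(f"duplicate segment ids in {name} table: {dupes[:5]}")
        missing = set(df["subject_id"]) - set(subjects["subject_id"])
        if missing:
            raise JoinError(f"{name} table references unknown subjects: {sorted(missing)[:5]}")

    keys = ["subject_id", "eye", "vessel_type"]
    ox = oximetry.groupby(keys, as_index=False).agg(
        o2_content=("o2_content", "mean"), so2=("so2", "mean")
    )
    tt = tortuosity.groupby(keys, as_index=False).agg(
        vti=("vti", "mean"), vii=("vii", "mean")
    )
    table = ox.merge(tt, on=keys, how="outer")

    subj = subjects.copy()
    subj["map_mmhg"] = [map_from_bp(s, d) for s, d in zip(subj["sbp"], subj["dbp"])]
    cols = ["subject_id", "diagnosis", "age", "hct", "map_mmhg"]
    table = table.merge(subj[cols], on="subject_id", how="left")
    return table.sort_values(keys).reset_index(drop=True)


def remove_outliers(
    table: pd.DataFrame,
    n_sd: float = 3.0,
    metrics: tuple[str, ...] = METRICS,
    min_rows: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows with any metric outside mean +/- n_sd * SD within its
    diagnosis x vessel-type stratum.

    Strata smaller than ``min_rows`` are left untouched (their SD estimate
    would be meaningless).  Returns the filtered table and a removal log
    with one row per (row, metric) violation.
    """
    drop_labels: set = set()
    log_rows = []
    for (diag, vtype), idx in table.groupby(["diagnosis", "vessel_type"]).groups.items():
        idx = np.asarray(idx)
        if len(idx) < min_rows:
            log.info("outlier rule skipped for stratum (%s, %s): n=%d", diag, vtype, len(idx))
            continue
        for metric in metrics:
            vals = table.loc[idx, metric].astype(float)
            mu, sd = vals.mean(), vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                continue
            lo, hi = mu - n_sd * sd, mu + n_sd * sd
            bad = idx[(vals < lo) | (vals > hi)]
            for b in bad:
                log_rows.append(
                    {
                        "row": int(b),
                        "subject_id": table.loc[b, "subject_id"],
                        "eye": table.loc[b, "eye"],
                        "vessel_type": vtype,
                        "metric": metric,
                        "value": float(table.loc[b, metric]),
                        "low": lo,
                        "high": hi,
                    }
                )
            drop_labels.update(bad.tolist())
    removal_log = pd.DataFrame(
        log_rows,
        columns=["row", "subject_id", "eye", "vessel_type", "metric", "value", "low", "high"],
    )
    kept = table.loc[~table.index.isin(drop_labels)].reset_index(drop=True)
    return kept, removal_log


def _fit_mixedlm(formula: str, data: pd.DataFrame, response: str, reml: bool = True) -> LmmResult:
    data = data.dropna(subset=[response]).copy()
    n_subjects = data["subject_id"].nunique()
    if data.groupby("diagnosis")["subject_id"].nunique().min() < 2 or n_subjects < 2:
        raise ModelError("need at least 2 subjects per diagnosis group")
    model = smf.mixedlm(formula, data, groups=data["subject_id"])
    singular = False
    method = "REML" if reml else "ML"
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit(reml=reml)
        if any("singular" in str(w.message).lower() or "converge" in str(w.message).lower()
               for w in caught):
            singular = True
    if singular and reml:
        log.warning("singular REML fit for %s; refitting by ML", response)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=False)
        method = "ML"
    params = {}
    for name in result.fe_params.index:
        params[name] = (
            float(result.fe_params[name]),
            float(result.bse_fe[name]),
            float(result.pvalues[name]),
        )
    return LmmResult(
        response=response,
        params=params,
        group_var=float(result.cov_re.iloc[0, 0]),
        n_obs=int(result.nobs),
        n_subjects=int(n_subjects),
        method=method,
        singular=singular,
    )


def fit_group_lmm(table: pd.DataFrame, response: str, reml: bool = True) -> LmmResult:
    """Mixed model of a response on diagnosis, eye and vessel type, adjusted
    for age and MAP, with a per-subject random intercept."""
    if response not in METRICS:
        raise ModelError(f"response must be one of {METRICS}, got {response!r}")
    formula = f"{response} ~ diagnosis + eye + vessel_type + age + map_mmhg"
    return _fit_mixedlm(formula, table, response, reml=reml)


def relate_o2_tortuosity(table: pd.DataFrame, metric: str, reml: bool = True) -> LmmResult:
    """Mixed model relating O2 content to a tortuosity metric (VTI or VII),
    accounting for vessel type and fellow eyes and adjusted for age and MAP.
    The metric's beta is the slope in mL O2/dL per metric unit."""
    if metric not in ("vti", "vii"):
        raise ModelError(f"metric must be 'vti' or 'vii', got {metric!r}")
    vals = table[metric].dropna()
    if vals.nunique() <= 1:
        raise ModelError(f"metric column {metric!r} is constant; design is rank deficient")
    formula = f"o2_content ~ {metric} + vessel_type + eye + age + map_mmhg"
    return _fit_mixedlm(formula, table, "o2_content", reml=reml)


# ---------------------------------------------------------------------------
# entropy and mutual information


def _n_bins(n: int, n_bins: int | None) -> int:
    return int(n_bins) if n_bins else max(int(math.ceil(math.sqrt(n))), 1)


def shannon_entropy(values, n_bins: int | None = None, base: float = 2.0) -> float:
    """Histogram Shannon entropy, H = -sum p_i log_base p_i.

    Equal-width bins over the data range; by default ceil(sqrt(n)) bins.
    Identical values collapse into one bin and give H = 0.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ModelError("entropy needs at least one finite value")
    k = _n_bins(v.size, n_bins)
    if v.max() == v.min():
        return 0.0
    counts, _ = np.histogram(v, bins=k)
    p = counts[counts > 0] / v.size
    return float(-np.sum(p * np.log(p) / np.log(base)))


def mutual_information(x, y, n_bins: int | None = None, base: float = 2.0) -> float:
    """Histogram mutual information between two samples (log base 2 bits).

    MI(x, y) = sum_ij p(x_i, y_j) log[ p(x_i, y_j) / (p(x_i) p(y_j)) ],
    evaluated on a joint equal-width histogram using each variable's own
    binning.  Nonnegative up to floating point rounding.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ModelError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ModelError("mutual information needs at least 2 paired values")
    k = _n_bins(x.size, n_bins)
    joint, _, _ = np.histogram2d(x, y, bins=(k, k))
    return mi_from_joint(joint / x.size, base=base)


def mi_from_joint(joint, base: float = 2.0) -> float:
    """Mutual information of a joint probability table (rows: x, cols: y)."""
    p = np.asarray(joint, float)
    if p.min() < 0:
        raise ModelError("joint table must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ModelError("joint table must have positive mass")
    p = p / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / (px * py), 1.0)
        terms = np.where(p > 0, p * np.log(ratio) / np.log(base), 0.0)
    return float(terms.sum())


# ---------------------------------------------------------------------------
# convenience demographic comparison (not a tested contract)


def demographics_report(subjects: pd.DataFrame) -> pd.DataFrame:
    """Unpaired t-tests (age, MAP, HCT) and a chi-square test (sex) between
    the NC and SCR groups; a thin convenience wrapper around scipy."""
    nc = subjects[subjects["diagnosis"] == "NC"]
    scr = subjects[subjects["diagnosis"] == "SCR"]
    rows = []
    subj = subjects.copy()
    subj["map_mmhg"] = [map_from_bp(s, d) for s, d in zip(subj["sbp"], subj["dbp"])]
    for col in ("age", "hct", "map_mmhg"):
        a = subj.loc[subj["diagnosis"] == "NC", col] if col == "map_mmhg" else nc[col]
        b = subj.loc[subj["diagnosis"] == "SCR", col] if col == "map_mmhg" else scr[col]
        t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append({"variable": col, "test": "t", "statistic": float(t), "p": float(p)})
    if "sex" in subjects.columns:
        tab = pd.crosstab(subjects["diagnosis"], subjects["sex"])
        if tab.shape == (2, 2):
            chi2, p, _, _ = sps.chi2_contingency(tab)
            rows.append({"variable": "sex", "test": "chi2", "statistic": float(chi2), "p": float(p)})
    return pd.DataFrame(rows)
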