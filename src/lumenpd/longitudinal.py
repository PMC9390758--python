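"""Longitudinal statistics linking luminal pressure difference to growth.

The analysis unit is one (patient, consecutive-scan interval, plane)
record holding the equivalent yearly aortic growth rate at that plane
and the maximum TL-FL pressure difference simulated on the earlier scan
of the interval.  The growth model is a linear mixed-effects regression

    growth ~ PD + C(interval) + C(plane),  random intercept per patient,

fitted by restricted maximum likelihood (REML): scan interval and plane
location enter as nominal fixed effects (reference-level dummy coding),
the pressure difference as a continuous fixed effect, and the intercept
as the sole random effect.  A receiver operating characteristic curve
over the PD values yields the optimal cut-off separating stable from
unstable (> 2.9 mm/yr) growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm

from .geometry import UNSTABLE_GROWTH_THRESHOLD, classify_growth, growth_rate

__all__ = [
    "GrowthRecord",
    "LmmFit",
    "RocResult",
    "StatsError",
    "records_to_frame",
    "assemble_records",
    "fit_lmm",
    "roc_threshold",
]

RECORD_COLUMNS = [
    "patient_id",
    "scan_index",
    "interval_index",
    "plane_id",
    "time_months",
    "pd_max_mmHg",
    "growth_mm_per_yr",
    "unstable",
]


class StatsError(ValueError):
    """Raised for statistically unusable input (missing classes, singular fits)."""


@dataclass(frozen=True)
class GrowthRecord:
    """One (patient, interval, plane) observation."""

    patient_id: str
    interval_index: int
    plane_id: str
    time_months: float
    pd_max_mmHg: float
    growth_mm_per_yr: float

    @property
    def unstable(self) -> bool:
        return classify_growth(self.growth_mm_per_yr) == "unstable"


@dataclass
class LmmFit:
    """REML mixed-effects fit summary.

    ``pd_coefficient`` is in mm/yr per mmHg; ``fixed_effects`` holds all
    fixed-effect estimates (intercept, interval and plane indicators).
    """

    pd_coefficient: float
    ci_lower: float
    ci_upper: float
    p_value: float
    fixed_effects: dict[str, float]
    random_intercept_var: float
    residual_var: float
    converged: bool
    method: str
    n_records: int
    log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RocResult:
    """Empirical ROC over PD thresholds (rule: unstable if PD > threshold)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    criterion: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_mmHg": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def records_to_frame(records) -> pd.DataFrame:
    """Normalise a list of GrowthRecord / a DataFrame to the record schema."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "interval_index": r.interval_index,
                    "plane_id": r.plane_id,
                    "time_months": r.time_months,
                    "pd_max_mmHg": r.pd_max_mmHg,
                    "growth_mm_per_yr": r.growth_mm_per_yr,
                }
                for r in records
            ]
        )
    if "unstable" not in df.columns:
        df["unstable"] = df["growth_mm_per_yr"] > UNSTABLE_GROWTH_THRESHOLD
    return df


# ---------------------------------------------------------------------------
# record assembly
# ---------------------------------------------------------------------------


def assemble_records(
    measurements: pd.DataFrame,
    pd_table: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Join per-plane diameters and simulated PD into growth records.

    Parameters
    ----------
    measurements
        Columns ``patient_id, scan_index, time_months, plane_id,
        diameter_mm`` — one row per plane per scan.
    pd_table
        Columns ``patient_id, scan_index, plane_id, pd_max_mmHg`` for
        every scan that was simulated (all but the last of each patient);
        ``NaN`` marks a plane whose FL pressure is unavailable
        (thrombosed / outside the flow domain).

    Returns the record table (one row per patient, consecutive-scan
    interval and plane, PD taken from the earlier scan) and the number of
    records dropped for missing FL pressure.
    """
    records = []
    n_dropped = 0
    pd_idx = pd_table.set_index(["patient_id", "scan_index", "plane_id"])[
        "pd_max_mmHg"
    ]
    for pid, g in measurements.groupby("patient_id", sort=False):
        scans = sorted(g["scan_index"].unique())
        for interval, (s0, s1) in enumerate(zip(scans[:-1], scans[1:]), start=1):
            g0 = g[g["scan_index"] == s0].set_index("plane_id")
            g1 = g[g["scan_index"] == s1].set_index("plane_id")
            if set(g0.index) != set(g1.index):
                raise StatsError(
                    f"patient {pid}: plane sets differ between scans {s0} and {s1}"
                )
            t0 = float(g0["time_months"].iloc[0])
            t1 = float(g1["time_months"].iloc[0])
            for plane in g0.index:
                try:
                    pd_val = pd_idx.loc[(pid, s0, plane)]
                except KeyError:
                    pd_val = np.nan
                if not np.isfinite(pd_val):
                    n_dropped += 1
                    continue
                rate = growth_rate(
                    g0.loc[plane, "diameter_mm"],
                    g1.loc[plane, "diameter_mm"],
                    t0,
                    t1,
                )
                records.append(
                    {
                        "patient_id": pid,
                        "scan_index": s0,
                        "interval_index": interval,
                        "plane_id": plane,
                        "time_months": t0,
                        "pd_max_mmHg": float(pd_val),
                        "growth_mm_per_yr": rate,
                        "unstable": rate > UNSTABLE_GROWTH_THRESHOLD,
                    }
                )
    if not records:
        warnings.warn("no usable records: all planes lacked FL pressure")
        return pd.DataFrame(columns=RECORD_COLUMNS), n_dropped
    return pd.DataFrame(records, columns=RECORD_COLUMNS), n_dropped


# ---------------------------------------------------------------------------
# mixed-effects fit
# ---------------------------------------------------------------------------

_FORMULA = "growth_mm_per_yr ~ pd_max_mmHg + C(interval_index) + C(plane_id)"


def fit_lmm(
    records, alpha: float = 0.05, random_intercept: bool = True
) -> LmmFit:
    """REML linear mixed-effects fit of growth on pressure difference.

    Fixed effects: PD (continuous), interval and plane indicators
    (reference-level dummy coding); random effect: per-patient intercept.
    The confidence interval and p-value for the PD coefficient are Wald
    (normal) based; a perfectly noise-free table (zero residual variance,
    where the REML criterion degenerates) is detected and returned as the
    exact least-squares limit.  ``random_intercept=False`` constrains the
    intercept variance to zero, in which limit the model is ordinary
    least squares.
    """
    df = records_to_frame(records)
    if df["patient_id"].nunique() < 2:
        raise StatsError("need at least 2 patients for a mixed-effects fit")
    if df["interval_index"].nunique() < 2:
        raise StatsError("need at least 2 scan intervals")
    if df[["pd_max_mmHg", "growth_mm_per_yr"]].isna().any().any():
        raise StatsError("records contain missing PD or growth values")

    log: list[str] = ["CI/p: Wald, normal reference (no Satterthwaite df in backend)"]

    # degenerate noise-free limit: REML variance components vanish and the
    # fixed effects reduce to exact OLS
    ols = smf.ols(_FORMULA, data=df).fit()
    if not random_intercept:
        ci = ols.conf_int(alpha).loc["pd_max_mmHg"]
        log.append("random-intercept variance constrained to 0: OLS limit")
        return LmmFit(
            pd_coefficient=float(ols.params["pd_max_mmHg"]),
            ci_lower=float(ci[0]),
            ci_upper=float(ci[1]),
            p_value=float(ols.pvalues["pd_max_mmHg"]),
            fixed_effects={k: float(v) for k, v in ols.params.items()},
            random_intercept_var=0.0,
            residual_var=float(ols.mse_resid),
            converged=True,
            method="OLS (zero random-intercept variance)",
            n_records=len(df),
            log=log,
        )
    resid_var = float(ols.mse_resid) if ols.df_resid > 0 else 0.0
    scale_ref = max(1.0, float(np.var(df["growth_mm_per_yr"])))
    if resid_var < 1e-16 * scale_ref:
        log.append("zero residual variance: exact least-squares limit returned")
        coef = float(ols.params["pd_max_mmHg"])
        return LmmFit(
            pd_coefficient=coef,
            ci_lower=coef,
            ci_upper=coef,
            p_value=0.0 if coef != 0 else 1.0,
            fixed_effects={k: float(v) for k, v in ols.params.items()},
            random_intercept_var=0.0,
            residual_var=0.0,
            converged=True,
            method="REML (degenerate noise-free limit)",
            n_records=len(df),
            log=log,
        )

    model = smf.mixedlm(_FORMULA, data=df, groups=df["patient_id"])
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for opt in ("lbfgs", "cg", "powell"):
            try:
                cand = model.fit(reml=True, method=opt)
            except np.linalg.LinAlgError as exc:
                raise StatsError(f"singular mixed-effects fit: {exc}") from exc
            if cand.converged:
                fit = cand
                if opt != "lbfgs":
                    log.append(f"optimizer fallback: {opt}")
                break
    if fit is None:
        raise StatsError(
            "REML did not converge under any optimizer; variance components: "
            f"group var={float(cand.cov_re.iloc[0, 0]):.3e}, "
            f"residual={float(cand.scale):.3e}"
        )
    z = float(norm.ppf(1 - alpha / 2))
    coef = float(fit.params["pd_max_mmHg"])
    se = float(fit.bse["pd_max_mmHg"])
    return LmmFit(
        pd_coefficient=coef,
        ci_lower=coef - z * se,
        ci_upper=coef + z * se,
        p_value=float(fit.pvalues["pd_max_mmHg"]),
        fixed_effects={
            k: float(v) for k, v in fit.fe_params.items()
        },
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        residual_var=float(fit.scale),
        converged=True,
        method="REML",
        n_records=len(df),
        log=log,
    )


# ---------------------------------------------------------------------------
# ROC threshold
# ---------------------------------------------------------------------------


def roc_threshold(records, criterion: str = "youden") -> RocResult:
    """Empirical ROC of PD against the unstable-growth label.

    A record is predicted unstable when its PD exceeds the threshold;
    thresholds run over the unique PD values.  The optimal cut-off
    maximises Youden's J = sensitivity + specificity - 1, ties broken
    toward the lower threshold.  The AUC is the trapezoidal area, which
    equals the normalised Mann-Whitney rank statistic.
    """
    if criterion != "youden":
        raise ValueError(f"unsupported ROC criterion {criterion!r}")
    df = records_to_frame(records)
    y = df["unstable"].to_numpy(dtype=bool)
    x = df["pd_max_mmHg"].to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatsError(
            f"both growth classes required (unstable={n_pos}, stable={n_neg})"
        )
    thresholds = np.unique(x)
    pred = x[None, :] > thresholds[:, None]
    sens = (pred & y).sum(axis=1) / n_pos
    spec = (~pred & ~y).sum(axis=1) / n_neg
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)[0]  # thresholds ascending
    # trapezoidal AUC over the full curve, endpoints included
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        cutoff=float(thresholds[best]),
        criterion=criterion,
    )
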