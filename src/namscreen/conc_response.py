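"""Vehicle normalization, assay QC, logistic curve fitting, and 1-SD POD derivation.

The point of departure (POD) for a chemical x phenotype pair is the lowest
concentration at which the fitted concentration-response curve departs from
the vehicle-control mean by one vehicle standard deviation — a benchmark
response anchored to assay noise rather than to an arbitrary percent effect.
PODs with no benchmark crossing inside the tested range are right-censored at
the highest tested concentration and kept, not dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import VEHICLE, hill_response

log = logging.getLogger(__name__)

MEDIUM = "medium"  # second negative control (cell medium only), when present


class QCError(ValueError):
    """Raised when required control wells are missing."""


class DegenerateInputError(ValueError):
    """Raised on inputs that make a quantity undefined (zero mean, zero SD)."""


class InsufficientDataError(ValueError):
    """Raised when too few concentrations are available for a curve fit."""


# ---------------------------------------------------------------------------
# Normalization


@dataclass(frozen=True)
class VehicleStats:
    """Row schema of the vehicle-stats table returned by
    :func:`normalize_to_vehicle`."""

    plate: str
    phenotype: str
    mean: float  # =100 after normalization
    sd: float  # % of control
    n: int


def normalize_to_vehicle(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Express every well as % of its plate/phenotype-matched vehicle mean.

    Returns the normalized table and a vehicle-stats table (one row per
    plate x phenotype, with the vehicle SD rescaled to % of control).
    Raises :class:`QCError` when a plate/phenotype has fewer than two vehicle
    wells and :class:`DegenerateInputError` on a zero vehicle mean.
    """
    out = raw.copy()
    stats_rows = []
    for (plate, pheno), grp in raw.groupby(["plate", "phenotype"], sort=True):
        veh = grp.loc[grp["chemical"] == VEHICLE, "response_pct"]
        if len(veh) < 2:
            raise QCError(f"fewer than 2 vehicle wells on plate {plate!r}, phenotype {pheno!r}")
        mu = float(veh.mean())
        if mu == 0:
            raise DegenerateInputError(
                f"vehicle mean is zero on plate {plate!r}, phenotype {pheno!r}"
            )
        sd = float(veh.std(ddof=1))
        mask = (out["plate"] == plate) & (out["phenotype"] == pheno)
        out.loc[mask, "response_pct"] = raw.loc[mask, "response_pct"] / mu * 100.0
        stats_rows.append(
            {
                "plate": plate,
                "phenotype": pheno,
                "mean": 100.0,
                "sd": abs(sd / mu) * 100.0,
                "n": int(len(veh)),
            }
        )
    return out, pd.DataFrame(stats_rows)


# ---------------------------------------------------------------------------
# Curve fitting


@dataclass(frozen=True)
class FitConfig:
    ec50_bounds: tuple[float, float] = (1e-4, 1e4)  # uM
    hill_bounds: tuple[float, float] = (0.3, 8.0)
    response_bounds: tuple[float, float] = (-100.0, 400.0)  # % control, generous


@dataclass(frozen=True)
class HillFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    direction: str | None  # None when flat
    rss: float
    converged: bool
    n_points: int

    def predict(self, conc):
        return hill_response(conc, self.bottom, self.top, self.ec50, self.hill)


def fit_hill(conc, response, config: FitConfig = FitConfig()) -> HillFit:
    """Least-squares four-parameter logistic fit on log10 concentration.

    All replicate points are used (no pre-averaging).  Points at
    concentration 0 (vehicle wells) observe the bottom asymptote directly
    and anchor the fitted baseline; the curve itself is fitted over the
    positive concentrations, of which >= 4 distinct values are required.
    Three starts seed the EC50 at the lowest, median, and highest tested
    concentration; the best residual wins.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    pos = conc > 0
    conc, response, baseline = conc[pos], response[pos], response[~pos]
    distinct = np.unique(conc)
    if distinct.size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct concentrations, got {distinct.size}"
        )
    if not (np.all(np.isfinite(response)) and np.all(np.isfinite(baseline))):
        raise DegenerateInputError("non-finite responses")

    lo = np.array(
        [config.response_bounds[0], config.response_bounds[0],
         np.log10(config.ec50_bounds[0]), config.hill_bounds[0]]
    )
    hi = np.array(
        [config.response_bounds[1], config.response_bounds[1],
         np.log10(config.ec50_bounds[1]), config.hill_bounds[1]]
    )

    log_conc = np.log10(conc)
    ln10 = np.log(10.0)
    n_base = baseline.size

    def residuals(params):
        bottom, top, log_ec50, hill = params
        r = hill_response(conc, bottom, top, 10.0 ** log_ec50, hill) - response
        if n_base:
            r = np.concatenate([r, bottom - baseline])
        return r

    def jacobian(params):
        bottom, top, log_ec50, hill = params
        q = 10.0 ** ((log_ec50 - log_conc) * hill)  # (ec50/c)^h
        u = 1.0 / (1.0 + q)
        span = top - bottom
        duv = -u * (1.0 - u)  # d u / d log10(ec50/c), up to the h*ln10 factor
        jac = np.column_stack(
            [
                1.0 - u,
                u,
                span * duv * hill * ln10,
                span * duv * (log_ec50 - log_conc) * ln10,
            ]
        )
        if n_base:
            base_rows = np.zeros((n_base, 4))
            base_rows[:, 0] = 1.0
            jac = np.vstack([jac, base_rows])
        return jac

    low_mean = float(response[conc == distinct[0]].mean())
    high_mean = float(response[conc == distinct[-1]].mean())
    starts = [
        np.array([low_mean, high_mean, np.log10(s), 1.0])
        for s in (distinct[0], np.median(distinct), distinct[-1])
    ]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = optimize.least_squares(
                residuals, x0, jac=jacobian, bounds=(lo, hi), method="trf"
            )
        except Exception:  # pragma: no cover - optimizer blowup
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")

    bottom, top, log_ec50, hill = best.x
    direction: str | None
    if top > bottom:
        direction = "increasing"
    elif top < bottom:
        direction = "decreasing"
    else:
        direction = None
    return HillFit(
        bottom=float(bottom),
        top=float(top),
        ec50=float(10.0 ** log_ec50),
        hill=float(hill),
        direction=direction,
        rss=float(2.0 * best.cost),
        converged=bool(best.success),
        n_points=int(conc.size),
    )


# ---------------------------------------------------------------------------
# POD derivation


@dataclass(frozen=True)
class PODResult:
    pod: float  # uM; censoring bound when censored
    censored: bool
    side: str | None  # "above" | "below" benchmark crossing side
    below_range: bool  # crossing at/under the extrapolation floor
    method: str = "fit"  # "fit" | "interpolation"


#: Extrapolation floor: one decade below the lowest tested concentration of
#: the standard 0.01-100 uM series.  Crossings below it are reported at the
#: floor and flagged, never extrapolated further.
MIN_CONC = 1e-3


def derive_pod(
    fit: HillFit,
    sigma_v: float,
    max_conc: float,
    mu_v: float = 100.0,
    min_conc: float = MIN_CONC,
) -> PODResult:
    """Lowest concentration where the fitted curve departs from the vehicle
    mean by one vehicle SD, found by bracketed root-finding on the fit.

    Censored at ``max_conc`` when no crossing exists in (0, max_conc].
    """
    if sigma_v <= 0:
        raise DegenerateInputError("vehicle SD must be > 0 to define the benchmark")

    def excess(c):
        return abs(float(fit.predict(c)) - mu_v) - sigma_v

    grid = np.logspace(np.log10(min_conc), np.log10(max_conc), 256)
    vals = np.abs(np.asarray(fit.predict(grid), dtype=float) - mu_v) - sigma_v
    if vals[0] >= 0:
        side = "above" if float(fit.predict(min_conc)) >= mu_v else "below"
        return PODResult(min_conc, False, side, True)
    cross = np.nonzero(vals >= 0)[0]
    if cross.size == 0:
        return PODResult(max_conc, True, None, False)
    i = int(cross[0])
    pod = float(optimize.brentq(excess, grid[i - 1], grid[i], xtol=1e-12, rtol=1e-12))
    side = "above" if float(fit.predict(pod)) >= mu_v else "below"
    return PODResult(pod, False, side, False)


def pod_interpolated(
    conc, response, sigma_v: float, max_conc: float, mu_v: float = 100.0
) -> PODResult:
    """Nonparametric fallback: linear interpolation of concentration-wise mean
    responses on log10 concentration to locate the benchmark crossing."""
    if sigma_v <= 0:
        raise DegenerateInputError("vehicle SD must be > 0 to define the benchmark")
    df = pd.DataFrame({"conc": np.asarray(conc, float), "resp": np.asarray(response, float)})
    df = df[df["conc"] > 0]
    means = df.groupby("conc")["resp"].mean().sort_index()
    x = np.log10(means.index.to_numpy())
    y = np.abs(means.to_numpy() - mu_v) - sigma_v
    if y[0] >= 0:
        side = "above" if means.iloc[0] >= mu_v else "below"
        return PODResult(float(means.index[0]), False, side, True, method="interpolation")
    idx = np.nonzero(y >= 0)[0]
    if idx.size == 0:
        return PODResult(max_conc, True, None, False, method="interpolation")
    i = int(idx[0])
    t = -y[i - 1] / (y[i] - y[i - 1])
    pod = float(10.0 ** (x[i - 1] + t * (x[i] - x[i - 1])))
    side = "above" if means.iloc[i] >= mu_v else "below"
    return PODResult(pod, False, side, False, method="interpolation")


def pod_table(
    normalized: pd.DataFrame,
    vehicle_stats: pd.DataFrame,
    config: FitConfig = FitConfig(),
) -> pd.DataFrame:
    """Fit every chemical x phenotype series and derive its POD.

    Returns the pipeline's central exchange table with one row per chemical,
    cell type and phenotype: ``pod_uM``, ``censored``, ``side``,
    ``below_range``, ``method``, plus the fitted curve parameters.
    Non-converged fits fall back to nonparametric interpolation.
    """
    sd_map = {(r.plate, r.phenotype): (r.sd) for r in vehicle_stats.itertuples()}
    vehicle_wells = {
        key: grp["response_pct"].to_numpy()
        for key, grp in normalized[normalized["chemical"] == VEHICLE].groupby(
            ["plate", "phenotype"], sort=False
        )
    }
    treated = normalized[~normalized["chemical"].isin([VEHICLE, MEDIUM])]
    rows = []
    for (chem, cls, cell_type, pheno, category, plate), grp in treated.groupby(
        ["chemical", "chem_class", "cell_type", "phenotype", "category", "plate"], sort=True
    ):
        sigma_v = sd_map.get((plate, pheno))
        if sigma_v is None:
            raise QCError(f"no vehicle stats for plate {plate!r}, phenotype {pheno!r}")
        if sigma_v == 0:
            raise DegenerateInputError(
                f"vehicle SD is zero on plate {plate!r}, phenotype {pheno!r}"
            )
        conc = grp["conc_uM"].to_numpy()
        resp = grp["response_pct"].to_numpy()
        veh = vehicle_wells.get((plate, pheno), np.empty(0))
        max_conc = float(conc.max())
        fit = fit_hill(
            np.concatenate([conc, np.zeros(veh.size)]),
            np.concatenate([resp, veh]),
            config,
        )
        if fit.converged:
            pr = derive_pod(fit, sigma_v, max_conc)
        else:
            pr = pod_interpolated(conc, resp, sigma_v, max_conc)
        rows.append(
            {
                "chemical": chem,
                "chem_class": cls,
                "cell_type": cell_type,
                "phenotype": pheno,
                "category": category,
                "pod_uM": pr.pod,
                "censored": pr.censored,
                "side": pr.side,
                "below_range": pr.below_range,
                "method": pr.method,
                "fit_bottom": fit.bottom,
                "fit_top": fit.top,
                "fit_ec50_uM": fit.ec50,
                "fit_hill": fit.hill,
                "fit_converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Assay QC


@dataclass(frozen=True)
class QCThresholds:
    max_negative_control_cv: float = 15.0  # % CV
    difference_alpha: float = 0.05  # vehicle-vs-medium two-sample test
    min_replicate_correlation: float = 0.8
    positive_controls: dict = field(default_factory=dict)
    # cell_type -> (chemical id, (ec50_lo, ec50_hi) window in uM)


def _correlation_of_replicates(grp: pd.DataFrame) -> float | None:
    wide = grp.pivot_table(
        index=["chemical", "conc_uM"], columns="replicate", values="response_pct"
    )
    wide = wide.dropna()
    if wide.shape[0] < 3 or wide.shape[1] < 2:
        return None
    cors = []
    cols = list(wide.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = np.corrcoef(wide[cols[i]], wide[cols[j]])[0, 1]
            if np.isfinite(r):
                cors.append(r)
    return float(np.mean(cors)) if cors else None


def qc_assay(measurements: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Five-parameter assay quality-control report.

    Parameters: (i) replicate-well variance of both negative controls,
    (ii) vehicle-vs-medium difference, (iii) intra-plate and (iv) inter-plate
    replicate correlation, (v) positive-control EC50 inside its expected
    window.  Checks whose data are absent are reported ``not-evaluable``,
    never silently passed.  Always returns a report; never raises.
    """
    rows = []

    def add(plate, pheno, parameter, value, passed):
        rows.append(
            {
                "plate": plate,
                "phenotype": pheno,
                "parameter": parameter,
                "value": value,
                "status": "not-evaluable" if passed is None else ("pass" if passed else "fail"),
            }
        )

    for (plate, pheno), grp in measurements.groupby(["plate", "phenotype"], sort=True):
        for label, chem_id in (("vehicle_cv", VEHICLE), ("medium_cv", MEDIUM)):
            wells = grp.loc[grp["chemical"] == chem_id, "response_pct"]
            if len(wells) < 2 or wells.mean() == 0:
                add(plate, pheno, label, np.nan, None)
            else:
                cv = abs(wells.std(ddof=1) / wells.mean()) * 100.0
                add(plate, pheno, label, cv, cv <= thresholds.max_negative_control_cv)

        veh = grp.loc[grp["chemical"] == VEHICLE, "response_pct"]
        med = grp.loc[grp["chemical"] == MEDIUM, "response_pct"]
        if len(veh) >= 2 and len(med) >= 2:
            t, p = stats.ttest_ind(veh, med, equal_var=False)
            add(plate, pheno, "vehicle_vs_medium", p, p > thresholds.difference_alpha)
        else:
            add(plate, pheno, "vehicle_vs_medium", np.nan, None)

        treated = grp[~grp["chemical"].isin([VEHICLE, MEDIUM])]
        r = _correlation_of_replicates(treated)
        if r is None:
            add(plate, pheno, "intra_plate_correlation", np.nan, None)
        else:
            add(plate, pheno, "intra_plate_correlation", r, r >= thresholds.min_replicate_correlation)

    # inter-plate: same phenotype + cell type measured on >= 2 plates
    treated = measurements[~measurements["chemical"].isin([VEHICLE, MEDIUM])]
    for (cell_type, pheno), grp in treated.groupby(["cell_type", "phenotype"], sort=True):
        plates = sorted(grp["plate"].unique())
        if len(plates) < 2:
            add(plates[0] if plates else "", pheno, "inter_plate_correlation", np.nan, None)
            continue
        wide = grp.pivot_table(index=["chemical", "conc_uM"], columns="plate", values="response_pct")
        wide = wide.dropna()
        cors = []
        for i in range(len(plates)):
            for j in range(i + 1, len(plates)):
                r = np.corrcoef(wide[plates[i]], wide[plates[j]])[0, 1]
                if np.isfinite(r):
                    cors.append(r)
        value = float(np.mean(cors)) if cors else np.nan
        add(
            "+".join(plates),
            pheno,
            "inter_plate_correlation",
            value,
            None if not cors else value >= thresholds.min_replicate_correlation,
        )

    # positive control EC50 windows
    for cell_type, (chem, (lo, hi)) in thresholds.positive_controls.items():
        sub = measurements[
            (measurements["cell_type"] == cell_type) & (measurements["chemical"] == chem)
        ]
        if sub.empty:
            add("", f"positive_control:{cell_type}", "positive_control_ec50", np.nan, None)
            continue
        for pheno, grp in sub.groupby("phenotype", sort=True):
            try:
                fit = fit_hill(grp["conc_uM"], grp["response_pct"])
            except (InsufficientDataError, DegenerateInputError):
                add("", f"{cell_type}:{pheno}", "positive_control_ec50", np.nan, None)
                continue
            add("", f"{cell_type}:{pheno}", "positive_control_ec50", fit.ec50, lo <= fit.ec50 <= hi)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Functional vs cytotoxicity contrast


def phenotype_category_contrast(pods: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum comparison of functional vs cytotoxicity POD distributions.

    One-sided Mann-Whitney test of whether functional PODs are lower (more
    sensitive) than cytotoxicity PODs, per cell type and pooled.  Censored
    PODs enter at their censoring bound, which is conservative for the
    one-sided alternative.
    """
    rows = []
    groups = [("all", pods)] + [(ct, g) for ct, g in pods.groupby("cell_type", sort=True)]
    for label, grp in groups:
        fun = grp.loc[grp["category"] == "functional", "pod_uM"].to_numpy()
        cyt = grp.loc[grp["category"] == "cytotoxicity", "pod_uM"].to_numpy()
        if fun.size == 0 or cyt.size == 0:
            rows.append(
                {
                    "cell_type": label,
                    "n_functional": int(fun.size),
                    "n_cytotoxicity": int(cyt.size),
                    "statistic": np.nan,
                    "p_one_sided": np.nan,
                    "status": "not-evaluable",
                }
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u, p = stats.mannwhitneyu(fun, cyt, alternative="less")
        rows.append(
            {
                "cell_type": label,
                "n_functional": int(fun.size),
                "n_cytotoxicity": int(cyt.size),
                "statistic": float(u),
                "p_one_sided": float(p),
                "status": "low-n" if min(fun.size, cyt.size) < 5 else "ok",
            }
        )
    return pd.DataFrame(rows)
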