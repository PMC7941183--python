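"""NAM-POD-based risk screening: reverse dosimetry and margins of exposure.

In vitro PODs (uM) become administered equivalent doses (AED, mg/kg/day) by
dividing by a chemical-specific steady-state plasma concentration at unit
oral dose (Css per 1 mg/kg/day, upper-95th-percentile toxicokinetic
variability), assuming linear dose-to-Css kinetics.  AEDs are compared to
exposure estimates as margins of exposure (MoE = AED / exposure); MoE < 100
(strict) flags potential concern.  Css factors are consumed as an input
table; toxicokinetic modeling itself is out of scope here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MOE_BENCHMARK = 100.0

UNIT_CONC = "uM"
UNIT_DOSE = "mg/kg/day"


class UnitError(ValueError):
    """Raised when declared units of paired quantities disagree."""


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class TKExposureRecord:
    """Toxicokinetic and exposure inputs for one chemical (supplied, not computed)."""

    chemical: str
    css_per_unit_dose: float  # uM steady state per 1 mg/kg/day oral dose
    exposure: float = 0.0  # mg/kg/day
    pod_rfd: float | None = None  # in vivo POD underlying the RfD, mg/kg/day

    def __post_init__(self) -> None:
        if self.css_per_unit_dose <= 0:
            raise InputError("css_per_unit_dose must be > 0")
        if self.exposure < 0:
            raise InputError("exposure must be >= 0")


def surrogate_pod(pods: pd.DataFrame, scope: str = "all") -> pd.DataFrame:
    """Most-sensitive (minimum) POD per chemical, within one cell type or all.

    Censored PODs never win the minimum while a finite POD exists; a chemical
    whose in-scope PODs are all censored gets a censored surrogate at its
    censoring bound (a lower bound on the true POD), flagged.
    """
    if scope != "all":
        pods = pods[pods["cell_type"] == scope]
        if pods.empty:
            raise InputError(f"no phenotypes in scope {scope!r}")
    if pods.empty:
        raise InputError("empty POD table")
    rows = []
    for chem, grp in pods.groupby("chemical", sort=True):
        finite = grp[~grp["censored"]]
        if finite.empty:
            rows.append(
                {
                    "chemical": chem,
                    "scope": scope,
                    "pod_uM": float(grp["pod_uM"].max()),
                    "censored": True,
                }
            )
        else:
            rows.append(
                {
                    "chemical": chem,
                    "scope": scope,
                    "pod_uM": float(finite["pod_uM"].min()),
                    "censored": False,
                }
            )
    return pd.DataFrame(rows)


def pod_to_aed(pod_uM: float, record: TKExposureRecord) -> float:
    """Administered equivalent dose (mg/kg/day) of a uM POD, assuming linear
    dose-to-Css kinetics: AED = POD / Css_per_unit_dose."""
    return pod_uM / record.css_per_unit_dose


def dose_to_css(dose_mgkgday: float, record: TKExposureRecord) -> float:
    """Inverse conversion: steady-state concentration (uM) at an oral dose."""
    return dose_mgkgday * record.css_per_unit_dose


def conservatism_comparison(
    nam_pods: pd.Series,
    in_vivo_pods: pd.Series,
    nam_unit: str = UNIT_DOSE,
    in_vivo_unit: str = UNIT_DOSE,
) -> dict:
    """Distribution of log10(NAM POD / in vivo POD) over paired chemicals.

    A NAM POD strictly above the in vivo POD is "unconservative" (it would
    underestimate in vivo potency).  Reports the per-chemical ratios, the
    unconservative fraction, and — among unconservative chemicals — the
    fraction within 10-fold of the in vivo value.  Pairs with a missing side
    are excluded pairwise with a logged count.
    """
    if nam_unit != in_vivo_unit:
        raise UnitError(f"unit mismatch: NAM in {nam_unit!r}, in vivo in {in_vivo_unit!r}")
    nam = pd.Series(nam_pods, dtype=float)
    vivo = pd.Series(in_vivo_pods, dtype=float)
    common = nam.index.intersection(vivo.index)
    paired = pd.DataFrame({"nam": nam.reindex(common), "in_vivo": vivo.reindex(common)}).dropna()
    dropped = len(set(nam.index) | set(vivo.index)) - len(paired)
    if dropped:
        log.info("conservatism comparison: %d chemicals excluded pairwise", dropped)
    if paired.empty:
        raise InputError("no paired NAM / in vivo POD values")
    ratios = np.log10(paired["nam"] / paired["in_vivo"])
    unconservative = paired["nam"] > paired["in_vivo"]
    n_uncons = int(unconservative.sum())
    within_10 = (
        float((ratios[unconservative] <= 1.0).mean()) if n_uncons else float("nan")
    )
    return {
        "log10_ratios": ratios,
        "n": int(len(paired)),
        "fraction_unconservative": n_uncons / len(paired),
        "fraction_unconservative_within_10fold": within_10,
    }


def margin_of_exposure(
    surrogates: pd.DataFrame,
    records: dict[str, TKExposureRecord],
    benchmark: float = MOE_BENCHMARK,
    conservative: bool = True,
) -> pd.DataFrame:
    """MoE = AED / exposure per chemical, with potential-concern flags.

    Strict inequality: MoE < benchmark flags concern; MoE exactly at the
    benchmark does not.  Zero exposure yields an infinite MoE (never
    flagged).  A censored surrogate POD yields an AED and MoE that are lower
    bounds; in ``conservative`` mode the flag fires when the bound is below
    the benchmark, otherwise bounded chemicals are never flagged.  Chemicals
    without a toxicokinetic record are dropped with a logged count.
    """
    rows = []
    dropped = 0
    for row in surrogates.itertuples():
        rec = records.get(row.chemical)
        if rec is None:
            dropped += 1
            continue
        if rec.exposure < 0:
            raise InputError(f"negative exposure for {row.chemical}")
        aed = pod_to_aed(row.pod_uM, rec)
        moe = math.inf if rec.exposure == 0 else aed / rec.exposure
        if math.isinf(moe):
            concern = False
        elif row.censored:
            concern = conservative and moe < benchmark
        else:
            concern = moe < benchmark
        rows.append(
            {
                "chemical": row.chemical,
                "scope": row.scope,
                "pod_uM": row.pod_uM,
                "pod_aed_mgkgday": aed,
                "exposure_mgkgday": rec.exposure,
                "moe": moe,
                "moe_is_lower_bound": bool(row.censored),
                "concern": bool(concern),
                "pod_unit": UNIT_CONC,
                "dose_unit": UNIT_DOSE,
            }
        )
    if dropped:
        log.info("margin_of_exposure: %d chemicals without toxicokinetic records dropped", dropped)
    out = pd.DataFrame(rows)
    if not out.empty:
        out.attrs["n_concern"] = int(out["concern"].sum())
        out.attrs["n_total"] = int(len(out))
    return out


def records_from_table(tk: pd.DataFrame) -> dict[str, TKExposureRecord]:
    """Build per-chemical records from a toxicokinetic/exposure table with
    columns ``chemical``, ``css_uM_per_mgkgday``, ``exposure_mgkgday`` and
    optionally ``pod_rfd_mgkgday``."""
    records = {}
    for row in tk.itertuples():
        records[row.chemical] = TKExposureRecord(
            chemical=row.chemical,
            css_per_unit_dose=float(row.css_uM_per_mgkgday),
            exposure=float(row.exposure_mgkgday),
            pod_rfd=float(row.pod_rfd_mgkgday)
            if "pod_rfd_mgkgday" in tk.columns and not pd.isna(row.pod_rfd_mgkgday)
            else None,
        )
    return records
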