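"""ToxPi score aggregation: scaled POD components, cell-type slices, ranking.

Each phenotype's PODs are inversely scaled to [0, 1] — the lowest POD in the
dataset (highest bioactivity) maps to 1, the highest to 0, and censored PODs
score exactly 0.  Phenotype scores are averaged within each cell-type slice,
and slices are combined with equal weights (configurable) into the overall
ToxPi score used to rank chemicals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class ToxPiConfigurationError(ValueError):
    pass


@dataclass
class ToxPiInputMatrix:
    """Chemicals x phenotypes matrix of scaled scores in [0, 1]."""

    scores: pd.DataFrame  # index: chemical, columns: phenotype key
    slices: dict[str, str]  # phenotype key -> slice (cell type)
    slice_weights: dict[str, float] = field(default_factory=dict)
    degenerate_phenotypes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.slice_weights:
            slices = sorted(set(self.slices.values()))
            self.slice_weights = {s: 1.0 / len(slices) for s in slices}
        total = sum(self.slice_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ToxPiConfigurationError(f"slice weights sum to {total}, not 1")
        vals = self.scores.to_numpy()
        if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
            raise ToxPiConfigurationError("scores outside [0, 1]")


def _phenotype_key(row) -> str:
    return f"{row.cell_type}:{row.phenotype}"


def scale_pod_matrix(pods: pd.DataFrame, scale_mode: str = "log10") -> ToxPiInputMatrix:
    """Inverse-scale a POD table onto [0, 1] per phenotype.

    ``scale_mode='log10'`` interpolates on log10 POD (natural for log-spaced
    test concentrations); ``'linear'`` interpolates on the raw value.  Within
    each phenotype the minimum finite POD maps to 1, the maximum to 0, and
    censored PODs score 0 exactly.  Phenotypes with fewer than two distinct
    finite PODs are scored all-0 and flagged.
    """
    if scale_mode not in ("log10", "linear"):
        raise ToxPiConfigurationError(f"unknown scale_mode {scale_mode!r}")
    df = pods.copy()
    df["key"] = [f"{ct}:{ph}" for ct, ph in zip(df["cell_type"], df["phenotype"])]
    slices = dict(zip(df["key"], df["cell_type"]))

    chemicals = sorted(df["chemical"].unique())
    keys = sorted(df["key"].unique())
    scores = pd.DataFrame(0.0, index=pd.Index(chemicals, name="chemical"), columns=keys)
    degenerate = []
    for key, grp in df.groupby("key", sort=True):
        finite = grp[~grp["censored"]]
        vals = finite["pod_uM"].to_numpy(dtype=float)
        if np.unique(vals).size < 2:
            degenerate.append(key)
            log.warning("phenotype %s has <2 distinct finite PODs; scored all-0", key)
            continue
        x = np.log10(vals) if scale_mode == "log10" else vals
        lo, hi = x.min(), x.max()
        s = (hi - x) / (hi - lo)
        scores.loc[finite["chemical"].to_numpy(), key] = s
    return ToxPiInputMatrix(scores=scores, slices=slices, degenerate_phenotypes=degenerate)


def toxpi_profile(matrix: ToxPiInputMatrix) -> pd.DataFrame:
    """Per-chemical slice scores, overall score, and rank.

    Slice score = unweighted mean of member phenotype scores; overall =
    weighted mean of slice scores.  Ranking is by descending overall score
    with ties broken lexicographically by chemical id.
    """
    slice_names = sorted(matrix.slice_weights)
    out = pd.DataFrame(index=matrix.scores.index)
    for s in slice_names:
        members = [k for k, v in matrix.slices.items() if v == s]
        if not members:
            raise ToxPiConfigurationError(f"slice {s!r} has no phenotypes")
        out[f"slice_{s}"] = matrix.scores[members].mean(axis=1)
    out["overall"] = sum(
        out[f"slice_{s}"] * matrix.slice_weights[s] for s in slice_names
    )
    # deterministic rank: descending overall; index is sorted by chemical id
    # and mergesort is stable, so ties keep lexicographic order
    out = out.sort_index()
    order = out.sort_values(by="overall", ascending=False, kind="mergesort").index
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    out["rank"] = ranks
    return out.reset_index()


def class_score_ranges(profiles: pd.DataFrame, classing: pd.DataFrame) -> pd.DataFrame:
    """Min / max / median of slice and overall scores per chemical class.

    ``classing`` maps ``chemical`` to ``chem_class``; every profiled chemical
    must be labelled.  Classes are ranked by median overall score
    (rank 1 = most bioactive).
    """
    class_map = dict(zip(classing["chemical"], classing["chem_class"]))
    unknown = [c for c in profiles["chemical"] if c not in class_map]
    if unknown:
        raise ValueError(f"chemicals without class label: {unknown[:5]}")
    df = profiles.copy()
    df["chem_class"] = df["chemical"].map(class_map)
    score_cols = [c for c in df.columns if c.startswith("slice_")] + ["overall"]
    rows = []
    for cls, grp in df.groupby("chem_class", sort=True):
        for col in score_cols:
            rows.append(
                {
                    "chem_class": cls,
                    "component": col.removeprefix("slice_"),
                    "min": float(grp[col].min()),
                    "max": float(grp[col].max()),
                    "median": float(grp[col].median()),
                    "n": int(len(grp)),
                }
            )
    out = pd.DataFrame(rows)
    overall = out[out["component"] == "overall"].sort_values(
        by=["median", "chem_class"], ascending=[False, True]
    )
    rank_map = {cls: i + 1 for i, cls in enumerate(overall["chem_class"])}
    out["class_rank_by_median_overall"] = out["chem_class"].map(rank_map)
    return out
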