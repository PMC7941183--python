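"""Readers and writers for the pipeline's delimited exchange tables.

All tables are comma-delimited UTF-8 with dot decimals; concentrations are
always uM and doses always mg/kg/day.  Two small tables ship with the
package: the reference chemical->class annotation (42 priority chemicals in
5 classes) and a synthetic toy toxicokinetic/exposure table for exercising
the risk stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "chemical",
    "chem_class",
    "cell_type",
    "phenotype",
    "category",
    "conc_uM",
    "replicate",
    "plate",
    "response_pct",
]

CLASSING_COLUMNS = ["chemical", "chem_class"]
TK_COLUMNS = ["chemical", "css_uM_per_mgkgday", "exposure_mgkgday"]


class TableFormatError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return df


def load_screen_table(path) -> pd.DataFrame:
    """Read a long-format well-measurement table, rejecting malformed rows.

    Rows with non-numeric concentration/replicate/response are dropped with a
    logged line-numbered message; an unknown header fails immediately.
    """
    df = _read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing columns {missing}; expected {MEASUREMENT_COLUMNS}"
        )
    n0 = len(df)
    for col in ("conc_uM", "replicate", "response_pct"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        for i in df.index[bad]:
            log.warning("%s line %d: non-numeric %s %r; row rejected", path, i + 2, col, df.loc[i, col])
        df[col] = coerced
    df = df.dropna(subset=["conc_uM", "replicate", "response_pct"])
    if df.empty:
        raise EmptyInputError(f"{path}: all rows malformed")
    if (df["conc_uM"] < 0).any():
        raise TableFormatError(f"{path}: negative concentrations")
    n_rejected = n0 - len(df)
    log.info("%s: %d rows read, %d rejected", path, len(df), n_rejected)
    df["chem_class"] = df["chem_class"].fillna("")
    return df.reset_index(drop=True)


def write_screen_table(measurements: pd.DataFrame, path) -> None:
    measurements.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def load_classing(path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in CLASSING_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    if df["chemical"].duplicated().any():
        raise TableFormatError(f"{path}: duplicate chemical ids")
    return df


def load_tk_table(path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in TK_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    return df


def _packaged(name: str):
    return resources.files("namscreen.data").joinpath(name)


def load_reference_classing() -> pd.DataFrame:
    """The packaged 42-chemical / 5-class reference annotation."""
    with resources.as_file(_packaged("atsdr_classes.csv")) as p:
        return load_classing(p)


def load_tk_toy() -> pd.DataFrame:
    """A synthetic toy toxicokinetic/exposure table (16 chemicals).

    Values are invented but plausibly scaled; they exist to exercise the
    dose-conversion and margin-of-exposure stages, not to describe any real
    chemical.
    """
    with resources.as_file(_packaged("tk_exposure_synthetic.csv")) as p:
        return load_tk_table(p)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    output_dir: Path
    measurements_path: Path | None = None  # None: simulate with `seed`
    classing_path: Path | None = None  # None: packaged reference classing
    tk_path: Path | None = None  # None: risk stage skipped
    seed: int = 0
    noise_sd: float = 10.0
    scale_mode: str = "log10"
    distance: str = "pearson"
    linkage: str = "average"
    k: int = 5
    cv_folds: int = 5
    cv_repeats: int = 50
    n_trees: int = 500
    moe_benchmark: float = 100.0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        paths = {k: Path(v) for k, v in raw.items() if k.endswith(("_path", "_dir")) and v}
        rest = {k: v for k, v in raw.items() if k not in paths}
        cfg = cls(**{**rest, **paths})
        for p in (cfg.measurements_path, cfg.classing_path, cfg.tk_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg
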