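"""Synthetic five-cell-type screening data with known concentration-response truth.

The generator emulates a plate-based high-content screen of environmental
chemicals across five human cell models (iPSC-derived hepatocytes, neurons,
cardiomyocytes, endothelial cells, and primary HUVECs).  Each chemical class
carries a potency profile per cell type (location/spread of log10 EC50,
probability that a phenotype responds at all), so class structure is planted
in the data and every downstream stage — POD derivation, ToxPi ranking,
clustering, supervised classification — can be validated against an exact
ground truth.

Well responses are Hill-curve values (in % of vehicle control) plus
independent Gaussian noise; vehicle wells are Normal(100, noise_sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VEHICLE = "vehicle"

#: Concentration series in uM, descending (log-spaced over five decades).
DEFAULT_CONCENTRATIONS = (100.0, 10.0, 1.0, 0.1, 0.01)

#: Phenotypes per cell type: (name, category). Functional readouts come from
#: imaging/kinetic endpoints specific to each model; cytotoxicity readouts are
#: shared morphology/viability endpoints.
DEFAULT_PHENOTYPES: dict[str, tuple[tuple[str, str], ...]] = {
    "hepatocyte": (
        ("mito_integrity", "functional"),
        ("mito_intensity", "functional"),
        ("cell_number", "cytotoxicity"),
        ("nuclei_intensity", "cytotoxicity"),
        ("cell_mean_area", "cytotoxicity"),
    ),
    "neuron": (
        ("total_outgrowth", "functional"),
        ("mean_outgrowth", "functional"),
        ("total_process", "functional"),
        ("total_branches", "functional"),
        ("cells_with_growth", "functional"),
        ("cell_number", "cytotoxicity"),
        ("mito_integrity", "cytotoxicity"),
        ("cytoplasm_integrity", "cytotoxicity"),
        ("cell_body_area", "cytotoxicity"),
        ("atp", "cytotoxicity"),
    ),
    "cardiomyocyte": (
        ("beats_per_minute", "functional"),
        ("peak_amplitude", "functional"),
        ("peak_spacing", "functional"),
        ("peak_width", "functional"),
        ("peak_rise_time", "functional"),
        ("peak_decay_time", "functional"),
        ("decay_rise_ratio", "functional"),
        ("cell_number", "cytotoxicity"),
        ("mito_integrity", "cytotoxicity"),
    ),
    "endothelial": (
        ("total_tube_length", "functional"),
        ("mean_tube_length", "functional"),
        ("total_tube_area", "functional"),
        ("cell_number", "cytotoxicity"),
        ("mito_integrity", "cytotoxicity"),
        ("mito_intensity", "cytotoxicity"),
        ("cytoplasm_integrity", "cytotoxicity"),
        ("nuclei_mean_area", "cytotoxicity"),
    ),
    "huvec": (
        ("total_tube_length", "functional"),
        ("mean_tube_length", "functional"),
        ("total_tube_area", "functional"),
        ("cell_number", "cytotoxicity"),
        ("mito_integrity", "cytotoxicity"),
        ("mito_intensity", "cytotoxicity"),
        ("cytoplasm_integrity", "cytotoxicity"),
        ("nuclei_mean_area", "cytotoxicity"),
        ("atp", "cytotoxicity"),
    ),
}


class ConfigurationError(ValueError):
    """Raised when a screen design is internally inconsistent or empty."""


class InputError(ValueError):
    """Raised on invalid user-supplied values (duplicates, bad parameters)."""


def hill_response(conc, bottom: float, top: float, ec50: float, hill: float):
    """Four-parameter logistic response at concentration ``conc`` (uM).

    ``bottom`` is the zero-concentration asymptote, ``top`` the
    high-concentration asymptote, both in % of vehicle control.
    """
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(conc > 0, (ec50 / np.maximum(conc, 1e-300)) ** hill, np.inf)
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass(frozen=True)
class CellTypePotency:
    """Potency of one chemical class in one cell type."""

    mu_log10_ec50: float  # location of log10(EC50/uM) for responding phenotypes
    sigma_log10_ec50: float  # spread of log10(EC50/uM)
    activity_probability: float  # fraction of phenotypes that respond at all

    def __post_init__(self) -> None:
        if not 0.0 <= self.activity_probability <= 1.0:
            raise InputError(
                f"activity_probability must be in [0, 1], got {self.activity_probability}"
            )
        if self.sigma_log10_ec50 < 0:
            raise InputError("sigma_log10_ec50 must be >= 0")


@dataclass(frozen=True)
class ClassPotencyProfile:
    """Per-cell-type potency signature of one chemical class.

    Chemicals in a class act through a shared mechanism, so the signature is
    drawn at two levels: the class determines which phenotypes respond (via
    ``activity_probability``), the response direction, and a shared potency
    offset per phenotype; individual members then vary around that shared
    structure.  ``phenotype_consistency`` is the fraction of the log10 EC50
    variance shared by class members; ``member_fidelity`` is the chance a
    member actually responds on a class-responsive phenotype; sporadic
    activity elsewhere occurs at ``sporadic_rate``.
    """

    class_label: str
    cell_types: dict[str, CellTypePotency]
    direction_probability: float = 0.8  # chance a responding phenotype decreases
    phenotype_consistency: float = 0.8
    member_fidelity: float = 0.95
    sporadic_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("direction_probability", "phenotype_consistency",
                     "member_fidelity", "sporadic_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class ScreenDesign:
    """Static layout of the screen: chemicals, cell types, doses, replication."""

    chemicals: dict[str, str]  # chemical -> class label
    phenotypes: dict[str, tuple[tuple[str, str], ...]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPES)
    )
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    n_replicates: int = 3
    n_vehicle_wells: int = 16

    def __post_init__(self) -> None:
        if not self.chemicals or not self.phenotypes:
            raise ConfigurationError("screen design has no chemicals or no cell types")
        if self.n_vehicle_wells < 2:
            raise ConfigurationError("need at least 2 vehicle wells per plate")
        if list(self.concentrations) != sorted(self.concentrations, reverse=True) or len(
            set(self.concentrations)
        ) != len(self.concentrations):
            raise ConfigurationError("concentration series must be strictly decreasing")
        if any(c <= 0 for c in self.concentrations):
            raise ConfigurationError("concentrations must be positive (uM)")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.chemicals.values()))


@dataclass(frozen=True)
class TrueCurve:
    """Ground-truth concentration-response curve for one chemical x phenotype."""

    chemical: str
    cell_type: str
    phenotype: str
    bottom: float
    top: float
    ec50: float
    hill: float
    direction: str  # "increasing" | "decreasing" | "flat"
    active: bool

    def response(self, conc):
        if not self.active:
            return np.full_like(np.asarray(conc, dtype=float), self.bottom)
        return hill_response(conc, self.bottom, self.top, self.ec50, self.hill)


@dataclass
class SyntheticScreen:
    """A simulated screen: design, well measurements, and the generating truth."""

    design: ScreenDesign
    measurements: pd.DataFrame
    truth: pd.DataFrame
    noise_sd: float
    seed: int


def default_class_profiles() -> list[ClassPotencyProfile]:
    """Potency profiles for the five reference chemical classes.

    The signatures mirror the qualitative structure of the screen being
    emulated: inorganic metal salts are broadly potent across cell types;
    pesticides are selectively potent in cardiomyocytes; PAHs act mainly on
    neurons; other industrial chemicals on the two endothelial models; and
    phthalates show moderate hepatocyte/cardiomyocyte activity.  Responding
    phenotypes sit well inside the tested range (0.01-100 uM) so their PODs
    are estimable; background activity in non-target cell types is sparse
    and weak.
    """

    def ct(mu, sigma, act):
        return CellTypePotency(mu, sigma, act)

    weak = ct(1.8, 0.4, 0.08)  # occasional high-concentration background hits
    return [
        ClassPotencyProfile(
            "inorganic",
            {
                "hepatocyte": ct(-0.5, 0.4, 0.9),
                "neuron": ct(-0.5, 0.4, 0.9),
                "cardiomyocyte": ct(-0.5, 0.4, 0.9),
                "endothelial": ct(-0.5, 0.4, 0.9),
                "huvec": ct(-0.5, 0.4, 0.9),
            },
        ),
        ClassPotencyProfile(
            "pesticide",
            {
                "hepatocyte": weak,
                "neuron": ct(1.0, 0.4, 0.35),
                "cardiomyocyte": ct(-1.0, 0.4, 0.95),
                "endothelial": weak,
                "huvec": weak,
            },
        ),
        ClassPotencyProfile(
            "PAH",
            {
                "hepatocyte": ct(1.2, 0.4, 0.3),
                "neuron": ct(-0.3, 0.4, 0.9),
                "cardiomyocyte": weak,
                "endothelial": weak,
                "huvec": weak,
            },
        ),
        ClassPotencyProfile(
            "industrial",
            {
                "hepatocyte": weak,
                "neuron": weak,
                "cardiomyocyte": weak,
                "endothelial": ct(0.0, 0.4, 0.9),
                "huvec": ct(0.0, 0.4, 0.9),
            },
        ),
        ClassPotencyProfile(
            "phthalate",
            {
                "hepatocyte": ct(0.5, 0.3, 0.85),
                "neuron": weak,
                "cardiomyocyte": ct(0.8, 0.3, 0.85),
                "endothelial": weak,
                "huvec": weak,
            },
        ),
    ]


def default_design(classing: pd.DataFrame | None = None) -> ScreenDesign:
    """Screen design for the 42 reference chemicals in 5 classes.

    ``classing`` is a frame with columns ``chemical`` and ``chem_class``;
    when omitted the packaged reference table is used.
    """
    if classing is None:
        from .io import load_reference_classing

        classing = load_reference_classing()
    chemicals = dict(zip(classing["chemical"], classing["chem_class"]))
    if len(chemicals) != len(classing):
        raise InputError("duplicate chemical ids in classing table")
    return ScreenDesign(chemicals=chemicals)


def _draw_truth(
    design: ScreenDesign,
    profiles: dict[str, ClassPotencyProfile],
    rng: np.random.Generator,
) -> list[TrueCurve]:
    # class-level structure first: which phenotypes a class responds on, in
    # which direction, and a shared potency offset per phenotype
    class_struct: dict[tuple[str, str, str], tuple[bool, bool, float]] = {}
    for cls in sorted(profiles):
        profile = profiles[cls]
        for cell_type, phenos in design.phenotypes.items():
            pot = profile.cell_types[cell_type]
            shared_sd = pot.sigma_log10_ec50 * math.sqrt(profile.phenotype_consistency)
            for pheno, _category in phenos:
                responsive = rng.random() < pot.activity_probability
                decreasing = rng.random() < profile.direction_probability
                offset = rng.normal(0.0, shared_sd)
                class_struct[(cls, cell_type, pheno)] = (responsive, decreasing, offset)

    curves: list[TrueCurve] = []
    for chemical, cls in design.chemicals.items():
        profile = profiles[cls]
        for cell_type, phenos in design.phenotypes.items():
            pot = profile.cell_types[cell_type]
            member_sd = pot.sigma_log10_ec50 * math.sqrt(1.0 - profile.phenotype_consistency)
            for pheno, _category in phenos:
                responsive, decreasing, offset = class_struct[(cls, cell_type, pheno)]
                p_active = profile.member_fidelity if responsive else profile.sporadic_rate
                active = rng.random() < p_active
                if not active:
                    curves.append(
                        TrueCurve(chemical, cell_type, pheno, 100.0, 100.0, 1.0, 1.0, "flat", False)
                    )
                    continue
                log_ec50 = pot.mu_log10_ec50 + offset + rng.normal(0.0, member_sd)
                ec50 = 10.0 ** log_ec50
                hill = rng.uniform(0.8, 3.0)
                effect = rng.uniform(45.0, 85.0)  # % of control, keeps |top-100| >> noise
                curves.append(
                    TrueCurve(
                        chemical,
                        cell_type,
                        pheno,
                        100.0,
                        100.0 - effect if decreasing else 100.0 + effect,
                        ec50,
                        hill,
                        "decreasing" if decreasing else "increasing",
                        True,
                    )
                )
    return curves


def simulate_screen(
    profiles: list[ClassPotencyProfile] | None = None,
    design: ScreenDesign | None = None,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> SyntheticScreen:
    """Simulate a full screen with Gaussian well noise.

    Parameters
    ----------
    profiles
        One :class:`ClassPotencyProfile` per chemical class in the design.
    design
        Screen layout; defaults to the 42-chemical / 5-cell-type reference
        design with 5 concentrations, 3 replicates, and 16 vehicle wells per
        plate (one plate per cell type).
    noise_sd
        Standard deviation of well noise, in % of vehicle control.
    seed
        Master seed; per-plate substreams are split off deterministically so
        cell-type subsets reproduce independently of one another.
    """
    if design is None:
        design = default_design()
    if profiles is None:
        profiles = default_class_profiles()
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    profile_map = {p.class_label: p for p in profiles}
    if len(profile_map) != len(profiles):
        raise InputError("duplicate class labels among potency profiles")
    missing = set(design.chemicals.values()) - set(profile_map)
    if missing:
        raise ConfigurationError(f"no potency profile for classes: {sorted(missing)}")
    for p in profiles:
        absent = set(design.phenotypes) - set(p.cell_types)
        if absent:
            raise ConfigurationError(
                f"profile {p.class_label!r} lacks cell types: {sorted(absent)}"
            )

    master = np.random.SeedSequence(seed)
    truth_seq, *plate_seqs = master.spawn(1 + len(design.phenotypes))
    truth = _draw_truth(design, profile_map, np.random.default_rng(truth_seq))
    by_key = {(c.chemical, c.cell_type, c.phenotype): c for c in truth}

    concs = np.asarray(design.concentrations, dtype=float)
    rows: list[dict] = []
    for (cell_type, phenos), plate_seq in zip(design.phenotypes.items(), plate_seqs):
        rng = np.random.default_rng(plate_seq)
        plate = f"plate_{cell_type}"
        for pheno, category in phenos:
            veh = rng.normal(100.0, noise_sd, design.n_vehicle_wells)
            for i, v in enumerate(veh, start=1):
                rows.append(
                    {
                        "chemical": VEHICLE,
                        "chem_class": "",
                        "cell_type": cell_type,
                        "phenotype": pheno,
                        "category": category,
                        "conc_uM": 0.0,
                        "replicate": i,
                        "plate": plate,
                        "response_pct": v,
                    }
                )
            for chemical, cls in design.chemicals.items():
                curve = by_key[(chemical, cell_type, pheno)]
                mean = curve.response(concs)
                noise = rng.normal(0.0, noise_sd, (design.n_replicates, concs.size))
                for rep in range(design.n_replicates):
                    for j, c in enumerate(concs):
                        rows.append(
                            {
                                "chemical": chemical,
                                "chem_class": cls,
                                "cell_type": cell_type,
                                "phenotype": pheno,
                                "category": category,
                                "conc_uM": c,
                                "replicate": rep + 1,
                                "plate": plate,
                                "response_pct": mean[j] + noise[rep, j],
                            }
                        )

    measurements = pd.DataFrame(rows)
    truth_df = pd.DataFrame(
        {
            "chemical": [c.chemical for c in truth],
            "chem_class": [design.chemicals[c.chemical] for c in truth],
            "cell_type": [c.cell_type for c in truth],
            "phenotype": [c.phenotype for c in truth],
            "bottom": [c.bottom for c in truth],
            "top": [c.top for c in truth],
            "ec50_uM": [c.ec50 for c in truth],
            "hill": [c.hill for c in truth],
            "direction": [c.direction for c in truth],
            "active": [c.active for c in truth],
        }
    )
    return SyntheticScreen(design, measurements, truth_df, noise_sd, seed)


def analytic_pod(curve: TrueCurve, vehicle_sd: float) -> float:
    """Closed-form POD of a true curve: lowest c with |response(c) - 100| = sd.

    Returns ``math.inf`` when the curve never departs from baseline by
    ``vehicle_sd`` (inactive curve, or asymptotic effect at or below the
    benchmark).  Solving ``|top - 100| / (1 + (ec50/c)^h) = sd`` for c gives
    ``c = ec50 / (|top - 100|/sd - 1)^(1/h)``.
    """
    if vehicle_sd <= 0:
        raise InputError("vehicle_sd must be > 0")
    if curve.ec50 <= 0 or curve.hill <= 0:
        raise InputError("ec50 and hill must be positive")
    if not curve.active:
        return math.inf
    delta = abs(curve.top - curve.bottom)
    if delta <= vehicle_sd:
        return math.inf
    return curve.ec50 / (delta / vehicle_sd - 1.0) ** (1.0 / curve.hill)
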