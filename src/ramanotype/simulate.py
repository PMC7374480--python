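"""Seeded synthetic tomato Raman spectra with class-diagnostic ν1 band shifts.

The simulator emulates surface scans of intact tomato fruit on a handheld
1064 nm instrument: a 512-point axis spanning 200–2500 cm⁻¹, common
carotenoid bands at 1007 cm⁻¹ (C–CH₃ rocking) and 1158 cm⁻¹ (C–C stretch),
and a C=C stretching ν1 band whose position encodes the dominant carotenoid —
1519 cm⁻¹ for all-trans-lycopene, 1523 cm⁻¹ for tetra-cis-lycopene and
1528 cm⁻¹ for β-carotene.  Raman lines are Lorentzian; band amplitude is
linear in pigment concentration (unit slope per analyte), so regression
models can be validated by exact parameter recovery.  Fruit-surface
variability enters as a smooth random polynomial baseline, a multiplicative
scatter factor, and additive Gaussian noise — the effects SNV and derivative
preprocessing are meant to remove.

Concentration ranges mirror the UV-Vis reference values of the emulated
study population: 1.8–21.5 mg/100 g all-trans-lycopene, 1.6–9.5 mg/100 g
β-carotene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import CLASS_LABELS, RamanSpectrum

AXIS_MIN_CM1 = 200.0
AXIS_MAX_CM1 = 2500.0
AXIS_POINTS = 512

#: ν1 (C=C stretch) band centers, cm⁻¹.
NU1_ALL_TRANS_LYCOPENE = 1519.0
NU1_TETRA_CIS_LYCOPENE = 1523.0
NU1_BETA_CAROTENE = 1528.0
#: γ-carotene ν1 and the anthocyanin marker band are simulator conventions
#: (no published Raman assignment is encoded here), kept as explicit config.
NU1_GAMMA_CAROTENE = 1516.0
ANTHOCYANIN_BAND_CM1 = 1600.0


def default_axis() -> np.ndarray:
    """512 equally spaced wavenumbers from 200 to 2500 cm⁻¹ inclusive."""
    return np.linspace(AXIS_MIN_CM1, AXIS_MAX_CM1, AXIS_POINTS)


@dataclass(frozen=True)
class BandSpec:
    """One Lorentzian Raman line: center (cm⁻¹), FWHM (cm⁻¹), relative amplitude."""

    center: float
    width: float
    relative_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band FWHM must be > 0")
        if self.relative_amplitude < 0:
            raise ValueError("relative amplitude must be >= 0")


def _carotenoid_bands(nu1_center: float) -> tuple[BandSpec, ...]:
    """Shared fingerprint of a carotenoid: 1007/1158 cm⁻¹ plus its ν1 line."""
    return (
        BandSpec(1007.0, 10.0, 0.5),
        BandSpec(1158.0, 10.0, 0.75),
        BandSpec(nu1_center, 12.0, 1.0),
    )


@dataclass(frozen=True)
class Component:
    """One pigment in a class recipe with its concentration range (mg/100 g).

    A minor pigment can be tied to the class's dominant (first) component via
    ``ratio_range``: its concentration is drawn as ratio × dominant, capped at
    the top of ``conc_range``.  This encodes what a "dominant carotenoid
    profile" class means — the minor pigment tracks the major one instead of
    varying freely, so e.g. "lycopene + β-carotene" fruit never degenerate
    into "β-carotene with trace lycopene" fruit.
    """

    name: str
    bands: tuple[BandSpec, ...]
    conc_range: tuple[float, float]
    ratio_range: tuple[float, float] | None = None


@dataclass(frozen=True)
class ClassRecipe:
    label: str
    components: tuple[Component, ...]
    anthocyanin: bool = False

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")


LYCOPENE_RANGE = (1.8, 21.5)
BCAROTENE_RANGE = (1.6, 9.5)
# No published reference range for γ-carotene in this population; reuse the
# β-carotene range (comparable minor-carotenoid levels).
GCAROTENE_RANGE = (1.6, 9.5)

_LYC = Component("all_trans_lycopene", _carotenoid_bands(NU1_ALL_TRANS_LYCOPENE), LYCOPENE_RANGE)
_BCAR = Component("beta_carotene", _carotenoid_bands(NU1_BETA_CAROTENE), BCAROTENE_RANGE)
_TCIS = Component("tetra_cis_lycopene", _carotenoid_bands(NU1_TETRA_CIS_LYCOPENE), LYCOPENE_RANGE)
# Mixed-profile red fruit are visibly red: their lycopene sits in the upper
# part of the reference range rather than at trace level.
_LYC_RED = Component(
    "all_trans_lycopene", _carotenoid_bands(NU1_ALL_TRANS_LYCOPENE), (6.0, 21.5)
)
# Minor components ride on the dominant pigment: β-carotene at 40–80% and
# γ-carotene at 50–100% of the lycopene level in the mixed red classes;
# trace lycopene at 5–25% of the β-carotene level in β-dominant fruit.  The
# ratio gaps keep each composite class a distinct pigment profile rather
# than a continuum blending into its neighbours — a mixed class is only
# identifiable (by HPLC or spectroscopy) when its second pigment is an
# appreciable fraction of the first.
_BCAR_MINOR = Component(
    "beta_carotene", _carotenoid_bands(NU1_BETA_CAROTENE), BCAROTENE_RANGE,
    ratio_range=(0.4, 0.8),
)
_GCAR_MINOR = Component(
    "gamma_carotene", _carotenoid_bands(NU1_GAMMA_CAROTENE), GCAROTENE_RANGE,
    ratio_range=(0.5, 1.0),
)
_LYC_TRACE = Component(
    "all_trans_lycopene", _carotenoid_bands(NU1_ALL_TRANS_LYCOPENE), LYCOPENE_RANGE,
    ratio_range=(0.05, 0.25),
)

DEFAULT_RECIPES: dict[str, ClassRecipe] = {
    "lycopene_high": ClassRecipe("lycopene_high", (_LYC,)),
    "lycopene_bcarotene": ClassRecipe("lycopene_bcarotene", (_LYC_RED, _BCAR_MINOR)),
    "lycopene_gcarotene": ClassRecipe("lycopene_gcarotene", (_LYC_RED, _GCAR_MINOR)),
    "bcarotene": ClassRecipe("bcarotene", (_BCAR, _LYC_TRACE)),
    "bcarotene_anthocyanin": ClassRecipe("bcarotene_anthocyanin", (_BCAR,), anthocyanin=True),
    "tetracis_lycopene": ClassRecipe("tetracis_lycopene", (_TCIS,)),
    "low_carotenoid": ClassRecipe("low_carotenoid", ()),
}

#: Anthocyanin-rich skin adds a broad feature near 1600 cm⁻¹ (aromatic ring
#: stretch region); amplitude range in the same arbitrary units as bands.
ANTHOCYANIN_BAND = BandSpec(ANTHOCYANIN_BAND_CM1, 60.0, 1.0)
ANTHOCYANIN_AMPLITUDE_RANGE = (2.0, 8.0)


@dataclass(frozen=True)
class NoiseConfig:
    """Baseline + scatter + noise model for fruit-surface variability.

    Defaults: quadratic baseline with a modest scale (1064 nm excitation is
    chosen in handheld fruit work precisely because fluorescence background
    stays low), multiplicative scatter sd 0.15, and
    additive noise with sd equal to 1% of the spectrum's peak band signal
    (``additive_noise_sd`` is that fraction; Raman shot noise scales with the
    signal, so a strongly pigmented fruit is absolutely noisier but equally
    noisy relative to its bands).  ``noise_floor`` is the detector noise
    floor in absolute counts, the sd applied when a spectrum has little or
    no band signal (low-carotenoid fruit).
    """

    baseline_poly_order: int = 2
    baseline_scale: float = 2.0
    multiplicative_scatter_sd: float = 0.15
    additive_noise_sd: float = 0.01
    noise_floor: float = 0.02

    def __post_init__(self) -> None:
        if self.baseline_poly_order < 0:
            raise ValueError("baseline polynomial order must be >= 0")
        scales = (self.multiplicative_scatter_sd, self.additive_noise_sd,
                  self.baseline_scale, self.noise_floor)
        if min(scales) < 0:
            raise ValueError("noise scales must be >= 0")


NOISELESS = NoiseConfig(baseline_scale=0.0, multiplicative_scatter_sd=0.0,
                        additive_noise_sd=0.0, noise_floor=0.0)


def lorentzian(axis: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-peak Lorentzian line shape: γ²/((x−x₀)² + γ²) with γ = FWHM/2."""
    gamma = fwhm / 2.0
    return gamma**2 / ((axis - center) ** 2 + gamma**2)


def _random_baseline(axis: np.ndarray, noise: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth nonnegative random polynomial baseline, min pinned at 0.5·scale."""
    if noise.baseline_scale == 0:
        return np.zeros_like(axis)
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    coef = rng.uniform(-1.0, 1.0, size=noise.baseline_poly_order + 1)
    poly = np.polynomial.polynomial.polyval(u, coef)
    span = np.ptp(poly)
    shape = (poly - poly.min()) / span if span > 0 else np.zeros_like(poly)
    return noise.baseline_scale * (0.5 + 0.5 * shape)


def generate_spectrum(
    recipe: ClassRecipe,
    concentrations: dict[str, float],
    noise: NoiseConfig = NoiseConfig(),
    seed: int | np.random.Generator = 0,
    sample_id: str = "sample",
    replicate: int = 1,
    axis: np.ndarray | None = None,
    anthocyanin_amplitude: float = 5.0,
) -> RamanSpectrum:
    """Render one replicate spectrum of a class recipe.

    intensity = scatter · (Σ conc·bands + baseline) + additive noise, with
    scatter ~ N(1, sd).  Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if axis is None:
        axis = default_axis()
    signal = np.zeros_like(axis)
    for comp in recipe.components:
        conc = concentrations.get(comp.name, 0.0)
        if conc < 0:
            raise ValueError(f"negative concentration for {comp.name!r}")
        for band in comp.bands:
            signal += conc * band.relative_amplitude * lorentzian(axis, band.center, band.width)
    if recipe.anthocyanin:
        amp = concentrations.get("anthocyanin", anthocyanin_amplitude)
        signal += amp * ANTHOCYANIN_BAND.relative_amplitude * lorentzian(
            axis, ANTHOCYANIN_BAND.center, ANTHOCYANIN_BAND.width
        )

    baseline = _random_baseline(axis, noise, rng)
    scatter = 1.0 + noise.multiplicative_scatter_sd * rng.standard_normal()
    noise_sd = max(noise.additive_noise_sd * float(signal.max()), noise.noise_floor)
    eps = noise_sd * rng.standard_normal(axis.size)
    # shot-like noise rides on the photon flux, so it scales with the same
    # surface scatter factor as the signal
    intensity = scatter * (signal + baseline + eps)
    return RamanSpectrum(axis=axis, intensity=intensity, sample_id=sample_id, replicate=replicate)


#: Per-class sample counts of the default 106-fruit classification benchmark
#: (red fruit split across the three lycopene-containing classes; orange into
#: tangerine and β-carotene types; yellow/green as low-carotenoid).
DEFAULT_N_PER_CLASS: dict[str, int] = {
    "lycopene_high": 28,
    "lycopene_bcarotene": 13,
    "lycopene_gcarotene": 10,
    "bcarotene": 14,
    "bcarotene_anthocyanin": 7,
    "tetracis_lycopene": 17,
    "low_carotenoid": 17,
}


def generate_dataset(
    n_per_class: dict[str, int] | None = None,
    noise: NoiseConfig = NoiseConfig(),
    replicates: int = 3,
    seed: int = 0,
    recipes: dict[str, ClassRecipe] | None = None,
) -> tuple[list[RamanSpectrum], pd.DataFrame]:
    """Draw a labelled multi-class dataset of replicate spectra.

    Concentrations are uniform over each component's recipe range; the
    replicates of a sample share concentrations but receive independent
    baseline/scatter/noise draws.  Returns the flat replicate list plus a
    metadata table (one row per sample) with the true class and the dominant
    analyte's concentration.
    """
    if n_per_class is None:
        n_per_class = DEFAULT_N_PER_CLASS
    if recipes is None:
        recipes = DEFAULT_RECIPES
    unknown = set(n_per_class) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown class keys: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    axis = default_axis()
    spectra: list[RamanSpectrum] = []
    meta_rows = []
    counter = 0
    for label in CLASS_LABELS:  # fixed class order for reproducibility
        n = n_per_class.get(label, 0)
        recipe = recipes[label]
        for _ in range(n):
            sid = f"{label}_{counter:04d}"
            counter += 1
            concs: dict[str, float] = {}
            dominant_conc = None
            for c in recipe.components:
                if c.ratio_range is None:
                    concs[c.name] = float(rng.uniform(*c.conc_range))
                    if dominant_conc is None:
                        dominant_conc = concs[c.name]
                else:
                    if dominant_conc is None:
                        raise ValueError(
                            f"ratio component {c.name!r} needs a preceding "
                            "absolute (dominant) component"
                        )
                    ratio = float(rng.uniform(*c.ratio_range))
                    concs[c.name] = min(ratio * dominant_conc, c.conc_range[1])
            if recipe.anthocyanin:
                concs["anthocyanin"] = float(rng.uniform(*ANTHOCYANIN_AMPLITUDE_RANGE))
            dominant = max(concs, key=concs.get) if concs else ""
            for rep in range(1, replicates + 1):
                spectra.append(
                    generate_spectrum(
                        recipe, concs, noise=noise, seed=rng, sample_id=sid,
                        replicate=rep, axis=axis,
                    )
                )
            meta_rows.append(
                {
                    "sample_id": sid,
                    "class": label,
                    "dominant_analyte": dominant,
                    "concentration_mg_per_100g": concs.get(dominant, 0.0),
                    **{f"conc_{k}": v for k, v in concs.items()},
                }
            )
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "class", "dominant_analyte", "concentration_mg_per_100g"]
        if not meta_rows
        else None,
    )
    return spectra, meta


def reference_concentration(
    absorbance: float,
    epsilon_mM_cm: float,
    path_cm: float = 1.0,
    hexane_volume_L: float = 0.004,
    sample_mass_g: float = 0.1,
    molar_mass_g_per_mol: float = 536.87,
) -> float:
    """Beer–Lambert pigment concentration in mg per 100 g of fruit.

    c [mM] = A / (ε·path); amount [mmol] = c · V; mass [mg] = amount · M;
    result = mass / sample_mass · 100.  Defaults match a hexane extraction
    (4 mL hexane phase from 8 mL of 2:1:1 hexane/ethanol/acetone per 0.1 g
    sample) of a C40 carotenoid (M = 536.87 g/mol); ε = 172 mM⁻¹cm⁻¹ for
    all-trans-lycopene at 503 nm, 139 mM⁻¹cm⁻¹ for β-carotene at 451 nm.
    """
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    for name, v in (
        ("epsilon", epsilon_mM_cm),
        ("path", path_cm),
        ("volume", hexane_volume_L),
        ("mass", sample_mass_g),
        ("molar mass", molar_mass_g_per_mol),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    millimolar = absorbance / (epsilon_mM_cm * path_cm)
    mg = millimolar * hexane_volume_L * molar_mass_g_per_mol
    return mg / sample_mass_g * 100.0
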