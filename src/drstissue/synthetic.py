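"""Synthetic diffuse-reflectance cohorts with known ground truth.

The generator emulates the statistical structure an ex-vivo prostate DRS
study produces — a few hundred measurements from ~59 patients, 5-10 probe
contacts each, two tissue classes with class-dependent chromophore
composition, patient-level random effects, instrument noise, and a large
fraction of measurements whose histology correlation is too uncertain to
label — without claiming physical accuracy for any individual spectrum.

Spectra come from a diffusion-style analytic surrogate:

    R(lambda) = S * exp(-mu_eff(lambda) * rho) / rho**2
    mu_eff    = sqrt(3 * mu_a * (mu_a + mu_s'))
    mu_s'     = a * (lambda / 500)**(-b)          (Mie-like power law)
    mu_a      = sum_i c_i * eps_i(lambda)         (linear chromophore mixing)

with source-detector separation rho = 2 mm.  The chromophore extinction
templates eps_i are fixed, version-stamped sums of Gaussians placed at the
canonical absorption bands (hemoglobin Soret/Q bands, water 970/1190/1450 nm,
lipid 930/1210 nm, a broad collagen background); they are synthetic
stand-ins, not literature coefficients.  The tumor/healthy contrast
(tumor: more blood and water, less lipid) is a modeling assumption chosen
to give the two classes distinguishable band structure, not a measured
prostate result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import Measurement, RawSpectrum, SpectraSet, Spectrum, WavelengthGrid, stitch_spectra

__all__ = [
    "TEMPLATE_VERSION",
    "CHROMOPHORE_BANDS",
    "ChromophoreSet",
    "TissueComposition",
    "ForwardModel",
    "GeneratorConfig",
    "absorption_spectrum",
    "reflectance_forward",
    "generate_dataset",
]

TEMPLATE_VERSION = "1.0"

# (center nm, width nm, relative amplitude) per chromophore; synthetic bands
CHROMOPHORE_BANDS = {
    "oxyHb": ((415.0, 18.0, 1.0), (542.0, 14.0, 0.28), (576.0, 13.0, 0.30)),
    "deoxyHb": ((430.0, 20.0, 1.0), (555.0, 18.0, 0.30), (760.0, 25.0, 0.12)),
    "water": ((970.0, 35.0, 0.30), (1190.0, 45.0, 0.50), (1450.0, 55.0, 1.00)),
    "lipid": ((930.0, 20.0, 0.40), (1210.0, 35.0, 1.00), (1395.0, 30.0, 0.20)),
    "collagen": ((1030.0, 60.0, 0.25), (1200.0, 80.0, 0.20), (1500.0, 70.0, 0.35)),
}

CHROMOPHORES = tuple(CHROMOPHORE_BANDS)


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class ChromophoreSet:
    """Fixed extinction templates on a wavelength grid (relative units)."""

    grid: WavelengthGrid
    version: str = TEMPLATE_VERSION

    def extinction(self, name: str) -> np.ndarray:
        if name not in CHROMOPHORE_BANDS:
            raise ParameterError(f"unknown chromophore {name!r}")
        lam = self.grid.values
        eps = np.zeros_like(lam)
        for center, width, amp in CHROMOPHORE_BANDS[name]:
            eps += amp * np.exp(-0.5 * ((lam - center) / width) ** 2)
        return eps

    @property
    def names(self) -> tuple:
        return CHROMOPHORES


@dataclass(frozen=True)
class TissueComposition:
    """Chromophore concentrations (relative) plus scattering parameters.

    ``a`` is the reduced-scattering amplitude at 500 nm (mm^-1),
    ``b`` the scattering power of the Mie-like power law.
    """

    concentrations: dict  # chromophore name -> c_i >= 0
    a: float = 1.6
    b: float = 1.2

    def __post_init__(self):
        for name, c in self.concentrations.items():
            if name not in CHROMOPHORE_BANDS:
                raise ParameterError(f"unknown chromophore {name!r}")
            if c < 0:
                raise ParameterError(f"negative concentration for {name}: {c}")
        if not (self.a > 0 and self.b > 0):
            raise ParameterError("scattering parameters a, b must be positive")


@dataclass(frozen=True)
class ForwardModel:
    """Diffusion-style surrogate mapping optical properties to reflectance."""

    rho_mm: float = 2.0  # source-detector separation
    source_scale: float = 1.0

    def __post_init__(self):
        if self.rho_mm <= 0:
            raise ParameterError("source-detector separation must be positive")


def absorption_spectrum(comp: TissueComposition, chromophores: ChromophoreSet) -> np.ndarray:
    """mu_a(lambda) = sum_i c_i * eps_i(lambda); linear in each concentration."""
    mu_a = np.zeros(len(chromophores.grid))
    for name, c in comp.concentrations.items():
        mu_a += c * chromophores.extinction(name)
    return mu_a


def reduced_scattering(comp: TissueComposition, grid: WavelengthGrid) -> np.ndarray:
    return comp.a * (grid.values / 500.0) ** (-comp.b)


def reflectance_forward(
    comp: TissueComposition,
    model: ForwardModel = ForwardModel(),
    chromophores: ChromophoreSet | None = None,
    grid: WavelengthGrid | None = None,
) -> Spectrum:
    """Forward-model a composition to a positive reflectance spectrum.

    R is strictly decreasing in mu_a at fixed mu_s' and rho; with mu_a = 0
    the exponential term is identically 1.
    """
    if grid is None:
        grid = WavelengthGrid.canonical()
    if chromophores is None:
        chromophores = ChromophoreSet(grid)
    mu_a = absorption_spectrum(comp, chromophores)
    mu_s = reduced_scattering(comp, grid)
    mu_eff = np.sqrt(3.0 * mu_a * (mu_a + mu_s))
    refl = model.source_scale * np.exp(-mu_eff * model.rho_mm) / model.rho_mm**2
    return Spectrum(grid=grid, reflectance=refl, meta={"synthetic": True})


# ---------------------------------------------------------------------------
# cohort generation

# healthy baseline and the tumor-minus-healthy composition contrast
BASE_HEALTHY = {"oxyHb": 0.35, "deoxyHb": 0.20, "water": 0.55, "lipid": 0.50, "collagen": 0.35}
TUMOR_SHIFT = {"oxyHb": 0.25, "deoxyHb": 0.15, "water": 0.20, "lipid": -0.25, "collagen": 0.05}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped defaults: 59 patients, 5-10 contacts each, 53% tumor
    prior, 152/542 of measurements retaining a confident label."""

    n_patients: int = 59
    measurements_per_patient: tuple = (5, 10)  # inclusive range
    p_tumor: float = 0.53
    separation: float = 1.0  # delta in [0, 1]: scales the class contrast
    patient_effect_sd: float = 0.06
    within_patient_sd: float = 0.03
    multiplicative_noise_sd: float = 0.02
    additive_noise_sd: float = 2e-4
    label_certainty: float = 152.0 / 542.0
    scatter_a: float = 1.6
    scatter_b: float = 1.2
    scatter_a_sd: float = 0.10
    two_channel: bool = False
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.measurements_per_patient
        if not (1 <= lo <= hi):
            raise ParameterError("measurements_per_patient must be an increasing range >= 1")
        if not (0 <= self.p_tumor <= 1 and 0 <= self.label_certainty <= 1):
            raise ParameterError("probabilities must lie in [0, 1]")
        if self.separation < 0:
            raise ParameterError("separation must be >= 0")
        for sd in (
            self.patient_effect_sd,
            self.within_patient_sd,
            self.multiplicative_noise_sd,
            self.additive_noise_sd,
            self.scatter_a_sd,
        ):
            if sd < 0:
                raise ParameterError("noise SDs must be >= 0")
        if self.n_patients < 1:
            raise ParameterError("need at least one patient")


def _composition(cfg: GeneratorConfig, rng, patient_effect, a_patient, is_tumor: bool) -> TissueComposition:
    conc = {}
    for j, name in enumerate(CHROMOPHORES):
        c = BASE_HEALTHY[name]
        if is_tumor:
            c += cfg.separation * TUMOR_SHIFT[name]
        c += patient_effect[j] + rng.normal(0.0, cfg.within_patient_sd)
        conc[name] = max(c, 0.0)
    return TissueComposition(concentrations=conc, a=max(a_patient, 0.2), b=cfg.scatter_b)


def _measure(spectrum: Spectrum, cfg: GeneratorConfig, rng) -> Spectrum:
    noisy = spectrum.reflectance * (1.0 + rng.normal(0.0, cfg.multiplicative_noise_sd)) + rng.normal(
        0.0, cfg.additive_noise_sd, size=len(spectrum.grid)
    )
    return Spectrum(grid=spectrum.grid, reflectance=noisy, meta=spectrum.meta)


def _two_channel_measure(comp, model, cfg, rng) -> Spectrum:
    """Simulate each spectrometer channel separately, add independent noise,
    then stitch — exercises the calibration/stitch path end to end."""
    vis_grid = WavelengthGrid.regular(400.0, 1160.0, 1.0)
    nir_grid = WavelengthGrid.regular(900.0, 1750.0, 1.0)
    parts = []
    for channel, g in (("vis", vis_grid), ("nir", nir_grid)):
        chroms = ChromophoreSet(g)
        clean = reflectance_forward(comp, model, chroms, g)
        noisy = _measure(clean, cfg, rng)
        parts.append(RawSpectrum(channel=channel, wavelengths=g.values, values=noisy.reflectance))
    return stitch_spectra(parts[0], parts[1])


def generate_dataset(cfg: GeneratorConfig) -> tuple[SpectraSet, pd.DataFrame]:
    """Generate a labeled cohort plus its ground-truth composition table.

    Per patient: a Gaussian composition effect shared by all of the
    patient's measurements.  Per measurement: a tissue class (tumor with
    probability ``p_tumor``), the class contrast scaled by ``separation``,
    within-patient jitter, the forward model, multiplicative and additive
    noise.  A ``1 - label_certainty`` fraction of measurements is relabeled
    'unlabeled' (uncertain histology); the truth table keeps every true
    class.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = WavelengthGrid.canonical()
    chroms = ChromophoreSet(grid)
    model = ForwardModel()
    lo, hi = cfg.measurements_per_patient

    measurements = []
    truth_rows = []
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:03d}"
        patient_effect = rng.normal(0.0, cfg.patient_effect_sd, size=len(CHROMOPHORES))
        a_patient = rng.normal(cfg.scatter_a, cfg.scatter_a_sd)
        n_meas = int(rng.integers(lo, hi + 1))
        for k in range(n_meas):
            is_tumor = bool(rng.random() < cfg.p_tumor)
            comp = _composition(cfg, rng, patient_effect, a_patient, is_tumor)
            if cfg.two_channel:
                spec = _two_channel_measure(comp, model, cfg, rng)
            else:
                clean = reflectance_forward(comp, model, chroms, grid)
                spec = _measure(clean, cfg, rng)
            true_label = "tumor" if is_tumor else "healthy"
            labeled = bool(rng.random() < cfg.label_certainty)
            lid = f"L{k + 1:02d}"
            measurements.append(
                Measurement(
                    patient_id=pid,
                    location_id=lid,
                    label=true_label if labeled else "unlabeled",
                    spectrum=spec,
                )
            )
            truth_rows.append(
                {"patient_id": pid, "location_id": lid, "true_class": true_label,
                 "labeled": labeled, "scatter_a": comp.a, "scatter_b": comp.b}
                | {f"c_{n}": comp.concentrations[n] for n in CHROMOPHORES}
            )
    out_grid = measurements[0].spectrum.grid
    return SpectraSet(tuple(measurements), out_grid), pd.DataFrame(truth_rows)
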