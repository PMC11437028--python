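"""Bio-optical parameterisations of the water column constituents.

The inversion retrieves three constituents — chlorophyll-a (mg Chl m⁻³),
chromophoric dissolved organic matter (CDOM, mg C m⁻³) and non-algal
particles (NAP, mg C m⁻³).  This module maps those concentrations to bulk
inherent optical properties (IOPs): total absorption a(λ), scattering b(λ)
and backscattering b_b(λ), each the sum of a pure-seawater term and
concentration × mass-specific coefficient terms.

Phytoplankton scattering is carbon-specific, so chlorophyll is converted to
carbon through a photoacclimation law: the cellular Chl:C ratio θ_CHL is a
decreasing sigmoid of surface PAR — cells hold more pigment per unit carbon
under low light.

CDOM and NAP absorption follow exponentially decreasing spectra; NAP
scattering follows a (550/λ)^f power law; CDOM does not scatter.

The module also houses the constructors used by the sensitivity ensembles
to perturb the phytoplankton optical spectra around the reference (REF)
table shipped with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, InvalidInputError

DEFAULT_WAVELENGTHS = (412.5, 442.5, 490.0, 510.0, 555.0)

# Anchor wavelengths of the ensemble slope perturbation (blue and green ends
# of the retrieval grid).
_BLUE_NM = 412.5
_GREEN_NM = 555.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing light wavelengths in nm, all within [300, 800]."""

    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS

    def __post_init__(self):
        lam = np.asarray(self.wavelengths, dtype=float)
        if lam.ndim != 1 or lam.size == 0:
            raise ConfigError("wavelength grid must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(lam)):
            raise ConfigError("wavelength grid contains non-finite values")
        if np.any(np.diff(lam) <= 0):
            raise ConfigError("wavelengths must be strictly increasing")
        if lam.min() < 300.0 or lam.max() > 800.0:
            raise ConfigError("wavelengths must lie within [300, 800] nm")
        object.__setattr__(self, "wavelengths", tuple(float(v) for v in lam))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.wavelengths, dtype=float)

    def __len__(self) -> int:
        return len(self.wavelengths)


def _spectrum(values, grid: WavelengthGrid, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (len(grid),):
        raise ConfigError(
            f"{name}: expected {len(grid)} values on the wavelength grid, "
            f"got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ConfigError(f"{name}: non-finite values")
    return arr


@dataclass(frozen=True)
class WaterIOP:
    """Pure-seawater absorption/scattering/backscattering spectra, m⁻¹."""

    grid: WavelengthGrid
    a_w: np.ndarray
    b_w: np.ndarray
    b_bw: np.ndarray

    def __post_init__(self):
        for name in ("a_w", "b_w", "b_bw"):
            arr = _spectrum(getattr(self, name), self.grid, name)
            if np.any(arr < 0):
                raise ConfigError(f"{name}: negative values")
            object.__setattr__(self, name, arr)
        if np.any(self.b_bw > self.b_w):
            raise ConfigError("water backscattering exceeds total scattering")


@dataclass(frozen=True)
class PhytoOpticalParams:
    """Phytoplankton specific spectra.

    a_star_ph is chlorophyll-specific (m² (mg Chl)⁻¹); the scattering and
    backscattering spectra are carbon-specific (m² (mg C)⁻¹).
    """

    grid: WavelengthGrid
    a_star_ph: np.ndarray
    b_star_ph: np.ndarray
    b_star_bph: np.ndarray

    def __post_init__(self):
        for name in ("a_star_ph", "b_star_ph", "b_star_bph"):
            arr = _spectrum(getattr(self, name), self.grid, name)
            if np.any(arr < 0):
                raise ConfigError(f"{name}: negative values")
            object.__setattr__(self, name, arr)
        if np.any(self.b_star_bph > self.b_star_ph):
            raise ConfigError("phytoplankton backscattering exceeds scattering")


@dataclass(frozen=True)
class CDOMParams:
    """Exponential CDOM absorption law parameters (REF: 0.015, 450, 0.017)."""

    a_star_ref: float = 0.015   # m^2 (mg C)^-1 at lambda_ref
    lambda_ref: float = 450.0   # nm
    s_cdom: float = 0.017       # nm^-1

    def __post_init__(self):
        if not (self.a_star_ref > 0 and self.s_cdom > 0):
            raise ConfigError("CDOM parameters must be positive")


@dataclass(frozen=True)
class NAPParams:
    """Non-algal-particle absorption and scattering law parameters."""

    a_star_ref: float = 0.0013   # m^2 (mg C)^-1 at 440 nm
    s_nap: float = 0.013         # nm^-1
    b_star_ref: float = 0.02875  # m^2 (mg C)^-1 at 550 nm
    f_nap: float = 0.5           # dimensionless power-law exponent
    bb_ratio: float = 0.005      # backscattering-to-scattering ratio

    lambda_ref_a: float = 440.0
    lambda_ref_b: float = 550.0

    def __post_init__(self):
        if not (
            self.a_star_ref > 0
            and self.s_nap > 0
            and self.b_star_ref > 0
            and self.f_nap > 0
            and self.bb_ratio > 0
        ):
            raise ConfigError("NAP parameters must be positive")
        if self.bb_ratio > 0.5:
            raise ConfigError("NAP bb_ratio must lie in (0, 0.5]")


@dataclass(frozen=True)
class PhotoacclimationParams:
    """Sigmoid Chl:C law parameters (REF: θ0=0.03, θmin=0.005, σ=20, β=500)."""

    theta0: float = 0.03      # mg Chl (mg C)^-1, dynamic range of the sigmoid
    theta_min: float = 0.005  # mg Chl (mg C)^-1, saturating-light floor
    sigma: float = 20.0       # umol quanta m^-2 s^-1, inflection slope scale
    beta: float = 500.0       # umol quanta m^-2 s^-1, inflection position

    def __post_init__(self):
        if not all(
            v > 0 for v in (self.theta0, self.theta_min, self.sigma, self.beta)
        ):
            raise ConfigError("photoacclimation parameters must be positive")


@dataclass(frozen=True)
class ConstituentVector:
    """Inversion target x = (Chl-a, CDOM, NAP) concentrations."""

    chl: float   # mg Chl m^-3
    cdom: float  # mg C m^-3
    nap: float   # mg C m^-3

    def __post_init__(self):
        vals = (self.chl, self.cdom, self.nap)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise InvalidInputError(
                f"constituent concentrations must be finite and >= 0, got {vals}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.chl, self.cdom, self.nap], dtype=float)


@dataclass(frozen=True)
class BulkIOP:
    """Bulk IOP spectra a, b, b_b (m⁻¹) on a wavelength grid."""

    grid: WavelengthGrid
    a: np.ndarray
    b: np.ndarray
    b_b: np.ndarray

    def __post_init__(self):
        for name in ("a", "b", "b_b"):
            object.__setattr__(
                self, name, _spectrum(getattr(self, name), self.grid, name)
            )
        if np.any(self.a <= 0):
            raise InvalidInputError("bulk absorption must be > 0 (water floor)")
        if np.any(self.b_b < 0) or np.any(self.b_b > self.b):
            raise InvalidInputError("bulk backscattering must satisfy 0 <= b_b <= b")


@dataclass(frozen=True)
class BioOpticalConfig:
    """All spectral and scalar bio-optical parameters of the model."""

    grid: WavelengthGrid
    water: WaterIOP
    phyto: PhytoOpticalParams
    cdom: CDOMParams = field(default_factory=CDOMParams)
    nap: NAPParams = field(default_factory=NAPParams)
    photo: PhotoacclimationParams = field(default_factory=PhotoacclimationParams)

    @classmethod
    def ref(cls) -> "BioOpticalConfig":
        """The reference (REF) configuration shipped with the package."""
        table = load_ref_table()
        grid = WavelengthGrid(tuple(table["wavelength_nm"]))
        water = WaterIOP(
            grid,
            table["a_w"].to_numpy(),
            table["b_w"].to_numpy(),
            table["b_bw"].to_numpy(),
        )
        phyto = PhytoOpticalParams(
            grid,
            table["a_star_ph"].to_numpy(),
            table["b_star_ph"].to_numpy(),
            table["b_star_bph"].to_numpy(),
        )
        return cls(grid=grid, water=water, phyto=phyto)

    def with_phyto(self, phyto: PhytoOpticalParams) -> "BioOpticalConfig":
        return replace(self, phyto=phyto)

    def with_photo(self, photo: PhotoacclimationParams) -> "BioOpticalConfig":
        return replace(self, photo=photo)


def load_ref_table() -> pd.DataFrame:
    """Load the packaged REF water/phytoplankton coefficient table."""
    with resources.files("tristream.data").joinpath("bio_optics_ref.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# Constituent-specific spectral laws
# ---------------------------------------------------------------------------

def _check_wavelength(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise InvalidInputError("wavelength must be finite")
    return lam


def cdom_specific_absorption(lam, p: CDOMParams | None = None):
    """CDOM mass-specific absorption a*_CDOM(λ), m² (mg C)⁻¹.

    Exponentially decreasing away from the reference wavelength:
    a*(λ) = a*(λ_ref) · exp(−S_CDOM (λ − λ_ref)).
    """
    p = p or CDOMParams()
    lam = _check_wavelength(lam)
    if np.any(lam < 300) or np.any(lam > 800):
        raise InvalidInputError("wavelength outside [300, 800] nm")
    return p.a_star_ref * np.exp(-p.s_cdom * (lam - p.lambda_ref))


def nap_specific_absorption(lam, p: NAPParams | None = None):
    """NAP mass-specific absorption a*_NAP(λ), m² (mg C)⁻¹ (440 nm reference)."""
    p = p or NAPParams()
    lam = _check_wavelength(lam)
    if np.any(lam < 300) or np.any(lam > 800):
        raise InvalidInputError("wavelength outside [300, 800] nm")
    return p.a_star_ref * np.exp(-p.s_nap * (lam - p.lambda_ref_a))


def nap_specific_scattering(lam, p: NAPParams | None = None):
    """NAP mass-specific scattering and backscattering, m² (mg C)⁻¹.

    b*(λ) = b*(550) (550/λ)^f_NAP; backscattering is a flat fraction of it.
    Returns ``(b_star_nap, b_star_bnap)``.
    """
    p = p or NAPParams()
    lam = _check_wavelength(lam)
    if np.any(lam <= 0):
        raise InvalidInputError("wavelength must be > 0")
    b = p.b_star_ref * (p.lambda_ref_b / lam) ** p.f_nap
    return b, p.bb_ratio * b


def theta_chl(par, p: PhotoacclimationParams | None = None):
    """Photoacclimated Chl:C ratio θ_CHL(PAR), mg Chl (mg C)⁻¹.

    θ = θ0 · sigmoid(−(PAR − β)/σ) + θmin — strictly decreasing in PAR,
    bounded in (θmin, θmin + θ0), equal to θ0/2 + θmin at PAR = β.
    Evaluated through the numerically stable logistic form (``expit``), so
    very low and very high PAR are overflow-safe.
    """
    p = p or PhotoacclimationParams()
    par = np.asarray(par, dtype=float)
    if not np.all(np.isfinite(par)) or np.any(par < 0):
        raise InvalidInputError("PAR must be finite and >= 0")
    return p.theta0 * expit(-(par - p.beta) / p.sigma) + p.theta_min


# ---------------------------------------------------------------------------
# Bulk IOP assembly
# ---------------------------------------------------------------------------

def bulk_iops(
    x: ConstituentVector,
    par: float,
    cfg: BioOpticalConfig,
    grid: WavelengthGrid | None = None,
) -> BulkIOP:
    """Assemble bulk IOP spectra from constituent concentrations.

    a   = a_w  + a*_PH·Chl + a*_CDOM·CDOM + a*_NAP·NAP
    b   = b_w  + b*_PH·C              + b*_NAP·NAP
    b_b = b_bw + b*_bPH·C             + b*_bNAP·NAP

    with phytoplankton carbon C = Chl / θ_CHL(PAR).  CDOM does not scatter.
    """
    grid = grid or cfg.grid
    if grid.wavelengths != cfg.grid.wavelengths:
        raise ConfigError("grid does not match the configuration grid")
    lam = grid.as_array()

    theta = float(theta_chl(par, cfg.photo))
    if x.chl > 0 and not (np.isfinite(theta) and theta > 0):
        raise InvalidInputError("non-finite Chl:C ratio for the supplied PAR")
    carbon = x.chl / theta

    a_cdom = cdom_specific_absorption(lam, cfg.cdom)
    a_nap = nap_specific_absorption(lam, cfg.nap)
    b_nap, b_bnap = nap_specific_scattering(lam, cfg.nap)

    a = cfg.water.a_w + cfg.phyto.a_star_ph * x.chl + a_cdom * x.cdom + a_nap * x.nap
    b = cfg.water.b_w + cfg.phyto.b_star_ph * carbon + b_nap * x.nap
    b_b = cfg.water.b_bw + cfg.phyto.b_star_bph * carbon + b_bnap * x.nap
    return BulkIOP(grid=grid, a=a, b=b, b_b=b_b)


# ---------------------------------------------------------------------------
# Ensemble perturbation constructors (phytoplankton optics)
# ---------------------------------------------------------------------------

APH_FACTOR_RANGE = (0.05, 1.95)
BPH_SLOPE_RANGE = (0.5, 22.0)
BBPH_RATIO_RANGE = (1.3e-4, 5e-3)


def perturb_phyto_optics(
    ref: PhytoOpticalParams,
    aph_factor: float,
    bph_slope_ratio: float,
    bb_ratio: float,
    aph_mode: str = "uniform",
) -> PhytoOpticalParams:
    """Perturbed phytoplankton spectra for the optical sensitivity ensemble.

    Three knobs, each explored over the documented ranges:

    * ``aph_factor`` ∈ [0.05, 1.95] scales a*_PH.  In the default
      ``uniform`` mode the whole spectrum is multiplied by the factor; the
      alternative ``tilt`` mode applies the factor fully at the blue end
      (412.5 nm) and tapers it to 1 at the green end (555 nm), changing the
      blue-to-green shape rather than the amplitude.
    * ``bph_slope_ratio`` ∈ [0.5, 22] sets the b*_PH(412.5)/b*_PH(555)
      ratio.  The REF curve is multiplied by the power-law tilt
      (555/λ)^(η−η_ref) with η = ln(ratio)/ln(555/412.5): the 555 nm value
      is preserved exactly and the requested blue/green ratio is attained
      exactly, while the REF spectral fine structure is retained (the
      identity ratio reproduces REF unchanged).
    * ``bb_ratio`` ∈ [1.3e-4, 5e-3] sets a wavelength-flat
      b*_bPH(λ)/b*_PH(λ) ratio (the REF table's own ratio is flat to ~2%).
    """
    lo, hi = APH_FACTOR_RANGE
    if not (lo <= aph_factor <= hi):
        raise ConfigError(f"aph_factor {aph_factor} outside [{lo}, {hi}]")
    lo, hi = BPH_SLOPE_RANGE
    if not (lo <= bph_slope_ratio <= hi):
        raise ConfigError(f"bph_slope_ratio {bph_slope_ratio} outside [{lo}, {hi}]")
    lo, hi = BBPH_RATIO_RANGE
    if not (lo <= bb_ratio <= hi):
        raise ConfigError(f"bb_ratio {bb_ratio} outside [{lo}, {hi}]")
    if aph_mode not in ("uniform", "tilt"):
        raise ConfigError(f"unknown aph_mode {aph_mode!r}")

    lam = ref.grid.as_array()

    if aph_mode == "uniform":
        a_ph = ref.a_star_ph * aph_factor
    else:
        # Blue-anchored tilt: full factor at 412.5 nm decaying to 1 at 555 nm.
        weight = (_GREEN_NM - lam) / (_GREEN_NM - _BLUE_NM)
        a_ph = ref.a_star_ph * aph_factor**np.clip(weight, 0.0, 1.0)

    i_green = int(np.argmin(np.abs(lam - _GREEN_NM)))
    i_blue = int(np.argmin(np.abs(lam - _BLUE_NM)))
    eta = np.log(bph_slope_ratio) / np.log(_GREEN_NM / _BLUE_NM)
    ref_ratio = ref.b_star_ph[i_blue] / ref.b_star_ph[i_green]
    eta_ref = np.log(ref_ratio) / np.log(_GREEN_NM / _BLUE_NM)
    b_ph = ref.b_star_ph * (_GREEN_NM / lam) ** (eta - eta_ref)

    return PhytoOpticalParams(
        grid=ref.grid,
        a_star_ph=a_ph,
        b_star_ph=b_ph,
        b_star_bph=bb_ratio * b_ph,
    )
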