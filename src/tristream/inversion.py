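"""Retrieval of (Chl-a, CDOM, NAP) from observed remote-sensing reflectance.

The retrieval minimises the spectral least-squares cost

    J(x) = Σ_λ ( Rrs_model(λ, x) − Rrs_obs(λ) )²        [sr⁻²]

over the available wavelengths, with x = (Chl-a, CDOM, NAP) bounded to a
physically admissible box, using the limited-memory bound-constrained
quasi-Newton optimiser (L-BFGS-B).  Because the constituents span decades,
the optimiser works on log10-transformed concentrations (bounds mapped
accordingly); results are reported in linear units.  The cost landscape
can hold local minima, so several seeded starts are attempted and the best
minimiser kept.

:class:`ForwardOperator` caches every day-independent spectral quantity so
the forward model inside the optimisation loop reduces to a handful of
vector operations on the wavelength grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConfigError, DataError, InsufficientDataError
from .forward import (
    INTERFACE_GAMMA,
    INTERFACE_T,
    GeometryParams,
    SurfaceBoundary,
    _RESONANCE_NUDGE,
    _RESONANCE_RTOL,
)
from .optics import (
    BioOpticalConfig,
    ConstituentVector,
    cdom_specific_absorption,
    nap_specific_absorption,
    nap_specific_scattering,
    theta_chl,
)

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS = {
    "chl": (1e-3, 50.0),    # mg m^-3
    "cdom": (1e-2, 1e3),    # mg C m^-3
    "nap": (1e-2, 1e3),     # mg C m^-3
}


@dataclass(frozen=True)
class InversionSettings:
    """Optimiser configuration for the bounded retrieval."""

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 4
    seed: int = 0
    maxiter: int = 500
    ftol: float = 1e-16
    gtol: float = 1e-12
    min_wavelengths: int = 3
    #: stop trying further starts once J falls below this (machine-zero fit)
    early_exit_j: float = 1e-20
    surface_mode: str = "interface"

    def __post_init__(self):
        for key in ("chl", "cdom", "nap"):
            if key not in self.bounds:
                raise ConfigError(f"bounds missing constituent {key!r}")
            lo, hi = self.bounds[key]
            if not (0 < lo < hi):
                raise ConfigError(f"bounds for {key} must satisfy 0 < low < high")
        if self.n_starts < 1:
            raise ConfigError("at least one start is required")
        if self.min_wavelengths < 1:
            raise ConfigError("min_wavelengths must be >= 1")

    def bounds_array(self) -> np.ndarray:
        return np.array(
            [self.bounds["chl"], self.bounds["cdom"], self.bounds["nap"]],
            dtype=float,
        )


@dataclass(frozen=True)
class InversionResult:
    """Outcome of a single-spectrum retrieval."""

    x_hat: ConstituentVector
    j_final: float           # sr^-2
    converged: bool
    n_wavelengths_used: int
    start_index: int
    model_rrs: np.ndarray


class ForwardOperator:
    """Pre-compiled forward model Rrs(x) for one day's boundary condition.

    Caches the wavelength-dependent specific spectra, the stream geometry
    and the photoacclimated Chl:C ratio so that evaluating the full chain
    (bulk IOPs → analytic three-stream profile → surface transfer) costs a
    few vector operations.
    """

    def __init__(
        self,
        cfg: BioOpticalConfig,
        bc: SurfaceBoundary,
        geom: GeometryParams | None = None,
        surface_mode: str = "interface",
    ):
        if surface_mode not in ("interface", "identity"):
            raise ConfigError(f"unknown surface mode {surface_mode!r}")
        geom = geom or GeometryParams.from_sun_zenith(bc.sun_zenith)
        lam = cfg.grid.as_array()
        self.cfg = cfg
        self.geom = geom
        self.bc = bc
        self.surface_mode = surface_mode

        self._a_w = cfg.water.a_w
        self._b_w = cfg.water.b_w
        self._b_bw = cfg.water.b_bw
        self._aph = cfg.phyto.a_star_ph
        self._bph = cfg.phyto.b_star_ph
        self._bbph = cfg.phyto.b_star_bph
        self._acdom = cdom_specific_absorption(lam, cfg.cdom)
        self._anap = nap_specific_absorption(lam, cfg.nap)
        self._bnap, self._bbnap = nap_specific_scattering(lam, cfg.nap)
        self._theta = float(theta_chl(bc.par, cfg.photo))

        g = geom
        self._inv_cos = 1.0 / g.cos_theta_d
        self._inv_vdif = 1.0 / g.v_dif
        self._inv_vu = 1.0 / g.v_u
        self._r_dir, self._r_dif, self._r_u = g.r_dir, g.r_dif, g.r_u
        self._q = g.q_factor
        self._e_dir0 = bc.e_dir0
        self._e_dif0 = bc.e_dif0
        self._e_down0 = bc.e_dir0 + bc.e_dif0
        if np.any(self._e_down0 <= 0):
            raise DataError("zero total downward surface irradiance at some band")

    def rrs(self, x: np.ndarray) -> np.ndarray:
        """Modelled Rrs spectrum for constituents ``x = (chl, cdom, nap)``."""
        chl, cdom, nap = x
        carbon = chl / self._theta
        a = self._a_w + self._aph * chl + self._acdom * cdom + self._anap * nap
        b = self._b_w + self._bph * carbon + self._bnap * nap
        b_b = self._b_bw + self._bbph * carbon + self._bbnap * nap

        c_dir = (a + b) * self._inv_cos
        c_s = (a + self._r_dif * b_b) * self._inv_vdif
        c_u = (a + self._r_u * b_b) * self._inv_vu
        b_u = self._r_u * b_b * self._inv_vu
        b_s = self._r_dif * b_b * self._inv_vdif
        f_d = (b - self._r_dir * b_b) * self._inv_cos
        b_d = self._r_dir * b_b * self._inv_cos

        disc = (c_s + c_u) ** 2 - 4.0 * b_u * b_s
        k_plus = 0.5 * ((c_s - c_u) + np.sqrt(disc))
        r_plus = b_s / (c_u + k_plus)

        det_p = (c_s - c_dir) * (c_u + c_dir) - b_u * b_s
        scale = (c_s + c_dir) * (c_u + c_dir)
        res = np.abs(det_p) < _RESONANCE_RTOL * scale
        if np.any(res):
            c_dir = np.where(res, c_dir * (1.0 + _RESONANCE_NUDGE), c_dir)
            det_p = (c_s - c_dir) * (c_u + c_dir) - b_u * b_s
        x_coef = (f_d * (c_u + c_dir) + b_u * b_d) / det_p
        y_coef = ((c_s - c_dir) * b_d + b_s * f_d) / det_p

        e_u0 = (self._e_dif0 - x_coef * self._e_dir0) * r_plus + y_coef * self._e_dir0
        r = e_u0 / (self._q * self._e_down0)
        if self.surface_mode == "interface":
            return INTERFACE_T * r / (1.0 - INTERFACE_GAMMA * r)
        return r


def cost_j(
    x,
    rrs_obs: np.ndarray,
    operator: ForwardOperator,
    min_wavelengths: int = 3,
) -> float:
    """Spectral least-squares cost J(x), sr⁻², over valid wavelengths only."""
    obs = np.asarray(rrs_obs, dtype=float)
    valid = np.isfinite(obs)
    if int(valid.sum()) < min_wavelengths:
        raise InsufficientDataError(
            f"only {int(valid.sum())} valid wavelengths, need {min_wavelengths}"
        )
    xarr = x.as_array() if isinstance(x, ConstituentVector) else np.asarray(x, float)
    model = operator.rrs(xarr)
    diff = model[valid] - obs[valid]
    return float(diff @ diff)


def _default_starts(settings: InversionSettings) -> np.ndarray:
    """Multi-start initial guesses: the log-mid-bounds point plus seeded
    log-uniform jitters inside the box."""
    log_b = np.log10(settings.bounds_array())
    starts = [log_b.mean(axis=1)]
    rng = np.random.default_rng(settings.seed)
    for _ in range(settings.n_starts - 1):
        starts.append(rng.uniform(log_b[:, 0], log_b[:, 1]))
    return np.asarray(starts)


def invert_spectrum(
    rrs_obs,
    bc: SurfaceBoundary,
    cfg: BioOpticalConfig,
    settings: InversionSettings | None = None,
    geom: GeometryParams | None = None,
    extra_starts=None,
) -> InversionResult:
    """Bounded multi-start minimisation of J for one observed spectrum.

    ``extra_starts`` (linear units) are tried first — used by the series
    driver to warm-start from the previous day's solution.  All starts
    failing to converge yields ``converged=False``, never an exception.
    """
    settings = settings or InversionSettings()
    obs = np.asarray(rrs_obs, dtype=float)
    valid = np.isfinite(obs)
    n_valid = int(valid.sum())
    if n_valid < settings.min_wavelengths:
        raise InsufficientDataError(
            f"only {n_valid} valid wavelengths, need {settings.min_wavelengths}"
        )
    if np.any(obs[valid] < 0):
        raise DataError("negative Rrs in observation: record rejected")

    operator = ForwardOperator(cfg, bc, geom=geom, surface_mode=settings.surface_mode)
    obs_v = obs[valid]

    def fun(u):
        model = operator.rrs(10.0**u)
        diff = model[valid] - obs_v
        return float(diff @ diff)

    log_bounds = np.log10(settings.bounds_array())
    starts = _default_starts(settings)
    if extra_starts is not None:
        extra = np.log10(np.atleast_2d(np.asarray(extra_starts, dtype=float)))
        extra = np.clip(extra, log_bounds[:, 0], log_bounds[:, 1])
        starts = np.vstack([extra, starts])

    best = None
    for idx, u0 in enumerate(starts):
        res = minimize(
            fun,
            u0,
            method="L-BFGS-B",
            bounds=log_bounds,
            options={
                "maxiter": settings.maxiter,
                "ftol": settings.ftol,
                "gtol": settings.gtol,
            },
        )
        if best is None or res.fun < best[1].fun:
            best = (idx, res)
        if res.fun <= settings.early_exit_j:
            break

    idx, res = best
    x_lin = 10.0**res.x
    lin_bounds = settings.bounds_array()
    at_bound = np.any(
        (x_lin <= lin_bounds[:, 0] * (1 + 1e-9))
        | (x_lin >= lin_bounds[:, 1] * (1 - 1e-9))
    )
    if at_bound:
        warnings.warn(
            "retrieval pinned at a constituent bound: degenerate or "
            "uninformative spectrum",
            stacklevel=2,
        )
    model_full = np.full_like(obs, np.nan)
    model_full[valid] = operator.rrs(x_lin)[valid]
    return InversionResult(
        x_hat=ConstituentVector(*x_lin),
        j_final=float(res.fun),
        converged=bool(res.success),
        n_wavelengths_used=n_valid,
        start_index=int(idx),
        model_rrs=model_full,
    )


def invert_series(
    rrs_series: pd.DataFrame,
    boundary_series: pd.DataFrame,
    cfg: BioOpticalConfig,
    settings: InversionSettings | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Day-by-day retrieval over a dated Rrs series.

    ``rrs_series``: wide table indexed by date, one column per wavelength.
    ``boundary_series``: indexed by date with per-band ``e_dir_*`` /
    ``e_dif_*`` columns plus ``par`` and ``sun_zenith``.

    Dates are inner-joined; duplicated dates keep the first record (with a
    warning); days with too few valid bands or failed boundary data are
    skipped and counted.  Returns ``(results, report)`` where ``report``
    carries the matched/skipped bookkeeping.
    """
    settings = settings or InversionSettings()
    cfg_grid = cfg.grid

    def _dedup(df, name):
        if df.index.has_duplicates:
            warnings.warn(f"duplicate dates in {name}: keeping first", stacklevel=2)
            df = df[~df.index.duplicated(keep="first")]
        return df.sort_index()

    rrs_series = _dedup(rrs_series, "rrs series")
    boundary_series = _dedup(boundary_series, "boundary series")
    dates = rrs_series.index.intersection(boundary_series.index)
    if len(dates) == 0:
        raise DataError("no common dates between Rrs and boundary series")

    lam = cfg_grid.as_array()
    rrs_cols = _match_wavelength_columns(rrs_series.columns, lam)

    rows = []
    n_skipped_bands = 0
    n_failed = 0
    prev = None
    for date in dates:
        obs = rrs_series.loc[date, rrs_cols].to_numpy(dtype=float)
        if np.isfinite(obs).sum() < settings.min_wavelengths:
            n_skipped_bands += 1
            logger.info("skipping %s: too few valid bands", date)
            continue
        bc = boundary_from_row(boundary_series.loc[date], cfg_grid)
        try:
            result = invert_spectrum(
                obs,
                bc,
                cfg,
                settings,
                extra_starts=None if prev is None else [prev],
            )
        except DataError:
            n_failed += 1
            logger.warning("record rejected at %s", date)
            continue
        prev = result.x_hat.as_array()
        rows.append(
            {
                "date": date,
                "chl": result.x_hat.chl,
                "cdom": result.x_hat.cdom,
                "nap": result.x_hat.nap,
                "j_final": result.j_final,
                "converged": result.converged,
                "n_bands": result.n_wavelengths_used,
            }
        )

    report = {
        "n_obs": int(len(rrs_series)),
        "n_matched": int(len(dates)),
        "n_inverted": len(rows),
        "n_skipped_insufficient_bands": n_skipped_bands,
        "n_rejected": n_failed,
    }
    results = pd.DataFrame(
        rows,
        columns=["date", "chl", "cdom", "nap", "j_final", "converged", "n_bands"],
    )
    return results.set_index("date"), report


def _match_wavelength_columns(columns, lam, tol: float = 0.5):
    """Match observation band columns to grid wavelengths within ``tol`` nm."""
    out = []
    for target in lam:
        found = None
        for col in columns:
            try:
                value = float(col)
            except (TypeError, ValueError):
                continue
            if abs(value - target) <= tol:
                found = col
                break
        if found is None:
            raise DataError(f"no observation column for wavelength {target} nm")
        out.append(found)
    return out


def boundary_from_row(row: pd.Series, grid) -> SurfaceBoundary:
    """Build a :class:`SurfaceBoundary` from a boundary-table row with
    ``e_dir_<λ>`` / ``e_dif_<λ>`` columns plus ``par`` and ``sun_zenith``."""
    lam = grid.as_array()
    e_dir = np.array([row[f"e_dir_{v:g}"] for v in lam], dtype=float)
    e_dif = np.array([row[f"e_dif_{v:g}"] for v in lam], dtype=float)
    return SurfaceBoundary(
        grid=grid,
        e_dir0=e_dir,
        e_dif0=e_dif,
        par=float(row["par"]),
        sun_zenith=float(row["sun_zenith"]),
    )
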