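"""Quantitative receptor autoradiography densitometry.

Grey values of digitized autoradiographs code for tissue radioactivity; a
calibration curve fitted to co-exposed plastic tritium standards linearizes
them, and the radioactivity concentration R is converted to a binding-site
concentration (fmol/mg protein)

    C_b = R / (E * B * W_b * S_a) * (K_D + L) / L

where E is the scintillation-counter efficiency, B the number of decays per
unit time and radioactivity, W_b the protein weight of a standard, S_a the
specific activity of the ligand, K_D its dissociation constant and L the free
ligand concentration during incubation.  Depth-averaged densities per area
feed the 14-receptor fingerprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit

from .gli import ContourPair, SectionImage, Traverse, sample_profile

#: receptor column order as used throughout the package (fixed, printed order)
RECEPTOR_ORDER = (
    "AMPA", "kainate", "NMDA", "GABAA", "GABAB", "BZ",
    "M1", "M2", "M3", "alpha1", "alpha2", "5-HT1A", "5-HT2", "D1",
)


@dataclass(frozen=True)
class LigandParams:
    """Incubation and counting constants entering the linearization formula."""

    E: float      # counter efficiency (dimensionless)
    B: float      # decays per unit time and radioactivity (Ci/min per Ci)
    W_b: float    # protein weight of a standard (mg)
    S_a: float    # specific activity (Ci/mmol)
    K_D: float    # dissociation constant (nM)
    L: float      # free ligand concentration during incubation (nM)

    def __post_init__(self):
        for name in ("E", "B", "W_b", "S_a", "L"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.K_D < 0:
            raise ValueError("K_D must be >= 0")

    @property
    def scale(self) -> float:
        """R -> C_b proportionality constant."""
        return (self.K_D + self.L) / (self.L * self.E * self.B * self.W_b * self.S_a)


def validate_standards(standards: pd.DataFrame) -> pd.DataFrame:
    if not {"grey_value", "radioactivity"} <= set(standards.columns):
        raise ValueError("standards need columns grey_value and radioactivity")
    if len(standards) < 3:
        raise ValueError("calibration needs at least 3 standards")
    st = standards.sort_values("radioactivity").reset_index(drop=True)
    if not st["radioactivity"].is_monotonic_increasing or st["radioactivity"].duplicated().any():
        raise ValueError("standard radioactivities must be strictly increasing")
    g = st["grey_value"].to_numpy(float)
    if not (np.all(np.diff(g) > 0) or np.all(np.diff(g) < 0)):
        raise ValueError("standard grey values must be strictly monotone in radioactivity")
    return st


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map from autoradiograph grey value to radioactivity.

    ``flipped`` marks films that darken with dose (grey decreasing in
    radioactivity); internally such curves work on 255 - grey.
    """

    grey: np.ndarray            # effective grey of standards, ascending
    radioactivity: np.ndarray
    form: str                   # "exponential" or "pchip"
    params: tuple = ()
    flipped: bool = False

    def _effective(self, g: np.ndarray) -> np.ndarray:
        return 255.0 - g if self.flipped else g

    @property
    def domain(self) -> tuple[float, float]:
        lo, hi = float(self.grey[0]), float(self.grey[-1])
        if self.flipped:
            return 255.0 - hi, 255.0 - lo
        return lo, hi

    def __call__(self, grey_values):
        g = self._effective(np.asarray(grey_values, dtype=float))
        if self.form == "exponential":
            g0, a, c = self.params
            frac = np.clip((g - g0) / a, 0.0, 1.0 - 1e-12)
            r = -np.log1p(-frac) / c
        else:
            r = PchipInterpolator(self.grey, self.radioactivity)(g)
        return r if r.shape else float(r)


def film_response(R, g0: float, a: float, c: float):
    """Saturating film response grey = g0 + a * (1 - exp(-c R))."""
    return g0 + a * (1.0 - np.exp(-c * np.asarray(R, float)))


def fit_calibration(standards: pd.DataFrame, form: str = "auto") -> CalibrationCurve:
    """Fit the grey-to-radioactivity calibration curve from co-exposed standards.

    ``form="auto"`` tries the saturating-exponential film response and falls
    back to monotone piecewise-cubic (PCHIP) interpolation when the
    parametric fit does not reproduce the standards (e.g. perfectly linear
    standards); ``"pchip"`` or ``"exponential"`` force one branch.
    """
    st = validate_standards(standards)
    r = st["radioactivity"].to_numpy(float)
    g = st["grey_value"].to_numpy(float)
    flip = g[0] > g[-1]
    if flip:
        # films that darken with dose: work with inverted grey internally
        g = 255.0 - g
    if form in ("auto", "exponential"):
        try:
            span = g[-1] - g[0]
            p0 = (g[0] - 0.05 * span, 1.5 * span, 1.0 / max(r[-1], 1e-12))
            with warnings.catch_warnings():
                # near-linear standards make the saturation level unidentified;
                # the residual check below decides whether to keep the fit
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(film_response, r, g, p0=p0, maxfev=20000)
            resid = np.abs(film_response(r, *popt) - g)
            ok = popt[1] > 0 and popt[2] > 0 and resid.max() <= max(1e-6 * span, 1e-9)
        except (RuntimeError, ValueError):
            ok = False
        if ok:
            return CalibrationCurve(g, r, "exponential", tuple(popt), flipped=flip)
        if form == "exponential":
            raise ValueError("exponential calibration fit failed to reproduce the standards")
    return CalibrationCurve(g, r, "pchip", flipped=flip)


def radioactivity_to_density(R, p: LigandParams):
    """Convert radioactivity concentration to binding-site density (fmol/mg)."""
    R = np.asarray(R, dtype=float)
    out = R * p.scale
    return out if out.shape else float(out)


def density_to_radioactivity(C_b, p: LigandParams):
    """Inverse of the linearization formula (used to synthesize autoradiographs)."""
    C = np.asarray(C_b, dtype=float)
    out = C / p.scale
    return out if out.shape else float(out)


def linearize_autoradiograph(image: SectionImage, curve: CalibrationCurve,
                             p: LigandParams) -> tuple[SectionImage, int]:
    """Per-pixel grey -> radioactivity -> binding-site density.

    Grey values outside the calibration domain are clamped to it; the count
    of clamped pixels is returned (and warned about) so saturated films are
    visible downstream.
    """
    lo, hi = curve.domain
    px = np.asarray(image.pixels, dtype=float)
    n_clamped = int(np.count_nonzero((px < lo) | (px > hi)))
    if n_clamped:
        warnings.warn(f"{n_clamped} pixels outside calibration domain were clamped",
                      stacklevel=2)
    r = curve(np.clip(px, lo, hi))
    dens = radioactivity_to_density(r, p)
    return SectionImage(dens, resolution=image.resolution), n_clamped


def area_mean_density(density_image: SectionImage, contours: ContourPair,
                      traverses: list[Traverse], n_depth: int = 101) -> float:
    """Mean density over all cortical layers for one region of interest.

    Computes the surface below each receptor profile (trapezoidal rule over
    relative depth, i.e. the depth-averaged profile value) and averages over
    traverses.
    """
    if len(traverses) == 0:
        raise ValueError("need at least one traverse")
    means = []
    for i, tr in enumerate(traverses):
        prof = sample_profile(density_image, tr, n_depth=n_depth, index=i)
        means.append(np.trapezoid(prof.values, dx=1.0 / (n_depth - 1)))
    return float(np.mean(means))


def zscore_table(table: pd.DataFrame) -> pd.DataFrame:
    """z-score each receptor column separately (equal weighting of receptors).

    The relative ordering of areas within a receptor is preserved; a constant
    column has no scale and is rejected.
    """
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 areas")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    bad = sd[sd == 0]
    if len(bad):
        raise ValueError(f"constant receptor column(s): {list(bad.index)}")
    return (table - mean) / sd


def table_extrema(table: pd.DataFrame, receptor: str):
    """(argmax area, max, argmin area, min) for one receptor column."""
    if receptor not in table.columns:
        raise ValueError(f"unknown receptor {receptor!r}; expected one of {list(table.columns)}")
    col = table[receptor]
    return str(col.idxmax()), float(col.max()), str(col.idxmin()), float(col.min())


def fingerprint(table: pd.DataFrame, area: str, normalized: bool = False) -> pd.Series:
    """The ordered 14-receptor density vector of one area."""
    src = zscore_table(table) if normalized else table
    if area not in src.index:
        raise ValueError(f"unknown area {area!r}")
    return src.loc[area, list(RECEPTOR_ORDER)]


def plot_fingerprint(table: pd.DataFrame, area: str, normalized: bool = True, ax=None):
    """Polar fingerprint plot, 14 axes in the fixed receptor order, closed."""
    import matplotlib.pyplot as plt

    fp = fingerprint(table, area, normalized=normalized)
    vals = np.concatenate([fp.to_numpy(float), fp.to_numpy(float)[:1]])
    theta = np.linspace(0, 2 * np.pi, len(fp) + 1)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(theta, vals)
    ax.fill(theta, vals, alpha=0.25)
    ax.set_xticks(theta[:-1])
    ax.set_xticklabels(list(fp.index))
    ax.set_title(area)
    return ax
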