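"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate, at desk scale, the raw material of a quantitative
architectonic study: (i) cortical ribbons whose laminar mean profile changes
at known border positions, (ii) autoradiographs produced through a known
monotone film response together with co-exposed calibration standards,
(iii) long-format receptor density tables following the linear mixed model
with area, receptor and area x receptor fixed effects and a hemisphere random
intercept, and (iv) multi-area vertex time courses with a planted block
correlation structure.  Every generator is a pure function of its spec,
including the mandatory seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import quant
from .gli import ContourPair, SectionImage


# ---------------------------------------------------------------------------
# cortical ribbons


@dataclass(frozen=True)
class RibbonSpec:
    """A flat cortical ribbon with piecewise-distinct laminar mean profiles.

    ``laminar_means`` holds one depth curve (vector over relative depth 0..1)
    per segment; segment s applies to profile indices in
    [border_positions[s-1], border_positions[s]).  ``noise_sd`` is i.i.d.
    Gaussian pixel noise in grey-value units, clipped to [0, 255].
    """

    n_profiles: int
    border_positions: tuple[int, ...]
    laminar_means: tuple
    noise_sd: float
    seed: int
    depth_px: int = 80

    def __post_init__(self):
        bp = tuple(int(b) for b in self.border_positions)
        object.__setattr__(self, "border_positions", bp)
        lm = tuple(np.asarray(m, dtype=float) for m in self.laminar_means)
        object.__setattr__(self, "laminar_means", lm)
        if self.n_profiles < 2:
            raise ValueError("n_profiles must be >= 2")
        if self.depth_px < 4:
            raise ValueError("depth_px must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(b <= 0 or b >= self.n_profiles for b in bp):
            raise ValueError("border positions must lie strictly inside (0, n_profiles)")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("border positions must be strictly increasing")
        if len(lm) != len(bp) + 1:
            raise ValueError("need exactly one laminar mean curve per segment")
        for a, b in zip(lm, lm[1:]):
            na = np.interp(np.linspace(0, 1, 64), np.linspace(0, 1, a.size), a)
            nb = np.interp(np.linspace(0, 1, 64), np.linspace(0, 1, b.size), b)
            if np.allclose(na, nb):
                raise ValueError("adjacent segments must have distinct laminar means")


def make_ribbon(spec: RibbonSpec) -> tuple[SectionImage, ContourPair, tuple[int, ...]]:
    """Render a ribbon image, its bounding contours and the true border indices.

    Column j of the image carries segment s(j)'s laminar mean curve
    interpolated to ``depth_px`` samples, plus pixel noise.  The outer contour
    runs along the top row, the inner along the bottom row, so traverse i of
    ``build_traverses(contours, n_profiles)`` reads back column i.
    """
    rng = np.random.default_rng(spec.seed)
    depth = np.linspace(0.0, 1.0, spec.depth_px)
    seg_curves = [
        np.interp(depth, np.linspace(0, 1, m.size), m) for m in spec.laminar_means
    ]
    seg_of = np.zeros(spec.n_profiles, dtype=int)
    for b in spec.border_positions:
        seg_of[b:] += 1
    img = np.empty((spec.depth_px, spec.n_profiles))
    for j in range(spec.n_profiles):
        img[:, j] = seg_curves[seg_of[j]]
    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape) if spec.noise_sd > 0 else img
    img = np.clip(img, 0.0, 255.0)
    w = spec.n_profiles
    outer = np.array([[0.0, 0.0], [w - 1.0, 0.0]])
    inner = np.array([[0.0, spec.depth_px - 1.0], [w - 1.0, spec.depth_px - 1.0]])
    return SectionImage(img), ContourPair(outer, inner), spec.border_positions


# ---------------------------------------------------------------------------
# autoradiographs


def make_autoradiograph(density_map: np.ndarray,
                        curve_params: tuple[float, float, float],
                        p: quant.LigandParams,
                        standard_radioactivities) -> tuple[SectionImage, pd.DataFrame]:
    """Forward-render an autoradiograph from a planted density map.

    Densities are converted to radioactivity through the inverse of the
    linearization formula, then to grey values through the saturating film
    response ``grey = g0 + a (1 - exp(-c R))`` with ``curve_params =
    (g0, a, c)``.  A standards table (grey value per known radioactivity) is
    produced from the same response, emulating co-exposed tritium standards.
    """
    g0, a, c = curve_params
    if a <= 0 or c <= 0:
        raise ValueError("film response requires a > 0 and c > 0")
    stds = np.asarray(standard_radioactivities, dtype=float)
    if stds.size < 3:
        raise ValueError("calibration needs >= 3 standards")
    dens = np.asarray(density_map, dtype=float)
    if np.any(dens < 0):
        raise ValueError("densities must be nonnegative")
    r = quant.density_to_radioactivity(dens, p)
    r_max = max(float(np.max(r, initial=0.0)), float(stds.max()))
    if c * r_max > -np.log(1e-9):
        raise ValueError("density outside the invertible range of the film response")
    grey = quant.film_response(r, g0, a, c)
    if np.any(grey < 0) or np.any(grey > 255):
        raise ValueError("film response leaves the 8-bit grey range for these densities")
    table = pd.DataFrame({
        "grey_value": quant.film_response(stds, g0, a, c),
        "radioactivity": stds,
    })
    return SectionImage(np.asarray(grey)), table


# ---------------------------------------------------------------------------
# long-format density tables


def _expand_effects(eff, shape, kind: str) -> np.ndarray:
    """Accept a scalar effect magnitude (deterministic centred pattern) or a
    fully specified array, in residual-SD units."""
    if np.isscalar(eff):
        e = float(eff)
        if kind == "area":
            pat = np.linspace(-1.0, 1.0, shape[0])
            return e * pat
        if kind == "receptor":
            pat = np.linspace(-1.0, 1.0, shape[0])
            return e * pat
        # interaction: +-1 checkerboard, orthogonal to both main effects
        a_idx = np.arange(shape[0])[:, None]
        r_idx = np.arange(shape[1])[None, :]
        pat = np.where((a_idx + r_idx) % 2 == 0, 1.0, -1.0)
        pat -= pat.mean()
        return e * pat
    arr = np.asarray(eff, dtype=float)
    if arr.shape != shape:
        raise ValueError(f"{kind} effect array must have shape {shape}, got {arr.shape}")
    return arr


@dataclass(frozen=True)
class DensitySimSpec:
    """Generative counterpart of the three-level density model.

    Effect sizes are standardized (residual-SD units); scalars expand into
    deterministic centred patterns, arrays are used as given.  Defaults match
    the study layout: 33 areas x 14 receptors x 4 hemispheres.
    """

    n_areas: int = 33
    n_receptors: int = 14
    n_hemispheres: int = 4
    grand_mean: float = 0.0
    area_effects: object = 0.0
    receptor_effects: object = 0.0
    interaction_effects: object = 0.0
    hemisphere_sd: float = 0.5
    residual_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_areas < 2 or self.n_receptors < 1:
            raise ValueError("need at least 2 areas and 1 receptor")
        if min(self.hemisphere_sd, self.residual_sd) < 0:
            raise ValueError("all SDs must be >= 0")
        # conformability check happens eagerly so bad specs fail at build time
        _expand_effects(self.area_effects, (self.n_areas,), "area")
        _expand_effects(self.receptor_effects, (self.n_receptors,), "receptor")
        _expand_effects(self.interaction_effects,
                        (self.n_areas, self.n_receptors), "interaction")


def make_density_long_table(spec: DensitySimSpec) -> pd.DataFrame:
    """One density row per (area, receptor, hemisphere), tidy format.

    D = grand_mean + sigma*(A_a + R_r + AR_ar) + H_h + eps, with Gaussian
    hemisphere intercepts H_h ~ N(0, hemisphere_sd^2) and residuals
    eps ~ N(0, residual_sd^2); sigma is the residual SD (1 when residual_sd
    is 0 so that noiseless tables still carry the requested effect pattern).
    """
    if spec.n_hemispheres < 2:
        warnings.warn("fewer than 2 hemispheres: hemisphere random effect unidentifiable",
                      stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    sigma = spec.residual_sd if spec.residual_sd > 0 else 1.0
    a_eff = _expand_effects(spec.area_effects, (spec.n_areas,), "area") * sigma
    r_eff = _expand_effects(spec.receptor_effects, (spec.n_receptors,), "receptor") * sigma
    ar_eff = _expand_effects(spec.interaction_effects,
                             (spec.n_areas, spec.n_receptors), "interaction") * sigma
    h_eff = rng.normal(0.0, spec.hemisphere_sd, size=spec.n_hemispheres)
    rows = []
    for h in range(spec.n_hemispheres):
        noise = rng.normal(0.0, spec.residual_sd,
                           size=(spec.n_areas, spec.n_receptors))
        d = (spec.grand_mean + a_eff[:, None] + r_eff[None, :] + ar_eff
             + h_eff[h] + noise)
        for a in range(spec.n_areas):
            for r in range(spec.n_receptors):
                rows.append((f"A{a:02d}", f"R{r:02d}", f"H{h}", d[a, r]))
    return pd.DataFrame(rows, columns=["area", "receptor", "hemisphere", "density"])


# ---------------------------------------------------------------------------
# BOLD-like time courses


@dataclass(frozen=True)
class BoldSimSpec:
    """Multi-area vertex time courses with a planted block covariance.

    Latent area signals are drawn through the Cholesky factor of
    ``block_structure`` (symmetric, unit diagonal, PSD); every vertex of an
    area carries that area's latent signal plus i.i.d. Gaussian noise.
    Defaults mirror one resting-state scan of 250 volumes.
    """

    n_areas: int
    vertices_per_area: int = 20
    n_timepoints: int = 250
    block_structure: object = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        bs = self.block_structure
        bs = np.eye(self.n_areas) if bs is None else np.asarray(bs, dtype=float)
        if bs.shape != (self.n_areas, self.n_areas):
            raise ValueError("block_structure must be n_areas x n_areas")
        if not np.allclose(bs, bs.T):
            raise ValueError("block_structure must be symmetric")
        if not np.allclose(np.diag(bs), 1.0):
            raise ValueError("block_structure must have unit diagonal")
        eig = np.linalg.eigvalsh(bs)
        if eig.min() < -1e-10:
            raise ValueError("block_structure must be positive semidefinite")
        object.__setattr__(self, "block_structure", bs)


@dataclass(frozen=True)
class TimeCourseSet:
    """Vertex x time matrix with vertex-to-area labels (one subject or a
    concatenated group)."""

    data: np.ndarray
    labels: np.ndarray
    subject_ids: tuple = ("s0",)
    segments: tuple = ()   # (start, stop) timepoint slices per subject

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        lab = np.asarray(self.labels)
        if d.ndim != 2 or d.shape[1] < 2:
            raise ValueError("data must be vertices x timepoints with >= 2 timepoints")
        if lab.shape[0] != d.shape[0]:
            raise ValueError("need one label per vertex")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "labels", lab)
        if not self.segments:
            object.__setattr__(self, "segments", ((0, d.shape[1]),))

    @property
    def areas(self) -> list[str]:
        seen = {}
        for l in self.labels:
            seen.setdefault(str(l), None)
        return list(seen)


def make_bold(spec: BoldSimSpec) -> TimeCourseSet:
    """Simulate one subject's labelled vertex time courses."""
    rng = np.random.default_rng(spec.seed)
    # eigh-based factor tolerates PSD (rank-deficient) structures, e.g. r = 1
    w, v = np.linalg.eigh(spec.block_structure)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    latent = rng.standard_normal((spec.n_timepoints, spec.n_areas)) @ factor.T
    v_total = spec.n_areas * spec.vertices_per_area
    data = np.empty((v_total, spec.n_timepoints))
    labels = np.empty(v_total, dtype=object)
    for a in range(spec.n_areas):
        sl = slice(a * spec.vertices_per_area, (a + 1) * spec.vertices_per_area)
        noise = (rng.normal(0.0, spec.noise_sd, size=(spec.vertices_per_area, spec.n_timepoints))
                 if spec.noise_sd > 0 else 0.0)
        data[sl] = latent[:, a][None, :] + noise
        labels[sl] = f"A{a:02d}"
    return TimeCourseSet(data, labels)
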