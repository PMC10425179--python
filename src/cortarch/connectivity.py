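"""Seed-based functional connectivity over labelled cortical areas.

Per-vertex time courses are demeaned per subject and concatenated in time so
a single group analysis covers all subjects.  Each area's representative
time course is the first principal component of its vertex courses
(sign-aligned with the area mean); seed maps are Pearson correlations of the
seed's representative course with every vertex (and every other area's
representative course), Fisher r-to-z transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import TimeCourseSet

#: |r| is clipped here before atanh so z stays finite at r = +-1
R_CLIP = 1.0 - 1e-7


def fisher_z(r, clip: float = R_CLIP):
    """Variance-stabilizing atanh transform with clipping at |r| <= clip."""
    r = np.asarray(r, dtype=float)
    out = np.arctanh(np.clip(r, -clip, clip))
    return out if out.shape else float(out)


def demean_concatenate(subject_matrices, labels, subject_ids=None) -> TimeCourseSet:
    """Demean each vertex course per subject, then concatenate in time."""
    mats = [np.asarray(m, dtype=float) for m in subject_matrices]
    if not mats:
        raise ValueError("need at least one subject")
    v = mats[0].shape[0]
    if any(m.ndim != 2 or m.shape[0] != v for m in mats):
        raise ValueError("all subjects must share the vertex count")
    demeaned = [m - m.mean(axis=1, keepdims=True) for m in mats]
    data = np.concatenate(demeaned, axis=1)
    stops = np.cumsum([m.shape[1] for m in mats])
    segments = tuple((int(a), int(b)) for a, b in zip(np.r_[0, stops[:-1]], stops))
    ids = tuple(subject_ids) if subject_ids is not None else tuple(
        f"s{i}" for i in range(len(mats)))
    if len(ids) != len(mats):
        raise ValueError("need one subject id per matrix")
    return TimeCourseSet(data, np.asarray(labels), subject_ids=ids, segments=segments)


def representative_timecourse(tcs: TimeCourseSet, area: str,
                              normalize: bool = False) -> np.ndarray:
    """First principal component of an area's vertex courses.

    The component is computed on demeaned courses (covariance PCA;
    ``normalize=True`` switches to correlation PCA) and sign-aligned to
    correlate positively with the area's mean course.  Among unit-norm
    linear combinations of the vertex courses it maximizes explained
    variance.
    """
    mask = np.asarray([str(l) == str(area) for l in tcs.labels])
    if not mask.any():
        raise ValueError(f"unknown area {area!r}")
    x = tcs.data[mask]
    x = x - x.mean(axis=1, keepdims=True)
    if normalize:
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x / sd
    if x.shape[0] == 1:
        rep = x[0]
    else:
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        rep = vt[0]
    mean_course = x.mean(axis=0)
    if mean_course.any() and np.dot(rep, mean_course) < 0:
        rep = -rep
    return rep


@dataclass(frozen=True)
class SeedMap:
    """Connectivity of one seed area with every vertex and every area."""

    seed: str
    vertex_r: np.ndarray
    vertex_z: np.ndarray
    valid: np.ndarray          # False where target variance was zero
    area_r: pd.Series
    area_z: pd.Series

    def __post_init__(self):
        r = self.vertex_r[self.valid]
        if r.size and (np.nanmin(r) < -1 - 1e-9 or np.nanmax(r) > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")


def _corr_with(vector: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = vector - vector.mean()
    m = matrix - matrix.mean(axis=1, keepdims=True)
    denom_v = np.sqrt((v ** 2).sum())
    denom_m = np.sqrt((m ** 2).sum(axis=1))
    valid = (denom_m > 0) & (denom_v > 0)
    r = np.full(matrix.shape[0], np.nan)
    r[valid] = (m[valid] @ v) / (denom_m[valid] * denom_v)
    return r, valid


def seed_map(tcs: TimeCourseSet, seed_area: str, clip: float = R_CLIP) -> SeedMap:
    """Pearson seed map of one area against all vertices and all areas."""
    rep = representative_timecourse(tcs, seed_area)
    vr, valid = _corr_with(rep, tcs.data)
    vz = np.where(valid, np.arctanh(np.clip(vr, -clip, clip)), np.nan)
    areas = tcs.areas
    ar = {}
    for a in areas:
        other = representative_timecourse(tcs, a)
        r, ok = _corr_with(rep, other[None, :])
        ar[a] = r[0] if ok[0] else np.nan
    area_r = pd.Series(ar)
    area_z = pd.Series({a: fisher_z(r, clip) if np.isfinite(r) else np.nan
                        for a, r in ar.items()})
    return SeedMap(seed=str(seed_area), vertex_r=vr, vertex_z=vz, valid=valid,
                   area_r=area_r, area_z=area_z)


def connectivity_summary(tcs: TimeCourseSet, areas=None,
                         clip: float = R_CLIP) -> pd.DataFrame:
    """Symmetric area x area Fisher-z matrix of representative-course
    correlations; the self-connectivity diagonal is flagged as NaN."""
    areas = list(areas) if areas is not None else tcs.areas
    reps = {}
    for a in areas:
        reps[a] = representative_timecourse(tcs, a)
    n = len(areas)
    z = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            r, ok = _corr_with(reps[areas[i]], reps[areas[j]][None, :])
            if not ok[0]:
                raise ValueError(f"zero-variance representative course for {areas[j]!r}")
            z[i, j] = z[j, i] = fisher_z(r[0], clip)
    return pd.DataFrame(z, index=areas, columns=areas)
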