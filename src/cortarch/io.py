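"""Packaged fixtures, the area registry, and shared format readers/writers.

The density fixture is the published 33-area x 14-receptor table of mean
absolute receptor densities (fmol/mg protein) with per-cell SDs; the ligand
fixture carries the free ligand concentration L (nM) used during incubation
for each receptor's tritiated ligand.  Both ship as CSV with an embedded
checksum so silent corruption is rejected at load time.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import numpy as np
import pandas as pd

from .gli import ContourPair, SectionImage
from .quant import RECEPTOR_ORDER, LigandParams

_DENSITY_SHA256 = "68afb6fb0d3ab331c89215e144653718c99caa09697691504a29d28287ae5199"

#: the 33 areas with measured densities, in fixture (rostro-caudal) order
PREFRONTAL_AREAS_MEASURED: tuple[str, ...] = (
    "10d", "10md", "10mv", "10o", "14r", "11m", "11l", "13b", "13m", "13l",
    "12r", "12m", "12l", "12o", "9m", "9d", "9l", "a46d", "a46df", "a46vf",
    "a46v", "p46d", "p46df", "p46vf", "p46v", "8Bm", "8Bd", "8Bs", "8Ad",
    "8Av", "45A", "45B", "44",
)

#: all 35 delineated prefrontal areas (13a and 14c lack density data)
PREFRONTAL_AREAS: tuple[str, ...] = PREFRONTAL_AREAS_MEASURED + ("13a", "14c")

#: cortical regions outside the prefrontal parcellation used as connectivity
#: targets, with their area counts (region names per lobe; individual target
#: labels are synthetic placeholders generated from these counts)
OTHER_REGION_COUNTS = {
    "premotor": 16,
    "cingulate": 15,
    "somatosensory": 6,
    "parietal": 23,
    "occipital": 16,
}


def _fixture_bytes(name: str) -> bytes:
    return resources.files("cortarch.data").joinpath(name).read_bytes()


def load_density_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged mean-density table and its SD table (33 areas x 14 receptors)."""
    raw = _fixture_bytes("receptor_densities.csv")
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _DENSITY_SHA256:
        raise ValueError(f"density fixture checksum mismatch: {digest}")
    df = pd.read_csv(pd.io.common.BytesIO(raw)).set_index("area")
    means = df[list(RECEPTOR_ORDER)].astype(float)
    sds = df[[f"{r}_sd" for r in RECEPTOR_ORDER]].astype(float)
    sds.columns = list(RECEPTOR_ORDER)
    return means, sds


def load_ligand_fixture() -> pd.DataFrame:
    """Per-receptor ligand table with the incubation concentration L (nM).

    The published labelling-protocol table covers 13 of the 14 receptors; the
    D1 row is present with L missing and must be supplied by configuration,
    as must the counting constants (E, B, W_b, S_a) and K_D for every ligand.
    """
    df = pd.read_csv(pd.io.common.BytesIO(_fixture_bytes("ligands.csv")))
    return df.set_index("receptor").reindex(list(RECEPTOR_ORDER))


def ligand_params(receptor: str, E: float, B: float, W_b: float, S_a: float,
                  K_D: float, L: float | None = None) -> LigandParams:
    """Build LigandParams, pulling L from the packaged fixture when omitted."""
    if L is None:
        lig = load_ligand_fixture()
        L = lig.loc[receptor, "L_nM"]
        if not np.isfinite(L):
            raise ValueError(
                f"no packaged incubation concentration for {receptor!r}; supply L")
    return LigandParams(E=E, B=B, W_b=W_b, S_a=S_a, K_D=K_D, L=float(L))


def area_registry() -> pd.DataFrame:
    """Registry of all connectivity areas: 35 prefrontal + 76 other = 111.

    Non-prefrontal target labels are synthetic placeholders (e.g.
    ``premotor-01``): the published analysis names them via prior
    parcellations whose labels are not part of this package's fixtures.
    Stable integer ids are assigned in registry order.
    """
    rows = [(a, "prefrontal") for a in PREFRONTAL_AREAS]
    for region, n in OTHER_REGION_COUNTS.items():
        rows += [(f"{region}-{i + 1:02d}", region) for i in range(n)]
    reg = pd.DataFrame(rows, columns=["area", "region"])
    reg.insert(0, "area_id", np.arange(len(reg)))
    return reg


# ---------------------------------------------------------------------------
# format readers / writers


def write_image(path, image: SectionImage) -> None:
    """8-bit PNG/TIFF for grey images, 32-bit float TIFF for density images."""
    import tifffile
    from PIL import Image

    path = str(path)
    px = np.asarray(image.pixels)
    if path.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, px.astype(np.float32))
    else:
        Image.fromarray(np.clip(px, 0, 255).astype(np.uint8)).save(path)


def read_image(path, resolution: float = 1.0) -> SectionImage:
    import tifffile
    from PIL import Image

    path = str(path)
    if path.endswith((".tif", ".tiff")):
        px = tifffile.imread(path)
    else:
        px = np.asarray(Image.open(path).convert("L"))
    return SectionImage(np.asarray(px, dtype=float), resolution=resolution)


def write_contours(path, contours: ContourPair) -> None:
    rows = []
    for role, poly in (("outer", contours.outer), ("inner", contours.inner)):
        for i, (x, y) in enumerate(poly):
            rows.append((0, role, i, x, y))
    pd.DataFrame(rows, columns=["contour_id", "role", "vertex_index", "x", "y"]
                 ).to_csv(path, index=False)


def read_contours(path) -> ContourPair:
    df = pd.read_csv(path)
    def poly(role):
        sub = df[df["role"] == role].sort_values("vertex_index")
        return sub[["x", "y"]].to_numpy(float)
    return ContourPair(poly("outer"), poly("inner"))


def write_profiles(path, profiles: np.ndarray) -> None:
    """Profiles or feature vectors as TSV with a profile_index column."""
    arr = np.atleast_2d(np.asarray(profiles, float))
    cols = [f"depth_{i}" for i in range(arr.shape[1])] if arr.shape[1] != 10 else [
        f"f{i + 1}" for i in range(10)]
    df = pd.DataFrame(arr, columns=cols)
    df.insert(0, "profile_index", np.arange(arr.shape[0]))
    df.to_csv(path, sep="\t", index=False)


def read_profiles(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=["profile_index"]).to_numpy(float)


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
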