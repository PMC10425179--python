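"""End-to-end demo pipeline on synthetic data, with a run manifest.

Stages run in dependency order on generated inputs: ribbon simulation, GLI
profile extraction, border detection, autoradiograph quantification,
three-level density statistics, fingerprint clustering/PCA on the packaged
density table, and seed-based connectivity.  Every stage is a pure function
of (inputs, config): the manifest records seeds, parameters and package
versions, and identical manifests imply identical outputs.
"""

from __future__ import annotations

import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, borders, cluster, connectivity, gli, io, quant, stats, synthetic

STAGES = ("simulate", "profiles", "borders", "quantify", "stats",
          "cluster", "connectivity")


@dataclass(frozen=True)
class PipelineConfig:
    """Every defaulted parameter appears in the emitted manifest."""

    seed: int = 0
    # ribbon / border stage
    n_profiles: int = 200
    border_positions: tuple[int, ...] = (100,)
    ribbon_noise_sd: float = 4.0
    block_range: tuple[int, ...] = borders.DEFAULT_BLOCK_RANGE
    alpha: float = 0.05
    stability_window: int = 2
    stability_fraction: float = 0.5
    n_depth: int = 101
    # densitometry stage (counting constants are configuration, not fixtures)
    ligand_receptor: str = "AMPA"
    E: float = 0.4
    B: float = 2.0
    W_b: float = 0.05
    S_a: float = 80.0
    K_D: float = 1.0
    calibration_form: str = "auto"
    # stats stage
    stats_areas: int = 5
    stats_receptors: int = 4
    stats_hemispheres: int = 4
    interaction_effect: float = 2.0
    # cluster stage
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_permutations: int = 99
    n_restarts: int = 10
    # connectivity stage
    n_subjects: int = 3
    n_areas_bold: int = 6
    n_timepoints: int = 250

    def validate(self) -> None:
        if self.ligand_receptor not in quant.RECEPTOR_ORDER:
            raise ValueError(f"unknown receptor {self.ligand_receptor!r}")
        for name in ("E", "B", "W_b", "S_a"):
            if not getattr(self, name) > 0:
                raise ValueError(f"missing/invalid ligand constant {name}")
        if self.K_D < 0:
            raise ValueError("missing/invalid ligand constant K_D")


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all analytic stages; write outputs and a machine-readable manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "package": "cortarch",
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": [],
        "outputs": {},
    }

    # --- simulate + profiles + borders -------------------------------------
    _log("simulate", "generating synthetic ribbon")
    base = np.full(32, 30.0)
    shifted = base + 12.0
    spec = synthetic.RibbonSpec(
        n_profiles=config.n_profiles, border_positions=config.border_positions,
        laminar_means=tuple([base] + [shifted, base][: len(config.border_positions)]),
        noise_sd=config.ribbon_noise_sd, seed=int(rng.integers(2 ** 31)))
    image, contours, truth = synthetic.make_ribbon(spec)
    io.write_image(outdir / "ribbon.tif", image)
    io.write_contours(outdir / "contours.csv", contours)
    manifest["stages"].append("simulate")

    _log("profiles", "extracting GLI profiles and feature vectors")
    traverses = gli.build_traverses(contours, spec.n_profiles)
    profiles = [gli.sample_profile(image, t, n_depth=config.n_depth, index=i)
                for i, t in enumerate(traverses)]
    feats = gli.featurize_ribbon(profiles)
    io.write_profiles(outdir / "features.tsv", feats)
    manifest["stages"].append("profiles")

    _log("borders", "sliding-window MD border detection")
    cands = borders.detect_borders(
        feats, block_range=config.block_range, alpha=config.alpha,
        stability_window=config.stability_window,
        stability_fraction=config.stability_fraction)
    io.write_manifest(outdir / "borders.json", {
        "true_borders": list(truth),
        "candidates": [asdict(c) for c in cands]})
    manifest["stages"].append("borders")

    # --- quantify ----------------------------------------------------------
    _log("quantify", "densitometric round trip on a synthetic autoradiograph")
    params = io.ligand_params(config.ligand_receptor, E=config.E, B=config.B,
                              W_b=config.W_b, S_a=config.S_a, K_D=config.K_D)
    dens_true = np.linspace(100.0, 900.0, 64)[None, :] * np.ones((32, 1))
    r_hi = quant.density_to_radioactivity(1200.0, params)
    curve_params = (10.0, 230.0, 1.5 / r_hi)
    standards = np.linspace(0.05, 1.0, 8) * r_hi
    auto_img, std_table = synthetic.make_autoradiograph(
        dens_true, curve_params, params, standards)
    curve = quant.fit_calibration(std_table, form=config.calibration_form)
    dens_img, n_clamped = quant.linearize_autoradiograph(auto_img, curve, params)
    rel_err = float(np.max(np.abs(dens_img.pixels - dens_true) / dens_true))
    io.write_image(outdir / "density.tif", dens_img)
    manifest["outputs"]["roundtrip_max_rel_error"] = rel_err
    manifest["outputs"]["clamped_pixels"] = n_clamped
    manifest["stages"].append("quantify")

    # --- stats -------------------------------------------------------------
    _log("stats", "three-level mixed-model statistics on simulated densities")
    dspec = synthetic.DensitySimSpec(
        n_areas=config.stats_areas, n_receptors=config.stats_receptors,
        n_hemispheres=config.stats_hemispheres,
        interaction_effects=config.interaction_effect,
        seed=int(rng.integers(2 ** 31)))
    long_table = synthetic.make_density_long_table(dspec)
    long_table.to_csv(outdir / "densities_long.csv", index=False)
    omni = stats.omnibus_interaction(long_table)
    ledger = [dict(level=1, contrast=omni.contrast, p_raw=omni.p_raw,
                   p_fdr=omni.p_fdr, family=omni.family)]
    if omni.p_raw <= config.alpha:
        lvl2 = stats.simple_effects(long_table, require_gate=False)
        ledger += lvl2[["level", "contrast", "p_raw", "p_fdr", "family"]
                       ].to_dict("records")
        for rec in lvl2.loc[lvl2["p_fdr"] <= config.alpha, "contrast"]:
            lvl3 = stats.posthoc_pairs(long_table, rec, require_gate=False)
            ledger += lvl3[["level", "contrast", "p_raw", "p_fdr", "family"]
                           ].head(3).to_dict("records")
    pd.DataFrame(ledger).to_csv(outdir / "test_ledger.csv", index=False)
    manifest["stages"].append("stats")

    # --- cluster -----------------------------------------------------------
    _log("cluster", "fingerprint clustering and PCA on the packaged table")
    means, _ = io.load_density_fixture()
    z = quant.zscore_table(means)
    dend = cluster.ward_cluster(z)
    coph = cluster.cophenetic_correlation(dend, z)
    sel = cluster.kmeans_select(z, k_range=config.k_range,
                                n_permutations=config.n_permutations,
                                n_restarts=config.n_restarts,
                                seed=int(rng.integers(2 ** 31)))
    _, scores, frac = cluster.pca(z)
    (outdir / "dendrogram.nwk").write_text(dend.to_newick())
    pd.DataFrame(scores[:, :2], index=z.index,
                 columns=["PC1", "PC2"]).to_csv(outdir / "pca_scores.csv")
    manifest["outputs"]["cophenetic_ward"] = coph
    manifest["outputs"]["kmeans_k"] = sel.k
    manifest["outputs"]["pca_two_component_variance"] = float(frac[:2].sum())
    manifest["stages"].append("cluster")

    # --- connectivity ------------------------------------------------------
    _log("connectivity", "seed-based connectivity on simulated time courses")
    n_a = config.n_areas_bold
    block = np.eye(n_a)
    half = n_a // 2
    block[:half, :half] = 0.6
    block[half:, half:] = 0.6
    np.fill_diagonal(block, 1.0)
    subjects = [synthetic.make_bold(synthetic.BoldSimSpec(
        n_areas=n_a, n_timepoints=config.n_timepoints,
        block_structure=block, seed=int(rng.integers(2 ** 31))))
        for _ in range(config.n_subjects)]
    tcs = connectivity.demean_concatenate(
        [s.data for s in subjects], subjects[0].labels)
    summary = connectivity.connectivity_summary(tcs)
    summary.to_csv(outdir / "connectivity_z.csv")
    manifest["outputs"]["n_concatenated_timepoints"] = int(tcs.data.shape[1])
    manifest["stages"].append("connectivity")

    io.write_manifest(outdir / "manifest.json", manifest)
    _log("report", f"manifest written to {outdir / 'manifest.json'}")
    return manifest
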