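"""End-to-end wiring: simulate → analyze → permeability (→ mixing), with manifests.

Every pipeline invocation writes a JSON manifest echoing the configuration,
seeds, package version and all input/output paths, sufficient to reproduce the
outputs bit-for-bit on the same platform RNG.
"""

from __future__ import annotations

import datetime
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .core import Profile1D, Thermo, load_config, read_profile, write_profile
from .mixing import MixingSpec, SpeciesState, crossing_pka, pka_sweep
from .ofr_analysis import (bdfdt_estimate, bin_work, combine_runs,
                           diffusion_profile, fr_estimates, integrate_pmf,
                           merge_stats)
from .permeability import isd_permeability
from .presets import (double_well_profiles, double_well_protocol,
                      o2_like_profiles, tyramine_like_profiles,
                      tyramine_like_protocol)
from .steer_sim import (SimConfig, default_dt, generate_fixture_set,
                        make_protocol, read_trajectory)

__all__ = ["run_pipeline", "make_demo_config", "analyze_trajectories"]

log = logging.getLogger("permeate")


def analyze_trajectories(trajs, bin_width: float = 0.2, window: int = 9,
                         reference_z: float | None = None,
                         estimator: str = "bdfdt"):
    """Shared analysis path: bin → estimate per run → combine → integrate/invert.

    Returns ``(pmf, diffusion, combined_estimates, per_run_stats)``.
    """
    if estimator not in ("fr", "bdfdt"):
        raise ValueError("estimator must be 'fr' or 'bdfdt'")
    stats_list = [bin_work(t, bin_width=bin_width) for t in trajs]
    est = fr_estimates if estimator == "fr" else bdfdt_estimate
    per_run = [est(s) for s in stats_list]
    combined = combine_runs(per_run)
    if reference_z is None:
        reference_z = float(combined.bin_edges[0])
    pmf = integrate_pmf(combined, reference_z=reference_z)
    pooled = merge_stats(stats_list)
    thermo = trajs[0].thermo
    diff = diffusion_profile(combined, pooled, thermo, window=window)
    return pmf, diff, combined, stats_list


def run_pipeline(config_path: str | Path, out_dir: str | Path,
                 traj_paths: list | None = None) -> dict:
    """Execute the configured pipeline stages and write outputs plus a manifest.

    Stages: simulate (skipped when ``traj_paths`` is given), analyze, perm,
    and mix when the config carries a species table.
    """
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)
    if "temperature_K" not in cfg:
        raise ValueError(f"{config_path}: temperature_K is required")
    thermo = Thermo(T=cfg["temperature_K"])
    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "package_version": __version__,
        "config_path": str(config_path),
        "config": cfg,
        "seed": seed,
        "started_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "stages": {},
        "outputs": {},
    }

    def _stage(name):
        t0 = time.perf_counter()
        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}
            log.info("stage %s finished in %.2fs %s", name,
                     time.perf_counter() - t0, info)
        return done

    # --- simulate ----------------------------------------------------------
    if traj_paths:
        done = _stage("load")
        trajs = [read_trajectory(p) for p in traj_paths]
        done(n_runs=len(trajs))
    else:
        done = _stage("simulate")
        proto_cfg = cfg.get("protocol")
        if proto_cfg is None:
            raise ValueError(f"{config_path}: protocol section required to simulate")
        protocol = make_protocol(z0=proto_cfg["z0"], v_d=proto_cfg["v_d"],
                                 A=proto_cfg["A"], n=proto_cfg["n"])
        pmf_true = read_profile(config_path.parent / cfg["profiles"]["pmf"], role="pmf")
        diff_true = read_profile(config_path.parent / cfg["profiles"]["diffusion"],
                                 role="diffusion")
        dt = cfg.get("dt_ns") or default_dt(protocol, cfg["bin_width_A"])
        sim = SimConfig(thermo=thermo, pmf_true=pmf_true, diff_true=diff_true,
                        dt=dt, seed=seed, duration=cfg["duration_ns"])
        traj_dir = out_dir / "trajectories"
        trajs = generate_fixture_set(sim, protocol, n_runs=int(cfg.get("n_runs", 6)),
                                     base_seed=seed, out_dir=traj_dir)
        manifest["outputs"]["trajectories"] = sorted(
            str(p) for p in traj_dir.glob("*.tsv"))
        done(n_runs=len(trajs), dt_ns=dt,
             n_steps=sum(len(t.dW) for t in trajs))

    # --- analyze -----------------------------------------------------------
    done = _stage("analyze")
    pmf, diff, combined, _ = analyze_trajectories(
        trajs, bin_width=cfg["bin_width_A"], window=cfg["smoothing_window"],
        reference_z=cfg.get("reference_z"), estimator=cfg.get("estimator", "bdfdt"))
    pmf_path, diff_path = out_dir / "pmf.tsv", out_dir / "diffusion.tsv"
    write_profile(pmf, pmf_path)
    write_profile(diff, diff_path)
    manifest["outputs"]["pmf"] = str(pmf_path)
    manifest["outputs"]["diffusion"] = str(diff_path)
    done(n_bins=int(combined.bin_edges.size - 1), estimator=cfg.get("estimator", "bdfdt"))

    # --- permeability ------------------------------------------------------
    done = _stage("perm")
    result = isd_permeability(pmf, diff, thermo,
                              half_bilayer=bool(cfg.get("half_bilayer", False)),
                              seed=seed + 1)
    perm_path = out_dir / "permeability.json"
    perm_payload = {"P_cm_s": result.P, "se_cm_s": result.se,
                    "resistance_s_cm": result.resistance, "L_A": result.L,
                    "half_bilayer": result.half_bilayer}
    perm_path.write_text(json.dumps(perm_payload, indent=2) + "\n")
    manifest["outputs"]["permeability"] = str(perm_path)
    done(P_cm_s=result.P)

    # --- mixing (optional) -------------------------------------------------
    if cfg.get("species"):
        done = _stage("mix")
        species = []
        for s in cfg["species"]:
            w = read_profile(config_path.parent / s["pmf"], role="pmf") if "pmf" in s else None
            D = (read_profile(config_path.parent / s["diffusion"], role="diffusion")
                 if "diffusion" in s else None)
            species.append(SpeciesState(label=s["label"], fraction=s.get("fraction", 0.0),
                                        P=s.get("P_cm_s"), w=w, D=D))
        spec = MixingSpec(species=species, pH=cfg.get("pH", 7.4), thermo=thermo,
                          P_exp=cfg.get("P_exp_cm_s"),
                          half_bilayer=bool(cfg.get("half_bilayer", False)))
        grid = np.asarray(cfg.get("pKa_grid", np.linspace(9.0, 11.7, 28)))
        sweep = pka_sweep(spec, grid)
        mix_path = out_dir / "pka_sweep.tsv"
        header = "# pKa\tP_slow_cm_s\tP_fast_cm_s\tP_mra_cm_s\n"
        rows = "\n".join(
            f"{k:.6g}\t{s1:.10g}\t{s2:.10g}\t{s3:.10g}" for k, s1, s2, s3 in
            zip(sweep["pKa"], sweep["P_slow"], sweep["P_fast"], sweep["P_mra"]))
        mix_path.write_text(header + rows + "\n")
        manifest["outputs"]["pka_sweep"] = str(mix_path)
        info = {}
        if spec.P_exp is not None:
            try:
                info["crossing_pKa"] = crossing_pka(spec, model="slow")
            except ValueError:
                info["crossing_pKa"] = None
        done(**info)

    manifest["finished_utc"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def make_demo_config(kind: str, out_dir: str | Path, seed: int = 2015) -> Path:
    """Write analytic demo profiles and a matching pipeline config JSON.

    ``kind='o2_like'`` builds the one-leaflet small-solute demo (323 K-like
    variant, half-bilayer doubling); ``kind='tyramine_like'`` the full-bilayer
    weak-base demo with a two-species table; ``kind='double_well'`` the compact
    recovery fixture.  Returns the config path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "double_well":
        pmf, diff = double_well_profiles()
        protocol = double_well_protocol()
        cfg = {"temperature_K": 310.0, "duration_ns": 60.0, "n_runs": 6,
               "reference_z": -4.5, "half_bilayer": False}
    elif kind == "o2_like":
        pmf, diff = o2_like_profiles("cold")
        protocol = make_protocol(z0=0.5, v_d=1.0, A=2.5, n=50)
        cfg = {"temperature_K": 323.0, "duration_ns": 27.0, "n_runs": 6,
               "reference_z": 28.0, "half_bilayer": True}
    elif kind == "tyramine_like":
        pmf, diff = tyramine_like_profiles("neutral")
        protocol = tyramine_like_protocol()
        pmf_p, diff_p = tyramine_like_profiles("protonated")
        write_profile(pmf_p, out_dir / "true_pmf_protonated.tsv")
        write_profile(diff_p, out_dir / "true_diffusion_protonated.tsv")
        cfg = {"temperature_K": 310.0, "duration_ns": 74.0, "n_runs": 10,
               "reference_z": -37.0, "half_bilayer": False, "pH": 7.4,
               "P_exp_cm_s": 2.26e-7,
               "species": [
                   {"label": "neutral", "pmf": "true_pmf.tsv",
                    "diffusion": "true_diffusion.tsv"},
                   {"label": "protonated", "pmf": "true_pmf_protonated.tsv",
                    "diffusion": "true_diffusion_protonated.tsv"},
               ]}
    else:
        raise ValueError(f"unknown demo kind {kind!r}")
    write_profile(pmf, out_dir / "true_pmf.tsv")
    write_profile(diff, out_dir / "true_diffusion.tsv")
    cfg.update({
        "bin_width_A": 0.2,
        "smoothing_window": 9,
        "seed": seed,
        "estimator": "bdfdt",
        "protocol": {"z0": protocol.z0, "v_d": protocol.v_d,
                     "A": protocol.A, "n": protocol.n},
        "profiles": {"pmf": "true_pmf.tsv", "diffusion": "true_diffusion.tsv"},
    })
    cfg_path = out_dir / f"{kind}_config.json"
    cfg_path.write_text(json.dumps(cfg, indent=2) + "\n")
    return cfg_path
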