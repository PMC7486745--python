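"""End-to-end orchestration: simulate -> fit lineshapes -> transients ->
kinetics -> spin classification -> yield check, from one configuration.

The configuration is a plain mapping (YAML-friendly); `validate_config`
fills defaults and rejects inconsistent requests before any computation.
Every stage logs its parameters, and `run_pipeline` writes a results
bundle: a directory of TSV tables plus a ``manifest.json`` listing every
output file with its SHA-256 content hash, the configuration echo and the
seeds used, so a run can be reproduced and verified bit for bit.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lineshape, synthetic_data, transient as transient_mod
from .kinetics import CascadeParams, fit_trace
from .spectra_core import write_spectrum, write_trace
from .spin_reference import match_spin, toy_reference_library
from .yield_estimate import (ExcitationConditions, consistency_ratio,
                             excited_fraction, observed_fraction)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "report",
           "load_config"]

log = logging.getLogger("spincascade")

STAGES = ("simulate", "lineshape", "transient", "kinetics", "classify", "yield")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": list(STAGES),
    "cascade": {"t0_ps": 0.0, "irf_fwhm_ps": 0.14, "tau1_ps": 0.61,
                "tau3_ps": 8.7, "f_exc": 0.3},
    "channels": ["kalpha", "kbeta"],
    "grid_step_ev": 0.2,
    "delays": {"start": -1.0, "stop": 50.0, "n_linear": 41, "n_log": 20},
    "noise": {"spectra": 0.0, "traces": 0.05},
    "traces": {
        "xanes": {"amplitudes": [0.70, 0.30]},
        "kalpha_fwhm": {"amplitudes": [0.50, 0.50]},
    },
    "windows": {"negative": [6402.0, 6405.0], "positive": [6405.0, 6408.0]},
    "lineshape": {"delay_ps": 0.2},
    "kinetics": {"n_components": 2, "n_boot": 100, "fix_irf": None},
    "classify": {"shift_range": [-3.0, 3.0]},
    "yield": {"fluence_mj_cm2": 3.0, "wavelength_nm": 400.0, "conc_mM": 4.0,
              "path_um": 100.0, "eps_M_cm": 20000.0},
}


def load_config(path) -> dict:
    """Load a YAML run configuration and validate it against the schema."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(config: dict) -> dict:
    """Merge with defaults and reject schema violations before any work."""
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = _merge(DEFAULT_CONFIG, config)
    bad_stages = set(cfg["stages"]) - set(STAGES)
    if bad_stages:
        raise ValueError(f"unknown stages: {sorted(bad_stages)}")
    stages = cfg["stages"]
    CascadeParams(**cfg["cascade"])  # raises on invalid kinetic truth
    for ch in cfg["channels"]:
        if ch not in ("kalpha", "kbeta"):
            raise ValueError(f"unknown channel {ch!r}")
    if cfg["noise"]["spectra"] < 0 or cfg["noise"]["traces"] < 0:
        raise ValueError("noise levels must be >= 0")
    needs_source = {"lineshape", "transient", "kinetics", "classify", "yield"}
    if needs_source & set(stages) and "simulate" not in stages:
        missing = sorted(needs_source & set(stages))
        raise ValueError(f"stages {missing} need inputs but no 'simulate' "
                         "stage provides them")
    if "lineshape" in stages and "kalpha" not in cfg["channels"]:
        raise ValueError("lineshape stage requires the kalpha channel")
    if "classify" in stages and "kbeta" not in cfg["channels"]:
        raise ValueError("classify stage requires the kbeta channel")
    for lo, hi in cfg["windows"].values():
        if not lo < hi:
            raise ValueError("integration windows must satisfy lo < hi")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _fit_row(label, fit):
    comp = dict(enumerate(fit.components, start=1))
    a1, tau1 = comp.get(1, (np.nan, np.nan))
    a3, tau3 = comp.get(len(comp), (np.nan, np.nan))
    total = sum(abs(a) for a, _ in fit.components) or np.nan
    return {
        "trace": label,
        "tau_r_ps": fit.irf_fwhm_ps,
        "tau1_ps": tau1, "a1": abs(a1) / total,
        "tau3_ps": tau3, "a3": abs(a3) / total,
        "t0_ps": fit.t0_ps, "baseline": fit.baseline,
        "residual_rms": fit.residual_rms,
        "converged": fit.converged,
        "flags": ";".join(fit.flags),
    }


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Execute the requested stages in dependency order.

    Returns the in-memory results bundle; when ``out_dir`` is given, also
    writes TSV tables, spectra and a ``manifest.json`` with content hashes.
    """
    cfg = validate_config(config or {})
    seed = int(cfg["seed"])
    rng_seeds = {"spectra": seed, "traces": seed + 1}
    params = CascadeParams(**cfg["cascade"])
    delays = synthetic_data.default_delays(**cfg["delays"])
    bundle: dict = {"config": cfg, "tables": {}, "scalars": {}}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pairs = {}
    traces = {}
    if "simulate" in cfg["stages"]:
        log.info("simulate: cascade %s, %d delays, noise %s",
                 cfg["cascade"], delays.size, cfg["noise"])
        for i, ch in enumerate(cfg["channels"]):
            grid = synthetic_data.default_xes_grid(ch, cfg["grid_step_ev"])
            pairs[ch] = synthetic_data.synth_timeseries(
                ch, params, delays=delays, noise_level=cfg["noise"]["spectra"],
                seed=rng_seeds["spectra"] + i, grid=grid)
        for j, (kind_key, tcfg) in enumerate(sorted(cfg["traces"].items())):
            kind = "xanes_amplitude" if kind_key == "xanes" else "kalpha_fwhm"
            amps = tcfg.get("amplitudes")
            weights = (None if amps is None else
                       synthetic_data.weights_for_biexp(*amps, params))
            traces[kind_key] = synthetic_data.synth_kinetic_trace(
                kind, params, weights=weights, delays=delays,
                noise_level=cfg["noise"]["traces"],
                seed=rng_seeds["traces"] + j)
        if out is not None:
            for kind_key, tr in traces.items():
                p = out / f"trace_{kind_key}.tsv"
                write_trace(tr, p)
                written.append(p)
            d0 = cfg["lineshape"]["delay_ps"]
            idx = int(np.argmin(np.abs(delays - d0)))
            for ch in pairs:
                off, on = pairs[ch][idx]
                for tag, sp in (("off", off), ("on", on)):
                    p = out / f"spectrum_{ch}_{tag}.tsv"
                    write_spectrum(sp, p)
                    written.append(p)

    if "lineshape" in cfg["stages"]:
        d0 = cfg["lineshape"]["delay_ps"]
        idx = int(np.argmin(np.abs(delays - d0)))
        off, on = pairs["kalpha"][idx]
        init = lineshape.initial_doublet_guess(off)
        fit_off = lineshape.fit_doublet(off, init)
        fit_on = lineshape.fit_laser_on(on, fit_off)
        dfw = lineshape.delta_fwhm(fit_on, fit_off)
        log.info("lineshape: delay %.3g ps, dFWHM = %.4g +- %.2g eV",
                 delays[idx], dfw.value_ev, dfw.sigma_ev)
        bundle["scalars"]["delta_fwhm_ev"] = dfw.value_ev
        bundle["scalars"]["delta_fwhm_sigma_ev"] = dfw.sigma_ev
        df = pd.DataFrame([
            {"laser_state": "off", "center1_ev": fit_off.params.line1.center_ev,
             "center2_ev": fit_off.params.line2.center_ev,
             "fwhm1_ev": fit_off.fwhm1_ev, "rms": fit_off.residual_rms},
            {"laser_state": "on", "center1_ev": fit_on.params.line1.center_ev,
             "center2_ev": fit_on.params.line2.center_ev,
             "fwhm1_ev": fit_on.fwhm1_ev, "rms": fit_on.residual_rms},
        ])
        bundle["tables"]["lineshape"] = df
        if out is not None:
            p = out / "lineshape_fits.tsv"
            _write_table(df, p)
            written.append(p)

    transients = {}
    if "transient" in cfg["stages"]:
        for ch, series in pairs.items():
            transients[ch] = [transient_mod.make_transient(on, off)
                              for off, on in series]
        rows = []
        for name, (lo, hi) in sorted(cfg["windows"].items()):
            tr = transient_mod.integrate_window(transients["kalpha"], (lo, hi))
            traces[f"window_{name}"] = tr
            rows.append({"window": name, "lo_ev": lo, "hi_ev": hi,
                         "peak_delay_ps":
                         float(tr.delay_ps[np.argmax(np.abs(tr.signal))])})
        df = pd.DataFrame(rows)
        bundle["tables"]["windows"] = df
        log.info("transient: %d spectra differenced, %d windows integrated",
                 sum(len(s) for s in transients.values()), len(rows))
        if out is not None:
            p = out / "window_traces.tsv"
            _write_table(df, p)
            written.append(p)
            d0 = cfg["lineshape"]["delay_ps"]
            idx = int(np.argmin(np.abs(delays - d0)))
            for ch in transients:
                sp = transients[ch][idx]
                pth = out / f"transient_{ch}.tsv"
                write_trace_like_spectrum = pd.DataFrame(
                    {"energy_ev": sp.energy_ev, "delta": sp.delta})
                _write_table(write_trace_like_spectrum, pth)
                written.append(pth)

    if "kinetics" in cfg["stages"]:
        kcfg = cfg["kinetics"]
        rows = []
        fit_targets = {"xanes": "XANES", "kalpha_fwhm": "Kalpha XES"}
        bundle["fits"] = {}
        for key, label in fit_targets.items():
            if key not in traces:
                continue
            fit = fit_trace(traces[key], n_components=kcfg["n_components"],
                            fix_irf=kcfg["fix_irf"], n_boot=kcfg["n_boot"],
                            seed=seed + 17)
            bundle["fits"][label] = fit
            rows.append(_fit_row(label, fit))
            log.info("kinetics: %s tau_r=%.3g tau1=%.3g tau3=%.3g", label,
                     fit.irf_fwhm_ps, rows[-1]["tau1_ps"], rows[-1]["tau3_ps"])
        df = pd.DataFrame(rows)
        bundle["tables"]["kinetics"] = df
        if out is not None:
            p = out / "kinetics_fits.tsv"
            _write_table(df, p)
            written.append(p)

    if "classify" in cfg["stages"]:
        d0 = cfg["lineshape"]["delay_ps"]
        idx = int(np.argmin(np.abs(delays - d0)))
        if "kbeta" in transients:
            probe = transients["kbeta"][idx]
        else:
            off, on = pairs["kbeta"][idx]
            probe = transient_mod.make_transient(on, off)
        lib = toy_reference_library(
            "kbeta", synthetic_data.default_xes_grid(
                "kbeta", cfg["grid_step_ev"]))
        result = match_spin(probe, lib,
                            shift_range=tuple(cfg["classify"]["shift_range"]))
        df = pd.DataFrame([a.__dict__ for a in result.ranking])
        df["ambiguous"] = result.ambiguous
        bundle["tables"]["classification"] = df
        log.info("classify: best=%s rms=%.3g ambiguous=%s",
                 result.best.label, result.best.rms, result.ambiguous)
        if out is not None:
            p = out / "classification.tsv"
            _write_table(df, p)
            written.append(p)

    if "yield" in cfg["stages"]:
        cond = ExcitationConditions(**cfg["yield"])
        f_exp = excited_fraction(cond)
        d0 = cfg["lineshape"]["delay_ps"]
        idx = int(np.argmin(np.abs(delays - d0)))
        if "kalpha" in transients:
            probe = transients["kalpha"][idx]
        else:
            off, on = pairs["kalpha"][idx]
            probe = transient_mod.make_transient(on, off)
        full = CascadeParams(**{**cfg["cascade"], "f_exc": 1.0})
        ref_pair = synthetic_data.synth_timeseries(
            "kalpha", full, delays=[delays[idx]], noise_level=0.0,
            grid=synthetic_data.default_xes_grid("kalpha",
                                                 cfg["grid_step_ev"]))[0]
        reference = transient_mod.make_transient(ref_pair[1], ref_pair[0])
        obs = observed_fraction(probe, reference)
        rep = consistency_ratio(f_exp, max(obs.fraction, 1e-12))
        bundle["scalars"].update({
            "yield_expected": f_exp, "yield_observed": obs.fraction,
            "yield_ratio": rep.ratio, "yield_agree": rep.agree_within_factor_2,
        })
        log.info("yield: expected %.3g observed %.3g ratio %.3g agree=%s",
                 f_exp, obs.fraction, rep.ratio, rep.agree_within_factor_2)

    if out is not None:
        manifest = {
            "config": cfg,
            "seeds": rng_seeds,
            "outputs": {p.name: _sha256(p) for p in sorted(written)},
        }
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                    default=str))
        bundle["manifest"] = manifest
        bundle["out_dir"] = str(out)
    return bundle


def report(bundle: dict) -> str:
    """Human-readable summary of a results bundle (rise/decay table,
    classification and yield sections)."""
    lines = ["spin-cascade analysis summary", "=" * 32]
    kin = bundle.get("tables", {}).get("kinetics")
    if kin is not None and len(kin):
        lines.append("")
        lines.append("kinetic fits (IRF-convolved biexponential):")
        lines.append(f"{'trace':<12}{'tau_r (ps)':>12}{'tau1 (a1)':>18}"
                     f"{'tau3 (a3)':>18}")
        for _, r in kin.iterrows():
            lines.append(
                f"{r['trace']:<12}{r['tau_r_ps']:>12.3f}"
                f"{r['tau1_ps']:>10.3f} ({r['a1']:.2f})"
                f"{r['tau3_ps']:>10.2f} ({r['a3']:.2f})")
            if r["flags"]:
                lines.append(f"    caveat: {r['flags']}")
    scal = bundle.get("scalars", {})
    if "delta_fwhm_ev" in scal:
        lines.append("")
        lines.append(f"K-alpha-1 laser-on broadening: "
                     f"{scal['delta_fwhm_ev']:.3f} eV")
    cls = bundle.get("tables", {}).get("classification")
    if cls is not None and len(cls):
        lines.append("")
        lines.append("spin classification (residual-ranked):")
        for _, r in cls.iterrows():
            lines.append(f"  {r['label']:<8} shift {r['shift_ev']:+.2f} eV, "
                         f"rms {r['rms']:.4f}")
        if bool(cls["ambiguous"].iloc[0]):
            lines.append("  caveat: top candidates are not distinguishable")
    if "yield_ratio" in scal:
        lines.append("")
        lines.append(
            f"yield check: expected {scal['yield_expected']:.3f}, "
            f"observed {scal['yield_observed']:.3f}, ratio "
            f"{scal['yield_ratio']:.2f} "
            + ("(agree within factor 2)" if scal["yield_agree"]
               else "(disagree beyond factor 2)"))
    return "\n".join(lines) + "\n"
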