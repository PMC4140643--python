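"""End-to-end pipeline: toy (or PDB) dimer -> REMD -> WHAM -> topography.

Composable stage helpers plus a config-driven driver that emits a
table-style summary (gap, roughness, entropy, Tf, Tg, Tf/Tg, binding time,
Lambda, rho) for rigid and flexible binding side by side.  All stochastic
stages require explicit seeds and the summary JSON is byte-stable, so a
rerun of the same configuration reproduces every number exactly.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import io as bio
from .combine import combine_topography, combined_global_gap
from .errors import ConfigError
from .kinetics import kinetic_comparison, mfpt, run_first_passage
from .remd import ReplicaEnsemble, ensemble_histograms, run_remd
from .structures import interfacial_flexibility
from .synthetic import ToySpec, extract_monomer, make_toy_homodimer
from .topography import (landscape_moments, native_gauge, partition_states,
                         topography_summary)
from .topology import ForceField, Restraint, build_topology
from .wham import heat_capacity, solve_wham

DEFAULT_CONFIG = {
    "toy": {"n_residues": 20, "n_inter": 6, "rho": 0.15, "n_intra": None,
            "seed": None, "jitter": 0.01},
    "ladder": {"n_temps": 48, "t_min": 0.2, "t_max": 2.2},
    "remd": {"n_steps": 200000, "exchange_interval": 20000, "dt": 5e-4,
             "friction": 1.0, "sample_every": 100, "seed": None},
    "wham": {"n_energy_bins": 60, "tol": 1e-7, "max_iter": 100000,
             "burn_in": 0.2},
    "stages": {"kinetics": False, "combine": False},
    # deepened interfacial wells put the toy in the 3-state regime
    # (comparable binding and folding transition temperatures)
    "force_field": {"epsilon": 1.0, "epsilon_inter": 2.0},
    "kinetics": {"T": None, "n_traj": 200, "max_steps": 2000000,
                 "q_threshold": 0.8, "hold_samples": 100, "seed": None},
    "restraint": {"r0": 6.0, "k": 1000.0},
}

_STOCHASTIC_STAGES = (("toy", "seed"), ("remd", "seed"))


def merge_config(config: dict | None) -> dict:
    merged = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for sec, vals in (config or {}).items():
        if sec not in merged:
            raise ConfigError(f"unknown config section {sec!r}")
        if not isinstance(vals, dict):
            raise ConfigError(f"config section {sec!r} must be a mapping")
        for k, v in vals.items():
            if k not in merged[sec]:
                raise ConfigError(f"unknown config key {sec}.{k}")
            merged[sec][k] = v
    return merged


def validate_config(config: dict) -> dict:
    """Check completeness; every stochastic stage needs an explicit seed."""
    cfg = merge_config(config)
    need = list(_STOCHASTIC_STAGES)
    if cfg["stages"]["kinetics"]:
        need.append(("kinetics", "seed"))
    for sec, key in need:
        if cfg[sec].get(key) is None:
            raise ConfigError(f"missing required config key {sec}.{key} "
                              "(stochastic stages need explicit seeds)")
    return cfg


def ladder_from_config(cfg: dict) -> np.ndarray:
    lc = cfg["ladder"]
    return np.geomspace(lc["t_min"], lc["t_max"], lc["n_temps"])


def add_global_q(ens: ReplicaEnsemble, n_inter: int, n_intra: int) -> None:
    """Attach the all-contact fraction q_all to each temperature's samples."""
    n_tot = n_inter + 2 * n_intra
    for s in ens.samples:
        s["q_all"] = (s["qb"] * n_inter + (s["qf1"] + s["qf2"]) * n_intra) / n_tot


def add_global_strata(ens: ReplicaEnsemble, q_native: float = 0.85) -> None:
    """Attach the composition stratum of each global-landscape sample.

    The weak-coupling combination composes the *product* of the three
    component ensembles, so the directly sampled global landscape is
    compared on the same strata: ``1.0`` when binding and both chains'
    folding are all in their native basins (Q >= q_native), ``0.5`` when
    all three are partial (0 < Q < q_native) — the product of the three
    non-native ensembles — and ``0.0`` otherwise (mixed or fully
    dissociated states, outside the composition).  In the weak-coupling
    limit the stratified global topography factorizes exactly into the
    combined closed forms.
    """
    for s in ens.samples:
        qs = np.stack([s["qb"], s["qf1"], s["qf2"]])
        native = np.all(qs >= q_native, axis=0)
        partial = np.all((qs > 0.0) & (qs < q_native), axis=0)
        s["q_strata"] = np.where(native, 1.0, np.where(partial, 0.5, 0.0))


def landscape_from_ensemble(ens: ReplicaEnsemble, *, energy_key: str,
                            q_key: str, n_contacts: int,
                            n_energy_bins: int = 60, burn_in: float = 0.2,
                            tol: float = 1e-7, max_iter: int = 100000,
                            T_grid=None, label: str = "",
                            q_native: float | None = 0.85,
                            q_floor: float | None = 0.0,
                            cap_energy: bool = True,
                            energy_cap: float | None = None):
    """WHAM + topography of one landscape projection of an REMD ensemble.

    Three estimator choices keep the topography statistics well
    conditioned at desk scale (see the methods note): the native
    macrostate is the basin Q >= ``q_native``; the non-native ensemble
    excludes the zero-contact stratum (``q_floor``); and with
    ``cap_energy`` the energy domain is truncated at the median energy of
    the hottest replica, so the highest retained bins — which dominate
    the state count — are always well sampled.

    Returns ``(dos, cv_curve, topography)`` with the DoS in the native
    gauge (native macrostate count = 1).
    """
    hist, edges, q_values = ensemble_histograms(
        ens, energy_key=energy_key, q_key=q_key, n_contacts=n_contacts,
        n_energy_bins=n_energy_bins, burn_in=burn_in)
    if cap_energy:
        cap = (energy_cap if energy_cap is not None
               else float(np.median(ens.field(energy_key, burn_in)[-1])))
        keep = edges[:-1] <= cap  # keep every bin that starts at/below cap
        if keep.sum() >= 2:
            hist = hist[:, keep, :]
            edges = np.append(edges[:-1][keep], edges[1:][keep][-1])
    dos = solve_wham(hist, ens.ladder, edges, q_values, tol=tol,
                     max_iter=max_iter)
    part = partition_states(dos, "max_q", q_native=q_native, q_floor=q_floor)
    dos = native_gauge(dos, part)
    if T_grid is None:
        T_grid = np.linspace(max(0.05, ens.ladder[0] * 0.5),
                             ens.ladder[-1] * 1.2, 2001)
    cv = heat_capacity(dos, T_grid)
    topo = topography_summary(dos, cv, q_native=q_native, q_floor=q_floor,
                              label=label)
    return dos, cv, topo


def _stage_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, k]
                                      ).generate_state(1)[0] % 2**31)


def run_pipeline(config: dict | None, outdir=None) -> dict:
    """Full toy pipeline per ``config``; returns the summary dictionary.

    Stages: build toy -> REMD (flexible + rigid) -> WHAM -> topography,
    then kinetics and combined-vs-global comparison when enabled.  When
    ``outdir`` is given, the contact map, densities of states, heat
    capacity curves and summary JSON are written there.
    """
    cfg = validate_config(config)
    toy_cfg = dict(cfg["toy"])
    toy = make_toy_homodimer(ToySpec(**toy_cfg))
    structure, cmap = toy.structure, toy.cmap
    rho = interfacial_flexibility(cmap).rho
    restraint = Restraint(**cfg["restraint"])
    ff = ForceField(**cfg["force_field"])
    top_flex = build_topology(structure, cmap, ff=ff, mode="flexible",
                              restraint=restraint)
    top_rigid = build_topology(structure, cmap, ff=ff, mode="rigid_chains",
                               restraint=restraint)
    ladder = ladder_from_config(cfg)
    rc = cfg["remd"]
    wc = cfg["wham"]
    ens = {}
    for idx, (name, top) in enumerate((("flexible", top_flex),
                                       ("rigid", top_rigid))):
        ens[name] = run_remd(top, ladder, rc["n_steps"],
                             rc["exchange_interval"],
                             seed=_stage_seed(rc["seed"], idx),
                             dt=rc["dt"], friction=rc["friction"],
                             sample_every=rc["sample_every"])
    landscapes = {}
    for name in ("rigid", "flexible"):
        dos, cv, topo = landscape_from_ensemble(
            ens[name], energy_key="e_inter", q_key="qb",
            n_contacts=cmap.n_inter, n_energy_bins=wc["n_energy_bins"],
            burn_in=wc["burn_in"], tol=wc["tol"], max_iter=wc["max_iter"],
            label=f"binding_{name}")
        landscapes[f"binding_{name}"] = (dos, cv, topo)

    summary = {
        "system": {k: v for k, v in toy_cfg.items()},
        "rho": rho,
        "binding": {name: asdict(landscapes[f"binding_{name}"][2])
                    for name in ("rigid", "flexible")},
    }

    if cfg["stages"]["combine"]:
        mono, mono_map = extract_monomer(structure, cmap)
        top_mono = build_topology(mono, mono_map, ff=ff, mode="flexible")
        ens_mono = run_remd(top_mono, ladder, rc["n_steps"],
                            rc["exchange_interval"],
                            seed=_stage_seed(rc["seed"], 2),
                            dt=rc["dt"], friction=rc["friction"],
                            sample_every=rc["sample_every"])
        dos_f, cv_f, topo_f = landscape_from_ensemble(
            ens_mono, energy_key="e_contact_intra", q_key="qf1",
            n_contacts=mono_map.n_intra, n_energy_bins=wc["n_energy_bins"],
            burn_in=wc["burn_in"], tol=wc["tol"], max_iter=wc["max_iter"],
            label="folding_isolated")
        landscapes["folding_isolated"] = (dos_f, cv_f, topo_f)
        add_global_q(ens["flexible"], cmap.n_inter, mono_map.n_intra)
        n_all = cmap.n_inter + 2 * mono_map.n_intra
        dos_g, cv_g, topo_g = landscape_from_ensemble(
            ens["flexible"], energy_key="e_contact", q_key="q_all",
            n_contacts=n_all, n_energy_bins=wc["n_energy_bins"],
            burn_in=wc["burn_in"], tol=wc["tol"], max_iter=wc["max_iter"],
            label="global")
        landscapes["global"] = (dos_g, cv_g, topo_g)
        comb = combine_topography(landscapes["binding_rigid"][2], topo_f)
        summary["folding"] = asdict(topo_f)
        summary["global"] = asdict(topo_g)
        summary["combined"] = asdict(comb)
        summary["combined_global_gap"] = combined_global_gap(
            comb.Lambda, topo_g.Lambda)

    if cfg["stages"]["kinetics"]:
        kc = cfg["kinetics"]
        T_kin = kc["T"]
        if T_kin is None:
            T_kin = 0.9 * landscapes["binding_flexible"][2].Tf
        kin = {}
        for idx, name in enumerate(("rigid", "flexible")):
            top = top_rigid if name == "rigid" else top_flex
            ensk = run_first_passage(
                top, T_kin, kc["n_traj"], kc["max_steps"],
                q_threshold=kc["q_threshold"],
                hold_samples=kc["hold_samples"],
                seed=_stage_seed(kc["seed"], idx))
            mean, se, cens = mfpt(ensk)
            kin[name] = {"mfpt_steps": mean, "se": se,
                         "censored_fraction": cens, "T": T_kin}
            kin[f"_ens_{name}"] = ensk
        ratio, ratio_se = kinetic_comparison(kin.pop("_ens_rigid"),
                                             kin.pop("_ens_flexible"))
        kin["ratio_rigid_over_flexible"] = ratio
        kin["ratio_se"] = ratio_se
        summary["kinetics"] = kin

    summary = _jsonable(summary)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bio.write_contact_map(outdir / "contact_map.tsv", cmap)
        bio.write_pdb(outdir / "toy_dimer.pdb", structure)
        for name, (dos, cv, _) in landscapes.items():
            bio.write_dos(outdir / f"dos_{name}.tsv", dos)
            bio.write_curve(outdir / f"cv_{name}.tsv", cv)
        bio.write_json(outdir / "summary.json", summary)
        bio.write_config(outdir / "config_used.yaml",
                         _jsonable(cfg))
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
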