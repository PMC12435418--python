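"""Config-driven orchestration of the apo-vs-holo ensemble comparison.

``run`` executes the stages in dependency order — input acquisition
(loading trajectories or generating synthetic ones), equilibration trim,
trimer geometry, loop clustering, collective-positioning statistics,
contact/H-bond persistence, and the independent NMR stages — writing every
table through :func:`c3ensemble.io.write_results` and stamping the bundle
with the config hash and seed.  ``report`` renders a completed bundle as a
human-readable summary.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import clustering, contacts, geometry, loopstats, nmr, synthetic
from .config import RunConfig
from .io import read_shift_table, read_trajectory, write_results

__all__ = ["run", "report", "StageError"]

log = logging.getLogger("c3ensemble")

REPORT_SECTIONS = [
    "distribution_shift",
    "competence_ratio",
    "clusters",
    "persistent_contacts",
    "csp",
    "rex",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                log.error("stage %s: FAILED (%s)", name, exc)
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("inputs")
def _acquire_ensembles(cfg: RunConfig):
    ensembles = {}
    truths = {}
    for state in ("apo", "holo"):
        path = getattr(cfg, f"{state}_trajectory")
        if path is not None:
            ensembles[state] = read_trajectory(path)
        elif state in cfg.simulate:
            spec = synthetic.TrimerSpec(**cfg.simulate[state])
            traj, truth = synthetic.generate_trimer_ensemble(spec)
            ensembles[state] = traj
            truths[state] = truth
    return ensembles, truths


@_stage("trim")
def _trim(cfg: RunConfig, ensembles):
    out = {}
    for state, traj in ensembles.items():
        if traj.times is not None:
            out[state] = geometry.equilibration_trim(traj, t_cut=cfg.trim_t_cut_ns)
        elif cfg.trim_fraction > 0:
            out[state] = geometry.equilibration_trim(traj, fraction=cfg.trim_fraction)
        else:
            out[state] = traj
    return out


@_stage("geometry")
def _geometry(cfg: RunConfig, ensembles):
    series = {}
    rg = {}
    for state, traj in ensembles.items():
        core = traj.select(residues=cfg.core_residues)
        orient = traj.select(residues=cfg.orientation_residues)
        series[state] = geometry.protrusion_distances(
            traj, (cfg.reporter_residue, cfg.reporter_atom), core, orient
        )
        rg[state] = geometry.radius_of_gyration(traj)
    return series, rg


@_stage("clustering")
def _cluster(cfg: RunConfig, ensembles):
    results = {}
    for state, traj in ensembles.items():
        loop_idx = traj.select(residues=cfg.loop_residues)
        mono, _ = clustering.concatenate_monomers(traj, loop_idx)
        # keep the pairwise matrix tractable: stride to <= 150 pseudo-frames
        stride = max(1, mono.n_frames // 150)
        mono = mono.slice_frames(np.arange(0, mono.n_frames, stride))
        mat = clustering.pairwise_rmsd_matrix(mono)
        try:
            cutoff, res = clustering.cutoff_for_coverage(
                mat, cfg.coverage_target, cfg.max_clusters
            )
        except ValueError:
            preset = cfg.cluster_cutoff_presets.get(f"loop_{state}", 5.0)
            cutoff, res = preset, clustering.daura_cluster(mat, preset)
        results[state] = res
    return results


@_stage("loop_statistics")
def _loop_statistics(cfg: RunConfig, series, seed: int):
    start, stop, step = cfg.theta_grid
    thresholds = np.arange(start, stop + step / 2, step)
    dists = {s: loopstats.protrusion_distribution(v) for s, v in series.items()}
    occs = {
        s: loopstats.collective_occupancy(v, thresholds) for s, v in series.items()
    }
    ratio = None
    if "apo" in occs and "holo" in occs:
        ratio = loopstats.competence_ratio(
            occs["holo"], occs["apo"], cfg.theta_star, seed=seed
        )
    return dists, occs, ratio


@_stage("contacts")
def _contacts(cfg: RunConfig):
    out = {}
    for state in ("apo", "holo"):
        block = cfg.simulate.get("hbond", {})
        if state not in block:
            continue
        traj, truth = synthetic.generate_contact_trajectory(
            block[state]["occupancy"], block[state].get("n_frames", 1000), seed=cfg.seed
        )
        recs = contacts.hbond_occurrence(
            traj, cfg.hbond_d_da_max, cfg.hbond_angle_min
        )
        out[state] = contacts.persistent_contacts(recs, cfg.persistence_min_pct)
    return out


@_stage("nmr")
def _nmr(cfg: RunConfig):
    out = {}
    if cfg.apo_shifts and cfg.holo_shifts:
        apo = read_shift_table(cfg.apo_shifts, label="apo")
        holo = read_shift_table(cfg.holo_shifts, label="holo")
        out["csp"] = nmr.compute_csp(apo, holo, thresholds=cfg.csp_flags)
    if "dispersion" in cfg.simulate:
        fits = []
        for params in cfg.simulate["dispersion"]:
            curve, truth = synthetic.generate_dispersion_set(
                **params, nu_grid=np.array(
                    [25, 50, 75, 100, 150, 200, 300, 400, 600, 800, 1000, 1500]
                ), seed=cfg.seed
            )
            fit = nmr.fit_dispersion(curve)
            fits.append((truth.parameters, fit))
        out["dispersion"] = fits
    return out


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the result bundle (also written to
    ``config.output_dir``)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    log.info("run: config hash %s, seed %d", cfg_hash, config.seed)

    ensembles, truths = _acquire_ensembles(config)
    ensembles = _trim(config, ensembles)
    bundle: dict = {"config_hash": cfg_hash, "seed": config.seed}
    tables = {}

    if ensembles:
        series, rg = _geometry(config, ensembles)
        clusters = _cluster(config, ensembles)
        dists, occs, ratio = _loop_statistics(config, series, config.seed)
        for state, s in series.items():
            import pandas as pd

            tables[f"protrusion_{state}_"] = pd.DataFrame(
                s.values, columns=[f"monomer_{m}" for m in s.monomers]
            )
            tables[f"occupancy_{state}_"] = occs[state].table()
            tables[f"clusters_{state}_"] = clusters[state].cluster_table()
        bundle["distribution_shift"] = (
            {
                "mean_apo_A": dists["apo"].mean,
                "mean_holo_A": dists["holo"].mean,
                "shift_A": dists["holo"].mean - dists["apo"].mean,
            }
            if {"apo", "holo"} <= set(dists)
            else None
        )
        bundle["competence_ratio"] = (
            {
                "theta_A": ratio.theta,
                "ratio": ratio.ratio,
                "ci_low": ratio.ci_low,
                "ci_high": ratio.ci_high,
                "lower_bound": ratio.lower_bound,
            }
            if ratio is not None
            else None
        )
        bundle["clusters"] = {
            state: {
                "cutoff_A": res.cutoff,
                "n_clusters": len(res.clusters),
                "populations": res.populations[:6].tolist(),
                "coverage_top6": res.coverage(6),
            }
            for state, res in clusters.items()
        }
        bundle["rg_mean_A"] = {s: float(v.mean()) for s, v in rg.items()}
    else:
        bundle["distribution_shift"] = None
        bundle["competence_ratio"] = None
        bundle["clusters"] = None

    hb = _contacts(config)
    bundle["persistent_contacts"] = (
        {
            state: [
                {
                    "donor": list(r.donor),
                    "acceptor": list(r.acceptor),
                    "occurrence_pct": r.occurrence,
                }
                for r in recs
            ]
            for state, recs in hb.items()
        }
        if hb
        else None
    )

    nmr_out = _nmr(config)
    if "csp" in nmr_out:
        prof = nmr_out["csp"].profile
        tables["csp_"] = prof
        flagged = prof[prof[f"above_{config.csp_flags[0]:g}"] == True]  # noqa: E712
        bundle["csp"] = {
            "n_residues": int(prof["delta_ppm"].notna().sum()),
            "n_flagged": int(len(flagged)),
            "max_csp_ppm": float(prof["delta_ppm"].max()),
        }
    else:
        bundle["csp"] = None
    if "dispersion" in nmr_out:
        bundle["rex"] = [
            {
                "true_rex": truth["rex"],
                "fitted_rex": fit.rex,
                "model": fit.model,
            }
            for truth, fit in nmr_out["dispersion"]
        ]
    else:
        bundle["rex"] = None

    write_results(tables, outdir / "run_", summaries=bundle)
    return bundle


def report(bundle: dict | str | Path) -> str:
    """Render a result bundle as a plain-text summary (idempotent)."""
    if not isinstance(bundle, dict):
        bundle = json.loads(Path(bundle).read_text())
    lines = [
        "C3 trimer ensemble comparison",
        f"config hash: {bundle.get('config_hash', '?')}  seed: {bundle.get('seed', '?')}",
        "",
    ]

    def section(title: str, key: str, render) -> None:
        lines.append(f"== {title} ==")
        val = bundle.get(key)
        if not val:
            lines.append("not computed")
        else:
            lines.extend(render(val))
        lines.append("")

    section(
        "Loop protrusion distribution shift",
        "distribution_shift",
        lambda v: [
            f"mean apo {v['mean_apo_A']:.2f} A, mean holo {v['mean_holo_A']:.2f} A, "
            f"shift {v['shift_A']:+.2f} A"
        ],
    )
    section(
        "Binding-competence ratio (three loops forward)",
        "competence_ratio",
        lambda v: [
            f"theta = {v['theta_A']:.1f} A: ratio {v['ratio']:.2f} "
            f"(95% CI {v['ci_low']:.2f}-{v['ci_high']:.2f})"
            + ("  [lower bound]" if v.get("lower_bound") else "")
        ],
    )
    section(
        "Cluster populations",
        "clusters",
        lambda v: [
            f"{state}: cutoff {c['cutoff_A']:.1f} A, {c['n_clusters']} clusters, "
            f"top-6 coverage {100 * c['coverage_top6']:.1f}%"
            for state, c in v.items()
        ],
    )
    section(
        "Persistent contacts",
        "persistent_contacts",
        lambda v: [
            f"{state}: " + "; ".join(
                f"{'/'.join(map(str, r['donor']))}->{'/'.join(map(str, r['acceptor']))} "
                f"{r['occurrence_pct']:.1f}%"
                for r in recs
            )
            for state, recs in v.items()
        ],
    )
    section(
        "Chemical-shift perturbations",
        "csp",
        lambda v: [
            f"{v['n_residues']} residues, {v['n_flagged']} above the flag line, "
            f"max CSP {v['max_csp_ppm']:.2f} ppm"
        ],
    )
    section(
        "Exchange contributions (Rex)",
        "rex",
        lambda v: [
            f"planted {r['true_rex']:.1f} s^-1 -> fitted {r['fitted_rex']:.1f} s^-1 "
            f"({r['model']})"
            for r in v
        ],
    )
    return "\n".join(lines)
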