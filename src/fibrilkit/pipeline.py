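"""End-to-end comparison pipeline for two (or more) fibril ensembles.

Runs every analysis stage — order parameter, RMSF, secondary-structure
probability, contact profile, H-bond and non-bonded maps, SASA,
inter-chain interaction surfaces and FMA — per labelled ensemble, writes
tab-separated tables plus a JSON summary, and a side-by-side comparison
table.  Fully deterministic for a fixed config + seed; every output
declares the config hash that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import (
    GeneratorParams,
    PlantedMode,
    SasaParams,
    Trajectory,
    classify_secondary_structure,
    compute_ordp,
    compute_rmsf,
    fit_pca,
    fit_fma,
    generate_trajectory,
    hydrogen_bond_map,
    interchain_contact_profile,
    interchain_interaction_surface,
    make_cterminal_mode,
    nonbonded_contact_map,
    ordp_distribution,
    read_multimodel_pdb,
    sinusoid_amplitudes,
    total_sasa,
)

__all__ = ["EnsembleSource", "RunConfig", "run_comparison", "load_config"]

logger = logging.getLogger("fibrilkit.pipeline")


@dataclass
class EnsembleSource:
    """One labelled ensemble: a PDB file or generator parameters."""

    label: str
    file: str | None = None
    first_residue: int = 17
    last_residue: int = 42
    # generator parameters (used when file is None)
    shape: str = "U"
    n_frames: int = 100
    noise_sigma: float = 0.02
    chain_tilt: float = 0.0
    stack_tilt: float = 0.0
    cterminal_mode_amplitude: float = 0.0

    def make_trajectory(self, seed: int) -> Trajectory:
        if self.file is not None:
            logger.info("[%s] reading %s", self.label, self.file)
            return read_multimodel_pdb(self.file, self.first_residue, self.last_residue)
        mode = None
        if self.cterminal_mode_amplitude > 0:
            mode = PlantedMode(
                directions=make_cterminal_mode(5),
                amplitudes=sinusoid_amplitudes(
                    self.n_frames, self.cterminal_mode_amplitude, jitter=0.0, seed=seed
                ),
            )
        params = GeneratorParams(
            shape=self.shape,
            n_frames=self.n_frames,
            noise_sigma=self.noise_sigma,
            chain_tilt=self.chain_tilt,
            stack_tilt=self.stack_tilt,
            planted_mode=mode,
            seed=seed,
        )
        logger.info(
            "[%s] generating %s-shaped ensemble: %d frames, noise %.3f nm",
            self.label, self.shape, self.n_frames, self.noise_sigma,
        )
        return generate_trajectory(params)


@dataclass
class RunConfig:
    """Configuration of a full comparison run."""

    ensembles: tuple[EnsembleSource, ...]
    contact_cutoff: float = 0.45
    hbond_cutoff: float = 0.35
    hbond_angle_max: float = 30.0
    sasa_probe: float = 0.14
    sasa_points: int = 960
    fma_split: str = "half"
    fma_modes: int | None = None
    ordp_bins: int = 40
    sasa_frames: int = 20      # frame subsample for SASA-based stages
    output_dir: str = "fibrilkit_out"
    seed: int = 0
    log_level: str = "INFO"
    figures: bool = False      # simple per-analysis PNG figures

    def __post_init__(self) -> None:
        labels = [e.label for e in self.ensembles]
        if len(set(labels)) != len(labels):
            raise ValueError("ensemble labels must be unique")
        for cut in (self.contact_cutoff, self.hbond_cutoff, self.sasa_probe):
            if cut <= 0:
                raise ValueError("cutoffs must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "ensembles": [vars(e) for e in self.ensembles],
                "contact_cutoff": self.contact_cutoff,
                "hbond_cutoff": self.hbond_cutoff,
                "hbond_angle_max": self.hbond_angle_max,
                "sasa_probe": self.sasa_probe,
                "sasa_points": self.sasa_points,
                "fma_split": self.fma_split,
                "fma_modes": self.fma_modes,
                "ordp_bins": self.ordp_bins,
                "sasa_frames": self.sasa_frames,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ----------------------------------------------------------------------
# Config file parsing (flat key = value text)
# ----------------------------------------------------------------------

def _write_figures(outdir: Path, label: str, ordp, centers, density, rmsf, contacts) -> None:
    """Simple per-analysis figures (ordP distribution, RMSF, contacts)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    axes[0].plot(centers, density, lw=1.5)
    axes[0].set(xlabel="ordP", ylabel="density", title=f"{label}: order parameter")
    axes[1].errorbar(rmsf.residue_numbers, rmsf.mean, yerr=rmsf.std, lw=1.2, capsize=2)
    axes[1].set(xlabel="residue", ylabel="RMSF (nm)", title="RMSF")
    axes[2].plot(contacts.residue_numbers, contacts.probability, lw=1.5)
    axes[2].set(xlabel="residue", ylabel="P(contact)", ylim=(-0.05, 1.05), title="inter-chain contacts")
    fig.tight_layout()
    fig.savefig(outdir / f"{label}_report.png", dpi=120)
    plt.close(fig)


_SOURCE_FIELDS = {
    "file": str, "first_residue": int, "last_residue": int, "shape": str,
    "n_frames": int, "noise_sigma": float, "chain_tilt": float,
    "stack_tilt": float, "cterminal_mode_amplitude": float,
}
def _parse_bool(value: str) -> bool:
    return value.strip().lower() in ("1", "true", "yes", "on")


_RUN_FIELDS = {
    "contact_cutoff": float, "hbond_cutoff": float, "hbond_angle_max": float,
    "sasa_probe": float, "sasa_points": int, "fma_split": str,
    "fma_modes": int, "ordp_bins": int, "sasa_frames": int,
    "output_dir": str, "seed": int, "log_level": str, "figures": _parse_bool,
}


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Parse a flat ``key = value`` config file.

    Ensemble keys are ``ensemble.<label>.<field>``; all other keys are
    top-level run settings.  ``overrides`` (e.g. CLI flags) win over the
    file.
    """
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        raw[key] = value
    if overrides:
        raw.update({k: str(v) for k, v in overrides.items()})

    sources: dict[str, dict] = {}
    run_kwargs: dict = {}
    for key, value in raw.items():
        if key.startswith("ensemble."):
            _, label, fieldname = key.split(".", 2)
            if fieldname not in _SOURCE_FIELDS:
                raise ValueError(f"unknown ensemble field {fieldname!r}")
            sources.setdefault(label, {})[fieldname] = _SOURCE_FIELDS[fieldname](value)
        else:
            if key not in _RUN_FIELDS:
                raise ValueError(f"unknown config key {key!r}")
            run_kwargs[key] = _RUN_FIELDS[key](value)
    ensembles = tuple(
        EnsembleSource(label=label, **fields) for label, fields in sorted(sources.items())
    )
    if not ensembles:
        raise ValueError("config defines no ensembles")
    return RunConfig(ensembles=ensembles, **run_kwargs)


# ----------------------------------------------------------------------
# Output helpers (deterministic formatting)
# ----------------------------------------------------------------------

def _write_table(path: Path, header: list[str], rows, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config {config_hash}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    f"{v:.6f}" if isinstance(v, (float, np.floating)) else str(v)
                    for v in row
                )
                + "\n"
            )


def _write_matrix(path: Path, matrix, config_hash: str) -> None:
    rows = []
    for i, ri in enumerate(matrix.row_residues):
        for j, rj in enumerate(matrix.col_residues):
            rows.append((int(ri), int(rj), float(matrix.values[i, j])))
    _write_table(path, ["res_i", "res_j", "value"], rows, config_hash)


def _subsample(traj: Trajectory, n: int) -> Trajectory:
    if traj.n_frames <= n:
        return traj
    idx = np.linspace(0, traj.n_frames - 1, n).round().astype(int)
    return Trajectory(
        topology=traj.topology, coordinates=traj.coordinates[idx], reference_frame=0,
        label=traj.label,
    )


# ----------------------------------------------------------------------
# The comparison run
# ----------------------------------------------------------------------

def _analyse_ensemble(
    traj: Trajectory, cfg: RunConfig, label: str, outdir: Path, chash: str
) -> dict:
    res_nums = traj.topology.residue_numbers
    summary: dict = {"label": label, "n_frames": traj.n_frames}

    t0 = time.perf_counter()
    logger.info("[%s] stage ordp: start (%d frames)", label, traj.n_frames)
    ordp = compute_ordp(traj)
    centers, density = ordp_distribution(ordp, cfg.ordp_bins)
    peak = float(centers[int(np.argmax(density))])
    summary["ordp"] = {"mean": ordp.mean, "std": ordp.std, "peak": peak}
    _write_table(
        outdir / f"{label}_ordp.tsv", ["frame", "ordp"],
        [(f, float(v)) for f, v in enumerate(ordp.values)], chash,
    )
    logger.info("[%s] stage ordp: done in %.2fs", label, time.perf_counter() - t0)

    t0 = time.perf_counter()
    logger.info("[%s] stage rmsf: start", label)
    rmsf = compute_rmsf(traj)
    summary["rmsf"] = {
        "mean": float(rmsf.mean.mean()),
        "cterminal_mean": float(rmsf.mean[res_nums >= 36].mean()),
        "a42": rmsf.value_at(int(res_nums[-1])),
    }
    _write_table(
        outdir / f"{label}_rmsf.tsv", ["residue", "rmsf_mean", "rmsf_std"],
        list(zip(res_nums.tolist(), rmsf.mean, rmsf.std)), chash,
    )
    logger.info("[%s] stage rmsf: done in %.2fs", label, time.perf_counter() - t0)

    t0 = time.perf_counter()
    logger.info("[%s] stage secondary structure: start", label)
    ss = classify_secondary_structure(traj, hbond_cutoff=cfg.hbond_cutoff)
    summary["beta_fraction"] = float(ss.beta.mean())
    _write_table(
        outdir / f"{label}_ss.tsv", ["residue", "p_beta", "p_helix", "p_coil"],
        list(zip(res_nums.tolist(), ss.beta, ss.helix, ss.coil)), chash,
    )
    logger.info("[%s] stage secondary structure: done in %.2fs", label, time.perf_counter() - t0)

    t0 = time.perf_counter()
    logger.info("[%s] stage contacts/maps: start", label)
    contacts = interchain_contact_profile(traj, cutoff=cfg.contact_cutoff)
    summary["contact"] = {
        "mean": float(contacts.probability.mean()),
        "cterminal_mean": float(contacts.probability[res_nums >= 39].mean()),
    }
    _write_table(
        outdir / f"{label}_contacts.tsv", ["residue", "probability"],
        list(zip(res_nums.tolist(), contacts.probability)), chash,
    )
    if cfg.figures:
        _write_figures(outdir, label, ordp, centers, density, rmsf, contacts)
    hb_inter = hydrogen_bond_map(
        traj, scope="inter", cutoff=cfg.hbond_cutoff, angle_max=cfg.hbond_angle_max
    )
    _write_matrix(outdir / f"{label}_hbond_inter.tsv", hb_inter, chash)
    hb_intra = hydrogen_bond_map(
        traj, scope="intra", cutoff=cfg.hbond_cutoff, angle_max=cfg.hbond_angle_max
    )
    _write_matrix(outdir / f"{label}_hbond_intra.tsv", hb_intra, chash)
    nb = nonbonded_contact_map(traj, cutoff=cfg.contact_cutoff)
    _write_matrix(outdir / f"{label}_nonbonded.tsv", nb, chash)
    summary["hbond_inter_diagonal_mean"] = float(np.diag(hb_inter.values).mean())
    logger.info("[%s] stage contacts/maps: done in %.2fs", label, time.perf_counter() - t0)

    t0 = time.perf_counter()
    sasa_traj = _subsample(traj, cfg.sasa_frames)
    logger.info("[%s] stage sasa/surfaces: start (%d frames)", label, sasa_traj.n_frames)
    params = SasaParams(probe_radius=cfg.sasa_probe, n_sphere_points=cfg.sasa_points)
    sasa = total_sasa(sasa_traj, params)
    summary["sasa"] = {"mean": sasa.mean, "std": sasa.std}
    isurf = interchain_interaction_surface(sasa_traj, params)
    summary["interaction_surface"] = {
        "total_mean": float(isurf.total.mean()),
        "hydrophobic_mean": float(isurf.hydrophobic.mean()),
        "hydrophilic_mean": float(isurf.hydrophilic.mean()),
    }
    _write_table(
        outdir / f"{label}_isurf.tsv",
        ["residue", "total", "hydrophobic", "hydrophilic"],
        list(zip(res_nums.tolist(), isurf.total, isurf.hydrophobic, isurf.hydrophilic)),
        chash,
    )
    logger.info("[%s] stage sasa/surfaces: done in %.2fs", label, time.perf_counter() - t0)

    t0 = time.perf_counter()
    logger.info("[%s] stage fma: start", label)
    if traj.n_frames >= 10:
        pca = fit_pca(traj)
        fma = fit_fma(pca, ordp, m=cfg.fma_modes, split=cfg.fma_split, seed=cfg.seed)
        summary["fma"] = {
            "n_modes": fma.n_modes_used,
            "pearson_build": fma.pearson_build,
            "pearson_validation": fma.pearson_validation,
        }
    else:
        summary["fma"] = None
        logger.info("[%s] stage fma: skipped (too few frames)", label)
    logger.info("[%s] stage fma: done in %.2fs", label, time.perf_counter() - t0)
    return summary


def run_comparison(cfg: RunConfig) -> dict:
    """Execute the full comparison; returns the summary dict it also writes."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, cfg.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    summaries = {}
    for source in cfg.ensembles:
        try:
            traj = source.make_trajectory(cfg.seed)
            summaries[source.label] = _analyse_ensemble(traj, cfg, source.label, outdir, chash)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for ensemble {source.label!r}: {exc}"
            ) from exc

    comparison_rows = []
    metrics = [
        ("ordp_peak", lambda s: s["ordp"]["peak"]),
        ("ordp_mean", lambda s: s["ordp"]["mean"]),
        ("rmsf_mean", lambda s: s["rmsf"]["mean"]),
        ("rmsf_cterminal", lambda s: s["rmsf"]["cterminal_mean"]),
        ("sasa_mean", lambda s: s["sasa"]["mean"]),
        ("contact_cterminal", lambda s: s["contact"]["cterminal_mean"]),
        ("beta_fraction", lambda s: s["beta_fraction"]),
    ]
    labels = [s.label for s in cfg.ensembles]
    for name, getter in metrics:
        row = [name] + [getter(summaries[lab]) for lab in labels]
        if len(labels) == 2:
            row.append(row[1] - row[2])
        comparison_rows.append(tuple(row))
    header = ["metric"] + labels + (["delta"] if len(labels) == 2 else [])
    _write_table(outdir / "comparison.tsv", header, comparison_rows, chash)

    result = {"config_hash": chash, "ensembles": summaries}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("comparison written to %s", outdir)
    return result
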