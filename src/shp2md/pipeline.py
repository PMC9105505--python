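"""End-to-end orchestration of the conformational-state analysis.

A run consumes a config describing a suite of constructs (each either a
multi-model PDB on disk or a synthetic ensemble spec), executes the
per-construct stages — RMSD series, the five loop/residue distance
observables, fraction curves, groove-volume averaging, cation-pi
fraction, averaged conformer — then fits each observable's curves
jointly across constructs (column-synchronized Gaussians) and evaluates
the hypergeometric probability of the closed-retention outcome across
the wild-type-like and mutant-like groups.

All numeric outputs are deterministic for a fixed seed and config; the
summary is written with sorted keys and fixed float formatting so two
identical runs produce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from scipy import stats

from . import ensemble_stats, geometry, surface_volume, synthetic
from .structure_io import Trajectory, read_pdb, write_pdb

logger = logging.getLogger(__name__)

#: The five loop/residue separation observables tracked per construct:
#: (name, (chain,res,atom), (chain,res,atom)).
STANDARD_OBSERVABLES: list[tuple[str, tuple, tuple]] = [
    ("Pro38CA-Thr59CA", ("A", 38, "CA"), ("A", 59, "CA")),
    ("Thr59N-Tyr62O", ("A", 59, "N"), ("A", 62, "O")),
    ("Gly67CA-Asn92CA", ("A", 67, "CA"), ("A", 92, "CA")),
    ("Lys55O-Tyr66N", ("A", 55, "O"), ("A", 66, "N")),
    ("Ser36CA-Lys55CA", ("A", 36, "CA"), ("A", 55, "CA")),
]

LOOP_SEPARATION = "Gly67CA-Asn92CA"


@dataclass
class ConstructConfig:
    """One construct of the suite."""

    name: str
    group: str  # "wt" or "mutant" (or anything; only these enter the test)
    pdb: str | None = None
    mixture: list[tuple[float, float, float]] | None = None
    cation_pi_fraction: float = 0.0
    n_frames: int = 1200
    seed_offset: int = 0


@dataclass
class RunConfig:
    """Full pipeline configuration with the analysis defaults.

    Defaults follow the standard protocol: 5-A interface threshold,
    cation-pi L <= 8 A and theta <= 60 deg, a 3-30 ns analysis window
    with 5-ps conformers and 1-ns volume snapshots.
    """

    constructs: list[ConstructConfig] = field(default_factory=list)
    outdir: str = "shp2md_out"
    seed: int = 0
    interface_threshold: float = 5.0
    cation_pi_l_max: float = 8.0
    cation_pi_theta_max: float = 60.0
    probe_radius: float = 0.0
    grid_spacing: float = 0.5
    envelope_radius: float = 6.0
    window: tuple[float, float] = (3.0, 30.0)
    volume_stride_ns: float = 1.0
    window_width: float = 1.5
    fit_components: int = 2
    closed_cutoff: float = 11.0
    n_fit_starts: int = 12

    def __post_init__(self) -> None:
        for val, what in [
            (self.interface_threshold, "interface threshold"),
            (self.cation_pi_l_max, "cation-pi L max"),
            (self.cation_pi_theta_max, "cation-pi theta max"),
            (self.grid_spacing, "grid spacing"),
        ]:
            if val <= 0:
                raise ValueError(f"{what} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        constructs = [
            ConstructConfig(
                name=c["name"],
                group=c.get("group", "wt"),
                pdb=c.get("pdb"),
                mixture=[tuple(m) for m in c["mixture"]] if "mixture" in c else None,
                cation_pi_fraction=float(c.get("cation_pi_fraction", 0.0)),
                n_frames=int(c.get("n_frames", 1200)),
                seed_offset=int(c.get("seed_offset", 0)),
            )
            for c in raw.pop("constructs", [])
        ]
        window = raw.pop("window", None)
        kwargs: dict[str, Any] = {
            k: v for k, v in raw.items() if k in cls.__dataclass_fields__
        }
        cfg = cls(constructs=constructs, **kwargs)
        if window is not None:
            cfg.window = (float(window[0]), float(window[1]))
        return cfg

    def echo(self) -> dict[str, Any]:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "constructs"
        }
        d["window"] = list(self.window)
        d["constructs"] = [
            {
                "name": c.name,
                "group": c.group,
                "pdb": c.pdb,
                "mixture": [list(m) for m in (c.mixture or [])],
                "cation_pi_fraction": c.cation_pi_fraction,
                "n_frames": c.n_frames,
                "seed_offset": c.seed_offset,
            }
            for c in self.constructs
        ]
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, construct: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed for construct {construct!r}: {cause}")
        self.stage = stage
        self.construct = construct


def _load_trajectory(c: ConstructConfig, config: RunConfig) -> Trajectory:
    if c.pdb is not None:
        return read_pdb(c.pdb)
    mixture = c.mixture or [(1.0, 8.8, 0.6)]
    t0, t1 = config.window
    n = c.n_frames
    dt = (t1 - t0) / n
    spec = synthetic.EnsembleSpec(
        n_frames=n,
        dt=dt,
        t0=t0,
        loop_separation_mixture=mixture,
        cation_pi_fraction=c.cation_pi_fraction,
        cation_pi_l_max=config.cation_pi_l_max,
        cation_pi_theta_max=config.cation_pi_theta_max,
        seed=(config.seed * 1009 + c.seed_offset) % (2**31 - 1),
    )
    traj, _ = synthetic.sample_trajectory(spec)
    return traj


def _round_floats(obj: Any, ndigits: int = 6) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.floating):
        return round(float(obj), ndigits)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis suite; returns the summary dict.

    Outputs land under ``config.outdir``: per-construct TSV series and
    curves, averaged-conformer PDBs, a column-fit table per observable,
    and ``summary.json``. Any stage failure raises :class:`StageError`
    naming the stage; partial outputs are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"config": config.echo(), "constructs": {}}
    curves_by_observable: dict[str, list[ensemble_stats.FractionCurve]] = {
        name: [] for name, _, _ in STANDARD_OBSERVABLES
    }
    construct_median_sep: dict[str, float] = {}

    for c in config.constructs:
        cdir = outdir / c.name
        cdir.mkdir(exist_ok=True)
        entry: dict[str, Any] = {"group": c.group}
        try:
            traj = _load_trajectory(c, config)
        except Exception as exc:
            raise StageError("load", c.name, exc) from exc
        entry["n_frames"] = len(traj)
        if len(traj) < 2:
            raise StageError(
                "load", c.name, ValueError("trajectory has fewer than 2 frames")
            )

        try:
            rser = geometry.rmsd_series(
                traj, traj.frames[0], selection="backbone",
                selection_name="backbone",
            )
            rser.to_tsv(cdir / "rmsd_vs_start.tsv")
            entry["rmsd_final_A"] = float(rser.values[-1])
        except Exception as exc:
            raise StageError("rmsd", c.name, exc) from exc

        try:
            obs_entries = {}
            for name, a, b in STANDARD_OBSERVABLES:
                series = geometry.distance_series(traj, (a, b), name=name)
                series.to_tsv(cdir / f"distance_{name}.tsv")
                curve = ensemble_stats.fraction_curve(
                    series, window_width=config.window_width, source=c.name
                )
                curve.to_tsv(cdir / f"curve_{name}.tsv")
                curves_by_observable[name].append(curve)
                obs_entries[name] = {
                    "median_A": float(np.median(series.values)),
                    "mean_A": float(np.mean(series.values)),
                }
                if name == LOOP_SEPARATION:
                    construct_median_sep[c.name] = float(np.median(series.values))
            entry["observables"] = obs_entries
        except Exception as exc:
            raise StageError("distances", c.name, exc) from exc

        try:
            t0 = float(traj.times[0])
            t1 = float(traj.times[-1])
            vseries = surface_volume.volume_series_average(
                traj,
                window=(t0, t1),
                stride_ns=config.volume_stride_ns,
                mouth_a="EF_loop",
                mouth_b="BG_loop",
                grid_spacing=config.grid_spacing,
                probe_radius=config.probe_radius,
                envelope_radius=config.envelope_radius,
                region_map=synthetic.sh2_region_map(),
            )
            vseries.to_tsv(cdir / "groove_volume.tsv")
            entry["groove_volume_mean_A3"] = vseries.mean
            entry["groove_volume_sd_A3"] = vseries.sd
        except Exception as exc:
            raise StageError("volume", c.name, exc) from exc

        try:
            frac = ensemble_stats.cation_pi_fraction(
                traj,
                ("A", 55),
                ("A", 66),
                l_max=config.cation_pi_l_max,
                theta_max=config.cation_pi_theta_max,
                window=None,
            )
            entry["cation_pi_fraction"] = frac
        except Exception as exc:
            raise StageError("cation-pi", c.name, exc) from exc

        try:
            avg = ensemble_stats.average_conformer(traj, align_selection="ca")
            write_pdb(avg, cdir / "average_conformer.pdb")
        except Exception as exc:
            raise StageError("average", c.name, exc) from exc

        summary["constructs"][c.name] = entry

    # column-synchronized fits across constructs (common grid per observable)
    fits: dict[str, Any] = {}
    for name, _, _ in STANDARD_OBSERVABLES:
        curves = curves_by_observable[name]
        if not curves:
            continue
        try:
            regridded = _common_grid(curves, config.window_width)
            fit = ensemble_stats.fit_column(
                regridded,
                config.fit_components,
                n_starts=config.n_fit_starts,
                seed=config.seed,
            )
            fit.to_tsv(outdir / f"fit_{name}.tsv")
            fits[name] = {
                "centers_A": [float(v) for v in fit.centers],
                "widths_A": [float(v) for v in fit.widths],
                "residual": float(fit.residual),
                "converged": bool(fit.converged),
                "amplitudes": {
                    src: [float(a) for a in fit.amplitudes[i]]
                    for i, src in enumerate(fit.curve_sources)
                },
            }
        except Exception as exc:
            raise StageError(f"fit[{name}]", "column", exc) from exc
    summary["column_fits"] = fits

    # closed-retention outcome test
    retained = {
        name: sep < config.closed_cutoff for name, sep in construct_median_sep.items()
    }
    groups = {c.name: c.group for c in config.constructs}
    n_total = len(retained)
    wt_names = [n for n, g in groups.items() if g == "wt"]
    n_retainers = sum(retained.values())
    matches = sum(1 for n in wt_names if retained.get(n, False))
    if n_total and wt_names:
        p = float(
            stats.hypergeom(M=n_total, n=n_retainers, N=len(wt_names)).pmf(matches)
        )
    else:
        p = float("nan")
    summary["outcome_test"] = {
        "closed_cutoff_A": config.closed_cutoff,
        "retained_closed": {k: bool(v) for k, v in sorted(retained.items())},
        "n_total": n_total,
        "n_wt": len(wt_names),
        "n_retainers": int(n_retainers),
        "matches_in_wt": int(matches),
        "hypergeometric_p": p,
    }

    text = json.dumps(_round_floats(summary), sort_keys=True, indent=1)
    (outdir / "summary.json").write_text(text + "\n")
    return summary


def _common_grid(
    curves: list[ensemble_stats.FractionCurve], window_width: float
) -> list[ensemble_stats.FractionCurve]:
    """Re-evaluate curves on a shared window grid for a joint column fit."""
    lo = min(float(c.window_centers.min()) for c in curves)
    hi = max(float(c.window_centers.max()) for c in curves)
    step = window_width / 5.0
    n = int(np.floor((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n)
    out = []
    for c in curves:
        vals = np.interp(grid, c.window_centers, c.fractions, left=0.0, right=0.0)
        out.append(
            ensemble_stats.FractionCurve(grid, vals, window_width, c.source)
        )
    return out


def default_six_construct_suite(seed: int = 0, n_frames: int = 900) -> RunConfig:
    """The standard synthetic suite: three wild-type-like runs that retain
    the closed conformation and three mutant-like runs that convert to the
    open conformation, mirroring the triplicate-versus-mutants comparison."""
    closed = [(0.85, 8.8, 0.6), (0.15, 10.0, 0.7)]
    mutants = [
        [(0.35, 9.0, 0.7), (0.65, 12.6, 0.9)],
        [(0.25, 9.0, 0.7), (0.75, 13.6, 0.9)],
        [(0.20, 9.2, 0.7), (0.80, 13.6, 0.8)],
    ]
    constructs = [
        ConstructConfig(
            name=f"wt_run{i + 1}",
            group="wt",
            mixture=closed,
            cation_pi_fraction=0.55,
            n_frames=n_frames,
            seed_offset=i,
        )
        for i in range(3)
    ] + [
        ConstructConfig(
            name=f"mutant{i + 1}",
            group="mutant",
            mixture=mutants[i],
            cation_pi_fraction=0.35,
            n_frames=n_frames,
            seed_offset=10 + i,
        )
        for i in range(3)
    ]
    return RunConfig(constructs=constructs, seed=seed)
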