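"""End-to-end orchestration: experiment grids, aggregation and reporting.

``run_grid`` reproduces the study protocol at configurable scale: for each
PEG surface fraction it runs ``trials_per_composition`` CBMC trials split
evenly over the three initial morphologies (random, striped, janus), keeps
the final ten snapshots of each trial (spaced by the snapshot interval),
converts every snapshot into a fragment distribution and SSR, and
aggregates per-composition statistics including the Janus character against
a 50-configuration perfect-Janus reference ensemble and number-weighted
patch sizes.

Everything is seeded from one grid seed through ``numpy.random.SeedSequence``
spawning, so a rerun with the same manifest is byte-identical, and every
statistic is recomputable from the stored trajectories alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cbmc import CBMCEngine, MoveSet
from .forcefield import ParameterSet
from .fragments import (binomial_reference, find_patches, janus_character,
                        number_weighted_patch_size,
                        sample_fragment_distribution, ssr, surface_fraction)
from .io import write_snapshot
from .monolayer import (default_core, init_janus, init_random, init_striped,
                        make_perfect_janus_ensemble, make_plan)

__all__ = ["ExperimentGrid", "GridResult", "run_grid", "report",
           "box_statistics", "snapshot_ssr"]

_INITS = {"random": init_random, "striped": init_striped, "janus": init_janus}


@dataclass(frozen=True)
class ExperimentGrid:
    """Grid manifest.  Defaults mirror the study protocol (nine surface
    fractions, 18 trials each, three init classes); proposals per trial has
    no published value and must be chosen by the caller."""

    x_values: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    trials_per_composition: int = 18
    proposals: int = 200_000
    snapshot_interval: int = 10_000
    keep_snapshots: int = 10
    seed: int = 0
    n_fragment_samples: int = 50_000
    fragment_cutoff: float = 6.0
    n_janus_reference: int = 50
    paper_mode: bool = True
    init_classes: tuple = ("random", "striped", "janus")
    out_root: str | None = None

    def __post_init__(self):
        if self.trials_per_composition % len(self.init_classes):
            raise ValueError("trials must divide evenly over init classes")


@dataclass
class GridResult:
    grid: ExperimentGrid
    per_snapshot: pd.DataFrame  # one row per (x, trial, snapshot)
    composition_summary: pd.DataFrame
    patch_summary: pd.DataFrame
    failures: list = field(default_factory=list)
    out_root: Path | None = None


def snapshot_ssr(config, n_samples: int, cutoff: float, seed: int):
    """theta, realized x and SSR against the binomial reference for one
    snapshot."""
    dist = sample_fragment_distribution(config, n_samples, cutoff, seed)
    x_hat = surface_fraction(dist)
    report_ = ssr(dist, binomial_reference(config.x_peg_realized))
    return dist, x_hat, report_.ssr


def run_grid(grid: ExperimentGrid, params: ParameterSet | None = None,
             core=None, moveset: MoveSet | None = None,
             progress: bool = False) -> GridResult:
    params = params or ParameterSet.default()
    core = core if core is not None else default_core()
    moveset = moveset or MoveSet()
    out_root = Path(grid.out_root) if grid.out_root else None
    if out_root:
        out_root.mkdir(parents=True, exist_ok=True)

    snap_rows = []
    comp_rows = []
    patch_rows = []
    failures = []
    per_class = grid.trials_per_composition // len(grid.init_classes)

    for xi, x in enumerate(grid.x_values):
        plan = make_plan(x, core=core, paper_mode=grid.paper_mode)
        x_ss = np.random.SeedSequence((grid.seed, xi))
        trial_seeds = [int(s.generate_state(1)[0] % 2**31)
                       for s in x_ss.spawn(grid.trials_per_composition + 2)]
        analysis_seed = trial_seeds[-2]
        janus_ref_seed = trial_seeds[-1]

        # perfect-Janus reference ensemble
        ref = make_perfect_janus_ensemble(
            x, core, params, grid.n_janus_reference, seed=janus_ref_seed,
            paper_mode=grid.paper_mode)
        ref_ssrs = []
        for j, rc in enumerate(ref):
            _, _, s = snapshot_ssr(rc, grid.n_fragment_samples,
                                   grid.fragment_cutoff, analysis_seed + j)
            ref_ssrs.append(s)
        ssr_janus_mean = float(np.mean(ref_ssrs))
        ssr_janus_sd = float(np.std(ref_ssrs, ddof=1))

        trial_idx = 0
        x_ssrs = []
        for init_name in grid.init_classes:
            for rep in range(per_class):
                seed = trial_seeds[trial_idx]
                try:
                    cfg = _INITS[init_name](plan, core, params, seed)
                    engine = CBMCEngine(cfg, moveset, seed=seed + 1)
                    record, traj = engine.run(
                        grid.proposals, snapshot_interval=grid.snapshot_interval)
                    snaps = traj[-grid.keep_snapshots:]
                    tdir = None
                    if out_root:
                        tdir = out_root / f"x{x:.2f}" / f"trial{trial_idx:02d}_{init_name}"
                        tdir.mkdir(parents=True, exist_ok=True)
                        (tdir / "run_record.json").write_text(record.to_json())
                        for k, snap in enumerate(snaps):
                            write_snapshot(snap, tdir / f"snapshot_{k:02d}.xyz")
                    for k, snap in enumerate(snaps):
                        sample_seed = analysis_seed + 1000 * trial_idx + k
                        dist, x_hat, s = snapshot_ssr(
                            snap, grid.n_fragment_samples, grid.fragment_cutoff,
                            sample_seed)
                        x_ssrs.append(s)
                        row = {"x_peg": x, "trial": trial_idx, "init": init_name,
                               "snapshot": k, "sample_seed": sample_seed,
                               "x_hat": x_hat, "ssr": s}
                        row.update({f"theta{i}": dist.theta[i] for i in range(5)})
                        snap_rows.append(row)
                        patches = find_patches(snap, grid.fragment_cutoff)
                        sizes = number_weighted_patch_size(patches)
                        patch_rows.append({"x_peg": x, "trial": trial_idx,
                                           "init": init_name, "snapshot": k,
                                           **{f"S_{t.lower()}": v
                                              for t, v in sizes.items()}})
                except Exception as exc:  # a failed trial is recorded, grid continues
                    failures.append({"x_peg": x, "trial": trial_idx,
                                     "init": init_name, "error": repr(exc)})
                trial_idx += 1
                if progress:
                    print(f"x={x} trial {trial_idx}/{grid.trials_per_composition}",
                          flush=True)

        if x_ssrs:
            mean_ssr = float(np.mean(x_ssrs))
            sd_ssr = float(np.std(x_ssrs, ddof=1)) if len(x_ssrs) > 1 else 0.0
            jc, jc_sd = janus_character(mean_ssr, ssr_janus_mean,
                                        sd_ssr, ssr_janus_sd)
            comp_rows.append({
                "x_peg": x, "n_snapshots": len(x_ssrs),
                "ssr_mean": mean_ssr, "ssr_sd": sd_ssr,
                "ssr_janus_mean": ssr_janus_mean, "ssr_janus_sd": ssr_janus_sd,
                "janus_character": jc, "janus_character_sd": jc_sd,
            })

    per_snapshot = pd.DataFrame(snap_rows)
    composition = pd.DataFrame(comp_rows)
    patch_df = pd.DataFrame(patch_rows)
    patch_summary = _patch_boxes(patch_df)
    result = GridResult(grid, per_snapshot, composition, patch_summary,
                        failures, out_root)
    if out_root:
        per_snapshot.to_csv(out_root / "per_snapshot.csv", index=False)
        composition.to_csv(out_root / "composition_summary.csv", index=False)
        patch_summary.to_csv(out_root / "patch_summary.csv", index=False)
        (out_root / "grid_manifest.json").write_text(
            json.dumps({**{k: getattr(grid, k) for k in (
                "x_values", "trials_per_composition", "proposals",
                "snapshot_interval", "keep_snapshots", "seed",
                "n_fragment_samples", "fragment_cutoff", "n_janus_reference",
                "paper_mode", "init_classes")},
                "failures": failures}, indent=1, default=list))
    return result


def box_statistics(values) -> dict:
    """Box-plot statistics: type-7 (linear interpolation) quartiles, whiskers
    at the extreme values within 1.5 IQR of the box, outliers beyond."""
    v = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # numpy default = type 7
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "q1": float(q1), "median": float(med), "q3": float(q3),
        "iqr": float(iqr),
        "whisker_lo": float(inside.min()) if len(inside) else float("nan"),
        "whisker_hi": float(inside.max()) if len(inside) else float("nan"),
        "outliers": [float(o) for o in v[(v < lo_fence) | (v > hi_fence)]],
        "n": int(len(v)),
    }


def _patch_boxes(patch_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    if patch_df.empty:
        return pd.DataFrame(rows)
    for x, grp in patch_df.groupby("x_peg"):
        for col, lt in (("S_peg", "PEG"), ("S_ddt", "DDT")):
            if col not in grp or grp[col].dropna().empty:
                continue
            stats = box_statistics(grp[col].dropna())
            stats["n_outliers"] = len(stats.pop("outliers"))
            rows.append({"x_peg": x, "ligand_type": lt, **stats})
    return pd.DataFrame(rows)


def report(result: GridResult) -> dict[str, pd.DataFrame]:
    """Aggregate tables keyed by x_PEG (SSR, Janus character, patch boxes)."""
    tables = {
        "ssr": result.composition_summary[
            ["x_peg", "ssr_mean", "ssr_sd", "n_snapshots"]]
        if not result.composition_summary.empty else pd.DataFrame(),
        "janus_character": result.composition_summary[
            ["x_peg", "janus_character", "janus_character_sd",
             "ssr_janus_mean", "ssr_janus_sd"]]
        if not result.composition_summary.empty else pd.DataFrame(),
        "patches": result.patch_summary,
    }
    if result.out_root:
        for name, df in tables.items():
            df.to_csv(result.out_root / f"report_{name}.csv", index=False)
    return tables
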