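"""End-to-end protocol orchestration.

The pipeline mirrors the two-round enhanced-sampling protocol:

1. **Round 1 (training system)** -- unbiased run to measure CV standard
   deviations; WT-MetaD biasing the two physically chosen CVs (exit
   distance and gate) with hill widths 0.75 x the unbiased CV std, to
   obtain a dissociation trajectory sampling bound and unbound states.
2. **SPIB** -- rule-initialized bound/unbound labels, SPIB training with
   label refinement; the learned linear RC is compiled to bias variables.
3. **Round 2 (library)** -- the transferred RC biases WT-MetaD for every
   ligand in the roster (hill widths 0.25 x the bound-state RC std),
   ``n_runs`` independent seeded dissociations per ligand.
4. **Kinetics** -- acceleration-factor rescaling, exponential fits with KS
   validation, relative off- and on-rates from the K_D table.
5. **Analysis** (optional) -- reweighted free-energy projections,
   end-to-end distances for ligands with an internal mode, and
   per-coordinate Delta RMSD flexibility profiles.

Every output is a pure function of (config, seed); the manifest records
seeds, the config digest and package versions, and a rerun with the same
config reproduces the kinetics CSV byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .analysis import delta_rmsd, end_to_end, fes_projection
from .cvs import CVDefinition, compute_cvs
from .kinetics import TransitionRecord, kinetics_report, transition_record
from .langevin import LangevinParams, integrate_langevin
from .metad import BiasVariable, MetadParams, run_wtmetad
from .plumed import write_colvar, write_hills
from .presets import (EXIT_CUTOFF, TRAINING_LIGAND, ToySystem, kd_table,
                      ligand_library, sigma_from_std)
from .spib import SPIB, SPIBConfig, initial_labels, project_rc, rc_statistics, \
    save_model, train_spib

_SEED_MOD = 2 ** 31


@dataclass
class PipelineConfig:
    """Configuration of a full protocol run."""

    roster: list[str] = field(default_factory=lambda: [
        "toyZMP", "toy1", "toy2", "toy23", "toy25", "toy26", "toy27", "toy4p"])
    training_ligand: str = TRAINING_LIGAND
    n_runs: int = 16
    seed: int = 1
    outdir: str = "mlmetad_out"
    run_analysis: bool = True
    write_plumed: bool = True
    # round 1
    unbiased_steps: int = 200_000
    round1_steps: int = 1_000_000
    round1_sigma_frac: float = 0.75
    # round 2
    round2_steps: int = 2_000_000
    round2_sigma_frac: float = 0.25
    # shared WT-MetaD settings (reduced units)
    h0: float = 1.5
    gamma: float = 40.0
    pace: float = 1.0
    stride: int = 10
    # analysis
    exit_window_frames: int = 500
    e2e_window_frames: int = 50  # short pre-exit window for the
    # end-to-end contraction signal (the transit through the bottleneck
    # is brief; a long window dilutes it with bound-basin frames)
    spib: SPIBConfig = field(default_factory=lambda: SPIBConfig(lag=20, epochs=40))
    kd_table_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 3:
            raise ValueError("n_runs must be >= 3 (kinetics needs >= 3 events)")
        if not self.roster:
            raise ValueError("ligand roster must be nonempty")
        if self.training_ligand not in self.roster:
            raise ValueError("training ligand must be part of the roster")

    def digest(self) -> str:
        d = asdict(self)
        payload = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        spib_doc = doc.pop("spib", None)
        cfg = cls(**doc)
        if spib_doc:
            cfg.spib = SPIBConfig(**spib_doc)
        return cfg


@dataclass
class PipelineResult:
    manifest: dict
    report: pd.DataFrame
    model: SPIB
    records: dict[str, list[TransitionRecord]]
    analysis: dict


def _seed(base: int, *idx: int) -> int:
    s = base * 1_000_003 + 17
    for i in idx:
        s = (s * 7_919 + i * 104_729 + 1) % _SEED_MOD
    return s


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full protocol; see the module docstring for the stages.

    Raises ``RuntimeError`` naming the failing stage; partial outputs
    written before the failure are preserved in ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "setup"
    manifest: dict = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": {"mlmetad": _pkg_version, "numpy": np.__version__},
        "stages": {},
    }
    try:
        systems = ligand_library(config.roster)
        train_sys = systems[config.training_ligand]
        th = train_sys.thermo
        dim = train_sys.surface.dim
        if config.kd_table_path:
            kds = pd.read_csv(config.kd_table_path)
        else:
            kds = kd_table(config.roster)

        # ---- round 1: unbiased + CV-biased runs on the training system
        stage = "round1"
        lp_u = LangevinParams(n_steps=config.unbiased_steps,
                              seed=_seed(config.seed, 1))
        traj_u = integrate_langevin(train_sys.surface, lp_u, th,
                                    stride=config.stride)
        traj_u = compute_cvs(traj_u, train_sys.cv_defs)
        stds = traj_u.cv_matrix.std(axis=0)
        names = [d.name for d in train_sys.cv_defs]
        r1_names = list(train_sys.round1_cvs)
        r1_idx = [names.index(n) for n in r1_names]
        r1_sigma = sigma_from_std(stds[r1_idx], config.round1_sigma_frac)
        r1_bvars = [BiasVariable(n, train_sys.cv_defs[i].linear_weights(dim))
                    for n, i in zip(r1_names, r1_idx)]
        mp1 = MetadParams(sigma=r1_sigma, h0=config.h0, gamma=config.gamma,
                          pace=config.pace, biased_variables=r1_names,
                          max_time=config.round1_steps * train_sys.langevin.dt)
        run1 = run_wtmetad(train_sys.surface, r1_bvars, mp1, th,
                           LangevinParams(n_steps=config.round1_steps,
                                          seed=_seed(config.seed, 2)),
                           stride=config.stride)
        traj1 = compute_cvs(run1.trajectory, train_sys.cv_defs)
        if config.write_plumed:
            write_hills(run1.ledger, out / "HILLS_round1")
            write_colvar(traj1, out / "COLVAR_round1")
        manifest["stages"]["round1"] = {
            "unbiased_std": dict(zip(names, stds.tolist())),
            "sigma": r1_sigma.tolist(),
            "n_hills": len(run1.ledger.hills),
        }

        # ---- SPIB training on the round-1 dissociation trajectory
        stage = "spib"
        labels = initial_labels(
            traj1, [(train_sys.bound.cv_name, ">", train_sys.bound.cutoff)])
        if labels.degenerate:
            raise RuntimeError("round-1 trajectory never dissociated; "
                               "cannot initialize two states")
        bound_mask = labels.labels == 0
        # copy so the caller's config (and its digest) stays untouched
        cfg_spib = replace(config.spib, seed=_seed(config.seed, 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = train_spib([traj1], [labels], cfg_spib,
                               norm_mask=bound_mask)
        rc_train = project_rc(model, traj1)
        rc_stats = rc_statistics(rc_train, bound_mask,
                                 fraction=config.round2_sigma_frac)
        if rc_stats.degenerate:
            raise RuntimeError("an RC is constant in the bound state; "
                               "sigma rule yields an invalid hill width")
        bvars = model.bias_variables(train_sys.cv_defs, dim)
        save_model(model, out / "spib_model.json")
        manifest["stages"]["spib"] = {
            "converged": bool(model.converged_),
            "weight_importance": dict(zip(names,
                                          model.weight_importance_.tolist())),
            "rc_sigma": rc_stats.sigma.tolist(),
        }

        # ---- round 2: transferred-RC WT-MetaD for the library
        stage = "round2"
        mp2 = MetadParams(sigma=rc_stats.sigma, h0=config.h0,
                          gamma=config.gamma, pace=config.pace,
                          biased_variables=[b.name for b in bvars],
                          max_time=config.round2_steps * train_sys.langevin.dt)
        records: dict[str, list[TransitionRecord]] = {}
        exit_windows: dict[str, list[np.ndarray]] = {}
        lig_trajs: dict[str, list] = {}
        lig_ledgers: dict[str, list] = {}
        for li, (lname, lsys) in enumerate(systems.items()):
            recs, wins, trajs, ledgers = [], [], [], []
            # the RC is defined on CV space; compile it onto this system's
            # coordinates (rosters share names, dimensionality may differ)
            bvars_l = model.bias_variables(lsys.cv_defs, lsys.surface.dim)
            rc_defs = [CVDefinition(bv.name, ("linear", bv.weights, -bv.mean))
                       for bv in bvars_l]
            for r in range(config.n_runs):
                lp = LangevinParams(n_steps=config.round2_steps,
                                    seed=_seed(config.seed, 4, li, r))
                mrun = run_wtmetad(lsys.surface, bvars_l, mp2, th, lp,
                                   stop=lsys.stop_condition(),
                                   stride=config.stride)
                tr = compute_cvs(mrun.trajectory, lsys.cv_defs + rc_defs)
                rec = transition_record(tr, th, lsys.bound, mrun.event,
                                        mrun.event_time)
                if not mrun.event:
                    raise RuntimeError(
                        f"{lname} run {r}: no dissociation within budget")
                recs.append(rec)
                bound_m = lsys.bound.mask(tr)
                kw = config.exit_window_frames
                bidx = np.where(bound_m)[0]
                w_idx = np.concatenate([bidx[-kw:],
                                        np.where(~bound_m)[0]])
                wins.append(tr.positions[np.sort(w_idx)])
                trajs.append(tr)
                ledgers.append(mrun.ledger)
            records[lname] = recs
            exit_windows[lname] = wins
            lig_trajs[lname] = trajs
            lig_ledgers[lname] = ledgers
        manifest["stages"]["round2"] = {
            lname: {"n_events": len(rs),
                    "mean_t_sim": float(np.mean([r.t_sim for r in rs])),
                    "mean_alpha": float(np.mean([r.alpha for r in rs]))}
            for lname, rs in records.items()}

        # ---- kinetics
        stage = "kinetics"
        report = kinetics_report(records, kds)
        report = report.sort_values("ligand", kind="stable").reset_index(drop=True)
        _write_csv(report, out / "kinetics.csv")
        ranking = report[report["in_ranking"]].sort_values(
            "k_on_rel", ascending=False, kind="stable").reset_index(drop=True)
        _write_csv(ranking, out / "ranking.csv")
        manifest["stages"]["kinetics"] = {
            "n_pass": int(report["ks_pass"].sum()),
            "n_total": int(len(report)),
        }

        # ---- analysis
        analysis: dict = {}
        if config.run_analysis:
            stage = "analysis"
            # apo-analog reference: unbiased bound-basin run of the
            # training system (per-coordinate fluctuation baseline)
            ref = traj_u.positions
            nshared = ref.shape[1]  # roster shared by all systems; a
            # ligand's internal-mode coordinate (when present) is excluded
            rows = []
            for lname in systems:
                wins_shared = [w[:, :nshared] for w in exit_windows[lname]]
                prof = delta_rmsd(wins_shared, ref,
                                  labels=[f"pos{j}" for j in range(nshared)])
                for lab, dv in zip(prof.labels, prof.delta):
                    rows.append(dict(ligand=lname, coordinate=lab,
                                     delta_rmsd=float(dv)))
            drms = pd.DataFrame(rows)
            _write_csv(drms, out / "delta_rmsd.csv")
            fes_ax = {}
            for lname, lsys in systems.items():
                grid = [(float(lsys.surface.box[0, 0]),
                         float(lsys.surface.box[0, 1]), 80)]
                fg = fes_projection(lig_trajs[lname], ["d_exit"], grid, th,
                                    ledgers=lig_ledgers[lname])
                fes_ax[lname] = fg
                df = pd.DataFrame({"d_exit": fg.axes[0],
                                   "free_energy": fg.free_energy})
                _write_csv(df, out / f"fes_{lname}.csv")
            e2e = {}
            for lname, lsys in systems.items():
                surf = lsys.surface
                if not getattr(surf, "has_internal", False):
                    continue
                vals_bound, vals_exit = [], []
                for tr in lig_trajs[lname]:
                    d = end_to_end(tr, ("fixed", [0.0]),
                                   ("coords", [surf.dim - 1]))
                    bm = lsys.bound.mask(tr)
                    bidx = np.where(bm)[0]
                    vals_bound.append(float(d[bidx].mean()))
                    vals_exit.append(float(d[bidx[-config.e2e_window_frames:]].mean()))
                e2e[lname] = {"bound_mean": float(np.mean(vals_bound)),
                              "pre_exit_mean": float(np.mean(vals_exit))}
            analysis = {"delta_rmsd": drms, "fes": fes_ax, "end_to_end": e2e}
            (out / "analysis.json").write_text(json.dumps(
                {"end_to_end": e2e}, indent=2))
            manifest["stages"]["analysis"] = {"end_to_end": e2e}

        stage = "finish"
        manifest["elapsed_s"] = round(time.time() - t_start, 2)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        return PipelineResult(manifest=manifest, report=report, model=model,
                              records=records, analysis=analysis)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
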