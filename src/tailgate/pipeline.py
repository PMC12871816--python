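"""Full translocation experiment: build, simulate, analyze, report.

``run_experiment`` generates matched full-tail and truncated-tail corridor
systems from one geometry, runs an ensemble of seeded Langevin
trajectories per system with early stopping once the tracked atom reaches
the P-site threshold, and reports dwell times, occupancy and the
full/truncated dwell-time fold change.  ``calibrate_tail`` sweeps the tail
excluded-volume radius to map the unspecified atomistic bulk of the tail
onto the coarse bead model, picking the smallest radius whose dwell ratio
enters the target band.

Each trajectory runs in fixed-size segments; segment n of trajectory i is
seeded from SeedSequence([base_seed, stream, i, n]) so results are
independent of execution order and bitwise reproducible.  A trajectory
that diverges numerically is retried once at half the timestep and
flagged; a second failure aborts the experiment with the stage, system
label and trajectory index.
"""

from __future__ import annotations

import configparser
import dataclasses
import datetime
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (DwellTime, FoldChange, OccupancyHistogram, RCSeries,
                       dwell_fold_change, first_passage_time,
                       occupancy_histogram, reaction_coordinate)
from .dynamics import CompiledSystem, run_langevin
from .errors import CalibrationError, DivergedError, TailgateError
from .forcefield import (ForceFieldParams, build_potential,
                         compute_contact_map)
from .structure import SimConfig, Structure
from .synthetic import GeometryParams, SystemBundle, make_translocation_system

FULL = "full"
TRUNCATED = "truncated"


@dataclass
class ExperimentConfig:
    """Complete parameter record of one experiment (INI-serializable)."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    # simulation block
    temperature: float = 0.5        # eps / k_B
    friction: float = 1.0           # 1 / tau
    timestep: float = 0.002         # tau
    max_steps: int = 800_000        # censoring horizon per trajectory
    output_stride: int = 50
    equil_steps: int = 2_000        # restrained pre-release equilibration
    segment_steps: int = 10_000     # early-stop granularity
    tracked_restraint_k: float = 100.0
    # analysis block
    threshold: float = 0.3          # nm, P-site arrival
    bin_width: float = 0.1          # nm, occupancy bins
    bin_max: float = 3.6            # nm
    n_bootstrap: int = 10_000
    occupancy_mode: str = "pooled"
    # experiment block
    n_events: int = 150
    base_seed: int = 0
    tail_sigma: float | None = None  # tail EV diameter; None = forcefield default
    calibration_events: int = 30
    calibration_sweep: tuple[float, ...] = (0.22, 0.30, 0.38)
    target_band: tuple[float, float] = (1.5, 3.0)

    def sim_config(self, seed: int, n_steps: int,
                   stride: int | None = None) -> SimConfig:
        return SimConfig(temperature=self.temperature, friction=self.friction,
                         timestep=self.timestep, n_steps=n_steps,
                         output_stride=stride or self.output_stride,
                         seed=seed)

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)

    # --- INI serialization ------------------------------------------------

    _SIM_KEYS = ("temperature", "friction", "timestep", "max_steps",
                 "output_stride", "equil_steps", "segment_steps",
                 "tracked_restraint_k")
    _ANA_KEYS = ("threshold", "bin_width", "bin_max", "n_bootstrap",
                 "occupancy_mode")
    _EXP_KEYS = ("n_events", "base_seed", "tail_sigma", "calibration_events",
                 "calibration_sweep", "target_band")

    def to_ini(self) -> str:
        cp = configparser.ConfigParser()
        cp["geometry"] = {k: repr(v) for k, v in
                          dataclasses.asdict(self.geometry).items()}
        cp["forcefield"] = {k: repr(v) for k, v in
                            dataclasses.asdict(self.forcefield).items()}
        cp["simulation"] = {k: repr(getattr(self, k)) for k in self._SIM_KEYS}
        cp["analysis"] = {k: repr(getattr(self, k)) for k in self._ANA_KEYS}
        cp["experiment"] = {
            k: ",".join(repr(x) for x in getattr(self, k))
            if isinstance(getattr(self, k), tuple)
            else repr(getattr(self, k)) for k in self._EXP_KEYS}
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def from_ini(cls, text: str) -> "ExperimentConfig":
        cp = configparser.ConfigParser()
        cp.read_string(text)

        def conv(ref, raw: str):
            raw = raw.strip()
            if isinstance(ref, tuple):
                return tuple(float(x) for x in raw.split(","))
            if raw == "None":
                return None
            if isinstance(ref, bool):
                return raw in ("True", "true", "1")
            if isinstance(ref, int):
                return int(raw)
            if isinstance(ref, float) or ref is None:
                return float(raw)
            return raw.strip("'\"")

        cfg = cls()
        geo = {k: conv(getattr(cfg.geometry, k), v)
               for k, v in cp["geometry"].items()} if "geometry" in cp else {}
        ff = {k: conv(getattr(cfg.forcefield, k), v)
              for k, v in cp["forcefield"].items()} if "forcefield" in cp \
            else {}
        kw: dict = {"geometry": cfg.geometry.replace(**geo),
                    "forcefield": cfg.forcefield.replace(**ff)}
        for section, keys in (("simulation", cls._SIM_KEYS),
                              ("analysis", cls._ANA_KEYS),
                              ("experiment", cls._EXP_KEYS)):
            if section not in cp:
                continue
            for k, v in cp[section].items():
                if k in keys:
                    kw[k] = conv(getattr(cfg, k), v)
        return cls(**kw)


def translocation_potential(bundle: SystemBundle, ff: ForceFieldParams,
                            tail_sigma: float | None = None
                            ) -> CompiledSystem:
    """Build the production potential for one system bundle.

    The native contact map comes from the post-translocation structure;
    contacts touching the disordered tail chain and contacts between two
    immobile atoms are dropped.  The tail's excluded-volume diameter may be
    overridden (the calibration knob), and the tail's anchored end is
    tethered to its reference position with the bond spring constant.
    """
    post = bundle.post_structure
    cm = compute_contact_map(post, cutoff=ff.cutoff,
                             min_seq_separation=ff.min_seq_separation)
    tail_chain = next((c for c, role in bundle.labels.items()
                       if role == "tail"), None)
    id_arr = post.atom_id
    keep = np.ones(cm.n_contacts, dtype=bool)
    mobile_of = dict(zip(id_arr.tolist(), post.mobile.tolist()))
    if tail_chain is not None:
        tail_ids = set(id_arr[post.chain_mask(tail_chain)].tolist())
    else:
        tail_ids = set()
    for n, (a, b) in enumerate(zip(cm.i.tolist(), cm.j.tolist())):
        if a in tail_ids or b in tail_ids:
            keep[n] = False
        elif not (mobile_of[a] or mobile_of[b]):
            keep[n] = False
    cm = cm.subset(keep)
    ligand_chain = next(c for c, role in bundle.labels.items()
                        if role == "ligand")
    pot = build_potential(post, cm, ff, rigid_chains=(ligand_chain,))
    if tail_chain is not None and tail_sigma is not None:
        pot = pot.with_chain_sigma(post, tail_chain, tail_sigma)
    if bundle.anchors:
        pot = pot.with_restraints(
            [(post.index_of(aid), point, ff.k_bond)
             for aid, point in bundle.anchors])
    return CompiledSystem(pot)


def _segment_seed(base_seed: int, stream: int, traj: int, seg: int) -> int:
    ss = np.random.SeedSequence([abs(base_seed), stream, traj, seg + 1])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _run_one_trajectory(sys: CompiledSystem, start: Structure,
                        cfg: ExperimentConfig, tracked_idx: int,
                        target: np.ndarray, seed: int, stream: int,
                        traj_index: int
                        ) -> tuple[RCSeries, DwellTime, bool]:
    """Equilibrate, release, and integrate until passage or the horizon.

    Returns (rc series, dwell time, retried-at-half-dt flag).
    """

    def attempt(timestep: float):
        # restrained equilibration at the A-site start
        eq_pot = sys.potential.with_restraints(
            [(tracked_idx, start.coords[tracked_idx],
              cfg.tracked_restraint_k)])
        eq_sys = CompiledSystem(eq_pot, skin=sys.skin)
        eq_cfg = SimConfig(temperature=cfg.temperature, friction=cfg.friction,
                           timestep=timestep, n_steps=cfg.equil_steps,
                           output_stride=cfg.equil_steps,
                           seed=_segment_seed(seed, stream, traj_index, -1))
        _, (coords, _) = run_langevin(eq_sys, start, eq_cfg,
                                      return_state=True)
        # production in early-stopping segments
        times_parts: list[np.ndarray] = []
        d_parts: list[np.ndarray] = []
        t_off = 0.0
        steps_done = 0
        seg = 0
        vels = None
        while steps_done < cfg.max_steps:
            n = min(cfg.segment_steps, cfg.max_steps - steps_done)
            seg_cfg = SimConfig(
                temperature=cfg.temperature, friction=cfg.friction,
                timestep=timestep, n_steps=n,
                output_stride=cfg.output_stride,
                seed=_segment_seed(seed, stream, traj_index, seg))
            traj, (coords, vels) = run_langevin(
                sys, start, seg_cfg, x0=coords, v0=vels, return_state=True)
            rc = reaction_coordinate(traj, tracked_idx, target)
            lo = 0 if seg == 0 else 1   # frame 0 repeats the previous end
            times_parts.append(rc.times[lo:] + t_off)
            d_parts.append(rc.d[lo:])
            t_off += float(rc.times[-1])
            steps_done += n
            seg += 1
            if np.min(rc.d) <= cfg.threshold:
                break
        rc_all = RCSeries(times=np.concatenate(times_parts),
                          d=np.concatenate(d_parts),
                          tracked_atom_id=int(sys.potential.atom_ids[tracked_idx]),
                          target_position=np.asarray(target, dtype=float))
        return rc_all, first_passage_time(rc_all, cfg.threshold)

    try:
        rc, dw = attempt(cfg.timestep)
        return rc, dw, False
    except DivergedError:
        rc, dw = attempt(cfg.timestep / 2.0)
        return rc, dw, True


@dataclass
class ExperimentReport:
    """All outputs of one experiment run."""

    config_snapshot: dict
    dwell_full: list[DwellTime]
    dwell_truncated: list[DwellTime]
    histogram: OccupancyHistogram
    fold_change: FoldChange | None   # None when every event was censored
    censored_counts: dict[str, int]
    retried_counts: dict[str, int]
    provenance: dict
    seeds: dict[str, list[int]]

    def dwell_table(self) -> pd.DataFrame:
        rows = []
        for system, dwells in ((FULL, self.dwell_full),
                               (TRUNCATED, self.dwell_truncated)):
            for k, d in enumerate(dwells):
                rows.append({"system": system, "trajectory": k,
                             "seed": self.seeds[system][k],
                             "tau": d.tau, "censored": d.censored})
        return pd.DataFrame(rows)

    def occupancy_table(self) -> pd.DataFrame:
        h = self.histogram
        out = {"bin_left": h.bin_edges[:-1], "bin_right": h.bin_edges[1:]}
        for label, dens in h.density.items():
            out[f"density_{label}"] = dens
        return pd.DataFrame(out)

    def fold_change_table(self) -> pd.DataFrame:
        fc = self.fold_change
        nan = float("nan")
        return pd.DataFrame([{
            "ratio": fc.ratio if fc else nan,
            "ci_low": fc.ci_low if fc else nan,
            "ci_high": fc.ci_high if fc else nan,
            "median_ratio": fc.median_ratio if fc else nan,
            "n_bootstrap": fc.n_bootstrap if fc else 0,
            "n_full": len(self.dwell_full),
            "n_truncated": len(self.dwell_truncated),
            "censored_full": self.censored_counts[FULL],
            "censored_truncated": self.censored_counts[TRUNCATED],
            "config_digest": self.provenance["config_digest"],
        }])

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dwell_table().to_csv(out / "dwell.tsv", sep="\t", index=False)
        self.occupancy_table().to_csv(out / "occupancy.tsv", sep="\t",
                                      index=False)
        self.fold_change_table().to_csv(out / "fold_change.tsv", sep="\t",
                                        index=False)
        (out / "report.json").write_text(json.dumps({
            "config": self.config_snapshot,
            "fold_change": None if self.fold_change is None else {
                "ratio": self.fold_change.ratio,
                "ci_low": self.fold_change.ci_low,
                "ci_high": self.fold_change.ci_high,
                "median_ratio": self.fold_change.median_ratio,
            },
            "censored_counts": self.censored_counts,
            "retried_counts": self.retried_counts,
            "provenance": self.provenance,
        }, indent=2))


def _config_snapshot(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return json.loads(json.dumps(d))  # plain JSON types only


def run_ensemble(cfg: ExperimentConfig, include_tail: bool, n_events: int,
                 tail_sigma: float | None, stream: int, label: str,
                 seed_offset: int = 0
                 ) -> tuple[list[DwellTime], list[RCSeries], list[int], int]:
    """Run one system's ensemble; returns (dwells, rc series, seeds, retries)."""
    bundle = make_translocation_system(cfg.geometry, include_tail,
                                       seed=cfg.base_seed)
    sys = translocation_potential(bundle, cfg.forcefield, tail_sigma)
    tracked_idx = bundle.post_structure.index_of(bundle.tracked_atom_id)
    dwells: list[DwellTime] = []
    rcs: list[RCSeries] = []
    seeds: list[int] = []
    retries = 0
    for k in range(n_events):
        seed = cfg.base_seed + seed_offset + k
        seeds.append(seed)
        try:
            rc, dw, retried = _run_one_trajectory(
                sys, bundle.pre_structure, cfg, tracked_idx,
                bundle.target_position, seed, stream, seed_offset + k)
        except TailgateError as exc:
            raise type(exc)(
                f"stage=simulate system={label} trajectory={k}: {exc}"
            ) from exc
        dwells.append(dw)
        rcs.append(rc)
        retries += int(retried)
    return dwells, rcs, seeds, retries


def run_experiment(cfg: ExperimentConfig,
                   out_dir: str | Path | None = None) -> ExperimentReport:
    """The full two-system experiment; deterministic for fixed config."""
    n = cfg.n_events
    tail_sigma = cfg.tail_sigma if cfg.tail_sigma is not None \
        else cfg.forcefield.sigma_ev
    dwell_f, rcs_f, seeds_f, retry_f = run_ensemble(
        cfg, True, n, tail_sigma, stream=1, label=FULL, seed_offset=0)
    dwell_t, rcs_t, seeds_t, retry_t = run_ensemble(
        cfg, False, n, None, stream=1, label=TRUNCATED, seed_offset=n)
    edges = np.arange(0.0, cfg.bin_max + cfg.bin_width / 2, cfg.bin_width)
    hist = occupancy_histogram({FULL: rcs_f, TRUNCATED: rcs_t}, edges,
                               mode=cfg.occupancy_mode,
                               threshold=cfg.threshold)
    from .errors import EstimationError
    try:
        fc = dwell_fold_change(dwell_f, dwell_t, n_bootstrap=cfg.n_bootstrap,
                               seed=cfg.base_seed)
    except EstimationError:
        # a fully censored tiny/smoke run still yields a structural report
        fc = None
    import hashlib
    snapshot = _config_snapshot(cfg)
    digest = hashlib.sha1(
        json.dumps(snapshot, sort_keys=True).encode()).hexdigest()[:12]
    report = ExperimentReport(
        config_snapshot=snapshot,
        dwell_full=dwell_f, dwell_truncated=dwell_t,
        histogram=hist, fold_change=fc,
        censored_counts={FULL: sum(d.censored for d in dwell_f),
                         TRUNCATED: sum(d.censored for d in dwell_t)},
        retried_counts={FULL: retry_f, TRUNCATED: retry_t},
        provenance={
            "base_seed": cfg.base_seed,
            "version": __version__,
            "config_digest": digest,
            "timestamp": datetime.datetime.now(
                datetime.timezone.utc).isoformat(),
        },
        seeds={FULL: seeds_f, TRUNCATED: seeds_t},
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


@dataclass
class CalibrationResult:
    """Outcome of the tail excluded-volume radius sweep."""

    chosen_sigma: float
    table: pd.DataFrame
    target_band: tuple[float, float]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "calibration.tsv", sep="\t", index=False)


def calibrate_tail(cfg: ExperimentConfig,
                   target_band: tuple[float, float] | None = None,
                   sweep: tuple[float, ...] | None = None
                   ) -> CalibrationResult:
    """Sweep the tail excluded-volume diameter; pick the smallest in-band one.

    Runs the truncated reference ensemble once (it has no tail), then one
    reduced full-tail ensemble per swept radius, and reports the dwell
    ratio curve.  Raises :class:`CalibrationError`, with the curve
    attached, if no radius reaches the band.
    """
    band = target_band or cfg.target_band
    radii = tuple(sweep if sweep is not None else cfg.calibration_sweep)
    if not radii:
        raise CalibrationError("empty calibration sweep", table=None)
    n = cfg.calibration_events
    dwell_t, _, _, _ = run_ensemble(cfg, False, n, None, stream=2,
                                    label=TRUNCATED, seed_offset=0)
    rows = []
    chosen = None
    from .errors import EstimationError
    for m, sigma in enumerate(sorted(radii)):
        dwell_f, _, _, _ = run_ensemble(cfg, True, n, sigma, stream=2,
                                        label=f"{FULL}@{sigma}",
                                        seed_offset=(m + 1) * n)
        try:
            fc = dwell_fold_change(dwell_f, dwell_t,
                                   n_bootstrap=cfg.n_bootstrap,
                                   seed=cfg.base_seed)
            ratio, lo, hi = fc.ratio, fc.ci_low, fc.ci_high
        except EstimationError:
            ratio = lo = hi = float("nan")   # fully censored at this radius
        in_band = bool(band[0] <= ratio <= band[1])
        rows.append({"tail_sigma": sigma, "ratio": ratio,
                     "ci_low": lo, "ci_high": hi,
                     "censored_full": sum(d.censored for d in dwell_f),
                     "in_band": in_band})
        if chosen is None and in_band:
            chosen = sigma
    table = pd.DataFrame(rows)
    table["ratio_nondecreasing_within_ci"] = _monotone_within_ci(table)
    if chosen is None:
        raise CalibrationError(
            f"no tail radius in {radii} reached dwell-ratio band {band}",
            table=table)
    return CalibrationResult(chosen_sigma=float(chosen), table=table,
                             target_band=tuple(band))


def _monotone_within_ci(table: pd.DataFrame) -> bool:
    """True if the ratio curve is non-decreasing up to CI overlap."""
    ok = True
    for a in range(1, len(table)):
        if table.ratio[a] < table.ratio[a - 1] and \
                table.ci_high[a] < table.ci_low[a - 1]:
            ok = False
    return ok
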