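"""Replica campaigns: N seeded metadynamics runs → replica statistics.

A campaign mirrors the published replica protocol: ``n_replicas``
independent metadynamics simulations of the same system differing only in
their random seed (derived deterministically as ``base_seed + index``),
post-processed per mode:

* ``flooding`` — well-tempered runs; each replica yields an acceleration
  factor series, a transition time and RT_calcd; the campaign reports the
  geometric mean τ (log₁₀-minute statistics, SEM over n), the ECD of
  RT_calcd and the exponentiality (Poisson rare-event) check.
* ``tmetad`` — constant-height runs; each replica yields the first
  unbound time, reported as mean t_META-D ± SEM in ns.

Replicas that never reach the unbound state within ``max_time`` are
censored: logged, excluded from the summary, and counted in
``n_effective``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as mio
from .engine import DepositionSchedule, WallSpec, WellTemperedParams, run_metad
from .recovery import (
    ReplicaSummary,
    aggregate_replicas,
    ecd,
    exponentiality_check,
    flooding_estimate,
    t_metad,
)
from .toys import (
    DoubleWell1D,
    DoubleWellSystem,
    Funnel2D,
    Funnel2DSystem,
    KB,
    LangevinParams,
    PseudoComplexSystem,
    generate_pseudo_complex,
)

logger = logging.getLogger("metadrt.campaign")

#: published deposition parameters: 1 ps stride; hill height 0.40 kcal/mol
#: with bias factor kT = 10 kcal/mol for the well-tempered (flooding) runs,
#: 0.25 kcal/mol constant height for the t_META-D runs
FLOODING_PARAMS = WellTemperedParams(omega0=0.40, kb_deltaT=10.0, enabled=True)
TMETAD_PARAMS = WellTemperedParams(omega0=0.25, kb_deltaT=10.0, enabled=False)


@dataclass
class CampaignConfig:
    """Declarative description of a replica campaign."""

    system: dict
    mode: str = "flooding"  # or "tmetad"
    n_replicas: int = 10
    base_seed: int = 1
    stride: float = 1.0
    max_time: float = 1000.0
    omega0: Optional[float] = None  # default by mode
    kb_deltaT: float = 10.0
    walls: list = field(default_factory=list)
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("flooding", "tmetad"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")

    def replica_seed(self, index: int) -> int:
        return self.base_seed + index

    @property
    def params(self) -> WellTemperedParams:
        if self.omega0 is None:
            return FLOODING_PARAMS if self.mode == "flooding" else TMETAD_PARAMS
        return WellTemperedParams(
            omega0=self.omega0,
            kb_deltaT=self.kb_deltaT,
            enabled=self.mode == "flooding",
        )

    @classmethod
    def from_yaml(cls, path) -> "CampaignConfig":
        return cls(**mio.load_config(path))

    def as_dict(self) -> dict:
        return {
            "system": self.system,
            "mode": self.mode,
            "n_replicas": self.n_replicas,
            "base_seed": self.base_seed,
            "stride": self.stride,
            "max_time": self.max_time,
            "omega0": self.omega0,
            "kb_deltaT": self.kb_deltaT,
            "walls": list(self.walls),
        }


def build_system(spec: dict):
    """Instantiate a toy system from its declarative spec."""
    spec = dict(spec)
    kind = spec.pop("kind")
    lp = LangevinParams(
        temperature=spec.pop("temperature", 300.0),
        friction=spec.pop("friction", 3.0),
        timestep=spec.pop("timestep", 0.002),
        mass=spec.pop("mass", 1.0),
    )
    if kind == "double_well":
        barrier = spec.pop("barrier", None)
        if barrier is None:
            barrier = spec.pop("barrier_kt", 8.0) * lp.kT
        pot = DoubleWell1D(barrier=barrier, x0=spec.pop("x0", 1.0))
        return DoubleWellSystem(
            pot, lp, cv_width=spec.pop("cv_width", 0.2), unbound_at=spec.pop("unbound_at", None)
        )
    if kind == "funnel2d":
        barrier = spec.pop("barrier", None)
        if barrier is None:
            barrier = spec.pop("barrier_kt", 6.0) * lp.kT
        pot = Funnel2D(
            barrier=barrier,
            x0=spec.pop("x0", 1.0),
            center=spec.pop("center", 0.0),
            k_transverse=spec.pop("k_transverse", 2.0),
        )
        return Funnel2DSystem(
            pot, lp, cv_widths=spec.pop("cv_widths", (0.2, 0.2)),
            unbound_at=spec.pop("unbound_at", None),
        )
    if kind == "pseudo_complex":
        complex_, specs = generate_pseudo_complex(seed=spec.pop("seed", 0))
        return PseudoComplexSystem(
            complex_, specs, lp,
            cv_widths=spec.pop("cv_widths", (0.2, 1.5, 1.5, 0.2, 0.1)),
            unbound_cutoff=spec.pop("unbound_cutoff", 5.0),
        )
    raise ValueError(f"unknown system kind {kind!r}")


def double_well_fixture(barrier_kt: float = 8.0) -> dict:
    """The standard 1-D double-well fixture spec used by the recovery tests.

    Barrier in units of k_BT at 300 K, minima at ±1 Å, friction γ·m = 3
    kcal·mol⁻¹·ps·Å⁻², 2 fs time step, CV width 0.2 Å (about a third of
    the thermal basin width).
    """
    return {
        "kind": "double_well",
        "barrier_kt": barrier_kt,
        "x0": 1.0,
        "temperature": 300.0,
        "friction": 3.0,
        "timestep": 0.002,
        "cv_width": 0.2,
    }


@dataclass
class CampaignResult:
    config: CampaignConfig
    replicas: pd.DataFrame
    summary: Optional[ReplicaSummary]
    n_effective: int
    ks_statistic: Optional[float] = None
    ks_pvalue: Optional[float] = None
    trajectories: list = field(default_factory=list)

    @property
    def tau_minutes(self) -> Optional[float]:
        return None if self.summary is None else self.summary.tau

    def summary_dict(self) -> dict:
        d = {
            "mode": self.config.mode,
            "n_replicas": self.config.n_replicas,
            "n_effective": self.n_effective,
            "base_seed": self.config.base_seed,
        }
        if self.summary is not None:
            if self.config.mode == "flooding":
                d.update(
                    {
                        "log10_tau_minutes": self.summary.log_mean,
                        "sem_log10": self.summary.sem,
                        "tau_minutes": self.summary.tau,
                    }
                )
            else:
                vals = self.summary.values
                d.update(
                    {
                        "mean_t_metad_ns": float(np.mean(vals)),
                        "sem_t_metad_ns": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                        if len(vals) > 1
                        else None,
                    }
                )
        if self.ks_statistic is not None:
            d.update({"ks_statistic": self.ks_statistic, "ks_pvalue": self.ks_pvalue})
        return d


def _usable(replicas: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for aggregation: reached unbound and not censored."""
    if "status" not in replicas:
        return replicas.iloc[0:0]
    if "censored" in replicas:
        cens = replicas["censored"].fillna(True).astype(bool)
    else:
        cens = pd.Series(False, index=replicas.index)
    return replicas[(replicas["status"] == "unbound") & (~cens)]


def run_campaign(config: CampaignConfig, keep_trajectories: bool = False) -> CampaignResult:
    """Run all replicas of a campaign and aggregate them.

    Fully reproducible from ``(config, base_seed)``.  A replica that fails
    numerically or is censored is logged and excluded; ``n_effective``
    counts the usable replicas.
    """
    system = build_system(config.system)
    schedule = DepositionSchedule(stride=config.stride, max_time=config.max_time)
    walls = [WallSpec(**w) if isinstance(w, dict) else w for w in config.walls]
    beta = system.langevin.beta

    rows = []
    trajs = []
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    for i in range(config.n_replicas):
        seed = config.replica_seed(i)
        try:
            traj = run_metad(system, config.params, schedule, walls=walls, seed=seed)
        except Exception as exc:  # noqa: BLE001 — campaign continues past a bad replica
            logger.warning("replica %d (seed %d) failed: %s", i, seed, exc)
            rows.append({"replica": i, "seed": seed, "status": "failed"})
            continue
        logger.info(
            "replica %d: %d hills deposited, stop reason %s", i, len(traj.hills), traj.status
        )
        row = {"replica": i, "seed": seed, "status": traj.status, "n_hills": len(traj.hills)}
        if config.mode == "flooding":
            if traj.status != "unbound":
                logger.warning("replica %d censored (no unbinding within max_time)", i)
                row["censored"] = True
            else:
                est = flooding_estimate(traj, beta)
                row.update(
                    {
                        "censored": not est.converged,
                        "alpha_max": est.alpha_max,
                        "log10_alpha_max": est.log10_alpha_max,
                        "t_transition_ps": est.t_transition,
                        "rt_calcd_ps": est.rt_calcd_ps,
                        "log10_rt_minutes": est.log10_rt_minutes,
                    }
                )
        else:
            res = t_metad(traj)
            if res.censored:
                logger.warning("replica %d censored (no unbinding within max_time)", i)
            row.update({"censored": res.censored, "t_metad_ns": res.t_metad_ns})
        rows.append(row)
        if keep_trajectories:
            trajs.append(traj)
        if outdir:
            mio.write_trajectory(outdir / f"replica_{i:02d}.colvar", traj)
            biasf = config.params.kb_deltaT if config.params.enabled else 0.0
            mio.write_hills(outdir / f"replica_{i:02d}.hills", traj.hills, bias_factor=biasf)

    replicas = pd.DataFrame(rows)
    ok = _usable(replicas)
    summary = None
    ks_stat = ks_p = None
    if len(ok) > 0:
        if config.mode == "flooding":
            values = 10.0 ** ok["log10_rt_minutes"].to_numpy()
            summary = aggregate_replicas(values)
            if len(ok) >= 5:
                finite = ok["rt_calcd_ps"].to_numpy()
                if np.all(np.isfinite(finite)):
                    ks_stat, ks_p = exponentiality_check(finite)
        else:
            summary = aggregate_replicas(ok["t_metad_ns"].to_numpy())
    n_effective = int(len(ok))

    result = CampaignResult(
        config=config,
        replicas=replicas,
        summary=summary,
        n_effective=n_effective,
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
        trajectories=trajs,
    )
    if outdir:
        replicas.to_csv(outdir / "replicas.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(result.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result


def report(result: CampaignResult, skr_fit=None, poisson_mode: str = "standard") -> dict:
    """Assemble a JSON-serialisable campaign report.

    With an :class:`~metadrt.skr.SKRFit` supplied, the campaign descriptor
    (log τ for flooding, mean t_META-D in ns otherwise) is pushed through
    the calibrated SKR line to a predicted experimental log RT.
    """
    out = {"summary": result.summary_dict(), "poisson_mode": poisson_mode}
    ok = _usable(result.replicas)
    if result.config.mode == "flooding" and "log10_rt_minutes" in ok:
        curve = ecd(10.0 ** ok["log10_rt_minutes"].to_numpy()) if len(ok) else None
    elif "t_metad_ns" in ok:
        curve = ecd(ok["t_metad_ns"].to_numpy()) if len(ok) else None
    else:
        curve = None
    if curve is not None:
        out["ecd"] = {
            "values": list(map(float, curve.values)),
            "probabilities": list(map(float, curve.probabilities)),
        }
    if skr_fit is not None and result.summary is not None:
        descriptor = (
            result.summary.log_mean
            if result.config.mode == "flooding"
            else float(np.mean(result.summary.values))
        )
        out["skr_prediction"] = {
            "descriptor": descriptor,
            "descriptor_kind": skr_fit.descriptor_kind,
            "predicted_log_rt_minutes": skr_fit.slope * descriptor + skr_fit.intercept,
            "units": "log10 minutes",
        }
    return out
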