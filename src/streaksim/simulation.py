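"""Scenario driver: wires embryo, fields, guidance, growth and metrics.

A scenario is: build the disk embryo, solve the induction morphogen and
differentiate the sickle, select the streak-tip group (or place two sickle
fragments for the double-streak experiment), pre-equilibrate the chemotactic
agent of the chosen mechanism, then iterate Monte Carlo steps.  Each MCS:

1. one Metropolis sweep under the active energy terms;
2. the chemotactic agent advances one time unit of its diffusion dynamics;
3. induced polarization updates synchronously (when enabled);
4. growth/division bookkeeping (when enabled);
5. recentering or ECM anchoring keeps the embryo positionally stable;
6. tracks are sampled on a fixed cadence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from . import proliferation
from .core import (AdhesionTable, EnergyModel, SimParams, TissueState,
                   recenter, run_mcs)
from .embryo import (MechanismConfig, build_disk_embryo, build_double_streak,
                     configure_mechanism, differentiate_mesoderm,
                     select_tip_cells)
from .fields import (ScalarField, build_ecm_anchor, equilibrate_field,
                     solve_induction_field, step_field)
from .guidance import (PolarizationParams, beta_by_type,
                       update_all_polarizations)
from .metrics import make_track_table, track_rows


@dataclass
class ScenarioConfig:
    """Plain-data description of one run; round-trips through YAML."""

    mechanism: str = "M3"
    n_cells: int = 625
    ap_radius: float = 77.0
    target_volume: int = 50
    n_mcs: int = 7000
    sample_every: int = 50
    seed: int = 0
    polarization: bool = True
    growth: bool = False
    growth_period: int = 200       # MCS per target-volume increment
    margin: int | None = None      # lattice margin; None = auto (wider
                                   # under growth to hold the swelling)
    double_streak: bool = False
    anchoring: str = "recenter"          # "recenter" | "ecm" | "none"
    induction_threshold: float = 0.7
    induction_peak: float = 1.3
    tip_fraction: float = 0.25
    relax_mcs: int = 100
    beta_ecm: float = 2.0
    chemotaxis: bool = True
    rate_scale: float | None = None
    calibrate_agent: bool = True
    agent_peak: float = 1.0
    adhesion_overrides: dict = dc_field(default_factory=dict)
    polarization_params: dict = dc_field(default_factory=dict)
    sim_params: dict = dc_field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def resolved_rate_scale(self) -> float:
        """Field-kinetics multiplier preserving concentration magnitudes
        when the embryo is scaled down.

        Steady concentrations scale as k1 R^2 / D (induction) and have
        diffusion length sqrt(D/k2); multiplying k1 and k2 by
        (area_full / area) keeps the concentration maxima and the ratio of
        diffusion length to embryo radius invariant.  Equal to 1 at the
        standard 625-cell size.
        """
        if self.rate_scale is not None:
            return self.rate_scale
        return (625 * 50) / (self.n_cells * self.target_volume)


def scaled_scenario(n_cells: int, **overrides) -> ScenarioConfig:
    """Consistently shrunken scenario: geometry scales with sqrt(n_cells),
    field kinetics with 1/area, run length with the embryo diameter."""
    s = float(np.sqrt(n_cells / 625))
    # field amplitude scales with s so the per-copy chemotactic energy
    # beta * grad(u) is scale-invariant (gradients steepen as 1/s when the
    # kinetic rates scale with 1/s^2)
    cfg = ScenarioConfig(n_cells=n_cells,
                         ap_radius=77.0 * s,
                         n_mcs=max(200, int(round(7000 * s))),
                         sample_every=max(10, int(round(50 * s))),
                         agent_peak=1.0 * s,
                         growth_period=max(20, int(round(200 * s))))
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


class Simulation:
    """One configured scenario, ready to advance MCS by MCS."""

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        params = SimParams(**config.sim_params)
        margin = config.margin
        if margin is None:
            margin = 45 if config.growth else 25
        self.state = build_disk_embryo(
            n_cells=config.n_cells, ap_radius=config.ap_radius,
            target_volume=config.target_volume, margin=margin,
            relax_mcs=config.relax_mcs, params=params, rng=self.rng)

        rs = config.resolved_rate_scale()
        self.rate_scale = rs
        self.induction = solve_induction_field(self.state, k1=1.5e-3 * rs,
                                               k2=1.0e-3 * rs,
                                               peak=config.induction_peak)
        differentiate_mesoderm(self.state, self.induction,
                               config.induction_threshold)
        if config.double_streak:
            # reset the single sickle, then place the two fragments
            live = self.state.live_cells()
            from .core import AP as _AP, S as _S, ST as _ST
            meso = live[np.isin(self.state.ctype[live], (_S, _ST))]
            self.state.ctype[meso] = _AP
            self.double = build_double_streak(
                self.state, ap_radius=config.ap_radius,
                tip_fraction=config.tip_fraction)
        else:
            select_tip_cells(self.state, config.tip_fraction)
            self.double = None

        self.mechanism: MechanismConfig = configure_mechanism(
            config.mechanism, polarization_on=config.polarization,
            growth_on=config.growth)
        overrides = dict(self.mechanism.adhesion_overrides)
        overrides.update({tuple(k.split("-")) if isinstance(k, str) else k: v
                          for k, v in config.adhesion_overrides.items()})
        self.adhesion = AdhesionTable.default().with_overrides(overrides)

        self.mechanism.field_params.setdefault("k1", 1.5e-3 * rs)
        self.mechanism.field_params.setdefault("k2", 1.0e-3 * rs)
        self.agent = self.mechanism.make_field(self.state.shape)
        equilibrate_field(self.agent, self.state)
        if config.calibrate_agent and self.mechanism.amplitude_mode == "calibrated":
            # calibrate the source amplitude so the equilibrated field peaks
            # at agent_peak (on the 0 -> k1/k2 display scale): a producing
            # region narrower than the diffusion length cannot reach the
            # saturation level at the printed rate, and the drive amplitude,
            # not the kinetics, is what the peak sets
            peak = self.agent.values.max()
            target = min(config.agent_peak * self.mechanism.amplitude_factor,
                         self.agent.k1 / self.agent.k2)
            if 0 < peak < target:
                scale = target / peak
                self.agent.k1 *= scale
                self.agent.values *= scale
        self.fields: dict[str, ScalarField] = {
            "induction": self.induction, self.agent.name: self.agent}
        self.anchoring = config.anchoring
        if self.anchoring == "ecm":
            self.ecm = build_ecm_anchor(self.state, k2_ecm=1.0e-4 * rs,
                                        k1=1.5e-3 * rs)
            self.fields["ecm"] = self.ecm
        else:
            self.ecm = None

        self.pol_params = PolarizationParams(**config.polarization_params)
        self._chemo_pairs = self._build_chemo_pairs()
        if config.growth:
            proliferation.init_growth(self.state, rng=self.rng)
        self._rows = track_rows(self.state)

    # -- energy wiring ------------------------------------------------------

    def _build_chemo_pairs(self):
        """(grid, beta-by-type) list shared by the per-voxel chemotaxis
        term and the polarization update's gradient drive."""
        beta = beta_by_type(self.mechanism.responses, self.agent.name)
        if not self.config.chemotaxis:
            beta = np.zeros_like(beta)
        return [(self.agent.values, beta)]

    def energy_model(self) -> EnergyModel:
        # the local chemotaxis term stays active alongside the polarization
        # term: it is self-limiting (the gradient at the tip collapses if
        # the tip outruns its source) and keeps the tip attached, while the
        # polarization term propagates the drive to neighbors
        chemo = []
        lambda_p = 0.0
        if self.config.chemotaxis:
            chemo.extend(self._chemo_pairs)
        if self.config.polarization:
            lambda_p = self.pol_params.strength
        if self.ecm is not None:
            beta = np.zeros(5)
            beta[2] = self.config.beta_ecm            # AO haptotaxis
            chemo.append((self.ecm.values, beta))
        return EnergyModel(adhesion=self.adhesion,
                           alpha=self.state.params.alpha,
                           chemo=chemo, lambda_p=lambda_p)

    # -- main loop ----------------------------------------------------------

    def advance(self, n_mcs: int) -> None:
        cfg = self.config
        state = self.state
        energy = self.energy_model()
        for _ in range(n_mcs):
            run_mcs(state, energy)
            step_field(self.agent, state, dt=1.0)
            if self.ecm is not None:
                step_field(self.ecm, state, dt=1.0)
            if cfg.polarization:
                update_all_polarizations(state, self._chemo_pairs,
                                         self.pol_params)
            if cfg.growth:
                proliferation.grow_cells(state, every=cfg.growth_period)
                proliferation.divide_ready_cells(state, rng=self.rng)
            if (self.anchoring == "recenter"
                    and state.step % state.params.recenter_every == 0):
                recenter(state, self.fields.values())
            if state.step % cfg.sample_every == 0:
                self._rows.extend(track_rows(state))
            # energy grids may have been reallocated (recenter keeps views,
            # division/growth never touch them) -- rebuild cheaply
            energy = self.energy_model()

    def run(self, n_mcs: int | None = None) -> "Simulation":
        self.advance(n_mcs if n_mcs is not None else self.config.n_mcs)
        return self

    @property
    def tracks(self):
        return make_track_table(self._rows)


def run_scenario(config: ScenarioConfig, n_mcs: int | None = None) -> Simulation:
    """Build and run a scenario; returns the finished Simulation."""
    return Simulation(config).run(n_mcs)
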