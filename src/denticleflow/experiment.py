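"""The 2x2x2 virtual experiment, independence protocol, and decision rule.

The full grid crosses geometry (idealized / empirical) x denticle
orientation (rostral / caudal) x inlet speed (0.05 / 0.5 m/s).  The
suspension-feeding hypothesis predicts recirculation in the spaces
between denticles only for the rostral orientation; the caudal mirror is
the null model.  The paper's visual "similar patterns" judgment is
operationalized as order-of-magnitude equality of the peak metrics plus
recirculation coverage of the interior gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import geometry as geo
from . import postprocess as post
from .solver import FluidProps, SolverConfig, solve_steady, reynolds, NU_REPORT

log = logging.getLogger(__name__)

REJECTED = "hypothesis_rejected"
SUPPORTED = "hypothesis_supported"
INCONCLUSIVE = "inconclusive"

INLET_SPEEDS = (0.05, 0.5)
INDEPENDENCE_TOL = 0.05      # max successive relative drag change


@dataclass(frozen=True)
class ScaleSettings:
    """Problem-size preset: the full published configuration, or the
    desk-scale variant justified by the edge-trimming argument."""

    n_denticles: int
    upstream_factor: float
    downstream_factor: float
    height: float
    n_exclude: int

    @classmethod
    def get(cls, scale: str) -> "ScaleSettings":
        if scale == "full":
            return cls(20, 3.0, 20.0, 0.01, 7)
        if scale == "small":
            return cls(10, 3.0, 10.0, 0.01, 2)
        raise ValueError(f"unknown scale {scale!r}")


@dataclass(frozen=True)
class RunSpec:
    geometry: str = "idealized"          # idealized | empirical
    orientation: str = geo.ROSTRAL
    inlet_velocity: float = 0.5
    seed: int = 1
    scale: str = "small"
    spacing_h: float = 1.0e-5
    perturbation_cv: float = 0.25
    solver_overrides: tuple = ()         # ((name, value), ...)

    @property
    def run_id(self) -> str:
        return (f"{self.geometry}_{self.orientation}"
                f"_U{self.inlet_velocity:g}_h{self.spacing_h:g}")


@dataclass
class RunResult:
    spec: RunSpec
    profile: geo.DenticleProfile
    domain: geo.FlowDomain
    mask: geo.MaskGrid
    solution: object
    metrics: post.FieldMetrics
    reynolds_number: float


@dataclass
class ExperimentReport:
    runs: list[RunResult] = field(default_factory=list)
    pair_verdicts: dict = field(default_factory=dict)
    overall_verdict: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.runs:
            m = r.metrics
            rows.append({
                "run_id": r.spec.run_id,
                "geometry": r.spec.geometry,
                "orientation": r.spec.orientation,
                "U_m_per_s": r.spec.inlet_velocity,
                "Re": r.reynolds_number,
                "converged": m.converged,
                "drag_N_per_m": r.solution.drag_force_Fd,
                "peak_velocity_m_per_s": m.peak_velocity_near_denticles,
                "peak_vorticity_per_s": m.peak_vorticity_near_denticles,
                "velocity_oom": m.velocity_oom,
                "vorticity_oom": m.vorticity_oom,
                "n_gaps": m.n_gaps,
                "n_gaps_recirculating": m.n_gaps_recirculating,
                "n_zones": len(m.recirculation_zones),
            })
        return pd.DataFrame(rows)


@dataclass
class IndependenceReport:
    parameter: str
    values: list
    drags: list
    successive_changes: list
    passed: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "value": self.values,
            "drag_N_per_m": self.drags,
            "relative_change": [np.nan] + list(self.successive_changes),
        })


def build_geometry(spec: RunSpec):
    """Profile, domain, and graded solver grid for one run."""
    s = ScaleSettings.get(spec.scale)
    params = geo.DenticleParams(
        n_denticles=s.n_denticles, orientation=spec.orientation,
        perturbation_cv=spec.perturbation_cv if spec.geometry == "empirical"
        else 0.0,
        seed=spec.seed)
    if spec.geometry == "empirical":
        profile = geo.make_empirical_profile(params)
    elif spec.geometry == "idealized":
        profile = geo.make_idealized_profile(params)
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    domain = geo.build_domain(profile, height=s.height,
                              upstream_factor=s.upstream_factor,
                              downstream_factor=s.downstream_factor)
    mask = geo.rasterize_graded(profile, domain, spec.spacing_h)
    return profile, domain, mask


def run_single(spec: RunSpec, fluid: FluidProps | None = None) -> RunResult:
    fluid = fluid or FluidProps()
    profile, domain, mask = build_geometry(spec)
    cfg = SolverConfig(inlet_velocity_U=spec.inlet_velocity,
                       spacing_h=spec.spacing_h)
    for name, value in spec.solver_overrides:
        setattr(cfg, name, value)
    log.info("run %s: grid %dx%d", spec.run_id, mask.nx, mask.ny)
    sol = solve_steady(mask, domain, fluid, cfg)
    s = ScaleSettings.get(spec.scale)
    metrics = post.field_metrics(sol, mask, profile, domain,
                                 n_exclude=s.n_exclude)
    re_num = reynolds(spec.inlet_velocity, profile.model_length_L, NU_REPORT)
    return RunResult(spec, profile, domain, mask, sol, metrics, re_num)


def default_grid(scale: str = "small", seed: int = 1,
                 spacing_h: float = 1.0e-5) -> list[RunSpec]:
    """The full 8-run grid: geometry x orientation x inlet speed."""
    return [RunSpec(geometry=g, orientation=o, inlet_velocity=U, seed=seed,
                    scale=scale, spacing_h=spacing_h)
            for g in ("idealized", "empirical")
            for o in (geo.ROSTRAL, geo.CAUDAL)
            for U in INLET_SPEEDS]


def evaluate_hypothesis(rostral: post.FieldMetrics,
                        caudal: post.FieldMetrics) -> str:
    """Pairwise decision: is rostral-specific recirculation present?

    hypothesis_rejected  -- both orientations recirculate in >=90% of the
                            interior gaps and their peak-metric orders of
                            magnitude match (the null model survives);
    hypothesis_supported -- rostral covers >=90% of gaps while caudal
                            covers <=10%;
    inconclusive         -- anything else, including unconverged runs.
    """
    if rostral.n_gaps != caudal.n_gaps:
        raise ValueError("paired runs must share the trimmed gap count")
    if not (rostral.converged and caudal.converged):
        return INCONCLUSIVE
    cov_r = rostral.n_gaps_recirculating / rostral.n_gaps
    cov_c = caudal.n_gaps_recirculating / caudal.n_gaps
    ooms_match = (rostral.velocity_oom == caudal.velocity_oom
                  and rostral.vorticity_oom == caudal.vorticity_oom)
    if cov_r >= 0.9 and cov_c >= 0.9 and ooms_match:
        return REJECTED
    if cov_r >= 0.9 and cov_c <= 0.1:
        return SUPPORTED
    return INCONCLUSIVE


def overall_verdict(pair_verdicts: dict) -> str | None:
    if not pair_verdicts:
        return None
    verdicts = set(pair_verdicts.values())
    if verdicts == {REJECTED}:
        return REJECTED
    if verdicts == {SUPPORTED}:
        return SUPPORTED
    return INCONCLUSIVE


def run_experiment(specs: list[RunSpec],
                   fluid: FluidProps | None = None) -> ExperimentReport:
    """Execute geometry -> solve -> postprocess for each spec and apply the
    decision rule to every (geometry, inlet speed) orientation pair."""
    report = ExperimentReport()
    for spec in specs:
        report.runs.append(run_single(spec, fluid))
    by_key: dict = {}
    for r in report.runs:
        key = (r.spec.geometry, r.spec.inlet_velocity)
        by_key.setdefault(key, {})[r.spec.orientation] = r.metrics
    for key, pair in by_key.items():
        if geo.ROSTRAL in pair and geo.CAUDAL in pair:
            report.pair_verdicts[key] = evaluate_hypothesis(
                pair[geo.ROSTRAL], pair[geo.CAUDAL])
    report.overall_verdict = overall_verdict(report.pair_verdicts)
    return report


def assess_drag_sequence(values, drags,
                         tol: float = INDEPENDENCE_TOL) -> tuple[list, bool]:
    """Successive relative drag changes and the <=5% pass flag; invariant
    under rescaling all drags by a constant."""
    drags = list(drags)
    if len(drags) < 2:
        raise ValueError("need at least two drag values")
    changes = [abs(b - a) / abs(a) for a, b in zip(drags[:-1], drags[1:])]
    # inclusive bound, guarded against float round-off at the boundary
    return changes, all(c <= tol * (1 + 1e-9) for c in changes)


def independence_test(base: RunSpec, parameter: str, values,
                      fluid: FluidProps | None = None) -> IndependenceReport:
    """Solve once per parameter value and apply the 5% drag criterion.

    ``parameter`` is one of spacing_h (refinement, decreasing) or
    downstream_factor / upstream_factor / height (extension, increasing).
    """
    values = list(values)
    if len(values) < 2:
        raise ValueError("need at least two parameter values")
    diffs = np.diff(values)
    if parameter == "spacing_h":
        if not np.all(diffs < 0):
            raise ValueError("grid refinement values must decrease")
    elif parameter in ("downstream_factor", "upstream_factor", "height"):
        if not np.all(diffs > 0):
            raise ValueError("domain extension values must increase")
    else:
        raise ValueError(f"unknown independence parameter {parameter!r}")

    drags = []
    for val in values:
        if parameter == "spacing_h":
            spec = dc_replace(base, spacing_h=float(val))
            res = run_single(spec, fluid)
        else:
            s = ScaleSettings.get(base.scale)
            profile, _, _ = build_geometry(base)
            kwargs = dict(height=s.height,
                          upstream_factor=s.upstream_factor,
                          downstream_factor=s.downstream_factor)
            kwargs[parameter] = float(val)
            domain = geo.build_domain(profile, **kwargs)
            mask = geo.rasterize_graded(profile, domain, base.spacing_h)
            cfg = SolverConfig(inlet_velocity_U=base.inlet_velocity,
                               spacing_h=base.spacing_h)
            for name, value in base.solver_overrides:
                setattr(cfg, name, value)
            sol = solve_steady(mask, domain, fluid or FluidProps(), cfg)
            res = type("R", (), {"solution": sol})()
        drags.append(res.solution.drag_force_Fd)
        log.info("independence %s=%g -> drag %.5g", parameter, val, drags[-1])
    changes, passed = assess_drag_sequence(values, drags)
    return IndependenceReport(parameter=parameter, values=values, drags=drags,
                              successive_changes=changes, passed=passed)
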