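"""Named, fully resolved experiment configurations and their runners.

Every figure-level experiment of the study regime (trajectories and phase
portraits at selected orders, bifurcation diagrams over the commensurate
order / single-equation orders / growth rates, Lyapunov-exponent curves,
equilibrium reports) maps to an :class:`ExperimentConfig` with no unset
fields.  Outputs are data first (CSV + JSON with a manifest); plots are
regenerated from the data, never pixel-matched.

Sweeps run at a documented desk-scale resolution (h = 0.02, t_end = 150 for
wide grids; h = 0.01, t_end = 300 for exemplar runs, the scan defaults), and
the manifest records the settings of every artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .model import ModelParams
from .solver import (
    DivergenceError,
    FractionalOrders,
    SolverSettings,
    Trajectory,
    corrector_weights,
    integrate,
    integrate_integer_reference,
    predictor_weights,
)
from .equilibria import (
    closed_form_equilibria,
    find_coexistence_equilibrium,
    stability_report,
    write_stability_json,
)
from .chaos import (
    LyapunovSettings,
    ScanSpec,
    bifurcation_scan,
    largest_lyapunov,
)

__all__ = [
    "ExperimentConfig",
    "EXPERIMENTS",
    "available_experiments",
    "run_experiment",
    "generate_fixtures",
    "config_from_yaml",
]

PRINTED_PARAMS = ModelParams(a=0.7455, b=0.7367, c=0.5619)
PRINTED_IC = (0.4, 0.5, 0.5)

_RUN = SolverSettings(h=0.01, t_end=300.0)   # exemplar single runs
_SWEEP = SolverSettings(h=0.02, t_end=150.0)  # wide grids, scaled resolution


@dataclass(frozen=True)
class ExperimentConfig:
    """A fully resolved experiment: what to run and with which settings."""

    id: str
    kind: str  # trajectory_panels | scan | lyapunov_curve | equilibria | integer_reference
    description: str
    params: ModelParams = PRINTED_PARAMS
    ic: tuple = PRINTED_IC
    settings: SolverSettings = _RUN
    # trajectory panels: list of (label, FractionalOrders, optional param override)
    panels: tuple = ()
    # scans
    swept: Optional[str] = None
    grid_start: Optional[float] = None
    grid_stop: Optional[float] = None
    grid_step: Optional[float] = None
    orders: FractionalOrders = FractionalOrders(1.0, 1.0, 1.0)
    lyapunov: str = "auto"
    transient_fraction: float = 0.6
    scaled: bool = True  # resolution reduced relative to a print-quality figure

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step))
        return np.round(
            self.grid_start + self.grid_step * np.arange(n + 1), 10
        )

    def to_dict(self) -> dict:
        d = {
            "id": self.id,
            "kind": self.kind,
            "description": self.description,
            "params": {"a": self.params.a, "b": self.params.b, "c": self.params.c},
            "ic": list(self.ic),
            "settings": self.settings.to_dict(),
            "scaled": self.scaled,
        }
        if self.kind == "scan":
            d.update(
                swept=self.swept,
                grid={"start": self.grid_start, "stop": self.grid_stop,
                      "step": self.grid_step},
                orders={"q1": self.orders.q1, "q2": self.orders.q2,
                        "q3": self.orders.q3},
                lyapunov=self.lyapunov,
                transient_fraction=self.transient_fraction,
            )
        if self.panels:
            d["panels"] = [
                {"label": lab, "orders": {"q1": o.q1, "q2": o.q2, "q3": o.q3},
                 "params": {"a": p.a, "b": p.b, "c": p.c}}
                for (lab, o, p) in self.panels
            ]
        return d


def _panel(label: str, orders: FractionalOrders,
           params: ModelParams = PRINTED_PARAMS):
    return (label, orders, params)


def _cq(q: float) -> FractionalOrders:
    return FractionalOrders.commensurate_order(q)


def _build_registry() -> dict[str, ExperimentConfig]:
    exps = [
        ExperimentConfig(
            id="fig1_integer_attractor",
            kind="integer_reference",
            description="Integer-order (q=1) attractor from the canonical "
                        "initial condition, reference integrator.",
            settings=SolverSettings(h=0.01, t_end=500.0),
        ),
        ExperimentConfig(
            id="equilibria_report",
            kind="equilibria",
            description="All five equilibria with eigenvalues, Matignon "
                        "margins and the chaos-threshold order q*.",
        ),
        ExperimentConfig(
            id="fig3_commensurate_q_scan",
            kind="scan",
            description="Bifurcation diagram over the commensurate order "
                        "q in (0.94, 1).",
            swept="q", grid_start=0.942, grid_stop=0.998, grid_step=0.004,
            settings=_SWEEP,
        ),
        ExperimentConfig(
            id="fig4_lle_commensurate",
            kind="lyapunov_curve",
            description="Largest Lyapunov exponent over q in (0.99, 1).",
            swept="q", grid_start=0.990, grid_stop=0.998, grid_step=0.002,
            settings=_RUN,
        ),
        ExperimentConfig(
            id="fig5_panels",
            kind="trajectory_panels",
            description="Time series and x-y phase portraits across the "
                        "stable / periodic / chaotic windows of q.",
            panels=tuple(
                _panel(f"q{q}", _cq(q)) for q in (0.95, 0.962, 0.97, 0.98, 0.995, 1.0)
            ),
        ),
        ExperimentConfig(
            id="fig6_chaotic_attractor",
            kind="trajectory_panels",
            description="3-D attractor at q = 0.995.",
            panels=(_panel("q0.995", _cq(0.995)),),
        ),
        ExperimentConfig(
            id="fig7_b_scan",
            kind="scan",
            description="Bifurcation diagram over the host growth rate b "
                        "at q = 0.99.",
            swept="b", grid_start=0.05, grid_stop=0.95, grid_step=0.03,
            orders=_cq(0.99), settings=_SWEEP,
        ),
        ExperimentConfig(
            id="fig8_panels",
            kind="trajectory_panels",
            description="Exemplar runs along the b route to chaos at q = 0.99.",
            panels=tuple(
                _panel(f"b{b}", _cq(0.99), PRINTED_PARAMS.replace(b=b))
                for b in (0.28, 0.35, 0.45, 0.53)
            ),
        ),
        ExperimentConfig(
            id="fig9_a_scan",
            kind="scan",
            description="Bifurcation diagram over the tumor growth rate a "
                        "at q = 0.99.",
            swept="a", grid_start=0.05, grid_stop=0.95, grid_step=0.03,
            orders=_cq(0.99), settings=_SWEEP,
        ),
        ExperimentConfig(
            id="fig9_c_scan",
            kind="scan",
            description="Bifurcation diagram over the effector growth rate c "
                        "at q = 0.99.",
            swept="c", grid_start=0.05, grid_stop=0.95, grid_step=0.03,
            orders=_cq(0.99), settings=_SWEEP,
        ),
        ExperimentConfig(
            id="fig10_order_comparison",
            kind="trajectory_panels",
            description="Integer vs commensurate fractional dynamics of the "
                        "tumor population.",
            panels=tuple(
                _panel(f"q{q}", _cq(q)) for q in (0.90, 0.95, 0.99, 1.0)
            ),
        ),
        ExperimentConfig(
            id="fig11_q1_scan",
            kind="scan",
            description="Incommensurate bifurcation diagram over q1 "
                        "(q2 = q3 = 1).",
            swept="q1", grid_start=0.60, grid_stop=0.98, grid_step=0.02,
            settings=_SWEEP,
        ),
        ExperimentConfig(
            id="fig11_q2_scan",
            kind="scan",
            description="Incommensurate bifurcation diagram over q2 "
                        "(q1 = q3 = 1).",
            swept="q2", grid_start=0.60, grid_stop=0.98, grid_step=0.02,
            settings=_SWEEP,
        ),
        ExperimentConfig(
            id="fig11_q3_scan",
            kind="scan",
            description="Incommensurate bifurcation diagram over q3 "
                        "(q1 = q2 = 1).",
            swept="q3", grid_start=0.60, grid_stop=0.98, grid_step=0.02,
            settings=_SWEEP,
        ),
        ExperimentConfig(
            id="fig12_panels",
            kind="trajectory_panels",
            description="Incommensurate attractors with one order at 0.999.",
            panels=(
                _panel("q1_0.999", FractionalOrders(0.999, 1.0, 1.0)),
                _panel("q2_0.999", FractionalOrders(1.0, 0.999, 1.0)),
                _panel("q3_0.999", FractionalOrders(1.0, 1.0, 0.999)),
            ),
        ),
        ExperimentConfig(
            id="fig13_b_scan_incommensurate",
            kind="scan",
            description="Bifurcation over b with q1 = 0.999, q2 = q3 = 1.",
            swept="b", grid_start=0.05, grid_stop=0.95, grid_step=0.03,
            orders=FractionalOrders(0.999, 1.0, 1.0), settings=_SWEEP,
        ),
        ExperimentConfig(
            id="fig14_attractors_b038",
            kind="trajectory_panels",
            description="Incommensurate attractors at b = 0.38.",
            panels=tuple(
                _panel(lab, o, PRINTED_PARAMS.replace(b=0.38))
                for lab, o in (
                    ("q1_0.999", FractionalOrders(0.999, 1.0, 1.0)),
                    ("q2_0.999", FractionalOrders(1.0, 0.999, 1.0)),
                    ("q3_0.999", FractionalOrders(1.0, 1.0, 0.999)),
                )
            ),
        ),
        ExperimentConfig(
            id="fig15_b_comparison",
            kind="trajectory_panels",
            description="Stable (b = 0.1) vs chaotic-range (b = 0.5) dynamics "
                        "across commensurate orders.",
            panels=tuple(
                _panel(f"b{b}_q{q}", _cq(q), PRINTED_PARAMS.replace(b=b))
                for b in (0.1, 0.5)
                for q in (0.60, 0.80, 0.995, 1.0)
            ),
        ),
    ]
    return {e.id: e for e in exps}


EXPERIMENTS: dict[str, ExperimentConfig] = _build_registry()


def available_experiments() -> list[str]:
    return sorted(EXPERIMENTS)


class UnknownExperiment(KeyError):
    def __init__(self, exp_id: str):
        ids = ", ".join(available_experiments())
        super().__init__(f"unknown experiment {exp_id!r}; available: {ids}")


def config_from_yaml(path) -> ExperimentConfig:
    """Load a custom experiment config from YAML (documented in the README).

    Required keys mirror :class:`ExperimentConfig`; a missing solver field is
    a validation error naming the field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    for req in ("id", "kind", "settings"):
        if req not in raw:
            raise ValueError(f"config is missing required field {req!r}")
    for req in ("h", "t_end"):
        if req not in raw["settings"]:
            raise ValueError(f"config settings are missing required field {req!r}")
    settings = SolverSettings(
        h=float(raw["settings"]["h"]),
        t_end=float(raw["settings"]["t_end"]),
        memory=raw["settings"].get("memory"),
    )
    p = raw.get("params", {})
    params = ModelParams(
        a=float(p.get("a", PRINTED_PARAMS.a)),
        b=float(p.get("b", PRINTED_PARAMS.b)),
        c=float(p.get("c", PRINTED_PARAMS.c)),
    )
    o = raw.get("orders", {"q1": 1.0, "q2": 1.0, "q3": 1.0})
    orders = FractionalOrders(float(o["q1"]), float(o["q2"]), float(o["q3"]))
    kw = dict(
        id=str(raw["id"]),
        kind=str(raw["kind"]),
        description=str(raw.get("description", "user config")),
        params=params,
        ic=tuple(raw.get("ic", PRINTED_IC)),
        settings=settings,
        orders=orders,
    )
    if raw["kind"] == "scan":
        for req in ("swept", "grid_start", "grid_stop", "grid_step"):
            if req not in raw:
                raise ValueError(f"scan config is missing required field {req!r}")
        kw.update(
            swept=raw["swept"],
            grid_start=float(raw["grid_start"]),
            grid_stop=float(raw["grid_stop"]),
            grid_step=float(raw["grid_step"]),
            lyapunov=raw.get("lyapunov", "auto"),
        )
    elif raw["kind"] == "trajectory_panels":
        panels = []
        for pan in raw.get("panels", []):
            po = pan.get("orders", o)
            pp = pan.get("params", {})
            panels.append(
                _panel(
                    str(pan["label"]),
                    FractionalOrders(float(po["q1"]), float(po["q2"]),
                                     float(po["q3"])),
                    ModelParams(
                        a=float(pp.get("a", params.a)),
                        b=float(pp.get("b", params.b)),
                        c=float(pp.get("c", params.c)),
                    ),
                )
            )
        if not panels:
            raise ValueError("trajectory_panels config needs at least one panel")
        kw["panels"] = tuple(panels)
    return ExperimentConfig(**kw)


def _plot_trajectory(traj: Trajectory, png_path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
    ax1.plot(traj.times, traj.x, "r-", lw=0.6, label="tumor x")
    ax1.plot(traj.times, traj.y, "b-", lw=0.6, label="host y")
    ax1.plot(traj.times, traj.z, "g-", lw=0.6, label="effector z")
    ax1.set_xlabel("t")
    ax1.legend(fontsize=7)
    ax2.plot(traj.x, traj.y, "k-", lw=0.4)
    ax2.set_xlabel("x")
    ax2.set_ylabel("y")
    fig.suptitle(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(png_path, dpi=110)
    plt.close(fig)


def _plot_scan(result, png_path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    for p in result.points:
        if p.extrema is not None and p.extrema.size:
            ax.plot([p.value] * p.extrema.size, p.extrema, "k.", ms=1.5)
        elif p.final_state is not None:
            ax.plot([p.value], [p.final_state[0]], "b.", ms=2)
    ax.set_xlabel(result.spec.swept)
    ax.set_ylabel(f"post-transient maxima of {result.spec.variable}")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(png_path, dpi=110)
    plt.close(fig)


def _plot_lle_curve(values, lles, swept, png_path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(values, lles, "ko-", ms=3)
    ax.axhline(0.0, color="r", lw=0.6)
    ax.set_xlabel(swept)
    ax.set_ylabel("largest Lyapunov exponent")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(png_path, dpi=110)
    plt.close(fig)


def run_experiment(
    config: ExperimentConfig | str,
    outdir,
    make_plots: bool = True,
    seed: int = 0,
) -> dict:
    """Run one experiment; writes CSV/JSON (+ PNG) artifacts and a manifest.

    Deterministic for a fixed config and seed.  Returns the manifest dict.
    """
    if isinstance(config, str):
        if config not in EXPERIMENTS:
            raise UnknownExperiment(config)
        config = EXPERIMENTS[config]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def note(path: Path) -> Path:
        artifacts.append(path.name)
        return path

    if config.kind in ("trajectory_panels", "integer_reference"):
        panels = config.panels or ((config.id, FractionalOrders(1, 1, 1),
                                    config.params),)
        for label, orders, params in panels:
            if config.kind == "integer_reference":
                traj = integrate_integer_reference(params, config.ic,
                                                   config.settings)
            else:
                traj = integrate(params, orders, config.ic, config.settings)
            csv = note(outdir / f"{config.id}_{label}.csv")
            traj.write_csv(csv)
            artifacts.append(csv.name + ".json")
            if make_plots:
                _plot_trajectory(traj, note(outdir / f"{config.id}_{label}.png"),
                                 f"{config.id} {label}")
    elif config.kind == "equilibria":
        eqs = closed_form_equilibria(config.params)
        e4 = find_coexistence_equilibrium(config.params)
        reports = [stability_report(e, config.params) for e in eqs + [e4]]
        write_stability_json(
            reports, note(outdir / f"{config.id}.json"),
            extra={"params": {"a": config.params.a, "b": config.params.b,
                              "c": config.params.c}},
        )
    elif config.kind == "scan":
        spec = ScanSpec(
            swept=config.swept,
            grid=config.grid(),
            params=config.params,
            orders=config.orders,
            ic=config.ic,
            settings=config.settings,
            transient_fraction=config.transient_fraction,
            lyapunov=config.lyapunov,
            lyap_settings=LyapunovSettings(seed=seed),
        )
        result = bifurcation_scan(spec)
        result.write(note(outdir / f"{config.id}.csv"),
                     note(outdir / f"{config.id}.json"))
        if make_plots:
            _plot_scan(result, note(outdir / f"{config.id}.png"),
                       config.description)
    elif config.kind == "lyapunov_curve":
        values, lles = [], []
        for v in config.grid():
            params, orders = config.params, _cq(float(v))
            try:
                r = largest_lyapunov(params, orders, config.ic, config.settings,
                                     LyapunovSettings(seed=seed))
                values.append(float(v))
                lles.append(r.lle)
            except DivergenceError:
                continue
        payload = [{"q": v, "lle": l} for v, l in zip(values, lles)]
        note(outdir / f"{config.id}.json").write_text(
            json.dumps(payload, indent=2) + "\n")
        if make_plots:
            _plot_lle_curve(values, lles, "q",
                            note(outdir / f"{config.id}.png"),
                            config.description)
    else:
        raise ValueError(f"unknown experiment kind {config.kind!r}")

    manifest = {
        "experiment": config.to_dict(),
        "package_version": __version__,
        "seed": seed,
        "artifacts": sorted(set(artifacts)),
    }
    (outdir / f"{config.id}_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n")
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixtures(outdir, seed: int = 0) -> dict:
    """Emit a small reference bundle (weight tables, short trajectories).

    Bit-identical for a fixed seed and settings; the manifest lists every
    file with its checksum.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    import pandas as pd

    w = corrector_weights(0.5, 10)
    pd.DataFrame({"j": np.arange(w.size), "eta": w}).to_csv(
        outdir / "corrector_weights_q0.5_n10.csv", index=False,
        float_format="%.17g")
    wp = predictor_weights(0.5, 0.04, 10)
    pd.DataFrame({"j": np.arange(wp.size), "omega": wp}).to_csv(
        outdir / "predictor_weights_q0.5_h0.04_n10.csv", index=False,
        float_format="%.17g")

    short = SolverSettings(h=0.01, t_end=20.0)  # 2000 steps
    t1 = integrate(PRINTED_PARAMS, FractionalOrders(1, 1, 1), PRINTED_IC, short)
    t1.write_csv(outdir / "trajectory_q1_short.csv")
    ref = integrate_integer_reference(PRINTED_PARAMS, PRINTED_IC, short)
    ref.write_csv(outdir / "trajectory_reference_short.csv")
    t09 = integrate(PRINTED_PARAMS, FractionalOrders.commensurate_order(0.9),
                    PRINTED_IC, short)
    t09.write_csv(outdir / "trajectory_q0.9_short.csv")

    files = sorted(p.name for p in outdir.iterdir()
                   if p.name != "fixtures_manifest.json")
    manifest = {
        "seed": seed,
        "package_version": __version__,
        "files": {name: _sha256(outdir / name) for name in files},
    }
    (outdir / "fixtures_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n")
    return manifest
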