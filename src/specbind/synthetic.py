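"""Seeded synthetic-data generators with known ground truth.

Each generator forward-evaluates the same model family the analysis chain
fits — the one-set-of-sites isotherm with mass balance, a static
Stern–Volmer/double-log quenching model, the two-state melt sigmoid, and
the integrated first/second-order rate laws — adds configured noise, and
returns the data object together with a ``truth`` record holding every
generating parameter.  Round-trip tests read the truth only from that
record.

Default designs emulate the study conditions the package targets: a
10-point 4–40 μM titrant series against 15 μM protein at 300 K, a
0–210 μM quencher series, a 25–65 °C melt scan in 1 °C steps, and a
61-point 1-h kinetic trace sampled once a minute.  Default noise is 0.5%
multiplicative for absorbance signals and additive with σ = 1% of F0 for
fluorescence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .core import BindingParameters, EndpointPair, SignalKind, TitrationSeries, solve_mass_balance
from .kinetics import KineticTrace
from .melt import MeltTrace
from .quenching import DEFAULT_TAU0, QuenchSeries

DESIGNS = ("uv_titration", "quench_titration", "melt", "kinetic")


@dataclass(frozen=True)
class NoiseSpec:
    """``additive_gaussian`` adds N(0, sigma) in signal units;
    ``multiplicative`` scales each reading by N(1, sigma)."""

    kind: str = "additive_gaussian"
    sigma: float = 0.0

    def __post_init__(self):
        if self.kind not in ("additive_gaussian", "multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, rng: np.random.Generator, values: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return values.copy()
        if self.kind == "additive_gaussian":
            return values + rng.normal(0.0, self.sigma, size=values.shape)
        return values * rng.normal(1.0, self.sigma, size=values.shape)


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully specified synthetic scenario; the seed fixes every byte."""

    seed: int
    design: str
    truth: dict
    grid: tuple  # concentrations (M), temperatures (K) or times (s)
    noise: NoiseSpec = NoiseSpec()
    protein_total: float = 15e-6
    temperature: float = 300.0
    endpoints: Optional[EndpointPair] = None

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; one of {DESIGNS}")
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))


def default_config(design: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Study-condition defaults for each design (see module docstring)."""
    if design == "uv_titration":
        base = dict(
            seed=seed,
            design=design,
            truth={"K_b": 6778.0, "K_H": 6778.0, "n_H": 1.0, "g": 1.0},
            grid=(0.0,) + tuple(np.linspace(4e-6, 40e-6, 10)),
            noise=NoiseSpec("multiplicative", 0.005),
            protein_total=15e-6,
            temperature=300.0,
            endpoints=EndpointPair(A0=0.90, A_inf=0.60),
        )
    elif design == "quench_titration":
        base = dict(
            seed=seed,
            design=design,
            truth={"model": "sv", "K_sv": 1e4, "K_a": 0.0, "F0": 100.0, "tau0": DEFAULT_TAU0},
            grid=(0.0,) + tuple(np.linspace(15e-6, 210e-6, 14)),
            noise=NoiseSpec("additive_gaussian", 1.0),  # 1% of F0 = 100
            temperature=300.0,
        )
    elif design == "melt":
        base = dict(
            seed=seed,
            design=design,
            truth={"T_m": 47.0 + 273.15, "width": 2.0},
            grid=tuple(273.15 + np.arange(25.0, 66.0, 1.0)),
            noise=NoiseSpec("multiplicative", 0.005),
            endpoints=EndpointPair(A0=0.60, A_inf=1.00),  # pre/post baselines
        )
    elif design == "kinetic":
        base = dict(
            seed=seed,
            design=design,
            truth={"order": "second", "rate": 0.005},  # a*k, AU^-1 s^-1
            grid=tuple(np.linspace(0.0, 3600.0, 61)),
            noise=NoiseSpec("multiplicative", 0.005),
            endpoints=EndpointPair(A0=0.50, A_inf=0.80),
        )
    else:
        raise ValueError(f"unknown design {design!r}")
    base.update(overrides)
    return ScenarioConfig(**base)


def _truth_record(cfg: ScenarioConfig, extra: dict = None) -> dict:
    rec = {
        "design": cfg.design,
        "seed": cfg.seed,
        "truth": dict(cfg.truth),
        "noise": dataclasses.asdict(cfg.noise),
        "protein_total_M": cfg.protein_total,
        "temperature_K": cfg.temperature,
    }
    if cfg.endpoints is not None:
        rec["endpoints"] = {"A0": cfg.endpoints.A0, "A_inf": cfg.endpoints.A_inf}
    if extra:
        rec.update(extra)
    return rec


def gen_uv_titration(cfg: ScenarioConfig) -> tuple:
    """UV titration from the binding model with full mass balance.

    Per grid point the mass balance is solved for the free ligand, the
    fractional saturation α = ν/g maps linearly onto the signal between
    the endpoints, and noise is applied.  Returns ``(series, truth)``.
    """
    if cfg.design != "uv_titration":
        raise ValueError("config design must be 'uv_titration'")
    rng = np.random.default_rng(cfg.seed)
    t = cfg.truth
    params = BindingParameters(K_b=t["K_b"], g=t["g"], n_H=t["n_H"], K_H=t["K_H"])
    ep = cfg.endpoints
    clean = np.empty(len(cfg.grid))
    for i, L in enumerate(cfg.grid):
        _, nu = solve_mass_balance(L, cfg.protein_total, params)
        alpha = nu / params.g
        clean[i] = ep.A0 + alpha * ep.amplitude
    noisy = np.maximum(cfg.noise.apply(rng, clean), 0.0)
    series = TitrationSeries(
        protein_total=cfg.protein_total,
        ligand_total=tuple(cfg.grid),
        signal=tuple(noisy),
        temperature=cfg.temperature,
        signal_kind=SignalKind.ABSORBANCE,
    )
    return series, _truth_record(cfg)


def gen_quench_titration(cfg: ScenarioConfig) -> tuple:
    """Quenching titration; returns ``(series, truth)``.

    ``truth["model"]`` selects the forward model: ``"sv"`` uses the
    combined static/dynamic product F0/F = (1 + K_sv Q)(1 + K_a Q) (K_a = 0
    gives a purely linear Stern–Volmer series); ``"double_log"`` uses
    (F0 − F)/F = K_b Q^n.
    """
    if cfg.design != "quench_titration":
        raise ValueError("config design must be 'quench_titration'")
    rng = np.random.default_rng(cfg.seed)
    t = cfg.truth
    Q = np.asarray(cfg.grid)
    F0 = float(t.get("F0", 100.0))
    model = t.get("model", "sv")
    if model == "sv":
        ratio = (1.0 + t["K_sv"] * Q) * (1.0 + t.get("K_a", 0.0) * Q)
    elif model == "double_log":
        ratio = 1.0 + t["K_b"] * Q ** t["n"]
    else:
        raise ValueError(f"unknown quench model {model!r}")
    clean = F0 / ratio
    noisy = np.maximum(cfg.noise.apply(rng, clean), 1e-6 * F0)
    F0_obs = float(noisy[0]) if Q[0] == 0 else F0
    series = QuenchSeries(
        Q=tuple(Q),
        F=tuple(noisy),
        F0=F0_obs,
        tau0=float(t.get("tau0", DEFAULT_TAU0)),
    )
    return series, _truth_record(cfg, {"F0_observed": F0_obs})


def gen_melt(cfg: ScenarioConfig) -> tuple:
    """Two-state melting trace; ``truth`` holds T_m and width in kelvin."""
    if cfg.design != "melt":
        raise ValueError("config design must be 'melt'")
    rng = np.random.default_rng(cfg.seed)
    T = np.asarray(cfg.grid)
    ep = cfg.endpoints
    clean = ep.A0 + ep.amplitude / (1.0 + np.exp((cfg.truth["T_m"] - T) / cfg.truth["width"]))
    noisy = cfg.noise.apply(rng, clean)
    trace = MeltTrace(temperature=tuple(T), signal=tuple(noisy), label=str(cfg.truth.get("label", "")))
    return trace, _truth_record(cfg)


def gen_kinetic(cfg: ScenarioConfig) -> tuple:
    """Kinetic trace from the integrated rate law named in ``truth["order"]``."""
    if cfg.design != "kinetic":
        raise ValueError("config design must be 'kinetic'")
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.grid)
    ep = cfg.endpoints
    rate = cfg.truth["rate"]
    d0 = ep.A_inf - ep.A0
    if cfg.truth["order"] == "first":
        clean = ep.A_inf - d0 * np.exp(-rate * t)
    elif cfg.truth["order"] == "second":
        clean = ep.A_inf - np.sign(d0) / (1.0 / abs(d0) + rate * t)
    else:
        raise ValueError(f"unknown kinetic order {cfg.truth['order']!r}")
    noisy = cfg.noise.apply(rng, clean)
    trace = KineticTrace(time=tuple(t), signal=tuple(noisy), A0=ep.A0, A_inf=ep.A_inf)
    return trace, _truth_record(cfg)


GENERATORS = {
    "uv_titration": gen_uv_titration,
    "quench_titration": gen_quench_titration,
    "melt": gen_melt,
    "kinetic": gen_kinetic,
}


def generate(cfg: ScenarioConfig) -> tuple:
    """Dispatch to the generator for ``cfg.design``."""
    return GENERATORS[cfg.design](cfg)


def write_scenario(cfg: ScenarioConfig, outdir) -> dict:
    """Generate a scenario and write it as delimited text plus truth.json.

    Returns a mapping of logical names to the paths written.  The data
    files use the same column dialects the readers in :mod:`specbind.io`
    accept.
    """
    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obj, truth = generate(cfg)
    paths = {}
    if cfg.design == "uv_titration":
        data_path = outdir / "titration.tsv"
        sio.write_titration(data_path, obj)
    elif cfg.design == "quench_titration":
        data_path = outdir / "quench.tsv"
        sio.write_quench(data_path, obj)
    elif cfg.design == "melt":
        data_path = outdir / "melt.tsv"
        sio.write_melt(data_path, obj)
    else:
        data_path = outdir / "kinetic.tsv"
        sio.write_kinetic(data_path, obj)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    paths["data"] = data_path
    paths["truth"] = truth_path
    return paths
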