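"""End-to-end study driver: read configured traces, run every configured
analysis stage, and assemble a structured report.

The configuration is a single JSON document; every stage key is optional
and only configured stages run, so partial reports are allowed::

    {
      "isotherm": {
        "protein_total_M": 1.5e-05,
        "g": 1.0,
        "noise_floor_AU": 0.0,
        "traces": [
          {"path": "titration_300K.tsv", "temperature_K": 300.0},
          {"path": "titration_310K.tsv", "temperature_K": 310.0}
        ]
      },
      "melt": {"free": "melt_free.tsv", "bound": "melt_bound.tsv"},
      "kinetics": {"path": "kinetic.tsv"},
      "quench": {"path": "quench.tsv", "tau0_s": 1e-08}
    }

Numeric report fields carry their units in the key name
(``K_b_per_M``, ``delta_H_kJ_per_mol`` ...) so the JSON is self-describing
and round-trips losslessly.  For fixed inputs the report is deterministic:
no analysis stage draws random numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io as sio
from .cooperativity import BindingPoint, capacity_diagnostic, hill_fit, scatchard
from .core import BindingParameters, classify_driving_force
from .isotherm import double_reciprocal_fit, fractional_saturation, thermo_table
from .kinetics import select_order
from .melt import fit_two_state_melt
from .quenching import DEFAULT_TAU0, analyze_quench

logger = logging.getLogger(__name__)


@dataclass
class StudyReport:
    """Structured result of :func:`run_study`; serializes to JSON losslessly."""

    isotherm: Optional[list] = None
    thermodynamics: Optional[dict] = None
    cooperativity: Optional[list] = None
    melt: Optional[dict] = None
    kinetics: Optional[dict] = None
    quench: Optional[dict] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        return cls(**json.loads(text))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve(base: Path, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p


def _binding_points(series, endpoints, g):
    """Model-free binding points: nu from the signal, L_free by conservation."""
    alpha = fractional_saturation(series, endpoints)
    points = []
    for L, a in zip(series.ligand_total, alpha):
        nu = float(a * g)
        L_free = max(L - nu * series.protein_total, 0.0)
        points.append(BindingPoint(nu=nu, L_free=L_free))
    return points


def _isotherm_stage(cfg: dict, base: Path, inputs: dict):
    protein_total = float(cfg["protein_total_M"])
    g = float(cfg.get("g", 1.0))
    noise_floor = float(cfg.get("noise_floor_AU", 0.0))
    results = []
    blocks = []
    coop_blocks = []
    for spec in cfg["traces"]:
        path = _resolve(base, spec["path"])
        inputs[str(path)] = _sha256(path)
        series = sio.read_titration(
            path, protein_total=protein_total, temperature=float(spec["temperature_K"])
        )
        res = double_reciprocal_fit(series, noise_floor=noise_floor)
        results.append(res)
        blocks.append(
            {
                "temperature_K": res.temperature,
                "K_b_per_M": res.K_b,
                "A0_AU": res.endpoints.A0,
                "A_inf_AU": res.endpoints.A_inf,
                "L_half_M": res.L_half,
                "L_half_extrapolated": res.L_half_extrapolated,
                "r_squared": res.fit.r_squared,
                "n_points": res.fit.n_points,
            }
        )
        # cooperativity analysis on the model-free binding points
        points = _binding_points(series, res.endpoints, g)
        try:
            hill = hill_fit(points, g=g)
        except ValueError as exc:
            logger.info("hill fit skipped at %s K: %s", res.temperature, exc)
            continue
        _, scat_class = scatchard([p for p in points if p.L_free > 0 and p.nu > 0])
        params = BindingParameters(K_b=res.K_b, g=g, n_H=hill.n_H, K_H=hill.K_H)
        cap = capacity_diagnostic(
            [p for p in points if 0 < p.nu < g], params, series.temperature
        )
        coop_blocks.append(
            {
                "temperature_K": res.temperature,
                "n_H": hill.n_H,
                "K_H_per_M_pow_nH": hill.K_H,
                "g": hill.g,
                "hill_r_squared": hill.fit.r_squared,
                "hill_cooperativity": hill.cooperativity.value,
                "scatchard_classification": scat_class.value,
                "capacity_single_set": cap.single_set,
                "capacity_r_squared": cap.fit.r_squared,
            }
        )
    thermo_block = None
    if len(results) >= 2:
        t1, t2 = thermo_table(results[0], results[1])
        thermo_block = {
            "rows": [
                {
                    "T_K": r.T,
                    "delta_G_kJ_per_mol": r.delta_G,
                    "delta_H_kJ_per_mol": r.delta_H,
                    "delta_S_J_per_mol_K": r.delta_S,
                    "source_Kb_per_M": r.source_Kb,
                }
                for r in (t1, t2)
            ],
            "driving_force": classify_driving_force(t1.delta_H, t1.delta_S).value,
        }
    return blocks, thermo_block, coop_blocks or None


def _melt_stage(cfg: dict, base: Path, inputs: dict) -> dict:
    block = {}
    fits = {}
    for role in ("free", "bound"):
        if role not in cfg:
            continue
        path = _resolve(base, cfg[role])
        inputs[str(path)] = _sha256(path)
        trace = sio.read_melt(path, label=role)
        fit = fit_two_state_melt(trace)
        fits[role] = fit
        block[role] = {
            "T_m_K": fit.T_m,
            "T_m_C": fit.T_m_celsius,
            "width_K": fit.width,
            "baseline_pre_AU": fit.baseline_pre,
            "baseline_post_AU": fit.baseline_post,
            "fit_quality_r_squared": fit.fit_quality,
            "midpoint_model_free_K": fit.midpoint_model_free,
        }
    if "free" in fits and "bound" in fits:
        delta = fits["bound"].T_m - fits["free"].T_m
        block["delta_Tm_K"] = delta
        block["verdict"] = (
            "stabilizing" if delta > 0 else "destabilizing" if delta < 0 else "neutral"
        )
    return block


def _kinetics_stage(cfg: dict, base: Path, inputs: dict) -> dict:
    path = _resolve(base, cfg["path"])
    inputs[str(path)] = _sha256(path)
    trace = sio.read_kinetic(path, A0=cfg.get("A0_AU"), A_inf=cfg.get("A_inf_AU"))
    sel = select_order(trace)
    return {
        "first": {"k_per_s": sel.first.k, "r_squared": sel.first.fit.r_squared},
        "second": {"ak_per_AU_s": sel.second.k, "r_squared": sel.second.fit.r_squared},
        "chosen_order": sel.chosen.value,
        "margin_r_squared": sel.margin,
        "indeterminate": sel.indeterminate,
    }


def _quench_stage(cfg: dict, base: Path, inputs: dict) -> dict:
    path = _resolve(base, cfg["path"])
    inputs[str(path)] = _sha256(path)
    series = sio.read_quench(
        path, F0=cfg.get("F0_AU"), tau0=float(cfg.get("tau0_s", DEFAULT_TAU0))
    )
    res = analyze_quench(series)
    return {
        "K_sv_per_M": res.K_sv,
        "k_q_per_M_s": res.k_q,
        "mechanism": res.mechanism.value,
        "K_b_doublelog_per_M": res.K_b_doublelog,
        "n_sites": res.n_sites,
        "sv_r_squared": res.sv_fit.r_squared,
        "dl_r_squared": res.dl_fit.r_squared,
    }


def run_study(config, base_dir=None) -> StudyReport:
    """Execute every configured stage and return the assembled report.

    ``config`` is a dict, or a path to a JSON file (then relative input
    paths resolve against the file's directory).  A failing stage raises
    ``RuntimeError`` naming the stage.
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        base = config_path.parent if base_dir is None else Path(base_dir)
        config = json.loads(config_path.read_text())
    else:
        base = Path(base_dir) if base_dir is not None else Path.cwd()

    report = StudyReport()
    inputs: dict = {}
    stages = (
        ("isotherm", None),
        ("melt", _melt_stage),
        ("kinetics", _kinetics_stage),
        ("quench", _quench_stage),
    )
    for name, runner in stages:
        if name not in config:
            continue
        logger.info("running stage %s", name)
        try:
            if name == "isotherm":
                blocks, thermo, coop = _isotherm_stage(config[name], base, inputs)
                report.isotherm = blocks
                report.thermodynamics = thermo
                report.cooperativity = coop
            else:
                setattr(report, name, runner(config[name], base, inputs))
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        logger.info("stage %s done", name)

    try:
        from importlib.metadata import version

        pkg_version = version("specbind")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    report.provenance = {"package": "specbind", "version": pkg_version, "inputs": inputs}
    return report
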