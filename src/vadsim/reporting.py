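"""Phase summaries, cross-scenario comparisons, and the pipeline runner.

Relaxation during a rest phase is quantified as
``100 * (sigma_start - sigma_end) / sigma_start`` over the rest window,
with ``sigma_start`` taken at the sample where the rest begins (the
boundary sample of the preceding pull).  Percent differences between
scenario peaks follow the same convention:
``100 * (peak_A - peak_B) / peak_A``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import calibrate_young_modulus
from .canal import SimulationResult, simulate_vad
from .errors import ComparabilityError, ConfigurationError
from .protocol import PullProtocol, build_scenarios
from .synthetic import synthetic_compression_curve

__all__ = [
    "PhaseSummary",
    "ScenarioComparison",
    "phase_summaries",
    "compare_scenarios",
    "run_pipeline",
    "run_sweep",
]

#: Ring whose stress drives the cross-scenario comparisons (the pelvic
#: floor muscle path).
PFM_RING = "levator"


@dataclass(frozen=True)
class PhaseSummary:
    """Per-phase stress summary for one ring.

    ``relaxation_pct`` is defined only for rest phases; it is ``None`` when
    the phase is not a rest or when the phase starts at zero stress.
    """

    phase: str
    peak_sigma1_MPa: float
    displacement_at_peak_mm: float
    sigma_start_MPa: float
    sigma_end_MPa: float
    relaxation_pct: float | None


@dataclass
class ScenarioComparison:
    """Peak table plus pairwise percent differences of peak PFM stress."""

    table: pd.DataFrame
    percent_difference: pd.DataFrame


def phase_summaries(result: SimulationResult, protocol: PullProtocol,
                    ring: str = PFM_RING) -> list[PhaseSummary]:
    """Summarize each protocol phase of a simulation for one ring."""
    sigma = result.sigma1[ring]
    disp = result.displacement
    out = []
    for label, block in result.phase_blocks():
        start_idx = block.start - 1 if block.start > 0 else block.start
        seg = slice(start_idx, block.stop)
        i_peak = start_idx + int(np.argmax(sigma[seg]))
        sigma_start = float(sigma[start_idx])
        sigma_end = float(sigma[block.stop - 1])
        relaxation = None
        if label.startswith("rest"):
            if sigma_start > 0.0:
                relaxation = 100.0 * (sigma_start - sigma_end) / sigma_start
            # else undefined: leave the None marker rather than divide
        out.append(
            PhaseSummary(
                phase=label,
                peak_sigma1_MPa=float(sigma[i_peak]),
                displacement_at_peak_mm=float(disp[i_peak]),
                sigma_start_MPa=sigma_start,
                sigma_end_MPa=sigma_end,
                relaxation_pct=relaxation,
            )
        )
    return out


def compare_scenarios(results: dict) -> ScenarioComparison:
    """Build the cross-scenario peak table and pairwise percent differences.

    ``results`` maps scenario labels to :class:`SimulationResult`.  All
    results must share the same anatomy; the percent decrease from scenario
    A (rows) to B (columns) is ``100 * (peak_A - peak_B) / peak_A``.
    """
    if len(results) < 2:
        raise ValueError("comparison needs at least two scenarios")
    signatures = {r.anatomy_signature for r in results.values()}
    if len(signatures) > 1:
        raise ComparabilityError("results were produced with different anatomies")

    rows = []
    for label, res in results.items():
        sigma = res.sigma1[PFM_RING]
        i = int(np.argmax(sigma))
        rows.append(
            {
                "label": label,
                "contraction_s": res.protocol.contraction_duration,
                "rest_s": res.protocol.rest_duration,
                "n_pulls": res.protocol.n_pulls,
                "peak_pfm_sigma1_MPa": float(sigma[i]),
                "displacement_at_peak_mm": float(res.displacement[i]),
                "peak_force_N": float(np.max(res.force)),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["contraction_s", "rest_s", "n_pulls"])
        .reset_index(drop=True)
    )
    peaks = table.set_index("label")["peak_pfm_sigma1_MPa"]
    pct = pd.DataFrame(
        100.0 * (peaks.values[:, None] - peaks.values[None, :]) / peaks.values[:, None],
        index=peaks.index,
        columns=peaks.index,
    )
    return ScenarioComparison(table=table, percent_difference=pct)


def run_sweep(anatomy, scenarios: pd.DataFrame | None = None,
              materials=None, dt: float = 1.0,
              engagement_dt: float = 60.0,
              total_descent: float = 100.0,
              engagement_duration: float = 10800.0) -> dict:
    """Simulate every scenario of the grid on one anatomy.

    Returns a dict label -> :class:`SimulationResult`, ordered like the
    scenario table.
    """
    head, rings = anatomy.build()
    if scenarios is None:
        scenarios = build_scenarios()
    results = {}
    for row in scenarios.itertuples(index=False):
        protocol = PullProtocol(
            contraction_duration=row.contraction_s,
            rest_duration=row.rest_s,
            n_pulls=int(row.n_pulls),
            engagement_duration=engagement_duration,
            total_descent=total_descent,
            dt=dt,
            engagement_dt=engagement_dt,
        )
        results[row.label] = simulate_vad(protocol, head, rings, materials)
    return results


def _summaries_frame(results: dict) -> pd.DataFrame:
    rows = []
    for label, res in results.items():
        for s in phase_summaries(res, res.protocol):
            rows.append(
                {
                    "scenario": label,
                    "phase": s.phase,
                    "peak_sigma1_MPa": s.peak_sigma1_MPa,
                    "displacement_at_peak_mm": s.displacement_at_peak_mm,
                    "sigma_start_MPa": s.sigma_start_MPa,
                    "sigma_end_MPa": s.sigma_end_MPa,
                    "relaxation_pct": s.relaxation_pct,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config_path=None, out_dir="vadsim_output", seed: int = 0,
                 dt: float | None = None) -> Path:
    """Full deterministic pipeline: sweep + comparison + head calibration.

    Loads the (default or user) config, runs the scenario sweep on the
    calibrated anatomy, writes one tidy CSV per scenario, a comparison
    table, a phase-summary table, a head-calibration report, and a run log
    recording the config hash, seed and library versions.  Rerunning with
    the same config and seed reproduces the CSVs byte for byte.
    """
    from .config import build_anatomy, build_materials, config_sha256, load_config

    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    proto_cfg = cfg["protocol"]
    if dt is not None:
        if dt <= 0:
            raise ConfigurationError("dt override must be positive")
        proto_cfg = {**proto_cfg, "dt": dt}
    scenarios = build_scenarios(
        proto_cfg["contractions"], proto_cfg["rests"], proto_cfg["pulls"]
    )
    anatomy = build_anatomy(cfg)
    materials = build_materials(cfg)
    results = run_sweep(
        anatomy,
        scenarios,
        materials=materials,
        dt=proto_cfg["dt"],
        engagement_dt=proto_cfg["engagement_dt"],
        total_descent=proto_cfg["total_descent"],
        engagement_duration=proto_cfg["engagement_duration"],
    )

    float_fmt = "%.12g"
    for label, res in results.items():
        res.to_frame().to_csv(out / f"scenario_{label}.csv", index=False,
                              float_format=float_fmt)
    comparison = compare_scenarios(results)
    comparison.table.to_csv(out / "scenario_comparison.csv", index=False,
                            float_format=float_fmt)
    _summaries_frame(results).to_csv(out / "phase_summaries.csv", index=False,
                                     float_format=float_fmt)

    cal_cfg = cfg["calibration"]
    curve = synthetic_compression_curve(
        E_true=cfg["materials"]["fetal_head"]["E"],
        n_points=cal_cfg["n_points"],
        noise_cv=cal_cfg["noise_cv"],
        seed=seed,
        nu=cal_cfg["nu"],
        R=cal_cfg["radius"],
        max_deflection=cal_cfg["max_deflection"],
    )
    cal = calibrate_young_modulus(curve, nu=cal_cfg["nu"], R=cal_cfg["radius"])
    (out / "calibration_report.json").write_text(
        json.dumps(
            {
                "E_true_MPa": cfg["materials"]["fetal_head"]["E"],
                "E_recovered_MPa": cal.E_MPa,
                "residual_norm_N": cal.residual_norm,
                "relative_std_error": cal.relative_std_error,
                "n_points": cal.n_points,
                "noise_cv": cal_cfg["noise_cv"],
                "seed": seed,
            },
            indent=2,
        )
        + "\n"
    )

    import numpy
    import pandas
    import scipy

    from . import __version__

    (out / "run_log.json").write_text(
        json.dumps(
            {
                "config_sha256": config_sha256(cfg),
                "seed": seed,
                "n_scenarios": len(results),
                "versions": {
                    "vadsim": __version__,
                    "numpy": numpy.__version__,
                    "scipy": scipy.__version__,
                    "pandas": pandas.__version__,
                },
            },
            indent=2,
        )
        + "\n"
    )
    return out
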