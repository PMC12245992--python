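"""Config loading, schema validation, and object construction.

The config is a nested key-value YAML file; the packaged default ships the
published tissue parameters and the twelve-scenario grid.  Validation is
strict: unknown keys anywhere raise :class:`~vadsim.errors.SchemaError`
listing every offender, and out-of-range values are rejected before any
simulation runs.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml

from .canal import PERINEUM_MATERIAL, PFM_MATERIAL, PerineumMaterial, PfmMaterial
from .constitutive import LinearElasticParams, MartinsParams
from .errors import SchemaError
from .synthetic import AnatomyConfig, default_anatomy
from .viscoelastic import MaxwellBranch

__all__ = [
    "load_config",
    "validate_config",
    "build_anatomy",
    "build_materials",
    "config_sha256",
]

_SCHEMA = {
    "materials": {
        "pfm": {"model", "c", "b", "A", "a", "T0M", "theta", "D",
                "matrix_branches", "fiber_branches"},
        "perineal_body": {"model", "E", "unit", "nu"},
        "bulbospongiosus": {"model", "E", "unit", "nu"},
        "anal_sphincter": {"model", "c10"},
        "fetal_head": {"model", "E", "unit", "nu"},
    },
    "protocol": {"engagement_duration", "contractions", "rests", "pulls",
                 "total_descent", "dt", "engagement_dt"},
    "anatomy": {"head_radius", "lambda_eng", "levator_area_mm2",
                "urogenital_area_mm2"},
    "calibration": {"nu", "radius", "max_deflection", "n_points", "noise_cv"},
}

_POSITIVE_PROTOCOL_KEYS = ("engagement_duration", "total_descent", "dt",
                           "engagement_dt")


def _default_config_text() -> str:
    return (resources.files("vadsim") / "data" / "default_config.yaml").read_text()


def load_config(path=None) -> dict:
    """Load and validate a config; ``None`` loads the packaged default."""
    if path is None:
        cfg = yaml.safe_load(_default_config_text())
    else:
        cfg = yaml.safe_load(Path(path).read_text())
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Strict schema check; collects every offending key/value."""
    offenders: list[str] = []
    if not isinstance(cfg, dict):
        raise SchemaError(["config root must be a mapping"])
    for key in cfg:
        if key not in _SCHEMA:
            offenders.append(key)
    for section, allowed in _SCHEMA.items():
        if section not in cfg:
            offenders.append(f"missing section {section}")
            continue
        sub = cfg[section]
        if not isinstance(sub, dict):
            offenders.append(f"{section} (not a mapping)")
            continue
        if isinstance(allowed, dict):
            for tissue in sub:
                if tissue not in allowed:
                    offenders.append(f"{section}.{tissue}")
                elif isinstance(sub[tissue], dict):
                    for k in sub[tissue]:
                        if k not in allowed[tissue]:
                            offenders.append(f"{section}.{tissue}.{k}")
        else:
            for k in sub:
                if k not in allowed:
                    offenders.append(f"{section}.{k}")
    if offenders:
        raise SchemaError(offenders)

    proto = cfg["protocol"]
    for k in _POSITIVE_PROTOCOL_KEYS:
        if not proto.get(k, 1) > 0:
            offenders.append(f"protocol.{k} (must be positive)")
    for k in ("contractions", "rests"):
        vals = proto.get(k, [])
        if not vals or any(v <= 0 for v in vals):
            offenders.append(f"protocol.{k} (must be positive durations)")
    pulls = proto.get("pulls", [])
    if not pulls or any(int(p) != p or p < 1 for p in pulls):
        offenders.append("protocol.pulls (must be integers >= 1)")
    anat = cfg["anatomy"]
    if not anat.get("head_radius", 1) > 0:
        offenders.append("anatomy.head_radius (must be positive)")
    if not anat.get("lambda_eng", 1) >= 1:
        offenders.append("anatomy.lambda_eng (must be >= 1)")
    if offenders:
        raise SchemaError(offenders)


def build_anatomy(cfg: dict) -> AnatomyConfig:
    """Anatomy calibrated to the stretch anchors, with config overrides."""
    from dataclasses import replace

    anat = cfg["anatomy"]
    base = default_anatomy(head_radius=anat["head_radius"])
    return replace(
        base,
        lambda_eng=anat["lambda_eng"],
        levator_area_mm2=anat["levator_area_mm2"],
        urogenital_area_mm2=anat["urogenital_area_mm2"],
    )


def build_materials(cfg: dict) -> dict:
    """Ring material map from the config's tissue entries."""
    pfm = cfg["materials"]["pfm"]
    perineum = cfg["materials"]["perineal_body"]
    return {
        PFM_MATERIAL: PfmMaterial(
            params=MartinsParams(
                c=pfm["c"], b=pfm["b"], A=pfm["A"], a=pfm["a"],
                T0M=pfm["T0M"], theta=pfm["theta"], D=pfm["D"],
            ),
            matrix_branches=tuple(
                MaxwellBranch(B, tau) for B, tau in pfm["matrix_branches"]
            ),
            fiber_branches=tuple(
                MaxwellBranch(B, tau) for B, tau in pfm["fiber_branches"]
            ),
        ),
        PERINEUM_MATERIAL: PerineumMaterial(
            params=LinearElasticParams(
                E=perineum["E"], nu=perineum["nu"], unit=perineum["unit"]
            )
        ),
    }


def config_sha256(cfg: dict) -> str:
    """Stable hash of the (validated) config contents."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=float).encode()
    ).hexdigest()
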