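"""Patient-record and configuration I/O plus run manifests.

CSV conventions are fixed: comma-separated, UTF-8, header row, "." decimal
separator, radii in mm, volumes in mm^3, rates per day.  Records may carry
either radius columns (R0_mm, R1_mm, R2_mm) or segmentation-volume columns
(v_necrotic_mm3, v_enhancing_mm3, v_edema_mm3), which are converted to
equivalent-sphere radii.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import pandas as pd

from .errors import ConfigError, DomainError
from .estimate import ImagingConfig, ParameterEstimate, PatientObservation, volumes_to_radii
from .kinetics import SHAPE_PRESETS, GrowthDeathModel

__all__ = [
    "read_patients",
    "write_estimates",
    "load_config",
    "RunManifest",
]

_RADIUS_COLS = ("R0_mm", "R1_mm", "R2_mm")
_VOLUME_COLS = ("v_necrotic_mm3", "v_enhancing_mm3", "v_edema_mm3")


def read_patients(path) -> tuple[list[PatientObservation], list[dict]]:
    """Read and validate patient records from CSV.

    Returns (valid records, row diagnostics); a malformed row is reported
    with its reason and the run continues for the remaining rows.
    """
    df = pd.read_csv(path)
    has_radii = all(c in df.columns for c in _RADIUS_COLS)
    has_volumes = all(c in df.columns for c in _VOLUME_COLS)
    if "patient_id" not in df.columns or not (has_radii or has_volumes):
        raise ConfigError(
            f"{path}: need a patient_id column plus either radius columns "
            f"{_RADIUS_COLS} or volume columns {_VOLUME_COLS}"
        )
    records: list[PatientObservation] = []
    problems: list[dict] = []
    for idx, row in df.iterrows():
        pid = str(row["patient_id"])
        try:
            if has_radii and pd.notna(row[_RADIUS_COLS[0]]):
                radii = tuple(float(row[c]) for c in _RADIUS_COLS)
            else:
                radii = volumes_to_radii(*(float(row[c]) for c in _VOLUME_COLS))
            V = None
            vsrc = None
            if "V_mm_per_day" in df.columns and pd.notna(row["V_mm_per_day"]):
                V = float(row["V_mm_per_day"])
                if "velocity_source" in df.columns and pd.notna(row["velocity_source"]):
                    vsrc = str(row["velocity_source"])
            records.append(
                PatientObservation(pid, *radii, V=V, velocity_source=vsrc)
            )
        except (DomainError, ValueError, TypeError) as err:
            reason = "ordering" if "R0 < R1 < R2" in str(err) else "invalid"
            problems.append({"row": int(idx), "patient_id": pid, "reason": reason, "detail": str(err)})
    return records, problems


def write_estimates(path, estimates: list[ParameterEstimate], problems: list[dict] | None = None):
    """Write the estimates CSV in the fixed output schema."""
    rows = [
        {
            "patient_id": e.patient_id,
            "D_mm2_per_day": e.D,
            "rho_per_day": e.rho,
            "k_per_day": e.k,
            "rho_hat": e.rho_hat,
            "c_mm_per_day": e.c,
            "tumor_age_days": e.tumor_age,
            "residual": e.residual,
            "status": "ok",
        }
        for e in estimates
    ]
    for p in problems or []:
        rows.append(
            {
                "patient_id": p.get("patient_id", ""),
                "D_mm2_per_day": None,
                "rho_per_day": None,
                "k_per_day": None,
                "rho_hat": None,
                "c_mm_per_day": None,
                "tumor_age_days": None,
                "residual": None,
                "status": p.get("reason", "error"),
            }
        )
    columns = [
        "patient_id",
        "D_mm2_per_day",
        "rho_per_day",
        "k_per_day",
        "rho_hat",
        "c_mm_per_day",
        "tumor_age_days",
        "residual",
        "status",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def load_config(path=None) -> tuple[ImagingConfig, GrowthDeathModel]:
    """Load an (ImagingConfig, GrowthDeathModel) pair from JSON.

    Recognised keys: a1, a2, p0, t_star_days, threshold_times_pmax,
    width_equation, rho_hat_bracket, rho_bracket, and "shapes" — either a
    preset name or {alpha_g, beta_g, alpha_d, beta_d}.  Missing keys take
    the package defaults (the configuration reproducing the published
    patient table).
    """
    if path is None:
        return ImagingConfig(), GrowthDeathModel()
    try:
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
    except (OSError, json.JSONDecodeError) as err:
        raise ConfigError(f"cannot read config {path}: {err}") from err
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top-level JSON value must be an object")
    shapes = raw.pop("shapes", None)
    kw = {}
    mapping = {
        "a1": "a1",
        "a2": "a2",
        "p0": "p0",
        "t_star_days": "t_star",
        "threshold_times_pmax": "threshold_times_pmax",
        "width_equation": "width_equation",
        "rho_hat_bracket": "rho_hat_bracket",
        "rho_bracket": "rho_bracket",
    }
    unknown = set(raw) - set(mapping)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    for key, attr in mapping.items():
        if key in raw:
            val = raw[key]
            kw[attr] = tuple(val) if attr.endswith("bracket") else val
    try:
        config = ImagingConfig(**kw)
        if shapes is None:
            model = GrowthDeathModel()
        elif isinstance(shapes, str):
            if shapes not in SHAPE_PRESETS:
                raise ConfigError(f"{path}: unknown shape preset {shapes!r}")
            model = GrowthDeathModel.from_preset(shapes)
        else:
            model = GrowthDeathModel(
                alpha_g=float(shapes["alpha_g"]),
                beta_g=float(shapes["beta_g"]),
                alpha_d=float(shapes["alpha_d"]),
                beta_d=float(shapes["beta_d"]),
            )
    except (DomainError, KeyError, TypeError) as err:
        raise ConfigError(f"{path}: invalid configuration: {err}") from err
    return config, model


def _file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record tying each output row to its input and config."""

    config: dict
    shapes: tuple
    input_path: str
    input_sha256: str
    tool_version: str = field(default_factory=lambda: _version())
    started_utc: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    statuses: list = field(default_factory=list)

    @classmethod
    def start(cls, input_path, config: ImagingConfig, model: GrowthDeathModel):
        return cls(
            config=asdict(config),
            shapes=model.shapes,
            input_path=str(input_path),
            input_sha256=_file_digest(input_path),
        )

    def record(self, patient_id: str, status: str):
        self.statuses.append({"patient_id": patient_id, "status": status})

    def write(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)
            fh.write("\n")


def _version() -> str:
    try:
        return _pkg_version("gbmwave")
    except PackageNotFoundError:
        return "unknown"
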