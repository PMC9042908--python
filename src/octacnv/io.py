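"""File formats: images, masks, cohort CSV, reports.

Images are single-channel 8/16-bit TIFF or PNG; ROI masks are same-sized
binary images.  Cohorts travel as one CSV row per eye using the column
dictionary below (booleans as 0/1, grades as 0/1).  Reports are JSON with a
checksum per written file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cohort_stats import EyeRecord
from .morphometry import BiomarkerSet


class IOFormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


#: Cohort CSV column dictionary: column -> (dtype kind, description).
COHORT_COLUMNS: dict[str, tuple[str, str]] = {
    "eye_id": ("str", "unique eye identifier"),
    "age": ("float", "age in years"),
    "sex": ("str", "M or F"),
    "axial_length": ("float", "axial length, mm"),
    "spherical_equivalent": ("float", "spherical equivalent, diopters"),
    "bcva_baseline": ("float", "baseline BCVA, ETDRS letters (0-100)"),
    "bcva_12m": ("float", "12-month BCVA, ETDRS letters (0-100)"),
    "sfct": ("float", "subfoveal choroidal thickness, um"),
    "cft": ("float", "central foveal thickness, um"),
    "ez_grade": ("int01", "ellipsoid zone integrity grade, 0=intact 1=severe"),
    "elm_grade": ("int01", "ELM integrity grade, 0=intact 1=severe"),
    "srf_present": ("bool01", "subretinal fluid present"),
    "morphology": ("str", "medusa_seafan or tangled"),
    "branching": ("bool01", "branching vessels present"),
    "loops": ("bool01", "anastomotic loops present"),
    "dark_halo": ("bool01", "perilesional dark halo present"),
    "n_injections": ("float", "anti-VEGF injections in 12 months"),
    "cnv_size": ("float", "lesion size, mm^2"),
    "vessel_density": ("float", "vessel density, percent"),
    "vessel_length_density": ("float", "vessel length density, percent"),
    "vessel_diameter_index": ("float", "VD/VLD"),
    "vessel_tortuosity": ("float", "mean arc/chord ratio"),
    "fractal_dimension": ("float", "box-counting dimension"),
    "lacunarity": ("float", "gliding-box lacunarity"),
}

_BIOMARKER_FIELDS = (
    "cnv_size",
    "vessel_density",
    "vessel_length_density",
    "vessel_diameter_index",
    "vessel_tortuosity",
    "fractal_dimension",
    "lacunarity",
)


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale raster; multi-channel input is rejected."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise IOFormatError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4) and (
        np.ptp(arr[..., :3], axis=2) == 0
    ).all():
        arr = arr[..., 0]  # gray stored as RGB
    if arr.ndim != 2:
        raise IOFormatError(f"{path} is not a single-channel 2-D image")
    return arr


def load_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    arr = load_image(path)
    if shape is not None and arr.shape != shape:
        raise IOFormatError(
            f"mask {path} has shape {arr.shape}, expected {shape}"
        )
    return arr > 0


def save_image(path: str | Path, arr: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_al_table(path: str | Path) -> dict[str, float]:
    """CSV with columns eye_id, axial_length -> mapping."""
    frame = pd.read_csv(path)
    missing = {"eye_id", "axial_length"} - set(frame.columns)
    if missing:
        raise IOFormatError(f"AL table missing columns: {sorted(missing)}")
    return dict(zip(frame["eye_id"].astype(str), frame["axial_length"].astype(float)))


def _coerce(value, kind: str):
    if pd.isna(value):
        return None
    if kind == "float":
        return float(value)
    if kind == "int01":
        iv = int(value)
        return iv
    if kind == "bool01":
        return bool(int(value))
    return str(value)


def validate_cohort_frame(frame: pd.DataFrame) -> None:
    required = {"eye_id", "bcva_baseline", "bcva_12m"}
    missing = required - set(frame.columns)
    unknown = set(frame.columns) - set(COHORT_COLUMNS) - {"outcome"}
    problems = []
    if missing:
        problems.append(f"missing required columns: {sorted(missing)}")
    if unknown:
        problems.append(f"unknown columns: {sorted(unknown)}")
    if len(frame) == 0:
        problems.append("cohort CSV has no rows")
    if problems:
        raise IOFormatError("; ".join(problems))


def read_cohort_csv(path: str | Path) -> list[EyeRecord]:
    frame = pd.read_csv(path)
    validate_cohort_frame(frame)
    records = []
    for _, row in frame.iterrows():
        fields = {}
        bm = {}
        for col, (kind, _) in COHORT_COLUMNS.items():
            if col not in frame.columns:
                continue
            val = _coerce(row[col], kind)
            if col in _BIOMARKER_FIELDS:
                bm[col] = val
            else:
                fields[col] = val
        biomarkers = None
        if any(v is not None for v in bm.values()) and all(
            bm.get(k) is not None
            for k in ("cnv_size", "vessel_density", "vessel_length_density",
                      "fractal_dimension", "lacunarity")
        ):
            biomarkers = BiomarkerSet(
                cnv_size=bm["cnv_size"],
                vessel_density=bm["vessel_density"],
                vessel_length_density=bm["vessel_length_density"],
                vessel_diameter_index=bm.get("vessel_diameter_index"),
                vessel_tortuosity=bm.get("vessel_tortuosity"),
                fractal_dimension=bm["fractal_dimension"],
                lacunarity=bm["lacunarity"],
            )
        records.append(EyeRecord(biomarkers=biomarkers, **fields))
    return records


def write_cohort_csv(path: str | Path, records: list[EyeRecord]) -> None:
    rows = []
    for rec in records:
        row = {}
        for col, (kind, _) in COHORT_COLUMNS.items():
            if col in _BIOMARKER_FIELDS:
                val = getattr(rec.biomarkers, col, None) if rec.biomarkers else None
            else:
                val = getattr(rec, col, None)
            if kind == "bool01" and val is not None:
                val = int(val)
            row[col] = val
        rows.append(row)
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def _round_sig(x, sig: int = 6):
    if isinstance(x, float):
        if x == 0 or not np.isfinite(x):
            return x
        return float(f"{x:.{sig}g}")
    return x


def write_json(path: str | Path, payload: dict, sig: int = 6) -> None:
    def conv(obj):
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.floating,)):
            return _round_sig(float(obj), sig)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, np.ndarray):
            return conv(obj.tolist())
        return _round_sig(obj, sig)

    Path(path).write_text(json.dumps(conv(payload), indent=2, sort_keys=True) + "\n")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunReport:
    """Per-run log: stages, outputs with checksums, failures."""

    command: str
    config: dict = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    failures: list[dict] = field(default_factory=list)

    def log_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def log_failure(self, stage: str, item: str, error: str) -> None:
        self.failures.append({"stage": stage, "item": item, "error": error})

    def register_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = sha256_of(path)

    def write(self, path: str | Path) -> None:
        write_json(path, {
            "command": self.command,
            "config": self.config,
            "stages": self.stages,
            "outputs": self.outputs,
            "failures": self.failures,
        })
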