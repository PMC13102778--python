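"""Manifest reading/writing, image cropping, and QC exclusion.

The manifest is a CSV with one row per imaged spheroid: provenance (domain,
laboratory, study, plate, well, microscope), the bright-field image path and
size, a fractional bounding box around the spheroid, the measured ATP in nM
when the well was assayed, and three ordinal pathologist scores when graded.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, asdict
from math import ceil, floor, isnan

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "ManifestError",
    "QC_REASONS",
    "read_manifest",
    "write_manifest",
    "records_to_frame",
    "load_image",
    "load_and_crop",
    "apply_qc",
    "read_qc_flags",
]


class ManifestError(ValueError):
    """Schema or row-level manifest problem."""


QC_REASONS = ("empty_well", "out_of_focus", "pipetting_error", "none")

# canonical name -> aliases accepted case-insensitively
_MANDATORY = [
    "domain", "location", "study", "day", "treatment", "compound",
    "concentration_um", "plate", "well", "microscope", "location_in_bucket",
    "value", "w", "h", "xmin", "ymin", "xmax", "ymax",
]
_OPTIONAL = ["cytoplasmic_score", "nuclear_score", "contour_score"]


@dataclass
class SampleRecord:
    """One manifest row, typed; ``None`` marks missing numeric cells."""

    domain: str
    location: str
    study: str
    day: int
    treatment: str
    compound: str
    concentration_uM: float | None
    plate: str
    well: str
    microscope: str
    image_path: str
    atp_nM: float | None
    width: int
    height: int
    bbox: tuple  # (xmin, ymin, xmax, ymax) as fractions of the frame
    cytoplasmic_score: int | None = None
    nuclear_score: int | None = None
    contour_score: int | None = None

    def validate(self):
        xmin, ymin, xmax, ymax = self.bbox
        if not (0.0 <= xmin < xmax <= 1.0 and 0.0 <= ymin < ymax <= 1.0):
            raise ManifestError(f"invalid bbox {self.bbox}")
        if self.atp_nM is not None and self.atp_nM < 0:
            raise ManifestError(f"negative ATP value {self.atp_nM}")
        for name in ("cytoplasmic_score", "nuclear_score", "contour_score"):
            s = getattr(self, name)
            if s is not None and s not in (0, 1, 2, 3, 4):
                raise ManifestError(f"{name}={s} outside 0-4")
        return self

    @property
    def key(self):
        return (self.study, self.plate, self.well)

    @property
    def labeled(self):
        return self.atp_nM is not None


def _norm_col(name):
    # unicode micro / greek mu both normalize to 'u'
    return (
        str(name).strip().replace("µ", "u").replace("μ", "u").lower()
    )


def _opt_float(x):
    try:
        f = float(x)
    except (TypeError, ValueError):
        return None
    return None if isnan(f) else f


def _opt_int(x):
    f = _opt_float(x)
    return None if f is None else int(round(f))


def read_manifest(path_or_df) -> list[SampleRecord]:
    """Parse a manifest CSV (or DataFrame) into typed records, order preserved.

    Column matching is case-insensitive and tolerant of the micro sign in
    ``Concentration_uM``.  A missing mandatory column raises
    :class:`ManifestError` naming the column; an invalid bounding box raises
    with the offending row index.
    """
    df = (
        path_or_df.copy() if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, float_precision="round_trip")
    )
    cols = {_norm_col(c): c for c in df.columns}
    for c in _MANDATORY:
        if c not in cols:
            raise ManifestError(f"manifest is missing mandatory column '{c}'")

    def get(row, name):
        return row[cols[name]]

    records = []
    for idx, row in df.iterrows():
        bbox = tuple(_opt_float(get(row, k)) for k in ("xmin", "ymin", "xmax", "ymax"))
        if any(b is None for b in bbox):
            raise ManifestError(f"row {idx}: unparseable bbox {bbox}")
        rec = SampleRecord(
            domain=str(get(row, "domain")),
            location=str(get(row, "location")),
            study=str(get(row, "study")),
            day=_opt_int(get(row, "day")) or 0,
            treatment=str(get(row, "treatment")).strip().lower(),
            compound=str(get(row, "compound")),
            concentration_uM=_opt_float(get(row, "concentration_um")),
            plate=str(get(row, "plate")),
            well=str(get(row, "well")),
            microscope=str(get(row, "microscope")),
            image_path=str(get(row, "location_in_bucket")),
            atp_nM=_opt_float(get(row, "value")),
            width=_opt_int(get(row, "w")) or 0,
            height=_opt_int(get(row, "h")) or 0,
            bbox=bbox,
            cytoplasmic_score=_opt_int(row[cols["cytoplasmic_score"]])
            if "cytoplasmic_score" in cols else None,
            nuclear_score=_opt_int(row[cols["nuclear_score"]])
            if "nuclear_score" in cols else None,
            contour_score=_opt_int(row[cols["contour_score"]])
            if "contour_score" in cols else None,
        )
        try:
            rec.validate()
        except ManifestError as e:
            raise ManifestError(f"row {idx}: {e}") from None
        records.append(rec)
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Records back to a DataFrame in the canonical column schema."""
    rows = []
    for r in records:
        d = asdict(r)
        xmin, ymin, xmax, ymax = d.pop("bbox")
        rows.append({
            "Domain": d["domain"], "Location": d["location"],
            "Study": d["study"], "Day": d["day"],
            "Treatment": d["treatment"], "Compound": d["compound"],
            "Concentration_uM": d["concentration_uM"], "Plate": d["plate"],
            "Well": d["well"], "Microscope": d["microscope"],
            "Location_in_bucket": d["image_path"], "Value": d["atp_nM"],
            "w": d["width"], "h": d["height"],
            "xmin": xmin, "ymin": ymin, "xmax": xmax, "ymax": ymax,
            "Cytoplasmic_score": d["cytoplasmic_score"],
            "Nuclear_score": d["nuclear_score"],
            "Contour_score": d["contour_score"],
        })
    return pd.DataFrame(rows)


def write_manifest(records, path):
    records_to_frame(records).to_csv(path, index=False)


def load_image(path) -> np.ndarray:
    """Load a grayscale PNG/TIFF as float in [0, 1]."""
    import imageio.v3 as iio

    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    raw = np.asarray(iio.imread(path))
    img = raw[..., :3].mean(axis=-1) if raw.ndim == 3 else raw.astype(np.float64)
    img = np.asarray(img, dtype=np.float64)
    if np.issubdtype(raw.dtype, np.integer):
        img = img / np.iinfo(raw.dtype).max
    return img


def crop_window(bbox, width, height, pad_fraction=0.1):
    """Pixel crop window for a fractional bbox: half-open [x0, x1) x [y0, y1).

    Fractions map to pixels as ``floor(f * W)`` / ``ceil(f * W)``; the window
    is expanded on every side by ``pad_fraction`` of its own size, then
    clipped to the frame.
    """
    xmin, ymin, xmax, ymax = bbox
    bw, bh = (xmax - xmin), (ymax - ymin)
    xmin, xmax = xmin - pad_fraction * bw, xmax + pad_fraction * bw
    ymin, ymax = ymin - pad_fraction * bh, ymax + pad_fraction * bh
    x0 = max(floor(xmin * width), 0)
    x1 = min(ceil(xmax * width), width)
    y0 = max(floor(ymin * height), 0)
    y1 = min(ceil(ymax * height), height)
    return x0, y0, x1, y1


def load_and_crop(record: SampleRecord, pad_fraction=0.1, root=".",
                  image=None) -> np.ndarray:
    """Crop the spheroid region of a record's image.

    The fractional bbox is interpreted against the manifest's (w, h) columns;
    if the on-disk image disagrees in size, the actual image size is used and
    a warning is emitted.  ``image`` may be passed directly to skip disk I/O.
    """
    if image is None:
        image = load_image(os.path.join(root, record.image_path))
    h, w = image.shape[:2]
    if (w, h) != (record.width, record.height) and record.width and record.height:
        warnings.warn(
            f"{record.image_path}: manifest says {record.width}x{record.height} "
            f"but image is {w}x{h}; using image size",
            stacklevel=2,
        )
    x0, y0, x1, y1 = crop_window(record.bbox, w, h, pad_fraction)
    return image[y0:y1, x0:x1]


def read_qc_flags(path) -> dict:
    """QC flag CSV (study, plate, well, reason) -> {(study, plate, well): reason}."""
    df = pd.read_csv(path)
    cols = {_norm_col(c): c for c in df.columns}
    for c in ("study", "plate", "well", "reason"):
        if c not in cols:
            raise ManifestError(f"QC flag file is missing column '{c}'")
    flags = {}
    for _, row in df.iterrows():
        reason = str(row[cols["reason"]]).strip()
        if reason not in QC_REASONS:
            raise ManifestError(f"unknown QC reason '{reason}'")
        flags[(str(row[cols["study"]]), str(row[cols["plate"]]),
               str(row[cols["well"]]))] = reason
    return flags


def apply_qc(records, flags):
    """Drop records flagged with a verified technical failure.

    Only flagged wells are removed; statistical outliers in ATP are retained
    deliberately to preserve biological variability.  Returns
    ``(kept_records, report)`` where ``report`` counts exclusions per reason.
    Flags pointing at unknown wells produce a warning, not an error.
    """
    keys = {r.key for r in records}
    for k, reason in flags.items():
        if k not in keys and reason != "none":
            warnings.warn(f"QC flag for unknown well {k}", stacklevel=2)
    report = {reason: 0 for reason in QC_REASONS if reason != "none"}
    kept = []
    for r in records:
        reason = flags.get(r.key, "none")
        if reason == "none":
            kept.append(r)
        else:
            report[reason] += 1
    report["kept"] = len(kept)
    report["total"] = len(records)
    return kept, report
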