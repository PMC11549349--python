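"""Vertebral morphometrics for precloacal snake vertebrae.

A snake vertebra is described here by a fixed vocabulary of linear
measurements (mm), angles (degrees), and discrete anatomical flags.  The
module computes the standard ratio suite used in madtsoiid systematics
(e.g. cotyle width/height ``coW/coH``, neural-spine height over total
height ``nsH/tvH``), classifies vertebrae along the trunk (anterior trunk
vertebrae carry a hypapophysis; mid-trunk vertebrae a chisel-shaped hemal
process, and are relatively wider than long), and selects the specimens a
body-size analysis should be based on (the largest mid-trunk vertebrae).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from paleosnake.errors import ValidationError

#: Linear measurements, all in millimetres.
LENGTH_FIELDS: tuple[str, ...] = (
    "cL",    # centrum length
    "prW",   # trans-prezygapophyseal width
    "poW",   # trans-postzygapophyseal width
    "coW", "coH",    # cotyle width / height
    "cnW", "cnH",    # condyle width / height
    "ncW", "ncH",    # neural canal width / height
    "zsW", "zsH",    # zygosphene width / height
    "zsfL", "zsfW",  # zygosphenal facet length / width
    "przL", "przW",  # prezygapophyseal facet length / width
    "pozL", "pozW",  # postzygapophyseal facet length / width
    "nsH",   # neural spine height
    "tvH",   # total vertebral height
)

#: Directly measured angles, in degrees.
ANGLE_FIELDS: tuple[str, ...] = (
    "alpha_syn",  # synapophysis vs horizontal, anterior view
    "beta_syn",   # synapophysis vs vertical, lateral view
    "pr_alpha",   # prezygapophyseal facet inclination
    "po_alpha",   # postzygapophyseal facet inclination
    "zs_alpha",   # anterior zygosphenal notch angle
    "ns_incl",    # neural spine inclination from vertical
)

FLAG_FIELDS: tuple[str, ...] = (
    "hypapophysis_present",
    "chisel_process_present",
    "hemapophyses_absent",
    "sutures_closed",
)

#: The fixed ratio vocabulary: name -> (numerator field, denominator field).
RATIO_DEFS: dict[str, tuple[str, str]] = {
    "coW/coH": ("coW", "coH"),
    "cnW/cnH": ("cnW", "cnH"),
    "ncW/ncH": ("ncW", "ncH"),
    "zsW/zsH": ("zsW", "zsH"),
    "zsfL/zsfW": ("zsfL", "zsfW"),
    "przL/przW": ("przL", "przW"),
    "pozL/pozW": ("pozL", "pozW"),
    "nsH/tvH": ("nsH", "tvH"),
    "prW/cL": ("prW", "cL"),
    "poW/cL": ("poW", "cL"),
}


class PositionClass(Enum):
    """Position of a vertebra along the column."""

    ATV = "ATV"                        # anterior trunk
    MTV = "MTV"                        # mid trunk
    POSTERIOR_TRUNK = "POSTERIOR_TRUNK"
    CLOACAL_CAUDAL = "CLOACAL_CAUDAL"
    UNKNOWN = "UNKNOWN"


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class VertebraSpecimen:
    """One vertebra: measurements, angles, flags, and column position.

    Missing measurements are simply absent from the maps; they are never
    stored as zero.  All recorded lengths must be positive and all angles
    in (0, 180] degrees.
    """

    specimen_id: str
    series_index: Optional[int] = None
    lengths_mm: dict[str, float] = field(default_factory=dict)
    angles_deg: dict[str, float] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)
    position_class: PositionClass = PositionClass.UNKNOWN

    def __post_init__(self) -> None:
        for name, value in self.lengths_mm.items():
            if name not in LENGTH_FIELDS:
                raise ValidationError(f"unknown length field {name!r}")
            if not value > 0:
                raise ValidationError(
                    f"{self.specimen_id}: length {name} must be > 0, got {value}"
                )
        for name, value in self.angles_deg.items():
            if name not in ANGLE_FIELDS:
                raise ValidationError(f"unknown angle field {name!r}")
            if not 0 < value <= 180:
                raise ValidationError(
                    f"{self.specimen_id}: angle {name} must be in (0, 180], got {value}"
                )
        for name in self.flags:
            if name not in FLAG_FIELDS:
                raise ValidationError(f"unknown flag {name!r}")

    def length(self, name: str) -> Optional[float]:
        return self.lengths_mm.get(name)

    def flag(self, name: str) -> bool:
        return bool(self.flags.get(name, False))


@dataclass
class RatioReport:
    """Ratio suite for one specimen; unavailable ratios listed in `missing`."""

    specimen_id: str
    ratios: dict[str, float]
    missing: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "specimen_id": self.specimen_id,
                "ratios": self.ratios,
                "missing": self.missing,
            },
            indent=2,
        )

    def to_csv_row(self) -> dict[str, object]:
        row: dict[str, object] = {"specimen_id": self.specimen_id}
        for name in RATIO_DEFS:
            row[name] = self.ratios.get(name, "")
        return row


def compute_ratio_suite(specimen: VertebraSpecimen, decimals: int = 2) -> RatioReport:
    """Compute every ratio in the fixed vocabulary whose operands are recorded.

    Ratios are rounded half-up to ``decimals`` places; the specimen's stored
    measurements are never modified.  Ratios with one or both operands
    missing are reported by name in ``missing``.
    """
    if decimals < 0:
        raise ValidationError("decimals must be >= 0")
    if not specimen.lengths_mm:
        raise ValidationError(
            f"{specimen.specimen_id}: at least one length must be recorded"
        )
    ratios: dict[str, float] = {}
    missing: list[str] = []
    for name, (num, den) in RATIO_DEFS.items():
        a = specimen.length(num)
        b = specimen.length(den)
        if a is None or b is None:
            missing.append(name)
        else:
            ratios[name] = _round_half_up(a / b, decimals)
    return RatioReport(specimen.specimen_id, ratios, missing)


def classify_trunk_position(
    specimen: VertebraSpecimen, width_field: str = "prW"
) -> PositionClass:
    """Assign a precloacal vertebra to a trunk region.

    Anatomical flags win: a hypapophysis marks an anterior trunk vertebra
    (ATV); a chisel-shaped hemal process marks a mid-trunk vertebra (MTV).
    Otherwise the neural-arch-width criterion applies: a vertebra whose
    zygapophyseal width exceeds its centrum length (width/cL > 1) is
    anterior to the posterior trunk and classified MTV; width/cL <= 1 is
    classified POSTERIOR_TRUNK.  With neither flags nor the needed
    measurements the result is UNKNOWN.
    """
    if width_field not in ("prW", "poW"):
        raise ValidationError("width_field must be 'prW' or 'poW'")
    if specimen.flag("hypapophysis_present"):
        return PositionClass.ATV
    if specimen.flag("chisel_process_present"):
        return PositionClass.MTV
    cl = specimen.length("cL")
    width = specimen.length(width_field)
    if cl is None or width is None:
        return PositionClass.UNKNOWN
    return PositionClass.MTV if width / cl > 1 else PositionClass.POSTERIOR_TRUNK


def select_size_estimation_specimens(
    collection: Sequence[VertebraSpecimen], width_field: str = "prW"
) -> list[VertebraSpecimen]:
    """Pick the mid-trunk vertebrae, widest first, for body-size regression.

    Body-length equations are calibrated on mid-trunk positions, so only
    MTV-classified specimens qualify.  Ties on width break lexicographically
    on specimen id, making the selection fully deterministic.
    """
    if not collection:
        raise ValidationError("collection must be non-empty")
    mtv = [
        s
        for s in collection
        if classify_trunk_position(s, width_field) is PositionClass.MTV
        and s.length(width_field) is not None
    ]
    return sorted(mtv, key=lambda s: (-s.lengths_mm[width_field], s.specimen_id))


# ---------------------------------------------------------------------------
# CSV interchange


def read_measurements_csv(path: str | Path) -> list[VertebraSpecimen]:
    """Read a measurement table (one row per vertebra; empty cell = missing)."""
    specimens = []
    with open(path, newline="", encoding="utf-8") as fh:
        # lines starting with '#' are provenance comments (config, seed)
        reader = csv.DictReader(line for line in fh if not line.startswith("#"))
        if reader.fieldnames is None or "specimen_id" not in reader.fieldnames:
            raise ValidationError(f"{path}: header with specimen_id required")
        for row in reader:
            lengths = {}
            angles = {}
            flags = {}
            for name in LENGTH_FIELDS:
                cell = (row.get(f"{name}_mm") or "").strip()
                if cell:
                    lengths[name] = float(cell)
            for name in ANGLE_FIELDS:
                cell = (row.get(f"{name}_deg") or "").strip()
                if cell:
                    angles[name] = float(cell)
            for name in FLAG_FIELDS:
                cell = (row.get(name) or "").strip().lower()
                if cell:
                    flags[name] = cell in ("1", "true", "yes")
            idx = (row.get("series_index") or "").strip()
            specimens.append(
                VertebraSpecimen(
                    specimen_id=row["specimen_id"],
                    series_index=int(idx) if idx else None,
                    lengths_mm=lengths,
                    angles_deg=angles,
                    flags=flags,
                )
            )
    return specimens


def write_measurements_csv(
    specimens: Iterable[VertebraSpecimen], path: str | Path, header_comment: str = ""
) -> None:
    fieldnames = (
        ["specimen_id", "series_index"]
        + [f"{n}_mm" for n in LENGTH_FIELDS]
        + [f"{n}_deg" for n in ANGLE_FIELDS]
        + list(FLAG_FIELDS)
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for s in specimens:
            row: dict[str, object] = {
                "specimen_id": s.specimen_id,
                "series_index": "" if s.series_index is None else s.series_index,
            }
            for n in LENGTH_FIELDS:
                row[f"{n}_mm"] = s.lengths_mm.get(n, "")
            for n in ANGLE_FIELDS:
                row[f"{n}_deg"] = s.angles_deg.get(n, "")
            for n in FLAG_FIELDS:
                row[n] = "true" if s.flags.get(n) else ""
            writer.writerow(row)


def write_ratio_reports_csv(reports: Iterable[RatioReport], path: str | Path) -> None:
    fieldnames = ["specimen_id"] + list(RATIO_DEFS)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for report in reports:
            writer.writerow(report.to_csv_row())
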