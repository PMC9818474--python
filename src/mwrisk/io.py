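"""CSV and JSON readers/writers for exam, panel and result data.

Thermogram CSV dialect (long format, UTF-8, '.' decimal separator, header
required), one row per measurement:

    patient_id,visit_date,side,point,channel,temp_c

with side in {L, R, REF}, point in {0..9} (breast) or {T1, T2} (reference),
channel in {mw, ir}.  Row order is irrelevant; duplicates and missing cells
are parse errors.  Unknown extra columns are ignored with a warning.

JSON outputs are canonical: sorted keys, versioned schema, newline-terminated
— byte-identical for identical inputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector
from .mirna import (
    PANEL_BY_NAME,
    MarkerMeasurement,
    canonical_marker_name,
)
from .thermogram import N_POINTS, REF_POINTS, Thermogram

logger = logging.getLogger("mwrisk")

SCHEMA_VERSION = "1"

_REQUIRED_COLUMNS = ["patient_id", "visit_date", "side", "point", "channel", "temp_c"]

_SIDE_MAP = {"L": "left", "R": "right", "REF": "reference"}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line when known."""


def write_thermogram_csv(thermograms: list[Thermogram] | Thermogram, path: str | Path) -> None:
    """Write one or more exams in the long CSV dialect."""
    if isinstance(thermograms, Thermogram):
        thermograms = [thermograms]
    rows = []
    for tg in thermograms:
        for side, skin, internal in (
            ("R", tg.t_skin_right, tg.t_int_right),
            ("L", tg.t_skin_left, tg.t_int_left),
        ):
            for i in range(N_POINTS):
                rows.append((tg.patient_id, tg.visit_date, side, str(i), "ir", skin[i]))
                rows.append((tg.patient_id, tg.visit_date, side, str(i), "mw", internal[i]))
        for j, name in enumerate(REF_POINTS):
            rows.append((tg.patient_id, tg.visit_date, "REF", name, "ir", tg.t_skin_ref[j]))
            rows.append((tg.patient_id, tg.visit_date, "REF", name, "mw", tg.t_int_ref[j]))
    pd.DataFrame(rows, columns=_REQUIRED_COLUMNS).to_csv(path, index=False)


def read_thermogram_csv(path: str | Path) -> list[Thermogram]:
    """Read every exam in a long-format CSV; validates completeness.

    One exam per (patient_id, visit_date) pair, in file order of first
    appearance.  Raises :class:`ParseError` naming the offending cell for
    malformed rows, duplicates or missing measurements.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc

    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {missing_cols}")
    extra = [c for c in df.columns if c not in _REQUIRED_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
        logger.warning("%s: ignoring unknown columns %s", path, extra)

    exams: dict[tuple[str, str], dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        side_code = str(row["side"]).strip()
        if side_code not in _SIDE_MAP:
            raise ParseError(f"{path}:{line}: unknown side {side_code!r}")
        side = _SIDE_MAP[side_code]
        point = str(row["point"]).strip()
        channel = str(row["channel"]).strip()
        if channel not in ("mw", "ir"):
            raise ParseError(f"{path}:{line}: unknown channel {channel!r}")
        if side == "reference":
            if point not in REF_POINTS:
                raise ParseError(f"{path}:{line}: reference point must be T1/T2, got {point!r}")
        else:
            if not (point.isdigit() and 0 <= int(point) < N_POINTS):
                raise ParseError(f"{path}:{line}: breast point must be 0..9, got {point!r}")
        try:
            temp = float(row["temp_c"])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}:{line}: temp_c {row['temp_c']!r} is not a number"
            ) from None

        key = (str(row["patient_id"]), str(row["visit_date"]))
        exam = exams.setdefault(key, {})
        cell = (side, point, channel)
        if cell in exam:
            raise ParseError(
                f"{path}:{line}: duplicate measurement for side={side_code} "
                f"point={point} channel={channel}"
            )
        exam[cell] = temp

    thermograms = []
    for (pid, date), cells in exams.items():
        vectors = {}
        for name, side, channel, points in (
            ("t_skin_right", "right", "ir", [str(i) for i in range(N_POINTS)]),
            ("t_skin_left", "left", "ir", [str(i) for i in range(N_POINTS)]),
            ("t_int_right", "right", "mw", [str(i) for i in range(N_POINTS)]),
            ("t_int_left", "left", "mw", [str(i) for i in range(N_POINTS)]),
            ("t_skin_ref", "reference", "ir", list(REF_POINTS)),
            ("t_int_ref", "reference", "mw", list(REF_POINTS)),
        ):
            vals = []
            for p in points:
                try:
                    vals.append(cells[(side, p, channel)])
                except KeyError:
                    raise ParseError(
                        f"{path}: exam ({pid}, {date}) is missing "
                        f"side={side} point={p} channel={channel}"
                    ) from None
            vectors[name] = np.asarray(vals)
        thermograms.append(Thermogram(patient_id=pid, visit_date=date, **vectors))
    return thermograms


def read_panel_csv(path: str | Path) -> list[MarkerMeasurement]:
    """Read an 8-marker panel: columns marker, norm_conc, path_conc [, label]."""
    path = Path(path)
    df = pd.read_csv(path)
    if "marker" not in df.columns:
        raise ParseError(f"{path}: missing required column 'marker'")
    out = []
    for idx, row in df.iterrows():
        line = idx + 2
        name = canonical_marker_name(str(row["marker"]))
        if name not in PANEL_BY_NAME:
            raise ParseError(f"{path}:{line}: unknown panel marker {row['marker']!r}")
        label = None
        if "label" in df.columns and pd.notna(row.get("label")):
            label = str(row["label"])
        norm = path_c = None
        if "norm_conc" in df.columns and pd.notna(row.get("norm_conc")):
            norm = float(row["norm_conc"])
        if "path_conc" in df.columns and pd.notna(row.get("path_conc")):
            path_c = float(row["path_conc"])
        if label is None and (norm is None or path_c is None):
            raise ParseError(
                f"{path}:{line}: marker {name} needs either a label or both concentrations"
            )
        out.append(
            MarkerMeasurement(
                marker=PANEL_BY_NAME[name], norm_conc=norm, path_conc=path_c, label=label
            )
        )
    return out


def write_panel_csv(measurements: list[MarkerMeasurement], path: str | Path) -> None:
    rows = [
        {
            "marker": m.marker.name,
            "norm_conc": m.norm_conc,
            "path_conc": m.path_conc,
            "label": m.label,
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def features_to_frame(fvs: list[FeatureVector], ids: list[str] | None = None) -> pd.DataFrame:
    """Wide feature table, one row per exam, columns in the documented order."""
    df = pd.DataFrame(np.vstack([fv.values for fv in fvs]), columns=list(FEATURE_NAMES))
    if ids is not None:
        df.insert(0, "patient_id", ids)
    return df


def write_json(obj: dict, path: str | Path) -> None:
    """Canonical JSON: schema-versioned, sorted keys, deterministic bytes."""
    payload = {"schema_version": SCHEMA_VERSION, **obj}
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, indent=2, allow_nan=False) + "\n",
        encoding="utf-8",
    )


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
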