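"""Batch segmentation of cataloged pot images into growth time series.

Walks the per-pot folder layout written by :mod:`phenotray.catalog`,
segments every image with a trained classifier, and emits one
(tray, pot, timestamp, area) record per image as a tidy CSV.  Series are
reported raw — no smoothing or interpolation — and simple windowed
least-squares slopes summarize growth phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, time
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from phenotray.catalog import ImageKey
from phenotray.segment import PipelineParams, segment_pot
from phenotray.training import SuperpixelClassifier

log = logging.getLogger(__name__)

CSV_COLUMNS = ["tray", "pot", "date", "time", "area_px"]


@dataclass(frozen=True)
class PlantRecord:
    """One measured plant area: (tray, pot, timestamp, pixels)."""

    tray: str
    pot: str
    timestamp: datetime
    area_px: int
    area_cm2: float | None = None

    def __post_init__(self):
        if self.area_px < 0:
            raise ValueError("area must be >= 0")


def batch_process(root: str | Path, model: SuperpixelClassifier,
                  params: PipelineParams | None = None,
                  out_csv: str | Path | None = None,
                  px_per_cm: float | None = None) -> list[PlantRecord]:
    """Segment every cataloged image under ``root``.

    Unreadable images are logged and skipped (batch jobs at acquisition
    scale must not die on one bad file); an unreadable root is an error.
    Records come back sorted by (tray, pot, timestamp); ``out_csv``
    optionally writes them as tidy CSV with a fixed five-column schema.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"root folder {root} does not exist")
    records: list[PlantRecord] = []
    for path in sorted(root.glob("*/*.png")):
        try:
            key = ImageKey.parse(path.stem)
        except (ValueError, IndexError):
            log.warning("skipping unparseable filename %s", path.name)
            continue
        try:
            img = np.asarray(Image.open(path).convert("RGB"))
            result = segment_pot(img, model, params)
        except Exception as err:
            log.warning("skipping %s: %s", path.name, err)
            continue
        area_cm2 = (result.area / px_per_cm**2) if px_per_cm else None
        records.append(PlantRecord(
            tray=key.tray, pot=key.pot,
            timestamp=datetime.combine(key.date, key.time),
            area_px=result.area, area_cm2=area_cm2))
    records.sort(key=lambda r: (r.tray, r.pot, r.timestamp))
    if out_csv is not None:
        write_records_csv(records, out_csv)
    return records


def write_records_csv(records: list[PlantRecord],
                      out_csv: str | Path) -> Path:
    out_csv = Path(out_csv)
    df = pd.DataFrame(
        [{"tray": r.tray, "pot": r.pot,
          "date": r.timestamp.date().isoformat(),
          "time": r.timestamp.strftime("%H%M"),
          "area_px": r.area_px} for r in records],
        columns=CSV_COLUMNS)
    df.to_csv(out_csv, index=False)
    return out_csv


def read_records_csv(path: str | Path) -> list[PlantRecord]:
    df = pd.read_csv(path, dtype={"time": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(PlantRecord(
            tray=row.tray, pot=row.pot,
            timestamp=datetime.combine(
                date.fromisoformat(row.date),
                time(int(row.time[:2]), int(row.time[2:]))),
            area_px=int(row.area_px)))
    return records


def growth_series(records: list[PlantRecord], tray: str,
                  pot: str) -> list[tuple[datetime, int]]:
    """Time-sorted (timestamp, area) pairs for one pot; gaps preserved.

    Unknown keys give an empty sequence.
    """
    series = [(r.timestamp, r.area_px) for r in records
              if r.tray == tray and r.pot == pot]
    series.sort(key=lambda p: p[0])
    return series


def growth_slope(series: list[tuple[datetime, int]],
                 window: tuple[float, float] | None = None
                 ) -> float | None:
    """Least-squares slope of area vs time (pixels/day) within a window.

    ``window`` is (start_day, end_day) measured from the first point of the
    series, endpoints inclusive; None uses the whole series.  Returns None
    when fewer than two points fall inside the window.
    """
    if len(series) < 2:
        return None
    t0 = series[0][0]
    days = np.array([(t - t0).total_seconds() / 86400.0 for t, _ in series])
    areas = np.array([a for _, a in series], dtype=float)
    if window is not None:
        lo, hi = window
        keep = (days >= lo) & (days <= hi)
        days, areas = days[keep], areas[keep]
    if len(days) < 2 or np.ptp(days) == 0:
        return None
    slope, _ = np.polyfit(days, areas, 1)
    return float(slope)
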