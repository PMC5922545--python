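"""Capture scheduling, tray/pot labeling, and image cataloging.

Models the acquisition cadence of a gantry-mounted camera visiting a room
of trays (default: 28 trays labeled F11..F47 on a 4 x 7 grid, imaged every
hour from 09:00 to 21:00 inclusive — 13 visits per day) and the on-disk
arrangement of cropped pot images: one ``<tray>_<pot>`` folder per pot,
files named ``<tray>_<pot>_<date>_<time>``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
from PIL import Image

from phenotray.geometry import TrayGeometry


def default_tray_labels(rows: int = 4, cols: int = 7) -> list[str]:
    """Row-major tray labels F11..F47 over the room's tray grid."""
    return [f"F{r}{c}" for r in range(1, rows + 1) for c in range(1, cols + 1)]


@dataclass(frozen=True)
class CaptureSchedule:
    """Daily acquisition schedule over a set of trays.

    Defaults give 13 capture times (09:00..21:00 hourly) over 28 trays.
    """

    start: time = time(9, 0)
    end: time = time(21, 0)
    interval: timedelta = timedelta(hours=1)
    tray_labels: tuple[str, ...] = field(
        default_factory=lambda: tuple(default_tray_labels()))
    days: int = 1

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("schedule start must not be after end")
        if self.interval <= timedelta(0):
            raise ValueError("interval must be positive")
        if len(set(self.tray_labels)) != len(self.tray_labels):
            raise ValueError("tray labels must be unique")
        if self.days < 0:
            raise ValueError("days must be >= 0")


def capture_times(sched: CaptureSchedule) -> list[time]:
    """Capture times within one day, endpoints inclusive."""
    times = []
    anchor = date(2000, 1, 1)
    t = datetime.combine(anchor, sched.start)
    end = datetime.combine(anchor, sched.end)
    while t <= end:
        times.append(t.time())
        t += sched.interval
    return times


def count_tray_images(sched: CaptureSchedule) -> tuple[int, int]:
    """(tray images per day across all trays, total over the run).

    Defaults: 13 captures x 28 trays = 364 per day; a 90-day run yields
    32,760.
    """
    per_day = len(capture_times(sched)) * len(sched.tray_labels)
    return per_day, per_day * sched.days


def count_pot_images(sched: CaptureSchedule,
                     pots_per_tray: int = 32) -> tuple[int, int]:
    """(pot crops per capture cycle, pot crops per day).

    One cycle visits every tray once: 28 trays x 32 pots = 896 crops;
    13 cycles per day yield 11,648.
    """
    if pots_per_tray <= 0:
        raise ValueError("pots_per_tray must be positive")
    per_cycle = len(sched.tray_labels) * pots_per_tray
    return per_cycle, per_cycle * len(capture_times(sched))


def pot_label(row: int, col: int, geom: TrayGeometry | None = None) -> str:
    """Row-major, 1-based pot label: (0, 0) -> 'Pot01', (3, 7) -> 'Pot32'."""
    geom = geom or TrayGeometry()
    if not (0 <= row < geom.n_rows and 0 <= col < geom.n_cols):
        raise IndexError(f"pot ({row}, {col}) outside {geom.n_rows} x "
                         f"{geom.n_cols} grid")
    return f"Pot{row * geom.n_cols + col + 1:02d}"


def pot_position(label: str, geom: TrayGeometry | None = None
                 ) -> tuple[int, int]:
    """Inverse of :func:`pot_label`: 'Pot09' -> (1, 0) on the 4 x 8 grid."""
    geom = geom or TrayGeometry()
    if not label.startswith("Pot"):
        raise ValueError(f"malformed pot label {label!r}")
    idx = int(label[3:]) - 1
    if not 0 <= idx < geom.n_rows * geom.n_cols:
        raise IndexError(f"pot label {label!r} outside grid")
    return divmod(idx, geom.n_cols)


@dataclass(frozen=True)
class ImageKey:
    """Identity of one cropped pot image: tray, pot, capture date and time."""

    tray: str
    pot: str
    date: date
    time: time

    def __post_init__(self):
        pot_position(self.pot)  # validates the pot index range

    @property
    def folder(self) -> str:
        return f"{self.tray}_{self.pot}"

    @property
    def stem(self) -> str:
        return (f"{self.tray}_{self.pot}_{self.date.isoformat()}"
                f"_{self.time.strftime('%H%M')}")

    @classmethod
    def parse(cls, stem: str) -> "ImageKey":
        """Parse 'F11_Pot01_2017-06-01_0900' back into a key."""
        tray, pot, d, t = stem.split("_")
        return cls(tray=tray, pot=pot, date=date.fromisoformat(d),
                   time=time(int(t[:2]), int(t[2:])))


def arrange(records: list[tuple[ImageKey, np.ndarray]],
            root: str | Path) -> list[Path]:
    """Write pot images into the per-pot folder layout.

    Creates ``root/<tray>_<pot>/<tray>_<pot>_<date>_<time>.png``.  Re-runs
    are idempotent; writing the same key twice overwrites with a warning.
    Returns the written paths.
    """
    root = Path(root)
    written = []
    for key, img in records:
        folder = root / key.folder
        folder.mkdir(parents=True, exist_ok=True)
        path = folder / f"{key.stem}.png"
        if path.exists():
            warnings.warn(f"overwriting existing image {path}", stacklevel=2)
        Image.fromarray(np.asarray(img)).save(path)
        written.append(path)
    return written


def write_manifest(paths: list[Path], root: str | Path,
                   out_csv: str | Path) -> Path:
    """CSV manifest (tray, pot, date, time, relative path) for batch jobs."""
    root = Path(root)
    out_csv = Path(out_csv)
    rows = []
    for p in sorted(paths):
        key = ImageKey.parse(p.stem)
        rows.append([key.tray, key.pot, key.date.isoformat(),
                     key.time.strftime("%H%M"), str(p.relative_to(root))])
    with open(out_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tray", "pot", "date", "time", "path"])
        w.writerows(rows)
    return out_csv
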