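"""CSV/PNG input-output with schema validation.

CSV dialect: comma-separated, UTF-8, mandatory header row, "." decimal
separator.  Schemas:

* specimens: ``id, year, island_group, white_rel, red_rel``
* pedigree:  ``id, sex, mother_id, father_id, generation, white_rel, red_rel``
  (parent ids empty for founders and wild mates; trait columns empty for
  males)
* landmarks: ``image_path, x1, y1, x2, y2`` (0-based pixel coordinates,
  origin top-left, x = column)
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .spotquant import LandmarkPair, WingImage
from .trends import SpecimenRecord

__all__ = [
    "SchemaError",
    "RowError",
    "read_specimens",
    "write_specimens",
    "read_pedigree",
    "write_pedigree",
    "read_landmarks",
    "write_landmarks",
    "load_wing_image",
    "save_wing_image",
]


class SchemaError(ValueError):
    """The file is missing required columns."""


class RowError(ValueError):
    """A data row is malformed; the message names the line number."""


_SPECIMEN_COLS = ["id", "year", "island_group", "white_rel"]


def read_specimens(path: str | Path, strict_range: bool = True) -> list[SpecimenRecord]:
    """Read and validate a specimen CSV.

    ``strict_range`` additionally enforces 0 <= white_rel <= 1 (the natural
    range of an area fraction); disable it for simulated series expressed
    in other units.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SPECIMEN_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records: list[SpecimenRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            year = int(row.year)
            white = float(row.white_rel)
            red = float(row.red_rel) if getattr(row, "red_rel", "") != "" else None
        except ValueError as exc:
            raise RowError(f"{path}: line {i}: non-numeric field ({exc})") from None
        if strict_range and not (0.0 <= white <= 1.0):
            raise RowError(f"{path}: line {i}: white_rel={white} outside [0, 1]")
        records.append(
            SpecimenRecord(
                id=str(row.id),
                year=year,
                island_group=str(row.island_group),
                white_rel=white,
                red_rel=red,
            )
        )
    return records


def write_specimens(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "year", "island_group", "white_rel", "red_rel"])
        for r in records:
            writer.writerow(
                [r.id, r.year, r.island_group, repr(r.white_rel),
                 "" if r.red_rel is None else repr(r.red_rel)]
            )


_PEDIGREE_COLS = ["id", "sex", "mother_id", "father_id", "generation", "white_rel", "red_rel"]


def read_pedigree(path: str | Path) -> Pedigree:
    """Read and fully validate a pedigree CSV (links, sexes, traits, cycles)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _PEDIGREE_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    ped = Pedigree()
    from .pedigree import Individual

    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            gen = int(row.generation)
            white = float(row.white_rel) if row.white_rel != "" else None
            red = float(row.red_rel) if row.red_rel != "" else None
        except ValueError as exc:
            raise RowError(f"{path}: line {i}: non-numeric field ({exc})") from None
        ped.add(
            Individual(
                id=str(row.id),
                sex=str(row.sex),
                mother_id=str(row.mother_id) or None,
                father_id=str(row.father_id) or None,
                generation=gen,
                white_rel=white,
                red_rel=red,
            )
        )
    ped.validate()
    return ped


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PEDIGREE_COLS)
        for ind in ped:
            writer.writerow(
                [
                    ind.id,
                    ind.sex,
                    ind.mother_id or "",
                    ind.father_id or "",
                    ind.generation,
                    "" if ind.white_rel is None else repr(ind.white_rel),
                    "" if ind.red_rel is None else repr(ind.red_rel),
                ]
            )


def write_landmarks(
    entries: Sequence[tuple[str, LandmarkPair]], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "x1", "y1", "x2", "y2"])
        for image_path, lm in entries:
            writer.writerow(
                [image_path, *(repr(v) for v in (*lm.landmark1, *lm.landmark2))]
            )


def read_landmarks(path: str | Path) -> dict[str, LandmarkPair]:
    df = pd.read_csv(path)
    missing = [c for c in ["image_path", "x1", "y1", "x2", "y2"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    out: dict[str, LandmarkPair] = {}
    for row in df.itertuples(index=False):
        out[str(row.image_path)] = LandmarkPair(
            (float(row.x1), float(row.y1)), (float(row.x2), float(row.y2))
        )
    return out


def load_wing_image(path: str | Path) -> WingImage:
    px = iio.imread(path)
    if px.ndim == 2:
        px = np.repeat(px[:, :, None], 3, axis=2)
    return WingImage(px[:, :, :3])


def save_wing_image(image: WingImage, path: str | Path) -> None:
    iio.imwrite(path, image.pixels)
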