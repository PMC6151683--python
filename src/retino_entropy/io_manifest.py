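"""Image and label I/O plus the dataset manifest.

Labels travel in the Kaggle diabetic-retinopathy dialect: a CSV with header
``image,level`` where ``image`` is an id without file extension and ``level``
is the International Clinical DR grade 0-4.  The manifest is the bookkeeping
unit of the package: one record per image with its id, file path, grade and
an interpretable-quality flag (quality grading is manual upstream; here it is
only consumed as a boolean).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

GRADES = (0, 1, 2, 3, 4)
#: grades that warrant specialist referral (referable DR)
REFERABLE_MIN_GRADE = 2

LABELS_HEADER = ("image", "level")


class ManifestError(ValueError):
    """Raised for malformed labels, duplicate ids or out-of-range grades."""


@dataclass(frozen=True)
class ManifestRecord:
    """One image in the dataset.

    ``source_id`` tracks augmentation provenance: for an image produced by a
    rotate/flip variant it names the original photograph, otherwise it equals
    ``id``.  ``interpretable`` carries the upstream photographic-quality call.
    """

    id: str
    grade: int
    path: Path | None = None
    interpretable: bool = True
    source_id: str = field(default="")

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ManifestError(f"grade {self.grade!r} of {self.id!r} not in 0-4")
        if not self.source_id:
            object.__setattr__(self, "source_id", self.id)

    @property
    def referable(self) -> bool:
        return self.grade >= REFERABLE_MIN_GRADE


def validate_manifest(records: list[ManifestRecord]) -> None:
    """Reject duplicate ids (grades are validated per record)."""
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ManifestError(f"duplicate id {r.id!r} in manifest")
        seen.add(r.id)


def read_labels_csv(path: str | Path) -> list[tuple[str, int]]:
    """Read a Kaggle-dialect label CSV into ``(id, grade)`` pairs.

    Raises :class:`ManifestError` on a missing/incorrect header or on a grade
    outside 0-4 (the offending row is named).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ManifestError(f"{path}: empty file, expected header image,level")
        if tuple(h.strip() for h in header[:2]) != LABELS_HEADER:
            raise ManifestError(
                f"{path}: bad header {header!r}, expected {','.join(LABELS_HEADER)}"
            )
        out: list[tuple[str, int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ManifestError(f"{path}:{lineno}: expected 2 columns, got {row!r}")
            image, level = row[0].strip(), row[1].strip()
            try:
                grade = int(level)
            except ValueError:
                raise ManifestError(f"{path}:{lineno}: non-integer level {level!r}")
            if grade not in GRADES:
                raise ManifestError(f"{path}:{lineno}: level {grade} outside 0-4")
            out.append((image, grade))
    return out


def write_labels_csv(records: list[tuple[str, int]] | list[ManifestRecord],
                     path: str | Path) -> None:
    """Write ``(id, grade)`` pairs (or records) sorted by id, Kaggle dialect."""
    if not records:
        raise ManifestError("refusing to write an empty label file")
    pairs = [(r.id, r.grade) if isinstance(r, ManifestRecord) else (r[0], int(r[1]))
             for r in records]
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ManifestError(f"duplicate ids in labels: {dupes[:5]}")
    for i, g in pairs:
        if g not in GRADES:
            raise ManifestError(f"level {g} for {i!r} outside 0-4")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LABELS_HEADER)
        for image, level in sorted(pairs):
            writer.writerow([image, level])


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as an H×W×3 uint8 array; grayscale is replicated."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except Exception as exc:  # Pillow raises a zoo of types for bad files
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return arr


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write an H×W or H×W×3 uint8 array as PNG (lossless)."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixels, got {arr.dtype}")
    Image.fromarray(arr).save(Path(path), format="PNG")


def manifest_from_labels(labels: list[tuple[str, int]],
                         image_dir: str | Path | None = None,
                         extensions: tuple[str, ...] = (".png", ".jpeg", ".jpg"),
                         interpretable: dict[str, bool] | None = None,
                         ) -> list[ManifestRecord]:
    """Build a manifest from label pairs, resolving ids against an image dir.

    Ids carry no extension; the first matching extension in ``extensions``
    wins.  With ``image_dir=None`` paths are left unresolved (in-memory use).
    """
    records = []
    for image_id, grade in labels:
        path = None
        if image_dir is not None:
            base = Path(image_dir)
            for ext in extensions:
                cand = base / f"{image_id}{ext}"
                if cand.exists():
                    path = cand
                    break
            if path is None:
                raise ManifestError(f"no image file for id {image_id!r} in {base}")
        flag = True if interpretable is None else interpretable.get(image_id, True)
        records.append(ManifestRecord(id=image_id, grade=grade, path=path,
                                      interpretable=flag))
    validate_manifest(records)
    return records


def with_grade(record: ManifestRecord, grade: int) -> ManifestRecord:
    return replace(record, grade=grade)
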