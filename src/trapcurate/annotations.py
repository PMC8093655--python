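"""PASCAL VOC bounding-box annotations and the dataset manifest.

Internal boxes use a 0-based, half-open pixel convention
``[xmin, xmax) x [ymin, ymax)`` so that widths and intersection/union
arithmetic need no ``+1`` corrections.  VOC XML on disk is 1-based and
inclusive; the conversion happens only at the I/O boundary:

    xmin_internal = xmin_voc - 1      xmax_internal = xmax_voc
    ymin_internal = ymin_voc - 1      ymax_internal = ymax_voc

A record with an empty object list is a *negative sample* -- an image
that contains no target-class animal.  Negatives matter for detector
evaluation because they contribute false-positive opportunities only.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("image_id", "path", "source_tag", "is_negative")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation data."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int

    def __post_init__(self) -> None:
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise AnnotationError(
                f"box ({self.xmin},{self.ymin},{self.xmax},{self.ymax}) "
                "has non-positive area"
            )

    @property
    def width(self) -> int:
        return self.xmax - self.xmin

    @property
    def height(self) -> int:
        return self.ymax - self.ymin

    @property
    def area(self) -> int:
        return self.width * self.height

    def shifted(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.xmin + dx, self.ymin + dy,
                           self.xmax + dx, self.ymax + dy)

    def clipped(self, width: int, height: int) -> "BoundingBox":
        """Clip to image bounds; raises if nothing is left."""
        xmin = max(0, self.xmin)
        ymin = max(0, self.ymin)
        xmax = min(width, self.xmax)
        ymax = min(height, self.ymax)
        if xmax <= xmin or ymax <= ymin:
            raise AnnotationError(
                f"box ({self.xmin},{self.ymin},{self.xmax},{self.ymax}) lies "
                f"entirely outside a {width}x{height} image"
            )
        return BoundingBox(xmin, ymin, xmax, ymax)


@dataclass(frozen=True)
class VocObject:
    """One annotated object: class label plus box and VOC flags.

    ``difficult`` and ``truncated`` are read and preserved but ignored by
    the evaluation module.
    """

    class_label: str
    box: BoundingBox
    difficult: bool = False
    truncated: bool = False


@dataclass(frozen=True)
class AnnotationSet:
    """All ground-truth objects for one image."""

    image_id: str
    width: int
    height: int
    objects: tuple[VocObject, ...] = ()

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise AnnotationError(
                f"{self.image_id}: image size {self.width}x{self.height} invalid"
            )
        object.__setattr__(self, "objects", tuple(self.objects))

    @property
    def is_negative(self) -> bool:
        return len(self.objects) == 0

    def class_labels(self) -> set[str]:
        return {o.class_label for o in self.objects}


@dataclass(frozen=True)
class ImageRecord:
    """One image in a dataset manifest."""

    image_id: str
    path: Path
    source_tag: str = ""
    is_negative: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", Path(self.path))


@dataclass
class DatasetManifest:
    """Validated collection of image records plus the class vocabulary."""

    records: list[ImageRecord] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise AnnotationError(f"duplicate image_ids in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.image_id for r in self.records]

    def by_id(self, image_id: str) -> ImageRecord:
        for r in self.records:
            if r.image_id == image_id:
                return r
        raise KeyError(image_id)

    def positives(self) -> list[ImageRecord]:
        return [r for r in self.records if not r.is_negative]

    def negatives(self) -> list[ImageRecord]:
        return [r for r in self.records if r.is_negative]

    def with_source(self, source_tag: str) -> list[ImageRecord]:
        return [r for r in self.records if r.source_tag == source_tag]


def _int_text(elem: ET.Element, tag: str, path: Path) -> int:
    child = elem.find(tag)
    if child is None or child.text is None:
        raise AnnotationError(f"{path}: missing <{tag}> element")
    # labelImg occasionally writes floats; truncate like the VOC devkit does
    return int(float(child.text))


def read_voc_xml(path: str | Path) -> AnnotationSet:
    """Read a PASCAL VOC XML annotation file (labelImg dialect).

    VOC coordinates are 1-based inclusive; they are converted to the
    internal 0-based half-open convention.  Boxes overflowing the image
    (common in hand-edited files) are clipped with a logged warning; a
    box with no area left after conversion raises :class:`AnnotationError`.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise AnnotationError(f"{path}: malformed XML ({exc})") from exc
    root = tree.getroot()

    size = root.find("size")
    if size is None:
        raise AnnotationError(f"{path}: missing <size> element")
    width = _int_text(size, "width", path)
    height = _int_text(size, "height", path)

    fname = root.findtext("filename") or path.name
    image_id = Path(fname).stem

    objects: list[VocObject] = []
    for obj in root.findall("object"):
        label = obj.findtext("name")
        if not label:
            raise AnnotationError(f"{path}: object without <name>")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationError(f"{path}: object '{label}' without <bndbox>")
        xmin = _int_text(bnd, "xmin", path) - 1
        ymin = _int_text(bnd, "ymin", path) - 1
        xmax = _int_text(bnd, "xmax", path)
        ymax = _int_text(bnd, "ymax", path)
        if xmax <= xmin or ymax <= ymin:
            raise AnnotationError(
                f"{path}: object '{label}' box has non-positive area "
                f"after conversion ({xmin},{ymin},{xmax},{ymax})"
            )
        box = BoundingBox(xmin, ymin, xmax, ymax)
        if box.xmin < 0 or box.ymin < 0 or box.xmax > width or box.ymax > height:
            clipped = box.clipped(width, height)
            log.warning("%s: clipped box %s -> %s", path, box, clipped)
            box = clipped
        objects.append(
            VocObject(
                class_label=label,
                box=box,
                difficult=(obj.findtext("difficult") or "0").strip() == "1",
                truncated=(obj.findtext("truncated") or "0").strip() == "1",
            )
        )
    return AnnotationSet(image_id=image_id, width=width, height=height,
                         objects=tuple(objects))


def write_voc_xml(ann: AnnotationSet, path: str | Path,
                  folder: str = "images", extension: str = ".png") -> Path:
    """Write an :class:`AnnotationSet` as PASCAL VOC XML.

    Internal half-open coordinates are converted back to the 1-based
    inclusive VOC convention, so ``read_voc_xml(write_voc_xml(a)) == a``.
    """
    path = Path(path)
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = folder
    ET.SubElement(root, "filename").text = ann.image_id + extension
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.width)
    ET.SubElement(size, "height").text = str(ann.height)
    ET.SubElement(size, "depth").text = "1"
    for obj in ann.objects:
        o = ET.SubElement(root, "object")
        ET.SubElement(o, "name").text = obj.class_label
        ET.SubElement(o, "pose").text = "Unspecified"
        ET.SubElement(o, "truncated").text = "1" if obj.truncated else "0"
        ET.SubElement(o, "difficult").text = "1" if obj.difficult else "0"
        b = ET.SubElement(o, "bndbox")
        ET.SubElement(b, "xmin").text = str(obj.box.xmin + 1)
        ET.SubElement(b, "ymin").text = str(obj.box.ymin + 1)
        ET.SubElement(b, "xmax").text = str(obj.box.xmax)
        ET.SubElement(b, "ymax").text = str(obj.box.ymax)
    ET.indent(root)
    tree = ET.ElementTree(root)
    path.parent.mkdir(parents=True, exist_ok=True)
    tree.write(path, encoding="unicode")
    return path


def load_manifest(path: str | Path,
                  annotations_dir: str | Path | None = None,
                  class_names: Sequence[str] = (),
                  source_vocabulary: Sequence[str] | None = None,
                  ) -> DatasetManifest:
    """Load the dataset manifest CSV (``image_id,path,source_tag,is_negative``).

    If ``annotations_dir`` is given, every non-negative record must have a
    ``<image_id>.xml`` annotation file there.  If ``source_vocabulary`` is
    given, every source_tag must be drawn from it.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: manifest missing columns {missing}")

    dupes = sorted(df.loc[df["image_id"].duplicated(), "image_id"].unique())
    if dupes:
        raise AnnotationError(f"{path}: duplicate image_ids {dupes}")

    records: list[ImageRecord] = []
    for row in df.itertuples(index=False):
        neg = str(row.is_negative).strip().lower() in ("1", "true", "yes")
        records.append(ImageRecord(image_id=row.image_id, path=Path(row.path),
                                   source_tag=row.source_tag, is_negative=neg))

    if source_vocabulary is not None:
        bad = sorted({r.source_tag for r in records}
                     - set(source_vocabulary))
        if bad:
            raise AnnotationError(
                f"{path}: source_tags {bad} not in declared vocabulary")

    if annotations_dir is not None:
        annotations_dir = Path(annotations_dir)
        absent = [r.image_id for r in records
                  if not r.is_negative
                  and not (annotations_dir / f"{r.image_id}.xml").exists()]
        if absent:
            raise AnnotationError(
                f"{path}: missing annotation files for non-negative records "
                f"{absent}")

    return DatasetManifest(records=records, class_names=list(class_names))


def save_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    """Write the manifest back to CSV (inverse of :func:`load_manifest`)."""
    path = Path(path)
    df = pd.DataFrame(
        [(r.image_id, str(r.path), r.source_tag, r.is_negative)
         for r in manifest.records],
        columns=list(MANIFEST_COLUMNS),
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_annotations(manifest: DatasetManifest,
                     annotations_dir: str | Path) -> dict[str, AnnotationSet]:
    """Read the VOC XML for every record; negatives get empty sets."""
    annotations_dir = Path(annotations_dir)
    out: dict[str, AnnotationSet] = {}
    for rec in manifest:
        xml = annotations_dir / f"{rec.image_id}.xml"
        if xml.exists():
            out[rec.image_id] = read_voc_xml(xml)
        elif rec.is_negative:
            # negatives may omit the XML entirely; size is unknown but unused
            out[rec.image_id] = AnnotationSet(rec.image_id, 1, 1, ())
        else:
            raise AnnotationError(f"missing annotation file {xml}")
        if not rec.is_negative and out[rec.image_id].is_negative:
            raise AnnotationError(
                f"{rec.image_id}: marked positive but annotation has no objects")
    return out
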