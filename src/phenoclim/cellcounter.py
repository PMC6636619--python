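"""Reading and writing ImageJ Cell Counter marker files.

The Cell Counter plugin saves one XML file per scored image.  Each marker
is a click at an (x, y) pixel position with a type number; type numbers
map onto phenophase classes (1 = bud ... 4 = mature fruit by default).
Counting markers per type yields the per-plant stage counts that feed the
phenological index.

Dialect (as written by the plugin)::

    <CellCounter_Marker_File>
      <Image_Properties><Image_Filename>...</Image_Filename></Image_Properties>
      <Marker_Data>
        <Marker_Type>
          <Type>1</Type>
          <Name>bud</Name>            <!-- optional -->
          <Marker><MarkerX>10</MarkerX><MarkerY>20</MarkerY><MarkerZ>1</MarkerZ></Marker>
          ...
        </Marker_Type>
      </Marker_Data>
    </CellCounter_Marker_File>

One file is taken to represent one plant; a sheet with several plants is
several files (or counts-table rows) sharing a ``sheet_id``.  Unknown
sibling elements are ignored so files from newer plugin versions still
parse.  Z coordinates are preserved but play no role in counting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence
from xml.etree import ElementTree as ET

import pandas as pd

from .core import PhenoclimError, PlantCounts, StageScheme, ValidationError, DEFAULT_SCHEME


class CellCounterFormatError(PhenoclimError):
    """Raised when an XML file is not in the Cell Counter dialect."""


class MarkerMappingError(PhenoclimError):
    """Raised when a marker type has no phenophase mapping."""


#: Default marker-type -> phenophase mapping matching the plugin's 1..4 labels.
DEFAULT_TYPE_MAP: dict[int, str] = {1: "bud", 2: "flower", 3: "immature_fruit", 4: "mature_fruit"}


@dataclass(frozen=True)
class Marker:
    x: int
    y: int
    z: int = 1


@dataclass
class MarkerTypeGroup:
    type_number: int
    name: str | None = None
    markers: list[Marker] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.markers)


@dataclass
class MarkerFile:
    image_filename: str = ""
    marker_types: list[MarkerTypeGroup] = field(default_factory=list)

    def validate(self) -> None:
        numbers = [g.type_number for g in self.marker_types]
        if len(set(numbers)) != len(numbers):
            raise ValidationError(f"duplicate marker type numbers: {numbers}")
        if any(n <= 0 for n in numbers):
            raise ValidationError(f"marker type numbers must be positive: {numbers}")

    @property
    def total_markers(self) -> int:
        return sum(g.count for g in self.marker_types)


def read_marker_file(path: str | os.PathLike) -> MarkerFile:
    """Parse a Cell Counter XML file.

    Raises ``FileNotFoundError`` for a missing file and
    :class:`CellCounterFormatError` when the ``Marker_Data`` element is
    absent (the file is not in the Cell Counter dialect).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such marker file: {path}")
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise CellCounterFormatError(f"{path}: not well-formed XML ({exc})") from exc
    root = tree.getroot()
    marker_data = root.find("Marker_Data")
    if marker_data is None:
        raise CellCounterFormatError(
            f"{path}: missing <Marker_Data> element — not a Cell Counter marker file"
        )
    image_filename = root.findtext("Image_Properties/Image_Filename", default="") or ""

    groups: list[MarkerTypeGroup] = []
    for mt in marker_data.findall("Marker_Type"):
        type_text = mt.findtext("Type")
        if type_text is None:
            raise CellCounterFormatError(f"{path}: <Marker_Type> without <Type> child")
        group = MarkerTypeGroup(type_number=int(type_text), name=mt.findtext("Name"))
        for m in mt.findall("Marker"):
            group.markers.append(
                Marker(
                    x=int(m.findtext("MarkerX", default="0")),
                    y=int(m.findtext("MarkerY", default="0")),
                    z=int(m.findtext("MarkerZ", default="1")),
                )
            )
        groups.append(group)
    mf = MarkerFile(image_filename=image_filename, marker_types=groups)
    mf.validate()
    return mf


def write_marker_file(mf: MarkerFile, path: str | os.PathLike) -> None:
    """Serialise ``mf`` in the dialect the ImageJ plugin reads back."""
    mf.validate()
    root = ET.Element("CellCounter_Marker_File")
    props = ET.SubElement(root, "Image_Properties")
    ET.SubElement(props, "Image_Filename").text = mf.image_filename
    data = ET.SubElement(root, "Marker_Data")
    for group in mf.marker_types:
        mt = ET.SubElement(data, "Marker_Type")
        ET.SubElement(mt, "Type").text = str(group.type_number)
        if group.name is not None:
            ET.SubElement(mt, "Name").text = group.name
        for marker in group.markers:
            m = ET.SubElement(mt, "Marker")
            ET.SubElement(m, "MarkerX").text = str(marker.x)
            ET.SubElement(m, "MarkerY").text = str(marker.y)
            ET.SubElement(m, "MarkerZ").text = str(marker.z)
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def markers_to_counts(
    mf: MarkerFile,
    scheme: StageScheme = DEFAULT_SCHEME,
    type_map: Mapping[int, str] | None = None,
    *,
    sheet_id: str = "",
    plant_id: str = "",
) -> PlantCounts:
    """Total markers per phenophase class.

    Two type numbers mapped to the same class sum; classes with no markers
    get 0.  A type number absent from ``type_map`` raises
    :class:`MarkerMappingError`.
    """
    if type_map is None:
        type_map = DEFAULT_TYPE_MAP
    orphans = sorted(g.type_number for g in mf.marker_types if g.type_number not in type_map)
    if orphans:
        raise MarkerMappingError(
            f"marker type(s) {orphans} have no phenophase mapping "
            f"(mapped types: {sorted(type_map)})"
        )
    bad = sorted(set(type_map.values()) - set(scheme.names))
    if bad:
        raise MarkerMappingError(f"type map targets unknown to the scheme: {bad}")
    counts = {name: 0 for name in scheme.names}
    for group in mf.marker_types:
        counts[type_map[group.type_number]] += group.count
    return PlantCounts(sheet_id=sheet_id, plant_id=plant_id, counts=counts)


# ---------------------------------------------------------------------------
# Tabular counts


def read_counts_table(
    path: str | os.PathLike, scheme: StageScheme = DEFAULT_SCHEME
) -> list[PlantCounts]:
    """Read per-plant counts from CSV (``sheet_id,plant_id,<class columns>``)."""
    df = pd.read_csv(path, dtype={"sheet_id": str, "plant_id": str})
    missing = [c for c in ("sheet_id", "plant_id", *scheme.names) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: counts table is missing columns {missing}")
    out: list[PlantCounts] = []
    for i, row in df.iterrows():
        counts = {}
        for name in scheme.names:
            v = row[name]
            if pd.isna(v) or float(v) != int(v) or int(v) < 0:
                raise ValidationError(
                    f"{path} row {i}: class {name!r} count must be a non-negative "
                    f"integer, got {v!r}"
                )
            counts[name] = int(v)
        out.append(PlantCounts(sheet_id=row["sheet_id"], plant_id=row["plant_id"], counts=counts))
    return out


def counts_to_frame(
    counts: Sequence[PlantCounts], scheme: StageScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Tabulate counts in the CSV contract's column order."""
    rows = []
    for pc in counts:
        pc.validate_against(scheme)
        rows.append({"sheet_id": pc.sheet_id, "plant_id": pc.plant_id, **{
            name: pc.counts[name] for name in scheme.names
        }})
    return pd.DataFrame(rows, columns=["sheet_id", "plant_id", *scheme.names])


def write_counts_table(
    counts: Sequence[PlantCounts], path: str | os.PathLike, scheme: StageScheme = DEFAULT_SCHEME
) -> None:
    counts_to_frame(counts, scheme).to_csv(path, index=False)
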