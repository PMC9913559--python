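"""Nodule annotation records and the XML annotation reader.

The reader targets a minimal LIDC-like XML dialect (documented in
docs/annotation_schema.md) and tolerates namespaced LIDC-style element names
by matching on local names.  When an exam carries several readers, the one
who identified the most lesions is kept, mirroring common practice for
avoiding duplicate nodules across readers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from lxml import etree


@dataclass
class NoduleAnnotation:
    nodule_id: str
    center: tuple[float, float, float]  # (z, y, x)
    diameter_mm: float
    malignancy_grade: int
    solid: bool = True
    reader_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.malignancy_grade <= 5):
            raise ValueError(
                f"malignancy grade {self.malignancy_grade} outside 1-5"
            )
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _find_text(el, *names):
    for child in el.iter():
        if _local(child.tag) in names and child.text is not None:
            return child.text.strip()
    return None


def read_annotations(source) -> list[NoduleAnnotation]:
    """Parse nodule annotations from an XML file path or bytes.

    Reader sessions (``<reader>`` or LIDC ``<readingSession>``) are compared
    by nodule count and only the most prolific reader's annotations are
    returned.  Records with a missing or out-of-range malignancy are skipped
    with a warning; malformed XML raises a parse error carrying the line
    number.
    """
    try:
        if isinstance(source, (bytes, str)) and (
            isinstance(source, bytes) or source.lstrip().startswith("<")
        ):
            root = etree.fromstring(
                source.encode() if isinstance(source, str) else source
            )
        else:
            root = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError:
        raise

    sessions = [
        el for el in root.iter()
        if _local(el.tag) in {"reader", "readingSession"}
    ]
    if not sessions:
        sessions = [root]

    per_reader: list[list[NoduleAnnotation]] = []
    for si, session in enumerate(sessions):
        reader_id = (
            session.get("id")
            or _find_text(session, "servicingRadiologistID")
            or f"reader{si}"
        )
        anns: list[NoduleAnnotation] = []
        for nod in session.iter():
            if _local(nod.tag) not in {"nodule", "unblindedReadNodule"}:
                continue
            nodule_id = (
                nod.get("id") or _find_text(nod, "noduleID") or "?"
            )
            mal_text = _find_text(nod, "malignancy")
            if mal_text is None:
                warnings.warn(
                    f"nodule {nodule_id}: missing malignancy, skipped",
                    RuntimeWarning, stacklevel=2,
                )
                continue
            grade = int(float(mal_text))
            if not (1 <= grade <= 5):
                warnings.warn(
                    f"nodule {nodule_id}: malignancy {grade} outside 1-5, "
                    "skipped",
                    RuntimeWarning, stacklevel=2,
                )
                continue
            center_el = next(
                (c for c in nod.iter() if _local(c.tag) == "center"), None
            )
            if center_el is not None:
                center = tuple(
                    float(center_el.get(ax, "0")) for ax in ("z", "y", "x")
                )
            else:
                z = _find_text(nod, "imageZposition") or "0"
                y = _find_text(nod, "yCoord") or "0"
                x = _find_text(nod, "xCoord") or "0"
                center = (float(z), float(y), float(x))
            diam = float(_find_text(nod, "diameter_mm", "diameter") or "0")
            solid_text = (_find_text(nod, "solid") or "true").lower()
            anns.append(
                NoduleAnnotation(
                    nodule_id=nodule_id, center=center,
                    diameter_mm=diam if diam > 0 else 1.0,
                    malignancy_grade=grade,
                    solid=solid_text in {"true", "1", "yes"},
                    reader_id=reader_id,
                )
            )
        per_reader.append(anns)
    if not per_reader:
        return []
    return max(per_reader, key=len)
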