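"""Frame-level behavior annotation parsing.

Annotation files carry one behavior label per frame, either as plain text
(one label per line) or as delimited columns (the label in a ``label`` /
``behavior`` column, or the last column when there is no header).  The
delimiter and header are auto-detected.  Labels outside the five retained
behaviors are kept in the track but flagged non-retained so downstream frame
extraction can drop them; spelling variants are normalized through a label
map (case-insensitive canonical names by default, user-extensible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ..model.network import CLASS_NAMES

CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}

# spelling variants observed in the wild map onto the canonical names
DEFAULT_LABEL_MAP = {
    "social nose contact": "Social Nose Contact",
    "nose contact": "Social Nose Contact",
    "contact": "Social Nose Contact",
    "moving away": "Moving Away",
    "move away": "Moving Away",
    "approaching": "Approaching",
    "following": "Following",
    "solitary": "Solitary",
}


class AnnotationError(ValueError):
    """Unreadable, empty or malformed annotation input."""


@dataclass
class AnnotationTrack:
    video_id: str
    labels: list[str]                   # normalized label per frame (0-based index)
    vocabulary: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.labels)

    def retained_mask(self) -> list[bool]:
        return [lab in CLASS_INDEX for lab in self.labels]

    def retained_count(self) -> int:
        return sum(self.retained_mask())

    def class_indices(self) -> list[int | None]:
        return [CLASS_INDEX.get(lab) for lab in self.labels]


def normalize_label(raw: str, label_map: dict[str, str] | None = None) -> str:
    key = raw.strip().lower()
    if label_map and key in {k.lower() for k in label_map}:
        merged = {k.lower(): v for k, v in label_map.items()}
        return merged[key]
    return DEFAULT_LABEL_MAP.get(key, raw.strip())


def _detect_dialect(lines: list[str]) -> tuple[str | None, bool]:
    """Return (delimiter or None, has_header)."""
    first = lines[0]
    delimiter = None
    for cand in (",", "\t", ";"):
        if cand in first:
            delimiter = cand
            break
    header = False
    if delimiter is not None:
        cells = [c.strip().lower() for c in first.split(delimiter)]
        header = any(c in ("label", "behavior", "behaviour", "frame", "class") for c in cells)
    return delimiter, header


def parse_annotations(
    path: Path | str,
    video_id: str | None = None,
    label_map: dict[str, str] | None = None,
) -> AnnotationTrack:
    """Parse an annotation file into a per-frame label track."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise AnnotationError(f"cannot read annotation file {path}: {exc}") from exc
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise AnnotationError(f"annotation file {path} is empty")
    delimiter, header = _detect_dialect(lines)
    label_col: int | None = None
    if header:
        cells = [c.strip().lower() for c in lines[0].split(delimiter)]
        for cand in ("label", "behavior", "behaviour", "class"):
            if cand in cells:
                label_col = cells.index(cand)
                break
        if label_col is None:
            raise AnnotationError(
                f"{path}: header line {lines[0]!r} has no label/behavior column"
            )
        lines = lines[1:]
        if not lines:
            raise AnnotationError(f"annotation file {path} has a header but no rows")
    labels: list[str] = []
    vocabulary: set[str] = set()
    for lineno, line in enumerate(lines, start=2 if header else 1):
        if delimiter is not None:
            cells = [c.strip() for c in line.split(delimiter)]
            raw = cells[label_col if label_col is not None else -1]
        else:
            raw = line.strip()
        if not raw:
            raise AnnotationError(f"{path}: empty label on line {lineno}")
        vocabulary.add(raw)
        labels.append(normalize_label(raw, label_map))
    return AnnotationTrack(video_id or path.stem, labels, vocabulary)
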