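"""Landmark template for the full human ribcage.

The measurement protocol is a fixed template of 526 (semi)landmarks covering
the 12 thoracic vertebrae, 24 ribs and the sternum.  The per-structure
composition used here is:

* 12 vertebrae x 4 vertebral-body corner points
  (anterior-superior/inferior, posterior-superior/inferior)      =  48
* 24 ribs x 19 points (head, tubercle, sternal end + 16 curve
  semilandmarks equally spaced in arc angle)                     = 456
* sternum: 22 midline points                                     =  22

which sums to 526.  The analysis subset drops ribs 11 and 12 bilaterally
(4 x 19 points), leaving 450 points.

Coordinate convention: units are mm, axes right-handed with +x left lateral,
+y ventral, +z cranial.  The midsagittal plane is x = 0 and mirroring is
x -> -x combined with swapping bilaterally paired labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: reflection matrix implementing the anatomical mirror (about x = 0)
MIRROR_MATRIX = np.diag([-1.0, 1.0, 1.0])

VERTEBRAL_LEVELS = tuple(f"T{i}" for i in range(1, 13))
VERTEBRAL_CORNERS = ("as", "ai", "ps", "pi")  # ant/post x sup/inf body corners
RIB_NUMBERS = tuple(range(1, 13))
N_RIB_POINTS = 19
N_STERNUM_POINTS = 22

FULL_TEMPLATE_SIZE = 526
ANALYSIS_TEMPLATE_SIZE = 450


@dataclass(frozen=True)
class TemplateEntry:
    """One named point of the template."""

    label: str
    element: str          # "T1".."T12", "rib<i>_L"/"rib<i>_R", "sternum"
    role: str             # "landmark" | "semilandmark"
    mirror_label: str     # bilateral partner; own label for midline points


@dataclass(frozen=True)
class Template:
    """Ordered landmark definitions with bilateral pairing.

    Canonical element order is vertebrae T1->T12, then ribs 1->12 (left
    before right), then sternum.  Labels are unique and the mirror pairing
    is an involution.
    """

    entries: tuple[TemplateEntry, ...]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("template labels must be unique")
        index = {lab: i for i, lab in enumerate(labels)}
        for e in self.entries:
            if e.mirror_label not in index:
                raise ValueError(f"mirror label {e.mirror_label!r} of "
                                 f"{e.label!r} not in template")
        for e in self.entries:
            partner = self.entries[index[e.mirror_label]]
            if partner.mirror_label != e.label:
                raise ValueError(f"mirror pairing of {e.label!r} is not an "
                                 "involution")
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)

    def index_of(self, label: str) -> int:
        return self._index[label]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def entry(self, label: str) -> TemplateEntry:
        return self.entries[self._index[label]]

    def mirror_permutation(self) -> np.ndarray:
        """Row permutation sending each point to its bilateral partner."""
        return np.array([self._index[e.mirror_label] for e in self.entries])

    def midline_mask(self) -> np.ndarray:
        """True for points that are their own mirror image."""
        return np.array([e.mirror_label == e.label for e in self.entries])

    def labels_for_element(self, element: str) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries if e.element == element)

    def subset(self, labels: Iterable[str]) -> "Template":
        """Template restricted to ``labels``, canonical order preserved.

        The mirror partner of every retained lateral point must also be
        retained.
        """
        keep = set(labels)
        unknown = keep - set(self._index)
        if unknown:
            raise KeyError(f"labels not in template: {sorted(unknown)[:5]}")
        for lab in keep:
            if self.entry(lab).mirror_label not in keep:
                raise ValueError(f"subset breaks mirror pairing at {lab!r}")
        return Template(tuple(e for e in self.entries if e.label in keep))

    def drop_ribs(self, numbers: Sequence[int]) -> "Template":
        drop = {f"rib{n}_{side}" for n in numbers for side in ("L", "R")}
        return Template(tuple(e for e in self.entries
                              if e.element not in drop))


def _rib_point_names() -> list[str]:
    return (["head", "tub", "stern"]
            + [f"c{j:02d}" for j in range(1, N_RIB_POINTS - 2)])


def default_template() -> Template:
    """The packaged 526-point full-ribcage template."""
    entries: list[TemplateEntry] = []
    for lvl in VERTEBRAL_LEVELS:
        for corner in VERTEBRAL_CORNERS:
            lab = f"{lvl}_{corner}"
            entries.append(TemplateEntry(lab, lvl, "landmark", lab))
    rib_points = _rib_point_names()
    for n in RIB_NUMBERS:
        for side, other in (("L", "R"), ("R", "L")):
            for pt in rib_points:
                role = "landmark" if pt in ("head", "tub", "stern") \
                    else "semilandmark"
                entries.append(TemplateEntry(
                    f"rib{n}_{side}_{pt}", f"rib{n}_{side}", role,
                    f"rib{n}_{other}_{pt}"))
    for j in range(1, N_STERNUM_POINTS + 1):
        lab = f"sternum_{j:02d}"
        role = "landmark" if j in (1, N_STERNUM_POINTS) else "semilandmark"
        entries.append(TemplateEntry(lab, "sternum", role, lab))
    return Template(tuple(entries))


def analysis_template() -> Template:
    """Default template with the floating ribs (11-12) removed: 450 points."""
    return default_template().drop_ribs((11, 12))
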