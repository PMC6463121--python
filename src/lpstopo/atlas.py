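"""84-ROI cortical atlas: 42 Brodmann areas x 2 hemispheres.

The source-space parcellation used throughout the pipeline assigns one ROI
per Brodmann area (BA) and hemisphere.  ROI ordering is fixed and documented:
indices 0..41 are the left-hemisphere BAs in ascending BA number, 42..83 the
right-hemisphere BAs in the same order.  All serialized matrices and tables
use the ``label`` field (e.g. ``BA17_L``) so files remain self-describing.

BA13 (insular cortex) does not fit the five-way lobe scheme used here
(frontal / parietal / temporal / occipital / limbic); it is grouped with the
limbic label, the conventional bucket for sub-lobar cortex in five-lobe
reductions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = ["Roi", "Atlas", "default_atlas", "BRODMANN_AREAS", "N_ROIS"]

#: The 42 Brodmann areas of the parcellation, ascending.
BRODMANN_AREAS: tuple[int, ...] = (
    1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 13, 17, 18, 19, 20, 21, 22, 23, 24,
    25, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39, 40, 41, 42, 43,
    44, 45, 46, 47,
)

N_ROIS = 2 * len(BRODMANN_AREAS)

_LOBE_BY_BA: dict[int, str] = {}
for _ba in (4, 6, 8, 9, 10, 11, 44, 45, 46, 47):
    _LOBE_BY_BA[_ba] = "frontal"
for _ba in (1, 2, 3, 5, 7, 39, 40, 43):
    _LOBE_BY_BA[_ba] = "parietal"
for _ba in (20, 21, 22, 37, 38, 41, 42):
    _LOBE_BY_BA[_ba] = "temporal"
for _ba in (17, 18, 19):
    _LOBE_BY_BA[_ba] = "occipital"
for _ba in (13, 23, 24, 25, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36):
    _LOBE_BY_BA[_ba] = "limbic"

assert set(_LOBE_BY_BA) == set(BRODMANN_AREAS)


@dataclass(frozen=True)
class Roi:
    """One region of interest: a (Brodmann area, hemisphere) pair."""

    index: int
    brodmann_area: int
    hemisphere: str  # "L" or "R"
    lobe: str

    @property
    def label(self) -> str:
        return f"BA{self.brodmann_area}_{self.hemisphere}"


@dataclass(frozen=True)
class Atlas:
    """Ordered collection of the 84 ROIs."""

    rois: tuple[Roi, ...]

    def __post_init__(self) -> None:
        if len(self.rois) != N_ROIS:
            raise ValueError(f"atlas must have {N_ROIS} ROIs, got {len(self.rois)}")
        if [r.index for r in self.rois] != list(range(N_ROIS)):
            raise ValueError("ROI indices must be 0..83 in order")
        pairs = {(r.brodmann_area, r.hemisphere) for r in self.rois}
        if len(pairs) != N_ROIS:
            raise ValueError("duplicate (BA, hemisphere) pair in atlas")

    def __len__(self) -> int:
        return N_ROIS

    def __iter__(self) -> Iterator[Roi]:
        return iter(self.rois)

    def __getitem__(self, index: int) -> Roi:
        return self.rois[index]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rois]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown ROI label {label!r}") from None

    def indices_by_lobe(self, lobe: str, hemisphere: str | None = None) -> list[int]:
        """ROI indices with the given lobe label, optionally one hemisphere."""
        return [
            r.index
            for r in self.rois
            if r.lobe == lobe and (hemisphere is None or r.hemisphere == hemisphere)
        ]


def default_atlas() -> Atlas:
    """Build the canonical 84-ROI atlas.

    Left hemisphere first (indices 0..41, BAs ascending), then right
    (42..83, same BA order).
    """
    rois = []
    for h_i, hemi in enumerate(("L", "R")):
        for b_i, ba in enumerate(BRODMANN_AREAS):
            idx = h_i * len(BRODMANN_AREAS) + b_i
            rois.append(Roi(index=idx, brodmann_area=ba, hemisphere=hemi, lobe=_LOBE_BY_BA[ba]))
    return Atlas(rois=tuple(rois))
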