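"""Cortical parcellation bookkeeping.

The pipeline operates on a fixed 68-region cortical parcellation
(34 gyral/sulcal regions per hemisphere) in a frozen canonical order:
left-hemisphere regions alphabetically, then right. Region identity,
short codes, lobe membership and cortical class are shipped as a
versioned data file and loaded here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

N_REGIONS = 68
N_EDGES = N_REGIONS * (N_REGIONS - 1) // 2  # 2278 unique region pairs

LOBES = frozenset({"frontal", "temporal", "parietal", "occipital", "cingulate", "insula"})
CLASSES = frozenset({"primary", "association", "paralimbic"})


@dataclass(frozen=True)
class RegionAtlas:
    """Frozen region table: names, short codes, lobes and cortical classes.

    ``names`` are FreeSurfer-style identifiers (``lh_bankssts`` ...),
    ``abbrevs`` the short codes used in reports (``BSTS_L`` ...). The
    order of both is the canonical region order used everywhere in the
    pipeline: position in these tuples is the region index.
    """

    names: tuple[str, ...]
    abbrevs: tuple[str, ...]
    hemispheres: tuple[str, ...]
    lobes: tuple[str, ...]
    classes: tuple[str, ...]
    _name_index: dict[str, int] = field(default_factory=dict, repr=False)
    _abbrev_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != N_REGIONS:
            raise ValueError(f"atlas must have {N_REGIONS} regions, got {len(self.names)}")
        for attr in ("abbrevs", "hemispheres", "lobes", "classes"):
            if len(getattr(self, attr)) != N_REGIONS:
                raise ValueError(f"atlas field {attr!r} length mismatch")
        if len(set(self.abbrevs)) != N_REGIONS:
            raise ValueError("region abbreviations are not unique")
        if not set(self.lobes) <= LOBES:
            raise ValueError(f"unknown lobe labels: {set(self.lobes) - LOBES}")
        if not set(self.classes) <= CLASSES:
            raise ValueError(f"unknown class labels: {set(self.classes) - CLASSES}")
        # left and right halves must mirror region-for-region
        half = N_REGIONS // 2
        for i in range(half):
            left, right = self.names[i], self.names[half + i]
            if left.removeprefix("lh_") != right.removeprefix("rh_"):
                raise ValueError(f"hemispheres do not mirror: {left!r} vs {right!r}")
        object.__setattr__(self, "_name_index", {n: i for i, n in enumerate(self.names)})
        object.__setattr__(self, "_abbrev_index", {a: i for i, a in enumerate(self.abbrevs)})

    def __len__(self) -> int:
        return N_REGIONS

    def index_of(self, region: str) -> int:
        """Region index from either the full name or the short code."""
        if region in self._name_index:
            return self._name_index[region]
        if region in self._abbrev_index:
            return self._abbrev_index[region]
        raise KeyError(f"unknown region {region!r}")

    def lobe_of(self, region: str) -> str:
        return self.lobes[self.index_of(region)]

    def class_of(self, region: str) -> str:
        return self.classes[self.index_of(region)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "abbrev": self.abbrevs,
                "hemisphere": self.hemispheres,
                "lobe": self.lobes,
                "class": self.classes,
            }
        )


def _data_path(filename: str):
    return resources.files("morphnet.data").joinpath(filename)


def load_atlas() -> RegionAtlas:
    """Load the packaged 68-region atlas in canonical order."""
    with resources.as_file(_data_path("dk_atlas.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return RegionAtlas(
        names=tuple(df["name"]),
        abbrevs=tuple(df["abbrev"]),
        hemispheres=tuple(df["hemisphere"]),
        lobes=tuple(df["lobe"]),
        classes=tuple(df["class"]),
    )


def load_centroids() -> pd.DataFrame:
    """Schematic per-region coordinates used only for viewer file export.

    These are a deterministic lobe-anchored layout, not measured
    stereotaxic coordinates.
    """
    with resources.as_file(_data_path("dk_centroids.tsv")) as path:
        return pd.read_csv(path, sep="\t")
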