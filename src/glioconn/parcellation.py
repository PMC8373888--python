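"""Atlas region set, hemisphere coding and edge-compartment classification.

The analyses operate on a fixed cortical/subcortical parcellation (246
regions by default, Brainnetome-style) in which region labels are 1-based
and hemispheres interleave: odd labels are left-hemispheric, even labels
right-hemispheric.  Every unordered pair of distinct regions falls into
exactly one of three compartments — within the left hemisphere, within the
right hemisphere, or interhemispheric — which are the units over which
connectivity is later averaged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

LEFT = "left"
RIGHT = "right"

_ATLAS_COLUMNS = ("region_id", "region_name", "hemisphere", "dmn_member")


class EdgeCompartment(str, enum.Enum):
    """One of the three hemispheric edge compartments."""

    INTRA_LEFT = "intra_left"
    INTRA_RIGHT = "intra_right"
    INTERHEMISPHERIC = "interhemispheric"


class AtlasError(ValueError):
    """Raised for invalid atlas definitions or region lookups."""


@dataclass(frozen=True)
class AtlasDefinition:
    """A parcellation: region ids, names, hemispheres and DMN membership.

    ``table`` has columns ``region_id, region_name, hemisphere, dmn_member``.
    Row order is ascending region id and defines matrix storage order.  A
    full atlas has contiguous ids 1..R; a sub-atlas (e.g. the DMN restriction)
    keeps the original ids, so positional row index — not the id — addresses
    matrix rows.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _ATLAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise AtlasError(f"atlas table lacks columns: {missing}")
        ids = self.table["region_id"].to_numpy()
        if len(ids) == 0:
            raise AtlasError("atlas table is empty")
        if len(np.unique(ids)) != len(ids):
            raise AtlasError("region_ids are not unique")
        if not np.all(np.diff(ids) > 0):
            raise AtlasError("atlas rows must be sorted by ascending region_id")
        bad = set(self.table["hemisphere"]) - {LEFT, RIGHT}
        if bad:
            raise AtlasError(f"unknown hemisphere labels: {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def is_left(self) -> np.ndarray:
        return self.hemispheres == LEFT

    @property
    def dmn_member(self) -> np.ndarray:
        return self.table["dmn_member"].to_numpy().astype(bool)

    @property
    def is_contiguous(self) -> bool:
        ids = self.region_ids
        return ids[0] == 1 and ids[-1] == len(ids)

    def index_of(self, region_id: int) -> int:
        """Positional row index of a region id (matrix row/column index)."""
        pos = np.searchsorted(self.region_ids, region_id)
        if pos >= self.n_regions or self.region_ids[pos] != region_id:
            raise AtlasError(f"region id {region_id} not in atlas")
        return int(pos)


def hemisphere_of(region_id: int, atlas: AtlasDefinition | None = None,
                  n_regions: int = 246) -> str:
    """Hemisphere of a region: odd id -> left, even id -> right.

    With an ``atlas`` the stored hemisphere column is authoritative (it may
    override the default odd/even coding for non-default parcellations).
    """
    if atlas is not None:
        return str(atlas.table.iloc[atlas.index_of(region_id)]["hemisphere"])
    region_id = int(region_id)
    if not 1 <= region_id <= n_regions:
        raise AtlasError(
            f"region id {region_id} outside valid range 1..{n_regions}")
    return LEFT if region_id % 2 == 1 else RIGHT


def classify_edge(i: int, j: int, atlas: AtlasDefinition) -> EdgeCompartment:
    """Compartment of the unordered region pair (i, j); symmetric in (i, j)."""
    if i == j:
        raise AtlasError(f"self-edge ({i}, {i}): self-edges are excluded")
    hi = hemisphere_of(i, atlas)
    hj = hemisphere_of(j, atlas)
    if hi != hj:
        return EdgeCompartment.INTERHEMISPHERIC
    return (EdgeCompartment.INTRA_LEFT if hi == LEFT
            else EdgeCompartment.INTRA_RIGHT)


# integer codes used in the vectorized compartment matrix
CODE_INTRA_LEFT = 0
CODE_INTRA_RIGHT = 1
CODE_INTER = 2
CODE_DIAGONAL = -1

_CODE_TO_COMPARTMENT = {
    CODE_INTRA_LEFT: EdgeCompartment.INTRA_LEFT,
    CODE_INTRA_RIGHT: EdgeCompartment.INTRA_RIGHT,
    CODE_INTER: EdgeCompartment.INTERHEMISPHERIC,
}


def compartment_codes(atlas: AtlasDefinition) -> np.ndarray:
    """R x R int8 matrix of compartment codes (-1 on the diagonal)."""
    left = atlas.is_left
    # 0 both-left, 1 both-right, 2 mixed
    codes = np.where(left[:, None] & left[None, :], CODE_INTRA_LEFT,
                     np.where(~left[:, None] & ~left[None, :],
                              CODE_INTRA_RIGHT, CODE_INTER)).astype(np.int8)
    np.fill_diagonal(codes, CODE_DIAGONAL)
    return codes


def dmn_subatlas(atlas: AtlasDefinition) -> AtlasDefinition:
    """Restrict the atlas to its default-mode-network members.

    Hemisphere labels and original region ids are preserved, so downstream
    operations accept the restricted atlas unchanged.  Idempotent.
    """
    members = atlas.dmn_member
    if not members.any():
        raise AtlasError("DMN member set is empty; set dmn_member flags")
    sub = atlas.table.loc[members].reset_index(drop=True)
    for hemi in (LEFT, RIGHT):
        if (sub["hemisphere"] == hemi).sum() < 2:
            raise AtlasError(
                f"DMN restriction needs >= 2 regions in the {hemi} hemisphere")
    return AtlasDefinition(sub)


def default_atlas() -> AtlasDefinition:
    """The packaged 246-region atlas (odd/even hemisphere coding)."""
    with resources.files("glioconn.data").joinpath(
            "brainnetome246.csv").open("r") as fh:
        return load_atlas(fh)


def load_atlas(path_or_buffer) -> AtlasDefinition:
    """Read an atlas CSV: ``region_id,region_name,hemisphere,dmn_member``."""
    table = pd.read_csv(path_or_buffer)
    missing = [c for c in _ATLAS_COLUMNS if c not in table.columns]
    if missing:
        raise AtlasError(f"atlas CSV lacks columns: {missing}")
    table["region_id"] = table["region_id"].astype(int)
    table["dmn_member"] = table["dmn_member"].astype(int)
    table = table.sort_values("region_id").reset_index(drop=True)
    return AtlasDefinition(table[list(_ATLAS_COLUMNS)])


def make_atlas(n_regions: int, dmn_region_ids=None) -> AtlasDefinition:
    """Construct a generic odd/even-coded atlas with ``n_regions`` regions.

    Used for reduced-size simulations.  ``dmn_region_ids`` optionally flags
    DMN members; by default the middle fifth of region pairs is flagged so a
    DMN restriction is always available.
    """
    if n_regions < 4 or n_regions % 2:
        raise AtlasError("n_regions must be an even integer >= 4")
    ids = np.arange(1, n_regions + 1)
    if dmn_region_ids is None:
        n_pairs = n_regions // 2
        lo, hi = int(0.4 * n_pairs), int(0.6 * n_pairs)
        hi = max(hi, lo + 2)
        pair_idx = np.arange(lo, hi)
        dmn_region_ids = np.concatenate([2 * pair_idx + 1, 2 * pair_idx + 2])
    dmn = np.isin(ids, np.asarray(list(dmn_region_ids)))
    table = pd.DataFrame({
        "region_id": ids,
        "region_name": [f"ROI_{i:03d}_{'L' if i % 2 else 'R'}" for i in ids],
        "hemisphere": [LEFT if i % 2 else RIGHT for i in ids],
        "dmn_member": dmn.astype(int),
    })
    return AtlasDefinition(table)
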