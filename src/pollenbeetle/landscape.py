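"""Torus landscape, crop rotation, sowing and oilseed-rape phenology.

The landscape is a grid of 1-ha cells (default 10x10) wrapped into a torus.
Cells are one of four kinds: ARABLE fields (grow oilseed rape, OSR, once in a
strict 4-year rotation, a non-host crop otherwise), non-crop REFUGE cells
(wild host plants all year), OVERWINTER habitats (woodland; host-free), and
EMPTY cells.  The default composition is 80/10/5/5.

Each arable cell carries a rotation phase in {0,1,2,3}; it grows OSR exactly
in years with ``year % 4 == phase``, so about a quarter of the arable area is
OSR each year.  The OSR type is spring-sown (SOSR) with probability
``p_sosr`` (default 5%) and winter-sown (WOSR) otherwise; sowing dates fall
uniformly within a week of 1 April (SOSR) or 1 September (WOSR) of the
preceding autumn.

Crop phenology is a parametric thermal-time/photoperiod model: the crop
emerges after a fixed thermal time from sowing, starts flowering after a
further crop-specific thermal time provided the day is long enough (no
vernalisation requirement), and finishes after a fixed flowering duration in
thermal time.  SOSR has the shorter emergence-to-flowering requirement.
Default parameters are chosen so that, under the maritime-UK climate preset,
WOSR sown around 1 September flowers in April-May and SOSR sown around
1 April flowers in June-July.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .weather import degree_days

SOSR_SOWING_DOY = 91   # 1 April
WOSR_SOWING_DOY = 244  # 1 September
SOWING_WINDOW_DAYS = 7

OSR_PLANTS_PER_M2 = 180.0
WILD_PLANTS_PER_M2 = 150.0
CELL_AREA_M2 = 10_000.0  # 1 ha


class CellKind(IntEnum):
    ARABLE = 0
    REFUGE = 1
    OVERWINTER = 2
    EMPTY = 3


class Crop(IntEnum):
    NONE = 0
    WOSR = 1
    SOSR = 2
    NON_HOST = 3
    WILD = 4


class PhenoState(IntEnum):
    NONE = 0
    SOWN = 1
    EMERGED = 2
    FLOWERING = 3
    FINISHED = 4


@dataclass(frozen=True)
class CropPhenologyParams:
    """Thermal-time (degree-days base 0 degC) and photoperiod parameters."""

    emergence_dd: float = 120.0
    wosr_to_flowering_dd: float = 1400.0
    sosr_to_flowering_dd: float = 550.0
    photoperiod_threshold_h: float = 12.5
    flowering_duration_dd: float = 700.0

    def to_flowering_dd(self, crop: int) -> float:
        return (
            self.sosr_to_flowering_dd
            if crop == Crop.SOSR
            else self.wosr_to_flowering_dd
        )


@dataclass
class CropPhenology:
    """Phenology state of a single sown crop."""

    crop: int
    sowing_day: int  # absolute simulation day
    params: CropPhenologyParams = field(default_factory=CropPhenologyParams)
    state: int = PhenoState.SOWN
    cum_dd: float = 0.0
    flowering_dd: float = 0.0
    flowering_onset_day: int | None = None


def update_phenology(
    phen: CropPhenology, tmean: float, day_length: float, day: int
) -> CropPhenology:
    """Advance a sown crop by one day of weather.

    Thermal time accrues from the day after sowing.  Transitions:
    SOWN -> EMERGED at ``emergence_dd``; EMERGED -> FLOWERING once total
    thermal time reaches emergence + crop-specific flowering requirement *and*
    day length is at or above the photoperiod threshold; FLOWERING ->
    FINISHED after ``flowering_duration_dd`` of flowering thermal time.
    States advance monotonically; a zero flowering duration collapses
    FLOWERING and FINISHED onto the same day.
    """
    p = phen.params
    if phen.state in (PhenoState.NONE, PhenoState.FINISHED) or day <= phen.sowing_day:
        return phen
    dd = float(degree_days(tmean))
    phen.cum_dd += dd
    if phen.state == PhenoState.SOWN and phen.cum_dd >= p.emergence_dd:
        phen.state = PhenoState.EMERGED
    if (
        phen.state == PhenoState.EMERGED
        and phen.cum_dd >= p.emergence_dd + p.to_flowering_dd(phen.crop)
        and day_length >= p.photoperiod_threshold_h
    ):
        phen.state = PhenoState.FLOWERING
        phen.flowering_onset_day = day
    if phen.state == PhenoState.FLOWERING:
        phen.flowering_dd += dd
        if phen.flowering_dd >= p.flowering_duration_dd:
            phen.state = PhenoState.FINISHED
    return phen


@dataclass
class Landscape:
    """Grid of 1-ha cells on a torus.

    ``kind`` and ``rotation_phase`` are flat arrays of length nrows*ncols;
    cell index = row * ncols + col; cell centres sit at integer coordinates.
    """

    nrows: int
    ncols: int
    kind: np.ndarray            # CellKind per cell
    rotation_phase: np.ndarray  # 0..3 for arable cells, -1 otherwise

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def cells_of_kind(self, kind: CellKind) -> np.ndarray:
        return np.flatnonzero(self.kind == kind)

    def composition(self) -> dict[str, int]:
        return {k.name: int(np.sum(self.kind == k)) for k in CellKind}

    def distance_matrix(self) -> np.ndarray:
        """Pairwise torus Euclidean distances between all cell centres."""
        idx = np.arange(self.n_cells)
        r = idx // self.ncols
        c = idx % self.ncols
        dr = np.abs(r[:, None] - r[None, :])
        dc = np.abs(c[:, None] - c[None, :])
        dr = np.minimum(dr, self.nrows - dr)
        dc = np.minimum(dc, self.ncols - dc)
        return np.sqrt(dr.astype(float) ** 2 + dc.astype(float) ** 2)

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(self.n_cells)
        return pd.DataFrame(
            {
                "cell": idx,
                "row": idx // self.ncols,
                "col": idx % self.ncols,
                "kind": [CellKind(k).name for k in self.kind],
                "rotation_phase": self.rotation_phase,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_text(self) -> str:
        """Compact grid rendering (A/R/O/. = arable/refuge/overwinter/empty)."""
        chars = {0: "A", 1: "R", 2: "O", 3: "."}
        grid = self.kind.reshape(self.nrows, self.ncols)
        return "\n".join("".join(chars[int(k)] for k in row) for row in grid)


DEFAULT_COMPOSITION = {"ARABLE": 80, "REFUGE": 10, "OVERWINTER": 5, "EMPTY": 5}


def generate_landscape(
    seed,
    composition: dict[str, int] | None = None,
    dims: tuple[int, int] = (10, 10),
) -> Landscape:
    """Place cell kinds uniformly at random and assign rotation phases.

    ``composition`` maps kind names to counts and must sum to the grid size.
    Arable rotation phases are drawn uniformly over {0,1,2,3}, staggering the
    4-year rotation so ~1/4 of arable fields grow OSR each year.
    """
    comp = dict(DEFAULT_COMPOSITION if composition is None else composition)
    nrows, ncols = dims
    n = nrows * ncols
    if sum(comp.values()) != n:
        raise ValueError(
            f"composition sums to {sum(comp.values())}, grid has {n} cells"
        )
    rng = np.random.default_rng(seed)
    kinds = np.concatenate(
        [np.full(comp.get(k.name, 0), int(k), dtype=np.int8) for k in CellKind]
    )
    rng.shuffle(kinds)
    phase = np.full(n, -1, dtype=np.int8)
    arable = kinds == CellKind.ARABLE
    phase[arable] = rng.integers(0, 4, size=int(arable.sum()))
    return Landscape(nrows, ncols, kinds, phase)


def plan_crop_for_year(
    rotation_phase: int, year: int, rng: np.random.Generator, p_sosr: float = 0.05
) -> tuple[int, int] | None:
    """Crop assignment and sowing calendar day for one arable cell and year.

    Returns ``None`` in non-OSR years (the cell grows a non-host crop).  In
    OSR years the crop is SOSR with probability ``p_sosr`` else WOSR; the
    sowing day is uniform within a week after the nominal date — 1 April of
    the harvest year for SOSR, 1 September of the *previous* year for WOSR
    (returned as a negative offset from 1 January of the harvest year).
    """
    if rotation_phase < 0:
        raise ValueError("cell is not arable")
    if year % 4 != rotation_phase:
        return None
    crop = Crop.SOSR if rng.random() < p_sosr else Crop.WOSR
    offset = int(rng.integers(0, SOWING_WINDOW_DAYS))
    if crop == Crop.SOSR:
        return Crop.SOSR, SOSR_SOWING_DOY + offset
    return Crop.WOSR, WOSR_SOWING_DOY + offset - 365


def torus_distance(
    a: tuple[int, int], b: tuple[int, int], dims: tuple[int, int]
) -> float:
    """Shortest Euclidean distance between cell centres on the torus."""
    dr = abs(a[0] - b[0])
    dc = abs(a[1] - b[1])
    dr = min(dr, dims[0] - dr)
    dc = min(dc, dims[1] - dc)
    return float(np.hypot(dr, dc))


def plants_per_cell(crop_or_kind_host: str) -> float:
    """Number of host plants in a 1-ha cell ('osr' or 'wild')."""
    density = OSR_PLANTS_PER_M2 if crop_or_kind_host == "osr" else WILD_PLANTS_PER_M2
    return density * CELL_AREA_M2
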