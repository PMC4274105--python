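"""Daily adult movement on the torus landscape.

Movement has two parts.  First, whether an adult leaves its cell: beetles in
a host-free cell always move; otherwise the daily movement probability is a
piecewise-linear function of conspecific adult density (insects per host
plant) — maximal at low density (mate finding), falling to a floor at
moderate density, and rising back to the maximum as crowding sets in.
Second, where it goes: a destination cell is drawn with probability
proportional to its attractiveness divided by torus distance from the origin
(``V / d^alpha``), over the phase-specific eligible set — flowering OSR and
wild-refuge cells during the season, overwintering habitats for the autumn
relocation.  Movement is instantaneous at the end of the daily step; all
non-adult stages are immobile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import CohortTable


@dataclass(frozen=True)
class MovementParams:
    """Movement probability knots and destination attractiveness by host."""

    p_max: dict = field(default_factory=lambda: {"osr": 0.35, "wild": 0.65})
    p_min: float = 0.05
    density_knots: dict = field(
        default_factory=lambda: {
            "osr": (2.5, 10.0, 70.0, 100.0),
            "wild": (1.5, 6.2, 44.0, 62.0),
        }
    )
    attractiveness: dict = field(default_factory=lambda: {"osr": 1.0, "wild": 0.2})
    distance_exponent: float = 1.0

    def __post_init__(self):
        for host, (d1, d2, d3, d4) in self.density_knots.items():
            if not d1 < d2 < d3 < d4:
                raise ValueError(f"density knots for {host!r} must increase")
            if not 0 < self.p_min <= self.p_max[host] <= 1:
                raise ValueError("require 0 < p_min <= p_max <= 1")


def movement_probability(
    host: str | None, density, params: MovementParams | None = None
):
    """Daily probability that an adult leaves its cell.

    1 when the cell holds no host plants (forced move).  With a host, the
    probability interpolates p_max -> p_min over [d1, d2], holds at p_min on
    [d2, d3], and returns to p_max over [d3, d4]; constant outside.
    """
    params = params or MovementParams()
    d = np.asarray(density, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be non-negative")
    if host is None:
        out = np.ones_like(d)
        return float(out) if np.isscalar(density) else out
    d1, d2, d3, d4 = params.density_knots[host]
    p_max = params.p_max[host]
    out = np.interp(d, [d1, d2, d3, d4], [p_max, params.p_min, params.p_min, p_max])
    return float(out) if np.isscalar(density) else out


def destination_probabilities(
    origin: int,
    dist_matrix: np.ndarray,
    attractiveness: np.ndarray,
    alpha: float = 1.0,
) -> np.ndarray | None:
    """Probability over destination cells for a mover leaving ``origin``.

    Weight of cell c is ``V(c) / dist(origin, c)^alpha``; the origin is
    excluded and weights are normalised.  ``attractiveness`` is a per-cell
    array, zero for ineligible cells.  Returns None when no cell is eligible
    (the mover stays).
    """
    w = attractiveness.astype(float).copy()
    w[origin] = 0.0
    eligible = w > 0
    if not eligible.any():
        return None
    dist = dist_matrix[origin]
    w[eligible] = w[eligible] / np.power(dist[eligible], alpha)
    return w / w.sum()


def destination_matrix(
    dist_matrix: np.ndarray, attractiveness: np.ndarray, alpha: float = 1.0
) -> np.ndarray:
    """Row-stochastic destination matrix for every origin (vectorised).

    Rows with no eligible destination are all-zero (movers stay put).
    """
    n = dist_matrix.shape[0]
    w = np.tile(attractiveness.astype(float), (n, 1))
    np.fill_diagonal(w, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(w > 0, w / np.power(dist_matrix, alpha, where=dist_matrix > 0, out=np.ones_like(dist_matrix)), 0.0)
    sums = w.sum(axis=1, keepdims=True)
    return np.divide(w, sums, out=np.zeros_like(w), where=sums > 0)


def execute_movements(
    table: CohortTable,
    mover_rows: np.ndarray,
    p_move_by_cell: np.ndarray,
    dest_probs: np.ndarray,
    rng: np.random.Generator,
) -> CohortTable:
    """Relocate a binomial share of each eligible cohort.

    ``mover_rows`` selects the cohorts allowed to move (adults, not
    hibernating); per cohort the number of movers is binomial with its
    cell's movement probability, and destinations are multinomial from the
    origin's row of ``dest_probs``.  All draws happen before any relocation
    is applied, so movement within one day cannot cascade.  Total count is
    conserved.  Returns the relocated cohorts (counts of the source cohorts
    are reduced in place).
    """
    rows = np.asarray(mover_rows)
    if rows.size == 0:
        return CohortTable(0)
    origin = table.cell[rows]
    p = p_move_by_cell[origin]
    # rows whose origin has no eligible destination stay put
    has_dest = dest_probs[origin].sum(axis=1) > 0
    p = np.where(has_dest, p, 0.0)
    movers = rng.binomial(table.count[rows], p)
    moving = movers > 0
    if not moving.any():
        return CohortTable(0)
    rows = rows[moving]
    movers = movers[moving]
    origin = origin[moving]
    table.count[rows] -= movers
    dests = rng.multinomial(movers, dest_probs[origin])  # (n_rows, n_cells)
    src, dst = np.nonzero(dests)
    moved = table.take(rows[src])
    moved.cell = dst.astype(np.int16)
    moved.count = dests[src, dst].astype(np.int64)
    return moved
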