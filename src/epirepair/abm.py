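"""Agent-based model of collective epithelial migration into an ablation gap.

The model represents a tubule epithelium as a planar sheet of point cells
(positions in µm) initialised on a square lattice at pitch ``cell_spacing``.
Each iteration every free cell takes (i) an isotropic Gaussian motility step
and (ii) a deterministic step equal to the vector sum of pairwise
neighbour interactions: repulsion when two cells are closer than ``d_rep``,
attraction when they are further apart than ``d_att``, and nothing in the
comfort zone in between.  Interactions act only within the cutoff ``d_max``
and are equal and opposite, so with motility switched off the sheet's
centre of mass is conserved (up to anchoring).

The sheet is a cut-open tubule: the axial direction (x) runs along the
nephron and is anchored at both ends (continuity with the rest of the
tubule), while the transverse direction (y) is periodic — the
circumference is conserved, so the sheet cannot thin itself to cover new
area and closure necessarily dilutes (stretches) the flanking epithelium.

A segmental ablation removes a centred band of lattice columns.  Cells
bordering the gap lack interaction partners on one side (a *free edge*),
and epithelial cells at a free edge mount an active migratory response:
a cell whose neighbourhood is strongly one-sided (the distance-tapered
resultant of directions toward its sensed neighbours is large) polarises
and crawls a fixed distance ``edge_speed`` per step toward the vacancy,
and the activation propagates ``activation_depth`` µm into the sheet, so
the near-edge epithelium advances as a coherent block — mirroring the
observation that the ~50 µm adjacent to an injury migrates at very
similar rates.  In the confluent bulk neighbour directions cancel and no
activity arises; migration therefore starts at the wound without any
explicit wound signal and stops by contact inhibition when the sheets
meet.  Weakly polarised cells (those flanking a single-cell vacancy)
crawl too, which keeps the advancing front and the suture confluent.

Passive cells adhere to the basement membrane: a weak plastic tether
(stiffness ``k_sub``, remodelling time ``tau_adh``) pulls each
non-migrating cell toward its adhesion reference.  Tension applied by the
migrating block therefore dissipates into the substrate over a finite
decay length instead of propagating to the sheet ends, so
migration-induced stretch is largest in a zone *behind* the activated
block — the model analogue of the finite stretch zone seen in cell-pair
tracing — and the closure rate declines from its initial maximum as
tension builds.

Proliferation is gated by stretch with a delay: a cell whose mean sensed
neighbour distance exceeds ``d_div`` accumulates a consecutive-step
counter; once the counter exceeds ``delay_steps`` the cell divides with
probability ``p_div`` per iteration, placing the daughter halfway toward
its most distant sensed neighbour (which locally relieves the stretch).
A short ablation advances each edge only ~10 µm and leaves the stretch
zone below threshold, so it induces no division; a long ablation leaves
two sustained over-threshold zones flanking the injury and produces two
bands of division events whose spacing matches the stretch-zone
geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import CoincidentCellsError, GeometryError, WindowError

__all__ = [
    "ISOLATED",
    "ModelParams",
    "Cell",
    "Sheet",
    "SimulationResult",
    "init_sheet",
    "pair_displacement",
    "interaction_displacements",
    "edge_crawl_displacements",
    "step",
    "stretch_metric",
    "stretch_metrics",
    "maybe_divide",
    "run_simulation",
    "migration_rate_series",
]

#: Sentinel returned by :func:`stretch_metric` for a cell with no neighbour
#: inside ``d_sense``.  Compares greater than any finite threshold, but
#: isolated cells are excluded from division eligibility.
ISOLATED = math.inf


@dataclass
class ModelParams:
    """Parameters of the migration/proliferation model.

    Lengths are µm, times are hours.  Interaction radii and the division
    threshold default to fixed multiples of ``cell_spacing`` (set any of
    them to ``None`` to re-derive after changing the spacing):

    ``d_rep = 0.9 s``, ``d_att = 1.05 s``, ``d_max = 1.25 s``,
    ``d_sense = 1.7 s``, ``d_div = 1.36 s``.

    Mechanics and sensing use different ranges.  Forces act through
    junctional contacts: the interaction ball ``d_max`` sits below the
    resting diagonal (``√2 s``), so springs connect the four
    axial/transverse neighbours, and the narrow comfort zone
    ``[0.9 s, 1.05 s]`` keeps the lattice stiff and force-free at rest.
    Stretch and free-edge sensing integrate over the wider ``d_sense``
    ball containing the full 8-cell neighbourhood (4 at ``s``, 4
    diagonals at ``√2 s``, resting mean ``1.207 s``).  Under axial strain
    the sensed mean rises (``1.33 s`` at 20 % for a uniformly strained
    interior cell) and saturates near ``1.45 s`` as strongly stretched
    diagonals leave the sensing ball; the default ``d_div = 1.36 s`` sits
    between the sustained stretch-zone response of a short (~20 µm)
    ablation and that of a long (55–100 µm) one, so short injuries and
    uninjured controls never trigger division while long injuries do.
    """

    cell_spacing: float = 6.7
    motility_sigma: float = 0.12
    d_rep: float | None = None
    d_att: float | None = None
    d_max: float | None = None
    d_sense: float | None = None
    k_rep: float = 0.4
    k_att: float = 0.4
    d_div: float | None = None
    p_div: float = 0.3
    delay_steps: int = 100
    step_hours: float = 0.04
    n_steps: int = 1200
    seed: int = 0
    #: Active crawling distance per step (µm) of edge-polarised cells and
    #: their activated followers.
    edge_speed: float = 0.3
    #: Magnitude of the distance-tapered neighbour resultant above which a
    #: cell counts as polarised at all.  Interior cells are near zero,
    #: cells flanking a single-cell vacancy ~0.4 (they close it), cells at
    #: a free edge ~0.65.
    polarity_threshold: float = 0.3
    #: Resultant magnitude marking a true wound-edge (leader) cell.
    front_threshold: float = 0.55
    #: Depth (µm) of the migratory activation behind the wound edge:
    #: followers within this distance of a leader cell crawl with it, so
    #: the near-edge epithelium translates as a coherent block and
    #: migration-induced stretch concentrates behind it.
    activation_depth: float = 120.0
    #: Cells closer than this (µm) to an anchored cell are ineligible to
    #: divide: deficit piling against the rigid anchored ends is a
    #: finite-window boundary artifact.  Default set in ``__post_init__``
    #: to ``5 * cell_spacing``.
    div_margin: float | None = None
    #: Substrate-adhesion stiffness (displacement gain per step toward the
    #: cell's adhesion reference).  Epithelial cells adhere to the basement
    #: membrane, so tension applied at the wound edge dissipates into the
    #: substrate over a decay length ~ cell_spacing * sqrt(k_att / k_sub)
    #: instead of propagating to the sheet ends; actively migrating cells
    #: release their adhesions and are exempt.
    k_sub: float = 0.0015
    #: Adhesion-remodelling time constant (steps): the adhesion reference
    #: position relaxes toward the cell's current position at this rate,
    #: so sustained deformation is eventually accommodated plastically.
    tau_adh: float = 400.0
    #: Stretch-independent division probability per step (default off).
    baseline_p_div: float = 0.0

    def __post_init__(self) -> None:
        s = self.cell_spacing
        if self.d_rep is None:
            self.d_rep = 0.9 * s
        if self.d_att is None:
            self.d_att = 1.05 * s
        if self.d_max is None:
            self.d_max = 1.25 * s
        if self.d_sense is None:
            self.d_sense = 1.7 * s
        if self.d_div is None:
            self.d_div = 1.36 * s
        if self.div_margin is None:
            self.div_margin = 5.0 * s
        for name in ("cell_spacing", "d_rep", "d_att", "d_max", "d_div",
                     "step_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.d_rep < s < self.d_att < self.d_max):
            raise ValueError(
                "require 0 < d_rep < cell_spacing < d_att < d_max, got "
                f"d_rep={self.d_rep}, spacing={s}, d_att={self.d_att}, "
                f"d_max={self.d_max}"
            )
        if self.d_sense < self.d_max:
            raise ValueError("d_sense must be >= d_max")
        for name in ("p_div", "baseline_p_div"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.delay_steps < 0:
            raise ValueError("delay_steps must be >= 0")
        if self.motility_sigma < 0:
            raise ValueError("motility_sigma must be >= 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.edge_speed < 0:
            raise ValueError("edge_speed must be >= 0")
        if self.polarity_threshold <= 0:
            raise ValueError("polarity_threshold must be positive")
        if self.front_threshold < self.polarity_threshold:
            raise ValueError("front_threshold must be >= polarity_threshold")
        if self.k_sub < 0:
            raise ValueError("k_sub must be >= 0")
        if self.tau_adh <= 0:
            raise ValueError("tau_adh must be positive")
        if self.activation_depth < 0:
            raise ValueError("activation_depth must be >= 0")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Cell:
    """Read-only view of one agent (see :meth:`Sheet.cell`)."""

    id: int
    position: np.ndarray
    anchored: bool
    over_threshold_run: int
    born_at: int


@dataclass
class Sheet:
    """State of the epithelial sheet.

    Cell attributes are stored as parallel arrays indexed by cell id in
    creation order; daughters are appended, so ids are stable and the
    update order is deterministic.
    """

    positions: np.ndarray          # (n, 2) float, µm
    anchored: np.ndarray           # (n,) bool
    over_threshold_run: np.ndarray  # (n,) int
    born_at: np.ndarray            # (n,) int
    gap: tuple[float, float]       # half-open axial interval [lo, hi)
    axial_extent: float
    transverse_extent: float       # circumference when periodic
    anchor_margin: float
    #: Period of the transverse (circumferential) direction; ``None`` for
    #: an open planar patch (used for small ad-hoc configurations).
    transverse_period: float | None = None
    #: Substrate-adhesion reference positions (n, 2); ``None`` disables
    #: the substrate tether (small ad-hoc configurations).
    adhesion_ref: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def gap_center(self) -> float:
        return 0.5 * (self.gap[0] + self.gap[1])

    def cell(self, cell_id: int) -> Cell:
        return Cell(
            id=cell_id,
            position=self.positions[cell_id].copy(),
            anchored=bool(self.anchored[cell_id]),
            over_threshold_run=int(self.over_threshold_run[cell_id]),
            born_at=int(self.born_at[cell_id]),
        )

    def copy(self) -> "Sheet":
        return Sheet(
            positions=self.positions.copy(),
            anchored=self.anchored.copy(),
            over_threshold_run=self.over_threshold_run.copy(),
            born_at=self.born_at.copy(),
            gap=self.gap,
            axial_extent=self.axial_extent,
            transverse_extent=self.transverse_extent,
            anchor_margin=self.anchor_margin,
            transverse_period=self.transverse_period,
            adhesion_ref=(None if self.adhesion_ref is None
                          else self.adhesion_ref.copy()),
        )


def init_sheet(
    rows: int,
    cols: int,
    params: ModelParams,
    gap_length: float,
    anchor_margin: float | None = None,
) -> Sheet:
    """Place cells on a ``rows x cols`` lattice and ablate a centred gap.

    The lattice pitch is ``params.cell_spacing``; x is the axial (tubule)
    coordinate, y the circumferential one (periodic with period
    ``rows * cell_spacing``).  Cells whose x falls in the centred
    half-open interval of width ``gap_length`` are removed.  Cells within
    ``anchor_margin`` (default ``2 * cell_spacing``) of either axial end
    are anchored.
    """
    if rows < 2 or cols < 2:
        raise GeometryError("need at least a 2 x 2 lattice")
    if gap_length < 0:
        raise GeometryError("gap_length must be >= 0")
    s = params.cell_spacing
    if anchor_margin is None:
        anchor_margin = 2.0 * s
    axial_extent = (cols - 1) * s
    transverse_extent = rows * s
    if gap_length >= axial_extent - 2.0 * anchor_margin:
        raise GeometryError(
            f"gap of {gap_length} µm leaves no free epithelium on a sheet "
            f"of axial extent {axial_extent} µm with anchored margins of "
            f"{anchor_margin} µm"
        )
    center = 0.5 * axial_extent
    gap = (center - 0.5 * gap_length, center + 0.5 * gap_length)

    xs = np.arange(cols) * s
    ys = np.arange(rows) * s
    gx, gy = np.meshgrid(xs, ys)
    pos = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    keep = ~((pos[:, 0] >= gap[0]) & (pos[:, 0] < gap[1]))
    pos = pos[keep]
    n = len(pos)
    eps = 1e-9 * s
    anchored = (pos[:, 0] <= anchor_margin + eps) | (
        pos[:, 0] >= axial_extent - anchor_margin - eps
    )
    free_x = pos[~anchored, 0]
    if gap_length > 0 and (
        free_x.size == 0
        or not ((free_x < gap[0]).any() and (free_x >= gap[1]).any())
    ):
        raise GeometryError("gap covers all non-anchored columns on one side")
    return Sheet(
        positions=pos,
        anchored=anchored,
        over_threshold_run=np.zeros(n, dtype=int),
        born_at=np.zeros(n, dtype=int),
        gap=gap,
        axial_extent=axial_extent,
        transverse_extent=transverse_extent,
        anchor_margin=anchor_margin,
        transverse_period=transverse_extent,
        adhesion_ref=pos.copy(),
    )


def pair_displacement(d, params: ModelParams):
    """Signed interaction displacement for one pair at separation ``d`` (µm).

    Positive values push the pair *apart* (repulsion), negative values pull
    it *together* (attraction); each cell of a free pair moves by the
    returned magnitude along the separation axis.  Piecewise linear and
    continuous: ``k_rep (d_rep - d)`` below ``d_rep``, zero in the comfort
    zone ``[d_rep, d_att]``, ``-k_att (d - d_att)`` up to the cutoff
    ``d_max``, zero beyond.  Accepts scalars or arrays.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr <= 0):
        raise CoincidentCellsError("pair separation must be positive")
    out = np.zeros_like(arr)
    rep = arr < params.d_rep
    att = (arr > params.d_att) & (arr <= params.d_max)
    out[rep] = params.k_rep * (params.d_rep - arr[rep])
    out[att] = -params.k_att * (arr[att] - params.d_att)
    if np.isscalar(d):
        return float(out)
    return out


def _pair_geometry(
    positions: np.ndarray, d_max: float, period_y: float | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbour pairs within ``d_max`` with separation vectors/distances.

    With ``period_y`` set, the y coordinate is treated as circumferential
    (minimum-image convention).  Returns ``(pairs, dvec, dist)`` where
    ``dvec = pos[i] - pos[j]`` (minimum image).
    """
    if period_y is None:
        tree = cKDTree(positions)
        pairs = tree.query_pairs(d_max, output_type="ndarray")
        if len(pairs) == 0:
            return pairs, np.empty((0, 2)), np.empty(0)
        dvec = positions[pairs[:, 0]] - positions[pairs[:, 1]]
    else:
        pts = positions.copy()
        pts[:, 1] %= period_y
        # make x strictly positive inside a box wide enough that the
        # artificial x-periodicity of the KD-tree box can never pair cells
        pad = 10.0 * d_max
        xmin = pts[:, 0].min()
        box_x = (pts[:, 0].max() - xmin) + 2.0 * pad
        pts[:, 0] += pad - xmin
        tree = cKDTree(pts, boxsize=[box_x, period_y])
        pairs = tree.query_pairs(d_max, output_type="ndarray")
        if len(pairs) == 0:
            return pairs, np.empty((0, 2)), np.empty(0)
        dvec = positions[pairs[:, 0]] - positions[pairs[:, 1]]
        dvec[:, 1] -= period_y * np.round(dvec[:, 1] / period_y)
    dist = np.hypot(dvec[:, 0], dvec[:, 1])
    return pairs, dvec, dist


def interaction_displacements(
    positions: np.ndarray,
    params: ModelParams,
    period_y: float | None = None,
) -> np.ndarray:
    """Per-cell displacement from summed pairwise interactions (n, 2)."""
    disp = np.zeros_like(positions)
    pairs, dvec, dist = _pair_geometry(positions, params.d_max, period_y)
    if len(pairs) == 0:
        return disp
    if np.any(dist <= 0):
        raise CoincidentCellsError("coincident cells in interaction sum")
    f = pair_displacement(dist, params)
    step_vec = (f / dist)[:, None] * dvec
    i, j = pairs[:, 0], pairs[:, 1]
    np.add.at(disp, i, step_vec)
    np.add.at(disp, j, -step_vec)
    return disp


def edge_crawl_displacements(
    positions: np.ndarray,
    params: ModelParams,
    period_y: float | None = None,
    anchored: np.ndarray | None = None,
) -> np.ndarray:
    """Active crawling displacement of polarised cells (n, 2).

    Each cell's polarity is minus the resultant of distance-tapered unit
    vectors toward its neighbours within ``d_sense``; where its magnitude
    exceeds ``polarity_threshold`` (a one-sided neighbourhood: a free
    edge, or a cell flanking a vacancy) the cell crawls ``edge_speed`` µm
    along the polarity direction.  Cells within ``activation_depth`` of a
    leader (magnitude above ``front_threshold``) and behind it follow it.
    Interior cells, whose neighbour directions cancel, do not move.
    """
    n = len(positions)
    resultant = np.zeros((n, 2))
    if params.edge_speed == 0:
        return resultant
    pairs, dvec, dist = _pair_geometry(positions, params.d_sense, period_y)
    if len(pairs) == 0:
        return resultant
    # Unit vectors tapered linearly to zero at the sensing boundary, so a
    # neighbour drifting across the boundary cannot flip a cell's polarity.
    w = 1.0 - dist / params.d_sense
    unit = (w / dist)[:, None] * dvec
    np.add.at(resultant, pairs[:, 0], -unit)   # i's neighbours lie at -unit
    np.add.at(resultant, pairs[:, 1], unit)
    mag = np.hypot(resultant[:, 0], resultant[:, 1])
    if anchored is not None:
        # the anchored sheet ends are not wound edges: they neither crawl
        # nor recruit followers
        mag = np.where(anchored, 0.0, mag)
    polar = mag > params.polarity_threshold
    out = np.zeros((n, 2))
    out[polar] = -params.edge_speed * resultant[polar] / mag[polar, None]
    # Follower activation: cells within activation_depth of a leader
    # (wound-edge) cell crawl along that leader's polarity, so the
    # near-edge block translates coherently.
    leaders = np.flatnonzero(mag > params.front_threshold)
    if len(leaders) and params.activation_depth > 0:
        ldir = -resultant[leaders] / mag[leaders, None]
        tree = cKDTree(positions[leaders])
        d_near, j_near = tree.query(positions, k=1)
        follow = (d_near <= params.activation_depth) & ~polar
        if follow.any():
            # a follower must sit behind its leader, not across the wound
            rel = positions[follow] - positions[leaders][j_near[follow]]
            behind = (rel * ldir[j_near[follow]]).sum(axis=1) <= 0.0
            idx = np.flatnonzero(follow)[behind]
            out[idx] = params.edge_speed * ldir[j_near[idx]]
    return out


def step(sheet: Sheet, params: ModelParams, rng: np.random.Generator) -> Sheet:
    """Advance all cells by one synchronous iteration (in place).

    Displacement of a free cell = isotropic Gaussian motility step
    (per-axis scale ``motility_sigma``) + summed neighbour interactions
    + active free-edge crawling.  Anchored cells never move.  Returns the
    same ``Sheet``.
    """
    disp = interaction_displacements(
        sheet.positions, params, sheet.transverse_period
    )
    crawl = None
    if params.edge_speed > 0:
        crawl = edge_crawl_displacements(
            sheet.positions, params, sheet.transverse_period, sheet.anchored
        )
        disp += crawl
    if params.k_sub > 0 and sheet.adhesion_ref is not None:
        # substrate tether for passive cells; migrating cells have
        # released their adhesions
        off = sheet.positions - sheet.adhesion_ref
        if sheet.transverse_period is not None:
            off[:, 1] -= sheet.transverse_period * np.round(
                off[:, 1] / sheet.transverse_period
            )
        tether = -params.k_sub * off
        if crawl is not None:
            tether[np.abs(crawl).sum(axis=1) > 0] = 0.0
        disp += tether
    if params.motility_sigma > 0:
        disp += rng.normal(0.0, params.motility_sigma, sheet.positions.shape)
    disp[sheet.anchored] = 0.0
    sheet.positions += disp
    if sheet.transverse_period is not None:
        sheet.positions[:, 1] %= sheet.transverse_period
    if sheet.adhesion_ref is not None:
        # adhesion remodelling: the reference creeps toward the cell
        off = sheet.positions - sheet.adhesion_ref
        if sheet.transverse_period is not None:
            off[:, 1] -= sheet.transverse_period * np.round(
                off[:, 1] / sheet.transverse_period
            )
        sheet.adhesion_ref += off / params.tau_adh
        if sheet.transverse_period is not None:
            sheet.adhesion_ref[:, 1] %= sheet.transverse_period
    return sheet


def stretch_metrics(sheet: Sheet, params: ModelParams) -> np.ndarray:
    """Mean sensed-neighbour distance (µm) for every cell; ``ISOLATED``
    (inf) for cells with no neighbour within ``d_sense``."""
    n = sheet.n_cells
    sums = np.zeros(n)
    counts = np.zeros(n)
    pairs, _, dist = _pair_geometry(
        sheet.positions, params.d_sense, sheet.transverse_period
    )
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        np.add.at(sums, i, dist)
        np.add.at(sums, j, dist)
        np.add.at(counts, i, 1)
        np.add.at(counts, j, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), ISOLATED)
    return out


def stretch_metric(sheet: Sheet, params: ModelParams, cell_id: int) -> float:
    """Stretch metric of a single cell (see :func:`stretch_metrics`)."""
    return float(stretch_metrics(sheet, params)[cell_id])


def maybe_divide(
    sheet: Sheet,
    params: ModelParams,
    rng: np.random.Generator,
    step_index: int,
) -> tuple[Sheet, list[tuple[int, float]]]:
    """Update stretch counters and perform stochastic divisions (in place).

    Each cell's consecutive over-threshold counter increments when its
    stretch metric exceeds ``d_div`` and resets to zero otherwise.  A free
    cell whose counter then *exceeds* ``delay_steps`` divides with
    probability ``p_div`` this step (so the earliest possible division is
    at step ``delay_steps + 1``: the delay must fully elapse first).
    Cells below threshold may still divide at the baseline rate
    ``baseline_p_div`` (zero by default).

    The daughter is placed at the midpoint between the mother and her most
    distant in-range neighbour, nudged ``0.1 * cell_spacing`` transversely
    to break symmetry; both counters reset.  Events are returned as
    ``(step_index, mother_axial_position_um)``.

    Cells within ``div_margin`` of an anchored cell are ineligible: the
    rigid anchored ends truncate the real nephron, and residual material
    deficit piling against them is a finite-window boundary artifact, not
    tissue stretch.
    """
    metrics = stretch_metrics(sheet, params)
    # Isolated cells (no neighbour in range) are excluded from eligibility:
    # division requires a partner for daughter placement, and an escaped
    # single cell must not accumulate competence indefinitely.
    over = (metrics > params.d_div) & np.isfinite(metrics)
    runs = sheet.over_threshold_run
    runs[:] = np.where(over, runs + 1, 0)

    p = np.where(runs > params.delay_steps, params.p_div, params.baseline_p_div)
    p[sheet.anchored] = 0.0
    if params.div_margin > 0 and sheet.anchored.any():
        atree = cKDTree(sheet.positions[sheet.anchored])
        d_anchor, _ = atree.query(sheet.positions, k=1)
        p[d_anchor < params.div_margin] = 0.0
    dividers = np.flatnonzero(rng.random(sheet.n_cells) < p)

    events: list[tuple[int, float]] = []
    if len(dividers) == 0:
        return sheet, events

    pairs, dvec, dist = _pair_geometry(
        sheet.positions, params.d_sense, sheet.transverse_period
    )
    # per-divider most distant in-range neighbour (minimum-image offset)
    far_offset = {int(k): None for k in dividers}
    far_dist = {int(k): -1.0 for k in dividers}
    for (i, j), v, d in zip(pairs, dvec, dist):
        i, j = int(i), int(j)
        if i in far_dist and d > far_dist[i]:
            far_dist[i], far_offset[i] = d, -v
        if j in far_dist and d > far_dist[j]:
            far_dist[j], far_offset[j] = d, v
    new_pos: list[np.ndarray] = []
    for idx in dividers:
        mother = sheet.positions[idx]
        off = far_offset[int(idx)]
        daughter = mother + 0.5 * off if off is not None else mother.copy()
        daughter = daughter + np.array(
            [0.0, 0.1 * params.cell_spacing * (1 if rng.random() < 0.5 else -1)]
        )
        if sheet.transverse_period is not None:
            daughter[1] %= sheet.transverse_period
        new_pos.append(daughter)
        events.append((step_index, float(mother[0])))

    runs[dividers] = 0
    k = len(new_pos)
    sheet.positions = np.vstack([sheet.positions, np.array(new_pos)])
    if sheet.adhesion_ref is not None:
        sheet.adhesion_ref = np.vstack([sheet.adhesion_ref, np.array(new_pos)])
    sheet.anchored = np.concatenate([sheet.anchored, np.zeros(k, dtype=bool)])
    sheet.over_threshold_run = np.concatenate([runs, np.zeros(k, dtype=int)])
    sheet.born_at = np.concatenate(
        [sheet.born_at, np.full(k, step_index, dtype=int)]
    )
    return sheet, events


def _edge_positions(sheet: Sheet, n_edge: int = 3) -> tuple[float, float]:
    """Mean x of the ``n_edge`` cells nearest the gap on each side."""
    x = sheet.positions[:, 0]
    c = sheet.gap_center
    left = x[x <= c]
    right = x[x > c]
    lx = float(np.mean(np.sort(left)[-n_edge:])) if left.size else c
    rx = float(np.mean(np.sort(right)[:n_edge])) if right.size else c
    return lx, rx


@dataclass
class SimulationResult:
    """Full record of one simulation run.

    ``positions`` holds one ``(n_t, 2)`` array per recorded step (index 0
    is the initial state) or ``None`` when recording was disabled.
    ``division_events`` is an ``(k, 2)`` array of (step, axial position µm);
    ``edge_left`` / ``edge_right`` track the mean x of the three cells
    nearest the gap on each side, one entry per step including step 0.
    """

    params: ModelParams
    rows: int
    cols: int
    gap_length: float
    gap: tuple[float, float]
    positions: list[np.ndarray] | None
    final_sheet: Sheet
    division_events: np.ndarray
    edge_steps: np.ndarray
    edge_left: np.ndarray
    edge_right: np.ndarray

    @property
    def gap_center(self) -> float:
        return 0.5 * (self.gap[0] + self.gap[1])

    @property
    def times_h(self) -> np.ndarray:
        return self.edge_steps * self.params.step_hours

    @property
    def n_divisions(self) -> int:
        return len(self.division_events)

    def gap_width_series(self) -> np.ndarray:
        """Apparent gap width (µm, floored at 0) per recorded step."""
        return np.maximum(self.edge_right - self.edge_left, 0.0)

    def division_positions(self) -> np.ndarray:
        """Axial positions (µm) of all division events."""
        if self.n_divisions == 0:
            return np.empty(0)
        return self.division_events[:, 1].astype(float)

    def to_tracks(self) -> pd.DataFrame:
        """Per-step positions as a tidy frame (requires position recording).

        Columns: step, time_h, cell_id, x_um, y_um, born_at_step, anchored.
        """
        if self.positions is None:
            raise ValueError("run_simulation was called with record_positions=False")
        frames = []
        born = self.final_sheet.born_at
        anch = self.final_sheet.anchored
        for step_i, pos in enumerate(self.positions):
            n = len(pos)
            frames.append(
                pd.DataFrame(
                    {
                        "step": step_i,
                        "time_h": step_i * self.params.step_hours,
                        "cell_id": np.arange(n),
                        "x_um": pos[:, 0],
                        "y_um": pos[:, 1],
                        "born_at_step": born[:n],
                        "anchored": anch[:n],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def edge_table(self) -> pd.DataFrame:
        """Edge traces as a tidy frame (step, time_h, side, edge_x_um)."""
        t = self.times_h
        left = pd.DataFrame(
            {"step": self.edge_steps, "time_h": t, "side": "left",
             "edge_x_um": self.edge_left}
        )
        right = pd.DataFrame(
            {"step": self.edge_steps, "time_h": t, "side": "right",
             "edge_x_um": self.edge_right}
        )
        return pd.concat([left, right], ignore_index=True)

    def events_table(self) -> pd.DataFrame:
        """Division events as a tidy frame (step, time_h, x_um)."""
        if self.n_divisions == 0:
            return pd.DataFrame(columns=["step", "time_h", "x_um"])
        steps = self.division_events[:, 0].astype(int)
        return pd.DataFrame(
            {"step": steps, "time_h": steps * self.params.step_hours,
             "x_um": self.division_events[:, 1].astype(float)}
        )


def run_simulation(
    params: ModelParams,
    rows: int = 10,
    cols: int = 80,
    gap_length: float = 90.0,
    anchor_margin: float | None = None,
    record_positions: bool = True,
) -> SimulationResult:
    """Initialise a sheet, run ``params.n_steps`` iterations, record traces.

    Fully reproducible from ``params.seed``: the same parameters give a
    bit-identical :class:`SimulationResult`.
    """
    rng = np.random.default_rng(params.seed)
    sheet = init_sheet(rows, cols, params, gap_length, anchor_margin)
    positions: list[np.ndarray] | None = [sheet.positions.copy()] if record_positions else None
    events: list[tuple[int, float]] = []
    lx, rx = _edge_positions(sheet)
    edge_left = [lx]
    edge_right = [rx]
    for step_i in range(1, params.n_steps + 1):
        step(sheet, params, rng)
        sheet, ev = maybe_divide(sheet, params, rng, step_i)
        events.extend(ev)
        if record_positions:
            positions.append(sheet.positions.copy())
        lx, rx = _edge_positions(sheet)
        edge_left.append(lx)
        edge_right.append(rx)
    ev_arr = (
        np.array(events, dtype=float) if events else np.empty((0, 2))
    )
    return SimulationResult(
        params=params,
        rows=rows,
        cols=cols,
        gap_length=gap_length,
        gap=sheet.gap,
        positions=positions,
        final_sheet=sheet,
        division_events=ev_arr,
        edge_steps=np.arange(params.n_steps + 1),
        edge_left=np.array(edge_left),
        edge_right=np.array(edge_right),
    )


def migration_rate_series(
    result: SimulationResult, side: str, bin_steps: int = 5
) -> np.ndarray:
    """Binned edge speed, oriented so closing movement is positive.

    The edge trace is averaged over consecutive windows of ``bin_steps``
    iterations and differenced, giving an ``(n_bins - 1, 2)`` array of
    (time h at interval midpoint, rate µm/h).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    trace = result.edge_left if side == "left" else result.edge_right
    if bin_steps < 1 or len(trace) < 2 * bin_steps:
        raise WindowError(
            f"edge trace of length {len(trace)} is shorter than two bins of "
            f"{bin_steps} steps"
        )
    n_bins = len(trace) // bin_steps
    trimmed = trace[: n_bins * bin_steps].reshape(n_bins, bin_steps)
    t = result.times_h[: n_bins * bin_steps].reshape(n_bins, bin_steps)
    xm = trimmed.mean(axis=1)
    tm = t.mean(axis=1)
    rate = np.diff(xm) / np.diff(tm)
    if side == "right":
        rate = -rate
    mid = 0.5 * (tm[:-1] + tm[1:])
    return np.column_stack([mid, rate])
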