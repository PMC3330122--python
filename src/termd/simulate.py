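"""Synthetic locus-dynamics and cell-population generator.

Two generators make every downstream statistic testable without microscopy
data:

* :func:`simulate_trajectory` — 2-D confined Brownian motion of a fluorescent
  locus imaged at 10-s frame intervals over 5 min, with Gaussian localization
  noise.  Confinement is a reflecting circular boundary of radius ``r_c``
  about the locus home position (an Ornstein–Uhlenbeck trap is available as a
  variant; the choice between the two bounded models is a convention, and the
  reflected disc gives the simpler contract).
* :func:`simulate_population` — an age-structured, exponentially growing
  population with Cooper–Helmstetter replication timing.  Per cell it derives
  the locus copy number from the replication schedule, applies a
  class-dependent sister-cohesion delay, scatters focus positions about the
  class home position and merges foci closer than a diffraction-scale merge
  radius, yielding the observed focus counts that feed the co-localization
  index.

All randomness flows through one integer seed; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import CircularGenome, GenomeError, _arc_len, _norm
from .insulation import (CellCycleStage, MobilityClass, StrainModel,
                         classify_marker)
from .stats import Trajectory

__all__ = [
    "MotionParams", "SimConfig", "GrowthParams", "CohesionParams",
    "PopMarker", "PopulationSample",
    "DEFAULT_MOTION", "DEFAULT_COHESION", "DEFAULT_GROWTH",
    "simulate_trajectory", "simulate_trajectories",
    "cooper_copy_number", "relative_map_position", "sample_cell_age",
    "simulate_population", "population_for_strain",
]


@dataclass(frozen=True)
class MotionParams:
    """Confined-diffusion parameters of one mobility class.

    D in µm²/s, radii and noise in µm.  ``r_c=None`` removes the confinement.
    ``center`` is the home position as a fraction of cell length (0.5 =
    mid-cell, 0.25 = quarter position).
    """

    D: float
    r_c: float | None = None
    center: float = 0.25
    sigma_loc: float = 0.04
    model: str = "reflected"  # or "ou"

    def __post_init__(self):
        if self.D < 0 or self.sigma_loc < 0:
            raise ValueError("D and sigma_loc must be non-negative")
        if self.r_c is not None and self.r_c <= 0:
            raise ValueError("r_c must be positive or None (unbounded)")
        if self.model not in {"reflected", "ou"}:
            raise ValueError("model must be 'reflected' or 'ou'")


@dataclass(frozen=True)
class SimConfig:
    """Imaging protocol: 31 frames at 10 s span the 5-min movies."""

    dt: float = 10.0
    n_frames: int = 31
    n_foci: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


@dataclass(frozen=True)
class GrowthParams:
    """Cooper–Helmstetter cell-cycle parameters (minutes; positions in bp)."""

    tau: float = 30.0       # doubling time
    C: float = 40.0         # replication period
    D_period: float = 20.0  # division period
    oriC_bp: int = 3_925_744
    ter_bp: int = 1_588_773

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("doubling time tau must be positive")
        if self.C <= 0 or self.D_period < 0:
            raise ValueError("C must be positive and D non-negative")


#: Default per-class motion parameters, calibrated to reproduce the ~2-3 fold
#: MD vs NS travelled-distance contrast and the mid-cell anchoring of Ter
#: markers.  Mean step length scales as sqrt(D), so the class D values span
#: more than an order of magnitude; localization noise (20 nm) sets the floor
#: under the slowest classes.
DEFAULT_MOTION: dict[MobilityClass, MotionParams] = {
    MobilityClass.FREE: MotionParams(D=1e-3, r_c=0.45, center=0.25,
                                     sigma_loc=0.02),
    MobilityClass.STRUCTURED: MotionParams(D=1.5e-4, r_c=0.22, center=0.25,
                                           sigma_loc=0.02),
    MobilityClass.CONSTRAINED: MotionParams(D=1.5e-4, r_c=0.22, center=0.25,
                                            sigma_loc=0.02),
    MobilityClass.TER_STRUCTURED: MotionParams(D=8e-5, r_c=0.18, center=0.5,
                                               sigma_loc=0.02),
    MobilityClass.TER_ANCHORED: MotionParams(D=5e-5, r_c=0.12, center=0.5,
                                             sigma_loc=0.02),
}


@dataclass(frozen=True)
class CohesionParams:
    """Sister-cohesion and focus-detection parameters.

    ``cohesion_frac`` gives, per class, the post-replication sister-cohesion
    time as a fraction of the doubling time.  ``merge_radius_um`` is the
    distance below which two foci are seen as one (diffraction scale).
    ``separation_um`` is the distance sisters move apart once resolved —
    zero for Ter classes, whose sisters stay at mid-cell.
    ``scatter_um`` is the positional scatter of a focus about its anchor.
    """

    cohesion_frac: dict[MobilityClass, float] = field(default_factory=lambda: {
        MobilityClass.FREE: 0.0,
        MobilityClass.STRUCTURED: 0.5,
        MobilityClass.CONSTRAINED: 0.5,
        MobilityClass.TER_STRUCTURED: 0.6,
        MobilityClass.TER_ANCHORED: 0.6,
    })
    merge_radius_um: float = 0.25
    separation_um: dict[MobilityClass, float] = field(default_factory=lambda: {
        MobilityClass.FREE: 0.5,
        MobilityClass.STRUCTURED: 0.5,
        MobilityClass.CONSTRAINED: 0.5,
        MobilityClass.TER_STRUCTURED: 0.0,
        MobilityClass.TER_ANCHORED: 0.0,
    })
    scatter_um: float = 0.08


DEFAULT_COHESION = CohesionParams()
DEFAULT_GROWTH = GrowthParams()


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def simulate_trajectory(params: MotionParams, config: SimConfig,
                        rng: np.random.Generator | int | None = None,
                        locus_id: str = "locus", cell_id: str = "cell",
                        cell_length_um: float = 3.0) -> Trajectory:
    """One noisy 2-D trajectory of a confined locus.

    Brownian increments have per-axis variance ``2*D*dt``; positions are
    reflected at the circular boundary of radius ``r_c`` about the home
    position; independent Gaussian localization noise ``sigma_loc`` is added
    per frame.  Pole coordinates place the cell long axis on x with poles at
    0 and ``cell_length_um``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = config.n_frames
    anchor = np.array([params.center * cell_length_um, 0.0])
    steps = rng.normal(0.0, math.sqrt(2.0 * params.D * config.dt), size=(n - 1, 2))
    pos = np.empty((n, 2))
    pos[0] = anchor
    if params.model == "ou" and params.r_c is not None:
        # OU variant: spring constant chosen so the stationary per-axis s.d.
        # is r_c/2; exact discrete-time update
        k = params.D / (params.r_c / 2.0) ** 2
        decay = math.exp(-k * config.dt)
        sd_inc = math.sqrt((params.D / k) * (1.0 - decay ** 2))
        for i in range(1, n):
            inc = rng.normal(0.0, sd_inc, 2)
            pos[i] = anchor + (pos[i - 1] - anchor) * decay + inc
    else:
        for i in range(1, n):
            p = pos[i - 1] + steps[i - 1]
            if params.r_c is not None:
                # radial reflection at the confinement boundary
                r = np.linalg.norm(p - anchor)
                while r > params.r_c:
                    p = anchor + (p - anchor) * (2.0 * params.r_c - r) / r
                    r = abs(2.0 * params.r_c - r)
            pos[i] = p
    noisy = pos + rng.normal(0.0, params.sigma_loc, size=pos.shape)
    t = np.arange(n) * config.dt
    poles = np.zeros((n, 4))
    poles[:, 2] = cell_length_um
    return Trajectory(locus_id=locus_id, cell_id=cell_id, t=t,
                      x=noisy[:, 0], y=noisy[:, 1], poles=poles)


def simulate_trajectories(params: MotionParams, config: SimConfig,
                          n: int | None = None, seed: int | None = None,
                          locus_id: str = "locus") -> list[Trajectory]:
    """``n`` independent trajectories (defaults to ``config.n_foci``)."""
    n = config.n_foci if n is None else n
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return [
        simulate_trajectory(params, config, rng, locus_id=locus_id,
                            cell_id=f"cell{i:04d}")
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Cooper–Helmstetter population model
# ---------------------------------------------------------------------------


def cooper_copy_number(m_rel: float, growth: GrowthParams) -> float:
    """Steady-state average copy number of a locus in an exponential culture.

    ``m_rel`` is the relative map position along the locus's replichore (0 at
    oriC, 1 at the terminus).  The locus is replicated ``C*(1-m_rel) + D``
    minutes before division, giving the classic average
    ``2**((C*(1-m_rel) + D) / tau)``.
    """
    if not 0.0 <= m_rel <= 1.0:
        raise ValueError("m_rel must lie in [0, 1]")
    x = growth.C * (1.0 - m_rel) + growth.D_period
    return 2.0 ** (x / growth.tau)


def relative_map_position(genome: CircularGenome, pos: int,
                          oriC: int | None = None, ter: int | None = None
                          ) -> float:
    """Fractional position of ``pos`` along its replichore (oriC=0, ter=1).

    Uses the genome's current (post-rearrangement) coordinates, so a
    transposed locus acquires the replication timing of its new map position.
    oriC/ter default to features named ``oriC``/``dif`` when present.
    """
    L = genome.length_bp
    if oriC is None:
        oriC = genome.feature("oriC").position_bp
    if ter is None:
        name = "dif" if genome.has_feature("dif") else "ter"
        ter = genome.feature(name).position_bp
    oriC, ter, pos = _norm(oriC, L), _norm(ter, L), _norm(pos, L)
    if oriC == ter:
        raise GenomeError("oriC and terminus coincide")
    asc_total = _arc_len(oriC, ter, L)
    asc_pos = _arc_len(oriC, pos, L)
    if asc_pos <= asc_total:
        return asc_pos / asc_total
    return _arc_len(pos, oriC, L) / _arc_len(ter, oriC, L)


def sample_cell_age(growth: GrowthParams,
                    rng: np.random.Generator | int | None = None,
                    n: int | None = None) -> float | np.ndarray:
    """Cell ages from the steady-state exponential age distribution.

    Density ``(2 ln2 / tau) * 2**(-a/tau)`` on [0, tau); sampled by inverting
    the CDF ``F(a) = 2 (1 - 2**(-a/tau))``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    u = rng.uniform(size=n) if n is not None else rng.uniform()
    return -growth.tau * np.log2(1.0 - u / 2.0)


@dataclass(frozen=True)
class PopMarker:
    """A locus as the population simulator sees it."""

    name: str
    m_rel: float
    mclass: MobilityClass


@dataclass
class PopulationSample:
    """Simulated cells with per-marker copy numbers and observed foci."""

    cells: pd.DataFrame  # cell_id, age_min, length_um, marker, copies, foci, foci_positions
    growth: GrowthParams
    cohesion: CohesionParams
    seed: int

    def mean_focus_count(self, marker: str) -> float:
        sub = self.cells[self.cells["marker"] == marker]
        return float(sub["foci"].mean())

    def nb_th(self, marker: str, m_rel: float) -> float:
        return cooper_copy_number(m_rel, self.growth)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# termd population sample seed={self.seed} "
                     f"tau={self.growth.tau} C={self.growth.C} "
                     f"D={self.growth.D_period}\n")
            self.cells.to_csv(fh, sep="\t", index=False)


def _merge_foci(points: np.ndarray, radius: float) -> np.ndarray:
    """Greedy single-linkage merging of focus positions within ``radius``."""
    if radius <= 0 or len(points) < 2:
        return points
    pts = [p for p in points]
    merged = True
    while merged and len(pts) > 1:
        merged = False
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.linalg.norm(pts[i] - pts[j]) < radius:
                    pts[i] = (pts[i] + pts[j]) / 2.0
                    pts.pop(j)
                    merged = True
                    break
            if merged:
                break
    return np.array(pts)


def simulate_population(markers: list[PopMarker],
                        growth: GrowthParams = DEFAULT_GROWTH,
                        cohesion: CohesionParams = DEFAULT_COHESION,
                        n_cells: int = 2000, seed: int = 0,
                        birth_length_um: float = 2.0) -> PopulationSample:
    """Simulate an asynchronous population and its observed focus counts.

    Per cell: draw an age from the steady-state distribution; a locus at
    relative position ``m`` is passed by a replication fork ``C*(1-m) + D``
    minutes before each division, so its copy number at age ``a`` is
    ``2**floor((C*(1-m) + D + a) / tau)`` (overlapping rounds fall out of the
    floor).  Sister pairs from the latest passage stay unresolved while the
    time since that passage is below the class cohesion time; resolved
    sisters separate by the class separation distance.  Focus positions are
    scattered about the class home position(s) and merged within the merge
    radius, giving the observed focus count.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    tau = growth.tau
    rows = []
    ages = np.asarray(sample_cell_age(growth, rng, n=n_cells))
    for ci, age in enumerate(ages):
        length = birth_length_um * (1.0 + age / tau)
        for mk in markers:
            x_before_div = growth.C * (1.0 - mk.m_rel) + growth.D_period
            copies = int(2 ** math.floor((x_before_div + age) / tau))
            t_since = (x_before_div + age) % tau
            coh_time = cohesion.cohesion_frac.get(mk.mclass, 0.0) * tau
            sep = cohesion.separation_um.get(mk.mclass, 0.5)
            # anchors: Ter-class foci at mid-cell, others split over the two
            # cell halves at the quarter positions
            if mk.mclass in (MobilityClass.TER_STRUCTURED,
                             MobilityClass.TER_ANCHORED):
                anchors_frac = [0.5] * max(copies // 2, 1)
            else:
                half = max(copies // 2, 1)
                anchors_frac = [0.25, 0.75] * ((half + 1) // 2)
                anchors_frac = anchors_frac[:half]
            pts = []
            if copies == 1:
                pts.append(np.array([anchors_frac[0] * length, 0.0])
                           + rng.normal(0, cohesion.scatter_um, 2))
            else:
                cohesive = t_since < coh_time
                for pair_i in range(copies // 2):
                    anchor = np.array([anchors_frac[pair_i] * length, 0.0])
                    if cohesive:
                        pts.append(anchor + rng.normal(0, cohesion.scatter_um, 2))
                    else:
                        for sign in (-0.5, 0.5):
                            pts.append(anchor + np.array([sign * sep, 0.0])
                                       + rng.normal(0, cohesion.scatter_um, 2))
            pts = _merge_foci(np.array(pts), cohesion.merge_radius_um)
            rows.append({
                "cell_id": f"cell{ci:05d}",
                "age_min": float(age),
                "length_um": float(length),
                "marker": mk.name,
                "copies": copies,
                "foci": len(pts),
                "foci_positions": ";".join(f"{p[0]:.3f}:{p[1]:.3f}" for p in pts),
            })
    cells = pd.DataFrame(rows)
    return PopulationSample(cells=cells, growth=growth, cohesion=cohesion,
                            seed=seed)


def population_for_strain(strain: StrainModel, marker_names: list[str],
                          stage: CellCycleStage = CellCycleStage.ANCHORED,
                          growth: GrowthParams = DEFAULT_GROWTH,
                          cohesion: CohesionParams = DEFAULT_COHESION,
                          n_cells: int = 2000, seed: int = 0
                          ) -> tuple[PopulationSample, dict[str, PopMarker]]:
    """Population sample for named markers of a strain.

    Relative map positions use the strain's post-rearrangement coordinates
    (gene dosage follows the new map) and mobility classes come from the
    insulation rule engine.
    """
    pms = {}
    for name in marker_names:
        f = strain.genome.feature(name)
        pms[name] = PopMarker(
            name=name,
            m_rel=relative_map_position(strain.genome, f.position_bp),
            mclass=classify_marker(strain, f, stage),
        )
    sample = simulate_population(list(pms.values()), growth, cohesion,
                                 n_cells, seed)
    return sample, pms
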