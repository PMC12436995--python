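"""From IPM growth rates to coexistence outcomes.

For each latitude, the zero-growth isocline is the set of (own, other)
density combinations at which the daily growth rate satisfies
log(lambda) = 0.  A least-squares line through the isocline points yields
axis intercepts whose reciprocals are Lotka-Volterra-style competition
coefficients (alpha_ij = per-capita effect of latitude j on latitude i;
index 1 = Southern by convention):

    niche overlap          rho   = sqrt((a12 * a21) / (a11 * a22))
    competitive ability    k1/k2 = sqrt((a11 * a12) / (a22 * a21))

Mutual invasibility (a11 > a21 and a22 > a12, equivalently
rho < k1/k2 < 1/rho) gives stable coexistence; exactly one invader gives
exclusion of the non-invader; neither gives a priority effect.  The
isocline intersection is the predicted equilibrium, summarized as the
Southern proportion p_S.  Dynamic 100-day projections of both latitudes,
updating each kernel with the current densities, provide a check of the
statics that does not assume isocline linearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ipm import DEFAULT_INTERVAL_DAYS, KernelBuilder, MeshConfig
from .vital_rates import ModelSet

CLASSIFICATIONS = (
    "stable_coexistence",
    "exclusion_of_south",
    "exclusion_of_north",
    "priority_effect",
)

DENSITY_RANGE = (1.0, 1000.0)
DEFAULT_N_GRID = 25


@dataclass(frozen=True)
class LVParameters:
    """Two-competitor Lotka-Volterra parameters (alpha_ij: effect of j on i)."""

    r1: float
    r2: float
    a11: float
    a12: float
    a21: float
    a22: float


@dataclass
class Isocline:
    latitude: str
    points: pd.DataFrame  # columns: other, own (densities with log lambda = 0)
    slope: float
    intercept_own: float     # own-axis intercept (other = 0)
    intercept_other: float   # competitor-axis intercept (own = 0); inf if none
    r_squared: float
    present: bool = True
    lam_low_density: float = np.nan

    @classmethod
    def absent(cls, latitude: str, lam_low: float) -> "Isocline":
        return cls(latitude=latitude, points=pd.DataFrame(columns=["other", "own"]),
                   slope=np.nan, intercept_own=np.nan, intercept_other=np.nan,
                   r_squared=np.nan, present=False, lam_low_density=lam_low)


@dataclass(frozen=True)
class CompetitionCoefficients:
    a11: float  # South on South
    a12: float  # North on South
    a21: float  # South on North
    a22: float  # North on North


@dataclass
class CoexistenceOutcome:
    temperature_std: float
    rho: float
    k_ratio: float
    classification: str
    N_south: float
    N_north: float
    p_south: float
    coefficients: CompetitionCoefficients | None
    south_viable: bool
    north_viable: bool
    isoclines: dict = field(default_factory=dict, repr=False)


def _lambda_function(models, T, latitude, mesh, draw, interval_days,
                     growth_mode):
    """Own/other-density -> daily growth rate, for one latitude."""
    builder = KernelBuilder(models, T, latitude, mesh=mesh, draw=draw,
                            interval_days=interval_days,
                            growth_mode=growth_mode)
    return builder.lam


def find_isocline(
    models,
    T: float | None = None,
    latitude: str | None = None,
    density_grid=DENSITY_RANGE,
    n_grid: int = DEFAULT_N_GRID,
    tolerance: float = 1e-6,
    mesh: MeshConfig | None = None,
    draw: int | None = None,
    interval_days: float = DEFAULT_INTERVAL_DAYS,
    growth_mode: str = "increment",
) -> Isocline:
    """Locate the zero-growth isocline of one latitude.

    `models` is either a :class:`ModelSet` (then `T` and `latitude` are
    required) or a callable lambda(own_density, other_density) used
    directly — the latter supports analytic test oracles.  Competitor
    densities are scanned on a log-spaced grid; for each, Brent's method
    solves log(lambda) = 0 for the own-latitude density inside the grid
    range (points without a root are omitted).  A least-squares line
    through the points provides both axis intercepts.
    """
    if callable(models):
        lam = models
        lat = latitude or "?"
    else:
        if T is None or latitude is None:
            raise ValueError("T and latitude are required with a ModelSet")
        lam = _lambda_function(models, T, latitude, mesh, draw,
                               interval_days, growth_mode)
        lat = latitude
    lo, hi = float(density_grid[0]), float(density_grid[-1])

    lam_low = lam(lo, lo)
    if not lam_low > 1.0:  # not viable even at low density
        return Isocline.absent(lat, lam_low)

    others = np.geomspace(lo, hi, n_grid)
    pts = []
    for a in others:
        f_lo = np.log(lam(lo, a))
        if f_lo < 0.0:
            continue
        f_hi = np.log(lam(hi, a))
        if f_hi > 0.0:
            continue
        root = brentq(lambda n: np.log(lam(n, a)), lo, hi,
                      xtol=1e-5, rtol=1e-10, maxiter=200)
        if abs(np.log(lam(root, a))) <= max(tolerance, 1e-9):
            pts.append((a, root))
    if len(pts) < 2:
        return Isocline.absent(lat, lam_low)

    points = pd.DataFrame(pts, columns=["other", "own"])
    slope, intercept = np.polyfit(points["other"], points["own"], 1)
    pred = intercept + slope * points["other"]
    ss_res = float(np.sum((points["own"] - pred) ** 2))
    ss_tot = float(np.sum((points["own"] - points["own"].mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    inter_other = (-intercept / slope) if slope < 0 else np.inf
    return Isocline(latitude=lat, points=points, slope=float(slope),
                    intercept_own=float(intercept),
                    intercept_other=float(inter_other), r_squared=r2,
                    present=True, lam_low_density=lam_low)


def competition_coefficients(iso_south: Isocline,
                             iso_north: Isocline) -> CompetitionCoefficients:
    """Reciprocal axis intercepts of both isoclines -> alpha coefficients.

    A competitor-axis intercept at infinity (no measurable inter-latitude
    effect) maps to an inter-latitude coefficient of 0.
    """
    if not (iso_south.present and iso_north.present):
        raise ValueError("both isoclines must be present")
    if iso_south.intercept_own <= 0 or iso_north.intercept_own <= 0:
        raise ValueError("own-axis intercepts must be positive")
    a11 = 1.0 / iso_south.intercept_own
    a12 = 0.0 if np.isinf(iso_south.intercept_other) else 1.0 / iso_south.intercept_other
    a22 = 1.0 / iso_north.intercept_own
    a21 = 0.0 if np.isinf(iso_north.intercept_other) else 1.0 / iso_north.intercept_other
    return CompetitionCoefficients(a11=a11, a12=a12, a21=a21, a22=a22)


def niche_overlap(coeffs: CompetitionCoefficients) -> float:
    """rho = sqrt((a12 a21)/(a11 a22)); intra coefficients must be positive."""
    if coeffs.a11 <= 0 or coeffs.a22 <= 0 or coeffs.a12 < 0 or coeffs.a21 < 0:
        raise ValueError("competition coefficients out of domain")
    return float(np.sqrt((coeffs.a12 * coeffs.a21) / (coeffs.a11 * coeffs.a22)))


def competitive_ability_ratio(coeffs: CompetitionCoefficients) -> float:
    """k1/k2 = sqrt((a11 a12)/(a22 a21)); inf/0 when one inter effect is 0."""
    if coeffs.a11 <= 0 or coeffs.a22 <= 0 or coeffs.a12 < 0 or coeffs.a21 < 0:
        raise ValueError("competition coefficients out of domain")
    num = coeffs.a11 * coeffs.a12
    den = coeffs.a22 * coeffs.a21
    if den == 0.0:
        return np.inf if num > 0 else np.nan
    return float(np.sqrt(num / den))


def classify_outcome(coeffs: CompetitionCoefficients | None = None,
                     south_viable: bool = True, north_viable: bool = True,
                     lam_south: float = np.nan,
                     lam_north: float = np.nan) -> str:
    """Map invasion conditions (or viability flags) to an outcome label.

    North invades the Southern equilibrium iff a11 > a21; South invades
    the Northern equilibrium iff a22 > a12 (strict; boundary ties count
    as failed invasion).  Non-viability at low density short-circuits:
    the non-viable latitude is excluded; if neither is viable the
    latitude with the lower low-density growth rate is reported excluded.
    """
    if not south_viable or not north_viable:
        if south_viable:
            return "exclusion_of_north"
        if north_viable:
            return "exclusion_of_south"
        return ("exclusion_of_south" if not lam_south >= lam_north
                else "exclusion_of_north")
    if coeffs is None:
        raise ValueError("need coefficients when both latitudes are viable")
    north_invades = coeffs.a11 > coeffs.a21
    south_invades = coeffs.a22 > coeffs.a12
    if north_invades and south_invades:
        return "stable_coexistence"
    if north_invades:
        return "exclusion_of_south"
    if south_invades:
        return "exclusion_of_north"
    return "priority_effect"


def equilibrium_point(iso_south: Isocline, iso_north: Isocline):
    """Intersect the fitted isocline lines.

    Returns (N_south, N_north, p_south) where p_south snaps to 0 or 1
    when the raw intersection leaves the positive quadrant (the dominant
    isocline's latitude takes the system).  Parallel lines fall back to
    comparing own-axis intercepts.
    """
    if not (iso_south.present and iso_north.present):
        raise ValueError("both isoclines must be present")
    # lines: N_S = b0S + b1S * N_N  and  N_N = b0N + b1N * N_S
    b0S, b1S = iso_south.intercept_own, iso_south.slope
    b0N, b1N = iso_north.intercept_own, iso_north.slope
    det = 1.0 - b1S * b1N
    if abs(det) < 1e-12:
        p = 1.0 if b0S > b0N else (0.0 if b0N > b0S else 0.5)
        return np.nan, np.nan, p
    n_s = (b0S + b1S * b0N) / det
    n_n = (b0N + b1N * b0S) / det
    if n_s <= 0.0 and n_n > 0.0:
        return n_s, n_n, 0.0
    if n_n <= 0.0 and n_s > 0.0:
        return n_s, n_n, 1.0
    if n_s <= 0.0 and n_n <= 0.0:
        return n_s, n_n, 1.0 if b0S > b0N else 0.0
    return n_s, n_n, float(n_s / (n_s + n_n))


def analyze_temperature(
    models: ModelSet,
    T: float,
    mesh: MeshConfig | None = None,
    draw: int | None = None,
    n_grid: int = DEFAULT_N_GRID,
    density_grid=DENSITY_RANGE,
    tolerance: float = 1e-6,
    interval_days: float = DEFAULT_INTERVAL_DAYS,
    growth_mode: str = "increment",
) -> CoexistenceOutcome:
    """Full isocline -> coefficients -> MCT chain at one temperature."""
    isos = {}
    for lat in ("S", "N"):
        isos[lat] = find_isocline(models, T, lat, density_grid=density_grid,
                                  n_grid=n_grid, tolerance=tolerance,
                                  mesh=mesh, draw=draw,
                                  interval_days=interval_days,
                                  growth_mode=growth_mode)
    sv, nv = isos["S"].present, isos["N"].present
    if sv and nv:
        coeffs = competition_coefficients(isos["S"], isos["N"])
        rho = niche_overlap(coeffs)
        k = competitive_ability_ratio(coeffs)
        label = classify_outcome(coeffs)
        n_s, n_n, p_s = equilibrium_point(isos["S"], isos["N"])
        # one-sided exclusion: the interior intersection (if any) is a
        # saddle; the stable state is the winner's single-genotype
        # equilibrium.  For priority effects the interior point (the
        # separatrix) is retained as the summary.
        if label == "exclusion_of_south":
            n_s, n_n, p_s = 0.0, isos["N"].intercept_own, 0.0
        elif label == "exclusion_of_north":
            n_s, n_n, p_s = isos["S"].intercept_own, 0.0, 1.0
    else:
        coeffs, rho, k = None, np.nan, np.nan
        label = classify_outcome(None, south_viable=sv, north_viable=nv,
                                 lam_south=isos["S"].lam_low_density,
                                 lam_north=isos["N"].lam_low_density)
        n_s = n_n = np.nan
        p_s = {"exclusion_of_south": 0.0, "exclusion_of_north": 1.0}[label]
    return CoexistenceOutcome(
        temperature_std=T, rho=rho, k_ratio=k, classification=label,
        N_south=n_s, N_north=n_n, p_south=p_s, coefficients=coeffs,
        south_viable=sv, north_viable=nv, isoclines=isos,
    )


def neonate_state(models: ModelSet, T: float, latitude: str,
                  n_individuals: float, mesh: MeshConfig,
                  draw: int | None = None) -> np.ndarray:
    """Initial size distribution: neonate sizes at low density (S=A=1)."""
    builder = KernelBuilder(models, T, latitude, mesh=mesh, draw=draw)
    _, F, _ = builder.matrices(1.0, 1.0)
    col = F[:, np.argmin(np.abs(mesh.midpoints))]  # mother of average size
    col = col / col.sum()
    return n_individuals * col


def simulate_competition(
    models: ModelSet,
    T: float,
    n_days: int = 100,
    init_per_latitude: float = 6.0,
    mesh: MeshConfig | None = None,
    draw: int | None = None,
    interval_days: float = DEFAULT_INTERVAL_DAYS,
    growth_mode: str = "increment",
    max_density: float = 1e6,
) -> pd.DataFrame:
    """Project both latitudes jointly, refreshing kernels with current densities.

    Returns a frame with columns day, N_south, N_north, p_south; row 0 is
    the initial state.  Densities are female totals (the kernels track
    females only).
    """
    mesh = mesh or MeshConfig()
    builders = {
        lat: KernelBuilder(models, T, lat, mesh=mesh, draw=draw,
                           interval_days=interval_days,
                           growth_mode=growth_mode)
        for lat in ("S", "N")
    }
    state = {
        lat: neonate_state(models, T, lat, init_per_latitude, mesh, draw)
        for lat in ("S", "N")
    }
    rows = []
    for day in range(n_days + 1):
        n_s = float(state["S"].sum())
        n_n = float(state["N"].sum())
        tot = n_s + n_n
        rows.append({"day": day, "N_south": n_s, "N_north": n_n,
                     "p_south": n_s / tot if tot > 0 else np.nan})
        if day == n_days:
            break
        if max(n_s, n_n) > max_density:
            raise RuntimeError(f"population diverged (> {max_density:g}) "
                               f"on day {day}")
        P_s, F_s, _ = builders["S"].matrices(S=n_s, A=n_n)
        P_n, F_n, _ = builders["N"].matrices(S=n_n, A=n_s)
        state["S"] = (P_s + F_s) @ state["S"]
        state["N"] = (P_n + F_n) @ state["N"]
    return pd.DataFrame(rows)


def propagate_uncertainty(
    models: ModelSet,
    T: float,
    n_draws: int = 1000,
    mesh: MeshConfig | None = None,
    n_grid: int = DEFAULT_N_GRID,
    density_grid=DENSITY_RANGE,
    interval_days: float = DEFAULT_INTERVAL_DAYS,
    growth_mode: str = "increment",
):
    """Re-run the MCT chain for each posterior draw of every vital rate.

    Returns (per_draw DataFrame, summary dict).  Draws with absent
    isoclines are classified by viability and counted, never dropped;
    classification fractions therefore sum to 1 over the four labels.
    """
    if n_draws > 0 and models.min_draws() < n_draws:
        raise ValueError(
            f"need >= {n_draws} draws per model, have {models.min_draws()}")
    rows = []
    for d in (range(n_draws) if n_draws > 0 else [None]):
        out = analyze_temperature(models, T, mesh=mesh, draw=d,
                                  n_grid=n_grid, density_grid=density_grid,
                                  interval_days=interval_days,
                                  growth_mode=growth_mode)
        c = out.coefficients
        rows.append({
            "draw": -1 if d is None else d, "rho": out.rho,
            "k_ratio": out.k_ratio, "classification": out.classification,
            "p_south": out.p_south,
            "a11": c.a11 if c else np.nan, "a12": c.a12 if c else np.nan,
            "a21": c.a21 if c else np.nan, "a22": c.a22 if c else np.nan,
        })
    per_draw = pd.DataFrame(rows)
    fractions = {label: float((per_draw["classification"] == label).mean())
                 for label in CLASSIFICATIONS}
    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    summary = {
        "classification_fractions": fractions,
        "quantiles": {
            col: dict(zip(map(str, qs),
                          np.nanquantile(per_draw[col].to_numpy(float), qs)))
            for col in ("rho", "k_ratio", "p_south")
        },
    }
    return per_draw, summary
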