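"""Mass-photometry oligomer decomposition.

A mass-photometry measurement yields one mass (kDa) per particle landing
event.  The distribution of these masses is decomposed into Gaussian
peaks; each peak is assigned an oligomeric state (subunit count) from a
candidate grid, and the peak-area percentages — which count *particles* —
are converted into monomer-level percentages by weighting each peak's area
by its subunit count:

    monomer_pct_i = 100 * area_pct_i * n_i / sum_j(area_pct_j * n_j)

For CaMKII this distinguishes a population dominated by dodecameric
holoenzymes from activity-induced 24-mer (holoenzyme pair) particles and
rare dissociated dimers.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import signal, stats

#: Calmodulin mass (kDa), added per subunit for ligand-bound assignments.
CALMODULIN_KDA = 16.7


@dataclass
class MixturePeak:
    """One fitted Gaussian peak of the particle-mass distribution."""

    mean: float               # kDa
    sd: float                 # kDa
    area_pct: float           # % of fitted particle population
    n_mer: int | None = None
    monomer_pct: float | None = None


@dataclass
class MixtureFit:
    """Multi-Gaussian decomposition with the density curve and residual."""

    peaks: list[MixturePeak]
    grid: np.ndarray
    density: np.ndarray
    fitted: np.ndarray

    @property
    def residual(self) -> np.ndarray:
        return self.density - self.fitted


@dataclass(frozen=True)
class OligomerAssignment:
    """Candidate subunit count closest to a peak mass, with audit fields."""

    n_mer: int
    expected_mass: float
    distance: float


def fit_mixture(
    events,
    n_peaks: int | str = "auto",
    mass_window: tuple[float, float] | None = None,
    grid_points: int = 512,
    min_events: int = 50,
    prominence_frac: float = 0.02,
) -> MixtureFit:
    """Decompose a particle-mass distribution into Gaussian peaks.

    Peaks are seeded at local maxima of a Gaussian kernel density estimate
    (Silverman bandwidth; or the ``n_peaks`` most prominent maxima), and
    the Gaussian components are then refined by least squares against the
    histogram density of the events, with inverse-variance (Poisson) bin
    weights.  Fitting the histogram rather than the KDE curve avoids the
    kernel broadening a global bandwidth imposes on narrow or minor peaks,
    and the weights keep the dominant peak from drowning out minor ones.
    Area percentages come from the analytic component integrals.
    """
    masses = np.asarray(getattr(events, "masses", events), dtype=float)
    masses = masses[np.isfinite(masses)]
    if mass_window is not None:
        lo, hi = mass_window
        masses = masses[(masses >= lo) & (masses <= hi)]
    if len(masses) < min_events:
        raise ValueError(
            f"need >={min_events} events in the mass window, got {len(masses)}"
        )
    lo = float(masses.min())
    hi = float(masses.max())
    pad = 0.05 * (hi - lo) if hi > lo else 1.0
    hist, edges = np.histogram(masses, bins=grid_points // 2,
                               range=(lo - pad, hi + pad), density=True)
    grid = 0.5 * (edges[:-1] + edges[1:])
    density = hist
    kde = stats.gaussian_kde(masses, bw_method="silverman")
    smooth = kde(grid)

    peak_idx, props = signal.find_peaks(
        smooth, prominence=prominence_frac * float(smooth.max())
    )
    if len(peak_idx) == 0:
        peak_idx = np.array([int(np.argmax(density))])
        props = {"prominences": np.array([float(density.max())])}
    if n_peaks != "auto":
        n_peaks = int(n_peaks)
        if len(peak_idx) < n_peaks:
            raise ValueError(
                f"requested {n_peaks} peaks but only {len(peak_idx)} local maxima found"
            )
        order = np.argsort(props["prominences"])[::-1][:n_peaks]
        peak_idx = np.sort(peak_idx[order])

    widths = signal.peak_widths(smooth, peak_idx, rel_height=0.5)[0]
    dx = grid[1] - grid[0]
    params = lmfit.Parameters()
    for i, (idx, w) in enumerate(zip(peak_idx, widths)):
        sigma0 = max(w * dx / 2.355, dx)
        amp0 = float(max(density[max(idx - 2, 0):idx + 3].max(), smooth[idx]))
        params.add(f"amp{i}", value=amp0, min=0.0)
        params.add(f"mu{i}", value=float(grid[idx]),
                   min=float(grid[0]), max=float(grid[-1]))
        params.add(f"sigma{i}", value=sigma0, min=dx / 2)

    k = len(peak_idx)
    # Poisson noise on bin densities: var = density / (n * bin_width)
    dens_floor = 1.0 / (len(masses) * dx)
    bin_sd = np.sqrt(np.maximum(density, dens_floor) / (len(masses) * dx))

    def model(p):
        out = np.zeros_like(grid)
        for i in range(k):
            out += p[f"amp{i}"].value * np.exp(
                -((grid - p[f"mu{i}"].value) ** 2) / (2 * p[f"sigma{i}"].value ** 2)
            )
        return out

    res = lmfit.minimize(lambda p: (model(p) - density) / bin_sd, params,
                         method="leastsq")
    if not res.success:
        raise RuntimeError(f"multi-Gaussian fit did not converge: {res.message}")
    p = res.params
    areas = np.array(
        [p[f"amp{i}"].value * p[f"sigma{i}"].value * np.sqrt(2 * np.pi) for i in range(k)]
    )
    total = areas.sum()
    if total <= 0:
        raise RuntimeError("degenerate multi-Gaussian fit: zero total area")
    peaks = [
        MixturePeak(
            mean=float(p[f"mu{i}"].value),
            sd=float(p[f"sigma{i}"].value),
            area_pct=float(100.0 * areas[i] / total),
        )
        for i in range(k)
    ]
    peaks.sort(key=lambda pk: pk.mean)
    return MixtureFit(peaks=peaks, grid=grid, density=density, fitted=model(p))


def assign_oligomer(
    peak_mean: float,
    monomer_mass: float,
    candidates,
    ligand_mass: float = 0.0,
    ligand_count: int = 0,
) -> OligomerAssignment:
    """Candidate subunit count whose expected mass is nearest the peak mean.

    The expected mass of an n-mer is ``n * (monomer_mass + ligand_count *
    ligand_mass)`` (one ligand per subunit at most, e.g. bound calmodulin
    in activated samples).  Ties break toward the smaller n.
    """
    candidates = sorted(int(n) for n in candidates)
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    if monomer_mass <= 0:
        raise ValueError("monomer_mass must be positive")
    per_subunit = monomer_mass + ligand_count * ligand_mass
    best = min(candidates, key=lambda n: (abs(peak_mean - n * per_subunit), n))
    expected = best * per_subunit
    return OligomerAssignment(n_mer=best, expected_mass=expected,
                              distance=abs(peak_mean - expected))


def monomer_weights(area_pcts, n_mers) -> tuple[np.ndarray, float]:
    """Monomer-weighted peak areas (area % x subunit count) and their total."""
    areas = np.asarray(area_pcts, dtype=float)
    ns = np.asarray(n_mers, dtype=float)
    if areas.size == 0:
        raise ValueError("empty peak list")
    if areas.shape != ns.shape:
        raise ValueError("area_pcts and n_mers must have equal length")
    if np.any(areas <= 0) or np.any(ns < 1):
        raise ValueError("areas must be positive and subunit counts >=1")
    weighted = areas * ns
    return weighted, float(weighted.sum())


def monomer_fractions(area_pcts, n_mers) -> np.ndarray:
    """Percent of monomers residing in each peak.

    Peak areas count particles; multiplying by the subunit count converts
    to monomers, and normalizing to the summed monomer count gives each
    peak's monomer-level share (sums to 100 exactly, before rounding).
    """
    weighted, total = monomer_weights(area_pcts, n_mers)
    return 100.0 * weighted / total


def annotate_peaks(
    fit: MixtureFit,
    monomer_mass: float,
    candidates,
    ligand_mass: float = 0.0,
    ligand_count: int = 0,
) -> list[MixturePeak]:
    """Assign oligomeric states and monomer percentages to fitted peaks."""
    for pk in fit.peaks:
        pk.n_mer = assign_oligomer(
            pk.mean, monomer_mass, candidates, ligand_mass, ligand_count
        ).n_mer
    fractions = monomer_fractions(
        [pk.area_pct for pk in fit.peaks], [pk.n_mer for pk in fit.peaks]
    )
    for pk, frac in zip(fit.peaks, fractions):
        pk.monomer_pct = float(frac)
    return fit.peaks
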