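"""Seeded synthetic data with known ground truth for every pipeline stage.

Each generator is a pure function of its truth object (the seed included):
calling it twice yields identical output.  The generators emulate the four
experimental readouts the pipeline analyses — phospho-western time courses,
mixed-isotope crosslink tables, mass-photometry landing-event lists and
two-channel TIRF fields — at the study's own conditions (enzyme titration
0.5/2/10/100 nM, triplicates, timepoints 1-60 min; two crosslinking
replicates; dimer/dodecamer/24-mer mass mixtures), so that parameter
recovery against known truth is the test surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._sequence import SYNTHETIC_SUBUNIT_SEQUENCE, lysine_positions, tryptic_peptide
from .kinetics import eval_model
from .xlms import DEFAULT_DOMAIN_MAP, DomainMap

#: Timepoints (min) and enzyme concentrations (nM) of the titration assay.
DEFAULT_TIMEPOINTS = (1.0, 2.0, 5.0, 10.0, 15.0, 30.0, 60.0)
DEFAULT_CONCENTRATIONS = (0.5, 2.0, 10.0, 100.0)

XL_SCENARIOS = ("basal", "ihp", "exchange")


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# kinetics

@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth parameters of the two-component phosphorylation model."""

    a1: float = 0.6
    r1: float = 0.3          # 1/min
    k2: float = 0.004        # 1/(nM min)
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    replicates: int = 3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.a1 <= 1.0:
            raise ValueError(f"A1 must lie in [0, 1], got {self.a1}")
        if self.r1 <= 0 or self.k2 <= 0:
            raise ValueError("rates r1 and k2 must be positive")
        for name, vals in (("concentrations", self.concentrations),
                           ("timepoints", self.timepoints)):
            arr = np.asarray(vals, float)
            if arr.size == 0 or np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly positive and sorted")
        if self.replicates < 1:
            raise ValueError("need >=1 replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def gen_timecourse(truth: KineticTruth) -> pd.DataFrame:
    """Triplicate phospho time courses with additive Gaussian noise.

    One row per (concentration, time, replicate); the normalized fraction
    is the model value plus N(0, noise_sd) noise, clipped to [0, 1.5].
    Total signal is fixed at 1 so phospho/total equals the fraction.
    """
    rngs = _spawn_rngs(truth.seed, truth.replicates)
    rows = []
    for rep, rng in enumerate(rngs, start=1):
        for c in truth.concentrations:
            clean = eval_model(np.asarray(truth.timepoints), truth.a1,
                               truth.r1, truth.k2, c)
            noisy = np.clip(clean + rng.normal(0.0, truth.noise_sd, len(clean))
                            if truth.noise_sd > 0 else clean, 0.0, 1.5)
            for t, v in zip(truth.timepoints, noisy):
                rows.append((c, t, rep, float(v), 1.0, float(v)))
    return pd.DataFrame(
        rows, columns=["conc_nM", "time_min", "replicate", "phospho", "total",
                       "normalized"]
    )


# ---------------------------------------------------------------------------
# crosslinking

@dataclass(frozen=True)
class XlScenario:
    """Mixed-isotope crosslink table generator settings.

    ``basal`` draws no heterotypic intensity anywhere; ``ihp`` draws it
    only for kinase-kinase site pairs at mean mixing ratio
    ``hetero_ratio``; ``exchange`` draws it for every domain pair at the
    same flat mean ratio.
    """

    name: str
    n_crosslinks: int = 200
    domain_map: DomainMap = field(default_factory=lambda: DEFAULT_DOMAIN_MAP)
    hetero_ratio: float = 0.25
    intensity_scale: float = 1e6
    noise_cv: float = 0.2
    replicates: int = 2
    incubation: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.name not in XL_SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; expected one of {XL_SCENARIOS}")
        if self.n_crosslinks <= 0:
            raise ValueError("n_crosslinks must be positive")
        if self.hetero_ratio < 0 or self.noise_cv < 0:
            raise ValueError("hetero_ratio and noise_cv must be nonnegative")
        if self.replicates < 1:
            raise ValueError("need >=1 replicate")
        lo, hi = self.domain_map.span
        if lo != 1 or hi > len(SYNTHETIC_SUBUNIT_SEQUENCE):
            raise ValueError("domain map must partition the subunit sequence range")


def domain_pair_weights(domain_map: DomainMap = DEFAULT_DOMAIN_MAP) -> dict[tuple[str, str], float]:
    """Sampling weight of each unordered domain pair.

    Proportional to the number of distinct lysine pairs the two domains
    offer (DSS is amine-reactive, so only lysine pairs are drawable).
    """
    names = domain_map.names
    n_lys = {n: len(lysine_positions(*domain_map.ranges[n])) for n in names}
    raw: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i:]:
            if a == b:
                raw[(a, b)] = n_lys[a] * (n_lys[a] - 1) / 2
            else:
                raw[(a, b)] = n_lys[a] * n_lys[b]
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the stated CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def gen_xl_table(scn: XlScenario) -> pd.DataFrame:
    """Synthetic crosslink table with ground-truth labels.

    Unique lysine site pairs are sampled by domain-pair weight (see
    ``domain_pair_weights``), then observed in every replicate with
    independent log-normal intensity noise.  Ground truth columns
    ``domain_a``/``domain_b``/``true_hetero``/``true_R`` are retained for
    recovery tests; the weights used are stored in
    ``df.attrs['domain_pair_weights']``.
    """
    rng = np.random.default_rng(scn.seed)
    weights = domain_pair_weights(scn.domain_map)
    pairs = list(weights)
    probs = np.array([weights[p] for p in pairs])
    lys = {n: lysine_positions(*scn.domain_map.ranges[n]) for n in scn.domain_map.names}

    seen: set[tuple[int, int]] = set()
    sites: list[tuple[int, int, str, str]] = []
    max_tries = 200 * scn.n_crosslinks
    tries = 0
    while len(sites) < scn.n_crosslinks and tries < max_tries:
        tries += 1
        dom_a, dom_b = pairs[rng.choice(len(pairs), p=probs)]
        if dom_a == dom_b:
            pos_a, pos_b = rng.choice(lys[dom_a], size=2, replace=False)
        else:
            pos_a = rng.choice(lys[dom_a])
            pos_b = rng.choice(lys[dom_b])
        key = (min(pos_a, pos_b), max(pos_a, pos_b))
        if key in seen:
            continue
        seen.add(key)
        sites.append((int(pos_a), int(pos_b), dom_a, dom_b))
    if len(sites) < scn.n_crosslinks:
        raise ValueError(
            f"could not draw {scn.n_crosslinks} unique lysine pairs "
            f"(only {len(sites)} available)"
        )

    condition = "basal" if scn.name == "basal" else "activated"
    rows = []
    for rep in range(1, scn.replicates + 1):
        n = len(sites)
        i_ll = scn.intensity_scale * _lognormal_factor(rng, scn.noise_cv, n)
        i_hh = scn.intensity_scale * _lognormal_factor(rng, scn.noise_cv, n)
        for j, (pos_a, pos_b, dom_a, dom_b) in enumerate(sites):
            if scn.name == "basal":
                hetero = False
            elif scn.name == "ihp":
                hetero = dom_a == "kinase" and dom_b == "kinase"
            else:
                hetero = True
            if hetero:
                base = scn.hetero_ratio * (i_ll[j] + i_hh[j]) / 2.0
                i_lh = base * _lognormal_factor(rng, scn.noise_cv, None)
                i_hl = base * _lognormal_factor(rng, scn.noise_cv, None)
                true_r = scn.hetero_ratio
            else:
                i_lh = i_hl = 0.0
                true_r = 0.0
            rows.append(
                (
                    tryptic_peptide(pos_a), tryptic_peptide(pos_b),
                    pos_a, pos_b, rep, condition, scn.incubation,
                    float(i_ll[j]), float(i_lh), float(i_hl), float(i_hh[j]),
                    dom_a, dom_b, hetero, true_r,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "pep_a", "pep_b", "pos_a", "pos_b", "replicate", "condition",
            "incubation", "I_LL", "I_LH", "I_HL", "I_HH",
            "domain_a", "domain_b", "true_hetero", "true_R",
        ],
    )
    df.attrs["domain_pair_weights"] = weights
    return df


# ---------------------------------------------------------------------------
# mass photometry

@dataclass(frozen=True)
class MassMixtureTruth:
    """Gaussian mixture of particle masses (kDa)."""

    components: Sequence[tuple[float, float, float]] = (
        (157.0, 12.0, 0.047),
        (721.0, 25.0, 0.859),
        (1442.0, 25.0, 0.094),
    )
    n_events: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_events < 0:
            raise ValueError("n_events must be nonnegative")
        if not self.components:
            raise ValueError("mixture needs >=1 component")
        weights = [w for _, _, w in self.components]
        if any(sd <= 0 for _, sd, _ in self.components):
            raise ValueError("component SDs must be positive")
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-6:
            raise ValueError("component weights must be nonnegative and sum to 1")


@dataclass
class MassEventList:
    """Particle masses (kDa), one landing event per entry."""

    masses: np.ndarray
    labels: np.ndarray        # ground-truth component index per event
    condition: str | None = None


def gen_mass_events(truth: MassMixtureTruth, condition: str | None = None) -> MassEventList:
    """Draw particle masses from the stated Gaussian mixture."""
    rng = np.random.default_rng(truth.seed)
    weights = np.array([w for _, _, w in truth.components])
    labels = rng.choice(len(truth.components), size=truth.n_events, p=weights)
    means = np.array([m for m, _, _ in truth.components])
    sds = np.array([s for _, s, _ in truth.components])
    masses = rng.normal(means[labels], sds[labels]) if truth.n_events else np.empty(0)
    return MassEventList(masses=np.asarray(masses, float), labels=labels,
                         condition=condition)


# ---------------------------------------------------------------------------
# TIRF spot images

@dataclass(frozen=True)
class SpotImageTruth:
    """Two-channel spot-field generator settings."""

    image_shape: tuple[int, int] = (512, 512)
    n_spots: int = 200
    coloc_fraction: float = 0.5
    psf_sigma: float = 1.5        # pixels
    amplitude: float = 500.0      # peak intensity per spot
    background: float = 100.0     # mean background level
    background_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.background_sd < 0 or self.amplitude <= 0:
            raise ValueError("amplitude must be positive, background_sd nonnegative")
        capacity = (self.image_shape[0] * self.image_shape[1]) // max(
            int(np.ceil((6 * self.psf_sigma) ** 2)), 1
        )
        if self.n_spots > capacity:
            raise ValueError(
                f"{self.n_spots} spots exceed image capacity (~{capacity} "
                f"non-overlapping PSF footprints)"
            )


@dataclass
class ImagePair:
    """Two-channel intensity field with ground-truth spot centers."""

    channel_1: np.ndarray
    channel_2: np.ndarray
    centers_1: np.ndarray
    centers_2: np.ndarray


def _render_spots(shape, centers, amplitude, sigma) -> np.ndarray:
    img = np.zeros(shape, float)
    half = int(np.ceil(4 * sigma))
    for cy, cx in centers:
        y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, shape[0])
        x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, shape[1])
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
        )
    return img


def gen_spot_images(truth: SpotImageTruth) -> ImagePair:
    """Two spot images sharing a controlled fraction of spot centers.

    ``coloc_fraction`` of the spots appear at identical positions in both
    channels; the remainder are placed independently.  Spots are rendered
    as Gaussian point-spread functions on a noisy background.
    """
    rng = np.random.default_rng(truth.seed)
    h, w = truth.image_shape
    margin = 4 * truth.psf_sigma

    def draw(n):
        return np.column_stack(
            [rng.uniform(margin, h - margin, n), rng.uniform(margin, w - margin, n)]
        )

    n_shared = int(round(truth.coloc_fraction * truth.n_spots))
    shared = draw(n_shared)
    own_1 = draw(truth.n_spots - n_shared)
    own_2 = draw(truth.n_spots - n_shared)
    centers_1 = np.vstack([shared, own_1])
    centers_2 = np.vstack([shared, own_2])

    pair = []
    for centers in (centers_1, centers_2):
        img = _render_spots((h, w), centers, truth.amplitude, truth.psf_sigma)
        img += truth.background
        if truth.background_sd > 0:
            img += rng.normal(0.0, truth.background_sd, (h, w))
        pair.append(np.clip(img, 0.0, None))
    return ImagePair(channel_1=pair[0], channel_2=pair[1],
                     centers_1=centers_1, centers_2=centers_2)
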