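# Methods

This note documents the models implemented in `ihp`, the synthetic data
they are validated against, the numerical choices, and the limits of what
the passing test suite demonstrates.

## Two-component autophosphorylation model (`ihp.kinetics`)

The phosphorylated fraction of an excess substrate kinase phosphorylated by
an active kinase at concentration `c` (nM) is modelled as

    f(t) = 1 − A1·exp(−r1·t) − (1 − A1)·exp(−c·k2·t)

with `A1 ∈ [0, 1]` (the second amplitude is identically `1 − A1`), `r1` in
1/min the concentration-independent rate (intra-holoenzyme reaction after
mixing, and any substrate-autonomous contribution) and `k2` in 1/(nM·min)
the concentration-scaled rate expected of a collisional, inter-holoenzyme
reaction. `f(0) = 0`, `f(∞) = 1`, and `f` is nondecreasing in `t` for all
valid parameters.

**Global fit.** One (A1, r1, k2) triple is fitted across all concentration
curves simultaneously by bounded least squares on per-(c, t) replicate
means. Weights are 1/SD across replicates, with each SD **floored at the
median SD of its curve**: SDs estimated from ~3 replicates are themselves
so noisy that an accidentally tiny SD otherwise dominates the loss and
visibly destabilizes `k2` (in seeded recovery runs the fraction of datasets
recovered within ±20% rose from ~78% to ~95% with the floor). A zero or
unavailable SD also falls back to the median; a curve with no usable SDs is
unweighted. Two-exponential surfaces are multimodal, so the fit restarts
from 5 spread initial points (A1 across (0.1, 0.9), rates log-spaced around
the data's time and concentration scales) and the lowest weighted residual
wins. At concentrations declared *saturating* the curve uses `A1 = 0`
(single component with rate `c·k2`), reflecting protocols in which the
fast phase is unresolvable at high enzyme concentration.

**Normalization.** Raw phospho/total ratios are normalized to the maximum
of a per-dataset preliminary fit, `ymax·(1 − A·e^(−r1 t) − (1−A)·e^(−r2 t))`,
with the one- or two-component variant selected by AICc. Rows with zero
total signal cannot be normalized; they are excluded, logged, and counted
in the output's `n_excluded` attribute.

**Half-times.** `half_time` returns the smallest `t` with `f(t) = 1/2`.
When a single exponential remains (`A1` = 1, or a saturating curve) the
closed form `ln 2 / rate` is used; otherwise the root is bracketed by
doubling and bisected to 1e−6 min. Degenerate parameters for which the
model cannot reach 1/2 raise an error. The Langmuir form
`y = ymax·t/(t_half + t)` is used for simple saturation courses; its
half-time is `t_half` by construction, and fits whose `t_half` collapses
below 1e−6 of the sampled time range are flagged degenerate.

**Defaults.** The synthetic truth defaults to A1 = 0.6, r1 = 0.3/min,
k2 = 0.004/(nM·min) — values that put the half-time at 10 nM near the
few-minute scale of the titration assay (timepoints 1–60 min, enzyme at
0.5/2/10/100 nM, triplicates) and give both components comparable weight so
the recovery problem is honest. Additive Gaussian noise on the normalized
fraction (default SD 0.05, clipped to [0, 1.5]) is an assumption; blot
densitometry has no published error model.

## Mixing-ratio crosslink quantification (`ihp.xlms`)

Each crosslinked peptide pair from a 1:1 ¹⁴N/¹⁵N holoenzyme mix occupies
four MS1 channels (L = light/¹⁴N, H = heavy/¹⁵N). The default mixing ratio

    R = (I_LH + I_HL) / (I_LL + I_HH)

places both uni-isotopic (homotypic) channels in the denominator,
consistent with the definition of homotypic crosslinks as ¹⁴N:¹⁴N plus
¹⁵N:¹⁵N. An `as_printed` variant with denominator `I_LL + I_LH` is also
shipped, reproducing an alternative typeset form of the equation; the two
differ and both are auditable. R is invariant to uniform intensity
rescaling and (under the default) to swapping the light/heavy labels of
both preparations. Records with a zero denominator carry undefined R: they
are flagged, excluded from group means, and counted in logs.

**Channel masses.** The light:light species mass is the sum of the two
neutral peptide monoisotopic masses (via `pyteomics`) plus the DSS linker
mass, 138.068 Da (the hydrolysed mono-link mass, 156.079 Da, is stored as a
constant but mono-links are not quantified). Heavy channels add
0.997035 Da × (peptide nitrogen count), assuming complete ¹⁵N
incorporation — real incorporation near 97% broadens isotope envelopes but
does not change this bookkeeping.

**Domains and heatmaps.** The default subunit domain map is kinase 1–274,
regulatory 275–314, linker 315–343, hub 344–478 (1-based, inclusive),
chosen so the frequently crosslinked hub lysines 344/347 classify as hub;
it is fully user-overridable. Crosslink identity for replicate intersection
is the **unordered residue-position pair**, so missed-cleavage peptide
variants collapse to one site pair. A site pair counts as heterotypic when
its mixed-isotope channels exceed a configurable floor (default 0) in every
replicate in which it appears. The heatmap counts each unordered domain
pair once, in its canonical cell (upper triangle in domain order), so the
matrix total equals the number of counted crosslinks.

**Structure mapping.** Cα coordinates are read from PDB with `biotite`;
each crosslink's minimal Cα–Cα distance is taken over the admissible chain
pairs (within one chain, across chains of one assembly, or across two
assemblies — pass a rigid-body-placed copy for the inter-holoenzyme case).
A single signed numbering offset reconciles construct and structure
numbering. The default satisfaction threshold is 30 Å Cα–Cα, common
practice for DSS (spacer ~11 Å plus two lysine side chains and coordinate
uncertainty); links missing from the coordinates are flagged unmapped,
never dropped. Pseudobond files (`/chain:res@CA /chain:res@CA` per line)
are written for structure viewers.

## Mass-photometry decomposition (`ihp.masspt`)

Events within the mass window are binned (density-normalized histogram,
256 bins by default); peaks are seeded at local maxima of a
Silverman-bandwidth Gaussian KDE (or the `n_peaks` most prominent maxima);
Gaussian components are then refined by least squares **against the
histogram density with inverse-variance (Poisson) bin weights**. The KDE is
deliberately not the fit target: a single global bandwidth (tens of kDa on
a dimer-to-24-mer range) convolves into narrow peaks and measurably biases
minor-peak means; the Poisson weights stop the dominant peak from drowning
out minor ones. Area percentages come from the analytic component
integrals `amp·sd·√(2π)`, normalized over components.

Oligomer assignment picks the candidate subunit count `n` minimizing
`|peak_mean − n·(monomer_mass + ligand_count·ligand_mass)|`, ties toward
smaller `n`; for CaMKII the monomer is ~55 kDa and bound calmodulin adds
16.7 kDa per subunit in activated samples. Monomer-level percentages are

    monomer%_i = 100 · area%_i · n_i / Σ_j area%_j · n_j

reported at one decimal with full precision retained; they sum to 100
exactly before rounding. On peak areas 4.7/85.9/9.4% with subunit counts
2/12/24 the monomer-weighted values are 9.4/1030.8/225.6 (total 1265.8) and
the shares are 0.74/81.43/17.82%.

**Generator defaults and power.** The default synthetic mixture mirrors an
activated sample: components at 157, 721 and 1442 kDa with particle weights
4.7/85.9/9.4% and 10⁴ events. Component SDs default to 12/25/25 kDa, chosen
so that each component mean is estimable to better than ±2 kDa at the
default event count (the 9.4%-weight component contributes ~10³ events, so
its empirical-mean SE is `sd/√1000`; at 25 kDa that is 0.8 kDa, leaving the
stated tolerance at ≥2.5 SE). Real instrument peak widths grow with
particle mass and can be substantially wider for MDa particles; with wider
peaks or fewer events the same tolerances would not be statistically
attainable, which bounds what the recovery tests say about real data.

## TIRF colocalization (`ihp.imaging`)

`threshold_mask` keeps the brightest `⌈f·n⌉` pixels (nearest rank,
default f = 0.01, i.e. "top 1% of pixels" rather than 1% of the intensity
range); all pixels tied at the cutoff are kept and the cutoff is reported.
Constant images are rejected as degenerate.

`pearson_coloc` computes the Pearson coefficient of the two channels over
the **union** of the two mask supports by default, with two alternatives:
`intersection` (pixels bright in both) and `full` (the mask-zeroed images
correlated over every pixel, the convention of mask-then-correlate image
plugins). The conventions differ in their null behaviour and all are
monotone in the true colocalized fraction: union is sensitive — unmatched
bright pixels pull r well below zero for uncorrelated fields — while
intersection and full leave independent channels near r = 0. Raw
intensities (not zeroed copies) are correlated on union/intersection
support; correlating zeroed copies over the union would force r ≈ −1 for
any non-colocalized field purely from the complementary zero patterns.
The coefficient is invariant to positive affine rescaling of either
channel and symmetric in channel order.

Condition groups of Pearson coefficients are compared against a control
with Dunnett's many-to-one test (`scipy.stats.dunnett`), which holds the
familywise error rate at α across the family of comparisons; a seeded null
simulation in the test suite confirms the empirical familywise error stays
below 0.07 at α = 0.05.

**Spot-field generator.** Spots are Gaussian PSFs (σ = 1.5 px, amplitude
500) on a noisy background (mean 100, SD 5) in 512² fields with 200 spots
per channel; a stated fraction of spot centers is shared exactly between
channels. It emulates neither camera physics nor photobleaching, and spot
intensities are uniform — the generator tests mask/correlation logic, not
detection.

## Pipeline and reproducibility (`ihp.pipeline`, CLI)

A single `RunConfig` (YAML-serializable; unknown keys rejected) drives all
stages. One seed governs every stochastic stage through deterministically
derived substreams, so a run is reproducible from its config alone. The
JSON report records the resolved value of every defaulted parameter, the
per-stage results, and exact record bookkeeping (rows in = rows used +
rows excluded, with reasons logged). All tabular outputs are TSV with a
commented header naming units and conventions (1-based residue numbering,
kDa, minutes).

The crosslink generator samples sites from the lysines of a **synthetic**
stand-in 478-residue subunit sequence (`ihp._sequence`) with lysines in
every domain, including K42 and the hub pair K344/K347; DSS chemistry
restricts sites to lysines and the domain-pair sampling weight is
proportional to the number of available lysine pairs. The stand-in
preserves these structural features but is not the real CaMKIIα sequence,
so peptide masses derived from it are exercise values, not literature
values.

## Known limitations

- Ring-resolved phosphorylation stochastics, raw MS spectra, FDR control,
  isotope-envelope deconvolution and phosphosite localization are out of
  scope; identified crosslinks with channel intensities are the input
  contract.
- The additive-Gaussian blot noise model and log-normal MS intensity noise
  (CV 0.2) are assumptions chosen for plausibility, not measured error
  models.
- Passing recovery tests demonstrate estimator correctness under the
  generator's conditions (sample sizes, noise levels, peak widths stated
  above), not performance on arbitrary real data.
- The union-vs-intersection support convention of the original image
  analysis is not recoverable from the source material; both (plus the
  plugin-style full-image convention) are implemented and none is asserted
  as canonical.
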