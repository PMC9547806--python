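# Methods

## Crosslinking model

**State.** A pool of `n` receptors, each carrying epitope slots per the
stoichiometry map (default α:2, β:1, δ:1, ε:1 — the adult muscle-type
pentamer).  Antibody species are bivalent, monospecific (one target subunit),
and counted in molecules; mapping molecule counts to mass concentrations is
out of scope.  IgG subclass labels are carried as metadata only — the model
describes crosslinking, not Fc effector chemistry.

**Dynamics.** Random sequential attachment with two event classes and no
unbinding (`k_off = 0`):

* *solution binding* — a free molecule of species *s* binds a uniformly
  chosen free epitope of its target subunit; total weight
  `k_on · n_solution(s) · n_free_epitopes(subunit)`;
* *crosslinking* — a uniformly chosen (singly bound antibody, free compatible
  epitope) pair binds; weight `k_cross` per eligible pair.  Pairs on the
  anchor receptor itself are excluded unless `allow_intra_receptor=True`;
  `allow_cycles=False` additionally excludes pairs inside the anchor's
  current component; in `geometric` mode only epitopes on receptors within
  `capture_radius` of the anchor are eligible.

Events are drawn proportionally to weight until none remain or `max_events`
is reached.  Because there is no unbinding, only the event *order*
distribution matters, so the loop is equivalent to a Gillespie simulation of
the corresponding mass-action system marginalised over time.  Identical
`(pool, species, params, seed)` reproduce identical trajectories; truncating
`max_events` replays a prefix of the same trajectory, which is how the
end-to-end demo snapshots "time points" of one stochastic run.

**Defaults and their rationale.**

| parameter | default | reasoning |
| --- | --- | --- |
| `k_on` | 1 (arbitrary units) | only the ratio `k_cross / k_on` matters |
| `k_cross` | 5 | the second arm is membrane-tethered: at synaptic receptor densities neighbouring epitopes are ~10 nm away, so its effective local antigen concentration exceeds the solution's.  The value places the default conditions in the crosslinking-dominated regime in which the dimer / chain / lattice hierarchy of the model is expressed rather than quenched by epitope blocking |
| saturating antibody count | `2·n` receptors | matches the largest per-subunit epitope pool (α), i.e. enough antibody to engage every epitope of any single target |
| `allow_intra_receptor` | `False` | an antibody bridging the two α epitopes of one receptor produces no crosslink; the chain regime requires inter-receptor binding.  Whether real IgG can span one pentamer's two α subunits is unresolved, so the flag exists |
| `allow_cycles` | `True` | nothing forbids ring closure; properties are stated as degree bounds, not acyclicity |
| `capture_radius` | 15 nm | the scale of antigen separation a bivalent IgG can span |
| geometric density | 1,000/µm² (demo uses up to 10,000/µm²) | spans the plausible range of membrane receptor densities; geometric mode is used for rendering only — all aggregate statistics use the well-mixed mode |

At these defaults (200 receptors, 400 total antibody, 50 seeds) a single
non-α species yields dimers only; a single anti-α species yields chains with
mean aggregate ≈ 9 receptors; every different-subunit pair at half counts
each strictly exceeds both of its constituent singles in mean aggregate size
and in the fraction of receptors in aggregates of ≥ 4, in all 50 seeds;
same-subunit pairs are statistically indistinguishable from the
corresponding single.  These are the regime laws the test suite asserts.

**Aggregate statistics.** Components are taken over the receptor projection
(receptors adjacent iff they share a doubly bound antibody).  The
*complement proxy* `complement_proxy(stats, s_min=4)` is the fraction of
receptors in components of at least `s_min` receptors.  It is a monotone
stand-in for the ability of crosslinked arrays to seed complement activation;
it is validated only qualitatively (singles vs. combinations pattern), never
as a calibrated C3 level.  `s_min = 4` reflects that a 4-receptor array binds
≥ 3 antibodies, the minimum multimeric IgG arrangement reported to engage C1
effectively; the qualitative pattern is insensitive to `s_min` in 3–6.

## Entropy thresholding

Thresholds are selected on a 256-bin histogram.  For split point `t` the
background (bins ≤ t) and foreground (bins > t) are renormalised and the
order-ρ Rényi entropy of each computed; the single-order method returns the
`t` maximising their sum (ρ → 1 is the Shannon/Kapur limit).  The default
`sahoo_combined` method computes the ρ = 0.5, 1, 2 maximisers, sorts them,
and combines them with the classic three-threshold weighting rule (weights
1/2/1, 0/1/3 or 3/1/0 depending on whether the three thresholds lie within
5 bins of each other).

Numerical conventions worth knowing:

* class emptiness is decided on exact integer count cumsums (floating
  cancellation in `1 − cumsum(p)` can make an empty foreground look
  occupied);
* candidate thresholds are restricted to occupied bins: an empty bin `t`
  scores identically to `t − 1`, so this canonicalises tie plateaus to their
  lowest member, implementing "ties break toward the lower threshold"
  robustly under floating-point noise;
* non-8-bit images are rescaled from their observed `[min, max]` onto 256
  bins and the chosen bin edge mapped back to native intensity, which makes
  the image-level threshold covariant under intensity shifts;
* a flat image (or single-bin histogram) raises a degenerate-histogram error
  at the histogram level; image pipelines treat it as "no foreground".

The vectorised selector is verified exactly, over thousands of random and
sparse histograms, against a naive per-candidate brute-force search.

## Cluster quantification

Per frame: maximum-intensity projection (acquisition stacks are assumed
already projected by the generator; `project_stack` handles raw planes) →
optional background reduction → entropy threshold → 8-connected labelling →
size filter.  Defaults: per-frame thresholds (a fixed series-wide threshold
is a config switch), background reduction by grey-level opening with a flat
square structuring element of side `2·radius + 1` (radius 50 px, disableable)
— the separable, fast stand-in for rolling-ball subtraction; 8-connectivity
(the particle-analysis convention); cluster size window 0.8–10.0 µm²
inclusive, area = pixel count × pixel size².

Growth rates are ordinary-least-squares slopes of cluster count, mean area
and total area against time (seconds), fitted on the post-addition frames
only; pre-addition slopes are reported alongside as a no-antibody control and
are *not* subtracted.  Fewer than two post-addition frames is an error.
Frames with no clusters have `NaN` mean area and are dropped from the
mean-area fit only.

## Junction morphometry

The junction mask comes from the presynaptic-marker (SV2A) channel: same
entropy threshold, morphological closing (disk, radius 3 px), minimum area
20 µm².  Receptor content is mean α-BTX / mean SV2A within the mask — means,
not integrals, so the ratio is mask-area invariant and unchanged under common
scaling of both channels; per-channel median of non-mask pixels is subtracted
first (disableable).  C3 deposition is the plain mean intensity within the
mask (no background subtraction by default, so a uniform field reports its
own level).  Fragmentation counts 8-connected receptor-label objects within
each junction's padded bounding box after thresholding; objects below
0.2 µm² are discarded as shot-noise speckle (set
`min_fragment_area_um2=0` to keep everything) — without this filter
Poisson noise above threshold splinters into 1–3 px objects and fragment
counts are meaningless at any realistic SNR.

## Assay statistics

* **GMFI ratio** — geometric mean `exp(mean(log x))` over strictly positive
  gated values (non-positive events, which compensated flow exports can
  contain, are excluded and counted); ratio of positive-gate over
  negative-gate mean.  Arithmetic means available by flag.  Default gates:
  the negative gate is everything below the 99.5th GFP percentile of an
  untransfected control, the positive gate everything above.
* **4PL / EC50** — `R(c) = bottom + (top − bottom)/(1 + (ec50/c)^h)`, fitted
  by least squares in log-concentration with multi-start over Hill slopes
  {0.5, 1, 2}.  Requires ≥ 5 concentrations spanning ≥ 2 decades; a response
  with < 5% dynamic range raises a fit failure rather than returning an
  arbitrary EC50.
* **Synergy index** — combination response divided by the best constituent
  single, all at matched total concentration (pairs at half concentration
  each); the fold matrix has unit diagonal by construction.
* **Trace peak** — post-stimulus maximum minus baseline median;
  normalisation divides by the mean of untreated wells.
* **Spearman permutation test** — mid-rank Spearman ρ; two-tailed p by
  permutation of one variable.  When `n! ≤ n_perm` all permutations are
  enumerated exactly (p = fraction with `|ρ*| ≥ |ρ|`); otherwise Monte Carlo
  with the add-one correction `(1 + hits)/(1 + n_perm)`, which makes the
  p-value valid (super-uniform) under the null.  Comparisons use a 1e-12
  tolerance so exact rank ties count as hits.

## Synthetic data: what it emulates, and what it does not

The generators produce the study's data modalities with exact ground truth:
receptor-label time-lapses whose post-addition cluster count and mean area
grow linearly at planted per-frame rates (default frame interval 20 s, i.e.
three frames per minute); pretzel-shaped junctions rendered into α-BTX /
SV2A / C3 channels with controllable receptor retention, fragmentation and
complement level; two-population log-normal flow event tables with planted
geometric-mean ratios; calcium traces with an exponentially decaying
stimulus-evoked transient.  Noise is Poisson shot noise plus Gaussian read
noise (the standard camera model); `apply_noise=False` returns the
unquantised expected image so planted values are recovered exactly.  Ground
truth is always measured back from the noise-free render (e.g. planted
cluster areas are the rendered pixel areas; junction retention is the
rendered mask-mean ratio, with fragment intensity compensated for the area
lost to inter-fragment gaps), so truth and data cannot drift apart.

Deliberately not modelled: realistic cell morphology, photobleaching, 3-D
point-spread functions, spectral bleed-through, stage drift, cluster motion
or merging, flow-cytometry spillover.  Passing tests therefore demonstrate
the pipelines' correctness on data satisfying the stated model, not
robustness to every artefact of real microscopy.

## Problem sizes and determinism

Test and acceptance workloads use 200-receptor simulations (50–100 seeds per
law), 256² pixel time-lapses with 30 frames over 10 seeds, 192² junction
images over 100 noisy seeds, 10,000-event flow tables, 20-seed triplicate
dose–response fits, and 1,000-draw null calibrations — sizes chosen so every
property is measured with comfortable statistical margin while the whole
suite runs in well under a workstation coffee break.  The EC50-with-noise
check fits triplicate measurements per concentration, the usual assay design
(dose–response experiments report means of three independent runs); single
9-point curves at 5% multiplicative noise carry ~10–25% EC50 sampling error,
which is a property of the design, not the fitter.

All randomness flows through `numpy.random.default_rng` seeds.  One global
seed expands to per-stage seeds as
`SeedSequence(entropy=seed, spawn_key=(crc32(stage_name), index))`, so stages
re-run in isolation reproduce in-pipeline behaviour.  OME-TIFF outputs embed
a content-derived UUID instead of a random one, making seeded pipeline runs
byte-identical — the property the reproducibility checks assert with file
checksums.
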