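# Methods

`gsrnet` compares voxel-level resting-state functional connectivity
networks built with and without global signal correction. Because no
real fMRI data ship with the package, every analysis runs on a
synthetic phantom whose statistical structure is controlled and whose
ground truth is known. This note records the models, the defaults and
why they are what they are, and what the synthetic results do and do
not show about real data.

## The correction schemes

Each node (voxel) series is OLS-residualized on an intercept plus one
of four nuisance sets: motion only (`NoCorr`); motion + white-matter +
ventricle means (`NoWB`); motion + whole-brain mean (`WBonly`); all of
the above (`Full`). The whole-brain series is the parenchyma mean (gray
nodes plus the white-matter sphere, excluding ventricles) — the mask
construction is a documented reading, since "brain parenchyma including
gray and white matter" fixes the inclusion of white matter but not the
treatment of ventricles. Band-pass filtering (zero-phase 4th-order
Butterworth, 0.009–0.08 Hz; an ideal FFT mask is available via
`design="ideal"`) precedes regression by default. Regressing *after*
filtering has been criticized because the regressors can reintroduce
out-of-band variance; `regress_out(..., filter_regressors=True)`
band-limits the regressors first for users who prefer that order. The
regression is ordinary least squares per node; near-collinear designs
(condition number above 1e8 after column normalization) raise an error
that names the offending columns rather than silently dropping them.

## Correlation distribution theory

For `t` time points and zero population correlation, the sample
Pearson correlation has the exact density

    f(r) = Γ((t−1)/2) / (√π Γ((t−2)/2)) · (1 − r²)^((t−4)/2),

symmetric about zero (uniform at t = 4). If every pair of series shares
an additive signal G, the population correlation between two otherwise
independent series W₁ = Y₁ + G, W₂ = Y₂ + G is

    ρ = Var(G) / √((Var(Y₁)+Var(G))(Var(Y₂)+Var(G))) > 0,

and the sample correlation follows the classical non-central series

    f(r) = (1−ρ²)^((t−1)/2) (1−r²)^((t−4)/2)
           / (√π Γ((t−1)/2) Γ((t−2)/2)) · Σⱼ Γ((t−1+j)/2)² (2ρr)ʲ / j!.

Only the `(1−ρ²)^((t−1)/2)` base reduces to the central density at
ρ = 0 *and* integrates to one (verified by the Legendre duplication
formula and by quadrature in the tests); a variant with a `(1−ρ)` base
circulates in print and is retained behind `base="as-printed"` for
comparison — it is not a proper density for ρ ≠ 0. The series is
evaluated through log-gamma with a per-point scale factor, truncated at
relative term 1e−12 (cap 500 terms, error on non-convergence).

One practical caveat discovered at desk scale: after whole-brain
regression the *mean* off-diagonal correlation is not exactly zero but
pinned near −1/(n−1), because the residuals of n series that sum to
(nearly) the regressor are anticorrelated on average. At n = 15,996
this offset is −6×10⁻⁵ — invisible at the precision a study reports —
but at a 180-node phantom it is −0.006 and deterministic. Tests treat
"centered at zero" as zero within this sum-constraint floor plus
Monte-Carlo error.

## Network construction and metrics

The correlation matrix is thresholded so that S = log N / log K (N all
mask nodes, K mean degree) is as close as possible to a target
(default 3.0; the comparison behaves similarly over 2.5–3.5). Edges are
strictly `r > threshold` and only positive correlations are eligible;
candidate thresholds are the distinct observed values plus zero, so the
search is exact (binary search over the monotone S plus a local scan).
N deliberately counts disconnected nodes: fragmentation is a result to
be measured, not an input restriction.

Path length is the Latora–Marchiori harmonic-mean form
L = 1 / mean(1/d) over all ordered pairs with 1/∞ = 0, so disconnected
pairs lengthen L. The clustering coefficient averages Watts–Strogatz
local clustering over nodes with degree ≥ 2 by default: with up to
~20% isolated nodes, zero-counting isolates would drag C in a way that
is inconsistent with C being nearly invariant across correction
methods, which is the observed behaviour of this metric; the all-node
denominator is available via `c_denominator="all"`. Hubs are the top
20% of nodes by degree, ties broken by node index.

## Parcellation

Nodes outside the giant component form a distinguished junk module.
The giant component is parcellated by iterative modularity
maximization in the Qcut style: spectral bipartition on the leading
eigenvector of the generalized modularity matrix (exact enumeration of
bipartitions for groups of ≤ 16 nodes, where it is cheap), a
Kernighan–Lin node-swap refinement after each split, multiway
single-node moves between communities (including into a new, empty
community), and a greedy pairwise merge pass; the split/refine/merge
cycle iterates until Q stops improving by more than 1e−10. For small
giant components (≤ 64 nodes) the cycle restarts from a few
seed-derived random partitions and keeps the best Q, since weakly
modular small graphs have many near-ties. The result is deterministic
given the seed. This is a faithful-behaviour reimplementation of the
published iterative scheme, not a bit-identical port; module counts by
default exclude the junk module (`n_modules_with_junk()` includes it).

## The phantom

### Geometry

A voxel lattice (default 10×10×7) whose top z-slab hosts the auxiliary
masks (a "white-matter sphere" and a "ventricle", disjoint from the
network); the remaining 600 voxels are gray-matter network nodes.
Ground-truth modules are contiguous blocks from an axis-aligned grid
factorization; with the default geometry consecutive blocks are mirror
pairs across the x-midline, and each pair shares a parent community —
the bilateral-homologue analogue. A contiguous midline sheet
(default 10% of nodes, biased toward the top of the lattice) is the
"interhemispheric fissure" hub analogue. A configurable share of nodes
(default 15%), drawn along module boundaries, is labelled white-matter
adjacent.

### Signals

Every latent series is white Gaussian noise FFT-masked to the passband
(0.009–0.08 Hz at TR = 2.5 s) and rescaled to exact unit sample
variance, so variance bookkeeping is exact rather than asymptotic. A
gray node i in module c receives

    x_i = a_i f_i √vm (√β P_parent(c) + √(1−β) M_c)
          + f_i √vl l_i + g_i √vg G + w_i + √vn e_i

* `a_i` — module loading, uniform on 1 ± 0.3 (voxel-level SNR spread),
  reduced ×0.8 on white-matter-adjacent nodes;
* `β = 0.8` — parent mixing: same-module pairs share vm, sibling
  (bilateral) modules share β·vm, so communities are hierarchical;
* `l_i` — a spatially smoothed field (Gaussian σ = 1 voxel), giving
  nearest-neighbour correlations that decay with distance;
* `g_i` — global-signal loading, 1 everywhere except the hub sheet
  (2.5), whose intrinsic loading `f_i` is reduced to 0.7 (high-artifact
  voxels trade neural SNR for artifact);
* `w_i` — white-matter-adjacent nodes add √(vw·λ) (λ = 2.5) of a
  tract-local patch signal (~6 spatially grouped nodes per patch), 40%
  of whose variance is the white-matter-sphere signal itself, so
  tissue regression can remove that shared part;
* defaults vm = vl = 1, vg = vn = 0.8, vw = 1, v_vent = 0.5.

Tissue mask voxels carry the global signal at loading 0.7 plus their
own compartment signal — the physiological reading that scanner-wide
artifacts pervade all tissue, which is exactly what makes the `NoWB`
scheme (white matter + ventricle regression) remove *part* of the
global signal and land between `NoCorr` and `Full`. Motion regressors
are six smoothed random walks; their leakage into node series defaults
to zero but exists so the motion-only scheme has something real to
regress.

### Why these mechanisms

The phantom is built so that the causal chain the comparison measures
is actually present, at desk scale, in the generator:

* a shared global signal inflates every pairwise correlation
  (`NoCorr`), partially survives tissue-only regression (`NoWB`), and
  is removed by any scheme containing the whole-brain mean;
* under a fixed S-ratio edge budget, the hub sheet's mutually
  correlated pairs absorb a large share of edges when the global
  signal is uncorrected, starving the rest of the network — producing
  fragmentation (smaller giant, lower connected fraction, longer
  harmonic-mean paths), a high-degree hub concentration at the
  midline, and larger max-degree variance;
* the inflated threshold also severs the weaker bilateral seams inside
  parent communities, so parcellation finds more, finer modules
  without the whole-brain regression than with it;
* white-matter-adjacent nodes waste variance on tract-local nuisance
  that only tissue regression can (partly) remove, so they drop out of
  the network as isolated nodes and small subgraphs — junk — much more
  often without correction.

Defaults were calibrated so that the *baseline* (Full) networks sit in
the regime a real whole-brain analysis reports — high connected
fraction, a connected giant spanning the communities, and a module
count of order 10–20 at S = 3 — and the hub loading was set from the
analytic condition that hub-pair correlations compete with
within-module pairs when uncorrected (vg·h²/(vm+vl+vg·h²+vn) at least
the within-neighbour correlation gives h ≈ 2.4). Given that baseline,
the method contrasts are measured outcomes of the pipeline.

### What the phantom does not emulate

No scanner physics, slice timing, image-domain head motion or spatial
normalization; spatial autocorrelation is a single-scale Gaussian
field rather than an empirically matched kernel; modules are
spatially compact blocks; physiological noise has no cardiac or
respiratory line structure. Passing tests therefore show that the
pipeline's statistics behave as the theory predicts under the stated
generative mechanisms — not that any particular real dataset will
reproduce the same effect sizes.

## Study design and problem sizes

The default study runs 10 replicate subjects (signal seeds differ,
geometry fixed) × 4 schemes on a 600-node phantom with t = 120,
TR = 2.5 s, S = 3.0 — mirroring a typical resting-state
acquisition (10 subjects, 120 volumes, S = 3.0) at a node count where the full
pipeline, including parcellation, runs in minutes on a single CPU.
Metrics are compared with classical paired t-tests (two-sided), plus
an F-test (larger-over-smaller variance convention, two-sided) on the
maximum node degree. P-values are reported raw; `bh_adjust=True` adds
Benjamini–Hochberg columns.

## Numerical choices

* Thresholding ties break toward the larger threshold (sparser
  network); field practice varies between ≥ and > at the cutoff,
  so the strict rule is declared in the export sidecar.
* Zero-variance nodes error by default (`drop_zero_variance=True`
  drops them with the survivors' order preserved).
* Histograms use 201 equal-width bins on [−1, 1]; summaries use
  unordered pairs, with the ordered count n(n−1) carried alongside.
* Correlation summaries at n ≈ 16,000 run in row blocks
  (`summarize_timeseries_blocked`) without a dense matrix.
* Eigenvector sign and module-id assignment are fixed by deterministic
  tie-breaks (smallest node index), so reruns are bit-identical.
* Subject seeds derive from the base seed as
  `(base·100003 + 7919·i) mod 2³¹`.

## Known limitations

* The parcellation is a strong heuristic, not an exact optimizer;
  exhaustive enumeration confirms optimality on all tested graphs with
  ≤ 10 giant nodes, but adversarial weakly-modular graphs above that
  size may end at a local optimum.
* The non-central density series loses accuracy as |ρr| → 1 (the term
  cap errs rather than returning a wrong value).
* Paired t-tests on 10 subjects have limited power; the study reports
  per-seed ordering rates alongside p-values for that reason.
* `exclude_wm_adjacent_rerun` re-thresholds the reduced matrix to the
  same S target, which changes the edge budget (K = N^(1/S) falls with
  N); path-length differences therefore mix node removal with budget
  effects; the paired comparison across schemes is still valid.
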