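# gsrnet

Voxel-level resting-state functional connectivity networks with and
without global signal correction — a tested, fully synthetic
re-implementation of the comparison pipeline.

## The problem

In resting-state fMRI, "global signals" — the mean BOLD time course of
the whole brain or of a tissue compartment — are regressed out of
voxel series by some groups and deliberately retained by others.
Whether to correct is contested: regression of the whole-brain mean
removes scanner-wide artifacts but also induces anticorrelations,
while *not* correcting leaves every pairwise correlation positively
biased. `gsrnet` quantifies what this choice does to graph-theoretic
connectivity networks. It implements four standard correction schemes

| scheme | regressors (plus intercept) |
|---|---|
| `NoCorr` | 6 motion parameters |
| `NoWB`   | motion + white matter + ventricle means |
| `WBonly` | motion + whole-brain mean |
| `Full`   | motion + white matter + ventricle + whole-brain means |

and carries each through the same pipeline: band-pass filter
(0.009–0.08 Hz) → nuisance regression → all-pairs Pearson correlation
→ binary network thresholded so that S = log N / log K hits 3.0 →
clustering C, harmonic-mean path length L (disconnected pairs count as
infinitely long), giant-component size Nc, degree distribution and hub
maps → Qcut-style modularity parcellation with a "junk" module for
disconnected nodes → paired t-tests and an F-test across schemes.

Two pieces of distribution theory anchor the comparison: the exact
null density of a sample correlation at t time points,
f(r) ∝ (1−r²)^((t−4)/2), and its non-central series form when all
voxels share an additive signal G, which shifts the whole correlation
distribution to ρ = Var(G)/√((Var(Y₁)+Var(G))(Var(Y₂)+Var(G))) > 0.

Because the original subject scans are not public, the package ships a
first-class synthetic phantom (`gsrnet.synth`) with known ground
truth: hierarchical bilateral modules, spatially decaying local
correlations, a shared global signal with an elevated-loading midline
"hub" sheet, tract-local white-matter nuisance on labelled nodes, and
six motion regressors. See `docs/methods.md` for the model and every
default.

## Worked example

```python
import gsrnet as g

phantom = g.generate_phantom((10, 10, 7), n_modules=20,
                             wm_adjacent_fraction=0.15, seed=0)
ds = g.simulate_timeseries(phantom, g.SignalModel(seed=7))
ds = g.bandpass(ds, 0.009, 0.08)
nuis = g.extract_nuisance(ds)

for method in (g.NOCORR, g.FULL):
    cleaned = g.regress_out(ds, method, nuis)
    cmat = g.correlation_matrix(cleaned)
    summ = g.summarize_distribution(cmat)
    net = g.threshold_for_S(cmat, 3.0)
    m = g.metric_set(net)
    part = g.qcut_partition(net)
    print(f"{method.name:7s} mean_r={summ.mean:+.3f} K={net.mean_degree:.1f} "
          f"L={m.L:.2f} Nc={m.Nc} modules={part.n_modules} "
          f"junk={part.junk_size}")
```

prints

```
NoCorr  mean_r=+0.295 K=8.4 L=8.19 Nc=435 modules=17 junk=165
Full    mean_r=-0.001 K=8.4 L=6.51 Nc=573 modules=12 junk=27
```

Read: without any global correction the correlation distribution is
strongly positively biased (+0.30 vs ≈0), and at the same edge budget
(K fixed by S = 3) the network fragments — a smaller giant component,
six times as many junk nodes, longer harmonic-mean paths — while the
parcellation of what remains splits into more modules. The full
study (`g.run_study(g.StudyConfig())`) repeats this over 10 replicate
subjects, adds the `NoWB`/`WBonly` arms, hub/module overlap maps, and
paired t / F statistics per metric pair.

A thin CLI mirrors the library:
`gsrnet simulate | preprocess | correlate | build | metrics |
parcellate | run-study` (see `--help`; `run-study` takes one YAML
config and writes TSV tables plus JSON sidecars).

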