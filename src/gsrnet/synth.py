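"""Synthetic resting-state phantom generation.

Builds voxel lattices with known community structure and simulates
BOLD-like node time series containing the signal components whose
interplay the rest of the pipeline measures:

* a band-limited intrinsic signal shared within each module,
* a spatially smooth local signal (short-range correlations between
  lattice neighbours),
* a global signal shared by every voxel, with elevated loading on a
  contiguous midline "hub" region (the interhemispheric-fissure
  analogue),
* white-matter and ventricle nuisance signals, with white-matter
  loading leaking into gray nodes labelled as white-matter adjacent,
* per-node independent noise and six motion regressors.

Everything is deterministic given the seeds, and every variance is
book-kept exactly (each latent series is rescaled to unit sample
variance before weighting), so the closed-form correlation values used
by the tests hold without asymptotics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Phantom",
    "SignalModel",
    "TimeSeriesDataset",
    "generate_phantom",
    "simulate_timeseries",
    "expected_shared_correlation",
]

GRAY = "gray"
GRAY_WM_ADJACENT = "gray_wm_adjacent"


class PhantomGeometryError(ValueError):
    """Requested lattice cannot host the network nodes and auxiliary masks."""


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Phantom:
    """Voxel lattice with node labels, module ground truth and tissue masks.

    The network (gray-matter) nodes live in the lower ``z`` slabs of the
    lattice; the top slab hosts the auxiliary white-matter-sphere and
    ventricle masks, which are disjoint from the network node set. The
    ``whole_brain`` mask is the parenchyma analogue: network nodes plus
    the white-matter sphere, excluding the ventricles.
    """

    dims: tuple[int, int, int]
    node_coords: np.ndarray            # (n, 3) int voxel indices
    tissue_labels: np.ndarray          # (n,) str, GRAY or GRAY_WM_ADJACENT
    true_module: np.ndarray            # (n,) int >= 0
    global_hub: np.ndarray             # (n,) bool, midline hub analogue
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    parent_module: np.ndarray | None = None  # pairs of adjacent modules

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_modules(self) -> int:
        return int(self.true_module.max()) + 1

    @property
    def wm_adjacent(self) -> np.ndarray:
        return self.tissue_labels == GRAY_WM_ADJACENT

    @property
    def parents(self) -> np.ndarray:
        """Parent-community id per node (module pairs; the bilateral
        homologue analogue). Falls back to the modules themselves."""
        if self.parent_module is not None:
            return self.parent_module
        return self.true_module

    def __post_init__(self):
        n = len(self.node_coords)
        if not (len(self.tissue_labels) == len(self.true_module)
                == len(self.global_hub) == n):
            raise ValueError("per-node arrays must all have n_nodes entries")
        net = {tuple(c) for c in self.node_coords}
        for name in ("white_matter_sphere", "ventricle"):
            aux = {tuple(c) for c in self.masks.get(name, ())}
            if aux & net:
                raise ValueError(f"mask {name!r} overlaps the network node set")
        wm = {tuple(c) for c in self.masks.get("white_matter_sphere", ())}
        vent = {tuple(c) for c in self.masks.get("ventricle", ())}
        if wm & vent:
            raise ValueError("white_matter_sphere and ventricle masks overlap")


def _module_blocks(coords: np.ndarray, n_modules: int) -> np.ndarray:
    """Assign contiguous spatial blocks as ground-truth modules.

    Tries a 3-factor grid of blocks aligned with the lattice axes; when
    no factorization fits the gray extents (e.g. a large prime count),
    falls back to contiguous runs in raster order.
    """
    extents = [len(np.unique(coords[:, ax])) for ax in range(3)]

    best = None
    for f0 in range(1, n_modules + 1):
        if n_modules % f0:
            continue
        for f1 in range(1, n_modules // f0 + 1):
            if (n_modules // f0) % f1:
                continue
            f2 = n_modules // (f0 * f1)
            fs = (f0, f1, f2)
            if any(f > e for f, e in zip(fs, extents)):
                continue
            # prefer near-isotropic blocks
            aspect = max(e / f for f, e in zip(fs, extents)) / \
                min(e / f for f, e in zip(fs, extents))
            if best is None or aspect < best[0]:
                best = (aspect, fs)

    if best is not None:
        fs = best[1]
        idx = np.zeros(len(coords), dtype=int)
        mult = 1
        for ax, f in enumerate(fs):
            vals = np.unique(coords[:, ax])
            bins = np.array_split(vals, f)
            lookup = {v: b for b, chunk in enumerate(bins) for v in chunk}
            idx += mult * np.array([lookup[v] for v in coords[:, ax]])
            mult *= f
        # compress ids to 0..n_modules-1 preserving order of first use
        _, labels = np.unique(idx, return_inverse=True)
        if labels.max() + 1 == n_modules:
            return labels

    # raster-order fallback: always yields n_modules nonempty runs
    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    labels = np.empty(len(coords), dtype=int)
    for m, chunk in enumerate(np.array_split(order, n_modules)):
        labels[chunk] = m
    return labels


def _boundary_nodes(coords: np.ndarray, modules: np.ndarray) -> np.ndarray:
    """Indices of nodes with a 6-neighbour in a different module."""
    where = {tuple(c): i for i, c in enumerate(coords)}
    out = []
    for i, c in enumerate(coords):
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                  (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            j = where.get((c[0] + d[0], c[1] + d[1], c[2] + d[2]))
            if j is not None and modules[j] != modules[i]:
                out.append(i)
                break
    return np.array(out, dtype=int)


def generate_phantom(dims, n_modules: int, wm_adjacent_fraction: float = 0.0,
                     seed: int = 0, *, hub_fraction: float = 0.10,
                     aux_mask_size: int = 20) -> Phantom:
    """Build the phantom lattice, module ground truth and tissue masks.

    Parameters
    ----------
    dims
        Lattice sizes ``(nx, ny, nz)``. The slab ``z = nz - 1`` is
        reserved for the auxiliary masks; all other voxels are network
        (gray) nodes.
    n_modules
        Number of contiguous ground-truth modules (>= 1).
    wm_adjacent_fraction
        Share of gray nodes, drawn from module boundaries, labelled
        white-matter adjacent (``0 <= f < 1``).
    seed
        Drives the white-matter-adjacent node draw.
    hub_fraction
        Share of gray nodes forming the contiguous midline hub region
        that later receives elevated global-signal loading.
    aux_mask_size
        Target voxel count of each auxiliary mask (trimmed to fit).
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise PhantomGeometryError(f"invalid lattice dims {dims}")
    if dims[2] < 2 or dims[0] < 2:
        raise PhantomGeometryError(
            f"dims {dims} leave no room for auxiliary masks outside the "
            "network (need nz >= 2 and nx >= 2)")
    if not (0 <= wm_adjacent_fraction < 1):
        raise ValueError("wm_adjacent_fraction must be in [0, 1)")
    nx, ny, nz = dims

    grid = np.array(list(itertools.product(range(nx), range(ny), range(nz - 1))),
                    dtype=int)
    n = len(grid)
    if not (1 <= n_modules <= n):
        raise PhantomGeometryError(
            f"cannot place {n_modules} modules on {n} network voxels")

    modules = _module_blocks(grid, n_modules)

    # auxiliary masks in the reserved top slab, split by hemisphere
    slab = np.array([(x, y, nz - 1) for x in range(nx) for y in range(ny)],
                    dtype=int)
    left = slab[slab[:, 0] < nx / 2]
    right = slab[slab[:, 0] >= nx / 2]
    if len(left) == 0 or len(right) == 0:
        raise PhantomGeometryError("auxiliary slab too small for two masks")

    def _sphere(cands, k):
        centre = cands.mean(axis=0)
        d = np.linalg.norm(cands - centre, axis=1)
        order = np.lexsort((cands[:, 2], cands[:, 1], cands[:, 0], d))
        return cands[order[:max(1, min(k, len(cands)))]]

    masks = {
        "white_matter_sphere": _sphere(left, aux_mask_size),
        "ventricle": _sphere(right, aux_mask_size),
    }

    # white-matter-adjacent labels: drawn along module boundaries
    labels = np.full(n, GRAY, dtype=object)
    k_adj = int(round(wm_adjacent_fraction * n))
    if k_adj > 0:
        rng = np.random.default_rng(seed)
        boundary = _boundary_nodes(grid, modules)
        if len(boundary) >= k_adj:
            chosen = rng.choice(boundary, size=k_adj, replace=False)
        else:
            rest = np.setdiff1d(np.arange(n), boundary)
            extra = rng.choice(rest, size=k_adj - len(boundary), replace=False)
            chosen = np.concatenate([boundary, extra])
        labels[chosen] = GRAY_WM_ADJACENT
    labels = labels.astype(str)

    # contiguous midline hub region, biased toward the top of the gray slab
    hub = np.zeros(n, dtype=bool)
    k_hub = int(round(hub_fraction * n))
    if k_hub > 0:
        mid = (nx - 1) / 2.0
        score = np.lexsort((np.arange(n), -grid[:, 2],
                            np.abs(grid[:, 0] - mid)))
        hub[score[:k_hub]] = True

    # parent communities: consecutive module ids are spatial neighbours
    # under the grid factorization (with the default geometry, mirror
    # pairs across the midline — the bilateral-homologue analogue)
    parents = modules // 2

    return Phantom(dims=dims, node_coords=grid, tissue_labels=labels,
                   true_module=modules, global_hub=hub, masks=masks,
                   parent_module=parents)


# ---------------------------------------------------------------------------
# Signal model and simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalModel:
    """Variance bookkeeping for the phantom time-series simulation.

    All component variances are in squared BOLD-like units. Each latent
    series is band-limited to ``passband`` and standardized to unit
    sample variance before weighting, so stated population correlations
    are exact at the sample level up to cross-terms.

    The defaults are the study conditions used throughout: a modular,
    locally smooth cortex with a global signal present in all tissue
    compartments, a midline region with doubled global loading, and
    white-matter-adjacent nodes carrying extra shared white-matter
    nuisance variance with a mildly reduced module loading.
    """

    t: int = 120
    tr: float = 2.5
    var_module: float = 1.0
    var_local: float = 1.0
    var_noise: float = 0.8
    var_global: float = 0.8
    var_wm: float = 1.0
    var_vent: float = 0.5
    wm_adjacent_loading: float = 2.5
    wm_adjacent_module_factor: float = 0.8
    wm_shared_fraction: float = 0.4
    wm_patch_size: int = 6
    module_loading_spread: float = 0.3
    parent_mixing: float = 0.8
    hub_global_loading: float = 2.5
    hub_module_factor: float = 0.7
    tissue_global_loading: float = 0.7
    aux_noise_sd: float = 0.3
    spatial_smooth_sigma: float = 1.0
    motion_amplitude: float = 1.0
    motion_leak: float = 0.0
    passband: tuple[float, float] = (0.009, 0.08)
    seed: int = 0

    def __post_init__(self):
        for name in ("var_module", "var_local", "var_noise", "var_global",
                     "var_wm", "var_vent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t < 5:
            raise ValueError("t must be >= 5")
        low, high = self.passband
        if not (0 <= low < high < 0.5 / self.tr):
            raise ValueError(
                f"passband {self.passband} invalid for tr={self.tr} "
                f"(Nyquist {0.5 / self.tr:g} Hz)")

    def with_seed(self, seed: int) -> "SignalModel":
        return replace(self, seed=int(seed))


@dataclass
class TimeSeriesDataset:
    """Node-by-time matrix plus the metadata the pipeline stages need.

    ``aux`` carries the voxel series of the auxiliary masks (white
    matter sphere, ventricle) so nuisance extraction does not need the
    latent signals.
    """

    data: np.ndarray                   # (n_nodes, t)
    tr: float
    phantom: Phantom
    motion: np.ndarray                 # (6, t)
    aux: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def t(self) -> int:
        return self.data.shape[1]

    def __post_init__(self):
        if self.data.shape[0] != self.phantom.n_nodes:
            raise ValueError("data rows must match phantom n_nodes")
        if self.motion.shape != (6, self.data.shape[1]):
            raise ValueError("motion must be a 6-by-t matrix")

    def copy_with(self, data=None, aux=None, step: str | None = None,
                  motion=None) -> "TimeSeriesDataset":
        out = TimeSeriesDataset(
            data=self.data.copy() if data is None else data,
            tr=self.tr, phantom=self.phantom,
            motion=self.motion.copy() if motion is None else motion,
            aux={k: v.copy() for k, v in self.aux.items()} if aux is None else aux,
            provenance=list(self.provenance))
        if step:
            out.provenance.append(step)
        return out


def _band_indices(t: int, tr: float, low: float, high: float) -> np.ndarray:
    f = np.fft.rfftfreq(t, d=tr)
    keep = (f >= low) & (f <= high)
    if not keep.any():
        raise ValueError(f"passband ({low}, {high}) Hz contains no DFT bin "
                         f"for t={t}, tr={tr}")
    return keep


def _bandlimited_unit(rng: np.random.Generator, t: int, tr: float,
                      low: float, high: float, shape=()) -> np.ndarray:
    """White Gaussian series FFT-masked to the passband, exact unit
    sample variance per series."""
    keep = _band_indices(t, tr, low, high)
    x = rng.standard_normal(shape + (t,))
    spec = np.fft.rfft(x)
    spec[..., ~keep] = 0.0
    y = np.fft.irfft(spec, n=t)
    y -= y.mean(axis=-1, keepdims=True)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _local_field(rng, phantom: Phantom, model: SignalModel) -> np.ndarray:
    """Spatially smoothed band-limited field sampled at the gray nodes,
    unit sample variance per node."""
    nx, ny, nz = phantom.dims
    series = _bandlimited_unit(rng, model.t, model.tr, *model.passband,
                               shape=(nx, ny, nz))
    smooth = gaussian_filter(
        series, sigma=(model.spatial_smooth_sigma,) * 3 + (0.0,),
        mode="nearest")
    c = phantom.node_coords
    y = smooth[c[:, 0], c[:, 1], c[:, 2], :]
    y -= y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _motion_regressors(rng, model: SignalModel) -> np.ndarray:
    """Six smooth, small-amplitude random walks (demeaned)."""
    steps = rng.standard_normal((6, model.t))
    walk = np.cumsum(steps, axis=1)
    # mild temporal smoothing to emulate slow drifts
    kernel = np.ones(5) / 5.0
    walk = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same"), 1, walk)
    walk -= walk.mean(axis=1, keepdims=True)
    sd = walk.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return model.motion_amplitude * walk / sd


def simulate_timeseries(phantom: Phantom, model: SignalModel) -> TimeSeriesDataset:
    """Simulate node and auxiliary-mask series under the signal model.

    Each gray node ``i`` in module ``c`` receives::

        x_i = a_i sqrt(vm) M_c + sqrt(vl) l_i + g_i sqrt(vg) G
              + b_i sqrt(vw * lambda) W + leak_i + sqrt(vn) e_i

    with ``a_i`` the module loading (spread across nodes, reduced on
    white-matter-adjacent nodes), ``l_i`` the local spatial field,
    ``g_i = 1`` except on hub nodes, and ``b_i = 1`` only on
    white-matter-adjacent nodes. With the spread, local field and
    nuisance terms switched off, two same-module nodes have population
    correlation ``(vm + vg) / (vm + vg + vn)`` and two different-module
    nodes ``vg / (vm + vg + vn)``; ``Cov(Y, G) = 0`` by construction.
    """
    rng = np.random.default_rng(model.seed)
    t, tr = model.t, model.tr
    low, high = model.passband
    n = phantom.n_nodes

    module_sig = _bandlimited_unit(rng, t, tr, low, high,
                                   shape=(phantom.n_modules,))
    parents = phantom.parents
    parent_sig = _bandlimited_unit(rng, t, tr, low, high,
                                   shape=(int(parents.max()) + 1,))
    global_sig = _bandlimited_unit(rng, t, tr, low, high)
    wm_sig = _bandlimited_unit(rng, t, tr, low, high)
    vent_sig = _bandlimited_unit(rng, t, tr, low, high)
    noise = _bandlimited_unit(rng, t, tr, low, high, shape=(n,))
    local = (_local_field(rng, phantom, model)
             if model.var_local > 0 else np.zeros((n, t)))
    motion = _motion_regressors(rng, model)

    spread = model.module_loading_spread
    a = (rng.uniform(1.0 - spread, 1.0 + spread, size=n)
         if spread > 0 else np.ones(n))
    adj = phantom.wm_adjacent
    a = np.where(adj, a * model.wm_adjacent_module_factor, a)
    g = np.where(phantom.global_hub, model.hub_global_loading, 1.0)
    # hub-region voxels trade intrinsic (module + local) signal for the
    # elevated global artifact: reduced neural SNR near the fissure
    f = np.where(phantom.global_hub, model.hub_module_factor, 1.0)

    # hierarchical community signal: each module's intrinsic series is a
    # mix of its parent community's signal and its own sub-signal, so
    # same-module pairs share var_module while sibling-module pairs
    # share parent_mixing * var_module
    beta = model.parent_mixing
    intrinsic = (np.sqrt(beta) * parent_sig[parents]
                 + np.sqrt(1.0 - beta) * module_sig[phantom.true_module])
    data = ((f * a)[:, None] * np.sqrt(model.var_module) * intrinsic
            + f[:, None] * np.sqrt(model.var_local) * local
            + g[:, None] * np.sqrt(model.var_global) * global_sig
            + np.sqrt(model.var_noise) * noise)
    if model.var_wm > 0 and adj.any():
        # tract-local nuisance: each spatial patch of adjacent nodes
        # shares its own signal, a fraction of which is the wm-sphere
        # signal itself (removable by tissue regression)
        adj_idx = np.flatnonzero(adj)
        c = phantom.node_coords[adj_idx]
        order = np.lexsort((c[:, 0], c[:, 1], c[:, 2]))
        n_patches = max(1, int(np.ceil(len(adj_idx) / model.wm_patch_size)))
        patch_sig = _bandlimited_unit(rng, t, tr, low, high,
                                      shape=(n_patches,))
        kappa = model.wm_shared_fraction
        amp = np.sqrt(model.var_wm * model.wm_adjacent_loading)
        for p, chunk in enumerate(np.array_split(order, n_patches)):
            nodes = adj_idx[chunk]
            data[nodes] += amp * (np.sqrt(kappa) * wm_sig
                                  + np.sqrt(1 - kappa) * patch_sig[p])
    if model.motion_leak > 0:
        leak = rng.uniform(0, model.motion_leak, size=(n, 6))
        data += leak @ motion

    aux = {}
    for name, sig, var in (("white_matter_sphere", wm_sig, model.var_wm),
                           ("ventricle", vent_sig, model.var_vent)):
        coords = phantom.masks[name]
        vox_noise = _bandlimited_unit(rng, t, tr, low, high,
                                      shape=(len(coords),))
        aux[name] = (model.tissue_global_loading * np.sqrt(model.var_global)
                     * global_sig
                     + np.sqrt(var) * sig
                     + model.aux_noise_sd * vox_noise)

    return TimeSeriesDataset(data=data, tr=tr, phantom=phantom,
                             motion=motion, aux=aux,
                             provenance=[f"simulate(seed={model.seed})"])


def expected_shared_correlation(var_y1: float, var_y2: float,
                                var_g: float) -> float:
    """Population correlation of W1 = Y1 + G and W2 = Y2 + G when Y1, Y2
    and G are mutually uncorrelated:

        Corr(W1, W2) = Var(G) / sqrt((Var(Y1)+Var(G)) (Var(Y2)+Var(G)))

    Strictly positive whenever Var(G) > 0 — shared-signal bias.
    """
    if var_y1 < 0 or var_y2 < 0 or var_g < 0:
        raise ValueError("variances must be nonnegative")
    d1 = var_y1 + var_g
    d2 = var_y2 + var_g
    if d1 == 0 or d2 == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    return var_g / np.sqrt(d1 * d2)
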