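"""File I/O: TSV datasets for headless runs, NIfTI-1 volumes, partitions.

A dataset directory contains:

* ``data.tsv``    — node-by-time series (tab-separated, no header),
* ``nodes.tsv``   — per-node coordinates, tissue label, true module, hub flag,
* ``motion.tsv``  — 6-by-time regressors,
* ``aux_<mask>.tsv`` — auxiliary-mask voxel series,
* ``meta.json``   — tr, dims, mask coordinates, provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synth import Phantom, TimeSeriesDataset

__all__ = ["save_dataset", "load_dataset", "dataset_to_nifti",
           "volume_from_node_values", "save_partition_tsv"]


def save_dataset(dataset: TimeSeriesDataset, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = dataset.phantom
    np.savetxt(outdir / "data.tsv", dataset.data, delimiter="\t", fmt="%.8g")
    np.savetxt(outdir / "motion.tsv", dataset.motion, delimiter="\t", fmt="%.8g")
    with open(outdir / "nodes.tsv", "w") as fh:
        fh.write("x\ty\tz\ttissue\ttrue_module\tglobal_hub\n")
        for c, lab, mod, hub in zip(p.node_coords, p.tissue_labels,
                                    p.true_module, p.global_hub):
            fh.write(f"{c[0]}\t{c[1]}\t{c[2]}\t{lab}\t{mod}\t{int(hub)}\n")
    for name, series in dataset.aux.items():
        np.savetxt(outdir / f"aux_{name}.tsv", series, delimiter="\t",
                   fmt="%.8g")
    meta = {
        "tr": dataset.tr,
        "dims": list(p.dims),
        "masks": {k: np.asarray(v).tolist() for k, v in p.masks.items()},
        "provenance": dataset.provenance,
    }
    with open(outdir / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return outdir


def load_dataset(indir) -> TimeSeriesDataset:
    indir = Path(indir)
    with open(indir / "meta.json") as fh:
        meta = json.load(fh)
    data = np.atleast_2d(np.loadtxt(indir / "data.tsv", delimiter="\t"))
    motion = np.atleast_2d(np.loadtxt(indir / "motion.tsv", delimiter="\t"))
    coords, labels, mods, hubs = [], [], [], []
    with open(indir / "nodes.tsv") as fh:
        next(fh)
        for line in fh:
            x, y, z, lab, mod, hub = line.rstrip("\n").split("\t")
            coords.append((int(x), int(y), int(z)))
            labels.append(lab)
            mods.append(int(mod))
            hubs.append(bool(int(hub)))
    masks = {k: np.array(v, dtype=int) for k, v in meta["masks"].items()}
    phantom = Phantom(dims=tuple(meta["dims"]),
                      node_coords=np.array(coords, dtype=int),
                      tissue_labels=np.array(labels, dtype=str),
                      true_module=np.array(mods, dtype=int),
                      global_hub=np.array(hubs, dtype=bool),
                      masks=masks)
    aux = {}
    for path in sorted(indir.glob("aux_*.tsv")):
        aux[path.stem[len("aux_"):]] = np.atleast_2d(
            np.loadtxt(path, delimiter="\t"))
    return TimeSeriesDataset(data=data, tr=float(meta["tr"]), phantom=phantom,
                             motion=motion, aux=aux,
                             provenance=list(meta["provenance"]))


def volume_from_node_values(phantom: Phantom, values: np.ndarray,
                            fill: float = 0.0) -> np.ndarray:
    """Scatter per-node values into a 3-D volume on the phantom lattice."""
    vol = np.full(phantom.dims, fill, dtype=float)
    c = phantom.node_coords
    vol[c[:, 0], c[:, 1], c[:, 2]] = values
    return vol


def dataset_to_nifti(dataset: TimeSeriesDataset, series_path,
                     labels_path=None):
    """Write the phantom series as 4-D NIfTI-1 plus optional label volume.

    The label volume encodes: 0 background, 1 gray, 2 gray/wm-adjacent,
    3 white-matter sphere, 4 ventricle.
    """
    import nibabel as nib
    p = dataset.phantom
    affine = np.diag([4.0, 4.0, 5.0, 1.0])  # BOLD-like voxel size in mm
    vol4 = np.zeros(p.dims + (dataset.t,), dtype=np.float32)
    c = p.node_coords
    vol4[c[:, 0], c[:, 1], c[:, 2], :] = dataset.data
    for name, series in dataset.aux.items():
        mc = p.masks[name]
        vol4[mc[:, 0], mc[:, 1], mc[:, 2], :] = series
    img = nib.Nifti1Image(vol4, affine)
    img.header["pixdim"][4] = dataset.tr
    nib.save(img, str(series_path))
    if labels_path is not None:
        lab = np.zeros(p.dims, dtype=np.int16)
        lab[c[:, 0], c[:, 1], c[:, 2]] = np.where(p.wm_adjacent, 2, 1)
        for code, name in ((3, "white_matter_sphere"), (4, "ventricle")):
            mc = p.masks[name]
            lab[mc[:, 0], mc[:, 1], mc[:, 2]] = code
        nib.save(nib.Nifti1Image(lab, affine), str(labels_path))


def node_values_to_nifti(phantom: Phantom, values: np.ndarray, path,
                         fill: float = 0.0):
    """Write per-node values (overlap counts, module ids, degrees...)
    as a 3-D NIfTI-1 volume on the phantom lattice."""
    import nibabel as nib
    vol = volume_from_node_values(phantom, np.asarray(values, dtype=float),
                                  fill=fill)
    affine = np.diag([4.0, 4.0, 5.0, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))


def save_partition_tsv(labels: np.ndarray, path):
    with open(path, "w") as fh:
        fh.write("node\tmodule\n")
        for i, c in enumerate(labels):
            fh.write(f"{i}\t{c}\n")
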