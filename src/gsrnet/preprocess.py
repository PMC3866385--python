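"""Band-pass filtering and the four global-signal correction schemes.

The four schemes differ only in which nuisance series join the six
motion regressors in a per-node ordinary-least-squares regression:

* ``NoCorr``  — motion only,
* ``NoWB``    — motion + white matter + ventricle,
* ``WBonly``  — motion + whole-brain mean,
* ``Full``    — motion + white matter + ventricle + whole-brain mean.

Filtering precedes regression by default, which matches common practice
for this pipeline; a band-pass of the regressors themselves is available
behind a flag for users who prefer to keep the regression inside the
filtered subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import Phantom, TimeSeriesDataset

__all__ = [
    "NuisanceSet",
    "CorrectionMethod",
    "NOCORR", "NOWB", "WBONLY", "FULL", "ALL_METHODS",
    "bandpass",
    "extract_nuisance",
    "regress_out",
]


class CollinearRegressorsError(ValueError):
    """Nuisance design matrix is (near-)rank-deficient."""


@dataclass(frozen=True)
class NuisanceSet:
    """Motion regressors plus the three tissue mean time courses."""

    motion: np.ndarray        # (6, t)
    whole_brain: np.ndarray   # (t,)
    white_matter: np.ndarray  # (t,)
    ventricle: np.ndarray     # (t,)

    def __post_init__(self):
        t = self.motion.shape[1]
        for name in ("whole_brain", "white_matter", "ventricle"):
            if getattr(self, name).shape != (t,):
                raise ValueError(f"{name} must have {t} time points")

    def stack(self, components: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
        """Rows of the requested components plus column labels."""
        rows, names = [], []
        for comp in components:
            if comp == "motion":
                rows.append(self.motion)
                names.extend(f"motion{k}" for k in range(6))
            else:
                rows.append(getattr(self, comp)[None, :])
                names.append(comp)
        return np.vstack(rows), names


@dataclass(frozen=True)
class CorrectionMethod:
    """A named global-signal correction scheme: which regressors it uses."""

    name: str
    regressors: tuple[str, ...]

    _ALLOWED = {
        "NoCorr": ("motion",),
        "NoWB": ("motion", "white_matter", "ventricle"),
        "WBonly": ("motion", "whole_brain"),
        "Full": ("motion", "white_matter", "ventricle", "whole_brain"),
    }

    def __post_init__(self):
        expect = self._ALLOWED.get(self.name)
        if expect is None:
            raise ValueError(f"unknown correction method {self.name!r}")
        if tuple(self.regressors) != expect:
            raise ValueError(
                f"{self.name} must use regressors {expect}, got {self.regressors}")

    @classmethod
    def from_name(cls, name: str) -> "CorrectionMethod":
        return cls(name=name, regressors=cls._ALLOWED[name])


NOCORR = CorrectionMethod.from_name("NoCorr")
NOWB = CorrectionMethod.from_name("NoWB")
WBONLY = CorrectionMethod.from_name("WBonly")
FULL = CorrectionMethod.from_name("Full")
ALL_METHODS = (NOCORR, NOWB, WBONLY, FULL)


def _butter_sos(low: float, high: float, tr: float, order: int = 4):
    fs = 1.0 / tr
    if low <= 0:
        return sps.butter(order, high, btype="lowpass", fs=fs, output="sos")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs,
                      output="sos")


def _ideal_band(x: np.ndarray, tr: float, low: float, high: float) -> np.ndarray:
    f = np.fft.rfftfreq(x.shape[-1], d=tr)
    keep = (f >= low) & (f <= high)
    spec = np.fft.rfft(x)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=x.shape[-1])


def bandpass(dataset: TimeSeriesDataset, low: float = 0.009,
             high: float = 0.08, design: str = "butterworth"
             ) -> TimeSeriesDataset:
    """Temporal band-pass of node and auxiliary series.

    ``design="butterworth"`` (default) applies a zero-phase
    forward-backward 4th-order Butterworth; ``design="ideal"`` applies a
    hard FFT mask on the passband. Motion regressors are left untouched.
    """
    nyq = 0.5 / dataset.tr
    if not (0 <= low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz invalid for tr="
                         f"{dataset.tr} (Nyquist {nyq:g} Hz)")
    if design == "butterworth":
        sos = _butter_sos(low, high, dataset.tr)

        def _apply(x):
            y = sps.sosfiltfilt(sos, x, axis=-1)
            if low <= 0:  # lowpass leaves the mean; remove DC explicitly
                y = y - y.mean(axis=-1, keepdims=True)
            return y
    elif design == "ideal":
        def _apply(x):
            return _ideal_band(x, dataset.tr, low, high)
    else:
        raise ValueError(f"unknown filter design {design!r}")

    return dataset.copy_with(
        data=_apply(dataset.data),
        aux={k: _apply(v) for k, v in dataset.aux.items()},
        step=f"bandpass({low}-{high}Hz,{design})")


def extract_nuisance(dataset: TimeSeriesDataset,
                     phantom: Phantom | None = None) -> NuisanceSet:
    """Unweighted mask-mean tissue series plus the motion regressors.

    The whole-brain series is the parenchyma mean — network (gray)
    nodes together with the white-matter sphere voxels — and excludes
    the ventricle voxels.
    """
    phantom = phantom or dataset.phantom
    for name in ("white_matter_sphere", "ventricle"):
        if name not in dataset.aux or len(dataset.aux[name]) == 0:
            raise ValueError(f"empty or missing auxiliary mask {name!r}")
    wm = dataset.aux["white_matter_sphere"]
    vent = dataset.aux["ventricle"]
    parenchyma = np.vstack([dataset.data, wm])
    return NuisanceSet(motion=dataset.motion,
                       whole_brain=parenchyma.mean(axis=0),
                       white_matter=wm.mean(axis=0),
                       ventricle=vent.mean(axis=0))


def _design_matrix(method: CorrectionMethod, nuisance: NuisanceSet,
                   t: int, cond_limit: float = 1e8):
    rows, names = nuisance.stack(method.regressors)
    rows = rows - rows.mean(axis=1, keepdims=True)
    X = np.column_stack([np.ones(t), rows.T])
    names = ["intercept"] + names
    # drop all-zero regressors (e.g. zero-amplitude motion) — they carry
    # no signal and would only make the design singular
    keep = [0] + [j for j in range(1, X.shape[1])
                  if np.linalg.norm(X[:, j]) > 0]
    dropped = [names[j] for j in range(1, X.shape[1]) if j not in keep]
    X, names = X[:, keep], [names[j] for j in keep]
    # scale-invariant collinearity check: small-but-independent
    # regressors are harmless, parallel ones are not
    sv = np.linalg.svd(X / np.linalg.norm(X, axis=0), compute_uv=False)
    if sv[-1] == 0 or sv[0] / sv[-1] > cond_limit:
        # identify the offending columns for the error message
        bad = []
        for j in range(1, X.shape[1]):
            rest = np.delete(X, j, axis=1)
            beta, *_ = np.linalg.lstsq(rest, X[:, j], rcond=None)
            resid = X[:, j] - rest @ beta
            if np.linalg.norm(resid) < 1e-8 * np.linalg.norm(X[:, j]):
                bad.append(names[j])
        raise CollinearRegressorsError(
            f"nuisance design for {method.name} is near-collinear "
            f"(condition {sv[0] / max(sv[-1], 1e-300):.2e}); "
            f"suspect columns: {bad or 'unidentified'}")
    return X, names, dropped


def regress_out(dataset: TimeSeriesDataset, method: CorrectionMethod,
                nuisance: NuisanceSet, *, filter_regressors: bool = False,
                band: tuple[float, float] = (0.009, 0.08)
                ) -> TimeSeriesDataset:
    """OLS-residualize every node series on the method's regressors.

    Each residual series is orthogonal to the intercept and to every
    regressor. With ``filter_regressors=True`` the nuisance series are
    band-passed before entering the design, keeping the regression
    within the filtered frequency band.
    """
    if filter_regressors:
        nuisance = NuisanceSet(
            motion=_ideal_band(nuisance.motion, dataset.tr, *band),
            whole_brain=_ideal_band(nuisance.whole_brain, dataset.tr, *band),
            white_matter=_ideal_band(nuisance.white_matter, dataset.tr, *band),
            ventricle=_ideal_band(nuisance.ventricle, dataset.tr, *band))
    X, _, _ = _design_matrix(method, nuisance, dataset.t)
    # residual maker applied to all nodes at once: R = Y - X (X^+ Y)
    beta, *_ = np.linalg.lstsq(X, dataset.data.T, rcond=None)
    resid = dataset.data - (X @ beta).T
    return dataset.copy_with(data=resid, step=f"regress_out({method.name})")
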