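"""Decode predicted pseudo-labels to NIR and evaluate the reconstruction.

The reconstructed spectrum is compared with the truth per land class via
NIR frequency-distribution curves (histogram mass on a shared grid), their
peaks, greedily matched peak gaps (surplus peaks reported separately — the
field comparison found multi-peak predictions against single true peaks),
and the medians of the two distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .errors import DegenerateInputError
from .types import CLASS_NAMES, ClusterCodebook

__all__ = [
    "reconstruct_nir", "frequency_curve", "find_peaks", "peak_gap",
    "SpectralCurve", "evaluate_reconstruction", "save_report",
]


def reconstruct_nir(pred_labels, codebook: ClusterCodebook) -> np.ndarray:
    """Label -> NIR center of that label (the quantization inverse)."""
    return codebook.decode(pred_labels)


@dataclass
class SpectralCurve:
    """Normalized NIR frequency curve: bin centers + mass (sums to 1)."""

    centers: np.ndarray
    mass: np.ndarray
    bin_width: float
    edges: np.ndarray = field(repr=False, default=None)


def frequency_curve(nir_values, bins: int = 64, value_range=None) -> SpectralCurve:
    """Histogram mass of NIR on a fixed grid.

    Pass the pooled (true + predicted) range as ``value_range`` so two
    curves share a grid and stay comparable.
    """
    v = np.asarray(nir_values, dtype=np.float64).ravel()
    if v.size < 10:
        raise DegenerateInputError("need at least 10 values for a frequency curve")
    if value_range is None:
        value_range = (v.min(), v.max())
    lo, hi = float(value_range[0]), float(value_range[1])
    if hi <= lo:
        hi = lo + 1e-6
    counts, edges = np.histogram(v, bins=bins, range=(lo, hi))
    mass = counts / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    return SpectralCurve(centers=centers, mass=mass,
                         bin_width=float(edges[1] - edges[0]), edges=edges)


def find_peaks(curve: SpectralCurve, min_prominence: float = 0.05) -> np.ndarray:
    """NIR locations of local maxima with prominence >= min_prominence * max.

    Sorted ascending; an empty array when the curve is flat. Peaks at the
    grid boundary are included (the mass vector is zero-padded before peak
    calling so single-bin masses register).
    """
    m = curve.mass
    if m.max() <= 0:
        return np.empty(0)
    padded = np.concatenate([[0.0], m, [0.0]])
    idx, _ = _scipy_find_peaks(padded, prominence=min_prominence * m.max())
    return np.sort(curve.centers[idx - 1])


def peak_gap(true_peaks, pred_peaks):
    """Greedy nearest matching of predicted to true peaks.

    Pairs are matched globally closest-first until the shorter list is
    exhausted; returns ``(max_gap, gaps, surplus)`` where ``surplus`` lists
    the unmatched peaks of the longer side.
    """
    t = list(np.asarray(true_peaks, dtype=np.float64).ravel())
    p = list(np.asarray(pred_peaks, dtype=np.float64).ravel())
    if not t or not p:
        raise DegenerateInputError("peak lists must be nonempty")
    gaps = []
    while t and p:
        pairs = [(abs(pv - tv), i, j) for i, tv in enumerate(t) for j, pv in enumerate(p)]
        d, i, j = min(pairs)
        gaps.append(d)
        t.pop(i)
        p.pop(j)
    surplus = t + p
    return float(max(gaps)), gaps, surplus


def evaluate_reconstruction(true_nir_by_class: dict, pred_nir_by_class: dict,
                            bins: int = 64, min_prominence: float = 0.05) -> dict:
    """Per-class reconstruction report.

    For every class present in the truth: peak lists of both curves (on a
    shared grid spanning the pooled range), matched gaps and surplus
    count, medians, and the curves themselves. Raises when a truth class
    is absent from the predictions.
    """
    report = {}
    for cls, t in true_nir_by_class.items():
        if cls not in pred_nir_by_class:
            raise DegenerateInputError(f"class {cls!r} missing from predictions")
        p = np.asarray(pred_nir_by_class[cls], dtype=np.float64)
        t = np.asarray(t, dtype=np.float64)
        rng = (min(t.min(), p.min()), max(t.max(), p.max()))
        ct = frequency_curve(t, bins=bins, value_range=rng)
        cp = frequency_curve(p, bins=bins, value_range=rng)
        tp = find_peaks(ct, min_prominence)
        pp = find_peaks(cp, min_prominence)
        entry = {
            "true_peaks": tp.tolist(),
            "pred_peaks": pp.tolist(),
            "median_true": float(np.median(t)),
            "median_pred": float(np.median(p)),
            "bin_width": ct.bin_width,
            "n_true": int(t.size),
            "n_pred": int(p.size),
        }
        if tp.size and pp.size:
            max_gap, gaps, surplus = peak_gap(tp, pp)
            entry.update(max_peak_diff=max_gap, matched_gaps=gaps,
                         surplus=[float(s) for s in surplus])
        else:
            entry.update(max_peak_diff=None, matched_gaps=[], surplus=[])
        entry["curves"] = {
            "grid": ct.centers.tolist(),
            "true_mass": ct.mass.tolist(),
            "pred_mass": cp.mass.tolist(),
        }
        report[cls] = entry
    return report


def save_report(report: dict, path, with_curves: bool = True) -> None:
    out = {}
    for cls, entry in report.items():
        e = dict(entry)
        if not with_curves:
            e.pop("curves", None)
        out[str(cls)] = e
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)


def plot_curves(report: dict, path) -> None:
    """Overlay true vs reconstructed NIR frequency curves, one panel per class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = [c for c in report if "curves" in report[c]]
    fig, axes = plt.subplots(1, max(len(classes), 1), figsize=(4 * len(classes), 3),
                             squeeze=False)
    for ax, cls in zip(axes[0], classes):
        cur = report[cls]["curves"]
        ax.plot(cur["grid"], cur["true_mass"], color="0.4", label="true")
        ax.plot(cur["grid"], cur["pred_mass"], color="tab:blue", label="reconstructed")
        for p in report[cls]["true_peaks"]:
            ax.axvline(p, color="0.7", lw=0.6, ls=":")
        for p in report[cls]["pred_peaks"]:
            ax.axvline(p, color="tab:red", lw=0.6, ls="--")
        ax.set_title(cls)
        ax.set_xlabel("NIR (grayscale)")
    axes[0][0].set_ylabel("frequency")
    axes[0][-1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def split_by_class(nir: np.ndarray, class_id: np.ndarray) -> dict:
    """Helper: {class_name: nir values} for the three land classes."""
    out = {}
    for c in np.unique(class_id):
        out[CLASS_NAMES.get(int(c), str(int(c)))] = nir[class_id == c]
    return out
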