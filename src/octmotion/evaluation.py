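"""Evaluation metrics and robustness sweeps for motion estimation.

Metrics follow the conventions of the motion-estimation literature:

MAE
    Per-axis mean +- std of the absolute error (mm) of the final-step shift.
rMAE
    Absolute errors normalized by the per-axis sample standard deviation
    (n-1) of the targets, pooled across the three axes and summarized as
    mean +- std.  A value of 1 is the scale of a trivial predictor.
aCC
    Pearson correlation between predictions and targets per axis, averaged
    over the three axes, in percent.  (The averaged-over-axes reading is
    used; concatenating axes before correlating differs negligibly.)

Model pairs are compared with the two-sided Wilcoxon signed-rank test on
paired per-sample rMAE values (zero differences dropped, the standard
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .augmentations import (DistortionSpec, RotationSpec, distort_sequence,
                            rotate_sequence)
from .trajectories import MotionSequence, sequences_to_arrays

__all__ = [
    "EvalReport",
    "mae_per_axis",
    "rmae",
    "rmae_samples",
    "acc_metric",
    "wilcoxon_compare",
    "magnitude_binned_mae",
    "evaluate_predictions",
    "evaluate_model",
    "robustness_sweep",
]


def _check_pairs(preds, targets) -> Tuple[np.ndarray, np.ndarray]:
    p = np.asarray(preds, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(
            f"predictions {p.shape} and targets {t.shape} must both be (N, 3)")
    if p.shape[0] == 0:
        raise ValueError("empty sample")
    return p, t


def mae_per_axis(preds, targets) -> Tuple[np.ndarray, np.ndarray]:
    """Per-axis (mean, std) of the absolute error, mm."""
    p, t = _check_pairs(preds, targets)
    err = np.abs(p - t)
    std = err.std(axis=0, ddof=1) if err.shape[0] > 1 else np.zeros(3)
    return err.mean(axis=0), std


def _axis_stds(targets: np.ndarray) -> np.ndarray:
    std = targets.std(axis=0, ddof=1)
    if np.any(std <= 0) or targets.shape[0] < 2:
        raise ValueError("target standard deviation is zero on some axis; "
                         "rMAE is undefined")
    return std


def rmae_samples(preds, targets) -> np.ndarray:
    """Per-sample rMAE: axis-normalized absolute errors averaged per sample."""
    p, t = _check_pairs(preds, targets)
    return (np.abs(p - t) / _axis_stds(t)).mean(axis=1)


def rmae(preds, targets) -> Tuple[float, float]:
    """(mean, std) of the pooled axis-normalized absolute errors."""
    p, t = _check_pairs(preds, targets)
    pooled = (np.abs(p - t) / _axis_stds(t)).ravel()
    return float(pooled.mean()), float(pooled.std(ddof=1))


def acc_metric(preds, targets) -> float:
    """Average correlation coefficient, percent."""
    p, t = _check_pairs(preds, targets)
    if p.shape[0] < 2:
        raise ValueError("aCC needs at least two samples")
    rs = []
    for ax in range(3):
        if p[:, ax].std() == 0 or t[:, ax].std() == 0:
            raise ValueError(f"degenerate variance on axis {ax}; "
                             "correlation undefined")
        rs.append(np.corrcoef(p[:, ax], t[:, ax])[0, 1])
    return float(np.mean(rs) * 100.0)


def wilcoxon_compare(errors_a, errors_b, alpha: float = 0.05
                     ) -> Tuple[float, float, bool]:
    """Two-sided paired signed-rank test on per-sample error values.

    Returns (statistic, p-value, significant-at-alpha).  Pairs with zero
    difference are dropped; if every difference is zero the comparison is
    reported as not significant with p = 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if len(a) < 6:
        raise ValueError("need at least 6 pairs for the signed-rank test")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0, False
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def magnitude_binned_mae(preds, targets, n_bins: int = 4
                         ) -> Dict[str, np.ndarray]:
    """MAE of the error norm within quantile bins of the target magnitude.

    Samples are assigned to ``n_bins`` quantile bins of ||shift|| so the
    bins cover increasing magnitudes of motion with (near) equal counts.
    """
    p, t = _check_pairs(preds, targets)
    if p.shape[0] < n_bins:
        raise ValueError(f"{p.shape[0]} samples cannot fill {n_bins} bins")
    mag = np.linalg.norm(t, axis=1)
    err = np.linalg.norm(p - t, axis=1)
    edges = np.quantile(mag, np.linspace(0, 1, n_bins + 1))
    edges[-1] = np.nextafter(edges[-1], np.inf)
    idx = np.clip(np.searchsorted(edges, mag, side="right") - 1, 0, n_bins - 1)
    per_bin = np.array([err[idx == b].mean() if np.any(idx == b) else np.nan
                        for b in range(n_bins)])
    counts = np.bincount(idx, minlength=n_bins)
    return {"bin_edges": edges, "per_bin_mae": per_bin, "counts": counts}


@dataclass
class EvalReport:
    """Summary of one evaluation run (all errors on the final-step shift)."""

    mae_mean: Tuple[float, float, float]
    mae_std: Tuple[float, float, float]
    rmae_mean: float
    rmae_std: float
    acc_percent: float
    per_bin_mae: Tuple[float, ...]
    bin_edges: Tuple[float, ...]
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_predictions(preds, targets, n_bins: int = 4) -> EvalReport:
    p, t = _check_pairs(preds, targets)
    mae_m, mae_s = mae_per_axis(p, t)
    rm, rs = rmae(p, t)
    binned = magnitude_binned_mae(p, t, n_bins=n_bins)
    return EvalReport(
        mae_mean=tuple(float(v) for v in mae_m),
        mae_std=tuple(float(v) for v in mae_s),
        rmae_mean=rm, rmae_std=rs,
        acc_percent=acc_metric(p, t),
        per_bin_mae=tuple(float(v) for v in binned["per_bin_mae"]),
        bin_edges=tuple(float(v) for v in binned["bin_edges"]),
        n=int(p.shape[0]),
    )


def evaluate_model(model, sequences: Sequence[MotionSequence],
                   n_bins: int = 4) -> EvalReport:
    """Evaluate a trained model's main head on a held-out sequence set."""
    x, y, _ = sequences_to_arrays(sequences)
    preds = model.predict_batch(x)
    return evaluate_predictions(preds, y[:, -1], n_bins=n_bins)


def robustness_sweep(model, sequences: Sequence[MotionSequence], axis: str,
                     levels: Optional[Sequence] = None,
                     seed: int = 0) -> Dict[Tuple, EvalReport]:
    """Evaluation-time augmentation sweep.

    ``axis='rotation'`` sweeps alpha_max over {2, 5, 10, 20} degrees crossed
    with the {noise, motion} label modes; ``axis='distortion'`` sweeps
    p_dist over {0.1, 0.25, 0.5} crossed with B-scan shifts of {1, 2}
    voxels.  Each cell evaluates the model on the augmented copies of
    ``sequences`` and returns one report keyed by the cell's parameters.
    """
    reports: Dict[Tuple, EvalReport] = {}
    if axis == "rotation":
        alphas = levels if levels is not None else (2.0, 5.0, 10.0, 20.0)
        for mode in ("noise", "motion"):
            for a in alphas:
                spec = RotationSpec(alpha_max=float(a), mode=mode)
                aug = [rotate_sequence(s, spec) for s in sequences]
                reports[(mode, float(a))] = evaluate_model(model, aug)
    elif axis == "distortion":
        ps = levels if levels is not None else (0.1, 0.25, 0.5)
        for shift_px in (1, 2):
            for p in ps:
                spec = DistortionSpec(p_dist=float(p), shift_px=shift_px)
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), shift_px,
                                            int(round(p * 1000))]))
                aug = [distort_sequence(s, spec, rng) for s in sequences]
                reports[(shift_px, float(p))] = evaluate_model(model, aug)
    else:
        raise ValueError("axis must be 'rotation' or 'distortion'")
    return reports


def plot_magnitude_curves(reports: Dict[str, EvalReport], path=None):
    """MAE-vs-magnitude curves for several models (optional figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, rep in reports.items():
        edges = np.asarray(rep.bin_edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ax.plot(centers, rep.per_bin_mae, marker="o", label=name)
    ax.set_xlabel("target shift magnitude (mm)")
    ax.set_ylabel("MAE of ||error|| (mm)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
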