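"""Pixel-to-pixel image quality metrics and per-dataset aggregation.

Metrics follow the conventions used for normalised conductivity images:

* ``rmse`` - root mean square error.
* ``corr2d`` - Pearson correlation of the flattened images.
* ``psnr`` - as defined for this pipeline, ``10 log10(N max(yhat) / SSE)``,
  which differs from the textbook definition (peak squared over MSE); the
  textbook form is available with ``conventional=True``.
* ``ssim_global`` - a single global (windowless) structural similarity value
  with stabilising constants c1, c2.

``evaluate_images`` / ``evaluate_model`` aggregate per-sample metrics into
mean +- sd reports per noise level, with histogram bin counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "rmse",
    "corr2d",
    "psnr",
    "ssim_global",
    "MetricsReport",
    "evaluate_images",
]

METRIC_NAMES = ("rmse", "psnr", "ssim", "cc2d")


def _flat(y_hat, y):
    a, b = np.asarray(y_hat, float).ravel(), np.asarray(y, float).ravel()
    if a.size != b.size:
        raise ValueError(f"shape mismatch: {a.size} vs {b.size} pixels")
    if a.size == 0:
        raise ValueError("empty images")
    return a, b


def rmse(y_hat, y) -> float:
    """Root mean square error between reconstruction and reference."""
    a, b = _flat(y_hat, y)
    return float(np.sqrt(np.mean((b - a) ** 2)))


def corr2d(y_hat, y) -> float:
    """Pearson (2D) correlation coefficient of the flattened images."""
    a, b = _flat(y_hat, y)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined for a constant image")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def psnr(y_hat, y, conventional: bool = False) -> float:
    """Peak signal-to-noise ratio in dB.

    Default form: ``10 log10( N * max(y_hat) / sum((y - y_hat)^2) )``.
    ``conventional=True`` gives ``10 log10( max(y_hat)^2 / MSE )``.
    A perfect match returns +inf.
    """
    a, b = _flat(y_hat, y)
    sse = float(np.sum((b - a) ** 2))
    peak = float(a.max())
    if peak <= 0:
        raise ValueError("PSNR undefined for a non-positive reconstruction peak")
    if sse == 0:
        return float("inf")
    if conventional:
        return float(10.0 * np.log10(peak**2 / (sse / a.size)))
    return float(10.0 * np.log10(a.size * peak / sse))


def ssim_global(y_hat, y, c1: float = (0.01 * 1.0) ** 2,
                c2: float = (0.03 * 1.0) ** 2) -> float:
    """Single global SSIM (no sliding window), for images on a [0, 1] scale.

    ``(2 mu_y mu_yh + c1)(2 cov + c2) / ((mu_y^2 + mu_yh^2 + c1)
    (var_y + var_yh + c2))``; the defaults use the standard constants
    with dynamic range L = 1.
    """
    a, b = _flat(y_hat, y)
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = np.mean((a - mu_a) * (b - mu_b))
    return float((2 * mu_a * mu_b + c1) * (2 * cov + c2)
                 / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)))


@dataclass
class MetricsReport:
    """Aggregated metrics for one sample set at one noise condition."""

    snr_db: float
    per_sample: dict                      # metric -> np.ndarray of per-sample values
    n_failed: int = 0
    histogram_bins: int = 20
    histograms: dict = field(default_factory=dict)  # metric -> (counts, edges)

    @property
    def mean(self) -> dict:
        return {k: float(np.mean(v)) for k, v in self.per_sample.items()}

    @property
    def sd(self) -> dict:
        return {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                for k, v in self.per_sample.items()}

    def as_dict(self) -> dict:
        return {"snr_db": self.snr_db, "mean": self.mean, "sd": self.sd,
                "n_samples": int(len(next(iter(self.per_sample.values())))),
                "n_failed": self.n_failed}

    def to_csv(self, path) -> None:
        import csv

        keys = list(self.per_sample)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample"] + keys)
            for i in range(len(self.per_sample[keys[0]])):
                w.writerow([i] + [repr(float(self.per_sample[k][i])) for k in keys])


def evaluate_images(y_hats, ys, snr_db: float = np.inf,
                    histogram_bins: int = 20) -> MetricsReport:
    """Per-sample RMSE / PSNR / SSIM / correlation over paired image sets.

    Samples for which a metric is undefined (for example a constant
    reference) are excluded from the aggregates and counted in
    ``n_failed``.
    """
    rows = {k: [] for k in METRIC_NAMES}
    failed = 0
    for yh, yy in zip(y_hats, ys):
        try:
            vals = (rmse(yh, yy), psnr(yh, yy), ssim_global(yh, yy), corr2d(yh, yy))
        except ValueError:
            failed += 1
            continue
        for k, v in zip(METRIC_NAMES, vals):
            rows[k].append(v)
    if not rows["rmse"]:
        raise ValueError("no valid samples to evaluate")
    per_sample = {k: np.asarray(v) for k, v in rows.items()}
    report = MetricsReport(snr_db, per_sample, failed, histogram_bins)
    for k, v in per_sample.items():
        finite = v[np.isfinite(v)]
        if finite.size:
            try:
                counts, edges = np.histogram(finite, bins=histogram_bins)
            except ValueError:  # degenerate range (e.g. all-identical values)
                counts, edges = np.histogram(finite, bins=1)
            report.histograms[k] = (counts, edges)
    return report


def save_histogram_pngs(reports, out_dir) -> None:
    """One histogram panel per metric across noise conditions (PNG files)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for metric in METRIC_NAMES:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for rep in reports:
            v = rep.per_sample[metric]
            v = v[np.isfinite(v)]
            ax.hist(v, bins=rep.histogram_bins, alpha=0.5,
                    label=f"SNR {rep.snr_db:g} dB")
        ax.set_xlabel(metric)
        ax.set_ylabel("samples")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / f"hist_{metric}.png", dpi=120)
        plt.close(fig)
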