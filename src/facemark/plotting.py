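"""Optional evaluation plots (requires matplotlib).

Boxplots of per-landmark error distributions and kernel-density plots of
Procrustes distances from the mean, for comparing landmarking methods.
matplotlib is imported lazily so the rest of the package has no hard
dependency on it.
"""

from __future__ import annotations

import numpy as np

from .morphometrics import ErrorReport

__all__ = ["error_boxplot", "procrustes_kde"]


def _pyplot():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib; install facemark[plot]"
        ) from exc
    return plt


def error_boxplot(reports: dict[str, ErrorReport], ax=None):
    """Side-by-side boxplots of per-landmark error distributions.

    ``reports`` maps a method label (e.g. "image-based", "NICP") to its
    :class:`ErrorReport`; one box per landmark per method.
    """
    plt = _pyplot()
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    n_methods = len(reports)
    for m, (label, report) in enumerate(reports.items()):
        k = report.distances.shape[1]
        positions = np.arange(k) * (n_methods + 1) + m
        ax.boxplot([report.distances[:, i] for i in range(k)],
                   positions=positions, widths=0.8,
                   label=label, whis=1.5)
    first = next(iter(reports.values()))
    k = first.distances.shape[1]
    ax.set_xticks(np.arange(k) * (n_methods + 1) + (n_methods - 1) / 2)
    ax.set_xticklabels(first.labels, rotation=45)
    ax.set_ylabel("landmark distance (mm)")
    ax.legend()
    return ax


def procrustes_kde(distances: dict[str, np.ndarray], ax=None):
    """Kernel-density plot of Procrustes distances from the mean, one
    curve per landmarking procedure."""
    from scipy.stats import gaussian_kde

    plt = _pyplot()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    hi = max(np.max(d) for d in distances.values())
    grid = np.linspace(0.0, hi * 1.2, 400)
    for label, d in distances.items():
        d = np.asarray(d, float)
        ax.plot(grid, gaussian_kde(d)(grid), label=label)
    ax.set_xlabel("Procrustes distance from the mean")
    ax.set_ylabel("density")
    ax.legend()
    return ax
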