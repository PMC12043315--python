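"""Quick-look plots for spectra, span histograms, and pull traces."""

from __future__ import annotations

import numpy as np


def plot_spectrum(spectrum, peaks=None, ax=None):
    """Line plot of a spectrum, optionally marking detected peak centroids."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(spectrum.mz, spectrum.intensity, lw=0.8, color="k")
    if peaks:
        ax.plot([p.centroid for p in peaks], [p.height for p in peaks],
                "v", color="crimson", ms=5)
    ax.set_xlabel("m/z")
    ax.set_ylabel("intensity")
    return ax


def plot_span_histogram(edges, counts, ax=None):
    """Bar plot of the log10 basic-residue span histogram."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    widths = np.diff(edges)
    ax.bar(edges[:-1], counts, width=widths, align="edge",
           color="steelblue", edgecolor="white")
    ax.set_xlabel("log10(max basic-residue span)")
    ax.set_ylabel("sites")
    return ax


def plot_force_traces(traces, d_stop=None, ax=None):
    """Overlay force–extension traces; optionally mark the work cutoff."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for trace in traces:
        ax.plot(trace.coordinate, trace.force, lw=0.6, alpha=0.7)
    if d_stop is not None:
        ax.axvline(d_stop, color="grey", ls="--", lw=1)
    ax.set_xlabel("pull coordinate (nm)")
    ax.set_ylabel("force (kJ mol$^{-1}$ nm$^{-1}$)")
    return ax
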