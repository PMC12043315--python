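"""Native-MS spectrum processing and the two stabilization readouts.

Two assays are implemented on top of peak detection and assignment:

* the lipid-adduct occupancy profile of an intact complex — how much signal
  sits at 0, 1, 2, ... bound lipids (per charge state, summed over the
  selected charge states); and
* the competitive stabilization assay: two protein variants are activated
  together so each ejects unfolded monomers; the ratio of one variant's
  monomer signal to the total monomer signal, measured with and without
  lipid, reports which tetramer the lipid protects more.  With species A as
  reference and B as test, the ratio B/(A+B) increases upon lipid addition
  when A is stabilized more than B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .masses import PeakAssignment, SpeciesModel, assign_peaks, expected_peak_table
from .stats import TwoSampleResult, two_sample_ttest

__all__ = [
    "Spectrum",
    "Peak",
    "AdductProfile",
    "StabilizationResult",
    "detect_peaks",
    "species_intensity",
    "adduct_profile",
    "stabilization_ratio",
    "compare_stabilization",
    "monomer_ratio_from_spectrum",
    "competition_assay",
]


@dataclass(frozen=True)
class Spectrum:
    """An m/z–intensity array with optional acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    condition: str = ""
    replicate: int | None = None

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or mz.size != inten.size:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size >= 2 and not np.all(np.diff(mz) > 0):
            raise ValueError("m/z values must be strictly ascending")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class Peak:
    """A detected peak: intensity-weighted centroid, height, trapezoid area."""

    centroid: float
    height: float
    area: float
    window: tuple

    def __post_init__(self):
        lo, hi = self.window
        if not lo <= self.centroid <= hi:
            raise ValueError("centroid must lie inside the peak window")


def _noise_scale(intensity: np.ndarray, baseline_width: int) -> float:
    """Robust noise sigma: 1.4826 * MAD of the median-detrended signal."""
    width = max(3, baseline_width)
    detrended = intensity - median_filter(intensity, size=width, mode="nearest")
    mad = np.median(np.abs(detrended - np.median(detrended)))
    return 1.4826 * float(mad)


def detect_peaks(spectrum: Spectrum,
                 min_snr: float = 5.0,
                 min_separation: float = 5.0,
                 baseline_width: int = 101) -> list[Peak]:
    """Find local maxima above an SNR threshold and integrate them.

    The noise scale is 1.4826 x the median absolute deviation of the
    median-filter-detrended signal (robust to the peaks themselves).  A
    peak's window extends from its apex down to the first local minimum or
    to where the signal falls below the noise floor; centroid is the
    intensity-weighted mean m/z over the window, area the trapezoid
    integral.
    """
    if min_snr <= 0:
        raise ValueError("min_snr must be positive")
    y = spectrum.intensity
    x = spectrum.mz
    if y.size < 3:
        raise ValueError("spectrum too short for peak detection")
    sigma = _noise_scale(y, baseline_width)
    # noiseless synthetic spectra have sigma == 0: fall back to a tiny
    # fraction of the maximum so real maxima still clear the threshold
    floor = max(min_snr * sigma, 1e-9 * float(y.max()) if y.max() > 0 else np.inf)
    step = float(np.median(np.diff(x))) if x.size > 1 else 1.0
    distance = max(1, int(round(min_separation / step)))
    idx, _ = find_peaks(y, height=floor, distance=distance)

    peaks: list[Peak] = []
    cut = max(sigma, 1e-12 * float(y.max()) if y.max() > 0 else 0.0)
    for i in idx:
        lo = i
        while lo > 0 and y[lo - 1] < y[lo] and y[lo - 1] > cut:
            lo -= 1
        hi = i
        while hi < y.size - 1 and y[hi + 1] < y[hi] and y[hi + 1] > cut:
            hi += 1
        w = slice(lo, hi + 1)
        weight = y[w].sum()
        centroid = float((x[w] * y[w]).sum() / weight) if weight > 0 else float(x[i])
        centroid = min(max(centroid, float(x[lo])), float(x[hi]))  # guard fp rounding
        area = float(np.trapezoid(y[w], x[w]))
        peaks.append(Peak(centroid=centroid, height=float(y[i]), area=area,
                          window=(float(x[lo]), float(x[hi]))))
    return peaks


ChargePolicy = Literal["all", "top_k"]
Measure = Literal["area", "height"]


def species_intensity(assignments: Sequence[PeakAssignment],
                      peaks: Sequence[Peak],
                      charge_policy: ChargePolicy = "all",
                      top_k: int = 3,
                      measure: Measure = "area") -> dict:
    """Summed signal per (species, n_adducts) over the selected charge states.

    ``top_k`` keeps, per species, the k charge states with the largest
    total signal (the "main charge states" convention; default 3).  Each
    peak contributes at most once.  Returns
    {"per_adduct": {(species, n): signal}, "total": {species: signal}}.
    """
    if measure not in ("area", "height"):
        raise ValueError(f"unknown intensity measure: {measure!r}")
    seen = set()
    per_charge: dict = {}
    for a in assignments:
        if a.peak_index is None or a.peak_index >= len(peaks):
            raise RuntimeError("assignment references an unknown peak")
        if a.peak_index in seen:
            continue
        seen.add(a.peak_index)
        value = getattr(peaks[a.peak_index], measure)
        key = (a.species, a.charge)
        per_charge.setdefault(key, {})
        per_charge[key][a.n_adducts] = per_charge[key].get(a.n_adducts, 0.0) + value

    if charge_policy == "top_k":
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        kept: dict = {}
        by_species: dict = {}
        for (sp, z), d in per_charge.items():
            by_species.setdefault(sp, []).append((sum(d.values()), z))
        for sp, entries in by_species.items():
            top = sorted(entries, reverse=True)[:top_k]
            for _, z in top:
                kept[(sp, z)] = per_charge[(sp, z)]
        per_charge = kept
    elif charge_policy != "all":
        raise ValueError(f"unknown charge policy: {charge_policy!r}")

    per_adduct: dict = {}
    total: dict = {}
    for (sp, _z), d in per_charge.items():
        for n, v in d.items():
            per_adduct[(sp, n)] = per_adduct.get((sp, n), 0.0) + v
            total[sp] = total.get(sp, 0.0) + v
    return {"per_adduct": per_adduct, "total": total}


@dataclass(frozen=True)
class AdductProfile:
    """Normalized intensity fractions across adduct counts 0..n."""

    fractions: np.ndarray
    mean_adducts: float

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)


def adduct_profile(per_adduct_intensity: Mapping[int, float] | Sequence[float]) -> AdductProfile:
    """Fractions f0..fn and the intensity-weighted mean adduct count.

    Accepts either a dense sequence indexed by adduct count or a mapping
    {n_adducts: intensity}.  All-zero input is undefined (NaN profile).
    """
    if isinstance(per_adduct_intensity, Mapping):
        n_max = max(per_adduct_intensity) if per_adduct_intensity else 0
        dense = np.zeros(n_max + 1)
        for n, v in per_adduct_intensity.items():
            if n < 0:
                raise ValueError("adduct counts must be non-negative")
            dense[n] = v
    else:
        dense = np.asarray(per_adduct_intensity, dtype=float)
    if np.any(dense < 0):
        raise ValueError("intensities must be non-negative")
    total = dense.sum()
    if total == 0:
        return AdductProfile(np.full(dense.size, np.nan), float("nan"))
    frac = dense / total
    mean = float((np.arange(dense.size) * frac).sum())
    return AdductProfile(frac, mean)


def stabilization_ratio(i_test: float, i_ref: float) -> float:
    """Test-species share of total monomer signal: I_test / (I_test + I_ref).

    Scale-invariant; NaN (undefined) when both intensities are zero.
    """
    if i_test < 0 or i_ref < 0:
        raise ValueError("intensities must be non-negative")
    total = i_test + i_ref
    if total == 0:
        return float("nan")
    return i_test / total


@dataclass(frozen=True)
class StabilizationResult:
    """Competitive stabilization assay outcome.

    ``delta`` = mean(with lipid) - mean(without); positive delta means the
    reference species is stabilized more than the test species (its monomer
    signal drops, so the test share rises).
    """

    ratios_no_lipid: tuple
    ratios_with_lipid: tuple
    delta: float
    t: float
    p: float
    n_no_lipid: int
    n_with_lipid: int
    test_kind: str

    def summary(self) -> str:
        a = ", ".join(f"{r:.3f}" for r in self.ratios_no_lipid)
        b = ", ".join(f"{r:.3f}" for r in self.ratios_with_lipid)
        sign = ("reference species stabilized more" if self.delta > 0
                else "test species stabilized more" if self.delta < 0
                else "no differential stabilization")
        return (f"ratios without lipid: [{a}]\n"
                f"ratios with lipid:    [{b}]\n"
                f"delta={self.delta:+.4f}, t={self.t:.4g}, p={self.p:.4g} "
                f"(two-sided {self.test_kind}, n={self.n_no_lipid}/{self.n_with_lipid})"
                f" -> {sign}")


def compare_stabilization(ratios_no_lipid: Sequence[float],
                          ratios_with_lipid: Sequence[float],
                          test: str = "student") -> StabilizationResult:
    """Two-sided t-test on per-replicate ratios between lipid conditions."""
    a = np.asarray(ratios_no_lipid, dtype=float)
    b = np.asarray(ratios_with_lipid, dtype=float)
    if np.any(a < 0) or np.any(a > 1) or np.any(b < 0) or np.any(b > 1):
        raise ValueError("ratios must lie in [0, 1]")
    res: TwoSampleResult = two_sample_ttest(b, a, kind=test)
    return StabilizationResult(
        ratios_no_lipid=tuple(float(v) for v in a),
        ratios_with_lipid=tuple(float(v) for v in b),
        delta=res.delta, t=res.t, p=res.p,
        n_no_lipid=a.size, n_with_lipid=b.size, test_kind=test)


def monomer_ratio_from_spectrum(spectrum: Spectrum,
                                test_monomer: SpeciesModel,
                                ref_monomer: SpeciesModel,
                                tolerance_ppm: float = 2000.0,
                                min_snr: float = 5.0,
                                min_separation: float = 5.0,
                                charge_policy: ChargePolicy = "all",
                                top_k: int = 3,
                                measure: Measure = "area") -> float:
    """One spectrum -> test/(test+ref) monomer intensity ratio.

    Runs the full pipeline: peak detection, assignment against the two
    monomer species models, per-species quantification, ratio.  The
    assignment tolerance default is wider than for adduct-series
    assignment: unfolded-monomer peaks are broad, so their centroids
    wander on the m/z scale, while the species are separated by tens of
    m/z units (thousands of ppm) — 2000 ppm keeps every centroid matched
    without cross-species ambiguity.
    """
    peaks = detect_peaks(spectrum, min_snr=min_snr, min_separation=min_separation)
    expected = expected_peak_table([test_monomer, ref_monomer])
    assignments, _ = assign_peaks([p.centroid for p in peaks], expected,
                                  tolerance_ppm=tolerance_ppm)
    quant = species_intensity(assignments, peaks, charge_policy=charge_policy,
                              top_k=top_k, measure=measure)
    return stabilization_ratio(quant["total"].get(test_monomer.name, 0.0),
                               quant["total"].get(ref_monomer.name, 0.0))


def competition_assay(spectra: Sequence[Spectrum],
                      test_monomer: SpeciesModel,
                      ref_monomer: SpeciesModel,
                      no_lipid_label: str = "no_lipid",
                      with_lipid_label: str = "with_lipid",
                      test: str = "student",
                      **pipeline_kwargs) -> StabilizationResult:
    """Full competitive stabilization assay over replicate spectra.

    Spectra are grouped by their ``condition`` metadata into the without-
    and with-lipid groups; each replicate spectrum yields one monomer
    ratio, and the two groups are compared with a two-sided t-test.
    """
    groups: dict[str, list[float]] = {no_lipid_label: [], with_lipid_label: []}
    for sp in spectra:
        if sp.condition not in groups:
            raise ValueError(
                f"spectrum condition {sp.condition!r} is neither "
                f"{no_lipid_label!r} nor {with_lipid_label!r}")
        groups[sp.condition].append(
            monomer_ratio_from_spectrum(sp, test_monomer, ref_monomer,
                                        **pipeline_kwargs))
    return compare_stabilization(groups[no_lipid_label],
                                 groups[with_lipid_label], test=test)
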