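"""Work integrals of steered-pull force–extension traces.

In a steered pull two groups of atoms are driven apart along a pull
coordinate (their centre-of-mass distance) and the restraint force is
recorded.  The mechanical work of separating the groups up to a chosen
displacement — here, by default, the 1.1 nm at which non-covalent
inter-helix contacts are lost — is the trapezoid integral of force over
the coordinate.  Comparing per-replicate works between lipid-present and
lipid-absent pulls isolates the lipid's mechanical contribution.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .stats import TwoSampleResult, two_sample_ttest

__all__ = [
    "DEFAULT_PULL_RATE",
    "ForceTrace",
    "WorkResult",
    "GroupComparison",
    "read_xvg",
    "work_integral",
    "compare_work",
]

#: default steered-pull rate, nm/ns
DEFAULT_PULL_RATE = 0.1125


@dataclass(frozen=True)
class ForceTrace:
    """Force (kJ mol^-1 nm^-1) against the pull coordinate (nm).

    Construct either directly from (coordinate, force) or from a timed
    force series via :meth:`from_time_series`, which reconstructs the
    coordinate as ``initial + rate * time``.
    """

    coordinate: np.ndarray
    force: np.ndarray
    label: str = ""

    def __post_init__(self):
        c = np.asarray(self.coordinate, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "coordinate", c)
        object.__setattr__(self, "force", f)
        if c.ndim != 1 or c.size != f.size or c.size < 2:
            raise ValueError("coordinate and force must be equal-length 1-D series (n >= 2)")
        if np.any(np.diff(c) < 0):
            raise ValueError("pull coordinate must be non-decreasing")

    @classmethod
    def from_time_series(cls, time_ns, force,
                         pull_rate: float = DEFAULT_PULL_RATE,
                         initial_coordinate: float = 0.0,
                         label: str = "") -> "ForceTrace":
        t = np.asarray(time_ns, dtype=float)
        return cls(initial_coordinate + pull_rate * t, force, label=label)


@dataclass(frozen=True)
class WorkResult:
    """Integrated work (kJ/mol) over [d_start, d_stop] of the pull coordinate."""

    work: float
    d_start: float
    d_stop: float
    n_samples: int

    def __post_init__(self):
        if self.d_stop <= self.d_start:
            raise ValueError("d_stop must exceed d_start")


def read_xvg(path_or_file) -> np.ndarray:
    """Parse a GROMACS-style xvg file into a (rows, columns) float array.

    Lines beginning with '#' or '@' are headers/commands and skipped; the
    rest must be whitespace-delimited floats with a consistent column
    count.
    """
    if isinstance(path_or_file, (str, os.PathLike)):
        with open(path_or_file) as fh:
            return read_xvg(fh)
    rows = []
    ncol = None
    for lineno, line in enumerate(path_or_file, start=1):
        s = line.strip()
        if not s or s.startswith("#") or s.startswith("@"):
            continue
        fields = s.split()
        try:
            values = [float(v) for v in fields]
        except ValueError as exc:
            raise ValueError(f"xvg line {lineno}: non-numeric field ({exc})") from exc
        if ncol is None:
            ncol = len(values)
        elif len(values) != ncol:
            raise ValueError(
                f"xvg line {lineno}: expected {ncol} columns, got {len(values)}")
        rows.append(values)
    if not rows:
        raise ValueError("xvg file contains no data lines")
    return np.asarray(rows, dtype=float)


def write_xvg(path, data: np.ndarray, comment: str = "") -> None:
    """Write a float array as a minimal xvg file (round-trips read_xvg)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("@    title \"pull\"\n")
        for row in data:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


Mode = Literal["displacement", "absolute"]


def work_integral(trace: ForceTrace,
                  displacement_stop: float = 1.1,
                  mode: Mode = "displacement") -> WorkResult:
    """Trapezoidal work of the pull up to a separation threshold.

    ``displacement`` mode (default) integrates from the trace's initial
    coordinate to initial + ``displacement_stop``; ``absolute`` mode treats
    ``displacement_stop`` as an absolute coordinate value.  The endpoint is
    linearly interpolated; a trace ending short of it is an error — no
    extrapolation.  Negative forces contribute negatively.
    """
    if displacement_stop <= 0 and mode == "displacement":
        raise ValueError("displacement_stop must be positive")
    c = trace.coordinate
    f = trace.force
    d_start = float(c[0])
    d_stop = d_start + displacement_stop if mode == "displacement" else float(displacement_stop)
    if mode == "absolute" and d_stop <= d_start:
        raise ValueError("absolute stop must exceed the initial coordinate")
    if c[-1] < d_stop - 1e-12:
        raise ValueError(
            f"trace ends at {c[-1]:.6g} nm, before the stop at {d_stop:.6g} nm")
    # clip to the window, interpolating force at the exact endpoint
    inside = (c >= d_start) & (c <= d_stop)
    cs = c[inside]
    fs = f[inside]
    if cs.size == 0 or cs[-1] < d_stop - 1e-12:
        f_stop = float(np.interp(d_stop, c, f))
        cs = np.append(cs, d_stop)
        fs = np.append(fs, f_stop)
    work = float(np.trapezoid(fs, cs))
    return WorkResult(work=work, d_start=d_start, d_stop=float(d_stop),
                      n_samples=int(cs.size))


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided comparison of per-replicate works between two groups."""

    works_a: tuple
    works_b: tuple
    difference: float
    t: float
    p: float
    n_a: int
    n_b: int
    test_kind: str

    def summary(self) -> str:
        return (f"group A: n={self.n_a}, mean {np.mean(self.works_a):.4g} kJ/mol\n"
                f"group B: n={self.n_b}, mean {np.mean(self.works_b):.4g} kJ/mol\n"
                f"difference (A-B) = {self.difference:+.4g} kJ/mol, "
                f"t={self.t:.4g}, p={self.p:.4g} (two-sided {self.test_kind})")


def compare_work(works_a: Sequence[float], works_b: Sequence[float],
                 test: str = "student") -> GroupComparison:
    """Compare per-replicate pull works of two groups (e.g. with/without lipid)."""
    a = np.asarray(works_a, dtype=float)
    b = np.asarray(works_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicate works per group")
    res: TwoSampleResult = two_sample_ttest(a, b, kind=test)
    return GroupComparison(tuple(map(float, a)), tuple(map(float, b)),
                           difference=res.delta, t=res.t, p=res.p,
                           n_a=a.size, n_b=b.size, test_kind=test)
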