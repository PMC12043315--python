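"""Plain-text readers and writers for the pipeline's standard inputs.

Formats: two-column whitespace-delimited spectra (m/z ascending,
intensity), delimited contact/distance traces with a one-line header
(columns frame, value), long-format binding-site CSV tables, and optional
mzML via pyteomics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contacts import ContactTrace, DistanceTrace
from .nms import Spectrum
from .sites import BindingSiteRecord, records_from_table, records_to_table

__all__ = [
    "read_spectrum_text",
    "write_spectrum_text",
    "read_spectrum_mzml",
    "read_trace_text",
    "write_trace_text",
    "read_site_table",
    "write_site_table",
]


def read_spectrum_text(path, condition: str = "", replicate: int | None = None) -> Spectrum:
    """Two-column whitespace-delimited text -> Spectrum ('#' lines skipped)."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (m/z, intensity)")
    return Spectrum(data[:, 0], data[:, 1], condition=condition, replicate=replicate)


def write_spectrum_text(path, spectrum: Spectrum) -> None:
    header = "mz intensity"
    np.savetxt(path, np.column_stack([spectrum.mz, spectrum.intensity]),
               fmt="%.6f %.8g", header=header)


def read_spectrum_mzml(path, index: int = 0,
                       condition: str = "", replicate: int | None = None) -> Spectrum:
    """Read one spectrum from an mzML file (requires pyteomics)."""
    from pyteomics import mzml as _mzml

    with _mzml.read(str(path)) as reader:
        for i, entry in enumerate(reader):
            if i == index:
                mz = np.asarray(entry["m/z array"], dtype=float)
                inten = np.asarray(entry["intensity array"], dtype=float)
                order = np.argsort(mz)
                return Spectrum(mz[order], inten[order],
                                condition=condition, replicate=replicate)
    raise IndexError(f"{path}: no spectrum at index {index}")


def read_trace_text(path, dt: float, label: str = "",
                    kind: str = "contact") -> ContactTrace | DistanceTrace:
    """Delimited (frame, value) text with a one-line header -> trace.

    ``kind`` selects a binary :class:`ContactTrace` or a nm-valued
    :class:`DistanceTrace`.
    """
    table = pd.read_csv(path, sep=None, engine="python", comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (frame, value)")
    values = table.iloc[:, 1].to_numpy()
    name = label or str(table.columns[1])
    if kind == "contact":
        return ContactTrace(name, dt, values.astype(int))
    if kind == "distance":
        return DistanceTrace(name, dt, values.astype(float))
    raise ValueError(f"unknown trace kind: {kind!r}")


def write_trace_text(path, trace: ContactTrace | DistanceTrace) -> None:
    values = trace.bound if isinstance(trace, ContactTrace) else trace.distances
    df = pd.DataFrame({"frame": np.arange(len(values)),
                       trace.residue_label or "value": values})
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path) -> list[BindingSiteRecord]:
    """CSV/TSV site table -> records (schema: protein_id, oligomeric_state,
    site_id, residue_position, residue_name; one row per residue)."""
    table = pd.read_csv(path, sep=None, engine="python")
    return records_from_table(table)


def write_site_table(path, records) -> None:
    records_to_table(records).to_csv(path, index=False)
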