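"""Screen lipid binding sites for stabilization-prone geometry.

Cardiolipin sites are annotated as sets of interacting residues.  When two
or more basic residues (Arg/Lys) of one site lie further apart in sequence
than ~30 positions they very likely sit on different transmembrane helices,
the geometry associated with lipid-mediated stabilization; sites spanning
fewer than 10 positions are confined to a single helix or loop.  The
maximum basic-residue sequence distance is therefore a cheap structural
proxy, and over a whole site database its log-scale histogram is bimodal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

__all__ = [
    "BASIC_RESIDUES",
    "BindingSiteRecord",
    "SpanResult",
    "ScreenResult",
    "basic_span",
    "classify_span",
    "screen_database",
    "span_histogram",
    "records_from_table",
    "records_to_table",
]

#: histidine is excluded: cardiolipin fingerprints are built on Arg/Lys
BASIC_RESIDUES = frozenset({"R", "K"})

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
_ONE_LETTER = set(protein_letters_1to3)

SpanClass = Literal["single_helix", "ambiguous", "multi_helix", "undefined"]


def normalize_residue_name(name: str) -> str:
    """One-letter code from a 1- or 3-letter amino-acid name."""
    s = str(name).strip().upper()
    if len(s) == 1 and s in _ONE_LETTER:
        return s
    if len(s) == 3 and s in _THREE_TO_ONE:
        return _THREE_TO_ONE[s]
    raise ValueError(f"unrecognized amino-acid name: {name!r}")


@dataclass(frozen=True)
class BindingSiteRecord:
    """One annotated lipid binding site.

    ``residues`` holds (1-based position, residue name) pairs; names may be
    one- or three-letter codes and are normalized to one-letter.
    """

    protein_id: str
    site_id: str
    residues: tuple
    oligomeric_state: Literal["monomer", "oligomer", "unknown"] = "unknown"

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"site {self.site_id!r} has no residues")
        norm = []
        for pos, name in self.residues:
            pos = int(pos)
            if pos < 1:
                raise ValueError(
                    f"site {self.protein_id}/{self.site_id}: residue position {pos} < 1")
            try:
                norm.append((pos, normalize_residue_name(name)))
            except ValueError as exc:
                raise ValueError(
                    f"site {self.protein_id}/{self.site_id}: {exc}") from exc
        object.__setattr__(self, "residues", tuple(norm))
        if self.oligomeric_state not in ("monomer", "oligomer", "unknown"):
            raise ValueError(f"bad oligomeric_state: {self.oligomeric_state!r}")

    def basic_positions(self, basic_set: frozenset = BASIC_RESIDUES) -> list[int]:
        return [p for p, n in self.residues if n in basic_set]


@dataclass(frozen=True)
class SpanResult:
    protein_id: str
    site_id: str
    n_basic: int
    span: int | None
    span_class: SpanClass


def basic_span(site: BindingSiteRecord,
               basic_set: Iterable[str] = BASIC_RESIDUES,
               single_max: int = 10,
               multi_min: int = 30) -> SpanResult:
    """Maximum sequence distance between basic residues of one site.

    Undefined (span None, class "undefined") when the site holds fewer than
    two basic residues — a single Arg/Lys cannot bridge helices.
    """
    basic_set = frozenset(normalize_residue_name(r) for r in basic_set)
    positions = site.basic_positions(basic_set)
    n_basic = len(positions)
    if n_basic < 2:
        return SpanResult(site.protein_id, site.site_id, n_basic, None, "undefined")
    span = int(max(positions) - min(positions))
    return SpanResult(site.protein_id, site.site_id, n_basic, span,
                      classify_span(span, single_max, multi_min))


def classify_span(span: int, single_max: int = 10, multi_min: int = 30) -> SpanClass:
    """single_helix below ``single_max``, multi_helix above ``multi_min``.

    Spans in between — including exactly ``multi_min`` — are ambiguous.
    """
    if single_max > multi_min:
        raise ValueError("single_max must not exceed multi_min")
    if span < 0:
        raise ValueError("span must be non-negative")
    if span < single_max:
        return "single_helix"
    if span > multi_min:
        return "multi_helix"
    return "ambiguous"


@dataclass(frozen=True)
class ScreenResult:
    """Database screen outcome.

    ``candidates`` are the sites with defined span > ``multi_min`` (after
    any monomer filter), sorted by span descending.  The four counts
    partition the filtered records: below, above, exactly at the threshold,
    and span-undefined.
    """

    candidates: pd.DataFrame
    n_below: int
    n_above: int
    n_ties: int
    n_undefined: int
    multi_min: int
    monomer_only: bool

    @property
    def n_records(self) -> int:
        return self.n_below + self.n_above + self.n_ties + self.n_undefined

    def counts(self) -> dict:
        return {
            "n_below": self.n_below,
            "n_above": self.n_above,
            "n_ties_at_threshold": self.n_ties,
            "n_undefined": self.n_undefined,
            "multi_min": self.multi_min,
            "monomer_only": self.monomer_only,
        }


def screen_database(records: Sequence[BindingSiteRecord],
                    monomer_only: bool = False,
                    multi_min: int = 30,
                    basic_set: Iterable[str] = BASIC_RESIDUES) -> ScreenResult:
    """Rank candidate stabilization-prone sites in a site database.

    Sites at exactly ``multi_min`` are counted separately rather than
    silently binned: a strict less-than / greater-than split leaves them
    unspecified.
    """
    if not records:
        raise ValueError("empty site database")
    if monomer_only:
        records = [r for r in records if r.oligomeric_state == "monomer"]
    rows = []
    n_below = n_above = n_ties = n_undef = 0
    for rec in records:
        res = basic_span(rec, basic_set=basic_set, multi_min=multi_min)
        if res.span is None:
            n_undef += 1
            continue
        if res.span < multi_min:
            n_below += 1
        elif res.span > multi_min:
            n_above += 1
            rows.append({
                "protein_id": rec.protein_id,
                "site_id": rec.site_id,
                "oligomeric_state": rec.oligomeric_state,
                "n_basic": res.n_basic,
                "span": res.span,
            })
        else:
            n_ties += 1
    candidates = pd.DataFrame(
        rows, columns=["protein_id", "site_id", "oligomeric_state", "n_basic", "span"])
    candidates = candidates.sort_values("span", ascending=False, kind="stable",
                                        ignore_index=True)
    return ScreenResult(candidates, n_below, n_above, n_ties, n_undef,
                        multi_min, monomer_only)


def span_histogram(spans: Iterable[int | None],
                   bin_width: float = 0.1) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of log10(span) with deterministic fixed-width bins.

    Returns (bin_edges, counts, n_excluded); zero and undefined spans have
    no logarithm and are excluded but counted.  Edges start at 0.0 so bins
    are comparable across datasets.
    """
    values = [s for s in spans if s is not None and s > 0]
    n_excluded = sum(1 for s in spans if s is None or s <= 0)
    if not values:
        edges = np.arange(0.0, bin_width * 10 + bin_width / 2, bin_width)
        return edges, np.zeros(edges.size - 1, dtype=int), n_excluded
    logs = np.log10(np.asarray(values, dtype=float))
    hi = math.ceil((logs.max() + 1e-9) / bin_width) * bin_width
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(logs, bins=edges)
    return edges, counts.astype(int), n_excluded


def records_from_table(table: pd.DataFrame) -> list[BindingSiteRecord]:
    """Long-format site table -> records.

    Expects columns protein_id, oligomeric_state, site_id, residue_position,
    residue_name; one row per interacting residue.  This is the package's
    canonical schema; external deposits are adapted to it by column renames.
    """
    required = {"protein_id", "oligomeric_state", "site_id",
                "residue_position", "residue_name"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    records = []
    for (protein_id, site_id), grp in table.groupby(["protein_id", "site_id"], sort=False):
        states = set(grp["oligomeric_state"])
        if len(states) > 1:
            raise ValueError(
                f"site {protein_id}/{site_id} has conflicting oligomeric states: {states}")
        records.append(BindingSiteRecord(
            protein_id=str(protein_id),
            site_id=str(site_id),
            residues=tuple(zip(grp["residue_position"].astype(int),
                               grp["residue_name"].astype(str))),
            oligomeric_state=str(next(iter(states))),
        ))
    return records


def records_to_table(records: Sequence[BindingSiteRecord]) -> pd.DataFrame:
    """Records -> long-format site table (inverse of records_from_table)."""
    rows = [
        {"protein_id": r.protein_id, "oligomeric_state": r.oligomeric_state,
         "site_id": r.site_id, "residue_position": pos,
         "residue_name": protein_letters_1to3[name].capitalize()}
        for r in records for pos, name in r.residues
    ]
    return pd.DataFrame(rows, columns=["protein_id", "oligomeric_state", "site_id",
                                       "residue_position", "residue_name"])
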