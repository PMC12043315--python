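"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of raw data the analysis consumes —
coarse-grained lipid-contact series, native mass spectra of ~100 kDa
tetramers carrying 0–3 lipid adducts of ~1.35 kDa, binding-site annotation
tables with a bimodal span distribution, steered-pull force curves with an
additive lipid work contribution, and the paired-condition competition
experiment — and returns the ground truth alongside, so estimator recovery
can be tested quantitatively.

All randomness flows through numpy Generators seeded from the spec's
``seed``; replicate streams are derived by deterministic seed offsetting,
so fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .contacts import ContactTrace
from .masses import CDL_AVERAGE_MASS, mz as _mz
from .nms import Spectrum
from .pull import DEFAULT_PULL_RATE, ForceTrace
from .sites import BindingSiteRecord

__all__ = [
    "BindingKineticsParams",
    "TwoSiteKineticsParams",
    "SpectrumSpecies",
    "SpectrumSpec",
    "SiteTableSpec",
    "ForceSimParams",
    "CompetitionSpecies",
    "CompetitionSpec",
    "sim_contact_trace",
    "sim_two_site_trace",
    "sim_spectrum",
    "sim_site_table",
    "sim_force_traces",
    "sim_competition_experiment",
]


def _rng(*seed_parts) -> np.random.Generator:
    """Deterministic per-task stream from a base seed plus integer offsets."""
    return np.random.default_rng([int(abs(p)) for p in seed_parts])


# ---------------------------------------------------------------------------
# two-state and two-site binding kinetics


@dataclass(frozen=True)
class BindingKineticsParams:
    """Two-state (bound/unbound) binding kinetics at frame resolution.

    Rates are per ns; the discrete chain uses per-frame transition
    probabilities 1 - exp(-k dt), exact for exponential dwell sampling at
    frame resolution.  Stationary occupancy is k_on / (k_on + k_off) and
    the mean bound dwell 1/k_off (dt / (1 - exp(-k_off dt)) in frames).
    """

    k_on: float
    k_off: float
    dt: float = 1.0
    n_frames: int = 100_000
    seed: int = 0
    residue_label: str = "residue"

    def __post_init__(self):
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("k_on and k_off must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def stationary_occupancy(self) -> float:
        return self.k_on / (self.k_on + self.k_off)

    @property
    def mean_dwell_frames(self) -> float:
        """Expected bound-run length in frames (geometric mean dwell)."""
        return 1.0 / (1.0 - np.exp(-self.k_off * self.dt))


def _alternating_chain(p_exit: Sequence[float], n_frames: int,
                       rng: np.random.Generator, start_state: int = 0) -> np.ndarray:
    """Simulate an alternating two-state chain by geometric dwell sampling."""
    states = np.empty(n_frames, dtype=np.int8)
    t = 0
    state = start_state
    while t < n_frames:
        p = p_exit[state]
        run = n_frames - t if p <= 0 else int(rng.geometric(p))
        run = min(run, n_frames - t)
        states[t:t + run] = state
        t += run
        state = 1 - state
    return states


def sim_contact_trace(params: BindingKineticsParams) -> ContactTrace:
    """Binary contact series from the two-state Markov chain.

    The chain starts unbound (a lipid approaching from bulk) and flips with
    per-frame probabilities 1 - exp(-k dt).
    """
    p_on = 1.0 - np.exp(-params.k_on * params.dt)
    p_off = 1.0 - np.exp(-params.k_off * params.dt)
    rng = _rng(params.seed)
    bound = _alternating_chain((p_on, p_off), params.n_frames, rng, start_state=0)
    return ContactTrace(params.residue_label, params.dt, bound)


@dataclass(frozen=True)
class TwoSiteKineticsParams:
    """Three-state kinetics: unbound, site 1, site 2, with inter-site hops.

    Emulates one lipid exchanging between two overlapping sites: at most
    one site is occupied per frame.  All rates per ns; at least one entry
    rate must be positive.
    """

    k_on_site1: float
    k_on_site2: float
    k_off_site1: float
    k_off_site2: float
    k_hop_12: float = 0.0
    k_hop_21: float = 0.0
    dt: float = 1.0
    n_frames: int = 100_000
    seed: int = 0

    def __post_init__(self):
        rates = (self.k_on_site1, self.k_on_site2, self.k_off_site1,
                 self.k_off_site2, self.k_hop_12, self.k_hop_21)
        if any(r < 0 for r in rates):
            raise ValueError("all rates must be non-negative")
        if self.k_on_site1 == 0 and self.k_on_site2 == 0:
            raise ValueError("at least one entry rate must be positive")
        if self.dt <= 0 or self.n_frames < 1:
            raise ValueError("dt must be positive and n_frames >= 1")

    def transition_matrix(self) -> np.ndarray:
        """Per-frame transition matrix (states: unbound, site1, site2).

        Competing exits from a state share one exponential exit step of
        total rate k_tot (exit probability 1 - exp(-k_tot dt)) and split
        it in proportion to their rates; this reduces to the two-state
        1 - exp(-k dt) rule when a state has a single exit.
        """
        out = np.array([
            [0.0, self.k_on_site1, self.k_on_site2],
            [self.k_off_site1, 0.0, self.k_hop_12],
            [self.k_off_site2, self.k_hop_21, 0.0],
        ])
        P = np.zeros((3, 3))
        for s in range(3):
            k_tot = out[s].sum()
            if k_tot == 0:
                P[s, s] = 1.0
                continue
            p_exit = 1.0 - np.exp(-k_tot * self.dt)
            P[s] = p_exit * out[s] / k_tot
            P[s, s] = 1.0 - p_exit
        return P


def sim_two_site_trace(params: TwoSiteKineticsParams) -> tuple[ContactTrace, ContactTrace]:
    """Indicator traces for site 1 and site 2 of the three-state chain."""
    P = params.transition_matrix()
    rng = _rng(params.seed)
    states = np.empty(params.n_frames, dtype=np.int8)
    state = 0  # start unbound
    # dwell-based simulation: geometric dwell in each state, then jump
    jump_p = []
    for s in range(3):
        stay = P[s, s]
        others = np.array([P[s, j] for j in range(3) if j != s])
        total = others.sum()
        jump_p.append((1.0 - stay, others / total if total > 0 else None,
                       [j for j in range(3) if j != s]))
    t = 0
    while t < params.n_frames:
        p_exit, probs, targets = jump_p[state]
        run = params.n_frames - t if p_exit <= 0 else int(rng.geometric(p_exit))
        run = min(run, params.n_frames - t)
        states[t:t + run] = state
        t += run
        if t < params.n_frames:
            state = int(rng.choice(targets, p=probs))
    site1 = ContactTrace("site1", params.dt, (states == 1).astype(np.int8))
    site2 = ContactTrace("site2", params.dt, (states == 2).astype(np.int8))
    return site1, site2


# ---------------------------------------------------------------------------
# native mass spectra


@dataclass(frozen=True)
class SpectrumSpecies:
    """One protein species in a simulated spectrum."""

    name: str
    base_mass: float
    charge_states: tuple
    abundance: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "charge_states",
                           tuple(int(z) for z in self.charge_states))
        if self.base_mass <= 0:
            raise ValueError("base_mass must be positive")
        if not self.charge_states or any(z < 1 for z in self.charge_states):
            raise ValueError("charge states must be positive integers")
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


@dataclass(frozen=True)
class SpectrumSpec:
    """Recipe for a synthetic native spectrum.

    Adduct counts are binomial(n_max_adducts, p_bind) — n_max independent
    lipid slots each occupied with probability p_bind.  Peaks are Gaussian
    envelopes (native peaks of 100 kDa complexes are envelope-limited, not
    isotope-resolved) whose *area* equals the species weight, plus additive
    Gaussian intensity noise clipped at zero, with sd = noise_sd x the
    tallest peak amplitude.
    """

    species: tuple
    adduct_mass: float = CDL_AVERAGE_MASS
    n_max_adducts: int = 3
    p_bind: float = 0.3
    peak_sigma: float = 1.5
    noise_sd: float = 0.01
    mz_min: float = 4000.0
    mz_max: float = 7000.0
    mz_step: float = 0.5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        if not self.species:
            raise ValueError("need at least one species")
        if not 0.0 <= self.p_bind <= 1.0:
            raise ValueError("p_bind must lie in [0, 1]")
        if self.adduct_mass <= 0 or self.peak_sigma <= 0:
            raise ValueError("adduct_mass and peak_sigma must be positive")
        if self.n_max_adducts < 0 or self.noise_sd < 0:
            raise ValueError("n_max_adducts and noise_sd must be non-negative")
        if not self.mz_min < self.mz_max or self.mz_step <= 0:
            raise ValueError("need mz_min < mz_max and mz_step > 0")


def _add_gaussian(grid: np.ndarray, intensity: np.ndarray,
                  center: float, sigma: float, area: float) -> None:
    """Add a Gaussian of given integrated area onto the intensity grid."""
    lo = np.searchsorted(grid, center - 8 * sigma)
    hi = np.searchsorted(grid, center + 8 * sigma)
    if hi <= lo:
        return
    g = grid[lo:hi]
    intensity[lo:hi] += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((g - center) / sigma) ** 2)


def sim_spectrum(spec: SpectrumSpec,
                 condition: str = "", replicate: int | None = None,
                 _abundance_scale: dict | None = None,
                 _seed_parts: tuple = ()) -> tuple[Spectrum, pd.DataFrame]:
    """Synthetic spectrum plus its ground-truth peak table.

    The truth table has one row per (species, charge, adduct count) with
    the noise-free integrated intensity; per species these sum to the
    species abundance.
    """
    grid = np.arange(spec.mz_min, spec.mz_max + spec.mz_step / 2, spec.mz_step)
    if np.any(np.diff(grid) <= 0):
        raise RuntimeError("internal error: m/z grid not strictly ascending")
    intensity = np.zeros_like(grid)
    pmf = binom.pmf(np.arange(spec.n_max_adducts + 1), spec.n_max_adducts, spec.p_bind)
    rows = []
    for sp in spec.species:
        scale = 1.0 if _abundance_scale is None else _abundance_scale.get(sp.name, 1.0)
        per_charge = sp.abundance * scale / len(sp.charge_states)
        for z in sp.charge_states:
            for n in range(spec.n_max_adducts + 1):
                if pmf[n] == 0.0:
                    continue
                center = _mz(sp.base_mass + n * spec.adduct_mass, z)
                weight = per_charge * pmf[n]
                in_window = spec.mz_min <= center <= spec.mz_max
                if in_window:
                    _add_gaussian(grid, intensity, center, spec.peak_sigma, weight)
                rows.append({"species": sp.name, "charge": z, "n_adducts": n,
                             "mz": center, "intensity": weight,
                             "in_window": in_window})
    if spec.noise_sd > 0:
        rng = _rng(spec.seed, *_seed_parts)
        amp_max = intensity.max() if intensity.max() > 0 else 1.0
        intensity = intensity + rng.normal(0.0, spec.noise_sd * amp_max, grid.size)
        np.clip(intensity, 0.0, None, out=intensity)
    truth = pd.DataFrame(rows, columns=["species", "charge", "n_adducts",
                                        "mz", "intensity", "in_window"])
    return Spectrum(grid, intensity, condition=condition, replicate=replicate), truth


# ---------------------------------------------------------------------------
# binding-site tables


@dataclass(frozen=True)
class SiteTableSpec:
    """Recipe for a synthetic binding-site database.

    Basic-residue spans are drawn from a two-component log-normal mixture —
    a single-helix population (short spans) and a multi-helix population
    (long spans) — giving the bimodal distribution seen in real site
    databases.  Class counts are allocated by stratification
    (round(n_sites x fraction_multi) multi-helix sites, the rest
    single-helix) so the expected composition is hit exactly; the default
    composition emulates a 255-site screen splitting 75 / 180 at the
    30-position boundary.
    """

    n_sites: int = 255
    fraction_multi: float = 180 / 255
    single_log_mu: float = float(np.log(5.0))
    single_log_sigma: float = 0.35
    multi_log_mu: float = float(np.log(70.0))
    multi_log_sigma: float = 0.25
    fraction_monomeric: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for frac in (self.fraction_multi, self.fraction_monomeric):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.single_log_sigma <= 0 or self.multi_log_sigma <= 0:
            raise ValueError("log-normal scales must be positive")


_BASIC = ("R", "K")
_AROMATIC = ("W", "Y")


def sim_site_table(spec: SiteTableSpec) -> tuple[list[BindingSiteRecord], pd.DataFrame]:
    """Synthetic site records plus ground-truth class labels.

    Each site carries two basic residues placed exactly its drawn span
    apart (occasionally a third in between, which cannot change the
    maximum) and one or two nearby aromatic residues.
    """
    rng = _rng(spec.seed)
    n_multi = int(round(spec.n_sites * spec.fraction_multi))
    labels = np.array(["multi_helix"] * n_multi
                      + ["single_helix"] * (spec.n_sites - n_multi))
    rng.shuffle(labels)
    records = []
    truth_rows = []
    for i, label in enumerate(labels):
        if label == "multi_helix":
            span = rng.lognormal(spec.multi_log_mu, spec.multi_log_sigma)
        else:
            span = rng.lognormal(spec.single_log_mu, spec.single_log_sigma)
        span = max(1, int(round(span)))
        p0 = int(rng.integers(5, 401))
        residues = [(p0, rng.choice(_BASIC)), (p0 + span, rng.choice(_BASIC))]
        if span > 2 and rng.random() < 0.5:  # optional interior basic residue
            residues.append((int(rng.integers(p0 + 1, p0 + span)), rng.choice(_BASIC)))
        for offset in (2, 3):
            if rng.random() < 0.6:
                residues.append((p0 + span + offset, rng.choice(_AROMATIC)))
        state = "monomer" if rng.random() < spec.fraction_monomeric else "oligomer"
        protein_id = f"SYNP{i:04d}"
        site_id = f"site{i:04d}"
        records.append(BindingSiteRecord(
            protein_id=protein_id, site_id=site_id,
            residues=tuple(residues), oligomeric_state=state))
        truth_rows.append({"protein_id": protein_id, "site_id": site_id,
                           "true_class": label, "true_span": span,
                           "oligomeric_state": state})
    truth = pd.DataFrame(truth_rows)
    return records, truth


# ---------------------------------------------------------------------------
# steered-pull force traces


@dataclass(frozen=True)
class ForceSimParams:
    """Recipe for synthetic pull force–extension traces.

    The deterministic backbone is a harmonic ramp F = k d up to the rupture
    displacement, then an exponential decay; a bound lipid adds a constant
    extra force lipid_work_bonus / rupture_displacement over the
    pre-rupture window, contributing exactly that much extra work.  Default
    stiffness and pull rate follow common steered-pull practice for
    gas-phase subunit separation (k = 1000 kJ/mol/nm^2, 0.1125 nm/ns).
    """

    k: float = 1000.0
    rupture_displacement: float = 1.1
    lipid_work_bonus: float = 0.0
    noise_sd: float = 25.0
    pull_rate: float = DEFAULT_PULL_RATE
    dt: float = 0.01
    overshoot: float = 1.25
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.k <= 0 or self.rupture_displacement <= 0:
            raise ValueError("k and rupture_displacement must be positive")
        if self.noise_sd < 0 or self.pull_rate <= 0 or self.dt <= 0:
            raise ValueError("noise_sd must be >= 0; pull_rate and dt positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.overshoot <= 1.0:
            raise ValueError("overshoot must exceed 1 so the rupture point is covered")


def sim_force_traces(params: ForceSimParams, with_lipid: bool = False) -> list[ForceTrace]:
    """Replicate force traces, optionally with the lipid work contribution.

    Replicate RNG streams are derived from (seed, condition, replicate), so
    the two conditions are independent yet each fully reproducible.
    """
    d_rupture = params.rupture_displacement
    dd = params.pull_rate * params.dt
    coord = np.arange(0.0, params.overshoot * d_rupture + dd / 2, dd)
    # place a sample exactly at the rupture kink so the piecewise-linear
    # trace represents the force profile without discretization error there
    coord = np.unique(np.append(coord, d_rupture))
    ramp = np.where(coord <= d_rupture,
                    params.k * coord,
                    params.k * d_rupture * np.exp(-(coord - d_rupture) / (0.05 * d_rupture)))
    if with_lipid and params.lipid_work_bonus != 0.0:
        ramp = ramp + np.where(coord <= d_rupture,
                               params.lipid_work_bonus / d_rupture, 0.0)
    traces = []
    for rep in range(params.n_replicates):
        rng = _rng(params.seed, 1 if with_lipid else 0, rep)
        noise = rng.normal(0.0, params.noise_sd, coord.size) if params.noise_sd > 0 else 0.0
        label = f"{'lipid' if with_lipid else 'apo'}_rep{rep}"
        traces.append(ForceTrace(coord, ramp + noise, label=label))
    return traces


# ---------------------------------------------------------------------------
# competition experiment


@dataclass(frozen=True)
class CompetitionSpecies:
    """One variant in the competitive stabilization assay."""

    name: str
    tetramer_mass: float
    monomer_mass: float
    tetramer_charges: tuple = (16, 17, 18)
    monomer_charges: tuple = (10, 11, 12)

    def __post_init__(self):
        object.__setattr__(self, "tetramer_charges",
                           tuple(int(z) for z in self.tetramer_charges))
        object.__setattr__(self, "monomer_charges",
                           tuple(int(z) for z in self.monomer_charges))
        if self.tetramer_mass <= 0 or self.monomer_mass <= 0:
            raise ValueError("species masses must be positive")


def _default_test_species() -> CompetitionSpecies:
    return CompetitionSpecies("variant", 100400.0, 25100.0)


def _default_ref_species() -> CompetitionSpecies:
    return CompetitionSpecies("reference", 99600.0, 24900.0)


@dataclass(frozen=True)
class CompetitionSpec:
    """Recipe for the paired-condition competition experiment.

    ``*_frac_*`` are the dissociated fractions — the share of each species'
    tetramer signal converted into ejected unfolded monomer at the working
    collision energy — per lipid condition.  Monomer peak intensity is
    proportional to the species' dissociated fraction; each (replicate,
    condition, species) gets an independent multiplicative log-normal
    factor emulating run-to-run intensity variation, on top of additive
    grid noise.  Defaults: both variants 30% dissociated without lipid;
    lipid halves the reference's dissociation (reference stabilized more),
    four replicates per condition.
    """

    test_species: CompetitionSpecies = field(default_factory=_default_test_species)
    ref_species: CompetitionSpecies = field(default_factory=_default_ref_species)
    test_frac_no_lipid: float = 0.30
    test_frac_with_lipid: float = 0.30
    ref_frac_no_lipid: float = 0.30
    ref_frac_with_lipid: float = 0.15
    n_replicates: int = 4
    peak_sigma: float = 2.0
    noise_sd: float = 0.01
    replicate_noise_sd: float = 0.05
    mz_min: float = 1500.0
    mz_max: float = 7000.0
    mz_step: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for f in (self.test_frac_no_lipid, self.test_frac_with_lipid,
                  self.ref_frac_no_lipid, self.ref_frac_with_lipid):
            if not 0.0 <= f <= 1.0:
                raise ValueError("dissociated fractions must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.peak_sigma <= 0 or self.noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ValueError("bad noise parameters")

    def fractions(self, condition: str) -> tuple[float, float]:
        """(test, reference) dissociated fractions for a condition."""
        if condition == "no_lipid":
            return self.test_frac_no_lipid, self.ref_frac_no_lipid
        if condition == "with_lipid":
            return self.test_frac_with_lipid, self.ref_frac_with_lipid
        raise KeyError(condition)

    def true_ratio(self, condition: str) -> float:
        ft, fr = self.fractions(condition)
        return ft / (ft + fr) if ft + fr > 0 else float("nan")

    @property
    def true_delta(self) -> float:
        return self.true_ratio("with_lipid") - self.true_ratio("no_lipid")


CONDITIONS = ("no_lipid", "with_lipid")


def _collision_warning(spec: CompetitionSpec) -> bool:
    """True when any peaks of the two species fall within 3 peak sigmas."""
    def centers(sp: CompetitionSpecies):
        return ([_mz(sp.tetramer_mass, z) for z in sp.tetramer_charges]
                + [_mz(sp.monomer_mass, z) for z in sp.monomer_charges])

    a = np.array(centers(spec.test_species))
    b = np.array(centers(spec.ref_species))
    return bool(np.min(np.abs(a[:, None] - b[None, :])) < 3 * spec.peak_sigma)


def sim_competition_experiment(spec: CompetitionSpec
                               ) -> tuple[dict, dict]:
    """Spectra for every (condition, replicate) plus the ground truth.

    Returns ``(spectra, truth)`` where ``spectra[(condition, rep)]`` is a
    :class:`~lipidstab.nms.Spectrum` containing tetramer and monomer peaks
    of both species, and ``truth`` holds the noise-free per-condition
    ratios, the true stabilization delta, a per-spectrum intensity table,
    and a mass-collision warning flag.
    """
    warn = _collision_warning(spec)
    spectra: dict = {}
    rows = []
    for condition in CONDITIONS:
        frac_test, frac_ref = spec.fractions(condition)
        for rep in range(spec.n_replicates):
            rng = _rng(spec.seed, CONDITIONS.index(condition), rep)
            grid = np.arange(spec.mz_min, spec.mz_max + spec.mz_step / 2, spec.mz_step)
            intensity = np.zeros_like(grid)
            for sp, frac in ((spec.test_species, frac_test),
                             (spec.ref_species, frac_ref)):
                factor_mono = float(np.exp(rng.normal(0.0, spec.replicate_noise_sd)))
                factor_tet = float(np.exp(rng.normal(0.0, spec.replicate_noise_sd)))
                mono_total = frac * factor_mono
                tet_total = (1.0 - frac) * factor_tet
                for z in sp.monomer_charges:
                    _add_gaussian(grid, intensity, _mz(sp.monomer_mass, z),
                                  spec.peak_sigma, mono_total / len(sp.monomer_charges))
                for z in sp.tetramer_charges:
                    _add_gaussian(grid, intensity, _mz(sp.tetramer_mass, z),
                                  spec.peak_sigma, tet_total / len(sp.tetramer_charges))
                rows.append({"condition": condition, "replicate": rep,
                             "species": sp.name, "dissociated_fraction": frac,
                             "monomer_intensity": mono_total,
                             "tetramer_intensity": tet_total})
            if spec.noise_sd > 0:
                amp = intensity.max() if intensity.max() > 0 else 1.0
                intensity = intensity + rng.normal(0.0, spec.noise_sd * amp, grid.size)
                np.clip(intensity, 0.0, None, out=intensity)
            spectra[(condition, rep)] = Spectrum(grid, intensity,
                                                 condition=condition, replicate=rep)
    truth = {
        "true_ratio_no_lipid": spec.true_ratio("no_lipid"),
        "true_ratio_with_lipid": spec.true_ratio("with_lipid"),
        "true_delta": spec.true_delta,
        "collision_warning": warn,
        "table": pd.DataFrame(rows),
    }
    return spectra, truth
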