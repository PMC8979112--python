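"""Synthetic pharmacokinetic / LC-MS data generator.

Emulates the statistical structure the pooled-AUC screening workflow
assumes: one-compartment oral parent compounds, first-order phase-II
metabolites (glucuronides / sulfates) with species-specific formation
preferences, a multiplicative log-normal assay-noise model with LLOQ
censoring, triplicate pooled measurements on the 12-point clinical
sampling schedule, and Gaussian chromatographic peaks for testing the EIC
quantifier. All defaults are explicitly synthetic: the study this mirrors
deposits no concentrations or rate constants.

All randomness flows through explicit integer seeds via
``numpy.random.SeedSequence``; no global state is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .auc import ConcentrationProfile, pool_concentration
from .errors import ValidationError
from .pooling import PoolingDesign, SamplingSchedule, pooling_volumes

#: Clinical sampling times (hours) used throughout as the default schedule.
DEFAULT_TIMES_H = (0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0)
#: Default total pooled plasma volume (μL).
DEFAULT_TOTAL_VOLUME_UL = 480.0

Pathway = Literal["glucuronidation", "sulfation", "oxidation", "other"]


@dataclass(frozen=True)
class PKParameters:
    """One-compartment oral-dose kinetics.

    dose in arbitrary amount units; F oral bioavailability; ka/ke first-order
    absorption/elimination rates (1/h); V apparent volume of distribution.
    """

    dose: float
    F: float
    ka: float
    ke: float
    V: float

    def __post_init__(self):
        if min(self.dose, self.ka, self.ke, self.V) < 0 or self.ka == 0 or self.ke == 0 or self.V == 0:
            raise ValidationError("dose must be >= 0; ka, ke, V must be > 0")
        if not (0 < self.F <= 1):
            raise ValidationError("bioavailability F must be in (0, 1]")
        if np.isclose(self.ka, self.ke, rtol=1e-9):
            raise ValidationError("ka must differ from ke (flip-flop limit unsupported)")


@dataclass(frozen=True)
class MetaboliteSpec:
    """First-order formation of a phase-II metabolite from its parent."""

    parent_id: str
    metabolite_id: str
    pathway: Pathway
    fraction: float
    km: float

    def __post_init__(self):
        if not (0 <= self.fraction <= 1):
            raise ValidationError("formation fraction must be in [0, 1]")
        if self.km <= 0:
            raise ValidationError("metabolite elimination rate km must be > 0")


@dataclass(frozen=True)
class AssayModel:
    """LC-MS response model: area = response_factor × concentration × noise.

    Noise is multiplicative log-normal with the stated coefficient of
    variation; measurements whose implied concentration falls below ``lloq``
    are flagged and zeroed. If ``is_area`` is set, areas are reported as
    internal-standard ratios.
    """

    response_factors: Mapping[str, float] = field(default_factory=dict)
    default_factor: float = 1.0
    cv: float = 0.0
    lloq: float = 0.0
    is_area: float | None = None

    def __post_init__(self):
        if self.default_factor <= 0 or any(v <= 0 for v in self.response_factors.values()):
            raise ValidationError("response factors must be > 0")
        if self.cv < 0:
            raise ValidationError("noise CV must be >= 0")
        if self.lloq < 0:
            raise ValidationError("LLOQ must be >= 0")
        if self.is_area is not None and self.is_area <= 0:
            raise ValidationError("internal-standard area must be > 0")

    def factor_for(self, compound_id: str) -> float:
        return self.response_factors.get(compound_id, self.default_factor)


@dataclass(frozen=True)
class CentroidSpectrum:
    """A centroided mass spectrum at one retention time (minutes)."""

    retention_time: float
    mz: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self):
        if self.retention_time < 0:
            raise ValidationError("retention time must be >= 0")
        if len(self.mz) != len(self.intensity):
            raise ValidationError("mz and intensity must have equal length")
        if any(m <= 0 for m in self.mz) or any(i < 0 for i in self.intensity):
            raise ValidationError("mz must be > 0 and intensities >= 0")


# ---------------------------------------------------------------------------
# Kinetic profiles
# ---------------------------------------------------------------------------

def simulate_parent(params: PKParameters, times: Sequence[float]) -> ConcentrationProfile:
    """Plasma concentration of an orally dosed parent compound.

    C(t) = F·D·ka / (V·(ka−ke)) × (exp(−ke·t) − exp(−ka·t)); zero at t = 0,
    single-peaked, with AUC(0,∞) = F·D/(V·ke).
    """
    t = np.asarray(list(times), dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    a = params.F * params.dose * params.ka / (params.V * (params.ka - params.ke))
    c = a * (np.exp(-params.ke * t) - np.exp(-params.ka * t))
    c = np.maximum(c, 0.0)
    return ConcentrationProfile(
        compound_id="parent", times=tuple(t), values=tuple(float(x) for x in c)
    )


def _metabolite_conc(
    parent: PKParameters, spec: MetaboliteSpec, t: np.ndarray
) -> np.ndarray:
    """Catenary (Bateman-type) metabolite concentration at times t.

    Formation rate is fraction × ke × (parent amount); elimination is km.
    Uses the three-exponential closed form when all rates are distinct and
    falls back to numerical integration of the linear system near rate
    degeneracies (never silent NaN).
    """
    ka, ke, km = parent.ka, parent.ke, spec.km
    scale = spec.fraction * ke * parent.F * parent.dose * ka / (ka - ke)
    rates_ok = not (
        np.isclose(km, ke, rtol=1e-6) or np.isclose(km, ka, rtol=1e-6)
    )
    if rates_ok:
        term_ke = (np.exp(-ke * t) - np.exp(-km * t)) / (km - ke)
        term_ka = (np.exp(-ka * t) - np.exp(-km * t)) / (km - ka)
        amount = scale * (term_ke - term_ka)
    else:
        # dA_g/dt = -ka*A_g ; dA_p/dt = ka*A_g - ke*A_p ;
        # dA_m/dt = fraction*ke*A_p - km*A_m
        def rhs(_t, y):
            ag, ap, am = y
            return [-ka * ag, ka * ag - ke * ap, spec.fraction * ke * ap - km * am]

        sol = solve_ivp(
            rhs,
            (0.0, float(t[-1]) if len(t) else 0.0),
            [parent.F * parent.dose, 0.0, 0.0],
            t_eval=t,
            rtol=1e-10,
            atol=1e-12,
            method="LSODA",
        )
        if not sol.success:
            raise RuntimeError(f"metabolite ODE integration failed: {sol.message}")
        amount = sol.y[2]
    return np.maximum(amount, 0.0) / parent.V


def simulate_metabolite(
    parent_params: PKParameters, spec: MetaboliteSpec, times: Sequence[float]
) -> ConcentrationProfile:
    """Plasma concentration of a metabolite formed first-order from its parent.

    Under this linear model the metabolite AUC(0,∞) equals
    fraction × parent AUC(0,∞) × ke/km.
    """
    t = np.asarray(list(times), dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    c = _metabolite_conc(parent_params, spec, t)
    return ConcentrationProfile(
        compound_id=spec.metabolite_id,
        times=tuple(t),
        values=tuple(float(x) for x in c),
    )


# ---------------------------------------------------------------------------
# Assay model
# ---------------------------------------------------------------------------

def _lognormal_factors(cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative log-normal factors with coefficient of
    variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def apply_assay(
    profile: ConcentrationProfile, assay: AssayModel, seed: int
) -> ConcentrationProfile:
    """Convert a concentration profile to measured peak areas.

    Same seed → identical output. Points whose measured concentration falls
    below the LLOQ are flagged and zeroed.
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(profile.values, dtype=float)
    factor = assay.factor_for(profile.compound_id)
    noisy_conc = conc * _lognormal_factors(assay.cv, len(conc), rng)
    flags = noisy_conc < assay.lloq
    area = factor * np.where(flags, 0.0, noisy_conc)
    if assay.is_area is not None:
        area = area / assay.is_area
        unit = "area ratio"
    else:
        unit = "area"
    return ConcentrationProfile(
        compound_id=profile.compound_id,
        times=profile.times,
        values=tuple(float(x) for x in area),
        unit_label=unit,
        below_lloq=tuple(bool(f) for f in flags),
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundPanel:
    """Parents plus their metabolites, with per-species pathway scaling.

    ``species_pathway_scale[species][pathway]`` multiplies the formation
    fraction of metabolites of that pathway in that species (the mechanism
    by which, e.g., sulfation dominates in humans while glucuronidation
    dominates in rodents).
    """

    parents: Mapping[str, PKParameters]
    metabolites: tuple[MetaboliteSpec, ...]
    species_pathway_scale: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        if not self.parents:
            raise ValidationError("panel needs at least one parent compound")
        for m in self.metabolites:
            if m.parent_id not in self.parents:
                raise ValidationError(f"unknown parent '{m.parent_id}' for {m.metabolite_id}")

    def compound_ids(self) -> list[str]:
        return list(self.parents) + [m.metabolite_id for m in self.metabolites]

    def scaled_fraction(self, m: MetaboliteSpec, species: str) -> float:
        scale = self.species_pathway_scale.get(species, {}).get(m.pathway, 1.0)
        return m.fraction * scale

    def validate_for_species(self, species: Iterable[str]) -> None:
        for sp in species:
            for pid in self.parents:
                total = sum(
                    self.scaled_fraction(m, sp)
                    for m in self.metabolites
                    if m.parent_id == pid
                )
                if total > 1 + 1e-12:
                    raise ValidationError(
                        f"pathway fractions for parent '{pid}' in species '{sp}' "
                        f"sum to {total:g} > 1"
                    )

    def species_profiles(
        self, species: str, times: Sequence[float]
    ) -> dict[str, ConcentrationProfile]:
        """Noise-free concentration profiles of every panel compound."""
        out: dict[str, ConcentrationProfile] = {}
        for pid, params in self.parents.items():
            prof = simulate_parent(params, times)
            out[pid] = ConcentrationProfile(
                compound_id=pid, times=prof.times, values=prof.values
            )
        for m in self.metabolites:
            spec = MetaboliteSpec(
                parent_id=m.parent_id,
                metabolite_id=m.metabolite_id,
                pathway=m.pathway,
                fraction=self.scaled_fraction(m, species),
                km=m.km,
            )
            out[m.metabolite_id] = simulate_metabolite(
                self.parents[m.parent_id], spec, times
            )
        return out


def default_panel() -> CompoundPanel:
    """Synthetic 10-compound panel: 2 anthraquinone-like parents and 8
    phase-II metabolites over human/rat/mouse.

    Parameter values are invented. The first parent is given the largest
    dose·F/V so that, like rhein in the clinical study, it dominates total
    exposure; the pathway scaling makes sulfation dominant in humans and
    glucuronidation dominant in rodents.
    """
    parents = {
        "P1": PKParameters(dose=100.0, F=0.9, ka=1.0, ke=0.10, V=10.0),
        "P2": PKParameters(dose=50.0, F=0.6, ka=1.5, ke=0.25, V=15.0),
    }
    mets = (
        MetaboliteSpec("P1", "P1-sulfate", "sulfation", 0.30, 0.20),
        MetaboliteSpec("P1", "P1-glucuronide", "glucuronidation", 0.30, 0.30),
        MetaboliteSpec("P1", "P1-oxide", "oxidation", 0.15, 0.15),
        MetaboliteSpec("P2", "P2-sulfate", "sulfation", 0.35, 0.25),
        MetaboliteSpec("P2", "P2-glucuronide", "glucuronidation", 0.35, 0.35),
        MetaboliteSpec("P2", "P2-oxide", "oxidation", 0.10, 0.20),
        MetaboliteSpec("P1", "P1-diglucuronide", "glucuronidation", 0.10, 0.40),
        MetaboliteSpec("P2", "P2-disulfate", "sulfation", 0.10, 0.30),
    )
    scale = {
        "human": {"sulfation": 1.5, "glucuronidation": 0.5},
        "rat": {"sulfation": 0.5, "glucuronidation": 1.5},
        "mouse": {"sulfation": 0.6, "glucuronidation": 1.4},
    }
    return CompoundPanel(parents=parents, metabolites=mets, species_pathway_scale=scale)


def simulate_cohort(
    species: Sequence[str],
    panel: CompoundPanel,
    schedule: SamplingSchedule,
    assay: AssayModel,
    replicates: int,
    seed: int,
    design: PoolingDesign | None = None,
):
    """Simulate pooled peak-area measurements for a cohort.

    For every compound × species × replicate, the true serial profile is
    pooled with the (exact, unless given) Hamilton design and the pooled
    concentration is measured once through the assay model. Returns a
    ``PeakAreaMatrix``; identical seeds give byte-identical tables.
    """
    from .io import PeakAreaMatrix  # local import: io depends on types here
    import pandas as pd

    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if not panel.compound_ids():
        raise ValidationError("empty compound panel")
    panel.validate_for_species(species)
    if design is None:
        design = pooling_volumes(schedule, DEFAULT_TOTAL_VOLUME_UL, rounding_increment=0.0)

    root = np.random.SeedSequence(seed)
    rows = []
    for sp_i, sp in enumerate(species):
        profiles = panel.species_profiles(sp, schedule.times)
        for c_i, cid in enumerate(panel.compound_ids()):
            pooled_true = pool_concentration(profiles[cid], design)
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(sp_i, c_i)
            )
            rng = np.random.default_rng(child)
            factors = _lognormal_factors(assay.cv, replicates, rng)
            for rep in range(replicates):
                measured = pooled_true * factors[rep]
                flagged = measured < assay.lloq
                area = 0.0 if flagged else assay.factor_for(cid) * measured
                if assay.is_area is not None:
                    area /= assay.is_area
                rows.append(
                    {
                        "compound_id": cid,
                        "species": sp,
                        "replicate": rep + 1,
                        "area": area,
                        "below_lloq": flagged,
                    }
                )
    return PeakAreaMatrix(pd.DataFrame(rows))


def pooled_vs_serial_trial(
    params: PKParameters,
    schedule: SamplingSchedule,
    cv: float,
    replicates: int,
    n_cohorts: int,
    seed: int,
    design: PoolingDesign | None = None,
) -> np.ndarray:
    """Percent differences between the pooled and serial-trapezoid AUC
    estimates over independently seeded cohorts.

    In each cohort the serial method measures every time point with
    multiplicative CV noise (``replicates`` independent profiles, trapezoid
    AUC averaged), while the pooled method mixes the true plasma exactly and
    measures the pooled concentration once per replicate. The two estimates
    therefore carry independent analytical noise, as they do on the bench.
    """
    from .auc import pooled_auc, trapezoid_auc

    if design is None:
        design = pooling_volumes(schedule, DEFAULT_TOTAL_VOLUME_UL, rounding_increment=0.0)
    truth = simulate_parent(params, schedule.times)
    pooled_true = pool_concentration(truth, design)
    n_t = len(schedule.times)
    root = np.random.SeedSequence(seed)
    diffs = np.empty(n_cohorts)
    for i, child in enumerate(root.spawn(n_cohorts)):
        rng = np.random.default_rng(child)
        serial_aucs = []
        for _ in range(replicates):
            noisy = np.asarray(truth.values) * _lognormal_factors(cv, n_t, rng)
            prof = ConcentrationProfile(
                compound_id=truth.compound_id,
                times=truth.times,
                values=tuple(float(x) for x in noisy),
            )
            serial_aucs.append(trapezoid_auc(prof).value)
        pooled_vals = pooled_true * _lognormal_factors(cv, replicates, rng)
        pooled_mean = float(np.mean(pooled_vals)) * schedule.span_h
        serial_mean = float(np.mean(serial_aucs))
        diffs[i] = abs(pooled_mean - serial_mean) / serial_mean * 100.0
    return diffs


# ---------------------------------------------------------------------------
# Synthetic spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralPeakSpec:
    """A Gaussian chromatographic peak for one compound."""

    compound_id: str
    mz: float
    rt_min: float
    height: float
    sigma_min: float

    def __post_init__(self):
        if self.mz <= 0 or self.sigma_min <= 0 or self.height < 0:
            raise ValidationError("mz and sigma must be > 0, height >= 0")


def synth_spectra(
    panel: Sequence[SpectralPeakSpec],
    rt_start: float,
    rt_end: float,
    n_spectra: int,
    seed: int = 0,
    noise_sd: float = 0.0,
    ppm_tolerance: float = 5.0,
) -> list[CentroidSpectrum]:
    """Centroided spectra with Gaussian chromatographic peaks.

    Each compound contributes a centroid at its m/z whose intensity follows
    height × exp(−(rt − rt0)²/(2σ²)); the analytic EIC area is
    height × σ × √(2π). Compounds whose m/z windows (at ``ppm_tolerance``)
    lie within twice the window of each other trigger an overlap warning.
    """
    if rt_end <= rt_start or n_spectra < 2:
        raise ValidationError("need rt_end > rt_start and n_spectra >= 2")
    sorted_panel = sorted(panel, key=lambda p: p.mz)
    for a, b in zip(sorted_panel, sorted_panel[1:]):
        if (b.mz - a.mz) / a.mz < 2 * ppm_tolerance * 1e-6 * 2:
            warnings.warn(
                f"m/z windows of {a.compound_id} and {b.compound_id} are within "
                f"2× the {ppm_tolerance} ppm tolerance; EICs will overlap",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    times = np.linspace(rt_start, rt_end, n_spectra)
    spectra = []
    for rt in times:
        mzs, ints = [], []
        for p in panel:
            inten = p.height * np.exp(-((rt - p.rt_min) ** 2) / (2 * p.sigma_min**2))
            if noise_sd > 0:
                inten = max(0.0, inten + rng.normal(0.0, noise_sd))
            mzs.append(p.mz)
            ints.append(float(inten))
        spectra.append(
            CentroidSpectrum(retention_time=float(rt), mz=tuple(mzs), intensity=tuple(ints))
        )
    return spectra
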