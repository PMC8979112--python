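"""Exposure ranking, cross-species shares, and Q-marker screening.

Exposure of a compound is its mean pooled peak area across replicates times
the schedule span (the pooled-AUC reading of a single mixed sample).
Candidate quality markers are screened by requiring every other top-ranked
compound to correlate strongly (Pearson) with the candidate's
percent-normalized time profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .auc import ConcentrationProfile
from .errors import ValidationError
from .pooling import SamplingSchedule

#: Screening bounds: companions must exceed this Pearson r ...
DEFAULT_R_THRESHOLD = 0.8
#: ... at a two-sided p-value below this.
DEFAULT_P_THRESHOLD = 0.001
#: Number of top-ranked compounds screened.
DEFAULT_TOP_K = 10


@dataclass(frozen=True)
class ExposureTable:
    """Ranked semi-quantitative exposures for one species.

    ``data`` columns: compound_id, species, exposure (area × h), rank,
    cumulative_fraction (%), reference_available. Rows sorted by rank.
    """

    data: pd.DataFrame

    def __post_init__(self):
        d = self.data
        ranks = d["rank"].to_numpy()
        if not np.array_equal(ranks, np.arange(1, len(d) + 1)):
            raise ValidationError("ranks must be 1..K without gaps")
        exp = d["exposure"].to_numpy()
        if np.any(np.diff(exp) > 0):
            raise ValidationError("exposures must be sorted non-increasing")
        cf = d["cumulative_fraction"].to_numpy()
        if np.any(np.diff(cf) < -1e-9) or abs(cf[-1] - 100.0) > 1e-9:
            raise ValidationError("cumulative fractions must reach 100%")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class CorrelationResult:
    compound_id: str
    reference_id: str
    r: float
    p: float
    n: int

    def __post_init__(self):
        if not (-1 - 1e-12 <= self.r <= 1 + 1e-12):
            raise ValidationError("r must lie in [-1, 1]")
        if not (0 <= self.p <= 1):
            raise ValidationError("p must lie in [0, 1]")
        if self.n < 3:
            raise ValidationError("correlation needs n >= 3 time points")


@dataclass(frozen=True)
class CompanionCheck:
    compound_id: str
    r: float
    p: float
    r_pass: bool
    p_pass: bool


@dataclass(frozen=True)
class QMarkerReport:
    """Outcome of the Q-marker screen; fails loudly via explicit flags."""

    candidate_id: str | None
    reason: str
    candidate_rank: int | None = None
    r_threshold: float = DEFAULT_R_THRESHOLD
    p_threshold: float = DEFAULT_P_THRESHOLD
    top_k: int = DEFAULT_TOP_K
    companions: tuple[CompanionCheck, ...] = ()
    selected: bool = False

    @property
    def min_r(self) -> float | None:
        return min((c.r for c in self.companions), default=None)

    @property
    def max_p(self) -> float | None:
        return max((c.p for c in self.companions), default=None)


def exposure_table(
    matrix,
    schedule: SamplingSchedule,
    species: str | None = None,
    reference_available: Iterable[str] = (),
) -> ExposureTable:
    """Rank compounds by exposure = mean pooled area × (t_n − t_0).

    ``matrix`` is a ``PeakAreaMatrix``; if it holds several species, pass
    the one to rank. Ties are broken by compound_id ascending.
    """
    d = matrix.data
    if species is not None:
        d = d[d["species"] == species]
        if d.empty:
            raise ValidationError(f"no rows for species '{species}'")
    elif d["species"].nunique() > 1:
        raise ValidationError("matrix holds several species; pass species=...")
    mean_area = d.groupby("compound_id", sort=False)["area"].mean()
    exposure = mean_area * schedule.span_h
    if exposure.sum() <= 0:
        raise ValidationError("all exposures are zero; nothing to rank")
    ref = set(reference_available)
    table = (
        exposure.rename("exposure")
        .reset_index()
        .sort_values(["exposure", "compound_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    table["species"] = species if species is not None else d["species"].iloc[0]
    table["rank"] = np.arange(1, len(table) + 1)
    table["cumulative_fraction"] = (
        table["exposure"].cumsum() / table["exposure"].sum() * 100.0
    )
    table["reference_available"] = table["compound_id"].isin(ref)
    cols = [
        "compound_id",
        "species",
        "exposure",
        "rank",
        "cumulative_fraction",
        "reference_available",
    ]
    return ExposureTable(table[cols])


def cumulative_fraction(table: ExposureTable, top_n: int) -> float:
    """Percent of total exposure carried by the top ``top_n`` compounds."""
    if not (1 <= top_n <= len(table)):
        raise ValidationError(f"top_n must be in [1, {len(table)}]")
    return float(table.data["cumulative_fraction"].iloc[top_n - 1])


def top_compounds(table: ExposureTable, top_n: int) -> list[str]:
    if not (1 <= top_n <= len(table)):
        raise ValidationError(f"top_n must be in [1, {len(table)}]")
    return table.data["compound_id"].head(top_n).tolist()


def species_share(
    reference_compounds: Iterable[str],
    table_other_species: ExposureTable,
    by_count: bool = False,
) -> float:
    """Share (%) of another species' exposure carried by a reference set.

    With ``by_count=True`` the share is of compound counts instead of
    exposure mass. Reference compounds absent from the other species
    contribute zero.
    """
    ref = set(reference_compounds)
    if not ref:
        raise ValidationError("reference compound set must be non-empty")
    d = table_other_species.data
    if d.empty:
        raise ValidationError("empty exposure table")
    in_ref = d["compound_id"].isin(ref)
    if by_count:
        return float(in_ref.sum() / len(d) * 100.0)
    return float(d.loc[in_ref, "exposure"].sum() / d["exposure"].sum() * 100.0)


def percent_profile(profile: ConcentrationProfile) -> ConcentrationProfile:
    """Normalize a profile so its values sum to 100% across time points."""
    v = profile.censored_values()
    total = v.sum()
    if total <= 0:
        raise ValidationError("cannot percent-normalize an all-zero profile")
    return ConcentrationProfile(
        compound_id=profile.compound_id,
        times=profile.times,
        values=tuple(float(x) for x in v / total * 100.0),
        unit_label="% of total",
        below_lloq=profile.below_lloq,
    )


def pearson(
    profile_a: ConcentrationProfile, profile_b: ConcentrationProfile
) -> CorrelationResult:
    """Pearson product-moment correlation between two time profiles.

    Two-sided p from the exact t-distribution of r·√((n−2)/(1−r²)) with
    n−2 degrees of freedom. Symmetric in its arguments.
    """
    if profile_a.times != profile_b.times:
        raise ValidationError("profiles must share identical time points")
    a = np.asarray(profile_a.values, dtype=float)
    b = np.asarray(profile_b.values, dtype=float)
    n = len(a)
    if n < 3:
        raise ValidationError("Pearson correlation needs n >= 3 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("correlation undefined for a constant profile")
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(
        compound_id=profile_b.compound_id,
        reference_id=profile_a.compound_id,
        r=float(np.clip(r, -1.0, 1.0)),
        p=float(p),
        n=n,
    )


def select_qmarker(
    table: ExposureTable,
    correlations: Mapping[str, CorrelationResult] | Sequence[CorrelationResult],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    top_k: int = DEFAULT_TOP_K,
) -> QMarkerReport:
    """Screen for a quality-marker candidate.

    The candidate is the highest-ranked compound with an obtainable
    reference substance; it is selected iff every other compound in the top
    ``top_k`` correlates with it at r > r_threshold and p < p_threshold.
    Missing correlations fail that companion explicitly.
    """
    if not (0 < r_threshold < 1) or not (0 < p_threshold < 1):
        raise ValidationError("thresholds must lie in (0, 1)")
    if top_k > len(table):
        raise ValidationError(f"top_k={top_k} exceeds table size {len(table)}")
    if isinstance(correlations, Mapping):
        corr = dict(correlations)
    else:
        corr = {c.compound_id: c for c in correlations}
    d = table.data
    available = d[d["reference_available"]]
    if available.empty:
        return QMarkerReport(
            candidate_id=None,
            reason="no compound with an obtainable reference substance",
            r_threshold=r_threshold,
            p_threshold=p_threshold,
            top_k=top_k,
        )
    cand = available.iloc[0]
    companions = []
    all_pass = True
    for cid in d["compound_id"].head(top_k):
        if cid == cand["compound_id"]:
            continue
        res = corr.get(cid)
        if res is None:
            companions.append(
                CompanionCheck(cid, r=float("nan"), p=float("nan"), r_pass=False, p_pass=False)
            )
            all_pass = False
            continue
        r_ok = res.r > r_threshold
        p_ok = res.p < p_threshold
        companions.append(CompanionCheck(cid, r=res.r, p=res.p, r_pass=r_ok, p_pass=p_ok))
        all_pass = all_pass and r_ok and p_ok
    reason = (
        "all top-{k} companions correlate above threshold".format(k=top_k)
        if all_pass
        else "one or more companions fail the correlation thresholds"
    )
    return QMarkerReport(
        candidate_id=str(cand["compound_id"]),
        candidate_rank=int(cand["rank"]),
        reason=reason,
        r_threshold=r_threshold,
        p_threshold=p_threshold,
        top_k=top_k,
        companions=tuple(companions),
        selected=all_pass,
    )
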