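"""High-resolution extracted-ion chromatograms (HREIC) and peak areas.

Targeted semi-quantification only: retention windows are inputs; there is
no smoothing, baseline model or peak detection. The ppm window is a closed
interval, so boundary ties are included (bit-exact testable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .simulate import CentroidSpectrum

#: Mass of a proton in Da; [M−H]⁻ = monoisotopic mass − PROTON_MASS_DA.
#: Provided as a helper for negative-mode target lists; never auto-applied.
PROTON_MASS_DA = 1.007276

#: Default extraction mass tolerance in parts per million.
DEFAULT_PPM_TOLERANCE = 5.0


@dataclass(frozen=True)
class EICTrace:
    target_mz: float
    ppm_tolerance: float
    times: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trace times must be strictly increasing")
        if any(i < 0 for i in self.intensities):
            raise ValidationError("trace intensities must be >= 0")


@dataclass(frozen=True)
class PeakArea:
    compound_id: str
    area: float
    rt_window: tuple[float, float]
    is_normalized: bool = False
    unit_label: str = "counts*min"

    def __post_init__(self):
        if self.area < 0:
            raise ValidationError("peak area must be >= 0")


def extract_eic(
    spectra: Sequence[CentroidSpectrum],
    target_mz: float,
    ppm_tolerance: float = DEFAULT_PPM_TOLERANCE,
) -> EICTrace:
    """Sum centroid intensities within ±ppm of the target m/z, per spectrum.

    One point per spectrum; spectra with no matching centroid contribute
    zero (zeros are kept so the trace always spans the run).
    """
    if not spectra:
        raise ValidationError("cannot extract an EIC from an empty spectrum sequence")
    if ppm_tolerance <= 0:
        raise ValidationError("ppm_tolerance must be > 0")
    lo = target_mz * (1.0 - ppm_tolerance * 1e-6)
    hi = target_mz * (1.0 + ppm_tolerance * 1e-6)
    ordered = sorted(spectra, key=lambda s: s.retention_time)
    times, intensities = [], []
    for s in ordered:
        mz = np.asarray(s.mz)
        inten = np.asarray(s.intensity)
        mask = (mz >= lo) & (mz <= hi)  # closed interval: boundary ties included
        times.append(s.retention_time)
        intensities.append(float(inten[mask].sum()))
    return EICTrace(
        target_mz=float(target_mz),
        ppm_tolerance=float(ppm_tolerance),
        times=tuple(times),
        intensities=tuple(intensities),
    )


def integrate_eic(
    trace: EICTrace, rt_window: tuple[float, float], compound_id: str = ""
) -> PeakArea:
    """Trapezoidal integral of the trace restricted to a retention window.

    No baseline subtraction. A window containing fewer than two trace points
    yields area 0 with a warning rather than an error.
    """
    lo, hi = rt_window
    if hi <= lo:
        raise ValidationError("rt_window must satisfy end > start")
    t = np.asarray(trace.times)
    if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
        raise ValidationError("rt_window must lie within the trace span")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        warnings.warn(
            f"retention window [{lo:g}, {hi:g}] min contains "
            f"{int(mask.sum())} trace point(s); area reported as 0",
            stacklevel=2,
        )
        return PeakArea(compound_id=compound_id, area=0.0, rt_window=(lo, hi))
    area = float(np.trapezoid(np.asarray(trace.intensities)[mask], t[mask]))
    return PeakArea(compound_id=compound_id, area=area, rt_window=(lo, hi))


def normalize_to_is(area: PeakArea, is_area: PeakArea) -> PeakArea:
    """Internal-standard normalization: the dimensionless area ratio."""
    if is_area.area <= 0:
        raise ValidationError("internal-standard area must be > 0")
    return PeakArea(
        compound_id=area.compound_id,
        area=area.area / is_area.area,
        rt_window=area.rt_window,
        is_normalized=True,
        unit_label="ratio (IS-normalized)",
    )


def _decode_binary_array(node, ns: str) -> np.ndarray:
    import base64
    import zlib

    accessions = {p.get("accession") for p in node.findall(f"{ns}cvParam")}
    raw = base64.b64decode((node.findtext(f"{ns}binary") or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> list[CentroidSpectrum]:
    """Read centroided MS1 spectra from an mzML file.

    Supports 32/64-bit float arrays with optional zlib compression, which
    covers centroided exports from the common converters. Retention times
    are taken from the ``scan start time`` cvParam and assumed to be in
    minutes (seconds are converted when the unit says so).
    """
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = "{%s}" % root.nsmap[None] if None in root.nsmap else ""
    spectra = []
    for sp in root.iter(f"{ns}spectrum"):
        params = {p.get("accession"): p for p in sp.findall(f"{ns}cvParam")}
        level = params.get("MS:1000511")
        if level is not None and level.get("value") not in ("1", "", None):
            continue
        rt = 0.0
        for scan in sp.iter(f"{ns}scan"):
            for p in scan.findall(f"{ns}cvParam"):
                if p.get("accession") == "MS:1000016":
                    rt = float(p.get("value"))
                    unit = (p.get("unitName") or "").lower()
                    if unit == "second":
                        rt /= 60.0
            break
        arrays: dict[str, np.ndarray] = {}
        for arr in sp.iter(f"{ns}binaryDataArray"):
            acc = {p.get("accession") for p in arr.findall(f"{ns}cvParam")}
            if "MS:1000514" in acc:
                arrays["mz"] = _decode_binary_array(arr, ns)
            elif "MS:1000515" in acc:
                arrays["intensity"] = _decode_binary_array(arr, ns)
        if "mz" not in arrays or "intensity" not in arrays:
            continue
        spectra.append(
            CentroidSpectrum(
                retention_time=rt,
                mz=tuple(float(x) for x in arrays["mz"]),
                intensity=tuple(float(x) for x in arrays["intensity"]),
            )
        )
    return spectra
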