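"""Annotation validation and spectrum-selection filters.

Produces the ML-ready subset of a harmonized library: spectra whose
precursor m/z agrees with the annotated structure + adduct within a ppm
tolerance, and whose fragmentation is significant (more than 4 peaks above
2% relative intensity after preprocessing).

Filter order is fixed and the rejection report counts drops per rule in
that order: library exclusion, missing structure, ion mode, precursor-mass
cap, precursor validation, peak preprocessing (empty after cleanup),
significant fragmentation. The final kept set does not depend on the order
of the per-spectrum rules; the attribution of a multiply-defective
spectrum to a rule does, which is why the order is part of the contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .chemstruct import Structure
from .spectra_io import AdductMap, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "CleaningConfig",
    "RejectionReport",
    "validate_precursor",
    "preprocess_peaks",
    "has_significant_fragmentation",
    "select_for_ml",
]

# report keys, in application order
FILTER_ORDER = [
    "excluded_library",
    "missing_structure",
    "ion_mode",
    "precursor_too_heavy",
    "precursor_mismatch",
    "empty_after_preprocessing",
    "insignificant_fragmentation",
]


@dataclass
class CleaningConfig:
    """Thresholds for spectrum selection.

    Defaults: precursors above 1500 Da discarded; peaks below 0.1% relative
    intensity or outside 10-2000 m/z removed; significant fragmentation
    means strictly more than 4 peaks above 2% relative intensity;
    annotation/precursor agreement within 50 ppm.
    """

    max_precursor_da: float = 1500.0
    min_rel_intensity: float = 0.001
    mz_min: float = 10.0
    mz_max: float = 2000.0
    sig_peak_rel_intensity: float = 0.02
    sig_peak_count_exclusive_min: int = 4
    max_ppm_error: float = 50.0
    excluded_libraries: list[str] = field(default_factory=list)
    ion_mode: str = "positive"

    def __post_init__(self):
        if not (0 < self.min_rel_intensity < self.sig_peak_rel_intensity < 1):
            raise ValueError("need 0 < min_rel_intensity < sig_peak_rel_intensity < 1")
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")


@dataclass
class RejectionReport:
    """Per-rule drop counts; kept + sum(drops) == input count."""

    input_count: int = 0
    kept_count: int = 0
    drops: dict[str, int] = field(default_factory=lambda: {k: 0 for k in FILTER_ORDER})

    def conserved(self) -> bool:
        return self.kept_count + sum(self.drops.values()) == self.input_count


def validate_precursor(
    s: Spectrum,
    st: Structure | None,
    adducts: AdductMap,
    max_ppm: float = 50.0,
) -> tuple[bool, float | None, str]:
    """Check the observed precursor m/z against the annotation.

    Theoretical m/z = (monoisotopic mass + adduct mass offset) / |charge|;
    the ppm error uses the theoretical value in the denominator. Spectra
    whose adduct or structure is missing are unverifiable and rejected.

    Returns (keep, ppm_error, reason).
    """
    if st is None or s.adduct is None or s.adduct not in adducts:
        return False, None, "unverifiable"
    offset = adducts.mass_offset(s.adduct)
    charge = abs(adducts.charge(s.adduct))
    theoretical = (st.monoisotopic_mass + offset) / charge
    ppm = 1e6 * abs(s.precursor_mz - theoretical) / theoretical
    if ppm <= max_ppm:
        return True, ppm, "ok"
    return False, ppm, "ppm_exceeded"


def preprocess_peaks(s: Spectrum, cfg: CleaningConfig | None = None) -> Spectrum:
    """Rescale intensities to the base peak, then drop sub-threshold and
    out-of-range peaks.

    Intensities are divided by the base-peak intensity (max = 1.0). Peaks
    with relative intensity strictly below ``min_rel_intensity`` are
    removed (a peak exactly at the threshold is kept), then peaks outside
    the inclusive [mz_min, mz_max] window. Peak order is preserved. The
    operation is idempotent.
    """
    cfg = cfg or CleaningConfig()
    if s.n_peaks == 0:
        return s
    base = float(s.intensity.max())
    if base <= 0:
        rel = np.zeros_like(s.intensity)
    else:
        rel = s.intensity / base
    keep = rel >= cfg.min_rel_intensity
    keep &= (s.mz >= cfg.mz_min) & (s.mz <= cfg.mz_max)
    return replace(s, mz=s.mz[keep], intensity=rel[keep])


def has_significant_fragmentation(s: Spectrum, cfg: CleaningConfig | None = None) -> bool:
    """True iff strictly more than ``sig_peak_count_exclusive_min`` peaks
    exceed ``sig_peak_rel_intensity`` (relative to the base peak)."""
    cfg = cfg or CleaningConfig()
    if s.n_peaks == 0:
        return False
    rel = s.intensity / s.intensity.max()
    return int((rel > cfg.sig_peak_rel_intensity).sum()) > cfg.sig_peak_count_exclusive_min


def select_for_ml(
    spectra: list[Spectrum],
    structures: dict[str, Structure],
    adducts: AdductMap,
    cfg: CleaningConfig | None = None,
) -> tuple[list[Spectrum], RejectionReport]:
    """Apply the full selection cascade and report per-rule drop counts.

    ``structures`` maps inchikey14 -> standardized Structure. Kept spectra
    are returned with preprocessed (base-peak normalized, range-filtered)
    peaks.
    """
    cfg = cfg or CleaningConfig()
    excluded = set(cfg.excluded_libraries)
    report = RejectionReport(input_count=len(spectra))
    kept: list[Spectrum] = []
    for s in spectra:
        if s.source_library in excluded:
            report.drops["excluded_library"] += 1
            continue
        st = structures.get(s.structure_ref) if s.structure_ref else None
        if st is None:
            report.drops["missing_structure"] += 1
            continue
        if cfg.ion_mode and s.ionmode is not None and s.ionmode != cfg.ion_mode:
            report.drops["ion_mode"] += 1
            continue
        if s.precursor_mz > cfg.max_precursor_da:
            report.drops["precursor_too_heavy"] += 1
            continue
        ok, ppm, reason = validate_precursor(s, st, adducts, cfg.max_ppm_error)
        if not ok:
            report.drops["precursor_mismatch"] += 1
            logger.debug("spectrum %s rejected: %s (ppm=%s)", s.spectrum_id, reason, ppm)
            continue
        cleaned = preprocess_peaks(s, cfg)
        if cleaned.n_peaks == 0:
            report.drops["empty_after_preprocessing"] += 1
            continue
        if not has_significant_fragmentation(cleaned, cfg):
            report.drops["insignificant_fragmentation"] += 1
            continue
        kept.append(cleaned)
    report.kept_count = len(kept)
    return kept, report
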