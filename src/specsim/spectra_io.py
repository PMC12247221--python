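"""Spectrum I/O and metadata harmonization.

The pipeline moves spectra around as MGF (peak lists plus a small header)
with a companion metadata CSV keyed by spectrum id, or as a combined JSON
record format. Free-text metadata from public libraries — adduct spellings,
collision energies embedded in compound names, instrument descriptions —
is harmonized here into structured fields.

MGF has no single standard; the dialect written by this package uses the
headers TITLE (spectrum id), PEPMASS, and optional KEY=VALUE lines for
ADDUCT, COLLISION_ENERGY, IONMODE. Anything richer travels in the CSV.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "AdductMap",
    "MgfFormatError",
    "read_mgf",
    "write_mgf",
    "read_metadata_csv",
    "write_metadata_csv",
    "read_json_records",
    "write_json_records",
    "attach_metadata",
    "load_default_adduct_map",
    "harmonize_adduct",
    "parse_collision_energy",
    "propagate_instrument_metadata",
]

# CSV metadata columns, fixed order
METADATA_COLUMNS = [
    "spectrum_id",
    "precursor_mz",
    "adduct",
    "collision_energy",
    "ionization_method",
    "mass_analyzer",
    "dissociation_method",
    "manufacturer",
    "ionmode",
    "source_library",
    "structure_ref",
]


class MgfFormatError(ValueError):
    """Malformed MGF block; carries the index of the offending block."""


@dataclass
class Spectrum:
    """One MS/MS spectrum with harmonized acquisition metadata.

    ``mz`` is strictly increasing and aligned with ``intensity``.
    ``structure_ref`` is the inchikey14 of the annotated structure, when
    known. Missing metadata is represented as ``None``.
    """

    spectrum_id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    adduct: str | None = None
    collision_energy: float | None = None
    ionization_method: str | None = None
    mass_analyzer: str | None = None
    dissociation_method: str | None = None
    manufacturer: str | None = None
    ionmode: str | None = None
    source_library: str = ""
    structure_ref: str | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        if not self.precursor_mz or self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")

    @property
    def n_peaks(self) -> int:
        return len(self.mz)

    def metadata_row(self) -> dict:
        d = {k: getattr(self, k) for k in METADATA_COLUMNS if k not in ("spectrum_id",)}
        d["spectrum_id"] = self.spectrum_id
        return d


# ---------------------------------------------------------------------------
# MGF

def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into Spectrum objects.

    Records without a PEPMASS header are skipped with a logged warning;
    otherwise-malformed blocks raise :class:`MgfFormatError` naming the
    block index.
    """
    spectra: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for idx, rec in enumerate(reader):
            params = rec.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                logger.warning("MGF block %d has no PEPMASS; skipped", idx)
                continue
            try:
                ce = params.get("collision_energy")
                spectra.append(
                    Spectrum(
                        spectrum_id=str(params.get("title", f"spectrum_{idx}")),
                        mz=rec["m/z array"],
                        intensity=rec["intensity array"],
                        precursor_mz=float(pepmass[0]),
                        adduct=params.get("adduct"),
                        collision_energy=float(ce) if ce is not None else None,
                        ionmode=params.get("ionmode"),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise MgfFormatError(f"malformed MGF block {idx}: {exc}") from exc
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with a deterministic header layout and peak
    m/z / intensity formatted to 6 decimal places (so write-read-write is
    byte stable)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.adduct is not None:
                fh.write(f"ADDUCT={s.adduct}\n")
            if s.collision_energy is not None:
                fh.write(f"COLLISION_ENERGY={s.collision_energy:.6f}\n")
            if s.ionmode is not None:
                fh.write(f"IONMODE={s.ionmode}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# Metadata CSV and combined JSON

def write_metadata_csv(spectra: list[Spectrum], path: str | Path) -> None:
    rows = [s.metadata_row() for s in spectra]
    df = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    df.to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"spectrum_id": str, "structure_ref": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return df


def attach_metadata(spectra: list[Spectrum], meta: pd.DataFrame) -> list[Spectrum]:
    """Join a metadata table onto spectra by spectrum_id (in place).

    CSV values override whatever the MGF header carried; NaN means missing.
    """
    indexed = meta.set_index("spectrum_id")
    for s in spectra:
        if s.spectrum_id not in indexed.index:
            logger.warning("no metadata row for spectrum %s", s.spectrum_id)
            continue
        row = indexed.loc[s.spectrum_id]
        for col in METADATA_COLUMNS:
            if col == "spectrum_id":
                continue
            val = row.get(col)
            if pd.isna(val):
                val = None
            if col == "precursor_mz":
                if val is not None:
                    s.precursor_mz = float(val)
            elif col == "collision_energy":
                s.collision_energy = float(val) if val is not None else None
            elif col == "source_library":
                s.source_library = str(val) if val is not None else ""
            else:
                setattr(s, col, val)
    return spectra


def write_json_records(spectra: list[Spectrum], path: str | Path) -> None:
    """Combined format: one JSON record per spectrum with metadata and peaks."""
    records = []
    for s in spectra:
        rec = s.metadata_row()
        rec["mz"] = [round(float(v), 6) for v in s.mz]
        rec["intensity"] = [round(float(v), 6) for v in s.intensity]
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=1))


def read_json_records(path: str | Path) -> list[Spectrum]:
    records = json.loads(Path(path).read_text())
    spectra = []
    for rec in records:
        mz = rec.pop("mz")
        intensity = rec.pop("intensity")
        spectra.append(Spectrum(mz=mz, intensity=intensity, **rec))
    return spectra


# ---------------------------------------------------------------------------
# Adduct harmonization

_BRACKET_CHARGE_RE = re.compile(r"^\[?(?P<core>[^\[\]]+?)\]?(?P<charge>\d*[+-]*)$")


@dataclass
class AdductMap:
    """Curated adduct table: raw spelling -> canonical form -> (offset, charge)."""

    aliases: dict[str, str]
    offsets: dict[str, tuple[float, int]] = field(default_factory=dict)

    def mass_offset(self, canonical: str) -> float:
        return self.offsets[canonical][0]

    def charge(self, canonical: str) -> int:
        return self.offsets[canonical][1]

    def __contains__(self, canonical: str) -> bool:
        return canonical in self.offsets


_ADDUCT_MAP_CACHE: AdductMap | None = None


def load_default_adduct_map() -> AdductMap:
    """Shipped curated adduct table (parsed once per process)."""
    global _ADDUCT_MAP_CACHE
    if _ADDUCT_MAP_CACHE is not None:
        return _ADDUCT_MAP_CACHE
    raw = yaml.safe_load(
        resources.files("specsim.data").joinpath("adducts.yaml").read_text()
    )
    offsets = {
        k: (float(v["mass_offset"]), int(v["charge"])) for k, v in raw["canonical"].items()
    }
    _ADDUCT_MAP_CACHE = AdductMap(aliases=dict(raw["aliases"]), offsets=offsets)
    return _ADDUCT_MAP_CACHE


def harmonize_adduct(raw: str | None, adduct_map: AdductMap) -> str | None:
    """Map a raw adduct spelling to its canonical form, or None if unknown.

    Canonical forms are fixed points. Whitespace, missing brackets and
    trailing charge-notation variants are normalized before alias lookup.
    """
    if raw is None:
        return None
    text = str(raw).strip()
    if not text:
        return None
    if text in adduct_map.offsets:
        return text
    if text in adduct_map.aliases:
        return adduct_map.aliases[text]
    squeezed = text.replace(" ", "")
    if squeezed in adduct_map.offsets:
        return squeezed
    if squeezed in adduct_map.aliases:
        return adduct_map.aliases[squeezed]
    m = _BRACKET_CHARGE_RE.match(squeezed)
    if m:
        core = m.group("core")
        for candidate in (core, f"[{core}]+", f"[{core}]{m.group('charge')}"):
            if candidate in adduct_map.offsets:
                return candidate
            if candidate in adduct_map.aliases:
                return adduct_map.aliases[candidate]
    return None


# ---------------------------------------------------------------------------
# Collision-energy extraction

def _load_ce_rules() -> list[tuple[str, re.Pattern]]:
    raw = yaml.safe_load(
        resources.files("specsim.data").joinpath("collision_energy_rules.yaml").read_text()
    )
    return [(r["name"], re.compile(r["pattern"], re.IGNORECASE)) for r in raw["rules"]]


_CE_RULES = _load_ce_rules()


def parse_collision_energy(
    compound_name: str | None, instrument_field: str | None = None
) -> float | None:
    """Extract a collision energy (eV) from free-text annotation fields.

    Rules from the shipped ordered rule list are tried in order, in the
    compound-name field first and then the instrument field; the first
    match wins. Normalized collision energy (percent / NCE) annotations
    are not eV and return missing. Negative values are rejected.
    """
    for text in (compound_name, instrument_field):
        if not text:
            continue
        for name, pattern in _CE_RULES:
            m = pattern.search(str(text))
            if m:
                try:
                    value = float(m.group(1))
                except (TypeError, ValueError):
                    logger.warning("rule %s matched non-numeric token in %r", name, text)
                    return None
                if value < 0:
                    return None
                return value
    return None


# ---------------------------------------------------------------------------
# Instrument metadata propagation

def _load_instrument_rules() -> dict[str, dict[str, str]]:
    return yaml.safe_load(
        resources.files("specsim.data").joinpath("instrument_rules.yaml").read_text()
    )


_INSTRUMENT_RULES = _load_instrument_rules()
_TOKEN_RE = re.compile(r"[a-z0-9]+")


def propagate_instrument_metadata(
    raw_annotation: str | None,
    explicit: dict[str, str] | None = None,
) -> tuple[str | None, str | None, str | None, str | None]:
    """Derive (ionization_method, mass_analyzer, dissociation_method,
    manufacturer) from a free-text instrument annotation.

    Tokens are matched case-insensitively against the shipped tables. If
    two tokens disagree within a category (e.g. two different mass
    analyzers) the whole annotation is ambiguous and all four fields are
    returned missing. Explicit provenance values (``explicit``) override
    anything derived from the annotation.
    """
    results: dict[str, str | None] = {
        "ionization": None,
        "mass_analyzer": None,
        "dissociation": None,
        "manufacturer": None,
    }
    if raw_annotation:
        tokens = _TOKEN_RE.findall(str(raw_annotation).lower())
        for category in results:
            table = _INSTRUMENT_RULES[category]
            hits = {table[t] for t in tokens if t in table}
            if len(hits) > 1:
                logger.warning(
                    "conflicting %s annotations in %r: %s",
                    category, raw_annotation, sorted(hits),
                )
                results = dict.fromkeys(results, None)
                break
            if hits:
                results[category] = next(iter(hits))
    if explicit:
        for key in ("ionization", "mass_analyzer", "dissociation", "manufacturer"):
            if explicit.get(key):
                results[key] = explicit[key]
    return (
        results["ionization"],
        results["mass_analyzer"],
        results["dissociation"],
        results["manufacturer"],
    )
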