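"""Synthetic structure families and similarity-correlated spectra.

The generator provides everything the pipeline needs to be exercised
end-to-end without downloading public libraries: families of related 2-D
structures (a scaffold with a growing alkyl substituent) whose pairwise
Tanimoto similarities span the full range, spectra whose peak overlap
tracks structural similarity, and acquisition metadata with realistic
missingness (collision energy absent for ~70.72% of spectra by default,
matching what public test libraries exhibit).

Spectra are simulated from substructure features, not physics: the on-bits
of a coarse path fingerprint are mapped deterministically to (m/z,
intensity) peaks, so structures sharing substructure share peaks and
spectral cosine similarity correlates with Tanimoto similarity. Poisson
noise peaks and lognormal intensity jitter degrade that correlation in a
controlled way. The fixture's contract is statistical, not chemical
fidelity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemstruct import Structure, standardize_structure
from .spectra_io import (
    Spectrum,
    load_default_adduct_map,
    write_metadata_csv,
    write_mgf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureConfig",
    "generate_structures",
    "simulate_spectrum",
    "generate_benchmark_fixture",
    "write_structures_csv",
    "read_structures_csv",
]

# scaffold attachment points; each family is one scaffold with alkyl chains
# of increasing length, giving high within-family and low between-family
# path-fingerprint similarity
_SCAFFOLDS = [
    "c1ccccc1",            # alkylbenzenes
    "c1ccc(O)cc1",         # 4-alkylphenols
    "c1ccc(N)cc1",         # 4-alkylanilines
    "c1ccncc1",            # 4-alkylpyridines
    "c1ccc2ccccc2c1",      # alkylnaphthalenes
    "c1cc2ccccc2[nH]1",    # alkylindoles
    "C1CCCCC1",            # alkylcyclohexanes
    "C1CCOC1",             # alkyltetrahydrofurans
    "c1ccco1",             # alkylfurans
    "c1cccs1",             # alkylthiophenes
    "c1cc[nH]c1",          # alkylpyrroles
    "C(=O)O",              # fatty acids
    "C(=O)N",              # fatty amides
    "C(=O)C",              # methyl ketones
    "C#N",                 # nitriles
    "OC(=O)C",             # acetate esters
    "c1ccc(Cl)cc1",        # 4-chloroalkylbenzenes
    "c1ccc(F)cc1",         # 4-fluoroalkylbenzenes
    "c1ccc(OC)cc1",        # 4-methoxyalkylbenzenes
    "N1CCOCC1",            # N-alkylmorpholines
    "N1CCNCC1",            # N-alkylpiperazines
    "c1ccc(S(N)(=O)=O)cc1",# alkylbenzenesulfonamides
]

_DEFAULT_PROFILES = [
    ("ESI", "Orbitrap", "HCD", "Thermo"),
    ("ESI", "TOF", "CID", "Bruker"),
]

_DEFAULT_ADDUCT_POOL = [("[M+H]+", 0.7), ("[M+Na]+", 0.2), ("[M+NH4]+", 0.1)]

_CE_LEVELS = [10.0, 20.0, 35.0, 55.0]

DEFAULT_PLANTED_DEFECTS = {
    "bad_ppm": 3,
    "sparse": 3,
    "excluded_library": 3,
    "out_of_range_precursor": 3,
    "missing_structure": 3,
}

EXCLUDED_LIBRARY_NAME = "SYNTH-HETEROGENEOUS"
MAIN_LIBRARY_NAME = "SYNTH-MAIN"


@dataclass
class FixtureConfig:
    """Scale and noise knobs for the synthetic benchmark fixture.

    Defaults give ~300 structures and ~1,500 spectra, enough to exercise
    every pipeline stage. ``ce_missing_fraction`` defaults to the realistic
    missingness rate of collision-energy metadata in public libraries.
    """

    n_families: int = 20
    members_per_family: int = 15
    spectra_per_structure: int = 5
    ce_missing_fraction: float = 0.7072
    instrument_profiles: list[tuple[str, str, str, str]] = field(
        default_factory=lambda: list(_DEFAULT_PROFILES)
    )
    adduct_pool: list[tuple[str, float]] = field(
        default_factory=lambda: list(_DEFAULT_ADDUCT_POOL)
    )
    noise_peak_rate: float = 3.0
    intensity_jitter: float = 0.1
    seed: int = 0
    planted_defects: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_DEFECTS)
    )

    def __post_init__(self):
        if not (0 <= self.ce_missing_fraction <= 1):
            raise ValueError("ce_missing_fraction must be in [0,1]")
        if min(self.n_families, self.members_per_family, self.spectra_per_structure) < 1:
            raise ValueError("counts must be >= 1")


def generate_structures(cfg: FixtureConfig) -> list[Structure]:
    """Deterministic structure families: scaffold + C1..Cn alkyl chains.

    All generated structures are already in standardized form and unique
    by inchikey14.
    """
    structures: list[Structure] = []
    seen: set[str] = set()
    for fam in range(cfg.n_families):
        scaffold = _SCAFFOLDS[fam % len(_SCAFFOLDS)]
        made = 0
        chain = 1
        while made < cfg.members_per_family and chain < cfg.members_per_family + 20:
            smiles = "C" * chain + scaffold
            chain += 1
            if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover
                continue
            st = standardize_structure(smiles)
            if st.inchikey14 in seen:
                continue
            seen.add(st.inchikey14)
            structures.append(st)
            made += 1
    return structures


def _feature_bits(st: Structure) -> np.ndarray:
    mol = Chem.MolFromSmiles(st.canonical_smiles)
    bv = Chem.RDKFingerprint(mol, fpSize=256, minPath=1, maxPath=4)
    return np.array(sorted(bv.GetOnBits()), dtype=np.int64)


def _bit_mz(bit: int) -> float:
    # stable bit -> m/z map with sub-Da scatter so peaks are distinguishable
    return 40.0 + bit * 6.1 + ((bit * 37) % 13) * 0.013


def _bit_intensity(bit: int) -> float:
    # stable bit -> base relative intensity in [0.05, 1.0]
    return 0.05 + 0.95 * ((bit * 2654435761) % 4096) / 4096.0


def simulate_spectrum(
    st: Structure,
    spectrum_id: str,
    rng: np.random.Generator,
    cfg: FixtureConfig,
    adduct: str | None = None,
) -> Spectrum:
    """Simulate one spectrum for a structure.

    Fragment peaks come from hashed substructure features (shared
    substructure means shared peaks); at most the 40 most intense feature
    peaks are kept. Noise peaks are Poisson-distributed and intensities
    carry lognormal jitter. The precursor m/z is exact for the drawn
    adduct; metadata fields are drawn from the configured profiles.
    """
    adduct_map = load_default_adduct_map()
    if adduct is None:
        names = [a for a, _ in cfg.adduct_pool]
        probs = np.array([w for _, w in cfg.adduct_pool], dtype=float)
        adduct = names[rng.choice(len(names), p=probs / probs.sum())]
    offset, charge = adduct_map.offsets[adduct]
    precursor = (st.monoisotopic_mass + offset) / charge

    bits = _feature_bits(st)
    mz = np.array([_bit_mz(b) for b in bits])
    inten = np.array([_bit_intensity(b) for b in bits])
    if len(bits) > 40:
        keep = np.argsort(inten)[::-1][:40]
        mz, inten = mz[keep], inten[keep]
    if cfg.intensity_jitter > 0:
        inten = inten * rng.lognormal(0.0, cfg.intensity_jitter, size=len(inten))
    n_noise = rng.poisson(cfg.noise_peak_rate) if cfg.noise_peak_rate > 0 else 0
    if n_noise:
        mz = np.concatenate([mz, rng.uniform(50.0, 1200.0, size=n_noise)])
        inten = np.concatenate([inten, rng.uniform(0.01, 0.2, size=n_noise)])
    inten = inten / inten.max()

    profile = cfg.instrument_profiles[rng.integers(len(cfg.instrument_profiles))]
    ce = None
    if rng.random() >= cfg.ce_missing_fraction:
        ce = float(_CE_LEVELS[rng.integers(len(_CE_LEVELS))])
    return Spectrum(
        spectrum_id=spectrum_id,
        mz=mz,
        intensity=inten,
        precursor_mz=precursor,
        adduct=adduct,
        collision_energy=ce,
        ionization_method=profile[0],
        mass_analyzer=profile[1],
        dissociation_method=profile[2],
        manufacturer=profile[3],
        ionmode="positive",
        source_library=MAIN_LIBRARY_NAME,
        structure_ref=st.inchikey14,
    )


def _plant_defects(
    spectra: list[Spectrum],
    structures: list[Structure],
    cfg: FixtureConfig,
    rng: np.random.Generator,
) -> list[Spectrum]:
    """Append defective copies of clean spectra, one defect each, at the
    configured counts. Each defect fails exactly one selection rule."""
    extra: list[Spectrum] = []
    counter = 0
    template_idx = 0

    def clone(tag: str) -> Spectrum:
        nonlocal counter, template_idx
        src = spectra[template_idx % len(spectra)]
        template_idx += 1
        counter += 1
        return Spectrum(
            spectrum_id=f"defect_{tag}_{counter:03d}",
            mz=src.mz.copy(),
            intensity=src.intensity.copy(),
            precursor_mz=src.precursor_mz,
            adduct=src.adduct,
            collision_energy=src.collision_energy,
            ionization_method=src.ionization_method,
            mass_analyzer=src.mass_analyzer,
            dissociation_method=src.dissociation_method,
            manufacturer=src.manufacturer,
            ionmode=src.ionmode,
            source_library=src.source_library,
            structure_ref=src.structure_ref,
        )

    for _ in range(cfg.planted_defects.get("bad_ppm", 0)):
        s = clone("ppm")
        s.precursor_mz *= 1 + 120e-6  # 120 ppm off, beyond the 50 ppm gate
        extra.append(s)
    for _ in range(cfg.planted_defects.get("sparse", 0)):
        s = clone("sparse")
        top = np.argsort(s.intensity)[::-1][:3]  # 3 significant peaks only
        s.mz, s.intensity = s.mz[np.sort(top)], s.intensity[np.sort(top)]
        extra.append(s)
    for _ in range(cfg.planted_defects.get("excluded_library", 0)):
        s = clone("lib")
        s.source_library = EXCLUDED_LIBRARY_NAME
        extra.append(s)
    for _ in range(cfg.planted_defects.get("out_of_range_precursor", 0)):
        s = clone("heavy")
        s.precursor_mz = 1600.0
        extra.append(s)
    for _ in range(cfg.planted_defects.get("missing_structure", 0)):
        s = clone("nostruct")
        s.structure_ref = None
        extra.append(s)
    return extra


def generate_benchmark_fixture(
    cfg: FixtureConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[Spectrum], list[Structure], dict[str, int]]:
    """Generate the full fixture: structures, clean spectra, planted
    defects; optionally written as spectra.mgf + metadata.csv +
    structures.csv under ``out_dir``.

    Fully deterministic for a fixed config (including seed).
    """
    cfg = cfg or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    structures = generate_structures(cfg)
    spectra: list[Spectrum] = []
    for st in structures:
        for rep in range(cfg.spectra_per_structure):
            sid = f"{st.inchikey14}_{rep:02d}"
            spectra.append(simulate_spectrum(st, sid, rng, cfg))
    defects = _plant_defects(spectra, structures, cfg, rng)
    all_spectra = spectra + defects
    defect_counts = dict(cfg.planted_defects)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mgf(all_spectra, out / "spectra.mgf")
        write_metadata_csv(all_spectra, out / "metadata.csv")
        write_structures_csv(structures, out / "structures.csv")
    return all_spectra, structures, defect_counts


def write_structures_csv(structures: list[Structure], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "inchikey14": [s.inchikey14 for s in structures],
            "inchikey": [s.inchikey for s in structures],
            "canonical_smiles": [s.canonical_smiles for s in structures],
            "raw_smiles": [s.raw_smiles for s in structures],
            "monoisotopic_mass": [s.monoisotopic_mass for s in structures],
            "residual_charge": [s.residual_charge for s in structures],
        }
    )
    df.to_csv(path, index=False)


def read_structures_csv(path: str | Path) -> list[Structure]:
    df = pd.read_csv(path)
    return [
        Structure(
            raw_smiles=row.raw_smiles,
            canonical_smiles=row.canonical_smiles,
            inchikey=row.inchikey,
            monoisotopic_mass=float(row.monoisotopic_mass),
            residual_charge=int(row.residual_charge),
        )
        for row in df.itertuples(index=False)
    ]
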