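"""All-Pairs / Filtered spectrum-pair datasets and biased epoch sampling.

Two pair regimes are supported: *All-Pairs*, the exhaustive enumeration of
ordered pairs of distinct spectra, and *Filtered*, which restricts pairs
to matched acquisition conditions (same ionization method, mass analyzer
and adduct; collision-energy difference below 5 eV when both energies are
known; precursor mass difference below 200 Da). A strict collision-energy
mode additionally rejects pairs where either energy is missing.

Training epochs are sampled from the train pairs so that every train
structure appears at least once per epoch (coverage-first), after which
similarity bins are drawn equiprobably and one pair sampled per drawn bin.
The *uniform* scheme uses ten equal-width similarity bins; the *biased*
scheme uses twenty bins whose edges are warped by an exponent of 0.3,
``e_i = (i/20)**0.3``, concentrating bins at high similarity. Because bins
are drawn equiprobably, half of all drawn pairs then fall above the middle
edge ``(1/2)**0.3 ~ 0.812`` — versus roughly 19% above 0.81 under the
uniform scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .chemstruct import SimilarityMatrix
from .spectra_io import Spectrum
from .split_sampler import SplitResult

logger = logging.getLogger(__name__)

__all__ = [
    "FilterCriteria",
    "PairRecord",
    "BiasedSamplerConfig",
    "pair_passes_filter",
    "enumerate_pairs",
    "pairs_to_frame",
    "biased_bin_edges",
    "uniform_bin_edges",
    "sample_epochs",
    "write_epochs_hdf",
    "read_epochs_hdf",
    "write_test_pairs_parquet",
    "read_test_pairs_parquet",
]

PAIR_COLUMNS = [
    "spectrum_id_a",
    "spectrum_id_b",
    "inchikey14_a",
    "inchikey14_b",
    "target_similarity",
    "mean_tt_similarity",
]


@dataclass
class FilterCriteria:
    """Matched-acquisition pair constraints.

    Difference thresholds are strict: a collision-energy difference of
    exactly ``max_ce_diff`` fails. With ``ce_required`` false (default),
    the collision-energy criterion is skipped when either spectrum lacks
    an annotated energy; strict mode rejects such pairs.
    """

    require_same_ionization: bool = True
    require_same_analyzer: bool = True
    require_same_adduct: bool = True
    max_ce_diff: float = 5.0
    ce_required: bool = False
    max_precursor_diff: float = 200.0

    def __post_init__(self):
        if self.max_ce_diff <= 0 or self.max_precursor_diff <= 0:
            raise ValueError("difference thresholds must be positive")


@dataclass
class PairRecord:
    """An ordered spectrum pair with its Tanimoto target."""

    spectrum_id_a: str
    spectrum_id_b: str
    inchikey14_a: str
    inchikey14_b: str
    target_similarity: float
    mean_tt_similarity: float | None = None


@dataclass
class BiasedSamplerConfig:
    n_bins: int = 20
    edge_exponent: float = 0.3
    pairs_per_epoch: int = 1000
    n_epochs: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.edge_exponent <= 1):
            raise ValueError("edge_exponent must be in (0, 1]")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")


def pair_passes_filter(
    a: Spectrum, b: Spectrum, criteria: FilterCriteria
) -> tuple[bool, str | None]:
    """Evaluate the matched-acquisition criteria for an ordered pair.

    Returns (passes, first failing criterion). A required metadata field
    that is missing on either side fails that criterion (the match cannot
    be verified), except collision energy, whose criterion is skipped on
    missingness unless ``ce_required``.
    """
    if criteria.require_same_ionization:
        if a.ionization_method is None or b.ionization_method is None:
            return False, "ionization_missing"
        if a.ionization_method != b.ionization_method:
            return False, "ionization"
    if criteria.require_same_analyzer:
        if a.mass_analyzer is None or b.mass_analyzer is None:
            return False, "analyzer_missing"
        if a.mass_analyzer != b.mass_analyzer:
            return False, "analyzer"
    if criteria.require_same_adduct:
        if a.adduct is None or b.adduct is None:
            return False, "adduct_missing"
        if a.adduct != b.adduct:
            return False, "adduct"
    if a.collision_energy is None or b.collision_energy is None:
        if criteria.ce_required:
            return False, "collision_energy_missing"
    else:
        if abs(a.collision_energy - b.collision_energy) >= criteria.max_ce_diff:
            return False, "collision_energy"
    if abs(a.precursor_mz - b.precursor_mz) >= criteria.max_precursor_diff:
        return False, "precursor_diff"
    return True, None


def enumerate_pairs(
    spectra: list[Spectrum],
    matrix: SimilarityMatrix,
    criteria: FilterCriteria | None = None,
    ordered: bool = True,
    tt_similarity: dict[str, float] | None = None,
) -> Iterator[PairRecord]:
    """Stream spectrum pairs with Tanimoto targets.

    Without criteria this is the exhaustive All-Pairs enumeration: every
    ordered pair of distinct spectra, n*(n-1) records (or n*(n-1)/2 with
    ``ordered=False``, keeping a before b in input order). With criteria,
    only passing pairs are yielded. Spectra lacking a structure annotation
    present in ``matrix`` are excluded up front. Self-pairs (same spectrum
    id) are always excluded; distinct spectra of the same structure pair
    with target 1.0.
    """
    usable = []
    for s in spectra:
        if s.structure_ref is None or s.structure_ref not in matrix:
            logger.warning("spectrum %s lacks a usable structure; excluded", s.spectrum_id)
            continue
        usable.append(s)
    for i, a in enumerate(usable):
        inner = usable if ordered else usable[i + 1:]
        for b in inner:
            if a.spectrum_id == b.spectrum_id:
                continue
            if criteria is not None:
                ok, _ = pair_passes_filter(a, b, criteria)
                if not ok:
                    continue
            target = matrix.get(a.structure_ref, b.structure_ref)
            mean_tt = None
            if tt_similarity is not None:
                ta = tt_similarity.get(a.structure_ref)
                tb = tt_similarity.get(b.structure_ref)
                if ta is not None and tb is not None:
                    mean_tt = (ta + tb) / 2.0
            yield PairRecord(
                spectrum_id_a=a.spectrum_id,
                spectrum_id_b=b.spectrum_id,
                inchikey14_a=a.structure_ref,
                inchikey14_b=b.structure_ref,
                target_similarity=target,
                mean_tt_similarity=mean_tt,
            )


def pairs_to_frame(pairs: Iterable[PairRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(p) for p in pairs], columns=PAIR_COLUMNS)
    return df


def biased_bin_edges(cfg: BiasedSamplerConfig) -> np.ndarray:
    """Similarity-bin edges warped toward high similarity:
    ``e_i = (i / n_bins) ** edge_exponent``."""
    i = np.arange(cfg.n_bins + 1)
    return (i / cfg.n_bins) ** cfg.edge_exponent


def uniform_bin_edges(n_bins: int = 10) -> np.ndarray:
    return np.linspace(0.0, 1.0, n_bins + 1)


def _assign_bins(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def sample_epochs(
    pairs: pd.DataFrame,
    cfg: BiasedSamplerConfig,
    mode: str = "biased20",
) -> list[pd.DataFrame]:
    """Draw pre-batched training epochs from a train pair table.

    Each epoch first covers every train structure (each inchikey14
    appearing in the table gets one uniformly drawn pair containing it),
    then similarity bins — uniform 10-bin or biased 20-bin depending on
    ``mode`` — are drawn equiprobably among non-empty bins and one pair is
    sampled from each drawn bin until ``pairs_per_epoch`` rows. Within-bin
    selection is uniform without replacement inside an epoch (falling back
    to replacement if a bin is exhausted) and with replacement across
    epochs.
    """
    if mode == "biased20":
        edges = biased_bin_edges(cfg)
    elif mode == "uniform10":
        edges = uniform_bin_edges(10)
    else:
        raise ValueError(f"unknown sampling mode: {mode}")
    if pairs.empty:
        raise ValueError("no pairs to sample from")
    rng = np.random.default_rng(cfg.seed)
    targets = pairs["target_similarity"].to_numpy()
    bin_of_pair = _assign_bins(targets, edges)
    n_bins = len(edges) - 1
    pairs_in_bin = {b: np.flatnonzero(bin_of_pair == b) for b in range(n_bins)}
    nonempty = [b for b in range(n_bins) if len(pairs_in_bin[b])]
    # pairs containing each structure, for the coverage-first pass
    keys = sorted(set(pairs["inchikey14_a"]) | set(pairs["inchikey14_b"]))
    by_key: dict[str, np.ndarray] = {}
    a_arr = pairs["inchikey14_a"].to_numpy()
    b_arr = pairs["inchikey14_b"].to_numpy()
    for k in keys:
        rows = np.flatnonzero((a_arr == k) | (b_arr == k))
        if len(rows) == 0:
            logger.warning("structure %s has no eligible pair; dropped from coverage", k)
            continue
        by_key[k] = rows

    epochs: list[pd.DataFrame] = []
    for _ in range(cfg.n_epochs):
        chosen: list[int] = []
        for k in sorted(by_key):
            rows = by_key[k]
            chosen.append(int(rows[rng.integers(len(rows))]))
            if len(chosen) >= cfg.pairs_per_epoch:
                break
        # per-bin shuffled queues: uniform without replacement inside the
        # epoch, reshuffled (replacement) once a bin is exhausted
        queues = {b: list(rng.permutation(pairs_in_bin[b])) for b in nonempty}
        while len(chosen) < cfg.pairs_per_epoch:
            b = nonempty[rng.integers(len(nonempty))]
            if not queues[b]:
                queues[b] = list(rng.permutation(pairs_in_bin[b]))
            chosen.append(int(queues[b].pop()))
        epochs.append(pairs.iloc[chosen].reset_index(drop=True))
    return epochs


def write_epochs_hdf(epochs: list[pd.DataFrame], path: str | Path, overwrite: bool = False) -> None:
    """Write epochs to an HDF5 file, one table per key ``epoch_0000``, ..."""
    if not epochs:
        raise ValueError("no epochs to write")
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    with pd.HDFStore(path, mode="w") as store:
        for i, df in enumerate(epochs):
            store.put(f"epoch_{i:04d}", df[PAIR_COLUMNS[:5]], format="table")


def read_epochs_hdf(path: str | Path) -> list[pd.DataFrame]:
    with pd.HDFStore(path, mode="r") as store:
        keys = sorted(store.keys())
        return [store[k] for k in keys]


def write_test_pairs_parquet(pairs: pd.DataFrame, path: str | Path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    pairs[PAIR_COLUMNS].to_parquet(path, index=False)


def read_test_pairs_parquet(path: str | Path) -> pd.DataFrame:
    return pd.read_parquet(path)
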