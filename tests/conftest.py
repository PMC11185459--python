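"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mzpipe import FeatureTable
from mzpipe.preannotation import IonTable


def make_table(
    mz: list[float],
    rt: list[float],
    intensities: np.ndarray | None = None,
    n_samples: int = 3,
    moniker: str = "t",
) -> FeatureTable:
    """Small literal feature table for worked examples."""
    n = len(mz)
    if intensities is None:
        intensities = np.full((n, n_samples), 1000.0)
    intensities = np.asarray(intensities, dtype=float)
    return FeatureTable.from_arrays(
        moniker,
        [f"f{i + 1}" for i in range(n)],
        mz,
        rt,
        intensities,
        [f"s{j + 1}" for j in range(intensities.shape[1])],
    )


def table_with_feature_counts(counts: list[int], n_features: int = 100) -> FeatureTable:
    """Table where sample j observes exactly counts[j] features."""
    intensities = np.zeros((n_features, len(counts)))
    for j, c in enumerate(counts):
        intensities[:c, j] = 100.0
    return make_table(
        list(np.linspace(100.0, 200.0, n_features)),
        list(np.linspace(10.0, 20.0, n_features)),
        intensities,
    )


def brute_force_partition(
    table: FeatureTable,
    ion_table: IonTable | None = None,
    mz_tol_ppm: float = 5.0,
    rt_tol_s: float = 2.0,
    isotope_ratio_cap: float = 1.5,
) -> set[frozenset[str]]:
    """Independent grouping oracle: enumerate all feature pairs, link those
    whose m/z difference matches an isotope step or adduct-pair delta within
    tolerance (on the heavier m/z) while co-eluting, then take connected
    components. Returns the partition as a set of frozensets of feature ids.
    """
    if ion_table is None:
        ion_table = IonTable.positive()
    mz = table.mz.to_numpy(dtype=float)
    rt = table.rtime.to_numpy(dtype=float)
    intens = table.intensities.to_numpy(dtype=float)
    fids = table.feature_ids
    n = len(fids)

    iso_deltas = [off for _, off in ion_table.isotope_steps if off > 0]
    adduct_offsets = [off for _, off in ion_table.adducts]
    adduct_deltas = [
        abs(a - b) for a, b in itertools.combinations(adduct_offsets, 2) if a != b
    ]

    adjacency: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        lo, hi = (i, j) if mz[i] <= mz[j] else (j, i)
        dmz = mz[hi] - mz[lo]
        if abs(rt[i] - rt[j]) > rt_tol_s:
            continue
        tol_da = mz[hi] * mz_tol_ppm * 1e-6
        linked = any(abs(dmz - d) <= tol_da for d in adduct_deltas)
        if not linked and any(abs(dmz - d) <= tol_da for d in iso_deltas):
            li, hv = intens[lo], intens[hi]
            both = (li > 0) & (hv > 0)
            if not both.any() or np.median(hv[both] / li[both]) <= isotope_ratio_cap:
                linked = True
        if linked:
            adjacency[i].add(j)
            adjacency[j].add(i)

    seen: set[int] = set()
    partition: set[frozenset[str]] = set()
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adjacency[x] - comp)
        seen |= comp
        partition.add(frozenset(fids[x] for x in comp))
    return partition


def grouping_partition(empcpds) -> set[frozenset[str]]:
    return {frozenset(e.feature_ids) for e in empcpds}


@pytest.fixture(scope="session")
def basic_bundle(tmp_path_factory):
    """The reference synthetic experiment: 50 compounds, 20 samples, 2 ppm noise."""
    from mzpipe import make_experiment

    directory = tmp_path_factory.mktemp("basic_fixture")
    return make_experiment(
        str(directory),
        n_compounds=50,
        n_samples=20,
        adduct_set=("M+H+", "M+Na+"),
        isotope_set=("M0", "13C/3C1"),
        mz_noise_ppm=2.0,
        seed=20260921,
    )


@pytest.fixture(scope="session")
def combined_bundle(tmp_path_factory):
    """Fixture with batches, blanks, contamination, a failed injection,
    standards and MS2 spectra: the full default-workflow exercise."""
    from mzpipe import make_preset

    directory = tmp_path_factory.mktemp("combined_fixture")
    return make_preset(str(directory), "combined", seed=20260921)
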