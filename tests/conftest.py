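"""Shared fixtures: programmatic panel construction, no on-disk test data."""

from __future__ import annotations

import numpy as np
import pytest

from signepi.genotype_io import GenotypePanel, MarkerRecord, SampleRecord


def build_panel(
    chroms,
    dosage,
    positions=None,
    alleles=None,
    families=None,
    stages=None,
    marker_ids=None,
    imputed_mask=None,
):
    """Construct a GenotypePanel from plain arrays.

    ``chroms`` is one label per marker; ``dosage`` a (markers x samples)
    array with NaN for missing. Positions default to 1 Mb spacing within each
    chromosome; alleles default to A (ref) / C (alt).
    """
    dosage = np.asarray(dosage, dtype=float)
    n_markers, n_samples = dosage.shape
    assert len(chroms) == n_markers
    if positions is None:
        counters: dict[str, int] = {}
        positions = []
        for c in chroms:
            counters[c] = counters.get(c, 0) + 1
            positions.append(counters[c] * 1_000_000)
    if alleles is None:
        alleles = [("A", "C")] * n_markers
    if marker_ids is None:
        marker_ids = [f"m{i}" for i in range(n_markers)]
    markers = [
        MarkerRecord(marker_ids[i], chroms[i], positions[i], alleles[i][0], alleles[i][1])
        for i in range(n_markers)
    ]
    samples = [
        SampleRecord(
            f"s{j}",
            family_id=families[j] if families is not None else None,
            stage=stages[j] if stages is not None else None,
        )
        for j in range(n_samples)
    ]
    return GenotypePanel.from_parts(markers, samples, dosage, imputed_mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def make_panel():
    return build_panel
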