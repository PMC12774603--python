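"""HapMap genotype panels for inbred lines: parsing, QC filters, mean imputation.

The panel container holds a markers x samples dosage matrix of alternate-allele
counts (0, 1, 2, NaN for missing; fractional values only after mean imputation),
marker metadata (chromosome, physical position, reference/alternate allele), and
per-sample breeding metadata (family, pipeline stage, panel membership).

The alternate allele of each marker is the minor allele observed at load time,
with ties broken alphabetically, so that downstream allelic-combination labels
(e.g. the "A/T" vs "C/C" combinations of a two-locus interaction) are
reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = [
    "CHROMOSOMES",
    "STAGES",
    "MarkerRecord",
    "SampleRecord",
    "GenotypePanel",
    "HapMapParseError",
    "GenotypeCodeError",
    "read_hapmap",
    "write_hapmap",
    "read_sample_metadata",
    "write_sample_metadata",
    "attach_sample_metadata",
    "compute_maf",
    "marker_stats",
    "filter_markers",
    "impute_mean",
    "subset_panel",
    "chromosome_sort_key",
]

#: Bread-wheat chromosome labels (7 groups x subgenomes A, B, D) plus unplaced.
CHROMOSOMES = tuple(f"{n}{g}" for n in range(1, 8) for g in "ABD") + ("UN",)

#: Breeding-pipeline stages from early to elite yield trials; the order is total.
STAGES = ("IPSR", "PYN", "AYN", "EYN")

PANELS = ("discovery", "validation", "program", "simulated")

#: Standard 11 HapMap metadata columns preceding the sample columns.
HAPMAP_COLUMNS = (
    "rs#",
    "alleles",
    "chrom",
    "pos",
    "strand",
    "assembly#",
    "center",
    "protLSID",
    "assayLSID",
    "panelLSID",
    "QCcode",
)

_IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

_BASES = ("A", "C", "G", "T")


class HapMapParseError(ValueError):
    """Malformed HapMap file (bad header, duplicate marker, unparsable field)."""


class GenotypeCodeError(ValueError):
    """A genotype call inconsistent with the marker's two alleles."""


def chromosome_sort_key(label: str) -> tuple:
    """Total order on chromosome labels: 1A < 1B < 1D < 2A < ... < 7D < UN."""
    if label == "UN":
        return (1, 0, "")
    return (0, int(label[:-1]), label[-1])


@dataclass(frozen=True)
class MarkerRecord:
    """A biallelic SNP: identifier, map location, and its two allele codes."""

    marker_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(
                f"marker {self.marker_id}: unknown chromosome {self.chromosome!r}"
            )
        if self.position < 1:
            raise ValueError(f"marker {self.marker_id}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"marker {self.marker_id}: alleles must differ")

    @property
    def subgenome(self) -> str:
        """Wheat subgenome letter (A/B/D), or 'unknown' for unplaced markers."""
        return "unknown" if self.chromosome == "UN" else self.chromosome[-1]

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class SampleRecord:
    """An experimental line with its breeding-program metadata."""

    sample_id: str
    family_id: str | None = None
    stage: str | None = None
    panel: str | None = None

    def __post_init__(self) -> None:
        if self.stage is not None and self.stage not in STAGES:
            raise ValueError(
                f"sample {self.sample_id}: stage must be one of {STAGES}, got {self.stage!r}"
            )
        if self.panel is not None and self.panel not in PANELS:
            raise ValueError(
                f"sample {self.sample_id}: panel must be one of {PANELS}, got {self.panel!r}"
            )


@dataclass
class GenotypePanel:
    """Markers x samples dosage matrix with marker and sample metadata.

    ``dosage[i, j]`` is the alternate-allele count of sample ``j`` at marker
    ``i``: 0/1/2 for called genotypes, NaN for missing, fractional in [0, 2]
    only for mean-imputed entries (exactly those flagged in ``imputed_mask``).
    Markers are kept sorted by (chromosome, position, marker_id).
    """

    markers: list[MarkerRecord]
    samples: list[SampleRecord]
    dosage: np.ndarray
    imputed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros(self.dosage.shape, dtype=bool)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        self.validate()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_parts(
        cls,
        markers: Sequence[MarkerRecord],
        samples: Sequence[SampleRecord],
        dosage: np.ndarray,
        imputed_mask: np.ndarray | None = None,
        sort: bool = True,
    ) -> "GenotypePanel":
        markers = list(markers)
        dosage = np.asarray(dosage, dtype=float)
        if imputed_mask is None:
            imputed_mask = np.zeros(dosage.shape, dtype=bool)
        if sort:
            order = sorted(
                range(len(markers)),
                key=lambda i: (
                    chromosome_sort_key(markers[i].chromosome),
                    markers[i].position,
                    markers[i].marker_id,
                ),
            )
            markers = [markers[i] for i in order]
            dosage = dosage[order]
            imputed_mask = np.asarray(imputed_mask, dtype=bool)[order]
        return cls(markers, list(samples), dosage, imputed_mask)

    def validate(self) -> None:
        if self.dosage.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        if self.imputed_mask.shape != self.dosage.shape:
            raise ValueError("imputed_mask shape does not match dosage shape")
        called = self.dosage[~np.isnan(self.dosage)]
        if called.size and (called.min() < 0 or called.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in panel")
        mids = [m.marker_id for m in self.markers]
        if len(set(mids)) != len(mids):
            raise ValueError("duplicate marker_id in panel")

    # -- accessors ------------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([m.chromosome for m in self.markers], dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position for m in self.markers], dtype=np.int64)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in panel") from None

    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            if s.family_id is not None:
                seen.setdefault(s.family_id, None)
        return list(seen)

    def split_families(self) -> dict[str, "GenotypePanel"]:
        """One sub-panel per family, in first-appearance order."""
        return {fam: subset_panel(self, families=[fam]) for fam in self.family_ids()}

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            list(self.markers),
            list(self.samples),
            self.dosage.copy(),
            self.imputed_mask.copy(),
        )


# ---------------------------------------------------------------------------
# HapMap parsing


def _parse_genotype_cell(cell: str) -> tuple[str, str] | None:
    """Return the (unordered) allele pair of a genotype call, or None if missing."""
    cell = cell.strip().upper()
    if cell in ("", "N", "NN", "NA", "--", "./."):
        return None
    if len(cell) == 1:
        if cell in _BASES:
            return (cell, cell)
        if cell in _IUPAC_HET:
            return _IUPAC_HET[cell]
        raise GenotypeCodeError(f"unrecognized genotype code {cell!r}")
    if len(cell) == 2:
        a, b = cell[0], cell[1]
        if a in _BASES and b in _BASES:
            return (a, b)
        if "N" in (a, b):
            return None
        raise GenotypeCodeError(f"unrecognized genotype code {cell!r}")
    raise GenotypeCodeError(f"unrecognized genotype code {cell!r}")


def _normalize_chrom(raw: str) -> str:
    label = raw.strip().upper()
    if label.startswith("CHR"):
        label = label[3:]
    if label in CHROMOSOMES:
        return label
    return "UN"


def read_hapmap(path: str | Path, metadata: str | Path | None = None) -> GenotypePanel:
    """Read a tab-separated HapMap (hmp.txt) genotype file into a panel.

    Genotype cells may be one-character IUPAC codes (heterozygotes as ambiguity
    codes) or two-character diploid codes; 'N'/'NN' is missing. The alternate
    allele of each marker is the minor allele at load time (ties broken
    alphabetically). An optional sample-metadata TSV (sample_id/family_id/
    stage/panel) is attached when given.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    header = list(df.columns)
    if len(header) < len(HAPMAP_COLUMNS):
        raise HapMapParseError(
            f"{path.name}: expected at least {len(HAPMAP_COLUMNS)} HapMap columns, "
            f"got {len(header)}"
        )
    for i, expected in enumerate(HAPMAP_COLUMNS):
        got = header[i].strip()
        # tolerate the 'assembly' vs 'assembly#' dialect difference
        if got.lower().rstrip("#") != expected.lower().rstrip("#"):
            raise HapMapParseError(
                f"{path.name}: HapMap header column {i + 1} should be "
                f"{expected!r}, got {got!r}"
            )
    sample_cols = header[len(HAPMAP_COLUMNS):]
    samples = [SampleRecord(sample_id=s) for s in sample_cols]

    markers: list[MarkerRecord] = []
    rows: list[np.ndarray] = []
    seen_ids: set[str] = set()
    geno = df[sample_cols].to_numpy(dtype=object) if sample_cols else np.empty((len(df), 0), object)

    for r in range(len(df)):
        marker_id = str(df.iloc[r, 0]).strip()
        if marker_id in seen_ids:
            raise HapMapParseError(f"{path.name}: duplicate marker_id {marker_id!r}")
        seen_ids.add(marker_id)
        chrom = _normalize_chrom(str(df.iloc[r, 2]))
        try:
            pos = int(str(df.iloc[r, 3]).strip())
        except ValueError:
            raise HapMapParseError(
                f"{path.name}: marker {marker_id}: unparsable position {df.iloc[r, 3]!r}"
            ) from None

        declared: tuple[str, str] | None = None
        alleles_field = str(df.iloc[r, 1]).strip().upper()
        if "/" in alleles_field:
            parts = alleles_field.split("/")
            if len(parts) == 2 and all(p in _BASES for p in parts) and parts[0] != parts[1]:
                declared = (parts[0], parts[1])

        calls: list[tuple[str, str] | None] = []
        counts: dict[str, int] = {}
        for c, sample_id in enumerate(sample_cols):
            try:
                pair = _parse_genotype_cell(str(geno[r, c]))
            except GenotypeCodeError as exc:
                raise GenotypeCodeError(
                    f"marker {marker_id}, sample {sample_id}: {exc}"
                ) from None
            if pair is not None and declared is not None:
                for a in pair:
                    if a not in declared:
                        raise GenotypeCodeError(
                            f"marker {marker_id}, sample {sample_id}: genotype "
                            f"{''.join(pair)!r} inconsistent with alleles "
                            f"{'/'.join(declared)}"
                        )
            calls.append(pair)
            if pair is not None:
                for a in pair:
                    counts[a] = counts.get(a, 0) + 1

        observed = sorted(counts)
        if len(observed) > 2:
            offenders = [
                (sample_cols[c], calls[c])
                for c in range(len(calls))
                if calls[c] is not None and any(a not in observed[:2] for a in calls[c])
            ]
            sample_id, pair = offenders[-1] if offenders else (sample_cols[0], None)
            raise GenotypeCodeError(
                f"marker {marker_id}, sample {sample_id}: more than two alleles "
                f"observed ({', '.join(observed)})"
            )
        if declared is not None:
            allele_universe = list(declared)
        elif len(observed) == 2:
            allele_universe = observed
        elif len(observed) == 1:
            other = next(b for b in _BASES if b != observed[0])
            allele_universe = [observed[0], other]
        else:  # fully missing marker
            allele_universe = ["A", "C"]

        # alternate allele = minor at load time; ties -> alphabetically later
        n_a = counts.get(allele_universe[0], 0)
        n_b = counts.get(allele_universe[1], 0)
        if n_a > n_b:
            ref, alt = allele_universe[0], allele_universe[1]
        elif n_b > n_a:
            ref, alt = allele_universe[1], allele_universe[0]
        else:
            ref, alt = sorted(allele_universe)

        row = np.full(len(sample_cols), np.nan)
        for c, pair in enumerate(calls):
            if pair is None:
                continue
            row[c] = (pair[0] == alt) + (pair[1] == alt)
        markers.append(MarkerRecord(marker_id, chrom, pos, ref, alt))
        rows.append(row)

    dosage = np.vstack(rows) if rows else np.empty((0, len(sample_cols)))
    panel = GenotypePanel.from_parts(markers, samples, dosage)
    if metadata is not None:
        panel = attach_sample_metadata(panel, read_sample_metadata(metadata))
    return panel


def write_hapmap(
    panel: GenotypePanel,
    path: str | Path,
    metadata_path: str | Path | None = None,
    mask_path: str | Path | None = None,
) -> None:
    """Write a panel as a HapMap file (two-character genotypes, 'NN' missing).

    Imputed (fractional) entries are emitted as missing; ``mask_path`` records
    them in a sidecar table (marker_id, sample_id, imputed_dosage) so the
    imputation is auditable. Sample metadata goes to a sidecar TSV when
    ``metadata_path`` is given.
    """
    if mask_path is not None:
        rows, cols = np.nonzero(panel.imputed_mask)
        pd.DataFrame(
            {
                "marker_id": [panel.markers[i].marker_id for i in rows],
                "sample_id": [panel.samples[j].sample_id for j in cols],
                "imputed_dosage": [panel.dosage[i, j] for i, j in zip(rows, cols)],
            }
        ).to_csv(mask_path, sep="\t", index=False)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS + tuple(panel.sample_ids)) + "\n")
        for i, m in enumerate(panel.markers):
            cells = []
            for j in range(panel.n_samples):
                d = panel.dosage[i, j]
                if np.isnan(d) or panel.imputed_mask[i, j] or d not in (0.0, 1.0, 2.0):
                    cells.append("NN")
                elif d == 0.0:
                    cells.append(m.ref_allele * 2)
                elif d == 2.0:
                    cells.append(m.alt_allele * 2)
                else:
                    cells.append(m.ref_allele + m.alt_allele)
            meta = [
                m.marker_id,
                f"{m.ref_allele}/{m.alt_allele}",
                m.chromosome,
                str(m.position),
                "+",
                "NA",
                "NA",
                "NA",
                "NA",
                "NA",
                "NA",
            ]
            fh.write("\t".join(meta + cells) + "\n")
    if metadata_path is not None:
        write_sample_metadata(panel, metadata_path)


def read_sample_metadata(path: str | Path) -> dict[str, SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    required = {"sample_id", "family_id", "stage", "panel"}
    if not required.issubset(df.columns):
        raise HapMapParseError(
            f"sample metadata must have columns {sorted(required)}, got {list(df.columns)}"
        )
    out: dict[str, SampleRecord] = {}
    for _, row in df.iterrows():
        out[row["sample_id"]] = SampleRecord(
            sample_id=row["sample_id"],
            family_id=row["family_id"] or None,
            stage=row["stage"] or None,
            panel=row["panel"] or None,
        )
    return out


def write_sample_metadata(panel: GenotypePanel, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in panel.samples],
            "family_id": [s.family_id or "" for s in panel.samples],
            "stage": [s.stage or "" for s in panel.samples],
            "panel": [s.panel or "" for s in panel.samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def attach_sample_metadata(
    panel: GenotypePanel, metadata: Mapping[str, SampleRecord]
) -> GenotypePanel:
    samples = [metadata.get(s.sample_id, s) for s in panel.samples]
    return GenotypePanel(list(panel.markers), samples, panel.dosage, panel.imputed_mask)


# ---------------------------------------------------------------------------
# Marker statistics and QC filters


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one marker's dosage values (NaN = missing)."""
    d = np.asarray(dosages, dtype=float)
    called = d[~np.isnan(d)]
    if called.size == 0:
        raise ValueError("MAF undefined: all dosage values missing")
    p = called.sum() / (2.0 * called.size)
    return float(min(p, 1.0 - p))


def marker_stats(panel: GenotypePanel) -> pd.DataFrame:
    """Per-marker MAF, missing fraction, heterozygote fraction (pre-imputation)."""
    d = panel.dosage
    missing = np.isnan(d)
    n_called = (~missing).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=1) / (2.0 * np.maximum(n_called, 1))
        maf = np.minimum(p, 1.0 - p)
    maf = np.where(n_called > 0, maf, np.nan)
    missing_frac = missing.mean(axis=1) if panel.n_samples else np.zeros(panel.n_markers)
    het_frac = np.where(
        n_called > 0, (d == 1.0).sum(axis=1) / np.maximum(n_called, 1), np.nan
    )
    return pd.DataFrame(
        {
            "marker_id": panel.marker_ids,
            "maf": maf,
            "missing_frac": missing_frac,
            "het_frac": het_frac,
        }
    ).set_index("marker_id")


def filter_markers(panel: GenotypePanel, config: AnalysisConfig | None = None) -> GenotypePanel:
    """Apply the genotyping-pipeline marker filters.

    Removal is strict, as printed: MAF < ``maf_min_pipeline``, missing fraction
    > ``max_missing``, or heterozygote fraction > ``max_het``. Idempotent; an
    empty survivor set yields a warning-carrying empty panel, not an error.
    """
    if config is None:
        config = AnalysisConfig()
    if panel.imputed_mask.any():
        raise ValueError("filter_markers must run before imputation")
    stats = marker_stats(panel)
    keep = (
        (stats["maf"].to_numpy() >= config.maf_min_pipeline)
        & (stats["missing_frac"].to_numpy() <= config.max_missing)
        & (stats["het_frac"].to_numpy() <= config.max_het)
    )
    keep &= ~np.isnan(stats["maf"].to_numpy())
    if not keep.any():
        warnings.warn("all markers removed by pipeline filters", stacklevel=2)
    idx = np.flatnonzero(keep)
    return GenotypePanel(
        [panel.markers[i] for i in idx],
        list(panel.samples),
        panel.dosage[idx],
        panel.imputed_mask[idx],
    )


def impute_mean(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages by the marker mean (column-mean imputation)."""
    dosage = panel.dosage.copy()
    mask = panel.imputed_mask.copy()
    missing = np.isnan(dosage)
    n_called = (~missing).sum(axis=1)
    for i in np.flatnonzero(n_called == 0):
        raise ValueError(
            f"marker {panel.markers[i].marker_id}: no called genotypes to impute from"
        )
    means = np.nansum(dosage, axis=1) / np.maximum(n_called, 1)
    rows, cols = np.nonzero(missing)
    dosage[rows, cols] = means[rows]
    mask[rows, cols] = True
    return GenotypePanel(list(panel.markers), list(panel.samples), dosage, mask)


def subset_panel(
    panel: GenotypePanel,
    families: Iterable[str] | None = None,
    stages: Iterable[str] | None = None,
    panels: Iterable[str] | None = None,
    sample_ids: Iterable[str] | None = None,
    marker_ids: Iterable[str] | None = None,
) -> GenotypePanel:
    """Restrict a panel by family/stage/panel labels, sample ids, or marker set.

    Selectors combine conjunctively; ordering is preserved. Unknown labels
    raise KeyError listing the available ones.
    """
    keep = np.ones(panel.n_samples, dtype=bool)

    def _check(requested, available, what):
        unknown = set(requested) - set(available)
        if unknown:
            raise KeyError(
                f"unknown {what} {sorted(unknown)}; available: {sorted(set(available) - {None})}"
            )

    if families is not None:
        families = list(families)
        _check(families, [s.family_id for s in panel.samples], "family_id")
        keep &= np.array([s.family_id in families for s in panel.samples])
    if stages is not None:
        stages = list(stages)
        _check(stages, STAGES, "stage")
        keep &= np.array([s.stage in stages for s in panel.samples])
    if panels is not None:
        panels = list(panels)
        _check(panels, PANELS, "panel")
        keep &= np.array([s.panel in panels for s in panel.samples])
    if sample_ids is not None:
        sample_ids = list(sample_ids)
        _check(sample_ids, panel.sample_ids, "sample_id")
        keep &= np.array([s.sample_id in sample_ids for s in panel.samples])

    cols = np.flatnonzero(keep)
    if marker_ids is not None:
        marker_ids = list(marker_ids)
        _check(marker_ids, panel.marker_ids, "marker_id")
        wanted = set(marker_ids)
        rows = np.array(
            [i for i, m in enumerate(panel.markers) if m.marker_id in wanted], dtype=int
        )
    else:
        rows = np.arange(panel.n_markers)

    return GenotypePanel(
        [panel.markers[i] for i in rows],
        [panel.samples[j] for j in cols],
        panel.dosage[np.ix_(rows, cols)],
        panel.imputed_mask[np.ix_(rows, cols)],
    )
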