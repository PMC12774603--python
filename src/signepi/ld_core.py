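"""Pairwise r^2 linkage disequilibrium on dosage vectors and interchromosomal scans.

r^2 is the squared Pearson correlation of allele dosages. For nearly fully
inbred F5-derived lines this coincides with the classical haplotype-frequency
r^2 (an exact haplotype-counting mode is provided for fully homozygous panels
and used as an independent cross-check), and it remains well defined on
fractional mean-imputed dosages where haplotype counting is not.

Undefined values (a marker monomorphic in the sample group, or fewer than two
paired observations) are represented as NaN and fail every threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypePanel, chromosome_sort_key, marker_stats

__all__ = [
    "LDMatrix",
    "FlankingWindowLD",
    "BlockCall",
    "ScanHit",
    "pairwise_r2",
    "haplotype_r2",
    "r2_matrix",
    "r2_pairs",
    "interchromosomal_scan",
    "flanking_window_ld",
    "detect_interchromosomal_block",
    "interchromosomal_mask",
    "mask_heterozygous_calls",
    "write_scan_tsv",
    "write_ld_matrix_tsv",
    "plot_flanking_heatmap",
]

# Variance below this (times n^2) is treated as monomorphic; dosages are in
# [0, 2] so any truly polymorphic vector has variance far above it.
_VAR_TOL = 1e-10


@dataclass
class LDMatrix:
    """r^2 values between a row marker set and a column marker set (NaN = undefined)."""

    row_markers: list[str]
    col_markers: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_markers), len(self.col_markers)):
            raise ValueError("LDMatrix shape does not match marker lists")


@dataclass
class FlankingWindowLD:
    """The three LD quadrants of two candidate loci and their flanking windows."""

    marker_a: str
    marker_b: str
    window_a: list[str]
    window_b: list[str]
    intra_a: LDMatrix
    intra_b: LDMatrix
    inter_ab: LDMatrix


@dataclass(frozen=True)
class BlockCall:
    """A run of flanking markers in strong LD with the partner locus's window."""

    side: str  # "A" or "B"
    start_marker: str
    end_marker: str
    n_markers: int
    mean_inter_r2: float


class ScanHit(NamedTuple):
    marker_a: str
    marker_b: str
    r2: float


def _paired(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"dosage vectors must be 1-D of equal length, got {x.shape} vs {y.shape}")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors on their paired mask.

    Returns NaN when fewer than two paired observations exist or either vector
    is constant on the paired mask; otherwise a value in [0, 1]. Symmetric and
    invariant under the allele flip d -> 2 - d of either vector.
    """
    xs, ys = _paired(x, y)
    n = xs.size
    if n < 2:
        return float("nan")
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx <= _VAR_TOL * n or sy <= _VAR_TOL * n:
        return float("nan")
    r2 = float(xc @ yc) ** 2 / (sx * sy)
    return float(min(max(r2, 0.0), 1.0))


def haplotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Haplotype-frequency r^2 = D^2 / (pA pa pB pb) by direct 2x2 counting.

    Only valid on fully homozygous, fully called dosage vectors (each inbred
    line contributes two identical haplotypes). Used as the independent
    cross-check for the dosage-correlation estimator on inbred panels.
    """
    xs, ys = _paired(x, y)
    if xs.size != np.asarray(x).size:
        raise ValueError("haplotype_r2 requires fully called vectors")
    if np.any((xs != 0) & (xs != 2)) or np.any((ys != 0) & (ys != 2)):
        raise ValueError("haplotype_r2 requires fully homozygous dosages (0 or 2)")
    n = xs.size
    if n < 2:
        return float("nan")
    pa = (xs == 2).mean()
    pb = (ys == 2).mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = ((xs == 2) & (ys == 2)).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _r2_block(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized pairwise-complete squared correlation between row sets."""
    if not (np.isnan(X).any() or np.isnan(Y).any()):
        n = X.shape[1]
        xc = X - X.mean(axis=1, keepdims=True)
        yc = Y - Y.mean(axis=1, keepdims=True)
        sx = np.einsum("ij,ij->i", xc, xc)
        sy = np.einsum("ij,ij->i", yc, yc)
        num = xc @ yc.T
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = num**2 / np.outer(sx, sy)
        r2[sx <= _VAR_TOL * n, :] = np.nan
        r2[:, sy <= _VAR_TOL * n] = np.nan
        if n < 2:
            r2[:] = np.nan
        return np.clip(r2, 0.0, 1.0)

    symmetric = Y is X
    Mxf = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X)
    Xsq = X0 * X0
    if symmetric:
        Myf, Y0, Ysq = Mxf, X0, Xsq
    else:
        Myf = (~np.isnan(Y)).astype(float)
        Y0 = np.nan_to_num(Y)
        Ysq = Y0 * Y0
    N = Mxf @ Myf.T
    Sx = X0 @ Myf.T
    Sy = Sx.T.copy() if symmetric else Mxf @ Y0.T
    Sxx = Xsq @ Myf.T
    Syy = Sxx.T.copy() if symmetric else Mxf @ Ysq.T
    Sxy = X0 @ Y0.T
    num = N * Sxy
    num -= Sx * Sy
    denx = N * Sxx
    denx -= Sx * Sx
    deny = N * Syy
    deny -= Sy * Sy
    np.square(num, out=num)
    den = denx * deny
    undefined = (N < 2) | (denx <= _VAR_TOL * N * N) | (deny <= _VAR_TOL * N * N)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = num / den
    r2[undefined] = np.nan
    return np.clip(r2, 0.0, 1.0, out=r2)


def r2_matrix(
    panel: GenotypePanel,
    rows: Sequence[str] | None = None,
    cols: Sequence[str] | None = None,
) -> LDMatrix:
    """All-pairs r^2 between two marker sets of a panel.

    Agrees with element-wise :func:`pairwise_r2` to numerical round-off; whole
    rows/columns are NaN for markers monomorphic in the panel's samples.
    """
    row_ids = list(rows) if rows is not None else panel.marker_ids
    col_ids = list(cols) if cols is not None else panel.marker_ids
    if not row_ids or not col_ids:
        raise ValueError("marker sets must be non-empty")
    ridx = [panel.marker_index(m) for m in row_ids]
    cidx = [panel.marker_index(m) for m in col_ids]
    values = _r2_block(panel.dosage[ridx], panel.dosage[cidx])
    return LDMatrix(row_ids, col_ids, values)


def r2_pairs(dosage: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """r^2 for an explicit list of row-index pairs of a dosage matrix."""
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    out = np.empty(idx_a.size, dtype=float)
    X = dosage[idx_a]
    Y = dosage[idx_b]
    if not (np.isnan(X).any() or np.isnan(Y).any()):
        n = X.shape[1]
        xc = X - X.mean(axis=1, keepdims=True)
        yc = Y - Y.mean(axis=1, keepdims=True)
        sx = np.einsum("ij,ij->i", xc, xc)
        sy = np.einsum("ij,ij->i", yc, yc)
        num = np.einsum("ij,ij->i", xc, yc)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = num**2 / (sx * sy)
        out[(sx <= _VAR_TOL * n) | (sy <= _VAR_TOL * n)] = np.nan
        if n < 2:
            out[:] = np.nan
        return np.clip(out, 0.0, 1.0)
    # pairwise-complete path, vectorized over the pair axis
    M = ~(np.isnan(X) | np.isnan(Y))
    X0 = np.where(M, np.nan_to_num(X), 0.0)
    Y0 = np.where(M, np.nan_to_num(Y), 0.0)
    n = M.sum(axis=1).astype(float)
    sx = X0.sum(axis=1)
    sy = Y0.sum(axis=1)
    sxx = np.einsum("ij,ij->i", X0, X0)
    syy = np.einsum("ij,ij->i", Y0, Y0)
    sxy = np.einsum("ij,ij->i", X0, Y0)
    num = n * sxy - sx * sy
    denx = n * sxx - sx**2
    deny = n * syy - sy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num**2 / (denx * deny)
    out[(n < 2) | (denx <= _VAR_TOL * n**2) | (deny <= _VAR_TOL * n**2)] = np.nan
    return np.clip(out, 0.0, 1.0)


def mask_heterozygous_calls(panel: GenotypePanel) -> GenotypePanel:
    """Copy of a panel with heterozygous calls (dosage 1) set to missing.

    In F5-derived, mostly homozygous lines the residual heterozygous calls are
    phase-ambiguous and disproportionately genotyping errors; LD screens on
    such panels conventionally restrict to homozygous calls. Allelic-
    combination counting is unaffected (it reads the original panel).
    """
    dosage = panel.dosage.copy()
    dosage[dosage == 1.0] = np.nan
    return GenotypePanel(list(panel.markers), list(panel.samples), dosage, panel.imputed_mask)


def interchromosomal_mask(chromosomes: np.ndarray) -> np.ndarray:
    """Boolean matrix: True where the row and column markers lie on different
    chromosomes and neither is unplaced (UN)."""
    chroms = np.asarray(chromosomes, dtype=object)
    diff = chroms[:, None] != chroms[None, :]
    placed = chroms != "UN"
    return diff & placed[:, None] & placed[None, :]


def interchromosomal_scan(
    panel: GenotypePanel,
    maf_min: float = 0.0,
    r2_min: float = 0.9,
    block_size: int = 512,
    het_as_missing: bool = True,
) -> list[ScanHit]:
    """Every interchromosomal marker pair with MAF > ``maf_min`` at both markers
    and r^2 >= ``r2_min``.

    Unplaced (UN) markers and pairs on the same chromosome are excluded;
    monomorphic markers yield undefined r^2 and can never appear. MAF is
    computed on all calls, but r^2 is restricted to homozygous calls by
    default (see :func:`mask_heterozygous_calls`). Output is sorted by
    descending r^2, ties by (chromosome, position, marker_id) of the first
    marker.
    """
    stats = marker_stats(panel)
    maf = stats["maf"].to_numpy()
    chroms = panel.chromosomes
    eligible = (maf > maf_min) & ~np.isnan(maf) & (chroms != "UN")
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return []
    ld_panel = mask_heterozygous_calls(panel) if het_as_missing else panel
    sub = ld_panel.dosage[idx]
    sub_chroms = chroms[idx]
    hits: list[tuple[int, int, float]] = []
    for start in range(0, idx.size, block_size):
        stop = min(start + block_size, idx.size)
        r2 = _r2_block(sub[start:stop], sub)
        ok = np.zeros_like(r2, dtype=bool)
        with np.errstate(invalid="ignore"):
            np.greater_equal(r2, r2_min, out=ok, where=~np.isnan(r2))
        ok &= sub_chroms[start:stop, None] != sub_chroms[None, :]
        # keep each unordered pair once (global row index < column index)
        cols = np.arange(idx.size)[None, :]
        ok &= (np.arange(start, stop)[:, None]) < cols
        for i, j in zip(*np.nonzero(ok)):
            hits.append((start + i, j, float(r2[i, j])))

    def sort_key(hit: tuple[int, int, float]):
        i, j, r2v = hit
        m = panel.markers[idx[i]]
        return (-r2v, chromosome_sort_key(m.chromosome), m.position, m.marker_id)

    hits.sort(key=sort_key)
    out = []
    for i, j, r2v in hits:
        out.append(
            ScanHit(panel.markers[idx[i]].marker_id, panel.markers[idx[j]].marker_id, r2v)
        )
    return out


def flanking_window_ld(
    panel: GenotypePanel,
    marker_a: str,
    marker_b: str,
    n_flank_per_side: int = 20,
    het_as_missing: bool = True,
) -> FlankingWindowLD:
    """LD quadrants of the windows of up to ``n_flank_per_side`` markers on each
    side of two candidate loci (map order; truncated at chromosome ends)."""
    ia = panel.marker_index(marker_a)
    ib = panel.marker_index(marker_b)
    if het_as_missing:
        panel = mask_heterozygous_calls(panel)
    if panel.markers[ia].chromosome == panel.markers[ib].chromosome:
        raise ValueError("candidate markers must lie on different chromosomes")

    def window_ids(center: int) -> list[str]:
        chrom = panel.markers[center].chromosome
        chrom_idx = [i for i, m in enumerate(panel.markers) if m.chromosome == chrom]
        k = chrom_idx.index(center)
        lo = max(0, k - n_flank_per_side)
        hi = min(len(chrom_idx), k + n_flank_per_side + 1)
        return [panel.markers[i].marker_id for i in chrom_idx[lo:hi]]

    win_a = window_ids(ia)
    win_b = window_ids(ib)
    return FlankingWindowLD(
        marker_a=marker_a,
        marker_b=marker_b,
        window_a=win_a,
        window_b=win_b,
        intra_a=r2_matrix(panel, win_a, win_a),
        intra_b=r2_matrix(panel, win_b, win_b),
        inter_ab=r2_matrix(panel, win_a, win_b),
    )


def detect_interchromosomal_block(
    window: FlankingWindowLD,
    block_r2: float = 0.5,
    block_min_run: int = 3,
) -> list[BlockCall]:
    """Maximal runs of consecutive flanking markers whose best inter-quadrant
    r^2 exceeds ``block_r2``; runs shorter than ``block_min_run`` are dropped.

    An empty list is the negative-control outcome (no interchromosomal block).
    """
    calls: list[BlockCall] = []
    inter = window.inter_ab.values
    for side, ids, best in (
        ("A", window.window_a, np.nanmax(inter, axis=1) if inter.size else np.array([])),
        ("B", window.window_b, np.nanmax(inter, axis=0) if inter.size else np.array([])),
    ):
        with np.errstate(invalid="ignore"):
            above = np.zeros(best.shape, dtype=bool)
            np.greater(best, block_r2, out=above, where=~np.isnan(best))
        start = None
        for k in range(above.size + 1):
            if k < above.size and above[k]:
                if start is None:
                    start = k
            elif start is not None:
                if k - start >= block_min_run:
                    calls.append(
                        BlockCall(
                            side=side,
                            start_marker=ids[start],
                            end_marker=ids[k - 1],
                            n_markers=k - start,
                            mean_inter_r2=float(np.mean(best[start:k])),
                        )
                    )
                start = None
    return calls


# ---------------------------------------------------------------------------
# Tabular / graphical export


def write_scan_tsv(panel: GenotypePanel, hits: Sequence[ScanHit], path: str | Path) -> None:
    rows = []
    for hit in hits:
        ma = panel.markers[panel.marker_index(hit.marker_a)]
        mb = panel.markers[panel.marker_index(hit.marker_b)]
        rows.append(
            {
                "markerA": ma.marker_id,
                "chromA": ma.chromosome,
                "posA": ma.position,
                "markerB": mb.marker_id,
                "chromB": mb.chromosome,
                "posB": mb.position,
                "r2": hit.r2,
            }
        )
    pd.DataFrame(
        rows, columns=["markerA", "chromA", "posA", "markerB", "chromB", "posB", "r2"]
    ).to_csv(path, sep="\t", index=False)


def write_ld_matrix_tsv(matrix: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.values, index=matrix.row_markers, columns=matrix.col_markers).to_csv(
        path, sep="\t"
    )


def plot_flanking_heatmap(window: FlankingWindowLD, path: str | Path) -> None:
    """2D LD heatmap of the two windows: intra quadrants on the diagonal,
    the interchromosomal quadrant off-diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    na, nb = len(window.window_a), len(window.window_b)
    full = np.full((na + nb, na + nb), np.nan)
    full[:na, :na] = window.intra_a.values
    full[na:, na:] = window.intra_b.values
    full[:na, na:] = window.inter_ab.values
    full[na:, :na] = window.inter_ab.values.T
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(full, vmin=0, vmax=1, cmap="Reds", interpolation="nearest")
    ax.axhline(na - 0.5, color="black", lw=0.8)
    ax.axvline(na - 0.5, color="black", lw=0.8)
    ax.set_title(f"{window.marker_a} x {window.marker_b}")
    ax.set_xlabel("window A | window B")
    ax.set_ylabel("window A | window B")
    fig.colorbar(im, ax=ax, label="$r^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
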