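"""End-to-end orchestration: discovery and validation runs with manifests.

Each run writes deterministic tab-separated tables plus a JSON manifest
carrying the configuration snapshot, input/output content digests, and
per-step row counts, so a rerun with identical inputs is auditable down to
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .combination_analysis import (
    classify_family_pattern,
    combination_table,
    favored_and_opposed,
    program_share_test,
    single_marker_flag,
    stage_frequency_track,
    validation_verdict,
)
from .config import AnalysisConfig
from .discovery import (
    Interaction,
    PairHit,
    Region,
    detect_multiway,
    discovery_marker_set,
    group_regions,
    pca_outlier_filter,
    per_family_screen,
    combined_screen,
    select_candidates,
)
from .genotype_io import GenotypePanel, filter_markers, read_hapmap, subset_panel

__all__ = [
    "RunManifest",
    "run_discovery_pipeline",
    "run_validation_pipeline",
    "write_interactions_tsv",
    "read_interactions_tsv",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    tool_version: str
    seed: int | None
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    steps: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _sha256(Path(path))

    def add_step(self, name: str, rows_in: int, rows_out: int, seconds: float) -> None:
        self.steps.append(
            {"name": name, "rows_in": rows_in, "rows_out": rows_out, "seconds": round(seconds, 3)}
        )

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = _sha256(Path(path))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Tabular serialization of discovery outputs


def write_pair_hits_tsv(hits: Sequence[PairHit], markers: Mapping, path: str | Path) -> None:
    rows = []
    for h in hits:
        ma, mb = markers[h.marker_a], markers[h.marker_b]
        fam = ";".join(
            f"{f}={v:.6g}" if not np.isnan(v) else f"{f}=NA"
            for f, v in sorted(h.family_r2.items())
        )
        rows.append(
            {
                "marker_a": h.marker_a,
                "chrom_a": ma.chromosome,
                "pos_a": ma.position,
                "marker_b": h.marker_b,
                "chrom_b": mb.chromosome,
                "pos_b": mb.position,
                "combined_r2": h.combined_r2,
                "n_families_passing": h.n_families_passing,
                "family_r2": fam,
            }
        )
    cols = [
        "marker_a", "chrom_a", "pos_a", "marker_b", "chrom_b", "pos_b",
        "combined_r2", "n_families_passing", "family_r2",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_regions_tsv(regions: Sequence[Region], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "chromosome": r.chromosome,
                "start": r.start,
                "end": r.end,
                "n_markers": r.n_markers,
                "members": ",".join(r.member_markers),
            }
            for r in regions
        ],
        columns=["region_id", "chromosome", "start", "end", "n_markers", "members"],
    ).to_csv(path, sep="\t", index=False)


def _representative_loci(interaction: Interaction) -> list[str]:
    """One marker per region: the member of the strongest pair touching it."""
    reps = []
    for region in interaction.regions:
        members = set(region.member_markers)
        best, best_r2 = None, -1.0
        for pair in interaction.member_pairs:
            for mid in (pair.marker_a, pair.marker_b):
                if mid in members and pair.combined_r2 > best_r2:
                    best, best_r2 = mid, pair.combined_r2
        reps.append(best if best is not None else region.member_markers[0])
    return reps


def write_interactions_tsv(interactions: Sequence[Interaction], path: str | Path) -> None:
    rows = []
    for ia in interactions:
        rows.append(
            {
                "interaction_id": ia.interaction_id,
                "k": ia.k,
                "region_ids": ",".join(r.region_id for r in ia.regions),
                "chromosomes": ",".join(r.chromosome for r in ia.regions),
                "starts": ",".join(str(r.start) for r in ia.regions),
                "ends": ",".join(str(r.end) for r in ia.regions),
                "region_n_markers": ",".join(str(r.n_markers) for r in ia.regions),
                "region_members": ";".join(",".join(r.member_markers) for r in ia.regions),
                "rep_loci": ",".join(_representative_loci(ia)),
                "n_pairs": len(ia.member_pairs),
                "max_combined_r2": max((p.combined_r2 for p in ia.member_pairs), default=np.nan),
                "status": ia.status,
                "reason": ia.rejection_reason,
            }
        )
    cols = [
        "interaction_id", "k", "region_ids", "chromosomes", "starts", "ends",
        "region_n_markers", "region_members", "rep_loci", "n_pairs",
        "max_combined_r2", "status", "reason",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_interactions_tsv(path: str | Path) -> list[Interaction]:
    """Rebuild Interaction objects (regions + representative structure) from
    a discovery run's interactions.tsv; member pair r^2 profiles are not
    round-tripped (the validation rules do not need them)."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    out: list[Interaction] = []
    for _, row in df.iterrows():
        region_ids = row["region_ids"].split(",")
        chroms = row["chromosomes"].split(",")
        starts = [int(x) for x in row["starts"].split(",")]
        ends = [int(x) for x in row["ends"].split(",")]
        members = [m.split(",") for m in row["region_members"].split(";")]
        regions = tuple(
            Region(rid, chrom, s, e, mem)
            for rid, chrom, s, e, mem in zip(region_ids, chroms, starts, ends, members)
        )
        ia = Interaction(
            interaction_id=row["interaction_id"],
            regions=regions,
            member_pairs=[],
            status=row["status"],
            rejection_reason=row["reason"],
        )
        ia.rep_loci = row["rep_loci"].split(",")  # type: ignore[attr-defined]
        out.append(ia)
    return out


# ---------------------------------------------------------------------------
# Pipelines


def run_discovery_pipeline(
    panel_path: str | Path,
    meta_path: str | Path,
    config: AnalysisConfig,
    out_dir: str | Path,
    apply_pipeline_filters: bool = True,
) -> RunManifest:
    """Full discovery chain: read -> marker filters -> per-family PCA QC ->
    two-stage screen -> region grouping -> multi-way assembly, writing
    pair_hits.tsv, regions.tsv, interactions.tsv and manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(tool_version=__version__, seed=None, config=config.to_dict())
    manifest.add_input(panel_path)
    manifest.add_input(meta_path)

    t0 = time.perf_counter()
    panel = read_hapmap(panel_path, metadata=meta_path)
    manifest.add_step("read_hapmap", 0, panel.n_markers, time.perf_counter() - t0)

    if apply_pipeline_filters:
        t0 = time.perf_counter()
        filtered = filter_markers(panel, config)
        manifest.add_step(
            "filter_markers", panel.n_markers, filtered.n_markers, time.perf_counter() - t0
        )
        panel = filtered

    t0 = time.perf_counter()
    kept_ids: list[str] = []
    for fam, fam_panel in panel.split_families().items():
        kept, _removed = pca_outlier_filter(fam_panel, config.outlier_sd)
        kept_ids.extend(kept)
    kept_ids.extend(s.sample_id for s in panel.samples if s.family_id is None)
    qc_panel = subset_panel(panel, sample_ids=kept_ids)
    manifest.add_step(
        "pca_outlier_filter", panel.n_samples, qc_panel.n_samples, time.perf_counter() - t0
    )

    t0 = time.perf_counter()
    marker_set = discovery_marker_set(
        qc_panel, config.maf_min_discovery, per_family=config.maf_per_family
    )
    families = {f: p for f, p in qc_panel.split_families().items() if p.n_samples >= 2}
    fam_result = per_family_screen(
        families, config.r2_family, marker_set, het_as_missing=config.ld_het_as_missing
    )
    combined = combined_screen(
        qc_panel, config.r2_combined, marker_set, het_as_missing=config.ld_het_as_missing
    )
    markers = {m.marker_id: m for m in qc_panel.markers}
    hits = select_candidates(
        fam_result, combined, markers, config.min_families, config.average_family_mode
    )
    manifest.add_step("two_stage_screen", len(marker_set), len(hits), time.perf_counter() - t0)

    t0 = time.perf_counter()
    if hits:
        regions, interactions = group_regions(hits, markers, config.region_gap_bp)
        interactions = detect_multiway(interactions)
    else:
        regions, interactions = [], []
    manifest.add_step("group_regions", len(hits), len(interactions), time.perf_counter() - t0)

    pair_path = out_dir / "pair_hits.tsv"
    region_path = out_dir / "regions.tsv"
    ia_path = out_dir / "interactions.tsv"
    write_pair_hits_tsv(hits, markers, pair_path)
    write_regions_tsv(regions, region_path)
    write_interactions_tsv(interactions, ia_path)
    for p in (pair_path, region_path, ia_path):
        manifest.add_output(p)
    manifest.save(out_dir / "manifest.json")
    return manifest


def run_validation_pipeline(
    interactions_path: str | Path,
    validation_panel_path: str | Path,
    validation_meta_path: str | Path,
    program_panel_path: str | Path,
    program_meta_path: str | Path,
    config: AnalysisConfig,
    out_dir: str | Path,
) -> RunManifest:
    """Apply every falsification rule to each candidate interaction.

    Rules run in the published order — independent validation families, the
    pooled breeding-program opposed-share rule, the single-marker-region
    artifact rule — and the stage-wise combination shares are tracked across
    the breeding pipeline. An interaction rejected by any rule is rejected,
    with all triggered reasons recorded in order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(tool_version=__version__, seed=None, config=config.to_dict())
    for p in (
        interactions_path,
        validation_panel_path,
        validation_meta_path,
        program_panel_path,
        program_meta_path,
    ):
        manifest.add_input(p)

    interactions = read_interactions_tsv(interactions_path)
    vpanel = read_hapmap(validation_panel_path, metadata=validation_meta_path)
    ppanel = read_hapmap(program_panel_path, metadata=program_meta_path)

    pattern_rows: list[dict] = []
    verdict_rows: list[dict] = []
    stage_frames: list[pd.DataFrame] = []
    for ia in interactions:
        loci = getattr(ia, "rep_loci", None) or _representative_loci(ia)
        missing = [m for m in loci if m not in set(vpanel.marker_ids) | set(ppanel.marker_ids)]
        if missing:
            verdict_rows.append(
                {
                    "interaction_id": ia.interaction_id,
                    "status": "flagged",
                    "reasons": "markers_absent_from_validation_panel",
                    "evidence": json.dumps({"missing": missing}),
                }
            )
            continue

        pooled_table = combination_table(vpanel, loci, group_id="validation_pooled")
        favored, opposed = favored_and_opposed(pooled_table)
        patterns = []
        for fam in vpanel.family_ids():
            sub = [s.sample_id for s in vpanel.samples if s.family_id == fam]
            table = combination_table(vpanel, loci, group_id=fam, sample_ids=sub)
            call = classify_family_pattern(table, config, favored, opposed)
            patterns.append(call)
            pattern_rows.append(
                {
                    "interaction_id": ia.interaction_id,
                    "family_id": fam,
                    "label": call.label,
                    "favored": "/".join(call.favored),
                    "opposed": "/".join(call.opposed),
                    "off_share": call.off_share,
                }
            )
        v_family = validation_verdict(ia.interaction_id, patterns)

        prog_table = combination_table(ppanel, loci, group_id=ia.interaction_id)
        prog_fav, prog_opp = favored_and_opposed(prog_table)
        v_share = program_share_test(prog_table, config.opposite_min_share, prog_fav, prog_opp)
        v_single = single_marker_flag(ia)

        reasons = [
            v.reason
            for v in (v_family, v_share, v_single)
            if v.status == "rejected"
        ]
        if reasons:
            status = "rejected"
        elif any(v.status == "flagged" for v in (v_family, v_share, v_single)):
            status = "flagged"
        else:
            status = "retained"
        verdict_rows.append(
            {
                "interaction_id": ia.interaction_id,
                "status": status,
                "reasons": ",".join(reasons) if reasons else "none",
                "evidence": json.dumps(
                    {
                        "validation": v_family.evidence,
                        "program_share": v_share.evidence,
                        "single_marker": v_single.evidence,
                    },
                    default=str,
                ),
            }
        )

        stages = {s.stage for s in ppanel.samples if s.stage is not None}
        if len(stages) >= 1:
            track = stage_frequency_track(ppanel, loci, prog_fav, prog_opp)
            track.insert(0, "interaction_id", ia.interaction_id)
            stage_frames.append(track)

    patterns_path = out_dir / "pattern_calls.tsv"
    verdicts_path = out_dir / "verdicts.tsv"
    stages_path = out_dir / "stage_tracks.tsv"
    pd.DataFrame(
        pattern_rows,
        columns=["interaction_id", "family_id", "label", "favored", "opposed", "off_share"],
    ).to_csv(patterns_path, sep="\t", index=False)
    pd.DataFrame(
        verdict_rows, columns=["interaction_id", "status", "reasons", "evidence"]
    ).to_csv(verdicts_path, sep="\t", index=False)
    if stage_frames:
        pd.concat(stage_frames, ignore_index=True).to_csv(stages_path, sep="\t", index=False)
    else:
        pd.DataFrame(columns=["interaction_id", "stage", "total"]).to_csv(
            stages_path, sep="\t", index=False
        )
    for p in (patterns_path, verdicts_path, stages_path):
        manifest.add_output(p)
    manifest.add_step("validate", len(interactions), len(verdict_rows), 0.0)
    manifest.save(out_dir / "manifest.json")
    return manifest
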