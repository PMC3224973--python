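"""Map summary statistics, coverage diagnostics and pipeline driver.

Implements the summary tables a linkage-map study reports: per-group
length, marker count, density, interval counts, large-gap counts and
mean interval; the fraction of map length within a radius of a marker;
and a Marey-style collinearity check of genetic versus physical marker
order on the reconstructed pseudochromosomes.
"""

from __future__ import annotations

import bisect
import json
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import anchoring, integration, linkage, simulate
from .anchoring import MarkerHit, PseudochromosomeBuild
from .linkage import LinkageMap


def round2(x: float) -> float:
    """Round half-up to 2 decimals, the convention of printed map tables."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GroupSummary:
    group: str
    length_cM: float
    n_markers: int
    density_cM_per_marker: float
    n_intervals: int
    n_gaps_gt_threshold: int
    avg_interval_cM: float


@dataclass
class CollinearityReport:
    per_scaffold: dict[str, dict] = field(default_factory=dict)
    collinear_fraction: float = 1.0
    n_markers: int = 0
    flagged_scaffolds: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Table-style summaries

def summarize_map(linkage_map: LinkageMap, gap_threshold_cM: float = 15.0) -> list[GroupSummary]:
    """Per-group summary rows plus a total row (group name 'Total').

    Intervals are gaps between consecutive distinct positions (bins), so
    cosegregating markers do not inflate the interval count. The total
    row's average interval is the arithmetic mean of the per-group
    averages — the convention printed by classic map summary tables —
    while total length / total intervals is exposed separately by
    callers that want the pooled figure.
    """
    import warnings

    rows: list[GroupSummary] = []
    for g in linkage_map.groups:
        if not g.loci:
            warnings.warn(f"group {g.name} is empty, excluded from summary")
            continue
        positions = sorted({p for _, p in g.loci})
        n_int = len(positions) - 1
        gaps = [b - a for a, b in zip(positions[:-1], positions[1:])]
        length = g.length_cM
        n_mark = len(g.loci)
        rows.append(
            GroupSummary(
                group=g.name,
                length_cM=round(length, 1),
                n_markers=n_mark,
                density_cM_per_marker=round2(length / n_mark),
                n_intervals=n_int,
                n_gaps_gt_threshold=sum(1 for x in gaps if x > gap_threshold_cM),
                avg_interval_cM=round2(length / n_int) if n_int else 0.0,
            )
        )
    if rows:
        tot_len = sum(r.length_cM for r in rows)
        tot_mark = sum(r.n_markers for r in rows)
        tot_int = sum(r.n_intervals for r in rows)
        with_int = [r for r in rows if r.n_intervals]
        rows.append(
            GroupSummary(
                group="Total",
                length_cM=round(tot_len, 1),
                n_markers=tot_mark,
                density_cM_per_marker=round2(tot_len / tot_mark),
                n_intervals=tot_int,
                n_gaps_gt_threshold=sum(r.n_gaps_gt_threshold for r in rows),
                # decimal mean of the (2-dp) per-group averages, so an
                # exact .005 boundary still rounds half-up
                avg_interval_cM=float(
                    (sum(Decimal(repr(r.avg_interval_cM)) for r in with_int)
                     / len(with_int)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
                ) if with_int else 0.0,
            )
        )
    return rows


def marker_proximity(linkage_map: LinkageMap, radius_cM: float = 5.0) -> float:
    """Fraction of covered map length within ``radius_cM`` of a marker.

    An interval of length L between adjacent distinct positions is
    covered over min(L, 2*radius); the fraction pools all intervals.
    """
    covered = 0.0
    total = 0.0
    for g in linkage_map.groups:
        positions = sorted({p for _, p in g.loci})
        if len(positions) < 2:
            continue
        for a, b in zip(positions[:-1], positions[1:]):
            L = b - a
            total += L
            covered += min(L, 2.0 * radius_cM)
    return covered / total if total else 1.0


# ---------------------------------------------------------------------------
# Marey collinearity

def longest_nondecreasing_length(values: list[float]) -> int:
    """Length of the longest non-decreasing subsequence, O(n log n)."""
    tails: list[float] = []
    for v in values:
        k = bisect.bisect_right(tails, v)
        if k == len(tails):
            tails.append(v)
        else:
            tails[k] = v
    return len(tails)


def marey_collinearity(
    linkage_map: LinkageMap,
    build: PseudochromosomeBuild,
    hits: list[MarkerHit],
) -> CollinearityReport:
    """Genetic-vs-physical collinearity on the reconstructed chromosomes.

    Markers are projected onto pseudomolecule coordinates through the
    AGP components; per chromosome, a marker counts as collinear when it
    belongs to a longest non-decreasing subsequence of cM along bp. A
    scaffold is flagged when its own markers trend with negative slope
    (likely mis-orientation) or break monotonicity against neighbours.
    """
    pos_of = linkage_map.position_of()
    group_of = linkage_map.group_of()
    # scaffold -> (object, offset 1-based, orientation, length)
    placement = {
        c.component_id: (c.object, c.object_beg, c.orientation, c.component_end - c.component_beg + 1)
        for c in build.components
        if c.component_type == "W"
    }
    per_chrom: dict[str, list[tuple[float, float, str]]] = {}
    per_scaffold_pts: dict[str, list[tuple[float, float]]] = {}
    for h in hits:
        if not h.unique or h.marker_id not in pos_of or h.scaffold_id not in placement:
            continue
        obj, beg, orient, length = placement[h.scaffold_id]
        if group_of[h.marker_id] != obj:
            continue
        mid_bp = (h.amplicon_start_bp + h.amplicon_end_bp) / 2
        obj_bp = (beg - 1) + (mid_bp if orient == "+" else length - mid_bp)
        per_chrom.setdefault(obj, []).append((obj_bp, pos_of[h.marker_id], h.scaffold_id))
        # slope is judged in pseudomolecule coordinates, where a
        # mis-oriented scaffold shows its markers' cM falling with bp
        per_scaffold_pts.setdefault(h.scaffold_id, []).append((obj_bp, pos_of[h.marker_id]))

    n_total = 0
    n_collinear = 0
    non_collinear_scaffolds: set[str] = set()
    for obj, pts in per_chrom.items():
        pts.sort(key=lambda t: t[0])
        cms = [cm for _, cm, _ in pts]
        n_total += len(cms)
        n_collinear += longest_nondecreasing_length(cms)
        # markers outside one LNDS mark their scaffold as monotonicity-breaking
        kept = _one_lnds_membership(cms)
        for (_, _, sid), inside in zip(pts, kept):
            if not inside:
                non_collinear_scaffolds.add(sid)

    report = CollinearityReport(n_markers=n_total)
    for sid, pts in per_scaffold_pts.items():
        pts.sort(key=lambda t: t[0])
        cms = [cm for _, cm in pts]
        slope = 0
        if len(cms) >= 2 and len(set(cms)) >= 2:
            from scipy.stats import kendalltau

            tau = kendalltau([b for b, _ in pts], cms).statistic
            slope = 0 if tau is None or np.isnan(tau) else int(np.sign(tau))
        flagged = slope < 0 or sid in non_collinear_scaffolds
        report.per_scaffold[sid] = dict(
            n_markers=len(cms), slope_sign=slope,
            collinear=not flagged,
        )
        if flagged:
            report.flagged_scaffolds.append(sid)
    report.flagged_scaffolds.sort()
    report.collinear_fraction = n_collinear / n_total if n_total else 1.0
    return report


def _one_lnds_membership(values: list[float]) -> list[bool]:
    """Membership flags for one longest non-decreasing subsequence (the
    lexicographically earliest by index), via O(n^2) DP."""
    n = len(values)
    if n == 0:
        return []
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if values[j] <= values[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -i))
    member = [False] * n
    while end != -1:
        member[end] = True
        end = prev[end]
    return member


# ---------------------------------------------------------------------------
# pipeline driver

class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    lod_threshold: float = 7.0
    gap_threshold_cM: float = 15.0
    proximity_radius_cM: float = 5.0
    gap_bp: int = 100
    write_fasta: bool = False
    preset_overrides: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, log=None) -> dict:
    """Simulate, map, anchor, integrate and report in one deterministic run.

    Writes the dataset, map TSV, hits BED, AGP, coverage/collinearity
    tables and a machine-readable ``summary.json`` under
    ``config.out_dir``; returns the summary dict. Any stage failure
    raises :class:`StageError` naming the stage after writing a partial
    manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def _log(msg: str) -> None:
        if log:
            log(msg)

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - stage-named rethrow
            (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(name, str(exc)) from exc
        _log(f"[{name}] done in {time.perf_counter() - t0:.1f}s")
        return result

    ds = _stage("simulate", lambda: simulate.simulate_dataset(
        seed=config.seed, **config.preset_overrides))
    paths = _stage("simulate", lambda: simulate.write_dataset(ds, out))
    manifest += [str(p) for p in paths.values()]

    seqs = {s.id: s.sequence for s in ds.scaffolds if s.sequence is not None}
    hits = _stage("align", lambda: anchoring.align_markers(ds.markers, seqs))
    anchoring.write_hits_bed(hits, out / "marker_hits.bed")
    manifest.append(str(out / "marker_hits.bed"))

    # SSR markers play the role of previously published sequence-tagged
    # anchors: they carry known chromosome assignments and positions.
    anchors = {m.id: m.truth_chrom for m in ds.markers if m.type == "SSR"}
    anchor_cm = {m.id: m.truth_cM for m in ds.markers if m.type == "SSR"}
    lmap = _stage("linkage", lambda: linkage.build_map(
        ds.genotypes, lod_threshold=config.lod_threshold,
        anchors=anchors, anchor_cm=anchor_cm))
    linkage.write_map_tsv(lmap, out / "linkage_map.tsv")
    manifest.append(str(out / "linkage_map.tsv"))

    assignments = _stage("anchor", lambda: anchoring.orient_scaffolds(
        anchoring.anchor_scaffolds(lmap, hits), hits, lmap))
    lengths = {s.id: s.length_bp for s in ds.scaffolds}
    good = [a for a in assignments if not a.conflict]
    build = _stage("anchor", lambda: anchoring.build_pseudochromosomes(
        good, lengths, gap_bp=config.gap_bp))
    anchoring.write_agp(build, out / "pseudochromosomes.agp")
    manifest.append(str(out / "pseudochromosomes.agp"))
    if config.write_fasta:
        anchoring.write_pseudomolecule_fasta(build, seqs, out / "pseudochromosomes.fasta")
        manifest.append(str(out / "pseudochromosomes.fasta"))
    cov = anchoring.coverage_stats(good, lengths, ds.genome.total_length_bp)

    summary_rows = _stage("report", lambda: summarize_map(lmap, config.gap_threshold_cM))
    proximity = marker_proximity(lmap, config.proximity_radius_cM)
    marey = _stage("report", lambda: marey_collinearity(lmap, build, hits))

    pd.DataFrame([r.__dict__ for r in summary_rows]).to_csv(
        out / "map_summary.tsv", sep="\t", index=False)
    manifest.append(str(out / "map_summary.tsv"))

    summary = {
        "seed": config.seed,
        "n_groups": len(lmap.groups),
        "n_markers_mapped": lmap.n_markers,
        "n_unlinked": len(lmap.unlinked),
        "total_length_cM": round(lmap.total_length_cM, 1),
        "density_cM_per_marker": round2(lmap.total_length_cM / max(lmap.n_markers, 1)),
        "n_anchored_scaffolds": sum(1 for a in assignments if not a.conflict and a.chromosome),
        "n_oriented_scaffolds": sum(1 for a in assignments if a.orientation in "+-"),
        "n_conflict_scaffolds": sum(1 for a in assignments if a.conflict),
        "total_anchored_bp": cov["total_anchored_bp"],
        "coverage_pct": cov["total_coverage_pct"],
        "proximity_fraction": round(proximity, 4),
        "collinear_fraction": round(marey.collinear_fraction, 4),
        "n_gaps_gt_threshold": summary_rows[-1].n_gaps_gt_threshold if summary_rows else 0,
        "per_chromosome_coverage": cov["per_chromosome"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest.append(str(out / "summary.json"))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
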