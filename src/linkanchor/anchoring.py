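"""In-silico PCR placement of markers on scaffolds and scaffold anchoring.

Markers are located by exact primer matching: a hit requires the forward
primer and the reverse complement of the reverse primer on the same
strand of a scaffold, spanning an amplicon of 80-200 bp; both template
orientations are searched. Scaffolds are anchored to the linkage group
holding the majority of their uniquely-hit mapped markers, positioned at
the median marker cM, oriented by the sign of the Kendall rank
correlation between marker cM and marker bp, and concatenated into
pseudochromosomes described by an AGP v2.1 file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import kendalltau

from ._seq import find_all, revcomp
from .linkage import LinkageMap
from .simulate import Marker, Scaffold

AMPLICON_RANGE = (80, 200)


@dataclass(frozen=True)
class MarkerHit:
    marker_id: str
    scaffold_id: str
    amplicon_start_bp: int  # 0-based
    amplicon_end_bp: int  # half-open
    template_strand: str  # '+' or '-'
    unique: bool = True


@dataclass
class AnchorAssignment:
    scaffold_id: str
    chromosome: str
    position_cM: float
    orientation: str = "undetermined"
    supporting_markers: list[str] = field(default_factory=list)
    conflict: bool = False


@dataclass
class AGPComponent:
    object: str
    object_beg: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # 'W' or 'U'
    component_id: str  # scaffold id, or gap length for U
    component_beg: int | str
    component_end: int | str
    orientation: str = "+"  # or 'na' for gaps


@dataclass
class PseudochromosomeBuild:
    components: list[AGPComponent]
    gap_bp: int = 100
    orientation_flags: dict[str, bool] = field(default_factory=dict)

    def scaffold_order(self) -> dict[str, list[tuple[str, str]]]:
        """Per chromosome: ordered (scaffold_id, orientation) list."""
        out: dict[str, list[tuple[str, str]]] = {}
        for c in self.components:
            if c.component_type == "W":
                out.setdefault(c.object, []).append((c.component_id, c.orientation))
        return out

    def object_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.components:
            out[c.object] = max(out.get(c.object, 0), c.object_end)
        return out


# ---------------------------------------------------------------------------
# marker alignment

def _load_scaffold_seqs(scaffold_source) -> dict[str, str]:
    if isinstance(scaffold_source, dict):
        return scaffold_source
    if isinstance(scaffold_source, (str, Path)):
        from Bio import SeqIO

        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(scaffold_source), "fasta")}
    # list of Scaffold objects
    return {s.id: s.sequence for s in scaffold_source if s.sequence is not None}


def align_markers(
    markers: list[Marker],
    scaffold_source,
    amplicon_range: tuple[int, int] = AMPLICON_RANGE,
) -> list[MarkerHit]:
    """Exact-match in-silico PCR of every marker against every scaffold.

    ``scaffold_source`` may be a FASTA path, a dict id -> sequence, or a
    list of Scaffold objects. Markers whose primers contain non-ACGT
    characters are skipped with a warning. Markers hitting more than one
    site genome-wide are flagged non-unique (every hit carries the flag).
    """
    import warnings

    seqs = _load_scaffold_seqs(scaffold_source)
    lo, hi = amplicon_range
    queries: list[str] = []
    slots: list[tuple[int, int]] = []  # (marker index, variant 0..3)
    kept: list[int] = []
    for mi, m in enumerate(markers):
        if not m.primer_fwd or not m.primer_rev:
            continue
        if set(m.primer_fwd + m.primer_rev) - set("ACGT"):
            warnings.warn(f"marker {m.id}: primer contains non-ACGT base, skipped")
            continue
        kept.append(mi)
        for variant in (m.primer_fwd, revcomp(m.primer_rev),
                        m.primer_rev, revcomp(m.primer_fwd)):
            queries.append(variant)
            slots.append((mi, len(slots) % 4))

    hits_by_marker: dict[int, list[MarkerHit]] = {mi: [] for mi in kept}
    for sid, seq in seqs.items():
        occ = find_all(seq, queries)
        per_marker: dict[int, list[list[int]]] = {}
        for q, positions in enumerate(occ):
            mi, variant = slots[q]
            per_marker.setdefault(mi, [[], [], [], []])[variant].extend(positions)
        for mi, (fw, rc_rev, rv, rc_fwd) in per_marker.items():
            m = markers[mi]
            # '+' template: fwd primer then revcomp(rev) downstream
            for s in fw:
                for p in rc_rev:
                    e = p + len(m.primer_rev)
                    if lo <= e - s <= hi:
                        hits_by_marker[mi].append(MarkerHit(m.id, sid, s, e, "+"))
            # '-' template: rev primer then revcomp(fwd) downstream
            for s in rv:
                for p in rc_fwd:
                    e = p + len(m.primer_fwd)
                    if lo <= e - s <= hi:
                        hits_by_marker[mi].append(MarkerHit(m.id, sid, s, e, "-"))

    out: list[MarkerHit] = []
    for mi in kept:
        hs = hits_by_marker[mi]
        unique = len(hs) == 1
        for h in sorted(hs, key=lambda h: (h.scaffold_id, h.amplicon_start_bp)):
            out.append(MarkerHit(h.marker_id, h.scaffold_id, h.amplicon_start_bp,
                                 h.amplicon_end_bp, h.template_strand, unique))
    return out


# ---------------------------------------------------------------------------
# anchoring & orientation

def anchor_scaffolds(
    linkage_map: LinkageMap,
    hits: list[MarkerHit],
    majority: float = 2 / 3,
) -> list[AnchorAssignment]:
    """Assign each scaffold to the majority linkage group of its markers.

    Only unique hits of mapped markers count as support. A scaffold whose
    top group holds less than ``majority`` of its supporting markers (or
    ties) is returned with ``conflict=True`` and no chromosome. Position
    is the median cM of the supporting markers.
    """
    group_of = linkage_map.group_of()
    pos_of = linkage_map.position_of()
    support: dict[str, list[MarkerHit]] = {}
    for h in hits:
        if h.unique and h.marker_id in group_of:
            support.setdefault(h.scaffold_id, []).append(h)

    out: list[AnchorAssignment] = []
    for sid in sorted(support):
        hs = support[sid]
        votes: dict[str, int] = {}
        for h in hs:
            g = group_of[h.marker_id]
            votes[g] = votes.get(g, 0) + 1
        top = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        total = sum(votes.values())
        tied = len(top) > 1 and top[0][1] == top[1][1]
        if tied or top[0][1] / total < majority:
            out.append(AnchorAssignment(sid, "", float("nan"), "undetermined",
                                        sorted(h.marker_id for h in hs), conflict=True))
            continue
        grp = top[0][0]
        sup = sorted(h.marker_id for h in hs if group_of[h.marker_id] == grp)
        med = float(np.median([pos_of[m] for m in sup]))
        out.append(AnchorAssignment(sid, grp, med, "undetermined", sup))
    return out


def orient_scaffolds(
    assignments: list[AnchorAssignment],
    hits: list[MarkerHit],
    linkage_map: LinkageMap,
) -> list[AnchorAssignment]:
    """Set orientation from the rank correlation of marker cM vs bp.

    Requires >= 2 supporting markers at distinct cM positions; the
    orientation is '+' when genetic position increases with scaffold bp,
    '-' when it decreases, undetermined on ties or zero correlation.
    A hit on the '-' template strand contributes its own bp unchanged
    (amplicon midpoint on the scaffold's coordinates).
    """
    pos_of = linkage_map.position_of()
    bp_of: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.unique:
            bp_of[(h.scaffold_id, h.marker_id)] = (h.amplicon_start_bp + h.amplicon_end_bp) / 2

    for a in assignments:
        if a.conflict:
            continue
        pts = [
            (bp_of[(a.scaffold_id, m)], pos_of[m])
            for m in a.supporting_markers
            if (a.scaffold_id, m) in bp_of
        ]
        cms = {cm for _, cm in pts}
        if len(pts) < 2 or len(cms) < 2:
            a.orientation = "undetermined"
            continue
        tau = kendalltau([b for b, _ in pts], [c for _, c in pts]).statistic
        if tau is None or np.isnan(tau) or tau == 0:
            a.orientation = "undetermined"
        else:
            a.orientation = "+" if tau > 0 else "-"
    return assignments


# ---------------------------------------------------------------------------
# pseudochromosome construction

def build_pseudochromosomes(
    assignments: list[AnchorAssignment],
    scaffold_lengths: dict[str, int],
    gap_bp: int = 100,
) -> PseudochromosomeBuild:
    """Concatenate anchored scaffolds into AGP pseudomolecules.

    Scaffolds are ordered by position_cM (ties: descending length, then
    id); undetermined orientations are emitted as '+' and flagged. Gaps
    of ``gap_bp`` unknown bases ('U' records) separate components.
    """
    seen: set[str] = set()
    per_chrom: dict[str, list[AnchorAssignment]] = {}
    for a in assignments:
        if a.conflict or not a.chromosome:
            continue
        if a.scaffold_id in seen:
            raise ValueError(f"scaffold {a.scaffold_id} assigned more than once")
        seen.add(a.scaffold_id)
        per_chrom.setdefault(a.chromosome, []).append(a)

    comps: list[AGPComponent] = []
    flags: dict[str, bool] = {}
    for chrom in sorted(per_chrom):
        rows = sorted(
            per_chrom[chrom],
            key=lambda a: (a.position_cM, -scaffold_lengths[a.scaffold_id], a.scaffold_id),
        )
        cursor = 0
        part = 0
        for k, a in enumerate(rows):
            if k > 0:
                part += 1
                comps.append(AGPComponent(chrom, cursor + 1, cursor + gap_bp, part,
                                          "U", str(gap_bp), "scaffold", "yes", "na"))
                cursor += gap_bp
            L = scaffold_lengths[a.scaffold_id]
            part += 1
            orient = a.orientation if a.orientation in "+-" else "+"
            flags[a.scaffold_id] = a.orientation == "undetermined"
            comps.append(AGPComponent(chrom, cursor + 1, cursor + L, part,
                                      "W", a.scaffold_id, 1, L, orient))
            cursor += L
    return PseudochromosomeBuild(components=comps, gap_bp=gap_bp, orientation_flags=flags)


def coverage_stats(
    assignments: list[AnchorAssignment],
    scaffold_lengths: dict[str, int],
    genome_size_bp: int,
) -> dict:
    """Anchored bp and percent coverage per chromosome and in total.

    percent = 100 * anchored_bp / genome_size_bp, reported to 2 decimals
    (round half up, as map summary tables conventionally print).
    """
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    from .report import round2

    per: dict[str, dict] = {}
    for a in assignments:
        if a.conflict or not a.chromosome:
            continue
        d = per.setdefault(a.chromosome, {"n_scaffolds": 0, "anchored_bp": 0})
        d["n_scaffolds"] += 1
        d["anchored_bp"] += scaffold_lengths[a.scaffold_id]
    total_bp = sum(d["anchored_bp"] for d in per.values())
    for d in per.values():
        d["coverage_pct"] = round2(100.0 * d["anchored_bp"] / genome_size_bp)
    return {
        "per_chromosome": dict(sorted(per.items())),
        "total_anchored_bp": total_bp,
        "total_coverage_pct": round2(100.0 * total_bp / genome_size_bp),
    }


# ---------------------------------------------------------------------------
# AGP / BED / FASTA writers

def write_agp(build: PseudochromosomeBuild, path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for c in build.components:
            if c.component_type == "W":
                fields = [c.object, c.object_beg, c.object_end, c.part_number, "W",
                          c.component_id, c.component_beg, c.component_end, c.orientation]
            else:
                fields = [c.object, c.object_beg, c.object_end, c.part_number, "U",
                          c.component_id, "scaffold", "yes", "map"]
            fh.write("\t".join(str(x) for x in fields) + "\n")


def read_agp(path) -> PseudochromosomeBuild:
    comps: list[AGPComponent] = []
    gap_bp = 100
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[4] == "W":
                comps.append(AGPComponent(f[0], int(f[1]), int(f[2]), int(f[3]), "W",
                                          f[5], int(f[6]), int(f[7]), f[8]))
            else:
                gap_bp = int(f[5])
                comps.append(AGPComponent(f[0], int(f[1]), int(f[2]), int(f[3]), "U",
                                          f[5], "scaffold", "yes", "na"))
    return PseudochromosomeBuild(components=comps, gap_bp=gap_bp)


def write_hits_bed(hits: list[MarkerHit], path) -> None:
    """Marker hits as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.scaffold_id}\t{h.amplicon_start_bp}\t{h.amplicon_end_bp}"
                     f"\t{h.marker_id}\t{int(h.unique)}\t{h.template_strand}\n")


def read_hits_bed(path) -> list[MarkerHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            sid, s, e, mid, uq, strand = line.split("\t")
            hits.append(MarkerHit(mid, sid, int(s), int(e), strand.strip(), bool(int(uq))))
    return hits


def write_pseudomolecule_fasta(
    build: PseudochromosomeBuild, scaffold_seqs: dict[str, str], path, width: int = 80
) -> None:
    with open(path, "w") as fh:
        by_obj: dict[str, list[AGPComponent]] = {}
        for c in build.components:
            by_obj.setdefault(c.object, []).append(c)
        for obj in sorted(by_obj):
            parts = []
            for c in sorted(by_obj[obj], key=lambda c: c.part_number):
                if c.component_type == "W":
                    seq = scaffold_seqs[c.component_id]
                    parts.append(seq if c.orientation == "+" else revcomp(seq))
                else:
                    parts.append("N" * (c.object_end - c.object_beg + 1))
            seq = "".join(parts)
            fh.write(f">{obj}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
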