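"""Cross-map locus matching and anchor-set integration.

Different genetic maps of the same genome tag loci with different marker
systems (PCR markers, BAC-derived loci). Two loci from two maps are
"common" when they sit on the same scaffold within 100 kbp of each
other; matching is greedy nearest-first and one-to-one. Anchor sets from
several maps are merged scaffold-wise: a scaffold anchored by any map is
anchored in the union, and chromosome disagreements are resolved by a
caller-supplied precedence order (first listed map wins), with every
conflict logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .anchoring import AnchorAssignment, coverage_stats


@dataclass(frozen=True)
class ExternalMapLocus:
    map_name: str
    locus_id: str
    chromosome: str
    position_cM: float
    scaffold_id: str
    scaffold_pos_bp: int


@dataclass
class IntegratedAnchorSet:
    assignments: list[AnchorAssignment]
    evidence: dict[str, list[str]]  # scaffold -> supporting map names
    conflicts: list[str] = field(default_factory=list)
    total_anchored_bp: int = 0
    coverage_pct: float = 0.0

    @property
    def n_scaffolds(self) -> int:
        return len(self.assignments)


def find_common_loci(
    loci_a: list[ExternalMapLocus],
    loci_b: list[ExternalMapLocus],
    window_bp: int = 100_000,
) -> list[tuple[ExternalMapLocus, ExternalMapLocus]]:
    """Greedy nearest-first one-to-one matching of loci on shared scaffolds.

    A pair qualifies when both loci lie on the same scaffold with
    |pos_a - pos_b| <= window_bp (inclusive boundary). Candidate pairs
    are taken in order of increasing distance, ties broken by locus ids,
    and each locus is consumed by its first (nearest) match.
    """
    by_scaffold: dict[str, list[ExternalMapLocus]] = {}
    for b in loci_b:
        by_scaffold.setdefault(b.scaffold_id, []).append(b)
    candidates = []
    for a in loci_a:
        for b in by_scaffold.get(a.scaffold_id, []):
            d = abs(a.scaffold_pos_bp - b.scaffold_pos_bp)
            if d <= window_bp:
                candidates.append((d, a.locus_id, b.locus_id, a, b))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for _, ida, idb, a, b in candidates:
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        pairs.append((a, b))
    return pairs


def integrate_anchors(
    anchor_sets: dict[str, list[AnchorAssignment]],
    precedence_order: list[str],
    scaffold_lengths: dict[str, int] | None = None,
    genome_size_bp: int | None = None,
) -> IntegratedAnchorSet:
    """Union anchor sets; precedence resolves chromosome disagreements.

    ``anchor_sets`` maps a map name to its (non-conflicting) scaffold
    assignments; ``precedence_order`` must list every map name, earlier
    names winning conflicts. Coverage is recomputed when scaffold
    lengths and a genome size are supplied.
    """
    missing = set(anchor_sets) - set(precedence_order)
    if missing:
        raise ValueError(f"precedence_order missing maps: {sorted(missing)}")
    chosen: dict[str, AnchorAssignment] = {}
    rank = {name: k for k, name in enumerate(precedence_order)}
    evidence: dict[str, list[str]] = {}
    source: dict[str, str] = {}
    conflicts: list[str] = []
    for name in sorted(anchor_sets, key=lambda n: rank[n]):
        for a in anchor_sets[name]:
            if a.conflict or not a.chromosome:
                continue
            sid = a.scaffold_id
            evidence.setdefault(sid, [])
            if name not in evidence[sid]:
                evidence[sid].append(name)
            if sid not in chosen:
                chosen[sid] = a
                source[sid] = name
            elif chosen[sid].chromosome != a.chromosome:
                conflicts.append(
                    f"{sid}: {source[sid]} says {chosen[sid].chromosome}, "
                    f"{name} says {a.chromosome}; kept {source[sid]}"
                )
    merged = [chosen[sid] for sid in sorted(chosen)]
    out = IntegratedAnchorSet(assignments=merged, evidence=evidence, conflicts=conflicts)
    if scaffold_lengths is not None and genome_size_bp:
        cov = coverage_stats(merged, scaffold_lengths, genome_size_bp)
        out.total_anchored_bp = cov["total_anchored_bp"]
        out.coverage_pct = cov["total_coverage_pct"]
    return out


# ---------------------------------------------------------------------------
# I/O

def read_external_map_tsv(path: str | Path) -> list[ExternalMapLocus]:
    """Columns: map, locus, chromosome, cM, scaffold, bp (tab-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"map": str, "locus": str,
                                            "chromosome": str, "scaffold": str})
    return [
        ExternalMapLocus(r.map, r.locus, r.chromosome, float(r.cM), r.scaffold, int(r.bp))
        for r in df.itertuples()
    ]


def write_integrated_tsv(result: IntegratedAnchorSet, path: str | Path) -> None:
    rows = [
        dict(scaffold=a.scaffold_id, chromosome=a.chromosome,
             position_cM=round(a.position_cM, 3), orientation=a.orientation,
             evidence=",".join(result.evidence.get(a.scaffold_id, [])))
        for a in result.assignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    log = Path(path).with_suffix(".conflicts.txt")
    log.write_text("\n".join(result.conflicts) + ("\n" if result.conflicts else ""))
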