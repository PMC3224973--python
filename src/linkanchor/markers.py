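"""InDel marker selection and flanking-primer design.

From a list of sequence variants between two parental lines, keep the
4-10 bp insertion/deletions and design a flanking primer pair for each,
under the classic PCR-marker constraints: amplicon length 80-200 bp
(spanning the indel), both primer Tm in [55, 63] C with a within-pair
difference under 3 C, and GC content above 35%. Tm uses the GC-count
approximation Tm = 64.9 + 41*(GC - 16.4)/length, which is closed-form
and adequate for ranking candidate primers; swap in a nearest-neighbour
model via the ``tm_fn`` hook if thermodynamic accuracy matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._seq import revcomp


@dataclass(frozen=True)
class VariantRecord:
    scaffold_id: str
    pos_bp: int  # 0-based
    ref_allele: str
    alt_allele: str

    @property
    def indel_length_bp(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))


@dataclass(frozen=True)
class PrimerConstraints:
    amplicon_min_bp: int = 80
    amplicon_max_bp: int = 200
    tm_min_C: float = 55.0
    tm_max_C: float = 63.0
    tm_diff_max_C: float = 3.0
    gc_min_frac: float = 0.35
    primer_len_min: int = 18
    primer_len_max: int = 24


@dataclass(frozen=True)
class PrimerPair:
    fwd_seq: str
    rev_seq: str
    fwd_tm_C: float
    rev_tm_C: float
    fwd_gc_frac: float
    rev_gc_frac: float
    amplicon_len_ref_bp: int
    amplicon_len_alt_bp: int


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def wallace_gc_tm(seq: str) -> float:
    """GC-count melting-temperature approximation (Marmur/Wallace form):
    Tm = 64.9 + 41*(#GC - 16.4)/len."""
    return 64.9 + 41.0 * (seq.count("G") + seq.count("C") - 16.4) / len(seq)


def select_indels(
    variants: list[VariantRecord], min_len: int = 4, max_len: int = 10
) -> list[VariantRecord]:
    """Keep variants whose indel length is within [min_len, max_len]
    inclusive; input order is preserved."""
    return [v for v in variants if min_len <= v.indel_length_bp <= max_len]


def _primer_ok(seq: str, c: PrimerConstraints, tm_fn) -> bool:
    return tm_fn(seq) >= c.tm_min_C and tm_fn(seq) <= c.tm_max_C and gc_fraction(seq) > c.gc_min_frac


def design_primer_pair(
    scaffold_seq: str,
    indel: VariantRecord,
    constraints: PrimerConstraints = PrimerConstraints(),
    tm_fn=wallace_gc_tm,
) -> PrimerPair | None:
    """First acceptable flanking pair under a fixed deterministic scan.

    Amplicon length expands from the minimum upward; for each length the
    amplicon slides across the indel and primer lengths scan 18-24
    (forward, then reverse). Returns ``None`` when no pair satisfies the
    Tm/GC/amplicon constraints — a normal outcome for extreme-composition
    templates, not an error.
    """
    c = constraints
    ind_start = indel.pos_bp
    ind_end = indel.pos_bp + max(len(indel.ref_allele), 1)
    if ind_start < 100 or len(scaffold_seq) - ind_end < 100:
        raise ValueError("need >= 100 bp of flank on each side of the indel")
    dlen = indel.indel_length_bp
    for amp_len in range(c.amplicon_min_bp, c.amplicon_max_bp + 1):
        lo = max(0, ind_end - amp_len)
        hi = min(len(scaffold_seq) - amp_len, ind_start)
        for start in range(lo, hi + 1):
            fwd = None
            for pl in range(c.primer_len_min, c.primer_len_max + 1):
                cand = scaffold_seq[start : start + pl]
                if start + pl <= ind_start and _primer_ok(cand, c, tm_fn):
                    fwd = cand
                    break
            if fwd is None:
                continue
            end = start + amp_len
            for pl in range(c.primer_len_min, c.primer_len_max + 1):
                if end - pl < ind_end:
                    break
                cand = revcomp(scaffold_seq[end - pl : end])
                if _primer_ok(cand, c, tm_fn) and abs(tm_fn(fwd) - tm_fn(cand)) < c.tm_diff_max_C:
                    alt_len = amp_len - dlen if len(indel.ref_allele) >= len(indel.alt_allele) else amp_len + dlen
                    return PrimerPair(
                        fwd_seq=fwd, rev_seq=cand,
                        fwd_tm_C=tm_fn(fwd), rev_tm_C=tm_fn(cand),
                        fwd_gc_frac=gc_fraction(fwd), rev_gc_frac=gc_fraction(cand),
                        amplicon_len_ref_bp=amp_len, amplicon_len_alt_bp=alt_len,
                    )
    return None


def check_uniqueness(
    primer_pair: PrimerPair,
    scaffold_seqs: dict[str, str],
    amplicon_range: tuple[int, int] = (80, 200),
) -> int:
    """Count amplifiable sites of a primer pair across a genome.

    A site is an exact forward-primer match paired with an exact
    reverse-complemented reverse-primer match spanning 80-200 bp, on
    either template orientation. A marker is unique iff the count is 1.
    """
    lo, hi = amplicon_range
    fwd, rev = primer_pair.fwd_seq, primer_pair.rev_seq
    count = 0
    for seq in scaffold_seqs.values():
        for left, right in ((fwd, revcomp(rev)), (rev, revcomp(fwd))):
            start = seq.find(left)
            starts = []
            while start != -1:
                starts.append(start)
                start = seq.find(left, start + 1)
            for s in starts:
                p = seq.find(right, s)
                while p != -1:
                    span = p + len(right) - s
                    if span > hi:
                        break
                    if span >= lo:
                        count += 1
                    p = seq.find(right, p + 1)
    return count


# ---------------------------------------------------------------------------
# I/O: VCF-like variant TSV and marker-table export

def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """CHROM / POS (1-based) / REF / ALT columns, tab-separated."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "REF": str, "ALT": str})
    return [
        VariantRecord(row.CHROM, int(row.POS) - 1, row.REF, row.ALT)
        for row in df.itertuples()
    ]


def write_marker_tsv(rows: list[dict], path: str | Path) -> None:
    """Marker table compatible with the synthetic-data marker format."""
    pd.DataFrame(
        rows,
        columns=["id", "type", "scaffold", "pos", "primer_fwd", "primer_rev",
                 "allele_size_A", "allele_size_B"],
    ).to_csv(path, sep="\t", index=False)
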