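"""Synthetic genome, scaffold, marker and DH-population simulation.

Generates a multi-chromosome genome with a uniform cM/Mbp recombination
rate, fragments it into scaffolds of random strand, places sequence-tagged
markers (InDel and SSR) whose primers are exact flanking subsequences of
the scaffold, and simulates a doubled-haploid (DH) mapping population under
the Haldane no-interference crossover model (Poisson crossover counts,
uniform positions in genetic distance).

Every object carries ground truth (chromosome, offset, strand, genetic
position) so that downstream grouping, ordering, anchoring and orientation
can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import random_sequence, revcomp

MISSING = "-"

# Desk-scale default preset: 10 chromosomes x 28.38 Mbp at 4.349 cM/Mbp
# (~283.8 Mbp, ~1234 cM total), ~150 scaffolds, 507 markers of which
# 415 are InDels, 119 DH lines.
DEFAULT_PRESET = dict(
    n_chrom=10,
    length_bp_per_chrom=28_380_000,
    cM_per_Mbp=4.349,
    mean_scaffold_bp=1_892_000,
    min_scaffold_bp=200_000,
    n_markers=507,
    indel_fraction=415 / 507,
    n_lines=119,
    missing_rate=0.02,
    error_rate=0.005,
)


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    genetic_length_cM: float


@dataclass(frozen=True)
class TrueGenome:
    """Simulated genome: chromosomes with a uniform cM/Mbp rate each."""

    chromosomes: list[Chromosome]
    rate_cM_per_Mbp: list[float]

    @property
    def total_length_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    @property
    def total_genetic_length_cM(self) -> float:
        return sum(c.genetic_length_cM for c in self.chromosomes)

    def rate_of(self, chrom_name: str) -> float:
        for c, r in zip(self.chromosomes, self.rate_cM_per_Mbp):
            if c.name == chrom_name:
                return r
        raise KeyError(chrom_name)


@dataclass
class Scaffold:
    """A contiguous sequence with hidden placement truth.

    ``sequence`` is the scaffold's own sequence; when ``truth_strand`` is
    '-' it is the reverse complement of the chromosome segment
    ``[truth_start, truth_start + length_bp)``.
    """

    id: str
    length_bp: int
    truth_chrom: str
    truth_start: int  # 0-based on the chromosome
    truth_strand: str  # '+' or '-'
    sequence: str | None = None

    def chrom_pos_of(self, scaffold_pos: int) -> int:
        """Chromosome coordinate of a 0-based scaffold position."""
        if self.truth_strand == "+":
            return self.truth_start + scaffold_pos
        return self.truth_start + (self.length_bp - 1 - scaffold_pos)


@dataclass
class Marker:
    """A sequence-tagged locus amplified by a primer pair.

    Parental alleles differ in amplicon size; for InDel markers the
    difference is 4-10 bp. ``truth_cM`` is the genetic position on
    ``truth_chrom`` implied by the genome's uniform recombination rate.
    """

    id: str
    type: str  # 'InDel' or 'SSR'
    scaffold_id: str
    scaffold_pos_bp: int
    primer_fwd: str
    primer_rev: str
    allele_size_A_bp: int
    allele_size_B_bp: int
    truth_chrom: str
    truth_cM: float


@dataclass
class GenotypeMatrix:
    """DH lines x markers over {'A', 'B', '-'} (missing)."""

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # dtype '<U1', shape (n_lines, n_markers)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls)) - {"A", "B", MISSING}
        if bad:
            raise ValueError(f"non-DH genotype symbols present: {sorted(bad)}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.line_ids, columns=self.marker_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(
            line_ids=[str(i) for i in df.index],
            marker_ids=[str(c) for c in df.columns],
            calls=df.to_numpy(dtype="<U1"),
        )


def simulate_genome(
    n_chrom: int = 10,
    length_bp_per_chrom: int | list[int] = 28_380_000,
    cM_per_Mbp: float | list[float] = 4.349,
    seed: int = 0,
) -> TrueGenome:
    """Build a genome of ``n_chrom`` chromosomes with uniform cM/Mbp rates.

    Genetic length of each chromosome is ``length_bp * rate * 1e-6``.
    Deterministic; ``seed`` is recorded by callers, not consumed here.
    """
    if not 1 <= n_chrom <= 26:
        raise ValueError("n_chrom must be in [1, 26]")
    lengths = (
        [int(length_bp_per_chrom)] * n_chrom
        if np.isscalar(length_bp_per_chrom)
        else [int(x) for x in length_bp_per_chrom]
    )
    rates = (
        [float(cM_per_Mbp)] * n_chrom
        if np.isscalar(cM_per_Mbp)
        else [float(x) for x in cM_per_Mbp]
    )
    if len(lengths) != n_chrom or len(rates) != n_chrom:
        raise ValueError("per-chromosome lists must have length n_chrom")
    if any(x <= 0 for x in lengths):
        raise ValueError("chromosome lengths must be positive")
    if any(r <= 0 for r in rates):
        raise ValueError("cM/Mbp rate must be positive")
    chroms = [
        Chromosome(f"A{i + 1:02d}", L, L * r * 1e-6)
        for i, (L, r) in enumerate(zip(lengths, rates))
    ]
    return TrueGenome(chromosomes=chroms, rate_cM_per_Mbp=rates)


def fragment_into_scaffolds(
    genome: TrueGenome,
    mean_scaffold_bp: int = 1_892_000,
    min_scaffold_bp: int = 200_000,
    seed: int = 0,
    with_sequence: bool = True,
) -> list[Scaffold]:
    """Cut each chromosome into scaffolds that tile it exactly.

    Breakpoints are a uniform random set with expected spacing
    ``mean_scaffold_bp``; fragments shorter than ``min_scaffold_bp`` are
    merged leftward. Strands are assigned uniformly at random so that
    orientation recovery downstream is nontrivial.
    """
    if min_scaffold_bp > mean_scaffold_bp:
        raise ValueError("min_scaffold_bp must be <= mean_scaffold_bp")
    rng = np.random.default_rng(seed)
    scaffolds: list[Scaffold] = []
    idx = 0
    for chrom in genome.chromosomes:
        L = chrom.length_bp
        n_cuts = rng.poisson(max(L / mean_scaffold_bp - 1, 0))
        cuts = np.sort(rng.integers(1, L, size=n_cuts)) if n_cuts else np.array([], int)
        bounds = [0, *cuts.tolist(), L]
        # merge short fragments into the previous one
        merged = [0]
        for b in bounds[1:]:
            if b - merged[-1] < min_scaffold_bp and b != L:
                continue
            if b == L and merged[-1] != 0 and b - merged[-1] < min_scaffold_bp:
                merged[-1] = b
            else:
                merged.append(b)
        chrom_seq = random_sequence(L, rng) if with_sequence else None
        for start, end in zip(merged[:-1], merged[1:]):
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            seq = None
            if chrom_seq is not None:
                seg = chrom_seq[start:end]
                seq = seg if strand == "+" else revcomp(seg)
            scaffolds.append(
                Scaffold(
                    id=f"Scaffold{idx:06d}",
                    length_bp=end - start,
                    truth_chrom=chrom.name,
                    truth_start=start,
                    truth_strand=strand,
                    sequence=seq,
                )
            )
    return scaffolds


def place_markers(
    scaffolds: list[Scaffold],
    genome: TrueGenome,
    n_markers: int = 507,
    indel_fraction: float = 415 / 507,
    seed: int = 0,
    primer_len_range: tuple[int, int] = (18, 24),
    amplicon_range: tuple[int, int] = (80, 200),
) -> list[Marker]:
    """Scatter sequence-tagged markers over scaffolds, length-proportional.

    Primer pairs are cut verbatim from the scaffold sequence flanking the
    marker position, so exact-match alignment recovers them by
    construction. InDel markers get parental amplicon sizes differing by
    4-10 bp; SSR markers by 2-30 bp (repeat-number variation).
    """
    if n_markers < 2:
        raise ValueError("n_markers must be >= 2")
    if not 0 <= indel_fraction <= 1:
        raise ValueError("indel_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    amp_lo, amp_hi = amplicon_range
    margin = amp_hi + 10
    lengths = np.array([s.length_bp for s in scaffolds], dtype=float)
    usable = np.maximum(lengths - 2 * margin, 0.0)
    if usable.sum() <= 0:
        raise ValueError("scaffolds too short to place any marker")
    capacity = int((usable // 50).sum())
    if n_markers > capacity:
        raise ValueError(f"marker density exceeds scaffold capacity ({capacity})")

    n_indel = int(round(n_markers * indel_fraction))
    markers: list[Marker] = []
    probs = usable / usable.sum()
    choice = rng.choice(len(scaffolds), size=n_markers, p=probs)
    for k in range(n_markers):
        sc = scaffolds[int(choice[k])]
        mtype = "InDel" if k < n_indel else "SSR"
        amp_len = int(rng.integers(amp_lo, amp_hi + 1))
        start = int(rng.integers(margin, sc.length_bp - margin - amp_len))
        p_len_f = int(rng.integers(primer_len_range[0], primer_len_range[1] + 1))
        p_len_r = int(rng.integers(primer_len_range[0], primer_len_range[1] + 1))
        if sc.sequence is not None:
            fwd = sc.sequence[start : start + p_len_f]
            rev = revcomp(sc.sequence[start + amp_len - p_len_r : start + amp_len])
        else:  # sequence-free runs still exercise the genetic layer
            fwd = rev = ""
        diff = int(rng.integers(4, 11)) if mtype == "InDel" else int(rng.integers(2, 31))
        size_a = amp_len
        size_b = amp_len - diff if amp_len - diff >= amp_lo else min(amp_len + diff, amp_hi)
        pos = start + amp_len // 2
        chrom_pos = sc.chrom_pos_of(pos)
        cm = chrom_pos * genome.rate_of(sc.truth_chrom) * 1e-6
        markers.append(
            Marker(
                id=f"{'IND' if mtype == 'InDel' else 'SSR'}{k + 1:05d}",
                type=mtype,
                scaffold_id=sc.id,
                scaffold_pos_bp=pos,
                primer_fwd=fwd,
                primer_rev=rev,
                allele_size_A_bp=size_a,
                allele_size_B_bp=size_b,
                truth_chrom=sc.truth_chrom,
                truth_cM=cm,
            )
        )
    return markers


def simulate_dh_population(
    markers: list[Marker],
    genome: TrueGenome,
    n_lines: int = 119,
    missing_rate: float = 0.02,
    error_rate: float = 0.005,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate one meiosis per DH line under the Haldane model.

    Per line and chromosome the crossover count is Poisson with mean
    genetic_length/100 (Morgans) and crossover positions are uniform in
    cM; the line's genotype is the resulting gamete doubled to
    homozygosity. Genotyping error is a symmetric A<->B flip applied
    independently at ``error_rate``; calls are masked to missing at
    ``missing_rate``.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    for name, rate in (("missing_rate", missing_rate), ("error_rate", error_rate)):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[int]] = {}
    for j, m in enumerate(markers):
        by_chrom.setdefault(m.truth_chrom, []).append(j)

    n_mark = len(markers)
    calls = np.empty((n_lines, n_mark), dtype="<U1")
    for chrom in genome.chromosomes:
        idx = by_chrom.get(chrom.name)
        if not idx:
            continue
        pos = np.array([markers[j].truth_cM for j in idx])
        G = chrom.genetic_length_cM
        for i in range(n_lines):
            n_xo = rng.poisson(G / 100.0)
            xo = np.sort(rng.uniform(0.0, G, size=n_xo))
            phase = int(rng.integers(0, 2))
            n_below = np.searchsorted(xo, pos, side="right")
            allele = (phase + n_below) % 2
            calls[i, idx] = np.where(allele == 0, "A", "B")

    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        flipped = np.where(calls == "A", "B", "A")
        calls = np.where(flip, flipped, calls)
    if missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < missing_rate, MISSING, calls)

    return GenotypeMatrix(
        line_ids=[f"DH{i + 1:03d}" for i in range(n_lines)],
        marker_ids=[m.id for m in markers],
        calls=calls,
    )


@dataclass
class SyntheticDataset:
    genome: TrueGenome
    scaffolds: list[Scaffold]
    markers: list[Marker]
    genotypes: GenotypeMatrix
    params: dict = field(default_factory=dict)


def simulate_dataset(seed: int = 0, with_sequence: bool = True, **overrides) -> SyntheticDataset:
    """Run the full default preset (or an override of it) end to end."""
    p = {**DEFAULT_PRESET, **overrides}
    genome = simulate_genome(p["n_chrom"], p["length_bp_per_chrom"], p["cM_per_Mbp"], seed)
    scaffolds = fragment_into_scaffolds(
        genome, p["mean_scaffold_bp"], p["min_scaffold_bp"], seed=seed + 1,
        with_sequence=with_sequence,
    )
    markers = place_markers(
        scaffolds, genome, p["n_markers"], p["indel_fraction"], seed=seed + 2
    )
    genotypes = simulate_dh_population(
        markers, genome, p["n_lines"], p["missing_rate"], p["error_rate"], seed=seed + 3
    )
    return SyntheticDataset(genome, scaffolds, markers, genotypes, params={**p, "seed": seed})


# ---------------------------------------------------------------------------
# serialization

def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write scaffolds (FASTA), markers (TSV + truth TSV), genotypes (CSV)
    and run metadata (JSON); returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scaffolds": out / "scaffolds.fasta",
        "markers": out / "markers.tsv",
        "truth": out / "truth.tsv",
        "genotypes": out / "genotypes.csv",
        "metadata": out / "metadata.json",
    }
    with open(paths["scaffolds"], "w") as fh:
        for sc in ds.scaffolds:
            if sc.sequence is None:
                continue
            fh.write(f">{sc.id}\n")
            for i in range(0, len(sc.sequence), 80):
                fh.write(sc.sequence[i : i + 80] + "\n")
    pd.DataFrame(
        [
            dict(
                id=m.id, type=m.type, scaffold=m.scaffold_id, pos=m.scaffold_pos_bp,
                primer_fwd=m.primer_fwd, primer_rev=m.primer_rev,
                allele_size_A=m.allele_size_A_bp, allele_size_B=m.allele_size_B_bp,
            )
            for m in ds.markers
        ]
    ).to_csv(paths["markers"], sep="\t", index=False)
    truth_rows = [
        dict(kind="scaffold", id=s.id, chrom=s.truth_chrom, start=s.truth_start,
             strand=s.truth_strand, cM="")
        for s in ds.scaffolds
    ] + [
        dict(kind="marker", id=m.id, chrom=m.truth_chrom, start="", strand="",
             cM=round(m.truth_cM, 6))
        for m in ds.markers
    ]
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    ds.genotypes.to_frame().to_csv(paths["genotypes"])
    with open(paths["metadata"], "w") as fh:
        json.dump(ds.params, fh, indent=2, sort_keys=True)
    return paths


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str).fillna(MISSING)
    return GenotypeMatrix.from_frame(df)
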