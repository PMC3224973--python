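"""Two-point linkage analysis and genetic map construction for DH lines.

A doubled-haploid line is one observable recombinant gamete, so the
recombination fraction between two loci is estimated as r_hat = R/N, with
N the lines scored at both loci and R the recombinant ones. The linkage
evidence is the base-10 likelihood ratio of r_hat against independence
(r = 0.5):

    LOD = R*log10(r_hat) + (N-R)*log10(1-r_hat) + N*log10(2)

with the convention 0*log10(0) = 0, so perfect cosegregation gives
LOD = N*log10(2). Groups are connected components of the graph with an
edge wherever LOD >= threshold and r_hat < 0.5; within a group,
cosegregating markers (r_hat = 0) are merged into bins, bins are ordered
to minimise the sum of adjacent recombination fractions (SARF; exhaustive
for <= 8 bins, greedy seriation plus 2-opt otherwise), and cM positions
accumulate the Haldane transform d = -50*ln(1-2r) along adjacent bins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .simulate import MISSING, GenotypeMatrix

LOG10_2 = np.log10(2.0)
R_CAP = 0.4999  # r_hat at/above this contributes no linkage edge


@dataclass(frozen=True)
class PairwiseLinkage:
    marker_i: str
    marker_j: str
    n_informative: int
    n_recombinant: int
    r_hat: float
    lod: float


@dataclass
class LinkageGroup:
    name: str
    loci: list[tuple[str, float]]  # (marker_id, position_cM), non-decreasing
    bins: list[list[str]] = field(default_factory=list)

    @property
    def length_cM(self) -> float:
        return self.loci[-1][1] if self.loci else 0.0

    @property
    def marker_ids(self) -> list[str]:
        return [m for m, _ in self.loci]

    @property
    def positions(self) -> dict[str, float]:
        return dict(self.loci)


@dataclass
class LinkageMap:
    groups: list[LinkageGroup]
    unlinked: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def total_length_cM(self) -> float:
        return sum(g.length_cM for g in self.groups)

    @property
    def n_markers(self) -> int:
        return sum(len(g.loci) for g in self.groups)

    def group_of(self) -> dict[str, str]:
        return {m: g.name for g in self.groups for m in g.marker_ids}

    def position_of(self) -> dict[str, float]:
        return {m: p for g in self.groups for m, p in g.loci}


# ---------------------------------------------------------------------------
# Haldane mapping function

def haldane_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Map distance in cM under no interference: d = -50*ln(1-2r)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    d = -50.0 * np.log1p(-2.0 * r)
    return float(d) if d.ndim == 0 else d


def inverse_haldane(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a map distance: r = (1 - e^(-d/50))/2."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * -np.expm1(-d / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# two-point estimation

def _check_dh_calls(calls: np.ndarray) -> None:
    bad = set(np.unique(calls)) - {"A", "B", MISSING}
    if bad:
        raise ValueError(f"non-DH genotype symbols: {sorted(bad)}")


def lod_score(n: int, r_count: int) -> float:
    """Base-10 likelihood ratio of linkage at r_hat = R/N vs r = 0.5."""
    if n == 0:
        return float("nan")
    r_hat = min(r_count / n, 0.5)  # capped, so r_hat >= 0.5 scores 0
    lod = n * LOG10_2
    if r_count > 0:
        lod += r_count * np.log10(r_hat)
    if r_count < n:
        lod += (n - r_count) * np.log10(1.0 - r_hat)
    return float(lod)


def pairwise_linkage(
    calls_i: np.ndarray, calls_j: np.ndarray, marker_i: str = "i", marker_j: str = "j"
) -> PairwiseLinkage:
    """Two-point r_hat and LOD from two DH call vectors.

    N counts lines non-missing at both loci; N = 0 yields NaN sentinels.
    """
    calls_i = np.asarray(calls_i, dtype="<U1")
    calls_j = np.asarray(calls_j, dtype="<U1")
    if calls_i.shape != calls_j.shape:
        raise ValueError("call vectors must have equal length")
    _check_dh_calls(calls_i)
    _check_dh_calls(calls_j)
    ok = (calls_i != MISSING) & (calls_j != MISSING)
    n = int(ok.sum())
    if n == 0:
        return PairwiseLinkage(marker_i, marker_j, 0, 0, float("nan"), float("nan"))
    r_count = int((calls_i[ok] != calls_j[ok]).sum())
    r_hat = min(r_count / n, 0.5)
    return PairwiseLinkage(marker_i, marker_j, n, r_count, r_hat, lod_score(n, r_count))


def pairwise_table(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs N, R, r_hat and LOD matrices, vectorised.

    Returns (N, R, r_hat, lod) as dense symmetric arrays; diagonal r_hat
    is 0 and diagonal LOD is the self-cosegregation score.
    """
    _check_dh_calls(genotypes.calls)
    mask = (genotypes.calls != MISSING).astype(np.float64)
    x = (genotypes.calls == "B").astype(np.float64) * mask
    n_mat = mask.T @ mask
    # R_ij = sum_l m_il m_jl (x_il + x_jl - 2 x_il x_jl)
    xm = x  # x already zero where masked
    s1 = xm.T @ mask
    r_mat = s1 + s1.T - 2.0 * (xm.T @ xm)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_hat = np.where(n_mat > 0, r_mat / n_mat, np.nan)
    r_hat = np.minimum(r_hat, 0.5)
    # vectorised LOD at the capped estimate, with 0*log(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r_mat > 0, r_mat * np.log10(np.where(r_mat > 0, r_hat, 1.0)), 0.0)
        k = n_mat - r_mat
        t2 = np.where(k > 0, k * np.log10(np.where(k > 0, 1.0 - r_hat, 1.0)), 0.0)
    lod = np.where(n_mat > 0, t1 + t2 + n_mat * LOG10_2, np.nan)
    return n_mat.astype(int), r_mat.astype(int), r_hat, lod


# ---------------------------------------------------------------------------
# grouping

def group_markers(
    marker_ids: list[str], r_hat: np.ndarray, lod: np.ndarray, lod_threshold: float = 7.0
) -> list[list[str]]:
    """Partition markers into connected components of the linkage graph.

    An edge joins i and j when lod >= threshold and r_hat < 0.5 (pairs at
    the cap carry no linkage evidence). Components are labelled and
    ordered by their smallest member marker id; singletons are returned
    too (the caller decides whether they count as "unlinked").
    """
    n = len(marker_ids)
    with np.errstate(invalid="ignore"):
        adj = (lod >= lod_threshold) & (r_hat < R_CAP)
    np.fill_diagonal(adj, False)
    # union-find over the boolean adjacency
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    ii, jj = np.nonzero(np.triu(adj, 1))
    for a, b in zip(ii.tolist(), jj.tolist()):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    comps: dict[int, list[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(marker_ids[i])
    groups = [sorted(v) for v in comps.values()]
    groups.sort(key=lambda g: g[0])
    return groups


# ---------------------------------------------------------------------------
# binning and ordering

def merge_bins(members: list[int], r_count: np.ndarray, n_mat: np.ndarray) -> list[list[int]]:
    """Merge cosegregating markers (observed R = 0 with N > 0) into bins."""
    parent = {i: i for i in members}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in itertools.combinations(members, 2):
        if n_mat[a, b] > 0 and r_count[a, b] == 0:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    bins: dict[int, list[int]] = {}
    for i in members:
        bins.setdefault(find(i), []).append(i)
    return [sorted(v) for v in bins.values()]


def _sarf(order: list[int], dist: np.ndarray) -> float:
    return float(sum(dist[order[k], order[k + 1]] for k in range(len(order) - 1)))


def _order_exhaustive(n: int, dist: np.ndarray) -> list[int]:
    best, best_s = None, np.inf
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:  # each order once (reversal-equivalent)
            continue
        s = _sarf(list(perm), dist)
        if s < best_s - 1e-12 or (abs(s - best_s) <= 1e-12 and (best is None or list(perm) < best)):
            best, best_s = list(perm), s
    return best if best is not None else list(range(n))


def _order_greedy_2opt(n: int, dist: np.ndarray) -> list[int]:
    # seed: endpoints = most distant pair; grow by nearest neighbour at
    # either end, then 2-opt until no improving segment reversal
    d = dist.copy()
    i0, j0 = divmod(int(np.argmax(d)), n)
    path = [min(i0, j0)]
    remaining = set(range(n)) - {path[0]}
    while remaining:
        tail = path[-1]
        nxt = min(remaining, key=lambda k: (d[tail, k], k))
        path.append(nxt)
        remaining.remove(nxt)
    improved = True
    while improved:
        improved = False
        for a in range(n - 1):
            for b in range(a + 1, n):
                cur = 0.0
                if a > 0:
                    cur += d[path[a - 1], path[a]]
                if b < n - 1:
                    cur += d[path[b], path[b + 1]]
                new = 0.0
                if a > 0:
                    new += d[path[a - 1], path[b]]
                if b < n - 1:
                    new += d[path[a], path[b + 1]]
                if new < cur - 1e-12:
                    path[a : b + 1] = path[a : b + 1][::-1]
                    improved = True
    return path


def order_group(
    bins: list[list[int]], r_hat: np.ndarray, n_mat: np.ndarray, marker_ids: list[str]
) -> list[list[int]]:
    """Order bins to minimise SARF; deterministic orientation.

    Inter-bin recombination fraction is the N-weighted pooled estimate
    over member pairs. Exhaustive search for <= 8 bins, greedy seriation
    plus 2-opt for larger groups. The returned order puts the
    lexicographically smaller terminal bin first (final orientation is
    fixed later by anchors).
    """
    nb = len(bins)
    if nb < 2:
        return bins
    dist = np.zeros((nb, nb))
    for a in range(nb):
        for b in range(a + 1, nb):
            rr = sum(r_hat[i, j] * n_mat[i, j] for i in bins[a] for j in bins[b])
            nn = sum(n_mat[i, j] for i in bins[a] for j in bins[b])
            if nn == 0:
                ia, ib = bins[a][0], bins[b][0]
                raise ValueError(
                    f"disconnected pairwise data between {marker_ids[ia]} and {marker_ids[ib]}"
                )
            dist[a, b] = dist[b, a] = rr / nn
    order = _order_exhaustive(nb, dist) if nb <= 8 else _order_greedy_2opt(nb, dist)
    first = min(marker_ids[i] for i in bins[order[0]])
    last = min(marker_ids[i] for i in bins[order[-1]])
    if last < first:
        order = order[::-1]
    return [bins[k] for k in order]


def _bin_positions(ordered_bins: list[list[int]], r_hat: np.ndarray, n_mat: np.ndarray) -> list[float]:
    """Cumulative Haldane distances between adjacent bins."""
    pos = [0.0]
    for a, b in zip(ordered_bins[:-1], ordered_bins[1:]):
        rr = sum(r_hat[i, j] * n_mat[i, j] for i in a for j in b)
        nn = sum(n_mat[i, j] for i in a for j in b)
        r = min(rr / nn if nn else 0.0, R_CAP)
        pos.append(pos[-1] + float(haldane_cm(r)))
    return pos


# ---------------------------------------------------------------------------
# sklearn-style estimator + build_map wrapper

class LinkageMapper:
    """Genetic-map estimator over a DH genotype matrix.

    Clusters markers into linkage groups by LOD-threshold connected
    components, orders each group by SARF minimisation and assigns
    Haldane cM positions. Follows the scikit-learn estimator protocol:
    ``fit`` consumes a :class:`GenotypeMatrix` (or lines x markers array
    of 'A'/'B'/'-'), fitted state lives in trailing-underscore
    attributes.

    Parameters
    ----------
    lod_threshold : float
        Minimum two-point LOD for a grouping edge (default 7).
    min_informative : int
        Pairs with fewer informative lines are flagged low-confidence.
    anchors : dict or None
        Optional marker_id -> chromosome-name hints; groups are named by
        majority anchor vote and flipped so anchor positions ascend.
    """

    def __init__(self, lod_threshold: float = 7.0, min_informative: int = 20,
                 anchors: dict[str, str] | None = None):
        self.lod_threshold = lod_threshold
        self.min_informative = min_informative
        self.anchors = anchors

    # minimal get/set_params so the estimator composes with sklearn tools
    def get_params(self, deep: bool = True) -> dict:
        return {
            "lod_threshold": self.lod_threshold,
            "min_informative": self.min_informative,
            "anchors": self.anchors,
        }

    def set_params(self, **params) -> "LinkageMapper":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "LinkageMapper":
        gm = X if isinstance(X, GenotypeMatrix) else GenotypeMatrix(
            line_ids=[f"L{i}" for i in range(np.asarray(X).shape[0])],
            marker_ids=[f"M{j}" for j in range(np.asarray(X).shape[1])],
            calls=np.asarray(X, dtype="<U1"),
        )
        ids = gm.marker_ids
        n_mat, r_count, r_hat, lod = pairwise_table(gm)
        self.n_informative_ = n_mat
        self.r_hat_ = r_hat
        self.lod_ = lod
        self.low_confidence_pairs_ = int(
            (np.triu(n_mat, 1) > 0).sum() - (np.triu(n_mat, 1) >= self.min_informative).sum()
        )
        # per-marker 1:1 segregation screen (markers retained regardless)
        from scipy.stats import binomtest
        self.segregation_pvalues_ = {}
        for j, mid in enumerate(ids):
            col = gm.calls[:, j]
            nb = int((col == "B").sum())
            nn = int((col != MISSING).sum())
            self.segregation_pvalues_[mid] = (
                binomtest(nb, nn, 0.5).pvalue if nn else float("nan")
            )

        comps = group_markers(ids, r_hat, lod, self.lod_threshold)
        id_to_idx = {m: i for i, m in enumerate(ids)}
        groups: list[LinkageGroup] = []
        unlinked: list[str] = []
        conflicts: list[str] = []
        for comp in comps:
            if len(comp) < 2:
                unlinked.extend(comp)
                continue
            members = [id_to_idx[m] for m in comp]
            bins = merge_bins(members, r_count, n_mat)
            bins.sort(key=lambda b: ids[b[0]])
            ordered = order_group(bins, r_hat, n_mat, ids)
            pos = _bin_positions(ordered, r_hat, n_mat)
            loci = []
            for b, p in zip(ordered, pos):
                for i in sorted(b, key=lambda k: ids[k]):
                    loci.append((ids[i], p))
            groups.append(LinkageGroup(name="", loci=loci,
                                       bins=[[ids[i] for i in b] for b in ordered]))
        self._name_and_orient(groups, conflicts)
        groups.sort(key=lambda g: (g.name.startswith("LG"), g.name))
        self.map_ = LinkageMap(
            groups=groups, unlinked=sorted(unlinked),
            metadata={
                "lod_threshold": self.lod_threshold,
                "mapping_function": "haldane",
                "anchor_conflicts": conflicts,
            },
        )
        self.labels_ = self.map_.group_of()
        return self

    def _name_and_orient(self, groups: list[LinkageGroup], conflicts: list[str]) -> None:
        anchors = self.anchors or {}
        used: set[str] = set()
        unnamed = 0
        for g in groups:
            votes: dict[str, int] = {}
            for m, _ in g.loci:
                if m in anchors:
                    votes[anchors[m]] = votes.get(anchors[m], 0) + 1
            name = ""
            if votes:
                top = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
                if len(top) > 1 and top[0][1] == top[1][1]:
                    conflicts.append(
                        f"tie between {top[0][0]} and {top[1][0]} ({top[0][1]} votes each)"
                    )
                elif top[0][0] in used:
                    conflicts.append(f"{top[0][0]} claimed by two groups")
                else:
                    name = top[0][0]
                    used.add(name)
            if not name:
                unnamed += 1
                name = f"LG{unnamed:02d}"
            g.name = name
            # flip so known anchor positions ascend along the group
            truth_cm = getattr(self, "_anchor_cm", None)
            if truth_cm:
                xy = [(p, truth_cm[m]) for m, p in g.loci if m in truth_cm]
                if len(xy) >= 2:
                    from scipy.stats import kendalltau
                    tau = kendalltau([a for a, _ in xy], [b for _, b in xy]).statistic
                    if tau is not None and tau < 0:
                        L = g.length_cM
                        g.loci = [(m, L - p) for m, p in reversed(g.loci)]
                        g.bins = list(reversed(g.bins))

    def set_anchor_positions(self, anchor_cm: dict[str, float]) -> "LinkageMapper":
        """Optional known genetic positions for anchor markers, used only
        to choose each group's coordinate direction."""
        self._anchor_cm = anchor_cm
        return self


def build_map(
    genotypes: GenotypeMatrix,
    lod_threshold: float = 7.0,
    anchors: dict[str, str] | None = None,
    anchor_cm: dict[str, float] | None = None,
) -> LinkageMap:
    """Grouping, binning, ordering and Haldane positioning in one call."""
    est = LinkageMapper(lod_threshold=lod_threshold, anchors=anchors)
    if anchor_cm:
        est.set_anchor_positions(anchor_cm)
    est.fit(genotypes)
    return est.map_


# ---------------------------------------------------------------------------
# map I/O

def write_map_tsv(linkage_map: LinkageMap, path) -> None:
    import pandas as pd

    rows = []
    for g in linkage_map.groups:
        bin_of = {m: k for k, b in enumerate(g.bins) for m in b}
        for m, p in g.loci:
            rows.append(dict(group=g.name, marker=m, position_cM=round(p, 3),
                             bin_id=f"{g.name}_bin{bin_of.get(m, -1):03d}"))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_loc(genotypes: GenotypeMatrix, path, name: str = "population") -> None:
    """JoinMap-style .loc export (DH population type)."""
    with open(path, "w") as fh:
        fh.write(f"name = {name}\npopt = DH\n")
        fh.write(f"nloc = {genotypes.n_markers}\nnind = {genotypes.n_lines}\n\n")
        for j, mid in enumerate(genotypes.marker_ids):
            calls = "".join(genotypes.calls[:, j]).replace(MISSING, "u").lower()
            fh.write(f"{mid}\n")
            for i in range(0, len(calls), 60):
                fh.write(" " + " ".join(calls[i : i + 60]) + "\n")
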