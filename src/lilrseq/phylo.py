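"""Evolutionary distances, neighbor-joining trees, and lineage assignment.

Distances follow the models used for the study's trees: Jukes-Cantor,
Tamura-Nei (TN93, with empirical base frequencies and transitions split by
purine/pyrimidine class), and the Nei-Gojobori proportion of nonsynonymous
substitutions per nonsynonymous site with Jukes-Cantor correction. Gapped
columns are excluded pairwise. Trees are built with the Saitou-Nei
neighbor-joining agglomeration with a deterministic tie rule, supports come
from column-resampling bootstrap, and allele lineages are maximal supported
clades whose internal divergence stays below a configurable ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from itertools import combinations, permutations

import numpy as np
from skbio import TreeNode

from .gene_model import STOP_CODONS, translate_cds

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturatedDistanceError(ValueError):
    """Observed divergence outside the model's correctable domain."""


def _ungapped_pairs(a: str, b: str):
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            yield x, y


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) with pairwise deletion."""
    n = diff = 0
    for x, y in _ungapped_pairs(a, b):
        n += 1
        diff += x != y
    if n == 0:
        raise ValueError("no comparable (ungapped) columns")
    p = diff / n
    if p >= 0.75:
        raise SaturatedDistanceError(f"p = {p:.3f} >= 3/4")
    return -0.75 * math.log(1 - 4 * p / 3)


def tamura_nei_distance(a: str, b: str) -> float:
    """TN93 distance with base frequencies estimated from the pair."""
    counts = {c: 0 for c in "ACGT"}
    n = p1 = p2 = q = 0
    for x, y in _ungapped_pairs(a, b):
        counts[x] += 1
        counts[y] += 1
        n += 1
        if x != y:
            if {x, y} <= PURINES:
                p1 += 1
            elif {x, y} <= PYRIMIDINES:
                p2 += 1
            else:
                q += 1
    if n == 0:
        raise ValueError("no comparable (ungapped) columns")
    total = 2 * n
    gA, gC, gG, gT = (counts[c] / total for c in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = p1 / n, p2 / n, q / n
    k1 = 2 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2 * gT * gC / gY if gY > 0 else 0.0
    k3 = 2 * (gR * gY - (gA * gG * gY / gR if gR else 0)
              - (gT * gC * gR / gY if gY else 0))
    try:
        w1 = 1 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 1.0
        w2 = 1 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 1.0
        w3 = 1 - Q / (2 * gR * gY)
        if min(w1, w2, w3) <= 0:
            raise ValueError
        return -(k1 * math.log(w1) + k2 * math.log(w2) + k3 * math.log(w3))
    except (ValueError, ZeroDivisionError) as exc:
        raise SaturatedDistanceError("TN93 logarithm domain violation") from exc


# -- Nei-Gojobori ---------------------------------------------------------

def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at ``pos`` that are synonymous
    (changes to stop codons count as nonsynonymous)."""
    aa = translate_cds(codon) or "*"
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt in STOP_CODONS:
            continue
        if (translate_cds(alt) or "*") == aa:
            syn += 1
    return syn / 3


def codon_syn_sites(codon: str) -> float:
    return sum(_syn_fraction(codon, i) for i in range(3))


def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences over all shortest
    mutational pathways between two codons, skipping paths through stops."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    totals = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_cds(cur) == translate_cds(nxt) and cur not in STOP_CODONS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:  # all paths blocked by stops: count ignoring the block
        totals = [(0, len(diffs))]
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def nei_gojobori_ns(a: str, b: str) -> float:
    """Nonsynonymous substitutions per nonsynonymous site (Jukes-Cantor
    corrected), by codon-pathway averaging."""
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("aligned CDS of equal length, multiple of 3, required")
    S = Nd = Sd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        c1, c2 = a[i : i + 3].upper(), b[i : i + 3].upper()
        if "-" in c1 + c2 or not set(c1 + c2) <= set("ACGT"):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError("internal stop codon in CDS")
        n_codons += 1
        S += (codon_syn_sites(c1) + codon_syn_sites(c2)) / 2
        sd, nd = codon_path_differences(c1, c2)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codons")
    N = 3 * n_codons - S
    pN = Nd / N
    if pN >= 0.75:
        raise SaturatedDistanceError(f"pN = {pN:.3f} >= 3/4")
    return -0.75 * math.log(1 - 4 * pN / 3)


DISTANCE_FUNCS = {
    "JC": jc_distance,
    "TN": tamura_nei_distance,
    "NG-nonsyn": nei_gojobori_ns,
}


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    method: str
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.d[i, j])


def distance_matrix(
    seqs: dict[str, str], method: str = "JC"
) -> DistanceMatrix:
    func = DISTANCE_FUNCS[method]
    labels = list(seqs)
    n = len(labels)
    d = np.zeros((n, n))
    saturated = []
    for i, j in combinations(range(n), 2):
        try:
            v = func(seqs[labels[i]], seqs[labels[j]])
        except SaturatedDistanceError:
            v = np.nan
            saturated.append((labels[i], labels[j]))
        d[i, j] = d[j, i] = v
    return DistanceMatrix(labels, d, method, saturated)


# -- neighbor joining -----------------------------------------------------

def build_nj_tree(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted newick string.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) pair of cluster representative labels; negative branch lengths
    are clamped to zero with the deficit moved to the sister branch.
    """
    if len(dm.labels) < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(dm.d).any():
        raise SaturatedDistanceError("saturated entries in distance matrix")
    labels = list(dm.labels)
    reps = list(dm.labels)  # representative (min leaf) per active cluster
    newicks = [_quote(l) for l in labels]
    d = dm.d.astype(float).copy()
    active = list(range(len(labels)))
    while len(active) > 2:
        n = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                i, j = active[ii], active[jj]
                qv = (n - 2) * d[i, j] - r[i] - r[j]
                key = (qv, tuple(sorted((reps[i], reps[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_nwk = f"({newicks[i]}:{li:.10f},{newicks[j]}:{lj:.10f})"
        new_d = {}
        for k in active:
            if k in (i, j):
                continue
            new_d[k] = (d[i, k] + d[j, k] - d[i, j]) / 2
        # reuse slot i for the merged cluster
        for k, v in new_d.items():
            d[i, k] = d[k, i] = v
        newicks[i] = new_nwk
        reps[i] = min(reps[i], reps[j])
        active.remove(j)
    i, j = active
    dist = max(d[i, j], 0.0)
    return f"({newicks[i]}:{dist / 2:.10f},{newicks[j]}:{dist / 2:.10f});"


def _quote(label: str) -> str:
    if any(c in label for c in "():;, '\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def nj_tree_from_seqs(seqs: dict[str, str], method: str = "JC") -> str:
    return build_nj_tree(distance_matrix(seqs, method))


# -- bootstrap ------------------------------------------------------------

def _bipartitions(newick: str) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each canonicalized as the side not
    containing the lexicographically smallest leaf."""
    tree = TreeNode.read(StringIO(newick))
    leaves = {t.name for t in tree.tips()}
    anchor = min(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        if anchor in side:
            side = frozenset(leaves - side)
        parts.add(side)
    return parts


def _jc_matrix(arr: np.ndarray, labels: list[str]) -> DistanceMatrix:
    """Vectorized JC distance matrix over a uint8 alignment (pairwise
    deletion); used for bootstrap replicates."""
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        m = int(both.sum())
        if m == 0:
            raise ValueError("no comparable columns")
        p = float((arr[i, both] != arr[j, both]).mean())
        if p >= 0.75:
            raise SaturatedDistanceError(f"p = {p:.3f} >= 3/4")
        d[i, j] = d[j, i] = -0.75 * math.log(1 - 4 * p / 3)
    return DistanceMatrix(labels, d, "JC")


def bootstrap_support(
    seqs: dict[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    method: str = "JC",
) -> tuple[str, dict[frozenset[str], float]]:
    """Column-resampling bootstrap clade support on the reference NJ tree.

    Returns the reference newick and, per non-trivial clade (canonical
    bipartition), the fraction of replicates containing it.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    reference = nj_tree_from_seqs(seqs, method)
    ref_parts = _bipartitions(reference)
    if n_reps == 0:
        return reference, {}
    rng = np.random.default_rng(seed)
    labels = list(seqs)
    arr = np.stack(
        [np.frombuffer(seqs[l].encode(), dtype=np.uint8) for l in labels]
    )
    ncol = arr.shape[1]
    hits = {p: 0 for p in ref_parts}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        sub = arr[:, cols]
        try:
            if method == "JC":
                dm = _jc_matrix(sub, labels)
            else:
                rep = {l: sub[i].tobytes().decode() for i, l in enumerate(labels)}
                dm = distance_matrix(rep, method)
            parts = _bipartitions(build_nj_tree(dm))
        except (SaturatedDistanceError, ValueError):
            continue
        for p in ref_parts:
            if p in parts:
                hits[p] += 1
    return reference, {p: h / n_reps for p, h in hits.items()}


# -- lineage assignment ---------------------------------------------------

@dataclass
class LineageAssignment:
    lineage_of: dict[str, str]  # allele -> 3-digit lineage id
    clades: dict[str, list[str]]  # lineage id -> member alleles
    support: dict[str, float]  # lineage id -> bootstrap support (1.0 singleton)


def assign_lineages(
    newick: str,
    dm: DistanceMatrix,
    support: dict[frozenset[str], float] | None = None,
    *,
    min_support: float = 0.7,
    max_intra: float = 0.04,
    legacy_map: dict[str, str] | None = None,
) -> LineageAssignment:
    """Cut a supported NJ tree into allele lineages.

    Lineages are maximal clades with bootstrap support >= ``min_support``
    whose internal pairwise divergence does not exceed ``max_intra``
    (substitutions/site); unresolved leaves become singleton lineages (the
    nomenclature explicitly allows single-allele lineages). Ids are 3-digit,
    assigned in discovery order unless pinned by ``legacy_map``
    (allele name -> lineage id).
    """
    tree = TreeNode.read(StringIO(newick))
    if len(list(tree.tips())) > 2:
        tree = tree.root_at_midpoint()
    leaves_all = {t.name for t in tree.tips()}
    anchor = min(leaves_all)
    support = support or {}

    def clade_support(node) -> float:
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves_all - side) < 2:
            return 1.0
        key = side if anchor not in side else frozenset(leaves_all - side)
        return support.get(key, 1.0)

    def max_pairwise(names: list[str]) -> float:
        return max(
            (dm[(a, b)] for a, b in combinations(names, 2)), default=0.0
        )

    clades: list[tuple[list[str], float]] = []

    def walk(node) -> None:
        names = sorted(t.name for t in node.tips())
        if len(names) == 1:
            clades.append((names, 1.0))
            return
        sup = clade_support(node)
        if sup >= min_support and max_pairwise(names) <= max_intra:
            clades.append((names, sup))
            return
        for child in node.children:
            walk(child)

    walk(tree)
    # stable ordering: by tree discovery order already; assign ids
    legacy_map = legacy_map or {}
    assignment: dict[str, str] = {}
    clade_of: dict[str, list[str]] = {}
    sup_of: dict[str, float] = {}
    used = set(legacy_map.values())
    next_id = 1
    for names, sup in clades:
        pinned = {legacy_map[n] for n in names if n in legacy_map}
        if len(pinned) > 1:
            raise ValueError(f"legacy map splits clade {names} across lineages")
        if pinned:
            lid = pinned.pop()
        else:
            while f"{next_id:03d}" in used:
                next_id += 1
            lid = f"{next_id:03d}"
            used.add(lid)
        for n in names:
            assignment[n] = lid
        clade_of[lid] = names
        sup_of[lid] = sup
    return LineageAssignment(assignment, clade_of, sup_of)
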