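"""Population genetics of presence/absence SINE insertion genotypes.

Loci are biallelic: ``I`` (insertion present) and ``A`` (insertion absent).
Per-locus statistics (insertion frequency f_SINE, observed heterozygosity,
conditional exact Hardy-Weinberg p), Nei genetic distances between
populations, a neighbor-joining tree, and a two-level AMOVA on 0/1/2 dosage
vectors with permutation p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sinepop.io import LocusTable

NEI_DISTANCE_CAP = 10.0


@dataclass
class LocusPopStats:
    locus_id: str
    population_id: str
    n: int
    n_II: int
    n_IA: int
    n_AA: int
    f_sine: float | None
    het_obs: float | None
    hwe_p: float | None

    @property
    def defined(self) -> bool:
        return self.n > 0


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    method: str = "nei1972"
    capped_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children=None):
        self.label = label
        self.children: list[tuple[_Node, float]] = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick_part(self) -> str:
        if self.is_leaf:
            return self.label
        inner = ",".join(f"{c.newick_part()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class PopTree:
    """An unrooted NJ tree (represented with a trifurcating root)."""

    root: _Node
    clamped_branches: int = 0

    def to_newick(self) -> str:
        return self.root.newick_part() + ";"

    def leaves(self) -> list[str]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.label)
            stack.extend(c for c, _ in node.children)
        return sorted(out)

    def cherries(self) -> set[frozenset[str]]:
        """Pairs of leaves attached to the same vertex (unrooted neighbors)."""
        found = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            kids = [c for c, _ in node.children]
            leaf_kids = [k.label for k in kids if k.is_leaf]
            for i in range(len(leaf_kids)):
                for j in range(i + 1, len(leaf_kids)):
                    found.add(frozenset((leaf_kids[i], leaf_kids[j])))
            stack.extend(kids)
        return found


# ---------------------------------------------------------------------------
# per-locus statistics


def _cell_stats(locus: str, pop: str, geno: pd.Series) -> LocusPopStats:
    geno = geno[geno != "missing"]
    n = len(geno)
    n_ii = int((geno == "II").sum())
    n_ia = int((geno == "IA").sum())
    n_aa = int((geno == "AA").sum())
    if n == 0:
        return LocusPopStats(locus, pop, 0, 0, 0, 0, None, None, None)
    f = (2 * n_ii + n_ia) / (2 * n)
    het = n_ia / n
    return LocusPopStats(locus, pop, n, n_ii, n_ia, n_aa, f, het, hwe_exact(n_ii, n_ia, n_aa))


def locus_stats(table: LocusTable) -> list[LocusPopStats]:
    """Exact genotype counts and derived statistics per (locus, population).

    Missing genotypes are excluded from n; an all-missing cell yields a row
    with ``n = 0`` and undefined statistics.
    """
    out = []
    for (locus, pop), sub in table.df.groupby(["locus_id", "population_id"], sort=True):
        out.append(_cell_stats(locus, pop, sub["genotype"]))
    return out


def stats_frame(stats: list[LocusPopStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": s.locus_id, "population_id": s.population_id, "n": s.n,
                "n_II": s.n_II, "n_IA": s.n_IA, "n_AA": s.n_AA,
                "f_sine": s.f_sine, "het_obs": s.het_obs, "hwe_p": s.hwe_p,
            }
            for s in stats
        ]
    )


def hwe_exact(n_II: int, n_IA: int, n_AA: int) -> float:
    """Conditional exact Hardy-Weinberg test for a biallelic locus.

    Conditioning on the observed allele counts, the probability of a
    configuration with h heterozygotes is proportional to
    ``n! / (n_II! h! n_AA!) * 2**h``; the two-sided p-value sums all
    configurations whose probability does not exceed the observed one
    (ties included, with a small relative tolerance on the log scale).
    Monomorphic input gives p = 1.
    """
    if min(n_II, n_IA, n_AA) < 0 or n_II + n_IA + n_AA < 1:
        raise ValueError("genotype counts must be non-negative with total >= 1")
    n = n_II + n_IA + n_AA
    n_i = 2 * n_II + n_IA  # insertion allele count

    hs = np.arange(n_i % 2, min(n_i, 2 * n - n_i) + 1, 2)
    iis = (n_i - hs) // 2
    aas = n - iis - hs
    from scipy.special import gammaln

    logw = (
        gammaln(n + 1)
        - gammaln(iis + 1)
        - gammaln(hs + 1)
        - gammaln(aas + 1)
        + hs * math.log(2.0)
    )
    log_obs = logw[np.nonzero(hs == n_IA)[0][0]]
    keep = logw <= log_obs + 1e-9
    # normalized sum of the kept configurations, in a stable log-sum-exp form
    shift = logw.max()
    return float(np.exp(logw[keep] - shift).sum() / np.exp(logw - shift).sum())


def ecotype_stats(
    table: LocusTable, grouping: dict[str, str]
) -> tuple[list[LocusPopStats], dict[str, tuple[float, float]]]:
    """Pool populations by ecotype, then per-locus stats and HWE per ecotype.

    Returns the pooled stats (``population_id`` holds the ecotype name) and
    the across-locus unweighted mean (f_SINE, Het) per ecotype.
    """
    missing = set(table.df["population_id"].unique()) - set(grouping)
    if missing:
        raise ValueError(f"population(s) {sorted(missing)} absent from grouping")
    df = table.df.copy()
    df["population_id"] = df["population_id"].map(grouping)
    df["individual_id"] = (
        table.df["population_id"].astype(str) + "/" + df["individual_id"].astype(str)
    )
    pooled = LocusTable(df)
    stats = locus_stats(pooled)
    means: dict[str, tuple[float, float]] = {}
    for eco in sorted(set(grouping.values())):
        rows = [s for s in stats if s.population_id == eco and s.defined]
        if rows:
            means[eco] = (
                float(np.mean([s.f_sine for s in rows])),
                float(np.mean([s.het_obs for s in rows])),
            )
    return stats, means


# ---------------------------------------------------------------------------
# distances and trees


def nei_distance(freqs: pd.DataFrame, method: str = "nei1972") -> DistanceMatrix:
    """Nei genetic distance between populations from insertion frequencies.

    ``freqs`` is populations x loci with entries f_SINE in [0, 1]; each locus
    contributes the two-allele vector (f, 1 - f).  ``nei1972`` is the standard
    distance D = -ln(J_xy / sqrt(J_x J_y)) with the J's summed over loci and
    alleles; ``nei1983`` (DA) is available as an alternative.  Disjoint allele
    sets (J_xy = 0) are reported at the cap ``NEI_DISTANCE_CAP`` and flagged.
    """
    if ((freqs < 0) | (freqs > 1)).any().any():
        raise ValueError("frequencies must lie in [0, 1]")
    labels = list(freqs.index.astype(str))
    f = freqs.to_numpy(dtype=float)
    p = np.stack([f, 1.0 - f], axis=-1)  # pop x locus x allele
    n = len(labels)
    d = np.zeros((n, n))
    capped = []
    for i in range(n):
        for j in range(i + 1, n):
            if method == "nei1972":
                jxy = float(np.sum(p[i] * p[j]))
                jx = float(np.sum(p[i] ** 2))
                jy = float(np.sum(p[j] ** 2))
                if jxy == 0.0:
                    dist = NEI_DISTANCE_CAP
                    capped.append((labels[i], labels[j]))
                else:
                    ratio = min(1.0, jxy / math.sqrt(jx * jy))
                    dist = -math.log(ratio)
            elif method == "nei1983":
                dist = 1.0 - float(np.mean(np.sum(np.sqrt(p[i] * p[j]), axis=-1)))
            else:
                raise ValueError(f"unknown distance method {method!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=labels, d=d, method=method, capped_pairs=capped)


def nj_tree(dist: DistanceMatrix) -> PopTree:
    """Neighbor joining (Saitou-Nei, Studier-Keppler Q criterion).

    Ties in Q are broken on the lexicographically smallest pair of node
    labels (an internal node carries the smallest leaf label beneath it), so
    the tree is deterministic.  Negative branch lengths are clamped to zero
    and counted in ``clamped_branches``.
    """
    m = len(dist.labels)
    if m < 3:
        raise ValueError("nj_tree needs at least 3 labels")
    nodes: list[_Node] = [_Node(label=lab) for lab in dist.labels]
    keys: list[str] = list(dist.labels)  # tie-break key = min leaf label below
    D = dist.d.astype(float).copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and pair_key < best[1]
                ):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = D[i, j] - li
        new = _Node(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        new_key = min(keys[i], keys[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        D2 = np.zeros((k - 1, k - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        nodes = [nodes[x] for x in keep] + [new]
        keys = [keys[x] for x in keep] + [new_key]
        D = D2

    # closed-form three-point star for the last three nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    root = _Node(children=[(nodes[0], clamp(la)), (nodes[1], clamp(lb)), (nodes[2], clamp(lc))])
    return PopTree(root=root, clamped_branches=clamped)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    percentages: tuple[float, float, float]
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_phi_st: float
    p_phi_ct: float
    p_phi_sc: float
    n_permutations: int
    seed: int | None
    truncated: bool


def _dosage_matrix(table: LocusTable) -> tuple[np.ndarray, list[str]]:
    """Individuals x loci insertion-allele dosage (0/1/2); drops individuals
    with any missing genotype."""
    code = {"II": 2, "IA": 1, "AA": 0}
    wide = table.df.pivot_table(
        index=["population_id", "individual_id"],
        columns="locus_id",
        values="genotype",
        aggfunc="first",
    )
    wide = wide.dropna(axis=0)
    wide = wide[~(wide == "missing").any(axis=1)]
    X = wide.apply(lambda col: col.map(code)).to_numpy(dtype=float)
    pops = [idx[0] for idx in wide.index]
    return X, pops


def _ss(X: np.ndarray) -> float:
    """Sum of squared deviations from the centroid (squared Euclidean)."""
    if len(X) == 0:
        return 0.0
    return float(np.sum((X - X.mean(axis=0)) ** 2))


def _components(
    X: np.ndarray, pop_of: np.ndarray, group_of_pop: dict[int, int], n_groups: int
) -> tuple[float, float, float]:
    """Nested variance components (sigma_a, sigma_b, sigma_c)."""
    N = len(X)
    pops = np.unique(pop_of)
    P = len(pops)
    G = n_groups
    group_of = np.array([group_of_pop[p] for p in pop_of])
    ss_wp = sum(_ss(X[pop_of == p]) for p in pops)
    ss_groups = sum(_ss(X[group_of == g]) for g in range(G))
    ss_total = _ss(X)
    ss_ap = ss_groups - ss_wp
    ss_ag = ss_total - ss_groups
    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1
    if df_wp < 1 or df_ap < 1 or df_ag < 1:
        raise ValueError("AMOVA needs more individuals/populations than levels")
    n_p = np.array([np.sum(pop_of == p) for p in pops], dtype=float)
    N_g = np.array([np.sum(group_of == g) for g in range(G)], dtype=float)
    sum_np2_by_g = np.array(
        [sum(n_p[k] ** 2 for k, p in enumerate(pops) if group_of_pop[p] == g) for g in range(G)]
    )
    n_c = (N - float(np.sum(sum_np2_by_g / N_g))) / df_ap
    n_cp = (float(np.sum(sum_np2_by_g / N_g)) - float(np.sum(n_p**2)) / N) / df_ag
    n_cpp = (N - float(np.sum(N_g**2)) / N) / df_ag
    ms_wp = ss_wp / df_wp
    ms_ap = ss_ap / df_ap
    ms_ag = ss_ag / df_ag
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n_c
    sigma_a = (ms_ag - sigma_c - n_cp * sigma_b) / n_cpp
    return sigma_a, sigma_b, sigma_c


def _phis(sa: float, sb: float, sc: float) -> tuple[float, float, float]:
    tot = sa + sb + sc
    phi_ct = sa / tot if tot > 0 else 0.0
    phi_st = (sa + sb) / tot if tot > 0 else 0.0
    phi_sc = sb / (sb + sc) if (sb + sc) > 0 else 0.0
    return phi_ct, phi_sc, phi_st


def amova(
    table: LocusTable,
    grouping: dict[str, str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA on insertion dosage vectors with permutation tests.

    Individuals are encoded as per-locus dosages (0/1/2); sums of squares use
    squared Euclidean distances partitioned among groups, among populations
    within groups, and within populations, with the standard nested-ANOVA
    expectations for unequal sizes.  Permutation p-values (seeded): Phi_ST
    permutes individuals across populations, Phi_CT permutes populations
    across groups, Phi_SC permutes individuals across populations within
    groups.
    """
    missing = set(table.df["population_id"].unique()) - set(grouping)
    if missing:
        raise ValueError(f"population(s) {sorted(missing)} absent from grouping")
    X, pop_names = _dosage_matrix(table)
    pop_labels = sorted(set(pop_names))
    group_labels = sorted(set(grouping[p] for p in pop_labels))
    if len(group_labels) < 2 or len(pop_labels) < 2:
        raise ValueError("AMOVA needs >= 2 groups and >= 2 populations")
    pop_index = {p: k for k, p in enumerate(pop_labels)}
    pop_of = np.array([pop_index[p] for p in pop_names])
    for p, k in pop_index.items():
        if np.sum(pop_of == k) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 complete individuals")
    group_index = {g: k for k, g in enumerate(group_labels)}
    group_of_pop = {pop_index[p]: group_index[grouping[p]] for p in pop_labels}
    G = len(group_labels)

    sa, sb, sc = _components(X, pop_of, group_of_pop, G)
    phi_ct, phi_sc, phi_st = _phis(sa, sb, sc)

    rng = np.random.default_rng(seed)
    ge_st = ge_ct = ge_sc = 0
    pops_arr = np.array(sorted(group_of_pop))
    pop_groups = np.array([group_of_pop[p] for p in pops_arr])
    group_of = np.array([group_of_pop[p] for p in pop_of])
    for _ in range(n_permutations):
        # Phi_ST: individuals shuffled across all populations
        perm = rng.permutation(len(X))
        a, b, c = _components(X[perm], pop_of, group_of_pop, G)
        if _phis(a, b, c)[2] >= phi_st - 1e-12:
            ge_st += 1
        # Phi_CT: whole populations shuffled across groups
        gperm = rng.permutation(pop_groups)
        gmap = {p: g for p, g in zip(pops_arr, gperm)}
        a, b, c = _components(X, pop_of, gmap, G)
        if _phis(a, b, c)[0] >= phi_ct - 1e-12:
            ge_ct += 1
        # Phi_SC: individuals shuffled across populations within their group
        perm2 = np.arange(len(X))
        for g in range(G):
            idx = np.flatnonzero(group_of == g)
            perm2[idx] = idx[rng.permutation(len(idx))]
        a, b, c = _components(X[perm2], pop_of, group_of_pop, G)
        if _phis(a, b, c)[1] >= phi_sc - 1e-12:
            ge_sc += 1
    B = n_permutations
    p_st = (1 + ge_st) / (B + 1)
    p_ct = (1 + ge_ct) / (B + 1)
    p_sc = (1 + ge_sc) / (B + 1)

    trunc = sa < 0 or sb < 0 or sc < 0
    pos = np.clip([sa, sb, sc], 0.0, None)
    total = float(pos.sum())
    pct = tuple(float(100.0 * x / total) for x in pos) if total > 0 else (0.0, 0.0, 100.0)
    return AmovaResult(
        sigma_a=sa, sigma_b=sb, sigma_c=sc,
        percentages=pct,
        phi_ct=phi_ct, phi_sc=phi_sc, phi_st=phi_st,
        p_phi_st=p_st, p_phi_ct=p_ct, p_phi_sc=p_sc,
        n_permutations=B, seed=seed, truncated=trunc,
    )


def frequencies_frame(stats: list[LocusPopStats]) -> pd.DataFrame:
    """Population x locus f_SINE frame from per-cell stats (NaN where undefined)."""
    df = stats_frame(stats)
    return df.pivot(index="population_id", columns="locus_id", values="f_sine")
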