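"""Population genetics: exact stats, HWE, Nei distance, NJ, AMOVA."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from sinepop import tables
from sinepop.io import LocusTable
from sinepop.popgen import (
    DistanceMatrix,
    amova,
    ecotype_stats,
    frequencies_frame,
    hwe_exact,
    locus_stats,
    nei_distance,
    nj_tree,
)
from sinepop.simulate import simulate_genotypes, table1_fixture

GROUPING = {p: ("resident" if p in ("PY", "DT") else "migratory")
            for p in tables.POPULATIONS}


# --- per-locus statistics ----------------------------------------------------


def test_locus_stats_agree_with_direct_recount(rng2):
    freqs = {f"P{p}": {f"L{l}": rng2.uniform() for l in range(4)} for p in range(3)}
    table = simulate_genotypes(freqs, 15, rng2)
    for s in locus_stats(table):
        sub = table.df[
            (table.df.locus_id == s.locus_id) & (table.df.population_id == s.population_id)
        ]["genotype"]
        n_ii, n_ia, n_aa = (sub == "II").sum(), (sub == "IA").sum(), (sub == "AA").sum()
        assert (s.n_II, s.n_IA, s.n_AA) == (n_ii, n_ia, n_aa)
        assert s.f_sine == pytest.approx((2 * n_ii + n_ia) / (2 * s.n))
        assert s.het_obs == pytest.approx(n_ia / s.n)


def test_all_missing_cell_flagged():
    df = pd.DataFrame(
        [{"locus_id": "L", "population_id": "P", "individual_id": f"I{i}",
          "genotype": "missing"} for i in range(5)]
    )
    (s,) = locus_stats(LocusTable(df))
    assert s.n == 0 and s.f_sine is None and s.het_obs is None


def test_monomorphic_cells():
    df = pd.DataFrame(
        [{"locus_id": "L", "population_id": "P", "individual_id": f"I{i}", "genotype": "II"}
         for i in range(8)]
    )
    (s,) = locus_stats(LocusTable(df))
    assert s.f_sine == 1.0 and s.het_obs == 0.0 and s.hwe_p == 1.0


# --- Hardy-Weinberg exact test ----------------------------------------------


def oracle_hwe(n_ii: int, n_ia: int, n_aa: int) -> Fraction:
    """Exact-rational enumeration over genotype configurations that share the
    observed allele counts (independent of the integer-weight implementation)."""
    n = n_ii + n_ia + n_aa
    n_i = 2 * n_ii + n_ia

    def prob(ii: int, ia: int, aa: int) -> Fraction:
        ways = (
            Fraction(math.factorial(n), math.factorial(ii) * math.factorial(ia) * math.factorial(aa))
            * Fraction(2) ** ia
        )
        return ways

    configs = []
    for ii in range(n + 1):
        ia = n_i - 2 * ii
        aa = n - ii - ia
        if ia < 0 or aa < 0:
            continue
        configs.append((ii, ia, aa))
    total = sum(prob(*c) for c in configs)
    obs = prob(n_ii, n_ia, n_aa)
    return sum(prob(*c) for c in configs if prob(*c) <= obs) / total


def test_hwe_exact_matches_enumeration_for_all_small_tables():
    for n in range(1, 26):
        for n_ii in range(n + 1):
            for n_ia in range(n - n_ii + 1):
                n_aa = n - n_ii - n_ia
                got = hwe_exact(n_ii, n_ia, n_aa)
                want = oracle_hwe(n_ii, n_ia, n_aa)
                assert got == pytest.approx(float(want), abs=1e-9), (n_ii, n_ia, n_aa)


def test_hwe_all_heterozygotes():
    assert hwe_exact(0, 10, 0) == pytest.approx(float(oracle_hwe(0, 10, 0)), abs=1e-12)
    assert hwe_exact(0, 10, 0) < 0.05  # 10/10 heterozygotes is extreme


def test_hwe_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact(0, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact(-1, 2, 3)


# --- ecotype pooling ---------------------------------------------------------


def test_single_population_per_ecotype_matches_locus_stats():
    table = table1_fixture()
    sub = LocusTable(table.df[table.df.population_id.isin(["XS", "PY"])])
    pooled, _ = ecotype_stats(sub, {"XS": "eco1", "PY": "eco2"})
    plain = locus_stats(sub)
    by_key = {(s.locus_id, s.population_id): s for s in plain}
    for s in pooled:
        ref = by_key[(s.locus_id, {"eco1": "XS", "eco2": "PY"}[s.population_id])]
        assert (s.n_II, s.n_IA, s.n_AA) == (ref.n_II, ref.n_IA, ref.n_AA)


def test_pooling_identical_populations_preserves_frequency():
    df = table1_fixture().df
    a = df[df.population_id == "XS"]
    b = a.copy()
    b["population_id"] = "XS2"
    merged = LocusTable(pd.concat([a, b], ignore_index=True))
    pooled, _ = ecotype_stats(merged, {"XS": "eco", "XS2": "eco"})
    singles = {s.locus_id: s for s in locus_stats(LocusTable(a))}
    for s in pooled:
        assert s.n == 2 * singles[s.locus_id].n
        assert s.f_sine == pytest.approx(singles[s.locus_id].f_sine)


def test_missing_population_in_grouping_errors():
    with pytest.raises(ValueError, match="absent"):
        ecotype_stats(table1_fixture(), {"XS": "eco"})


# --- Nei distance ------------------------------------------------------------


def test_nei_identical_populations_distance_zero():
    freqs = pd.DataFrame({"L1": [0.3, 0.3], "L2": [0.8, 0.8]}, index=["A", "B"])
    d = nei_distance(freqs)
    assert d.get("A", "B") == 0.0


def test_nei_hand_computed_value():
    freqs = pd.DataFrame({"L1": [0.9, 0.1]}, index=["A", "B"])
    d = nei_distance(freqs)
    # J_xy = 0.18, J_x = J_y = 0.82 -> D = -ln(0.18/0.82)
    assert d.get("A", "B") == pytest.approx(-math.log(0.18 / 0.82), abs=1e-9)
    assert d.get("A", "B") == pytest.approx(1.5163, abs=1e-4)


def test_nei_disjoint_alleles_capped():
    freqs = pd.DataFrame({"L1": [1.0, 0.0]}, index=["A", "B"])
    d = nei_distance(freqs)
    assert d.get("A", "B") == 10.0
    assert ("A", "B") in d.capped_pairs


def test_nei_monotone_in_frequency_gap():
    prev = -1.0
    for gap in np.linspace(0, 0.4, 9):
        freqs = pd.DataFrame({"L1": [0.5 - gap, 0.5 + gap]}, index=["A", "B"])
        cur = nei_distance(freqs).get("A", "B")
        assert cur >= prev - 1e-12
        prev = cur


def test_nei_da_alternative():
    freqs = pd.DataFrame({"L1": [0.9, 0.1]}, index=["A", "B"])
    d = nei_distance(freqs, method="nei1983")
    want = 1 - (math.sqrt(0.9 * 0.1) + math.sqrt(0.1 * 0.9))
    assert d.get("A", "B") == pytest.approx(want, abs=1e-12)


# --- neighbor joining --------------------------------------------------------


def _tree_leaf_distances(tree) -> dict[frozenset, float]:
    """Pairwise leaf path lengths from the reconstructed tree."""
    adj: dict[int, list[tuple[int, float]]] = {}
    labels: dict[int, str] = {}
    counter = itertools.count()

    def walk(node):
        nid = next(counter)
        if node.is_leaf:
            labels[nid] = node.label
        adj.setdefault(nid, [])
        for child, bl in node.children:
            cid = walk(child)
            adj[nid].append((cid, bl))
            adj[cid].append((nid, bl))
        return nid

    walk(tree.root)
    out = {}
    for leaf in labels:
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            cur = stack.pop()
            for nxt, bl in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + bl
                    stack.append(nxt)
        for other, d in dist.items():
            if other in labels and other != leaf:
                out[frozenset((labels[leaf], labels[other]))] = d
    return out


def test_three_taxa_closed_form():
    d = DistanceMatrix(
        labels=["A", "B", "C"],
        d=np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float),
    )
    tree = nj_tree(d)
    got = _tree_leaf_distances(tree)
    assert got[frozenset(("A", "B"))] == pytest.approx(5.0)
    assert got[frozenset(("A", "C"))] == pytest.approx(9.0)
    assert got[frozenset(("B", "C"))] == pytest.approx(10.0)


def test_additive_four_taxon_matrix_recovered():
    # ((A:2,B:3):1,(C:4,D:5)) -> additive distances
    D = np.array(
        [
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ],
        dtype=float,
    )
    tree = nj_tree(DistanceMatrix(labels=["A", "B", "C", "D"], d=D))
    got = _tree_leaf_distances(tree)
    for (i, a) in enumerate("ABCD"):
        for (j, b) in enumerate("ABCD"):
            if i < j:
                assert got[frozenset((a, b))] == pytest.approx(D[i, j], abs=1e-9)
    assert frozenset(("A", "B")) in tree.cherries()
    assert frozenset(("C", "D")) in tree.cherries()


def test_random_additive_matrices_reproduce_tree():
    # random additive metrics built by splitting a random leaf's pendant edge
    rng = np.random.default_rng(60)
    for rep in range(50):
        k = int(rng.integers(4, 8))
        labels = [f"T{i}" for i in range(k)]
        pend = {labels[0]: float(rng.uniform(0.5, 2.0)),
                labels[1]: float(rng.uniform(0.5, 2.0))}
        D = {frozenset(labels[:2]): pend[labels[0]] + pend[labels[1]]}
        placed = labels[:2]
        for lab in labels[2:]:
            host = placed[int(rng.integers(len(placed)))]
            stem = float(rng.uniform(0.2, 0.8)) * pend[host]
            drop = float(rng.uniform(0.2, 1.5))
            for other in placed:
                if other == host:
                    D[frozenset((lab, host))] = stem + drop
                else:
                    D[frozenset((lab, other))] = D[frozenset((host, other))] - stem + drop
            pend[host] = stem
            pend[lab] = drop
            placed.append(lab)
        mat = np.zeros((k, k))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    mat[i, j] = mat[j, i] = D[frozenset((a, b))]
        tree = nj_tree(DistanceMatrix(labels=labels, d=mat))
        got = _tree_leaf_distances(tree)
        for pair, d in D.items():
            assert got[pair] == pytest.approx(d, abs=1e-8)


def test_nj_is_deterministic_and_matches_skbio_topology():
    table = table1_fixture()
    freqs = frequencies_frame(locus_stats(table))
    dist = nei_distance(freqs)
    t1 = nj_tree(dist).to_newick()
    t2 = nj_tree(dist).to_newick()
    assert t1 == t2
    import skbio

    sk = skbio.tree.nj(skbio.DistanceMatrix(dist.d, ids=dist.labels))
    # resident populations form a cherry in both implementations
    py = sk.find("PY")
    siblings = {t.name for t in py.parent.children if t.name}
    assert "DT" in siblings
    assert frozenset(("PY", "DT")) in nj_tree(dist).cherries()


def test_nonsymmetric_matrix_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(labels=["A", "B"], d=np.array([[0.0, 1.0], [2.0, 0.0]]))


# --- AMOVA -------------------------------------------------------------------


def oracle_amova_components(X, pop_of, group_of_pop, n_groups):
    """Variance components from pairwise squared Euclidean distances."""
    N = len(X)
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)

    def ss(idx):
        if len(idx) < 2:
            return 0.0
        pairs = [(i, j) for i in idx for j in idx if i < j]
        return sum(d2[i, j] for i, j in pairs) / len(idx)

    pops = sorted(set(pop_of))
    group_of = [group_of_pop[p] for p in pop_of]
    idx_all = list(range(N))
    ss_total = ss(idx_all)
    ss_wp = sum(ss([i for i in idx_all if pop_of[i] == p]) for p in pops)
    ss_groups = sum(
        ss([i for i in idx_all if group_of[i] == g]) for g in range(n_groups)
    )
    P, G = len(pops), n_groups
    ms_wp = ss_wp / (N - P)
    ms_ap = (ss_groups - ss_wp) / (P - G)
    ms_ag = (ss_total - ss_groups) / (G - 1)
    n_p = {p: sum(1 for q in pop_of if q == p) for p in pops}
    N_g = {g: sum(1 for q in group_of if q == g) for g in range(n_groups)}
    sum_np2_by_g = {
        g: sum(n_p[p] ** 2 for p in pops if group_of_pop[p] == g) for g in range(n_groups)
    }
    n_c = (N - sum(sum_np2_by_g[g] / N_g[g] for g in N_g)) / (P - G)
    n_cp = (
        sum(sum_np2_by_g[g] / N_g[g] for g in N_g) - sum(v**2 for v in n_p.values()) / N
    ) / (G - 1)
    n_cpp = (N - sum(v**2 for v in N_g.values()) / N) / (G - 1)
    sc = ms_wp
    sb = (ms_ap - sc) / n_c
    sa = (ms_ag - sc - n_cp * sb) / n_cpp
    return sa, sb, sc


def _random_table(rng, freq_by_pop, n_ind):
    return simulate_genotypes(freq_by_pop, n_ind, rng)


def test_amova_components_match_pairwise_oracle(rng2):
    from sinepop.popgen import _components, _dosage_matrix

    for rep in range(10):
        freqs = {
            "P1": {"L1": rng2.uniform(), "L2": rng2.uniform()},
            "P2": {"L1": rng2.uniform(), "L2": rng2.uniform()},
            "P3": {"L1": rng2.uniform(), "L2": rng2.uniform()},
            "P4": {"L1": rng2.uniform(), "L2": rng2.uniform()},
        }
        table = _random_table(rng2, freqs, 3)  # 12 individuals
        X, pops = _dosage_matrix(table)
        pop_labels = sorted(set(pops))
        pop_index = {p: i for i, p in enumerate(pop_labels)}
        pop_of = np.array([pop_index[p] for p in pops])
        gmap = {0: 0, 1: 0, 2: 1, 3: 1}
        got = _components(X, pop_of, gmap, 2)
        want = oracle_amova_components(X, list(pop_of), gmap, 2)
        assert got == pytest.approx(want, abs=1e-9)


def test_amova_detects_planted_divergence(rng2):
    freqs = {
        "P1": {f"L{l}": 0.95 for l in range(5)},
        "P2": {f"L{l}": 0.95 for l in range(5)},
        "P3": {f"L{l}": 0.05 for l in range(5)},
        "P4": {f"L{l}": 0.05 for l in range(5)},
    }
    table = _random_table(rng2, freqs, 10)
    res = amova(table, {"P1": "g1", "P2": "g1", "P3": "g2", "P4": "g2"},
                n_permutations=999, seed=5)
    assert res.phi_ct > 0.5
    assert res.p_phi_st <= 0.01


def test_amova_null_components_truncate(rng2):
    freqs = {f"P{k}": {f"L{l}": 0.5 for l in range(5)} for k in range(1, 5)}
    table = _random_table(rng2, freqs, 10)
    res = amova(table, {"P1": "g1", "P2": "g1", "P3": "g2", "P4": "g2"},
                n_permutations=99, seed=6)
    assert sum(res.percentages) == pytest.approx(100.0)
    assert all(p >= 0 for p in res.percentages)


def test_amova_rejects_singleton_population():
    df = table1_fixture().df
    keep = df[df.population_id != "XS"]
    one = df[(df.population_id == "XS") & (df.individual_id == "XS_01")]
    table = LocusTable(pd.concat([keep, one], ignore_index=True))
    with pytest.raises(ValueError, match="fewer than 2"):
        amova(table, GROUPING, n_permutations=9, seed=0)


def test_amova_permutation_seed_reproducible():
    table = table1_fixture()
    r1 = amova(table, GROUPING, n_permutations=49, seed=9)
    r2 = amova(table, GROUPING, n_permutations=49, seed=9)
    assert (r1.p_phi_st, r1.p_phi_ct, r1.p_phi_sc) == (r2.p_phi_st, r2.p_phi_ct, r2.p_phi_sc)
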