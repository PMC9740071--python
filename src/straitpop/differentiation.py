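"""Population differentiation: haplotypic AMOVA, pairwise Phi-ST,
between-group distances and a moment-based divergence-time summary.

The AMOVA is the Excoffier-Smouse-Quattro decomposition on squared
inter-haplotype distances.  For the pairwise-difference metric used here
the squared distance is taken to be the difference count itself (the
haplotypic-data convention of the standard implementation); pass
``squared=True`` to square the counts instead.  Negative variance
components are reported as computed (flagged), never truncated, so the
Phi definitions stay exact.

Permutation significance (default 10,000 permutations) follows the
standard schemes: Phi_ST permutes sequences among all populations,
Phi_SC permutes sequences among populations within their group, and
Phi_CT permutes intact populations among groups; p-values carry the
+1/(B+1) correction.  When the number of distinct whole-population
reassignments is smaller than the request, Phi_CT is evaluated by
exhaustive enumeration instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .alignment import LocusAlignment, PopulationMap

__all__ = [
    "AmovaResult",
    "DivergenceSummary",
    "pairwise_distance_matrix",
    "amova",
    "pairwise_phist",
    "between_group_distance",
    "divergence_summary",
    "multilocus_divergence",
]


@dataclass(frozen=True)
class AmovaResult:
    df: tuple[int, int, int]                 # among groups, among pops/groups, within pops
    ss: tuple[float, float, float]
    sigma2: tuple[float, float, float]       # sigma2_a, sigma2_b, sigma2_c
    percent: tuple[float, float, float]
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float
    p_sc: float
    p_st: float
    permutations: int
    negative_components: bool
    exhaustive_ct: bool = False


@dataclass(frozen=True)
class DivergenceSummary:
    pair: tuple[str, str]
    dxy: float            # per site
    da: float             # per site, net of within-unit diversity
    t_hat_years: float    # Da / (2 mu); NaN when Da < 0
    note: str = "no-migration moment estimator"


def pairwise_distance_matrix(aln: LocusAlignment) -> tuple[np.ndarray, int]:
    """(n, n) matrix of pairwise difference counts over complete-deletion
    columns, plus the usable column count."""
    mask = aln.usable_mask()
    if not mask.any():
        raise ValueError(f"{aln.locus_name}: no comparable sites after deletion")
    mat = aln.matrix()[:, mask]
    n = mat.shape[0]
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        diffs = (mat[i + 1:] != mat[i]).sum(axis=1)
        d[i, i + 1:] = diffs
        d[i + 1:, i] = diffs
    return d, int(mask.sum())


def _ssd(d2: np.ndarray, parts: list[np.ndarray]) -> float:
    """Sum over partitions of (sum of squared distances within) / size."""
    return sum(d2[np.ix_(p, p)].sum() / (2.0 * len(p)) for p in parts)


def _components(d2: np.ndarray, pops: list[np.ndarray], pop_groups: list[int],
                n_groups: int) -> tuple:
    """Variance components from the three-level decomposition.

    ``pops`` is a list of per-population sequence index arrays;
    ``pop_groups[i]`` is the group index of population i.
    """
    N = d2.shape[0]
    P, G = len(pops), n_groups
    groups = [np.concatenate([p for p, g in zip(pops, pop_groups) if g == gi])
              for gi in range(G)]
    ssd_total = d2.sum() / (2.0 * N)
    ssd_wp = _ssd(d2, pops)
    ssd_wg = _ssd(d2, groups)
    ss_ag = ssd_total - ssd_wg
    ss_ap = ssd_wg - ssd_wp
    df = (G - 1, P - G, N - P)
    n_p = np.array([len(p) for p in pops], dtype=float)
    n_g = np.array([len(g) for g in groups], dtype=float)
    sum_np2_over_ng = sum(
        (n_p[[i for i in range(P) if pop_groups[i] == gi]] ** 2).sum() / n_g[gi]
        for gi in range(G)
    )
    n1 = (N - sum_np2_over_ng) / max(df[1], 1)
    n2 = (sum_np2_over_ng - (n_p ** 2).sum() / N) / max(df[0], 1)
    n3 = (N - (n_g ** 2).sum() / N) / max(df[0], 1)
    sigma_c = ssd_wp / df[2] if df[2] > 0 else 0.0
    sigma_b = ((ss_ap / df[1]) - sigma_c) / n1 if df[1] > 0 else 0.0
    sigma_a = ((ss_ag / df[0]) - sigma_c - n2 * sigma_b) / n3 if df[0] > 0 else 0.0
    return df, (ss_ag, ss_ap, ssd_wp), (sigma_a, sigma_b, sigma_c)


def _phis(sig: tuple[float, float, float]) -> tuple[float, float, float]:
    a, b, c = sig
    tot = a + b + c
    phi_ct = a / tot if tot else math.nan
    phi_st = (a + b) / tot if tot else math.nan
    phi_sc = b / (b + c) if (b + c) else math.nan
    return phi_ct, phi_sc, phi_st


def _layout(aln: LocusAlignment, pmap: PopulationMap):
    pop_of = pmap.population_of()
    grp_of_pop = pmap.group_of_population()
    pops_order = [p for p in pmap.populations()
                  if any(pop_of.get(sid) == p for sid in aln.sample_ids)]
    groups_order = list(dict.fromkeys(grp_of_pop[p] for p in pops_order))
    pop_idx = {p: i for i, p in enumerate(pops_order)}
    seq_pop = np.array([pop_idx[pop_of[sid]] for sid in aln.sample_ids])
    pops = [np.nonzero(seq_pop == i)[0] for i in range(len(pops_order))]
    pop_groups = [groups_order.index(grp_of_pop[p]) for p in pops_order]
    return pops, pop_groups, len(groups_order), pops_order, groups_order


def amova(aln: LocusAlignment, pmap: PopulationMap, permutations: int = 10_000,
          seed=None, squared: bool = False) -> AmovaResult:
    """Three-level hierarchical AMOVA with permutation p-values."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d, _ = pairwise_distance_matrix(aln)
    d2 = (d.astype(float) ** 2) if squared else d.astype(float)
    pops, pop_groups, G, *_ = _layout(aln, pmap)
    if G < 2:
        raise ValueError("AMOVA needs at least two groups")
    df, ss, sig = _components(d2, pops, pop_groups, G)
    phi_ct, phi_sc, phi_st = _phis(sig)
    tot = sum(sig)
    percent = tuple(100.0 * s / tot if tot else math.nan for s in sig)

    sizes = [len(p) for p in pops]
    N = d2.shape[0]

    def stat_from_assignment(perm_pops, perm_pop_groups):
        _, _, s = _components(d2, perm_pops, perm_pop_groups, G)
        return _phis(s)

    # Phi_ST: permute sequences among all populations
    ge_st = 0
    for _ in range(permutations):
        order = rng.permutation(N)
        cuts = np.cumsum(sizes)[:-1]
        perm_pops = np.split(order, cuts)
        _, _, st = stat_from_assignment(perm_pops, pop_groups)
        ge_st += st >= phi_st
    p_st = (ge_st + 1) / (permutations + 1)

    # Phi_SC: permute sequences among populations within their group
    ge_sc = 0
    group_members = [np.concatenate([pops[i] for i in range(len(pops))
                                     if pop_groups[i] == gi]) for gi in range(G)]
    for _ in range(permutations):
        perm_pops = [None] * len(pops)
        for gi in range(G):
            order = rng.permutation(group_members[gi])
            idx = [i for i in range(len(pops)) if pop_groups[i] == gi]
            cuts = np.cumsum([sizes[i] for i in idx])[:-1]
            for i, chunk in zip(idx, np.split(order, cuts)):
                perm_pops[i] = chunk
        _, sc, _ = stat_from_assignment(perm_pops, pop_groups)
        ge_sc += sc >= phi_sc
    p_sc = (ge_sc + 1) / (permutations + 1)

    # Phi_CT: permute intact populations among groups (group sizes in
    # populations held fixed); exhaustive when the assignment space is small
    group_sizes = [sum(1 for g in pop_groups if g == gi) for gi in range(G)]
    n_assign = math.factorial(len(pops))
    for gs in group_sizes:
        n_assign //= math.factorial(gs)
    exhaustive = n_assign <= permutations
    if exhaustive:
        all_assignments = _distinct_assignments(len(pops), group_sizes)
        vals = [stat_from_assignment(pops, list(a))[0] for a in all_assignments]
        p_ct = sum(v >= phi_ct for v in vals) / len(vals)
    else:
        ge_ct = 0
        for _ in range(permutations):
            perm = rng.permutation(len(pops))
            assign = [0] * len(pops)
            pos = 0
            for gi, gs in enumerate(group_sizes):
                for j in perm[pos:pos + gs]:
                    assign[j] = gi
                pos += gs
            ge_ct += stat_from_assignment(pops, assign)[0] >= phi_ct
        p_ct = (ge_ct + 1) / (permutations + 1)

    return AmovaResult(
        df=df, ss=ss, sigma2=sig, percent=percent,
        phi_ct=phi_ct, phi_sc=phi_sc, phi_st=phi_st,
        p_ct=p_ct, p_sc=p_sc, p_st=p_st,
        permutations=permutations,
        negative_components=any(s < 0 for s in sig),
        exhaustive_ct=exhaustive,
    )


def _distinct_assignments(P: int, group_sizes: list[int]) -> list[tuple[int, ...]]:
    """All assignments of P populations to groups with the given sizes,
    capped (lazily) at a workable enumeration bound."""
    out = []
    limit = 200_000
    def rec(remaining, assign):
        if len(out) > limit:
            return
        if not remaining:
            out.append(tuple(assign))
            return
        counts = [assign.count(gi) for gi in range(len(group_sizes))]
        i = P - len(remaining)
        for gi, gs in enumerate(group_sizes):
            if counts[gi] < gs:
                rec(remaining[1:], assign + [gi])
    rec(list(range(P)), [])
    return out


def _two_level_phist(d2: np.ndarray, parts: list[np.ndarray]) -> float:
    """Single-level Phi_ST for the given partition of sequences."""
    N = d2.shape[0]
    P = len(parts)
    ssd_total = d2.sum() / (2.0 * N)
    ssd_w = _ssd(d2, parts)
    ss_a = ssd_total - ssd_w
    df_a, df_w = P - 1, N - P
    n_p = np.array([len(p) for p in parts], dtype=float)
    n0 = (N - (n_p ** 2).sum() / N) / df_a
    sigma_w = ssd_w / df_w if df_w > 0 else 0.0
    sigma_a = (ss_a / df_a - sigma_w) / n0
    tot = sigma_a + sigma_w
    return sigma_a / tot if tot else math.nan


def pairwise_phist(aln: LocusAlignment, pmap: PopulationMap,
                   level: str = "group", permutations: int = 10_000,
                   seed=None, squared: bool = False):
    """Pairwise Phi_ST between units (populations or region groups) with
    sequence-permutation p-values.

    Returns ``(units, phist_matrix, pvalue_matrix)``; units with fewer than
    two sequences give NaN rows.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d, _ = pairwise_distance_matrix(aln)
    d2 = (d.astype(float) ** 2) if squared else d.astype(float)
    label_of = pmap.group_of() if level == "group" else pmap.population_of()
    labels = [label_of[sid] for sid in aln.sample_ids]
    units = list(dict.fromkeys(labels))
    if len(units) < 2:
        raise ValueError("need at least two units")
    members = {u: np.array([i for i, l in enumerate(labels) if l == u]) for u in units}
    k = len(units)
    phi = np.full((k, k), math.nan)
    pval = np.full((k, k), math.nan)
    np.fill_diagonal(phi, 0.0)
    for a, b in itertools.combinations(range(k), 2):
        ia, ib = members[units[a]], members[units[b]]
        if len(ia) < 2 or len(ib) < 2:
            continue
        idx = np.concatenate([ia, ib])
        sub = d2[np.ix_(idx, idx)]
        na = len(ia)
        obs = _two_level_phist(sub, [np.arange(na), np.arange(na, len(idx))])
        ge = 0
        for _ in range(permutations):
            order = rng.permutation(len(idx))
            ge += _two_level_phist(sub, [order[:na], order[na:]]) >= obs
        phi[a, b] = phi[b, a] = obs
        pval[a, b] = pval[b, a] = (ge + 1) / (permutations + 1)
    return units, phi, pval


def between_group_distance(aln: LocusAlignment, pmap: PopulationMap):
    """Mean p-distance (differences per usable site) over cross-group pairs."""
    d, L = pairwise_distance_matrix(aln)
    grp_of = pmap.group_of()
    labels = [grp_of[sid] for sid in aln.sample_ids]
    units = list(dict.fromkeys(labels))
    if len(units) < 2:
        raise ValueError("need at least two groups")
    k = len(units)
    out = np.zeros((k, k))
    for a, b in itertools.combinations(range(k), 2):
        ia = [i for i, l in enumerate(labels) if l == units[a]]
        ib = [i for i, l in enumerate(labels) if l == units[b]]
        mean_d = d[np.ix_(ia, ib)].mean() / L
        out[a, b] = out[b, a] = mean_d
    return units, out


def divergence_summary(aln: LocusAlignment, pmap: PopulationMap, mu: float,
                       level: str = "group") -> list[DivergenceSummary]:
    """dxy, net divergence Da = dxy - mean within-unit pi, and the moment
    split-time estimate T = Da / (2 mu) per unit pair.

    Valid only without post-split gene flow; Da < 0 yields a NaN time with
    the pair still reported.
    """
    d, L = pairwise_distance_matrix(aln)
    label_of = pmap.group_of() if level == "group" else pmap.population_of()
    labels = [label_of[sid] for sid in aln.sample_ids]
    units = list(dict.fromkeys(labels))
    out = []
    for a, b in itertools.combinations(units, 2):
        ia = [i for i, l in enumerate(labels) if l == a]
        ib = [i for i, l in enumerate(labels) if l == b]
        if len(ia) < 2 or len(ib) < 2:
            continue
        dxy = d[np.ix_(ia, ib)].mean() / L
        pi_a = d[np.ix_(ia, ia)].sum() / (len(ia) * (len(ia) - 1)) / L
        pi_b = d[np.ix_(ib, ib)].sum() / (len(ib) * (len(ib) - 1)) / L
        da = dxy - 0.5 * (pi_a + pi_b)
        t_hat = da / (2.0 * mu) if da >= 0 else math.nan
        out.append(DivergenceSummary((a, b), dxy, da, t_hat))
    return out


def multilocus_divergence(alns: list[LocusAlignment], pmap: PopulationMap,
                          mu: float, level: str = "group") -> list[DivergenceSummary]:
    """Divergence summary pooled across loci (site-weighted means)."""
    per_locus = [divergence_summary(a, pmap, mu, level) for a in alns]
    weights = []
    for a in alns:
        weights.append(int(a.usable_mask().sum()))
    pairs = [s.pair for s in per_locus[0]]
    out = []
    for i, pair in enumerate(pairs):
        w = np.array(weights, dtype=float)
        dxy = float(sum(pl[i].dxy * wi for pl, wi in zip(per_locus, w)) / w.sum())
        da = float(sum(pl[i].da * wi for pl, wi in zip(per_locus, w)) / w.sum())
        t_hat = da / (2.0 * mu) if da >= 0 else math.nan
        out.append(DivergenceSummary(pair, dxy, da, t_hat))
    return out
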