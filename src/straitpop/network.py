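"""Statistical-parsimony haplotype networks with simple indel coding.

Sequences are collapsed to haplotypes over (i) the gap-free nucleotide
columns and (ii) binary indel characters produced by simple indel coding:
every distinct contiguous gap run (start, end) in the alignment is one
presence/absence character, and a sequence whose own gap strictly contains
a shorter character's span scores *missing* for that character.  Each indel
character counts one mutational step, the same weight as a substitution;
missing states are skipped pairwise.

Networks are minimum-spanning networks: haplotype pairs are processed in
increasing step distance, an edge is added when it joins two components and
also when it ties the distance at which its endpoints' components were
first joined (so loops/ambiguities are retained).  Pairs farther apart than
the connection limit stay unconnected, yielding disconnected subnetworks.
Multi-step edges are rendered as chains of hypothetical (median) nodes so
every drawn edge is one step — the hollow squares of a classical
statistical-parsimony figure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from .alignment import LocusAlignment, PopulationMap

__all__ = [
    "IndelCoding",
    "HaplotypeNodes",
    "HaplotypeNetwork",
    "encode_indels",
    "collapse_haplotypes",
    "haplotype_distances",
    "connection_limit",
    "parsimony_probability",
    "build_network",
    "group_step_distance",
]

MISSING = -1


@dataclass(frozen=True)
class IndelCoding:
    """Gap-free nucleotide matrix plus binary indel characters.

    ``characters`` are (start, end) column spans (0-based, half-open, in
    original alignment coordinates); ``states`` is an (n, n_chars) int
    matrix over {0 absent, 1 present, -1 missing}.
    """

    nucleotides: LocusAlignment
    characters: tuple[tuple[int, int], ...]
    states: np.ndarray


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, ch in enumerate(seq):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def encode_indels(aln: LocusAlignment) -> IndelCoding:
    """Simple indel coding; gap columns are dropped from the nucleotide matrix."""
    per_seq_runs = [_gap_runs(s) for s in aln.sequences]
    characters = sorted({r for runs in per_seq_runs for r in runs})
    states = np.zeros((aln.n, len(characters)), dtype=np.int8)
    for i, runs in enumerate(per_seq_runs):
        runset = set(runs)
        for j, (cs, ce) in enumerate(characters):
            if (cs, ce) in runset:
                states[i, j] = 1
            elif any(s <= cs and ce <= e and (s, e) != (cs, ce) for s, e in runs):
                states[i, j] = MISSING  # own gap strictly contains the span
            else:
                states[i, j] = 0
    gap_cols = {c for cs, ce in characters for c in range(cs, ce)}
    keep = [c for c in range(aln.length) if c not in gap_cols]
    seqs = ["".join(s[c] for c in keep) for s in aln.sequences]
    nuc = LocusAlignment(aln.locus_name, aln.sample_ids, tuple(seqs))
    return IndelCoding(nuc, tuple(characters), states)


@dataclass(frozen=True)
class HaplotypeNodes:
    """Collapsed haplotypes: signatures, frequencies, per-population counts."""

    ids: tuple[str, ...]                       # H1, H2, ... by first occurrence
    signatures: tuple[tuple[str, tuple[int, ...]], ...]
    frequencies: tuple[int, ...]
    members: tuple[tuple[str, ...], ...]       # sample ids per haplotype

    def population_counts(self, pmap: PopulationMap) -> list[dict[str, int]]:
        pop_of = pmap.population_of()
        out = []
        for mem in self.members:
            counts: dict[str, int] = {}
            for sid in mem:
                p = pop_of.get(sid)
                counts[p] = counts.get(p, 0) + 1
            out.append(counts)
        return out


def collapse_haplotypes(coding: IndelCoding) -> HaplotypeNodes:
    """Group sequences identical over nucleotides and indel characters."""
    aln = coding.nucleotides
    seen: dict[tuple, int] = {}
    members: list[list[str]] = []
    signatures = []
    for i, sid in enumerate(aln.sample_ids):
        key = (aln.sequences[i], tuple(int(x) for x in coding.states[i]))
        if key not in seen:
            seen[key] = len(members)
            members.append([])
            signatures.append(key)
        members[seen[key]].append(sid)
    ids = tuple(f"H{k + 1}" for k in range(len(members)))
    return HaplotypeNodes(
        ids=ids,
        signatures=tuple(signatures),
        frequencies=tuple(len(m) for m in members),
        members=tuple(tuple(m) for m in members),
    )


def haplotype_distances(nodes: HaplotypeNodes) -> np.ndarray:
    """Step distances between haplotypes: nucleotide differences over
    columns where neither is N, plus one step per differing indel
    character (missing indel states skipped pairwise)."""
    k = len(nodes.ids)
    d = np.zeros((k, k), dtype=np.int64)
    seqs = [np.frombuffer(s.encode(), dtype="S1") for s, _ in nodes.signatures]
    indels = [np.array(v, dtype=np.int64) for _, v in nodes.signatures]
    for i, j in itertools.combinations(range(k), 2):
        a, b = seqs[i], seqs[j]
        ok = (a != b"N") & (b != b"N")
        steps = int(((a != b) & ok).sum())
        ia, ib = indels[i], indels[j]
        both = (ia != MISSING) & (ib != MISSING)
        steps += int((ia[both] != ib[both]).sum())
        d[i, j] = d[j, i] = steps
    return d


# -- connection limit --------------------------------------------------------

def parsimony_probability(j: int, n_sites: int, extra: int = 40) -> float:
    """Probability that j observed differences over ``n_sites`` columns
    involve no superimposed change.

    Occupancy model: substitutions fall as Poisson(lambda) uniformly over
    sites, with lambda anchored at the Jukes-Cantor-corrected expected
    substitution count for an observed difference fraction j/n_sites.
    Parsimony holds when the substitution count equals the number of
    changed sites; the estimator is P(M = j | j distinct sites changed),
    summing the occupancy likelihood over M = j .. j + ``extra``.
    """
    if j <= 0:
        return 1.0
    L = n_sites
    p = j / L
    if p >= 0.75:
        return 0.0
    lam = -0.75 * L * math.log1p(-4.0 * p / 3.0)
    ms = np.arange(j, j + extra + 1)
    log_pois = poisson.logpmf(ms, lam)
    # P(exactly j occupied sites | m shots over L sites)
    log_occ = np.array([_log_occupancy(int(m), j, L) for m in ms])
    log_terms = log_pois + log_occ
    return float(np.exp(log_terms[0] - logsumexp(log_terms)))


def _log_occupancy(m: int, j: int, L: int) -> float:
    """log P(m uniform shots over L sites occupy exactly j sites)."""
    if m < j:
        return -np.inf
    # C(L, j) * j! * S2(m, j) / L^m ; S2 via inclusion-exclusion in log space
    i = np.arange(j + 1)
    signs = (-1.0) ** (j - i)
    with np.errstate(divide="ignore"):
        mags = gammaln(j + 1) - gammaln(i + 1) - gammaln(j - i + 1) \
            + m * np.where(i > 0, np.log(np.maximum(i, 1)), -np.inf)
    # signed logsumexp
    order = np.argsort(mags)[::-1]
    tot = 0.0
    for o in order:
        tot += signs[o] * math.exp(mags[o] - mags[order[0]])
    log_surj = mags[order[0]] + math.log(max(tot, 1e-300))
    return (gammaln(L + 1) - gammaln(j + 1) - gammaln(L - j + 1)
            + log_surj - m * math.log(L))


def connection_limit(n_sites: int, confidence: float = 0.95,
                     fixed: int | None = None) -> int:
    """Largest step count j whose probability of parsimony is >= confidence.

    Single steps are always connectable (the limit is at least 1); passing
    ``fixed`` overrides the estimator entirely.
    """
    if fixed is not None:
        return int(fixed)
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    limit = 1
    for j in range(2, n_sites + 1):
        if parsimony_probability(j, n_sites) >= confidence:
            limit = j
        else:
            break
    return limit


# -- network construction ----------------------------------------------------

@dataclass
class HaplotypeNetwork:
    """Minimum-spanning haplotype network with median (hypothetical) nodes."""

    graph: nx.Graph                   # 1-step edges only, medians included
    nodes: HaplotypeNodes
    connection_limit: int
    raw_edges: tuple[tuple[int, int, int], ...]   # (i, j, steps) pre-median

    @property
    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def observed_components(self) -> list[set]:
        out = []
        for c in self.components:
            obs = {v for v in c if not self.graph.nodes[v].get("is_median")}
            if obs:
                out.append(obs)
        return out


def build_network(nodes: HaplotypeNodes, distances: np.ndarray,
                  limit: int) -> HaplotypeNetwork:
    """Minimum-spanning network under a step limit (see module docstring)."""
    k = len(nodes.ids)
    g = nx.Graph()
    for i, hid in enumerate(nodes.ids):
        g.add_node(hid, frequency=nodes.frequencies[i], is_median=False)

    pairs = [(int(distances[i, j]), i, j)
             for i, j in itertools.combinations(range(k), 2)
             if 0 < distances[i, j] <= limit]
    pairs.sort()
    comp = {i: i for i in range(k)}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    raw_edges = []
    for d, group in itertools.groupby(pairs, key=lambda t: t[0]):
        batch = list(group)
        snapshot = {i: find(i) for i in range(k)}  # components before this class
        added = []
        for _, i, j in batch:
            if snapshot[i] != snapshot[j]:
                raw_edges.append((i, j, d))
                added.append((i, j))
        for i, j in added:
            ri, rj = find(i), find(j)
            if ri != rj:
                comp[ri] = rj

    median_count = 0
    for i, j, d in raw_edges:
        if d == 1:
            g.add_edge(nodes.ids[i], nodes.ids[j], steps=1)
        else:
            chain = [nodes.ids[i]]
            for _ in range(d - 1):
                median_count += 1
                mid = f"M{median_count}"
                g.add_node(mid, frequency=0, is_median=True)
                chain.append(mid)
            chain.append(nodes.ids[j])
            for a, b in zip(chain, chain[1:]):
                g.add_edge(a, b, steps=1)

    return HaplotypeNetwork(g, nodes, limit, tuple(raw_edges))


def group_step_distance(distances: np.ndarray, nodes: HaplotypeNodes,
                        pmap: PopulationMap):
    """Per group pair, (min, max) step distance over cross-group haplotype
    pairs.  A haplotype shared by both groups gives a minimum of 0."""
    grp_of = pmap.group_of()
    groups_of_hap = []
    for mem in nodes.members:
        groups_of_hap.append({grp_of[sid] for sid in mem})
    groups = sorted({g for gs in groups_of_hap for g in gs})
    out = {}
    for ga, gb in itertools.combinations(groups, 2):
        ha = [i for i, gs in enumerate(groups_of_hap) if ga in gs]
        hb = [i for i, gs in enumerate(groups_of_hap) if gb in gs]
        if not ha or not hb:
            continue
        vals = [int(distances[i, j]) for i in ha for j in hb]
        out[(ga, gb)] = (min(vals), max(vals))
    return out
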