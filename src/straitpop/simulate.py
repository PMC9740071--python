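"""Structured-coalescent simulator for a three-deme isolation-with-migration
history, with infinite-sites (or finite-sites Jukes-Cantor) mutations and
optional indels.

The demographic model mirrors the inferred history of *Conandron
ramondioides*: three extant demes — Honshu+Shikoku ("HS"), Southeast China
("C") and Taiwan+Iriomote ("TI") — where C and TI merge (backwards in time)
into ancestor A1 at ``t0`` years, and A1 and HS merge into the root ancestor
A2 at ``t1`` years.  Defaults are the study's point estimates
(:meth:`IMModel.conandron`): Ne_HS = 547,070, Ne_TI = 810,240,
Ne_C = 122,784 diploid individuals, t0 = 0.75 Myr, t1 = 1.14 Myr,
mu = 3.7e-9 substitutions/site/year, no migration.

Within a deme of effective size ``Ne`` (scaled by the locus inheritance
factor: 1.0 for biparental nuclear loci, 0.25 for chloroplast DNA in a
diploid outcrosser), each lineage pair coalesces at rate ``1/(2*Ne*scale)``
per generation.  Migration entries are the forward-in-time ``2Nm`` of the
receiving deme and are converted to backward per-lineage hop rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import LocusAlignment, PopulationMap

__all__ = [
    "IMModel",
    "LocusSpec",
    "Genealogy",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_dataset",
    "neutral_pi_s",
    "neutral_tree_stats",
]

DEMES = ("HS", "C", "TI")


@dataclass(frozen=True)
class IMModel:
    """Three-deme isolation-with-migration parameterisation.

    Sizes are diploid individuals; times are years before present
    (``t1 > t0 > 0``).  ``migration[(a, b)]`` is the forward-in-time 2Nm
    into receiving deme ``b`` from ``a``; the default (empty) means no
    gene flow, matching the study's inference that all migration
    posteriors peaked at zero.  Ancestral sizes default to the mean of
    their daughter demes (their posteriors carry no usable point value).
    """

    ne_hs: float = 547_070.0
    ne_c: float = 122_784.0
    ne_ti: float = 810_240.0
    t0: float = 0.75e6
    t1: float = 1.14e6
    ne_a1: float | None = None
    ne_a2: float | None = None
    migration: dict = field(default_factory=dict)
    mu: float = 3.7e-9
    generation_time: float = 1.0

    def __post_init__(self):
        if not (self.t1 > self.t0 > 0):
            raise ValueError("need t1 > t0 > 0")
        for ne in (self.ne_hs, self.ne_c, self.ne_ti):
            if ne <= 0:
                raise ValueError("all Ne must be > 0")
        if any(v < 0 for v in self.migration.values()):
            raise ValueError("migration entries must be >= 0")

    @classmethod
    def conandron(cls, **overrides) -> "IMModel":
        """The study's point-estimate history (see module docstring)."""
        return cls(**overrides)

    @property
    def size_of(self) -> dict[str, float]:
        a1 = self.ne_a1 if self.ne_a1 is not None else 0.5 * (self.ne_c + self.ne_ti)
        a2 = self.ne_a2 if self.ne_a2 is not None else 0.5 * (self.ne_hs + a1)
        return {"HS": self.ne_hs, "C": self.ne_c, "TI": self.ne_ti,
                "A1": a1, "A2": a2}


@dataclass(frozen=True)
class LocusSpec:
    """One simulated locus: name, length (bp), inheritance scaling on Ne
    (1.0 nuclear, 0.25 cpDNA), optional indel rate (events/site/year), and
    the mutation model (``"infinite_sites"`` or ``"jukes_cantor"``)."""

    name: str
    length: int
    inheritance_scale: float = 1.0
    indel_rate: float = 0.0
    mutation_model: str = "infinite_sites"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if not (0 < self.inheritance_scale <= 1):
            raise ValueError("inheritance_scale must be in (0, 1]")
        if self.mutation_model not in ("infinite_sites", "jukes_cantor"):
            raise ValueError(f"unknown mutation model {self.mutation_model!r}")


@dataclass
class Genealogy:
    """Rooted coalescent tree: nodes ``0..n-1`` are leaves; ``parent[i]``
    is -1 for the root; ``time`` is in generations before present."""

    n_leaves: int
    parent: np.ndarray
    time: np.ndarray
    leaf_demes: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def branch_lengths(self) -> np.ndarray:
        """Length (generations) of the branch above each non-root node."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.time.max())

    def leaves_below(self) -> list[np.ndarray]:
        """For each node, the sorted array of leaf indices beneath it."""
        below = [None] * self.n_nodes
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(i)
        for node in range(self.n_nodes):  # children always have lower index
            if node < self.n_leaves:
                below[node] = np.array([node])
            else:
                below[node] = np.sort(np.concatenate([below[c] for c in children[node]]))
        return below


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genealogy(model: IMModel, spec: LocusSpec,
                       samples_per_deme: dict[str, int] | tuple[int, int, int],
                       seed=None) -> Genealogy:
    """Draw one structured-coalescent genealogy under the IM history.

    ``samples_per_deme`` maps deme labels to sample counts (or is an
    ``(HS, C, TI)`` triple).  Event-driven simulation: exponential waiting
    times for per-deme coalescence and backward migration, with deme merges
    at ``t0`` and ``t1`` (converted to generations).
    """
    rng = _as_rng(seed)
    if not isinstance(samples_per_deme, dict):
        samples_per_deme = dict(zip(DEMES, samples_per_deme))
    counts = {d: int(samples_per_deme.get(d, 0)) for d in DEMES}
    if any(v < 0 for v in counts.values()):
        raise ValueError("sample counts must be >= 0")
    n = sum(counts.values())
    if n < 1:
        raise ValueError("total sample count must be >= 1")

    sizes = model.size_of
    scale = spec.inheritance_scale
    gt = model.generation_time
    t0g, t1g = model.t0 / gt, model.t1 / gt

    leaf_demes, lineages = [], {d: [] for d in ("HS", "C", "TI", "A1", "A2")}
    node = 0
    for d in DEMES:
        for _ in range(counts[d]):
            leaf_demes.append(d)
            lineages[d].append(node)
            node += 1

    parent = list(np.full(n, -1))
    times = list(np.zeros(n))
    t = 0.0
    # (merge time, absorbing deme, merged demes)
    merges = [(t0g, "A1", ("C", "TI")), (t1g, "A2", ("HS", "A1")), (np.inf, None, ())]
    merge_i = 0

    def backward_mig_rates():
        """(src_deme, dst_deme, per-lineage rate) for currently coexisting demes."""
        out = []
        for (a, b), m2nm in model.migration.items():
            # forward a->b with 2Nm of receiver b: backwards, a lineage now in
            # b hops to a at rate 2Nm / (2 Ne_b scale) per generation
            if lineages.get(b) and a in sizes and b in sizes:
                out.append((b, a, m2nm / (2.0 * sizes[b] * scale)))
        return out

    active = lambda: sum(len(v) for v in lineages.values())
    while active() > 1:
        events = []
        for d, lins in lineages.items():
            k = len(lins)
            if k >= 2:
                events.append(("coal", d, k * (k - 1) / 2.0 / (2.0 * sizes[d] * scale)))
        for src, dst, rate in backward_mig_rates():
            k = len(lineages[src])
            if k:
                events.append(("mig", (src, dst), k * rate))
        total = sum(r for *_, r in events)
        next_merge, absorb, merged = merges[merge_i]
        if total > 0:
            wait = rng.exponential(1.0 / total)
        else:
            wait = np.inf
        if t + wait >= next_merge:
            t = next_merge
            for d in merged:
                lineages[absorb].extend(lineages[d])
                lineages[d] = []
            merge_i += 1
            continue
        t += wait
        u = rng.uniform(0, total)
        acc = 0.0
        for kind, what, rate in events:
            acc += rate
            if u <= acc:
                break
        if kind == "coal":
            lins = lineages[what]
            i, j = rng.choice(len(lins), size=2, replace=False)
            a, b = lins[i], lins[j]
            parent.append(-1)
            times.append(t)
            new = len(parent) - 1
            parent[a] = parent[b] = new
            lineages[what] = [x for x in lins if x not in (a, b)] + [new]
        else:
            src, dst = what
            lins = lineages[src]
            i = rng.integers(len(lins))
            mover = lins.pop(i)
            lineages[dst].append(mover)

    return Genealogy(n, np.asarray(parent), np.asarray(times), tuple(leaf_demes))


class SaturationError(RuntimeError):
    """More mutations than columns under the infinite-sites model."""


def drop_mutations(gen: Genealogy, spec: LocusSpec, mu: float,
                   seed=None, generation_time: float = 1.0) -> LocusAlignment:
    """Scatter mutations on a genealogy and emit the haplotype alignment.

    ``mu`` is per site per year; branch lengths are generations, so the
    per-branch mutation count is Poisson(length_gen * mu * generation_time
    * L).  Under infinite sites every mutation takes a fresh column; the
    Jukes-Cantor option allows recurrent hits at a column.  Optional indels
    (deletions with geometric run length, mean 3) are applied after
    substitutions.
    """
    rng = _as_rng(seed)
    L = spec.length
    mu_gen = mu * generation_time
    bl = gen.branch_lengths()
    below = gen.leaves_below()
    n = gen.n_leaves

    anc = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L)
    mat = np.tile(anc, (n, 1))

    n_mut = rng.poisson(bl * mu_gen * L)
    if spec.mutation_model == "infinite_sites":
        total = int(n_mut.sum())
        if total > L:
            raise SaturationError(
                f"{spec.name}: {total} mutations for {L} sites under infinite "
                "sites; increase the locus length or reduce theta"
            )
        cols = rng.choice(L, size=total, replace=False)
        ci = 0
        bases = np.frombuffer(b"ACGT", dtype="S1")
        for node in range(gen.n_nodes):
            for _ in range(n_mut[node]):
                col = cols[ci]; ci += 1
                cur = anc[col]
                derived = rng.choice(bases[bases != cur])
                mat[below[node], col] = derived
    else:  # finite-sites Jukes-Cantor: propagate sequences root -> leaves
        order = np.argsort(-gen.time, kind="stable")  # root first
        seqs = {int(order[0]): anc.copy()}
        bases = np.frombuffer(b"ACGT", dtype="S1")
        for node in order[1:]:
            node = int(node)
            s = seqs[int(gen.parent[node])].copy()
            for _ in range(n_mut[node]):
                col = rng.integers(L)
                s[col] = rng.choice(bases[bases != s[col]])
            seqs[node] = s
        for leaf in range(n):
            mat[leaf] = seqs[leaf]

    if spec.indel_rate > 0:
        n_indel = rng.poisson(bl * spec.indel_rate * generation_time * L)
        for node in range(gen.n_nodes):
            for _ in range(n_indel[node]):
                start = rng.integers(L)
                run = rng.geometric(1.0 / 3.0)
                mat[below[node], start:min(L, start + run)] = b"-"

    ids = [f"{d}_{i:03d}" for i, d in enumerate(gen.leaf_demes)]
    seq_strs = ["".join(row.astype(str)) for row in mat.astype("U1")]
    return LocusAlignment(spec.name, tuple(ids), tuple(seq_strs))


def simulate_dataset(model: IMModel, loci: list[LocusSpec],
                     samples_per_deme, seed=None,
                     populations_per_deme: int = 1
                     ) -> tuple[list[LocusAlignment], PopulationMap]:
    """Independent genealogies per locus plus a matching population map.

    Samples of each deme are split round-robin into
    ``populations_per_deme`` populations named ``<deme>1..<deme>k`` (all
    belonging to the deme-named group), so hierarchical AMOVA has a
    within-group population level to work with.  Populations receive
    plausible distinct coordinates inside their deme's region.
    """
    rng = _as_rng(seed)
    alns = [
        drop_mutations(
            simulate_genealogy(model, spec, samples_per_deme, rng),
            spec, model.mu, rng, model.generation_time,
        )
        for spec in loci
    ]
    if not isinstance(samples_per_deme, dict):
        samples_per_deme = dict(zip(DEMES, samples_per_deme))
    region_anchor = {"HS": (34.0, 134.0), "C": (26.5, 118.0), "TI": (23.8, 121.0)}
    records = []
    ids = alns[0].sample_ids if alns else []
    counters = {d: 0 for d in DEMES}
    for sid in ids:
        deme = sid.split("_")[0]
        k = counters[deme]; counters[deme] += 1
        pop_idx = k % max(1, populations_per_deme)
        lat0, lon0 = region_anchor[deme]
        records.append((
            sid, f"{deme}{pop_idx + 1}", deme,
            round(lat0 + 0.3 * pop_idx, 4), round(lon0 + 0.2 * pop_idx, 4),
        ))
    return alns, PopulationMap.from_records(records)


# ---------------------------------------------------------------------------
# Panmictic neutral null machinery (constant size, coalescent units).
# Used for neutrality-test p-values; theta is per sequence (4*N*mu*L).

def neutral_pi_s(n: int, theta: float, reps: int, seed=None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Batched neutral coalescent draws of (mean pairwise differences, S).

    Vectorised across replicates: at each coalescent interval the per-lineage
    mutation count is Poisson(interval * theta / 2) and contributes
    ``c * (n - c)`` pairwise differences, where ``c`` is the lineage's leaf
    count.  Returns per-replicate k-bar (per sequence, not per site) and S.
    """
    rng = _as_rng(seed)
    counts = np.zeros((reps, n), dtype=np.int64)
    counts[:, :] = 1
    diffs = np.zeros(reps)
    S = np.zeros(reps, dtype=np.int64)
    for k in range(n, 1, -1):
        t = rng.exponential(2.0 / (k * (k - 1)), size=reps)
        m = rng.poisson(t[:, None] * (theta / 2.0), size=(reps, k))
        c = counts[:, :k]
        diffs += (m * c * (n - c)).sum(axis=1)
        S += m.sum(axis=1)
        # merge a uniform random pair (i, j): j's count folds into i
        i = rng.integers(k, size=reps)
        j = rng.integers(k - 1, size=reps)
        j = j + (j >= i)
        rows = np.arange(reps)
        counts[rows, i] += counts[rows, j]
        counts[rows, j] = counts[rows, k - 1]
    kbar = diffs / (n * (n - 1) / 2.0)
    return kbar, S


def neutral_tree_stats(n: int, theta: float, seed=None) -> tuple[float, int, int]:
    """One neutral replicate of (k-bar, S, haplotype count).

    Builds an explicit coalescent merge sequence; the haplotype count under
    infinite sites is the number of leaf classes left after contracting
    every branch that carries no mutation.
    """
    rng = _as_rng(seed)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    leafcount = np.ones(n_nodes, dtype=np.int64)
    muts = np.zeros(n_nodes, dtype=np.int64)
    active = list(range(n))
    t_created = np.zeros(n_nodes)
    t = 0.0
    nxt = n
    for k in range(n, 1, -1):
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        leafcount[nxt] = leafcount[a] + leafcount[b]
        t_created[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    # branch lengths in coalescent units; mutations Poisson(len * theta/2)
    has_parent = parent >= 0
    bl = np.zeros(n_nodes)
    bl[has_parent] = t_created[parent[has_parent]] - t_created[has_parent]
    muts = rng.poisson(bl * theta / 2.0)
    c = leafcount[has_parent]
    kbar = float((muts[has_parent] * c * (n - c)).sum() / (n * (n - 1) / 2.0))
    S = int(muts[has_parent].sum())
    # haplotype classes: union leaf-to-parent through unmutated branches
    root = np.arange(n_nodes)

    def find(x):
        while root[x] != x:
            root[x] = root[root[x]]
            x = root[x]
        return x

    for x in range(n_nodes):
        p = parent[x]
        if p >= 0 and muts[x] == 0:
            root[find(x)] = find(p)
    k_hap = len({find(leaf) for leaf in range(n)})
    return kbar, S, k_hap
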