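"""Within-unit diversity and neutrality statistics.

Statistics follow the classical definitions: S (segregating sites), Hd
(sample-size-corrected haplotype diversity), pi (mean pairwise differences
per site), Watterson's theta per sequence (S / a1), Tajima's D, and Fu's Fs
from the Ewens sampling distribution.  All statistics use *complete
deletion*: any column containing a gap or N in any retained sequence is
excluded, so pi, S and D stay internally consistent (indels score zero here
and are handled by the haplotype-network stage instead).

Significance of D and Fs is assessed against neutral constant-size
coalescent simulations with theta matched to the observed mean pairwise
difference, the convention of the classical implementations.
Undefined statistics are reported as NaN, never 0, to avoid spurious
"stable population" calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import LocusAlignment
from . import simulate as sim

__all__ = [
    "DiversityStats",
    "NeutralityPValues",
    "diversity",
    "tajimas_d",
    "tajimas_d_from_counts",
    "fus_fs",
    "fs_from_counts",
    "neutrality_pvalues",
    "summarize",
]


@dataclass(frozen=True)
class DiversityStats:
    unit: str
    n: int
    usable_sites: int
    S: int
    Hd: float
    pi: float                 # per site
    theta_w: float            # per sequence
    pi_fraction: float        # parsimony-informative site fraction
    n_haplotypes: int
    k_bar: float              # mean pairwise differences per sequence
    tajima_d: float = math.nan
    fu_fs: float = math.nan
    p_tajima: float = math.nan
    p_fs: float = math.nan


@dataclass(frozen=True)
class NeutralityPValues:
    p_tajima: float
    p_fs_lower: float
    p_fs_upper: float
    reps: int


def _usable_matrix(aln: LocusAlignment) -> np.ndarray:
    mask = aln.usable_mask()
    if not mask.any():
        raise ValueError(f"{aln.locus_name}: no comparable sites after deletion")
    return aln.matrix()[:, mask]


def _pairwise_total(mat: np.ndarray) -> float:
    """Sum of Hamming differences over all sequence pairs."""
    n = mat.shape[0]
    total = 0
    for i in range(n - 1):
        total += int((mat[i + 1:] != mat[i]).sum())
    return float(total)


def _haplotype_counts(mat: np.ndarray) -> np.ndarray:
    mat = np.ascontiguousarray(mat)
    _, counts = np.unique(mat.view(f"S{mat.shape[1]}").ravel(), return_counts=True)
    return counts


def a1_of(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def diversity(aln: LocusAlignment, unit: str | None = None) -> DiversityStats:
    """S, Hd, pi, Watterson's theta and the parsimony-informative fraction."""
    mat = _usable_matrix(aln)
    n, L = mat.shape
    n_states = np.array([len(np.unique(mat[:, j])) for j in range(L)])
    S = int((n_states > 1).sum())

    informative = 0
    for j in np.nonzero(n_states > 1)[0]:
        _, counts = np.unique(mat[:, j], return_counts=True)
        if (counts >= 2).sum() >= 2:
            informative += 1

    hap_counts = _haplotype_counts(mat)
    k_hap = len(hap_counts)
    if n >= 2:
        freqs = hap_counts / n
        Hd = n / (n - 1) * (1.0 - float((freqs ** 2).sum()))
        kbar = _pairwise_total(mat) / (n * (n - 1) / 2.0)
        theta_w = S / a1_of(n)
    else:
        Hd, kbar, theta_w = math.nan, math.nan, math.nan

    return DiversityStats(
        unit=unit or aln.locus_name,
        n=n, usable_sites=L, S=S, Hd=Hd,
        pi=(kbar / L if n >= 2 else math.nan),
        theta_w=theta_w,
        pi_fraction=informative / L,
        n_haplotypes=k_hap,
        k_bar=kbar,
    )


# -- Tajima's D --------------------------------------------------------------

def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) from the 1989 normalisation, computed from n."""
    a1 = a1_of(n)
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return e1, e2


def tajimas_d_from_counts(n: int, S: int, k_bar: float) -> float:
    """D from sample size, segregating sites and mean pairwise differences."""
    if S == 0 or n < 2:
        return math.nan
    e1, e2 = _tajima_constants(n)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0:
        return math.nan
    return (k_bar - S / a1_of(n)) / denom


def tajimas_d(aln: LocusAlignment) -> float:
    d = diversity(aln)
    return tajimas_d_from_counts(d.n, d.S, d.k_bar)


# -- Fu's Fs -----------------------------------------------------------------

def _log_stirling1_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(n):  # build row m+1 from row m
        new = np.full(n + 1, -np.inf)
        if m > 0:
            with np.errstate(divide="ignore"):
                new = np.logaddexp(math.log(m) + row, np.concatenate(([-np.inf], row[:-1])))
        else:
            new[1] = 0.0  # |s(1,1)| = 1
        row = new
    return row


def _ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 0..n under the Ewens sampling distribution."""
    ls = _log_stirling1_row(n)
    k = np.arange(n + 1)
    log_rising = sum(math.log(theta + i) for i in range(n))
    with np.errstate(divide="ignore"):
        return ls + k * math.log(theta) - log_rising


def fs_from_counts(n: int, k_obs: int, k_bar: float) -> float:
    """Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta = k_bar)."""
    if n < 2 or not (k_bar > 0):
        return math.nan
    logp = _ewens_log_pmf(n, k_bar)
    # ln(S'/(1-S')) with both tails formed in log space (stable near 0 and 1)
    log_upper = logsumexp(logp[k_obs:])
    log_lower = logsumexp(logp[:k_obs]) if k_obs > 1 else -math.inf
    if log_lower == -math.inf:
        return math.inf
    if log_upper == -math.inf:
        return -math.inf
    return float(log_upper - log_lower)


def fus_fs(aln: LocusAlignment) -> float:
    d = diversity(aln)
    return fs_from_counts(d.n, d.n_haplotypes, d.k_bar)


# -- simulation p-values -----------------------------------------------------

def neutrality_pvalues(aln: LocusAlignment, reps: int = 1000, seed=None,
                       statistics=("tajima", "fs")) -> NeutralityPValues:
    """Coalescent-simulation p-values for Tajima's D and Fu's Fs.

    Neutral constant-size replicates are drawn with n matched and theta set
    to the observed mean pairwise difference.  D is tested two-tailed
    (|D_sim| >= |D_obs|); Fs is reported lower-tailed (expansion-sensitive,
    the headline value) and upper-tailed.  p-values carry the +1/(reps+1)
    correction so they are never exactly 0.
    """
    rng = sim._as_rng(seed)
    d = diversity(aln)
    p_t = p_lo = p_hi = math.nan
    if "tajima" in statistics:
        d_obs = tajimas_d_from_counts(d.n, d.S, d.k_bar)
        if not math.isnan(d_obs) and d.k_bar > 0:
            kbar_s, S_s = sim.neutral_pi_s(d.n, d.k_bar, reps, rng)
            e1, e2 = _tajima_constants(d.n)
            with np.errstate(divide="ignore", invalid="ignore"):
                d_sim = (kbar_s - S_s / a1_of(d.n)) / np.sqrt(
                    e1 * S_s + e2 * S_s * (S_s - 1.0))
            d_sim = d_sim[S_s > 0]
            p_t = (int((np.abs(d_sim) >= abs(d_obs)).sum()) + 1) / (len(d_sim) + 1)
    if "fs" in statistics:
        fs_obs = fs_from_counts(d.n, d.n_haplotypes, d.k_bar)
        if not math.isnan(fs_obs) and d.k_bar > 0:
            lo = hi = used = 0
            for _ in range(reps):
                kb, _, k_hap = sim.neutral_tree_stats(d.n, d.k_bar, rng)
                fs = fs_from_counts(d.n, k_hap, kb)
                if math.isnan(fs):
                    continue
                used += 1
                lo += fs <= fs_obs
                hi += fs >= fs_obs
            if used:
                p_lo = (lo + 1) / (used + 1)
                p_hi = (hi + 1) / (used + 1)
    return NeutralityPValues(p_t, p_lo, p_hi, reps)


def summarize(aln: LocusAlignment, unit: str | None = None, reps: int = 1000,
              seed=None) -> DiversityStats:
    """Full per-unit summary: diversity plus neutrality statistics and
    their simulation p-values."""
    d = diversity(aln, unit)
    dt = tajimas_d_from_counts(d.n, d.S, d.k_bar)
    fs = fs_from_counts(d.n, d.n_haplotypes, d.k_bar)
    pv = neutrality_pvalues(aln, reps=reps, seed=seed)
    return DiversityStats(
        unit=d.unit, n=d.n, usable_sites=d.usable_sites, S=d.S, Hd=d.Hd,
        pi=d.pi, theta_w=d.theta_w, pi_fraction=d.pi_fraction,
        n_haplotypes=d.n_haplotypes, k_bar=d.k_bar,
        tajima_d=dt, fu_fs=fs, p_tajima=pv.p_tajima, p_fs=pv.p_fs_lower,
    )
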