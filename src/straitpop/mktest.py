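"""McDonald-Kreitman test on a coding alignment plus an aligned outgroup.

Per codon column-triplet, changes segregating within the ingroup are
polymorphisms and codons where a monomorphic ingroup differs from the
outgroup are fixed differences; each nucleotide change is classified
synonymous or non-synonymous under the configured genetic code.  Multi-hit
codons are resolved by pathway averaging (mean over all orderings of the
differing positions, stop-codon routes excluded when any stop-free route
exists) — the Nei-Gojobori convention.  Significance is a Pearson chi-square
on the 2x2 table without continuity correction, the convention that
reproduces classical published MK tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio.Data import CodonTable
from scipy.stats import chi2, fisher_exact

from .alignment import LocusAlignment

__all__ = ["MKTable", "classify_changes", "mk_chi2", "mk_test"]


@dataclass(frozen=True)
class MKTable:
    Ps: float   # synonymous polymorphisms
    Pn: float   # non-synonymous polymorphisms
    Ds: float   # synonymous fixed differences
    Dn: float   # non-synonymous fixed differences
    excluded_codons: int = 0
    warnings: tuple[str, ...] = ()

    @property
    def neutrality_index(self) -> float:
        if self.Ps == 0 or self.Dn == 0:
            return math.nan
        return (self.Pn * self.Ds) / (self.Ps * self.Dn)


def _codon_table(code_id: int = 1):
    return CodonTable.unambiguous_dna_by_id[code_id]


def _translate(codon: str, table) -> str | None:
    if codon in table.stop_codons:
        return "*"
    return table.forward_table.get(codon)


def _pathway_counts(c1: str, c2: str, table) -> tuple[float, float]:
    """(synonymous, non-synonymous) change counts between two codons,
    averaged over all minimal-change orderings; routes through stop codons
    are excluded unless every route hits one."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    routes = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = non = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            aa_from, aa_to = _translate(cur, table), _translate(nxt, table)
            if aa_to == "*" or aa_from == "*":
                hit_stop = True
            if aa_from == aa_to:
                syn += 1
            else:
                non += 1
            cur = nxt
        routes.append((hit_stop, syn, non))
    clean = [r for r in routes if not r[0]] or routes
    s = sum(r[1] for r in clean) / len(clean)
    n = sum(r[2] for r in clean) / len(clean)
    return s, n


def classify_changes(ingroup: LocusAlignment, outgroup: str,
                     frame_offset: int = 0, code_id: int = 1) -> MKTable:
    """Build the MK 2x2 counts from an in-frame coding alignment.

    ``outgroup`` is one sequence aligned to the same columns.  Codons
    containing a gap or N in any counted sequence are excluded; internal
    stop codons in the ingroup consensus are excluded with a warning.
    Polymorphism with more than two ingroup codons is scored as a star from
    the most frequent codon (ties broken lexicographically).
    """
    table = _codon_table(code_id)
    outgroup = outgroup.upper()
    if len(outgroup) != ingroup.length:
        raise ValueError("outgroup length does not match alignment columns")
    usable_len = ingroup.length - frame_offset
    if usable_len % 3 != 0:
        raise ValueError(
            f"alignment length {usable_len} after frame offset is not a "
            "multiple of 3"
        )
    Ps = Pn = Ds = Dn = 0.0
    excluded = 0
    warnings = []
    seqs = [s.upper() for s in ingroup.sequences]
    for start in range(frame_offset, ingroup.length, 3):
        in_codons = [s[start:start + 3] for s in seqs]
        out_codon = outgroup[start:start + 3]
        all_codons = in_codons + [out_codon]
        if any(ch not in "ACGT" for c in all_codons for ch in c):
            excluded += 1
            continue
        distinct = list(dict.fromkeys(in_codons))
        if any(c in table.stop_codons for c in distinct):
            warnings.append(f"internal stop codon at codon {start // 3 + 1}; excluded")
            excluded += 1
            continue
        if len(distinct) > 1:
            counts = {c: in_codons.count(c) for c in distinct}
            ref = sorted(distinct, key=lambda c: (-counts[c], c))[0]
            for other in distinct:
                if other == ref:
                    continue
                s, n = _pathway_counts(ref, other, table)
                Ps += s
                Pn += n
        else:
            if distinct[0] != out_codon:
                s, n = _pathway_counts(distinct[0], out_codon, table)
                Ds += s
                Dn += n
    return MKTable(Ps, Pn, Ds, Dn, excluded, tuple(warnings))


def mk_chi2(tab: MKTable) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and its df=1 p-value.

    Falls back to NaN (with Fisher's exact available via
    :func:`mk_fisher`) when a margin is zero.
    """
    a, b, c, d = tab.Ps, tab.Ds, tab.Pn, tab.Dn
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        return math.nan, math.nan
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return stat, float(chi2.sf(stat, df=1))


def mk_fisher(tab: MKTable) -> float:
    """Fisher's exact p-value on the rounded 2x2 table (zero-margin fallback)."""
    _, p = fisher_exact([[round(tab.Ps), round(tab.Ds)],
                         [round(tab.Pn), round(tab.Dn)]])
    return float(p)


def mk_test(ingroup: LocusAlignment, outgroup: str, frame_offset: int = 0,
            code_id: int = 1):
    """Counts plus chi-square in one call; returns (MKTable, chi2, p)."""
    tab = classify_changes(ingroup, outgroup, frame_offset, code_id)
    stat, p = mk_chi2(tab)
    return tab, stat, p
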