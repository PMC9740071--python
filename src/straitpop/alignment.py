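"""Aligned-locus containers, the sample/population/group map, and shared I/O.

All downstream stages operate on :class:`LocusAlignment` (one aligned locus,
haplotype sequences over ``{A,C,G,T,-,N}``) and :class:`PopulationMap`
(sample -> population -> region group, with coordinates).  Alignment columns
are 0-based internally; anything user-facing is reported 1-based.

``N`` is treated as missing data and is excluded site-wise by downstream
statistics; ``-`` is an alignment gap whose handling is stage-specific
(complete deletion for diversity statistics, simple indel coding for
haplotype networks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT-N")

__all__ = [
    "LocusAlignment",
    "PopulationMap",
    "AnalysisConfig",
    "AlignmentError",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_population_map",
    "subset_alignment",
    "concatenate_loci",
]


class AlignmentError(ValueError):
    """Malformed alignment or population-map input."""


@dataclass(frozen=True)
class LocusAlignment:
    """One locus: equal-length haplotype sequences with stable sample ids."""

    locus_name: str
    sample_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    #: per-locus column boundaries when this alignment is a concatenation
    partitions: tuple[tuple[str, int, int], ...] = field(default=())

    def __post_init__(self):
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences length mismatch")
        if len(self.sequences) == 0:
            raise AlignmentError(f"{self.locus_name}: no records")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            bad = [
                sid for sid, s in zip(self.sample_ids, self.sequences)
                if len(s) != len(self.sequences[0])
            ]
            raise AlignmentError(
                f"{self.locus_name}: ragged alignment, offending record(s): "
                + ", ".join(bad)
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen, dups = set(), []
            for sid in self.sample_ids:
                if sid in seen:
                    dups.append(sid)
                seen.add(sid)
            raise AlignmentError(
                f"{self.locus_name}: duplicate sample id(s): {', '.join(dups)}"
            )
        for sid, s in zip(self.sample_ids, self.sequences):
            bad = set(s) - ALPHABET
            if bad:
                ch = min(bad)
                raise AlignmentError(
                    f"{self.locus_name}: illegal character {ch!r} in record "
                    f"{sid!r} at column {s.index(ch) + 1}"
                )

    @classmethod
    def from_pairs(cls, locus_name, pairs, partitions=()):
        ids, seqs = zip(*[(sid, s.upper()) for sid, s in pairs])
        return cls(locus_name, tuple(ids), tuple(seqs), tuple(partitions))

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def matrix(self) -> np.ndarray:
        """(n, length) array of single-byte characters (dtype ``S1``)."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n, self.length)

    def usable_mask(self) -> np.ndarray:
        """Columns free of ``-`` and ``N`` in every sequence (complete deletion)."""
        m = self.matrix()
        return ~((m == b"-") | (m == b"N")).any(axis=0)

    def take(self, sample_ids) -> "LocusAlignment":
        wanted = list(sample_ids)
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise AlignmentError(
                f"{self.locus_name}: samples not in alignment: {', '.join(missing)}"
            )
        return LocusAlignment(
            self.locus_name,
            tuple(wanted),
            tuple(self.sequences[index[s]] for s in wanted),
            self.partitions,
        )


def read_fasta_alignment(path, locus_name: str) -> LocusAlignment:
    """Read an aligned FASTA file into a :class:`LocusAlignment`.

    Record order is preserved; sequences are uppercased.  Ragged records or
    characters outside ``{A,C,G,T,-,N}`` raise :class:`AlignmentError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no records")
    return LocusAlignment.from_pairs(
        locus_name, [(r.id, str(r.seq)) for r in records]
    )


def write_fasta_alignment(aln: LocusAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.sample_ids, aln.sequences)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


_PMAP_COLUMNS = ["sample_id", "population", "group", "lat", "lon"]


@dataclass(frozen=True)
class PopulationMap:
    """Sample -> population -> region-group table with coordinates.

    Backed by a pandas DataFrame with columns
    ``sample_id, population, group, lat, lon``.
    """

    table: pd.DataFrame
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        t = self.table
        missing = [c for c in _PMAP_COLUMNS if c not in t.columns]
        if missing:
            raise AlignmentError(f"population map missing column(s): {missing}")
        dups = t.sample_id[t.sample_id.duplicated()].tolist()
        if dups:
            raise AlignmentError(f"duplicate sample id(s): {', '.join(map(str, dups))}")
        lat, lon = t.lat.astype(float), t.lon.astype(float)
        bad_lat = t.sample_id[(lat.notna()) & ((lat < -90) | (lat > 90))].tolist()
        bad_lon = t.sample_id[(lon.notna()) & ((lon < -180) | (lon > 180))].tolist()
        if bad_lat or bad_lon:
            raise AlignmentError(
                f"coordinates out of range for: {', '.join(map(str, bad_lat + bad_lon))}"
            )

    @classmethod
    def from_records(cls, records, warnings=()):
        """records: iterable of (sample_id, population, group, lat, lon)."""
        df = pd.DataFrame(list(records), columns=_PMAP_COLUMNS)
        return cls(df.reset_index(drop=True), tuple(warnings))

    @property
    def sample_ids(self) -> list[str]:
        return self.table.sample_id.tolist()

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table.sample_id, self.table.population))

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.table.sample_id, self.table.group))

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table.population))

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table.group))

    def group_of_population(self) -> dict[str, str]:
        out = {}
        for pop, grp in zip(self.table.population, self.table.group):
            if pop in out and out[pop] != grp:
                raise AlignmentError(f"population {pop!r} assigned to two groups")
            out[pop] = grp
        return out

    def samples_in(self, unit: str) -> list[str]:
        t = self.table
        hit = t.sample_id[(t.population == unit) | (t.group == unit)]
        return hit.tolist()

    def coordinates(self) -> pd.DataFrame:
        """Per-population mean coordinates (populations may span sites)."""
        return (
            self.table.groupby("population", sort=False)[["lat", "lon"]]
            .mean()
            .reset_index()
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_population_map(path) -> PopulationMap:
    """Read the tab-separated population map.

    Header must contain ``sample_id  population  group  lat  lon``.  Rows with
    missing coordinates are kept (a warning is recorded); landscape analyses
    will refuse them later.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str, "group": str})
    missing = [c for c in _PMAP_COLUMNS if c not in df.columns]
    if missing:
        raise AlignmentError(f"{path}: population map missing column(s): {missing}")
    warnings = tuple(
        f"sample {sid}: missing coordinate(s)"
        for sid in df.sample_id[df[["lat", "lon"]].isna().any(axis=1)]
    )
    return PopulationMap(df[_PMAP_COLUMNS].reset_index(drop=True), warnings)


def subset_alignment(aln: LocusAlignment, pmap: PopulationMap, unit: str) -> LocusAlignment:
    """Restrict an alignment to samples of one population or region group."""
    members = set(pmap.samples_in(unit))
    if not members:
        raise AlignmentError(f"unknown population/group: {unit!r}")
    keep = [sid for sid in aln.sample_ids if sid in members]
    if not keep:
        raise AlignmentError(
            f"{aln.locus_name}: no samples of unit {unit!r} present"
        )
    return aln.take(keep)


def concatenate_loci(alns: list[LocusAlignment], name: str = "concat") -> tuple[LocusAlignment, list[str]]:
    """Concatenate loci over the intersection of their sample ids.

    Returns the concatenated alignment (with per-locus column partitions
    recorded, 0-based half-open) and a list of warnings naming samples
    dropped because they are absent from at least one locus.
    """
    if not alns:
        raise AlignmentError("no alignments to concatenate")
    if len(alns) == 1:
        return alns[0], []
    shared = [sid for sid in alns[0].sample_ids
              if all(sid in a.sample_ids for a in alns[1:])]
    if not shared:
        raise AlignmentError("concatenation: no shared samples across loci")
    warnings = []
    all_ids = {sid for a in alns for sid in a.sample_ids}
    for sid in sorted(all_ids - set(shared)):
        warnings.append(f"sample {sid} absent from at least one locus; dropped")
    parts, offset = [], 0
    pieces = []
    for a in alns:
        sub = a.take(shared)
        pieces.append(sub)
        parts.append((a.locus_name, offset, offset + a.length))
        offset += a.length
    seqs = ["".join(p.sequences[i] for p in pieces) for i in range(len(shared))]
    return (
        LocusAlignment(name, tuple(shared), tuple(seqs), tuple(parts)),
        warnings,
    )


@dataclass
class AnalysisConfig:
    """Run-wide knobs shared by the pipeline stages.

    permutations
        AMOVA / pairwise-PhiST permutation count (study convention: 10,000).
    coalescent_reps
        replicates behind neutrality-test p-values (study convention: 1,000).
    network_connection_limit_mode
        ``"parsimony95"`` or ``"fixed:<j>"`` for the network step limit.
    cpdna_inheritance_scale
        effective-size multiplier for the uniparental chloroplast locus
        relative to nuclear loci (0.25 for a diploid outcrosser).
    mutation_rate_per_site_per_year
        reference substitution rate (LFY anchor, 3.7e-9 /site/yr).
    """

    permutations: int = 10_000
    coalescent_reps: int = 1_000
    network_connection_limit_mode: str = "parsimony95"
    mk_genetic_code: int = 1
    rng_seed: int = 0
    cpdna_inheritance_scale: float = 0.25
    mutation_rate_per_site_per_year: float = 3.7e-9

    def __post_init__(self):
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.coalescent_reps < 1:
            raise ValueError("coalescent_reps must be >= 1")
        if not (0 < self.cpdna_inheritance_scale <= 1):
            raise ValueError("cpdna_inheritance_scale must be in (0, 1]")
        mode = self.network_connection_limit_mode
        if mode != "parsimony95" and not mode.startswith("fixed:"):
            raise ValueError(f"bad network_connection_limit_mode: {mode!r}")

    @property
    def fixed_connection_limit(self) -> int | None:
        mode = self.network_connection_limit_mode
        if mode.startswith("fixed:"):
            return int(mode.split(":", 1)[1])
        return None

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Plain ``key=value`` file, one pair per line, ``#`` comments."""
        kwargs = {}
        casts = {f: t for f, t in cls.__annotations__.items()}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in casts:
                    raise ValueError(f"unknown config key: {key!r}")
                typ = {"int": int, "float": float, "str": str}[casts[key]]
                kwargs[key] = typ(value.strip())
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in self.__dataclass_fields__:
                fh.write(f"{f}={getattr(self, f)}\n")
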