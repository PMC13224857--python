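"""Sequences, SNV tables, restriction digests and fragment maps.

A 4C experiment is anchored on an in-silico double digest: the primary
enzyme defines ligatable fragments, the secondary enzyme trims circles.
Fragments lacking an internal secondary site are "blind" and flagged
``valid=False``; they are retained in the map and excluded downstream.

Coordinates are 0-based half-open throughout.  A cut places the primary
motif at the START of the downstream fragment, so trimmed reads (which
begin at the motif) align at fragment starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")
#: DpnII recognition sequence (primary enzyme default).
PRIMARY_MOTIF_DEFAULT = "GATC"
#: Csp6I recognition sequence (secondary enzyme default).
SECONDARY_MOTIF_DEFAULT = "GTAC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str, allow_n: bool = True) -> None:
    allowed = DNA_ALPHABET if allow_n else frozenset("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)!r}")


@dataclass(frozen=True)
class Haplotype:
    """One parental chromosome of the locus (e.g. '129' or 'CAST')."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        _check_dna(self.seq, f"haplotype {self.name!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SnvRecord:
    pos: int
    base129: str
    baseCAST: str

    def __post_init__(self) -> None:
        if self.base129 == self.baseCAST:
            raise ValueError(f"SNV at {self.pos} has identical bases on both alleles")


class SnvTable:
    """Discriminating single-nucleotide variants on the shared locus coordinates."""

    def __init__(self, records: Sequence[SnvRecord]):
        positions = [r.pos for r in records]
        if any(b >= a for a, b in zip(positions[1:], positions[:-1])):
            raise ValueError("SNV positions must be strictly increasing")
        self.records = list(records)
        self.positions = np.asarray(positions, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnvRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SnvRecord:
        return self.records[i]

    def in_interval(self, start: int, end: int) -> list[SnvRecord]:
        """SNVs with start <= pos < end."""
        lo = int(np.searchsorted(self.positions, start, side="left"))
        hi = int(np.searchsorted(self.positions, end, side="left"))
        return self.records[lo:hi]


@dataclass(frozen=True)
class EnzymePair:
    """Primary (fragment-defining) and secondary (circle-trimming) motifs."""

    primary_motif: str = PRIMARY_MOTIF_DEFAULT
    secondary_motif: str = SECONDARY_MOTIF_DEFAULT

    def __post_init__(self) -> None:
        for motif, what in ((self.primary_motif, "primary motif"), (self.secondary_motif, "secondary motif")):
            if not motif:
                raise ValueError(f"{what} must be non-empty")
            _check_dna(motif, what, allow_n=False)


@dataclass(frozen=True)
class RestrictionFragment:
    index: int
    start: int
    end: int
    valid: bool

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.index}: start {self.start} >= end {self.end}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class FragmentMap:
    """Ordered primary-digest fragments tiling one haplotype."""

    haplotype_name: str
    enzymes: EnzymePair
    fragments: list[RestrictionFragment]
    _starts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("fragment map must contain at least one fragment")
        if self.fragments[0].start != 0:
            raise ValueError("first fragment must start at 0")
        for prev, nxt in zip(self.fragments, self.fragments[1:]):
            if nxt.start != prev.end:
                raise ValueError("fragments must tile without gaps or overlaps")
        self._starts = np.asarray([f.start for f in self.fragments], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[RestrictionFragment]:
        return iter(self.fragments)

    def __getitem__(self, i: int) -> RestrictionFragment:
        return self.fragments[i]

    @property
    def sequence_length(self) -> int:
        return self.fragments[-1].end

    @property
    def valid_mask(self) -> np.ndarray:
        return np.asarray([f.valid for f in self.fragments], dtype=bool)

    @property
    def starts(self) -> np.ndarray:
        return self._starts

    @property
    def ends(self) -> np.ndarray:
        return np.asarray([f.end for f in self.fragments], dtype=np.int64)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0


@dataclass(frozen=True)
class Region:
    """Named genomic interval on the shared locus (0-based half-open)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.name!r}: start must be < end")

    def contains(self, pos: float) -> bool:
        return self.start <= pos < self.end


def scan_motif(seq: str, motif: str) -> list[int]:
    """All 0-based start positions where ``motif`` occurs in ``seq``.

    Overlapping occurrences are reported.  ``N`` bases never match.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    _check_dna(motif, "motif", allow_n=False)
    hits: list[int] = []
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1  # step one base so overlapping matches are found


def build_fragment_map(hap: Haplotype, enz: EnzymePair = EnzymePair()) -> FragmentMap:
    """Digest ``hap`` with the primary enzyme; flag fragments holding a secondary site.

    Each primary-motif occurrence starts a new fragment.  A fragment is
    ``valid`` iff at least one secondary-motif occurrence lies entirely
    within it (occurrences straddling a boundary validate neither side).
    """
    if hap.length == 0:
        raise ValueError("cannot digest an empty sequence")
    cuts = scan_motif(hap.seq, enz.primary_motif)
    boundaries = [0] + [c for c in cuts if c > 0] + [hap.length]
    sec = np.asarray(scan_motif(hap.seq, enz.secondary_motif), dtype=np.int64)
    m = len(enz.secondary_motif)
    fragments = []
    for k, (s, e) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        if sec.size:
            lo = np.searchsorted(sec, s, side="left")
            hi = np.searchsorted(sec, e - m, side="right")
            valid = hi > lo
        else:
            valid = False
        fragments.append(RestrictionFragment(index=k, start=int(s), end=int(e), valid=bool(valid)))
    return FragmentMap(haplotype_name=hap.name, enzymes=enz, fragments=fragments)


def fragment_of(fmap: FragmentMap, pos: int) -> int:
    """Index of the unique fragment with start <= pos < end."""
    if pos < 0 or pos >= fmap.sequence_length:
        raise ValueError(f"position {pos} outside [0, {fmap.sequence_length})")
    return int(np.searchsorted(fmap.starts, pos, side="right") - 1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a (small) FASTA file into {name: uppercase sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_haplotypes(path) -> list[Haplotype]:
    return [Haplotype(name=n, seq=s) for n, s in read_fasta(path).items()]


def write_fragment_bed(path, fmap: FragmentMap) -> None:
    """BED: chrom=haplotype name, start, end, name=index, score=valid as 0/1."""
    with open(path, "w") as fh:
        for frag in fmap:
            fh.write(
                f"{fmap.haplotype_name}\t{frag.start}\t{frag.end}\t{frag.index}\t{int(frag.valid)}\n"
            )


def read_fragment_bed(path, enzymes: EnzymePair = EnzymePair()) -> FragmentMap:
    """Rebuild a FragmentMap from the BED written by :func:`write_fragment_bed`."""
    fragments = []
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, start, end, idx, valid = line.split("\t")[:5]
            name = chrom
            fragments.append(
                RestrictionFragment(index=int(idx), start=int(start), end=int(end), valid=bool(int(valid)))
            )
    if name is None:
        raise ValueError("empty fragment BED")
    return FragmentMap(haplotype_name=name, enzymes=enzymes, fragments=fragments)


def read_regions_bed(path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            name = cols[3] if len(cols) > 3 else f"region{i}"
            regions.append(Region(name=name, start=int(cols[1]), end=int(cols[2])))
    return regions
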