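"""4C-seq processing: demultiplex, count, normalize, smooth, quantify.

Raw paired reads are demultiplexed by anchored primer matching (up to a
configurable number of mismatches, default 2), trimmed to the primary
restriction site, optionally split into alleles at a discriminating SNV on
the mate, aligned externally, and counted onto restriction fragments by
exact boundary match.  Per-fragment counts are scaled to counts per million
over included (valid, non-viewpoint) fragments and smoothed with a centered
rolling mean (default window 21 fragments).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from loopquant.locus import FragmentMap, Region

ALLELE_129 = "129"
ALLELE_CAST = "CAST"
ALLELE_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AlleleSnv:
    """Discriminating SNV read on the mate: offset within the mate read."""

    offset: int
    base129: str
    baseCAST: str

    def __post_init__(self) -> None:
        if self.base129 == self.baseCAST:
            raise ValueError("allele SNV must have distinct bases")
        if self.offset < 0:
            raise ValueError("allele SNV offset must be >= 0")


@dataclass(frozen=True)
class ViewpointSpec:
    """A 4C viewpoint: reading primer plus its anchor fragment."""

    name: str
    primer_seq: str
    viewpoint_fragment: int
    max_mismatch: int = 2
    allele_snv: Optional[AlleleSnv] = None

    def __post_init__(self) -> None:
        if not self.primer_seq:
            raise ValueError("primer must be non-empty")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass
class DemuxedRead:
    viewpoint: str
    allele: str
    trimmed_seq: str
    mate_seq: str


@dataclass
class QCTally:
    """Read-fate bookkeeping; categories partition the input exactly."""

    total: int = 0
    matched: int = 0
    unmatched_primer: int = 0
    ambiguous: int = 0
    no_motif: int = 0
    allele_129: int = 0
    allele_cast: int = 0
    allele_unassigned: int = 0
    offset_out_of_range: int = 0
    multi_fragment_discard: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class AlignedReadRecord:
    ref_name: str
    start: int
    end: int
    is_paired: bool = True
    is_unique: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("aligned read must have start < end")


@dataclass
class ContactTrack:
    """Per-fragment raw/normalized/smoothed signal for one viewpoint x allele x replicate."""

    viewpoint: str
    allele: str
    replicate: str
    window: int
    raw: np.ndarray
    normalized: np.ndarray
    smoothed: np.ndarray
    included: np.ndarray  # fragments participating in normalization/quantification


@dataclass(frozen=True)
class RegionQuant:
    region: str
    viewpoint: str
    allele: str
    replicate: str
    value: float
    n_fragments: int


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def match_viewpoint(read_seq: str, viewpoints: Sequence[ViewpointSpec]) -> tuple[Optional[str], str]:
    """Anchored primer match at read position 0.

    Returns ``(viewpoint_name, "matched")``, ``(None, "unmatched")`` or
    ``(None, "ambiguous")`` when two or more viewpoints qualify.
    """
    if not read_seq:
        raise ValueError("read must be non-empty")
    hits = []
    for vp in viewpoints:
        n = len(vp.primer_seq)
        if len(read_seq) < n:
            continue
        if hamming(read_seq[:n], vp.primer_seq) <= vp.max_mismatch:
            hits.append(vp.name)
    if len(hits) == 1:
        return hits[0], "matched"
    if len(hits) > 1:
        return None, "ambiguous"
    return None, "unmatched"


def trim_to_primary_site(read_seq: str, primer_len: int, primary_motif: str) -> Optional[str]:
    """Suffix of the read starting at the primary motif the primer reads into.

    The search starts at ``primer_len - len(motif)`` (the motif may be the
    primer's own 3' end); the leftmost occurrence wins.  ``None`` when the
    read carries no motif occurrence (read is discarded upstream).
    """
    start = max(0, primer_len - len(primary_motif))
    i = read_seq.find(primary_motif, start)
    if i < 0:
        return None
    return read_seq[i:]


def split_allele(mate_seq: str, allele_snv: AlleleSnv) -> str:
    """Allele label from the sequenced base at the SNV offset on the mate."""
    if allele_snv.offset >= len(mate_seq):
        return ALLELE_UNASSIGNED
    base = mate_seq[allele_snv.offset]
    if base == allele_snv.base129:
        return ALLELE_129
    if base == allele_snv.baseCAST:
        return ALLELE_CAST
    return ALLELE_UNASSIGNED


def demux_pairs(
    pairs: Iterable[tuple[str, str]],
    viewpoints: Sequence[ViewpointSpec],
    primary_motif: str,
) -> tuple[list[DemuxedRead], QCTally]:
    """Demultiplex (read1, read2) pairs into trimmed, allele-labeled reads.

    Fate categories are mutually exclusive:
    ``total == matched + unmatched_primer + ambiguous + no_motif``.
    """
    vp_by_name = {vp.name: vp for vp in viewpoints}
    out: list[DemuxedRead] = []
    tally = QCTally()
    for read1, read2 in pairs:
        tally.total += 1
        name, status = match_viewpoint(read1, viewpoints)
        if status == "ambiguous":
            tally.ambiguous += 1
            continue
        if status == "unmatched":
            tally.unmatched_primer += 1
            continue
        vp = vp_by_name[name]
        trimmed = trim_to_primary_site(read1, len(vp.primer_seq), primary_motif)
        if trimmed is None:
            tally.no_motif += 1
            continue
        tally.matched += 1
        if vp.allele_snv is None:
            allele = ALLELE_UNASSIGNED
        else:
            if vp.allele_snv.offset >= len(read2):
                tally.offset_out_of_range += 1
            allele = split_allele(read2, vp.allele_snv)
        if allele == ALLELE_129:
            tally.allele_129 += 1
        elif allele == ALLELE_CAST:
            tally.allele_cast += 1
        else:
            tally.allele_unassigned += 1
        out.append(DemuxedRead(viewpoint=name, allele=allele, trimmed_seq=trimmed, mate_seq=read2))
    return out, tally


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_fragments(
    reads: Iterable[AlignedReadRecord],
    fmap: FragmentMap,
    tally: Optional[QCTally] = None,
) -> np.ndarray:
    """Count reads onto fragments by exact start-or-end boundary match.

    A read contributes once to fragment ``f`` iff ``read.start == f.start``
    or ``read.end == f.end``.  A read matching both boundaries of the same
    fragment counts once; a read matching boundaries of two different
    fragments is discarded (tallied) rather than double-counted.
    """
    start_idx = {f.start: f.index for f in fmap}
    end_idx = {f.end: f.index for f in fmap}
    counts = np.zeros(len(fmap), dtype=np.int64)
    for read in reads:
        if not (read.is_paired and read.is_unique):
            continue
        hits = set()
        i = start_idx.get(read.start)
        if i is not None:
            hits.add(i)
        j = end_idx.get(read.end)
        if j is not None:
            hits.add(j)
        if len(hits) == 1:
            counts[hits.pop()] += 1
        elif len(hits) == 2:
            if tally is not None:
                tally.multi_fragment_discard += 1
    return counts


def read_alignments_sam(path, min_mapq: int = 20) -> list[AlignedReadRecord]:
    """Load alignments from SAM/BAM; 'unique' = MAPQ >= threshold and not secondary."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            records.append(
                AlignedReadRecord(
                    ref_name=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    is_paired=aln.is_paired,
                    is_unique=(aln.mapping_quality >= min_mapq and not aln.is_secondary),
                )
            )
    return records


def read_alignments_tsv(path) -> list[AlignedReadRecord]:
    """4-column TSV: ref, start, end, flags ('paired,unique' subset)."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ref, start, end, flags = line.split("\t")[:4]
            flagset = set(flags.split(","))
            records.append(
                AlignedReadRecord(
                    ref_name=ref,
                    start=int(start),
                    end=int(end),
                    is_paired="paired" in flagset,
                    is_unique="unique" in flagset,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Normalization / smoothing / quantification
# ---------------------------------------------------------------------------

def cpm_normalize(raw: np.ndarray, valid_mask: np.ndarray) -> np.ndarray:
    """Counts-per-million over included fragments; excluded fragments set to 0."""
    raw = np.asarray(raw, dtype=float)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if raw.shape != valid_mask.shape:
        raise ValueError("raw and valid_mask must have the same shape")
    total = raw[valid_mask].sum()
    if total <= 0:
        raise ValueError("empty library: no counts on included fragments")
    out = np.zeros_like(raw)
    out[valid_mask] = raw[valid_mask] * 1e6 / total
    return out


def rolling_mean(track: np.ndarray, window: int = 21, edge: str = "shrink") -> np.ndarray:
    """Centered rolling mean with symmetric shrinking windows at the edges.

    ``edge='shrink'`` truncates the half-window symmetrically to what exists;
    ``edge='nan'`` emits NaN where the full window does not fit.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    x = np.asarray(track, dtype=float)
    n = x.size
    if n == 0 or window == 1:
        return x.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - h
    hi = idx + h + 1
    out = (csum[hi] - csum[lo]) / (hi - lo)
    if edge == "nan":
        out[idx - half < 0] = np.nan
        out[idx + half >= n] = np.nan
    elif edge != "shrink":
        raise ValueError(f"unknown edge policy {edge!r}")
    return out


def included_fragments(
    fmap: FragmentMap,
    viewpoint_fragment: Optional[int] = None,
    exclude_viewpoint_neighbors: int = 1,
) -> np.ndarray:
    """Mask of fragments used for normalization and quantification.

    Blind (invalid) fragments are excluded, as are the viewpoint fragment
    and ``exclude_viewpoint_neighbors`` fragments on each side
    (self-ligation / undigested guard).
    """
    mask = fmap.valid_mask.copy()
    if viewpoint_fragment is not None:
        lo = max(0, viewpoint_fragment - exclude_viewpoint_neighbors)
        hi = min(len(fmap), viewpoint_fragment + exclude_viewpoint_neighbors + 1)
        mask[lo:hi] = False
    return mask


def build_track(
    raw: np.ndarray,
    fmap: FragmentMap,
    viewpoint: str,
    allele: str = ALLELE_UNASSIGNED,
    replicate: str = "rep1",
    viewpoint_fragment: Optional[int] = None,
    exclude_viewpoint_neighbors: int = 1,
    window: int = 21,
    edge: str = "shrink",
) -> ContactTrack:
    """Raw counts -> CPM -> rolling mean, with the standard inclusion mask."""
    mask = included_fragments(fmap, viewpoint_fragment, exclude_viewpoint_neighbors)
    normalized = cpm_normalize(np.asarray(raw), mask)
    smoothed = rolling_mean(normalized, window=window, edge=edge)
    return ContactTrack(
        viewpoint=viewpoint,
        allele=allele,
        replicate=replicate,
        window=window,
        raw=np.asarray(raw, dtype=np.int64),
        normalized=normalized,
        smoothed=smoothed,
        included=mask,
    )


def quantify_region(
    track: ContactTrack,
    region: Region,
    fmap: FragmentMap,
    stat: str = "mean",
    use: str = "normalized",
) -> RegionQuant:
    """Summarize the track over fragments whose midpoint falls in the region.

    Only included fragments participate.  ``stat`` is 'mean' (default,
    window-width invariant) or 'sum'; ``use`` selects the normalized
    (default) or smoothed vector.
    """
    values = getattr(track, use)
    mids = fmap.midpoints
    sel = (mids >= region.start) & (mids < region.end) & track.included
    if not sel.any():
        raise ValueError(f"region {region.name!r} overlaps no included fragment")
    if stat == "mean":
        value = float(values[sel].mean())
    elif stat == "sum":
        value = float(values[sel].sum())
    else:
        raise ValueError(f"unknown stat {stat!r}")
    return RegionQuant(
        region=region.name,
        viewpoint=track.viewpoint,
        allele=track.allele,
        replicate=track.replicate,
        value=value,
        n_fragments=int(sel.sum()),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_bedgraph(path, fmap: FragmentMap, values: np.ndarray) -> None:
    with open(path, "w") as fh:
        for frag, v in zip(fmap, np.asarray(values, dtype=float)):
            fh.write(f"{fmap.haplotype_name}\t{frag.start}\t{frag.end}\t{v:.6g}\n")


def write_region_quants(path, quants: Sequence[RegionQuant]) -> None:
    with open(path, "w") as fh:
        fh.write("region\tviewpoint\tallele\treplicate\tvalue\tn_fragments\n")
        for q in quants:
            fh.write(f"{q.region}\t{q.viewpoint}\t{q.allele}\t{q.replicate}\t{q.value:.6g}\t{q.n_fragments}\n")


def write_qc_tally(path, tally: QCTally) -> None:
    with open(path, "w") as fh:
        fh.write("category\tcount\n")
        for key, value in tally.as_dict().items():
            fh.write(f"{key}\t{value}\n")


def read_fastq_pairs(path1, path2) -> Iterable[tuple[str, str]]:
    """Iterate (seq1, seq2) from two coordinated FASTQ files."""

    def seqs(path):
        with open(path) as fh:
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    yield line.strip().upper()

    yield from zip(seqs(path1), seqs(path2))
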