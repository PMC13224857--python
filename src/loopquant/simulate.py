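"""Synthetic diploid locus and simulated libraries with known ground truth.

Everything the pipeline consumes can be generated here: a two-haplotype
locus with a discriminating SNV on average every ~135 bp, paired 4C reads
drawn from a distance-decay + loop-enrichment contact model with
allele-specific loop strengths, negative-binomial allelic count tables, Ct
tables with per-replicate random intercepts, and 3D stacks with planted
Gaussian spots.  Every generator is a pure function of its seed and
configuration.

The contact model is a deliberately minimal stand-in (power-law decay
times a multiplicative loop factor over the target region), not a polymer
simulation; it is sufficient to exercise recovery of relative contact
changes.  A naive exact-match read placer ships here for test closure
only — it is not a general aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from loopquant.fourc import (
    ALLELE_129,
    ALLELE_CAST,
    AlignedReadRecord,
    AlleleSnv,
    DemuxedRead,
    ViewpointSpec,
    build_track,
    count_fragments,
    demux_pairs,
    quantify_region,
)
from loopquant.locus import (
    EnzymePair,
    FragmentMap,
    Haplotype,
    Region,
    SnvRecord,
    SnvTable,
    build_fragment_map,
    scan_motif,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Diploid locus
# ---------------------------------------------------------------------------

@dataclass
class LocusConfig:
    seed: int = 0
    length: int = 120_000
    snv_spacing: float = 135.0
    primary_spacing: float = 450.0  # mean bp between planted primary sites
    secondary_per_fragment: int = 2  # planted secondary sites per fragment
    viewpoint_frac: float = 0.5  # viewpoint position as a fraction of length
    target_offset: Optional[int] = None  # loop target center, bp downstream of viewpoint
    target_width: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length < 5_000:
            raise ValueError("locus length must be >= 5 kb")
        if self.snv_spacing <= 0:
            raise ValueError("SNV spacing must be > 0")
        if self.target_offset is None:
            self.target_offset = self.length // 4
        if self.target_width is None:
            self.target_width = max(self.length // 30, 1_000)


@dataclass
class DiploidLocus:
    """Two haplotypes sharing one coordinate system and one fragment map."""

    hap129: Haplotype
    hapCAST: Haplotype
    snvs: SnvTable
    enzymes: EnzymePair
    fmap129: FragmentMap
    fmapCAST: FragmentMap
    config: LocusConfig

    @property
    def fmap(self) -> FragmentMap:
        # boundaries are identical by construction; 129's map is canonical
        return self.fmap129


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _plant(seq: np.ndarray, pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")


def _motif_footprint(seq: str, motifs: Sequence[str]) -> np.ndarray:
    """Boolean mask of bases covered by any motif occurrence."""
    mask = np.zeros(len(seq), dtype=bool)
    for motif in motifs:
        for p in scan_motif(seq, motif):
            mask[p : p + len(motif)] = True
    return mask


def make_diploid_locus(cfg: LocusConfig) -> DiploidLocus:
    """Seeded diploid toy locus with shared restriction landscape.

    SNV positions follow a Poisson process at the configured mean spacing
    but are never placed inside (or allowed to create) a motif occurrence,
    so both haplotypes share one fragment map.
    """
    rng = np.random.default_rng(cfg.seed)
    enz = EnzymePair()
    pm, sm = enz.primary_motif, enz.secondary_motif
    seq = _random_bases(rng, cfg.length)

    # plant primary sites at jittered spacing, then secondary sites between them
    cuts = []
    pos = cfg.primary_spacing * 0.5
    while pos < cfg.length - len(pm) - 1:
        cuts.append(int(pos))
        pos += cfg.primary_spacing * rng.uniform(0.5, 1.5)
    for c in cuts:
        _plant(seq, c, pm)
    planted = np.asarray(cuts + [cfg.length], dtype=int)
    for lo, hi in zip(planted[:-1], planted[1:]):
        inner_lo, inner_hi = lo + len(pm) + 2, hi - len(sm) - 2
        if inner_hi <= inner_lo:
            continue
        for _ in range(cfg.secondary_per_fragment):
            p = int(rng.integers(inner_lo, inner_hi))
            _plant(seq, p, sm)

    seq129 = seq.tobytes().decode()
    footprint = _motif_footprint(seq129, [pm, sm])

    # Poisson-process SNVs avoiding motif occurrences on either haplotype
    seq_cast = seq.copy()
    records: list[SnvRecord] = []
    guard = max(len(pm), len(sm))
    p = rng.exponential(cfg.snv_spacing)
    while p < cfg.length:
        pos_i = int(p)
        p += rng.exponential(cfg.snv_spacing)
        if pos_i >= cfg.length or footprint[pos_i]:
            continue
        if records and pos_i <= records[-1].pos:
            continue
        ref = seq129[pos_i]
        alts = [b for b in "ACGT" if b != ref]
        rng.shuffle(alts)
        lo, hi = max(0, pos_i - guard + 1), min(cfg.length, pos_i + guard)
        # window taken from the CAST sequence in progress: nearby earlier
        # SNVs could otherwise combine with this one into a new motif
        ctx = seq_cast[lo:hi].tobytes().decode()
        for alt in alts:
            window = ctx[: pos_i - lo] + alt + ctx[pos_i - lo + 1 :]
            if not scan_motif(window, pm) and not scan_motif(window, sm):
                _plant(seq_cast, pos_i, alt)
                records.append(SnvRecord(pos=pos_i, base129=ref, baseCAST=alt))
                break

    hap129 = Haplotype(name="129", seq=seq129)
    hapCAST = Haplotype(name="CAST", seq=seq_cast.tobytes().decode())
    fmap129 = build_fragment_map(hap129, enz)
    fmapCAST = build_fragment_map(hapCAST, enz)
    if not np.array_equal(fmap129.starts, fmapCAST.starts):
        raise RuntimeError("haplotypes do not share a fragment map (construction bug)")
    n_valid = int(fmap129.valid_mask.sum())
    if n_valid < 50:
        raise ValueError(f"only {n_valid} valid fragments; increase length or site density")
    return DiploidLocus(
        hap129=hap129,
        hapCAST=hapCAST,
        snvs=SnvTable(records),
        enzymes=enz,
        fmap129=fmap129,
        fmapCAST=fmapCAST,
        config=cfg,
    )


def design_viewpoint(
    locus: DiploidLocus,
    name: str = "VP",
    primer_len: int = 20,
    mate_len: int = 50,
    mate_snv_offset: int = 20,
    max_mismatch: int = 2,
) -> tuple[ViewpointSpec, int]:
    """Pick a viewpoint fragment near the configured position and derive its primer.

    The reading primer is the ``primer_len`` bases ending with the primary
    motif at the viewpoint fragment's downstream boundary; the window must
    be SNV-free so one primer serves both alleles.  The mate read is
    anchored so a nearby discriminating SNV sits at a fixed offset.
    Returns (spec, mate_start).
    """
    fmap = locus.fmap
    pm = locus.enzymes.primary_motif
    want = int(locus.config.length * locus.config.viewpoint_frac)
    order = np.argsort(np.abs(fmap.midpoints - want))
    for idx in order:
        frag = fmap[int(idx)]
        end = frag.end
        lo = end - (primer_len - len(pm))
        if lo <= 0 or end + len(pm) > locus.config.length:
            continue
        if not frag.valid:
            continue
        if locus.snvs.in_interval(lo, end + len(pm)):
            continue  # primer window must be allele-invariant
        primer = locus.hap129.seq[lo : end + len(pm)]
        if primer.find(pm, primer_len - len(pm)) != primer_len - len(pm):
            continue  # another motif occurrence would shift the trim point
        # nearest SNV after the junction anchors the allele-typing mate read
        snv_after = locus.snvs.in_interval(end + len(pm), locus.config.length)
        snv_before = locus.snvs.in_interval(0, lo)
        candidates = ([snv_after[0]] if snv_after else []) + ([snv_before[-1]] if snv_before else [])
        ok = None
        for snv in candidates:
            mate_start = snv.pos - mate_snv_offset
            if 0 <= mate_start and mate_start + mate_len <= locus.config.length:
                ok = (snv, mate_start)
                break
        if ok is None:
            continue
        snv, mate_start = ok
        spec = ViewpointSpec(
            name=name,
            primer_seq=primer,
            viewpoint_fragment=int(idx),
            max_mismatch=max_mismatch,
            allele_snv=AlleleSnv(offset=mate_snv_offset, base129=snv.base129, baseCAST=snv.baseCAST),
        )
        return spec, mate_start
    raise ValueError("no suitable viewpoint fragment found")


def default_regions(locus: DiploidLocus, viewpoint: ViewpointSpec) -> tuple[Region, Region]:
    """Loop target region downstream of the viewpoint and its mirrored control."""
    cfg = locus.config
    vp_mid = locus.fmap[viewpoint.viewpoint_fragment].midpoint
    half = cfg.target_width // 2
    t_lo = int(vp_mid + cfg.target_offset - half)
    t_hi = int(vp_mid + cfg.target_offset + half)
    c_lo = int(vp_mid - cfg.target_offset - half)
    c_hi = int(vp_mid - cfg.target_offset + half)
    if t_lo < 0 or t_hi > cfg.length or c_lo < 0 or c_hi > cfg.length:
        raise ValueError("target/control regions fall outside the locus")
    return Region("target", t_lo, t_hi), Region("control", c_lo, c_hi)


# ---------------------------------------------------------------------------
# 4C library simulation
# ---------------------------------------------------------------------------

@dataclass
class ContactModel:
    """Power-law distance decay with a multiplicative loop over the target region."""

    decay_exponent: float = 1.0
    loop_129: float = 1.0
    loop_CAST: float = 1.0
    n_reads: int = 10_000
    error_rate: float = 0.001
    allele_mix: float = 0.5  # probability a read originates from the 129 allele
    read_len: int = 75
    min_distance: float = 1_000.0  # decay floor to avoid the singularity at 0

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent must be > 0")
        if self.loop_129 < 0 or self.loop_CAST < 0:
            raise ValueError("loop enrichments must be >= 0")


@dataclass
class TruthBundle:
    """Ground truth keyed to emitted records."""

    contact_probs: dict[str, np.ndarray]  # allele -> per-fragment probability
    read_truth: pd.DataFrame  # read_id, allele, fragment
    target_region: Region
    control_region: Region


def contact_probabilities(
    locus: DiploidLocus,
    model: ContactModel,
    viewpoint: ViewpointSpec,
    target: Region,
    exclude_viewpoint_neighbors: int = 1,
) -> dict[str, np.ndarray]:
    """Normalized per-fragment capture probabilities per allele."""
    fmap = locus.fmap
    mids = fmap.midpoints
    vp_mid = mids[viewpoint.viewpoint_fragment]
    dist = np.maximum(np.abs(mids - vp_mid), model.min_distance)
    base = dist ** (-model.decay_exponent)
    mask = fmap.valid_mask.copy()
    lo = max(0, viewpoint.viewpoint_fragment - exclude_viewpoint_neighbors)
    hi = min(len(fmap), viewpoint.viewpoint_fragment + exclude_viewpoint_neighbors + 1)
    mask[lo:hi] = False
    base[~mask] = 0.0
    in_target = (mids >= target.start) & (mids < target.end)
    out = {}
    for allele, lam in ((ALLELE_129, model.loop_129), (ALLELE_CAST, model.loop_CAST)):
        w = base.copy()
        w[in_target] *= lam
        total = w.sum()
        if total <= 0:
            raise ValueError("contact model has zero mass over included fragments")
        out[allele] = w / total
    return out


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_4c_library(
    locus: DiploidLocus,
    model: ContactModel,
    viewpoint: ViewpointSpec,
    mate_start: int,
    seed: int = 0,
    target: Optional[Region] = None,
    control: Optional[Region] = None,
    mate_len: int = 50,
) -> tuple[list[tuple[str, str]], TruthBundle]:
    """Paired ligation-junction reads from the allele-specific contact model.

    read1 = reading primer + junction sequence into the captured fragment
    (the trimmed read therefore aligns exactly at the fragment start);
    read2 covers the discriminating SNV downstream of the reverse primer.
    Substitution errors are applied at the configured per-base rate.
    """
    rng = np.random.default_rng(seed)
    if target is None or control is None:
        target, control = default_regions(locus, viewpoint)
    probs = contact_probabilities(locus, model, viewpoint, target)
    fmap = locus.fmap
    haps = {ALLELE_129: locus.hap129, ALLELE_CAST: locus.hapCAST}
    pm_len = len(locus.enzymes.primary_motif)
    primer = viewpoint.primer_seq
    junction_len = model.read_len - len(primer)

    alleles = np.where(rng.random(model.n_reads) < model.allele_mix, ALLELE_129, ALLELE_CAST)
    pairs: list[tuple[str, str]] = []
    truth_rows = {"read_id": [], "allele": [], "fragment": []}
    n_frag = len(fmap)
    frag_choice = np.empty(model.n_reads, dtype=np.int64)
    for allele in (ALLELE_129, ALLELE_CAST):
        sel = alleles == allele
        if sel.any():
            frag_choice[sel] = rng.choice(n_frag, size=int(sel.sum()), p=probs[allele])
    for i in range(model.n_reads):
        allele = str(alleles[i])
        f = fmap[int(frag_choice[i])]
        hap = haps[allele]
        junction = hap.seq[f.start + pm_len : f.start + pm_len + junction_len]
        read1 = _mutate(rng, primer + junction, model.error_rate)
        read2 = _mutate(rng, hap.seq[mate_start : mate_start + mate_len], model.error_rate)
        pairs.append((read1, read2))
        truth_rows["read_id"].append(f"read{i}")
        truth_rows["allele"].append(allele)
        truth_rows["fragment"].append(int(frag_choice[i]))
    truth = TruthBundle(
        contact_probs=probs,
        read_truth=pd.DataFrame(truth_rows),
        target_region=target,
        control_region=control,
    )
    return pairs, truth


def place_demuxed(
    demuxed: Sequence[DemuxedRead],
    locus: DiploidLocus,
    k: int = 24,
) -> dict[str, list[AlignedReadRecord]]:
    """Naive exact-match placer for synthetic trimmed reads (test closure only).

    Each fragment is keyed by its first ``k`` bases on either haplotype;
    reads whose prefix hits exactly one fragment are placed at the fragment
    start with the end clipped at the fragment boundary.  Reads with
    sequencing errors in the prefix simply go unplaced.
    """
    index: dict[str, Optional[int]] = {}
    for fmap_hap, hap in ((locus.fmap129, locus.hap129), (locus.fmapCAST, locus.hapCAST)):
        for frag in fmap_hap:
            # junction reads run past short fragments, so the genomic k-mer
            # at the fragment start is a valid key regardless of fragment size
            key = hap.seq[frag.start : frag.start + k]
            if len(key) < k:
                continue
            if key in index and index[key] != frag.index:
                index[key] = None  # ambiguous k-mer
            else:
                index[key] = frag.index
    placed: dict[str, list[AlignedReadRecord]] = {}
    fmap = locus.fmap
    for read in demuxed:
        if len(read.trimmed_seq) < k:
            continue
        hit = index.get(read.trimmed_seq[:k])
        if hit is None:
            continue
        frag = fmap[hit]
        end = min(frag.start + len(read.trimmed_seq), frag.end)
        rec = AlignedReadRecord(ref_name=fmap.haplotype_name, start=frag.start, end=end)
        placed.setdefault(read.allele, []).append(rec)
    return placed


def run_4c_end_to_end(
    locus: DiploidLocus,
    model: ContactModel,
    viewpoint: ViewpointSpec,
    mate_start: int,
    seed: int = 0,
    window: int = 21,
    replicate: str = "rep1",
):
    """Simulate a library and push it through demux -> place -> count -> track.

    Returns (tracks per allele, region quants per allele x region, tally, truth).
    """
    pairs, truth = simulate_4c_library(locus, model, viewpoint, mate_start, seed=seed)
    demuxed, tally = demux_pairs(pairs, [viewpoint], locus.enzymes.primary_motif)
    placed = place_demuxed(demuxed, locus)
    fmap = locus.fmap
    tracks = {}
    quants = {}
    for allele in (ALLELE_129, ALLELE_CAST):
        recs = placed.get(allele, [])
        if not recs:
            continue
        raw = count_fragments(recs, fmap, tally)
        track = build_track(
            raw,
            fmap,
            viewpoint=viewpoint.name,
            allele=allele,
            replicate=replicate,
            viewpoint_fragment=viewpoint.viewpoint_fragment,
            window=window,
        )
        tracks[allele] = track
        for region in (truth.target_region, truth.control_region):
            quants[(allele, region.name)] = quantify_region(track, region, fmap)
    return tracks, quants, tally, truth


# ---------------------------------------------------------------------------
# Allelic count tables
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """NB2 draw: var = mean + dispersion * mean^2; dispersion <= 0 -> Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size=size)
    return rng.poisson(lam)


def simulate_allelic_counts(
    features: Sequence[str],
    conditions: Sequence[str],
    n_replicates: int,
    total: float,
    ratios: dict[tuple[str, str], float],
    dispersion: float = 0.05,
    seed: int = 0,
    unassigned_total: float = 10_000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial allelic count table plus its truth table.

    ``ratios[(feature, condition)]`` is the expected 129 proportion; per
    design cell n_129 ~ NB(total * ratio), n_CAST ~ NB(total * (1-ratio))
    with shared dispersion.
    """
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for feature in features:
        for condition in conditions:
            ratio = ratios[(feature, condition)]
            if not (0.0 < ratio < 1.0):
                raise ValueError("allelic ratios must lie in (0, 1)")
            n129 = _nb_sample(rng, total * ratio, dispersion, n_replicates)
            ncast = _nb_sample(rng, total * (1.0 - ratio), dispersion, n_replicates)
            nun = rng.poisson(unassigned_total, size=n_replicates)
            for r in range(n_replicates):
                rows.append(
                    {
                        "feature": feature,
                        "condition": condition,
                        "replicate": f"rep{r + 1}",
                        "n_129": int(n129[r]),
                        "n_CAST": int(ncast[r]),
                        "n_unassigned": int(nun[r]),
                    }
                )
            truth_rows.append({"feature": feature, "condition": condition, "ratio": ratio})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    conditions: Sequence[str],
    n_replicates: int,
    condition_effects: dict[str, float],
    replicate_sd: float = 0.3,
    residual_sd: float = 0.2,
    baseline_target: float = 25.0,
    baseline_housekeeping: float = 20.0,
    target: str = "gene",
    housekeeping: str = "housekeeping",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table with per-replicate random intercepts shared by the housekeeping gene.

    Ct(target) = baseline + condition effect + replicate intercept + noise;
    the housekeeping Ct shares the replicate intercept, so the intercept
    cancels in delta-Ct only through the mixed model, not arithmetically.
    """
    if replicate_sd < 0 or residual_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0.0, replicate_sd, size=n_replicates)
    rows = []
    for r in range(n_replicates):
        for condition in conditions:
            sample = f"{condition}_rep{r + 1}"
            effect = condition_effects.get(condition, 0.0)
            ct_t = baseline_target + effect + intercepts[r] + rng.normal(0.0, residual_sd)
            ct_h = baseline_housekeeping + intercepts[r] + rng.normal(0.0, residual_sd)
            rows.append(
                {"sample": sample, "replicate": f"rep{r + 1}", "condition": condition, "target": target, "ct": ct_t}
            )
            rows.append(
                {
                    "sample": sample,
                    "replicate": f"rep{r + 1}",
                    "condition": condition,
                    "target": housekeeping,
                    "ct": ct_h,
                }
            )
    truth = pd.DataFrame(
        [{"condition": c, "effect_cycles": condition_effects.get(c, 0.0)} for c in conditions]
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# smFISH simulation
# ---------------------------------------------------------------------------

@dataclass
class SmfishConfig:
    shape: tuple[int, int, int] = (15, 256, 256)
    n_cells: int = 6
    cell_radius: int = 34
    nucleus_radius: int = 14
    n_cytoplasmic: int = 8  # single-RNA spots per cell
    site_rna_equivalents: Sequence[float] = field(default_factory=lambda: ())  # per cell; 0 = none
    rna_amplitude: float = 200.0  # peak intensity of one RNA
    sigma: tuple[float, float, float] = (1.0, 1.5, 1.5)
    noise_sd: float = 10.0
    cell_baseline: float = 60.0
    nucleus_intensity: float = 800.0
    camera_offset: float = 100.0  # keeps read noise un-truncated by the >=0 clip


def _render_gaussians(
    shape: tuple[int, int, int],
    centers: np.ndarray,
    amplitudes: np.ndarray,
    sigma: Sequence[float],
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    win = np.ceil(5 * sigma).astype(int)
    for c, a in zip(centers, amplitudes):
        lo = np.maximum(np.floor(c).astype(int) - win, 0)
        hi = np.minimum(np.floor(c).astype(int) + win + 1, np.asarray(shape))
        grids = np.meshgrid(*[np.arange(a_, b_) for a_, b_ in zip(lo, hi)], indexing="ij")
        g = np.exp(-0.5 * sum(((g_ - c_) / s_) ** 2 for g_, c_, s_ in zip(grids, c, sigma)))
        img[tuple(slice(a_, b_) for a_, b_ in zip(lo, hi))] += a * g
    return img


def plant_spots(
    shape: tuple[int, int, int],
    centers: np.ndarray,
    amplitudes: Sequence[float],
    sigma: Sequence[float] = (1.0, 1.5, 1.5),
    noise_sd: float = 0.0,
    baseline: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """Planted 3D Gaussian spots on a flat background with Gaussian read noise."""
    rng = np.random.default_rng(seed)
    img = baseline + _render_gaussians(shape, np.asarray(centers, dtype=float), np.asarray(amplitudes), sigma)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    return np.clip(img, 0.0, None)


def simulate_smfish_stack(cfg: SmfishConfig, seed: int = 0):
    """Render nuclear-stain and FISH stacks with planted cells and spots.

    Returns (nuclear ImageStack, fish ImageStack, truth) where truth holds
    the planted masks, spot table and per-cell site RNA equivalents.
    Raises when the requested cells do not fit the field of view.
    """
    from loopquant.smfish import ImageStack

    rng = np.random.default_rng(seed)
    nz, ny, nx = cfg.shape
    margin = cfg.cell_radius + 4
    pitch = 2 * cfg.cell_radius + 10
    cols = max(1, (nx - 2 * margin) // pitch + 1)
    rows_n = max(1, (ny - 2 * margin) // pitch + 1)
    if cols * rows_n < cfg.n_cells:
        raise ValueError(f"cannot fit {cfg.n_cells} cells of radius {cfg.cell_radius} in {(ny, nx)}")

    yy, xx = np.mgrid[0:ny, 0:nx]
    cells_mask = np.zeros((ny, nx), dtype=np.int32)
    nuclei_mask = np.zeros((ny, nx), dtype=np.int32)
    centers2d = []
    for i in range(cfg.n_cells):
        cy = margin + (i // cols) * pitch
        cx = margin + (i % cols) * pitch
        centers2d.append((cy, cx))
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cells_mask[r2 <= cfg.cell_radius**2] = i + 1
        nuclei_mask[r2 <= cfg.nucleus_radius**2] = i + 1

    site_rna = list(cfg.site_rna_equivalents) + [0.0] * max(0, cfg.n_cells - len(cfg.site_rna_equivalents))
    spot_rows = []
    centers, amps = [], []
    for i, (cy, cx) in enumerate(centers2d):
        label = i + 1
        # cytoplasmic single RNAs: inside the cell, outside the nucleus
        placed = 0
        while placed < cfg.n_cytoplasmic:
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(cfg.nucleus_radius + 4, cfg.cell_radius - 4)
            y, x = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            z = rng.uniform(3, nz - 4)
            centers.append((z, y, x))
            amps.append(cfg.rna_amplitude)
            spot_rows.append(
                {"z": z, "y": y, "x": x, "rna": 1.0, "cell": label, "compartment": "cytoplasmic"}
            )
            placed += 1
        if site_rna[i] > 0:
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, cfg.nucleus_radius - 4)
            y, x = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            z = rng.uniform(3, nz - 4)
            centers.append((z, y, x))
            amps.append(cfg.rna_amplitude * site_rna[i])
            spot_rows.append(
                {"z": z, "y": y, "x": x, "rna": site_rna[i], "cell": label, "compartment": "nuclear"}
            )

    from scipy import ndimage

    fish = np.full(cfg.shape, cfg.camera_offset, dtype=float)
    # smooth cytoplasmic baseline: real cell bodies have no step edges
    body = ndimage.gaussian_filter(cfg.cell_baseline * (cells_mask > 0).astype(float), 10.0)
    fish += body[None, :, :]
    if centers:
        fish += _render_gaussians(cfg.shape, np.asarray(centers), np.asarray(amps), cfg.sigma)
    fish += rng.normal(0.0, cfg.noise_sd, size=cfg.shape)
    nuclear = cfg.camera_offset + cfg.nucleus_intensity * (nuclei_mask > 0)[None, :, :] * np.ones(cfg.shape)
    nuclear += rng.normal(0.0, cfg.noise_sd, size=cfg.shape)

    truth = {
        "cells": cells_mask,
        "nuclei": nuclei_mask,
        "spots": pd.DataFrame(spot_rows, columns=["z", "y", "x", "rna", "cell", "compartment"]),
        "site_rna": site_rna[: cfg.n_cells],
    }
    return (
        ImageStack(data=np.clip(nuclear, 0, None), channel="nuclear"),
        ImageStack(data=np.clip(fish, 0, None), channel="FISH"),
        truth,
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_fastq_pairs(path1, path2, pairs: Sequence[tuple[str, str]], prefix: str = "read") -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, (r1, r2) in enumerate(pairs):
            f1.write(f"@{prefix}{i}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{prefix}{i}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def write_snv_table(path, snvs: SnvTable) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tbase129\tbaseCAST\n")
        for rec in snvs:
            fh.write(f"{rec.pos}\t{rec.base129}\t{rec.baseCAST}\n")
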