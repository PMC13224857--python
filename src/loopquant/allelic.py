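"""Allele assignment, allelic imbalance statistics and methylation calls.

Reads aligned separately to both parental genomes are assigned to the
allele with the higher alignment score (ties unassigned).  Allelic
proportions use size-factor-normalized counts, with each sample's size
factor defaulting to its total unassigned-read count.  The imbalance test
is a SIMPLIFIED stand-in for a DESeq2-style analysis: a log-linear
negative-binomial (or Poisson fallback) model with an allele x condition
interaction, tested by Wald statistic.  It is validated by its own
simulation calibration, not by equivalence to any external package.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from loopquant.fourc import ALLELE_129, ALLELE_CAST, ALLELE_UNASSIGNED

COUNT_COLUMNS = ("feature", "condition", "replicate", "n_129", "n_CAST", "n_unassigned")


@dataclass(frozen=True)
class DualAlignment:
    """Per-read alignment scores against the two parental genomes (higher is better)."""

    read_id: str
    score_129: float
    score_CAST: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.score_129) and np.isfinite(self.score_CAST)):
            raise ValueError("alignment scores must be finite")


@dataclass(frozen=True)
class ImbalanceResult:
    estimate: float  # log fold change of the allele ratio between conditions
    std_error: float
    statistic: float
    p_value: float
    family: str  # 'negative-binomial' or 'poisson'
    dispersion: float


def assign_by_score(d: DualAlignment) -> str:
    """Allele with the higher alignment score; exact tie -> unassigned."""
    if d.score_129 > d.score_CAST:
        return ALLELE_129
    if d.score_CAST > d.score_129:
        return ALLELE_CAST
    return ALLELE_UNASSIGNED


def assign_reads(alignments: Sequence[DualAlignment]) -> dict[str, str]:
    return {d.read_id: assign_by_score(d) for d in alignments}


def read_score_table(path) -> list[DualAlignment]:
    """TSV with columns read_id, score_129, score_CAST."""
    df = pd.read_csv(path, sep="\t")
    return [
        DualAlignment(read_id=str(r.read_id), score_129=float(r.score_129), score_CAST=float(r.score_CAST))
        for r in df.itertuples()
    ]


def read_scores_from_sam_pair(path_129, path_CAST, tag: str = "AS") -> list[DualAlignment]:
    """Pair score tags from two coordinate-matched SAM/BAM files by read name."""
    import pysam

    def scores(path):
        out = {}
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary:
                    continue
                if aln.has_tag(tag):
                    out[aln.query_name] = float(aln.get_tag(tag))
        return out

    s129, scast = scores(path_129), scores(path_CAST)
    shared = sorted(set(s129) & set(scast))
    return [DualAlignment(read_id=rid, score_129=s129[rid], score_CAST=scast[rid]) for rid in shared]


def allelic_proportion(
    n_129: float,
    n_CAST: float,
    size_factors: Optional[tuple[float, float]] = None,
) -> float:
    """Proportion of 129 after dividing each count by its sample's size factor.

    The size factor of a sample conventionally defaults to its total
    unassigned-read count (library-size proxy); equal factors reduce to the
    raw proportion.
    """
    if size_factors is None:
        size_factors = (1.0, 1.0)
    sf1, sf2 = size_factors
    if sf1 <= 0 or sf2 <= 0:
        raise ValueError("size factors must be positive")
    a = n_129 / sf1
    b = n_CAST / sf2
    if a + b <= 0:
        raise ValueError("zero denominator: no assigned reads after normalization")
    return a / (a + b)


def _dispersion_moment_estimate(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Cameron-Trivedi auxiliary moment estimate of the NB2 dispersion alpha."""
    n = y.size
    df = max(n - n_params, 1)
    return float(np.sum(((y - mu) ** 2 - mu) / mu**2) / df)


def imbalance_test(table: pd.DataFrame, size_factors: Optional[dict] = None) -> ImbalanceResult:
    """Wald test of the allele x condition interaction in a log-linear count model.

    ``table`` holds one row per (feature, condition, replicate) with columns
    ``n_129`` and ``n_CAST``, restricted to exactly two conditions with >= 2
    replicates each.  A common NB2 dispersion is moment-estimated from a
    Poisson fit; a non-positive estimate falls back to Poisson.  Optional
    ``size_factors`` maps (condition, replicate) -> factor used as model
    offset.
    """
    conditions = sorted(table["condition"].unique())
    if len(conditions) != 2:
        raise ValueError("imbalance_test requires exactly 2 conditions")
    for cond in conditions:
        sub = table[table["condition"] == cond]
        if sub["replicate"].nunique() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        if (sub[["n_129", "n_CAST"]].to_numpy().sum()) == 0:
            raise ValueError(f"condition {cond!r} has all-zero counts")

    long = table.melt(
        id_vars=["condition", "replicate"],
        value_vars=["n_129", "n_CAST"],
        var_name="allele",
        value_name="count",
    )
    y = long["count"].to_numpy(dtype=float)
    allele = (long["allele"] == "n_129").to_numpy(dtype=float)
    cond = (long["condition"] == conditions[1]).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), allele, cond, allele * cond])
    if size_factors is not None:
        sf = np.array(
            [size_factors[(c, r)] for c, r in zip(long["condition"], long["replicate"])], dtype=float
        )
        offset = np.log(sf)
    else:
        offset = None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        alpha = _dispersion_moment_estimate(y, pois.fittedvalues, X.shape[1])
        if alpha > 0:
            family = sm.families.NegativeBinomial(alpha=alpha)
            fam_name = "negative-binomial"
        else:
            family = sm.families.Poisson()
            fam_name = "poisson"
            alpha = 0.0
        fit = sm.GLM(y, X, family=family, offset=offset).fit()

    est = float(fit.params[3])
    se = float(fit.bse[3])
    z = est / se if se > 0 else 0.0
    # t reference with residual df: the normal reference is anti-conservative
    # at the handful of observations a replicate design provides
    p = float(2.0 * stats.t.sf(abs(z), df=max(y.size - X.shape[1], 1)))
    return ImbalanceResult(
        estimate=est, std_error=se, statistic=z, p_value=p, family=fam_name, dispersion=alpha
    )


# ---------------------------------------------------------------------------
# Bisulfite amplicon methylation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconRead:
    """A bisulfite read aligned to the amplicon coordinate system."""

    start: int
    seq: str

    def base_at(self, pos: int) -> Optional[str]:
        off = pos - self.start
        if 0 <= off < len(self.seq):
            return self.seq[off]
        return None


@dataclass(frozen=True)
class SnpSpec:
    pos: int
    base129: str
    baseCAST: str


def assign_amplicon_read(read: AmpliconRead, snp_specs: Sequence[SnpSpec]) -> str:
    """Majority vote over the covered discriminating SNVs; tie -> unassigned."""
    votes = Counter()
    for snp in snp_specs:
        base = read.base_at(snp.pos)
        if base == snp.base129:
            votes[ALLELE_129] += 1
        elif base == snp.baseCAST:
            votes[ALLELE_CAST] += 1
    if votes[ALLELE_129] > votes[ALLELE_CAST]:
        return ALLELE_129
    if votes[ALLELE_CAST] > votes[ALLELE_129]:
        return ALLELE_CAST
    return ALLELE_UNASSIGNED


def methylation_fractions(
    amplicon_reads: Sequence[AmpliconRead],
    cpg_positions: Sequence[int],
    snp_specs: Sequence[SnpSpec],
) -> pd.DataFrame:
    """Per-CpG, per-allele methylation as C/(C+T) over allele-assigned reads.

    Bisulfite conversion leaves methylated cytosines as C and converts
    unmethylated ones to T; bases other than C/T at a CpG are ignored.
    Reads without a majority-vote allele are excluded.
    """
    rows = []
    by_allele: dict[str, list[AmpliconRead]] = {ALLELE_129: [], ALLELE_CAST: []}
    for read in amplicon_reads:
        allele = assign_amplicon_read(read, snp_specs)
        if allele in by_allele:
            by_allele[allele].append(read)
    for pos in cpg_positions:
        for allele, reads in by_allele.items():
            n_c = sum(1 for r in reads if r.base_at(pos) == "C")
            n_t = sum(1 for r in reads if r.base_at(pos) == "T")
            frac = n_c / (n_c + n_t) if (n_c + n_t) > 0 else float("nan")
            rows.append({"cpg_pos": pos, "allele": allele, "n_C": n_c, "n_T": n_t, "fraction": frac})
    return pd.DataFrame(rows, columns=["cpg_pos", "allele", "n_C", "n_T", "fraction"])


def read_count_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df
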