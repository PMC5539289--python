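"""Background resampling and significance testing (step 2 statistics).

For every (TF, mutation block) the patient-specific ddbA values are
compared against ddbA of randomly generated background mutation blocks:
intervals drawn from the 1000-bp-upstream window of random genes (never the
gene carrying the tested block), with the same sequence length and mutation
count, each mutation substituting a uniformly random different base. The
comparison is a two-sided Wilcoxon rank-sum test (normal approximation with
tie and continuity corrections; exact enumeration for small samples),
Bonferroni-corrected over the PWMs tested, and repeated three times with
fresh backgrounds — a TF is reported only when all replicates are
significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)


@dataclass
class BackgroundBlock:
    """One randomly generated mutation block with its sequence pair."""

    chrom: str
    start: int  # 1-based
    end: int
    ref_seq: str
    alt_seq: str
    gene_id: str  # gene whose upstream region the block came from


@dataclass
class BackgroundBlockSet:
    blocks: list[BackgroundBlock]
    source_regions: list[tuple[str, str, int, int]]  # (gene_id, chrom, start, end)
    seed: int


@dataclass
class SignificanceRecord:
    """Wilcoxon outcome for one (TF, block) with per-patient tail probs."""

    tf: str  # pwm_id
    tf_name: str
    block_id: str
    direction: str  # {"positive", "negative"}
    per_patient_p: dict[str, float]
    wilcoxon_p: float
    bonferroni_p: float
    n_replicates_significant: int = 0


def upstream_universe(
    tss_records: Sequence, genome, width: int = 1000
) -> list[tuple[str, str, int, int]]:
    """The 1000-bp-upstream window of every annotated gene (one per TSS).

    Upstream is strand-aware: [tss-width, tss-1] on '+', [tss+1, tss+width]
    on '-', clipped to the chromosome.
    """
    out = []
    for t in tss_records:
        chrom_len = len(genome[t.chrom])
        if t.strand == "+":
            lo, hi = max(1, t.tss - width), t.tss - 1
        else:
            lo, hi = t.tss + 1, min(chrom_len, t.tss + width)
        if hi >= lo:
            out.append((t.gene_id, t.chrom, lo, hi))
    return out


def generate_background_blocks(
    universe: Sequence[tuple[str, str, int, int]],
    block_length: int,
    n_mutations: int,
    excluded_gene: str | None,
    count: int,
    seed: int,
    genome,
) -> BackgroundBlockSet:
    """Sample ``count`` random mutation blocks from the promoter universe.

    Each block is a uniformly placed ``block_length`` window inside a
    region, carrying ``n_mutations`` uniformly placed substitutions to a
    random different base. Regions of the excluded gene are never used;
    regions shorter than the block are skipped. When ``count`` exceeds the
    number of eligible regions, regions are re-drawn with replacement
    (placement and mutations still differ per draw).
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1 (a tested block always has >= 2 SNVs)")
    rng = np.random.default_rng(seed)
    eligible = [r for r in universe if r[0] != excluded_gene]
    n_short = sum(1 for r in eligible if r[3] - r[2] + 1 < block_length)
    if n_short:
        logger.info("skipping %d regions shorter than the block (%d bp)", n_short, block_length)
    eligible = [r for r in eligible if r[3] - r[2] + 1 >= block_length]
    if not eligible:
        raise ValueError("no eligible background regions of sufficient length")
    if count <= len(eligible):
        idx = rng.choice(len(eligible), size=count, replace=False)
    else:
        idx = rng.choice(len(eligible), size=count, replace=True)
    bases = "ACGT"
    blocks = []
    for i in idx:
        gene_id, chrom, lo, hi = eligible[i]
        max_start = hi - block_length + 1
        start = int(rng.integers(lo, max_start + 1))
        end = start + block_length - 1
        ref_seq = str(genome[chrom][start - 1 : end]).upper()
        offsets = rng.choice(block_length, size=n_mutations, replace=False)
        alt = list(ref_seq)
        for off in offsets:
            ref_b = alt[off]
            choices = [b for b in bases if b != ref_b]
            alt[off] = choices[int(rng.integers(3))] if ref_b in bases else ref_b
        blocks.append(
            BackgroundBlock(
                chrom=chrom,
                start=start,
                end=end,
                ref_seq=ref_seq,
                alt_seq="".join(alt),
                gene_id=gene_id,
            )
        )
    return BackgroundBlockSet(blocks=blocks, source_regions=list(universe), seed=seed)


# ---------------------------------------------------------------------------
# Statistics

def per_patient_tail_probability(
    patient_ddba: float, background_ddbas: Sequence[float], direction: str
) -> float:
    """Empirical probability of a background ddbA as extreme as the patient's.

    positive direction: (1 + #{bg >= patient}) / (1 + n); negative:
    (1 + #{bg <= patient}) / (1 + n).
    """
    bg = np.asarray(background_ddbas, dtype=float)
    if len(bg) < 20:
        raise ValueError("need >= 20 background values")
    if direction == "positive":
        extreme = int((bg >= patient_ddba).sum())
    elif direction == "negative":
        extreme = int((bg <= patient_ddba).sum())
    else:
        raise ValueError(f"direction must be positive/negative, got {direction!r}")
    return (1 + extreme) / (1 + len(bg))


def _exact_ranksum_p(w: float, n1: int, n2: int) -> float:
    """Exact two-sided p for the rank-sum W of n1 untied ranks out of n1+n2.

    DP over the number of subsets of {1..N} of size k with rank-sum s.
    """
    n = n1 + n2
    max_sum = n1 * n - n1 * (n1 - 1) // 2
    table = np.zeros((n1 + 1, max_sum + 1))
    table[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            table[k, rank:] += table[k - 1, : max_sum + 1 - rank]
    dist = table[n1]
    dist /= dist.sum()
    w_idx = int(round(w))
    cdf = dist[: w_idx + 1].sum()
    sf = dist[w_idx:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_block_test(
    patient_ddbas: Sequence[float],
    background_ddbas: Sequence[float],
    method: str = "auto",
) -> tuple[float, float, str]:
    """Wilcoxon rank-sum test of patient vs background ddbA.

    Returns (rank-sum statistic of the patient sample, two-sided p,
    direction). Direction is the sign of median(patient) - median(bg).
    ``method``: "normal" (approximation with tie + continuity correction),
    "exact" (enumeration, untied data), or "auto" (exact when untied and
    n_patient * n_bg <= 10,000).
    """
    x = np.asarray(patient_ddbas, dtype=float)
    y = np.asarray(background_ddbas, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2:
        raise ValueError("need >= 2 patient values")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w = float(ranks[:n1].sum())
    med_diff = float(np.median(x) - np.median(y))
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    if med_diff != 0:
        direction = "positive" if med_diff > 0 else "negative"
    else:
        direction = "positive" if w >= mean_w else "negative"
    if np.all(combined == combined[0]):
        return w, 1.0, direction
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if method == "exact" or (method == "auto" and not has_ties and n1 * n2 <= 10_000):
        if has_ties:
            logger.warning("ties present; falling back to normal approximation")
        else:
            return w, _exact_ranksum_p(w, n1, n2), direction
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0, direction
    diff = w - mean_w
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var_w)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return w, p, direction


def bonferroni(p: float, m: int) -> float:
    """min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def triplicate_consensus(
    records: Sequence[SignificanceRecord],
    alpha: float = 0.05,
    expected_replicates: int = 3,
) -> SignificanceRecord:
    """Consolidate replicate significance runs for one (TF, block).

    Counts replicates with bonferroni_p < alpha; the consolidated record
    carries the median p-values (and median per-patient tail probability),
    and is significant — reported by the pipeline — only when every
    replicate was.
    """
    if len(records) != expected_replicates:
        raise ValueError(
            f"expected {expected_replicates} replicates, got {len(records)}"
        )
    keys = {(r.tf, r.block_id) for r in records}
    if len(keys) != 1:
        raise ValueError(f"replicates mix (tf, block) pairs: {keys}")
    n_sig = sum(1 for r in records if r.bonferroni_p < alpha)
    directions = [r.direction for r in records]
    consensus_dir = max(set(directions), key=directions.count)
    patients = records[0].per_patient_p.keys()
    per_patient = {
        pid: float(median(r.per_patient_p[pid] for r in records)) for pid in patients
    }
    return SignificanceRecord(
        tf=records[0].tf,
        tf_name=records[0].tf_name,
        block_id=records[0].block_id,
        direction=consensus_dir,
        per_patient_p=per_patient,
        wilcoxon_p=float(median(r.wilcoxon_p for r in records)),
        bonferroni_p=float(median(r.bonferroni_p for r in records)),
        n_replicates_significant=n_sig,
    )
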