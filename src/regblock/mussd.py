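"""Recurrent mutation-block discovery (step 1 of the pipeline).

SNVs pooled across patients are clustered per chromosome by single linkage:
two mutations whose distance is smaller than ``max_gap`` (default 30 bp)
belong to the same block. Blocks are kept when they carry at least two SNVs
from at least two distinct patients, assigned to genes whose promoter
window (TSS +/- 1000 bp) they hit, and gated on tumor-vs-normal
differential expression of the assigned gene with a two-sample
Kolmogorov-Smirnov test. For each retained block, every carrier patient
gets a patient-specific alternative sequence: the block-spanning reference
with all of that patient's block SNVs substituted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import kolmogorov

from .core_io import ExpressionTable, InputError, SnvRecord, TssRecord, promoter_window

logger = logging.getLogger(__name__)


@dataclass
class MutationBlock:
    """A clustered genomic interval of recurrent SNVs."""

    chrom: str
    start: int  # 1-based inclusive, min member position
    end: int  # max member position
    snvs: tuple[SnvRecord, ...]
    gene_id: str | None = None
    de_pvalue: float | None = None

    @property
    def patients(self) -> tuple[str, ...]:
        return tuple(sorted({s.patient_id for s in self.snvs}))

    @property
    def block_id(self) -> str:
        gene = f":{self.gene_id}" if self.gene_id else ""
        return f"{self.chrom}:{self.start}-{self.end}{gene}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PatientBlockSequences:
    """Reference and patient-specific alternative sequence for one block."""

    block_id: str
    patient_id: str
    ref_seq: str
    alt_seq: str
    seq_start: int  # 1-based genomic position of ref_seq[0]

    def __post_init__(self):
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValueError("ref and alt sequences must have equal length")


def cluster_snvs(snvs: Iterable[SnvRecord], max_gap: int = 30) -> list[MutationBlock]:
    """Single-linkage clustering of SNVs into blocks per chromosome.

    A sorted sweep: a new block starts whenever the gap to the previous SNV
    is >= max_gap (strict ``< max_gap`` merges, so positions 100 and 129
    merge at the default but 100 and 130 do not). Same-position SNVs from
    different patients always share a block.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    by_chrom: dict[str, list[SnvRecord]] = {}
    for s in snvs:
        by_chrom.setdefault(s.chrom, []).append(s)
    blocks: list[MutationBlock] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda s: (s.pos, s.patient_id, s.alt_base))
        current: list[SnvRecord] = []
        for s in members:
            if current and s.pos - current[-1].pos >= max_gap:
                blocks.append(_make_block(chrom, current))
                current = []
            current.append(s)
        if current:
            blocks.append(_make_block(chrom, current))
    return blocks


def _make_block(chrom: str, members: list[SnvRecord]) -> MutationBlock:
    return MutationBlock(
        chrom=chrom,
        start=members[0].pos,
        end=members[-1].pos,
        snvs=tuple(members),
    )


def filter_recurrent(blocks: Iterable[MutationBlock]) -> list[MutationBlock]:
    """Keep blocks with >= 2 SNVs from >= 2 distinct patients."""
    return [b for b in blocks if len(b.snvs) >= 2 and len(b.patients) >= 2]


def assign_to_promoters(
    blocks: Iterable[MutationBlock],
    tss_records: Sequence[TssRecord],
    half_width: int = 1000,
) -> list[MutationBlock]:
    """Assign blocks to genes via promoter-window overlap of member SNVs.

    A block overlapping promoter windows of several genes is duplicated,
    once per gene; blocks hitting no promoter are dropped.
    """
    windows: dict[str, list[tuple[int, int, str]]] = {}
    for t in tss_records:
        lo, hi = promoter_window(t, half_width)
        windows.setdefault(t.chrom, []).append((lo, hi, t.gene_id))
    out: list[MutationBlock] = []
    for b in blocks:
        hit_genes: dict[str, None] = {}
        for lo, hi, gene in windows.get(b.chrom, ()):
            if any(lo <= s.pos <= hi for s in b.snvs):
                hit_genes[gene] = None
        for gene in sorted(hit_genes):
            out.append(replace(b, gene_id=gene))
    return out


# ---------------------------------------------------------------------------
# KS differential-expression gate

def ks_2sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic two-sided p-value.

    D is the sup of |ECDF_x - ECDF_y|; the p-value uses the Kolmogorov
    limiting distribution with the standard small-sample effective-n
    correction ``(sqrt(en) + 0.12 + 0.11/sqrt(en)) * D``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n
    cdf_y = np.searchsorted(y, pooled, side="right") / m
    d = float(np.abs(cdf_x - cdf_y).max())
    if d == 0.0:
        return 0.0, 1.0
    sqrt_en = math.sqrt(n * m / (n + m))
    lam = (sqrt_en + 0.12 + 0.11 / sqrt_en) * d
    p = float(min(1.0, max(0.0, kolmogorov(lam))))
    return d, p


def ks_gate(
    block: MutationBlock, expr: ExpressionTable, alpha: float = 0.05
) -> tuple[float, bool]:
    """Differential-expression gate for the block's assigned gene.

    Returns (p-value, keep); keep iff p < alpha for the tumor-vs-normal KS
    comparison of the gene's RPKM values.
    """
    if block.gene_id is None:
        raise ValueError(f"block {block.block_id} has no assigned gene")
    if not expr.has_gene(block.gene_id):
        raise InputError(f"gene {block.gene_id!r} absent from expression table")
    tumor = expr.gene_values(block.gene_id, "tumor")
    normal = expr.gene_values(block.gene_id, "normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise InputError(
            f"gene {block.gene_id}: need >=2 tumor and >=2 normal samples"
        )
    _, p = ks_2sample(tumor, normal)
    return p, p < alpha


def apply_ks_gate(
    blocks: Iterable[MutationBlock], expr: ExpressionTable, alpha: float = 0.05
) -> list[MutationBlock]:
    """Annotate blocks with de_pvalue and keep those passing the gate."""
    kept = []
    for b in blocks:
        p, keep = ks_gate(b, expr, alpha)
        if keep:
            kept.append(replace(b, de_pvalue=p))
    return kept


# ---------------------------------------------------------------------------
# Sequence construction

def _fetch(genome, chrom: str, start: int, end: int) -> tuple[str, int]:
    """Fetch genome[start..end] 1-based inclusive, clipped to the chromosome."""
    chrom_len = len(genome[chrom])
    start = max(1, start)
    end = min(end, chrom_len)
    seq = str(genome[chrom][start - 1 : end]).upper()
    return seq, start


def build_patient_sequences(
    block: MutationBlock, genome, flank: int = 30
) -> list[PatientBlockSequences]:
    """Patient-specific alternative sequences spanning the block +/- flank.

    One record per patient carrying >= 1 SNV in the block; the alternative
    sequence substitutes all of that patient's block SNVs at once.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    ref_seq, seq_start = _fetch(genome, block.chrom, block.start - flank, block.end + flank)
    for s in block.snvs:
        got = ref_seq[s.pos - seq_start]
        if got != s.ref_base:
            raise InputError(
                f"block {block.block_id}: genome base {got} at {block.chrom}:{s.pos} "
                f"does not match SNV ref {s.ref_base}"
            )
    out = []
    by_patient: dict[str, list[SnvRecord]] = {}
    for s in block.snvs:
        by_patient.setdefault(s.patient_id, []).append(s)
    for patient_id in sorted(by_patient):
        alt = list(ref_seq)
        for s in by_patient[patient_id]:
            alt[s.pos - seq_start] = s.alt_base
        out.append(
            PatientBlockSequences(
                block_id=block.block_id,
                patient_id=patient_id,
                ref_seq=ref_seq,
                alt_seq="".join(alt),
                seq_start=seq_start,
            )
        )
    return out


def snv_window_sequences(
    snv: SnvRecord, genome, half: int = 30
) -> tuple[str, str]:
    """(ref, alt) sequences of the window snv.pos +/- half (61 bp default).

    Windows running off a chromosome end are clipped with a warning; the
    mutated base stays at offset ``snv.pos - window_start``.
    """
    chrom_len = len(genome[snv.chrom])
    lo, hi = snv.pos - half, snv.pos + half
    if lo < 1 or hi > chrom_len:
        logger.warning(
            "SNV %s:%d window clipped to chromosome bounds", snv.chrom, snv.pos
        )
    ref_seq, seq_start = _fetch(genome, snv.chrom, lo, hi)
    offset = snv.pos - seq_start
    if ref_seq[offset] != snv.ref_base:
        raise InputError(
            f"genome base {ref_seq[offset]} at {snv.chrom}:{snv.pos} does not "
            f"match SNV ref {snv.ref_base}"
        )
    alt_seq = ref_seq[:offset] + snv.alt_base + ref_seq[offset + 1 :]
    return ref_seq, alt_seq
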