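"""Post-hoc annotation: TF expression filtering and SHM hotspot enrichment.

A TF whose gene is essentially unexpressed in the tumor samples (median
RPKM below 0.03, the conventional noise floor) cannot mediate a regulatory
effect, so it is dropped from rankings and significance outputs. Surviving
TFs get a quartile category: "+" top 25% of TF median RPKMs, "-" bottom
25%, "•" in between.

The SHM (somatic hypermutation) test asks whether a block's mutations fall
inside AID hotspot motifs (DGYW and its reverse complement WRCH) more often
than chance, via an exact two-sided binomial test against the fraction of
block positions covered by hotspot motifs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binomtest

from .core_io import ExpressionTable

logger = logging.getLogger(__name__)

DEFAULT_RPKM_THRESHOLD = 0.03

# IUPAC: D={A,G,T} Y={C,T} W={A,T} R={A,G} H={A,C,T}
_DGYW = re.compile(r"(?=[AGT]G[CT][AT])")
_WRCH = re.compile(r"(?=[AT][AG]C[ACT])")


@dataclass
class TfExpressionAnnotation:
    tf_name: str
    median_rpkm: float
    category: str  # {"+", "•", "-", "filtered"}


def _component_median(symbol: str, expr: ExpressionTable) -> float | None:
    """Median tumor RPKM for one gene symbol (case-insensitive)."""
    if not expr.has_gene(symbol):
        return None
    return float(np.median(expr.gene_values(symbol, "tumor")))


def filter_tfs_by_expression(
    tf_names: Sequence[str],
    expr: ExpressionTable,
    threshold: float = DEFAULT_RPKM_THRESHOLD,
    aliases: Mapping[str, str] | None = None,
) -> list[TfExpressionAnnotation]:
    """Annotate TFs with tumor median RPKM and quartile category.

    Heterodimer names ("AHR::ARNT") use the minimum of the components'
    medians. TFs without an expression row are annotated "filtered" with a
    warning; quartiles are computed over the surviving TFs only.
    """
    if expr.values.shape[0] == 0:
        raise ValueError("empty expression table")
    aliases = {k.lower(): v for k, v in (aliases or {}).items()}
    medians: dict[str, float | None] = {}
    for name in tf_names:
        parts = [aliases.get(p.lower(), p) for p in name.split("::")]
        vals = [_component_median(p, expr) for p in parts]
        if any(v is None for v in vals):
            logger.warning("TF %s not found in expression table; filtered", name)
            medians[name] = None
        else:
            medians[name] = min(vals)
    surviving = {
        n: m for n, m in medians.items() if m is not None and m >= threshold
    }
    if surviving:
        vals = np.array(list(surviving.values()))
        hi = np.percentile(vals, 75)
        lo = np.percentile(vals, 25)
    out = []
    for name in tf_names:
        m = medians[name]
        if m is None or m < threshold:
            out.append(TfExpressionAnnotation(name, float("nan") if m is None else m, "filtered"))
        elif m >= hi:
            out.append(TfExpressionAnnotation(name, m, "+"))
        elif m <= lo:
            out.append(TfExpressionAnnotation(name, m, "-"))
        else:
            out.append(TfExpressionAnnotation(name, m, "•"))
    return out


# ---------------------------------------------------------------------------
# SHM hotspot motifs

@dataclass
class ShmTestResult:
    block_id: str
    n_mutations: int
    n_in_hotspot: int
    p0: float
    binom_p: float


def find_hotspot_positions(sequence: str) -> set[int]:
    """0-based positions covered by any DGYW or WRCH occurrence.

    WRCH is the reverse complement of DGYW, so scanning both patterns on
    the forward strand covers both strands.
    """
    seq = sequence.upper()
    covered: set[int] = set()
    for pat in (_DGYW, _WRCH):
        for m in pat.finditer(seq):
            covered.update(range(m.start(), m.start() + 4))
    return covered


def shm_enrichment_test(
    block_seq: str, mutation_offsets: Sequence[int], block_id: str = "?"
) -> ShmTestResult:
    """Two-sided exact binomial test of mutation enrichment in SHM hotspots.

    Null rate p0 = fraction of block positions covered by hotspot motifs in
    the reference block sequence.
    """
    if len(mutation_offsets) < 1:
        raise ValueError("need at least one mutation offset")
    hotspots = find_hotspot_positions(block_seq)
    n = len(mutation_offsets)
    k = sum(1 for off in mutation_offsets if off in hotspots)
    p0 = len(hotspots) / len(block_seq)
    if p0 <= 0.0 or p0 >= 1.0:
        logger.warning("block %s: degenerate hotspot rate p0=%g; p set to 1", block_id, p0)
        return ShmTestResult(block_id, n, k, p0, 1.0)
    p = float(binomtest(k, n, p0).pvalue)
    return ShmTestResult(block_id, n, k, p0, p)
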