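"""Null-calibration utilities: empirical type-I error of the pipeline's
statistical gates when no signal is present.

These run the real machinery — background-block generation, the occupancy
model and the rank-sum test — on null "patient" blocks that are themselves
drawn from the background generator, so the measured rejection rates
reflect the pipeline as deployed, not an idealized statistic.
"""

from __future__ import annotations

import numpy as np

from .affinity import AffinityParams, EnergyMatrix, delta_dba_many, encode
from .mussd import ks_2sample
from .significance import generate_background_blocks, wilcoxon_block_test


def wilcoxon_null_pvalues(
    universe,
    genome,
    ems: list[EnergyMatrix],
    params: AffinityParams,
    n_blocks: int = 50,
    n_patients: int = 5,
    n_background: int = 200,
    block_length: int = 160,
    n_mutations: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Wilcoxon p-values for null (TF, block) pairs.

    For each simulated block, the "patient" ddbA values are drawn from the
    same background generator as the reference distribution, so every
    p-value is a draw under the null; returns n_blocks * len(ems) values.
    """
    rng = np.random.default_rng(seed)
    pvals = []
    for b in range(n_blocks):
        pat = generate_background_blocks(
            universe, block_length, n_mutations, excluded_gene=None,
            count=n_patients, seed=int(rng.integers(2**31)), genome=genome,
        )
        bg = generate_background_blocks(
            universe, block_length, n_mutations, excluded_gene=None,
            count=n_background, seed=int(rng.integers(2**31)), genome=genome,
        )
        pat_ref = np.stack([encode(x.ref_seq) for x in pat.blocks])
        pat_alt = np.stack([encode(x.alt_seq) for x in pat.blocks])
        bg_ref = np.stack([encode(x.ref_seq) for x in bg.blocks])
        bg_alt = np.stack([encode(x.alt_seq) for x in bg.blocks])
        for em in ems:
            pat_d = delta_dba_many(pat_ref, pat_alt, em, params)
            bg_d = delta_dba_many(bg_ref, bg_alt, em, params)
            _, p, _ = wilcoxon_block_test(pat_d, bg_d)
            pvals.append(p)
    return np.array(pvals)


def ks_gate_null_rate(
    n_tumor: int = 12,
    n_normal: int = 4,
    n_genes: int = 2000,
    alpha: float = 0.05,
    sigma: float = 0.5,
    seed: int = 0,
) -> float:
    """Fraction of null genes (no expression shift) passing the KS gate."""
    rng = np.random.default_rng(seed)
    kept = 0
    for _ in range(n_genes):
        tumor = rng.lognormal(0.0, sigma, n_tumor)
        normal = rng.lognormal(0.0, sigma, n_normal)
        _, p = ks_2sample(tumor, normal)
        kept += p < alpha
    return kept / n_genes
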