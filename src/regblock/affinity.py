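"""Biophysical PWM-occupancy scoring of TF binding affinity changes.

The model: a PWM is converted to a mismatch energy matrix (consensus base =
0 energy per position, in ln-probability units). A candidate site of length
L at window ``w`` has energy ``E(w) = sum_i energies[i, base_{w+i}]`` and is
occupied with Fermi-Dirac probability ``1 / (1 + exp(beta*(E - mu)))`` at
chemical potential ``mu`` (TF concentration proxy) and inverse temperature
``beta`` (fixed at 1). The sequence-level binding affinity is

    dbA(s) = ln( sum over all windows on both strands of occupancy )

and the differential binding affinity of a mutated sequence is

    ddbA = mean over a mu grid of [ dbA(alt) - dbA(ref) ]

positive when the mutation gains binding, negative when it disrupts a site.
Per TF, raw ddbA values are z-scored across all scored units so that
magnitudes are comparable between TFs with different motif information
content.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

from .core_io import BASES, Pwm

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

DEFAULT_MU_GRID = (-2.0, 0.0, 2.0, 4.0)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


@dataclass(frozen=True)
class AffinityParams:
    """Occupancy-model parameters: mu grid, beta, strand handling."""

    mu_grid: tuple[float, ...] = DEFAULT_MU_GRID
    beta: float = 1.0
    both_strands: bool = True

    def __post_init__(self):
        if len(self.mu_grid) == 0:
            raise ValueError("mu_grid must be non-empty")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class EnergyMatrix:
    """Per-position binding energies; consensus base has energy 0."""

    tf_name: str
    pwm_id: str
    energies: np.ndarray  # (L, 4), >= 0, row minima 0

    def __len__(self) -> int:
        return self.energies.shape[0]

    @property
    def reverse_complement_energies(self) -> np.ndarray:
        # scanning the forward strand with this matrix == scanning the
        # reverse complement with the original
        return self.energies[::-1, ::-1]


@dataclass
class DeltaDbaResult:
    """ddbA for one (TF, scored unit); normalized across units per TF."""

    tf: str  # pwm_id
    tf_name: str
    unit_id: str
    patient_id: str
    ddba_raw: float
    ddba_norm: float | None = None
    p_direct: float | None = None


def pwm_to_energy(pwm: Pwm) -> EnergyMatrix:
    """Convert probability PWM to mismatch energies.

    ``energies[i][b] = ln(max_b' p[i][b']) - ln(p[i][b])``; the consensus
    base at each position has energy 0.
    """
    probs = pwm.probs
    if np.any(probs <= 0):
        raise ValueError(f"PWM {pwm.pwm_id} has zero probabilities; regularize first")
    logs = np.log(probs)
    energies = logs.max(axis=1, keepdims=True) - logs
    return EnergyMatrix(tf_name=pwm.tf_name, pwm_id=pwm.pwm_id, energies=energies)


def site_occupancy(seq_window: str, em: EnergyMatrix, mu: float, beta: float = 1.0) -> float:
    """Fermi-Dirac occupancy of a single L-mer site."""
    codes = encode(seq_window)
    if codes.shape[0] != len(em):
        raise ValueError("window length must equal motif length")
    if (codes > 3).any():
        raise ValueError("window contains non-ACGT characters")
    energy = em.energies[np.arange(len(em)), codes].sum()
    return float(1.0 / (1.0 + math.exp(min(700.0, beta * (energy - mu)))))


def _window_energies(codes: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Sum of per-position energies for every window along the last axis.

    Windows containing a non-ACGT code get +inf (zero occupancy, i.e.
    skipped). ``codes``: (..., N) int8; returns (..., N-L+1).
    """
    L = energies.shape[0]
    padded = np.hstack([energies, np.full((L, 1), np.inf)])
    wins = sliding_window_view(codes, L, axis=-1)
    return padded[np.arange(L), wins].sum(axis=-1)


def _log_occ_sum(all_energies: np.ndarray, mu: float, beta: float) -> np.ndarray:
    """ln sum of occupancies over the window axis (last)."""
    with np.errstate(invalid="ignore"):
        log_occ = -np.logaddexp(0.0, beta * (all_energies - mu))
    return logsumexp(log_occ, axis=-1)


def dba_profile(codes: np.ndarray, em: EnergyMatrix, params: AffinityParams) -> np.ndarray:
    """dbA at every mu in the grid for one or many equal-length sequences.

    ``codes``: (N,) or (n_seq, N) int8. Returns (n_mu,) or (n_seq, n_mu).
    """
    L = len(em)
    if codes.shape[-1] < L:
        raise ValueError(
            f"sequence of length {codes.shape[-1]} shorter than motif "
            f"{em.pwm_id} (L={L})"
        )
    e_fwd = _window_energies(codes, em.energies)
    if params.both_strands:
        e_rev = _window_energies(codes, em.reverse_complement_energies)
        all_e = np.concatenate([e_fwd, e_rev], axis=-1)
    else:
        all_e = e_fwd
    cols = [_log_occ_sum(all_e, mu, params.beta) for mu in params.mu_grid]
    return np.stack(cols, axis=-1)


def dba(sequence: str, em: EnergyMatrix, params: AffinityParams, mu: float) -> float:
    """ln total occupancy over all windows (both strands) at one mu."""
    one_mu = AffinityParams(mu_grid=(mu,), beta=params.beta, both_strands=params.both_strands)
    return float(dba_profile(encode(sequence), em, one_mu)[0])


def delta_dba(ref_seq: str, alt_seq: str, em: EnergyMatrix, params: AffinityParams) -> float:
    """Mean over the mu grid of dbA(alt) - dbA(ref); 0 for identical pair."""
    if len(ref_seq) != len(alt_seq):
        raise ValueError("ref and alt sequences must have equal length")
    if ref_seq == alt_seq:
        return 0.0
    prof_ref = dba_profile(encode(ref_seq), em, params)
    prof_alt = dba_profile(encode(alt_seq), em, params)
    return float((prof_alt - prof_ref).mean())


def delta_dba_many(
    ref_codes: np.ndarray, alt_codes: np.ndarray, em: EnergyMatrix, params: AffinityParams
) -> np.ndarray:
    """Vectorized ddbA for stacks of equal-length (ref, alt) pairs."""
    if ref_codes.shape != alt_codes.shape:
        raise ValueError("ref and alt stacks must have identical shape")
    prof_ref = dba_profile(ref_codes, em, params)
    prof_alt = dba_profile(alt_codes, em, params)
    out = (prof_alt - prof_ref).mean(axis=-1)
    identical = (ref_codes == alt_codes).all(axis=-1)
    return np.where(identical, 0.0, out)


def normalize_deltas(results: Sequence[DeltaDbaResult]) -> list[DeltaDbaResult]:
    """z-score ddba_raw across all units of one TF (population sd).

    A single unit, or zero spread, yields ddba_norm = 0 for all.
    """
    raws = np.array([r.ddba_raw for r in results], dtype=float)
    if len(raws) < 2:
        if len(raws) == 1:
            logger.warning(
                "TF %s: only one scored unit; ddba_norm set to 0", results[0].tf
            )
        return [replace(r, ddba_norm=0.0) for r in results]
    mean = raws.mean()
    sd = raws.std()  # population sd for determinism at n=2
    if sd == 0:
        norm = np.zeros_like(raws)
    else:
        norm = (raws - mean) / sd
    return [replace(r, ddba_norm=float(z)) for r, z in zip(results, norm)]


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Altschul-Erickson) and the direct-binding
# p-value

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random sequence with the same dinucleotide (edge) multiset as seq.

    Uniform over Eulerian paths via the arborescence method: pick a random
    last-exit edge per vertex, accept when the last edges form paths into
    the terminal vertex, shuffle the rest, then walk.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(edges)
    non_terminal = [v for v in vertices if v != last]
    for _attempt in range(1000):
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in non_terminal}
        # every non-terminal vertex must reach `last` through last-edges
        ok = True
        for v in non_terminal:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - arborescence sampling virtually always succeeds
        return seq
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_edge[v])
        rest = [rest[i] for i in rng.permutation(len(rest))]
        if v != last:
            rest.append(last_edge[v])
        shuffled[v] = rest
    out = [first]
    cur = first
    counters = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def direct_binding_pvalue(
    ref_seq: str,
    em: EnergyMatrix,
    params: AffinityParams,
    n_background: int = 100,
    seed: int = 0,
    early_stop: bool = True,
) -> float:
    """Empirical p that a dinucleotide shuffle binds as strongly as ref_seq.

    p = (1 + #{background dbA >= observed}) / (1 + n_generated), where the
    per-sequence score is the mean dbA over the mu grid. With early_stop,
    generation halts once ceil(0.2 * n_background) shuffles have exceeded
    the observed score — p is then already guaranteed above the 0.1 ranking
    cutoff.
    """
    if n_background < 20:
        raise ValueError("n_background must be >= 20")
    rng = np.random.default_rng(seed)
    observed = float(dba_profile(encode(ref_seq), em, params).mean())
    stop_at = math.ceil(0.2 * n_background)
    n_exceed = 0
    n_generated = 0
    chunk = 25
    while n_generated < n_background:
        size = min(chunk, n_background - n_generated)
        codes = np.stack(
            [encode(dinucleotide_shuffle(ref_seq, rng)) for _ in range(size)]
        )
        scores = dba_profile(codes, em, params).mean(axis=-1)
        n_exceed += int((scores >= observed).sum())
        n_generated += size
        if early_stop and n_exceed >= stop_at:
            break
    return (1 + n_exceed) / (1 + n_generated)


# ---------------------------------------------------------------------------
# Ranking

def rank_tfs(
    results: Sequence[DeltaDbaResult],
    k: int = 15,
    p_direct_cutoff: float = 0.1,
    magnitude_percentile: float = 80.0,
) -> tuple[list[DeltaDbaResult], list[DeltaDbaResult]]:
    """Rank the TFs affected at one scored unit.

    Keeps TFs with direct-binding p below ``p_direct_cutoff`` whose
    |ddba_norm| reaches the ``magnitude_percentile`` of the surviving set,
    splits by sign, sorts by decreasing magnitude (pwm_id breaks ties) and
    truncates each direction to ``k``.
    """
    passing = [
        r
        for r in results
        if r.p_direct is not None
        and r.p_direct < p_direct_cutoff
        and r.ddba_norm is not None
    ]
    if not passing:
        return [], []
    mags = np.array([abs(r.ddba_norm) for r in passing])
    threshold = np.percentile(mags, magnitude_percentile)
    strong = [r for r in passing if abs(r.ddba_norm) >= threshold]
    key = lambda r: (-abs(r.ddba_norm), r.tf)
    positive = sorted((r for r in strong if r.ddba_norm > 0), key=key)[:k]
    negative = sorted((r for r in strong if r.ddba_norm < 0), key=key)[:k]
    return positive, negative
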