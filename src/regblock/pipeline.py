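"""End-to-end orchestration of the two-step analysis.

Step 1 (block discovery): promoter SNVs are clustered into recurrent
mutation blocks, assigned to genes and gated on differential expression.
Step 2 (affinity statistics): per patient-block sequence, the differential
binding affinity (ddbA) of every PWM is computed, z-scored per TF,
filtered by direct-binding plausibility and magnitude, and the surviving
TFs are tested against randomly generated background mutation blocks with
a Bonferroni-corrected Wilcoxon rank-sum test, in triplicate.

All randomness derives from the run seed; serial and parallel execution
produce identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .affinity import (
    AffinityParams,
    DEFAULT_MU_GRID,
    DeltaDbaResult,
    EnergyMatrix,
    delta_dba_many,
    direct_binding_pvalue,
    encode,
    normalize_deltas,
    pwm_to_energy,
    rank_tfs,
)
from .annotate import (
    DEFAULT_RPKM_THRESHOLD,
    filter_tfs_by_expression,
    shm_enrichment_test,
)
from .core_io import (
    ExpressionTable,
    Pwm,
    SnvRecord,
    TssRecord,
    open_genome,
    promoter_window,
    read_expression_table,
    read_pwms,
    read_snvs,
    read_tss_table,
    write_bed,
)
from .mussd import (
    MutationBlock,
    PatientBlockSequences,
    apply_ks_gate,
    assign_to_promoters,
    build_patient_sequences,
    cluster_snvs,
    filter_recurrent,
    snv_window_sequences,
)
from .significance import (
    SignificanceRecord,
    bonferroni,
    generate_background_blocks,
    per_patient_tail_probability,
    triplicate_consensus,
    upstream_universe,
    wilcoxon_block_test,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters; numeric defaults are the published settings."""

    genome_fasta: str = ""
    tss_table: str = ""
    pwm_file: str = ""
    vcf_paths: dict[str, str] = field(default_factory=dict)
    expression_table: str | None = None
    sample_groups: dict[str, str] = field(default_factory=dict)

    promoter_half_width: int = 1000
    max_gap: int = 30
    ks_alpha: float = 0.05
    rpkm_threshold: float = DEFAULT_RPKM_THRESHOLD
    p_direct_cutoff: float = 0.1
    magnitude_percentile: float = 80.0
    top_k: int = 15
    mu_grid: tuple[float, ...] = DEFAULT_MU_GRID
    beta: float = 1.0
    block_flank: int = 30
    snv_half_window: int = 30
    n_background: int | None = None  # None = one per eligible promoter region
    n_direct_shuffles: int = 100
    replicates: int = 3
    significance_alpha: float = 0.05
    expression_filter: bool = True
    exact_background: bool = False  # disable early stopping
    seed: int = 0
    threads: int = 1

    def affinity_params(self) -> AffinityParams:
        return AffinityParams(mu_grid=tuple(self.mu_grid), beta=self.beta)


def _derived_seed(*parts) -> int:
    """Stable sub-2^31 seed from arbitrary string/int parts."""
    key = "|".join(str(p) for p in parts).encode()
    return zlib.crc32(key) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Step 1

def discover_blocks(
    snvs: Sequence[SnvRecord],
    tss_records: Sequence[TssRecord],
    expr: ExpressionTable | None,
    config: RunConfig,
) -> list[MutationBlock]:
    """MuSSD: promoter restriction -> cluster -> recurrence -> assignment -> KS gate."""
    promoter_snvs = restrict_to_promoters(snvs, tss_records, config.promoter_half_width)
    logger.info("%d of %d SNVs fall in promoter windows", len(promoter_snvs), len(snvs))
    blocks = cluster_snvs(promoter_snvs, config.max_gap)
    blocks = filter_recurrent(blocks)
    blocks = assign_to_promoters(blocks, tss_records, config.promoter_half_width)
    if expr is not None:
        blocks = apply_ks_gate(blocks, expr, config.ks_alpha)
    return blocks


def restrict_to_promoters(
    snvs: Sequence[SnvRecord], tss_records: Sequence[TssRecord], half_width: int
) -> list[SnvRecord]:
    windows: dict[str, list[tuple[int, int]]] = {}
    for t in tss_records:
        windows.setdefault(t.chrom, []).append(promoter_window(t, half_width))
    out = []
    for s in snvs:
        if any(lo <= s.pos <= hi for lo, hi in windows.get(s.chrom, ())):
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Step 2

@dataclass
class BlockScoring:
    """Scored units of one block: patient ddbA per PWM, plus p_direct."""

    block: MutationBlock
    sequences: list[PatientBlockSequences]
    results: dict[str, list[DeltaDbaResult]]  # pwm_id -> per-patient results
    p_direct: dict[str, float]  # pwm_id -> block-level direct-binding p
    n_bg_mutations: int = 0
    bg_deltas: dict[str, np.ndarray] = field(default_factory=dict)  # replicate-0 backgrounds


def score_block(
    block: MutationBlock,
    genome,
    ems: Sequence[EnergyMatrix],
    config: RunConfig,
) -> BlockScoring:
    """Patient-specific ddbA for every PWM, plus the block-level p_direct."""
    params = config.affinity_params()
    seqs = build_patient_sequences(block, genome, config.block_flank)
    ref_codes = np.stack([encode(s.ref_seq) for s in seqs])
    alt_codes = np.stack([encode(s.alt_seq) for s in seqs])
    results: dict[str, list[DeltaDbaResult]] = {}
    p_direct: dict[str, float] = {}
    for em in ems:
        deltas = delta_dba_many(ref_codes, alt_codes, em, params)
        results[em.pwm_id] = [
            DeltaDbaResult(
                tf=em.pwm_id,
                tf_name=em.tf_name,
                unit_id=f"{block.block_id}|{s.patient_id}",
                patient_id=s.patient_id,
                ddba_raw=float(d),
            )
            for s, d in zip(seqs, deltas)
        ]
        p_direct[em.pwm_id] = direct_binding_pvalue(
            seqs[0].ref_seq,
            em,
            params,
            n_background=config.n_direct_shuffles,
            seed=_derived_seed(config.seed, "pdirect", block.block_id, em.pwm_id),
            early_stop=not config.exact_background,
        )
    return BlockScoring(block=block, sequences=seqs, results=results, p_direct=p_direct)


def score_backgrounds(
    scoring: BlockScoring,
    ems: Sequence[EnergyMatrix],
    universe,
    genome,
    config: RunConfig,
    n_background: int,
    replicate: int,
) -> dict[str, np.ndarray]:
    """Background ddbA per PWM for one block and replicate."""
    params = config.affinity_params()
    block = scoring.block
    seq_len = len(scoring.sequences[0].ref_seq)
    bg_seed = _derived_seed(config.seed, "background", block.block_id, replicate)
    bg = generate_background_blocks(
        universe,
        block_length=seq_len,
        n_mutations=scoring.n_bg_mutations,
        excluded_gene=block.gene_id,
        count=n_background,
        seed=bg_seed,
        genome=genome,
    )
    bg_ref = np.stack([encode(b.ref_seq) for b in bg.blocks])
    bg_alt = np.stack([encode(b.alt_seq) for b in bg.blocks])
    return {em.pwm_id: delta_dba_many(bg_ref, bg_alt, em, params) for em in ems}


def normalize_scorings(scorings: Sequence[BlockScoring]) -> None:
    """z-score ddbA per TF over all units plus backgrounds, attach p_direct.

    The reference distribution per TF pools every patient unit of the run
    with the replicate-0 background blocks of every block, so the mean sits
    near zero (backgrounds dominate) and a recurrent effect shared by all
    patients keeps its sign and magnitude after normalization.
    """
    pwm_ids = sorted({pid for sc in scorings for pid in sc.results})
    for pid in pwm_ids:
        pooled: list[tuple[BlockScoring, int]] = []
        flat: list[DeltaDbaResult] = []
        for sc in scorings:
            for i, r in enumerate(sc.results.get(pid, ())):
                pooled.append((sc, i))
                flat.append(r)
        bg_values = np.concatenate(
            [sc.bg_deltas[pid] for sc in scorings if pid in sc.bg_deltas]
            or [np.array([])]
        )
        if len(bg_values):
            raws = np.array([r.ddba_raw for r in flat])
            pool = np.concatenate([raws, bg_values])
            sd = pool.std()
            mean = pool.mean()
            for (sc, i), r in zip(pooled, flat):
                z = 0.0 if sd == 0 else (r.ddba_raw - mean) / sd
                r.ddba_norm = float(z)
                r.p_direct = sc.p_direct[pid]
                sc.results[pid][i] = r
        else:
            for (sc, i), r in zip(pooled, normalize_deltas(flat)):
                r.p_direct = sc.p_direct[pid]
                sc.results[pid][i] = r


def rank_block_units(
    scoring: BlockScoring, config: RunConfig
) -> pd.DataFrame:
    """Per-unit TF rankings (both directions) as a tidy table."""
    rows = []
    for idx, seq in enumerate(scoring.sequences):
        unit_id = f"{scoring.block.block_id}|{seq.patient_id}"
        unit_results = [scoring.results[pid][idx] for pid in sorted(scoring.results)]
        pos, neg = rank_tfs(
            unit_results,
            k=config.top_k,
            p_direct_cutoff=config.p_direct_cutoff,
            magnitude_percentile=config.magnitude_percentile,
        )
        for direction, ranked in (("positive", pos), ("negative", neg)):
            for rank, r in enumerate(ranked, start=1):
                rows.append(
                    {
                        "unit_id": unit_id,
                        "tf_name": r.tf_name,
                        "pwm_id": r.tf,
                        "direction": direction,
                        "ddba_raw": r.ddba_raw,
                        "ddba_norm": r.ddba_norm,
                        "p_direct": r.p_direct,
                        "rank": rank,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "tf_name", "pwm_id", "direction",
            "ddba_raw", "ddba_norm", "p_direct", "rank",
        ],
    )


def candidate_pwms(ranking: pd.DataFrame) -> list[str]:
    """PWMs appearing in any unit's ranked lists for the block."""
    return sorted(ranking["pwm_id"].unique()) if len(ranking) else []


def test_block_significance(
    scoring: BlockScoring,
    candidates: Sequence[str],
    ems_by_id: Mapping[str, EnergyMatrix],
    universe,
    genome,
    m_hypotheses: int,
    config: RunConfig,
    n_background: int,
) -> list[SignificanceRecord]:
    """Triplicate background-resampling Wilcoxon test for one block."""
    if not candidates:
        return []
    block = scoring.block
    replicate_records: dict[str, list[SignificanceRecord]] = {pid: [] for pid in candidates}
    candidate_ems = [ems_by_id[pid] for pid in candidates]
    for rep in range(config.replicates):
        if rep == 0 and scoring.bg_deltas:
            rep_deltas = scoring.bg_deltas
        else:
            rep_deltas = score_backgrounds(
                scoring, candidate_ems, universe, genome, config, n_background, rep
            )
        for pid in candidates:
            em = ems_by_id[pid]
            bg_deltas = rep_deltas[pid]
            patient_deltas = [r.ddba_raw for r in scoring.results[pid]]
            stat, p, direction = wilcoxon_block_test(patient_deltas, bg_deltas)
            per_patient = {
                r.patient_id: per_patient_tail_probability(r.ddba_raw, bg_deltas, direction)
                for r in scoring.results[pid]
            }
            replicate_records[pid].append(
                SignificanceRecord(
                    tf=pid,
                    tf_name=em.tf_name,
                    block_id=block.block_id,
                    direction=direction,
                    per_patient_p=per_patient,
                    wilcoxon_p=p,
                    bonferroni_p=bonferroni(p, m_hypotheses),
                )
            )
    return [
        triplicate_consensus(
            replicate_records[pid],
            alpha=config.significance_alpha,
            expected_replicates=config.replicates,
        )
        for pid in candidates
    ]


# ---------------------------------------------------------------------------
# Whole-run driver

def load_inputs(config: RunConfig):
    genome = open_genome(config.genome_fasta)
    tss_records = read_tss_table(config.tss_table)
    pwms = read_pwms(config.pwm_file)
    snvs = read_snvs(config.vcf_paths)
    expr = None
    if config.expression_table:
        expr = read_expression_table(config.expression_table, config.sample_groups)
    return genome, tss_records, pwms, snvs, expr


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline and write all stage tables under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, tss_records, pwms, snvs, expr = load_inputs(config)

    # TF expression filter
    annotations = None
    if expr is not None and config.expression_filter:
        annotations = filter_tfs_by_expression(
            [p.tf_name for p in pwms], expr, config.rpkm_threshold
        )
        category = {a.tf_name: a.category for a in annotations}
        pwms = [p for p in pwms if category[p.tf_name] != "filtered"]
        pd.DataFrame(
            [
                {"tf_name": a.tf_name, "median_rpkm": a.median_rpkm, "category": a.category}
                for a in annotations
            ]
        ).to_csv(outdir / "tf_expression.tsv", sep="\t", index=False)
    else:
        pd.DataFrame(
            [{"tf_name": p.tf_name, "median_rpkm": float("nan"), "category": "•"} for p in pwms]
        ).to_csv(outdir / "tf_expression.tsv", sep="\t", index=False)

    # Step 1
    blocks = discover_blocks(snvs, tss_records, expr, config)
    block_table = pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "chrom": b.chrom,
                "start": b.start,
                "end": b.end,
                "n_snvs": len(b.snvs),
                "n_patients": len(b.patients),
                "gene_id": b.gene_id,
                "de_pvalue": b.de_pvalue,
            }
            for b in blocks
        ],
        columns=["block_id", "chrom", "start", "end", "n_snvs", "n_patients", "gene_id", "de_pvalue"],
    )
    block_table.to_csv(outdir / "blocks.tsv", sep="\t", index=False)
    write_bed([(b.chrom, b.start, b.end, b.block_id) for b in blocks], outdir / "blocks.bed")

    ems = [pwm_to_energy(p) for p in pwms]
    ems_by_id = {em.pwm_id: em for em in ems}
    m_hypotheses = max(1, len(pwms))
    universe = upstream_universe(tss_records, genome, width=1000)
    n_background = config.n_background
    if n_background is None:
        n_background = max(20, len(universe) - 1)

    def _process(block: MutationBlock) -> BlockScoring:
        scoring = score_block(block, genome, ems, config)
        per_patient_counts = [
            sum(1 for a, b in zip(s.ref_seq, s.alt_seq) if a != b)
            for s in scoring.sequences
        ]
        scoring.n_bg_mutations = max(1, round(float(np.mean(per_patient_counts))))
        scoring.bg_deltas = score_backgrounds(
            scoring, ems, universe, genome, config, n_background, replicate=0
        )
        return scoring

    if config.threads > 1:
        from joblib import Parallel, delayed

        scorings = Parallel(n_jobs=config.threads)(delayed(_process)(b) for b in blocks)
    else:
        scorings = [_process(b) for b in blocks]
    normalize_scorings(scorings)

    rankings = []
    sig_records: list[SignificanceRecord] = []
    shm_rows = []
    for scoring in scorings:
        ranking = rank_block_units(scoring, config)
        rankings.append(ranking)
        cands = candidate_pwms(ranking)
        sig_records.extend(
            test_block_significance(
                scoring, cands, ems_by_id, universe, genome,
                m_hypotheses, config, n_background,
            )
        )
        ref_seq = scoring.sequences[0].ref_seq
        seq_start = scoring.sequences[0].seq_start
        offsets = sorted({s.pos - seq_start for s in scoring.block.snvs})
        shm = shm_enrichment_test(ref_seq, offsets, block_id=scoring.block.block_id)
        shm_rows.append(
            {
                "block_id": shm.block_id,
                "n_mutations": shm.n_mutations,
                "n_in_hotspot": shm.n_in_hotspot,
                "p0": shm.p0,
                "binom_p": shm.binom_p,
            }
        )

    ranking_df = (
        pd.concat(rankings, ignore_index=True)
        if rankings
        else pd.DataFrame(
            columns=["unit_id", "tf_name", "pwm_id", "direction", "ddba_raw", "ddba_norm", "p_direct", "rank"]
        )
    )
    ranking_df.to_csv(outdir / "rankings.tsv", sep="\t", index=False)

    sig_rows = []
    for r in sorted(sig_records, key=lambda r: (r.block_id, r.tf)):
        row = {
            "tf_name": r.tf_name,
            "pwm_id": r.tf,
            "block_id": r.block_id,
            "direction": r.direction,
            "wilcoxon_p": r.wilcoxon_p,
            "bonferroni_p": r.bonferroni_p,
            "n_replicates_significant": r.n_replicates_significant,
            "significant": r.n_replicates_significant == config.replicates,
        }
        for pid, p in sorted(r.per_patient_p.items()):
            row[f"p_{pid}"] = p
        sig_rows.append(row)
    pd.DataFrame(sig_rows).to_csv(outdir / "significance.tsv", sep="\t", index=False)
    pd.DataFrame(
        shm_rows, columns=["block_id", "n_mutations", "n_in_hotspot", "p0", "binom_p"]
    ).to_csv(outdir / "shm.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_snvs": len(snvs),
        "n_blocks": len(blocks),
        "n_pwms_tested": len(pwms),
        "n_background": n_background,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# Per-SNV 61-bp analysis

def rank_individual_snvs(
    snvs: Sequence[SnvRecord], genome, pwms: Sequence[Pwm], config: RunConfig
) -> pd.DataFrame:
    """Rank TFs for each SNV on the 61-bp window centered at the variant."""
    params = config.affinity_params()
    ems = [pwm_to_energy(p) for p in pwms]
    pairs = [snv_window_sequences(s, genome, config.snv_half_window) for s in snvs]
    unit_ids = [f"{s.chrom}:{s.pos}:{s.ref_base}>{s.alt_base}|{s.patient_id}" for s in snvs]
    per_tf: dict[str, list[DeltaDbaResult]] = {}
    for em in ems:
        results = []
        for (ref_seq, alt_seq), uid, s in zip(pairs, unit_ids, snvs):
            from .affinity import delta_dba

            d = delta_dba(ref_seq, alt_seq, em, params)
            results.append(
                DeltaDbaResult(
                    tf=em.pwm_id, tf_name=em.tf_name, unit_id=uid,
                    patient_id=s.patient_id, ddba_raw=d,
                )
            )
        per_tf[em.pwm_id] = normalize_deltas(results)
    rows = []
    for i, uid in enumerate(unit_ids):
        unit_results = []
        for em in ems:
            r = per_tf[em.pwm_id][i]
            r.p_direct = direct_binding_pvalue(
                pairs[i][0], em, params,
                n_background=config.n_direct_shuffles,
                seed=_derived_seed(config.seed, "snv-pdirect", uid, em.pwm_id),
                early_stop=not config.exact_background,
            )
            unit_results.append(r)
        pos, neg = rank_tfs(
            unit_results, k=config.top_k,
            p_direct_cutoff=config.p_direct_cutoff,
            magnitude_percentile=config.magnitude_percentile,
        )
        for direction, ranked in (("positive", pos), ("negative", neg)):
            for rank, r in enumerate(ranked, start=1):
                rows.append(
                    {
                        "unit_id": uid, "tf_name": r.tf_name, "pwm_id": r.tf,
                        "direction": direction, "ddba_raw": r.ddba_raw,
                        "ddba_norm": r.ddba_norm, "p_direct": r.p_direct, "rank": rank,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "tf_name", "pwm_id", "direction", "ddba_raw", "ddba_norm", "p_direct", "rank"],
    )
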