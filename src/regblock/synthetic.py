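"""Synthetic miniature cohort generator.

Produces a complete on-disk study — genome, TSS annotation, JASPAR PWM
file, per-patient VCFs, tumor/normal expression table, and a truth table —
that emulates the structure of a multi-patient promoter-mutation cohort:
most somatic SNVs are sparse background noise, but each "driver" gene's
promoter carries a recurrent mutation block in which patient SNVs disrupt
planted occurrences of one known TF motif, and driver genes are
differentially expressed between tumor and normal samples.

The miniature scale (one ~200 kb chromosome, tens of genes) keeps every
pipeline stage exercisable end-to-end; see docs/methods.md for what the
simulation does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .core_io import BASES, Pwm, write_pwms_jaspar

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SyntheticScenario:
    """Parameters of the simulated cohort (defaults = the study conditions)."""

    n_patients: int = 12
    n_genes: int = 50
    chrom_length: int = 200_000
    n_driver_genes: int = 2
    n_decoy_pwms: int = 50
    motif_length: int = 10
    n_motif_occurrences: int = 3  # planted per driver block
    occurrence_spacing: int = 20  # bp between occurrence starts
    block_width: int = 100  # region of the promoter holding the occurrences
    snvs_per_patient_in_block: int = 2
    block_probability: float = 0.7  # chance a patient carries block SNVs
    background_snv_rate: float = 5e-6  # per bp per patient
    n_normal_samples: int = 4
    expression_effect: float = 6.0  # tumor fold-change for driver genes
    expression_sigma: float = 0.5  # log-normal spread around gene means
    n_low_expression_tfs: int = 5  # decoy TFs below the 0.03 RPKM floor
    weak_effect: bool = False  # halve the per-patient disruptions
    seed: int = 0


@dataclass
class ScenarioBundle:
    """Paths of the generated files plus in-memory truth."""

    genome_fasta: Path
    tss_table: Path
    pwm_file: Path
    vcf_paths: dict[str, Path]
    expression_table: Path
    sample_groups: dict[str, str]
    truth: pd.DataFrame
    truth_table: Path
    planted_pwm: Pwm
    scenario: SyntheticScenario


def _sharp_pwm(rng: np.random.Generator, tf_name: str, pwm_id: str, length: int) -> Pwm:
    """An informative PWM around a random consensus word (decoy)."""
    probs = np.zeros((length, 4))
    consensus = rng.integers(0, 4, size=length)
    for i, c in enumerate(consensus):
        others = [b for b in range(4) if b != c]
        weights = rng.dirichlet([1.0, 1.0, 1.0]) * 0.25
        probs[i, c] = 0.75
        for b, w in zip(others, weights):
            probs[i, b] = w
    probs += 0.001
    probs /= probs.sum(axis=1, keepdims=True)
    return Pwm(tf_name=tf_name, pwm_id=pwm_id, probs=probs)


def _shares_kmer(a: str, b: str, k: int) -> bool:
    """True when a and b (or revcomp of b) share any exact k-mer."""
    rc = "".join(_COMPLEMENT[c] for c in reversed(b))
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(
        s[j : j + k] in kmers for s in (b, rc) for j in range(len(s) - k + 1)
    )


def _planted_pwm(rng: np.random.Generator, length: int) -> Pwm:
    """High-information PWM with a unique worst base at each position."""
    probs = np.zeros((length, 4))
    consensus = rng.integers(0, 4, size=length)
    for i, c in enumerate(consensus):
        others = [b for b in range(4) if b != c]
        probs[i, c] = 0.85
        for b, p in zip(others, (0.07, 0.05, 0.03)):
            probs[i, b] = p
    return Pwm(tf_name="PTF1", pwm_id="PL0001", probs=probs)


def _worst_base(pwm: Pwm, position: int) -> str:
    return BASES[int(pwm.probs[position].argmin())]


def _max_info_position(pwm: Pwm) -> int:
    info = (pwm.probs * np.log2(pwm.probs * 4)).sum(axis=1)
    return int(info.argmax())


def generate_scenario(
    scenario: SyntheticScenario, outdir: str | Path
) -> ScenarioBundle:
    """Write the full synthetic bundle under ``outdir`` and return its paths."""
    sc = scenario
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sc.seed)
    chrom = "1"

    margin = 2000
    spacing = (sc.chrom_length - 2 * margin) // sc.n_genes
    if spacing < 2100:  # keep +/-1000 promoter windows disjoint
        raise ValueError("chromosome too short for the requested gene count")
    tss_positions = [margin + i * spacing for i in range(sc.n_genes)]
    gene_ids = [f"G{i:03d}" for i in range(sc.n_genes)]
    strands = ["+" if i % 2 == 0 else "-" for i in range(sc.n_genes)]

    genome = rng.integers(0, 4, size=sc.chrom_length)

    planted = _planted_pwm(rng, sc.motif_length)
    occ_span = (sc.n_motif_occurrences - 1) * sc.occurrence_spacing + sc.motif_length
    if occ_span > sc.block_width:
        raise ValueError("motif occurrences do not fit inside block_width")
    if sc.block_width > 1000:
        raise ValueError("planted block wider than the promoter window")

    driver_idx = sorted(rng.choice(sc.n_genes, size=sc.n_driver_genes, replace=False))
    driver_genes = [gene_ids[i] for i in driver_idx]
    consensus_codes = planted.probs.argmax(axis=1)
    occurrence_starts: dict[str, list[int]] = {}
    for gi in driver_idx:
        # block region upstream-ish of the TSS, inside the +/-1000 promoter
        block_start = tss_positions[gi] - 400
        starts = [
            block_start + j * sc.occurrence_spacing
            for j in range(sc.n_motif_occurrences)
        ]
        for s in starts:
            genome[s - 1 : s - 1 + sc.motif_length] = consensus_codes
        occurrence_starts[gene_ids[gi]] = starts

    genome_str = "".join(BASES[b] for b in genome)

    patients = [f"P{i + 1:02d}" for i in range(sc.n_patients)]
    snvs: dict[str, list[tuple[int, str, str]]] = {p: [] for p in patients}
    truth_rows = []
    n_disruptions = sc.snvs_per_patient_in_block
    if sc.weak_effect:
        n_disruptions = max(1, n_disruptions // 2)
    for gene, starts in occurrence_starts.items():
        planted_positions: list[int] = []
        carriers = []
        for p in patients:
            if rng.random() >= sc.block_probability:
                continue
            chosen = rng.choice(len(starts), size=min(n_disruptions, len(starts)), replace=False)
            for j in sorted(chosen):
                # each patient hits a different position of their occurrence,
                # always replacing the consensus base with the worst base there
                off = int(rng.integers(sc.motif_length))
                pos = starts[j] + off  # 1-based: starts are 1-based
                ref = BASES[consensus_codes[off]]
                alt = _worst_base(planted, off)
                snvs[p].append((pos, ref, alt))
                planted_positions.append(pos)
            carriers.append(p)
        truth_rows.append(
            {
                "gene_id": gene,
                "chrom": chrom,
                "block_start": min(planted_positions) if planted_positions else -1,
                "block_end": max(planted_positions) if planted_positions else -1,
                "planted_pwm_id": planted.pwm_id,
                "expected_sign": "negative",
                "n_carriers": len(carriers),
            }
        )

    # genome-wide background SNVs
    for p in patients:
        n_bg = rng.binomial(sc.chrom_length, sc.background_snv_rate)
        for pos in sorted(rng.choice(sc.chrom_length, size=n_bg, replace=False) + 1):
            ref = genome_str[pos - 1]
            alt = BASES[(BASE_ORDER[ref] + int(rng.integers(1, 4))) % 4]
            snvs[p].append((int(pos), ref, alt))

    # ----- write files -----
    genome_fasta = outdir / "genome.fa"
    with open(genome_fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome_str), 80):
            fh.write(genome_str[i : i + 80] + "\n")

    tss_table = outdir / "tss.tsv"
    pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_name": gene_ids,
            "chrom": chrom,
            "tss": tss_positions,
            "strand": strands,
        }
    ).to_csv(tss_table, sep="\t", index=False)

    # decoys must be genuinely unrelated to the planted motif: reject any
    # whose consensus shares a 5-mer with it (either strand)
    decoys = []
    for i in range(sc.n_decoy_pwms):
        for _ in range(100):
            cand = _sharp_pwm(
                rng, f"DTF{i + 1:02d}", f"DM{i + 1:04d}", int(rng.integers(8, 13))
            )
            if not _shares_kmer(planted.consensus, cand.consensus, 5):
                break
        decoys.append(cand)
    pwm_file = outdir / "pwms.jaspar"
    write_pwms_jaspar([planted] + decoys, pwm_file)

    vcf_paths = {}
    for p in patients:
        path = outdir / f"{p}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom},length={sc.chrom_length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for pos, ref, alt in sorted(set(snvs[p])):
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
        vcf_paths[p] = path

    # ----- expression -----
    normals = [f"N{i + 1:02d}" for i in range(sc.n_normal_samples)]
    sample_groups = {p: "tumor" for p in patients} | {n: "normal" for n in normals}
    tf_names = [planted.tf_name] + [d.tf_name for d in decoys]
    low_tfs = set(tf_names[-sc.n_low_expression_tfs :]) if sc.n_low_expression_tfs else set()
    all_genes = gene_ids + tf_names
    rows = {}
    for g in all_genes:
        if g in low_tfs:
            base = 0.01
        else:
            base = float(rng.lognormal(mean=np.log(5.0), sigma=1.0))
        vals = base * rng.lognormal(mean=0.0, sigma=sc.expression_sigma, size=len(sample_groups))
        row = dict(zip(list(patients) + normals, vals))
        if g in driver_genes:
            for p in patients:
                row[p] *= sc.expression_effect
        rows[g] = row
    expr_df = pd.DataFrame(rows).T[list(patients) + normals]
    expression_table = outdir / "expression.tsv"
    expr_df.to_csv(expression_table, sep="\t", index_label="gene")

    truth = pd.DataFrame(truth_rows)
    truth_table = outdir / "truth.tsv"
    truth.to_csv(truth_table, sep="\t", index=False)

    return ScenarioBundle(
        genome_fasta=genome_fasta,
        tss_table=tss_table,
        pwm_file=pwm_file,
        vcf_paths=vcf_paths,
        expression_table=expression_table,
        sample_groups=sample_groups,
        truth=truth,
        truth_table=truth_table,
        planted_pwm=planted,
        scenario=sc,
    )


BASE_ORDER = {b: i for i, b in enumerate(BASES)}


def nucleotide_change_stats(snvs) -> pd.DataFrame:
    """Six-category substitution spectrum with reverse-complement collapsing.

    Substitutions from a purine reference are complemented onto the
    pyrimidine strand, yielding the conventional C>A, C>G, C>T, T>A, T>C,
    T>G categories. Returns a DataFrame with counts and fractions.
    """
    categories = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    counts = dict.fromkeys(categories, 0)
    for s in snvs:
        ref, alt = s.ref_base, s.alt_base
        if ref in "AG":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "category": categories,
            "count": [counts[c] for c in categories],
            "fraction": [counts[c] / total if total else 0.0 for c in categories],
        }
    )
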