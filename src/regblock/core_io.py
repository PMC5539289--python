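"""Domain types and readers/writers for the external formats.

Coordinate convention: 1-based inclusive internally (VCF style); BED output
converts to 0-based half-open. Chromosome names are normalized by stripping
any leading ``chr`` prefix so that inputs from mixed sources compare equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class InputError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_chrom(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class SnvRecord:
    """A somatic single-nucleotide substitution attributed to one patient."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    patient_id: str

    def __post_init__(self):
        if self.ref_base not in BASE_INDEX or self.alt_base not in BASE_INDEX:
            raise InputError(
                f"SNV {self.chrom}:{self.pos} has non-ACGT alleles "
                f"{self.ref_base}>{self.alt_base}"
            )
        if self.ref_base == self.alt_base:
            raise InputError(f"SNV {self.chrom}:{self.pos} ref equals alt")
        if self.pos < 1:
            raise InputError(f"SNV position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class TssRecord:
    """One transcription start site; a gene may contribute several."""

    gene_id: str
    gene_name: str
    chrom: str
    tss: int  # 1-based
    strand: str

    def __post_init__(self):
        if self.tss < 1:
            raise InputError(f"TSS position must be >= 1, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class Pwm:
    """Position weight matrix as base probabilities (columns A,C,G,T)."""

    tf_name: str
    pwm_id: str
    probs: np.ndarray  # (L, 4)
    source_tier: str = "known"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise InputError(f"PWM {self.pwm_id}: matrix must be Lx4")
        if self.probs.shape[0] < 4:
            raise InputError(f"PWM {self.pwm_id}: length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise InputError(f"PWM {self.pwm_id}: rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


@dataclass
class ExpressionTable:
    """Gene-by-sample RPKM matrix with tumor/normal sample labels."""

    values: pd.DataFrame  # genes x samples, non-negative
    sample_groups: Mapping[str, str]  # sample -> {"tumor", "normal"}

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise InputError("expression values must be non-negative")
        for s in self.values.columns:
            g = self.sample_groups.get(s)
            if g not in ("tumor", "normal"):
                raise InputError(f"sample {s!r} has no tumor/normal group")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    def gene_values(self, gene: str, group: str) -> np.ndarray:
        key = self._resolve_gene(gene)
        if key is None:
            raise InputError(f"gene {gene!r} absent from expression table")
        return self.values.loc[key, self.samples(group)].to_numpy(dtype=float)

    def has_gene(self, gene: str) -> bool:
        return self._resolve_gene(gene) is not None

    def _resolve_gene(self, gene: str):
        if gene in self.values.index:
            return gene
        lower = {str(g).lower(): g for g in self.values.index}
        return lower.get(str(gene).lower())


# ---------------------------------------------------------------------------
# VCF

def read_snvs(vcf_paths: Mapping[str, str | Path]) -> list[SnvRecord]:
    """Read per-patient VCFs, keeping only biallelic SNVs.

    Parameters
    ----------
    vcf_paths
        Mapping patient_id -> VCF path (one file per patient).

    Returns
    -------
    SNVs sorted by (chrom, pos). Indels and multi-allelic records are
    skipped with a logged count per file.
    """
    from cyvcf2 import VCF

    out: list[SnvRecord] = []
    for patient_id, path in vcf_paths.items():
        path = str(path)
        n_skipped = 0
        try:
            vcf = VCF(path)
        except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
            raise InputError(f"cannot parse VCF {path}: {exc}") from exc
        for rec in vcf:
            alts = rec.ALT
            if (
                len(alts) != 1
                or len(rec.REF) != 1
                or len(alts[0]) != 1
                or rec.REF not in BASE_INDEX
                or alts[0] not in BASE_INDEX
            ):
                n_skipped += 1
                continue
            out.append(
                SnvRecord(
                    chrom=normalize_chrom(rec.CHROM),
                    pos=rec.POS,
                    ref_base=rec.REF,
                    alt_base=alts[0],
                    patient_id=patient_id,
                )
            )
        if n_skipped:
            logger.info("%s: skipped %d non-SNV records", path, n_skipped)
    out.sort(key=lambda s: (s.chrom, s.pos, s.patient_id))
    return out


def check_reference_consistency(snvs: Iterable[SnvRecord], genome) -> None:
    """Verify each SNV's ref_base against the genome FASTA (pyfaidx)."""
    for snv in snvs:
        base = str(genome[snv.chrom][snv.pos - 1 : snv.pos]).upper()
        if base != snv.ref_base:
            raise InputError(
                f"SNV {snv.chrom}:{snv.pos} ref {snv.ref_base} does not match "
                f"genome base {base}"
            )


def open_genome(path: str | Path):
    """Open a FASTA reference with chromosome-name normalization."""
    from pyfaidx import Fasta

    return Fasta(
        str(path),
        key_function=normalize_chrom,
        sequence_always_upper=True,
    )


# ---------------------------------------------------------------------------
# PWMs (JASPAR-like format)

def read_pwms(
    path: str | Path,
    tier_map: Mapping[str, str] | None = None,
) -> list[Pwm]:
    """Read a JASPAR-format matrix file into probability PWMs.

    Count matrices get a +1 per-cell pseudocount; matrices that already look
    like probabilities (rows summing to ~1) get +0.001 before renormalizing.
    ``tier_map`` optionally maps pwm_id -> {"known", "other"}.
    """
    from Bio import motifs

    path = Path(path)
    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.column_stack([np.asarray(m.counts[b], dtype=float) for b in BASES])
        pwm_id = m.matrix_id or m.name
        tf_name = m.name or pwm_id
        probs = regularize_matrix(counts, pwm_id=pwm_id)
        tier = (tier_map or {}).get(pwm_id, "known")
        out.append(Pwm(tf_name=tf_name, pwm_id=pwm_id, probs=probs, source_tier=tier))
    return out


def regularize_matrix(matrix: np.ndarray, pwm_id: str = "?") -> np.ndarray:
    """Convert a count or probability matrix to pseudocounted probabilities."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise InputError(f"PWM {pwm_id}: expected an Lx4 matrix")
    row_sums = matrix.sum(axis=1)
    if np.any(row_sums <= 0):
        raise InputError(f"PWM {pwm_id}: row of all zeros")
    if np.allclose(row_sums, 1.0, atol=1e-3):
        # already probabilities; pseudocount only needed to lift zeros
        reg = matrix + 0.001 if (matrix < 1e-9).any() else matrix
    else:
        reg = matrix + 1.0
    return reg / reg.sum(axis=1, keepdims=True)


def write_pwms_jaspar(pwms: Sequence[Pwm], path: str | Path) -> None:
    """Write PWMs in JASPAR probability-matrix format."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.pwm_id} {p.tf_name}\n")
            for j, base in enumerate(BASES):
                vals = " ".join(f"{v:.6f}" for v in p.probs[:, j])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# TSS annotation

def read_tss_table(path: str | Path) -> list[TssRecord]:
    """Read a TSS TSV: gene_id, chrom, tss, strand (+ optional gene_name)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"TSS table {path} missing columns: {sorted(missing)}")
    if "gene_name" not in df.columns:
        df["gene_name"] = df["gene_id"]
    return [
        TssRecord(
            gene_id=str(r.gene_id),
            gene_name=str(r.gene_name),
            chrom=normalize_chrom(str(r.chrom)),
            tss=int(r.tss),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]


def read_tss_gtf(path: str | Path, feature: str = "transcript") -> list[TssRecord]:
    """Extract per-transcript TSSs from a GTF (TSS = start on +, end on -)."""
    import pyranges as pr

    gr = pr.read_gtf(str(path)).df
    gr = gr[gr["Feature"] == feature]
    out = []
    for r in gr.itertuples():
        tss = int(r.Start) + 1 if r.Strand == "+" else int(r.End)
        name = getattr(r, "gene_name", None) or r.gene_id
        out.append(
            TssRecord(
                gene_id=str(r.gene_id),
                gene_name=str(name),
                chrom=normalize_chrom(str(r.Chromosome)),
                tss=tss,
                strand=str(r.Strand),
            )
        )
    return out


def promoter_window(
    tss: TssRecord, half_width: int = 1000, chrom_length: int | None = None
) -> tuple[int, int]:
    """Symmetric promoter interval [tss-half_width, tss+half_width].

    1-based inclusive; clipped at the chromosome start (and end when
    ``chrom_length`` is given). Strand does not affect the window.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if chrom_length is not None and tss.tss > chrom_length:
        raise InputError(
            f"TSS {tss.gene_id}@{tss.chrom}:{tss.tss} beyond chromosome end "
            f"({chrom_length})"
        )
    start = max(1, tss.tss - half_width)
    end = tss.tss + half_width
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


# ---------------------------------------------------------------------------
# Expression

def read_expression_table(
    path: str | Path, sample_groups: Mapping[str, str]
) -> ExpressionTable:
    """Read a gene x sample TSV of RPKM values (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df[[c for c in df.columns if c in sample_groups]]
    if df.shape[1] == 0:
        raise InputError(f"no expression samples in {path} match the group map")
    return ExpressionTable(values=df, sample_groups=dict(sample_groups))


# ---------------------------------------------------------------------------
# BED round-trip for intervals (1-based inclusive <-> 0-based half-open)

def write_bed(
    intervals: Sequence[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name) 1-based inclusive intervals as BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED file back to 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"malformed BED line in {path}: {line!r}")
            name = fields[3] if len(fields) > 3 else "."
            out.append(
                (normalize_chrom(fields[0]), int(fields[1]) + 1, int(fields[2]), name)
            )
    return out
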