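"""Data model and readers/writers for signal matrices, sample sheets, and transcripts.

The central container is :class:`SignalMatrix`: a gene x sample table of
non-negative abundance signals together with a sample sheet describing the
2 genotype x 2 condition x 2 fraction replicated design (wild type vs mutant,
control vs cold, total vs polysomal RNA). Signals are treated as
already-normalized abundances; an optional total-sum scaling helper is
provided but nothing in the pipeline applies it implicitly.

Transcript models carry, per gene, one representative isoform's spliced
5'-UTR and CDS in transcript orientation; they feed the initiation-context
and uORF analyses.

Coordinate conventions: GFF3 input is 1-based inclusive; every internal
sequence offset is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "Genotype",
    "Condition",
    "Fraction",
    "DesignCell",
    "SampleMeta",
    "SignalMatrix",
    "TranscriptModel",
    "SchemaError",
    "read_signal_matrix",
    "write_signal_matrix",
    "read_transcripts",
    "read_transcripts_table",
    "write_transcripts_table",
    "total_sum_scale",
]


class Genotype(str, Enum):
    WT = "WT"
    MUT = "MUT"


class Condition(str, Enum):
    CK = "CK"
    COLD = "COLD"


class Fraction(str, Enum):
    TOTAL = "TOTAL"
    POLY = "POLY"


class SchemaError(ValueError):
    """Input file violates the documented schema."""


@dataclass(frozen=True)
class DesignCell:
    """One cell of the genotype x condition x fraction design."""

    genotype: Genotype
    condition: Condition
    fraction: Fraction

    def __str__(self) -> str:  # used in error messages and file names
        return f"{self.genotype.value}_{self.condition.value}_{self.fraction.value}"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: Genotype
    condition: Condition
    fraction: Fraction
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate index must be positive, got {self.replicate}")

    @property
    def cell(self) -> DesignCell:
        return DesignCell(self.genotype, self.condition, self.fraction)


@dataclass
class SignalMatrix:
    """Gene x sample matrix of non-negative signals plus sample metadata."""

    genes: list[str]
    samples: list[SampleMeta]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in sample sheet")
        cells: dict[tuple, set[int]] = {}
        for s in self.samples:
            reps = cells.setdefault((s.genotype, s.condition, s.fraction), set())
            if s.replicate in reps:
                raise ValueError(
                    f"duplicate replicate {s.replicate} within design cell {s.cell}"
                )
            reps.add(s.replicate)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("signal values must be finite and >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def cell_columns(self, cell: DesignCell) -> list[int]:
        """Column indices of the replicates in one design cell, by replicate order."""
        cols = [
            (s.replicate, j)
            for j, s in enumerate(self.samples)
            if s.cell == cell
        ]
        return [j for _, j in sorted(cols)]

    def cell_values(self, cell: DesignCell) -> np.ndarray:
        """(n_genes, n_replicates) slice for one design cell."""
        cols = self.cell_columns(cell)
        if not cols:
            raise KeyError(f"no samples for design cell {cell}")
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.genes, name="gene_id"),
            columns=[s.sample_id for s in self.samples],
        )


@dataclass(frozen=True)
class TranscriptModel:
    """Representative transcript: spliced 5'-UTR and CDS in transcript orientation."""

    transcript_id: str
    gene_id: str
    utr5: str
    cds: str
    representative: bool = True

    def __post_init__(self) -> None:
        if len(self.cds) < 3:
            raise ValueError(f"{self.transcript_id}: CDS shorter than one codon")
        if self.representative and not self.cds.startswith("ATG"):
            raise ValueError(
                f"{self.transcript_id}: representative CDS does not start with ATG"
            )


# ---------------------------------------------------------------------------
# signal matrix TSV I/O
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ["sample_id", "genotype", "condition", "fraction", "replicate"]


def _parse_sample_sheet(samples_path: Path) -> list[SampleMeta]:
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    missing = [c for c in _SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise SchemaError(f"sample sheet {samples_path} missing columns {missing}")
    metas = []
    for _, row in sheet.iterrows():
        try:
            metas.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    genotype=Genotype(row["genotype"]),
                    condition=Condition(row["condition"]),
                    fraction=Fraction(row["fraction"]),
                    replicate=int(row["replicate"]),
                )
            )
        except ValueError as exc:
            raise SchemaError(
                f"sample sheet row for {row['sample_id']!r}: {exc}"
            ) from exc
    return metas


def read_signal_matrix(matrix_path: str | Path, samples_path: str | Path) -> SignalMatrix:
    """Read a gene x sample TSV and its sample sheet into a validated SignalMatrix.

    The matrix header is ``gene_id`` followed by sample ids; the sheet has
    columns sample_id/genotype/condition/fraction/replicate with vocabularies
    WT/MUT, CK/COLD, TOTAL/POLY. Matrix columns and sheet rows must agree as
    sets; the matrix column order wins.
    """
    matrix_path, samples_path = Path(matrix_path), Path(samples_path)
    metas = _parse_sample_sheet(samples_path)
    by_id = {m.sample_id: m for m in metas}

    frame = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if frame.columns[0] != "gene_id":
        raise SchemaError(
            f"{matrix_path}: first column must be 'gene_id', got {frame.columns[0]!r}"
        )
    matrix_ids = list(frame.columns[1:])
    extra = sorted(set(matrix_ids) - set(by_id))
    absent = sorted(set(by_id) - set(matrix_ids))
    if extra or absent:
        raise SchemaError(
            f"sample id mismatch between {matrix_path} and {samples_path}: "
            f"in matrix only {extra}, in sheet only {absent}"
        )
    data = frame[matrix_ids]
    for col in matrix_ids:
        nonnum = pd.to_numeric(data[col], errors="coerce")
        bad_rows = np.where(nonnum.isna() & data[col].notna())[0]
        if data[col].isna().any():
            bad_rows = np.union1d(bad_rows, np.where(data[col].isna())[0])
        if bad_rows.size:
            raise SchemaError(
                f"{matrix_path}: non-numeric or missing value at gene "
                f"{frame.iloc[bad_rows[0], 0]!r}, column {col!r}"
            )
        neg = np.where(nonnum < 0)[0]
        if neg.size:
            raise SchemaError(
                f"{matrix_path}: negative signal at gene "
                f"{frame.iloc[neg[0], 0]!r}, column {col!r}"
            )
    genes = list(frame["gene_id"])
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise SchemaError(f"{matrix_path}: duplicate gene_id(s) {dupes[:5]}")
    samples = [by_id[i] for i in matrix_ids]
    return SignalMatrix(genes=genes, samples=samples, values=data.to_numpy(dtype=float))


def write_signal_matrix(
    matrix: SignalMatrix, matrix_path: str | Path, samples_path: str | Path
) -> None:
    """Write the matrix TSV (full float precision) and its sample sheet."""
    frame = matrix.to_frame()
    frame.to_csv(matrix_path, sep="\t", float_format="%.12g")
    sheet = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in matrix.samples],
            "genotype": [s.genotype.value for s in matrix.samples],
            "condition": [s.condition.value for s in matrix.samples],
            "fraction": [s.fraction.value for s in matrix.samples],
            "replicate": [s.replicate for s in matrix.samples],
        }
    )
    sheet.to_csv(samples_path, sep="\t", index=False)


def total_sum_scale(matrix: SignalMatrix, target: float | None = None) -> SignalMatrix:
    """Optional column-sum scaling (off by default throughout the pipeline)."""
    sums = matrix.values.sum(axis=0)
    if np.any(sums == 0):
        raise ValueError("cannot total-sum scale: a sample has zero total signal")
    target = float(np.mean(sums)) if target is None else target
    return SignalMatrix(
        genes=list(matrix.genes),
        samples=list(matrix.samples),
        values=matrix.values * (target / sums),
    )


# ---------------------------------------------------------------------------
# transcript models: flat table and FASTA + GFF3
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["transcript_id", "gene_id", "utr5_seq", "cds_seq"]


def _select_representative(
    candidates: dict[str, list[TranscriptModel]], isoform_rule: str
) -> list[TranscriptModel]:
    if isoform_rule not in ("first", "longest_cds"):
        raise ValueError(f"unknown isoform_rule {isoform_rule!r}")
    chosen = []
    for gene_id in sorted(candidates):
        models = candidates[gene_id]
        if isoform_rule == "first":
            pick = min(models, key=lambda m: m.transcript_id)
        else:
            pick = max(models, key=lambda m: (len(m.cds), m.transcript_id))
        chosen.append(
            TranscriptModel(pick.transcript_id, gene_id, pick.utr5, pick.cds, True)
        )
    return chosen


def read_transcripts_table(
    path: str | Path, isoform_rule: str = "first"
) -> list[TranscriptModel]:
    """Read transcripts from a flat TSV (transcript_id, gene_id, utr5_seq, cds_seq).

    Transcripts whose CDS does not start with ATG (or has no CDS) are skipped
    with a logged warning; one representative per gene is then selected by
    ``isoform_rule`` ("first" = lowest-sorting transcript_id, or "longest_cds").
    """
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"transcript table {path} missing columns {missing}")
    candidates: dict[str, list[TranscriptModel]] = {}
    n_skipped = 0
    for _, row in frame.iterrows():
        cds = row["cds_seq"].upper()
        if len(cds) < 3 or not cds.startswith("ATG"):
            logger.warning(
                "skipping transcript %s: CDS missing or not starting with ATG",
                row["transcript_id"],
            )
            n_skipped += 1
            continue
        candidates.setdefault(row["gene_id"], []).append(
            TranscriptModel(
                row["transcript_id"], row["gene_id"], row["utr5_seq"].upper(), cds,
                representative=False,
            )
        )
    if n_skipped:
        logger.warning("%d transcript(s) skipped during load", n_skipped)
    return _select_representative(candidates, isoform_rule)


def write_transcripts_table(models: Iterable[TranscriptModel], path: str | Path) -> None:
    models = list(models)
    frame = pd.DataFrame(
        {
            "transcript_id": [m.transcript_id for m in models],
            "gene_id": [m.gene_id for m in models],
            "utr5_seq": [m.utr5 for m in models],
            "cds_seq": [m.cds for m in models],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def _spliced_sequence(segments, genome: dict[str, str], strand: str) -> str:
    """Concatenate exonic segments (1-based inclusive) in transcript orientation."""
    ordered = sorted(segments, key=lambda seg: seg[1])
    parts = [genome[seqid][start - 1 : end] for seqid, start, end in ordered]
    seq = "".join(parts)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.upper()


def read_transcripts(
    fasta_path: str | Path,
    annotation_path: str | Path,
    isoform_rule: str = "first",
) -> list[TranscriptModel]:
    """Read transcript models from a genome FASTA plus GFF3 annotation.

    five_prime_UTR and CDS features are grouped by their ``Parent`` transcript;
    the spliced 5'-UTR and CDS are assembled strand-aware in transcript
    orientation. Gene ids come from mRNA features' ``Parent`` when present,
    otherwise from the transcript id stem before the last ".". Transcripts
    with no CDS or a CDS not starting with ATG are skipped with a warning.
    """
    import gffutils

    genome = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    tx_gene: dict[str, str] = {}
    for feat in db.all_features(featuretype=("mRNA", "transcript")):
        parents = feat.attributes.get("Parent", [])
        if parents:
            tx_gene[feat.id] = parents[0]

    utr_segs: dict[str, list] = {}
    cds_segs: dict[str, list] = {}
    strands: dict[str, str] = {}
    for ftype, store in (("five_prime_UTR", utr_segs), ("CDS", cds_segs)):
        for feat in db.all_features(featuretype=ftype):
            for parent in feat.attributes.get("Parent", []):
                store.setdefault(parent, []).append((feat.seqid, feat.start, feat.end))
                strands[parent] = feat.strand

    candidates: dict[str, list[TranscriptModel]] = {}
    n_skipped = 0
    for tx_id in sorted(set(utr_segs) | set(cds_segs)):
        if tx_id not in cds_segs:
            logger.warning("skipping transcript %s: no CDS features", tx_id)
            n_skipped += 1
            continue
        strand = strands[tx_id]
        cds = _spliced_sequence(cds_segs[tx_id], genome, strand)
        utr5 = (
            _spliced_sequence(utr_segs[tx_id], genome, strand)
            if tx_id in utr_segs
            else ""
        )
        if not cds.startswith("ATG"):
            logger.warning(
                "skipping transcript %s: CDS starts with %s, not ATG", tx_id, cds[:3]
            )
            n_skipped += 1
            continue
        gene_id = tx_gene.get(tx_id, tx_id.rsplit(".", 1)[0])
        candidates.setdefault(gene_id, []).append(
            TranscriptModel(tx_id, gene_id, utr5, cds, representative=False)
        )
    if n_skipped:
        logger.warning("%d transcript(s) skipped during GFF3 load", n_skipped)
    return _select_representative(candidates, isoform_rule)
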