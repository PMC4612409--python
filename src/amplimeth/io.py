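"""Readers and writers for the pipeline's plain-text interchange formats.

Expression matrices travel as a gene × sample TSV plus a sample-annotation
sidecar (sample id, stage, context).  Reads and templates use FASTA/FASTQ via
Biopython; CpG sites and island calls use BED-like 0-based half-open TSVs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentResult, AmpliconTemplate
from .cpg import CpGIslandCall
from .mirna import CtPlateSet
from .trends import ExpressionMatrix

__all__ = [
    "read_expression", "write_expression",
    "read_fasta", "write_fasta", "write_fastq",
    "read_template", "write_cpg_bed",
    "write_islands_bed",
    "write_alignment_report",
    "read_ct_plates", "write_ct_plates",
    "read_prediction_table",
]


def read_expression(matrix_path, annotation_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(annotation_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, samples)


def write_expression(matrix: ExpressionMatrix, matrix_path, annotation_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", float_format="%.6g")
    matrix.samples.to_csv(annotation_path, sep="\t")


def read_fasta(path) -> list[tuple[str, str]]:
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def _records(reads):
    for rid, seq in reads:
        yield SeqRecord(Seq(seq), id=rid, description="")


def write_fasta(reads, path) -> None:
    SeqIO.write(_records(reads), str(path), "fasta")


def write_fastq(reads, path, quality: int = 30) -> None:
    recs = []
    for rec in _records(reads):
        rec.letter_annotations["phred_quality"] = [quality] * len(rec.seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_template(fasta_path, cpg_bed_path=None, mask_bed_path=None) -> AmpliconTemplate:
    """First record of a FASTA as an amplicon template.

    CpG sites are auto-detected unless a BED of site positions is given;
    an optional mask BED lists primer intervals excluded from calling.
    """
    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    cpg = None
    if cpg_bed_path is not None:
        bed = pd.read_csv(cpg_bed_path, sep="\t", header=None)
        cpg = sorted(int(x) for x in bed[1])
    masks = []
    if mask_bed_path is not None:
        bed = pd.read_csv(mask_bed_path, sep="\t", header=None)
        masks = [(int(r[1]), int(r[2])) for _, r in bed.iterrows()]
    return AmpliconTemplate(rec.id, str(rec.seq), cpg, masks)


def write_cpg_bed(template: AmpliconTemplate, path) -> None:
    with open(path, "w") as fh:
        for p in template.cpg_positions:
            fh.write(f"{template.name}\t{p}\t{p + 2}\tCpG\n")


def write_islands_bed(name: str, islands: list[CpGIslandCall], path) -> None:
    with open(path, "w") as fh:
        for k, isl in enumerate(islands):
            fh.write(
                f"{name}\t{isl.start}\t{isl.end}\tisland_{k + 1}\t"
                f"{isl.gc_percent:.2f}\t{isl.obs_exp:.3f}\n"
            )


def write_alignment_report(alignments: list[AlignmentResult], path) -> None:
    rows = [
        {
            "read_id": a.read_id,
            "template": a.template,
            "orientation": a.orientation,
            "start": a.start,
            "end": a.end,
            "score": a.score,
            "max_score": a.max_attainable,
            "score_fraction": round(a.score_fraction, 6),
            "pass": bool(a.passed),
        }
        for a in alignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ct_plates(plates: CtPlateSet, path) -> None:
    plates.wells.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ct_plates(path, reference=None) -> CtPlateSet:
    df = pd.read_csv(path, sep="\t")
    df["is_calibrator"] = df["is_calibrator"].astype(bool)
    kwargs = {"reference": reference} if reference else {}
    return CtPlateSet(df, **kwargs)


def read_prediction_table(path) -> pd.DataFrame:
    """miRNA → gene target-prediction table (columns mirna, gene[, source])."""
    df = pd.read_csv(path, sep="\t")
    if not {"mirna", "gene"} <= set(df.columns):
        raise ValueError("prediction table needs 'mirna' and 'gene' columns")
    return df
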