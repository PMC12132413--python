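"""Readers and writers for the pipeline's file formats.

Everything on disk is plain text: FASTA for references and pools (Biopython),
FASTQ for simulated reads, TSV for tables (pandas) and JSON for architecture
specs and run manifests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coords import axis_labels
from .footprint_stats import ExpressionShiftMatrix, Footprint
from .library_design import (BarcodeAssignment, DesignConfig, PromoterRegion,
                             VariantLibrary, extract_window)


def read_reference(path: str | Path) -> dict[str, str]:
    """Load a reference FASTA as {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_promoter_table(path: str | Path) -> pd.DataFrame:
    """Promoter definitions TSV: promoter_id, gene, contig, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"promoter_id": str, "gene": str,
                                            "contig": str, "strand": str})
    required = {"promoter_id", "gene", "tss", "strand"}
    if not required <= set(df.columns):
        raise ValueError(f"promoter table needs columns {sorted(required)}")
    return df


def load_promoters(table: pd.DataFrame,
                   reference: dict[str, str]) -> list[PromoterRegion]:
    regions = []
    for row in table.itertuples():
        contig = getattr(row, "contig", None) or next(iter(reference))
        regions.append(extract_window(reference[contig], int(row.tss),
                                      row.strand, promoter_id=row.promoter_id,
                                      gene=row.gene))
    return regions


def write_pool_fasta(manifest: pd.DataFrame, path: str | Path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.variant_id,
                         description=r.promoter_id)
               for r in manifest.itertuples()]
    SeqIO.write(records, str(path), "fasta")


def write_barcode_map(assignments: list[BarcodeAssignment] | pd.DataFrame,
                      path: str | Path) -> None:
    if not isinstance(assignments, pd.DataFrame):
        from .synthetic_data import barcode_map_frame
        assignments = barcode_map_frame(assignments)
    assignments.to_csv(path, sep="\t", index=False)


def read_barcode_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"barcode": str})


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"barcode": str})


def write_reads_fastq(reads: pd.DataFrame, variant_path: str | Path,
                      barcode_path: str | Path) -> None:
    """Write paired mapping reads as two FASTQ files with matched ids."""
    v_records, b_records = [], []
    for i, row in enumerate(reads.itertuples()):
        rid = f"read{i + 1}"
        for rec_list, seq in ((v_records, row.variant_read),
                              (b_records, row.barcode_read)):
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            rec_list.append(rec)
    SeqIO.write(v_records, str(variant_path), "fastq")
    SeqIO.write(b_records, str(barcode_path), "fastq")


def read_paired_fastq(variant_path: str | Path,
                      barcode_path: str | Path) -> pd.DataFrame:
    v = [str(r.seq) for r in SeqIO.parse(str(variant_path), "fastq")]
    b = [str(r.seq) for r in SeqIO.parse(str(barcode_path), "fastq")]
    if len(v) != len(b):
        raise ValueError("variant and barcode FASTQ files differ in length")
    return pd.DataFrame({"variant_read": v, "barcode_read": b})


def library_to_frame(library: VariantLibrary) -> pd.DataFrame:
    """Serialize a library, masks encoded as 0/1 strings."""
    return pd.DataFrame({
        "promoter_id": library.promoter_id,
        "variant_id": library.variant_ids,
        "sequence": library.sequences,
        "mutation_mask": ["".join("1" if m else "0" for m in row)
                          for row in library.masks],
    })


def library_from_frame(df: pd.DataFrame) -> VariantLibrary:
    masks = np.array([[c == "1" for c in m] for m in df["mutation_mask"]])
    wt = df.loc[~masks.any(axis=1), "variant_id"].iloc[0]
    return VariantLibrary(promoter_id=df["promoter_id"].iloc[0],
                          variant_ids=df["variant_id"].tolist(),
                          sequences=df["sequence"].tolist(),
                          masks=masks, wildtype_id=wt)


def footprint_to_frame(fp: Footprint) -> pd.DataFrame:
    df = fp.to_frame()
    df.insert(0, "promoter_id", fp.promoter_id)
    df.insert(1, "condition", fp.condition)
    df.insert(2, "replicate", fp.replicate)
    return df


def shifts_to_frame(shifts: ExpressionShiftMatrix) -> pd.DataFrame:
    labels = axis_labels()[: shifts.shifts.shape[1]]
    rows = []
    for code, base in enumerate("ACGT"):
        for j, pos in enumerate(labels):
            rows.append((shifts.promoter_id, shifts.condition, shifts.replicate,
                         pos, base, shifts.shifts[code, j],
                         base == "ACGT"[shifts.wildtype[j]]))
    return pd.DataFrame(rows, columns=["promoter_id", "condition", "replicate",
                                       "position", "base", "shift_log2",
                                       "is_wildtype"])
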