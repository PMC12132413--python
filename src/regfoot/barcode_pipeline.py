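"""Barcode-to-variant mapping and count aggregation.

Paired mapping reads (variant side, barcode side) are collapsed into a
barcode -> variant lookup: read pairs are grouped by barcode, pairs supported
by fewer than 3 total reads are discarded, a per-position majority consensus
is taken over the variant-side reads, and the consensus is assigned to the
nearest designed variant by edit distance.  Consensi far from every design
are retained as novel variants when well supported, since synthesized pools
carry real synthesis errors.  Count tables are then exact-match barcode
tallies per sample, summed per variant.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_SUPPORT = 3  # read pairs below this total are discarded


@dataclass(frozen=True)
class MappingRecord:
    barcode: str
    matched_variant_id: str
    read_support: int
    edit_distance: int


def _consensus(reads: list[str]) -> str:
    """Per-position majority vote over equal-length reads (ties: first seen)."""
    lengths = Counter(len(r) for r in reads)
    L = lengths.most_common(1)[0][0]
    reads = [r for r in reads if len(r) == L]
    if len(reads) == 1:
        return reads[0]
    cols = []
    for i in range(L):
        counts = Counter(r[i] for r in reads)
        cols.append(counts.most_common(1)[0][0])
    return "".join(cols)


def map_barcodes(reads: pd.DataFrame, pool: pd.DataFrame,
                 min_support: int = MIN_SUPPORT,
                 max_edit_distance: int = 20,
                 min_novel_support: int | None = None) -> pd.DataFrame:
    """Reconstruct the barcode -> variant map from paired mapping reads.

    ``reads`` needs columns ``variant_read``/``barcode_read``; ``pool`` is the
    design manifest (promoter_id, variant_id, sequence).  The promoter is
    resolved first by the best wild-type match, then the consensus is aligned
    against that promoter's designed variants.  Consensi beyond
    ``max_edit_distance`` from every design become ``novel`` variants when
    supported by at least ``min_novel_support`` reads (default: ``min_support``).

    Returns a DataFrame with columns barcode, variant_id, promoter_id,
    read_support, edit_distance.
    """
    if min_novel_support is None:
        min_novel_support = min_support
    required = {"variant_read", "barcode_read"}
    if not required <= set(reads.columns):
        raise ValueError(f"reads must have columns {sorted(required)}")
    n_bad = int(reads[list(required)].isna().any(axis=1).sum())
    if n_bad:
        logger.warning("skipping %d malformed read pairs", n_bad)
        reads = reads.dropna(subset=list(required))
    if reads.empty:
        return pd.DataFrame(columns=["barcode", "variant_id", "promoter_id",
                                     "read_support", "edit_distance"])

    by_promoter: dict[str, tuple[list[str], list[str]]] = {}
    wildtypes: dict[str, str] = {}
    for pid, grp in pool.groupby("promoter_id", sort=False):
        by_promoter[pid] = (grp["variant_id"].tolist(), grp["sequence"].tolist())
        wt = grp[grp["variant_id"].str.endswith(".wt")]
        wildtypes[pid] = (wt["sequence"].iloc[0] if len(wt)
                          else grp["sequence"].iloc[0])

    grouped: dict[str, list[str]] = defaultdict(list)
    for bc, vr in zip(reads["barcode_read"], reads["variant_read"]):
        grouped[bc].append(vr)

    novel_seen: dict[str, str] = {}
    records = []
    for bc, vreads in grouped.items():
        support = len(vreads)
        if support < min_support:
            continue
        cons = _consensus(vreads)
        pid = min(wildtypes,
                  key=lambda p: edlib.align(cons, wildtypes[p])["editDistance"])
        vids, seqs = by_promoter[pid]
        dists = [edlib.align(cons, s, k=max_edit_distance + 1)["editDistance"]
                 for s in seqs]
        dists = [d if d >= 0 else max_edit_distance + 1 for d in dists]
        best = int(np.argmin(dists))
        if dists[best] <= max_edit_distance:
            vid, dist = vids[best], dists[best]
        elif support >= min_novel_support:
            if cons not in novel_seen:
                novel_seen[cons] = f"{pid}.novel{len(novel_seen) + 1}"
            vid, dist = novel_seen[cons], dists[best]
        else:
            continue
        records.append((bc, vid, pid, support, dist))
    out = pd.DataFrame(records, columns=["barcode", "variant_id", "promoter_id",
                                         "read_support", "edit_distance"])
    return out.sort_values("barcode", ignore_index=True)


def count_barcodes(barcode_reads: dict[tuple[str, int], list[str]],
                   mapping: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact-match barcode tallies per (condition, replicate) sample.

    ``barcode_reads`` maps (condition, replicate) to the DNA- and RNA-side
    barcode sequences observed in that sample, given as a dict with keys
    ``("dna", condition, replicate)`` and ``("rna", condition, replicate)``.
    Returns (CountTable, unmapped tally).
    """
    known = set(mapping["barcode"])
    tallies: dict[tuple[str, int], dict[str, list[int]]] = {}
    unmapped_rows = []
    for key, seqs in barcode_reads.items():
        kind, condition, replicate = key
        if kind not in {"dna", "rna"}:
            raise ValueError(f"sample key {key!r}: first field must be dna/rna")
        counts = Counter(seqs)
        sample = tallies.setdefault((condition, replicate), {})
        n_unmapped = 0
        for bc, k in counts.items():
            if bc not in known:
                n_unmapped += k
                continue
            entry = sample.setdefault(bc, [0, 0])
            entry[0 if kind == "dna" else 1] += k
        unmapped_rows.append((condition, replicate, kind, n_unmapped))
    rows = []
    for (condition, replicate), sample in tallies.items():
        for bc, (d, r) in sample.items():
            rows.append((bc, condition, replicate, d, r))
    table = pd.DataFrame(rows, columns=["barcode", "condition", "replicate",
                                        "dna_count", "rna_count"])
    unmapped = pd.DataFrame(unmapped_rows, columns=["condition", "replicate",
                                                    "kind", "n_unmapped"])
    return table.sort_values(["condition", "replicate", "barcode"],
                             ignore_index=True), unmapped


def aggregate_variant_counts(counts: pd.DataFrame,
                             mapping: pd.DataFrame) -> pd.DataFrame:
    """Sum barcode counts per variant; emit per-variant barcode multiplicity.

    Variants present in the mapping but absent from ``counts`` appear with
    zero counts and n_barcodes 0.  Returns columns promoter_id, variant_id,
    condition, replicate, dna_count, rna_count, n_barcodes.
    """
    merged = counts.merge(mapping[["barcode", "variant_id", "promoter_id"]],
                          on="barcode", how="inner")
    grouped = (merged.groupby(["promoter_id", "variant_id", "condition",
                               "replicate"], sort=False)
               .agg(dna_count=("dna_count", "sum"),
                    rna_count=("rna_count", "sum"),
                    n_barcodes=("barcode", "nunique"))
               .reset_index())
    # variants whose barcodes were all filtered still get a row per sample
    samples = counts[["condition", "replicate"]].drop_duplicates()
    variants = mapping[["promoter_id", "variant_id"]].drop_duplicates()
    full = variants.merge(samples, how="cross")
    out = full.merge(grouped, on=["promoter_id", "variant_id", "condition",
                                  "replicate"], how="left")
    out[["dna_count", "rna_count", "n_barcodes"]] = (
        out[["dna_count", "rna_count", "n_barcodes"]].fillna(0).astype(int))
    return out


def median_barcodes_per_variant(mapping: pd.DataFrame) -> float:
    """Median number of retained barcodes per mapped variant."""
    return float(mapping.groupby("variant_id")["barcode"].nunique().median())
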