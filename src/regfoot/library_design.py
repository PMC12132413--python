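"""Design of mutagenized promoter libraries and barcode assignments.

A reporter library is built from a 160-bp TSS-anchored promoter window:
1500 variants are drawn by mutating every position independently at a rate of
0.1 per base (substitutions only, uniform over the three alternatives), the
unmutated wild type is included once, and each variant receives one or more
randomized 20-bp DNA barcodes that are unique across the whole pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coords import DOWNSTREAM, UPSTREAM, WINDOW_LENGTH, axis_labels

BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: constant oligo flanks (restriction sites plus primer pads) that surround the
#: variable promoter region on the synthesized oligo; carried in manifests for
#: completeness, never used analytically.
SPEI_SITE = "ACTAGT"
APAI_SITE = "GGGCCC"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array (A=0,...,T=3)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    if (out < 0).any():
        raise ValueError("sequence contains characters outside ACGT")
    return out


def ints_to_seq(ints: np.ndarray) -> str:
    return "".join(BASES[ints])


@dataclass(frozen=True)
class PromoterRegion:
    """A 160-bp promoter window anchored at the transcription start site."""

    promoter_id: str
    gene: str
    tss: int
    strand: str
    sequence: str

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(
                f"promoter window must be {WINDOW_LENGTH} bases, got {len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError("promoter sequence must be over ACGT")

    @property
    def offsets(self) -> np.ndarray:
        """Axis labels -115..-1, +1..+45 for each base of ``sequence``."""
        return axis_labels()


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the mutagenesis and barcoding design."""

    mutation_rate: float = 0.1
    n_variants: int = 1500
    barcode_length: int = 20
    min_barcodes_per_variant: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")


@dataclass
class VariantLibrary:
    """Mutant pool for one promoter: sequences plus per-position mutation masks."""

    promoter_id: str
    variant_ids: list[str]
    sequences: list[str]
    masks: np.ndarray  # (n_entries, L) boolean, True where base != wild type
    wildtype_id: str

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def wildtype_sequence(self) -> str:
        return self.sequences[self.variant_ids.index(self.wildtype_id)]

    def mutation_frequency(self) -> float:
        """Mean fraction of mutated (variant, position) cells, wild type excluded."""
        keep = [i for i, v in enumerate(self.variant_ids) if v != self.wildtype_id]
        return float(self.masks[keep].mean())


@dataclass(frozen=True)
class BarcodeAssignment:
    barcode: str
    variant_id: str
    promoter_id: str


def extract_window(reference: str, tss: int, strand: str, *, promoter_id: str = "prom",
                   gene: str = "") -> PromoterRegion:
    """Cut the 160-bp window from 115 bp upstream to 45 bp downstream of a TSS.

    ``tss`` is the 0-based reference coordinate of the +1 base.  For minus-strand
    promoters "upstream" lies at higher reference coordinates, so the genomic
    interval [tss-44, tss+116) is taken and reverse-complemented; the returned
    sequence always reads -115..+45 in the direction of transcription.
    """
    reference = reference.upper()
    if strand == "+":
        start, end = tss - UPSTREAM, tss + DOWNSTREAM
    elif strand == "-":
        start, end = tss - DOWNSTREAM + 1, tss + UPSTREAM + 1
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if start < 0 or end > len(reference):
        raise IndexError(
            f"promoter window [{start}, {end}) exceeds reference of length {len(reference)}"
        )
    window = reference[start:end]
    if strand == "-":
        window = reverse_complement(window)
    return PromoterRegion(promoter_id=promoter_id, gene=gene, tss=tss,
                          strand=strand, sequence=window)


def mutate_variants(region: PromoterRegion, config: DesignConfig,
                    rng: np.random.Generator | None = None) -> VariantLibrary:
    """Draw the mutant pool: each position mutated independently at ``mutation_rate``.

    Substituted bases are uniform over the three non-wild-type alternatives;
    no insertions or deletions are generated.  The wild type is entry 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    wt = seq_to_ints(region.sequence)
    L = wt.size
    if L == 0:
        raise ValueError("empty promoter region")
    n = config.n_variants
    mask = rng.random((n, L)) < config.mutation_rate
    # offset 1..3 from the wild-type base, mod 4, is uniform over alternatives
    offsets = rng.integers(1, 4, size=(n, L), dtype=np.int8)
    seqs = np.where(mask, (wt[None, :] + offsets) % 4, wt[None, :]).astype(np.int8)

    variant_ids = [f"{region.promoter_id}.wt"]
    sequences = [region.sequence]
    masks = np.zeros((n + 1, L), dtype=bool)
    masks[1:] = mask
    width = len(str(n))
    for i in range(n):
        variant_ids.append(f"{region.promoter_id}.v{i + 1:0{width}d}")
        sequences.append(ints_to_seq(seqs[i]))
    return VariantLibrary(promoter_id=region.promoter_id, variant_ids=variant_ids,
                          sequences=sequences, masks=masks,
                          wildtype_id=variant_ids[0])


def draw_barcode_counts(n_variants: int, median: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-variant barcode multiplicities with a configured median.

    Counts are Poisson(``median``) clamped below at 1; at the multiplicities
    realistic for these libraries (median 13-28) the Poisson median equals its
    integer mean, so the realized pool median reproduces the configured value.
    """
    if median < 1:
        raise ValueError("median barcode count must be >= 1")
    return np.maximum(1, rng.poisson(median, size=n_variants))


def _random_barcodes(n: int, length: int, rng: np.random.Generator,
                     taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            bc = ints_to_seq(row)
            if bc not in taken:
                taken.add(bc)
                out.append(bc)
    return out


def assign_barcodes(library: VariantLibrary,
                    per_variant: int | Sequence[int],
                    config: DesignConfig,
                    rng: np.random.Generator | None = None,
                    taken: set[str] | None = None) -> list[BarcodeAssignment]:
    """Assign randomized barcodes, unique across the pool (collisions redrawn)."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    if taken is None:
        taken = set()
    n_entries = len(library)
    if np.isscalar(per_variant):
        counts = np.full(n_entries, int(per_variant))
    else:
        counts = np.asarray(per_variant, dtype=int)
        if counts.size != n_entries:
            raise ValueError("per_variant length must match the library")
    if (counts < 1).any():
        raise ValueError("every variant needs at least one barcode")
    total = int(counts.sum()) + len(taken)
    if total > 4 ** config.barcode_length:
        raise ValueError(
            f"cannot draw {total} unique barcodes of length {config.barcode_length}"
        )
    assignments: list[BarcodeAssignment] = []
    for vid, k in zip(library.variant_ids, counts):
        for bc in _random_barcodes(int(k), config.barcode_length, rng, taken):
            assignments.append(BarcodeAssignment(bc, vid, library.promoter_id))
    return assignments


def design_pool(promoters: Iterable[PromoterRegion],
                config: DesignConfig) -> tuple[dict[str, VariantLibrary], pd.DataFrame]:
    """Build libraries for every promoter and the flat pool manifest.

    The manifest holds one row per synthesized oligo: all mutants plus one
    wild-type entry per promoter, n_promoters x (n_variants + 1) rows total.
    """
    promoters = list(promoters)
    ids = [p.promoter_id for p in promoters]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate promoter_ids in the design")
    rng = np.random.default_rng(config.rng_seed)
    libraries: dict[str, VariantLibrary] = {}
    rows = []
    for region in promoters:
        lib = mutate_variants(region, config, rng=rng)
        libraries[region.promoter_id] = lib
        for vid, seq in zip(lib.variant_ids, lib.sequences):
            rows.append((region.promoter_id, vid, seq))
    manifest = pd.DataFrame(rows, columns=["promoter_id", "variant_id", "sequence"])
    return libraries, manifest
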