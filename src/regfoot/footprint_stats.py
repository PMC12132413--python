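"""Information footprints and expression-shift matrices.

The information footprint is the per-position mutual information (in bits)
between the mutation status of a base (wild type vs mutated) and the
sequencing class of a read (DNA vs RNA): positions that matter for expression
change the RNA/DNA balance of the variants mutated there.  The expression
shift matrix complements it with sign: for every position and substituted
base, the mean change in log2 expression relative to variants carrying the
wild-type base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .coords import WINDOW_LENGTH, axis_labels
from .library_design import VariantLibrary, seq_to_ints

#: per-cell pseudocount stabilizing the plug-in MI estimator and count ratios
PSEUDOCOUNT = 0.5


@dataclass
class Footprint:
    """Per-position mutual information footprint for one promoter sample."""

    promoter_id: str
    condition: str
    replicate: int | str
    mi: np.ndarray          # (L,) bits
    coverage: np.ndarray    # (L,) mutant read mass informing each position

    def __post_init__(self):
        self.mi = np.asarray(self.mi, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.mi.shape != self.coverage.shape:
            raise ValueError("mi and coverage must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": axis_labels()[: self.mi.size],
            "mi_bits": self.mi, "coverage": self.coverage,
        })


@dataclass
class ExpressionShiftMatrix:
    """4 x L matrix of mean log2-expression shifts; wild-type cells are zero."""

    promoter_id: str
    condition: str
    replicate: int | str
    shifts: np.ndarray           # (4, L), NaN where no variant carries that base
    wildtype: np.ndarray         # (L,) int codes of the wild-type base
    coverage: np.ndarray = field(default=None)  # (4, L) variant support per cell

    def mean_shift(self, start: int, end: int,
                   weights: np.ndarray | None = None) -> float:
        """Coverage-weighted mean shift of mutations within [start, end)."""
        block = self.shifts[:, start:end]
        mask = np.isfinite(block).astype(float)
        wt_cols = self.wildtype[start:end]
        mask[wt_cols, np.arange(end - start)] = 0.0
        if self.coverage is not None:
            mask *= self.coverage[:, start:end]
        if weights is not None:
            mask *= weights[None, start:end]
        total = mask.sum()
        if total == 0:
            return float("nan")
        return float(np.nansum(np.where(mask > 0, block, 0.0) * mask) / total)


def mutual_information_2x2(table: np.ndarray, pseudocount: float = 0.0) -> float:
    """Plug-in mutual information (bits) of one 2x2 contingency table."""
    n = np.asarray(table, dtype=float) + pseudocount
    total = n.sum()
    if total == 0:
        raise ValueError("all-zero contingency table")
    p = n / total
    pm = p.sum(axis=1, keepdims=True)
    pmu = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pm * pmu))
    return float(np.nansum(terms))


def information_footprint(counts: pd.DataFrame, library: VariantLibrary,
                          pseudocount: float = PSEUDOCOUNT) -> Footprint:
    """Compute the information footprint from aggregated variant counts.

    ``counts`` holds one promoter x condition x replicate slice with columns
    variant_id, dna_count, rna_count.  At every position the 2x2 table
    n(mutation status, read class) is accumulated by weighting each variant
    with its DNA and RNA counts; the plug-in MI with a per-cell pseudocount
    is returned.  Positions with zero mutant mass get MI 0 and coverage 0.
    """
    vid_index = {v: i for i, v in enumerate(library.variant_ids)}
    idx = counts["variant_id"].map(vid_index)
    if idx.isna().any():
        raise ValueError("counts reference variants absent from the library")
    dna = np.zeros(len(library))
    rna = np.zeros(len(library))
    np.add.at(dna, idx.to_numpy(int), counts["dna_count"].to_numpy(float))
    np.add.at(rna, idx.to_numpy(int), counts["rna_count"].to_numpy(float))
    if dna.sum() + rna.sum() == 0:
        raise ValueError("count table is all zero")

    masks = library.masks  # (n, L)
    mut_dna = masks.T @ dna
    mut_rna = masks.T @ rna
    wt_dna = dna.sum() - mut_dna
    wt_rna = rna.sum() - mut_rna

    n = np.stack([wt_dna, wt_rna, mut_dna, mut_rna], axis=1) + pseudocount
    total = n.sum(axis=1, keepdims=True)
    p = n / total
    pm_wt = p[:, 0] + p[:, 1]
    pm_mut = p[:, 2] + p[:, 3]
    pmu_dna = p[:, 0] + p[:, 2]
    pmu_rna = p[:, 1] + p[:, 3]
    marg = np.stack([pm_wt * pmu_dna, pm_wt * pmu_rna,
                     pm_mut * pmu_dna, pm_mut * pmu_rna], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / marg)
    mi = np.nansum(terms, axis=1)

    coverage = mut_dna + mut_rna
    mi[coverage == 0] = 0.0
    cond = counts["condition"].iloc[0] if "condition" in counts else ""
    rep = counts["replicate"].iloc[0] if "replicate" in counts else 0
    return Footprint(promoter_id=library.promoter_id, condition=cond,
                     replicate=rep, mi=mi, coverage=coverage)


def expression_shift_matrix(counts: pd.DataFrame, library: VariantLibrary,
                            pseudocount: float = PSEUDOCOUNT
                            ) -> ExpressionShiftMatrix:
    """Mean log2-expression shift of every substitution at every position.

    Each variant's expression is rho = (rna + psi) / (dna + psi), normalized
    by the library-wide RNA/DNA totals; the shift Delta(i, b) is the mean
    log2(rho) over variants carrying base b at i minus the mean over variants
    carrying the wild-type base.  Wild-type cells are exactly zero; cells no
    variant covers are NaN.
    """
    vid_index = {v: i for i, v in enumerate(library.variant_ids)}
    idx = counts["variant_id"].map(vid_index)
    if idx.isna().any():
        raise ValueError("counts reference variants absent from the library")
    dna = np.zeros(len(library))
    rna = np.zeros(len(library))
    np.add.at(dna, idx.to_numpy(int), counts["dna_count"].to_numpy(float))
    np.add.at(rna, idx.to_numpy(int), counts["rna_count"].to_numpy(float))
    norm = (dna.sum() + pseudocount) / (rna.sum() + pseudocount)
    log_rho = np.log2((rna + pseudocount) / (dna + pseudocount) * norm)

    base_codes = np.stack([seq_to_ints(s) for s in library.sequences])  # (n, L)
    wt_codes = seq_to_ints(library.wildtype_sequence)
    L = wt_codes.size

    sums = np.zeros((4, L))
    support = np.zeros((4, L))
    for b in range(4):
        carrier = base_codes == b
        sums[b] = carrier.T @ log_rho
        support[b] = carrier.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = sums / support
    cols = np.arange(L)
    shifts = means - means[wt_codes, cols][None, :]
    shifts[wt_codes, cols] = 0.0
    shifts[support == 0] = np.nan
    cond = counts["condition"].iloc[0] if "condition" in counts else ""
    rep = counts["replicate"].iloc[0] if "replicate" in counts else 0
    return ExpressionShiftMatrix(promoter_id=library.promoter_id, condition=cond,
                                 replicate=rep, shifts=shifts, wildtype=wt_codes,
                                 coverage=support)


def smooth_footprint(fp: Footprint, sigma: float) -> Footprint:
    """Gaussian smoothing of the footprint (reflective boundaries)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    smoothed = gaussian_filter1d(fp.mi, sigma=sigma, mode="reflect")
    return Footprint(promoter_id=fp.promoter_id, condition=fp.condition,
                     replicate=fp.replicate, mi=smoothed, coverage=fp.coverage)


def combine_replicates(counts: pd.DataFrame, library: VariantLibrary,
                       pseudocount: float = PSEUDOCOUNT) -> Footprint:
    """Footprint of the count-sum over replicates (not an MI average)."""
    pooled = counts.copy()
    pooled["replicate"] = "pooled"
    return information_footprint(pooled, library, pseudocount)
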