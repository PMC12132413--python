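"""Ground-truth dataset generation for pipeline validation.

Every downstream stage of the package is testable without sequencing data:
a planted regulatory architecture (RNAP site plus transcription-factor sites
with known energy matrices and condition-dependent activities) drives a
thermodynamic expression model, and DNA/RNA barcode counts are drawn from it
with realistic library structure -- 1500 mutants per promoter at 10 %
mutation rate, multiple barcodes per variant, lognormal abundance jitter and
multinomial sequencing noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .coords import label_to_index, index_to_label
from .library_design import (BarcodeAssignment, VariantLibrary, ints_to_seq,
                             seq_to_ints)
from .thermo import (EnergyMatrix, RegArchitecture, RegSite, expression_rate,
                     mismatch_matrix)

COUNT_COLUMNS = ["barcode", "condition", "replicate", "dna_count", "rna_count"]


def barcode_map_frame(assignments: list[BarcodeAssignment]) -> pd.DataFrame:
    return pd.DataFrame([asdict(a) for a in assignments],
                        columns=["barcode", "variant_id", "promoter_id"])


def variant_rates(library: VariantLibrary, arch: RegArchitecture,
                  condition: str) -> np.ndarray:
    """Expression rate of every library entry in one condition."""
    return np.array([
        expression_rate(seq, arch, condition) for seq in library.sequences
    ])


def simulate_counts(library: VariantLibrary, barcode_map: pd.DataFrame,
                    arch: RegArchitecture, conditions: list[str],
                    depth_dna: int, depth_rna: int, seed: int,
                    n_replicates: int = 2, abundance_sigma: float = 0.3,
                    overdispersion: float | None = None) -> pd.DataFrame:
    """Draw a DNA/RNA barcode count table for every condition and replicate.

    DNA counts are multinomial over barcodes with lognormal abundance jitter;
    RNA counts are multinomial with probabilities proportional to abundance
    times the variant's thermodynamic expression rate.  ``overdispersion``
    (Dirichlet concentration scale) optionally adds the extra-multinomial
    noise real libraries show; by default counts are exactly multinomial.
    """
    if depth_dna <= 0 or depth_rna <= 0:
        raise ValueError("sequencing depths must be positive")
    bmap = barcode_map[barcode_map["promoter_id"] == library.promoter_id]
    vid_index = {v: i for i, v in enumerate(library.variant_ids)}
    missing = set(library.variant_ids) - set(bmap["variant_id"])
    if missing:
        raise ValueError(f"{len(missing)} variants have no barcode")
    rng = np.random.default_rng(seed)
    barcodes = bmap["barcode"].to_numpy()
    variant_of = np.array([vid_index[v] for v in bmap["variant_id"]])
    abundance = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=barcodes.size)

    rows = []
    for condition in conditions:
        rates = variant_rates(library, arch, condition)
        rna_weight = abundance * rates[variant_of]
        if rna_weight.sum() <= 0:
            raise ValueError(f"zero total expression in condition {condition!r}")
        for rep in range(1, n_replicates + 1):
            p_dna = abundance / abundance.sum()
            p_rna = rna_weight / rna_weight.sum()
            if overdispersion is not None:
                p_dna = rng.dirichlet(p_dna * overdispersion)
                p_rna = rng.dirichlet(p_rna * overdispersion)
            dna = rng.multinomial(depth_dna, p_dna)
            rna = rng.multinomial(depth_rna, p_rna)
            rows.append(pd.DataFrame({
                "barcode": barcodes, "condition": condition, "replicate": rep,
                "dna_count": dna, "rna_count": rna,
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_reads(library: VariantLibrary, barcode_map: pd.DataFrame,
                   n_reads: int, error_rate: float, seed: int) -> pd.DataFrame:
    """Paired mapping reads: variant-side sequence and barcode-side sequence.

    Each read pair picks a barcode uniformly at random and copies the designed
    variant and barcode sequences with independent per-base substitution
    errors at ``error_rate``.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    bmap = barcode_map[barcode_map["promoter_id"] == library.promoter_id]
    rng = np.random.default_rng(seed)
    seq_of = dict(zip(library.variant_ids, library.sequences))
    if n_reads == 0:
        return pd.DataFrame(columns=["variant_read", "barcode_read"])
    pick = rng.integers(0, len(bmap), size=n_reads)
    v_reads, b_reads = [], []
    for i in pick:
        row = bmap.iloc[i]
        v_reads.append(_with_errors(seq_of[row["variant_id"]], error_rate, rng))
        b_reads.append(_with_errors(row["barcode"], error_rate, rng))
    return pd.DataFrame({"variant_read": v_reads, "barcode_read": b_reads})


def _with_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0.0:
        return seq
    ints = seq_to_ints(seq)
    hit = rng.random(ints.size) < error_rate
    if hit.any():
        ints = ints.copy()
        ints[hit] = (ints[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return ints_to_seq(ints)


# ---------------------------------------------------------------------------
# Planted architectures

def default_architecture(library: VariantLibrary, rng: np.random.Generator,
                         active_conditions: list[str],
                         inactive_conditions: list[str] | None = None,
                         include_repressor: bool = False) -> RegArchitecture:
    """RNAP at -40..-1 plus a condition-specific activator at -75..-55.

    Energy matrices take the wild type as consensus with per-position
    mismatch penalties in k_BT: Uniform(0.5, 1.5) for the polymerase site and
    Uniform(2, 3) for transcription-factor sites.  Weights put the bare
    promoter at weak occupancy (p ~ 0.05), the activator at half occupancy
    with ~25-fold stabilization -- the steep part of its occupancy curve, so
    site mutations move expression severalfold and every site is visible in
    an information footprint.  With ``include_repressor`` a constitutively
    active repressor (~15-fold repression at the wild type) is added at
    -100..-85.
    """
    wt = library.wildtype_sequence
    sites = [_site_on_wt("rnap", "rnap", -40, -1, wt, rng, weight=0.05,
                         penalty_range=(0.5, 1.5))]
    # half-occupied at the wild type so mutations shift occupancy steeply
    sites.append(_site_on_wt("activator", "activator", -75, -55, wt, rng,
                             weight=1.0, omega=25.0,
                             penalty_range=(2.0, 3.0)))
    if include_repressor:
        sites.append(_site_on_wt("repressor", "repressor", -100, -85, wt, rng,
                                 weight=15.0, penalty_range=(2.0, 3.0)))
    activity: dict[str, dict[str, float]] = {}
    for cond in active_conditions:
        activity[cond] = {"activator": 1.0}
    for cond in (inactive_conditions or []):
        activity[cond] = {"activator": 0.0}
    return RegArchitecture(promoter_id=library.promoter_id, sites=sites,
                           condition_activity=activity)


def repressor_architecture(library: VariantLibrary, rng: np.random.Generator,
                           active_conditions: list[str],
                           inactive_conditions: list[str] | None = None
                           ) -> RegArchitecture:
    """RNAP at -40..-1 plus a condition-specific repressor at -60..-45."""
    wt = library.wildtype_sequence
    sites = [
        _site_on_wt("rnap", "rnap", -40, -1, wt, rng, weight=0.3,
                    penalty_range=(0.5, 1.5)),
        _site_on_wt("repressor", "repressor", -60, -45, wt, rng, weight=15.0,
                    penalty_range=(2.0, 3.0)),
    ]
    activity: dict[str, dict[str, float]] = {}
    for cond in active_conditions:
        activity[cond] = {"repressor": 1.0}
    for cond in (inactive_conditions or []):
        activity[cond] = {"repressor": 0.0}
    return RegArchitecture(promoter_id=library.promoter_id, sites=sites,
                           condition_activity=activity)


def null_architecture(library: VariantLibrary) -> RegArchitecture:
    """Flat expression: an all-zero RNAP matrix, no sequence dependence."""
    site = RegSite(name="rnap", kind="rnap", start=label_to_index(-40),
                   end=label_to_index(-1) + 1,
                   matrix=EnergyMatrix(np.zeros((4, 40))), weight=0.1)
    return RegArchitecture(promoter_id=library.promoter_id, sites=[site])


def _site_on_wt(name: str, kind: str, start_label: int, end_label: int, wt: str,
                rng: np.random.Generator, weight: float, omega: float = 1.0,
                penalty_range: tuple[float, float] = (1.0, 2.5)) -> RegSite:
    start = label_to_index(start_label)
    end = label_to_index(end_label) + 1
    penalties = rng.uniform(*penalty_range, size=end - start)
    matrix = mismatch_matrix(wt[start:end], penalties)
    return RegSite(name=name, kind=kind, start=start, end=end, matrix=matrix,
                   weight=weight, interaction_omega=omega)


def ground_truth_sites(arch: RegArchitecture) -> pd.DataFrame:
    """BED-like table of planted site intervals in promoter coordinates."""
    rows = [{
        "promoter_id": arch.promoter_id, "name": s.name, "kind": s.kind,
        "start": s.start, "end": s.end,
        "start_label": index_to_label(s.start),
        "end_label": index_to_label(s.end - 1),
    } for s in arch.sites]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Architecture JSON round-trip

def architecture_to_json(arch: RegArchitecture) -> str:
    payload = {
        "promoter_id": arch.promoter_id,
        "condition_activity": arch.condition_activity,
        "sites": [{
            "name": s.name, "kind": s.kind, "start": s.start, "end": s.end,
            "weight": s.weight, "interaction_omega": s.interaction_omega,
            "reference_energy": s.matrix.reference_energy,
            "epsilon": s.matrix.epsilon.tolist(),
        } for s in arch.sites],
    }
    return json.dumps(payload, indent=1)


def architecture_from_json(text: str) -> RegArchitecture:
    payload = json.loads(text)
    sites = [RegSite(
        name=s["name"], kind=s["kind"], start=s["start"], end=s["end"],
        matrix=EnergyMatrix(np.array(s["epsilon"]), s.get("reference_energy", 0.0)),
        weight=s["weight"], interaction_omega=s.get("interaction_omega", 1.0),
    ) for s in payload["sites"]]
    return RegArchitecture(promoter_id=payload["promoter_id"], sites=sites,
                           condition_activity=payload.get("condition_activity", {}))
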