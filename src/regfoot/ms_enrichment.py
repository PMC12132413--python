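"""Transcription-factor enrichment from DNA-chromatography mass spectrometry.

Bead-tethered binding-site oligos pull proteins out of cell lysate; protein
abundances from the target bait are compared with a control bait carrying no
specific binding site.  A protein is called enriched when its log2
target/control ratio clears a floor *and* its abundance ranks well above the
bulk of the proteome -- weakly abundant proteins (the CRP caveat) are
reported separately rather than called.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def enrichment_scores(table: pd.DataFrame,
                      pseudocount: float | None = None) -> pd.DataFrame:
    """Score every protein's enrichment of target over control bait.

    ``table`` needs columns protein_id, target, control (nonnegative
    abundances; a protein missing from one column counts as zero and is
    flagged).  The default pseudocount is half the smallest nonzero abundance
    in the table.  Returns records sorted by descending log2 ratio with the
    target-abundance percentile of each protein.
    """
    t = table.copy()
    for col in ("target", "control"):
        if col not in t.columns:
            raise ValueError(f"missing column {col!r}")
        t[col] = pd.to_numeric(t[col], errors="raise")
    flagged = t[["target", "control"]].isna().any(axis=1)
    t[["target", "control"]] = t[["target", "control"]].fillna(0.0)
    if (t[["target", "control"]] < 0).any().any():
        raise ValueError("abundances must be nonnegative")
    if pseudocount is None:
        nonzero = t[["target", "control"]].to_numpy()
        nonzero = nonzero[nonzero > 0]
        pseudocount = float(nonzero.min()) / 2 if nonzero.size else 1.0
    out = pd.DataFrame({
        "protein_id": t["protein_id"],
        "target_abundance": t["target"],
        "control_abundance": t["control"],
        "log2_ratio": np.log2((t["target"] + pseudocount)
                              / (t["control"] + pseudocount)),
        "flagged_missing": flagged.to_numpy(),
    })
    ranks = out["target_abundance"].rank(pct=True) * 100
    out["abundance_percentile"] = ranks
    return out.sort_values("log2_ratio", ascending=False, ignore_index=True)


def call_enriched(records: pd.DataFrame, ratio_floor: float = 2.0,
                  percentile_floor: float = 50.0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the ratio and abundance criteria to scored records.

    Returns (called, low_abundance): proteins clearing both floors, and
    proteins whose ratio clears the floor but whose abundance percentile does
    not -- candidate binders the assay cannot confidently detect.
    """
    if records.empty:
        return records.copy(), records.copy()
    high_ratio = records["log2_ratio"] >= ratio_floor
    abundant = records["abundance_percentile"] >= percentile_floor
    called = records[high_ratio & abundant].reset_index(drop=True)
    low_abundance = records[high_ratio & ~abundant].reset_index(drop=True)
    return called, low_abundance


def simulate_pulldown(n_null: int = 2000, planted_fold: float = 16.0,
                      noise_sigma: float = 0.25, seed: int = 0,
                      planted_percentile: float = 90.0) -> pd.DataFrame:
    """Synthetic abundance table: lognormal null proteome plus one binder.

    Null proteins have equal expected target and control abundances with
    independent lognormal measurement noise; the planted binder sits at
    ``planted_percentile`` of the control abundance distribution and is
    ``planted_fold`` times higher on the target bait.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=10.0, sigma=1.5, size=n_null)
    target = base * rng.lognormal(0.0, noise_sigma, n_null)
    control = base * rng.lognormal(0.0, noise_sigma, n_null)
    planted_base = float(np.percentile(base, planted_percentile))
    rows = pd.DataFrame({
        "protein_id": [f"null_{i:04d}" for i in range(n_null)],
        "target": target, "control": control,
    })
    planted = pd.DataFrame({
        "protein_id": ["planted_binder"],
        "target": [planted_base * planted_fold
                   * rng.lognormal(0.0, noise_sigma)],
        "control": [planted_base * rng.lognormal(0.0, noise_sigma)],
    })
    return pd.concat([rows, planted], ignore_index=True)
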