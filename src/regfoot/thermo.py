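"""Thermodynamic (Boltzmann-weight) model of transcription.

Expression from a promoter variant is modeled as the equilibrium probability
that RNA polymerase occupies its site.  Each regulatory site carries an
additive 4xL energy matrix (units of k_BT, beta = 1); a dimensionless weight
subsumes copy number, the non-specific background and the reference binding
energy.  Repressors act by competitive exclusion of the polymerase, activators
by a cooperativity factor omega > 1 that stabilizes the polymerase-bound
state.  Condition dependence enters through a per-condition active fraction in
[0, 1] for each transcription-factor site (the allosteric state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords import WINDOW_LENGTH
from .library_design import seq_to_ints


@dataclass
class EnergyMatrix:
    """Additive nucleotide-by-nucleotide binding energy model, in k_BT."""

    epsilon: np.ndarray  # (4, L), rows A,C,G,T
    reference_energy: float = 0.0

    def __post_init__(self):
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.ndim != 2 or self.epsilon.shape[0] != 4:
            raise ValueError("epsilon must be a 4 x L matrix")

    @property
    def site_length(self) -> int:
        return self.epsilon.shape[1]

    def gauge(self) -> "EnergyMatrix":
        """Return a copy with each column's minimum shifted to zero."""
        mins = self.epsilon.min(axis=0)
        return EnergyMatrix(self.epsilon - mins, self.reference_energy + mins.sum())


@dataclass
class RegSite:
    """One regulatory site: RNAP, activator or repressor.

    ``start``/``end`` are 0-based half-open indices into the 160-base window
    (use :func:`regfoot.coords.label_to_index` to convert promoter-axis
    labels).  ``weight`` is the dimensionless prefactor multiplying the
    Boltzmann factor; ``interaction_omega`` the RNAP cooperativity (> 1 for
    activators, exactly 1 for repressors).
    """

    name: str
    kind: str  # {"rnap", "activator", "repressor"}
    start: int
    end: int
    matrix: EnergyMatrix
    weight: float = 1.0
    interaction_omega: float = 1.0

    def __post_init__(self):
        if self.kind not in {"rnap", "activator", "repressor"}:
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.end - self.start != self.matrix.site_length:
            raise ValueError("site span must equal the energy-matrix length")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.interaction_omega <= 0:
            raise ValueError("omega must be > 0")
        if self.kind == "repressor" and self.interaction_omega != 1.0:
            raise ValueError("repressors act by exclusion; omega must be 1")


@dataclass
class RegArchitecture:
    """Ground-truth regulatory architecture of one promoter.

    ``condition_activity`` maps condition -> {site name -> active fraction in
    [0, 1]}; sites absent from a condition's map default to fully active
    (the RNAP site is always active).
    """

    promoter_id: str
    sites: list[RegSite]
    condition_activity: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if sum(s.kind == "rnap" for s in self.sites) != 1:
            raise ValueError("architecture must contain exactly one RNAP site")
        for cond, act in self.condition_activity.items():
            for name, a in act.items():
                if not 0.0 <= a <= 1.0:
                    raise ValueError(f"activity {a} for {name} in {cond} not in [0,1]")

    @property
    def rnap(self) -> RegSite:
        return next(s for s in self.sites if s.kind == "rnap")

    def tf_sites(self) -> list[RegSite]:
        return [s for s in self.sites if s.kind != "rnap"]

    def activity(self, condition: str, site: RegSite) -> float:
        if site.kind == "rnap":
            return 1.0
        return self.condition_activity.get(condition, {}).get(site.name, 1.0)


def site_energy(sequence: str | np.ndarray, site: RegSite) -> float:
    """Binding energy of ``site`` on a promoter window, in k_BT (additive)."""
    ints = seq_to_ints(sequence) if isinstance(sequence, str) else sequence
    if site.end > ints.size:
        raise ValueError("sequence window shorter than the site")
    idx = ints[site.start:site.end]
    e = site.matrix.epsilon[idx, np.arange(site.matrix.site_length)].sum()
    return float(site.matrix.reference_energy + e)


def expression_rate(sequence: str | np.ndarray, arch: RegArchitecture,
                    condition: str) -> float:
    """Equilibrium RNAP occupancy p_bound of a variant in one condition.

    p_bound = p * omega_eff / (1 + p * omega_eff + r) with
    p the RNAP Boltzmann weight, r the summed weights of active repressors
    (competitive exclusion) and omega_eff the activator stabilization factor
    in the simple-activation limit, each activator contributing through its
    occupancy and its cooperativity omega.
    """
    ints = seq_to_ints(sequence) if isinstance(sequence, str) else sequence
    e_rnap = site_energy(ints, arch.rnap)
    if np.isnan(e_rnap):
        raise ValueError("NaN RNAP binding energy")
    p = arch.rnap.weight * np.exp(-e_rnap)
    r = 0.0
    omega_eff = 1.0
    for site in arch.tf_sites():
        a = arch.activity(condition, site)
        if a == 0.0:
            continue
        w = site.weight * np.exp(-site_energy(ints, site))
        if np.isnan(w):
            raise ValueError(f"NaN binding energy for site {site.name}")
        if site.kind == "repressor":
            r += a * w
        else:
            omega_eff += a * w * (site.interaction_omega - 1.0) / (1.0 + w)
    return float(p * omega_eff / (1.0 + p * omega_eff + r))


def mismatch_matrix(consensus: str, penalties: np.ndarray | float) -> EnergyMatrix:
    """Energy matrix that is 0 on a consensus sequence and positive off it.

    ``penalties`` gives the cost (k_BT) of any mismatch at each position, as a
    scalar or a length-L vector.
    """
    cons = seq_to_ints(consensus)
    L = cons.size
    pen = np.broadcast_to(np.asarray(penalties, dtype=float), (L,))
    eps = np.tile(pen, (4, 1)).copy()
    eps[cons, np.arange(L)] = 0.0
    return EnergyMatrix(eps)
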