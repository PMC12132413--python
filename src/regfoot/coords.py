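"""Promoter coordinate conventions.

Footprints and binding-site calls are reported on a TSS-anchored axis running
from -115 (furthest upstream base) to +45 (furthest downstream base), with the
transcription start site itself at +1 and no position 0 — the convention used
on promoter figure axes throughout bacterial regulatory genomics.  Internally
everything is stored as 0-based, half-open indices into the 160-base window;
these helpers convert between the two.
"""

from __future__ import annotations

import numpy as np

#: bases upstream of the TSS included in the mutagenesis window
UPSTREAM = 115
#: bases downstream of (and including) the TSS
DOWNSTREAM = 45
#: total window length
WINDOW_LENGTH = UPSTREAM + DOWNSTREAM


def label_to_index(label: int) -> int:
    """Convert a promoter-axis label (-115..-1, +1..+45) to a window index."""
    if label == 0:
        raise ValueError("promoter axis has no position 0")
    if label < 0:
        idx = label + UPSTREAM
    else:
        idx = label + UPSTREAM - 1
    if not 0 <= idx < WINDOW_LENGTH:
        raise ValueError(f"label {label} outside the -{UPSTREAM}..+{DOWNSTREAM} axis")
    return idx


def index_to_label(idx: int) -> int:
    """Convert a 0-based window index to a promoter-axis label."""
    if not 0 <= idx < WINDOW_LENGTH:
        raise ValueError(f"index {idx} outside the {WINDOW_LENGTH}-base window")
    return idx - UPSTREAM if idx < UPSTREAM else idx - UPSTREAM + 1


def axis_labels() -> np.ndarray:
    """All 160 axis labels in window order (-115..-1, +1..+45)."""
    return np.array([index_to_label(i) for i in range(WINDOW_LENGTH)])
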