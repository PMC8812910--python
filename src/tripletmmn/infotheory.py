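"""Information-theoretic characterization of the triplet-stream paradigm.

Quantifies the predictability of the three manipulated stimulus
dimensions — *what* (triplet-ending identity), *where* (sound location) and
*when* (stimulus onset) — in bits:

* surprisal (information content) of an ending or location,
  ``h = log2(1/p)``;
* conditional entropy of the ending given the triplet root,
  ``H = sum_i p_i log2(1/p_i)``;
* entropy of the inter-stimulus-pause distribution, ``log2(n)`` for ``n``
  equiprobable pause durations (0 for isochronous presentation, where the
  pause set collapses to a single value).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from tripletmmn.paradigm import StreamConfig, TransitionTable

__all__ = [
    "information_content",
    "conditional_entropy",
    "isi_entropy",
    "PredictabilityTable",
    "predictability_table",
]


def information_content(p: float) -> float:
    """Surprisal of an event with probability ``p``, in bits.

    Parameters
    ----------
    p
        Occurrence probability, ``0 < p <= 1``.

    Returns
    -------
    float
        ``log2(1/p)``; 0 for a certain event.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {p}")
    return float(-np.log2(p))


def conditional_entropy(conditional_probs: Iterable[float], *, tol: float = 1e-8) -> float:
    """Entropy of an outcome given its context, in bits.

    ``conditional_probs`` is the conditional distribution over all possible
    outcomes (e.g. the two triplet endings given a root); it must be
    non-negative and sum to one within ``tol``.  The convention
    ``0 * log2(1/0) = 0`` applies.
    """
    p = np.asarray(list(conditional_probs), dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > tol:
        raise ValueError(f"probabilities sum to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def isi_entropy(n_levels: int) -> float:
    """Entropy in bits of a uniform distribution over ``n_levels`` pause
    durations.

    Isochronous presentation has a single pause value (``n_levels = 1``,
    entropy 0); the jittered mode draws from 301 equiprobable integer
    millisecond pauses (entropy ``log2(301) ≈ 8.23`` bits).
    """
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    return float(np.log2(n_levels))


@dataclass(frozen=True)
class PredictabilityTable:
    """Predictability values (bits) for the triplet-ending paradigm.

    One row per manipulated dimension: surprisal of high/low-probability
    endings (*what*), conditional entropy of the ending given the root,
    surprisal of standard/deviant locations (*where*), and the temporal
    entropy of the isochronous and jittered presentation modes (*when*).
    """

    ic_standard_ending: float
    ic_stat_deviant: float
    cond_entropy_ending: float
    ic_standard_location: float
    ic_deviant_location: float
    entropy_iso: float
    entropy_noniso: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def to_tsv(self) -> str:
        """Render as a two-column TSV (quantity, bits)."""
        rows = [("quantity", "bits")] + [
            (f.name, f"{getattr(self, f.name):.2f}") for f in fields(self)
        ]
        return "\n".join("\t".join(r) for r in rows) + "\n"


def predictability_table(tt: "TransitionTable", cfg: "StreamConfig") -> PredictabilityTable:
    """Compute the full predictability characterization of a design.

    ``entropy_noniso`` reflects the pause set of ``cfg``: the number of
    equiprobable integer-millisecond pauses in random mode, or 0 when the
    configuration itself is isochronous.
    """
    if cfg.soa_mode == "random":
        lo, hi = cfg.pause_range_ms
        n_pauses = hi - lo + 1
    else:
        n_pauses = 1
    return PredictabilityTable(
        ic_standard_ending=information_content(tt.p_ending_high),
        ic_stat_deviant=information_content(tt.p_ending_low),
        cond_entropy_ending=conditional_entropy([tt.p_ending_high, tt.p_ending_low]),
        ic_standard_location=information_content(tt.p_loc_std_ending),
        ic_deviant_location=information_content(1.0 - tt.p_loc_std_ending),
        entropy_iso=0.0,
        entropy_noniso=isi_entropy(n_pauses),
    )
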