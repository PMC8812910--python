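"""Triplet-stream stimulus generation.

The paradigm presents a continuous stream of sound triplets built from six
sounds, referred to by the labels A–F.  Sounds A–D form the two triplet
*roots* (AB and CD); E and F are the triplet *endings*.  Ending identity
follows the root with a high (0.9) or low (0.1) transition probability
(AB→E high / AB→F low; CD→F high / CD→E low), and every sound is presented
from a *standard* or *deviant* loudspeaker.  Crossing transition
probability with ending location yields four ending categories:

========================  =====================  ==========
category                  transition × location  probability
========================  =====================  ==========
standard                  high × standard        0.72
stat_deviant              low  × standard        0.08
phys_deviant              high × deviant         0.18
double_deviant            low  × deviant         0.02
========================  =====================  ==========

Blocks of 400 triplets realize these probabilities *exactly* by quota
construction, with root families balanced 200/200.  Triplets from the
low-transition-probability set (statistical and double deviants) are kept
at least three triplets apart.  Stimulus-onset asynchrony (SOA) is either
constant at 300 ms (isochronous mode) or 150 ms sound duration plus a
uniformly random integer pause of 0–300 ms (non-isochronous mode, SOA
uniform on 150–450 ms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROOT_FAMILIES",
    "ENDING_CATEGORIES",
    "LOW_PROBABILITY_CATEGORIES",
    "SoundPermutation",
    "TransitionTable",
    "StreamConfig",
    "TripletSpec",
    "build_block_composition",
    "arrange_stream",
    "assign_locations",
    "assign_timing",
    "generate_block_events",
    "generate_stream",
    "insert_targets_and_presses",
    "make_familiarity_block",
    "min_low_probability_gap",
]

ROOT_FAMILIES = ("AB", "CD")
ENDING_CATEGORIES = ("standard", "stat_deviant", "phys_deviant", "double_deviant")
#: categories whose ending has low transition probability; these triplets
#: are mutually separated in the stream
LOW_PROBABILITY_CATEGORIES = frozenset({"stat_deviant", "double_deviant"})

#: high-probability ending sound for each root family (Fig-style pairing:
#: AB→E / CD→F are the frequent continuations)
_HIGH_ENDING = {"AB": "E", "CD": "F"}
_LOW_ENDING = {"AB": "F", "CD": "E"}

EVENT_COLUMNS = [
    "onset_ms",
    "block",
    "triplet_index",
    "position",
    "sound",
    "side",
    "category",
    "is_target",
]


@dataclass(frozen=True)
class SoundPermutation:
    """Bijection from the six sound labels A–F to physical sound slots 0–5.

    The assignment of physical sounds to structural roles is permuted
    across participants so acoustic idiosyncrasies cannot bias
    condition contrasts.
    """

    mapping: tuple[int, ...] = (0, 1, 2, 3, 4, 5)

    LABELS = ("A", "B", "C", "D", "E", "F")

    def __post_init__(self) -> None:
        if sorted(self.mapping) != list(range(6)):
            raise ValueError("mapping must be a permutation of 0..5")

    def physical_index(self, label: str) -> int:
        return self.mapping[self.LABELS.index(label)]

    @classmethod
    def random(cls, rng: np.random.Generator) -> "SoundPermutation":
        return cls(tuple(int(i) for i in rng.permutation(6)))


@dataclass(frozen=True)
class TransitionTable:
    """Root→ending transition probabilities and location probabilities."""

    p_ending_high: float = 0.9
    p_ending_low: float = 0.1
    p_root_given_ending: float = 0.5
    p_loc_std_root: float = 0.95
    p_loc_std_ending: float = 0.80

    def __post_init__(self) -> None:
        probs = (
            self.p_ending_high,
            self.p_ending_low,
            self.p_root_given_ending,
            self.p_loc_std_root,
            self.p_loc_std_ending,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(self.p_ending_high + self.p_ending_low - 1.0) > 1e-12:
            raise ValueError("p_ending_high + p_ending_low must equal 1")

    @property
    def category_probabilities(self) -> dict[str, float]:
        """Occurrence probability of each ending category."""
        pl = self.p_loc_std_ending
        return {
            "standard": self.p_ending_high * pl,
            "stat_deviant": self.p_ending_low * pl,
            "phys_deviant": self.p_ending_high * (1.0 - pl),
            "double_deviant": self.p_ending_low * (1.0 - pl),
        }


@dataclass(frozen=True)
class StreamConfig:
    """Block structure and timing of a stimulus stream.

    ``soa_mode='random'`` uses 150 ms sounds followed by a uniformly random
    integer pause of 0–300 ms (SOA 150–450 ms, mean 300 ms);
    ``soa_mode='isochronous'`` uses 220 ms sounds with a fixed 80 ms pause
    (constant 300 ms SOA).
    """

    n_triplets_per_block: int = 400
    n_blocks: int = 6
    soa_mode: str = "random"
    stim_duration_ms: int = 150
    pause_range_ms: tuple[int, int] = (0, 300)
    min_separation: int = 3
    standard_side_first_block: str = "left"
    target_rate_per_min: float = 2.0
    inter_block_gap_ms: float = 4000.0

    def __post_init__(self) -> None:
        if self.soa_mode not in ("random", "isochronous"):
            raise ValueError(f"unknown soa_mode {self.soa_mode!r}")
        if self.standard_side_first_block not in ("left", "right"):
            raise ValueError("standard_side_first_block must be 'left' or 'right'")
        lo, hi = self.pause_range_ms
        if not 0 <= lo <= hi:
            raise ValueError("invalid pause range")

    @classmethod
    def isochronous(cls, **kwargs) -> "StreamConfig":
        kwargs.setdefault("soa_mode", "isochronous")
        kwargs.setdefault("stim_duration_ms", 220)
        kwargs.setdefault("pause_range_ms", (80, 80))
        return cls(**kwargs)

    @classmethod
    def random_soa(cls, **kwargs) -> "StreamConfig":
        return cls(**kwargs)

    def standard_side(self, block: int) -> str:
        """Standard loudspeaker side for a 1-based block (alternates)."""
        first = self.standard_side_first_block
        other = "right" if first == "left" else "left"
        return first if block % 2 == 1 else other


@dataclass(frozen=True)
class TripletSpec:
    """One triplet before location/timing assignment."""

    family: str  # 'AB' | 'CD'
    category: str  # one of ENDING_CATEGORIES

    @property
    def root_sounds(self) -> tuple[str, str]:
        return (self.family[0], self.family[1])

    @property
    def ending_sound(self) -> str:
        if self.category in ("standard", "phys_deviant"):
            return _HIGH_ENDING[self.family]
        return _LOW_ENDING[self.family]

    @property
    def ending_on_deviant_side(self) -> bool:
        return self.category in ("phys_deviant", "double_deviant")


def build_block_composition(
    cfg: StreamConfig, tt: TransitionTable
) -> list[TripletSpec]:
    """Exact-count multiset of triplets for one block.

    Category counts are ``n × p`` for the four ending probabilities and
    must be integers (otherwise the configuration is rejected); the root
    marginal is split exactly in half, and each category is divided across
    the two root families as evenly as its count permits while keeping the
    family totals equal.
    """
    n = cfg.n_triplets_per_block
    probs = tt.category_probabilities
    counts: dict[str, int] = {}
    for cat in ENDING_CATEGORIES:
        x = probs[cat] * n
        if abs(x - round(x)) > 1e-9:
            raise ValueError(
                f"n_triplets_per_block={n} gives non-integer quota "
                f"{x:.3f} for category {cat!r}"
            )
        counts[cat] = int(round(x))
    if n % 2:
        raise ValueError("n_triplets_per_block must be even to balance root families")

    per_family = {f: {} for f in ROOT_FAMILIES}
    totals = {f: 0 for f in ROOT_FAMILIES}
    for cat in ENDING_CATEGORIES:
        base, rem = divmod(counts[cat], 2)
        for f in ROOT_FAMILIES:
            per_family[f][cat] = base
        if rem:
            # give the odd count to whichever family is currently lighter
            f = min(ROOT_FAMILIES, key=lambda f: (totals[f], f))
            per_family[f][cat] += 1
        for f in ROOT_FAMILIES:
            totals[f] += per_family[f][cat]
    if totals["AB"] != totals["CD"]:
        raise ValueError(
            "category quotas cannot be balanced across root families "
            f"(AB={totals['AB']}, CD={totals['CD']})"
        )

    out = []
    for f in ROOT_FAMILIES:
        for cat in ENDING_CATEGORIES:
            out.extend([TripletSpec(f, cat)] * per_family[f][cat])
    return out


def min_low_probability_gap(sequence: Sequence[TripletSpec]) -> int:
    """Smallest number of intervening triplets between two consecutive
    low-transition-probability triplets (``len(sequence)`` if fewer than
    two occur)."""
    idx = [i for i, t in enumerate(sequence) if t.category in LOW_PROBABILITY_CATEGORIES]
    if len(idx) < 2:
        return len(sequence)
    return int(min(b - a for a, b in zip(idx, idx[1:]))) - 1


def arrange_stream(
    composition: Sequence[TripletSpec],
    cfg: StreamConfig,
    rng: np.random.Generator,
    *,
    max_repairs: int = 10_000,
    max_reshuffles: int = 50,
) -> list[TripletSpec]:
    """Pseudorandom triplet order with the separation constraint.

    A uniform shuffle is repaired by swapping offending low-probability
    triplets into admissible positions (bounded retries, then a fresh
    shuffle).  The resulting order is approximately, not exactly, uniform
    over admissible orders.
    """
    sep = cfg.min_separation
    items = list(composition)
    n = len(items)

    def neighbour_count(mask: np.ndarray) -> np.ndarray:
        """Number of low-probability triplets within ±sep of each position
        (excluding the position itself)."""
        c = np.concatenate([[0], np.cumsum(mask)])
        lo = np.maximum(np.arange(n) - sep, 0)
        hi = np.minimum(np.arange(n) + sep + 1, n)
        return c[hi] - c[lo] - mask

    for _ in range(max_reshuffles):
        order = [items[i] for i in rng.permutation(n)]
        low = np.array(
            [t.category in LOW_PROBABILITY_CATEGORIES for t in order], dtype=bool
        )
        for _ in range(max_repairs):
            near = neighbour_count(low)
            bad = np.flatnonzero(low & (near > 0))
            if not len(bad):
                return order
            i = int(bad[0])
            trial = low.copy()
            trial[i] = False  # positions judged as if the offender moved away
            candidates = np.flatnonzero(~low & (neighbour_count(trial) == 0))
            if not len(candidates):
                break  # reshuffle
            j = int(rng.choice(candidates))
            order[i], order[j] = order[j], order[i]
            low[i], low[j] = False, True
    raise RuntimeError(
        "could not satisfy the separation constraint; quotas may be too dense"
    )


def assign_locations(
    sequence: Sequence[TripletSpec],
    cfg: StreamConfig,
    tt: TransitionTable,
    rng: np.random.Generator,
    block: int = 1,
) -> list[dict]:
    """Expand triplets to per-sound records with loudspeaker sides.

    Root sounds fall on the deviant side independently with probability
    ``1 − p_loc_std_root`` (0.05); ending sides are already fixed by the
    category quota.  The standard side alternates across blocks.
    """
    std = cfg.standard_side(block)
    dev = "right" if std == "left" else "left"
    records = []
    for t_idx, trip in enumerate(sequence):
        for pos, sound in zip(("root1", "root2"), trip.root_sounds):
            side = dev if rng.random() < (1.0 - tt.p_loc_std_root) else std
            records.append(
                dict(
                    block=block,
                    triplet_index=t_idx,
                    position=pos,
                    sound=sound,
                    side=side,
                    category="root",
                    is_target=False,
                )
            )
        records.append(
            dict(
                block=block,
                triplet_index=t_idx,
                position="ending",
                sound=trip.ending_sound,
                side=dev if trip.ending_on_deviant_side else std,
                category=trip.category,
                is_target=False,
            )
        )
    return records


def assign_timing(
    records: list[dict],
    cfg: StreamConfig,
    rng: np.random.Generator,
    start_ms: float = 0.0,
) -> pd.DataFrame:
    """Attach strictly increasing onsets.

    Non-isochronous mode: SOA = sound duration + pause, the pause drawn
    uniformly from the integer milliseconds of ``pause_range_ms`` (301
    equiprobable values by default).  Isochronous mode: constant SOA.
    """
    lo, hi = cfg.pause_range_ms
    n = len(records)
    if cfg.soa_mode == "random":
        pauses = rng.integers(lo, hi + 1, size=n)
    else:
        pauses = np.full(n, lo)
    soas = cfg.stim_duration_ms + pauses
    onsets = start_ms + np.concatenate([[0.0], np.cumsum(soas[:-1])])
    df = pd.DataFrame(records)
    df.insert(0, "onset_ms", onsets.astype(float))
    return df[EVENT_COLUMNS]


def generate_block_events(
    cfg: StreamConfig,
    tt: TransitionTable,
    rng: np.random.Generator,
    block: int = 1,
    start_ms: float = 0.0,
) -> pd.DataFrame:
    """Composition → arrangement → locations → timing for one block."""
    comp = build_block_composition(cfg, tt)
    seq = arrange_stream(comp, cfg, rng)
    recs = assign_locations(seq, cfg, tt, rng, block=block)
    return assign_timing(recs, cfg, rng, start_ms=start_ms)


def generate_stream(
    cfg: StreamConfig,
    tt: TransitionTable,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Full multi-block event stream on a single experiment clock."""
    frames = []
    t0 = 0.0
    for b in range(1, cfg.n_blocks + 1):
        df = generate_block_events(cfg, tt, rng, block=b, start_ms=t0)
        frames.append(df)
        t0 = float(df["onset_ms"].iloc[-1]) + cfg.stim_duration_ms + cfg.inter_block_gap_ms
    out = pd.concat(frames, ignore_index=True)
    if not out["onset_ms"].is_monotonic_increasing:
        raise AssertionError("onsets must be strictly increasing")
    return out


def insert_targets_and_presses(
    events: pd.DataFrame,
    cfg: StreamConfig,
    rng: np.random.Generator,
    hit_rate: float = 0.979,
    rt_median_ms: float = 450.0,
    rt_sigma: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Insert cover-task target sounds between triplets and simulate
    button presses.

    Targets are placed at ``cfg.target_rate_per_min`` per minute at random
    inter-triplet boundaries; subsequent onsets shift by one extra SOA.
    A ``hit_rate`` fraction of targets receives a press with lognormal
    latency (median ``rt_median_ms``).

    Returns the augmented event table and a press table
    (``press_time_ms``, ``target_onset_ms``).
    """
    if not 0.0 <= hit_rate <= 1.0:
        raise ValueError("hit_rate must be in [0, 1]")
    ev = events.copy().reset_index(drop=True)
    duration_min = (ev["onset_ms"].iloc[-1] - ev["onset_ms"].iloc[0]) / 60_000.0
    n_targets = int(round(cfg.target_rate_per_min * duration_min))
    if n_targets == 0:
        return ev, pd.DataFrame(columns=["press_time_ms", "target_onset_ms"])

    # boundaries: rows where a new triplet starts (insert the target before it)
    starts = ev.index[(ev["position"] == "root1") & (ev["triplet_index"] > 0)]
    chosen = np.sort(rng.choice(starts, size=min(n_targets, len(starts)), replace=False))

    lo, hi = cfg.pause_range_ms
    rows = []
    shift = np.zeros(len(ev))
    total_shift = 0.0
    for k in chosen:
        if cfg.soa_mode == "random":
            soa = cfg.stim_duration_ms + int(rng.integers(lo, hi + 1))
        else:
            soa = cfg.stim_duration_ms + lo
        onset = ev["onset_ms"].iloc[k] + total_shift
        rows.append(
            dict(
                onset_ms=onset,
                block=int(ev["block"].iloc[k]),
                triplet_index=-1,
                position="target",
                sound="TARGET",
                side="both",
                category="target",
                is_target=True,
            )
        )
        total_shift += soa
        shift[k:] += soa
    ev["onset_ms"] = ev["onset_ms"] + shift
    out = (
        pd.concat([ev, pd.DataFrame(rows)], ignore_index=True)
        .sort_values("onset_ms", kind="stable")
        .reset_index(drop=True)
    )

    targets = out.loc[out["is_target"], "onset_ms"].to_numpy()
    hit = rng.random(len(targets)) < hit_rate
    lat = rt_median_ms * np.exp(rng.normal(0.0, rt_sigma, size=len(targets)))
    presses = pd.DataFrame(
        {
            "press_time_ms": targets[hit] + lat[hit],
            "target_onset_ms": targets[hit],
        }
    )
    return out, presses


def make_familiarity_block(
    tt: TransitionTable, rng: np.random.Generator
) -> pd.DataFrame:
    """Twelve two-alternative familiarity trials.

    Each of the four pairings (high-probability triplet first or second,
    for each root family) appears three times; exactly one member of every
    pair carries the high-probability ending, consecutive trials never
    share a root, and the correct choice is counterbalanced 6/6.

    With six trials per root family, "consecutive trials never share a
    root" forces strict alternation, so the order is drawn uniformly over
    admissible sequences by shuffling within each family and interleaving.
    """
    per_family = {}
    for fam in ROOT_FAMILIES:
        high = fam + _HIGH_ENDING[fam]
        low = fam + _LOW_ENDING[fam]
        trials = [(high, low, 1, fam), (low, high, 2, fam)] * 3
        per_family[fam] = [trials[i] for i in rng.permutation(len(trials))]
    first, second = (
        ROOT_FAMILIES if rng.random() < 0.5 else tuple(reversed(ROOT_FAMILIES))
    )
    order = [
        t
        for pair in zip(per_family[first], per_family[second])
        for t in pair
    ]
    return pd.DataFrame(
        order, columns=["first", "second", "correct_choice", "root"]
    ).assign(inter_triplet_pause_ms=335)
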