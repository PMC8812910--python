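"""Window means and from-scratch repeated-measures / mixed-design ANOVA.

ERP amplitudes are summarized as window means per subject × condition ×
ROI, the ROI axis re-expressed as scalp area (frontal/central/parietal) ×
lateralisation (left/midline/right), and evaluated with balanced
repeated-measures ANOVA.  The decomposition uses the classical balanced
least-squares identity: for every effect term the cell deviations are
obtained by Möbius inversion (inclusion–exclusion) over the marginal-means
lattice, each within-subject effect is tested against its own
effect × subject interaction stratum, and with a between-subjects factor
(isochronicity) subjects are nested in groups.

Effect sizes: classical η² = SS_effect / SS_total (corrected for the
grand mean) is the headline value; partial η² is reported alongside.
No sphericity correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WindowSpec",
    "WINDOWS",
    "ROI_FACTORS",
    "group_blocks",
    "window_means",
    "contrast_cells",
    "rm_anova",
    "anova_array",
    "interaction_contrast",
    "chance_test",
    "null_rejection_rate",
    "format_effect",
]


@dataclass(frozen=True)
class WindowSpec:
    """Named analysis latency window, bounds in ms post-onset
    (half-open on the sample grid)."""

    name: str
    lo_ms: float
    hi_ms: float

    def __post_init__(self) -> None:
        if not self.lo_ms < self.hi_ms:
            raise ValueError("window bounds must satisfy lo < hi")


WINDOWS = {
    "smmn_main": WindowSpec("smmn_main", 180.0, 260.0),
    "smmn_early": WindowSpec("smmn_early", 150.0, 200.0),
    "locmmn": WindowSpec("locmmn", 150.0, 220.0),
    "early_neg": WindowSpec("early_neg", 0.0, 100.0),
    "positivity": WindowSpec("positivity", 100.0, 200.0),
}

#: ROI name → (scalp area, lateralisation)
ROI_FACTORS = {
    f"{area}_{lat}": (area, {"left": "left", "middle": "midline", "right": "right"}[lat])
    for area in ("frontal", "central", "parietal")
    for lat in ("left", "middle", "right")
}


def group_blocks(block: int) -> int:
    """Experiment blocks 1–6 → block groups 1–3 ({1,2}, {3,4}, {5,6})."""
    if not 1 <= block <= 6:
        raise ValueError(f"block must be 1..6, got {block}")
    return (block + 1) // 2


def window_means(waveforms: pd.DataFrame, win: WindowSpec) -> pd.DataFrame:
    """Mean amplitude over a latency window, with the ROI axis split into
    area × lateralisation.

    ``waveforms``: DataFrame whose index includes a ``roi`` level (plus any
    condition levels, e.g. subject / category / block_group) and whose
    columns are sample times in ms.  Returns a long DataFrame with the
    index levels as columns plus ``area``, ``lateralisation`` and
    ``amplitude``.
    """
    t = waveforms.columns.to_numpy(dtype=float)
    in_win = (t >= win.lo_ms) & (t < win.hi_ms)
    if not in_win.any():
        raise ValueError(f"no samples inside window {win.name}")
    out = waveforms.loc[:, in_win].mean(axis=1).rename("amplitude").reset_index()
    out["area"] = out["roi"].map(lambda r: ROI_FACTORS[r][0])
    out["lateralisation"] = out["roi"].map(lambda r: ROI_FACTORS[r][1])
    return out.drop(columns="roi")


def contrast_cells(
    wm: pd.DataFrame,
    standard: str = "standard",
    deviant: str = "stat_deviant",
    factors: Sequence[str] = ("area", "lateralisation", "block_group"),
) -> pd.DataFrame:
    """Two-level deviance cell table for one condition contrast.

    Keeps only the two requested ending categories, relabels them as
    ``standard`` / ``deviant``, and averages amplitudes over any index
    factors not retained in ``factors``.
    """
    df = wm[wm["category"].isin([standard, deviant])].copy()
    if df.empty:
        raise ValueError(f"no rows for categories {standard!r}/{deviant!r}")
    df["deviance"] = np.where(df["category"] == standard, "standard", "deviant")
    keep = ["subject", "deviance"] + [f for f in factors if f in df.columns]
    return df.groupby(keep, as_index=False, observed=True)["amplitude"].mean()


def _check_balanced(cells: pd.DataFrame, subject: str, within: Sequence[str]) -> None:
    counts = cells.groupby([subject, *within], observed=True).size()
    full = 1
    for w in within:
        full *= cells[w].nunique()
    per_subj = counts.groupby(level=0).size()
    if (counts != 1).any() or (per_subj != full).any():
        missing = []
        subjects = cells[subject].unique()
        levels = [sorted(cells[w].unique()) for w in within]
        have = set(map(tuple, cells[[subject, *within]].itertuples(index=False)))
        from itertools import product

        for s in subjects:
            for combo in product(*levels):
                if (s, *combo) not in have:
                    missing.append((s, *combo))
        raise ValueError(f"unbalanced design; missing cells: {missing[:10]}")


def rm_anova(
    cells: pd.DataFrame,
    within: Sequence[str],
    between: str | None = None,
    subject: str = "subject",
    dv: str = "amplitude",
) -> pd.DataFrame:
    """Repeated-measures (optionally mixed) ANOVA on a balanced cell table.

    ``cells``: long DataFrame with one row per subject × within-cell.
    Returns an effect table with SS, dfs, F, p, and both η² variants; rows
    are all within effects/interactions, plus — with ``between`` — the
    between-subjects factor and its interactions.
    """
    cells = cells.copy()
    _check_balanced(cells, subject, within)
    subjects = np.sort(cells[subject].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    levels = {w: np.array(sorted(cells[w].unique())) for w in within}

    idx = cells.set_index([subject, *within])[dv]
    shape = (len(subjects),) + tuple(len(levels[w]) for w in within)
    y = np.empty(shape)
    order = pd.MultiIndex.from_product([subjects, *(levels[w] for w in within)])
    y.flat = idx.reindex(order).to_numpy()
    if np.isnan(y).any():
        raise ValueError("missing amplitude values in cell table")

    groups = None
    if between is not None:
        gmap = cells.groupby(subject, observed=True)[between].agg(
            lambda s: s.iloc[0] if s.nunique() == 1 else np.nan
        )
        if gmap.isna().any():
            raise ValueError(f"between factor {between!r} varies within subject")
        groups = gmap.reindex(subjects).to_numpy()
    return anova_array(y, list(within), groups=groups, between_name=between or "group")


def anova_array(
    y: np.ndarray,
    within_names: Sequence[str],
    groups: np.ndarray | None = None,
    between_name: str = "group",
) -> pd.DataFrame:
    """ANOVA core on an (subjects × within-levels...) array.

    Each within effect (and its interaction with the between factor) is
    tested against the corresponding effect × subject(within-group)
    stratum; the between factor is tested against subjects within groups.
    Requires equal group sizes.
    """
    y = np.asarray(y, dtype=float)
    n_subj = y.shape[0]
    k = y.ndim - 1
    if len(within_names) != k:
        raise ValueError("within_names must match array dimensions")
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    for name, n_lev in zip(within_names, y.shape[1:]):
        if n_lev < 2:
            raise ValueError(f"within factor {name!r} has fewer than 2 levels")

    if groups is None:
        g_labels = np.zeros(n_subj, dtype=int)
        n_groups = 1
    else:
        uniq, g_labels = np.unique(np.asarray(groups), return_inverse=True)
        n_groups = len(uniq)
        counts = np.bincount(g_labels)
        if not (counts == counts[0]).all():
            raise ValueError("groups must be of equal size")
        if counts[0] < 2:
            raise ValueError("need at least 2 subjects per group")

    within_axes = tuple(range(1, k + 1))
    lv = {ax: y.shape[ax] for ax in within_axes}

    def marginal(t: frozenset, b: int) -> np.ndarray:
        """Full-shape array of marginal means for grouping (t, b)."""
        m = y.mean(axis=tuple(ax for ax in within_axes if ax not in t), keepdims=True)
        if b == 0:  # collapse subjects entirely
            m = m.mean(axis=0, keepdims=True)
        elif b == 1:  # collapse subjects within each between-group
            out = np.empty_like(m)
            for g in range(n_groups):
                sel = g_labels == g
                out[sel] = m[sel].mean(axis=0, keepdims=True)
            m = out
        return np.broadcast_to(m, y.shape)

    # Möbius inversion over the (within-subset, subject-level) lattice;
    # subject level ordered none(0) < group(1) < subject(2)
    b_levels = (0, 1, 2) if n_groups > 1 else (0, 2)
    terms = [
        (frozenset(c), b)
        for r in range(k + 1)
        for c in combinations(within_axes, r)
        for b in b_levels
    ]
    terms.sort(key=lambda tb: (len(tb[0]), tb[1]))
    u: dict[tuple[frozenset, int], np.ndarray] = {}
    for t, b in terms:
        acc = marginal(t, b).copy()
        for (t2, b2), u2 in u.items():
            if t2 <= t and b2 <= b:
                acc -= u2
        u[(t, b)] = acc

    def df_of(t: frozenset, b: int) -> int:
        d = 1
        for ax in t:
            d *= lv[ax] - 1
        if b == 1:
            d *= n_groups - 1
        elif b == 2:
            d *= n_subj - n_groups if n_groups > 1 else n_subj - 1
        return d

    ss = {tb: float((arr * arr).sum()) for tb, arr in u.items()}
    # clear floating-point crumbs so degenerate (constant) strata give F = 0
    tol = max(float((y * y).sum()), 1.0) * 1e-12
    ss = {tb: (0.0 if v < tol else v) for tb, v in ss.items()}
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    def name_of(t: frozenset, b: int) -> str:
        parts = [within_names[ax - 1] for ax in sorted(t)]
        if b == 1:
            parts.append(between_name)
        return " × ".join(parts) if parts else between_name

    rows = []
    for t, b in terms:
        if b == 2 or (b == 0 and not t):
            continue  # error strata and grand mean
        err = (t, 2)
        ss_e, df_e = ss[err], df_of(*err)
        df_n = df_of(t, b)
        ms_n = ss[(t, b)] / df_n
        ms_e = ss_e / df_e
        F = ms_n / ms_e if ms_e > 0 else (0.0 if ms_n == 0 else np.inf)
        p = float(sps.f.sf(F, df_n, df_e)) if np.isfinite(F) else 0.0
        if F == 0.0:
            p = 1.0
        rows.append(
            dict(
                effect=name_of(t, b),
                SS=ss[(t, b)],
                df_num=df_n,
                df_den=df_e,
                SS_error=ss_e,
                F=F,
                p=p,
                eta_sq=ss[(t, b)] / ss_total if ss_total > 0 else 0.0,
                eta_sq_partial=(
                    ss[(t, b)] / (ss[(t, b)] + ss_e) if ss[(t, b)] + ss_e > 0 else 0.0
                ),
            )
        )
    out = pd.DataFrame(rows).set_index("effect")
    out.attrs["ss_total"] = ss_total
    return out


def interaction_contrast(
    cells_iso: pd.DataFrame,
    cells_noniso: pd.DataFrame,
    within: Sequence[str] = ("deviance", "area", "lateralisation", "block_group"),
) -> tuple[pd.DataFrame, dict]:
    """Mixed ANOVA across presentation modes.

    Combines two cohorts' cell tables with a between-subjects
    ``isochronicity`` factor and reports, in addition, per-group simple
    effects of deviance (estimate = mean deviant − standard amplitude,
    with the within-group F test).
    """
    frames = []
    for label, cells in (("isochronous", cells_iso), ("non-isochronous", cells_noniso)):
        df = cells.copy()
        df["isochronicity"] = label
        df["subject"] = [f"{label}:{s}" for s in df["subject"]]
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    within = [w for w in within if w in combined.columns]
    table = rm_anova(combined, within=within, between="isochronicity")

    simple = {}
    for label, cells in (("isochronous", cells_iso), ("non-isochronous", cells_noniso)):
        sub = rm_anova(cells, within=within)
        means = cells.groupby("deviance", observed=True)["amplitude"].mean()
        simple[label] = dict(
            estimate=float(means.get("deviant", np.nan) - means.get("standard", np.nan)),
            F=float(sub.loc["deviance", "F"]),
            p=float(sub.loc["deviance", "p"]),
        )
    return table, simple


def chance_test(scores: Sequence[float], chance: float = 0.5) -> tuple[float, float, float]:
    """One-sample two-sided t test of proportions against chance level.

    Returns (t, p, Cohen's d).  With zero variance the test degenerates:
    t and d are 0 when the mean equals chance (p = 1), ±inf otherwise
    (p = 0).
    """
    x = np.asarray(list(scores), dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 scores")
    sd = x.std(ddof=1)
    diff = x.mean() - chance
    if sd == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, 0.0
        return float(np.sign(diff) * np.inf), 0.0, float(np.sign(diff) * np.inf)
    t, p = sps.ttest_1samp(x, chance)
    return float(t), float(p), float(diff / sd)


def null_rejection_rate(
    n_sims: int,
    n_subjects: int = 21,
    shape: tuple[int, ...] = (2, 3, 3, 3),
    effect: str = "deviance",
    within_names: Sequence[str] = ("deviance", "area", "lateralisation", "block_group"),
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical type-I error of one within effect under the null.

    Each simulated cohort draws subject intercepts plus independent cell
    noise (both unit SD) with no condition effect.
    """
    rng = rng or np.random.default_rng()
    hits = 0
    for _ in range(n_sims):
        y = rng.standard_normal((n_subjects,) + shape)
        y += rng.standard_normal((n_subjects,) + (1,) * len(shape))
        table = anova_array(y, list(within_names))
        if table.loc[effect, "p"] < alpha:
            hits += 1
    return hits / n_sims


def format_effect(table: pd.DataFrame, effect: str) -> str:
    """Report one effect in conventional notation:
    ``F(df1, df2) = …, p …, η² = …``."""
    r = table.loc[effect]
    p = r["p"]
    p_str = "p < 0.001" if p < 0.001 else f"p = {p:.3f}"
    return (
        f"{effect}: F({int(r['df_num'])}, {int(r['df_den'])}) = {r['F']:.2f}, "
        f"{p_str}, η² = {r['eta_sq']:.3f}"
    )
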