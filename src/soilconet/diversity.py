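"""Community diversity and group-comparison statistics.

Shannon–Wiener diversity (natural log by default), taxon richness, relative
percent change of abundances between a treatment and its control, and
one-way ANOVA with Tukey-HSD compact letter displays in the style of soil
chemistry tables (mean ± SE with superscript letters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def shannon_index(counts, base: float | None = None) -> float:
    """Shannon–Wiener index H = −Σ p_i log p_i over taxa with p_i > 0.

    Natural log (nats) unless ``base`` is given.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def richness(counts) -> int:
    """Number of taxa with count > 0."""
    return int((np.asarray(counts) > 0).sum())


def relabund_change(p_treatment: float, p_control: float) -> float:
    """Relative percent change, 100·(p_t − p_c)/p_c."""
    if p_control == 0:
        raise ValueError("control proportion must be > 0")
    return 100.0 * (p_treatment - p_control) / p_control


@dataclass
class AnovaResult:
    levels: list[str]
    means: dict[str, float]
    sems: dict[str, float]
    F: float
    p: float
    letters: dict[str, str]
    alpha: float


def compact_letter_display(
    levels: list[str], sig_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one letter covering all levels; each significantly different
    pair splits every column containing both members, and columns that
    become subsets of another are absorbed.  Two levels share a letter iff
    they were never declared significantly different.
    """
    columns: list[set[str]] = [set(levels)]
    for a, b in sig_pairs:
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for new in (col - {b}, col - {a}):
                if new and not any(new <= other for other in columns):
                    columns.append(new)
    # deterministic letter order: by first member in the given level order
    pos = {lv: i for i, lv in enumerate(levels)}
    columns.sort(key=lambda c: min(pos[lv] for lv in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for letter, col in zip(alphabet, columns):
        for lv in levels:
            if lv in col:
                out[lv] += letter
    return out


def anova_oneway(groups: dict[str, list | np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA with Tukey-HSD letters.

    ``groups`` maps factor level → observations (each level needs >= 2).
    Levels that share a letter are not significantly different at ``alpha``
    under all-pairwise Tukey HSD.
    """
    levels = list(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for lv in levels:
        a = np.asarray(groups[lv], dtype=float)
        if a.size < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 observations")
        arrays.append(a)

    f_stat, p_val = stats.f_oneway(*arrays)
    if not np.isfinite(f_stat):  # zero within- and between-group variance
        f_stat, p_val = 0.0, 1.0

    tukey = stats.tukey_hsd(*arrays)
    sig = {
        (levels[i], levels[j])
        for i in range(len(levels))
        for j in range(i + 1, len(levels))
        if tukey.pvalue[i, j] < alpha
    }
    letters = compact_letter_display(levels, sig)
    return AnovaResult(
        levels=levels,
        means={lv: float(a.mean()) for lv, a in zip(levels, arrays)},
        sems={lv: float(stats.sem(a)) for lv, a in zip(levels, arrays)},
        F=float(f_stat),
        p=float(p_val),
        letters=letters,
        alpha=alpha,
    )
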