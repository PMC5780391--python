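"""Behavioural statistics: paired before/after comparisons, partner-preference
summaries, and the rank-correlation screen of behaviours against receptor
densities.

These are the descriptive and screening analyses that accompany the
heritability estimation: paired t-tests on per-animal before-mating vs
after-mating differences across a family of behaviours (with a Bonferroni
family-wise correction), a summary of the partner-preference distribution
(time in contact with the partner), and Spearman rank correlations between
every behaviour contrast (before, after, after - before) and the optical
density of vasopressin-receptor binding in each brain section.

Spearman P-values are exact (full permutation enumeration) at n <= 7 and
use the usual t-approximation above that; ties get average ranks.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bonferroni_alpha",
    "paired_before_after",
    "spearman_screen",
    "spearman_with_exact_p",
    "partner_preference_summary",
    "PartnerPreferenceSummary",
]

EXACT_P_MAX_N = 7


def bonferroni_alpha(family_size: int, base_alpha: float = 0.05) -> float:
    """Per-test significance level: base_alpha / family_size."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if not 0 < base_alpha < 1:
        raise ValueError("base_alpha must lie in (0, 1)")
    return base_alpha / family_size


def paired_before_after(
    measurements: pd.DataFrame,
    base_alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Paired t-tests of each behaviour across phases, Bonferroni-flagged.

    ``measurements`` is long-format with columns animal, assay, behaviour,
    phase ("before"/"after"), value.  Animals measured in only one phase
    are excluded (a warning reports the count); behaviours with fewer than
    two complete pairs are skipped.  The test is a classic paired t on the
    per-animal (after - before) differences; the significance flag uses
    ``base_alpha`` divided by the family size (defaulting to the number of
    behaviours tested).
    """
    required = {"animal", "assay", "behaviour", "phase", "value"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements needs columns {sorted(required)}")
    wide = measurements.pivot_table(
        index=["assay", "behaviour", "animal"], columns="phase", values="value",
        aggfunc="first",
    )
    for phase in ("before", "after"):
        if phase not in wide.columns:
            wide[phase] = np.nan
    n_unpaired = int(wide[["before", "after"]].isna().any(axis=1).sum())
    if n_unpaired:
        warnings.warn(
            f"excluded {n_unpaired} animal-behaviour pair(s) missing one phase",
            stacklevel=2,
        )
    wide = wide.dropna(subset=["before", "after"])
    rows = []
    for (assay, behaviour), grp in wide.groupby(level=["assay", "behaviour"]):
        before = grp["before"].to_numpy()
        after = grp["after"].to_numpy()
        n = before.size
        if n < 2:
            warnings.warn(
                f"behaviour {behaviour!r} ({assay}) skipped: fewer than 2 pairs",
                stacklevel=2,
            )
            continue
        diff = after - before
        if np.all(diff == 0):
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat, p_value = stats.ttest_rel(after, before)
        rows.append(
            {
                "assay": assay,
                "behaviour": behaviour,
                "n": n,
                "mean_before": before.mean(),
                "se_before": before.std(ddof=1) / math.sqrt(n),
                "mean_after": after.mean(),
                "se_after": after.std(ddof=1) / math.sqrt(n),
                "mean_diff": diff.mean(),
                "t": float(t_stat),
                "p": float(p_value),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no behaviour had two or more complete pairs")
    alpha = bonferroni_alpha(family_size or len(table), base_alpha)
    table["alpha"] = alpha
    table["significant"] = table["p"] < alpha
    return table


def _exact_spearman_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho: float) -> float:
    """Two-sided exact P by enumerating all permutations of one rank vector."""
    n = x_ranks.size
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    hits = 0
    total = 0
    threshold = abs(rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(xc[list(perm)] @ yc) / denom
        hits += abs(r) >= threshold
        total += 1
    return hits / total


def spearman_with_exact_p(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with an exact permutation
    P-value at n <= 7, t-approximation otherwise.

    Returns (nan, nan) when either vector is constant (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if n <= EXACT_P_MAX_N:
        p = _exact_spearman_p(xr, yr, rho)
    else:
        # t approximation on rho with n - 2 degrees of freedom
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def spearman_screen(
    behaviours: pd.DataFrame,
    densities: pd.DataFrame,
    base_alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Rank-correlate every behaviour contrast with every region section.

    For each behaviour the contrasts are the before value, the after value
    and the after - before difference; each is correlated with the density
    of every (region, section) including any total-average rows.  Pairs
    with a constant vector get NaN rho/P and are never flagged.  The
    significance threshold is ``base_alpha`` over ``family_size``
    (defaulting to the number of correlations actually computed — the
    screen's multiplicity divisor is deliberately explicit config).
    """
    wide = behaviours.pivot_table(
        index="animal", columns=["assay", "behaviour", "phase"], values="value",
        aggfunc="first",
    )
    dens = densities.pivot_table(
        index="animal", columns=["region", "section"], values="density",
        aggfunc="first",
    )
    rows = []
    for (assay, behaviour) in sorted(
        {(a, b) for a, b, _ in wide.columns}
    ):
        contrasts: dict[str, pd.Series] = {}
        if (assay, behaviour, "before") in wide.columns:
            contrasts["before"] = wide[(assay, behaviour, "before")]
        if (assay, behaviour, "after") in wide.columns:
            contrasts["after"] = wide[(assay, behaviour, "after")]
        if len(contrasts) == 2:
            contrasts["difference"] = contrasts["after"] - contrasts["before"]
        for contrast, bvals in contrasts.items():
            for (region, section) in dens.columns:
                joined = pd.concat([bvals, dens[(region, section)]], axis=1).dropna()
                if len(joined) < 4:
                    continue
                rho, p = spearman_with_exact_p(
                    joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
                )
                rows.append(
                    {
                        "assay": assay,
                        "behaviour": behaviour,
                        "contrast": contrast,
                        "region": region,
                        "section": section,
                        "n": len(joined),
                        "rho": rho,
                        "p": p,
                    }
                )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no behaviour-density pair had enough animals")
    alpha = bonferroni_alpha(family_size or len(table), base_alpha)
    table["alpha"] = alpha
    table["significant"] = table["p"] < alpha
    return table


@dataclass(frozen=True)
class PartnerPreferenceSummary:
    """Distribution summary of partner-contact time across males."""

    n: int
    mean: float
    se: float
    min: float
    max: float
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "se": self.se,
            "min": self.min,
            "max": self.max,
            "bin_edges": list(self.bin_edges),
            "bin_counts": list(self.bin_counts),
        }


def partner_preference_summary(
    values, bin_width: float = 10.0, upper: float | None = None
) -> PartnerPreferenceSummary:
    """Mean +/- SE, range and histogram counts of partner-contact durations.

    ``bin_width`` defaults to 10 (minutes, for a distribution histogram of
    a three-hour test); bins span 0 to ``upper`` (default: next bin edge
    above the maximum).  Bin counts always sum to n.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no partner-preference values supplied")
    if np.any(values < 0):
        raise ValueError("durations must be non-negative")
    vmax = float(values.max())
    if upper is None:
        upper = bin_width * max(1, math.ceil((vmax + 1e-9) / bin_width))
    edges = np.arange(0.0, upper + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    n = values.size
    return PartnerPreferenceSummary(
        n=n,
        mean=float(values.mean()),
        se=float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        min=float(values.min()),
        max=vmax,
        bin_edges=tuple(edges.tolist()),
        bin_counts=tuple(int(c) for c in counts),
    )
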