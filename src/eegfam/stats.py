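"""Replication-balanced two-way ANOVA and paired connectivity tests.

The single-electrode analysis asks whether band PSD depends on music
familiarity (2 levels) and on subject identity (n levels).  Because
subjects contribute unequal numbers of windows, every
(familiarity × subject) cell is first subsampled without replacement
to the global minimum cell size r ("replication balancing"), after
which a classical fixed-effects two-way ANOVA with interaction is fit
and Tukey HSD post-hoc comparisons are run on the subject factor.

The connectivity analysis aggregates one overall index per subject and
familiarity stratum and compares strata with a two-sided paired
t-test.

Significance thresholds follow the two analysis regimes (α = 0.05 for
the music geometry, α = 0.0001 for the video geometry) and no
multiple-testing correction is applied across electrodes or bands —
a deliberate fidelity-over-best-practice choice, so treat per-table
p-values as descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BalancedPsdDesign",
    "AnovaOutcome",
    "PairedTestOutcome",
    "balance_replications",
    "two_way_anova",
    "paired_connectivity_test",
    "familiarity_ratio_screen",
    "psd_cells_from_table",
    "familiarity_anova_scan",
    "connectivity_contrast_table",
]


class DesignError(ValueError):
    """A cell of the two-way design is unusable."""


@dataclass
class BalancedPsdDesign:
    """Long-format balanced design: every cell holds exactly r values."""

    data: pd.DataFrame  # columns: familiarity, subject, value
    r: int
    electrode: str | None = None
    band: str | None = None
    seed: int | None = None

    @property
    def familiarity_levels(self) -> list[str]:
        return sorted(self.data["familiarity"].unique())

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject"].unique())


@dataclass
class AnovaOutcome:
    """F/p for both main effects and the interaction, plus post-hoc."""

    f_familiarity: float
    p_familiarity: float
    f_subject: float
    p_subject: float
    f_interaction: float
    p_interaction: float
    dof: dict[str, int]
    high_greater: bool
    alpha: float
    tukey: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def familiarity_significant(self) -> bool:
        return self.p_familiarity < self.alpha


@dataclass
class PairedTestOutcome:
    """Two-sided paired t-test on per-subject overall indices."""

    t: float
    p: float
    direction: str  # 'high' or 'low': stratum with the larger mean
    n: int
    degenerate: bool = False
    electrode_pair: tuple[str, str] | None = None
    band: str | None = None
    method: str | None = None


def balance_replications(
    cells: Mapping[tuple[str, str], Sequence[float]], seed: int = 0
) -> BalancedPsdDesign:
    """Subsample every (familiarity, subject) cell to the minimum size.

    Each cell is drawn without replacement, independently, from a
    generator seeded with ``seed``; identical input + seed reproduces
    the identical subsample.  An empty cell raises
    :class:`DesignError` naming the cell.
    """
    if not cells:
        raise DesignError("no cells supplied")
    for key, values in cells.items():
        if len(values) == 0:
            raise DesignError(f"empty cell (familiarity={key[0]!r}, subject={key[1]!r})")
    r = min(len(v) for v in cells.values())
    rng = np.random.default_rng(seed)
    rows = []
    for key in sorted(cells):
        values = np.asarray(cells[key], dtype=float)
        chosen = values[rng.choice(len(values), size=r, replace=False)]
        for v in chosen:
            rows.append({"familiarity": key[0], "subject": key[1], "value": v})
    return BalancedPsdDesign(data=pd.DataFrame(rows), r=r, seed=seed)


def psd_cells_from_table(
    table: pd.DataFrame, electrode: str, band: str
) -> dict[tuple[str, str], np.ndarray]:
    """Group one PSD column into (familiarity_group, subject) cells.

    NaN entries (e.g. electrode exclusions) are dropped; subjects with
    no finite data in either stratum simply contribute no cell and
    will surface as a :class:`DesignError` during balancing if the
    design becomes incomplete.
    """
    col = f"PSD:{electrode}:{band}"
    if col not in table.columns:
        raise KeyError(f"column {col!r} not in table")
    cells: dict[tuple[str, str], np.ndarray] = {}
    for (fam, subject), grp in table.groupby(["familiarity_group", "subject_id"]):
        vals = grp[col].dropna().to_numpy()
        if vals.size:
            cells[(fam, subject)] = vals
    if not cells:
        raise DesignError(f"no usable data for {col}")
    subjects = {s for _, s in cells}
    for s in subjects:
        for fam in ("low", "high"):
            if (fam, s) not in cells:
                raise DesignError(f"empty cell (familiarity={fam!r}, subject={s!r})")
    return cells


def two_way_anova(
    design: BalancedPsdDesign, alpha: float = 0.05, post_hoc: bool = True
) -> AnovaOutcome:
    """Fixed-effects two-way ANOVA with interaction on a balanced design.

    Requires r >= 2 replications per cell (otherwise the within-cell
    error cannot be estimated).  With ``post_hoc`` enabled, Tukey HSD
    is run on the subject factor when it has more than two levels and
    its main effect is significant; the two-level familiarity factor
    needs no post-hoc beyond the main test.  Disable ``post_hoc`` in
    simulation loops that only consume the F tests.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if design.r < 2:
        raise DesignError("r must be >= 2 to estimate within-cell error")
    data = design.data
    a = data["familiarity"].nunique()
    b = data["subject"].nunique()
    model = ols("value ~ C(familiarity) * C(subject)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)

    def row(name: str) -> tuple[float, float]:
        return float(table.loc[name, "F"]), float(table.loc[name, "PR(>F)"])

    f_fam, p_fam = row("C(familiarity)")
    f_sub, p_sub = row("C(subject)")
    f_int, p_int = row("C(familiarity):C(subject)")
    dof = {
        "familiarity": a - 1,
        "subject": b - 1,
        "interaction": (a - 1) * (b - 1),
        "error": a * b * (design.r - 1),
    }
    means = data.groupby("familiarity")["value"].mean()
    high_greater = bool(means.get("high", np.nan) > means.get("low", np.nan))

    tukey = None
    if post_hoc and b > 2 and p_sub < alpha:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(data["value"], data["subject"], alpha=alpha)
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return AnovaOutcome(
        f_familiarity=f_fam,
        p_familiarity=p_fam,
        f_subject=f_sub,
        p_subject=p_sub,
        f_interaction=f_int,
        p_interaction=p_int,
        dof=dof,
        high_greater=high_greater,
        alpha=alpha,
        tukey=tukey,
    )


def paired_connectivity_test(
    overall_low: Sequence[float],
    overall_high: Sequence[float],
    electrode_pair: tuple[str, str] | None = None,
    band: str | None = None,
    method: str | None = None,
) -> PairedTestOutcome:
    """Two-sided paired t-test of per-subject overall indices.

    ``overall_low[i]`` and ``overall_high[i]`` must belong to the same
    subject.  With all differences exactly zero the outcome is the
    degenerate t = 0, p = 1; a non-zero constant difference (zero
    variance) yields an infinite t, p = 0, flagged degenerate.
    """
    low = np.asarray(overall_low, dtype=float)
    high = np.asarray(overall_high, dtype=float)
    if low.shape != high.shape:
        raise ValueError("paired vectors differ in length")
    n = low.size
    if n < 2:
        raise ValueError("need at least 2 paired subjects")
    d = high - low
    mean_d = d.mean()
    direction = "high" if mean_d > 0 else "low"
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean_d == 0.0:
            return PairedTestOutcome(0.0, 1.0, direction, n, degenerate=True,
                                     electrode_pair=electrode_pair, band=band,
                                     method=method)
        t = float(np.inf) if mean_d > 0 else float(-np.inf)
        return PairedTestOutcome(t, 0.0, direction, n, degenerate=True,
                                 electrode_pair=electrode_pair, band=band,
                                 method=method)
    res = sps.ttest_rel(high, low)
    return PairedTestOutcome(
        float(res.statistic), float(res.pvalue), direction, n,
        electrode_pair=electrode_pair, band=band, method=method,
    )


def familiarity_anova_scan(
    table: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
    post_hoc: bool = False,
) -> pd.DataFrame:
    """Replication-balanced ANOVA over every electrode × band PSD column.

    Returns one row per ``PSD:<electrode>:<band>`` column with the
    familiarity F and p, the direction flag (high-familiarity mean
    greater) and a significance flag at ``alpha`` — the layout of a
    per-electrode significance table.  Columns whose design is
    incomplete (e.g. after exclusions) are skipped.
    """
    rows = []
    for col in table.columns:
        if not col.startswith("PSD:"):
            continue
        _, electrode, band = col.split(":")
        try:
            cells = psd_cells_from_table(table, electrode, band)
            design = balance_replications(cells, seed=seed)
            out = two_way_anova(design, alpha=alpha, post_hoc=post_hoc)
        except DesignError:
            continue
        rows.append(
            {
                "electrode": electrode,
                "band": band,
                "F": out.f_familiarity,
                "p": out.p_familiarity,
                "high_greater": out.high_greater,
                "significant": out.p_familiarity < alpha,
                "r": design.r,
            }
        )
    return pd.DataFrame(
        rows, columns=["electrode", "band", "F", "p", "high_greater", "significant", "r"]
    )


def connectivity_contrast_table(conn: pd.DataFrame) -> pd.DataFrame:
    """Paired familiarity contrast per (electrode pair, band, method).

    ``conn`` is the long-format output of
    :func:`~eegfam.connectivity.connectivity_matrix` concatenated over
    recordings (it must carry ``familiarity_group``).  Per subject and
    stratum the indices are aggregated across stimuli (arithmetic mean
    for coherence/PSI, quadratic mean for correlation) and strata are
    compared with a two-sided paired t-test across subjects.
    """
    from .connectivity import aggregate_indices

    if conn["familiarity_group"].isna().any():
        raise ValueError("connectivity frame lacks familiarity_group")
    rows = []
    keys = ["electrode_1", "electrode_2", "band", "method"]
    for (e1, e2, band, method), grp in conn.groupby(keys):
        per_subject: dict[str, dict[str, float]] = {}
        for (subject, stratum), g in grp.groupby(["subject_id", "familiarity_group"]):
            per_subject.setdefault(subject, {})[stratum] = aggregate_indices(
                g["value"], method
            )
        subjects = sorted(
            s for s, v in per_subject.items() if {"low", "high"} <= set(v)
        )
        if len(subjects) < 2:
            continue
        low = [per_subject[s]["low"] for s in subjects]
        high = [per_subject[s]["high"] for s in subjects]
        out = paired_connectivity_test(low, high, electrode_pair=(e1, e2),
                                       band=band, method=method)
        rows.append(
            {
                "electrode_1": e1,
                "electrode_2": e2,
                "band": band,
                "method": method,
                "t": out.t,
                "p": out.p,
                "direction": out.direction,
                "n_subjects": out.n,
                "degenerate": out.degenerate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["electrode_1", "electrode_2", "band", "method", "t", "p",
                 "direction", "n_subjects", "degenerate"],
    )


def familiarity_ratio_screen(
    count_low: int, count_high: int, min_ratio: float = 0.30
) -> tuple[bool, str]:
    """Keep/drop decision for a subject's familiarity balance.

    The subject is dropped when ``min(high/low, low/high)`` falls
    below ``min_ratio`` (the screen is symmetric so an excess of
    either stratum disqualifies).  Returns ``(keep, reason)``.
    """
    if count_low < 0 or count_high < 0:
        raise ValueError("counts must be non-negative")
    if count_low == 0 and count_high == 0:
        return False, "no familiarity reports"
    if count_low == 0 or count_high == 0:
        return False, "one familiarity stratum empty (ratio 0)"
    ratio = min(count_high / count_low, count_low / count_high)
    if ratio < min_ratio:
        return False, f"imbalance ratio {ratio:.3f} < {min_ratio}"
    return True, f"ratio {ratio:.3f} >= {min_ratio}"
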