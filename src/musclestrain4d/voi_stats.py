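"""Muscle VOIs, strain indices at peak force, coactivation and statistics.

A volume of interest (VOI) is a small in-plane box (nominally 9.38 mm x
28.13 mm) placed inside one muscle and replicated over adjacent slices.
Strain indices (principal strains, maximum shear, volumetric strain) are
averaged over the VOI at the frame of maximum force; the compressive
principal strain L_l1 is reported as a magnitude.  Coactivation is the ratio
of antagonist (hamstrings) to agonist (quadriceps) average compressive
strain.

The statistics ladder mirrors standard practice for a within-subject
muscle x %MVC design: Shapiro-Wilk normality per cell gates between a
repeated-measures ANOVA (with Greenhouse-Geisser correction when Mauchly's
sphericity test fails) and nonparametric tests (Friedman across muscles per
%MVC level, Wilcoxon signed-rank between the two %MVC levels), with
Bonferroni-adjusted pairwise Wilcoxon post-hocs on a significant muscle
effect.  L_l2 is excluded from testing (values at noise level); descriptives
are mean +/- SD for normal data, median +/- IQR otherwise.

The Friedman p-value can be computed by full enumeration of within-subject
permutations (small tables), seeded Monte-Carlo permutation, or the
asymptotic chi-square; the statistic itself matches the classical
tie-corrected form.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import ForceTrace
from .strain import StrainField

__all__ = [
    "Voi",
    "StatsReport",
    "build_voi",
    "peak_force_frame",
    "extract_voi_indices",
    "coactivation_ratio",
    "friedman_statistic",
    "friedman_test",
    "bonferroni",
    "run_statistics",
    "simulate_voi_table",
    "QUADRICEPS",
    "HAMSTRINGS",
]

QUADRICEPS = ("VM", "VL", "VI", "RF")
HAMSTRINGS = ("SBF", "LBF", "SM", "ST")

#: strain indices carried per VOI row; lambda1 is stored as a magnitude
INDEX_COLUMNS = ("lambda1", "lambda2", "lambda3", "l_max", "l_vol")
#: indices entering the statistics ladder (lambda2 is at noise level)
TESTED_INDICES = ("lambda1", "lambda3", "l_max", "l_vol")


@dataclass
class Voi:
    """A muscle volume of interest: in-plane box replicated across slices."""

    muscle_label: str
    group: str
    center_voxel: tuple[int, int]
    center_slice: int
    extent_voxels: tuple[int, int]
    n_slices: int

    def __post_init__(self) -> None:
        if self.n_slices % 2 != 1:
            raise ValueError("n_slices must be odd (center +/- equal flanks)")

    def slices(self) -> tuple[slice, slice, slice]:
        """Index slices (x, y, z) of the VOI box."""
        wx, wy = self.extent_voxels
        cx, cy = self.center_voxel
        half = self.n_slices // 2
        return (
            slice(cx - wx // 2, cx - wx // 2 + wx),
            slice(cy - wy // 2, cy - wy // 2 + wy),
            slice(self.center_slice - half, self.center_slice + half + 1),
        )


def build_voi(
    muscle_label: str,
    center_mm: tuple[float, float, float],
    box_mm: tuple[float, float] = (9.38, 28.13),
    n_slices: int = 5,
    spacing: tuple[float, float, float] = (1.875, 1.875, 5.0),
    grid_shape: tuple[int, int, int] | None = None,
    group: str = "",
) -> Voi:
    """Convert a mm-specified box at a mm center into a voxel-space VOI.

    The box edge lengths are rounded to the nearest voxel count (minimum 1);
    the slice set is the center slice plus ``(n_slices - 1) / 2`` flanking
    slices on either side.  Raises if the box does not fit in ``grid_shape``.
    """
    cx = int(round(center_mm[0] / spacing[0]))
    cy = int(round(center_mm[1] / spacing[1]))
    cz = int(round(center_mm[2] / spacing[2]))
    wx = max(1, int(round(box_mm[0] / spacing[0])))
    wy = max(1, int(round(box_mm[1] / spacing[1])))
    voi = Voi(
        muscle_label=muscle_label,
        group=group,
        center_voxel=(cx, cy),
        center_slice=cz,
        extent_voxels=(wx, wy),
        n_slices=n_slices,
    )
    if grid_shape is not None:
        for sl, n in zip(voi.slices(), grid_shape):
            if sl.start < 0 or sl.stop > n:
                raise ValueError(
                    f"VOI {muscle_label} box [{sl.start}, {sl.stop}) exceeds "
                    f"volume extent {n}"
                )
    return voi


def peak_force_frame(force: ForceTrace) -> int:
    """Frame of maximum force; the earliest index on ties."""
    values = np.asarray(force.values, float)
    if values.size == 0:
        raise ValueError("empty force trace")
    return int(np.argmax(values))


def extract_voi_indices(
    strain_series: list[StrainField],
    voi: Voi,
    frame: int,
    subject_id: str = "s0",
    pct_mvc: float = 0.30,
) -> dict | None:
    """VOI-mean strain indices at one frame, as a table row.

    Means are taken over valid voxels only; if fewer than 50% of the VOI's
    voxels are valid the VOI is flagged and no row is returned.  ``lambda1``
    is the magnitude of the compressive (most negative) principal strain.
    """
    f = strain_series[frame]
    sl = voi.slices()
    valid = f.valid_mask[sl]
    n_total = valid.size
    if n_total == 0:
        raise ValueError("empty VOI box")
    if valid.sum() < 0.5 * n_total:
        warnings.warn(
            f"VOI {voi.muscle_label}: only {int(valid.sum())}/{n_total} valid "
            "voxels (<50%), row flagged and skipped",
            stacklevel=2,
        )
        return None
    lam = f.eigenvalues[sl][valid]
    return {
        "subject": subject_id,
        "muscle": voi.muscle_label,
        "group": voi.group,
        "pct_mvc": pct_mvc,
        "lambda1": float(np.abs(lam[:, 0]).mean()),
        "lambda2": float(lam[:, 1].mean()),
        "lambda3": float(lam[:, 2].mean()),
        "l_max": float(f.l_max[sl][valid].mean()),
        "l_vol": float(f.l_vol[sl][valid].mean()),
    }


def coactivation_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Antagonist/agonist compressive-strain ratio per subject and %MVC.

    Ratio of the hamstrings-group average |L_l1| to the quadriceps-group
    average.  A zero agonist denominator yields NaN with a warning.
    """
    rows = []
    for (subject, mvc), sub in table.groupby(["subject", "pct_mvc"]):
        ham = sub.loc[sub.group == "hamstrings", "lambda1"]
        quad = sub.loc[sub.group == "quadriceps", "lambda1"]
        if ham.empty or quad.empty:
            raise ValueError(f"missing group rows for subject {subject}")
        denom = quad.mean()
        if denom == 0:
            warnings.warn(f"zero agonist strain for subject {subject}",
                          stacklevel=2)
            ratio = float("nan")
        else:
            ratio = float(ham.mean() / denom)
        rows.append({"subject": subject, "pct_mvc": mvc, "ratio": ratio})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Friedman test with exact / Monte-Carlo / asymptotic p-values


def _row_ranks(data: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, np.asarray(data, float))


def friedman_statistic(data: np.ndarray) -> float:
    """Classical tie-corrected Friedman chi-square for an (n, k) table."""
    data = np.asarray(data, float)
    n, k = data.shape
    ranks = _row_ranks(data)
    col_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * (col_sums**2).sum() - 3.0 * n * (k + 1)
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts**3 - counts).sum()
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0
    return float(q / correction)


def _statistic_from_ranks(rank_rows: np.ndarray, correction: float) -> np.ndarray:
    """Vectorized statistic for (m, n, k) stacked rank tables."""
    n, k = rank_rows.shape[-2:]
    col_sums = rank_rows.sum(axis=-2)
    q = 12.0 / (n * k * (k + 1)) * (col_sums**2).sum(axis=-1) - 3.0 * n * (k + 1)
    return q / correction


def friedman_test(
    data: np.ndarray,
    method: str = "auto",
    n_perm: int = 4000,
    seed: int = 0,
    max_exact: int = 500_000,
) -> tuple[float, float]:
    """Friedman test for an (n subjects, k conditions) within-subject table.

    Returns ``(statistic, p_value)``.  ``method``:

    - ``"exact"``: full enumeration of all (k!)^n within-subject orderings of
      the observed ranks (the permutation null of the test);
    - ``"mc"``: seeded Monte-Carlo permutation (``n_perm`` draws);
    - ``"asymptotic"``: chi-square with k-1 degrees of freedom;
    - ``"auto"``: exact when (k!)^n <= ``max_exact``, else Monte-Carlo.
    """
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need an (n, k) table with k >= 2 conditions")
    n, k = data.shape
    stat = friedman_statistic(data)
    ranks = _row_ranks(data)
    ties = sum(
        (counts**3 - counts).sum()
        for row in ranks
        for _, counts in [np.unique(row, return_counts=True)]
    )
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        return stat, 1.0

    if method == "auto":
        method = "exact" if math.factorial(k) ** n <= max_exact else "mc"

    if method == "asymptotic":
        return stat, float(stats.chi2.sf(stat, k - 1))

    if method == "exact":
        if math.factorial(k) ** n > max_exact:
            raise ValueError("table too large for exact enumeration")
        acc = np.zeros((1, k))
        for row in ranks:
            perms = np.array(list(itertools.permutations(row)))
            acc = (acc[:, None, :] + perms[None, :, :]).reshape(-1, k)
        q = 12.0 / (n * k * (k + 1)) * (acc**2).sum(axis=1) - 3.0 * n * (k + 1)
        q = q / correction
        p = float(np.mean(q >= stat - 1e-12))
        return stat, p

    if method == "mc":
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_perm, n, k)), axis=-1)
        perm_ranks = np.take_along_axis(
            np.broadcast_to(ranks, (n_perm, n, k)), order, axis=-1
        )
        q = _statistic_from_ranks(perm_ranks, correction)
        p = float((1 + np.sum(q >= stat - 1e-12)) / (1 + n_perm))
        return stat, p

    raise ValueError(f"unknown method {method!r}")


def bonferroni(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Bonferroni adjustment: p * m, capped at 1."""
    p = np.asarray(p_values, float)
    return np.minimum(p * p.size, 1.0)


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p (exact where scipy supports it)."""
    d = np.asarray(x, float) - np.asarray(y, float)
    if np.all(d == 0):
        return 1.0
    res = stats.wilcoxon(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Statistics ladder


@dataclass
class IndexReport:
    """Ladder result for one strain index."""

    normality_p: dict
    all_normal: bool
    test: str
    muscle_p: float
    mvc_p: float
    muscle_p_by_level: dict = dc_field(default_factory=dict)
    sphericity: dict = dc_field(default_factory=dict)
    posthoc: list = dc_field(default_factory=list)
    descriptives: dict = dc_field(default_factory=dict)


@dataclass
class StatsReport:
    """Full report: one :class:`IndexReport` per tested strain index."""

    alpha: float
    indices: dict

    def to_dict(self) -> dict:
        out = {"alpha": self.alpha, "indices": {}}
        for name, rep in self.indices.items():
            out["indices"][name] = {
                "normality_p": {str(k): v for k, v in rep.normality_p.items()},
                "all_normal": rep.all_normal,
                "test": rep.test,
                "muscle_p": rep.muscle_p,
                "mvc_p": rep.mvc_p,
                "muscle_p_by_level": {
                    str(k): v for k, v in rep.muscle_p_by_level.items()
                },
                "sphericity": rep.sphericity,
                "posthoc": rep.posthoc,
                "descriptives": {str(k): v for k, v in rep.descriptives.items()},
            }
        return out


def _check_balanced(table: pd.DataFrame) -> tuple[list, list, list]:
    subjects = sorted(table.subject.unique())
    muscles = sorted(table.muscle.unique())
    levels = sorted(table.pct_mvc.unique())
    counts = table.groupby(["subject", "muscle", "pct_mvc"]).size()
    missing = [
        cell
        for cell in itertools.product(subjects, muscles, levels)
        if cell not in counts.index
    ]
    if missing or (counts != 1).any():
        dupes = [tuple(ix) for ix, c in counts.items() if c != 1]
        raise ValueError(
            f"unbalanced table; missing cells: {missing}; duplicated: {dupes}"
        )
    return subjects, muscles, levels


def _cell_matrix(table: pd.DataFrame, value: str, subjects: list,
                 muscles: list, level) -> np.ndarray:
    """(n_subjects, n_muscles) value matrix at one %MVC level."""
    sub = table[table.pct_mvc == level]
    piv = sub.pivot(index="subject", columns="muscle", values=value)
    return piv.loc[subjects, muscles].to_numpy()


def run_statistics(
    table: pd.DataFrame,
    alpha: float = 0.05,
    indices: tuple[str, ...] = TESTED_INDICES,
) -> StatsReport:
    """Run the normality-gated within-subject ladder on a balanced VOI table.

    For each index: Shapiro-Wilk per muscle x %MVC cell; if every cell is
    normal a two-way repeated-measures ANOVA gives the muscle and %MVC main
    effects (muscle effect Greenhouse-Geisser corrected when Mauchly's test
    fails); otherwise the muscle effect is tested by Friedman per %MVC level
    (reported per level plus a single Bonferroni-combined decision p) and the
    %MVC effect by exact Wilcoxon signed-rank on subject means across
    muscles.  A significant muscle effect triggers Bonferroni-adjusted
    pairwise Wilcoxon tests on subject values averaged over %MVC levels.
    """
    import pingouin as pg

    subjects, muscles, levels = _check_balanced(table)
    if len(levels) != 2:
        raise ValueError("the ladder expects exactly two %MVC levels")
    reports: dict[str, IndexReport] = {}
    for index in indices:
        normality: dict = {}
        for muscle in muscles:
            for level in levels:
                vals = table.loc[
                    (table.muscle == muscle) & (table.pct_mvc == level), index
                ].to_numpy()
                normality[(muscle, level)] = float(stats.shapiro(vals).pvalue)
        all_normal = all(p > alpha for p in normality.values())

        sphericity: dict = {}
        muscle_by_level: dict = {}
        if all_normal:
            aov = pg.rm_anova(
                data=table, dv=index, within=["muscle", "pct_mvc"],
                subject="subject", detailed=True,
            ).set_index("Source")
            collapsed = (
                table.groupby(["subject", "muscle"], as_index=False)[index].mean()
            )
            spher = pg.sphericity(
                data=collapsed, dv=index, subject="subject", within="muscle"
            )
            sphericity = {"W": float(spher.W), "p": float(spher.pval)}
            col = "p_unc" if spher.pval > alpha else "p_GG_corr"
            muscle_p = float(aov.loc["muscle", col])
            mvc_p = float(aov.loc["pct_mvc", "p_unc"])  # 2 levels: sphericity trivial
            test = "rm_anova"
        else:
            for level in levels:
                mat = _cell_matrix(table, index, subjects, muscles, level)
                _, p = friedman_test(mat)
                muscle_by_level[level] = p
            muscle_p = float(
                min(1.0, len(levels) * min(muscle_by_level.values()))
            )
            lo = (
                table[table.pct_mvc == levels[0]]
                .groupby("subject")[index].mean().loc[subjects].to_numpy()
            )
            hi = (
                table[table.pct_mvc == levels[1]]
                .groupby("subject")[index].mean().loc[subjects].to_numpy()
            )
            mvc_p = _wilcoxon_p(hi, lo)
            test = "friedman"

        posthoc = []
        if muscle_p < alpha and len(muscles) > 2:
            means = (
                table.groupby(["subject", "muscle"])[index]
                .mean().unstack().loc[subjects, muscles]
            )
            pairs = list(itertools.combinations(muscles, 2))
            raw = [
                _wilcoxon_p(means[a].to_numpy(), means[b].to_numpy())
                for a, b in pairs
            ]
            adj = bonferroni(raw)
            posthoc = [
                {"pair": [a, b], "p_raw": float(r), "p_adj": float(q)}
                for (a, b), r, q in zip(pairs, raw, adj)
            ]

        descriptives: dict = {}
        for muscle in muscles:
            for level in levels:
                vals = table.loc[
                    (table.muscle == muscle) & (table.pct_mvc == level), index
                ].to_numpy()
                if all_normal:
                    descriptives[(muscle, level)] = {
                        "kind": "mean+-sd",
                        "center": float(np.mean(vals)),
                        "spread": float(np.std(vals, ddof=1)),
                    }
                else:
                    q1, med, q3 = np.percentile(vals, [25, 50, 75])
                    descriptives[(muscle, level)] = {
                        "kind": "median+-iqr",
                        "center": float(med),
                        "spread": float(q3 - q1),
                    }

        reports[index] = IndexReport(
            normality_p=normality,
            all_normal=all_normal,
            test=test,
            muscle_p=muscle_p,
            mvc_p=mvc_p,
            muscle_p_by_level=muscle_by_level,
            sphericity=sphericity,
            posthoc=posthoc,
            descriptives=descriptives,
        )
    return StatsReport(alpha=alpha, indices=reports)


def simulate_voi_table(
    n_subjects: int = 12,
    muscles: tuple[str, ...] = QUADRICEPS,
    mvc_levels: tuple[float, float] = (0.30, 0.45),
    baseline: float = 0.20,
    mvc_effect: float = 0.0,
    muscle_effects: dict | None = None,
    subject_sd: float = 0.0,
    sigma: float = 0.05,
    index: str = "lambda1",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulated balanced VOI table for power / type-I studies.

    Values are ``baseline + muscle effect + mvc_effect * [level == high]
    + subject offset + N(0, sigma)``; all index columns carry the same draw
    so a chosen ``index`` can be analyzed.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    muscle_effects = muscle_effects or {}
    rows = []
    for s in range(n_subjects):
        offset = rng.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
        for muscle in muscles:
            for level in mvc_levels:
                val = (
                    baseline
                    + muscle_effects.get(muscle, 0.0)
                    + (mvc_effect if level == max(mvc_levels) else 0.0)
                    + offset
                    + rng.normal(0.0, sigma)
                )
                row = {
                    "subject": f"s{s:02d}",
                    "muscle": muscle,
                    "group": "quadriceps",
                    "pct_mvc": level,
                }
                row.update({col: val for col in INDEX_COLUMNS})
                rows.append(row)
    return pd.DataFrame(rows)
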