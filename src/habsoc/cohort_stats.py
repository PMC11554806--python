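"""Cohort-level statistics for sociability and social-approach measures.

Cohort sociability distributions are compared with a two-sample
Kolmogorov–Smirnov test on the per-pair values and displayed as
relative-frequency histograms.  Near-cup dwell times from the three-chamber
task are analyzed with a two-way ANOVA treating stimulus (social vs.
non-social) as a within-animal factor and genotype as a between-animal
factor, followed by uncorrected Fisher's LSD contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass(frozen=True)
class KSResult:
    statistic: float  # sup-gap D between empirical CDFs
    pvalue: float
    n: int
    m: int


def ks_two_sample(x, y) -> KSResult:
    """Two-sample Kolmogorov–Smirnov test.

    D is the exact supremum gap between the two empirical CDFs, evaluated by
    a sorted-merge sweep over the jump points of either sample (ties
    handled by evaluating after all jumps at a value).  The two-sided
    p-value uses the asymptotic Kolmogorov distribution with the effective
    sample size n·m/(n+m).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    # evaluate both ECDFs at every jump point of the pooled sample
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n
    cdf_y = np.searchsorted(y, pooled, side="right") / m
    d = float(np.abs(cdf_x - cdf_y).max())
    en = n * m / (n + m)
    p = float(np.clip(special.kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    return KSResult(d, p, n, m)


@dataclass(frozen=True)
class RelFreqHistogram:
    edges: np.ndarray
    frequencies: np.ndarray  # counts / n; sums to 1
    n: int


def relative_frequency_histogram(values, edges, *, clip: bool = False) -> RelFreqHistogram:
    """Histogram of counts/n with half-open bins (last bin closed).

    With ``clip=True`` out-of-range values are clipped into the end bins;
    otherwise they must already lie within ``[edges[0], edges[-1]]``.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if values.size == 0:
        raise ValueError("no values to histogram")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    if clip:
        values = np.clip(values, edges[0], edges[-1])
    elif values.min() < edges[0] or values.max() > edges[-1]:
        raise ValueError("values outside histogram range (use clip=True)")
    counts, _ = np.histogram(values, bins=edges)
    return RelFreqHistogram(edges, counts / values.size, int(values.size))


def significance_stars(p: float) -> str:
    """Reporting convention: *, **, *** at 0.05, 0.01, 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class FactorialResult:
    """Two-way mixed ANOVA (genotype between, stimulus within) with LSD posthocs."""

    cell_means: pd.DataFrame      # genotype × stimulus means and n
    anova: pd.DataFrame           # effect, ss, df, ms, F, p
    contrasts: pd.DataFrame       # LSD pairwise contrasts
    ss_total: float = 0.0
    notes: list[str] = field(default_factory=list)


def two_way_anova_lsd(
    table: pd.DataFrame,
    *,
    value: str = "value",
    genotype: str = "genotype",
    stimulus: str = "stimulus",
    animal: str = "animal",
) -> FactorialResult:
    """Repeated-measures two-way ANOVA with uncorrected Fisher's LSD.

    Each animal contributes one value per stimulus level (exactly two
    levels), so stimulus is a within-animal factor and genotype a
    between-animal factor.  The sums of squares split into a
    between-animals stratum (genotype + animals-within-genotype error) and a
    within-animals stratum (stimulus + genotype×stimulus + residual); the
    identity SS_total = Σ effect SS holds exactly.

    LSD contrasts: within-genotype stimulus differences use the
    within-stratum residual mean square (paired error); between-genotype
    differences at a fixed stimulus use the mean of the two error mean
    squares, the standard pooled error for mixed-design cell comparisons.
    No multiplicity correction is applied.
    """
    df = table[[animal, genotype, stimulus, value]].copy()
    stim_levels = sorted(df[stimulus].unique())
    if len(stim_levels) != 2:
        raise ValueError("exactly two stimulus levels required")
    wide = df.pivot_table(index=[animal, genotype], columns=stimulus,
                          values=value, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("every animal needs a value for both stimulus levels")
    wide = wide.reset_index()
    genos = sorted(wide[genotype].unique())
    counts = wide.groupby(genotype).size()
    if (counts < 2).any():
        raise ValueError("need at least 2 animals per genotype cell")

    y = wide[stim_levels].to_numpy(dtype=float)       # subjects × 2
    g = wide[genotype].to_numpy()
    subj_mean = y.mean(axis=1)
    diff = y[:, 1] - y[:, 0]                          # stim_levels[1] − [0]
    grand = y.mean()
    n_total = len(wide)
    n_g = {gg: int((g == gg).sum()) for gg in genos}
    G = len(genos)

    # between-animals stratum (each subject mean represents 2 observations)
    gmeans = {gg: subj_mean[g == gg].mean() for gg in genos}
    ss_geno = 2.0 * sum(n_g[gg] * (gmeans[gg] - grand) ** 2 for gg in genos)
    ss_subj = 2.0 * sum(
        ((subj_mean[g == gg] - gmeans[gg]) ** 2).sum() for gg in genos
    )
    df_subj = n_total - G

    # within-animals stratum, expressed through per-subject differences
    dmeans = {gg: diff[g == gg].mean() for gg in genos}
    dbar = diff.mean()
    ss_stim = n_total * dbar**2 / 2.0
    ss_inter = sum(n_g[gg] * (dmeans[gg] - dbar) ** 2 for gg in genos) / 2.0
    ss_resid = sum(((diff[g == gg] - dmeans[gg]) ** 2).sum() for gg in genos) / 2.0
    df_resid = n_total - G

    ms_subj = ss_subj / df_subj
    ms_resid = ss_resid / df_resid
    rows = []
    for name, ss, dof, err_ms, err_df in [
        (genotype, ss_geno, G - 1, ms_subj, df_subj),
        (stimulus, ss_stim, 1, ms_resid, df_resid),
        (f"{genotype} x {stimulus}", ss_inter, G - 1, ms_resid, df_resid),
    ]:
        ms = ss / dof
        f = ms / err_ms if err_ms > 0 else 0.0
        p = float(stats.f.sf(f, dof, err_df)) if err_ms > 0 else 1.0
        rows.append((name, ss, dof, ms, f, p))
    rows.append(("animals (error between)", ss_subj, df_subj, ms_subj, np.nan, np.nan))
    rows.append(("residual (error within)", ss_resid, df_resid, ms_resid, np.nan, np.nan))
    anova = pd.DataFrame(rows, columns=["effect", "ss", "df", "ms", "F", "p"])

    cell_rows = []
    for gg in genos:
        for k, s_level in enumerate(stim_levels):
            cell_rows.append((gg, s_level, y[g == gg, k].mean(), n_g[gg]))
    cells = pd.DataFrame(cell_rows, columns=[genotype, stimulus, "mean", "n"])

    # LSD contrasts
    contrasts = []
    for gg in genos:  # stimulus effect within genotype (paired)
        est = dmeans[gg]
        se = np.sqrt(2.0 * ms_resid / n_g[gg])
        t = est / se if se > 0 else 0.0
        p = 2.0 * float(stats.t.sf(abs(t), df_resid))
        contrasts.append((f"{gg}: {stim_levels[1]} - {stim_levels[0]}",
                          est, se, t, df_resid, p, significance_stars(p)))
    ms_pooled = (ss_subj + ss_resid) / (df_subj + df_resid)
    df_pooled = df_subj + df_resid
    for k, s_level in enumerate(stim_levels):  # genotype pairs at fixed stimulus
        for i1 in range(G):
            for i2 in range(i1 + 1, G):
                g1, g2 = genos[i1], genos[i2]
                est = y[g == g1, k].mean() - y[g == g2, k].mean()
                se = np.sqrt(ms_pooled * (1.0 / n_g[g1] + 1.0 / n_g[g2]))
                t = est / se if se > 0 else 0.0
                p = 2.0 * float(stats.t.sf(abs(t), df_pooled))
                contrasts.append((f"{s_level}: {g1} - {g2}",
                                  est, se, t, df_pooled, p, significance_stars(p)))
    contrasts = pd.DataFrame(
        contrasts, columns=["contrast", "estimate", "se", "t", "df", "p", "stars"]
    )

    ss_total = float(((y - grand) ** 2).sum())
    return FactorialResult(cells, anova, contrasts, ss_total=ss_total)
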