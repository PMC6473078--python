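"""Two-arm time-course responsiveness cascade.

The experimental design is an induction time course: cultures sampled at
t = 0, 10, 20, 40, 60, 120, 180 min after autoinducer (AHL) addition, with a
solvent-only (DMSO) control arm sequenced at t = 0, 60, 180 min. Per gene and
time point a negative-binomial likelihood-ratio test contrasts counts against
the pre-induction baseline; Benjamini-Hochberg adjustment converts raw
p-values to FDR. Two pooling choices stabilize the test at 3 replicates:
the t = 0 samples of both arms describe the same untreated culture and are
pooled into one baseline group (which also makes the AHL-DMSO fold-change
difference cancel the baseline exactly), and the gene-wise method-of-moments
dispersion is pooled over every (arm, time) cell of the series rather than
just the two groups of one contrast. A gene is called responsive when it passes the significance and
fold-change gates in the AHL arm at some time point AND its AHL response is
distinguishable from the control response at a sequenced control time
(otherwise the change is attributed to solvent or cultivation time and the
gene is flagged ``excluded_by_control``). The earliest gate-passing time point
is the gene's activation onset.

The DE statistic is a deliberately simple, self-contained test (method-of-
moments gene-wise dispersion, chi-square LRT); externally produced result
tables in the same schema can be fed to the filter cascade instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

AHL_TIMES = (0, 10, 20, 40, 60, 120, 180)
DMSO_TIMES = (0, 60, 180)
CONTROL_TIMES = (60, 180)

#: continuity constant added to group means before forming log2 fold changes
LFC_CONTINUITY = 0.5
#: lower bound for the method-of-moments dispersion estimate
DISPERSION_FLOOR = 1e-6


@dataclass
class ExpressionSeries:
    """Raw counts (genes x samples) with per-sample arm/time/replicate labels."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # index: sample name; columns: arm, time_min, replicate

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample sheet rows must match in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not (self.samples["time_min"] == 0).any():
            raise ValueError("the series must contain t = 0 samples")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def sample_names(self, arm: str, time: int) -> list[str]:
        m = (self.samples["arm"] == arm) & (self.samples["time_min"] == time)
        return list(self.samples.index[m])


def normalize_libsizes(series: ExpressionSeries) -> pd.Series:
    """Per-sample size factors: total count / geometric mean of totals."""
    totals = series.counts.sum(axis=0).astype(float)
    if series.counts.shape[0] == 0 or series.counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    geomean = float(np.exp(np.mean(np.log(totals))))
    return totals / geomean


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood, parameterized by mean and dispersion.

    Var = mu + phi*mu^2; phi is per gene (column vector broadcast over samples).
    Written with gammaln so that it is stable for phi down to the floor.
    """
    r = 1.0 / phi  # shape parameter
    mu = np.maximum(mu, 1e-12)
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def estimate_dispersion(
    series: ExpressionSeries, size_factors: pd.Series | None = None
) -> np.ndarray:
    """Gene-wise method-of-moments NB dispersion, pooled over all cells.

    Within each (arm, time) cell the NB model implies an expected residual sum
    of squares of (k-1)*(mu + phi*mu^2) around the cell mean mu; summing over
    cells and solving for phi gives
    phi = (sum_c SS_c - sum_c (k_c-1)*mu_c) / sum_c (k_c-1)*mu_c^2,
    floored at DISPERSION_FLOOR (negative estimates = Poisson-like genes).
    """
    if size_factors is None:
        size_factors = normalize_libsizes(series)
    norm = series.counts.to_numpy(float) / size_factors.to_numpy(float)
    col_index = {s: i for i, s in enumerate(series.counts.columns)}
    resid_ss = np.zeros(norm.shape[0])
    denom = np.zeros(norm.shape[0])
    for arm, t in series.samples[["arm", "time_min"]].drop_duplicates().itertuples(index=False):
        cols = [col_index[s] for s in series.sample_names(arm, int(t))]
        sub = norm[:, cols]
        k = len(cols)
        if k < 2:
            continue
        mu = sub.mean(axis=1)
        resid_ss += sub.var(axis=1, ddof=1) * (k - 1) - (k - 1) * mu
        denom += (k - 1) * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = resid_ss / np.where(denom > 0, denom, 1.0)
    return np.maximum(np.nan_to_num(phi, nan=DISPERSION_FLOOR), DISPERSION_FLOOR)


def de_test(
    series: ExpressionSeries,
    arm: str,
    time: int,
    size_factors: pd.Series | None = None,
    dispersion: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression of (arm, time) versus the t=0 baseline.

    The baseline pools the t = 0 samples of every arm (pre-induction, before
    the arms diverge). log2FC = log2((mean normalized count at t + c) /
    (mean at baseline + c)) with c = 0.5; p from a negative-binomial
    likelihood-ratio test with the pooled gene-wise method-of-moments
    dispersion. Genes with zero counts in both groups get log2FC = 0, p = 1.
    FDR is Benjamini-Hochberg across genes.
    """
    if time == 0:
        raise ValueError("contrast time must differ from the baseline t = 0")
    cols_t = series.sample_names(arm, time)
    cols_0 = list(series.samples.index[series.samples["time_min"] == 0])
    if len(cols_t) < 2 or len(cols_0) < 2:
        raise ValueError(f"contrast {arm} t={time} needs >= 2 replicates in both groups")
    if size_factors is None:
        size_factors = normalize_libsizes(series)
    if dispersion is None:
        dispersion = estimate_dispersion(series, size_factors)

    y_t = series.counts[cols_t].to_numpy(float)
    y_0 = series.counts[cols_0].to_numpy(float)
    s_t = size_factors[cols_t].to_numpy(float)
    s_0 = size_factors[cols_0].to_numpy(float)
    n_t = y_t / s_t
    n_0 = y_0 / s_0

    m_t = n_t.mean(axis=1)
    m_0 = n_0.mean(axis=1)
    log2fc = np.log2((m_t + LFC_CONTINUITY) / (m_0 + LFC_CONTINUITY))

    k_t, k_0 = n_t.shape[1], n_0.shape[1]
    grand_mean = (n_t.sum(axis=1) + n_0.sum(axis=1)) / (k_t + k_0)
    phi = np.asarray(dispersion, float)[:, None]
    y = np.hstack([y_t, y_0])
    s = np.concatenate([s_t, s_0])
    mu_alt = np.hstack([np.repeat(m_t[:, None], k_t, 1), np.repeat(m_0[:, None], k_0, 1)]) * s
    mu_null = grand_mean[:, None] * s
    lr = 2.0 * (_nb_loglik(y, mu_alt, phi) - _nb_loglik(y, mu_null, phi))
    pvals = stats.chi2.sf(np.maximum(lr, 0.0), df=1)

    allzero = (y_t.sum(axis=1) + y_0.sum(axis=1)) == 0
    log2fc[allzero] = 0.0
    pvals[allzero] = 1.0

    return pd.DataFrame(
        {
            "locus_tag": series.genes,
            "arm": arm,
            "time_min": time,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        }
    ).set_index("locus_tag", drop=False)


def de_test_all(
    series: ExpressionSeries, size_factors: pd.Series | None = None
) -> pd.DataFrame:
    """DE results for every non-zero (arm, time) present in the sample sheet."""
    if size_factors is None:
        size_factors = normalize_libsizes(series)
    dispersion = estimate_dispersion(series, size_factors)
    frames = []
    cells = (
        series.samples[["arm", "time_min"]].drop_duplicates().sort_values(["arm", "time_min"])
    )
    for arm, t in cells.itertuples(index=False):
        if t == 0:
            continue
        frames.append(de_test(series, arm, int(t), size_factors, dispersion))
    return pd.concat(frames, ignore_index=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d p-value vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def activation_time(
    gene_results: pd.DataFrame, fdr_max: float = 0.05, lfc_min: float = 1.0
) -> tuple[int | None, str | None]:
    """Earliest time passing both gates, with the direction of change there.

    ``gene_results`` holds one gene's AHL-arm rows (columns time_min, log2fc,
    fdr). Returns (None, None) when no time point qualifies.
    """
    rows = gene_results.sort_values("time_min")
    hit = rows[(rows["fdr"] < fdr_max) & (rows["log2fc"].abs() > lfc_min)]
    if hit.empty:
        return None, None
    first = hit.iloc[0]
    return int(first["time_min"]), "up" if first["log2fc"] > 0 else "down"


def responsive_filter(
    ahl_results: pd.DataFrame,
    dmso_results: pd.DataFrame,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    control_delta: float = 1.0,
    control_times: tuple[int, ...] = CONTROL_TIMES,
    categories: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply the full responsiveness cascade; one row per gene.

    A gene passes the gate when some AHL time point has FDR < fdr_max and
    |log2FC| > lfc_min. A gate-passing gene is excluded as a control artifact
    when |log2FC_AHL(t) - log2FC_DMSO(t)| <= control_delta at every control
    time, i.e. its trajectory never separates from the solvent control at the
    times the control was sequenced. Responsive genes carry the onset time and
    direction of their earliest gate-passing time point.
    """
    genes = sorted(set(ahl_results["locus_tag"]))
    if set(dmso_results["locus_tag"]) != set(genes):
        raise ValueError("AHL and DMSO result tables must cover the same gene universe")
    for t in control_times:
        if not ((dmso_results["time_min"] == t).any()):
            raise ValueError(f"missing DMSO contrast at control time {t} min")
        if not ((ahl_results["time_min"] == t).any()):
            raise ValueError(f"missing AHL contrast at control time {t} min")

    ahl_piv = ahl_results.pivot_table(index="locus_tag", columns="time_min", values="log2fc")
    dmso_piv = dmso_results.pivot_table(index="locus_tag", columns="time_min", values="log2fc")
    delta = (ahl_piv[list(control_times)] - dmso_piv[list(control_times)]).abs()
    control_like = (delta <= control_delta).all(axis=1)

    rows = []
    for gene, sub in ahl_results.groupby("locus_tag"):
        onset, direction = activation_time(sub, fdr_max, lfc_min)
        passes = onset is not None
        excluded = bool(passes and control_like.loc[gene])
        rows.append(
            {
                "locus_tag": gene,
                "responsive": passes and not excluded,
                "excluded_by_control": excluded,
                "onset_min": onset if (passes and not excluded) else None,
                "direction": direction if (passes and not excluded) else None,
                "category": categories.get(gene, "") if categories is not None else "",
            }
        )
    return pd.DataFrame(rows).set_index("locus_tag", drop=False)


def replicate_correlation(series: ExpressionSeries) -> pd.DataFrame:
    """Pearson r between replicate pairs on log2(count+1), per (arm, time).

    Constant replicates give an undefined correlation, reported as NaN.
    """
    logc = np.log2(series.counts + 1.0)
    rows = []
    cells = series.samples[["arm", "time_min"]].drop_duplicates()
    for arm, t in cells.itertuples(index=False):
        names = series.sample_names(arm, int(t))
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                x, y = logc[a].to_numpy(), logc[b].to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                rows.append({"arm": arm, "time_min": int(t), "sample_a": a,
                             "sample_b": b, "pearson_r": r})
    return pd.DataFrame(rows, columns=["arm", "time_min", "sample_a", "sample_b", "pearson_r"])
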