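"""Circular synchrony statistics and region contrasts.

The degree of phase synchrony within a region is summarised by the
resultant length R of the unit phase vectors (R = 1: perfect synchrony,
R = 0: uniform dispersion), the circular SD sqrt(-2 ln R), and the Rayleigh
test of circular uniformity (z = n R², with Zar's small-sample-corrected
exponential p-value).  Region contrasts (amplitude, time-to-first-peak)
use one-way ANOVA with Dunnett's many-to-one post hoc comparisons against a
control region, mirroring standard practice for multi-region slice
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .movie_io import MovieStack, RegionMask
from .traces import Trace, extract_trace, moving_average_detrend


@dataclass
class SynchronyStats:
    n: int
    circular_mean: float      # radians in [0, 2*pi)
    resultant_length: float   # R in [0, 1]
    circular_sd: float        # sqrt(-2 ln R); inf at R = 0
    rayleigh_z: float         # n * R^2
    rayleigh_p: float


def circular_summary(phases) -> SynchronyStats:
    """Circular mean, resultant length, circular SD and Rayleigh test."""
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 1 or len(phases) < 2:
        raise ValueError("need a 1-D collection of at least 2 phases")
    if not np.all(np.isfinite(phases)):
        raise ValueError("phases must be finite")
    n = len(phases)
    c = np.cos(phases).mean()
    s = np.sin(phases).mean()
    r = float(np.hypot(c, s))
    mean = float(np.mod(np.arctan2(s, c), 2.0 * np.pi))
    sd = float(np.sqrt(-2.0 * np.log(r))) if r > 0 else np.inf
    z = n * r * r
    # Zar's small-sample-corrected exponential approximation.
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return SynchronyStats(
        n=n,
        circular_mean=mean,
        resultant_length=r,
        circular_sd=sd,
        rayleigh_z=float(z),
        rayleigh_p=float(np.clip(p, 0.0, 1.0)),
    )


def circular_sd(phases) -> float:
    return circular_summary(phases).circular_sd


@dataclass
class RegionComparison:
    """One-way ANOVA plus many-to-one contrasts against a control region."""

    control: str
    summaries: pd.DataFrame       # region, n, mean, sem
    f_statistic: float
    p_omnibus: float | None
    contrasts: pd.DataFrame       # region, diff, p_unadjusted, p_adjusted
    method: str                   # multiplicity adjustment used
    degenerate: bool = False      # all-constant input, no p emitted


def _pooled_t_pvalues(samples, control):
    """Per-contrast two-sided p from the pooled-variance t statistic (the
    marginal statistic underlying Dunnett's procedure)."""
    all_vals = samples + [control]
    n_tot = sum(len(v) for v in all_vals)
    k = len(all_vals)
    ss = sum(np.sum((v - v.mean()) ** 2) for v in all_vals)
    df = n_tot - k
    if df <= 0 or ss <= 0:
        return [np.nan] * len(samples)
    s2 = ss / df
    out = []
    for v in samples:
        se = np.sqrt(s2 * (1.0 / len(v) + 1.0 / len(control)))
        tstat = (v.mean() - control.mean()) / se
        out.append(2.0 * sps.t.sf(abs(tstat), df))
    return out


def compare_regions(values_by_region: dict, control: str) -> RegionComparison:
    """Compare a per-region quantity against a control region.

    ``values_by_region`` maps region name -> 1-D samples.  Emits the omnibus
    one-way ANOVA and, for every non-control region, a Dunnett-adjusted
    contrast (falling back to Holm-adjusted Welch t tests if the exact
    Dunnett distribution is unavailable; the method used is recorded).
    """
    if control not in values_by_region:
        raise ValueError(f"control region {control!r} missing from input")
    if len(values_by_region) < 2:
        raise ValueError("need at least 2 regions to compare")
    clean = {}
    for reg, vals in values_by_region.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(f"region {reg!r} has fewer than 2 finite values")
        clean[reg] = v
    others = [r for r in clean if r != control]
    summaries = pd.DataFrame(
        {
            "region": list(clean),
            "n": [len(clean[r]) for r in clean],
            "mean": [clean[r].mean() for r in clean],
            "sem": [clean[r].std(ddof=1) / np.sqrt(len(clean[r])) for r in clean],
        }
    )
    degenerate = all(np.ptp(clean[r]) == 0.0 for r in clean)
    if degenerate:
        contrasts = pd.DataFrame(
            {
                "region": others,
                "diff": [clean[r].mean() - clean[control].mean() for r in others],
                "p_unadjusted": np.nan,
                "p_adjusted": np.nan,
            }
        )
        return RegionComparison(
            control=control,
            summaries=summaries,
            f_statistic=np.nan,
            p_omnibus=None,
            contrasts=contrasts,
            method="none (degenerate zero-variance input)",
            degenerate=True,
        )
    f_stat, p_omni = sps.f_oneway(*clean.values())
    samples = [clean[r] for r in others]
    p_unadj = _pooled_t_pvalues(samples, clean[control])
    try:
        res = sps.dunnett(*samples, control=clean[control])
        p_adj = list(np.atleast_1d(res.pvalue))
        method = "dunnett"
    except Exception:
        welch = [
            sps.ttest_ind(v, clean[control], equal_var=False) for v in samples
        ]
        p_unadj = [t.pvalue for t in welch]
        order = np.argsort(p_unadj)
        m = len(p_unadj)
        p_adj = [np.nan] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_unadj[idx])
            p_adj[idx] = min(1.0, running)
        method = "holm-welch"
    p_adj = [max(a, u) for a, u in zip(p_adj, p_unadj)]
    contrasts = pd.DataFrame(
        {
            "region": others,
            "diff": [clean[r].mean() - clean[control].mean() for r in others],
            "p_unadjusted": p_unadj,
            "p_adjusted": p_adj,
        }
    )
    return RegionComparison(
        control=control,
        summaries=summaries,
        f_statistic=float(f_stat),
        p_omnibus=float(p_omni),
        contrasts=contrasts,
        method=method,
    )


def region_difference_timecourse(
    stack: MovieStack,
    mask: RegionMask,
    span: float = 72.0,
    detrend_window: float = 24.0,
    cycle_length: float = 24.0,
):
    """Detrended fibrotic-minus-nonfibrotic parenchyma difference trace.

    Returns ``(difference Trace, summary)`` where the summary is the mean
    per-cycle peak-to-trough range of the difference over the first ``span``
    hours — one number per movie, comparable across animals/genotypes.
    """
    for region in ("parenchyma_fibrotic", "parenchyma_nonfibrotic"):
        if region not in mask.regions_present():
            raise ValueError(f"region {region!r} missing from mask")
    if stack.duration < span - 1e-9:
        raise ValueError(
            f"movie spans {stack.duration:.3g} h, shorter than span {span} h"
        )
    fib = moving_average_detrend(
        extract_trace(stack, mask, "parenchyma_fibrotic"), detrend_window
    )
    non = moving_average_detrend(
        extract_trace(stack, mask, "parenchyma_nonfibrotic"), detrend_window
    )
    keep = stack.times - stack.times[0] < span - 1e-9
    diff = Trace(
        fib.times[keep],
        fib.values[keep] - non.values[keep],
        label="parenchyma_fibrotic - parenchyma_nonfibrotic",
        detrended=True,
    )
    frames_per_cycle = int(round(cycle_length / stack.frame_interval))
    n_cycles = len(diff.values) // frames_per_cycle
    if n_cycles == 0:
        raise ValueError("span too short for one full cycle")
    ranges = [
        float(np.ptp(diff.values[i * frames_per_cycle : (i + 1) * frames_per_cycle]))
        for i in range(n_cycles)
    ]
    return diff, float(np.mean(ranges))


@dataclass
class CorrelationResult:
    pearson_r: float
    spearman_rho: float
    p_value: float   # two-sided, for the Pearson correlation
    n: int


def density_amplitude_correlation(
    density_map, amplitude_map, qc_mask
) -> CorrelationResult:
    """Correlate cellularity against fitted amplitude over QC-passing bins."""
    density_map = np.asarray(density_map, dtype=float)
    amplitude_map = np.asarray(amplitude_map, dtype=float)
    qc_mask = np.asarray(qc_mask, dtype=bool)
    if not (density_map.shape == amplitude_map.shape == qc_mask.shape):
        raise ValueError("density, amplitude and QC maps must share a shape")
    use = qc_mask & np.isfinite(density_map) & np.isfinite(amplitude_map)
    n = int(use.sum())
    if n < 10:
        raise ValueError(f"only {n} usable bins; need at least 10")
    d = density_map[use]
    a = amplitude_map[use]
    pr = sps.pearsonr(d, a)
    rho = sps.spearmanr(d, a).statistic
    return CorrelationResult(
        pearson_r=float(pr.statistic),
        spearman_rho=float(rho),
        p_value=float(pr.pvalue),
        n=n,
    )


def _circular_mean(angles: np.ndarray) -> float:
    return float(np.arctan2(np.sin(angles).mean(), np.cos(angles).mean()))


def _to_signed(angle):
    """Reduce angle(s) into (-pi, pi]."""
    a = np.mod(np.asarray(angle, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(a == -np.pi, np.pi, a)


@dataclass
class PhaseShiftResult:
    mean_shift: float                 # radians in (-pi, pi]
    ci: tuple[float, float]           # bootstrap percentile interval
    n: int
    n_boot: int
    seed: int


def phase_shift(
    phases_pre, phases_post, n_boot: int = 1000, seed: int = 0
) -> PhaseShiftResult:
    """Mean paired circular phase shift with a seeded bootstrap CI.

    Per-pair differences are reduced into (-pi, pi]; the point estimate is
    their circular mean and the CI the 2.5/97.5 percentiles of circular
    means over ``n_boot`` resamples.
    """
    pre = np.asarray(phases_pre, dtype=float)
    post = np.asarray(phases_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(
            f"paired phase lists differ in length: {pre.shape} vs {post.shape}"
        )
    if pre.ndim != 1 or len(pre) < 3:
        raise ValueError("need at least 3 phase pairs")
    diffs = _to_signed(post - pre)
    mean = float(_to_signed(_circular_mean(diffs)))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5F)))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        sample = rng.choice(diffs, size=len(diffs), replace=True)
        boot[i] = _to_signed(_circular_mean(sample))
    lo, hi = np.quantile(boot, [0.025, 0.975])
    return PhaseShiftResult(
        mean_shift=mean, ci=(float(lo), float(hi)), n=len(pre),
        n_boot=n_boot, seed=seed,
    )
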