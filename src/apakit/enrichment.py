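"""IP-MS enrichment calling: Welch t-test plus hyperbolic significance curve.

Input is a proteins x samples table of log2 intensities with NaN for
missing quantifications. Missing values are imputed from a down-shifted
normal per sample (mean - shift*sd, width*sd), the standard treatment for
label-free IPs where control pulldowns show structural missingness. Each
protein then gets a two-sided Welch t-test (bait vs control) and a log2
fold change; significance combines both through the SAM-style hyperbola

    significant  <=>  log2_fc > x0  and  -log10(p) > c / (log2_fc - x0)

with curvature c and minimum fold change x0 (strict inequalities; boundary
points are not significant). Only the enrichment side is called. The FDR
attached to a curve is estimated by label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

VAR_FLOOR = 1e-8  # keeps degenerate zero-variance proteins finite (p ~ 1, not NaN)


@dataclass(frozen=True)
class CurveParams:
    """Hyperbolic significance curve: target FDR, curvature c, min fold change x0."""

    fdr_target: float = 0.04
    curvature: float = 0.75
    min_fold_change: float = 0.0

    def __post_init__(self):
        if self.curvature <= 0:
            raise ValueError("curvature must be > 0")
        if self.min_fold_change < 0:
            raise ValueError("min_fold_change must be >= 0")


def impute_downshifted(
    table: pd.DataFrame,
    shift: float = 1.8,
    width: float = 0.3,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Replace NaN with draws from a per-sample down-shifted normal.

    For each sample column, missing entries are drawn from
    N(mean_obs - shift*sd_obs, (width*sd_obs)^2), emulating quantifications
    near the detection limit. Columns with < 2 observed values fall back to
    the table-wide mean and sd.
    """
    rng = rng or np.random.default_rng()
    out = table.copy()
    all_values = table.to_numpy(dtype=float)
    global_mean = float(np.nanmean(all_values))
    global_sd = float(np.nanstd(all_values))
    if not np.isfinite(global_sd) or global_sd == 0:
        global_sd = 1.0
    for col in out.columns:
        values = out[col].to_numpy(dtype=float)
        missing = np.isnan(values)
        if not missing.any():
            continue
        observed = values[~missing]
        if observed.size >= 2:
            mu, sd = float(observed.mean()), float(observed.std())
            if sd == 0:
                sd = global_sd
        else:
            mu, sd = global_mean, global_sd
        values[missing] = rng.normal(mu - shift * sd, width * sd, missing.sum())
        out[col] = values
    return out


def _welch(bait: np.ndarray, control: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided Welch t-test with a variance floor (rows = proteins)."""
    n1, n2 = bait.shape[1], control.shape[1]
    m1, m2 = bait.mean(axis=1), control.mean(axis=1)
    v1 = np.maximum(bait.var(axis=1, ddof=1), VAR_FLOOR)
    v2 = np.maximum(control.var(axis=1, ddof=1), VAR_FLOOR)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def enrich_test(
    table: pd.DataFrame,
    bait_samples: Sequence[str],
    control_samples: Sequence[str],
    shift: float = 1.8,
    width: float = 0.3,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Score every protein: imputation, Welch t-test, log2 fold change.

    `table` holds log2 intensities (proteins x samples, NaN = missing).
    Proteins missing in every sample are dropped. Returns one row per
    scored protein with log2_fc (bait mean - control mean), p_value,
    neg_log10_p and a significant column initialised to False.
    """
    if len(bait_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need >= 2 replicates per group")
    sub = table[list(bait_samples) + list(control_samples)]
    all_missing = sub.isna().all(axis=1)
    if all_missing.any():
        sub = sub.loc[~all_missing]
    rng = np.random.default_rng(seed)
    imputed = impute_downshifted(sub, shift=shift, width=width, rng=rng)
    bait = imputed[list(bait_samples)].to_numpy(dtype=float)
    control = imputed[list(control_samples)].to_numpy(dtype=float)
    _, p = _welch(bait, control)
    log2_fc = bait.mean(axis=1) - control.mean(axis=1)
    return pd.DataFrame(
        {
            "protein": sub.index,
            "log2_fc": log2_fc,
            "p_value": p,
            "neg_log10_p": -np.log10(p),
            "significant": False,
        }
    ).set_index("protein")


def hyperbolic_call(records: pd.DataFrame, params: CurveParams) -> pd.DataFrame:
    """Apply the hyperbolic significance curve; returns a copy with flags set.

    significant <=> log2_fc > x0 and -log10(p) > c / (log2_fc - x0), both
    strict, enrichment side only.
    """
    out = records.copy()
    fc = out["log2_fc"].to_numpy(dtype=float)
    nlp = out["neg_log10_p"].to_numpy(dtype=float)
    x0, c = params.min_fold_change, params.curvature
    above = fc > x0
    threshold = np.full_like(fc, np.inf)
    threshold[above] = c / (fc[above] - x0)
    out["significant"] = above & (nlp > threshold)
    return out


def _label_permutations(
    n_bait: int, n_total: int, n_permutations: int, rng: np.random.Generator
) -> List[np.ndarray]:
    """Random relabelings (bait column index sets), excluding the observed one."""
    observed = tuple(range(n_bait))
    all_assignments = [
        c for c in combinations(range(n_total), n_bait) if c != observed
    ]
    if len(all_assignments) <= n_permutations:
        return [np.asarray(c) for c in all_assignments]
    picks = rng.choice(len(all_assignments), size=n_permutations, replace=False)
    return [np.asarray(all_assignments[i]) for i in picks]


def calibrate_curve_fdr(
    table: pd.DataFrame,
    bait_samples: Sequence[str],
    control_samples: Sequence[str],
    params_grid: Iterable[CurveParams],
    n_permutations: int = 20,
    seed: Optional[int] = None,
    shift: float = 1.8,
    width: float = 0.3,
) -> pd.DataFrame:
    """Permutation-estimated FDR for each candidate curve.

    The table is imputed once (seeded); sample labels are then permuted
    across the pooled columns, the t-test and curve call recomputed per
    permutation, and estimated FDR = mean permuted significant count /
    observed significant count (NaN when nothing is observed significant).
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    rng = np.random.default_rng(seed)
    records = enrich_test(
        table, bait_samples, control_samples, shift=shift, width=width,
        seed=None if seed is None else seed,
    )
    # permute on the same imputed matrix the observed call used
    sub = table[list(bait_samples) + list(control_samples)]
    sub = sub.loc[~sub.isna().all(axis=1)]
    imputed = impute_downshifted(
        sub, shift=shift, width=width,
        rng=np.random.default_rng(seed),
    ).to_numpy(dtype=float)
    n_bait, n_total = len(bait_samples), len(bait_samples) + len(control_samples)
    perms = _label_permutations(n_bait, n_total, n_permutations, rng)
    grid = list(params_grid)
    permuted_counts = np.zeros((len(perms), len(grid)))
    for i, bait_idx in enumerate(perms):
        control_idx = np.setdiff1d(np.arange(n_total), bait_idx)
        bait = imputed[:, bait_idx]
        control = imputed[:, control_idx]
        _, p = _welch(bait, control)
        fc = bait.mean(axis=1) - control.mean(axis=1)
        nlp = -np.log10(p)
        for j, params in enumerate(grid):
            above = fc > params.min_fold_change
            with np.errstate(divide="ignore"):
                hit = above & (
                    nlp > params.curvature / np.where(above, fc - params.min_fold_change, np.inf)
                )
            permuted_counts[i, j] = hit.sum()
    rows = []
    for j, params in enumerate(grid):
        observed = int(hyperbolic_call(records, params)["significant"].sum())
        mean_perm = float(permuted_counts[:, j].mean()) if len(perms) else np.nan
        fdr = mean_perm / observed if observed > 0 else np.nan
        rows.append(
            {
                "curvature": params.curvature,
                "min_fold_change": params.min_fold_change,
                "observed_significant": observed,
                "mean_permuted_significant": mean_perm,
                "estimated_fdr": fdr,
            }
        )
    return pd.DataFrame(rows)
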