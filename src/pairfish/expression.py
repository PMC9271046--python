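"""Stage-resolved mRNA quantification and the silencing index (SI).

The silencing index is the ratio of mean mid-plane smFISH dot counts between
an early and a later germline stage (by default GSC over 2-4-cell
spermatogonia).  An SI near 2 reflects the normal two-fold transcriptional
downregulation upon differentiation; an SI near 1 means downregulation
failed.  The SI is a ratio of stage means (cells are not paired across
stages), with a seeded percentile-bootstrap confidence interval over cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import DetectionParams, GERMLINE_STAGES
from .detect import count_dots_for_cells


@dataclass(frozen=True)
class SilencingIndex:
    numerator_stage: str
    denominator_stage: str
    mean_dots_numerator: float
    mean_dots_denominator: float
    si: float
    n_numerator: int
    n_denominator: int
    ci_level: float
    ci_lower: float
    ci_upper: float


def silencing_index(counts: pd.DataFrame,
                    stages: tuple[str, str] = ("GSC", "SG2_4"),
                    n_boot: int = 2000, seed: int = 0,
                    ci_level: float = 0.95,
                    min_n: int = 5) -> SilencingIndex:
    """SI = mean(counts in stages[0]) / mean(counts in stages[1]).

    ``counts`` needs columns ``stage`` and ``count``.  Requires at least
    ``min_n`` cells per stage and a nonzero denominator mean.
    """
    num_stage, den_stage = stages
    a = counts.loc[counts["stage"] == num_stage, "count"].to_numpy(dtype=float)
    b = counts.loc[counts["stage"] == den_stage, "count"].to_numpy(dtype=float)
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(
            f"need >= {min_n} cells per stage; got {len(a)} {num_stage}, "
            f"{len(b)} {den_stage}")
    if b.mean() == 0:
        raise ValueError(f"mean count of {den_stage} is zero; SI undefined")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    den = b[ib].mean(axis=1)
    den[den == 0] = np.nan
    ratios = a[ia].mean(axis=1) / den
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.nanquantile(ratios, [alpha, 1.0 - alpha])
    return SilencingIndex(
        numerator_stage=num_stage, denominator_stage=den_stage,
        mean_dots_numerator=float(a.mean()), mean_dots_denominator=float(b.mean()),
        si=float(a.mean() / b.mean()), n_numerator=len(a), n_denominator=len(b),
        ci_level=ci_level, ci_lower=float(lo), ci_upper=float(hi),
    )


def stage_profile(counts: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-stage table (mean, SD, n), germline stages in
    developmental order with CySC reported last.  Stages with no cells are
    omitted."""
    order = list(GERMLINE_STAGES) + ["CySC"]
    rows = []
    for stage in order:
        sub = counts.loc[counts["stage"] == stage, "count"]
        if len(sub) == 0:
            continue
        rows.append(dict(stage=stage, mean=float(sub.mean()),
                         sd=float(sub.std(ddof=1)) if len(sub) > 1 else 0.0,
                         n=len(sub)))
    return pd.DataFrame(rows, columns=["stage", "mean", "sd", "n"])


def midplane_vs_wholecell_validation(scene, params: DetectionParams | None = None,
                                     stages: tuple[str, str] = ("GSC", "SG2_4"),
                                     n_boot: int = 2000, seed: int = 0) -> dict:
    """Run both smFISH scoring modes on the same cells and compare SIs.

    Single-plane scoring avoids the somatic-surface contamination confound;
    whole-cell scoring includes it.  Returns both SilencingIndex results and
    their relative difference |SI_mid - SI_whole| / SI_whole.
    """
    params = params or DetectionParams()
    cells = scene.cells[scene.cells["stage"].isin(stages)]
    mid = count_dots_for_cells(scene.fields, cells, "exon", params, "midplane")
    whole = count_dots_for_cells(scene.fields, cells, "exon", params, "wholecell")
    si_mid = silencing_index(mid, stages, n_boot=n_boot, seed=seed)
    si_whole = silencing_index(whole, stages, n_boot=n_boot, seed=seed + 1)
    rel = abs(si_mid.si - si_whole.si) / si_whole.si
    return dict(si_midplane=si_mid, si_wholecell=si_whole,
                relative_difference=rel, counts_midplane=mid,
                counts_wholecell=whole)


def copy_number_linearity(counts: pd.DataFrame) -> dict:
    """Least-squares line of mRNA dot count against gene copy number.

    ``counts`` needs columns ``copy_number`` (1-3) and ``count``.  The line
    is fit on per-cell counts (OLS, giving standard errors for slope and
    intercept); R^2 is reported for the per-copy-number mean counts against
    the fitted line, which is the quantity of interest when checking that
    scoring scales linearly with dosage.
    """
    levels = sorted(counts["copy_number"].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 distinct copy numbers for a line")
    x = counts["copy_number"].to_numpy(dtype=float)
    y = counts["count"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    se_intercept, se_slope = model.bse
    means = counts.groupby("copy_number")["count"].mean()
    fitted = intercept + slope * means.index.to_numpy(dtype=float)
    ss_res = float(((means.to_numpy() - fitted) ** 2).sum())
    ss_tot = float(((means.to_numpy() - means.to_numpy().mean()) ** 2).sum())
    r2_means = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return dict(slope=float(slope), intercept=float(intercept),
                se_slope=float(se_slope), se_intercept=float(se_intercept),
                r_squared=float(r2_means), n_levels=len(levels),
                means={int(k): float(v) for k, v in means.items()})
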