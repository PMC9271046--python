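"""Pairing-state classification and allele-resolved intensity analysis.

A nucleus showing a single resolvable punctum in a locus channel is scored
*paired* (the two homologous alleles are colocalized; its inter-allele
distance is plotted as zero by convention).  Two puncta are *unpaired*, and
the inter-allele distance combines the in-plane separation x with the
z-stack offset as D = sqrt(x^2 + z^2).  Cells with more than three puncta
(S-phase sister-chromatid patterns) are excluded from pairing statistics, as
are puncta whose intensity is wildly outside their cohort's range.

Nascent-transcript intensities are expressed relative to an internal
reference: the mean intensity of two or three randomly picked *paired*
somatic cyst stem cells (CySCs) in the same field of view.  Paired puncta
contain two alleles, so per-allele values halve the per-punctum value.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PairingParams

CALL_COLUMNS = (
    "cell_id", "field", "stage", "channel", "n_foci", "state",
    "distance_um", "exclusion_reason",
)


def pair_distance(x_um: float, z_um: float) -> float:
    """3D inter-punctum distance from in-plane and z-stack components.

    D = sqrt(x^2 + z^2), with x the lateral (in-plane) separation and z the
    z-stack offset (plane-index difference times the z-step), both in um.
    """
    if x_um < 0 or z_um < 0:
        raise ValueError(f"distance components must be >= 0, got ({x_um}, {z_um})")
    return math.hypot(x_um, z_um)


def intensity_outlier_filter(intensities, k: float = 3.0,
                             min_cohort: int = 10) -> np.ndarray:
    """Flag puncta whose intensity is outside [median/k, median*k].

    The cohort should be state-stratified (e.g. all single-punctum GB cells).
    Below ``min_cohort`` measurements the filter is disabled (all pass) —
    robust statistics on tiny cohorts would be noise.
    """
    values = np.asarray(intensities, dtype=float)
    if k <= 1:
        raise ValueError("k must be > 1")
    if len(values) < min_cohort:
        return np.zeros(len(values), dtype=bool)
    med = float(np.median(values))
    if med <= 0:
        return np.zeros(len(values), dtype=bool)
    return (values < med / k) | (values > med * k)


def classify_pairing(spots: pd.DataFrame, z_step_um: float,
                     params: PairingParams | None = None) -> dict:
    """Classify one cell's puncta (one channel) into a pairing call.

    ``spots`` must already carry an ``outlier`` boolean column (from
    :func:`intensity_outlier_filter`); flagged puncta are dropped before
    counting.  Returns a mapping with n_foci, state, distance_um and
    exclusion_reason.  The call is independent of row order.
    """
    params = params or PairingParams()
    if "outlier" in spots.columns:
        kept = spots[~spots["outlier"].astype(bool)]
    else:
        kept = spots
    n = len(kept)
    call = dict(n_foci=n, state="excluded", distance_um=np.nan,
                exclusion_reason="none")
    if n == 0:
        call["exclusion_reason"] = "no_signal"
        return call
    if n == 1:
        call.update(state="paired", distance_um=0.0)
        return call
    if n == 3 and params.three_foci_policy == "exclude":
        call["exclusion_reason"] = "ambiguous_three_foci"
        return call
    if n > 3 or (n == 3 and params.three_foci_policy != "keep"):
        call["exclusion_reason"] = "too_many_foci"
        return call
    if n == 3:  # keep policy: score the two brightest as the allele pair
        kept = kept.nlargest(2, "integrated_intensity")
    a, b = kept.iloc[0], kept.iloc[1]
    x = math.hypot(a["x_um"] - b["x_um"], a["y_um"] - b["y_um"])
    z = abs(int(a["z_plane"]) - int(b["z_plane"])) * z_step_um
    call.update(state="unpaired", distance_um=pair_distance(x, z))
    return call


def classify_pairing_table(spots: pd.DataFrame, cells: pd.DataFrame,
                           z_step_um: float,
                           params: PairingParams | None = None) -> pd.DataFrame:
    """Per-cell pairing calls for one channel's spot table.

    Outlier flags are computed on cohorts stratified by stage and by the
    cell's focus count (single- vs two-punctum patterns have ~2:1 intensity)
    before classification.  Cells with no detections get a no_signal
    exclusion.
    """
    params = params or PairingParams()
    spots = spots.merge(cells[["cell_id", "stage"]], on="cell_id", how="left")
    spots = spots.copy()
    n_map = spots.groupby("cell_id")["spot_id"].size()
    spots["n_foci_cell"] = spots["cell_id"].map(n_map)
    spots["outlier"] = False
    for (_, _), idx in spots.groupby(["stage", "n_foci_cell"]).groups.items():
        sub = spots.loc[idx]
        if sub["n_foci_cell"].iloc[0] > 2:
            continue
        flags = intensity_outlier_filter(
            sub["integrated_intensity"], k=params.outlier_k,
            min_cohort=params.min_cohort)
        spots.loc[idx, "outlier"] = flags
    rows = []
    channel = spots["channel"].iloc[0] if len(spots) else ""
    grouped = dict(tuple(spots.groupby("cell_id")))
    for rec in cells.itertuples(index=False):
        sub = grouped.get(rec.cell_id, spots.iloc[0:0])
        call = classify_pairing(sub, z_step_um, params)
        rows.append(dict(cell_id=rec.cell_id, field=rec.field, stage=rec.stage,
                         channel=channel, **call))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


@dataclass
class CyscReference:
    field: str
    reference_value: float
    reference_ids: tuple[str, ...]


def normalize_to_cysc(spots: pd.DataFrame, calls: pd.DataFrame,
                      seed: int = 0, n_reference: int = 3) -> pd.DataFrame:
    """Normalize per-punctum intensities to paired-CySC internal references.

    For each field of view, the reference is the mean punctum intensity of
    ``n_reference`` (or two, if only two exist) seeded-randomly chosen
    *paired* CySCs.  Each punctum row gains:

    per_punctum : intensity / field reference
    per_allele : per_punctum halved for paired cells (two alleles in one
        punctum), unchanged for unpaired cells
    reference_value, reference_ids : the field's reference

    Raises ``ValueError`` when a field has fewer than two paired CySCs.
    """
    merged = spots.merge(
        calls[["cell_id", "state", "stage"]], on="cell_id", how="inner")
    merged = merged[merged["state"].isin(["paired", "unpaired"])].copy()
    out = []
    for field, sub in merged.groupby("field", sort=True):
        cysc = sub[(sub["stage"] == "CySC") & (sub["state"] == "paired")]
        cysc_cells = sorted(cysc["cell_id"].unique())
        if len(cysc_cells) < 2:
            raise ValueError(
                f"field {field!r} has {len(cysc_cells)} paired CySCs; "
                f"need >= 2 for the internal reference")
        rng = np.random.default_rng([seed, zlib.crc32(str(field).encode())])
        n_pick = min(n_reference, len(cysc_cells))
        picks = sorted(rng.choice(cysc_cells, size=n_pick, replace=False))
        ref_values = cysc[cysc["cell_id"].isin(picks)].groupby(
            "cell_id")["integrated_intensity"].mean()
        reference = float(ref_values.mean())
        sub = sub.copy()
        sub["per_punctum"] = sub["integrated_intensity"] / reference
        halve = sub["state"].map({"paired": 0.5, "unpaired": 1.0})
        sub["per_allele"] = sub["per_punctum"] * halve
        sub["reference_value"] = reference
        sub["reference_ids"] = ";".join(picks)
        out.append(sub)
    result = pd.concat(out, ignore_index=True) if out else merged.iloc[0:0]
    return result


def _bootstrap_ratio(a: np.ndarray, b: np.ndarray, n_boot: int, seed: int,
                     level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for mean(a)/mean(b)."""
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    ratios = a[ia].mean(axis=1) / b[ib].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(ratios, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def paired_unpaired_ratio(normalized: pd.DataFrame, stage: str = "GB",
                          n_boot: int = 2000, seed: int = 0,
                          min_per_state: int = 10) -> dict:
    """Compare punctum intensities between paired and unpaired cells.

    Returns per-punctum means for each state, the paired/unpaired per-punctum
    ratio (expected ~2 when both alleles carry equal label), per-allele means
    and the unpaired/paired per-allele ratio (the suppression estimate),
    each with a percentile bootstrap 95% CI.  When a state is missing the
    result carries ``missing_state`` and NaN ratios instead of failing.
    """
    sub = normalized[normalized["stage"] == stage] if stage else normalized
    paired = sub[sub["state"] == "paired"]["per_punctum"].to_numpy()
    unpaired = sub[sub["state"] == "unpaired"]["per_punctum"].to_numpy()
    paired_a = sub[sub["state"] == "paired"]["per_allele"].to_numpy()
    unpaired_a = sub[sub["state"] == "unpaired"]["per_allele"].to_numpy()
    result = dict(
        stage=stage, n_paired=len(paired), n_unpaired=len(unpaired),
        mean_per_punctum_paired=float(paired.mean()) if len(paired) else np.nan,
        mean_per_punctum_unpaired=float(unpaired.mean()) if len(unpaired) else np.nan,
        mean_per_allele_paired=float(paired_a.mean()) if len(paired_a) else np.nan,
        mean_per_allele_unpaired=float(unpaired_a.mean()) if len(unpaired_a) else np.nan,
        missing_state="",
    )
    if len(paired) == 0 or len(unpaired) == 0:
        result["missing_state"] = "paired" if len(paired) == 0 else "unpaired"
        result.update(per_punctum_ratio=np.nan, per_punctum_ci=(np.nan, np.nan),
                      per_allele_ratio=np.nan, per_allele_ci=(np.nan, np.nan))
        return result
    if min(len(paired), len(unpaired)) < min_per_state:
        result["missing_state"] = "underpowered"
    result["per_punctum_ratio"] = result["mean_per_punctum_paired"] / \
        result["mean_per_punctum_unpaired"]
    result["per_punctum_ci"] = _bootstrap_ratio(paired, unpaired, n_boot, seed)
    result["per_allele_ratio"] = result["mean_per_allele_unpaired"] / \
        result["mean_per_allele_paired"]
    result["per_allele_ci"] = _bootstrap_ratio(unpaired_a, paired_a, n_boot,
                                               seed + 1)
    return result


def summarize_pairing_by_stage(calls: pd.DataFrame,
                               stage_order: tuple[str, ...] | None = None
                               ) -> pd.DataFrame:
    """Per-stage pairing summary: n, paired fraction, distance quantiles.

    Paired cells contribute a distance of zero (the plotting convention for
    single-punctum nuclei); excluded cells are tallied separately and never
    enter the fraction or the distance distribution.
    """
    rows = []
    stages = stage_order or sorted(calls["stage"].unique())
    for stage in stages:
        sub = calls[calls["stage"] == stage]
        scored = sub[sub["state"].isin(["paired", "unpaired"])]
        n = len(scored)
        excluded = sub[sub["state"] == "excluded"]
        if n:
            d = scored["distance_um"].to_numpy(dtype=float)
            q = np.quantile(d, [0.0, 0.25, 0.5, 0.75, 1.0])
            frac = float((scored["state"] == "paired").mean())
        else:
            q = [np.nan] * 5
            frac = np.nan
        reasons = excluded["exclusion_reason"].value_counts().to_dict()
        rows.append(dict(
            stage=stage, n_scored=n, paired_fraction=frac,
            distance_min=q[0], distance_q1=q[1], distance_median=q[2],
            distance_q3=q[3], distance_max=q[4], n_excluded=len(excluded),
            excluded_reasons=";".join(f"{k}={v}" for k, v in sorted(reasons.items())),
        ))
    return pd.DataFrame(rows)


def pairwise_distance_check(n: int = 1000, seed: int = 0) -> float:
    """Max |pair_distance - full 3D Euclidean| over random point pairs.

    The Eq.-style decomposition (in-plane x, axial z) must agree with the
    direct 3D distance whenever x is the true lateral separation; this is the
    equivalence oracle used by the acceptance suite.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(-10, 10, size=(n, 3))
    q = rng.uniform(-10, 10, size=(n, 3))
    worst = 0.0
    for a, b in zip(p, q):
        x = math.hypot(a[0] - b[0], a[1] - b[1])
        z = abs(a[2] - b[2])
        d_eq = pair_distance(x, z)
        d_full = float(np.linalg.norm(a - b))
        worst = max(worst, abs(d_eq - d_full))
    return worst
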