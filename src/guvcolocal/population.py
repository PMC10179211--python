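"""Population classification, exchange quantification and derived estimates.

Vesicles are assigned to populations (single-positive, double-positive,
negative) by automatic thresholds placed at the *antimode* — the density
minimum between the two main modes — of bimodal fluorescence or correlation
distributions. Thresholds can come from the mixed sample itself or from a
synthetic mixture resampled out of labelled control pools, whose
positive-to-negative ratio can be optimized against classification accuracy.

The double-positive percentage is corrected for false positives by
subtracting the double-positive rate observed in a negative-control (unfused
1:1) sample. Further estimates: vesicle concentration from counts, imaged
area and chamber geometry (valid once sedimentation is complete); true
vesicle radius from the observed cross-section via spherical-cap inversion;
and sedimentation kinetics via asymptotic exponential fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .io import AcquisitionMeta

__all__ = [
    "NotBimodalError",
    "AntimodeResult",
    "ThresholdSet",
    "PopulationSummary",
    "SedimentationFit",
    "find_antimode",
    "sample_mixture",
    "optimize_correlation_threshold",
    "classify",
    "summarize_population",
    "correct_false_positives",
    "estimate_concentration",
    "compensate_radius",
    "projected_radius",
    "fit_sedimentation",
    "anova_across_replicates",
    "radius_rank_test",
]


class NotBimodalError(ValueError):
    """The sample does not show two separated modes; no antimode exists."""


@dataclass(frozen=True)
class AntimodeResult:
    threshold: float
    modes: tuple[float, ...]
    bandwidth: float
    n: int


@dataclass
class ThresholdSet:
    """Fluorescence and correlation thresholds with their provenance."""

    channel_thresholds: dict[str, float] = dc_field(default_factory=dict)
    correlation_threshold: float | None = None
    provenance: str = "mixed_sample"
    bandwidth: float | None = None


@dataclass
class PopulationSummary:
    sample_id: str
    n_total: int
    counts: dict[str, int]
    percentages: dict[str, float]
    dp_percent: float
    fp_corrected_dp_percent: float
    concentration_per_uL: float | None = None
    concentration_caveat: bool = True


@dataclass
class SedimentationFit:
    per_thickness: pd.DataFrame  # thickness_um, n_inf, tau_min, converged
    slope: float
    intercept: float
    r_squared: float


# ---------------------------------------------------------------------------
# antimode thresholding


def find_antimode(
    values: np.ndarray,
    bandwidth_policy: str | float = "silverman",
    grid_points: int = 512,
    rel_prominence: float = 0.05,
    min_n: int = 50,
    scale: str = "linear",
) -> AntimodeResult:
    """Threshold at the density minimum between the two highest modes.

    A Gaussian kernel density estimate (Silverman's rule unless a numeric
    bandwidth factor is given) is evaluated on a regular grid spanning the
    data; modes are density peaks with at least ``rel_prominence`` of the
    maximum density. Fewer than two modes raises :class:`NotBimodalError`,
    letting callers fall back to resampled-control thresholds.

    ``scale='log'`` runs the KDE on log-transformed values and reports the
    threshold back on the original scale — the natural choice for
    fluorescence intensities, whose positive and negative populations live
    on very different scales (gating such histograms is conventionally done
    in log space). Non-positive values are floored to a tenth of the
    smallest positive value first.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < min_n:
        raise NotBimodalError(f"need at least {min_n} values, got {values.size}")
    if scale == "log":
        positive = values[values > 0]
        if positive.size == 0:
            raise NotBimodalError("no positive values for log-scale density")
        work = np.log(np.clip(values, positive.min() / 10.0, None))
    elif scale == "linear":
        work = values
    else:
        raise ValueError("scale must be 'linear' or 'log'")
    if np.ptp(work) == 0:
        raise NotBimodalError("not bimodal: all values identical")
    kde = stats.gaussian_kde(work, bw_method=bandwidth_policy)
    bw = kde.factor * work.std(ddof=1)
    # pad the grid so a mode sitting at the data boundary is still a peak
    grid = np.linspace(work.min() - 3 * bw, work.max() + 3 * bw, grid_points)
    density = kde(grid)
    peaks, _ = signal.find_peaks(density, prominence=rel_prominence * density.max())
    if peaks.size < 2:
        raise NotBimodalError("not bimodal: fewer than two modes found")
    # two highest modes by density
    order = np.argsort(density[peaks])[::-1]
    top = np.sort(peaks[order[:2]])
    valley = top[0] + int(np.argmin(density[top[0] : top[1] + 1]))
    back = np.exp if scale == "log" else (lambda v: v)
    return AntimodeResult(
        threshold=float(back(grid[valley])),
        modes=tuple(float(back(grid[p])) for p in peaks),
        bandwidth=float(kde.factor * work.std(ddof=1)),
        n=int(values.size),
    )


def sample_mixture(
    neg_values: np.ndarray,
    pos_values: np.ndarray,
    pos_fraction: float,
    n: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a labelled synthetic mixture from negative and positive pools.

    Each draw is positive with probability ``pos_fraction`` and sampled with
    replacement from the corresponding pool. Returns ``(values, is_positive)``.
    """
    neg_values = np.asarray(neg_values, dtype=float)
    pos_values = np.asarray(pos_values, dtype=float)
    if neg_values.size == 0 or pos_values.size == 0:
        raise ValueError("both pools must be non-empty")
    if not (0.0 <= pos_fraction <= 1.0):
        raise ValueError("pos_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    is_pos = rng.random(n) < pos_fraction
    values = np.where(
        is_pos,
        rng.choice(pos_values, size=n, replace=True),
        rng.choice(neg_values, size=n, replace=True),
    )
    return values, is_pos


def optimize_correlation_threshold(
    neg_scores: np.ndarray,
    pos_scores: np.ndarray,
    fractions: np.ndarray | list[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    n: int = 2000,
    seed: int = 0,
) -> tuple[ThresholdSet, pd.DataFrame]:
    """Pick the resampling ratio whose antimode classifies the controls best.

    For each positive fraction a labelled mixture is resampled from the two
    control pools, its antimode located, and classification accuracy against
    the known labels recorded. The threshold at the best fraction is
    returned together with the full stability table (fraction, threshold,
    accuracy, failed).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        values, labels = sample_mixture(neg_scores, pos_scores, frac, n, rng)
        try:
            res = find_antimode(values)
        except NotBimodalError:
            rows.append({"fraction": frac, "threshold": np.nan, "accuracy": np.nan, "failed": True})
            continue
        predicted = values > res.threshold
        accuracy = float((predicted == labels).mean())
        rows.append({"fraction": frac, "threshold": res.threshold, "accuracy": accuracy, "failed": False})
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise NotBimodalError("antimode failed at every mixture fraction")
    best = ok.loc[ok["accuracy"].idxmax()]
    ts = ThresholdSet(
        correlation_threshold=float(best["threshold"]),
        provenance="resampled_synthetic",
    )
    return ts, table


# ---------------------------------------------------------------------------
# classification


def classify(
    records: pd.DataFrame,
    thresholds: ThresholdSet,
    pair: tuple[str, str],
    channel_roles: dict[str, str],
    scores: pd.DataFrame | None = None,
    intensity_stat: str = "mean",
) -> pd.DataFrame:
    """Label every object by fluorescence and (optionally) by correlation.

    An object is positive for a channel when its background-corrected mean
    intensity (lumen mean for content channels, membrane mean for lipid
    channels) exceeds that channel's threshold. The fluorescence population
    is DP / P1 / P2 / neg for the declared pair; the exchange label is
    correlation score > correlation threshold when scores are supplied.
    """
    ch_a, ch_b = pair
    out = records[["object_id", "field_index"]].copy()

    def value_column(ch: str) -> pd.Series:
        prefix = "lum" if channel_roles.get(ch) == "content" else "mem"
        col = f"{prefix}_{intensity_stat}_{ch}"
        vals = records[col]
        if prefix == "lum":
            # objects with no matched lumen fall back to membrane-region signal
            vals = vals.fillna(records[f"mem_{intensity_stat}_{ch}"])
        return vals

    pos_a = value_column(ch_a) > thresholds.channel_thresholds[ch_a]
    pos_b = value_column(ch_b) > thresholds.channel_thresholds[ch_b]
    out["positive_" + ch_a] = pos_a
    out["positive_" + ch_b] = pos_b
    population = np.where(
        pos_a & pos_b, "DP", np.where(pos_a, "P1", np.where(pos_b, "P2", "neg"))
    )
    out["population"] = population
    if scores is not None and thresholds.correlation_threshold is not None:
        sc = scores.set_index(["field_index", "object_id"])["value"]
        idx = pd.MultiIndex.from_frame(records[["field_index", "object_id"]])
        vals = sc.reindex(idx).to_numpy()
        out["correlation"] = vals
        out["exchange_positive"] = vals > thresholds.correlation_threshold
    return out


def correct_false_positives(dp_percent: float, nc_dp_percent: float) -> float:
    """Subtract the double-positive rate seen in the negative control (floor 0)."""
    if not (0.0 <= dp_percent <= 100.0 and 0.0 <= nc_dp_percent <= 100.0):
        raise ValueError("percentages must lie in [0, 100]")
    return max(dp_percent - nc_dp_percent, 0.0)


def summarize_population(
    labels: pd.DataFrame,
    sample_id: str,
    nc_dp_percent: float = 0.0,
    imaged_area_mm2: float | None = None,
    meta: AcquisitionMeta | None = None,
    sedimentation_complete: bool = False,
) -> PopulationSummary:
    """Counts, percentages, FP-corrected DP percentage, concentration."""
    n = len(labels)
    counts = {pop: int((labels["population"] == pop).sum()) for pop in ("P1", "P2", "DP", "neg")}
    percentages = {pop: (100.0 * c / n if n else 0.0) for pop, c in counts.items()}
    dp_percent = percentages["DP"]
    conc = None
    if imaged_area_mm2 is not None and meta is not None:
        conc = estimate_concentration(n, imaged_area_mm2, meta)
    return PopulationSummary(
        sample_id=sample_id,
        n_total=n,
        counts=counts,
        percentages=percentages,
        dp_percent=dp_percent,
        fp_corrected_dp_percent=correct_false_positives(dp_percent, nc_dp_percent),
        concentration_per_uL=conc,
        concentration_caveat=not sedimentation_complete,
    )


# ---------------------------------------------------------------------------
# concentration, size compensation, sedimentation


def estimate_concentration(n_objects: int, imaged_area_mm2: float, meta: AcquisitionMeta) -> float:
    """Objects per µL of original suspension, assuming complete sedimentation.

    The imaged volume is area x chamber thickness; 1 µL = 1 mm³. The result
    is multiplied back up by the dilution applied before imaging.
    """
    if imaged_area_mm2 <= 0:
        raise ValueError("imaged area must be positive")
    volume_uL = imaged_area_mm2 * meta.chamber_thickness_um * 1e-3
    return n_objects / volume_uL * meta.dilution_factor


def projected_radius(true_radius_um: np.ndarray | float, plane_offset_um: float) -> np.ndarray | float:
    """Cross-section radius of a coverslip-resting sphere cut at height h.

    r = sqrt(2Rh - h²), defined for R >= h/2 (smaller spheres never reach
    the imaging plane).
    """
    R = np.asarray(true_radius_um, dtype=float)
    h = plane_offset_um
    if h <= 0:
        raise ValueError("plane offset must be > 0")
    if np.any(R < h / 2):
        raise ValueError("spheres with R < h/2 do not intersect the imaging plane")
    out = np.sqrt(2.0 * R * h - h * h)
    return float(out) if np.isscalar(true_radius_um) else out


def compensate_radius(
    observed_radius_um: np.ndarray | float, plane_offset_um: float
) -> tuple[np.ndarray | float, np.ndarray | bool]:
    """Invert the spherical-cap projection: R = (r² + h²) / (2h).

    Objects observed with r = 0 sit exactly at tangency (R = h/2) and are
    flagged. Returns ``(true_radius, at_tangency)``.
    """
    h = plane_offset_um
    if h <= 0:
        raise ValueError("plane offset must be > 0")
    r = np.asarray(observed_radius_um, dtype=float)
    if np.any(r < 0):
        raise ValueError("observed radius must be >= 0")
    R = (r * r + h * h) / (2.0 * h)
    flag = r == 0
    if np.isscalar(observed_radius_um):
        return float(R), bool(flag)
    return R, flag


def _exp_saturation(t: np.ndarray, n_inf: float, tau: float) -> np.ndarray:
    return n_inf * (1.0 - np.exp(-t / tau))


def fit_sedimentation(series: dict[float, tuple[np.ndarray, np.ndarray]]) -> SedimentationFit:
    """Fit N(t) = N_inf (1 - exp(-t/tau)) per chamber thickness, then N_inf vs thickness.

    ``series`` maps thickness (µm) to ``(times_min, counts)``. Series that
    fail to converge (or are identically zero, where tau is unidentifiable)
    are flagged and excluded from the linear step. The linear step is an
    ordinary least-squares regression with its R² reported.
    """
    rows = []
    for thickness, (times, counts) in series.items():
        times = np.asarray(times, dtype=float)
        counts = np.asarray(counts, dtype=float)
        if times.size < 4:
            raise ValueError(f"thickness {thickness}: need >= 4 time points")
        if np.all(counts == 0):
            rows.append({"thickness_um": thickness, "n_inf": 0.0, "tau_min": np.nan, "converged": False})
            continue
        n0 = counts.max()
        half_idx = np.argmax(counts >= 0.63 * n0)
        tau0 = max(times[half_idx], times[times > 0].min() if np.any(times > 0) else 1.0)
        try:
            popt, _ = optimize.curve_fit(
                _exp_saturation,
                times,
                counts,
                p0=(n0, tau0),
                bounds=((0.0, 1e-9), (np.inf, np.inf)),
                maxfev=10000,
            )
            rows.append(
                {"thickness_um": thickness, "n_inf": float(popt[0]), "tau_min": float(popt[1]), "converged": True}
            )
        except RuntimeError:
            rows.append({"thickness_um": thickness, "n_inf": np.nan, "tau_min": np.nan, "converged": False})
    table = pd.DataFrame(rows).sort_values("thickness_um").reset_index(drop=True)
    ok = table[table["converged"]]
    if len(ok) >= 2:
        fit = stats.linregress(ok["thickness_um"], ok["n_inf"])
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    else:
        slope = intercept = r2 = np.nan
    return SedimentationFit(per_thickness=table, slope=slope, intercept=intercept, r_squared=r2)


# ---------------------------------------------------------------------------
# thin statistical wrappers (non-novel conveniences)


def anova_across_replicates(*replicate_percentages: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA across replicate exchange percentages: (F, p)."""
    res = stats.f_oneway(*replicate_percentages)
    return float(res.statistic), float(res.pvalue)


def radius_rank_test(positive_radii: np.ndarray, negative_radii: np.ndarray) -> tuple[float, float]:
    """One-tailed Wilcoxon rank-sum: are exchange-positive vesicles larger? (U, p)."""
    res = stats.mannwhitneyu(positive_radii, negative_radii, alternative="greater")
    return float(res.statistic), float(res.pvalue)
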