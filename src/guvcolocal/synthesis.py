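"""Ground-truthed synthetic GUV micrographs and a hemifusion transfer model.

The renderer emulates sedimented vesicle fields as seen by a spinning-disc
confocal a couple of microns above the coverslip: membrane markers image as
annuli with a Gaussian radial profile, content markers as filled lumina.
Population identity (P1 / P2 / PC) decides which channels a vesicle carries
signal in; per-vesicle marker amounts are lognormally dispersed to emulate
encapsulation variability. Heterogeneity knobs reproduce the failure modes
of real preparations: patchy (phase-separated) membranes, bright
multilamellar-like objects, oil-inclusion hot spots, out-of-focus haze from
a phantom vesicle layer, and tangent aggregates. Shot (Poisson) and read
(Gaussian) noise are applied last. Everything is deterministic per seed and
every rendered vesicle has a ground-truth record and label.

The content-transfer simulator implements symmetric fractional exchange
between hemifused partners: with transfer fraction phi drawn per pair, each
partner keeps (1 - phi) of its own marker and receives phi of the other's,
conserving the total amount of each marker exactly. This reproduces the
negative correlation between the two marker intensities observed among
exchange-positive vesicles: final amounts ((1-phi)A, phi B) are
anticorrelated through phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (
    AcquisitionMeta,
    ChannelSpec,
    FieldOfView,
    save_channel_config,
    write_dataset,
    write_label_map,
)

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "TransferSimSpec",
    "default_content_exchange_layout",
    "mixture_fractions",
    "allocate_populations",
    "render_scene",
    "simulate_content_transfer",
    "generate_dataset",
    "MIXTURE_RATIOS",
]

# volumetric P1:P2:PC ratios of the reference validation series
MIXTURE_RATIOS: dict[str, tuple[float, float, float]] = {
    "M1": (1.0, 1.0, 1.0),
    "M2": (1.0, 1.0, 0.5),
    "M3": (1.0, 1.0, 0.1),
    "M4": (1.0, 1.0, 0.05),
    "NC": (1.0, 1.0, 0.0),
}


def default_content_exchange_layout() -> tuple[list[ChannelSpec], dict[str, dict[str, float]]]:
    """Channel layout of a content-exchange assay.

    One membrane stain shared by every population plus two lumen markers.
    The dual-stained positive control carries each content marker at half
    the single-population amount (it is loaded with both dextrans at half
    concentration each).
    """
    channels = [
        ChannelSpec("rho", "lipid", marker_name="membrane stain", pair_group="content"),
        ChannelSpec("dexA", "content", marker_name="lumen marker A", pair_group="content"),
        ChannelSpec("dexB", "content", marker_name="lumen marker B", pair_group="content"),
    ]
    amounts = {
        "P1": {"rho": 1.0, "dexA": 1.0},
        "P2": {"rho": 1.0, "dexB": 1.0},
        "PC": {"rho": 1.0, "dexA": 0.5, "dexB": 0.5},
    }
    return channels, amounts


@dataclass(frozen=True)
class SceneSpec:
    """Conditions for one rendered field of view."""

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.4  # µm/px
    n_vesicles: int = 120
    radius_median_um: float = 4.0
    radius_sigma_log: float = 0.4
    fractions: dict[str, float] = dc_field(
        default_factory=lambda: {"P1": 0.5, "P2": 0.5, "PC": 0.0}
    )
    ring_width_px: float = 1.5
    amount_sigma_log: float = 0.35
    background: float = 0.05
    read_sigma: float = 0.02
    photon_scale: float = 400.0
    haze_amplitude: float = 0.0
    haze_n: int = 60
    haze_blur_px: float = 12.0
    patchy_fraction: float = 0.0
    patchy_depth: float = 0.8
    multilamellar_fraction: float = 0.0
    multilamellar_gain: float = 4.0
    inclusion_fraction: float = 0.0
    inclusion_gain: float = 3.0
    cluster_fraction: float = 0.0
    min_gap_px: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and not np.isclose(total, 1.0):
            raise ValueError(f"population fractions must sum to 1, got {total}")
        if any(f < 0 or f > 1 for f in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 1]")
        if self.radius_median_um <= 0:
            raise ValueError("radius_median_um must be > 0")


@dataclass
class SyntheticScene:
    channels: dict[str, np.ndarray]
    label_map: np.ndarray
    truth: pd.DataFrame
    spec: SceneSpec


@dataclass(frozen=True)
class TransferSimSpec:
    """Conditions of the random content-transfer simulation."""

    n_pairs: int = 5000
    amount_marker1: float = 1.0
    amount_marker2: float = 1.0
    p_exchanged: float = 1.0
    transfer_low: float = 0.0
    transfer_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amount_marker1 < 0 or self.amount_marker2 < 0:
            raise ValueError("amounts must be >= 0")
        if not (0.0 <= self.p_exchanged <= 1.0):
            raise ValueError("p_exchanged must lie in [0, 1]")


# ---------------------------------------------------------------------------
# population bookkeeping


def mixture_fractions(ratio: tuple[float, float, float]) -> dict[str, float]:
    """Volumetric P1:P2:PC ratio -> per-vesicle population fractions."""
    total = sum(ratio)
    if total <= 0:
        raise ValueError("ratio must have positive total")
    return {"P1": ratio[0] / total, "P2": ratio[1] / total, "PC": ratio[2] / total}


def allocate_populations(n: int, fractions: dict[str, float], rng: np.random.Generator) -> list[str]:
    """Deterministic (largest-remainder) population counts, shuffled.

    Exact counts — rather than per-vesicle multinomial draws — make the
    realized mixture fraction equal the nominal one, so recovery error
    measures the pipeline, not generator sampling noise.
    """
    pops = [p for p, f in fractions.items() if f > 0]
    exact = np.array([n * fractions[p] for p in pops])
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(exact - counts)[::-1]
    for i in range(remainder):
        counts[order[i % len(pops)]] += 1
    labels = [p for p, c in zip(pops, counts) for _ in range(c)]
    rng.shuffle(labels)
    return labels


# ---------------------------------------------------------------------------
# placement


def _place_vesicles(
    spec: SceneSpec, radii_px: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Hard-sphere rejection sampling; clustered vesicles are placed tangent.

    Returns centers (n, 2) and cluster ids (0 = unclustered).
    """
    h, w = spec.image_shape
    n = len(radii_px)
    centers = np.zeros((n, 2))
    cluster_ids = np.zeros(n, dtype=int)
    clustered = rng.random(n) < spec.cluster_fraction
    placed: list[int] = []
    next_cluster = 1
    max_attempts = 2000
    for i in range(n):
        r = radii_px[i]
        attach_to = None
        if clustered[i] and placed:
            attach_to = int(rng.choice(placed))
        for attempt in range(max_attempts):
            if attach_to is not None:
                theta = rng.uniform(0, 2 * np.pi)
                dist = radii_px[attach_to] + r
                cand = centers[attach_to] + dist * np.array([np.sin(theta), np.cos(theta)])
                if not (r + 2 <= cand[0] <= h - r - 2 and r + 2 <= cand[1] <= w - r - 2):
                    continue
                others = [j for j in placed if j != attach_to]
            else:
                cand = np.array(
                    [rng.uniform(r + 2, h - r - 2), rng.uniform(r + 2, w - r - 2)]
                )
                others = placed
            ok = True
            for j in others:
                if np.hypot(*(cand - centers[j])) < r + radii_px[j] + spec.min_gap_px:
                    ok = False
                    break
            if ok:
                centers[i] = cand
                if attach_to is not None:
                    if cluster_ids[attach_to] == 0:
                        cluster_ids[attach_to] = next_cluster
                        next_cluster += 1
                    cluster_ids[i] = cluster_ids[attach_to]
                placed.append(i)
                break
        else:
            raise RuntimeError(
                f"could not place vesicle {i} after {max_attempts} attempts; density too high"
            )
    return centers, cluster_ids


# ---------------------------------------------------------------------------
# rendering


def _render_vesicle(
    canvas: dict[str, np.ndarray],
    label_map: np.ndarray,
    label: int,
    center: np.ndarray,
    radius_px: float,
    amounts: dict[str, float],
    roles: dict[str, str],
    spec: SceneSpec,
    patchy: bool,
    multilamellar: bool,
    n_inclusions: int,
    rng: np.random.Generator,
) -> None:
    h, w = spec.image_shape
    rw = spec.ring_width_px
    pad = int(np.ceil(radius_px + 4 * rw + 3))
    r0, r1 = max(int(center[0]) - pad, 0), min(int(center[0]) + pad + 1, h)
    c0, c1 = max(int(center[1]) - pad, 0), min(int(center[1]) + pad + 1, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - center[0], cc - center[1]
    d = np.hypot(dy, dx)

    ring = np.exp(-((d - radius_px) ** 2) / (2.0 * rw * rw))
    if patchy:
        theta = np.arctan2(dy, dx)
        mod = np.ones_like(theta)
        for k in (1, 2, 3):
            mod += (
                spec.patchy_depth
                / k
                * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
            )
        ring = ring * np.clip(mod, 0.1, None)
    if multilamellar:
        ring = spec.multilamellar_gain * (ring + 0.5 * (d < radius_px))
    if n_inclusions > 0:
        for _ in range(n_inclusions):
            ang = rng.uniform(0, 2 * np.pi)
            sr = center[0] + radius_px * np.sin(ang)
            sc = center[1] + radius_px * np.cos(ang)
            ring = ring + spec.inclusion_gain * np.exp(
                -((rr - sr) ** 2 + (cc - sc) ** 2) / (2.0 * 1.5**2)
            )

    lumen_r = max(radius_px - rw, 1.0)
    lumen = 1.0 / (1.0 + np.exp((d - lumen_r) / 0.8))

    for ch, amount in amounts.items():
        if amount <= 0 or ch not in canvas:
            continue
        profile = ring if roles[ch] == "lipid" else lumen
        canvas[ch][r0:r1, c0:c1] += amount * profile

    label_map[r0:r1, c0:c1][d <= radius_px] = label


def render_scene(
    spec: SceneSpec,
    channel_specs: list[ChannelSpec] | None = None,
    population_amounts: dict[str, dict[str, float]] | None = None,
    populations: list[str] | None = None,
) -> SyntheticScene:
    """Render one field with its ground-truth table and label map."""
    if channel_specs is None or population_amounts is None:
        channel_specs, population_amounts = default_content_exchange_layout()
    roles = {s.channel_id: s.role for s in channel_specs}
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    canvas = {s.channel_id: np.zeros((h, w)) for s in channel_specs}
    label_map = np.zeros((h, w), dtype=np.int32)

    n = spec.n_vesicles
    if populations is None:
        populations = allocate_populations(n, spec.fractions, rng)
    elif len(populations) != n:
        raise ValueError("populations list must match n_vesicles")

    radii_um = spec.radius_median_um * np.exp(rng.normal(0.0, spec.radius_sigma_log, n))
    radii_px = np.clip(radii_um / spec.pixel_size, 3.0, None)
    if n > 0:
        centers, cluster_ids = _place_vesicles(spec, radii_px, rng)
    else:
        centers = np.zeros((0, 2))
        cluster_ids = np.zeros(0, dtype=int)

    patchy = rng.random(n) < spec.patchy_fraction
    multilamellar = rng.random(n) < spec.multilamellar_fraction
    has_inclusions = rng.random(n) < spec.inclusion_fraction
    n_inclusions = np.where(has_inclusions, rng.integers(1, 4, n), 0)

    rows = []
    for i in range(n):
        base = population_amounts.get(populations[i], {})
        amounts = {
            ch: a * float(np.exp(rng.normal(0.0, spec.amount_sigma_log)))
            for ch, a in base.items()
        }
        _render_vesicle(
            canvas,
            label_map,
            i + 1,
            centers[i],
            radii_px[i],
            amounts,
            roles,
            spec,
            bool(patchy[i]),
            bool(multilamellar[i]),
            int(n_inclusions[i]),
            rng,
        )
        row = {
            "vesicle_id": i + 1,
            "center_row": centers[i][0],
            "center_col": centers[i][1],
            "radius_px": radii_px[i],
            "radius_um": radii_px[i] * spec.pixel_size,
            "population": populations[i],
            "cluster_id": int(cluster_ids[i]),
            "patchy": bool(patchy[i]),
            "multilamellar": bool(multilamellar[i]),
            "n_inclusions": int(n_inclusions[i]),
        }
        for s in channel_specs:
            row[f"amount_{s.channel_id}"] = amounts.get(s.channel_id, 0.0)
        rows.append(row)
    truth_cols = [
        "vesicle_id",
        "center_row",
        "center_col",
        "radius_px",
        "radius_um",
        "population",
        "cluster_id",
        "patchy",
        "multilamellar",
        "n_inclusions",
    ] + [f"amount_{s.channel_id}" for s in channel_specs]
    truth = pd.DataFrame(rows, columns=truth_cols)

    if spec.haze_amplitude > 0 and spec.haze_n > 0:
        phantom = np.zeros((h, w))
        p_centers = rng.uniform([0, 0], [h, w], size=(spec.haze_n, 2))
        p_radii = spec.radius_median_um / spec.pixel_size * np.exp(
            rng.normal(0.0, spec.radius_sigma_log, spec.haze_n)
        )
        rr, cc = np.mgrid[0:h, 0:w]
        for (pr, pc), prad in zip(p_centers, p_radii):
            rr0, rr1 = max(int(pr - prad - 2), 0), min(int(pr + prad + 3), h)
            cc0, cc1 = max(int(pc - prad - 2), 0), min(int(pc + prad + 3), w)
            if rr0 >= rr1 or cc0 >= cc1:
                continue
            dd = np.hypot(rr[rr0:rr1, cc0:cc1] - pr, cc[rr0:rr1, cc0:cc1] - pc)
            phantom[rr0:rr1, cc0:cc1] += dd <= prad
        phantom = ndimage.gaussian_filter(phantom, spec.haze_blur_px)
        for ch in canvas:
            canvas[ch] += spec.haze_amplitude * phantom

    for ch in canvas:
        img = canvas[ch] + spec.background
        if spec.photon_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * spec.photon_scale) / spec.photon_scale
        if spec.read_sigma > 0:
            img = img + rng.normal(0.0, spec.read_sigma, img.shape)
        canvas[ch] = np.clip(img, 0.0, None).astype(np.float32)

    return SyntheticScene(channels=canvas, label_map=label_map, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# content-transfer simulation


def simulate_content_transfer(spec: TransferSimSpec) -> pd.DataFrame:
    """Random fractional content exchange between hemifused partners.

    Partner 1 starts with marker-1 amount A, partner 2 with marker-2 amount
    B. For an exchanged pair with transfer fraction phi ~ U(low, high):
    partner 1 ends with ((1-phi)A, phi B) and partner 2 with (phi A,
    (1-phi)B); totals of each marker are conserved exactly. Non-exchanged
    pairs keep their initial amounts.
    """
    rng = np.random.default_rng(spec.seed)
    phi = rng.uniform(spec.transfer_low, spec.transfer_high, spec.n_pairs)
    exchanged = rng.random(spec.n_pairs) < spec.p_exchanged
    phi = np.where(exchanged, phi, 0.0)
    A, B = spec.amount_marker1, spec.amount_marker2
    rows = []
    for k in range(spec.n_pairs):
        f = phi[k]
        rows.append(
            {
                "vesicle_id": 2 * k + 1,
                "pair_id": k + 1,
                "partner": 1,
                "exchanged": bool(exchanged[k]),
                "transfer_fraction": f,
                "marker1": (1.0 - f) * A,
                "marker2": f * B,
            }
        )
        rows.append(
            {
                "vesicle_id": 2 * k + 2,
                "pair_id": k + 1,
                "partner": 2,
                "exchanged": bool(exchanged[k]),
                "transfer_fraction": f,
                "marker1": f * A,
                "marker2": (1.0 - f) * B,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset emission


def generate_dataset(
    out_dir: str | Path,
    sample_specs: dict[str, SceneSpec],
    n_fields: int = 1,
    channel_specs: list[ChannelSpec] | None = None,
    population_amounts: dict[str, dict[str, float]] | None = None,
    write_gt_labels: bool = False,
) -> dict[str, pd.DataFrame]:
    """Emit per-sample directories readable by the io module, with ground truth.

    Each sample gets ``n_fields`` rendered fields (per-field seeds derived
    from the sample seed), a ``ground_truth.csv`` whose centers are in each
    field's own pixel frame, and a ``channels.yaml`` describing layout and
    acquisition. Population counts are allocated once across the whole
    sample so the realized mixture matches the nominal fractions exactly.
    """
    if channel_specs is None or population_amounts is None:
        channel_specs, population_amounts = default_content_exchange_layout()
    out_root = Path(out_dir)
    truths: dict[str, pd.DataFrame] = {}
    grid_cols = int(np.ceil(np.sqrt(n_fields)))
    grid_rows = int(np.ceil(n_fields / grid_cols))
    for sample_id, spec in sample_specs.items():
        sample_dir = out_root / sample_id
        sample_dir.mkdir(parents=True, exist_ok=True)
        rng = np.random.default_rng(spec.seed)
        total = spec.n_vesicles * n_fields
        populations = allocate_populations(total, spec.fractions, rng)
        fovs = []
        gt_parts = []
        for f_idx in range(n_fields):
            field_seed = int(
                np.random.SeedSequence([spec.seed, f_idx]).generate_state(1)[0] % (2**31)
            )
            field_spec = replace(spec, seed=field_seed)
            pops = populations[f_idx * spec.n_vesicles : (f_idx + 1) * spec.n_vesicles]
            scene = render_scene(field_spec, channel_specs, population_amounts, populations=pops)
            from .io import grid_position

            pos = grid_position(f_idx, grid_rows, grid_cols, "snake_by_rows")
            fovs.append(
                FieldOfView(
                    field_index=f_idx,
                    grid_position=pos,
                    channels=scene.channels,
                    pixel_size=spec.pixel_size,
                )
            )
            gt = scene.truth.copy()
            gt.insert(0, "field_index", f_idx)
            gt_parts.append(gt)
            if write_gt_labels:
                write_label_map(scene.label_map, sample_dir / f"gt_labels_{f_idx:04d}.tif")
        write_dataset(sample_dir, fovs)
        truth = pd.concat(gt_parts, ignore_index=True)
        truth.to_csv(sample_dir / "ground_truth.csv", index=False)
        meta = AcquisitionMeta(grid_rows=grid_rows, grid_cols=grid_cols)
        save_channel_config(sample_dir / "channels.yaml", channel_specs, meta)
        truths[sample_id] = truth
    return truths
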