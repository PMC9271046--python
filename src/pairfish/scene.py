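"""Ground-truthed synthetic FISH scene generator.

Simulates fields of view of a testis tip: spheroidal cells on a jittered
grid, each carrying one or two homologous loci rendered into a DNA-FISH
channel and a nascent-transcript (intron) channel, plus cytoplasmic
single-molecule mRNA dots in an exon channel.  Every rendered object is
recorded in a ground-truth table so each downstream measurement can be
checked against what was actually placed.

Geometry and units: all coordinates in micrometres, (x, y) lateral from the
image origin, z along the optical axis.  Plane k is centred at z = k * z_step.
Spots are anisotropic 3D Gaussians integrated over voxel extents, so a spot's
summed contribution equals its amplitude whenever it lies fully inside the
grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import erf

from .config import ConfigError, NoiseParams, SceneConfig, dump_config
from .io import FieldOfView, ImageStack, write_cells, write_fields, write_table

CHANNELS = ("dna", "intron", "exon")

#: fields of view are capped at a 10 x 10 cell grid to bound stack size
MAX_CELLS_PER_FIELD = 100

#: sister sub-foci are placed this far (um) from the parent locus, uniform
SISTER_SPLIT_RANGE_UM = (0.3, 0.6)

#: loci are drawn inside this fraction of the nuclear radius
_LOCUS_RADIUS_FRACTION = 0.8

#: nucleus radius as a fraction of the cell radius (concentric spheroid)
NUCLEUS_FRACTION = 0.6


class CapacityError(ValueError):
    """Requested more cells per field than the field grid can hold."""


@dataclass(frozen=True)
class CellGeometry:
    """Spheroidal cell with a concentric nuclear spheroid."""

    center_um: tuple[float, float, float]  # (x, y, z)
    radius_lateral_um: float
    radius_axial_um: float
    nucleus_fraction: float = NUCLEUS_FRACTION

    @property
    def nucleus_radii(self) -> tuple[float, float]:
        return (self.radius_lateral_um * self.nucleus_fraction,
                self.radius_axial_um * self.nucleus_fraction)

    def contains(self, p: np.ndarray, lateral: float, axial: float) -> np.ndarray:
        cx, cy, cz = self.center_um
        p = np.atleast_2d(p)
        return (((p[:, 0] - cx) / lateral) ** 2
                + ((p[:, 1] - cy) / lateral) ** 2
                + ((p[:, 2] - cz) / axial) ** 2) <= 1.0

    def in_cell(self, p: np.ndarray) -> np.ndarray:
        return self.contains(p, self.radius_lateral_um, self.radius_axial_um)

    def in_nucleus(self, p: np.ndarray) -> np.ndarray:
        return self.contains(p, *self.nucleus_radii)

    def cytoplasm_area_um2(self, z_um: float) -> float:
        """Cross-sectional cytoplasm area (cell minus nucleus) at height z."""
        h = z_um - self.center_um[2]

        def area(a: float, c: float) -> float:
            if abs(h) >= c:
                return 0.0
            return math.pi * a * a * (1.0 - (h / c) ** 2)

        na, nc = self.nucleus_radii
        return area(self.radius_lateral_um, self.radius_axial_um) - area(na, nc)


@dataclass
class SceneGroundTruth:
    """Everything the generator placed: per-cell states and per-spot records.

    cells : one row per cell — true pairing state, inter-allele distance,
        per-allele amplitudes, true dot counts (mid-plane / whole-cell /
        contamination).
    spots : one row per rendered spot — field, cell, channel, kind
        (locus / mrna / contamination), coordinates and amplitude.
    """

    cells: pd.DataFrame
    spots: pd.DataFrame


@dataclass
class Scene:
    """A generated scene: rendered fields, the cell table and the truth."""

    config: SceneConfig
    fields: list[FieldOfView]
    cells: pd.DataFrame
    truth: SceneGroundTruth

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fields(self.fields, out_dir)
        write_cells(self.cells, out_dir / "cells.csv")
        write_table(self.truth.cells, out_dir / "truth_cells.csv")
        write_table(self.truth.spots, out_dir / "truth_spots.csv")
        dump_config(self.config, out_dir / "scene_config.json")
        return out_dir


def _axis_profile(centers: np.ndarray, center: float, sigma: float,
                  step: float) -> np.ndarray:
    """Integral of a unit 1D Gaussian over voxel extents [c - s/2, c + s/2]."""
    a = (centers - step / 2.0 - center) / (math.sqrt(2.0) * sigma)
    b = (centers + step / 2.0 - center) / (math.sqrt(2.0) * sigma)
    return 0.5 * (erf(b) - erf(a))


def render_spot(grid: np.ndarray, center_um: tuple[float, float, float],
                amplitude: float, psf_sigma: tuple[float, float],
                voxel_size: tuple[float, float]) -> np.ndarray:
    """Add one anisotropic Gaussian spot to a (z, y, x) grid, in place.

    The spot integrates to ``amplitude`` when fully inside the grid (the
    voxel-extent integrals are exact up to the +/- 6 sigma truncation).
    Raises ``ValueError`` when the centre lies outside the grid.
    """
    nz, ny, nx = grid.shape
    lat, zstep = voxel_size
    sig_lat, sig_ax = psf_sigma
    x, y, z = center_um
    if not (0.0 <= x <= nx * lat and 0.0 <= y <= ny * lat
            and -zstep / 2.0 <= z <= (nz - 0.5) * zstep):
        raise ValueError(
            f"spot centre {center_um} lies outside the grid "
            f"(extent x<{nx * lat:.2f} um, y<{ny * lat:.2f} um, "
            f"z<{(nz - 0.5) * zstep:.2f} um)"
        )
    reach_lat = 6.0 * sig_lat
    reach_ax = 6.0 * sig_ax
    x0, x1 = max(0, int((x - reach_lat) / lat)), min(nx, int((x + reach_lat) / lat) + 2)
    y0, y1 = max(0, int((y - reach_lat) / lat)), min(ny, int((y + reach_lat) / lat) + 2)
    z0, z1 = max(0, int((z - reach_ax) / zstep)), min(nz, int((z + reach_ax) / zstep) + 2)
    # voxel centres: lateral voxel i spans [i*lat, (i+1)*lat); plane k is
    # centred at k*zstep
    px = _axis_profile(np.arange(x0, x1) * lat + lat / 2.0, x, sig_lat, lat)
    py = _axis_profile(np.arange(y0, y1) * lat + lat / 2.0, y, sig_lat, lat)
    pz = _axis_profile(np.arange(z0, z1) * zstep, z, sig_ax, zstep)
    grid[z0:z1, y0:y1, x0:x1] += amplitude * (
        pz[:, None, None] * py[None, :, None] * px[None, None, :]
    )
    return grid


def add_noise(grid: np.ndarray, noise: NoiseParams,
              rng: np.random.Generator) -> np.ndarray:
    """Constant background, optional Poisson shot noise, Gaussian read noise.

    Returns a new float32 grid clamped at zero.
    """
    if not np.isfinite([noise.background, noise.gaussian_sd]).all():
        raise ValueError("noise parameters must be finite")
    out = np.asarray(grid, dtype=np.float64) + noise.background
    if noise.poisson:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(np.float64)
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None).astype(np.float32)


def place_transcript_dots(cell: CellGeometry, rate: float,
                          contamination_rate: float,
                          rng: np.random.Generator,
                          z_step_um: float,
                          n_planes: int) -> tuple[np.ndarray, np.ndarray]:
    """Place cytoplasmic mRNA dots and surface contamination dots.

    Cytoplasmic dots follow a homogeneous spatial Poisson process in the
    cytoplasm (cell minus nucleus), calibrated so that the expected number of
    dots whose nearest plane is the cell's mid-plane equals ``rate``.
    Contamination dots (signal from adjacent somatic cells) sit on a thin
    shell just inside the cell surface.

    Returns ``(dots, contamination)`` as (n, 3) arrays of (x, y, z) um.
    """
    if rate < 0 or contamination_rate < 0:
        raise ValueError("rates must be >= 0")
    cx, cy, cz = cell.center_um
    mid_plane = int(round(cz / z_step_um))

    def slab_volume(k: int, n_grid: int = 20) -> float:
        zs = (k + (np.arange(n_grid) + 0.5) / n_grid - 0.5) * z_step_um
        areas = [cell.cytoplasm_area_um2(z) for z in zs]
        return float(np.mean(areas) * z_step_um)

    v_mid = slab_volume(mid_plane)
    dots = []
    if rate > 0 and v_mid > 0:
        density = rate / v_mid
        k_reach = int(math.ceil(cell.radius_axial_um / z_step_um)) + 1
        for k in range(max(0, mid_plane - k_reach),
                       min(n_planes, mid_plane + k_reach + 1)):
            vk = slab_volume(k)
            n_k = rng.poisson(density * vk)
            placed = 0
            a = cell.radius_lateral_um
            while placed < n_k:
                m = (n_k - placed) * 3 + 8
                cand = np.empty((m, 3))
                cand[:, 0] = cx + rng.uniform(-a, a, m)
                cand[:, 1] = cy + rng.uniform(-a, a, m)
                cand[:, 2] = (k + rng.uniform(-0.5, 0.5, m)) * z_step_um
                ok = cell.in_cell(cand) & ~cell.in_nucleus(cand)
                take = cand[ok][: n_k - placed]
                dots.extend(take)
                placed += len(take)
    contamination = []
    n_c = rng.poisson(contamination_rate) if contamination_rate > 0 else 0
    if n_c:
        u = rng.normal(size=(n_c, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        f = rng.uniform(0.92, 0.99, n_c)
        contamination = np.column_stack([
            cx + cell.radius_lateral_um * u[:, 0] * f,
            cy + cell.radius_lateral_um * u[:, 1] * f,
            cz + cell.radius_axial_um * u[:, 2] * f,
        ])
    dots_arr = np.asarray(dots, dtype=float).reshape(-1, 3)
    cont_arr = np.asarray(contamination, dtype=float).reshape(-1, 3)
    return dots_arr, cont_arr


def _lognorm_factor(rng: np.random.Generator, cv: float, n: int = 1) -> np.ndarray:
    """Unit-mean lognormal multiplicative variation with the given CV."""
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, n)


def _draw_unpaired_distance(cfg: SceneConfig, rng: np.random.Generator) -> float:
    mean, sd = cfg.unpaired_distance_dist
    if sd == 0:
        return max(mean, cfg.unpaired_distance_min)
    a = (cfg.unpaired_distance_min - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _generate_cell(cfg: SceneConfig, stage: str, cell: CellGeometry,
                   rng: np.random.Generator):
    """Draw one cell's loci, pairing state and amplitudes.

    Returns (sites, state, distance_um, allele_amps, n_split) where sites is
    a list of (pos, dna_amp, nascent_amp) puncta to render.
    """
    na_, nc_ = cell.nucleus_radii
    na = na_ * _LOCUS_RADIUS_FRACTION
    nc = nc_ * _LOCUS_RADIUS_FRACTION
    cx, cy, cz = cell.center_um

    def random_point() -> np.ndarray:
        while True:
            p = rng.uniform(-1, 1, 3)
            if p @ p <= 1.0:
                return np.array([cx + na * p[0], cy + na * p[1], cz + nc * p[2]])

    def inside_nucleus(p: np.ndarray) -> bool:
        return bool(cell.contains(p, na_, nc_)[0])

    if cfg.n_alleles == 1:
        allele_pos = [random_point()]
        state, distance = "single", 0.0
    else:
        paired = rng.random() < cfg.pairing_prob[stage]
        if paired:
            p = random_point()
            allele_pos = [p, p.copy()]
            state, distance = "paired", 0.0
        else:
            state = "unpaired"
            for _ in range(200):
                centre = random_point()
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                distance = _draw_unpaired_distance(cfg, rng)
                p1 = centre + 0.5 * distance * u
                p2 = centre - 0.5 * distance * u
                if inside_nucleus(p1) and inside_nucleus(p2):
                    allele_pos = [p1, p2]
                    break
            else:  # fall back to a lateral split about the nucleus centre
                u = np.array([1.0, 0.0, 0.0])
                distance = min(_draw_unpaired_distance(cfg, rng), 2 * na * 0.9)
                base = np.array([cx, cy, cz])
                allele_pos = [base + 0.5 * distance * u, base - 0.5 * distance * u]

    suppressed = state == "unpaired"
    allele_amps = []
    for _ in allele_pos:
        dna_amp = cfg.dna_amplitude * _lognorm_factor(rng, cfg.amplitude_cv)[0]
        nas = cfg.nascent_rate[stage] * _lognorm_factor(rng, cfg.amplitude_cv)[0]
        if suppressed:
            nas *= cfg.suppression_factor
        allele_amps.append((dna_amp, nas))

    sites: list[tuple[np.ndarray, float, float]] = []
    n_split = 0
    for pos, (dna_amp, nas_amp) in zip(allele_pos, allele_amps):
        if rng.random() < cfg.sister_split_prob:
            n_split += 1
            d = rng.uniform(*SISTER_SPLIT_RANGE_UM)
            for _ in range(200):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                q1 = pos + 0.5 * d * u
                q2 = pos - 0.5 * d * u
                if inside_nucleus(q1) and inside_nucleus(q2):
                    break
            sites.append((q1, dna_amp / 2, nas_amp / 2))
            sites.append((q2, dna_amp / 2, nas_amp / 2))
        else:
            sites.append((pos, dna_amp, nas_amp))

    # distinct rendered puncta: colocalized (paired, unsplit) alleles merge
    merged: list[list] = []
    for pos, d_amp, n_amp in sites:
        for m in merged:
            if np.linalg.norm(m[0] - pos) < 0.05:
                m[1] += d_amp
                m[2] += n_amp
                break
        else:
            merged.append([pos, d_amp, n_amp])
    return merged, state, distance, allele_amps, n_split


def generate_scene(config: SceneConfig) -> Scene:
    """Generate rendered fields, the cell annotation table and ground truth.

    Deterministic: identical (config, seed) gives bit-identical stacks and
    tables.  Cells of all stages are interleaved across fields so that every
    field carries CySC reference cells.
    """
    cfg = config
    if cfg.cells_per_field > MAX_CELLS_PER_FIELD:
        raise CapacityError(
            f"cells_per_field={cfg.cells_per_field} exceeds the "
            f"{MAX_CELLS_PER_FIELD}-cell field capacity; lower it and let the "
            f"generator emit more fields"
        )
    lat, zstep = cfg.voxel_size
    r_lat, r_ax = cfg.cell_radius_um

    # deal cells round-robin across fields so every field carries a
    # proportional stage mix (in particular CySC reference cells); the
    # deal order is deterministic
    n_total = sum(cfg.n_cells_per_stage.values())
    if n_total == 0:
        raise ConfigError("scene has zero cells")
    n_fields = int(math.ceil(n_total / cfg.cells_per_field))
    fields_rosters: list[list[str]] = [[] for _ in range(n_fields)]
    deal = 0
    for s in cfg.stage_labels:
        for _ in range(cfg.n_cells_per_stage[s]):
            fields_rosters[deal % n_fields].append(s)
            deal += 1

    n_cols = int(math.ceil(math.sqrt(cfg.cells_per_field)))
    margin = r_lat + 1.0
    side_um = n_cols * cfg.cell_spacing_um + 2 * margin - cfg.cell_spacing_um + 0.0
    n_xy = int(math.ceil((2 * margin + n_cols * cfg.cell_spacing_um) / lat))
    n_z = 2 * int(math.ceil(r_ax / zstep)) + 7
    mid_plane = n_z // 2
    del side_um

    if cfg.cell_spacing_um < 2 * r_lat + 1.0:
        raise CapacityError(
            f"cell_spacing_um={cfg.cell_spacing_um} cannot hold cells of "
            f"lateral radius {r_lat} um without overlap"
        )

    fields: list[FieldOfView] = []
    cell_rows, truth_rows, spot_rows = [], [], []
    cell_counter = 0

    for f_idx, f_roster in enumerate(fields_rosters):
        field_name = f"fov{f_idx:03d}"
        grids = np.zeros((len(CHANNELS), n_z, n_xy, n_xy), dtype=np.float64)
        masks = np.zeros((n_z, n_xy, n_xy), dtype=np.uint16)
        layout_rng = np.random.default_rng([cfg.seed, f_idx, 777_001])

        for c_idx, stage in enumerate(f_roster):
            cell_counter += 1
            cell_id = f"cell{cell_counter:05d}"
            mask_label = c_idx + 1
            rng = np.random.default_rng([cfg.seed, f_idx, c_idx])
            gi, gj = divmod(c_idx, n_cols)
            cx = margin + gj * cfg.cell_spacing_um + layout_rng.uniform(-0.4, 0.4)
            cy = margin + gi * cfg.cell_spacing_um + layout_rng.uniform(-0.4, 0.4)
            cz = mid_plane * zstep
            geom = CellGeometry((cx, cy, cz), r_lat, r_ax)

            _rasterize_mask(masks, geom, lat, zstep, mask_label)

            sites, state, distance, allele_amps, n_split = _generate_cell(
                cfg, stage, geom, rng
            )
            for pos, dna_amp, nas_amp in sites:
                render_spot(grids[0], tuple(pos), dna_amp, cfg.psf_sigma, cfg.voxel_size)
                render_spot(grids[1], tuple(pos), nas_amp, cfg.psf_sigma, cfg.voxel_size)
                for ch, amp in (("dna", dna_amp), ("intron", nas_amp)):
                    spot_rows.append(dict(
                        field=field_name, cell_id=cell_id, channel=ch,
                        kind="locus", x_um=pos[0], y_um=pos[1], z_um=pos[2],
                        z_plane=int(round(pos[2] / zstep)), amplitude=amp,
                    ))

            dots, cont = place_transcript_dots(
                geom, cfg.mrna_rate[stage], cfg.contamination_rate, rng,
                zstep, n_z,
            )
            mid_count = 0
            for p in dots:
                amp = cfg.mrna_dot_amplitude * _lognorm_factor(rng, 0.1)[0]
                render_spot(grids[2], tuple(p), amp, cfg.psf_sigma, cfg.voxel_size)
                kz = int(round(p[2] / zstep))
                mid_count += int(kz == mid_plane)
                spot_rows.append(dict(
                    field=field_name, cell_id=cell_id, channel="exon",
                    kind="mrna", x_um=p[0], y_um=p[1], z_um=p[2],
                    z_plane=kz, amplitude=amp,
                ))
            cont_mid = 0
            for p in cont:
                amp = cfg.mrna_dot_amplitude * _lognorm_factor(rng, 0.1)[0]
                render_spot(grids[2], tuple(p), amp, cfg.psf_sigma, cfg.voxel_size)
                kz = int(round(p[2] / zstep))
                cont_mid += int(kz == mid_plane)
                spot_rows.append(dict(
                    field=field_name, cell_id=cell_id, channel="exon",
                    kind="contamination", x_um=p[0], y_um=p[1], z_um=p[2],
                    z_plane=kz, amplitude=amp,
                ))

            cell_rows.append(dict(
                cell_id=cell_id, field=field_name, stage=stage,
                genotype="synthetic", mask_label=mask_label,
                mid_plane=mid_plane, cycle_tag="unknown",
            ))
            a1 = allele_amps[0]
            a2 = allele_amps[1] if len(allele_amps) > 1 else (np.nan, np.nan)
            truth_rows.append(dict(
                cell_id=cell_id, field=field_name, stage=stage,
                mask_label=mask_label, mid_plane=mid_plane,
                true_state=state, true_distance_um=distance,
                true_n_foci=len(sites), n_split_alleles=n_split,
                dna_amp_allele1=a1[0], dna_amp_allele2=a2[0],
                nascent_amp_allele1=a1[1], nascent_amp_allele2=a2[1],
                true_mid_dots=mid_count, true_wholecell_dots=len(dots),
                contamination_dots=len(cont), contamination_mid_dots=cont_mid,
                center_x_um=cx, center_y_um=cy, center_z_um=cz,
            ))

        noise_rng = np.random.default_rng([cfg.seed, f_idx, 999_999])
        noisy = np.stack([
            add_noise(grids[c], cfg.noise, noise_rng) for c in range(len(CHANNELS))
        ])
        stack = ImageStack(
            voxels=noisy, lateral_size_um=lat, z_step_um=zstep,
            channel_names=CHANNELS,
        )
        fields.append(FieldOfView(name=field_name, stack=stack, masks=masks))

    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "field", "stage", "genotype", "mask_label",
                 "mid_plane", "cycle_tag"],
    )
    truth = SceneGroundTruth(
        cells=pd.DataFrame(truth_rows),
        spots=pd.DataFrame(
            spot_rows,
            columns=["field", "cell_id", "channel", "kind", "x_um", "y_um",
                     "z_um", "z_plane", "amplitude"],
        ),
    )
    return Scene(config=cfg, fields=fields, cells=cells, truth=truth)


def _rasterize_mask(masks: np.ndarray, geom: CellGeometry, lat: float,
                    zstep: float, label: int) -> None:
    """Fill the cell's spheroid into the label grid (background voxels only)."""
    nz, ny, nx = masks.shape
    cx, cy, cz = geom.center_um
    a, c = geom.radius_lateral_um, geom.radius_axial_um
    x0, x1 = max(0, int((cx - a) / lat)), min(nx, int((cx + a) / lat) + 2)
    y0, y1 = max(0, int((cy - a) / lat)), min(ny, int((cy + a) / lat) + 2)
    z0, z1 = max(0, int((cz - c) / zstep) - 1), min(nz, int((cz + c) / zstep) + 2)
    xs = (np.arange(x0, x1) + 0.5) * lat
    ys = (np.arange(y0, y1) + 0.5) * lat
    zs = np.arange(z0, z1) * zstep
    inside = (((xs[None, None, :] - cx) / a) ** 2
              + ((ys[None, :, None] - cy) / a) ** 2
              + ((zs[:, None, None] - cz) / c) ** 2) <= 1.0
    region = masks[z0:z1, y0:y1, x0:x1]
    region[inside & (region == 0)] = label
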