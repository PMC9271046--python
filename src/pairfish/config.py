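"""Configuration objects for the synthetic scene generator and the pipeline.

Two documents drive everything: a :class:`SceneConfig` (what the simulated
tissue looks like) and a :class:`PipelineConfig` (how it is measured).  Both
load from YAML/JSON mappings with strict unknown-key rejection so that a typo
in a config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Closed vocabulary of cell stages, in developmental order.  CySC is the
#: somatic cyst stem cell used as the internal intensity reference.
STAGES: tuple[str, ...] = ("GSC", "GB", "SG2_4", "SG8_16", "SC", "CySC")

GERMLINE_STAGES: tuple[str, ...] = ("GSC", "GB", "SG2_4", "SG8_16", "SC")

SCHEMA_VERSION = "1"


class ConfigError(ValueError):
    """Raised when a configuration value or key is invalid."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if not (value >= 0.0):
        raise ConfigError(f"{name} must be >= 0, got {value!r}")


def _check_pos(name: str, value: float) -> None:
    if not (value > 0.0):
        raise ConfigError(f"{name} must be > 0, got {value!r}")


def _stage_map(name: str, value, stages: tuple[str, ...]) -> dict[str, float]:
    """Broadcast a scalar to all stages, or validate a per-stage mapping."""
    if isinstance(value, (int, float)):
        return {s: float(value) for s in stages}
    if isinstance(value, Mapping):
        unknown = set(value) - set(stages)
        if unknown:
            raise ConfigError(
                f"{name} has entries for unknown stages {sorted(unknown)}; "
                f"allowed: {list(stages)}"
            )
        missing = set(stages) - set(value)
        if missing:
            raise ConfigError(f"{name} is missing stages {sorted(missing)}")
        return {s: float(value[s]) for s in stages}
    raise ConfigError(f"{name} must be a number or a per-stage mapping")


@dataclass(frozen=True)
class NoiseParams:
    """Additive camera/photon noise model.

    background : constant offset added to every voxel (a.u.)
    gaussian_sd : read-noise standard deviation (a.u.)
    poisson : apply Poisson shot noise to signal + background
    """

    background: float = 20.0
    gaussian_sd: float = 3.0
    poisson: bool = True

    def __post_init__(self) -> None:
        _check_nonneg("noise.background", self.background)
        _check_nonneg("noise.gaussian_sd", self.gaussian_sd)


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic testis-tip FISH scene.

    Distances are in micrometres, intensities in arbitrary units.  Stage-keyed
    parameters accept either a scalar (broadcast) or a per-stage mapping.
    Defaults emulate wild-type tissue: high homolog pairing in stem cells that
    drops upon differentiation, and a roughly two-fold decline in cytoplasmic
    mRNA density from GSC to 2-4-cell spermatogonia.
    """

    n_cells_per_stage: Mapping[str, int] | int = field(
        default_factory=lambda: {
            "GSC": 10, "GB": 10, "SG2_4": 10, "SG8_16": 8, "SC": 6, "CySC": 8,
        }
    )
    stage_labels: tuple[str, ...] = STAGES
    # probability that the two homologous loci are colocalized (one punctum)
    pairing_prob: Mapping[str, float] | float = field(
        default_factory=lambda: {
            "GSC": 0.85, "GB": 0.45, "SG2_4": 0.35, "SG8_16": 0.5,
            "SC": 0.9, "CySC": 0.95,
        }
    )
    # (mean, sd) of the truncated-normal inter-allele 3D distance when unpaired
    unpaired_distance_dist: tuple[float, float] = (1.5, 0.5)
    unpaired_distance_min: float = 0.5
    n_alleles: int = 2
    # probability that a locus resolves as two sister sub-foci (S-phase mimic)
    sister_split_prob: float = 0.05
    # expected cytoplasmic mRNA dots on the cell's mid-plane, per stage
    mrna_rate: Mapping[str, float] | float = field(
        default_factory=lambda: {
            "GSC": 12.0, "GB": 9.0, "SG2_4": 6.0, "SG8_16": 5.0,
            "SC": 4.0, "CySC": 8.0,
        }
    )
    # expected integrated nascent-transcript intensity per allele, per stage
    nascent_rate: Mapping[str, float] | float = field(
        default_factory=lambda: {
            "GSC": 2000.0, "GB": 1600.0, "SG2_4": 1000.0, "SG8_16": 600.0,
            "SC": 300.0, "CySC": 1800.0,
        }
    )
    # multiplier on per-allele nascent output when the locus is unpaired
    suppression_factor: float = 1.0
    dna_amplitude: float = 1500.0
    mrna_dot_amplitude: float = 1200.0
    amplitude_cv: float = 0.15
    psf_sigma: tuple[float, float] = (0.08, 0.25)  # (lateral, axial) um
    voxel_size: tuple[float, float] = (0.1, 0.5)   # (lateral, z-step) um
    noise: NoiseParams = field(default_factory=NoiseParams)
    # expected somatic-surface contamination dots per cell (exon channel)
    contamination_rate: float = 2.0
    # geometry
    cell_radius_um: tuple[float, float] = (4.0, 3.0)  # (lateral, axial)
    cell_spacing_um: float = 9.0
    cells_per_field: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        stages = tuple(self.stage_labels)
        if len(set(stages)) != len(stages):
            raise ConfigError("stage_labels must be unique")
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ConfigError(
                f"stage_labels contains unknown stages {sorted(unknown)}; "
                f"allowed: {list(STAGES)}"
            )
        object.__setattr__(self, "stage_labels", stages)
        if isinstance(self.n_cells_per_stage, int):
            counts = {s: int(self.n_cells_per_stage) for s in stages}
        else:
            counts = {
                s: int(v)
                for s, v in _stage_map("n_cells_per_stage",
                                       dict(self.n_cells_per_stage), stages).items()
            }
        for s, c in counts.items():
            if c < 0:
                raise ConfigError(f"n_cells_per_stage[{s}] must be >= 0")
        object.__setattr__(self, "n_cells_per_stage", counts)
        object.__setattr__(
            self, "pairing_prob", _stage_map("pairing_prob", self.pairing_prob, stages)
        )
        for s, p in self.pairing_prob.items():
            _check_prob(f"pairing_prob[{s}]", p)
        object.__setattr__(
            self, "mrna_rate", _stage_map("mrna_rate", self.mrna_rate, stages)
        )
        for s, r in self.mrna_rate.items():
            _check_nonneg(f"mrna_rate[{s}]", r)
        object.__setattr__(
            self, "nascent_rate", _stage_map("nascent_rate", self.nascent_rate, stages)
        )
        for s, r in self.nascent_rate.items():
            _check_nonneg(f"nascent_rate[{s}]", r)
        _check_prob("sister_split_prob", self.sister_split_prob)
        if self.n_alleles not in (1, 2):
            raise ConfigError(f"n_alleles must be 1 or 2, got {self.n_alleles!r}")
        mean, sd = self.unpaired_distance_dist
        _check_pos("unpaired_distance_dist mean", mean)
        _check_nonneg("unpaired_distance_dist sd", sd)
        _check_pos("unpaired_distance_min", self.unpaired_distance_min)
        _check_pos("suppression_factor", self.suppression_factor)
        _check_pos("dna_amplitude", self.dna_amplitude)
        _check_pos("mrna_dot_amplitude", self.mrna_dot_amplitude)
        _check_nonneg("amplitude_cv", self.amplitude_cv)
        for label, v in (("psf_sigma lateral", self.psf_sigma[0]),
                         ("psf_sigma axial", self.psf_sigma[1]),
                         ("voxel_size lateral", self.voxel_size[0]),
                         ("voxel_size z-step", self.voxel_size[1]),
                         ("cell_radius_um lateral", self.cell_radius_um[0]),
                         ("cell_radius_um axial", self.cell_radius_um[1]),
                         ("cell_spacing_um", self.cell_spacing_um)):
            _check_pos(label, v)
        _check_nonneg("contamination_rate", self.contamination_rate)
        if self.cells_per_field < 1:
            raise ConfigError("cells_per_field must be >= 1")
        if not isinstance(self.noise, NoiseParams):
            if isinstance(self.noise, Mapping):
                object.__setattr__(self, "noise", NoiseParams(**dict(self.noise)))
            else:
                raise ConfigError("noise must be a mapping or NoiseParams")


@dataclass(frozen=True)
class DetectionParams:
    """Spot-detection and intensity-integration knobs.

    sigma_um : (lateral, axial) matched-filter Gaussian sigma; should track
        the optical PSF.
    threshold_k : detection threshold in robust-SD units above the filtered
        background (median + k * 1.4826 * MAD).
    min_separation_um : (lateral, axial) minimum separation between maxima;
        closer peaks merge into one detection (the operational definition of
        "paired" signal).
    integration_radius_sigma : half-width of the lateral integration box, in
        units of lateral sigma.
    plane_peak_fraction : neighbour z-planes whose in-plane peak is at least
        this fraction of the brightest plane's peak join the 1-3-plane
        integration span.
    annulus_width_px : width (voxels) of the local-background annulus.
    """

    sigma_um: tuple[float, float] = (0.08, 0.25)
    threshold_k: float = 6.0
    min_separation_um: tuple[float, float] = (0.12, 0.5)
    integration_radius_sigma: float = 4.0
    plane_peak_fraction: float = 0.15
    annulus_width_px: int = 2

    def __post_init__(self) -> None:
        _check_pos("sigma_um lateral", self.sigma_um[0])
        _check_pos("sigma_um axial", self.sigma_um[1])
        _check_pos("threshold_k", self.threshold_k)
        _check_pos("integration_radius_sigma", self.integration_radius_sigma)
        if not (0.0 < self.plane_peak_fraction <= 1.0):
            raise ConfigError("plane_peak_fraction must be in (0, 1]")
        if self.annulus_width_px < 1:
            raise ConfigError("annulus_width_px must be >= 1")


@dataclass(frozen=True)
class PairingParams:
    """Pairing-classification quality-control knobs.

    outlier_k : a punctum is flagged when its intensity falls outside
        [cohort median / k, cohort median * k] within its focus-count cohort.
    min_cohort : below this cohort size the outlier filter is disabled.
    three_foci_policy : 'exclude' (default) drops 3-focus cells as ambiguous
        sister-chromatid patterns; 'keep' scores the two brightest foci as an
        unpaired pair.
    """

    outlier_k: float = 3.0
    min_cohort: int = 10
    three_foci_policy: str = "exclude"

    def __post_init__(self) -> None:
        if self.outlier_k <= 1.0:
            raise ConfigError("outlier_k must be > 1")
        if self.min_cohort < 2:
            raise ConfigError("min_cohort must be >= 2")
        if self.three_foci_policy not in ("exclude", "keep"):
            raise ConfigError("three_foci_policy must be 'exclude' or 'keep'")


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level pipeline configuration: scene + measurement + statistics."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    pairing: PairingParams = field(default_factory=PairingParams)
    si_stages: tuple[str, str] = ("GSC", "SG2_4")
    min_cells_per_stage: int = 5
    bootstrap_resamples: int = 2000
    adjustment: str = "sidak"
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.si_stages:
            if s not in STAGES:
                raise ConfigError(f"si_stages stage {s!r} not in {list(STAGES)}")
        if self.min_cells_per_stage < 1:
            raise ConfigError("min_cells_per_stage must be >= 1")
        if self.bootstrap_resamples < 10:
            raise ConfigError("bootstrap_resamples must be >= 10")
        if self.adjustment not in ("none", "sidak"):
            raise ConfigError("adjustment must be 'none' or 'sidak'")
        for dc, name in ((self.scene, "scene"), (self.detection, "detection"),
                         (self.pairing, "pairing")):
            if isinstance(dc, Mapping):
                raise ConfigError(f"{name} must be built via from_mapping/load")


def _from_mapping(cls, data: Mapping[str, Any], path: str = ""):
    """Build a (possibly nested) config dataclass from a plain mapping,
    rejecting unknown keys with a nearest-key hint."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in fields:
            hint = difflib.get_close_matches(key, fields, n=1)
            loc = f"{path}{key}"
            msg = f"unknown config key {loc!r}"
            if hint:
                msg += f" (did you mean {hint[0]!r}?)"
            raise ConfigError(msg)
        ftype = fields[key].type
        nested = {
            "scene": SceneConfig, "detection": DetectionParams,
            "pairing": PairingParams, "noise": NoiseParams,
        }
        if key in nested and isinstance(value, Mapping):
            value = _from_mapping(nested[key], value, path=f"{path}{key}.")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
        del ftype
    return cls(**kwargs)


def scene_config_from_mapping(data: Mapping[str, Any]) -> SceneConfig:
    return _from_mapping(SceneConfig, data)


def pipeline_config_from_mapping(data: Mapping[str, Any]) -> PipelineConfig:
    return _from_mapping(PipelineConfig, data)


def load_config(path: str | Path, kind: str = "pipeline"):
    """Load a SceneConfig or PipelineConfig from a YAML or JSON file.

    An empty document yields the full default config.  Unknown keys are
    rejected with a nearest-key suggestion.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config root in {path} must be a mapping")
    if kind == "scene":
        return scene_config_from_mapping(data)
    if kind == "pipeline":
        return pipeline_config_from_mapping(data)
    raise ConfigError(f"unknown config kind {kind!r}")


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_as_jsonable(v) for v in obj]
    return obj


def dump_config(config, path: str | Path) -> Path:
    """Write a config dataclass as JSON (also valid YAML)."""
    path = Path(path)
    path.write_text(json.dumps(_as_jsonable(config), indent=2) + "\n")
    return path
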