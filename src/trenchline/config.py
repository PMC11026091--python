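"""Typed pipeline configuration shared by every stage.

The parameter set mirrors the knobs of a classical mother-machine analysis:
channel geometry for compilation, the alignment window for background
subtraction, morphological/threshold settings for segmentation, and the
decision-tree bounds for tracking.  A flat, human-readable key/value file
(YAML with dotted section prefixes, e.g. ``segment.otsu_scale: 1.2``)
overrides the defaults; everything is validated eagerly so a bad value
fails loudly with the offending key named.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PipelineParams",
    "CompileParams",
    "SubtractParams",
    "SegmentParams",
    "TrackParams",
    "Calibration",
    "ParamError",
    "load_params",
    "serialize_params",
    "effective_pixel_size",
]


class ParamError(ValueError):
    """Raised for malformed configuration documents or out-of-range values."""


def effective_pixel_size(camera_pixel: float, magnification: float) -> float:
    """Physical size of one image pixel, in µm/px.

    ``camera_pixel`` is the camera sensor pixel pitch in µm and
    ``magnification`` the total optical magnification; e.g. a 6.5 µm sensor
    behind a 100x objective images 0.065 µm per pixel.
    """
    if camera_pixel <= 0:
        raise ParamError(f"camera_pixel must be > 0, got {camera_pixel}")
    if magnification <= 0:
        raise ParamError(f"magnification must be > 0, got {magnification}")
    return camera_pixel / magnification


@dataclass
class Calibration:
    """Physical calibration; defaults are dimensionless (1 px, 1 frame)."""

    pixel_size: float = 1.0  # µm per px
    frame_interval: float = 1.0  # minutes per frame

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ParamError(f"calibration.pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval <= 0:
            raise ParamError(
                f"calibration.frame_interval must be > 0, got {self.frame_interval}"
            )


@dataclass
class CompileParams:
    channel_width: float = 10.0  # px, expected growth-channel width
    channel_separation: float = 45.0  # px, center-to-center spacing
    empty_threshold: float = 0.97  # y-profile time-correlation cut for empty channels
    correlation_lag: int = 0  # frame lag for the correlation score; 0 = auto (~T/10)

    def validate(self) -> None:
        if self.channel_width <= 0:
            raise ParamError(f"compile.channel_width must be > 0, got {self.channel_width}")
        if self.channel_separation <= 0:
            raise ParamError(
                f"compile.channel_separation must be > 0, got {self.channel_separation}"
            )
        if not -1.0 <= self.empty_threshold <= 1.0:
            raise ParamError(
                f"compile.empty_threshold must be in [-1, 1], got {self.empty_threshold}"
            )
        if self.correlation_lag < 0:
            raise ParamError(
                f"compile.correlation_lag must be >= 0, got {self.correlation_lag}"
            )


@dataclass
class SubtractParams:
    align_pad: int = 10  # px, max alignment search shift

    def validate(self) -> None:
        if self.align_pad < 0:
            raise ParamError(f"subtract.align_pad must be >= 0, got {self.align_pad}")


@dataclass
class SegmentParams:
    first_opening: int = 2  # px, disk radius of the first morphological opening
    distance_threshold: float = 2.0  # px, cut on the Euclidean distance transform
    second_opening: int = 1  # px, disk radius of the second opening
    otsu_scale: float = 1.0  # dimensionless multiplier on the Otsu threshold
    min_object_size: int = 25  # px^2, regions smaller than this are dropped
    random_walker_beta: float = 130.0  # diffusion sharpness of the random walker

    def validate(self) -> None:
        for key in ("first_opening", "distance_threshold", "second_opening",
                    "otsu_scale", "min_object_size", "random_walker_beta"):
            v = getattr(self, key)
            if v <= 0:
                raise ParamError(f"segment.{key} must be > 0, got {v}")


@dataclass
class TrackParams:
    growth_length_ratio: tuple[float, float] = (0.8, 1.3)
    growth_area_ratio: tuple[float, float] = (0.8, 1.3)
    lost_cell_time: int = 3  # frames a vanished cell is retried before being lost
    new_cell_y_cutoff: float = 150.0  # px from the closed end

    def validate(self) -> None:
        for key in ("growth_length_ratio", "growth_area_ratio"):
            lo, hi = getattr(self, key)
            if not (0 < lo < 1 < hi):
                raise ParamError(
                    f"track.{key} must satisfy 0 < min < 1 < max, got ({lo}, {hi})"
                )
        if self.lost_cell_time <= 0:
            raise ParamError(f"track.lost_cell_time must be > 0, got {self.lost_cell_time}")
        if self.new_cell_y_cutoff <= 0:
            raise ParamError(
                f"track.new_cell_y_cutoff must be > 0, got {self.new_cell_y_cutoff}"
            )


@dataclass
class PipelineParams:
    """The full parameter set; single source of truth for all stages."""

    compile: CompileParams = field(default_factory=CompileParams)
    subtract: SubtractParams = field(default_factory=SubtractParams)
    segment: SegmentParams = field(default_factory=SegmentParams)
    track: TrackParams = field(default_factory=TrackParams)
    calibration: Calibration = field(default_factory=Calibration)

    def validate(self) -> "PipelineParams":
        for section in dataclasses.fields(self):
            getattr(self, section.name).validate()
        return self

    def replace(self, **dotted: object) -> "PipelineParams":
        """Return a copy with dotted-key overrides, e.g. ``segment.otsu_scale=1.2``.

        Keys are given with ``__`` in place of the dot when used as Python
        keyword arguments (``segment__otsu_scale=1.2``) or as a mapping of
        dotted strings.
        """
        flat = dict(_flatten(serial_dict(self)))
        for key, value in dotted.items():
            flat[key.replace("__", ".")] = value
        return _from_flat(flat)


_SECTIONS = ("compile", "subtract", "segment", "track", "calibration")
_TUPLE_KEYS = {"track.growth_length_ratio", "track.growth_area_ratio"}


def serial_dict(params: PipelineParams) -> dict:
    """Nested plain-dict form of the parameter set (tuples become lists)."""
    out: dict = {}
    for section in _SECTIONS:
        sec = getattr(params, section)
        out[section] = {
            f.name: (list(v) if isinstance(v := getattr(sec, f.name), tuple) else v)
            for f in dataclasses.fields(sec)
        }
    return out


def _flatten(nested: dict, prefix: str = ""):
    for key, value in nested.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, dict):
            yield from _flatten(value, f"{dotted}.")
        else:
            yield dotted, value


def _known_keys() -> dict[str, type]:
    defaults = PipelineParams()
    return {dotted: type(v) for dotted, v in _flatten(serial_dict(defaults))}


def _from_flat(flat: dict) -> PipelineParams:
    known = _known_keys()
    sections = {name: {} for name in _SECTIONS}
    for dotted, value in flat.items():
        if dotted not in known:
            raise ParamError(f"unknown parameter: {dotted!r}")
        section, key = dotted.split(".", 1)
        if dotted in _TUPLE_KEYS:
            if not (isinstance(value, (list, tuple)) and len(value) == 2):
                raise ParamError(f"{dotted} must be a (min, max) pair, got {value!r}")
            value = (float(value[0]), float(value[1]))
        elif isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ParamError(f"{dotted} must be a number, got {value!r}")
        sections[section][key] = value
    params = PipelineParams(
        compile=CompileParams(**sections["compile"]),
        subtract=SubtractParams(**sections["subtract"]),
        segment=SegmentParams(**sections["segment"]),
        track=TrackParams(**sections["track"]),
        calibration=Calibration(**sections["calibration"]),
    )
    return params.validate()


def load_params(source: str | Path | dict | None = None) -> PipelineParams:
    """Load a parameter set, filling unspecified keys with the defaults.

    ``source`` may be None/empty (all defaults), a YAML document or path to
    one, or an already-parsed mapping.  Keys use dotted section prefixes
    (``segment.otsu_scale``) or equivalently nested sections.  Unknown keys
    are rejected rather than silently ignored.
    """
    if source is None:
        doc: dict = {}
    elif isinstance(source, dict):
        doc = source
    else:
        if isinstance(source, Path):
            text = source.read_text()
        elif source.strip() and "\n" not in source and (
            source.endswith((".yaml", ".yml")) or Path(source).is_file()
        ):
            text = Path(source).read_text()
        else:
            text = source
        try:
            parsed = yaml.safe_load(io.StringIO(text))
        except yaml.YAMLError as exc:
            raise ParamError(f"malformed configuration document: {exc}") from exc
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise ParamError("configuration document must be a key/value mapping")
        doc = parsed

    flat = dict(_flatten(serial_dict(PipelineParams())))
    for key, value in doc.items():
        if isinstance(value, dict):  # nested section form
            for sub, v in _flatten(value, f"{key}."):
                flat[sub] = v
        else:
            flat[key] = value
    return _from_flat(flat)


def serialize_params(params: PipelineParams) -> str:
    """Flat dotted-key YAML document; ``load_params`` round-trips it."""
    flat = dict(_flatten(serial_dict(params)))
    return yaml.safe_dump(flat, sort_keys=True, default_flow_style=None)
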