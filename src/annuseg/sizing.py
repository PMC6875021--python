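"""Prosthesis-size selection from annulus measurements.

Balloon-expandable Edwards Sapien 3 valves are sized by annulus *area*,
self-expanding Medtronic Evolut valves by annulus *perimeter*.  Charts are
ordered, contiguous, non-overlapping half-open bands ``[lower, upper)``
mapping a measurement interval to a size label; values outside the chart
yield explicit out-of-range sentinels rather than the nearest size, leaving
the final interpretation to the physician.

The numeric bands ship as editable YAML data files
(:data:`DEFAULT_SAPIEN3_CHART`, :data:`DEFAULT_EVOLUT_CHART`): they are
transcriptions of publicly available manufacturer sizing matrices, not
ground truth, and any chart with the same schema can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .core import Measurement, ValidationError

__all__ = [
    "SizingChart",
    "DeviceSelection",
    "OUT_OF_RANGE_LOW",
    "OUT_OF_RANGE_HIGH",
    "load_chart",
    "default_chart_path",
    "select_size",
    "size_case",
]

OUT_OF_RANGE_LOW = "OUT_OF_RANGE_LOW"
OUT_OF_RANGE_HIGH = "OUT_OF_RANGE_HIGH"

_PARAMETERS = ("area_mm2", "perimeter_mm")


@dataclass(frozen=True)
class SizingChart:
    """Ordered contiguous half-open sizing bands for one device family."""

    device_family: str
    parameter: str  # "area_mm2" or "perimeter_mm"
    bands: tuple[tuple[float, float, str], ...]  # (lower, upper, size_label)

    def validate(self) -> None:
        if self.parameter not in _PARAMETERS:
            raise ValidationError(
                f"parameter must be one of {_PARAMETERS}, got {self.parameter!r}"
            )
        if not self.bands:
            raise ValidationError("chart has no bands")
        for lower, upper, size in self.bands:
            if not lower < upper:
                raise ValidationError(f"band {size!r} has lower {lower} >= upper {upper}")
        for (lo1, up1, s1), (lo2, up2, s2) in zip(self.bands, self.bands[1:]):
            if lo2 < up1:
                raise ValidationError(
                    f"overlapping bands: {s1!r} [{lo1}, {up1}) and {s2!r} [{lo2}, {up2})"
                )
            if lo2 > up1:
                raise ValidationError(
                    f"gap between bands: {s1!r} [{lo1}, {up1}) and {s2!r} [{lo2}, {up2})"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(size for _, _, size in self.bands)


@dataclass(frozen=True)
class DeviceSelection:
    """One sizing decision: device family, chosen label (or sentinel), input."""

    device_family: str
    size_label: str
    input_value: float

    @property
    def in_range(self) -> bool:
        return self.size_label not in (OUT_OF_RANGE_LOW, OUT_OF_RANGE_HIGH)


def default_chart_path(name: str) -> Path:
    """Path of a chart shipped with the package ('sapien3' or 'evolut')."""
    fname = {"sapien3": "sapien3_area.yaml", "evolut": "evolut_perimeter.yaml"}[name]
    return Path(resources.files("annuseg") / "charts" / fname)


def load_chart(path) -> SizingChart:
    """Parse and validate a YAML sizing chart; rejects overlaps and gaps."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        bands = tuple(
            (float(b["lower"]), float(b["upper"]), str(b["size"])) for b in raw["bands"]
        )
        chart = SizingChart(
            device_family=str(raw["device_family"]),
            parameter=str(raw["parameter"]),
            bands=bands,
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed chart file {path}: {exc}") from exc
    chart.validate()
    return chart


def select_size(value: float, chart: SizingChart) -> DeviceSelection:
    """Look up the half-open band containing ``value``.

    Below every band returns the low sentinel, at/above the top band's upper
    bound the high sentinel; band boundaries belong to the upper band.
    """
    chart.validate()
    if not value > 0:
        raise ValidationError(f"measurement must be > 0, got {value}")
    if value < chart.bands[0][0]:
        label = OUT_OF_RANGE_LOW
    elif value >= chart.bands[-1][1]:
        label = OUT_OF_RANGE_HIGH
    else:
        label = next(
            size for lower, upper, size in chart.bands if lower <= value < upper
        )
    return DeviceSelection(
        device_family=chart.device_family, size_label=label, input_value=float(value)
    )


def size_case(
    measurement: Measurement, sapien_chart: SizingChart, evolut_chart: SizingChart
) -> tuple[DeviceSelection, DeviceSelection]:
    """Size one case: Sapien 3 from area, Evolut from perimeter."""
    if sapien_chart.parameter != "area_mm2":
        raise ValidationError("Sapien 3 chart must be parameterised by area_mm2")
    if evolut_chart.parameter != "perimeter_mm":
        raise ValidationError("Evolut chart must be parameterised by perimeter_mm")
    return (
        select_size(measurement.area, sapien_chart),
        select_size(measurement.perimeter, evolut_chart),
    )
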