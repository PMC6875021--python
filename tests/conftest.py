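import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from annuseg.core import AnnularPlane, ProbabilityMap
from annuseg.sizing import default_chart_path, load_chart

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def charts():
    """Default (Sapien 3 area, Evolut perimeter) chart pair."""
    return load_chart(default_chart_path("sapien3")), load_chart(default_chart_path("evolut"))


def make_plane(values, spacing=1.0, origin=(0.0, 0.0), center=None):
    values = np.asarray(values, dtype=float)
    if center is None:
        center = (
            origin[0] + (values.shape[1] - 1) / 2.0 * (spacing if np.isscalar(spacing) else spacing[1]),
            origin[1] + (values.shape[0] - 1) / 2.0 * (spacing if np.isscalar(spacing) else spacing[0]),
        )
    return AnnularPlane(values=values, spacing=spacing, origin=origin, annulus_center=center)


def disc_probability_map(radius_mm, n=128, spacing=0.5, center=None, value=1.0):
    """Binary disc probability map centred in an n x n grid."""
    if center is None:
        c = (n - 1) / 2.0 * spacing
        center = (c, c)
    xs = np.arange(n) * spacing
    xx, yy = np.meshgrid(xs, xs)
    vals = np.where(np.hypot(xx - center[0], yy - center[1]) <= radius_mm, value, 0.0)
    return ProbabilityMap(values=vals, spacing=(spacing, spacing), origin=(0.0, 0.0))


def regular_polygon(n, r, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
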