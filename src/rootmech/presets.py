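"""Published reference values: fitted moduli per species/diameter group and
the sample-accounting counts, packaged as fixtures.

Twelve (species, diameter) groups of root tensile tests were fitted with
the one-parameter model; their linear elastic modulus E0 and peak secant
modulus Ep (MPa) are reproduced here together with the published
dimensionless modulus, critical point and residual statistics.  The peak
stress and strain of each group were not published, so presets adopt a
conventional sigma_p (30 MPa) with eps_p = sigma_p/Ep; this scaling leaves
every dimensionless quantity untouched.

Sample accounting covers 22888 pulls in four gauge lengths, of which 6462
used the 50 mm gauge reported throughout.
"""

from __future__ import annotations

from typing import NamedTuple

from .constitutive import RootMaterialParams
from .machine_io import SampleSummaryRow

__all__ = [
    "ModulusRow",
    "MODULUS_TABLE",
    "DEFAULT_SIGMA_P",
    "table2_presets",
    "preset_name",
    "sample_counts_all_gauges",
    "sample_counts_gauge50",
]

#: Conventional peak stress (MPa) used to give presets a dimensional scale.
DEFAULT_SIGMA_P = 30.0


class ModulusRow(NamedTuple):
    """One published group: moduli in MPa, the rest dimensionless."""

    species: str
    diameter_mm: float
    E0: float
    Ep: float
    E_printed: float
    x_e_printed: float
    avg_residual_printed: float
    residual_variance_printed: float
    #: True where the printed E equals E0/Ep at 5 decimals; elsewhere the
    #: printed inputs were evidently rounded after E was computed.
    exact_5dp: bool


MODULUS_TABLE: tuple[ModulusRow, ...] = (
    ModulusRow("Pinus tabulaeformis", 1.11, 150.00, 100.50, 1.49241, 0.39733, 0.02445, 0.00095, False),
    ModulusRow("Pinus tabulaeformis", 2.00, 107.12, 61.46, 1.74292, 0.40057, 0.06534, 0.001366, True),
    ModulusRow("Pinus tabulaeformis", 3.06, 84.06, 52.09, 1.61375, 0.41726, 0.03231, 0.002625, True),
    ModulusRow("Pinus tabulaeformis", 3.90, 81.06, 56.90, 1.42460, 0.55640, 0.081422, 0.017675, True),
    ModulusRow("Larix gmelinii", 2.15, 159.85, 80.06, 1.99673, 0.40986, 0.11016, 0.006868, False),
    ModulusRow("Larix gmelinii", 2.99, 75.40, 39.09, 1.92888, 0.40330, 0.099363, 0.013765, True),
    ModulusRow("Larix gmelinii", 3.98, 74.94, 51.34, 1.45980, 0.62916, 0.138209, 0.01151, False),
    ModulusRow("Betula platyphylla", 1.06, 183.26, 116.93, 1.56715, 0.40629, 0.004367, 0.003816, False),
    ModulusRow("Betula platyphylla", 2.41, 180.67, 93.98, 1.92247, 0.40248, 0.083052, 0.012329, False),
    ModulusRow("Betula platyphylla", 3.03, 180.56, 135.70, 1.33044, 0.59350, 0.051374, 0.001545, False),
    ModulusRow("Quercus mongolica", 2.10, 213.27, 151.08, 1.41163, 0.39885, 0.016976, 0.002841, False),
    ModulusRow("Quercus mongolica", 4.39, 209.96, 122.61, 1.71242, 0.43298, 0.057633, 0.003057, True),
)


def preset_name(species: str, diameter_mm: float) -> str:
    """Canonical preset key, e.g. ``Pinus_tabulaeformis_2.00``."""
    return f"{species.replace(' ', '_')}_{diameter_mm:.2f}"


def table2_presets(sigma_p: float = DEFAULT_SIGMA_P) -> dict[str, RootMaterialParams]:
    """The 12 published groups as specimen parameter sets.

    ``sigma_p`` sets the (unpublished) dimensional scale; eps_p is derived
    as sigma_p/Ep so Ep matches the published value exactly.
    """
    presets: dict[str, RootMaterialParams] = {}
    for row in MODULUS_TABLE:
        presets[preset_name(row.species, row.diameter_mm)] = RootMaterialParams(
            sigma_p=sigma_p, eps_p=sigma_p / row.Ep, E0=row.E0, Ep=row.Ep
        )
    return presets


# (species, diameter scope, total, effective, gauge-50 total, gauge-50 effective)
_SAMPLE_COUNTS = (
    ("Pinus tabulaeformis", "0.5-1.5", 1539, 985, 471, 362),
    ("Pinus tabulaeformis", "1.5-2.5", 2091, 1203, 647, 341),
    ("Pinus tabulaeformis", "2.5-3.5", 2101, 1453, 664, 413),
    ("Pinus tabulaeformis", "3.5-4.5", 2280, 1400, 664, 278),
    ("Larix gmelinii", "1.5-2.5", 1659, 1217, 407, 321),
    ("Larix gmelinii", "2.5-3.5", 2291, 1782, 741, 498),
    ("Larix gmelinii", "3.5-4.5", 2164, 1225, 702, 266),
    ("Betula platyphylla", "0.5-1.5", 1611, 1026, 490, 295),
    ("Betula platyphylla", "1.5-2.5", 2500, 1178, 526, 344),
    ("Betula platyphylla", "2.5-3.5", 1442, 781, 463, 278),
    ("Quercus mongolica", "1.5-2.5", 1516, 872, 687, 299),
    ("Quercus mongolica", "3.5-4.5", 1694, 855, 594, 246),
)


def sample_counts_all_gauges() -> list[SampleSummaryRow]:
    """Published sample counts pooled over all four gauge lengths."""
    return [
        SampleSummaryRow(species=s, diameter_scope=scope, total=t, effective=e)
        for s, scope, t, e, _, _ in _SAMPLE_COUNTS
    ]


def sample_counts_gauge50() -> list[SampleSummaryRow]:
    """Published sample counts restricted to the 50 mm gauge."""
    return [
        SampleSummaryRow(species=s, diameter_scope=scope, total=t50, effective=e50)
        for s, scope, _, _, t50, e50 in _SAMPLE_COUNTS
    ]
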