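"""Stimulus specification in DKL cone-opponent coordinates.

The stimuli this package is built around are colored patches defined in the
cone-opponent (DKL) color space: four hues on the intermediate chromatic
directions (45° pink, 135° blue, 225° green, 315° orange) crossed with two
luminance polarities (a Weber increment, "light", and a decrement, "dark",
relative to a neutral adapting background).  Stimulus strength is expressed
in cone-contrast units: the contrast between two stimuli is
``|dL/sumL| + |dM/sumM|`` over the L and M cone excitations, and is converted
to multiples of a psychophysical detection threshold (0.014 for luminance
contrast, 0.001724 for chromatic contrast).

A full display-calibration chain (xyY -> LMS -> DKL) is deliberately out of
scope; cone excitations are either supplied directly or constructed
abstractly by :func:`canonical_stimulus_set`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "HUES",
    "POLARITIES",
    "AZIMUTH_BY_HUE",
    "SIGN_TABLE",
    "DETECTION_THRESHOLD",
    "StimulusSpec",
    "Background",
    "canonical_stimulus_set",
    "cone_contrast",
    "threshold_units",
    "weber_contrast",
    "read_stimulus_table",
    "write_stimulus_table",
]

HUES = ("pink", "blue", "green", "orange")
POLARITIES = ("light", "dark")

#: DKL azimuth of each hue (degrees); the four intermediate directions.
AZIMUTH_BY_HUE = {"pink": 45.0, "blue": 135.0, "green": 225.0, "orange": 315.0}

#: Sign of the (L-M, S) modulation for each azimuth.
SIGN_TABLE = {
    45.0: (+1, +1),
    135.0: (-1, +1),
    225.0: (-1, -1),
    315.0: (+1, -1),
}

#: Psychophysical detection thresholds in |L|+|M| cone-contrast units.
DETECTION_THRESHOLD = {"luminance": 0.014, "color": 0.001724}

ELEVATION = {"light": +20.0, "dark": -20.0}


@dataclass(frozen=True)
class StimulusSpec:
    """One colored stimulus: label, DKL coordinates and cone excitations."""

    hue: str
    polarity: str
    dkl_azimuth: float
    dkl_elevation: float
    L: float
    M: float
    S: float
    luminance: float

    def __post_init__(self) -> None:
        if self.L <= 0 or self.M <= 0 or self.S <= 0:
            raise ValueError("cone excitations must be strictly positive")

    @property
    def label(self) -> str:
        return f"{self.polarity}_{self.hue}"


@dataclass(frozen=True)
class Background:
    """The neutral adapting background (cone excitations + luminance)."""

    L: float
    M: float
    S: float
    luminance: float = 33.5

    def __post_init__(self) -> None:
        if min(self.L, self.M, self.S, self.luminance) <= 0:
            raise ValueError("background entries must be strictly positive")


def canonical_stimulus_set(
    background: Background,
    lm_modulation: float,
    s_modulation: float,
    lum_contrast: float = 0.25,
) -> list[StimulusSpec]:
    """Construct the canonical 8-stimulus set (4 hues x 2 polarities).

    Each hue's chromatic point displaces the background by ``+-lm_modulation/2``
    on L and M (opposite signs, so the luminance channel L+M is untouched) and
    by ``+-s_modulation`` on S, with the sign pair taken from the azimuth
    table.  The light/dark members scale all three cone excitations of that
    chromatic point by ``1 +- lum_contrast``, so every stimulus has Weber
    luminance contrast exactly ``+-lum_contrast`` against the background and
    the light/dark cone contrast (|dL/sumL|+|dM/sumM| = 2*lum_contrast) is
    matched across hues.

    Parameters
    ----------
    background
        Adapting background cone excitations and luminance.
    lm_modulation
        Absolute L-M modulation, identical for all hues (>= 0).
    s_modulation
        Absolute S modulation, identical for all hues (>= 0).
    lum_contrast
        Weber luminance contrast of every stimulus, in (0, 1).
    """
    if lm_modulation < 0 or s_modulation < 0:
        raise ValueError("modulations must be non-negative")
    if not 0 < lum_contrast < 1:
        raise ValueError("lum_contrast must lie in (0, 1)")

    stimuli = []
    for hue in HUES:
        azimuth = AZIMUTH_BY_HUE[hue]
        sign_lm, sign_s = SIGN_TABLE[azimuth]
        chroma_L = background.L + sign_lm * lm_modulation / 2.0
        chroma_M = background.M - sign_lm * lm_modulation / 2.0
        chroma_S = background.S + sign_s * s_modulation
        if min(chroma_L, chroma_M, chroma_S) <= 0:
            raise ValueError("modulation drives a cone excitation non-positive")
        for polarity in POLARITIES:
            gain = 1.0 + (lum_contrast if polarity == "light" else -lum_contrast)
            stimuli.append(
                StimulusSpec(
                    hue=hue,
                    polarity=polarity,
                    dkl_azimuth=azimuth,
                    dkl_elevation=ELEVATION[polarity],
                    L=chroma_L * gain,
                    M=chroma_M * gain,
                    S=chroma_S * gain,
                    luminance=background.luminance * gain,
                )
            )
    return stimuli


def cone_contrast(a: StimulusSpec, b: StimulusSpec) -> float:
    """Cone contrast |dL/sumL| + |dM/sumM| between two stimuli.

    The S cone is deliberately excluded: the detection-threshold data the
    quotients are referred to are expressed in |L|+|M| units.
    """
    sum_L = a.L + b.L
    sum_M = a.M + b.M
    if sum_L == 0 or sum_M == 0:
        raise ValueError("zero cone-excitation sum; contrast undefined")
    return abs((a.L - b.L) / sum_L) + abs((a.M - b.M) / sum_M)


def threshold_units(contrast: float, mechanism: str) -> float:
    """Express a cone contrast in multiples of the detection threshold.

    ``mechanism`` is ``"luminance"`` (threshold 0.014) or ``"color"``
    (threshold 0.001724).
    """
    if contrast < 0:
        raise ValueError("contrast must be non-negative")
    try:
        thr = DETECTION_THRESHOLD[mechanism]
    except KeyError:
        raise ValueError(f"unknown mechanism {mechanism!r}") from None
    return contrast / thr


def weber_contrast(stim_lum: float, bg_lum: float) -> float:
    """Weber contrast (stim - bg)/bg; the sign encodes luminance polarity."""
    if bg_lum <= 0:
        raise ValueError("background luminance must be positive")
    return (stim_lum - bg_lum) / bg_lum


_TABLE_COLUMNS = [
    "label",
    "azimuth_deg",
    "elevation_deg",
    "L",
    "M",
    "S",
    "luminance_cd_m2",
]


def write_stimulus_table(stimuli: list[StimulusSpec], path: str | Path) -> None:
    """Write a stimulus set as a plain-text TSV table."""
    rows = [
        {
            "label": s.label,
            "azimuth_deg": s.dkl_azimuth,
            "elevation_deg": s.dkl_elevation,
            "L": s.L,
            "M": s.M,
            "S": s.S,
            "luminance_cd_m2": s.luminance,
        }
        for s in stimuli
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_stimulus_table(path: str | Path) -> list[StimulusSpec]:
    """Read a stimulus set written by :func:`write_stimulus_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stimulus table missing columns: {sorted(missing)}")
    stimuli = []
    for row in df.itertuples(index=False):
        polarity, _, hue = row.label.partition("_")
        stimuli.append(
            StimulusSpec(
                hue=hue,
                polarity=polarity,
                dkl_azimuth=float(row.azimuth_deg),
                dkl_elevation=float(row.elevation_deg),
                L=float(row.L),
                M=float(row.M),
                S=float(row.S),
                luminance=float(row.luminance_cd_m2),
            )
        )
    return stimuli
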