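"""Enumeration of the binary decoding problems.

Every analysis in the package is a binary classification between two
condition labels ("light_pink" vs "dark_pink", ...).  Problems come in two
families:

* **polarity** problems decode light vs dark.  Identity problems train and
  test on the same hue; generalization problems train on one hue's light/dark
  pair and test on another hue's pair, probing a hue-invariant representation
  of luminance polarity.
* **hue** problems decode one hue vs another within a fixed polarity.
  Identity problems test at the training polarity; generalization problems
  test at the opposite polarity, with class correspondence by hue name.

Generalization problems are ordered (train -> test): the 4x4 train-hue x
test-hue grid of polarity problems is asymmetric by construction, and
averaged summaries simply average all ordered problems.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

from .colorimetry import AZIMUTH_BY_HUE, HUES, POLARITIES, SIGN_TABLE

__all__ = [
    "ProblemSpec",
    "polarity_problems",
    "hue_problems",
    "polarity_matrix_problems",
    "axes_crossed",
]


def _split(label: str) -> tuple[str, str]:
    polarity, _, hue = label.partition("_")
    if polarity not in POLARITIES or not hue:
        raise ValueError(f"malformed condition label {label!r}")
    return polarity, hue


@dataclass(frozen=True)
class ProblemSpec:
    """A binary decoding problem (ordered train pair -> ordered test pair).

    Class ``k`` of ``test_pair`` corresponds to class ``k`` of ``train_pair``;
    for hue problems generalizing across polarity that correspondence is by
    hue name (light_pink <-> dark_pink).
    """

    id: str
    feature: str  # "polarity" | "hue"
    mode: str  # "identity" | "generalization"
    train_pair: tuple[str, str]
    test_pair: tuple[str, str]

    def __post_init__(self) -> None:
        if self.feature not in ("polarity", "hue"):
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.mode not in ("identity", "generalization"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for pair in (self.train_pair, self.test_pair):
            (p0, h0), (p1, h1) = _split(pair[0]), _split(pair[1])
            if self.feature == "polarity":
                if h0 != h1 or p0 == p1:
                    raise ValueError(
                        f"polarity problem classes must differ only in polarity: {pair}"
                    )
            else:
                if p0 != p1 or h0 == h1:
                    raise ValueError(
                        f"hue problem classes must differ only in hue: {pair}"
                    )
        if (self.mode == "identity") != (self.train_pair == self.test_pair):
            raise ValueError("mode 'identity' iff train_pair == test_pair")

    @property
    def conditions(self) -> tuple[str, ...]:
        """All distinct condition labels the problem touches, train first."""
        seen: dict[str, None] = {}
        for label in (*self.train_pair, *self.test_pair):
            seen.setdefault(label)
        return tuple(seen)


def _polarity_pair(hue: str) -> tuple[str, str]:
    return (f"light_{hue}", f"dark_{hue}")


def polarity_problems(hues: tuple[str, ...] = HUES) -> list[ProblemSpec]:
    """The luminance-polarity problems: H identity + H(H-1) generalization."""
    if len(hues) < 2:
        raise ValueError("need at least 2 hues")
    out = [
        ProblemSpec(
            id=f"pol_id_{h}",
            feature="polarity",
            mode="identity",
            train_pair=_polarity_pair(h),
            test_pair=_polarity_pair(h),
        )
        for h in hues
    ]
    out += [
        ProblemSpec(
            id=f"pol_gen_{a}_to_{b}",
            feature="polarity",
            mode="generalization",
            train_pair=_polarity_pair(a),
            test_pair=_polarity_pair(b),
        )
        for a, b in permutations(hues, 2)
    ]
    return out


def hue_problems(
    hues: tuple[str, ...] = HUES, polarities: tuple[str, ...] = POLARITIES
) -> list[ProblemSpec]:
    """The hue problems: C(H,2)*P identity + C(H,2)*P generalization."""
    if len(hues) < 2:
        raise ValueError("need at least 2 hues")
    out = []
    for h0, h1 in combinations(hues, 2):
        for pol in polarities:
            other = polarities[1 - polarities.index(pol)]
            train = (f"{pol}_{h0}", f"{pol}_{h1}")
            out.append(
                ProblemSpec(
                    id=f"hue_id_{h0}_{h1}_{pol}",
                    feature="hue",
                    mode="identity",
                    train_pair=train,
                    test_pair=train,
                )
            )
            out.append(
                ProblemSpec(
                    id=f"hue_gen_{h0}_{h1}_{pol}_to_{other}",
                    feature="hue",
                    mode="generalization",
                    train_pair=train,
                    test_pair=(f"{other}_{h0}", f"{other}_{h1}"),
                )
            )
    # identity problems first, then generalization, for stable ordering
    return sorted(out, key=lambda p: (p.mode != "identity",))


def polarity_matrix_problems(
    hues: tuple[str, ...] = HUES,
) -> dict[tuple[str, str], ProblemSpec]:
    """Train-hue x test-hue grid of polarity problems (diagonal = identity)."""
    grid: dict[tuple[str, str], ProblemSpec] = {}
    for p in polarity_problems(hues):
        train_hue = _split(p.train_pair[0])[1]
        test_hue = _split(p.test_pair[0])[1]
        grid[(train_hue, test_hue)] = p
    return grid


def axes_crossed(train_hue: str, test_hue: str) -> int:
    """Number of cone-opponent sign axes (L-M, S) that flip between two hues.

    2 means the pair sits across the origin of the chromatic plane
    (pink<->green, blue<->orange), the regime where a purely cone-mechanism-
    linked polarity code cannot generalize.
    """
    s_train = SIGN_TABLE[AZIMUTH_BY_HUE[train_hue]]
    s_test = SIGN_TABLE[AZIMUTH_BY_HUE[test_hue]]
    return sum(a != b for a, b in zip(s_train, s_test))
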