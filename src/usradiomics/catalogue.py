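"""Master catalogue of the 730 texture-feature names.

Each lesion yields 146 features per channel — 14 first-order statistics,
22 gray-level co-occurrence (GLCM) features at 4 angles, and 11 gray-level
run-length (GLRLM) features at 4 angles — on 5 channels: the original
patch and its four one-level wavelet subbands (LL, LH, HL, HH).
146 x 5 = 730.

Names render as ``[subband_]abbrev_index_angle`` (e.g. ``mad_6_0``,
``LL_se_42_90``).  The index is the feature's position in the master
numbering: first-order features occupy 1-14, GLCM features 23-44 and
GLRLM features 45-55.  Positions 15-22 are reserved (unused); keeping
the gap makes published Radiomics Score formulas resolve verbatim
against this registry.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Optional

ANGLES = (0, 45, 90, 135)
SUBBANDS = (None, "LL", "LH", "HL", "HH")

# (abbrev, long name) in catalogue order; indices 1..14
FIRST_ORDER = (
    ("ene", "energy"),
    ("ent", "entropy"),
    ("kur", "kurtosis"),
    ("max", "maximum"),
    ("mea", "mean"),
    ("mad", "mean_absolute_deviation"),
    ("med", "median"),
    ("min", "minimum"),
    ("rng", "range"),
    ("rms", "root_mean_square"),
    ("ske", "skewness"),
    ("std", "standard_deviation"),
    ("uni", "uniformity"),
    ("var", "variance"),
)

# indices 23..44
GLCM = (
    ("acor", "autocorrelation"),
    ("clp", "cluster_prominence"),
    ("cls", "cluster_shade"),
    ("clt", "cluster_tendency"),
    ("con", "contrast"),
    ("cor", "correlation"),
    ("dent", "difference_entropy"),
    ("diss", "dissimilarity"),
    ("ene", "energy"),
    ("ent", "entropy"),
    ("hom1", "homogeneity_1"),
    ("hom2", "homogeneity_2"),
    ("imc1", "informational_measure_of_correlation_1"),
    ("imc2", "informational_measure_of_correlation_2"),
    ("idmn", "inverse_difference_moment_normalized"),
    ("idn", "inverse_difference_normalized"),
    ("ivar", "inverse_variance"),
    ("maxp", "maximum_probability"),
    ("sa", "sum_average"),
    ("se", "sum_entropy"),
    ("sv", "sum_variance"),
    ("var", "variance"),
)

# indices 45..55
GLRLM = (
    ("sre", "short_run_emphasis"),
    ("lre", "long_run_emphasis"),
    ("gln", "gray_level_nonuniformity"),
    ("rln", "run_length_nonuniformity"),
    ("rp", "run_percentage"),
    ("lglre", "low_gray_level_run_emphasis"),
    ("hglre", "high_gray_level_run_emphasis"),
    ("srlgle", "short_run_low_gray_level_emphasis"),
    ("srhgle", "short_run_high_gray_level_emphasis"),
    ("lrlgle", "long_run_low_gray_level_emphasis"),
    ("lrhgle", "long_run_high_gray_level_emphasis"),
)

FIRST_ORDER_BASE = 1
GLCM_BASE = 23
GLRLM_BASE = 45


@dataclass(frozen=True)
class FeatureName:
    """A single catalogue entry; renders to the token used in score formulas."""

    subband: Optional[str]  # None for the original channel
    family: str             # first_order | glcm | glrlm
    abbrev: str
    index: int              # position in the master numbering
    angle: int              # 0 for first-order features

    def __str__(self) -> str:
        prefix = f"{self.subband}_" if self.subband else ""
        return f"{prefix}{self.abbrev}_{self.index}_{self.angle}"


def _build_catalogue() -> tuple[FeatureName, ...]:
    names: list[FeatureName] = []
    for sb in SUBBANDS:
        for k, (abbrev, _) in enumerate(FIRST_ORDER):
            names.append(FeatureName(sb, "first_order", abbrev, FIRST_ORDER_BASE + k, 0))
        for angle in ANGLES:
            for k, (abbrev, _) in enumerate(GLCM):
                names.append(FeatureName(sb, "glcm", abbrev, GLCM_BASE + k, angle))
        for angle in ANGLES:
            for k, (abbrev, _) in enumerate(GLRLM):
                names.append(FeatureName(sb, "glrlm", abbrev, GLRLM_BASE + k, angle))
    return tuple(names)


CATALOGUE: tuple[FeatureName, ...] = _build_catalogue()
CATALOGUE_STRINGS: tuple[str, ...] = tuple(str(n) for n in CATALOGUE)
_BY_STRING = {s: n for s, n in zip(CATALOGUE_STRINGS, CATALOGUE)}

assert len(CATALOGUE) == 730
assert len(_BY_STRING) == 730

_NAME_RE = re.compile(
    r"^(?:(LL|LH|HL|HH)_)?([a-z]+[12]?)_(\d+)_(0|45|90|135)$"
)


def parse(token: str) -> FeatureName:
    """Parse a rendered feature token and resolve it in the catalogue.

    Raises ``KeyError`` if the token does not name a catalogue entry.
    """
    m = _NAME_RE.match(token)
    if m is None:
        raise KeyError(f"unparseable feature name: {token!r}")
    if token not in _BY_STRING:
        raise KeyError(f"feature name not in catalogue: {token!r}")
    return _BY_STRING[token]


def registry() -> list[dict]:
    """The catalogue as plain records (for JSON export)."""
    return [
        {
            "name": str(n),
            "subband": n.subband,
            "family": n.family,
            "abbrev": n.abbrev,
            "index": n.index,
            "angle": n.angle,
        }
        for n in CATALOGUE
    ]


def write_registry(path) -> None:
    with open(path, "w") as fh:
        json.dump(registry(), fh, indent=1)
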