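"""Frequency-band definitions shared across the pipeline.

The six canonical EEG bands used throughout: delta (0.5–4 Hz), theta
(4–8 Hz), alpha (8–13 Hz), beta1 (13–22 Hz), beta2 (22–30 Hz) and gamma
(30–40 Hz). They are non-overlapping and ordered by frequency; that
order is also the deterministic tie-break order used when ranking
band features.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with passband edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"band {self.name!r}: need 0 < low_hz < high_hz, "
                f"got ({self.low_hz}, {self.high_hz})"
            )


CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta1", 13.0, 22.0),
    BandDefinition("beta2", 22.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)

BAND_ORDER: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)

#: rank of each band in the canonical order, for deterministic tie-breaks
BAND_RANK: dict[str, int] = {name: i for i, name in enumerate(BAND_ORDER)}

BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in CANONICAL_BANDS}

#: the three sleep stages the analysis keeps, in fixed report order
STAGE_ORDER: tuple[str, ...] = ("REM", "N2", "N3")

#: the three pairwise stage contrasts, in fixed report order
CLASS_PAIRS: tuple[tuple[str, str], ...] = (("REM", "N2"), ("REM", "N3"), ("N2", "N3"))


def class_pair_label(a: str, b: str) -> str:
    return f"{a}|{b}"
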