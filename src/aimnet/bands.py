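"""Individualized frequency-band definitions anchored to the alpha peak.

Band edges are derived from each subject's individual alpha frequency
(IAF), the 8-12 Hz spectral peak of eyes-closed occipital EEG:

    theta = [IAF - 6, IAF - 3]
    alpha = [IAF - 2, IAF + 2]
    beta  = [IAF + 3, 30]

The beta ceiling is fixed at 30 Hz, the conventional upper beta edge,
consistent with a 40 Hz acquisition low-pass and the 50 Hz analysis
filter.
"""

from __future__ import annotations

from dataclasses import dataclass

BETA_CEILING_HZ = 30.0
BAND_NAMES = ("theta", "alpha", "beta")


@dataclass(frozen=True)
class BandDefinition:
    """One analysis band: a name and its [low, high] edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.name not in BAND_NAMES:
            raise ValueError(f"band name must be one of {BAND_NAMES}, got {self.name!r}")
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low ({self.low}) must be < high ({self.high})")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


def bands_from_iaf(iaf: float) -> tuple[BandDefinition, BandDefinition, BandDefinition]:
    """Theta/alpha/beta band edges for a subject with alpha peak at *iaf* Hz."""
    if not 8.0 <= iaf <= 12.0:
        raise ValueError(f"IAF must lie in [8, 12] Hz, got {iaf}")
    return (
        BandDefinition("theta", iaf - 6.0, iaf - 3.0),
        BandDefinition("alpha", iaf - 2.0, iaf + 2.0),
        BandDefinition("beta", iaf + 3.0, BETA_CEILING_HZ),
    )
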