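"""Marker panel and marker-expression model.

The panel mirrors a 16-antibody CSF immunophenotyping cocktail (CD45, CD14,
CD3, CD19, CD56, HLA-DR, CD4, CD8, CD38, CD27, CD45RA, CD11c, CD127, CD25,
CXCR3, CCR6) plus one side-scatter channel.  Synthetic intensities are
generated directly on a transformed (arcsinh-like) scale as a three-state
location model (negative / positive / high) with a shared spread, so that
hard threshold gating is well-posed by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MARKERS: tuple[str, ...] = (
    "CD45", "CD14", "CD3", "CD19", "CD56", "HLA-DR", "CD4", "CD8",
    "CD38", "CD27", "CD45RA", "CD11c", "CD127", "CD25", "CXCR3", "CCR6",
)

SSC_CHANNEL = "SSC"

#: Channels for which a second ("high") boundary may be defined.
HIGH_CAPABLE_CHANNELS = ("CD27", "CD38", "SSC", "CD127", "CD25")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered 17-channel panel: the 16 markers followed by SSC."""

    channels: tuple[str, ...] = MARKERS + (SSC_CHANNEL,)

    def __post_init__(self) -> None:
        if len(self.channels) != 17:
            raise ValueError(f"panel must have exactly 17 channels, got {len(self.channels)}")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("panel channel names must be unique")
        if self.channels[-1] != SSC_CHANNEL:
            raise ValueError("SSC must be the last panel channel")
        if tuple(self.channels[:-1]) != MARKERS:
            raise ValueError("the 16 fluorescence markers do not match the panel definition")

    @property
    def fluorescence(self) -> tuple[str, ...]:
        return self.channels[:-1]

    def index(self, channel: str) -> int:
        return self.channels.index(channel)


@dataclass(frozen=True)
class ExpressionModel:
    """Per-state locations (transformed-intensity units) for synthetic events.

    ``mu_neg < mu_pos < mu_hi`` with a shared ``sigma``; the positive/negative
    separation is required to be at least 6 sigma so that fixed mid-way
    thresholds misclassify a negligible fraction of events.  SSC uses its own
    two-state (lo/hi) model.
    """

    mu_neg: float = 0.0
    mu_pos: float = 4.0
    mu_hi: float = 6.0
    sigma: float = 0.5
    ssc_mu_lo: float = 0.0
    ssc_mu_hi: float = 6.0
    ssc_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not (self.mu_neg < self.mu_pos < self.mu_hi):
            raise ValueError("expression states must satisfy mu_neg < mu_pos < mu_hi")
        if self.sigma <= 0 or self.ssc_sigma <= 0:
            raise ValueError("sigma must be positive")
        if (self.mu_pos - self.mu_neg) < 6 * self.sigma:
            raise ValueError("pos/neg separation must be at least 6 sigma")

    def locations(self) -> dict[str, float]:
        return {"neg": self.mu_neg, "pos": self.mu_pos, "hi": self.mu_hi}
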